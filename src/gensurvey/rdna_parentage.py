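"""Parental-haplotype classification of rDNA survey reads.

In a recent interspecific hybrid the tandem rDNA arrays have not yet been
homogenized by concerted evolution, so shotgun reads spanning the fast-
evolving ITS2 spacer carry one parental haplotype or the other.  The module
mines rDNA-matching reads, builds a reference-anchored alignment, trims it
to the diagnostic ~150-bp ITS2 block (removing columns gapped in more than
95 % of rows — indel noise concentrates in homopolymers), and assigns every
read to its nearest haplotype by substitution distance over shared columns.
Full Bayesian tree inference is deliberately exported (NEXUS) rather than
re-implemented: the biological question — a bipartition of reads between two
parents — is answered by the distance classification.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

from .micro_aligner import AlignerParams, SubjectIndex, align_indexed, best_hit
from .sequence_io import SurveyRead

log = logging.getLogger("gensurvey")


@dataclass
class ITSBlock:
    """A trimmed, reference-anchored multiple alignment.

    ``anchor_pos[k]`` is the anchor coordinate consumed by column k (or None
    for an insertion column, in which case ``insert_before[k]`` names the
    anchor coordinate the insertion precedes).  ``coverage`` maps each row id
    to its aligned anchor interval (0-based half-open).
    """

    ids: list[str]
    origins: list[str]                 # 'reference' or 'read' per row
    rows: list[str]
    anchor_pos: list[int | None]
    insert_before: list[int | None]
    coverage: dict[str, tuple[int, int]]
    anchor_id: str

    def __post_init__(self):
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, row_id: str) -> str:
        return self.rows[self.ids.index(row_id)]


@dataclass
class ParentageCall:
    read_id: str
    assigned_haplotype: str            # reference id or 'ambiguous'
    distance_to_best: int
    distance_to_second: int

    def __post_init__(self):
        if self.distance_to_best > self.distance_to_second:
            raise ValueError("best distance exceeds second-best distance")


def mine_rdna_reads(reads: list[SurveyRead], rdna_refs,
                    min_identity: float = 0.90,
                    params: AlignerParams | None = None) -> list[SurveyRead]:
    """Reads aligning to any rDNA reference at >= ``min_identity``."""
    if not rdna_refs:
        raise ValueError("rDNA reference set is empty")
    params = params or AlignerParams()
    indexes = [SubjectIndex(i, s, params.word_size) for i, s in rdna_refs]
    mined = []
    per_anchor = Counter()
    for read in reads:
        hit = False
        for index in indexes:
            recs = align_indexed(read.read_id, read.sequence, index, params)
            if any(r.percent_identity / 100.0 >= min_identity for r in recs):
                per_anchor[index.subject_id] += 1
                hit = True
        if hit:
            mined.append(read)
    log.info("rDNA mining: %d of %d reads matched (%s)", len(mined),
             len(reads), dict(per_anchor))
    return mined


def build_its_alignment(mined_reads: list[SurveyRead], refs,
                        anchor_id: str | None = None,
                        min_overlap: int = 50, min_identity: float = 0.80,
                        params: AlignerParams | None = None) -> ITSBlock:
    """Reference-anchored multiple alignment of reads and reference sequences.

    Every sequence is placed by its best local alignment to the designated
    anchor; insertions relative to the anchor open shared gap columns.
    Sequences failing the overlap/identity gate are dropped with the reason
    logged; an alignment containing no read at all is an error.
    """
    params = params or AlignerParams()
    refs = list(refs)
    if anchor_id is None:
        anchor_id = refs[0][0]
    anchor_seq = dict(refs)[anchor_id]
    index = SubjectIndex(anchor_id, anchor_seq, params.word_size)

    entries = [(rid, seq, "reference") for rid, seq in refs if rid != anchor_id]
    entries += [(r.read_id, r.sequence, "read") for r in mined_reads]

    placed = []   # (id, origin, cover_lo, cover_hi, bases{j: ch}, ins{j: str})
    for rid, seq, origin in entries:
        rec = best_hit(align_indexed(rid, seq, index, params))
        if rec is None:
            log.info("dropped %s: no alignment to anchor %s", rid, anchor_id)
            continue
        if rec.alignment_length_bp < min_overlap:
            log.info("dropped %s: overlap %d < %d", rid,
                     rec.alignment_length_bp, min_overlap)
            continue
        if rec.percent_identity / 100.0 < min_identity:
            log.info("dropped %s: identity %.1f%% below %.0f%%", rid,
                     rec.percent_identity, min_identity * 100)
            continue
        slo = min(rec.subject_start, rec.subject_end) - 1
        bases: dict[int, str] = {}
        ins: dict[int, str] = {}
        j = slo
        for qc, sc in zip(rec.query_aln, rec.subject_aln):
            if sc != "-":
                bases[j] = qc
                j += 1
            else:
                ins[j] = ins.get(j, "") + qc
        placed.append((rid, origin, slo, j, bases, ins))

    if not any(origin == "read" for _, origin, *_ in placed):
        raise ValueError("no read passed the overlap/identity gate: "
                         "empty alignment")

    ins_width: dict[int, int] = {}
    for _, _, _, _, _, ins in placed:
        for j, s in ins.items():
            ins_width[j] = max(ins_width.get(j, 0), len(s))

    ids = [anchor_id] + [p[0] for p in placed]
    origins = ["reference"] + [p[1] for p in placed]
    coverage = {anchor_id: (0, len(anchor_seq))}
    for rid, _, lo, hi, _, _ in placed:
        coverage[rid] = (lo, hi)

    anchor_pos: list[int | None] = []
    insert_before: list[int | None] = []
    rows = [[] for _ in ids]
    for j in range(len(anchor_seq) + 1):
        w = ins_width.get(j, 0)
        if w:
            for k in range(w):
                anchor_pos.append(None)
                insert_before.append(j)
            rows[0].append("-" * w)
            for r, (_, _, lo, hi, bases, ins) in enumerate(placed, start=1):
                s = ins.get(j, "")
                rows[r].append("-" * (w - len(s)) + s)
        if j < len(anchor_seq):
            anchor_pos.append(j)
            insert_before.append(None)
            rows[0].append(anchor_seq[j])
            for r, (_, _, lo, hi, bases, ins) in enumerate(placed, start=1):
                rows[r].append(bases.get(j, "-"))
    return ITSBlock(ids=ids, origins=origins,
                    rows=["".join(r) for r in rows],
                    anchor_pos=anchor_pos, insert_before=insert_before,
                    coverage=coverage, anchor_id=anchor_id)


def trim_block(block: ITSBlock, region: tuple[int, int],
               gap_column_threshold: float = 0.95,
               drop_n_reads: bool = True) -> ITSBlock:
    """Trim an anchored alignment to a diagnostic region.

    Columns outside ``region`` (anchor coordinates, 0-based half-open) are
    cut; rows whose aligned interval does not fully span the region are
    dropped, as are read rows containing ``N`` inside it (no quality scores
    exist, so any ambiguous call disqualifies a read); finally columns gapped
    in strictly more than ``gap_column_threshold`` of the remaining rows are
    removed.  Idempotent for a fixed region.
    """
    start, end = region
    n_anchor_cols = sum(p is not None for p in block.anchor_pos)
    max_anchor = max((p for p in block.anchor_pos if p is not None),
                     default=-1)
    if end - start > max(n_anchor_cols, max_anchor + 1):
        raise ValueError(
            f"region {region} longer than the aligned anchor span")
    if start < 0 or end <= start:
        raise ValueError(f"bad region {region}")

    keep_cols = [k for k in range(block.n_columns)
                 if (block.anchor_pos[k] is not None
                     and start <= block.anchor_pos[k] < end)
                 or (block.insert_before[k] is not None
                     and start < block.insert_before[k] < end)]

    keep_rows = []
    for r, rid in enumerate(block.ids):
        lo, hi = block.coverage[rid]
        if lo > start or hi < end:
            log.info("trim: dropped %s (covers %d-%d, region %d-%d)",
                     rid, lo, hi, start, end)
            continue
        slice_ = "".join(block.rows[r][k] for k in keep_cols)
        if drop_n_reads and block.origins[r] == "read" and "N" in slice_:
            log.info("trim: dropped %s (ambiguous base in block)", rid)
            continue
        keep_rows.append(r)

    n_rows = len(keep_rows)
    final_cols = []
    for k in keep_cols:
        gaps = sum(1 for r in keep_rows if block.rows[r][k] == "-")
        if n_rows and gaps / n_rows > gap_column_threshold:
            continue
        final_cols.append(k)

    return ITSBlock(
        ids=[block.ids[r] for r in keep_rows],
        origins=[block.origins[r] for r in keep_rows],
        rows=["".join(block.rows[r][k] for k in final_cols)
              for r in keep_rows],
        anchor_pos=[block.anchor_pos[k] for k in final_cols],
        insert_before=[block.insert_before[k] for k in final_cols],
        coverage={rid: block.coverage[rid]
                  for rid in (block.ids[r] for r in keep_rows)},
        anchor_id=block.anchor_id,
    )


def classify_parentage(block: ITSBlock, haplotype_ids: list[str]):
    """Assign each read row to its nearest haplotype reference.

    Distance is the substitution count over columns where both the read and
    the haplotype carry an unambiguous base; a strict minimum is required —
    equidistant reads are called ``ambiguous``.  Returns
    ``(calls, tallies)``.
    """
    if len(haplotype_ids) < 2:
        raise ValueError("need >= 2 haplotype references")
    hap_rows = {h: block.row(h) for h in haplotype_ids}
    pairs_differ = False
    for i, a in enumerate(haplotype_ids):
        for b in haplotype_ids[i + 1:]:
            if any(x != y and x in "ACGT" and y in "ACGT"
                   for x, y in zip(hap_rows[a], hap_rows[b])):
                pairs_differ = True
    if not pairs_differ:
        raise ValueError("haplotype references are identical within the "
                         "block: no discriminating sites")

    calls = []
    tallies = Counter()
    for r, rid in enumerate(block.ids):
        if block.origins[r] != "read":
            continue
        row = block.rows[r]
        dists = []
        for h in haplotype_ids:
            hap = hap_rows[h]
            d = sum(1 for x, y in zip(row, hap)
                    if x in "ACGT" and y in "ACGT" and x != y)
            dists.append((d, h))
        dists.sort()
        (d1, h1), (d2, _) = dists[0], dists[1]
        assigned = h1 if d1 < d2 else "ambiguous"
        calls.append(ParentageCall(rid, assigned, d1, d2))
        tallies[assigned] += 1
    return calls, dict(tallies)


def write_nexus(block: ITSBlock, path) -> Path:
    """Write the block as a NEXUS DATA matrix (datatype DNA, gap '-')."""
    if not block.rows:
        raise ValueError("empty block")
    path = Path(path)
    matrix = dendropy.DnaCharacterMatrix.from_dict(
        {rid: row for rid, row in zip(block.ids, block.rows)})
    matrix.write(path=str(path), schema="nexus")
    return path


def read_nexus(path) -> dict[str, str]:
    """Read a NEXUS DNA matrix back as an id -> row mapping."""
    matrix = dendropy.DnaCharacterMatrix.get(path=str(path), schema="nexus")
    return {taxon.label: str(matrix[taxon]).replace(" ", "")
            for taxon in matrix.taxon_namespace}
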