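"""Read-set statistics, genome-size and coverage arithmetic, contamination
screening, identity histograms, and the gene-space / exon-space estimators.

Rounding conventions are pinned per quantity because the printed values of a
survey report are only reproducible under specific rules: contamination
percentages are truncated to 2 decimals, the 3C genome size is rounded to the
nearest 0.5 Gbp and the per-haploid size to 2 significant figures, the coding
percentage to 1 decimal, and per-subgenome locus counts to the nearest 1,000.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .micro_aligner import AlignerParams, SubjectIndex, align_indexed, best_hit
from .sequence_io import SurveyRead

log = logging.getLogger("gensurvey")


@dataclass
class GenomeSizeParams:
    """Flow-cytometry DNA contents (pg) and the pg-to-Mbp conversion."""

    pg_values: list[float]
    mbp_per_pg: float = 980.0
    ploidy: int = 3

    def __post_init__(self):
        if not self.pg_values:
            raise ValueError("pg_values must be non-empty")
        if any(v <= 0 for v in self.pg_values):
            raise ValueError("pg_values must be positive")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")


@dataclass
class GeneContentParams:
    """Parameters of the exon-space and gene-content chain.

    E: mean exon length; L: mean read length; m: minimum read-exon overlap
    required for a full-length alignment call; G: effective genome size.
    """

    mean_exon_bp: float = 250.0
    mean_read_bp: float = 229.0
    min_overlap_bp: float = 50.0
    mean_cds_bp: float = 1500.0
    effective_genome_bp: float | None = None
    n_subgenomes: int = 3

    def __post_init__(self):
        if self.mean_exon_bp <= 0 or self.mean_read_bp <= 0:
            raise ValueError("exon and read lengths must be positive")
        if 2 * self.min_overlap_bp >= self.mean_exon_bp + self.mean_read_bp:
            raise ValueError("2*min_overlap must be < exon + read length")


def truncate_pct(fraction: float, decimals: int = 2) -> float:
    """Truncate (not round) a fraction expressed as a percentage."""
    scale = 10 ** decimals
    return math.floor(fraction * 100 * scale) / scale


def read_stats(reads: list[SurveyRead]):
    """Count, total bp, mean length and GC fraction of a read set.

    GC counts G+C over A+C+G+T; N and ambiguity codes are excluded from both
    numerator and denominator (but still count toward lengths).
    """
    if not reads:
        raise ValueError("read set is empty")
    lengths = np.array([r.length_bp for r in reads])
    gc = acgt = 0
    for r in reads:
        for b in "ACGT":
            n = r.sequence.count(b)
            acgt += n
            if b in "GC":
                gc += n
    return {
        "count": len(reads),
        "total_bp": int(lengths.sum()),
        "mean_length_bp": float(lengths.mean()),
        "gc_fraction": gc / acgt if acgt else float("nan"),
    }


def genome_size_from_pg(params: GenomeSizeParams):
    """3C genome size from flow-cytometry pg values.

    Total = mean(pg) * Mbp/pg / 1000 (Gbp), rounded to the nearest 0.5 Gbp;
    per-haploid = total / ploidy, rounded to 2 significant figures.
    """
    total = float(np.mean(params.pg_values)) * params.mbp_per_pg / 1000.0
    per_haploid = total / params.ploidy
    return {
        "total_gbp": total,
        "total_gbp_rounded": round(total * 2) / 2,
        "per_haploid_gbp": per_haploid,
        "per_haploid_gbp_rounded": float(f"{per_haploid:.2g}"),
    }


def coverage_estimate(total_read_bp: float, effective_genome_bp: float):
    """Survey coverage fraction c = read bp / effective genome bp."""
    if effective_genome_bp <= 0:
        raise ValueError("effective genome size must be positive")
    if total_read_bp < 0:
        raise ValueError("total read bp must be non-negative")
    c = total_read_bp / effective_genome_bp
    return {"coverage": c, "coverage_pct": c * 100}


def contamination_screen(reads: list[SurveyRead], organelle_refs,
                         evalue_cutoff: float = 1e-6,
                         params: AlignerParams | None = None) -> pd.DataFrame:
    """Count reads hitting each organelle reference below an e-value cutoff.

    A read counts once per reference class; the percentage is truncated to
    2 decimals (matching how maximum-contamination values are reported).
    """
    if not organelle_refs:
        raise ValueError("organelle reference set is empty")
    params = params or AlignerParams()
    rows = []
    for ref_id, ref_seq in organelle_refs:
        index = SubjectIndex(ref_id, ref_seq, params.word_size)
        n_hit = 0
        for r in reads:
            recs = align_indexed(r.read_id, r.sequence, index, params)
            if any(rec.e_value <= evalue_cutoff for rec in recs):
                n_hit += 1
        rows.append({
            "reference": ref_id,
            "hit_count": n_hit,
            "percent": truncate_pct(n_hit / len(reads)) if reads else 0.0,
        })
    return pd.DataFrame(rows)


def identity_histogram(alignments, n_reads: int,
                       bin_width: float = 1.0) -> pd.DataFrame:
    """Fraction of all reads per percent-identity bin over [75, 100].

    Each read contributes its single best alignment (highest bit score,
    ties resolved toward higher identity); bin fractions sum to the total
    matched-read fraction.
    """
    by_query: dict[str, list] = {}
    for rec in alignments:
        by_query.setdefault(rec.query_id, []).append(rec)
    idents = [best_hit(recs).percent_identity for recs in by_query.values()]
    edges = np.arange(75.0, 100.0 + bin_width, bin_width)
    if not idents:
        return pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:],
                             "fraction": np.zeros(len(edges) - 1)})
    counts, _ = np.histogram(idents, bins=edges)
    return pd.DataFrame({
        "bin_low": edges[:-1],
        "bin_high": edges[1:],
        "fraction": counts / n_reads,
    })


def gene_space_reads(reads: list[SurveyRead], cds_set, repeat_library,
                     identity_window: tuple[float, float] = (94.0, 99.0),
                     evalue_cutoff: float = 1e-6,
                     params: AlignerParams | None = None):
    """Reads whose best hit to repeat-filtered coding sequence falls in the
    identity window (inclusive at both ends, exclusive of everything else).

    Coding entries hitting the repeat library at e <= cutoff are removed
    before read matching.  Returns ``(selected_reads, fraction_of_all_reads)``.
    """
    if not cds_set:
        raise ValueError("coding sequence set is empty")
    params = params or AlignerParams()
    lib_indexes = [SubjectIndex(i, s, params.word_size) for i, s in repeat_library]
    filtered = []
    for cid, cseq in cds_set:
        repeat_like = False
        for index in lib_indexes:
            recs = align_indexed(cid, cseq, index, params)
            if any(r.e_value <= evalue_cutoff for r in recs):
                repeat_like = True
                break
        if not repeat_like:
            filtered.append((cid, cseq))
    if not filtered:
        raise ValueError(
            "repeat filtering removed every coding sequence; "
            "no gene-space targets remain")
    cds_indexes = [SubjectIndex(i, s, params.word_size) for i, s in filtered]
    lo, hi = identity_window
    selected = []
    for r in reads:
        recs = []
        for index in cds_indexes:
            recs.extend(align_indexed(r.read_id, r.sequence, index, params))
        top = best_hit(recs)
        if top is not None and lo <= top.percent_identity <= hi:
            selected.append(r)
    return selected, len(selected) / len(reads) if reads else 0.0


def exon_space_fraction(params: GeneContentParams):
    """Fraction of coding-matching read sequence expected to lie in exons.

    f = E / (E + L - 2m): a read is called coding when it overlaps an exon by
    at least m bp, so the window of qualifying read starts spans E + L - 2m
    around an exon of length E, of which E is exonic.
    """
    denom = (params.mean_exon_bp + params.mean_read_bp
             - 2 * params.min_overlap_bp)
    if denom <= 0:
        raise ValueError("E + L - 2m must be positive")
    f = params.mean_exon_bp / denom
    return {"fraction": f, "percent_rounded": int(round(f * 100))}


def gene_content_estimate(coding_read_fraction: float,
                          params: GeneContentParams):
    """Chain from coding-read fraction to genome-wide gene-content numbers.

    coding % = coding-read fraction x exon-space fraction (1 decimal);
    coding bp = coding % x G; loci = coding bp / mean CDS bp;
    per-subgenome loci rounded to the nearest 1,000.
    """
    if not 0.0 <= coding_read_fraction <= 1.0:
        raise ValueError("coding_read_fraction must lie in [0, 1]")
    if params.effective_genome_bp is None:
        raise ValueError("effective_genome_bp is unset")
    f_exon = exon_space_fraction(params)["fraction"]
    coding_pct = round(coding_read_fraction * f_exon * 100, 1)
    coding_bp = coding_pct / 100.0 * params.effective_genome_bp
    loci_total = coding_bp / params.mean_cds_bp
    per_subgenome = round(loci_total / params.n_subgenomes / 1000) * 1000
    return {
        "coding_fraction_pct": coding_pct,
        "coding_bp": coding_bp,
        "loci_total": loci_total,
        "loci_per_subgenome": per_subgenome,
    }
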