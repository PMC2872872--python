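"""Non-cognate assembly: cluster overlapping survey reads into repeat families.

At sub-1x coverage two reads only overlap, with appreciable probability, when
they derive from a sequence present in many copies; connected components of
the exact-overlap graph are therefore repeat-family representatives, not
genuine assemblies.  Components of three or more reads are reported, their
consensus called by per-column majority over a greedy maximum-spanning-tree
layout, and the >= 3-read threshold is justified by Lander-Waterman island
statistics (``cluster_significance``).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .micro_aligner import AlignerParams, SubjectIndex, align_indexed, best_hit
from .sequence_io import SurveyRead, revcomp
from .synthetic_data import REPEAT_CLASSES

log = logging.getLogger("gensurvey")


@dataclass
class OverlapEdge:
    """Ungapped overlap between two reads (ids sorted), either orientation.

    ``offset`` places read ``b`` (reverse-complemented when ``rc``) relative
    to the start of read ``a``.
    """

    a: str
    b: str
    rc: bool
    offset: int
    overlap_len: int
    identity: float


@dataclass
class RepeatCluster:
    cluster_id: str
    member_read_ids: list[str]
    consensus: str
    repeat_class: str = "unannotated"
    best_library_hit: tuple[str, float] | None = None

    @property
    def length_bp(self) -> int:
        return len(self.consensus)


@dataclass
class ClusterSignificance:
    k: int
    p_null: float
    p_null_closed_form: float
    mc_standard_error: float

    @property
    def p_multicopy(self) -> float:
        return 1.0 - self.p_null


def _overlap_identity(a: str, b: str, lo: int, hi: int, off: int):
    """Identity of the ungapped overlap of b (at offset off) with a."""
    n = hi - lo
    matches = 0
    for x in range(lo, hi):
        ca, cb = a[x], b[x - off]
        if ca == cb and ca in "ACGT":
            matches += 1
    return matches / n if n else 0.0


def overlap_graph(reads: list[SurveyRead], min_overlap_bp: int = 14,
                  overlap_identity: float = 1.0) -> list[OverlapEdge]:
    """All pairwise suffix/prefix or containment overlaps, either orientation.

    An edge joins two reads when some ungapped offset gives an overlap of at
    least ``min_overlap_bp`` bases at identity >= ``overlap_identity``.
    Candidate offsets come from shared exact words of length
    ``min_overlap_bp`` (identity 1.0; detection is then exhaustive) or a
    shorter seed when mismatches are tolerated.
    """
    reads = sorted(reads, key=lambda r: r.read_id)
    seqs = [r.sequence for r in reads]
    ids = [r.read_id for r in reads]
    k = min_overlap_bp if overlap_identity >= 1.0 else max(8, min_overlap_bp // 2)

    index: dict[str, list[tuple[int, int]]] = {}
    for j, seq in enumerate(seqs):
        for p in range(len(seq) - k + 1):
            word = seq[p:p + k]
            if "N" in word:
                continue
            index.setdefault(word, []).append((j, p))

    best: dict[tuple[int, int], OverlapEdge] = {}
    for i, seq in enumerate(seqs):
        la = len(seq)
        cands: set[tuple[int, bool, int]] = set()
        for p in range(la - k + 1):
            word = seq[p:p + k]
            if "N" in word:
                continue
            for j, pj in index.get(word, ()):
                if j != i:
                    cands.add((j, False, p - pj))
        rc_seq = revcomp(seq)
        for p in range(la - k + 1):
            word = rc_seq[p:p + k]
            if "N" in word:
                continue
            for j, pj in index.get(word, ()):
                if j == i:
                    continue
                # rc(seq_i)[p..] == seq_j[pj..]  =>  rc(seq_j) sits at this
                # offset in i's forward frame
                off = (la - k - p) - (len(seqs[j]) - k - pj)
                cands.add((j, True, off))
        for j, rc, off in cands:
            if j < i:
                continue  # handled from the smaller index
            b = revcomp(seqs[j]) if rc else seqs[j]
            lo, hi = max(0, off), min(la, off + len(b))
            if hi - lo < min_overlap_bp:
                continue
            ident = _overlap_identity(seq, b, lo, hi, off)
            if ident + 1e-12 < overlap_identity:
                continue
            edge = OverlapEdge(ids[i], ids[j], rc, off, hi - lo, ident)
            key = (i, j)
            cur = best.get(key)
            if cur is None or (edge.overlap_len, edge.identity, -abs(edge.offset)) \
                    > (cur.overlap_len, cur.identity, -abs(cur.offset)):
                best[key] = edge
    return [best[key] for key in sorted(best)]


def _layout_component(members: list[str], edges: list[OverlapEdge],
                      seq_of: dict[str, str]):
    """Greedy layout: maximum-spanning forest over overlap length.

    Returns ``{read_id: (position, flipped)}``; edges closing a cycle are
    dropped (the weakest-overlap side of any inconsistency), which splits
    nothing here because the spanning tree keeps the component connected.
    """
    edges = sorted(edges, key=lambda e: (-e.overlap_len, -e.identity, e.a, e.b))
    parent = {m: m for m in members}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    adj: dict[str, list[OverlapEdge]] = {m: [] for m in members}
    for e in edges:
        ra, rb = find(e.a), find(e.b)
        if ra == rb:
            continue
        parent[ra] = rb
        adj[e.a].append(e)
        adj[e.b].append(e)

    # Edge semantics: b (rc'd when e.rc) starts at e.offset in a's forward
    # frame.  With a placed at (p_a, f_a):
    #   f_b = f_a ^ e.rc
    #   p_b = p_a + offset                      when f_a is False
    #   p_b = p_a + len(a) - offset - len(b)    when f_a is True
    root = min(members)
    place = {root: (0, False)}
    stack = [root]
    while stack:
        cur = stack.pop()
        p_cur, f_cur = place[cur]
        for e in adj[cur]:
            other = e.b if e.a == cur else e.a
            if other in place:
                continue
            la, lb = len(seq_of[e.a]), len(seq_of[e.b])
            if e.a == cur:
                f_b = f_cur ^ e.rc
                p_b = p_cur + e.offset if not f_cur \
                    else p_cur + la - e.offset - lb
                place[other] = (p_b, f_b)
            else:
                f_a = f_cur ^ e.rc          # invert: cur is b, place a
                p_a = p_cur - e.offset if not f_a \
                    else p_cur - la + e.offset + lb
                place[other] = (p_a, f_a)
            stack.append(other)
    return place


def cluster_and_consensus(edges: list[OverlapEdge],
                          reads: list[SurveyRead],
                          min_members: int = 3) -> list[RepeatCluster]:
    """Connected components of >= ``min_members`` reads with majority consensus.

    Reads are placed by a greedy strongest-overlap-first spanning-tree layout;
    the consensus is the per-column majority base, with columns supported by
    fewer than two reads trimmed from the ends.  Output is invariant to read
    input order (everything is sorted canonically).
    """
    seq_of = {r.read_id: r.sequence for r in reads}
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.a, e.b)
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= min_members]
    comps.sort(key=lambda c: (-len(c), c[0]))

    clusters = []
    for ci, members in enumerate(comps):
        mset = set(members)
        comp_edges = [e for e in edges if e.a in mset and e.b in mset]
        place = _layout_component(members, comp_edges, seq_of)
        lo = min(p for p, _ in place.values())
        span = max(p + len(seq_of[m]) for m, (p, _) in place.items()) - lo
        counts = np.zeros((4, span), dtype=np.int32)
        cover = np.zeros(span, dtype=np.int32)
        basemap = {b: i for i, b in enumerate("ACGT")}
        for m in members:
            p, flipped = place[m]
            seq = revcomp(seq_of[m]) if flipped else seq_of[m]
            p -= lo
            for x, ch in enumerate(seq):
                bi = basemap.get(ch)
                if bi is not None:
                    counts[bi, p + x] += 1
                cover[p + x] += 1
        # majority base; ties resolve to the lexicographically first base
        cons = np.array(list("ACGT"))[counts.argmax(axis=0)]
        cons[counts.sum(axis=0) == 0] = "N"
        supported = np.flatnonzero(cover >= 2)
        if supported.size == 0:
            continue
        cons = cons[supported.min():supported.max() + 1]
        clusters.append(RepeatCluster(
            cluster_id=f"C{ci + 1:05d}",
            member_read_ids=members,
            consensus="".join(cons),
        ))
    return clusters


def cluster_significance(k: int, c: float, mean_read_bp: float,
                         min_overlap_bp: float, n_reads: int, genome_bp: float,
                         n_sim: int = 10_000,
                         seed: int = 0) -> ClusterSignificance:
    """Probability that >= k reads chain together at a single-copy locus.

    Monte-Carlo: drop ``n_reads`` reads uniformly on a single-copy genome and
    record whether any k reads are mutually chained by >= ``min_overlap_bp``
    overlaps.  The closed form is the Lander-Waterman island-size tail
    (islands as a Poisson process of apparent islands of >= k reads):
    ``p = 1 - exp(-N * e^(-a*t) * (1 - e^(-a*t))^(k-1))`` with
    ``t = L - T`` the maximum chaining gap and ``a = N/G`` the read-start
    rate.  ``c`` is accepted for the caller's bookkeeping (c = N*L/G).
    """
    if k < 1 or n_reads < 1 or genome_bp <= 0 or mean_read_bp <= 0:
        raise ValueError("k, read count and lengths must be positive")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for a usable standard error")
    if k == 1:
        return ClusterSignificance(k, 1.0, 1.0, 0.0)
    t = mean_read_bp - min_overlap_bp
    if t <= 0:
        raise ValueError("min_overlap_bp must be smaller than the read length")
    a = n_reads / genome_bp
    mu = n_reads * math.exp(-a * t) * (1.0 - math.exp(-a * t)) ** (k - 1)
    p_closed = 1.0 - math.exp(-mu)

    rng = np.random.default_rng(seed)
    starts = rng.random((n_sim, n_reads)) * (genome_bp - mean_read_bp)
    starts.sort(axis=1)
    gaps_ok = np.diff(starts, axis=1) <= t
    # longest run of consecutive chained gaps per replicate
    hit = np.zeros(n_sim, dtype=bool)
    run = np.zeros(n_sim, dtype=np.int32)
    for j in range(gaps_ok.shape[1]):
        run = np.where(gaps_ok[:, j], run + 1, 0)
        hit |= run >= (k - 1)
    p_mc = float(hit.mean())
    se = math.sqrt(max(p_mc * (1 - p_mc), 1e-12) / n_sim)
    return ClusterSignificance(k, p_mc, p_closed, se)


def parse_class_code(library_id: str) -> str | None:
    """Class code prefix of a library identifier (grammar: CLASS|family|...)."""
    code = library_id.split("|")[0]
    return code if code in REPEAT_CLASSES else None


def classify_clusters(clusters: list[RepeatCluster], repeat_library,
                      evalue_cutoff: float = 1e-6,
                      params: AlignerParams | None = None) -> list[RepeatCluster]:
    """Assign each cluster the class code of its best library hit.

    Library identifiers must carry a parseable class code prefix
    (``CLASS|family|...``); hits whose id lacks one classify as
    ``unclassified``; clusters with no hit at e <= cutoff stay
    ``unannotated``.  Classes are written in place and the list returned.
    """
    params = params or AlignerParams()
    indexes = [SubjectIndex(i, s, params.word_size) for i, s in repeat_library]
    for cl in clusters:
        recs = []
        for index in indexes:
            recs.extend(align_indexed(cl.cluster_id, cl.consensus, index, params))
        recs = [r for r in recs if r.e_value <= evalue_cutoff]
        top = best_hit(recs)
        if top is None:
            cl.repeat_class = "unannotated"
            cl.best_library_hit = None
            continue
        cl.best_library_hit = (top.subject_id, top.e_value)
        code = parse_class_code(top.subject_id)
        if code is None:
            log.warning("library id %r carries no parseable class code",
                        top.subject_id)
            cl.repeat_class = "unclassified"
        else:
            cl.repeat_class = code
    return clusters


def class_composition(clusters: list[RepeatCluster]):
    """Per-class cluster counts and fractions (composition-table data)."""
    import pandas as pd

    counts = Counter(cl.repeat_class for cl in clusters)
    total = sum(counts.values())
    return pd.DataFrame(
        [{"repeat_class": k, "clusters": v, "fraction": v / total}
         for k, v in sorted(counts.items())])


def novelty_screen(clusters: list[RepeatCluster], reference_set,
                   evalue_cutoff: float = 1e-6,
                   params: AlignerParams | None = None):
    """Partition clusters into known/novel by presence of a reference hit."""
    if not reference_set:
        raise ValueError("reference set is empty")
    params = params or AlignerParams()
    indexes = [SubjectIndex(i, s, params.word_size) for i, s in reference_set]
    known, novel = [], []
    for cl in clusters:
        found = False
        for index in indexes:
            recs = align_indexed(cl.cluster_id, cl.consensus, index, params)
            if any(r.e_value <= evalue_cutoff for r in recs):
                found = True
                break
        (known if found else novel).append(cl)
    return {"known": known, "novel": novel,
            "n_known": len(known), "n_novel": len(novel)}
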