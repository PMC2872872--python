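"""Seed-and-extend local nucleotide aligner.

One seeded aligner plays the candidate-detection and exact-local-alignment
roles that desk-scale pipelines usually delegate to BLAT/blastz/BLASTN:
exact word seeding on an indexed subject, grouping of seeds into diagonal
bands, and an affine-gap Smith-Waterman extension restricted to a window
around each band.  Scores are integers on an internal x100 scale
(match +100, mismatch -100); a gap of length g costs open + g*extend.
``N`` (and any IUPAC ambiguity code) aligns to nothing: it never seeds and
always scores as a mismatch.

E-values follow the ungapped Karlin-Altschul formula E = K*m*n*exp(-lambda*S)
with S the raw score in match units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import AlignmentRecord, revcomp

log = logging.getLogger("gensurvey")

_SCALE = 100

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def encode(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3 and every other code as 4 (never matches)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class AlignerParams:
    word_size: int = 11
    min_score: float = 30.0          # raw score, match units
    gap_open: float = 400.0          # internal x100 scale
    gap_extend: float = 30.0         # internal x100 scale
    match: float = 1.0               # match units; x100 internally
    mismatch: float = -1.0
    karlin_K: float = 0.711
    karlin_lambda: float = 1.37
    min_identity: float = 0.0        # fraction of alignment columns
    both_strands: bool = True
    band_pad: int = 48               # window padding around a seed band

    def __post_init__(self):
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


def evalue(score: float, query_len: int, db_len: int,
           params: AlignerParams | None = None) -> float:
    """Karlin-Altschul expectation for a raw local-alignment score.

    Strictly decreasing in ``score`` and strictly increasing in
    ``query_len * db_len``.
    """
    params = params or AlignerParams()
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    return params.karlin_K * query_len * db_len * math.exp(
        -params.karlin_lambda * score)


def bit_score(score: float, params: AlignerParams | None = None) -> float:
    params = params or AlignerParams()
    return (params.karlin_lambda * score - math.log(params.karlin_K)) / math.log(2)


def smith_waterman(query: str, subject: str, params: AlignerParams | None = None):
    """Affine-gap local alignment by dynamic programming.

    Returns ``(raw_score, q_aln, s_aln, q_interval, s_interval)`` with
    0-based half-open intervals, or ``None`` when no positive-scoring local
    alignment exists.  Rows are vectorised over the subject; horizontal
    (subject-side) gaps use a prefix-max scan, which is exact for the
    open + g*extend gap cost.
    """
    params = params or AlignerParams()
    q = encode(query)
    s = encode(subject)
    nq, ns = len(q), len(s)
    if nq == 0 or ns == 0:
        return None
    match = int(round(params.match * _SCALE))
    mismatch = int(round(params.mismatch * _SCALE))
    open_ = int(round(params.gap_open))
    ext = int(round(params.gap_extend))

    NEG = np.int64(-(1 << 40))
    H = np.zeros((nq + 1, ns + 1), dtype=np.int64)
    e_prev = np.full(ns, NEG, dtype=np.int64)       # E of previous row, j = 1..ns
    jidx = np.arange(1, ns + 1, dtype=np.int64)
    valid = s < 4
    for i in range(1, nq + 1):
        sub = np.where((s == q[i - 1]) & valid & (q[i - 1] < 4), match, mismatch)
        # vertical gaps (in subject): E(i,j) = max(H(i-1,j)-open-ext, E(i-1,j)-ext)
        e_cur = np.maximum(H[i - 1, 1:] - open_ - ext, e_prev - ext)
        diag = H[i - 1, :-1] + sub
        H0 = np.maximum(0, np.maximum(diag, e_cur))
        # horizontal gaps (in query): F(i,j) = max_{j'<j} H0(i,j') - open - (j-j')*ext
        A = H0 + ext * jidx
        M = np.maximum.accumulate(A)
        F = np.full(ns, NEG, dtype=np.int64)
        F[1:] = M[:-1] - open_ - ext * jidx[1:]
        H[i, 1:] = np.maximum(H0, F)
        e_prev = e_cur

    best = int(H.max())
    if best <= 0:
        return None
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    i, j = int(i), int(j)
    q_aln: list[str] = []
    s_aln: list[str] = []
    qi_end, sj_end = i, j
    while i > 0 and j > 0 and H[i, j] > 0:
        h = int(H[i, j])
        sub = match if (q[i - 1] == s[j - 1] and q[i - 1] < 4 and s[j - 1] < 4) \
            else mismatch
        if h == H[i - 1, j - 1] + sub:
            q_aln.append(query[i - 1])
            s_aln.append(subject[j - 1])
            i -= 1
            j -= 1
            continue
        moved = False
        for g in range(1, i + 1):                     # vertical: gap in subject
            if h == H[i - g, j] - open_ - g * ext:
                q_aln.extend(reversed(query[i - g:i]))
                s_aln.extend("-" * g)
                i -= g
                moved = True
                break
        if moved:
            continue
        for g in range(1, j + 1):                     # horizontal: gap in query
            if h == H[i, j - g] - open_ - g * ext:
                s_aln.extend(reversed(subject[j - g:j]))
                q_aln.extend("-" * g)
                j -= g
                moved = True
                break
        if not moved:                                  # score born here
            break
    q_aln.reverse()
    s_aln.reverse()
    return (best / _SCALE, "".join(q_aln), "".join(s_aln),
            (i, qi_end), (j, sj_end))


class SubjectIndex:
    """Exact word index of a subject sequence for seed lookup."""

    def __init__(self, subject_id: str, sequence: str, word_size: int):
        self.subject_id = subject_id
        self.sequence = sequence
        self.word_size = word_size
        self.words: dict[str, list[int]] = {}
        w = word_size
        seq = sequence
        for p in range(len(seq) - w + 1):
            word = seq[p:p + w]
            if "N" in word:
                continue
            self.words.setdefault(word, []).append(p)


def _alignment_stats(q_aln: str, s_aln: str):
    matches = mismatches = gap_opens = 0
    in_gap = False
    for a, b in zip(q_aln, s_aln):
        if a == "-" or b == "-":
            if not in_gap:
                gap_opens += 1
            in_gap = True
        else:
            in_gap = False
            if a == b and a in "ACGT":
                matches += 1
            else:
                mismatches += 1
    length = len(q_aln)
    pident = 100.0 * matches / length if length else 0.0
    return matches, mismatches, gap_opens, length, pident


def _band_windows(hits: list[tuple[int, int]], qlen: int, slen: int, pad: int):
    """Group seed hits into diagonal bands and yield subject windows."""
    diags = sorted({sp - qp for qp, sp in hits})
    groups: list[list[int]] = [[diags[0]]]
    for d in diags[1:]:
        if d - groups[-1][-1] <= pad:
            groups[-1].append(d)
        else:
            groups.append([d])
    for grp in groups:
        lo = max(0, grp[0] - pad)
        hi = min(slen, grp[-1] + qlen + pad)
        yield lo, hi


def _align_one_strand(query: str, query_id: str, index: SubjectIndex,
                      params: AlignerParams, minus: bool):
    qseq = revcomp(query) if minus else query
    w = params.word_size
    hits = []
    for p in range(len(qseq) - w + 1):
        word = qseq[p:p + w]
        if "N" in word:
            continue
        for sp in index.words.get(word, ()):
            hits.append((p, sp))
    if not hits:
        return []
    qlen = len(query)
    slen = len(index.sequence)
    out = []
    for lo, hi in _band_windows(hits, qlen, slen, max(params.band_pad, qlen)):
        res = smith_waterman(qseq, index.sequence[lo:hi], params)
        if res is None:
            continue
        score, q_aln, s_aln, (qa, qb), (sa, sb) = res
        sa, sb = sa + lo, sb + lo
        matches, mism, gaps, length, pident = _alignment_stats(q_aln, s_aln)
        if score < params.min_score or pident / 100.0 < params.min_identity:
            continue
        if minus:
            qa, qb = qlen - qb, qlen - qa
            ss1, se1 = sb, sa + 1          # swapped: minus strand
        else:
            ss1, se1 = sa + 1, sb
        out.append(AlignmentRecord(
            query_id=query_id, subject_id=index.subject_id,
            percent_identity=round(pident, 2),
            alignment_length_bp=length, mismatches=mism, gap_opens=gaps,
            query_start=qa + 1, query_end=qb,
            subject_start=ss1, subject_end=se1,
            e_value=evalue(score, qlen, slen, params),
            bit_score=round(bit_score(score, params), 2),
            query_aln=q_aln, subject_aln=s_aln, raw_score=score,
        ))
    return out


def _merge_overlapping(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Among overlapping alignments of the same pair keep the highest-scoring.

    Ties break to the leftmost query start, then leftmost subject start.
    """
    records = sorted(records, key=lambda r: (-r.raw_score, r.query_start,
                                             min(r.subject_start, r.subject_end)))
    kept: list[AlignmentRecord] = []
    for rec in records:
        qlo, qhi = rec.query_start, rec.query_end
        slo = min(rec.subject_start, rec.subject_end)
        shi = max(rec.subject_start, rec.subject_end)
        clash = False
        for k in kept:
            if k.query_start <= qhi and qlo <= k.query_end:
                kslo = min(k.subject_start, k.subject_end)
                kshi = max(k.subject_start, k.subject_end)
                if kslo <= shi and slo <= kshi:
                    clash = True
                    break
        if not clash:
            kept.append(rec)
    return kept


def align(query, subject, params: AlignerParams | None = None) -> list[AlignmentRecord]:
    """Local alignments of ``query`` against ``subject`` on both strands.

    ``query``/``subject`` may be plain sequences or ``(id, sequence)`` pairs.
    Returns records sorted by descending score; a query shorter than the
    seeding word yields an empty list with a warning.
    """
    params = params or AlignerParams()
    qid, qseq = query if isinstance(query, tuple) else ("query", query)
    sid, sseq = subject if isinstance(subject, tuple) else ("subject", subject)
    if len(qseq) < params.word_size:
        log.warning("query %s shorter than word size %d; no alignment attempted",
                    qid, params.word_size)
        return []
    index = SubjectIndex(sid, sseq, params.word_size)
    return align_indexed(qid, qseq, index, params)


def align_indexed(query_id: str, query_seq: str, index: SubjectIndex,
                  params: AlignerParams | None = None) -> list[AlignmentRecord]:
    """Align one query against a pre-built :class:`SubjectIndex`."""
    params = params or AlignerParams()
    if len(query_seq) < params.word_size:
        log.warning("query %s shorter than word size %d; no alignment attempted",
                    query_id, params.word_size)
        return []
    records = _align_one_strand(query_seq, query_id, index, params, minus=False)
    if params.both_strands:
        records += _align_one_strand(query_seq, query_id, index, params, minus=True)
    return _merge_overlapping(records)


def align_many(queries: Iterable, subjects: Iterable,
               params: AlignerParams | None = None) -> list[AlignmentRecord]:
    """All-vs-all alignment of ``(id, seq)`` queries against subjects.

    Subject indexes are built once and reused across queries.
    """
    params = params or AlignerParams()
    indexes = [SubjectIndex(sid, seq, params.word_size) for sid, seq in subjects]
    out: list[AlignmentRecord] = []
    for qid, qseq in queries:
        for index in indexes:
            out.extend(align_indexed(qid, qseq, index, params))
    return out


def best_hit(records: Sequence[AlignmentRecord]) -> AlignmentRecord | None:
    """Best hit: max bit score, ties by identity then subject id."""
    if not records:
        return None
    return sorted(records,
                  key=lambda r: (-r.bit_score, -r.percent_identity,
                                 r.subject_id))[0]
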