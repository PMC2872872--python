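"""Read-depth copy-number estimation for repeat clusters and reference windows.

The estimator inverts the expected number of survey reads matching a target
window under uniform sampling: a single-copy window of ``w`` bp is hit by
reads whose start falls in a ``w + L`` interval, so
``E[N | copy number CN] = CN * c * (w + L) / L`` and

    CN-hat = N * L / (c * (w + L))

with ``N`` the number of matching reads, ``L`` the mean read length and
``c`` the survey coverage fraction.  The genome fraction of a repeat is
``CN * length / G``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .micro_aligner import AlignerParams, SubjectIndex, align_indexed
from .sequence_io import SurveyRead

log = logging.getLogger("gensurvey")


@dataclass
class CopyNumberInputs:
    """Symbols of the depth-to-copy-number inversion."""

    N: float                 # reads matching the target/window
    w: float                 # target or window length, bp
    L: float = 229.0         # mean read length, bp
    c: float = 0.012         # survey coverage fraction
    G: float | None = None   # genome size, for fractions

    def __post_init__(self):
        if self.N < 0:
            raise ValueError("N must be >= 0")
        if self.w <= 0 or self.L <= 0:
            raise ValueError("window and read lengths must be positive")
        if self.c <= 0:
            raise ValueError("coverage fraction must be positive "
                             "(c = 0 makes copy number undefined)")


@dataclass
class CopyNumberEstimate:
    target_id: str
    copy_number: float
    length_bp: int
    genome_fraction: float
    best_library_hit: str | None = None
    window_profile: pd.DataFrame | None = None


def estimate_copy_number(inputs: CopyNumberInputs) -> float:
    """CN-hat = N*L / (c*(w+L)); exactly 1.0 at the single-copy expectation."""
    return inputs.N * inputs.L / (inputs.c * (inputs.w + inputs.L))


def single_copy_expectation(w: float, L: float = 229.0, c: float = 0.012) -> float:
    """Expected matching-read count for a single-copy window: c*(w+L)/L."""
    return c * (w + L) / L


def count_window_hits(reads: list[SurveyRead], target,
                      window_bp: int = 1000, min_identity: float = 0.90,
                      params: AlignerParams | None = None) -> pd.DataFrame:
    """Matching reads per non-overlapping window along a target sequence.

    A read counts in every window its alignment overlaps by at least one
    base pair, on either strand, and at most once per window even when it
    aligns several times.  Alignments below ``min_identity`` are ignored.
    """
    target_id, target_seq = target if isinstance(target, tuple) \
        else ("target", target)
    params = params or AlignerParams(min_identity=min_identity)
    if params.min_identity < min_identity:
        params = AlignerParams(**{**params.__dict__, "min_identity": min_identity})
    tlen = len(target_seq)
    if tlen < window_bp:
        log.warning("target %s (%d bp) shorter than the %d-bp window; "
                    "using a single whole-target window", target_id, tlen,
                    window_bp)
        window_bp = tlen
    n_windows = (tlen + window_bp - 1) // window_bp
    counts = np.zeros(n_windows, dtype=int)
    index = SubjectIndex(target_id, target_seq, params.word_size)
    for read in reads:
        recs = align_indexed(read.read_id, read.sequence, index, params)
        touched = set()
        for rec in recs:
            lo = min(rec.subject_start, rec.subject_end) - 1
            hi = max(rec.subject_start, rec.subject_end)
            touched.update(range(lo // window_bp, (hi - 1) // window_bp + 1))
        for wdx in touched:
            counts[wdx] += 1
    return pd.DataFrame({
        "window_start": np.arange(n_windows) * window_bp,
        "window_end": np.minimum((np.arange(n_windows) + 1) * window_bp, tlen),
        "N": counts,
    })


def genome_fraction(copy_number: float, length_bp: float, genome_bp: float):
    """Fraction of the genome occupied: CN * length / G (also as %).

    The percentage is rounded to two decimals; fractions above one are
    flagged as over-collapsed repeats (clipping is left to report writers).
    """
    if length_bp <= 0 or genome_bp <= 0:
        raise ValueError("lengths must be positive")
    frac = copy_number * length_bp / genome_bp
    if frac > 1:
        log.warning("genome fraction %.3f exceeds 1 (over-collapsed repeat?)",
                    frac)
    return {"fraction": frac, "percent": round(frac * 100, 2)}


def profile_target(reads, target, inputs_template: CopyNumberInputs,
                   window_bp: int = 1000, min_identity: float = 0.90,
                   params: AlignerParams | None = None) -> pd.DataFrame:
    """Per-window copy-number profile of a reference sequence."""
    hits = count_window_hits(reads, target, window_bp, min_identity, params)
    cn = [estimate_copy_number(CopyNumberInputs(
        N=row.N, w=row.window_end - row.window_start,
        L=inputs_template.L, c=inputs_template.c))
        for row in hits.itertuples()]
    hits = hits.copy()
    hits["copy_number"] = cn
    return hits


def top_repeats_table(estimates: list[CopyNumberEstimate],
                      n: int = 10) -> pd.DataFrame:
    """Rank repeats by genome fraction, one row per distinct best library hit.

    Among clusters sharing an identical best-hit subject id only the
    highest-ranked survives; unannotated clusters are each kept.
    """
    rows = sorted(estimates, key=lambda e: (-e.genome_fraction, e.target_id))
    seen: set[str] = set()
    out = []
    for e in rows:
        hit = e.best_library_hit
        if hit is not None:
            if hit in seen:
                continue
            seen.add(hit)
        out.append({
            "cluster_id": e.target_id,
            "length_bp": e.length_bp,
            "copy_number": e.copy_number,
            "genome_fraction": e.genome_fraction,
            "genome_pct": round(e.genome_fraction * 100, 2),
            "best_library_hit": hit,
        })
        if len(out) == n:
            break
    return pd.DataFrame(out)


def fraction_reads_in_repeats(reads: list[SurveyRead], clusters,
                              min_identity: float = 0.90,
                              min_read_coverage: float = 0.90,
                              params: AlignerParams | None = None) -> float:
    """Fraction of survey reads matching any repeat cluster.

    A read must align at >= ``min_identity`` over at least
    ``min_read_coverage`` of its length; each read counts once no matter how
    many clusters it matches.
    """
    if not clusters:
        raise ValueError("cluster set is empty")
    params = params or AlignerParams(min_identity=min_identity)
    indexes = [SubjectIndex(cl.cluster_id, cl.consensus, params.word_size)
               for cl in clusters]
    matched = 0
    for read in reads:
        need = min_read_coverage * read.length_bp
        found = False
        for index in indexes:
            for rec in align_indexed(read.read_id, read.sequence, index, params):
                span = rec.query_end - rec.query_start + 1
                if span >= need and rec.percent_identity / 100.0 >= min_identity:
                    found = True
                    break
            if found:
                break
        if found:
            matched += 1
    return matched / len(reads) if reads else 0.0


def count_matching_reads(reads: list[SurveyRead], target,
                         min_identity: float = 0.90,
                         params: AlignerParams | None = None) -> int:
    """Number of reads with any alignment to the target at >= min_identity."""
    target_id, target_seq = target if isinstance(target, tuple) \
        else ("target", target)
    params = params or AlignerParams(min_identity=min_identity)
    if params.min_identity < min_identity:
        params = AlignerParams(**{**params.__dict__, "min_identity": min_identity})
    index = SubjectIndex(target_id, target_seq, params.word_size)
    n = 0
    for read in reads:
        if align_indexed(read.read_id, read.sequence, index, params):
            n += 1
    return n
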