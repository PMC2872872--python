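"""Small-RNA signature mapping, normalization and copy-number correlation.

Signatures (18-32 nt) are mapped exhaustively against repeat consensi and
gene-space reads: every position on either strand where the full signature
aligns with at most one substitution is a hit (one mismatch over an 18-32-mer
subsumes a >= 94 % identity rule at 100 % coverage; an indel breaks full
coverage and is a non-hit).  Abundances are normalized to transcripts per
quarter-million sequenced signatures (TPQ) and to per-genomic-kilobase rates
``count / (copy_number * length_kb)``; rates are binned by estimated copy
number and the copy-number/abundance relationship summarized by OLS R-squared
and a chi-square test against a uniform distribution of counts across bins.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_io import revcomp
from .synthetic_data import SRnaSignature

log = logging.getLogger("gensurvey")


@dataclass(frozen=True)
class SRnaHit:
    signature_id: str
    target_id: str
    position: int          # 0-based start on the target's forward strand
    strand: str            # '+' or '-'
    mismatches: int


def _piece_offsets(length: int, n_pieces: int):
    """Split [0, length) into n_pieces near-equal pieces (pigeonhole seeds)."""
    bounds = np.linspace(0, length, n_pieces + 1).astype(int)
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(n_pieces)]


def map_srna(signatures: list[SRnaSignature], targets,
             max_mismatch: int = 1) -> list[SRnaHit]:
    """Exhaustively map signatures to targets with <= ``max_mismatch``
    substitutions over the full signature length, on both strands.

    Completeness comes from pigeonhole seeding: a hit with at most m
    mismatches contains at least one of m+1 equal pieces exactly; candidate
    placements from exact-piece lookups are then verified in full.
    Signatures outside 18-32 nt are skipped with a warning.
    """
    targets = list(targets)
    sig_lengths = sorted({len(s.sequence) for s in signatures
                          if 18 <= len(s.sequence) <= 32})
    piece_lengths = set()
    pieces_by_len = {}
    for s in sig_lengths:
        pieces = _piece_offsets(s, max_mismatch + 1)
        pieces_by_len[s] = pieces
        piece_lengths.update(b - a for a, b in pieces)

    # one exact-substring index per distinct piece length, over all targets
    index: dict[int, dict[str, list[tuple[int, int]]]] = {}
    for plen in piece_lengths:
        d: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for t_idx, (_, tseq) in enumerate(targets):
            for p in range(len(tseq) - plen + 1):
                d[tseq[p:p + plen]].append((t_idx, p))
        index[plen] = d

    hits: set[SRnaHit] = set()
    for sig in signatures:
        s = len(sig.sequence)
        if not 18 <= s <= 32:
            log.warning("signature %s length %d outside 18-32; skipped",
                        sig.signature_id, s)
            continue
        for strand, seq in (("+", sig.sequence), ("-", revcomp(sig.sequence))):
            cands: set[tuple[int, int]] = set()
            for a, b in pieces_by_len[s]:
                for t_idx, p in index[b - a].get(seq[a:b], ()):
                    cands.add((t_idx, p - a))
            for t_idx, start in cands:
                tseq = targets[t_idx][1]
                if start < 0 or start + s > len(tseq):
                    continue
                window = tseq[start:start + s]
                mism = sum(1 for x, y in zip(seq, window)
                           if x != y or x not in "ACGT")
                if mism <= max_mismatch:
                    hits.add(SRnaHit(sig.signature_id, targets[t_idx][0],
                                     start, strand, mism))
    return sorted(hits, key=lambda h: (h.signature_id, h.target_id,
                                       h.position, h.strand))


def map_srna_bruteforce(signatures, targets, max_mismatch: int = 1):
    """Reference scan over every offset and strand (oracle for map_srna)."""
    hits = []
    for sig in signatures:
        s = len(sig.sequence)
        if not 18 <= s <= 32:
            continue
        for strand, seq in (("+", sig.sequence), ("-", revcomp(sig.sequence))):
            for t_id, tseq in targets:
                for start in range(len(tseq) - s + 1):
                    mism = sum(1 for x, y in zip(seq, tseq[start:start + s])
                               if x != y or x not in "ACGT")
                    if mism <= max_mismatch:
                        hits.append(SRnaHit(sig.signature_id, t_id, start,
                                            strand, mism))
    return sorted(set(hits), key=lambda h: (h.signature_id, h.target_id,
                                            h.position, h.strand))


def tpq_normalize(count: float, library_total: float) -> float:
    """Transcripts per quarter-million reads: count / total * 250,000."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return count / library_total * 250_000.0


def per_kb_rate(matched_count: float, copy_number: float,
                length_bp: float) -> float:
    """Signatures per kilobase of genomic repeat content.

    rate = count / (copy_number * length_bp / 1000).
    """
    genomic_kb = copy_number * length_bp / 1000.0
    if genomic_kb <= 0:
        raise ValueError("zero genomic kb: rate undefined")
    return matched_count / genomic_kb


def bin_and_aggregate(cluster_table: pd.DataFrame, hits: list[SRnaHit],
                      bin_width: int, signatures=None,
                      only_24nt: bool = False) -> pd.DataFrame:
    """Per (repeat class x copy-number bin) signature counts and per-kb rates.

    ``cluster_table`` needs columns cluster_id, repeat_class, copy_number,
    length_bp.  A signature's abundance is credited to every cluster it hits
    (once per cluster).  Bins are ``[k*b, (k+1)*b)`` and indexed by their
    minimum copy number; empty bins are omitted.
    """
    if not 25 <= bin_width <= 200:
        raise ValueError("bin_width must lie in [25, 200]")
    abundance = {}
    length_of = {}
    if signatures is not None:
        for s in signatures:
            abundance[s.signature_id] = s.abundance
            length_of[s.signature_id] = len(s.sequence)
    per_cluster: dict[str, float] = defaultdict(float)
    for (sig_id, t_id) in {(h.signature_id, h.target_id) for h in hits}:
        if only_24nt and length_of.get(sig_id, 24) != 24:
            continue
        per_cluster[t_id] += abundance.get(sig_id, 1)

    df = cluster_table.copy()
    bad = df["copy_number"] * df["length_bp"] <= 0
    if bad.any():
        log.warning("%d clusters with zero genomic kb excluded from binning",
                    int(bad.sum()))
        df = df[~bad]
    df["count"] = df["cluster_id"].map(per_cluster).fillna(0.0)
    df["genomic_kb"] = df["copy_number"] * df["length_bp"] / 1000.0
    df["bin_min"] = (df["copy_number"] // bin_width).astype(int) * bin_width
    out = (df.groupby(["repeat_class", "bin_min"], as_index=False)
             .agg(count=("count", "sum"), genomic_kb=("genomic_kb", "sum"),
                  n_clusters=("cluster_id", "count")))
    out = out[out["count"] > 0].reset_index(drop=True)
    out["rate_per_kb"] = out["count"] / out["genomic_kb"]
    out.attrs["bin_width"] = bin_width
    return out


def linearity_stats(binned: pd.DataFrame):
    """OLS and chi-square summaries of the copy-number/abundance relationship.

    Total matched signatures per bin are regressed on the bin's minimum copy
    number (R-squared), and the observed per-bin counts are tested against a
    uniform expectation by chi-square goodness of fit.
    """
    per_bin = binned.groupby("bin_min")["count"].sum().sort_index()
    if len(per_bin) < 3:
        raise ValueError("need >= 3 non-empty bins")
    x = per_bin.index.to_numpy(dtype=float)
    y = per_bin.to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    chi = stats.chisquare(y)
    return {
        "r_squared": fit.rvalue ** 2,
        "slope": fit.slope,
        "chi_square": float(chi.statistic),
        "chi_square_p": float(chi.pvalue),
        "n_bins": len(per_bin),
    }


def class_share(hits: list[SRnaHit], signatures,
                class_of_target: dict) -> pd.DataFrame:
    """Percentage of matched sRNA abundance produced per repeat class.

    A signature hitting several classes is apportioned equally among them,
    so shares sum to 100 over all matched abundance.
    """
    abundance = {s.signature_id: s.abundance for s in signatures}
    classes_by_sig: dict[str, set] = defaultdict(set)
    for h in hits:
        cls = class_of_target.get(h.target_id)
        if cls is not None:
            classes_by_sig[h.signature_id].add(cls)
    weight: dict[str, float] = defaultdict(float)
    total = 0.0
    for sig_id, classes in classes_by_sig.items():
        ab = abundance.get(sig_id, 1)
        total += ab
        for cls in classes:
            weight[cls] += ab / len(classes)
    rows = [{"repeat_class": cls,
             "share_pct": 100.0 * w / total if total else 0.0}
            for cls, w in sorted(weight.items())]
    return pd.DataFrame(rows)


def size_distribution(signatures) -> pd.DataFrame:
    """Fraction of total signature abundance per signature length."""
    per_len: dict[int, float] = defaultdict(float)
    total = 0.0
    for s in signatures:
        per_len[len(s.sequence)] += s.abundance
        total += s.abundance
    return pd.DataFrame(
        [{"length_nt": k, "fraction": v / total if total else 0.0}
         for k, v in sorted(per_len.items())])
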