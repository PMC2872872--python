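"""Synthetic genomes, survey reads and small-RNA signatures with ground truth.

The generator emulates the statistical structure a sub-1x genome survey of a
large repeat-rich grass genome assumes: repeat families spanning copy numbers
around the ~100-copy detection limit (dispersed retrotransposon / transposon /
MITE families, tandem centromeric and rDNA arrays), i.i.d. background sequence
at a configurable GC fraction (default 0.44), pyrosequencing-like reads
(mean 229 bp, homopolymer-weighted indels) at a coverage fraction c, and
small-RNA signatures (18-32 nt, 24-nt majority) produced at class-specific
per-copy rates.  rDNA arrays carry two parental ITS haplotypes.

Every operation is deterministic for a fixed seed, and a truth table
(0-based half-open intervals) enumerates every planted feature so that
downstream estimators can be tested by parameter recovery rather than by
re-alignment.  Read names encode true origin as
``readNNN|familyID|copyIndex|start|strand`` (``.``/``-1`` for background).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence_io import SurveyRead, revcomp

log = logging.getLogger("gensurvey")

REPEAT_CLASSES = (
    "retrotransposon", "transposon", "MITE", "centromeric_tandem",
    "rDNA", "telomere", "unclassified",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PackingError(ValueError):
    """Planted repeat base pairs exceed the genome size."""


class CoverageUnderflowError(ValueError):
    """Requested coverage yields less sequence than a single read."""


@dataclass
class RepeatFamilySpec:
    """One repeat family to plant: class, unit length, copy number, divergence."""

    family_id: str
    repeat_class: str
    unit_length_bp: int
    copy_number: int
    intra_family_divergence: float = 0.0
    tandem: bool = False

    def __post_init__(self):
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if self.unit_length_bp < 50:
            raise ValueError("unit_length_bp must be >= 50")
        if not 0.0 <= self.intra_family_divergence <= 0.1:
            raise ValueError("intra_family_divergence must lie in [0, 0.1]")


@dataclass
class GenomeSpec:
    genome_size_bp: int
    families: list[RepeatFamilySpec] = field(default_factory=list)
    gene_count: int = 0
    mean_exon_bp: int = 250
    mean_cds_bp: int = 1500
    gc_fraction: float = 0.44
    its_haplotypes: tuple[str, str] | None = None
    its_hap_weights: tuple[float, float] = (0.5, 0.5)
    rng_seed: int = 0

    def __post_init__(self):
        if self.genome_size_bp <= 0:
            raise ValueError("genome_size_bp must be positive")
        planted = sum(f.copy_number * f.unit_length_bp for f in self.families)
        if planted > self.genome_size_bp:
            worst = max(self.families,
                        key=lambda f: f.copy_number * f.unit_length_bp)
            raise PackingError(
                f"planted repeat bp ({planted}) exceed genome size "
                f"({self.genome_size_bp}); largest family {worst.family_id!r} "
                f"alone occupies {worst.copy_number * worst.unit_length_bp} bp")
        if self.its_haplotypes is not None:
            a, b = self.its_haplotypes
            if len(a) < 150 or len(b) < 150:
                raise ValueError("ITS haplotypes must be >= 150 bp")
            diffs = sum(x != y for x, y in zip(a, b))
            if diffs < 3:
                raise ValueError("ITS haplotypes must differ at >= 3 sites")


@dataclass
class ReadProfile:
    mean_length_bp: float = 229.0
    length_sd_bp: float = 0.0
    substitution_rate: float = 0.0
    homopolymer_indel_rate: float = 0.0
    coverage_fraction: float = 0.012

    def __post_init__(self):
        for r in (self.substitution_rate, self.homopolymer_indel_rate):
            if not 0.0 <= r <= 0.05:
                raise ValueError("error rates must lie in [0, 0.05]")
        if not 0.0 < self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must lie in (0, 1]")
        if self.mean_length_bp <= 0:
            raise ValueError("mean_length_bp must be positive")


@dataclass
class SRnaProfile:
    length_range: tuple[int, int] = (18, 32)
    fraction_24nt: float = 0.65
    per_copy_rate_by_class: dict = field(default_factory=dict)
    library_labels: list[str] = field(
        default_factory=lambda: ["leaf", "inflorescence", "rhizome"])

    def __post_init__(self):
        lo, hi = self.length_range
        if lo < 18 or hi > 32 or lo > hi:
            raise ValueError("length_range must lie within [18, 32]")
        if any(r < 0 for r in self.per_copy_rate_by_class.values()):
            raise ValueError("per-copy rates must be >= 0")
        if not 0.0 <= self.fraction_24nt <= 1.0:
            raise ValueError("fraction_24nt must lie in [0, 1]")


@dataclass
class SRnaSignature:
    signature_id: str
    sequence: str
    abundance: int = 1
    library_label: str = ""

    def __post_init__(self):
        if not 18 <= len(self.sequence) <= 32:
            raise ValueError(
                f"signature {self.signature_id!r} length {len(self.sequence)} "
                "outside [18, 32]")


TRUTH_COLUMNS = ["family_id", "repeat_class", "start", "end",
                 "copy_index", "source_haplotype"]


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _mutate(rng: np.random.Generator, unit: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return unit.copy()
    out = unit.copy()
    hit = np.flatnonzero(rng.random(len(unit)) < rate)
    if hit.size:
        # substitute with one of the three other bases, uniformly
        cur = np.searchsorted(_BASES, out[hit])  # ACGT sorted already
        shift = rng.integers(1, 4, size=hit.size)
        out[hit] = _BASES[(cur + shift) % 4]
    return out


def _gap_scan_place(rng, occupied, length):
    """Uniform placement over the free gaps that can still hold ``length``."""
    free = ~occupied
    edges = np.flatnonzero(np.diff(np.concatenate(([0], free.view(np.int8),
                                                   [0]))))
    gap_starts, gap_ends = edges[::2], edges[1::2]
    room = gap_ends - gap_starts - length + 1
    ok = room > 0
    if not ok.any():
        return None
    weights = room[ok] / room[ok].sum()
    g = rng.choice(np.flatnonzero(ok), p=weights)
    return int(gap_starts[g] + rng.integers(0, room[g]))


def _place_dispersed(rng, occupied, G, n, length):
    """Random non-overlapping placements.

    Rejection sampling while the genome is sparse, falling back to an exact
    scan over remaining free gaps once rejections dominate.
    """
    starts = []
    tries = 0
    while len(starts) < n:
        tries += 1
        if tries > 50 * (len(starts) + 1) + 200:
            s = _gap_scan_place(rng, occupied, length)
            if s is None:
                raise PackingError(
                    f"could not place {n} copies of length {length} "
                    f"in remaining free space")
            tries = 50 * (len(starts) + 1)
        else:
            s = int(rng.integers(0, G - length + 1))
            if occupied[s:s + length].any():
                continue
        occupied[s:s + length] = True
        starts.append(s)
    return starts


def simulate_genome(spec: GenomeSpec):
    """Build a genome and its truth table from a :class:`GenomeSpec`.

    Returns ``(sequence, truth)`` where ``truth`` is a DataFrame with one row
    per planted copy (columns: family_id, repeat_class, start, end,
    copy_index, source_haplotype).  Every copy differs from its family master
    by at most the family's divergence rate (i.i.d. substitutions); the
    master sequences themselves are stashed in ``truth.attrs["masters"]``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    G = spec.genome_size_bp
    genome = _random_bases(rng, G, spec.gc_fraction)
    occupied = np.zeros(G, dtype=bool)
    rows = []
    masters: dict[str, str] = {}

    # biggest footprints placed first so tandem blocks find contiguous room
    order = sorted(spec.families,
                   key=lambda f: -(f.copy_number * f.unit_length_bp
                                   if f.tandem else f.unit_length_bp))
    for fam in order:
        master = _random_bases(rng, fam.unit_length_bp, spec.gc_fraction)
        masters[fam.family_id] = master.tobytes().decode("ascii")
        its_offset = None
        if fam.repeat_class == "rDNA" and spec.its_haplotypes is not None:
            hap_len = max(len(h) for h in spec.its_haplotypes)
            if fam.unit_length_bp < hap_len + 20:
                raise ValueError(
                    f"rDNA unit of family {fam.family_id!r} too short to "
                    f"carry an ITS haplotype of {hap_len} bp")
            its_offset = (fam.unit_length_bp - hap_len) // 2

        if fam.tandem:
            block = fam.copy_number * fam.unit_length_bp
            starts_block = _place_dispersed(rng, occupied, G, 1, block)[0]
            starts = [starts_block + k * fam.unit_length_bp
                      for k in range(fam.copy_number)]
        else:
            starts = _place_dispersed(rng, occupied, G,
                                      fam.copy_number, fam.unit_length_bp)

        for k, s in enumerate(starts):
            copy = _mutate(rng, master, fam.intra_family_divergence)
            hap = None
            if its_offset is not None:
                hap_idx = int(rng.choice(2, p=np.asarray(spec.its_hap_weights)
                                         / sum(spec.its_hap_weights)))
                hap_seq = spec.its_haplotypes[hap_idx]
                enc = np.frombuffer(hap_seq.encode(), dtype=np.uint8)
                copy[its_offset:its_offset + len(enc)] = enc
                hap = f"hap{hap_idx}"
            genome[s:s + fam.unit_length_bp] = copy
            rows.append((fam.family_id, fam.repeat_class, s,
                         s + fam.unit_length_bp, k, hap))

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["start", "family_id"]).reset_index(drop=True)
    truth.attrs["masters"] = masters
    return genome.tobytes().decode("ascii"), truth


def _feature_tag(truth: pd.DataFrame, pos: np.ndarray):
    """Family/copy of the feature containing each position (or background)."""
    if truth is None or truth.empty:
        fam = np.full(len(pos), ".", dtype=object)
        return fam, np.full(len(pos), -1)
    starts = truth["start"].to_numpy()
    ends = truth["end"].to_numpy()
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    fams = truth["family_id"].to_numpy()[order]
    copies = truth["copy_index"].to_numpy()[order]
    idx = np.searchsorted(starts, pos, side="right") - 1
    inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
    fam = np.where(inside, fams[np.clip(idx, 0, None)], ".")
    cp = np.where(inside, copies[np.clip(idx, 0, None)], -1)
    return fam.astype(object), cp


def _homopolymer_indels(rng, seq: list, rate: float) -> list:
    """Apply 454-style indels: per-run indel probability = rate * run length."""
    if rate <= 0:
        return seq
    out = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        p = min(0.9, rate * (j - i))
        if rng.random() < p:
            if rng.random() < 0.5 and len(run) > 1:
                run = run[:-1]                    # contraction
            else:
                run = run + [run[0]]              # expansion
        out.extend(run)
        i = j
    return out


def simulate_survey_reads(genome: str, profile: ReadProfile, seed: int,
                          truth: pd.DataFrame | None = None,
                          name_prefix: str = "read") -> list[SurveyRead]:
    """Sample shotgun survey reads uniformly over both strands.

    The number of reads is ``round(c * G / L)`` so total read bases land
    within a few percent of ``c * G``; substitution and homopolymer-indel
    errors are applied per the profile.
    """
    rng = np.random.default_rng(seed)
    G = len(genome)
    L = profile.mean_length_bp
    c = profile.coverage_fraction
    if c * G < L:
        raise CoverageUnderflowError(
            f"coverage {c} of a {G}-bp genome yields less than one "
            f"{L}-bp read")
    n_reads = int(round(c * G / L))
    if profile.length_sd_bp > 0:
        lengths = np.maximum(
            30, np.round(rng.normal(L, profile.length_sd_bp, n_reads))
        ).astype(int)
    else:
        lengths = np.full(n_reads, int(round(L)))
    lengths = np.minimum(lengths, G)
    starts = (rng.random(n_reads) * (G - lengths + 1)).astype(np.int64)
    strands = rng.choice(np.array(["+", "-"]), size=n_reads)
    mids = starts + lengths // 2
    fams, copies = _feature_tag(truth, mids)

    reads = []
    for i in range(n_reads):
        s, ln = int(starts[i]), int(lengths[i])
        seq = genome[s:s + ln]
        if strands[i] == "-":
            seq = revcomp(seq)
        if profile.substitution_rate > 0 or profile.homopolymer_indel_rate > 0:
            chars = list(seq)
            if profile.substitution_rate > 0:
                hits = np.flatnonzero(rng.random(ln) < profile.substitution_rate)
                for h in hits:
                    if chars[h] in "ACGT":
                        others = [b for b in "ACGT" if b != chars[h]]
                        chars[h] = others[int(rng.integers(3))]
            chars = _homopolymer_indels(rng, chars,
                                        profile.homopolymer_indel_rate)
            seq = "".join(chars)
        name = (f"{name_prefix}{i:06d}|{fams[i]}|{copies[i]}|{s}|{strands[i]}")
        reads.append(SurveyRead(name, seq, source_tag=str(fams[i])))
    return reads


def read_origin(read_id: str) -> dict:
    """Decode the provenance fields encoded in a simulated read name."""
    parts = read_id.split("|")
    if len(parts) != 5:
        raise ValueError(f"read id {read_id!r} carries no provenance encoding")
    return {
        "family_id": None if parts[1] == "." else parts[1],
        "copy_index": int(parts[2]),
        "start": int(parts[3]),
        "strand": parts[4],
    }


def simulate_srna(truth: pd.DataFrame, genome: str, profile: SRnaProfile,
                  seed: int) -> list[SRnaSignature]:
    """Draw small-RNA signatures from planted repeat copies.

    The expected signature count of a family is
    ``per_copy_rate * copy_number * unit_length_kb`` and realized counts are
    Poisson; each signature is a genomic substring (either strand) of one
    planted copy with length 24 at probability ``fraction_24nt`` and
    otherwise uniform over the remaining allowed lengths.
    """
    rng = np.random.default_rng(seed)
    rates = profile.per_copy_rate_by_class
    if not rates or all(r == 0 for r in rates.values()):
        log.warning("all per-class sRNA rates are zero; no signatures produced")
        return []
    lo, hi = profile.length_range
    other_lengths = [l for l in range(lo, hi + 1) if l != 24]
    sigs = []
    i = 0
    for fam_id, grp in truth.groupby("family_id", sort=True):
        cls = grp["repeat_class"].iloc[0]
        rate = rates.get(cls, 0.0)
        if rate <= 0:
            continue
        unit_kb = float((grp["end"] - grp["start"]).mean()) / 1000.0
        expected = rate * len(grp) * unit_kb
        count = rng.poisson(expected)
        if count == 0:
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        which = rng.integers(0, len(grp), size=count)
        for w in which:
            if 24 <= ends[w] - starts[w] and (not other_lengths or
                                              rng.random() < profile.fraction_24nt):
                ln = 24
            else:
                ln = int(rng.choice(other_lengths)) if other_lengths else 24
            ln = min(ln, int(ends[w] - starts[w]))
            s = int(rng.integers(starts[w], ends[w] - ln + 1))
            seq = genome[s:s + ln]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            lib = profile.library_labels[
                int(rng.integers(len(profile.library_labels)))]
            sigs.append(SRnaSignature(f"sig{i:07d}|{fam_id}", seq,
                                      abundance=1, library_label=lib))
            i += 1
    return sigs
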