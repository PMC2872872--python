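"""Readers and writers for the on-disk formats used throughout the pipeline.

FASTA and FASTQ parsing is strict by design: malformed input raises a
:class:`ParseError` carrying file and line context instead of being silently
coerced.  Lowercase input is uppercased and RNA ``U`` is mapped to ``T`` on
the way in.  Internal coordinates are 0-based half-open everywhere; the
12-column tabular alignment dialect (and every human-facing report) is
1-based inclusive, with the conversion confined to this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

log = logging.getLogger("gensurvey")

# IUPAC nucleotide codes accepted on input (after U -> T mapping).
IUPAC = set("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed input file; message carries file path and line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f"{path}"
            if line is not None:
                where += f":{line}"
            where = f" [{where}]"
        super().__init__(message + where)


class DuplicateIdError(ParseError):
    """Two records in one file share an identifier."""


@dataclass
class SurveyRead:
    """One shotgun survey read."""

    read_id: str
    sequence: str
    source_tag: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has empty sequence")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentRecord:
    """One row of the 12-column tabular alignment dialect.

    Coordinates are 1-based inclusive; a minus-strand match is represented
    by ``subject_start > subject_end`` (coordinates swapped, never negative).
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length_bp: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    e_value: float
    bit_score: float
    # optional gapped alignment strings (query/subject rows), not serialized
    query_aln: str | None = field(default=None, compare=False, repr=False)
    subject_aln: str | None = field(default=None, compare=False, repr=False)
    raw_score: float = field(default=0.0, compare=False, repr=False)

    @property
    def minus_strand(self) -> bool:
        return self.subject_start > self.subject_end

    def as_row(self) -> list:
        return [
            self.query_id, self.subject_id,
            f"{self.percent_identity:.2f}", self.alignment_length_bp,
            self.mismatches, self.gap_opens,
            self.query_start, self.query_end,
            self.subject_start, self.subject_end,
            f"{self.e_value:.2e}", f"{self.bit_score:.1f}",
        ]


def _normalize(seq: str, seq_id: str, path, line: int) -> str:
    out = seq.upper().replace("U", "T")
    bad = set(out) - IUPAC
    if bad:
        raise ParseError(
            f"non-IUPAC character(s) {sorted(bad)} in record {seq_id!r}",
            path, line,
        )
    return out


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a FASTA file into ``(identifier, sequence)`` pairs.

    Rejects empty files, duplicate identifiers and non-IUPAC characters.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    cur_id = None
    cur_line = 0
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if cur_id is not None:
                    records.append(
                        (cur_id, _normalize("".join(chunks), cur_id, path, cur_line))
                    )
                cur_id = line[1:].split()[0] if line[1:].strip() else ""
                if not cur_id:
                    raise ParseError("empty FASTA identifier", path, lineno)
                if cur_id in seen:
                    raise DuplicateIdError(
                        f"duplicate identifier {cur_id!r} "
                        f"(first seen at line {seen[cur_id]})",
                        path, lineno,
                    )
                seen[cur_id] = lineno
                cur_line = lineno
                chunks = []
            else:
                if cur_id is None:
                    raise ParseError("sequence data before first '>' header", path, lineno)
                chunks.append(line)
    if cur_id is not None:
        records.append((cur_id, _normalize("".join(chunks), cur_id, path, cur_line)))
    if not records:
        raise ParseError("empty FASTA file", path, None)
    for rid, seq in records:
        if not seq:
            raise ParseError(f"record {rid!r} has no sequence", path, seen[rid])
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, wrap: int = 60):
    """Write ``(identifier, sequence)`` pairs as wrapped FASTA."""
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")
    return path


def read_fastq(path) -> list[SurveyRead]:
    """Parse a 4-line-per-record FASTQ file into :class:`SurveyRead` objects."""
    path = Path(path)
    reads: list[SurveyRead] = []
    seen: set[str] = set()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise ParseError("empty FASTQ file", path, None)
    if len(lines) % 4:
        raise ParseError("FASTQ record count not a multiple of 4 lines", path, len(lines))
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i:i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise ParseError("FASTQ header must start with '@'", path, lineno)
        if not plus.startswith("+"):
            raise ParseError("FASTQ separator must start with '+'", path, lineno + 2)
        rid = head[1:].split()[0]
        if rid in seen:
            raise DuplicateIdError(f"duplicate identifier {rid!r}", path, lineno)
        seen.add(rid)
        if len(qual) != len(seq):
            raise ParseError(
                f"quality length {len(qual)} != sequence length {len(seq)} "
                f"for {rid!r}", path, lineno + 3,
            )
        reads.append(SurveyRead(rid, _normalize(seq, rid, path, lineno + 1)))
    return reads


def write_fastq(reads: Iterable[SurveyRead], path, quality_char: str = "I"):
    """Write reads as FASTQ with uniform dummy qualities."""
    path = Path(path)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{quality_char * r.length_bp}\n")
    return path


_TAB_COLUMNS = 12


def read_alignment_table(path) -> list[AlignmentRecord]:
    """Parse 12-column tab-separated alignment records.

    Strand is inferred from the subject coordinate order.
    """
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _TAB_COLUMNS:
                raise ParseError(
                    f"expected {_TAB_COLUMNS} tab-separated columns, got {len(cols)}",
                    path, lineno,
                )
            try:
                rec = AlignmentRecord(
                    query_id=cols[0], subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length_bp=int(cols[3]),
                    mismatches=int(cols[4]), gap_opens=int(cols[5]),
                    query_start=int(cols[6]), query_end=int(cols[7]),
                    subject_start=int(cols[8]), subject_end=int(cols[9]),
                    e_value=float(cols[10]), bit_score=float(cols[11]),
                )
            except ValueError as exc:
                raise ParseError(f"bad field: {exc}", path, lineno) from exc
            if rec.alignment_length_bp < 1:
                raise ParseError("alignment length must be >= 1", path, lineno)
            records.append(rec)
    return records


def write_alignment_table(records: Iterable[AlignmentRecord], path):
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec.as_row()) + "\n")
    return path


def write_truth_table(truth, path):
    """Write a planted-feature truth table as 6-column BED-style TSV.

    Columns: family_id, repeat_class, start (0-based), end (exclusive),
    copy_index, source_haplotype ('.' when absent).
    """
    import pandas as pd

    df = truth.copy()
    df["source_haplotype"] = df["source_haplotype"].fillna(".")
    df.to_csv(path, sep="\t", index=False)
    return path


def read_truth_table(path):
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    df["source_haplotype"] = df["source_haplotype"].replace(".", np.nan)
    return df


def load_config(path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError("top-level YAML structure must be a mapping", path, None)
    return cfg


def setup_logging(verbose: bool = False, quiet: bool = False):
    """Structured logs to stderr; --verbose / --quiet control the level."""
    level = logging.INFO
    if verbose:
        level = logging.DEBUG
    if quiet:
        level = logging.ERROR
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        force=True,
    )
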