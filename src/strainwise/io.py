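"""Readers and writers for every on-disk artifact the pipeline touches.

Coordinate convention is globally 0-based half-open (BED-native).  The only
place a conversion happens is at the I/O boundary: the minimal VCF-like TSV is
1-based on disk and shifted to 0-based at read time (and back at write time).
Elements are strandless.  FASTA sequences are upper-cased on read.

Tables are plain :class:`pandas.DataFrame` objects with fixed column sets,
validated on read/write:

* signal table:      element_id, strain, condition, assay, value
* expression table:  gene_id, strain, condition, replicate, tpm, count [, q]
* variant table:     chrom, pos, ref_allele, alt_allele, strain
* interaction table: chrom1, start1, end1, chrom2, start2, end2, strength
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval", "PWM", "FormatError",
    "read_bed", "write_bed", "read_pfm",
    "read_signal_table", "write_signal_table",
    "read_expression_table", "write_expression_table",
    "read_vcf_like", "write_vcf_like",
    "read_bedpe", "write_bedpe",
    "read_fasta", "write_fasta",
    "validate_signal_table", "validate_variant_table",
    "validate_expression_table", "validate_interaction_table",
]

SIGNAL_COLUMNS = ["element_id", "strain", "condition", "assay", "value"]
EXPRESSION_COLUMNS = ["gene_id", "strain", "condition", "replicate", "tpm", "count"]
VARIANT_COLUMNS = ["chrom", "pos", "ref_allele", "alt_allele", "strain"]
BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "strength"]


class FormatError(ValueError):
    """Raised for malformed input files or invariant-violating tables."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strandless genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    id: str = ""
    kind: str = "unassigned"  # promoter | enhancer | unassigned

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError(
                f"interval {self.chrom}:{self.start}-{self.end}: start must be < end")
        if self.kind not in ("promoter", "enhancer", "unassigned"):
            raise FormatError(f"unknown interval kind {self.kind!r}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def with_kind(self, kind: str) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start, self.end, self.id, kind)


@dataclass
class PWM:
    """Position probability matrix over A, C, G, T with scoring parameters.

    ``matrix`` has shape (length, 4); each row sums to 1 after pseudocount
    normalization.  ``background`` is the nucleotide frequency vector used by
    log-odds scoring.
    """

    name: str
    matrix: np.ndarray
    pseudocount: float = 0.25
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise FormatError(f"PWM {self.name}: matrix must be (L, 4)")
        if self.matrix.shape[0] < 4:
            raise FormatError(f"PWM {self.name}: length must be >= 4")
        rows = self.matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise FormatError(f"PWM {self.name}: columns must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, pseudocount: float = 0.25,
                    background: np.ndarray | None = None) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise FormatError(f"PWM {name}: counts must be (L, 4)")
        probs = counts + pseudocount
        probs = probs / probs.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(name, probs, pseudocount, bg)


# --------------------------------------------------------------------------
# provenance headers

def _header_lines(meta: dict | None) -> str:
    from strainwise import __version__
    lines = [f"# strainwise v{__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def _read_table(path: str | Path, columns: list[str] | None = None,
                **kwargs) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", **kwargs)
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
    return df


def _write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep="\t", index=False)


# --------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals (column 4, when present, is the id)."""
    out: list[GenomicInterval] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinates {parts[1]!r}, {parts[2]!r}"
                ) from exc
            iid = parts[3] if len(parts) >= 4 and parts[3] not in (".", "") \
                else f"{chrom}:{start}-{end}"
            if iid in seen_ids:
                raise FormatError(f"{path}:{lineno}: duplicate interval id {iid!r}")
            seen_ids.add(iid)
            try:
                out.append(GenomicInterval(chrom, start, end, iid))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")


# --------------------------------------------------------------------------
# JASPAR PFM

def read_pfm(path: str | Path, pseudocount: float = 0.25,
             background: np.ndarray | None = None) -> list[PWM]:
    """Read JASPAR-format PFMs (counts or probabilities) into :class:`PWM`s.

    Counts are converted to probabilities with ``pseudocount`` added per cell
    before normalization; probability-format input re-normalizes to the same
    result up to the (small) pseudocount.
    """
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
            parsed = [(m.name or m.matrix_id or f"motif_{i}",
                       np.array([m.counts[b] for b in "ACGT"], dtype=float).T)
                      for i, m in enumerate(records)]
    # Bio.motifs raises a bare Exception subclass tree for ragged input
        except Exception as exc:
            raise FormatError(f"{path}: cannot parse JASPAR PFM: {exc}") from exc
    if not parsed:
        raise FormatError(f"{path}: no motifs found")
    return [PWM.from_counts(name, counts, pseudocount, background)
            for name, counts in parsed]


# --------------------------------------------------------------------------
# signal table

def validate_signal_table(df: pd.DataFrame, elements: list[GenomicInterval] | None = None,
                          source: str = "signal table") -> pd.DataFrame:
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing columns {missing}")
    key = ["element_id", "strain", "condition", "assay"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise FormatError(f"{source}: duplicate key {tuple(first)}")
    if (df["value"] < 0).any():
        bad = df.loc[df["value"] < 0].iloc[0]
        raise FormatError(f"{source}: negative signal for element "
                          f"{bad['element_id']!r} ({bad['value']})")
    if elements is not None:
        known = {iv.id for iv in elements}
        unknown = set(df["element_id"]) - known
        if unknown:
            raise FormatError(f"{source}: unknown element ids {sorted(unknown)[:5]}")
    return df


def read_signal_table(path: str | Path,
                      elements: list[GenomicInterval] | None = None) -> pd.DataFrame:
    df = _read_table(path, SIGNAL_COLUMNS)
    return validate_signal_table(df, elements, source=str(path))


def write_signal_table(df: pd.DataFrame, path: str | Path,
                       meta: dict | None = None) -> None:
    validate_signal_table(df)
    _write_table(df[SIGNAL_COLUMNS], path, meta)


# --------------------------------------------------------------------------
# expression table

def validate_expression_table(df: pd.DataFrame, source: str = "expression table"
                              ) -> pd.DataFrame:
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing columns {missing}")
    if (df["tpm"] < 0).any():
        raise FormatError(f"{source}: negative TPM")
    counts = df["count"]
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise FormatError(f"{source}: counts must be non-negative integers")
    if "q" in df.columns:
        q = df["q"].dropna()
        if ((q < 0) | (q > 1)).any():
            raise FormatError(f"{source}: q values must lie in [0, 1]")
    return df


def read_expression_table(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    return validate_expression_table(df, source=str(path))


def write_expression_table(df: pd.DataFrame, path: str | Path,
                           meta: dict | None = None) -> None:
    validate_expression_table(df)
    cols = EXPRESSION_COLUMNS + (["q"] if "q" in df.columns else [])
    _write_table(df[cols], path, meta)


# --------------------------------------------------------------------------
# minimal VCF-like TSV

def validate_variant_table(df: pd.DataFrame, genomes: dict[str, str] | None = None,
                           source: str = "variant table") -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing columns {missing}")
    for col in ("ref_allele", "alt_allele"):
        vals = df[col].astype(str)
        if (vals.str.len() == 0).any():
            raise FormatError(f"{source}: empty {col}")
    same = df["ref_allele"].astype(str) == df["alt_allele"].astype(str)
    if same.any():
        raise FormatError(f"{source}: ref and alt alleles identical at row "
                          f"{int(np.flatnonzero(same)[0])}")
    if (df["pos"] < 0).any():
        raise FormatError(f"{source}: negative position")
    if genomes is not None:
        for chrom, sub in df.groupby("chrom"):
            if chrom not in genomes:
                raise FormatError(f"{source}: unknown chromosome {chrom!r}")
            if (sub["pos"] >= len(genomes[chrom])).any():
                raise FormatError(f"{source}: position beyond end of {chrom}")
    return df


def read_vcf_like(path: str | Path) -> pd.DataFrame:
    """Read the minimal VCF-like TSV; 1-based on-disk positions become 0-based."""
    df = _read_table(path, VARIANT_COLUMNS)
    df = df.copy()
    df["pos"] = df["pos"].astype(int) - 1  # 1-based on disk -> 0-based internal
    return validate_variant_table(df, source=str(path))


def write_vcf_like(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    validate_variant_table(df)
    out = df[VARIANT_COLUMNS].copy()
    out["pos"] = out["pos"].astype(int) + 1  # 0-based internal -> 1-based on disk
    _write_table(out, path, meta)


# --------------------------------------------------------------------------
# BEDPE

def validate_interaction_table(df: pd.DataFrame, source: str = "interaction table"
                               ) -> pd.DataFrame:
    missing = [c for c in BEDPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing columns {missing}")
    if (df["strength"] < 0).any():
        raise FormatError(f"{source}: negative interaction strength")
    for s, e in (("start1", "end1"), ("start2", "end2")):
        if (df[s] >= df[e]).any():
            raise FormatError(f"{source}: anchor with {s} >= {e}")
    return df


def read_bedpe(path: str | Path) -> pd.DataFrame:
    """Read a BEDPE file (6 coordinate columns; column 7, if present, is strength)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 BEDPE columns")
            try:
                row = [parts[0], int(parts[1]), int(parts[2]),
                       parts[3], int(parts[4]), int(parts[5]),
                       float(parts[6]) if len(parts) > 6 else 1.0]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad BEDPE fields") from exc
            rows.append(row)
    df = pd.DataFrame(rows, columns=BEDPE_COLUMNS)
    return validate_interaction_table(df, source=str(path))


def write_bedpe(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    validate_interaction_table(df)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))  # comment lines only: BEDPE has no header row
        df[BEDPE_COLUMNS].to_csv(fh, sep="\t", index=False, header=False)


# --------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {name: upper-cased sequence}."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
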