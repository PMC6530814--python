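"""Readers and writers for the external formats the framework touches.

All genomic intervals are handled internally in 0-based half-open
coordinates.  GTF input (1-based, inclusive) is converted on read; the
representative TSS of a gene is kept 1-based, matching the convention of
genome browsers.

Peak files are BED3+ or ENCODE narrowPeak.  In narrowPeak files, column 5
("score") is taken as the ChIP peak score and column 7 ("signalValue") as
the DNase signal of the peak.

Position-specific energy matrices (PSEMs) use a plain-text grammar of this
package (the upstream databases each print their own):

    >TF_NAME [lambda=<float>] [ln_r0=<float>]
    e_A e_C e_G e_T          # one row per motif position, energies >= 0
    ...

When the header omits the TRAP parameters, the reference parameterisation
``lambda = 0.7`` and ``ln R0 = 0.584 * width - 5.66`` is filled in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "Peak",
    "GeneModel",
    "EnergyMatrix",
    "FeatureMatrix",
    "PEAK_FEATURE_COLUMNS",
    "TRAP_LAMBDA_DEFAULT",
    "read_peaks",
    "write_peaks",
    "read_genes",
    "read_psem",
    "write_psem",
    "read_expression",
    "write_expression",
    "read_matrix",
    "write_matrix",
]

#: Names of the aggregate chromatin-activity features (distance-weighted
#: peak count, total peak length and total peak signal per gene).
PEAK_FEATURE_COLUMNS = ("Peak_Count", "Peak_Length", "Peak_Signal")

TRAP_LAMBDA_DEFAULT = 0.7


def trap_ln_r0_default(width: int) -> float:
    """Reference TRAP ln(R0) as a linear function of motif width."""
    return 0.584 * width - 5.66


@dataclass(frozen=True)
class Peak:
    """A genomic interval with a per-peak score and optional signal.

    ``score`` carries the ChIP peak score; ``signal`` the DNase signal of
    the peak (0 when not applicable).  Coordinates are 0-based half-open.
    """

    chrom: str
    start: int
    end: int
    score: float = 0.0
    signal: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if self.score < 0 or self.signal < 0:
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: negative score/signal"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def key(self) -> str:
        """Stable identifier used to join peaks with affinity tables."""
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneModel:
    """A gene with its representative (most 5') transcription start site.

    ``tss`` is 1-based: for a + strand gene the smallest transcript start,
    for a - strand gene the largest transcript end.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.tss < 1:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 1")

    @property
    def tss0(self) -> int:
        """TSS in 0-based coordinates."""
        return self.tss - 1


@dataclass
class EnergyMatrix:
    """Position-specific energy matrix (PSEM) plus TRAP parameters.

    ``energies`` has one row per motif position and four columns (A, C, G,
    T) of non-negative mismatch energies; the consensus base of a position
    has energy 0.
    """

    tf_name: str
    energies: np.ndarray
    lambda_param: float = TRAP_LAMBDA_DEFAULT
    ln_r0: float | None = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim != 2 or self.energies.shape[1] != 4:
            raise ValueError(f"PSEM {self.tf_name}: energies must be width x 4")
        if self.energies.shape[0] < 1:
            raise ValueError(f"PSEM {self.tf_name}: empty matrix")
        if (self.energies < 0).any():
            raise ValueError(f"PSEM {self.tf_name}: negative energy")
        if self.lambda_param <= 0:
            raise ValueError(f"PSEM {self.tf_name}: lambda must be positive")
        if self.ln_r0 is None:
            self.ln_r0 = trap_ln_r0_default(self.width)

    @property
    def width(self) -> int:
        return self.energies.shape[0]


@dataclass
class FeatureMatrix:
    """Genes x features table tagged with the scoring variant it came from.

    ``variant`` is one of C, CN, CPF, D, DS, DN, DSN, DPF, DPFS; the
    column set is fixed by the variant (TF columns and/or the aggregate
    peak features).
    """

    values: pd.DataFrame
    variant: str = ""

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate feature name {dup!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> pd.Index:
        return self.values.columns

    @property
    def tf_columns(self) -> list[str]:
        return [c for c in self.values.columns if c not in PEAK_FEATURE_COLUMNS]

    @property
    def peak_feature_columns(self) -> list[str]:
        return [c for c in self.values.columns if c in PEAK_FEATURE_COLUMNS]


# ---------------------------------------------------------------------------
# peaks


def read_peaks(path: str | Path, format: str = "narrowPeak") -> list[Peak]:
    """Read a BED3+ or narrowPeak file into a list of :class:`Peak`.

    narrowPeak: column 5 -> score, column 7 (signalValue) -> signal.
    BED: column 5 -> score when present; signal stays 0.
    """
    if format not in ("narrowPeak", "bed"):
        raise ValueError(f"unknown peak format {format!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                signal = 0.0
                if format == "narrowPeak" and len(fields) > 6:
                    signal = float(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
            if end <= start:
                raise ValueError(f"{path}:{lineno}: start >= end")
            peaks.append(
                Peak(chrom=chrom, start=start, end=end, score=score, signal=signal, name=name)
            )
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path, format: str = "narrowPeak") -> None:
    """Write peaks as BED6+ (bed) or 10-column narrowPeak."""
    with open(path, "w") as fh:
        for p in peaks:
            if format == "narrowPeak":
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t.\t"
                    f"{p.signal:g}\t-1\t-1\t-1\n"
                )
            else:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t.\n")


# ---------------------------------------------------------------------------
# genes


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read a GTF and return one :class:`GeneModel` per gene.

    The representative TSS is the most 5' transcript start across all of a
    gene's transcripts (minimum start on +, maximum end on -).  Genes
    without transcript records fall back to the gene record's own 5' end.
    Records lacking a gene_id are skipped with a warning; a gene with
    transcripts on conflicting strands is an error.
    """
    df = pr.read_gtf(str(path)).df
    if df.empty:
        return []
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: no gene_id attribute in any record")
    n_missing = int(df["gene_id"].isna().sum() + (df["gene_id"] == "").sum())
    if n_missing:
        warnings.warn(f"{path}: skipped {n_missing} records without gene_id")
        df = df[df["gene_id"].notna() & (df["gene_id"] != "")]

    genes: list[GeneModel] = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        strands = set(grp["Strand"])
        if len(strands) > 1:
            raise ValueError(f"gene {gene_id}: transcripts on conflicting strands")
        strand = strands.pop()
        chrom = str(grp["Chromosome"].iloc[0])
        tx = grp[grp["Feature"] == "transcript"]
        src = tx if len(tx) else grp[grp["Feature"] == "gene"]
        if not len(src):
            src = grp
        # pyranges Start is 0-based; End is the 1-based inclusive end.
        if strand == "+":
            tss = int(src["Start"].min()) + 1
        else:
            tss = int(src["End"].max())
        genes.append(GeneModel(gene_id=str(gene_id), chrom=chrom, strand=strand, tss=tss))
    return genes


# ---------------------------------------------------------------------------
# PSEMs


def read_psem(path: str | Path) -> list[EnergyMatrix]:
    """Parse a plain-text PSEM file (grammar in the module docstring)."""
    matrices: list[EnergyMatrix] = []
    name: str | None = None
    params: dict[str, float] = {}
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal name, params, rows
        if name is None:
            return
        if not rows:
            raise ValueError(f"PSEM {name}: no energy rows")
        matrices.append(
            EnergyMatrix(
                tf_name=name,
                energies=np.array(rows, dtype=float),
                lambda_param=params.get("lambda", TRAP_LAMBDA_DEFAULT),
                ln_r0=params.get("ln_r0"),
            )
        )
        name, params, rows = None, {}, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                if not parts:
                    raise ValueError(f"{path}:{lineno}: header without a TF name")
                name = parts[0]
                for tok in parts[1:]:
                    if "=" not in tok:
                        raise ValueError(f"{path}:{lineno}: bad header token {tok!r}")
                    key, val = tok.split("=", 1)
                    params[key] = float(val)
            else:
                if name is None:
                    raise ValueError(f"{path}:{lineno}: energy row before any header")
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 energies, got {len(vals)}")
                if any(v < 0 for v in vals):
                    raise ValueError(f"{path}:{lineno}: negative energy")
                rows.append(vals)
    flush()
    return matrices


def write_psem(matrices: Iterable[EnergyMatrix], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in matrices:
            fh.write(f">{m.tf_name} lambda={m.lambda_param!r} ln_r0={m.ln_r0!r}\n")
            for row in m.energies:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path) -> pd.Series:
    """Read a two-column TSV (gene id, expression) into a Series."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene_id", "expression"])
    # tolerate a header row
    if len(df) and df.iloc[0, 0] in ("gene_id", "gene", "id"):
        df = df.iloc[1:]
    s = pd.Series(df["expression"].astype(float).values, index=df["gene_id"].astype(str).values)
    if s.index.duplicated().any():
        dup = s.index[s.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    if (s < 0).any():
        raise ValueError(f"{path}: negative expression value")
    s.index.name = "gene_id"
    s.name = "expression"
    return s


def write_expression(expression: pd.Series | Mapping[str, float], path: str | Path) -> None:
    s = pd.Series(expression)
    with open(path, "w") as fh:
        for gid, val in s.items():
            fh.write(f"{gid}\t{val!r}\n")


# ---------------------------------------------------------------------------
# feature matrices


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as TSV; the variant tag goes into a '#' header."""
    if matrix.values.columns.duplicated().any():
        raise ValueError("duplicate feature names")
    with open(path, "w") as fh:
        if matrix.variant:
            fh.write(f"# variant={matrix.variant}\n")
        fh.write("gene_id\t" + "\t".join(map(str, matrix.values.columns)) + "\n")
        for gid, row in zip(matrix.values.index, matrix.values.to_numpy()):
            fh.write(str(gid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix(path: str | Path) -> FeatureMatrix:
    variant = ""
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.startswith("variant="):
                variant = stripped.split("=", 1)[1]
            pos = fh.tell()
            line = fh.readline()
        header = line.rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            raise ValueError(f"{path}: duplicated feature column")
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return FeatureMatrix(values=df, variant=variant)
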