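"""TRAP-style transcription factor affinities in open-chromatin peaks.

The affinity of a TF for a sequence is its expected occupancy: every
window of motif width on both strands contributes a logistic binding
probability

    p(E) = R0 * exp(-E / lambda) / (1 + R0 * exp(-E / lambda)),

where E is the sum of the PSEM mismatch energies over the window.  The
affinity is the sum of these probabilities, so it grows with sequence
length and has no per-site threshold.  Windows overlapping an N base
contribute zero.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import EnergyMatrix, Peak

__all__ = [
    "site_probability",
    "peak_affinity",
    "annotate_peaks",
    "AffinityTable",
]

# base encoding: A C G T N -> 0 1 2 3 4; complement of code b is 3-b for ACGT
_BASE_CODES = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _BASE_CODES[ord(b)] = i
    _BASE_CODES[ord(b.lower())] = i
_BASE_CODES[ord("N")] = 4
_BASE_CODES[ord("n")] = 4


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a DNA string over {A,C,G,T,N} to integer codes 0..4."""
    codes = _BASE_CODES[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sequence[int(np.argmax(codes < 0))]
        raise ValueError(f"invalid base {bad!r} in sequence")
    return codes


def site_probability(energy: float | np.ndarray, lambda_param: float, ln_r0: float):
    """Binding probability of a single window with summed mismatch energy E.

    Monotonically decreasing in E; equals R0/(1+R0) at E=0.
    """
    return expit(ln_r0 - np.asarray(energy, dtype=float) / lambda_param)


def _window_energies(codes: np.ndarray, energies5: np.ndarray) -> np.ndarray:
    """Summed energies of all forward windows; windows with N get +inf.

    ``energies5`` is the PSEM extended with a 5th (N) column of +inf.
    """
    width = energies5.shape[0]
    n_win = codes.size - width + 1
    if n_win <= 0:
        return np.empty(0)
    total = np.zeros(n_win)
    for j in range(width):
        total += energies5[j, codes[j : j + n_win]]
    return total


def _windows_energy_both_strands(codes: np.ndarray, matrix: EnergyMatrix) -> tuple[np.ndarray, np.ndarray]:
    energies5 = np.column_stack([matrix.energies, np.full(matrix.width, np.inf)])
    fwd = _window_energies(codes, energies5)
    # reverse strand: scan the reverse complement with the same matrix,
    # equivalently scan forward with the reversed, complemented matrix
    rc_energies5 = np.column_stack(
        [matrix.energies[::-1, ::-1], np.full(matrix.width, np.inf)]
    )
    rev = _window_energies(codes, rc_energies5)
    return fwd, rev


def peak_affinity(sequence: str, matrix: EnergyMatrix) -> float:
    """Total affinity of a PSEM for one sequence, both strands.

    Returns 0 when the sequence is shorter than the motif.
    """
    codes = encode_sequence(sequence)
    if codes.size < matrix.width:
        return 0.0
    fwd, rev = _windows_energy_both_strands(codes, matrix)
    p_fwd = site_probability(fwd, matrix.lambda_param, matrix.ln_r0)
    p_rev = site_probability(rev, matrix.lambda_param, matrix.ln_r0)
    # inf energy (N in window) -> probability exactly 0 via expit(-inf)
    return float(p_fwd.sum() + p_rev.sum())


class AffinityTable:
    """Peaks x TFs affinity table plus the motif widths behind it.

    Rows are keyed ``chrom:start-end``; widths are needed downstream for
    the per-peak binding-site normalisation |p| - |m| + 1.
    """

    def __init__(self, values: pd.DataFrame, widths: Mapping[str, int]):
        missing = set(values.columns) - set(widths)
        if missing:
            raise ValueError(f"no motif width for TFs {sorted(missing)}")
        self.values = values
        self.widths = dict(widths)

    @property
    def tf_names(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# widths=" + ",".join(f"{t}:{w}" for t, w in self.widths.items()) + "\n")
            self.values.to_csv(fh, sep="\t", index_label="peak", float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AffinityTable":
        widths: dict[str, int] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                stripped = line[1:].strip()
                if stripped.startswith("widths="):
                    for tok in stripped.split("=", 1)[1].split(","):
                        tf, w = tok.rsplit(":", 1)
                        widths[tf] = int(w)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(df, widths)


def annotate_peaks(
    peaks: Sequence[Peak],
    genome: str | Path | Mapping[str, str],
    matrices: Iterable[EnergyMatrix],
) -> AffinityTable:
    """Compute the affinity of every PSEM in every peak sequence.

    ``genome`` is a FASTA path or a chrom -> sequence mapping.  Every peak
    must lie within its chromosome.
    """
    matrices = list(matrices)
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(genome), rebuild=False)

        def fetch(chrom: str, start: int, end: int) -> str:
            if chrom not in fa:
                raise ValueError(f"peak on unknown chromosome {chrom!r}")
            if end > len(fa[chrom]):
                raise ValueError(f"peak {chrom}:{start}-{end} beyond chromosome end")
            return str(fa[chrom][start:end])

    else:

        def fetch(chrom: str, start: int, end: int) -> str:
            if chrom not in genome:
                raise ValueError(f"peak on unknown chromosome {chrom!r}")
            if end > len(genome[chrom]):
                raise ValueError(f"peak {chrom}:{start}-{end} beyond chromosome end")
            return genome[chrom][start:end]

    keys = [p.key for p in peaks]
    if not peaks:
        return AffinityTable(
            pd.DataFrame(index=pd.Index([], name="peak"), columns=[m.tf_name for m in matrices], dtype=float),
            {m.tf_name: m.width for m in matrices},
        )

    # concatenate all peak sequences with N spacers wide enough that no
    # window spans two peaks, then scan each matrix once over the blob
    max_width = max((m.width for m in matrices), default=1)
    seqs = [encode_sequence(fetch(p.chrom, p.start, p.end)) for p in peaks]
    spacer = np.full(max_width, 4, dtype=np.int8)
    parts: list[np.ndarray] = []
    starts = np.empty(len(seqs), dtype=np.int64)
    offset = 0
    for i, s in enumerate(seqs):
        starts[i] = offset
        parts.append(s)
        parts.append(spacer)
        offset += s.size + spacer.size
    blob = np.concatenate(parts)
    lengths = np.array([s.size for s in seqs], dtype=np.int64)

    out = np.zeros((len(peaks), len(matrices)))
    for j, m in enumerate(matrices):
        fwd, rev = _windows_energy_both_strands(blob, m)
        p = site_probability(fwd, m.lambda_param, m.ln_r0) + site_probability(
            rev, m.lambda_param, m.ln_r0
        )
        # windows fully inside peak i start in [starts[i], starts[i]+len_i-width]
        csum = np.concatenate([[0.0], np.cumsum(p)])
        last = starts + np.maximum(lengths - m.width + 1, 0)
        out[:, j] = csum[np.minimum(last, csum.size - 1)] - csum[np.minimum(starts, csum.size - 1)]

    df = pd.DataFrame(out, index=pd.Index(keys, name="peak"), columns=[m.tf_name for m in matrices])
    return AffinityTable(df, {m.tf_name: m.width for m in matrices})
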