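"""Aggregate peak-level evidence into gene-level features.

All nine scoring variants share the same skeleton: collect the peaks
overlapping a 50 kb window centred on a gene's most-5' TSS and sum a
per-peak quantity weighted by the exponential decay exp(-d / d0), where d
is the distance (bp) from the peak midpoint to the TSS.

ChIP-seq variants
    C    per-TF sum of peak scores, decay-weighted
    CN   C divided per gene by the decay-weighted peak count c^C, plus
         the aggregate features Peak_Count (c^C) and Peak_Length (l^C)
    CPF  Peak_Count and Peak_Length only

DNase variants (TF affinities a_{p,t} from the affinity module)
    D     decay-weighted affinity sums
    DS    affinities scaled by the per-peak DNase signal s_p
    DN    affinities normalised per peak by the number of possible
          binding sites |p| - |m| + 1, plus Peak_Count and Peak_Length
    DSN   DN plus Peak_Signal (the decay-weighted signal sum f^D)
    DPF   Peak_Count, Peak_Length only
    DPFS  Peak_Count, Peak_Length, Peak_Signal
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .affinity import AffinityTable
from .io import FeatureMatrix, GeneModel, Peak

__all__ = [
    "DecayParams",
    "WindowAssignment",
    "decay_weight",
    "assign_windows",
    "chip_scores_C",
    "chip_peak_features",
    "chip_scores_CN",
    "chip_scores_CPF",
    "dnase_scores",
    "build_design",
    "CHIP_VARIANTS",
    "DNASE_VARIANTS",
]

CHIP_VARIANTS = ("C", "CN", "CPF")
DNASE_VARIANTS = ("D", "DS", "DN", "DSN", "DPF", "DPFS")


@dataclass(frozen=True)
class DecayParams:
    """Window size and decay scale of the TF-gene score aggregation.

    ``d0`` controls how fast peak influence decays with TSS distance;
    ``window`` is the total width of the window centred on the TSS.
    """

    d0: float = 5000.0
    window: int = 50000

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.window <= 0:
            raise ValueError("window must be positive")


@dataclass
class WindowAssignment:
    """The peaks falling into one gene's TSS window, with TSS distances."""

    gene_id: str
    peak_indices: np.ndarray  # indices into the peak list passed in
    distances: np.ndarray  # |peak midpoint - tss| in bp


def decay_weight(d: float | np.ndarray, params: DecayParams) -> float | np.ndarray:
    """Exponential decay weight exp(-d/d0) of a peak at TSS distance d."""
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distance must be non-negative")
    out = np.exp(-d / params.d0)
    return float(out) if out.ndim == 0 else out


def assign_windows(
    genes: Sequence[GeneModel],
    peaks: Sequence[Peak],
    params: DecayParams = DecayParams(),
) -> list[WindowAssignment]:
    """Assign peaks to genes by overlap with the TSS-centred window.

    A peak is admitted when its interval overlaps
    [tss - window/2, tss + window/2) (0-based TSS); any overlap counts,
    not only midpoint containment.
    """
    half = params.window / 2.0
    by_chrom: dict[str, list[int]] = {}
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append(i)
    # sort peaks per chromosome by start for a windowed sweep
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    mids: dict[str, np.ndarray] = {}
    order: dict[str, np.ndarray] = {}
    for chrom, idx in by_chrom.items():
        idx = np.array(idx)
        s = np.array([peaks[i].start for i in idx])
        o = np.argsort(s, kind="stable")
        order[chrom] = idx[o]
        starts[chrom] = s[o]
        ends[chrom] = np.array([peaks[i].end for i in idx])[o]
        mids[chrom] = np.array([peaks[i].midpoint for i in idx])[o]

    out: list[WindowAssignment] = []
    for g in genes:
        if g.chrom not in order:
            out.append(WindowAssignment(g.gene_id, np.empty(0, dtype=int), np.empty(0)))
            continue
        lo, hi = g.tss0 - half, g.tss0 + half
        s, e = starts[g.chrom], ends[g.chrom]
        # overlap: start < hi and end > lo
        cand = np.searchsorted(s, hi, side="left")
        mask = e[:cand] > lo
        sel = np.flatnonzero(mask)
        d = np.abs(mids[g.chrom][sel] - g.tss0).astype(float)
        out.append(WindowAssignment(g.gene_id, order[g.chrom][sel], d))
    return out


def _empty_matrix(genes: Sequence[GeneModel], columns: Sequence[str], variant: str) -> FeatureMatrix:
    df = pd.DataFrame(
        0.0, index=pd.Index([g.gene_id for g in genes], name="gene_id"), columns=list(columns)
    )
    return FeatureMatrix(values=df, variant=variant)


def chip_scores_C(
    genes: Sequence[GeneModel],
    chip_peaks_by_tf: Mapping[str, Sequence[Peak]],
    params: DecayParams = DecayParams(),
) -> FeatureMatrix:
    """Decay-weighted sum of ChIP peak scores per (gene, TF)."""
    fm = _empty_matrix(genes, list(chip_peaks_by_tf), "C")
    for tf, peaks in chip_peaks_by_tf.items():
        scores = np.array([p.score for p in peaks])
        for g, asg in zip(genes, assign_windows(genes, peaks, params)):
            if asg.peak_indices.size:
                w = np.exp(-asg.distances / params.d0)
                fm.values.at[g.gene_id, tf] = float(np.sum(scores[asg.peak_indices] * w))
    return fm


def chip_peak_features(
    genes: Sequence[GeneModel],
    chip_peaks_by_tf: Mapping[str, Sequence[Peak]],
    params: DecayParams = DecayParams(),
) -> tuple[pd.Series, pd.Series]:
    """Aggregate ChIP activity per gene: decay-weighted peak count c^C and
    total peak length l^C, summed over all TFs.

    Every existing peak counts once (presence indicator), regardless of
    its score value.
    """
    gene_ids = pd.Index([g.gene_id for g in genes], name="gene_id")
    c = pd.Series(0.0, index=gene_ids, name="Peak_Count")
    l = pd.Series(0.0, index=gene_ids, name="Peak_Length")
    for tf, peaks in chip_peaks_by_tf.items():
        lengths = np.array([p.length for p in peaks], dtype=float)
        for g, asg in zip(genes, assign_windows(genes, peaks, params)):
            if asg.peak_indices.size:
                w = np.exp(-asg.distances / params.d0)
                c[g.gene_id] += float(w.sum())
                l[g.gene_id] += float(np.sum(lengths[asg.peak_indices] * w))
    return c, l


def chip_scores_CN(
    c_matrix: FeatureMatrix, c_vector: pd.Series, l_vector: pd.Series
) -> FeatureMatrix:
    """Normalise C scores per gene by the decay-weighted peak count.

    Genes without peaks (c^C = 0) keep all-zero scores.  The aggregate
    count and length enter as two additional features.
    """
    if not c_matrix.values.index.equals(c_vector.index) or not c_matrix.values.index.equals(
        l_vector.index
    ):
        raise ValueError("C matrix and peak-feature vectors must share gene ids")
    if (c_vector < 0).any():
        raise ValueError("negative peak count")
    denom = c_vector.to_numpy()
    safe = np.where(denom > 0, denom, 1.0)
    normed = c_matrix.values.to_numpy() / safe[:, None]
    normed[denom == 0, :] = 0.0
    df = pd.DataFrame(normed, index=c_matrix.values.index, columns=c_matrix.values.columns)
    df["Peak_Count"] = c_vector
    df["Peak_Length"] = l_vector
    return FeatureMatrix(values=df, variant="CN")


def chip_scores_CPF(c_vector: pd.Series, l_vector: pd.Series) -> FeatureMatrix:
    """Peak count and peak length as the only two features."""
    df = pd.DataFrame({"Peak_Count": c_vector, "Peak_Length": l_vector})
    df.index.name = "gene_id"
    return FeatureMatrix(values=df, variant="CPF")


def dnase_scores(
    genes: Sequence[GeneModel],
    dnase_peaks: Sequence[Peak],
    affinities: AffinityTable | None,
    params: DecayParams = DecayParams(),
    variant: str = "D",
) -> FeatureMatrix:
    """Gene-level features from DNase peaks and per-peak TF affinities.

    ``affinities`` may be None for the purely peak-based variants
    (DPF, DPFS).  Affinity rows are looked up by the peak key
    ``chrom:start-end`` and must cover every assigned peak.
    """
    if variant not in DNASE_VARIANTS:
        raise ValueError(f"unknown DNase variant {variant!r}")
    needs_aff = variant in ("D", "DS", "DN", "DSN")
    if needs_aff and affinities is None:
        raise ValueError(f"variant {variant} requires an affinity table")

    assignments = assign_windows(genes, dnase_peaks, params)
    gene_ids = pd.Index([g.gene_id for g in genes], name="gene_id")

    lengths = np.array([p.length for p in dnase_peaks], dtype=float)
    signals = np.array([p.signal for p in dnase_peaks], dtype=float)

    if needs_aff:
        tf_names = affinities.tf_names
        keys = [p.key for p in dnase_peaks]
        locs = affinities.values.index.get_indexer(keys)
        aff = affinities.values.to_numpy()
        widths = np.array([affinities.widths[t] for t in tf_names], dtype=float)

    c = np.zeros(len(genes))
    l = np.zeros(len(genes))
    f = np.zeros(len(genes))
    tf_block = np.zeros((len(genes), len(tf_names))) if needs_aff else None

    for gi, asg in enumerate(assignments):
        if not asg.peak_indices.size:
            continue
        w = np.exp(-asg.distances / params.d0)
        idx = asg.peak_indices
        c[gi] = w.sum()
        l[gi] = np.sum(lengths[idx] * w)
        f[gi] = np.sum(signals[idx] * w)
        if needs_aff:
            rows = locs[idx]
            if (rows < 0).any():
                missing = [keys[i] for i, r in zip(idx, rows) if r < 0]
                raise ValueError(f"no affinities for assigned peaks {missing[:3]}")
            a = aff[rows, :]  # peaks-in-window x TFs
            if variant == "D":
                tf_block[gi] = w @ a
            elif variant == "DS":
                tf_block[gi] = (w * signals[idx]) @ a
            else:  # DN, DSN use binding-site-normalised affinities
                sites = np.maximum(lengths[idx][:, None] - widths[None, :] + 1.0, 1.0)
                tf_block[gi] = w @ (a / sites)

    cols: dict[str, np.ndarray] = {}
    if variant in ("D", "DS"):
        df = pd.DataFrame(tf_block, index=gene_ids, columns=tf_names)
        return FeatureMatrix(values=df, variant=variant)
    if variant in ("DN", "DSN"):
        df = pd.DataFrame(tf_block, index=gene_ids, columns=tf_names)
        df["Peak_Count"] = c
        df["Peak_Length"] = l
        if variant == "DSN":
            df["Peak_Signal"] = f
        return FeatureMatrix(values=df, variant=variant)
    cols["Peak_Count"] = c
    cols["Peak_Length"] = l
    if variant == "DPFS":
        cols["Peak_Signal"] = f
    return FeatureMatrix(values=pd.DataFrame(cols, index=gene_ids), variant=variant)


def build_design(
    matrix: FeatureMatrix, expression: pd.Series | Mapping[str, float]
) -> tuple[pd.DataFrame, pd.Series]:
    """Align a feature matrix with expression and log-transform both.

    Rows are restricted to the gene-id intersection (sorted); every entry
    of X and y becomes log2(value + 1).  Centering and scaling happen
    later, per training fold, inside the model.
    """
    expr = pd.Series(expression).astype(float)
    shared = sorted(set(matrix.values.index) & set(expr.index))
    if len(shared) < 2:
        raise ValueError("need at least 2 genes shared between matrix and expression")
    X = np.log2(matrix.values.loc[shared] + 1.0)
    y = np.log2(expr.loc[shared] + 1.0)
    y.name = "expression"
    y.index.name = "gene_id"
    return X, y
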