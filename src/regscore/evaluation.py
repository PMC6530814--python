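"""Confounder diagnostics and gold-standard scoring of inferred regulators.

Pairwise Spearman correlations between TF-gene score columns quantify
feature redundancy; correlations of TF columns against the aggregate
peak features (count, length, signal) expose chromatin-activity
confounding.  Gold-standard evaluation ranks TFs by their regression
coefficient and scores the ranking by precision/recall against a set of
TFs deemed truly relevant, with the area under the PR curve computed by
the nonlinear (hyperbolic) interpolation between operating points that
PR analysis packages use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ranksums, spearmanr

from .io import PEAK_FEATURE_COLUMNS, FeatureMatrix, Peak

__all__ = [
    "pairwise_correlation",
    "feature_confounder_correlation",
    "GoldStandard",
    "PRResult",
    "gold_standard_eval",
    "expressed_top_tf_check",
    "overlap_fraction",
]


def _as_frame(X: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    return X.values if isinstance(X, FeatureMatrix) else X


def pairwise_correlation(
    X: FeatureMatrix | pd.DataFrame, subset: str = "tf_columns"
) -> tuple[pd.DataFrame, float]:
    """All-against-all Spearman correlations of feature columns.

    Returns the symmetric correlation matrix (unit diagonal) and the
    median over its strictly-upper-triangle entries.  Constant columns
    have undefined correlations; those entries are NaN and excluded from
    the median, with a warning.
    """
    df = _as_frame(X)
    if subset == "tf_columns":
        df = df[[c for c in df.columns if c not in PEAK_FEATURE_COLUMNS]]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    if df.shape[1] < 2 or df.shape[0] < 3:
        raise ValueError("need at least 2 columns and 3 rows")

    arr = df.to_numpy(dtype=float)
    const = arr.std(axis=0) == 0
    ranks = np.apply_along_axis(rankdata, 0, arr)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr[const, :] = np.nan
    corr[:, const] = np.nan
    np.fill_diagonal(corr, 1.0)
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant column(s) excluded from the correlation median"
        )
    iu = np.triu_indices_from(corr, k=1)
    upper = corr[iu]
    median = float(np.nanmedian(upper)) if np.isfinite(upper).any() else float("nan")
    cm = pd.DataFrame(corr, index=df.columns, columns=df.columns)
    return cm, median


def feature_confounder_correlation(
    X: FeatureMatrix | pd.DataFrame,
    confounders: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Spearman correlation of every TF column against each peak feature.

    The peak-feature columns are taken from ``X`` itself or supplied
    separately via ``confounders`` (genes x {Peak_Count, Peak_Length,
    Peak_Signal}).  Returns a TFs x confounders table.
    """
    df = _as_frame(X)
    tf_cols = [c for c in df.columns if c not in PEAK_FEATURE_COLUMNS]
    if confounders is None:
        conf_cols = [c for c in df.columns if c in PEAK_FEATURE_COLUMNS]
        if not conf_cols:
            raise ValueError("matrix has no peak-feature columns and none were supplied")
        confounders = df[conf_cols]
    confounders = confounders.loc[df.index]
    out = pd.DataFrame(index=pd.Index(tf_cols, name="tf"), columns=confounders.columns, dtype=float)
    for cc in confounders.columns:
        cv = confounders[cc].to_numpy(dtype=float)
        for tf in tf_cols:
            out.at[tf, cc] = spearmanr(df[tf].to_numpy(dtype=float), cv).statistic
    return out


# ---------------------------------------------------------------------------
# gold standard


@dataclass
class GoldStandard:
    """TFs deemed truly relevant (e.g. expressed >= 5 TPM in the tissue)."""

    tf_names: frozenset[str]
    expression_threshold: float = 5.0

    def __post_init__(self) -> None:
        self.tf_names = frozenset(self.tf_names)
        if not self.tf_names:
            raise ValueError("gold standard is empty")

    @classmethod
    def from_expression(
        cls,
        expression: pd.Series | Mapping[str, float],
        universe: Sequence[str] | None = None,
        threshold: float = 5.0,
    ) -> "GoldStandard":
        """All genes expressed at or above ``threshold``, optionally
        restricted to a TF universe (e.g. the PSEM collection)."""
        s = pd.Series(expression)
        names = set(s.index[s >= threshold])
        if universe is not None:
            names &= set(universe)
        return cls(tf_names=frozenset(names), expression_threshold=threshold)


@dataclass
class PRResult:
    """Precision-recall points over a TF ranking, plus the AUPR."""

    precision: np.ndarray
    recall: np.ndarray
    aupr: float
    tp: int
    fp: int
    fn: int


def _dg_segment_area(tp_a: float, fp_a: float, tp_b: float, fp_b: float) -> float:
    """Area under the interpolated precision between two operating points.

    TP and FP are interpolated linearly in between, giving precision
    x / (c1*x + c0) as a function of the TP count x — the standard
    nonlinear PR interpolation.  The area is over recall, i.e. the
    integral dx is divided by the positive count later.
    """
    if tp_b <= tp_a:
        return 0.0
    s = (fp_b - fp_a) / (tp_b - tp_a)
    c1 = 1.0 + s
    c0 = fp_a - s * tp_a
    if c0 <= 1e-12:
        # precision constant 1/c1 over the segment
        return (tp_b - tp_a) / c1

    def antideriv(x: float) -> float:
        return x / c1 - (c0 / c1**2) * np.log(c1 * x + c0)

    return antideriv(tp_b) - antideriv(tp_a)


def gold_standard_eval(
    coefficients: pd.Series | Mapping[str, float],
    gs: GoldStandard,
    absolute: bool = False,
) -> PRResult:
    """Precision/recall of a coefficient ranking against a gold standard.

    TFs are ranked by descending coefficient (or |coefficient| with
    ``absolute``); ties form a single operating point.  Recall is against
    the gold-standard members present in the ranked universe; members the
    model could never retrieve are ignored with a warning.
    """
    coef = pd.Series(coefficients).astype(float)
    if coef.empty:
        raise ValueError("no coefficients to rank")
    universe = set(coef.index)
    positives = gs.tf_names & universe
    outside = gs.tf_names - universe
    if outside:
        warnings.warn(f"{len(outside)} gold-standard TFs not in the ranked universe")
    if not positives:
        return PRResult(np.array([0.0]), np.array([0.0]), 0.0, 0, len(coef), 0)

    key = coef.abs() if absolute else coef
    order = key.sort_values(ascending=False)
    is_pos = np.array([name in positives for name in order.index])
    vals = order.to_numpy()
    # group boundaries: last index of each tie group
    boundaries = np.flatnonzero(np.diff(vals) != 0)
    ends = np.append(boundaries, len(vals) - 1)

    tp_cum = np.cumsum(is_pos)
    fp_cum = np.cumsum(~is_pos)
    tps = tp_cum[ends].astype(float)
    fps = fp_cum[ends].astype(float)
    n_pos = float(len(positives))

    precision = tps / (tps + fps)
    recall = tps / n_pos
    area = 0.0
    prev_tp, prev_fp = 0.0, 0.0
    for tp_b, fp_b in zip(tps, fps):
        area += _dg_segment_area(prev_tp, prev_fp, tp_b, fp_b)
        prev_tp, prev_fp = tp_b, fp_b
    aupr = area / n_pos

    tp_final = int(tps[-1])
    return PRResult(
        precision=precision,
        recall=recall,
        aupr=float(aupr),
        tp=tp_final,
        fp=int(fps[-1]),
        fn=int(n_pos) - tp_final,
    )


def expressed_top_tf_check(
    coefficients_original: pd.Series | Mapping[str, float],
    coefficients_permuted: pd.Series | Mapping[str, float],
    expression: pd.Series | Mapping[str, float],
    k: int = 100,
) -> tuple[pd.Series, pd.Series, float]:
    """Compare the expression of the top-k selected TFs between models.

    "Selected" means a nonzero coefficient; the top k by |coefficient|
    from each model are mapped to expression (a TF that cannot be mapped
    counts as not expressed, i.e. 0).  If the original model selected
    fewer than k TFs, the same reduced number is drawn from the permuted
    model.  Returns both expression samples and the two-sided Wilcoxon
    rank-sum p-value.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    co = pd.Series(coefficients_original).astype(float)
    cp = pd.Series(coefficients_permuted).astype(float)
    expr = pd.Series(expression).astype(float)
    sel_o = co[co != 0]
    sel_p = cp[cp != 0]
    if sel_o.empty and sel_p.empty:
        raise ValueError("no nonzero coefficients in either model")
    k_eff = min(k, len(sel_o)) if len(sel_o) else min(k, len(sel_p))
    top_o = sel_o.abs().sort_values(ascending=False).head(k_eff).index
    top_p = sel_p.abs().sort_values(ascending=False).head(k_eff).index
    ex_o = pd.Series([float(expr.get(t, 0.0)) for t in top_o], index=top_o)
    ex_p = pd.Series([float(expr.get(t, 0.0)) for t in top_p], index=top_p)
    if ex_o.equals(ex_p) or (ex_o.to_numpy() == ex_p.to_numpy()).all():
        return ex_o, ex_p, 1.0
    stat = ranksums(ex_o.to_numpy(), ex_p.to_numpy())
    return ex_o, ex_p, float(stat.pvalue)


# ---------------------------------------------------------------------------
# peak overlap


def _merge_intervals(ivs: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    ivs = sorted(ivs)
    starts, ends = [], []
    for s, e in ivs:
        if ends and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.array(starts), np.array(ends)


def overlap_fraction(
    query_peaks: Sequence[Peak],
    reference_peaks: Sequence[Peak],
    windows: Sequence[tuple[str, int, int]] | None = None,
) -> float:
    """Fraction of query peaks overlapping (>=1 bp) any reference peak.

    With ``windows`` (chrom, start, end triples, e.g. gene TSS windows),
    the query is first restricted to peaks overlapping any window.
    """
    if windows is not None:
        win_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in windows:
            win_by_chrom.setdefault(chrom, []).append((s, e))
        merged = {c: _merge_intervals(v) for c, v in win_by_chrom.items()}

        def in_windows(p: Peak) -> bool:
            if p.chrom not in merged:
                return False
            ws, we = merged[p.chrom]
            i = np.searchsorted(ws, p.end, side="left")
            return bool((we[:i] > p.start).any())

        query_peaks = [p for p in query_peaks if in_windows(p)]
    if not query_peaks:
        return 0.0

    ref_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in reference_peaks:
        ref_by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    merged_ref = {c: _merge_intervals(v) for c, v in ref_by_chrom.items()}

    hits = 0
    for p in query_peaks:
        if p.chrom not in merged_ref:
            continue
        rs, re = merged_ref[p.chrom]
        i = np.searchsorted(rs, p.end, side="left")
        if (re[:i] > p.start).any():
            hits += 1
    return hits / len(query_peaks)
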