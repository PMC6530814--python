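"""End-to-end experiment: simulate -> score -> permute -> model -> diagnose.

``run_experiment`` reproduces the study skeleton on one input set: for
each requested scoring variant it builds the feature matrix, fits the
elastic-net expression model on the original and on the row-permuted
matrix, and collects the diagnostics (fold performances with a paired
Wilcoxon comparison, nonzero-coefficient counts, confounder
correlations, gold-standard AUPR, expression of the top selected TFs).
All intermediates land on disk next to a manifest, so every number in
the summary can be recomputed by calling the module operations directly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from . import io as rio
from .evaluation import (
    GoldStandard,
    expressed_top_tf_check,
    feature_confounder_correlation,
    gold_standard_eval,
    pairwise_correlation,
)
from .io import FeatureMatrix
from .model import ExpressionModel, ModelConfig
from .permutation import PermutationScheme, permute_rows
from .scoring import (
    DecayParams,
    chip_peak_features,
    chip_scores_C,
    chip_scores_CN,
    chip_scores_CPF,
    dnase_scores,
)
from .simulate import Fixture, FixtureConfig, generate_fixture

logger = logging.getLogger("regscore")

__all__ = ["RunConfig", "run_experiment"]


@dataclass
class RunConfig:
    """Configuration of one experiment run.

    The experiment permutes whole rows of each matrix (every column in
    scope), mirroring the shuffle used in the randomization diagnostics;
    the per-variant scoped default of the ``permute`` CLI applies only
    there.
    """

    out_dir: str | Path = "regscore_run"
    variants: tuple[str, ...] = ("D", "DN")
    fixture: FixtureConfig = field(default_factory=FixtureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    permutation_seed: int = 0
    permutation_scope: str = "all_columns"
    gold_standard_threshold: float = 5.0
    top_k_tfs: int = 100
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "fixture" in d and isinstance(d["fixture"], dict):
            d["fixture"] = FixtureConfig(**d["fixture"])
        if "model" in d and isinstance(d["model"], dict):
            m = dict(d["model"])
            if "alpha_grid" in m:
                m["alpha_grid"] = tuple(m["alpha_grid"])
            d["model"] = ModelConfig(**m)
        if "variants" in d:
            d["variants"] = tuple(d["variants"])
        return cls(**d)


def _fit_matrix(matrix: FeatureMatrix, expression: pd.Series, config: ModelConfig):
    return ExpressionModel.from_feature_matrix(matrix, expression, config).fit()


def run_experiment(config: RunConfig) -> dict:
    """Run the original-versus-permuted experiment; returns the summary."""
    t_start = time.time()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        logger.info("stage %s", stage)
        fx = generate_fixture(config.fixture, out / "fixture")

        stage = "annotate"
        logger.info("stage %s", stage)
        params = DecayParams(d0=config.fixture.d0, window=config.fixture.window)
        matrices: dict[str, FeatureMatrix] = {}
        for variant in config.variants:
            if variant == "D":
                matrices[variant] = fx.d_matrix
            elif variant in ("C", "CN", "CPF"):
                if variant == "C":
                    matrices[variant] = chip_scores_C(fx.genes, fx.chip_peaks_by_tf, params)
                else:
                    c, l = chip_peak_features(fx.genes, fx.chip_peaks_by_tf, params)
                    if variant == "CPF":
                        matrices[variant] = chip_scores_CPF(c, l)
                    else:
                        matrices[variant] = chip_scores_CN(
                            chip_scores_C(fx.genes, fx.chip_peaks_by_tf, params), c, l
                        )
            else:
                matrices[variant] = dnase_scores(
                    fx.genes, fx.dnase_peaks, fx.affinities, params, variant
                )
            rio.write_matrix(matrices[variant], out / f"matrix_{variant}.tsv")

        gs = GoldStandard.from_expression(
            fx.tf_expression,
            universe=[m.tf_name for m in fx.psems],
            threshold=config.gold_standard_threshold,
        )

        summary: dict = {
            "config": {
                "variants": list(config.variants),
                "fixture": asdict(config.fixture),
                "model": {**asdict(config.model), "alpha_grid": list(config.model.alpha_grid)},
                "permutation_seed": config.permutation_seed,
                "permutation_scope": config.permutation_scope,
            },
            "ground_truth": fx.ground_truth,
            "variants": {},
        }
        manifest: dict[str, str] = {k: str(v) for k, v in fx.paths.items()}

        for variant in config.variants:
            stage = f"permute[{variant}]"
            logger.info("stage %s", stage)
            fm = matrices[variant]
            perm = permute_rows(
                fm, PermutationScheme(seed=config.permutation_seed, scope=config.permutation_scope)
            )
            rio.write_matrix(perm, out / f"matrix_{variant}_permuted.tsv")

            stage = f"train[{variant}]"
            logger.info("stage %s", stage)
            res_o = _fit_matrix(fm, fx.expression, config.model)
            res_p = _fit_matrix(perm, fx.expression, config.model)
            for tag, res in (("original", res_o), ("permuted", res_p)):
                res.to_frame().to_csv(out / f"folds_{variant}_{tag}.tsv", sep="\t", index=False)
                res.coef_table.to_csv(out / f"coefficients_{variant}_{tag}.tsv", sep="\t")

            stage = f"diagnose[{variant}]"
            logger.info("stage %s", stage)
            has_tfs = len(fm.tf_columns) >= 2
            if has_tfs:
                _, med_o = pairwise_correlation(fm, subset="tf_columns")
                _, med_p = pairwise_correlation(perm, subset="tf_columns")
                conf = feature_confounder_correlation(
                    fm.values[fm.tf_columns].join(fx.peak_features)
                )

            stage = f"evaluate[{variant}]"
            logger.info("stage %s", stage)
            if has_tfs:
                coef_o = res_o.mean_coefficients[fm.tf_columns]
                coef_p = res_p.mean_coefficients[fm.tf_columns]
                pr = gold_standard_eval(coef_o, gs)
                ex_o, ex_p, p_expr = expressed_top_tf_check(
                    coef_o, coef_p, fx.tf_expression, k=config.top_k_tfs
                )
            sp_o, sp_p = res_o.spearman_values, res_p.spearman_values
            if np.allclose(sp_o, sp_p):
                p_perf = 1.0
            else:
                p_perf = float(wilcoxon(sp_o, sp_p).pvalue)

            summary["variants"][variant] = {
                "n_features": int(fm.values.shape[1]),
                "original": {
                    "mean_spearman": float(sp_o.mean()),
                    "sd_spearman": float(sp_o.std(ddof=1)),
                    "mean_mse": res_o.mean_mse,
                    "mean_nonzero": float(res_o.nonzero_counts.mean()),
                },
                "permuted": {
                    "mean_spearman": float(sp_p.mean()),
                    "sd_spearman": float(sp_p.std(ddof=1)),
                    "mean_mse": res_p.mean_mse,
                    "mean_nonzero": float(res_p.nonzero_counts.mean()),
                },
                "wilcoxon_p_original_vs_permuted": p_perf,
            }
            if has_tfs:
                summary["variants"][variant].update(
                    {
                        "median_pairwise_tf_correlation": {
                            "original": med_o,
                            "permuted": med_p,
                        },
                        "median_corr_tf_vs_peak_length": float(conf["Peak_Length"].median()),
                        "aupr_vs_gold_standard": pr.aupr,
                        "gold_standard_tp_fp_fn": [pr.tp, pr.fp, pr.fn],
                        "top_tf_expression_ranksum_p": p_expr,
                        "mean_top_tf_expression": {
                            "original": float(ex_o.mean()),
                            "permuted": float(ex_p.mean()),
                        },
                    }
                )
            for suffix in (
                f"matrix_{variant}.tsv",
                f"matrix_{variant}_permuted.tsv",
                f"folds_{variant}_original.tsv",
                f"folds_{variant}_permuted.tsv",
                f"coefficients_{variant}_original.tsv",
                f"coefficients_{variant}_permuted.tsv",
            ):
                manifest[suffix] = str(out / suffix)
    except Exception:
        logger.exception("experiment failed at stage %s", stage)
        raise

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest["summary"] = str(out / "summary.json")
    manifest["runtime_seconds"] = f"{time.time() - t_start:.2f}"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return summary
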