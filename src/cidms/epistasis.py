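"""Double-mutant prediction and epistasis under four sub-models.

Sub-models of the genotype-phenotype map compared here:

* ``log_additive`` — null model: log2 GFP effects of the two singles add.
* ``full`` — folding ddG adds; GFP follows the folding sigmoid composed
  with the Ackers repression curve at the condition's CI_E.
* ``folding_only`` — folding ddG adds, but GFP is linear in log2 of the
  functional repressor concentration (slope beta, intercept alpha, with the
  two conditions offset by C = beta * log2(expression ratio)).
* ``regulation_only`` — the functional repressor concentration adds; GFP
  follows the Ackers curve.

Epistasis is scored against the log-additive null: positive epistasis means
more repression (lower GFP) than expected, i.e. suppressive; negative means
less repression, i.e. enhancing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import wilcoxon

from . import thermo
from .thermo import ThermoParams

MODELS = ("log_additive", "full", "folding_only", "regulation_only")


# ---------------------------------------------------------------------------
# Null model and epistasis score
# ---------------------------------------------------------------------------

def log_additive_prediction(log2_gfp_a, log2_gfp_b, log2_gfp_wt):
    """Log-additive double-mutant expectation (inputs and output in log2 AU)."""
    return (
        np.asarray(log2_gfp_a, float)
        + np.asarray(log2_gfp_b, float)
        - np.asarray(log2_gfp_wt, float)
    )


def epistasis_score(observed_log2, expected_log2):
    """Signed deviation from the expectation, in log2 AU.

    Positive when the observed (or model-predicted) GFP is lower than the
    log-additive expectation — repression greater than expected
    (suppressive interaction); negative for the converse (enhancing).
    """
    return np.asarray(expected_log2, float) - np.asarray(observed_log2, float)


# ---------------------------------------------------------------------------
# Folding-only linear sub-model
# ---------------------------------------------------------------------------

@dataclass
class FoldingOnlyModel:
    """log2 GFP = alpha + beta * log2([CI_T]); conditions differ by
    C = beta * log2(expression_ratio)."""

    c: float
    beta: float
    alpha: float

    def log2_gfp_from_citotal(self, ci_total):
        return self.alpha + self.beta * np.log2(np.asarray(ci_total, float))

    def citotal_from_log2_gfp(self, log2_gfp):
        return 2.0 ** ((np.asarray(log2_gfp, float) - self.alpha) / self.beta)

    def log2_gfp_from_dgf(self, dg_f, condition: str, params: ThermoParams):
        f_n = thermo.fraction_folded(dg_f, params)
        return self.log2_gfp_from_citotal(f_n * params.ci_e(condition))

    def dgf_from_log2_gfp(self, log2_gfp, condition: str, params: ThermoParams):
        f_n = self.citotal_from_log2_gfp(log2_gfp) / params.ci_e(condition)
        return thermo.dgf_from_fraction(f_n, params)


def fit_folding_only(
    low_log2,
    high_log2,
    params: ThermoParams,
    c_range: tuple[float, float] = (-3.3, -1.3),
    c_step: float = 0.03,
    n_line_points: int = 100,
) -> FoldingOnlyModel:
    """Grid search for the inter-condition offset C of the folding-only model.

    For each candidate C the line high = low + C is sampled between the
    wild-type and maximal low-expression GFP (``n_line_points`` points) and
    the sum of squared distances from the observed (low, high) pairs to the
    sampled line is accumulated; the smallest-SSDC C wins.  beta follows
    from C = beta * log2(expression_ratio) and alpha from the wild-type
    anchor at low expression.
    """
    low = np.asarray(low_log2, float)
    high = np.asarray(high_log2, float)
    if low.size == 0:
        raise ValueError("no observed (low, high) phenotype pairs")
    candidates = np.arange(c_range[0], c_range[1] + 0.5 * c_step, c_step)
    xs = np.linspace(params.log2_gfp_wt_low, params.log2_gfp_max, n_line_points)
    best_c, best_ssdc = None, np.inf
    for c in candidates:
        line = np.column_stack([xs, xs + c])
        _, dist2, ssdc = project_to_points(np.column_stack([low, high]), line)
        if ssdc < best_ssdc:
            best_c, best_ssdc = float(c), float(ssdc)
    beta = best_c / np.log2(params.expression_ratio)
    alpha = params.log2_gfp_wt_low - beta * np.log2(
        params.f_n_wt * params.ci_e_low
    )
    return FoldingOnlyModel(c=best_c, beta=beta, alpha=alpha)


# ---------------------------------------------------------------------------
# Model curves in the (low, high) plane and projection
# ---------------------------------------------------------------------------

@dataclass
class CurveModel:
    """A sub-model's predicted (log2 GFP low, log2 GFP high) curve.

    ``parameter`` holds the latent coordinate of each curve point: dG_F for
    the full and folding-only models, [CI_T] at low expression for the
    regulation-only model.
    """

    model_id: str
    parameter: np.ndarray
    low: np.ndarray
    high: np.ndarray

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.low, self.high])


def build_curve(
    model_id: str,
    params: ThermoParams,
    n_grid: int = 100,
    dg_range: tuple[float, float] = (-3.0, 3.0),
    folding_model: FoldingOnlyModel | None = None,
) -> CurveModel:
    """Sample a sub-model's two-condition phenotype curve.

    The full and folding-only models sample ``n_grid`` dG_F values evenly
    spaced over ``dg_range``; the regulation-only model samples the
    functional concentration from 0 to its wild-type value at low
    expression.  The log-additive "curve" is the wild-type offset line
    high = low + (wt_high - wt_low).
    """
    if model_id == "full":
        grid = np.linspace(*dg_range, n_grid)
        low = thermo.log2_gfp_from_dgf(grid, "low", params)
        high = thermo.log2_gfp_from_dgf(grid, "high", params)
    elif model_id == "folding_only":
        if folding_model is None:
            raise ValueError("folding_only curve needs a fitted FoldingOnlyModel")
        grid = np.linspace(*dg_range, n_grid)
        low = folding_model.log2_gfp_from_dgf(grid, "low", params)
        high = folding_model.log2_gfp_from_dgf(grid, "high", params)
    elif model_id == "regulation_only":
        cit_wt = params.f_n_wt * params.ci_e_low
        grid = np.linspace(0.0, cit_wt, n_grid)
        low = np.log2(thermo.gfp_from_citotal(grid, params))
        high = np.log2(
            thermo.gfp_from_citotal(grid * params.expression_ratio, params)
        )
    elif model_id == "log_additive":
        wt_low = params.log2_gfp_wt_low
        wt_high = float(
            thermo.log2_gfp_from_dgf(params.dgf_wt, "high", params)
        )
        grid = np.linspace(wt_low, params.log2_gfp_max, n_grid)
        low = grid.copy()
        high = grid + (wt_high - wt_low)
    else:
        raise ValueError(f"unknown model {model_id!r}")
    return CurveModel(model_id, grid, np.asarray(low), np.asarray(high))


def densify_curve(
    curve: CurveModel,
    params: ThermoParams,
    n_dense: int = 10_000,
    folding_model: FoldingOnlyModel | None = None,
) -> CurveModel:
    """Re-evaluate the model on a dense parameter grid (exact, not interpolated)."""
    if curve.model_id in ("full", "folding_only"):
        dg_range = (curve.parameter[0], curve.parameter[-1])
        return build_curve(
            curve.model_id, params, n_dense, dg_range, folding_model
        )
    return build_curve(curve.model_id, params, n_dense)


def project_to_points(
    points: np.ndarray, curve_points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Nearest-point projection onto a sampled curve.

    Returns (indices of nearest curve points, squared distances, SSDC).
    """
    tree = cKDTree(curve_points)
    dist, idx = tree.query(np.asarray(points, float))
    return idx, dist**2, float((dist**2).sum())


def project_to_curve(
    points: np.ndarray,
    curve: CurveModel,
    params: ThermoParams,
    n_dense: int = 10_000,
    folding_model: FoldingOnlyModel | None = None,
) -> dict:
    """Project observed (low, high) pairs to a sub-model curve.

    Each point maps to the nearest point of the densely resampled curve,
    which carries a unique latent parameter (dG_F or [CI_T]).  Returns
    projected coordinates, per-point squared distance, the total SSDC, and
    the per-point latent parameter.
    """
    dense = densify_curve(curve, params, n_dense, folding_model)
    idx, dist2, ssdc = project_to_points(points, dense.points)
    return {
        "projected": dense.points[idx],
        "parameter": dense.parameter[idx],
        "dist2": dist2,
        "ssdc": ssdc,
    }


# ---------------------------------------------------------------------------
# Double-mutant prediction
# ---------------------------------------------------------------------------

def predict_doubles(
    singles: pd.DataFrame,
    pairs: pd.DataFrame,
    model_id: str,
    params: ThermoParams,
    condition: str,
    folding_model: FoldingOnlyModel | None = None,
) -> pd.DataFrame:
    """Predict double-mutant log2 GFP under one sub-model.

    ``singles`` indexes single variants and must carry the columns the model
    needs: ``log2_gfp`` (observed, this condition) for the log-additive
    model, ``dgf`` (projected folding free energy) for the full and
    folding-only models, ``cit_low`` (projected functional concentration at
    low expression) for the regulation-only model.  ``pairs`` has columns
    single_a, single_b.  Negative composed concentrations in the
    regulation-only model are clamped to zero and flagged.
    """
    sa = singles.loc[pairs["single_a"]]
    sb = singles.loc[pairs["single_b"]]
    out = pairs.copy()
    out["condition"] = condition
    out["model"] = model_id
    out["clamped"] = False
    if model_id == "log_additive":
        wt_log2 = float(thermo.log2_gfp_from_dgf(params.dgf_wt, condition, params))
        out["predicted_log2_gfp"] = log_additive_prediction(
            sa["log2_gfp"].to_numpy(), sb["log2_gfp"].to_numpy(), wt_log2
        )
    elif model_id in ("full", "folding_only"):
        dgf_ab = thermo.additive_ddg(
            sa["dgf"].to_numpy(), sb["dgf"].to_numpy(), params.dgf_wt
        )
        if model_id == "full":
            out["predicted_log2_gfp"] = thermo.log2_gfp_from_dgf(
                dgf_ab, condition, params
            )
        else:
            if folding_model is None:
                raise ValueError("folding_only predictions need a fitted model")
            out["predicted_log2_gfp"] = folding_model.log2_gfp_from_dgf(
                dgf_ab, condition, params
            )
    elif model_id == "regulation_only":
        scale = params.ci_e(condition) / params.ci_e_low
        cit_wt = params.f_n_wt * params.ci_e_low
        cit_ab = sa["cit_low"].to_numpy() + sb["cit_low"].to_numpy() - cit_wt
        clamped = cit_ab < 0
        out["clamped"] = clamped
        cit_ab = np.maximum(cit_ab, 0.0)
        out["predicted_log2_gfp"] = np.log2(
            thermo.gfp_from_citotal(cit_ab * scale, params)
        )
    else:
        raise ValueError(f"unknown model {model_id!r}")
    return out


def percent_variance_explained(observed, predicted) -> float:
    """PVE = (1 - SS_res / SS_total) x 100; may be negative."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.size < 2:
        raise ValueError("PVE needs at least 2 observations")
    ss_res = ((observed - predicted) ** 2).sum()
    ss_tot = ((observed - observed.mean()) ** 2).sum()
    return float((1.0 - ss_res / ss_tot) * 100.0)


# ---------------------------------------------------------------------------
# Summaries and epistasis classification
# ---------------------------------------------------------------------------

def assign_effect_bins(singles: pd.DataFrame, effect_col: str, n_bins: int = 5) -> pd.Series:
    """Equal-population bins of single mutants ordered by effect.

    Ties broken by a stable sort on (effect, variant id); bin populations
    differ by at most one.
    """
    effect = singles[effect_col].to_numpy(float)
    ids = singles.index.to_numpy().astype(str)
    order = np.lexsort((ids, effect))
    ranks = np.empty(len(effect), dtype=int)
    ranks[order] = np.arange(len(effect))
    bins = (ranks * n_bins) // len(effect)
    return pd.Series(bins, index=singles.index, name="bin")


def binned_median_summary(
    singles: pd.DataFrame,
    doubles: pd.DataFrame,
    effect_col: str,
    value_cols,
    n_bins: int = 5,
) -> pd.DataFrame:
    """n_bins x n_bins grid of double-mutant medians.

    Singles are ranked into equally populated bins by ``effect_col``;
    ``doubles`` rows (single_a, single_b, value columns) land in the
    unordered bin pair of their constituents; medians are reported per cell.
    """
    bins = assign_effect_bins(singles, effect_col, n_bins)
    ba = bins.loc[doubles["single_a"]].to_numpy()
    bb = bins.loc[doubles["single_b"]].to_numpy()
    cell = pd.DataFrame({
        "bin_a": np.minimum(ba, bb),
        "bin_b": np.maximum(ba, bb),
    })
    for col in value_cols:
        cell[col] = doubles[col].to_numpy()
    return (
        cell.groupby(["bin_a", "bin_b"])[list(value_cols)]
        .median()
        .reset_index()
    )


EPISTASIS_CLASSES = (
    "stable",
    "magnitude_shift",
    "sign_switch_pos_to_neg",
    "sign_switch_neg_to_pos",
)


def classify_epistasis_change(eps_low, eps_high, dead_band: float = 0.1) -> np.ndarray:
    """Class of the epistasis change between low and high expression.

    Scores within ``dead_band`` of zero count as null.  Pairs null at both
    conditions, or with the same sign at both, and a magnitude change within
    the dead band are "stable"; same-sign (or one-null) changes larger than
    the dead band are "magnitude_shift"; opposite active signs are the two
    sign-switch classes.
    """
    lo = np.atleast_1d(np.asarray(eps_low, float))
    hi = np.atleast_1d(np.asarray(eps_high, float))
    sign_lo = np.where(np.abs(lo) <= dead_band, 0, np.sign(lo))
    sign_hi = np.where(np.abs(hi) <= dead_band, 0, np.sign(hi))
    out = np.full(lo.shape, "stable", dtype=object)
    shift = (sign_lo * sign_hi >= 0) & (np.abs(hi - lo) > dead_band)
    out[shift] = "magnitude_shift"
    out[(sign_lo > 0) & (sign_hi < 0)] = "sign_switch_pos_to_neg"
    out[(sign_lo < 0) & (sign_hi > 0)] = "sign_switch_neg_to_pos"
    return out


def wilcoxon_epistasis_tests(
    epistasis: pd.DataFrame, value_col: str, group_cols
) -> pd.DataFrame:
    """One-sample Wilcoxon signed-rank tests of epistasis against 0 per group,
    with Bonferroni correction across groups."""
    rows = []
    for key, sub in epistasis.groupby(list(group_cols)):
        values = sub[value_col].to_numpy()
        if np.allclose(values, 0) or len(values) < 5:
            p = np.nan
        else:
            p = wilcoxon(values).pvalue
        rows.append({
            **dict(zip(group_cols, key if isinstance(key, tuple) else (key,))),
            "n": len(values),
            "median": float(np.median(values)),
            "p_value": p,
        })
    out = pd.DataFrame(rows)
    m = out["p_value"].notna().sum()
    out["p_bonferroni"] = np.minimum(out["p_value"] * m, 1.0)
    return out


SINGLE_CLASSES = (
    "neutral_both",
    "low_only_detrimental",
    "partial_high_null_low",
    "null_both",
    "other",
)


def classify_single_mutants(
    low_log2,
    high_log2,
    wt_low: float,
    wt_high: float,
    max_log2: float,
    tol: float = 1.0,
) -> np.ndarray:
    """Four-class pattern of single-mutant effects at two expression levels.

    Classes: near-neutral at both; near-neutral at high but detrimental at
    low; partially detrimental at high and null-like at low; null-like at
    both; anything else is "other".  ``tol`` (log2 AU) is the half-width of
    the "near" bands around the wild-type and null phenotypes.
    """
    low = np.atleast_1d(np.asarray(low_log2, float))
    high = np.atleast_1d(np.asarray(high_log2, float))
    near_wt_low = np.abs(low - wt_low) <= tol
    near_wt_high = np.abs(high - wt_high) <= tol
    null_low = np.abs(low - max_log2) <= tol
    null_high = np.abs(high - max_log2) <= tol
    out = np.full(low.shape, "other", dtype=object)
    out[near_wt_low & near_wt_high] = "neutral_both"
    out[near_wt_high & ~near_wt_low] = "low_only_detrimental"
    out[null_low & ~near_wt_high & ~null_high] = "partial_high_null_low"
    out[null_low & null_high] = "null_both"
    return out
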