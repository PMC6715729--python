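"""Count-to-phenotype scoring for the two-output sort-seq experiment.

Per condition (low/high repressor expression) the pipeline turns per-variant
read counts from Input, Output1 (near-neutral gate) and Output2 (intermediate
gate) x 3 biological replicates into calibrated log2-GFP phenotypes:

1. keep variants with >= 100 input reads in every replicate and at most two
   nucleotide changes;
2. per-replicate log2 enrichment scores relative to wild type with 0.5
   pseudocounts and Poisson-based standard errors;
3. iterative random-effects combination of replicate scores (50 iterations);
4. variants whose combined Output1+Output2 error exceeds 1 are dropped;
5. Output2 scores of strongly depleted variants are reflected to positive
   values so they rank above the intermediate class;
6. a weighted linear calibration against individually measured genotypes
   maps scores to log2-GFP with full error propagation;
7. replicates are affinely mapped onto a reference replicate using wild-type
   and nonsense anchors, combined by the same random-effects model,
   aggregated to amino-acid level, and finally rescaled into the
   experimentally accessible GFP window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .sequences import WT_ID, hamming_distance

DETECTION_RANGE = (4.5, 12.8)


# ---------------------------------------------------------------------------
# Enrichment scores
# ---------------------------------------------------------------------------

def enrichment_scores(
    counts: pd.DataFrame, wt_id: str = WT_ID, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-variant, per-output, per-replicate enrichment scores and errors.

    ``counts`` is tidy with columns variant_id, sample (input|output1|output2),
    replicate, count, for a single condition.  The score is the log2
    output/input frequency ratio relative to wild type; the error combines
    the four Poisson terms with the same pseudocounts.
    """
    wide = counts.pivot_table(
        index="variant_id", columns=["sample", "replicate"], values="count",
        fill_value=0, aggfunc="sum",
    )
    if wt_id not in wide.index:
        raise ValueError(f"wild-type row {wt_id!r} missing from count table")
    records = []
    replicates = sorted({rep for (_, rep) in wide.columns})
    for output_id, sample in (("o1", "output1"), ("o2", "output2")):
        for rep in replicates:
            c_out = wide[(sample, rep)].to_numpy(float) + pseudocount
            c_in = wide[("input", rep)].to_numpy(float) + pseudocount
            wt_out = wide.loc[wt_id, (sample, rep)] + pseudocount
            wt_in = wide.loc[wt_id, ("input", rep)] + pseudocount
            score = np.log2(c_out / wt_out) - np.log2(c_in / wt_in)
            se = np.sqrt(1 / c_in + 1 / wt_in + 1 / c_out + 1 / wt_out)
            records.append(pd.DataFrame({
                "variant_id": wide.index,
                "output_id": output_id,
                "replicate": rep,
                "score": score,
                "se": se,
            }))
    return pd.concat(records, ignore_index=True)


def filter_min_input_counts(
    counts: pd.DataFrame, threshold: int = 100, max_hamming: int = 2
) -> pd.Index:
    """Variants with >= threshold input reads in every replicate and at most
    ``max_hamming`` nucleotide changes."""
    inputs = counts[counts["sample"] == "input"].pivot_table(
        index="variant_id", columns="replicate", values="count",
        fill_value=0, aggfunc="sum",
    )
    kept = inputs.index[(inputs >= threshold).all(axis=1)]
    hamming = kept.map(hamming_distance)
    return kept[hamming <= max_hamming]


# ---------------------------------------------------------------------------
# Random-effects combination (iterative maximum-likelihood estimator)
# ---------------------------------------------------------------------------

def combine_random_effects(
    values: np.ndarray, ses: np.ndarray, n_iterations: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Combine replicate measurements with a random-effects error model.

    ``values`` and ``ses`` are (n_items, n_replicates) arrays.  The
    between-replicate variance starts at the unweighted sample variance and
    is updated for exactly ``n_iterations`` multiplicative steps; replicate
    weights are the inverse of (between-variance + within-variance).

    Returns (mean, se, between_replicate_variance), each of length n_items.
    """
    s = np.atleast_2d(np.asarray(values, dtype=float))
    se2 = np.atleast_2d(np.asarray(ses, dtype=float)) ** 2
    n = s.shape[1]
    if n < 2:
        raise ValueError("random-effects combination needs at least 2 replicates")
    if np.any(se2 <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite and standard errors positive")
    var = s.var(axis=1, ddof=1)
    for _ in range(n_iterations):
        w = 1.0 / (var[:, None] + se2)
        sw = w.sum(axis=1)
        sw2 = (w**2).sum(axis=1)
        mean = (s * w).sum(axis=1) / sw
        num = ((s - mean[:, None]) ** 2 * w**2).sum(axis=1)
        var = var * num / (sw - sw2 / sw)
    w = 1.0 / (var[:, None] + se2)
    sw = w.sum(axis=1)
    mean = (s * w).sum(axis=1) / sw
    se = sw**-0.5
    return mean, se, var


def filter_combined_error(se_o1, se_o2, threshold: float = 1.0) -> np.ndarray:
    """Keep mask: sqrt(se_o1^2 + se_o2^2) <= threshold."""
    combined = np.hypot(np.asarray(se_o1, float), np.asarray(se_o2, float))
    return combined <= threshold


# ---------------------------------------------------------------------------
# Output2 transformation
# ---------------------------------------------------------------------------

def transform_output2(s_o1, s_o2, q95_wt_syn_o1: float, q95_o2: float) -> np.ndarray:
    """Reflect Output2 scores of strongly depleted variants to positive values.

    Variants depleted from the near-neutral gate (s_o1 below the 95th
    percentile of wild-type-synonymous scores) and depleted from the
    intermediate gate (s_o2 < 0) are more detrimental than any enriched
    variant; their score becomes q95(all o2) + |s_o2| so the transformed
    score increases monotonically with severity.
    """
    s_o1 = np.asarray(s_o1, dtype=float)
    s_o2 = np.asarray(s_o2, dtype=float)
    reflect = (s_o1 < q95_wt_syn_o1) & (s_o2 < 0)
    return np.where(reflect, q95_o2 + np.abs(s_o2), s_o2)


def output2_thresholds(
    scores: pd.DataFrame, wt_syn_ids, replicate, depletion_quantile: float = 0.05
) -> tuple[float, float]:
    """Per-replicate thresholds for the Output2 reflection (type-7 quantiles).

    The detriment threshold is the depletion edge of the wild-type +
    synonymous Output1 score distribution (so only variants depleted beyond
    essentially the whole neutral cloud are reflected), and the reflection
    offset is the 95th percentile of all Output2 scores (a robust proxy for
    the largest pre-transformation enrichment).
    """
    rep = scores[scores["replicate"] == replicate]
    o1 = rep[rep["output_id"] == "o1"]
    o2 = rep[rep["output_id"] == "o2"]
    q_wt_syn = float(np.quantile(
        o1[o1["variant_id"].isin(wt_syn_ids)]["score"], depletion_quantile
    ))
    q_o2 = float(np.quantile(o2["score"], 0.95))
    return q_wt_syn, q_o2


# ---------------------------------------------------------------------------
# GFP calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """Weighted linear map from (S_o1, S_o2trans) to log2-GFP."""

    alpha: float
    beta: float
    gamma: float
    alpha_se: float
    beta_se: float
    gamma_se: float
    gamma_forced_zero: bool = False
    cov_o1_o2trans: float = 0.0


def fit_gfp_calibration(
    s_o1,
    s_o2trans,
    measured_log2_gfp,
    variances,
    gamma_policy: str = "auto",
    alpha_level: float = 0.05,
) -> CalibrationModel:
    """Weighted least squares of measured log2-GFP on the two scores.

    Weights are inverse variances.  ``gamma_policy`` is "keep", "force_zero"
    or "auto" (drop the Output2 term and refit when it is not significant at
    ``alpha_level`` — the behaviour used for the high-expression condition).
    """
    s_o1 = np.asarray(s_o1, dtype=float)
    s_o2trans = np.asarray(s_o2trans, dtype=float)
    y = np.asarray(measured_log2_gfp, dtype=float)
    w = 1.0 / np.asarray(variances, dtype=float)
    if len(y) < 3:
        raise ValueError("calibration needs at least 3 confirmation genotypes")

    def _fit(with_gamma: bool):
        cols = [np.ones_like(s_o1), s_o1] + ([s_o2trans] if with_gamma else [])
        x = np.column_stack(cols)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("calibration design matrix is rank deficient")
        return sm.WLS(y, x, weights=w).fit()

    force_zero = gamma_policy == "force_zero"
    if gamma_policy == "auto":
        full = _fit(True)
        force_zero = full.pvalues[2] > alpha_level
    if force_zero:
        res = _fit(False)
        return CalibrationModel(
            alpha=res.params[0], beta=res.params[1], gamma=0.0,
            alpha_se=res.bse[0], beta_se=res.bse[1], gamma_se=0.0,
            gamma_forced_zero=True,
        )
    res = _fit(True)
    return CalibrationModel(
        alpha=res.params[0], beta=res.params[1], gamma=res.params[2],
        alpha_se=res.bse[0], beta_se=res.bse[1], gamma_se=res.bse[2],
        gamma_forced_zero=False,
    )


def apply_calibration(
    model: CalibrationModel, s_o1, s_o2trans, se_o1, se_o2trans, cov: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Map scores to log2-GFP and propagate score + coefficient errors.

    When the Output2 coefficient was forced to zero the Output2 score and all
    gamma terms are excluded (so the unused term does not inflate errors).
    ``cov`` is the empirical covariance of (S_o1, S_o2trans) in the replicate.
    """
    s_o1 = np.asarray(s_o1, dtype=float)
    se_o1 = np.asarray(se_o1, dtype=float)
    if model.gamma_forced_zero:
        s_o2trans = np.zeros_like(s_o1)
        se_o2trans = np.zeros_like(s_o1)
        cov = 0.0
    else:
        s_o2trans = np.asarray(s_o2trans, dtype=float)
        se_o2trans = np.asarray(se_o2trans, dtype=float)
    o = model.alpha + model.beta * s_o1 + model.gamma * s_o2trans
    var = (
        model.beta**2 * se_o1**2
        + model.gamma**2 * se_o2trans**2
        + 2.0 * model.beta * model.gamma * cov
        + model.beta_se**2 * s_o1**2
        + model.gamma_se**2 * s_o2trans**2
        + model.alpha_se**2
    )
    return o, np.sqrt(np.maximum(var, 0.0))


# ---------------------------------------------------------------------------
# Batch correction
# ---------------------------------------------------------------------------

def batch_correction_coefficients(
    wt_rep: float, non_rep: float, wt_ref: float, non_ref: float
) -> tuple[float, float]:
    """Affine map sending a replicate's (wild-type, nonsense) anchors onto the
    reference replicate's anchors; returns (slope, intercept)."""
    span = non_rep - wt_rep
    if span == 0:
        raise ValueError("degenerate anchors: wild-type equals nonsense mean")
    slope = (non_ref - wt_ref) / span
    intercept = (non_rep * wt_ref - non_ref * wt_rep) / span
    return slope, intercept


def batch_correct(
    o_replicate, wt_rep: float, non_rep: float, wt_ref: float, non_ref: float
) -> np.ndarray:
    slope, intercept = batch_correction_coefficients(wt_rep, non_rep, wt_ref, non_ref)
    return slope * np.asarray(o_replicate, dtype=float) + intercept


# ---------------------------------------------------------------------------
# Amino-acid aggregation
# ---------------------------------------------------------------------------

def aggregate_amino_acid(
    records: pd.DataFrame,
    weight_mode: str = "inverse_se",
) -> pd.DataFrame:
    """Within-replicate weighted mean over synonymous nucleotide encodings.

    ``records`` has columns aa_id, replicate, o, oe.  Weights are 1/SE (the
    description "inverse of the GFP signal errors" read literally) or 1/SE^2
    with ``weight_mode="inverse_variance"``.  Errors propagate as the error
    of the weighted mean: sqrt(sum (w_i * oe_i)^2) / sum w_i.
    """
    if weight_mode == "inverse_se":
        records = records.assign(_w=1.0 / records["oe"])
    elif weight_mode == "inverse_variance":
        records = records.assign(_w=1.0 / records["oe"] ** 2)
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")

    def _agg(group: pd.DataFrame) -> pd.Series:
        w = group["_w"].to_numpy()
        o = group["o"].to_numpy()
        oe = group["oe"].to_numpy()
        mean = (w * o).sum() / w.sum()
        se = np.sqrt(((w * oe) ** 2).sum()) / w.sum()
        return pd.Series({"o": mean, "oe": se, "n_encodings": len(group)})

    out = (
        records.groupby(["aa_id", "replicate"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n_encodings"] = out["n_encodings"].astype(int)
    return out


# ---------------------------------------------------------------------------
# Rescaling to the detection window
# ---------------------------------------------------------------------------

def rescale_to_detection_limits(
    o, oe, detection_range: tuple[float, float] = DETECTION_RANGE, n_bins: int = 1000
) -> np.ndarray:
    """Gaussian-weighted mean over bins spanning the detection window.

    The window is split into ``n_bins`` even bins (bin value = center); each
    variant's rescaled mean is the weighted mean of bin centers, weighted by
    the Gaussian probability (mean o, sd oe) of the true value lying in each
    bin.  Standard errors are not changed by rescaling.
    """
    o = np.atleast_1d(np.asarray(o, dtype=float))
    oe = np.atleast_1d(np.asarray(oe, dtype=float))
    if np.any(oe <= 0):
        raise ValueError("standard errors must be positive")
    lo, hi = detection_range
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    z2 = ((o[:, None] - centers[None, :]) / oe[:, None]) ** 2
    # shift by the row minimum so far-outside values do not underflow to 0/0
    weights = np.exp(-0.5 * (z2 - z2.min(axis=1, keepdims=True)))
    return (weights * centers).sum(axis=1) / weights.sum(axis=1)


# ---------------------------------------------------------------------------
# Condition-level orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Thresholds and policies of the scoring pipeline (paper defaults)."""

    pseudocount: float = 0.5
    min_input_count: int = 100
    max_hamming: int = 2
    n_iterations: int = 50
    se_filter: float = 1.0
    detection_range: tuple[float, float] = DETECTION_RANGE
    n_bins: int = 1000
    reference_replicate: int = 2
    gamma_policy: dict = field(
        default_factory=lambda: {"low": "keep", "high": "force_zero"}
    )
    aa_weight_mode: str = "inverse_se"
    # anchor the final combined phenotypes onto the individually measured
    # confirmation scale (wild-type and nonsense-mean anchors); corrects the
    # global scale compromise a weighted linear calibration can leave behind
    anchor_to_confirmation: bool = True


def _combine_scores_by_output(scores: pd.DataFrame, n_iterations: int) -> pd.DataFrame:
    """Random-effects combination of replicate scores, per variant and output."""
    out = []
    for output_id, sub in scores.groupby("output_id"):
        wide_s = sub.pivot(index="variant_id", columns="replicate", values="score")
        wide_e = sub.pivot(index="variant_id", columns="replicate", values="se")
        mean, se, var = combine_random_effects(
            wide_s.to_numpy(), wide_e.to_numpy(), n_iterations
        )
        out.append(pd.DataFrame({
            "variant_id": wide_s.index,
            "output_id": output_id,
            "mean": mean,
            "se": se,
            "between_var": var,
        }))
    return pd.concat(out, ignore_index=True)


def score_condition(
    counts: pd.DataFrame,
    confirmation: pd.DataFrame,
    annotations: pd.DataFrame,
    condition: str,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full scoring pipeline for one condition.

    Parameters
    ----------
    counts:
        tidy count table for one condition (variant_id, sample, replicate,
        count).
    confirmation:
        individually measured genotypes: variant_id, measured_log2_gfp,
        variance.
    annotations:
        variant_id, aa_changes, class (syn|missense|nonsense).
    condition:
        "low" or "high"; selects the gamma policy.

    Returns a dict with the nucleotide- and amino-acid-level phenotype tables
    and intermediate objects (scores, calibration model, filter log).
    """
    config = config or PipelineConfig()
    ann = annotations.set_index("variant_id")

    kept = filter_min_input_counts(counts, config.min_input_count, config.max_hamming)
    log = {"n_input_filter": len(kept)}
    counts = counts[counts["variant_id"].isin(kept)]

    scores = enrichment_scores(counts, pseudocount=config.pseudocount)

    # per-replicate Output2 reflection
    wt_syn_ids = ann.index[(ann["class"] == "syn")]
    transformed = []
    for rep, sub in scores.groupby("replicate"):
        q_wt_syn, q_o2 = output2_thresholds(scores, wt_syn_ids, rep)
        o1 = sub[sub["output_id"] == "o1"].set_index("variant_id")
        o2 = sub[sub["output_id"] == "o2"].set_index("variant_id")
        o2 = o2.loc[o1.index]
        s_trans = transform_output2(
            o1["score"].to_numpy(), o2["score"].to_numpy(), q_wt_syn, q_o2
        )
        transformed.append(pd.DataFrame({
            "variant_id": o1.index,
            "replicate": rep,
            "s_o1": o1["score"].to_numpy(),
            "se_o1": o1["se"].to_numpy(),
            "s_o2trans": s_trans,
            "se_o2trans": o2["se"].to_numpy(),
        }))
    per_rep = pd.concat(transformed, ignore_index=True)

    # combined (cross-replicate) scores for filtering and calibration
    scores_trans = per_rep.melt(
        id_vars=["variant_id", "replicate"],
        value_vars=["s_o1", "s_o2trans"], var_name="output_id", value_name="score",
    )
    scores_trans["se"] = per_rep.melt(
        id_vars=["variant_id", "replicate"],
        value_vars=["se_o1", "se_o2trans"], value_name="se",
    )["se"].to_numpy()
    scores_trans["output_id"] = scores_trans["output_id"].map(
        {"s_o1": "o1", "s_o2trans": "o2trans"}
    )
    combined = _combine_scores_by_output(scores_trans, config.n_iterations)
    wide = combined.pivot(index="variant_id", columns="output_id", values=["mean", "se"])
    keep_mask = filter_combined_error(
        wide[("se", "o1")], wide[("se", "o2trans")], config.se_filter
    )
    retained = wide.index[keep_mask]
    log["n_se_filter"] = int(keep_mask.sum())

    # calibration on combined scores of the confirmation genotypes
    conf = confirmation[confirmation["variant_id"].isin(retained)]
    calib = fit_gfp_calibration(
        wide.loc[conf["variant_id"], ("mean", "o1")],
        wide.loc[conf["variant_id"], ("mean", "o2trans")],
        conf["measured_log2_gfp"],
        conf["variance"],
        gamma_policy=config.gamma_policy.get(condition, "auto"),
    )

    # per-replicate log2-GFP with error propagation, then batch correction
    per_rep = per_rep[per_rep["variant_id"].isin(retained)].copy()
    o_records = []
    for rep, sub in per_rep.groupby("replicate"):
        cov = float(np.cov(sub["s_o1"], sub["s_o2trans"])[0, 1])
        o, oe = apply_calibration(
            calib, sub["s_o1"], sub["s_o2trans"], sub["se_o1"], sub["se_o2trans"], cov
        )
        o_records.append(pd.DataFrame({
            "variant_id": sub["variant_id"].to_numpy(),
            "replicate": rep,
            "o": o,
            "oe": oe,
        }))
    o_df = pd.concat(o_records, ignore_index=True)

    nonsense_ids = ann.index[ann["class"] == "nonsense"]
    anchors = {}
    for rep, sub in o_df.groupby("replicate"):
        sub = sub.set_index("variant_id")
        non = sub.loc[sub.index.intersection(nonsense_ids)]
        w = 1.0 / non["oe"] ** 2
        anchors[rep] = (
            float(sub.loc[WT_ID, "o"]),
            float((non["o"] * w).sum() / w.sum()),
        )
    ref = config.reference_replicate
    if ref not in anchors:
        raise ValueError(f"reference replicate {ref} not present")
    corrected = []
    for rep, sub in o_df.groupby("replicate"):
        sub = sub.copy()
        if rep != ref:
            slope, intercept = batch_correction_coefficients(
                *anchors[rep], *anchors[ref]
            )
            sub["o"] = slope * sub["o"] + intercept
            sub["oe"] = np.abs(slope) * sub["oe"]
        corrected.append(sub)
    o_df = pd.concat(corrected, ignore_index=True)

    # nucleotide-level cross-replicate combination
    wide_o = o_df.pivot(index="variant_id", columns="replicate", values="o")
    wide_oe = o_df.pivot(index="variant_id", columns="replicate", values="oe")
    nt_mean, nt_se, _ = combine_random_effects(
        wide_o.to_numpy(), wide_oe.to_numpy(), config.n_iterations
    )
    nt_index = wide_o.index
    n_reps = wide_o.shape[1]

    # amino-acid-level aggregation (per replicate, then across replicates)
    aa_input = o_df.copy()
    aa_input["aa_id"] = ann.loc[aa_input["variant_id"], "aa_changes"].to_numpy()
    aa_input.loc[aa_input["aa_id"] == "", "aa_id"] = WT_ID
    aa_rep = aggregate_amino_acid(aa_input, config.aa_weight_mode)
    wide_o = aa_rep.pivot(index="aa_id", columns="replicate", values="o")
    wide_oe = aa_rep.pivot(index="aa_id", columns="replicate", values="oe")
    full = wide_o.notna().all(axis=1)
    aa_mean, aa_se, _ = combine_random_effects(
        wide_o[full].to_numpy(), wide_oe[full].to_numpy(), config.n_iterations
    )
    aa_index = wide_o.index[full]

    # anchor the combined phenotypes onto the individually measured scale
    anchor_log = {}
    if config.anchor_to_confirmation:
        nt_series = pd.Series(nt_mean, index=nt_index)
        nt_se_series = pd.Series(nt_se, index=nt_index)
        conf = confirmation.set_index("variant_id")
        # class-level anchors: all nonsense genotypes share one phenotype,
        # so the measured and pipeline sides need not be the same variants
        conf_non = conf.index.intersection(ann.index[ann["class"] == "nonsense"])
        # the wild-type anchor pools WT with synonymous genotypes (identical
        # phenotype), reducing the single-measurement noise of the anchor
        syn_ids = ann.index[ann["class"] == "syn"]
        conf_wt = conf.index.intersection(syn_ids)
        if len(conf_wt) and WT_ID in nt_series.index and len(conf_non):
            def _wmean(values, variances):
                w = 1.0 / np.asarray(variances, float)
                return float((np.asarray(values, float) * w).sum() / w.sum())

            conf_wt_mean = _wmean(
                conf.loc[conf_wt, "measured_log2_gfp"], conf.loc[conf_wt, "variance"]
            )
            conf_non_mean = _wmean(
                conf.loc[conf_non, "measured_log2_gfp"], conf.loc[conf_non, "variance"]
            )
            pipe_wt_ids = nt_series.index.intersection(syn_ids)
            pipe_non_ids = nt_series.index.intersection(
                ann.index[ann["class"] == "nonsense"]
            )
            pipe_wt_mean = _wmean(
                nt_series.loc[pipe_wt_ids], nt_se_series.loc[pipe_wt_ids] ** 2
            )
            pipe_non_mean = _wmean(
                nt_series.loc[pipe_non_ids], nt_se_series.loc[pipe_non_ids] ** 2
            )
            slope, intercept = batch_correction_coefficients(
                pipe_wt_mean, pipe_non_mean, conf_wt_mean, conf_non_mean,
            )
            nt_mean = slope * nt_mean + intercept
            nt_se = np.abs(slope) * nt_se
            aa_mean = slope * aa_mean + intercept
            aa_se = np.abs(slope) * aa_se
            anchor_log = {"slope": slope, "intercept": intercept}

    nt = pd.DataFrame({
        "variant_id": nt_index,
        "level": "nucleotide",
        "condition": condition,
        "mean_log2_gfp": rescale_to_detection_limits(
            nt_mean, nt_se, config.detection_range, config.n_bins
        ),
        "se": nt_se,
        "n_replicates": n_reps,
    })
    nt["aa_changes"] = ann.loc[nt["variant_id"], "aa_changes"].to_numpy()
    nt["class"] = ann.loc[nt["variant_id"], "class"].to_numpy()

    aa_class = (
        aa_input.drop_duplicates("aa_id").set_index("aa_id")["variant_id"]
        .map(lambda v: ann.loc[v, "class"]) if len(aa_input) else pd.Series()
    )
    aa = pd.DataFrame({
        "variant_id": aa_index,
        "level": "amino_acid",
        "condition": condition,
        "mean_log2_gfp": rescale_to_detection_limits(
            aa_mean, aa_se, config.detection_range, config.n_bins
        ),
        "se": aa_se,
        "n_replicates": n_reps,
    })
    aa["aa_changes"] = np.where(aa["variant_id"] == WT_ID, "", aa["variant_id"])
    aa["class"] = aa_class.loc[aa["variant_id"]].to_numpy()
    log["confirmation_anchor"] = anchor_log

    return {
        "nucleotide": nt.reset_index(drop=True),
        "amino_acid": aa.reset_index(drop=True),
        "calibration": calib,
        "scores": per_rep,
        "combined_scores": combined,
        "anchors": anchors,
        "log": log,
    }


def run_pipeline(
    counts: pd.DataFrame,
    confirmation: pd.DataFrame,
    annotations: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict:
    """Score both expression conditions; returns {condition: result dict} plus
    a concatenated phenotype table under "phenotypes"."""
    results = {}
    tables = []
    for condition, sub in counts.groupby("condition"):
        conf = confirmation
        if "condition" in confirmation.columns:
            conf = confirmation[confirmation["condition"] == condition]
        res = score_condition(sub, conf, annotations, condition, config)
        results[condition] = res
        tables += [res["nucleotide"], res["amino_acid"]]
    results["phenotypes"] = pd.concat(tables, ignore_index=True)
    return results
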