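"""Two-state folding thermodynamics coupled to the Ackers 8-configuration
statistical-mechanics model of P_R repression.

The hierarchical model maps a variant's folding free energy dG_F to a
reporter (GFP) level in two steps:

1. folding: the fraction natively folded ``f_N = e^(-dG_F/RT) / (1 +
   e^(-dG_F/RT))`` sets the functional repressor concentration
   ``[CI_T] = f_N * [CI_E]`` for a given total expressed concentration.
2. regulation: the three operators OR1-3 can be occupied by CI dimers in
   eight configuration states; Boltzmann weighting over those states gives
   the repression probability and hence GFP between the auto-fluorescence
   floor and the unrepressed ceiling.

All forward maps are strictly monotone; inverses are computed by bracketed
bisection in log-concentration space (the bracket [1e-40, 1e-3] M contains
every physically relevant free-dimer concentration).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq

CI2_BRACKET = (1e-40, 1e-3)  # M, free-dimer search interval
_BISECT_STEPS = 120


@dataclass
class ThermoParams:
    """All constants of the folding + regulation model.

    Configuration state CS1 is the empty operator (reference, dG = 0); CS2 is
    the single non-repressing bound state (dimer on OR3 only).  Free energies
    in kcal/mol, concentrations in M, GFP levels stored in log2 arbitrary
    units.
    """

    dg_cs: np.ndarray
    n_cs: np.ndarray
    ka: float
    or_total: float
    r: float = 1.98e-3
    t: float = 310.15
    log2_gfp_max: float = 11.76
    log2_gfp_auto: float = 4.54
    k_fold_wt: float = 114.0
    expression_ratio: float = 15.0
    ci_e_low: float = 5.5e-8
    ci_e_high: float = 8.25e-7
    log2_gfp_wt_low: float = 7.23

    def __post_init__(self):
        self.dg_cs = np.asarray(self.dg_cs, dtype=float)
        self.n_cs = np.asarray(self.n_cs, dtype=float)
        if self.dg_cs.shape != (8,) or self.n_cs.shape != (8,):
            raise ValueError("dg_cs and n_cs must each list 8 configuration states")
        if self.dg_cs[0] != 0.0:
            raise ValueError("CS1 is the reference state and must have dG = 0")
        if not np.array_equal(self.n_cs, [0, 1, 1, 1, 2, 2, 2, 3]):
            raise ValueError("N_CS must be (0,1,1,1,2,2,2,3)")
        for name in ("ka", "or_total", "r", "t"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.log2_gfp_auto >= self.log2_gfp_max:
            raise ValueError("GFP_auto must lie below GFP_max")

    # -- convenience scalars ------------------------------------------------
    @property
    def rt(self) -> float:
        return self.r * self.t

    @property
    def gfp_max(self) -> float:
        return 2.0**self.log2_gfp_max

    @property
    def gfp_auto(self) -> float:
        return 2.0**self.log2_gfp_auto

    @property
    def dgf_wt(self) -> float:
        """Wild-type folding free energy implied by K_fold."""
        return -self.rt * np.log(self.k_fold_wt)

    @property
    def f_n_wt(self) -> float:
        return self.k_fold_wt / (1.0 + self.k_fold_wt)

    def ci_e(self, condition: str) -> float:
        if condition == "low":
            return self.ci_e_low
        if condition == "high":
            return self.ci_e_high
        raise ValueError(f"condition must be 'low' or 'high', got {condition!r}")

    # -- (de)serialization --------------------------------------------------
    _YAML_KEYS = {
        "dG_CS": "dg_cs",
        "N_CS": "n_cs",
        "Ka": "ka",
        "OR_total": "or_total",
        "R": "r",
        "T": "t",
        "log2_gfp_max": "log2_gfp_max",
        "log2_gfp_auto": "log2_gfp_auto",
        "K_fold_wt": "k_fold_wt",
        "expression_ratio": "expression_ratio",
        "CI_E_low": "ci_e_low",
        "CI_E_high": "ci_e_high",
        "log2_gfp_wt_low": "log2_gfp_wt_low",
    }

    @classmethod
    def from_dict(cls, data: dict) -> "ThermoParams":
        kwargs = {attr: data[key] for key, attr in cls._YAML_KEYS.items() if key in data}
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ThermoParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ThermoParams":
        with resources.files("cidms.data").joinpath("ackers_default.yaml").open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        out = {}
        for key, attr in self._YAML_KEYS.items():
            value = getattr(self, attr)
            if isinstance(value, np.ndarray):
                value = value.tolist()
            out[key] = value
        return out

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def replace(self, **kwargs) -> "ThermoParams":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Ackers configuration statistics
# ---------------------------------------------------------------------------

def _boltzmann_terms(ci2, params: ThermoParams) -> np.ndarray:
    """Unnormalized statistical weights e^(-dG_i/RT) * [CI2]^N_i, shape (..., 8)."""
    ci2 = np.asarray(ci2, dtype=float)[..., None]
    return np.exp(-params.dg_cs / params.rt) * ci2**params.n_cs


def config_probabilities(ci2, params: ThermoParams) -> np.ndarray:
    """Probability of each of the 8 operator configuration states (..., 8)."""
    if np.any(np.asarray(ci2) < 0):
        raise ValueError("free dimer concentration must be non-negative")
    terms = _boltzmann_terms(ci2, params)
    return terms / terms.sum(axis=-1, keepdims=True)


def repression_probability(ci2, params: ThermoParams):
    """P_s: probability that P_R is repressed (any state but CS1/CS2)."""
    f = config_probabilities(ci2, params)
    return 1.0 - f[..., 0] - f[..., 1]


def mean_operator_occupancy(ci2, params: ThermoParams):
    """Mean number of operator-bound dimers, sum_i N_i * f_CSi."""
    f = config_probabilities(ci2, params)
    return (f * params.n_cs).sum(axis=-1)


def gfp_from_ci2(ci2, params: ThermoParams):
    """Reporter level (linear AU) as a function of free dimer concentration."""
    ps = repression_probability(ci2, params)
    return (params.gfp_max - params.gfp_auto) * (1.0 - ps) + params.gfp_auto


def citotal_from_ci2(ci2, params: ThermoParams):
    """Total CI concentration: free monomer + 2x free dimer + 2x bound dimers."""
    ci2 = np.asarray(ci2, dtype=float)
    monomer = np.sqrt(ci2 / params.ka)
    occupancy = mean_operator_occupancy(ci2, params)
    return monomer + 2.0 * ci2 + 2.0 * params.or_total * occupancy


# ---------------------------------------------------------------------------
# Monotone inversion
# ---------------------------------------------------------------------------

def _bisect_decreasing(func, targets, lo: float, hi: float, steps: int = _BISECT_STEPS):
    """Vectorized log-space bisection for a decreasing ``func`` of ci2."""
    targets = np.asarray(targets, dtype=float)
    log_lo = np.full(targets.shape, np.log(lo))
    log_hi = np.full(targets.shape, np.log(hi))
    for _ in range(steps):
        mid = 0.5 * (log_lo + log_hi)
        too_high = func(np.exp(mid)) > targets
        log_lo = np.where(too_high, mid, log_lo)
        log_hi = np.where(too_high, log_hi, mid)
    return np.exp(0.5 * (log_lo + log_hi))


def ci2_from_gfp(gfp, params: ThermoParams):
    """Invert the regulation model: free dimer concentration from GFP (AU).

    GFP must lie in (GFP_auto, GFP_max]; GFP == GFP_max maps to ci2 = 0.
    """
    gfp_arr = np.asarray(gfp, dtype=float)
    scalar = gfp_arr.ndim == 0
    gfp_arr = np.atleast_1d(gfp_arr)
    if np.any(gfp_arr <= params.gfp_auto) or np.any(gfp_arr > params.gfp_max):
        bad = gfp_arr[(gfp_arr <= params.gfp_auto) | (gfp_arr > params.gfp_max)]
        raise ValueError(
            f"GFP {bad} outside the model range ({params.gfp_auto:.4g}, "
            f"{params.gfp_max:.4g}] AU"
        )
    out = _bisect_decreasing(lambda c: gfp_from_ci2(c, params), gfp_arr, *CI2_BRACKET)
    out[gfp_arr == params.gfp_max] = 0.0
    return float(out[0]) if scalar else out


def ci2_from_citotal(ci_total, params: ThermoParams):
    """Invert the total-CI map by bracketed bisection (monotone increasing)."""
    cit = np.asarray(ci_total, dtype=float)
    scalar = cit.ndim == 0
    cit = np.atleast_1d(cit)
    if np.any(cit < 0):
        raise ValueError("total CI concentration must be non-negative")
    # forward map is increasing; negate to reuse the decreasing solver
    out = _bisect_decreasing(
        lambda c: -citotal_from_ci2(c, params), -cit, *CI2_BRACKET
    )
    out[cit == 0.0] = 0.0
    # below the bracket the monomer term dominates: [CI_T] ~ sqrt(ci2/Ka)
    tiny = (cit > 0) & (cit <= citotal_from_ci2(CI2_BRACKET[0], params))
    out[tiny] = params.ka * cit[tiny] ** 2
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Folding thermodynamics
# ---------------------------------------------------------------------------

def fraction_folded(dg_f, params: ThermoParams):
    """Two-state folding sigmoid f_N(dG_F)."""
    x = -np.asarray(dg_f, dtype=float) / params.rt
    # stable logistic evaluation
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))


def dgf_from_fraction(f_n, params: ThermoParams):
    """Inverse folding sigmoid; f_N must lie in (0, 1)."""
    f_n = np.asarray(f_n, dtype=float)
    if np.any(f_n <= 0) or np.any(f_n >= 1):
        raise ValueError("fraction folded must lie strictly inside (0, 1)")
    return -params.rt * np.log(f_n / (1.0 - f_n))


def additive_ddg(dg_a, dg_b, dg_wt):
    """Additivity of folding free energies: dG_AB = dG_A + dG_B - dG_wt."""
    return np.asarray(dg_a, dtype=float) + np.asarray(dg_b, dtype=float) - dg_wt


# ---------------------------------------------------------------------------
# Combined model
# ---------------------------------------------------------------------------

def gfp_from_dgf(dg_f, condition: str, params: ThermoParams):
    """Full hierarchical forward map dG_F -> GFP (linear AU) at a condition."""
    f_n = fraction_folded(dg_f, params)
    ci_total = f_n * params.ci_e(condition)
    ci2 = ci2_from_citotal(ci_total, params)
    return gfp_from_ci2(ci2, params)


def log2_gfp_from_dgf(dg_f, condition: str, params: ThermoParams):
    return np.log2(gfp_from_dgf(dg_f, condition, params))


def citotal_from_gfp(gfp, params: ThermoParams):
    """f'_Ackers: total functional CI concentration inferred from GFP (AU)."""
    return citotal_from_ci2(ci2_from_gfp(gfp, params), params)


def gfp_from_citotal(ci_total, params: ThermoParams):
    """f_Ackers: GFP (AU) from total functional CI concentration."""
    return gfp_from_ci2(ci2_from_citotal(ci_total, params), params)


def dgf_from_gfp(gfp, condition: str, params: ThermoParams):
    """Invert the full model: folding free energy from GFP (AU)."""
    f_n = citotal_from_gfp(gfp, params) / params.ci_e(condition)
    return dgf_from_fraction(f_n, params)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_gfp_auto(
    gfp_wt_low: float,
    gfp_wt_high: float,
    params: ThermoParams,
    ratio: float | None = None,
    tol: float = 1e-6,
) -> float:
    """Find GFP_auto so the inferred wild-type total-CI ratio matches ``ratio``.

    The auto-fluorescence floor is the one free parameter of the regulation
    model not measured directly; it is pinned by requiring the high/low
    expression conditions to differ by the experimentally determined
    expression ratio (default 15).  Returns GFP_auto in linear AU.
    """
    if ratio is None:
        ratio = params.expression_ratio
    if not gfp_wt_high < gfp_wt_low:
        raise ValueError("wild-type GFP at high expression must be below low")

    def log_ratio_error(gfp_auto: float) -> float:
        trial = params.replace(log2_gfp_auto=float(np.log2(gfp_auto)))
        cit_high = citotal_from_gfp(gfp_wt_high, trial)
        cit_low = citotal_from_gfp(gfp_wt_low, trial)
        return np.log(cit_high / cit_low) - np.log(ratio)

    lo = 1e-6
    hi = gfp_wt_high * (1.0 - 1e-9)
    f_lo, f_hi = log_ratio_error(lo), log_ratio_error(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            "no GFP_auto in (0, GFP_wt_high) reproduces the expression ratio "
            f"{ratio}: bracket errors ({f_lo:.3g}, {f_hi:.3g})"
        )
    return brentq(log_ratio_error, lo, hi, xtol=1e-12, rtol=1e-14, maxiter=200)


def compute_ci_e(gfp_wt: float, f_n_wt: float, params: ThermoParams) -> float:
    """Total expressed CI concentration from the wild-type GFP level.

    The functional wild-type concentration f'_Ackers(GFP_wt) is divided by
    the wild-type folded fraction to recover the total expressed amount.
    """
    return float(citotal_from_gfp(gfp_wt, params) / f_n_wt)


def calibrate_expression(params: ThermoParams, log2_gfp_wt_low: float | None = None) -> ThermoParams:
    """Set CI_E_low / CI_E_high self-consistently from the wild-type phenotype.

    CI_E_low is inferred from the observed wild-type low-expression GFP and
    the wild-type folded fraction; CI_E_high follows from the expression
    ratio.  Returns a new parameter set.
    """
    if log2_gfp_wt_low is None:
        log2_gfp_wt_low = params.log2_gfp_wt_low
    ci_e_low = compute_ci_e(2.0**log2_gfp_wt_low, params.f_n_wt, params)
    return params.replace(
        ci_e_low=ci_e_low,
        ci_e_high=ci_e_low * params.expression_ratio,
        log2_gfp_wt_low=float(log2_gfp_wt_low),
    )
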