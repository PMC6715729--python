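"""Toy expression-fitness landscapes composed with folding thermodynamics.

Three stylized expression-fitness transfer functions motivated by
systematically measured yeast expression-fitness curves:

* increasing  — saturating benefit:      w = p / (0.1 + p)
* optimal     — concave peaked:          w = 1.2 p / (0.1 + p) * 1 / (1 + 0.1 p)
* decreasing  — cost of expression:      w = 1 / (1 + 0.1 p)

Each replaces the Ackers repression curve downstream of the two-state
folding sigmoid, so a mutation's folding ddG maps to a fitness value via
the folded-protein concentration f_N(dG_F) * [expressed protein].  Epistasis
between mutation pairs (additive in ddG space) is compared at two expressed
concentrations, and non-monotonic landscapes are probed for ambiguous
inversion (one fitness value -> two folding energies -> up to four
double-mutant outcomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from . import thermo
from .thermo import ThermoParams

SHAPES = ("increasing", "optimal", "decreasing")
DG_SEARCH_INTERVAL = (-15.0, 15.0)  # kcal/mol; f_N is numerically 0/1 outside


def fitness(shape: str, protein_concentration):
    """Evaluate a named expression-fitness transfer function."""
    p = np.asarray(protein_concentration, float)
    if np.any(p < 0):
        raise ValueError("protein concentration must be non-negative")
    if shape == "increasing":
        return p / (0.1 + p)
    if shape == "optimal":
        return 1.2 * p / (0.1 + p) / (1.0 + 0.1 * p)
    if shape == "decreasing":
        return 1.0 / (1.0 + 0.1 * p)
    raise ValueError(f"unknown landscape shape {shape!r}")


def optimal_concentration(shape: str) -> float:
    """Concentration maximizing fitness (the peak of the 'optimal' shape)."""
    res = minimize_scalar(
        lambda logp: -fitness(shape, np.exp(logp)), bounds=(-8, 8), method="bounded"
    )
    return float(np.exp(res.x))


@dataclass
class LandscapeSpec:
    """An expression-fitness landscape plus wild-type stability settings.

    ``concentration_low`` / ``concentration_high`` are the two expressed
    protein amounts compared (arbitrary concentration units matching the
    transfer functions); the wild-type functional amount at each is
    f_N(wt_dgf) x concentration.  The mutation grid spans ddG in
    [-1, +5] kcal/mol with 50 evenly spaced values.
    """

    shape: str = "optimal"
    wt_dgf: float = -1.6
    concentration_low: float = 0.25
    concentration_high: float = 5.0
    n_mutations: int = 50
    ddg_range: tuple[float, float] = (-1.0, 5.0)
    params: ThermoParams = field(default_factory=ThermoParams.default)

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}")
        if min(self.concentration_low, self.concentration_high) <= 0:
            raise ValueError("concentrations must be positive")

    @property
    def mutation_grid(self) -> np.ndarray:
        return np.linspace(*self.ddg_range, self.n_mutations)

    def concentration(self, scenario: str) -> float:
        return {"low": self.concentration_low, "high": self.concentration_high}[scenario]


def landscape_fitness(dg_f, spec: LandscapeSpec, scenario: str):
    """Fitness of a genotype with folding free energy dG_F at a scenario."""
    f_n = thermo.fraction_folded(dg_f, spec.params)
    return fitness(spec.shape, f_n * spec.concentration(scenario))


def paired_concentrations(
    shape: str,
    wt_dgf: float,
    params: ThermoParams | None = None,
    target_fitness: float | None = None,
) -> tuple[float, float]:
    """Concentrations giving equal wild-type fitness astride the optimum.

    For the peaked landscape, solve w(f_N * c) = target on each side of the
    optimal concentration; the default target is 85% of the peak fitness.
    """
    if shape != "optimal":
        raise ValueError("paired concentrations are defined for the peaked shape")
    params = params or ThermoParams.default()
    f_n = float(thermo.fraction_folded(wt_dgf, params))
    p_opt = optimal_concentration(shape)
    w_max = float(fitness(shape, p_opt))
    if target_fitness is None:
        target_fitness = 0.85 * w_max
    if not 0 < target_fitness < w_max:
        raise ValueError("target fitness must lie below the peak")

    def err(p):
        return float(fitness(shape, p) - target_fitness)

    p_low = brentq(err, 1e-9, p_opt)
    p_high = brentq(err, p_opt, 1e6)
    return p_low / f_n, p_high / f_n


# ---------------------------------------------------------------------------
# Pairwise epistasis grids
# ---------------------------------------------------------------------------

def epistasis_grid(spec: LandscapeSpec) -> dict:
    """Double-mutant fitness and epistasis matrices at both concentrations.

    Observed double-mutant fitness assumes ddG additivity:
    w(dG_wt + ddG_A + ddG_B).  The expectation composes the single-mutant
    fitness effects log-additively (w_A * w_B / w_wt), mirroring the
    log-additive null of the reporter analysis; epistasis is the plain
    difference observed - expected on the fitness scale.

    Returns per scenario: singles (vector), observed, expected and epistasis
    (symmetric n x n matrices).
    """
    ddg = spec.mutation_grid
    out = {"ddg": ddg}
    for scenario in ("low", "high"):
        w_wt = float(landscape_fitness(spec.wt_dgf, spec, scenario))
        singles = np.asarray(landscape_fitness(spec.wt_dgf + ddg, spec, scenario))
        observed = np.asarray(landscape_fitness(
            spec.wt_dgf + ddg[:, None] + ddg[None, :], spec, scenario
        ))
        expected = singles[:, None] * singles[None, :] / w_wt
        out[scenario] = {
            "wt_fitness": w_wt,
            "singles": singles,
            "observed": observed,
            "expected": expected,
            "epistasis": observed - expected,
        }
    return out


def sign_switch_map(eps_low: np.ndarray, eps_high: np.ndarray, dead_band: float = 0.0) -> dict:
    """Per-cell epistasis-change classes between the two concentrations."""
    from .epistasis import classify_epistasis_change

    classes = classify_epistasis_change(
        eps_low.ravel(), eps_high.ravel(), dead_band
    ).reshape(eps_low.shape)
    labels, counts = np.unique(classes, return_counts=True)
    return {"classes": classes, "counts": dict(zip(labels.tolist(), counts.tolist()))}


# ---------------------------------------------------------------------------
# Ambiguous inversion
# ---------------------------------------------------------------------------

def invert_fitness(
    omega_target: float,
    spec: LandscapeSpec,
    scenario: str,
    n_scan: int = 2001,
    interval: tuple[float, float] = DG_SEARCH_INTERVAL,
) -> np.ndarray:
    """All folding free energies mapping to a target fitness.

    Scans ``interval`` for sign changes of w(dG) - target and refines each
    bracket with Brent's method.  Monotone landscapes yield exactly one
    root inside the achievable range; the peaked landscape one or two.
    Returns an empty array when the target is outside the landscape's range.
    """
    grid = np.linspace(*interval, n_scan)
    values = np.asarray(landscape_fitness(grid, spec, scenario)) - omega_target
    roots = []
    for i in np.nonzero(np.diff(np.sign(values)) != 0)[0]:
        root = brentq(
            lambda dg: float(landscape_fitness(dg, spec, scenario) - omega_target),
            grid[i], grid[i + 1], xtol=1e-12,
        )
        roots.append(root)
    all_roots = np.concatenate([np.asarray(roots), grid[values == 0.0]])
    if all_roots.size == 0:
        return np.array([])
    return np.unique(np.round(all_roots, 9))


def enumerate_double_outcomes(
    omega_a: float,
    omega_b: float,
    spec: LandscapeSpec,
    scenario: str,
    tol: float = 1e-9,
) -> np.ndarray:
    """Possible double-mutant fitness values for two single-mutant fitnesses.

    Each single's fitness may invert to multiple ddG values; combining every
    root pair additively and mapping forward gives up to
    |roots_A| x |roots_B| outcomes, deduplicated within ``tol``.
    """
    roots_a = invert_fitness(omega_a, spec, scenario)
    roots_b = invert_fitness(omega_b, spec, scenario)
    if roots_a.size == 0 or roots_b.size == 0:
        return np.array([])
    ddg_a = roots_a - spec.wt_dgf
    ddg_b = roots_b - spec.wt_dgf
    outcomes = np.asarray(landscape_fitness(
        spec.wt_dgf + (ddg_a[:, None] + ddg_b[None, :]), spec, scenario
    )).ravel()
    outcomes = np.sort(outcomes)
    keep = np.ones(outcomes.size, dtype=bool)
    keep[1:] = np.diff(outcomes) > tol
    return outcomes[keep]
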