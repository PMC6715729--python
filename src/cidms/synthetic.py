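"""Synthetic doped-library sort-seq experiments.

Emulates the study conditions end to end: a 177-nt doped oligo library
(0.4% per non-reference nucleotide per position), true phenotypes assigned
through the folding + regulation model from a per-(position, amino acid)
ddG table, and three-gate FACS sorting with multinomial read sampling,
replicate-specific affine batch offsets on log2-GFP and Gaussian cell noise.

Gate occupancy probabilities are computed analytically (Gaussian integrals
of the cell-noise distribution), i.e. the infinite-cell limit of the
cell-level model, and reads are multinomial over within-gate expected cell
frequencies so every sample's counts sum exactly to its requested depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import laplace, norm

from . import sequences, thermo
from .sequences import WT_ID
from .thermo import ThermoParams

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CONDITIONS = ("low", "high")


@dataclass
class DopedLibrarySpec:
    """Doped-synthesis library: each position of the reference mutates to each
    of the three non-reference nucleotides independently with ``doping_rate``."""

    reference_sequence: str = ""
    doping_rate: float = 0.004
    n_molecules: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if not self.reference_sequence:
            self.reference_sequence = sequences.load_oligo().doped
        self.reference_sequence = sequences.validate_reference(self.reference_sequence)
        if not 0.0 <= self.doping_rate <= 1.0 / 3.0:
            raise ValueError("doping_rate must lie in [0, 1/3]")
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")


def generate_doped_library(spec: DopedLibrarySpec) -> pd.DataFrame:
    """Simulate doped-oligo synthesis; returns unique variants with counts.

    Columns: variant_id, nt_changes (count), count.  Reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    ref = np.frombuffer(spec.reference_sequence.encode(), dtype="S1")
    length = len(ref)
    alt_lookup = {
        base: [b for b in sequences.NUCLEOTIDES if b != base]
        for base in sequences.NUCLEOTIDES
    }
    counter: dict[tuple, int] = {}
    chunk = 200_000
    for start in range(0, spec.n_molecules, chunk):
        n = min(chunk, spec.n_molecules - start)
        mutated = rng.random((n, length)) < 3.0 * spec.doping_rate
        which = rng.integers(0, 3, size=(n, length))
        rows, cols = np.nonzero(mutated)
        boundaries = np.searchsorted(rows, np.arange(n + 1))
        for i in range(n):
            lo, hi = boundaries[i], boundaries[i + 1]
            changes = tuple(
                (int(pos), alt_lookup[spec.reference_sequence[pos]][which[i, pos]])
                for pos in cols[lo:hi]
            )
            counter[changes] = counter.get(changes, 0) + 1
    records = [
        {
            "variant_id": sequences.format_variant_id(spec.reference_sequence, ch),
            "nt_changes": len(ch),
            "count": count,
        }
        for ch, count in counter.items()
    ]
    return (
        pd.DataFrame(records)
        .sort_values(["nt_changes", "variant_id"], kind="stable")
        .reset_index(drop=True)
    )


def annotate_library(library: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Add aa_changes and class (syn|missense|nonsense) columns."""
    aa_changes, classes = [], []
    for vid in library["variant_id"]:
        aa, cls = sequences.describe_variant(reference, sequences.parse_variant_id(vid))
        aa_changes.append(aa)
        classes.append(cls)
    return library.assign(aa_changes=aa_changes, **{"class": classes})


DDG_MIXTURE = (
    # (weight, mean, sd) in kcal/mol
    (0.46, 1.0, 1.0),  # mildly destabilizing, buffered by the folding reserve
    (0.30, 3.3, 0.8),  # intermediate: detrimental at low expression only
    (0.24, 6.5, 1.0),  # unfolding: null-like at both expression levels
)


def make_ddg_table(
    n_codons: int = 59,
    protein: str | None = None,
    seed: int = 0,
    mixture=DDG_MIXTURE,
) -> pd.DataFrame:
    """Random per-(position, amino acid) folding ddG table (kcal/mol).

    Effects are drawn from a three-component Gaussian mixture whose weights
    and locations were chosen, through the repression model, to reproduce
    the reported proportions of the four single-mutant phenotype classes
    (~42% near-neutral at both expression levels, ~26% detrimental at low
    expression only, ~5% partially detrimental at high / null at low, ~20%
    null at both) and hence the bimodal phenotype distributions.
    """
    if protein is None:
        protein = sequences.load_oligo().protein[:n_codons]
    rng = np.random.default_rng(seed)
    weights = [w for w, _, _ in mixture]
    rows = []
    for pos in range(1, n_codons + 1):
        wt_aa = protein[pos - 1]
        for aa in AMINO_ACIDS:
            if aa == wt_aa:
                continue
            comp = rng.choice(len(mixture), p=weights)
            _, mean, sd = mixture[comp]
            rows.append({
                "position": pos, "aa": aa,
                "ddg": float(rng.normal(mean, sd)),
            })
    return pd.DataFrame(rows)


def assign_true_phenotypes(
    variants: pd.DataFrame, ddg_table: pd.DataFrame, params: ThermoParams
) -> pd.DataFrame:
    """True phenotypes through the mechanistic model.

    A variant's folding free energy is the wild-type value plus the sum of
    its amino-acid changes' ddG; synonymous variants are wild-type-like and
    nonsense variants sit at the unrepressed ceiling GFP_max.  Adds columns
    ddg, log2_gfp_low, log2_gfp_high.
    """
    lookup = {(int(p), a): d for p, a, d in ddg_table.itertuples(index=False)}
    ddgs = np.zeros(len(variants))
    for i, (aa_changes, cls) in enumerate(
        zip(variants["aa_changes"], variants["class"])
    ):
        if cls != "missense":
            continue
        total = 0.0
        for change in aa_changes.split(","):
            key = (int(change[1:-1]), change[-1])
            if key not in lookup:
                raise KeyError(f"ddG table has no entry for {change!r}")
            total += lookup[key]
        ddgs[i] = total
    out = variants.copy()
    out["ddg"] = np.where(out["class"].to_numpy() == "nonsense", np.nan, ddgs)

    dgf = params.dgf_wt + ddgs
    unique_dgf, inverse = np.unique(dgf, return_inverse=True)
    for condition in CONDITIONS:
        log2_gfp = thermo.log2_gfp_from_dgf(unique_dgf, condition, params)[inverse]
        out[f"log2_gfp_{condition}"] = np.where(
            out["class"].to_numpy() == "nonsense", params.log2_gfp_max, log2_gfp
        )
    return out


@dataclass
class SortSpec:
    """Three-gate FACS sort + sequencing, per condition.

    Gates are drawn per replicate from that replicate's (batch-shifted)
    wild-type and unrepressed control populations: the near-neutral gate is
    the central ``gate_mass`` of the wild-type population, the completely
    detrimental gate the central ``gate_mass`` of the no-repressor
    population, and the intermediate (Output2) gate everything in between.
    ``batch_offsets`` are per-replicate (slope, intercept) on log2-GFP.

    ``noise_model`` selects the within-clone spread of measured log2-GFP
    around the (batch-shifted) true value: "laplace" (default; the
    exponential tails typical of log-scale cytometry distributions, under
    which gate-depletion log-ratios are linear in the true phenotype) or
    "gaussian".  ``cell_noise_sd`` is the standard deviation in log2 units
    for either family.
    """

    depth: int = 1_000_000
    n_replicates: int = 3
    cell_noise_sd: float = 0.8
    noise_model: str = "laplace"
    gate_mass: float = 0.90
    batch_offsets: tuple[tuple[float, float], ...] = (
        (1.03, -0.25),
        (1.00, 0.00),
        (0.97, 0.20),
    )
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")
        if len(self.batch_offsets) != self.n_replicates:
            raise ValueError("need one (slope, intercept) per replicate")
        if not 0 < self.gate_mass < 1:
            raise ValueError("gate_mass must lie in (0, 1)")
        if self.noise_model not in ("laplace", "gaussian"):
            raise ValueError("noise_model must be 'laplace' or 'gaussian'")

    @property
    def noise_dist(self):
        """Frozen scipy distribution of the cell noise (zero mean)."""
        if self.noise_model == "gaussian":
            return norm(scale=self.cell_noise_sd)
        return laplace(scale=self.cell_noise_sd / np.sqrt(2.0))


def gate_boundaries(
    spec: SortSpec, wt_mu: float, max_mu: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """(Output1, Output2) gate bounds on measured log2-GFP for one replicate."""
    half = spec.noise_dist.ppf(0.5 + spec.gate_mass / 2.0)
    o1 = (wt_mu - half, wt_mu + half)
    detrimental_lo = max_mu - half
    if o1[1] >= detrimental_lo:
        raise ValueError("near-neutral and detrimental gates overlap")
    return o1, (o1[1], detrimental_lo)


def gate_probabilities(
    mu, sd: float, gate: tuple[float, float], noise_model: str = "gaussian"
) -> np.ndarray:
    """P(measured log2-GFP falls in the gate) for cells with true mean mu."""
    lo, hi = gate
    mu = np.asarray(mu, dtype=float)
    if sd == 0:
        return ((mu > lo) & (mu <= hi)).astype(float)
    if noise_model == "gaussian":
        dist = norm(scale=sd)
    elif noise_model == "laplace":
        dist = laplace(scale=sd / np.sqrt(2.0))
    else:
        raise ValueError("noise_model must be 'laplace' or 'gaussian'")
    return dist.cdf(hi - mu) - dist.cdf(lo - mu)


def simulate_sort_counts(
    phenotypes: pd.DataFrame,
    sort: SortSpec,
    params: ThermoParams,
    conditions=CONDITIONS,
) -> pd.DataFrame:
    """Simulate Input/Output1/Output2 read counts for both conditions.

    ``phenotypes`` must carry variant_id, count (library molecules) and
    log2_gfp_low / log2_gfp_high.  Returns a tidy table with columns
    variant_id, condition, sample, replicate, count (only nonzero rows).
    """
    rng = np.random.default_rng(sort.seed)
    lib_freq = phenotypes["count"].to_numpy(float)
    lib_freq = lib_freq / lib_freq.sum()
    wt_row = phenotypes.index[phenotypes["variant_id"] == WT_ID]
    if len(wt_row) == 0:
        raise ValueError("phenotype table must include the wild type")
    records = []
    for condition in conditions:
        true = phenotypes[f"log2_gfp_{condition}"].to_numpy(float)
        wt_true = float(phenotypes.loc[wt_row[0], f"log2_gfp_{condition}"])
        for rep in range(1, sort.n_replicates + 1):
            slope, intercept = sort.batch_offsets[rep - 1]
            mu = intercept + slope * true
            wt_mu = intercept + slope * wt_true
            max_mu = intercept + slope * params.log2_gfp_max
            o1_gate, o2_gate = gate_boundaries(sort, wt_mu, max_mu)
            samples = {
                "input": lib_freq,
                "output1": lib_freq * gate_probabilities(
                    mu, sort.cell_noise_sd, o1_gate, sort.noise_model
                ),
                "output2": lib_freq * gate_probabilities(
                    mu, sort.cell_noise_sd, o2_gate, sort.noise_model
                ),
            }
            for sample, weights in samples.items():
                total = weights.sum()
                if total == 0:
                    counts = np.zeros(len(weights), dtype=int)
                    # empty gate: no cells, no reads
                else:
                    counts = rng.multinomial(sort.depth, weights / total)
                nz = counts > 0
                records.append(pd.DataFrame({
                    "variant_id": phenotypes["variant_id"].to_numpy()[nz],
                    "condition": condition,
                    "sample": sample,
                    "replicate": rep,
                    "count": counts[nz],
                }))
    return pd.concat(records, ignore_index=True)


@dataclass
class ExperimentSpec:
    """A complete synthetic study: library, effect table, sorting, model."""

    library: DopedLibrarySpec = field(default_factory=DopedLibrarySpec)
    sort: SortSpec = field(default_factory=SortSpec)
    ddg_seed: int = 0
    n_confirmation: int = 31
    confirmation_noise_sd: float = 0.1


def simulate_experiment(
    spec: ExperimentSpec, params: ThermoParams | None = None
) -> dict:
    """Generate a full synthetic experiment.

    Returns dict with: truth (annotated library + true phenotypes), counts
    (tidy table, both conditions), confirmation (per-condition individually
    measured genotypes), params (expression-calibrated model constants).
    """
    if params is None:
        params = thermo.calibrate_expression(ThermoParams.default())
    library = generate_doped_library(spec.library)
    library = annotate_library(library, spec.library.reference_sequence)
    ddg_table = make_ddg_table(
        n_codons=len(spec.library.reference_sequence) // 3, seed=spec.ddg_seed
    )
    truth = assign_true_phenotypes(library, ddg_table, params)
    counts = simulate_sort_counts(truth, spec.sort, params)
    confirmation = _make_confirmation_set(truth, spec, params)
    return {
        "truth": truth,
        "ddg_table": ddg_table,
        "counts": counts,
        "confirmation": confirmation,
        "params": params,
    }


def _make_confirmation_set(
    truth: pd.DataFrame, spec: ExperimentSpec, params: ThermoParams
) -> pd.DataFrame:
    """Individually measured genotypes spanning the phenotype range.

    Mirrors the study's confirmation experiment: a small set of genotypes
    (wild type, synonymous, missense, nonsense) re-measured with small
    errors, used to calibrate scores to log2-GFP.
    """
    rng = np.random.default_rng(spec.library.seed + 1)
    min_count = max(3, spec.library.n_molecules // 5000)
    candidates = truth[(truth["nt_changes"] <= 2) & (truth["count"] >= min_count)]
    # mirror the study's confirmation design: the wild type, synonymous and
    # nonsense genotypes are always included, and the remaining picks span
    # the phenotype range evenly in value (not rank)
    forced = [candidates.index[candidates["variant_id"] == sequences.WT_ID]]
    for cls, k in (("syn", 2), ("nonsense", 2)):
        pool = candidates.index[candidates["class"] == cls]
        forced.append(pool[:k])
    forced = np.concatenate([np.asarray(ix) for ix in forced])
    n_spread = max(spec.n_confirmation - len(forced), 3)
    targets = np.linspace(
        candidates["log2_gfp_low"].min(),
        candidates["log2_gfp_low"].max(),
        n_spread,
    )
    values = candidates["log2_gfp_low"].to_numpy()
    idx = {int(np.argmin(np.abs(values - target))) for target in targets}
    picks = (
        pd.concat([candidates.loc[forced], candidates.iloc[sorted(idx)]])
        .drop_duplicates("variant_id")
    )
    rows = []
    for condition in CONDITIONS:
        noise = rng.normal(0.0, spec.confirmation_noise_sd, len(picks))
        rows.append(pd.DataFrame({
            "variant_id": picks["variant_id"].to_numpy(),
            "condition": condition,
            "measured_log2_gfp": picks[f"log2_gfp_{condition}"].to_numpy() + noise,
            "variance": spec.confirmation_noise_sd**2,
        }))
    return pd.concat(rows, ignore_index=True)
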