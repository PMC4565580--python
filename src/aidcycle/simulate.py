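"""Synthetic single-cell data generation.

This module produces the three kinds of synthetic raw data consumed by the
downstream analysis stages, each with known ground truth:

* per-cell two-compartment (cytoplasm/nucleus) protein abundances under a
  linear shuttling/degradation kinetic model, with drug treatments that block
  CRM1-dependent nuclear export (LMB) and/or nuclear proteasomal degradation
  (MG132) from a given onset time;
* observed high-content-screening (HCS) feature records derived from those
  abundances through a linear cytoplasm-into-nucleus bleed-through measurement
  model plus multiplicative noise, with per-phase compartment areas and total
  DAPI (DNA content) intensities;
* immunoglobulin heavy-chain V-region (VH) mutant sequences drawn from a
  substitution spectrum and per-sequence mutation-load distribution, and
  surface-IgM staining intensities drawn from a two-component mixture.

The kinetic model per cell is the linear ODE system

    dC/dt = s - (k_imp + d_c) C + k_exp N
    dN/dt = k_imp C - (k_exp + d_n(phase)) N

where C and N are cytoplasmic and nuclear average signals, s is synthesis,
k_imp/k_exp are import/export rates, and d_c/d_n are compartment degradation
rates.  Cell-cycle phase is frozen per cell over the short (<= 4 hr)
observation window, and nuclear degradation is phase specific (faster in
S and G2/M than in G1).  The system is solved exactly with piecewise matrix
exponentials across the treatment onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm

__all__ = [
    "KineticParams",
    "TreatmentSpec",
    "TREATMENTS",
    "MeasurementModel",
    "SpectrumModel",
    "CellTruth",
    "TRUTH_COLUMNS",
    "CELL_COLUMNS",
    "simulate_shuttling_population",
    "simulate_trajectory_population",
    "apply_measurement_model",
    "simulate_mock_population",
    "simulate_vh_mutations",
    "simulate_sigm_population",
    "DEFAULT_PHASE_MIX",
    "TIME_GRID",
]

PHASES = ("G1", "S", "G2M")

#: Analysis time grid in hours (time points at which populations are sampled).
TIME_GRID = (0.0, 0.5, 1.0, 2.0, 4.0)

#: Default cell-cycle phase proportions of an asynchronously cycling
#: B-cell population.  Chosen so that the phase boundaries line up with the
#: DNA-content rank windows used by the phase-gating stage (G1 occupies the
#: bottom 37.5 %, G2/M the top 25 %).
DEFAULT_PHASE_MIX = {"G1": 0.375, "S": 0.375, "G2M": 0.25}

MAX_TIME_HR = 4.0


class ParameterError(ValueError):
    """Invalid model parameter or simulation argument."""


@dataclass(frozen=True)
class KineticParams:
    """Rates of the two-compartment shuttling model (units: /hr, except
    ``synthesis_rate`` in signal units/hr).

    The defaults are *fitted* constants, calibrated so that the simulated
    observed population time courses reproduce the qualitative behaviour of
    the system under export/proteasome blockade (cytoplasmic signal halving
    under export block by 4 hr; nuclear accumulation to ~1.7-fold plateau
    when both export and nuclear proteolysis are blocked; near-flat response
    to proteasome blockade alone).  They are not measured quantities.
    Nuclear degradation is faster in S and G2/M than in G1 (ratios 1.56 and
    1.54).
    """

    synthesis_rate: float = 68.7
    import_rate: float = 0.48
    export_rate: float = 8.0
    cyto_degradation: float = 0.32
    nuc_degradation_G1: float = 0.41
    nuc_degradation_S: float = 0.41 * 1.56
    nuc_degradation_G2M: float = 0.41 * 1.54

    def __post_init__(self) -> None:
        for name in (
            "synthesis_rate",
            "import_rate",
            "export_rate",
            "cyto_degradation",
            "nuc_degradation_G1",
            "nuc_degradation_S",
            "nuc_degradation_G2M",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ParameterError(f"{name} must be a finite non-negative rate, got {value!r}")

    def nuc_degradation(self, phase: str) -> float:
        try:
            return {
                "G1": self.nuc_degradation_G1,
                "S": self.nuc_degradation_S,
                "G2M": self.nuc_degradation_G2M,
            }[phase]
        except KeyError:
            raise ParameterError(f"unknown phase {phase!r}") from None


@dataclass(frozen=True)
class TreatmentSpec:
    """A drug treatment and which kinetic sinks it blocks from ``onset_hr``."""

    name: str
    export_blocked: bool = False
    nuc_proteolysis_blocked: bool = False
    onset_hr: float = 0.0

    def __post_init__(self) -> None:
        if self.onset_hr < 0:
            raise ParameterError("onset_hr must be >= 0")


#: The four treatment arms of the HCS time-course design.
TREATMENTS = {
    "untreated": TreatmentSpec("untreated"),
    "MG132": TreatmentSpec("MG132", nuc_proteolysis_blocked=True),
    "LMB": TreatmentSpec("LMB", export_blocked=True),
    "LMB+MG132": TreatmentSpec("LMB+MG132", export_blocked=True, nuc_proteolysis_blocked=True),
}


@dataclass(frozen=True)
class CellTruth:
    """Latent per-cell state behind one observed HCS record."""

    cell_id: str
    phase: str
    true_nuclear: float
    true_cytoplasmic: float
    time_hr: float
    treatment: str


TRUTH_COLUMNS = ["cell_id", "phase", "treatment", "time_hr", "true_nuclear", "true_cytoplasmic"]

CELL_COLUMNS = [
    "cell_id",
    "construct",
    "treatment",
    "time_hr",
    "phase_true",
    "nuclear_area",
    "cyto_area",
    "cell_area",
    "nuclear_total",
    "cyto_total",
    "dapi_total",
]


def _default_area_model() -> dict:
    # per-phase (mean, cv) of nuclear and cytoplasmic areas in pixels;
    # whole-cell area is their sum so the compartment identity holds exactly
    return {
        "G1": {"nuclear": (150.0, 0.10), "cyto": (370.0, 0.10)},
        "S": {"nuclear": (170.0, 0.10), "cyto": (390.0, 0.10)},
        "G2M": {"nuclear": (190.0, 0.10), "cyto": (410.0, 0.10)},
    }


def _default_dapi_model() -> dict:
    # total DAPI intensity per phase; G2/M ~ 2x G1, S intermediate
    return {"G1": (100.0, 0.06), "S": (148.0, 0.06), "G2M": (196.0, 0.06)}


@dataclass(frozen=True)
class MeasurementModel:
    """Maps true compartment abundances to observed HCS signals.

    Observed cytoplasmic average = true cytoplasmic * multiplicative noise;
    observed nuclear average = (true nuclear + bleed_slope * observed
    cytoplasmic + bleed_intercept) * multiplicative noise.  The bleed term
    models out-of-focus cytoplasmic signal above/below the nucleus being
    attributed to the nuclear compartment by the imager; it scales with the
    *observed* cytoplasmic signal because both compartment masks record the
    same exposure of the same fluorophore.
    """

    bleed_slope: float = 0.848
    bleed_intercept: float = 21.1
    noise_cv: float = 0.05
    area_model: dict = field(default_factory=_default_area_model)
    dapi_model: dict = field(default_factory=_default_dapi_model)
    #: intensity scale of mock-transduced (fluorophore-free) cells
    mock_background: tuple = (6.0, 0.5)

    def __post_init__(self) -> None:
        if not 0.0 <= self.bleed_slope <= 1.0:
            raise ParameterError("bleed_slope must be in [0, 1]")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")
        dapi_means = [self.dapi_model[p][0] for p in PHASES]
        if not dapi_means[0] < dapi_means[1] < dapi_means[2]:
            raise ParameterError("DAPI means must satisfy G1 < S < G2/M")


def _lognormal_multipliers(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one lognormal multipliers with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _validate_times(times) -> np.ndarray:
    t = np.asarray(list(times), dtype=float)
    if t.size == 0:
        raise ParameterError("times must be non-empty")
    if np.any(np.diff(t) < 0):
        raise ParameterError("times must be sorted ascending")
    if t[0] < 0 or t[-1] > MAX_TIME_HR:
        raise ParameterError(f"times must lie within [0, {MAX_TIME_HR}] hr")
    return t


def _validate_phase_mix(phase_mix: dict) -> dict:
    mix = {p: float(phase_mix.get(p, 0.0)) for p in PHASES}
    total = sum(mix.values())
    if any(v < 0 for v in mix.values()) or not math.isclose(total, 1.0, abs_tol=1e-8):
        raise ParameterError("phase_mix must be non-negative and sum to 1 over G1/S/G2M")
    return mix


def _system_matrix(params: KineticParams, phase: str, export_blocked: bool, proteolysis_blocked: bool) -> np.ndarray:
    k_exp = 0.0 if export_blocked else params.export_rate
    d_n = 0.0 if proteolysis_blocked else params.nuc_degradation(phase)
    a, c = params.import_rate, params.cyto_degradation
    return np.array([[-(a + c), k_exp], [a, -(k_exp + d_n)]])


def _propagators(A: np.ndarray, times: np.ndarray):
    """Exact propagators x(t) = M(t) x0 + v(t) * s for dx/dt = A x + [s, 0].

    Computed with a single augmented matrix exponential per time point, which
    is exact for the linear system regardless of whether A is singular.
    """
    Ms, vs = [], []
    aug = np.zeros((3, 3))
    aug[:2, :2] = A
    aug[0, 2] = 1.0
    for t in times:
        E = expm(aug * t)
        Ms.append(E[:2, :2])
        vs.append(E[:2, 2])
    return np.array(Ms), np.array(vs)


def steady_state(params: KineticParams, phase: str) -> tuple[float, float]:
    """Pre-treatment steady state (C*, N*) of the untreated system.

    Closed form: N*/C* = k_imp / (k_exp + d_n); requires at least one
    degradation sink so that a steady state exists.
    """
    A = _system_matrix(params, phase, export_blocked=False, proteolysis_blocked=False)
    if abs(np.linalg.det(A)) < 1e-12:
        raise ParameterError("steady state undefined: system has no degradation sink")
    x = np.linalg.solve(A, [-params.synthesis_rate, 0.0])
    return float(x[0]), float(x[1])


def simulate_shuttling_population(
    params: KineticParams,
    treatment: TreatmentSpec,
    phase_mix: dict | None = None,
    n_cells: int = 1000,
    times=TIME_GRID,
    seed: int = 0,
    heterogeneity_cv: float = 0.35,
    initial_state: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Simulate per-cell nuclear/cytoplasmic trajectories under a treatment.

    Each cell keeps a fixed cell-cycle phase over the window.  Per-cell
    heterogeneity enters as mean-one lognormal multipliers on the synthesis
    rate and on the initial abundance.  Cells start from the pre-treatment
    steady state (or from ``initial_state`` when given, e.g. for degenerate
    parameter sets without a steady state); the treatment's blocked sinks are
    zeroed from ``treatment.onset_hr`` onward.

    Returns a long-format DataFrame with columns ``TRUTH_COLUMNS``
    (one row per cell per time point).  Deterministic given ``seed``.
    """
    if n_cells <= 0:
        raise ParameterError("n_cells must be positive")
    t = _validate_times(times)
    mix = _validate_phase_mix(phase_mix or DEFAULT_PHASE_MIX)
    rng = np.random.default_rng(seed)

    phases = rng.choice(PHASES, size=n_cells, p=[mix[p] for p in PHASES])
    m_syn = _lognormal_multipliers(rng, heterogeneity_cv, n_cells)
    m_init = _lognormal_multipliers(rng, heterogeneity_cv, n_cells)

    onset = min(max(treatment.onset_hr, 0.0), MAX_TIME_HR)
    frames = []
    for phase in PHASES:
        idx = np.flatnonzero(phases == phase)
        if idx.size == 0:
            continue
        A_pre = _system_matrix(params, phase, False, False)
        A_post = _system_matrix(
            params, phase, treatment.export_blocked, treatment.nuc_proteolysis_blocked
        )
        if initial_state is not None:
            x_star = np.asarray(initial_state, dtype=float)
        else:
            x_star = np.array(steady_state(params, phase))
        if np.any(x_star < 0):
            raise ParameterError("initial abundances must be non-negative")

        # piecewise-exact propagation across the onset
        pre_times = t[t <= onset]
        post_times = t[t > onset]
        M_pre, v_pre = _propagators(A_pre, pre_times)
        M_on, v_on = _propagators(A_pre, np.array([onset]))
        M_post, v_post = _propagators(A_post, post_times - onset)

        # x0 per cell = m_init * m_syn * x_star (steady state scales with s)
        scale0 = (m_init[idx] * m_syn[idx]) if initial_state is None else m_init[idx]
        x0 = np.einsum("c,j->cj", scale0, x_star)  # (cells, 2)
        s_cell = params.synthesis_rate * m_syn[idx]

        states = np.empty((idx.size, t.size, 2))
        k = 0
        for Mi, vi in zip(M_pre, v_pre):
            states[:, k, :] = x0 @ Mi.T + np.outer(s_cell, vi)
            k += 1
        if post_times.size:
            x_onset = x0 @ M_on[0].T + np.outer(s_cell, v_on[0])
            for Mi, vi in zip(M_post, v_post):
                states[:, k, :] = x_onset @ Mi.T + np.outer(s_cell, vi)
                k += 1

        frames.append(
            pd.DataFrame(
                {
                    "cell_id": np.repeat([f"cell{j:06d}" for j in idx], t.size),
                    "phase": phase,
                    "treatment": treatment.name,
                    "time_hr": np.tile(t, idx.size),
                    "true_nuclear": states[:, :, 1].ravel(),
                    "true_cytoplasmic": states[:, :, 0].ravel(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["cell_id", "time_hr"], kind="stable", ignore_index=True)[TRUTH_COLUMNS]


def simulate_trajectory_population(
    mean_curves: pd.DataFrame,
    n_cells: int = 300,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-cell nuclear signals around specified population mean curves.

    ``mean_curves`` has columns ``phase``, ``time_hr``, ``value`` giving the
    target population mean (e.g. a fold value) per phase and time.  Per-cell
    values are mean-one lognormal perturbations of the target, so the
    population mean converges to the input curve as ``n_cells`` grows.  This
    direct-mean mode decouples downstream rate-estimator checks from the ODE
    parameterization.
    """
    if n_cells <= 0:
        raise ParameterError("n_cells must be positive")
    required = {"phase", "time_hr", "value"}
    if not required.issubset(mean_curves.columns):
        raise ParameterError(f"mean_curves must have columns {sorted(required)}")
    if (mean_curves["value"] <= 0).any():
        raise ParameterError("mean curve values must be > 0")
    rng = np.random.default_rng(seed)
    frames = []
    for phase, grp in mean_curves.groupby("phase", sort=True):
        times = grp["time_hr"].to_numpy(dtype=float)
        values = grp["value"].to_numpy(dtype=float)
        noise = _lognormal_multipliers(rng, noise_cv, (n_cells, times.size))
        signals = values[None, :] * noise
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": np.repeat([f"{phase}_cell{i:05d}" for i in range(n_cells)], times.size),
                    "phase": phase,
                    "treatment": "trajectory",
                    "time_hr": np.tile(times, n_cells),
                    "true_nuclear": signals.ravel(),
                    "true_cytoplasmic": 1.0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[TRUTH_COLUMNS]


def apply_measurement_model(
    truths: pd.DataFrame,
    mm: MeasurementModel | None = None,
    seed: int = 0,
    construct: str = "AID-mCherry",
) -> pd.DataFrame:
    """Turn latent per-cell states into schema-complete observed HCS records.

    Applies the linear bleed-through model to the nuclear average, draws
    per-phase compartment areas and total DAPI, and converts compartment
    averages to the total intensities the HCS feature table reports.
    One observed record is emitted per (cell, time) row of ``truths``.
    """
    mm = mm or MeasurementModel()
    rng = np.random.default_rng(seed)
    n = len(truths)
    phase = truths["phase"].to_numpy()

    nuc_area = np.empty(n)
    cyto_area = np.empty(n)
    dapi = np.empty(n)
    for p in PHASES:
        sel = phase == p
        if not sel.any():
            continue
        am = mm.area_model[p]
        nuc_area[sel] = am["nuclear"][0] * _lognormal_multipliers(rng, am["nuclear"][1], sel.sum())
        cyto_area[sel] = am["cyto"][0] * _lognormal_multipliers(rng, am["cyto"][1], sel.sum())
        dm = mm.dapi_model[p]
        dapi[sel] = dm[0] * _lognormal_multipliers(rng, dm[1], sel.sum())

    true_n = truths["true_nuclear"].to_numpy(dtype=float)
    true_c = truths["true_cytoplasmic"].to_numpy(dtype=float)
    obs_cyto_avg = true_c * _lognormal_multipliers(rng, mm.noise_cv, n)
    # the out-of-focus light recorded in the nuclear mask scales with the
    # light recorded in the cytoplasmic mask (same exposure of the same
    # fluorophore), so the bleed term uses the observed cytoplasmic average
    obs_nuc_avg = (true_n + mm.bleed_slope * obs_cyto_avg + mm.bleed_intercept) * _lognormal_multipliers(
        rng, mm.noise_cv, n
    )

    return pd.DataFrame(
        {
            "cell_id": truths["cell_id"].to_numpy(),
            "construct": construct,
            "treatment": truths["treatment"].to_numpy(),
            "time_hr": truths["time_hr"].to_numpy(),
            "phase_true": phase,
            "nuclear_area": nuc_area,
            "cyto_area": cyto_area,
            "cell_area": nuc_area + cyto_area,
            "nuclear_total": obs_nuc_avg * nuc_area,
            "cyto_total": obs_cyto_avg * cyto_area,
            "dapi_total": dapi,
        }
    )[CELL_COLUMNS]


def simulate_mock_population(
    n_cells: int,
    mm: MeasurementModel | None = None,
    seed: int = 0,
    time_hr: float = 0.0,
) -> pd.DataFrame:
    """Observed records for mock-transduced (fluorophore-free) cells.

    Their mCherry-channel signal is pure imaging background, drawn from the
    measurement model's ``mock_background`` (mean, cv) in both compartments;
    used to set the low gate of the per-cell gating stage.
    """
    if n_cells <= 0:
        raise ParameterError("n_cells must be positive")
    mm = mm or MeasurementModel()
    rng = np.random.default_rng(seed)
    mean, cv = mm.mock_background
    phases = rng.choice(PHASES, size=n_cells, p=[DEFAULT_PHASE_MIX[p] for p in PHASES])
    truths = pd.DataFrame(
        {
            "cell_id": [f"mock{i:06d}" for i in range(n_cells)],
            "phase": phases,
            "treatment": "untreated",
            "time_hr": time_hr,
            "true_nuclear": mean * _lognormal_multipliers(rng, cv, n_cells),
            "true_cytoplasmic": mean * _lognormal_multipliers(rng, cv, n_cells),
        }
    )
    # mock cells have no fluorophore, hence no bleed-through structure: bypass
    # the bleed model by emitting their background directly
    mm_plain = replace(mm, bleed_slope=0.0, bleed_intercept=0.0)
    return apply_measurement_model(truths, mm_plain, seed=seed + 1, construct="mock")


# ---------------------------------------------------------------------------
# VH mutant sequences and sIgM staining


@dataclass(frozen=True)
class SpectrumModel:
    """Substitution spectrum and mutation-load model for VH mutant simulation.

    ``substitution_matrix`` is a 4x4 row-stochastic matrix of conditional
    probabilities P(alt | ref) over base order A, C, G, T with zero diagonal;
    ``base_mutability`` gives the relative propensity of each reference base
    to be mutated; ``load_distribution`` is a probability vector over
    {0, 1, 2, 3, 4, >=5} mutations per sequence; ``indel_rates`` are the
    per-mutated-sequence probabilities of carrying one deletion/insertion.
    """

    substitution_matrix: np.ndarray
    base_mutability: dict
    load_distribution: dict
    indel_rates: tuple = (0.04, 0.02)

    def __post_init__(self) -> None:
        m = np.asarray(self.substitution_matrix, dtype=float)
        if m.shape != (4, 4) or (m < 0).any():
            raise ParameterError("substitution_matrix must be a non-negative 4x4 matrix")
        if np.abs(np.diag(m)).max() > 1e-12:
            raise ParameterError("substitution_matrix diagonal must be zero")
        sums = m.sum(axis=1)
        for i, s in enumerate(sums):
            if s > 0 and not math.isclose(s, 1.0, abs_tol=1e-8):
                raise ParameterError(f"substitution_matrix row {i} must sum to 1 (or 0), got {s}")
        object.__setattr__(self, "substitution_matrix", m)
        loads = {int(k): float(v) for k, v in self.load_distribution.items()}
        if any(v < 0 for v in loads.values()) or not math.isclose(sum(loads.values()), 1.0, abs_tol=1e-8):
            raise ParameterError("load_distribution must be non-negative and sum to 1")
        object.__setattr__(self, "load_distribution", loads)
        if any(v < 0 for v in self.base_mutability.values()):
            raise ParameterError("base_mutability weights must be >= 0")
        if any(not 0 <= r <= 1 for r in self.indel_rates):
            raise ParameterError("indel_rates must be probabilities")

    @classmethod
    def from_joint_percentages(
        cls,
        joint: dict,
        reference: str,
        load_distribution: dict,
        indel_rates: tuple = (0.04, 0.02),
    ) -> "SpectrumModel":
        """Build a model whose simulated mutations reproduce a joint spectrum.

        ``joint`` maps (ref, alt) base pairs to percentages of all point
        mutations (the 12 off-diagonal cells, summing to ~100).  Base
        mutability is set proportional to the ref-base marginal divided by
        that base's count in ``reference``, so the empirical marginals of a
        large simulation match the target regardless of base composition.
        """
        bases = "ACGT"
        counts = {b: reference.count(b) for b in bases}
        matrix = np.zeros((4, 4))
        marginals = {b: 0.0 for b in bases}
        for (ref, alt), pct in joint.items():
            marginals[ref] += pct
        mutability = {}
        for i, ref in enumerate(bases):
            if marginals[ref] > 0:
                for j, alt in enumerate(bases):
                    if alt != ref:
                        matrix[i, j] = joint.get((ref, alt), 0.0) / marginals[ref]
            if counts[ref] == 0 and marginals[ref] > 0:
                raise ParameterError(f"reference contains no {ref} but spectrum assigns it mass")
            mutability[ref] = marginals[ref] / counts[ref] if counts[ref] else 0.0
        return cls(matrix, mutability, load_distribution, indel_rates)


def simulate_vh_mutations(
    reference: str,
    spec: SpectrumModel,
    n_cells: int,
    seed: int = 0,
) -> list:
    """Draw mutant VH sequences and their ground-truth mutation sets.

    Per sequence: draw the mutation load, pick distinct positions weighted by
    the mutability of their reference base, draw the substituted base from the
    spectrum row, and optionally add one short deletion and/or insertion.
    Positions are 1-based on the reference (numbering from the first base of
    the first codon).  Returns a list of ``(cell_id, sequence,
    frozenset_of_mutations)`` tuples where each mutation is a
    :class:`~aidcycle.shm.Mutation`.
    """
    from .shm import Mutation  # local import to avoid a cycle

    reference = reference.upper()
    if not reference or set(reference) - set("ACGT"):
        raise ParameterError("reference must be non-empty uppercase ACGT")
    if n_cells <= 0:
        raise ParameterError("n_cells must be positive")
    rng = np.random.default_rng(seed)

    ref_arr = np.frombuffer(reference.encode(), dtype="S1").astype("U1")
    weights = np.array([spec.base_mutability.get(b, 0.0) for b in ref_arr])
    if weights.sum() == 0 and any(v > 0 for v in spec.load_distribution.values() if v):
        weights = None  # only relevant when loads can be drawn > 0
    loads_support = np.array(sorted(spec.load_distribution))
    loads_p = np.array([spec.load_distribution[k] for k in loads_support])

    bases = np.array(list("ACGT"))
    base_index = {b: i for i, b in enumerate(bases)}
    del_rate, ins_rate = spec.indel_rates

    out = []
    for i in range(n_cells):
        load = int(rng.choice(loads_support, p=loads_p))
        if load >= 5:
            # the top bin is ">=5"; draw the actual count geometrically above 5
            load = 5 + int(rng.geometric(0.6) - 1)
        if load > len(reference):
            raise ParameterError("mutation load exceeds reference length")
        muts = set()
        seq = list(reference)
        if load > 0:
            if weights is None or weights.sum() == 0:
                raise ParameterError("base_mutability assigns zero weight to every reference base")
            p = weights / weights.sum()
            positions = rng.choice(len(reference), size=load, replace=False, p=p)
            for pos in sorted(int(x) for x in positions):
                ref_base = reference[pos]
                row = spec.substitution_matrix[base_index[ref_base]]
                alt = str(rng.choice(bases, p=row))
                seq[pos] = alt
                muts.add(Mutation("substitution", pos + 1, ref_base, alt))
            # indels only arise in mutated sequences (they accompany SHM)
            if rng.random() < del_rate:
                dlen = int(rng.integers(1, 4))
                start = int(rng.integers(0, len(reference) - dlen))
                if not any(m.position - 1 in range(start, start + dlen) for m in muts):
                    muts.add(Mutation("deletion", start + 1, reference[start : start + dlen], ""))
                    for k in range(start, start + dlen):
                        seq[k] = ""
            if rng.random() < ins_rate:
                ilen = int(rng.integers(1, 4))
                pos = int(rng.integers(1, len(reference)))
                ins = "".join(rng.choice(bases, size=ilen))
                muts.add(Mutation("insertion", pos, "", ins))
                seq[pos - 1] = seq[pos - 1] + ins
        out.append((f"cell{i:05d}", "".join(seq), frozenset(muts)))
    return out


def simulate_sigm_population(
    true_loss_fraction: float,
    n_cells: int,
    stain_model: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Surface-IgM staining intensities from a two-component mixture.

    A fraction ``true_loss_fraction`` of cells is sIgM-negative (low-intensity
    component); the rest are positive.  Both components are lognormal with
    (mean, cv) given by ``stain_model``'s ``negative`` and ``positive``
    entries.  Returns a DataFrame with ``cell_id``, ``intensity`` and the
    ground-truth ``is_negative`` label.
    """
    if not 0.0 <= true_loss_fraction <= 1.0:
        raise ParameterError("true_loss_fraction must be in [0, 1]")
    if n_cells <= 0:
        raise ParameterError("n_cells must be positive")
    stain_model = stain_model or {"negative": (30.0, 0.4), "positive": (1000.0, 0.4)}
    rng = np.random.default_rng(seed)
    negative = rng.random(n_cells) < true_loss_fraction
    intensity = np.empty(n_cells)
    for label, sel in (("negative", negative), ("positive", ~negative)):
        mean, cv = stain_model[label]
        intensity[sel] = mean * _lognormal_multipliers(rng, cv, int(sel.sum()))
    return pd.DataFrame(
        {
            "cell_id": [f"cell{i:06d}" for i in range(n_cells)],
            "intensity": intensity,
            "is_negative": negative,
        }
    )
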