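"""End-to-end orchestration of the simulation and analysis stages.

The pipeline chains: synthetic HCS experiment generation, per-cell
quantification (gating, phase assignment, bleed baseline and correction,
population summaries), treatment time-course analysis (fold changes, curve
shapes, degradation-rate ratios), VH hypermutation analysis, and the
surface-IgM loss assay.  Each stage receives its own seed spawned
deterministically from the run seed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import hcs, io, kinetics, shm, simulate, spectra
from .config import RunConfig, stage_seed

logger = logging.getLogger(__name__)

__all__ = [
    "simulate_hcs_experiment",
    "quantify_cells",
    "treatment_fold_curves",
    "trajectory_mean_curves",
    "rate_ratio_experiment",
    "shm_experiment",
    "sigm_experiment",
    "run_pipeline",
    "RunManifest",
]


def simulate_hcs_experiment(
    params: simulate.KineticParams | None = None,
    mm: simulate.MeasurementModel | None = None,
    n_cells: int = 2000,
    n_mock: int = 2000,
    times=simulate.TIME_GRID,
    seed: int = 0,
    heterogeneity_cv: float = 0.35,
    construct: str = "AID-mCherry",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate observed per-cell tables for all four treatment arms plus a
    mock-transduction control.  Returns (cells, mock_cells)."""
    params = params or simulate.KineticParams()
    mm = mm or simulate.MeasurementModel()
    frames = []
    for i, treatment in enumerate(simulate.TREATMENTS.values()):
        truths = simulate.simulate_shuttling_population(
            params,
            treatment,
            n_cells=n_cells,
            times=times,
            seed=stage_seed(seed, 10 + i),
            heterogeneity_cv=heterogeneity_cv,
        )
        frames.append(
            simulate.apply_measurement_model(
                truths, mm, seed=stage_seed(seed, 20 + i), construct=construct
            )
        )
    cells = pd.concat(frames, ignore_index=True)
    # treatment is encoded in the treatment column; make ids globally unique
    cells["cell_id"] = cells["treatment"].str.replace("+", "_", regex=False) + "_" + cells["cell_id"]
    mock = simulate.simulate_mock_population(n_mock, mm, seed=stage_seed(seed, 30))
    return cells, mock


def quantify_cells(
    cells: pd.DataFrame,
    mock: pd.DataFrame,
    gate_cfg: hcs.GateConfig | None = None,
    n_bins: int = 24,
) -> tuple[pd.DataFrame, hcs.GateReport, hcs.BaselineFit]:
    """Run the per-cell quantification stage.

    Computes compartment averages, applies the two-sided gate against the
    mock control, assigns cell-cycle phase by DNA-content rank within each
    (treatment, time) group, fits the bleed baseline on untreated cells and
    appends the corrected nuclear signal.
    """
    cells = hcs.compute_compartment_averages(cells)
    mock = hcs.compute_compartment_averages(mock)
    gated, report = hcs.gate_population(cells, mock, gate_cfg)
    gated = (
        gated.groupby(["treatment", "time_hr"], group_keys=False, observed=True)
        .apply(lambda g: hcs.assign_phase(g, n_bins=n_bins), include_groups=False)
        .join(gated[["treatment", "time_hr"]])
    )
    untreated = gated[gated["treatment"] == "untreated"]
    fit = hcs.fit_bleed_baseline(untreated)
    gated = hcs.correct_nuclear_signal(gated, fit)
    return gated, report, fit


def treatment_fold_curves(
    quantified: pd.DataFrame,
    value: str = "nuclear_avg",
    per_phase: bool = False,
) -> dict:
    """Fold-change curves of each treatment relative to time-matched
    untreated cells, population-wide or per phase.

    Returns {treatment: curve} or {(treatment, phase): curve}.
    """
    by = ("construct", "treatment", "phase", "time_hr") if per_phase else (
        "construct",
        "treatment",
        "time_hr",
    )
    summaries = hcs.summarize_population(quantified, value=value, by=by)
    out = {}
    group_cols = ["treatment", "phase"] if per_phase else ["treatment"]
    untreated_key = "untreated"
    for key, grp in summaries.groupby(group_cols, observed=True):
        treatment = key[0] if per_phase else key[0]
        if treatment == untreated_key:
            continue
        if per_phase:
            ref = summaries[
                (summaries["treatment"] == untreated_key) & (summaries["phase"] == key[1])
            ]
        else:
            ref = summaries[summaries["treatment"] == untreated_key]
        out[key if per_phase else treatment] = kinetics.compute_fold_change(grp, ref)
    return out


def trajectory_mean_curves(rates_cfg: dict) -> pd.DataFrame:
    """Per-phase target fold curves encoding phase-specific degradation slopes.

    All phases share the 1 hr fold; the 2 hr fold of each phase is set so the
    1-to-2 hr slope equals the G1 slope times that phase's relative rate.
    """
    f1 = rates_cfg["fold_1hr"]
    g1 = rates_cfg["g1_slope"]
    ratios = {"G1": 1.0, "S": rates_cfg["s_over_g1"], "G2M": rates_cfg["g2m_over_g1"]}
    rows = []
    for phase, r in ratios.items():
        slope = g1 * r
        for t, v in ((0.0, 1.0), (0.5, (1.0 + f1) / 2), (1.0, f1), (2.0, f1 + slope), (4.0, max(f1 + 3 * slope, 0.05))):
            rows.append({"phase": phase, "time_hr": t, "value": v})
    return pd.DataFrame(rows)


def rate_ratio_experiment(rates_cfg: dict | None = None, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate per-phase degradation-rate ratios from replicate experiments.

    Runs ``n_replicates`` seeded trajectory-mode simulations, pushes each
    through the population-summary and slope estimators, and returns
    (per-replicate slopes, relative-rate table with Welch p-values vs G1).
    """
    from .config import _default_rates

    cfg = dict(_default_rates())
    cfg.update(rates_cfg or {})
    curves = trajectory_mean_curves(cfg)
    slope_rows = []
    for rep in range(int(cfg["n_replicates"])):
        truths = simulate.simulate_trajectory_population(
            curves,
            n_cells=int(cfg["n_cells"]),
            noise_cv=float(cfg["noise_cv"]),
            seed=stage_seed(seed, 100 + rep),
        )
        summary = (
            truths.groupby(["phase", "time_hr"], observed=True)["true_nuclear"]
            .agg(["mean", "sem", "count"])
            .reset_index()
            .rename(columns={"count": "n"})
        )
        for phase, grp in summary.groupby("phase", observed=True):
            curve = grp.rename(columns={"mean": "fold"})[["time_hr", "fold"]]
            slope_rows.append(
                {
                    "replicate": rep,
                    "phase": phase,
                    "slope": kinetics.estimate_degradation_slope(curve),
                }
            )
    slopes = pd.DataFrame(slope_rows)
    return slopes, kinetics.relative_rates_vs_G1(slopes)


def shm_experiment(
    construct: str,
    n_cells: int = 400,
    seed: int = 0,
    reference: str | None = None,
) -> dict:
    """Simulate, call and summarize VH hypermutation for one construct.

    Returns a dict with the simulated reads, called mutation sets, distinct
    spectra with multiplicities, the genealogy, the substitution spectrum and
    the load distribution.
    """
    reference = reference or spectra.VH_REFERENCE
    model = simulate.SpectrumModel.from_joint_percentages(
        spectra.SUBSTITUTION_SPECTRA[construct],
        reference,
        spectra.LOAD_DISTRIBUTIONS[construct],
        spectra.INDEL_RATES,
    )
    sim = simulate.simulate_vh_mutations(reference, model, n_cells=n_cells, seed=seed)
    reads = {cid: seq for cid, seq, _truth in sim}
    called, n_failed = shm.call_mutations(reads, reference)
    unique = shm.dedupe_spectra(called)
    return {
        "construct": construct,
        "reads": reads,
        "truth": {cid: muts for cid, _seq, muts in sim},
        "called": called,
        "n_failed": n_failed,
        "unique": unique,
        "genealogy": shm.build_genealogy(unique),
        "spectrum": shm.spectrum_matrix(called),
        "load": shm.load_distribution(called),
    }


def sigm_experiment(loss_fraction: float, n_cells: int = 100_000, seed: int = 0) -> dict:
    """Simulate an sIgM staining population and estimate the loss frequency.

    The negativity gate is placed at the geometric midpoint between the two
    stain components, mimicking gating on well-separated FACS populations.
    """
    pop = simulate.simulate_sigm_population(loss_fraction, n_cells=n_cells, seed=seed)
    stain = {"negative": 30.0, "positive": 1000.0}
    threshold = float((stain["negative"] * stain["positive"]) ** 0.5)
    estimate = shm.sigm_loss_frequency(pop["intensity"], threshold=threshold)
    return {"population": pop, "threshold": threshold, "loss_percent": estimate}


@dataclasses.dataclass
class RunManifest:
    config_digest: str
    seed: int
    counts: dict
    stages_run: list
    version: str = "0.1.0"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages and write their outputs to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    stages_run: list = []
    quantified = None

    if config.stages.get("hcs", True):
        stages_run.append("hcs")
        params = simulate.KineticParams(**config.kinetics)
        mm = simulate.MeasurementModel(**config.measurement)
        cells, mock = simulate_hcs_experiment(
            params,
            mm,
            n_cells=config.n_cells,
            n_mock=config.n_mock,
            times=config.times,
            seed=stage_seed(config.seed, 1),
            heterogeneity_cv=config.heterogeneity_cv,
        )
        io.write_cell_table(cells, out / "cells.csv")
        io.write_cell_table(mock, out / "mock.csv")
        gate_cfg = hcs.GateConfig(**config.gate)
        quantified, report, fit = quantify_cells(cells, mock, gate_cfg, n_bins=config.n_bins)
        io.write_json(report.to_dict(), out / "gate_report.json")
        io.write_json(fit.to_dict(), out / "baseline_fit.json")
        summaries = hcs.summarize_population(
            quantified, by=("construct", "treatment", "phase", "time_hr")
        )
        summaries.to_csv(out / "summaries.csv", index=False)
        counts["hcs"] = {
            "cells_simulated": len(cells),
            "mock_simulated": len(mock),
            "gated_out": report.n_low_removed + report.n_high_removed,
            "kept": report.n_kept,
            "phase_assigned": int((quantified["phase"] != "unassigned").sum()),
        }

    if config.stages.get("kinetics", True):
        stages_run.append("kinetics")
        shapes = {}
        if quantified is not None:
            value = "nuclear_avg_corrected" if config.use_corrected_for_folds else "nuclear_avg"
            nuclear = treatment_fold_curves(quantified, value=value)
            cyto = treatment_fold_curves(quantified, value="cyto_avg")
            folds = pd.concat(
                [c.assign(treatment=k, compartment="nuclear") for k, c in nuclear.items()]
                + [c.assign(treatment=k, compartment="cytoplasmic") for k, c in cyto.items()],
                ignore_index=True,
            )
            folds.to_csv(out / "fold_curves.csv", index=False)
            for k, c in nuclear.items():
                shapes[f"nuclear/{k}"] = kinetics.characterize_curve(c)
            for k, c in cyto.items():
                shapes[f"cytoplasmic/{k}"] = kinetics.characterize_curve(c)
            io.write_json(shapes, out / "curve_shapes.json")
        slopes, ratios = rate_ratio_experiment(config.rates, seed=stage_seed(config.seed, 2))
        slopes.to_csv(out / "slopes.csv", index=False)
        ratios.to_csv(out / "rate_ratios.csv", index=False)
        counts["kinetics"] = {
            "fold_curves": 0 if quantified is None else int(folds["treatment"].nunique()),
            "replicates": int(slopes["replicate"].nunique()),
        }

    if config.stages.get("shm", True):
        stages_run.append("shm")
        reference = config.shm.get("reference") or spectra.VH_REFERENCE
        ref_load = None
        shm_counts = {}
        for i, construct in enumerate(config.shm["constructs"]):
            res = shm_experiment(
                construct,
                n_cells=int(config.shm["n_cells"]),
                seed=stage_seed(config.seed, 200 + i),
                reference=reference,
            )
            tag = construct.replace("/", "_")
            io.write_fasta(res["reads"], out / f"shm_{tag}.fasta")
            io.write_mutations_tsv(res["called"], out / f"shm_{tag}_mutations.tsv")
            res["spectrum"].to_frame().to_csv(out / f"shm_{tag}_spectrum.tsv", sep="\t", index=False)
            (out / f"shm_{tag}_genealogy.nwk").write_text(res["genealogy"].to_newick() + "\n")
            load = res["load"]
            pd.DataFrame(
                {"mutations": list(load.counts), "sequences": list(load.counts.values())}
            ).to_csv(out / f"shm_{tag}_load.tsv", sep="\t", index=False)
            if construct == "AID-mCherry":
                ref_load = load
            shm_counts[construct] = {
                "sequences": len(res["reads"]),
                "failed_amplicons": res["n_failed"],
                "distinct_spectra": len(res["unique"]),
                "point_mutations": res["spectrum"].n_point,
            }
            if ref_load is not None and construct != "AID-mCherry":
                chi2, df, p = shm.chi2_vs_reference(load, ref_load)
                shm_counts[construct]["chi2_vs_AID-mCherry"] = {"chi2": chi2, "df": df, "p": p}
        io.write_json(shm_counts, out / "shm_summary.json")
        counts["shm"] = shm_counts

    if config.stages.get("sigm", True):
        stages_run.append("sigm")
        sigm_out = {}
        for i, (construct, frac) in enumerate(sorted(config.sigm["loss_fractions"].items())):
            res = sigm_experiment(
                float(frac), n_cells=int(config.sigm["n_cells"]), seed=stage_seed(config.seed, 300 + i)
            )
            sigm_out[construct] = {
                "true_loss_percent": 100.0 * float(frac),
                "estimated_loss_percent": res["loss_percent"],
            }
        io.write_json(sigm_out, out / "sigm_loss.json")
        counts["sigm"] = sigm_out

    manifest = RunManifest(
        config_digest=config.digest(), seed=config.seed, counts=counts, stages_run=stages_run
    )
    io.write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
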