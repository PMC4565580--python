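"""Unit tests for the synthetic-data generator."""

import math

import numpy as np
import pandas as pd
import pytest

from aidcycle import simulate
from aidcycle.simulate import (
    DEFAULT_PHASE_MIX,
    KineticParams,
    MeasurementModel,
    ParameterError,
    SpectrumModel,
    TREATMENTS,
    TreatmentSpec,
    simulate_shuttling_population,
    simulate_sigm_population,
    simulate_trajectory_population,
    simulate_vh_mutations,
    steady_state,
)
from aidcycle.spectra import LOAD_DISTRIBUTIONS, SUBSTITUTION_SPECTRA, VH_REFERENCE


class TestKineticParams:
    def test_defaults_valid(self):
        p = KineticParams()
        assert p.nuc_degradation("S") / p.nuc_degradation("G1") == pytest.approx(1.56)
        assert p.nuc_degradation("G2M") / p.nuc_degradation("G1") == pytest.approx(1.54)

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError, match="import_rate"):
            KineticParams(import_rate=-0.1)

    def test_unknown_phase_rejected(self):
        with pytest.raises(ParameterError, match="phase"):
            KineticParams().nuc_degradation("M")


class TestSteadyState:
    def test_closed_form(self):
        # independent hand solution of 0 = s - (a+c)C + kN, 0 = aC - (k+d)N:
        #   N/C = a/(k+d);  C = s(k+d) / ((a+c)(k+d) - k a)
        p = KineticParams(
            synthesis_rate=10.0,
            import_rate=0.5,
            export_rate=2.0,
            cyto_degradation=0.3,
            nuc_degradation_G1=0.4,
        )
        a, k, c, d, s = 0.5, 2.0, 0.3, 0.4, 10.0
        c_star, n_star = steady_state(p, "G1")
        assert c_star == pytest.approx(s * (k + d) / ((a + c) * (k + d) - k * a))
        assert n_star / c_star == pytest.approx(a / (k + d))
        # the derivatives vanish at the fixed point
        assert s - (a + c) * c_star + k * n_star == pytest.approx(0.0, abs=1e-10)
        assert a * c_star - (k + d) * n_star == pytest.approx(0.0, abs=1e-10)

    def test_no_sink_raises(self):
        p = KineticParams(
            cyto_degradation=0.0,
            nuc_degradation_G1=0.0,
            nuc_degradation_S=0.0,
            nuc_degradation_G2M=0.0,
        )
        with pytest.raises(ParameterError, match="sink"):
            steady_state(p, "G1")


class TestShuttlingPopulation:
    def test_conservation_without_sources_or_sinks(self):
        # s = 0 and no degradation: C + N is conserved exactly along every
        # trajectory (the system only moves mass between compartments)
        p = KineticParams(
            synthesis_rate=0.0,
            import_rate=0.7,
            export_rate=1.3,
            cyto_degradation=0.0,
            nuc_degradation_G1=0.0,
            nuc_degradation_S=0.0,
            nuc_degradation_G2M=0.0,
        )
        df = simulate_shuttling_population(
            p,
            TREATMENTS["untreated"],
            n_cells=30,
            seed=5,
            heterogeneity_cv=0.0,
            initial_state=(100.0, 50.0),
        )
        totals = df["true_nuclear"] + df["true_cytoplasmic"]
        assert np.allclose(totals, 150.0, rtol=1e-9)

    def test_decoupled_exponential_decay(self):
        # with no synthesis, import or export each compartment decays
        # independently: N(t) = N0 exp(-d_n t), C(t) = C0 exp(-d_c t)
        p = KineticParams(
            synthesis_rate=0.0,
            import_rate=0.0,
            export_rate=0.0,
            cyto_degradation=0.2,
            nuc_degradation_G1=0.5,
            nuc_degradation_S=0.5,
            nuc_degradation_G2M=0.5,
        )
        df = simulate_shuttling_population(
            p,
            TREATMENTS["untreated"],
            n_cells=10,
            times=(0.0, 1.0, 2.0),
            seed=5,
            heterogeneity_cv=0.0,
            initial_state=(80.0, 40.0),
        )
        for t in (0.0, 1.0, 2.0):
            at_t = df[df["time_hr"] == t]
            assert np.allclose(at_t["true_nuclear"], 40.0 * math.exp(-0.5 * t), rtol=1e-9)
            assert np.allclose(at_t["true_cytoplasmic"], 80.0 * math.exp(-0.2 * t), rtol=1e-9)

    def test_untreated_stays_at_steady_state(self):
        p = KineticParams()
        df = simulate_shuttling_population(
            p, TREATMENTS["untreated"], n_cells=50, seed=2, heterogeneity_cv=0.0
        )
        for phase in ("G1", "S", "G2M"):
            c_star, n_star = steady_state(p, phase)
            sub = df[df["phase"] == phase]
            assert np.allclose(sub["true_cytoplasmic"], c_star, rtol=1e-8)
            assert np.allclose(sub["true_nuclear"], n_star, rtol=1e-8)

    def test_blocking_both_sinks_makes_nucleus_accumulate(self):
        df = simulate_shuttling_population(
            KineticParams(), TREATMENTS["LMB+MG132"], n_cells=200, seed=3, heterogeneity_cv=0.0
        )
        means = df.groupby("time_hr")["true_nuclear"].mean()
        assert means.is_monotonic_increasing
        assert means.loc[4.0] > means.loc[0.0]

    def test_deterministic_given_seed(self):
        kw = dict(n_cells=40, seed=11, heterogeneity_cv=0.3)
        a = simulate_shuttling_population(KineticParams(), TREATMENTS["LMB"], **kw)
        b = simulate_shuttling_population(KineticParams(), TREATMENTS["LMB"], **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_arguments(self):
        with pytest.raises(ParameterError):
            simulate_shuttling_population(KineticParams(), TREATMENTS["LMB"], n_cells=0)
        with pytest.raises(ParameterError, match="times"):
            simulate_shuttling_population(KineticParams(), TREATMENTS["LMB"], times=[2.0, 1.0])
        with pytest.raises(ParameterError, match="phase_mix"):
            simulate_shuttling_population(
                KineticParams(), TREATMENTS["LMB"], phase_mix={"G1": 0.5, "S": 0.2, "G2M": 0.2}
            )

    def test_onset_validation(self):
        with pytest.raises(ParameterError):
            TreatmentSpec("x", onset_hr=-1.0)


class TestTrajectoryPopulation:
    def test_population_mean_converges_to_curve(self):
        curves = pd.DataFrame(
            {
                "phase": ["G1"] * 3,
                "time_hr": [0.0, 1.0, 2.0],
                "value": [1.0, 1.4, 1.1],
            }
        )
        df = simulate_trajectory_population(curves, n_cells=20000, noise_cv=0.05, seed=9)
        means = df.groupby("time_hr")["true_nuclear"].mean()
        assert means.loc[1.0] == pytest.approx(1.4, rel=0.005)
        assert means.loc[2.0] == pytest.approx(1.1, rel=0.005)

    def test_nonpositive_curve_rejected(self):
        bad = pd.DataFrame({"phase": ["G1"], "time_hr": [0.0], "value": [0.0]})
        with pytest.raises(ParameterError):
            simulate_trajectory_population(bad)


class TestMeasurementModel:
    def test_bleed_arithmetic_zero_noise(self, zero_noise_mm):
        # true nuclear 0, cyto 100 -> observed nuclear avg 0.848*100 + 21.1
        truths = pd.DataFrame(
            {
                "cell_id": ["a"],
                "phase": ["G1"],
                "treatment": ["untreated"],
                "time_hr": [0.0],
                "true_nuclear": [0.0],
                "true_cytoplasmic": [100.0],
            }
        )
        obs = simulate.apply_measurement_model(truths, zero_noise_mm, seed=0)
        assert obs["nuclear_total"].iloc[0] / obs["nuclear_area"].iloc[0] == pytest.approx(105.9)
        assert obs["cyto_total"].iloc[0] / obs["cyto_area"].iloc[0] == pytest.approx(100.0)

    def test_identity_without_bleed_or_noise(self):
        mm = MeasurementModel(bleed_slope=0.0, bleed_intercept=0.0, noise_cv=0.0)
        truths = pd.DataFrame(
            {
                "cell_id": ["a", "b"],
                "phase": ["G1", "S"],
                "treatment": "untreated",
                "time_hr": 0.0,
                "true_nuclear": [55.0, 70.0],
                "true_cytoplasmic": [150.0, 90.0],
            }
        )
        obs = simulate.apply_measurement_model(truths, mm, seed=0)
        assert np.allclose(obs["nuclear_total"] / obs["nuclear_area"], [55.0, 70.0])
        assert np.allclose(obs["cyto_total"] / obs["cyto_area"], [150.0, 90.0])

    def test_area_identity(self, cell_table, zero_noise_mm):
        truths = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(50)],
                "phase": "G1",
                "treatment": "untreated",
                "time_hr": 0.0,
                "true_nuclear": 10.0,
                "true_cytoplasmic": 20.0,
            }
        )
        obs = simulate.apply_measurement_model(truths, zero_noise_mm, seed=4)
        assert np.allclose(obs["cell_area"], obs["nuclear_area"] + obs["cyto_area"])

    def test_model_validation(self):
        with pytest.raises(ParameterError):
            MeasurementModel(bleed_slope=1.5)
        with pytest.raises(ParameterError):
            MeasurementModel(noise_cv=-0.1)
        with pytest.raises(ParameterError, match="DAPI"):
            MeasurementModel(dapi_model={"G1": (200.0, 0.06), "S": (148.0, 0.06), "G2M": (196.0, 0.06)})

    def test_dapi_ordering_default(self):
        mm = MeasurementModel()
        means = [mm.dapi_model[p][0] for p in ("G1", "S", "G2M")]
        assert means[0] < means[1] < means[2]
        # G2/M DNA content is about twice G1
        assert means[2] / means[0] == pytest.approx(2.0, rel=0.05)

    def test_mock_population_schema(self):
        mock = simulate.simulate_mock_population(100, seed=6)
        assert list(mock.columns) == simulate.CELL_COLUMNS
        assert (mock["construct"] == "mock").all()
        # background-only signal stays far below transduced intensities
        assert (mock["nuclear_total"] / mock["nuclear_area"]).mean() < 20.0


class TestSpectrumModel:
    def test_from_joint_percentages_rows_stochastic(self):
        model = SpectrumModel.from_joint_percentages(
            SUBSTITUTION_SPECTRA["AID-mCherry"], VH_REFERENCE, LOAD_DISTRIBUTIONS["AID-mCherry"]
        )
        sums = model.substitution_matrix.sum(axis=1)
        assert np.allclose(sums, 1.0)
        assert np.allclose(np.diag(model.substitution_matrix), 0.0)

    def test_base_mutability_scales_with_marginal_over_count(self):
        joint = {("A", "G"): 50.0, ("C", "T"): 50.0}
        ref = "AACCCC"  # 2 A's, 4 C's
        model = SpectrumModel.from_joint_percentages(joint, ref, {0: 0.5, 1: 0.5})
        # equal marginals, but A is half as frequent -> per-base weight 2x
        assert model.base_mutability["A"] / model.base_mutability["C"] == pytest.approx(2.0)

    def test_validation(self):
        bad = np.full((4, 4), 0.25)
        with pytest.raises(ParameterError, match="diagonal"):
            SpectrumModel(bad, {"A": 1.0}, {0: 1.0})
        with pytest.raises(ParameterError, match="load_distribution"):
            SpectrumModel(np.zeros((4, 4)), {"A": 1.0}, {0: 0.5, 1: 0.6})


class TestVhMutations:
    def test_truth_matches_sequence_substitutions_only(self):
        model = SpectrumModel.from_joint_percentages(
            SUBSTITUTION_SPECTRA["AID-mCherry"],
            VH_REFERENCE,
            LOAD_DISTRIBUTIONS["AID-mCherry"],
            indel_rates=(0.0, 0.0),
        )
        sim = simulate_vh_mutations(VH_REFERENCE, model, n_cells=100, seed=12)
        for _cid, seq, truth in sim:
            rebuilt = list(VH_REFERENCE)
            for m in truth:
                assert m.kind == "substitution"
                assert VH_REFERENCE[m.position - 1] == m.ref
                rebuilt[m.position - 1] = m.alt
            assert "".join(rebuilt) == seq

    def test_zero_load_gives_reference(self):
        model = SpectrumModel(np.zeros((4, 4)), {b: 0.0 for b in "ACGT"}, {0: 1.0})
        sim = simulate_vh_mutations(VH_REFERENCE, model, n_cells=5, seed=0)
        assert all(seq == VH_REFERENCE and not truth for _c, seq, truth in sim)

    def test_deterministic(self):
        model = SpectrumModel.from_joint_percentages(
            SUBSTITUTION_SPECTRA["AID-mCherry-GEM"],
            VH_REFERENCE,
            LOAD_DISTRIBUTIONS["AID-mCherry-GEM"],
        )
        a = simulate_vh_mutations(VH_REFERENCE, model, n_cells=30, seed=7)
        b = simulate_vh_mutations(VH_REFERENCE, model, n_cells=30, seed=7)
        assert a == b

    def test_bad_reference(self):
        model = SpectrumModel(np.zeros((4, 4)), {b: 0.0 for b in "ACGT"}, {0: 1.0})
        with pytest.raises(ParameterError):
            simulate_vh_mutations("ACGTN", model, n_cells=1)


class TestSigmPopulation:
    def test_negative_fraction_matches_request(self):
        pop = simulate_sigm_population(0.411, n_cells=50000, seed=8)
        assert pop["is_negative"].mean() == pytest.approx(0.411, abs=0.01)
        assert (pop["intensity"] > 0).all()

    def test_components_well_separated(self):
        pop = simulate_sigm_population(0.3, n_cells=20000, seed=8)
        neg = pop.loc[pop["is_negative"], "intensity"]
        pos = pop.loc[~pop["is_negative"], "intensity"]
        assert neg.median() < 100 < pos.median()

    def test_validation(self):
        with pytest.raises(ParameterError):
            simulate_sigm_population(1.5, n_cells=10)
        with pytest.raises(ParameterError):
            simulate_sigm_population(0.1, n_cells=0)


def test_default_phase_mix_sums_to_one():
    assert sum(DEFAULT_PHASE_MIX.values()) == pytest.approx(1.0)
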