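"""Mass-action ErbB signaling model: construction, integration,
metrics, mutants, inhibitor and resistance scenarios."""

import numpy as np
import pytest

from erbbscale import signaling as sig
from erbbscale.errors import ConfigError, IntegrationError, LookupError_, UsageError
from erbbscale.signaling import (
    ModelSpec,
    MutantProfile,
    Reaction,
    Species,
    apply_mutant,
    build_model,
    mass_action_rhs,
    output_metric,
    resistance_scenario,
    simulate,
)


def toy_bimolecular():
    return ModelSpec(
        species=[
            Species("A", 2.0, composition={"A": 1}),
            Species("B", 3.0, composition={"B": 1}),
            Species("C", 0.0, composition={"A": 1, "B": 1}),
        ],
        reactions=[Reaction("bind", {"A": 1, "B": 1}, {"C": 1}, "k")],
        parameters={"k": 0.5},
    )


def toy_reversible(kf=2.0, kr=1.0):
    return ModelSpec(
        species=[
            Species("A", 1.0, composition={"X": 1}),
            Species("B", 2.0, composition={"X": 1}),
        ],
        reactions=[
            Reaction("iso", {"A": 1}, {"B": 1}, "kf", reversible=True,
                     reverse_rate_name="kr")
        ],
        parameters={"kf": kf, "kr": kr},
    )


class TestMassActionRhs:
    def test_bimolecular_rate(self):
        rhs = mass_action_rhs(toy_bimolecular())
        dx = rhs(np.array([2.0, 3.0, 0.0]))
        # d[C]/dt = k A B = 0.5 * 2 * 3
        np.testing.assert_allclose(dx, [-3.0, -3.0, 3.0])

    def test_reversible_equilibrium(self):
        # kf A = kr B at A=1, B=2 with kf=2, kr=1.
        rhs = mass_action_rhs(toy_reversible())
        np.testing.assert_allclose(rhs(np.array([1.0, 2.0])), 0.0, atol=1e-14)

    def test_conservation_left_null_space(self):
        """Moiety vectors annihilate the stoichiometric matrix, so any
        conservation-weighted derivative sum is zero at any state."""
        model = build_model({"ligands": {"EGF": 8.0, "NRG": 25.0}, "lapatinib": 100.0})
        rhs = mass_action_rhs(model)
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, size=len(model.species))
        dx = rhs(x)
        for moiety in model.moieties():
            v = model.moiety_vector(moiety)
            assert abs(v @ dx) < 1e-9

    def test_negative_state_rejected(self):
        rhs = mass_action_rhs(toy_bimolecular())
        with pytest.raises(UsageError):
            rhs(np.array([-1.0, 3.0, 0.0]))


class TestBuildModel:
    def test_egf_only_has_no_nrg_species(self):
        model = build_model({"ligands": {"EGF": 8.0}, "receptors": {"ErbB3": 0.0}})
        names = {s.name for s in model.species}
        assert "NRG" not in names and "R3N" not in names and "D23" not in names

    def test_single_weak_kinase_parameter(self):
        """Exactly one catalytic-rate parameter carries the 1/1000
        ErbB3 scale."""
        model = build_model({"ligands": {"NRG": 25.0}})
        assert model.parameters["erbb3_cat_scale"] == pytest.approx(1e-3)
        assert model.parameters["k_p3_weak"] == pytest.approx(
            model.parameters["k_p3"] * 1e-3
        )
        weak = [r for r in model.reactions if r.rate_name == "k_p3_weak"]
        assert len(weak) == 1 and "D33" in weak[0].reactants

    def test_lapatinib_species_and_blocked_catalysis(self):
        model = build_model({"ligands": {"NRG": 25.0, "EGF": 8.0}, "lapatinib": 500.0})
        names = {s.name for s in model.species}
        assert {"Lap", "R1_lap", "R2_lap", "D23_lap"} <= names
        # Dimers whose catalytically competent kinases are all
        # inhibitor-bound carry no phosphorylation flux at all.
        phos_drivers = {
            next(iter(r.reactants))
            for r in model.reactions
            if r.name.startswith("phos_")
        }
        for dead in ("D11_lap2", "D12_lap2", "D12_lapR2", "D23_lap", "D13_lap"):
            assert dead in names
            assert dead not in phos_drivers
        # A half-inhibited homodimer still phosphorylates the blocked
        # partner's tail (dimerization and substrate role persist).
        assert "D11_lap" in phos_drivers

    def test_zero_dose_omits_inhibitor(self):
        model = build_model({"ligands": {"EGF": 8.0}})
        assert "Lap" not in {s.name for s in model.species}

    def test_unknown_mutant_rejected(self):
        with pytest.raises(ConfigError):
            build_model({"mutant": "V600E"})

    def test_conserved_totals_consistent(self):
        model = build_model({"ligands": {"EGF": 8.0, "NRG": 25.0}})
        totals = model.conserved_totals()
        assert totals["R1"] == pytest.approx(100.0)
        assert totals["AKT"] == pytest.approx(200.0)


class TestSimulate:
    def test_zero_ligand_wt_stays_at_baseline(self):
        model = build_model({"ligands": {"EGF": 0.0}, "receptors": {"ErbB3": 0.0}})
        result = simulate(model)
        assert output_metric(result, "pERK") == pytest.approx(0.0, abs=1e-9)
        assert output_metric(result, "pAKT") == pytest.approx(0.0, abs=1e-9)

    def test_saturating_lapatinib_no_erbb3_shuts_down_akt(self):
        model = build_model(
            {"ligands": {"EGF": 8.0}, "receptors": {"ErbB3": 0.0},
             "lapatinib": 5000.0}
        )
        result = simulate(model, t_end=120.0)
        final = output_metric(result, "pAKT", ("value_at", 120.0))
        peak = output_metric(result, "pAKT")
        assert final < 2.0
        assert final <= peak

    def test_erbb3_sustains_akt_under_lapatinib(self):
        model = build_model({"ligands": {"NRG": 25.0}, "lapatinib": 1000.0})
        result = simulate(model)
        assert output_metric(result, "pAKT", ("value_at", 60.0)) > 1.0

    def test_conservation_drift_below_tolerance(self):
        model = build_model({"ligands": {"EGF": 8.0, "NRG": 25.0}, "lapatinib": 100.0})
        result = simulate(model)
        assert result.diagnostics["max_conservation_drift"] < 1e-6

    def test_nonnegativity_at_tight_tolerances(self):
        model = build_model({"ligands": {"EGF": 8.0, "NRG": 25.0}})
        result = simulate(model, rtol=1e-8, atol=1e-12)
        assert result.diagnostics["min_state"] >= -1e-9

    def test_bad_horizon(self):
        with pytest.raises(UsageError):
            simulate(build_model({"ligands": {"EGF": 1.0}}), t_end=0.0)


class TestOutputMetric:
    @pytest.fixture(scope="class")
    def decay_result(self):
        model = ModelSpec(
            species=[Species("X", 10.0, composition={"X": 1}),
                     Species("Xd", 0.0, composition={"X": 1})],
            reactions=[Reaction("decay", {"X": 1}, {"Xd": 1}, "k")],
            parameters={"k": 0.1},
        )
        return simulate(model, t_end=30.0)

    def test_integral_of_constant(self):
        model = ModelSpec(
            species=[Species("X", 5.0, composition={"X": 1})],
            reactions=[],
            parameters={},
        )
        result = simulate(model, t_end=10.0)
        assert output_metric(result, "X", "integral") == pytest.approx(50.0, rel=1e-6)

    def test_peak_of_monotone_decay_is_initial(self, decay_result):
        assert output_metric(decay_result, "X", "peak") == pytest.approx(10.0, rel=1e-6)

    def test_value_at_matches_refined_grid(self, decay_result):
        coarse = output_metric(decay_result, "X", ("value_at", 7.3))
        model = decay_result.model
        fine = simulate(model, t_end=30.0, n_points=3001)
        refined = output_metric(fine, "X", ("value_at", 7.3))
        assert abs(coarse - refined) / refined < 1e-3

    def test_unknown_species(self, decay_result):
        with pytest.raises(LookupError_):
            output_metric(decay_result, "nope")


class TestMutants:
    def test_wt_profile_is_identity(self):
        model = build_model({"ligands": {"EGF": 8.0}})
        again = apply_mutant(model, sig.get_mutant_profile("WT"))
        assert again.parameters == model.parameters

    def test_double_mutant_is_exactly_100x_wt(self):
        wt = build_model({"ligands": {"EGF": 8.0}, "mutant": "WT"})
        dm = build_model({"ligands": {"EGF": 8.0}, "mutant": "L834R/T766M"})
        assert dm.parameters["k1068"] == pytest.approx(100.0 * wt.parameters["k1068"])
        assert dm.parameters["k1173"] == pytest.approx(100.0 * wt.parameters["k1173"])

    def test_deletion_mutant_signals_without_ligand(self):
        zero = {"ligands": {"EGF": 0.0}, "receptors": {"ErbB3": 0.0}}
        wt = simulate(build_model({**zero, "mutant": "WT"}))
        mut = simulate(build_model({**zero, "mutant": "del723-729insS"}))
        assert output_metric(mut, "pERK") > output_metric(wt, "pERK")
        assert output_metric(mut, "pAKT") > output_metric(wt, "pAKT")

    def test_l834r_fold_changes(self):
        comp = sig.mutant_comparison("L834R")
        assert comp["erk_fold_reduction"] == pytest.approx(5.0, rel=0.05)
        assert comp["akt_percent_decrease"] == pytest.approx(15.0, abs=1.0)

    def test_invalid_profile(self):
        with pytest.raises(UsageError):
            MutantProfile("bad", s1068=0.0)


class TestResistanceScenario:
    def test_two_fold_erbb3_restores_60_percent(self):
        res = resistance_scenario(erbb3_fold=2.0, nrg_dose=25.0)
        assert res.ratio == pytest.approx(0.60, abs=0.05)

    def test_one_fold_residual_small_but_positive(self):
        res2 = resistance_scenario(erbb3_fold=2.0, nrg_dose=25.0)
        res1 = resistance_scenario(erbb3_fold=1.0, nrg_dose=25.0)
        assert 0.0 < res1.ratio < res2.ratio - 0.15

    def test_phosphatase_reduction_amplifies(self):
        base = resistance_scenario(erbb3_fold=1.0, nrg_dose=25.0)
        reduced = resistance_scenario(
            erbb3_fold=1.0, phosphatase_scale=0.5, nrg_dose=25.0
        )
        assert reduced.ratio > base.ratio

    def test_bad_fold(self):
        with pytest.raises(UsageError):
            resistance_scenario(erbb3_fold=0.0)


class TestDoseMonotonicity:
    def test_pakt_nondecreasing_in_nrg(self):
        peaks = []
        for dose in (5.0, 25.0, 100.0):
            r = simulate(build_model({"ligands": {"NRG": dose, "EGF": 0.0}}))
            peaks.append(output_metric(r, "pAKT"))
        assert peaks[0] <= peaks[1] + 1e-6 <= peaks[2] + 2e-6

    def test_pakt_nonincreasing_in_lapatinib(self):
        peaks = []
        for dose in (0.0, 50.0, 1000.0):
            r = simulate(
                build_model({"ligands": {"NRG": 25.0, "EGF": 0.0}, "lapatinib": dose})
            )
            peaks.append(output_metric(r, "pAKT"))
        assert peaks[0] + 1e-6 >= peaks[1] >= peaks[2] - 1e-6
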