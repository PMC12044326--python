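"""Dynamic engine: closed-form oracles, mass balance, interaction terms."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import pbpkddi as p
from pbpkddi.compound_io import (
    CompoundModel,
    InductionParams,
    PopulationSpec,
    Regimen,
    StudyDesign,
    VictimArm,
    PerpetratorArm,
)
from pbpkddi.pbpk_engine import EngineOptions, induction_step, inhibition_factor
from pbpkddi.population import Individual
from pbpkddi.trial_stats import nca, run_ddi_study


def _design(dose=300.0, sampling=72.0, n=1, seed=0):
    return StudyDesign(
        name="t",
        victim=VictimArm(
            compound="soticlestat", dose_mg=dose, sampling_duration_h=sampling
        ),
        population=PopulationSpec(n=n, seed=seed),
    )


def _linear_compound(**over):
    """One-compartment-reducible compound: linear hepatic clearance only,
    no gut metabolism, no SAC, no renal pathway."""
    data = {
        "name": "linear_probe",
        "mw": 300.0,
        "logp": 1.0,
        "compound_class": "neutral",
        "bp_ratio": 1.0,
        "fu_plasma": 0.1,
        "absorption": {"ka": 0.8, "fa": 1.0, "fu_gut": 1.0, "qgut": 10.0},
        "distribution": {
            "vss": 0.5,
            "k_in": 0.0,
            "k_out": 0.0,
            "v_sac": 0.0,
            "kp_liver": 1.0,
        },
        "elimination": {"cl_iv": 5.0, "cl_renal": 0.0, "fm_map": {}},
    }
    data.update(over)
    return CompoundModel.model_validate(data)


@pytest.fixture(scope="module")
def tiny_liver_individual(system):
    """Subject whose liver volume is negligible, so the explicit liver
    collapses and the model reduces to one compartment + absorption."""
    d = system.model_dump()
    d["liver_weight"] = 1.0  # g
    d["mppgl"] = 40.0
    from pbpkddi.population import SystemParameters

    return Individual(
        id=0, sex="M", age=30, body_weight=70.0,
        system=SystemParameters.model_validate(d),
    )


class TestEngineOracles:
    def test_zero_dose_gives_identically_zero_profile(
        self, soticlestat, nominal_individual
    ):
        res = p.simulate(soticlestat, _design(dose=0.0), nominal_individual)
        assert np.all(res.victim.plasma == 0.0)

    def test_linear_case_matches_one_compartment_closed_form(
        self, tiny_liver_individual
    ):
        """With linear clearance, no gut metabolism and no SAC, the
        simulated profile must match C(t) = F*D*ka/(V*(ka-k)) *
        (exp(-k t) - exp(-ka t)) to 0.1% of Cmax."""
        c = _linear_compound()
        design = StudyDesign(
            name="lin",
            victim=VictimArm(compound="linear_probe", dose_mg=100.0,
                             sampling_duration_h=96.0),
            population=PopulationSpec(n=1),
        )
        res = p.simulate(c, design, tiny_liver_individual)
        sysd = tiny_liver_individual.system
        q = sysd.q_hepatic
        cl = 5.0  # blood == plasma clearance here (B:P = 1)
        fh = 1.0 - cl / q
        vc = 0.5 * 70.0 - sysd.liver_weight / 1000.0
        k = cl / vc
        ka = 0.8
        ke = sysd.q_villous / sysd.enterocyte_volume  # enterocyte stage
        t = res.victim.time
        # Bateman solution of the lumen -> enterocyte -> central catenary
        bateman = (
            np.exp(-ka * t) / ((ke - ka) * (k - ka))
            + np.exp(-ke * t) / ((ka - ke) * (k - ke))
            + np.exp(-k * t) / ((ka - k) * (ke - k))
        )
        closed = fh * 100.0 * ka * ke / vc * bateman * 1000.0  # mg/L -> ng/mL
        err = np.max(np.abs(res.victim.plasma - closed)) / closed.max()
        assert err < 1e-3

    def test_mass_balance_within_0p1_percent(self, soticlestat, nominal_individual):
        res = p.simulate(soticlestat, _design(), nominal_individual)
        assert res.mass_balance_error["soticlestat"] < 1e-3

    def test_halving_tolerances_leaves_auc_unchanged(
        self, soticlestat, nominal_individual
    ):
        base = p.simulate(soticlestat, _design(), nominal_individual)
        tight = p.simulate(
            soticlestat, _design(), nominal_individual,
            options=EngineOptions(rtol=5e-9, atol=5e-11),
        )
        auc0 = nca(base.victim).auc_0_inf
        auc1 = nca(tight.victim).auc_0_inf
        assert abs(auc1 - auc0) / auc0 < 1e-4

    def test_profile_invariant_to_grid_refinement(
        self, soticlestat, nominal_individual
    ):
        base = p.simulate(soticlestat, _design(), nominal_individual)
        fine = p.simulate(
            soticlestat, _design(), nominal_individual,
            options=EngineOptions(dt_dense=0.05, dt_coarse=0.25),
        )
        # the solution itself must not depend on where it is sampled
        auc_b = nca(base.victim).auc_0_inf
        auc_f = nca(fine.victim).auc_0_inf
        assert abs(auc_f - auc_b) / auc_b < 1e-3


class TestDoseSuperposition:
    def test_linear_model_doubles_exactly(self, tiny_liver_individual):
        c = _linear_compound()
        vic = lambda dose: StudyDesign(
            name="lin",
            victim=VictimArm(compound="linear_probe", dose_mg=dose),
            population=PopulationSpec(n=1),
        )
        lo = p.simulate(c, vic(50.0), tiny_liver_individual)
        hi = p.simulate(c, vic(100.0), tiny_liver_individual)
        ratio = hi.victim.plasma[1:] / lo.victim.plasma[1:]
        assert np.allclose(ratio[lo.victim.plasma[1:] > 1e-6], 2.0, rtol=1e-6)

    def test_saturable_ugt_gives_greater_than_proportional_auc(
        self, soticlestat, nominal_individual
    ):
        """Doubling the dose must more than double AUC under saturable
        (Michaelis-Menten) UGT metabolism."""
        lo = nca(p.simulate(soticlestat, _design(300.0), nominal_individual).victim)
        hi = nca(p.simulate(soticlestat, _design(600.0), nominal_individual).victim)
        assert hi.auc_0_inf / lo.auc_0_inf > 2.02


class TestInhibitionFactor:
    def test_limits_and_half_inhibition(self, soticlestat):
        inter = soticlestat.interaction
        assert inhibition_factor(inter, "CYP3A4", 0.0) == 1.0
        ki_u = inter.ki_u("CYP3A4")
        assert inhibition_factor(inter, "CYP3A4", ki_u) == pytest.approx(0.5)

    def test_ten_percent_occupancy_arithmetic(self, soticlestat):
        # Cu = 0.1 * Ki,u = 1.1656 uM -> factor 1/1.1
        f = inhibition_factor(soticlestat.interaction, "CYP3A4", 1.16560)
        assert f == pytest.approx(1.0 / 1.1, rel=1e-5)

    def test_untargeted_enzyme_is_unaffected(self, soticlestat):
        assert inhibition_factor(soticlestat.interaction, "UGT1A1", 50.0) == 1.0


class TestInductionStep:
    PARAMS = InductionParams(target="CYP3A4", ind_max=8.0, ind_c50=0.6)

    def test_baseline_steady_state(self):
        assert induction_step(1.0, 1.0, 0.02, self.PARAMS, 0.0) == 0.0

    def test_half_max_steady_state_fold(self):
        e_ss = 1.0 + self.PARAMS.ind_max / 2.0
        assert induction_step(e_ss, 1.0, 0.02, self.PARAMS, 0.6) == pytest.approx(0.0)

    def test_washout_decays_with_turnover_half_life(self):
        kdeg = 0.05
        sol = solve_ivp(
            lambda t, y: [induction_step(y[0], 1.0, kdeg, self.PARAMS, 0.0)],
            (0.0, np.log(2) / kdeg),
            [5.0],
            rtol=1e-10, atol=1e-12,
        )
        # after one turnover half-life the excess activity halves
        assert sol.y[0, -1] == pytest.approx(1.0 + 4.0 / 2.0, rel=1e-6)


class TestInteractionlessCoupling:
    def test_victim_profile_bitwise_identical_with_inert_co_drug(
        self, soticlestat, nominal_individual, library
    ):
        inert = library["midazolam"].model_copy(deep=True)
        inert.name = "inert_probe"
        assert not inert.has_interactions()
        design = _design()
        design.perpetrator = PerpetratorArm(
            compound="inert_probe", dose_mg=5.0,
            regimen=Regimen(interval_h=24.0, n_doses=3),
            lead_in_days=2.0, victim_dose_day=2.0,
        )
        alone = p.simulate(soticlestat, _design(), nominal_individual)
        combo = p.simulate(soticlestat, design, nominal_individual, inert)
        assert np.array_equal(alone.victim.plasma, combo.victim.plasma)
        assert combo.perpetrator is not None

    def test_gmr_is_exactly_one_for_interactionless_perpetrator(self, library):
        lib = dict(library)
        inert = library["midazolam"].model_copy(deep=True)
        inert.name = "inert_probe"
        lib["inert_probe"] = inert
        design = _design(n=3, seed=9)
        design.population.n = 3
        design.perpetrator = PerpetratorArm(
            compound="inert_probe", dose_mg=5.0,
            regimen=Regimen(interval_h=24.0, n_doses=3),
            lead_in_days=2.0, victim_dose_day=2.0,
        )
        res = run_ddi_study(design, lib, seed=9)
        assert res.gmr_auc.point == 1.0
        assert res.gmr_cmax.point == 1.0
        assert res.gmr_auc.ci_lower == res.gmr_auc.ci_upper == 1.0


def test_same_seed_same_study_result(library):
    design = _design(n=2, seed=4)
    design.population.n = 2
    a = run_ddi_study(design, library, seed=4)
    b = run_ddi_study(design, library, seed=4)
    assert [m.auc_0_inf for m in a.reference] == [m.auc_0_inf for m in b.reference]


def test_multiple_dose_regimen_accumulates(soticlestat, nominal_individual):
    """Repeat dosing: trough-to-trough accumulation is mild (short
    half-life) but the post-final-dose peak exceeds the single-dose peak."""
    multi = StudyDesign(
        name="mrd",
        victim=VictimArm(
            compound="soticlestat", dose_mg=300.0,
            regimen=Regimen(interval_h=24.0, n_doses=3),
            sampling_duration_h=48.0,
        ),
        population=PopulationSpec(n=1),
    )
    single = p.simulate(soticlestat, _design(), nominal_individual)
    rep = p.simulate(soticlestat, multi, nominal_individual)
    from pbpkddi.trial_stats import _victim_window

    cmax_single = nca(_victim_window(single.victim)).cmax
    cmax_multi = nca(_victim_window(rep.victim)).cmax
    assert cmax_multi >= cmax_single
    assert cmax_multi < 2.0 * cmax_single
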