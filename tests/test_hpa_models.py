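"""Structure and dynamics of the two feedback models."""

import numpy as np
import pytest

from fcshpa.hpa_models import (
    BASAL_REFERENCE_NM,
    HpaParameterSet,
    Param,
    Scenario,
    default_parameters,
    extended_rhs,
    parsimonious_rhs,
    percent_change,
    simulate,
    steady_state,
)


def params_with(model_id, **overrides):
    """Parameter set with values forced outside the default search bounds."""
    base = default_parameters(model_id)
    new = {}
    for name, p in base.params.items():
        v = overrides.get(name, p.value)
        new[name] = Param(v, min(v, p.lo) / 10, max(v, p.hi) * 10, p.ref, p.unit)
    return HpaParameterSet(model_id, new)


class TestRhsStructure:
    @pytest.mark.parametrize("model_id, rhs, nstates", [
        ("parsimonious", parsimonious_rhs, 3),
        ("extended", extended_rhs, 10),
    ])
    def test_zero_production_zero_state_is_fixed_point(self, model_id, rhs, nstates):
        tiny = 1e-300
        if model_id == "parsimonious":
            params = params_with(model_id, kr_b=tiny, b0=tiny)
        else:
            params = params_with(model_id, a0=tiny)
        sc = Scenario("basal", 0.0, 0.0, np.array([0.0]))
        d = rhs(np.zeros(nstates), 0.0, params, sc)
        assert np.allclose(d, 0.0, atol=1e-12)

    @pytest.mark.parametrize("model_id, rhs", [
        ("parsimonious", parsimonious_rhs),
        ("extended", extended_rhs),
    ])
    def test_negative_state_rejected(self, model_id, rhs):
        params = default_parameters(model_id)
        sc = Scenario("basal", 0.0, 0.0, np.array([0.0]))
        n = 3 if model_id == "parsimonious" else 10
        with pytest.raises(ValueError):
            rhs(-np.ones(n), 0.0, params, sc)


class TestSteadyState:
    @pytest.mark.parametrize("model_id", ["parsimonious", "extended"])
    def test_residual_norm(self, model_id):
        params = default_parameters(model_id)
        x = steady_state(model_id, params)
        sc = Scenario("basal", 0.0, 0.0, np.array([0.0]))
        rhs = parsimonious_rhs if model_id == "parsimonious" else extended_rhs
        d = np.asarray(rhs(x, 0.0, params, sc))[:-1]  # extracellular ACTH clamped
        assert np.linalg.norm(d) < 1e-10

    def test_independent_of_start(self):
        params = default_parameters("extended")
        ref = steady_state("extended", params)
        rng = np.random.default_rng(0)
        for _ in range(3):
            start = ref * (1 + 0.5 * rng.random(ref.shape))
            x = steady_state("extended", params, start=start)
            np.testing.assert_allclose(x, ref, rtol=1e-6, atol=1e-12)

    def test_rejects_dosed_scenario(self):
        with pytest.raises(ValueError):
            steady_state("extended", default_parameters("extended"),
                         Scenario("crh", 10.0, 0.0, np.array([0.0])))


class TestSimulate:
    def test_percent_change_zero_at_t0(self, t_obs_table2):
        traj = simulate("extended", Scenario("crh", 10.0, 0.0, t_obs_table2))
        assert traj.pct_change[0] == pytest.approx(0.0, abs=1e-9)

    def test_crh_response_rises_monotonically(self):
        t = np.linspace(0, 120, 25)
        for model_id in ("parsimonious", "extended"):
            traj = simulate(model_id, Scenario("crh", 10.0, 0.0, t))
            assert np.all(np.diff(traj.acth_nM) > 0)

    def test_tolerance_convergence(self, t_obs_table2):
        sc = Scenario("crh_cortisol", 10.0, 100.0, t_obs_table2)
        a = simulate("extended", sc, rtol=1e-8).acth_nM
        b = simulate("extended", sc, rtol=1e-10).acth_nM
        assert np.max(np.abs(a - b) / b) < 1e-4

    def test_non_negative_trajectories(self, t_obs_table2):
        for label, crh, cort in [("basal", 0, 0), ("crh", 10, 0),
                                 ("crh_cortisol", 10, 100)]:
            traj = simulate("extended", Scenario(label, crh, cort, t_obs_table2))
            assert np.all(traj.states >= -1e-12)

    def test_receptor_conservation(self, t_obs_table2):
        params = default_parameters("extended")
        traj = simulate("extended",
                        Scenario("crh_cortisol", 10.0, 100.0, t_obs_table2), params)
        names = traj.state_names
        crhr_free = params["rc_tot"] - traj.states[:, names.index("crhr_bound")]
        total = crhr_free + traj.states[:, names.index("crhr_bound")]
        np.testing.assert_allclose(total, params["rc_tot"], rtol=1e-8)
        # GR is conserved across its cytosolic/dimer/nuclear forms
        gr_total = (
            traj.states[:, names.index("gr_free")]
            + traj.states[:, names.index("gr_cortisol")]
            + 2 * traj.states[:, names.index("gr_dimer")]
            + 2 * traj.states[:, names.index("gr_dimer_nuc")]
        )
        np.testing.assert_allclose(gr_total, gr_total[0], rtol=1e-8)

    def test_gpcr_knockout_removes_fast_feedback(self):
        t = np.array([0.0, 1.0, 5.0, 10.0, 15.0])
        params = params_with("extended", rg_tot=1e-12)
        a = simulate("extended", Scenario("crh", 10.0, 0.0, t), params)
        b = simulate("extended", Scenario("crh_cortisol", 10.0, 100.0, t), params)
        # without the membrane receptor only the (slow) genomic branch
        # distinguishes the arms on a 15-min window
        assert np.max(np.abs(a.pct_change - b.pct_change)) < 0.25

    def test_dose_response_monotone_at_22h(self):
        t = np.array([0.0, 1320.0])
        acth = [
            simulate("extended", Scenario("x", 10.0, cort, t)).acth_nM[-1]
            for cort in (0.0, 50.0, 100.0)
        ]
        assert acth[0] >= acth[1] >= acth[2]


class TestPercentChange:
    def test_examples(self):
        assert percent_change(BASAL_REFERENCE_NM, BASAL_REFERENCE_NM) == 0.0
        assert percent_change(1.0748 * 15.016, 15.016) == pytest.approx(7.48, abs=1e-10)

    def test_linear(self):
        ref = 15.016
        c = np.array([14.0, 15.0, 16.0])
        np.testing.assert_allclose(
            percent_change(2 * c - ref, ref), 2 * percent_change(c, ref), rtol=1e-12
        )

    def test_positive_reference_required(self):
        with pytest.raises(ValueError):
            percent_change(15.0, 0.0)


class TestLimitReduction:
    def test_extended_reduces_to_parsimonious_without_cortisol(self):
        """With fast, far-from-saturation receptors and fast transcript
        turnover the extended secretion pathway maps onto the parsimonious
        CRH terms; the CRH-only observables must then agree closely."""
        pars = default_parameters("parsimonious")
        crh = 10.0
        # fast linear CRHR: occupancy rc_tot*kon*crh/koff equilibrates in ~1 s
        rc_tot, kon, koff = 10.0, 0.005, 50.0
        rc_b = rc_tot * kon * crh / koff
        d_m_fast, k_pool = 5.0, 0.01
        ext = params_with(
            "extended",
            kon_crhr=kon, koff_crhr=koff, rc_tot=rc_tot,
            d_m=d_m_fast,
            a0=pars["b0"] * d_m_fast / k_pool,
            a1=pars["b1"] * crh * d_m_fast / (k_pool * rc_b),
            k_pool=k_pool,
            v0=pars["s0"],
            v1=pars["s1"] * crh / rc_b,
            k_loss=pars["k_loss"],
        )
        t = np.array([0.0, 1.0, 5.0, 15.0, 30.0, 60.0, 120.0])
        a = simulate("extended", Scenario("crh", crh, 0.0, t), ext)
        b = simulate("parsimonious", Scenario("crh", crh, 0.0, t), pars)
        mask = b.pct_change > 0.5
        rel = np.abs(a.pct_change[mask] - b.pct_change[mask]) / b.pct_change[mask]
        assert np.max(rel) < 0.05
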