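"""ODE models of glucocorticoid feedback on pituitary ACTH secretion.

Two models of the anterior-pituitary (corticotroph) response to clamped
extracellular CRH and cortisol are provided, mirroring an in-vitro
closed-well experiment: secreted ACTH accumulates in the supernatant
(with at most a small first-order loss) and is reported as percent change
relative to the basal concentration at t = 0.

Parsimonious model
    The classical four-species feedback loop (CRH, ACTH, glucocorticoid
    receptor GR, cortisol) in which cortisol acts *only* genomically: the
    cortisol-GR complex, a transcription factor when dimerized, represses
    ACTH production. In vitro, CRH and cortisol are clamped at their
    doses and adrenal cortisol production is absent, leaving the GR level
    and an intracellular releasable ACTH pool as dynamic species. CRH
    stimulates both production and secretion of the pool; cortisol
    touches production only.

Extended model
    Adds the fast, non-genomic feedback branch and explicit
    compartments. Extracellular CRH binds a membrane CRH receptor
    (CRHR); extracellular cortisol binds a membrane G-protein-coupled
    receptor (GPCR) and also passes the membrane. Bound CRHR stimulates
    POMC transcript production (genomic, slow) and the secretion rate of
    the releasable ACTH pool (non-genomic, fast); bound GPCR inhibits
    that secretion rate (fast negative feedback); intracellular cortisol
    binds GR, the complex dimerizes and translocates to the nucleus where
    it represses transcript production with a Hill-2 law (slow negative
    feedback). All binding is mass action, transport and degradation are
    first order.

Units: minutes and nanomolar throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint
from scipy.optimize import root

__all__ = [
    "Param",
    "HpaParameterSet",
    "Scenario",
    "Trajectory",
    "IntegrationError",
    "default_parameters",
    "make_rhs",
    "parsimonious_rhs",
    "extended_rhs",
    "steady_state",
    "simulate",
    "percent_change",
    "STATE_NAMES",
    "STATE_COMPARTMENTS",
    "BASAL_REFERENCE_NM",
]

#: Basal extracellular ACTH concentration (nM) used as the default
#: percent-change reference (the measured basal level of the assay).
BASAL_REFERENCE_NM = 15.016


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails to produce a trajectory."""


@dataclass
class Param:
    """One named rate/affinity constant with bounds and a reference value."""

    value: float
    lo: float
    hi: float
    ref: float | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        if self.ref is None:
            self.ref = self.value
        if not (self.lo <= self.value <= self.hi):
            raise ValueError(f"value {self.value} outside bounds [{self.lo}, {self.hi}]")
        if self.lo <= 0:
            raise ValueError("bounds must be strictly positive (log-space search)")


@dataclass
class HpaParameterSet:
    """Named parameters of one of the two models."""

    model_id: str
    params: dict[str, Param]

    def __getitem__(self, name: str) -> float:
        return self.params[name].value

    @property
    def names(self) -> list[str]:
        return list(self.params)

    def values(self, names=None) -> np.ndarray:
        names = names or self.names
        return np.array([self.params[n].value for n in names])

    def refs(self, names=None) -> np.ndarray:
        names = names or self.names
        return np.array([self.params[n].ref for n in names])

    def bounds(self, names=None) -> tuple[np.ndarray, np.ndarray]:
        names = names or self.names
        return (
            np.array([self.params[n].lo for n in names]),
            np.array([self.params[n].hi for n in names]),
        )

    def with_values(self, updates: dict[str, float]) -> "HpaParameterSet":
        new = {
            n: Param(updates.get(n, p.value), p.lo, p.hi, p.ref, p.unit)
            for n, p in self.params.items()
        }
        return HpaParameterSet(self.model_id, new)


def _p(value, span=30.0, unit="", lo=None, hi=None):
    return Param(value, lo if lo is not None else value / span,
                 hi if hi is not None else value * span, value, unit)


def default_parameters(model_id: str) -> HpaParameterSet:
    """Reference parameter sets (also the Tikhonov anchors p_ref).

    Values are order-of-magnitude physiological choices: receptor
    equilibration within a minute, membrane passage and nuclear
    translocation over tens of minutes, transcript turnover ~20 min, and
    secretion rates sized so the basal flux accumulates a few percent of
    the basal supernatant concentration per day.
    """
    if model_id == "extended":
        params = {
            # membrane receptors (totals in nM, mass-action kinetics)
            "rc_tot": _p(10.0, 10, "nM"),
            "kon_crhr": _p(0.3, unit="1/(nM min)"),
            "koff_crhr": _p(1.0, unit="1/min"),
            "rg_tot": _p(10.0, 10, "nM"),
            "kon_gpcr": _p(0.03, unit="1/(nM min)"),
            "koff_gpcr": _p(1.0, unit="1/min"),
            # cortisol passage and nuclear GR branch
            "k_mem": _p(0.05, unit="1/min"),
            "gr_tot": _p(10.0, 10, "nM"),
            "kb_gr": _p(0.002, unit="1/(nM min)"),
            "ku_gr": _p(0.01, unit="1/min"),
            "k_dim": _p(0.01, unit="1/(nM min)"),
            "k_nuc": _p(0.05, unit="1/min"),
            "k_exp": _p(0.005, unit="1/min"),
            # transcription and releasable pool
            "a0": _p(0.043, unit="nM/min"),
            "a1": _p(0.0013, unit="1/min"),
            "k_rep": _p(10.0, unit="nM"),
            "d_m": _p(0.05, unit="1/min"),
            "k_pool": _p(0.01, unit="1/min"),
            # secretion and extracellular turnover
            "v0": _p(0.0072, unit="1/min"),
            "v1": _p(0.12, unit="1/(nM min)"),
            "k_inh": _p(0.25, unit="nM"),
            "k_loss": _p(5e-4, unit="1/min", lo=1e-5, hi=1e-3),
        }
    elif model_id == "parsimonious":
        params = {
            "kr_b": _p(0.005, unit="nM/min"),
            "kr_max": _p(0.05, unit="nM/min"),
            "kr_d": _p(100.0, unit="nM^2"),
            "kr_deg": _p(0.005, unit="1/min"),
            "b0": _p(0.0087, unit="nM/min"),
            "b1": _p(0.0004, unit="1/min"),
            "k_i": _p(200.0, unit="nM"),
            "s0": _p(0.0072, unit="1/min"),
            "s1": _p(0.09, unit="1/(nM min)"),
            "k_loss": _p(5e-4, unit="1/min", lo=1e-5, hi=1e-3),
        }
    else:
        raise ValueError(f"unknown model_id {model_id!r}")
    return HpaParameterSet(model_id, params)


@dataclass
class Scenario:
    """One experimental arm: clamped doses and an observation grid."""

    label: str
    crh_dose_nM: float = 0.0
    cortisol_dose_nM: float = 0.0
    t_obs_min: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    reference_conc_nM: float = BASAL_REFERENCE_NM

    def __post_init__(self) -> None:
        if self.crh_dose_nM < 0 or self.cortisol_dose_nM < 0:
            raise ValueError("doses must be >= 0")
        self.t_obs_min = np.asarray(self.t_obs_min, dtype=float)
        if self.t_obs_min[0] != 0 or np.any(np.diff(self.t_obs_min) <= 0):
            raise ValueError("t_obs must be increasing and start at 0")
        if self.reference_conc_nM <= 0:
            raise ValueError("reference concentration must be > 0")

    @classmethod
    def basal(cls, t_obs=(0.0,)) -> "Scenario":
        return cls("basal", 0.0, 0.0, np.asarray(t_obs, dtype=float))

    @classmethod
    def crh(cls, t_obs=(0.0,), dose_nM: float = 10.0) -> "Scenario":
        return cls("crh", dose_nM, 0.0, np.asarray(t_obs, dtype=float))

    @classmethod
    def crh_cortisol(
        cls, t_obs=(0.0,), crh_nM: float = 10.0, cortisol_nM: float = 100.0
    ) -> "Scenario":
        return cls("crh_cortisol", crh_nM, cortisol_nM, np.asarray(t_obs, dtype=float))


STATE_NAMES = {
    "extended": [
        "crhr_bound", "gpcr_bound", "cortisol_ic", "gr_free", "gr_cortisol",
        "gr_dimer", "gr_dimer_nuc", "pomc_transcript", "acth_pool", "acth_ec",
    ],
    "parsimonious": ["gr", "acth_pool", "acth_ec"],
}

STATE_COMPARTMENTS = {
    "extended": [
        "membrane", "membrane", "intracellular", "intracellular", "intracellular",
        "intracellular", "nucleus", "intracellular", "intracellular", "extracellular",
    ],
    "parsimonious": ["intracellular", "intracellular", "extracellular"],
}


_PARSIMONIOUS_ORDER = ["kr_b", "kr_max", "kr_d", "kr_deg", "b0", "b1", "k_i",
                       "s0", "s1", "k_loss"]
_EXTENDED_ORDER = ["rc_tot", "kon_crhr", "koff_crhr", "rg_tot", "kon_gpcr",
                   "koff_gpcr", "k_mem", "gr_tot", "kb_gr", "ku_gr", "k_dim",
                   "k_nuc", "k_exp", "a0", "a1", "k_rep", "d_m", "k_pool",
                   "v0", "v1", "k_inh", "k_loss"]


def _parsimonious_core(state, crh, cort, v):
    (kr_b, kr_max, kr_d, kr_deg, b0, b1, k_i, s0, s1, k_loss) = v
    r = state[0] if state[0] > 0.0 else 0.0
    a = state[1] if state[1] > 0.0 else 0.0
    a_e = state[2] if state[2] > 0.0 else 0.0

    occ = cort * r  # cortisol-GR activity driving the dimer feedback
    occ2 = occ * occ
    dr = kr_b + kr_max * occ2 / (kr_d * kr_d + occ2) - kr_deg * r
    production = (b0 + b1 * crh) / (1.0 + (occ / k_i) ** 2)
    sec_rate = s0 + s1 * crh
    da = production - sec_rate * a
    da_e = sec_rate * a - k_loss * a_e
    return [dr, da, da_e]


def _extended_core(state, crh, cort, v):
    (rc_tot, kon_crhr, koff_crhr, rg_tot, kon_gpcr, koff_gpcr, k_mem, gr_tot,
     kb_gr, ku_gr, k_dim, k_nuc, k_exp, a0, a1, k_rep, d_m, k_pool,
     v0, v1, k_inh, k_loss) = v
    rc_b, rg_b, co_i, gr, grc, dim, dn, m, pool, a_e = (
        s if s > 0.0 else 0.0 for s in state
    )

    drc = kon_crhr * crh * (rc_tot - rc_b) - koff_crhr * rc_b
    drg = kon_gpcr * cort * (rg_tot - rg_b) - koff_gpcr * rg_b

    bind = kb_gr * co_i * gr
    unbind = ku_gr * grc
    dimerize = k_dim * grc * grc
    dco = k_mem * (cort - co_i) - bind + unbind
    dgr = -bind + unbind + 2.0 * k_exp * dn
    dgrc = bind - unbind - 2.0 * dimerize
    ddim = dimerize - k_nuc * dim
    ddn = k_nuc * dim - k_exp * dn

    repression = 1.0 + (dn / k_rep) ** 2
    dm = (a0 + a1 * rc_b) / repression - d_m * m

    sec_rate = (v0 + v1 * rc_b) / (1.0 + rg_b / k_inh)
    dpool = k_pool * m - sec_rate * pool
    da_e = sec_rate * pool - k_loss * a_e
    return [drc, drg, dco, dgr, dgrc, ddim, ddn, dm, dpool, da_e]


def make_rhs(model_id: str, params: HpaParameterSet, scenario: Scenario):
    """Bind a model's parameters and clamped inputs into a fast ``f(y, t)``."""
    crh = scenario.crh_dose_nM
    cort = scenario.cortisol_dose_nM
    if model_id == "extended":
        v = tuple(params.params[n].value for n in _EXTENDED_ORDER)
        return lambda y, t: _extended_core(y, crh, cort, v)
    if model_id == "parsimonious":
        v = tuple(params.params[n].value for n in _PARSIMONIOUS_ORDER)
        return lambda y, t: _parsimonious_core(y, crh, cort, v)
    raise ValueError(f"unknown model_id {model_id!r}")


def parsimonious_rhs(state, t, params: HpaParameterSet, scenario: Scenario):
    """Right-hand side of the parsimonious (genomic-feedback-only) model.

    States: [gr, acth_pool, acth_ec]; CRH and cortisol are clamped at the
    scenario doses (no hypothalamic or adrenal dynamics in vitro).
    """
    if np.any(np.asarray(state) < -1e-9):
        raise ValueError("negative state passed to parsimonious_rhs")
    return _parsimonious_core(
        state, scenario.crh_dose_nM, scenario.cortisol_dose_nM,
        tuple(params.params[n].value for n in _PARSIMONIOUS_ORDER),
    )


def extended_rhs(state, t, params: HpaParameterSet, scenario: Scenario):
    """Right-hand side of the extended three-compartment receptor model.

    States (nM): bound CRHR, bound GPCR, intracellular cortisol, free GR,
    GR-cortisol complex, cytosolic GR dimer, nuclear GR dimer, POMC
    transcript, releasable ACTH pool, extracellular ACTH. Extracellular
    CRH and cortisol are clamped at the scenario doses; bound GPCR
    divides, and bound CRHR multiplies, the pool secretion rate (the
    fast, non-genomic branch), while the nuclear GR dimer represses
    transcript production (the slow, genomic branch).
    """
    if np.any(np.asarray(state) < -1e-9):
        raise ValueError("negative state passed to extended_rhs")
    return _extended_core(
        state, scenario.crh_dose_nM, scenario.cortisol_dose_nM,
        tuple(params.params[n].value for n in _EXTENDED_ORDER),
    )


def _basal_guess(model_id: str, params: HpaParameterSet, reference: float) -> np.ndarray:
    """Closed-form basal (zero-dose) steady state used to seed the solver."""
    p = params.params
    if model_id == "extended":
        m0 = p["a0"].value / p["d_m"].value
        pool0 = p["k_pool"].value * m0 / p["v0"].value
        return np.array(
            [0.0, 0.0, 0.0, p["gr_tot"].value, 0.0, 0.0, 0.0, m0, pool0, reference]
        )
    r0 = p["kr_b"].value / p["kr_deg"].value
    a0 = p["b0"].value / p["s0"].value
    return np.array([r0, a0, reference])


def steady_state(
    model_id: str,
    params: HpaParameterSet,
    scenario: Scenario | None = None,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Basal steady state of the cellular states.

    The extracellular ACTH concentration has no steady state under the
    default (negligible) supernatant loss — basal secretion accumulates
    indefinitely — so it is clamped at the scenario reference
    concentration and the remaining states are solved to a residual norm
    below 1e-10 (short relaxation integration, then root polish).
    """
    scenario = scenario or Scenario.basal()
    if scenario.crh_dose_nM != 0 or scenario.cortisol_dose_nM != 0:
        raise ValueError("steady_state is defined for the zero-dose scenario")
    rhs = make_rhs(model_id, params, scenario)
    ref = scenario.reference_conc_nM
    x0 = np.asarray(start, dtype=float) if start is not None else _basal_guess(
        model_id, params, ref
    )

    def internal_rhs(x):
        """Cellular-state derivatives with supernatant ACTH clamped; the
        neutrally stable free-GR equation is replaced by the GR
        conservation constraint (root solve only, not dynamics)."""
        full = np.append(x, ref)
        d = np.asarray(rhs(full, 0.0))[:-1]
        if model_id == "extended":
            gr, grc, dim, dn = x[3], x[4], x[5], x[6]
            d[3] = gr + grc + 2.0 * (dim + dn) - params["gr_tot"]
        return d

    # relax the true dynamics, then polish the constrained system
    def relax_rhs(x, t):
        full = np.append(np.maximum(x, 0.0), ref)
        return np.asarray(rhs(full, 0.0))[:-1]

    relaxed = np.maximum(
        odeint(relax_rhs, x0[:-1], [0.0, 5e4], rtol=1e-10, atol=1e-12,
               mxstep=100000)[-1],
        0.0,
    )
    if model_id == "extended":
        # project the neutrally stable free-GR level onto the conservation
        # constraint so the polish starts from a consistent point
        relaxed[3] = max(
            params["gr_tot"] - relaxed[4] - 2.0 * (relaxed[5] + relaxed[6]), 0.0
        )
    sol = root(internal_rhs, relaxed, method="hybr", tol=1e-13)
    resid = float(np.linalg.norm(internal_rhs(sol.x)))
    if resid > 1e-10:
        raise IntegrationError(f"no steady state found (residual {resid:g})")
    return np.append(np.maximum(sol.x, 0.0), ref)


@dataclass
class Trajectory:
    """Simulated time course of one scenario."""

    model_id: str
    times_min: np.ndarray
    states: np.ndarray
    acth_nM: np.ndarray
    pct_change: np.ndarray
    state_names: list[str]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=self.state_names)
        df.insert(0, "t_min", self.times_min)
        df["acth_nM"] = self.acth_nM
        df["pct_change"] = self.pct_change
        return df


def percent_change(acth_nM, reference_nM: float):
    """Percent change of extracellular ACTH relative to the basal reference."""
    if reference_nM <= 0:
        raise ValueError("reference must be > 0")
    return 100.0 * (np.asarray(acth_nM, dtype=float) - reference_nM) / reference_nM


def simulate(
    model_id: str,
    scenario: Scenario,
    params: HpaParameterSet | None = None,
    t_grid_min: np.ndarray | None = None,
    rtol: float = 1e-8,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate a model from the basal steady state with doses applied at t=0.

    The initial state is the zero-dose steady state of the cellular
    species with extracellular ACTH at the scenario reference; at t = 0
    the clamped extracellular inputs jump to the scenario doses.
    """
    params = params or default_parameters(model_id)
    t = np.asarray(t_grid_min if t_grid_min is not None else scenario.t_obs_min,
                   dtype=float)
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must start at 0 and increase")
    if x0 is None:
        basal = Scenario("basal", 0.0, 0.0, np.array([0.0]),
                         scenario.reference_conc_nM)
        x0 = steady_state(model_id, params, basal)
    rhs = make_rhs(model_id, params, scenario)

    t_solve = t if len(t) > 1 else np.array([0.0, 1.0])
    sol, info = odeint(
        rhs, x0, t_solve, rtol=rtol, atol=1e-12, full_output=True, mxstep=20000,
    )
    if info["message"] != "Integration successful.":
        raise IntegrationError(f"ODE integration failed: {info['message']}")
    sol = sol[: len(t)]
    if np.any(sol < -1e-6):
        raise IntegrationError("trajectory left the non-negative domain")
    acth = np.clip(sol[:, -1], 0.0, None)
    return Trajectory(
        model_id=model_id,
        times_min=t,
        states=np.clip(sol, -1e-12, None),
        acth_nM=acth,
        pct_change=percent_change(acth, scenario.reference_conc_nM),
        state_names=STATE_NAMES[model_id],
    )
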