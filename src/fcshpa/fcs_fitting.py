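"""Nonlinear least-squares analysis of FCS correlation curves.

The immunoassay analysis runs in two stages. A curve of pure labeled
antibody is fitted with the one-component model to pin down the free
antibody's diffusion time tau_D1. Sample curves (antibody + immunocomplex)
are then fitted with the two-component model holding tau_D1 fixed, which
yields the total particle number N', the bound mole fraction Y and the
complex diffusion time tau_D2. Since every immunocomplex carries exactly
one analyte molecule, Y*N' counts analyte (ACTH) particles and (1-Y)*N'
the remaining free labeled antibody; the effective-volume constant turns
both into molar concentrations.

Per-series statistics follow the instrument convention: mean with a
two-sided Student-t confidence half-width (default alpha = 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize
from scipy import stats

from .fcs_core import (
    STRUCTURAL_PARAMETER_DEFAULT,
    ConfocalVolume,
    CorrelationCurve,
    one_component_model,
    particles_to_concentration,
    two_component_model,
)

__all__ = [
    "OneComponentFit",
    "TwoComponentFit",
    "AssayResult",
    "SeriesEstimate",
    "NoSignalError",
    "fit_one_component",
    "fit_two_component",
    "extract_assay_result",
    "aggregate_series",
    "write_fit_report",
]


class NoSignalError(ValueError):
    """Raised when a curve carries no correlated signal above the noise."""


@dataclass
class OneComponentFit:
    n_particles: float
    n_particles_stderr: float | None
    tau_d_s: float
    tau_d_stderr: float | None
    residual_norm: float
    converged: bool


@dataclass
class TwoComponentFit:
    n_total: float
    n_total_stderr: float | None
    mole_fraction_y: float
    mole_fraction_y_stderr: float | None
    tau_d2_s: float
    tau_d2_stderr: float | None
    tau_d1_fixed_s: float
    residual_norm: float
    converged: bool
    component_collapse: bool = False


@dataclass
class AssayResult:
    """Absolute particle counts and molar concentrations from one fit."""

    n_acth: float
    n_free_igg: float
    c_acth_mol_l: float
    c_free_igg_mol_l: float


@dataclass
class SeriesEstimate:
    mean: float
    halfwidth: float
    n_runs: int
    alpha: float


def _weights(curve: CorrelationCurve) -> np.ndarray | None:
    if curve.stderr is None:
        return None
    positive = curve.stderr > 0
    if not positive.any():
        return None  # no usable uncertainties: uniform weighting
    # zero-stderr channels get the weight of the tightest real channel
    floor = float(curve.stderr[positive].min())
    return 1.0 / np.where(positive, curve.stderr, floor)


def _check_signal(curve: CorrelationCurve) -> None:
    if len(curve.lags_s) < 10:
        raise ValueError("curve must have at least 10 lags")
    if curve.stderr is not None:
        floor = 10.0 * float(np.median(curve.stderr))
        if float(np.max(curve.g)) - 1.0 < floor:
            raise NoSignalError("correlation amplitude below 10x median stderr")
    elif float(np.max(curve.g)) - 1.0 <= 0:
        raise NoSignalError("curve has no positive correlation amplitude")


def _amplitude_guess(curve: CorrelationCurve) -> float:
    amp = float(curve.g[0]) - 1.0
    return 1.0 / amp if amp > 1e-6 else 10.0


def fit_one_component(
    curve: CorrelationCurve,
    structural_parameter: float = STRUCTURAL_PARAMETER_DEFAULT,
    init: dict | None = None,
) -> OneComponentFit:
    """Fit the one-component diffusion model to a correlation curve.

    Weighted least squares (per-lag stderr weights when available,
    uniform otherwise); parameter standard errors from the Gauss-Newton
    curvature of the objective at the optimum.
    """
    _check_signal(curve)
    init = init or {}
    w = _weights(curve)

    params = Parameters()
    params.add("n", value=init.get("n_particles", _amplitude_guess(curve)),
               min=1e-3, max=1e4)
    # tau_D guess: lag where the decay has dropped to half amplitude
    amp = float(curve.g[0]) - 1.0
    half = 1.0 + 0.5 * amp
    idx = int(np.searchsorted(-curve.g, -half))
    tau_guess = init.get("tau_d_s", float(curve.lags_s[min(idx, len(curve.lags_s) - 1)]))
    params.add("tau_d", value=max(tau_guess, curve.lags_s[0]),
               min=curve.lags_s[0] / 10, max=curve.lags_s[-1] * 10)

    def resid(p):
        r = one_component_model(curve.lags_s, p["n"].value, p["tau_d"].value,
                                structural_parameter) - curve.g
        return r * w if w is not None else r

    out = minimize(resid, params, method="least_squares")
    best = out.params
    return OneComponentFit(
        n_particles=float(best["n"].value),
        n_particles_stderr=(float(best["n"].stderr) if best["n"].stderr else None),
        tau_d_s=float(best["tau_d"].value),
        tau_d_stderr=(float(best["tau_d"].stderr) if best["tau_d"].stderr else None),
        residual_norm=float(np.sqrt(np.sum(np.asarray(out.residual) ** 2))),
        converged=bool(out.success),
    )


def fit_two_component(
    curve: CorrelationCurve,
    tau_d1_fixed_s: float,
    structural_parameter: float = STRUCTURAL_PARAMETER_DEFAULT,
    init: dict | None = None,
) -> TwoComponentFit:
    """Fit the two-component model with the free-antibody time held fixed.

    Minimizes over (N', Y, tau_D2) with tau_D2 constrained to be at least
    tau_D1 (the bound complex diffuses more slowly). Three multistarts
    seed tau_D2 at {1.5, 2.5, 5} x tau_D1; the best weighted residual
    wins, which makes the fit deterministic for a given curve. A fit that
    drives tau_D2 onto its lower bound is flagged ``component_collapse``
    (the two components are indistinguishable, e.g. Y ~ 0).
    """
    if tau_d1_fixed_s <= 0:
        raise ValueError("tau_d1_fixed_s must be > 0")
    _check_signal(curve)
    init = init or {}
    w = _weights(curve)

    def resid(p):
        r = two_component_model(
            curve.lags_s, p["n_total"].value, p["y"].value,
            tau_d1_fixed_s, p["tau_d2"].value, structural_parameter,
        ) - curve.g
        return r * w if w is not None else r

    best_out = None
    starts = init.get("tau_d2_starts_s", [1.5 * tau_d1_fixed_s,
                                          2.5 * tau_d1_fixed_s,
                                          5.0 * tau_d1_fixed_s])
    for tau2_start in starts:
        params = Parameters()
        params.add("n_total", value=init.get("n_total", _amplitude_guess(curve)),
                   min=1e-3, max=1e4)
        params.add("y", value=init.get("mole_fraction_y", 0.3), min=0.0, max=1.0)
        params.add("tau_d2", value=tau2_start, min=tau_d1_fixed_s,
                   max=100.0 * tau_d1_fixed_s)
        out = minimize(resid, params, method="least_squares")
        chi = float(np.sum(np.asarray(out.residual) ** 2))
        if best_out is None or chi < best_out[0]:
            best_out = (chi, out)

    chi, out = best_out
    best = out.params
    tau2 = float(best["tau_d2"].value)
    collapse = (tau2 - tau_d1_fixed_s) < 1e-3 * tau_d1_fixed_s
    return TwoComponentFit(
        n_total=float(best["n_total"].value),
        n_total_stderr=(float(best["n_total"].stderr) if best["n_total"].stderr else None),
        mole_fraction_y=float(best["y"].value),
        mole_fraction_y_stderr=(float(best["y"].stderr) if best["y"].stderr else None),
        tau_d2_s=tau2,
        tau_d2_stderr=(float(best["tau_d2"].stderr) if best["tau_d2"].stderr else None),
        tau_d1_fixed_s=tau_d1_fixed_s,
        residual_norm=float(np.sqrt(chi)),
        converged=bool(out.success),
        component_collapse=collapse,
    )


def extract_assay_result(fit: TwoComponentFit, volume: ConfocalVolume) -> AssayResult:
    """Particle counts and concentrations from a converged two-component fit.

    Each immunocomplex contains one analyte molecule, so the slow
    component counts analyte: N_ACTH = Y * N', N_freeIgG = (1 - Y) * N'.
    """
    if not fit.converged:
        raise ValueError("cannot extract concentrations from an unconverged fit")
    n_acth = fit.mole_fraction_y * fit.n_total
    n_igg = (1.0 - fit.mole_fraction_y) * fit.n_total
    return AssayResult(
        n_acth=n_acth,
        n_free_igg=n_igg,
        c_acth_mol_l=particles_to_concentration(n_acth, volume.v_eff_l),
        c_free_igg_mol_l=particles_to_concentration(n_igg, volume.v_eff_l),
    )


def write_fit_report(fit, path) -> None:
    """Write a fit as a ``param,estimate,stderr`` CSV report."""
    import pandas as pd

    if isinstance(fit, OneComponentFit):
        rows = [("n_particles", fit.n_particles, fit.n_particles_stderr),
                ("tau_d_s", fit.tau_d_s, fit.tau_d_stderr)]
    elif isinstance(fit, TwoComponentFit):
        rows = [("n_total", fit.n_total, fit.n_total_stderr),
                ("mole_fraction_y", fit.mole_fraction_y, fit.mole_fraction_y_stderr),
                ("tau_d2_s", fit.tau_d2_s, fit.tau_d2_stderr),
                ("tau_d1_fixed_s", fit.tau_d1_fixed_s, None)]
    else:
        raise TypeError(f"cannot report fit of type {type(fit).__name__}")
    pd.DataFrame(rows, columns=["param", "estimate", "stderr"]).to_csv(
        path, index=False
    )


def aggregate_series(values, alpha: float = 0.1) -> SeriesEstimate:
    """Mean and two-sided Student-t confidence half-width of a run series.

    ``halfwidth = t_{1-alpha/2, n-1} * s / sqrt(n)`` — the deviation
    convention used for all reported series statistics.
    """
    values = np.asarray(list(values), dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values to aggregate")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    t = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - 1))
    return SeriesEstimate(mean=mean, halfwidth=t * sd / np.sqrt(n), n_runs=n, alpha=alpha)
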