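"""Synthetic FCS data: noisy curves, Brownian-dynamics oracle, assay series.

Three layers stand in for the instrument:

* :func:`generate_correlation_curve` draws noisy curves directly from the
  analytic two-component model — the fast generator used for parameter
  recovery studies.
* :func:`simulate_photon_trace` plus :func:`multiple_tau_autocorrelate`
  form a brute-force oracle: point emitters take Brownian steps through a
  3D-Gaussian detection profile in a periodic box, Poisson photon counts
  are binned, and a multiple-tau correlator estimates G(tau) without ever
  touching the closed-form model.
* :func:`generate_assay_series` encodes the sandwich-immunoassay
  stoichiometry (complete capture of analyte by excess labeled antibody)
  and emits whole 50-run measurement series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .fcs_core import (
    ConfocalVolume,
    CorrelationCurve,
    concentration_to_particles,
    two_component_model,
)

__all__ = [
    "AssayProtocol",
    "PhotonTrace",
    "BrownianSimConfig",
    "AntibodySaturationError",
    "mole_fraction_from_capture",
    "make_lag_grid",
    "generate_correlation_curve",
    "simulate_photon_trace",
    "multiple_tau_autocorrelate",
    "generate_assay_series",
]

#: Default relative noise scale of the direct curve generator; calibrated
#: loosely so a 50-run series at 15 nM analyte reproduces sub-nanomolar
#: series deviations of the assay (see docs/methods.md).
NOISE_SCALE_DEFAULT = 0.01


class AntibodySaturationError(ValueError):
    """Analyte exceeds labeled antibody: outside the complete-capture regime."""


@dataclass
class AssayProtocol:
    """Measurement protocol of the sandwich FCS immunoassay.

    Defaults mirror the assay conditions: 60 nM labeled plus 60 nM
    unlabeled monoclonal antibody, free-antibody diffusion time 220 us,
    immunocomplex 483 us, series of 50 x 10 s runs.
    """

    c_labeled_ab_mol_l: float = 60e-9
    c_unlabeled_ab_mol_l: float = 60e-9
    tau_free_s: float = 220e-6
    tau_complex_s: float = 483e-6
    n_runs: int = 50
    meas_time_s: float = 10.0
    volume: ConfocalVolume = field(default_factory=ConfocalVolume)

    def __post_init__(self) -> None:
        if self.c_labeled_ab_mol_l <= 0 or self.c_unlabeled_ab_mol_l <= 0:
            raise ValueError("antibody concentrations must be > 0")
        if not self.tau_complex_s > self.tau_free_s > 0:
            raise ValueError("need tau_complex > tau_free > 0")


@dataclass
class PhotonTrace:
    """Binned photon counts from the detector (or its simulation)."""

    bin_width_s: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.bin_width_s * len(self.counts)


@dataclass
class BrownianSimConfig:
    """Configuration of the Brownian-dynamics photon-trace simulator.

    The box must dwarf the detection volume (each length >= 10x the
    corresponding 1/e^2 radius) and the time step must resolve the
    fastest diffusion time (dt <= tau_D,min / 50).
    """

    box_lengths_um: tuple = (2.0, 2.0, 10.0)
    n_particles_per_species: tuple = (32,)
    d_coeffs_cm2_s: tuple = (3.7e-7,)
    brightness_cps: float = 2.0e5
    time_step_s: float = 3e-6
    duration_s: float = 60.0
    seed: int = 0
    #: start all particles at the focus centre instead of uniformly in the
    #: box (useful for degenerate checks, e.g. an immobile emitter)
    start_at_origin: bool = False

    def validate(self, volume: ConfocalVolume) -> None:
        if len(self.n_particles_per_species) != len(self.d_coeffs_cm2_s):
            raise ValueError("one particle count per species required")
        radii = (volume.radial_r_um, volume.radial_r_um, volume.axial_z_um)
        for L, r in zip(self.box_lengths_um, radii):
            if L < 10.0 * r:
                raise ValueError(
                    f"box length {L} um below 10x detection radius {r} um"
                )
        from .fcs_core import diffusion_time_from_coefficient

        tau_min = min(
            diffusion_time_from_coefficient(d, volume.radial_r_um)
            for d in self.d_coeffs_cm2_s
        )
        if self.time_step_s > tau_min / 50.0:
            raise ValueError(
                f"time step {self.time_step_s} s too coarse for tau_D {tau_min} s"
            )
        if self.brightness_cps < 0 or self.duration_s <= 0:
            raise ValueError("brightness must be >= 0 and duration > 0")


def mole_fraction_from_capture(c_acth_mol_l: float, protocol: AssayProtocol) -> float:
    """Bound mole fraction Y implied by complete sandwich capture.

    In the antibody-excess regime every analyte molecule is captured by
    exactly one labeled antibody, so Y = c_analyte / c_labeled_ab.
    """
    if c_acth_mol_l < 0:
        raise ValueError("analyte concentration must be >= 0")
    # tolerate rounding right at the equivalence point
    if c_acth_mol_l > protocol.c_labeled_ab_mol_l * (1.0 + 1e-9):
        raise AntibodySaturationError(
            "analyte exceeds labeled antibody; complete capture assumption broken"
        )
    return min(c_acth_mol_l / protocol.c_labeled_ab_mol_l, 1.0)


def make_lag_grid(
    channels_per_octave: int = 16, t_min_s: float = 1e-6, t_max_s: float = 1.0
) -> np.ndarray:
    """Quasi-logarithmic multiple-tau lag grid (bin width doubles per octave)."""
    if channels_per_octave < 1 or t_min_s <= 0 or t_max_s <= t_min_s:
        raise ValueError("invalid lag-grid specification")
    lags = [t_min_s * k for k in range(1, 2 * channels_per_octave + 1)]
    delta = 2.0 * t_min_s
    while lags[-1] < t_max_s:
        start = lags[-1] + delta
        lags.extend(
            start + i * delta for i in range(channels_per_octave)
        )
        delta *= 2.0
    return np.array([t for t in lags if t <= t_max_s])


def generate_correlation_curve(
    n_total: float,
    mole_fraction_y: float,
    protocol: AssayProtocol,
    lags_s: np.ndarray | None = None,
    noise_scale: float = NOISE_SCALE_DEFAULT,
    seed: int = 0,
) -> CorrelationCurve:
    """Draw one noisy correlation curve from the analytic mixture model.

    The per-lag noise is heteroscedastic Gaussian with standard deviation
    ``noise_scale * ((G(tau) - 1) + sqrt(tau / T))``: short-lag channels
    are averaged over many more fluctuations during a measurement of
    length T and are correspondingly cleaner. The stderr column is
    populated with the generating standard deviations.
    """
    if lags_s is None:
        lags_s = make_lag_grid()
    lags_s = np.asarray(lags_s, dtype=float)
    if lags_s.size == 0:
        raise ValueError("empty lag grid")
    g_model = two_component_model(
        lags_s, n_total, mole_fraction_y,
        protocol.tau_free_s, protocol.tau_complex_s,
        protocol.volume.structural_parameter,
    )
    sd = noise_scale * ((g_model - 1.0) + np.sqrt(lags_s / protocol.meas_time_s))
    rng = np.random.default_rng(seed)
    g = g_model + rng.normal(0.0, 1.0, size=lags_s.shape) * sd
    return CorrelationCurve(
        lags_s, g, stderr=sd, meas_time_s=protocol.meas_time_s, n_runs=protocol.n_runs
    )


@njit(cache=True)
def _brownian_counts(
    n_steps, box, n_per_species, step_sd_um, r_um, z_um, brightness_per_bin, seed,
    start_at_origin,
):  # pragma: no cover - exercised through simulate_photon_trace
    np.random.seed(seed)
    n_total = 0
    for n in n_per_species:
        n_total += n
    pos = np.empty((n_total, 3))
    sd = np.empty(n_total)
    i = 0
    for s in range(len(n_per_species)):
        for _ in range(n_per_species[s]):
            for ax in range(3):
                if start_at_origin:
                    pos[i, ax] = 0.0
                else:
                    pos[i, ax] = (np.random.random() - 0.5) * box[ax]
            sd[i] = step_sd_um[s]
            i += 1
    counts = np.zeros(n_steps, dtype=np.int64)
    inv_r2 = 2.0 / (r_um * r_um)
    inv_z2 = 2.0 / (z_um * z_um)
    for t in range(n_steps):
        lam = 0.0
        for p in range(n_total):
            for ax in range(3):
                x = pos[p, ax] + np.random.normal(0.0, sd[p])
                # periodic wrap into [-L/2, L/2)
                half = 0.5 * box[ax]
                if x >= half:
                    x -= box[ax]
                elif x < -half:
                    x += box[ax]
                pos[p, ax] = x
            lam += np.exp(
                -(pos[p, 0] * pos[p, 0] + pos[p, 1] * pos[p, 1]) * inv_r2
                - pos[p, 2] * pos[p, 2] * inv_z2
            )
        counts[t] = np.random.poisson(lam * brightness_per_bin)
    return counts


def simulate_photon_trace(
    config: BrownianSimConfig, volume: ConfocalVolume
) -> PhotonTrace:
    """Brute-force photon trace from Brownian point emitters.

    Each particle takes independent Gaussian steps of standard deviation
    sqrt(2 D dt) per axis with periodic wrapping; the expected count per
    bin is the sum of molecular brightnesses weighted by the Gaussian
    detection profile exp(-2x^2/r^2 - 2y^2/r^2 - 2z^2/z_ax^2), and
    emitted counts are Poisson. Deterministic for a given seed.
    """
    config.validate(volume)
    n_steps = int(round(config.duration_s / config.time_step_s))
    step_sd_um = np.array(
        [
            np.sqrt(2.0 * d * config.time_step_s) * 1e4  # cm -> um
            for d in config.d_coeffs_cm2_s
        ]
    )
    counts = _brownian_counts(
        n_steps,
        np.asarray(config.box_lengths_um, dtype=float),
        np.asarray(config.n_particles_per_species, dtype=np.int64),
        step_sd_um,
        volume.radial_r_um,
        volume.axial_z_um,
        config.brightness_cps * config.time_step_s,
        config.seed % (2**31),
        config.start_at_origin,
    )
    return PhotonTrace(bin_width_s=config.time_step_s, counts=counts)


def multiple_tau_autocorrelate(
    trace: PhotonTrace, channels_per_octave: int = 16
) -> CorrelationCurve:
    """Multiple-tau estimate of G(tau) with symmetric normalization.

    ``G(k delta) = <F(t) F(t + k delta)> / (<F(t)> <F(t + k delta)>)``
    evaluated on a quasi-logarithmic grid: the finest ``2 m`` lags at the
    native bin width, then ``m`` lags per octave on successively
    2x-downsampled (summed) traces. A constant trace gives G = 1.
    """
    x = np.asarray(trace.counts, dtype=float)
    if len(x) < 2**10:
        raise ValueError("trace too short for multiple-tau correlation (need >= 1024 bins)")
    m = channels_per_octave
    delta = trace.bin_width_s
    lags, gs = [], []
    level = 0
    while len(x) >= 2 * (2 * m):
        ks = range(1, 2 * m + 1) if level == 0 else range(m + 1, 2 * m + 1)
        for k in ks:
            left = x[:-k]
            right = x[k:]
            mean_l = left.mean()
            mean_r = right.mean()
            if mean_l <= 0 or mean_r <= 0:
                g = 1.0
            else:
                g = float(left @ right) / len(left) / (mean_l * mean_r)
            lags.append(k * delta)
            gs.append(g)
        n_even = len(x) - (len(x) % 2)
        x = x[:n_even:2] + x[1:n_even:2]
        delta *= 2.0
        level += 1
    return CorrelationCurve(
        np.asarray(lags), np.asarray(gs), meas_time_s=trace.duration_s, n_runs=1
    )


def generate_assay_series(
    c_acth_true_mol_l: float,
    protocol: AssayProtocol | None = None,
    noise_scale: float = NOISE_SCALE_DEFAULT,
    seed: int = 0,
    lags_s: np.ndarray | None = None,
) -> list[CorrelationCurve]:
    """A full measurement series for one sample at a true analyte level.

    The total particle number N' follows from the labeled-antibody dose
    through the effective-volume conversion, the bound fraction Y from
    complete capture; per-run seeds are spawned deterministically from
    the master seed.
    """
    protocol = protocol or AssayProtocol()
    n_total = concentration_to_particles(
        protocol.c_labeled_ab_mol_l, protocol.volume.v_eff_l
    )
    y = mole_fraction_from_capture(c_acth_true_mol_l, protocol)
    run_seeds = np.random.SeedSequence(seed).generate_state(protocol.n_runs) % (2**31)
    return [
        generate_correlation_curve(
            n_total, y, protocol, lags_s=lags_s, noise_scale=noise_scale, seed=int(s)
        )
        for s in run_seeds
    ]
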