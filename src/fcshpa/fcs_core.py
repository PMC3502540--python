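"""Closed-form fluorescence correlation spectroscopy (FCS) models.

The autocorrelation function of fluorescence-intensity fluctuations in a
3D-Gaussian confocal detection volume carries two pieces of information:
its amplitude, ``G(0) - 1 = 1/N``, gives the mean number of fluorescent
particles in the volume, and its decay time gives the diffusion time
``tau_D = r**2 / (4 D)`` of the species through the radial waist ``r``.

This module provides the one- and two-component diffusion models, the
confocal-volume calibration relations, and the particle-number to molar
concentration conversion used by the sandwich-immunoassay quantification.

Units
-----
Times are seconds, diffusion coefficients cm^2/s, volume-element
dimensions micrometres, effective volumes litres, concentrations mol/l.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AVOGADRO",
    "V_EFF_DEFAULT",
    "STRUCTURAL_PARAMETER_DEFAULT",
    "ConfocalVolume",
    "CorrelationCurve",
    "DiffusingSpecies",
    "diffusion_time_from_coefficient",
    "calibrate_radial",
    "calibrate_confocal_volume",
    "one_component_model",
    "two_component_model",
    "particles_to_concentration",
    "concentration_to_particles",
]

#: Avogadro constant as used throughout the concentration arithmetic
#: (1/N_A / V_eff with V_eff = 5e-16 l gives the factor 30.115e7 particles
#: per mol/l). The historical 6.023e23 value is kept deliberately so that
#: printed conversion factors reproduce exactly.
AVOGADRO = 6.023e23

#: Default effective detection volume in litres (confocal volume element).
V_EFF_DEFAULT = 5e-16

#: Default axial-to-radial ratio of the Gaussian detection volume; held
#: fixed in all fits.
STRUCTURAL_PARAMETER_DEFAULT = 5.0

_UM_TO_CM = 1e-4


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class ConfocalVolume:
    """Calibrated geometry of the Gaussian detection volume.

    Parameters
    ----------
    radial_r_um : float
        1/e^2 radius of the volume in the focal plane, micrometres.
    axial_z_um : float
        1/e^2 half-height along the optical axis, micrometres.
    structural_parameter : float
        Axial-to-radial ratio z/r used by the fit models. Stored
        explicitly because instrument software rounds it (0.88/0.17 is
        carried as 5); it must agree with z/r within 5%.
    v_eff_l : float
        Effective volume in litres. An independent calibration constant,
        not derived from r and z (see Notes).

    Notes
    -----
    The effective volume is decoupled from the printed geometry: no
    standard Gaussian-volume convention (e.g. ``pi**1.5 * r**2 * z``)
    reproduces the 5e-16 l calibration constant from r = 0.17 um and
    z = 0.88 um, so the two are stored independently and the volume
    constant governs all concentration arithmetic.
    """

    radial_r_um: float = 0.17
    axial_z_um: float = 0.88
    structural_parameter: float = STRUCTURAL_PARAMETER_DEFAULT
    v_eff_l: float = V_EFF_DEFAULT

    def __post_init__(self) -> None:
        _require_positive(
            radial_r_um=self.radial_r_um,
            axial_z_um=self.axial_z_um,
            structural_parameter=self.structural_parameter,
            v_eff_l=self.v_eff_l,
        )
        ratio = self.axial_z_um / self.radial_r_um
        if abs(self.structural_parameter - ratio) / self.structural_parameter > 0.05:
            raise ValueError(
                "structural_parameter %.4g inconsistent with z/r = %.4g"
                % (self.structural_parameter, ratio)
            )


@dataclass
class CorrelationCurve:
    """A measured or synthetic autocorrelation curve G(tau).

    ``lags_s`` must be strictly increasing and positive; ``g`` holds the
    normalized correlation values (baseline 1), and ``stderr`` optional
    per-lag standard errors used as least-squares weights.
    """

    lags_s: np.ndarray
    g: np.ndarray
    stderr: np.ndarray | None = None
    meas_time_s: float = 10.0
    n_runs: int = 50

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags_s.ndim != 1 or self.g.shape != self.lags_s.shape:
            raise ValueError("lags and g must be 1-D arrays of equal length")
        if not np.all(np.diff(self.lags_s) > 0) or self.lags_s[0] <= 0:
            raise ValueError("lags must be strictly increasing and positive")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("g must be finite")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if self.stderr.shape != self.lags_s.shape:
                raise ValueError("stderr must match lags in length")
            if np.any(self.stderr < 0):
                raise ValueError("stderr must be >= 0")

    def to_csv(self, path) -> None:
        """Write the curve in the package CSV dialect (header lag_s,g[,stderr])."""
        import pandas as pd

        cols = {"lag_s": self.lags_s, "g": self.g}
        if self.stderr is not None:
            cols["stderr"] = self.stderr
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meas_time_s: float = 10.0, n_runs: int = 50) -> "CorrelationCurve":
        import pandas as pd

        df = pd.read_csv(path)
        if "lag_s" not in df.columns or "g" not in df.columns:
            raise ValueError("correlation-curve CSV needs columns lag_s,g[,stderr]")
        stderr = df["stderr"].to_numpy() if "stderr" in df.columns else None
        return cls(df["lag_s"].to_numpy(), df["g"].to_numpy(), stderr,
                   meas_time_s=meas_time_s, n_runs=n_runs)


@dataclass(frozen=True)
class DiffusingSpecies:
    """A fluorescent species characterised by D and/or its diffusion time."""

    name: str
    d_coeff_cm2_s: float | None = None
    tau_d_s: float | None = None
    volume: ConfocalVolume | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.d_coeff_cm2_s is not None:
            _require_positive(d_coeff_cm2_s=self.d_coeff_cm2_s)
        if self.tau_d_s is not None:
            _require_positive(tau_d_s=self.tau_d_s)
        if (
            self.d_coeff_cm2_s is not None
            and self.tau_d_s is not None
            and self.volume is not None
        ):
            expected = diffusion_time_from_coefficient(
                self.d_coeff_cm2_s, self.volume.radial_r_um
            )
            if abs(expected - self.tau_d_s) / expected > 0.01:
                raise ValueError(
                    f"tau_d {self.tau_d_s:g} s inconsistent with D and r "
                    f"(expected {expected:g} s)"
                )


def diffusion_time_from_coefficient(d_coeff_cm2_s: float, radial_r_um: float) -> float:
    """Diffusion time tau_D = r^2 / (4 D) for one-photon excitation.

    Parameters are the diffusion coefficient in cm^2/s and the radial
    1/e^2 waist in micrometres; the result is in seconds.
    """
    _require_positive(d_coeff_cm2_s=d_coeff_cm2_s, radial_r_um=radial_r_um)
    r_cm = radial_r_um * _UM_TO_CM
    return r_cm * r_cm / (4.0 * d_coeff_cm2_s)


def calibrate_radial(d_coeff_cm2_s: float, tau_d_s: float) -> float:
    """Radial waist (um) from a measured diffusion time of a known standard,
    via D = r^2/(4 tau_D) inverted: r = sqrt(4 D tau_D)."""
    _require_positive(d_coeff_cm2_s=d_coeff_cm2_s, tau_d_s=tau_d_s)
    return math.sqrt(4.0 * d_coeff_cm2_s * tau_d_s) / _UM_TO_CM


def calibrate_confocal_volume(
    tau_d_measured_s: float,
    d_known_cm2_s: float,
    structural_parameter: float = STRUCTURAL_PARAMETER_DEFAULT,
    v_eff_l: float = V_EFF_DEFAULT,
) -> ConfocalVolume:
    """Calibrate the detection-volume geometry from a dye standard.

    A dye with known diffusion coefficient (rhodamine 6G in water,
    D = 2.8e-6 cm^2/s) is measured; its fitted diffusion time yields the
    radial waist through r = sqrt(4 D tau_D), and the axial half-height
    follows from the structural parameter. The effective volume is an
    independent constant and is stored as given.
    """
    _require_positive(
        tau_d_measured_s=tau_d_measured_s,
        d_known_cm2_s=d_known_cm2_s,
        structural_parameter=structural_parameter,
        v_eff_l=v_eff_l,
    )
    r_um = calibrate_radial(d_known_cm2_s, tau_d_measured_s)
    return ConfocalVolume(
        radial_r_um=r_um,
        axial_z_um=structural_parameter * r_um,
        structural_parameter=structural_parameter,
        v_eff_l=v_eff_l,
    )


def _g_diff(tau, tau_d, structural_parameter):
    """Single-species diffusion factor g(tau) = (1+t/tD)^-1 (1+t/(s^2 tD))^-1/2."""
    x = tau / tau_d
    return 1.0 / ((1.0 + x) * np.sqrt(1.0 + x / (structural_parameter**2)))


def one_component_model(
    tau_s,
    n_particles: float,
    tau_d_s: float,
    structural_parameter: float = STRUCTURAL_PARAMETER_DEFAULT,
):
    """G(tau) for a single diffusing species in a 3D-Gaussian volume.

    ``G(tau) = 1 + (1/N) (1 + tau/tau_D)^-1 (1 + tau/(s^2 tau_D))^-1/2``

    with amplitude ``G(0) - 1 = 1/N``. Accepts scalar or array lags.
    """
    _require_positive(
        n_particles=n_particles, tau_d_s=tau_d_s, structural_parameter=structural_parameter
    )
    tau = np.asarray(tau_s, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    g = 1.0 + _g_diff(tau, tau_d_s, structural_parameter) / n_particles
    return g if g.ndim else float(g)


def two_component_model(
    tau_s,
    n_total: float,
    mole_fraction_y: float,
    tau_d1_s: float,
    tau_d2_s: float,
    structural_parameter: float = STRUCTURAL_PARAMETER_DEFAULT,
):
    """G(tau) for a mixture of two diffusing species of equal brightness.

    ``G(tau) = 1 + (1/N') [(1 - Y) g_D1(tau) + Y g_D2(tau)]``

    where ``N' = N1 + N2`` is the total particle number and Y the mole
    fraction of the slow component (the immunocomplex). The amplitude
    ``G(0) - 1 = 1/N'`` is independent of Y.
    """
    _require_positive(
        n_total=n_total,
        tau_d1_s=tau_d1_s,
        tau_d2_s=tau_d2_s,
        structural_parameter=structural_parameter,
    )
    if not 0.0 <= mole_fraction_y <= 1.0:
        raise ValueError(f"mole fraction Y must be in [0, 1], got {mole_fraction_y}")
    tau = np.asarray(tau_s, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    g = 1.0 + (
        (1.0 - mole_fraction_y) * _g_diff(tau, tau_d1_s, structural_parameter)
        + mole_fraction_y * _g_diff(tau, tau_d2_s, structural_parameter)
    ) / n_total
    return g if g.ndim else float(g)


def particles_to_concentration(n_particles: float, v_eff_l: float = V_EFF_DEFAULT) -> float:
    """Molar concentration of N particles in the effective volume.

    ``c = N / (N_A * V_eff)``; for the default 5e-16 l volume the
    denominator is the conversion factor 30.115e7 particles per mol/l.
    """
    if n_particles < 0:
        raise ValueError("particle number must be >= 0")
    _require_positive(v_eff_l=v_eff_l)
    return n_particles / (AVOGADRO * v_eff_l)


def concentration_to_particles(c_mol_l: float, v_eff_l: float = V_EFF_DEFAULT) -> float:
    """Inverse of :func:`particles_to_concentration`."""
    if c_mol_l < 0:
        raise ValueError("concentration must be >= 0")
    _require_positive(v_eff_l=v_eff_l)
    return c_mol_l * AVOGADRO * v_eff_l
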