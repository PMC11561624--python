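"""Calibrated synthetic-data generators.

These emulate the statistical structure of the study's laboratory
recordings so that every analysis stage is testable without the raw
data:

* coupled pCa/pH traces — a linear pH drift between the reported
  endpoints plus zero-mean colored (discretized Ornstein–Uhlenbeck)
  noise around the reported channel means;
* harmonic stimulation input/output pairs for a set of harmonic
  numbers of a 1-minute fundamental;
* impedance and capacitance spectra whose summary statistics reproduce
  the reported per-sample means exactly by construction (the circuit
  parameters are back-solved from the printed values);
* microsphere packing images with known ground-truth centers.

All generators are pure functions of their parameter object including
the seed.  They are phenomenological: no crystallization kinetics are
modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .electrochem import CapacitanceSpectrum, ImpedanceSpectrum
from .signals import TimeSeries

__all__ = [
    "PcaPhParams",
    "HarmonicDatasetParams",
    "SpectrumParams",
    "SphereImageParams",
    "PCA_PH_PRESETS",
    "SPECTRUM_TARGETS",
    "gen_pca_ph",
    "gen_harmonic_dataset",
    "gen_spectrum",
    "gen_microsphere_image",
]

# ---------------------------------------------------------------------------
# pCa / pH traces

PcaPhProfile = Literal["kp_composite", "control"]


@dataclass(frozen=True)
class PcaPhParams:
    """Parameters of the coupled pCa/pH trace generator.

    The ``kp_composite`` profile reproduces the kombucha–proteinoid
    composite: mean pCa 2.452 and a pH drift from 8.551 to 8.520 over
    1526 s.  The ``control`` profile is the proteinoid-free control
    with flat mean pH 8.282; its pCa mean 2.523 corresponds to the
    3 mM microsphere concentration (−log10 3×10⁻³).
    """

    profile: PcaPhProfile = "kp_composite"
    duration: float = 1526.0          # s
    dt: float = 1.0                   # s
    pca_mean: float = 2.452           # pCa units
    pca_noise_sd: float = 0.05        # pCa units
    ph_init: float = 8.551            # pH units
    ph_final: float = 8.520           # pH units
    ph_noise_sd: float = 0.05         # pH units
    noise_corr_time: float = 60.0     # s
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.duration > 0 and self.dt > 0):
            raise ValueError("duration and dt must be positive")
        if self.pca_noise_sd < 0 or self.ph_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.ph_init < self.ph_final:
            raise ValueError("drift presets require ph_init >= ph_final")
        if not self.noise_corr_time > 0:
            raise ValueError("noise correlation time must be positive")


PCA_PH_PRESETS: dict[str, PcaPhParams] = {
    "kp_composite": PcaPhParams(profile="kp_composite"),
    "control": PcaPhParams(
        profile="control",
        pca_mean=2.523, ph_init=8.282, ph_final=8.282,
    ),
}


def _time_grid(duration: float, dt: float) -> np.ndarray:
    """Closed grid [0, duration] with step dt."""
    n = int(round(duration / dt))
    return np.arange(n + 1) * dt


def _ou_noise(n: int, sd: float, corr_time: float, dt: float,
              rng: np.random.Generator) -> np.ndarray:
    """Stationary discretized Ornstein–Uhlenbeck noise, zero mean, sd ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    phi = np.exp(-dt / corr_time)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for k in range(1, n):
        x[k] = phi * x[k - 1] + eps[k - 1]
    return x


def gen_pca_ph(params: PcaPhParams) -> tuple[TimeSeries, TimeSeries]:
    """Generate coupled (pCa, pH) traces on one time grid.

    pCa is its mean plus colored noise; pH drifts linearly from
    ``ph_init`` to ``ph_final`` over ``duration`` plus independent
    colored noise.
    """
    t = _time_grid(params.duration, params.dt)
    rng = np.random.default_rng(params.seed)
    pca = params.pca_mean + _ou_noise(
        t.size, params.pca_noise_sd, params.noise_corr_time, params.dt, rng)
    drift = params.ph_init + (params.ph_final - params.ph_init) * (
        t / params.duration)
    ph = drift + _ou_noise(
        t.size, params.ph_noise_sd, params.noise_corr_time, params.dt, rng)
    return (
        TimeSeries(t, pca, channel_label="pCa", units="pCa"),
        TimeSeries(t, ph, channel_label="pH", units="pH"),
    )


# ---------------------------------------------------------------------------
# Harmonic stimulation

Nonlinearity = Literal["none", "soft_clip", "polynomial"]


@dataclass(frozen=True)
class HarmonicDatasetParams:
    """Input/output pair generator for sinusoidal harmonic stimulation.

    Defaults follow the stimulation protocol: harmonics h ∈ {2, 3, 6,
    10, 12, 15, 16} of a 1-minute fundamental, amplitude 1 V.  The
    output channel is ``gain · nonlinearity(input) + white noise``; the
    ``soft_clip`` nonlinearity is a normalized tanh, ``polynomial`` a
    cubic with even and odd distortion terms.
    """

    harmonics: tuple[int, ...] = (2, 3, 6, 10, 12, 15, 16)
    fundamental_f: float = 1.0 / 60.0     # Hz
    amplitude: float = 1.0                # volts
    phase: float = 0.0                    # radians
    duration: float = 600.0               # s (10 fundamental periods)
    dt: float = 0.25                      # s
    nonlinearity: Nonlinearity = "none"
    gain: float = 1.0
    noise_sd: float = 0.0                 # volts
    seed: int = 0

    def __post_init__(self) -> None:
        hs = tuple(int(h) for h in self.harmonics)
        if len(hs) == 0:
            raise ValueError("harmonics list must be non-empty")
        if any(h < 1 for h in hs):
            raise ValueError("harmonic numbers must be positive integers")
        object.__setattr__(self, "harmonics", hs)
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if not (self.duration > 0 and self.dt > 0):
            raise ValueError("duration and dt must be positive")
        f_max = max(hs) * self.fundamental_f
        if not self.dt < 1.0 / (2.0 * f_max):
            raise ValueError(
                f"dt={self.dt} violates Nyquist for h_max={max(hs)} "
                f"(need dt < {1.0 / (2.0 * f_max):.4g} s)")


def _apply_nonlinearity(x: np.ndarray, kind: Nonlinearity,
                        amplitude: float) -> np.ndarray:
    if kind == "none":
        return x
    if kind == "soft_clip":
        k = 3.0                        # saturation sharpness
        return amplitude * np.tanh(k * x / amplitude) / np.tanh(k)
    if kind == "polynomial":
        u = x / amplitude
        return amplitude * (u + 0.5 * u * u - 0.3 * u ** 3)
    raise ValueError(f"unknown nonlinearity {kind!r}")


def gen_harmonic_dataset(
    params: HarmonicDatasetParams,
) -> list[tuple[int, TimeSeries, TimeSeries]]:
    """Generate (harmonic, input, output) records per harmonic number."""
    t = _time_grid(params.duration, params.dt)
    rng = np.random.default_rng(params.seed)
    out = []
    for h in params.harmonics:
        omega = 2.0 * np.pi * h * params.fundamental_f
        vin = params.amplitude * np.sin(omega * t + params.phase)
        vout = params.gain * _apply_nonlinearity(
            vin, params.nonlinearity, params.amplitude)
        if params.noise_sd > 0:
            vout = vout + rng.normal(0.0, params.noise_sd, size=t.size)
        out.append((
            h,
            TimeSeries(t, vin, channel_label=f"vin_h{h}", units="V"),
            TimeSeries(t, vout, channel_label=f"vout_h{h}", units="V"),
        ))
    return out


# ---------------------------------------------------------------------------
# Impedance / capacitance spectra

SpectrumProfile = Literal[
    "spontaneous", "proteinoid", "kombucha_seeded",
    "kombucha_capacitive", "control_capacitive", "proteinoid_capacitive",
]

#: Printed per-sample summaries the generator reproduces by construction:
#: mean |Z| over the sweep for the impedance profiles (ohms), and the
#: low-frequency plateau capacitance for the capacitive profiles (farads;
#: the reported "nF scaled by 10⁻⁹" strings are read verbatim in nF).
SPECTRUM_TARGETS: dict[str, float] = {
    "spontaneous": 3.8935e15,          # ohm
    "proteinoid": 3.8935e15,           # ohm
    "kombucha_seeded": 2.6291e12,      # ohm
    "kombucha_capacitive": 40_389e-9,  # F  (40,389 nF)
    "control_capacitive": 78e-9 * 1e-9,        # F  (78e-9 nF)
    "proteinoid_capacitive": -72e-9 * 1e-9,    # F  (−72e-9 nF)
}

_IMPEDANCE_PROFILES = ("spontaneous", "proteinoid", "kombucha_seeded")
_CAPACITIVE_PROFILES = (
    "kombucha_capacitive", "control_capacitive", "proteinoid_capacitive")

#: Single-dispersion corner frequency shared by all profiles (Hz).
CORNER_F_HZ = 1.0e3


@dataclass(frozen=True)
class SpectrumParams:
    """Log-swept spectrum generator parameters (1 Hz – 1 MHz default)."""

    profile: SpectrumProfile = "kombucha_seeded"
    f_min: float = 1.0                # Hz
    f_max: float = 1.0e6              # Hz
    points_per_decade: int = 10
    noise_sd_log10: float = 0.0       # multiplicative noise in decades
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.f_min < self.f_max):
            raise ValueError("require 0 < f_min < f_max")
        if self.points_per_decade < 1:
            raise ValueError("points_per_decade must be >= 1")
        if self.profile not in _IMPEDANCE_PROFILES + _CAPACITIVE_PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")


def _log_grid(f_min: float, f_max: float, ppd: int) -> np.ndarray:
    n_dec = np.log10(f_max / f_min)
    n = int(round(n_dec * ppd)) + 1
    return np.logspace(np.log10(f_min), np.log10(f_max), n)


def gen_spectrum(
    params: SpectrumParams,
) -> ImpedanceSpectrum | CapacitanceSpectrum:
    """Generate a calibrated impedance or capacitance spectrum.

    Impedance profiles follow a parallel R‖C dispersion
    |Z|(f) = R/√(1+(f/f_c)²) with fixed corner f_c; R is back-solved so
    the arithmetic mean of |Z| over the sweep equals the printed
    per-sample mean exactly.  Capacitive profiles follow
    C(f) = C₀/(1+f/f_c) with C₀ back-solved so the lowest-decade mean
    equals the printed plateau value; the implied |Z| = 1/(2πf|C|) is
    then strictly decreasing in frequency.
    """
    f = _log_grid(params.f_min, params.f_max, params.points_per_decade)
    rng = np.random.default_rng(params.seed)
    target = SPECTRUM_TARGETS[params.profile]
    if params.profile in _IMPEDANCE_PROFILES:
        shape = 1.0 / np.sqrt(1.0 + (f / CORNER_F_HZ) ** 2)
        r = target / float(np.mean(shape))     # linear in R -> exact closure
        z_mag = r * shape
        phase = -np.degrees(np.arctan(f / CORNER_F_HZ))
        if params.noise_sd_log10 > 0:
            z_mag = z_mag * 10.0 ** rng.normal(
                0.0, params.noise_sd_log10, size=f.size)
        return ImpedanceSpectrum(f, z_mag, phase,
                                 sample_label=params.profile)
    shape = 1.0 / (1.0 + f / CORNER_F_HZ)
    low_decade = f <= 10.0 * f[0]
    c0 = target / float(np.mean(shape[low_decade]))
    cap = c0 * shape
    if params.noise_sd_log10 > 0:
        cap = cap * 10.0 ** rng.normal(
            0.0, params.noise_sd_log10, size=f.size)
    return CapacitanceSpectrum(f, cap, sample_label=params.profile)


# ---------------------------------------------------------------------------
# Microsphere packing images

Lattice = Literal["hexagonal", "random_sequential"]


@dataclass(frozen=True)
class SphereImageParams:
    """Synthetic micrograph of bright microspheres on a dark background.

    Ground-truth stand-in for the SEM micrographs: 8-bit grayscale,
    disks at intensity 200 on background 30, optional Gaussian pixel
    noise and center jitter.  ``spacing_px`` is the lattice constant of
    the hexagonal arrangement (center-to-center distance).
    """

    n_spheres: int = 25
    radius_px: int = 10
    image_size: tuple[int, int] = (256, 256)
    lattice: Lattice = "hexagonal"
    spacing_px: float = 40.0
    jitter_px: float = 0.0
    px_size_nm: float = 10.0
    intensity_noise_sd: float = 0.0
    seed: int = 0
    foreground: int = 200
    background: int = 30

    def __post_init__(self) -> None:
        if self.radius_px < 2:
            raise ValueError("radius_px must be >= 2")
        if self.n_spheres < 1:
            raise ValueError("n_spheres must be >= 1")
        if self.lattice == "hexagonal" and self.spacing_px < 2 * self.radius_px:
            raise ValueError("hexagonal spacing must be >= sphere diameter")
        if self.jitter_px < 0 or self.intensity_noise_sd < 0:
            raise ValueError("jitter and noise must be >= 0")


class PlacementError(RuntimeError):
    """Raised when non-overlapping sphere placement fails."""


def _hex_centers(params: SphereImageParams) -> np.ndarray:
    """First n positions of a hexagonal lattice centered in the frame."""
    s = params.spacing_px
    row_h = s * np.sqrt(3.0) / 2.0
    ncols = int(np.ceil(np.sqrt(params.n_spheres)))
    nrows = int(np.ceil(params.n_spheres / ncols))
    h, w = params.image_size
    width = (ncols - 1) * s + s / 2.0
    height = (nrows - 1) * row_h
    r0 = (h - height) / 2.0
    c0 = (w - width) / 2.0
    centers = []
    for i in range(nrows):
        offset = (s / 2.0) if i % 2 else 0.0
        for j in range(ncols):
            centers.append((r0 + i * row_h, c0 + offset + j * s))
            if len(centers) == params.n_spheres:
                return np.array(centers)
    return np.array(centers)


def _rsa_centers(params: SphereImageParams,
                 rng: np.random.Generator) -> np.ndarray:
    """Random sequential adsorption: no two centers closer than 2r."""
    h, w = params.image_size
    margin = params.radius_px + 1
    min_d2 = (2.0 * params.radius_px) ** 2
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 10_000 * params.n_spheres
    while len(centers) < params.n_spheres:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {params.n_spheres} non-overlapping "
                f"spheres in {params.image_size} after {max_attempts} tries")
        r = rng.uniform(margin, h - 1 - margin)
        c = rng.uniform(margin, w - 1 - margin)
        if all((r - rc) ** 2 + (c - cc) ** 2 >= min_d2 for rc, cc in centers):
            centers.append((r, c))
    return np.array(centers)


def gen_microsphere_image(
    params: SphereImageParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the packing image; returns (uint8 image, (n,2) centers).

    Centers are (row, col) pixel coordinates, 0-based.  Raises
    :class:`PlacementError` when the random arrangement cannot be
    placed, and ``ValueError`` when any sphere would cross the frame.
    """
    from skimage.draw import disk

    rng = np.random.default_rng(params.seed)
    if params.lattice == "hexagonal":
        centers = _hex_centers(params)
    else:
        centers = _rsa_centers(params, rng)
    if params.jitter_px > 0:
        centers = centers + rng.normal(0.0, params.jitter_px,
                                       size=centers.shape)
    h, w = params.image_size
    r = params.radius_px
    if (np.any(centers[:, 0] < r) or np.any(centers[:, 0] > h - 1 - r)
            or np.any(centers[:, 1] < r) or np.any(centers[:, 1] > w - 1 - r)):
        raise ValueError("spheres must lie fully inside the image")
    img = np.full(params.image_size, params.background, dtype=float)
    for rc, cc in centers:
        rr, cc_ = disk((rc, cc), r, shape=params.image_size)
        img[rr, cc_] = params.foreground
    if params.intensity_noise_sd > 0:
        img = img + rng.normal(0.0, params.intensity_noise_sd,
                               size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), centers
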