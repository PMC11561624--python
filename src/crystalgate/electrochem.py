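"""Electrical characterization of crystal bioelectric circuits.

Covers ideal-capacitor impedance, specific capacitance of a disk-shaped
sample, spectrum summaries, harmonic sinusoidal stimuli, empirical
frequency response H(ω) = V_out(ω)/V_in(ω), voltage-distribution
statistics, and Nernstian calibration of a calcium ion-selective
electrode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .signals import TimeSeries

__all__ = [
    "ImpedanceSpectrum",
    "CapacitanceSpectrum",
    "HarmonicStimulus",
    "FrequencyResponse",
    "DistributionStats",
    "CalciumCalibration",
    "capacitor_impedance",
    "specific_capacitance",
    "spectrum_summary",
    "capacitance_summary",
    "harmonic_frequencies",
    "sine_stimulus",
    "frequency_response",
    "response_distribution",
    "calibrate_calcium",
    "potential_from_concentration",
    "pca_from_concentration",
    "concentration_from_pca",
]

#: Nernstian slope for a divalent ion at 25 °C, mV per decade.
NERNST_SLOPE_DIVALENT_MV = 29.58


def _positive_increasing(f: np.ndarray, name: str) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    if not np.all(f > 0):
        raise ValueError(f"{name} must be strictly positive")
    if f.size > 1 and not np.all(np.diff(f) > 0):
        raise ValueError(f"{name} must be strictly increasing")
    return f


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """|Z| (ohms) and phase (degrees) on a strictly increasing Hz grid."""

    frequencies: np.ndarray
    z_magnitude: np.ndarray
    z_phase: np.ndarray
    sample_label: str = ""

    def __post_init__(self) -> None:
        f = _positive_increasing(self.frequencies, "frequencies")
        zm = np.asarray(self.z_magnitude, dtype=float)
        zp = np.asarray(self.z_phase, dtype=float)
        if zm.shape != f.shape or zp.shape != f.shape:
            raise ValueError("frequency/magnitude/phase length mismatch")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "z_magnitude", zm)
        object.__setattr__(self, "z_phase", zp)

    def __len__(self) -> int:
        return int(self.frequencies.size)


@dataclass(frozen=True)
class CapacitanceSpectrum:
    """Capacitance (farads, may be negative) vs frequency (Hz)."""

    frequencies: np.ndarray
    capacitance: np.ndarray
    sample_label: str = ""

    def __post_init__(self) -> None:
        f = _positive_increasing(self.frequencies, "frequencies")
        c = np.asarray(self.capacitance, dtype=float)
        if c.shape != f.shape:
            raise ValueError("frequency/capacitance length mismatch")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "capacitance", c)

    def __len__(self) -> int:
        return int(self.frequencies.size)


@dataclass(frozen=True)
class HarmonicStimulus:
    """A sinusoid A·sin(2π·h·f·t + φ) at the h-th harmonic of f."""

    amplitude: float = 1.0        # volts
    fundamental_f: float = 1.0 / 60.0   # Hz; 1-minute period default
    harmonic: int = 1
    phase: float = 0.0            # radians

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if self.harmonic < 1:
            raise ValueError("harmonic number must be >= 1")
        if not self.fundamental_f > 0:
            raise ValueError("fundamental frequency must be positive")

    @property
    def frequency(self) -> float:
        """Stimulus frequency h·f in Hz."""
        return self.harmonic * self.fundamental_f

    @property
    def omega(self) -> float:
        """Angular frequency 2π·h·f in rad/s."""
        return 2.0 * np.pi * self.frequency


@dataclass(frozen=True)
class FrequencyResponse:
    frequencies: np.ndarray       # Hz, retained bins only
    gain: np.ndarray              # |H(ω)|, dimensionless
    phase: np.ndarray             # degrees in (−180, 180]

    def __post_init__(self) -> None:
        for name in ("frequencies", "gain", "phase"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))


@dataclass(frozen=True)
class DistributionStats:
    median: float
    q1: float
    q3: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ValueError("quartile ordering violated")

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class CalciumCalibration:
    """Linear electrode response E = intercept + slope·log10(c).

    slope is in mV per decade of molar concentration; the default is the
    Nernstian value for a divalent cation at 25 °C.  valid_range bounds
    the molar concentrations the calibration was fitted over.
    """

    slope: float = NERNST_SLOPE_DIVALENT_MV
    intercept: float = 0.0
    valid_range: tuple[float, float] = (3.0e-3, 4.75e-3)

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if not (0 < lo < hi):
            raise ValueError("valid_range must satisfy 0 < lo < hi")
        if self.slope == 0:
            raise ValueError("slope must be nonzero")


def capacitor_impedance(capacitance: float, frequency: float) -> complex:
    """Complex impedance of an ideal capacitor, Z = 1/(j·2πf·C).

    For positive C the phase is −90° and |Z| = 1/(2πfC).
    """
    if not frequency > 0:
        raise ValueError("frequency must be positive")
    if capacitance == 0:
        raise ValueError("capacitance must be nonzero")
    return 1.0 / (1j * 2.0 * np.pi * frequency * capacitance)


def specific_capacitance(
    capacitance: float,
    diameter_cm: float,
    thickness_cm: float,
    expected_per_area: float | None = None,
    expected_per_volume: float | None = None,
) -> dict:
    """Area/volume-normalized capacitance of a circular disk sample.

    Returns area (cm²), volume (cm³), per_area (F/cm²), per_volume
    (F/cm³) and a ``consistent`` flag.  When expected per-area or
    per-volume values are supplied, the flag is False if either
    recomputed value disagrees with its expectation by more than a
    factor of two.
    """
    if not (diameter_cm > 0 and thickness_cm > 0):
        raise ValueError("diameter and thickness must be positive")
    area = np.pi * (diameter_cm / 2.0) ** 2
    volume = area * thickness_cm
    per_area = capacitance / area
    per_volume = capacitance / volume
    consistent = True
    for computed, expected in ((per_area, expected_per_area),
                               (per_volume, expected_per_volume)):
        if expected is not None and expected != 0 and computed != 0:
            ratio = abs(computed / expected)
            if ratio > 2.0 or ratio < 0.5:
                consistent = False
    return {
        "area_cm2": float(area),
        "volume_cm3": float(volume),
        "per_area_f_cm2": float(per_area),
        "per_volume_f_cm3": float(per_volume),
        "consistent": consistent,
    }


def spectrum_summary(spec: ImpedanceSpectrum) -> dict:
    """Arithmetic means of |Z| and phase across the sweep.

    Also reports an unwrapped-phase mean: measured mean phases can fall
    below −180° when the instrument accumulates phase across the sweep,
    so the wrapped per-point mean alone is not comparable with such
    summaries.
    """
    if len(spec) == 0:
        raise ValueError("empty spectrum")
    phase_rad = np.deg2rad(spec.z_phase)
    unwrapped = np.rad2deg(np.unwrap(phase_rad))
    return {
        "mean_z_ohm": float(np.mean(spec.z_magnitude)),
        "mean_phase_deg": float(np.mean(spec.z_phase)),
        "mean_phase_unwrapped_deg": float(np.mean(unwrapped)),
    }


def capacitance_summary(spec: CapacitanceSpectrum) -> float:
    """Low-frequency plateau capacitance, farads.

    Estimated as the mean capacitance over the lowest frequency decade
    of the sweep (f ≤ 10·f_min).
    """
    if len(spec) == 0:
        raise ValueError("empty spectrum")
    f = spec.frequencies
    mask = f <= 10.0 * f[0]
    return float(np.mean(spec.capacitance[mask]))


def harmonic_frequencies(fundamental_f: float, harmonics) -> list[float]:
    """Frequencies h·f for each harmonic number h ≥ 1."""
    hs = list(harmonics)
    if any(int(h) != h or h < 1 for h in hs):
        raise ValueError("harmonic numbers must be integers >= 1")
    return [float(h) * fundamental_f for h in hs]


def sine_stimulus(stim: HarmonicStimulus, timestamps) -> TimeSeries:
    """Evaluate A·sin(2π·h·f·t + φ) on the given time grid."""
    t = np.asarray(timestamps, dtype=float)
    if t.size == 0:
        raise ValueError("timestamps must be non-empty")
    v = stim.amplitude * np.sin(stim.omega * t + stim.phase)
    return TimeSeries(t, v, channel_label=f"sin_h{stim.harmonic}", units="V")


def frequency_response(
    v_in: TimeSeries,
    v_out: TimeSeries,
    power_floor: float = 1e-6,
) -> FrequencyResponse:
    """Empirical transfer function H(ω) = F{v_out}/F{v_in}.

    Both series must share one uniform time grid.  A rectangular window
    is used (intended for records spanning whole periods of the
    stimulus, where it incurs no leakage).  Bins whose input power is
    below ``power_floor`` times the maximum input power are discarded
    rather than divided, to avoid noise blow-up.
    """
    if len(v_in) != len(v_out) or not np.allclose(
            v_in.timestamps, v_out.timestamps):
        raise ValueError("input and output must share one time grid")
    n = len(v_in)
    if n < 8:
        raise ValueError("need at least 8 samples")
    dts = np.diff(v_in.timestamps)
    if not np.allclose(dts, dts[0], rtol=1e-8, atol=0.0):
        raise ValueError("time grid must be uniform")
    if not np.any(v_in.values):
        raise ValueError("input signal is identically zero")
    dt = dts[0]
    fin = np.fft.rfft(v_in.values)
    fout = np.fft.rfft(v_out.values)
    freqs = np.fft.rfftfreq(n, d=dt)
    power = np.abs(fin) ** 2
    keep = power >= power_floor * power.max()
    h = fout[keep] / fin[keep]
    phase = np.angle(h, deg=True)
    # map −180 exactly to +180 to keep phase in (−180, 180]
    phase[phase == -180.0] = 180.0
    return FrequencyResponse(freqs[keep], np.abs(h), phase)


def response_distribution(series: TimeSeries) -> DistributionStats:
    """Median, quartiles (linear interpolation), min and max of a trace."""
    if len(series) < 4:
        raise ValueError("need at least 4 samples")
    v = series.values
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return DistributionStats(
        median=float(med), q1=float(q1), q3=float(q3),
        min=float(v.min()), max=float(v.max()),
    )


def calibrate_calcium(
    voltage_mv: float, calib: CalciumCalibration | None = None
) -> float:
    """Molar Ca²⁺ concentration from electrode potential (mV).

    Inverts E = intercept + slope·log10(c).  Emits a warning when the
    result falls outside the calibration's valid range.
    """
    calib = calib or CalciumCalibration()
    c = 10.0 ** ((voltage_mv - calib.intercept) / calib.slope)
    lo, hi = calib.valid_range
    if not (lo <= c <= hi):
        warnings.warn(
            f"concentration {c:.4g} M outside calibration range "
            f"[{lo:g}, {hi:g}] M", stacklevel=2)
    return float(c)


def potential_from_concentration(
    concentration_m: float, calib: CalciumCalibration | None = None
) -> float:
    """Electrode potential (mV) for a molar Ca²⁺ concentration."""
    calib = calib or CalciumCalibration()
    if not concentration_m > 0:
        raise ValueError("concentration must be positive")
    return float(calib.intercept + calib.slope * np.log10(concentration_m))


def pca_from_concentration(c: float) -> float:
    """pCa = −log10 of the molar free-calcium concentration."""
    if not c > 0:
        raise ValueError("concentration must be positive")
    return float(-np.log10(c))


def concentration_from_pca(pca: float) -> float:
    """Inverse of :func:`pca_from_concentration`."""
    return float(10.0 ** (-pca))
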