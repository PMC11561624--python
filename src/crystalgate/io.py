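"""File-format layer shared by all modules.

CSV (RFC 4180, UTF-8, '.' decimal separator) for signals, traces and
spectra; JSON for reports and circuit specs; PNG/TIFF for images.
Numeric JSON output is serialized with 9 significant digits so repeated
runs are byte-identical across platforms.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .electrochem import CapacitanceSpectrum, ImpedanceSpectrum
from .gates import BooleanTrace
from .signals import TimeSeries

__all__ = [
    "read_timeseries", "write_timeseries",
    "read_impedance", "write_impedance",
    "read_capacitance", "write_capacitance",
    "read_boolean_trace", "write_boolean_trace",
    "write_json", "read_image", "write_image",
]


def write_timeseries(path, series: TimeSeries) -> None:
    pd.DataFrame({
        "time_s": series.timestamps,
        "value": series.values,
        "channel": series.channel_label,
    }).to_csv(path, index=False)


def read_timeseries(path, channel: str | None = None) -> TimeSeries:
    """Read a `time_s,value,channel` CSV; filter by channel if given."""
    df = pd.read_csv(path)
    if channel is not None and "channel" in df.columns:
        df = df[df["channel"] == channel]
        if df.empty:
            raise ValueError(f"no rows for channel {channel!r} in {path}")
    label = ""
    if "channel" in df.columns and df["channel"].nunique() == 1:
        label = str(df["channel"].iloc[0])
    return TimeSeries(df["time_s"].to_numpy(), df["value"].to_numpy(),
                      channel_label=label)


def write_impedance(path, spec: ImpedanceSpectrum) -> None:
    pd.DataFrame({
        "freq_hz": spec.frequencies,
        "z_mag_ohm": spec.z_magnitude,
        "z_phase_deg": spec.z_phase,
    }).to_csv(path, index=False)


def read_impedance(path, sample_label: str = "") -> ImpedanceSpectrum:
    df = pd.read_csv(path)
    return ImpedanceSpectrum(
        df["freq_hz"].to_numpy(), df["z_mag_ohm"].to_numpy(),
        df["z_phase_deg"].to_numpy(), sample_label=sample_label)


def write_capacitance(path, spec: CapacitanceSpectrum) -> None:
    pd.DataFrame({
        "freq_hz": spec.frequencies,
        "cap_f": spec.capacitance,
    }).to_csv(path, index=False)


def read_capacitance(path, sample_label: str = "") -> CapacitanceSpectrum:
    df = pd.read_csv(path)
    return CapacitanceSpectrum(
        df["freq_hz"].to_numpy(), df["cap_f"].to_numpy(),
        sample_label=sample_label)


def write_boolean_trace(path, trace: BooleanTrace) -> None:
    pd.DataFrame({
        "time_s": trace.timestamps,
        "bit": trace.bits.astype(int),
    }).to_csv(path, index=False)


def read_boolean_trace(path) -> BooleanTrace:
    df = pd.read_csv(path)
    return BooleanTrace(df["time_s"].to_numpy(), df["bit"].to_numpy())


def _round_floats(obj, sig: int = 9):
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return float(f"{x:.{sig}g}") if np.isfinite(x) else x
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    return obj


def write_json(path, obj: dict, sig: int = 9) -> None:
    """Write a JSON report with floats at 9 significant digits."""
    Path(path).write_text(
        json.dumps(_round_floats(obj, sig), indent=2, sort_keys=True) + "\n")


def read_image(path) -> np.ndarray:
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:          # RGB(A) -> luminance
        img = np.asarray(img)[..., :3].mean(axis=-1).astype(np.uint8)
    return np.asarray(img)


def write_image(path, img: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, img)
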