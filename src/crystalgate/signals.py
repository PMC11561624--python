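"""Core signal containers shared by every analysis module.

A :class:`TimeSeries` is a timestamped scalar channel (pCa, pH or volts);
a :class:`BinarySequence` is its binarized form together with the mean
sampling interval, which is what the entropy-rate statistic needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries", "BinarySequence"]


@dataclass(frozen=True)
class TimeSeries:
    """A single scalar channel sampled at strictly increasing times.

    Parameters
    ----------
    timestamps : array-like of float
        Sample times in seconds, strictly increasing.
    values : array-like of float
        Channel values, same length as ``timestamps``.
    channel_label : str
        Free-text channel name, e.g. ``"pCa"``, ``"pH"``, ``"voltage"``.
    units : str
        Physical units of ``values``.
    """

    timestamps: np.ndarray
    values: np.ndarray
    channel_label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1:
            raise ValueError("timestamps and values must be 1-D")
        if t.size != v.size:
            raise ValueError(
                f"length mismatch: {t.size} timestamps vs {v.size} values"
            )
        if t.size == 0:
            raise ValueError("empty time series")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def mean_dt(self) -> float:
        """Arithmetic mean of consecutive timestamp differences (s)."""
        if len(self) < 2:
            raise ValueError("mean_dt needs at least two samples")
        return float(np.mean(np.diff(self.timestamps)))

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass(frozen=True)
class BinarySequence:
    """An ordered 0/1 symbol sequence with its mean sampling interval."""

    bits: np.ndarray
    mean_dt: float = 1.0
    threshold_used: float = float("nan")
    source_label: str = ""

    def __post_init__(self) -> None:
        b = np.asarray(self.bits, dtype=np.uint8)
        if b.ndim != 1:
            raise ValueError("bits must be 1-D")
        if b.size == 0:
            raise ValueError("empty binary sequence")
        if not np.all((b == 0) | (b == 1)):
            raise ValueError("bits must be 0 or 1")
        if not self.mean_dt > 0:
            raise ValueError("mean_dt must be positive")
        object.__setattr__(self, "bits", b)

    def __len__(self) -> int:
        return int(self.bits.size)

    @property
    def p_ones(self) -> float:
        """Proportion of 1 symbols."""
        return float(np.mean(self.bits))

    def to_string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    @classmethod
    def from_string(cls, s: str, mean_dt: float = 1.0, **kw) -> "BinarySequence":
        if not s or set(s) - {"0", "1"}:
            raise ValueError("string must be non-empty and contain only 0/1")
        return cls(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"),
                   mean_dt=mean_dt, **kw)
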