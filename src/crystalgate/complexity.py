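"""Complexity, entropy and chaos statistics for pCa/pH/voltage signals.

The statistics quantify how algorithmically compressible and how
predictable a binarized physicochemical signal is:

* ``lz_pattern_count`` — number of phrases c(x) in the Lempel–Ziv 1976
  exhaustive-history parsing (Kaspar–Schuster algorithm) of a binary
  sequence.
* ``kolmogorov_complexity`` — normalized LZ76 phrase count, an
  approximation of Kolmogorov complexity per symbol.
* ``shannon_entropy`` — binary entropy of the proportion of 1s (bits).
* ``entropy_rate`` — Shannon entropy divided by the mean sampling
  interval (bits/s); 1.000 bits/s is the maximum for a balanced
  sequence at 1 s sampling.
* ``chaos_trace`` — absolute second-order finite difference of the raw
  signal, an unpredictability indicator; its standard deviation
  (``dispersion``) summarizes the spread of the chaotic fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

from .signals import BinarySequence, TimeSeries

__all__ = [
    "ComplexityReport",
    "binarize",
    "lz_pattern_count",
    "kolmogorov_complexity",
    "shannon_entropy",
    "entropy_rate",
    "chaos_trace",
    "dispersion",
    "complexity_report",
]

BinarizeMethod = Literal["median", "mean", "fixed"]
KNormalization = Literal["phrase_log", "sequence_log"]


@dataclass(frozen=True)
class ComplexityReport:
    """Bundle of the five complexity statistics for one channel."""

    lz_pattern_count: int
    kolmogorov_bits: float          # bits per symbol
    shannon_entropy: float          # bits
    entropy_rate: float             # bits per second
    chaos_sd: float                 # channel units
    n: int
    channel_label: str = ""
    binarize_method: str = "median"
    threshold_used: float = float("nan")
    normalization: str = "phrase_log"

    def to_dict(self) -> dict:
        return asdict(self)


def binarize(
    series: TimeSeries,
    method: BinarizeMethod = "median",
    threshold: float | None = None,
) -> BinarySequence:
    """Threshold a time series into a 0/1 sequence.

    A symbol is 1 iff the value strictly exceeds the threshold; ties map
    to 0.  ``method="median"`` (default) and ``"mean"`` derive the
    threshold from the data; ``"fixed"`` requires ``threshold``.
    """
    v = series.values
    if method == "median":
        theta = float(np.median(v))
    elif method == "mean":
        theta = float(np.mean(v))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed binarization requires a threshold")
        theta = float(threshold)
    else:
        raise ValueError(f"unknown binarization method: {method!r}")
    mean_dt = series.mean_dt if len(series) > 1 else 1.0
    return BinarySequence(
        (v > theta).astype(np.uint8),
        mean_dt=mean_dt,
        threshold_used=theta,
        source_label=series.channel_label,
    )


def lz_pattern_count(seq: BinarySequence | str) -> int:
    """Number of phrases in the LZ76 exhaustive-history parsing.

    Scans left to right; a new phrase starts whenever the current word
    cannot be reproduced from the preceding history (copying with
    overlap allowed).  The final, possibly incomplete phrase counts.
    """
    bits = seq.bits if isinstance(seq, BinarySequence) else \
        BinarySequence.from_string(seq).bits
    n = bits.size
    if n == 1:
        return 1
    # Kaspar–Schuster pointer scan: i is the candidate copy origin, k the
    # current match length, l the start of the phrase being parsed.
    c = 1
    l, i, k, k_max = 1, 0, 1, 1
    while True:
        if bits[i + k - 1] == bits[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


def kolmogorov_complexity(
    seq: BinarySequence,
    normalization: KNormalization = "phrase_log",
) -> float:
    """LZ76-based approximation of Kolmogorov complexity per symbol.

    ``phrase_log`` (default): K = c(x)·(log2 c(x) + 1)/n.
    ``sequence_log``: K = c(x)·log2(n)/n, the classical asymptotic
    normalization.  Both tend to 1 for incompressible sequences and to 0
    for trivially regular ones.
    """
    n = len(seq)
    if n < 2:
        raise ValueError("kolmogorov_complexity needs at least 2 symbols")
    c = lz_pattern_count(seq)
    if normalization == "phrase_log":
        return c * (np.log2(c) + 1.0) / n
    if normalization == "sequence_log":
        return c * np.log2(n) / n
    raise ValueError(f"unknown normalization: {normalization!r}")


def shannon_entropy(seq: BinarySequence) -> float:
    """Binary Shannon entropy H = −p log2 p − (1−p) log2(1−p), bits."""
    p = seq.p_ones
    if p in (0.0, 1.0):
        return 0.0
    return float(-p * np.log2(p) - (1.0 - p) * np.log2(1.0 - p))


def entropy_rate(seq: BinarySequence) -> float:
    """Shannon entropy divided by the mean time step (bits/s)."""
    if not seq.mean_dt > 0:
        raise ValueError("mean_dt must be positive")
    return shannon_entropy(seq) / seq.mean_dt


def chaos_trace(series: TimeSeries) -> TimeSeries:
    """Absolute second-order difference |X(t_{k+2}) − 2X(t_{k+1}) + X(t_k)|.

    Annihilates affine signals; the output has length n−2 and keeps the
    timestamp of the first element of each triple.
    """
    if len(series) < 3:
        raise ValueError("chaos trace needs at least 3 samples")
    v = series.values
    out = np.abs(v[2:] - 2.0 * v[1:-1] + v[:-2])
    return TimeSeries(
        series.timestamps[:-2], out,
        channel_label=f"|d2 {series.channel_label}|".strip(),
        units=series.units,
    )


def dispersion(series: TimeSeries) -> float:
    """Sample standard deviation (n−1 denominator) of a series."""
    if len(series) < 2:
        raise ValueError("dispersion needs at least 2 samples")
    return float(np.std(series.values, ddof=1))


def complexity_report(
    series: TimeSeries,
    binarize_method: BinarizeMethod = "median",
    threshold: float | None = None,
    normalization: KNormalization = "phrase_log",
) -> ComplexityReport:
    """Compute all five statistics consistently from one time series."""
    if len(series) < 3:
        raise ValueError("complexity_report needs at least 3 samples")
    seq = binarize(series, method=binarize_method, threshold=threshold)
    trace = chaos_trace(series)
    return ComplexityReport(
        lz_pattern_count=lz_pattern_count(seq),
        kolmogorov_bits=kolmogorov_complexity(seq, normalization=normalization),
        shannon_entropy=shannon_entropy(seq),
        entropy_rate=entropy_rate(seq),
        chaos_sd=dispersion(trace) if len(trace) >= 2 else 0.0,
        n=len(seq),
        channel_label=series.channel_label,
        binarize_method=binarize_method,
        threshold_used=seq.threshold_used,
        normalization=normalization,
    )
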