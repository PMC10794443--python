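"""Neuronal avalanches and their size/duration distributions.

An avalanche is the cascade of spikes between two consecutive firings of
the offline drive: the drive fires exactly when the network has fallen
silent, so each forced spike starts a new avalanche and the interval up
to the next forced spike is one avalanche.  Size is the total spike
count in the interval, duration its length in steps (ms).  At the
critical point both distributions are power-law-like with an
exponential cutoff that grows with network size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import SpikeRaster

__all__ = ["Avalanche", "CCDFCurve", "extract_avalanches", "ccdf"]


@dataclass(frozen=True)
class Avalanche:
    start: int
    duration: int
    size: int


@dataclass
class CCDFCurve:
    """Empirical complementary CDF: survival[i] = P(X >= values[i])."""

    values: np.ndarray
    survival: np.ndarray


def extract_avalanches(raster: SpikeRaster) -> list[Avalanche]:
    """Segment a raster into avalanches delimited by the drive times.

    One avalanche per maximal interval between consecutive forced spikes;
    the trailing interval, cut off by the end of the recording, is
    discarded (its true size and duration are unknown).
    """
    drives = np.sort(np.asarray(raster.drive_times, dtype=np.int64))
    if drives.size < 2:
        return []
    A = raster.activity()
    csum = np.concatenate([[0], np.cumsum(A)])
    out: list[Avalanche] = []
    for s, e in zip(drives[:-1], drives[1:]):
        out.append(Avalanche(start=int(s), duration=int(e - s),
                             size=int(csum[e] - csum[s])))
    return out


def ccdf(samples) -> CCDFCurve:
    """Empirical survival function P(X >= x) at each distinct sample value."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("ccdf of an empty sample")
    values, counts = np.unique(samples, return_counts=True)
    # P(X >= v_i) = (count of samples >= v_i) / n
    tail = np.cumsum(counts[::-1])[::-1]
    return CCDFCurve(values=values, survival=tail / samples.size)
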