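"""Spike-train containers and time binning."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import SpikeRaster

__all__ = ["SpikeTrainSet", "raster_to_trains", "bin_spike_counts"]


@dataclass
class SpikeTrainSet:
    """Per-neuron sorted spike times (ms) on a common observation window."""

    trains: list[np.ndarray]
    t_start: float
    t_end: float
    neuron_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("empty observation window")
        self.trains = [np.asarray(tr, dtype=float) for tr in self.trains]
        for tr in self.trains:
            if tr.size and (np.any(np.diff(tr) < 0)
                            or tr[0] < self.t_start or tr[-1] > self.t_end):
                raise ValueError("spike times must be sorted and inside the window")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(len(self.trains))
        else:
            self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.trains)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def subset(self, indices) -> "SpikeTrainSet":
        indices = np.asarray(indices, dtype=np.int64)
        return SpikeTrainSet(trains=[self.trains[i] for i in indices],
                             t_start=self.t_start, t_end=self.t_end,
                             neuron_ids=self.neuron_ids[indices])


def raster_to_trains(raster: SpikeRaster) -> SpikeTrainSet:
    """View a spike raster as a set of per-neuron spike-time lists."""
    return SpikeTrainSet(trains=raster.spike_times(), t_start=0.0,
                         t_end=float(raster.T))


def bin_spike_counts(trains: SpikeTrainSet, bin_ms: float) -> np.ndarray:
    """Spike counts per neuron per half-open bin [k*bin_ms, (k+1)*bin_ms).

    Bins tile the window from ``t_start``; a trailing partial bin is
    dropped.  Returns an (n_neurons, n_bins) integer array.
    """
    if bin_ms < 1:
        raise ValueError("bin_ms must be >= 1")
    n_bins = int(np.floor(trains.duration / bin_ms))
    if n_bins == 0:
        raise ValueError("window shorter than one bin")
    counts = np.zeros((len(trains), n_bins), dtype=np.int64)
    for i, tr in enumerate(trains.trains):
        if tr.size == 0:
            continue
        k = np.floor((tr - trains.t_start) / bin_ms).astype(np.int64)
        k = k[k < n_bins]
        counts[i] = np.bincount(k, minlength=n_bins)
    return counts
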