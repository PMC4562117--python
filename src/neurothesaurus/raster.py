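"""Spike rasters and binary population words.

A recording consists of repeated presentations of one identical stimulus
clip. Spikes are discretized into binary population *words*: for each
repeat and time bin, a length-``N`` 0/1 vector saying which neurons fired
at least once in that bin. The time-bin index doubles as the stimulus
identity, since every repeat shows the same clip.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrainSet",
    "BinnedRaster",
    "load_spike_times",
    "bin_spikes",
    "split_repeats",
    "select_neuron_groups",
    "population_rate",
]


@dataclass(frozen=True)
class SpikeTrainSet:
    """Raw spike times from repeated presentations of one stimulus clip.

    Parameters
    ----------
    events : ndarray, shape (n_events, 3)
        Columns ``(repeat_id, neuron_id, time_s)``. Ids are integral,
        times in seconds.
    n_repeats, n_neurons : int
        Declared dimensions; every event must respect them.
    duration : float
        Clip length in seconds; all spike times lie in ``[0, duration)``.
    """

    events: np.ndarray
    n_repeats: int
    n_neurons: int
    duration: float

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=float)
        if ev.size == 0:
            ev = ev.reshape(0, 3)
        if ev.ndim != 2 or ev.shape[1] != 3:
            raise ValueError("events must have shape (n_events, 3)")
        object.__setattr__(self, "events", ev)
        if self.n_repeats < 1 or self.n_neurons < 1:
            raise ValueError("n_repeats and n_neurons must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if ev.shape[0]:
            rep, neu, t = ev[:, 0], ev[:, 1], ev[:, 2]
            if np.any((rep < 0) | (rep >= self.n_repeats)):
                raise ValueError("repeat_id out of range [0, n_repeats)")
            if np.any((neu < 0) | (neu >= self.n_neurons)):
                raise ValueError("neuron_id out of range [0, n_neurons)")
            if np.any((t < 0) | (t >= self.duration)):
                raise ValueError("spike time out of range [0, duration)")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]


@dataclass(frozen=True)
class BinnedRaster:
    """Binary tensor of population words, indexed (repeat, time_bin, neuron).

    ``words[rep, t, i]`` is 1 iff neuron ``i`` fired at least once in bin
    ``t`` on repeat ``rep``. The time-bin index ``t`` identifies the
    stimulus ``s(t)``.
    """

    words: np.ndarray
    bin_width: float
    neuron_ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        w = np.asarray(self.words)
        if w.ndim != 3:
            raise ValueError("words must be a (repeat, time_bin, neuron) array")
        if w.size and not np.isin(w, (0, 1)).all():
            raise ValueError("words entries must be 0 or 1")
        object.__setattr__(self, "words", w.astype(np.uint8))
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.neuron_ids is not None:
            ids = np.asarray(self.neuron_ids, dtype=int)
            if ids.shape != (w.shape[2],):
                raise ValueError("neuron_ids length must equal n_neurons")
            object.__setattr__(self, "neuron_ids", ids)

    @property
    def n_repeats(self) -> int:
        return self.words.shape[0]

    @property
    def n_bins(self) -> int:
        return self.words.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.words.shape[2]

    def subset_neurons(self, indices) -> "BinnedRaster":
        """Restrict to a neuron group (keeps original ids for bookkeeping)."""
        idx = np.asarray(list(indices), dtype=int)
        ids = self.neuron_ids if self.neuron_ids is not None else np.arange(self.n_neurons)
        return BinnedRaster(self.words[:, :, idx], self.bin_width, neuron_ids=ids[idx])

    def save_npz(self, path) -> None:
        np.savez(path, words=self.words, bin_width=np.float64(self.bin_width),
                 neuron_ids=(self.neuron_ids if self.neuron_ids is not None
                             else np.arange(self.n_neurons)))

    @classmethod
    def load_npz(cls, path) -> "BinnedRaster":
        with np.load(path) as f:
            return cls(f["words"], float(f["bin_width"]),
                       neuron_ids=f["neuron_ids"] if "neuron_ids" in f else None)


def load_spike_times(path, n_repeats: int, n_neurons: int,
                     duration: float) -> SpikeTrainSet:
    """Read a CSV spike list (header ``repeat,neuron,time``) and validate it.

    Raises
    ------
    ValueError
        On a malformed row (naming its line number) or an out-of-range
        repeat/neuron id or spike time.
    """
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (lineno == 1 and not row[0].strip().lstrip("-").replace(".", "").isdigit()):
                continue  # header or blank line
            if len(row) != 3:
                raise ValueError(f"line {lineno}: expected 3 fields, got {len(row)}")
            try:
                rep, neu, t = int(row[0]), int(row[1]), float(row[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: cannot parse row {row!r}") from exc
            rows.append((rep, neu, t))
    events = np.array(rows, dtype=float).reshape(-1, 3)
    return SpikeTrainSet(events, n_repeats=n_repeats, n_neurons=n_neurons,
                         duration=duration)


def bin_spikes(spikes: SpikeTrainSet, bin_width: float) -> BinnedRaster:
    """Discretize spike times into binary words.

    Bin edges are half-open ``[t*dt, (t+1)*dt)``; a trailing partial bin is
    dropped, so ``T = floor(duration / bin_width)``. Multiple spikes from
    one neuron in one bin map to a single 1 (words are binary, not counts).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if bin_width > spikes.duration:
        raise ValueError("bin_width exceeds recording duration")
    n_bins = int(np.floor(spikes.duration / bin_width + 1e-12))
    words = np.zeros((spikes.n_repeats, n_bins, spikes.n_neurons), dtype=np.uint8)
    if spikes.n_events:
        rep = spikes.events[:, 0].astype(int)
        neu = spikes.events[:, 1].astype(int)
        t = np.floor(spikes.events[:, 2] / bin_width).astype(int)
        keep = t < n_bins
        words[rep[keep], t[keep], neu[keep]] = 1
    return BinnedRaster(words, bin_width)


def split_repeats(raster: BinnedRaster, train_fraction: float,
                  seed: int) -> tuple[BinnedRaster, BinnedRaster]:
    """Randomly partition repeats into disjoint train/test rasters.

    The time axis is untouched: both halves see every stimulus, with
    different repeats. The split is purely random over repeats,
    deterministic under ``seed``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    R = raster.n_repeats
    if R < 2:
        raise ValueError("need at least 2 repeats to split")
    n_train = int(round(train_fraction * R))
    if n_train == 0 or n_train == R:
        raise ValueError("train_fraction leaves one side empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(R)
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    return (BinnedRaster(raster.words[tr], raster.bin_width, raster.neuron_ids),
            BinnedRaster(raster.words[te], raster.bin_width, raster.neuron_ids))


def select_neuron_groups(raster: BinnedRaster, group_size: int,
                         n_groups: int, seed: int) -> list[np.ndarray]:
    """Draw random neuron groups (without replacement within each group)."""
    N = raster.n_neurons
    if group_size > N:
        raise ValueError(f"group_size {group_size} exceeds population size {N}")
    rng = np.random.default_rng(seed)
    return [np.sort(rng.choice(N, size=group_size, replace=False))
            for _ in range(n_groups)]


def population_rate(raster: BinnedRaster) -> np.ndarray:
    """Mean spikes per neuron per bin at each time bin (length T)."""
    return raster.words.mean(axis=(0, 2))
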