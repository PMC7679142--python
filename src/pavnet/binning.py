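"""Event binning, trial-aligned PETHs and labeled decoding datasets.

Conventions: half-open [start, end) bins, 0-based bin indices, all times in
seconds from session start.  Analyses use 500 ms bins for PETHs and 1 s bins
for decoding and transfer entropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .synth import EventTrain, SessionTimeline, CS_DURATION

logger = logging.getLogger(__name__)

PETH_WINDOW = (-8.0, 18.0)  # s relative to CS onset


@dataclass
class BinnedMatrix:
    """Neurons x time-bins event counts with per-neuron metadata."""

    counts: np.ndarray  # (n_neurons, n_bins) nonnegative ints
    bin_width: float
    t0: float
    neuron_ids: list[str]
    regions: list[str]
    stages: list[str] = field(default_factory=list)
    treatments: list[str] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def t_end(self) -> float:
        return self.t0 + self.n_bins * self.bin_width

    def bin_of(self, t: float) -> int:
        return int(np.floor((t - self.t0) / self.bin_width))

    def region_index(self, region: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.regions) == np.asarray(region))


@dataclass
class PETH:
    """Trial-aligned z-scored responses: (trials, neurons, relative bins).

    z-scoring is per neuron within the recording stage; masked (trial, bin)
    entries are NaN in ``z`` and flagged in ``mask`` so they cannot silently
    enter downstream means.
    """

    z: np.ndarray
    mask: np.ndarray  # (trials, bins) True where masked
    bin_width: float
    window: tuple[float, float] = PETH_WINDOW
    cs_types: list[str] = field(default_factory=list)
    smoothing_degree: float = 5.0

    @property
    def rel_times(self) -> np.ndarray:
        lo, _ = self.window
        return lo + (np.arange(self.z.shape[2]) + 0.5) * self.bin_width


@dataclass
class LabeledDataset:
    """Feature matrix (time bins x neurons) with per-bin class labels.

    Tasks: "CS" (pre-CS vs CS bins), "US" (pre-CS vs post-US bins),
    "CS3" (pre-CS vs R-CS vs F-CS bins).
    """

    X: np.ndarray
    y: np.ndarray
    task: str
    neuron_ids: list[str] = field(default_factory=list)
    regions: list[str] = field(default_factory=list)
    stage: str = ""
    empty: bool = False

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.X.shape[1]

    def classes(self) -> np.ndarray:
        return np.unique(self.y)


def bin_events(
    trains: list[EventTrain] | EventTrain,
    bin_width: float,
    t0: float,
    t_end: float,
) -> BinnedMatrix:
    """Bin event trains into counts on the half-open grid
    [t0 + b*w, t0 + (b+1)*w); boundary events belong to the later bin.
    Out-of-range events are dropped (count logged)."""
    if t_end <= t0:
        raise ValueError("t_end must be > t0")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if isinstance(trains, EventTrain):
        trains = [trains]
    n_bins = int(np.ceil((t_end - t0) / bin_width - 1e-9))
    edges = t0 + np.arange(n_bins + 1) * bin_width
    counts = np.zeros((len(trains), n_bins), dtype=np.int64)
    dropped = 0
    for i, tr in enumerate(trains):
        t = tr.event_times
        in_range = (t >= t0) & (t < edges[-1])
        dropped += int(len(t) - in_range.sum())
        idx = np.floor((t[in_range] - t0) / bin_width).astype(int)
        np.add.at(counts[i], idx, 1)
    if dropped:
        logger.info("bin_events: dropped %d out-of-range events", dropped)
    return BinnedMatrix(
        counts=counts,
        bin_width=bin_width,
        t0=t0,
        neuron_ids=[tr.neuron_id for tr in trains],
        regions=[tr.region for tr in trains],
        stages=[tr.stage for tr in trains],
        treatments=[tr.treatment for tr in trains],
    )


def _zscore_rows(counts: np.ndarray) -> np.ndarray:
    """z-score each neuron over the stage; zero-variance rows become zeros."""
    mu = counts.mean(axis=1, keepdims=True)
    sd = counts.std(axis=1, keepdims=True)
    z = np.zeros_like(counts, dtype=float)
    nz = sd[:, 0] > 0
    z[nz] = (counts[nz] - mu[nz]) / sd[nz]
    return z

def make_peth(
    binned: BinnedMatrix,
    timeline: SessionTimeline,
    smoothing_degree: float = 5.0,
    shock_mask: bool = True,
    blackout_channels: list[tuple[int, int]] | None = None,
    smooth: bool = True,
) -> PETH:
    """Trial-aligned PETH over the [-8, 18] s window around each CS onset.

    Counts (500 ms bins) are z-scored per neuron within the stage, the window
    extracted per trial, Gaussian-smoothed along time (``smoothing_degree`` =
    kernel SD in bins, truncated at 4 SD; 5 for cortical, 8 for amygdala
    data), shock-artifact bins masked to NaN, and any (trial, bin) from a
    blacked-out channel replaced by the population mean of that bin.

    Trials whose pre-window starts before the session are skipped with a
    warning.
    """
    if abs(binned.bin_width - 0.5) > 1e-9:
        raise ValueError("make_peth expects 500 ms bins")
    w = binned.bin_width
    lo, hi = PETH_WINDOW
    n_rel = int(round((hi - lo) / w))
    z_full = _zscore_rows(binned.counts.astype(float))

    trials = []
    cs_types = []
    for onset, typ in timeline.cs_trials:
        b_on = binned.bin_of(onset)
        b_lo = b_on + int(round(lo / w))
        b_hi = b_lo + n_rel
        if b_lo < 0 or b_hi > binned.n_bins:
            logger.warning("make_peth: trial at %.1f s skipped (window out of range)", onset)
            continue
        trials.append(z_full[:, b_lo:b_hi].copy())
        cs_types.append(typ)
    if not trials:
        return PETH(
            z=np.zeros((0, binned.n_neurons, n_rel)),
            mask=np.zeros((0, n_rel), dtype=bool),
            bin_width=w,
            smoothing_degree=smoothing_degree,
        )
    z = np.stack(trials)  # (trials, neurons, rel bins)
    mask = np.zeros((z.shape[0], n_rel), dtype=bool)

    if shock_mask:
        # shock artifact: bins containing an F-US delivery (1 s shock)
        kept = [on for on, _ in timeline.cs_trials if binned.bin_of(on) + int(round(lo / w)) >= 0
                and binned.bin_of(on) + int(round(lo / w)) + n_rel <= binned.n_bins]
        for ti, onset in enumerate(kept):
            for t_us, us_type in timeline.us_events:
                if us_type != "F":
                    continue
                rel = t_us - onset
                if lo <= rel < hi:
                    b0 = int(round((rel - lo) / w))
                    mask[ti, b0 : min(b0 + int(round(1.0 / w)), n_rel)] = True
    z[np.broadcast_to(mask[:, None, :], z.shape)] = np.nan

    if blackout_channels:
        for trial_i, neuron_i in blackout_channels:
            if 0 <= trial_i < z.shape[0] and 0 <= neuron_i < z.shape[1]:
                others = np.delete(z[trial_i], neuron_i, axis=0)
                z[trial_i, neuron_i] = np.nanmean(others, axis=0)

    if smooth and smoothing_degree > 0:
        # smooth only along time, NaN-aware (masked bins stay NaN)
        nanmask = np.isnan(z)
        filled = np.where(nanmask, 0.0, z)
        sm = gaussian_filter1d(filled, sigma=smoothing_degree, axis=2, truncate=4.0, mode="nearest")
        norm = gaussian_filter1d((~nanmask).astype(float), sigma=smoothing_degree, axis=2, truncate=4.0, mode="nearest")
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(nanmask, np.nan, sm / np.maximum(norm, 1e-12))

    return PETH(z=z, mask=mask, bin_width=w, cs_types=cs_types, smoothing_degree=smoothing_degree)


def build_labels(
    binned: BinnedMatrix,
    timeline: SessionTimeline,
    task: str,
    pre_window_bins: int = 10,
    post_us_bins: int = 8,
) -> LabeledDataset:
    """Assemble the bins x neurons feature matrix and class vector.

    CS task: class 0 = ``pre_window_bins`` immediately before each CS onset,
    class 1 = the 10 CS bins.  US task: class 0 as above, class 1 =
    ``post_us_bins`` after US offset.  CS3 task: class 0 = pre-CS bins of
    both CS types, class 1 = R-CS bins, class 2 = F-CS bins.

    Pre-windows that would overlap the previous trial's CS window are
    truncated (logged).  Bins are 1 s.
    """
    if task not in ("CS", "US", "CS3"):
        raise ValueError(f"unknown task {task!r}")
    if abs(binned.bin_width - 1.0) > 1e-9:
        raise ValueError("build_labels expects 1 s bins")
    if not timeline.cs_trials:
        return LabeledDataset(
            X=np.zeros((0, binned.n_neurons)),
            y=np.zeros(0, dtype=int),
            task=task,
            neuron_ids=binned.neuron_ids,
            regions=binned.regions,
            empty=True,
        )

    n_cs_bins = int(round(timeline.cs_duration))
    rows: list[np.ndarray] = []
    labels: list[int] = []
    prev_end_bin = 0
    us_by_time = sorted(timeline.us_events)

    for onset, typ in sorted(timeline.cs_trials):
        b_on = binned.bin_of(onset)
        b_pre0 = max(b_on - pre_window_bins, prev_end_bin, 0)
        if b_pre0 > b_on - pre_window_bins:
            logger.info("build_labels: pre-window truncated at trial onset %.1f s", onset)
        pre_bins = np.arange(b_pre0, b_on)
        cs_bins = np.arange(b_on, min(b_on + n_cs_bins, binned.n_bins))

        if task == "CS":
            sel0, sel1 = pre_bins, cs_bins
            cls1 = 1
        elif task == "CS3":
            sel0, sel1 = pre_bins, cs_bins
            cls1 = 1 if typ == "R" else 2
        else:  # US
            us_after = [t for t, ut in us_by_time if ut == typ and onset <= t <= onset + timeline.cs_duration + 2]
            if not us_after:
                prev_end_bin = b_on + n_cs_bins
                continue
            t_us = us_after[0]
            b_us_off = binned.bin_of(t_us) + 1  # US lasts ~1 s
            sel0 = pre_bins
            sel1 = np.arange(b_us_off, min(b_us_off + post_us_bins, binned.n_bins))
            cls1 = 1

        for b in sel0:
            rows.append(binned.counts[:, b])
            labels.append(0)
        for b in sel1:
            rows.append(binned.counts[:, b])
            labels.append(cls1)
        prev_end_bin = int(max(sel1[-1] + 1 if len(sel1) else b_on + n_cs_bins, b_on + n_cs_bins))

    X = np.array(rows, dtype=float) if rows else np.zeros((0, binned.n_neurons))
    return LabeledDataset(
        X=X,
        y=np.asarray(labels, dtype=int),
        task=task,
        neuron_ids=binned.neuron_ids,
        regions=binned.regions,
        stage=binned.stages[0] if binned.stages else "",
        empty=len(rows) == 0,
    )
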