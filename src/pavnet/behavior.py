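"""Freezing scoring from motion traces and correct/incorrect classification
of behavioral episodes and CS trials.

A behavioral episode is "correct" when its onset falls inside the 10 s window
of the matching CS (port visits for the reward CS, freezing onsets for the
fear CS); anything outside the matching CS — including before CS onset — is
"incorrect".  A CS trial is correct iff at least one correct episode of the
matching kind occurs within its window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synth import MotionTrace, SessionTimeline

logger = logging.getLogger(__name__)

MATCHING_KIND = {"R": "port_visit", "F": "freezing_onset"}


@dataclass
class Episode:
    onset: float
    kind: str  # "port_visit" | "freezing_onset"
    duration: float = 0.0  # s; freezing only
    correctness: str = "unassigned"  # "correct" | "incorrect" | "unassigned"


def score_freezing(
    motion: MotionTrace,
    threshold: float,
    min_dur: float = 1.0,
    window: float = 1.0,
) -> list[Episode]:
    """Detect freezing bouts: maximal runs where the sliding-window mean of
    the motion index stays below ``threshold`` for at least ``min_dur``.

    A window starting at frame t covers frames [t, t + W).  A run of
    consecutive sub-threshold windows [a, b] covers frames a .. b + W - 1;
    the episode onset is frame a and its duration the covered span.
    Episodes are non-overlapping by construction.
    """
    m = np.asarray(motion.motion, dtype=float)
    if np.all(np.isnan(m)):
        raise ValueError("all-NaN motion trace")
    fs = motion.fs
    W = max(int(round(window * fs)), 1)
    if len(m) < W:
        return []
    # sliding-window means for every start frame 0 .. n-W
    csum = np.concatenate([[0.0], np.nancumsum(m)])
    means = (csum[W:] - csum[:-W]) / W
    below = means < threshold

    episodes: list[Episode] = []
    i = 0
    n = len(below)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            covered = (j - i + 1) + W - 1  # frames
            duration = covered / fs
            if duration >= min_dur:
                episodes.append(
                    Episode(onset=i / fs, kind="freezing_onset", duration=duration)
                )
            i = j + 1
        else:
            i += 1
    return episodes


def classify_episodes(
    episodes: list[Episode], timeline: SessionTimeline
) -> list[Episode]:
    """Assign correctness by onset membership: a port visit whose onset lies
    in an R-CS window is correct; a freezing onset in an F-CS window is
    correct; everything else is incorrect.  Episodes outside the session are
    dropped (logged).  Episode order does not affect labels."""
    out: list[Episode] = []
    windows = timeline.cs_windows()
    for ep in episodes:
        if not (0.0 <= ep.onset <= timeline.session_length):
            logger.info("classify_episodes: dropping episode at %.1f s (outside session)", ep.onset)
            continue
        correct = any(
            lo <= ep.onset < hi and MATCHING_KIND[typ] == ep.kind
            for lo, hi, typ in windows
        )
        out.append(
            Episode(
                onset=ep.onset,
                kind=ep.kind,
                duration=ep.duration,
                correctness="correct" if correct else "incorrect",
            )
        )
    return out


def classify_cs_trials(
    timeline: SessionTimeline, episodes: list[Episode]
) -> list[str]:
    """Per-trial flag: "correct" iff >= 1 correct episode of the matching
    kind has its onset within the trial's 10 s window, else "incorrect"."""
    flags = []
    for onset, typ in timeline.cs_trials:
        hi = onset + timeline.cs_duration
        hit = any(
            ep.correctness == "correct"
            and ep.kind == MATCHING_KIND[typ]
            and onset <= ep.onset < hi
            for ep in episodes
        )
        flags.append("correct" if hit else "incorrect")
    return flags


def episodes_from_timeline(timeline: SessionTimeline) -> list[Episode]:
    """Convert raw timeline (onset, kind) tuples into Episode objects."""
    return [Episode(onset=t, kind=k) for t, k in timeline.behavior_episodes]
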