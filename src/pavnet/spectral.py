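"""Spike-triggered averages of LFP and spike-field coherence.

The STA is the mean of 200 ms LFP snippets centered on spike times taken
inside a condition window (the 10 s pre-CS period or the 10 s CS).  SFC is
the power spectrum of the STA normalized, frequency by frequency, by the
mean power spectrum of the individual snippets: perfectly phase-locked
spikes give SFC = 1 at the locked frequency, unlocked spikes give ~1/n.
Snippets are Hann-tapered before both spectra so numerator and denominator
see the same window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann

from .synth import LFPRecord

__all__ = [
    "STAResult",
    "SFCResult",
    "condition_mask_from_timeline",
    "spike_triggered_average",
    "spike_field_coherence",
    "compare_sfc",
]


@dataclass
class STAResult:
    sta: np.ndarray  # mean LFP snippet, length round(window * fs)
    snippets: np.ndarray  # (n_spikes, len) individual snippets
    n_spikes: int
    fs: float
    window: float = 0.2
    condition: str = ""
    spike_region: str = ""
    lfp_region: str = ""

    @property
    def lags(self) -> np.ndarray:
        n = len(self.sta)
        return (np.arange(n) - n // 2) / self.fs


@dataclass
class SFCResult:
    freqs: np.ndarray
    sfc: np.ndarray  # in [0, 1]
    sta_power: np.ndarray = field(default_factory=lambda: np.array([]))
    condition: str = ""
    taper: str = "hann"

    @property
    def peak_freq(self) -> float:
        valid = ~np.isnan(self.sfc)
        if not valid.any():
            return np.nan
        i = int(np.nanargmax(self.sfc))
        return float(self.freqs[i])


def condition_mask_from_timeline(timeline, condition: str) -> list[tuple[float, float]]:
    """Time intervals for a named condition: "preCS" = the 10 s before each
    CS onset, "CS" = the 10 s stimulus window."""
    if condition == "preCS":
        return [(on - 10.0, on) for on, _ in timeline.cs_trials]
    if condition == "CS":
        return [(on, on + timeline.cs_duration) for on, _ in timeline.cs_trials]
    raise ValueError(f"unknown condition {condition!r}")


def spike_triggered_average(
    lfp: LFPRecord,
    spikes: np.ndarray,
    window: float = 0.2,
    condition_mask: list[tuple[float, float]] | None = None,
    condition: str = "",
) -> STAResult:
    """Mean LFP snippet [t - window/2, t + window/2) around each eligible
    spike.  Spikes whose snippet crosses the record edge or a condition
    boundary are excluded."""
    spikes = np.asarray(spikes, dtype=float)
    fs = lfp.fs
    half = window / 2.0
    n_snip = int(round(window * fs))
    t_max = len(lfp.samples) / fs

    def eligible(t: float) -> bool:
        if t - half < 0 or t + half >= t_max:
            return False
        if condition_mask is None:
            return True
        return any(lo <= t - half and t + half <= hi for lo, hi in condition_mask)

    keep = [t for t in spikes if eligible(t)]
    if not keep:
        raise ValueError("zero eligible spikes for STA")
    snippets = np.empty((len(keep), n_snip))
    for i, t in enumerate(keep):
        i0 = int(round((t - half) * fs))
        snippets[i] = lfp.samples[i0 : i0 + n_snip]
    return STAResult(
        sta=snippets.mean(axis=0),
        snippets=snippets,
        n_spikes=len(keep),
        fs=fs,
        window=window,
        condition=condition,
        lfp_region=lfp.region,
    )


def spike_field_coherence(sta: STAResult, nfft: int | None = None) -> SFCResult:
    """SFC(f) = |FFT(taper * STA)|^2 / mean_i |FFT(taper * snippet_i)|^2.

    Bounded in [0, 1] (up to float rounding) by convexity of the power
    spectrum; frequencies with zero mean snippet power are flagged NaN.
    Spectra are zero-padded to ``nfft`` (default: >= 4x the snippet length,
    rounded up to a power of two) so the frequency grid resolves peaks
    finer than the 1/window native resolution.
    """
    if sta.snippets.shape[0] == 0:
        raise ValueError("zero snippets")
    n = len(sta.sta)
    if nfft is None:
        nfft = int(2 ** np.ceil(np.log2(max(4 * n, 256))))
    taper = hann(n, sym=False)
    num = np.abs(np.fft.rfft(sta.sta * taper, n=nfft)) ** 2
    den = np.mean(np.abs(np.fft.rfft(sta.snippets * taper, axis=1, n=nfft)) ** 2, axis=0)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sta.fs)
    with np.errstate(invalid="ignore", divide="ignore"):
        sfc = np.where(den > 0, num / den, np.nan)
    # SFC <= 1 holds exactly (power of a mean <= mean power); shave the
    # float-rounding excess at near-zero-power frequencies
    sfc = np.minimum(sfc, 1.0)
    # restrict to (0, fs/2): drop DC and Nyquist, where phase is meaningless
    keep = (freqs > 0) & (freqs < sta.fs / 2)
    return SFCResult(
        freqs=freqs[keep],
        sfc=sfc[keep],
        sta_power=num[keep],
        condition=sta.condition,
    )


def compare_sfc(pre: SFCResult, cs: SFCResult) -> dict:
    """Elementwise CS - preCS difference plus per-condition peak report."""
    if len(pre.freqs) != len(cs.freqs) or not np.allclose(pre.freqs, cs.freqs):
        raise ValueError("frequency grids differ")
    return {
        "freqs": pre.freqs,
        "difference": cs.sfc - pre.sfc,
        "peak_preCS": pre.peak_freq,
        "peak_CS": cs.peak_freq,
    }
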