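import numpy as np
import pytest

from pavnet.synth import SynthConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """One small synthetic recall session with planted CS responses,
    aIC -> CE_SST coupling, a 33 Hz pIC oscillation and mostly-correct
    behavior; shared across read-only tests."""
    from pavnet.synth import Coupling, Oscillation

    cfg = SynthConfig(
        n_neurons_per_region={"aIC": 10, "pIC": 10, "CE_SST": 6, "CE_PKCd": 6, "CEm": 4},
        baseline_rate={r: 0.2 for r in ("aIC", "pIC", "CE_SST", "CE_PKCd", "CEm")},
        cs_response_amp={(r, t, "recall"): 3.0 for r in ("aIC", "pIC") for t in ("R", "F")},
        coupling=[Coupling("aIC", "CE_SST", 0.35, 1)],
        lfp_osc=[Oscillation("pIC", 33.0, 1.0, 0.0)],
        behavior_correct_prob=0.8,
        session_length=600.0,
        n_trials_per_cs=6,
        stage="recall",
        seed=11,
    )
    return cfg, generate_session(cfg)


def te_bruteforce(x, y, k):
    """Independent exhaustive joint-histogram plug-in transfer entropy
    (bits); dictionary counting, no shared code with the implementation."""
    import math
    from collections import Counter

    x = list(x)
    y = list(y)
    n = len(x)
    joint = Counter()
    cond_src = Counter()
    cond_tgt = Counter()
    hist = Counter()
    for t in range(k, n):
        xh = tuple(x[t - k : t])
        yh = tuple(y[t - k : t])
        yn = y[t]
        joint[(xh, yh, yn)] += 1
        cond_src[(xh, yh)] += 1
        cond_tgt[(yh, yn)] += 1
        hist[yh] += 1
    N = n - k
    te = 0.0
    for (xh, yh, yn), c in joint.items():
        te += (c / N) * math.log2(c * hist[yh] / (cond_src[(xh, yh)] * cond_tgt[(yh, yn)]))
    return te


def freezing_bruteforce(motion, fs, threshold, min_dur=1.0, window=1.0):
    """Frame-by-frame sliding-window freezing scorer: for every start frame
    compute the window mean explicitly, then collect maximal runs."""
    m = np.asarray(motion, dtype=float)
    W = max(int(round(window * fs)), 1)
    n = len(m)
    if n < W:
        return []
    below = []
    for t in range(n - W + 1):
        below.append(np.mean(m[t : t + W]) < threshold)
    episodes = []
    t = 0
    while t < len(below):
        if below[t]:
            start = t
            while t + 1 < len(below) and below[t + 1]:
                t += 1
            covered = (t - start + 1) + W - 1
            if covered / fs >= min_dur:
                episodes.append((start / fs, covered / fs))
            t += 1
        else:
            t += 1
    return episodes
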