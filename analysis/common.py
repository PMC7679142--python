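"""Shared session setup for the numbered analysis scripts.

One synthetic recall session, regenerated deterministically by every script:
insular cortex (aIC, pIC) responds to both CSs, aIC drives CE_SST with a
lag-1 coupling, the pIC LFP carries a 33 Hz oscillation that aIC spikes are
locked to, and behavior is 80% correct.
"""

from pathlib import Path

from pavnet.synth import Coupling, Oscillation, SynthConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

SEED = 2024
REGIONS = ("aIC", "pIC", "CE_SST", "CE_PKCd", "CEm")


def session_config(seed: int = SEED) -> SynthConfig:
    return SynthConfig(
        n_neurons_per_region={"aIC": 25, "pIC": 25, "CE_SST": 12, "CE_PKCd": 12, "CEm": 8},
        baseline_rate={r: 0.2 for r in REGIONS},
        cs_response_amp={(r, t, "recall"): 3.0 for r in ("aIC", "pIC") for t in ("R", "F")},
        coupling=[Coupling("aIC", "CE_SST", 0.35, 1)],
        lfp_osc=[
            Oscillation("pIC", 33.0, 1.0, 0.0),
            Oscillation("aIC", 33.0, 0.0, 4.0),  # locking target for aIC spikes
        ],
        behavior_correct_prob=0.8,
        session_length=600.0,
        n_trials_per_cs=6,
        stage="recall",
        seed=seed,
    )
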