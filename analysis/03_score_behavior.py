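"""Score behavior: freezing episodes from the motion index, correctness of
all episodes, and per-trial correct/incorrect flags.

With behavior_correct_prob = 0.8 planted, roughly 80% of CS trials should
come out correct.  Summary in results/behavior_summary.json.
"""

import json

from common import RESULTS, session_config
from pavnet.behavior import (
    classify_cs_trials,
    classify_episodes,
    episodes_from_timeline,
    score_freezing,
)
from pavnet.synth import generate_session


def main():
    cfg = session_config()
    _, timeline, _, _, motion = generate_session(cfg)
    frozen = score_freezing(motion, threshold=0.5)
    episodes = classify_episodes(episodes_from_timeline(timeline), timeline)
    flags = classify_cs_trials(timeline, episodes)

    summary = {
        "n_freezing_episodes_scored": len(frozen),
        "mean_freezing_duration_s": round(
            sum(e.duration for e in frozen) / max(len(frozen), 1), 2
        ),
        "n_episodes": len(episodes),
        "n_correct_episodes": sum(e.correctness == "correct" for e in episodes),
        "n_incorrect_episodes": sum(e.correctness == "incorrect" for e in episodes),
        "n_trials": len(flags),
        "fraction_correct_trials": round(flags.count("correct") / len(flags), 3),
        "planted_correct_prob": cfg.behavior_correct_prob,
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "behavior_summary.json").write_text(json.dumps(summary, indent=1))
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
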