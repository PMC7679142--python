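"""Decode CS information from population activity.

Single-region MLP decoding per region (Da with shuffled-label control),
then multi-region random-forest decoding with per-region feature
importance.  The IC regions carry the planted CS response, so they should
decode well and dominate the importance profile.  Table in
results/decoding_summary.csv, importances in results/importance_by_region.json.
"""

import json

import pandas as pd

from common import RESULTS, SEED, session_config
from pavnet.binning import LabeledDataset, bin_events, build_labels
from pavnet.decoding import decode_multi_region, decode_single_region
from pavnet.synth import generate_session


def main():
    cfg = session_config()
    trains, timeline, *_ = generate_session(cfg)
    b1 = bin_events(trains, 1.0, 0.0, cfg.session_length)
    labels = build_labels(b1, timeline, task="CS")

    rows = []
    for region in cfg.n_neurons_per_region:
        idx = b1.region_index(region)
        ds = LabeledDataset(
            X=labels.X[:, idx], y=labels.y, task="CS",
            regions=[labels.regions[i] for i in idx],
        )
        res = decode_single_region(ds, n_neurons=min(10, len(idx)), repeats=5, seed=SEED)
        rows.append({
            "region": region,
            "n_neurons_used": min(10, len(idx)),
            "Da": round(res.da, 3),
            "Da_shuffled": round(res.da_shuffled, 3),
        })
    df = pd.DataFrame(rows)

    mres, prof = decode_multi_region(labels, n_total=50, repeats=10, seed=SEED + 1)
    importances = {r: round(v, 5) for r, v in prof.mean_by_region().items()}

    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "decoding_summary.csv", index=False)
    (RESULTS / "importance_by_region.json").write_text(json.dumps({
        "multi_region_Da": round(mres.da, 3),
        "mean_feature_importance": importances,
    }, indent=1))
    print(df.to_string(index=False))
    print("\nmulti-region RF Da:", round(mres.da, 3))
    print("importance by region:", importances)


if __name__ == "__main__":
    main()
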