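"""Network export and the end-to-end pipeline driver.

``run_pipeline`` executes simulate -> bin -> behavior -> decode -> TE ->
SFC -> report on one config, logging every stage, and writes an
AnalysisManifest listing every produced artifact with a content hash.  A
single master seed parameterizes all stages: stage seeds are derived as
``master * 1000 + stage_index`` so any stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as pio
from .behavior import classify_cs_trials, classify_episodes, episodes_from_timeline, score_freezing
from .binning import bin_events, build_labels, make_peth
from .decoding import decode_multi_region, decode_single_region
from .spectral import condition_mask_from_timeline, spike_field_coherence, spike_triggered_average
from .synth import Coupling, Oscillation, SynthConfig, generate_session
from .te import TENetwork, build_te_network

logger = logging.getLogger(__name__)

STAGE_NAMES = ["simulate", "bin", "behavior", "decode", "te", "sfc", "report"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class AnalysisManifest:
    config: dict[str, str]
    master_seed: int
    stage_seeds: dict[str, int]
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def add(self, path: str | Path) -> None:
        p = Path(path)
        self.artifacts[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "master_seed": self.master_seed,
                "stage_seeds": self.stage_seeds,
                "artifacts": dict(sorted(self.artifacts.items())),
            },
            indent=1,
            sort_keys=True,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def export_network(net: TENetwork, out_base: str | Path) -> list[Path]:
    """Write a TE network as GraphML, a directed edge-list CSV
    (source, target, te_bits, p_value, significant) and a JSON file of node
    importances.  Returns the written paths."""
    out_base = Path(out_base)
    paths = []

    g = net.graph.copy()
    for _, d in g.nodes(data=True):
        for k, v in list(d.items()):
            if isinstance(v, float) and np.isnan(v):
                d[k] = -1.0  # GraphML has no NaN literal
    p_gml = out_base.with_suffix(".graphml")
    nx.write_graphml(g, p_gml)
    paths.append(p_gml)

    rows = [
        {"source": u, "target": v, "te_bits": d["te_bits"],
         "p_value": d["p_value"], "significant": d["significant"]}
        for u, v, d in net.graph.edges(data=True)
    ]
    p_csv = out_base.with_suffix(".edges.csv")
    pd.DataFrame(rows, columns=["source", "target", "te_bits", "p_value", "significant"]).to_csv(
        p_csv, index=False
    )
    paths.append(p_csv)

    p_json = out_base.with_suffix(".nodes.json")
    Path(p_json).write_text(
        json.dumps(
            {n: {k: (None if isinstance(v, float) and np.isnan(v) else v)
                 for k, v in d.items()}
             for n, d in net.graph.nodes(data=True)},
            indent=1, sort_keys=True,
        )
    )
    paths.append(p_json)
    return paths


def import_network(out_base: str | Path, alpha: float = 0.05) -> TENetwork:
    g = nx.read_graphml(Path(out_base).with_suffix(".graphml"))
    dg = nx.DiGraph()
    for n, d in g.nodes(data=True):
        dg.add_node(n, **d)
    for u, v, d in g.edges(data=True):
        dg.add_edge(u, v, **d)
    return TENetwork(graph=dg, alpha=alpha)


def _synth_config_from(cfg: dict[str, str], seed: int) -> SynthConfig:
    f, s, i = float, str, int
    cs_amp = f(cfg["cs_amp"])
    regions = ["aIC", "pIC", "CE_SST", "CE_PKCd", "CEm"]
    return SynthConfig(
        n_neurons_per_region={r: i(cfg[f"n_{r}"]) for r in regions},
        baseline_rate={r: f(cfg["baseline_rate"]) for r in regions},
        cs_response_amp={(r, t, "recall"): cs_amp for r in regions for t in ("R", "F")},
        coupling=[Coupling("aIC", "CE_SST", f(cfg["coupling_excess"]), 1)],
        lfp_osc=[Oscillation("pIC", f(cfg["lfp_freq"]), f(cfg["lfp_amp"]), 0.0),
                 Oscillation("aIC", f(cfg["lfp_freq"]), 0.0, f(cfg["lfp_kappa"]))],
        behavior_correct_prob=f(cfg["behavior_correct_prob"]),
        session_length=f(cfg["session_length"]),
        n_trials_per_cs=i(cfg["n_trials_per_cs"]),
        stage="recall",
        seed=seed,
    )


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> AnalysisManifest:
    """Run the full analysis chain on one config file; returns the manifest.

    Stages: simulate (synthetic session), bin (1 s and 500 ms matrices,
    PETH), behavior (freezing scoring + correctness), decode (single- and
    multi-region), te (directed region network on CS bins), sfc (pre-CS vs
    CS spike-field coherence), report (network files + summary + manifest).
    Any stage failure aborts with a stage-tagged error.
    """
    cfg = dict(pio.default_config())
    cfg.update(pio.parse_config(config_path))
    master = int(cfg["seed"])
    seeds = {name: master * 1000 + i for i, name in enumerate(STAGE_NAMES)}
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = AnalysisManifest(config=cfg, master_seed=master, stage_seeds=seeds)

    stage = "simulate"
    try:
        logger.info("stage %s (seed %d)", stage, seeds[stage])
        scfg = _synth_config_from(cfg, seeds[stage])
        trains, timeline, lfps, calcium, motion = generate_session(scfg)
        pio.write_events_csv(trains, out / "events.csv")
        pio.write_timeline_json(timeline, out / "timeline.json")
        pio.write_signals_h5(out / "signals.h5", lfps=lfps, calcium=calcium, motion=motion)
        for name in ("events.csv", "timeline.json", "signals.h5"):
            manifest.add(out / name)

        stage = "bin"
        logger.info("stage %s", stage)
        b1 = bin_events(trains, 1.0, 0.0, scfg.session_length)
        b05 = bin_events(trains, 0.5, 0.0, scfg.session_length)
        peth = make_peth(b05, timeline, smoothing_degree=5.0)
        np.savetxt(out / "binned_1s.csv", b1.counts, fmt="%d", delimiter=",")
        pd.DataFrame(
            {"trial": np.arange(peth.z.shape[0]),
             "cs_type": peth.cs_types,
             "mean_cs_z": np.nanmean(peth.z[:, :, 16:36], axis=(1, 2))}
        ).to_csv(out / "peth_summary.csv", index=False)
        manifest.add(out / "binned_1s.csv")
        manifest.add(out / "peth_summary.csv")

        stage = "behavior"
        logger.info("stage %s", stage)
        frozen = score_freezing(motion, threshold=float(cfg["motion_threshold"]))
        episodes = classify_episodes(episodes_from_timeline(timeline), timeline)
        trial_flags = classify_cs_trials(timeline, episodes)
        pd.DataFrame(
            {"trial_onset": [t for t, _ in timeline.cs_trials],
             "cs_type": [ty for _, ty in timeline.cs_trials],
             "flag": trial_flags}
        ).to_csv(out / "trial_correctness.csv", index=False)
        (out / "behavior_summary.json").write_text(json.dumps({
            "n_freezing_scored": len(frozen),
            "n_correct_episodes": sum(e.correctness == "correct" for e in episodes),
            "n_incorrect_episodes": sum(e.correctness == "incorrect" for e in episodes),
            "fraction_correct_trials": trial_flags.count("correct") / max(len(trial_flags), 1),
        }, indent=1))
        manifest.add(out / "trial_correctness.csv")
        manifest.add(out / "behavior_summary.json")

        stage = "decode"
        logger.info("stage %s", stage)
        labels = build_labels(b1, timeline, task="CS")
        aic_cols = b1.region_index("aIC")
        from .binning import LabeledDataset
        aic_ds = LabeledDataset(
            X=labels.X[:, aic_cols], y=labels.y, task="CS",
            neuron_ids=[labels.neuron_ids[i] for i in aic_cols],
            regions=[labels.regions[i] for i in aic_cols],
        )
        dres = decode_single_region(
            aic_ds, n_neurons=int(cfg["decode_n_neurons"]),
            repeats=int(cfg["decode_repeats"]), seed=seeds[stage],
        )
        mres, imp = decode_multi_region(
            labels, n_total=min(50, labels.n_neurons),
            repeats=int(cfg["decode_repeats"]), seed=seeds[stage] + 1,
        )
        (out / "decoding.json").write_text(json.dumps({
            "single_region_aIC_Da": dres.da,
            "single_region_aIC_Da_shuffled": dres.da_shuffled,
            "multi_region_Da": mres.da,
            "importance_by_region": imp.mean_by_region(),
        }, indent=1))
        manifest.add(out / "decoding.json")

        stage = "te"
        logger.info("stage %s", stage)
        net = build_te_network(
            b1, timeline, window_spec="cs",
            n_draw=int(cfg["te_n_draw"]), seed=seeds[stage],
            n_surr=int(cfg["te_n_surr"]), alpha=float(cfg["te_alpha"]),
            importance=imp.mean_by_region(),
        )
        for p in export_network(net, out / "te_network"):
            manifest.add(p)

        stage = "sfc"
        logger.info("stage %s", stage)
        aic_spikes = np.concatenate(
            [tr.event_times for tr in trains if tr.region == "aIC"]
        )
        sfc_out = {}
        for cond in ("preCS", "CS"):
            mask = condition_mask_from_timeline(timeline, cond)
            sta = spike_triggered_average(
                lfps["pIC"], np.sort(aic_spikes),
                window=float(cfg["sfc_window"]), condition_mask=mask, condition=cond,
            )
            sfc = spike_field_coherence(sta)
            sfc_out[cond] = {"peak_freq_hz": sfc.peak_freq,
                             "peak_sfc": float(np.nanmax(sfc.sfc)),
                             "n_spikes": sta.n_spikes}
        (out / "sfc.json").write_text(json.dumps(sfc_out, indent=1))
        manifest.add(out / "sfc.json")

        stage = "report"
        logger.info("stage %s", stage)
        manifest.write(out / "manifest.json")
    except Exception as e:  # noqa: BLE001 - stage-tagged abort
        raise PipelineStageError(stage, e) from e
    return manifest
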