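"""Discrete transfer entropy on binned event trains, region-level
aggregation, surrogate significance, and directed network assembly.

Transfer entropy TE(X -> Y) with history length k is the plug-in estimate

    TE = sum p(y_{t+1}, y_t^{(k)}, x_t^{(k)})
             * log2[ p(y_{t+1} | y_t^{(k)}, x_t^{(k)}) / p(y_{t+1} | y_t^{(k)}) ]

over all valid t, in bits.  It is computed pairwise between all neurons of a
source and a target region; the local maximum over the history-length scan is
taken per pair (the default scan is k = 1, i.e. a 1 s history at 1 s bins);
only the upper 50% of pairs per region combination is retained, and the
region-level TE is their mean.  Significance comes from surrogate data: the
source neurons' time bins are permuted, the full pipeline recomputed, and
p = proportion of surrogate region TEs >= the real one.

Bin counts are clipped to a small finite alphabet (binary by default: any
event in the bin -> 1) as the estimator requires discrete states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .binning import BinnedMatrix
from .synth import SessionTimeline

__all__ = [
    "discrete_te",
    "pairwise_te_matrix",
    "pairwise_peak_te",
    "region_te",
    "surrogate_test",
    "select_window_bins",
    "build_te_network",
    "TEPairResult",
    "TERegionResult",
    "TENetwork",
]


@dataclass
class TEPairResult:
    source: str  # neuron id n1
    target: str  # neuron id n2
    te_by_k: dict[int, float]  # history length k -> TE bits

    @property
    def peak(self) -> float:
        return max(self.te_by_k.values())


@dataclass
class TERegionResult:
    source_region: str
    target_region: str
    te: float  # mean of retained (upper 50%) pair TEs, bits
    retained: np.ndarray = field(default_factory=lambda: np.array([]))
    n_pairs: int = 0
    flagged_single: bool = False


@dataclass
class TENetwork:
    """Directed region-level graph; edges carry TE (bits) and surrogate p."""

    graph: nx.DiGraph
    alpha: float = 0.05
    window_spec: str = ""
    n_drawn: int = 0

    def significant_view(self) -> nx.DiGraph:
        keep = [
            (u, v)
            for u, v, d in self.graph.edges(data=True)
            if d.get("p_value", 1.0) < self.alpha
        ]
        return self.graph.edge_subgraph(keep).copy() if keep else nx.DiGraph(
            nx.create_empty_copy(self.graph)
        )


# ---------------------------------------------------------------------------
# estimator core


def _codes(series: np.ndarray, k: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """History codes x_t^{(k)} in [0, m^k) and (y-history, y-next) codes.

    For a series of length T the valid transitions are t = k .. T-1,
    giving T - k samples.
    """
    s = np.asarray(series)
    T = s.shape[-1]
    hist = np.zeros(s[..., : T - k].shape, dtype=np.int64)
    for j in range(k):
        hist = hist * m + s[..., j : T - k + j]
    return hist, s[..., k:]


def _xlogx(n: np.ndarray) -> np.ndarray:
    out = np.zeros_like(n, dtype=float)
    nz = n > 0
    out[nz] = n[nz] * np.log2(n[nz])
    return out


def discrete_te(x: Sequence[int], y: Sequence[int], k: int = 1) -> float:
    """Plug-in transfer entropy TE(X -> Y) in bits for one series pair."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if len(x) <= k + 1:
        raise ValueError(f"series length {len(x)} too short for k={k}")
    if np.min(x) < 0 or np.min(y) < 0:
        raise ValueError("states must be nonnegative integers")
    m = int(max(x.max(), y.max())) + 1
    te = pairwise_te_matrix(x[None, :], y[None, :], k=k, alphabet=m)[0, 0]
    return float(te)


def pairwise_te_matrix(
    sources: np.ndarray,
    targets: np.ndarray,
    k: int = 1,
    alphabet: int | None = None,
) -> np.ndarray:
    """TE in bits for every (source, target) row pair: (N_src, N_tgt) array.

    Vectorized over pairs: joint histograms are accumulated as one-hot
    tensor contractions, so surrogate loops stay cheap.
    """
    X = np.asarray(sources, dtype=np.int64)
    Y = np.asarray(targets, dtype=np.int64)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("sources/targets must be 2-D with a shared bin axis")
    T = X.shape[1]
    if T <= k + 1:
        raise ValueError(f"series length {T} too short for k={k}")
    m = alphabet or int(max(X.max(initial=0), Y.max(initial=0))) + 1
    m = max(m, 2)
    A = m**k  # x-history states
    H = m**k  # y-history states

    xh, _ = _codes(X, k, m)  # (N, T-k)
    yh, yn = _codes(Y, k, m)  # (M, T-k), (M, T-k)
    yhn = yh * m + yn  # joint (y-history, y-next) code, [0, H*m)
    n_t = T - k

    Xoh = np.zeros((X.shape[0], A, n_t), dtype=np.float64)
    idx0 = np.repeat(np.arange(X.shape[0]), n_t)
    Xoh[idx0, xh.ravel(), np.tile(np.arange(n_t), X.shape[0])] = 1.0
    Yoh = np.zeros((Y.shape[0], H * m, n_t), dtype=np.float64)
    idx1 = np.repeat(np.arange(Y.shape[0]), n_t)
    Yoh[idx1, yhn.ravel(), np.tile(np.arange(n_t), Y.shape[0])] = 1.0

    # counts[i, a, j, b] = #t with x-hist a (src i) and (y-hist, y') b (tgt j)
    counts = np.tensordot(Xoh, Yoh, axes=([2], [2]))  # (N, A, M, H*m)
    counts = counts.reshape(X.shape[0], A, Y.shape[0], H, m)

    n_xh_yh = counts.sum(axis=4)  # (N, A, M, H)
    n_yh_yn = counts.sum(axis=1)  # (N, M, H, m) -- constant over sources
    n_yh = n_xh_yh.sum(axis=1)  # (N, M, H)

    # sum n * [log n + log n_yh - log n_xh_yh - log n_yh_yn]
    s = (
        _xlogx(counts).sum(axis=(1, 3, 4))
        - _xlogx(n_xh_yh).sum(axis=(1, 3))
        - _xlogx(n_yh_yn).sum(axis=(2, 3))
        + _xlogx(n_yh).sum(axis=2)
    )
    te = s / n_t
    # clip tiny negative rounding residue; the plug-in TE is nonnegative
    return np.maximum(te, 0.0)


def clip_states(counts: np.ndarray, max_state: int = 1) -> np.ndarray:
    """Map bin counts to the analysis alphabet (binary by default)."""
    return np.minimum(np.asarray(counts, dtype=np.int64), max_state)


def pairwise_peak_te(
    source: BinnedMatrix | np.ndarray,
    target: BinnedMatrix | np.ndarray,
    k_range: Iterable[int] = (1,),
    max_state: int = 1,
    source_ids: list[str] | None = None,
    target_ids: list[str] | None = None,
) -> list[TEPairResult]:
    """TE for every ordered neuron pair and every history length k; the
    pair's peak is the maximum over the scan.  Self-pairings (shared neuron
    ids) are excluded."""
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("k_range must be nonempty")
    if isinstance(source, BinnedMatrix):
        source_ids = source.neuron_ids
        source = source.counts
    if isinstance(target, BinnedMatrix):
        target_ids = target.neuron_ids
        target = target.counts
    Xs = clip_states(source, max_state)
    Ys = clip_states(target, max_state)
    if Xs.size == 0 or Ys.size == 0:
        raise ValueError("empty matrices")
    sids = source_ids or [f"src_{i}" for i in range(Xs.shape[0])]
    tids = target_ids or [f"tgt_{j}" for j in range(Ys.shape[0])]

    te_by_k = {k: pairwise_te_matrix(Xs, Ys, k=k, alphabet=max_state + 1) for k in k_range}
    results = []
    for i, sid in enumerate(sids):
        for j, tid in enumerate(tids):
            if sid == tid:
                continue
            results.append(
                TEPairResult(
                    source=sid,
                    target=tid,
                    te_by_k={k: float(te_by_k[k][i, j]) for k in k_range},
                )
            )
    return results


def region_te(
    pairs: list[TEPairResult],
    source_region: str = "",
    target_region: str = "",
) -> TERegionResult:
    """Aggregate pair TEs: sort peaks descending (stable; ties broken by
    pair order), keep the top ceil(n/2), average."""
    if not pairs:
        raise ValueError("no pairs")
    peaks = np.array([p.peak for p in pairs])
    if len(pairs) < 2:
        return TERegionResult(
            source_region=source_region,
            target_region=target_region,
            te=float(peaks[0]),
            retained=peaks,
            n_pairs=1,
            flagged_single=True,
        )
    order = np.argsort(-peaks, kind="stable")
    n_keep = int(np.ceil(len(peaks) / 2))
    retained = peaks[order[:n_keep]]
    return TERegionResult(
        source_region=source_region,
        target_region=target_region,
        te=float(retained.mean()),
        retained=retained,
        n_pairs=len(peaks),
    )


def _region_te_value(Xs: np.ndarray, Ys: np.ndarray, k_range: Sequence[int], m: int) -> float:
    """Fast path: pairwise peak TE -> top-50% -> mean, on clipped states."""
    te = np.stack([pairwise_te_matrix(Xs, Ys, k=k, alphabet=m) for k in k_range])
    peaks = te.max(axis=0).ravel()
    n_keep = int(np.ceil(len(peaks) / 2)) if len(peaks) >= 2 else len(peaks)
    retained = np.sort(peaks)[::-1][:n_keep]
    return float(retained.mean())


def surrogate_test(
    source: BinnedMatrix | np.ndarray,
    target: BinnedMatrix | np.ndarray,
    n_surr: int = 1000,
    seed: int = 0,
    k_range: Iterable[int] = (1,),
    max_state: int = 1,
    shuffle: str = "permute_source",
) -> tuple[float, float, float]:
    """Surrogate significance for the region-level TE.

    Each surrogate independently permutes every source neuron's time bins
    (destroying source->target dependence while preserving marginal rates
    and the target's own dynamics, which the TE conditions on), then
    recomputes the full pipeline: pairwise peak TE -> top-50% -> region
    mean.  ``shuffle="permute_all"`` additionally permutes target neurons;
    ``shuffle="circular"`` applies random circular shifts instead.

    Returns (p_value, te_real, p_conservative) where p_value is the plain
    proportion of surrogate TEs >= the real TE (may be exactly 0) and
    p_conservative = (count + 1) / (n_surr + 1).
    """
    if n_surr < 1:
        raise ValueError("n_surr must be >= 1")
    if isinstance(source, BinnedMatrix):
        source = source.counts
    if isinstance(target, BinnedMatrix):
        target = target.counts
    Xs = clip_states(source, max_state)
    Ys = clip_states(target, max_state)
    k_range = sorted(set(int(k) for k in k_range))
    m = max_state + 1
    te_real = _region_te_value(Xs, Ys, k_range, m)

    rng = np.random.default_rng(seed)
    T = Xs.shape[1]
    count = 0
    for _ in range(n_surr):
        if shuffle == "circular":
            shifts = rng.integers(0, T, size=Xs.shape[0])
            Xp = np.stack([np.roll(row, s) for row, s in zip(Xs, shifts)])
            Yp = Ys
        else:
            Xp = rng.permuted(Xs, axis=1)
            Yp = rng.permuted(Ys, axis=1) if shuffle == "permute_all" else Ys
        te_s = _region_te_value(Xp, Yp, k_range, m)
        if te_s >= te_real:
            count += 1
    p = count / n_surr
    return p, te_real, (count + 1) / (n_surr + 1)


# ---------------------------------------------------------------------------
# windows and network assembly


def select_window_bins(
    timeline: SessionTimeline,
    n_bins: int,
    spec: str,
    cs_type: str | None = None,
    post_us_bins: int = 8,
    episode_halfwidth: int = 2,
) -> np.ndarray:
    """1 s bin indices for a named analysis window.

    spec: "cs" (the 10 CS bins per trial, optionally one CS type),
    "post_us" (bins after US offset), "episode" (the bin containing each
    behavioral episode onset +/- ``episode_halfwidth`` bins), "pre_cs"
    (the 10 bins before each CS onset).
    """
    sel: list[int] = []
    if spec == "cs":
        for onset, typ in timeline.cs_trials:
            if cs_type is not None and typ != cs_type:
                continue
            b0 = int(onset)
            sel.extend(range(b0, min(b0 + int(timeline.cs_duration), n_bins)))
    elif spec == "pre_cs":
        for onset, typ in timeline.cs_trials:
            if cs_type is not None and typ != cs_type:
                continue
            b0 = int(onset)
            sel.extend(range(max(b0 - 10, 0), b0))
    elif spec == "post_us":
        for t_us, typ in timeline.us_events:
            if cs_type is not None and typ != cs_type:
                continue
            b0 = int(t_us) + 1
            sel.extend(range(b0, min(b0 + post_us_bins, n_bins)))
    elif spec == "episode":
        for t_ep, _kind in timeline.behavior_episodes:
            b = int(t_ep)
            sel.extend(range(max(b - episode_halfwidth, 0), min(b + episode_halfwidth + 1, n_bins)))
    else:
        raise ValueError(f"unknown window spec {spec!r}")
    sel = sorted(set(b for b in sel if 0 <= b < n_bins))
    if not sel:
        raise ValueError(f"window spec {spec!r} selected no bins")
    return np.asarray(sel, dtype=int)


def _proportional_allocation(pool_sizes: dict[str, int], n_total: int) -> dict[str, int]:
    """Largest-remainder allocation of n_total draws across regions."""
    total = sum(pool_sizes.values())
    if total <= n_total:
        return dict(pool_sizes)
    quotas = {r: n_total * c / total for r, c in pool_sizes.items()}
    alloc = {r: int(np.floor(q)) for r, q in quotas.items()}
    short = n_total - sum(alloc.values())
    rema = sorted(quotas, key=lambda r: (-(quotas[r] - alloc[r]), r))
    for r in rema[:short]:
        alloc[r] += 1
    return {r: min(a, pool_sizes[r]) for r, a in alloc.items()}


def build_te_network(
    binned: BinnedMatrix,
    timeline: SessionTimeline,
    window_spec: str = "cs",
    n_draw: int = 500,
    importance: dict[str, float] | None = None,
    seed: int = 0,
    n_surr: int = 1000,
    alpha: float = 0.05,
    k_range: Iterable[int] = (1,),
    cs_type: str | None = None,
) -> TENetwork:
    """Directed region-level TE network on a named analysis window.

    Bins selected by ``window_spec`` are extracted and concatenated;
    ``n_draw`` neurons are drawn respecting the regions' proportions
    (largest-remainder rounding); every ordered region pair gets a TE edge
    with a surrogate p-value; node attributes carry the supplied mean
    feature importances.
    """
    if abs(binned.bin_width - 1.0) > 1e-9:
        raise ValueError("build_te_network expects 1 s bins")
    rng = np.random.default_rng(seed)
    bins = select_window_bins(timeline, binned.n_bins, window_spec, cs_type=cs_type)
    regions = sorted(set(binned.regions))
    reg_arr = np.asarray(binned.regions)
    pool = {r: int((reg_arr == r).sum()) for r in regions}
    alloc = _proportional_allocation(pool, n_draw)

    drawn: dict[str, np.ndarray] = {}
    for r in regions:
        idx = np.flatnonzero(reg_arr == r)
        take = alloc.get(r, 0)
        if take > 0:
            drawn[r] = np.sort(rng.choice(idx, size=take, replace=False))

    sub = {r: binned.counts[idx][:, bins] for r, idx in drawn.items()}

    g = nx.DiGraph()
    for r in regions:
        g.add_node(
            r,
            n_drawn=len(drawn.get(r, [])),
            importance=float(importance.get(r, np.nan)) if importance else np.nan,
        )
    pair_seed = int(rng.integers(0, 2**20))
    d = sorted(drawn)
    for pair_i, (ra, rb) in enumerate(
        (a, b) for a in d for b in d if a != b
    ):
        p, te_val, p_cons = surrogate_test(
            sub[ra],
            sub[rb],
            n_surr=n_surr,
            seed=(pair_seed * 1000 + pair_i) % 2**31,
            k_range=k_range,
        )
        g.add_edge(
            ra, rb, te_bits=te_val, p_value=p, p_conservative=p_cons,
            significant=bool(p < alpha),
        )
    return TENetwork(
        graph=g, alpha=alpha, window_spec=window_spec, n_drawn=sum(alloc.values())
    )
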