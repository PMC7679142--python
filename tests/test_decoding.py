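"""Decoding-suite checks on planted-coding datasets (reduced repeat counts;
the full-size chance/power checks live in the acceptance suite)."""

import numpy as np
import pytest

from pavnet.binning import LabeledDataset
from pavnet.decoding import (
    ImportanceProfile,
    _largest_remainder,
    _undersample,
    contrast_importance,
    cross_stimulus_transfer,
    decode_multi_region,
    decode_single_region,
    discriminate_cs,
    rank_best_neurons,
)


def _planted(n_samples=160, n_neurons=20, coders=10, effect=2.0, seed=0,
             regions=None, n_classes=2):
    """Balanced dataset where the first ``coders`` neurons shift by
    ``effect`` z on class 1 (and the next ``coders`` on class 2 if 3-class)."""
    rng = np.random.default_rng(seed)
    per = n_samples // n_classes
    y = np.repeat(np.arange(n_classes), per)
    X = rng.normal(0, 1, (per * n_classes, n_neurons))
    X[y == 1, :coders] += effect
    if n_classes == 3:
        X[y == 2, coders : 2 * coders] += effect
    return LabeledDataset(
        X=X, y=y, task="CS" if n_classes == 2 else "CS3",
        regions=list(regions) if regions else ["r0"] * n_neurons,
        neuron_ids=[f"n{i}" for i in range(n_neurons)],
    )


class TestUndersample:
    def test_balances_classes(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 30 + [1] * 10)
        rows = _undersample(y, rng)
        assert (y[rows] == 0).sum() == (y[rows] == 1).sum() == 10


class TestDecodeSingleRegion:
    def test_planted_coding_high_da_and_chance_shuffle(self):
        ds = _planted(effect=2.0)
        res = decode_single_region(ds, n_neurons=20, repeats=5, seed=1)
        assert res.da >= 0.85
        assert 0.40 <= res.da_shuffled <= 0.60

    def test_identical_features_chance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 10))
        ds = LabeledDataset(X=X, y=np.repeat([0, 1], 60), task="CS")
        res = decode_single_region(ds, n_neurons=10, repeats=5, seed=2)
        assert 0.35 <= res.da <= 0.65

    def test_reproducible_to_float_precision(self):
        ds = _planted(effect=1.0)
        r1 = decode_single_region(ds, n_neurons=10, repeats=2, seed=3)
        r2 = decode_single_region(ds, n_neurons=10, repeats=2, seed=3)
        assert abs(r1.da - r2.da) < 1e-12

    def test_monotone_in_effect_size(self):
        das = []
        for effect in (0.0, 0.5, 2.0):
            ds = _planted(effect=effect, seed=4)
            das.append(decode_single_region(ds, n_neurons=20, repeats=3, seed=5,
                                            shuffled_control=False).da)
        assert das[0] < das[2]
        assert das[1] <= das[2] + 0.05

    def test_errors(self):
        ds = _planted()
        with pytest.raises(ValueError):
            decode_single_region(ds, n_neurons=50)
        bad = LabeledDataset(X=np.zeros((10, 3)), y=np.zeros(10, dtype=int), task="CS")
        with pytest.raises(ValueError):
            decode_single_region(bad, n_neurons=3)

    def test_no_leakage_from_test_artifact(self):
        """A feature informative only through a test-set artifact must not
        lift shuffled-label accuracy (z-scoring/balancing fit on train)."""
        ds = _planted(effect=0.0, seed=6)
        res = decode_single_region(ds, n_neurons=20, repeats=5, seed=7)
        assert 0.35 <= res.da_shuffled <= 0.65


class TestRankBestNeurons:
    def test_perfect_coder_ranked_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (120, 5))
        y = np.repeat([0, 1], 60)
        X[y == 1, 3] += 4.0  # neuron 3 is the only coder
        ds = LabeledDataset(X=X, y=y, task="CS")
        ranking = rank_best_neurons(ds, repeats=2, seed=1)
        assert ranking[0][0] == 3

    def test_tie_breaks_on_id_order(self):
        X = np.zeros((40, 4))
        y = np.repeat([0, 1], 20)
        ds = LabeledDataset(X=X, y=y, task="CS")
        ranking = rank_best_neurons(ds, repeats=1, seed=2)
        assert [i for i, _ in ranking] == [0, 1, 2, 3]


class TestCrossStimulusTransfer:
    def test_shared_coding_transfers(self):
        a = _planted(seed=10)
        b = _planted(seed=11)  # identical coding neurons/amplitudes
        within = decode_single_region(a, n_neurons=20, repeats=3, seed=1,
                                      shuffled_control=False).da
        tr = cross_stimulus_transfer(a, b, repeats=5, seed=2)
        assert abs(tr.mean - within) <= 0.1
        assert 0.35 <= np.mean(tr.shuffled_accuracies) <= 0.65

    def test_disjoint_coding_does_not_transfer(self):
        rng = np.random.default_rng(12)
        y = np.repeat([0, 1], 80)
        Xa = rng.normal(0, 1, (160, 20))
        Xa[y == 1, :10] += 2.0
        Xb = rng.normal(0, 1, (160, 20))
        Xb[y == 1, 10:] += 2.0
        a = LabeledDataset(X=Xa, y=y, task="CS")
        b = LabeledDataset(X=Xb, y=y, task="CS")
        within = decode_single_region(a, n_neurons=20, repeats=3, seed=3,
                                      shuffled_control=False).da
        tr = cross_stimulus_transfer(a, b, repeats=5, seed=4)
        assert within >= 0.85
        assert tr.mean <= 0.6

    def test_feature_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_stimulus_transfer(_planted(n_neurons=10), _planted(n_neurons=12))


class TestDiscriminateCS:
    def test_disjoint_three_class_coding(self):
        ds = _planted(n_samples=180, n_classes=3, effect=2.5, seed=20)
        res = discriminate_cs(ds, repeats=3, seed=5)
        assert res.conditional_cs_accuracy >= 0.85
        assert not res.undefined

    def test_identical_cs_classes_near_half(self):
        rng = np.random.default_rng(21)
        y = np.repeat([0, 1, 2], 60)
        X = rng.normal(0, 1, (180, 20))
        X[y > 0, :10] += 2.0  # CS classes share one code, indistinguishable
        ds = LabeledDataset(X=X, y=y, task="CS3")
        res = discriminate_cs(ds, repeats=3, seed=6)
        assert abs(res.conditional_cs_accuracy - 0.5) <= 0.1

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            discriminate_cs(_planted(n_classes=2))


class TestMultiRegion:
    def test_largest_remainder_allocation(self):
        assert _largest_remainder({"a": 400, "b": 300, "c": 200, "d": 100}, 100) == {
            "a": 40, "b": 30, "c": 20, "d": 10,
        }

    def test_signal_region_gets_highest_importance(self):
        regions = ["aIC"] * 10 + ["pIC"] * 10 + ["CEm"] * 10
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            y = np.repeat([0, 1], 60)
            X = rng.normal(0, 1, (120, 30))
            X[y == 1, :10] += 2.0  # only aIC carries signal
            ds = LabeledDataset(X=X, y=y, task="CS", regions=regions)
            _, prof = decode_multi_region(ds, n_total=15, repeats=4, seed=seed)
            means = prof.mean_by_region()
            hits += max(means, key=means.get) == "aIC"
        assert hits == 5

    def test_importances_sum_to_one_per_iteration(self):
        regions = ["aIC"] * 6 + ["pIC"] * 6
        ds = _planted(n_neurons=12, coders=6, regions=regions, seed=30)
        _, prof = decode_multi_region(ds, n_total=12, repeats=3, seed=1)
        # full draw: per-region mean * region count sums to ~1 per iteration
        for it in range(prof.n_iterations):
            total = sum(prof.per_region[r][it] * 6 for r in ("aIC", "pIC"))
            assert total == pytest.approx(1.0, abs=1e-9)


class TestContrastImportance:
    def _profile(self, values_by_region):
        return ImportanceProfile(
            regions=list(values_by_region),
            per_region={r: np.asarray(v, dtype=float) for r, v in values_by_region.items()},
            per_neuron=np.array([]),
            n_iterations=len(next(iter(values_by_region.values()))),
        )

    def test_equal_profiles_no_effect(self):
        a = self._profile({"aIC": [0.1, 0.2, 0.15, 0.12]})
        out = contrast_importance(a, a, n_perm=500, seed=0)
        diff, p = out["aIC"]
        assert diff == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_distributions_minimal_p(self):
        a = self._profile({"aIC": np.linspace(10, 11, 12)})
        b = self._profile({"aIC": np.linspace(0, 1, 12)})
        out = contrast_importance(a, b, n_perm=2000, seed=1)
        diff, p = out["aIC"]
        assert diff == pytest.approx(10.0)
        assert p <= 1 / 1000  # only degenerate permutations reach |obs|

    def test_shifted_gaussians_detected(self):
        rng = np.random.default_rng(2)
        rej = 0
        runs = 30
        for _ in range(runs):
            va = rng.normal(0, 1, 40)
            vb = rng.normal(1, 1, 40)  # delta = 1 SD
            a = self._profile({"aIC": va})
            b = self._profile({"aIC": vb})
            _, p = contrast_importance(a, b, n_perm=400, seed=int(rng.integers(1e6)))["aIC"]
            rej += p < 0.05
        assert rej / runs >= 0.9

    def test_region_mismatch_rejected(self):
        a = self._profile({"aIC": [0.1, 0.2]})
        b = self._profile({"pIC": [0.1, 0.2]})
        with pytest.raises(ValueError):
            contrast_importance(a, b)
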