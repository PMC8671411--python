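"""Bin grid, MCC classifier, pseudo-population assembly, CV decoding."""

import numpy as np
import pytest

from fixsel.decoding import (DecodingCurve, build_pseudopopulation,
                             compare_groups, decode_sliding,
                             decoding_significance, make_bins, mcc_fit,
                             mcc_predict)
from fixsel.stats import spawn_rng


class TestBinGrid:
    def test_default_grid_last_bin(self):
        grid = make_bins(-0.6, 0.5, 0.05, 27)
        last = grid.intervals[-1]
        assert last[0] == pytest.approx(0.7)
        assert last[1] == pytest.approx(1.2)
        assert grid.centers[-1] == pytest.approx(0.95)

    def test_single_bin(self):
        grid = make_bins(0.0, 0.3, 0.1, 1)
        np.testing.assert_allclose(grid.intervals, [[0.0, 0.3]])

    def test_centers_closed_form(self):
        grid = make_bins(-1.0, 0.4, 0.07, 12)
        expect = -1.0 + 0.07 * np.arange(12) + 0.2
        np.testing.assert_allclose(grid.centers, expect)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            make_bins(0, -0.1, 0.05, 5)


class TestMcc:
    def test_template_recovery(self):
        x = np.array([[1.0, 0, 0], [3.0, 0, 0], [0, 1.0, 2.0], [0, 3.0, 6.0]])
        y = np.array(["a", "a", "b", "b"])
        templates = mcc_fit(x, y)
        np.testing.assert_allclose(templates["a"], [2.0, 0, 0])
        assert mcc_predict(templates, np.array([5.0, 0.1, 0])) == "a"
        assert mcc_predict(templates, np.array([0, 2.0, 4.1])) == "b"

    def test_exact_tie_takes_first_sorted_label(self):
        templates = {"b": np.array([1.0, 2.0]), "a": np.array([1.0, 2.0])}
        assert mcc_predict(templates, np.array([1.0, 2.0])) == "a"

    def test_zero_variance_vector_correlation_zero(self):
        templates = {"a": np.array([1.0, 2.0]), "b": np.array([2.0, 1.0])}
        # flat test vector correlates 0 with both -> tie -> first label
        assert mcc_predict(templates, np.array([3.0, 3.0])) == "a"

    def test_separable_gaussians_high_accuracy(self):
        rng = spawn_rng(1, 20)
        n, d = 200, 30
        mu_a, mu_b = rng.normal(0, 1, d), rng.normal(0, 1, d)
        xa = mu_a + 0.3 * rng.normal(size=(n, d))
        xb = mu_b + 0.3 * rng.normal(size=(n, d))
        templates = mcc_fit(np.vstack([xa[:100], xb[:100]]),
                            np.array(["a"] * 100 + ["b"] * 100))
        pred = mcc_predict(templates, np.vstack([xa[100:], xb[100:]]))
        truth = np.array(["a"] * 100 + ["b"] * 100)
        assert (pred == truth).mean() > 0.95


class TestPseudoPopulation:
    def test_tensor_shape_and_balance(self, small_session):
        session, _ = small_session
        grid = make_bins(n=5)
        pseudo = build_pseudopopulation([session], grid, n_per_class=10, seed=0)
        assert pseudo.counts.shape == (len(session.units), 20, 5)
        assert (pseudo.labels == "eyes").sum() == 10
        assert (pseudo.labels == "mouth").sum() == 10

    def test_counts_verifiable_by_hand(self, small_session):
        session, _ = small_session
        grid = make_bins(start=-0.1, width=0.2, step=0.2, n=1)
        pseudo = build_pseudopopulation([session], grid, n_per_class=5, seed=1)
        # recount one cell manually: events are sorted per class block
        u = session.units[0]
        total = pseudo.counts[0].sum()
        assert total == int(total)
        assert pseudo.counts.min() >= 0

    def test_insufficient_events_error(self, small_session):
        session, _ = small_session
        with pytest.raises(ValueError, match="insufficient"):
            build_pseudopopulation([session], make_bins(n=3),
                                   n_per_class=10_000)


class TestDecoding:
    def _toy_pseudo(self, gain, n_units=40, n_events=48, seed=0):
        """Direct Poisson pseudo-population: even units prefer 'eyes', odd
        units prefer 'mouth', with `gain`x rate in bins 2-4 of the preferred
        class. A correlation classifier needs such cross-unit *pattern*
        differences — a uniform same-sign shift would be removed by the
        per-vector centering."""
        rng = spawn_rng(seed, 21)
        grid = make_bins(-0.1, 0.1, 0.1, 6)
        base = rng.uniform(1.0, 4.0, size=n_units)
        counts = np.empty((n_units, 2 * n_events, grid.n_bins))
        labels = np.array(["eyes"] * n_events + ["mouth"] * n_events)
        for u in range(n_units):
            lam = np.full((2 * n_events, grid.n_bins), base[u] * 0.5)
            pref = slice(None, n_events) if u % 2 == 0 else slice(n_events, None)
            lam[pref, 2:5] *= gain
            counts[u] = rng.poisson(lam)
        from fixsel.decoding import PseudoPopulation
        return PseudoPopulation(counts=counts, labels=labels,
                                unit_ids=[f"u{i}" for i in range(n_units)],
                                grid=grid)

    def test_planted_gain_decoded_in_modulated_bins(self):
        pseudo = self._toy_pseudo(2.0)
        curve = decode_sliding(pseudo, n_runs=5, seed=2)
        assert curve.mean[2:5].min() > 0.8
        assert abs(curve.mean[[0, 1, 5]].mean() - 0.5) < 0.15

    def test_fixed_seed_reproducible(self):
        pseudo = self._toy_pseudo(1.5)
        a = decode_sliding(pseudo, n_runs=3, seed=7)
        b = decode_sliding(pseudo, n_runs=3, seed=7)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)

    def test_accuracy_monotone_in_gain(self):
        accs = [decode_sliding(self._toy_pseudo(g, seed=3), n_runs=3,
                               seed=4).mean[2:5].mean()
                for g in (1.0, 1.5, 2.0)]
        assert accs[0] < accs[1] < accs[2]

    def test_label_shuffle_at_chance(self):
        pseudo = self._toy_pseudo(2.0, seed=5)
        curve = decode_sliding(pseudo, n_runs=8, seed=5, shuffle_labels=True)
        assert np.abs(curve.mean - 0.5).max() < 0.08

    def test_affine_rescaling_invariance(self):
        # z-scoring absorbs per-unit affine transforms of the counts
        pseudo = self._toy_pseudo(2.0, seed=6)
        a = decode_sliding(pseudo, n_runs=2, seed=8)
        pseudo.counts = pseudo.counts * 7.0 + 3.0
        b = decode_sliding(pseudo, n_runs=2, seed=8)
        np.testing.assert_allclose(a.accuracies, b.accuracies)

    def test_insufficient_events_names_class(self):
        pseudo = self._toy_pseudo(1.0, n_events=4)
        with pytest.raises(ValueError, match="eyes|mouth"):
            decode_sliding(pseudo, k_folds=8)


class TestSignificance:
    def _curve(self, accs):
        accs = np.asarray(accs, dtype=float)
        return DecodingCurve(accuracies=accs, grid=make_bins(n=accs.shape[1]))

    def test_all_runs_above_chance(self):
        curve = self._curve(np.full((50, 4), 0.8))
        sig = decoding_significance(curve)
        np.testing.assert_allclose(sig["p_values"], 1 / 51)
        assert sig["fdr_mask"].all()

    def test_all_runs_below_chance(self):
        curve = self._curve(np.full((10, 3), 0.4))
        sig = decoding_significance(curve)
        np.testing.assert_allclose(sig["p_values"], 1.0)
        assert not sig["fdr_mask"].any()

    def test_identical_curves_not_different(self):
        a = self._curve(np.full((20, 5), 0.7))
        out = compare_groups(a, a)
        assert not out["fdr_mask"].any()

    def test_group_comparison_direction_flips_on_swap(self):
        rng = spawn_rng(9, 22)
        a = self._curve(0.75 + 0.01 * rng.normal(size=(20, 5)))
        b = self._curve(0.60 + 0.01 * rng.normal(size=(20, 5)))
        ab = compare_groups(a, b)
        ba = compare_groups(b, a)
        assert (ab["direction"] == "a>b").all()
        assert (ba["direction"] == "b>a").all()
        assert ab["fdr_mask"].all() and not ba["fdr_mask"].any()

    def test_mismatched_grids_rejected(self):
        a = self._curve(np.full((5, 4), 0.6))
        b = DecodingCurve(accuracies=np.full((5, 4), 0.6),
                          grid=make_bins(start=0.0, n=4))
        with pytest.raises(ValueError):
            compare_groups(a, b)
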