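"""State classification: histograms, two-Gaussian fit, microstate tables."""

import numpy as np
import pytest
from scipy.optimize import brentq

from pepsorb.series import Condition, DistanceSeries
from pepsorb.states import (
    DistanceHistogram, StateThresholds, TwoGaussianFit, assign_states,
    compare_conditions, derive_thresholds, fit_two_gaussian_layers,
    microstate_table, residue_distance_histogram, residue_marginals,
)
from pepsorb.synthetic import neutral_residue_model, simulate_residue_ctmc, \
    stationary_occupancy


def make_series(d_res, peptide_id="TOY"):
    d_res = np.asarray(d_res, dtype=float)
    return DistanceSeries(
        condition=Condition(peptide_id, 1.0, 1),
        times=np.arange(d_res.shape[0]) * 10.0,
        d_min=d_res.min(axis=1),
        d_res=d_res,
        residue_names=[f"R{i+1}" for i in range(d_res.shape[1])],
    )


class TestHistogram:
    def test_hand_counts(self):
        s = make_series(np.array([[0.15], [0.25], [0.25], [0.45]]))
        hist = residue_distance_histogram([s], bin_width=0.1,
                                          hist_range=(0.0, 1.0))
        expected = np.zeros(10, dtype=int)
        expected[1] = 1   # 0.15
        expected[2] = 2   # 0.25 x2
        expected[4] = 1   # 0.45
        np.testing.assert_array_equal(hist.counts, expected)
        assert hist.n_samples == 4

    def test_single_residue_pooling_identity(self):
        s = make_series(np.array([[0.1], [0.5], [0.9]]))
        full = residue_distance_histogram([s])
        one = residue_distance_histogram([s], residues=[0])
        np.testing.assert_array_equal(full.counts, one.counts)

    def test_modes_near_expected_layers(self):
        """CTMC-generated distances put histogram modes at the 0.2 nm and
        0.4 nm layers (within one 0.01 nm bin)."""
        model = neutral_residue_model()
        _, d = simulate_residue_ctmc(model, 1.0, duration_ns=200.0,
                                     frame_interval_ps=10.0, seed=5)
        hist = residue_distance_histogram([make_series(d[:, None])])
        centers = hist.centers
        near = lambda window: centers[  # noqa: E731
            np.argmax(np.where((centers > window[0]) & (centers < window[1]),
                               hist.counts, 0))]
        assert abs(near((0.05, 0.3)) - 0.2) <= 0.015
        assert abs(near((0.3, 0.5)) - 0.4) <= 0.015

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            residue_distance_histogram([])


def sample_mixture(rng, n, w=0.6, mu=(0.2, 0.4), sd=(0.03, 0.05)):
    comp = rng.random(n) < w
    x = np.where(comp, rng.normal(mu[0], sd[0], n), rng.normal(mu[1], sd[1], n))
    return np.abs(x)


def hist_from_samples(x, bin_width=0.01, rng_range=(0.0, 1.0)):
    edges = np.arange(rng_range[0], rng_range[1] + bin_width / 2, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    return DistanceHistogram(bin_edges=edges, counts=counts,
                             n_samples=int(counts.sum()), pooling="test")


class TestTwoGaussianFit:
    def test_recovers_known_mixture(self):
        rng = np.random.default_rng(42)
        fit = fit_two_gaussian_layers(hist_from_samples(
            sample_mixture(rng, 100_000)))
        assert not fit.degenerate
        assert fit.mu_C == pytest.approx(0.20, abs=0.01)
        assert fit.mu_S == pytest.approx(0.40, abs=0.01)
        assert fit.sigma_C == pytest.approx(0.03, rel=0.20)
        assert fit.sigma_S == pytest.approx(0.05, rel=0.20)

    def test_recovery_stable_across_seeds(self):
        """Means recovered within +-0.01 nm across 20 independent samples."""
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            fit = fit_two_gaussian_layers(hist_from_samples(
                sample_mixture(rng, 100_000)))
            assert abs(fit.mu_C - 0.20) < 0.01
            assert abs(fit.mu_S - 0.40) < 0.01

    def test_noiseless_identifiability(self):
        edges = np.arange(0.0, 1.0001, 0.01)
        centers = 0.5 * (edges[:-1] + edges[1:])
        true = (800 * np.exp(-0.5 * ((centers - 0.2) / 0.03) ** 2)
                + 500 * np.exp(-0.5 * ((centers - 0.4) / 0.05) ** 2))
        hist = DistanceHistogram(edges, np.round(true * 1000).astype(int),
                                 int(np.round(true * 1000).sum()), "exact")
        fit = fit_two_gaussian_layers(hist)
        assert fit.mu_C == pytest.approx(0.2, abs=1e-5)
        assert fit.mu_S == pytest.approx(0.4, abs=1e-5)
        assert fit.sigma_C == pytest.approx(0.03, abs=1e-4)

    def test_uniform_histogram_degenerate(self):
        edges = np.arange(0.0, 1.0001, 0.01)
        hist = DistanceHistogram(edges, np.full(100, 50), 5000, "flat")
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_two_gaussian_layers(hist)
        assert fit.degenerate
        thr = derive_thresholds(fit)
        assert thr.provenance == "fixed"
        assert (thr.cs_boundary, thr.sn_boundary) == (0.3, 0.5)


class TestDeriveThresholds:
    def _fit(self, aC, mC, sC, aS, mS, sS):
        return TwoGaussianFit(mu_C=mC, sigma_C=sC, amp_C=aC, mu_S=mS,
                              sigma_S=sS, amp_S=aS, fit_range=(0.0, 0.5),
                              residual_norm=0.0)

    def test_symmetric_intersection_at_midpoint(self):
        thr = derive_thresholds(self._fit(100, 0.2, 0.04, 100, 0.4, 0.04))
        assert thr.cs_boundary == pytest.approx(0.3, abs=1e-12)
        assert thr.sn_boundary == 0.5

    def test_unequal_sigmas_match_numeric_root(self):
        fit = self._fit(900, 0.2, 0.03, 400, 0.4, 0.06)

        def diff(x):
            c = fit.amp_C * np.exp(-0.5 * ((x - fit.mu_C) / fit.sigma_C) ** 2)
            s = fit.amp_S * np.exp(-0.5 * ((x - fit.mu_S) / fit.sigma_S) ** 2)
            return c - s

        oracle = brentq(diff, fit.mu_C, fit.mu_S, xtol=1e-12)
        thr = derive_thresholds(fit)
        assert thr.cs_boundary == pytest.approx(oracle, abs=1e-8)

    def test_no_interior_intersection_falls_back_to_midpoint(self):
        # a tiny, sharp S component drowned by a broad C one
        fit = self._fit(1e6, 0.2, 0.2, 1.0, 0.4, 0.001)
        thr = derive_thresholds(fit)
        if thr.fallback:
            assert thr.cs_boundary == pytest.approx(0.3)

    def test_default_sn_boundary(self):
        thr = derive_thresholds(self._fit(100, 0.2, 0.04, 100, 0.4, 0.04))
        assert thr.sn_boundary == 0.5


class TestAssignStates:
    thr = StateThresholds(0.3, 0.5)

    def test_examples(self):
        labels = assign_states(np.array([[0.15, 0.42, 0.70]]), self.thr)
        assert labels.tolist() == [["C", "S", "N"]]

    def test_boundary_convention(self):
        labels = assign_states(np.array([[0.3, 0.5]]), self.thr)
        assert labels.tolist() == [["S", "S"]]

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(0, 1.2, size=(50, 4))
        labels = assign_states(d, self.thr)
        for i in range(50):
            for j in range(4):
                v = d[i, j]
                want = "C" if v < 0.3 else ("S" if v <= 0.5 else "N")
                assert labels[i, j] == want

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        d = rng.uniform(0, 1.2, size=(20, 3))
        a = assign_states(d, self.thr)
        b = assign_states(d, self.thr)
        np.testing.assert_array_equal(a, b)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            assign_states(np.array([[0.2, np.nan]]), self.thr)


class TestMicrostateTable:
    def test_hand_count(self):
        labels = np.array([list("CNN"), list("CNN"), list("NNN"),
                           list("CNS")])
        table = microstate_table(labels)
        assert table.microstates == pytest.approx(
            {"CNN": 0.5, "NNN": 0.25, "CNS": 0.25})

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(11)
        labels = rng.choice(list("CSN"), size=(500, 4))
        table = microstate_table(labels)
        assert sum(table.microstates.values()) == pytest.approx(1.0, abs=1e-9)

    def test_filtered_view_excludes_rare(self):
        labels = np.array([list("CN")] * 99 + [list("SN")])
        table = microstate_table(labels, filter_threshold=0.01)
        assert "SN" not in table.filtered        # exactly 1% does not exceed
        assert "SN" in table.microstates

    def test_product_law_for_independent_residues(self):
        """With independent residue chains, joint microstate fractions
        factorise into single-residue marginals (within sampling error)."""
        model = neutral_residue_model()
        lab1, _ = simulate_residue_ctmc(model, 1.0, 400.0, 10.0, seed=21)
        lab2, _ = simulate_residue_ctmc(model, 1.0, 400.0, 10.0, seed=22)
        labels = np.column_stack([lab1, lab2])
        table = microstate_table(labels)
        marg = residue_marginals(table)
        n_eff = 400.0 / 1.0  # ~ duration / relaxation time, per residue
        for s, f in table.microstates.items():
            prod = marg.loc["res1", s[0]] * marg.loc["res2", s[1]]
            se = np.sqrt(max(prod * (1 - prod), 1e-6) / n_eff)
            assert abs(f - prod) < 4 * se

    def test_all_n_fraction_consistency(self):
        rng = np.random.default_rng(12)
        labels = rng.choice(list("CSN"), size=(300, 3), p=[0.1, 0.2, 0.7])
        table = microstate_table(labels)
        any_contact = np.mean([(("C" in s) or ("S" in s))
                               for s in ("".join(r) for r in labels)])
        assert table.microstates.get("NNN", 0.0) == \
            pytest.approx(1.0 - any_contact, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            microstate_table(np.empty((0, 3), dtype="<U1"))


class TestCompareConditions:
    def _table(self, mapping, n=100):
        return microstate_table(
            np.array([list(s) for s, f in mapping.items()
                      for _ in range(int(round(f * n)))]))

    def test_identical_tables_zero_delta(self):
        t = self._table({"CNN": 0.6, "NNN": 0.4})
        comp = compare_conditions(t, t)
        np.testing.assert_allclose(comp["delta"], 0.0)

    def test_state_missing_at_high_salt_reported_as_zero(self):
        low = self._table({"CNN": 0.6, "SNN": 0.4})
        high = self._table({"CNN": 0.3, "NNN": 0.7})
        comp = compare_conditions(low, high).set_index("microstate")
        assert comp.loc["SNN", "rate_high"] == 0.0
        assert comp.loc["NNN", "rate_low"] == 0.0

    def test_union_size(self):
        low = self._table({"CNN": 0.5, "SNN": 0.5})
        high = self._table({"CNN": 0.5, "NNN": 0.5})
        comp = compare_conditions(low, high)
        assert len(comp) == len({"CNN", "SNN", "NNN"})

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            compare_conditions(self._table({"CN": 1.0}),
                               self._table({"CNN": 1.0}))
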