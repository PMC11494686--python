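import numpy as np
import pytest

import hopfec as h
from hopfec.connectivity import split_indices
from hopfec.validation import (BENCHMARK_HOPF, benchmark_network,
                               offdiag_correlation, simulate_group)

TR = 0.8


def run(values, labels=None):
    values = np.asarray(values, float)
    labels = labels or [f"r{i}" for i in range(values.shape[1])]
    return h.TimeseriesRun(values, TR, labels)


#: small fit configuration: enough iterations to exercise the machinery
FAST_FIT = dict(max_iter=20, patience=20, sim_length_samples=300)


@pytest.fixture(scope="module")
def small_group():
    """FC / lagged FC for 6 participants from a 6-region benchmark network."""
    net = benchmark_network(n=6, density=0.3, seed=3)
    fcs, lagfcs = simulate_group(net, BENCHMARK_HOPF, n_participants=6,
                                 n_samples=696, data_seed=42, lag_samples=3)
    return net, fcs, lagfcs


class TestFunctionalConnectivity:
    def test_duplicated_region_correlates_at_one(self):
        x = np.random.default_rng(0).normal(size=(50, 1))
        fc = h.functional_connectivity(run(np.hstack([x, x])), band=None)
        assert fc.values[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_negated_copy_correlates_at_minus_one(self):
        x = np.random.default_rng(1).normal(size=(50, 1))
        fc = h.functional_connectivity(run(np.hstack([x, -x])), band=None)
        assert fc.values[0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_matches_bruteforce_formula(self):
        x = np.random.default_rng(2).normal(size=(50, 3))
        fc = h.functional_connectivity(run(x), band=None).values
        for i in range(3):
            for j in range(3):
                xi, xj = x[:, i] - x[:, i].mean(), x[:, j] - x[:, j].mean()
                expected = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
                assert fc[i, j] == pytest.approx(expected, rel=1e-10)

    def test_symmetry_unit_diagonal_range(self, small_group):
        _, fcs, _ = small_group
        for fc in fcs:
            np.testing.assert_allclose(fc.values, fc.values.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(fc.values), 1.0)
            assert np.abs(fc.values).max() <= 1.0 + 1e-12

    def test_zero_variance_region_named(self):
        x = np.random.default_rng(3).normal(size=(50, 2))
        x[:, 1] = 4.2
        with pytest.raises(ValueError, match="r1"):
            h.functional_connectivity(run(x), band=None)


class TestLaggedFC:
    def test_zero_lag_equals_plain_fc(self):
        x = np.random.default_rng(4).normal(size=(60, 3))
        fc = h.functional_connectivity(run(x), band=None).values
        lfc = h.lagged_fc(run(x), 0, band=None).values
        np.testing.assert_allclose(lfc, fc, atol=1e-12)

    def test_exact_lagged_copy_scores_one(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=200)
        k = 4
        # x1 is x0 delayed by k samples: x1(t + k) = x0(t), so entry (0, 1) = 1
        x = np.column_stack([base[k:], base[:-k]])
        lfc = h.lagged_fc(run(x), k, band=None)
        assert lfc.values[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_matches_bruteforce_shifted_loop(self):
        x = np.random.default_rng(6).normal(size=(40, 2))
        lag = 3
        got = h.lagged_fc(run(x), lag, band=None).values
        for i in range(2):
            for j in range(2):
                a, b = x[:-lag, i], x[lag:, j]
                expected = np.corrcoef(a, b)[0, 1]
                assert got[i, j] == pytest.approx(expected, rel=1e-10)

    def test_out_of_range_lag_rejected(self):
        x = np.random.default_rng(7).normal(size=(20, 2))
        with pytest.raises(ValueError, match="out of range"):
            h.lagged_fc(run(x), 19, band=None)

    def test_tau_to_lag_rounding(self):
        assert h.GECConfig(tau_seconds=2.0).lag_samples(0.8) == 3
        assert h.GECConfig(tau_seconds=1.6).lag_samples(0.8) == 2
        with pytest.raises(ValueError, match="below one TR"):
            h.GECConfig(tau_seconds=0.2).lag_samples(0.8)


class TestFisherAveraging:
    def test_zero_mean_is_zero(self):
        out = h.fisher_z_mean([np.zeros((3, 3)), np.zeros((3, 3))])
        np.testing.assert_allclose(out, 0.0)

    def test_two_matrix_average_matches_formula(self):
        rng = np.random.default_rng(8)
        mats = [np.clip(rng.uniform(-0.9, 0.9, (4, 4)), -1, 1) for _ in range(2)]
        for m in mats:
            np.fill_diagonal(m, 1.0)
        out = h.fisher_z_mean(mats)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                expected = np.tanh(0.5 * (np.arctanh(mats[0][i, j])
                                          + np.arctanh(mats[1][i, j])))
                assert out[i, j] == pytest.approx(expected, rel=1e-10)


@pytest.fixture(scope="module")
def fitted(small_group):
    net, fcs, lagfcs = small_group
    cfg = h.GECConfig(seed=13, **FAST_FIT)
    return h.group_gec(fcs, lagfcs, BENCHMARK_HOPF, cfg)


class TestECOperations:
    def test_entries_respect_clip(self, fitted):
        assert fitted.values.min() >= 0.0
        assert fitted.values.max() <= 0.2
        assert np.all(np.diag(fitted.values) == 0)

    def test_running_minimum_non_increasing(self, fitted):
        rm = fitted.diagnostics["running_min"]
        assert all(b <= a + 1e-15 for a, b in zip(rm, rm[1:]))

    def test_reversal_is_involution(self, fitted):
        twice = h.reverse_directionality(h.reverse_directionality(fitted))
        np.testing.assert_array_equal(twice.values, fitted.values)
        assert twice.reversed == fitted.reversed

    def test_reversal_transposes_and_flags(self, fitted):
        rev = h.reverse_directionality(fitted)
        np.testing.assert_array_equal(rev.values, fitted.values.T)
        assert rev.reversed != fitted.reversed

    def test_symmetric_matrix_unchanged_by_reversal(self):
        S = np.array([[0, 0.1], [0.1, 0]])
        ec = h.ECMatrix(S, ["a", "b"])
        rev = h.reverse_directionality(ec)
        np.testing.assert_array_equal(rev.values, S)
        assert rev.reversed

    def test_directional_difference_antisymmetric(self, fitted):
        D = h.directional_difference(fitted)
        np.testing.assert_array_equal(D, -D.T)

    def test_directional_difference_arithmetic(self):
        ec = h.ECMatrix(np.array([[0.0, 0.1], [0.04, 0.0]]), ["a", "b"])
        D = h.directional_difference(ec)
        assert D[0, 1] == pytest.approx(0.06)
        assert D[1, 0] == pytest.approx(-0.06)

    def test_label_mismatch_rejected(self, small_group):
        _, fcs, lagfcs = small_group
        bad = h.LaggedFC(lagfcs[0].values, ["x"] * 6, 3, 2.4)
        with pytest.raises(ValueError, match="label mismatch"):
            h.fit_gec(fcs[0], bad, BENCHMARK_HOPF, h.GECConfig(seed=1, **FAST_FIT))


class TestGroupAndSplitHalf:
    def test_identical_participants_match_single_fit(self, small_group):
        _, fcs, lagfcs = small_group
        cfg = h.GECConfig(seed=17, **FAST_FIT)
        single = h.fit_gec(fcs[0], lagfcs[0], BENCHMARK_HOPF, cfg)
        group = h.group_gec([fcs[0]] * 3, [lagfcs[0]] * 3, BENCHMARK_HOPF, cfg)
        np.testing.assert_allclose(group.values, single.values, atol=1e-12)

    def test_inconsistent_labels_rejected(self, small_group):
        _, fcs, lagfcs = small_group
        other = h.FCMatrix(fcs[1].values, ["x"] * 6)
        with pytest.raises(ValueError, match="inconsistent labels"):
            h.group_gec([fcs[0], other], lagfcs[:2], BENCHMARK_HOPF,
                        h.GECConfig(seed=1, **FAST_FIT))

    def test_split_sizes_11_and_12_for_23(self):
        a, b = split_indices(23, split_seed=5)
        assert sorted((len(a), len(b))) == [11, 12]
        assert sorted(np.concatenate([a, b])) == list(range(23))

    def test_zero_between_participant_variability_gives_r_near_one(self, small_group):
        _, fcs, lagfcs = small_group
        cfg = h.GECConfig(seed=19, **FAST_FIT)
        r = h.split_half_reliability([fcs[0]] * 6, [lagfcs[0]] * 6, BENCHMARK_HOPF,
                                     cfg, split_seed=1)
        assert r > 0.95

    def test_unrelated_networks_correlate_within_null_band(self):
        """Group ECs fitted to cohorts from independent networks: r ~ 0."""
        cfg = h.GECConfig(seed=23, max_iter=40, patience=40, sim_length_samples=300)
        ecs = []
        for net_seed, data_seed in ((101, 201), (102, 202)):
            net = benchmark_network(n=6, density=0.3, seed=net_seed)
            fcs, lagfcs = simulate_group(net, BENCHMARK_HOPF, n_participants=4,
                                         n_samples=696, data_seed=data_seed,
                                         lag_samples=3)
            ecs.append(h.group_gec(fcs, lagfcs, BENCHMARK_HOPF, cfg))
        r = offdiag_correlation(ecs[0].values, ecs[1].values)
        # null band for 30 off-diagonal entries at the 1% level
        assert abs(r) < 2.58 / np.sqrt(30 - 3)

    def test_too_few_participants_rejected(self, small_group):
        _, fcs, lagfcs = small_group
        with pytest.raises(ValueError, match="at least 4"):
            h.split_half_reliability(fcs[:3], lagfcs[:3], BENCHMARK_HOPF,
                                     h.GECConfig(seed=1, **FAST_FIT))
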