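import json

import numpy as np
import pytest

import hopfec as h
from hopfec.synth import paradigm_regressor


class TestGroundTruthNetwork:
    def test_zero_density_gives_empty_network(self):
        net = h.make_ground_truth_network(6, 0.0, seed=1)
        assert not net.C.any()

    def test_edge_count_matches_replayed_rng_stream(self):
        # oracle: replay the same seeded draws that the generator makes
        net = h.make_ground_truth_network(10, 0.3, seed=1)
        rng = np.random.default_rng(1)
        edges = rng.random((10, 10)) < 0.3
        np.fill_diagonal(edges, False)
        assert np.count_nonzero(net.C) == edges.sum()

    def test_entries_within_cap(self):
        net = h.make_ground_truth_network(12, 0.9, strength_scale=5.0, seed=2)
        assert net.C.max() <= 0.2
        assert np.all(np.diag(net.C) == 0)

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            h.make_ground_truth_network(5, 1.5)

    def test_seeded_determinism(self):
        a = h.make_ground_truth_network(8, 0.4, seed=7)
        b = h.make_ground_truth_network(8, 0.4, seed=7)
        np.testing.assert_array_equal(a.C, b.C)


class TestHopfSimulation:
    def test_supercritical_amplitude_reaches_sqrt_a(self):
        # noiseless Hopf normal form: limit cycle radius sqrt(a); fine dt so
        # the Euler rotation error (~omega^2 dt / 2 on r^2) stays within 2%
        net = h.GroundTruthNetwork(np.zeros((1, 1)))
        hp = h.HopfParams(a=0.04, sigma=0.0, dt=0.01, burn_in=300.0)
        x, y = h.simulate_hopf(net, hp, h.AcquisitionParams(tr=0.8, n_samples=100),
                               seed=1, return_y=True)
        radius = np.sqrt(x**2 + y**2)[-50:].mean()
        assert radius == pytest.approx(np.sqrt(0.04), rel=0.02)

    def test_subcritical_noiseless_decays_to_zero(self):
        net = h.GroundTruthNetwork(np.zeros((2, 2)))
        hp = h.HopfParams(a=-0.02, sigma=0.0, burn_in=0.0)
        x = h.simulate_hopf(net, hp, h.AcquisitionParams(tr=0.8, n_samples=696), seed=3)
        early = np.abs(x[:50]).mean()
        late = np.abs(x[-50:]).mean()
        assert late < 0.2 * early

    def test_uncoupled_nodes_uncorrelated_within_surrogate_band(self):
        net = h.GroundTruthNetwork(np.zeros((2, 2)))
        x = h.simulate_hopf(net, h.HopfParams(), h.AcquisitionParams(), seed=4)
        r_obs = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
        # circular-shift surrogates preserve each node's autocorrelation
        rng = np.random.default_rng(0)
        null = []
        for _ in range(200):
            shift = rng.integers(50, 646)
            null.append(np.corrcoef(x[:, 0], np.roll(x[:, 1], shift))[0, 1])
        assert abs(r_obs) < np.quantile(np.abs(null), 0.99)

    def test_non_integer_tr_over_dt_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            h.simulate_hopf(h.GroundTruthNetwork(np.zeros((1, 1))),
                            h.HopfParams(dt=0.3), h.AcquisitionParams(), seed=0)

    def test_divergence_raises_with_step_index(self):
        hp = h.HopfParams(a=100.0, sigma=0.0, dt=0.4, burn_in=0.0)
        with pytest.raises(FloatingPointError, match="step"):
            h.simulate_hopf(h.GroundTruthNetwork(np.zeros((1, 1))), hp,
                            h.AcquisitionParams(tr=0.8, n_samples=100), seed=1)

    def test_seeded_determinism(self):
        net = h.make_ground_truth_network(4, 0.5, seed=2)
        acq = h.AcquisitionParams(tr=0.8, n_samples=100)
        a = h.simulate_hopf(net, h.HopfParams(), acq, seed=11)
        b = h.simulate_hopf(net, h.HopfParams(), acq, seed=11)
        np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def roi_sets():
    return {"target": h.ROISet("target", ("VMV1",))}


class TestTaskModulation:
    def make_run(self, scheme, task="object_location", seed=0, sigma=0.0):
        acq = h.AcquisitionParams()
        values = h.simulate_hopf(
            h.GroundTruthNetwork(np.zeros((scheme.n_regions,) * 2)),
            h.HopfParams(sigma=sigma), acq, seed=seed)
        return h.SimulatedRun(values, acq, h.build_task_design(task),
                              scheme.column_labels, "sub-01", task)

    def test_zero_gain_is_identity(self, tiny_scheme, roi_sets):
        run = self.make_run(tiny_scheme)
        eff = h.EffectSpec(roi="target", gain=0.0)
        out = h.apply_task_modulation(run, [eff], tiny_scheme, roi_sets)
        np.testing.assert_array_equal(out.values, run.values)

    def test_untargeted_regions_bit_identical(self, tiny_scheme, roi_sets):
        run = self.make_run(tiny_scheme, sigma=0.01)
        eff = h.EffectSpec(roi="target", gain=1.0, hemisphere="L")
        out = h.apply_task_modulation(run, [eff], tiny_scheme, roi_sets)
        target = tiny_scheme.position("VMV1", "L")
        untouched = [i for i in range(tiny_scheme.n_regions) if i != target]
        np.testing.assert_array_equal(out.values[:, untouched], run.values[:, untouched])
        assert not np.array_equal(out.values[:, target], run.values[:, target])

    def test_doubled_gain_doubles_added_component_rmssd(self, tiny_scheme, roi_sets):
        run = self.make_run(tiny_scheme)
        col = tiny_scheme.position("VMV1", "L")
        outs = []
        for gain in (1.0, 2.0):
            eff = h.EffectSpec(roi="target", gain=gain, hemisphere="L")
            out = h.apply_task_modulation(run, [eff], tiny_scheme, roi_sets)
            outs.append(out.values[:, col] - run.values[:, col])
        assert h.rmssd(outs[1]) == pytest.approx(2.0 * h.rmssd(outs[0]), rel=1e-10)

    def test_right_only_effect_gives_positive_laterality(self, tiny_scheme, roi_sets):
        import pandas as pd
        run = self.make_run(tiny_scheme)
        eff = h.EffectSpec(roi="target", gain=1.0, hemisphere="R", phase="storage")
        out = h.apply_task_modulation(run, [eff], tiny_scheme, roi_sets)
        act = h.activation_from_run(out.as_timeseries(), run.design, "storage")
        table = h.ActivationTable(pd.DataFrame([act], index=["sub-01"],
                                               columns=tiny_scheme.column_labels),
                                  "object_location", "storage")
        lat, _ = h.laterality(table, tiny_scheme)
        assert lat.loc["sub-01", "VMV1"] > 0
        # untargeted regions carry only the decaying transient, far below the effect
        assert lat.loc["sub-01", "VMV1"] > 5 * lat.abs().loc["sub-01", "V1"]

    def test_unknown_roi_rejected(self, tiny_scheme, roi_sets):
        run = self.make_run(tiny_scheme)
        with pytest.raises(KeyError, match="nonexistent"):
            h.apply_task_modulation(run, [h.EffectSpec(roi="nonexistent")],
                                    tiny_scheme, roi_sets)

    def test_regressor_peaks_follow_trials(self, tiny_scheme):
        design = h.build_task_design("object_location")
        reg = paradigm_regressor(design, h.AcquisitionParams(), "storage")
        assert reg.max() == pytest.approx(1.0)
        # response is zero before the first encoding image can act (onset 10 s)
        assert np.abs(reg[: int(10 / 0.8)]).max() < 1e-12


class TestCohortGeneration:
    def test_manifest_counts_and_row_counts(self, noisy_small_cohort):
        man = noisy_small_cohort["manifest"]
        assert man["n_participants"] == 3
        # one timeseries + events + sidecar per participant x task
        assert len(man["files"]) == 3 * 1 * 3
        ts = h.load_run(noisy_small_cohort["dir"], "sub-01", "object_location")
        assert ts.values.shape == (696, 8)

    def test_regeneration_reproduces_digests(self, noisy_small_cohort, tmp_path):
        again = h.generate_cohort(noisy_small_cohort["spec"], tmp_path / "again")
        d1 = {f["path"]: f["sha256"] for f in noisy_small_cohort["manifest"]["files"]}
        d2 = {f["path"]: f["sha256"] for f in again["files"]}
        assert d1 == d2

    def test_sidecar_metadata(self, noisy_small_cohort):
        sc = json.loads((noisy_small_cohort["dir"]
                         / "sub-02_task-object_location_bold.json").read_text())
        assert sc["TR"] == 0.8
        assert sc["participant"] == "sub-02"
        assert sc["task"] == "object_location"
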