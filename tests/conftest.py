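import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hopfec as h

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def full_scheme():
    return h.default_scheme()


@pytest.fixture(scope="session")
def roi_scheme(full_scheme):
    """Reduced scheme containing every a-priori ROI label plus visual regions."""
    labels = []
    for rs in h.apriori_roi_sets(full_scheme).values():
        labels.extend(rs.labels)
    labels.extend(["V1", "V2", "V3", "V4", "FFC", "PIT", "V8", "TE2p"])
    return full_scheme.subset(dict.fromkeys(labels))


@pytest.fixture(scope="session")
def tiny_scheme(full_scheme):
    """Four region pairs: enough for hemisphere and laterality logic."""
    return full_scheme.subset(["V1", "V2", "VMV1", "PHA1"])


@pytest.fixture(scope="session")
def noiseless_cohort(tmp_path_factory, tiny_scheme):
    """Deterministic cohort with no oscillator noise and a known injected effect.

    Scene-ROI storage effect in the object_location task only, so activation
    contrasts have an exact ground truth.
    """
    roi_sets = {"scene_pair": h.ROISet("scene_pair", ("VMV1", "PHA1"))}
    spec = h.CohortSpec(
        scheme=tiny_scheme,
        network=h.GroundTruthNetwork(np.zeros((8, 8))),
        hopf=h.HopfParams(sigma=0.0),
        effects=(h.EffectSpec(roi="scene_pair", task="object_location",
                              phase="storage", gain=1.0, base_amplitude=0.05),),
        n_participants=4,
        tasks=("object_location", "word_pair"),
        seed=5,
        subject_gain_jitter_sd=0.0,
        subject_coupling_jitter_sd=0.0,
        roi_sets=roi_sets,
    )
    out = tmp_path_factory.mktemp("noiseless_cohort")
    manifest = h.generate_cohort(spec, out)
    return {"dir": out, "spec": spec, "manifest": manifest, "scheme": tiny_scheme}


@pytest.fixture(scope="session")
def noisy_small_cohort(tmp_path_factory, tiny_scheme):
    """Small noisy cohort for determinism and shape contracts."""
    spec = h.CohortSpec(
        scheme=tiny_scheme,
        network=h.make_ground_truth_network(8, 0.2, seed=3),
        hopf=h.HopfParams(),
        effects=(),
        n_participants=3,
        tasks=("object_location",),
        seed=9,
    )
    out = tmp_path_factory.mktemp("noisy_cohort")
    manifest = h.generate_cohort(spec, out)
    return {"dir": out, "spec": spec, "manifest": manifest, "scheme": tiny_scheme}
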