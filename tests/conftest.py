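import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ramancell as rc
from ramancell.preprocessing import (
    estimate_background,
    infer_cell_mask,
    normalize_map,
    split_regions,
    subtract_background,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def preprocess_fingerprint(smap, mask=None, estimator="mean"):
    """Mask → split → background-subtract → normalize; fingerprint region."""
    if mask is None:
        mask = infer_cell_mask(smap)
    fp = split_regions(smap).fingerprint
    fp = subtract_background(fp, estimate_background(fp, mask, estimator))
    fp, constant = normalize_map(fp)
    return fp, mask, constant


def analyze_experiment(experiment, seed=0, k=7, n_pcs=6, n_restarts=20):
    """Preprocess + pooled PCA + K-means for a simulated experiment.

    Returns (dataset, kmeans model, summary, truths) with the extracellular
    cluster identified.
    """
    maps, truths = [], []
    for smap, truth in experiment:
        fp, _, _ = preprocess_fingerprint(smap)
        maps.append(fp)
        truths.append(truth)
    dataset = rc.pool_maps(maps)
    pca = rc.fit_pca(dataset)
    scores = rc.project(dataset, pca, K=n_pcs)
    km = rc.fit_kmeans(scores, k=k, seed=seed, n_restarts=n_restarts)
    rc.identify_outside_cluster(km, dataset)
    summary = rc.summarize_clusters(km, dataset)
    return dataset, km, summary, truths


def pooled_truth_labels(truths):
    return np.concatenate([t.region_label.ravel() for t in truths])


@pytest.fixture(scope="session")
def toy_axis():
    return rc.WavenumberAxis(np.array([400.0, 500.0, 600.0]))


@pytest.fixture(scope="session")
def default_axis():
    return rc.default_axis()


@pytest.fixture(scope="session")
def components():
    return rc.default_components()


@pytest.fixture(scope="session")
def quiet_scene_map(components, default_axis):
    """One noise-free iPSC-like cell with ground truth."""
    scene = rc.generate_cell_scene(48, 48, seed=7)
    smap = rc.simulate_map(
        scene, components, rc.LineProfile.ipsc_like(), rc.NoiseModel.quiet(),
        default_axis, map_id="quiet_ipsc",
    )
    return smap, scene


@pytest.fixture(scope="session")
def discrimination_analysis():
    """One planted-difference experiment (dna ×2) fully analyzed; shared by
    score-displacement, cluster-map and band tests."""
    experiment = rc.generate_experiment(n_per_line=3, dna_scale_ipsc=2.0, seed=11)
    dataset, km, summary, truths = analyze_experiment(experiment, seed=0)
    return {
        "experiment": experiment,
        "dataset": dataset,
        "kmeans": km,
        "summary": summary,
        "truths": truths,
    }
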