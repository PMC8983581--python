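"""Shared fixtures: small synthetic scenes analysed once per session."""

import numpy as np
import pytest

from punctaquant import SceneParams, generate_cell_stack
from punctaquant.pipeline import RunConfig, analyze_stack


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free 50-punctum scene with the default geometry."""
    params = SceneParams(puncta_count=50, poisson_scale=0.0, gaussian_sd=0.0, seed=7)
    stack, truth = generate_cell_stack(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def clean_analysis(clean_scene):
    """Full pipeline output for the clean scene."""
    params, stack, truth = clean_scene
    config = RunConfig(psf_sigma_um=params.psf_sigma)
    nuclei, puncta, cells = analyze_stack(stack, config)
    return params, stack, truth, nuclei, puncta, cells


def match_detections(records, truth, tol_um=0.3):
    """Greedy nearest matching of detected centroids to true centres.

    Returns (recall, precision, matched_pairs) where matched_pairs is a
    list of (record, truth_index).
    """
    from scipy.spatial import cKDTree

    if not records:
        return 0.0, float("nan"), []
    centers = np.asarray(truth.centers_um)
    tree = cKDTree(centers)
    dist, idx = tree.query(np.asarray([r.centroid for r in records]))
    pairs = [(rec, int(i)) for rec, d, i in zip(records, dist, idx) if d < tol_um]
    recall = len({i for _, i in pairs}) / len(centers)
    precision = len(pairs) / len(records)
    return recall, precision, pairs
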