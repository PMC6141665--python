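"""Glucose-residue formula, normalized density, per-ROI metrics, stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glycopap import (GrParams, compute_roi_metrics, generate_study,
                      glucose_residues, normalized_density, stratify,
                      compute_distances)
from glycopap.errors import ValidationError
from glycopap.model import StudyDataset

# frozen 30-digit evaluation of 13 * (2**(27.2/3.8) - 1)
GR_27_2 = 1843.45477515520866169798783005


def test_gr_base_cases():
    assert glucose_residues(0.0) == 0.0
    assert glucose_residues(3.8) == 13.0          # exponent exactly 1: one chain tier
    assert glucose_residues(27.2) == pytest.approx(GR_27_2, rel=1e-12)


def test_gr_rejects_negative_diameter_and_bad_params():
    with pytest.raises(ValidationError):
        glucose_residues(-1.0)
    with pytest.raises(ValidationError):
        GrParams(tier_length_nm=0.0)


def test_gr_monotone_and_recurrence():
    """GR(d + 2L) = b GR(d) + c (b - 1) on a diameter grid."""
    p = GrParams()
    d = np.linspace(0.0, 60.0, 100)
    gr = glucose_residues(d, p)
    assert np.all(np.diff(glucose_residues(np.sort(d), p)) > 0)
    lhs = glucose_residues(d + 2 * p.tier_length_nm, p)
    rhs = p.branching_degree * gr + p.residues_per_chain * (p.branching_degree - 1)
    assert np.allclose(lhs, rhs, rtol=1e-9)


@given(st.floats(min_value=0.0, max_value=80.0), st.floats(min_value=0.01, max_value=80.0))
@settings(derandomize=True, max_examples=50)
def test_gr_strictly_increasing_property(d, delta):
    assert glucose_residues(d + delta) > glucose_residues(d)


def test_normalized_density():
    assert normalized_density(10, 0.1) == pytest.approx(100.0, rel=1e-12)
    assert normalized_density(0, 2.5) == 0.0
    with pytest.raises(ValidationError):
        normalized_density(5, 0.0)
    rng = np.random.default_rng(0)
    for _ in range(20):
        n, v = int(rng.integers(0, 500)), float(rng.uniform(0.01, 5.0))
        assert normalized_density(n, v) == pytest.approx(n / v, rel=1e-12)


def _toy_dataset(diams=(1e-9, 3.8)):
    """Two ROIs in one condition; the second ROI is empty."""
    rois = pd.DataFrame({
        "roi_id": ["r0", "r1"], "condition": ["S", "S"], "mouse_id": ["m1", "m1"],
        "bbox_x_nm": 0.0, "bbox_y_nm": 0.0, "bbox_z_nm": 0.0,
        "edge_x_nm": 3000.0, "edge_y_nm": 3000.0, "edge_z_nm": 3000.0,
        "roi_volume_um3": 27.0, "astro_volume_um3": 2.0, "asi_area_um2": 0.2,
        "ser_flag": [True, False], "mito_flag": [False, False],
        "asi_mesh_ref": ["r0", "r1"],
    })
    granules = pd.DataFrame({
        "granule_id": [f"g{i}" for i in range(len(diams))],
        "roi_id": "r0", "x_nm": 100.0, "y_nm": 100.0, "z_nm": 100.0,
        "diameter_nm": list(diams),
    })
    return StudyDataset(granules=granules, rois=rois, meshes={}, meta={})


def test_compute_roi_metrics_mean_gr_and_empty_roi():
    ds = _toy_dataset(diams=(0.0, 3.8))   # GR values 0 and 13
    empty = pd.DataFrame(columns=["granule_id", "roi_id", "distance_nm", "within_window"])
    m = compute_roi_metrics(ds, empty).set_index("roi_id")
    assert m.loc["r0", "mean_gr"] == pytest.approx(6.5, rel=1e-12)
    assert m.loc["r0", "granule_count"] == 2
    assert m.loc["r0", "density"] == pytest.approx(1.0, rel=1e-12)
    assert m.loc["r1", "granule_count"] == 0
    assert m.loc["r1", "density"] == 0.0
    assert np.isnan(m.loc["r1", "mean_gr"])


def test_granule_count_conservation(small_study):
    distances = compute_distances(small_study)
    m = compute_roi_metrics(small_study, distances)
    assert m["granule_count"].sum() == len(small_study.granules)
    # density agrees with an independent group-by
    counts = small_study.granules["roi_id"].value_counts()
    vols = small_study.rois.set_index("roi_id")["astro_volume_um3"]
    expect = (counts.reindex(vols.index).fillna(0) / vols)
    got = m.set_index("roi_id")["density"].reindex(vols.index)
    assert np.allclose(got, expect, rtol=1e-12)


def test_per_condition_mean_density_groupby_oracle(small_study, small_report):
    distances = compute_distances(small_study)
    m = compute_roi_metrics(small_study, distances)
    oracle = m.groupby("condition")["density"].mean()
    table = small_report.per_condition_tables["density"].set_index("condition")
    for cond, val in oracle.items():
        assert table.loc[cond, "mean"] == pytest.approx(val, rel=1e-12)


def test_density_scaling_invariance():
    """Scaling lengths by k scales volume by k^3 and density by k^-3."""
    k = 2.0
    assert normalized_density(50, 0.4 * k ** 3) == pytest.approx(
        normalized_density(50, 0.4) / k ** 3, rel=1e-12)


def test_stratify_partition():
    ds = _toy_dataset()
    empty = pd.DataFrame(columns=["granule_id", "roi_id", "distance_nm", "within_window"])
    m = compute_roi_metrics(ds, empty)
    parts = stratify(m, "ser_flag")
    pos, neg = parts["S"]
    assert len(pos) == 1 and len(neg) == 1
    assert len(pos) + len(neg) == len(m)
    # all-true flag leaves an empty, well-formed complement
    m2 = m.assign(mito_flag=True)
    pos2, neg2 = stratify(m2, "mito_flag")["S"]
    assert len(pos2) == 2 and len(neg2) == 0


def test_ser_prevalence_matches_binomial_sampling():
    """S condition at 57.5% SER prevalence, n = 308: within 3 binomial SE."""
    from glycopap import default_config

    cfg = {"S": default_config()["S"]}
    ds = generate_study(cfg, seed=11)
    p_hat = ds.rois["ser_flag"].mean()
    se = np.sqrt(0.575 * 0.425 / 308)
    assert abs(p_hat - 0.575) <= 3 * se
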