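"""Per-granule and per-ROI glycogen metrics.

Glycogen granules grow in concentric tiers of branching glucose chains. With
``c`` residues per chain (13 on average), branching degree ``b`` (2) and
tier thickness ``L`` (~1.9 nm), a granule of diameter ``d`` holds an
estimated

    GR(d) = c * (b ** (d / (2 L)) - 1)

glucose residues: ``d / (2 L)`` is the number of tiers spanned by the radius
and each tier doubles the number of chains. GR(0) = 0 and GR(2L) = c.

Granule density is normalised to the astrocytic volume inside each ROI
(granules per um^3 of astrocyte), since glycogen lives only in the
astrocytic compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import per_roi_mean_distances
from .model import StudyDataset
from . import geometry

ROI_METRIC_COLUMNS = [
    "roi_id", "condition", "mouse_id", "granule_count", "density",
    "mean_gr", "mean_distance", "coverage", "asi_area_um2",
    "ser_flag", "mito_flag",
]


@dataclass(frozen=True)
class GrParams:
    """Parameters of the tiered-branching glucose-residue formula."""

    residues_per_chain: float = 13.0
    branching_degree: float = 2.0
    tier_length_nm: float = 1.9

    def __post_init__(self) -> None:
        if min(self.residues_per_chain, self.branching_degree, self.tier_length_nm) <= 0:
            raise ValidationError("all GrParams fields must be strictly positive")


def glucose_residues(diameter_nm, params: GrParams = GrParams()):
    """Estimated glucose residues in a granule of the given diameter (nm).

    Accepts scalars or arrays; strictly increasing and continuous in the
    diameter; returns a real-valued count (not rounded).
    """
    d = np.asarray(diameter_nm, dtype=float)
    if np.any(d < 0):
        raise ValidationError("diameter must be non-negative")
    tiers = d / (2.0 * params.tier_length_nm)
    out = params.residues_per_chain * (params.branching_degree ** tiers - 1.0)
    return float(out) if np.isscalar(diameter_nm) else out


def normalized_density(granule_count: int, astro_volume_um3: float) -> float:
    """Granules per um^3 of astrocytic volume."""
    if not astro_volume_um3 > 0:
        raise ValidationError(f"astro_volume must be > 0, got {astro_volume_um3}")
    return granule_count / astro_volume_um3


def compute_roi_metrics(dataset: StudyDataset, distances: pd.DataFrame,
                        params: GrParams = GrParams(), window_nm: float = 500.0,
                        ) -> pd.DataFrame:
    """One metrics row per ROI: count, density, mean GR, mean distance, coverage.

    ``granule_count`` counts every granule annotated in the ROI's astrocytic
    compartment (no window applied); ``mean_gr`` averages the glucose-residue
    estimate over those granules (NaN for empty ROIs); ``mean_distance`` is
    the within-window average from the geometry module (NaN where no granule
    falls inside the window); ``coverage`` is the PAP-contact fraction of the
    ASI perimeter (NaN for ROIs whose mesh carries no perimeter).
    """
    dangling = set(distances["roi_id"]) - set(dataset.rois["roi_id"]) if len(distances) else set()
    if dangling:
        raise ValidationError(f"distance records reference unknown ROIs: {sorted(dangling)[:5]}")

    g = dataset.granules.copy()
    g["gr"] = glucose_residues(g["diameter_nm"].to_numpy(), params)
    per_roi = g.groupby("roi_id").agg(granule_count=("granule_id", "size"),
                                      mean_gr=("gr", "mean"))
    mean_dist = per_roi_mean_distances(distances, window_nm) if len(distances) else pd.Series(dtype=float)

    rows = dataset.rois.set_index("roi_id")
    out = pd.DataFrame(index=rows.index)
    out["condition"] = rows["condition"]
    out["mouse_id"] = rows["mouse_id"]
    out["granule_count"] = per_roi["granule_count"].reindex(out.index).fillna(0).astype(int)
    out["density"] = out["granule_count"] / rows["astro_volume_um3"]
    out["mean_gr"] = per_roi["mean_gr"].reindex(out.index)
    out["mean_distance"] = mean_dist.reindex(out.index)
    coverage = {}
    for roi_id, ref in rows["asi_mesh_ref"].items():
        mesh = dataset.meshes.get(ref)
        if mesh is not None and mesh.n_segments:
            coverage[roi_id] = geometry.coverage_fraction(mesh)
    out["coverage"] = pd.Series(coverage, dtype=float).reindex(out.index)
    out["asi_area_um2"] = rows["asi_area_um2"]
    out["ser_flag"] = rows["ser_flag"]
    out["mito_flag"] = rows["mito_flag"]
    return out.reset_index()[ROI_METRIC_COLUMNS]


def stratify(metrics: pd.DataFrame, flag: str) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Partition ROI metrics into flag-true / flag-false groups per condition.

    ``flag`` is ``"ser_flag"`` or ``"mito_flag"``. The partition is exhaustive
    and disjoint; empty complement groups are returned as empty frames.
    """
    if flag not in ("ser_flag", "mito_flag"):
        raise ValidationError(f"unknown stratification flag {flag!r}")
    out = {}
    for cond, sub in metrics.groupby("condition", sort=False):
        mask = sub[flag].astype(bool)
        out[cond] = (sub[mask], sub[~mask])
    return out
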