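"""Granule-to-ASI geometry.

The distance of a glycogen granule from the synaptic cleft is defined as the
shortest Euclidean distance between the ball annotation and the nearest
vertex of the ASI's unique-vertex set — vertex distance, not closest point
on a triangle, matching how the annotations were measured. Two modes exist:

* ``center``  (default): distance from the ball centre to the nearest vertex;
* ``surface``: the same minus the ball radius, floored at zero.

Only granules within a fixed window of the ASI (default 500 nm, inclusive)
enter distance statistics, and distances are averaged within each ROI.
Astrocytic coverage of the synapse is the fraction of the ASI perimeter
length whose segments are in contact with the PAP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError
from .model import AsiMesh, GranuleAnnotation, StudyDataset

DISTANCE_COLUMNS = ["granule_id", "roi_id", "distance_nm", "within_window"]


@dataclass(frozen=True)
class DistanceRecord:
    """Ball-to-nearest-unique-vertex distance for one granule."""

    granule_id: str
    roi_id: str
    distance: float  # nm
    within_window: bool


def nearest_vertex_distances(centers: np.ndarray, mesh: AsiMesh) -> np.ndarray:
    """Centre-to-nearest-vertex distances for an ``(n, 3)`` array of centres (nm)."""
    if len(mesh.vertices) == 0:
        raise GeometryError("mesh has an empty vertex set")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    # (n, V) pairwise distances; meshes are small so the exhaustive scan is exact and cheap
    d2 = ((centers[:, None, :] - mesh.vertices[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2.min(axis=1))


def nearest_vertex_distance(granule: GranuleAnnotation, mesh: AsiMesh,
                            mode: str = "center") -> float:
    """Shortest path between a ball annotation and the nearest ASI vertex, in nm."""
    if mode not in ("center", "surface"):
        raise ValidationError(f"unknown distance mode {mode!r}")
    d = float(nearest_vertex_distances(granule.center[None, :], mesh)[0])
    if mode == "surface":
        d = max(0.0, d - granule.diameter / 2.0)
    return d


def compute_distances(dataset: StudyDataset, window_nm: float = 500.0,
                      mode: str = "center", *, skip_missing_geometry: bool = False,
                      ) -> pd.DataFrame:
    """Distance of every granule from its ROI's ASI, with the window flag.

    Returns a DataFrame with columns :data:`DISTANCE_COLUMNS`, one row per
    granule, in input granule order. With ``skip_missing_geometry`` granules
    of ROIs lacking a mesh are silently omitted (their ROI ids are listed in
    ``df.attrs['skipped_rois']``); otherwise a missing mesh raises
    :class:`GeometryError` naming the ROI.
    """
    if mode not in ("center", "surface"):
        raise ValidationError(f"unknown distance mode {mode!r}")
    ref_of = dict(zip(dataset.rois["roi_id"], dataset.rois["asi_mesh_ref"]))
    parts, skipped = [], []
    for roi_id, sub in dataset.granules.groupby("roi_id", sort=False):
        ref = ref_of.get(roi_id)
        mesh = dataset.meshes.get(ref) if ref is not None else None
        if mesh is None:
            if skip_missing_geometry:
                skipped.append(roi_id)
                continue
            raise GeometryError(f"roi {roi_id}: no ASI mesh available (ref {ref!r})")
        centers = sub[["x_nm", "y_nm", "z_nm"]].to_numpy()
        d = nearest_vertex_distances(centers, mesh)
        if mode == "surface":
            d = np.maximum(0.0, d - sub["diameter_nm"].to_numpy() / 2.0)
        parts.append(pd.DataFrame({
            "granule_id": sub["granule_id"].to_numpy(),
            "roi_id": roi_id,
            "distance_nm": d,
            "within_window": d <= window_nm,
        }, index=sub.index))
    if parts:
        out = pd.concat(parts).sort_index()
    else:
        out = pd.DataFrame(columns=DISTANCE_COLUMNS)
    out.attrs["skipped_rois"] = skipped
    out.attrs["window_nm"] = window_nm
    out.attrs["mode"] = mode
    return out


def apply_window(records: pd.DataFrame, window_nm: float) -> pd.DataFrame:
    """Keep only records with ``distance_nm <= window_nm`` (inclusive), preserving order."""
    if not window_nm > 0:
        raise ValidationError("window_nm must be > 0")
    return records[records["distance_nm"] <= window_nm]


def mean_roi_distance(records: pd.DataFrame, window_nm: float) -> float | None:
    """Arithmetic mean of within-window distances for one ROI's records.

    Returns ``None`` (the undefined marker) when no granule lies within the
    window; such ROIs are excluded from downstream distance statistics.
    """
    if len(records) and records["roi_id"].nunique() > 1:
        raise ValidationError("mean_roi_distance requires records from a single ROI")
    kept = apply_window(records, window_nm)
    if len(kept) == 0:
        return None
    return float(kept["distance_nm"].mean())


def per_roi_mean_distances(records: pd.DataFrame, window_nm: float) -> pd.Series:
    """Within-window mean distance per ROI; ROIs with no within-window granule are absent."""
    kept = apply_window(records, window_nm)
    return kept.groupby("roi_id")["distance_nm"].mean()


def coverage_fraction(mesh: AsiMesh) -> float:
    """Fraction of the ASI perimeter length contacted by the PAP, in [0, 1]."""
    if mesh.n_segments == 0:
        raise GeometryError("mesh has no perimeter")
    pts = mesh.vertices[mesh.perimeter]
    seg = np.roll(pts, -1, axis=0) - pts
    lengths = np.linalg.norm(seg, axis=1)
    total = lengths.sum()
    if total <= 0:
        raise GeometryError("perimeter has zero total length")
    return float(lengths[mesh.contact_labels].sum() / total)
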