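"""Domain model for perisynaptic-glycogen studies.

A *study* is a set of cuboid neuropil regions of interest (ROIs), each drawn
around one axon-spine synapse in one of four behavioural conditions (S =
sleep, W = spontaneous wake, SD = acute sleep deprivation, CSR = chronic
sleep restriction). Within each ROI the astrocytic compartment carries
glycogen granules annotated as balls (centre + diameter, nm), and the
axon-spine interface (ASI) is a triangulated surface whose perimeter carries
per-segment labels marking contact with the perisynaptic astrocytic process
(PAP).

Tabular collections (granules, ROIs) are held as pandas DataFrames for
vectorised computation; per-record dataclasses are provided for the
single-object API surface.

Unit conventions: all lengths in nm, volumes in um^3, areas in um^2.
The nm^3 -> um^3 conversion factor is NM3_PER_UM3 and lives only here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

#: fixed condition order used in every table and figure-panel analogue
CONDITIONS: tuple[str, ...] = ("S", "W", "SD", "CSR")

#: exactly one place where the cubic unit conversion is defined
NM3_PER_UM3: float = 1e9
NM2_PER_UM2: float = 1e6

GRANULE_COLUMNS = ["granule_id", "roi_id", "x_nm", "y_nm", "z_nm", "diameter_nm"]
ROI_COLUMNS = [
    "roi_id", "condition", "mouse_id",
    "bbox_x_nm", "bbox_y_nm", "bbox_z_nm",
    "edge_x_nm", "edge_y_nm", "edge_z_nm",
    "roi_volume_um3", "astro_volume_um3", "asi_area_um2",
    "ser_flag", "mito_flag", "asi_mesh_ref",
]


@dataclass(frozen=True)
class GranuleAnnotation:
    """One glycogen granule modelled as a ball inside an ROI's astrocytic compartment."""

    granule_id: str
    roi_id: str
    center: np.ndarray  # shape (3,), nm
    diameter: float     # nm

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.center.shape != (3,):
            raise ValidationError(f"granule {self.granule_id}: center must be a 3-vector")
        if not self.diameter > 0:
            raise ValidationError(f"granule {self.granule_id}: diameter must be > 0, got {self.diameter}")


@dataclass
class RoiRecord:
    """One cuboid neuropil region of interest around a synapse."""

    roi_id: str
    condition: str
    mouse_id: str
    bbox_corner: np.ndarray  # (3,), nm
    bbox_edges: np.ndarray   # (3,), nm
    roi_volume: float        # um^3
    astro_volume: float      # um^3, astrocytic volume within the ROI
    asi_area: float          # um^2
    ser_flag: bool
    mito_flag: bool
    asi_mesh_ref: str

    def validate(self, *, paper_conforming: bool = False) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"roi {self.roi_id}: unknown condition {self.condition!r}")
        if not (0 < self.astro_volume <= self.roi_volume):
            raise ValidationError(
                f"roi {self.roi_id}: need 0 < astro_volume <= roi_volume, "
                f"got {self.astro_volume} / {self.roi_volume}"
            )
        bbox_vol = float(np.prod(self.bbox_edges)) / NM3_PER_UM3
        if not np.isclose(bbox_vol, self.roi_volume, rtol=1e-6, atol=0.0):
            raise ValidationError(
                f"roi {self.roi_id}: roi_volume {self.roi_volume} != bbox volume {bbox_vol}"
            )
        if not self.asi_area > 0:
            raise ValidationError(f"roi {self.roi_id}: asi_area must be > 0")
        if paper_conforming and not (
            np.all(self.bbox_edges >= 2000.0) and np.all(self.bbox_edges <= 4000.0)
        ):
            raise ValidationError(f"roi {self.roi_id}: edges outside [2000, 4000] nm")


@dataclass
class AsiMesh:
    """Triangulated axon-spine-interface surface.

    ``vertices`` is the unique-vertex set (no duplicate coordinates);
    ``perimeter`` is an ordered closed polyline of vertex indices where
    closure is implicit (last index connects back to the first), so a
    perimeter of length S defines S segments; ``contact_labels[k]`` marks
    whether segment (perimeter[k], perimeter[(k+1) % S]) touches the PAP.
    """

    vertices: np.ndarray        # (V, 3), nm
    faces: np.ndarray           # (F, 3), int indices
    perimeter: np.ndarray       # (S,), int indices, implicit closure
    contact_labels: np.ndarray  # (S,), bool

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.perimeter = np.asarray(self.perimeter, dtype=np.int64).ravel()
        self.contact_labels = np.asarray(self.contact_labels, dtype=bool).ravel()

    def validate(self) -> None:
        if len(self.vertices) == 0:
            raise ValidationError("mesh has no vertices")
        uniq = np.unique(self.vertices, axis=0)
        if len(uniq) != len(self.vertices):
            raise ValidationError("mesh vertex list contains duplicate coordinates")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValidationError("face indices out of range")
        if self.perimeter.size:
            if self.perimeter.min() < 0 or self.perimeter.max() >= len(self.vertices):
                raise ValidationError("perimeter indices out of range")
            if len(self.contact_labels) != len(self.perimeter):
                raise ValidationError(
                    "need exactly one contact label per perimeter segment "
                    f"({len(self.perimeter)} segments, {len(self.contact_labels)} labels)"
                )

    @property
    def n_segments(self) -> int:
        return len(self.perimeter)


@dataclass
class StudyDataset:
    """All ROIs, granules and ASI meshes of one study (real or synthetic).

    ``granules`` and ``rois`` are DataFrames with the canonical column sets
    (:data:`GRANULE_COLUMNS`, :data:`ROI_COLUMNS`); ``meshes`` maps
    ``asi_mesh_ref`` -> :class:`AsiMesh`; ``meta`` records provenance
    (generator seed, config hash, source path).
    """

    granules: pd.DataFrame
    rois: pd.DataFrame
    meshes: Mapping[str, AsiMesh]
    meta: dict = field(default_factory=dict)

    def validate(self, *, allow_missing_meshes: bool = False) -> None:
        for col in GRANULE_COLUMNS:
            if col not in self.granules.columns:
                raise ValidationError(f"granule table missing column {col!r}")
        for col in ROI_COLUMNS:
            if col not in self.rois.columns:
                raise ValidationError(f"roi table missing column {col!r}")
        bad_cond = set(self.rois["condition"].unique()) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown condition labels: {sorted(bad_cond)}")
        known = set(self.rois["roi_id"])
        dangling = set(self.granules["roi_id"]) - known
        if dangling:
            raise ValidationError(f"granules reference unknown ROIs: {sorted(dangling)[:5]}")
        missing = set(self.rois["asi_mesh_ref"]) - set(self.meshes)
        if missing and not allow_missing_meshes:
            raise ValidationError(f"unresolved mesh refs: {sorted(missing)[:5]}")
        if (self.granules["diameter_nm"] <= 0).any():
            raise ValidationError("granule table contains non-positive diameters")
        if len(self.granules):
            joined = self.granules.merge(
                self.rois[["roi_id", "bbox_x_nm", "bbox_y_nm", "bbox_z_nm",
                           "edge_x_nm", "edge_y_nm", "edge_z_nm"]], on="roi_id")
            for ax in "xyz":
                lo = joined[f"bbox_{ax}_nm"]
                hi = lo + joined[f"edge_{ax}_nm"]
                if ((joined[f"{ax}_nm"] < lo) | (joined[f"{ax}_nm"] > hi)).any():
                    raise ValidationError("granule centre outside its ROI bounding box")

    def roi_records(self):
        """Iterate ROIs as :class:`RoiRecord` objects."""
        for row in self.rois.itertuples(index=False):
            yield RoiRecord(
                roi_id=row.roi_id, condition=row.condition, mouse_id=str(row.mouse_id),
                bbox_corner=np.array([row.bbox_x_nm, row.bbox_y_nm, row.bbox_z_nm]),
                bbox_edges=np.array([row.edge_x_nm, row.edge_y_nm, row.edge_z_nm]),
                roi_volume=row.roi_volume_um3, astro_volume=row.astro_volume_um3,
                asi_area=row.asi_area_um2, ser_flag=bool(row.ser_flag),
                mito_flag=bool(row.mito_flag), asi_mesh_ref=row.asi_mesh_ref,
            )

    def granule_records(self):
        """Iterate granules as :class:`GranuleAnnotation` objects."""
        for row in self.granules.itertuples(index=False):
            yield GranuleAnnotation(
                granule_id=row.granule_id, roi_id=row.roi_id,
                center=np.array([row.x_nm, row.y_nm, row.z_nm]),
                diameter=row.diameter_nm,
            )


@dataclass
class StatReport:
    """Full pipeline output mirroring the study's figure panels.

    * ``per_condition_tables``: name -> summary DataFrame (n, mean, sem, ...).
    * ``omnibus``: one row per omnibus (Kruskal-Wallis) test.
    * ``posthoc``: one row per Dunn pairwise comparison.
    * ``correlations``: one row per Spearman correlation, with grain
      ("roi" or "granule") and sample size.
    * ``meta``: the pipeline configuration that produced the report.
    """

    per_condition_tables: dict[str, pd.DataFrame]
    omnibus: pd.DataFrame
    posthoc: pd.DataFrame
    correlations: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        for df, cols in ((self.omnibus, ["p"]), (self.posthoc, ["p_raw", "p_adjusted"]),
                         (self.correlations, ["p"])):
            for c in cols:
                if len(df) and ((df[c] < 0).any() or (df[c] > 1).any()):
                    raise ValidationError(f"column {c} outside [0, 1]")
        if len(self.posthoc) and (self.posthoc["p_adjusted"] < self.posthoc["p_raw"] - 1e-15).any():
            raise ValidationError("adjusted p below raw p")
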