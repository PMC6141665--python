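"""Readers and writers for every external artifact.

Tables are delimited text (comma by default; tab for ``.tsv`` paths) with a
header row. Meshes are standard OBJ or PLY triangle meshes; the ASI
perimeter and its PAP-contact labels travel in a delimited sidecar table of
ordered vertex-index pairs. Floats are written at 10 significant digits,
which makes write -> read lossless for any value representable at 6
significant digits and keeps output byte-reproducible.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .errors import SchemaError, ValidationError
from .model import (
    GRANULE_COLUMNS, ROI_COLUMNS, AsiMesh, StatReport, StudyDataset,
)

_FLOAT_FMT = "%.10g"


def _sep_for(path: Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# granule / ROI tables

def read_granule_table(path) -> pd.DataFrame:
    """Read a granule annotation table (one ball per row, coordinates in nm)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    _require_columns(df, GRANULE_COLUMNS, path)
    bad = df.index[df["diameter_nm"] <= 0]
    if len(bad):
        raise ValidationError(f"{path}: non-positive diameter at row {int(bad[0])}")
    return df[GRANULE_COLUMNS].astype(
        {"granule_id": str, "roi_id": str, "x_nm": float, "y_nm": float,
         "z_nm": float, "diameter_nm": float}
    )


def write_granule_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df[GRANULE_COLUMNS].to_csv(path, sep=_sep_for(path), index=False, float_format=_FLOAT_FMT)


def read_roi_table(path) -> pd.DataFrame:
    """Read the per-ROI table (volumes in um^3, bbox in nm, synapse flags)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    _require_columns(df, ROI_COLUMNS, path)
    for col in ("roi_volume_um3", "astro_volume_um3", "asi_area_um2"):
        bad = df.index[df[col] <= 0]
        if len(bad):
            raise ValidationError(f"{path}: non-positive {col} at row {int(bad[0])}")
    out = df[ROI_COLUMNS].copy()
    out["roi_id"] = out["roi_id"].astype(str)
    out["ser_flag"] = out["ser_flag"].astype(bool)
    out["mito_flag"] = out["mito_flag"].astype(bool)
    return out


def write_roi_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df[ROI_COLUMNS].to_csv(path, sep=_sep_for(path), index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# meshes

def _merge_exact_duplicates(vertices: np.ndarray, faces: np.ndarray):
    """Merge exactly-coincident vertices, keeping first-occurrence order.

    The distance definition operates on the unique-vertex set of the meshed
    surface, so duplicates (common in OBJ exports) must collapse before any
    distance computation. Matching is exact, not tolerance-based.
    """
    uniq, first_idx, inverse = np.unique(
        vertices, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first_idx)                 # restore file order
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    new_vertices = uniq[order]
    remap = rank[inverse]                         # old index -> new index
    return new_vertices, remap[faces], remap


def read_asi_mesh(path, sidecar_path=None) -> AsiMesh:
    """Read an OBJ/PLY triangle mesh and its perimeter/contact sidecar.

    The sidecar is a delimited table with columns ``v_start, v_end,
    pap_contact`` whose rows, in order, chain into the closed ASI perimeter.
    Sidecar indices refer to positions in the mesh file's vertex list and are
    remapped onto the merged unique-vertex set. With no sidecar the mesh has
    an empty perimeter (distance computations still work; coverage does not).
    """
    path = Path(path)
    if path.suffix.lower() == ".obj":
        # trimesh silently fan-triangulates polygon faces; reject them up front
        for line in path.read_text().splitlines():
            if line.startswith("f ") and len(line.split()) != 4:
                raise SchemaError(f"{path}: mesh faces must be triangles")
    mesh = trimesh.load(path, process=False, force="mesh")
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if faces.size and faces.shape[1] != 3:
        raise SchemaError(f"{path}: mesh faces must be triangles")
    vertices, faces, remap = _merge_exact_duplicates(
        np.asarray(mesh.vertices, dtype=float), faces
    )

    perimeter = np.empty(0, dtype=np.int64)
    labels = np.empty(0, dtype=bool)
    if sidecar_path is not None:
        sidecar_path = Path(sidecar_path)
        sc = pd.read_csv(sidecar_path, sep=_sep_for(sidecar_path))
        _require_columns(sc, ["v_start", "v_end", "pap_contact"], sidecar_path)
        starts = remap[sc["v_start"].to_numpy(dtype=np.int64)]
        ends = remap[sc["v_end"].to_numpy(dtype=np.int64)]
        if not (np.array_equal(starts[1:], ends[:-1]) and ends[-1] == starts[0]):
            raise ValidationError(f"{sidecar_path}: perimeter segments do not chain into a closed loop")
        perimeter = starts
        labels = sc["pap_contact"].to_numpy(dtype=bool)

    out = AsiMesh(vertices=vertices, faces=faces, perimeter=perimeter, contact_labels=labels)
    out.validate()
    return out


def write_asi_mesh(mesh: AsiMesh, path, sidecar_path=None) -> None:
    """Write a mesh as OBJ/PLY plus (optionally) its perimeter sidecar."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    payload = tm.export(file_type=path.suffix.lstrip("."))
    path.write_bytes(payload.encode() if isinstance(payload, str) else payload)
    if sidecar_path is not None and mesh.n_segments:
        nxt = np.roll(mesh.perimeter, -1)
        pd.DataFrame({
            "v_start": mesh.perimeter, "v_end": nxt,
            "pap_contact": mesh.contact_labels.astype(int),
        }).to_csv(Path(sidecar_path), sep=_sep_for(Path(sidecar_path)), index=False)


# ---------------------------------------------------------------------------
# whole studies

def save_study(dataset: StudyDataset, out_dir) -> None:
    """Write a study as granules.csv + rois.csv + meshes/ + meta.yaml."""
    out_dir = Path(out_dir)
    (out_dir / "meshes").mkdir(parents=True, exist_ok=True)
    write_granule_table(dataset.granules, out_dir / "granules.csv")
    write_roi_table(dataset.rois, out_dir / "rois.csv")
    for ref in sorted(dataset.meshes):
        write_asi_mesh(dataset.meshes[ref], out_dir / "meshes" / f"{ref}.obj",
                       out_dir / "meshes" / f"{ref}.perimeter.csv")
    with open(out_dir / "meta.yaml", "w") as fh:
        yaml.safe_dump(dataset.meta, fh, sort_keys=True)


def load_study(in_dir) -> StudyDataset:
    in_dir = Path(in_dir)
    granules = read_granule_table(in_dir / "granules.csv")
    rois = read_roi_table(in_dir / "rois.csv")
    meshes = {}
    for ref in rois["asi_mesh_ref"].unique():
        meshes[ref] = read_asi_mesh(in_dir / "meshes" / f"{ref}.obj",
                                    in_dir / "meshes" / f"{ref}.perimeter.csv")
    meta_path = in_dir / "meta.yaml"
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    ds = StudyDataset(granules=granules, rois=rois, meshes=meshes, meta=meta or {})
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# configuration and reports

def read_config(path) -> dict:
    """Read a YAML configuration file into a plain dict."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def config_hash(config: dict) -> str:
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(report: StatReport, out_dir) -> list[Path]:
    """Serialize a :class:`StatReport` as one CSV per figure-panel analogue.

    Output is deterministic: fixed table order, fixed column order, fixed
    float format, so identical reports produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(report.per_condition_tables):
        p = out_dir / f"summary_{name}.csv"
        report.per_condition_tables[name].to_csv(p, index=False, float_format=_FLOAT_FMT)
        written.append(p)
    for name, df in (("omnibus", report.omnibus), ("posthoc", report.posthoc),
                     ("correlations", report.correlations)):
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format=_FLOAT_FMT)
        written.append(p)
    with open(out_dir / "run_meta.yaml", "w") as fh:
        yaml.safe_dump(report.meta, fh, sort_keys=True)
    written.append(out_dir / "run_meta.yaml")
    return written
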