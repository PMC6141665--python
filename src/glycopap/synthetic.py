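"""Seeded synthetic-study generator.

Emulates the structure of the EM annotation study the pipeline analyses:
4 behavioural conditions x 3 mice, a few hundred cuboid ROIs per condition,
per-ROI astrocytic volumes, ball-annotated glycogen granules, a planar-disc
ASI mesh per ROI with PAP-contact labels on its perimeter, and SER /
presynaptic-mitochondrion flags.

Calibration targets are the study's per-condition summaries: normalized
granule density and within-window mean distance are reported as mean +- SEM
over ROIs, granule diameter as mean +- SEM over granules, so population SDs
are derived as SD = SEM * sqrt(n) at the reported ns. Margins:

* density: gamma, moment-matched (positive support; exact mean/SD; SD=0
  degenerates to the mean so that the count rounding is the only noise);
* diameter: truncated-at-zero normal (truncation negligible at ~4.8 SD) or
  optionally lognormal, both moment-matched;
* per-ROI mean distance target t_i: Beta on [0, 500] nm, moment-matched;
  granule distances: Beta on [0, 500] nm with mean t_i (concentration
  ``granule_beta_conc``) for the within-window share, uniform in
  (500, far_max] for the rest;
* ASI area: truncated lognormal; coverage: Beta.

Rank correlations between variable pairs (density-ASI area per condition;
diameter-distance and coverage-distance where the study reports them) are
induced by a Gaussian-copula reordering (Iman-Conover) that preserves every
margin exactly: latent Pearson correlation r = 2 sin(pi rho / 6) maps the
target Spearman rho onto normal scores.

Granule centres are placed perpendicular to the ASI disc plane from a
randomly chosen mesh vertex, so the generated distance *is* the
nearest-unique-vertex distance exactly (all other vertices are coplanar and
therefore farther). Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from .model import CONDITIONS, NM2_PER_UM2, NM3_PER_UM3, AsiMesh, StudyDataset
from . import io as gio


@dataclass(frozen=True)
class ConditionParams:
    """Calibration targets for one behavioural condition."""

    condition: str
    n_rois: int
    density_mean: float      # granules per um^3 of astrocyte (ROI grain)
    density_sem: float
    diam_mean: float         # nm (granule grain)
    diam_sem: float
    n_granules_expected: int  # granule count at which diam_sem was reported
    dist_mean: float         # nm, within-window per-ROI mean (ROI grain)
    dist_sem: float
    ser_prev: float          # fraction of synapses with SER in the spine head
    mito_prev: float         # fraction with a presynaptic mitochondrion
    rank_corrs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rois <= 0:
            raise ConfigurationError("n_rois must be > 0")
        for name in ("density_mean", "diam_mean", "dist_mean"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("ser_prev", "mito_prev"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")

    # population SDs implied by the reported SEMs
    @property
    def density_sd(self) -> float:
        return self.density_sem * np.sqrt(self.n_rois)

    @property
    def diam_sd(self) -> float:
        return self.diam_sem * np.sqrt(self.n_granules_expected)

    @property
    def dist_sd(self) -> float:
        return self.dist_sem * np.sqrt(self.n_rois)


@dataclass(frozen=True)
class GeneratorSettings:
    """Structural knobs not pinned by any reported summary."""

    edge_range_nm: tuple[float, float] = (2000.0, 4000.0)
    astro_frac_range: tuple[float, float] = (0.05, 0.15)
    far_fraction: float = 0.2            # granules beyond the 500 nm window
    far_max_nm: float = 900.0
    window_nm: float = 500.0
    granule_beta_conc: float = 8.0       # within-ROI distance concentration
    mesh_segments: int = 32
    asi_area_median_um2: float = 0.15
    asi_area_sigma: float = 0.6          # lognormal shape
    asi_area_max_um2: float = 0.6
    n_mice: int = 3
    diameter_family: str = "normal"      # or "lognormal"
    coverage_beta: tuple[float, float] = (4.0, 6.0)  # mean 0.4

    def validate(self) -> None:
        if self.diameter_family not in ("normal", "lognormal"):
            raise ConfigurationError(f"unknown diameter_family {self.diameter_family!r}")
        if not 0.0 <= self.far_fraction < 1.0:
            raise ConfigurationError("far_fraction must be in [0, 1)")
        if self.far_max_nm >= self.edge_range_nm[0] / 2.0:
            raise ConfigurationError("far_max_nm must fit inside the smallest ROI half-edge")
        r_max = np.sqrt(self.asi_area_max_um2 * NM2_PER_UM2 / np.pi)
        if r_max >= self.edge_range_nm[0] / 2.0:
            raise ConfigurationError("asi_area_max_um2 disc does not fit the smallest ROI")


def default_config() -> dict[str, ConditionParams]:
    """Per-condition calibration at the study's reported summaries."""
    return {
        "S": ConditionParams(
            "S", 308, 103.6, 5.4, 27.2, 0.1, 3248, 357.2, 6.9, 0.575, 0.695,
            {"density_vs_asi": -0.16, "diameter_vs_distance": -0.001,
             "coverage_vs_distance": -0.07}),
        "W": ConditionParams(
            "W", 268, 116.3, 5.2, 27.1, 0.1, 3718, 368.7, 7.6, 0.359, 0.661,
            {"density_vs_asi": -0.16, "diameter_vs_distance": 0.0,
             "coverage_vs_distance": 0.0}),
        "SD": ConditionParams(
            "SD", 339, 125.7, 3.8, 26.9, 0.1, 5399, 366.5, 6.9, 0.472, 0.677,
            {"density_vs_asi": -0.1, "diameter_vs_distance": 0.0,
             "coverage_vs_distance": 0.0}),
        "CSR": ConditionParams(
            "CSR", 339, 123.1, 4.7, 26.3, 0.1, 4289, 334.9, 6.1, 0.486, 0.599,
            {"density_vs_asi": 0.0, "diameter_vs_distance": -0.16,
             "coverage_vs_distance": -0.2}),
    }


def induce_rank_correlation(u, v, rho_target: float):
    """Pair two samples at a target Spearman correlation, preserving both margins.

    Gaussian-copula reordering: map both samples to van der Waerden normal
    scores, mix the second with the first at latent Pearson correlation
    r = 2 sin(pi rho / 6), and reorder the second sample's *values* to follow
    the mixed scores' ranks. The returned pair is ``(u, v_reordered)`` where
    ``v_reordered`` is a permutation of ``v`` (empirical margin unchanged);
    the realized sample Spearman rho is within O(1/sqrt(n)) of the target.
    """
    if not abs(rho_target) < 1.0:
        raise ConfigurationError(f"|rho_target| must be < 1, got {rho_target}")
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if len(u) != len(v):
        raise ConfigurationError("u and v must have equal length")
    n = len(u)
    if n < 2 or rho_target == 0.0:
        return u, v
    r = 2.0 * np.sin(np.pi * rho_target / 6.0)
    z1 = sps.norm.ppf(sps.rankdata(u) / (n + 1.0))
    z2 = sps.norm.ppf(sps.rankdata(v) / (n + 1.0))
    mixed = r * z1 + np.sqrt(1.0 - r * r) * z2
    order = np.argsort(np.argsort(mixed))     # ranks (0-based) of the mixed scores
    return u, np.sort(v)[order]


def _gamma_margin(rng, mean, sd, n):
    if sd == 0.0:
        return np.full(n, mean)
    k = (mean / sd) ** 2
    return rng.gamma(k, sd * sd / mean, size=n)


def _beta_on_interval(rng, mean, sd, n, hi):
    """Moment-matched Beta sample on [0, hi]."""
    mu, sig = mean / hi, sd / hi
    if sig == 0.0:
        return np.full(n, mean)
    nu = mu * (1.0 - mu) / (sig * sig) - 1.0
    if nu <= 0:
        raise ConfigurationError(
            f"infeasible Beta moments: mean {mean}, sd {sd} on [0, {hi}]")
    return hi * rng.beta(mu * nu, (1.0 - mu) * nu, size=n)


def _diameter_margin(rng, params: ConditionParams, settings: GeneratorSettings, n):
    m, sd = params.diam_mean, params.diam_sd
    if sd == 0.0:
        return np.full(n, m)
    if settings.diameter_family == "lognormal":
        s2 = np.log1p((sd / m) ** 2)
        return rng.lognormal(np.log(m) - s2 / 2.0, np.sqrt(s2), size=n)
    return sps.truncnorm.rvs((0.0 - m) / sd, np.inf, loc=m, scale=sd,
                             size=n, random_state=rng)


def _disc_mesh(center, area_nm2, segments):
    """Regular-polygon disc (fan triangulation) with exact polygon area ``area_nm2``."""
    r = np.sqrt(2.0 * area_nm2 / (segments * np.sin(2.0 * np.pi / segments)))
    ang = 2.0 * np.pi * np.arange(segments) / segments
    ring = np.column_stack([center[0] + r * np.cos(ang),
                            center[1] + r * np.sin(ang),
                            np.full(segments, center[2])])
    vertices = np.vstack([center, ring])
    idx = np.arange(1, segments + 1)
    faces = np.column_stack([np.zeros(segments, dtype=int), idx, np.roll(idx, -1)])
    return vertices, faces, idx


def generate_study(config: Mapping[str, ConditionParams] | None = None,
                   seed: int = 0,
                   settings: GeneratorSettings = GeneratorSettings(),
                   ) -> StudyDataset:
    """Generate one full synthetic study; bit-identical for a fixed seed."""
    config = default_config() if config is None else config
    settings.validate()
    rng = np.random.default_rng(seed)

    roi_rows, granule_frames, meshes = [], [], {}
    for cond in CONDITIONS:
        if cond not in config:
            continue
        p = config[cond]
        n = p.n_rois
        seg = settings.mesh_segments

        edges = rng.uniform(*settings.edge_range_nm, size=(n, 3))
        corners = rng.uniform(0.0, 1e6, size=(n, 3))
        roi_vol = edges.prod(axis=1) / NM3_PER_UM3
        astro_vol = rng.uniform(*settings.astro_frac_range, size=n) * roi_vol

        density = _gamma_margin(rng, p.density_mean, p.density_sd, n)
        asi_area = np.minimum(
            rng.lognormal(np.log(settings.asi_area_median_um2),
                          settings.asi_area_sigma, size=n),
            settings.asi_area_max_um2)
        density, asi_area = induce_rank_correlation(
            density, asi_area, p.rank_corrs.get("density_vs_asi", 0.0))

        t_roi = _beta_on_interval(rng, p.dist_mean, p.dist_sd, n, settings.window_nm)
        coverage = rng.beta(*settings.coverage_beta, size=n)
        t_roi, coverage = induce_rank_correlation(
            t_roi, coverage, p.rank_corrs.get("coverage_vs_distance", 0.0))

        counts = np.rint(density * astro_vol).astype(int)
        ser = rng.random(n) < p.ser_prev
        mito = rng.random(n) < p.mito_prev

        # granule distances: per-ROI Beta share within the window + a far tail
        total = int(counts.sum())
        roi_of_granule = np.repeat(np.arange(n), counts)
        mu = np.clip(t_roi / settings.window_nm, 1e-3, 1.0 - 1e-3)[roi_of_granule]
        nu = settings.granule_beta_conc
        dist = settings.window_nm * rng.beta(mu * nu, (1.0 - mu) * nu, size=total)
        far = rng.random(total) < settings.far_fraction
        dist[far] = rng.uniform(settings.window_nm, settings.far_max_nm, size=int(far.sum()))

        diam = _diameter_margin(rng, p, settings, total)
        dist, diam = induce_rank_correlation(
            dist, diam, p.rank_corrs.get("diameter_vs_distance", 0.0))

        vidx = rng.integers(0, seg + 1, size=total)
        sign = rng.choice([-1.0, 1.0], size=total)

        roi_ids = np.array([f"{cond}{i:04d}" for i in range(n)])
        for i in range(n):
            center = corners[i] + edges[i] / 2.0
            vertices, faces, ring = _disc_mesh(center, asi_area[i] * NM2_PER_UM2, seg)
            k = int(np.rint(coverage[i] * seg))
            labels = np.zeros(seg, dtype=bool)
            if k > 0:
                start = int(rng.integers(0, seg))
                labels[(start + np.arange(k)) % seg] = True
            meshes[roi_ids[i]] = AsiMesh(vertices=vertices, faces=faces,
                                         perimeter=ring, contact_labels=labels)
            roi_rows.append({
                "roi_id": roi_ids[i], "condition": cond,
                "mouse_id": f"{cond}_m{i % settings.n_mice + 1}",
                "bbox_x_nm": corners[i, 0], "bbox_y_nm": corners[i, 1],
                "bbox_z_nm": corners[i, 2],
                "edge_x_nm": edges[i, 0], "edge_y_nm": edges[i, 1],
                "edge_z_nm": edges[i, 2],
                "roi_volume_um3": roi_vol[i], "astro_volume_um3": astro_vol[i],
                "asi_area_um2": asi_area[i],
                "ser_flag": bool(ser[i]), "mito_flag": bool(mito[i]),
                "asi_mesh_ref": roi_ids[i],
            })

        if total:
            # offset perpendicular to the (coplanar) disc => exact nearest-vertex distance
            anchor = np.empty((total, 3))
            for i in range(n):
                sel = roi_of_granule == i
                if sel.any():
                    anchor[sel] = meshes[roi_ids[i]].vertices[vidx[sel]]
            centers = anchor.copy()
            centers[:, 2] += sign * dist
            granule_frames.append(pd.DataFrame({
                "granule_id": [f"{cond}_g{j:06d}" for j in range(total)],
                "roi_id": roi_ids[roi_of_granule],
                "x_nm": centers[:, 0], "y_nm": centers[:, 1], "z_nm": centers[:, 2],
                "diameter_nm": diam,
            }))

    granules = (pd.concat(granule_frames, ignore_index=True) if granule_frames
                else pd.DataFrame(columns=["granule_id", "roi_id", "x_nm", "y_nm",
                                           "z_nm", "diameter_nm"]))
    rois = pd.DataFrame(roi_rows)
    cfg_blob = {c: {k: dict(v) if isinstance(v, Mapping) else v
                    for k, v in asdict(p).items()} for c, p in config.items()}
    settings_blob = {k: list(v) if isinstance(v, tuple) else v
                     for k, v in asdict(settings).items()}
    meta = {
        "generator": "glycopap.synthetic.generate_study",
        "seed": int(seed),
        "config_hash": gio.config_hash(cfg_blob),
        "settings": settings_blob,
    }
    ds = StudyDataset(granules=granules, rois=rois, meshes=meshes, meta=meta)
    ds.validate()
    return ds
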