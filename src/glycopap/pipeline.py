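"""End-to-end analysis: from a study dataset to the figure-panel statistics.

Stages, in order (each mirroring one results panel of the study design):

1. ROI-volume comparability across conditions (omnibus only);
2. normalized granule density per condition, omnibus + post hoc;
3. per-condition Spearman of log2(density) vs ASI area (ROI grain);
4. density stratified by SER and by presynaptic mitochondrion: omnibus +
   post hoc across conditions within each flag level, plus the two-group
   within-condition comparison (Dunn on two groups, i.e. the tie-corrected
   rank test);
5. granule diameter and glucose-residue content per condition (granule
   grain), omnibus + post hoc;
6. within-window per-ROI mean granule-to-ASI distance, omnibus + post hoc;
7. granule-level diameter vs distance Spearman for S and CSR;
8. ROI-level astrocytic coverage vs mean distance Spearman for S and CSR.

Every table records the grain ("roi" or "granule"), the n actually used and
the p-value adjustment method. A failing stage aborts the run with an error
naming the stage; no partial report object is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import GlycopapError, ValidationError
from .model import CONDITIONS, StatReport, StudyDataset
from .geometry import compute_distances, apply_window
from .metrics import GrParams, compute_roi_metrics, glucose_residues, stratify
from .stats import dunn_posthoc, kruskal_wallis, spearman

#: condition pairs reported for the correlation panels of stages 7-8
_CORR_CONDITIONS = ("S", "CSR")


@dataclass(frozen=True)
class PipelineConfig:
    window_nm: float = 500.0
    alpha: float = 0.05
    gr_params: GrParams = field(default_factory=GrParams)
    adjustment: str = "bonferroni"
    distance_mode: str = "center"
    log2_density_for_asi_corr: bool = True
    skip_missing_geometry: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if not self.window_nm > 0:
            raise ValidationError("window_nm must be > 0")


def _summary(values_by_condition: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for cond in CONDITIONS:
        if cond not in values_by_condition:
            continue
        v = np.asarray(values_by_condition[cond], dtype=float)
        v = v[np.isfinite(v)]
        rows.append({
            "condition": cond, "n": len(v),
            "mean": float(v.mean()) if len(v) else np.nan,
            "sem": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
        })
    return pd.DataFrame(rows, columns=["condition", "n", "mean", "sem"])


def _groups(metric: pd.Series, by: pd.Series) -> dict[str, np.ndarray]:
    out = {}
    for cond in CONDITIONS:
        v = metric[by == cond].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if len(v):
            out[cond] = v
    return out


class _Collector:
    def __init__(self, adjustment: str):
        self.adjustment = adjustment
        self.omnibus, self.posthoc, self.correlations = [], [], []

    def omnibus_and_posthoc(self, analysis: str, grain: str,
                            groups: dict[str, np.ndarray], *, posthoc: bool = True):
        labels = [c for c in CONDITIONS if c in groups]
        if len(labels) < 2:
            return
        kw = kruskal_wallis([groups[c] for c in labels], labels)
        self.omnibus.append({
            "analysis": analysis, "grain": grain, "test": "kruskal_wallis",
            "statistic": kw.statistic, "df": kw.df,
            "n": int(sum(len(groups[c]) for c in labels)), "p": kw.p_value,
        })
        if posthoc:
            for pr in dunn_posthoc([groups[c] for c in labels], labels, self.adjustment):
                self.posthoc.append({
                    "analysis": analysis, "grain": grain,
                    "group1": pr.pair[0], "group2": pr.pair[1], "z": pr.z,
                    "p_raw": pr.p_raw, "p_adjusted": pr.p_adjusted,
                    "adjustment": pr.adjustment,
                })

    def two_group(self, analysis: str, grain: str, label1: str, label2: str,
                  g1: np.ndarray, g2: np.ndarray):
        """Within-condition two-group rank comparison (Dunn on two groups)."""
        if len(g1) == 0 or len(g2) == 0 or len(g1) + len(g2) < 3:
            return
        pr = dunn_posthoc([g1, g2], [label1, label2], "none")[0]
        self.posthoc.append({
            "analysis": analysis, "grain": grain,
            "group1": pr.pair[0], "group2": pr.pair[1], "z": pr.z,
            "p_raw": pr.p_raw, "p_adjusted": pr.p_adjusted, "adjustment": "none",
        })

    def correlation(self, analysis: str, condition: str, grain: str,
                    x: np.ndarray, y: np.ndarray, n_excluded: int = 0):
        row = {"analysis": analysis, "condition": condition, "grain": grain,
               "n": len(x), "n_excluded": n_excluded}
        try:
            res = spearman(x, y)
            row.update(rho=res.statistic, p=res.p_value)
        except ValidationError:          # degenerate (constant) input
            row.update(rho=np.nan, p=np.nan)
        self.correlations.append(row)


def run_full_analysis(dataset: StudyDataset, config: PipelineConfig = PipelineConfig(),
                      ) -> StatReport:
    """Run the whole analysis battery on a validated study dataset."""
    stage = "validate_input"
    try:
        dataset.validate(allow_missing_meshes=config.skip_missing_geometry)
        col = _Collector(config.adjustment)
        tables: dict[str, pd.DataFrame] = {}

        stage = "distances"
        distances = compute_distances(
            dataset, window_nm=config.window_nm, mode=config.distance_mode,
            skip_missing_geometry=config.skip_missing_geometry)

        stage = "roi_metrics"
        metrics = compute_roi_metrics(dataset, distances, config.gr_params,
                                      config.window_nm)
        tables["roi_metrics"] = metrics

        stage = "roi_volume"
        by = dataset.rois["condition"]
        vol_groups = _groups(dataset.rois["roi_volume_um3"], by)
        tables["roi_volume"] = _summary(vol_groups)
        col.omnibus_and_posthoc("roi_volume", "roi", vol_groups, posthoc=False)

        stage = "density"
        dens_groups = _groups(metrics["density"], metrics["condition"])
        tables["density"] = _summary(dens_groups)
        col.omnibus_and_posthoc("density", "roi", dens_groups)

        stage = "density_vs_asi"
        for cond in CONDITIONS:
            sub = metrics[metrics["condition"] == cond]
            if len(sub) < 3:
                continue
            if config.log2_density_for_asi_corr:
                sub = sub[sub["density"] > 0]  # log2 undefined at zero granules
                x = np.log2(sub["density"].to_numpy())
            else:
                x = sub["density"].to_numpy()
            excl = int((metrics["condition"] == cond).sum() - len(sub))
            y = sub["asi_area_um2"].to_numpy()
            if len(x) >= 3:
                col.correlation("log2_density_vs_asi", cond, "roi", x, y, excl)

        stage = "density_stratified"
        for flag, tag in (("ser_flag", "ser"), ("mito_flag", "mito")):
            parts = stratify(metrics, flag)
            for present, suffix in ((True, "pos"), (False, "neg")):
                groups = {}
                rows = []
                for cond in CONDITIONS:
                    if cond not in parts:
                        continue
                    sub = parts[cond][0 if present else 1]
                    v = sub["density"].to_numpy(dtype=float)
                    if len(v):
                        groups[cond] = v
                    rows.append({"condition": cond, "n": len(v),
                                 "mean": float(v.mean()) if len(v) else np.nan,
                                 "sem": float(v.std(ddof=1) / np.sqrt(len(v)))
                                 if len(v) > 1 else np.nan})
                tables[f"density_{tag}_{suffix}"] = pd.DataFrame(
                    rows, columns=["condition", "n", "mean", "sem"])
                col.omnibus_and_posthoc(f"density_{tag}_{suffix}", "roi", groups)
            for cond in CONDITIONS:
                if cond not in parts:
                    continue
                pos, neg = parts[cond]
                col.two_group(f"density_{tag}_within_{cond}", "roi",
                              f"{tag}+", f"{tag}-",
                              pos["density"].to_numpy(dtype=float),
                              neg["density"].to_numpy(dtype=float))

        stage = "diameter_and_gr"
        g = dataset.granules.merge(dataset.rois[["roi_id", "condition"]], on="roi_id")
        diam_groups = _groups(g["diameter_nm"], g["condition"])
        tables["diameter"] = _summary(diam_groups)
        col.omnibus_and_posthoc("diameter", "granule", diam_groups)
        gr_values = pd.Series(glucose_residues(g["diameter_nm"].to_numpy(),
                                               config.gr_params), index=g.index)
        gr_groups = _groups(gr_values, g["condition"])
        tables["gr"] = _summary(gr_groups)
        col.omnibus_and_posthoc("gr", "granule", gr_groups)

        stage = "distance"
        dist_groups = _groups(metrics["mean_distance"], metrics["condition"])
        tables["distance"] = _summary(dist_groups)
        col.omnibus_and_posthoc("distance", "roi", dist_groups)

        stage = "diameter_vs_distance"
        gd = g.merge(distances[["granule_id", "distance_nm", "within_window"]],
                     on="granule_id")
        for cond in _CORR_CONDITIONS:
            sub = gd[(gd["condition"] == cond) & gd["within_window"]]
            if len(sub) >= 3:
                col.correlation("diameter_vs_distance", cond, "granule",
                                sub["distance_nm"].to_numpy(),
                                sub["diameter_nm"].to_numpy(),
                                int((gd["condition"] == cond).sum() - len(sub)))

        stage = "coverage_vs_distance"
        for cond in _CORR_CONDITIONS:
            sub = metrics[(metrics["condition"] == cond)
                          & metrics["coverage"].notna()
                          & metrics["mean_distance"].notna()]
            if len(sub) >= 3:
                col.correlation("coverage_vs_distance", cond, "roi",
                                sub["coverage"].to_numpy(),
                                sub["mean_distance"].to_numpy(),
                                int((metrics["condition"] == cond).sum() - len(sub)))

        stage = "assemble_report"
        report = StatReport(
            per_condition_tables=tables,
            omnibus=pd.DataFrame(col.omnibus, columns=[
                "analysis", "grain", "test", "statistic", "df", "n", "p"]),
            posthoc=pd.DataFrame(col.posthoc, columns=[
                "analysis", "grain", "group1", "group2", "z",
                "p_raw", "p_adjusted", "adjustment"]),
            correlations=pd.DataFrame(col.correlations, columns=[
                "analysis", "condition", "grain", "n", "n_excluded", "rho", "p"]),
            meta={
                "config": asdict(config),
                "dataset_meta": dict(dataset.meta),
                "skipped_rois": list(distances.attrs.get("skipped_rois", [])),
            },
        )
        report.validate()
        return report
    except GlycopapError as err:
        raise type(err)(f"stage {stage!r}: {err}") from err
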