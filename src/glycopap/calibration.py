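"""Simulation suites: type-I error, parameter recovery, qualitative checks.

These routines exercise the whole package end to end on seeded synthetic
studies and are what the acceptance machinery and the
``glycopap simulate-calibration`` subcommand run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model import CONDITIONS, StudyDataset
from .pipeline import PipelineConfig, run_full_analysis
from .stats import kruskal_wallis, spearman
from .synthetic import ConditionParams, GeneratorSettings, default_config, generate_study


def kw_null_rejection_rate(n_replicates: int = 10_000, k: int = 4,
                           n_per_group: int = 80, alpha: float = 0.05,
                           seed: int = 0) -> float:
    """Empirical type-I error of the Kruskal-Wallis test under a continuous null.

    Draws ``n_replicates`` datasets of ``k`` groups x ``n_per_group`` i.i.d.
    standard-normal observations and returns the fraction of p-values below
    ``alpha``. Should sit within Monte-Carlo error of ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejected = 0
    for _ in range(n_replicates):
        data = rng.standard_normal((k, n_per_group))
        if kruskal_wallis(list(data)).p_value < alpha:
            rejected += 1
    return rejected / n_replicates


def realized_correlations(dataset: StudyDataset, window_nm: float = 500.0,
                          ) -> pd.DataFrame:
    """Sample Spearman rho for every copula-coupled variable pair, per condition.

    Measures the pairs on the grain at which the generator coupled them:
    density vs ASI area and coverage vs within-window mean distance at ROI
    grain, diameter vs distance over all granules at granule grain.
    """
    from .geometry import compute_distances, per_roi_mean_distances, coverage_fraction

    distances = compute_distances(dataset, window_nm=window_nm)
    rows = []
    rois = dataset.rois
    g = dataset.granules.merge(rois[["roi_id", "condition"]], on="roi_id")
    gd = g.merge(distances[["granule_id", "distance_nm"]], on="granule_id")
    mean_dist = per_roi_mean_distances(distances, window_nm)
    coverage = pd.Series({rid: coverage_fraction(dataset.meshes[ref])
                          for rid, ref in zip(rois["roi_id"], rois["asi_mesh_ref"])
                          if dataset.meshes[ref].n_segments})
    for cond in CONDITIONS:
        sub = rois[rois["condition"] == cond]
        if len(sub) < 3:
            continue
        counts = dataset.granules["roi_id"].value_counts()
        dens = (counts.reindex(sub["roi_id"]).fillna(0)
                / sub.set_index("roi_id")["astro_volume_um3"]).to_numpy()
        res = spearman(dens, sub["asi_area_um2"].to_numpy())
        rows.append({"condition": cond, "pair": "density_vs_asi",
                     "rho": res.statistic, "n": res.df})
        gsub = gd[gd["condition"] == cond]
        if len(gsub) >= 3:
            res = spearman(gsub["distance_nm"].to_numpy(),
                           gsub["diameter_nm"].to_numpy())
            rows.append({"condition": cond, "pair": "diameter_vs_distance",
                         "rho": res.statistic, "n": res.df})
        joined = pd.DataFrame({"cov": coverage, "dist": mean_dist}).dropna()
        joined = joined.loc[joined.index.intersection(sub["roi_id"])]
        if len(joined) >= 3:
            res = spearman(joined["cov"].to_numpy(), joined["dist"].to_numpy())
            rows.append({"condition": cond, "pair": "coverage_vs_distance",
                         "rho": res.statistic, "n": res.df})
    return pd.DataFrame(rows, columns=["condition", "pair", "rho", "n"])


@dataclass
class SeedOutcome:
    """Per-seed recovery and qualitative-reproduction summary."""

    seed: int
    means: pd.DataFrame            # condition x metric: recovered vs configured
    correlations: pd.DataFrame     # realized rho vs copula target
    density_omnibus_p: float
    density_dunn: dict             # pair -> (z, p_adjusted)
    diameter_means: dict
    distance_means: dict
    corr_panel: pd.DataFrame       # the pipeline's S/CSR correlation panels

    def means_recovered(self, tol_sems: float = 3.0) -> bool:
        m = self.means
        return bool((np.abs(m["recovered"] - m["target"])
                     <= tol_sems * m["target_sem"]).all())

    def correlations_recovered(self) -> bool:
        c = self.correlations
        return bool((np.abs(c["rho"] - c["target"]) <= 3.0 / np.sqrt(c["n"])).all())

    def qualitative(self, alpha: float = 0.05) -> dict[str, bool]:
        dens_dir = all(self.density_dunn[("S", c)][0] < 0 for c in ("W", "SD", "CSR"))
        dm = self.diameter_means
        order = dm["S"] > dm["W"] > dm["SD"] > dm["CSR"]
        csr_closest = min(self.distance_means, key=self.distance_means.get) == "CSR"
        cp = self.corr_panel.set_index(["analysis", "condition"])
        neg = {}
        for name in ("diameter_vs_distance", "coverage_vs_distance"):
            row = cp.loc[(name, "CSR")]
            neg[name] = bool(row["rho"] < 0 and row["p"] < alpha)
        return {
            "density_omnibus": self.density_omnibus_p < alpha,
            "density_wake_above_sleep": dens_dir,
            "diameter_ordering": order,
            "csr_distance_smallest": csr_closest,
            "csr_negative_correlations": neg["diameter_vs_distance"]
                                         and neg["coverage_vs_distance"],
        }

    def qualitative_all(self, alpha: float = 0.05) -> bool:
        return all(self.qualitative(alpha).values())


def mean_correlation_recovery(outcomes: list["SeedOutcome"]) -> pd.DataFrame:
    """Seed-averaged realized rho per condition/pair vs its copula target.

    The copula contract is an expectation statement: the seed-averaged
    realized Spearman rho should sit within 3/sqrt(n) of the target.
    """
    stacked = pd.concat([o.correlations for o in outcomes], ignore_index=True)
    agg = stacked.groupby(["condition", "pair"]).agg(
        rho=("rho", "mean"), n=("n", "mean"), target=("target", "first")).reset_index()
    agg["band"] = 3.0 / np.sqrt(agg["n"])
    agg["ok"] = np.abs(agg["rho"] - agg["target"]) <= agg["band"]
    return agg


def evaluate_seed(seed: int, config: Mapping[str, ConditionParams] | None = None,
                  settings: GeneratorSettings = GeneratorSettings(),
                  pipeline_config: PipelineConfig = PipelineConfig()) -> SeedOutcome:
    """Generate one study, run the full pipeline, compare against calibration."""
    config = default_config() if config is None else config
    dataset = generate_study(config, seed=seed, settings=settings)
    report = run_full_analysis(dataset, pipeline_config)

    mean_rows = []
    for metric, table in (("density", "density"), ("diameter", "diameter"),
                          ("distance", "distance")):
        tab = report.per_condition_tables[table].set_index("condition")
        for cond, p in config.items():
            target = {"density": p.density_mean, "diameter": p.diam_mean,
                      "distance": p.dist_mean}[metric]
            sem = {"density": p.density_sem, "diameter": p.diam_sem,
                   "distance": p.dist_sem}[metric]
            mean_rows.append({"condition": cond, "metric": metric,
                              "recovered": float(tab.loc[cond, "mean"]),
                              "target": target, "target_sem": sem})
    means = pd.DataFrame(mean_rows)

    realized = realized_correlations(dataset, pipeline_config.window_nm)
    targets = []
    for cond, p in config.items():
        for pair_key, pair in (("density_vs_asi", "density_vs_asi"),
                               ("diameter_vs_distance", "diameter_vs_distance"),
                               ("coverage_vs_distance", "coverage_vs_distance")):
            targets.append({"condition": cond, "pair": pair,
                            "target": p.rank_corrs.get(pair_key, 0.0)})
    corr = realized.merge(pd.DataFrame(targets), on=["condition", "pair"])

    omnibus = report.omnibus.set_index("analysis")
    dens_p = float(omnibus.loc["density", "p"])
    dunn = {}
    ph = report.posthoc
    for row in ph[ph["analysis"] == "density"].itertuples(index=False):
        dunn[(row.group1, row.group2)] = (row.z, row.p_adjusted)
    diam = dict(zip(report.per_condition_tables["diameter"]["condition"],
                    report.per_condition_tables["diameter"]["mean"]))
    dist = dict(zip(report.per_condition_tables["distance"]["condition"],
                    report.per_condition_tables["distance"]["mean"]))
    panel = report.correlations[report.correlations["analysis"].isin(
        ("diameter_vs_distance", "coverage_vs_distance"))]
    return SeedOutcome(seed=seed, means=means, correlations=corr,
                       density_omnibus_p=dens_p, density_dunn=dunn,
                       diameter_means=diam, distance_means=dist,
                       corr_panel=panel)


def pooled_mean_gr(dataset: StudyDataset, condition: str = "S") -> float:
    """Granule-pooled mean glucose-residue count for one condition."""
    from .metrics import glucose_residues

    g = dataset.granules.merge(dataset.rois[["roi_id", "condition"]], on="roi_id")
    d = g.loc[g["condition"] == condition, "diameter_nm"].to_numpy()
    return float(np.mean(glucose_residues(d)))
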