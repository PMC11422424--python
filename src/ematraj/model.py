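"""Model/results interface to the trajectory-clustering analysis.

:class:`EmaTrajectoryModel` wraps long-format EMA records (one row per item
per beep) plus the presented-beep information needed for compliance
filtering.  ``fit()`` runs the full analysis — item extraction, compliance
filtering, slot-grid harmonization, random-forest imputation, composite
scoring, banded DTW at every configured window, Ward.D2 and k-means
clustering over the configured k range, and subsampling Jaccard stability —
and returns a :class:`TrajectoryClusterResults` carrying the cluster
assignments, per-cluster stability, the selected number of clusters, and a
``summary()`` table.  Cluster characterization against baseline variables
hangs off the results object.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocess, stats
from .cluster import ClusterSolution, cluster_matrix, hclust_ward2
from .config import ITEMS, PipelineConfig
from .dtw import DtwConfig, pairwise_dtw
from .impute import composite_score, impute_all_items
from .simulate import BeepSchedule
from .stability import KSelection, StabilityReport, select_k, stability_scan


class EmaTrajectoryModel:
    """Trajectory-clustering model over long-format EMA records."""

    def __init__(
        self,
        records: pd.DataFrame,
        schedules: dict[str, BeepSchedule] | None = None,
        presented_beeps: dict[str, int] | None = None,
        config: PipelineConfig | None = None,
    ) -> None:
        required = {"participant_id", "day", "time", "item", "rating"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        self.records = records
        self.schedules = schedules
        self.presented_beeps = presented_beeps
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, **kwargs) -> "EmaTrajectoryModel":
        return cls(records, **kwargs)

    @classmethod
    def from_csv(cls, path: str, **kwargs) -> "EmaTrajectoryModel":
        from .io import read_ema_csv

        return cls(read_ema_csv(path), **kwargs)

    def fit(self) -> "TrajectoryClusterResults":
        cfg = self.config
        records = preprocess.extract_psychotic_items(self.records)

        if self.schedules is not None or self.presented_beeps is not None:
            comp = preprocess.filter_compliance(
                records,
                schedules=self.schedules,
                presented_beeps=self.presented_beeps,
                min_response_rate=cfg.min_response_rate,
            )
            records = records[records["participant_id"].isin(comp.included)]
            exclusion_log = comp.log
        else:
            warnings.warn(
                "no presented-beep information; compliance filtering skipped",
                stacklevel=2,
            )
            exclusion_log = pd.DataFrame()

        grid = preprocess.assign_slots(records)
        item_mats = {item: preprocess.item_matrix(grid, item) for item in ITEMS}
        completed, imputation_reports = impute_all_items(
            item_mats,
            n_trees=cfg.n_trees,
            seed=cfg.seed_for("impute"),
            max_iter=cfg.max_impute_iter,
        )
        composite = composite_score(completed)

        distances: dict[int, np.ndarray] = {}
        trees: dict[int, np.ndarray] = {}
        ids: list[str] = [str(i) for i in composite.index]
        for w in cfg.windows:
            _, D = pairwise_dtw(
                composite, DtwConfig(window=w, normalize=cfg.normalize_dtw)
            )
            distances[w] = D
            trees[w] = hclust_ward2(D)

        stability_reports: dict[int, list[StabilityReport]] = {}
        selections: dict[int, KSelection] = {}
        algorithms = (
            ("hierarchical", "kmeans")
            if cfg.kmeans_variant == "rows"
            else ("hierarchical", "kmedoids")
        )
        for w in cfg.windows:
            reports = stability_scan(
                distances[w],
                algorithms=algorithms,
                k_range=cfg.k_range,
                n_resamples=cfg.n_resamples,
                fraction=cfg.subsample_fraction,
                seed=cfg.seed_for("stability"),
                ids=ids,
                n_init=cfg.stability_n_init,
            )
            stability_reports[w] = reports
            selections[w] = select_k(
                reports,
                threshold=cfg.stability_threshold,
                aggregate=cfg.stability_aggregate,
            )

        # primary solution: selected k at the primary window
        w0 = cfg.primary_window if cfg.primary_window in distances else cfg.windows[0]
        sel = selections[w0]
        solutions: dict[tuple[str, int], ClusterSolution] = {}
        for algorithm in algorithms:
            for k in cfg.k_range:
                solutions[(algorithm, k)] = cluster_matrix(
                    distances[w0],
                    algorithm,
                    k,
                    ids=ids,
                    n_init=cfg.kmeans_n_init,
                    seed=cfg.seed_for("cluster"),
                )
        if sel.primary is not None:
            primary_solution = solutions[sel.primary]
        else:
            primary_solution = solutions[(algorithms[0], cfg.k_range[0])]

        return TrajectoryClusterResults(
            model=self,
            composite=composite,
            distances=distances,
            trees=trees,
            stability_reports=stability_reports,
            selections=selections,
            solutions=solutions,
            primary_window=w0,
            primary_solution=primary_solution,
            exclusion_log=exclusion_log,
            imputation_reports=imputation_reports,
        )


@dataclass
class TrajectoryClusterResults:
    """Fitted trajectory-clustering results."""

    model: EmaTrajectoryModel
    composite: pd.DataFrame
    distances: dict[int, np.ndarray]
    trees: dict[int, np.ndarray]
    stability_reports: dict[int, list[StabilityReport]]
    selections: dict[int, KSelection]
    solutions: dict[tuple[str, int], ClusterSolution]
    primary_window: int
    primary_solution: ClusterSolution
    exclusion_log: pd.DataFrame = field(default_factory=pd.DataFrame)
    imputation_reports: list = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return self.primary_solution.ids

    @property
    def labels_(self) -> pd.Series:
        return pd.Series(
            self.primary_solution.labels, index=self.ids, name="cluster"
        )

    @property
    def selected_k(self) -> int | None:
        return self.selections[self.primary_window].selected_k

    def selected_k_by_window(self) -> dict[int, int | None]:
        return {w: sel.selected_k for w, sel in self.selections.items()}

    def stability_table(self, window: int | None = None) -> pd.DataFrame:
        """Tidy frame: algorithm, k, cluster, mean Jaccard, skips."""
        window = window if window is not None else self.primary_window
        rows = []
        for rep in self.stability_reports[window]:
            for ci, (mj, sk) in enumerate(
                zip(rep.mean_jaccard, rep.n_skipped), start=1
            ):
                rows.append(
                    dict(algorithm=rep.algorithm, k=rep.k, cluster=ci,
                         mean_jaccard=float(mj), n_skipped=int(sk),
                         n_resamples=rep.n_resamples, seed=rep.seed)
                )
        return pd.DataFrame(rows)

    def trajectory_summaries(self) -> pd.DataFrame:
        """Per-participant mean rating and corrected rating variance."""
        rows = []
        for pid, traj in self.composite.iterrows():
            s = stats.summarize_trajectory(traj.to_numpy(), participant_id=str(pid))
            rows.append(
                dict(participant_id=s.participant_id,
                     mean_rating=s.mean_rating,
                     corrected_variance=s.corrected_variance)
            )
        return pd.DataFrame(rows).set_index("participant_id")

    def characterize(
        self,
        baseline: pd.DataFrame | None = None,
        variables: list[stats.VariableSpec] | None = None,
        fdr_level: float | None = None,
    ) -> pd.DataFrame:
        """Compare clusters on EMA summaries, group labels and baseline
        variables, with family-wise BH-FDR."""
        summaries = self.trajectory_summaries()
        data = summaries.copy()
        recs = self.model.records
        group_map = (
            recs.drop_duplicates("participant_id")
            .set_index("participant_id")["group"]
            if "group" in recs.columns
            else None
        )
        specs = [
            stats.VariableSpec("mean_rating", "cluster_characterization"),
            stats.VariableSpec("corrected_variance", "cluster_characterization"),
        ]
        if group_map is not None:
            data["group"] = group_map.reindex(data.index)
            specs.append(
                stats.VariableSpec("group", "demographics", kind="categorical")
            )
        if baseline is not None:
            data = data.join(baseline, how="left")
        if variables:
            specs.extend(variables)
        fdr = fdr_level if fdr_level is not None else self.model.config.fdr_level
        return stats.characterize_clusters(
            self.labels_, data, specs, fdr_level=fdr
        )

    def adjusted_rand(self, true_labels: pd.Series) -> float:
        """Adjusted Rand index of the primary solution vs external labels."""
        from sklearn.metrics import adjusted_rand_score

        truth = true_labels.reindex(self.ids)
        if truth.isna().any():
            raise ValueError("true labels missing for some participants")
        return float(adjusted_rand_score(truth.to_numpy(), self.primary_solution.labels))

    def summary(self) -> str:
        """Plain-text fit summary."""
        buf = _io.StringIO()
        n = len(self.ids)
        print("EMA trajectory clustering results", file=buf)
        print("=" * 42, file=buf)
        print(f"participants: {n}", file=buf)
        print(f"windows: {sorted(self.distances)}", file=buf)
        sel_by_w = self.selected_k_by_window()
        print(f"selected k by window: {sel_by_w}", file=buf)
        sel = self.selections[self.primary_window]
        print(f"primary window: {self.primary_window}", file=buf)
        if sel.primary:
            print(f"primary solution: {sel.primary[0]}, k={sel.primary[1]}", file=buf)
        else:
            print("primary solution: none stable; fallback shown", file=buf)
        labels = self.labels_
        sizes = labels.value_counts().sort_index()
        print("cluster sizes: "
              + ", ".join(f"{c}: {s}" for c, s in sizes.items()), file=buf)
        summ = self.trajectory_summaries().join(labels)
        means = summ.groupby("cluster")["mean_rating"].mean()
        print("mean composite rating by cluster: "
              + ", ".join(f"{c}: {m:.2f}" for c, m in means.items()), file=buf)
        tab = self.stability_table()
        stable = tab.groupby(["algorithm", "k"])["mean_jaccard"].min().reset_index()
        print("min clusterwise Jaccard by (algorithm, k):", file=buf)
        for _, r in stable.iterrows():
            flag = " *" if r["mean_jaccard"] > self.model.config.stability_threshold else ""
            print(f"  {r['algorithm']:>12} k={int(r['k']):<2} "
                  f"{r['mean_jaccard']:.3f}{flag}", file=buf)
        return buf.getvalue()

    def plot_heatmap(self, window: int | None = None, ax=None):
        """Distance-matrix heatmap ordered by the primary clustering."""
        import matplotlib.pyplot as plt

        window = window if window is not None else self.primary_window
        order = np.argsort(self.primary_solution.labels, kind="stable")
        D = self.distances[window][np.ix_(order, order)]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(D, cmap="RdBu", interpolation="nearest")
        ax.set_title(f"Pairwise DTW distances (window={window})")
        plt.colorbar(im, ax=ax)
        return ax

    def plot_dendrogram(self, window: int | None = None, ax=None):
        """Dendrogram of the Ward.D2 merge tree."""
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram

        window = window if window is not None else self.primary_window
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        dendrogram(self.trees[window], ax=ax, no_labels=True)
        ax.set_title(f"Ward.D2 dendrogram (window={window})")
        return ax
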