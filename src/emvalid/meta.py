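"""Metric meta-analysis: correlation, clustering and composite Z-rankings.

Given a table of model scores (rows = submitted models, columns = metrics),
this module reproduces the comparison methodology used to study how
validation metrics behave as a population: pooled and per-target Pearson
correlation matrices, hierarchical clustering of metrics by the similarity
1 - |r| (complete linkage), per-target score distribution summaries, and
composite Z-score rankings of models and teams under declared metric
weights.

Scores are never imputed: correlations use pairwise-complete observations
and Z-rankings drop a metric within a target when its scores are missing or
degenerate.  Every metric used in a ranking must have a declared
orientation (higher- or lower-is-better); refusing to guess prevents silent
sign errors, the worst failure mode of composite rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ScoreTable", "CorrMatrix", "ClusterResult", "ZRanking",
    "load_scores", "correlation_matrix", "cluster_metrics", "composite_z",
    "distribution_summary", "planted_score_table",
    "DEFAULT_ORIENTATIONS", "DEFAULT_WEIGHT_SETS",
]

ID_COLUMNS = ("model", "team", "target", "category")

# higher-is-better unless stated; outlier counts and deviations are lower
DEFAULT_ORIENTATIONS = {
    "ccbox": "higher", "ccc": "higher", "ccmask": "higher", "ccpeaks": "higher",
    "ccc_ov": "higher", "lap": "higher", "mi": "higher", "mi_ov": "higher",
    "smoc": "higher", "fsc_avg": "higher", "atom_inclusion": "higher",
    "env": "higher", "qscore": "higher", "emringer": "higher",
    "fsc05": "lower",          # a resolution in Å: smaller is better
    "bond_rmsd": "lower", "angle_rmsd": "lower", "chiral_rmsd": "lower",
    "planar_rmsd": "lower", "dihedral_rmsd": "lower",
    "clashscore": "lower", "rama_outliers": "lower", "rotamer_outliers": "lower",
    "cablam_outliers": "lower", "ca_geom_outliers": "lower",
    "gdt_ts": "higher", "gdc_all": "higher", "gdc_sc": "higher",
    "ca_rmsd": "lower", "lddt": "higher", "cad": "higher", "hbpr_gt6": "higher",
    "davis_qa": "higher",
}

# published default weight sets for composite rankings
DEFAULT_WEIGHT_SETS = {
    "coordinates_only": {"cablam_outliers": 0.5, "ca_geom_outliers": 0.3,
                         "clashscore": 0.2},
    "fit_to_map": {"emringer": 0.3, "qscore": 0.3, "atom_inclusion": 0.2,
                   "smoc": 0.2},
    "vs_reference": {"lddt": 0.9, "gdc_all": 0.9, "hbpr_gt6": 0.2},
}


def planted_score_table(seed: int, sizes=(16, 15, 15, 17), n_blocks: int = 3,
                        per_block: int = 3, noise: float = 0.15,
                        ) -> tuple["ScoreTable", dict[str, int]]:
    """Synthetic score table with a planted metric correlation block
    structure, for validating the clustering methodology.

    Each pseudo-target contributes models whose metric values are driven by
    ``n_blocks`` independent latent factors; metrics in the same block share
    a factor (the last metric of each block negated, exercising the |r|
    similarity), plus Gaussian noise.  Returns the table and the true
    metric -> block labeling.
    """
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for k, n in enumerate(sizes):
        target = f"T{k + 1}"
        for _ in range(n):
            latent = rng.normal(size=n_blocks)
            row = {"model": f"m{i:03d}", "target": target}
            for b in range(n_blocks):
                for j in range(per_block):
                    sign = -1.0 if j == per_block - 1 else 1.0
                    row[f"metric_{b}{j}"] = (sign * latent[b]
                                             + noise * rng.normal())
            rows.append(row)
            i += 1
    truth = {f"metric_{b}{j}": b for b in range(n_blocks)
             for j in range(per_block)}
    table = ScoreTable(pd.DataFrame(rows))
    return table, truth


# ---------------------------------------------------------------------------
# Score table
# ---------------------------------------------------------------------------

@dataclass
class ScoreTable:
    """Models × metrics score table with per-metric orientations.

    ``data`` must carry ``model`` and ``target`` identifier columns
    (``team`` and ``category`` optional); every other column is a metric.
    """

    data: pd.DataFrame
    orientations: dict[str, str] = field(default_factory=dict)
    n_missing: int = 0

    def __post_init__(self) -> None:
        for col in ("model", "target"):
            if col not in self.data.columns:
                raise ValueError(f"score table needs a {col!r} column")
        dup = self.data.duplicated(subset=["model", "target"])
        if dup.any():
            bad = self.data.loc[dup, "model"].tolist()
            raise ValueError(f"duplicate (model, target) rows for: {bad}")
        for m, o in self.orientations.items():
            if o not in ("higher", "lower"):
                raise ValueError(f"orientation for {m!r} must be higher|lower")

    @property
    def metrics(self) -> list[str]:
        return [c for c in self.data.columns if c not in ID_COLUMNS]

    @property
    def targets(self) -> list[str]:
        return sorted(self.data["target"].unique().tolist())

    def orientation(self, metric: str) -> str | None:
        return self.orientations.get(metric, DEFAULT_ORIENTATIONS.get(metric))


def load_scores(path, orientations: dict[str, str] | None = None) -> ScoreTable:
    """Load a CSV of model scores.

    Unparsable metric cells become missing values and are counted in
    ``n_missing``; duplicated (model, target) rows are an error.
    """
    raw = pd.read_csv(path, dtype=str).rename(columns=str.strip)
    if "model" not in raw.columns or "target" not in raw.columns:
        raise ValueError("CSV must have 'model' and 'target' columns")
    out = raw[[c for c in raw.columns if c in ID_COLUMNS]].copy()
    n_missing = 0
    for col in raw.columns:
        if col in ID_COLUMNS:
            continue
        vals = pd.to_numeric(raw[col], errors="coerce")
        n_missing += int((vals.isna() & raw[col].notna()
                          & (raw[col].str.strip() != "")).sum())
        n_missing += int((raw[col].isna() | (raw[col].str.strip() == "")).sum())
        out[col] = vals
    return ScoreTable(data=out, orientations=orientations or {},
                      n_missing=n_missing)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrMatrix:
    metrics: list[str]
    values: np.ndarray          # symmetric, diagonal 1, entries may be NaN
    counts: np.ndarray          # pairwise-complete sample sizes
    scope: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.max(np.abs(finite)) > 1 + 1e-9:
            raise ValueError("|r| must be <= 1")

    @property
    def undefined_metrics(self) -> list[str]:
        off = ~np.eye(len(self.metrics), dtype=bool)
        return [m for i, m in enumerate(self.metrics)
                if np.all(~np.isfinite(self.values[i][off[i]]))]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.metrics, columns=self.metrics)


def _pairwise_corr(df: pd.DataFrame, min_n: int = 3):
    cols = df.columns
    k = len(cols)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        r[i, i] = 1.0
        n[i, i] = df[cols[i]].notna().sum()
        for j in range(i + 1, k):
            sub = df[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(sub)
            if len(sub) < min_n:
                continue
            x = sub.iloc[:, 0].to_numpy(float)
            y = sub.iloc[:, 1].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                continue
            r[i, j] = r[j, i] = float(np.corrcoef(x, y)[0, 1])
    return r, n


def correlation_matrix(table: ScoreTable, scope: str = "pooled",
                       min_n: int = 3) -> CorrMatrix:
    """Metric × metric Pearson matrix.

    ``pooled`` correlates over all models and targets at once;
    ``per-target-averaged`` computes one matrix per target and averages the
    coefficients, which removes between-target score-range differences.
    Zero-variance metrics yield NaN entries (flagged, excluded from
    clustering).
    """
    metrics = table.metrics
    if scope == "pooled":
        r, n = _pairwise_corr(table.data[metrics], min_n)
        return CorrMatrix(metrics, r, n, scope)
    if scope in ("per-target-averaged", "averaged"):
        mats, counts = [], []
        for t in table.targets:
            sub = table.data[table.data["target"] == t][metrics]
            r, n = _pairwise_corr(sub, min_n)
            mats.append(r)
            counts.append(n)
        stacked = np.stack(mats)
        with np.errstate(invalid="ignore"):
            mean_r = np.nanmean(stacked, axis=0)
        return CorrMatrix(metrics, mean_r, np.stack(counts).sum(axis=0), scope)
    if scope == "per-target":
        return {t: correlation_matrix(
                    ScoreTable(table.data[table.data["target"] == t].copy(),
                               table.orientations), "pooled", min_n)
                for t in table.targets}
    raise ValueError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    metrics: list[str]
    labels: dict[str, int]
    merge_heights: np.ndarray
    linkage: np.ndarray

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for m, l in self.labels.items():
            out.setdefault(l, []).append(m)
        return {k: sorted(v) for k, v in out.items()}


def cluster_metrics(corr: CorrMatrix, n_clusters: int) -> ClusterResult:
    """Complete-linkage agglomeration of metrics on distance 1 - |r|.

    The absolute value means perfectly anti-correlated metrics merge first:
    they carry the same information with opposite sign.  Metric order is
    canonicalized (lexicographic) before linkage for deterministic
    tie-breaking; merge heights are monotone under complete linkage.
    """
    if corr.undefined_metrics:
        raise ValueError(
            f"correlation undefined for {corr.undefined_metrics}; "
            "drop these metrics before clustering")
    if not 1 <= n_clusters <= len(corr.metrics):
        raise ValueError("n_clusters out of range")
    order = np.argsort(corr.metrics)
    names = [corr.metrics[i] for i in order]
    r = corr.values[np.ix_(order, order)]
    if np.any(~np.isfinite(r)):
        raise ValueError("correlation matrix contains undefined entries")
    d = 1.0 - np.abs(r)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    Z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return ClusterResult(metrics=names,
                         labels={m: int(l) for m, l in zip(names, flat)},
                         merge_heights=Z[:, 2].copy(), linkage=Z)


# ---------------------------------------------------------------------------
# Composite Z-scores
# ---------------------------------------------------------------------------

@dataclass
class ZRanking:
    z_scores: pd.DataFrame      # per (model, target): one column per metric
    composite: pd.DataFrame     # model, target, composite
    weights: dict[str, float]
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (target, metric)

    def by_team(self, table: ScoreTable) -> pd.DataFrame:
        if "team" not in table.data.columns:
            raise ValueError("score table has no 'team' column")
        merged = self.composite.merge(
            table.data[["model", "target", "team"]], on=["model", "target"])
        return (merged.groupby("team")["composite"].mean()
                .sort_values(ascending=False).reset_index())

    def averaged_over(self, targets: list[str]) -> pd.DataFrame:
        sub = self.composite[self.composite["target"].isin(targets)]
        return (sub.groupby("model")["composite"].mean()
                .sort_values(ascending=False).reset_index())


def composite_z(table: ScoreTable, weights: dict[str, float]) -> ZRanking:
    """Per-target standardized composite scores.

    Within each target, every weighted metric is standardized over that
    target's models ((x - mean) / sd); lower-is-better metrics are negated
    first so that positive Z always means better.  The composite is the
    weighted sum.  Metrics with zero variance or missing orientation within
    a target are dropped for that target and recorded.
    """
    for m in weights:
        if m not in table.metrics:
            raise ValueError(f"weighted metric {m!r} not in table")
        if table.orientation(m) is None:
            raise ValueError(
                f"metric {m!r} has no declared orientation; refusing to rank")

    z_rows, comp_rows, dropped = [], [], []
    for t in table.targets:
        sub = table.data[table.data["target"] == t]
        zcols: dict[str, pd.Series] = {}
        for m in weights:
            vals = sub[m].astype(float)
            sd = vals.std(ddof=0)
            if vals.notna().sum() < 2 or not np.isfinite(sd) or sd == 0:
                dropped.append((t, m))
                continue
            z = (vals - vals.mean()) / sd
            if table.orientation(m) == "lower":
                z = -z
            zcols[m] = z
        for idx, row in sub.iterrows():
            zs = {m: float(zcols[m].loc[idx]) if m in zcols and
                  np.isfinite(zcols[m].loc[idx]) else np.nan for m in weights}
            comp = sum(w * zs[m] for m, w in weights.items()
                       if np.isfinite(zs[m]))
            z_rows.append({"model": row["model"], "target": t, **zs})
            comp_rows.append({"model": row["model"], "target": t,
                              "composite": comp})
    return ZRanking(z_scores=pd.DataFrame(z_rows),
                    composite=pd.DataFrame(comp_rows),
                    weights=dict(weights), dropped=dropped)


# ---------------------------------------------------------------------------
# Distribution summaries
# ---------------------------------------------------------------------------

def distribution_summary(table: ScoreTable, metric: str) -> pd.DataFrame:
    """Per-target percentile summary of one metric.

    10th/25th/50th/75th/90th percentiles with the linear-interpolation
    convention (box-and-whisker reproduction depends on the convention, so
    it is fixed and documented).  ``degenerate`` marks targets whose
    quartile limits coincide, where a box plot would collapse.
    """
    if metric not in table.metrics:
        raise ValueError(f"unknown metric {metric!r}")
    rows = []
    for t in table.targets:
        vals = table.data.loc[table.data["target"] == t, metric].dropna()
        if vals.empty:
            continue
        p = np.percentile(vals, [10, 25, 50, 75, 90],
                          method="linear")
        rows.append({
            "target": t, "n": len(vals),
            "p10": p[0], "p25": p[1], "p50": p[2], "p75": p[3], "p90": p[4],
            "degenerate": bool(p[1] == p[2] == p[3]),
            "points": vals.tolist(),
        })
    return pd.DataFrame(rows)
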