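"""Stage discovery: PCA reduction, k-means with joint SSE/silhouette model
selection, ordering clusters into differentiation stages by collection time,
and cluster-level summaries.

The clusters are ordered into stages I, II, ... by the mean collection-time
rank of their member cells — the pipeline's replacement for pseudotime
ordering, justified by the observation that expression-defined clusters track
the actual collection days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from ._util import child_rng, natural_time_rank, roman, round_half_up
from .droplet import CellMatrix

# silhouette is O(n^2); above this many cells it is estimated on a seeded
# subsample of this size
_SILHOUETTE_SUBSAMPLE = 5000


@dataclass
class StagingConfig:
    n_components_M: int = 10
    k_candidates: tuple = tuple(range(2, 11))
    km_seed: int = 0
    km_restarts: int = 10

    def __post_init__(self) -> None:
        if self.n_components_M < 2:
            raise ValueError("n_components_M must be >= 2")
        if any(k < 2 for k in self.k_candidates):
            raise ValueError("all k candidates must be >= 2")


@dataclass
class StageAssignment:
    cluster: np.ndarray  # per-cell cluster id
    stage: np.ndarray | None = None  # per-cell ordered label "I".."V"...
    chosen_k: int = 0
    diagnostics: pd.DataFrame | None = None  # per-k SSE and mean silhouette
    stage_order: list = field(default_factory=list)  # labels in order

    @property
    def stages(self) -> list:
        if self.stage is None:
            raise ValueError("stages not yet ordered")
        return self.stage_order


def log_expression(cells: CellMatrix) -> np.ndarray:
    """Dense log1p of the median-normalized matrix (float32)."""
    if cells.normalized is None:
        raise ValueError("normalized matrix required; run normalize_to_median first")
    x = np.asarray(cells.normalized.todense(), dtype=np.float32)
    return np.log1p(x, out=x)


def reduce_pca(cells: CellMatrix, cfg: StagingConfig) -> np.ndarray:
    """Project log1p-normalized expression onto the top-M principal
    components (per-gene centering)."""
    x = log_expression(cells)
    n, g = x.shape
    if cfg.n_components_M >= min(n, g):
        raise ValueError(
            f"n_components_M={cfg.n_components_M} must be < min(cells, genes)"
            f"={min(n, g)}"
        )
    pca = PCA(n_components=cfg.n_components_M, svd_solver="randomized",
              random_state=cfg.km_seed)
    scores = pca.fit_transform(x)
    return scores.astype(np.float64)


def select_k_and_cluster(scores: np.ndarray, cfg: StagingConfig) -> StageAssignment:
    """Run seeded k-means over the candidate k values; pick the k with the
    highest mean silhouette, breaking exact ties by the SSE elbow (largest
    second difference), then by the smaller k."""
    scores = np.asarray(scores, dtype=float)
    if np.allclose(scores, scores[0]):
        raise ValueError("degenerate scores: all cells identical")
    n = scores.shape[0]
    if n <= max(cfg.k_candidates):
        raise ValueError("need more cells than the largest candidate k")

    rows = []
    labels_by_k = {}
    for k in cfg.k_candidates:
        km = KMeans(n_clusters=k, n_init=cfg.km_restarts, random_state=cfg.km_seed)
        lab = km.fit_predict(scores)
        labels_by_k[k] = lab
        sil_kwargs = {}
        if n > _SILHOUETTE_SUBSAMPLE:
            sil_kwargs = dict(sample_size=_SILHOUETTE_SUBSAMPLE,
                              random_state=cfg.km_seed)
        sil = silhouette_score(scores, lab, **sil_kwargs)
        rows.append({"k": k, "sse": float(km.inertia_), "silhouette": float(sil)})
    diag = pd.DataFrame(rows)

    best_sil = diag["silhouette"].max()
    tied = diag.loc[diag["silhouette"] == best_sil, "k"].tolist()
    if len(tied) > 1:
        # elbow: largest second difference of SSE over the candidate grid
        sse = diag.set_index("k")["sse"]
        ks = diag["k"].tolist()
        second_diff = {}
        for k in tied:
            i = ks.index(k)
            if 0 < i < len(ks) - 1:
                second_diff[k] = sse[ks[i - 1]] - 2 * sse[k] + sse[ks[i + 1]]
            else:
                second_diff[k] = -np.inf
        top = max(second_diff.values())
        tied = [k for k in tied if second_diff[k] == top]
    chosen = min(tied)
    return StageAssignment(cluster=labels_by_k[chosen].copy(), chosen_k=chosen,
                           diagnostics=diag)


def order_stages(
    assignment: StageAssignment, cell_table: pd.DataFrame, time_order: list | None = None
) -> StageAssignment:
    """Relabel clusters as stages I, II, ... by ascending mean
    collection-time rank; ties broken by descending cluster size."""
    tp = cell_table["time_point"].to_numpy()
    if len(tp) != len(assignment.cluster):
        raise ValueError("cell table and assignment size mismatch")
    rank_map = (
        {lab: i for i, lab in enumerate(time_order)}
        if time_order is not None
        else natural_time_rank(tp)
    )
    ranks = np.array([rank_map[t] for t in tp], dtype=float)
    ids = np.unique(assignment.cluster)
    stats = []
    for c in ids:
        mask = assignment.cluster == c
        stats.append((float(ranks[mask].mean()), -int(mask.sum()), int(c)))
    stats.sort()
    label_of = {c: roman(i) for i, (_, _, c) in enumerate(stats)}
    assignment.stage = np.array([label_of[c] for c in assignment.cluster])
    assignment.stage_order = [roman(i) for i in range(len(ids))]
    return assignment


def cluster_correlation(cells: CellMatrix, assignment: StageAssignment) -> pd.DataFrame:
    """Pearson correlation between per-stage mean log1p-normalized expression
    profiles (unit diagonal, symmetric)."""
    if assignment.stage is None:
        raise ValueError("stages not assigned")
    labels = assignment.stage_order
    if len(labels) < 2:
        raise ValueError("need at least two stages")
    x = log_expression(cells)
    profiles = []
    for lab in labels:
        mask = assignment.stage == lab
        if not mask.any():
            raise ValueError(f"stage {lab} has no cells")
        profiles.append(x[mask].mean(axis=0))
    corr = np.corrcoef(np.vstack(profiles))
    return pd.DataFrame(corr, index=labels, columns=labels)


def stage_composition(
    assignment: StageAssignment, cell_table: pd.DataFrame, time_order: list | None = None
) -> pd.DataFrame:
    """Stage x time-point cell counts with row percentages (2-decimal,
    half-up), matching the printed composition-table convention."""
    if assignment.stage is None:
        raise ValueError("stages not assigned")
    tp = cell_table["time_point"].to_numpy()
    order = time_order or list(natural_time_rank(tp))
    rows = []
    for lab in assignment.stage_order:
        mask = assignment.stage == lab
        total = int(mask.sum())
        row = {"stage": lab, "total": total}
        for t in order:
            c = int((tp[mask] == t).sum())
            row[f"{t}_count"] = c
            row[f"{t}_pct"] = round_half_up(100.0 * c / total, 2) if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
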