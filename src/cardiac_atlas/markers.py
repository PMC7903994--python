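"""Stage-specific marker detection with a two-part (hurdle) likelihood-ratio
test, stage vs rest, and Benjamini-Hochberg control over the full
gene x stage family.

The test combines a binomial component on the detection fraction (gene
observed with >= 1 UMI) with a Gaussian component on log1p-normalized
expression among detected cells (separate group means, shared variance).
Under the null both components collapse to pooled parameters, giving a chi2
statistic with 2 degrees of freedom.  The two components and the df are
isolated in :func:`hurdle_lrt` so an alternative (e.g. negative-binomial)
likelihood can be substituted without touching the scan logic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .droplet import CellMatrix
from .staging import StageAssignment

_LFC_EPS = 1e-9
_VAR_TINY = 1e-12


@dataclass
class MarkerConfig:
    alpha_adjusted: float = 0.05
    min_fraction_expressed: float = 0.1
    top_per_stage: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha_adjusted < 1:
            raise ValueError("alpha_adjusted must be in (0,1)")
        if not 0 <= self.min_fraction_expressed <= 1:
            raise ValueError("min_fraction_expressed must be in [0,1]")


@dataclass
class MarkerResult:
    table: pd.DataFrame  # gene, stage, stat, p, p_adj, lfc, tested, is_marker

    @property
    def marker_symbols(self) -> list[str]:
        return sorted(self.table.loc[self.table["is_marker"], "gene"].unique())

    def markers_for(self, stage: str) -> pd.DataFrame:
        t = self.table
        return t[(t["stage"] == stage) & t["is_marker"]].copy()


def _binom_ll(k: np.ndarray, n: float) -> np.ndarray:
    """Maximized Bernoulli log-likelihood with p̂ = k/n (0·log0 = 0)."""
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(k / n), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log((n - k) / n), 0.0)
    return t1 + t2


def hurdle_lrt(
    k1, n1, sum1, sumsq1, k2, n2, sum2, sumsq2
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-part LRT from per-group sufficient statistics.

    ``k``: detected cells, ``n``: group size, ``sum``/``sumsq``: sums of the
    log1p-normalized values over detected cells.  Returns (statistic, df=2
    chi-square p-value).  When one group has no detected cells the Gaussian
    component is dropped (the difference is fully absorbed by the binomial
    part); a zero within-group variance with a positive total variance gives
    perfect separation and p = 0.
    """
    k1 = np.asarray(k1, float)
    k2 = np.asarray(k2, float)
    stat_b = 2.0 * (_binom_ll(k1, n1) + _binom_ll(k2, n2)
                    - _binom_ll(k1 + k2, n1 + n2))

    nd = k1 + k2
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = np.where(k1 > 0, sum1 / np.maximum(k1, 1), 0.0)
        m2 = np.where(k2 > 0, sum2 / np.maximum(k2, 1), 0.0)
        m0 = np.where(nd > 0, (sum1 + sum2) / np.maximum(nd, 1), 0.0)
    ss_within = (sumsq1 - k1 * m1**2) + (sumsq2 - k2 * m2**2)
    ss_total = (sumsq1 + sumsq2) - nd * m0**2
    ss_within = np.maximum(ss_within, 0.0)
    ss_total = np.maximum(ss_total, 0.0)

    both = (k1 > 0) & (k2 > 0) & (nd >= 2)
    stat_g = np.zeros_like(stat_b)
    sep = both & (ss_within <= _VAR_TINY) & (ss_total > _VAR_TINY)
    ok = both & (ss_within > _VAR_TINY) & (ss_total > _VAR_TINY)
    stat_g[ok] = nd[ok] * (np.log(ss_total[ok]) - np.log(ss_within[ok]))
    stat_g[sep] = np.inf

    stat = stat_b + stat_g
    p = chi2.sf(stat, df=2)
    return stat, p


def detect_markers(
    cells: CellMatrix, assignment: StageAssignment, cfg: MarkerConfig | None = None
) -> MarkerResult:
    """Scan every (gene, stage) pair with the stage-vs-rest hurdle LRT.

    Genes detected in fewer than ``min_fraction_expressed`` of cells in both
    groups are reported untested.  BH adjustment spans all tested pairs; only
    up-regulated genes (positive log fold-change of mean normalized
    expression) are flagged as markers.
    """
    cfg = cfg or MarkerConfig()
    if assignment.stage is None:
        raise ValueError("stages must be assigned before marker detection")
    stages = assignment.stage_order
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    if cells.normalized is None:
        raise ValueError("normalized matrix required")

    y = cells.normalized.copy().astype(float)
    y.data = np.log1p(y.data)
    y = sp.csr_matrix(y)
    det = y.copy()
    det.data = np.ones_like(det.data)
    ysq = y.copy()
    ysq.data = ysq.data**2
    norm_mean_all = np.asarray(cells.normalized.mean(axis=0)).ravel()

    tot_k = np.asarray(det.sum(axis=0)).ravel()
    tot_s = np.asarray(y.sum(axis=0)).ravel()
    tot_sq = np.asarray(ysq.sum(axis=0)).ravel()
    n_all = cells.n_cells

    frames = []
    for lab in stages:
        mask = assignment.stage == lab
        n1 = int(mask.sum())
        n2 = n_all - n1
        if n1 < 2 or n2 < 2:
            raise ValueError(f"stage {lab} needs >= 2 cells in and out of group")
        k1 = np.asarray(det[mask].sum(axis=0)).ravel()
        s1 = np.asarray(y[mask].sum(axis=0)).ravel()
        sq1 = np.asarray(ysq[mask].sum(axis=0)).ravel()
        if k1.sum() == 0:
            raise ValueError(f"stage {lab} has all-zero counts for all genes")
        k2, s2, sq2 = tot_k - k1, tot_s - s1, tot_sq - sq1

        tested = (k1 / n1 >= cfg.min_fraction_expressed) | (
            k2 / n2 >= cfg.min_fraction_expressed
        )
        stat, p = hurdle_lrt(k1, n1, s1, sq1, k2, n2, s2, sq2)
        mean1 = np.asarray(cells.normalized[mask].mean(axis=0)).ravel()
        mean2 = (norm_mean_all * n_all - mean1 * n1) / n2
        lfc = np.log2((mean1 + _LFC_EPS) / (mean2 + _LFC_EPS))
        frames.append(
            pd.DataFrame(
                {
                    "gene": cells.genes["symbol"].to_numpy(),
                    "stage": lab,
                    "stat": stat,
                    "p": np.where(tested, p, np.nan),
                    "lfc": lfc,
                    "tested": tested,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)

    table["p_adj"] = np.nan
    tested_mask = table["tested"].to_numpy()
    if tested_mask.any():
        _, q, _, _ = multipletests(
            table.loc[tested_mask, "p"].to_numpy(), method="fdr_bh"
        )
        table.loc[tested_mask, "p_adj"] = q
    table["is_marker"] = (
        tested_mask
        & (table["p_adj"].to_numpy() < cfg.alpha_adjusted)
        & (table["lfc"].to_numpy() > 0)
    )

    if cfg.top_per_stage is not None:
        keep = np.zeros(len(table), dtype=bool)
        for lab in stages:
            sub = table[(table["stage"] == lab) & table["is_marker"]]
            top = sub.sort_values(["p_adj", "lfc"], ascending=[True, False]).head(
                cfg.top_per_stage
            )
            keep[top.index] = True
        table["is_marker"] &= keep
    return MarkerResult(table=table)
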