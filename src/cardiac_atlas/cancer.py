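"""Cancer-gene analysis: catalog loading, marker overlap, stage-mean
expression profiles (UMI/cell), monotone trend classification, rank trend
significance, per-cell positivity and stage co-occurrence calls.

Conventions fixed here: a cell is positive for a gene at >= 1 raw UMI (the
only reading under which a "silenced" gene is a zero count); a trend is
"continuous" only when the ordered stage means are strictly monotone, so any
tie breaks the trend; expression tiers are inclusive at the lower bound
(mean >= 1.00 UMI/cell) and strict at the stage-V high tier (> 10.00).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from ._util import round_half_up
from .droplet import CellMatrix
from .staging import StageAssignment


@dataclass
class GeneCatalog:
    oncogenes: set
    tsgs: set

    @property
    def dual(self) -> set:
        return self.oncogenes & self.tsgs

    @property
    def union(self) -> set:
        return self.oncogenes | self.tsgs

    def role_of(self, symbol: str) -> str:
        s = symbol.upper()
        if s in self.dual:
            return "dual"
        if s in self.oncogenes:
            return "oncogene"
        if s in self.tsgs:
            return "TSG"
        raise KeyError(f"gene not in catalog: {symbol}")


@dataclass
class TrendConfig:
    expr_tier1: float = 1.00  # UMI/cell
    expr_tier2: float = 10.00  # UMI/cell, final stage
    positivity_min_umi: int = 1
    trend_alpha: float = 0.001

    def __post_init__(self) -> None:
        if not 0 < self.expr_tier1 < self.expr_tier2:
            raise ValueError("tiers must satisfy 0 < tier1 < tier2")


@dataclass
class TrendCall:
    gene: str
    role: str
    trend_class: str  # continuous_up / continuous_down / other
    max_stage_mean: float
    tier: str  # below1 / ge1 / gt10_stageV
    trend_p: float = float("nan")


@dataclass
class CooccurrenceResult:
    stage: str
    n_stage_cells: int
    n_tnnt2_pos: int
    n_tnnt2_myc_pos: int
    n_tp53_expressing_among_double_pos: int
    n_tp53_silent_among_double_pos: int

    def __post_init__(self) -> None:
        assert (
            self.n_tp53_expressing_among_double_pos
            + self.n_tp53_silent_among_double_pos
            == self.n_tnnt2_myc_pos
        )

    @property
    def pct_double_pos(self) -> float:
        """Double-positive share of all stage cells, 1 decimal."""
        if self.n_stage_cells == 0:
            return 0.0
        return round_half_up(100.0 * self.n_tnnt2_myc_pos / self.n_stage_cells, 1)

    @property
    def pct_tp53_silent(self) -> float:
        if self.n_tnnt2_myc_pos == 0:
            return 0.0
        return round_half_up(
            100.0 * self.n_tp53_silent_among_double_pos / self.n_tnnt2_myc_pos, 1
        )

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_stage_cells": self.n_stage_cells,
            "n_tnnt2_pos": self.n_tnnt2_pos,
            "n_tnnt2_myc_pos": self.n_tnnt2_myc_pos,
            "n_tp53_expressing_among_double_pos": self.n_tp53_expressing_among_double_pos,
            "n_tp53_silent_among_double_pos": self.n_tp53_silent_among_double_pos,
            "pct_double_pos": self.pct_double_pos,
            "pct_tp53_silent": self.pct_tp53_silent,
        }


# ---------------------------------------------------------------------------
# operations


def _read_catalog_file(path: str | Path) -> pd.DataFrame:
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed row at line {i}: {line!r}")
        rows.append((parts[0].strip().upper(), parts[1].strip()))
    return pd.DataFrame(rows, columns=["symbol", "role"])


def load_catalog(oncogene_tsv: str | Path, tsg_tsv: str | Path) -> GeneCatalog:
    """Load two-column (symbol TAB role) gene lists; symbols are upper-cased
    and de-duplicated; a symbol in both files is dual-role."""
    onc = _read_catalog_file(oncogene_tsv)
    tsg = _read_catalog_file(tsg_tsv)
    return GeneCatalog(oncogenes=set(onc["symbol"]), tsgs=set(tsg["symbol"]))


def overlap_markers(markers, catalog: GeneCatalog) -> pd.DataFrame:
    """Marker genes that carry an oncogenic or tumor-suppressive role."""
    tab = markers.table
    flagged = tab[tab["is_marker"]]
    rows = []
    for sym in sorted(set(flagged["gene"]) & {s.upper() for s in catalog.union}):
        stages = sorted(flagged.loc[flagged["gene"] == sym, "stage"].unique())
        rows.append({"gene": sym, "role": catalog.role_of(sym),
                     "stages": ",".join(stages)})
    return pd.DataFrame(rows, columns=["gene", "role", "stages"])


def stage_means(cells: CellMatrix, assignment: StageAssignment) -> pd.DataFrame:
    """Mean raw UMI per cell for every gene in every ordered stage
    (genes x stages, unit UMI/cell)."""
    if assignment.stage is None:
        raise ValueError("stages not assigned")
    cols = {}
    for lab in assignment.stage_order:
        mask = assignment.stage == lab
        if not mask.any():
            raise ValueError(f"stage {lab} has no cells")
        cols[lab] = np.asarray(cells.raw[mask].mean(axis=0)).ravel()
    return pd.DataFrame(cols, index=cells.genes["symbol"].to_numpy())


def classify_trend(
    profile: pd.DataFrame, gene: str, cfg: TrendConfig | None = None,
    role: str = "",
) -> TrendCall:
    """Classify a gene's stage-mean trajectory.

    continuous_up/down requires strict monotonicity across all consecutive
    ordered stages; everything else (including any tie) is "other".
    """
    cfg = cfg or TrendConfig()
    if profile.shape[1] < 3:
        raise ValueError("need at least 3 ordered stages")
    if gene not in profile.index:
        raise KeyError(f"unknown gene: {gene}")
    means = profile.loc[gene].to_numpy(float)
    d = np.diff(means)
    if (d > 0).all():
        trend = "continuous_up"
    elif (d < 0).all():
        trend = "continuous_down"
    else:
        trend = "other"
    if means[-1] > cfg.expr_tier2:
        tier = "gt10_stageV"
    elif (means >= cfg.expr_tier1).any():
        tier = "ge1"
    else:
        tier = "below1"
    return TrendCall(gene=gene, role=role, trend_class=trend,
                     max_stage_mean=float(means.max()), tier=tier)


def classify_trends(
    profile: pd.DataFrame, catalog: GeneCatalog, cfg: TrendConfig | None = None
) -> pd.DataFrame:
    """Trend calls for every catalog gene expressed in the data (any stage
    mean > 0)."""
    cfg = cfg or TrendConfig()
    rows = []
    for sym in sorted(catalog.union):
        if sym not in profile.index:
            continue
        means = profile.loc[sym].to_numpy(float)
        if not (means > 0).any():
            continue
        call = classify_trend(profile, sym, cfg, role=catalog.role_of(sym))
        rows.append(vars(call))
    return pd.DataFrame(
        rows, columns=["gene", "role", "trend_class", "max_stage_mean", "tier",
                       "trend_p"]
    )


def trend_significance(
    cells: CellMatrix, assignment: StageAssignment, gene: str
) -> float:
    """Two-sided p-value of a rank trend test: Spearman correlation between
    per-cell raw expression and the ordinal stage index, normal
    approximation z = rho * sqrt(n-1).  Constant expression gives p = 1."""
    if assignment.stage is None:
        raise ValueError("stages not assigned")
    x = cells.raw_gene(gene).astype(float)
    stage_idx = np.array(
        [assignment.stage_order.index(s) for s in assignment.stage], dtype=float
    )
    if np.all(x == x[0]) or np.all(stage_idx == stage_idx[0]):
        return 1.0
    rx = rankdata(x)
    ry = rankdata(stage_idx)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    z = rho * np.sqrt(len(x) - 1)
    return float(2 * norm.sf(abs(z)))


def positivity(
    cells: CellMatrix, gene: str, cfg: TrendConfig | None = None
) -> np.ndarray:
    """Per-cell boolean: raw UMI >= positivity_min_umi."""
    cfg = cfg or TrendConfig()
    return cells.raw_gene(gene) >= cfg.positivity_min_umi


def cooccurrence(
    cells: CellMatrix,
    assignment: StageAssignment,
    stage: str,
    panel: tuple = ("TNNT2", "MYC", "TP53"),
    cfg: TrendConfig | None = None,
) -> CooccurrenceResult:
    """Single-cell co-occurrence in one stage: TNNT2+/MYC+ double positives,
    partitioned by TP53 positivity (raw counts only)."""
    cfg = cfg or TrendConfig()
    if assignment.stage is None:
        raise ValueError("stages not assigned")
    if stage not in assignment.stage_order:
        raise ValueError(f"unknown stage: {stage}")
    for g in panel:
        try:
            cells.gene_index(g)
        except KeyError:
            raise KeyError(f"panel gene missing from data: {g}") from None
    tnnt2, myc, tp53 = panel
    mask = assignment.stage == stage
    pos = {g: positivity(cells, g, cfg)[mask] for g in panel}
    double = pos[tnnt2] & pos[myc]
    n_double = int(double.sum())
    n_tp53_expr = int((double & pos[tp53]).sum())
    return CooccurrenceResult(
        stage=stage,
        n_stage_cells=int(mask.sum()),
        n_tnnt2_pos=int(pos[tnnt2].sum()),
        n_tnnt2_myc_pos=n_double,
        n_tp53_expressing_among_double_pos=n_tp53_expr,
        n_tp53_silent_among_double_pos=n_double - n_tp53_expr,
    )
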