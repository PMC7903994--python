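"""Seeded synthetic droplet scRNA-seq generator emulating a two-line
iPSC -> cardiomyocyte differentiation time course.

The generator reproduces the statistical design the downstream pipeline is
built for: four collection days (0/2/4/10), five latent differentiation
stages with a fixed day-by-stage composition, two cell lines separated by an
on/off Y-linked RPS4Y1 signal, negative-binomial UMI counts with lognormal
per-cell size factors, ambient (empty) droplets with tiny totals, planted
strictly monotone oncogene/TSG expression trends, and a planted
TNNT2+/MYC+/TP53-silenced co-occurrence structure in the final stage.

Counts are negative binomial with one shared dispersion and a lognormal
library-size factor per cell: the simplest overdispersed model the hurdle
likelihood-ratio marker test must tolerate.  TP53 silencing is modeled as a
forced zero count, matching the convention that a "silenced" cell shows no
UMI; the complementary "expressing" cells are guaranteed >= 1 UMI so planted
fractions are identifiable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._util import child_rng, roman
from .droplet import RawDropletMatrix, write_mtx_dir

N_STAGES = 5
TIME_POINTS = ("day0", "day2", "day4", "day10")

# Day-by-stage cell counts of the published composition table
# (rows = day0/2/4/10, columns = stages I..V).
PRINTED_STAGE_COUNTS = np.array(
    [
        [11281, 0, 0, 0, 0],
        [29, 6437, 0, 0, 0],
        [23, 581, 8040, 6, 0],
        [2, 23, 87, 4669, 1187],
    ],
    dtype=float,
)


def emulate_printed_composition() -> np.ndarray:
    """Row-stochastic time x stage mixture reproducing the published
    composition of each stage (e.g. the day-0 row is (1,0,0,0,0))."""
    return PRINTED_STAGE_COUNTS / PRINTED_STAGE_COUNTS.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class CooccurrenceConfig:
    """Planted stage-V co-occurrence structure.

    frac_myc_pos: probability a stage-V cell is MYC-high (default mirrors the
    published 14.9% MYC+ fraction).  frac_tp53_silent_given_myc: probability
    TP53 is forced to zero in a MYC-high cell.  MYC-high counts are drawn as
    1 + NegBin so planted cells are always detected.
    """

    frac_myc_pos: float = 0.149
    frac_tp53_silent_given_myc: float = 0.70
    myc_high_mean: float = 30.0
    tp53_expressed_mean: float = 2.0


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_time_points: int = 4
    stage_mixture: np.ndarray = field(default_factory=emulate_printed_composition)
    cells_per_timepoint: tuple = (11281, 6466, 8650, 5968)
    ambient_per_timepoint: int = 50000
    ambient_total_mean: float = 10.0
    depth_lognormal: tuple = (0.0, 0.25)  # (mu, sigma) of the size factor
    nb_dispersion: float = 2.0  # NB size r; var = mu + mu^2/r
    line1_fraction: float = 0.5
    cooccurrence: CooccurrenceConfig = field(default_factory=CooccurrenceConfig)

    def validate(self) -> None:
        mix = np.asarray(self.stage_mixture, dtype=float)
        if mix.ndim != 2 or mix.shape[0] != self.n_time_points:
            raise ValueError("stage_mixture must have one row per time point")
        if (mix < 0).any() or np.abs(mix.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("stage_mixture rows must be nonnegative and sum to 1")
        if len(self.cells_per_timepoint) != self.n_time_points:
            raise ValueError("cells_per_timepoint length mismatch")
        if any(c <= 0 for c in self.cells_per_timepoint):
            raise ValueError("cell counts must be strictly positive")
        if self.ambient_per_timepoint < 0:
            raise ValueError("ambient_per_timepoint must be >= 0")
        if not 0 <= self.line1_fraction <= 1:
            raise ValueError("line1_fraction must be a probability")
        co = self.cooccurrence
        if not (0 <= co.frac_myc_pos <= 1 and 0 <= co.frac_tp53_silent_given_myc <= 1):
            raise ValueError("cooccurrence fractions must be probabilities")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    def expected_umi_per_cell(self, panel: "GenePanel") -> float:
        """Expected mean total UMI over real cells, for QC cross-checks."""
        self.validate()
        mu, sigma = self.depth_lognormal
        depth_mean = float(np.exp(mu + sigma**2 / 2))
        stage_totals = panel.profile.sum(axis=0)  # per-stage panel totals
        w = np.zeros(N_STAGES)
        for t, n in enumerate(self.cells_per_timepoint):
            w += n * np.asarray(self.stage_mixture, float)[t]
        w /= w.sum()
        return depth_mean * float(w @ stage_totals)


# ---------------------------------------------------------------------------
# gene panel


@dataclass
class GenePanel:
    """Gene symbols, roles and 5-stage mean-expression profiles.

    ``table`` columns: symbol, role in {stage_marker, oncogene, TSG,
    housekeeping, sex_marker}, trend_truth in {continuous_up,
    continuous_down, other}, marker_stage (stage index or -1), and the five
    stage means s1..s5.  ``catalog_extra`` lists stage-marker symbols that
    additionally appear in the cancer-gene catalogs (the planted
    marker/catalog overlap).
    """

    table: pd.DataFrame
    catalog_extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table["symbol"].duplicated().any():
            raise ValueError("gene symbols must be unique")
        if "RPS4Y1" not in set(self.table["symbol"]):
            raise ValueError("panel must contain the RPS4Y1 sex marker")
        prof = self.profile
        up = self.table["trend_truth"] == "continuous_up"
        down = self.table["trend_truth"] == "continuous_down"
        if up.any() and not (np.diff(prof[up.to_numpy()], axis=1) > 0).all():
            raise ValueError("continuous_up profiles must strictly increase")
        if down.any() and not (np.diff(prof[down.to_numpy()], axis=1) < 0).all():
            raise ValueError("continuous_down profiles must strictly decrease")

    @property
    def symbols(self) -> list[str]:
        return self.table["symbol"].tolist()

    @property
    def profile(self) -> np.ndarray:
        """genes x stages matrix of mean expression per stage."""
        return self.table[[f"s{i+1}" for i in range(N_STAGES)]].to_numpy(float)

    def index(self, symbol: str) -> int:
        hits = np.flatnonzero(self.table["symbol"].to_numpy() == symbol)
        if hits.size == 0:
            raise KeyError(symbol)
        return int(hits[0])

    def catalog(self, role: str) -> list[str]:
        """Catalog gene list for ``role`` ('oncogene' or 'TSG'), including the
        planted stage-marker overlap genes."""
        base = self.table.loc[self.table["role"] == role, "symbol"].tolist()
        extra = [s for s, r in self.catalog_extra.items() if r == role]
        return sorted(set(base) | set(extra))


_STAGE_MARKERS = [
    # ten markers per stage; pluripotency -> mesoderm -> cardiac precursor ->
    # cardiac progenitor -> cardiomyocyte
    ["POU5F1", "NANOG", "PODXL", "TDGF1", "LIN28A", "SALL4", "ZFP42", "DPPA4", "SOX2", "L1TD1"],
    ["T", "MIXL1", "EOMES", "GSC", "DKK1", "DKK4", "HES7", "CER1", "FGF4", "WNT3"],
    ["GATA4", "MESP1", "ISL1", "TBX5", "HAND1", "CCBE1", "NKX2-5", "BMP4", "PDGFRA", "KDR"],
    ["HAND2", "MEF2C", "MYH6", "TNNC1", "SOX6", "ERBB4", "TTN", "ACTC1", "NPPA", "WNT2"],
    ["TNNT2", "ACTN2", "MYH7", "MYOZ2", "MYOM1", "PLN", "TNNI3", "MYL7", "MYL4", "DES"],
]

# stage markers that the synthetic cancer catalogs also list (the planted
# marker/cancer-gene overlap)
_CATALOG_EXTRA = {
    "SOX2": "oncogene", "LIN28A": "oncogene", "SALL4": "oncogene",
    "FGF4": "oncogene", "WNT3": "oncogene", "BMP4": "oncogene", "WNT2": "oncogene",
    "DKK1": "TSG", "DKK4": "TSG", "GSC": "TSG", "TDGF1": "TSG",
}


def default_panel(
    n_oncogenes: int = 300,
    n_tsgs: int = 500,
    n_housekeeping: int = 349,
    n_up_oncogenes: int = 15,
    n_down_oncogenes: int = 13,
    n_down_tsgs: int = 7,
    n_up_tsgs: int = 25,
    panel_seed: int = 20210215,
) -> GenePanel:
    """Build the default ~1,200-gene panel.

    The panel is a fixed study condition: it is generated from its own seed,
    independent of the dataset seed, so the gene set and planted truth are
    identical across simulated datasets.  Planted trend counts mirror the
    published tallies (15 continuously up / 13 down oncogenes; 7 down / 25 up
    TSGs).  MALAT1 is the top expressed oncogene (stage-V mean 576.07);
    MYC and TP53 carry non-monotone baseline profiles and are additionally
    overridden in stage V by the co-occurrence plant.
    """
    rng = np.random.default_rng(panel_seed)
    rows: list[dict] = []

    def add(symbol, role, prof, trend="other", marker_stage=-1):
        rows.append(
            dict(symbol=symbol, role=role, trend_truth=trend,
                 marker_stage=marker_stage,
                 **{f"s{i+1}": float(prof[i]) for i in range(N_STAGES)})
        )

    add("RPS4Y1", "sex_marker", [5.0] * N_STAGES)

    for s, names in enumerate(_STAGE_MARKERS):
        for sym in names:
            prof = np.full(N_STAGES, 0.1)
            prof[s] = 30.0 if sym == "TNNT2" else 10.0
            add(sym, "stage_marker", prof, marker_stage=s)

    def up_profile(base):
        return base * np.array([0.2, 0.55, 1.4, 3.6, 9.0])

    def down_profile(base):
        return base * np.array([9.0, 3.6, 1.4, 0.55, 0.2])

    def other_profile(base):
        # non-monotone by construction: shuffled multipliers, re-drawn if the
        # permutation happens to be monotone
        mult = np.array([0.5, 1.5, 0.8, 1.2, 1.0])
        while True:
            p = rng.permutation(mult)
            d = np.diff(p)
            if not ((d > 0).all() or (d < 0).all()):
                return base * p

    # oncogenes
    add("MALAT1", "oncogene", 576.07 / 9.0 * np.array([0.2, 0.55, 1.4, 3.6, 9.0]),
        trend="continuous_up")
    add("MYC", "oncogene", [1.2, 0.6, 0.9, 0.3, 0.0])  # stage V overridden
    for i in range(n_up_oncogenes - 1):
        add(f"ONCU{i+1:03d}", "oncogene", up_profile(rng.lognormal(0.0, 0.5)),
            trend="continuous_up")
    for i in range(n_down_oncogenes):
        add(f"ONCD{i+1:03d}", "oncogene", down_profile(rng.lognormal(0.0, 0.5)),
            trend="continuous_down")
    n_other_onc = n_oncogenes - n_up_oncogenes - n_down_oncogenes - 1  # MYC counted
    for i in range(n_other_onc):
        add(f"ONCO{i+1:03d}", "oncogene", other_profile(rng.lognormal(-1.0, 0.8)))

    # tumor suppressors
    add("SFRP2", "TSG", down_profile(1.5), trend="continuous_down")
    add("DNMT3B", "TSG", down_profile(1.0), trend="continuous_down")
    add("TP53", "TSG", [0.8, 0.6, 0.5, 0.45, 0.5])  # <1 UMI/cell; stage V overridden
    for i in range(n_down_tsgs - 2):
        add(f"TSGD{i+1:03d}", "TSG", down_profile(rng.lognormal(0.0, 0.5)),
            trend="continuous_down")
    for i in range(n_up_tsgs):
        add(f"TSGU{i+1:03d}", "TSG", up_profile(rng.lognormal(0.0, 0.5)),
            trend="continuous_up")
    n_other_tsg = n_tsgs - n_down_tsgs - n_up_tsgs - 1  # TP53 counted
    for i in range(n_other_tsg):
        add(f"TSGO{i+1:03d}", "TSG", other_profile(rng.lognormal(-1.0, 0.8)))

    for i in range(n_housekeeping):
        base = rng.lognormal(1.0, 0.6)
        add(f"HK{i+1:04d}", "housekeeping", [base] * N_STAGES)

    return GenePanel(pd.DataFrame(rows), dict(_CATALOG_EXTRA))


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    cells: pd.DataFrame  # barcode, time_point, is_cell, stage, cell_line, myc_high, tp53_silent
    genes: pd.DataFrame  # symbol, role, trend_truth

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cells": self.cells.to_dict(orient="list"),
            "genes": self.genes.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(pd.DataFrame(payload["cells"]), pd.DataFrame(payload["genes"]))

    @property
    def cell_barcodes(self) -> set:
        return set(self.cells.loc[self.cells["is_cell"], "barcode"])


# ---------------------------------------------------------------------------
# generation

_BASES = np.array(list("ACGT"))


def _barcode(i: int, suffix: int) -> str:
    digits = []
    for _ in range(16):
        digits.append(i % 4)
        i //= 4
    return "".join(_BASES[digits]) + f"-{suffix}"


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, r: float) -> np.ndarray:
    """NegBin draws with target mean and size r (var = mu + mu^2/r)."""
    p = r / (r + np.maximum(mean, 0.0))
    return rng.negative_binomial(r, p).astype(np.int32)


def generate_dataset(
    config: SyntheticConfig, panel: GenePanel | None = None
) -> tuple[list[RawDropletMatrix], GroundTruth, dict]:
    """Generate one raw droplet matrix per time point plus ground truth and
    cancer-gene catalogs.

    Real cells draw NegBin counts around stage-profile means scaled by a
    lognormal size factor; ambient droplets draw a Poisson total around
    ``ambient_total_mean`` spread over the pooled expression profile.  The
    same seed always yields byte-identical output.
    """
    config.validate()
    panel = panel or default_panel()
    mix = np.asarray(config.stage_mixture, dtype=float)
    if mix.shape[1] != N_STAGES:
        raise ValueError("stage mixture column count must equal number of stages")
    profile = panel.profile
    G = profile.shape[0]
    r = config.nb_dispersion
    mu, sigma = config.depth_lognormal
    co = config.cooccurrence
    j_sex = panel.index("RPS4Y1")
    j_myc = panel.index("MYC")
    j_tp53 = panel.index("TP53")

    # ambient soup: pooled profile without the sex marker
    soup = profile.mean(axis=1).copy()
    soup[j_sex] = 0.0
    soup /= soup.sum()
    soup_cdf = np.cumsum(soup)

    gene_df = pd.DataFrame(
        {
            "gene_id": [f"SYN{i:05d}" for i in range(G)],
            "symbol": panel.symbols,
        }
    )

    matrices: list[RawDropletMatrix] = []
    truth_rows: list[pd.DataFrame] = []
    for t in range(config.n_time_points):
        rng = child_rng(config.seed, 1, t)
        n_cells = int(config.cells_per_timepoint[t])
        n_amb = int(config.ambient_per_timepoint)
        tp = TIME_POINTS[t] if t < len(TIME_POINTS) else f"tp{t}"

        stages = rng.choice(N_STAGES, size=n_cells, p=mix[t])
        line1 = rng.random(n_cells) < config.line1_fraction
        depth = rng.lognormal(mu, sigma, size=n_cells)

        mean = profile.T[stages] * depth[:, None]  # cells x genes
        mean[~line1, j_sex] = 0.0
        counts = _nb_draw(rng, mean, r)
        # the line signal is on/off: line-1 cells always show >= 1 UMI of the
        # sex marker (shifted draw), line-2 cells exactly 0
        sex_mean = np.maximum(profile[j_sex, stages[line1]] - 1.0, 0.0)
        counts[line1, j_sex] = 1 + _nb_draw(rng, sex_mean * depth[line1], r)

        # planted stage-V co-occurrence
        myc_high = np.zeros(n_cells, dtype=bool)
        tp53_silent = np.zeros(n_cells, dtype=bool)
        in_v = stages == N_STAGES - 1
        if in_v.any():
            iv = np.flatnonzero(in_v)
            high = iv[rng.random(iv.size) < co.frac_myc_pos]
            myc_high[high] = True
            counts[high, j_myc] = 1 + _nb_draw(
                rng, co.myc_high_mean * depth[high], r
            )
            silent_draw = rng.random(high.size) < co.frac_tp53_silent_given_myc
            silent = high[silent_draw]
            expressing = high[~silent_draw]
            tp53_silent[silent] = True
            counts[silent, j_tp53] = 0
            counts[expressing, j_tp53] = 1 + _nb_draw(
                rng, co.tp53_expressed_mean * depth[expressing], r
            )

        cell_mat = sp.csr_matrix(counts)
        del counts, mean

        # ambient droplets: tiny Poisson totals over the soup profile
        if n_amb > 0:
            amb_totals = rng.poisson(config.ambient_total_mean, size=n_amb)
            total = int(amb_totals.sum())
            draws = np.searchsorted(soup_cdf, rng.random(total))
            rows = np.repeat(np.arange(n_amb), amb_totals)
            amb_mat = sp.csr_matrix(
                (np.ones(total, dtype=np.int32), (rows, draws)), shape=(n_amb, G)
            )
            full = sp.vstack([cell_mat, amb_mat], format="csr")
        else:
            full = cell_mat

        n_total = n_cells + n_amb
        order = rng.permutation(n_total)
        full = sp.csr_matrix(full[order])
        barcodes = [_barcode(i, t + 1) for i in range(n_total)]

        is_cell = np.concatenate(
            [np.ones(n_cells, bool), np.zeros(n_amb, bool)]
        )[order]
        stage_lab = np.concatenate(
            [np.array([roman(s) for s in stages]), np.array([""] * n_amb)]
        )[order]
        line_lab = np.concatenate(
            [np.where(line1, "line1", "line2"), np.array([""] * n_amb)]
        )[order]
        myc_f = np.concatenate([myc_high, np.zeros(n_amb, bool)])[order]
        tp53_f = np.concatenate([tp53_silent, np.zeros(n_amb, bool)])[order]

        matrices.append(RawDropletMatrix(full, barcodes, gene_df.copy(), tp))
        truth_rows.append(
            pd.DataFrame(
                {
                    "barcode": barcodes,
                    "time_point": tp,
                    "is_cell": is_cell,
                    "stage": stage_lab,
                    "cell_line": line_lab,
                    "myc_high": myc_f,
                    "tp53_silent": tp53_f,
                }
            )
        )

    truth = GroundTruth(
        cells=pd.concat(truth_rows, ignore_index=True),
        genes=panel.table[["symbol", "role", "trend_truth"]].copy(),
    )
    # catalogs additionally list a few genes never expressed in the panel, as
    # real literature-curated catalogs would
    absent_onc = [f"ONGX{i+1:03d}" for i in range(10)]
    absent_tsg = [f"TSGX{i+1:03d}" for i in range(10)]
    catalogs = {
        "oncogenes": pd.DataFrame(
            {"symbol": panel.catalog("oncogene") + absent_onc, "role": "oncogene"}
        ),
        "tsgs": pd.DataFrame(
            {"symbol": panel.catalog("TSG") + absent_tsg, "role": "TSG"}
        ),
    }
    return matrices, truth, catalogs


def write_dataset(
    matrices: list[RawDropletMatrix],
    truth: GroundTruth,
    catalogs: dict,
    out_dir: str | Path,
) -> None:
    """Write MTX triples (one directory per time point), ground_truth.json and
    the two catalog TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m in matrices:
        write_mtx_dir(m, out / m.time_point)
    truth.to_json(out / "ground_truth.json")
    catalogs["oncogenes"].to_csv(
        out / "oncogenes.tsv", sep="\t", header=False, index=False
    )
    catalogs["tsgs"].to_csv(out / "tsgs.tsv", sep="\t", header=False, index=False)
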