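"""Pipeline orchestration and the printed-constants consistency report.

``run_pipeline`` chains the whole analysis — simulate (optional), cell
calling, normalization, staging, marker detection, cancer-gene trends,
co-expression network, co-occurrence — into a run directory with a
``run_report.json`` recording every threshold, the seed, and a SHA-256
checksum of every output, so identical config + seed gives identical
checksums.  With ``resume=True`` stages whose outputs already exist are
reloaded instead of recomputed.

``consistency_report`` recomputes, from the published primary counts only,
every derived quantity the study prints (totals, mean read depth,
composition percentages, positivity percentages), with the rounding
conventions fixed to reproduce the printed figures.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cancer, coexpression, droplet, markers, staging, synthetic
from ._util import logger, round_half_up

# ---------------------------------------------------------------------------
# printed constants and the consistency report


@dataclass
class PaperConstants:
    """Primary counts as printed in the study; the consistency report derives
    every published percentage/average from these alone."""

    per_day_cells: tuple = (11281, 6466, 8650, 5968)
    total_clean_reads: int = 2_066_741_896
    # stage x day counts (stages I..V as rows)
    stage_composition_counts: tuple = (
        (11281, 29, 23, 2),
        (0, 6437, 581, 23),
        (0, 0, 8040, 87),
        (0, 0, 6, 4669),
        (0, 0, 0, 1187),
    )
    stage_v_myc_pos: int = 177
    tp53_expressing_among_double_pos: int = 53
    oncogenes_expressed: int = 695
    oncogenes_tier1: int = 189
    universe_size: int = 1734

    @property
    def stage_totals(self) -> tuple:
        return tuple(sum(r) for r in self.stage_composition_counts)

    def validate(self) -> None:
        if sum(self.stage_totals) != sum(self.per_day_cells):
            raise ValueError("stage totals must sum to the per-day cell total")


def consistency_report(constants: PaperConstants | None = None) -> pd.DataFrame:
    """Derived quantities recomputed from printed primary counts.

    Rounding conventions: composition percentages half-up at 2 decimals,
    positivity percentage half-up at 1 decimal, read depth nearest integer,
    the oncogene below-tier share truncated to a whole percent.
    """
    c = constants or PaperConstants()
    c.validate()
    days = ["day0", "day2", "day4", "day10"]
    rows = []

    def add(q, v, formula):
        rows.append({"quantity": q, "value": v, "formula": formula})

    total = sum(c.per_day_cells)
    add("total_cells", total, "+".join(map(str, c.per_day_cells)))
    depth = round(c.total_clean_reads / total)
    add("mean_read_depth", depth, f"round({c.total_clean_reads}/{total})")
    for i, row in enumerate(c.stage_composition_counts):
        stage_total = sum(row)
        add(f"stage_{i+1}_total", stage_total, "+".join(map(str, row)))
        for d, cnt in zip(days, row):
            if cnt == 0:
                continue
            add(
                f"stage_{i+1}_{d}_pct",
                round_half_up(100.0 * cnt / stage_total, 2),
                f"100*{cnt}/{stage_total}",
            )
    add(
        "stage_v_myc_pos_pct",
        round_half_up(100.0 * c.stage_v_myc_pos / c.stage_totals[-1], 1),
        f"100*{c.stage_v_myc_pos}/{c.stage_totals[-1]}",
    )
    below = c.oncogenes_expressed - c.oncogenes_tier1
    add(
        "oncogene_below_tier1_pct",
        math.floor(100.0 * below / c.oncogenes_expressed),
        f"floor(100*{below}/{c.oncogenes_expressed})",
    )
    add(
        "evaluated_pair_count",
        c.universe_size**2,
        f"{c.universe_size}^2",
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "atlas_run"
    # either simulate synthetic data ...
    simulate: bool = True
    synthetic: synthetic.SyntheticConfig | None = None
    # ... or read raw matrices + catalogs from disk
    input_dirs: tuple = ()  # one MTX directory per time point
    oncogene_tsv: str = ""
    tsg_tsv: str = ""
    expected_cells: tuple = ()  # N per time point (defaults to synthetic sizes)
    normalize_per_timepoint: bool = False
    staging: staging.StagingConfig = field(default_factory=staging.StagingConfig)
    markers: markers.MarkerConfig = field(default_factory=markers.MarkerConfig)
    trend: cancer.TrendConfig = field(default_factory=cancer.TrendConfig)
    network: coexpression.NetworkConfig = field(
        default_factory=coexpression.NetworkConfig
    )
    cooccur_stage: str = ""  # default: final stage

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        simple = {
            "seed", "out_dir", "simulate", "oncogene_tsv", "tsg_tsv",
            "normalize_per_timepoint", "cooccur_stage",
        }
        for key, val in raw.items():
            if key in simple:
                setattr(cfg, key, val)
            elif key in ("input_dirs", "expected_cells"):
                setattr(cfg, key, tuple(val))
            elif key == "synthetic":
                co = val.pop("cooccurrence", None)
                sc = synthetic.SyntheticConfig(**val)
                if co:
                    sc.cooccurrence = synthetic.CooccurrenceConfig(**co)
                cfg.synthetic = sc
            elif key == "staging":
                cfg.staging = staging.StagingConfig(**val)
            elif key == "markers":
                cfg.markers = markers.MarkerConfig(**val)
            elif key == "trend":
                cfg.trend = cancer.TrendConfig(**val)
            elif key == "network":
                cfg.network = coexpression.NetworkConfig(**val)
            else:
                raise ValueError(f"unknown config key: {key}")
        return cfg


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> dict:
    """Execute the full analysis into ``cfg.out_dir``; returns the run report
    (also written as ``run_report.json``)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stages_run: list[str] = []
    results: dict = {}

    def record(*paths: Path):
        outputs.extend(paths)

    # -- simulate / load ----------------------------------------------------
    stage_name = "simulate" if cfg.simulate else "load"
    try:
        if cfg.simulate:
            syn = cfg.synthetic or synthetic.SyntheticConfig(seed=cfg.seed)
            data_dir = out / "data"
            if resume and (data_dir / "ground_truth.json").exists():
                raws = [
                    droplet.read_mtx_dir(data_dir / tp, tp)
                    for tp in synthetic.TIME_POINTS[: syn.n_time_points]
                ]
                catalog_paths = (data_dir / "oncogenes.tsv", data_dir / "tsgs.tsv")
            else:
                raws, truth, catalogs = synthetic.generate_dataset(syn)
                synthetic.write_dataset(raws, truth, catalogs, data_dir)
                catalog_paths = (data_dir / "oncogenes.tsv", data_dir / "tsgs.tsv")
            record(*(data_dir / tp / "matrix.mtx" for tp in
                     synthetic.TIME_POINTS[: syn.n_time_points]),
                   data_dir / "ground_truth.json")
            expected = cfg.expected_cells or syn.cells_per_timepoint
        else:
            if not cfg.input_dirs:
                raise ValueError("input_dirs required when simulate is false")
            if not cfg.oncogene_tsv or not cfg.tsg_tsv:
                raise ValueError("catalog paths (oncogene_tsv/tsg_tsv) required")
            raws = [droplet.read_mtx_dir(d) for d in cfg.input_dirs]
            catalog_paths = (Path(cfg.oncogene_tsv), Path(cfg.tsg_tsv))
            expected = cfg.expected_cells
            if not expected:
                raise ValueError("expected_cells required for cell calling")
        stages_run.append(stage_name)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage_name, e) from e

    # -- cell calling -------------------------------------------------------
    try:
        callings = [
            droplet.call_cells(r, droplet.CellCallingConfig(expected_cells_N=int(n)))
            for r, n in zip(raws, expected)
        ]
        cells = droplet.build_cell_matrix(raws, callings)
        calling_summary = {
            r.time_point: {"m": c.m, "threshold": c.threshold,
                           "n_called": len(c.called_barcodes)}
            for r, c in zip(raws, callings)
        }
        _write_json(out / "cell_calling.json", calling_summary)
        record(out / "cell_calling.json")
        results["calling"] = calling_summary
        stages_run.append("call_cells")
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("call_cells", e) from e

    # -- normalization + QC -------------------------------------------------
    try:
        droplet.assign_cell_line(cells)
        if cfg.normalize_per_timepoint:
            import scipy.sparse as sp

            parts = []
            tps = cells.cell_table["time_point"].to_numpy()
            for tp in dict.fromkeys(tps):
                idx = np.flatnonzero(tps == tp)
                sub = droplet.CellMatrix(
                    raw=cells.raw[idx], genes=cells.genes,
                    cell_table=cells.cell_table.iloc[idx].reset_index(drop=True),
                )
                droplet.normalize_to_median(sub)
                parts.append(sub.normalized)
            cells.normalized = sp.csr_matrix(sp.vstack(parts))
        else:
            droplet.normalize_to_median(cells)
        qc = droplet.qc_summary(cells)
        _write_json(out / "qc.json", qc)
        record(out / "qc.json")
        results["qc"] = qc
        stages_run.append("normalize")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("normalize", e) from e

    # -- staging ------------------------------------------------------------
    try:
        scfg = cfg.staging
        if scfg.km_seed == 0:
            scfg.km_seed = cfg.seed + 1
        scores = staging.reduce_pca(cells, scfg)
        assignment = staging.select_k_and_cluster(scores, scfg)
        staging.order_stages(assignment, cells.cell_table)
        cells.cell_table["stage"] = assignment.stage
        cells.cell_table.to_csv(out / "cell_table.tsv", sep="\t", index=False)
        comp = staging.stage_composition(assignment, cells.cell_table)
        comp.to_csv(out / "composition.tsv", sep="\t", index=False)
        corr = staging.cluster_correlation(cells, assignment)
        corr.to_csv(out / "correlation.tsv", sep="\t")
        assignment.diagnostics.to_csv(out / "k_diagnostics.tsv", sep="\t",
                                      index=False)
        record(out / "cell_table.tsv", out / "composition.tsv",
               out / "correlation.tsv", out / "k_diagnostics.tsv")
        results["chosen_k"] = assignment.chosen_k
        results["composition"] = comp
        stages_run.append("stage")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("stage", e) from e

    # -- markers ------------------------------------------------------------
    try:
        marker_res = markers.detect_markers(cells, assignment, cfg.markers)
        marker_res.table.to_csv(out / "markers.tsv", sep="\t", index=False)
        record(out / "markers.tsv")
        results["n_markers"] = len(marker_res.marker_symbols)
        stages_run.append("markers")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("markers", e) from e

    # -- cancer-gene trends -------------------------------------------------
    try:
        catalog = cancer.load_catalog(*catalog_paths)
        profile = cancer.stage_means(cells, assignment)
        trends = cancer.classify_trends(profile, catalog, cfg.trend)
        trends.to_csv(out / "trend_calls.tsv", sep="\t", index=False)
        overlap = cancer.overlap_markers(marker_res, catalog)
        overlap.to_csv(out / "overlap.tsv", sep="\t", index=False)
        profile.to_csv(out / "stage_means.tsv", sep="\t")
        record(out / "trend_calls.tsv", out / "overlap.tsv",
               out / "stage_means.tsv")
        results["trends"] = trends
        results["n_overlap"] = len(overlap)
        stages_run.append("trends")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("trends", e) from e

    # -- co-expression network ----------------------------------------------
    try:
        universe = coexpression.build_universe(marker_res, catalog, profile)
        edges = coexpression.pairwise_spearman(profile, universe, cfg.network)
        coexpression.write_edges(edges, out / "edges.tsv")
        coexpression.write_graphml(edges, out / "network.graphml")
        topo = coexpression.network_topology(edges, marker_res.marker_symbols)
        topo["n_universe"] = len(universe)
        topo["evaluated_pairs"] = coexpression.evaluated_pair_count(
            universe, cfg.network
        )
        _write_json(out / "topology.json", topo)
        record(out / "edges.tsv", out / "network.graphml", out / "topology.json")
        results["topology"] = topo
        results["n_edges"] = len(edges)
        stages_run.append("network")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("network", e) from e

    # -- co-occurrence ------------------------------------------------------
    try:
        stage_label = cfg.cooccur_stage or assignment.stage_order[-1]
        co = cancer.cooccurrence(cells, assignment, stage_label, cfg=cfg.trend)
        _write_json(out / "cooccurrence.json", co.to_dict())
        record(out / "cooccurrence.json")
        results["cooccurrence"] = co
        stages_run.append("cooccur")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("cooccur", e) from e

    report = {
        "seed": cfg.seed,
        "stages": stages_run,
        "thresholds": {
            "marker_alpha_adjusted": cfg.markers.alpha_adjusted,
            "min_fraction_expressed": cfg.markers.min_fraction_expressed,
            "expr_tier1": cfg.trend.expr_tier1,
            "expr_tier2": cfg.trend.expr_tier2,
            "positivity_min_umi": cfg.trend.positivity_min_umi,
            "trend_alpha": cfg.trend.trend_alpha,
            "rho_threshold": cfg.network.rho_threshold,
            "fdr_threshold": cfg.network.fdr_threshold,
            "calling_percentile": 99.0,
            "calling_divisor": 10.0,
        },
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    _write_json(out / "run_report.json", report)
    logger.info("pipeline complete: %d stages, %d outputs", len(stages_run),
                len(outputs))
    results["report"] = report
    results["cells"] = cells
    results["assignment"] = assignment
    results["markers"] = marker_res
    results["profile"] = profile
    results["edges"] = edges
    return results
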