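"""Shared fixtures.

``small_run`` exercises the full pipeline on a scaled-down simulation (fast;
used by most integration-style tests).  ``default_run`` is the full
study-scale simulation (~32k cells + 200k ambient droplets) run once per
session and shared by the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import cardiac_atlas as ca

SMALL_CELLS = (400, 250, 300, 250)


@pytest.fixture(scope="session")
def tiny_config():
    return ca.SyntheticConfig(
        seed=7, cells_per_timepoint=(60, 50, 50, 60), ambient_per_timepoint=200
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return ca.generate_dataset(tiny_config)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("small_run")
    cfg = ca.PipelineConfig(
        seed=11,
        out_dir=str(out),
        synthetic=ca.SyntheticConfig(
            seed=11, cells_per_timepoint=SMALL_CELLS, ambient_per_timepoint=2000
        ),
    )
    results = ca.run_pipeline(cfg)
    results["truth"] = ca.GroundTruth.from_json(out / "data" / "ground_truth.json")
    results["out_dir"] = out
    return results


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full study-scale pipeline run on the default synthetic configuration."""
    out = tmp_path_factory.mktemp("default_run")
    syn = ca.SyntheticConfig(seed=1)
    raws, truth, catalogs = ca.generate_dataset(syn)
    callings = [
        ca.call_cells(r, ca.CellCallingConfig(expected_cells_N=int(n)))
        for r, n in zip(raws, syn.cells_per_timepoint)
    ]
    cells = ca.build_cell_matrix(raws, callings)
    del raws
    ca.assign_cell_line(cells)
    ca.normalize_to_median(cells)
    scfg = ca.StagingConfig(km_seed=2)
    scores = ca.reduce_pca(cells, scfg)
    assignment = ca.select_k_and_cluster(scores, scfg)
    ca.order_stages(assignment, cells.cell_table)
    cells.cell_table["stage"] = assignment.stage
    marker_res = ca.detect_markers(cells, assignment)
    import tempfile
    from pathlib import Path

    cat_dir = Path(tempfile.mkdtemp(dir=out))
    catalogs["oncogenes"].to_csv(cat_dir / "onc.tsv", sep="\t", header=False,
                                 index=False)
    catalogs["tsgs"].to_csv(cat_dir / "tsg.tsv", sep="\t", header=False,
                            index=False)
    catalog = ca.load_catalog(cat_dir / "onc.tsv", cat_dir / "tsg.tsv")
    profile = ca.stage_means(cells, assignment)
    return {
        "config": syn,
        "truth": truth,
        "callings": callings,
        "cells": cells,
        "assignment": assignment,
        "markers": marker_res,
        "catalog": catalog,
        "profile": profile,
    }


def best_relabel_agreement(pred: np.ndarray, true: np.ndarray) -> float:
    """Fraction of cells agreeing after the optimal one-to-one relabeling."""
    from scipy.optimize import linear_sum_assignment

    pl = sorted(set(pred))
    tl = sorted(set(true))
    cm = np.zeros((len(pl), len(tl)))
    for i, a in enumerate(pl):
        for j, b in enumerate(tl):
            cm[i, j] = np.sum((pred == a) & (true == b))
    r, c = linear_sum_assignment(-cm)
    return float(cm[r, c].sum() / len(pred))
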