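# cardiac-atlas

Single-cell analysis pipeline for the **oncogenic expression atlas** of human
iPSC-derived cardiomyocyte differentiation. Two iPSC lines are differentiated
toward cardiomyocytes and sampled by droplet scRNA-seq on days 0, 2, 4 and 10;
the pipeline reconstructs five ordered differentiation stages (I–V) and asks
how oncogenes and tumor suppressor genes (TSGs) behave along them — which are
continuously up- or down-regulated, and in which single cells the oncogene
*MYC* is overexpressed while the tumor suppressor *TP53* is silenced.

It is written for computational biologists who want the whole chain — droplet
cell calling, normalization, stage discovery, marker detection, cancer-gene
trend classification, co-expression network, co-occurrence calls — as tested,
reusable library functions, plus a seeded synthetic-data generator that
emulates the study design so every step can be exercised without any external
download.

## Methods at a glance

* **Cell calling** — with *N* expected cells, the robust maximum total UMI *m*
  is the 99th percentile of the top-*N* barcode totals; every barcode with
  total UMI > *m*/10 is a cell.
* **Cell lines** — cells with ≥ 1 UMI of the Y-linked *RPS4Y1* belong to the
  male line (line 1), the rest to line 2.
* **Normalization** — each cell is scaled to the median total UMI;
  log1p-transformed values feed PCA (top *M* = 10 components) and k-means.
  *k* is selected over 2…10 by mean silhouette, with an SSE-elbow tie-break;
  clusters are ordered into stages I–V by mean collection-time rank.
* **Markers** — per (gene, stage) a two-part hurdle likelihood-ratio test
  (binomial detection + Gaussian expression, χ², df = 2), BH-adjusted
  *p* < 0.05, up-regulated only.
* **Trends** — per cancer gene the stage-mean profile (UMI/cell) is classified
  `continuous_up` / `continuous_down` (strictly monotone over the five
  stages) / `other`, with expression tiers at ≥ 1.00 and > 10.00 UMI/cell,
  and a cell-level rank trend test for significance.
* **Network** — Spearman ρ between 5-point stage profiles for every pair in
  the marker ∪ oncogene ∪ TSG universe; edges kept at ρ > 0.99 and
  BH-FDR *q* < 0.01 (with 5 support points this keeps exactly the perfectly
  rank-concordant pairs).
* **Co-occurrence** — in stage V, cells positive (≥ 1 UMI) for both *TNNT2*
  and *MYC* are partitioned by *TP53* positivity; a double-positive cell with
  0 *TP53* UMI is *TP53*-silent.

## Worked example

```python
import cardiac_atlas as ca

cfg = ca.PipelineConfig(
    seed=11,
    out_dir="atlas_run",
    synthetic=ca.SyntheticConfig(
        seed=11, cells_per_timepoint=(400, 250, 300, 250),
        ambient_per_timepoint=2000,
    ),
)
res = ca.run_pipeline(cfg)
print("chosen_k:", res["chosen_k"])
print(res["cooccurrence"].to_dict())
```

prints (exactly reproducible at this seed):

```
chosen_k: 5
{'stage': 'V', 'n_stage_cells': 66, 'n_tnnt2_pos': 65, 'n_tnnt2_myc_pos': 14,
 'n_tp53_expressing_among_double_pos': 4, 'n_tp53_silent_among_double_pos': 10,
 'pct_double_pos': 21.2, 'pct_tp53_silent': 71.4}
```

i.e. model selection recovers the five planted stages, and in stage V 14 of
66 cells are *TNNT2*+/*MYC*+ double positives (21.2%, planted rate 14.9%),
10 of which have zero *TP53* UMI (71.4% silent, planted rate 70%) —
small-sample fluctuations around the planted fractions; at the full study
scale (`scripts/acceptance.py`) the estimates land within 3 binomial SE of
the planted values. The same run writes
`composition.tsv`, `markers.tsv`, `trend_calls.tsv`, `edges.tsv`,
`topology.json` and `cooccurrence.json` into `atlas_run/` together with a
`run_report.json` of thresholds, seed and output checksums.

The same pipeline is available from the shell:

```bash
atlas run --seed 11 --out-dir atlas_run
atlas consistency
atlas simulate --seed 7 --out-dir data/
atlas call-cells --mtx-dir data/day0 -n 11281 --out-dir called/
```

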