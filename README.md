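# ewsdda

Early-warning dynamic ratio networks for staged omics data.

Diseases such as hepatocellular carcinoma develop through ordered stages,
and some molecular relationships change *only* at the earliest disease
stage — exactly the signals worth catching in a screening setting.
`ewsdda` finds them by working on **molecular ratios** r_ij = f_i / f_j
(genes or metabolites), each read as the outcome of an assumed pathway
reaction, and asking at which stage each reaction's readout departs from
its cohort-wide behaviour.  It is aimed at computational biologists
analysing multi-stage cross-sectional cohorts (e.g. normal plus tumour
stages I–IV) or paired longitudinal animal-model designs (model and
control arms over ordered time points).

## The statistic and the pipeline

For every ratio and every ordered class c_k the package computes the
shrunken-centroid contrast

    d_ijk = (μ_ijk − μ_ij) / (m_k (s_ij + s_0)),    m_k = √(1/n + 1/n_k)

with μ_ijk the class-k mean of the ratio, μ_ij its grand mean, s_ij the
pooled within-class SD, and s_0 the median of s_ij over all ratios.  One
signed network per stage links f_i and f_j when |d_ijk| ≥ ε (red edge for
d ≥ ε, green for d ≤ −ε; defaults ε = 0.6 staged, 2.3 time-series).  The
earliest disease stage's graph is mined for a warning signal: nodes are
ranked by degree, the top hubs and their first linking nodes form the
crucial subnetwork, and the ratios on hub-incident edges become candidate
biomarkers.  Candidates then pass stage-wise t-test rules and a
trajectory-shape filter, and the surviving panel is evaluated by logistic
ROC (AUC, sensitivity, specificity, Hanley–McNeil SE, 95% CI), PCA score
plots, and multivariate Cox risk scores with a median split and
Kaplan–Meier log-rank comparison.

A synthetic-data module generates both study designs with planted
hub-and-partners ratio signals, so the entire chain is testable end to end
without external cohorts (see `docs/methods.md` for the generator's model
and calibration).

## Worked example

Plant one hub (`f001`) with five partner ratios that switch on at stage I
and deepen stepwise, then run the staged pipeline:

```python
from ewsdda import (PlantedSignal, generate_staged, run_staged,
                    PipelineConfig, compute_ratios, panel_roc)

signal = PlantedSignal(
    hub_feature="f001",
    partner_features=("f002", "f003", "f004", "f005", "f006"),
    signal_class="I", effect_size=4.0, persistent=True)

ds = generate_staged(
    n_features=6,
    class_sizes={c: 30 for c in ["normal", "I", "II", "III", "IV"]},
    signals=[signal], seed=7)

result = run_staged(ds, PipelineConfig(epsilon=0.6, top_k_hubs=1))
print("hubs:", result.subnetwork.hubs)
print("funnel:", result.panel.funnel)
print("panel:", result.panel.labels())

ratios = compute_ratios(result.dataset)
X = ratios.loc[result.panel.labels()].to_numpy().T
y = (result.dataset.classes != "normal").astype(int)
rep = panel_roc(X, y)
print(f"AUC={rep.auc:.3f}  Spe.={rep.specificity_at_cutoff:.3f}  "
      f"Sen.={rep.sensitivity_at_cutoff:.3f}")
```

Output:

```
hubs: ['f001']
funnel: {'candidates': 5, 'after_stage_tests': 5, 'after_trajectory': 5}
panel: ['f001/f002', 'f001/f003', 'f001/f004', 'f001/f005', 'f001/f006']
AUC=1.000  Spe.=1.000  Sen.=1.000
```

The degree ranking identifies the planted hub; all five hub-incident
candidate ratios survive the stage-significance tests and the monotone
trajectory filter (the funnel line is the audit trail: 5 → 5 → 5); and the
selected panel separates normal from disease samples perfectly on this
strongly planted dataset.  On null data the funnel typically ends at 0.

The same analysis is scriptable from a shell:

```bash
ewsdda simulate --design staged --config cfg.yaml --out data/
ewsdda network  --matrix data/matrix.tsv --metadata data/metadata.tsv \
                --class-order normal,I,II,III,IV --epsilon 0.6 --out nets/
ewsdda select   --matrix data/matrix.tsv --metadata data/metadata.tsv \
                --class-order normal,I,II,III,IV --top-k 1 --out panel/
ewsdda evaluate --matrix data/matrix.tsv --metadata data/metadata.tsv \
                --class-order normal,I,II,III,IV --panel panel/panel.json \
                --task roc --out eval/
```

Networks are written as GraphML and SIF (Cytoscape-readable).

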