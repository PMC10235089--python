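# phenotil

Contextual phenotyping of tumor-infiltrating lymphocytes (TILs) on
H&E histology, for computational-pathology researchers studying the
immune microenvironment of solid tumors (the design target is
non-small-cell lung cancer).

The density of TILs alone is a blunt prognostic marker: lymphocytes in
different *micro-environmental contexts* — packed immune niches,
sparse stromal infiltrate, tumor-adjacent rims — behave differently.
`phenotil` characterizes every TIL by its surroundings, groups TILs
into recurring niches, and turns a patient's niche composition into a
survival risk score.

## The method

1. **Contextual features.** For each TIL, three nested discs of radius
   `dL·10`, `dL·20`, `dL·30` pixels (`dL = 20` px, the average
   lymphocyte diameter at 20×) are centered on its centroid. Within
   each disc, 96 descriptors of the neighboring cells are computed —
   counts and densities, centroid-distance statistics, neighbor
   morphology (area, perimeter, eccentricity, equivalent diameter,
   solidity), neighbor color, and 12 gray-level co-occurrence texture
   statistics, each split by TIL / non-TIL neighbor class — giving a
   288-dimensional vector per TIL.
2. **Niche clustering.** Feature vectors are z-scored and clustered
   with an 8-component Gaussian mixture (diagonal covariances). Each
   patient *i* is then the count vector *N<sub>i1</sub> … N<sub>i8</sub>*
   of their TILs per cluster.
3. **Risk score.** A Cox proportional-hazards model with elastic-net
   regularization yields coefficients *β<sub>j</sub>*, and each
   patient's overall-survival risk score is

   &nbsp;&nbsp;&nbsp;&nbsp;OSRS<sub>i</sub> = Σ<sub>j</sub> N<sub>ij</sub> β<sub>j</sub>

   Patients above the training-median OSRS are "high risk"; clusters
   with β<sub>j</sub> > 0 are *constructive*, β<sub>j</sub> < 0
   *obstructive*. Separation is evaluated with the Mantel–Haenszel
   log-rank test, the high-vs-low hazard ratio, Harrell's C-index and
   Kaplan–Meier curves.

Companion modules provide the upstream imaging stages (Macenko stain
normalization, marker-controlled watershed nuclei segmentation,
rule/SVM TIL classification), the **denTIL** (19 density features) and
reduced **spaTIL** (spatial-architecture) comparator families with
4-moment patient aggregation, H&E↔immunofluorescence co-registration
with per-TIL CD4/CD8/CD20 subtype calling (membrane-ring intensities,
AQUA normalization, argmax label), and gene-expression association
(Pearson correlation to niches, 50%-of-maximum activation-gene
selection, hypergeometric gene-set enrichment with BH control).

A synthetic-data module simulates every input — clustered TIL/non-TIL
point patterns, rendered H&E-like tiles with ground-truth masks,
survival with planted niche effects, co-registered IF stacks,
expression matrices with planted correlations — so the full pipeline
is testable without clinical data.

## Worked example

```python
import phenotil as pt
from phenotil.synthetic import STRONG_BETA_STAR

N = pt.gen_cluster_counts(n_patients=300, mean_counts=30.0, seed=0)
survival = pt.gen_survival(N, STRONG_BETA_STAR, censor_rate=0.3, seed=1)
model = pt.fit_risk_model(N, survival, seed=0)
report = pt.evaluate_survival(survival, scores=model.scores(N),
                              cutoff=model.cutoff)
print(report.hr, report.logrank_p, report.c_index)
```

prints (see `examples/02_niche_clustering_and_risk.py` for the full
script):

```
high vs low risk (median OSRS cutoff 4.37):
  HR   = 2.97  (95% CI 2.20-4.02)
  logrank p = 2.19e-13
  C-index   = 0.728 +/- 0.003
```

The fitted coefficient signs match all eight planted log-hazard signs,
the high-risk group dies about three times faster, and a risk-ordered
pair of patients is correctly ordered 73% of the time. The other
capabilities each have a narrative script under `examples/`
(simulation + feature extraction, segmentation, IF subtype pairing,
gene association).

## Layout

- `src/phenotil/` — library (`synthetic`, `stain`, `segmentation`,
  `features`, `clustering`, `risk`, `comparators`, `qmif`, `genes`,
  `pipeline`, `cli`)
- `examples/` — one short narrative script per capability
- `docs/methods.md` — models, assumptions, parameter defaults and
  numerical choices
- `phenotil` console script — thin CLI over the pipeline stages
  (`phenotil demo --out run --seed 0`)
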