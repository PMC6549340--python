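# combiscreen

Design and label-free image-based analysis of **higher-order drug
combination screens** in 384-well plates.

Most drug combination studies stop at pairs. Clinical multi-drug
protocols, however, combine many repurposed drugs at once, and deciding
which members of such a cocktail actually drive its effect requires an
*exhaustive* in vitro experiment: every subset of the drug panel up to a
chosen order, each drug at one fixed concentration. `combiscreen`
provides the full workflow for such screens, for cell biologists and
pharmacologists running label-free time-lapse microscopy (e.g. on
glioma-initiating cell cultures challenged with a nine-drug cocktail):

* **Plate design** — with $N_d$ drugs screened up to order $c$ the
  number of treated wells is
  $N_w(N_d, c) = \sum_{i=1}^{c} \binom{N_d}{i}$;
  nine drugs up to order four need 255 wells and fit, with ≥ 40
  untreated controls, on a single 384-well plate. Conditions are
  assigned to wells by an independent seeded random permutation per
  replicate plate, and exported as destination CSVs for acoustic liquid
  handling.
* **Temporal image quantification** — an adaptive background interval
  $[\mathrm{lo}, \mathrm{hi}]$ (median split plus one-sided Otsu
  thresholds on each side) segments foreground; per well the pipeline
  reports confluence change
  $\Delta C(t_i) = \frac{c(t_i) - c(t_0)}{c(t_0)}$ and morphology change
  $\Delta M(t_i) = \frac{\lVert h(t_i) - h(t_0)\rVert_1}{\lVert h(t_0)\rVert_1}$,
  where $h$ is a hierarchical pixel histogram of foreground intensities
  over an image pyramid.
* **Apoptotic-like object counting** — a linear matched filter
  $w = s - b$ built from a user-selected prototype patch $s$; the
  response $y = w^{\top} r$ is thresholded and counted by two
  algorithms (greedy taboo peak-picking and interval projection), whose
  mean is the per-frame count. The detection threshold is tuned by
  repeated k-fold cross-validation on annotated images, with an abort
  when the median leave-out loss shows the threshold cannot generalize.
* **Plate quality control** — intra-plate exclusion of wells with
  deviating first-frame histograms, then a resampling null for the
  inter-plate variability
  $V_w = \sum_t \left( \Delta C_w^{\max}(t) - \Delta C_w^{\min}(t) \right)$:
  one untreated well per plate drawn with replacement, 10000 times; a
  condition whose $V_w$ exceeds the 95th percentile of the null is not
  merged (5% false-alarm rate by construction).
* **Higher-order Bliss synergy** — survival index
  $S = \frac{f - \tilde f_{\mathrm{blank}}}{\tilde f_{\mathrm{control}} - \tilde f_{\mathrm{blank}}}$,
  Bliss index $B = \prod_i S(c_i) - S(\mathbf{c}_n)$, and the scaled
  index $B_S = B \cdot \left(1 - \min\{\textstyle\prod_i S(c_i), S(\mathbf{c}_n)\}\right)$
  which disambiguates equal-$B$ pairs; significance by replicate
  resampling with Benjamini–Hochberg FDR across the family.
* **Response mining** — the four readouts ($\Delta C$, $\Delta M$,
  counts, viability) are standardized and fused into one profile of
  length $4n$; top-down multilevel K-means++ (K chosen as the smallest
  K whose SSE drop beats 20%) groups conditions into prototypical
  behaviors, and each group is reduced to its *non-redundant
  representative set* — the subset-minimal combinations, so a group of
  dozens of combinations explained by one drug is reported as exactly
  that drug.

Everything is seeded and deterministic; a synthetic fixture generator
(`combiscreen.fixtures`) simulates plates, images, planted objects and
end-point assays with full ground truth, so the whole pipeline is
testable without a microscope.

## Worked example

```python
import numpy as np
from combiscreen.design import (DrugPanel, DesignSpec, check_feasibility,
                                randomize_layout)
from combiscreen.synergy import survival_index, bliss_index, scaled_bliss

panel = DrugPanel(tuple((d, 1.0, "uM") for d in
    ("Apr", "Aur", "Cap", "Cel", "Dis", "Itr", "Min", "Que", "Ser")))
spec = DesignSpec(panel=panel, max_order=4, replicates=4, seed=7)
report = check_feasibility(spec)
print(f"treated wells required: {report.n_treated}")
print(f"feasible on one 384-well plate: {report.feasible}")
layout = randomize_layout(spec, replicate_id=1)
print(f"replicate 1: {len(layout.conditions())} treated, "
      f"{len(layout.untreated_wells())} untreated, "
      f"{len(layout.blank_wells())} blank")

blanks = np.array([510.0, 498.0, 505.0])
controls = np.array([29500.0, 30200.0, 30100.0])
S_dis = survival_index(3480.0, blanks, controls)
S_apr = survival_index(28900.0, blanks, controls)
S_combo = survival_index(2310.0, blanks, controls)
print(f"S(Dis)={S_dis:.3f}  S(Apr)={S_apr:.3f}  S(Dis+Apr)={S_combo:.3f}")
print(f"B   = {bliss_index([S_dis, S_apr], S_combo):.4f}")
print(f"B_S = {scaled_bliss([S_dis, S_apr], S_combo):.4f}")
```

prints

```
treated wells required: 255
feasible on one 384-well plate: True
replicate 1: 255 treated, 53 untreated, 76 blank
S(Dis)=0.101  S(Apr)=0.959  S(Dis+Apr)=0.061
B   = 0.0355
B_S = 0.0333
```

The nine-drug panel screened exhaustively up to order four occupies 255
treated wells — 9 singles, 36 pairs, 84 triples, 126 quadruples — plus
53 untreated controls per plate. In the synergy block, the combination
kills slightly more than the product of its singles predicts
($B > 0$, weak synergy), and the scaled index stays close to $B$
because the observed survival is low.

From a shell, the same stages are driven by subcommands:

```sh
combiscreen design   --spec experiment.txt --out layouts/
combiscreen fixtures --spec experiment.txt --out data/ --seed 3
combiscreen features --images data/images --layout data/R1_layout.csv \
                     --out feats1/ --plate R1
combiscreen mf tune  --train annotations.csv --prototype proto.tif
combiscreen qc       --profiles feats1/profiles.csv --profiles feats2/profiles.csv \
                     --layout data/R1_layout.csv --layout data/R2_layout.csv --out qc.csv
combiscreen synergy  --fmca data/R1_fmca.csv --layout data/R1_layout.csv --out syn.csv
combiscreen run      --config run.yaml
```

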