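# tbstrat

Stratification toolkit for the **true-basal (tB) subtype of triple-negative
breast cancer (TNBC)**, defined by a three-marker basal panel — smooth
muscle actin (SMA/*ACTA2*), transgelin (TAGL/*TAGLN*) and β-tropomyosin
(TPM2) — and exploitable for drug repurposing (e.g. dasatinib sensitivity).

TNBC lacks the ERα/PR/HER2 markers used clinically, leaving an aggressive,
heterogeneous disease without targeted options.  A subset of TNBC tumors
retains the identity of mammary **basal cells** (the contractile outer
layer of the duct) and can be recognised histologically by the percentage
of tumor cells staining positive for the three basal markers.  `tbstrat`
implements the full computational chain that discovers such markers and
puts them to work:

1. **Marker discovery** (`tbstrat.markers`) — from compartment-annotated
   single-cell counts: QC (mitochondrial %, detected genes), log
   normalisation `ln(1 + c/T·10⁴)`, PCA on highly-variable genes, gene
   ranking by PC1 loading (the basal-vs-luminal axis), Wilcoxon rank-sum
   differential expression with Benjamini–Hochberg correction,
   expression-fraction filters, UCell-style rank signature scores, and a
   cross-species consistency filter.
2. **Cohort stratification** (`tbstrat.cohort`) — per-marker positivity
   cutoffs at the **valley of each bimodal %-positive distribution**
   (two-pass kernel density estimate), a **k-of-n rule** (tB ⇔ ≥2 of 3
   markers above cutoff), unsupervised hierarchical clustering (Euclidean,
   complete linkage) as the independent route, concordance, ROC/AUC with
   bootstrap SE, and prevalence.
3. **Screen analysis** (`tbstrat.screen`) — viability normalisation,
   per-compound tB/nB group means, the selective-hit rule (tB mean < 20%
   while nB mean > 20%), a composite tB z-score for cell-line
   stratification, marker–sensitivity Pearson correlation, and 4PL
   dose–response fitting `v(d) = bottom + (top−bottom)/(1+(d/IC50)^h)`.
4. **Survival analysis** (`tbstrat.survival`) — three-gene average
   expression, upper/lower-quartile trichotomization, Kaplan–Meier curves,
   the two-group log-rank test, and the log-rank O/E hazard ratio
   `HR = (O₁/E₁)/(O₂/E₂)` with 95% CI.
5. **Synthetic data** (`tbstrat.synthetic`) — first-class generators for
   every input (NB count matrices with planted markers and QC artifacts,
   bimodal IHC cohorts with known valleys, screens with planted hits, 4PL
   dose series with known IC50, exponential survival with a known HR), so
   every downstream guarantee is testable against recorded ground truth.

A `tbstrat` command-line interface wraps the library
(`simulate`, `discover-markers`, `stratify`, `screen`, `dose-response`,
`survival`, `run-all`).

## Worked example

Derive cutoffs and classify a synthetic validation-size cohort (n = 243,
planted tB prevalence 55/243):

```python
from tbstrat.config import SimConfig
from tbstrat import synthetic as syn, cohort as co

cfg = SimConfig(seed=1)
cohort, truth = syn.gen_ihc_cohort(cfg)

cutoffs = co.derive_cutoffs(cohort)
for m, e in cutoffs.entries.items():
    print(f"{m}: cutoff {e.cutoff:.1f}% (true valley {truth.true_cutoffs[m]:.1f}%, flag {e.flag})")

calls = co.classify_samples(cohort, cutoffs, k=2)   # tB <=> >=2 of 3 positive
count, total, pct = co.prevalence(calls)
print(f"tB-TNBC prevalence: {count}/{total} = {pct}%")
print(f"accuracy vs ground truth: {(calls['label'] == truth.sample_subtypes).mean():.3f}")
auc, se = co.marker_auc(cohort['TAGL'], truth.sample_subtypes, seed=1)
print(f"TAGL AUC: {auc:.2f} ± {se:.2f}")
```

prints

```
SMA: cutoff 6.5% (true valley 5.4%, flag bimodal)
TAGL: cutoff 30.0% (true valley 32.6%, flag bimodal)
TPM2: cutoff 39.0% (true valley 40.8%, flag bimodal)
tB-TNBC prevalence: 53/243 = 21.8%
accuracy vs ground truth: 0.992
TAGL AUC: 0.89 ± 0.03
```

The derived cutoffs sit at the density valleys of the three bimodal
%-positive distributions (within ~2 pp of the generating mixture's true
valleys), the 2-of-3 rule recovers 53 of the 55 planted tB tumors plus no
false calls beyond 0.8% of the cohort, and TAGL discriminates the two
subtypes with an AUC near 0.9.  The same chain from the shell:

```bash
tbstrat simulate ihc --out demo --seed 1
tbstrat stratify --cohort demo/cohort.csv --out demo
tbstrat run-all --seed 1 --out demo_full     # every stage + manifest
```

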