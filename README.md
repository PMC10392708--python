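# tilscore

Immune cell scoring and survival stratification for overlapping
targeted gene-expression panels.

Bulk tumor profiling with targeted count panels (e.g. NanoString-style
codesets) is a practical way to read out the immune contexture of a
tumor from nanograms of RNA. When a study runs **two** overlapping
panels, the counts must be normalized per panel, placed on a common
scale, and summarized into interpretable immune cell scores before any
of the downstream questions — which genes differ between patient
groups, which immune cell ratios track tumor grade, which markers
stratify time-to-event outcomes — can be asked. `tilscore` implements
that full analysis chain as a tested, reusable library plus CLI, and
ships a synthetic cohort generator with known planted structure so
every stage can be validated end-to-end without access to any patient
data.

## What it computes

**Normalization and merge.** Candidate reference genes are ranked by
geNorm expression stability
*M<sub>j</sub>* = mean<sub>k≠j</sub> SD<sub>samples</sub>(log₂ x<sub>j</sub> − log₂ x<sub>k</sub>),
with the pairwise variation *V(n, n+1)* deciding how many references to
keep. Each sample *s* is scaled by
*f<sub>s</sub>* = mean<sub>s′</sub>(g<sub>s′</sub>) / g<sub>s</sub>, where
*g<sub>s</sub>* is the geometric mean of the reference genes (counts + 0.5);
samples with *g<sub>s</sub>* below a QC floor are excluded. The two
normalized panels are merged by the ratio *r* of geometric means of all
common probes: every probe of the second codeset is multiplied by *r*,
common probes are averaged entrywise, unique probes carried through.

**Cell scores.** A cell type's raw score is the mean log₂ expression of
its marker genes. The TIL composite is the average raw score of B
cells, T cells, CD45, macrophages, and cytotoxic cells. A relative
score is the log₂-space ratio raw(c) − score(denominator), with the TIL
composite or another subset (e.g. exhausted CD8) as denominator;
centered scores subtract the cohort mean.

**Inference.** Per-gene Welch *t* tests on log₂ data with
Benjamini–Yekutieli FDR (BH inflated by c(m) = Σ 1/i, valid under
dependence) and volcano classification; exact RxC Fisher tests by full
enumeration of the fixed-margins fiber; Wilcoxon/Kruskal–Wallis rank
tests with Dunn–Bonferroni post-hoc pairs; Kaplan–Meier curves,
log-rank tests, Youden-index (*J* = sensitivity + specificity − 1) and
median cutpoints, and univariate Cox fits with Efron tie handling;
hypergeometric overrepresentation of gene lists against GMT collections
restricted to the panel universe.

## Worked example

```python
from tilscore import (SynthConfig, generate_cohort, housekeeping_normalize,
                      merge_panels, score_table, dichotomize, logrank_test,
                      cox_univariate)
from tilscore.pipeline import select_references

cfg = SynthConfig(n_samples=120, n_endog_a=80, n_endog_b=70, n_common=30,
                  n_hk_a=8, n_hk_b=8, markers_per_type=3, seed=42)
cohort = generate_cohort(cfg)   # plants log-hazard -1 of mast-vs-TIL on metastasis

na = housekeeping_normalize(cohort.panel_a, select_references(cohort.panel_a))
nb = housekeeping_normalize(cohort.panel_b, select_references(cohort.panel_b))
merged = merge_panels(na.matrix, nb.matrix.subset_samples(na.matrix.sample_names))

scores = score_table(merged.to_log2(), cohort.marker_map,
                     pairs=[("mast_cells", "TIL")])
mast = scores.relative.iloc[0]
cl = cohort.clinical.set_index("sample").loc[mast.index]
t, e = cl["time_metastasis"].to_numpy(), cl["event_metastasis"].to_numpy()

beta, hr, se, p = cox_univariate(t, e, mast.to_numpy())
cut = dichotomize(mast, "youden", event=e)
chi2, lr_p = logrank_test(t, e, cut.groups.to_numpy())
```

Output:

```text
merged genes: 136
mast-vs-TIL continuous Cox: beta=-0.936 HR=0.392 p=3.30e-13
Youden cutoff: -0.094 (J=0.455, events enriched low)
log-rank high vs low: chi2=57.91 p=2.75e-14
group sizes: {'high': 61, 'low': 59}
```

The continuous Cox fit recovers the planted protective coefficient
(−1 per log₂ unit of the mast-vs-TIL ratio; the −0.936 estimate
reflects marker-level count noise), the Youden split lands near the
score's center, and the low-mast group shows significantly worse
metastasis-free survival — the direction the generator planted.

The same analysis is scriptable end-to-end:

```bash
tilscore run --config run.yaml --out results/
tilscore synth --config synth.yaml --out cohort/ --seed 7
tilscore normalize --counts cohort/panel_A_counts.csv --refs auto --out normA.csv
```

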