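# fuccitrack

Headless analysis of FUCCI time-lapse movies: how long do individual cells
spend in G1 versus S/G2/M, and does a genotype change that?

The FUCCI reporter pair marks G1 nuclei in red (mKO2-Cdt1_30-120) and
S/G2/M nuclei in green (mAG-Geminin_1-110), with transient co-expression
around the G1/S transition and a dark window of several frames right after
mitosis when neither reporter has accumulated. `fuccitrack` turns
two-channel stacks into per-cell phase durations:

1. **Segmentation** — each channel is binarized per frame with a local
   mean + *k*·sd adaptive threshold, the channel masks are unioned, and
   speckle below an area floor is dropped.
2. **Click-scripted tracking** — an ordered CSV of seed points (the
   scriptable stand-in for interactive mouse clicks) names each cell and
   its progeny; the tracker selects the seeded connected component per
   frame, propagates between clicks by nearest-centroid matching, and
   bridges the post-mitotic dark gap.
3. **Phase timing** — mean red/green intensity traces over each tracked
   nucleus are thresholded (smoothed, sustained crossings) to find the
   green onset (G1/S transition) and green collapse (cytokinesis); a
   daughter's G1 runs from the frame after her mother's division to her
   own green onset. Phases whose bounding event falls outside the movie
   are censored and kept in a separate audit table.
4. **Statistics** — Mann–Whitney U (exact enumeration for n ≤ 8 without
   ties, tie-corrected normal approximation otherwise), Bonferroni
   adjustment, boxplot summaries (quartiles, 1.5×IQR whiskers), and a
   Kaplan–Meier median for right-censored duration tables.

Because public FUCCI data with ground truth are scarce, the package ships
a first-class synthetic-data module: lognormal per-phase duration models,
lineage simulation, a renderer (elliptical nuclei, persistent random walks
with nuclear exclusion, linear reporter ramps, Poisson + Gaussian noise)
that exports exact transition frames, plus fixtures for the ancillary
assays — propidium-iodide DNA-content histograms, replicated TaqMan Ct
tables, two-group immunofluorescence nuclei fields, and CRISPR
single-allele amplicon sets.

## Worked example

Simulate a wild-type-like cohort and a short-G1 mutant cohort, run the
full pipeline on each, and compare:

```python
from fuccitrack import ImagingConfig, NPC_MUT, NPC_WT, measure_cohort
from fuccitrack.stats import compare_cohorts, phase_km_median

imaging = ImagingConfig(n_frames=280, frame_interval_min=15.0,
                        height=256, width=256)
wt, wt_audit = measure_cohort(NPC_WT, imaging, n_movies=4, n_founders=12,
                              seed=7, genotype="wt")
mut, mut_audit = measure_cohort(NPC_MUT, imaging, n_movies=4, n_founders=7,
                                seed=8, genotype="mut")
print("wt  G1 median (KM):", phase_km_median(wt, wt_audit, "G1"))
print("mut G1 median (KM):", phase_km_median(mut, mut_audit, "G1"))
print(compare_cohorts(wt, mut).to_text())
```

prints (seeds as above):

```
wt  G1 median (KM): 1515.0
mut G1 median (KM): 600.0
wt vs mut (Bonferroni m=2)
  G1: wt 1342±654 min (n=104) | mut 510±373 min (n=210) | U=19334.5, p=1.08e-28, adj p=2.15e-28
  SG2M: wt 728±208 min (n=68) | mut 705±197 min (n=131) | U=4613.0, p=0.681, adj p=1
```

The Kaplan–Meier medians track the generating models (1408 and 517 min;
a 4-movie pool leaves a few percent of Monte-Carlo spread — the test
suite pools 10+ movies): G1 differs sharply between genotypes while
S/G2/M does not — the mutant reaches the G1/S transition roughly 900
minutes (~15 h) sooner. The naive medians of only the complete phases
(1342/510) understate long G1 because phases running past the movie end
are right-truncated; the KM estimator uses the censored spans in the
audit table to correct for this.

A command-line interface mirrors the library
(`fucci simulate movie|flow|qpcr|nuclei|alleles`, `fucci segment`,
`fucci track`, `fucci phases`, `fucci compare`, `fucci flow gate`,
`fucci qpcr ddct`, `fucci quantify`, `fucci genotype`); run
`fucci --help` for details.

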