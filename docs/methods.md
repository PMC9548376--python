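# Methods

## Cell-cycle duration model

Each genotype is described by a `CellCycleModel`: independent lognormal
G1 and S/G2/M durations parameterized by their median (minutes) and
log-scale sd. The lognormal was chosen for its positive support and the
strongly right-skewed spread reported for neural-progenitor G1; the
log-sd is solved in closed form from a printed median ± sd pair
(`logsd_from_median_sd`). Shipped presets:

| preset     | G1 median (min) | G1 sd | S/G2/M median | overlap | genotype |
|------------|-----------------|-------|---------------|---------|----------|
| `NPC_WT`   | 1408            | 982   | 720           | 60 min  | CHD8+/+  |
| `NPC_MUT`  | 517             | 410   | 720           | 60 min  | CHD8+/−  |
| `HESC_WT`  | 198             | 78    | 600           | 0       | CHD8+/+  |
| `HESC_MUT` | 153             | 61    | 600           | 0       | CHD8+/−  |

G1 medians/sds are the published cohort statistics. S/G2/M medians are
not published per genotype; 720 min (NPC) and 600 min (hESC) are typical
values and identical across genotypes, since no genotype effect on
S/G2/M was reported. S/G2/M log-sd is fixed at 0.25 (modest skew). The
co-expression `overlap_min` is 60 min for progenitor models (protracted
G1/S transitions) and 0 for embryonic stem cell models, where a clear
G1/S overlap is rarely seen; the post-mitotic dark gap defaults to 3
frames.

## Reporter kinetics and rendering

The generative timeline anchors the G1/S transition at birth + G1: the
green reporter (mAG-Geminin) ramps linearly from the transition over 60
min and collapses at cytokinesis; the red reporter (mKO2-Cdt1) ramps
from birth over 120 min, holds through G1, and decays over `overlap_min`
*after* green onset, producing the red+green co-expression window on the
S side of the transition. Anchoring the transition this way makes the
model's G1 median exactly the quantity the trace analysis measures
(birth to green onset), so synthetic calibration and recovery refer to
the same measurand. Both reporters are dark for `dark_gap_frames` after
mitosis.

Nuclei are rendered as ellipses (aspect 0.8, optional curvature for the
boomerang-shaped progenitor nucleus), convolved with a Gaussian PSF
(σ = 1.5 px), over a flat background (20 counts); Poisson photon noise
is applied first, then Gaussian read noise (sd 2), then quantization to
the configured bit depth. Motion is a persistent random walk
(persistence 0.8, step 1 px/frame) with pairwise nuclear exclusion
(minimum centre distance 2.3 radii) — nuclei in a monolayer do not
interpenetrate, and without exclusion sibling nuclei merge into single
segmented components for many consecutive frames, which no clicking
scheme can disambiguate. Walks reflect at a two-radius margin so no
nucleus leaves the field. The frame interval defaults to 15 min, enough
to resolve the shortest modeled G1 (153 min ≈ 10 frames).

The renderer exports, alongside the pixel data, a per-(cell, frame)
table of centroids, dark flags and pre-noise amplitudes, and the frame
indices of every birth, G1/S transition and division — the oracle used
throughout the tests.

## Segmentation

Foreground is `value > local_mean + k·local_sd` over a square window
with reflective padding. The window must be much larger than a nucleus:
an object occupying fraction *f* of the window is detectable only when
*f* < 1/(1+k²), so the defaults are a 49-px window (~8 nucleus radii,
*f* ≈ 0.04) with k = 2 (bound 0.2, which also tolerates the doubling of
*f* caused by border reflection). A small epsilon proportional to the
threshold guards against separable-filter rounding on constant
backgrounds. Objects under 25 px are dropped as speckle. Channel masks
are unioned; connectivity defaults to 8.

## Tracking

A click script is a CSV of `(frame, x, y, cell_id, parent_id)` records;
the synthetic generator can emit a perfect script from truth (one click
per visible frame, as in the original per-frame interactive workflow).
The tracker sweeps frame-major: at each frame, explicitly clicked cells
bind their components first, then unclicked active cells propagate from
their previous centroid to the nearest unclaimed component within
`search_radius_px` (default 18 = 3 nucleus radii). No component is ever
assigned to two cells in one frame. Up to `max_dark_frames` (default 5)
consecutive unmatched frames are tolerated as dark — this bridges the
3-frame post-mitotic gap plus the sub-threshold early ramp — after which
the track halts as lost. Ambiguous matches are broken by larger area,
then lower label, and logged. A mother's track ends the frame before her
first daughter's click; trailing dark frames are trimmed, so her last
tracked frame estimates the division frame.

## Phase timing and censoring

Traces are per-frame mean channel intensities over the tracked region.
Onsets are sustained crossings (≥ `min_run` = 2 frames) of the 3-frame
median-smoothed trace above `bg_mean + 5·bg_sd`, with background
estimated robustly (median / scaled MAD over the stack, sd floored at
one grey level so noiseless renders remain thresholdable).

Rules, chosen where the trace analysis was genuinely underdetermined:

- G1 of a daughter starts the frame after her mother's last tracked
  frame (the dark gap counts toward G1) and ends at green onset; the
  co-expression window therefore belongs to S/G2/M side of the marker.
- A founder whose track begins at frame 0 was mid-phase at acquisition
  start: start-censored. A founder that emerges from darkness later has
  an observed (reporter-ramp) birth and counts as complete.
- A daughter whose mother was lost more than 8 frames before the
  daughter appears has an unknown division time: her G1 is
  start-censored rather than anchored to a stale track end.
- Green onset before birth is contradictory; the cell is flagged
  unresolvable and excluded (logged).
- Censored spans go to an audit table, never the statistical table.
  End-censored spans are right-censored at the last frame the cell was
  still observed in-phase.

Complete-phase tables feed the genotype comparison directly (as the
published analysis did). For *median recovery* the package provides
`phase_km_median`, a Kaplan–Meier median over complete plus end-censored
records: with a 70 h movie and a 23.5 h median G1, phases that started
late are right-truncated and the naive median of complete phases is
biased several percent low; the product-limit estimator removes this.
Start-censored spans (unobserved birth) are excluded from the survival
estimate since they are not right-censored observations.

## Statistics

Mann–Whitney U: exact two-sided p by full enumeration of the
C(n1+n2, n1) rank assignments when both n ≤ 8 and no ties are present
(feasible and exact where the normal approximation is weakest);
otherwise midranks with tie correction and continuity correction.
Bonferroni m defaults to 2 (G1 and S/G2/M compared per experiment).
Boxplot summaries use linearly interpolated quartiles and whiskers at
the most extreme data point within 1.5×IQR. The exact binomial census
p-value is the minimum-likelihood sum (all outcomes no more probable
than the observed count), with "consistent with heterozygous" declared
at p ≥ 0.05.

## Ancillary assays

**DNA-content gating.** The 2N mode is the most prominent peak of a
smoothed histogram (with a guard that reassigns to a half-position peak
when the 4N peak dominates); the 4N mode is the peak nearest twice the
2N position; debris below 0.5× the 2N mode is cut first. Peak gates
span ±3 estimated sds. Because S-phase events also lie underneath the
peak gates, the S density estimated from the inter-gate plateau is added
back to S and subtracted from the peak counts (event totals conserved).
At ±2 sds the Gaussian tails of the peaks contaminate the plateau
estimate and the correction degrades, which is why 3 is the default;
both the width and fully manual gates are configurable (manual gates
take events as they fall, as in manual analysis). The automated
round-trip recovers generator fractions within ±2 points at n = 10000
for cv ≤ 0.08.

**2^−ΔΔCt.** Replicates are averaged at the Ct level per (sample, gene,
experiment); ΔCt subtracts the POLR2a reference, ΔΔCt subtracts the
wild-type ΔCt, fold = 2^−ΔΔCt per experiment, reported mean ± sd across
experiments. Any constant offset applied to one (sample, experiment)
cancels.

**ROI quantification.** Mean intensity per labeled ROI;
nucleus/cytoplasm ratio per paired ROIs (zero-cytoplasm cells flagged
and excluded); percent decrease 100·(1 − mean_b/mean_a) with the sd of
per-cell percent values taken relative to the group-a mean (the
per-cell convention; a per-experiment convention would need replicate
experiments).

**Genotyping.** Global pairwise alignment (match +1, mismatch −1, gap
−2, linear gaps — adequate for clean Sanger-resolved alleles); the net
gap length within ±20 bp of the cut site classifies the allele, with
substitution-only or distant/balanced-indel sequences reported as
`complex`. Premature-stop scanning translates the edited sequence
in-frame from the codon containing the edit and reports the first stop
absent from the reference at the same distance.

## Problem sizes and determinism

Every generator draws all randomness from one explicit integer seed;
identical seeds give bit-identical outputs. The cohort-recovery tests
use 10–12 replicate 280-frame (NPC) or 80-frame (hESC) movies at
256×256 px with 7–14 founders per movie, pooling well over 200 complete
G1 phases per genotype; the noiseless boundary-accuracy suite uses two
130-frame movies (~140 cells). These sizes put the Monte-Carlo error of
a recovered median at a few percent.

## What the simulation does and does not show

The generator reproduces the statistical structure the analysis relies
on — lognormal phase durations, reporter overlap and dark gap, dividing
and migrating nuclei, Poisson + read noise, 2N/4N PI mixtures, replicate
Ct structure, heterozygous allele mixtures — so passing tests show the
*measurement machinery* is unbiased under those assumptions. It does not
emulate photobleaching, focus drift, 3D optics, apoptosis, cell-cycle
exit, segmentation-resistant nuclear shapes, or fluorescence bleed-
through; robustness to those belongs to real-data validation. Touching
nuclei are handled only through seeded selection and exclusion dynamics;
there is deliberately no watershed splitting, so heavily overcrowded
fields lose tracks (recorded as censored) rather than guessing.
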