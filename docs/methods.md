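# Methods

## The lamina co-localization model

A cell's REST distribution is summarized from a 1-D cross-section
through the nucleus.  Each channel is reduced to a *normalized
spectrum*: distance divided by the total segment length (so x spans
[0, 1]) and intensity divided by its maximum (so max y = 1).  Dividing
by the maximum — rather than by the sum — is the only normalization
under which the "area under the graph" of a constant channel equals 1
and the area is independent of sampling density; areas are computed by
the trapezoidal rule, whose difference from a sample-sum is far below
reporting precision on ≥150-sample profiles (the refinement test bounds
it at <1 %).

The score `log10(|red−blue| / |red−green|)` compares the REST area to
the DAPI area (numerator) and the Lamin B area (denominator).  It is
undefined when two areas coincide, so both terms are clamped at
ε = 1e-6; the clamp keeps scores finite and order-preserving.  The
score inherits two exact invariances from the normalization: scaling
any channel's raw intensity leaves it unchanged, and swapping the
green/blue roles flips its sign.

*Peak thickness* is the full width at half maximum of the REST local
maximum nearest each Lamin B peak (within a window of 0.25 on the
normalized axis), above a local baseline taken as the profile minimum
between the peak and the nucleus center; the two lamina-adjacent widths
are averaged.  FWHM is used because it is the standard parameter-free
width measure; for a sampled Gaussian of width σ it converges to
2√(2 ln 2)·σ (verified to within 0.3 % at 512 samples, and within 10 %
down to σ = 0.01).  Width is floored at one sample spacing; flat or
peak-free profiles return NaN rather than a number.

*Ring-positive* classification is a threshold on the score.  The
original readout was a manual 0/1 call per cell, so manual labels are
first-class inputs to `ring_fraction`; the threshold is a calibration
parameter (e.g. by Youden's J on a held-out cohort), not a constant of
the method.

## Aggregate counting

Pixels inside the cell with intensity in [15,000, 65,535] (raw 16-bit
units) are binarized; 8-connected components are converted to µm² via
the pixel size squared and kept when in [0.2, 20] µm².  Components of
≥ 4 µm² are flagged aggresomes.  A component is *nuclear* if its
centroid falls in the nucleus mask, *perinuclear* if the centroid lies
outside but strictly within 10 px of the nucleus (Euclidean distance
transform of the mask complement), else *cytoplasmic*.  The intensity
thresholds are in raw camera units by convention, so the µm²
conversion requires an explicit `pixel_size_um` (default 0.2 µm/px).
Segmentation of nuclei and cells from pixels is out of scope: masks are
supplied by the caller or the simulator.

## Gene-set statistics

Two-set overlap: exact upper-tail hypergeometric, P(X ≥ k) at the
observed intersection k (the boundary convention is ≥ k, not > k).
Three-set overlap: the null redraws three sets of the observed sizes
uniformly without replacement from the universe and records the
triple-intersection size; p = (1 + #{perm ≥ obs}) / (n_perm + 1) with
10,000 permutations by default.  The add-one correction matches the
resolution bound of the permutation count and guarantees p > 0; ties
count as ≥ (conservative).  Sampling the null exploits an exact
distributional identity — |A′∩B′| ~ HG(N, a, b) and then
|A′∩B′∩C′| | |A′∩B′| ~ HG(N, |A′∩B′|, c) — so each permutation costs two
hypergeometric draws instead of three set draws; the test suite checks
this chain against an explicit set-drawing oracle on a small instance.

Enrichment against a term library is per-term hypergeometric with
Benjamini–Hochberg FDR across terms.  Two enrichment analyses are
meta-combined by *intersection-then-Fisher*: only terms significant
(FDR < α) in both tables survive, and their p-values are combined as
X² = −2(ln pA + ln pB) on 4 degrees of freedom.  The intersection rule
reflects the requirement that a candidate be supported by both
analyses; Stouffer combination is available as a config switch.
Identifier matching is exact and case-sensitive, with an optional
uppercase mapping for human symbols; ortholog mapping is out of scope.

The upregulated-gene filter keeps rows with padj < 0.05 AND
log2FC > 1.5, both strict, so boundary rows are excluded.

## Region statistics

All intervals are 0-based half-open; [a, b) and [b, c) never overlap,
and domain sets are merged before any overlap query.  The overlap
statistic is the count of peaks with ≥ 1 bp intersection (the fraction
is the count divided by the peak number) — chosen over base-pair
coverage to match a "fraction of peaks overlapping" readout.

Randomization preserves each region's length exactly and places it
uniformly over all valid (chromosome, start) positions genome-wide;
per-chromosome placement is available by flag.  The permutation test
repeats this 3,000 times (default) and reports the add-one p and the
z-score against the permutation mean and sd.  A constant null
(sd = 0) yields a degenerate flag and a signed-infinity z rather than
an error, keeping batch runs alive on tiny fixtures.  The null is
evaluated in a concatenated-genome coordinate space: randomized regions
never span a chromosome boundary by construction, so one binary search
against the merged domain union is exact.

Consensus across replicates clusters peaks by summit proximity:
single-linkage per chromosome, with gaps up to the summit window
(250 bp default, inclusive at the boundary) joining a chain, and at
most one peak per replicate per cluster (nearest to the cluster median
summit wins).  A cluster is *present* when ≥ min_support (default 2)
distinct replicates contribute, and its consensus interval is the
merged span of its members.  Emerging/vanishing calls between two
replicate groups share one cluster scaffold, so presence in the two
groups is evaluated on identical clusters.  The 250 bp window is a
convention, not an inference — the matching width used originally is
not recorded.

The annotation z-test assumes the observed count shares the randomized
counts' standard deviation (sample sd, ddof = 1; 10 randomizations in
the original design): z = (obs − mean)/sd with a one-sided normal p,
upper-tailed for enrichment or lower-tailed for depletion.

TSS annotation keeps peaks with q < 1e-5 (strict; a missing q-value
column with a q filter requested is a schema error) and assigns a gene
when a kept peak's summit (midpoint when no summit is recorded) lies
within ±3,000 bp of the TSS, closed at both ends and
strand-independent.  Both boundary conventions are documented here
because only the bounds themselves were printed.

## Expression correlation

Per donor brain, Pearson R between the anchor gene's profile and each
candidate across brain structures, with two-sided p-values; structures
with missing values are dropped pairwise, since microarray panels
differ per brain, and fewer than 3 shared structures or a
zero-variance profile yields NaN.  The sample × target R table is
clustered with average linkage on Euclidean distances of the R vectors,
rows and columns pre-sorted by label so ties break deterministically.
The linkage choice is a display convention and is configurable.

## What the synthetic generators emulate

* **Cells** — a filled nuclear disk (DAPI), an isotropic Gaussian
  annulus at the nuclear boundary (Lamin B; the Gaussian is the
  simplest ring shape with a controllable FWHM, which the thickness
  tests exploit), and a REST channel mixing ring, diffuse-nuclear and
  cytoplasmic components whose weights sum to ≤ 1, plus
  Poisson-distributed cytoplasmic condensates and additive Gaussian
  noise clipped at zero.  Intensities follow a 16-bit convention
  (amplitudes 20,000–30,000; condensates painted at 45,000) so the
  aggregate thresholds are meaningful on simulated data.  Condensates
  are placed fully inside the cytoplasm, clear of the lamina annulus by
  3σ, and pairwise disjoint, making the planted count the detection
  ceiling: the counter recovers it exactly.  The WT preset puts 80 % of
  REST signal in the ring; the KO preset 20 %, with heavier diffuse and
  cytoplasmic pools and a condensate rate of 3 per cell.  Defaults
  (0.2 µm/px, 192×192 px, nucleus radius 38 px, ring σ 3 px, noise sd
  600) are acquisition conventions, not measured values.
* **Gene sets** — a planted core common to all sets plus remainders
  drawn disjointly, so the realized multi-set intersection equals the
  planted size exactly.
* **Regions** — one domain block per chromosome covering a set
  fraction; base-peak summits planted inside/outside domains at the
  requested overlap fraction, ≥ 600 bp apart so distinct peaks never
  collapse into one summit cluster; replicates derived by independent
  dropout and rounded-Normal summit jitter with lengths preserved.
* **Expression** — targets built as ρ·z + √(1−ρ²)·e against a standard
  normal anchor, so the planted population correlation is exact (and
  the sample correlation is exactly ±1 at ρ = ±1).

Every generator consumes one integer seed and is bit-deterministic; no
global random state is touched.  What the generators do **not**
emulate: optics (PSF, depth, bleaching), segmentation errors,
non-circular nuclei, GC or mappability bias in peak placement, and
inter-gene correlation structure beyond the planted anchor — so
passing recovery tests demonstrates correctness of the estimators
under the stated model, not robustness to real-data artifacts.

## Problem sizes and calibration

The permutation calibration checks run 2,000 null simulations of 500
permutations each and require the p-value ECDF to be within KS
D < 0.05 of uniform.  The null configurations (universe 1,000 with
three sets of 500; 800 single-bp peaks against a 50 %-coverage domain)
are chosen so the null statistic has wide support: with few support
points any permutation p-value is lattice-valued and a KS distance to
the uniform is dominated by discreteness rather than miscalibration.
Recovery studies use 100–200 cells or replicates per condition and the
acceptance script uses 100 cells per group, 10,000 gene permutations
and 3,000 region permutations — the defaults of the statistics
themselves.

## Known limitations

* Line profiles assume the segment crosses the nucleus roughly through
  its center; strongly off-center chords bias the DAPI area upward.
* The thickness estimator needs a resolvable local maximum near each
  lamina position; heavily diffuse cells return NaN by design and must
  be handled (they are "cells without a REST peak", not zeros).
* The aggregate counter labels compartments by centroid only; an
  elongated aggregate straddling the nuclear boundary gets a single
  label.
* Genome-wide randomization treats the genome as unannotated — no
  blacklist, gap or mappability masking.
* The intersection-then-Fisher meta-combination is one defensible
  reading of combining two enrichment screens; Stouffer's method is
  provided as an alternative because the combination statistic is a
  design choice, not a derived fact.
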