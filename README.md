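# restquant

Quantification tools for studying how the neural-gene repressor REST
(RE-1 silencing transcription factor) is distributed inside cells and
across the genome, built for experiments that compare SIRT6-proficient
(WT) and SIRT6-deficient (KO) conditions.  The package bundles the
bespoke statistics such a study needs — a nuclear-lamina co-localization
score for three-channel immunofluorescence, cytoplasmic aggregate
counting, gene-set and genomic-region overlap permutation tests, and
expression-profile correlation — together with synthetic-data generators
that plant known ground truth, so the whole pipeline is testable without
microscopes or sequencers.

## Who it is for

Groups quantifying (a) whether a nuclear protein forms a peripheral
"ring" at the nuclear lamina versus a diffuse or cytoplasmic
distribution, (b) how many cytoplasmic condensates/aggregates cells
carry, and (c) whether gene sets or peak sets overlap more than chance
against a protein-coding or genomic background.

## The core quantities

**Laminar co-localization score.**  For a line profile drawn across a
nucleus, each channel (DAPI, Lamin B, REST) is normalized to unit length
and unit maximum intensity, and the area under each normalized curve is
taken.  With `red` = REST area, `green` = Lamin B area, `blue` = DAPI
area:

```
score = log10( |red − blue| / |red − green| )
```

A REST distribution hugging the lamina has an area close to Lamin B's
and far from DAPI's, so lamina-ring cells score high and
diffuse-nuclear cells score low (both terms are clamped at 1e-6 so the
score stays finite).  The thickness of the lamina-adjacent REST peak is
its full width at half maximum above a local baseline.

**Overlap statistics.**  Two gene sets are tested with the upper-tail
hypergeometric probability P(X ≥ k); three sets with a permutation test
(10,000 draws of same-sized sets from the universe, add-one-corrected
p).  Peak sets are tested against annotation domains (LADs, H3K27me3
domains) by size-preserving genome-wide randomization (3,000
permutations), and replicate peak sets are reduced to consensus peaks by
an at-least-2-of-3 summit-proximity rule.

**Aggregate counting.**  Intensity thresholding (15,000–65,535 raw
units) plus 8-connected components and size gates (0.2–20 µm²;
aggresomes ≥ 4 µm²), with nuclear / perinuclear (< 10 px from the
nucleus) / cytoplasmic compartment labels.

## Worked example

```python
from restquant import imaging, synthgen

# the score formula itself
imaging.laminar_score(0.6, 0.5, 0.9)      # 0.47712125471966266  (= log10 3)

# simulate one lamina-ring cell and one diffuse/cytoplasmic cell
wt = imaging.profile_laminar_result(
    synthgen.simulate_line_profile(synthgen.wt_preset(seed=1)))
ko = imaging.profile_laminar_result(
    synthgen.simulate_line_profile(synthgen.ko_preset(seed=1)))
print(wt.score, wt.thickness)              # 0.5584  0.0440
print(ko.score, ko.thickness)              # -0.6815 0.0293
```

The WT preset (80 % of REST signal in the lamina ring) scores ~0.56 —
its REST area tracks the Lamin B area — while the KO preset (20 % ring,
mostly diffuse and cytoplasmic) scores ~−0.68.  Over 100 cells per
group the preset score distributions separate completely (AUC = 1.0 at
the default noise level).

The same pipeline runs from the shell:

```
restquant simulate --out fixtures --seed 3
restquant ringscore --manifest fixtures/manifest.tsv --out ring.tsv
restquant geneset-overlap fixtures/genesets/set{1,2,3}.txt \
    --universe fixtures/genesets/universe.txt --out overlap.tsv --seed 3
```

`ring.tsv` carries one row per cell (score, thickness, ring call) with
the resolved parameters and the WT/KO group comparison in its header;
`overlap.tsv` reports the pairwise hypergeometric p-values and the
three-way permutation test (planted core of 40 genes: p = 1/10001,
z ≈ 42).

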