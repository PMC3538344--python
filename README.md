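# radmap

Linkage mapping and pedigree genetics for an F2 intercross genotyped with
RAD markers — the complete downstream analysis of a ddRADSeq cross between
two diverged fish lines: marker QC and segregation testing, two-point
genetic-map construction, segregation-distortion block detection,
cross-genome conserved-synteny scoring, and pedigree-based de novo
mutation-rate estimation.  A synthetic-pedigree generator with full ground
truth (true map, selection blocks, injected mutations) makes every stage
testable without any sequencing data.

## Who it is for

Geneticists building a linkage map from an F2 cross (two parents, an F1
sibling pair, a large F2 cohort) scored at codominant or partially
informative markers with per-allele read depths — and anyone who wants a
transparent, scriptable reimplementation of the classical two-point
mapping workflow with reproducible simulations behind it.

## The models at the core

**Two-point recombination fractions.** For each marker pair the
recombination fraction `r` is estimated by maximum likelihood with an EM
algorithm over the joint F2 genotype classes.  The double heterozygote is
a phase mixture (zero or two recombinant gametes); collapsed one-sided
codes (`c` = not-a, `d` = not-b) widen the compatible class sets.  Phase
is a nuisance parameter: the EM runs over `r ∈ (0, 1)` from coupling and
repulsion starts and reports the folded `r̂ = min(r, 1−r)` with
`LOD = log₁₀ L(r̂) − log₁₀ L(½)`.

**Map construction.** Markers are grouped by single-linkage closure over
pairs with LOD ≥ 6, then each group is ordered regression-mapping style:
markers are inserted in decreasing order of linkage information, candidate
positions are scored by a weighted least-squares fit of pairwise Kosambi
distances (pairs used when `r ≤ 0.400` and `LOD ≥ 1.0`), a goodness-of-fit
jump > 5.00 postpones a marker, and a window-permutation *ripple* polishes
the order after each insertion.  Distances use Kosambi's map function
`d = 25 ln((1+2r)/(1−2r))` cM.

**Segregation distortion.** Each marker is tested against its Mendelian
expectation (1:2:1, or 1:3 for one-sided markers); blocks are maximal runs
of map-adjacent distorted markers (p < 0.05, ≥ 3 distorted members, at
most one interior skip), classified by the standardized residuals as
paternal/maternal-allele excess or heterozygote excess/deficit.

**Conserved synteny.** Tabular (12-column) alignment hits of marker
sequences against a reference genome are filtered by e-value, resolved to
unique locations (best hit kept only when it leads the runner-up by > 20
bits), and scored: the conserved-synteny percentage is the share of
qualifying markers that land on their linkage group's modal orthologous
reference group.  An Oxford grid with both coordinates size-normalised to
[0, 1] summarises marker-order conservation.

**De novo mutation rate.** Progeny alleles absent from both parents are
candidate mutations; a candidate is retained when its locus has ≥ 8 reads
with ≥ 4 per allele, its original/novel depth ratio lies in [0.5, 2.0],
and the ratio falls inside the central 95% of the empirical allele-balance
distribution of genuine heterozygous calls.  After collapsing identical
mutations within a generation, the rate is `u = m / (2 · n · L)` per
nucleotide per generation over `L` surveyed sites in `n` individuals, and
generation rates are averaged unweighted.

## Worked example

```python
from radmap import PipelineConfig, SimConfig, run_pipeline
from radmap.sim import SelectionBlock, simulate_dataset

cfg = SimConfig(
    n_groups=5, markers_per_group=[30] * 5, group_lengths_cm=[60.0] * 5,
    n_f2=343,
    distortion_blocks=[SelectionBlock(2, 20.0, 40.0, "against_maternal", 0.5)],
    seed=1,
)
ds = simulate_dataset(cfg)                 # truth-tracked synthetic cross
res = run_pipeline(ds.f2, PipelineConfig())
print(res.map_results.summary())
```

prints

```
Linkage map (two-point regression mapping, Kosambi distances)
==============================================================
grouping LOD threshold           6.00  (linkage)
ordering max rf / min LOD       0.400 / 1.00
goodness-of-fit jump             5.00
--------------------------------------------------------------
linkage groups                      5
mapped markers                    150
ungrouped / unplaced                0 / 0
total map length (cM)           296.2
mean marker spacing (cM)         2.04
largest gap (cM)                 13.2  on LG5
--------------------------------------------------------------
LG1      30 markers    64.3 cM
LG2      30 markers    60.1 cM
...
```

All five simulated 60 cM chromosomes are recovered as linkage groups with
their 30 markers each; `res.distortion_blocks` flags a block of markers
with an excess of the `b` (paternal) allele on the group carrying the
simulated viability-selected locus.  Groups are named `LG1..` by
decreasing map length, so the selected true chromosome need not be `LG2`
in the output.

The same stages are available from the shell:

```sh
radmap simulate --out sim/                 # synthetic cross + truth files
radmap all --genotypes sim/genotypes.tsv --out results/
radmap synteny --map results/map.tsv --hits hits.tsv \
    --lengths tilapia_lengths.tsv --out syn/
```

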