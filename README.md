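# decaplex

Statistics and quantification for multi-bait proximity-labelling
(TurboID/BioID) interactomics and for fluorescence localization of
posterior-pole RNA granules — the analysis stack behind interactome studies
of the trypanosome mRNA decapping complex (an ApaH-like phosphatase,
ALPH1-type enzyme, its kinase and 5'-3' exonuclease partners).

It is aimed at researchers who have label-free quantification (LFQ)
protein-groups tables from bait/control proximity-labelling or affinity
capture experiments and want: volcano statistics with significance-curve
classes, auditable candidate-list filtering across baits, and matched
microscopy quantification of granule localization — plus synthetic-data
generators with known ground truth to validate every stage.

## What it computes

**Volcano statistics with s0 curves.** For each protein, the difference of
log2 group means `d` between a bait and the untagged control, a two-tailed
pooled-variance Student t-test p-value, the linear enrichment ratio `2^d`,
and membership in significance classes bounded by hyperbolic cut-off
curves. A class is defined by a target false discovery rate and the s0
parameter through the modified statistic

    t' = d / (se + s0 · k),   k = mean(se),

whose rejection threshold is calibrated by sample-label permutation so that
the median-based FDR estimate stays at or below the target (defaults:
SigA = (FDR 0.01, s0 0.1), SigB = (0.05, 0.1), SigC = (0.05, 2.0)). At
s0 = 0 only the p-value matters; at larger s0 the effect size dominates.
Missing LFQ values are imputed from a downshifted normal distribution
(width 0.3 SD, downshift 1.8 SD per sample column) after a
minimum-quantification filter.

**Filter cascades.** Candidate interactor lists via explicit, auditable
rules: intersection of significant hits across full-length bait
experiments, subtraction of free-ligase (eYFP-TurboID) control hits with
allowlist/denylist overrides, replicate-evidence and fold-change rules,
curated mRNA-metabolism / domain-dependency retention, and the strict
multi-bait intersection that defines a core complex. Every protein carries
a trace of each rule applied and its outcome.

**Granule quantification.** From two-channel cell images: the percentage of
a channel's background-corrected fluorescence inside a circle of radius
12 px = 0.774 µm at the posterior pole, the PP score (bait % divided by
reference-marker % in the same circle; > 1 flags localization), the
percentage of bait signal in marker-defined stress granules, pooled t-test
group comparisons and integer-percent tallies.

**Construct masses.** Average-mass theoretical molecular weights of
sequence ranges and oligomeric-state calls from SEC-MALS-style measured
masses (e.g. a 79.3 kDa construct eluting at 166.7 kDa is a dimer).

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

```python
from decaplex import *

# synthetic LFQ experiment: 1500 proteins, triplicate bait / wt / eYFP
# groups, 20 planted interactors at +4 log2 units, 5% bystanders
design = default_design()
matrix, truth = simulate_lfq(design=design, seed=1)

log, _ = filter_min_values(log_transform(matrix), 3)
imputed = impute_downshifted(log, seed=1)
table = two_sample_ttest(imputed, design.by_group("bait", "bait1"),
                         design.by_group("wt_control"))
table = classify_significance(table, imputed, DEFAULT_CUTOFFS, seed=1)
for name in ("SigA", "SigB", "SigC"):
    hits = table.significant(name)
    print(f"{name}: {len(hits)} enriched, "
          f"{len(hits & truth.interactors)}/20 planted interactors")
```

prints

```
SigA: 95 enriched, 20/20 planted interactors
SigB: 99 enriched, 20/20 planted interactors
SigC: 98 enriched, 20/20 planted interactors
```

All 20 planted interactors are recovered in every class; the remaining
enriched proteins are almost entirely the planted bystanders, which are
also enriched over the untagged control — running the cascade against the
eYFP-control volcano table removes them
(`high_confidence_cascade(...)`). The imaging side closes the same loop:

```python
cell, t = simulate_cell(pp_fraction={"bait": 2.6, "marker": 2.0}, seed=4)
bait = background_correct(cell.channels["bait"], cell_mask=cell.cell_mask)
ref = background_correct(cell.channels["marker"], cell_mask=cell.cell_mask)
print(px_to_um(12, 6.45, 100))                                  # 0.774
print(round(pp_fraction(bait, t.pp_center, 12, cell.cell_mask), 2))  # 2.6
print(round(pp_score(bait, ref, t.pp_center, 12, cell.cell_mask), 2))  # 1.3
```

A cell simulated with 2.6% of the bait at the posterior pole measures 2.6%
under realistic noise; the PP score 1.3 (= 2.6/2.0) is above 1, flagging
posterior-pole localization. And on the mass side,
`oligomer_state(166.7, 79.3)` returns `(2, 'dimer')`.

The same stages are available as a CLI:

```
decaplex --config config.yaml simulate-lfq --out-dir run/
decaplex --config config.yaml volcano  --proteins run/proteinGroups.tsv --design run/design.tsv --out-dir run/
decaplex --config config.yaml cascade  --proteins run/proteinGroups.tsv --design run/design.tsv --out-dir run/
decaplex simulate-cells --out-dir cells/ && decaplex quantify --cells-dir cells/ --out cells.tsv
decaplex mw --fasta constructs.fasta --out mw.tsv
```

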