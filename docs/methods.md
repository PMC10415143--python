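# Methods

`decaplex` implements the quantitative analysis behind a multi-bait
proximity-labelling (TurboID/BioID) study of the trypanosome mRNA decapping
machinery, together with the fluorescence quantification of its
posterior-pole (PP) granule localization. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Volcano statistics for LFQ proximity labelling

**Input model.** The unit of analysis is a protein-groups label-free
quantification (LFQ) matrix: proteins x samples, raw linear intensities,
with zeros treated as missing (a zero LFQ value carries no quantitative
information; the log transform is undefined there). Samples belong to
triplicate groups: one or more tagged baits, an untagged parental
(`wt_control`) group, and a free biotin-ligase (`eyfp_control`) group that
estimates bystander labelling.

**Pipeline order.** log2 transform → minimum-quantification filter →
downshifted-normal imputation → pooled t-test → s0 classification. The
minimum-values filter runs *before* imputation because counting imputed
values would be circular; imputation runs before testing because the
pooled t-test needs complete groups.

**Imputation.** Missing values in each sample column are drawn from
`Normal(mu - downshift*sigma, (width*sigma)^2)` where `mu`, `sigma` are that
column's observed mean and SD. Defaults `width = 0.3`, `downshift = 1.8`
(column-SD units) are the conventional settings for this workflow: they
place imputed values around the instrument's detection limit, matching the
left-censored missingness of LFQ data. A column with fewer than two
observed values has no estimable distribution and is an error.

**Test.** Per protein, a two-tailed pooled-variance (homoscedastic Student)
t-test of bait vs parental control; the same statistic is used for imaging
group comparisons (one shared implementation). Degenerate inputs: zero
pooled variance with zero difference is defined as p = 1 (identical constant
groups carry no evidence); zero pooled variance with a nonzero difference
has no finite statistic and is an error. The linear enrichment ratio is
`2**diff` where `diff` is the difference of group means on the log2 scale.

**Significance classes (s0 curves).** A protein's class is decided by the
modified statistic

    t' = diff / (se + s0 * k),    k = mean(se) over the table,

a SAM-style construction: at `s0 = 0` only the p-value matters, while at
nonzero `s0` the absolute difference of means contributes, producing a
hyperbolic boundary in (difference, -log10 p) space. `k` rescales `s0` so
that it is expressed in units comparable to a typical standard error. Three
classes are configured by default: SigA (FDR 0.01, s0 0.1), SigB (FDR 0.05,
s0 0.1) and SigC (FDR 0.05, s0 2.0); at equal s0 a stricter FDR is nested
inside the looser one by construction.

**FDR calibration.** The rejection threshold on |t'| is calibrated by group
label permutation: whole sample columns are permuted (preserving
between-protein correlation), t' is recomputed, and the estimated FDR at a
candidate threshold c is `median_b(#null |t'| >= c) / (#observed |t'| >= c)`.
The threshold is the smallest observed |t'| with estimated FDR at or below
the target. When the number of distinct label splits is enumerable
(`C(n, n_a)` at or below the permutation budget, e.g. 20 splits for 3v3),
every distinct split is used exactly once — a complete balanced null —
otherwise 250 random permutations are drawn (seeded). With triplicates the
null has 4 degrees of freedom and fat tails, so calibrated thresholds are
conservative; this is a property of the design size, not of the estimator.
Only the bait-enriched (positive-difference) side feeds downstream candidate
lists; the depleted side is reported alongside.

## Candidate cascades and the core complex

Candidate lists are produced by explicit set-logic rules, each recorded per
protein in a `FilterTrace` so that every exclusion names the failing rule:

1. **Intersection** — significant at a minimum class (default SigB, which
   includes the stronger SigA) in *every* full-length bait experiment.
2. **Control subtraction** — candidates also significant (SigA or SigB) with
   the free-ligase control are removed as bystanders, unless an explicit
   curation allowlist overrides the removal (the override is recorded);
   denylisted recurrent contaminants are removed unconditionally.
3. **Curation** — keep proteins with a curated mRNA-metabolism link, or
   whose domain-dependency call shows a terminal-domain-specific
   interaction. Curation flags are user-supplied literature judgements; the
   pipeline never infers them.

Auxiliary rules used by single-bait lists: a replicate-evidence rule
(observed, never imputed, in at least k of the bait replicates; e.g. 2 of
3), "enriched vs control" operationalized as `diff > 0`, and a fold-change
rule keeping ratios at or above a threshold (default 2.5, boundary
inclusive, since the exclusion is of proteins *less than* 2.5-fold
enriched). These rules commute — the final set does not depend on
application order.

**Domain dependency.** With baits FL (full length; endogenous and
overexpressed entries must both be significant when both are given), dN
(N-terminal truncation), dC (C-terminal truncation) and cat (catalytic
core): significant with all truncations including cat → `catalytic`;
FL + dN only → `C-terminal`; FL + dC only → `N-terminal`; FL + dN + dC but
not cat → `both-termini`; anything else → `unresolved`. Mixed classes at or
above the configured minimum all count as "significant" (strictness
configurable).

**Core complex** is the strict intersection of per-bait candidate sets over
at least two experiments.

## Synthetic LFQ matrices

`simulate_lfq` emulates the statistical structure the pipeline consumes:
per-protein baseline log2 intensities `Normal(26, 2)` (a log-normal
proteome); interactors elevated by `effect` log2 units in their bait
samples only; bystanders elevated in bait *and* eYFP-control samples;
per-cell Gaussian replicate noise (`noise_sd = 0.4` log2 units, a ~30%
replicate CV typical of LFQ); and left-censored missingness with
`P(missing | x) = 1/(1 + exp(steepness*(x - midpoint)))` of the true
(pre-noise) log2 intensity (defaults steepness 0.8, midpoint 22, a ~10%
marginal missing rate concentrated in low-abundance proteins). Defaults:
1500 proteins (the scale of the real experiments), 20 interactors, effect
4 log2 units, 5% bystanders, triplicate groups. The generator does **not**
model peptide-level effects, shared-peptide protein grouping,
normalization artefacts, or correlated (batch) noise — so passing tests
demonstrate calibration and power under idealized independent noise, not
robustness to those real-data features.

## Image quantification

Measurements follow the microscopy workflow: sum-slice Z projection,
background correction (default: mean over a 5-pixel image border ring
excluding the cell mask; an explicit background region or a border
percentile can be used instead), then region fractions. The posterior-pole
fraction is the percentage of a channel's background-corrected total cell
fluorescence inside a circle of radius 12 pixels — 0.774 um at the 6.45
um/pixel camera behind a 100x objective — placed at the posterior pole
(user-supplied coordinates, or automatically at the extreme point of the
cell mask along its principal axis). A pixel belongs to the circle iff its
0-based center coordinate lies within the radius. The PP score divides the
bait channel's percentage by the reference channel's percentage in the same
circle; any score strictly above 1 flags PP localization. Stress-granule
localization is the percentage of bait signal inside a granule mask
segmented from the marker channel as pixels above the in-cell mean + 2 SD,
keeping connected components of at least 4 pixels (the segmentation rule is
a package choice, exposed in config). Category tallies are displayed as
integer percentages (round half away from zero; 26/41 → 63%) with the raw
value retained.

## Synthetic cell images

`simulate_cell` draws an elongated elliptical cell (default semi-axes
20 x 150 pixels in an 80 x 340 frame, a trypanosome-like aspect at the
instrument's pixel pitch) with uniform cytoplasmic signal, a
truncated-Gaussian pole spot (sigma = circle radius / 2, restricted to
circle-and-mask pixels), optional disk granules in the interior, a constant
additive background (default 10% of the cytoplasmic level) and additive
Gaussian noise (default 5% of the cytoplasmic level).

**Calibrated fraction semantics.** The generator's `pp_fraction` parameter
is the fraction of the channel's pre-noise total contained in the standard
measuring circle — pole spot plus the diffuse cytoplasm beneath it. The
spot mass solves a small linear system so that the circle (and, when
granules are planted, the granule pixels) hold exactly the requested
percentages. Consequences: quantification of a noise-free image returns the
parameter exactly (round-trip closure, tested at two resolutions); at
`pp_fraction 0` no spot exists and the measurement returns the circle's
area share of the uniform signal (~1.1% at the default geometry); requested
fractions below that diffuse share are infeasible and raise an error. The
default reference-channel fraction in two-channel simulations is 2.0%,
just above the diffuse share, representing a marker that does not
concentrate at the pole. The generator does not model the point-spread
function, photon (Poisson) noise, or realistic trypanosome morphology, so
closure results validate the measurement arithmetic and its noise
robustness, not segmentation of real cells.

## Construct masses and oligomeric state

Theoretical molecular weights are sums of average (not monoisotopic)
residue masses plus one water — the quantity SEC-MALS molar masses are
compared with. Residue ranges are 1-based and inclusive; constructs are
modelled as native ranges without expression-tag remnants (tags are
protease-removed in the workflow this supports; residual residues can be
included in the range if needed). Oligomeric state: `n =
round(measured/theoretical)`, accepted when the measured mass is within a
fractional tolerance (default 0.15) of the n-mer mass, else "ambiguous".
The packaged `data/alph1_synthetic.fasta` is a synthetic stand-in sequence
(734 aa) constructed so that the standard construct ranges reproduce the
published theoretical masses at one decimal; it is not a natural sequence
and is used only to exercise the mass arithmetic end to end.

## Problem sizes and determinism

Default analyses run in seconds on one core: 1500-protein matrices with
triplicate groups classify in ~0.2 s (the 3v3 null is the 20-split complete
enumeration); the test suite's calibration checks use 20 independent
matrices for the null FDR and 5 for power; imaging closure uses 50–100
synthetic cells per condition. Every stochastic stage takes an explicit
seed (numpy `default_rng`), and identical configurations produce
byte-identical result tables. Result files carry a header comment recording
the pipeline version and the parameters that produced them.

## Known limitations

- The permutation-FDR calibration is conservative for small designs and
  depends on the fraction of truly changed proteins through the observed
  exceedance count; per-table thresholds therefore differ between bait and
  control comparisons.
- The curation rule cannot be validated synthetically beyond plumbing,
  since its content is literature judgement supplied by the user.
- Granule segmentation (mean + 2 SD, min 4 px) is a pragmatic default; real
  stress-granule data may need tuned thresholds or a dedicated spot
  detector.
- Cell-cycle staging, kinetoplast/nucleus counting and cell segmentation
  from brightfield are out of scope; masks and stage labels are inputs.
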