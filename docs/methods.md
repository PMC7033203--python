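# Methods

## Scope and design

triptofunnel implements a staged multi-omics candidate screen and the
paralog-divergence statistics used to detect and date whole-genome
multiplications. It is organised as a pipeline of small, composable
function modules (expression, peaks, network, families, wgd, funnel,
synthetic) rather than a single fitted model object: no stage estimates
parameters with uncertainties — every stage is a deterministic transform
or a classical test — so the natural surface is functions over typed
containers, with a thin `click` CLI on top.

## Expression processing

RPKM is the standard 10⁹·count/(length·library) normalisation; a zero
library size is an error naming the offending sample. Differential
expression uses the two-sided pooled-variance Student *t* on
log₂(x + 1) values, per gene per time point; the reported fold change is
the ratio of raw arithmetic means (pseudocount 1). When both groups have
zero variance the statistic is undefined and we map the case to *p* = 0
if the means differ, *p* = 1 otherwise — the limiting behaviour of the
test as variance → 0. No multiple-testing correction is applied to DE
p-values: the screen's thresholds are intended as raw per-test cutoffs,
and a Benjamini–Hochberg option exists on the network side for users who
want it. Tissue dominance is operationalised as: focal tissue holds the
(possibly tied) maximum across tissues *and* exceeds `min_ratio` (default
2) times the median of the other tissues. "Highly expressed in the focal
tissue" has no unique formalisation; this rule is simple, monotone in its
threshold, and exposed in config.

Profile normalisation for correlation is per-row z-scoring of
log₂(x + 1); constant rows are mapped to all-zero and flagged rather
than propagating NaN.

## Peak filtering

Three filters: inclusive m/z window (295–400 Da by default — bounds are
treated as inclusive on feature m/z since no convention is forced by the
quantity itself), one-way ANOVA across sample groups on log₂ intensities
with a raw-scale max-fold gate (pseudocount 1 avoids division by zero),
and removal of features with `fragment_count` 0. The ANOVA filter
*retains* changing peaks by default (`keep_changing=True`); the inverted
reading — retaining stable peaks — is selectable, since a responsiveness
screen can be phrased either way and downstream correlation analysis only
makes sense on the changing set. The grouping factor (condition × time,
or condition only) is config-driven.

## Correlation network

Pearson *r* with the exact *t*-reference p-value
(*t* = *r*·√((*n*−2)/(1−*r*²)), *n*−2 df, two-sided). Cutoffs are strict:
*r* > 0.7 and *p* < 0.05, positive correlations only by default (the
signed-*r* reading; an |r| screen can be had by disabling
`positive_only`). Gene and metabolite matrices are inner-joined on exact
sample-id strings; unmatched columns are dropped with a logged count.
Time-course and tissue panels may be correlated jointly or as separate
networks merged by `union_networks` (strongest edge wins).

## Protein families

Percent identity comes from one global alignment (BLOSUM62, gap open −10,
extend −0.5, via Biopython's PairwiseAligner): identity = matches /
aligned columns excluding terminal-gap columns, so overhangs do not dilute
identity but internal gaps do; coverage is the fraction of query residues
aligned opposite a subject residue and is role-specific. Thresholds follow
their phrasing: homologs need coverage ≥ 50% and identity strictly > 50%;
species specificity requires the best cross-species identity strictly
below the 55% subfamily cutoff; duplicate collapse links pairs at ≥ 97%.
Collapse is single-linkage with the longest sequence (ties:
lexicographically smallest id) as representative. Exhaustive pairwise
alignment replaces database search: it is deterministic and adequate at
the curated-input scale this package targets; E-values and domain models
are out of scope.

## Divergence statistics

**4DTv** is the raw proportion of fourfold-degenerate third-codon sites
(both sequences sharing one of the prefixes TC, CT, CC, CG, AC, GT, GC,
GG) whose third bases differ by a transversion. It is reported
uncorrected; at the divergences of interest (recent WGT) multiple hits at
4D sites are rare.

**Ks/Ka (NG86).** Synonymous site counts per codon weight each position by
the fraction of its three possible changes that are synonymous (changes to
stop codons count as nonsynonymous); counts are averaged over the two
sequences. Observed differences are classified by averaging over all
minimal mutational pathways between differing codons, excluding pathways
that pass through a stop; a codon pair whose pathways all hit stops is
skipped with a warning. Jukes–Cantor correction gives
Ks = −(3/4)·ln(1 − 4pS/3); pS ≥ 3/4 flags saturation. This counting
estimator replaces codon-model maximum likelihood: it is closed-form,
deterministic, and accurate for Ks below ~1, which covers the recent-event
dating this package performs; ML and counting estimates diverge at higher
saturation, a known limitation. Independent NG86 implementations weight
stop-blocked pathways slightly differently, which moves Ks in the third
decimal on stop-adjacent codon pairs.

**Clock.** *T* = Ks/(2*r*) with *r* = 6.5 × 10⁻⁹ per site per year (a
standard eudicot rate), reported in MYA.

**Peaks in divergence distributions** are modes of a Gaussian KDE
(Scott's rule unless a bandwidth is passed) on a 512-point grid, keeping
local maxima above 10% of the global density maximum to suppress ripple.

**Collinearity** re-implements block detection as greedy longest-first
extraction of monotone homolog chains per chromosome pair: ranks strictly
monotone on both genomes (either orientation), adjacent gaps ≤ `max_gap`
(default 10 ranks), chains shorter than `min_genes` (default 5) discarded.
Ties break deterministically toward the forward orientation and leftmost
start. This is simpler than dynamic-programming collinearity scoring but
recovers block structure exactly on the planted maps used here. Gene
ranks are 1-based; block intervals are inclusive. Syntenic depth of a
reference gene is the number of distinct query blocks whose
reference-side interval covers its rank; the modal depth over covered
genes summarises the multiplication level.

## Synthetic benchmark

The generators emulate the study design the pipeline was built for:

- **Expression**: an 8-point elicitation time course (0–240 h), treated
  ("CM") vs control ("CC"), 3 replicates, plus a 7-tissue panel.
  Pathway genes and the two bait diterpene synthases share one latent
  logistic induction trajectory (midpoint 24 h, scale 12 h) with
  gene-specific amplitudes around a 6-fold peak induction, multiplicative
  log-normal noise (σ = 0.25 on the log scale), and 8-fold dominance in
  root bark. Counts are integer-rounded log-normal draws — a convention,
  since no count model is implied by the design. All other genes are
  independent noise.
- **Metabolome**: target peaks lie inside the 295–400 Da window, carry
  fragments, track the same latent trajectory reaching a 3.6-fold
  treated/control ratio at the final time point, and are elevated in the
  focal tissue; decoys are flat noise split among out-of-window and
  fragmentless classes.
- **Protein families**: shared families mutate from common roots at
  85–92% member identity (cross-species identities comfortably above the
  55% cutoff); the planted specific subfamily descends from a root
  diverged to ~10 points below the cutoff; the tandem pair is duplicated
  at ≥ 97% (mutation counts floored so the realized identity never falls
  below the inclusive collapse threshold). Identity targets are met to
  ±1 point because substitution at k positions fixes point identity
  exactly and global alignment reproduces it at these similarity levels.
- **Paralog pairs**: per-site Jukes–Cantor evolution on both lineages
  from random stop-free ancestors; codons that would become stops are
  re-drawn, which trims a small fraction of (mostly nonsynonymous)
  changes — raw nucleotide differences sit a few percent below the
  unconstrained closed form 3/4·(1 − e^(−8rT/3)) while Ks, which counts
  synonymous changes, remains unbiased. The default plants two events
  (21 and 65 MYA) so the Ks distribution is bimodal like real paralog
  sets.
- **Triplicated map**: the query genome carries three copies of each
  reference chromosome with independent per-copy gene loss (default 40%)
  and occasional 3–10-gene local inversions.

A single top-level seed feeds named per-generator streams
(`numpy.random.SeedSequence` spawn keys), so identical configs give
byte-identical output files. What the benchmark does *not* emulate:
read-level sequencing noise, chromatogram/spectral artefacts, indels,
correlated decoy structure, or batch effects — so passing tests show the
pipeline's rules behave as specified on data matching its assumptions,
not that the thresholds are optimal for any particular real dataset.

## Funnel logic

Stage order: (1) network-linked CYPs; (2) expressed (RPKM > 1 in ≥ 1
sample); (3) union with species-specific CYPs that are induced or
focal-tissue-dominant (the "and/or" augmentation enters here, after the
expression floor); (4) DE at ≥ 1 configured time point or tissue
dominance, and Pearson *r* to a bait gene above the network cutoff —
"highly similar expression pattern" has no stated formula, so bait
similarity reuses the network's own *r* threshold; (5) user-supplied
exclusions, then near-duplicate collapse. Counts are monotone
non-increasing after the union stage. Ranking is by descending best *r*
to a target metabolite. The exact Boolean combination in stages 3–4 is
the package's own reading of a narrative procedure and every threshold is
config-overridable.

## Problem sizes and numerics

The bundled analyses run at desk scale by design: 500 pairs × 1,000
codons for clock recovery, a 3,000-gene/19-chromosome map for depth
recovery, 5,000 features for null calibration — sizes at which the
sampling error of each check is far smaller than its acceptance band.
NG86 codon-pair difference tables are precomputed once and cached.
Degenerate inputs (constant rows, zero variance, zero 4D sites, empty
networks) are handled by explicit flags or typed errors rather than NaN
propagation; boundary conventions (inclusive mass window, strict r and
identity cutoffs) are stated at each operation.

## Known limitations

- NG86+JC underestimates Ks relative to ML codon models as saturation
  grows; dates beyond ~75 MYA at the default rate should be treated as
  lower bounds.
- Greedy chain extraction can split one true block in pathological
  overlap configurations where an optimal scorer would not; planted-map
  tests bound this in practice.
- The pairwise-identity definition (terminal gaps excluded) differs from
  full-length identity for length-discordant pairs; coverage thresholds
  catch most such cases.
- The correlation network assumes aligned sample designs between
  expression and metabolite tables; it does not model replicate
  structure, time autocorrelation, or compositionality.
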