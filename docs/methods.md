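# Methods

This note documents the models, statistical procedures and numerical
choices behind `opsinevol`, what the synthetic-data generator does and
does not emulate, and the design decisions taken where more than one
defensible option existed.

## Selection summaries and likelihood-ratio tests

Site models are consumed as discrete site-class distributions: ordered
(ω, proportion) pairs with proportions summing to one (tolerance 1e-9).
The parser targets the PAML 4.x codeml dialect only — the `lnL` line,
the `dN/dS (w) for site classes` block for M7/M8/M8a and the
`w (dN/dS) for branches` line for branch models — and fails loudly on
anything else rather than guessing across codeml versions.

`discretize_beta(p, q, K)` builds the M7/M8 beta classes as the
conditional means of Beta(p, q) over K equal-probability quantile
intervals (computed from the regularized incomplete beta function), so
the weighted mean equals p/(p+q) exactly for every K. K defaults to 10,
the common codeml setting. Class means, not medians, are used.

The LRT is 2(ℓ_alt − ℓ_null) against χ²(df). For M8a vs M8 the true
null is on the boundary of the parameter space; the default is the
plain χ²₁ (conservative) with the 50:50 χ²₀:χ²₁ mixture available via
`mixture=True`. A negative statistic (an upstream optimiser artefact)
is clamped to zero with a warning.

## Clade comparison and the odd score

For two site-class distributions (bird ωB, mammal ωM), the comparison
statistic is p = Σᵢ Σⱼ pBᵢ pMⱼ [ωBᵢ > ωMⱼ]. Ties contribute nothing
under the default strict rule ("being higher"), or half their mass under
the optional midpoint rule. The bootstrap expectation E[p] draws
`n_draws` category pairs per replicate (default 1,000) over
`n_replicates` replicates (default 10,000; published analyses have used
both 10,000 and 100,000 — the count is a parameter, not an assertion)
and reports the replicate mean with its standard error. The odd score
(1 − p)/p is computed from E[p]; p = 0 maps to +∞.

The packaged table `data/opsin_siteclass_summary.tsv` carries the
published per-opsin mean ω, selection verdicts and E[p] values used by
the reproduction script; it is an input, not something the package
estimates.

## Counting dN/dS and ω-lineage

Codon-model maximum likelihood is deliberately out of scope: codeml is
the upstream tool and its outputs are parsed. For self-contained runs
the package provides the Nei–Gojobori (1986) counting estimator:
synonymous site counts are the per-position fractions of synonymous
single-nucleotide changes (changes creating a stop codon count as
nonsynonymous), differences are averaged over all orderings of the
changed positions with pathways through stop codons excluded, counts
are averaged over both sequences, and the Jukes–Cantor correction
−(3/4)·ln(1 − 4p/3) is applied. pS ≥ 3/4 makes dS undefined (NaN);
dS = 0 with dN > 0 flags ω = +∞; no substitutions at all flag ω
undefined. The estimator is exactly symmetric in its arguments. Note the
degenerate consequence: a single synonymous difference in a very short
sequence saturates pS and yields an undefined dS — short fragments need
context codons before the correction is meaningful. Being a counting
method with equal-rate site classification, it is also biased downward
under strong transition bias (κ ≫ 1); the test suite checks neutral
recovery at κ = 1 and regime recovery (±0.15) elsewhere.

ω-lineage — the foreground rate of one species' root-to-tip path — is
approximated by reconstructing the root sequence with one Fitch pass per
codon column (observed tip codons as the state alphabet; gap/ambiguous/
stop codons treated as missing; root ties broken toward the most
frequent tip codon, then lexicographically) and applying NG86 between
root and tip. Undefined or infinite ω propagates as a missing table
entry. All other branches are implicitly background.

## Pseudogene screen and site numbering

Internal stops are any TAA/TAG/TGA strictly before the final codon
column of the alignment. Indels are gap runs in the focal row relative
to a chosen reference row; length mod 3 ≠ 0 marks a frameshift,
otherwise an in-frame indel. Reference-anchored numbering (the
bovine-rhodopsin-style convention) comes from a bidirectional map
between 1-based alignment columns and 1-based ungapped reference
positions; reference gap columns map to nothing. Internally all indices
are 0-based half-open; conversion happens only at the I/O boundary.

## Fitch ancestral reconstruction

Single-site Fitch parsimony: bottom-up intersection/union sets with one
change counted per union, then a deterministic top-down pass (keep the
parent state when admissible, otherwise the lexicographically smallest
member). Tips without a state are wildcards by default (`missing=
"error"` to reject). The minimum change count is checked in tests
against Sankoff dynamic programming and, on small trees, full labelling
enumeration.

## Quartile categories and the co-evolution test

Per gene, species are classified against the gene's own 0.25/0.75
quantiles (numpy linear-interpolation convention) with strict
inequalities, so threshold values and constant genes are neutral; a
pooled-quantile mode exists but per-gene is the default. Genes with
fewer than 4 non-missing values are dropped. Under independence two
genes match categories with probability 0.25² + 0.25² + 0.5² = 6/16 =
0.375; each gene pair with at least `min_n = 15` jointly observed
lineages (the "fewer than 15 are excluded" reading; the floor is a
parameter) is tested one-sided against that null with the exact binomial
tail (default; a continuity-corrected normal approximation is
available). The Bonferroni divisor is the number of tests actually run,
never a hard-coded historical count; results carry both the corrected
verdict and an uncorrected p < α "strong" tier.

## VS/UVS classification and the logistic link

The default spectral rule is the minimal, well-supported site-90 rule
(C → UVS, S → VS in reference numbering); the full literature rule
tables are not reproduced here, so the rule set is user-extensible
config and every call reports the observed residues at sites 86/90/93
plus the basis of each call — no silent classification. Per-species
overrides always win (e.g. lineages whose published spectral class
contradicts the genomic rule).

The logistic model P(VS) = logit⁻¹(β0 + β1·ω) is fitted by ML
(statsmodels) with Wald inference, VS coded 1 so the linear predictor is
the VS log-odd score. Ordinary rather than phylogenetically corrected
regression is implemented — the tree-structured residual model is a
separate method — and the prediction interface accepts fixed
coefficients so published estimates remain directly evaluable. Complete
separation (including a response class with fewer than two members, and
solver failure on separable data) is flagged and no Wald p is reported;
a constant predictor short-circuits to the closed form β1 = 0,
β0 = logit of the VS fraction.

## Robust outlier map

Full ROBPCA (projection pursuit plus MCD reweighting) is replaced by a
deliberately reduced robust variant: columns are centered by medians and
scaled by normalized MAD (1.4826·MAD), the principal axes come from the
SVD of the standardized matrix, and each lineage gets a score distance
SDᵢ = √(Σⱼ tᵢⱼ²/λⱼ) with cutoff √χ²₍k,0.975₎ and an orthogonal distance
ODᵢ to the k-subspace with cutoff (m̂ + ŝ·z₀.₉₇₅)^{3/2} computed from
median/MAD estimates of the OD^{2/3} values (Wilson–Hilferty). k is the
smallest count explaining ≥ 90 % of robustly scaled variance unless
fixed. The diagnostic surface (SD/OD/flags) matches the full method;
the subspace itself is not projection-pursuit robust, which is
acceptable because the map is used only to flag lineages, and the
planted-outlier and null-calibration tests pin down that behaviour.
Because centering is by column medians, the "all OD = 0" property of
exactly low-rank data holds for subspaces through the robust center.
Zero-MAD (constant) columns are rejected rather than silently rescaled.
Missing entries are handled upstream: genes under 50 % observed are
dropped, the rest gene-median imputed (or incomplete genes dropped),
with every imputed cell recorded.

## Synthetic data: what it emulates, and what not

The generator reproduces the *shape* and *controlled ground truth* of a
comparative avian dataset, not avian realism:

- **Species tree**: Yule (pure birth) via DendroPy, tips relabelled
  `sp01…`, branch lengths rescaled so the root-to-tip height is 0.3
  substitutions/site by default — a realistic within-class divergence.
  Default panel size 48 species.
- **Codon alignments**: an M0-style codon process — single-nucleotide
  steps at rate π(target)·κ^[transition]·ω^[nonsynonymous], nucleotide
  frequencies set by a target GC fraction, stop codons masked out of the
  state space — simulated per site and branch by a Gillespie scheme from
  a stationary root sequence, with rates normalized so one branch-length
  unit is one expected substitution per nucleotide site. Defaults:
  500 codons (opsin-scale), κ = 4, ω = 0.2 (gene-wide purifying
  regime), GC = 0.5. No indel process, no among-site rate variation, no
  heterotachy, no realistic avian base composition — planted features
  (stops, deletions) are injected explicitly and returned as ground
  truth.
- **ω-lineage tables**: per species a latent A/C/N category with
  probabilities (0.25, 0.25, 0.5); a gene pair coupled at strength ρ
  copies categories with probability ρ, giving matching probability
  ρ + (1 − ρ)·6/16 — exactly 0.375 at ρ = 0 and 1 at ρ = 1. ω values
  are drawn uniformly inside the category's band of the gene's value
  range so quartile categorization recovers the latent truth up to
  sampling noise at the band edges. Missingness is independent
  Bernoulli (default 0.1).
- **Traits**: VS with probability logit⁻¹(β0 + β1·ω), defaults
  (4.44, −79.91) — the published coefficient scale. Note that the trait
  seed must differ from the seed that generated the ω values themselves;
  reusing one seed reuses the underlying uniform stream and produces
  artificially separable data (the test suite and examples use distinct
  seeds).

Consequently, passing tests demonstrate internal correctness and
statistical calibration under these idealized conditions; they do not
demonstrate robustness to alignment error, assembly artefacts, indel
evolution or base-composition heterogeneity in real genomes.

## Problem sizes and determinism

Every stochastic routine takes an explicit integer seed and is
byte-deterministic under it. The test suite and the reproduction script
use desk-scale sizes chosen to make the statistical checks sharp while
staying light: 10,000 lineages for the independence null (±0.015),
10,000 bootstrap replicates for exact-vs-bootstrap agreement (4·SE),
3,000 codons for estimator-recovery checks (±0.15), 200 replicates of
n = 500 for logistic CI coverage (≥ 90 %), 300–400 replicates for
type-I-error calibration of the co-evolution scan, and 1,000 replicates
for the Gaussian null of the outlier map.

## Known limitations

- NG86 is a stand-in, not a substitute for codon ML: it is biased under
  strong transition bias and high divergence, and undefined on nearly
  identical or saturated sequences.
- The Fitch root reconstruction ignores branch lengths; on very
  asymmetric trees the implied foreground path can differ from a
  likelihood reconstruction.
- The outlier map's subspace is robust only through median/MAD
  standardization (see above).
- The spectral rule table ships with the site-90 core rule only;
  comprehensive classification requires user-supplied rules or
  overrides.
- Insertions cannot be planted by the pseudogene injector (deletions
  only); insertion *detection* relative to a reference row is supported.
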