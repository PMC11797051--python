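# Methods

This note documents the statistical procedures implemented in
`ecoassembly`, the generative model behind the synthetic experiments, the
numerical conventions, and the design choices that were genuinely open.

## Table QC and normalization

The pipeline applies three filters in a fixed order, then normalizes:

1. **Negative-control exclusion** (`subtract_control_asvs`). Any taxon with
   reads in the negative controls is removed, *unless* its reads summed over
   all controls are below `control_read_cap` (default 4) **and** its mean
   relative abundance across biological samples is at least
   `abundance_floor` (default 0.1 %). The exception protects genuinely
   abundant community members from being discarded over trace
   cross-contamination. Two readings of the control threshold are possible
   (per control sample or summed over controls); we sum, which is the
   stricter exclusion. "Abundant" has no standard numeric definition; mean
   relative abundance with an explicit floor keeps it a single transparent
   parameter.
2. **Curated drop-list** (`drop_taxa`) for known artefacts such as amplified
   host genes, supplied by taxon id — these cannot be detected from counts.
3. **Low-abundance filter** (`filter_min_reads`). "Fewer than *t* reads in
   all samples" is ambiguous. The default mode `total` removes taxa whose
   count summed across samples is below *t* (the reading recommended by the
   USEARCH documentation for zOTU tables, *t* = 8); `per_sample_max`
   (maximum single-sample count below *t*) is available as a flag. The two
   coincide whenever a taxon's reads are concentrated in one sample.

**Normalization** (`normalize_scaling`) performs total-sum scaling to a
common depth (default 11 000 reads, the smallest per-sample total in the
emulated study): counts are converted to per-sample fractions, multiplied
by the depth, and rounded half-up (banker's rounding available). Column
sums are deliberately *not* repaired to the exact depth afterwards; the
deviation is bounded by ceil(n_taxa/2) and in practice is a few reads.
Rarefaction (subsampling without replacement) is not implemented because
the workflow this package mirrors used scaling.

## Diversity

* Richness *S* is the count of taxa with nonzero reads. Chao1 uses the
  bias-corrected form S + F₁(F₁−1)/(2(F₂+1)) (F₁ singletons, F₂
  doubletons), which is defined even when F₂ = 0; the classic form is a
  flag. Shannon entropy uses natural log; the order-1 Hill number e^H is
  reported so that a uniform community of S taxa scores exactly S, and
  evenness is e^H/S ∈ (0, 1].
* Bray–Curtis is computed on the normalized counts via
  `scipy.spatial.distance.pdist`. Internally everything is a
  *dissimilarity*; reporting layers convert to similarity (1 − d) where a
  similarity framing is conventional. Two all-zero samples have no defined
  dissimilarity and are rejected during validation.
* PCoA is classical metric scaling: eigendecomposition of the
  double-centred −½D². Negative eigenvalues (non-Euclidean input such as
  Bray–Curtis) are reported as-is with zero coordinates and zero
  proportion explained — never silently clipped — and the Lingoes additive
  correction is available. Proportions explained are computed over the
  positive eigenvalues only.
* One-way PERMANOVA uses the pseudo-F from within/between sums of squared
  distances with free permutation of sample labels (no strata), a seeded
  generator, and p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm). All
  permutations are evaluated as one vectorised batch, which makes the
  1000-replicate type-I calibration run in seconds. Restricted (per-flask)
  permutation would be a scientifically stricter alternative for nested
  designs; it is noted here, not implemented, to match the one-way design
  analysed.
* SIMPER averages per-taxon contributions |xₜ−yₜ|/Σₖ(xₖ+yₖ) over all
  between-group sample pairs; per pair these sum exactly to the pair's
  Bray–Curtis dissimilarity, so the table decomposes the average
  between-group dissimilarity. Percent contributions sum to 100.
* `compare_groups` records the standard decision path: Shapiro–Wilk on both
  groups (α = 0.05); non-normality in either → Wilcoxon rank-sum
  (Mann–Whitney); otherwise a two-sided F-test of variances decides between
  Welch's and Student's t-test. The chosen test, statistic, p-value, and
  the intermediate p-values are all returned.

## Phylogenetic machinery

Trees are Newick with branch lengths (scikit-bio `TreeNode`); construction
of the tree itself (alignment, NJ/ML) is upstream of this package.
`root_longest_branch` re-roots at the midpoint of the longest branch,
breaking ties deterministically by preorder position (logged); rooting
never changes cophenetic distances, which is asserted in tests against a
Dijkstra shortest-path oracle. `cophenetic` is the tip-to-tip path-length
matrix.

The null models assume phylogenetic signal in the niche: closely related
taxa should have similar ecology. `mantel_correlogram` quantifies this by
binning phylogenetic distances into equal-width classes (Sturges' rule by
default) and correlating niche distances with the within-class indicator,
sign-flipped so that positive r at short distances means related taxa are
ecologically similar. p-values come from whole-matrix taxon permutations
(two-tailed) with progressive Holm correction across classes (class k is
Holm-adjusted among classes 1..k). Because the niche variable fed to the
correlogram is analysis-specific, two proxies are provided: the
abundance-weighted mean of a per-sample score (natural when an
environmental value per sample is known, e.g. synthetic data), and the
distance between per-taxon relative-abundance profiles.

## Null models (NTI, βNTI)

The null model is the *taxa-labels shuffle*: taxon labels are permuted
across the tips of the phylogeny — equivalently, rows/columns of the
cophenetic matrix are relabelled — while community membership and
abundances stay fixed. One permutation per run is applied to all
communities simultaneously.

* **NTI.** MNTD of each sample is recomputed under `runs` permutations
  (default 999) restricted to the null pool; NTI = −(obs − mean)/sd, so
  clustering gives positive NTI. Unweighted MNTD is the default (weights
  are a flag); the pool defaults to all taxa present in the analysed table
  — the single-metacommunity reading, appropriate when all samples derive
  from one source community.
* **βNTI.** βMNTD = ½[Σₜ wₜ min_u d(t,u) + Σᵤ wᵤ min_t d(u,t)], t over taxa
  of one sample, u over the other; a shared taxon finds itself at distance
  zero. Abundance weighting is the default. βNTI = (obs − mean)/sd with the
  same shuffle null, one shuffle shared by all pairs per run (which is also
  what makes the computation fast). Classification: > 2 heterogeneous
  selection, < −2 homogeneous selection, boundary values ±2 inclusive are
  stochastic, non-finite undefined.
* **Degenerate nulls.** If every permutation yields the same statistic
  (e.g. a sample containing the whole pool, or two identical samples —
  every shared taxon is shared under any relabelling), the null sd is zero
  and the index is reported as undefined with a diagnostic, never as ±∞.
  A tolerance guard treats pure floating-point spread as zero. A
  consequence worth stating: *two identical samples have undefined βNTI*
  under this null, because no permutation can change their βMNTD from
  zero; near-identical samples (a little unique membership each) are the
  ones that score strongly negative.
* **Exhaustive mode.** For pools of ≤ 8 taxa, `runs="exhaustive"`
  enumerates all pool permutations and returns the exact null mean and
  (population) sd; the sampled mode is tested to agree within Monte-Carlo
  error, and the exhaustive mode to agree exactly with an independent
  enumeration oracle.
* **Null pools.** For per-group βNTI runs the pool can be the group's own
  taxa or the whole table. The pipeline default is the whole filtered table
  (single metacommunity): at a desk-scale pool of ~200 taxa, a per-group
  pool under strong selection nearly coincides with the selected guild
  itself, leaving the shuffle null no room and pushing every comparison
  toward "stochastic" for lack of contrast. With thousands of ASVs this
  distinction matters much less.

Sign conventions follow the field: the standardized effect size of MNTD is
negated for NTI (clustered ⇒ positive), but βNTI keeps the raw z-score sign
(clustered pair ⇒ negative).

## Synthetic experiments

`generate_experiment` emulates a flask-rearing amplicon study:
2 water treatments × 2 host strains × 4 flasks, 4 gut samples and 1
rearing-water sample per flask (64 guts, 16 rearing-water), added-water
samples on days 14/16/18/21 per treatment, 2 negative controls, and 11 000
multinomial reads per sample. Sampling weights for one community are

    p_t ∝ m_t · n_t · o_t · f(t)

* `m` — lognormal metacommunity profile (log-sd 0.75), shared by all
  samples;
* `n` — per-sample lognormal drift noise (log-sd 1.0), the "lottery"
  component that makes replicate individuals diverge;
* `o` — per-sample Bernoulli occupancy mask (p = 0.5), founder effects: a
  taxon may simply never have reached this individual. This is what gives
  samples presence-level turnover at any sequencing depth;
* `f` — the niche filter. Under selection, `f` is a Gaussian in
  *cophenetic distance to a focal ecotype tip*, truncated to zero beyond a
  hard washout radius; the radius is the distance to the focal tip's
  `guild_size`-th neighbour (default 40) and the Gaussian width is half the
  radius. Under the neutral scenario `f ≡ 1` (the σ → ∞ limit).

Scenarios: **homogeneous selection** — one focal ecotype (the tip with the
densest guild, a deterministic function of the tree) filters every flask
sample; **heterogeneous selection** — the two water treatments are filtered
toward two distant focal ecotypes (the second is the densest guild among
the half of tips farthest from the first); **neutral** — no filter.
Added-water samples are always drawn without selection: they represent the
source water sampled *before* it enters the flasks, and they keep the
dataset-wide taxon pool broader than any selected guild. Negative controls
contain a few contaminant taxa at 0–3 reads, below the default QC cap, to
exercise the control filter.

Why a phylogenetic guild rather than a Brownian trait band: with 200 taxa
on a Yule tree, a single Brownian trait correlates only weakly with the
tree at the tip scale (Mantel r ≈ 0.1 in our checks), so a band of trait
space is phylogenetically diffuse and neither NTI nor βNTI can recover
selection reliably. Defining the niche directly as proximity to a focal
ecotype makes niche conservatism exact — which is the regime the null
models are designed to detect — while Brownian traits remain available
(`evolve_trait_bm`) for phylogenetic-signal analyses. The hard washout edge
models flow-through flasks in which maladapted lineages cannot persist at
all; without it, deep-tail multinomial sampling at depth 11 000 re-admits
every taxon and saturates presence.

Parameter defaults and what they trade off: the metacommunity log-sd is
milder than in large real surveys because, with only 200 taxa, heavier
dominance concentrates the abundance-weighted βMNTD on a handful of taxa
and inflates the null sd (weakening all βNTI signals); occupancy 0.5 and
noise log-sd 1.0 together give per-sample richness of roughly 15–30 under
selection and ~60–80 neutrally, with strong between-individual turnover, a
scaled-down version of the high inter-individual variability typical of
larval-fish gut microbiomes. All randomness flows from a single master
seed through `numpy` seed sequences; identical configs reproduce
byte-identical outputs.

What passing the recovery tests does and does not show: the generator
produces clustered, turnover-rich communities whose assembly process is
known, and the pipeline's classification agrees with that truth. Real
amplicon data add features the generator does not emulate — compositional
noise from PCR/sequencing, taxonomy-dependent copy-number variation,
chimeras and contamination beyond trace levels, non-Gaussian niches, and
phylogenies estimated with error — so recovery here validates the
statistics, not the wet-lab pipeline upstream of them.

## Numerical conventions

* Half-up rounding in normalization is floor(x + 0.5), applied to
  nonnegative values only.
* Eigenvalues within 1e-10 of zero (relative to the leading eigenvalue)
  are treated as zero when scaling PCoA coordinates.
* Permutation p-values always include the observed statistic:
  (1 + #extreme) / (1 + runs), so p ∈ [1/(runs+1), 1].
* Sampled null sds use ddof = 1; exhaustive (complete-population) nulls use
  ddof = 0.
* Ties for the longest branch during rooting are broken by preorder
  position and logged.
* Seeds derived inside the pipeline are `seed * 1000 + offset` reduced mod
  2³¹ − 1, so distinct stages never share a stream.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full study design
(200 taxa, 88 samples, depth 11 000) with 199 null runs for the recovery
checks and 999 elsewhere, 10 master seeds per scenario in the suite and 3
in the acceptance script, and a 1000-replicate × 999-permutation PERMANOVA
calibration. These sizes were chosen so the whole suite completes in a few
minutes on one CPU while keeping Monte-Carlo error well below the decision
thresholds being tested.

## Known limitations

* RCbray-based splitting of the stochastic fraction (dispersal limitation
  vs homogenizing dispersal vs drift) is not implemented; comparisons are
  partitioned into selection vs stochastic only.
* PERMANOVA permutes freely; flask-level restricted permutation is not
  available.
* The Mantel correlogram's niche variable is a proxy chosen by the analyst;
  both provided proxies are imperfect stand-ins for measured traits.
* Tree inference and read processing (merging, denoising, taxonomy) are out
  of scope; the package consumes a finished count table and Newick tree.
* UniFrac, rarefaction curves and differential-abundance testing are
  deliberately absent.
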