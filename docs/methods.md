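# Methods

## Study design and data model

The package targets a three-cohort observational design — healthy controls
(Ctrl, n = 17), liver cirrhosis (LC, n = 18) and hepatocellular carcinoma
(HCC, n = 10) — measured on four omics layers: gut bacterial genera and gut
viral species as sequencing count tables, and plasma metabolites and
cytokines/chemokines as continuous concentration tables. A
`FeatureTable` is a nonnegative features × samples matrix tagged with its
layer and value semantics (`counts`, `relative_abundance`,
`concentration`); a `MultiOmicsDataset` is a set of layers sharing one
ordered sample set plus cohort metadata. All tables travel as
tab-separated UTF-8 text. Count layers are converted to relative
abundances per sample and filtered to features whose mean relative
abundance across all samples strictly exceeds 0.01 % (`1e-4`) before any
statistics; whether that mean should instead be taken within cohorts is
genuinely ambiguous in this design, so the across-all-samples reading is
the default and a per-cohort option exists.

## Differential screening

Each feature is tested across cohorts with the tie-corrected
Kruskal–Wallis statistic (p from the χ² approximation with k − 1 df; the
cohort sizes here make exact enumeration pointless, and a permutation
oracle lives in the test suite instead). Features with p < α proceed to
Dunn's post hoc test: pairwise *z* statistics on the pooled ranks,

z_jk = (R̄_j − R̄_k) / √{[N(N+1)/12 − Σ(t³−t)/(12(N−1))] (1/n_j + 1/n_k)},

with two-sided normal p-values adjusted across the three pairs. The
adjustment defaults to Benjamini–Hochberg with Bonferroni and Holm
options; the underlying study design reports only "adjusted p" without
naming a method, so this is an explicit package choice. A feature is
*significant* when the Kruskal–Wallis p is below α **and** at least one
Dunn pair survives adjustment; its *enriched group* is the cohort with the
maximal mean on the analysed scale (medians by flag). When every pooled
observation is identical the rank tests carry no information and (H, p) =
(0, 1) is returned rather than an error.

Summary-statistic utilities reproduce clinical characteristics tables
exactly from printed numbers: a pooled-variance two-sample *t*-test from
(mean, SD, n) per group, a 2×2 χ² test with optional Yates correction,
and a Mann–Whitney test that switches to exact enumeration when both
sides have ≤ 8 observations and no cross-sample ties. Of the packaged
characteristics rows, the pooled *t*-test reproduces the printed p-value
at 3-decimal rounding for 15 of 19 rows; the remaining four (BMI LC–HCC,
HbA1c, platelet count, Child–Pugh score) were evidently compared with a
different routing (Welch or rank-based) in the original analysis and are
reported without assertion.

## Diversity

Alpha diversity uses the amplicon-toolchain conventions: Shannon entropy
in natural log, Simpson as Gini–Simpson (1 − Σp²; inverse and dominance
variants by flag), Chao1 in the bias-corrected form S_obs +
F1(F1−1)/(2(F2+1)) (classic form by flag; it is undefined at F2 = 0), and
ACE with rare-species cutoff 10. ACE degenerate cases are handled
explicitly: if all rare species are singletons the coverage C is zero and
the function falls back to bias-corrected Chao1 with a warning; with at
most one rare individual it returns the observed richness. No rarefaction
is applied before alpha diversity; a seeded `rarefy` utility exists but is
never called implicitly.

Beta diversity is Bray–Curtis on relative abundances, embedded by
classical PCoA (Gower centering of −½d², eigendecomposition, coordinates
scaled by √λ). Bray–Curtis is not Euclidean-embeddable in general, so
negative eigenvalues are reported but never embedded, and explained
fractions are computed over positive eigenvalues only. Group separation
is tested with PERMANOVA (pseudo-F on squared distances, p = (1 +
#{F_perm ≥ F_obs})/(1 + n_perm), 999 permutations by default); the method
that produced the original ordination significance claims is unnamed, so
PERMANOVA is the package's explicit stand-in. Venn overlap counts use a
configurable presence rule, by default a nonzero count in at least one
sample of the cohort, and report all region counts plus "shared X of Y"
pair summaries.

## LDA effect-size scoring

The biomarker score is a from-scratch implementation of the familiar
LEfSe recipe. Samples are scaled to a total of 10⁶ so scores land on the
log₁₀ range where the conventional "score ≥ 3" cutoff is meaningful.
Features failing the Kruskal–Wallis filter at α = 0.05 never receive a
score. For each of 30 bootstrap rounds, two-thirds of each class is
subsampled and a linear discriminant is fitted (the axis scaled to unit
within-class variance); a feature's effect size blends its raw
between-class mean difference d with its coefficient-weighted displacement
along the axis, 0.5·(|d| + |w·d|), reported as log₁₀(1 + effect) and
averaged over rounds. The exact blend mirrors the reference tool's
convention and is a compatibility choice, not a derived statistic. The
within-class (subclass) consistency stage is a no-op for plain cohort
labels. With three classes the default strategy scores each feature's
winning class one-against-all; an all-against-all flag scores the extreme
class pair instead.

## Joint correlation networks and signatures

Candidates are the union of screen-significant features across the four
layers, recomputed within each subject subset (all subjects, Ctrl–LC,
Ctrl–HCC, LC–HCC; two-cohort subsets reduce the screen to a two-group rank
test). All candidate pairs are correlated with Pearson's r and the
two-sided p from t = r√(n−2)/√(1−r²); a constant vector makes the
correlation *missing*, not zero. Edges require unadjusted p < 0.05 (no
multiplicity correction, matching common practice in these reports; a
BH-adjusted option exists) and optionally |r| ≥ r_min. Correlations run on
the analysed scale by default, with a log10(x + pseudocount) option for
abundance layers. Endotoxin, zonulin and TMAO-style barrier markers are
not network nodes; the four layers are.

"The network centered on X" is formalised as the radius-1 ego graph
(star) of X. The composition filter keeps stars whose layer coverage has
at least four layers, with the center's own layer counting toward
coverage by default (a center-exclusive reading is available by flag).
Membership of a center across the four subset analyses is then classified
in rule order: both disease contrasts → **Common**; Ctrl–LC only → **LC
specific**; Ctrl–HCC only → **HCC specific**; all-subjects only →
**Common*** (the weaker, direction-based class) when the control mean is
strictly the extreme of the three cohort means with both disease cohorts
on the same side, otherwise unclassified. Presence in the LC–HCC network
is an orthogonal severity flag. The Common rule deliberately does not
require the all-subjects flag: no observed flag pattern distinguishes the
two readings, and the permissive one is simpler. The packaged 39-center
membership table reproduces every printed label and severity flag under
these rules. How the original analysis chose which qualifying stars to
highlight (exactly 12 or 21 per subset) is not derivable from the text,
so no count-level reproduction is claimed on real data.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not raw reads or assay physics. Count layers draw, per sample, a
composition from a Dirichlet over per-feature base concentrations and
counts from a multinomial at a fixed depth (default 70 000, the order of
cleaned read counts in such studies); cohort effects multiply the
Dirichlet concentration (1 = null). Concentration layers draw independent
normals per feature (means and SDs settable; log-normal means with
coefficient of variation 0.6 by default, matching the large relative SDs
of plasma panels), truncated at zero — truncation rather than resampling,
because published cohort tables contain means near zero with SDs larger
than the mean; the truncated fraction is logged in the truth record.
Cohort effects are additive on the mean (0 = null). Cross-layer
dependence is planted as latent-factor stars: one Gaussian factor per
star with signed loadings in [−1, 1], entering count layers on the log
scale (multiplying the Dirichlet concentration by e^{loading·z}) and
concentration layers linearly in units of the feature's noise SD, so a
loading is a comparable effect size across layers. All draws flow through
a single seeded `numpy` generator; equal (spec, seed) gives byte-identical
output.

`demo_spec` fixes the study conditions used throughout the tests and the
acceptance script: 20/20/15/12 features per layer, symmetric Dirichlet
concentration 5 per count feature, an 8-fold concentration shift for
shifted count features, a 2.5-SD additive shift for shifted concentration
features, star loadings 0.9 and latent SD 1.0. One star's members are
shifted in both disease cohorts (a shared-disease signature), the other's
only in LC. These magnitudes produce cohort separations of the size the
published group tables display; they are a modelling choice, not an
estimate of any real effect size.

What the generator does *not* emulate: sequencing error, taxonomic
misassignment, compositional bias between layers, batch effects, covariate
structure (age, BMI, etc.), or heavy-tailed concentration distributions.
Passing recovery tests therefore show the pipeline is correct and
well-calibrated under its own assumptions, not that real cohorts of this
size would yield stable networks. One realistic artefact the generator
*does* reproduce is compositional closure: a strongly shifted taxon
depresses the relative abundance of every other taxon in that cohort, so
planted signals recruit "passenger" features into the screen and the
networks — visible in the worked example's report. Recovery is therefore
validated as recall of planted centers, not as specificity against
closure-induced stars.

## Numerical choices and problem sizes

- Strict inequality in the 0.01 % abundance filter.
- Kruskal–Wallis degenerate input (all values equal) returns (0, 1); the
  same convention applies to Dunn pairs with no rank variance and to the
  summary t-test with two zero-SD groups and equal means.
- PCoA treats eigenvalues below max(λ)·1e−12 as zero.
- PERMANOVA with zero within-group variance returns F = ∞ (p at the
  permutation floor) or 0 for an all-zero matrix.
- The permutation p convention (1 + hits)/(1 + n_perm) never returns 0;
  with balanced two-group designs the label-swapped permutation duplicates
  the observed partition, so the attainable floor is 2/(1 + n_perm).
- Edge lists store each unordered pair once, in canonical feature order;
  star extraction is order-invariant.
- Test and acceptance simulations use a sequencing depth of 5 000 and the
  `demo_spec` layer sizes: the Dirichlet, not the multinomial, dominates
  the sampling variance at these depths, so conclusions match the 70 000
  default while the suite stays fast. Null-calibration checks use 1 500
  features; planted-recovery checks use 50 seeds (20 for the full
  end-to-end label recovery).

## Known limitations

- UniFrac distances are out of scope (no phylogeny in this design), as are
  read-level processing, cladograms and heatmap rendering.
- LDA scores on three classes depend on the chosen strategy near the
  score threshold; only the two-class behaviour is anchored by planted
  recovery tests.
- The χ² approximation for Kruskal–Wallis is inaccurate deep in the tail
  at these sample sizes (an extreme three-group separation has exact
  permutation p ≈ 0.004 but χ² p ≈ 0.027); screening decisions at α = 0.05
  are unaffected, which is what the permutation cross-check asserts.
- Correlation networks are pairwise Pearson only: no partial correlations
  or graphical-model estimation, and abundance–abundance correlations on
  the relative scale inherit compositional coupling.
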