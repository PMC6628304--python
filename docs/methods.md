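# Methods

## The diallel model

A half diallel with selfs crosses `p` parents in all unordered pairs,
giving `g = p(p+1)/2` genotype entries (p parents + p(p-1)/2 F1 hybrids)
grown in `b` complete blocks. The phenotype model behind both the
simulator and the estimators is

```
y_ijk = mu + beta_k + g_i + g_j + s_ij + e_ijk        (i < j, hybrid)
y_iik = mu + beta_k + 2 g_i + s_ii + e_iik            (self / parent)
```

with block effects `beta_k ~ N(0, sigma2_block)`, residuals
`e ~ N(0, sigma2_e)`, GCA effects `g` and SCA effects `s`. The factor 2 on
the self entries is what makes Griffing's Method 2 estimators consistent:
a parent expresses its general combining ability through both gametes.

Estimation is fixed-effects (Model 1): the closed-form estimators in the
README are the least-squares solution on the `g` distinct entry means
under the constraint `sum(g_i) = 0`, which we verified is exactly the
sequential projection onto {intercept} ⊂ {intercept + additive} ⊂
{saturated}. Two identities follow and are enforced in tests at machine
precision: the fit is saturated (`mu + g_i + g_j + s_ij = x_ij` cell by
cell) and the ANOVA partition is exact (`SS_genotype = SS_GCA + SS_SCA`).

Combining-ability sums of squares are computed from entry means and then
multiplied by `b`, so GCA/SCA mean squares share the per-plot scale of the
RCBD error mean square; consequently the genotype MS equals the
df-weighted combination of the GCA and SCA MS. F-tests use the error MS
as denominator (no random-model synthesis), with df `(p-1)`, `p(p-1)/2`
and `(b-1)(g-1)`.

Standard errors come from the effects being fixed linear combinations of
the independent entry means (variance `MS_error/b` each); the package
computes the coefficient vectors explicitly, which reproduces the
classical closed forms (e.g. `Var(g_i) = (p-1)/(p(p+2)) · MS_error/b`).
Two-sided t-tests use the error df; stars mark 0.05/0.01/0.001.

## Derived summary statistics

**Baker ratio.** Computed from mean squares,
`2 MS_GCA / (2 MS_GCA + MS_SCA)`, the form under which the package's
recomputed values agree with published combining-ability tables at the
printed precision. A variance-component variant (`mode="varcomp"`) is
provided because the ratio is sometimes defined on that scale; the two do
not coincide in general.

**Variance components (method of moments).** With per-plot-scale mean
squares and the generative model above (centred GCA draws, i.i.d. SCA
draws), the expected mean squares are exactly

```
E[MS_error] = sigma2_e
E[MS_SCA]   = sigma2_e + b·sigma2_s
E[MS_GCA]   = sigma2_e + b·sigma2_s + b(p+2)·sigma2_g
```

(the `b(p+2)` coefficient was verified both algebraically via projection
traces and by Monte Carlo). Inverting this triangular system gives
unbiased estimators; the test suite checks recovery within 5% over 500
simulated trials at p = 10, b = 3.

**Heritabilities.** Conventions for diallel heritabilities differ between
software packages. We use `var_g = (MS_GCA − MS_SCA)/(p+2)`,
`var_s = MS_SCA − MS_error`, `var_e = MS_error` and

```
h2_narrow = 2 var_g / (2 var_g + var_s + var_e)
h2_broad  = (2 var_g + var_s) / (2 var_g + var_s + var_e)
```

with negative component estimates truncated at zero (warning). Note the
`var_s` here is on the per-plot MS scale (no division by `b`), matching
the convention of widely used diallel-ANOVA software; it differs from the
method-of-moments `sigma2_s` above, which is the generative-model scale.

**Heterosis significance.** The test of `F1 − MP` uses
`Var(F1 − MP) = (3/2)·MS_error/b` (an entry mean has variance
`MS_error/b`; the contrast has coefficient norm `1 + 1/4 + 1/4`), with the
ANOVA error df. This is a convention — heterosis testing procedures vary —
and is labelled as such in the output.

## Browning traits

`CD` is the three-term Euclidean (ΔE-style) distance between the 0-min and
10-min CIELAB readings. `DW` is the distance of the 0-min reading from the
nominal white point (100, 0, 0); a measured white tile could be
substituted but is not modelled. `DB` uses the `lightness_drop` convention
`L*_0 − L*_10` (browning darkens the flesh); it is the only convention
implemented, named explicitly in the API so alternatives can be added
without ambiguity, and satisfies `|DB| = CD` whenever only lightness
moves. PPO activity is the OLS slope of A420 over all supplied time
points, divided by 0.1 and the sample's dry mass; negative slopes are
reported, not clamped, so assay drift remains visible.

## Correlations and path analysis

Correlations are pairwise-complete Pearson over genotype-entry means
(parents and hybrids together, 55 rows at the default design), with exact
t-based p-values on n−2 df. Path analysis is the classical
correlation-matrix formulation: direct effects solve `R_xx P = r_xy`, and
are identical to standardized multiple-regression coefficients (asserted
against an independent least-squares oracle). We deliberately do not fit
latent-variable structural models; the direct/indirect vocabulary here is
the textbook path-analysis one. A condition-number guard (default 1e6)
rejects near-singular predictor sets naming the most collinear pair,
rather than silently pseudo-inverting — relevant because flesh-colour
trait panels routinely contain |r| ≈ 0.9 pairs.

## Genetic distances and dendrograms

Per-locus IBS between diploid calls x, y ∈ {0,1,2} is the shared-allele
fraction `1 − |x−y|/2`; pair IBS averages over loci where both calls are
present, and `GD = 1 − IBS`. A strict-match variant (IBS = 1 iff identical
call) is selectable; the shared-allele form is the default because it is
the convention of standard SNP toolkits. The distance is invariant to
marker order and to per-marker allele-coding flips (0↔2), both asserted by
randomized tests.

UPGMA is implemented in-package rather than via a generic linkage routine
because its tie-breaking is part of the contract: among equal-distance
cluster pairs the lexicographically smallest label pair merges first, and
each merge puts the cluster with the smaller minimal label on the left.
This makes trees — and their Newick serialization and leaf orders —
byte-reproducible across runs and platforms. Correctness is checked
against a brute-force reference that recomputes every cluster distance
from the original matrix (average linkage's defining property) on ~1000
random integer matrices up to p = 7.

Entanglement between two dendrograms on the same leaves is the L-norm
(default L = 1.5, the common tanglegram default) of leaf-rank differences
normalized by the fully-reversed worst case: 0 = identical order, 1 =
reversed. By default it is computed on as-built leaf orders; an exhaustive
rotation search over the second tree's internal-node flips (feasible for
the ≤ 12 internal nodes of a parent-scale tree) gives the rotation-minimal
value.

## The synthetic-data generator

The generator's defaults emulate a 10-parent eggplant half diallel in
three blocks (nine cultivated accessions plus the wild relative INS2) for
eleven traits: dry matter, total phenolics, chlorogenic acid (CGA), CGA
chromatogram area %, L*0, a*0, b*0, DW0, PPO, DB, CD. The per-trait
variance components in `config.DEFAULT_TRAIT_PARAMS` were set once to
give the additive-dominant structure characteristic of such trials —
GCA-attributable variance exceeding SCA variance for every trait (Baker
ratios ≳ 0.8), residual noise of the same order as SCA variance, and weak
block effects — with trait means on their natural scales (e.g. dry matter
≈ 9.5%, L*0 ≈ 81).

True GCA vectors are drawn i.i.d. normal and centred to sum exactly to
zero; true SCA matrices are symmetric i.i.d. draws left uncentred, because
Griffing's estimates are defined only up to the identifiability
constraints — recovery tests therefore compare estimates to the
least-squares projection of the truth (equivalently, rely on the
saturated-fit and EMS identities), not to the raw draws.

The SNP simulator uses an ancestral-flip model: each marker gets an
ancestral allele, flipped independently per parent with rate `eps_a`, so
two parents mismatch with probability `eps_a + eps_b − 2 eps_a eps_b`.
Scalar targets have a closed-form rate (attainable up to 0.5 — a binary
model cannot make *all* pairs more than 50% divergent simultaneously);
matrix targets are fitted by bounded least squares and are matched exactly
when they have the model's rank structure (e.g. the default
cultivated-vs-wild block pattern). Calls are homozygous 0/2 with
missingness applied independently; heterozygous calls appear in real RAD
data but are not generated, which the IBS tests cover separately with
hand-built matrices. There is no linkage disequilibrium and no coupling
between the SNP and trait simulators — marker-trait association is
explicitly out of scope, so passing tests say nothing about
genotype-phenotype prediction on real data.

The colour-kinetics generator draws a latent baseline colour per genotype
entry and applies a fixed browning drift plus measurement noise per plot;
it emulates paired-readings structure (within-entry correlation between
t=0 and t=10), not the biochemical kinetics of browning.

Plots are simulated at replication level (one observation per entry per
block), matching the error degrees of freedom `(b−1)(g−1)` of the target
ANOVA layout; per-fruit subsampling within a replication is not modelled.
All generators take explicit seeds; the pipeline derives per-stage
substreams by hashing `(seed, stage)` so adding or reordering traits does
not shift other streams.

## Numerical choices and scale of validation

Zero-variance data yield SS = 0 and NaN F-statistics (not errors);
missing plots are a hard error listing the offending cells (no
missing-value augmentation — the design is assumed complete). Monte-Carlo
test sizes (500 seeds for variance-component recovery, 1000 replicates for
correlation calibration, ~1000 matrices for the UPGMA oracle) were chosen
so each suite runs in seconds while leaving at least 3–4 standard errors
of margin at the asserted tolerances.

## Known limitations

Only Griffing Method 2 / Model 1 is implemented (no reciprocals, no
random-effects inference, no Hayman analysis). Heritability conventions
other than the one above are not selectable. The tanglegram is summarised
by entanglement only (no plotting). The SNP model's divergence targets are
expectation-level, not exact per realization.
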