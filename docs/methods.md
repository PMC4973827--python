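# Methods

## Model

The expert class of variant *i* is an ordinal response `Y_i ∈ {1..J}` (J = 5
by default, IARC numbering) modeled as `Y_i ~ Categorical(π_i)` with a
proportional-odds cumulative link:

    logit P(Y_i ≤ j) = θ_j − x_iᵀβ ,   −∞ < θ₁ < … < θ_{J−1} < ∞ ,

no intercept, and the scaled deleteriousness score as the single covariate
(the code accepts a covariate vector). The sign convention is fixed as
`θ_j − x β`: positive β shifts cumulative mass downward, i.e. toward higher
classes, as the score rises. Class probabilities are first differences of
the cumulative probabilities and are evaluated through log-sigmoid
differences, `log(σ(a) − σ(b)) = logσ(a) + logσ(−b) + log1p(−e^{b−a})`,
which stays accurate for linear predictors of any magnitude (structural
variants can carry scores far outside the typical −4..14 band). The argmax
class breaks exact ties toward the lower class index.

## Inference

Scores are internally centered and scaled for mixing; all reported draws are
back-transformed to the original score scale (`θ ← θ_z + β_z·x̄/s`,
`β ← β_z/s`).

Priors, placed on the standardized scale (vague but proper, in the spirit of
common practice for Gibbs-sampled ordinal regressions): `β_k ~ N(0, 10²)`,
`θ₁ ~ N(0, 10²)`, cut-off increments `~ HalfNormal(10)`. At n ≈ 2,000 the
posterior is likelihood-dominated and insensitive to these scales.

The sampler works on the unconstrained parameterization (θ₁,
log-increments, β), which enforces the θ ordering by construction. Each
iteration performs a component-wise random-walk Metropolis scan (per-
coordinate step sizes adapted toward ≈ 44% acceptance) followed by one joint
multivariate-normal proposal whose covariance is the empirical covariance of
the burn-in history (Haario-style, scale adapted toward ≈ 23% acceptance).
All adaptation happens during burn-in only; the post-burn-in chain uses
frozen step sizes and covariance and is a valid Markov chain. The joint
proposal matters: the posterior over (θ, β) is strongly correlated when the
standardized β is large, and the component-wise scan alone mixes too slowly
there.

Defaults are 4 chains × 5,000 iterations with 2,500 burn-in; the test suite
and examples use 2 chains × 1,200–1,500 iterations, which on the ~2,200-
record emulated dataset already gives all split-R̂ < 1.05. Convergence is
assessed with the split potential scale reduction factor, rank-normalized by
default (the plain estimator is available; chains that are exactly identical
return 1 by definition). Threshold 1.05; a failed check returns the draws
with `converged=False` and a prominent warning rather than discarding them.
Sampling is bit-reproducible given (data, config): chain seeds are spawned
from the configured seed via `SeedSequence`.

The maximum-likelihood fit (BFGS on the same unconstrained
parameterization) is kept as an independent oracle. Complete separation is
detected by checking that jointly doubling the fitted (θ, β) strictly
worsens the likelihood; when it does not, no MLE exists and the fit raises
instead of returning a divergent β.

## Discrepancy flagging and reassignment

Per-variant deviance `−2 log P(Y_i | θ, β)` is averaged over posterior draws
("mean deviance"; a switch evaluates it at the posterior-mean parameters
instead). The flag threshold is the linear-interpolation 95th percentile of
the mean deviances, and flagging is *strictly above* threshold — so a
degenerate dataset with all-equal deviances flags nothing, and at most
`0.05·n + 1` records can ever be flagged. Unflagged records keep their
expert class; flagged records are assigned the argmax class at the
posterior-mean parameters (a switch uses posterior-averaged class
probabilities). This is the only reading under which the reassignment
matrix's column sums equal the per-class input counts while reassignments
can only land in classes that win the argmax somewhere. The discordant
count is the flagged subset whose argmax differs from the expert class, so
it is bounded by (and typically a shade under) the flagged count; reports
carry both numbers.

## Prioritization and override

A class-3 variant is prioritized when its model probability of the extreme
class (pathogenic by default, benign available) at the posterior-mean
parameters reaches the threshold (default 0.99). For positive β that filter
is equivalent to a score cutoff, reported in closed form as
`(θ_{J−1} − logit(1−t))/β`; the cutoff is a property of each fit, never a
constant of the method. The second-tier override promotes any variant with
model class ≤ 2 and impact HIGH to class 5 (both bounds configurable).
Impact is consumed as data (TSV column or the third pipe-field of SnpEff
`ANN` entries, maximum impact across entries); it is never computed here.
The override never demotes and is idempotent. The per-gene informativeness
statistic is the rank-based AUC (Mann–Whitney U scaled to [0,1], ties 0.5).

## Synthetic data

`emulate_insight` draws, per class, the published number of variants with
Gaussian scores at the published per-class means and SDs (151, 84, 751, 181,
1043; means 8.41–29.04; SDs 6.13–10.28). The Gaussian shape is an
approximation — the real per-class distributions are skewed and class 3 is
much flatter — so checks built on the emulation are tolerance-based, never
exact; the emulated Spearman correlation (≈ 0.61 ± 0.01 across seeds)
brackets the published 0.595, and a moment-matched Pearson on the mixture
gives 0.59 analytically. What passing these checks shows is that the
pipeline reproduces the *structure* of the real analysis (flag fraction,
class-2/4 dominance, extreme-corner counts of the right order); it cannot
certify behavior on the real data's skewness or its HGVS-level details.

`generate_from_clm` samples classes exactly from the model at user-supplied
scores, so parameter-recovery experiments have known truth; the acceptance
experiment uses θ = (−6, −4, 0, 4), β = 0.25, scores ~ U(−40, 40), n =
2,000, 20 replicates — sizes chosen so the whole experiment runs in a couple
of minutes while the credible-interval coverage estimate is still stable.

`make_structural_fixture` emulates the known failure mode of rank-based
score scaling on large structural variants: class-5 records with HIGH-impact
effect labels whose scores are drawn from the *lower 5% tail* of the benign
class-1 Gaussian (a truncated normal). The truncation is deliberate: the
failure reverts such variants to the very bottom of the scaled range, and
the fixture's contract is that a score-trained model calls them benign
(scores near the class-1 *mean* would often land in the class-3 argmax
region instead).

All generators draw from named substreams of one global seed (stream name
CRC-keyed into a `SeedSequence`), so modules are testable independently yet
reproducibly.

## Numerical and design notes

* Quantiles (deviance threshold, credible intervals) use numpy's
  linear-interpolation definition.
* Class probabilities are renormalized after exponentiation to remove
  ~1e-16 rounding; the sum-to-one invariant is enforced at 1e-12.
* Empty datasets: log-likelihood 0 with a warning; fitting raises.
  All-one-class data raise (no cut-off is identified).
* Multi-allelic VCF records are decomposed to one record per alt allele and
  the decomposition is logged; ambiguous IUPAC alleles (R, Y, …) are
  excluded, not expanded.
* Exclusions are never silent: every dropped input row appears in the
  dataset's exclusion log with a reason, and row counts are conserved.

## Limitations

* The Gaussian emulation cannot reproduce skewness-driven effects; counts
  that depend on distribution tails (e.g. the exact number of extreme-corner
  disagreements) vary across generator seeds.
* The random-walk sampler is adequate for this 5-parameter posterior but is
  not meant for models with many covariates; no NUTS/HMC is provided.
* Only the logit link is implemented; no partial/non-proportional odds.
* The pipeline consumes pre-scored, pre-annotated variants; it never runs
  scoring or annotation tools, parses HGVS beyond treating identifiers as
  opaque strings, or rescales mis-scaled structural-variant scores (it
  surfaces them via the override path instead).
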