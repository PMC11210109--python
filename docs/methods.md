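# Methods

## The three-layer signature model

A differential-expression signature is a per-gene log2 fold-change (LFC)
vector.  `consig` composes each value from three layers: a modality
(up = 1, non-deregulated = 2, down = 3), a sub-modality rank selecting one
amplitude distribution within the modality, and a uniform probability
mapped through that distribution's quantile function.  The decomposition
is generative only: a given LFC vector does not decompose uniquely back
into layers, and no such inversion is attempted.

Modality codes are fixed (1/2/3 as above) because the transition matrix
rows and columns are indexed by them.  Down-regulation is realized as the
*negated* gamma quantile, Q_down(p) = −Q_gamma(p): the stored descriptor
keeps a nondecreasing base quantile and a sign.  This choice makes the
deterministic-everything transition at c = −1 an exact negation of the
deregulated genes (the natural meaning of "perfectly reversed"), at the
price that the composed down-quantile is decreasing in p.  Sub-modality
ranks within a modality are ordered by strictly increasing mean amplitude
|ξ|, so that rank-coupling transitions (binomial, copula) act on a
meaningful scale.

### Default amplitude bank

Real LFC distributions show a large near-zero mass plus heavier up/down
tails.  The default bank uses a Gaussian(0, 0.1) non-deregulated mode and
three gamma sub-modalities per tail with mean amplitudes
|ξ| = {0.8, 1.6, 3.0}, proportions ∝ (1, 0.6, 0.36) (geometric decay,
ratio 0.6), and a common gamma shape of 20 (coefficient of variation
≈ 22%), which keeps |LFC| essentially inside [0.5, 5].  These values are a
documented stand-in chosen once for realism; nothing in the package
depends on them beyond the defaults.

## Transitions

The secondary signature is generated conditionally on the primary, one
layer at a time and independently across genes (no gene–gene dependency
is modeled; network-based scores are out of scope for the same reason).

* **Modality**: each gene transitions through a row-stochastic 3×3 matrix
  Λ, either supplied in full or built from the symmetric connectivity
  model (c, γ).  The five defining formulas are algebraically
  row-stochastic for every (c, γ) ∈ [−1, 1] × [0, 0.5].
* **Sub-modality**: genes non-deregulated in either signature always draw
  independently from the secondary proportions.  Doubly-deregulated genes
  follow the configured strategy: independent; deterministic (υ = τ,
  requires equal rank counts); stochastic (υ ~ Binomial(N, τ/N), also
  requiring equal counts); or copula.  The binomial draw can produce 0,
  outside the rank support [1, N]; it is clamped to 1, a small upward
  bias at τ = 1 documented here and preferred over resampling, which
  would distort the stated law less transparently.
* **Probability**: independent (fresh uniforms), deterministic (copy), or
  copula-coupled.

### Copulas

Frank, Plackett and Gaussian copulas are implemented with closed-form
CDFs and conditional CDFs (the Gaussian CDF uses Owen's T, accurate to
~1e−14).  Conditional sampling inverts the conditional CDF analytically
for Frank and Gauss and by 60-step bisection for Plackett.

For the probability layer the copula parameter θ is chosen so that the
Pearson correlation of the two uniform margins — which equals the
copula's Spearman rho — matches the requested target: closed form for
Gauss (θ = 2 sin(πρ/6)), Hoeffding-identity quadrature
(ρ = 12∬C − 3, 96-point Gauss–Legendre) plus Brent root-finding for the
others.  For the sub-modality layer the joint pmf over the two rank
margins is built from rectangle differences of the copula CDF at the
cumulative margins (so the margins are reproduced exactly, to 1e−9), and
θ is optimized until the *exact* Pearson correlation of the coupled ranks
meets the target (tolerance 1e−4).  Targets outside the attainable
(Fréchet) range for the given margins are clamped to the bound with a
warning, never silently.  The Frank parameter is capped at |θ| ≤ 35
(attainable ρ ≈ ±0.97) for numerical stability of the expm1-based CDF;
the Plackett parameter is searched on a log scale in e^±14.

## Count pipeline

The pipeline emulates how real bulk RNA-seq DE signatures are produced.

1. **Replicates**: n in-silico replicates of the signature are generated
   as near-identity transitions of the parent (defaults c = 0.9,
   γ = 0.02, deterministic sub-modality/probability).
2. **Control expression**: μ_Ct = 2μ̃ / (1 + 2^ξ), with ξ the mean LFC of
   each gene's assigned sub-modality, so that the supplied base
   expression μ̃ is exactly the mean of control and treated levels.
3. **Counts**: per sample, gene means Δ = μ_Ct · X · L / S · N (S the
   library-composition normalizer, N the library size, L = 1 for
   3'RNA-seq) sum to N exactly; counts are negative binomial with size
   r = f·Δ, i.e. a constant variance/mean ratio 1 + 1/f (default
   f = 1/3 → ratio 4; f large recovers Poisson).  Control samples use
   X = 1 and receive multiplicative noise 2^ε, ε ~ N(0, sd) with
   sd = 0.5 by default — the noise is placed on the log2 scale so
   expression stays nonnegative and the noise is scale-free.
4. **DE re-inference**: a deliberately transparent NB-Wald two-group
   test — median-of-ratios size factors, per-gene moment dispersion
   (floor 1e−8) pooled across conditions, log2 ratio of group means with
   pseudocount 0.5, delta-method standard errors, normal two-sided
   p-values, Benjamini–Hochberg adjustment.  It is *not* a DESeq2
   re-implementation (no shrinkage, no outlier filtering, unpaired
   design only), but on matrices from this simulator its per-gene LFCs
   agree with pydeseq2's to r > 0.9999 (cross-checked in the test
   suite).  Count matrices can be exported as TSV for external tools.

A consequence worth knowing: at replicate connectivity 0.9 each
replicate sign-flips a deregulated gene with probability ≈ 0.05, and a
single flipped replicate dominates the linear-scale group mean for
down-regulated genes.  End-to-end recovery correlation between estimated
and simulated LFC on strongly deregulated, well-expressed genes
therefore plateaus around 0.87–0.89 under the default replicate noise —
an intrinsic property of the replicate model, not of the estimator (the
pydeseq2 cross-check gives the same value).

## Connectivity scores

Seven scores are implemented from their operational definitions; ties in
reference ranking are always broken by gene id for determinism.

* **cmap1**: signed one-sided KS statistics of the query's up and down
  sets in the rank-ordered reference; score = (ks_up − ks_down)/2 when
  the signs differ, else 0.  The original cross-batch normalization
  (positives / max, negatives / |min|) requires a collection and is
  applied inside the benchmark per dataset replicate.
* **cmap2 (WTCS)**: GSEA-style weighted running-sum enrichment
  (|LFC|-weighted hits, −1/(G−t) misses) of both sets; (ES_up − ES_down)/2
  when the signs oppose, else 0.
* **CSS**: signed magnitude-rank products of the query's deregulated set
  (default: its top-100 |LFC| genes), normalized by the maximum
  attainable for a set of that size; self-score is exactly 1.
* **xsum / xcos / xpearson / xspearman**: the reference is masked to its
  n_extreme most up- and down-regulated genes (default 500) before a
  set-sum, cosine, Pearson or Spearman comparison; Spearman uses average
  ranks on ties.

All scores except xsum are bounded in [−1, 1]; css and the four extreme
similarities are exactly antisymmetric under reference negation, cmap1
and cmap2 are antisymmetric whenever nonzero (the same-sign rule can
send both orientations to 0).

## Benchmark

A dataset holds n_pairs interconnected pairs with true connectivities
evenly spaced on [0, 1] (a single pair sits at c = 1).  Positive labels
are the top-N pairs by true connectivity, matching the retrieval
question "are the truly most-connected pairs ranked first?".  Average
precision is the exact finite sum Σ P_k Δr_k; evaluation regenerates the
dataset for each replicate and reports the mean AP per method and top-N
with a 95% t-interval across replicates.  Ranking ties are broken by
pair id, so a seeded evaluation is bit-reproducible.

The KL-divergence utility compares two LFC histograms on a shared
100-bin equal-width grid spanning both samples with additive smoothing
1e−9.

## Parameter fitting

`detect_lfc_modes` (Gaussian KDE, strict local maxima above 5% of the
global density peak) is diagnostic.  `fit_bank_from_lfc` drives the
refit: modality proportions from a |LFC| > 0.5 threshold (configurable),
a Gaussian for the central mass, and a gamma mixture per tail fitted by
EM on |LFC| with a moment-based M-step, initialized from a seeded
Gaussian mixture.  A plain quantile-band average was rejected because
band means are biased estimators of component means whenever components
overlap, and a pure Gaussian EM leaves a skew bias of ~10% on the
largest-amplitude component; the gamma EM recovers the default bank's
amplitude ladder within ~4% at 50 000 genes.  Each tail requires at
least 20 genes per requested sub-modality.

## What the synthetic world does and does not establish

The generators emulate: multimodal LFC distributions (gamma tails,
Gaussian center), asymmetric deregulation proportions (defaults
p_up = 0.07, p_down = 0.13), expression-dependent count noise,
replicate-level variability, and pairs with known connectivity.  They do
not emulate gene–gene correlation structure, batch effects, GC or
duplication artifacts, paired designs, or heterogeneity between
biological models (e.g. different cell lines).  A green benchmark result
therefore speaks to a method's behavior under the stated noise model,
not to its robustness across heterogeneous real libraries — which is
exactly the regime where rank-based scores are expected to regain
ground.

## Numerical conventions

One seeded generator per top-level call; child streams are derived
deterministically per layer/replicate, so enlarging one layer never
reshuffles another.  Probabilities are clipped away from {0, 1} by 1e−12
before quantile/copula evaluation.  Score ranking ties break by gene or
pair id.  Degenerate inputs (zero-variance margins, single-rank
modalities, empty tails, all-zero expression) raise explicit errors or
fall back to exactly defined independence couplings, as documented in
the docstrings.
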