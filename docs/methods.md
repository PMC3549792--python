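# Methods

## Penetrance models and their summaries

A biallelic locus with minor allele frequency *q* (0 < q ≤ 0.5) has HWE
genotype frequencies (p², 2pq, q²) with p = 1 − q. An *n*-locus penetrance
model assigns each multi-locus genotype (MLG) a disease probability f_G.
Loci are assumed independent (linkage equilibrium), so the joint MLG
probability is the product of per-locus frequencies. MLGs are indexed
canonically: per-locus genotype code g ∈ {0, 1, 2} counts minor alleles and
the flat index is Σ g_i 3^(n−1−i) (locus 0 slowest), which for two loci puts
locus 0 on table rows and locus 1 on columns.

Prevalence K is the P-weighted mean penetrance; heritability is the
P-weighted variance of penetrance normalized by the Bernoulli phenotypic
variance K(1 − K). A model is *pure* and *strict* when every marginal
penetrance table over every proper nonempty locus subset is flat at K; the
checker only examines the (n−1)-locus marginals because averaging a flat
table over further loci stays flat. Flatness is tested to a caller-chosen
absolute tolerance: 1e-9 for internally generated models (which are flat to
machine precision), 1e-3 when validating tables transcribed at three printed
decimals, such as the bundled two-locus example.

## Difficulty metrics

Three per-model statistics predict how hard a detector will find the model's
loci in data:

- **EDM** = (1 / 2(K(1−K))²) Σ_G P(G)² (f_G − K)². Because P(G) enters
  squared, rare MLGs count for less than they do in heritability. The same
  number equals ½ Σ_G (P(G|case) − P(G|control))², half the squared Euclidean
  distance between the class-conditional MLG distributions; both forms are
  implemented independently and agree to < 1e-12 over randomized models. The
  verbal description of the second form as "half the Euclidean distance" is
  treated as loose wording: only the squared form equals the first.
- **COR**: MLGs are classed high risk when the expected case share
  E_case = P(G) f_G / K meets or exceeds the expected control share (ties are
  high risk); collapsing to expected high/low-risk case/control proportions
  (a, b, c, d) gives the odds ratio a·d / (b·c). High-risk MLGs are exactly
  the case-enriched ones, so COR ≥ 1 whenever defined. When b or c is zero
  (e.g. any flat model) the odds ratio is undefined and the library raises an
  explicit error carrying the degenerate table rather than returning ±inf —
  ranking code must filter these, never sort infinities.
- **PTV**: the unweighted variance of the 3ⁿ penetrance values, with
  denominator 3ⁿ (the table is the whole population of cells, not a sample).

**Control normalization.** The expected control share is normalized by
(1 − K), which makes both class-conditional vectors proper distributions,
reduces the high-risk rule to f_G ≥ K, and is required for the two EDM forms
to coincide. A published variant instead divides by K (making the rule
f_G ≥ 0.5 and leaving the control vector unnormalized); it is available as
`literal_control=True` on the relevant functions for reproducibility, but is
not the default because it breaks normalization.

## Model generation

For fixed MAFs, deviation tables d with every weighted proper-subset
marginal equal to zero form a linear space of dimension 2ⁿ. We construct an
explicit orthonormal basis: per locus, Gram–Schmidt under that locus's
genotype-frequency weights turns the additive (0, 1, 2) and recessive
(0, 0, 1) codings into two contrasts orthogonal to the constant vector; the
2ⁿ tensor products taking one contrast per locus are orthonormal under the
joint MLG probabilities, and every proper-subset weighted marginal of every
basis table vanishes identically.

One generation attempt draws a uniform unit direction u ∈ R^(2ⁿ) (normalized
Gaussian), forms d = Σ u_j b_j — which satisfies Σ P d = 0 and Σ P d² = 1 by
construction — and sets

    f_G = K + c d_G,   c = √(h² K(1−K)),

solving the heritability definition in closed form. Prevalence and
heritability therefore hold *exactly* on acceptance, and purity/strictness
holds to machine precision. The attempt is accepted iff every f_G ∈ [0, 1];
otherwise the algorithm starts over. Populations are built by repeating
attempts until a population cap (default 100,000) or an attempt cap (default
10,000,000) is reached; an undersized or empty population is a reportable
outcome, not an error, since some (h², MAF, K) combinations admit few or no
valid tables. Attempt k draws from the counter-derived substream
`default_rng((seed, k))`, so a run is reproducible and attempt k does not
depend on how many earlier attempts were rejected.

Equivalence with other direct generators of pure, strict models is claimed
only at the level of the constraints satisfied (exact n, MAFs, h², K,
purity, strictness), not as distributional identity over architectures.

**Quantile selection.** A population is ranked ascending by a chosen metric
(EDM, COR, PTV or heritability; stable sort, generation order breaks ties —
determinism under a fixed seed). The selected ranks are
round(i (M−1)/(n_select−1)): n_select = 2 returns exactly the minimum- and
maximum-metric models, n_select = 1 the median rank. The rounding rule for
intermediate quantiles is a package choice; nothing downstream depends on
it beyond monotonicity. Members with an undefined COR are dropped from COR
rankings with a warning.

## Dataset simulation

Each sample's predictive genotypes are drawn per locus from the HWE triples
and its affection status is Bernoulli(f_G) at the drawn MLG. Balance is
enforced by **quota rejection sampling**: draws accumulate into the case and
control quotas (half each) in draw order, surplus draws for a filled class
are discarded, and rows are shuffled afterwards. This choice preserves the
within-class MLG distributions P(G|case) and P(G|control) exactly — the
quantities the metrics reason about — which post-hoc rebalancing of a fixed
cohort would also do but with more machinery. A cap of 10⁴ × total_samples
draws bounds pathological near-degenerate models; exceeding it raises an
error naming the starved class.

Noise SNPs each get one MAF drawn uniformly from a configured range (default
0.05–0.5) and genotypes i.i.d. from HWE at that MAF, independent of class.
Genotypes are encoded as minor-allele counts {0, 1, 2}; columns are the
predictive SNPs (P0, P1, …) then noise (N0, …) then the class label
(1 = case). Replicate r of a dataset specification uses the child stream
`default_rng((seed, r))`, so any replicate can be regenerated alone,
bit-identically.

**What the generator emulates, and what it does not.** Simulated data embody
exactly the idealized model: HWE at every locus, linkage equilibrium between
all SNPs, no genotyping error or missingness, no covariates or population
structure, balanced sampling. Passing fidelity tests therefore demonstrates
that datasets realize the specified penetrance model faithfully — not that
any detector's behavior on them transfers to real cohorts, where LD,
stratification and noise SNP correlation structure all intrude.

## Numerical choices

- Degenerate models (K within 1e-12 of 0 or 1, e.g. an all-ones table whose
  floating HWE weights sum to 1 − 1 ulp) raise a degenerate-model error from
  heritability and the metrics rather than returning NaN or noise.
- Risk-class ties are compared with a 1e-12 relative margin so that a flat
  table at exactly K classifies as all high risk regardless of rounding
  direction in E_case vs E_control.
- Acceptance in the generator is strict (f ∈ [0, 1] with no tolerance, no
  clipping), since clipping would silently break the exact-h² contract.
- Model files serialize penetrances and MAFs at full float precision
  (`repr`), so write/read round trips are lossless; header metrics are
  recomputed on read and the body wins over a stale header (with a logged
  warning).

## Problem sizes used in the tests

The test suite and acceptance script scale the study down to sizes that keep
the numbers meaningful while running in seconds: population-level constraint
recovery uses 1,000 accepted models per two-locus grid combination (12
combinations, all constraints recovered to 1e-9); the EDM form-equivalence
sweep uses 10,000 randomized models of 1–3 loci; simulator fidelity uses one
10⁵-sample dataset checked by chi-square goodness of fit against the
class-conditional distributions at α = 0.01; the acceptance script's grid run
uses populations of 100 models per combination, which is ample for selecting
two EDM extremes per population.

## Known limitations

- Phased haplotypes, LD between loci, covariates, quantitative traits and
  X-linked inheritance are out of scope; so are unbalanced designs and
  genotyping-error models.
- The feasible (h², MAF, K) region is not derived analytically; infeasible
  constraint sets simply exhaust the attempt cap and return small or empty
  populations.
- Rank correlations between the metrics and actual detector success require
  running third-party search algorithms over thousands of datasets and are
  outside this package; the package's own evidence is that EDM varies across
  architectures at fixed constraints (the max/min EDM ratio within a
  population exceeds 1), which is the phenomenon quantile selection exploits.
- COR confidence intervals and empirical (dataset-estimated) odds ratios are
  not provided; COR here is an expected-table quantity.
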