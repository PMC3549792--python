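# epistasim

Simulation studies of gene–gene interaction detectors (exhaustive searches,
Relief-style filters, evolutionary algorithms) need benchmark models whose
difficulty is controlled, not accidental. Two genetic models can share every
headline constraint — number of loci *n*, minor allele frequencies (MAFs),
heritability *h²*, population prevalence *K* — and still differ wildly in how
easily a search algorithm finds their predictive SNPs, purely because of their
*architecture*: the particular arrangement of penetrance values across
multi-locus genotypes (MLGs).

`epistasim` is a toolkit for researchers who build such benchmarks. It

1. **generates** random *pure, strict*, *n*-locus epistatic penetrance models
   that hit exactly specified MAFs, *h²* and *K* — "pure" meaning no locus has
   a marginal effect, "strict" meaning no proper subset of the loci is
   predictive at all;
2. **scores** each model's expected detection difficulty directly from the
   penetrance table, without running any detector;
3. **selects** quantile-representative architectures from large generated
   populations; and
4. **simulates** balanced case-control SNP datasets (predictive loci plus
   noise SNPs) from any selected model.

## The model and the metrics

A penetrance model assigns each of the 3ⁿ MLGs *G* a disease probability
*f_G*. Under Hardy–Weinberg equilibrium and linkage equilibrium the joint MLG
probability *P(G)* is the product of per-locus genotype frequencies
(*p²*, 2*pq*, *q²*). The derived quantities are

- prevalence K = Σ_G P(G) f_G
- heritability (broad-sense) h² = (1 / K(1−K)) Σ_G P(G) (f_G − K)²
- **EDM** (ease of detection measure)
  EDM = (1 / 2(K(1−K))²) Σ_G P(G)² (f_G − K)²,
  equal to half the squared Euclidean distance between the MLG distributions
  of cases and of controls, ½ Σ_G (P(G|case) − P(G|control))²
- **COR** (customized odds ratio) a·d / (b·c) of the expected 2×2 table that
  splits MLGs into high/low risk by whether the expected case proportion
  meets or exceeds the expected control proportion
- **PTV** (penetrance table variance): the unweighted variance of the 3ⁿ
  values f_G.

EDM and COR weight deviations by genotype probability and therefore track how
strongly the predictive loci stand out from noise; PTV ignores genotype
frequencies. Model generation works in a 2ⁿ-dimensional orthonormal basis of
pure-interaction tables (every weighted marginal zero), so accepted models
satisfy their constraints to machine precision — see `docs/methods.md`.

## Worked example

The package ships a classic two-locus pure, strict model with MAFs 0.4/0.5
(`epistasim.two_locus_example`). Score it from Python or the CLI:

```python
from epistasim import two_locus_example, write_model
write_model("example.model", two_locus_example())
```

```
$ epistasim score example.model
K            0.61434
h2           0.242532
EDM          0.0628767
COR          7.32572
PTV          0.0711087
```

`K` is the population disease prevalence implied by the table (61.4% — every
single-locus marginal penetrance equals this same value, which is what makes
the model purely epistatic), `h2` the fraction of phenotypic variance
explained by genotype, and the last three lines the difficulty metrics
defined above (COR here says high-risk MLGs carry ~7.3× the disease odds of
low-risk ones).

Generating populations and selecting EDM extremes:

```
$ epistasim generate --n-loci 2 --h2 0.01 --h2 0.1 --maf 0.2 --k 0.3 \
      --pop-size 500 --n-select 2 --metric edm --seed 1 --out models/
generating population for n=2 h2=0.01 maf=0.2 K=0.3 (seed 2)
  500 models in 970 attempts; wrote 2 selected
generating population for n=2 h2=0.1 maf=0.2 K=0.3 (seed 3)
  500 models in 22776 attempts; wrote 2 selected
wrote 4 models to models/
```

Each combination yields the lowest- and highest-EDM architecture found in its
population (`*_q0.model`, `*_q1.model`) plus a JSON manifest recording seeds
and attempts. Datasets then follow with
`epistasim simulate --model models/L2_h0.1_maf0.2_edm_q1.model --samples 800
--snps 20 --replicates 100 --seed 3 --out data/`, producing tab-delimited
files of {0,1,2} genotype codes with an exactly balanced `Class` column.

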