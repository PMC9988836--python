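# modmap

Modifier-locus mapping in inbred mouse strain panels.

`modmap` is a reusable implementation of the statistical-genetics workflow
used to discover and prioritize a dominant modifier locus for a binary
trait — the motivating case being *Bphs* (pertussis-toxin-induced histamine
sensitization), where several wild-derived strains carrying the resistant
*Hrh1* allotype are nevertheless susceptible, implying an enhancer locus
(*Bphse*) that complements the resistant allele. The package is for
statistical geneticists working with inbred strain panels who want each
stage of that workflow as tested, scriptable components:

1. **Susceptibility testing** — pool per-dose affected/tested counts per
   strain and test against a resistant reference with a two-sided Fisher
   exact test (point-probability rule, exact log-space enumeration).
2. **Backcross linkage scan** — per-marker Pearson chi-square (no
   continuity correction) of genotype (Ho/He) against phenotype in BC1
   cohorts.
3. **HMM genotype imputation** — Viterbi decoding over a reference panel of
   the k most concordant strains; hidden states are reference strains,
   emissions allow an error rate epsilon, transitions switch reference with
   probability tau.
4. **Mixed-model association** — EMMA-style maximum-likelihood linear mixed
   model `y = Xb + u + e`, `u ~ N(0, sigma_g^2 K)` with identity-by-state
   kinship K, profiled over `delta = sigma_e^2/sigma_g^2` by
   eigendecomposition, with per-SNP likelihood-ratio tests and Bonferroni
   thresholds.
5. **Functional prioritization** — per trait-term gene module, an ensemble
   of 100 linear SVMs over functional-network connectivity features,
   converted to empirical false-positive rates.
6. **Combined gene score** — `S_cg = assoc/max(assoc) + func/max(func)`
   over positional candidates, ranking genes by joint genetic and
   functional support.

A `synthetic_data`-style simulation layer (group-structured strain panels,
a two-locus complementation trait with incomplete penetrance, Haldane-model
backcrosses, planted-module networks) generates every input the pipeline
consumes, so the whole workflow is testable offline. See
[docs/methods.md](docs/methods.md) for models, defaults and limitations.

## Worked example

The published strain-screen counts ship with the package; the
susceptibility stage reproduces the printed table:

```python
from modmap.datasets import hrh1r_screen_dose_response
from modmap.phenotype import susceptibility_screen

for r in susceptibility_screen(hrh1r_screen_dose_response(), "C3H")[:8]:
    print(f"{r.strain:<15} {r.affected}/{r.tested:<6} {r.percent_affected:<4} {r.p_display}")
```

```
C3H/HeJ         0/7    0    1.0
C3H/HeN         0/6    0    1.0
AKR/J           1/7    14   0.4
CAST/EiJ        1/9    11   0.4
CBA/J           0/7    0    1.0
CBA/N           0/7    0    1.0
CBA             0/14   0    1.0
I/LnJ           2/10   20   0.2
```

AKR/J's pooled 1/7 is indistinguishable from the resistant C3H reference
(p = 0.4), while further down the table BPL/1 J's 5/6 gives p = 0.0005 —
the susceptible call despite the resistant receptor allotype.

The full pipeline runs from one TOML config. The bundled demo generates a
30-strain panel in which a dominant enhancer allele at 52 Mb rescues
susceptibility, plus a backcross, a functional network whose planted module
contains the enhancer gene, and gene coordinates:

```python
from modmap.demo import build_demo_inputs
from modmap.pipeline import PipelineConfig, run_all
from modmap.io import read_table

config = build_demo_inputs("demo", seed=1)
artifacts = run_all(PipelineConfig.from_toml(config))
print(read_table(artifacts["rank"]).head(3))
```

```
 rank gene_id  assoc_neglog10p  func_neglog10fpr     s_cg
    1    Enh1       300.000000          3.477266 2.000000
    2     L09       300.000000          0.192240 1.055285
    3     L05         3.757990          0.208309 0.072433
```

The planted enhancer gene `Enh1` attains both the association maximum and
the functional maximum, so its combined score is exactly 2.0 and it ranks
first; `L09` happens to tag a SNP perfectly co-segregating with the trait
(a perfectly separating SNP saturates the p-value floor, hence the capped
-log10 p of 300) but has no functional support. The same run writes the
per-stage TSVs (phenotype screen, linkage scan, imputed genotypes,
association results with threshold headers, functional FPRs) and a
manifest with config hash and seeds; rerunning is byte-identical, and
deleting one output regenerates only that stage.

Every stage is also a CLI subcommand of the `modmap` console script
(`simulate-panel`, `pheno-test`, `linkage-scan`, `impute`, `assoc`,
`prioritize`, `rank`, `run`).

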