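# copulse

Hierarchical co-demographic simulation and inference for comparative
population genomics.

## The problem

Comparative phylogeography asks whether co-distributed taxa responded to a
shared environmental driver — a glacial retreat, a habitat shift — by
changing population size *synchronously*. Given population-genomic data
(e.g. RAD-seq SNPs) or mitochondrial alignments from `n` independent
populations, `copulse` tests multi-taxa hypotheses in a single hierarchical
analysis instead of stitching together per-taxon results.

Each taxon follows an instantaneous size-change history with three
parameters: the current size `N` (gene copies), the ancestral/current ratio
`ε` (`ε < 1` is an expansion), and the change time `τ` (generations).
A hierarchical model groups the `n` taxa into `Ψ` event times: `ψ`
synchronous *pulses* shared by ≥ 2 taxa and `σ` idiosyncratic single-taxon
events, with `Ψ = ψ + σ`. The proportion of taxa in the pulses is `ζ_T`
(per-pulse proportions `ζ_s = {ζ_1, …, ζ_ψ}`, most recent first), and the
dispersion of event times is summarised by `Ω_τ = Var(τ)/E(τ)` together with
`E(τ)`. A *pulse buffer* `β` keeps distinct event times at least `β`
generations apart a priori, which makes pulse counts identifiable as
temporal variability rather than labels for arbitrarily close events.

Inference is simulation-based. Per-taxon folded site frequency spectra are
simulated one SNP per independent genealogy, re-ordered into the
**aggregate SFS (aSFS)** — for each allele-frequency class, the `n` taxa's
SNP proportions sorted descending, classes concatenated — an exchangeable
multi-taxa summary. Reference tables of (hyperparameters, aSFS) pairs feed
two estimators:

* **hABC** — simple rejection: retain the `tolerance × n_sims` simulations
  nearest in standardised Euclidean distance; point estimates are the mean,
  median and mode of retained values, with per-`Ψ` category posteriors for
  model selection.
* **hRF** — random-forest regression on numeric `Ψ`: 100 cycles × 10 trees,
  each cycle on a class-balanced subsample (1,000 simulations per `ψ`),
  33 split candidates for a 100-bin aSFS.

Mitochondrial mode replaces the aSFS by 16 moment statistics
({mean, variance, skewness, kurtosis} × {number of haplotypes, haplotype
diversity, nucleotide diversity, Tajima's D}).

## Worked example

```python
import numpy as np
from copulse import build_hyperprior, simulate_reference_table, loo_crossval

spec = build_hyperprior({
    "n_taxa": 10, "scheme": "psi", "psi_support": (0, 1),
    "fixed_zeta": {1: (1.0,)},          # one pulse holding all ten taxa
    "tau_prior": (5_000, 250_000),      # generations
    "epsilon_prior": (0.01, 0.10),      # 10-100x expansions
    "n_prior": (50_000, 250_000),       # gene copies
    "beta": 30_000, "beta_overrides": {0: 10_000},
})
table = simulate_reference_table(spec, seed=1, n_per_psi=600, convert_psi=True)
report = loo_crossval(table, 20, "rf", np.random.default_rng(0),
                      rf_options={"per_class": 120})
r, rmse = report.scores["rf"]
print(f"hRF leave-one-out: r={r:.3f} rmse={rmse:.2f}")
```

This simulates 600 aSFS per pulse-count value under the buffered
co-expansion model (`ψ = 0`, full idiosyncrasy, is converted to `Ψ = 10`;
`ψ = 1` is full synchrony, `Ψ = 1`), removes 20 pseudo-observed datasets
(PODs) per `Ψ` value, trains the forest on the rest and scores predicted
against true `Ψ`. It prints

```
hRF leave-one-out: r=0.888 rmse=2.08
```

meaning predicted and true event counts correlate at r ≈ 0.89 even at this
small table size; accuracy rises steeply with more simulations (r ≈ 0.97 at
the 14,000-per-value scale the acceptance script uses). The same
`loo_crossval` call with `method="abc-model"` and a tolerance scores the
rejection estimator, and `method="abc-param"` with
`value_column="omega_tau"` or `"e_tau"` scores parameter-summary recovery.

A command-line interface mirrors the library:

```bash
copulse simulate  --spec spec.yaml --sims 1000 --seed 1 --out sims/
copulse aggregate --in sims/ --convert-psi --out table.tsv
copulse infer     --table table.tsv --target observed_asfs.tsv --tol 0.0025 --out post.json
copulse crossval  --table table.tsv --pods-per-value 20 --method rf --out cv.tsv
```

`copulse asfs` converts a directory of empirical per-taxon SFS files (the
plain-text header format or the dadi folded dialect) into an aSFS row, and
`copulse sumstats` converts per-taxon FASTA alignments into the 16
mitochondrial statistics.

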