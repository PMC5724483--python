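# Methods

## Model

`copulse` implements hierarchical co-demographic models of independent
single-population size changes. Each of `n` taxa is a panmictic population
with an instantaneous size change: current size `N` (gene copies), ancestral
size `εN`, change time `τ` generations before sampling. Backward in time the
coalescence rate with `k` lineages in a population of size `M` is
`k(k−1)/(2M)` per generation; the size switches from `N` to `εN` exactly at
`τ` (events at time ≥ `τ` use the ancestral size). `ε < 1` therefore encodes
a forward-time expansion and `ε > 1` a contraction.

The hierarchical layer assigns the `n` taxa to `Ψ` event times: `ψ`
synchronous pulses (≥ 2 taxa each, proportions `ζ_s = {ζ_1, …, ζ_ψ}` ordered
by pulse recency, totalling `ζ_T`) and `σ = n − S_T` idiosyncratic events
(`S_T = ζ_T·n`), with `Ψ = ψ + σ`. Taxa are allocated to events by a uniform
random permutation; each taxon independently draws its nuisance `ε` and `N`.
Event-time dispersion is summarised by `E(τ)` and the dispersion index
`Ω_τ = Var(τ)/E(τ)`.

### Hyperprior schemes

* **`psi`** — a discrete uniform hyperprior on `ψ`; within each `ψ` every
  admissible `ζ_T` (i.e. every whole taxon count `S_T ∈ {2ψ, …, n}`) is
  weighted equally, and within each `ζ_T` every partition of `S_T` into `ψ`
  parts ≥ 2 is weighted equally. A per-`ψ` table of fixed `ζ_s` multisets can
  replace the enumeration (the multiset is shuffled across time-ordered
  pulses per draw).
* **`zeta-t`** — `ψ` restricted to {0, 1} with a discrete hyperprior grid on
  `ζ_T`; `Ψ = 1 + n − S_T` when `ψ = 1` and `ζ_T = 0` when `ψ = 0`.
* **`crp`** — all set partitions of the `n` labelled taxa weighted equally
  (the Dirichlet-process construction); a block-size multiset receives
  weight proportional to its number of set partitions, `ψ` counts blocks of
  size ≥ 2 and `σ` the singletons.
* **`custom`** — the `psi` enumeration filtered by min/max rules on
  `ζ_T`/`ζ_s`.

Non-integer `ζ_T·n` is rejected at specification time: only whole taxon
counts are enumerable, so admissible grids are built rather than rounded.

### Pulse buffer

The buffer `β` forbids any two event times closer than `β`: each new time is
drawn uniformly from the integer prior range minus the union of *closed*
windows `[t−β, t+β]` around already-placed times (with `β = 0` only the
placed points are excluded; with an integer prior `U{10,000, 1,000,000}`,
`β = 20,000` and a first draw at 100,000, the second draw comes from
`U{10,000, 79,999} ∪ U{120,001, 1,000,000}`). Because sequential draws can
paint themselves into a corner even when a feasible arrangement exists, the
whole time vector is retried on a dead end (default 100 attempts) before a
buffer-infeasibility error propagates; a necessary feasibility condition is
`(k−1)·β <` prior width for `k` events. Idiosyncratic events participate in
buffering by default (`buffer_idiosyncratic=False` restricts the buffer to
pulse times). `β` may be overridden per `ψ` value — the standard design
reduces `β` from 30,000 to 10,000 generations at `ψ = 0`, where ten mutually
buffered events could not otherwise fit the `τ` prior width of 245,000.

## Simulation of the folded SFS

Genomic mode emulates SFS simulation with one SNP per independent genealogy
(a set number of genealogies standing in for the number of SNPs sampled).
For each genealogy the engine draws the coalescent interval durations
`T_k`, `k = n…2`, under the piecewise-constant rate (memoryless exponential
rescaling across `τ`), selects the interval carrying the SNP with
probability `k·T_k / Σ_j j·T_j` (its share of total branch length), and
draws the derived class from the leaves-subtended distribution of a random
lineage at level `k`, `P(i|k) = C(n−i−1, k−2)/C(n−1, k−1)`. Because Kingman
topology is independent of interval durations, this is distributionally
identical to realising the full tree and dropping a uniformly placed
mutation — i.e. the per-genealogy SNP class probability is exactly
`ℓ_i/ℓ_tot` — while avoiding per-tree bookkeeping. The kernel is
numba-compiled and consumes bulk SFC64 float32 random streams; an explicit
topology mode (`method="tree"`) exists for cross-validation of the kernel,
and the tests compare the two distributions directly.

Classes are folded (`i` merged with `n−i`; the middle class unmerged for
even `n`) and normalised to proportions over the `floor(n/2)` polymorphic
minor-allele classes.

`expected_sfs` provides two documented estimators. The default
(`"snp-share"`) is `E[ℓ_i/ℓ_tot]`, the quantity FREQ-style simulation
converges to, computed by high-replicate duration averaging with the
topology integrated out analytically. `"branch-share"` is the classical
length-ratio `E[ℓ_i]/E[ℓ_tot]`, with the constant-size closed form
(unfolded class share ∝ `1/i`). The two differ by a few percent in the
singleton class even at constant size — the expectation of a ratio is not
the ratio of expectations — so the convergence oracle for simulation is
`"snp-share"` and the classical closed form is kept for analytic reference.

Single-locus mode realises the topology explicitly and drops a Poisson
number of infinite-sites mutations (mean `µ·L·ℓ_tot`) uniformly on
branches; mutations exceeding the locus length raise a saturation error
rather than silently recycling sites. Under this scaling
`E[S] = θ·a_{n−1}` with `θ = 2NµL`.

### Population-size convention

`N` is the number of gene copies (haploid size) throughout, so the printed
prior ranges are used as-is. This is an internal convention applied
consistently to simulation and inference; only the absolute time scale, not
the structure of the inference problem, depends on it.

## Multi-taxa summaries

The aggregate SFS sorts, for each frequency class independently, the `n`
taxa's SNP proportions in descending order and concatenates the classes
(length `n × floor(n_samples/2)`, e.g. 100 for 10 taxa × 20 haploids). The
per-class sort — rather than a single global taxon ranking — makes the
summary exactly invariant to taxon permutation, matching the model's
exchangeability assumption; a given vector position does not track one
taxon across classes.

Mitochondrial mode computes per taxon the number of haplotypes `K`,
haplotype diversity `H = (n/(n−1))(1 − Σp_i²)` (unbiased correction, so
empirical and simulated values agree), nucleotide diversity `π` (mean
pairwise differences per site) and Tajima's D (1989 constants; `D` reported
as 0 with a flag when `S = 0`), then the first four moments of each across
taxa: mean, sample variance (divisor `n−1`), and skewness/kurtosis as
standardised central moments (kurtosis non-excess); a zero-variance
statistic maps skewness and kurtosis to 0 with a warning. The moment
conventions are fixed so reference tables remain comparable across runs.

## Inference

**hABC rejection.** Summaries are standardised per statistic by the median
absolute deviation of the reference column (falling back to the standard
deviation, then to 1, for degenerate columns) — the common ABC practice;
the choice affects only relative distances and makes rejection invariant to
per-statistic affine rescaling. The nearest `round(tolerance·n_sims)`
simulations are retained. Point estimates: mean and median of retained
values; the mode is a Gaussian-KDE (Silverman bandwidth) argmax on a
512-point grid for continuous targets, and the highest-posterior category
(ties toward the lowest value) for model selection, where each discrete `Ψ`
is a model and retained-count proportions form the category posterior.

**hRF regression.** `Ψ` is treated as numeric and estimated by
variance-reduction regression trees: 100 cycles × 10 trees, each cycle
fitting on a class-balanced subsample (1,000 simulations per `ψ` value
drawn without replacement when the class allows, with replacement and a
warning otherwise; the subsample returns to the pool between cycles);
`max(floor(n_stats/3), 1)` split candidates (33 for the 100-bin aSFS); the
prediction is the mean over all 1,000 trees.

**PLS.** An optional latent-component transformation fits a PLS regression
of labels on a 10,000-row training subset and projects the remaining rows
onto the smallest number of components explaining ≥ 95 % of summary
variance. It is not part of any default path; its effect on accuracy is
design- and scale-dependent (the framework-comparison run in
`scripts/extended_validation.py` reports the transformed and untransformed
scores side by side).

**Cross-validation.** PODs are selected stratified by label (a set count
per `Ψ` value; unstratified selection is available for free-hyperprior
experiments). For hABC each POD is excluded from its own reference set; for
hRF all PODs are removed once and a single forest serves them all — the
asymmetry is intentional and mirrors how the two estimators are deployed.
Cross-design runs draw PODs from one table (e.g. unbuffered) and infer
against another (e.g. buffered). Scores are Pearson's r and RMSE on the
estimation scale — `Ψ` after the `ψ → Ψ` conversion (`ψ = 0 → Ψ = n` when
all taxa are assigned to events), so full idiosyncrasy and full synchrony
sit at opposite ends of one numeric axis.

## Reproducibility

Every simulation `i` of a run with root seed `s` uses its own SFC64
generator seeded from `SeedSequence(s, spawn_key=(i,))`: runs are
bit-reproducible, and shards covering disjoint index ranges concatenate to
exactly the rows of a single run, so parallelisation never changes results.
Text outputs are written at 6 significant digits with provenance (spec
fingerprint, seed, row counts) sufficient to re-run them.

## Synthetic data and what passing tests show

All test inputs are generated by the package's own simulator under the
hierarchical model; no empirical data ship with the package. The generator
emulates the idealised sampling regime of the inference model itself —
independent panmictic populations, free recombination between SNPs (one SNP
per genealogy), no migration, no selection, no sequencing error, equal
sampling across taxa. Passing cross-validation therefore demonstrates
internal statistical calibration (the estimators recover hyperparameters
from data generated under the assumed model), not robustness to model
misspecification in real data — taxon structure, linked SNPs, uneven
sampling or ascertainment bias are outside what these tests can show.

## Problem sizes and stochastic tolerances

The flagship cross-validation (the truncated `ψ ~ U{0, 1}` buffered
co-expansion design) uses 14,000 reference simulations per pulse-count
value, 5,000 genealogies per SFS, 20 PODs per `Ψ` value and 1,500 retained
simulations for hABC, replicated over three seed streams; the original
experiments used 100,000 simulations per value. Accuracy at this scale is
dominated by a handful of intrinsically ambiguous PODs (pulses old relative
to `N`, whose spectra are near the constant-size limit for every taxon), so
single-replicate Pearson r fluctuates by a few hundredths and RMSE by
several tenths; the seed-replicated mean is the stable quantity reported by
`scripts/acceptance.py`. The longer buffer-comparison and
framework-comparison experiments live in `scripts/extended_validation.py`
at one-tenth of the original table sizes.

## Known limitations

* No recombination within loci, migration, multi-population joint spectra,
  selection, exponential growth or three-epoch histories; folded spectra
  only; no monomorphic-class handling beyond the import dialects.
* The `ψ`-scheme enumeration is combinatorial in `n` and intended for the
  tens-of-taxa regime, not hundreds.
* Composite-likelihood optimisation over the aSFS is deliberately out of
  scope.
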