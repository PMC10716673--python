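# Methods

## The model

`heteroscape` is a spatially explicit, individual-based metacommunity
simulator.  A landscape is a 20×20 toroidal grid of habitat patches (the
dimensions are configurable), each carrying two environmental attributes: a
temperature `T` and a second, unspecified habitat variable `H`.  Patches are
inhabited by annual, asexual organisms belonging to clonal species that
differ in their Gaussian environmental niches and dispersal tendencies.
Communities assemble from external immigration alone — landscapes start
uninhabited — and turn over under temporal environmental fluctuation,
density-dependent competition, and dispersal.

### Landscapes

Attribute fields are fractal random fields produced by 2-D spectral
synthesis: white Gaussian noise is Fourier-filtered with the radial
amplitude spectrum `|f|^-(Hurst+1)` and inverse-transformed.  We chose
spectral synthesis over midpoint displacement because the discrete Fourier
basis is inherently periodic, which makes the landscape an exact torus
(opposite edges connect seamlessly; no edge effects).  The Hurst index
controls spatial autocorrelation: 1 gives smooth landscapes where neighbours
share similar environments, 0 a largely random arrangement.  At Hurst = 0
the `|f|^-1` amplitude still carries mild residual correlation; we accept
this as "largely random".

Each field is standardized empirically to sample mean 0 and sd 1, so the
frequency distribution of environment values is identical across spatial
configurations.  The compositional-heterogeneity multiplier `G` then scales
the field (`sd = G` exactly); `G = 0` is a fully homogeneous landscape.
`T` and `H` fields of one landscape are generated from distinct RNG
substreams with the same Hurst index, hence statistically independent.

Temperature fluctuates globally over time: one standard-normal deviate per
step is added to every patch's scaled `T`.  Fluctuations keep sd = 1
regardless of `G` (heterogeneity scales spatial variation only) and the full
series is pre-generated at initialization.  Landscapes can also be loaded
from whitespace-delimited text files (`<prefix>_T.txt` / `<prefix>_H.txt`,
header `# width=W height=H hurst=X`, row-major values).

### Species

A species is described by six traits fixed at its founding:

| trait | meaning | distribution |
|---|---|---|
| `T_opt`, `H_opt` | niche optima | Normal(0, G) |
| `T_tol`, `H_tol` | niche tolerances | LogNormal(μ=0, σ=1) |
| `P_disp` | dispersal probability | Uniform(0, 1) |
| `P_global` | global-dispersal preference | Uniform(0, 1) |

Immigrants arrive from unspecified regions beyond the landscape, so they
draw niche optima from broader distributions: Normal(`T_trend`, 1.5·G) for
`T_opt` and Normal(0, 1.5·G) for `H_opt`.  `T_trend` = 0 throughout: no
directional temperature trend is simulated.  Log-normal parameters are those of the
underlying normal on the log scale, so the median tolerance is 1.  Every
immigrant individual founds a new species; ids are never reused.

### Life cycle

Each step runs, in fixed order, reproduction → immigration → competition →
dispersal; metrics are recorded after dispersal.

**Reproduction.**  Expected fecundity is

    E_fert = R0 · exp(−(T_eff − T_opt)²/T_tol²) · exp(−(H − H_opt)²/H_tol²)
                · exp(−T_tol²/(2α²)) · exp(−H_tol²/(2α²))

with `T_eff` the scaled patch temperature plus the step's global
fluctuation.  There is deliberately no factor 2 in the mismatch
denominators; the `2α²` factors implement a tolerance–fecundity trade-off
that penalizes broad niches and prevents unbounded generalism.  Offspring
per species are Poisson(n·E_fert); parents die (complete generational
replacement).

**Immigration.**  Each patch receives Poisson(E_immi) immigrants per step,
each founding a new species with abundance 1.  They join the offspring pool
*before* competition: new arrivals are part of the new generation and
compete with it.  The alternative placement (after competition) is kept
behind the `immigration_before_competition` switch for sensitivity
analysis.

**Competition.**  With `L0` total offspring in a patch, each survives
independently with probability `S_A = 1/(1 + a·L0)`, `a = (R0−1)/(K·R0)`;
survivors per species are Binomial(n, S_A) with the same probability for
every species (competition on an equal basis).  `S_A` is interpreted as the
per-offspring survival *probability* — as a count it could not exceed 1 —
which gives expected survivors `L0·S_A`, exactly `K` when `L0 = R0·K`, and a
saturating maximum of `1/a = K·R0/(R0−1) ≈ 160.7`.  Maladaptation lowers
`E_fert` and thereby the realized carrying capacity of a patch.

**Dispersal.**  Each survivor disperses with probability `P_disp`; a
disperser takes random global dispersal with probability `P_global`
(uniform over the other `W·H−1` patches) and otherwise nearest-neighbour
dispersal (uniform over the 8 Moore neighbours, 1/8 each, with toroidal
wrap).  Dispersal conserves the total population exactly.

### Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `R0` | 15 | intrinsic maximum expected offspring |
| `K` | 150 individuals | patch carrying capacity at perfect fitness |
| `α` | 3 | tolerance trade-off strength (lower = stronger) |
| `E_immi` | 2.5 patch⁻¹ step⁻¹ | expected immigrants |
| `G` | grid {0, 0.05, 0.1, 0.3, 0.7, 1, 1.3, 1.7} | heterogeneity multiplier |
| Hurst | {0, 1} | spatial autocorrelation |
| grid | 20×20 patches | landscape dimensions |
| `t_max` | 10,000 steps | full run length |

All attribute values, optima and tolerances are unitless (standardized
environment scale); abundances are individuals; time is in non-overlapping
generations.  The landscape carrying capacity at perfect fitness is
`20·20·150 = 60,000` individuals, and immigration amounts to
`2.5/2250 ≈ 0.0011` of a perfectly adapted patch's offspring production.

## Implementation notes

State is count-aggregated: parallel arrays of (patch, species, count)
triples, one entry per occupied pair.  All phases draw from the exact
aggregation of the per-individual rules (Poisson sums, binomial splits, a
multinomial over the 8 neighbour offsets; global targets are drawn per
individual).  The test suite verifies distributional identity against a
literal per-individual oracle.  A single `numpy` PCG64 generator per run
makes runs bit-reproducible from their seed; experiment grids derive per-run
seeds from (base seed, G, Hurst, landscape, replicate) via `SeedSequence`,
so a manifest row alone reproduces its run.

Numerical conventions: Shannon–Wiener diversity uses the natural log
(base-free orderings are unaffected); the empty community has H′ = 0;
landscape H′ is computed on pooled counts, never by averaging patch values.
Empirical standardization of landscape fields is exact per realization
(mean 0, sd 1 to 1e-9).  Degenerate cases: `G = 0` collapses optima to
point masses and the landscape to homogeneity; `E_immi = 0` with an empty
start stays empty forever; an all-zero field cannot be standardized and is
rejected.

## Scaled replication profile

The full experiment (16 scenarios × 10 landscapes × 3 replicates × 10,000
steps) is available through `run_experiment` but takes CPU-days.  The
package's own verification profile, used by the acceptance script and test
suite, is:

- **Plateau/colonization:** one run, G = 0.3, Hurst = 1, 2,000 steps;
  population median over steps 500–2,000.
- **Response grid:** 8 G × 2 Hurst × 3 independent 1,000-step runs
  (distinct landscapes and seeds); landscape metrics summarized over steps
  500–1,000, patch metrics at the final step.

At this scale the fast, strongly expressed patterns reproduce: rapid
colonization (<50 steps), a stable plateau slightly below 60,000, landscape
diversity increasing with G while landscape richness falls beyond G = 0.1,
and declining temporal variance of landscape diversity with G.  Patterns
that in the full study emerge from long-run competitive exclusion and heavy
replication are not resolved at this scale.  After 1,000 steps homogeneous
landscapes have not yet purged their transient immigrant richness, so
patch-level diversity is nearly flat in G and its maximizing G value is
noise-dominated across seeds; probes at 3,000 steps recover the low-G flank
of the unimodal patch-diversity pattern (patch diversity collapses toward
zero as G → 0) but not the decline beyond G = 0.3, and the temporal
variance of landscape *richness* does not yet decline with G while the
colonization transient still dominates the recording window.  The
corresponding checks are retained at the documented scale rather than
re-tuned, and their failures there are reported as-is.

## What the generator does and does not emulate

The synthetic landscapes and trait draws reproduce the study's generating
process itself, so passing tests show the simulator implements that process
faithfully — they say nothing about real landscapes, which have
non-Gaussian attribute distributions, correlated environmental axes,
anisotropy, true boundaries instead of a torus, and species with
demographic structure, mutation, and informed dispersal.  Within the model,
known limitations are: only two dispersal modes, both uninformed; no
overlapping generations, dormancy, mutation, or trophic interactions; and
fluctuations that are perfectly global and serially uncorrelated.
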