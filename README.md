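# heteroscape

An individual-based metacommunity simulator for studying how landscape
structure shapes biodiversity.  Guilds of annual, asexual species live on
toroidal fractal landscapes, reproduce according to Gaussian environmental
niches, compete under Beverton–Holt density dependence, disperse by
nearest-neighbour or random global movement, and are continually replenished
by external immigration.  Two landscape knobs drive the experiments:

- **G** — compositional heterogeneity: the standardized environmental
  fields are multiplied by G, widening or shrinking the range of
  environments present;
- **Hurst index** — spatial autocorrelation of the fractal fields: 1 gives
  smooth landscapes, 0 a largely random mosaic.

The simulator reports species richness and Shannon–Wiener diversity
(H′ = −Σ pᵢ ln pᵢ) at the patch and landscape scales, which respond to G
and Hurst in opposite ways at the two scales.  It is aimed at spatial
ecologists exploring community-assembly mechanisms — mass effects,
heterogeneity-driven beta diversity, immigrant turnover — with a fully
reproducible, seeded experiment pipeline.

## Model core

Each time step (one non-overlapping generation) runs four phases per patch:

1. **Reproduction**: offspring per parent ~ Poisson(E_fert) with

   E_fert = R₀ · e^(−(T_eff−T_opt)²/T_tol²) · e^(−(H−H_opt)²/H_tol²)
            · e^(−T_tol²/2α²) · e^(−H_tol²/2α²)

   where T_eff is the G-scaled patch temperature plus a global standard-
   normal fluctuation for the step, and the last two factors are a
   tolerance–fecundity trade-off (α = 3).
2. **Immigration**: Poisson(E_immi = 2.5) new individuals per patch, each
   founding a new species with optima ~ Normal(0, 1.5·G).
3. **Competition**: every offspring in a patch survives with probability
   S_A = 1/(1 + a·L₀), a = (R₀−1)/(K·R₀), so a perfectly adapted patch
   equilibrates at K = 150 individuals (landscape capacity 20·20·150 =
   60,000).
4. **Dispersal**: with probability P_disp an individual leaves its natal
   patch — globally (uniform over the other 399 patches) with probability
   P_global, otherwise to one of its 8 toroidally wrapped Moore neighbours.

See `docs/methods.md` for the full model description, parameter table, and
numerical conventions.

## Worked example

```python
import heteroscape as hs

cfg = hs.ScenarioConfig(g=0.3, hurst=1.0, t_max=300, seed=42)
ts, census, patches = hs.run(cfg)
print(ts.iloc[[0, 49, 299]])
print("patch-level mean richness:", round(patches["richness"].mean(), 2))
```

prints

```
     step  total_population  richness   shannon
0       1               966       966  6.873164
49     50             58281       370  3.836526
299   300             57814       219  2.345546
patch-level mean richness: 9.75
```

Reading this: the landscape starts uninhabited; step 1 holds only that
step's surviving immigrants (966 singleton species, hence H′ = ln 966 ≈
6.87).  Within 50 steps the population colonizes to a plateau just below
the 60,000-individual landscape capacity, while richness falls as
competition sorts the community; by step 300 some 219 species persist
landscape-wide (H′ ≈ 2.35), of which about 10 coexist per patch on
average.

The same run is available from the shell:

```sh
heteroscape landscape --hurst 1 --seed 7 --out land     # write land_T.txt / land_H.txt
heteroscape run --seed 42 --out myrun                   # timeseries/census/patches CSVs
heteroscape experiment --landscapes 10 --replicates 3 --out exp   # full scenario grid
heteroscape plot --experiment exp                       # response-curve figure
```

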