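"""One generation of the annual life cycle.

Organisms are annual and asexual with complete generational replacement.
Each time step runs four phases in a fixed order:

1. **Reproduction** — every parent produces Poisson-distributed offspring
   with expectation given by its Gaussian niche fitness,

   ``E_fert = R0 * exp(-(T_eff - T_opt)^2 / T_tol^2)
            * exp(-(H_patch - H_opt)^2 / H_tol^2)
            * exp(-T_tol^2 / (2 alpha^2)) * exp(-H_tol^2 / (2 alpha^2))``

   The last two factors are a tolerance–fecundity trade-off: broader niche
   tolerance costs maximum fecundity, preventing unbounded generalism.
   Parents die after reproducing.
2. **Immigration** — each patch independently receives Poisson(E_immi) new
   immigrant individuals, each founding a brand-new species; they join the
   patch's offspring pool.
3. **Competition** — density-dependent Beverton–Holt survival: with L0
   offspring in a patch, each survives independently with probability
   ``S_A = 1 / (1 + a * L0)`` where ``a = (R0 - 1) / (K * R0)``, so a patch
   of perfectly adapted organisms equilibrates at K survivors.  All species
   compete on an equal basis (identical survival probability).
4. **Dispersal** — each survivor leaves its natal patch with probability
   ``p_disp``; a disperser uses random global dispersal with probability
   ``p_global`` (uniform over the other W*H - 1 patches), otherwise moves to
   one of its 8 Moore neighbours, uniformly, with toroidal wrap-around.

State is count-aggregated: parallel arrays ``(patch, species, count)`` hold
one entry per occupied (patch, species) pair.  Because conspecifics are
identical clones and all random draws are Poisson/binomial/multinomial
aggregations of the per-individual rules, this representation is
distributionally identical to simulating every individual (verified against
a per-individual brute-force oracle in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .species import ImmigrantTraitConfig, SpeciesRegistry, SpeciesTraits

__all__ = [
    "DemographicParams",
    "expected_fertility",
    "fertility_profile",
    "reproduce",
    "survival_probability",
    "compete",
    "disperse",
    "immigrate",
    "MOORE_OFFSETS",
]

# The 8 Moore-neighbourhood offsets (dx, dy), each chosen with probability
# 1/8 by a nearest-neighbour disperser (the (0,0) self-move is excluded).
MOORE_OFFSETS = np.array(
    [(dx, dy) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dx, dy) != (0, 0)],
    dtype=np.int64,
)
_UNIFORM8 = np.full(8, 1.0 / 8.0)


@dataclass(frozen=True)
class DemographicParams:
    """Demographic constants of the life cycle.

    ``r0``: intrinsic maximum expected offspring per parent (15).
    ``k``: patch carrying capacity when every organism has perfect fitness
    (150 individuals).
    ``alpha``: tolerance trade-off strength; lower alpha penalizes broad
    niche tolerances more strongly (3).
    The Beverton–Holt coefficient ``a = (r0 - 1) / (k * r0)`` is derived.
    """

    r0: float = 15.0
    k: int = 150
    alpha: float = 3.0

    def __post_init__(self) -> None:
        if self.r0 <= 1:
            raise ValueError("R0 must exceed 1")
        if self.k < 1:
            raise ValueError("K must be at least 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def a(self) -> float:
        return (self.r0 - 1.0) / (self.k * self.r0)


def fertility_profile(
    t_opt,
    t_tol,
    h_opt,
    h_tol,
    t_eff,
    h_patch,
    params: DemographicParams,
):
    """Vectorized expected fecundity; all arguments broadcast.

    No factor 2 appears in the niche-mismatch denominators (the mismatch
    term is ``(dT)^2 / T_tol^2``); the factor 2 appears only in the
    trade-off denominators ``2 alpha^2``.
    """
    t_tol2 = np.square(t_tol)
    h_tol2 = np.square(h_tol)
    two_a2 = 2.0 * params.alpha**2
    log_f = (
        -np.square(t_eff - t_opt) / t_tol2
        - np.square(h_patch - h_opt) / h_tol2
        - t_tol2 / two_a2
        - h_tol2 / two_a2
    )
    return params.r0 * np.exp(log_f)


def expected_fertility(
    traits: SpeciesTraits,
    t_eff: float,
    h_patch: float,
    params: DemographicParams,
) -> float:
    """Expected offspring number of one species in one patch environment.

    Lies in (0, R0]; approaches R0 for a perfectly matched specialist with
    vanishing tolerances.
    """
    if traits.t_tol <= 0 or traits.h_tol <= 0:
        raise ValueError("niche tolerances must be strictly positive")
    return float(
        fertility_profile(
            traits.t_opt, traits.t_tol, traits.h_opt, traits.h_tol,
            t_eff, h_patch, params,
        )
    )


def reproduce(
    patch: np.ndarray,
    species: np.ndarray,
    counts: np.ndarray,
    registry: SpeciesRegistry,
    t_eff: np.ndarray,
    h_patch: np.ndarray,
    params: DemographicParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fitness-dependent reproduction with complete parental replacement.

    ``t_eff`` / ``h_patch`` are flat per-patch environment arrays for the
    current step.  A species with n parents and fecundity E_fert leaves
    Poisson(n * E_fert) offspring — the exact aggregation of n independent
    Poisson(E_fert) draws.  Returns the offspring pool as a new
    (patch, species, count) triple; zero-count entries are dropped.
    """
    if len(patch) == 0:
        return patch, species, counts
    fert = fertility_profile(
        registry.trait("t_opt")[species],
        registry.trait("t_tol")[species],
        registry.trait("h_opt")[species],
        registry.trait("h_tol")[species],
        t_eff[patch],
        h_patch[patch],
        params,
    )
    offspring = rng.poisson(counts * fert)
    keep = offspring > 0
    return patch[keep], species[keep], offspring[keep]


def survival_probability(l0, params: DemographicParams):
    """Beverton–Holt per-offspring survival probability 1 / (1 + a * L0).

    Equals 1 in an empty patch and decreases monotonically with the total
    offspring pool L0; expected survivors L0 * S_A saturate at
    1/a = K*R0/(R0-1) and equal exactly K when L0 = R0*K.
    """
    l0 = np.asarray(l0)
    if np.any(l0 < 0):
        raise ValueError("total offspring L0 must be non-negative")
    return 1.0 / (1.0 + params.a * l0)


def compete(
    patch: np.ndarray,
    species: np.ndarray,
    counts: np.ndarray,
    params: DemographicParams,
    n_patches: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Density-dependent competition among all offspring of a patch.

    Every offspring in a patch survives independently with the same
    probability S_A(L0) regardless of species; per-species survivor counts
    are Binomial(n_species, S_A).  Species identity is conserved (survivors
    are a subset of offspring species); zero-count species are removed.
    """
    if len(patch) == 0:
        return patch, species, counts
    l0 = np.bincount(patch, weights=counts, minlength=n_patches)
    p_surv = survival_probability(l0, params)
    survivors = rng.binomial(counts, p_surv[patch])
    keep = survivors > 0
    return patch[keep], species[keep], survivors[keep]


def immigrate(
    n_patches: int,
    g: float,
    cfg: ImmigrantTraitConfig,
    registry: SpeciesRegistry,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """External immigration into every patch.

    Each patch independently receives Poisson(e_immi) immigrants; every
    immigrant founds a new species (fresh id, immigrant trait distributions)
    with abundance 1.  Returns the immigrant (patch, species, count) triple,
    to be merged into the offspring pool before competition.
    """
    if cfg.e_immi == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), empty.copy()
    arrivals = rng.poisson(cfg.e_immi, n_patches)
    total = int(arrivals.sum())
    ids = registry.draw_immigrant_traits(g, cfg, rng, n=total)
    patch = np.repeat(np.arange(n_patches, dtype=np.int64), arrivals)
    return patch, ids, np.ones(total, dtype=np.int64)


def _merge(
    patch: np.ndarray, species: np.ndarray, counts: np.ndarray, n_species: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum counts of duplicate (patch, species) pairs."""
    key = patch.astype(np.int64) * np.int64(n_species) + species
    uniq, inverse = np.unique(key, return_inverse=True)
    summed = np.bincount(inverse, weights=counts).astype(np.int64)
    return (uniq // n_species).astype(np.int64), (uniq % n_species), summed


def disperse(
    patch: np.ndarray,
    species: np.ndarray,
    counts: np.ndarray,
    registry: SpeciesRegistry,
    width: int,
    height: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-mode dispersal of the post-competition survivors.

    Per individual: disperse with probability p_disp of its species; a
    disperser takes random global dispersal with probability p_global
    (uniform over the W*H - 1 non-natal patches), otherwise moves to one of
    the 8 toroidally wrapped Moore neighbours with probability 1/8 each.
    Implemented by binomial splits (stay/disperse, global/neighbour), a
    multinomial over the 8 neighbour offsets, and literal per-individual
    uniform draws for global targets — distributionally identical to the
    per-individual rule.  Total population is conserved exactly.
    """
    if len(patch) == 0:
        return patch, species, counts
    n_patches = width * height
    p_disp = registry.trait("p_disp")[species]
    p_global = registry.trait("p_global")[species]

    dispersers = rng.binomial(counts, p_disp)
    stay_counts = counts - dispersers
    global_counts = rng.binomial(dispersers, p_global)
    nb_counts = dispersers - global_counts

    parts_patch = [patch]
    parts_species = [species]
    parts_counts = [stay_counts]

    nb_mask = nb_counts > 0
    if nb_mask.any():
        src = np.flatnonzero(nb_mask)
        split = rng.multinomial(nb_counts[src], _UNIFORM8)  # (m, 8)
        x = patch[src] % width
        y = patch[src] // width
        tx = (x[:, None] + MOORE_OFFSETS[:, 0]) % width
        ty = (y[:, None] + MOORE_OFFSETS[:, 1]) % height
        target = ty * width + tx  # (m, 8)
        parts_patch.append(target.ravel())
        parts_species.append(np.repeat(species[src], 8))
        parts_counts.append(split.ravel())

    g_mask = global_counts > 0
    if g_mask.any():
        src = np.flatnonzero(g_mask)
        reps = global_counts[src]
        origin = np.repeat(patch[src], reps)
        target = rng.integers(0, n_patches - 1, size=len(origin))
        target += target >= origin  # uniform over the non-natal patches
        parts_patch.append(target)
        parts_species.append(np.repeat(species[src], reps))
        parts_counts.append(np.ones(len(origin), dtype=np.int64))

    all_patch = np.concatenate(parts_patch)
    all_species = np.concatenate(parts_species)
    all_counts = np.concatenate(parts_counts)
    nz = all_counts > 0
    return _merge(
        all_patch[nz], all_species[nz], all_counts[nz], registry.n_species
    )
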