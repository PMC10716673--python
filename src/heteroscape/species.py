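"""Species traits and the stochastic trait generators.

Every species is a clonal lineage identified by an integer id and described
by six trait values fixed at the moment the species first appears:

==============  =========================================================
``t_opt``       temperature niche optimum            Normal(0, G)
``t_tol``       temperature niche tolerance (> 0)    LogNormal(mu=0, sigma=1)
``h_opt``       habitat niche optimum                Normal(0, G)
``h_tol``       habitat niche tolerance (> 0)        LogNormal(mu=0, sigma=1)
``p_disp``      probability of dispersing            Uniform(0, 1)
``p_global``    preference for global dispersal      Uniform(0, 1)
==============  =========================================================

Immigrants arriving from outside the landscape draw their niche optima from
broader distributions, Normal(t_trend, 1.5*G) for ``t_opt`` and
Normal(0, 1.5*G) for ``h_opt``; tolerances and dispersal traits follow the
initialization distributions.  Every immigrant individual founds a new
species, so species ids are unique for the lifetime of a run and never
reused.  Log-normal parameters are those of the underlying normal on the
log scale (median tolerance = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpeciesTraits",
    "ImmigrantTraitConfig",
    "SpeciesRegistry",
    "TRAIT_NAMES",
]

TRAIT_NAMES = ("t_opt", "t_tol", "h_opt", "h_tol", "p_disp", "p_global")


@dataclass(frozen=True)
class SpeciesTraits:
    """Trait record of a single species."""

    species_id: int
    t_opt: float
    t_tol: float
    h_opt: float
    h_tol: float
    p_disp: float
    p_global: float

    def __post_init__(self) -> None:
        if self.t_tol <= 0 or self.h_tol <= 0:
            raise ValueError("niche tolerances must be strictly positive")
        if not (0.0 <= self.p_disp <= 1.0 and 0.0 <= self.p_global <= 1.0):
            raise ValueError("dispersal probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class ImmigrantTraitConfig:
    """Parameters of the immigrant trait distributions.

    ``t_trend`` shifts the mean of immigrant temperature optima (0 here: no
    directional temperature trend is simulated); ``optimum_sd_factor``
    multiplies G to broaden immigrant optimum distributions relative to the
    initialization distributions; ``e_immi`` is the expected number of
    immigrants per patch per time step.
    """

    t_trend: float = 0.0
    optimum_sd_factor: float = 1.5
    e_immi: float = 2.5

    def __post_init__(self) -> None:
        if self.e_immi < 0:
            raise ValueError("e_immi must be non-negative")


class SpeciesRegistry:
    """Append-only store of species traits, indexed by species id.

    Trait values live in parallel numpy arrays so that per-step fitness and
    dispersal computations can gather traits for thousands of species in one
    vectorized indexing operation.  Ids are consecutive integers starting at
    0; extinct species keep their slot (the id space is never reused), which
    also preserves the full trait archive for the final census.
    """

    _GROW = 1024

    def __init__(self) -> None:
        self._n = 0
        self._cap = self._GROW
        self._traits = {name: np.empty(self._cap) for name in TRAIT_NAMES}

    def __len__(self) -> int:
        return self._n

    @property
    def n_species(self) -> int:
        return self._n

    def _ensure(self, extra: int) -> None:
        need = self._n + extra
        if need <= self._cap:
            return
        while self._cap < need:
            self._cap *= 2
        for name in TRAIT_NAMES:
            arr = np.empty(self._cap)
            arr[: self._n] = self._traits[name][: self._n]
            self._traits[name] = arr

    def trait(self, name: str) -> np.ndarray:
        """View of one trait array over all registered species."""
        return self._traits[name][: self._n]

    def __getitem__(self, species_id: int) -> SpeciesTraits:
        if not 0 <= species_id < self._n:
            raise KeyError(species_id)
        return SpeciesTraits(
            species_id=species_id,
            **{name: float(self._traits[name][species_id]) for name in TRAIT_NAMES},
        )

    # -- trait generation ---------------------------------------------------

    def _register(
        self,
        n: int,
        opt_mean: float,
        opt_sd: float,
        rng: np.random.Generator,
    ) -> np.ndarray:
        self._ensure(n)
        lo, hi = self._n, self._n + n
        tr = self._traits
        tr["t_opt"][lo:hi] = rng.normal(opt_mean, opt_sd, n) if opt_sd > 0 else opt_mean
        tr["h_opt"][lo:hi] = rng.normal(0.0, opt_sd, n) if opt_sd > 0 else 0.0
        tr["t_tol"][lo:hi] = rng.lognormal(0.0, 1.0, n)
        tr["h_tol"][lo:hi] = rng.lognormal(0.0, 1.0, n)
        tr["p_disp"][lo:hi] = rng.uniform(0.0, 1.0, n)
        tr["p_global"][lo:hi] = rng.uniform(0.0, 1.0, n)
        self._n = hi
        return np.arange(lo, hi, dtype=np.int64)

    def draw_initial_traits(
        self, g: float, rng: np.random.Generator, n: int = 1
    ) -> np.ndarray:
        """Register ``n`` new species with initialization-distribution traits.

        Optima ~ Normal(0, G) (a point mass at 0 when G = 0).  Returns the
        fresh species ids.
        """
        if g < 0:
            raise ValueError("G must be non-negative")
        return self._register(n, 0.0, g, rng)

    def draw_immigrant_traits(
        self,
        g: float,
        cfg: ImmigrantTraitConfig,
        rng: np.random.Generator,
        n: int = 1,
    ) -> np.ndarray:
        """Register ``n`` immigrant-founded species.

        Optima are drawn from the broader immigrant distributions:
        t_opt ~ Normal(t_trend, 1.5*G), h_opt ~ Normal(0, 1.5*G).  Each
        immigrant founds its own new species; returns the fresh ids.
        """
        if g < 0:
            raise ValueError("G must be non-negative")
        return self._register(n, cfg.t_trend, cfg.optimum_sd_factor * g, rng)

    def add_species(
        self,
        t_opt: float = 0.0,
        t_tol: float = 1.0,
        h_opt: float = 0.0,
        h_tol: float = 1.0,
        p_disp: float = 0.0,
        p_global: float = 0.0,
    ) -> int:
        """Register one species with explicit trait values.

        For controlled experiments (e.g. monocultures with dispersal turned
        off); validates the trait invariants and returns the fresh id.
        """
        SpeciesTraits(0, t_opt, t_tol, h_opt, h_tol, p_disp, p_global)
        self._ensure(1)
        vals = dict(t_opt=t_opt, t_tol=t_tol, h_opt=h_opt, h_tol=h_tol,
                    p_disp=p_disp, p_global=p_global)
        for name in TRAIT_NAMES:
            self._traits[name][self._n] = vals[name]
        self._n += 1
        return self._n - 1

    # -- export -------------------------------------------------------------

    def as_table(self) -> dict[str, np.ndarray]:
        """Registry contents as column arrays (census serialization)."""
        out: dict[str, np.ndarray] = {
            "species_id": np.arange(self._n, dtype=np.int64)
        }
        for name in TRAIT_NAMES:
            out[name] = self.trait(name).copy()
        return out
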