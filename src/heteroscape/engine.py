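"""Simulation orchestration: configuration, state, the step schedule, runs,
and the scenario/replicate experiment grid.

A run starts from an uninhabited landscape; external immigrants colonize it
over time.  Each step executes, in fixed order: reproduction at the step's
effective environment, immigration into the offspring pools, density-
dependent competition, and dispersal of the survivors.  Landscape metrics
(total population, richness, pooled Shannon diversity) are recorded at the
end of every step, after dispersal; the per-patch census is taken at the
final step.

All randomness flows through one numpy Generator seeded from the scenario
seed, so identical seeds give bit-identical runs.  Experiment grids derive
per-run seeds deterministically from (base_seed, G, hurst, landscape_id,
replicate_id) via a SeedSequence, so the manifest alone reproduces any run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import lifecycle, metrics
from .landscape import (
    FluctuationSeries,
    LandscapeGrid,
    effective_temperature,
    generate_fluctuations,
    generate_landscape,
)
from .lifecycle import DemographicParams
from .species import ImmigrantTraitConfig, SpeciesRegistry

__all__ = [
    "ScenarioConfig",
    "CommunityState",
    "initialize",
    "step",
    "run",
    "run_experiment",
    "derive_seed_sequence",
    "load_config",
    "save_config",
]

# Replication scenario grid: 8 heterogeneity levels x 2 autocorrelation levels.
G_GRID = (0.0, 0.05, 0.1, 0.3, 0.7, 1.0, 1.3, 1.7)
HURST_GRID = (0.0, 1.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """All parameters of one simulation run (defaults = the study values)."""

    g: float = 0.3
    hurst: float = 1.0
    width: int = 20
    height: int = 20
    t_max: int = 10_000
    r0: float = 15.0
    k: int = 150
    alpha: float = 3.0
    e_immi: float = 2.5
    t_trend: float = 0.0
    optimum_sd_factor: float = 1.5
    seed: int = 0
    landscape_id: int = 0
    replicate_id: int = 0
    # Immigrants join the offspring pool before the competition phase; the
    # alternative (arrival after competition, escaping density regulation in
    # the arrival step) is kept behind this switch for sensitivity checks.
    immigration_before_competition: bool = True

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("G must be non-negative")
        if not 0.0 <= self.hurst <= 1.0:
            raise ValueError("hurst must lie in [0, 1]")
        if self.width < 2 or self.height < 2:
            raise ValueError("landscape dimensions must be >= 2")
        if self.t_max < 0:
            raise ValueError("t_max must be non-negative")

    @property
    def n_patches(self) -> int:
        return self.width * self.height

    def demographic_params(self) -> DemographicParams:
        return DemographicParams(r0=self.r0, k=self.k, alpha=self.alpha)

    def immigrant_config(self) -> ImmigrantTraitConfig:
        return ImmigrantTraitConfig(
            t_trend=self.t_trend,
            optimum_sd_factor=self.optimum_sd_factor,
            e_immi=self.e_immi,
        )


@dataclass
class CommunityState:
    """Full simulation state at one step.

    Patch occupancy is count-aggregated: ``patch``, ``species`` and
    ``counts`` are parallel arrays with one entry per occupied
    (patch, species) pair; patch index = y * width + x.
    """

    step: int
    patch: np.ndarray
    species: np.ndarray
    counts: np.ndarray
    registry: SpeciesRegistry
    landscape: LandscapeGrid
    fluctuations: FluctuationSeries

    @property
    def total_population(self) -> int:
        return int(self.counts.sum())

    def species_totals(self) -> tuple[np.ndarray, np.ndarray]:
        """Pooled landscape-wide (species_id, abundance)."""
        if len(self.species) == 0:
            return self.species, self.counts
        uniq, inverse = np.unique(self.species, return_inverse=True)
        totals = np.bincount(inverse, weights=self.counts).astype(np.int64)
        return uniq, totals

    def patch_population(self, x: int, y: int) -> dict[int, int]:
        """Species -> count map of one patch (toroidal coordinates)."""
        x, y = self.landscape.wrap(x, y)
        idx = self.patch == y * self.landscape.width + x
        return dict(
            zip(self.species[idx].tolist(), self.counts[idx].tolist())
        )

    def landscape_record(self) -> dict:
        """Landscape-level metrics row for the current step."""
        _, totals = self.species_totals()
        return {
            "step": self.step,
            "total_population": self.total_population,
            "richness": len(totals),
            "shannon": metrics.shannon_from_counts(totals.astype(float)),
        }


def initialize(config: ScenarioConfig, landscape: LandscapeGrid) -> CommunityState:
    """Build the uninhabited initial state for one run.

    Pre-generates the full fluctuation series (length t_max) from the
    scenario seed before the run starts.
    """
    if (landscape.width, landscape.height) != (config.width, config.height):
        raise ValueError(
            f"landscape is {landscape.width}x{landscape.height}, config wants "
            f"{config.width}x{config.height}"
        )
    rng = np.random.default_rng(config.seed)
    empty = np.empty(0, dtype=np.int64)
    return CommunityState(
        step=0,
        patch=empty,
        species=empty.copy(),
        counts=empty.copy(),
        registry=SpeciesRegistry(),
        landscape=landscape,
        fluctuations=generate_fluctuations(config.t_max, rng),
    )


def step(
    state: CommunityState,
    config: ScenarioConfig,
    rng: np.random.Generator,
    *,
    t_scaled: np.ndarray | None = None,
    h_scaled: np.ndarray | None = None,
) -> CommunityState:
    """Advance the community by one generation (mutates and returns state).

    Phase order: reproduction -> immigration -> competition -> dispersal.
    The step's environment is the G-scaled base fields plus the step's
    global temperature fluctuation.
    """
    if state.step >= config.t_max:
        raise ValueError(f"run already finished at step {state.step}")
    if t_scaled is None:
        t_scaled = state.landscape.scaled_t().ravel()
    if h_scaled is None:
        h_scaled = state.landscape.scaled_h().ravel()
    params = config.demographic_params()
    immi_cfg = config.immigrant_config()
    t_eff = effective_temperature(t_scaled, state.fluctuations[state.step])

    patch, species, counts = lifecycle.reproduce(
        state.patch, state.species, state.counts,
        state.registry, t_eff, h_scaled, params, rng,
    )
    if config.immigration_before_competition:
        ip, is_, ic = lifecycle.immigrate(
            config.n_patches, config.g, immi_cfg, state.registry, rng
        )
        patch = np.concatenate([patch, ip])
        species = np.concatenate([species, is_])
        counts = np.concatenate([counts, ic])
    patch, species, counts = lifecycle.compete(
        patch, species, counts, params, config.n_patches, rng
    )
    if not config.immigration_before_competition:
        ip, is_, ic = lifecycle.immigrate(
            config.n_patches, config.g, immi_cfg, state.registry, rng
        )
        patch = np.concatenate([patch, ip])
        species = np.concatenate([species, is_])
        counts = np.concatenate([counts, ic])
    patch, species, counts = lifecycle.disperse(
        patch, species, counts, state.registry,
        config.width, config.height, rng,
    )
    state.patch, state.species, state.counts = patch, species, counts
    state.step += 1
    return state


def run(
    config: ScenarioConfig,
    landscape: LandscapeGrid | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run one full simulation.

    Returns ``(timeseries, census, patches)``: one landscape-level record
    per step (recorded after dispersal), the final per-patch census, and the
    per-patch summary table.  If no landscape is given one is generated from
    the scenario seed with the configured Hurst index.
    """
    rng = np.random.default_rng(config.seed)
    land_rng, run_rng = rng.spawn(2)
    if landscape is None:
        landscape = generate_landscape(
            config.width, config.height, config.hurst, land_rng, g=config.g
        )
    elif landscape.g != config.g:
        landscape = dataclasses.replace(landscape, g=config.g)
    state = initialize(config, landscape)
    t_scaled = landscape.scaled_t().ravel()
    h_scaled = landscape.scaled_h().ravel()
    records = []
    for _ in range(config.t_max):
        step(state, config, run_rng, t_scaled=t_scaled, h_scaled=h_scaled)
        records.append(state.landscape_record())
    columns = ["step", "total_population", "richness", "shannon"]
    timeseries = pd.DataFrame(records, columns=columns)
    census = metrics.census_table(state)
    patches = metrics.patch_summaries(state)
    return timeseries, census, patches


def derive_seed_sequence(
    base_seed: int, g: float, hurst: float, landscape_id: int, replicate_id: int
) -> np.random.SeedSequence:
    """Deterministic per-run seed material from the scenario coordinates."""
    return np.random.SeedSequence(
        entropy=[
            int(base_seed),
            int(round(g * 10_000)),
            int(round(hurst * 10_000)),
            int(landscape_id),
            int(replicate_id),
        ]
    )


def _run_seed(base_seed, g, hurst, landscape_id, replicate_id) -> int:
    seq = derive_seed_sequence(base_seed, g, hurst, landscape_id, replicate_id)
    return int(seq.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_experiment(
    out_dir: str | Path,
    g_values=G_GRID,
    hurst_values=HURST_GRID,
    n_landscapes: int = 10,
    n_replicates: int = 3,
    base_seed: int = 0,
    t_max: int = 10_000,
    overwrite: bool = False,
    **config_overrides,
) -> pd.DataFrame:
    """Run the full scenario grid and write per-run outputs plus a manifest.

    For each (G, hurst) cell, ``n_landscapes`` landscapes are generated
    (shared across that cell's replicates) and each is run ``n_replicates``
    times with distinct derived seeds.  Each run writes timeseries.csv,
    census.csv and patches.csv under ``out_dir/run_<index>/``; the manifest
    (run -> G, hurst, landscape_id, replicate_id, seed) is written to
    ``out_dir/manifest.csv`` and returned.
    """
    if n_landscapes < 1 or n_replicates < 1:
        raise ValueError("n_landscapes and n_replicates must be >= 1")
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; pass overwrite=True to replace it"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    run_index = 0
    for g in g_values:
        for hurst in hurst_values:
            for land_id in range(n_landscapes):
                # replicate slot 2**20 is reserved for landscape generation,
                # so the landscape stream never collides with a run stream
                land_seq = derive_seed_sequence(base_seed, g, hurst, land_id, 2**20)
                land = generate_landscape(
                    config_overrides.get("width", 20),
                    config_overrides.get("height", 20),
                    hurst,
                    np.random.default_rng(land_seq),
                    g=g,
                )
                for rep in range(n_replicates):
                    seed = _run_seed(base_seed, g, hurst, land_id, rep)
                    cfg = ScenarioConfig(
                        g=g, hurst=hurst, t_max=t_max, seed=seed,
                        landscape_id=land_id, replicate_id=rep,
                        **config_overrides,
                    )
                    ts, census, patches = run(cfg, land)
                    run_dir = out_dir / f"run_{run_index:04d}"
                    run_dir.mkdir(exist_ok=True)
                    ts.to_csv(run_dir / "timeseries.csv", index=False)
                    census.to_csv(run_dir / "census.csv", index=False)
                    patches.to_csv(run_dir / "patches.csv", index=False)
                    rows.append(
                        {
                            "run": run_index,
                            "g": g,
                            "hurst": hurst,
                            "landscape_id": land_id,
                            "replicate_id": rep,
                            "seed": seed,
                            "path": str(run_dir),
                        }
                    )
                    run_index += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    return manifest


def run_grid_summary(
    g_values=G_GRID,
    hurst_values=HURST_GRID,
    n_runs: int = 3,
    t_max: int = 1000,
    base_seed: int = 0,
    burn_in: int | None = None,
    **config_overrides,
) -> pd.DataFrame:
    """Run a (G, hurst) scenario grid in memory and summarize each run.

    Each grid cell gets ``n_runs`` independent runs (distinct landscapes and
    derived seeds).  Returns one row per run with the landscape-level median
    and variance of richness and Shannon diversity over the post-burn-in
    window (default: second half of the run), the median total population
    over that window, and the mean patch richness/Shannon at the final step.
    """
    if burn_in is None:
        burn_in = t_max // 2
    rows = []
    for g in g_values:
        for hurst in hurst_values:
            for i in range(n_runs):
                seed = _run_seed(base_seed, g, hurst, i, 0)
                cfg = ScenarioConfig(
                    g=g, hurst=hurst, t_max=t_max, seed=seed,
                    landscape_id=i, **config_overrides,
                )
                ts, _, patches = run(cfg)
                win = ts[ts["step"] >= burn_in]
                rows.append(
                    {
                        "g": g,
                        "hurst": hurst,
                        "run": i,
                        "seed": seed,
                        "median_population": float(win["total_population"].median()),
                        "median_richness": float(win["richness"].median()),
                        "var_richness": float(win["richness"].var()),
                        "median_shannon": float(win["shannon"].median()),
                        "var_shannon": float(win["shannon"].var()),
                        "mean_patch_richness": float(patches["richness"].mean()),
                        "mean_patch_shannon": float(patches["shannon"].mean()),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flat key-value configuration files
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {f.name: f.type for f in dataclasses.fields(ScenarioConfig)}


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario as `key = value` lines."""
    lines = [
        f"{f.name} = {getattr(config, f.name)}"
        for f in dataclasses.fields(ScenarioConfig)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path, **overrides) -> ScenarioConfig:
    """Read a `key = value` scenario file; keyword overrides win."""
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = (tok.strip() for tok in line.partition("="))
        if key not in _CONFIG_FIELDS:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = val
    values.update({k: str(v) for k, v in overrides.items()})
    kwargs: dict = {}
    for key, val in values.items():
        hint = ScenarioConfig.__dataclass_fields__[key].type
        if "bool" in str(hint):
            kwargs[key] = val.lower() in ("1", "true", "yes", "on")
        elif "int" in str(hint):
            kwargs[key] = int(val)
        else:
            kwargs[key] = float(val)
    return ScenarioConfig(**kwargs)
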