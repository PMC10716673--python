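"""Richness, Shannon–Wiener diversity, and population summaries.

Richness counts the species present (abundance >= 1).  The Shannon–Wiener
index is ``H' = -sum p_i ln p_i`` with ``p_i = n_i / N`` and the natural
logarithm (nats); the empty community has H' = 0 by convention, which the
uninhabited initial state requires.  Landscape-level H' is computed on the
pooled species counts of the whole landscape, not by averaging patch-level
values — the two differ whenever patch communities are dissimilar, and that
difference (beta diversity) is exactly what distinguishes landscape from
patch responses.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from .species import TRAIT_NAMES

__all__ = [
    "richness",
    "shannon",
    "shannon_from_counts",
    "patch_summaries",
    "census_table",
    "expand_individuals",
    "window_statistics",
]


def _count_array(counts) -> np.ndarray:
    if isinstance(counts, Mapping):
        arr = np.fromiter(counts.values(), dtype=float, count=len(counts))
    else:
        arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise ValueError("abundances must be non-negative")
    return arr[arr > 0]


def richness(counts) -> int:
    """Number of species with abundance >= 1.

    Accepts a species -> count mapping or a plain abundance vector.
    """
    return int(len(_count_array(counts)))


def shannon(counts) -> float:
    """Shannon–Wiener diversity H' in nats; 0 for empty communities."""
    arr = _count_array(counts)
    return shannon_from_counts(arr)


def shannon_from_counts(arr: np.ndarray) -> float:
    """H' from a strictly positive abundance vector (fast path)."""
    if len(arr) == 0:
        return 0.0
    total = arr.sum()
    p = arr / total
    return float(-(p * np.log(p)).sum())


def census_table(state) -> pd.DataFrame:
    """Final census: one row per occupied (patch, species) pair.

    Columns: patch coordinates x, y; species_id; abundance; and the six
    species trait values.  Conspecifics are identical clones, so the
    per-pair rows carry full individual-level information; pass the result
    through :func:`expand_individuals` for literal one-row-per-individual
    output.
    """
    width = state.landscape.width
    data = {
        "x": state.patch % width,
        "y": state.patch // width,
        "species_id": state.species,
        "abundance": state.counts,
    }
    for name in TRAIT_NAMES:
        data[name] = state.registry.trait(name)[state.species]
    df = pd.DataFrame(data)
    return df.sort_values(["y", "x", "species_id"], ignore_index=True)


def expand_individuals(census: pd.DataFrame) -> pd.DataFrame:
    """Expand a census to one row per individual organism."""
    idx = np.repeat(census.index.to_numpy(), census["abundance"].to_numpy())
    out = census.loc[idx].reset_index(drop=True)
    out["abundance"] = 1
    return out


def patch_summaries(state) -> pd.DataFrame:
    """Per-patch population, richness, and Shannon diversity.

    One row per patch (including empty ones), derived from the same counts
    the census reports: columns x, y, population, richness, shannon.
    """
    width, height = state.landscape.width, state.landscape.height
    n_patches = width * height
    pop = np.bincount(state.patch, weights=state.counts, minlength=n_patches)
    rich = np.bincount(state.patch, minlength=n_patches)
    sh = np.zeros(n_patches)
    order = np.argsort(state.patch, kind="stable")
    bounds = np.searchsorted(state.patch[order], np.arange(n_patches + 1))
    counts_sorted = state.counts[order].astype(float)
    for p in range(n_patches):
        lo, hi = bounds[p], bounds[p + 1]
        if hi > lo:
            sh[p] = shannon_from_counts(counts_sorted[lo:hi])
    patches = np.arange(n_patches)
    return pd.DataFrame(
        {
            "x": patches % width,
            "y": patches // width,
            "population": pop.astype(np.int64),
            "richness": rich.astype(np.int64),
            "shannon": sh,
        }
    )


def window_statistics(
    series: pd.DataFrame, from_step: int, to_step: int
) -> pd.DataFrame:
    """Distributional summary of landscape metrics over a step window.

    Summarizes total_population, richness, and shannon over steps
    ``from_step..to_step`` inclusive: median, mean, variance, and quartiles.
    Raises on an empty window.
    """
    if from_step > to_step:
        raise ValueError(f"empty window: [{from_step}, {to_step}]")
    window = series[(series["step"] >= from_step) & (series["step"] <= to_step)]
    if window.empty:
        raise ValueError(
            f"window [{from_step}, {to_step}] contains no recorded steps"
        )
    rows = {}
    for col in ("total_population", "richness", "shannon"):
        vals = window[col].to_numpy(dtype=float)
        rows[col] = {
            "median": float(np.median(vals)),
            "mean": float(vals.mean()),
            "variance": float(vals.var(ddof=1)) if len(vals) > 1 else 0.0,
            "q25": float(np.quantile(vals, 0.25)),
            "q75": float(np.quantile(vals, 0.75)),
            "n_steps": len(vals),
        }
    return pd.DataFrame(rows).T
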