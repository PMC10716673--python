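"""Toroidal fractal landscapes with controllable spatial autocorrelation.

A landscape is a grid of habitat patches carrying two environmental
attributes: a temperature ``T`` and a second, unspecified habitat variable
``H`` (e.g. a soil property).  Both attribute fields are fractal random
fields generated by 2-D spectral synthesis: white Gaussian noise is filtered
in Fourier space with an amplitude spectrum ``|f|**-(hurst + 1)`` and
transformed back to a real field.  Because the construction works on the
discrete Fourier basis it is inherently periodic, so opposite grid edges
connect seamlessly (a torus) and no edge effects occur.

The Hurst index controls spatial autocorrelation: ``hurst = 1`` yields
smooth fields in which neighbouring patches have similar environments,
``hurst = 0`` yields a largely random spatial arrangement.  Each generated
field is standardized to sample mean 0 and standard deviation 1, so the
frequency distribution of environment values is identical across spatial
configurations; the heterogeneity multiplier ``G`` then rescales the field,
setting the magnitude of spatial variation (sd of the scaled field = G).

Temperature additionally fluctuates over time: a single standard-normal
deviate per time step is added to every patch's scaled T value (global
fluctuation, unaffected by G).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LandscapeGrid",
    "FluctuationSeries",
    "generate_fractal_field",
    "generate_landscape",
    "generate_fluctuations",
    "scale_landscape",
    "effective_temperature",
    "write_landscape",
    "read_landscape",
    "morans_i",
]


class LandscapeFormatError(ValueError):
    """Raised when a landscape file cannot be parsed or is inconsistent."""


@dataclass(frozen=True)
class LandscapeGrid:
    """Two standardized fractal attribute fields on a toroidal grid.

    ``t_base`` and ``h_base`` are the standardized (mean 0, sd 1) base
    fields, indexed ``[y, x]`` (row-major); the heterogeneity multiplier
    ``g`` is applied via :func:`scale_landscape` when the simulation reads
    patch environments.  All coordinates are zero-based and wrap modulo the
    grid dimensions.
    """

    width: int
    height: int
    t_base: np.ndarray
    h_base: np.ndarray
    hurst: float
    g: float = 1.0

    def __post_init__(self) -> None:
        for name in ("t_base", "h_base"):
            arr = getattr(self, name)
            if arr.shape != (self.height, self.width):
                raise LandscapeFormatError(
                    f"{name} has shape {arr.shape}, expected "
                    f"({self.height}, {self.width})"
                )

    @property
    def n_patches(self) -> int:
        return self.width * self.height

    def scaled_t(self) -> np.ndarray:
        """T base field multiplied by G."""
        return scale_landscape(self.t_base, self.g)

    def scaled_h(self) -> np.ndarray:
        """H base field multiplied by G."""
        return scale_landscape(self.h_base, self.g)

    def wrap(self, x: int, y: int) -> tuple[int, int]:
        """Toroidal coordinate wrap."""
        return x % self.width, y % self.height


@dataclass(frozen=True)
class FluctuationSeries:
    """Pre-generated global temperature fluctuations, one per time step.

    Each value is drawn from a standard normal distribution at
    initialization, before the run starts; the value at index ``t`` is added
    to every patch's scaled T attribute during step ``t``.
    """

    values: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, step: int) -> float:
        return float(self.values[step])


def generate_fluctuations(t_max: int, rng: np.random.Generator) -> FluctuationSeries:
    """Draw the full fluctuation series for a ``t_max``-step run."""
    if t_max < 0:
        raise ValueError(f"t_max must be non-negative, got {t_max}")
    return FluctuationSeries(values=rng.standard_normal(t_max))


def generate_fractal_field(
    width: int, height: int, hurst: float, rng: np.random.Generator
) -> np.ndarray:
    """Generate one standardized periodic fractal field.

    Spectral synthesis: filter 2-D white Gaussian noise with the radial
    amplitude spectrum ``|f|**-(hurst + 1)`` (zero frequency removed), then
    inverse-transform.  Larger ``hurst`` concentrates power at low
    frequencies, producing smoother, more autocorrelated fields.

    Returns a ``(height, width)`` array with sample mean 0 and sample
    standard deviation 1 (exact empirical standardization).
    """
    if width < 2 or height < 2:
        raise ValueError(f"grid dimensions must be >= 2, got {width}x{height}")
    if not 0.0 <= hurst <= 1.0:
        raise ValueError(f"hurst must lie in [0, 1], got {hurst}")

    noise = rng.standard_normal((height, width))
    spectrum = np.fft.fft2(noise)
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    freq = np.hypot(fx, fy)
    with np.errstate(divide="ignore"):
        amplitude = np.where(freq > 0.0, freq ** -(hurst + 1.0), 0.0)
    fld = np.fft.ifft2(spectrum * amplitude).real
    return _standardize(fld)


def _standardize(fld: np.ndarray) -> np.ndarray:
    sd = fld.std()
    if sd == 0.0:
        raise ValueError("degenerate field: zero variance before standardization")
    return (fld - fld.mean()) / sd


def generate_landscape(
    width: int,
    height: int,
    hurst: float,
    rng: np.random.Generator,
    g: float = 1.0,
) -> LandscapeGrid:
    """Generate a landscape with independent T and H fields.

    The two fields share the Hurst index but are produced from distinct RNG
    substreams (spawned child generators), so they are statistically
    independent and do not spatially correlate with each other.
    """
    t_rng, h_rng = rng.spawn(2)
    return LandscapeGrid(
        width=width,
        height=height,
        t_base=generate_fractal_field(width, height, hurst, t_rng),
        h_base=generate_fractal_field(width, height, hurst, h_rng),
        hurst=hurst,
        g=g,
    )


def scale_landscape(field_: np.ndarray, g: float) -> np.ndarray:
    """Multiply a standardized attribute field by the heterogeneity G.

    For a standardized input the result has sd exactly ``g``; ``g = 0``
    collapses the landscape to full homogeneity.
    """
    if g < 0:
        raise ValueError(f"G must be non-negative, got {g}")
    return field_ * g


def effective_temperature(t_scaled, fluctuation: float):
    """Patch temperature at one step: scaled base T plus the step's global
    fluctuation (identical for all patches; not multiplied by G)."""
    return t_scaled + fluctuation


# ---------------------------------------------------------------------------
# Text-file persistence
#
# One file per attribute: `<prefix>_T.txt` and `<prefix>_H.txt`, each with a
# header line `# width=W height=H hurst=X` followed by H rows of W
# whitespace-delimited floats (row-major, row y on line y).
# ---------------------------------------------------------------------------


def _write_field(path: Path, fld: np.ndarray, hurst: float) -> None:
    height, width = fld.shape
    header = f"width={width} height={height} hurst={hurst:.12g}"
    np.savetxt(path, fld, fmt="%.15e", header=header)


def _read_field(path: Path) -> tuple[np.ndarray, int, int, float]:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise LandscapeFormatError(f"{path}: missing '# width=...' header line")
        try:
            meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
            width, height = int(meta["width"]), int(meta["height"])
            hurst = float(meta["hurst"])
        except (KeyError, ValueError) as exc:
            raise LandscapeFormatError(f"{path}: malformed header {header!r}") from exc
        body = fh.read()
    try:
        values = np.array(body.split(), dtype=float)
    except ValueError as exc:
        raise LandscapeFormatError(f"{path}: non-numeric token in grid body") from exc
    if values.size != width * height:
        raise LandscapeFormatError(
            f"{path}: header promises {width * height} values, found {values.size}"
        )
    return values.reshape(height, width), width, height, hurst


def write_landscape(prefix: str | Path, grid: LandscapeGrid) -> tuple[Path, Path]:
    """Write a landscape to ``<prefix>_T.txt`` and ``<prefix>_H.txt``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    t_path = prefix.with_name(prefix.name + "_T.txt")
    h_path = prefix.with_name(prefix.name + "_H.txt")
    _write_field(t_path, grid.t_base, grid.hurst)
    _write_field(h_path, grid.h_base, grid.hurst)
    return t_path, h_path


def read_landscape(prefix: str | Path, g: float = 1.0) -> LandscapeGrid:
    """Read a landscape written by :func:`write_landscape`.

    Round trip is lossless to at least 12 significant digits.  Raises
    :class:`LandscapeFormatError` on dimension mismatch between the T and H
    files or on malformed content.
    """
    prefix = Path(prefix)
    t_field, tw, th, t_hurst = _read_field(prefix.with_name(prefix.name + "_T.txt"))
    h_field, hw, hh, h_hurst = _read_field(prefix.with_name(prefix.name + "_H.txt"))
    if (tw, th) != (hw, hh):
        raise LandscapeFormatError(
            f"T grid is {tw}x{th} but H grid is {hw}x{hh}"
        )
    if t_hurst != h_hurst:
        raise LandscapeFormatError(
            f"T and H files disagree on hurst: {t_hurst} vs {h_hurst}"
        )
    return LandscapeGrid(
        width=tw, height=th, t_base=t_field, h_base=h_field, hurst=t_hurst, g=g
    )


def morans_i(fld: np.ndarray) -> float:
    """Moran's I spatial autocorrelation with rook neighbours on a torus.

    With the periodic rook weight matrix every cell has exactly four
    neighbours, so I reduces to the mean lag-1 product of deviations over
    the four wrapped shifts, divided by the field variance.  Used to verify
    the autocorrelation ordering between Hurst scenarios.
    """
    z = fld - fld.mean()
    denom = (z**2).sum()
    if denom == 0.0:
        return 0.0
    num = sum(
        (z * np.roll(z, shift, axis=axis)).sum()
        for axis in (0, 1)
        for shift in (1, -1)
    )
    return float(num / (4.0 * denom))
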