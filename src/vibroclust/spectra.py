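"""Vibrational line spectra and broadened grid spectra.

A molecule with N atoms has 3N-6 harmonic normal modes, each a (frequency,
activity) pair: IR intensity in km/mol, Raman activity, or unit weight when
only the density of vibrational states (VDOS) is wanted. For similarity
analysis the discrete line spectrum is convolved with a Gaussian of fixed
width and sampled on a uniform wavenumber grid restricted to the fingerprint
region, where bending/stretching patterns of functional groups give each
molecule its characteristic signature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "KINDS",
    "VibrationalMode",
    "LineSpectrum",
    "FrequencyGrid",
    "GridSpectrum",
    "BroadeningParams",
    "SpectrumFormatError",
    "GridMismatchError",
    "broaden",
    "window",
    "shift_frequencies",
    "read_line_spectrum",
    "write_line_spectrum",
    "read_grid_spectrum",
    "write_grid_spectrum",
]

#: Supported spectroscopies. VDOS is the mode-density pseudo-spectrum
#: (every mode enters with unit weight).
KINDS = ("IR", "Raman", "VDOS")

# Default fingerprint window (cm^-1). The classic fingerprint region starts
# at 600, but the S-S stretch of dialkyl sulfides sits near 452, so the
# default grid reaches down to 400 to retain it.
DEFAULT_GRID = (400.0, 1800.0, 1.0)
FINGERPRINT_WINDOW = (600.0, 1800.0)


class SpectrumFormatError(ValueError):
    """A spectrum file violates the two-column (frequency, intensity) format."""


class GridMismatchError(ValueError):
    """Operation requires spectra on a common/valid frequency grid."""


class VibrationalMode(NamedTuple):
    frequency: float  # wavenumber, cm^-1, > 0
    intensity: float  # activity, >= 0 (unit weight for VDOS)


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class LineSpectrum:
    """Discrete vibrational spectrum: 3N-6 modes of one compound.

    Modes are kept sorted by ascending frequency; frequencies are strictly
    positive and intensities non-negative. For ``kind="VDOS"`` every
    intensity is 1 (density of states counts modes, it does not weight them).
    """

    compound_id: str
    frequencies: np.ndarray
    intensities: np.ndarray
    kind: str = "IR"
    compound_name: str = ""

    def __post_init__(self):
        freqs = _as_float_array(self.frequencies)
        intens = _as_float_array(self.intensities)
        if freqs.ndim != 1 or intens.ndim != 1 or freqs.shape != intens.shape:
            raise ValueError("frequencies and intensities must be 1-D and equally long")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if np.any(freqs <= 0):
            raise ValueError("mode frequencies must be > 0 cm^-1")
        if np.any(intens < 0):
            raise ValueError("mode intensities must be >= 0")
        if self.kind == "VDOS" and freqs.size and not np.allclose(intens, 1.0):
            raise ValueError("VDOS spectra must carry unit intensities")
        order = np.argsort(freqs, kind="stable")
        object.__setattr__(self, "frequencies", freqs[order])
        object.__setattr__(self, "intensities", intens[order])
        self.frequencies.setflags(write=False)
        self.intensities.setflags(write=False)

    @property
    def modes(self) -> list[VibrationalMode]:
        return [VibrationalMode(f, i) for f, i in zip(self.frequencies, self.intensities)]

    @property
    def n_modes(self) -> int:
        return int(self.frequencies.size)

    def as_vdos(self) -> "LineSpectrum":
        """Forget activities: same mode positions with unit weights."""
        return LineSpectrum(
            compound_id=self.compound_id,
            frequencies=self.frequencies,
            intensities=np.ones_like(self.frequencies),
            kind="VDOS",
            compound_name=self.compound_name,
        )


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform wavenumber grid [start, stop] with spacing ``step`` (cm^-1)."""

    start: float
    stop: float
    step: float

    def __post_init__(self):
        if not self.start < self.stop:
            raise ValueError("grid requires start < stop")
        if not self.step > 0:
            raise ValueError("grid step must be > 0")

    @property
    def n_points(self) -> int:
        return int(math.floor((self.stop - self.start) / self.step + 1e-9)) + 1

    def points(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)


@dataclass(frozen=True)
class GridSpectrum:
    """Broadened spectrum sampled on a uniform grid."""

    compound_id: str
    grid: FrequencyGrid
    intensities: np.ndarray
    kind: str = "IR"

    def __post_init__(self):
        intens = _as_float_array(self.intensities)
        if intens.ndim != 1:
            raise ValueError("intensities must be 1-D")
        if intens.size != self.grid.n_points:
            raise ValueError(
                f"intensity vector length {intens.size} does not match "
                f"grid point count {self.grid.n_points}"
            )
        if np.any(intens < 0):
            raise ValueError("grid intensities must be >= 0")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        object.__setattr__(self, "intensities", intens)
        self.intensities.setflags(write=False)

    def integral(self) -> float:
        """Trapezoid integral over the grid (intensity x cm^-1)."""
        return float(np.trapezoid(self.intensities, dx=self.grid.step))


@dataclass(frozen=True)
class BroadeningParams:
    """Gaussian line-shape parameters.

    sigma
        Standard deviation of the Gaussian placed on each mode, in cm^-1.
        The default of 10 gives good resolution in the fingerprint region.
    amplitude
        ``"area"`` (default): each mode contributes a unit-area Gaussian
        scaled by its intensity, so the integrated spectrum equals the
        summed line intensities. ``"peak"``: each Gaussian has peak height
        equal to the line intensity instead.
    """

    sigma: float = 10.0
    amplitude: str = "area"

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0 cm^-1")
        if self.amplitude not in ("area", "peak"):
            raise ValueError("amplitude must be 'area' or 'peak'")


def broaden(
    line: LineSpectrum,
    grid: FrequencyGrid,
    params: BroadeningParams = BroadeningParams(),
) -> GridSpectrum:
    """Convolve a line spectrum with Gaussians of width ``params.sigma``.

    Under the default unit-area convention the value at grid point nu is

        I(nu) = sum_m I_m * exp(-(nu - nu_m)^2 / (2 sigma^2)) / (sigma sqrt(2 pi))

    so the numerically integrated spectrum over a grid covering all modes
    amply equals sum_m I_m.
    """
    nu = grid.points()
    if line.n_modes == 0:
        return GridSpectrum(line.compound_id, grid, np.zeros(grid.n_points), line.kind)
    sigma = params.sigma
    diff = nu[None, :] - line.frequencies[:, None]
    shapes = np.exp(-0.5 * (diff / sigma) ** 2)
    if params.amplitude == "area":
        shapes /= sigma * math.sqrt(2.0 * math.pi)
    values = line.intensities @ shapes
    # clip tiny negative round-off
    np.maximum(values, 0.0, out=values)
    return GridSpectrum(line.compound_id, grid, values, line.kind)


def window(spectrum: GridSpectrum, lo: float, hi: float) -> GridSpectrum:
    """Restrict a grid spectrum to points nu with lo <= nu <= hi."""
    if not lo < hi:
        raise ValueError("window requires lo < hi")
    nu = spectrum.grid.points()
    mask = (nu >= lo - 1e-9) & (nu <= hi + 1e-9)
    if not mask.any():
        raise GridMismatchError(
            f"window [{lo}, {hi}] does not overlap grid "
            f"[{spectrum.grid.start}, {spectrum.grid.stop}]"
        )
    kept = nu[mask]
    new_grid = FrequencyGrid(float(kept[0]), float(kept[-1]), spectrum.grid.step)
    return GridSpectrum(spectrum.compound_id, new_grid, spectrum.intensities[mask], spectrum.kind)


def shift_frequencies(line: LineSpectrum, delta: float) -> LineSpectrum:
    """Shift every mode frequency by ``delta`` cm^-1.

    Harmonic DFT frequencies overestimate experiment by roughly 50 cm^-1,
    so ``delta=-50`` applies the customary correction. Modes whose shifted
    frequency is <= 0 are dropped with a warning.
    """
    shifted = line.frequencies + delta
    keep = shifted > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"{line.compound_id}: dropped {n_dropped} mode(s) shifted to <= 0 cm^-1",
            stacklevel=2,
        )
    return LineSpectrum(
        compound_id=line.compound_id,
        frequencies=shifted[keep],
        intensities=line.intensities[keep],
        kind=line.kind,
        compound_name=line.compound_name,
    )


# ---------------------------------------------------------------------------
# Plain-text IO: two columns (frequency_cm1, intensity), comma/tab/whitespace
# delimited, optional header, UTF-8, '.' decimal separator.
# ---------------------------------------------------------------------------

_HEADER = "frequency_cm1,intensity"


def _parse_two_columns(path: Path) -> tuple[np.ndarray, np.ndarray]:
    freqs: list[float] = []
    intens: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text or text.startswith("#"):
                continue
            for delim in (",", "\t"):
                if delim in text:
                    parts = [p.strip() for p in text.split(delim)]
                    break
            else:
                parts = text.split()
            if len(parts) != 2:
                raise SpectrumFormatError(
                    f"{path}, line {lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                f, i = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # tolerate a header row
                    continue
                raise SpectrumFormatError(
                    f"{path}, line {lineno}: non-numeric row {text!r}"
                ) from None
            if i < 0:
                raise SpectrumFormatError(
                    f"{path}, line {lineno}: negative intensity {i}"
                )
            freqs.append(f)
            intens.append(i)
    return np.array(freqs), np.array(intens)


def read_line_spectrum(path, kind: str = "IR", compound_id: str | None = None) -> LineSpectrum:
    """Read a line spectrum from a two-column text file.

    Rows may appear in any frequency order; they are re-sorted ascending.
    The compound id defaults to the file stem.
    """
    path = Path(path)
    freqs, intens = _parse_two_columns(path)
    try:
        return LineSpectrum(
            compound_id=compound_id or path.stem,
            frequencies=freqs,
            intensities=intens,
            kind=kind,
        )
    except ValueError as exc:
        raise SpectrumFormatError(f"{path}: {exc}") from exc


def write_line_spectrum(line: LineSpectrum, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        for f, i in zip(line.frequencies, line.intensities):
            fh.write(f"{f:.12g},{i:.12g}\n")


def read_grid_spectrum(path, kind: str = "IR", compound_id: str | None = None) -> GridSpectrum:
    """Read a broadened spectrum from (frequency, intensity) rows on a uniform grid."""
    path = Path(path)
    freqs, intens = _parse_two_columns(path)
    if freqs.size < 2:
        raise SpectrumFormatError(f"{path}: a grid spectrum needs >= 2 points")
    order = np.argsort(freqs)
    freqs, intens = freqs[order], intens[order]
    steps = np.diff(freqs)
    step = float(steps[0])
    if step <= 0 or np.any(np.abs(steps - step) > 1e-6 * max(step, 1.0)):
        raise SpectrumFormatError(f"{path}: frequency points are not on a uniform grid")
    grid = FrequencyGrid(float(freqs[0]), float(freqs[-1]), step)
    return GridSpectrum(compound_id or path.stem, grid, intens, kind)


def write_grid_spectrum(spectrum: GridSpectrum, path) -> None:
    path = Path(path)
    nu = spectrum.grid.points()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        for f, i in zip(nu, spectrum.intensities):
            fh.write(f"{f:.12g},{i:.12g}\n")
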