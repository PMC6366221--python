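"""FTIR spectrum container, text I/O and preprocessing.

The preprocessing chain mirrors a standard transmission-FTIR workflow for
microbial fingerprinting: a signal-to-noise quality test on the silent
2100-1900 cm-1 interval, rubberband (lower convex hull) baseline
correction, and vector normalization of the whole spectrum.  Spectra are
stored on a descending wavenumber grid (4000 -> 400 cm-1 by convention)
and all replicate spectra of one experiment share a single grid.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "read_spectrum_table",
    "write_spectrum_table",
    "resample_to_grid",
    "rubberband_baseline",
    "vector_normalize",
    "quality_snr",
    "average_replicates",
]

log = logging.getLogger(__name__)

#: Default signal-free interval used by the quality test (cm-1).
DEFAULT_NOISE_WINDOW = (1900.0, 2100.0)

#: Default SNR acceptance threshold of the quality test.
DEFAULT_SNR_THRESHOLD = 4000.0


@dataclass(frozen=True)
class Spectrum:
    """A single FTIR absorbance measurement.

    Parameters
    ----------
    wavenumbers
        Strictly monotone wavenumber grid in cm-1, stored descending
        (4000 -> 400) by convention.
    intensities
        Absorbance values, same length as ``wavenumbers``.
    strain, condition, replicate
        Free-form sample metadata (biosensor strain id, stress condition /
        relative-concentration label, replicate id).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    strain: str | None = None
    condition: str | None = None
    replicate: str | None = None

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or y.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if wn.size != y.size:
            raise ValueError(
                f"length mismatch: {wn.size} wavenumbers vs {y.size} intensities"
            )
        if wn.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        d = np.diff(wn)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumbers must be strictly monotone")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def descending(self) -> bool:
        return bool(self.wavenumbers[0] > self.wavenumbers[-1])

    def sorted_descending(self) -> "Spectrum":
        """Return the spectrum on a descending grid (no-op if already so)."""
        if self.descending:
            return self
        return replace(
            self,
            wavenumbers=self.wavenumbers[::-1].copy(),
            intensities=self.intensities[::-1].copy(),
        )

    def with_intensities(self, y: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(y, dtype=float))

    def key(self) -> tuple:
        return (self.strain, self.condition, self.replicate)


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

def _parse_pair(token_line: str, lineno: int, delimiter: str | None):
    for delim in ((delimiter,) if delimiter else (",", "\t", ";", None)):
        parts = token_line.split(delim) if delim else token_line.split()
        parts = [p for p in (s.strip() for s in parts) if p]
        if len(parts) == 2:
            try:
                return float(parts[0]), float(parts[1])
            except ValueError:
                break
    raise ValueError(
        f"line {lineno}: expected two numeric columns, got {token_line!r}"
    )


def read_spectrum_table(
    source,
    *,
    strain: str | None = None,
    condition: str | None = None,
    replicate: str | None = None,
    delimiter: str | None = None,
) -> Spectrum:
    """Read a two-column (wavenumber, absorbance) text table.

    Accepts a path or an open text stream.  Lines starting with ``#`` (and
    JCAMP-DX-style ``##`` labelled-data-records) are treated as comments;
    inside a ``##XYDATA`` block, plain ``x y`` pairs are read until the next
    ``##`` record.  The returned spectrum is sorted onto a descending grid.

    Raises
    ------
    ValueError
        On a non-numeric data row (the message names the offending line)
        or on duplicate wavenumbers.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_spectrum_table(
                fh, strain=strain, condition=condition,
                replicate=replicate, delimiter=delimiter,
            )

    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            # JCAMP-DX-like labelled record; XYDATA introduces the data block,
            # anything else (##TITLE, ##END, ...) is metadata.
            continue
        if line.startswith("#"):
            continue
        x, y = _parse_pair(line, lineno, delimiter)
        xs.append(x)
        ys.append(y)

    if len(xs) < 2:
        raise ValueError("need at least 2 (wavenumber, intensity) pairs")
    wn = np.asarray(xs)
    sorted_wn = np.sort(wn)
    dups = sorted_wn[:-1][np.diff(sorted_wn) == 0]
    if dups.size:
        raise ValueError(f"duplicate wavenumbers in input (e.g. {dups[0]:g})")
    order = np.argsort(wn)[::-1]
    return Spectrum(
        wavenumbers=wn[order],
        intensities=np.asarray(ys)[order],
        strain=strain,
        condition=condition,
        replicate=replicate,
    )


def write_spectrum_table(s: Spectrum, dest, *, delimiter: str = ",") -> None:
    """Write the two-column text dialect (9 significant digits, reproducible)."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            write_spectrum_table(s, fh, delimiter=delimiter)
            return
    dest.write("#wavenumber_cm-1%sabsorbance\n" % delimiter)
    for x, y in zip(s.wavenumbers, s.intensities):
        dest.write(f"{x:.9g}{delimiter}{y:.9g}\n")


def spectrum_to_text(s: Spectrum) -> str:
    buf = io.StringIO()
    write_spectrum_table(s, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def resample_to_grid(s: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation).

    The grid must lie within the span of the source wavenumbers; metadata is
    preserved and the output keeps the ordering of ``grid``.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.wavenumbers.min(), s.wavenumbers.max()
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise ValueError(
            f"grid [{grid.min():g}, {grid.max():g}] outside data span [{lo:g}, {hi:g}]"
        )
    asc = np.argsort(s.wavenumbers)
    y = np.interp(grid, s.wavenumbers[asc], s.intensities[asc])
    return replace(s, wavenumbers=grid.copy(), intensities=y)


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> list[int]:
    """Andrew monotone-chain lower hull of points sorted by ascending x."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # keep k only if it lies strictly below the (j, i) chord
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _prune_hull(x: np.ndarray, y: np.ndarray, hull: list[int], n_points: int) -> list[int]:
    """Reduce hull support to ``n_points`` vertices, keeping the endpoints.

    Greedily removes the interior vertex whose removal adds the least area
    between the chord of its neighbours and the removed vertex.
    """
    hull = list(hull)
    while len(hull) > n_points:
        best, best_area = None, np.inf
        for idx in range(1, len(hull) - 1):
            j, k, l = hull[idx - 1], hull[idx], hull[idx + 1]
            area = abs(
                (x[l] - x[j]) * (y[k] - y[j]) - (x[k] - x[j]) * (y[l] - y[j])
            ) / 2.0
            if area < best_area:
                best, best_area = idx, area
        hull.pop(best)
    return hull


def rubberband_baseline(
    s: Spectrum, n_points: int = 64
) -> tuple[Spectrum, Spectrum]:
    """Rubberband baseline correction.

    The baseline is the lower convex hull of the (wavenumber, absorbance)
    points — the shape of a rubber band stretched under the spectrum —
    evaluated by linear interpolation between hull vertices.  At most
    ``n_points`` support points are kept (the OPUS-style "64 points"
    parameter); when the hull has fewer vertices, which is the usual case,
    this is exactly the plain lower convex hull and the corrected spectrum
    is non-negative and touches zero at the hull vertices.

    Returns ``(baseline, corrected)`` with ``corrected = s - baseline``.
    """
    if len(s) < 3:
        raise ValueError("rubberband baseline needs at least 3 points")
    asc = np.argsort(s.wavenumbers)
    x = s.wavenumbers[asc]
    y = s.intensities[asc]
    hull = _lower_hull_indices(x, y)
    if len(hull) > n_points:
        hull = _prune_hull(x, y, hull, n_points)
    base_asc = np.interp(x, x[hull], y[hull])
    # map back to the spectrum's own ordering
    base = np.empty_like(base_asc)
    base[asc] = base_asc
    baseline = s.with_intensities(base)
    corrected = s.with_intensities(s.intensities - base)
    return baseline, corrected


def vector_normalize(s: Spectrum, *, center: bool = True) -> Spectrum:
    """Vector normalization: mean-center, then scale to unit Euclidean norm.

    ``center=False`` gives plain unit-L2 scaling without centering.
    """
    y = s.intensities
    if center:
        y = y - y.mean()
    norm = float(np.linalg.norm(y))
    if norm < 1e-300 or not np.isfinite(norm):
        raise ValueError("zero variance spectrum: vector normalization undefined")
    return s.with_intensities(y / norm)


def quality_snr(
    s: Spectrum,
    noise_window: tuple[float, float] = DEFAULT_NOISE_WINDOW,
) -> float:
    """Signal-to-noise ratio for the spectral quality test.

    SNR = (max - min of the full spectrum) divided by the RMS of the
    residuals after a linear detrend of the signal-free ``noise_window``
    (default 2100-1900 cm-1, where cell spectra carry no bands).  A
    noise-free window returns ``inf`` (an unconditional pass).
    """
    lo, hi = sorted(noise_window)
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if mask.sum() < 8:
        raise ValueError(
            f"noise window [{lo:g}, {hi:g}] cm-1 not covered (need >= 8 points)"
        )
    xw = s.wavenumbers[mask]
    yw = s.intensities[mask]
    coeffs = np.polyfit(xw, yw, 1)
    resid = yw - np.polyval(coeffs, xw)
    rms = float(np.sqrt(np.mean(resid**2)))
    signal = float(s.intensities.max() - s.intensities.min())
    # residuals at float rounding level: noise-free window, unconditional pass
    if rms <= 1e-12 * max(signal, 1e-300):
        return float("inf")
    return signal / rms


def average_replicates(spectra: Iterable[Spectrum]) -> Spectrum:
    """Point-wise mean of replicate spectra sharing one grid."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("empty replicate group")
    grid = spectra[0].wavenumbers
    for sp in spectra[1:]:
        if sp.wavenumbers.shape != grid.shape or not np.array_equal(
            sp.wavenumbers, grid
        ):
            raise ValueError("replicates do not share a common wavenumber grid")
    mean = np.mean([sp.intensities for sp in spectra], axis=0)
    first = spectra[0]
    return Spectrum(
        wavenumbers=grid.copy(),
        intensities=mean,
        strain=first.strain,
        condition=first.condition,
        replicate=None,
    )


# ---------------------------------------------------------------------------
# collections
# ---------------------------------------------------------------------------

@dataclass
class SpectrumSet:
    """Spectra of one experiment on a shared wavenumber grid.

    Grouping is by ``(strain, condition)``; the experimental design is three
    replicates per group, but any positive count is accepted.
    """

    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spectra:
            grid = self.spectra[0].wavenumbers
            for sp in self.spectra[1:]:
                if not np.array_equal(sp.wavenumbers, grid):
                    raise ValueError(
                        "all spectra in a SpectrumSet must share one grid; "
                        "resample first (resample_to_grid)"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def grid(self) -> np.ndarray:
        if not self.spectra:
            raise ValueError("empty SpectrumSet has no grid")
        return self.spectra[0].wavenumbers

    @property
    def n_points(self) -> int:
        return int(self.grid.size)

    def groups(self) -> Mapping[tuple, list[Spectrum]]:
        out: dict[tuple, list[Spectrum]] = {}
        for sp in self.spectra:
            out.setdefault((sp.strain, sp.condition), []).append(sp)
        return out

    def strains(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp in self.spectra:
            seen.setdefault(sp.strain)
        return list(seen)

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp in self.spectra:
            seen.setdefault(sp.condition)
        return list(seen)

    def select(self, strain=None, condition=None) -> list[Spectrum]:
        return [
            sp
            for sp in self.spectra
            if (strain is None or sp.strain == strain)
            and (condition is None or sp.condition == condition)
        ]

    def group_mean(self, strain, condition) -> Spectrum:
        group = self.select(strain=strain, condition=condition)
        if not group:
            raise ValueError(f"empty group (strain={strain!r}, condition={condition!r})")
        return average_replicates(group)

    def map(self, fn) -> "SpectrumSet":
        return SpectrumSet([fn(sp) for sp in self.spectra])


def preprocess_set(
    sset: SpectrumSet,
    *,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    noise_window: tuple[float, float] = DEFAULT_NOISE_WINDOW,
    n_baseline_points: int = 64,
    check_quality: bool = True,
) -> SpectrumSet:
    """Quality test, rubberband baseline, vector normalization — in order.

    Spectra failing the SNR cut-off are excluded with a logged warning
    rather than raising, mirroring how an operator would discard a bad
    replicate and re-measure.
    """
    kept: list[Spectrum] = []
    for sp in sset:
        if check_quality:
            snr = quality_snr(sp, noise_window)
            if snr < snr_threshold:
                log.warning(
                    "quality test failed (SNR %.1f < %.1f): excluding %s",
                    snr, snr_threshold, sp.key(),
                )
                continue
        _, corrected = rubberband_baseline(sp, n_baseline_points)
        kept.append(vector_normalize(corrected))
    return SpectrumSet(kept)
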