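"""Spectral stress indexes.

A stress index (SI) quantifies how far the FTIR fingerprint of stressed
cells has moved from that of unstressed cells kept in water: it is the
Euclidean distance between the two intensity vectors over a biochemical
spectral window, normalized by the ratio of total to window point counts,

    SI_w = ED_w / (n_total / n_w)

so that windows of different widths are comparable.  The SI over the whole
recorded range is the global stress index (GSI); for it the divisor is 1.

Windows follow the standard biochemical assignment for microbial cells:
fatty acids (W1, 3000-2800 cm-1), amides (W2, 1800-1500), mixed region
(W3, 1500-1200), carbohydrates (W4, 1200-900) and the typing region
(W5, 900-700), which responds to strain identity rather than stress and is
computed but excluded from dose models downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSet, average_replicates

__all__ = [
    "SpectralWindow",
    "default_windows",
    "window_slice",
    "stress_index",
    "compute_si_table",
    "compute_si_points",
]

#: Name of the whole-spectrum pseudo-window.
WHOLE_SPECTRUM = "WS"

#: Windows used by the dose models (the typing region W5 is excluded).
MODEL_WINDOWS = ("W1", "W2", "W3", "W4", WHOLE_SPECTRUM)


@dataclass(frozen=True)
class SpectralWindow:
    """A wavenumber interval [lo, hi] cm-1, inclusive on both bounds.

    ``lo is None`` marks the whole-spectrum window (GSI).
    """

    name: str
    lo: float | None
    hi: float | None

    @property
    def is_whole(self) -> bool:
        return self.lo is None or self.hi is None


_WINDOW_BOUNDS = {
    "W1": (2800.0, 3000.0),
    "W2": (1500.0, 1800.0),
    "W3": (1200.0, 1500.0),
    "W4": (900.0, 1200.0),
    "W5": (700.0, 900.0),
}


def default_windows(include_typing: bool = True) -> list[SpectralWindow]:
    """The five biochemical windows plus the whole-spectrum window."""
    names = ["W1", "W2", "W3", "W4"] + (["W5"] if include_typing else [])
    out = [SpectralWindow(n, *_WINDOW_BOUNDS[n]) for n in names]
    out.append(SpectralWindow(WHOLE_SPECTRUM, None, None))
    return out


def window_slice(s: Spectrum, w: SpectralWindow) -> Spectrum:
    """Restrict a spectrum to a window (inclusive bounds); WS returns it whole."""
    if w.is_whole:
        return s
    mask = (s.wavenumbers >= w.lo) & (s.wavenumbers <= w.hi)
    if not mask.any():
        raise ValueError(f"window {w.name} [{w.lo:g}, {w.hi:g}] does not overlap the grid")
    return replace(s, wavenumbers=s.wavenumbers[mask], intensities=s.intensities[mask])


def stress_index(
    stress: Spectrum,
    control: Spectrum,
    w: SpectralWindow,
    n_total: int | None = None,
) -> float:
    """SI between a stressed and a control spectrum over one window.

    ``n_total`` is the point count of the whole spectrum; it defaults to the
    length of the supplied spectra (which must share a grid).  Equivalent to
    ``ED_w * n_w / n_total``; for the whole-spectrum window this is the plain
    Euclidean distance (GSI).
    """
    if stress.wavenumbers.shape != control.wavenumbers.shape or not np.array_equal(
        stress.wavenumbers, control.wavenumbers
    ):
        raise ValueError("stressed and control spectra must share one grid")
    if n_total is None:
        n_total = len(stress)
    sw = window_slice(stress, w)
    cw = window_slice(control, w)
    ed = float(np.linalg.norm(sw.intensities - cw.intensities))
    n_w = len(sw)
    return ed * n_w / n_total


def _replicate_pair_sis(
    stressed: list[Spectrum],
    controls: list[Spectrum],
    w: SpectralWindow,
    n_total: int,
) -> list[float]:
    """SIs of index-paired replicates (stress rep i vs control rep i)."""
    key = lambda sp: str(sp.replicate)
    s_sorted = sorted(stressed, key=key)
    c_sorted = sorted(controls, key=key)
    n = min(len(s_sorted), len(c_sorted))
    return [
        stress_index(s_sorted[i], c_sorted[i], w, n_total) for i in range(n)
    ]


def compute_si_table(
    sset: SpectrumSet,
    control_condition: str,
    windows: list[SpectralWindow] | None = None,
) -> pd.DataFrame:
    """Per (strain, condition, window) stress indexes for a preprocessed set.

    The SI is computed between the replicate-averaged stressed spectrum and
    the replicate-averaged control spectrum of the same strain; the
    replicate spread ``si_sd`` is the standard deviation of the SIs of
    index-paired replicates.  Returns a tidy frame with columns
    ``strain, condition, window, si, si_sd``.
    """
    if windows is None:
        windows = default_windows()
    n_total = sset.n_points
    rows = []
    for strain in sset.strains():
        controls = sset.select(strain=strain, condition=control_condition)
        if not controls:
            raise ValueError(
                f"no control condition {control_condition!r} for strain {strain!r}"
            )
        control_mean = average_replicates(controls)
        for condition in sset.conditions():
            if condition == control_condition:
                continue
            stressed = sset.select(strain=strain, condition=condition)
            if not stressed:
                continue
            stress_mean = average_replicates(stressed)
            for w in windows:
                si = stress_index(stress_mean, control_mean, w, n_total)
                pair_sis = _replicate_pair_sis(stressed, controls, w, n_total)
                sd = float(np.std(pair_sis, ddof=1)) if len(pair_sis) > 1 else 0.0
                rows.append(
                    dict(strain=strain, condition=condition, window=w.name,
                         si=si, si_sd=sd)
                )
    return pd.DataFrame(rows, columns=["strain", "condition", "window", "si", "si_sd"])


def compute_si_points(
    sset: SpectrumSet,
    control_condition: str,
    windows: list[SpectralWindow] | None = None,
) -> pd.DataFrame:
    """Replicate-level SIs for calibration fitting.

    Each stressed replicate is compared with the replicate-averaged control
    of its strain; control replicates themselves are included the same way
    (their SIs hover near zero and anchor the zero-dose end of the fit).
    Columns: ``strain, condition, window, replicate, si``.
    """
    if windows is None:
        windows = default_windows()
    n_total = sset.n_points
    rows = []
    for strain in sset.strains():
        controls = sset.select(strain=strain, condition=control_condition)
        if not controls:
            raise ValueError(
                f"no control condition {control_condition!r} for strain {strain!r}"
            )
        control_mean = average_replicates(controls)
        for condition in sset.conditions():
            for sp in sset.select(strain=strain, condition=condition):
                for w in windows:
                    rows.append(
                        dict(
                            strain=strain,
                            condition=condition,
                            window=w.name,
                            replicate=sp.replicate,
                            si=stress_index(sp, control_mean, w, n_total),
                        )
                    )
    return pd.DataFrame(
        rows, columns=["strain", "condition", "window", "replicate", "si"]
    )
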