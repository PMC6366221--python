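"""Synthetic FTIR bioassay experiments.

Generates complete experiments — control and dose-stressed yeast
fingerprint spectra plus viable plate counts — with the statistical
structure the analysis assumes: Gaussian biochemical bands populating the
four analysis windows, a mild smooth baseline drift, between-replicate
band-amplitude jitter (the dominant source of replicate variability in
cell spectra), small i.i.d. detector noise, dose-dependent strain-specific
band perturbations that grow monotonically with relative concentration,
and mortality following a logistic kill curve that saturates at the
highest dose.

Three strain archetypes mirror the biosensor panel: a resistant strain
(low mortality, low spectral response), a sensitive strain (high
mortality, lowest spectral response) and an intermediate strain (low
mortality, high spectral response).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSet, write_spectrum_table
from .stress import _WINDOW_BOUNDS

__all__ = [
    "Band",
    "StrainProfile",
    "SyntheticConfig",
    "default_profiles",
    "generate_control_spectrum",
    "generate_stressed_spectrum",
    "generate_experiment",
    "quadratic_si_points",
    "write_experiment",
]


@dataclass(frozen=True)
class Band:
    """One Gaussian absorbance band: center (cm-1), sigma (cm-1), amplitude."""

    center: float
    sigma: float
    amplitude: float


def default_peak_table() -> tuple[Band, ...]:
    """A yeast-like fingerprint: bands in all four analysis windows.

    Assignments: amide A / OH stretch (3290), CH2 stretches (2925, 2855),
    amide I/II (1655, 1545), CH2 scissoring and carboxylate (1455, 1400),
    phosphate (1240, 1080), carbohydrate C-O (1045), typing-region band (855).
    """
    return (
        Band(3290.0, 100.0, 0.30),
        Band(2925.0, 16.0, 0.45),
        Band(2855.0, 12.0, 0.30),
        Band(1655.0, 22.0, 1.00),
        Band(1545.0, 20.0, 0.65),
        Band(1455.0, 14.0, 0.45),
        Band(1400.0, 14.0, 0.35),
        Band(1240.0, 18.0, 0.40),
        Band(1080.0, 30.0, 0.65),
        Band(1045.0, 22.0, 0.55),
        Band(855.0, 12.0, 0.12),
    )


@dataclass(frozen=True)
class StrainProfile:
    """Generating parameters of one synthetic biosensor strain.

    ``response`` gives the fractional band modulation per window at the
    full dose (RC = 100); the dose dependence is the saturating power law
    ``(rc/100) ** gamma`` (gamma < 1: concave SI growth, so the inverse
    dose-from-SI relation is convex and well captured by a quadratic).
    Mortality follows the logistic survival ``1/(1+exp((rc-mid)/steep))``
    normalized to the control.
    """

    name: str
    tolerance_class: str  # resistant | intermediate | sensitive
    response: dict  # window -> fractional modulation at RC = 100
    kill_midpoint: float
    kill_steepness: float
    gamma: float = 0.6

    def dose_response(self, rc: float) -> float:
        if rc <= 0:
            return 0.0
        return (rc / 100.0) ** self.gamma

    def survival(self, rc: float) -> float:
        return 1.0 / (1.0 + np.exp((rc - self.kill_midpoint) / self.kill_steepness))


def default_profiles() -> tuple[StrainProfile, ...]:
    """The three biosensor archetypes (resistant / intermediate / sensitive)."""
    return (
        StrainProfile(
            name="R1",
            tolerance_class="resistant",
            response={"W1": 0.75, "W2": 0.45, "W3": 0.45, "W4": 0.35, "W5": 0.06},
            kill_midpoint=170.0,
            kill_steepness=30.0,
            gamma=0.60,
        ),
        StrainProfile(
            name="I1",
            tolerance_class="intermediate",
            response={"W1": 0.70, "W2": 0.60, "W3": 1.00, "W4": 0.70, "W5": 0.08},
            kill_midpoint=140.0,
            kill_steepness=25.0,
            gamma=0.55,
        ),
        StrainProfile(
            name="S1",
            tolerance_class="sensitive",
            response={"W1": 0.30, "W2": 0.25, "W3": 0.25, "W4": 0.60, "W5": 0.05},
            kill_midpoint=35.0,
            kill_steepness=12.0,
            gamma=0.65,
        ),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic experiment.

    Defaults reproduce the published assay design: 4000-400 cm-1 range,
    three replicates, dose levels 0 / 25 / 50 / 100, detector noise small
    enough to pass the SNR > 4000 quality test, and replicate
    band-amplitude jitter calibrated so the between-replicate GSI spread
    sits near the published 2.5e-2.
    """

    grid_start: float = 4000.0
    grid_stop: float = 400.0
    grid_step: float = 2.0
    peaks: tuple = field(default_factory=default_peak_table)
    n_replicates: int = 3
    noise_sigma: float = 5e-5
    amplitude_jitter: float = 0.06
    drift_amplitude: float = 0.01
    rc_levels: dict = field(
        default_factory=lambda: {"RC_0": 0.0, "RC_L": 25.0, "RC_M": 50.0, "RC_H": 100.0}
    )
    base_count: float = 1.0e8
    seed: int = 0

    def grid(self) -> np.ndarray:
        """Descending wavenumber grid."""
        n = int(round((self.grid_start - self.grid_stop) / self.grid_step)) + 1
        return self.grid_start - self.grid_step * np.arange(n)


def _band_profile(wn: np.ndarray, bands) -> np.ndarray:
    y = np.zeros_like(wn)
    for b in bands:
        y += b.amplitude * np.exp(-0.5 * ((wn - b.center) / b.sigma) ** 2)
    return y


def _drift(wn: np.ndarray, amplitude: float) -> np.ndarray:
    # gentle linear tilt plus a very broad hump; removable by the rubberband
    t = (wn - wn.min()) / max(wn.max() - wn.min(), 1.0)
    return amplitude * t + amplitude * np.exp(-0.5 * ((wn - 1800.0) / 1200.0) ** 2)


def _window_of(center: float) -> str | None:
    for name, (lo, hi) in _WINDOW_BOUNDS.items():
        if lo <= center <= hi:
            return name
    return None


def _perturbed_bands(
    bands, profile: StrainProfile, rc: float
) -> list[Band]:
    """Apply the strain's dose response to the band table.

    Band amplitudes within a window are modulated with alternating sign,
    band centers shift by a fraction of the band width and widths broaden
    with dose — a shape change, so vector normalization cannot cancel the
    effect and the stress index grows monotonically with dose.
    """
    g = profile.dose_response(rc)
    out: list[Band] = []
    per_window_rank: dict[str, int] = {}
    for b in bands:
        w = _window_of(b.center)
        amp_w = profile.response.get(w, 0.0) if w else 0.0
        if amp_w == 0.0 or g == 0.0:
            out.append(b)
            continue
        rank = per_window_rank.get(w, 0)
        per_window_rank[w] = rank + 1
        sign = 1.0 if rank % 2 == 0 else -0.7
        out.append(
            Band(
                center=b.center + sign * 1.0 * b.sigma * amp_w * g,
                sigma=b.sigma * (1.0 + 0.35 * amp_w * g),
                amplitude=b.amplitude * (1.0 + 0.9 * sign * amp_w * g),
            )
        )
    return out


def _realize(
    cfg: SyntheticConfig,
    bands,
    rng: np.random.Generator,
    *,
    strain=None,
    condition=None,
    replicate=None,
) -> Spectrum:
    """One measured spectrum: bands (with replicate jitter) + drift + noise."""
    wn = cfg.grid()
    if cfg.amplitude_jitter > 0:
        factors = 1.0 + cfg.amplitude_jitter * rng.standard_normal(len(bands))
        bands = [replace(b, amplitude=b.amplitude * f) for b, f in zip(bands, factors)]
    y = _band_profile(wn, bands)
    y += _drift(wn, cfg.drift_amplitude)
    if cfg.noise_sigma > 0:
        y += cfg.noise_sigma * rng.standard_normal(wn.size)
    return Spectrum(
        wavenumbers=wn, intensities=y,
        strain=strain, condition=condition, replicate=replicate,
    )


def generate_control_spectrum(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    *,
    strain: str | None = None,
    condition: str = "RC_0",
    replicate: str | None = None,
) -> Spectrum:
    """An unstressed cell spectrum (water control)."""
    if not cfg.peaks:
        raise ValueError("empty peak table")
    return _realize(
        cfg, cfg.peaks, rng, strain=strain, condition=condition, replicate=replicate
    )


def generate_stressed_spectrum(
    cfg: SyntheticConfig,
    profile: StrainProfile,
    rc: float,
    rng: np.random.Generator,
    *,
    condition: str | None = None,
    replicate: str | None = None,
) -> Spectrum:
    """A spectrum of cells stressed at relative concentration ``rc``."""
    if rc < 0:
        raise ValueError("rc must be >= 0")
    if not cfg.peaks:
        raise ValueError("empty peak table")
    bands = _perturbed_bands(cfg.peaks, profile, rc)
    return _realize(
        cfg, bands, rng,
        strain=profile.name, condition=condition, replicate=replicate,
    )


def generate_experiment(
    cfg: SyntheticConfig,
    profiles=None,
    rng: np.random.Generator | None = None,
):
    """Full factorial strains x dose levels x replicates, plus viable counts.

    Returns ``(SpectrumSet, counts, truth)``: raw spectra (preprocess before
    computing SIs), a replicate counts table (strain, condition, replicate,
    cfu_per_ml) with counts drawn Poisson around base_count * survival(rc),
    and a truth table recording every generating parameter.
    """
    if profiles is None:
        profiles = default_profiles()
    if not profiles:
        raise ValueError("need at least one strain profile")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    spectra: list[Spectrum] = []
    count_rows = []
    truth_rows = []
    for profile in profiles:
        for condition, rc in cfg.rc_levels.items():
            for rep in range(1, cfg.n_replicates + 1):
                rep_id = str(rep)
                if rc == 0:
                    sp = generate_control_spectrum(
                        cfg, rng, strain=profile.name,
                        condition=condition, replicate=rep_id,
                    )
                else:
                    sp = generate_stressed_spectrum(
                        cfg, profile, rc, rng,
                        condition=condition, replicate=rep_id,
                    )
                spectra.append(sp)
                lam = cfg.base_count * profile.survival(rc)
                count_rows.append(
                    dict(
                        strain=profile.name,
                        condition=condition,
                        replicate=rep_id,
                        cfu_per_ml=float(rng.poisson(lam)),
                    )
                )
            truth_rows.append(
                dict(
                    strain=profile.name,
                    tolerance_class=profile.tolerance_class,
                    condition=condition,
                    rc=rc,
                    dose_response=profile.dose_response(rc),
                    survival=profile.survival(rc),
                    expected_mortality_pct=100.0
                    * (1.0 - profile.survival(rc) / profile.survival(0.0)),
                    kill_midpoint=profile.kill_midpoint,
                    kill_steepness=profile.kill_steepness,
                    gamma=profile.gamma,
                    **{f"response_{w}": profile.response.get(w, 0.0)
                       for w in ("W1", "W2", "W3", "W4", "W5")},
                )
            )
    return (
        SpectrumSet(spectra),
        pd.DataFrame(count_rows),
        pd.DataFrame(truth_rows),
    )


def quadratic_si_points(
    a: float,
    b: float,
    c: float,
    rc_levels=(25.0, 50.0, 100.0),
    n_replicates: int = 3,
    si_noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float]]:
    """(SI, RC) calibration points drawn from a known quadratic dose model.

    For each dose level the noiseless SI is the positive root of
    ``a SI^2 + b SI + c = rc``; Gaussian noise of scale ``si_noise`` is
    added to the SIs (none by default, so a quadratic fit recovers
    (a, b, c) exactly).  Control points (SI = 0, RC = c evaluated at 0,
    i.e. RC = 0 when c = 0) are represented by the dose-0 root when it
    exists, else (0, c).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    pts: list[tuple[float, float]] = []
    for rc in (0.0, *rc_levels):
        if rc == 0.0:
            si_true = 0.0
            rc_val = c  # the quadratic's own value at SI = 0
        else:
            if a == 0:
                si_true = (rc - c) / b
            else:
                disc = b * b - 4.0 * a * (c - rc)
                if disc < 0:
                    raise ValueError(f"no real SI solves the quadratic at rc={rc:g}")
                si_true = (-b + np.sqrt(disc)) / (2.0 * a)
                if si_true < 0:
                    si_true = (-b - np.sqrt(disc)) / (2.0 * a)
            rc_val = rc
        for _ in range(n_replicates):
            si = si_true + (si_noise * rng.standard_normal() if si_noise > 0 else 0.0)
            pts.append((si, rc_val))
    return pts


def write_experiment(
    sset: SpectrumSet,
    counts: pd.DataFrame,
    truth: pd.DataFrame,
    outdir,
) -> pd.DataFrame:
    """Write spectra, manifest, counts and truth tables to a directory.

    Emits the same file formats the analysis pipeline consumes: one
    two-column text file per spectrum plus a manifest CSV mapping files to
    (strain, condition, replicate).  Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spectra_dir = outdir / "spectra"
    spectra_dir.mkdir(exist_ok=True)
    manifest_rows = []
    for sp in sset:
        fname = f"{sp.strain}_{sp.condition}_r{sp.replicate}.csv"
        write_spectrum_table(sp, spectra_dir / fname)
        manifest_rows.append(
            dict(
                file=f"spectra/{fname}",
                strain=sp.strain,
                condition=sp.condition,
                replicate=sp.replicate,
            )
        )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    counts.to_csv(outdir / "counts.csv", index=False, float_format="%.9g")
    truth.to_csv(outdir / "truth.csv", index=False, float_format="%.9g")
    return manifest
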