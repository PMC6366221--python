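"""Published reference calibration for the three-strain yeast biosensor panel.

The bioassay was originally calibrated on three *Saccharomyces cerevisiae*
biosensor strains challenged with quaternary mixtures of lignocellulosic
inhibitors (acetic acid, formic acid, furfural, HMF) at relative
concentrations 25 / 50 / 100: Fm17 (resistant), Fp84 (intermediate) and
DSM70449 (sensitive).  This module carries the published calibration
constants and model outputs as a plain-text fixture so that the evaluation
statistics (correlation, t-test, quartile classification) can be recomputed
and checked without the original spectra, which were never deposited.

Two general-model variants were published per strain: the whole-spectrum
model (all weight on WS) and the weighted regional model over W1-W4.
"""

from __future__ import annotations

__all__ = [
    "STRAINS",
    "PRIMARY_COEFFICIENTS",
    "REFERENCE_PREDICTIONS",
    "EXPECTED_RCS",
    "EXPECTED_QUARTILES",
    "REPLICATE_SI_SPREAD",
]

STRAINS = ("Fp84", "DSM70449", "Fm17")

#: Published primary-model coefficients (a, b, c) and R^2 per strain/window.
PRIMARY_COEFFICIENTS = {
    ("Fp84", "W1"): dict(a=0.997, b=13.056, c=0.142, r2=0.498),
    ("Fp84", "W2"): dict(a=0.895, b=1.553, c=0.078, r2=0.938),
    ("Fp84", "W3"): dict(a=2.544, b=-10.997, c=-0.134, r2=0.990),
    ("Fp84", "W4"): dict(a=-0.989, b=15.862, c=-1.344, r2=0.502),
    ("Fp84", "WS"): dict(a=43.077, b=-96.031, c=0.063, r2=0.990),
    ("DSM70449", "W1"): dict(a=3.198, b=9.209, c=7.156, r2=0.960),
    ("DSM70449", "W2"): dict(a=0.679, b=1.147, c=5.264, r2=0.906),
    ("DSM70449", "W3"): dict(a=1.592, b=2.410, c=7.418, r2=0.941),
    ("DSM70449", "W4"): dict(a=14.301, b=-17.229, c=-0.122, r2=0.998),
    ("DSM70449", "WS"): dict(a=9.412, b=8.529, c=4.426, r2=0.957),
    ("Fm17", "W1"): dict(a=2.093, b=3.819, c=5.399, r2=0.950),
    ("Fm17", "W2"): dict(a=-0.005, b=5.776, c=5.083, r2=0.785),
    ("Fm17", "W3"): dict(a=-2.405, b=31.267, c=-9.201, r2=0.846),
    ("Fm17", "W4"): dict(a=-2.658, b=25.816, c=-1.647, r2=0.503),
    ("Fm17", "WS"): dict(a=2.990, b=10.959, c=3.898, r2=0.824),
}

#: Expected (true) relative concentrations of the three stressed dose levels.
EXPECTED_RCS = (25.00, 50.00, 100.00)

#: Published quartile classes of the expected doses.
EXPECTED_QUARTILES = (1, 2, 4)

#: Published general-model predictions and evaluation statistics.
#: ``weights`` follows (w1, w2, w3, w4, wS); ``predicted`` are the RCs at the
#: low / medium / high dose levels; ``corr``, ``t_test`` and ``quartiles``
#: are the published evaluation columns; ``p_value`` is the p-value quoted
#: in the published discussion of each model variant.
REFERENCE_PREDICTIONS = {
    ("Fp84", "whole"): dict(
        weights=(0, 0, 0, 0, 1),
        predicted=(21.61, 56.09, 97.24),
        corr=0.99, t_test=1.00, quartiles=(1, 2, 4), p_value=1.00,
    ),
    ("DSM70449", "whole"): dict(
        weights=(0, 0, 0, 0, 1),
        predicted=(15.54, 60.00, 95.01),
        corr=0.97, t_test=0.97, quartiles=(1, 2, 4), p_value=0.97,
    ),
    ("Fm17", "whole"): dict(
        weights=(0, 0, 0, 0, 1),
        predicted=(17.40, 72.86, 80.84),
        corr=0.83, t_test=0.97, quartiles=(1, 3, 4), p_value=None,
    ),
    ("Fp84", "regional"): dict(
        weights=(0, 0, 1, 0, 0),
        predicted=(29.48, 44.07, 100.00),
        corr=0.99, t_test=0.99, quartiles=(1, 2, 4), p_value=0.99,
    ),
    ("DSM70449", "regional"): dict(
        weights=(0.1, 0, 0.1, 0.8, 0),
        predicted=(24.30, 49.59, 99.75),
        corr=1.00, t_test=0.99, quartiles=(1, 2, 4), p_value=0.99,
    ),
    ("Fm17", "regional"): dict(
        weights=(1, 0, 0, 0, 0),
        predicted=(14.55, 60.33, 94.72),
        corr=0.96, t_test=0.96, quartiles=(1, 2, 4), p_value=0.96,
    ),
}

#: Published between-replicate spectral variability (SI units).
REPLICATE_SI_SPREAD = 2.5e-2
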