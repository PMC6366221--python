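"""Inverse calibration of inhibitor dose from spectral stress indexes.

Primary models are per-strain, per-window quadratics mapping a stress
index to a relative concentration (RC),

    RC_sw = a SI_sw^2 + b SI_sw + c ,

fitted by ordinary least squares on (SI, RC) calibration points.  A
general model for a strain is the weight-normalized combination of its
primary models,

    RC_s = sum_i w_i (a_i SI_i^2 + b_i SI_i + c_i) / sum_i w_i ,

over the four biochemical windows W1-W4 and/or the whole spectrum (WS).
Predicted concentrations are classified into quartile classes,

    CRC = floor(RC/25 + 1/2) ,

i.e. RC/25 rounded half-up, so the expected doses 25 / 50 / 100 fall in
classes 1 / 2 / 4.  Model quality against the expected dose scale is
assessed by the Pearson correlation and a pooled-variance two-sample
two-sided Student t-test between predicted and expected RC triples.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RCScale",
    "PrimaryModel",
    "GeneralModel",
    "PredictionReport",
    "fit_primary",
    "predict_primary",
    "predict_general",
    "classify_crc",
    "pearson_r",
    "ttest_predicted_vs_expected",
    "select_weights",
    "build_report",
]

log = logging.getLogger(__name__)

#: Window order used for weight vectors.
WEIGHT_ORDER = ("W1", "W2", "W3", "W4", "WS")


@dataclass(frozen=True)
class RCScale:
    """The relative-concentration dose scale of the bioassay.

    Levels: control (0), low (25), medium (50), high (100).  The quartile
    width used by classification is ``quartile`` (default 25).
    """

    levels: dict = field(
        default_factory=lambda: {"RC_0": 0.0, "RC_L": 25.0, "RC_M": 50.0, "RC_H": 100.0}
    )
    quartile: float = 25.0

    @property
    def stressed_levels(self) -> list[str]:
        return [k for k, v in self.levels.items() if v > 0]

    def value(self, label: str) -> float:
        return self.levels[label]

    def expected(self) -> np.ndarray:
        return np.array([self.levels[k] for k in self.stressed_levels])


@dataclass(frozen=True)
class PrimaryModel:
    """Quadratic SI -> RC calibration for one strain and spectral window."""

    strain: str
    window: str
    a: float
    b: float
    c: float
    r2: float = float("nan")

    def __call__(self, si: float) -> float:
        return predict_primary(self, si)


@dataclass(frozen=True)
class GeneralModel:
    """Weighted combination of a strain's primary models."""

    strain: str
    weights: dict  # window -> weight >= 0
    members: dict  # window -> PrimaryModel

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if total <= 0:
            raise ValueError("general model weights must not all be zero")
        for w, wt in self.weights.items():
            if wt < 0:
                raise ValueError(f"negative weight for window {w}")
            if wt > 0 and w not in self.members:
                raise ValueError(f"nonzero weight for window {w} without a primary model")


def fit_primary(points, strain: str = "", window: str = "") -> PrimaryModel:
    """Ordinary least-squares quadratic fit of RC on SI.

    ``points`` is a sequence of (SI, RC) pairs with at least 3 distinct SI
    values.  R^2 = 1 - SS_res/SS_tot is computed on the fitted points; a fit
    through exactly 3 distinct points is saturated (R^2 = 1).
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (SI, RC) points")
    si, rc = pts[:, 0], pts[:, 1]
    if np.unique(si).size < 3:
        raise ValueError("need >= 3 distinct SI values (quadratic underdetermined)")
    a, b, c = np.polyfit(si, rc, 2)
    resid = rc - (a * si**2 + b * si + c)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((rc - rc.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return PrimaryModel(strain=strain, window=window, a=float(a), b=float(b), c=float(c), r2=r2)


def predict_primary(m: PrimaryModel, si: float) -> float:
    """RC predicted by one primary model; raw (may be negative near SI=0)."""
    return m.a * si * si + m.b * si + m.c


def predict_general(g: GeneralModel, si_by_window: dict) -> float:
    """Weight-normalized RC prediction; reduces to the member under one-hot weights."""
    num = 0.0
    den = 0.0
    for window, wt in g.weights.items():
        if wt == 0:
            continue
        if window not in si_by_window:
            raise ValueError(f"missing SI for window {window} (weight {wt:g})")
        num += wt * predict_primary(g.members[window], si_by_window[window])
        den += wt
    if den == 0:
        raise ValueError("general model weights must not all be zero")
    return num / den


def classify_crc(rc: float, quartile: float = 25.0) -> int:
    """Quartile class of a predicted RC: floor(rc/quartile + 1/2), min 0.

    Negative predictions (a raw quadratic can dip below zero at small SI)
    map to class 0 with a logged note.
    """
    if not math.isfinite(rc):
        raise ValueError("RC must be finite")
    if rc < 0:
        log.info("negative predicted RC %.3f classified as 0", rc)
        return 0
    return int(math.floor(rc / quartile + 0.5))


def pearson_r(predicted, expected) -> float:
    """Sample Pearson correlation between predicted and expected RCs."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(expected, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length sequences of >= 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def ttest_predicted_vs_expected(predicted, expected) -> float:
    """Two-sample pooled-variance two-sided t-test p-value.

    Degenerate zero-variance case: p = 1 for equal means, else p = 0.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(expected, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per sample")
    pooled = np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)
    if pooled == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.pvalue)


def _weight_grid(n_windows: int, step: int = 10):
    """All weight vectors with entries in {0, 0.1, ..., 1} summing to 1."""
    for combo in itertools.product(range(step + 1), repeat=n_windows):
        if sum(combo) == step:
            yield tuple(c / step for c in combo)


def select_weights(
    primaries: dict,
    si_by_window_per_level: dict | None = None,
    expected: RCScale | None = None,
    strategy: str = "grid",
    manual_weights: dict | None = None,
    include_ws: bool = False,
) -> GeneralModel:
    """Choose the weight vector of a strain's general model.

    ``primaries`` maps window name -> PrimaryModel (same strain).
    Strategies:

    - ``manual``: use ``manual_weights`` verbatim.
    - ``best_r2``: all weight on the window with highest R^2 among W1-W4
      (WS included only with ``include_ws=True``).
    - ``grid``: exhaustive search over the weight simplex in steps of 0.1,
      minimizing the summed squared error of the general-model predictions
      against the expected RCs across the stressed dose levels
      (``si_by_window_per_level``: level label -> {window -> SI}).  Ties are
      broken toward fewer nonzero weights, then toward weight on
      higher-R^2 windows.
    """
    if not primaries:
        raise ValueError("no primary models supplied")
    strain = next(iter(primaries.values())).strain
    windows = [w for w in WEIGHT_ORDER if w in primaries and (include_ws or w != "WS")]
    if not windows:
        raise ValueError("no candidate windows for weighting")

    if strategy == "manual":
        if not manual_weights:
            raise ValueError("manual strategy requires manual_weights")
        weights = {w: float(manual_weights.get(w, 0.0)) for w in WEIGHT_ORDER if manual_weights.get(w, 0.0) != 0}
        return GeneralModel(strain=strain, weights=weights, members=dict(primaries))

    if strategy == "best_r2":
        best = max(windows, key=lambda w: primaries[w].r2)
        return GeneralModel(strain=strain, weights={best: 1.0}, members=dict(primaries))

    if strategy != "grid":
        raise ValueError(f"unknown weight strategy {strategy!r}")
    if si_by_window_per_level is None or expected is None:
        raise ValueError("grid strategy needs per-level SIs and the expected RC scale")

    levels = list(si_by_window_per_level)
    targets = np.array([expected.value(lv) for lv in levels])
    # member predictions per level are fixed; precompute
    member_pred = {
        w: np.array(
            [predict_primary(primaries[w], si_by_window_per_level[lv][w]) for lv in levels]
        )
        for w in windows
    }
    best_vec, best_key = None, None
    for vec in _weight_grid(len(windows)):
        pred = sum(wt * member_pred[w] for wt, w in zip(vec, windows))
        sse = float(np.sum((pred - targets) ** 2))
        n_nonzero = sum(1 for wt in vec if wt > 0)
        # tie-breaks: fewer nonzero weights, then more weight on high-R2 windows
        r2_score = -sum(wt * primaries[w].r2 for wt, w in zip(vec, windows))
        key = (round(sse, 12), n_nonzero, r2_score, vec)
        if best_key is None or key < best_key:
            best_key, best_vec = key, vec
    weights = {w: wt for w, wt in zip(windows, best_vec) if wt > 0}
    return GeneralModel(strain=strain, weights=weights, members=dict(primaries))


@dataclass
class PredictionReport:
    """Predicted doses of one general model against the expected scale."""

    strain: str
    levels: list
    predicted: list
    expected: list
    crc_predicted: list
    crc_expected: list
    pearson: float
    t_test_p: float

    @property
    def crc_match(self) -> list:
        return [p == e for p, e in zip(self.crc_predicted, self.crc_expected)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                strain=self.strain,
                level=self.levels,
                predicted_rc=self.predicted,
                expected_rc=self.expected,
                crc_predicted=self.crc_predicted,
                crc_expected=self.crc_expected,
                crc_match=self.crc_match,
                pearson=self.pearson,
                t_test_p=self.t_test_p,
            )
        )


def build_report(
    g: GeneralModel,
    si_by_window_per_level: dict,
    expected: RCScale | None = None,
) -> PredictionReport:
    """Predict each stressed dose level and score against the expected scale.

    Predictions are reported raw (not clamped); clamping to class >= 0
    happens only inside classification.
    """
    if expected is None:
        expected = RCScale()
    levels = [lv for lv in expected.stressed_levels if lv in si_by_window_per_level]
    if len(levels) < len(expected.stressed_levels):
        missing = set(expected.stressed_levels) - set(levels)
        raise ValueError(f"missing SIs for levels {sorted(missing)}")
    predicted = [predict_general(g, si_by_window_per_level[lv]) for lv in levels]
    exp_vals = [expected.value(lv) for lv in levels]
    return PredictionReport(
        strain=g.strain,
        levels=levels,
        predicted=predicted,
        expected=exp_vals,
        crc_predicted=[classify_crc(p, expected.quartile) for p in predicted],
        crc_expected=[classify_crc(e, expected.quartile) for e in exp_vals],
        pearson=pearson_r(predicted, exp_vals),
        t_test_p=ttest_predicted_vs_expected(predicted, exp_vals),
    )


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def primaries_to_frame(models) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(strain=m.strain, window=m.window, a=m.a, b=m.b, c=m.c, r2=m.r2) for m in models]
    )


def frame_to_primaries(df: pd.DataFrame) -> list[PrimaryModel]:
    return [
        PrimaryModel(strain=r.strain, window=r.window, a=r.a, b=r.b, c=r.c, r2=r.r2)
        for r in df.itertuples()
    ]


def general_to_frame(models) -> pd.DataFrame:
    rows = []
    for g in models:
        row = dict(strain=g.strain)
        for w in WEIGHT_ORDER:
            row[f"w_{w}"] = g.weights.get(w, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def fit_primaries_from_points(
    si_points: pd.DataFrame,
    scale: RCScale | None = None,
    windows=("W1", "W2", "W3", "W4", "WS"),
) -> dict:
    """Fit all (strain, window) primary models from a replicate-level SI table.

    ``si_points`` columns: strain, condition, window, si (see
    ``stress.compute_si_points``); conditions are RC level labels on
    ``scale``.  Returns {strain: {window: PrimaryModel}}.
    """
    if scale is None:
        scale = RCScale()
    out: dict[str, dict[str, PrimaryModel]] = {}
    for (strain, window), grp in si_points.groupby(["strain", "window"], sort=False):
        if window not in windows:
            continue
        pts = [
            (row.si, scale.value(row.condition))
            for row in grp.itertuples()
            if row.condition in scale.levels
        ]
        out.setdefault(strain, {})[window] = fit_primary(pts, strain=strain, window=window)
    return out
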