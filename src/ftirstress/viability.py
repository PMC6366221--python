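"""Cell mortality from viable plate counts.

M = (1 - Cv/Ct) * 100, with Cv the viable count (cells/ml) of the treated
suspension and Ct that of the untreated control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ViabilityRecord", "mortality", "mortality_table"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ViabilityRecord:
    strain: str
    condition: str
    cv: float  # viable cells/ml, treated
    ct: float  # viable cells/ml, control
    mortality_pct: float
    mortality_raw: float  # unclamped, diagnostic
    se_pct: float = float("nan")  # delta-method standard error of M


def mortality(cv: float, ct: float) -> tuple[float, float]:
    """Mortality percent from viable counts.

    Returns ``(clamped, raw)``: the raw value ``(1 - cv/ct) * 100`` and the
    value clamped to [0, 100].  A treated count above the control (growth
    during the assay) gives negative raw mortality, reported as 0.
    """
    if ct <= 0:
        raise ValueError("control count Ct must be positive")
    if cv < 0:
        raise ValueError("viable count Cv cannot be negative")
    raw = (1.0 - cv / ct) * 100.0
    clamped = min(100.0, max(0.0, raw))
    if raw < 0:
        log.info("Cv > Ct (raw mortality %.2f%%): clamped to 0", raw)
    return clamped, raw


def _delta_se(cv_mean, cv_sem, ct_mean, ct_sem) -> float:
    # M = 100 (1 - Cv/Ct); first-order error propagation in (Cv, Ct)
    if ct_mean <= 0:
        return float("nan")
    r = cv_mean / ct_mean
    var = (cv_sem / ct_mean) ** 2 + (r * ct_sem / ct_mean) ** 2
    return 100.0 * math.sqrt(var)


def mortality_table(
    counts: pd.DataFrame, control_condition: str
) -> list[ViabilityRecord]:
    """Mortality per (strain, condition) from a replicate counts table.

    ``counts`` columns: strain, condition, replicate, cfu_per_ml.  Replicate
    counts are averaged before the ratio; the standard error of M comes from
    the delta method on the replicate means.
    """
    required = {"strain", "condition", "cfu_per_ml"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    out: list[ViabilityRecord] = []
    for strain, sub in counts.groupby("strain", sort=False):
        ctrl = sub[sub["condition"] == control_condition]["cfu_per_ml"]
        if ctrl.empty:
            raise ValueError(f"no control counts for strain {strain!r}")
        ct_mean = float(ctrl.mean())
        ct_sem = float(ctrl.sem()) if len(ctrl) > 1 else 0.0
        for condition, grp in sub.groupby("condition", sort=False):
            if condition == control_condition:
                continue
            cv_mean = float(grp["cfu_per_ml"].mean())
            cv_sem = float(grp["cfu_per_ml"].sem()) if len(grp) > 1 else 0.0
            clamped, raw = mortality(cv_mean, ct_mean)
            out.append(
                ViabilityRecord(
                    strain=strain,
                    condition=condition,
                    cv=cv_mean,
                    ct=ct_mean,
                    mortality_pct=clamped,
                    mortality_raw=raw,
                    se_pct=_delta_se(cv_mean, cv_sem, ct_mean, ct_sem),
                )
            )
    return out


def mortality_frame(records: list[ViabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
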