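"""Growth-curve kinetics (lag, rate, endpoint) and response classification.

The screen distinguishes drug responses of a mismatch-repair-proficient
("WT") and a mismatch-repair-deficient mutator ("msh2") strain by three
summary statistics of each well's OD600 trace:

- ``mu_max`` — maximum specific growth rate (1/h), the steepest slope of
  the blank-subtracted log-OD curve;
- ``lag_h`` — lag phase (h), where the tangent at the ``mu_max`` window
  crosses the detection level (tangent-intercept method);
- ``od_end`` — OD at the final timepoint.

Classification into the five screen categories uses endpoint ratios
(resistance hit when WT OD600 / mutator OD600 <= 0.4) and the mutator's
lag (>= 24 h = resistance by selection of a mutant subpopulation;
< 24 h = resistance as a direct consequence of the MMR defect).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth_sim import GrowthCurve

__all__ = [
    "GrowthMetrics",
    "ResponseClass",
    "ResponseCall",
    "estimate_growth_metrics",
    "classify_response",
    "tally_catalog",
    "metrics_frame",
]


@dataclass(frozen=True)
class GrowthMetrics:
    """Summary kinetics of one well; ``lag_h is None`` means growth was
    never detected (censored)."""

    lag_h: float | None
    mu_max: float
    od_end: float
    od_blank: float
    t_end: float

    @property
    def censored(self) -> bool:
        return self.lag_h is None


class ResponseClass(enum.Enum):
    NO_EFFECT = "no_effect"
    SENSITIVE = "sensitive"
    RESISTANT_SHORT_LAG = "resistant_short_lag"
    RESISTANT_LONG_LAG = "resistant_long_lag"
    SYNTHETIC_GROWTH_DEFECT = "synthetic_growth_defect"


@dataclass(frozen=True)
class ResponseCall:
    """Classifier output: the category plus the relative-lag flag
    (mutator lag >= 2x its DMSO control's lag)."""

    category: ResponseClass
    prolonged_vs_control: bool


def estimate_growth_metrics(
    curve: GrowthCurve,
    *,
    window: int = 5,
    eps: float = 1e-6,
    detection_margin: float = 0.05,
    quant_floor: float = 0.01,
) -> GrowthMetrics:
    """Tangent-intercept kinetics on the ln-transformed, blank-subtracted OD.

    - ``od_blank`` = median of the first 3 readings (captures compound
      colour plus the inoculum signal).
    - ``mu_max`` = the largest least-squares slope of ``ln(od - blank + eps)``
      over a sliding ``window`` of points, restricted to windows whose
      blank-subtracted OD is everywhere >= ``quant_floor`` (below that the
      log of the blank-subtracted signal is dominated by the inoculum
      subtraction and its slope diverges).
    - ``lag_h`` = time where the tangent at the ``mu_max`` window crosses
      ``ln(detection_margin)``, clipped to [0, t_end].
    - censored (``lag_h = None``, ``mu_max = 0``) when the OD never exceeds
      ``blank + detection_margin``.
    """
    t = curve.times
    od = curve.od
    if len(t) < 10:
        raise ValueError(f"need >= 10 timepoints, got {len(t)}")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("timepoints must be uniformly spaced")
    if window < 2:
        raise ValueError("window must be >= 2")

    blank = float(np.median(od[:3]))
    y = od - blank
    od_end = float(od[-1])
    t_end = float(t[-1])

    if float(np.max(y)) < detection_margin:
        return GrowthMetrics(lag_h=None, mu_max=0.0, od_end=od_end, od_blank=blank, t_end=t_end)

    logy = np.log(np.clip(y, eps, None))

    # sliding least-squares slope: beta_i = sum_j c_j * logy[i+j]
    w = window
    tw = t[:w] - t[:w].mean()
    c = tw / np.sum(tw**2)
    slopes = np.convolve(logy, c[::-1], mode="valid")
    means = np.convolve(logy, np.ones(w) / w, mode="valid")

    ok = np.convolve((y >= quant_floor).astype(float), np.ones(w), mode="valid") >= w - 0.5
    if not np.any(ok):
        # grew past detection but never yielded a clean quantification window
        return GrowthMetrics(lag_h=None, mu_max=0.0, od_end=od_end, od_blank=blank, t_end=t_end)

    idx = int(np.argmax(np.where(ok, slopes, -np.inf)))
    mu_max = max(float(slopes[idx]), 0.0)

    if mu_max == 0.0:
        lag: float | None = None
    else:
        t_mid = float(t[idx : idx + w].mean())
        intercept = float(means[idx]) - mu_max * t_mid
        lag = (math.log(detection_margin) - intercept) / mu_max
        lag = min(max(lag, 0.0), t_end)
    return GrowthMetrics(lag_h=lag, mu_max=mu_max, od_end=od_end, od_blank=blank, t_end=t_end)


def classify_response(
    wt: GrowthMetrics,
    mut: GrowthMetrics,
    wt_ctrl: GrowthMetrics,
    mut_ctrl: GrowthMetrics,
    *,
    od_ratio_threshold: float = 0.4,
    lag_threshold_h: float = 24.0,
    kill_fraction: float = 0.4,
    unaffected_fraction: float = 0.7,
) -> ResponseCall:
    """Five-way call for one compound from (WT, mutator) drug wells and
    their DMSO controls.

    Decision rules, in order:

    1. both strains' od_end < ``kill_fraction`` of their controls -> sensitive;
    2. WT od_end / mutator od_end <= ``od_ratio_threshold`` -> resistance hit,
       long lag if the mutator's lag >= ``lag_threshold_h`` (censored lag
       counts as long), else short lag;
    3. mutator od_end < ``kill_fraction`` of its control while the WT is
       unaffected (>= ``unaffected_fraction`` of its control) ->
       synthetic growth defect;
    4. otherwise no effect.
    """
    if wt_ctrl.censored or mut_ctrl.censored:
        raise ValueError("control well failed to grow (censored control metrics)")
    if wt_ctrl.od_end <= 0 or mut_ctrl.od_end <= 0:
        raise ValueError("control endpoint OD must be positive")

    wt_rel = wt.od_end / wt_ctrl.od_end
    mut_rel = mut.od_end / mut_ctrl.od_end

    mut_lag = mut.lag_h if mut.lag_h is not None else math.inf
    ctrl_lag = mut_ctrl.lag_h if mut_ctrl.lag_h is not None else 0.0
    prolonged = mut_lag >= 2.0 * ctrl_lag if ctrl_lag > 0 else mut_lag > 0

    if wt_rel < kill_fraction and mut_rel < kill_fraction:
        cat = ResponseClass.SENSITIVE
    elif mut.od_end > 0 and wt.od_end / mut.od_end <= od_ratio_threshold:
        cat = (
            ResponseClass.RESISTANT_LONG_LAG
            if mut_lag >= lag_threshold_h
            else ResponseClass.RESISTANT_SHORT_LAG
        )
    elif mut_rel < kill_fraction and wt_rel >= unaffected_fraction:
        cat = ResponseClass.SYNTHETIC_GROWTH_DEFECT
    else:
        cat = ResponseClass.NO_EFFECT
    return ResponseCall(category=cat, prolonged_vs_control=prolonged)


def tally_catalog(sets: list[tuple[str, int]]) -> tuple[int, dict[str, int]]:
    """Sum compound-set sizes for screen bookkeeping.

    Returns (total, per-set breakdown). Negative counts are rejected.
    """
    breakdown: dict[str, int] = {}
    for name, n in sets:
        if n < 0:
            raise ValueError(f"negative compound count for set {name!r}: {n}")
        breakdown[name] = breakdown.get(name, 0) + n
    return sum(breakdown.values()), breakdown


def metrics_frame(curves: list[GrowthCurve], **kwargs) -> pd.DataFrame:
    """Per-well metrics table for a list of curves (plate CSV schema)."""
    rows = []
    for c in curves:
        m = estimate_growth_metrics(c, **kwargs)
        rows.append(
            {
                "well": c.well_id,
                "strain": c.strain,
                "compound": c.compound,
                "dose": c.dose,
                "lag_h": m.lag_h if m.lag_h is not None else float("nan"),
                "censored": m.censored,
                "mu_max": m.mu_max,
                "od_end": m.od_end,
                "od_blank": m.od_blank,
            }
        )
    return pd.DataFrame(rows)
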