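"""Dose-group comparison statistics.

The study design compares each irradiated group against the unirradiated
(0 Gy) group, per metric, with a classical two-tailed unpaired Student's
t-test (pooled variance, df = n_a + n_b - 2) at alpha = 0.05.  The unit of
replication is the image.  P-values are reported raw — no multiple-testing
correction — matching the original presentation; downstream reports state
this explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .morphometrics import summarize_morphology
from .topology import TopologyMetrics

__all__ = [
    "TTestResult",
    "DoseGroup",
    "ZeroVarianceError",
    "two_sample_ttest",
    "compare_doses",
]

_TOPOLOGY_METRICS = ("sw", "cc", "cpl", "k_mean")
_MORPHOLOGY_METRICS = ("area", "perimeter", "eccentricity", "roundness")


class ZeroVarianceError(ValueError):
    """Pooled variance is zero while group means differ: t undefined."""


@dataclass
class TTestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    n: tuple[int, int]


@dataclass
class DoseGroup:
    """All per-image observations for one (cell line, dose) condition."""

    cell_line_label: str
    dose: float
    per_image_metrics: list[TopologyMetrics] = field(default_factory=list)
    per_image_morphology: list = field(default_factory=list)  # lists of CellRecord

    def metric_values(self, metric: str) -> np.ndarray:
        """Per-image values of one metric (topology per image; morphology as
        the per-image mean over cells)."""
        if metric in _TOPOLOGY_METRICS:
            return np.array([getattr(t, metric) for t in self.per_image_metrics], float)
        if metric in _MORPHOLOGY_METRICS:
            return np.array(
                [
                    summarize_morphology(recs).loc[metric, "mean"]
                    for recs in self.per_image_morphology
                ],
                float,
            )
        raise ValueError(f"unknown metric {metric!r}")


def two_sample_ttest(a, b, welch: bool = False) -> TTestResult:
    """Two-tailed unpaired t-test; pooled-variance Student by default.

    With zero pooled variance the statistic is undefined: equal means give
    p = 1 by convention, unequal means raise :class:`ZeroVarianceError`.
    ``welch=True`` switches to the unequal-variance (Welch) form.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 observations")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            if ma == mb:
                return TTestResult(0.0, float(na + nb - 2), 1.0, (ma, mb),
                                   (math.sqrt(va), math.sqrt(vb)), (na, nb))
            raise ZeroVarianceError("zero variance with unequal means")
        t = (ma - mb) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if sp2 == 0:
            if ma == mb:
                return TTestResult(0.0, df, 1.0, (ma, mb), (0.0, 0.0), (na, nb))
            raise ZeroVarianceError("zero pooled variance with unequal means")
        t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(
        statistic=float(t),
        degrees_of_freedom=float(df),
        p_value=min(p, 1.0),
        group_means=(float(ma), float(mb)),
        group_sds=(float(math.sqrt(va)), float(math.sqrt(vb))),
        n=(na, nb),
    )


def compare_doses(
    groups: list[DoseGroup],
    metric: str = "sw",
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Test every nonzero-dose group against the 0 Gy group on one metric.

    Returns one row per nonzero dose: dose, group means/sds/sizes, t statistic,
    df, raw p-value and the significance flag at ``alpha``.
    """
    baseline = [g for g in groups if g.dose == 0]
    if not baseline:
        raise ValueError("a 0 Gy group is required as the comparison baseline")
    ref = baseline[0]
    ref_vals = ref.metric_values(metric)
    rows = []
    for g in sorted((g for g in groups if g.dose != 0), key=lambda g: g.dose):
        res = two_sample_ttest(ref_vals, g.metric_values(metric), welch=welch)
        rows.append(
            {
                "metric": metric,
                "dose": g.dose,
                "mean_0Gy": res.group_means[0],
                "sd_0Gy": res.group_sds[0],
                "mean_dose": res.group_means[1],
                "sd_dose": res.group_sds[1],
                "n_0Gy": res.n[0],
                "n_dose": res.n[1],
                "statistic": res.statistic,
                "df": res.degrees_of_freedom,
                "p_value": res.p_value,
                "significant": res.p_value < alpha,
            }
        )
    return pd.DataFrame(rows)
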