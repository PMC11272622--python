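"""Validation arithmetic and statistics for predicted vs measured pressures.

Deviation ratio (DRO), Shapiro-Wilk normality, Pearson correlation, and
paired t tests with Bonferroni correction — the standard battery for
comparing simulated interface pressures against instrument readings at the
small sample sizes (n < 50) of a pressure-testing study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedPressureSet",
    "dro",
    "mean_dro",
    "dro_table",
    "shapiro_wilk",
    "pearson_r",
    "paired_t_bonferroni",
    "validation_report",
]


@dataclass(frozen=True)
class PairedPressureSet:
    """Two matched pressure sets (mmHg) to compare, with optional labels."""

    x: tuple[float, ...]
    y: tuple[float, ...]
    name: str = ""
    labels: tuple | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", tuple(float(v) for v in self.x))
        object.__setattr__(self, "y", tuple(float(v) for v in self.y))
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if len(self.x) < 3:
            raise ValueError("need at least 3 pairs")
        if any(v < 0 for v in self.x + self.y):
            raise ValueError("pressures must be non-negative")
        if self.labels is not None and len(self.labels) != len(self.x):
            raise ValueError("labels must match the number of pairs")


def dro(P_rigid, P_LM):
    """Deviation ratio |P_rigid - P_LM| / P_rigid * 100, percent.

    The prediction-error metric between a measured reference pressure and a
    simulated one; scale-invariant.  Accepts scalars or arrays.
    """
    P_rigid = np.asarray(P_rigid, dtype=float)
    P_LM = np.asarray(P_LM, dtype=float)
    if np.any(P_rigid <= 0):
        raise ValueError("reference pressure P_rigid must be positive")
    out = np.abs(P_rigid - P_LM) / P_rigid * 100.0
    return float(out) if out.ndim == 0 else out


def mean_dro(P_rigid, P_LM) -> float:
    """Mean deviation ratio over matched pressure sets, percent."""
    return float(np.mean(dro(P_rigid, P_LM)))


def dro_table(P_rigid, P_LM, labels=None) -> pd.DataFrame:
    """Per-entry DRO table with reference, prediction and percent deviation."""
    vals = dro(P_rigid, P_LM)
    df = pd.DataFrame(
        {
            "P_rigid_mmHg": np.asarray(P_rigid, dtype=float),
            "P_LM_mmHg": np.asarray(P_LM, dtype=float),
            "DRO_percent": np.atleast_1d(vals),
        }
    )
    if labels is not None:
        df.insert(0, "label", list(labels))
    return df


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p) for small samples (3 <= n <= 50)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if not 3 <= n <= 50:
        raise ValueError(f"Shapiro-Wilk here is restricted to 3 <= n <= 50, got {n}")
    if np.ptp(x) == 0.0:
        raise ValueError("constant sample has no distribution to test")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation (rho, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("constant input has no defined correlation")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t_bonferroni(
    groups: list[PairedPressureSet], alpha: float = 0.05
) -> pd.DataFrame:
    """Paired t test per group with Bonferroni-adjusted two-sided p values.

    The adjustment multiplies each raw p by the number of comparisons
    actually run (capped at 1); significance is judged on the adjusted p at
    ``alpha``.  Identical pairs give t = 0, p = 1 by convention (the test
    statistic is degenerate at zero variance).
    """
    if not groups:
        raise ValueError("need at least one group")
    m = len(groups)
    rows = []
    for i, g in enumerate(groups):
        x = np.asarray(g.x)
        y = np.asarray(g.y)
        d = x - y
        if np.ptp(d) == 0.0:
            if d[0] == 0.0:
                t, p = 0.0, 1.0
            else:
                # constant non-zero shift: the t statistic diverges
                t, p = float(np.inf if d[0] > 0 else -np.inf), 0.0
        else:
            res = stats.ttest_rel(x, y)
            t, p = float(res.statistic), float(res.pvalue)
        p_adj = min(1.0, p * m)
        rows.append(
            {
                "group": g.name or f"group{i}",
                "n": len(x),
                "t": t,
                "p_raw": p,
                "p_adj": p_adj,
                "significant": bool(p_adj < alpha),
            }
        )
    return pd.DataFrame(rows)


def validation_report(
    pred_mmhg, meas_mmhg, labels=None, alpha: float = 0.05
) -> dict:
    """The full comparison battery between predicted and measured pressures.

    Returns per-entry DRO with its mean, Shapiro-Wilk normality of both
    sets, the Pearson correlation, and the paired t test (a single
    comparison, so the Bonferroni factor is 1).
    """
    pred = np.asarray(pred_mmhg, dtype=float)
    meas = np.asarray(meas_mmhg, dtype=float)
    table = dro_table(meas, pred, labels=labels)
    w_pred, p_pred = shapiro_wilk(pred)
    w_meas, p_meas = shapiro_wilk(meas)
    rho, p_rho = pearson_r(meas, pred)
    paired = paired_t_bonferroni(
        [PairedPressureSet(x=tuple(meas), y=tuple(pred), name="measured_vs_predicted")],
        alpha=alpha,
    )
    return {
        "n": int(len(pred)),
        "dro": table.to_dict(orient="records"),
        "mean_dro_percent": mean_dro(meas, pred),
        "normality": {
            "predicted": {"W": w_pred, "p": p_pred},
            "measured": {"W": w_meas, "p": p_meas},
        },
        "pearson": {"rho": rho, "p": p_rho},
        "paired_t": paired.to_dict(orient="records"),
    }
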