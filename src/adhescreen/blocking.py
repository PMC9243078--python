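"""Antibody-blocking adhesion assay statistics.

Adhesion is read out by liquid scintillation of metabolically radiolabeled
bacteria: percent adhesion = 100 * cpm(adherent) / cpm(added), per
replicate well (typically five technical replicates per condition).  Each
antibody-blocked condition is compared with the basic (unblocked) assay by
a two-sided, equal-variance two-sample Student's t-test at alpha = 0.05;
the statistic is computed from the pooled-variance formula

    t = (mean_x - mean_y) / (s_p * sqrt(1/n_x + 1/n_y)),
    s_p^2 = ((n_x - 1) s_x^2 + (n_y - 1) s_y^2) / (n_x + n_y - 2),

with a Welch variant available.  Only the reference distribution (the
Student t CDF) is delegated to scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AdhesionMeasurement",
    "PercentAdhesion",
    "BlockingResult",
    "percent_adhesion",
    "student_t",
    "compare_blocking",
    "blocking_table",
    "null_type_one_error",
]


@dataclass
class AdhesionMeasurement:
    """Scintillation counts for one condition: replicate adherent cpm and
    the cpm of the added bacterial suspension."""

    condition_id: str
    cpm_adherent: list[float]
    cpm_added: float

    def __post_init__(self) -> None:
        if self.cpm_added <= 0:
            raise ValueError("cpm_added must be positive")
        if any(c < 0 for c in self.cpm_adherent):
            raise ValueError("cpm values must be >= 0")


@dataclass
class PercentAdhesion:
    condition_id: str
    per_replicate: list[float]  # percent
    mean: float
    sd: float  # sample (n-1) standard deviation
    warning: bool = False  # adherent > added in some replicate


@dataclass
class BlockingResult:
    condition_id: str
    percent_adhesion_mean: float
    percent_adhesion_sd: float
    t_stat: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def percent_adhesion(measurement: AdhesionMeasurement) -> PercentAdhesion:
    """Per-replicate percent adhesion with mean and sample sd."""
    pct = [100.0 * c / measurement.cpm_added for c in measurement.cpm_adherent]
    arr = np.asarray(pct, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return PercentAdhesion(
        condition_id=measurement.condition_id,
        per_replicate=pct,
        mean=float(arr.mean()) if len(arr) else float("nan"),
        sd=sd,
        warning=any(c > measurement.cpm_added for c in measurement.cpm_adherent),
    )


def student_t(
    x: Sequence[float], y: Sequence[float], *, equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sample t statistic, degrees of freedom and two-sided p.

    Pooled-variance Student form by default; Welch-Satterthwaite when
    ``equal_var`` is False.  Degenerate zero-variance inputs: equal means
    give (t=0, p=1); unequal means give t = +/-inf, p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need at least two replicates per group")
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if equal_var:
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        denom = math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    else:
        se2x, se2y = vx / nx, vy / ny
        denom = math.sqrt(se2x + se2y)
        df = (
            (se2x + se2y) ** 2 / (se2x**2 / (nx - 1) + se2y**2 / (ny - 1))
            if denom > 0
            else nx + ny - 2
        )
    diff = mx - my
    if denom == 0.0:
        if diff == 0.0:
            return 0.0, float(df), 1.0
        return math.copysign(math.inf, diff), float(df), 0.0
    t = diff / denom
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), float(df), min(1.0, p)


def compare_blocking(
    treatment: AdhesionMeasurement,
    control: AdhesionMeasurement,
    *,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> BlockingResult:
    """Test an antibody-blocked condition against the basic adhesion assay.

    The test runs on per-replicate percent-adhesion values; ``significant``
    is a strict p < alpha decision.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    pt = percent_adhesion(treatment)
    pc = percent_adhesion(control)
    t, _, p = student_t(pt.per_replicate, pc.per_replicate, equal_var=equal_var)
    return BlockingResult(
        condition_id=treatment.condition_id,
        percent_adhesion_mean=pt.mean,
        percent_adhesion_sd=pt.sd,
        t_stat=t,
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
    )


def blocking_table(
    counts: pd.DataFrame,
    *,
    control_condition: str = "basic",
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Run the blocking comparison for every condition in a counts table.

    ``counts`` columns: condition, replicate, cpm_adherent, cpm_added.
    The control condition row reports its own mean/sd with no test.
    """
    meas = {}
    for cond, grp in counts.groupby("condition", sort=True):
        added = grp["cpm_added"].astype(float)
        if added.nunique() > 1:
            raise ValueError(f"{cond}: cpm_added must be constant within a condition")
        meas[cond] = AdhesionMeasurement(
            str(cond), grp["cpm_adherent"].astype(float).tolist(), float(added.iloc[0])
        )
    if control_condition not in meas:
        raise ValueError(f"control condition {control_condition!r} missing")
    control = meas[control_condition]
    rows = []
    pc = percent_adhesion(control)
    rows.append(
        {
            "condition": control.condition_id,
            "percent_adhesion_mean": pc.mean,
            "percent_adhesion_sd": pc.sd,
            "t_stat": float("nan"),
            "p_value": float("nan"),
            "significant": False,
        }
    )
    for cond, m in meas.items():
        if cond == control_condition:
            continue
        res = compare_blocking(m, control, alpha=alpha, equal_var=equal_var)
        rows.append(
            {
                "condition": res.condition_id,
                "percent_adhesion_mean": res.percent_adhesion_mean,
                "percent_adhesion_sd": res.percent_adhesion_sd,
                "t_stat": res.t_stat,
                "p_value": res.p_value,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)


def null_type_one_error(
    *,
    n_draws: int = 10_000,
    n_per_group: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
    equal_var: bool = True,
) -> float:
    """Empirical type-I error of the t-test under a shared-normal null.

    Vectorized: draws ``n_draws`` pairs of groups from the same normal and
    returns the fraction rejected at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_draws, n_per_group))
    y = rng.normal(size=(n_draws, n_per_group))
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    n = n_per_group
    if equal_var:
        df = 2 * n - 2
        sp2 = ((n - 1) * vx + (n - 1) * vy) / df
        t = (mx - my) / np.sqrt(sp2 * (2.0 / n))
        p = 2.0 * sps.t.sf(np.abs(t), df)
    else:
        se2 = vx / n + vy / n
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / ((vx / n) ** 2 / (n - 1) + (vy / n) ** 2 / (n - 1))
        p = 2.0 * sps.t.sf(np.abs(t), df)
    return float(np.mean(p < alpha))
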