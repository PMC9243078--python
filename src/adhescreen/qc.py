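"""Per-plate quality control on control-well distributions.

Every plate carries scrambled-siRNA negative controls, lethal transfection
(death) controls, antiserum adhesion-block controls and untreated wells.
QC summarizes each class (median/mean/sd of the bacteria-to-nuclei ratio
and of nuclei counts, over unflagged wells) and applies three rules:

* transfection — death-control wells must lose most nuclei relative to
  the negative controls (otherwise transfection failed);
* block — antiserum wells must sit near the assay floor, far below the
  negative-control ratio (otherwise staining or adhesion is off);
* reagent — scrambled and untreated ratios must agree (otherwise the
  transfection reagent itself perturbs adhesion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import CONTROL_CLASSES

__all__ = ["QCRules", "QCReport", "summarize_controls", "qc_plate", "qc_screen"]


@dataclass(frozen=True)
class QCRules:
    """Thresholds for the three plate-level control rules.

    r_death: max allowed death-control nuclei median as a fraction of the
    negative-control nuclei median.  r_block: max allowed antiserum-block
    ratio median as a fraction of the negative-control ratio median.
    r_reagent: max allowed relative difference between scrambled and
    untreated ratio medians.
    """

    r_death: float = 0.5
    r_block: float = 0.3
    r_reagent: float = 0.3


@dataclass
class QCReport:
    plate_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)
    separation_score: float | None = None

    def __post_init__(self) -> None:
        if self.passed != (not self.reasons):
            raise ValueError("pass flag inconsistent with reasons")


def summarize_controls(quant_table: pd.DataFrame) -> pd.DataFrame:
    """Per-control-class statistics for one plate.

    Expects well rows joined with their layout (``content_class``,
    ``bac_nuc_ratio``, ``n_nuclei``, ``flags``).  Flagged wells are excluded
    from the statistics.  Returns a frame indexed by content class with
    columns n_wells, ratio_median/mean/sd, nuclei_median/mean/sd.
    """
    ctrl = quant_table[quant_table["content_class"].isin(CONTROL_CLASSES)]
    if ctrl.empty:
        raise ValueError("plate has no control wells; QC impossible")
    flags = ctrl.get("flags")
    usable = ctrl if flags is None else ctrl[flags.fillna("").astype(str) == ""]
    out = {}
    for cls, grp in usable.groupby("content_class"):
        r = grp["bac_nuc_ratio"].astype(float)
        n = grp["n_nuclei"].astype(float)
        out[cls] = {
            "n_wells": len(grp),
            "ratio_median": r.median(),
            "ratio_mean": r.mean(),
            "ratio_sd": r.std(ddof=1),
            "nuclei_median": n.median(),
            "nuclei_mean": n.mean(),
            "nuclei_sd": n.std(ddof=1),
        }
    return pd.DataFrame.from_dict(out, orient="index").rename_axis("content_class")


def qc_plate(stats: pd.DataFrame, rules: QCRules | None = None, *, plate_id: str = "") -> QCReport:
    """Apply the control rules to one plate's :func:`summarize_controls` output."""
    rules = rules or QCRules()
    if "neg_ctrl_scrambled" not in stats.index:
        raise ValueError("QC requires negative-control statistics")
    neg = stats.loc["neg_ctrl_scrambled"]
    reasons: list[str] = []

    if "pos_ctrl_death" in stats.index:
        death = stats.loc["pos_ctrl_death"]
        if death["nuclei_median"] > rules.r_death * neg["nuclei_median"]:
            reasons.append("transfection")

    sep = None
    if "ab_block" in stats.index:
        ab = stats.loc["ab_block"]
        if ab["ratio_median"] > rules.r_block * neg["ratio_median"]:
            reasons.append("block")
        denom = float(np.nansum([neg["ratio_sd"], ab["ratio_sd"]]))
        if denom > 0:
            sep = float((neg["ratio_median"] - ab["ratio_median"]) / denom)

    if "untreated" in stats.index and neg["ratio_median"] > 0:
        unt = stats.loc["untreated"]
        rel = abs(unt["ratio_median"] - neg["ratio_median"]) / neg["ratio_median"]
        if rel > rules.r_reagent:
            reasons.append("reagent")

    return QCReport(plate_id=plate_id, passed=not reasons, reasons=reasons, separation_score=sep)


def qc_screen(quant_table: pd.DataFrame, rules: QCRules | None = None) -> pd.DataFrame:
    """QC every plate in a joined quant table; one report row per plate."""
    rows = []
    for plate_id, grp in quant_table.groupby("plate_id", sort=True):
        rep = qc_plate(summarize_controls(grp), rules, plate_id=str(plate_id))
        rows.append(
            {
                "plate_id": rep.plate_id,
                "pass": rep.passed,
                "reasons": ";".join(rep.reasons),
                "separation_score": rep.separation_score,
            }
        )
    return pd.DataFrame(rows)
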