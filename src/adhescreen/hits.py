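"""Plate normalization and the multi-round hit-calling cascade.

Normalization is control-based and per plate: percent-of-negative-control
(each well's bacteria-to-nuclei ratio as a percent of the same plate's
scrambled-siRNA median) for the primary and first validation rounds, and
fold-over-antiserum-block for the second validation round.  Hit calling is
threshold-based: a pooled-well gene is a primary hit when its adhesion
decrease exceeds 30%; deconvolved rounds require a minimum number of
concordant single siRNAs (2 of 3, then 2 of 5 with an independent library)
each exceeding the per-siRNA decrease threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .library import SAMPLE_CLASSES

__all__ = [
    "NormalizationError",
    "RoundSpec",
    "DecreaseBins",
    "CascadeResult",
    "normalize_percent_neg",
    "normalize_fold_abblock",
    "bin_decreases",
    "call_primary_hits",
    "call_concordance_hits",
    "run_cascade",
]


class NormalizationError(ValueError):
    """A plate cannot be normalized (no usable controls, or zero median)."""


@dataclass(frozen=True)
class RoundSpec:
    """Decision rule for one screening round.

    round 1 (pooled): hit iff decrease > threshold on the single pooled
    value; rounds 2-3: hit iff at least ``min_support`` of the gene's
    ``n_sirnas`` separately-tested duplexes each decrease adhesion by more
    than ``per_sirna_decrease_threshold`` percent.
    """

    round_id: int
    normalization_mode: str = "percent_neg"
    per_sirna_decrease_threshold: float = 30.0
    min_support: int = 1
    n_sirnas: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.min_support <= self.n_sirnas:
            raise ValueError("need 1 <= min_support <= n_sirnas")
        if not 0.0 < self.per_sirna_decrease_threshold < 100.0:
            raise ValueError("threshold must lie in (0, 100)")
        if self.normalization_mode not in ("percent_neg", "fold_abblock"):
            raise ValueError(f"unknown normalization mode {self.normalization_mode!r}")


DEFAULT_ROUNDS = (
    RoundSpec(1, "percent_neg", 30.0, 1, 1),
    RoundSpec(2, "percent_neg", 30.0, 2, 3),
    RoundSpec(3, "fold_abblock", 30.0, 2, 5),
)


@dataclass
class DecreaseBins:
    """Decrease-percentage histogram over sample wells: (70, 100],
    (50, 70], (25, 50], and everything else (incl. increased adhesion)."""

    gt70: int
    b50_70: int
    b25_50: int
    remainder: int

    @property
    def total(self) -> int:
        return self.gt70 + self.b50_70 + self.b25_50 + self.remainder

    def as_dict(self) -> dict:
        return {
            "(70,100]": self.gt70,
            "(50,70]": self.b50_70,
            "(25,50]": self.b25_50,
            "remainder": self.remainder,
        }


def _drop_flagged(df: pd.DataFrame) -> pd.DataFrame:
    if "flags" not in df.columns:
        return df
    return df[df["flags"].fillna("").astype(str) == ""]


def _normalize(
    quant_table: pd.DataFrame,
    *,
    reference_class: str,
    mode: str,
) -> pd.DataFrame:
    frames = []
    for plate_id, grp in quant_table.groupby("plate_id", sort=True):
        grp = _drop_flagged(grp).copy()
        ref = grp.loc[grp["content_class"] == reference_class, "bac_nuc_ratio"].astype(float)
        ref = ref[np.isfinite(ref)]
        if ref.empty:
            raise NormalizationError(f"plate {plate_id}: no usable {reference_class} wells")
        med = float(ref.median())
        if med <= 0:
            raise NormalizationError(f"plate {plate_id}: {reference_class} median is zero")
        if mode == "percent_neg":
            grp["normalized"] = 100.0 * grp["bac_nuc_ratio"].astype(float) / med
            grp["decrease_pct"] = 100.0 - grp["normalized"]
        else:
            grp["normalized"] = grp["bac_nuc_ratio"].astype(float) / med
            # decreases for concordance calls are still referenced to the
            # negative controls' fold values on the same plate
            neg = grp.loc[
                grp["content_class"] == "neg_ctrl_scrambled", "normalized"
            ].astype(float)
            neg = neg[np.isfinite(neg)]
            if not neg.empty and neg.median() > 0:
                grp["decrease_pct"] = 100.0 - 100.0 * grp["normalized"] / float(neg.median())
            else:
                grp["decrease_pct"] = np.nan
        grp["normalization_mode"] = mode
        frames.append(grp)
    if not frames:
        cols = list(quant_table.columns) + ["normalized", "decrease_pct", "normalization_mode"]
        return pd.DataFrame(columns=pd.unique(cols))
    return pd.concat(frames, ignore_index=True)


def normalize_percent_neg(quant_table: pd.DataFrame) -> pd.DataFrame:
    """Percent-to-negative-control normalization, per plate.

    normalized = 100 * ratio / median(scrambled-control ratios on the same
    plate); decrease_pct = 100 - normalized.  Flagged wells are dropped
    before the median is taken.
    """
    return _normalize(quant_table, reference_class="neg_ctrl_scrambled", mode="percent_neg")


def normalize_fold_abblock(quant_table: pd.DataFrame) -> pd.DataFrame:
    """Fold-over-antiserum-block normalization, per plate.

    normalized = ratio / median(antibody-block ratios on the same plate).
    A ``decrease_pct`` column referenced to the plate's negative-control
    fold median is added for hit calling.
    """
    return _normalize(quant_table, reference_class="ab_block", mode="fold_abblock")


def bin_decreases(normalized: pd.DataFrame, *, sample_only: bool = True) -> DecreaseBins:
    """Histogram adhesion decreases with upper-inclusive half-open bins.

    A well exactly on a boundary goes to the bin whose upper edge it
    equals (70 -> (50, 70]).  Wells with increased adhesion land in the
    remainder.
    """
    if (normalized["normalization_mode"] != "percent_neg").any():
        raise ValueError("bin_decreases requires percent_neg-normalized wells")
    df = normalized
    if sample_only:
        df = df[df["content_class"].isin(SAMPLE_CLASSES)]
    d = df["decrease_pct"].astype(float)
    d = d[np.isfinite(d)]
    gt70 = int(((d > 70) & (d <= 100)).sum())
    b50_70 = int(((d > 50) & (d <= 70)).sum())
    b25_50 = int(((d > 25) & (d <= 50)).sum())
    return DecreaseBins(gt70, b50_70, b25_50, remainder=int(len(d)) - gt70 - b50_70 - b25_50)


def call_primary_hits(normalized: pd.DataFrame, spec: RoundSpec) -> pd.DataFrame:
    """Round-1 calls on pooled wells: hit iff decrease strictly exceeds the
    threshold.  One row per gene, sorted by decrease descending (ties by
    gene id)."""
    df = normalized[normalized["content_class"] == "gene_pool"].copy()
    if df["gene_id"].duplicated().any():
        dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
        raise ValueError(f"duplicate pooled rows for genes: {dupes[:5]}")
    df["decrease_pct"] = df["decrease_pct"].astype(float)
    out = df[["gene_id", "normalized", "decrease_pct"]].copy()
    out["round_id"] = spec.round_id
    out["support"] = (out["decrease_pct"] > spec.per_sirna_decrease_threshold).astype(int)
    out["n_measured"] = 1
    out["mean_decrease_pct"] = out["decrease_pct"]
    out["hit"] = out["decrease_pct"] > spec.per_sirna_decrease_threshold
    out = out.sort_values(
        ["decrease_pct", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out[
        ["gene_id", "round_id", "normalized", "mean_decrease_pct", "support", "n_measured", "hit"]
    ]


def call_concordance_hits(normalized: pd.DataFrame, spec: RoundSpec) -> pd.DataFrame:
    """Deconvolution-round calls: per gene, support = number of single-siRNA
    wells whose decrease strictly exceeds the per-siRNA threshold; hit iff
    support >= min_support.  Genes with no measured wells are excluded."""
    df = normalized[normalized["content_class"] == "gene_single"].copy()
    rows = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        d = grp["decrease_pct"].astype(float)
        d = d[np.isfinite(d)]
        if d.empty:
            continue  # unmeasured gene: reported nowhere, warned by caller
        if len(d) > spec.n_sirnas:
            raise ValueError(f"gene {gene_id}: {len(d)} wells exceed n_sirnas={spec.n_sirnas}")
        support = int((d > spec.per_sirna_decrease_threshold).sum())
        rows.append(
            {
                "gene_id": gene_id,
                "round_id": spec.round_id,
                "normalized": float(grp["normalized"].astype(float).mean()),
                "mean_decrease_pct": float(d.mean()),
                "support": support,
                "n_measured": int(len(d)),
                "hit": support >= spec.min_support,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "round_id", "normalized", "mean_decrease_pct",
            "support", "n_measured", "hit",
        ],
    )
    if not out.empty:
        out = out.sort_values(
            ["mean_decrease_pct", "gene_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return out


@dataclass
class CascadeResult:
    candidates: list[str]
    rounds: list[pd.DataFrame]
    audit: pd.DataFrame

    @property
    def funnel(self) -> list[int]:
        return [int(r["hit"].sum()) for r in self.rounds]


def run_cascade(
    round_tables: Sequence[pd.DataFrame],
    specs: Sequence[RoundSpec] = DEFAULT_ROUNDS,
) -> CascadeResult:
    """Execute the hit cascade over normalized per-round well tables.

    ``round_tables[0]`` holds pooled wells; later tables hold single-siRNA
    wells and may only contain genes that were hits in the previous round
    (anything else is a protocol error).  Final candidates are the genes
    that are hits in every round.
    """
    if len(round_tables) != len(specs):
        raise ValueError("one RoundSpec per round table required")
    results: list[pd.DataFrame] = []
    prev_hits: set[str] | None = None
    for table, spec in zip(round_tables, specs):
        if spec.round_id == 1 or spec.n_sirnas == 1:
            res = call_primary_hits(table, spec)
        else:
            res = call_concordance_hits(table, spec)
        if prev_hits is not None:
            extra = set(res["gene_id"]) - prev_hits
            if extra:
                raise ValueError(
                    f"round {spec.round_id} contains genes absent from the prior "
                    f"round's hits: {sorted(extra)[:5]}"
                )
        results.append(res)
        prev_hits = set(res.loc[res["hit"], "gene_id"])

    candidates = sorted(prev_hits) if prev_hits is not None else []

    audit_cols = ["gene_id", "round_id", "support", "n_measured", "mean_decrease_pct", "hit"]
    audit_frames = [res[audit_cols] for res in results if not res.empty]
    audit = (
        pd.concat(audit_frames, ignore_index=True)
        if audit_frames
        else pd.DataFrame(columns=audit_cols)
    )
    return CascadeResult(candidates=candidates, rounds=results, audit=audit)
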