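"""End-to-end screen runs: simulate -> (quantify) -> QC -> normalize ->
hit cascade -> blocking, reproducible from (config, seed) alone.

The fast path ("counts" mode) draws well counts directly from the
generative model; "render" mode renders every well image and pushes it
through the image-quantification stage, which is slower and meant for
small screens and oracle checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blocking import blocking_table
from .hits import (
    DEFAULT_ROUNDS,
    CascadeResult,
    DecreaseBins,
    RoundSpec,
    bin_decreases,
    normalize_fold_abblock,
    normalize_percent_neg,
    run_cascade,
)
from .library import LibraryManifest, build_library, layout_plates, library_for_genes
from .qc import QCRules, qc_screen
from .quantify import SegmentationParams, WellImage, quantify_well
from .simulate import (
    GroundTruth,
    RenderSpec,
    extend_knockdown,
    render_well,
    sample_ground_truth,
    simulate_blocking_counts,
    simulate_screen_counts,
    well_rng,
)

__all__ = ["RunConfig", "RunReport", "run_all", "render_report"]

log = logging.getLogger("adhescreen")


@dataclass
class RunConfig:
    """Complete description of a synthetic screen run."""

    seed: int = 0
    n_genes: int = 200
    duplexes_per_gene: int = 3
    validation_duplexes_per_gene: int = 5
    n_receptors: int = 4
    effect_range: tuple[float, float] = (0.7, 0.95)
    knockdown_range: tuple[float, float] = (0.6, 0.9)
    offtarget_sd: float = 0.15
    death_efficacy: float = 0.85
    abblock_residual: float = 0.05
    pool_rule: str = "independent"
    controls_per_plate: int = 32
    plate_format: int = 384
    plate_effect_sd: float = 0.15
    mode: str = "counts"  # counts | render
    exclude_failed_plates: bool = True
    repeat_failed_plates: bool = True  # re-screen a QC-failed plate once
    render: RenderSpec = field(default_factory=RenderSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    qc_rules: QCRules = field(default_factory=QCRules)
    rounds: tuple[RoundSpec, ...] = DEFAULT_ROUNDS
    blocking_basic_adhesion: float = 0.10
    blocking_reduction: float = 0.35
    blocking_replicates: int = 5
    blocking_cpm_added: float = 50_000.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "render" in data and isinstance(data["render"], dict):
            d = data["render"]
            for k in ("image_shape", "nucleus_radius", "background_offset", "background_gradient"):
                if k in d:
                    d[k] = tuple(d[k])
            data["render"] = RenderSpec(**d)
        if "segmentation" in data and isinstance(data["segmentation"], dict):
            d = data["segmentation"]
            for k in ("nucleus_area_range", "bacteria_area_range"):
                if k in d:
                    d[k] = tuple(d[k])
            data["segmentation"] = SegmentationParams(**d)
        if "qc_rules" in data and isinstance(data["qc_rules"], dict):
            data["qc_rules"] = QCRules(**data["qc_rules"])
        if "rounds" in data:
            data["rounds"] = tuple(
                RoundSpec(**r) if isinstance(r, dict) else r for r in data["rounds"]
            )
        for k in ("effect_range", "knockdown_range"):
            if k in data and isinstance(data[k], list):
                data[k] = tuple(data[k])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Everything a run computed, plus provenance."""

    config_hash: str
    seed: int
    version: str
    candidates: list[str]
    receptor_genes: list[str]
    recall: float
    false_positive_rate: float
    funnel: list[int]
    bins: DecreaseBins
    qc: pd.DataFrame
    cascade: CascadeResult
    normalized_rounds: list[pd.DataFrame]
    blocking: pd.DataFrame

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "version": self.version,
            "funnel": self.funnel,
            "bins": self.bins.as_dict(),
            "candidates": self.candidates,
            "receptor_genes": self.receptor_genes,
            "recall": self.recall,
            "false_positive_rate": self.false_positive_rate,
            "plates_passing_qc": int(self.qc["pass"].sum()) if len(self.qc) else 0,
            "plates_total": int(len(self.qc)),
        }


def _sub_seeds(seed: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31 - 1)) for s in state]


def _quantify_rendered(
    plates, truth: GroundTruth, render: RenderSpec, seg: SegmentationParams,
    seed: int, pool_rule: str,
) -> pd.DataFrame:
    """Render every well in memory and quantify it (slow path)."""
    rows = []
    for p_idx, plate in enumerate(plates):
        for w_idx, coord in enumerate(sorted(plate.well_map)):
            spec = plate.well_map[coord]
            if spec.content_class == "empty":
                continue
            rng = well_rng(seed, p_idx, w_idx)
            wr = render_well(
                spec, truth, render, rng=rng, pool_rule=pool_rule,
                plate_id=plate.plate_id, coord=coord,
            )
            q = quantify_well(
                WellImage(wr.image[0], wr.image[1], well_id=coord, plate_id=plate.plate_id),
                seg,
            )
            row = q.to_row()
            row["content_class"] = spec.content_class
            row["gene_id"] = spec.gene_id or ""
            row["sirna_ids"] = ";".join(spec.sirna_ids)
            row["true_multiplier"] = wr.counts.true_multiplier
            rows.append(row)
    return pd.DataFrame(rows)


def _simulate_round(
    config: RunConfig, plates, truth: GroundTruth, seed: int
) -> pd.DataFrame:
    if config.mode == "render":
        return _quantify_rendered(
            plates, truth, config.render, config.segmentation, seed, config.pool_rule
        )
    return simulate_screen_counts(
        plates, truth, config.render,
        seed=seed, pool_rule=config.pool_rule, plate_effect_sd=config.plate_effect_sd,
    )


_EMPTY_QUANT_COLS = [
    "plate_id", "well", "content_class", "gene_id", "sirna_ids",
    "n_nuclei", "n_bacteria", "bac_nuc_ratio", "true_multiplier", "flags",
]
_EMPTY_QC_COLS = ["plate_id", "pass", "reasons", "separation_score"]


def _screen_round(
    config: RunConfig, plates, truth: GroundTruth, seed: int, repeat_seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one round and apply plate QC.

    A plate whose controls fail QC is re-screened once (fresh seed), as a
    lab would repeat it; plates failing twice are excluded when
    ``exclude_failed_plates`` is set.  A round with every plate excluded is
    an error.
    """
    quant = _simulate_round(config, plates, truth, seed)
    qc = qc_screen(quant, config.qc_rules)
    qc["attempt"] = 1
    failed = sorted(qc.loc[~qc["pass"], "plate_id"])
    if failed and config.repeat_failed_plates:
        log.warning("re-screening %d plate(s) failing QC: %s", len(failed), failed)
        subset = [p for p in plates if p.plate_id in set(failed)]
        requant = _simulate_round(config, subset, truth, repeat_seed)
        reqc = qc_screen(requant, config.qc_rules)
        reqc["attempt"] = 2
        quant = pd.concat(
            [quant[~quant["plate_id"].isin(set(failed))], requant], ignore_index=True
        )
        qc = pd.concat([qc, reqc], ignore_index=True)
        failed = sorted(reqc.loc[~reqc["pass"], "plate_id"])
    if config.exclude_failed_plates and failed:
        log.warning("excluding %d plate(s) failing QC: %s", len(failed), failed)
        quant = quant[~quant["plate_id"].isin(set(failed))]
        if quant.empty:
            raise RuntimeError("all plates failed QC; nothing to analyze")
    return quant, qc


def _empty_round(mode: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """No genes to test: nothing is plated, normalized table is empty."""
    norm = pd.DataFrame(
        columns=_EMPTY_QUANT_COLS + ["normalized", "decrease_pct", "normalization_mode"]
    )
    return norm, pd.DataFrame(columns=_EMPTY_QC_COLS + ["attempt"])


def run_all(config: RunConfig) -> RunReport:
    """Execute the full screen: three siRNA rounds plus antibody blocking."""
    seeds = _sub_seeds(config.seed, 12)
    specs = config.rounds

    log.info("stage simulate: %d genes, %d receptors", config.n_genes, config.n_receptors)
    library = build_library(
        config.n_genes, config.duplexes_per_gene, supplier_tag="supplier-A", seed=seeds[0]
    )
    frac = config.n_receptors / config.n_genes if config.n_genes else 0.0
    truth = sample_ground_truth(
        library,
        receptor_fraction=frac,
        effect_range=config.effect_range,
        knockdown_range=config.knockdown_range,
        offtarget_sd=config.offtarget_sd,
        death_efficacy=config.death_efficacy,
        abblock_residual=config.abblock_residual,
        seed=seeds[1],
    )

    # -- round 1: pooled genome-wide screen, percent-of-negative-control
    plates1 = layout_plates(
        library, pooled=True, controls_per_plate=config.controls_per_plate,
        plate_format=config.plate_format, plate_prefix="R1P",
    )
    quant1, qc1 = _screen_round(config, plates1, truth, seeds[2], seeds[8])
    norm1 = normalize_percent_neg(quant1)
    bins = bin_decreases(norm1)

    # -- round 2: hits deconvolved, one duplex per well, same library
    from .hits import call_concordance_hits, call_primary_hits

    r1 = call_primary_hits(norm1, specs[0])
    hits1 = r1.loc[r1["hit"], "gene_id"].tolist()
    lib2 = LibraryManifest(
        [g for g in library.genes if g.gene_id in set(hits1)], library.supplier_tag
    )
    if lib2.n_genes:
        plates2 = layout_plates(
            lib2, pooled=False, controls_per_plate=config.controls_per_plate,
            plate_format=config.plate_format, plate_prefix="R2P",
        )
        quant2, qc2 = _screen_round(config, plates2, truth, seeds[3], seeds[9])
        norm2 = normalize_percent_neg(quant2)
    else:
        norm2, qc2 = _empty_round("percent_neg")

    r2 = call_concordance_hits(norm2, specs[1])
    hits2 = r2.loc[r2["hit"], "gene_id"].tolist()

    # -- round 3: independent 5-duplex library, fold-over-antiserum-block
    lib3 = library_for_genes(
        hits2, config.validation_duplexes_per_gene, supplier_tag="supplier-B", seed=seeds[4]
    )
    if lib3.n_genes:
        truth3 = extend_knockdown(
            truth, lib3, knockdown_range=config.knockdown_range, seed=seeds[5]
        )
        plates3 = layout_plates(
            lib3, pooled=False, controls_per_plate=config.controls_per_plate,
            plate_format=config.plate_format, plate_prefix="R3P",
        )
        quant3, qc3 = _screen_round(config, plates3, truth3, seeds[6], seeds[10])
        norm3 = normalize_fold_abblock(quant3)
    else:
        norm3, qc3 = _empty_round("fold_abblock")

    cascade = run_cascade([norm1, norm2, norm3], specs)

    receptors = truth.receptor_genes
    n_null = config.n_genes - len(receptors)
    tp = len(set(cascade.candidates) & set(receptors))
    fp = len(set(cascade.candidates) - set(receptors))
    recall = tp / len(receptors) if receptors else float("nan")
    fpr = fp / n_null if n_null else float("nan")

    # -- antibody-blocking validation of the final candidates
    conditions = {"basic": config.blocking_basic_adhesion}
    for gene in cascade.candidates:
        conditions[f"anti-{gene}"] = config.blocking_basic_adhesion * (
            1.0 - config.blocking_reduction
        )
    blocking = blocking_table(
        simulate_blocking_counts(
            conditions,
            n_replicates=config.blocking_replicates,
            cpm_added=config.blocking_cpm_added,
            seed=seeds[7],
        )
    )

    qc_frames = [q for q in (qc1, qc2, qc3) if not q.empty]
    qc = (
        pd.concat(qc_frames, ignore_index=True)
        if qc_frames
        else pd.DataFrame(columns=_EMPTY_QC_COLS + ["attempt"])
    )
    return RunReport(
        config_hash=config.config_hash(),
        seed=config.seed,
        version=__version__,
        candidates=cascade.candidates,
        receptor_genes=receptors,
        recall=recall,
        false_positive_rate=fpr,
        funnel=cascade.funnel,
        bins=bins,
        qc=qc,
        cascade=cascade,
        normalized_rounds=[norm1, norm2, norm3],
        blocking=blocking,
    )


_CLASS_COLORS = {
    "gene_pool": "0.6",
    "gene_single": "0.6",
    "neg_ctrl_scrambled": "tab:red",
    "pos_ctrl_death": "tab:blue",
    "ab_block": "indigo",
    "untreated": "tab:green",
}


def render_report(report: RunReport, out_dir: str | Path) -> Path:
    """Write a markdown summary, per-round scatter figures and the audit
    tables for a completed run; returns the report path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    for i, norm in enumerate(report.normalized_rounds, start=1):
        if norm.empty:
            continue
        fig, ax = plt.subplots(figsize=(7, 3.2))
        df = norm.reset_index(drop=True)
        for cls, grp in df.groupby("content_class"):
            ax.scatter(
                grp.index, grp["normalized"], s=8,
                color=_CLASS_COLORS.get(cls, "0.6"), label=cls, alpha=0.8,
            )
        ax.set_xlabel("well")
        ax.set_ylabel(
            "% of negative control" if (norm["normalization_mode"] == "percent_neg").all()
            else "fold over antiserum block"
        )
        ax.set_title(f"round {i} normalized adhesion")
        ax.legend(fontsize=6, loc="upper right", ncol=2)
        fig.tight_layout()
        fig.savefig(out_dir / f"round{i}_scatter.png", dpi=120)
        plt.close(fig)

    report.cascade.audit.to_csv(out_dir / "audit.csv", index=False)
    report.qc.to_csv(out_dir / "qc.csv", index=False)
    report.blocking.to_csv(out_dir / "blocking_results.csv", index=False)

    s = report.summary()
    lines = [
        "# Screen run report",
        "",
        f"- seed: {s['seed']}  |  config: `{s['config_hash']}`  |  version: {s['version']}",
        f"- plates passing QC: {s['plates_passing_qc']}/{s['plates_total']}",
        f"- hit funnel (rounds 1-3): {' -> '.join(str(v) for v in s['funnel'])}",
        f"- final candidates: {', '.join(s['candidates']) or '(none)'}",
        f"- planted receptors: {', '.join(s['receptor_genes']) or '(none)'}",
        f"- recall: {s['recall']:.3f}  |  null false-positive rate: {s['false_positive_rate']:.4f}",
        "",
        "## Adhesion-decrease bins (round 1 sample wells)",
        "",
        "| bin | wells |",
        "|---|---|",
    ]
    for k, v in s["bins"].items():
        lines.append(f"| {k} | {v} |")
    lines += ["", "## Antibody blocking", "", "```", report.blocking.to_string(index=False), "```"]
    path = out_dir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
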