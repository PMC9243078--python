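"""Synthetic screen generator.

The latent model the screen estimates: each gene g carries an adhesion
effect e_g in [0, 1] (the fractional loss of bacterial adhesion under full
silencing; 0 for non-receptor genes) and each siRNA duplex a knockdown
efficacy k in [0, 1].  A well's expected adhesion, relative to untreated
cells, is the multiplier

    m = (1 - e_g * k_eff) * L,    L ~ lognormal, E[L] = 1,

where k_eff combines the duplexes present in the well (independent-action
pooling by default) and L is two-sided multiplicative off-target noise —
real screens show both decreased and increased adhesion.  Control wells:
scrambled/untreated have e = 0, antiserum-block wells sit at a small
residual adhesion fraction, and death-control wells keep m = 1 but lose
most nuclei.

Readouts are generated either as counts (nuclei ~ Poisson, bacteria ~
Poisson conditional on nuclei) or as rendered two-channel 16-bit images:
DAPI nuclei as Gaussian blobs, immunostained bacteria as diffraction-
limited puncta, over an offset + gradient background with Poisson photon
and Gaussian read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .library import CONTROL_CLASSES, LibraryManifest, PlateLayout, WellSpec

__all__ = [
    "GroundTruth",
    "RenderSpec",
    "WellCounts",
    "WellRender",
    "sample_ground_truth",
    "extend_knockdown",
    "adhesion_multiplier",
    "emit_counts",
    "simulate_screen_counts",
    "render_well",
    "render_screen",
    "simulate_blocking_counts",
    "write_well_tiff",
    "read_well_tiff",
    "well_rng",
]


@dataclass
class GroundTruth:
    """Latent per-gene effects and per-duplex efficacies behind a screen."""

    gene_effect: dict[str, float]
    knockdown: dict[str, float]
    offtarget_sd: float = 0.15
    death_efficacy: float = 0.85
    abblock_residual: float = 0.05

    def validate(self) -> None:
        for name, vals in (("gene_effect", self.gene_effect), ("knockdown", self.knockdown)):
            for k, v in vals.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{k}] = {v} outside [0, 1]")
        for name in ("death_efficacy", "abblock_residual"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.offtarget_sd < 0:
            raise ValueError("offtarget_sd must be >= 0")

    @property
    def receptor_genes(self) -> list[str]:
        return sorted(g for g, e in self.gene_effect.items() if e > 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"kind": "gene", "id": g, "value": e} for g, e in self.gene_effect.items()]
        rows += [{"kind": "sirna", "id": s, "value": k} for s, k in self.knockdown.items()]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RenderSpec:
    """Optical and statistical description of one rendered well image.

    Defaults describe a single 512x512 field of a confluent monolayer:
    ~300 nuclei of radius 8 +/- 2 px (Gaussian profile, sigma = radius/2)
    and on average 4 adherent bacteria per nucleus rendered as puncta of
    sigma 1.2 px.  Intensities are photon counts on a 16-bit detector.
    """

    image_shape: tuple[int, int] = (512, 512)
    bit_depth: int = 16
    pixel_size: float = 0.65  # um/px
    nuclei_per_well: float = 300.0
    nucleus_radius: tuple[float, float] = (8.0, 2.0)  # mean, sd in px
    bacteria_per_nucleus_baseline: float = 4.0
    punctum_sigma: float = 1.2
    dapi_amplitude: float = 3000.0
    green_amplitude: float = 1500.0
    background_offset: tuple[float, float] = (100.0, 80.0)  # per channel
    background_gradient: tuple[float, float] = (40.0, 30.0)  # ramp amplitude
    photon_noise: bool = True
    read_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.nuclei_per_well < 0 or self.bacteria_per_nucleus_baseline < 0:
            raise ValueError("expected object counts must be >= 0")
        if min(self.image_shape) <= 0:
            raise ValueError("image dimensions must be positive")

    def noise_free(self) -> "RenderSpec":
        """Copy with all noise and background terms off (oracle renders)."""
        return replace(
            self,
            background_offset=(0.0, 0.0),
            background_gradient=(0.0, 0.0),
            photon_noise=False,
            read_noise_sd=0.0,
        )


@dataclass
class WellCounts:
    """Fast-path readout record, carrying its generating multiplier."""

    plate_id: str
    well: str
    content_class: str
    gene_id: str | None
    n_nuclei: int
    n_bacteria: int
    bac_nuc_ratio: float
    true_multiplier: float


@dataclass
class WellRender:
    """Rendered image plus the embedded ground-truth object lists."""

    image: np.ndarray  # (2, h, w) uint16; page 0 DAPI, page 1 green
    nuclei: pd.DataFrame  # row, col, radius
    puncta: pd.DataFrame  # row, col
    counts: WellCounts
    clipped: bool = False


def well_rng(seed: int, plate_index: int, well_index: int) -> np.random.Generator:
    """Per-well generator from a top-level seed via a counter spawn-key.

    Any well is re-simulable in isolation from ``(seed, plate, well)``.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(plate_index, well_index))
    )


def sample_ground_truth(
    manifest: LibraryManifest,
    *,
    receptor_fraction: float = 0.02,
    effect_range: tuple[float, float] = (0.7, 0.95),
    knockdown_range: tuple[float, float] = (0.6, 0.9),
    offtarget_sd: float = 0.15,
    death_efficacy: float = 0.85,
    abblock_residual: float = 0.05,
    receptor_genes: list[str] | None = None,
    gene_effects: dict[str, float] | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Draw the latent screen parameters for a library.

    A ``receptor_fraction`` of genes (or an explicit ``receptor_genes``
    list) receives an adhesion effect drawn uniformly from
    ``effect_range``; every other gene has effect 0.  ``gene_effects``
    overrides sampling for the genes it names (used to carry effects across
    screening rounds with a new library).
    """
    if not 0.0 <= receptor_fraction <= 1.0:
        raise ValueError("receptor_fraction must be in [0, 1]")
    for lo, hi in (effect_range, knockdown_range):
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("distribution ranges must satisfy 0 <= lo <= hi <= 1")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    gene_ids = [g.gene_id for g in manifest.genes]
    if receptor_genes is None:
        n_receptors = int(round(receptor_fraction * len(gene_ids)))
        receptor_genes = sorted(rng.choice(gene_ids, size=n_receptors, replace=False).tolist())
    else:
        unknown = set(receptor_genes) - set(gene_ids)
        if unknown:
            raise ValueError(f"receptor genes not in manifest: {sorted(unknown)}")

    effect = {g: 0.0 for g in gene_ids}
    draws = rng.uniform(effect_range[0], effect_range[1], size=len(receptor_genes))
    for g, e in zip(receptor_genes, draws):
        effect[g] = float(e)
    if gene_effects:
        effect.update({g: float(e) for g, e in gene_effects.items() if g in effect})

    knockdown = {}
    for g in manifest.genes:
        for s in g.sirna_ids:
            knockdown[s] = float(rng.uniform(*knockdown_range))

    truth = GroundTruth(
        gene_effect=effect,
        knockdown=knockdown,
        offtarget_sd=offtarget_sd,
        death_efficacy=death_efficacy,
        abblock_residual=abblock_residual,
    )
    truth.validate()
    return truth


def extend_knockdown(
    truth: GroundTruth,
    manifest: LibraryManifest,
    *,
    knockdown_range: tuple[float, float] = (0.6, 0.9),
    seed: int = 0,
) -> GroundTruth:
    """Ground truth for a new library (e.g. a second supplier's duplexes)
    keeping gene effects fixed and sampling efficacies for unseen duplexes."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    knockdown = dict(truth.knockdown)
    effect = dict(truth.gene_effect)
    for g in manifest.genes:
        effect.setdefault(g.gene_id, 0.0)
        for s in g.sirna_ids:
            if s not in knockdown:
                knockdown[s] = float(rng.uniform(*knockdown_range))
    out = replace(truth, gene_effect=effect, knockdown=knockdown)
    out.validate()
    return out


def _pooled_knockdown(ks: list[float], pool_rule: str) -> float:
    if not ks:
        return 0.0
    if pool_rule == "independent":
        prod = 1.0
        for k in ks:
            prod *= 1.0 - k
        return 1.0 - prod
    if pool_rule == "max":
        return max(ks)
    raise ValueError(f"unknown pool_rule {pool_rule!r}")


def adhesion_multiplier(
    well: WellSpec,
    truth: GroundTruth,
    rng: np.random.Generator,
    *,
    pool_rule: str = "independent",
) -> float:
    """Latent adhesion multiplier m for one well (1 = untreated level)."""
    if well.content_class == "empty":
        raise ValueError("empty wells carry no biology to simulate")
    sd = truth.offtarget_sd
    noise = float(rng.lognormal(mean=-0.5 * sd * sd, sigma=sd)) if sd > 0 else 1.0
    cls = well.content_class
    if cls in ("neg_ctrl_scrambled", "untreated", "pos_ctrl_death"):
        return noise
    if cls == "ab_block":
        return truth.abblock_residual * noise
    if cls in ("gene_pool", "gene_single"):
        e = truth.gene_effect.get(well.gene_id, 0.0)
        ks = [truth.knockdown[s] for s in well.sirna_ids]
        k_eff = _pooled_knockdown(ks, pool_rule)
        return (1.0 - e * k_eff) * noise
    raise ValueError(f"unknown content class {cls!r}")


def emit_counts(
    well: WellSpec,
    truth: GroundTruth,
    render: RenderSpec,
    rng: np.random.Generator,
    *,
    pool_rule: str = "independent",
    plate_id: str = "P001",
    coord: str = "A01",
) -> WellCounts:
    """Draw a well's (nuclei, bacteria) counts without rendering pixels.

    nuclei ~ Poisson(nuclei_per_well * survival) where survival is
    1 - death_efficacy for the death control and 1 otherwise;
    bacteria | nuclei ~ Poisson(nuclei * baseline * m).
    """
    m = adhesion_multiplier(well, truth, rng, pool_rule=pool_rule)
    survival = 1.0 - truth.death_efficacy if well.content_class == "pos_ctrl_death" else 1.0
    n_nuclei = int(rng.poisson(render.nuclei_per_well * survival))
    lam = n_nuclei * render.bacteria_per_nucleus_baseline * m
    n_bacteria = int(rng.poisson(lam)) if lam > 0 else 0
    ratio = n_bacteria / n_nuclei if n_nuclei > 0 else float("nan")
    return WellCounts(
        plate_id=plate_id,
        well=coord,
        content_class=well.content_class,
        gene_id=well.gene_id,
        n_nuclei=n_nuclei,
        n_bacteria=n_bacteria,
        bac_nuc_ratio=ratio,
        true_multiplier=m,
    )


def simulate_screen_counts(
    plates: list[PlateLayout],
    truth: GroundTruth,
    render: RenderSpec,
    *,
    seed: int = 0,
    pool_rule: str = "independent",
    plate_effect_sd: float = 0.0,
) -> pd.DataFrame:
    """Counts-mode simulation of a whole screen.

    Optionally applies a per-plate lognormal scale to the bacterial channel
    (plate-to-plate staining/adhesion batch effects) which per-plate
    normalization must cancel.
    """
    rows = []
    plate_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    for p_idx, plate in enumerate(plates):
        scale = (
            float(plate_rng.lognormal(mean=0.0, sigma=plate_effect_sd))
            if plate_effect_sd > 0
            else 1.0
        )
        for w_idx, coord in enumerate(sorted(plate.well_map)):
            spec = plate.well_map[coord]
            if spec.content_class == "empty":
                continue
            rng = well_rng(seed, p_idx, w_idx)
            rec = emit_counts(
                spec, truth, render, rng, pool_rule=pool_rule, plate_id=plate.plate_id, coord=coord
            )
            rows.append(
                {
                    "plate_id": rec.plate_id,
                    "well": rec.well,
                    "content_class": rec.content_class,
                    "gene_id": rec.gene_id if rec.gene_id else "",
                    "sirna_ids": ";".join(spec.sirna_ids),
                    "n_nuclei": rec.n_nuclei,
                    "n_bacteria": rec.n_bacteria,
                    "bac_nuc_ratio": rec.bac_nuc_ratio * scale,
                    "true_multiplier": rec.true_multiplier,
                    "flags": "" if rec.n_nuclei > 0 else "zero_nuclei",
                }
            )
    return pd.DataFrame(rows)


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_dist: float,
    max_tries: int = 200,
) -> tuple[np.ndarray, bool]:
    """Uniform positions with pairwise separation; flags when crowding
    forces unconstrained placement."""
    pts: list[tuple[float, float]] = []
    clipped = False
    h, w = shape
    lo_r, hi_r = margin, h - margin
    lo_c, hi_c = margin, w - margin
    if lo_r >= hi_r or lo_c >= hi_c:
        raise ValueError("image too small for the requested margin")
    d2 = min_dist * min_dist
    for _ in range(n):
        placed = False
        for _ in range(max_tries):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= d2 for pr, pc in pts):
                pts.append((r, c))
                placed = True
                break
        if not placed:
            pts.append((rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)))
            clipped = True
    return np.asarray(pts, dtype=float).reshape(n, 2), clipped


def _add_gaussian(img: np.ndarray, r0: float, c0: float, sigma: float, amp: float) -> None:
    h, w = img.shape
    half = max(2, int(math.ceil(4 * sigma)))
    r_lo, r_hi = max(0, int(r0) - half), min(h, int(r0) + half + 1)
    c_lo, c_hi = max(0, int(c0) - half), min(w, int(c0) + half + 1)
    rr = np.arange(r_lo, r_hi)[:, None] - r0
    cc = np.arange(c_lo, c_hi)[None, :] - c0
    img[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(-(rr * rr + cc * cc) / (2 * sigma * sigma))


def render_well(
    well: WellSpec,
    truth: GroundTruth,
    render: RenderSpec,
    seed: int = 0,
    *,
    pool_rule: str = "independent",
    plate_id: str = "P001",
    coord: str = "A01",
    rng: np.random.Generator | None = None,
) -> WellRender:
    """Render a two-channel 16-bit well image with embedded ground truth.

    Channel 0 (DAPI): nuclei as Gaussian blobs, sigma = radius / 2.
    Channel 1 (green): bacteria as Gaussian puncta of ``punctum_sigma``.
    Identical (well, truth, render, seed) gives a bit-identical image.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(4,)))
    counts = emit_counts(
        well, truth, render, rng, pool_rule=pool_rule, plate_id=plate_id, coord=coord
    )
    h, w = render.image_shape
    mean_r, sd_r = render.nucleus_radius

    # blobs keep >= 4 radii of separation so thresholded footprints of even
    # the largest nuclei stay disjoint; crowded fields fall back to
    # unconstrained placement and set the clipped flag
    nuc_margin = 3.0 * mean_r
    nuc_pos, clipped_n = _place_points(
        rng, counts.n_nuclei, (h, w), nuc_margin, min_dist=4.0 * mean_r
    )
    radii = np.clip(rng.normal(mean_r, sd_r, size=counts.n_nuclei), 0.6 * mean_r, 1.75 * mean_r)

    punc_margin = 6.0 * render.punctum_sigma
    punc_pos, clipped_p = _place_points(
        rng, counts.n_bacteria, (h, w), punc_margin, min_dist=8.0 * render.punctum_sigma
    )

    dapi = np.zeros((h, w), dtype=float)
    green = np.zeros((h, w), dtype=float)
    for (r0, c0), rad in zip(nuc_pos, radii):
        _add_gaussian(dapi, r0, c0, sigma=rad / 2.0, amp=render.dapi_amplitude)
    for r0, c0 in punc_pos:
        _add_gaussian(green, r0, c0, sigma=render.punctum_sigma, amp=render.green_amplitude)

    ramp = (np.arange(h)[:, None] + np.arange(w)[None, :]) / max(1, h + w - 2)
    channels = []
    for img, off, grad in zip(
        (dapi, green), render.background_offset, render.background_gradient
    ):
        img = img + off + grad * ramp
        if render.photon_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if render.read_noise_sd > 0:
            img = img + rng.normal(0.0, render.read_noise_sd, size=img.shape)
        channels.append(np.clip(np.round(img), 0, 2**render.bit_depth - 1).astype(np.uint16))

    nuclei_df = pd.DataFrame(
        {"row": nuc_pos[:, 0], "col": nuc_pos[:, 1], "radius": radii}
        if counts.n_nuclei
        else {"row": [], "col": [], "radius": []}
    )
    puncta_df = pd.DataFrame(
        {"row": punc_pos[:, 0], "col": punc_pos[:, 1]}
        if counts.n_bacteria
        else {"row": [], "col": []}
    )
    return WellRender(
        image=np.stack(channels),
        nuclei=nuclei_df,
        puncta=puncta_df,
        counts=counts,
        clipped=clipped_n or clipped_p,
    )


def render_screen(
    plates: list[PlateLayout],
    truth: GroundTruth,
    render: RenderSpec,
    out_dir: str | Path,
    *,
    seed: int = 0,
    pool_rule: str = "independent",
) -> pd.DataFrame:
    """Render every well of a screen to multi-page TIFFs; returns a manifest
    table of file paths and generating counts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
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
            path = out_dir / f"{plate.plate_id}_{coord}.tif"
            write_well_tiff(wr.image, path)
            rows.append(
                {
                    "plate_id": plate.plate_id,
                    "well": coord,
                    "content_class": spec.content_class,
                    "gene_id": spec.gene_id or "",
                    "sirna_ids": ";".join(spec.sirna_ids),
                    "path": str(path),
                    "true_nuclei": wr.counts.n_nuclei,
                    "true_bacteria": wr.counts.n_bacteria,
                    "true_multiplier": wr.counts.true_multiplier,
                    "clipped": wr.clipped,
                }
            )
    return pd.DataFrame(rows)


def write_well_tiff(image: np.ndarray, path: str | Path) -> None:
    """Write a (2, h, w) uint16 stack as a two-page grayscale TIFF
    (page 0 = DAPI, page 1 = green)."""
    tifffile.imwrite(path, image, photometric="minisblack")


def read_well_tiff(path: str | Path) -> np.ndarray:
    image = tifffile.imread(path)
    if image.ndim != 3 or image.shape[0] != 2:
        raise ValueError(f"{path}: expected a two-page (DAPI, green) TIFF")
    return image


def simulate_blocking_counts(
    condition_adhesion: dict[str, float],
    *,
    n_replicates: int = 5,
    cpm_added: float = 50_000.0,
    noise_cv: float = 0.08,
    seed: int = 0,
) -> pd.DataFrame:
    """Radiolabel adhesion-assay counts for antibody-blocking experiments.

    ``condition_adhesion`` maps condition name -> true fraction of added
    bacteria that adhere (e.g. basic ~0.10; antibody conditions lower).
    Per replicate well: cpm_adherent ~ Poisson(cpm_added * fraction * L),
    L lognormal with coefficient of variation ``noise_cv``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(5,)))
    sigma = math.sqrt(math.log(1 + noise_cv**2))
    rows = []
    for cond, frac in condition_adhesion.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"adhesion fraction for {cond!r} outside [0, 1]")
        for rep in range(1, n_replicates + 1):
            lam = cpm_added * frac * rng.lognormal(-0.5 * sigma * sigma, sigma)
            rows.append(
                {
                    "condition": cond,
                    "replicate": rep,
                    "cpm_adherent": float(rng.poisson(lam)),
                    "cpm_added": cpm_added,
                }
            )
    return pd.DataFrame(rows)
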