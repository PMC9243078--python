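"""Two-channel well-image quantification.

Each well image is reduced to the screen's readout in three steps per
channel: background correction (subtraction of a coarse Gaussian-blurred
copy by default), automatic thresholding (Otsu by default), and connected-
component analysis.  DAPI components are the main objects (nuclei); green
components are subobjects (adherent bacteria) filtered by area and
optionally by mean intensity.  The per-well readout is the ratio of
bacteria count to nuclei count, ``bac_nuc_ratio``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops_table
from skimage.morphology import white_tophat
from skimage.segmentation import watershed

from .simulate import read_well_tiff

__all__ = [
    "SegmentationParams",
    "WellImage",
    "WellQuant",
    "correct_background",
    "segment_nuclei",
    "detect_bacteria",
    "quantify_well",
    "combine_fields",
    "quantify_image_dir",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation settings, shared by both channels.

    ``nucleus_area_range`` and ``bacteria_area_range`` are in px^2 and
    bracket the thresholded object footprints (a radius-8 px nucleus
    thresholded mid-amplitude covers roughly 60-150 px).
    ``bacteria_min_intensity`` (mean counts over the object) is 0 by
    default, i.e. no absolute-intensity gate, keeping counts invariant
    under detector gain when Otsu thresholding is used.
    """

    background_method: str = "gaussian_subtract"
    background_scale: float = 50.0
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    nucleus_area_range: tuple[float, float] = (30.0, 3000.0)
    split_touching: bool = False
    bacteria_area_range: tuple[float, float] = (1.0, 80.0)
    bacteria_min_intensity: float = 0.0
    min_nuclei: int = 20
    saturation_fraction: float = 0.01

    def __post_init__(self) -> None:
        for lo, hi in (self.nucleus_area_range, self.bacteria_area_range):
            if lo <= 0 or hi <= lo:
                raise ValueError("area ranges must be positive with min < max")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold method requires fixed_threshold")


@dataclass
class WellImage:
    """One well's two corrected-registered channels plus identity."""

    dapi: np.ndarray
    green: np.ndarray
    well_id: str = "A01"
    plate_id: str = "P001"
    pixel_size: float = 0.65

    def __post_init__(self) -> None:
        if self.dapi.shape != self.green.shape:
            raise ValueError("DAPI and green channels must share a shape")


@dataclass
class WellQuant:
    """Per-well quantification record (the screen's raw readout)."""

    plate_id: str
    well_id: str
    n_nuclei: int
    n_bacteria: int
    total_bacteria_area: float
    mean_bacteria_intensity: float
    bac_nuc_ratio: float  # NaN when n_nuclei == 0
    intensity_sum_ratio: float  # integrated green / integrated DAPI object intensity
    flags: set[str] = field(default_factory=set)
    nuclei: pd.DataFrame | None = None
    bacteria: pd.DataFrame | None = None

    def to_row(self) -> dict:
        return {
            "plate_id": self.plate_id,
            "well": self.well_id,
            "n_nuclei": self.n_nuclei,
            "n_bacteria": self.n_bacteria,
            "total_bacteria_area": self.total_bacteria_area,
            "mean_bacteria_intensity": self.mean_bacteria_intensity,
            "bac_nuc_ratio": self.bac_nuc_ratio,
            "intensity_sum_ratio": self.intensity_sum_ratio,
            "flags": ";".join(sorted(self.flags)),
        }


def correct_background(channel: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Remove smooth background, keeping compact objects.

    gaussian_subtract estimates the background as a Gaussian blur at
    ``background_scale`` px and subtracts it; tophat applies a white
    top-hat with a square footprint of that scale.  Output is float,
    clipped at zero, so a flat field maps to (near-)zero everywhere.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty channel")
    if params.background_scale > min(channel.shape):
        raise ValueError("background_scale exceeds image size")
    if params.background_method == "gaussian_subtract":
        bg = ndi.gaussian_filter(channel, sigma=params.background_scale, mode="nearest")
        return np.clip(channel - bg, 0.0, None)
    if params.background_method == "tophat":
        size = int(params.background_scale)
        return white_tophat(channel, footprint=np.ones((size, size)))
    raise ValueError(f"unknown background_method {params.background_method!r}")


def _threshold(channel: np.ndarray, params: SegmentationParams) -> float:
    if params.threshold_method == "fixed":
        return float(params.fixed_threshold)
    if params.threshold_method == "otsu":
        if not np.any(channel > 0) or np.ptp(channel) == 0:
            return float("inf")  # no contrast: no foreground
        return float(threshold_otsu(channel))
    raise ValueError(f"unknown threshold_method {params.threshold_method!r}")


def _split_touching(mask: np.ndarray, min_area: float) -> np.ndarray:
    """Distance-transform watershed to separate merged blobs."""
    distance = ndi.distance_transform_edt(mask)
    min_sep = max(3, int(np.sqrt(min_area / np.pi)))
    coords = peak_local_max(distance, min_distance=min_sep, labels=mask, exclude_border=False)
    markers = np.zeros(mask.shape, dtype=int)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return sk_label(mask, connectivity=2)
    return watershed(-distance, markers, mask=mask)


def _objects(
    corrected: np.ndarray,
    params: SegmentationParams,
    area_range: tuple[float, float],
    *,
    split: bool = False,
) -> pd.DataFrame:
    thr = _threshold(corrected, params)
    mask = corrected > thr
    if not mask.any():
        return pd.DataFrame(columns=["label", "area", "mean_intensity", "row", "col"])
    labels = _split_touching(mask, area_range[0]) if split else sk_label(mask, connectivity=2)
    props = regionprops_table(
        labels, intensity_image=corrected, properties=("label", "area", "mean_intensity", "centroid")
    )
    df = pd.DataFrame(props).rename(columns={"centroid-0": "row", "centroid-1": "col"})
    lo, hi = area_range
    df = df[(df["area"] >= lo) & (df["area"] <= hi)].reset_index(drop=True)
    return df


def segment_nuclei(dapi_corrected: np.ndarray, params: SegmentationParams) -> pd.DataFrame:
    """Main objects: connected DAPI components above threshold, area-filtered,
    optionally watershed-split when nuclei touch."""
    return _objects(
        dapi_corrected, params, params.nucleus_area_range, split=params.split_touching
    )


def detect_bacteria(green_corrected: np.ndarray, params: SegmentationParams) -> pd.DataFrame:
    """Subobjects: green puncta above threshold, filtered by area and by
    minimum mean intensity."""
    df = _objects(green_corrected, params, params.bacteria_area_range)
    if params.bacteria_min_intensity > 0:
        df = df[df["mean_intensity"] >= params.bacteria_min_intensity].reset_index(drop=True)
    return df


def quantify_well(
    image: WellImage,
    params: SegmentationParams | None = None,
    *,
    keep_objects: bool = False,
) -> WellQuant:
    """Full per-well quantification: correct, segment, detect, ratio."""
    params = params or SegmentationParams()
    if image.dapi.shape != image.green.shape:
        raise ValueError("channel shapes differ")

    max_val = 2**16 - 1
    flags: set[str] = set()
    for ch in (image.dapi, image.green):
        if np.mean(np.asarray(ch) >= max_val) > params.saturation_fraction:
            flags.add("saturated")

    dapi_c = correct_background(image.dapi, params)
    green_c = correct_background(image.green, params)
    nuclei = segment_nuclei(dapi_c, params)
    bacteria = detect_bacteria(green_c, params)

    n_nuc, n_bac = len(nuclei), len(bacteria)
    if n_nuc == 0:
        flags.add("zero_nuclei")
        ratio = float("nan")
    else:
        ratio = n_bac / n_nuc
        if n_nuc < params.min_nuclei:
            flags.add("low_confluence")

    dapi_int = float((nuclei["area"] * nuclei["mean_intensity"]).sum()) if n_nuc else 0.0
    green_int = float((bacteria["area"] * bacteria["mean_intensity"]).sum()) if n_bac else 0.0

    return WellQuant(
        plate_id=image.plate_id,
        well_id=image.well_id,
        n_nuclei=n_nuc,
        n_bacteria=n_bac,
        total_bacteria_area=float(bacteria["area"].sum()) if n_bac else 0.0,
        mean_bacteria_intensity=float(bacteria["mean_intensity"].mean()) if n_bac else 0.0,
        bac_nuc_ratio=ratio,
        intensity_sum_ratio=green_int / dapi_int if dapi_int > 0 else float("nan"),
        flags=flags,
        nuclei=nuclei if keep_objects else None,
        bacteria=bacteria if keep_objects else None,
    )


def combine_fields(quants: list[WellQuant]) -> WellQuant:
    """Sum several fields of view of one well object-wise before the ratio."""
    if not quants:
        raise ValueError("no fields to combine")
    n_nuc = sum(q.n_nuclei for q in quants)
    n_bac = sum(q.n_bacteria for q in quants)
    tot_area = sum(q.total_bacteria_area for q in quants)
    mean_int = (
        sum(q.mean_bacteria_intensity * q.n_bacteria for q in quants) / n_bac if n_bac else 0.0
    )
    flags = set().union(*(q.flags for q in quants))
    flags.discard("zero_nuclei")
    flags.discard("low_confluence")
    if n_nuc == 0:
        flags.add("zero_nuclei")
    return WellQuant(
        plate_id=quants[0].plate_id,
        well_id=quants[0].well_id,
        n_nuclei=n_nuc,
        n_bacteria=n_bac,
        total_bacteria_area=tot_area,
        mean_bacteria_intensity=mean_int,
        bac_nuc_ratio=n_bac / n_nuc if n_nuc else float("nan"),
        intensity_sum_ratio=float("nan"),
        flags=flags,
    )


def quantify_image_dir(
    images_dir: str | Path,
    params: SegmentationParams | None = None,
    *,
    pattern: str = "*.tif",
) -> pd.DataFrame:
    """Quantify every ``<plate>_<well>.tif`` two-page TIFF in a directory."""
    images_dir = Path(images_dir)
    rows = []
    for path in sorted(images_dir.glob(pattern)):
        stem = path.stem
        plate_id, _, coord = stem.rpartition("_")
        stack = read_well_tiff(path)
        img = WellImage(stack[0], stack[1], well_id=coord, plate_id=plate_id or "P001")
        rows.append(quantify_well(img, params).to_row())
    return pd.DataFrame(rows)
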