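"""Sensory-evoked widefield response maps and their geometry.

Trial stacks (trials x frames x H x W) around a stimulus are reduced to a
dF/F response map — post-stimulus frames averaged and referenced to the
1 s pre-stimulus baseline — thresholded at k (default 5) times the
per-pixel baseline standard deviation, and summarized by response area
(mm^2), peak amplitude and intensity-weighted centroid.  Centroid shifts
between sessions quantify map displacement (e.g. of a limb
representation) in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon2mask

__all__ = [
    "ResponseMap",
    "MapComparison",
    "pixel_scale_um",
    "trial_average_map",
    "threshold_map",
    "map_shift",
    "roi_amplitude",
]


def pixel_scale_um(field_um: float, n_pixels: int) -> float:
    """Micrometres per pixel of a square field (e.g. 434 um / 512 px)."""
    if field_um <= 0 or n_pixels <= 0:
        raise ValueError("field size and pixel count must be positive")
    return field_um / n_pixels


@dataclass
class ResponseMap:
    """Thresholded widefield dF/F map with geometric summaries."""

    dff_map: np.ndarray
    baseline_sd_map: np.ndarray
    mask: np.ndarray
    k: float
    pixel_scale_mm: float

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.pixel_scale_mm**2

    @property
    def peak_amplitude(self) -> float:
        """Peak dF/F within the supra-threshold mask (NaN if empty)."""
        return float(self.dff_map[self.mask].max()) if self.mask.any() else np.nan

    @property
    def centroid_mm(self) -> tuple[float, float] | None:
        """Intensity-weighted centroid (x, y) in mm; None when mask empty."""
        if not self.mask.any():
            return None
        rows, cols = np.nonzero(self.mask)
        w = self.dff_map[rows, cols]
        cx = float((cols * w).sum() / w.sum()) * self.pixel_scale_mm
        cy = float((rows * w).sum() / w.sum()) * self.pixel_scale_mm
        return (cx, cy)


@dataclass
class MapComparison:
    shift_mm: float
    roi_peak_amplitude: float | None = None
    roi_mean_amplitude: float | None = None


def trial_average_map(
    stack: np.ndarray,
    stim_onset: int,
    pre_frames: int = 10,
    post_frames: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged dF/F response map and per-pixel baseline sd.

    Trials are averaged first; per pixel the map is
    (mean post-stimulus - mean pre-stimulus) / mean pre-stimulus over
    ``post_frames`` after and ``pre_frames`` before the onset.  The
    baseline sd map is the per-pixel standard deviation of the
    pre-stimulus dF/F frames of the trial average.  Pixels with
    non-positive baseline are returned NaN.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 4:
        raise ValueError("stack must be trials x frames x H x W")
    n_frames = stack.shape[1]
    if stim_onset - pre_frames < 0 or stim_onset + post_frames > n_frames:
        raise ValueError("not enough frames around the stimulus onset")
    avg = stack.mean(axis=0)  # frames x H x W
    pre = avg[stim_onset - pre_frames : stim_onset]
    post = avg[stim_onset : stim_onset + post_frames]
    pre_mean = pre.mean(axis=0)
    invalid = pre_mean <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dff_map = (post.mean(axis=0) - pre_mean) / pre_mean
        baseline_dff = (pre - pre_mean[None]) / pre_mean[None]
    sd_map = baseline_dff.std(axis=0, ddof=1)
    dff_map[invalid] = np.nan
    sd_map[invalid] = np.nan
    return dff_map, sd_map


def threshold_map(
    dff_map: np.ndarray,
    baseline_sd_map: np.ndarray,
    k: float = 5.0,
    pixel_scale_mm: float = 1.0,
) -> ResponseMap:
    """Mask pixels whose response exceeds k x baseline sd."""
    dff_map = np.asarray(dff_map, float)
    baseline_sd_map = np.asarray(baseline_sd_map, float)
    if dff_map.shape != baseline_sd_map.shape:
        raise ValueError("maps must share shape")
    with np.errstate(invalid="ignore"):
        mask = dff_map > k * baseline_sd_map
    return ResponseMap(
        dff_map=dff_map,
        baseline_sd_map=baseline_sd_map,
        mask=mask,
        k=k,
        pixel_scale_mm=pixel_scale_mm,
    )


def map_shift(map_a: ResponseMap, map_b: ResponseMap) -> float:
    """Euclidean distance between the two maps' centroids in mm."""
    ca, cb = map_a.centroid_mm, map_b.centroid_mm
    if ca is None or cb is None:
        raise ValueError("cannot compute shift: a map has an empty mask")
    if map_a.pixel_scale_mm != map_b.pixel_scale_mm:
        raise ValueError("maps must share pixel scale")
    return float(np.hypot(ca[0] - cb[0], ca[1] - cb[1]))


def roi_amplitude(dff_map: np.ndarray, roi_polygon: np.ndarray) -> tuple[float, float]:
    """Peak and mean dF/F inside a polygonal ROI.

    ``roi_polygon`` is an (m, 2) array of (x, y) pixel vertices.
    """
    dff_map = np.asarray(dff_map, float)
    poly = np.asarray(roi_polygon, float)
    if poly.ndim != 2 or poly.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    # polygon2mask expects (row, col) = (y, x)
    mask = polygon2mask(dff_map.shape, poly[:, ::-1])
    if not mask.any():
        raise ValueError("polygon covers no pixels")
    vals = dff_map[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("polygon covers only invalid pixels")
    return float(vals.max()), float(vals.mean())
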