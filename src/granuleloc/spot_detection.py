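"""Single-molecule spot detection in 3D smFISH stacks.

The detection chain mirrors the standard FISH-quant procedure: a 3D
Laplacian-of-Gaussian band-pass (kernel size 5 voxels, s.d. 1 voxel by
default), strict local-maximum pre-detection inside the embryo outline,
3D Gaussian sub-region fitting (±2 px in x/y, ±3 px in z by default) and a
manual, image-set-dependent intensity and quality threshold.

The LoG kernel is defined in *voxel* units: the conventional detection
parameters are stated in pixels and anisotropy is deliberately not
compensated during filtering.  The Gaussian fit, in contrast, estimates
σ_z and σ_xy separately, in µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .image_model import EmbryoAnnotation, ImageStack, Spot

__all__ = [
    "DetectionConfig",
    "log_kernel",
    "log_filter",
    "predetect",
    "fit_spots",
    "apply_thresholds",
    "detect_spots",
]


@dataclass
class DetectionConfig:
    """Detection parameters.

    ``log_size``/``log_sd`` are in voxels (odd size >= 3).  Sub-regions are
    half-widths in voxels.  Thresholds are applied to the fitted amplitude
    (image intensity units) and to the unitless fit-quality score in [0, 1].
    """

    log_size: int = 5
    log_sd: float = 1.0
    intensity_threshold: float = 0.0
    quality_threshold: float = 0.0
    subregion_xy: int = 2
    subregion_z: int = 3
    #: optional LoG-response floor for pre-detection (0 keeps every
    #: positive-response maximum) and a cap on candidates passed to the
    #: fitter, strongest first.  Both purely practical: weak noise maxima
    #: are fitted and rejected anyway, at real cost.
    response_floor: float = 0.0
    max_candidates: int | None = None

    def __post_init__(self) -> None:
        if self.log_size < 3 or self.log_size % 2 == 0:
            raise ValueError("log_size must be odd and >= 3")
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")
        if self.intensity_threshold < 0 or self.quality_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.subregion_xy < 1 or self.subregion_z < 1:
            raise ValueError("sub-regions must be >= 1 voxel")


def log_kernel(size: int = 5, sd: float = 1.0) -> np.ndarray:
    """Analytic 3D LoG kernel, sign-flipped so blob maxima respond positive.

    The kernel samples -∇²G at voxel centers on a ``size³`` grid and is
    shifted to zero sum so that a constant image gives zero response.
    """
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = z**2 + y**2 + x**2
    g = np.exp(-r2 / (2 * sd**2))
    log = (r2 / sd**4 - 3.0 / sd**2) * g  # ∇²G up to a positive constant
    kernel = -log  # maxima positive at blobs
    kernel -= kernel.mean()
    return kernel


def log_filter(image: ImageStack, config: DetectionConfig | None = None) -> ImageStack:
    """Band-pass the stack with the analytic LoG kernel (reflected borders)."""
    config = config or DetectionConfig()
    if any(s < config.log_size for s in image.shape):
        raise ValueError(f"image shape {image.shape} smaller than LoG kernel size {config.log_size}")
    kernel = log_kernel(config.log_size, config.log_sd)
    response = ndimage.convolve(image.voxels, kernel, mode="reflect")
    return ImageStack(response, image.spacing, channel_label=image.channel_label)


def predetect(
    filtered: ImageStack,
    annotation: EmbryoAnnotation | None = None,
    config: DetectionConfig | None = None,
) -> np.ndarray:
    """Strict 26-neighborhood local maxima of the LoG response.

    Returns an (N, 3) integer voxel-index array ranked by descending
    response.  Only voxels with positive response count, and — when an
    annotation is supplied — only voxels inside the embryo outline.
    Plateaus of equal-valued adjacent maxima keep the lexicographically
    smallest voxel index.
    """
    resp = filtered.voxels
    floor = max(0.0, config.response_floor) if config is not None else 0.0
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = (resp == ndimage.maximum_filter(resp, footprint=footprint, mode="reflect")) & (resp > floor)
    if not local_max.any():
        return np.empty((0, 3), dtype=int)
    # resolve plateaus: keep one voxel (lexicographically smallest) per
    # connected component of equal-valued maxima
    labels, n = ndimage.label(local_max, structure=footprint)
    if n < local_max.sum():
        keep = np.zeros_like(local_max)
        idx = np.argwhere(local_max)
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
        seen: set[int] = set()
        for i in order:
            lab = labels[tuple(idx[i])]
            if lab not in seen:
                seen.add(lab)
                keep[tuple(idx[i])] = True
        local_max = keep
    candidates = np.argwhere(local_max)
    if annotation is not None:
        pos_um = candidates * np.asarray(filtered.spacing)
        candidates = candidates[annotation.contains(pos_um)]
    if len(candidates) == 0:
        return np.empty((0, 3), dtype=int)
    values = resp[tuple(candidates.T)]
    ranked = candidates[np.argsort(-values, kind="stable")]
    if config is not None and config.max_candidates is not None:
        ranked = ranked[: config.max_candidates]
    return ranked


def _gauss3d(params: np.ndarray, zz: np.ndarray, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    amp, cz, cy, cx, sz, sxy, off = params
    return off + amp * np.exp(
        -((zz - cz) ** 2) / (2 * sz**2) - ((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sxy**2)
    )


def fit_spots(
    image: ImageStack,
    candidates: np.ndarray,
    config: DetectionConfig | None = None,
) -> list[Spot]:
    """Fit a 3D Gaussian to each candidate over its sub-region window.

    Each candidate voxel gets an anisotropic Gaussian fit (amplitude,
    center, σ_z, σ_xy, constant offset) over the ±``subregion_z``/
    ±``subregion_xy`` window.  Centers are reported in µm.  Fits that do
    not converge, end with non-positive amplitude or σ, or whose center
    drifts out of the window are dropped.  Windows clipped by the image
    border are fitted on the clipped window and flagged ``border``.

    Quality is 1 − RSS/TSS of the fit (clipped to [0, 1]); integrated
    intensity is the closed-form Gaussian integral divided by the voxel
    volume, i.e. total counts attributable to the spot.
    """
    config = config or DetectionConfig()
    dz, dy, dx = image.spacing
    nzv, nyv, nxv = image.shape
    half = np.array([config.subregion_z, config.subregion_xy, config.subregion_xy])
    spots: list[Spot] = []
    taken_voxels: set[tuple[int, int, int]] = set()
    for cand in np.atleast_2d(np.asarray(candidates, dtype=int)):
        lo = cand - half
        hi = cand + half + 1
        border = bool((lo < 0).any() or (hi > np.array(image.shape)).any())
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, np.array(image.shape))
        window = image.voxels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        zz, yy, xx = np.meshgrid(
            (np.arange(lo[0], hi[0])) * dz,
            (np.arange(lo[1], hi[1])) * dy,
            (np.arange(lo[2], hi[2])) * dx,
            indexing="ij",
        )
        off0 = float(window.min())
        amp0 = float(window.max() - off0)
        if amp0 <= 0:
            continue
        p0 = np.array([amp0, cand[0] * dz, cand[1] * dy, cand[2] * dx, max(dz, 0.3), max(dx, 0.1), off0])
        lo_um = lo * np.array([dz, dy, dx])
        hi_um = (hi - 1) * np.array([dz, dy, dx])
        bounds = (
            [0.0, lo_um[0], lo_um[1], lo_um[2], 0.05 * dz, 0.05 * dx, -np.inf],
            [np.inf, hi_um[0], hi_um[1], hi_um[2], 10 * config.subregion_z * dz, 10 * config.subregion_xy * dx, np.inf],
        )
        data = window.ravel()
        try:
            fit = least_squares(
                lambda p: _gauss3d(p, zz, yy, xx).ravel() - data,
                p0,
                bounds=bounds,
                method="trf",
                max_nfev=200,
            )
        except Exception:
            continue
        amp, cz, cy, cx, sz, sxy, off = fit.x
        if not fit.success or amp <= 0 or sz <= 0 or sxy <= 0:
            continue
        # two candidates converging onto the same molecule yield duplicate
        # fits; keep only the first (candidates arrive strongest-first)
        vox_key = (int(round(cz / dz)), int(round(cy / dy)), int(round(cx / dx)))
        if vox_key in taken_voxels:
            continue
        taken_voxels.add(vox_key)
        rss = float(np.sum(fit.fun**2))
        tss = float(np.sum((data - data.mean()) ** 2))
        quality = float(np.clip(1.0 - rss / tss, 0.0, 1.0)) if tss > 0 else 0.0
        integrated = amp * (2 * np.pi) ** 1.5 * sxy**2 * sz / image.voxel_volume
        spots.append(
            Spot(
                position=(float(cz), float(cy), float(cx)),
                amplitude=float(amp),
                sigma_z=float(sz),
                sigma_xy=float(sxy),
                offset=float(off),
                quality=quality,
                integrated_intensity=float(integrated),
                border=border,
            )
        )
    return spots


def apply_thresholds(spots: list[Spot], config: DetectionConfig) -> list[Spot]:
    """Keep spots with amplitude and quality at or above the thresholds.

    The retained set shrinks monotonically as either threshold grows; the
    thresholds themselves are an image-set-level choice (set manually per
    image in the original procedure).
    """
    return [
        s
        for s in spots
        if s.amplitude >= config.intensity_threshold and s.quality >= config.quality_threshold
    ]


def detect_spots(
    image: ImageStack,
    annotation: EmbryoAnnotation | None = None,
    config: DetectionConfig | None = None,
) -> list[Spot]:
    """Full detection chain: LoG filter → pre-detect → fit → threshold."""
    config = config or DetectionConfig()
    filtered = log_filter(image, config)
    candidates = predetect(filtered, annotation, config)
    spots = fit_spots(image, candidates, config)
    return apply_thresholds(spots, config)


def suggest_intensity_threshold(spots: list[Spot]) -> float:
    """Elbow-point suggestion for the intensity threshold.

    Sorts fitted amplitudes descending and returns the amplitude at the
    point of maximum distance from the straight line joining the curve's
    endpoints.  The suggestion is advisory only — it is logged by the CLI
    but never applied silently.
    """
    if len(spots) < 3:
        return 0.0
    amps = np.sort([s.amplitude for s in spots])[::-1]
    n = len(amps)
    t = np.linspace(0, 1, n)
    line = amps[0] + (amps[-1] - amps[0]) * t
    return float(amps[int(np.argmax(np.abs(amps - line)))])
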