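"""Rendering helpers shared across test modules."""

from __future__ import annotations

import numpy as np

import granuleloc as g
from granuleloc.synthetic import _render_gaussians

SPACING = (0.2, 0.1, 0.1)
PSF_Z = 0.35
PSF_XY = 0.13
AMPLITUDE = 100.0


def render_spots(
    positions: np.ndarray,
    shape: tuple[int, int, int],
    amplitudes: np.ndarray | float = AMPLITUDE,
    spacing: tuple[float, float, float] = SPACING,
    background: float = 0.0,
    sigma_z: float = PSF_Z,
    sigma_xy: float = PSF_XY,
) -> g.ImageStack:
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    amps = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(positions),))
    vox = _render_gaussians(shape, spacing, positions, amps, sigma_z, sigma_xy) + background
    return g.ImageStack(vox, spacing)


def reference_spot(voxel_volume: float = float(np.prod(SPACING))) -> g.ReferenceSpot:
    """Closed-form reference signature for the standard rendered PSF."""
    integ = AMPLITUDE * (2 * np.pi) ** 1.5 * PSF_XY**2 * PSF_Z / voxel_volume
    return g.ReferenceSpot(
        amplitude=AMPLITUDE, sigma_z=PSF_Z, sigma_xy=PSF_XY, integrated_intensity=integ
    )
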