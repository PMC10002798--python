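"""Deterministic classical segmenter.

A morphology/threshold pipeline that maps the two initial-estimate
reconstructions (scatter-window and photopeak NAC) to the six tissue
classes without any training: body support by thresholding and closing,
the patient table split off by a posterior half-space prior, lungs as
low-intensity interior regions, bone as high-intensity core structure, and
the skin/adipose rind as the body's outer shell.  It exercises the full
segmentation-to-attenuation-map pipeline and serves as the default
segmentation backend when no trained network is supplied.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import (
    binary_closing,
    binary_erosion,
    binary_fill_holes,
    binary_opening,
    label as cc_label,
)

from ..phantom import ADIPOSE, BACKGROUND, BONE, LUNGS, SOFT_TISSUE, TABLE

__all__ = ["classical_fallback_segment"]


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = cc_label(mask)
    if n == 0:
        raise ValueError("empty body mask")
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (1 + int(np.argmax(sizes)))


def classical_fallback_segment(
    scatter_recon: np.ndarray,
    photopeak_recon: np.ndarray,
    strong_frac: float = 0.45,
    weak_frac: float = 0.25,
    lung_frac: float = 0.55,
    bone_frac: float = 1.25,
    rind_vox: int = 2,
) -> np.ndarray:
    """Six-class label volume from the two initial estimates.

    The scatter-window reconstruction carries the attenuation contrast and
    drives every decision; thresholds are fractions of its interior median,
    so the pipeline is insensitive to global intensity normalization.  The
    photopeak channel is accepted for interface symmetry with the trained
    segmenter (its activity contrast adds nothing for tissue boundaries that
    the scatter channel does not already show on these phantoms).
    """
    s = np.asarray(scatter_recon, dtype=np.float64)
    p = np.asarray(photopeak_recon, dtype=np.float64)
    if s.shape != p.shape:
        raise ValueError("reconstructions must share a grid")
    if s.max() <= 0:
        raise ValueError("empty scatter reconstruction")

    rough = float(np.median(s[s > 0.3 * s[s > 0].mean()]))
    strong = binary_closing(s > strong_frac * rough, np.ones((3, 3, 1)))
    body = _largest_component(strong)
    solid = np.stack(
        [binary_fill_holes(body[:, :, z]) for z in range(body.shape[2])], axis=2
    )

    # posterior half-space prior: anything in the weak mask behind the
    # body's per-(x, z) posterior edge belongs to the patient table
    weak = s > weak_frac * rough
    ny = s.shape[1]
    ycoord = np.arange(ny)[None, :, None]
    back_edge = np.where(solid, ycoord, -1).max(axis=1)  # (x, z)
    table = weak & ~solid & (ycoord > back_edge[:, None, :] + 1)
    table &= back_edge[:, None, :] >= 0

    core = binary_erosion(
        solid, np.ones((2 * rind_vox + 1, 2 * rind_vox + 1, 1))
    )
    interior = float(np.median(s[core])) if core.any() else rough
    lungs = solid & (s < lung_frac * interior)
    lungs = binary_opening(lungs, np.ones((2, 2, 2)))
    bone = core & (s > bone_frac * interior) & ~lungs
    rind = solid & ~core

    labels = np.zeros(s.shape, dtype=np.uint8)
    labels[solid] = SOFT_TISSUE
    labels[rind] = ADIPOSE
    labels[lungs] = LUNGS
    labels[bone] = BONE
    labels[table] = TABLE
    return labels
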