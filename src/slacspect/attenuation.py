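"""Attenuation-map machinery.

Bilinear HU <-> mu conversion at 140 keV, Markov-random-field (Potts/ICM)
six-class segmentation of attenuation maps, per-class mean coefficient
estimation ("predefined attenuation coefficients"), and piecewise-constant
mu assignment from a segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .forward_model import MU_WATER_140KEV
from .phantom import BACKGROUND, CLASS_NAMES, TABLE

__all__ = [
    "BilinearModel",
    "TissueModel",
    "bilinear_hu_to_mu",
    "mu_to_hu",
    "mrf_segment",
    "fit_tissue_model",
    "assign_mu",
    "match_labels",
]


@dataclass(frozen=True)
class BilinearModel:
    """Piecewise-linear HU -> mu conversion with its breakpoint at 0 HU.

    The soft branch runs from (-1000 HU, 0) to (0 HU, mu_water); the bone
    branch continues with ``bone_slope`` per HU, chosen by default so that
    1000 HU maps to 0.25 cm^-1.
    """

    mu_water: float = MU_WATER_140KEV
    bone_slope: float = (0.25 - MU_WATER_140KEV) / 1000.0

    @property
    def soft_slope(self) -> float:
        return self.mu_water / 1000.0


def bilinear_hu_to_mu(hu: np.ndarray, model: BilinearModel | None = None) -> np.ndarray:
    """Voxelwise bilinear HU -> mu (cm^-1), clipped below at zero."""
    model = model or BilinearModel()
    hu = np.asarray(hu, dtype=np.float64)
    mu = np.where(
        hu <= 0.0,
        model.mu_water + model.soft_slope * hu,
        model.mu_water + model.bone_slope * hu,
    )
    return np.clip(mu, 0.0, None)


def mu_to_hu(mu: np.ndarray, model: BilinearModel | None = None) -> np.ndarray:
    """Inverse of :func:`bilinear_hu_to_mu` (mu below the air point maps to
    -1000 HU)."""
    model = model or BilinearModel()
    mu = np.asarray(mu, dtype=np.float64)
    hu = np.where(
        mu <= model.mu_water,
        (mu - model.mu_water) / model.soft_slope,
        (mu - model.mu_water) / model.bone_slope,
    )
    return np.clip(hu, -1000.0, None)


@dataclass
class TissueModel:
    """Class label -> attenuation coefficient table (cm^-1)."""

    class_mu: dict[int, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        for c, m in self.class_mu.items():
            if not (0.0 <= m <= 0.5):
                raise ValueError(f"coefficient for class {c} outside [0, 0.5]")


def _icm_energy(labels, intensities, means, inv_var, beta):
    data = inv_var * (intensities - means[labels]) ** 2
    pair = 0.0
    for ax in range(3):
        a = np.take(labels, range(0, labels.shape[ax] - 1), axis=ax)
        b = np.take(labels, range(1, labels.shape[ax]), axis=ax)
        pair += np.count_nonzero(a != b)
    return float(data.sum()) + beta * pair


def mrf_segment(
    mu_map: np.ndarray,
    n_classes: int = 6,
    beta: float = 0.5,
    n_icm_iters: int = 10,
    seed: int = 0,
    return_energy: bool = False,
):
    """Six-class Potts-model segmentation of an attenuation map.

    K-means (on intensities) initializes the labels; ICM then minimizes
    ``sum((I - mu_c)^2 / (2 sigma^2)) + beta * #{disagreeing 6-neighbors}``
    with checkerboard updates (energy non-increasing per sweep).  ``sigma``
    is the pooled within-cluster standard deviation, so ``beta`` is
    dimensionless.  Classes are reported in ascending order of their mean
    intensity (background = lowest); the patient-table class is then
    disambiguated from bone by a spatial prior: table voxels lie in the
    posterior (+y) half-space behind the body.
    """
    vals = np.asarray(mu_map, dtype=np.float64)
    if not np.all(np.isfinite(vals)):
        raise ValueError("mu map must be finite")
    flat = vals.reshape(-1, 1)
    if np.unique(np.round(flat, 8)).size < n_classes:
        raise ValueError("fewer distinct intensities than classes")
    km = KMeans(n_clusters=n_classes, n_init=4, random_state=seed).fit(flat)
    order = np.argsort(km.cluster_centers_.ravel())
    rank = np.empty(n_classes, dtype=np.int64)
    rank[order] = np.arange(n_classes)
    # ascending-intensity ranks -> tissue labels; for the six-class problem
    # the two highest ranks are table (~0.20) then bone (~0.25)
    if n_classes == 6:
        rank_to_label = np.array([0, 1, 2, 3, TABLE, 4])
    else:
        rank_to_label = np.arange(n_classes)
    label_of = rank_to_label[rank]
    labels = label_of[km.labels_].reshape(vals.shape)
    means = np.empty(n_classes)
    means[label_of] = km.cluster_centers_.ravel()

    resid = vals - means[labels]
    sigma2 = max(float(np.mean(resid**2)), 1e-12)
    inv_var = 1.0 / (2.0 * sigma2)

    # data costs per class, computed once
    costs = inv_var * (vals[..., None] - means[None, None, None, :]) ** 2

    ii, jj, kk = np.indices(vals.shape)
    parity = (ii + jj + kk) % 2
    energies = [_icm_energy(labels, vals, means, inv_var, beta)]
    for _ in range(n_icm_iters):
        for color in (0, 1):
            disagree = np.zeros_like(costs)
            padded = np.pad(labels, 1, mode="edge")
            for ax in range(3):
                for off in (0, 2):
                    sl = [slice(1, -1)] * 3
                    sl[ax] = slice(off, off + vals.shape[ax])
                    nb = padded[tuple(sl)]
                    disagree += (nb[..., None] != np.arange(len(means))).astype(
                        costs.dtype
                    )
            total = costs + beta * disagree
            new = np.argmin(total, axis=-1)
            mask = parity == color
            labels[mask] = new[mask]
        energies.append(_icm_energy(labels, vals, means, inv_var, beta))
        if energies[-1] >= energies[-2] - 1e-9:
            break

    if n_classes == 6:
        labels = _resolve_table_class(labels, vals)
    labels = labels.astype(np.uint8)
    if return_energy:
        return labels, np.asarray(energies)
    return labels


def _resolve_table_class(labels: np.ndarray, vals: np.ndarray) -> np.ndarray:
    """Spatial prior resolving table vs bone.

    Intensity alone can confuse the table (~0.20 cm^-1) with bone (~0.25);
    the table lies in the posterior (+y) half-space, separated from the body
    by an air gap.  Voxels labeled table anterior of that gap become bone and
    bone-labeled voxels posterior of it become table.
    """
    out = labels.copy()
    fg_rows = (labels > 0).any(axis=(0, 2))
    ys = np.nonzero(fg_rows)[0]
    if ys.size == 0:
        return out
    interior = np.arange(ys[0], ys[-1] + 1)
    gaps = interior[~fg_rows[interior]]
    if gaps.size:
        slab = np.zeros_like(out, dtype=bool)
        slab[:, gaps[-1] + 1:, :] = True
        out[slab & (out == 4)] = TABLE
        out[~slab & (out == TABLE)] = 4
    return out


def fit_tissue_model(
    mu_maps,
    label_maps,
    provenance: str = "",
) -> TissueModel:
    """Pool all training voxels per class and average their attenuation."""
    mu_maps = list(mu_maps)
    label_maps = list(label_maps)
    if len(mu_maps) == 0 or len(mu_maps) != len(label_maps):
        raise ValueError("need >= 1 paired (mu map, label map)")
    sums = {c: 0.0 for c in CLASS_NAMES}
    counts = {c: 0 for c in CLASS_NAMES}
    for mu, lab in zip(mu_maps, label_maps):
        for c in CLASS_NAMES:
            m = lab == c
            counts[c] += int(m.sum())
            sums[c] += float(mu[m].sum())
    class_mu = {}
    for c in CLASS_NAMES:
        if counts[c] == 0:
            raise ValueError(f"no training voxels for class {c} ({CLASS_NAMES[c]})")
        class_mu[c] = sums[c] / counts[c]
    return TissueModel(class_mu=class_mu, provenance=provenance)


def assign_mu(labels: np.ndarray, model: TissueModel) -> np.ndarray:
    """Piecewise-constant attenuation map from a segmentation."""
    labels = np.asarray(labels)
    known = np.array(sorted(model.class_mu))
    present = np.unique(labels)
    unknown = set(present.tolist()) - set(known.tolist())
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in the tissue model")
    lut = np.zeros(int(known.max()) + 1, dtype=np.float32)
    for c, m in model.class_mu.items():
        lut[c] = m
    return lut[labels]


def match_labels(pred: np.ndarray, truth: np.ndarray, n_classes: int = 6) -> np.ndarray:
    """Relabel ``pred`` by the one-to-one assignment maximizing agreement
    with ``truth`` (Hungarian algorithm on the confusion matrix)."""
    conf = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(conf, (pred.ravel(), truth.ravel()), 1)
    rows, cols = linear_sum_assignment(-conf)
    mapping = np.arange(n_classes)
    mapping[rows] = cols
    return mapping[pred]
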