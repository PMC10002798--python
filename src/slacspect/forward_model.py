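"""Parallel-beam SPECT forward model.

Simulates photopeak- and scatter-window projections of an activity/attenuation
volume pair: rotation-based attenuated projection with a depth-dependent
Gaussian collimator-detector response (CDR), a phenomenological scatter-window
channel, and Poisson count noise.  The back projector is the exact adjoint of
the forward projector by construction (sparse rotation operators are
transposed, the symmetric per-plane blur is self-adjoint, and the attenuation
factors are diagonal), which is what OSEM requires.

Conventions
-----------
Volumes are indexed ``(x, y, z)`` with ``z`` the scanner axis; the in-plane
grid must be square and match the detector ``u`` bins, ``z`` matches the
axial ``v`` bins.  For each view the volume is rotated in-plane so rays run
along ``+y`` toward the detector; projections have shape
``(n_angles, n_u, n_v)``.  Ray sums are scaled by the bin size (cm) so that a
uniform slab of attenuation ``mu`` and thickness ``L`` attenuates a point
source by ``exp(-mu * L)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter

__all__ = [
    "AcquisitionGeometry",
    "ProjectionSet",
    "Projector",
    "forward_project",
    "back_project",
    "simulate_scatter",
    "add_poisson",
    "PHOTOPEAK_WINDOW_KEV",
    "SCATTER_WINDOW_KEV",
    "MU_WATER_140KEV",
]

#: Energy windows (keV) used for primary and Compton-scatter acquisition.
PHOTOPEAK_WINDOW_KEV = (126.0, 154.0)
SCATTER_WINDOW_KEV = (114.0, 126.0)

#: Linear attenuation coefficient of water at 140 keV (cm^-1).
MU_WATER_140KEV = 0.1537


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Parallel-beam acquisition description.

    Parameters
    ----------
    n_angles:
        Number of views, spread uniformly over ``angular_range_deg``.
    angular_range_deg:
        Total angular coverage in degrees (180 for a standard MPS arc).
    n_bins:
        Detector bins ``(u, v)``; ``u`` is transverse, ``v`` axial.
    bin_size_cm:
        Detector bin pitch, equal to the reconstruction voxel size.
    cdr_sigma_cm, cdr_slope:
        Depth-dependent CDR blur ``sigma(d) = cdr_sigma_cm + cdr_slope * d``
        with ``d`` the source-to-collimator distance in cm.
    orbit_radius_cm:
        Distance from the rotation axis to the collimator face.

    The default ``start_angle_deg`` of 90 puts the arc on the anterior side
    of a supine patient (the standard RAO-to-LPO cardiac orbit, chosen
    clinically to keep the detector away from the most attenuating posterior
    paths).
    """

    n_angles: int = 60
    angular_range_deg: float = 180.0
    start_angle_deg: float = 90.0
    n_bins: tuple[int, int] = (64, 64)
    bin_size_cm: float = 0.68
    cdr_sigma_cm: float = 0.17
    cdr_slope: float = 0.018
    orbit_radius_cm: float = 25.0

    def __post_init__(self) -> None:
        if self.n_angles < 4:
            raise ValueError("n_angles must be >= 4")
        if self.bin_size_cm <= 0:
            raise ValueError("bin_size_cm must be > 0")
        if self.cdr_slope < 0:
            raise ValueError("CDR slope must be >= 0")
        object.__setattr__(self, "n_bins", tuple(int(b) for b in self.n_bins))

    @property
    def angles_deg(self) -> np.ndarray:
        return (
            self.start_angle_deg
            + self.angular_range_deg * np.arange(self.n_angles) / self.n_angles
        )

    def without_cdr(self) -> "AcquisitionGeometry":
        return replace(self, cdr_sigma_cm=0.0, cdr_slope=0.0)


@dataclass
class ProjectionSet:
    """Paired photopeak- and scatter-window projection data."""

    geometry: AcquisitionGeometry
    photopeak: np.ndarray
    scatter: np.ndarray | None = None
    window_bounds_kev: tuple[tuple[float, float], tuple[float, float]] = (
        PHOTOPEAK_WINDOW_KEV,
        SCATTER_WINDOW_KEV,
    )
    is_noisy: bool = False

    def __post_init__(self) -> None:
        expected = (self.geometry.n_angles, *self.geometry.n_bins)
        for name, arr in (("photopeak", self.photopeak), ("scatter", self.scatter)):
            if arr is None:
                continue
            if arr.shape != expected:
                raise ValueError(
                    f"{name} projections have shape {arr.shape}, expected {expected}"
                )
            if np.any(arr < 0):
                raise ValueError(f"{name} projections must be nonnegative")


def _rotation_operator(n: int, angle_deg: float, dtype) -> sparse.csr_matrix:
    """Sparse bilinear-interpolation rotation of an ``n x n`` in-plane grid.

    Maps a flattened plane to the plane rotated by ``angle_deg`` about the
    grid center; samples falling outside the grid contribute zero.
    """
    c = (n - 1) / 2.0
    th = np.deg2rad(angle_deg)
    cos, sin = np.cos(th), np.sin(th)
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    # source coordinates in the unrotated volume for each rotated-grid point
    x = c + cos * (ii - c) - sin * (jj - c)
    y = c + sin * (ii - c) + cos * (jj - c)
    x0 = np.floor(x).astype(np.int64)
    y0 = np.floor(y).astype(np.int64)
    fx = x - x0
    fy = y - y0
    rows, cols, vals = [], [], []
    out_idx = (ii * n + jj).ravel()
    for dx, wx in ((0, 1.0 - fx), (1, fx)):
        for dy, wy in ((0, 1.0 - fy), (1, fy)):
            xs = x0 + dx
            ys = y0 + dy
            w = (wx * wy).ravel()
            inside = ((xs >= 0) & (xs < n) & (ys >= 0) & (ys < n)).ravel() & (w > 0)
            rows.append(out_idx[inside])
            cols.append((xs * n + ys).ravel()[inside])
            vals.append(w[inside])
    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n),
    )
    return mat.tocsr().astype(dtype)


class Projector:
    """Matched forward/back projector for a fixed geometry and grid.

    Precomputes per-view rotation operators and the depth-grouped CDR blur
    plan; ``attenuation_plan`` caches the per-view attenuation factors for a
    given mu map so OSEM iterations do not recompute them.
    """

    def __init__(
        self,
        geometry: AcquisitionGeometry,
        dtype=np.float32,
    ) -> None:
        nu, nv = geometry.n_bins
        self.geometry = geometry
        self.dtype = np.dtype(dtype)
        self.n = nu
        self.nz = nv
        angles = geometry.angles_deg
        # rotate the volume by -angle so the ray direction is +y for a view
        # acquired at +angle
        self._rot = [_rotation_operator(nu, -a, self.dtype) for a in angles]
        self._rot_t = [r.T.tocsr() for r in self._rot]
        self._blur_groups = self._build_blur_groups()

    # -- CDR blur plan -----------------------------------------------------
    def _build_blur_groups(self) -> list[tuple[float, np.ndarray]]:
        g = self.geometry
        c = (self.n - 1) / 2.0
        y_world = (np.arange(self.n) - c) * g.bin_size_cm
        depth = np.maximum(g.orbit_radius_cm - y_world, 0.0)
        sigma_cm = g.cdr_sigma_cm + g.cdr_slope * depth
        sigma_vox = sigma_cm / g.bin_size_cm
        # quantize so planes with near-identical blur are summed then blurred
        # once; blur is linear so grouping before blurring is exact
        q = np.round(sigma_vox / 0.25) * 0.25
        groups = []
        for s in np.unique(q):
            groups.append((float(s), np.nonzero(q == s)[0]))
        return groups

    def _blur(self, plane: np.ndarray, sigma: float) -> np.ndarray:
        if sigma < 1e-3:
            return plane
        # constant-mode Gaussian correlation with a symmetric kernel is
        # exactly self-adjoint, preserving the adjoint identity
        return gaussian_filter(plane, sigma=sigma, mode="constant")

    # -- attenuation -------------------------------------------------------
    def attenuation_plan(self, mu: np.ndarray | None) -> list[np.ndarray] | None:
        """Per-view survival factors exp(-integral of mu to the detector)."""
        if mu is None:
            return None
        self._check_volume(mu, "mu")
        if np.any(mu < 0):
            raise ValueError("mu must be nonnegative")
        d = self.geometry.bin_size_cm
        mu2d = np.asarray(mu, dtype=self.dtype).reshape(self.n * self.n, self.nz)
        plan = []
        for rot in self._rot:
            mu_rot = (rot @ mu2d).reshape(self.n, self.n, self.nz)
            # suffix sum of mu beyond each voxel toward the detector (+y),
            # plus half the voxel's own mu
            suffix = np.flip(np.cumsum(np.flip(mu_rot, axis=1), axis=1), axis=1)
            path = suffix - 0.5 * mu_rot
            plan.append(np.exp(-d * path).astype(self.dtype))
        return plan

    def _check_volume(self, vol: np.ndarray, name: str) -> None:
        if vol.shape != (self.n, self.n, self.nz):
            raise ValueError(
                f"{name} has shape {vol.shape}, expected {(self.n, self.n, self.nz)}"
            )

    # -- projection --------------------------------------------------------
    def forward_view(self, activity2d: np.ndarray, att, view: int) -> np.ndarray:
        vol = (self._rot[view] @ activity2d).reshape(self.n, self.n, self.nz)
        if att is not None:
            vol = vol * att[view]
        proj = np.zeros((self.n, self.nz), dtype=self.dtype)
        for sigma, planes in self._blur_groups:
            proj += self._blur(vol[:, planes, :].sum(axis=1), sigma)
        return proj * self.dtype.type(self.geometry.bin_size_cm)

    def back_view(self, proj: np.ndarray, att, view: int) -> np.ndarray:
        vol = np.zeros((self.n, self.n, self.nz), dtype=self.dtype)
        p = np.asarray(proj, dtype=self.dtype) * self.dtype.type(
            self.geometry.bin_size_cm
        )
        for sigma, planes in self._blur_groups:
            vol[:, planes, :] = self._blur(p, sigma)[:, None, :]
        if att is not None:
            vol = vol * att[view]
        out = self._rot_t[view] @ vol.reshape(self.n * self.n, self.nz)
        return out.reshape(self.n, self.n, self.nz)

    def forward(
        self,
        activity: np.ndarray,
        mu: np.ndarray | None = None,
        att_plan=None,
        views=None,
    ) -> np.ndarray:
        self._check_volume(activity, "activity")
        if att_plan is None:
            att_plan = self.attenuation_plan(mu)
        act2d = np.asarray(activity, dtype=self.dtype).reshape(
            self.n * self.n, self.nz
        )
        views = list(range(self.geometry.n_angles)) if views is None else list(views)
        out = np.empty((len(views), self.n, self.nz), dtype=self.dtype)
        for k, v in enumerate(views):
            out[k] = self.forward_view(act2d, att_plan, v)
        return out

    def back(
        self,
        projections: np.ndarray,
        mu: np.ndarray | None = None,
        att_plan=None,
        views=None,
    ) -> np.ndarray:
        views = list(range(self.geometry.n_angles)) if views is None else list(views)
        if projections.shape != (len(views), self.n, self.nz):
            raise ValueError(
                f"projections have shape {projections.shape}, expected "
                f"{(len(views), self.n, self.nz)}"
            )
        if att_plan is None:
            att_plan = self.attenuation_plan(mu)
        out = np.zeros((self.n, self.n, self.nz), dtype=self.dtype)
        for k, v in enumerate(views):
            out += self.back_view(projections[k], att_plan, v)
        return out


@lru_cache(maxsize=8)
def _cached_projector(geometry: AcquisitionGeometry, dtype_str: str) -> Projector:
    return Projector(geometry, dtype=np.dtype(dtype_str))


def get_projector(geometry: AcquisitionGeometry, dtype=np.float32) -> Projector:
    """Shared, cached :class:`Projector` for a geometry."""
    return _cached_projector(geometry, np.dtype(dtype).str)


def forward_project(
    activity: np.ndarray,
    mu: np.ndarray | None = None,
    geometry: AcquisitionGeometry | None = None,
    dtype=np.float32,
) -> np.ndarray:
    """Attenuated, CDR-blurred parallel-beam projections of ``activity``."""
    geometry = geometry or AcquisitionGeometry()
    if mu is not None and mu.shape != activity.shape:
        raise ValueError("activity and mu must share a grid")
    return get_projector(geometry, dtype).forward(activity, mu)


def back_project(
    projections: np.ndarray,
    mu: np.ndarray | None = None,
    geometry: AcquisitionGeometry | None = None,
    dtype=np.float32,
) -> np.ndarray:
    """Exact adjoint of :func:`forward_project` (fixed mu)."""
    geometry = geometry or AcquisitionGeometry()
    return get_projector(geometry, dtype).back(projections, mu)


@lru_cache(maxsize=4)
def _fluence_kernel(shape: tuple, voxel_cm: float) -> np.ndarray:
    """Inverse-square photon-fluence kernel, capped inside one voxel."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * voxel_cm for n in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    r2 = xx**2 + yy**2 + zz**2
    return 1.0 / np.maximum(r2, voxel_cm**2)


def simulate_scatter(
    activity: np.ndarray,
    mu: np.ndarray,
    geometry: AcquisitionGeometry | None = None,
    scatter_fraction: float = 0.3,
    kernel_fwhm_cm: float = 6.0,
    attenuation_scale: float = 0.3,
    primary: np.ndarray | None = None,
    dtype=np.float32,
) -> np.ndarray:
    """Expected scatter-window projections.

    Effective-scatter-source model: the first-order scatter source is the
    unscattered photon fluence (activity convolved with an inverse-square
    kernel, then lightly smoothed with a Gaussian of ``kernel_fwhm_cm``)
    modulated voxelwise by ``mu / mu_water`` — the probability of scatter at
    a location tracks the attenuation there.  The source is projected
    through the system model with a reduced (broad-beam) attenuation map
    ``attenuation_scale * mu``, since photons accepted in the scatter window
    have already scattered and see far less effective attenuation than
    primaries.  The result is globally scaled so that total scatter counts
    equal ``scatter_fraction`` times total primary counts.
    """
    if scatter_fraction < 0:
        raise ValueError("scatter_fraction must be >= 0")
    if not (0 <= attenuation_scale <= 1):
        raise ValueError("attenuation_scale must lie in [0, 1]")
    geometry = geometry or AcquisitionGeometry()
    proj = get_projector(geometry, dtype)
    if primary is None:
        primary = proj.forward(activity, mu)
    from scipy.signal import fftconvolve

    kern = _fluence_kernel(activity.shape, geometry.bin_size_cm)
    flux = np.maximum(
        fftconvolve(np.asarray(activity, dtype=np.float64), kern, mode="same"),
        0.0,
    )
    if kernel_fwhm_cm > 0:
        flux = gaussian_filter(
            flux, sigma=kernel_fwhm_cm / 2.3548 / geometry.bin_size_cm
        )
    src = flux * (np.asarray(mu, dtype=np.float64) / MU_WATER_140KEV)
    scat = proj.forward(
        src.astype(dtype), (attenuation_scale * mu).astype(dtype)
    )
    total = float(scat.sum())
    if total <= 0:
        return np.zeros_like(scat)
    scat *= dtype(scatter_fraction * float(primary.sum()) / total)
    return scat


def add_poisson(
    projections: ProjectionSet,
    total_counts: float,
    seed: int,
) -> ProjectionSet:
    """Scale the photopeak expectation to ``total_counts`` and draw Poisson
    counts in both windows (the scatter window keeps its relative scale)."""
    if total_counts <= 0:
        raise ValueError("total_counts must be > 0")
    pp = np.asarray(projections.photopeak, dtype=np.float64)
    if np.any(pp < 0):
        raise ValueError("expectations must be nonnegative")
    s = total_counts / pp.sum()
    rng = np.random.default_rng(seed)
    noisy_pp = rng.poisson(pp * s).astype(np.float64)
    noisy_sc = None
    if projections.scatter is not None:
        sc = np.asarray(projections.scatter, dtype=np.float64)
        if np.any(sc < 0):
            raise ValueError("expectations must be nonnegative")
        noisy_sc = rng.poisson(sc * s).astype(np.float64)
    return ProjectionSet(
        geometry=projections.geometry,
        photopeak=noisy_pp,
        scatter=noisy_sc,
        window_bounds_kev=projections.window_bounds_kev,
        is_noisy=True,
    )
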