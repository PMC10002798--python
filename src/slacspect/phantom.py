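"""Randomized digital thorax phantoms for myocardial perfusion SPECT.

Each phantom pairs a Tc-99m activity map, a 140 keV attenuation map, a
six-class tissue segmentation (background, lungs, skin/subcutaneous adipose,
muscles/organs, bones, patient table) and the left-ventricular (LV) geometry
needed to insert parametric perfusion defects and to reorient reconstructions
into short-axis slices.

Anatomy is procedurally generated: an elliptical-cylinder body with a
skin/adipose rind, two ellipsoidal lungs, a spine and sternum, a liver, a
half-ellipsoidal LV myocardial shell, and a flat patient table.  Organ sizes,
positions, per-class attenuation coefficients and uptake ratios are jittered
per seed, so class-mean attenuation estimation and segmentation are
nontrivial across a cohort.

Coordinates: 0-based voxel indices, axis order ``(x, y, z)`` with ``z`` the
scanner axis and ``+y`` posterior (the table side); world coordinates in cm
at voxel centers, origin at the volume center.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeGrid",
    "HeartGeometry",
    "DefectSpec",
    "PhantomInstance",
    "AnatomyParams",
    "CLASS_NAMES",
    "NOMINAL_CLASS_MU",
    "BACKGROUND",
    "LUNGS",
    "ADIPOSE",
    "SOFT_TISSUE",
    "BONE",
    "TABLE",
    "defect_catalog",
    "generate_phantom",
    "insert_defect",
    "myocardium_mask",
    "defect_sector_mask",
    "defect_centroid",
    "simulate_pseudo_ct",
]

# Tissue class labels.
BACKGROUND, LUNGS, ADIPOSE, SOFT_TISSUE, BONE, TABLE = 0, 1, 2, 3, 4, 5

CLASS_NAMES = {
    BACKGROUND: "background",
    LUNGS: "lungs",
    ADIPOSE: "skin/subcutaneous adipose",
    SOFT_TISSUE: "muscles/organs",
    BONE: "bones",
    TABLE: "patient table",
}

#: Nominal linear attenuation coefficients at 140 keV (cm^-1) per class.
NOMINAL_CLASS_MU = {
    BACKGROUND: 0.0,
    LUNGS: 0.04,
    ADIPOSE: 0.14,
    SOFT_TISSUE: 0.154,
    BONE: 0.25,
    TABLE: 0.20,
}

WALL_ANGLES_DEG = {"lateral": 0.0, "anterior": 90.0, "inferior": 270.0}
WALLS = ("anterior", "inferior", "lateral")
EXTENTS_DEG = (30.0, 60.0, 90.0)
SEVERITIES = (0.10, 0.25, 0.50)


@dataclass(frozen=True)
class VolumeGrid:
    """Reconstruction/simulation grid: shape in voxels, voxel size in cm."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_cm: tuple[float, float, float] = (0.68, 0.68, 0.68)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vs = self.voxel_size_cm
        if np.isscalar(vs):
            vs = (float(vs),) * 3
        vs = tuple(float(v) for v in vs)
        if any(s < 8 for s in shape):
            raise ValueError("all grid dimensions must be >= 8 voxels")
        if any(v <= 0 for v in vs):
            raise ValueError("voxel size must be positive")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size_cm", vs)

    def world_coords(self):
        """Meshgrid of world coordinates (cm) at voxel centers."""
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * v
            for n, v in zip(self.shape, self.voxel_size_cm)
        ]
        return np.meshgrid(*axes, indexing="ij")

    def voxel_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        n = np.asarray(self.shape, dtype=float)
        return (idx - (n - 1) / 2.0) * np.asarray(self.voxel_size_cm)

    def world_to_voxel(self, xyz) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        n = np.asarray(self.shape, dtype=float)
        return xyz / np.asarray(self.voxel_size_cm) + (n - 1) / 2.0


@dataclass(frozen=True)
class HeartGeometry:
    """LV geometry: center, long axis, shell radii and wall reference angles.

    The long axis points from the base toward the apex.  Circumferential
    angles are measured in the short-axis plane about the long axis, with the
    lateral wall at 0 deg, anterior at 90 deg and inferior at 270 deg.
    """

    center_cm: tuple[float, float, float]
    long_axis: tuple[float, float, float]
    r_outer_cm: float
    r_inner_cm: float
    long_outer_cm: float
    long_inner_cm: float
    wall_angles_deg: dict = field(default_factory=lambda: dict(WALL_ANGLES_DEG))
    anterior: tuple[float, float, float] = (0.0, -1.0, 0.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.long_axis, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm < 1e-8:
            raise ValueError("degenerate long axis")
        object.__setattr__(self, "long_axis", tuple(d / nrm))
        if not (0 < self.r_inner_cm < self.r_outer_cm):
            raise ValueError("need 0 < inner radius < outer radius")
        if not (0 < self.long_inner_cm < self.long_outer_cm):
            raise ValueError("need 0 < inner long semi-axis < outer")

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (e1, e2, d): e1 lateral (0 deg), e2 anterior (90 deg)."""
        d = np.asarray(self.long_axis)
        anterior = np.asarray(self.anterior, dtype=float)  # -y: patient front
        e2 = anterior - np.dot(anterior, d) * d
        n = np.linalg.norm(e2)
        if n < 1e-8:
            raise ValueError("long axis parallel to the anterior direction")
        e2 = e2 / n
        e1 = np.cross(e2, d)
        return e1, e2, d


@dataclass(frozen=True)
class DefectSpec:
    """Perfusion-defect parameters: circumferential extent (deg), fractional
    severity (activity reduction) and LV wall location.

    ``severity=0`` is a degenerate identity spec accepted for testing; the
    catalog proper uses the {10%, 25%, 50%} x {30, 60, 90} deg x
    {anterior, inferior, lateral} grid.
    """

    extent_deg: float
    severity: float
    wall: str

    def __post_init__(self) -> None:
        if float(self.extent_deg) not in EXTENTS_DEG:
            raise ValueError(f"extent must be one of {EXTENTS_DEG}")
        if float(self.severity) not in (0.0,) + SEVERITIES:
            raise ValueError(f"severity must be one of {SEVERITIES} (or 0)")
        if self.wall not in WALLS:
            raise ValueError(f"wall must be one of {WALLS}")
        object.__setattr__(self, "extent_deg", float(self.extent_deg))
        object.__setattr__(self, "severity", float(self.severity))


def defect_catalog() -> list[DefectSpec]:
    """The full 27-entry defect grid, ordered by wall, extent, severity."""
    return [
        DefectSpec(extent_deg=e, severity=s, wall=w)
        for w in WALLS
        for e in EXTENTS_DEG
        for s in SEVERITIES
    ]


@dataclass
class AnatomyParams:
    """Anatomy-parameter set with per-seed jitter amplitudes.

    Lengths in cm; uptake ratios relative to soft tissue (=1).  Ranges are
    validated; jitter fractions are uniform half-widths applied per seed.
    """

    body_semiaxes_cm: tuple[float, float] = (15.5, 10.5)
    rind_thickness_cm: float = 1.4
    lung_semiaxes_cm: tuple[float, float, float] = (4.2, 6.0, 10.0)
    lung_offset_cm: tuple[float, float, float] = (6.2, -1.5, 1.5)
    spine_radius_cm: float = 1.9
    spine_y_cm: float = 7.5
    sternum_radius_cm: float = 1.0
    sternum_y_cm: float = -9.0
    liver_center_cm: tuple[float, float, float] = (-5.5, 1.5, -8.5)
    liver_semiaxes_cm: tuple[float, float, float] = (6.5, 5.0, 5.5)
    heart_center_cm: tuple[float, float, float] = (3.8, -2.8, 2.4)
    heart_axis: tuple[float, float, float] = (0.6, -0.5, -0.62)
    lv_outer_radius_cm: float = 3.1
    lv_inner_radius_cm: float = 2.0
    lv_outer_long_cm: float = 4.6
    lv_inner_long_cm: float = 3.5
    table_gap_cm: float = 1.9
    table_thickness_cm: float = 2.0
    table_halfwidth_cm: float = 14.0
    uptake_myocardium: tuple[float, float] = (5.0, 7.0)
    uptake_liver: tuple[float, float] = (1.8, 2.5)
    uptake_lungs: tuple[float, float] = (0.2, 0.4)
    uptake_adipose: float = 0.4
    uptake_bone: float = 0.4
    size_jitter: float = 0.15
    position_jitter_cm: float = 1.2
    lv_size_jitter: float = 0.07
    lv_position_jitter_cm: float = 0.6
    mu_jitter: float = 0.05

    def validate(self) -> None:
        if not (0 <= self.size_jitter <= 0.2):
            raise ValueError("size_jitter must be in [0, 0.2]")
        if not (0 <= self.mu_jitter <= 0.2):
            raise ValueError("mu_jitter must be in [0, 0.2]")
        if not (0 <= self.position_jitter_cm <= 2.0):
            raise ValueError("position_jitter_cm must be in [0, 2] cm")
        if self.uptake_myocardium[0] < 3.0:
            raise ValueError("myocardial uptake ratio must be >= 3x soft tissue")
        if not (0 < self.lv_inner_radius_cm < self.lv_outer_radius_cm):
            raise ValueError("LV inner radius must be below the outer radius")
        if self.rind_thickness_cm <= 0:
            raise ValueError("rind thickness must be positive")


@dataclass
class PhantomInstance:
    """Paired activity / attenuation / segmentation volumes of one phantom."""

    grid: VolumeGrid
    activity: np.ndarray
    mu: np.ndarray
    labels: np.ndarray
    heart: HeartGeometry
    seed: int
    class_mu: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name, arr in (("activity", self.activity), ("mu", self.mu),
                          ("labels", self.labels)):
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
        if np.any(self.activity < 0):
            raise ValueError("activity must be nonnegative")
        if np.any(self.mu < 0) or np.any(self.mu > 0.5):
            raise ValueError("mu must lie in [0, 0.5] cm^-1")
        present = set(np.unique(self.labels).tolist())
        if not present <= set(CLASS_NAMES):
            raise ValueError("labels outside the six tissue classes")
        if np.any(self.activity[self.labels == BACKGROUND] != 0):
            raise ValueError("activity outside the body must be zero")

    def copy(self) -> "PhantomInstance":
        return dataclasses.replace(
            self,
            activity=self.activity.copy(),
            mu=self.mu.copy(),
            labels=self.labels.copy(),
            class_mu=dict(self.class_mu),
        )


def _ellipsoid(X, Y, Z, center, semi) -> np.ndarray:
    return (
        ((X - center[0]) / semi[0]) ** 2
        + ((Y - center[1]) / semi[1]) ** 2
        + ((Z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _heart_frame(grid: VolumeGrid, heart: HeartGeometry):
    """Heart-frame coordinates (q1, q2, q3) of every voxel: q1/q2 span the
    short-axis plane (lateral / anterior), q3 runs base -> apex."""
    X, Y, Z = grid.world_coords()
    c = heart.center_cm
    e1, e2, d = heart.basis()
    dx, dy, dz = X - c[0], Y - c[1], Z - c[2]
    q1 = dx * e1[0] + dy * e1[1] + dz * e1[2]
    q2 = dx * e2[0] + dy * e2[1] + dz * e2[2]
    q3 = dx * d[0] + dy * d[1] + dz * d[2]
    return q1, q2, q3


def myocardium_mask(grid: VolumeGrid, heart: HeartGeometry) -> np.ndarray:
    """Boolean mask of the LV myocardial shell (half-ellipsoid, apex side)."""
    q1, q2, q3 = _heart_frame(grid, heart)
    r2 = q1**2 + q2**2
    outer = r2 / heart.r_outer_cm**2 + q3**2 / heart.long_outer_cm**2 <= 1.0
    inner = r2 / heart.r_inner_cm**2 + q3**2 / heart.long_inner_cm**2 <= 1.0
    apex_half = q3 <= 0.0
    return outer & ~inner & apex_half


def circumferential_angle_deg(grid: VolumeGrid, heart: HeartGeometry) -> np.ndarray:
    """Per-voxel circumferential angle (deg, in [0, 360)) about the LV axis."""
    q1, q2, _ = _heart_frame(grid, heart)
    return np.degrees(np.arctan2(q2, q1)) % 360.0


def defect_sector_mask(
    grid: VolumeGrid, heart: HeartGeometry, spec: DefectSpec
) -> np.ndarray:
    """Myocardial voxels whose circumferential angle falls within the defect
    sector (full apex-to-base extent, sharp boundaries)."""
    myo = myocardium_mask(grid, heart)
    theta = circumferential_angle_deg(grid, heart)
    ref = heart.wall_angles_deg[spec.wall]
    dist = np.abs((theta - ref + 180.0) % 360.0 - 180.0)
    return myo & (dist <= spec.extent_deg / 2.0)


def defect_centroid(
    grid: VolumeGrid, heart: HeartGeometry, spec: DefectSpec
) -> np.ndarray:
    """Centroid (float voxel coordinates) of the defect sector."""
    sector = defect_sector_mask(grid, heart, spec)
    if not sector.any():
        raise ValueError("defect sector does not intersect the myocardium")
    return np.array(np.nonzero(sector), dtype=float).mean(axis=1)


def insert_defect(phantom: PhantomInstance, spec: DefectSpec) -> PhantomInstance:
    """Return a copy with in-sector myocardial activity reduced by the
    defect severity; attenuation and labels are untouched."""
    sector = defect_sector_mask(phantom.grid, phantom.heart, spec)
    if not sector.any():
        raise ValueError("defect sector does not intersect the myocardium")
    out = phantom.copy()
    out.activity[sector] *= 1.0 - spec.severity
    return out


def generate_phantom(
    seed: int,
    params: AnatomyParams | None = None,
    grid: VolumeGrid | None = None,
) -> PhantomInstance:
    """Generate one randomized thorax phantom; pure function of its inputs."""
    if seed < 0:
        raise ValueError("seed must be >= 0")
    params = params or AnatomyParams()
    params.validate()
    grid = grid or VolumeGrid()
    rng = np.random.default_rng(seed)

    def jit_size(x):
        return np.asarray(x) * rng.uniform(1 - params.size_jitter,
                                           1 + params.size_jitter)

    def jit_pos(x):
        return np.asarray(x, dtype=float) + rng.uniform(
            -params.position_jitter_cm, params.position_jitter_cm, size=np.shape(x)
        )

    X, Y, Z = grid.world_coords()
    # lateral width and anterior-posterior depth vary independently across
    # a population (habitus), which drives inferior-wall attenuation spread
    bx = params.body_semiaxes_cm[0] * rng.uniform(
        1 - params.size_jitter, 1 + params.size_jitter
    )
    by = params.body_semiaxes_cm[1] * rng.uniform(
        1 - params.size_jitter, 1 + params.size_jitter
    )
    body = (X / bx) ** 2 + (Y / by) ** 2 <= 1.0
    t = params.rind_thickness_cm
    core = (X / (bx - t)) ** 2 + (Y / (by - t)) ** 2 <= 1.0

    lung_semi = jit_size(params.lung_semiaxes_cm)
    lox, loy, loz = jit_pos(params.lung_offset_cm)
    lung_l = _ellipsoid(X, Y, Z, (lox, loy, loz), lung_semi)
    lung_r = _ellipsoid(X, Y, Z, (-lox, loy, loz), lung_semi)
    lungs = (lung_l | lung_r) & core

    sy = jit_pos(params.spine_y_cm)
    spine = (X**2 + (Y - sy) ** 2) <= jit_size(params.spine_radius_cm) ** 2
    sternum = (X**2 + (Y - params.sternum_y_cm) ** 2) <= params.sternum_radius_cm**2
    bones = (spine | sternum) & core

    liver = _ellipsoid(
        X, Y, Z, jit_pos(params.liver_center_cm), jit_size(params.liver_semiaxes_cm)
    ) & core & ~lungs

    # the LV is jittered on its own, tighter scale: cardiac size and pose
    # vary less across a population than body habitus, and short-axis
    # reorientation leaves residual LV variability small
    hc = np.asarray(params.heart_center_cm) + rng.uniform(
        -params.lv_position_jitter_cm, params.lv_position_jitter_cm, 3
    )
    axis = np.asarray(params.heart_axis, dtype=float) + rng.uniform(-0.08, 0.08, 3)
    lv_scale = rng.uniform(1 - params.lv_size_jitter, 1 + params.lv_size_jitter)
    heart = HeartGeometry(
        center_cm=tuple(hc),
        long_axis=tuple(axis),
        r_outer_cm=params.lv_outer_radius_cm * lv_scale,
        r_inner_cm=params.lv_inner_radius_cm * lv_scale,
        long_outer_cm=params.lv_outer_long_cm * lv_scale,
        long_inner_cm=params.lv_inner_long_cm * lv_scale,
    )
    myo = myocardium_mask(grid, heart)

    table_top = by + params.table_gap_cm
    table = (
        (Y >= table_top)
        & (Y <= table_top + params.table_thickness_cm)
        & (np.abs(X) <= params.table_halfwidth_cm)
    )

    labels = np.zeros(grid.shape, dtype=np.uint8)
    labels[body] = ADIPOSE
    labels[core] = SOFT_TISSUE
    labels[lungs] = LUNGS
    labels[bones] = BONE
    labels[myo & core] = SOFT_TISSUE  # myocardium belongs to muscles/organs
    labels[table & ~body] = TABLE

    class_mu = {
        c: (0.0 if c == BACKGROUND else
            float(m * rng.uniform(1 - params.mu_jitter, 1 + params.mu_jitter)))
        for c, m in NOMINAL_CLASS_MU.items()
    }
    mu = np.zeros(grid.shape, dtype=np.float32)
    for c, m in class_mu.items():
        mu[labels == c] = m

    activity = np.zeros(grid.shape, dtype=np.float32)
    activity[labels == SOFT_TISSUE] = 1.0
    activity[labels == ADIPOSE] = params.uptake_adipose
    activity[labels == BONE] = params.uptake_bone
    activity[labels == LUNGS] = rng.uniform(*params.uptake_lungs)
    activity[liver & (labels == SOFT_TISSUE)] = rng.uniform(*params.uptake_liver)
    activity[myo & (labels == SOFT_TISSUE)] = rng.uniform(*params.uptake_myocardium)

    phantom = PhantomInstance(
        grid=grid, activity=activity, mu=mu, labels=labels,
        heart=heart, seed=int(seed), class_mu=class_mu,
    )
    phantom.validate()
    return phantom


def simulate_pseudo_ct(
    phantom: PhantomInstance,
    noise_sd_hu: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Pseudo-CT in Hounsfield units: the inverse-bilinear image of the
    phantom's attenuation map plus zero-mean Gaussian noise (air = -1000 HU).
    """
    from .attenuation import BilinearModel, mu_to_hu

    hu = mu_to_hu(phantom.mu, BilinearModel())
    if noise_sd_hu > 0:
        rng = np.random.default_rng(phantom.seed + 7919 if seed is None else seed)
        hu = hu + rng.normal(0.0, noise_sd_hu, size=hu.shape)
    return hu.astype(np.float32)
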