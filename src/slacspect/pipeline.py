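"""Three-arm experiment orchestration: SLAC vs CTAC vs NAC.

Generates a phantom cohort, fits the tissue model on the training split,
simulates paired photopeak/scatter projections per study record, runs the
identically configured OSEM + post-processing chain per arm (differing only
in the attenuation-map input), and evaluates defect detection (CHO, ROC,
AUC) and fidelity (RMSE/SSIM against the CTAC arm).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import attenuation as att
from . import phantom as ph
from . import recon as rc
from .forward_model import (
    AcquisitionGeometry,
    ProjectionSet,
    add_poisson,
    forward_project,
    simulate_scatter,
)
from .mceun import classical_fallback_segment, predict_segmentation
from .observer import (
    ObserverStudyResult,
    binormal_fit,
    cho_scores,
    empirical_roc_auc,
    fidelity_metrics,
    make_channel_bank,
)

__all__ = [
    "ExperimentConfig",
    "StudyRecord",
    "StudyDesign",
    "ArmOutput",
    "ExperimentReport",
    "build_study_design",
    "simulate_cohort",
    "run_arm",
    "run_full_experiment",
]

ARMS = ("SLAC", "CTAC", "NAC")


@dataclass
class ExperimentConfig:
    """Desk-scale three-arm experiment configuration.

    The cohort sizes and acquisition settings are scaled-down analogues of a
    clinical MPS study; every random choice derives from ``seed``.
    """

    n_train: int = 10
    n_present: int = 12
    n_absent: int = 12
    wall: str | None = "inferior"
    seed: int = 1234
    geometry: AcquisitionGeometry = field(
        default_factory=lambda: AcquisitionGeometry(n_angles=30)
    )
    total_counts: float = 4e6
    scatter_fraction: float = 0.3
    pseudo_ct_noise_hu: float = 20.0
    recon_subsets: int = 6
    recon_iterations: int = 10
    init_subsets: int = 6
    init_iterations: int = 2
    mrf_beta: float = 0.5
    mrf_iters: int = 4
    segmentation_backend: str = "fallback"  # mceun | fallback | ground-truth
    roi_normalization: str = "roi-max"  # roi-max | roi-mean | volume | none
    n_boot: int = 500

    def validate(self) -> None:
        if min(self.n_train, self.n_present, self.n_absent) < 1:
            raise ValueError("all cohort groups need at least one patient")
        if self.segmentation_backend not in ("mceun", "fallback", "ground-truth"):
            raise ValueError(f"unknown backend {self.segmentation_backend!r}")
        if self.wall is not None and self.wall not in ph.WALLS:
            raise ValueError(f"unknown wall {self.wall!r}")


@dataclass(frozen=True)
class StudyRecord:
    """One observer-study sample: a patient scanned with (present) or
    without (absent) a defect; ``roi_spec`` fixes the ROI location."""

    patient_id: str
    defect: ph.DefectSpec | None
    roi_spec: ph.DefectSpec

    @property
    def present(self) -> bool:
        return self.defect is not None


@dataclass
class StudyDesign:
    records: list
    n_present_records: int
    n_absent_records: int

    def __len__(self) -> int:
        return len(self.records)


def build_study_design(config: ExperimentConfig, catalog=None) -> StudyDesign:
    """Cross product of defect-present patients and in-scope defect specs,
    plus one record per (defect-absent patient, in-scope spec)."""
    config.validate()
    catalog = list(catalog if catalog is not None else ph.defect_catalog())
    if not catalog:
        raise ValueError("empty defect catalog")
    specs = [s for s in catalog if config.wall is None or s.wall == config.wall]
    records = []
    for i in range(config.n_present):
        pid = f"present{i:03d}"
        for spec in specs:
            records.append(StudyRecord(pid, spec, spec))
    n_present = len(records)
    for i in range(config.n_absent):
        pid = f"absent{i:03d}"
        for spec in specs:
            records.append(StudyRecord(pid, None, spec))
    return StudyDesign(
        records=records,
        n_present_records=n_present,
        n_absent_records=len(records) - n_present,
    )


# --------------------------------------------------------------------------
# cohort simulation


@dataclass
class PatientAssets:
    phantom: ph.PhantomInstance
    ct_mu: np.ndarray            # bilinear-converted pseudo-CT map (CTAC)
    healthy_pset: ProjectionSet  # noisy scan without defect
    record_psets: dict = field(default_factory=dict)  # spec -> noisy ProjectionSet


@dataclass
class CohortAssets:
    tissue_model: att.TissueModel
    patients: dict  # patient_id -> PatientAssets
    slac_mu: dict = field(default_factory=dict)
    slac_labels: dict = field(default_factory=dict)


def _simulate_scan(
    activity: np.ndarray,
    mu: np.ndarray,
    config: ExperimentConfig,
    noise_seed: int,
) -> ProjectionSet:
    primary = forward_project(activity, mu, config.geometry)
    scatter = simulate_scatter(
        activity, mu, config.geometry,
        scatter_fraction=config.scatter_fraction, primary=primary,
    )
    clean = ProjectionSet(config.geometry, primary.astype(np.float64),
                          scatter.astype(np.float64))
    return add_poisson(clean, config.total_counts, noise_seed)


def fit_training_tissue_model(config: ExperimentConfig) -> att.TissueModel:
    """Training arm of the pipeline: per-patient pseudo-CT -> bilinear mu
    maps, MRF segmentation, pooled per-class mean coefficients."""
    base = config.seed % 100_000
    mu_maps, label_maps = [], []
    for i in range(config.n_train):
        p = ph.generate_phantom(base + i)
        hu = ph.simulate_pseudo_ct(p, noise_sd_hu=config.pseudo_ct_noise_hu)
        mu = att.bilinear_hu_to_mu(hu)
        labels = att.mrf_segment(
            mu, beta=config.mrf_beta, n_icm_iters=config.mrf_iters
        )
        mu_maps.append(mu)
        label_maps.append(labels)
    return att.fit_tissue_model(
        mu_maps, label_maps, provenance=f"train(seed={config.seed}, n={config.n_train})"
    )


def estimate_slac_labels(
    pset: ProjectionSet,
    config: ExperimentConfig,
    network=None,
    true_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Segmentation step of the SLAC chain for one scan."""
    if config.segmentation_backend == "ground-truth":
        if true_labels is None:
            raise ValueError("ground-truth backend needs the true labels")
        return true_labels
    init_cfg = rc.ReconConfig(
        n_subsets=config.init_subsets, n_iterations=config.init_iterations
    )
    scatter_rec, pp_rec = rc.reconstruct_initial_estimates(pset, init_cfg)
    if config.segmentation_backend == "mceun":
        if network is None:
            raise ValueError("mceun backend needs a trained network")
        return predict_segmentation(network, scatter_rec, pp_rec)
    return classical_fallback_segment(scatter_rec, pp_rec)


def simulate_cohort(
    config: ExperimentConfig,
    study: StudyDesign,
    network=None,
    tissue_model: att.TissueModel | None = None,
) -> CohortAssets:
    """Generate phantoms, simulate all scans and estimate per-patient
    attenuation maps for every arm's input."""
    config.validate()
    base = config.seed % 100_000
    if tissue_model is None:
        tissue_model = fit_training_tissue_model(config)
    patients: dict[str, PatientAssets] = {}
    pids = sorted({r.patient_id for r in study.records})
    for pid in pids:
        group, idx = pid[:-3], int(pid[-3:])
        pseed = base + (1000 if group == "present" else 2000) + idx
        p = ph.generate_phantom(pseed)
        hu = ph.simulate_pseudo_ct(p, noise_sd_hu=config.pseudo_ct_noise_hu)
        ct_mu = att.bilinear_hu_to_mu(hu).astype(np.float32)
        healthy = _simulate_scan(p.activity, p.mu, config, pseed + 50_000)
        patients[pid] = PatientAssets(p, ct_mu, healthy)
    assets = CohortAssets(tissue_model=tissue_model, patients=patients)
    # per-record simulations (defect-present scans)
    for k, rec in enumerate(study.records):
        if not rec.present:
            continue
        pa = patients[rec.patient_id]
        defected = ph.insert_defect(pa.phantom, rec.defect)
        pa.record_psets[rec.defect] = _simulate_scan(
            defected.activity, defected.mu, config,
            base + 300_000 + k,
        )
    # per-patient SLAC attenuation estimate (from the healthy-tracer scan;
    # attenuation is a patient property, unchanged by the perfusion defect)
    for pid, pa in patients.items():
        labels = estimate_slac_labels(
            pa.healthy_pset, config, network=network,
            true_labels=pa.phantom.labels,
        )
        assets.slac_labels[pid] = labels
        assets.slac_mu[pid] = att.assign_mu(labels, tissue_model)
    return assets


# --------------------------------------------------------------------------
# per-arm reconstruction


def arm_recon_config(config: ExperimentConfig, mu_map: np.ndarray | None
                     ) -> rc.ReconConfig:
    """Identical reconstruction settings for every arm; only the attenuation
    input differs."""
    return rc.ReconConfig(
        n_subsets=config.recon_subsets,
        n_iterations=config.recon_iterations,
        use_attenuation=mu_map is not None,
        mu_map=mu_map,
        use_cdr=True,
    )


@dataclass
class ArmOutput:
    arm: str
    rois: np.ndarray          # (n_records, 32, 32)
    labels: np.ndarray        # defect present/absent per record
    volumes: dict             # (patient_id, defect-or-None) -> filtered SA volume


_AUTO = object()


def run_arm(
    study: StudyDesign,
    arm: str,
    assets: CohortAssets,
    config: ExperimentConfig,
    mu_maps=_AUTO,
) -> ArmOutput:
    """Reconstruct every study record for one arm and extract its ROI.

    ``mu_maps`` overrides the per-patient attenuation input (mapping
    patient_id -> map); by default CTAC uses the bilinear pseudo-CT map,
    SLAC the segmentation-derived map, and NAC none (the NAC arm never
    touches an attenuation map).
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if mu_maps is _AUTO:
        if arm == "CTAC":
            mu_maps = {pid: pa.ct_mu for pid, pa in assets.patients.items()}
        elif arm == "SLAC":
            mu_maps = assets.slac_mu
        else:
            mu_maps = None
    if arm != "NAC" and mu_maps is None:
        raise ValueError(f"{arm} arm requires attenuation maps")

    volumes: dict = {}
    rois = np.empty((len(study.records), 32, 32), dtype=np.float32)
    labels = np.zeros(len(study.records), dtype=bool)
    for k, rec in enumerate(study.records):
        pa = assets.patients[rec.patient_id]
        key = (rec.patient_id, rec.defect)
        if key not in volumes:
            pset = (
                pa.record_psets[rec.defect] if rec.present else pa.healthy_pset
            )
            mu = mu_maps[rec.patient_id] if mu_maps is not None else None
            recon = rc.osem(
                pset.photopeak, config.geometry, arm_recon_config(config, mu)
            )
            filtered = rc.butterworth_filter(
                recon,
                voxel_size_cm=pa.phantom.grid.voxel_size_cm[0],
            )
            sa = rc.reorient_short_axis(
                filtered, pa.phantom.heart, pa.phantom.grid
            ).astype(np.float32)
            if config.roi_normalization == "volume" and sa.max() > 0:
                sa = sa / sa.max()
            volumes[key] = sa
        centroid = ph.defect_centroid(pa.phantom.grid, pa.phantom.heart,
                                      rec.roi_spec)
        sa_centroid = rc.short_axis_point(centroid, pa.phantom.heart,
                                          pa.phantom.grid)
        roi = rc.extract_roi(volumes[key], sa_centroid)
        # perfusion images are read on a relative scale; anchoring each ROI
        # to its own peak (the normal myocardial wall) removes patient-level
        # brightness differences while keeping local dimming
        if config.roi_normalization == "roi-max" and roi.max() > 0:
            roi = roi / roi.max()
        elif config.roi_normalization == "roi-mean" and roi.mean() > 0:
            roi = roi / roi.mean()
        rois[k] = roi
        labels[k] = rec.present
    return ArmOutput(arm=arm, rois=rois, labels=labels, volumes=volumes)


# --------------------------------------------------------------------------
# full experiment


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    observer: dict            # arm -> ObserverStudyResult
    fidelity: dict            # arm -> {"rmse": (mean, lo, hi), "ssim": ...}
    counts: dict
    manifest: dict
    runtime_s: float = 0.0

    def summary(self) -> dict:
        out = {"counts": self.counts, "runtime_s": round(self.runtime_s, 1)}
        for arm, res in self.observer.items():
            out[f"auc_{arm.lower()}"] = round(res.auc, 4)
            out[f"auc_{arm.lower()}_ci"] = [round(v, 4) for v in res.auc_ci]
        for arm, fid in self.fidelity.items():
            for m in ("rmse", "ssim"):
                out[f"{m}_{arm.lower()}_vs_ctac"] = round(fid[m][0], 4)
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"summary": self.summary(), "manifest": self.manifest},
                      fh, indent=2)


def _mean_ci(values: np.ndarray, n_boot: int, seed: int):
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=np.float64)
    boots = np.array([
        rng.choice(values, size=len(values), replace=True).mean()
        for _ in range(n_boot)
    ])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(values.mean()), float(lo), float(hi)


def run_full_experiment(
    config: ExperimentConfig | None = None,
    network=None,
) -> ExperimentReport:
    """End-to-end three-arm study on a synthetic cohort.

    Returns per-arm AUCs with bootstrap CIs, binormal fits, and RMSE/SSIM of
    the SLAC and NAC arms against the CTAC reference, plus a manifest from
    which the run can be reproduced bit-identically.
    """
    t0 = time.time()
    config = config or ExperimentConfig()
    config.validate()
    study = build_study_design(config)
    assets = simulate_cohort(config, study, network=network)
    bank = make_channel_bank(32)
    outputs = {arm: run_arm(study, arm, assets, config) for arm in ARMS}

    observer = {}
    for arm, out in outputs.items():
        # image-level leave-one-out, the standard protocol for this task
        stats = cho_scores(out.rois, out.labels, bank)
        roc, auc, ci = empirical_roc_auc(
            stats, out.labels, n_boot=config.n_boot, seed=config.seed + 11
        )
        try:
            bn = binormal_fit(stats, out.labels)
        except ValueError:  # too few samples per class for the ML fit
            bn = None
        observer[arm] = ObserverStudyResult(
            method=arm, statistics=stats, labels=out.labels,
            roc=roc, auc=auc, auc_ci=ci, binormal=bn,
        )

    fidelity = {}
    ref = outputs["CTAC"].volumes
    for arm in ("SLAC", "NAC"):
        rmses, ssims = [], []
        for key, vol in outputs[arm].volumes.items():
            r, s = fidelity_metrics(vol, ref[key])
            rmses.append(r)
            ssims.append(s)
        fidelity[arm] = {
            "rmse": _mean_ci(np.array(rmses), config.n_boot, config.seed + 21),
            "ssim": _mean_ci(np.array(ssims), config.n_boot, config.seed + 22),
        }

    counts = {
        "n_records": len(study),
        "n_present_records": study.n_present_records,
        "n_absent_records": study.n_absent_records,
        "n_train": config.n_train,
    }
    manifest = {
        "config": _config_manifest(config),
        "arms": list(ARMS),
    }
    return ExperimentReport(
        config=config, observer=observer, fidelity=fidelity,
        counts=counts, manifest=manifest, runtime_s=time.time() - t0,
    )


def _config_manifest(config: ExperimentConfig) -> dict:
    d = asdict(config)
    d["geometry"] = asdict(config.geometry)
    return d


def config_from_manifest(manifest: dict) -> ExperimentConfig:
    """Rebuild the experiment configuration recorded in a report manifest."""
    d = dict(manifest["config"])
    geom = d.pop("geometry")
    geom["n_bins"] = tuple(geom["n_bins"])
    return ExperimentConfig(geometry=AcquisitionGeometry(**geom), **d)
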