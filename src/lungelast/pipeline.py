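"""End-to-end orchestration: simulate -> fit-motion -> estimate-elasticity
-> mask -> heterogeneity -> cohort-report, with a manifest for
reproducible reruns.

Every random operation traces to an explicit seed in the config; volumes
are written as uncompressed NIfTI so deterministic stages produce
bit-identical files across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import biomech, heterogeneity, io, masking, motion, phantom

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "fit_motion",
    "estimate_elasticity",
    "mask",
    "heterogeneity",
    "cohort_report",
)


@dataclass
class SubjectConfig:
    subject_id: str
    severity_preset: str = "none"
    seed: int = 0
    tumor_lobes: tuple[int, ...] = ()
    #: group label for the cohort tables (defaults to the preset)
    severity: str | None = None


@dataclass
class RunConfig:
    """All tunables of a pipeline run; round-trips losslessly via YAML."""

    out_dir: str = "run"
    stages: tuple[str, ...] = STAGES
    subjects: tuple[SubjectConfig, ...] = (SubjectConfig("s001"),)
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    vessel_fraction: float = 0.02
    # breathing signal
    signal_duration_s: float = 120.0
    signal_period_s: float = 4.0
    signal_drift: float = 0.0
    # scan set
    n_scans: int = 25
    dvf_noise_sd_mm: float = 0.5
    # motion model phases
    p_exhale: float = 5.0
    p_inhale: float = 85.0
    # masking / indices
    hu_threshold: float = -700.0
    band_kpa: tuple[float, float] = (1.0, 3.0)
    # biomechanical model
    shear_modulus_kpa: float = 4.0
    outer_tol_mm: float = 0.1
    max_outer: int = 30
    #: analyze the inverse-estimated map (slow) instead of the phantom's
    #: ground-truth elasticity
    analyze_estimated: bool = False
    alpha: float = 0.05
    holm: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subjects"] = [dataclasses.asdict(s) for s in self.subjects]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["subjects"] = tuple(
            SubjectConfig(**{**s, "tumor_lobes": tuple(s.get("tumor_lobes", ()))})
            for s in d.get("subjects", [])
        )
        for key in ("stages", "grid_shape", "spacing", "band_kpa"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run the '{stage}' stage first"
        )
    return path


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    Writes ``manifest.yaml`` with the config, library versions, and a
    sha256 checksum per output file, enabling bit-identical rerun checks
    of deterministic stages.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "versions": _versions(),
        "stages": {},
    }
    reports: list[heterogeneity.HeterogeneityReport] = []
    for subj in config.subjects:
        sdir = out / subj.subject_id
        sdir.mkdir(exist_ok=True)
        report = _run_subject(config, subj, sdir, manifest)
        if report is not None:
            reports.append(report)

    if "cohort_report" in config.stages and reports:
        t0 = time.perf_counter()
        cohort = heterogeneity.cohort_report(
            reports, alpha=config.alpha, holm=config.holm
        )
        for name in ("lobar_elasticity", "ehi_summary", "cv_summary",
                     "cv_histogram", "nu_summary", "comparisons"):
            getattr(cohort, name).to_csv(out / f"cohort_{name}.csv",
                                         index=False)
        _record(manifest, "cohort_report", out,
                sorted(out.glob("cohort_*.csv")), t0)

    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest))
    return out


def _versions() -> dict:
    import nibabel
    import scipy

    from . import __version__

    return {
        "lungelast": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "nibabel": nibabel.__version__,
    }


def _record(manifest, stage, base: Path, files, t0) -> None:
    manifest["stages"].setdefault(stage, {"files": {}, "seconds": 0.0})
    entry = manifest["stages"][stage]
    entry["seconds"] = round(entry["seconds"] + time.perf_counter() - t0, 3)
    for f in files:
        entry["files"][str(Path(f).relative_to(base))] = _sha256(Path(f))
    logger.info("stage %s: %d files, %.1fs", stage,
                len(entry["files"]), entry["seconds"])


def _run_subject(config, subj, sdir: Path, manifest):
    spec = phantom.severity_preset(
        subj.severity_preset,
        grid_shape=config.grid_shape,
        spacing=config.spacing,
        vessel_fraction=config.vessel_fraction,
        tumor_spec=(
            phantom.TumorSpec(tuple(subj.tumor_lobes))
            if subj.tumor_lobes else None
        ),
        seed=subj.seed,
    )
    if "simulate" in config.stages:
        t0 = time.perf_counter()
        ph = phantom.generate_phantom(spec)
        signal = phantom.generate_breathing_signal(
            config.signal_duration_s, config.signal_period_s,
            config.signal_drift, seed=subj.seed,
        )
        scans = phantom.generate_scan_set(
            ph, signal, config.n_scans, config.dvf_noise_sd_mm,
            seed=subj.seed,
        )
        io.save_spec(sdir / "phantom_spec.yaml", spec)
        io.save_volume(sdir / "hu_exhale.nii", ph.hu_exhale, spec.spacing)
        io.save_volume(sdir / "lobe_labels.nii",
                       ph.lobe_labels.astype(np.int16), spec.spacing)
        io.save_volume(sdir / "elasticity_truth.nii", ph.elasticity_truth,
                       spec.spacing)
        io.save_volume(sdir / "tumor_labels.nii",
                       ph.tumor_labels.astype(np.uint8), spec.spacing)
        io.save_volume(sdir / "alpha.nii", ph.alpha, spec.spacing)
        io.save_volume(sdir / "beta.nii", ph.beta, spec.spacing)
        io.save_signal(sdir / "breathing_signal.csv", signal)
        io.save_scan_set(sdir / "scans", scans)
        _record(manifest, "simulate", sdir.parent,
                [p for p in sdir.iterdir() if p.is_file()]
                + sorted((sdir / "scans").iterdir()), t0)

    if "fit_motion" in config.stages:
        t0 = time.perf_counter()
        scans = io.load_scan_set(_require(sdir / "scans", "simulate"))
        signal = io.load_signal(
            _require(sdir / "breathing_signal.csv", "simulate"))
        params = motion.fit_motion_model(scans)
        pair = motion.synthesize_phase_pair(
            params, signal, config.p_exhale, config.p_inhale)
        io.save_volume(sdir / "fit_alpha.nii", params.alpha, scans.spacing)
        io.save_volume(sdir / "fit_beta.nii", params.beta, scans.spacing)
        io.save_volume(sdir / "fit_residual.nii", params.fit_residual,
                       scans.spacing)
        io.save_volume(sdir / "exhale_to_inhale_dvf.nii",
                       pair.exhale_to_inhale_dvf, scans.spacing)
        _record(manifest, "fit_motion", sdir.parent,
                [sdir / f for f in ("fit_alpha.nii", "fit_beta.nii",
                                    "fit_residual.nii",
                                    "exhale_to_inhale_dvf.nii")], t0)

    if "mask" in config.stages:
        t0 = time.perf_counter()
        hu, spacing = io.load_volume(_require(sdir / "hu_exhale.nii",
                                              "simulate"))
        labels, _ = io.load_volume(sdir / "lobe_labels.nii")
        pmask = masking.parenchyma_mask(hu, labels.astype(int),
                                        config.hu_threshold)
        io.save_volume(sdir / "parenchyma_mask.nii",
                       pmask.mask.astype(np.uint8), spacing)
        _record(manifest, "mask", sdir.parent,
                [sdir / "parenchyma_mask.nii"], t0)

    if "estimate_elasticity" in config.stages:
        t0 = time.perf_counter()
        hu, spacing = io.load_volume(_require(sdir / "hu_exhale.nii",
                                              "simulate"))
        pmask_vol, _ = io.load_volume(
            _require(sdir / "parenchyma_mask.nii", "mask"))
        dvf, _ = io.load_volume(
            _require(sdir / "exhale_to_inhale_dvf.nii", "fit_motion"))
        mask = pmask_vol > 0
        grid = biomech.build_element_grid(
            mask, spacing, dvf, shear_modulus=config.shear_modulus_kpa)
        init = biomech.init_elasticity_from_hu(hu, mask)
        result = biomech.estimate_elasticity(
            grid, dvf, init, outer_tol=config.outer_tol_mm,
            max_outer=config.max_outer)
        io.save_volume(sdir / "elasticity_estimated.nii",
                       result.elasticity.to_volume(grid), spacing)
        np.savetxt(sdir / "convergence_trace.csv",
                   np.asarray(result.error_trace), header="mean_dvf_error_mm",
                   comments="")
        _record(manifest, "estimate_elasticity", sdir.parent,
                [sdir / "elasticity_estimated.nii",
                 sdir / "convergence_trace.csv"], t0)

    report = None
    if "heterogeneity" in config.stages:
        t0 = time.perf_counter()
        elast_file = (
            "elasticity_estimated.nii" if config.analyze_estimated
            else "elasticity_truth.nii"
        )
        needed_stage = (
            "estimate_elasticity" if config.analyze_estimated else "simulate"
        )
        elast, _ = io.load_volume(_require(sdir / elast_file, needed_stage))
        hu, _ = io.load_volume(_require(sdir / "hu_exhale.nii", "simulate"))
        labels, _ = io.load_volume(sdir / "lobe_labels.nii")
        report = heterogeneity.subject_report(
            elast, hu, labels.astype(int),
            subject_id=subj.subject_id,
            severity=subj.severity or (
                "none" if subj.severity_preset == "homogeneous"
                else subj.severity_preset
            ),
            tumor_lobes=subj.tumor_lobes or None,
            threshold_hu=config.hu_threshold,
            band=config.band_kpa,
        )
        io.save_json(sdir / "heterogeneity_report.json", report.to_dict())
        _record(manifest, "heterogeneity", sdir.parent,
                [sdir / "heterogeneity_report.json"], t0)
    return report
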