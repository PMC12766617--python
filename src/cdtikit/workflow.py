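"""Experiment orchestration: config, cohort generation, I/O, end-to-end runs.

Ties the pipeline together in the order the method runs: synthetic LV
cohort -> forward DWI simulation -> breath-hold subsetting and averaging ->
LLS tensor fit -> ensemble de-noising -> map computation -> error report.
Also hosts the protocol-time arithmetic (scan minutes, heartbeats per
repetition) and the NIfTI/JSON persistence layer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import denoise as dn
from . import dwi_sim, evaluate, maps, phantom, tensor_fit

__all__ = [
    "ExperimentConfig",
    "PhantomSubject",
    "scan_time_minutes",
    "repetition_heartbeats",
    "repetition_seconds",
    "cohort_percentage",
    "make_cohort_subject",
    "simulate_and_fit_subject",
    "build_training_pairs",
    "train_ensemble",
    "run_experiment",
    "save_tensor_field",
    "load_tensor_field",
    "save_map",
    "save_mask",
    "load_config",
    "save_config",
    "save_checkpoint",
    "load_checkpoint",
    "write_json",
    "HEARTBEATS_PER_REPETITION",
]

#: One complete repetition (one b=0 image plus 6 DWIs, with preparation
#: pulses) spans 18 heartbeats in the stimulated-echo acquisition.
HEARTBEATS_PER_REPETITION = 18


# ---------------------------------------------------------------------------
# Protocol-time arithmetic
# ---------------------------------------------------------------------------

def scan_time_minutes(minutes_per_slice_per_phase: float, n_phases: int,
                      n_slices: int) -> float:
    """Total scan time: minutes per slice per cardiac phase x phases x slices.

    E.g. 8 min/slice at two phases (systole + diastole) gives 16 min per
    slice; whole-heart coverage at ~12 slices gives 192 min.
    """
    for name, v in (("minutes_per_slice_per_phase", minutes_per_slice_per_phase),
                    ("n_phases", n_phases), ("n_slices", n_slices)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    return minutes_per_slice_per_phase * n_phases * n_slices


def repetition_heartbeats(n_repetitions: int) -> int:
    """Heartbeats consumed by n repetitions (18 per repetition)."""
    if n_repetitions < 0:
        raise ValueError("n_repetitions must be non-negative")
    return HEARTBEATS_PER_REPETITION * n_repetitions


def repetition_seconds(n_repetitions: int, bpm: float) -> float:
    """Seconds for n repetitions at a given heart rate."""
    if bpm <= 0:
        raise ValueError("heart rate must be positive")
    return repetition_heartbeats(n_repetitions) * 60.0 / bpm


def cohort_percentage(counts: dict[str, int], key: str) -> float:
    """Percentage of one condition in a cohort count table, 1-decimal rounded."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("cohort is empty")
    if key not in counts:
        raise KeyError(f"unknown condition {key!r}")
    return round(100.0 * counts[key] / total, 1)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Knobs of one synthetic-cohort de-noising experiment.

    Geometry and tissue parameters are per-subject sampling distributions
    (uniform ranges / normal jitter around the stated means); acquisition
    follows the breath-hold regimes; the de-noiser presets are ``tiny``
    (desk scale) or ``reference`` (full scale).
    """

    grid_shape: tuple[int, int] = (64, 64)
    n_subjects: int = 50
    regimes: tuple[str, ...] = ("1BH",)
    snr: float = 25.0
    s0: float = 1.0
    # geometry sampling
    center_jitter: float = 1.5
    r_endo_range: tuple[float, float] = (8.0, 10.0)
    r_epi_range: tuple[float, float] = (18.0, 22.0)
    # tissue sampling
    ha_endo_mean: float = 60.0
    ha_epi_mean: float = -60.0
    ha_jitter_sd: float = 5.0
    e2a_range: tuple[float, float] = (10.0, 30.0)
    md_mean: float = 1.0e-3
    md_jitter_sd: float = 0.05e-3
    fa_mean: float = 0.45
    fa_jitter_sd: float = 0.03
    # model / training
    generator_preset: str = "tiny"
    train_preset: str = "tiny"
    n_members: int = 2
    epochs: int | None = 30
    crop_shape: tuple[int, int] = (48, 48)
    split_seed: int = 0
    seed: int = 0
    output_dir: str | None = None

    @property
    def noise_sigma(self) -> float:
        return self.s0 / self.snr

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an experiment config from YAML (or JSON — valid YAML subset)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("grid_shape", "regimes", "r_endo_range", "r_epi_range",
                "e2a_range", "crop_shape"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return ExperimentConfig(**raw)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.as_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class PhantomSubject:
    """One synthetic subject: geometry, prescription, and ground truth."""

    subject_id: int
    geometry: phantom.LVGeometry
    orientation: phantom.OrientationField
    tensor_field: phantom.TensorField
    s0_map: np.ndarray
    params: dict = field(default_factory=dict)


def make_cohort_subject(config: ExperimentConfig, subject_id: int,
                        sit_flag: bool = False) -> PhantomSubject:
    """Sample one subject's phantom from the cohort distributions.

    Per-subject randomness comes from a substream of the master seed, so a
    subject is reproducible independently of cohort size.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 77, subject_id])
    )
    rows, cols = config.grid_shape
    cr = rows / 2 - 0.5 + rng.uniform(-config.center_jitter, config.center_jitter)
    cc = cols / 2 - 0.5 + rng.uniform(-config.center_jitter, config.center_jitter)
    r_endo = rng.uniform(*config.r_endo_range)
    r_epi = rng.uniform(*config.r_epi_range)
    geom = phantom.make_lv_geometry(config.grid_shape, (cr, cc), r_endo, r_epi)
    ha_endo = float(np.clip(rng.normal(config.ha_endo_mean, config.ha_jitter_sd),
                            -90, 90))
    ha_epi = float(np.clip(rng.normal(config.ha_epi_mean, config.ha_jitter_sd),
                           -90, 90))
    e2a = float(rng.uniform(*config.e2a_range))
    orient = phantom.prescribe_orientation(geom, ha_endo, ha_epi, e2a,
                                           sit_flag=sit_flag)
    md = float(rng.normal(config.md_mean, config.md_jitter_sd))
    fa = float(np.clip(rng.normal(config.fa_mean, config.fa_jitter_sd), 0.3, 0.6))
    tf = phantom.build_tensor_field(orient, md, fa)
    s0_map = np.where(geom.myo_mask | geom.blood_mask, config.s0, 0.0)
    return PhantomSubject(
        subject_id=subject_id, geometry=geom, orientation=orient,
        tensor_field=tf, s0_map=s0_map,
        params={"ha_endo": ha_endo, "ha_epi": ha_epi, "e2a": e2a,
                "md": md, "fa": fa, "r_endo": r_endo, "r_epi": r_epi,
                "sit": sit_flag},
    )


@dataclass
class FittedSubject:
    """LLS fits of one subject: full-repetition reference + per-regime noisy."""

    subject: PhantomSubject
    reference: tensor_fit.LLSFit
    noisy: dict[tuple[str, str], tensor_fit.LLSFit]  # (regime, position)


def _lls(series: dwi_sim.DWISeries, mask: np.ndarray) -> tensor_fit.LLSFit:
    stack, meta = dwi_sim.average_repetitions(series)
    design = tensor_fit.build_design_matrix(meta)
    return tensor_fit.fit_lls(stack, design, mask)


def simulate_and_fit_subject(
    config: ExperimentConfig, subject: PhantomSubject,
    positions: tuple[str, ...] = ("first",),
) -> FittedSubject:
    """Simulate the full protocol once, then fit reference and regime subsets."""
    protocol = dwi_sim.make_protocol("full")
    series = dwi_sim.simulate_dwi(
        subject.tensor_field, subject.s0_map, protocol, config.noise_sigma,
        seed=int(np.random.SeedSequence(
            [config.seed, 1000, subject.subject_id]).generate_state(1)[0] % (2**31)),
    )
    mask = subject.geometry.myo_mask
    reference = _lls(series, mask)
    noisy = {}
    for regime in config.regimes:
        for pos in positions:
            sub = dwi_sim.select_regime_subset(series, regime, pos)
            noisy[(regime, pos)] = _lls(sub, mask)
    return FittedSubject(subject=subject, reference=reference, noisy=noisy)


# ---------------------------------------------------------------------------
# Training assembly
# ---------------------------------------------------------------------------

def build_training_pairs(
    fitted: list[FittedSubject],
    regime: str,
    spec: tensor_fit.NormalizationSpec,
    crop_shape: tuple[int, int],
    positions: tuple[str, ...] = ("first", "central", "last"),
) -> list[dn.TrainingSample]:
    """Normalized (noisy, reference) pairs, one per repetition subset."""
    pairs = []
    for fs in fitted:
        mask = fs.subject.geometry.myo_mask
        for pos in positions:
            if (regime, pos) not in fs.noisy:
                continue
            noisy_c, target_c, mask_c = dn.augment_sample(
                fs.noisy[(regime, pos)].tensor_field,
                fs.reference.tensor_field, mask, 0.0, crop_shape,
            )
            x = tensor_fit.normalize_tensor(noisy_c, spec)
            y = tensor_fit.normalize_tensor(target_c, spec)
            pairs.append(dn.TrainingSample(
                noisy=np.moveaxis(x, -1, 0), target=np.moveaxis(y, -1, 0)
            ))
    return pairs


def train_ensemble(
    train_pairs: list[dn.TrainingSample],
    val_pairs: list[dn.TrainingSample],
    config: ExperimentConfig,
    spec: tensor_fit.NormalizationSpec,
    master_seed: int | None = None,
) -> list[dn.Checkpoint]:
    """Train ``n_members`` independently initialized members (bagging)."""
    gen_cfg = dn.GENERATOR_PRESETS[config.generator_preset]
    base = dn.TRAIN_PRESETS[config.train_preset]
    if config.epochs is not None:
        base = dataclasses.replace(base, epochs=config.epochs)
    seed0 = config.seed if master_seed is None else master_seed
    members = []
    for m in range(config.n_members):
        tcfg = dataclasses.replace(base, seed=seed0 * 1009 + m)
        members.append(dn.train(train_pairs, val_pairs, gen_cfg, tcfg,
                                norm_spec=spec))
    return members


# ---------------------------------------------------------------------------
# End-to-end experiment
# ---------------------------------------------------------------------------

def run_experiment(config: ExperimentConfig) -> dict:
    """Full pipeline; returns (and optionally persists) the error report.

    Stages: cohort generation, DWI simulation, LLS fitting, patient-level
    splitting, normalization-statistics fit, ensemble training, de-noising
    of the held-out test subjects, and evaluation of LLS vs de-noised maps
    against the full-repetition reference maps.  Fully reproducible from
    the config (all randomness descends from ``config.seed``).
    """
    stage = "cohort"
    try:
        subjects = [make_cohort_subject(config, sid)
                    for sid in range(config.n_subjects)]
        stage = "split"
        train_ids, val_ids, test_ids = dn.split_patients(
            [s.subject_id for s in subjects], seed=config.split_seed
        )
        stage = "simulate+fit"
        fitted: dict[int, FittedSubject] = {}
        for s in subjects:
            positions = (("first", "central", "last")
                         if s.subject_id in train_ids or s.subject_id in val_ids
                         else ("first",))
            fitted[s.subject_id] = simulate_and_fit_subject(config, s, positions)
        stage = "normalization"
        spec = tensor_fit.fit_zscore_spec(
            [fitted[i].reference.tensor_field for i in train_ids]
        )
        stage = "train"
        report: dict = {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "split": {"train": sorted(train_ids), "val": sorted(val_ids),
                      "test": sorted(test_ids)},
            "regimes": {},
        }
        ensembles: dict[str, list[dn.Checkpoint]] = {}
        for regime in config.regimes:
            train_pairs = build_training_pairs(
                [fitted[i] for i in train_ids], regime, spec, config.crop_shape
            )
            val_pairs = build_training_pairs(
                [fitted[i] for i in val_ids], regime, spec, config.crop_shape,
                positions=("first",),
            )
            ensembles[regime] = train_ensemble(train_pairs, val_pairs, config, spec)
        stage = "evaluate"
        for regime in config.regimes:
            entries_lls, entries_dn = [], []
            for i in test_ids:
                fs = fitted[i]
                geom = fs.subject.geometry
                frame = geom.frame()
                ref_maps = maps.compute_cdti_maps(fs.reference.tensor_field, frame)
                noisy_tf = fs.noisy[(regime, "first")].tensor_field
                lls_maps = maps.compute_cdti_maps(noisy_tf, frame)
                den = dn.denoise_field(ensembles[regime], noisy_tf)
                den_maps = maps.compute_cdti_maps(den, frame)
                entries_lls.append(
                    evaluate.map_errors(lls_maps, ref_maps, geom.myo_mask))
                entries_dn.append(
                    evaluate.map_errors(den_maps, ref_maps, geom.myo_mask))
                if config.output_dir is not None:
                    _persist_subject(config, regime, fs, den)
            s_lls = evaluate.cohort_summary(entries_lls)
            s_dn = evaluate.cohort_summary(entries_dn)
            report["regimes"][regime] = {
                "lls": {"median": s_lls.median, "iqr": s_lls.iqr},
                "denoised": {"median": s_dn.median, "iqr": s_dn.iqr},
                "per_subject": {
                    "lls": [e.as_dict() for e in entries_lls],
                    "denoised": [e.as_dict() for e in entries_dn],
                },
                "reduction_percent": {
                    k: 100.0 * (1.0 - s_dn.median[k] / s_lls.median[k])
                    for k in s_lls.median
                },
            }
    except Exception as err:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {err}") from err

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json(report, out / "report.json")
        save_config(config, out / "config.yaml")
    return report


def _persist_subject(config: ExperimentConfig, regime: str,
                     fs: FittedSubject, denoised: phantom.TensorField) -> None:
    out = Path(config.output_dir) / f"subject_{fs.subject.subject_id:03d}" / regime
    out.mkdir(parents=True, exist_ok=True)
    sidecar = {"config_hash": config.content_hash(), "seed": config.seed,
               "subject": fs.subject.subject_id, "regime": regime,
               "params": fs.subject.params}
    save_tensor_field(fs.noisy[(regime, "first")].tensor_field,
                      out / "tensor_lls.nii.gz", sidecar)
    save_tensor_field(denoised, out / "tensor_denoised.nii.gz", sidecar)
    save_tensor_field(fs.reference.tensor_field,
                      out / "tensor_reference.nii.gz", sidecar)
    save_mask(fs.subject.geometry.myo_mask, out / "myo_mask.nii.gz")


# ---------------------------------------------------------------------------
# NIfTI / JSON I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_tensor_field(tf: phantom.TensorField, path: str | Path,
                      sidecar: dict | None = None) -> None:
    """Tensor field as a 6-volume NIfTI (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)."""
    path = Path(path)
    img = nib.Nifti1Image(tf.d.astype(np.float64), np.eye(4))
    nib.save(img, str(path))
    mask_img = nib.Nifti1Image(tf.mask.astype(np.uint8), np.eye(4))
    nib.save(mask_img, str(path.with_name("mask_" + path.name)))
    meta = {"channels": list(phantom.TENSOR_CHANNELS), "units": "mm^2/s"}
    if sidecar:
        meta.update(sidecar)
    write_json(meta, _sidecar_path(path))


def load_tensor_field(path: str | Path) -> phantom.TensorField:
    path = Path(path)
    d = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    mask_path = path.with_name("mask_" + path.name)
    if mask_path.exists():
        mask = np.asarray(nib.load(str(mask_path)).dataobj).astype(bool)
    else:
        mask = np.any(d != 0, axis=-1)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("channels") != list(phantom.TENSOR_CHANNELS):
            raise ValueError(f"unexpected channel order in {sidecar}")
    return phantom.TensorField(d=d, mask=mask)


def save_map(arr: np.ndarray, path: str | Path, units: str = "") -> None:
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), np.eye(4)),
             str(path))
    if units:
        write_json({"units": units}, _sidecar_path(Path(path)))


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.eye(4)),
             str(path))


def save_checkpoint(ckpt: dn.Checkpoint, path: str | Path) -> None:
    """Checkpoint as .npz: weights + config/seed/history/normalization."""
    spec = ckpt.norm_spec
    header = {
        "generator_config": dataclasses.asdict(ckpt.generator_config),
        "seed": ckpt.seed,
        "best_epoch": ckpt.best_epoch,
        "history": ckpt.history,
        "norm_mode": spec.mode,
        "scale_factor": spec.scale_factor,
    }
    arrays = {f"param_{i:03d}": a for i, a in enumerate(ckpt.params)}
    if spec.channel_mean is not None:
        arrays["channel_mean"] = spec.channel_mean
        arrays["channel_std"] = spec.channel_std
    np.savez(path, header=json.dumps(header, default=float), **arrays)


def load_checkpoint(path: str | Path) -> dn.Checkpoint:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        params = [data[k] for k in sorted(data.files) if k.startswith("param_")]
        cfg_raw = header["generator_config"]
        cfg_raw["depths"] = tuple(cfg_raw["depths"])
        spec = tensor_fit.NormalizationSpec(
            mode=header["norm_mode"],
            scale_factor=header["scale_factor"],
            channel_mean=(data["channel_mean"] if "channel_mean" in data.files
                          else None),
            channel_std=(data["channel_std"] if "channel_std" in data.files
                         else None),
        )
    return dn.Checkpoint(
        generator_config=dn.GeneratorConfig(**cfg_raw), params=params,
        norm_spec=spec, seed=header["seed"], best_epoch=header["best_epoch"],
        history=header["history"],
    )


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
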