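"""File-format plumbing: HDF5 containers, CSV metric tables, YAML run
configuration, and the ``run_full`` orchestrator.

Layout of the HDF5 containers:

* raw M-scan:      /frames (time x pixel), /wavelength_nm, acquisition and
  laser settings as attributes, optional /truth group with the phantom;
* cohort:          one group per region (``/<region_id>/column_000/...``)
  plus a /manifest CSV-equivalent table of per-region ground truth;
* B-scan channels: /oct, /srs_amp, /srs_phase, /valid (depth x lateral),
  /depth_um, optional /surface_um.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .physics import LaserConfig, RamanLine, SpectralAxis
from .pipeline import AnalysisConfig, analyze_cohort, discrimination_report
from .reconstruct import BScanChannels
from .simulate import (
    AcquisitionConfig,
    CohortConfig,
    CohortPlan,
    Phantom,
    PhantomPopulation,
    RawMScan,
    make_cohort,
)

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "RunConfig",
    "RunManifest",
    "save_mscan",
    "load_mscan",
    "save_bscan",
    "load_bscan",
    "save_bscan_channels",
    "load_bscan_channels",
    "save_cohort",
    "write_metrics_csv",
    "read_metrics_csv",
    "run_full",
]

SCHEMA_VERSION = 1


class SchemaError(RuntimeError):
    """Raised when a container misses required datasets or has a version
    this code does not understand."""


def _write_dataclass_attrs(group, obj, skip=()):
    for f in dataclasses.fields(obj):
        if f.name in skip:
            continue
        value = getattr(obj, f.name)
        if isinstance(value, (int, float, str, bool, np.integer, np.floating)):
            group.attrs[f.name] = value


def _read_attrs_into(cls, attrs, **extra):
    names = {f.name for f in dataclasses.fields(cls)}
    kw = {k: (v.item() if isinstance(v, np.generic) else v) for k, v in attrs.items() if k in names}
    kw.update(extra)
    return cls(**kw)


def _save_phantom(group, phantom: Phantom):
    group.create_dataset("depth_axis_um", data=phantom.depth_axis_um)
    group.create_dataset("reflectivity", data=phantom.reflectivity)
    group.create_dataset("interaction_profile", data=phantom.interaction_profile)
    _write_dataclass_attrs(group, phantom, skip=("depth_axis_um", "reflectivity", "interaction_profile", "chi_lines"))
    lines = np.array([(ln.center_cm, ln.width_cm, ln.amplitude) for ln in phantom.chi_lines])
    group.create_dataset("chi_lines", data=lines)


def _load_phantom(group) -> Phantom:
    lines = [RamanLine(*row) for row in group["chi_lines"][...]]
    kw = {k: (v.item() if isinstance(v, np.generic) else v) for k, v in group.attrs.items()}
    return Phantom(
        depth_axis_um=group["depth_axis_um"][...],
        reflectivity=group["reflectivity"][...],
        interaction_profile=group["interaction_profile"][...],
        chi_lines=lines,
        **kw,
    )


def _save_mscan_group(group, mscan: RawMScan):
    group.attrs["schema_version"] = SCHEMA_VERSION
    group.create_dataset("frames", data=mscan.frames)
    group.create_dataset("wavelength_nm", data=mscan.spectral_axis.wavelengths_nm)
    group.attrs["stokes_on"] = mscan.stokes_on
    group.attrs["lateral_position_um"] = mscan.lateral_position_um
    acq = group.create_group("acquisition")
    _write_dataclass_attrs(acq, mscan.acquisition)
    las = group.create_group("laser")
    _write_dataclass_attrs(las, mscan.laser)
    if mscan.truth is not None:
        _save_phantom(group.create_group("truth"), mscan.truth)


def _load_mscan_group(group) -> RawMScan:
    for required in ("frames", "wavelength_nm", "acquisition", "laser"):
        if required not in group:
            raise SchemaError(f"missing {required!r} in M-scan container")
    if int(group.attrs.get("schema_version", -1)) != SCHEMA_VERSION:
        raise SchemaError("unsupported schema version")
    return RawMScan(
        frames=group["frames"][...],
        spectral_axis=SpectralAxis(group["wavelength_nm"][...]),
        acquisition=_read_attrs_into(AcquisitionConfig, group["acquisition"].attrs),
        laser=_read_attrs_into(LaserConfig, group["laser"].attrs),
        stokes_on=bool(group.attrs["stokes_on"]),
        lateral_position_um=float(group.attrs["lateral_position_um"]),
        truth=_load_phantom(group["truth"]) if "truth" in group else None,
    )


def save_mscan(path, mscan: RawMScan):
    with h5py.File(path, "w") as f:
        _save_mscan_group(f, mscan)


def load_mscan(path) -> RawMScan:
    try:
        with h5py.File(path, "r") as f:
            return _load_mscan_group(f)
    except (OSError, KeyError) as exc:
        raise SchemaError(f"cannot read M-scan container {path}: {exc}") from exc


def save_bscan(path, columns):
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["n_columns"] = len(columns)
        for i, col in enumerate(columns):
            _save_mscan_group(f.create_group(f"column_{i:03d}"), col)


def load_bscan(path):
    try:
        with h5py.File(path, "r") as f:
            n = int(f.attrs["n_columns"])
            return [_load_mscan_group(f[f"column_{i:03d}"]) for i in range(n)]
    except (OSError, KeyError) as exc:
        raise SchemaError(f"cannot read B-scan container {path}: {exc}") from exc


def save_cohort(path, plan: CohortPlan):
    """Simulate and stream a full cohort to one HDF5 file (one region at a
    time; memory stays at one B-scan)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["region_ids"] = json.dumps([s.region_id for s in plan.regions])
        for spec, columns in plan.iter_regions():
            g = f.create_group(spec.region_id)
            g.attrs["label"] = spec.label
            g.attrs["n_columns"] = len(columns)
            for i, col in enumerate(columns):
                _save_mscan_group(g.create_group(f"column_{i:03d}"), col)


def save_bscan_channels(path, bscan: BScanChannels):
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["band"] = bscan.band
        f.create_dataset("oct", data=bscan.oct)
        f.create_dataset("srs_amp", data=bscan.srs_amp)
        f.create_dataset("srs_phase", data=bscan.srs_phase)
        f.create_dataset("valid", data=bscan.valid)
        f.create_dataset("depth_um", data=bscan.depth_axis_um)
        if bscan.surface_um is not None:
            f.create_dataset("surface_um", data=bscan.surface_um)


def load_bscan_channels(path) -> BScanChannels:
    try:
        with h5py.File(path, "r") as f:
            if int(f.attrs.get("schema_version", -1)) != SCHEMA_VERSION:
                raise SchemaError("unsupported schema version")
            return BScanChannels(
                oct=f["oct"][...],
                srs_amp=f["srs_amp"][...],
                srs_phase=f["srs_phase"][...],
                valid=f["valid"][...].astype(bool),
                depth_axis_um=f["depth_um"][...],
                band=str(f.attrs["band"]),
                surface_um=f["surface_um"][...] if "surface_um" in f else None,
            )
    except (OSError, KeyError) as exc:
        raise SchemaError(f"cannot read channel container {path}: {exc}") from exc


def write_metrics_csv(path, metrics_df):
    """Metrics table as CSV; units are encoded in the column names
    (``*_mm`` = mm^-1 decay coefficients, ratios dimensionless)."""
    metrics_df.to_csv(path, index=False)


def read_metrics_csv(path):
    import pandas as pd

    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated end-to-end run configuration (YAML-serializable).

    Unknown keys in a YAML file are rejected.  ``scale`` picks the
    acquisition preset ('test': 1024 pixels x 512 frames x 20 A-scans;
    'full': 2048 x 2048 x 200).
    """

    n_tumor: int = 34
    n_healthy: int = 20
    seed: int = 0
    scale: str = "test"
    compute_spectral: bool = True
    laser: dict = field(default_factory=dict)
    acquisition: dict = field(default_factory=dict)
    tumor_population: dict = field(default_factory=dict)
    healthy_population: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scale not in ("test", "full"):
            raise ValueError("scale must be 'test' or 'full'")
        if self.n_tumor < 0 or self.n_healthy < 0:
            raise ValueError("region counts must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def cohort_config(self) -> CohortConfig:
        acq_cls = (
            AcquisitionConfig.test_scale if self.scale == "test" else AcquisitionConfig.full_scale
        )
        return CohortConfig(
            laser=LaserConfig(**self.laser),
            acquisition=acq_cls(**self.acquisition),
            tumor_population=PhantomPopulation.tumor(**self.tumor_population),
            healthy_population=PhantomPopulation.healthy(**self.healthy_population),
        )

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(compute_spectral=self.compute_spectral, **self.analysis)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    outputs: dict
    wall_clock_s: float
    n_regions: int
    defaults_used: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_full(config: RunConfig, out_dir) -> RunManifest:
    """Simulate a cohort, analyze it, and write metrics + discrimination
    report + manifest under ``out_dir``.  Idempotent for a fixed config."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plan = make_cohort(config.n_tumor, config.n_healthy, config.cohort_config(), seed=config.seed)
    outputs = {}
    manifest_df = plan.manifest()
    truth_path = out / "cohort_truth.csv"
    manifest_df.to_csv(truth_path, index=False)
    outputs["cohort_truth"] = str(truth_path)

    if len(plan) > 0:
        metrics = analyze_cohort(plan, config.analysis_config())
        metrics_path = out / "metrics.csv"
        write_metrics_csv(metrics_path, metrics)
        outputs["metrics"] = str(metrics_path)
        labels = set(metrics["label"])
        if {"tumor", "healthy"} <= labels and (metrics["label"] == "tumor").sum() >= 2 and (
            metrics["label"] == "healthy"
        ).sum() >= 2:
            report = discrimination_report(metrics)
            report_path = out / "discrimination.json"
            report_path.write_text(json.dumps(report, indent=2))
            outputs["discrimination"] = str(report_path)
    else:
        import pandas as pd

        from .pipeline import METRIC_COLUMNS

        metrics_path = out / "metrics.csv"
        write_metrics_csv(metrics_path, pd.DataFrame(columns=METRIC_COLUMNS))
        outputs["metrics"] = str(metrics_path)

    acfg = config.analysis_config()
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        outputs=outputs,
        wall_clock_s=time.time() - t0,
        n_regions=len(plan),
        defaults_used={
            "butterworth_order": 4,
            "fit_start_offset_um": acfg.start_offset_um,
            "fit_extent_um": acfg.fit_extent_um,
            "modulation_waveform": config.acquisition.get("modulation_waveform", "sine"),
        },
    )
    manifest.to_json(out / "manifest.json")
    return manifest
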