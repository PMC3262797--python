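"""Pipeline orchestration: configuration, staged execution, manifest.

``run_pipeline`` runs simulate -> decompose -> filter -> invert -> fit on
a synthetic wave-field for the configured medium, then simulates a
cohort and computes the statistics report.  Every intermediate artifact
is persisted with a SHA-256 checksum into a JSON manifest, so identical
(config, seed) pairs produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from brainmre import io as mre_io
from brainmre.cohort_stats import statistics_report
from brainmre.inversion import InversionConfig, helmholtz_invert, roi_average
from brainmre.springpot import DEFAULT_ETA, fit_springpot
from brainmre.synthetic import (
    DEFAULT_DIRECTIONS,
    AcquisitionSpec,
    CohortSpec,
    MediumSpec,
    simulate_cohort,
    simulate_wavefield,
)
from brainmre.wave_processing import (
    BandpassSpec,
    bandpass_filter,
    temporal_fourier_decompose,
)

_pkg_version = "0.1.0"


@dataclass(frozen=True)
class NoiseConfig:
    """Displacement-noise and contaminant settings for the simulator."""

    noise_sd_fraction: float = 0.02  # fraction of vibration amplitude
    compression_amplitude_fraction: float = 0.2
    compression_spatial_frequency: float = 0.05  # cycles/m

    def __post_init__(self) -> None:
        if self.noise_sd_fraction < 0 or self.compression_amplitude_fraction < 0:
            raise ValueError("noise fractions must be non-negative")


@dataclass(frozen=True)
class FilterConfig:
    """k-space filtering numerics used by the pipeline.

    ``edge_apodization`` (pixels) is on by default: it suppresses the
    mask-edge spectral spillover that otherwise biases the algebraic
    inversion; the companion ``PipelineConfig`` default erodes the
    inversion mask past the apodization ramp.
    """

    taper: float = 0.0  # cycles/m of raised-cosine band-edge rolloff
    edge_apodization: int = 16  # pixels of mask-edge ramp

    def __post_init__(self) -> None:
        if self.taper < 0 or self.edge_apodization < 0:
            raise ValueError("filter parameters must be non-negative")


@dataclass(frozen=True)
class FitConfig:
    eta: float = DEFAULT_ETA

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise ValueError("eta must be positive")


@dataclass(frozen=True)
class StatsConfig:
    roc_direction: str = "lower"

    def __post_init__(self) -> None:
        if self.roc_direction not in ("lower", "higher"):
            raise ValueError("roc_direction must be 'lower' or 'higher'")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for the full pipeline.

    All defaults follow the in-vivo protocol: four drive frequencies over
    an 80 ms period sampled 64 times, 128x128 grid at 1.5 mm, rho = 1000
    kg/m^3, eta = 3.7 Pa.s, and the per-frequency bandpass thresholds.
    The default medium is the healthy-control group (mu = 3278 Pa,
    alpha = 0.2934).
    """

    medium: MediumSpec = field(default_factory=lambda: MediumSpec(mu=3278.0, alpha=0.2934))
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    directions: tuple[tuple[float, float], ...] = DEFAULT_DIRECTIONS
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    bandpass: BandpassSpec = field(default_factory=BandpassSpec)
    filter: FilterConfig = field(default_factory=FilterConfig)
    inversion: InversionConfig = field(
        default_factory=lambda: InversionConfig(laplacian_tolerance=0.3, mask_erosion=18)
    )
    fit: FitConfig = field(default_factory=FitConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    output_dir: str = "mre_run"


_BLOCK_TYPES: dict[str, type] = {
    "medium": MediumSpec,
    "acquisition": AcquisitionSpec,
    "noise": NoiseConfig,
    "filter": FilterConfig,
    "inversion": InversionConfig,
    "fit": FitConfig,
    "stats": StatsConfig,
}


def config_from_dict(raw: Mapping[str, Any]) -> PipelineConfig:
    """Build a validated PipelineConfig from a plain mapping.

    Unknown keys — at the top level or inside any block — are rejected,
    so a typo in a config file fails before any stage runs.
    """
    known_top = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _BLOCK_TYPES:
            cls = _BLOCK_TYPES[key]
            valid = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - valid
            if bad:
                raise ValueError(f"unknown key(s) in '{key}' block: {sorted(bad)}")
            if key == "acquisition":
                value = dict(value)
                if "grid_shape" in value:
                    value["grid_shape"] = tuple(value["grid_shape"])
                if "frequencies" in value:
                    value["frequencies"] = tuple(value["frequencies"])
            kwargs[key] = cls(**value)
        elif key == "bandpass":
            kwargs[key] = BandpassSpec(bands={float(f): tuple(b) for f, b in value.items()})
        elif key == "directions":
            kwargs[key] = tuple(tuple(float(c) for c in d) for d in value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    def default(o: Any):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, Mapping):
            return dict(o)
        raise TypeError(type(o).__name__)

    payload = dataclasses.asdict(config)
    payload.pop("output_dir", None)  # hash covers the science, not the path
    blob = json.dumps(payload, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def analyze_wavefield(
    series,
    frequencies=None,
    bandpass: BandpassSpec | None = None,
    filter_config: FilterConfig | None = None,
    inversion_config: InversionConfig | None = None,
    eta: float = DEFAULT_ETA,
):
    """In-memory decompose -> filter -> invert -> average -> fit chain.

    Returns ``(fit, samples)``: the springpot fit and the per-frequency
    ROI-averaged dispersion samples.  With fewer than two frequencies no
    dispersion fit is possible and ``fit`` is None.  Uses the pipeline's
    default processing choices (edge apodization, deep mask erosion)
    unless overridden.
    """
    from brainmre.springpot import fit_springpot

    if frequencies is None:
        frequencies = series.frequencies
    if bandpass is None:
        bandpass = BandpassSpec()
    if filter_config is None:
        filter_config = FilterConfig()
    if inversion_config is None:
        inversion_config = InversionConfig(laplacian_tolerance=0.3, mask_erosion=18)
    fields = temporal_fourier_decompose(series, frequencies)
    maps = [
        helmholtz_invert(
            bandpass_filter(
                f,
                bandpass,
                taper=filter_config.taper,
                edge_apodization=filter_config.edge_apodization,
            ),
            inversion_config,
        )
        for f in fields
    ]
    samples = roi_average(maps)
    fit = fit_springpot(samples, eta=eta) if len(samples) >= 2 else None
    return fit, samples


def run_pipeline(config: PipelineConfig | None = None) -> dict[str, Any]:
    """Execute all stages and return the run manifest (also written to disk).

    Stage order: simulate -> decompose -> filter -> invert -> fit ->
    stats.  A stage failure raises with the failing stage named; partial
    outputs written before the failure are left in the output directory
    for inspection.
    """
    if config is None:
        config = PipelineConfig()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": _pkg_version,
        "stages": {},
    }

    def record(stage: str, files: list[Path], **extra: Any) -> None:
        manifest["stages"][stage] = {
            "outputs": {f.name: _sha256(f) for f in files},
            **extra,
        }

    stage = "simulate"
    try:
        acq = config.acquisition
        series = simulate_wavefield(
            config.medium,
            acq,
            directions=config.directions,
            noise_sd=config.noise.noise_sd_fraction * acq.vibration_amplitude,
            seed=config.seed,
            compression_amplitude_fraction=config.noise.compression_amplitude_fraction,
            compression_spatial_frequency=config.noise.compression_spatial_frequency,
        )
        wf_path = mre_io.write_wavefield(series, out / "wavefield.nii")
        record(stage, [wf_path], shape=list(series.data.shape))

        stage = "decompose"
        fields = temporal_fourier_decompose(series, acq.frequencies)
        files = []
        for fld in fields:
            files.extend(mre_io.write_complex_field(fld, out / f"wave_{fld.frequency:g}hz"))
        record(stage, files, frequencies=list(acq.frequencies))

        stage = "filter"
        filtered = [
            bandpass_filter(
                fld,
                config.bandpass,
                taper=config.filter.taper,
                edge_apodization=config.filter.edge_apodization,
            )
            for fld in fields
        ]
        files = []
        for fld in filtered:
            files.extend(mre_io.write_complex_field(fld, out / f"filt_{fld.frequency:g}hz"))
        record(stage, files)

        stage = "invert"
        maps = [helmholtz_invert(fld, config.inversion) for fld in filtered]
        for m in maps:
            mre_io.write_modulus_map(m, out / f"gstar_{m.frequency:g}hz", series.spacing)
        samples = roi_average(maps)
        disp_path = mre_io.write_dispersion(samples, out / "dispersion.csv")
        record(
            stage,
            [disp_path],
            valid_fraction=[float(m.valid.mean()) for m in maps],
        )

        stage = "fit"
        fit = fit_springpot(samples, eta=config.fit.eta)
        fit_path = mre_io.write_fit(fit, out / "springpot_fit.csv")
        record(stage, [fit_path], mu_pa=fit.mu, alpha=fit.alpha, residual=fit.residual)

        stage = "stats"
        cohort = simulate_cohort(CohortSpec(seed=config.seed))
        cohort_path = mre_io.write_cohort(cohort, out / "cohort.csv")
        report = statistics_report(cohort)
        report_path = out / "statistics.csv"
        report.to_csv(report_path, index=False)
        record(stage, [cohort_path, report_path])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
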