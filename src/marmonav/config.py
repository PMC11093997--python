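"""Analysis configuration.

Every threshold used anywhere in the pipeline lives here, with defaults set
to the values used throughout the analyses (movement thresholds, shuffle
counts, smoothing widths, frequency bands).  Configs are plain dataclasses
so they serialize to/from YAML mappings without surprises.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class MovementConfig:
    """Thresholds for significant-movement detection.

    Head events require angular head velocity (AHV) above
    ``head_velocity_deg_s`` and integrated amplitude above
    ``head_amplitude_deg``; body translations require translation speed (TS)
    above ``body_speed_cm_s`` and path length above ``body_amplitude_cm``.
    Events whose peak velocity exceeds the artifact ceilings are recorded as
    artifacts and excluded.
    """

    head_velocity_deg_s: float = 200.0
    head_amplitude_deg: float = 10.0
    head_artifact_deg_s: float = 2000.0
    body_speed_cm_s: float = 16.0
    body_amplitude_cm: float = 30.0
    body_artifact_cm_s: float = 300.0
    position_lowpass_hz: float = 4.0
    # epoch edges extend to the nearest local minimum below this fraction of
    # the detection threshold
    edge_fraction: float = 0.5


@dataclass
class UnitConfig:
    min_spikes: int = 100
    duplicate_overlap_frac: float = 0.5
    # burst-index ISI windows, ms
    isi_range_ms: tuple[float, float] = (2.0, 40.0)
    burst_range_ms: tuple[float, float] = (2.0, 20.0)
    isi_bin_ms: float = 1.0
    # "integrated" uses the exact per-bin mass of the exponential ISI density;
    # "center" evaluates the density at bin centers
    predicted_isi_mode: str = "integrated"
    kmeans_n_init: int = 10


@dataclass
class TuningConfig:
    n_perm: int = 5000
    cell_percentile: float = 95.0
    bin_alpha: float = 0.05  # Bonferroni-corrected by the number of bins
    min_visits: int = 3      # bins need strictly more visits than this
    min_occupancy_s: float = 0.2
    min_shift_s: float = 1.0
    speed_smooth_sd_ms: float = 250.0
    speed_threshold: float = 0.3
    speed_n_shift: int = 1000
    speed_percentile: float = 95.0


@dataclass
class EncodingConfig:
    frame_s: float = 1.0 / 60.0
    n_shuffle: int = 100
    alpha: float = 0.05
    n_splines: int = 8
    fourier_order: int = 3
    penalty: float = 1.0
    ed_formula: str = "conventional"  # or "printed"
    n_folds: int = 5
    min_shift_s: float = 1.0


@dataclass
class DecodingConfig:
    window_s: float = 0.2
    low_ahv_deg_s: float = 200.0
    min_trials_per_class: int = 50
    n_classes: int = 4
    n_repeats: int = 10
    n_folds: int = 5
    svm_c: float = 1.0
    max_ensemble: int = 20
    stop_tol: float = 0.005
    stop_patience: int = 3
    n_random_combos: int = 100


@dataclass
class LfpConfig:
    fs_hz: float = 1000.0
    antialias_hz: float = 250.0
    highpass_hz: float = 1.0
    artifact_band_hz: tuple[float, float] = (100.0, 249.0)
    artifact_boxcar_s: float = 0.2
    artifact_z: float = 4.0
    artifact_pad_s: float = 0.1
    theta_band_hz: tuple[float, float] = (4.0, 10.0)
    tfr_fmin_hz: float = 1.0
    tfr_fmax_hz: float = 30.0
    tfr_fstep_hz: float = 1.0
    tfr_n_cycles: float = 7.0
    tfr_smooth_s: float = 0.025
    rayleigh_window_s: float = 0.4
    rayleigh_alpha: float = 0.01
    mod_window_s: float = 0.4
    mod_n_bins: int = 8
    mod_n_shuffle: int = 1000
    mod_percentile: float = 97.5


@dataclass
class AnalysisConfig:
    movement: MovementConfig = field(default_factory=MovementConfig)
    units: UnitConfig = field(default_factory=UnitConfig)
    tuning: TuningConfig = field(default_factory=TuningConfig)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    lfp: LfpConfig = field(default_factory=LfpConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.tuning.n_perm <= 0 or self.decoding.n_repeats <= 0:
            raise ValueError("counts must be positive")
        nyq = self.lfp.fs_hz / 2.0
        for lo, hi in (self.lfp.theta_band_hz, self.lfp.artifact_band_hz):
            if not (0 < lo < hi < nyq):
                raise ValueError(f"band ({lo}, {hi}) outside (0, Nyquist)")
        if self.lfp.tfr_fmax_hz >= nyq:
            raise ValueError("TFR ceiling above Nyquist")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = {}
        sub = {
            "movement": MovementConfig, "units": UnitConfig,
            "tuning": TuningConfig, "encoding": EncodingConfig,
            "decoding": DecodingConfig, "lfp": LfpConfig,
        }
        for key, klass in sub.items():
            if key in d:
                payload = dict(d[key])
                for name, val in payload.items():
                    if isinstance(val, list):
                        payload[name] = tuple(val)
                kwargs[key] = klass(**payload)
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
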