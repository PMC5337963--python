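"""Analysis configuration: one structured object, YAML on disk.

Defaults equal the study-design values the models assume (filter cutoffs,
window lengths, lag counts, permutation counts); everything else is a
documented package default. All random seeds are explicit so a
config file pins an entire run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class SdtConfig:
    sigma: float = 2.723          # internal noise SD (inverse probit slope)
    criterion: float = 0.0
    mu_range: tuple[float, float] = (0.0, 6.0)
    n_trials: int = 1_000_000
    n_bins: int = 100
    seed: int = 0


@dataclass
class MotionEnergyConfig:
    sigma_g: float = 0.05         # Gaussian envelope SD (deg)
    sigma_c: float = 0.35         # carrier scale (deg)
    k: float = 60.0               # temporal envelope rate (1/s)
    n_fast: int = 3               # stages of the early-peaking filter
    n_slow: int = 5               # stages of the late-peaking filter
    spatial_halfwidth: float = 0.7    # deg; spatial support [-hw, hw]
    temporal_support: float = 0.35    # s
    px_per_deg: float = 10.0
    frame_rate: float = 60.0
    ramp_skip: float = 0.15       # s of filter ramp-up dropped per interval


@dataclass
class PupilConfig:
    blink_pad: float = 0.15       # s, padding around blink intervals
    velocity_nsd: float = 10.0    # robust-SD threshold for velocity blinks
    deconv_window: float = 6.0    # s
    deconv_rate: float = 10.0     # Hz FIR tap resolution
    band_low: float = 0.01        # Hz
    band_high: float = 10.0       # Hz
    filter_order: int = 2
    out_rate: float = 100.0       # Hz
    baseline_window: float = 0.5  # s before reference onset
    response_window: float = 0.25  # s before feedback


@dataclass
class HistoryConfig:
    n_lags: int = 7
    n_basis: int = 3
    basis_taus: tuple[float, ...] = (1.0, 3.0, 9.0)  # lags
    max_iter: int = 2000
    tol: float = 1e-6
    n_restarts: int = 5
    n_perm: int = 1000
    n_boot: int = 500
    ci_level: float = 0.68
    seed: int = 0


@dataclass
class StatsConfig:
    n_perm: int = 10_000
    cluster_alpha: float = 0.05
    seed: int = 0


@dataclass
class SyntheticConfig:
    block_len: int = 50
    full_len: int = 53
    n_blocks: int = 10
    n_sessions: int = 5
    seed: int = 0


@dataclass
class AnalysisConfig:
    """Top-level configuration grouping per-stage parameter sets."""

    sdt: SdtConfig = field(default_factory=SdtConfig)
    motion_energy: MotionEnergyConfig = field(default_factory=MotionEnergyConfig)
    pupil: PupilConfig = field(default_factory=PupilConfig)
    history: HistoryConfig = field(default_factory=HistoryConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            sub = d.get(f.name, {})
            sub_cls = f.default_factory
            known = {sf.name for sf in dataclasses.fields(sub_cls)}
            unknown = set(sub) - known
            if unknown:
                raise KeyError(
                    f"unknown key(s) in section {f.name!r}: {sorted(unknown)}")
            coerced = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in sub.items()
            }
            kwargs[f.name] = sub_cls(**coerced)
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
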