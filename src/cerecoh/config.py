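"""Analysis configuration: every fixed constant the pipeline uses, in one place.

Serialized as a flat ``key = value`` text file (TOML subset) so a run's
parameters travel with its outputs.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path

__all__ = ["AnalysisConfig", "load_config", "save_config"]


@dataclass
class AnalysisConfig:
    # Behavioral-state segmentation
    theta_band: tuple[float, float] = (5.0, 10.0)   # Hz
    ratio_cap: float = 45.0                          # Hz; theta-ratio denominator cap
    speed_z_threshold: float = 0.0                   # locomotion: z-scored speed > 0
    min_bout_duration: float = 1.0                   # s; drop shorter locomotion runs
    gap_merge: float = 0.5                           # s; merge subthreshold gaps
    spindle_band: tuple[float, float] = (10.0, 15.0)  # Hz
    spindle_z: float = 2.5                           # envelope threshold (SD over mean)
    spindle_min_duration: float = 0.4                # s
    spindle_pad: float = 0.5                         # s excluded around each spindle

    # Multitaper spectral estimation
    mt_window: float = 2.0                           # s analysis window
    mt_bandwidth: float = 1.0                        # Hz half-bandwidth W
    alpha: float = 0.05

    # Directed coherence (bivariate AR)
    ar_fs: float = 200.0                             # Hz; decimation target before AR fit
    ar_order_max: int = 20
    n_surrogates: int = 200

    # Peri-stimulus unit analysis
    psth_bin: float = 0.1                            # s
    psth_pre: float = 2.0                            # s before train onset
    psth_post: float = 5.0                           # s after train onset
    kernel_sigma: float = 0.1                        # s Gaussian smoothing kernel SD
    n_permutations: int = 10000
    n_bootstrap: int = 1000
    min_consecutive_bins: int = 2

    # Correlograms
    correlogram_bin: float = 0.04                    # s
    correlogram_window: float = 2.0                  # s pre/post-stimulation windows
    correlogram_lag: float = 1.0                     # s; half-extent of the lag axis
    n_shuffle_pairings: int = 100

    # Evoked field potentials
    blank_half_width: float = 0.001                  # s excluded around each pulse
    evoked_baseline: tuple[float, float] = (-0.055, -0.007)  # s rel. reference pulse
    onset_k_sd: float = 2.0
    onset_n_consecutive: int = 5
    p2t_window: tuple[float, float] = (0.0, 0.1)     # s peak-to-trough search

    # Cluster quality gate and cell-type classification
    iso_dist_min: float = 15.0
    l_ratio_max: float = 0.35
    pyramidal_width_min: float = 0.3e-3              # s trough-to-peak
    pyramidal_rate_max: float = 10.0                 # Hz

    # Parsing / reproducibility
    strict: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.theta_band
        if not (0 < lo < hi <= self.ratio_cap):
            raise ValueError("theta_band must lie within (0, ratio_cap]")
        for name in ("psth_bin", "psth_pre", "psth_post", "kernel_sigma",
                     "mt_window", "mt_bandwidth", "correlogram_bin",
                     "correlogram_window", "correlogram_lag"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @property
    def n_tapers(self) -> int:
        """K = 2·NW − 1 with NW = window × bandwidth."""
        return int(2 * self.mt_window * self.mt_bandwidth - 1)

    def replace(self, **kw) -> "AnalysisConfig":
        return dataclasses.replace(self, **kw)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    lines = []
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, tuple):
            lines.append(f"{f.name} = [{', '.join(repr(x) for x in v)}]")
        elif isinstance(v, bool):
            lines.append(f"{f.name} = {'true' if v else 'false'}")
        elif isinstance(v, str):
            lines.append(f'{f.name} = "{v}"')
        else:
            lines.append(f"{f.name} = {v!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> AnalysisConfig:
    raw = tomllib.loads(Path(path).read_text())
    kw = {}
    for f in dataclasses.fields(AnalysisConfig):
        if f.name in raw:
            v = raw[f.name]
            kw[f.name] = tuple(v) if isinstance(v, list) else v
    return AnalysisConfig(**kw)
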