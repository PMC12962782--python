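"""Hierarchical analysis configuration.

A single nested mapping, keyed by module, holds every tunable the
pipeline exposes.  Defaults reproduce the analysis parameters of the
study design (bin widths, windows, thresholds, filter settings); unknown
keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

__all__ = ["DEFAULTS", "AnalysisConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid parameter values."""


#: Full default configuration.  All times are seconds.
DEFAULTS: dict[str, dict[str, Any]] = {
    "io": {
        "time_column": "time",
        "f465_column": "f465",
        "f405_column": "f405",
    },
    "acg": {
        "bin_width": 0.0005,          # 0.5 ms resolution
        "max_lag": 0.5,
        "spike_cap": 50_000,          # memory guard for very active units
        "smooth_window": 0.0025,      # 2.5 ms (five-point) moving average
        "burst_win": (0.0, 0.025),
        "base_win": (0.180, 0.200),
        "theta_search_win": (0.100, 0.200),
        "theta_peak_halfwidth": 0.025,
        "theta_flank_wins": ((0.050, 0.075), (0.225, 0.250)),
        "refractory_smooth": 0.010,   # 10 ms moving average
        "reg_refractory_min": 0.040,  # classification thresholds (not from
        "sb_burst_index_min": 0.4,    # the study; exposed as configuration)
    },
    "responses": {
        "peth_bin_width": 0.010,
        "search_win": 0.5,
        "baseline_win": 0.5,
        "alpha": 0.01,
        "optotag_pulse_dur": 0.2,
        "optotag_latency_max": 0.010,
        "optotag_max_rate": 0.5,
        "optotag_baseline_win": 1.0,
        "optotag_bin_width": 0.001,
        "n_clusters": 4,
        "n_components": 3,
        "linkage": "ward",
    },
    "photometry": {
        "lowpass_hz": 20.0,
        "highpass_hz": 0.2,
        "filter_order": 4,
        "baseline_win": 2.0,
        "response_win": 1.0,
        "trial_window": (-2.0, 3.0),
        "trialwise_resp_win": (0.0, 0.5),
        "trialwise_base_win": (-0.5, 0.0),
        "trialwise_alpha": 0.05,
    },
    "coupling": {
        "max_lag": 10.0,
        "exclude": 0.020,            # common-mode rejection window (±20 ms)
        "center": True,
        "te_n_bins": 200,
        "te_history_len": 1,
        "te_downsample_hz": 20.0,
        "te_base": 2.0,              # bits
        "peak_threshold_sd": 2.0,
        "peak_min_separation": 1.0,
        "pta_window": (-2.0, 4.0),
    },
    "invitro": {
        "spike_threshold_mv": -20.0,
        "min_isi": 0.001,
        "acg_bin_width": 0.0005,
        "acg_max_lag": 0.5,
        "acg_smooth_window": 0.005,  # 5 ms moving average for evoked ACGs
    },
    "anatomy": {
        "density_mode": "mean_probability",
        "density_threshold": 0.5,
    },
    "synthetic": {
        "seed": 0,
    },
}


def _check_keys(defaults: Any, override: Any, path: str) -> None:
    if isinstance(defaults, dict):
        if not isinstance(override, dict):
            raise ConfigError(f"{path or 'config'}: expected a mapping")
        for key, value in override.items():
            if key not in defaults:
                raise ConfigError(f"unknown config key: {path + key}")
            _check_keys(defaults[key], value, f"{path}{key}.")


def _merge(defaults: dict, override: dict) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        if isinstance(value, dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


class AnalysisConfig:
    """Validated hierarchical configuration with study defaults.

    >>> cfg = AnalysisConfig({"acg": {"max_lag": 0.3}})
    >>> cfg["acg"]["max_lag"]
    0.3
    """

    def __init__(self, overrides: dict[str, Any] | None = None) -> None:
        overrides = overrides or {}
        _check_keys(DEFAULTS, overrides, "")
        self._data = _merge(DEFAULTS, overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(data)

    def __getitem__(self, module: str) -> dict[str, Any]:
        return self._data[module]

    def to_dict(self) -> dict[str, Any]:
        return copy.deepcopy(self._data)

    def hash(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        payload = json.dumps(self._data, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
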