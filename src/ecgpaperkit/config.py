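"""Pipeline configuration.

Every stage of the digitizer reads its parameters from a :class:`ToolConfig`.
The defaults are the published operating point of the method: Canny
thresholds 100/200 on the Sobel magnitude scale, a Hough accumulator with
180 angular bins and a 100-vote support floor, a 0.85 cosine gate for
same-orientation line suppression, red-grid hue bands [0,10] and [156,180]
on the half-degree (0-180) hue scale, 4x4 thresholding blocks with a 0.8
gamma stretch, and a second-order 100 Hz Butterworth high-pass for
calibration-pulse recognition.

Overrides come from a JSON file (nested objects or dotted keys) and are
tracked so the effective configuration can be dumped with provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = ["ConfigError", "ToolConfig", "load_config", "DEFAULTS"]


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range values."""


#: Default value and validator for every recognised dotted key.
_SPEC: dict[str, tuple[Any, Any]] = {
    "canny.low": (100.0, lambda v: 0 < v),
    "canny.high": (200.0, lambda v: 0 < v),
    "hough.theta_bins": (180, lambda v: int(v) >= 2),
    "hough.min_support": (100, lambda v: int(v) >= 1),
    "orientation.cosine_threshold": (0.85, lambda v: 0 <= v <= 1),
    "rectify.aspect_ratio": (None, lambda v: v is None or v > 0),
    "hsv.bands": ("red", lambda v: _valid_bands(v)),
    "hsv.min_saturation": (30, lambda v: 0 <= v <= 255),
    "gamma.value": (0.8, lambda v: v > 0),
    "gamma.gain": (1.0, lambda v: v > 0),
    "blocks.rows": (4, lambda v: int(v) >= 1),
    "blocks.cols": (4, lambda v: int(v) >= 1),
    "blocks.min_contrast": (40.0, lambda v: v >= 0),
    "butterworth.order": (2, lambda v: int(v) >= 1),
    "butterworth.cutoff_hz": (100.0, lambda v: v > 0),
    "square_wave.threshold_mV": (0.2, lambda v: v > 0),
    "square_wave.search_factor": (2.0, lambda v: v >= 1),
}

#: Named grid-color hue bands on the [0, 180) circular hue scale.
NAMED_BANDS: dict[str, list[tuple[float, float]]] = {
    "red": [(0.0, 10.0), (156.0, 180.0)],
    "blue": [(100.0, 124.0)],
}


def _valid_bands(v: Any) -> bool:
    if isinstance(v, str):
        return v in NAMED_BANDS
    try:
        return all(
            len(pair) == 2 and 0 <= pair[0] <= 180 and 0 <= pair[1] <= 180
            for pair in v
        )
    except TypeError:
        return False


DEFAULTS: dict[str, Any] = {k: v for k, (v, _) in _SPEC.items()}


@dataclass
class ToolConfig:
    """Validated, fully-defaulted parameter set with override provenance."""

    values: dict[str, Any] = field(default_factory=lambda: dict(DEFAULTS))
    overrides: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def hue_bands(self) -> list[tuple[float, float]]:
        bands = self.values["hsv.bands"]
        if isinstance(bands, str):
            return NAMED_BANDS[bands]
        return [tuple(map(float, b)) for b in bands]

    def provenance(self) -> str:
        """Printable account of which keys deviate from the defaults."""
        lines = []
        for key in sorted(self.values):
            mark = "  (override)" if key in self.overrides else ""
            lines.append(f"{key} = {self.values[key]!r}{mark}")
        return "\n".join(lines)

    def dump(self) -> str:
        """Deterministic JSON dump of the effective configuration."""
        return json.dumps(self.values, sort_keys=True, default=str)


def _flatten(obj: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for key, val in obj.items():
        name = f"{prefix}{key}"
        if isinstance(val, Mapping) and "." not in key:
            flat.update(_flatten(val, prefix=f"{name}."))
        else:
            flat[name] = val
    return flat


def load_config(path: str | None = None, overrides: Mapping[str, Any] | None = None) -> ToolConfig:
    """Build a :class:`ToolConfig` from defaults, an optional JSON file and
    optional in-process overrides (dotted keys), in that precedence order.

    Raises
    ------
    ConfigError
        If a key is unknown or a value fails its range check. The offending
        key is named in the message.
    """
    merged: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            merged.update(_flatten(json.load(fh)))
    if overrides:
        merged.update(_flatten(dict(overrides)))

    cfg = ToolConfig()
    for key, val in merged.items():
        if key not in _SPEC:
            raise ConfigError(f"unknown configuration key: {key!r}")
        _, check = _SPEC[key]
        if not check(val):
            raise ConfigError(f"out-of-range value for {key!r}: {val!r}")
        cfg.values[key] = val
        cfg.overrides[key] = val
    return cfg
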