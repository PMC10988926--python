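"""Field-dependent superficial-scalp conductivity and tissue conductivities.

The adaptive mechanism of the model: the outer (superficial) scalp layer's
conductivity at the 1 kHz representative frequency rises piecewise-linearly
with the local electric-field magnitude E:

    sigma_SS(E) = A                for 0 <= E < B
                = C * E - D        for B <= E < E_sat
                = sigma_ss_max     for E >= E_sat

with subject-invariant constants A (floor conductivity), B (field
threshold), C (slope) and D (offset), and a subject-specific saturation
conductivity ``sigma_ss_max``.  Continuity of the middle branch at the knee
fixes the saturation field:

    E_sat = (sigma_ss_max + D) / C

e.g. sigma_ss_max = 0.16 S/m saturates at ~428 V/m.  Note the function as
printed has a small upward jump at E = B (A = 0.005 vs C*B - D ~= 0.00617
S/m); it is implemented verbatim, with an optional linear blend (default
off) available for solver robustness.

The deep scalp layer has a fixed, subject-specific conductivity sigma_DS
(typically 4.5e-4 .. 8e-3 S/m); all remaining tissues carry fixed,
subject-invariant 1 kHz conductivities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "TransferFunctionParams",
    "ScalpParams",
    "TissueTable",
    "DEFAULT_TISSUES",
    "DEFAULT_SIGMA_DS_BOUNDS",
    "sigma_ss",
    "saturation_field",
    "load_config",
]

# default subject-specific deep-scalp conductivity range, S/m (soft bounds)
DEFAULT_SIGMA_DS_BOUNDS = (4.5e-4, 8e-3)

# fixed 1 kHz tissue conductivities, S/m
DEFAULT_TISSUES: Mapping[str, float] = MappingProxyType(
    {
        "skull": 0.01,
        "gray_matter": 0.276,
        "white_matter": 0.126,
        "csf": 0.85,
        "air": 1e-15,
        "gel": 0.018,
    }
)


@dataclass(frozen=True)
class TransferFunctionParams:
    """Constants (A, B, C, D) of the field-to-conductivity transfer function."""

    floor_conductivity: float = 5e-3  # A, S/m
    field_threshold: float = 85.0  # B, V/m
    slope: float = 4.49e-4  # C, S/m per V/m
    offset: float = 0.032  # D, S/m

    def __post_init__(self) -> None:
        for name in ("floor_conductivity", "field_threshold", "slope", "offset"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.slope * self.field_threshold - self.offset > 0:
            raise ValueError(
                "middle branch must be positive at the threshold "
                "(slope * field_threshold - offset > 0)"
            )


@dataclass(frozen=True)
class ScalpParams:
    """Subject-specific scalp parameters.

    ``deep_scalp_conductivity`` (sigma_DS) is fixed per subject;
    ``max_superficial_conductivity`` (sigma_ss_max) caps the adaptive layer;
    ``saturation_field`` is derived from the transfer function continuity.
    """

    deep_scalp_conductivity: float
    max_superficial_conductivity: float
    transfer_function: TransferFunctionParams = field(
        default_factory=TransferFunctionParams
    )
    sigma_ds_bounds: tuple[float, float] = DEFAULT_SIGMA_DS_BOUNDS

    def __post_init__(self) -> None:
        lo, hi = self.sigma_ds_bounds
        if not lo <= self.deep_scalp_conductivity <= hi:
            raise ValueError(
                f"deep_scalp_conductivity {self.deep_scalp_conductivity} "
                f"outside bounds [{lo}, {hi}]"
            )
        if not (
            self.max_superficial_conductivity
            >= self.transfer_function.floor_conductivity
        ):
            raise ValueError(
                "max_superficial_conductivity must be at least the floor "
                "conductivity"
            )

    @property
    def saturation_field(self) -> float:
        """Knee field E_sat; degenerates to the threshold B when the maximum
        conductivity sits at or below the middle branch's starting value
        (flat transfer function)."""
        tf = self.transfer_function
        branch_at_threshold = tf.slope * tf.field_threshold - tf.offset
        if self.max_superficial_conductivity <= branch_at_threshold:
            return tf.field_threshold
        return saturation_field(tf, self.max_superficial_conductivity)


@dataclass(frozen=True)
class TissueTable:
    """Tissue label -> fixed conductivity (S/m) map."""

    conductivities: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUES)
    )

    def __post_init__(self) -> None:
        for label, sigma in self.conductivities.items():
            if not sigma > 0:
                raise ValueError(f"conductivity for '{label}' must be positive")

    def __getitem__(self, label: str) -> float:
        return self.conductivities[label]

    def __contains__(self, label: str) -> bool:
        return label in self.conductivities


def saturation_field(
    params: TransferFunctionParams, max_conductivity: float
) -> float:
    """Field (V/m) at which the middle branch reaches ``max_conductivity``.

    E_sat = (sigma_ss_max + D) / C.  Errors if the requested maximum lies at
    or below the branch value at the threshold, where no knee would exist.
    """
    branch_at_threshold = params.slope * params.field_threshold - params.offset
    if max_conductivity <= branch_at_threshold:
        raise ValueError(
            f"max_conductivity {max_conductivity} must exceed the middle-branch "
            f"value at the threshold ({branch_at_threshold:.6g} S/m)"
        )
    return (max_conductivity + params.offset) / params.slope


def sigma_ss(
    electric_field,
    params: TransferFunctionParams,
    scalp: ScalpParams,
    blend_width: float = 0.0,
):
    """Superficial-scalp conductivity (S/m) at field magnitude(s) in V/m.

    ``blend_width`` > 0 linearly interpolates the floor and middle branches
    over [B - w/2, B + w/2] to remove the jump at the threshold; the default
    0 evaluates the piecewise function verbatim.
    """
    e = np.asarray(electric_field, dtype=float)
    if np.any(e < 0):
        raise ValueError("electric field magnitude must be nonnegative")
    e_sat = scalp.saturation_field
    middle = params.slope * e - params.offset
    out = np.where(
        e < params.field_threshold,
        params.floor_conductivity,
        np.where(e < e_sat, middle, scalp.max_superficial_conductivity),
    )
    if blend_width > 0:
        b, w = params.field_threshold, blend_width
        lo_val = params.floor_conductivity
        hi_val = params.slope * (b + w / 2) - params.offset
        in_blend = (e >= b - w / 2) & (e < b + w / 2)
        frac = (e - (b - w / 2)) / w
        out = np.where(in_blend, lo_val + frac * (hi_val - lo_val), out)
    return float(out) if np.isscalar(electric_field) else out


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML config with optional sections ``transfer_function``
    ({A, B, C, D}), ``tissues`` ({label: sigma}) and ``subject``
    ({sigma_ds, sigma_ss_max}); returns a dict with typed objects filled in
    from the defaults where a section is absent."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    raw = raw or {}
    tf_raw = raw.get("transfer_function", {})
    tf = TransferFunctionParams(
        floor_conductivity=tf_raw.get("A", 5e-3),
        field_threshold=tf_raw.get("B", 85.0),
        slope=tf_raw.get("C", 4.49e-4),
        offset=tf_raw.get("D", 0.032),
    )
    tissues = TissueTable(
        conductivities={**DEFAULT_TISSUES, **raw.get("tissues", {})}
    )
    out = {"transfer_function": tf, "tissues": tissues, "subject": None}
    if "subject" in raw:
        out["subject"] = ScalpParams(
            deep_scalp_conductivity=raw["subject"]["sigma_ds"],
            max_superficial_conductivity=raw["subject"]["sigma_ss_max"],
            transfer_function=tf,
        )
    return out
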