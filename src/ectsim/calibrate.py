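"""Subject-specific calibration against clinical impedance pairs.

Each ECT subject contributes two scalars: the device-reported static
impedance (low-intensity 2 uA test conditions) and the dynamic impedance
during the 900 mA stimulus.  Calibration searches for the deep-scalp
conductivity sigma_DS and the maximum superficial-scalp conductivity
sigma_ss_max such that the adaptive forward model reproduces both.

The search exploits two monotonicities of the forward model: static
impedance is strictly decreasing in sigma_DS (at 2 uA, scalp fields stay
below the transfer-function threshold, so sigma_ss_max barely matters), and
dynamic impedance is strictly decreasing in sigma_ss_max at fixed sigma_DS.
A nested bisection on the log-parameters is therefore robust and
deterministic: the outer loop brackets sigma_DS on the static residual and
the inner loop brackets sigma_ss_max on the dynamic residual; a second
round absorbs any residual cross-sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .conductivity import (
    DEFAULT_SIGMA_DS_BOUNDS,
    ScalpParams,
    TissueTable,
    TransferFunctionParams,
    saturation_field,
)
from .fem import (
    DYNAMIC_CURRENT,
    STATIC_CURRENT,
    BoundaryCondition,
    SolverSettings,
    solve_adaptive,
)
from .phantom import LabeledMesh

__all__ = [
    "ClinicalImpedancePair",
    "CalibrationBounds",
    "CalibrationResult",
    "UnreachableTargetError",
    "calibrate",
    "subject_report",
]


class UnreachableTargetError(ValueError):
    pass


@dataclass(frozen=True)
class ClinicalImpedancePair:
    """Per-subject (static, dynamic) impedance targets in ohms."""

    static_impedance: float
    dynamic_impedance: float

    def __post_init__(self) -> None:
        if not self.dynamic_impedance > 0:
            raise ValueError("dynamic impedance must be positive")
        if not self.static_impedance > self.dynamic_impedance:
            raise ValueError(
                "static impedance must exceed dynamic impedance "
                "(high-current conductivity increase lowers impedance)"
            )


@dataclass(frozen=True)
class CalibrationBounds:
    sigma_ds: tuple = DEFAULT_SIGMA_DS_BOUNDS
    sigma_ss_max: tuple = (0.02, 1.0)


@dataclass(frozen=True)
class CalibrationResult:
    sigma_ds: float
    sigma_ss_max: float
    static_impedance: float
    dynamic_impedance: float
    static_relative_error: float
    dynamic_relative_error: float
    evaluations: int
    converged: bool


# default forward-solve settings for calibration: tighter than the plain
# solver defaults because bisection must resolve impedance differences well
# below the 2% match tolerance
_CAL_SETTINGS = SolverSettings(
    linear_tolerance=1e-9, adaptive_tolerance=1e-6, max_adaptive_iterations=400
)


def calibrate(
    mesh: LabeledMesh,
    tissues: TissueTable,
    tf: TransferFunctionParams,
    target: ClinicalImpedancePair,
    bounds: CalibrationBounds | None = None,
    tolerance: float = 0.02,
    max_evals: int = 200,
    static_current: float = STATIC_CURRENT,
    dynamic_current: float = DYNAMIC_CURRENT,
    settings: SolverSettings | None = None,
    bracket_resolution: float = 1e-3,
) -> CalibrationResult:
    """Fit (sigma_DS, sigma_ss_max) to a clinical impedance pair.

    Bisection on each log-parameter proceeds until the matching impedance
    residual is far below ``tolerance`` or the bracket shrinks to
    ``bracket_resolution`` in log space.  Raises
    :class:`UnreachableTargetError` when a target lies outside the model's
    range over the given bounds; exhausting ``max_evals`` returns a result
    flagged ``converged=False``.
    """
    if not 0 < tolerance < 0.5:
        raise ValueError("tolerance must be in (0, 0.5)")
    bounds = bounds or CalibrationBounds()
    settings = settings or _CAL_SETTINGS
    static_bc = BoundaryCondition(applied_current=static_current)
    dynamic_bc = BoundaryCondition(applied_current=dynamic_current)
    evals = 0

    def forward(sigma_ds: float, sigma_ss_max: float, bc: BoundaryCondition):
        nonlocal evals
        evals += 1
        scalp = ScalpParams(
            deep_scalp_conductivity=sigma_ds,
            max_superficial_conductivity=sigma_ss_max,
            transfer_function=tf,
            sigma_ds_bounds=bounds.sigma_ds,
        )
        return solve_adaptive(mesh, tissues, scalp, tf, bc, settings).impedance

    def bisect(fn, lo, hi, target_z, bound_name):
        """Root of fn(x) - target_z on [lo, hi] for decreasing fn, in log x."""
        z_lo = fn(lo)
        z_hi = fn(hi)
        if target_z > z_lo:
            raise UnreachableTargetError(
                f"target {target_z:.1f} ohm above model range; "
                f"limited by the {bound_name} lower bound {lo:g}"
            )
        if target_z < z_hi:
            raise UnreachableTargetError(
                f"target {target_z:.1f} ohm below model range; "
                f"limited by the {bound_name} upper bound {hi:g}"
            )
        a, b = math.log(lo), math.log(hi)
        best_x, best_err = lo, abs(z_lo - target_z) / target_z
        if abs(z_hi - target_z) / target_z < best_err:
            best_x, best_err = hi, abs(z_hi - target_z) / target_z
        while b - a > bracket_resolution and evals < max_evals:
            mid = 0.5 * (a + b)
            z_mid = fn(math.exp(mid))
            err = abs(z_mid - target_z) / target_z
            if err < best_err:
                best_x, best_err = math.exp(mid), err
            if z_mid > target_z:
                a = mid
            else:
                b = mid
            if err < tolerance * 1e-2:
                break
        return best_x

    # round 1: sigma_DS from the static target (superficial layer pinned at
    # the floor under 2 uA), then sigma_ss_max from the dynamic target
    ss_mid = math.sqrt(bounds.sigma_ss_max[0] * bounds.sigma_ss_max[1])
    sigma_ds = bisect(
        lambda x: forward(x, ss_mid, static_bc),
        *bounds.sigma_ds,
        target.static_impedance,
        "sigma_ds",
    )
    sigma_ss_max = bisect(
        lambda x: forward(sigma_ds, x, dynamic_bc),
        *bounds.sigma_ss_max,
        target.dynamic_impedance,
        "sigma_ss_max",
    )

    def residuals(sds, sss):
        z_s = forward(sds, sss, static_bc)
        z_d = forward(sds, sss, dynamic_bc)
        return (
            z_s,
            z_d,
            abs(z_s - target.static_impedance) / target.static_impedance,
            abs(z_d - target.dynamic_impedance) / target.dynamic_impedance,
        )

    z_s, z_d, err_s, err_d = residuals(sigma_ds, sigma_ss_max)
    # round 2 only if cross-sensitivity left a residual above tolerance
    if (err_s > tolerance or err_d > tolerance) and evals < max_evals:
        sigma_ds = bisect(
            lambda x: forward(x, sigma_ss_max, static_bc),
            *bounds.sigma_ds,
            target.static_impedance,
            "sigma_ds",
        )
        sigma_ss_max = bisect(
            lambda x: forward(sigma_ds, x, dynamic_bc),
            *bounds.sigma_ss_max,
            target.dynamic_impedance,
            "sigma_ss_max",
        )
        z_s, z_d, err_s, err_d = residuals(sigma_ds, sigma_ss_max)

    return CalibrationResult(
        sigma_ds=float(sigma_ds),
        sigma_ss_max=float(sigma_ss_max),
        static_impedance=float(z_s),
        dynamic_impedance=float(z_d),
        static_relative_error=float(err_s),
        dynamic_relative_error=float(err_d),
        evaluations=evals,
        converged=bool(err_s <= tolerance and err_d <= tolerance),
    )


def subject_report(
    result: CalibrationResult,
    target: ClinicalImpedancePair,
    tf: TransferFunctionParams | None = None,
) -> dict:
    """JSON-serializable record of a calibration run."""
    tf = tf or TransferFunctionParams()
    return {
        "target": {
            "static_ohm": target.static_impedance,
            "dynamic_ohm": target.dynamic_impedance,
        },
        "fitted": {
            "sigma_ds_s_per_m": result.sigma_ds,
            "sigma_ss_max_s_per_m": result.sigma_ss_max,
            "saturation_field_v_per_m": saturation_field(tf, result.sigma_ss_max),
        },
        "achieved": {
            "static_ohm": result.static_impedance,
            "dynamic_ohm": result.dynamic_impedance,
            "static_relative_error": result.static_relative_error,
            "dynamic_relative_error": result.dynamic_relative_error,
        },
        "evaluations": result.evaluations,
        "converged": result.converged,
    }
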