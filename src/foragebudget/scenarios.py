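"""Stocking-rate scenarios: static-BW baselines versus precision BW.

Three ways of feeding body weight into the intake ledger:

* ``initial_bw`` — the traditional method: every animal held at the herd
  average initial BW for the whole period.
* ``midseason_bw`` — a static mid-season herd average, a cheap correction
  for growth over the period.
* ``precision`` — the cleaned per-animal daily BW panel from in-pasture
  scales.

Because cattle gain weight over a grazing period, the initial-BW method
understates forage demand; comparing scenario totals quantifies by how
much, and ``extrapolate_overgrazing`` scales the per-herd shortfall to a
regional head count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .core import (
    ForageSupply,
    GrazingPeriod,
    HerdWeightMatrix,
    IntakeLedger,
    IntakeParameters,
    ParameterError,
    run_intake_ledger,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "ScenarioComparison",
    "ExtrapolationInputs",
    "midseason_bw",
    "build_scenario",
    "run_scenario",
    "compare_scenarios",
    "extrapolate_overgrazing",
]

SCENARIO_KINDS = ("initial_bw", "midseason_bw", "precision")


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario: a static BW (kinds 1-2) or a precision herd matrix."""

    kind: str
    static_bw_kg: float | None = None
    herd: HerdWeightMatrix | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ParameterError(f"kind must be one of {SCENARIO_KINDS}, got {self.kind!r}")
        if self.kind == "precision":
            if self.herd is None:
                raise ParameterError("a precision scenario needs a HerdWeightMatrix")
        elif self.static_bw_kg is None or self.static_bw_kg <= 0:
            raise ParameterError(f"{self.kind} scenario needs static_bw_kg > 0")


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    ledger: IntakeLedger

    @property
    def total_dmi_kg(self) -> float:
        return self.ledger.total_dmi_kg

    @property
    def total_ha(self) -> float:
        return self.ledger.total_ha


@dataclass(frozen=True)
class ScenarioComparison:
    """Signed differences b - a in area and intake between two scenarios."""

    label_a: str
    label_b: str
    delta_ha: float
    delta_dmi_kg: float


@dataclass(frozen=True)
class ExtrapolationInputs:
    """Scale a per-herd area difference to a regional herd.

    ``animals_state`` is the regional head count, ``animals_local`` the
    herd size behind ``delta_ha``.
    """

    animals_state: int
    animals_local: int
    delta_ha: float

    def __post_init__(self) -> None:
        if self.animals_state < 0 or self.animals_local < 1:
            raise ParameterError("head counts must satisfy state >= 0, local >= 1")


def midseason_bw(
    method: str,
    initial: float | None = None,
    final: float | None = None,
    target: float | None = None,
    fraction: float = 0.5,
    value: float | None = None,
) -> float:
    """Static mid-season BW under one of three conventions.

    ``endpoint_mean``
        (initial + final) / 2 — for cohorts with a measured end weight.
    ``target_fraction``
        initial + (target - initial) * fraction — for cohorts managed
        toward a target weight (e.g. a breeding weight); the default
        fraction 0.5 takes the arithmetic midpoint to the target.
    ``passthrough``
        A supplied literal, for reproducing published values whose
        derivation used an unpublished horizon.
    """
    if method == "endpoint_mean":
        if initial is None or final is None:
            raise ParameterError("endpoint_mean needs initial and final BW")
        return (initial + final) / 2.0
    if method == "target_fraction":
        if initial is None or target is None:
            raise ParameterError("target_fraction needs initial and target BW")
        if target < initial:
            warnings.warn(
                f"target BW {target} below initial {initial}; mid-season BW "
                "will sit below initial",
                UserWarning,
                stacklevel=2,
            )
        return initial + (target - initial) * fraction
    if method == "passthrough":
        if value is None:
            raise ParameterError("passthrough needs a value")
        return float(value)
    raise ParameterError(
        f"method must be endpoint_mean, target_fraction or passthrough, got {method!r}"
    )


def build_scenario(
    spec: ScenarioSpec, params: IntakeParameters, period: GrazingPeriod
) -> HerdWeightMatrix:
    """Materialize the BW matrix a scenario feeds to the ledger."""
    if spec.kind == "precision":
        herd = spec.herd
        if herd.n_animals != params.head_count or herd.n_days != period.n_days:
            raise ValueError("precision matrix does not match params/period")
        return herd
    return HerdWeightMatrix.constant(spec.static_bw_kg, params.head_count, period)


def run_scenario(
    spec: ScenarioSpec,
    params: IntakeParameters,
    supply: ForageSupply,
    period: GrazingPeriod | None = None,
) -> ScenarioResult:
    """Build the scenario matrix and run it through the intake ledger."""
    if period is None:
        period = GrazingPeriod(params.period_days)
    herd = build_scenario(spec, params, period)
    return ScenarioResult(spec=spec, ledger=run_intake_ledger(herd, params, supply))


def compare_scenarios(result_a: ScenarioResult, result_b: ScenarioResult) -> ScenarioComparison:
    """Signed comparison b - a; positive delta_ha means b needs more land."""
    return ScenarioComparison(
        label_a=result_a.spec.label or result_a.spec.kind,
        label_b=result_b.spec.label or result_b.spec.kind,
        delta_ha=result_b.total_ha - result_a.total_ha,
        delta_dmi_kg=result_b.total_dmi_kg - result_a.total_dmi_kg,
    )


def extrapolate_overgrazing(inputs: ExtrapolationInputs) -> int:
    """Regional hectares implied by a per-herd area difference.

    ``(animals_state / animals_local) * delta_ha``, truncated toward
    zero — whole hectares, never rounding demand upward.
    """
    scaled = inputs.animals_state / inputs.animals_local * inputs.delta_ha
    return math.trunc(scaled)
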