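"""Reproduce the published case-study numbers from their printed inputs.

``reproduce_case_study`` reruns the static-BW scenarios from the frozen
parameter tables in :mod:`foragebudget.reference` and reports each
computed value next to its published counterpart with a pass/fail at a
stated tolerance.  Scenario-3 (precision) totals cannot be recomputed —
the per-animal weight streams were never deposited — so only the
static scenarios and the extrapolation arithmetic are checked.
"""

from __future__ import annotations

import pandas as pd

from . import reference
from .core import ForageSupply, GrazingPeriod, IntakeParameters
from .scenarios import (
    ExtrapolationInputs,
    ScenarioSpec,
    extrapolate_overgrazing,
    run_scenario,
)

__all__ = ["reproduce_case_study", "HA_RTOL", "EXACT"]

#: relative tolerance for recomputed hectare totals (printed values
#: carry ~0.01% rounding slack)
HA_RTOL = 1e-3
EXACT = 0.0


def _row(quantity, computed, ref, tolerance):
    if tolerance == EXACT:
        ok = computed == ref
    else:
        ok = abs(computed - ref) <= tolerance * abs(ref)
    return {
        "quantity": quantity,
        "computed": computed,
        "reference": ref,
        "rel_tolerance": tolerance,
        "pass": bool(ok),
    }


def _heifer_report() -> pd.DataFrame:
    h = reference.HEIFER
    params = IntakeParameters(
        pct_bw=h["pct_bw"], head_count=h["head_count"], period_days=h["period_days"]
    )
    supply = ForageSupply(h["forage_kg_per_ha"], h["harvest_efficiency"])
    period = GrazingPeriod(h["period_days"], label="heifer")

    rows = []
    for num, kind, bw in (
        (1, "initial_bw", h["initial_bw_kg"]),
        (2, "midseason_bw", h["midseason_bw_kg"]),
    ):
        result = run_scenario(ScenarioSpec(kind=kind, static_bw_kg=bw), params, supply, period)
        rows.append(
            _row(f"scenario {num} total ha", result.total_ha, h["reported_ha"][num], HA_RTOL)
        )

    ex = reference.EXTRAPOLATION
    for num, ha in ((1, ex["scenario1_ha"]), (3, ex["scenario3_ha"])):
        state_ha = extrapolate_overgrazing(
            ExtrapolationInputs(ex["animals_state"], ex["animals_local"], ha)
        )
        rows.append(_row(f"scenario {num} state ha", state_ha, ex["state_ha"][num], EXACT))
    overgrazed = extrapolate_overgrazing(
        ExtrapolationInputs(ex["animals_state"], ex["animals_local"], ex["delta_ha"])
    )
    rows.append(_row("overgrazed ha", overgrazed, ex["overgrazed_ha"], EXACT))
    return pd.DataFrame(rows)


def _steer_report(head_counts: dict) -> pd.DataFrame:
    s = reference.STEER
    rows = []
    for pasture, by_year in s["forage_kg_per_ha"].items():
        for year, forage in by_year.items():
            n = head_counts.get((pasture, year))
            if n is None:
                continue
            params = IntakeParameters(
                pct_bw=s["pct_bw"], head_count=n, period_days=s["period_days"]
            )
            supply = ForageSupply(forage, s["harvest_efficiency"])
            period = GrazingPeriod(s["period_days"], label=f"steer p{pasture} {year}")
            for num, kind, bw_table in (
                (1, "initial_bw", s["initial_bw_kg"]),
                (2, "midseason_bw", s["midseason_bw_kg"]),
            ):
                bw = bw_table[pasture][year]
                result = run_scenario(
                    ScenarioSpec(kind=kind, static_bw_kg=bw), params, supply, period
                )
                rows.append(
                    _row(
                        f"pasture {pasture} {year} scenario {num} total ha",
                        result.total_ha,
                        s["reported_ha"][num][pasture][year],
                        HA_RTOL,
                    )
                )
    return pd.DataFrame(rows)


def reproduce_case_study(name: str, steer_head_counts: dict | None = None) -> pd.DataFrame:
    """Recompute one case study's published numbers from printed inputs.

    Parameters
    ----------
    name : {"heifer", "steer"}
    steer_head_counts : dict, optional
        Required for the steer case: mapping ``(pasture, year) -> head
        count``.  Only yearly totals (127 and 135) were ever published,
        so per-pasture counts must be supplied by the user; with
        approximate counts the steer comparison is indicative only.

    Returns
    -------
    pandas.DataFrame
        Columns quantity, computed, reference, rel_tolerance, pass.
    """
    if name == "heifer":
        return _heifer_report()
    if name == "steer":
        if not steer_head_counts:
            raise ValueError(
                "steer case study needs per-pasture head counts, e.g. "
                "{(1, 2021): 21, ...}; only yearly totals (127, 135) were "
                "published, so these must be supplied"
            )
        return _steer_report(steer_head_counts)
    raise ValueError(f"unknown case study {name!r}; use 'heifer' or 'steer'")
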