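"""Animal-unit arithmetic and the daily intake / grazing-area ledger.

Rangeland stocking calculations express forage demand in animal unit
months (AUM): one animal unit (AU) is a 454 kg cow eating 2.6% of her
body weight per day on a dry-matter basis, so one AUM is roughly 354 kg
of forage dry matter over a 30-day month.  Given a per-animal daily body
weight (BW) panel, daily dry-matter intake (DMI) is modelled as

    DMI_{i,d} = BW_{i,d} * pct_bw / 100        [kg DM d^-1]

and herd demand is accumulated day by day (a discrete, daily-timestep
stock-and-flow model).  Dividing cumulative DMI by the *consumable*
forage density — standing forage (kg DM ha^-1) times a harvest
efficiency, 0.25 under the NRCS "take half, leave half" guideline —
gives the cumulative hectares the herd requires.

Everything here is deliberately linear: in ``pct_bw``, in head count,
and in BW.  Downstream modules (scenarios, sensitivity) lean on that
linearity, and the tests verify it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelConstants",
    "IntakeParameters",
    "ForageSupply",
    "GrazingPeriod",
    "HerdWeightMatrix",
    "IntakeLedger",
    "daily_dmi",
    "animal_unit_equivalent",
    "monthly_aum_forage",
    "ha_per_aum",
    "hectares_required",
    "run_intake_ledger",
    "DEFAULT_CONSTANTS",
]


class ParameterError(ValueError):
    """A model parameter violates its documented range."""


@dataclass(frozen=True)
class ModelConstants:
    """Constants defining the animal unit.

    Parameters
    ----------
    au_base_bw : float
        Body weight of the reference animal unit, kg (default 454).
    au_pct_bw : float
        Daily intake of the reference AU as percent of BW (default 2.6).
    days_per_month : float
        Days in a stocking "month" (default 30).
    """

    au_base_bw: float = 454.0
    au_pct_bw: float = 2.6
    days_per_month: float = 30.0

    def __post_init__(self) -> None:
        if self.au_base_bw <= 0 or self.au_pct_bw <= 0 or self.days_per_month < 0:
            raise ParameterError("animal-unit constants must be positive")


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class IntakeParameters:
    """Herd-level intake parameters.

    Parameters
    ----------
    pct_bw : float
        Daily dry-matter intake as percent of body weight (default 2.5,
        the nominal value for growing cattle on rangeland; plausible
        range roughly 1.8-2.7 depending on forage quality).
    head_count : int
        Number of animals in the herd.
    period_days : int
        Length of the grazing period in days.
    """

    pct_bw: float = 2.5
    head_count: int = 1
    period_days: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.pct_bw < 100:
            raise ParameterError(f"pct_bw must be in (0, 100), got {self.pct_bw}")
        if self.head_count < 1:
            raise ParameterError("head_count must be >= 1")
        if self.period_days < 1:
            raise ParameterError("period_days must be >= 1")


@dataclass(frozen=True)
class ForageSupply:
    """Standing forage and the fraction of it animals may consume.

    ``consumable_kg_per_ha`` is the forage actually available to the
    herd: total standing crop times harvest efficiency.  The default
    harvest efficiency of 0.25 encodes "take half, leave half": 50% of
    biomass is left standing, and of the taken half, half again is lost
    to trampling and fouling.
    """

    forage_kg_per_ha: float
    harvest_efficiency: float = 0.25

    def __post_init__(self) -> None:
        if self.forage_kg_per_ha <= 0:
            raise ParameterError("forage_kg_per_ha must be > 0")
        if not 0 < self.harvest_efficiency <= 1:
            raise ParameterError("harvest_efficiency must be in (0, 1]")

    @property
    def consumable_kg_per_ha(self) -> float:
        return self.forage_kg_per_ha * self.harvest_efficiency


@dataclass(frozen=True)
class GrazingPeriod:
    """A contiguous span of grazing days; day indices are 0-based."""

    n_days: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ParameterError("a grazing period needs at least one day")


@dataclass
class HerdWeightMatrix:
    """Per-animal, per-day body weights (kg) on a gap-free daily grid.

    ``values`` has one row per animal and one column per day of the
    grazing period; every entry must be strictly positive.
    """

    values: np.ndarray
    animal_ids: tuple
    period: GrazingPeriod

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("herd weight matrix must be 2-D (animals x days)")
        self.animal_ids = tuple(self.animal_ids)
        n_animals, n_days = self.values.shape
        if n_animals != len(self.animal_ids):
            raise ValueError(
                f"{len(self.animal_ids)} animal ids for {n_animals} rows"
            )
        if n_days != self.period.n_days:
            raise ValueError(
                f"matrix has {n_days} days but period declares {self.period.n_days}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("body weights must be finite and strictly positive")

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]

    @property
    def n_days(self) -> int:
        return self.values.shape[1]

    @classmethod
    def constant(
        cls, bw_kg: float, head_count: int, period: GrazingPeriod, prefix: str = "animal"
    ) -> "HerdWeightMatrix":
        """A herd held at a single static BW — the traditional AUM input."""
        if bw_kg <= 0:
            raise ParameterError("static BW must be positive")
        ids = tuple(f"{prefix}{i:03d}" for i in range(head_count))
        return cls(np.full((head_count, period.n_days), float(bw_kg)), ids, period)

    @classmethod
    def from_frame(cls, wide: pd.DataFrame, period: GrazingPeriod | None = None) -> "HerdWeightMatrix":
        """Build from a wide DataFrame (index = animal id, columns = day)."""
        wide = wide.sort_index()
        if period is None:
            period = GrazingPeriod(n_days=wide.shape[1])
        return cls(wide.to_numpy(dtype=float), tuple(wide.index), period)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.animal_ids, name="animal_id"),
            columns=pd.RangeIndex(self.n_days, name="day"),
        )


def daily_dmi(bw_kg, pct_bw: float):
    """Daily dry-matter intake, kg DM d^-1: ``bw_kg * pct_bw / 100``.

    Accepts a scalar or array BW.  A 454 kg AU at 2.6 %BW eats 11.804 kg
    per day, i.e. ~354 kg per 30-day month.
    """
    bw = np.asarray(bw_kg, dtype=float)
    if np.any(bw < 0):
        raise ParameterError("body weight must be non-negative")
    if pct_bw <= 0:
        raise ParameterError("pct_bw must be positive")
    out = bw * pct_bw / 100.0
    return float(out) if np.isscalar(bw_kg) else out


def animal_unit_equivalent(bw_kg: float, constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """AU equivalent of an animal: BW relative to the 454 kg reference cow."""
    if bw_kg < 0:
        raise ParameterError("body weight must be non-negative")
    return bw_kg / constants.au_base_bw


def monthly_aum_forage(constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Forage dry matter (kg) one AU consumes in one month: 1 AUM ~= 354 kg."""
    return constants.au_base_bw * constants.au_pct_bw / 100.0 * constants.days_per_month


def ha_per_aum(
    bw_kg: float,
    pct_bw: float,
    days_per_month: float,
    consumable_kg_per_ha: float,
) -> float:
    """Hectares needed to feed one animal for one month.

    Monthly demand ``bw * pct/100 * days`` divided by the consumable
    forage density.  E.g. a 227 kg heifer at 2.5 %BW on 700 kg ha^-1
    consumable forage needs 0.24 ha per month.
    """
    if consumable_kg_per_ha <= 0:
        raise ParameterError("consumable forage density must be positive")
    return daily_dmi(bw_kg, pct_bw) * days_per_month / consumable_kg_per_ha


def hectares_required(total_dmi_kg: float, supply: ForageSupply) -> float:
    """Area needed to supply ``total_dmi_kg`` of intake from ``supply``."""
    if total_dmi_kg < 0:
        raise ParameterError("total DMI must be non-negative")
    return total_dmi_kg / supply.consumable_kg_per_ha


@dataclass
class IntakeLedger:
    """Day-by-day intake and area accounting for a herd.

    Attributes
    ----------
    per_animal_dmi : pandas.DataFrame
        Daily DMI per animal (kg d^-1), animals x days.
    herd_dmi : pandas.Series
        Herd total DMI per day (kg d^-1), indexed by day.
    cum_dmi : pandas.Series
        Cumulative herd DMI (kg), non-decreasing in day.
    cum_ha : pandas.Series
        Cumulative hectares required; satisfies the conservation
        identity ``cum_ha * consumable_kg_per_ha == cum_dmi`` exactly.
    monthly : pandas.DataFrame
        Cumulative values sampled at the end of each 30-day block and at
        the period end (final block may be partial).
    """

    per_animal_dmi: pd.DataFrame
    herd_dmi: pd.Series
    cum_dmi: pd.Series
    cum_ha: pd.Series
    monthly: pd.DataFrame
    params: IntakeParameters
    supply: ForageSupply

    @property
    def total_dmi_kg(self) -> float:
        return float(self.cum_dmi.iloc[-1])

    @property
    def total_ha(self) -> float:
        return float(self.cum_ha.iloc[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-day export: day, herd_dmi_kg, cum_dmi_kg, cum_ha."""
        return pd.DataFrame(
            {
                "day": self.herd_dmi.index.to_numpy(),
                "herd_dmi_kg": self.herd_dmi.to_numpy(),
                "cum_dmi_kg": self.cum_dmi.to_numpy(),
                "cum_ha": self.cum_ha.to_numpy(),
            }
        )


def run_intake_ledger(
    herd: HerdWeightMatrix,
    params: IntakeParameters,
    supply: ForageSupply,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> IntakeLedger:
    """Accumulate daily herd DMI and hectares over the grazing period.

    The accumulation is the discrete daily-timestep recursion

        cumDMI(d) = cumDMI(d-1) + sum_i BW_{i,d} * pct_bw / 100,
        cumHa(d)  = cumDMI(d) / (forage * harvest_efficiency),

    with cumDMI(-1) = 0.  Monthly aggregates are the cumulative series
    sampled at days 30, 60, ... and at the period end.

    Raises
    ------
    ValueError
        If the matrix shape disagrees with ``params`` (head count or
        period length), or contains non-positive weights (the cleaning
        contract is violated upstream).
    """
    if herd.n_animals != params.head_count:
        raise ValueError(
            f"params declare {params.head_count} head but matrix has {herd.n_animals}"
        )
    if herd.n_days != params.period_days:
        raise ValueError(
            f"params declare {params.period_days} days but matrix has {herd.n_days}"
        )
    per_animal = herd.values * (params.pct_bw / 100.0)
    days = pd.RangeIndex(herd.n_days, name="day")
    per_animal_df = pd.DataFrame(
        per_animal, index=pd.Index(herd.animal_ids, name="animal_id"), columns=days
    )
    herd_daily = pd.Series(per_animal.sum(axis=0), index=days, name="herd_dmi_kg")
    cum_dmi = herd_daily.cumsum().rename("cum_dmi_kg")
    cum_ha = (cum_dmi / supply.consumable_kg_per_ha).rename("cum_ha")

    block = int(constants.days_per_month)
    sample_days = list(range(block - 1, herd.n_days - 1, block)) + [herd.n_days - 1]
    monthly = pd.DataFrame(
        {
            "day": [d + 1 for d in sample_days],  # report as day counts, not indices
            "cum_dmi_kg": cum_dmi.iloc[sample_days].to_numpy(),
            "cum_ha": cum_ha.iloc[sample_days].to_numpy(),
        }
    )
    return IntakeLedger(
        per_animal_dmi=per_animal_df,
        herd_dmi=herd_daily,
        cum_dmi=cum_dmi,
        cum_ha=cum_ha,
        monthly=monthly,
        params=params,
        supply=supply,
    )
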