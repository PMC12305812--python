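"""Cost-effectiveness evaluation: costs, ICER, WTP classification, NMB.

Costs cover complementary feeding only: a per-day cost of home-based
foods common to both arms, plus the per-day increment of iron-fortified
cereals (IFC) in the intervention arm, over an intervention window of
up to 18 months (ages 6-24 months). The ICER divides incremental cost
by incremental effect; with disability days as the effect measure the
intervention arm's lower burden makes the denominator negative, so the
cost-effectiveness plane quadrant is reported alongside the ratio and
the WHO-CHOICE classification compares |ICER| with multiples of daily
GDP per capita.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CostInputs",
    "WTPThreshold",
    "ICERResult",
    "CEAResult",
    "PopulationSavings",
    "total_food_cost",
    "icer",
    "classify_who_choice",
    "net_monetary_benefit",
    "population_savings",
]


@dataclass(frozen=True)
class CostInputs:
    """Per-day food costs (USD) and intervention duration."""

    home_food_per_day: float = 0.37
    ifc_increment_per_day: float = 0.17
    intervention_months: int = 18
    days_per_month: float = 30.0

    def __post_init__(self):
        if self.home_food_per_day < 0 or self.ifc_increment_per_day < 0:
            raise ValueError("per-day costs must be non-negative")
        if not 0 <= self.intervention_months <= 18:
            raise ValueError(
                "intervention_months must lie in [0, 18] (the 6-24 month window)"
            )
        if self.days_per_month <= 0:
            raise ValueError("days_per_month must be positive")

    @property
    def intervention_days(self) -> float:
        return self.intervention_months * self.days_per_month


@dataclass(frozen=True)
class WTPThreshold:
    """Willingness-to-pay benchmark (USD per effect unit per day)."""

    gdp_per_capita_per_day: float = 6.6
    multiplier: float = 1.0

    def __post_init__(self):
        if self.gdp_per_capita_per_day <= 0 or self.multiplier <= 0:
            raise ValueError("threshold components must be positive")

    @property
    def value(self) -> float:
        return self.multiplier * self.gdp_per_capita_per_day


def total_food_cost(c: CostInputs, with_ifc: bool) -> float:
    """Total per-child food cost (USD) over the intervention window."""
    per_day = c.home_food_per_day + (c.ifc_increment_per_day if with_ifc else 0.0)
    return per_day * c.intervention_days


_QUADRANTS = {
    (1, 1): "NE: more costly, more effective",
    (1, -1): "NW: more costly, less effective (dominated)",
    (-1, 1): "SE: less costly, more effective (dominant)",
    (-1, -1): "SW: less costly, less effective",
}


@dataclass
class ICERResult:
    """An ICER with its cost-effectiveness-plane quadrant."""

    value: float
    delta_cost: float
    delta_effect: float
    quadrant: str

    def __float__(self):
        return self.value


def icer(
    cost_int: float,
    cost_comp: float,
    eff_int: float,
    eff_comp: float,
    lower_effect_is_better: bool = True,
) -> ICERResult:
    """Incremental cost-effectiveness ratio with quadrant labelling.

    Returns (cost_int - cost_comp) / (eff_int - eff_comp). The quadrant
    distinguishes "more costly, more effective" from dominance; with
    burden-type effect units (disability days, default) a lower effect
    value counts as more effective.
    """
    d_cost = cost_int - cost_comp
    d_eff = eff_int - eff_comp
    if d_eff == 0:
        raise ZeroDivisionError(
            "equal effects: the ICER is undefined; compare net monetary "
            "benefit at a chosen willingness-to-pay instead"
        )
    gain = -d_eff if lower_effect_is_better else d_eff  # >0 = more effective
    sign_c = 1 if d_cost > 0 else (-1 if d_cost < 0 else 1)
    sign_e = 1 if gain > 0 else -1
    quadrant = _QUADRANTS[(sign_c, sign_e)]
    if d_cost == 0:
        quadrant = "on the cost axis: " + ("more" if gain > 0 else "less") + " effective at equal cost"
    return ICERResult(
        value=d_cost / d_eff, delta_cost=d_cost, delta_effect=d_eff, quadrant=quadrant
    )


def classify_who_choice(icer_value: float, t: WTPThreshold) -> str:
    """WHO-CHOICE style classification of an ICER against GDP thresholds.

    |ICER| < 1x threshold -> "highly cost-effective"; < 3x ->
    "cost-effective"; otherwise "not cost-effective". The absolute value
    is used because a negative ratio arising from an averted-burden
    denominator is interpreted independently of its sign.
    """
    v = abs(float(icer_value))
    if v < t.value:
        return "highly cost-effective"
    if v < 3.0 * t.value:
        return "cost-effective"
    return "not cost-effective"


def net_monetary_benefit(delta_effect: float, delta_cost: float, wtp: float) -> float:
    """NMB = wtp * delta_effect - delta_cost (positive = acceptable).

    ``delta_effect`` is the health gain (e.g. disability days averted,
    positive when the intervention helps).
    """
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * delta_effect - delta_cost


@dataclass
class PopulationSavings:
    total_usd: float
    millions: float


def population_savings(cost_per_unit: float, population: float) -> PopulationSavings:
    """Scale a per-child saving to a population; reported in millions (2 dp)."""
    if cost_per_unit < 0 or population < 0:
        raise ValueError("inputs must be non-negative")
    total = cost_per_unit * population
    return PopulationSavings(total_usd=total, millions=round(total / 1e6, 2))


@dataclass
class CEAResult:
    """Full cost-effectiveness comparison of the IFC vs non-IFC arms."""

    cost_ifc: float
    cost_non_ifc: float
    effect_days_ifc: float
    effect_days_non_ifc: float
    incremental_cost: float
    incremental_effect_days: float
    icer_per_disability_day: ICERResult
    icer_per_daly: float
    classification: str
    nmb: float
    wtp: WTPThreshold

    @classmethod
    def evaluate(
        cls,
        cost_ifc: float,
        cost_non_ifc: float,
        days_ifc: float,
        days_non_ifc: float,
        wtp: WTPThreshold | None = None,
    ) -> "CEAResult":
        if wtp is None:
            wtp = WTPThreshold()
        r = icer(cost_ifc, cost_non_ifc, days_ifc, days_non_ifc)
        d_cost = cost_ifc - cost_non_ifc
        days_averted = days_non_ifc - days_ifc
        dalys_averted = days_averted / 365.0
        icer_daly = d_cost / -dalys_averted if dalys_averted != 0 else float("nan")
        return cls(
            cost_ifc=cost_ifc,
            cost_non_ifc=cost_non_ifc,
            effect_days_ifc=days_ifc,
            effect_days_non_ifc=days_non_ifc,
            incremental_cost=d_cost,
            incremental_effect_days=days_ifc - days_non_ifc,
            icer_per_disability_day=r,
            icer_per_daly=icer_daly,
            classification=classify_who_choice(r.value, wtp),
            nmb=net_monetary_benefit(days_averted, d_cost, wtp.value),
            wtp=wtp,
        )
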