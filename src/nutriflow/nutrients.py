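"""Nutrient vocabulary shared across the package.

Seven nutrients are tracked through catch and trade: protein, calcium,
iron, zinc, selenium, long-chain omega-3 fatty acids, and vitamin A.
Concentrations are expressed per 100 g of raw fish, each in its own
native unit (grams, milligrams, or micrograms); masses derived from them
stay in that unit, so no cross-nutrient arithmetic is ever performed on
raw masses — comparisons across nutrients go through RNI-equivalents.
"""

from __future__ import annotations

#: The seven nutrients whose mass is tracked, with native units per 100 g.
NUTRIENTS: tuple[str, ...] = (
    "protein",
    "calcium",
    "iron",
    "zinc",
    "selenium",
    "omega3",
    "vitamin_a",
)

#: Native unit of each nutrient's concentration (per 100 g raw portion).
NUTRIENT_UNITS: dict[str, str] = {
    "protein": "g",
    "calcium": "mg",
    "iron": "mg",
    "zinc": "mg",
    "selenium": "mcg",
    "omega3": "g",
    "vitamin_a": "mcg",
}

#: The four micronutrients for which national inadequate-intake prevalence
#: data exist; only these get source→sink flow matrices.
FLOW_NUTRIENTS: tuple[str, ...] = ("calcium", "iron", "zinc", "vitamin_a")

#: The fourteen micronutrients averaged into the inadequate-intake index
#: (S_PIMII) used by the sensitivity component of the vulnerability framework.
PIMII_MICRONUTRIENTS: tuple[str, ...] = (
    "calcium",
    "copper",
    "iron",
    "folate",
    "magnesium",
    "niacin",
    "phosphorus",
    "riboflavin",
    "thiamin",
    "vitamin_a",
    "vitamin_b12",
    "vitamin_b6",
    "vitamin_c",
    "zinc",
)

#: Reserved zone token for waters outside all exclusive economic zones.
HIGH_SEAS: str = "HS"

#: Pseudo-nation receiving catch reattributed to flag-of-convenience vessels.
FOC_POOL: str = "FOC"

#: Hundred-gram portions per tonne: 1 t = 1e6 g = 1e4 × 100 g.
PORTIONS_PER_TONNE: float = 1e4

CONC_COLUMNS: tuple[str, ...] = tuple(f"conc_{n}" for n in NUTRIENTS)
PREV_COLUMNS: tuple[str, ...] = tuple(f"prev_{m}" for m in PIMII_MICRONUTRIENTS)
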