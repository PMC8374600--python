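"""Canonical 49-component nutrient schema.

Every nutrient profile and every recall report addresses exactly these 49
components, in this order, in these units. Densities are stored per 100 g of
food (per 100 mL for liquids); report totals use the same units scaled to the
amount consumed. Water is carried in mL so liquid intake totals read
naturally; energy in kcal; minerals in mg except selenium in μg; vitamins in
the unit conventional for each (vitamin D in μg, with a 40×
IU view available in reporting).
"""

from typing import NamedTuple

__all__ = [
    "Component",
    "COMPONENT_SCHEMA",
    "COMPONENT_IDS",
    "COMPONENT_INDEX",
    "MACRO_IDS",
    "ATWATER_KCAL_PER_G",
    "atwater_energy",
]


class Component(NamedTuple):
    component_id: str
    name: str
    unit: str


#: Fixed report schema: (component_id, display name, canonical unit).
COMPONENT_SCHEMA: tuple[Component, ...] = (
    Component("water", "Water", "mL"),
    Component("energy", "Energy", "kcal"),
    Component("protein", "Protein", "g"),
    Component("fat", "Total lipid (fat)", "g"),
    Component("ash", "Ash", "g"),
    Component("carbohydrate", "Carbohydrate, by difference", "g"),
    Component("fiber", "Fiber, total dietary", "g"),
    Component("sugars", "Sugars, total including NLEA", "g"),
    Component("calcium", "Calcium, Ca", "mg"),
    Component("iron", "Iron, Fe", "mg"),
    Component("magnesium", "Magnesium, Mg", "mg"),
    Component("phosphorus", "Phosphorus, P", "mg"),
    Component("potassium", "Potassium, K", "mg"),
    Component("sodium", "Sodium, Na", "mg"),
    Component("zinc", "Zinc, Zn", "mg"),
    Component("copper", "Copper, Cu", "mg"),
    Component("manganese", "Manganese, Mn", "mg"),
    Component("selenium", "Selenium, Se", "μg"),
    Component("vitamin_c", "Vitamin C, total ascorbic acid", "mg"),
    Component("thiamin", "Thiamin", "mg"),
    Component("riboflavin", "Riboflavin", "mg"),
    Component("niacin", "Niacin", "mg"),
    Component("pantothenic_acid", "Pantothenic acid", "mg"),
    Component("vitamin_b6", "Vitamin B-6", "mg"),
    Component("folate", "Folate, total", "μg"),
    Component("choline", "Choline, total", "mg"),
    Component("vitamin_b12", "Vitamin B-12", "μg"),
    Component("vitamin_a_rae", "Vitamin A, RAE", "μg"),
    Component("retinol", "Retinol", "μg"),
    Component("carotene_beta", "Carotene, beta", "μg"),
    Component("carotene_alpha", "Carotene, alpha", "μg"),
    Component("cryptoxanthin_beta", "Cryptoxanthin, beta", "μg"),
    Component("lycopene", "Lycopene", "μg"),
    Component("lutein_zeaxanthin", "Lutein + zeaxanthin", "μg"),
    Component("vitamin_e", "Vitamin E (alpha-tocopherol)", "mg"),
    Component("vitamin_d", "Vitamin D (D2 + D3)", "μg"),
    Component("vitamin_k", "Vitamin K (phylloquinone)", "μg"),
    Component("sfa", "Fatty acids, total saturated", "g"),
    Component("mufa", "Fatty acids, total monounsaturated", "g"),
    Component("pufa", "Fatty acids, total polyunsaturated", "g"),
    Component("ala_18_3", "Omega 3 (18:3)", "g"),
    Component("epa_20_5", "20:5 n-3 (EPA)", "g"),
    Component("dpa_22_5", "22:5 n-3 (DPA)", "g"),
    Component("dha_22_6", "22:6 n-3 (DHA)", "g"),
    Component("la_18_2", "Omega 6 (18:2)", "g"),
    Component("cholesterol", "Cholesterol", "mg"),
    Component("alcohol", "Alcohol, ethyl", "g"),
    Component("caffeine", "Caffeine", "mg"),
    Component("theobromine", "Theobromine", "mg"),
)

assert len(COMPONENT_SCHEMA) == 49

COMPONENT_IDS: tuple[str, ...] = tuple(c.component_id for c in COMPONENT_SCHEMA)
COMPONENT_INDEX: dict[str, Component] = {c.component_id: c for c in COMPONENT_SCHEMA}

#: Components entering the Atwater energy identity, with their factors.
ATWATER_KCAL_PER_G: dict[str, float] = {
    "protein": 4.0,
    "carbohydrate": 4.0,
    "fat": 9.0,
    "alcohol": 7.0,
}

MACRO_IDS: tuple[str, ...] = (
    "water", "protein", "fat", "ash", "carbohydrate", "fiber", "sugars", "alcohol",
)


def atwater_energy(protein_g: float, carbohydrate_g: float, fat_g: float,
                   alcohol_g: float = 0.0) -> float:
    """Energy (kcal) from the Atwater factors 4/4/9/7."""
    return 4.0 * protein_g + 4.0 * carbohydrate_g + 9.0 * fat_g + 7.0 * alcohol_g
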