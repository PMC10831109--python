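"""Food-group taxonomy.

Seventeen food groups partitioned into three classes:

* ASF  — animal-source foods (meat, eggs, dairy, seafood),
* PBA  — plant-based alternatives, processed foods mimicking an ASF,
* WF   — whole foods and everything else ("Other" bundles sugar products,
  salt, soft drinks, coffee and juice and is held constant across scenarios).
"""

from __future__ import annotations

GROUPS: tuple[str, ...] = (
    "Meats",
    "Plant-based Meat",
    "Eggs",
    "Dairy",
    "Plant-based Dairy",
    "Seafood",
    "Plant-based Seafood",
    "Vegetables",
    "Fruits",
    "Potatoes",
    "Grains",
    "Plant fats",
    "Legumes",
    "Nuts",
    "Snacks",
    "Plant-based Snacks",
    "Other",
)

ASF_GROUPS = frozenset({"Meats", "Eggs", "Dairy", "Seafood"})
PBA_GROUPS = frozenset(
    {"Plant-based Meat", "Plant-based Dairy", "Plant-based Seafood", "Plant-based Snacks"}
)
WF_GROUPS = frozenset(GROUPS) - ASF_GROUPS - PBA_GROUPS

#: For each PBA group, the conventional (animal or processed) group it mimics.
PBA_COUNTERPART = {
    "Plant-based Meat": "Meats",
    "Plant-based Dairy": "Dairy",
    "Plant-based Seafood": "Seafood",
    "Plant-based Snacks": "Snacks",
}

#: Deterministic group ordering index, used to sort rows in exports.
GROUP_ORDER = {g: i for i, g in enumerate(GROUPS)}


def classify(group: str) -> str:
    """Return the class of *group*: ``"ASF"``, ``"PBA"`` or ``"WF"``."""
    if group in ASF_GROUPS:
        return "ASF"
    if group in PBA_GROUPS:
        return "PBA"
    if group in WF_GROUPS:
        return "WF"
    raise KeyError(f"unknown food group: {group!r}")


def is_known_group(group: str) -> bool:
    return group in GROUP_ORDER
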