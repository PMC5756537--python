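"""Solution recipes, free-ion compositions, Nernst potentials and nominal osmolarity.

Patch-clamp and cell-swell experiments are defined by their bath and pipette
solutions.  This module turns a printed recipe (a list of chemicals with
concentrations in mM) into a free-ion composition by stoichiometric expansion,
from which the chloride equilibrium (Nernst) potential and a nominal ideal
osmolarity can be computed.

Assumptions
-----------
* Strong salts dissociate fully; di-/tri-valent chloride salts contribute
  2x / 3x free Cl-.
* Hepes, EGTA and Tris-ATP are counted as osmotically active particles with
  approximately zero net charge at pH 7.2-7.4 and contribute no free Cl-.
* Osmolarity is the ideal-solution particle sum with no osmotic coefficients;
  it is a nominal estimate, not a prediction of an osmometer reading.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "SolutionRecipe",
    "IonComposition",
    "dissociate",
    "nernst_potential",
    "nominal_osmolarity",
    "load_recipe",
    "ION_CHARGES",
    "DEFAULT_TEMPERATURE_K",
]

#: Default physiological temperature (37 degC).  Used wherever a recipe does
#: not carry its own temperature.
DEFAULT_TEMPERATURE_K = 310.15

GAS_CONSTANT = 8.314462618  # J/(mol K)
FARADAY = 96485.33212  # C/mol

#: Signed valence of each free-ion species tracked in :class:`IonComposition`.
ION_CHARGES: dict[str, int] = {
    "na": +1,
    "k": +1,
    "cs": +1,
    "tea": +1,
    "cl": -1,
    "aspartate": -1,
    "h2po4": -1,
    "gtp": -2,
    "mg": +2,
    "ca": +2,
    "ba": +2,
    "gd": +3,
}

# Stoichiometry of every chemical used in the bath/pipette recipes.
# Each entry maps to (ion -> count) plus a count of neutral osmolytes.
# Hepes/EGTA/ATP are treated as single neutral particles (see module docstring).
_STOICHIOMETRY: dict[str, tuple[dict[str, int], int]] = {
    "mannitol": ({}, 1),
    "glucose": ({}, 1),
    "hepes": ({}, 1),
    "egta": ({}, 1),
    "tris-atp": ({}, 1),
    "nacl": ({"na": 1, "cl": 1}, 0),
    "kcl": ({"k": 1, "cl": 1}, 0),
    "cscl": ({"cs": 1, "cl": 1}, 0),
    "tea-chloride": ({"tea": 1, "cl": 1}, 0),
    "caesium aspartate": ({"cs": 1, "aspartate": 1}, 0),
    "mgcl2": ({"mg": 1, "cl": 2}, 0),
    "cacl2": ({"ca": 1, "cl": 2}, 0),
    "bacl2": ({"ba": 1, "cl": 2}, 0),
    "gdcl3": ({"gd": 1, "cl": 3}, 0),
    "nah2po4": ({"na": 1, "h2po4": 1}, 0),
    "na2-gtp": ({"na": 2, "gtp": 1}, 0),
}

_ALIASES = {
    "tea-cl": "tea-chloride",
    "teacl": "tea-chloride",
    "cesium aspartate": "caesium aspartate",
    "cs-aspartate": "caesium aspartate",
    "tris atp": "tris-atp",
    "na2gtp": "na2-gtp",
    "na2 gtp": "na2-gtp",
}


def _canonical(chemical: str) -> str:
    key = chemical.strip().lower()
    key = _ALIASES.get(key, key)
    if key not in _STOICHIOMETRY:
        raise ValueError(
            f"unknown chemical {chemical!r}: not in the stoichiometry table "
            f"({sorted(_STOICHIOMETRY)})"
        )
    return key


@dataclass
class SolutionRecipe:
    """A named solution: chemicals with concentrations in mM."""

    name: str
    components: list[tuple[str, float]]
    pH: float = 7.4
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        for chemical, mM in self.components:
            if mM < 0:
                raise ValueError(f"negative concentration for {chemical!r}: {mM}")
            _canonical(chemical)  # raises on unknown chemical

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "temperature_K": self.temperature_K,
            "pH": self.pH,
            "components": [{"chemical": c, "mM": m} for c, m in self.components],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_recipe(path: str | Path) -> SolutionRecipe:
    """Read a recipe from its JSON representation."""
    payload = json.loads(Path(path).read_text())
    return SolutionRecipe(
        name=payload["name"],
        components=[(c["chemical"], float(c["mM"])) for c in payload["components"]],
        pH=float(payload.get("pH", 7.4)),
        temperature_K=float(payload.get("temperature_K", DEFAULT_TEMPERATURE_K)),
    )


@dataclass
class IonComposition:
    """Free-ion concentrations (mM) plus the total of neutral osmolytes (mM)."""

    ions: dict[str, float] = field(default_factory=dict)
    neutral_mM: float = 0.0

    def __post_init__(self) -> None:
        for ion, mM in self.ions.items():
            if ion not in ION_CHARGES:
                raise ValueError(f"unknown ion species {ion!r}")
            if mM < 0:
                raise ValueError(f"negative concentration for ion {ion!r}")
        if self.neutral_mM < 0:
            raise ValueError("negative neutral osmolyte total")

    def __getitem__(self, ion: str) -> float:
        return self.ions.get(ion, 0.0)

    def __add__(self, other: "IonComposition") -> "IonComposition":
        ions = dict(self.ions)
        for k, v in other.ions.items():
            ions[k] = ions.get(k, 0.0) + v
        return IonComposition(ions=ions, neutral_mM=self.neutral_mM + other.neutral_mM)

    def charge_imbalance(self) -> float:
        """Net charge concentration sum(z*c) in mEq/L (0 for a balanced solution)."""
        return sum(ION_CHARGES[i] * c for i, c in self.ions.items())

    def ionic_strength_proxy(self) -> float:
        return sum(abs(ION_CHARGES[i]) * c for i, c in self.ions.items())


def dissociate(
    recipe: SolutionRecipe, *, charge_tolerance_fraction: float = 0.02
) -> IonComposition:
    """Stoichiometric expansion of a recipe into free-ion concentrations.

    Full dissociation is assumed for all salts.  A net-charge imbalance larger
    than ``charge_tolerance_fraction`` of the total ionic strength raises a
    warning (charge states of aspartate/Hepes are approximations), never an
    error.
    """
    ions: dict[str, float] = {}
    neutral = 0.0
    for chemical, mM in recipe.components:
        stoich, n_neutral = _STOICHIOMETRY[_canonical(chemical)]
        for ion, count in stoich.items():
            ions[ion] = ions.get(ion, 0.0) + count * mM
        neutral += n_neutral * mM
    comp = IonComposition(ions=ions, neutral_mM=neutral)
    strength = comp.ionic_strength_proxy()
    if strength > 0 and abs(comp.charge_imbalance()) > charge_tolerance_fraction * strength:
        warnings.warn(
            f"recipe {recipe.name!r}: net charge {comp.charge_imbalance():+.2f} mEq/L "
            f"exceeds {charge_tolerance_fraction:.0%} of ionic strength",
            stacklevel=2,
        )
    return comp


def nernst_potential(
    ion: str,
    inside_mM: float,
    outside_mM: float,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Equilibrium potential E = (RT/zF) ln([out]/[in]) in mV (inside relative to outside).

    For chloride (z = -1) with a higher outside than inside concentration this
    is negative; its magnitude for the standard patch recipes rounds to 19 mV
    at 37 degC.
    """
    if inside_mM <= 0 or outside_mM <= 0:
        raise ValueError("Nernst potential requires strictly positive concentrations")
    try:
        z = ION_CHARGES[ion.lower()]
    except KeyError:
        raise ValueError(f"unknown ion {ion!r}") from None
    return (
        1e3
        * GAS_CONSTANT
        * temperature_K
        / (z * FARADAY)
        * math.log(outside_mM / inside_mM)
    )


def nominal_osmolarity(composition: IonComposition) -> float:
    """Ideal-solution osmolarity (mOsm/L): the plain sum of all dissolved particles."""
    return sum(composition.ions.values()) + composition.neutral_mM
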