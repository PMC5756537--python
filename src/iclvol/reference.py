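"""Reference parameter sets for the rabbit ACLT chondrocyte study conditions.

These are the published group-level estimates the synthetic generators are
parameterized from: Boltzmann conductance parameters per surgical group and
osmotic condition, swell-assay cohort parameters, and caspase-3/7 fold
changes.  They serve as generating truth in round-trip recovery tests and as
defaults for the fixture generators.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "BoltzmannParams",
    "BOLTZMANN_SETS",
    "ECL_MV",
    "SWELL_GROUPS",
    "SwellGroup",
    "CASPASE_FOLDS",
    "CASPASE_N_PER_GROUP",
    "recipe_path",
]


@dataclass(frozen=True)
class BoltzmannParams:
    """(gmax, Vh, k) triple of the two-state conductance-voltage sigmoid."""

    gmax_pS_per_pF: float
    vh_mV: float
    k_mV: float


#: Reported Boltzmann fits, keyed by (group, condition).  "difference" is the
#: fit to the hypotonic-minus-isotonic difference current, which isolates the
#: swelling-activated component.
BOLTZMANN_SETS: dict[tuple[str, str], BoltzmannParams] = {
    ("control", "iso"): BoltzmannParams(364.0, 40.0, 62.0),
    ("control", "hypo"): BoltzmannParams(1350.0, -2.0, 31.0),
    ("control", "difference"): BoltzmannParams(1035.0, 68.0, 31.0),
    ("aclt4w", "iso"): BoltzmannParams(762.0, 23.0, 42.0),
    ("aclt4w", "hypo"): BoltzmannParams(2290.0, 10.0, 25.0),
    ("aclt4w", "difference"): BoltzmannParams(2290.0, 7.0, 24.0),
}

#: Calculated chloride reversal potential for the patch recipes (mV, signed).
#: The exact Nernst value from the recipes is about -18.6 mV at 37 degC; the
#: rounded value -19 mV is the convention used by the simulator defaults.
ECL_MV = -19.0


@dataclass(frozen=True)
class SwellGroup:
    """Cohort-level swell-assay parameters for one surgical group."""

    initial_area_um2: float
    plateau_relative_area: float  # normalized cross-sectional area at 5 min
    n_cells: int


SWELL_GROUPS: dict[str, SwellGroup] = {
    "control": SwellGroup(875.0, 1.06, 15),
    "aclt2w": SwellGroup(726.0, 1.08, 21),
    "aclt4w": SwellGroup(935.0, 1.11, 11),
}

#: Caspase-3/7 luminescence fold changes vs the control-group mean.  DCPIB and
#: TNFa+DCPIB were reported as not significantly different from control; their
#: generating folds are nominal near-unity choices.
CASPASE_FOLDS: dict[str, float] = {
    "control": 1.00,
    "aclt2w": 1.24,
    "aclt4w": 1.52,
    "tnfa": 2.15,
    "dcpib": 1.00,
    "tnfa_dcpib": 1.05,
}

CASPASE_N_PER_GROUP = 20


def recipe_path(name: str) -> Path:
    """Path of a shipped solution recipe ('pipette', 'bath_iso', 'swell_iso', 'swell_hypo')."""
    ref = resources.files("iclvol").joinpath(f"data/recipes/{name}.json")
    with resources.as_file(ref) as p:
        return Path(p)
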