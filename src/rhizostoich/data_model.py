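"""Domain types for plot-level plant-soil-microbe observations.

The atomic analysis unit is one plot: its design key (stand age class,
N-application level, block), paired rhizospheric and non-rhizospheric
(bulk) soil chemistry, rhizospheric-soil extracellular enzyme activities,
and fine-root chemistry.  All concentrations and activities are strictly
positive; enzyme activities additionally need ln(activity) > 0 for the
vector analysis, which is checked at the point of use (see
:mod:`rhizostoich.vectors`) and reported by :func:`rhizostoich.io.validate_dataset`.

Units are fixed by convention and declared, never inferred:

====================  =================
soil SOC, TN, TP      g kg-1
soil NH4+-N, NO3--N   mg kg-1
soil available P      mg kg-1
root TC, TN, TP       mg g-1 dry mass
enzymes BG/NAG/LAP/ACP  nmol g-1 h-1
====================  =================
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

from .errors import DataValidationError, PairingError

DEFAULT_AGE_LEVELS = (42, 55, 65)
DEFAULT_N_LEVELS = ("N0", "N1", "N2", "N3", "N4")
#: nominal N-application rate annotation per ordinal level (label -> rate).
#: The rate is an annotation only; analyses treat the level as ordinal 0..4.
DEFAULT_N_RATES = {"N0": 0.0, "N1": 5.0, "N2": 10.0, "N3": 15.0, "N4": 20.0}

SOIL_VARS = ("soc", "tn", "tp", "nh4", "no3", "ap")
ENZYME_VARS = ("bg", "nag", "lap", "acp")
ROOT_VARS = ("tc", "tn", "tp")

UNITS = {
    "soc": "g kg-1", "tn": "g kg-1", "tp": "g kg-1",
    "nh4": "mg kg-1", "no3": "mg kg-1", "ap": "mg kg-1",
    "root_tc": "mg g-1", "root_tn": "mg g-1", "root_tp": "mg g-1",
    "enzyme": "nmol g-1 h-1",
}


def _check_positive_finite(obj, names):
    for name in names:
        v = getattr(obj, name)
        if not isinstance(v, (int, float)) or not math.isfinite(v) or v <= 0:
            raise DataValidationError(
                f"{type(obj).__name__}.{name} must be finite and > 0, got {v!r}"
            )


@dataclass(frozen=True, order=True)
class DesignKey:
    """Identifies one plot in the age x N-level x block factorial."""

    age_class: int
    n_level: str
    block: str
    plot: str = ""

    @property
    def cell(self) -> tuple:
        """The (age, N level) treatment cell, pooling blocks."""
        return (self.age_class, self.n_level)


@dataclass(frozen=True)
class SoilChemistry:
    """One soil compartment's chemistry. Totals g kg-1, available pools mg kg-1."""

    soc: float
    tn: float
    tp: float
    nh4: float
    no3: float
    ap: float

    def __post_init__(self):
        _check_positive_finite(self, SOIL_VARS)


@dataclass(frozen=True)
class EnzymeProfile:
    """Potential activities of the four assayed enzymes, nmol g-1 h-1.

    BG acquires C, NAG and LAP acquire N, ACP acquires P.  Positivity is
    enforced here; the stricter log-domain rule (BG, NAG+LAP and ACP all
    > 1 so natural logs are strictly positive) belongs to the vector
    formulas and is enforced there.
    """

    bg: float
    nag: float
    lap: float
    acp: float

    def __post_init__(self):
        _check_positive_finite(self, ENZYME_VARS)

    @property
    def n_acq(self) -> float:
        """Combined N-acquiring activity NAG + LAP."""
        return self.nag + self.lap

    def log_domain_ok(self) -> bool:
        """True when BG, NAG+LAP and ACP all exceed 1 nmol g-1 h-1."""
        return self.bg > 1.0 and self.n_acq > 1.0 and self.acp > 1.0


@dataclass(frozen=True)
class RootChemistry:
    """Fine-root total C, N and P contents, mg g-1 dry mass."""

    tc: float
    tn: float
    tp: float

    def __post_init__(self):
        _check_positive_finite(self, ROOT_VARS)


@dataclass(frozen=True)
class PlotObservation:
    """One plot's complete record: paired soils, enzymes, roots."""

    key: DesignKey
    rhizo_soil: SoilChemistry
    bulk_soil: SoilChemistry
    rhizo_enzymes: EnzymeProfile
    root: RootChemistry


@dataclass
class Dataset:
    """Ordered, key-unique collection of plot observations."""

    observations: list[PlotObservation]
    age_levels: tuple = DEFAULT_AGE_LEVELS
    n_levels: tuple = DEFAULT_N_LEVELS
    units: dict = field(default_factory=lambda: dict(UNITS))

    def __post_init__(self):
        if not self.observations:
            raise DataValidationError("Dataset must contain at least one observation")
        seen = set()
        for obs in self.observations:
            k = (obs.key.age_class, obs.key.n_level, obs.key.block)
            if k in seen:
                raise PairingError(f"duplicate design key {k}")
            seen.add(k)

    def __len__(self):
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    @property
    def is_balanced(self) -> bool:
        """True when every age x N cell has the same number of blocks."""
        counts = {}
        for obs in self.observations:
            counts[obs.key.cell] = counts.get(obs.key.cell, 0) + 1
        expected = len(self.age_levels) * len(self.n_levels)
        return len(counts) == expected and len(set(counts.values())) == 1

    def cell_counts(self) -> dict:
        counts: dict = {}
        for obs in self.observations:
            counts[obs.key.cell] = counts.get(obs.key.cell, 0) + 1
        return counts
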