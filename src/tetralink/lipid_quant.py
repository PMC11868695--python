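"""GDGT mass arithmetic, identification and quantification.

Membrane-spanning tetraether lipids (GDGTs) form homologue series related by
simple compositional steps: methylation adds CH2 (+14 Da nominal), a
cyclopentane ring removes H2 (-2 Da), and the GMGT "H" bridge -- a covalent
C-C bond between the two alkyl chains -- also removes H2.  Species are
identified in HRMS data by the accurate mass of their singly charged adducts
([M+H]+, [M+NH4]+, [M+Na]+), and quantified by summing the extracted-ion peak
areas of the adducts present, normalizing to a co-injected internal standard
(which cancels per-sample matrix effects) and dividing by the litres of water
filtered, yielding "response units per litre".
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import ValidationError

__all__ = [
    "MolecularFormula",
    "LipidSpecies",
    "MONOISOTOPIC_MASS",
    "ADDUCT_MASS",
    "SERIES_STEPS",
    "monoisotopic_mass",
    "adduct_mz",
    "rounded_mz",
    "apply_series_step",
    "combine_adduct_areas",
    "is_normalize",
    "relative_abundance_profile",
    "load_registry",
    "verify_registry",
    "quantify_peaks",
]

#: IUPAC monoisotopic atomic masses (Da) for the elements that occur in
#: tetraether lipids and their adducts.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.0078250,
    "N": 14.0030740,
    "O": 15.9949146,
    "Na": 22.9897693,
}

#: Mass added by each singly charged adduct (Da).  The proton constant
#: 1.00728 already carries the electron-mass deficit; [M+NH4]+ and [M+Na]+
#: use the matching cation masses.
ADDUCT_MASS: dict[str, float] = {
    "M+H": 1.00728,
    "M+NH4": 18.03383,
    "M+Na": 22.98922,
}

#: Compositional deltas of the homologue-series steps.
SERIES_STEPS: dict[str, dict[str, int]] = {
    "methylation": {"C": 1, "H": 2},   # +CH2, +14 nominal
    "ring": {"H": -2},                 # cyclopentane ring, -2 nominal
    "gmgt_bridge": {"H": -2},          # covalent C-C chain bridge, -2 nominal
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts of a neutral molecule, e.g. C66H132O6."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        total = 0
        for element, n in self.counts:
            if n < 0:
                raise ValidationError(f"negative count for element {element}")
            total += n
        if total == 0:
            raise ValidationError("formula must contain at least one atom")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "MolecularFormula":
        items = tuple(sorted((e, int(n)) for e, n in counts.items() if n != 0))
        return cls(items)

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a Hill-style formula string such as ``C66H132O6``."""
        text = text.strip()
        if not text:
            raise ValidationError("empty molecular formula")
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(text):
            if m.start() != pos:
                raise ValidationError(f"cannot parse formula {text!r}")
            if not m.group(0):
                break
            element = m.group(1)
            counts[element] = counts.get(element, 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text):
            raise ValidationError(f"cannot parse formula {text!r}")
        return cls.from_counts(counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def n_atoms(self) -> int:
        return sum(n for _, n in self.counts)

    def __str__(self) -> str:
        order = {"C": 0, "H": 1}
        items = sorted(self.counts, key=lambda en: (order.get(en[0], 2), en[0]))
        return "".join(f"{e}{n if n != 1 else ''}" for e, n in items)


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Monoisotopic mass (Da): sum of IUPAC monoisotopic atomic masses."""
    mass = 0.0
    for element, n in formula.counts:
        if element not in MONOISOTOPIC_MASS:
            raise ValidationError(f"unknown element {element!r}")
        mass += MONOISOTOPIC_MASS[element] * n
    return mass


def adduct_mz(formula: MolecularFormula, adduct: str) -> float:
    """m/z of a singly charged adduct ion of the neutral molecule."""
    if adduct not in ADDUCT_MASS:
        raise ValidationError(
            f"unsupported adduct {adduct!r}; expected one of {sorted(ADDUCT_MASS)}"
        )
    return monoisotopic_mass(formula) + ADDUCT_MASS[adduct]


def rounded_mz(mz: float) -> int:
    """Round an m/z to the nearest integer, half away from zero."""
    return int(math.copysign(math.floor(abs(mz) + 0.5), mz))


def apply_series_step(formula: MolecularFormula, step: str) -> MolecularFormula:
    """Apply one homologue-series step (methylation, ring or gmgt_bridge)."""
    if step not in SERIES_STEPS:
        raise ValidationError(
            f"unknown series step {step!r}; expected one of {sorted(SERIES_STEPS)}"
        )
    counts = dict(formula.counts)
    for element, delta in SERIES_STEPS[step].items():
        new = counts.get(element, 0) + delta
        if new < 0:
            raise ValidationError(
                f"step {step!r} would make the {element} count negative"
            )
        counts[element] = new
    return MolecularFormula.from_counts(counts)


@dataclass(frozen=True)
class LipidSpecies:
    """A registered tetraether species.

    The formula is either declared directly or derived from a parent species
    by a list of series steps; ``nominal_mz`` is the declared integer [M+H]+
    m/z used as an identification cross-check.
    """

    name: str
    series_class: str
    formula: MolecularFormula
    nominal_mz: int
    parent: str | None = None
    steps: tuple[str, ...] = ()
    notes: str = ""

    def mz(self, adduct: str = "M+H") -> float:
        return adduct_mz(self.formula, adduct)


def _default_registry_path():
    return resources.files("tetralink").joinpath("data/gdgt_registry.yaml")


def load_registry(path=None) -> dict[str, LipidSpecies]:
    """Load the lipid registry (packaged GDGT registry by default).

    Entries may declare a ``formula`` directly or a ``parent`` plus series
    ``steps``; parents must be declared before their derivatives.
    """
    if path is None:
        text = _default_registry_path().read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    registry: dict[str, LipidSpecies] = {}
    for entry in raw["species"]:
        name = entry["name"]
        if name in registry:
            raise ValidationError(f"duplicate lipid name {name!r} in registry")
        steps: tuple[str, ...] = tuple(entry.get("steps", ()))
        parent = entry.get("parent")
        if "formula" in entry:
            formula = MolecularFormula.parse(entry["formula"])
        elif parent is not None:
            if parent not in registry:
                raise ValidationError(
                    f"species {name!r} refers to unknown parent {parent!r}"
                )
            formula = registry[parent].formula
            for step in steps:
                formula = apply_series_step(formula, step)
        else:
            raise ValidationError(f"species {name!r} has neither formula nor parent")
        registry[name] = LipidSpecies(
            name=name,
            series_class=entry["series_class"],
            formula=formula,
            nominal_mz=int(entry["nominal_mz"]),
            parent=parent,
            steps=steps,
            notes=entry.get("notes", ""),
        )
    return registry


def verify_registry(registry: Mapping[str, LipidSpecies]) -> list[str]:
    """Return the names of species whose computed rounded [M+H]+ m/z
    conflicts with their declared nominal mass (empty list = consistent)."""
    return [
        sp.name
        for sp in registry.values()
        if rounded_mz(sp.mz("M+H")) != sp.nominal_mz
    ]


def combine_adduct_areas(areas: Mapping[str, float]) -> float:
    """Sum peak areas over the adducts present for one (lipid, sample).

    Adducts absent from the mapping contribute nothing; an empty mapping
    yields 0.
    """
    total = 0.0
    for adduct, area in areas.items():
        if adduct not in ADDUCT_MASS:
            raise ValidationError(f"unknown adduct label {adduct!r}")
        if area < 0:
            raise ValidationError(f"negative peak area for adduct {adduct!r}")
        total += area
    return total


def is_normalize(combined_area: float, is_area: float, litres: float = 1.0) -> float:
    """Internal-standard normalization: (area / IS area) / litres filtered.

    Dividing by the internal-standard response cancels per-sample matrix
    effects and instrument drift that scale analyte and standard alike.
    """
    if is_area <= 0:
        raise ValidationError("internal-standard area must be positive")
    if litres <= 0:
        raise ValidationError("litres filtered must be positive")
    return (combined_area / is_area) / litres


def relative_abundance_profile(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundance of each lipid (columns = samples).

    Each column is divided by its sum over the reported lipid set.  Samples
    where every lipid has zero response are undefined and returned as NaN
    rather than 0/0.
    """
    if (responses.to_numpy() < 0).any():
        raise ValidationError("responses must be non-negative")
    totals = responses.sum(axis=0)
    out = responses.divide(totals.where(totals > 0), axis=1)
    return out


def quantify_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Quantify a validated peak table into response units per litre.

    ``peaks`` has columns lipid, sample_depth_m, adduct, area, is_area,
    litres (one row per observed adduct).  Returns a lipid x sample frame of
    (combined adduct area / IS area) / litres.  The internal-standard area
    and litres must be consistent within a sample.
    """
    if peaks.empty:
        return pd.DataFrame()
    for sample, group in peaks.groupby("sample_depth_m"):
        if group["is_area"].nunique() != 1:
            raise ValidationError(
                f"inconsistent internal-standard area within sample {sample}"
            )
        if group["litres"].nunique() != 1:
            raise ValidationError(f"inconsistent litres within sample {sample}")
    combined = (
        peaks.groupby(["lipid", "sample_depth_m"])["area"].sum().unstack(fill_value=0.0)
    )
    per_sample = peaks.drop_duplicates("sample_depth_m").set_index("sample_depth_m")
    result = combined.copy().astype(float)
    for sample in combined.columns:
        is_area = float(per_sample.loc[sample, "is_area"])
        litres = float(per_sample.loc[sample, "litres"])
        result[sample] = [
            is_normalize(a, is_area, litres) for a in combined[sample]
        ]
    return result
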