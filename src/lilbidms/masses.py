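"""Protein and complex mass arithmetic for native (LILBID) mass spectrometry.

All masses are average-isotopic and neutral, expressed in kDa.  LILBID
time-of-flight spectra of nanodisc samples resolve features on the
~0.01 kDa scale, so isotopologue fine structure is irrelevant and average
masses are used throughout.  Proton loss in anionic detection mode (a few
Da at most) is below display precision and is ignored: species are reported
at their neutral mass, matching how complex masses are quoted in the
native-MS literature.

Stable-isotope labeling follows the cell-free expression convention for
algal ``15N,d`` amino-acid mixes: sixteen amino acids carry both 15N and
non-exchangeable 2H, while Asn, Gln and Trp (supplemented separately) are
15N-only and Cys is unlabeled.  "Non-exchangeable" hydrogens are the
carbon-bound hydrogens of each residue; amide, hydroxyl, thiol and amine
protons re-exchange in aqueous buffer and contribute no mass shift.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ATOMIC_WEIGHTS_DA",
    "STANDARD_AMINO_ACIDS",
    "WATER_DA",
    "DELTA_15N_DA",
    "DELTA_2H_DA",
    "AminoAcidComposition",
    "LabelClass",
    "LabelingScheme",
    "Role",
    "ComponentSpec",
    "average_mass_da",
    "protein_mass_from_composition",
    "labeled_mass",
    "label_shift",
    "complex_mass",
    "read_component_registry",
    "write_component_registry",
]

# ---------------------------------------------------------------------------
# Residue tables
# ---------------------------------------------------------------------------

#: Mass added per 14N -> 15N substitution (Da).
DELTA_15N_DA = 0.99703
#: Mass added per 1H -> 2H substitution at a non-exchangeable site (Da).
DELTA_2H_DA = 1.00628


#: Fixed atomic-weight table (IUPAC 2021 abridged standard atomic weights).
#: One table for everything — amino acids, water, lipids — so all derived
#: masses are mutually consistent.
ATOMIC_WEIGHTS_DA: Mapping[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Na": 22.990,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def average_mass_da(formula: str) -> float:
    """Average molecular mass (Da) of a molecular formula such as ``C2H5NO2``."""
    pos = 0
    total = 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        pos = match.end()
        element, count = match.group(1), match.group(2)
        if element not in ATOMIC_WEIGHTS_DA:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        total += ATOMIC_WEIGHTS_DA[element] * (int(count) if count else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
    return total


#: Mass of one water molecule (Da), lost per peptide bond formed.
WATER_DA = average_mass_da("H2O")


@dataclass(frozen=True)
class _Residue:
    """Static per-amino-acid data used for mass and label arithmetic.

    ``n_nitrogen`` counts all N atoms of the residue (backbone included);
    ``n_cbound_h`` counts hydrogens bound to carbon once the residue sits in
    a peptide chain — these are the non-exchangeable sites that retain 2H.
    """

    code: str
    name: str
    formula: str  # free amino acid
    n_nitrogen: int
    n_cbound_h: int

    @property
    def free_mass_da(self) -> float:
        return average_mass_da(self.formula)


STANDARD_AMINO_ACIDS: Mapping[str, _Residue] = {
    r.code: r
    for r in [
        _Residue("A", "alanine", "C3H7NO2", 1, 4),
        _Residue("R", "arginine", "C6H14N4O2", 4, 7),
        _Residue("N", "asparagine", "C4H8N2O3", 2, 3),
        _Residue("D", "aspartate", "C4H7NO4", 1, 3),
        _Residue("C", "cysteine", "C3H7NO2S", 1, 3),
        _Residue("E", "glutamate", "C5H9NO4", 1, 5),
        _Residue("Q", "glutamine", "C5H10N2O3", 2, 5),
        _Residue("G", "glycine", "C2H5NO2", 1, 2),
        _Residue("H", "histidine", "C6H9N3O2", 3, 5),
        _Residue("I", "isoleucine", "C6H13NO2", 1, 10),
        _Residue("L", "leucine", "C6H13NO2", 1, 10),
        _Residue("K", "lysine", "C6H14N2O2", 2, 9),
        _Residue("M", "methionine", "C5H11NO2S", 1, 8),
        _Residue("F", "phenylalanine", "C9H11NO2", 1, 8),
        _Residue("P", "proline", "C5H9NO2", 1, 7),
        _Residue("S", "serine", "C3H7NO3", 1, 3),
        _Residue("T", "threonine", "C4H9NO3", 1, 5),
        _Residue("W", "tryptophan", "C11H12N2O2", 2, 8),
        _Residue("Y", "tyrosine", "C9H11NO3", 1, 7),
        _Residue("V", "valine", "C5H11NO2", 1, 8),
    ]
}


# ---------------------------------------------------------------------------
# Compositions and labeling schemes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AminoAcidComposition:
    """Counts per standard one-letter amino-acid code."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for code, count in self.counts.items():
            if code not in STANDARD_AMINO_ACIDS:
                raise ValueError(f"unknown amino-acid code: {code!r}")
            if int(count) != count or count < 0:
                raise ValueError(f"count for {code} must be a non-negative integer")
        if self.n < 1:
            raise ValueError("composition must contain at least one residue")
        object.__setattr__(self, "counts", dict(self.counts))

    @classmethod
    def from_sequence(cls, sequence: str) -> "AminoAcidComposition":
        seq = re.sub(r"\s+", "", sequence).upper()
        counts: dict[str, int] = {}
        for code in seq:
            if code not in STANDARD_AMINO_ACIDS:
                raise ValueError(f"unknown amino-acid code: {code!r}")
            counts[code] = counts.get(code, 0) + 1
        return cls(counts)

    @property
    def n(self) -> int:
        """Total residue count."""
        return sum(self.counts.values())

    def items(self):
        return self.counts.items()


class LabelClass(enum.Enum):
    """Isotope label applied to an amino acid during cell-free expression."""

    N15_H2 = "15N+2H"
    N15 = "15N-only"
    UNLABELED = "unlabeled"


#: Amino acids supplied outside the algal mix, hence 15N-only or unlabeled.
_N15_ONLY = frozenset("NQW")
_UNLABELED = frozenset("C")


@dataclass(frozen=True)
class LabelingScheme:
    """Per-amino-acid label classes plus the isotope mass increments."""

    classes: Mapping[str, LabelClass]
    delta_15n_da: float = DELTA_15N_DA
    delta_2h_da: float = DELTA_2H_DA

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", dict(self.classes))

    @classmethod
    def default(cls) -> "LabelingScheme":
        """The algal-mix scheme: 16 amino acids 15N+2H; Asn/Gln/Trp 15N; Cys free."""
        classes = {}
        for code in STANDARD_AMINO_ACIDS:
            if code in _UNLABELED:
                classes[code] = LabelClass.UNLABELED
            elif code in _N15_ONLY:
                classes[code] = LabelClass.N15
            else:
                classes[code] = LabelClass.N15_H2
        return cls(classes)

    @classmethod
    def unlabeled(cls) -> "LabelingScheme":
        return cls({code: LabelClass.UNLABELED for code in STANDARD_AMINO_ACIDS})

    def residue_shift_da(self, code: str) -> float:
        """Mass shift (Da) of one labeled residue of the given amino acid."""
        if code not in self.classes:
            raise ValueError(f"labeling scheme does not cover amino acid {code!r}")
        residue = STANDARD_AMINO_ACIDS[code]
        label = self.classes[code]
        if label is LabelClass.UNLABELED:
            return 0.0
        shift = residue.n_nitrogen * self.delta_15n_da
        if label is LabelClass.N15_H2:
            shift += residue.n_cbound_h * self.delta_2h_da
        return shift


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------


class Role(enum.Enum):
    TARGET = "target"
    SCAFFOLD = "scaffold"
    LIPID = "lipid"


@dataclass(frozen=True)
class ComponentSpec:
    """A sample component: target protein, scaffold protein, or lipid.

    ``mass_kda`` is the neutral average mass of one copy.  When a
    composition is supplied it must agree with the stated mass within
    0.01 kDa, catching transcription errors between sequence and mass.
    """

    name: str
    role: Role
    mass_kda: float
    composition: AminoAcidComposition | None = None
    labeled_mass_kda: float | None = None

    def __post_init__(self) -> None:
        if self.mass_kda <= 0:
            raise ValueError(f"component {self.name!r}: mass must be positive")
        if self.labeled_mass_kda is not None and self.labeled_mass_kda <= 0:
            raise ValueError(f"component {self.name!r}: labeled mass must be positive")
        if self.composition is not None:
            computed = protein_mass_from_composition(self.composition)
            if abs(computed - self.mass_kda) > 0.01:
                raise ValueError(
                    f"component {self.name!r}: stated mass {self.mass_kda:.4f} kDa "
                    f"disagrees with composition mass {computed:.4f} kDa by more "
                    "than 0.01 kDa"
                )

    def labeled(self, scheme: LabelingScheme | None = None) -> "ComponentSpec":
        """A copy of this component carrying its isotope-labeled mass.

        Uses the explicit ``labeled_mass_kda`` if set, otherwise computes it
        from the composition under ``scheme`` (default algal-mix scheme).
        """
        if self.labeled_mass_kda is not None:
            new_mass = self.labeled_mass_kda
        elif self.composition is not None:
            new_mass = labeled_mass(self.composition, scheme or LabelingScheme.default())
        else:
            raise ValueError(
                f"component {self.name!r} has neither a labeled mass nor a composition"
            )
        return replace(self, mass_kda=new_mass, labeled_mass_kda=None,
                       composition=None, name=f"{self.name}*")


# ---------------------------------------------------------------------------
# Mass operations
# ---------------------------------------------------------------------------


def protein_mass_from_composition(comp: AminoAcidComposition) -> float:
    """Neutral average mass (kDa) of a polypeptide from its composition.

    Sum of free amino-acid masses minus one water per peptide bond
    (n − 1 bonds for n residues).
    """
    total_da = sum(
        count * STANDARD_AMINO_ACIDS[code].free_mass_da for code, count in comp.items()
    )
    total_da -= (comp.n - 1) * WATER_DA
    return total_da / 1000.0


def label_shift(comp: AminoAcidComposition, scheme: LabelingScheme) -> float:
    """Total isotope mass shift (kDa) of a composition under a labeling scheme."""
    missing = sorted(code for code in comp.counts if code not in scheme.classes)
    if missing:
        raise ValueError(
            "labeling scheme does not cover amino acid(s): " + ", ".join(missing)
        )
    shift_da = sum(count * scheme.residue_shift_da(code) for code, count in comp.items())
    return shift_da / 1000.0


def labeled_mass(comp: AminoAcidComposition, scheme: LabelingScheme) -> float:
    """Neutral average mass (kDa) of the isotope-labeled polypeptide."""
    return protein_mass_from_composition(comp) + label_shift(comp, scheme)


def complex_mass(
    stoich: tuple[int, int, int],
    target: ComponentSpec,
    scaffold: ComponentSpec,
    lipid: ComponentSpec | None = None,
) -> float:
    """Neutral mass (kDa) of a complex with ``(n, m, k)`` stoichiometry.

    ``n`` target copies, ``m`` scaffold copies, ``k`` attached lipids;
    strictly additive, no adduct corrections.
    """
    n, m, k = stoich
    if n < 0 or m < 0 or k < 0:
        raise ValueError("stoichiometry counts must be non-negative")
    if n + m == 0:
        raise ValueError("complex must contain at least one protein (n + m >= 1)")
    if k > 0 and lipid is None:
        raise ValueError("lipid component required when k > 0")
    mass = n * target.mass_kda + m * scaffold.mass_kda
    if lipid is not None:
        mass += k * lipid.mass_kda
    return mass


# ---------------------------------------------------------------------------
# Component registry I/O
# ---------------------------------------------------------------------------


def _component_to_dict(spec: ComponentSpec) -> dict:
    entry: dict = {"name": spec.name, "role": spec.role.value,
                   "mass_kda": spec.mass_kda}
    if spec.composition is not None:
        entry["composition"] = dict(spec.composition.counts)
    if spec.labeled_mass_kda is not None:
        entry["labeled_mass_kda"] = spec.labeled_mass_kda
    return entry


def _component_from_dict(entry: Mapping) -> ComponentSpec:
    comp = entry.get("composition")
    return ComponentSpec(
        name=entry["name"],
        role=Role(entry["role"]),
        mass_kda=float(entry["mass_kda"]),
        composition=AminoAcidComposition(comp) if comp else None,
        labeled_mass_kda=(
            float(entry["labeled_mass_kda"]) if "labeled_mass_kda" in entry else None
        ),
    )


def write_component_registry(components: list[ComponentSpec], path: str | Path) -> None:
    """Write components to a YAML registry file (lossless round trip)."""
    doc = {"components": [_component_to_dict(c) for c in components]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_component_registry(path: str | Path) -> list[ComponentSpec]:
    doc = yaml.safe_load(Path(path).read_text())
    return [_component_from_dict(e) for e in doc["components"]]
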