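"""Published-value fixtures: construct masses, nanodisc characteristics,
lipid formulas, and small geometry helpers.

The shipped YAML resource binds printed construct masses (theoretical vs
experimental, labeled vs unlabeled — never conflated) and the nanodisc
characterization table to typed, immutable records, each value carrying a
provenance string.  Lipid monomer masses are not printed anywhere in the
source tables; they are derived here from molecular formulas and are
therefore computed values, not transcription.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from types import MappingProxyType
from typing import Mapping

import yaml

from .masses import ComponentSpec, Role, average_mass_da

__all__ = [
    "ConstructFixture",
    "NanodiscFixture",
    "LipidFixture",
    "FootprintResult",
    "load_fixture",
    "list_fixtures",
    "lipid_mass_kda",
    "lipid_component",
    "construct_component",
    "lipids_per_disc",
    "footprint_check",
    "MSP1E3D1_DISC_AREA_NM2",
    "PR_MONOMER_FOOTPRINT_NM2",
]


@dataclass(frozen=True)
class ConstructFixture:
    """Printed masses (kDa) for one protein construct."""

    name: str
    full_name: str
    theoretical_kda: float
    experimental_kda: float
    theoretical_labeled_kda: float | None = None
    experimental_labeled_kda: float | None = None
    theoretical_cleaved_kda: float | None = None
    experimental_cleaved_kda: float | None = None
    theoretical_labeled_alt_kda: float | None = None
    notes: str | None = None
    provenance: Mapping[str, str] = None  # type: ignore[assignment]


@dataclass(frozen=True)
class NanodiscFixture:
    """One scaffold/lipid nanodisc characterization row.

    ``protein_lipid_ratio`` is lipids per scaffold protein in the
    reconstitution mix; ``attached_lipids`` the FWHM-derived adduct count
    (None where not investigated).
    """

    scaffold: str
    lipid: str
    diameter_nm: float
    protein_lipid_ratio: float
    attached_lipids: int | None
    transition_c: float | str | None
    headgroup_charge: int | str | None
    double_bonds: int | str | None
    tail_length: int | str | None
    lipid_ratio: str | None
    confidence: str
    provenance: str


@dataclass(frozen=True)
class LipidFixture:
    """A lipid species with formula-derived average mass."""

    name: str
    full_name: str
    formula: str
    mass_kda: float


@dataclass(frozen=True)
class FootprintResult:
    """Membrane-area requirement of an oligomer vs the available disc area."""

    required_nm2: float
    disc_area_nm2: float
    fits: bool


@lru_cache(maxsize=1)
def _raw() -> Mapping:
    text = resources.files("lilbidms.data").joinpath("fixtures.yaml").read_text()
    return yaml.safe_load(text)


def _norm(name: str) -> str:
    return name.replace("Δ", "d").strip()


@lru_cache(maxsize=1)
def _index() -> Mapping[str, object]:
    raw = _raw()
    idx: dict[str, object] = {}
    for key, entry in raw["constructs"].items():
        fields = {k: v for k, v in entry.items()}
        fields["provenance"] = MappingProxyType(dict(fields.get("provenance") or {}))
        idx[key] = ConstructFixture(name=key, **fields)
    for row in raw["nanodiscs"]:
        row = dict(row)
        fix = NanodiscFixture(
            scaffold=row.pop("scaffold"),
            lipid=row.pop("lipid"),
            diameter_nm=row.pop("diameter_nm"),
            protein_lipid_ratio=row.pop("protein_lipid_ratio"),
            attached_lipids=row.pop("attached_lipids", None),
            transition_c=row.pop("transition_c", None),
            headgroup_charge=row.pop("headgroup_charge", None),
            double_bonds=row.pop("double_bonds", None),
            tail_length=row.pop("tail_length", None),
            lipid_ratio=row.pop("lipid_ratio", None),
            confidence=row.pop("confidence"),
            provenance=row.pop("provenance"),
        )
        idx[f"{fix.scaffold}+{fix.lipid}"] = fix
    for key, entry in raw["lipids"].items():
        idx[key] = LipidFixture(
            name=key,
            full_name=entry["name"],
            formula=entry["formula"],
            mass_kda=average_mass_da(entry["formula"]) / 1000.0,
        )
    return MappingProxyType(idx)


def list_fixtures() -> list[str]:
    """Names of all registered fixtures (constructs, disc rows, lipids)."""
    return sorted(_index())


def load_fixture(name: str):
    """Look up a fixture record by name.

    Constructs by name (``"KcsA"``), nanodisc rows as ``"SCAFFOLD+LIPID"``
    (``"MSP1E3D1+DPPC"``), lipids by abbreviation (``"DOPG"``).  Unknown
    names raise a ``KeyError`` listing what is available.
    """
    idx = _index()
    key = _norm(name)
    if key not in idx:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(idx))}"
        )
    return idx[key]


def lipid_mass_kda(name: str) -> float:
    """Formula-derived average mass (kDa) of a registered lipid."""
    fix = load_fixture(name)
    if not isinstance(fix, LipidFixture):
        raise KeyError(f"{name!r} is not a lipid fixture")
    return fix.mass_kda


def lipid_component(name: str) -> ComponentSpec:
    """A registered lipid as a :class:`ComponentSpec`."""
    return ComponentSpec(name=name, role=Role.LIPID, mass_kda=lipid_mass_kda(name))


def construct_component(
    name: str,
    role: Role,
    *,
    basis: str = "theoretical",
    labeled: bool = False,
    cleaved: bool = False,
) -> ComponentSpec:
    """A registered construct as a :class:`ComponentSpec`.

    ``basis`` selects ``"theoretical"`` or ``"experimental"`` masses;
    ``labeled`` the stable-isotope-labeled variant; ``cleaved`` the
    tag-cleaved variant (scaffolds only).  The labeled mass, when
    available, is attached as ``labeled_mass_kda`` so ``.labeled()`` works.
    """
    fix = load_fixture(name)
    if not isinstance(fix, ConstructFixture):
        raise KeyError(f"{name!r} is not a construct fixture")
    if basis not in ("theoretical", "experimental"):
        raise ValueError("basis must be 'theoretical' or 'experimental'")
    suffix = "_labeled_kda" if labeled else ("_cleaved_kda" if cleaved else "_kda")
    mass = getattr(fix, basis + suffix)
    if mass is None:
        raise ValueError(f"fixture {name!r} has no {basis}{suffix} value")
    labeled_mass = None if labeled else getattr(fix, basis + "_labeled_kda")
    return ComponentSpec(
        name=fix.name + ("*" if labeled else ""),
        role=role,
        mass_kda=float(mass),
        labeled_mass_kda=None if labeled_mass is None else float(labeled_mass),
    )


def lipids_per_disc(protein_to_lipid_ratio: float, scaffolds_per_disc: int = 2) -> float:
    """Expected lipid count per disc from the reconstitution ratio.

    ``protein_to_lipid_ratio`` is lipids per scaffold protein (a 1:100 mix
    ratio is passed as 100); a disc with two scaffold copies at 1:100 holds
    about 200 lipids.
    """
    if protein_to_lipid_ratio <= 0:
        raise ValueError("protein-to-lipid ratio must be positive")
    if scaffolds_per_disc < 1:
        raise ValueError("a disc carries at least one scaffold copy")
    return scaffolds_per_disc * protein_to_lipid_ratio


def _geometry(key: str) -> float:
    return float(_raw()["geometry"][key]["value"])


MSP1E3D1_DISC_AREA_NM2 = 113.0
PR_MONOMER_FOOTPRINT_NM2 = 6.0


def footprint_check(
    per_monomer_area_nm2: float,
    n: int,
    disc_area_nm2: float | None = None,
) -> FootprintResult:
    """Does an n-mer of the given membrane footprint fit in the disc bilayer?

    Defaults to the stored MSP1E3D1 disc area (113 nm²).
    """
    if per_monomer_area_nm2 <= 0 or n <= 0:
        raise ValueError("footprint and copy number must be positive")
    disc = _geometry("msp1e3d1_disc_area_nm2") if disc_area_nm2 is None else disc_area_nm2
    required = n * per_monomer_area_nm2
    return FootprintResult(required_nm2=required, disc_area_nm2=disc,
                           fits=required <= disc)
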