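"""Peak-to-species assignment and oligomer-distribution statistics.

Detected peaks are matched in mass-per-charge space against every candidate
species' charge ladder.  A peak with exactly one candidate within tolerance
is unique; one with several is ambiguous and is *never* silently dropped —
it propagates as its own "ambiguous" class through the distribution
statistics, mirroring how overlapped species are left unassigned rather
than guessed.  Oligomer distributions normalize per-peak integrals to the
overall assigned peak area within each replicate and report the mean and
sample standard deviation across replicates.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .complexes import ComplexSpecies
from .spectra import Peak

__all__ = [
    "AssignmentStatus",
    "Candidate",
    "Assignment",
    "OligomerDistribution",
    "LaserSeriesReport",
    "assign_peaks",
    "oligomer_distribution",
    "laser_series_report",
    "condition_comparison",
    "AMBIGUOUS_CLASS",
    "DEFAULT_PRESENCE_THRESHOLD",
]

#: Class label carried by peaks that match several species within tolerance.
AMBIGUOUS_CLASS = "ambiguous"

#: Minimum mean class fraction for an oligomeric state to be called present.
DEFAULT_PRESENCE_THRESHOLD = 0.02


class AssignmentStatus(enum.Enum):
    UNIQUE = "unique"
    AMBIGUOUS = "ambiguous"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Candidate:
    """One species/charge-state combination matching a peak."""

    species: ComplexSpecies
    z: int
    error_kda: float


@dataclass(frozen=True)
class Assignment:
    """A peak with its candidate matches, ordered best first."""

    peak: Peak
    candidates: tuple[Candidate, ...]
    status: AssignmentStatus
    tolerance_kda: float

    @property
    def best(self) -> Candidate | None:
        return self.candidates[0] if self.candidates else None


def assign_peaks(
    peaks: Sequence[Peak],
    species_list: Sequence[ComplexSpecies],
    tolerance_kda: float,
) -> list[Assignment]:
    """Match each peak against every species' charge ladder.

    A candidate is any (species, z) whose mass-per-charge lies within
    ``tolerance_kda`` of the peak apex.  Candidates are ordered by absolute
    mass error, then by fewest total protein copies (the more parsimonious
    stoichiometry wins ties).  Status is unique / ambiguous / unassigned for
    one / several / no candidates.
    """
    if tolerance_kda <= 0:
        raise ValueError("tolerance must be positive")
    if not species_list:
        raise ValueError("species list must not be empty")
    assignments = []
    for peak in peaks:
        candidates = []
        for sp in species_list:
            for z in range(1, sp.z_max + 1):
                err = peak.apex_kda - sp.mz(z)
                if abs(err) <= tolerance_kda:
                    candidates.append(Candidate(sp, z, err))
        candidates.sort(key=lambda c: (abs(c.error_kda), c.species.protein_copies))
        if not candidates:
            status = AssignmentStatus.UNASSIGNED
        elif len(candidates) == 1:
            status = AssignmentStatus.UNIQUE
        else:
            status = AssignmentStatus.AMBIGUOUS
        assignments.append(
            Assignment(peak, tuple(candidates), status, tolerance_kda)
        )
    return assignments


ClassKey = tuple[int, int] | str


def _default_grouping(species: ComplexSpecies) -> ClassKey:
    """Group by (target copies, scaffold copies), ignoring lipid adducts."""
    return (species.n, species.m)


@dataclass(frozen=True)
class OligomerDistribution:
    """Per-class mean fraction and sample SD across replicates.

    Fractions within each replicate are peak integrals normalized to the
    total assigned (plus ambiguous) peak area, so they sum to 1.  The SD is
    the n−1 sample standard deviation, 0 when only one replicate exists.
    """

    classes: Mapping[ClassKey, tuple[float, float]]
    n_replicates: int
    n_excluded: int = 0
    grouping: str = "nm"

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", dict(self.classes))

    def mean_fraction(self, key: ClassKey) -> float:
        return self.classes.get(key, (0.0, 0.0))[0]

    def sd(self, key: ClassKey) -> float:
        return self.classes.get(key, (0.0, 0.0))[1]

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for key, (mean, sd) in sorted(
            self.classes.items(), key=lambda kv: (isinstance(kv[0], str), kv[0])
        ):
            label = key if isinstance(key, str) else f"({key[0]},{key[1]})"
            rows.append({"class": label, "mean_fraction": mean, "sd": sd})
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "grouping": self.grouping,
            "n_replicates": self.n_replicates,
            "n_excluded": self.n_excluded,
            "classes": [
                {
                    "class": key if isinstance(key, str) else list(key),
                    "mean_fraction": mean,
                    "sd": sd,
                }
                for key, (mean, sd) in self.classes.items()
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def oligomer_distribution(
    assignments_per_replicate: Sequence[Sequence[Assignment]],
    grouping: Callable[[ComplexSpecies], ClassKey] | None = None,
    grouping_name: str = "nm",
) -> OligomerDistribution:
    """Oligomer-class fractions across replicates.

    Per replicate, each uniquely assigned peak contributes its integral to
    its species class (default class: target and scaffold copy numbers,
    lipid adducts ignored); ambiguous peaks contribute to the "ambiguous"
    class; unassigned peaks are excluded from the total.  Fractions are the
    class integrals over the summed assigned area.  A replicate with zero
    assigned area is excluded with a warning and counted in ``n_excluded``.
    """
    if not assignments_per_replicate:
        raise ValueError("need at least one replicate")
    group = grouping or _default_grouping
    per_replicate: list[dict[ClassKey, float]] = []
    n_excluded = 0
    for i, assignments in enumerate(assignments_per_replicate):
        integrals: dict[ClassKey, float] = {}
        for a in assignments:
            if a.status is AssignmentStatus.UNASSIGNED:
                continue
            key = (
                AMBIGUOUS_CLASS
                if a.status is AssignmentStatus.AMBIGUOUS
                else group(a.best.species)
            )
            integrals[key] = integrals.get(key, 0.0) + a.peak.integral
        total = sum(integrals.values())
        if total <= 0:
            warnings.warn(
                f"replicate {i}: no assigned peak area; replicate excluded",
                stacklevel=2,
            )
            n_excluded += 1
            continue
        per_replicate.append({k: v / total for k, v in integrals.items()})
    if not per_replicate:
        raise ValueError("every replicate had zero assigned peak area")

    keys = sorted(
        {k for rep in per_replicate for k in rep},
        key=lambda k: (isinstance(k, str), k),
    )
    classes = {}
    n_rep = len(per_replicate)
    for key in keys:
        values = np.array([rep.get(key, 0.0) for rep in per_replicate])
        sd = float(values.std(ddof=1)) if n_rep > 1 else 0.0
        classes[key] = (float(values.mean()), sd)
    return OligomerDistribution(
        classes=classes,
        n_replicates=n_rep,
        n_excluded=n_excluded,
        grouping=grouping_name,
    )


@dataclass(frozen=True)
class LaserSeriesReport:
    """Class fractions vs laser energy, with dissociation-trend flags.

    ``violations`` lists (class description, energy pair) where the
    expected monotonicity — scaffold-containing fractions non-increasing,
    scaffold-free fractions non-decreasing with energy — is broken.
    Violations are reported, never suppressed.
    """

    table: pd.DataFrame
    violations: tuple[str, ...]

    @property
    def trends_pass(self) -> bool:
        return not self.violations


def laser_series_report(
    distributions_by_energy: Mapping[float, OligomerDistribution],
    trend_slack: float = 0.0,
) -> LaserSeriesReport:
    """Tabulate class fractions against laser energy and flag trends.

    Requires at least two energy levels sharing one grouping mode.
    ``trend_slack`` allows a small tolerance before a monotonicity
    violation is flagged (0 by default: exact).
    """
    if len(distributions_by_energy) < 2:
        raise ValueError("need at least two laser-energy levels")
    groupings = {d.grouping for d in distributions_by_energy.values()}
    if len(groupings) != 1:
        raise ValueError("distributions use inconsistent groupings: "
                         + ", ".join(sorted(groupings)))
    energies = sorted(distributions_by_energy)
    keys = sorted(
        {k for d in distributions_by_energy.values() for k in d.classes},
        key=lambda k: (isinstance(k, str), k),
    )
    rows = []
    for key in keys:
        label = key if isinstance(key, str) else f"({key[0]},{key[1]})"
        row = {"class": label}
        for e in energies:
            row[f"E={e:g}mJ"] = distributions_by_energy[e].mean_fraction(key)
        rows.append(row)
    table = pd.DataFrame(rows)

    def aggregate(predicate) -> list[float]:
        return [
            sum(
                distributions_by_energy[e].mean_fraction(k)
                for k in keys
                if isinstance(k, tuple) and predicate(k)
            )
            for e in energies
        ]

    scaffolded = aggregate(lambda k: k[1] >= 1)
    free = aggregate(lambda k: k[1] == 0)
    violations = []
    for i in range(1, len(energies)):
        if scaffolded[i] > scaffolded[i - 1] + trend_slack:
            violations.append(
                f"scaffold-containing fraction rises from E={energies[i-1]:g} "
                f"to E={energies[i]:g} mJ ({scaffolded[i-1]:.4f} -> {scaffolded[i]:.4f})"
            )
        if free[i] < free[i - 1] - trend_slack:
            violations.append(
                f"scaffold-free fraction falls from E={energies[i-1]:g} "
                f"to E={energies[i]:g} mJ ({free[i-1]:.4f} -> {free[i]:.4f})"
            )
    return LaserSeriesReport(table=table, violations=tuple(violations))


def condition_comparison(
    distributions_by_condition: Mapping[str, OligomerDistribution],
    threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> pd.DataFrame:
    """Highest oligomeric state present per condition.

    For each condition, sums mean class fractions over scaffold counts and
    calls the highest target copy number ``n`` whose summed fraction exceeds
    ``threshold``.  Returns a side-by-side call table with one row per
    condition (columns: condition, call, fraction_at_call).
    """
    if not distributions_by_condition:
        raise ValueError("need at least one condition")
    groupings = {d.grouping for d in distributions_by_condition.values()}
    if len(groupings) != 1:
        raise ValueError("conditions use inconsistent groupings")
    rows = []
    for condition, dist in distributions_by_condition.items():
        by_n: dict[int, float] = {}
        for key, (mean, _sd) in dist.classes.items():
            if isinstance(key, tuple) and key[0] > 0:
                by_n[key[0]] = by_n.get(key[0], 0.0) + mean
        present = [n for n, frac in by_n.items() if frac > threshold]
        call = max(present) if present else 0
        rows.append(
            {
                "condition": condition,
                "call": call,
                "fraction_at_call": by_n.get(call, 0.0),
            }
        )
    return pd.DataFrame(rows)
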