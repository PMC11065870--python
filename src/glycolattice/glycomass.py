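"""Exact mass arithmetic for glycan residues, adducts and combinatorial ladders.

Intact glycoproteins carrying several complex N-glycans show mass heterogeneity
dominated by three repeating additions:

* fucosylation        (+Fuc,            146.14 Da average)
* sialylation         (+Neu5Ac,         291.26 Da average)
* antenna branching   (+GlcNAc1Gal1,    365.33 Da average)

Because 146.14 ≈ 2 × 73, 291.26 ≈ 4 × 73 and 365.33 ≈ 5 × 73, every
combination of these additions lands close to a lattice with a ~72.95 Da unit
spacing.  This module provides residue/adduct mass tables, glycan-composition
arithmetic, exhaustive ladder enumeration over residue-count ranges, repeat-unit
(lattice spacing) estimation, composition search for an observed mass
difference, and degeneracy detection for compositions that native MS cannot
tell apart at the intact level.

Average masses use the current IUPAC standard atomic weights (2021 abridged
values); monoisotopic masses use the CODATA/AME principal-isotope masses.
Every mass-returning API requires an explicit ``kind`` of ``"mono"`` or
``"average"`` — the two conventions differ by ~0.5 Da per residue and silent
defaults are a classic source of mis-annotation.
"""

from __future__ import annotations

import csv
import itertools
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "PROTON_MASS",
    "AVERAGE_ATOMIC_MASS",
    "MONOISOTOPIC_ATOMIC_MASS",
    "LATTICE_UNITS",
    "UnknownResidueError",
    "InsufficientDataError",
    "GlycanComposition",
    "ResidueTable",
    "AdductTable",
    "LadderEntry",
    "CompositionMatch",
    "residue_mass",
    "composition_mass",
    "enumerate_ladder",
    "repeat_unit",
    "find_compositions",
    "degeneracy_report",
]

#: Mass of a proton in Da, used for m/z <-> neutral-mass conversion
#: (positive-mode electrospray: m/z = (M + z * PROTON_MASS) / z).
PROTON_MASS = 1.00728

#: IUPAC 2021 standard (abridged) atomic weights, Da.
AVERAGE_ATOMIC_MASS: Dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

#: Principal-isotope (monoisotopic) masses, Da.
MONOISOTOPIC_ATOMIC_MASS: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

#: Number of ~73 Da lattice units contributed by one residue of each kind
#: (146.14 / 73 ≈ 2, 291.26 / 73 ≈ 4, 365.33 / 73 ≈ 5).
LATTICE_UNITS: Dict[str, int] = {"Fuc": 2, "Neu5Ac": 4, "branch": 5}

_KINDS = ("mono", "average")

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownResidueError(KeyError):
    """Raised when a residue or adduct name is not present in its table."""


class InsufficientDataError(ValueError):
    """Raised when an estimator is given too few points to be meaningful."""


def _check_kind(kind: str) -> str:
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    return kind


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a molecular formula like ``'C6H10O5'`` into element counts."""
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.group(0) == "":
            continue
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element = match.group(1)
        counts[element] = counts.get(element, 0) + int(match.group(2) or 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def formula_mass(composition: Mapping[str, int], kind: str) -> float:
    """Mass of an element-count composition under the selected atomic-weight set."""
    _check_kind(kind)
    table = AVERAGE_ATOMIC_MASS if kind == "average" else MONOISOTOPIC_ATOMIC_MASS
    try:
        return float(sum(table[el] * n for el, n in composition.items()))
    except KeyError as exc:  # pragma: no cover - defensive
        raise UnknownResidueError(f"no atomic mass for element {exc.args[0]!r}") from exc


class GlycanComposition(Mapping[str, int]):
    """Integer residue counts defining a glycoform mass delta.

    Behaves as an immutable mapping residue-name -> count; supports ``+`` for
    the union of two compositions (counts add).  Mass is strictly additive
    over counts and the empty composition has mass zero.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: Dict[str, int] = {}
        for source in (counts or {}, kwargs):
            for name, count in source.items():
                count = int(count)
                if count < 0:
                    raise ValueError(f"negative count for residue {name!r}: {count}")
                if count:
                    merged[name] = merged.get(name, 0) + count
        self._counts: Dict[str, int] = dict(sorted(merged.items()))

    def __getitem__(self, name: str) -> int:
        return self._counts.get(name, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        counts = dict(self._counts)
        for name, n in other.items():
            counts[name] = counts.get(name, 0) + n
        return GlycanComposition(counts)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, GlycanComposition):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}: {v}" for k, v in self._counts.items())
        return f"GlycanComposition({{{inner}}})"

    def __str__(self) -> str:
        return "".join(f"{k}{v}" for k, v in self._counts.items()) or "(none)"

    @property
    def total_residues(self) -> int:
        return sum(self._counts.values())

    def lattice_units(self) -> int:
        """Total ~73 Da lattice units (2 per Fuc, 4 per Neu5Ac, 5 per branch)."""
        return sum(LATTICE_UNITS.get(name, 0) * n for name, n in self._counts.items())

    def mass(self, kind: str, table: "ResidueTable | None" = None) -> float:
        return composition_mass(self, kind, table)

    def without(self, name: str) -> "GlycanComposition":
        """Copy with all residues of ``name`` removed."""
        return GlycanComposition({k: v for k, v in self._counts.items() if k != name})


@dataclass(frozen=True)
class ResidueTable:
    """Monosaccharide residue definitions: name -> element composition.

    The built-in entries are the four residue classes that dominate complex
    N-glycan heterogeneity, plus the named unit ``branch`` (one GlcNAc + one
    Gal antenna extension) whose composition is HexNAc + Hex exactly.
    """

    entries: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: dict(_BUILTIN_RESIDUES)
    )

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self) -> List[str]:
        return list(self.entries)

    def composition(self, name: str) -> Dict[str, int]:
        try:
            return dict(self.entries[name])
        except KeyError:
            raise UnknownResidueError(
                f"unknown residue {name!r}; known: {sorted(self.entries)}"
            ) from None

    def mass(self, name: str, kind: str) -> float:
        # compound residues are summed from their parts so that e.g.
        # mass("branch") == mass("HexNAc") + mass("Hex") holds exactly
        parts = _COMPOUND_RESIDUES.get(name)
        if parts is not None and name in self.entries:
            return sum(self.mass(p, kind) for p in parts)
        return formula_mass(self.composition(name), kind)

    @classmethod
    def default(cls) -> "ResidueTable":
        return cls()

    def with_residue(self, name: str, formula: str) -> "ResidueTable":
        entries = dict(self.entries)
        entries[name] = parse_formula(formula)
        return ResidueTable(entries)


_BUILTIN_RESIDUES: Dict[str, Dict[str, int]] = {
    "Hex": parse_formula("C6H10O5"),
    "HexNAc": parse_formula("C8H13NO5"),
    "Fuc": parse_formula("C6H10O4"),
    "Neu5Ac": parse_formula("C11H17NO8"),
}
# "branch" (GlcNAc1Gal1 antenna unit) is defined as HexNAc + Hex; its mass is
# computed as their sum exactly (see ResidueTable.mass).
_COMPOUND_RESIDUES = {"branch": ("HexNAc", "Hex")}
_BUILTIN_RESIDUES["branch"] = {
    el: _BUILTIN_RESIDUES["HexNAc"].get(el, 0) + _BUILTIN_RESIDUES["Hex"].get(el, 0)
    for el in set(_BUILTIN_RESIDUES["HexNAc"]) | set(_BUILTIN_RESIDUES["Hex"])
}

_DEFAULT_TABLE = ResidueTable()


@dataclass(frozen=True)
class AdductEntry:
    name: str
    mass: float  # average mass shift, Da
    adduct_class: str  # "PTM" | "lipid" | "detergent"

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"adduct {self.name!r} must have positive mass shift")


@dataclass(frozen=True)
class AdductTable:
    """Named mass shifts for PTMs, bound lipids and detergent monomers.

    Defaults cover the adducts recurrently seen on intact membrane-protein
    ions: phosphorylation (+HPO3), S-palmitoylation (+C16H30O), the weighted
    average masses of the endogenous phospholipid classes PE / PS / PI, and
    monomer masses of common neopentyl-glycol/steroid detergents whose
    incomplete stripping produces satellite tails.
    """

    entries: Mapping[str, AdductEntry] = field(
        default_factory=lambda: dict(_BUILTIN_ADDUCTS)
    )

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self) -> List[str]:
        return list(self.entries)

    def mass(self, name: str) -> float:
        try:
            return self.entries[name].mass
        except KeyError:
            raise UnknownResidueError(
                f"unknown adduct {name!r}; known: {sorted(self.entries)}"
            ) from None

    def adduct_class(self, name: str) -> str:
        try:
            return self.entries[name].adduct_class
        except KeyError:
            raise UnknownResidueError(f"unknown adduct {name!r}") from None

    def by_class(self, adduct_class: str) -> List[str]:
        return [n for n, e in self.entries.items() if e.adduct_class == adduct_class]

    def with_adduct(self, name: str, mass: float, adduct_class: str) -> "AdductTable":
        entries = dict(self.entries)
        entries[name] = AdductEntry(name, float(mass), adduct_class)
        return AdductTable(entries)

    @classmethod
    def default(cls) -> "AdductTable":
        return cls()

    # CSV round-trip is bit-exact: masses are written with repr() precision.
    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "mass_Da", "class"])
            for entry in self.entries.values():
                writer.writerow([entry.name, repr(entry.mass), entry.adduct_class])

    @classmethod
    def from_csv(cls, path) -> "AdductTable":
        entries: Dict[str, AdductEntry] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries[row["name"]] = AdductEntry(
                    row["name"], float(row["mass_Da"]), row["class"]
                )
        return cls(entries)


_BUILTIN_ADDUCTS: Dict[str, AdductEntry] = {
    e.name: e
    for e in [
        AdductEntry("phospho", 79.98, "PTM"),
        AdductEntry("palmitoyl", 238.41, "PTM"),
        AdductEntry("PE", 731.0, "lipid"),
        AdductEntry("PS", 796.0, "lipid"),
        AdductEntry("PI", 870.0, "lipid"),
        AdductEntry("OGNG", 568.74, "detergent"),
        AdductEntry("LMNG", 1005.19, "detergent"),
        AdductEntry("GDN", 1165.31, "detergent"),
    ]
}


@dataclass(frozen=True)
class LadderEntry:
    """One rung of a combinatorial glycan-addition ladder."""

    composition: GlycanComposition
    delta_mass: float  # Da above the unmodified anchor
    unit_count: int  # lattice units: 2*Fuc + 4*Neu5Ac + 5*branch


@dataclass(frozen=True)
class CompositionMatch:
    """A candidate composition for an observed mass difference."""

    composition: GlycanComposition
    mass: float
    error: float  # signed: composition mass minus the queried delta


def residue_mass(name: str, kind: str, table: ResidueTable | None = None) -> float:
    """Mass in Da of one residue under the ``"mono"`` or ``"average"`` convention.

    Raises
    ------
    UnknownResidueError
        If ``name`` is not in the residue table.
    """
    _check_kind(kind)
    return (table or _DEFAULT_TABLE).mass(name, kind)


def composition_mass(
    comp: Mapping[str, int], kind: str, table: ResidueTable | None = None
) -> float:
    """Additive mass of a glycan composition: sum of count x residue mass."""
    _check_kind(kind)
    table = table or _DEFAULT_TABLE
    total = 0.0
    for name, count in comp.items():
        count = int(count)
        if count < 0:
            raise ValueError(f"negative count for residue {name!r}")
        if count:
            total += count * table.mass(name, kind)
    return total


def _iter_range_grid(ranges: Mapping[str, int]) -> Iterable[GlycanComposition]:
    names = sorted(ranges)
    maxima = [int(ranges[n]) for n in names]
    if any(m < 0 for m in maxima):
        raise ValueError("residue range maxima must be non-negative")
    for counts in itertools.product(*(range(m + 1) for m in maxima)):
        yield GlycanComposition(dict(zip(names, counts)))


def enumerate_ladder(
    ranges: Mapping[str, int], kind: str, table: ResidueTable | None = None
) -> List[LadderEntry]:
    """All compositions within per-residue count maxima, sorted by delta mass.

    ``ranges`` maps residue name -> maximum count (inclusive).  An empty
    mapping yields the single zero-mass entry.
    """
    _check_kind(kind)
    entries = [
        LadderEntry(comp, composition_mass(comp, kind, table), comp.lattice_units())
        for comp in _iter_range_grid(ranges)
    ]
    entries.sort(key=lambda e: e.delta_mass)
    return entries


def _ladder_masses(ladder: Sequence[LadderEntry] | Sequence[float]) -> np.ndarray:
    if len(ladder) and isinstance(ladder[0], LadderEntry):
        masses = np.array([e.delta_mass for e in ladder], dtype=float)
    else:
        masses = np.asarray(ladder, dtype=float)
    return np.unique(masses)


def collapse_masses(masses: np.ndarray, merge_tol: float) -> np.ndarray:
    """Collapse near-degenerate masses to their (intensity-agnostic) centroids.

    Sorted masses are chained into one cluster while consecutive gaps stay
    within ``merge_tol``; each cluster is replaced by its plain mean.
    """
    masses = np.sort(np.asarray(masses, dtype=float))
    if masses.size == 0:
        return masses
    boundaries = np.flatnonzero(np.diff(masses) > merge_tol)
    clusters = np.split(masses, boundaries + 1)
    return np.array([c.mean() for c in clusters])


def repeat_unit(
    ladder: Sequence[LadderEntry] | Sequence[float],
    merge_tol: float = 1.5,
    fill_vacancies: bool = True,
) -> Tuple[float, float]:
    """Estimate the lattice repeat unit (mean spacing, sd) of a mass ladder.

    Masses within ``merge_tol`` of each other are collapsed to centroids, and
    the consecutive spacings of the collapsed ladder are averaged.  Real and
    theoretical combinatorial ladders have occasional vacant rungs (count
    combinations that no composition realizes), which would register as
    double/triple spacings; with ``fill_vacancies`` any gap near an integer
    multiple k >= 2 of the median gap is split into k equal sub-gaps before
    averaging.

    Returns
    -------
    (mean, sd) of the consecutive spacings in Da.  Fewer than 2 collapsed
    masses raises :class:`InsufficientDataError`.
    """
    masses = _ladder_masses(ladder)
    if masses.size < 3:
        raise InsufficientDataError("repeat_unit needs >= 3 distinct masses")
    collapsed = collapse_masses(masses, merge_tol)
    if collapsed.size < 2:
        raise InsufficientDataError(
            "fewer than 2 collapsed masses; merge_tol too large for this ladder"
        )
    gaps = np.diff(collapsed)
    if fill_vacancies and gaps.size >= 2:
        median_gap = float(np.median(gaps))
        split: List[float] = []
        for gap in gaps:
            k = max(1, int(round(gap / median_gap)))
            split.extend([gap / k] * k)
        gaps = np.asarray(split)
    mean = float(np.mean(gaps))
    sd = float(np.std(gaps, ddof=1)) if gaps.size > 1 else 0.0
    return mean, sd


def find_compositions(
    delta: float,
    tol: float,
    ranges: Mapping[str, int],
    kind: str,
    table: ResidueTable | None = None,
) -> List[CompositionMatch]:
    """Exhaustive candidate compositions for an observed mass difference.

    Brute-force enumeration over the residue-count grid defined by ``ranges``;
    every composition with |mass - delta| <= tol is returned, sorted by
    absolute error, then fewest total residues, then lexicographic residue
    order (deterministic output).  The error is signed (mass - delta).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    _check_kind(kind)
    matches = []
    for comp in _iter_range_grid(ranges):
        mass = composition_mass(comp, kind, table)
        err = mass - delta
        if abs(err) <= tol:
            matches.append(CompositionMatch(comp, mass, err))
    matches.sort(
        key=lambda m: (
            abs(m.error),
            m.composition.total_residues,
            tuple(m.composition.items()),
        )
    )
    return matches


def degeneracy_report(
    ladder: Sequence[LadderEntry], tol: float
) -> List[Dict[str, object]]:
    """Group ladder entries whose masses are indistinguishable within ``tol``.

    Grouping is transitive (single linkage on consecutive gaps), mirroring how
    overlapping peaks merge in a spectrum.  Each group reports its member
    compositions, masses, and the pairwise mass gaps.  ``tol <= 0`` returns
    every entry as its own group.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    entries = sorted(ladder, key=lambda e: e.delta_mass)
    groups: List[List[LadderEntry]] = []
    for entry in entries:
        if (
            groups
            and tol > 0
            and entry.delta_mass - groups[-1][-1].delta_mass <= tol
        ):
            groups[-1].append(entry)
        else:
            groups.append([entry])
    report = []
    for gid, members in enumerate(groups):
        masses = [m.delta_mass for m in members]
        pairwise = [
            abs(a - b) for i, a in enumerate(masses) for b in masses[i + 1 :]
        ]
        report.append(
            {
                "group_id": gid,
                "compositions": [m.composition for m in members],
                "masses": masses,
                "pairwise_gaps": pairwise,
            }
        )
    return report


def report_to_rows(
    matches: Sequence[CompositionMatch], delta: float, group_id: int | None = None
) -> List[Dict[str, object]]:
    """Flatten composition matches into CSV-ready rows."""
    return [
        {
            "delta_Da": delta,
            "composition": str(m.composition),
            "error_Da": m.error,
            "group_id": group_id if group_id is not None else "",
        }
        for m in matches
    ]
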