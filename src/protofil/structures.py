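"""Core domain types: atoms, residues, protomers, dimer frames, trajectories.

A :class:`Protomer` is one FtsZ subunit — an ordered list of residues, each
holding its atoms.  A :class:`DimerFrame` is one MD snapshot of the two
subunits; a :class:`Trajectory` is a uniformly spaced series of frames.
Coordinates are in Angstroms, masses in daltons, times in nanoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .errors import StructureError

# Monoisotopic-ish average masses for elements common in protein MD systems.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "MG": 24.305,
    "K": 39.098,
    "NA": 22.990,
    "CL": 35.45,
    "CA": 40.078,  # calcium, only via an explicit element column
    "FE": 55.845,
    "ZN": 65.38,
}

#: Named atom selections. ``None`` selects every atom.
SELECTIONS: dict[str, Callable[["Atom"], bool]] = {
    "all": lambda a: True,
    "heavy": lambda a: not a.is_hydrogen,
    "CA": lambda a: a.name == "CA",
    "backbone": lambda a: a.name in ("N", "CA", "C", "O"),
}

Selection = str | Iterable[str] | None


def element_from_name(name: str) -> str:
    """Infer an element symbol from a PDB atom name when no element column exists.

    Protein/MD conventions: a leading digit or 'H' means hydrogen ("1HB", "HG1");
    otherwise the first letter is the element ("CA" is an alpha carbon here —
    metals only ever arrive through an explicit element column).
    """
    raw = name.strip()
    if not raw:
        return "C"
    if raw[0].isdigit():
        return "H"
    return raw[0].upper()


def resolve_selection(selection: Selection) -> Callable[["Atom"], bool]:
    """Turn a selection spec (name, iterable of atom names, or None) into a predicate."""
    if selection is None:
        return SELECTIONS["all"]
    if isinstance(selection, str):
        if selection in SELECTIONS:
            return SELECTIONS[selection]
        wanted = {selection}
        return lambda a: a.name in wanted
    wanted = {str(s) for s in selection}
    return lambda a: a.name in wanted


@dataclass(slots=True)
class Atom:
    serial: int
    name: str
    element: str
    mass: float
    coords: np.ndarray  # shape (3,), Angstrom
    is_hydrogen: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.serial} {self.name!r}: coords must be a finite 3-vector")
        if not self.mass > 0:
            raise StructureError(f"atom {self.serial} {self.name!r}: mass must be positive")


@dataclass(slots=True)
class Residue:
    chain_id: str
    resseq: int  # author (PDB) numbering, 1-based — Arg67/Asp97/Gly193 live here
    resname: str
    atoms: list[Atom]

    def __post_init__(self):
        if not self.atoms:
            raise StructureError(f"residue {self.chain_id}{self.resseq} has no atoms")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resseq, self.resname)

    def coords(self, selection: Selection = None) -> np.ndarray:
        pred = resolve_selection(selection)
        return np.array([a.coords for a in self.atoms if pred(a)], dtype=float).reshape(-1, 3)

    def center_of_mass(self, heavy_only: bool = True) -> np.ndarray:
        atoms = [a for a in self.atoms if not (heavy_only and a.is_hydrogen)]
        if not atoms:
            raise StructureError(f"residue {self.chain_id}{self.resseq}: no atoms left after selection")
        masses = np.array([a.mass for a in atoms])
        xyz = np.array([a.coords for a in atoms])
        return masses @ xyz / masses.sum()


@dataclass
class Protomer:
    """One subunit: residues sorted by resseq, each (chain_id, resseq) unique."""

    label: str
    residues: list[Residue]
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        if not self.residues:
            raise StructureError(f"protomer {self.label!r} is empty")
        seqs = [r.resseq for r in self.residues]
        if any(b <= a for a, b in zip(seqs, seqs[1:])):
            self.residues = sorted(self.residues, key=lambda r: r.resseq)
            seqs = [r.resseq for r in self.residues]
        if len(set(seqs)) != len(seqs):
            raise StructureError(f"protomer {self.label!r}: duplicate resseq")

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def get_residue(self, resseq: int) -> Residue | None:
        for r in self.residues:
            if r.resseq == resseq:
                return r
        return None

    def atoms(self) -> Iterator[Atom]:
        for r in self.residues:
            yield from r.atoms

    def coords(self, selection: Selection = None) -> np.ndarray:
        pred = resolve_selection(selection)
        return np.array(
            [a.coords for r in self.residues for a in r.atoms if pred(a)], dtype=float
        ).reshape(-1, 3)

    def centroid(self, selection: Selection = "CA") -> np.ndarray:
        xyz = self.coords(selection)
        if xyz.shape[0] == 0:
            raise StructureError(f"protomer {self.label!r}: empty selection {selection!r}")
        return xyz.mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray, label: str | None = None) -> "Protomer":
        """Return a copy with every atom mapped through x -> R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new_res = []
        for r in self.residues:
            new_atoms = [
                Atom(a.serial, a.name, a.element, a.mass, R @ a.coords + t, a.is_hydrogen)
                for a in r.atoms
            ]
            new_res.append(Residue(r.chain_id, r.resseq, r.resname, new_atoms))
        return Protomer(label if label is not None else self.label, new_res)


@dataclass
class DimerFrame:
    """Two protomers at one time point."""

    time_ns: float
    subunit_a: Protomer
    subunit_b: Protomer

    def __post_init__(self):
        if self.time_ns < 0:
            raise StructureError("frame time must be non-negative")

    def matched_coords(
        self, selection: Selection = "CA"
    ) -> tuple[np.ndarray, np.ndarray, list[tuple[int, str]]]:
        """Coordinates of atoms matched by (resseq, atom name) across subunits.

        Returns (coords_a, coords_b, keys) with identical row ordering.
        """
        pred = resolve_selection(selection)
        index_b: dict[tuple[int, str], np.ndarray] = {}
        for r in self.subunit_b.residues:
            for a in r.atoms:
                if pred(a):
                    index_b[(r.resseq, a.name)] = a.coords
        xa, xb, keys = [], [], []
        for r in self.subunit_a.residues:
            for a in r.atoms:
                if pred(a) and (r.resseq, a.name) in index_b:
                    xa.append(a.coords)
                    xb.append(index_b[(r.resseq, a.name)])
                    keys.append((r.resseq, a.name))
        return (
            np.array(xa, float).reshape(-1, 3),
            np.array(xb, float).reshape(-1, 3),
            keys,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "DimerFrame":
        """Rigidly move the whole frame (both subunits together)."""
        return DimerFrame(
            self.time_ns,
            self.subunit_a.transformed(rotation, translation),
            self.subunit_b.transformed(rotation, translation),
        )


@dataclass
class Trajectory:
    """Ordered, uniformly spaced series of dimer frames."""

    frames: list[DimerFrame]
    dt_ns: float

    def __post_init__(self):
        if not self.frames:
            raise StructureError("trajectory has no frames")
        times = np.array([f.time_ns for f in self.frames])
        if len(times) > 1:
            if np.any(np.diff(times) <= 0):
                raise StructureError("frame times must be strictly increasing")
            if np.max(np.abs(np.diff(times) - self.dt_ns)) > 1e-9:
                raise StructureError("frame spacing is not uniform within 1e-9 ns")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[DimerFrame]:
        return iter(self.frames)

    def __getitem__(self, k: int) -> DimerFrame:
        return self.frames[k]

    @property
    def times_ns(self) -> np.ndarray:
        return np.array([f.time_ns for f in self.frames])

    @property
    def duration_ns(self) -> float:
        """Total span covered, counting each frame as one dt-wide sample."""
        return len(self.frames) * self.dt_ns


def build_protomer(
    label: str,
    chain_id: str,
    residue_specs: Sequence[tuple[int, str, Sequence[tuple[str, np.ndarray]]]],
) -> Protomer:
    """Convenience constructor from (resseq, resname, [(atom_name, xyz), ...]) tuples."""
    residues = []
    serial = 1
    for resseq, resname, atoms in residue_specs:
        atom_objs = []
        for name, xyz in atoms:
            el = element_from_name(name)
            atom_objs.append(
                Atom(serial, name, el, ATOMIC_MASSES.get(el, 12.011), np.asarray(xyz, float), el == "H")
            )
            serial += 1
        residues.append(Residue(chain_id, resseq, resname, atom_objs))
    return Protomer(label, residues)
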