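"""Extrapolate a dimer's interface transform into an n-subunit filament model.

Repeating the subunit A -> subunit B rigid map k times places subunit k of a
protofilament; the map's screw parameters are the filament's helical twist
and rise per subunit.  A 14-subunit filament is the default rendering length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError
from .geometry import (
    DEFAULT_SELECTION,
    RigidTransform,
    ScrewParameters,
    interface_transform,
    screw_decompose,
)
from .structures import DimerFrame, Protomer, Selection


@dataclass(frozen=True)
class HelixParameters:
    twist_per_subunit_deg: float
    rise_per_subunit_A: float
    subunits_per_turn: float  # inf for an untwisted (straight) filament
    helix_radius_A: float


@dataclass
class FilamentModel:
    """Subunit copies generated by repeated application of one rigid map."""

    subunits: list[Protomer]
    generator: RigidTransform
    screw: ScrewParameters
    helix: HelixParameters

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)

    def centroids(self, selection: Selection = DEFAULT_SELECTION) -> np.ndarray:
        return np.array([s.centroid(selection) for s in self.subunits])


def helix_parameters(screw: ScrewParameters, subunit_centroid: np.ndarray) -> HelixParameters:
    twist = screw.angle_deg
    per_turn = math.inf if twist == 0 else 360.0 / abs(twist)
    rel = np.asarray(subunit_centroid, float) - screw.axis_point
    radial = rel - (rel @ screw.axis) * screw.axis
    return HelixParameters(twist, screw.rise_A, per_turn, float(np.linalg.norm(radial)))


def extrapolate_filament(
    frame: DimerFrame,
    n_subunits: int = 14,
    selection: Selection = DEFAULT_SELECTION,
    anchor: str = "a",
) -> FilamentModel:
    """Build an n-subunit filament by repeating the dimer's interface transform.

    Subunit 0 is the anchoring protomer of ``frame`` (subunit A by default;
    ``anchor="b"`` grows from subunit B with the inverse map); subunit k is
    the k-fold application of the generator.  Raises
    :class:`GeometryError` if the transform is degenerate (rotation < 0.01 deg
    and rise < 0.01 A): the subunits would superimpose.
    """
    if n_subunits < 2:
        raise GeometryError("a filament needs at least 2 subunits")
    if anchor not in ("a", "b"):
        raise GeometryError(f"anchor must be 'a' or 'b', got {anchor!r}")
    gen = interface_transform(frame, selection)
    seed = frame.subunit_a
    if anchor == "b":
        gen = gen.inverse()
        seed = frame.subunit_b
    screw = screw_decompose(gen)
    if abs(screw.angle_deg) < 0.01 and screw.rise_A < 0.01:
        raise GeometryError("degenerate interface transform: subunits would superimpose")
    subunits = [seed.transformed(np.eye(3), np.zeros(3), label="0")]
    current = RigidTransform.identity()
    for k in range(1, n_subunits):
        current = gen.compose(current)
        subunits.append(seed.transformed(current.rotation, current.translation, label=str(k)))
    helix = helix_parameters(screw, seed.centroid(selection))
    return FilamentModel(subunits, gen, screw, helix)


def clash_report(
    model: FilamentModel, cutoff_A: float = 2.0
) -> list[tuple[int, int, float]]:
    """Non-adjacent subunit pairs with any interatomic distance below cutoff.

    Adjacent subunits are exempt — they share the physical interface.  An
    empty list means the extrapolated model is sterically plausible.
    """
    if model.n_subunits < 2:
        raise GeometryError("clash report needs at least 2 subunits")
    coords = [s.coords(None) for s in model.subunits]
    trees = [cKDTree(c) for c in coords]
    clashes = []
    for i in range(model.n_subunits):
        for j in range(i + 2, model.n_subunits):
            d = trees[i].query(coords[j], k=1)[0].min()
            if d < cutoff_A:
                clashes.append((i, j, float(d)))
    return clashes
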