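"""Cross-subunit residue contacts, block occupancy, and temporal classification.

A residue pair is "in contact" in a frame when the minimum distance between
their (heavy, by default) atoms is below a cutoff — 5 A is the convention
used throughout.  Per-pair contact fractions are aggregated in fixed-width
time blocks (12.5 ns by default); a pair counts as *present* in a block when
its occupancy reaches a threshold (0.5).  Comparing a wild-type-like and a
variant-like run, pairs are then classified into three temporal groups:

* ``nontwisted_specific`` — present early (a block fully inside the first
  100 ns) in the WT run, absent from every WT block starting at/after 150 ns,
  and absent from the variant run entirely;
* ``twisted_general`` — present in every variant block and in every WT block
  starting at/after 150 ns;
* ``variant_specific`` — present somewhere in the variant run and nowhere in
  the WT run;
* everything else is ``unclassified``.

The three rules are mutually exclusive whenever the runs have at least one
variant block and one late WT block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError, PartialBlockWarning, StructureError
from .structures import DimerFrame, Trajectory

ResidueKey = tuple[str, int, str]  # (chain_id, resseq, resname)
PairKey = tuple[ResidueKey, ResidueKey]

LABELS = ("nontwisted_specific", "twisted_general", "variant_specific", "unclassified")


def _selected(frame: DimerFrame, heavy_only: bool):
    """Per-subunit coordinate arrays plus residue index per atom."""
    out = []
    for sub in (frame.subunit_a, frame.subunit_b):
        coords, ridx, keys = [], [], []
        for i, res in enumerate(sub.residues):
            keys.append(res.key)
            for a in res.atoms:
                if heavy_only and a.is_hydrogen:
                    continue
                coords.append(a.coords)
                ridx.append(i)
        out.append((np.asarray(coords, float).reshape(-1, 3), np.asarray(ridx, int), keys))
    return out


def find_contacts(
    frame: DimerFrame,
    cutoff_A: float = 5.0,
    heavy_only: bool = True,
    method: str = "kdtree",
) -> dict[PairKey, float]:
    """All cross-subunit residue pairs whose closest atoms lie within cutoff.

    Returns {((chain, resseq, resname)_a, (..)_b): min_distance_A} for pairs
    with min distance strictly below ``cutoff_A``.  ``method`` selects the
    k-d-tree implementation or the O(N^2) brute-force reference; both give
    identical results.
    """
    (ca, ra, keys_a), (cb, rb, keys_b) = _selected(frame, heavy_only)
    if ca.shape[0] == 0 or cb.shape[0] == 0:
        return {}
    best: dict[tuple[int, int], float] = {}
    if method == "kdtree":
        pairs = cKDTree(ca).sparse_distance_matrix(cKDTree(cb), cutoff_A, output_type="coo_matrix")
        for i, j, d in zip(pairs.row, pairs.col, pairs.data):
            key = (ra[i], rb[j])
            if d < best.get(key, np.inf):
                best[key] = d
    elif method == "brute":
        from scipy.spatial.distance import cdist

        D = cdist(ca, cb)
        for i in range(ca.shape[0]):
            for j in range(cb.shape[0]):
                d = D[i, j]
                if d <= cutoff_A:
                    key = (ra[i], rb[j])
                    if d < best.get(key, np.inf):
                        best[key] = d
    else:
        raise ConfigurationError(f"unknown contact method {method!r}")
    return {
        (keys_a[i], keys_b[j]): float(d) for (i, j), d in best.items() if d < cutoff_A
    }


def contact_count_series(
    traj: Trajectory, cutoff_A: float = 5.0, heavy_only: bool = True
) -> np.ndarray:
    """Number of in-contact residue pairs in every frame."""
    return np.array(
        [len(find_contacts(f, cutoff_A, heavy_only)) for f in traj], dtype=int
    )


@dataclass
class OccupancyMatrix:
    """Per-pair contact fraction in fixed-width time blocks."""

    pairs: list[PairKey]
    block_edges_ns: np.ndarray  # length n_blocks + 1, uniform width
    occupancy: np.ndarray  # (n_pairs, n_blocks), fractions in [0, 1]
    frames_per_block: np.ndarray
    presence_threshold: float = 0.5

    @property
    def block_ns(self) -> float:
        return float(self.block_edges_ns[1] - self.block_edges_ns[0])

    @property
    def n_blocks(self) -> int:
        return len(self.block_edges_ns) - 1

    def presence(self) -> np.ndarray:
        """Boolean (n_pairs, n_blocks): occupancy >= threshold."""
        return self.occupancy >= self.presence_threshold

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "resseq_a": [p[0][1] for p in self.pairs],
            "resname_a": [p[0][2] for p in self.pairs],
            "resseq_b": [p[1][1] for p in self.pairs],
            "resname_b": [p[1][2] for p in self.pairs],
        }
        for b in range(self.n_blocks):
            lo, hi = self.block_edges_ns[b], self.block_edges_ns[b + 1]
            cols[f"occ_{lo:g}_{hi:g}ns"] = self.occupancy[:, b]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def occupancy_matrix(
    traj: Trajectory,
    block_ns: float = 12.5,
    cutoff_A: float = 5.0,
    presence_threshold: float = 0.5,
    heavy_only: bool = True,
) -> OccupancyMatrix:
    """Block-averaged contact occupancy over a trajectory.

    Each frame samples one dt-wide slice of time; blocks are half-open
    [t, t + block_ns).  A trailing partial block shorter than half a block is
    dropped (with a warning); a longer one is kept.
    """
    duration = traj.duration_ns
    if duration + 1e-9 < block_ns:
        raise ConfigurationError(
            f"trajectory spans {duration:g} ns < one {block_ns:g} ns block"
        )
    n_full = int(np.floor(duration / block_ns + 1e-9))
    remainder = duration - n_full * block_ns
    n_blocks = n_full + (1 if remainder >= 0.5 * block_ns - 1e-9 else 0)
    per_frame = [find_contacts(f, cutoff_A, heavy_only) for f in traj]
    block_of = np.floor(traj.times_ns / block_ns + 1e-9).astype(int)
    kept = block_of < n_blocks
    if not np.all(kept):
        warnings.warn(
            f"dropped {int((~kept).sum())} frame(s) in a trailing partial block "
            f"({remainder:g} ns < half of {block_ns:g} ns)",
            PartialBlockWarning,
            stacklevel=2,
        )
    pairs = sorted({p for contacts in per_frame for p in contacts})
    index = {p: i for i, p in enumerate(pairs)}
    counts = np.zeros((len(pairs), n_blocks))
    frames_per_block = np.zeros(n_blocks, dtype=int)
    for k, contacts in enumerate(per_frame):
        if not kept[k]:
            continue
        b = block_of[k]
        frames_per_block[b] += 1
        for p in contacts:
            counts[index[p], b] += 1
    occ = counts / np.maximum(frames_per_block, 1)
    edges = np.arange(n_blocks + 1) * block_ns
    return OccupancyMatrix(pairs, edges, occ, frames_per_block, presence_threshold)


@dataclass
class ContactClassification:
    """Temporal label per residue pair (keyed by (resseq_a, resseq_b))."""

    labels: dict[tuple[int, int], str]
    resnames: dict[tuple[int, int], tuple[str, str]] = field(default_factory=dict)

    def group(self, label: str) -> list[tuple[int, int]]:
        return sorted(k for k, v in self.labels.items() if v == label)

    def counts(self) -> dict[str, int]:
        return {lab: sum(1 for v in self.labels.values() if v == lab) for lab in LABELS}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (sa, sb), lab in sorted(self.labels.items()):
            na, nb = self.resnames.get((sa, sb), ("", ""))
            rows.append(
                {"resseq_a": sa, "resname_a": na, "resseq_b": sb, "resname_b": nb, "label": lab}
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _presence_by_resseq(occ: OccupancyMatrix) -> dict[tuple[int, int], np.ndarray]:
    pres = occ.presence()
    return {(p[0][1], p[1][1]): pres[i] for i, p in enumerate(occ.pairs)}


def classify_contacts(
    occ_wt: OccupancyMatrix,
    occ_variant: OccupancyMatrix,
    early_end_ns: float = 100.0,
    late_start_ns: float = 150.0,
) -> ContactClassification:
    """Apply the three temporal rules to a WT-like and a variant-like run.

    The pair universe is the union of both runs' pairs, keyed by
    (resseq_a, resseq_b) — residue identity at a mutated position may differ
    between runs, the interface position does not.  A pair absent from a run
    is treated as never present there.
    """
    if abs(occ_wt.block_ns - occ_variant.block_ns) > 1e-9:
        raise ConfigurationError(
            f"block widths differ: {occ_wt.block_ns} vs {occ_variant.block_ns} ns"
        )
    pres_wt = _presence_by_resseq(occ_wt)
    pres_var = _presence_by_resseq(occ_variant)
    starts_wt = occ_wt.block_edges_ns[:-1]
    ends_wt = occ_wt.block_edges_ns[1:]
    early_wt = (starts_wt >= 0) & (ends_wt <= early_end_ns + 1e-9)
    late_wt = starts_wt >= late_start_ns - 1e-9
    n_var_blocks = occ_variant.n_blocks

    labels: dict[tuple[int, int], str] = {}
    resnames: dict[tuple[int, int], tuple[str, str]] = {}
    universe = set(pres_wt) | set(pres_var)
    for key in universe:
        wt = pres_wt.get(key, np.zeros(occ_wt.n_blocks, dtype=bool))
        var = pres_var.get(key, np.zeros(n_var_blocks, dtype=bool))
        wt_any = bool(wt.any())
        wt_early = bool(wt[early_wt].any())
        wt_late_any = bool(wt[late_wt].any())
        wt_late_all = bool(wt[late_wt].all()) and late_wt.any()
        var_any = bool(var.any())
        var_all = bool(var.all()) and n_var_blocks > 0
        if wt_early and not wt_late_any and not var_any:
            labels[key] = "nontwisted_specific"
        elif var_all and wt_late_all:
            labels[key] = "twisted_general"
        elif var_any and not wt_any:
            labels[key] = "variant_specific"
        else:
            labels[key] = "unclassified"
    for occ in (occ_variant, occ_wt):  # WT resnames win where both exist
        for p in occ.pairs:
            resnames[(p[0][1], p[1][1])] = (p[0][2], p[1][2])
    return ContactClassification(labels, resnames)


@dataclass
class SaltBridgeTrace:
    """Center-of-mass distance between one subunit-A and one subunit-B residue."""

    res_a: ResidueKey
    res_b: ResidueKey
    times_ns: np.ndarray
    com_distance_A: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times_ns, "distance_A": self.com_distance_A})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def residue_com_distance(
    traj: Trajectory, resseq_a: int, resseq_b: int, heavy_only: bool = True
) -> SaltBridgeTrace:
    """Per-frame distance between the mass-weighted centers of two residues.

    ``resseq_a`` names a residue of subunit A, ``resseq_b`` one of subunit B
    (the Arg67-Asp97 cross-interface bridge geometry).
    """
    dists = np.empty(len(traj))
    key_a = key_b = None
    for k, frame in enumerate(traj):
        ra = frame.subunit_a.get_residue(resseq_a)
        rb = frame.subunit_b.get_residue(resseq_b)
        if ra is None:
            raise StructureError(f"frame {k}: residue {resseq_a} absent from subunit A")
        if rb is None:
            raise StructureError(f"frame {k}: residue {resseq_b} absent from subunit B")
        dists[k] = np.linalg.norm(
            ra.center_of_mass(heavy_only) - rb.center_of_mass(heavy_only)
        )
        key_a, key_b = ra.key, rb.key
    return SaltBridgeTrace(key_a, key_b, traj.times_ns, dists)
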