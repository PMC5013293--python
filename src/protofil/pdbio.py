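"""Fixed-column PDB reading and writing.

Covers the dialects this package needs: single-model two-chain dimers,
MODEL/ENDMDL multi-model trajectories, and multi-chain filament output.
Parsing is tolerant of trailing whitespace and of a missing element column
(the element is then inferred from the atom name); altlocs beyond the first
are dropped with a warning, as are insertion-code duplicates — MD-derived
structures never carry either.
"""

from __future__ import annotations

import io
import warnings
from pathlib import Path

import numpy as np

from .errors import AltlocDroppedWarning, ConfigurationError, PDBParseError, StructureError
from .filament import FilamentModel
from .structures import (
    ATOMIC_MASSES,
    Atom,
    DimerFrame,
    Protomer,
    Residue,
    Trajectory,
    element_from_name,
)

_CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def _as_lines(source) -> list[str]:
    """Accept a path, raw PDB text, or a file-like object."""
    if isinstance(source, Path):
        return source.read_text().splitlines()
    if hasattr(source, "read"):
        return source.read().splitlines()
    if isinstance(source, str):
        if "\n" in source or source.lstrip().startswith(("ATOM", "HETATM", "MODEL")):
            return source.splitlines()
        return Path(source).read_text().splitlines()
    raise TypeError(f"unsupported PDB source type {type(source)!r}")


def _parse_atom_line(line: str, lineno: int):
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError("ATOM/HETATM record shorter than the coordinate columns", lineno)
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip()
        resseq = int(line[22:26])
        icode = line[26].strip()
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    except ValueError as exc:
        raise PDBParseError(f"malformed fixed columns ({exc})", lineno) from None
    element = line[76:78].strip().upper() if len(line) >= 77 else ""
    if not element or element.isdigit():
        element = element_from_name(name)
    return serial, name, altloc, resname, chain_id, resseq, icode, xyz, element


def _parse_model(lines: list[tuple[int, str]]) -> dict[str, list[Residue]]:
    """Parse one model's ATOM/HETATM lines into chains of residues (file order)."""
    chains: dict[str, list[Residue]] = {}
    current: dict[str, Residue] = {}  # chain -> residue being filled
    seen_atoms: set[tuple[str, int, str]] = set()
    dropped_altloc = 0
    for lineno, line in lines:
        serial, name, altloc, resname, chain_id, resseq, icode, xyz, element = _parse_atom_line(
            line, lineno
        )
        key = (chain_id, resseq, name)
        if key in seen_atoms:
            # second altloc / insertion-code duplicate of an atom we already have
            dropped_altloc += 1
            continue
        seen_atoms.add(key)
        atom = Atom(
            serial,
            name,
            element,
            ATOMIC_MASSES.get(element, 12.011),
            xyz,
            element == "H",
        )
        res = current.get(chain_id)
        if res is not None and res.resseq == resseq and res.resname == resname:
            res.atoms.append(atom)
        else:
            res = Residue(chain_id, resseq, resname, [atom])
            chains.setdefault(chain_id, []).append(res)
            current[chain_id] = res
    if dropped_altloc:
        warnings.warn(
            f"dropped {dropped_altloc} alternate-location/duplicate atom record(s); first kept",
            AltlocDroppedWarning,
            stacklevel=3,
        )
    return chains


def _split_models(lines: list[str]) -> list[list[tuple[int, str]]]:
    models: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] = []
    in_model = False
    saw_model_record = False
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model_record = True
            in_model = True
            current = []
        elif rec == "ENDMDL":
            in_model = False
            models.append(current)
            current = []
        elif rec in ("ATOM", "HETATM"):
            current.append((lineno, line))
    if not saw_model_record:
        return [current] if current else []
    if in_model and current:
        models.append(current)  # unterminated final MODEL
    return models


def _chains_to_dimer(
    chains: dict[str, list[Residue]],
    chain_map: tuple[str, str] | None,
    time_ns: float,
) -> DimerFrame:
    if chain_map is None:
        ids = list(chains)
        if len(ids) != 2:
            raise ConfigurationError(
                f"structure has {len(ids)} chain(s) {ids}; supply an explicit two-chain mapping"
            )
        chain_map = (ids[0], ids[1])
    for cid in chain_map:
        if cid not in chains:
            raise ConfigurationError(
                f"requested chain {cid!r} not present (available: {sorted(chains)})"
            )
    a = Protomer(chain_map[0], chains[chain_map[0]])
    b = Protomer(chain_map[1], chains[chain_map[1]])
    return DimerFrame(time_ns, a, b)


def read_structure(source, chains: tuple[str, str] | None = None) -> DimerFrame:
    """Read a single-model PDB dimer into a :class:`DimerFrame` at t = 0.

    ``chains`` optionally names (subunit_a, subunit_b); without it the file
    must contain exactly two chains, taken in order of appearance.
    """
    lines = _as_lines(source)
    models = _split_models(lines)
    if not models:
        raise PDBParseError("no ATOM/HETATM records found")
    parsed = _parse_model(models[0])
    return _chains_to_dimer(parsed, chains, 0.0)


def read_trajectory(
    source, dt_ns: float = 0.5, chains: tuple[str, str] | None = None
) -> Trajectory:
    """Read a MODEL/ENDMDL multi-model PDB as a trajectory; frame k gets time k*dt_ns.

    PDB files carry no time axis, so the frame spacing is a user input.
    A single-model file yields a length-1 trajectory.
    """
    if dt_ns <= 0:
        raise ConfigurationError("dt_ns must be positive")
    lines = _as_lines(source)
    models = _split_models(lines)
    if not models:
        raise PDBParseError("no ATOM/HETATM records found")
    frames: list[DimerFrame] = []
    n_atoms_ref: int | None = None
    for k, model_lines in enumerate(models):
        parsed = _parse_model(model_lines)
        frame = _chains_to_dimer(parsed, chains, k * dt_ns)
        n_atoms = frame.subunit_a.n_atoms + frame.subunit_b.n_atoms
        if n_atoms_ref is None:
            n_atoms_ref = n_atoms
        elif n_atoms != n_atoms_ref:
            raise StructureError(
                f"model {k + 1}: atom count {n_atoms} differs from model 1 ({n_atoms_ref})"
            )
        frames.append(frame)
    return Trajectory(frames, dt_ns)


def _format_atom_line(
    serial: int, atom: Atom, resname: str, chain_id: str, resseq: int
) -> str:
    name = atom.name
    # 1-3 character names start one column in (PDB convention)
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"ATOM  {serial % 100000:5d} {name_field} {resname:>3s} {chain_id}{resseq:4d}    "
        f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
    )


def _protomer_lines(protomer: Protomer, chain_id: str, serial_start: int) -> tuple[list[str], int]:
    lines = []
    serial = serial_start
    for res in protomer.residues:
        for atom in res.atoms:
            lines.append(_format_atom_line(serial, atom, res.resname, chain_id, res.resseq))
            serial += 1
    return lines, serial


def write_structure(frame: DimerFrame, path=None) -> str:
    """Write a dimer frame as a two-chain PDB (chains A and B). Returns the text."""
    lines, serial = _protomer_lines(frame.subunit_a, "A", 1)
    lines.append("TER")
    more, _ = _protomer_lines(frame.subunit_b, "B", serial)
    lines += more
    lines += ["TER", "END", ""]
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


def write_trajectory(traj: Trajectory, path=None) -> str:
    """Write a trajectory as a MODEL/ENDMDL multi-model two-chain PDB."""
    chunks = []
    for k, frame in enumerate(traj.frames):
        chunks.append(f"MODEL     {k + 1:4d}")
        lines, serial = _protomer_lines(frame.subunit_a, "A", 1)
        chunks += lines
        chunks.append("TER")
        more, _ = _protomer_lines(frame.subunit_b, "B", serial)
        chunks += more
        chunks += ["TER", "ENDMDL"]
    chunks += ["END", ""]
    text = "\n".join(chunks)
    if path is not None:
        Path(path).write_text(text)
    return text


def write_filament(model: FilamentModel, path=None) -> str:
    """Write a filament model as one chain per subunit (A, B, C, ...)."""
    if model.n_subunits < 2:
        raise ConfigurationError("a filament needs at least 2 subunits")
    if model.n_subunits > len(_CHAIN_ALPHABET):
        raise ConfigurationError(
            f"{model.n_subunits} subunits exhaust the {len(_CHAIN_ALPHABET)}-letter chain-id "
            "alphabet; write per-subunit files or use segment-id mode (not implemented)"
        )
    lines: list[str] = []
    serial = 1
    for k, subunit in enumerate(model.subunits):
        chunk, serial = _protomer_lines(subunit, _CHAIN_ALPHABET[k], serial)
        lines += chunk
        lines.append("TER")
    lines += ["END", ""]
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


def read_filament(source) -> list[Protomer]:
    """Read a multi-chain filament PDB back as a list of protomers (file order)."""
    lines = _as_lines(source)
    models = _split_models(lines)
    if not models:
        raise PDBParseError("no ATOM/HETATM records found")
    chains = _parse_model(models[0])
    return [Protomer(cid, residues) for cid, residues in chains.items()]
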