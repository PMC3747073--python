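"""Coarse-grained structural I/O.

Reads PDB files into a one-node-per-residue model (Cα coordinate plus heavy
side-chain atoms), handles multi-MODEL conformational ensembles, maintains the
crystal (author) ↔ consecutive (serial) residue numbering map, and writes
structures back to PDB with per-residue values in the B-factor column for
structure coloring.

Conventions
-----------
* Coordinates are in Å throughout.
* Serial indexing is 0-based and consecutive; author numbering (including
  insertion codes) is preserved for all reports.
* Only altloc ' '/'A' conformers are kept; HETATM records (waters, nucleotides,
  ligands) are ignored — the residue network is protein-only.
* Chain gaps are compressed in serial numbering (no loop building); a gap
  report is logged.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

#: Backbone heavy-atom names excluded from the side-chain atom set.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class ParseError(ValueError):
    """Raised when a PDB input yields no usable coarse-grained residues."""


class EnsembleConsistencyError(ValueError):
    """Raised when frames of a multi-model input disagree on residue identity."""


@dataclass
class Residue:
    """One coarse-grained node: a residue represented by its Cα.

    Parameters
    ----------
    chain_id : str
        Author chain identifier.
    author_number : int
        Crystal (author) residue number.
    insertion_code : str
        PDB insertion code ('' if absent); part of the author numbering key.
    serial_index : int
        0-based consecutive index within the parent structure.
    residue_type : str
        Three-letter amino-acid code.
    ca_coord : numpy.ndarray
        Cα coordinate, shape (3,), Å.
    sidechain_atoms : list of (str, numpy.ndarray)
        Heavy side-chain atoms as (atom name, coordinate) pairs; may be empty
        (e.g. glycine).
    """

    chain_id: str
    author_number: int
    serial_index: int
    residue_type: str
    ca_coord: np.ndarray
    insertion_code: str = ""
    sidechain_atoms: list[tuple[str, np.ndarray]] = field(default_factory=list)

    @property
    def author_key(self) -> tuple[str, int, str]:
        """Hashable author-numbering key ``(chain, number, insertion code)``."""
        return (self.chain_id, self.author_number, self.insertion_code)

    @property
    def identity(self) -> tuple[str, int, str, str]:
        """Key used for ensemble-frame and cross-structure matching."""
        return (self.chain_id, self.author_number, self.insertion_code,
                self.residue_type)


@dataclass
class CoarseStructure:
    """Ordered residue list with consecutive serial indexing."""

    residues: list[Residue]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ParseError(
                f"structure {self.label!r} has {len(self.residues)} residues; "
                "at least 2 are required"
            )
        for k, res in enumerate(self.residues):
            if res.serial_index != k:
                raise ValueError(
                    f"serial_index {res.serial_index} at position {k}: serial "
                    "indices must be 0..N-1 consecutive"
                )
            if not np.all(np.isfinite(res.ca_coord)):
                raise ValueError(f"non-finite Cα coordinate at residue {k}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """All Cα coordinates as an (N, 3) array."""
        return np.array([r.ca_coord for r in self.residues], dtype=float)

    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)


@dataclass
class StructureEnsemble:
    """Index-aligned conformational ensemble (e.g. MD snapshots as models)."""

    frames: list[CoarseStructure]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise EnsembleConsistencyError("ensemble has no frames")
        ref = [r.identity for r in self.frames[0].residues]
        for f, frame in enumerate(self.frames[1:], start=2):
            ids = [r.identity for r in frame.residues]
            if ids != ref:
                raise EnsembleConsistencyError(
                    f"frame {f} residue identities differ from frame 1 "
                    f"(N={len(ids)} vs {len(ref)})"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_residues(self) -> int:
        return self.frames[0].n_residues


def _structure_from_atoms(atoms: AtomArray, label: str) -> CoarseStructure:
    """Group an atom array into residues sorted chain-then-author-number."""
    mask = ~atoms.hetero
    atoms = atoms[mask]
    groups: dict[tuple[str, int, str], dict] = {}
    for i in range(atoms.array_length()):
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]),
               str(atoms.ins_code[i]).strip())
        g = groups.setdefault(key, {"res_name": str(atoms.res_name[i]),
                                    "ca": None, "side": []})
        name = str(atoms.atom_name[i])
        element = str(atoms.element[i]).upper() if atoms.element[i] else ""
        coord = np.array(atoms.coord[i], dtype=float)
        if name == "CA" and element != "D":
            g["ca"] = coord
        elif name not in BACKBONE_ATOMS and element != "H":
            g["side"].append((name, coord))

    residues: list[Residue] = []
    dropped = []
    for key in sorted(groups):
        g = groups[key]
        if g["ca"] is None:
            dropped.append(key)
            continue
        chain, number, icode = key
        residues.append(Residue(
            chain_id=chain, author_number=number, insertion_code=icode,
            serial_index=len(residues), residue_type=g["res_name"],
            ca_coord=g["ca"], sidechain_atoms=g["side"],
        ))
    if dropped:
        logger.warning("%s: dropped %d residue(s) lacking a CA atom: %s",
                       label, len(dropped), dropped[:10])
    if not residues:
        raise ParseError(f"{label!r}: no residues with CA atoms found")

    _log_gap_report(residues, label)
    return CoarseStructure(residues=residues, label=label)


def _log_gap_report(residues: list[Residue], label: str) -> None:
    by_chain: dict[str, list[int]] = {}
    for r in residues:
        by_chain.setdefault(r.chain_id, []).append(r.author_number)
    for chain, numbers in by_chain.items():
        gaps = [(a, b) for a, b in zip(numbers, numbers[1:]) if b - a > 1]
        if gaps:
            logger.info("%s chain %s: %d author-numbering gap(s) compressed "
                        "in serial indexing: %s", label, chain, len(gaps),
                        gaps[:10])


def read_structure(
    pdb_text: str,
    model_index: int | str = 1,
    label: str = "",
) -> CoarseStructure | StructureEnsemble:
    """Parse PDB text into a coarse-grained structure or ensemble.

    Parameters
    ----------
    pdb_text : str
        PDB-format text (single- or multi-MODEL).
    model_index : int or "all"
        1-based model to read, or ``"all"`` to read every model into a
        :class:`StructureEnsemble`.
    label : str
        Label attached to the returned structure(s).

    Returns
    -------
    CoarseStructure or StructureEnsemble

    Raises
    ------
    ParseError
        If no residue with a CA atom is present.
    EnsembleConsistencyError
        If, under ``model_index="all"``, frames disagree on residue identity.
    """
    pdb_file = PDBFile.read(io.StringIO(pdb_text))
    n_models = pdb_file.get_model_count()
    if model_index == "all":
        frames = []
        for m in range(1, n_models + 1):
            atoms = pdb_file.get_structure(model=m, altloc="first")
            frames.append(_structure_from_atoms(atoms, f"{label}[{m}]"))
        if n_models == 1:
            # Degenerate but legal: a single-model ensemble.
            return StructureEnsemble(frames=frames, label=label)
        return StructureEnsemble(frames=frames, label=label)
    atoms = pdb_file.get_structure(model=int(model_index), altloc="first")
    return _structure_from_atoms(atoms, label)


def read_structure_file(path, model_index: int | str = 1,
                        label: str | None = None):
    """Read a coarse structure or ensemble from a PDB file on disk."""
    with open(path) as fh:
        text = fh.read()
    if label is None:
        label = str(path)
    return read_structure(text, model_index=model_index, label=label)


def renumber_map(structure: CoarseStructure) -> tuple[dict, dict]:
    """Bijective crystal (author) ↔ consecutive (serial) numbering map.

    Returns
    -------
    (author_to_serial, serial_to_author)
        ``author_to_serial`` maps ``(chain, author_number, insertion_code)`` to
        the 0-based serial index; ``serial_to_author`` is its inverse.

    Raises
    ------
    ValueError
        If two residues share the same author-numbering key.
    """
    author_to_serial: dict[tuple[str, int, str], int] = {}
    for res in structure.residues:
        if res.author_key in author_to_serial:
            raise ValueError(
                f"duplicate author numbering key {res.author_key}"
            )
        author_to_serial[res.author_key] = res.serial_index
    serial_to_author = {v: k for k, v in author_to_serial.items()}
    return author_to_serial, serial_to_author


def _coarse_atom_array(structure: CoarseStructure,
                       values: np.ndarray) -> AtomArray:
    n_atoms = sum(1 + len(r.sidechain_atoms) for r in structure.residues)
    atoms = AtomArray(n_atoms)
    atoms.add_annotation("b_factor", dtype=float)
    i = 0
    for res, value in zip(structure.residues, values):
        entries = [("CA", res.ca_coord)] + list(res.sidechain_atoms)
        for name, coord in entries:
            atoms.chain_id[i] = res.chain_id
            atoms.res_id[i] = res.author_number
            atoms.ins_code[i] = res.insertion_code
            atoms.res_name[i] = res.residue_type
            atoms.atom_name[i] = name
            # First alphabetic character of a heavy-atom name is its element.
            atoms.element[i] = next((c for c in name if c.isalpha()), "C")
            atoms.hetero[i] = False
            atoms.coord[i] = coord
            atoms.b_factor[i] = round(float(value), 2)
            i += 1
    return atoms


def write_mobility_pdb(structure: CoarseStructure,
                       per_residue_values: np.ndarray | None = None) -> str:
    """Serialize the coarse model to PDB with values in the B-factor column.

    Every atom of residue *i* carries ``per_residue_values[i]`` rounded to two
    decimals (0.0 if no values are given). The output re-parses to the same
    coarse structure with coordinates preserved to PDB precision (3 decimals).

    Raises
    ------
    ValueError
        If the value vector length does not match N or contains non-finite
        entries.
    """
    n = structure.n_residues
    if per_residue_values is None:
        values = np.zeros(n)
    else:
        values = np.asarray(per_residue_values, dtype=float)
        if values.shape != (n,):
            raise ValueError(
                f"per_residue_values has shape {values.shape}; expected ({n},)"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("per_residue_values must be finite")
    pdb_file = PDBFile()
    pdb_file.set_structure(_coarse_atom_array(structure, values))
    buf = io.StringIO()
    pdb_file.write(buf)
    return buf.getvalue()


def write_ensemble_pdb(ensemble: StructureEnsemble) -> str:
    """Serialize an ensemble as a multi-MODEL PDB (B-factors zero)."""
    out = []
    for m, frame in enumerate(ensemble.frames, start=1):
        out.append(f"MODEL     {m:4d}")
        body = write_mobility_pdb(frame)
        out.extend(line for line in body.splitlines()
                   if line.startswith(("ATOM", "TER")))
        out.append("ENDMDL")
    out.append("END")
    return "\n".join(out) + "\n"


def residue_table(structure: CoarseStructure):
    """Residue bookkeeping table (chain, author number, serial, type)."""
    import pandas as pd

    return pd.DataFrame({
        "chain": [r.chain_id for r in structure.residues],
        "author_number": [r.author_number for r in structure.residues],
        "insertion_code": [r.insertion_code for r in structure.residues],
        "serial_index": [r.serial_index for r in structure.residues],
        "residue_type": [r.residue_type for r in structure.residues],
    })
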