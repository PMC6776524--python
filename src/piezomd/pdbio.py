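"""Minimal fixed-column PDB reading and writing.

This reader covers the subset of the PDB format the package produces and
consumes — ATOM/HETATM, TER, MODEL/ENDMDL and CRYST1 records — and exists
so that molecule boundaries (TER records and chain changes) and malformed
records can be reported exactly.  Binary trajectory formats (DCD, XTC) are
handled elsewhere through MDAnalysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class PDBParseError(ValueError):
    """Raised when an ATOM/HETATM/CRYST1 record cannot be parsed."""


@dataclass
class RawPDB:
    """Parsed content of a (possibly multi-model) PDB file."""

    serials: list[int] = field(default_factory=list)
    names: list[str] = field(default_factory=list)
    resnames: list[str] = field(default_factory=list)
    chains: list[str] = field(default_factory=list)
    resids: list[int] = field(default_factory=list)
    elements: list[str] = field(default_factory=list)
    # 0-based atom indices immediately after which a TER record occurred
    ter_after: list[int] = field(default_factory=list)
    models: list[np.ndarray] = field(default_factory=list)  # (n_atoms, 3) each
    box: tuple[float, float, float] | None = None


def _guess_element(name: str) -> str:
    """Element from an atom name: first alphabetic character, with a
    two-letter fixup for common ions (CL, NA, MG, BR, ZN)."""
    stripped = name.strip()
    upper = stripped.upper()
    if upper in ("CL", "NA", "MG", "BR", "ZN", "FE", "K", "CS"):
        return upper.capitalize() if len(upper) > 1 else upper
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_pdb(path: str) -> RawPDB:
    """Parse ATOM/HETATM/TER/MODEL/ENDMDL/CRYST1 records from ``path``.

    Raises
    ------
    PDBParseError
        If a coordinate or CRYST1 field fails to parse; the message names
        the offending line number.
    ValueError
        If the file contains no atoms.
    """
    raw = RawPDB()
    coords: list[list[float]] = []
    first_model_done = False
    n_first = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise PDBParseError(
                        f"{path}: malformed coordinate field on line {lineno}: {line.rstrip()!r}"
                    ) from exc
                coords.append([x, y, z])
                if not first_model_done:
                    try:
                        serial = int(line[6:11])
                    except ValueError:
                        serial = len(raw.serials) + 1
                    name = line[12:16].strip()
                    raw.serials.append(serial)
                    raw.names.append(name)
                    raw.resnames.append(line[17:21].strip())
                    raw.chains.append(line[21].strip() or "A")
                    try:
                        raw.resids.append(int(line[22:26]))
                    except ValueError as exc:
                        raise PDBParseError(
                            f"{path}: malformed residue number on line {lineno}: {line.rstrip()!r}"
                        ) from exc
                    element = line[76:78].strip() if len(line) >= 78 else ""
                    raw.elements.append(element.capitalize() if element else _guess_element(name))
            elif rec == "TER":
                if not first_model_done and coords:
                    raw.ter_after.append(len(coords) - 1)
            elif rec == "ENDMDL":
                if coords:
                    if not first_model_done:
                        n_first = len(coords)
                        first_model_done = True
                    elif len(coords) != n_first:
                        raise PDBParseError(
                            f"{path}: model ending on line {lineno} has {len(coords)} atoms, "
                            f"expected {n_first}"
                        )
                    raw.models.append(np.asarray(coords, dtype=float))
                    coords = []
            elif rec == "CRYST1":
                try:
                    raw.box = (float(line[6:15]), float(line[15:24]), float(line[24:33]))
                except ValueError as exc:
                    raise PDBParseError(
                        f"{path}: malformed CRYST1 record on line {lineno}"
                    ) from exc

    if coords:  # trailing model without ENDMDL, or single-model file
        if first_model_done and len(coords) != n_first:
            raise PDBParseError(
                f"{path}: trailing model has {len(coords)} atoms, expected {n_first}"
            )
        raw.models.append(np.asarray(coords, dtype=float))

    if not raw.models:
        raise ValueError(f"{path}: no ATOM/HETATM records found")

    if len(set(raw.serials)) != len(raw.serials):
        warnings.warn(
            f"{path}: duplicate atom serial numbers; atoms re-indexed 0..{len(raw.serials) - 1}",
            stacklevel=2,
        )
    return raw


def write_pdb(
    path: str,
    coords_models: np.ndarray,
    names,
    resnames,
    chains,
    resids,
    elements,
    molecule_ids,
    box=None,
) -> None:
    """Write a multi-model PDB with TER records at molecule boundaries.

    ``coords_models`` has shape (n_models, n_atoms, 3) in Å.  ``box`` is an
    optional (Lx, Ly, Lz) written as an orthorhombic CRYST1 record.
    """
    coords_models = np.asarray(coords_models, dtype=float)
    if coords_models.ndim == 2:
        coords_models = coords_models[None]
    n_atoms = coords_models.shape[1]
    molecule_ids = np.asarray(molecule_ids)

    with open(path, "w") as fh:
        if box is not None:
            fh.write(
                f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        multi = coords_models.shape[0] > 1
        for m, frame in enumerate(coords_models, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for i in range(n_atoms):
                name = names[i]
                # short names start in column 14, 4-char names in column 13
                fname = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
                serial = (i % 99999) + 1
                resid = int(resids[i]) % 10000
                x, y, z = frame[i]
                fh.write(
                    f"ATOM  {serial:5d} {fname} {resnames[i]:<3.3s} "
                    f"{str(chains[i])[:1]:1s}{resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {elements[i][:2]:>2s}\n"
                )
                last_of_mol = i == n_atoms - 1 or molecule_ids[i + 1] != molecule_ids[i]
                if last_of_mol:
                    fh.write(f"TER   {serial + 1:5d}      {resnames[i]:<3.3s} "
                             f"{str(chains[i])[:1]:1s}{resid:4d}\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
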