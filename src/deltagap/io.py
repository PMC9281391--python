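"""Extended-XYZ and CIF input/output.

The extended-XYZ dialect used here stores the lattice, energy, virial,
periodicity and provenance in the comment line as key=value entries and
per-atom forces as extra columns, e.g.::

    6
    Lattice="8 0 0 0 8 0 0 0 8" Properties=species:S:1:pos:R:3:forces:R:3 \
        energy=-1.25 virial="..." pbc="T T T" provenance="toy"
    O 0.0 0.0 0.0 0.01 0.0 0.0
    ...

The reader tolerates missing labels.  CIF files are read through gemmi and
expanded to P1.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np

from .structures import EFSResult, PeriodicStructure

__all__ = ["read_cif", "read_extxyz", "write_extxyz"]

_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _format_comment(s: PeriodicStructure) -> str:
    props = "species:S:1:pos:R:3"
    if s.labels is not None and s.labels.forces is not None:
        props += ":forces:R:3"
    fields = [
        'Lattice="' + " ".join(f"{v:.12g}" for v in s.cell.ravel()) + '"',
        f"Properties={props}",
        'pbc="' + " ".join("T" if b else "F" for b in s.pbc) + '"',
    ]
    if s.labels is not None:
        fields.append(f"energy={s.labels.energy:.12g}")
        if s.labels.virial is not None:
            fields.append(
                'virial="' + " ".join(f"{v:.12g}" for v in s.labels.virial.ravel()) + '"'
            )
    if s.provenance:
        fields.append(f'provenance="{s.provenance}"')
    return " ".join(fields)


def write_extxyz(target: str | Path | TextIO, structures: Iterable[PeriodicStructure] | PeriodicStructure) -> None:
    """Write one or more structures as multi-frame extended XYZ."""
    if isinstance(structures, PeriodicStructure):
        structures = [structures]
    own = isinstance(target, (str, Path))
    fh: TextIO = open(target, "w") if own else target
    try:
        for s in structures:
            fh.write(f"{s.n_atoms}\n")
            fh.write(_format_comment(s) + "\n")
            forces = None if s.labels is None else s.labels.forces
            for i in range(s.n_atoms):
                row = f"{s.species[i]} " + " ".join(f"{v:.12f}" for v in s.positions[i])
                if forces is not None:
                    row += " " + " ".join(f"{v:.12f}" for v in forces[i])
                fh.write(row + "\n")
    finally:
        if own:
            fh.close()


def _parse_comment(line: str) -> dict:
    out = {}
    for m in _KV_RE.finditer(line):
        key = m.group(1)
        out[key] = m.group(2) if m.group(2) is not None else m.group(3)
    return out


def _parse_properties(spec: str) -> list[tuple[str, str, int]]:
    toks = spec.split(":")
    cols = []
    for k in range(0, len(toks) - 2, 3):
        cols.append((toks[k], toks[k + 1], int(toks[k + 2])))
    return cols


def read_extxyz(source: str | Path | TextIO) -> list[PeriodicStructure]:
    """Read all frames from an extended-XYZ file."""
    own = isinstance(source, (str, Path))
    fh: TextIO = open(source) if own else source
    try:
        text = fh.read()
    finally:
        if own:
            fh.close()
    lines = text.splitlines()
    frames: list[PeriodicStructure] = []
    pos_line = 0
    while pos_line < len(lines):
        if not lines[pos_line].strip():
            pos_line += 1
            continue
        natoms = int(lines[pos_line].strip())
        meta = _parse_comment(lines[pos_line + 1])
        body = lines[pos_line + 2 : pos_line + 2 + natoms]
        pos_line += 2 + natoms

        cols = _parse_properties(meta.get("Properties", "species:S:1:pos:R:3"))
        species: list[str] = []
        arrays: dict[str, list] = {name: [] for name, _, _ in cols if name != "species"}
        for row in body:
            toks = row.split()
            ofs = 0
            for name, _kind, width in cols:
                vals = toks[ofs : ofs + width]
                ofs += width
                if name == "species":
                    species.append(vals[0])
                else:
                    arrays[name].append([float(v) for v in vals])

        cell = np.array([float(v) for v in meta.get("Lattice", "0 0 0 0 0 0 0 0 0").split()]).reshape(3, 3)
        pbc_str = meta.get("pbc", "T T T").replace('"', "").split()
        pbc = tuple(t.upper().startswith("T") for t in pbc_str)
        if not any(pbc) and not np.any(cell):
            cell = np.eye(3)

        labels = None
        if "energy" in meta or "forces" in arrays:
            energy = float(meta.get("energy", "nan"))
            forces = np.array(arrays.get("forces", np.zeros((natoms, 3))))
            virial = None
            if "virial" in meta:
                virial = np.array([float(v) for v in meta["virial"].split()]).reshape(3, 3)
            labels = EFSResult(energy, forces, virial)

        frames.append(
            PeriodicStructure(
                tuple(species),
                np.array(arrays["pos"]),
                cell,
                pbc,
                labels=labels,
                provenance=meta.get("provenance", ""),
            )
        )
    return frames


def read_cif(path: str | Path) -> PeriodicStructure:
    """Read a (small-molecule) CIF file, expanding symmetry to P1."""
    import gemmi

    small = gemmi.read_small_structure(str(path))
    cell = np.array(
        [
            _orth(small.cell, 1.0, 0.0, 0.0),
            _orth(small.cell, 0.0, 1.0, 0.0),
            _orth(small.cell, 0.0, 0.0, 1.0),
        ]
    )
    species: list[str] = []
    frac: list[np.ndarray] = []
    for site in small.get_all_unit_cell_sites():
        f = np.array([site.fract.x, site.fract.y, site.fract.z]) % 1.0
        # drop symmetry-generated duplicates sitting on special positions
        dup = any(
            s == site.element.name and np.linalg.norm(((f - g + 0.5) % 1.0) - 0.5) < 1e-4
            for s, g in zip(species, frac)
        )
        if not dup:
            species.append(site.element.name)
            frac.append(f)
    positions = np.array(frac) @ cell
    return PeriodicStructure(tuple(species), positions, cell, (True, True, True), provenance=str(path))


def _orth(cell, fx: float, fy: float, fz: float) -> np.ndarray:
    import gemmi

    p = cell.orthogonalize(gemmi.Fractional(fx, fy, fz))
    return np.array([p.x, p.y, p.z])
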