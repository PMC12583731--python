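"""Trajectory and table I/O.

Ensembles travel as extended-XYZ (with a ``Lattice`` header, a
per-atom molecule-index column and, when available, a per-atom label
column) or as PDB files, where chains (falling back to residues) are
the molecules.  Atom labels are the universal addressing scheme of
the analysis; when a format cannot carry them a label-map CSV
(columns ``atom_index,atom_label``, index within the molecule) maps
positions to labels.
"""

from __future__ import annotations

import shlex

import numpy as np
import pandas as pd

from .metrics import Atom, Frame, Molecule

__all__ = [
    "read_extxyz",
    "write_extxyz",
    "read_pdb",
    "read_label_map",
    "read_trajectory",
]


def read_label_map(path_or_buf):
    """Read a label-map CSV: atom_index (within molecule) -> atom_label."""
    df = pd.read_csv(path_or_buf, comment="#")
    return dict(zip(df.atom_index.astype(int), df.atom_label.astype(str)))


def _parse_info_line(line):
    """Parse an extended-XYZ comment line of key=value pairs (quotes honoured)."""
    info = {}
    for token in shlex.split(line):
        if "=" not in token:
            continue
        key, val = token.split("=", 1)
        info[key] = val
    return info


def _parse_properties(spec):
    """Split a Properties spec into (name, dtype, ncols) triples."""
    parts = spec.split(":")
    cols = []
    for i in range(0, len(parts), 3):
        cols.append((parts[i], parts[i + 1], int(parts[i + 2])))
    return cols


def read_extxyz(path, label_map=None, require_cell=True):
    """Read a multi-frame extended-XYZ trajectory into Frames.

    Requires a per-atom molecule-index column (``mol`` or
    ``molecule``); labels come from a ``label`` column or, failing
    that, from ``label_map``.

    Returns
    -------
    list of (info, Frame)
        ``info`` is the parsed comment-line dict of each frame.
    """
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    nframe = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        natoms = int(lines[i].strip())
        info = _parse_info_line(lines[i + 1])
        cell = None
        if "Lattice" in info:
            vals = [float(x) for x in info["Lattice"].split()]
            cell = np.array(vals, dtype=float).reshape(3, 3)
        elif require_cell:
            raise ValueError(f"frame {nframe}: extended-XYZ is missing a Lattice header")
        props = _parse_properties(info.get("Properties", "species:S:1:pos:R:3"))
        col_of = {}
        col = 0
        for name, _, ncols in props:
            col_of[name] = (col, ncols)
            col += ncols
        for needed in ("species", "pos"):
            if needed not in col_of:
                raise ValueError(f"frame {nframe}: Properties lacks {needed!r}")
        mol_col = next((k for k in ("mol", "molecule", "mol_id") if k in col_of), None)
        if mol_col is None:
            raise ValueError(
                f"frame {nframe}: no molecule-index column (expected a "
                f"'mol' entry in Properties)"
            )
        per_mol = {}
        for j in range(natoms):
            fields = lines[i + 2 + j].split()
            el = fields[col_of["species"][0]]
            x0 = col_of["pos"][0]
            xyz = tuple(float(fields[x0 + k]) for k in range(3))
            mol_idx = int(fields[col_of[mol_col][0]])
            if "label" in col_of:
                label = fields[col_of["label"][0]]
            elif label_map is not None:
                within = len(per_mol.get(mol_idx, []))
                if within not in label_map:
                    raise ValueError(f"label map has no entry for atom index {within}")
                label = label_map[within]
            else:
                raise ValueError(
                    f"frame {nframe}: no per-atom labels; supply a label map"
                )
            per_mol.setdefault(mol_idx, []).append(Atom(label=label, element=el, xyz=xyz))
        mols = [Molecule(index=k, atoms=v) for k, v in sorted(per_mol.items())]
        frames.append((info, Frame(molecules=mols, cell=cell)))
        i += 2 + natoms
        nframe += 1
    return frames


def write_extxyz(path, frames, info=None):
    """Write Frames as extended-XYZ with mol and label per-atom columns."""
    out = []
    for fidx, frame in enumerate(frames):
        natoms = sum(len(m.atoms) for m in frame.molecules)
        out.append(str(natoms))
        parts = []
        if frame.cell is not None:
            flat = " ".join(f"{v:.8f}" for v in np.asarray(frame.cell).ravel())
            parts.append(f'Lattice="{flat}"')
        parts.append("Properties=species:S:1:pos:R:3:mol:I:1:label:S:1")
        parts.append(f"frame={fidx}")
        parts.append('pbc="T T T"' if frame.cell is not None else 'pbc="F F F"')
        for key, val in (info or {}).items():
            parts.append(f"{key}={val}")
        out.append(" ".join(parts))
        for mol in frame.molecules:
            for a in mol.atoms:
                x, y, z = a.xyz
                out.append(f"{a.element} {x:.8f} {y:.8f} {z:.8f} {mol.index} {a.label}")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def read_pdb(path, label_map=None):
    """Read a PDB file; chains (else residues) become molecules.

    Atom labels default to the PDB atom names, or come from
    ``label_map`` (index within molecule -> label).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(path)
    frames = []
    for model in range(1, pdb.get_model_count() + 1):
        arr = pdb.get_structure(model=model)
        cell = None
        box = getattr(arr, "box", None)
        if box is not None:
            cell = np.asarray(box, dtype=float)
        chains = np.unique(arr.chain_id)
        if len(chains) > 1:
            groups = [(i, arr[arr.chain_id == c]) for i, c in enumerate(chains)]
        else:
            res_ids = np.unique(arr.res_id)
            groups = [(i, arr[arr.res_id == r]) for i, r in enumerate(res_ids)]
        mols = []
        for idx, sub in groups:
            atoms = []
            for j in range(sub.array_length()):
                if label_map is not None:
                    label = label_map[j]
                else:
                    label = str(sub.atom_name[j])
                atoms.append(Atom(label=label, element=str(sub.element[j]).capitalize(),
                                  xyz=tuple(float(v) for v in sub.coord[j])))
            mols.append(Molecule(index=idx, atoms=atoms))
        frames.append(({"model": model}, Frame(molecules=mols, cell=cell)))
    return frames


def read_trajectory(path, label_map_path=None, require_cell=True):
    """Read an ensemble from extended-XYZ or PDB, dispatching on suffix."""
    label_map = read_label_map(label_map_path) if label_map_path else None
    p = str(path)
    if p.endswith((".pdb", ".ent")):
        return read_pdb(p, label_map)
    return read_extxyz(p, label_map, require_cell=require_cell)
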