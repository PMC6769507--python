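"""Reading and writing structures and tabular inputs.

Structures travel as (multi-model) PDB through biotite; a plain
XYZ-per-frame dialect with a sidecar topology table covers trajectory-like
inputs that have no standard text format. Tabular inputs (quenching series,
depth profiles, shift tables, sPRE titrations) are delimited text with
headers, read through pandas.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .chem import element_from_name, infer_group, mass_of_element
from .errors import InvalidInputError
from .frame import Ensemble, Frame
from .quench import DepthQuenchProfile, QuenchSeries

__all__ = [
    "read_structure", "write_structure", "read_xyz", "write_xyz",
    "read_quench_series", "read_depth_profile", "read_shift_table",
    "read_spre_table", "report_to_json",
]


# --------------------------------------------------------------------------
# PDB
# --------------------------------------------------------------------------

def _atom_array_to_frame(arr: struc.AtomArray) -> Frame:
    n = arr.array_length()
    elements, masses = [], []
    for i in range(n):
        el = str(arr.element[i]).strip()
        if not el:
            el = element_from_name(str(arr.atom_name[i]))
            warnings.warn(
                f"missing element for atom {arr.atom_name[i]!r}: inferred {el}",
                stacklevel=3)
        elements.append(el.upper())
        masses.append(mass_of_element(el))
    res_names = [str(r) for r in arr.res_name]
    box = None
    if arr.box is not None:
        diag = np.diagonal(np.asarray(arr.box, float).reshape(3, 3))
        if np.all(diag > 0):
            box = diag.copy()
    return Frame(
        names=[str(a) for a in arr.atom_name], elements=elements, masses=masses,
        residue_index=np.asarray(arr.res_id, dtype=int),
        residue_names=res_names,
        group_tags=[infer_group(rn) for rn in res_names],
        xyz=np.asarray(arr.coord, dtype=float), box=box,
    )


def read_structure(path: str | Path) -> Frame | Ensemble:
    """Read a (multi-model) PDB file into a Frame or an Ensemble.

    MODEL/ENDMDL records become frames; the first altloc of each atom is
    kept (a warning is logged when alternates are present); elements absent
    from the file are inferred from atom names with a warning.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None, altloc="first")
    except Exception as exc:
        raise InvalidInputError(f"cannot parse {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise InvalidInputError(f"{path} contains no atoms")
    frames = [_atom_array_to_frame(stack[i]) for i in range(stack.stack_depth())]
    if len(frames) == 1:
        return frames[0]
    return Ensemble.from_frames(frames)


def _frame_to_atom_array(frame: Frame) -> struc.AtomArray:
    n = frame.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(frame.xyz, dtype=np.float32)
    arr.atom_name = np.asarray(frame.names, dtype="U6")
    arr.res_id = np.asarray(frame.residue_index, dtype=int)
    arr.res_name = np.asarray(frame.residue_names, dtype="U5")
    arr.element = np.asarray([e.upper() for e in frame.elements], dtype="U2")
    arr.chain_id = np.asarray(
        ["A" if t == "peptide" else "B" for t in frame.group_tags], dtype="U4")
    arr.hetero = np.asarray([t != "peptide" for t in frame.group_tags])
    if frame.box is not None:
        arr.box = np.diag(frame.box)
    return arr


def write_structure(path: str | Path, obj: Frame | Ensemble) -> None:
    """Write a Frame (single model) or Ensemble (multi-model) as PDB."""
    frames = [obj] if isinstance(obj, Frame) else list(obj)
    arrays = [_frame_to_atom_array(f) for f in frames]
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))


# --------------------------------------------------------------------------
# XYZ + sidecar topology
# --------------------------------------------------------------------------

TOPOLOGY_COLUMNS = ["name", "residue_index", "residue_name", "element",
                    "mass", "group_tag"]


def write_xyz(path: str | Path, obj: Frame | Ensemble,
              topology_path: str | Path) -> None:
    """Write frames as plain XYZ blocks plus a CSV topology sidecar."""
    frames = [obj] if isinstance(obj, Frame) else list(obj)
    top = frames[0]
    pd.DataFrame({
        "name": top.names, "residue_index": top.residue_index,
        "residue_name": top.residue_names, "element": top.elements,
        "mass": top.masses, "group_tag": top.group_tags,
    }).to_csv(topology_path, index=False)
    with open(path, "w") as fh:
        for i, f in enumerate(frames):
            fh.write(f"{f.n_atoms}\n")
            fh.write(f"frame {i}\n")
            for name, (x, y, z) in zip(f.names, f.xyz):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: str | Path, topology_path: str | Path) -> Frame | Ensemble:
    """Read the XYZ-per-frame dialect with its sidecar topology table."""
    top = pd.read_csv(topology_path)
    missing = set(TOPOLOGY_COLUMNS) - set(top.columns)
    if missing:
        raise InvalidInputError(f"topology lacks columns {sorted(missing)}")
    n_atoms = len(top)
    frames_xyz = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].split()[0])
        except ValueError as exc:
            raise InvalidInputError(
                f"{path}:{i + 1}: expected an atom count") from exc
        if count != n_atoms:
            raise InvalidInputError(
                f"{path}:{i + 1}: frame has {count} atoms, topology {n_atoms}")
        block = lines[i + 2:i + 2 + count]
        if len(block) < count:
            raise InvalidInputError(f"{path}: truncated final frame")
        xyz = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames_xyz.append(xyz)
        i += 2 + count
    if not frames_xyz:
        raise InvalidInputError(f"{path} contains no frames")

    def build(xyz: np.ndarray) -> Frame:
        return Frame(
            names=top["name"].astype(str).tolist(),
            elements=top["element"].astype(str).tolist(),
            masses=top["mass"].to_numpy(float),
            residue_index=top["residue_index"].to_numpy(int),
            residue_names=top["residue_name"].astype(str).tolist(),
            group_tags=top["group_tag"].astype(str).tolist(), xyz=xyz)

    if len(frames_xyz) == 1:
        return build(frames_xyz[0])
    return Ensemble.from_frames([build(x) for x in frames_xyz])


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------

def _read_delimited(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_quench_series(path: str | Path) -> QuenchSeries:
    """Read a titration table with headers ``q_conc,f_ratio``."""
    df = _read_delimited(path)
    if not {"q_conc", "f_ratio"}.issubset(df.columns):
        raise InvalidInputError("quench series needs columns q_conc,f_ratio")
    df = df.sort_values("q_conc")
    return QuenchSeries(df["q_conc"].to_numpy(float), df["f_ratio"].to_numpy(float))


def read_depth_profile(path: str | Path) -> DepthQuenchProfile:
    """Read a depth-quenching table.

    Accepts either ``h_angstrom,ln_ratio`` or ``h_angstrom,f0,f`` (converted
    to ln(F0/F)).
    """
    df = _read_delimited(path)
    if "h_angstrom" not in df.columns:
        raise InvalidInputError("depth profile needs a h_angstrom column")
    h = df["h_angstrom"].to_numpy(float)
    if "ln_ratio" in df.columns:
        return DepthQuenchProfile(h, df["ln_ratio"].to_numpy(float))
    if {"f0", "f"}.issubset(df.columns):
        return DepthQuenchProfile.from_f_ratio(
            h, df["f0"].to_numpy(float), df["f"].to_numpy(float))
    raise InvalidInputError("depth profile needs ln_ratio or f0,f columns")


def read_shift_table(path: str | Path) -> pd.DataFrame:
    """Read a chemical-shift table with columns ``residue,aa,shift_ppm``."""
    df = _read_delimited(path)
    needed = {"residue", "aa", "shift_ppm"}
    if not needed.issubset(df.columns):
        raise InvalidInputError(f"shift table needs columns {sorted(needed)}")
    return df


def read_spre_table(path: str | Path) -> pd.DataFrame:
    """Read an sPRE titration with columns ``atom,conc_mM,intensity``."""
    df = _read_delimited(path)
    needed = {"atom", "conc_mM", "intensity"}
    if not needed.issubset(df.columns):
        raise InvalidInputError(f"sPRE table needs columns {sorted(needed)}")
    return df


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------

def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, float) and (obj != obj):  # NaN
        return None
    return obj


def report_to_json(obj, path: str | Path | None = None) -> str:
    """Serialize a fit/result object to deterministic JSON."""
    text = json.dumps(_jsonify(obj), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
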