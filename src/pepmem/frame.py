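"""In-memory containers for peptide/bilayer coordinate data.

A :class:`Frame` is a struct-of-arrays snapshot (names, residues, masses,
coordinates); an :class:`Ensemble` shares one topology across many frames.
Coordinates are in Angstrom throughout, and the bilayer normal defaults to
the z axis (``normal_axis = 2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .chem import BACKBONE_ATOM_NAMES, infer_group
from .errors import InvalidInputError, SelectionError

__all__ = ["Frame", "Ensemble", "parse_selection"]


def _as_str_array(values: Sequence[str]) -> np.ndarray:
    return np.asarray(list(values), dtype=object)


@dataclass
class Frame:
    """One snapshot of a peptide, optionally embedded in a bilayer + solvent."""

    names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    residue_index: np.ndarray
    residue_names: np.ndarray
    group_tags: np.ndarray
    xyz: np.ndarray
    box: np.ndarray | None = None
    normal_axis: int = 2
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.names = _as_str_array(self.names)
        self.elements = _as_str_array(self.elements)
        self.masses = np.asarray(self.masses, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_names = _as_str_array(self.residue_names)
        self.group_tags = _as_str_array(self.group_tags)
        self.xyz = np.asarray(self.xyz, dtype=float)
        n = len(self.names)
        for arr, label in [
            (self.elements, "elements"), (self.masses, "masses"),
            (self.residue_index, "residue_index"),
            (self.residue_names, "residue_names"),
            (self.group_tags, "group_tags"),
        ]:
            if len(arr) != n:
                raise InvalidInputError(f"{label} has length {len(arr)}, expected {n}")
        if self.xyz.shape != (n, 3):
            raise InvalidInputError(f"xyz has shape {self.xyz.shape}, expected ({n}, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise InvalidInputError("coordinates must be finite")
        if np.any(self.masses <= 0):
            raise InvalidInputError("atom masses must be positive")
        if np.any(self.residue_index < 1):
            raise InvalidInputError("residue indices are 1-based and must be >= 1")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise InvalidInputError("box must be three positive edge lengths")

    # -- basic queries ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, self.normal_axis]

    def mask(self, *, group: str | None = None, residue: int | None = None,
             residues: Sequence[int] | None = None,
             names: Sequence[str] | None = None,
             residue_name: str | None = None) -> np.ndarray:
        m = np.ones(self.n_atoms, dtype=bool)
        if group is not None:
            m &= self.group_tags == group
        if residue is not None:
            m &= self.residue_index == residue
        if residues is not None:
            m &= np.isin(self.residue_index, list(residues))
        if names is not None:
            m &= np.isin(self.names, list(names))
        if residue_name is not None:
            m &= self.residue_names == residue_name
        return m

    def atom_index(self, residue: int, name: str) -> int:
        idx = np.flatnonzero((self.residue_index == residue) & (self.names == name))
        if len(idx) == 0:
            raise SelectionError(f"no atom {name!r} in residue {residue}")
        return int(idx[0])

    def subset(self, mask: np.ndarray) -> "Frame":
        return Frame(
            names=self.names[mask], elements=self.elements[mask],
            masses=self.masses[mask], residue_index=self.residue_index[mask],
            residue_names=self.residue_names[mask], group_tags=self.group_tags[mask],
            xyz=self.xyz[mask].copy(), box=None if self.box is None else self.box.copy(),
            normal_axis=self.normal_axis, metadata=dict(self.metadata),
        )

    def peptide_residues(self) -> np.ndarray:
        return np.unique(self.residue_index[self.group_tags == "peptide"])

    def sidechain_mask(self, residue: int) -> np.ndarray:
        m = (self.residue_index == residue) & (self.group_tags == "peptide")
        return m & ~np.isin(self.names, list(BACKBONE_ATOM_NAMES))

    def com(self, mask: np.ndarray | None = None) -> np.ndarray:
        if mask is None:
            mask = np.ones(self.n_atoms, dtype=bool)
        if not np.any(mask):
            raise SelectionError("center of mass of an empty selection")
        w = self.masses[mask]
        return np.average(self.xyz[mask], axis=0, weights=w)

    # -- transforms (return new frames; never mutate) ---------------------
    def translated(self, shift: Sequence[float]) -> "Frame":
        out = self.copy()
        out.xyz = out.xyz + np.asarray(shift, dtype=float)
        return out

    def rotated(self, rotation: np.ndarray, center: Sequence[float] | None = None) -> "Frame":
        rotation = np.asarray(rotation, dtype=float)
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        out = self.copy()
        out.xyz = (out.xyz - c) @ rotation.T + c
        return out

    def copy(self) -> "Frame":
        return replace(
            self, names=self.names.copy(), elements=self.elements.copy(),
            masses=self.masses.copy(), residue_index=self.residue_index.copy(),
            residue_names=self.residue_names.copy(), group_tags=self.group_tags.copy(),
            xyz=self.xyz.copy(), box=None if self.box is None else self.box.copy(),
            metadata=dict(self.metadata),
        )

    @staticmethod
    def merge(a: "Frame", b: "Frame") -> "Frame":
        """Concatenate two frames (e.g. peptide into a bilayer slab)."""
        if a.normal_axis != b.normal_axis:
            raise InvalidInputError("frames disagree on the bilayer normal axis")
        box = a.box if a.box is not None else b.box
        return Frame(
            names=np.concatenate([a.names, b.names]),
            elements=np.concatenate([a.elements, b.elements]),
            masses=np.concatenate([a.masses, b.masses]),
            residue_index=np.concatenate([a.residue_index, b.residue_index]),
            residue_names=np.concatenate([a.residue_names, b.residue_names]),
            group_tags=np.concatenate([a.group_tags, b.group_tags]),
            xyz=np.vstack([a.xyz, b.xyz]), box=box,
            normal_axis=a.normal_axis,
            metadata={**a.metadata, **b.metadata},
        )


@dataclass
class Ensemble:
    """Multiple frames sharing one topology (a trajectory-like object)."""

    topology: Frame
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray | None = None  # [ns]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (self.topology.n_atoms, 3):
            raise InvalidInputError(
                f"coords shape {self.coords.shape} incompatible with "
                f"{self.topology.n_atoms} atoms")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != self.n_frames:
                raise InvalidInputError("one time per frame required")
            if np.any(np.diff(self.times) < 0):
                raise InvalidInputError("frame times must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Frame:
        f = self.topology.copy()
        f.xyz = self.coords[i].copy()
        return f

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    @staticmethod
    def from_frames(frames: Sequence[Frame], times: Sequence[float] | None = None) -> "Ensemble":
        if len(frames) == 0:
            raise InvalidInputError("at least one frame required")
        coords = np.stack([f.xyz for f in frames])
        return Ensemble(topology=frames[0].copy(), coords=coords,
                        times=None if times is None else np.asarray(times, float))


def parse_selection(frame: Frame, expression: str) -> np.ndarray:
    """Resolve a small selection mini-language to a boolean atom mask.

    Clauses are joined with ``and``:

    * ``group peptide|lipid|water|ion``
    * ``resid 2`` or ``resid 2-13`` (1-based, inclusive)
    * ``name CA CB NE``
    * ``resname TRP``
    * ``all``
    """
    mask = np.ones(frame.n_atoms, dtype=bool)
    for clause in [c.strip() for c in expression.split(" and ")]:
        if not clause:
            raise SelectionError("empty selection clause")
        tokens = clause.split()
        key, args = tokens[0].lower(), tokens[1:]
        if key == "all":
            continue
        if key == "group":
            mask &= frame.mask(group=args[0])
        elif key == "resid":
            resids: list[int] = []
            for a in args:
                if "-" in a[1:]:
                    lo, hi = a.split("-")
                    resids.extend(range(int(lo), int(hi) + 1))
                else:
                    resids.append(int(a))
            mask &= frame.mask(residues=resids)
        elif key == "name":
            mask &= frame.mask(names=args)
        elif key == "resname":
            mask &= np.isin(frame.residue_names, args)
        else:
            raise SelectionError(f"unknown selection keyword {key!r}")
    return mask


def tag_groups(residue_names: Sequence[str]) -> np.ndarray:
    """Vectorized group inference from residue names."""
    return _as_str_array([infer_group(rn) for rn in residue_names])
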