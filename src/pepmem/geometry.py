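"""Coordinate-level analytics for helical peptides in bilayers.

Conventions
-----------
* Coordinates are in Angstrom; the bilayer normal is +z unless a frame says
  otherwise.
* Depths are absolute distances from the bilayer center plane.
* The helix tilt is measured against the *outward* normal of the leaflet
  hosting the peptide (pointing from the bilayer center toward the peptide),
  so a flipped membrane analyzes identically. Tilt < 90 deg means the
  N-terminal reference residue sits deeper in the membrane.
* The azimuthal angle describes the rotation of the helix about its own
  axis: 0 deg means the reference side chain points straight toward water.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .chem import ARG_GUANIDINIUM_N, TRP_RING_ATOMS
from .errors import DegenerateGeometryError, InvalidInputError, SelectionError
from .frame import Ensemble, Frame

__all__ = [
    "TiltResult", "ContactRecord", "bilayer_center", "bilayer_center_diagnostics",
    "outward_normal_sign", "tilt_from_calpha", "helix_axis", "azimuthal_angle",
    "residue_depths", "com_distance", "count_hbonds", "detect_bidentate",
    "detect_pi_cation", "helical_wheel", "rotation_about",
]

PHOSPHATE_OXYGEN_NAMES = ("O1", "O2", "O3", "O4", "O11", "O12", "O13", "O14",
                          "OP1", "OP2", "OP3")
WATER_OXYGEN_NAMES = ("OW", "O", "OH2")


def rotation_about(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about an arbitrary axis."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise DegenerateGeometryError("rotation axis has zero length")
    return Rotation.from_rotvec(np.radians(angle_deg) * axis / norm).as_matrix()


# --------------------------------------------------------------------------
# bilayer geometry
# --------------------------------------------------------------------------

def bilayer_center(frame: Frame, mode: str = "mass",
                   phosphate_names: Sequence[str] = ("P",)) -> float:
    """z position of the bilayer center along the frame's normal axis.

    ``mode='mass'``: mass-weighted centroid of all lipid atoms.
    ``mode='phosphate'``: midpoint of the two leaflet phosphate means, with
    leaflets split by sign relative to the lipid centroid.
    """
    lipid = frame.mask(group="lipid")
    if not np.any(lipid):
        raise SelectionError("frame contains no lipid atoms")
    z = frame.z
    z_centroid = float(np.average(z[lipid], weights=frame.masses[lipid]))
    if mode == "mass":
        return z_centroid
    if mode == "phosphate":
        pmask = lipid & np.isin(frame.names, list(phosphate_names))
        if not np.any(pmask):
            raise SelectionError("no phosphate atoms found for phosphate mode")
        zp = z[pmask]
        upper, lower = zp[zp >= z_centroid], zp[zp < z_centroid]
        if len(upper) == 0 or len(lower) == 0:
            raise SelectionError("phosphates found in only one leaflet")
        return 0.5 * (float(upper.mean()) + float(lower.mean()))
    raise InvalidInputError(f"unknown bilayer-center mode {mode!r}")


def bilayer_center_diagnostics(frame: Frame) -> dict[str, float]:
    """Both center estimates; they differ for asymmetric leaflets."""
    out = {"mass": bilayer_center(frame, "mass")}
    try:
        out["phosphate_midpoint"] = bilayer_center(frame, "phosphate")
    except SelectionError:
        pass
    return out


def outward_normal_sign(frame: Frame, z0: float | None = None) -> float:
    """+1 if the peptide COM sits above the bilayer center, else -1."""
    pep = frame.mask(group="peptide")
    if not np.any(pep):
        raise SelectionError("frame contains no peptide atoms")
    if z0 is None:
        z0 = bilayer_center(frame) if np.any(frame.group_tags == "lipid") else 0.0
    z_com = float(np.average(frame.z[pep], weights=frame.masses[pep]))
    return 1.0 if z_com >= z0 else -1.0


def _resolve_center(frame: Frame, z0) -> float:
    if z0 is not None:
        return float(z0)
    if np.any(frame.group_tags == "lipid"):
        return bilayer_center(frame)
    return 0.0


# --------------------------------------------------------------------------
# tilt and helix axis
# --------------------------------------------------------------------------

@dataclass
class TiltResult:
    """Per-frame helix tilt derived from two C-alpha z positions."""

    per_frame_tilt: np.ndarray       # [deg]
    per_frame_dz: np.ndarray         # signed z difference along outward normal [A]
    mean_tilt: float
    tilt_sd: float
    dz_histogram: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)
    tilt_histogram: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)
    res_n: int = 2
    res_c: int = 13


def _frames_of(obj: Frame | Ensemble) -> list[Frame]:
    return [obj] if isinstance(obj, Frame) else list(obj)


def tilt_from_calpha(obj: Frame | Ensemble, res_n: int = 2, res_c: int = 13,
                     z0: float | None = None, n_bins: int = 36) -> TiltResult:
    """Helix tilt from the C-alpha positions of two reference residues.

    ``v`` points from the N-side residue to the C-side residue; the tilt is
    the angle between v and the outward leaflet normal. Tilt < 90 deg means
    the N-side residue is inserted deeper.
    """
    tilts, dzs = [], []
    for f in _frames_of(obj):
        ca_n = f.xyz[f.atom_index(res_n, "CA")]
        ca_c = f.xyz[f.atom_index(res_c, "CA")]
        v = ca_c - ca_n
        norm = np.linalg.norm(v)
        if norm == 0:
            raise DegenerateGeometryError("reference C-alphas coincide")
        sign = outward_normal_sign(f, z0=z0)
        n_hat = np.zeros(3)
        n_hat[f.normal_axis] = sign
        cosang = float(np.clip(np.dot(v, n_hat) / norm, -1.0, 1.0))
        tilts.append(math.degrees(math.acos(cosang)))
        dzs.append(float(np.dot(v, n_hat)))
    tilts = np.asarray(tilts)
    dzs = np.asarray(dzs)
    dz_hist = np.histogram(dzs, bins=n_bins)
    tilt_hist = np.histogram(tilts, bins=n_bins, range=(0.0, 180.0))
    return TiltResult(per_frame_tilt=tilts, per_frame_dz=dzs,
                      mean_tilt=float(tilts.mean()),
                      tilt_sd=float(tilts.std(ddof=0)),
                      dz_histogram=dz_hist, tilt_histogram=tilt_hist,
                      res_n=res_n, res_c=res_c)


def helix_axis(frame: Frame, residue_range: tuple[int, int] | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Principal axis of the C-alpha trace, oriented N-terminus to C-terminus.

    Returns (unit axis vector, centroid point on the axis).
    """
    mask = frame.mask(group="peptide", names=["CA"])
    if residue_range is not None:
        lo, hi = residue_range
        mask &= (frame.residue_index >= lo) & (frame.residue_index <= hi)
    idx = np.flatnonzero(mask)
    if len(idx) < 4:
        raise SelectionError("helix axis needs >= 4 C-alpha atoms")
    order = np.argsort(frame.residue_index[idx])
    coords = frame.xyz[idx[order]]
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis), centroid


def tilt_from_axis(frame: Frame, residue_range: tuple[int, int] | None = None,
                   z0: float | None = None) -> float:
    """Tilt of the principal helix axis against the outward leaflet normal."""
    axis, _ = helix_axis(frame, residue_range)
    sign = outward_normal_sign(frame, z0=z0)
    n_hat = np.zeros(3)
    n_hat[frame.normal_axis] = sign
    # axis points N->C; tilt < 90 deg when the N-terminus is deeper.
    cosang = float(np.clip(np.dot(axis, n_hat), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def helix_midpoint_depth(frame: Frame, z0: float | None = None,
                         residue_range: tuple[int, int] | None = None) -> float:
    """Depth of the helix-axis midpoint from the bilayer center [A].

    The midpoint is halfway between the extreme C-alpha projections onto the
    principal axis; the depth is its absolute distance from the center.
    """
    axis, point = helix_axis(frame, residue_range)
    mask = frame.mask(group="peptide", names=["CA"])
    proj = (frame.xyz[mask] - point) @ axis
    midpoint = point + 0.5 * (proj.min() + proj.max()) * axis
    zc = _resolve_center(frame, z0)
    return abs(float(midpoint[frame.normal_axis]) - zc)


def azimuthal_angle(frame: Frame, reference_residue: int,
                    axis: np.ndarray | None = None,
                    z0: float | None = None) -> float:
    """Rotation of the helix about its own axis, in degrees in [0, 360).

    Measured between the projections, onto the plane normal to the helix
    axis, of the outward bilayer normal and of the reference side chain
    (side-chain COM minus C-alpha). 0 deg: side chain points straight toward
    water; 180 deg: straight toward the membrane center.
    """
    if axis is None:
        axis, _ = helix_axis(frame)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    sc_mask = frame.sidechain_mask(reference_residue)
    if not np.any(sc_mask):
        raise SelectionError(f"residue {reference_residue} has no side-chain atoms")
    ca = frame.xyz[frame.atom_index(reference_residue, "CA")]
    w = frame.com(sc_mask) - ca
    sign = outward_normal_sign(frame, z0=z0)
    n_vec = np.zeros(3)
    n_vec[frame.normal_axis] = sign
    n_proj = n_vec - np.dot(n_vec, axis) * axis
    w_proj = w - np.dot(w, axis) * axis
    if np.linalg.norm(n_proj) < 1e-9:
        raise DegenerateGeometryError("helix axis is parallel to the bilayer normal")
    if np.linalg.norm(w_proj) < 1e-9:
        raise DegenerateGeometryError("side chain is parallel to the helix axis")
    e1 = n_proj / np.linalg.norm(n_proj)
    e2 = np.cross(e1, axis)
    angle = math.degrees(math.atan2(float(np.dot(w_proj, e2)),
                                    float(np.dot(w_proj, e1))))
    return angle % 360.0


# --------------------------------------------------------------------------
# per-residue depths and COM distances
# --------------------------------------------------------------------------

def residue_depths(obj: Frame | Ensemble, z0: float | None = None,
                   center_mode: str = "mass",
                   discard_fraction: float = 0.0) -> pd.DataFrame:
    """Per-residue insertion depths |z - z0| for C-alpha and side-chain COM.

    The side chain is every non-backbone atom of the residue; glycine-like
    residues without side-chain atoms get a C-alpha depth only and are
    flagged. For ensembles the leading ``discard_fraction`` of frames is
    dropped before averaging.
    """
    frames = _frames_of(obj)
    if not 0 <= discard_fraction < 1:
        raise InvalidInputError("discard_fraction must be in [0, 1)")
    start = int(len(frames) * discard_fraction)
    frames = frames[start:] or frames[-1:]
    residues = frames[0].peptide_residues()
    if len(residues) == 0:
        raise SelectionError("no peptide residues present")
    ca_depths = {r: [] for r in residues}
    sc_depths = {r: [] for r in residues}
    for f in frames:
        zc = (float(z0) if z0 is not None else
              bilayer_center(f, mode=center_mode)
              if np.any(f.group_tags == "lipid") else 0.0)
        for r in residues:
            try:
                ca = f.xyz[f.atom_index(r, "CA")]
                ca_depths[r].append(abs(ca[f.normal_axis] - zc))
            except SelectionError:
                pass
            sc = f.sidechain_mask(r)
            if np.any(sc):
                com = f.com(sc)
                sc_depths[r].append(abs(com[f.normal_axis] - zc))
    rows = []
    for r in residues:
        name = frames[0].residue_names[frames[0].residue_index == r][0]
        ca = np.asarray(ca_depths[r])
        sc = np.asarray(sc_depths[r])
        rows.append({
            "residue_index": int(r), "residue_name": str(name),
            "calpha_depth_mean": float(ca.mean()) if len(ca) else float("nan"),
            "calpha_depth_sd": float(ca.std(ddof=0)) if len(ca) else float("nan"),
            "sidechain_depth_mean": float(sc.mean()) if len(sc) else float("nan"),
            "sidechain_depth_sd": float(sc.std(ddof=0)) if len(sc) else float("nan"),
            "sidechain_missing": len(sc) == 0,
        })
    return pd.DataFrame(rows)


def _min_image(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)


def com_distance(frame: Frame, res_a: int, res_b: int,
                 selection: str = "sidechain") -> float:
    """Distance between mass-weighted centroids of two residue selections.

    ``selection`` is 'sidechain' or 'all'; minimum-image convention applies
    when the frame carries a box.
    """
    def sel(r: int) -> np.ndarray:
        if selection == "sidechain":
            m = frame.sidechain_mask(r)
        elif selection == "all":
            m = frame.residue_index == r
        else:
            raise InvalidInputError(f"unknown selection {selection!r}")
        if not np.any(m):
            raise SelectionError(f"empty selection for residue {r}")
        return m

    d = frame.com(sel(res_b)) - frame.com(sel(res_a))
    return float(np.linalg.norm(_min_image(d, frame.box)))


# --------------------------------------------------------------------------
# hydrogen bonds and contacts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactRecord:
    """A detected contact (hydrogen bond or pi-cation) with its geometry."""

    kind: str
    frame_index: int
    donor_residue: int
    donor_atom: str
    acceptor_residue: int
    acceptor_atom: str
    distance: float          # [A]
    angle: float             # [deg]


def _donor_hydrogens(frame: Frame, donor_idx: int) -> np.ndarray:
    """Hydrogens bound to a donor heavy atom, resolved by naming convention.

    For donor 'XYZ' the attached hydrogens are named 'H' + 'YZ...' plus an
    optional digit (NE -> HE; NH1 -> HH11, HH12; N -> H, H1..H3; OW -> HW1).
    """
    name = str(frame.names[donor_idx])
    resid = frame.residue_index[donor_idx]
    suffix = name[1:]
    in_res = np.flatnonzero((frame.residue_index == resid) &
                            (frame.elements == "H"))
    out = []
    for i in in_res:
        hname = str(frame.names[i])
        stem = "H" + suffix
        if hname == stem or (hname.startswith(stem) and
                             hname[len(stem):].isdigit()):
            out.append(i)
    return np.asarray(out, dtype=int)


def select_arg_guanidinium_n(frame: Frame) -> np.ndarray:
    return np.flatnonzero((frame.residue_names == "ARG") &
                          np.isin(frame.names, list(ARG_GUANIDINIUM_N)))


def select_phosphate_oxygens(frame: Frame) -> np.ndarray:
    return np.flatnonzero((frame.group_tags == "lipid") &
                          np.isin(frame.names, list(PHOSPHATE_OXYGEN_NAMES)))


def select_water_oxygens(frame: Frame) -> np.ndarray:
    return np.flatnonzero((frame.group_tags == "water") &
                          np.isin(frame.names, list(WATER_OXYGEN_NAMES)))


HBOND_PRESETS = {
    "arg-phosphate": (select_arg_guanidinium_n, select_phosphate_oxygens),
    "arg-water": (select_arg_guanidinium_n, select_water_oxygens),
}


def count_hbonds(frame: Frame,
                 donors: np.ndarray | str = "arg-phosphate",
                 acceptors: np.ndarray | None = None,
                 distance_cutoff: float = 3.5,
                 angle_cutoff: float = 30.0,
                 missing_hydrogens: str = "error",
                 frame_index: int = 0) -> tuple[int, list[ContactRecord]]:
    """Geometric hydrogen-bond count between donor and acceptor selections.

    Criterion: donor-acceptor heavy-atom distance <= 3.5 A *and*
    H-donor-acceptor angle <= 30 deg (both configurable). Donors without
    resolvable hydrogens either raise (``missing_hydrogens='error'``) or fall
    back to the distance-only criterion with a warning (``'distance'``).
    """
    if isinstance(donors, str):
        donor_fn, acceptor_fn = HBOND_PRESETS[donors]
        donor_idx = donor_fn(frame)
        acceptor_idx = acceptor_fn(frame) if acceptors is None else np.asarray(acceptors)
    else:
        donor_idx = np.asarray(donors, dtype=int)
        if acceptors is None:
            raise InvalidInputError("explicit donors require explicit acceptors")
        acceptor_idx = np.asarray(acceptors, dtype=int)
    records: list[ContactRecord] = []
    box = frame.box
    for d in donor_idx:
        hyds = _donor_hydrogens(frame, d)
        if len(hyds) == 0:
            if missing_hydrogens == "error":
                raise SelectionError(
                    f"donor {frame.names[d]} in residue {frame.residue_index[d]} "
                    "has no resolvable hydrogens")
            warnings.warn("donor without hydrogens: using distance-only criterion",
                          stacklevel=2)
        dpos = frame.xyz[d]
        for a in acceptor_idx:
            if a == d:
                continue
            vec = _min_image(frame.xyz[a] - dpos, box)
            r_da = float(np.linalg.norm(vec))
            if r_da > distance_cutoff or r_da == 0.0:
                continue
            if len(hyds) == 0:
                best_angle = float("nan")
            else:
                angles = []
                for h in hyds:
                    hv = _min_image(frame.xyz[h] - dpos, box)
                    denom = np.linalg.norm(hv) * r_da
                    if denom == 0:
                        continue
                    cosang = float(np.clip(np.dot(hv, vec) / denom, -1.0, 1.0))
                    angles.append(math.degrees(math.acos(cosang)))
                if not angles:
                    continue
                best_angle = min(angles)
                if best_angle > angle_cutoff:
                    continue
            records.append(ContactRecord(
                kind="hbond", frame_index=frame_index,
                donor_residue=int(frame.residue_index[d]),
                donor_atom=str(frame.names[d]),
                acceptor_residue=int(frame.residue_index[a]),
                acceptor_atom=str(frame.names[a]),
                distance=r_da, angle=best_angle))
    return len(records), records


def detect_bidentate(records: Sequence[ContactRecord]) -> pd.DataFrame:
    """Bidentate arginine-phosphate bonds from hydrogen-bond records.

    An arginine is bidentate in a frame iff >= 2 simultaneous hydrogen bonds
    run from its guanidinium nitrogens to oxygens of a single phosphate
    group (identified by the acceptor residue). Returns one row per
    (frame, donor residue) with the bond count and a bidentate flag.
    """
    guan = set(ARG_GUANIDINIUM_N)
    rows: dict[tuple[int, int, int], int] = {}
    for rec in records:
        if rec.kind != "hbond" or rec.donor_atom not in guan:
            continue
        key = (rec.frame_index, rec.donor_residue, rec.acceptor_residue)
        rows[key] = rows.get(key, 0) + 1
    out = []
    per_res: dict[tuple[int, int], dict] = {}
    for (fi, dres, ares), n in rows.items():
        slot = per_res.setdefault((fi, dres), {"n_bonds": 0, "bidentate": 0})
        slot["n_bonds"] += n
        if n >= 2:
            slot["bidentate"] += 1
    for (fi, dres), slot in sorted(per_res.items()):
        out.append({"frame_index": fi, "donor_residue": dres,
                    "n_bonds": slot["n_bonds"],
                    "n_bidentate": slot["bidentate"],
                    "bidentate": slot["bidentate"] > 0})
    return pd.DataFrame(out, columns=["frame_index", "donor_residue", "n_bonds",
                                      "n_bidentate", "bidentate"])


def _ring_centroid_normal(frame: Frame, residue: int) -> tuple[np.ndarray, np.ndarray]:
    idx = [frame.atom_index(residue, a) for a in TRP_RING_ATOMS]
    coords = frame.xyz[idx]
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid, full_matrices=False)
    return centroid, vt[2]  # smallest-variance direction = ring normal


def detect_pi_cation(frame: Frame,
                     cation_residues: Sequence[int] | None = None,
                     aromatic_residues: Sequence[int] | None = None,
                     distance_cutoff: float = 6.0,
                     frame_index: int = 0) -> list[ContactRecord]:
    """Pi-cation contacts between arginine guanidinium carbons and Trp rings.

    A contact is declared when the CZ-to-indole-centroid distance is at most
    ``distance_cutoff`` (default 6 A). The angle between the ring normal and
    the CZ-centroid vector is reported but not thresholded.
    """
    if cation_residues is None:
        cation_residues = np.unique(
            frame.residue_index[frame.residue_names == "ARG"])
    if aromatic_residues is None:
        aromatic_residues = np.unique(
            frame.residue_index[frame.residue_names == "TRP"])
    records = []
    for c in cation_residues:
        cz = frame.xyz[frame.atom_index(int(c), "CZ")]
        for t in aromatic_residues:
            centroid, normal = _ring_centroid_normal(frame, int(t))
            vec = _min_image(cz - centroid, frame.box)
            dist = float(np.linalg.norm(vec))
            if dist > distance_cutoff or dist == 0.0:
                continue
            cosang = abs(float(np.clip(np.dot(vec / dist, normal), -1.0, 1.0)))
            records.append(ContactRecord(
                kind="pi_cation", frame_index=frame_index,
                donor_residue=int(c), donor_atom="CZ",
                acceptor_residue=int(t), acceptor_atom="ring",
                distance=dist, angle=math.degrees(math.acos(cosang))))
    return records


# --------------------------------------------------------------------------
# helical wheel
# --------------------------------------------------------------------------

def _circular_mean(angles_deg: np.ndarray) -> tuple[float, float]:
    """Mean direction and resultant length of angles in degrees."""
    rad = np.radians(angles_deg)
    s, c = np.sin(rad).mean(), np.cos(rad).mean()
    return math.degrees(math.atan2(s, c)) % 360.0, float(np.hypot(s, c))


def _minimal_arc(angles_deg: np.ndarray) -> float:
    """Smallest arc (deg) containing all given wheel angles."""
    a = np.sort(np.asarray(angles_deg) % 360.0)
    if len(a) < 2:
        return 0.0
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    return 360.0 - float(gaps.max())


def helical_wheel(sequence: str, twist: float = 100.0,
                  class_a: str = "W", class_b: str = "R") -> dict:
    """Edmundson helical-wheel projection with class segregation summary.

    Residue i sits at angle ``(i-1)*twist mod 360``. The summary reports the
    mean resultant direction of each residue class (default Trp vs Arg), the
    angular gap between the two class means, and the minimal arc spanned by
    class A — an amphipathic helix confines one class to a half-wheel.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise InvalidInputError("empty sequence")
    from .chem import AA1_TO_3
    for ch in sequence:
        if ch not in AA1_TO_3:
            raise InvalidInputError(f"unknown residue letter {ch!r}")
    angles = np.array([((i) * twist) % 360.0 for i in range(len(sequence))])
    table = pd.DataFrame({
        "position": np.arange(1, len(sequence) + 1),
        "letter": list(sequence),
        "angle": angles,
    })
    a_angles = angles[[c in class_a for c in sequence]]
    b_angles = angles[[c in class_b for c in sequence]]
    summary: dict = {"table": table}
    if len(a_angles):
        mean_a, r_a = _circular_mean(a_angles)
        summary["class_a_mean_angle"] = mean_a
        summary["class_a_resultant"] = r_a
        summary["class_a_arc"] = _minimal_arc(a_angles)
    if len(b_angles):
        mean_b, r_b = _circular_mean(b_angles)
        summary["class_b_mean_angle"] = mean_b
        summary["class_b_resultant"] = r_b
    if len(a_angles) and len(b_angles):
        gap = abs(summary["class_a_mean_angle"] - summary["class_b_mean_angle"]) % 360.0
        summary["class_gap"] = min(gap, 360.0 - gap)
    return summary
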