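"""Synthetic generators with known ground truth for every pipeline input.

The generators build desk-scale stand-ins for the study's raw data: an
ideal alpha-helix with full backbone geometry, a slab bilayer with marker
particles at canonical subgroup depths, placement of the helix at a
controlled (tilt, azimuth, depth) pose, thermally jittered multi-frame
ensembles, contact-geometry fixtures (guanidinium-phosphate, Arg-in-Trp
pocket) and per-residue chemical-shift tables. Each generator is
deterministic given its seed and records complete ground truth in the
output metadata, so every analysis has a construction-vs-recovery test.

All fixtures are synthetic: marker depths are idealized constants, not
samples from a lipid force field — the analyses only need known ground
truth, not physical realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import (AA1_TO_3, ELEMENT_MASSES, SIDECHAIN_MASSES)
from .errors import InvalidInputError
from .frame import Ensemble, Frame
from .geometry import azimuthal_angle, helix_axis, rotation_about
from .secstruct import RANDOM_COIL_HA

__all__ = [
    "PoseSpec", "SlabSpec", "build_ideal_helix", "build_slab", "place_helix",
    "make_ensemble", "make_shift_table", "build_guanidinium_phosphate",
    "build_arg_trp_pocket", "make_spre_table",
]

RW16_SEQUENCE = "RRWRRWWRRWWRRWRR"

# Ideal backbone internal coordinates (bond lengths [A], angles [deg]).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.00
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N = 121.7, 111.2, 116.2


@dataclass(frozen=True)
class PoseSpec:
    """Target helix pose: tilt/azimuth [deg] and axis-midpoint depth [A]."""

    tilt: float = 90.0
    azimuth: float = 0.0
    depth: float = 13.0
    leaflet: str = "upper"
    sequence: str = RW16_SEQUENCE
    reference_residue: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.tilt < 180.0:
            raise InvalidInputError("tilt must be in (0, 180) degrees")
        if self.depth < 0:
            raise InvalidInputError("depth must be >= 0")
        if self.leaflet not in ("upper", "lower"):
            raise InvalidInputError("leaflet must be 'upper' or 'lower'")


@dataclass(frozen=True)
class SlabSpec:
    """Slab bilayer with marker particles at canonical subgroup depths.

    Default depths emulate a ~30 A hydrocarbon core within a ~50 A bilayer:
    chain markers < glycerol (16 A) < phosphate (20 A) < choline N (22 A),
    mirrored in both leaflets. Water fills the slabs beyond ``water_zmin``.
    """

    n_lipids_per_leaflet: int = 36
    area_per_lipid: float = 70.0          # [A^2]
    depth_phosphate: float = 20.0
    depth_glycerol: float = 16.0
    depth_choline: float = 22.0
    chain_depths: tuple[float, ...] = (4.0, 8.0, 12.0)
    water_zmin: float = 25.0
    water_zmax: float = 34.0
    water_density: float = 0.01           # particles per A^3 (down-sampled)
    jitter_xy: float = 0.8                # lattice jitter [A]

    def __post_init__(self) -> None:
        if not max(self.chain_depths) < self.depth_glycerol < \
                self.depth_phosphate < self.depth_choline:
            raise InvalidInputError(
                "marker depths must be ordered chain < glycerol < phosphate < choline")
        if not self.depth_choline < self.water_zmin < self.water_zmax:
            raise InvalidInputError("water slab must sit beyond the headgroups")


# --------------------------------------------------------------------------
# ideal helix
# --------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d from internal coordinates."""
    theta, phi = math.radians(angle_deg), math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        bond * math.sin(theta) * math.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_helix(sequence: str = RW16_SEQUENCE, phi: float = -57.0,
                      psi: float = -47.0, omega: float = 180.0,
                      sidechain_distance: float = 2.5,
                      with_amide_h: bool = True) -> Frame:
    """Ideal helical peptide with full backbone and pseudo side chains.

    The backbone (N, H, CA, C, O) is chained from standard internal
    coordinates at the requested dihedrals; alpha-helical defaults give a
    rise of ~1.5 A and ~100 deg of twist per residue. Each residue carries a
    single pseudo side-chain particle named ``SC`` placed
    ``sidechain_distance`` from CA directed radially outward from the helix
    axis, carrying the residue's full side-chain mass.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise InvalidInputError("empty sequence")
    for ch in sequence:
        if ch not in AA1_TO_3:
            raise InvalidInputError(f"unknown residue letter {ch!r}")
    n_res = len(sequence)
    # seed atoms of residue 1
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = math.radians(_A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, n_res):
        N.append(_place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi))
        CA.append(_place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, omega))
        C.append(_place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi))
    # pseudo next-residue N to orient the last carbonyl
    n_next = _place_atom(N[-1], CA[-1], C[-1], _B_C_N, _A_CA_C_N, psi)
    O = []
    for i in range(n_res):
        nn = N[i + 1] if i + 1 < n_res else n_next
        u = C[i] - CA[i]
        v = C[i] - nn
        bis = u / np.linalg.norm(u) + v / np.linalg.norm(v)
        O.append(C[i] + _B_C_O * bis / np.linalg.norm(bis))
    H = {}
    if with_amide_h:
        for i in range(1, n_res):
            if sequence[i] == "P":
                continue
            u = N[i] - C[i - 1]
            v = N[i] - CA[i]
            bis = u / np.linalg.norm(u) + v / np.linalg.norm(v)
            H[i] = N[i] + _B_N_H * bis / np.linalg.norm(bis)

    names, elements, masses, resid, resname, xyz = [], [], [], [], [], []

    def add(name: str, element: str, mass: float, i: int, pos: np.ndarray) -> None:
        names.append(name)
        elements.append(element)
        masses.append(mass)
        resid.append(i + 1)
        resname.append(AA1_TO_3[sequence[i]])
        xyz.append(pos)

    for i in range(n_res):
        add("N", "N", ELEMENT_MASSES["N"], i, N[i])
        if i in H:
            add("H", "H", ELEMENT_MASSES["H"], i, H[i])
        add("CA", "C", ELEMENT_MASSES["C"], i, CA[i])
        add("C", "C", ELEMENT_MASSES["C"], i, C[i])
        add("O", "O", ELEMENT_MASSES["O"], i, O[i])

    frame = Frame(names=names, elements=elements, masses=masses,
                  residue_index=resid, residue_names=resname,
                  group_tags=["peptide"] * len(names), xyz=np.array(xyz))
    # radial pseudo side chains need the helix axis of the finished backbone
    if n_res >= 4:
        axis, point = helix_axis(frame)
    else:
        point = np.mean(CA, axis=0)
        direction = CA[-1] - CA[0]
        norm = np.linalg.norm(direction)
        axis = direction / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
    sc_entries = []
    for i in range(n_res):
        ca = CA[i]
        radial = ca - (point + np.dot(ca - point, axis) * axis)
        norm = np.linalg.norm(radial)
        radial = radial / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        sc_entries.append((i, ca + sidechain_distance * radial))
    names2, elements2, masses2, resid2, resname2, xyz2 = [], [], [], [], [], []
    cursor = 0
    for i in range(n_res):
        n_atoms_res = int(np.sum(frame.residue_index == i + 1))
        for k in range(cursor, cursor + n_atoms_res):
            names2.append(frame.names[k]); elements2.append(frame.elements[k])
            masses2.append(frame.masses[k]); resid2.append(frame.residue_index[k])
            resname2.append(frame.residue_names[k]); xyz2.append(frame.xyz[k])
        cursor += n_atoms_res
        sc_mass = SIDECHAIN_MASSES[sequence[i]]
        names2.append("SC"); elements2.append("C"); masses2.append(sc_mass)
        resid2.append(i + 1); resname2.append(AA1_TO_3[sequence[i]])
        xyz2.append(sc_entries[i][1])
    out = Frame(names=names2, elements=elements2, masses=masses2,
                residue_index=resid2, residue_names=resname2,
                group_tags=["peptide"] * len(names2), xyz=np.array(xyz2),
                metadata={"sequence": sequence, "phi": phi, "psi": psi})
    return out


# --------------------------------------------------------------------------
# slab bilayer
# --------------------------------------------------------------------------

def build_slab(spec: SlabSpec = SlabSpec(), seed: int = 0) -> Frame:
    """Slab bilayer of marker particles plus uniform water, ground truth known.

    Each lipid is one residue (``LIP``) carrying a choline-N marker ``NC``,
    a phosphate ``P``, a glycerol ``GL`` and chain fillers ``CH`` stacked at
    the spec depths on a jittered square lattice. Water is a single-particle
    oxygen ``OW`` (mass 18.015, the full water mass) filling both water
    slabs uniformly. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n_side = int(math.ceil(math.sqrt(spec.n_lipids_per_leaflet)))
    spacing = math.sqrt(spec.area_per_lipid)
    box_l = n_side * spacing
    box = np.array([box_l, box_l, 2.0 * spec.water_zmax])

    names, elements, masses, resid, resname, group, xyz = [], [], [], [], [], [], []
    res_counter = 0

    def add(name, element, mass, r, rn, tag, pos):
        names.append(name); elements.append(element); masses.append(mass)
        resid.append(r); resname.append(rn); group.append(tag); xyz.append(pos)

    for leaflet_sign in (+1.0, -1.0):
        placed = 0
        for ix in range(n_side):
            for iy in range(n_side):
                if placed >= spec.n_lipids_per_leaflet:
                    break
                placed += 1
                res_counter += 1
                x = (ix + 0.5) * spacing + rng.uniform(-spec.jitter_xy, spec.jitter_xy)
                y = (iy + 0.5) * spacing + rng.uniform(-spec.jitter_xy, spec.jitter_xy)
                add("NC", "N", ELEMENT_MASSES["N"], res_counter, "LIP", "lipid",
                    np.array([x, y, leaflet_sign * spec.depth_choline]))
                add("P", "P", ELEMENT_MASSES["P"], res_counter, "LIP", "lipid",
                    np.array([x, y, leaflet_sign * spec.depth_phosphate]))
                add("GL", "C", ELEMENT_MASSES["C"], res_counter, "LIP", "lipid",
                    np.array([x, y, leaflet_sign * spec.depth_glycerol]))
                for k, dz in enumerate(spec.chain_depths):
                    add(f"CH{k+1}", "C", ELEMENT_MASSES["C"], res_counter, "LIP",
                        "lipid", np.array([x, y, leaflet_sign * dz]))
    water_volume = box_l * box_l * (spec.water_zmax - spec.water_zmin)
    n_water = max(1, int(round(spec.water_density * water_volume)))
    for leaflet_sign in (+1.0, -1.0):
        pos = np.column_stack([
            rng.uniform(0.0, box_l, n_water),
            rng.uniform(0.0, box_l, n_water),
            leaflet_sign * rng.uniform(spec.water_zmin, spec.water_zmax, n_water),
        ])
        for p in pos:
            res_counter += 1
            add("OW", "O", 18.015, res_counter, "HOH", "water", p)
    return Frame(names=names, elements=elements, masses=masses,
                 residue_index=resid, residue_names=resname, group_tags=group,
                 xyz=np.array(xyz), box=box,
                 metadata={"slab_spec": spec.__dict__ | {"seed": seed}})


# --------------------------------------------------------------------------
# pose placement
# --------------------------------------------------------------------------

def place_helix(helix: Frame, slab: Frame | None, pose: PoseSpec) -> Frame:
    """Place a helix into a slab at a controlled (tilt, azimuth, depth) pose.

    The helix is rotated so its N-to-C principal axis makes the requested
    tilt with the outward leaflet normal, spun about its own axis until the
    analysis azimuth of the reference residue equals the requested value,
    and translated so the axis midpoint sits at the requested depth from the
    bilayer center. Ground truth is recorded in the metadata.
    """
    sign = 1.0 if pose.leaflet == "upper" else -1.0
    axis, point = helix_axis(helix)
    work = helix.copy()
    # 1) rotate the helix axis onto the target direction
    theta = math.radians(pose.tilt)
    target = np.array([math.sin(theta), 0.0, sign * math.cos(theta)])
    rot_axis = np.cross(axis, target)
    if np.linalg.norm(rot_axis) < 1e-12:
        rot = np.eye(3) if np.dot(axis, target) > 0 else rotation_about([0, 0, 1], 180.0)
    else:
        angle = math.degrees(math.acos(float(np.clip(np.dot(axis, target), -1, 1))))
        rot = rotation_about(rot_axis, angle)
    work = work.rotated(rot, center=point)
    # 2) translate the axis midpoint to the target depth
    axis2, point2 = helix_axis(work)
    proj = [float(np.dot(work.xyz[i] - point2, axis2))
            for i in np.flatnonzero(work.mask(names=["CA"]))]
    midpoint = point2 + 0.5 * (min(proj) + max(proj)) * axis2
    target_mid = np.array([midpoint[0], midpoint[1], sign * pose.depth])
    work = work.translated(target_mid - midpoint)
    # 3) spin about the axis until the analysis azimuth matches the request
    axis3, _ = helix_axis(work)
    current = azimuthal_angle(work, pose.reference_residue, axis=axis3,
                              z0=0.0)
    # rotating the frame by +delta about the axis lowers the azimuth by delta
    delta = (current - pose.azimuth) % 360.0
    ca_ref = work.xyz[work.atom_index(pose.reference_residue, "CA")]
    work = work.rotated(rotation_about(axis3, delta), center=ca_ref)
    # re-set the depth (spin about an off-axis center can shift the midpoint)
    axis4, point4 = helix_axis(work)
    proj = [float(np.dot(work.xyz[i] - point4, axis4))
            for i in np.flatnonzero(work.mask(names=["CA"]))]
    midpoint = point4 + 0.5 * (min(proj) + max(proj)) * axis4
    shift = np.array([0.0, 0.0, sign * pose.depth - midpoint[2]])
    work = work.translated(shift)

    if slab is not None:
        if slab.box is not None and pose.depth > slab.box[2] / 2.0:
            raise InvalidInputError("pose depth places the peptide outside the box")
        center = np.array([slab.box[0] / 2.0 if slab.box is not None else 0.0,
                           slab.box[1] / 2.0 if slab.box is not None else 0.0, 0.0])
        axis5, point5 = helix_axis(work)
        mid_xy = np.array([point5[0], point5[1], 0.0])
        work = work.translated(center - mid_xy)
        merged = Frame.merge(work, slab)
    else:
        merged = work
    gt_depths = {}
    for r in work.peptide_residues():
        sc = work.sidechain_mask(int(r))
        gt_depths[int(r)] = {
            "calpha": abs(float(work.xyz[work.atom_index(int(r), "CA")][2])),
            "sidechain": abs(float(work.com(sc)[2])) if np.any(sc) else None,
        }
    merged.metadata["pose"] = {
        "tilt": pose.tilt, "azimuth": pose.azimuth, "depth": pose.depth,
        "leaflet": pose.leaflet, "reference_residue": pose.reference_residue,
    }
    merged.metadata["ground_truth_depths"] = gt_depths
    return merged


# --------------------------------------------------------------------------
# ensembles
# --------------------------------------------------------------------------

def make_ensemble(base: Frame, n_frames: int, jitter_sd: float = 0.0,
                  pose_drift_sd: float = 0.0, seed: int = 0,
                  dt_ns: float = 1.0) -> Ensemble:
    """Multi-frame ensemble: i.i.d. Gaussian jitter plus optional pose drift.

    ``pose_drift_sd`` adds a smooth per-frame tilt perturbation (degrees) by
    rotating the peptide about an in-plane axis through its centroid with a
    moving-average noise sequence; jitter is per atom per frame. Frame times
    are assigned at ``dt_ns`` spacing. Deterministic given the seed.
    """
    if n_frames < 1:
        raise InvalidInputError("need at least one frame")
    if jitter_sd < 0 or pose_drift_sd < 0:
        raise InvalidInputError("noise amplitudes must be >= 0")
    rng = np.random.default_rng(seed)
    coords = np.repeat(base.xyz[None, :, :], n_frames, axis=0)
    pep = base.mask(group="peptide")
    if pose_drift_sd > 0 and np.any(pep):
        raw = rng.normal(0.0, pose_drift_sd, n_frames + 8)
        kernel = np.ones(9) / 9.0
        drift = np.convolve(raw, kernel, mode="valid") * 3.0  # restore variance
        centroid = base.xyz[pep].mean(axis=0)
        for i in range(n_frames):
            rot = rotation_about([0.0, 1.0, 0.0], float(drift[i]))
            coords[i, pep] = (coords[i, pep] - centroid) @ rot.T + centroid
    if jitter_sd > 0:
        coords = coords + rng.normal(0.0, jitter_sd, coords.shape)
    times = np.arange(n_frames, dtype=float) * dt_ns
    meta = dict(base.metadata)
    meta["ensemble"] = {"n_frames": n_frames, "jitter_sd": jitter_sd,
                        "pose_drift_sd": pose_drift_sd, "seed": seed,
                        "dt_ns": dt_ns}
    return Ensemble(topology=base.copy(), coords=coords, times=times,
                    metadata=meta)


# --------------------------------------------------------------------------
# contact-geometry fixtures
# --------------------------------------------------------------------------

def build_guanidinium_phosphate(n_o_distance: float = 2.8,
                                bidentate: bool = True,
                                separate_phosphates: bool = False) -> Frame:
    """Arginine guanidinium donating to phosphate oxygens, ideal geometry.

    With ``bidentate`` both NH1 and NH2 donate to two oxygens of one
    phosphate (H on the N-O line, angle 0). With ``separate_phosphates`` the
    two oxygens belong to two different lipid residues, producing two
    monodentate bonds instead.
    """
    nh_sep = 2.3  # NH1-NH2 distance in a guanidinium
    names, elements, masses, resid, resname, group, xyz = [], [], [], [], [], [], []

    def add(name, element, r, rn, tag, pos):
        names.append(name); elements.append(element)
        masses.append(ELEMENT_MASSES[element]); resid.append(r)
        resname.append(rn); group.append(tag); xyz.append(np.asarray(pos, float))

    nh1 = np.array([-nh_sep / 2.0, 0.0, 0.0])
    nh2 = np.array([+nh_sep / 2.0, 0.0, 0.0])
    cz = np.array([0.0, -1.16, 0.0])
    ne = np.array([0.0, -2.49, 0.0])
    add("CZ", "C", 1, "ARG", "peptide", cz)
    add("NE", "N", 1, "ARG", "peptide", ne)
    add("HE", "H", 1, "ARG", "peptide", ne + np.array([0.0, -1.0, 0.0]))
    o_dir = np.array([0.0, 1.0, 0.0])
    o1 = nh1 + n_o_distance * o_dir
    o2 = nh2 + n_o_distance * o_dir
    add("NH1", "N", 1, "ARG", "peptide", nh1)
    add("HH11", "H", 1, "ARG", "peptide", nh1 + _B_N_H * o_dir)
    add("HH12", "H", 1, "ARG", "peptide", nh1 + _B_N_H * np.array([-0.82, -0.57, 0.0]))
    add("NH2", "N", 1, "ARG", "peptide", nh2)
    add("HH21", "H", 1, "ARG", "peptide", nh2 + _B_N_H * o_dir)
    add("HH22", "H", 1, "ARG", "peptide", nh2 + _B_N_H * np.array([0.82, -0.57, 0.0]))
    if separate_phosphates:
        add("O1", "O", 2, "LIP", "lipid", o1)
        add("P", "P", 2, "LIP", "lipid", o1 + np.array([-0.8, 1.3, 0.0]))
        add("O1", "O", 3, "LIP", "lipid", o2)
        add("P", "P", 3, "LIP", "lipid", o2 + np.array([0.8, 1.3, 0.0]))
    else:
        p = 0.5 * (o1 + o2) + np.array([0.0, 1.2, 0.0])
        add("O1", "O", 2, "LIP", "lipid", o1)
        add("O2", "O", 2, "LIP", "lipid", o2)
        add("P", "P", 2, "LIP", "lipid", p)
    return Frame(names=names, elements=elements, masses=masses,
                 residue_index=resid, residue_names=resname, group_tags=group,
                 xyz=np.array(xyz),
                 metadata={"fixture": "guanidinium-phosphate",
                           "bidentate": bidentate and not separate_phosphates})


def _ideal_indole(center: np.ndarray, normal: np.ndarray) -> dict[str, np.ndarray]:
    """Idealized planar 9-atom indole ring centered at ``center``.

    Synthetic geometry: atoms on two fused regular rings of 1.39 A bond
    length lying in the plane perpendicular to ``normal``.
    """
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, normal)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    r6 = 1.39  # hexagon circumradius ~ bond length
    hexagon = {name: r6 * np.array([math.cos(a), math.sin(a)])
               for name, a in zip(
                   ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
                   [math.radians(60.0 * k + 90.0) for k in range(6)])}
    # pentagon fused on the CD2-CE2 edge
    mid = 0.5 * (hexagon["CD2"] + hexagon["CE2"])
    out_dir = mid / np.linalg.norm(mid)
    pent = {
        "NE1": hexagon["CE2"] + 1.37 * out_dir + 0.4 * (hexagon["CE2"] - mid),
        "CG": hexagon["CD2"] + 1.37 * out_dir + 0.4 * (hexagon["CD2"] - mid),
    }
    pent["CD1"] = 0.5 * (pent["NE1"] + pent["CG"]) + 0.9 * out_dir
    flat = {**hexagon, **pent}
    centroid2d = np.mean(list(flat.values()), axis=0)
    return {name: center + (p2 - centroid2d)[0] * e1 + (p2 - centroid2d)[1] * e2
            for name, p2 in flat.items()}


def build_arg_trp_pocket(distance: float = 4.5,
                         trp_residues: Sequence[int] = (10, 11, 14),
                         arg_residue: int = 15) -> Frame:
    """Synthetic Arg-in-Trp-pocket fixture: CZ surrounded by indole rings.

    The guanidinium carbon sits at the origin; each tryptophan contributes
    an idealized planar indole whose centroid lies ``distance`` away with
    the ring normal pointing at CZ — the pocket geometry seen when a lone
    arginine is caged by neighboring tryptophan side chains.
    """
    names, elements, masses, resid, resname, group, xyz = [], [], [], [], [], [], []

    def add(name, element, r, rn, pos):
        names.append(name); elements.append(element)
        masses.append(ELEMENT_MASSES[element]); resid.append(r)
        resname.append(rn); group.append("peptide"); xyz.append(np.asarray(pos, float))

    add("CZ", "C", arg_residue, "ARG", np.zeros(3))
    add("NH1", "N", arg_residue, "ARG", np.array([1.2, 0.6, 0.0]))
    add("NH2", "N", arg_residue, "ARG", np.array([-1.2, 0.6, 0.0]))
    directions = [np.array([0.0, 0.0, 1.0]),
                  np.array([math.sin(math.radians(120.0)), 0.0,
                            math.cos(math.radians(120.0))]),
                  np.array([-math.sin(math.radians(120.0)), 0.0,
                            math.cos(math.radians(120.0))])]
    for r, direction in zip(trp_residues, directions):
        center = distance * direction
        ring = _ideal_indole(center, normal=direction)
        for name, pos in ring.items():
            add(name, "N" if name.startswith("N") else "C", r, "TRP", pos)
    return Frame(names=names, elements=elements, masses=masses,
                 residue_index=resid, residue_names=resname, group_tags=group,
                 xyz=np.array(xyz),
                 metadata={"fixture": "arg-trp-pocket", "distance": distance})


# --------------------------------------------------------------------------
# chemical-shift and sPRE tables
# --------------------------------------------------------------------------

def make_shift_table(sequence: str = RW16_SEQUENCE,
                     helical_range: tuple[int, int] = (2, 14),
                     offset_ppm: float = -0.3, noise_sd: float = 0.0,
                     seed: int = 0) -> pd.DataFrame:
    """Per-residue H-alpha shift table with a helical offset inside a range.

    Observed shifts equal the random-coil reference plus ``offset_ppm`` for
    residues in ``helical_range`` (1-based, inclusive), plus optional
    Gaussian noise. Ground truth is stored in ``DataFrame.attrs``.
    """
    sequence = sequence.strip().upper()
    lo, hi = helical_range
    if not (1 <= lo <= hi <= len(sequence)):
        raise InvalidInputError("helical range outside the sequence")
    rng = np.random.default_rng(seed)
    rows = []
    for i, ch in enumerate(sequence, start=1):
        ref = RANDOM_COIL_HA[ch]
        shift = ref + (offset_ppm if lo <= i <= hi else 0.0)
        if noise_sd > 0:
            shift += rng.normal(0.0, noise_sd)
        rows.append({"residue": i, "aa": ch, "shift_ppm": shift})
    df = pd.DataFrame(rows)
    df.attrs["ground_truth"] = {"helical_range": [lo, hi],
                                "offset_ppm": offset_ppm,
                                "noise_sd": noise_sd, "seed": seed}
    return df


def make_spre_table(slopes: dict[str, float],
                    concentrations: Sequence[float] = (0, 1, 2, 3, 4, 5, 7.5, 10),
                    noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Synthetic sPRE titration: linear intensity decay per atom.

    ``slopes`` maps atom identifiers to decay slopes (per mM); intensity at
    concentration c is ``1 - slope*c`` clipped at a small positive floor.
    """
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, float)
    rows = []
    for atom, slope in slopes.items():
        intens = np.clip(1.0 - slope * conc, 1e-3, None)
        if noise_sd > 0:
            intens = np.clip(intens + rng.normal(0.0, noise_sd, len(conc)), 1e-3, None)
        for c, it in zip(conc, intens):
            rows.append({"atom": atom, "conc_mM": float(c), "intensity": float(it)})
    df = pd.DataFrame(rows)
    df.attrs["ground_truth"] = {"slopes": dict(slopes), "noise_sd": noise_sd,
                                "seed": seed}
    return df
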