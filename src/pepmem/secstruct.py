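"""Hydrogen-bond-pattern secondary structure, helix fractions, NMR observables.

Secondary structure is assigned per frame from backbone hydrogen bonds
using the classical electrostatic bond energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  [kcal/mol]

with a bond declared below -0.5 kcal/mol. An n-turn at residue i means the
carbonyl of i accepts from the amide of i+n (n in 3, 4, 5); two consecutive
n-turns make a minimal helix (G for n=3, H for n=4, I for n=5, priority
H > G > I on overlap), isolated turns are T and everything else C. Strand
machinery is deliberately absent — the package targets short helical
peptides with no beta content — but long-range bonds that look bridge-like
trigger a warning.

The module also block-averages helix fractions over trajectory ensembles
(discard the leading time, split each trajectory into equal blocks, report
mean and SD across all blocks), computes H-alpha secondary chemical shifts
against a shipped random-coil reference table, and fits solvent-PRE
titration slopes into normalized accessibility scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import AA3_TO_1
from .errors import ClashError, InvalidInputError, SelectionError
from .frame import Ensemble, Frame

__all__ = [
    "SecStructTrace", "HelixFractionBlocks", "place_amide_hydrogens",
    "ks_hbond_energy", "assign_secstruct", "helix_fraction",
    "secondary_shift", "spre_fit", "RANDOM_COIL_HA",
]

HELIX_CODES = frozenset("HGI")
KS_ENERGY_CUTOFF = -0.5   # [kcal/mol]
_KS_PREFACTOR = 0.084 * 332.0

# Random-coil H-alpha chemical shifts [ppm], standard published reference
# set for unstructured peptides; swappable via the ``reference`` argument of
# :func:`secondary_shift`.
RANDOM_COIL_HA: dict[str, float] = {
    "A": 4.32, "C": 4.55, "D": 4.64, "E": 4.35, "F": 4.62,
    "G": 3.96, "H": 4.73, "I": 4.17, "K": 4.32, "L": 4.34,
    "M": 4.48, "N": 4.74, "P": 4.42, "Q": 4.34, "R": 4.34,
    "S": 4.47, "T": 4.35, "V": 4.12, "W": 4.66, "Y": 4.55,
}


@dataclass
class SecStructTrace:
    """Per-residue, per-frame secondary-structure codes."""

    codes: np.ndarray                 # (n_frames, n_residues) of 'H','G','I','T','C'
    residue_index: np.ndarray
    times: np.ndarray | None = None  # [ns]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype="<U1")
        if self.codes.ndim == 1:
            self.codes = self.codes[None, :]
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if self.codes.shape[1] != len(self.residue_index):
            raise InvalidInputError("one code per residue per frame required")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != self.codes.shape[0]:
                raise InvalidInputError("one time per frame required")
            if np.any(np.diff(self.times) < 0):
                raise InvalidInputError("frame times must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]

    def as_strings(self) -> list[str]:
        return ["".join(row) for row in self.codes]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fi in range(self.n_frames):
            for ri, code in zip(self.residue_index, self.codes[fi]):
                rows.append({"frame": fi, "residue": int(ri), "code": code})
        return pd.DataFrame(rows)


@dataclass
class HelixFractionBlocks:
    """Block-averaged helix fractions per segment."""

    segments: dict[str, tuple[int, int]]
    block_means: dict[str, list[float]]
    mean: dict[str, float]
    sd: dict[str, float]
    discard_ns: float
    blocks_per_traj: int
    n_blocks: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"segment": seg, "mean": self.mean[seg], "sd": self.sd[seg],
             "n_blocks": len(self.block_means[seg])}
            for seg in self.segments
        ])


# --------------------------------------------------------------------------
# hydrogen placement and bond energy
# --------------------------------------------------------------------------

def _backbone_index(frame: Frame, residue: int, name: str) -> int | None:
    idx = np.flatnonzero((frame.residue_index == residue) & (frame.names == name))
    return int(idx[0]) if len(idx) else None


def place_amide_hydrogens(frame: Frame) -> Frame:
    """Add missing backbone amide hydrogens by ideal geometry.

    For each non-proline residue i > 1 lacking an H, the hydrogen is placed
    1.00 A from N along the unit vector opposite the bisector of the
    C(i-1)->N and CA(i)->N directions. Existing hydrogens are untouched;
    residues with missing backbone atoms are flagged and skipped.
    """
    residues = sorted(frame.peptide_residues())
    additions: list[tuple[int, np.ndarray]] = []  # (insert-after index, position)
    flagged = []
    for k, r in enumerate(residues):
        if k == 0:
            continue
        rn = frame.residue_names[frame.residue_index == r][0]
        if rn == "PRO":
            continue
        if _backbone_index(frame, r, "H") is not None:
            continue
        i_n = _backbone_index(frame, r, "N")
        i_ca = _backbone_index(frame, r, "CA")
        i_cprev = _backbone_index(frame, residues[k - 1], "C")
        if i_n is None or i_ca is None or i_cprev is None:
            flagged.append(int(r))
            continue
        n = frame.xyz[i_n]
        u = n - frame.xyz[i_cprev]
        v = n - frame.xyz[i_ca]
        bis = u / np.linalg.norm(u) + v / np.linalg.norm(v)
        h = n + 1.00 * bis / np.linalg.norm(bis)
        additions.append((i_n, h))
    if flagged:
        warnings.warn(f"residues {flagged} lack backbone atoms; no H placed",
                      stacklevel=2)
    if not additions:
        return frame.copy()
    names = list(frame.names); elements = list(frame.elements)
    masses = list(frame.masses); resid = list(frame.residue_index)
    resname = list(frame.residue_names); group = list(frame.group_tags)
    xyz = list(frame.xyz)
    for i_n, h in sorted(additions, key=lambda t: -t[0]):
        names.insert(i_n + 1, "H"); elements.insert(i_n + 1, "H")
        masses.insert(i_n + 1, 1.008); resid.insert(i_n + 1, resid[i_n])
        resname.insert(i_n + 1, resname[i_n]); group.insert(i_n + 1, group[i_n])
        xyz.insert(i_n + 1, h)
    return Frame(names=names, elements=elements, masses=masses,
                 residue_index=resid, residue_names=resname, group_tags=group,
                 xyz=np.array(xyz), box=frame.box, normal_axis=frame.normal_axis,
                 metadata=dict(frame.metadata))


def ks_hbond_energy(frame: Frame, donor_residue: int, acceptor_residue: int) -> float:
    """Electrostatic backbone hydrogen-bond energy [kcal/mol].

    The donor contributes its amide N-H, the acceptor its carbonyl C=O.
    Depends only on the four pairwise distances r_ON, r_CH, r_OH, r_CN; a
    distance below 0.5 A raises :class:`ClashError`.
    """
    i_n = _backbone_index(frame, donor_residue, "N")
    i_h = _backbone_index(frame, donor_residue, "H")
    i_c = _backbone_index(frame, acceptor_residue, "C")
    i_o = _backbone_index(frame, acceptor_residue, "O")
    if i_n is None or i_h is None:
        raise SelectionError(f"donor residue {donor_residue} lacks N or amide H")
    if i_c is None or i_o is None:
        raise SelectionError(f"acceptor residue {acceptor_residue} lacks C or O")
    xyz = frame.xyz
    r_on = float(np.linalg.norm(xyz[i_o] - xyz[i_n]))
    r_ch = float(np.linalg.norm(xyz[i_c] - xyz[i_h]))
    r_oh = float(np.linalg.norm(xyz[i_o] - xyz[i_h]))
    r_cn = float(np.linalg.norm(xyz[i_c] - xyz[i_n]))
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        raise ClashError("atoms closer than 0.5 A in hydrogen-bond energy")
    return _KS_PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


# --------------------------------------------------------------------------
# assignment
# --------------------------------------------------------------------------

def _assign_frame(frame: Frame, warn_bridges: bool = True) -> tuple[np.ndarray, np.ndarray]:
    residues = sorted(frame.peptide_residues())
    n = len(residues)
    codes = np.full(n, "C", dtype="<U1")
    if n < 5:
        if n > 1:
            warnings.warn("chain shorter than 5 residues: all coil", stacklevel=3)
        return codes, np.asarray(residues)
    work = place_amide_hydrogens(frame)
    resnames = {r: work.residue_names[work.residue_index == r][0] for r in residues}

    def bonded(i_acc: int, j_don: int) -> bool:
        if resnames[residues[j_don]] == "PRO":
            return False
        try:
            e = ks_hbond_energy(work, residues[j_don], residues[i_acc])
        except SelectionError:
            return False
        return e < KS_ENERGY_CUTOFF

    turns = {nn: np.zeros(n, dtype=bool) for nn in (3, 4, 5)}
    for nn in (3, 4, 5):
        for i in range(n - nn):
            turns[nn][i] = bonded(i, i + nn)
    if warn_bridges:
        # long-range bonds outside the helical ladder hint at beta bridges,
        # which this assigner does not classify
        for i in range(n):
            for j in range(n):
                off = j - i
                if off in (3, 4, 5) or abs(off) < 2:
                    continue
                if off > 5 and bonded(i, j):
                    warnings.warn(
                        f"bridge-like hydrogen bond CO({residues[i]})-NH({residues[j]}); "
                        "strand assignment is out of scope", stacklevel=3)
                    break
            else:
                continue
            break
    # minimal helices from two consecutive n-turns; priority H > G > I
    for nn, code in ((4, "H"), (3, "G"), (5, "I")):
        for i in range(1, n - nn):
            if turns[nn][i - 1] and turns[nn][i]:
                for k in range(i, i + nn):
                    if codes[k] == "C" or (code == "H" and codes[k] in "GI"):
                        codes[k] = code
    # isolated turns
    for nn in (3, 4, 5):
        for i in range(n - nn):
            if turns[nn][i]:
                for k in range(i + 1, i + nn):
                    if codes[k] == "C":
                        codes[k] = "T"
    return codes, np.asarray(residues)


def assign_secstruct(obj: Frame | Ensemble) -> SecStructTrace:
    """Assign helix/turn/coil codes per residue (and per frame for ensembles)."""
    if isinstance(obj, Frame):
        codes, residues = _assign_frame(obj)
        return SecStructTrace(codes=codes[None, :], residue_index=residues)
    all_codes = []
    residues = None
    for i, f in enumerate(obj):
        codes, residues = _assign_frame(f, warn_bridges=(i == 0))
        all_codes.append(codes)
    return SecStructTrace(codes=np.stack(all_codes), residue_index=residues,
                          times=obj.times)


# --------------------------------------------------------------------------
# helix fractions
# --------------------------------------------------------------------------

def helix_fraction(traces: SecStructTrace | Sequence[SecStructTrace],
                   segments: dict[str, tuple[int, int]] | None = None,
                   discard_ns: float = 10.0,
                   blocks_per_traj: int = 2) -> HelixFractionBlocks:
    """Block-averaged helix fraction (H, G and I all count as helix).

    For each trajectory trace, frames earlier than ``discard_ns`` are
    dropped, the remainder is split into ``blocks_per_traj`` equal blocks,
    and the helix fraction of each segment is averaged per block. The
    summary is the mean and SD across all blocks of all trajectories.
    """
    if isinstance(traces, SecStructTrace):
        traces = [traces]
    if not traces:
        raise InvalidInputError("at least one trace required")
    if blocks_per_traj < 1:
        raise InvalidInputError("blocks_per_traj must be >= 1")
    residues = traces[0].residue_index
    if segments is None:
        segments = {f"{residues.min()}-{residues.max()}":
                    (int(residues.min()), int(residues.max()))}
    for seg, (lo, hi) in segments.items():
        if not np.any((residues >= lo) & (residues <= hi)):
            raise InvalidInputError(f"segment {seg!r} selects no residues")
    block_means: dict[str, list[float]] = {seg: [] for seg in segments}
    for trace in traces:
        times = (trace.times if trace.times is not None
                 else np.arange(trace.n_frames, dtype=float))
        keep = times >= discard_ns
        if not np.any(keep):
            raise InvalidInputError("discard time exceeds the trajectory length")
        codes = trace.codes[keep]
        for block in np.array_split(np.arange(codes.shape[0]), blocks_per_traj):
            if len(block) == 0:
                continue
            for seg, (lo, hi) in segments.items():
                cols = (residues >= lo) & (residues <= hi)
                helical = np.isin(codes[block][:, cols], list(HELIX_CODES))
                block_means[seg].append(float(helical.mean()))
    mean = {seg: float(np.mean(v)) for seg, v in block_means.items()}
    sd = {seg: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
          for seg, v in block_means.items()}
    n_blocks = len(next(iter(block_means.values())))
    return HelixFractionBlocks(segments=segments, block_means=block_means,
                               mean=mean, sd=sd, discard_ns=discard_ns,
                               blocks_per_traj=blocks_per_traj, n_blocks=n_blocks)


# --------------------------------------------------------------------------
# secondary chemical shifts
# --------------------------------------------------------------------------

def secondary_shift(observed: pd.DataFrame,
                    reference: dict[str, float] | None = None,
                    helical_run_length: int = 4) -> pd.DataFrame:
    """H-alpha secondary shifts: observed minus random-coil reference.

    ``observed`` needs columns ``residue``, ``aa`` (one- or three-letter)
    and ``shift_ppm``. A run of at least ``helical_run_length`` consecutive
    residues with negative delta is flagged helical; detected runs are
    stored in ``DataFrame.attrs['helical_runs']``.
    """
    reference = RANDOM_COIL_HA if reference is None else reference
    df = observed.copy().sort_values("residue").reset_index(drop=True)
    deltas, refs = [], []
    for _, row in df.iterrows():
        aa = str(row["aa"]).strip().upper()
        if len(aa) == 3:
            aa = AA3_TO_1.get(aa, aa)
        if aa not in reference:
            raise InvalidInputError(f"no random-coil reference for residue {aa!r}")
        refs.append(reference[aa])
        deltas.append(float(row["shift_ppm"]) - reference[aa])
    df["reference_ppm"] = refs
    df["delta_ppm"] = deltas
    runs: list[tuple[int, int]] = []
    residues = df["residue"].to_numpy()
    current: list[int] = []
    for i, d in enumerate(deltas):
        contiguous = not current or residues[i] == current[-1] + 1
        if d < 0 and contiguous:
            current.append(int(residues[i]))
        else:
            if len(current) >= helical_run_length:
                runs.append((current[0], current[-1]))
            current = [int(residues[i])] if d < 0 else []
    if len(current) >= helical_run_length:
        runs.append((current[0], current[-1]))
    df.attrs["helical_runs"] = runs
    df.attrs["helical"] = bool(runs)
    return df


# --------------------------------------------------------------------------
# solvent-PRE accessibility
# --------------------------------------------------------------------------

def spre_fit(series: pd.DataFrame) -> pd.DataFrame:
    """Per-atom solvent-accessibility scores from a paramagnetic titration.

    ``series`` needs columns ``atom``, ``conc_mM``, ``intensity``. Each
    atom's intensities are normalized to its zero-agent point, a
    least-squares slope versus concentration is fitted, and |slope| is
    min-max normalized across the dataset to a score in [0, 1]
    (1 = most solvent-exposed). A flat dataset scores 0 with a warning.
    """
    required = {"atom", "conc_mM", "intensity"}
    if not required.issubset(series.columns):
        raise InvalidInputError(f"sPRE table needs columns {sorted(required)}")
    rows = []
    for atom, grp in series.groupby("atom", sort=False):
        grp = grp.sort_values("conc_mM")
        conc = grp["conc_mM"].to_numpy(float)
        intens = grp["intensity"].to_numpy(float)
        if len(conc) < 3 or conc[0] != 0.0:
            raise InvalidInputError(
                f"atom {atom!r}: need >= 3 concentrations including 0")
        if np.any(intens <= 0):
            raise InvalidInputError(f"atom {atom!r}: intensities must be positive")
        norm = intens / intens[0]
        slope = float(np.polyfit(conc, norm, 1)[0])
        rows.append({"atom": atom, "slope_per_mM": slope})
    df = pd.DataFrame(rows)
    mags = df["slope_per_mM"].abs().to_numpy()
    span = mags.max() - mags.min()
    if span == 0:
        warnings.warn("flat sPRE response: all accessibility scores set to 0",
                      stacklevel=2)
        df["score"] = 0.0
    else:
        df["score"] = (mags - mags.min()) / span
    return df
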