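"""Scalar geometric observables on channel trajectories.

Distances, side-chain chi torsions, the S6 kink angle, Arg-Asp salt-bridge
detection, water counts near a residue, and their per-trajectory statistics.
All observables are plain functions of atomic coordinates and are therefore
invariant under rigid-body motion of a frame.

Conventions
-----------
* Distance-table statistics use the population SD (denominator n), reported to
  one decimal Angstrom like printed structural tables.
* Torsions follow the IUPAC sign convention (clockwise positive looking from
  the second toward the third atom), wrapped to (-180, 180] with the branch
  value +180.  Torsion summaries use the circular mean; a linear mean would be
  wrong for distributions near +/-180.
* "Arg(N)-Asp(O)" distances are the minimum over the 6 side-chain pairs
  {NE, NH1, NH2} x {OD1, OD2}, the standard salt-bridge convention; a bridge
  is called formed when the series mean is strictly below the 3 Å cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import circmean, circstd

from .errors import SelectionError, UndefinedTorsionError
from .io import Frame, Trajectory

ARG_SIDECHAIN_N = ("NE", "NH1", "NH2")
ASP_SIDECHAIN_O = ("OD1", "OD2")
SALT_BRIDGE_CUTOFF = 3.0  # Å, series-mean threshold for a formed bridge
WATER_SHELL_CUTOFF = 8.0  # Å, default water-count radius around a residue

#: chi-angle atom quadruples per residue type (chi1 about CA-CB, chi2 about CB-CG)
CHI_ATOMS: dict[tuple[str, int], tuple[str, str, str, str]] = {
    ("TYR", 1): ("N", "CA", "CB", "CG"),
    ("PHE", 1): ("N", "CA", "CB", "CG"),
    ("ILE", 1): ("N", "CA", "CB", "CG1"),
    ("SER", 1): ("N", "CA", "CB", "OG"),
    ("TYR", 2): ("CA", "CB", "CG", "CD1"),
    ("PHE", 2): ("CA", "CB", "CG", "CD1"),
    ("ILE", 2): ("CA", "CB", "CG1", "CD1"),
}

#: backbone-N residues of the S6 kink measurement (WT numbering)
KINK_RESIDUES = (294, 314, 325)  # W294, P314, V325

ILE_CD_NAMES = ("CD1", "CD")  # both dialects appear in the wild


@dataclass(frozen=True)
class ResidueSelector:
    """Identify one residue on one monomer, optionally guarded by its type."""

    monomer: str
    res_seq: int
    expected_name: str | None = None

    def __post_init__(self) -> None:
        if self.res_seq < 1:
            raise SelectionError(f"res_seq must be >= 1, got {self.res_seq}")

    def check(self, traj: Trajectory) -> None:
        name = traj.residue_name(self.monomer, self.res_seq)
        if self.expected_name is not None and name != self.expected_name:
            raise SelectionError(
                f"residue {self.res_seq} (monomer {self.monomer}) is {name}, "
                f"expected {self.expected_name}"
            )

    def label(self) -> str:
        return f"{self.res_seq}({self.monomer})"


@dataclass
class DistanceSeries:
    """A per-frame distance observable with its mean +/- SD (population)."""

    label: str
    values: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty distance series")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        self.mean = float(np.mean(self.values))
        self.sd = float(np.std(self.values))  # population SD, denominator n


@dataclass
class TorsionSeries:
    """Per-frame chi torsion values in degrees, wrapped to (-180, 180]."""

    residue: ResidueSelector
    chi_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def circular_mean(self) -> float:
        return float(circmean(self.values, low=-180.0, high=180.0))

    @property
    def circular_sd(self) -> float:
        return float(circstd(self.values, low=-180.0, high=180.0))


@dataclass
class SaltBridgePair:
    """An Arg-Asp contact: minimum side-chain N-O distance per frame."""

    arg: ResidueSelector
    asp: ResidueSelector
    series: DistanceSeries
    formed: bool
    #: fraction of frames with min N-O below the cutoff (transparency metric)
    occupancy: float


# ---------------------------------------------------------------------------
# Elementary operators
# ---------------------------------------------------------------------------

def distance(a, b) -> float:
    """Euclidean distance between two points (Å)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b))


def _wrap_deg(angle):
    """Wrap degrees to (-180, 180] with branch value +180."""
    wrapped = np.mod(np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


def dihedral_array(p1, p2, p3, p4) -> np.ndarray:
    """Signed dihedral (degrees, IUPAC sign) for stacked (n, 3) point sets."""
    p1, p2, p3, p4 = (np.atleast_2d(np.asarray(p, dtype=float)) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1_norm = np.linalg.norm(n1, axis=1)
    n2_norm = np.linalg.norm(n2, axis=1)
    scale = np.maximum(np.linalg.norm(b2, axis=1), 1e-30)
    if np.any(n1_norm < 1e-9 * scale) or np.any(n2_norm < 1e-9 * scale):
        raise UndefinedTorsionError("collinear bond vectors: torsion undefined")
    b2u = b2 / scale[:, None]
    m = np.cross(b2u, n1)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    return np.asarray(_wrap_deg(np.degrees(np.arctan2(y, x))))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of four points, degrees in (-180, 180].

    IUPAC convention: looking from p2 toward p3, a clockwise rotation of the
    far bond relative to the near bond is positive.  Cis is 0, trans is +180.
    """
    return float(dihedral_array(p1, p2, p3, p4)[0])


def angle_at(vertex, a, b) -> float:
    """Interior angle at ``vertex`` between directions toward a and b, degrees."""
    v1 = np.asarray(a, dtype=float) - np.asarray(vertex, dtype=float)
    v2 = np.asarray(b, dtype=float) - np.asarray(vertex, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise UndefinedTorsionError("coincident points: angle undefined")
    # atan2 form is stable for nearly (anti)parallel vectors
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(v1, v2)), np.dot(v1, v2))))


# ---------------------------------------------------------------------------
# Trajectory observables
# ---------------------------------------------------------------------------

def residue_pair_distance(traj: Trajectory, sel_a: ResidueSelector, sel_b: ResidueSelector,
                          atom_name) -> DistanceSeries:
    """Per-frame distance between the named atom of two residues.

    ``atom_name`` may be a single name or a tuple of accepted alternatives
    (e.g. ``("CD1", "CD")``); the same resolution is applied to both residues.
    """
    sel_a.check(traj)
    sel_b.check(traj)
    pa = traj.atom_series(sel_a.monomer, sel_a.res_seq, atom_name)
    pb = traj.atom_series(sel_b.monomer, sel_b.res_seq, atom_name)
    values = np.linalg.norm(pa - pb, axis=1)
    name = atom_name if isinstance(atom_name, str) else atom_name[0]
    label = f"{sel_a.label()}-{sel_b.label()} {name}"
    return DistanceSeries(label=label, values=values)


def _sidechain_positions(traj: Trajectory, sel: ResidueSelector, names) -> np.ndarray:
    """(n_frames, len(names), 3) positions; all atoms must be present."""
    cols = []
    for n in names:
        try:
            cols.append(traj.atom_series(sel.monomer, sel.res_seq, n))
        except SelectionError:
            raise SelectionError(
                f"side-chain atom {n} missing on residue {sel.label()}"
            ) from None
    return np.stack(cols, axis=1)


def min_NO_distance(frame: Frame, arg: ResidueSelector, asp: ResidueSelector) -> float:
    """Minimum Arg{NE,NH1,NH2} - Asp{OD1,OD2} distance in one frame (Å)."""
    series = min_NO_series(frame.traj, arg, asp)
    return float(series.values[frame.index])


def min_NO_series(traj: Trajectory, arg: ResidueSelector, asp: ResidueSelector) -> DistanceSeries:
    """Per-frame minimum side-chain N-O distance of an Arg-Asp pair."""
    arg.check(traj)
    asp.check(traj)
    npos = _sidechain_positions(traj, arg, ARG_SIDECHAIN_N)  # (nf, 3, 3)
    opos = _sidechain_positions(traj, asp, ASP_SIDECHAIN_O)  # (nf, 2, 3)
    diff = npos[:, :, None, :] - opos[:, None, :, :]
    d = np.linalg.norm(diff, axis=-1)  # (nf, 3, 2)
    values = d.reshape(d.shape[0], -1).min(axis=1)
    label = f"R{arg.label()}(N)-D{asp.label()}(O)"
    return DistanceSeries(label=label, values=values)


def classify_salt_bridge(series: DistanceSeries, cutoff: float = SALT_BRIDGE_CUTOFF) -> bool:
    """True iff the series mean is strictly below the cutoff."""
    return bool(series.mean < cutoff)


def salt_bridge_pair(traj: Trajectory, arg: ResidueSelector, asp: ResidueSelector,
                     cutoff: float = SALT_BRIDGE_CUTOFF) -> SaltBridgePair:
    """Measure an Arg-Asp pair and classify it (mean < cutoff)."""
    series = min_NO_series(traj, arg, asp)
    return SaltBridgePair(
        arg=arg,
        asp=asp,
        series=series,
        formed=classify_salt_bridge(series, cutoff),
        occupancy=float(np.mean(series.values < cutoff)),
    )


def sidechain_chi(traj: Trajectory, residue: ResidueSelector, chi_index: int) -> TorsionSeries:
    """Per-frame chi1 or chi2 torsion of a supported residue type."""
    residue.check(traj)
    res_name = traj.residue_name(residue.monomer, residue.res_seq)
    key = (res_name, chi_index)
    if key not in CHI_ATOMS:
        raise SelectionError(
            f"chi{chi_index} is not defined for residue type {res_name}"
        )
    quads = [traj.atom_series(residue.monomer, residue.res_seq, n) for n in CHI_ATOMS[key]]
    values = dihedral_array(*quads)
    return TorsionSeries(residue=residue, chi_index=chi_index, values=values)


def kink_angle(frame: Frame, monomer: str,
               residues: tuple[int, int, int] = KINK_RESIDUES) -> float:
    """S6 kink: interior angle at the P314 backbone N between the directions
    toward the W294 and V325 backbone N atoms (WT numbering; the trajectory's
    numbering map translates for the deletion mutant).  Degrees in [0, 180]."""
    traj = frame.traj
    w, p, v = (traj.map_res(r) for r in residues)
    pw = frame.atom_position(monomer, w, "N")
    pp = frame.atom_position(monomer, p, "N")
    pv = frame.atom_position(monomer, v, "N")
    return angle_at(pp, pw, pv)


def kink_angle_series(traj: Trajectory, monomer: str,
                      residues: tuple[int, int, int] = KINK_RESIDUES) -> np.ndarray:
    w, p, v = (traj.map_res(r) for r in residues)
    pw = traj.atom_series(monomer, w, "N")
    pp = traj.atom_series(monomer, p, "N")
    pv = traj.atom_series(monomer, v, "N")
    v1 = pw - pp
    v2 = pv - pp
    cross = np.linalg.norm(np.cross(v1, v2), axis=1)
    dot = np.einsum("ij,ij->i", v1, v2)
    return np.degrees(np.arctan2(cross, dot))


def count_waters_within(frame: Frame, residue: ResidueSelector,
                        cutoff: float = WATER_SHELL_CUTOFF) -> int:
    """Number of water oxygens whose minimum distance to any atom of the
    residue is <= cutoff (Å)."""
    residue.check(frame.traj)
    waters = frame.water_positions
    if waters.shape[0] == 0:
        return 0
    res_atoms = frame.residue_positions(residue.monomer, residue.res_seq)
    d = cdist(waters, res_atoms)
    return int(np.sum(d.min(axis=1) <= cutoff))


def histogram_series(values, bin_width: float, circular: bool = False):
    """Normalized histogram of a series; frequencies sum to 1.

    For torsion data set ``circular=True``: the domain is recentered on the
    circular mean before binning so a distribution straddling +/-180 is not
    split artificially; returned bin centers are wrapped back to (-180, 180].
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if circular:
        mu = circmean(values, low=-180.0, high=180.0)
        shifted = _wrap_deg(values - mu)  # now centered on 0, no wrap within data
        lo = np.floor(shifted.min() / bin_width) * bin_width
        hi = np.ceil(shifted.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
        counts, edges = np.histogram(shifted, bins=edges)
        centers = _wrap_deg((edges[:-1] + edges[1:]) / 2.0 + mu)
    else:
        lo = np.floor(values.min() / bin_width) * bin_width
        hi = np.ceil(values.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
        counts, edges = np.histogram(values, bins=edges)
        centers = (edges[:-1] + edges[1:]) / 2.0
    freqs = counts / counts.sum()
    return centers, freqs


def apply_rigid_transform(traj: Trajectory, rotation, translation) -> Trajectory:
    """Return a copy of the trajectory with every frame rotated + translated
    (useful for checking rigid-motion invariance of observables)."""
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    coords = traj.coords @ rotation.T + translation
    return Trajectory(
        monomers=traj.monomers, res_names=traj.res_names, res_seqs=traj.res_seqs,
        atom_names=traj.atom_names, coords=coords, variant=traj.variant,
        numbering_map=traj.numbering_map,
    )
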