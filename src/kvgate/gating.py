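"""Hydrophobic-gate criterion and selectivity-filter/cavity occupancy states.

The cavity entrance of Kv7.4 is lined by the delta carbons of the I308 ring
(I307 in the S269-deletion mutant).  A hydrated K+ ion (radius 3.5 Å) passes
this apolar constriction only if the cross-monomer Cd-Cd distance leaves room
for the ion plus the Cd van der Waals radii: 2 x (3.5 + 1.7) = 10.4 Å.  The
gate call is purely geometric, per frame, on the narrower of the two cross
distances (A-C and B-D) - the narrowest dimension limits passage.

Filter sites S0-S4 and the cavity C are half-open z intervals along the pore
axis.  Only the S4 center (+4.8 Å) and the cytoplasmic boundary (z < -9 Å)
are anchored by the channel geometry; the remaining sites follow the canonical
K+-channel spacing of 3.3 Å and everything is configurable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, SelectionError
from .geometry import ILE_CD_NAMES, ResidueSelector
from .io import Frame, Trajectory

HYDRATED_K_RADIUS = 3.5   # Å, K+ ion with first hydration shell
CD_VDW_RADIUS = 1.7       # Å, van der Waals radius of an aliphatic carbon
ILE_RING_RES_WT = 308     # WT numbering of the gate Ile; mutants map via NumberingMap

S_SITE_LABELS = ("S0", "S1", "S2", "S3", "S4")
CAVITY_LABEL = "C"
S4_CENTER = 4.8           # Å, the filter site adjacent to the cavity
SITE_SPACING = 3.3        # Å, canonical K+/water site spacing in the filter
CYTOPLASM_BOUNDARY = -9.0  # Å, below this z an ion is in the cytoplasm


def passage_threshold(r_hydrated: float = HYDRATED_K_RADIUS,
                      r_vdw: float = CD_VDW_RADIUS) -> float:
    """Minimal cross Cd-Cd distance (Å) for passage of a hydrated K+ ion.

    ``2 * (r_hydrated + r_vdw)``; with the default radii this is 10.4 Å.
    """
    if r_hydrated < 0 or r_vdw < 0:
        raise ValueError("radii must be non-negative")
    return 2.0 * (r_hydrated + r_vdw)


@dataclass
class GateGeometry:
    """Per-frame gate geometry and open/closed calls."""

    threshold: float
    ac: np.ndarray          # Å, Cd-Cd distance monomer A - monomer C
    bd: np.ndarray          # Å, Cd-Cd distance monomer B - monomer D
    open_flags: np.ndarray = field(init=False)
    fraction_open: float = field(init=False)

    def __post_init__(self) -> None:
        self.ac = np.asarray(self.ac, dtype=float)
        self.bd = np.asarray(self.bd, dtype=float)
        if self.ac.shape != self.bd.shape:
            raise ValueError("A-C and B-D series must have equal length")
        self.open_flags = np.minimum(self.ac, self.bd) >= self.threshold
        self.fraction_open = float(np.mean(self.open_flags))


def classify_gate(traj: Trajectory, ile_selectors: dict[str, ResidueSelector] | None = None,
                  threshold: float | None = None) -> GateGeometry:
    """Classify the hydrophobic gate over a trajectory.

    ``ile_selectors`` maps monomer label -> gate Ile selector; by default the
    WT residue 308 is used, translated through the trajectory's numbering map.
    A frame is open iff min(d_AC, d_BD) >= threshold (default 10.4 Å).
    """
    if threshold is None:
        threshold = passage_threshold()
    if ile_selectors is None:
        res = traj.map_res(ILE_RING_RES_WT)
        ile_selectors = {m: ResidueSelector(m, res, "ILE") for m in "ABCD"}
    for m in "ABCD":
        if m not in ile_selectors:
            raise SelectionError(f"no gate Ile selector for monomer {m}")
        ile_selectors[m].check(traj)
    pos = {m: traj.atom_series(s.monomer, s.res_seq, ILE_CD_NAMES)
           for m, s in ile_selectors.items()}
    ac = np.linalg.norm(pos["A"] - pos["C"], axis=1)
    bd = np.linalg.norm(pos["B"] - pos["D"], axis=1)
    return GateGeometry(threshold=threshold, ac=ac, bd=bd)


# ---------------------------------------------------------------------------
# Filter/cavity occupancy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteDefinition:
    """A binding site as a half-open z interval [lo, hi) along the pore axis."""

    label: str
    z_lo: float
    z_hi: float

    def __post_init__(self) -> None:
        if self.label not in S_SITE_LABELS + (CAVITY_LABEL,):
            raise ConfigError(f"invalid site label {self.label!r}")
        if not self.z_lo < self.z_hi:
            raise ConfigError(f"site {self.label}: need z_lo < z_hi")

    def contains(self, z: float) -> bool:
        return self.z_lo <= z < self.z_hi


def default_sites(s4_center: float = S4_CENTER, spacing: float = SITE_SPACING,
                  cavity_floor: float = CYTOPLASM_BOUNDARY) -> list[SiteDefinition]:
    """Default site intervals: S4 centered at +4.8 Å, S3..S0 at successive
    +3.3 Å offsets (each +/- half the spacing, half-open), cavity C from the
    cytoplasmic boundary up to the bottom of S4."""
    half = spacing / 2.0
    sites = []
    for i, label in enumerate(S_SITE_LABELS):  # S0 highest ... S4 lowest
        center = s4_center + spacing * (4 - i)
        sites.append(SiteDefinition(label, center - half, center + half))
    sites.append(SiteDefinition(CAVITY_LABEL, cavity_floor, s4_center - half))
    return sites


def _validate_sites(sites) -> list[SiteDefinition]:
    sites = list(sites)
    intervals = sorted((s.z_lo, s.z_hi, s.label) for s in sites)
    for (lo1, hi1, l1), (lo2, hi2, l2) in zip(intervals, intervals[1:]):
        if lo2 < hi1 - 1e-9:  # tolerance absorbs float rounding at shared edges
            raise ConfigError(f"site intervals {l1} and {l2} overlap")
    return sites


def assign_site(z: float, sites=None) -> str | None:
    """Site label whose half-open interval [lo, hi) contains z, else None."""
    if sites is None:
        sites = default_sites()
    for s in _validate_sites(sites):
        if s.contains(z):
            return s.label
    return None


@dataclass
class OccupancyState:
    """Occupants of S0-S4 and the cavity, with the canonical state string.

    The canonical string lists, from S0 downward, the site label itself when
    K-occupied, "W" when water-occupied, nothing when empty; a trailing "C"
    appears iff the cavity holds a K+ ion (e.g. "S0-W-S2-W-S4-C").
    """

    occupants: dict[str, str]      # site label -> "K" | "W" | "empty"
    canonical: str
    anomalies: tuple[str, ...] = ()  # e.g. two ions in one filter site


def _render_canonical(occupants: dict[str, str]) -> str:
    parts = []
    for label in S_SITE_LABELS:
        occ = occupants.get(label, "empty")
        if occ == "K":
            parts.append(label)
        elif occ == "W":
            parts.append("W")
    if occupants.get(CAVITY_LABEL) == "K":
        parts.append(CAVITY_LABEL)
    return "-".join(parts)


def occupancy_state(frame: Frame, sites=None) -> OccupancyState:
    """Classify each site's occupant (K+ ion beats water beats empty) from the
    z coordinates of ions and water oxygens in one frame."""
    if sites is None:
        sites = default_sites()
    sites = _validate_sites(sites)
    ion_z = np.sort(frame.ion_positions[:, 2]) if frame.ion_positions.size else np.empty(0)
    wat_z = np.sort(frame.water_positions[:, 2]) if frame.water_positions.size else np.empty(0)
    occupants: dict[str, str] = {}
    anomalies: list[str] = []
    for s in sites:
        n_ions = int(np.searchsorted(ion_z, s.z_hi) - np.searchsorted(ion_z, s.z_lo))
        n_wat = int(np.searchsorted(wat_z, s.z_hi) - np.searchsorted(wat_z, s.z_lo))
        if n_ions >= 1:
            occupants[s.label] = "K"
            if n_ions > 1 and s.label != CAVITY_LABEL:
                anomalies.append(f"{n_ions} ions in site {s.label}")
        elif n_wat >= 1:
            occupants[s.label] = "W"
        else:
            occupants[s.label] = "empty"
    return OccupancyState(
        occupants=occupants,
        canonical=_render_canonical(occupants),
        anomalies=tuple(anomalies),
    )


def state_census(traj: Trajectory, sites=None) -> dict[str, float]:
    """Fraction of frames in each canonical occupancy state (sums to 1)."""
    if sites is None:
        sites = default_sites()
    sites = _validate_sites(sites)
    counts = Counter(occupancy_state(frame, sites).canonical for frame in traj)
    n = traj.n_frames
    return {state: c / n for state, c in sorted(counts.items(), key=lambda kv: -kv[1])}
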