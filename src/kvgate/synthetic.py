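"""Synthetic stand-in for the MD data.

Two generators live here:

* :func:`build_toy_channel` constructs a minimal homotetrameric channel
  trajectory (four monomers of the residues the analysis touches, plus filter
  ions and waters) whose *targeted* observables - the cross-monomer Ca-Ca and
  Cd-Cd distances, the adjacent-monomer Ile-Phe Ca-Ca distances and the
  Arg-Asp minimum N-O distances - have exactly the requested mean +/- SD.
  Each targeted distance is drawn per frame from its Gaussian and realized by
  placing the two endpoint atoms along a fixed direction; this is the
  zero-transverse-noise limit of coordinate-noise calibration and makes the
  recovery tests pure statistics.  Untargeted atoms get small isotropic
  jitter.  No physics is simulated.

* :func:`sample_umbrella_windows` draws *exact* Boltzmann samples from a known
  reference free-energy profile under each harmonic umbrella bias, by
  inverse-CDF sampling on a fine grid (step <= 0.01 Å).  There is no dynamics,
  so no autocorrelation or equilibration confounds WHAM parameter-recovery
  tests.

Default parameters are the wild-type / S269-deletion channel statistics the
analysis is built around (see :func:`wt_channel_spec` and
:func:`mutant_channel_spec`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GenerationError
from .gating import default_sites
from .io import NumberingMap, Trajectory
from .pmf import UmbrellaWindow, thermal_energy

WT = "WT"
MUTANT = "dS269"

# -- geometry layout constants (local monomer-A frame: +x radially outward,
#    +z along the pore axis toward the selectivity filter) -------------------
Z_ILE_CA = 0.0
Z_ILE_CD = -3.5
SHELL_RADIUS = (3.0, 6.5)      # Å around the monomer-A Ile Cd, inside the 8 Å cutoff
DECOY_Z = 35.0                 # Å, far above the filter: outside every site and cutoff
SITE_Z_JITTER = 0.3            # Å SD of ion/water placement inside a site (clipped)
INCIDENTAL_JITTER = 0.05       # Å SD on untargeted protein atoms

MONOMER_ANGLES = {"A": 0.0, "B": 90.0, "C": 180.0, "D": 270.0}
ADJACENT = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")]
#: which Asp the table pairs each interface's Arg with (WT numbering)
SALT_PAIR_ASP = {"C-D": 272, "D-A": 272, "A-B": 288, "B-C": 288}

# residues (WT author numbering)
RES_SER, RES_TYR, RES_ASP1, RES_ASP2, RES_TRP, RES_ARG = 269, 270, 272, 288, 294, 297
RES_ILE, RES_PHE, RES_PRO, RES_VAL = 308, 311, 314, 325

#: Tables 1-4 statistics as generator targets: label -> (mean Å, sd Å)
WT_DISTANCE_TARGETS: dict[str, tuple[float, float]] = {
    "cross_ca:A-C": (14.1, 0.5), "cross_ca:B-D": (14.2, 0.5),
    "cross_cd:A-C": (10.8, 0.5), "cross_cd:B-D": (10.9, 0.4),
    "adjacent_ca:A-B": (8.1, 0.6), "adjacent_ca:B-C": (8.6, 0.7),
    "adjacent_ca:C-D": (7.7, 0.7), "adjacent_ca:D-A": (8.3, 0.9),
    "salt:C-D": (3.2, 0.3), "salt:D-A": (5.6, 0.2),
    "salt:A-B": (6.3, 0.4), "salt:B-C": (5.5, 0.3),
}
MUTANT_DISTANCE_TARGETS: dict[str, tuple[float, float]] = {
    "cross_ca:A-C": (11.3, 0.4), "cross_ca:B-D": (11.1, 0.3),
    "cross_cd:A-C": (9.3, 0.5), "cross_cd:B-D": (8.7, 0.5),
    "adjacent_ca:A-B": (7.7, 0.6), "adjacent_ca:B-C": (7.6, 0.5),
    "adjacent_ca:C-D": (7.8, 0.7), "adjacent_ca:D-A": (7.8, 0.8),
    "salt:C-D": (2.6, 0.2), "salt:D-A": (2.7, 0.2),
    "salt:A-B": (2.9, 0.3), "salt:B-C": (2.6, 0.2),
}

#: filter/cavity plans: the WT holds S0-W-S2-W-S4, the mutant traps a fourth
#: ion in the cavity (S0-W-S2-W-S4-C)
WT_SITE_PLAN = {"S0": "K", "S1": "W", "S2": "K", "S3": "W", "S4": "K", "C": "empty"}
MUTANT_SITE_PLAN = {"S0": "K", "S1": "W", "S2": "K", "S3": "W", "S4": "K", "C": "K"}

#: chi torsion modes (degrees) and spreads: the deletion shifts the Tyr chi1
#: mode and tightens the Phe chi2 distribution
WT_CHI_MODES = {"TYR:1": (-65.0, 12.0), "PHE:2": (90.0, 18.0)}
MUTANT_CHI_MODES = {"TYR:1": (180.0, 12.0), "PHE:2": (90.0, 9.0)}


@dataclass
class ToyChannelSpec:
    """Parameters of one synthetic channel trajectory."""

    variant: str
    distance_targets: dict[str, tuple[float, float]]
    chi_modes: dict[str, tuple[float, float]]
    site_plan: dict[str, str]
    shell_waters: int
    decoy_waters: int
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise GenerationError("n_frames must be >= 1")
        valid = {"S0", "S1", "S2", "S3", "S4", "C"}
        if not set(self.site_plan) <= valid:
            raise GenerationError(f"invalid site labels {set(self.site_plan) - valid}")
        for label, (m, s) in self.distance_targets.items():
            if s < 0:
                raise GenerationError(f"target {label}: sd must be >= 0")
            if m <= 0 or m - 6.0 * s <= 0:
                raise GenerationError(
                    f"target {label}: mean {m} with sd {s} implies non-positive distances "
                    "(negative implied radius)"
                )


def wt_channel_spec(n_frames: int = 2000, seed: int = 0, **overrides) -> ToyChannelSpec:
    """The packaged wild-type fixture specification (Tables 1-4 statistics)."""
    kw = dict(
        variant=WT,
        distance_targets=dict(WT_DISTANCE_TARGETS),
        chi_modes=dict(WT_CHI_MODES),
        site_plan=dict(WT_SITE_PLAN),
        shell_waters=50,
        decoy_waters=20,
        n_frames=n_frames,
        seed=seed,
    )
    kw.update(overrides)
    return ToyChannelSpec(**kw)


def mutant_channel_spec(n_frames: int = 2000, seed: int = 1, **overrides) -> ToyChannelSpec:
    """The packaged S269-deletion fixture specification."""
    kw = dict(
        variant=MUTANT,
        distance_targets=dict(MUTANT_DISTANCE_TARGETS),
        chi_modes=dict(MUTANT_CHI_MODES),
        site_plan=dict(MUTANT_SITE_PLAN),
        shell_waters=30,
        decoy_waters=20,
        n_frames=n_frames,
        seed=seed,
    )
    kw.update(overrides)
    return ToyChannelSpec(**kw)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _rot_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _place_torsion(a, b, c, bond: float, angle_deg: float, torsion_deg) -> np.ndarray:
    """Fourth-atom placement from internal coordinates (vectorized NeRF);
    the returned point D satisfies dihedral(a, b, c, D) == torsion_deg."""
    a, b, c = (np.atleast_2d(np.asarray(p, float)) for p in (a, b, c))
    torsion = np.radians(np.atleast_1d(torsion_deg))
    theta = math.radians(angle_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=1, keepdims=True)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n, axis=1, keepdims=True)
    m = np.cross(n, bc)
    d0 = -bond * math.cos(theta) * np.ones_like(torsion)
    d1 = bond * math.sin(theta) * np.cos(torsion)
    d2 = bond * math.sin(theta) * np.sin(torsion)
    return c + d0[:, None] * bc + d1[:, None] * m + d2[:, None] * n


class _Builder:
    """Accumulates the atom table and per-frame coordinates."""

    def __init__(self, n_frames: int):
        self.n = n_frames
        self.monomers: list[str] = []
        self.res_names: list[str] = []
        self.res_seqs: list[int] = []
        self.atom_names: list[str] = []
        self.coords: list[np.ndarray] = []

    def add(self, monomer: str, res_name: str, res_seq: int, atom_name: str, pos) -> None:
        pos = np.asarray(pos, dtype=float)
        if pos.ndim == 1:
            pos = np.tile(pos, (self.n, 1))
        self.monomers.append(monomer)
        self.res_names.append(res_name)
        self.res_seqs.append(res_seq)
        self.atom_names.append(atom_name)
        self.coords.append(pos)

    def build(self, variant: str) -> Trajectory:
        return Trajectory(
            monomers=self.monomers,
            res_names=self.res_names,
            res_seqs=self.res_seqs,
            atom_names=self.atom_names,
            coords=np.stack(self.coords, axis=1),
            variant=variant,
            numbering_map=None if variant == WT else NumberingMap(),
        )


def _pair_key(kind: str, a: str, b: str) -> str:
    return f"{kind}:{a}-{b}"


# ---------------------------------------------------------------------------
# trajectory generator
# ---------------------------------------------------------------------------

def build_toy_channel(spec: ToyChannelSpec) -> Trajectory:
    """Build a synthetic four-fold channel trajectory realizing ``spec``.

    Per frame the channel carries, on each monomer: the gate Ile and ring Phe
    (N, CA, CB, CG1/CG, CD1), the salt-bridge Arg (NE, NH1, NH2) and both Asp
    residues (OD1, OD2), the pore-helix Tyr (chi1 atoms), the S6 kink backbone
    N atoms (Trp/Pro/Val) and, in the WT, the pore Ser; plus K+ ions and water
    oxygens per ``site_plan``, ``shell_waters`` water oxygens within the 8 Å
    shell of the monomer-A Ile and ``decoy_waters`` far outside it.
    Reproducible bit-for-bit from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    mutant = spec.variant != WT
    nmap = NumberingMap() if mutant else None

    def res(wt_seq: int) -> int:
        return nmap.map_res(wt_seq) if nmap else wt_seq

    # deterministic draw order: sorted target labels
    draws = {}
    for key in sorted(spec.distance_targets):
        m, s = spec.distance_targets[key]
        draws[key] = m + s * rng.standard_normal(n)

    b = _Builder(n)
    rot = {m: _rot_z(a) for m, a in MONOMER_ANGLES.items()}

    def jitter():
        return INCIDENTAL_JITTER * rng.standard_normal((n, 3))

    # -- Ile ring (cross targets) + Phe ring (adjacent targets) -------------
    axis = {"A": np.array([1.0, 0, 0]), "C": np.array([-1.0, 0, 0]),
            "B": np.array([0, 1.0, 0]), "D": np.array([0, -1.0, 0])}
    pair_of = {"A": "A-C", "C": "A-C", "B": "B-D", "D": "B-D"}
    ile_ca: dict[str, np.ndarray] = {}
    ile_cd: dict[str, np.ndarray] = {}
    for m in "ABCD":
        d_ca = draws[f"cross_ca:{pair_of[m]}"]
        d_cd = draws[f"cross_cd:{pair_of[m]}"]
        ca = 0.5 * d_ca[:, None] * axis[m] + np.array([0.0, 0.0, Z_ILE_CA])
        cd = 0.5 * d_cd[:, None] * axis[m] + np.array([0.0, 0.0, Z_ILE_CD])
        ile_ca[m] = ca
        ile_cd[m] = cd

    ile_offsets = {
        "N": np.array([0.6, -1.2, 0.6]),
        "CB": np.array([-0.55, 0.8, -1.15]),
        "CG1": np.array([-1.1, 0.35, -2.4]),
    }
    # adjacent Ile->Phe base direction, from the WT-scale base ring
    r_ca_base = spec.distance_targets["cross_ca:A-C"][0] / 2.0
    i_base = np.array([r_ca_base, 0.0, Z_ILE_CA])
    f_base = np.array([6.3 * math.cos(math.radians(65.0)),
                       6.3 * math.sin(math.radians(65.0)), -1.0])
    u0 = (f_base - i_base) / np.linalg.norm(f_base - i_base)

    phe_ca: dict[str, np.ndarray] = {}
    for x, y in ADJACENT:
        d_adj = draws[f"adjacent_ca:{x}-{y}"]
        u = rot[x] @ u0
        phe_ca[y] = ile_ca[x] + d_adj[:, None] * u

    phe_offsets = {"N": np.array([0.5, -1.3, 0.5]), "CB": np.array([-1.0, 0.6, -1.0])}
    phe_cg_off = np.array([-2.2, 0.8, -1.9])  # CB + (-1.2, 0.2, -0.9)
    phe_chi2_mode, phe_chi2_sd = spec.chi_modes.get("PHE:2", (90.0, 15.0))

    for m in "ABCD":
        R = rot[m]
        # Ile
        b.add(m, "ILE", res(RES_ILE), "N", ile_ca[m] + ile_offsets["N"] @ R.T + jitter())
        b.add(m, "ILE", res(RES_ILE), "CA", ile_ca[m])
        b.add(m, "ILE", res(RES_ILE), "CB", ile_ca[m] + ile_offsets["CB"] @ R.T + jitter())
        b.add(m, "ILE", res(RES_ILE), "CG1", ile_ca[m] + ile_offsets["CG1"] @ R.T + jitter())
        b.add(m, "ILE", res(RES_ILE), "CD1", ile_cd[m])
        # Phe
        ca = phe_ca[m]
        n_pos = ca + phe_offsets["N"] @ R.T + jitter()
        cb = ca + phe_offsets["CB"] @ R.T
        cg = ca + phe_cg_off @ R.T
        chi2 = phe_chi2_mode + phe_chi2_sd * rng.standard_normal(n)
        cd1 = _place_torsion(ca, cb, cg, 1.45, 120.0, chi2)
        b.add(m, "PHE", res(RES_PHE), "N", n_pos)
        b.add(m, "PHE", res(RES_PHE), "CA", ca)
        b.add(m, "PHE", res(RES_PHE), "CB", cb)
        b.add(m, "PHE", res(RES_PHE), "CG", cg)
        b.add(m, "PHE", res(RES_PHE), "CD1", cd1)

    # -- pore-helix Tyr (chi1 from chi_modes) and WT Ser ---------------------
    tyr_ca0 = np.array([7.2, 2.5, 5.0])
    tyr_n_off = np.array([0.8, -1.1, 0.6])
    tyr_cb_off = np.array([-0.4, 0.9, 1.1])
    tyr_mode, tyr_sd = spec.chi_modes.get("TYR:1", (-65.0, 12.0))
    ser_ca0 = np.array([7.4, 2.0, 4.2])
    for m in "ABCD":
        R = rot[m]
        ca = (R @ tyr_ca0)[None, :].repeat(n, axis=0)
        npos = ca + tyr_n_off @ R.T
        cb = ca + tyr_cb_off @ R.T
        chi1 = tyr_mode + tyr_sd * rng.standard_normal(n)
        cg = _place_torsion(npos, ca, cb, 1.51, 114.0, chi1)
        b.add(m, "TYR", res(RES_TYR), "N", npos)
        b.add(m, "TYR", res(RES_TYR), "CA", ca)
        b.add(m, "TYR", res(RES_TYR), "CB", cb)
        b.add(m, "TYR", res(RES_TYR), "CG", cg)
        if not mutant:
            ca_s = (R @ ser_ca0)[None, :].repeat(n, axis=0)
            npos_s = ca_s + tyr_n_off @ R.T
            cb_s = ca_s + tyr_cb_off @ R.T
            og = _place_torsion(npos_s, ca_s, cb_s, 1.42, 110.5,
                                -60.0 + 10.0 * rng.standard_normal(n))
            b.add(m, "SER", RES_SER, "N", npos_s)
            b.add(m, "SER", RES_SER, "CA", ca_s)
            b.add(m, "SER", RES_SER, "CB", cb_s)
            b.add(m, "SER", RES_SER, "OG", og)

    # -- interfacial Arg-Asp pairs (salt targets) ----------------------------
    z_asp = {RES_ASP1: 7.0, RES_ASP2: 9.5}
    r_salt = 10.5
    targeted_asp: set[tuple[str, int]] = set()
    for x, y in ADJACENT:
        label = f"{x}-{y}"
        asp_wt = SALT_PAIR_ASP[label]
        targeted_asp.add((y, asp_wt))
        mid = math.radians((MONOMER_ANGLES[x] + MONOMER_ANGLES[y]) / 2.0
                           if not (x, y) == ("D", "A") else 315.0)
        od1 = np.array([r_salt * math.cos(mid), r_salt * math.sin(mid), z_asp[asp_wt]])
        arg_ref = np.array([r_salt * math.cos(math.radians(MONOMER_ANGLES[x])),
                            r_salt * math.sin(math.radians(MONOMER_ANGLES[x])),
                            z_asp[asp_wt]])
        v = arg_ref - od1
        v /= np.linalg.norm(v)
        w = np.cross([0.0, 0.0, 1.0], v)
        w /= np.linalg.norm(w)
        d = draws[f"salt:{label}"]
        mean_d = spec.distance_targets[f"salt:{label}"][0]
        nh1 = od1 + d[:, None] * v
        b.add(x, "ARG", res(RES_ARG), "CA", od1 + (mean_d + 4.0) * v + np.array([0, 0, 1.5]))
        b.add(x, "ARG", res(RES_ARG), "NE", nh1 + 2.3 * v)
        b.add(x, "ARG", res(RES_ARG), "NH1", nh1)
        b.add(x, "ARG", res(RES_ARG), "NH2", nh1 + 1.15 * v + 1.99 * w)
        b.add(y, "ASP", res(asp_wt), "CA", od1 - 1.5 * v + np.array([0, 0, -1.2]))
        b.add(y, "ASP", res(asp_wt), "OD1", od1)
        b.add(y, "ASP", res(asp_wt), "OD2", od1 - 2.2 * v)
    # untargeted Asp copies so every monomer carries both Asp residues
    for m in "ABCD":
        for asp_wt in (RES_ASP1, RES_ASP2):
            if (m, asp_wt) in targeted_asp:
                continue
            base = rot[m] @ np.array([r_salt, 1.5, z_asp[asp_wt]])
            b.add(m, "ASP", res(asp_wt), "CA", base + rot[m] @ np.array([-1.5, 0.3, -1.2]))
            b.add(m, "ASP", res(asp_wt), "OD1", base)
            b.add(m, "ASP", res(asp_wt), "OD2", base + rot[m] @ np.array([-1.6, 1.5, 0.0]))

    # -- S6 kink backbone N atoms -------------------------------------------
    trp_n0 = np.array([9.5, -1.2, 2.0])
    pro_n0 = np.array([9.9 - (0.3 if mutant else 0.0), 0.6, -6.0])
    val_n0 = np.array([8.6, 2.0, -13.5])
    for m in "ABCD":
        R = rot[m]
        kjit = 0.1 * rng.standard_normal((3, n, 3))
        b.add(m, "TRP", res(RES_TRP), "N", (R @ trp_n0) + kjit[0])
        b.add(m, "PRO", res(RES_PRO), "N", (R @ pro_n0) + kjit[1])
        b.add(m, "VAL", res(RES_VAL), "N", (R @ val_n0) + kjit[2])

    # -- ions and waters -----------------------------------------------------
    sites = {s.label: s for s in default_sites()}
    solvent_seq = 1
    for label in ("S0", "S1", "S2", "S3", "S4", "C"):
        occupant = spec.site_plan.get(label, "empty")
        if occupant == "empty":
            continue
        s = sites[label]
        zc = (s.z_lo + s.z_hi) / 2.0
        dz = np.clip(SITE_Z_JITTER * rng.standard_normal(n), -1.2, 1.2)
        half = (s.z_hi - s.z_lo) / 2.0
        dz = np.clip(dz, -0.9 * half, 0.9 * half)
        pos = np.column_stack([np.zeros(n), np.zeros(n), zc + dz])
        if occupant == "K":
            b.add("S", "K", solvent_seq, "K", pos)
        elif occupant == "W":
            b.add("S", "HOH", solvent_seq, "O", pos)
        else:
            raise GenerationError(f"site {label}: occupant must be K/W/empty")
        solvent_seq += 1

    # hydration shell around the monomer-A Ile Cd (inside the 8 Å count)
    for _ in range(spec.shell_waters):
        vec = rng.standard_normal((n, 3))
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        radius = rng.uniform(*SHELL_RADIUS, size=n)
        b.add("S", "HOH", solvent_seq, "O", ile_cd["A"] + radius[:, None] * vec)
        solvent_seq += 1
    # decoy waters far outside every site interval and the 8 Å shell
    for i in range(spec.decoy_waters):
        ang = 2.0 * math.pi * i / max(1, spec.decoy_waters)
        base = np.array([8.0 * math.cos(ang), 8.0 * math.sin(ang), DECOY_Z + 0.5 * i])
        b.add("S", "HOH", solvent_seq, "O", base + 0.5 * rng.standard_normal((n, 3)))
        solvent_seq += 1

    return b.build(spec.variant)


# ---------------------------------------------------------------------------
# reference profiles + exact umbrella sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferencePmf:
    """A known free-energy profile U(z) on a strictly increasing grid."""

    grid: np.ndarray
    U: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "U", np.asarray(self.U, dtype=float))
        if self.grid.size < 2 or not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if self.grid.shape != self.U.shape or not np.all(np.isfinite(self.U)):
            raise ValueError("U must be finite and match the grid")

    def __call__(self, z):
        return np.interp(z, self.grid, self.U)


def reference_pmf_flat(z_range: tuple[float, float] = (-16.0, 1.0),
                       grid_step: float = 0.01) -> ReferencePmf:
    """U(z) = 0: the featureless cytoplasm-to-cavity profile of the WT channel."""
    lo, hi = z_range
    if hi <= lo:
        raise ValueError("z_range must be non-degenerate")
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    return ReferencePmf(grid=grid, U=np.zeros_like(grid), description="flat")


def reference_pmf_barrier(height: float, center: float, width: float,
                          z_range: tuple[float, float] = (-16.0, 1.0),
                          grid_step: float = 0.01) -> ReferencePmf:
    """A Gaussian barrier ``height * exp(-(z-center)^2 / (2 width^2))`` over a
    flat baseline - the mutant-like profile shape."""
    if width <= 0:
        raise ValueError("width must be > 0")
    lo, hi = z_range
    if hi <= lo:
        raise ValueError("z_range must be non-degenerate")
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    U = height * np.exp(-((grid - center) ** 2) / (2.0 * width ** 2))
    return ReferencePmf(grid=grid, U=U,
                        description=f"gaussian barrier h={height} at {center} w={width}")


def sample_umbrella_windows(ref: ReferencePmf, centers, force_constant: float = 10.0,
                            n_per_window: int = 10_000, temperature: float = 300.0,
                            seed: int = 0) -> list[UmbrellaWindow]:
    """Exact Boltzmann draws from ``exp(-[U(z) + k/2 (z-c)^2] / kT)`` per window.

    Sampling is inverse-CDF on a grid of step <= 0.01 Å, so samples follow the
    biased density exactly (no dynamics, no autocorrelation).  Reproducible
    from ``seed``; windows draw from independent child streams so the set is
    invariant to window order.
    """
    if n_per_window < 1:
        raise ValueError("n_per_window must be >= 1")
    centers = np.asarray(centers, dtype=float)
    lo, hi = float(ref.grid[0]), float(ref.grid[-1])
    if np.any(centers < lo) or np.any(centers > hi):
        raise ValueError("window centers must lie within the reference grid")
    step = min(0.01, float(np.min(np.diff(ref.grid))))
    grid = np.arange(lo, hi + 0.5 * step, step)
    U = ref(grid)
    kT = thermal_energy(temperature)
    ss = np.random.SeedSequence(seed)
    windows = []
    for c, child in zip(centers, ss.spawn(len(centers))):
        rng = np.random.default_rng(child)
        logp = -(U + 0.5 * force_constant * (grid - c) ** 2) / kT
        logp -= logp.max()
        p = np.exp(logp)
        if not np.any(p > 0):
            raise GenerationError(f"biased density vanishes everywhere for center {c}")
        cdf = np.concatenate([[0.0], np.cumsum((p[1:] + p[:-1]) * 0.5 * step)])
        cdf /= cdf[-1]
        u = rng.random(n_per_window)
        samples = np.interp(u, cdf, grid)
        windows.append(UmbrellaWindow(center=float(c), force_constant=force_constant,
                                      samples=samples))
    return windows
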