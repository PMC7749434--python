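"""On-disk formats and the in-memory trajectory container.

Reads and writes multi-model PDB trajectories (one MODEL/ENDMDL block per
frame), WHAM-style umbrella-window metadata + time-series files, YAML analysis
configs, and TSV report tables.  The :class:`Trajectory` container stores a
single atom table shared by all frames plus a ``(n_frames, n_atoms, 3)``
coordinate array, MDAnalysis-style, so geometric observables can be computed
vectorized across frames.

Conventions
-----------
* The PDB chain-ID column carries the monomer label A-D of the homotetramer;
  ions and waters live on chain ``S`` (solvent).
* Waters are recognized by residue name HOH/TIP3/WAT/SOL, potassium ions by
  K/POT/K+.  Everything else is protein.
* Author (1-based) residue numbering is preserved verbatim.  The WT <-> mutant
  correspondence of the S269-deletion channel is an explicit
  :class:`NumberingMap` (offset -1 for residues >= 270), never a silent
  renumbering.
* Umbrella time-series files have two whitespace-separated columns; the first
  (time) is ignored and the second is the reaction coordinate z in Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .errors import ConfigError, ParseError, StructureError, SelectionError

WATER_RES_NAMES = frozenset({"HOH", "TIP3", "WAT", "SOL"})
ION_RES_NAMES = frozenset({"K", "POT", "K+"})
MONOMER_LABELS = ("A", "B", "C", "D")
SOLVENT_CHAIN = "S"
#: water oxygen atom names accepted when extracting water positions
WATER_O_NAMES = frozenset({"O", "OW", "OH2"})

CAT_PROTEIN, CAT_ION, CAT_WATER = "protein", "ion", "water"


def _category(res_name: str) -> str:
    if res_name in ION_RES_NAMES:
        return CAT_ION
    if res_name in WATER_RES_NAMES:
        return CAT_WATER
    return CAT_PROTEIN


@dataclass(frozen=True)
class AtomRecord:
    """One atom: monomer (chain) label, residue identity and position in Angstrom."""

    monomer: str
    res_name: str
    res_seq: int
    atom_name: str
    pos: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise StructureError("atom_name must be non-empty")
        if len(self.monomer) != 1:
            raise StructureError(f"monomer label must be one character, got {self.monomer!r}")
        if _category(self.res_name) == CAT_PROTEIN and self.monomer not in MONOMER_LABELS:
            raise StructureError(
                f"protein monomer label must be one of {MONOMER_LABELS}, got {self.monomer!r}"
            )
        if not all(math.isfinite(c) for c in self.pos):
            raise StructureError(f"non-finite position for atom {self.atom_name}")

    @property
    def category(self) -> str:
        return _category(self.res_name)


@dataclass(frozen=True)
class NumberingMap:
    """Residue-number correspondence between WT and a deletion mutant.

    The deletion of one residue shifts all author numbers at or beyond
    ``threshold`` by ``offset`` (default: S269 deletion, -1 for res >= 270,
    so WT I308/F311 become mutant I307/F310).
    """

    offset: int = -1
    threshold: int = 270

    def map_res(self, wt_res_seq: int) -> int:
        """Map a WT residue number to the mutant's author numbering."""
        return wt_res_seq + self.offset if wt_res_seq >= self.threshold else wt_res_seq


class Frame:
    """A lightweight per-frame view onto a :class:`Trajectory`."""

    __slots__ = ("traj", "index")

    def __init__(self, traj: "Trajectory", index: int):
        if not 0 <= index < traj.n_frames:
            raise IndexError(f"frame index {index} out of range")
        self.traj = traj
        self.index = index

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinates of this frame."""
        return self.traj.coords[self.index]

    # -- selections -------------------------------------------------------
    def atom_position(self, monomer: str, res_seq: int, atom_name) -> np.ndarray:
        i = self.traj.atom_index(monomer, res_seq, atom_name)
        return self.coords[i]

    def residue_positions(self, monomer: str, res_seq: int) -> np.ndarray:
        idx = self.traj.residue_indices(monomer, res_seq)
        return self.coords[idx]

    @property
    def ion_positions(self) -> np.ndarray:
        return self.coords[self.traj.ion_indices]

    @property
    def water_positions(self) -> np.ndarray:
        """Positions of water oxygens (O/OW/OH2) in this frame."""
        return self.coords[self.traj.water_o_indices]

    def records(self, category: str | None = None) -> list[AtomRecord]:
        t = self.traj
        out = []
        for i in range(t.n_atoms):
            if category is not None and t.categories[i] != category:
                continue
            x, y, z = self.coords[i]
            out.append(
                AtomRecord(t.monomers[i], t.res_names[i], int(t.res_seqs[i]),
                           t.atom_names[i], (float(x), float(y), float(z)))
            )
        return out

    @property
    def atoms(self) -> list[AtomRecord]:
        return self.records(CAT_PROTEIN)

    @property
    def ions(self) -> list[AtomRecord]:
        return self.records(CAT_ION)

    @property
    def waters(self) -> list[AtomRecord]:
        return [r for r in self.records(CAT_WATER) if r.atom_name in WATER_O_NAMES]


class Trajectory:
    """An ordered set of frames over one fixed atom table.

    Parameters
    ----------
    monomers, res_names, res_seqs, atom_names
        Per-atom annotation arrays of length ``n_atoms``.
    coords
        ``(n_frames, n_atoms, 3)`` array, Angstrom.
    variant
        ``"WT"`` or ``"dS269"`` (the S269-deletion mutant).
    numbering_map
        Optional :class:`NumberingMap` translating WT residue numbers into
        this trajectory's own numbering; ``None`` means identity.
    """

    def __init__(self, monomers, res_names, res_seqs, atom_names, coords,
                 variant: str = "WT", numbering_map: NumberingMap | None = None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise StructureError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise StructureError("a trajectory needs at least one frame")
        n_atoms = coords.shape[1]
        self.monomers = np.asarray(monomers, dtype="U1")
        self.res_names = np.asarray(res_names, dtype="U4")
        self.res_seqs = np.asarray(res_seqs, dtype=int)
        self.atom_names = np.asarray(atom_names, dtype="U4")
        for arr, name in ((self.monomers, "monomers"), (self.res_names, "res_names"),
                          (self.res_seqs, "res_seqs"), (self.atom_names, "atom_names")):
            if len(arr) != n_atoms:
                raise StructureError(f"{name} length {len(arr)} != n_atoms {n_atoms}")
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates")
        self.coords = coords
        self.variant = variant
        self.numbering_map = numbering_map
        self.categories = np.array([_category(r) for r in self.res_names], dtype="U7")
        bad = (self.categories == CAT_PROTEIN) & ~np.isin(self.monomers, MONOMER_LABELS)
        if np.any(bad):
            raise StructureError(
                f"protein atoms on invalid chain(s) {sorted(set(self.monomers[bad]))}; "
                f"expected {MONOMER_LABELS}"
            )
        present = set(self.monomers[self.categories == CAT_PROTEIN])
        if present and present != set(MONOMER_LABELS):
            missing = sorted(set(MONOMER_LABELS) - present)
            if missing:
                raise StructureError(f"monomer(s) {missing} missing from trajectory")
        self._atom_lookup: dict[tuple[str, int, str], int] = {}
        self._residue_lookup: dict[tuple[str, int], list[int]] = {}
        for i in range(n_atoms):
            key = (str(self.monomers[i]), int(self.res_seqs[i]), str(self.atom_names[i]))
            self._atom_lookup.setdefault(key, i)
            self._residue_lookup.setdefault(key[:2], []).append(i)
        self.ion_indices = np.flatnonzero(self.categories == CAT_ION)
        self.water_o_indices = np.flatnonzero(
            (self.categories == CAT_WATER) & np.isin(self.atom_names, sorted(WATER_O_NAMES))
        )

    # -- basic shape -------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, index: int) -> Frame:
        return Frame(self, index)

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Frame]:
        return (Frame(self, i) for i in range(self.n_frames))

    # -- selections --------------------------------------------------------
    def map_res(self, wt_res_seq: int) -> int:
        """WT residue number -> this trajectory's numbering (identity if no map)."""
        if self.numbering_map is None:
            return wt_res_seq
        return self.numbering_map.map_res(wt_res_seq)

    def atom_index(self, monomer: str, res_seq: int, atom_name) -> int:
        """Index of one atom; ``atom_name`` may be a string or a tuple of
        accepted alternatives (e.g. ``("CD1", "CD")`` for the Ile delta carbon)."""
        names = (atom_name,) if isinstance(atom_name, str) else tuple(atom_name)
        for name in names:
            i = self._atom_lookup.get((monomer, res_seq, name))
            if i is not None:
                return i
        raise SelectionError(
            f"atom {'/'.join(names)} of residue {res_seq} (monomer {monomer}) not found"
        )

    def residue_indices(self, monomer: str, res_seq: int) -> np.ndarray:
        idx = self._residue_lookup.get((monomer, res_seq))
        if not idx:
            raise SelectionError(f"residue {res_seq} (monomer {monomer}) not found")
        return np.asarray(idx)

    def residue_name(self, monomer: str, res_seq: int) -> str:
        return str(self.res_names[self.residue_indices(monomer, res_seq)[0]])

    def atom_series(self, monomer: str, res_seq: int, atom_name) -> np.ndarray:
        """(n_frames, 3) positions of one atom across all frames."""
        return self.coords[:, self.atom_index(monomer, res_seq, atom_name), :]


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

def _diagnose_pdb(path: Path) -> None:
    """Line-scan a PDB file that biotite rejected; raise a located error."""
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                    fld = line[lo:hi]
                    try:
                        float(fld)
                    except ValueError:
                        raise ParseError(
                            f"{path}: malformed {label} coordinate field {fld.strip()!r} "
                            f"on line {lineno}"
                        ) from None
                current += 1
    if in_model:
        counts.append(current)
    if len(set(counts)) > 1:
        raise StructureError(f"{path}: inconsistent atom counts across MODEL blocks: {counts}")


def read_pdb_frames(path, variant: str = "WT",
                    numbering_map: NumberingMap | None = None) -> Trajectory:
    """Read a (multi-)model PDB file into a :class:`Trajectory`.

    Frames are delimited by MODEL/ENDMDL records; a file without MODEL records
    is a single implicit frame.  Atoms are partitioned into protein, K+ ions
    (K/POT/K+) and waters (HOH/TIP3/WAT/SOL) by residue name.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:
        _diagnose_pdb(path)  # raises ParseError/StructureError when it finds the cause
        raise ParseError(f"{path}: {exc}") from exc
    if stack.array_length() == 0:
        raise StructureError(f"{path}: no coordinate records")
    return Trajectory(
        monomers=stack.chain_id,
        res_names=stack.res_name,
        res_seqs=stack.res_id,
        atom_names=stack.atom_name,
        coords=stack.coord,
        variant=variant,
        numbering_map=numbering_map,
    )


_ELEMENT_SPECIAL = {"K": "K", "POT": "K", "K+": "K"}


def _guess_element(res_name: str, atom_name: str) -> str:
    if res_name in _ELEMENT_SPECIAL:
        return _ELEMENT_SPECIAL[res_name]
    return atom_name.lstrip("0123456789")[0]


def write_pdb_frames(traj: Trajectory, path) -> None:
    """Write a trajectory as a fixed-column multi-model PDB (coords to 3 decimals)."""
    if traj.n_frames < 1:
        raise StructureError("cannot write an empty trajectory")
    if np.any(traj.res_seqs > 9999):
        raise StructureError("res_seq > 9999 exceeds the fixed-column PDB format limit")
    n = traj.n_atoms
    template = struc.AtomArray(n)
    template.coord = traj.coords[0]
    template.chain_id = traj.monomers.copy()
    template.res_id = traj.res_seqs.copy()
    template.res_name = traj.res_names.copy()
    template.atom_name = traj.atom_names.copy()
    template.element = np.array(
        [_guess_element(r, a) for r, a in zip(traj.res_names, traj.atom_names)], dtype="U2"
    )
    template.hetero = traj.categories != CAT_PROTEIN
    stack = struc.AtomArrayStack(traj.n_frames, n)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = traj.coords
    out = pdbio.PDBFile()
    out.set_structure(stack)
    out.write(str(path))


# ---------------------------------------------------------------------------
# Umbrella windows (WHAM-style metadata + time series)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowFileSet:
    """Entries of a window metadata file: (series path, center Å, k kcal/mol/Å²)."""

    entries: tuple[tuple[Path, float, float], ...]

    def __post_init__(self) -> None:
        centers = [c for _, c, _ in self.entries]
        if len(centers) > 1:
            diffs = np.diff(centers)
            if not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise ParseError("window centers must be strictly monotone")
        if any(k <= 0 for _, _, k in self.entries):
            raise ParseError("window force constants must be > 0")


def _read_series(path: Path) -> np.ndarray:
    """Load the reaction-coordinate column (2nd) of a time-series file."""
    if not path.exists():
        raise FileNotFoundError(f"umbrella time-series file not found: {path}")
    try:
        data = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric sample ({exc})") from exc
    if data.size == 0:
        raise ParseError(f"{path}: empty time series")
    if data.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (time, z), got {data.shape[1]}")
    return data[:, 1]


def read_window_set(metadata_path):
    """Read umbrella windows from a WHAM-style metadata file.

    Each non-blank, non-comment metadata line holds ``series_path center
    force_constant`` (whitespace-separated); series paths are resolved
    relative to the metadata file.  Returns a list of
    :class:`kvgate.pmf.UmbrellaWindow`.
    """
    from .pmf import UmbrellaWindow  # deferred: pmf does not import io

    metadata_path = Path(metadata_path)
    if not metadata_path.exists():
        raise FileNotFoundError(f"window metadata file not found: {metadata_path}")
    entries: list[tuple[Path, float, float]] = []
    with open(metadata_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(
                    f"{metadata_path}:{lineno}: expected 'path center force_constant'"
                )
            try:
                center, k = float(parts[1]), float(parts[2])
            except ValueError:
                raise ParseError(
                    f"{metadata_path}:{lineno}: non-numeric center/force constant"
                ) from None
            series_path = Path(parts[0])
            if not series_path.is_absolute():
                series_path = metadata_path.parent / series_path
            entries.append((series_path, center, k))
    fileset = WindowFileSet(tuple(entries))  # validates monotone centers, k > 0
    return [
        UmbrellaWindow(center=c, force_constant=k, samples=_read_series(p))
        for p, c, k in fileset.entries
    ]


def write_window_set(windows, metadata_path, prefix: str = "window") -> Path:
    """Write umbrella windows as per-window series files plus a metadata file.

    Series lines are ``index z`` with z at 10 significant digits; the metadata
    file references the series files by relative name so the directory is
    relocatable.  Returns the metadata path.
    """
    metadata_path = Path(metadata_path)
    metadata_path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for i, w in enumerate(windows):
        name = f"{prefix}_{i:03d}.dat"
        series_path = metadata_path.parent / name
        with open(series_path, "w") as fh:
            for t, z in enumerate(w.samples):
                fh.write(f"{t} {z:.10g}\n")
        lines.append(f"{name} {w.center:.10g} {w.force_constant:.10g}\n")
    with open(metadata_path, "w") as fh:
        fh.writelines(lines)
    return metadata_path


# ---------------------------------------------------------------------------
# Reports and config
# ---------------------------------------------------------------------------

def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up (the convention of printed structural tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def write_report(table, path) -> None:
    """Write a TSV report.

    ``table`` is either a mapping ``label -> (mean, sd)`` (rendered to one
    decimal Angstrom, the precision of printed distance tables) or a sequence
    of ``(z, G)`` pairs (z to 3 decimals, G to 2 decimals kcal/mol).
    """
    path = Path(path)
    if isinstance(table, Mapping):
        if not table:
            raise ValueError("empty report table")
        with open(path, "w") as fh:
            fh.write("label\tmean_A\tsd_A\n")
            for label, (mean, sd) in table.items():
                fh.write(f"{label}\t{round_half_up(mean, 1):.1f}\t{round_half_up(sd, 1):.1f}\n")
    else:
        rows = list(table)
        if not rows:
            raise ValueError("empty report table")
        with open(path, "w") as fh:
            fh.write("z_A\tG_kcal_mol\n")
            for z, g in rows:
                if g is None or (isinstance(g, float) and math.isnan(g)):
                    fh.write(f"{z:.3f}\tnan\n")
                else:
                    fh.write(f"{z:.3f}\t{g:.2f}\n")


def read_config(path) -> dict:
    """Read a YAML analysis config into a plain dict."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return cfg


def write_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)
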