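"""WT-vs-mutant comparison pipeline and the PMF runner.

Chains the other modules into the full comparative analysis: the four
distance/salt-bridge tables, their WT - mutant differences, the hydrophobic
gate verdict, the filter/cavity occupancy census, cavity water counts and,
when umbrella windows are supplied (or synthesized), the WHAM profile with a
barrier readout in kcal/mol and thermal (kT) units.

Every number in the report is reproducible by calling the underlying module
operation directly - the pipeline performs no arithmetic of its own beyond
row differences.  Each run logs the fully resolved configuration (defaults
included) next to its outputs so reports are self-describing.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import gating, geometry, io, pmf as pmfmod, synthetic
from .errors import ConfigError
from .geometry import ResidueSelector
from .io import NumberingMap, Trajectory

#: WT author numbering of the residues the comparison touches
WT_RES = {"ile": 308, "phe": 311, "arg": 297, "asp1": 272, "asp2": 288}
SALT_LABELS = ("C-D", "D-A", "A-B", "B-C")
CROSS_PAIRS = (("A", "C"), ("B", "D"))

DEFAULT_COMPARE_CONFIG: dict = {
    "seed": 0,
    "n_frames": 2000,
    "wt": {"source": "fixture"},
    "mutant": {"source": "fixture"},
    "gate": {"r_hydrated": gating.HYDRATED_K_RADIUS, "r_vdw": gating.CD_VDW_RADIUS},
    "salt_bridge_cutoff": geometry.SALT_BRIDGE_CUTOFF,
    "water_cutoff": geometry.WATER_SHELL_CUTOFF,
    "pmf": None,
}

DEFAULT_PMF_CONFIG: dict = {
    "temperature": pmfmod.DEFAULT_TEMPERATURE,
    "bin_width": pmfmod.DEFAULT_BIN_WIDTH,
    "tolerance": pmfmod.DEFAULT_TOLERANCE,
    "max_iterations": pmfmod.DEFAULT_MAX_ITERATIONS,
    # far-cytoplasmic baseline: inside z < -9 but clear of the barrier flank
    "reference_interval": [-15.0, -12.0],
    "barrier_region": [-10.0, -5.0],
    "fractions": None,
}


def _merge(defaults: dict, overrides: dict | None) -> dict:
    out = copy.deepcopy(defaults)
    for k, v in (overrides or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _load_config(config) -> dict:
    if config is None:
        config = {}
    elif isinstance(config, (str, Path)):
        config = io.read_config(config)
    return _merge(DEFAULT_COMPARE_CONFIG, config)


def _load_variant(vcfg: dict, variant: str, n_frames: int, seed: int) -> Trajectory:
    source = vcfg.get("source", "fixture")
    if source == "fixture":
        if variant == "wt":
            return synthetic.build_toy_channel(
                synthetic.wt_channel_spec(n_frames=n_frames, seed=seed))
        return synthetic.build_toy_channel(
            synthetic.mutant_channel_spec(n_frames=n_frames, seed=seed + 1))
    if source == "pdb":
        nmap = None if variant == "wt" else NumberingMap()
        return io.read_pdb_frames(vcfg["path"], variant="WT" if variant == "wt" else
                                  synthetic.MUTANT, numbering_map=nmap)
    raise ConfigError(f"variant {variant}: unknown source {source!r}")


@dataclass
class VariantResult:
    """All per-variant measurements feeding the comparison tables."""

    traj: Trajectory
    salt: dict[str, geometry.SaltBridgePair]
    adjacent: dict[str, geometry.DistanceSeries]
    cross_ca: dict[str, geometry.DistanceSeries]
    cross_cd: dict[str, geometry.DistanceSeries]
    gate: gating.GateGeometry
    census: dict[str, float]
    mean_waters: float


@dataclass
class ComparisonReport:
    """The WT-vs-mutant comparison: tables, gate verdict, census and PMF."""

    salt_bridge_table: pd.DataFrame
    adjacent_table: pd.DataFrame
    cross_ca_table: pd.DataFrame
    cross_cd_table: pd.DataFrame
    adjacent_mean_diff: float
    variants: dict[str, VariantResult]
    threshold: float
    pmf_profiles: dict[str, pmfmod.PmfProfile]
    barrier: tuple[float, float, float] | None  # (dG kcal/mol, z Å, kT multiple)


def measure_variant(traj: Trajectory, salt_cutoff: float = geometry.SALT_BRIDGE_CUTOFF,
                    water_cutoff: float = geometry.WATER_SHELL_CUTOFF,
                    threshold: float | None = None) -> VariantResult:
    """Run every geometric observable of the comparison on one trajectory."""
    r = {k: traj.map_res(v) for k, v in WT_RES.items()}
    salt = {}
    for label in SALT_LABELS:
        x, y = label.split("-")
        asp_wt = synthetic.SALT_PAIR_ASP[label]
        salt[label] = geometry.salt_bridge_pair(
            traj,
            ResidueSelector(x, r["arg"], "ARG"),
            ResidueSelector(y, traj.map_res(asp_wt), "ASP"),
            cutoff=salt_cutoff,
        )
    adjacent = {}
    for x, y in synthetic.ADJACENT:
        adjacent[f"{x}-{y}"] = geometry.residue_pair_distance(
            traj, ResidueSelector(x, r["ile"], "ILE"),
            ResidueSelector(y, r["phe"], "PHE"), "CA")
    cross_ca = {}
    cross_cd = {}
    for x, y in CROSS_PAIRS:
        cross_ca[f"{x}-{y}"] = geometry.residue_pair_distance(
            traj, ResidueSelector(x, r["ile"], "ILE"),
            ResidueSelector(y, r["ile"], "ILE"), "CA")
        cross_cd[f"{x}-{y}"] = geometry.residue_pair_distance(
            traj, ResidueSelector(x, r["ile"], "ILE"),
            ResidueSelector(y, r["ile"], "ILE"), geometry.ILE_CD_NAMES)
    gate = gating.classify_gate(traj, threshold=threshold)
    census = gating.state_census(traj)
    ile_a = ResidueSelector("A", r["ile"], "ILE")
    mean_waters = float(np.mean(
        [geometry.count_waters_within(f, ile_a, water_cutoff) for f in traj]))
    return VariantResult(traj=traj, salt=salt, adjacent=adjacent, cross_ca=cross_ca,
                         cross_cd=cross_cd, gate=gate, census=census,
                         mean_waters=mean_waters)


def _res_label(traj: Trajectory, letter: str, wt_seq: int, monomer: str) -> str:
    return f"{letter}{traj.map_res(wt_seq)}({monomer})"


def _comparison_tables(wt: VariantResult, mut: VariantResult):
    rows = []
    for label in SALT_LABELS:
        x, y = label.split("-")
        asp_wt = synthetic.SALT_PAIR_ASP[label]
        rows.append({
            "pair": label,
            "wt_label": f"{_res_label(wt.traj, 'R', WT_RES['arg'], x)}(N)-"
                        f"{_res_label(wt.traj, 'D', asp_wt, y)}(O)",
            "mut_label": f"{_res_label(mut.traj, 'R', WT_RES['arg'], x)}(N)-"
                         f"{_res_label(mut.traj, 'D', asp_wt, y)}(O)",
            "wt_mean_A": wt.salt[label].series.mean, "wt_sd_A": wt.salt[label].series.sd,
            "wt_formed": wt.salt[label].formed,
            "wt_occupancy": wt.salt[label].occupancy,
            "mut_mean_A": mut.salt[label].series.mean, "mut_sd_A": mut.salt[label].series.sd,
            "mut_formed": mut.salt[label].formed,
            "mut_occupancy": mut.salt[label].occupancy,
            "diff_A": wt.salt[label].series.mean - mut.salt[label].series.mean,
        })
    salt_table = pd.DataFrame(rows)

    def dist_table(wt_d, mut_d, wt_lbl, mut_lbl):
        out = []
        for key in wt_d:
            out.append({
                "pair": key,
                "wt_label": wt_lbl(key), "mut_label": mut_lbl(key),
                "wt_mean_A": wt_d[key].mean, "wt_sd_A": wt_d[key].sd,
                "mut_mean_A": mut_d[key].mean, "mut_sd_A": mut_d[key].sd,
                "diff_A": wt_d[key].mean - mut_d[key].mean,
            })
        return pd.DataFrame(out)

    def ilab(traj, key, letter_a="I", letter_b="F", res_a="ile", res_b="phe"):
        x, y = key.split("-")
        return (f"{_res_label(traj, letter_a, WT_RES[res_a], x)}-"
                f"{_res_label(traj, letter_b, WT_RES[res_b], y)}")

    adjacent_table = dist_table(
        wt.adjacent, mut.adjacent,
        lambda k: ilab(wt.traj, k), lambda k: ilab(mut.traj, k))
    cross_ca_table = dist_table(
        wt.cross_ca, mut.cross_ca,
        lambda k: ilab(wt.traj, k, "I", "I", "ile", "ile"),
        lambda k: ilab(mut.traj, k, "I", "I", "ile", "ile"))
    cross_cd_table = dist_table(
        wt.cross_cd, mut.cross_cd,
        lambda k: ilab(wt.traj, k, "I", "I", "ile", "ile"),
        lambda k: ilab(mut.traj, k, "I", "I", "ile", "ile"))
    return salt_table, adjacent_table, cross_ca_table, cross_cd_table


def _run_pmf_stage(pcfg: dict, seed: int):
    """Resolve a per-variant PMF stage: read or synthesize windows, solve."""
    pcfg = _merge(DEFAULT_PMF_CONFIG, pcfg)
    if "windows" in pcfg and pcfg["windows"]:
        windows = io.read_window_set(pcfg["windows"])
    elif "synthetic" in pcfg and pcfg["synthetic"]:
        s = pcfg["synthetic"]
        kind = s.get("kind", "flat")
        z_range = tuple(s.get("z_range", (-16.0, 1.0)))
        if kind == "flat":
            ref = synthetic.reference_pmf_flat(z_range)
        elif kind == "barrier":
            ref = synthetic.reference_pmf_barrier(
                s.get("height", 3.0), s.get("center", -8.0), s.get("width", 1.5), z_range)
        else:
            raise ConfigError(f"unknown synthetic reference kind {kind!r}")
        start, stop, step = s.get("centers", (-14.0, 0.25, 0.5))
        centers = np.arange(start, stop, step)
        windows = synthetic.sample_umbrella_windows(
            ref, centers, force_constant=s.get("force_constant", 10.0),
            n_per_window=int(s.get("n_per_window", 10_000)),
            temperature=pcfg["temperature"], seed=seed)
    else:
        raise ConfigError("pmf stage needs 'windows' (metadata path) or 'synthetic'")
    config = pmfmod.WhamConfig.for_windows(
        windows, bin_width=pcfg["bin_width"], temperature=pcfg["temperature"],
        tolerance=pcfg["tolerance"], max_iterations=int(pcfg["max_iterations"]))
    profile = pmfmod.wham_solve(windows, config)
    profile = pmfmod.anchor_pmf(profile, tuple(pcfg["reference_interval"]))
    dg, z_at = pmfmod.barrier_height(profile, tuple(pcfg["barrier_region"]),
                                     tuple(pcfg["reference_interval"]))
    blocks = None
    if pcfg.get("fractions"):
        blocks = pmfmod.convergence_blocks(windows, config, pcfg["fractions"])
    return profile, (dg, z_at), blocks, pcfg


def run_compare(config=None, output_dir=None) -> ComparisonReport:
    """Run the full WT-vs-mutant comparison; optionally write TSV reports.

    ``config`` is a dict or YAML path layered over the packaged defaults
    (fixture-backed variants, 2000 frames).  When ``output_dir`` is given the
    comparison tables, per-variant census/gate TSVs, optional PMF profiles, a
    plain-text summary and the resolved config are written there.
    """
    cfg = _load_config(config)
    seed = int(cfg["seed"])
    n_frames = int(cfg["n_frames"])
    threshold = gating.passage_threshold(cfg["gate"]["r_hydrated"], cfg["gate"]["r_vdw"])
    results: dict[str, VariantResult] = {}
    for variant in ("wt", "mutant"):
        traj = _load_variant(cfg[variant], variant, n_frames, seed)
        results[variant] = measure_variant(
            traj, salt_cutoff=cfg["salt_bridge_cutoff"],
            water_cutoff=cfg["water_cutoff"], threshold=threshold)
    wt, mut = results["wt"], results["mutant"]
    salt_t, adj_t, cca_t, ccd_t = _comparison_tables(wt, mut)
    adjacent_mean_diff = float(adj_t["diff_A"].mean())

    pmf_profiles: dict[str, pmfmod.PmfProfile] = {}
    barrier = None
    blocks: dict[str, list] = {}
    if cfg.get("pmf"):
        for variant in ("wt", "mutant"):
            pstage = cfg["pmf"].get(variant)
            if not pstage:
                continue
            profile, (dg, z_at), bl, _ = _run_pmf_stage(pstage, seed + 17)
            pmf_profiles[variant] = profile
            if bl:
                blocks[variant] = bl
            if variant == "mutant":
                barrier = (dg, z_at, dg / profile.kT)
        if barrier is None and "wt" in pmf_profiles:
            p = pmf_profiles["wt"]
            dg, z_at = pmfmod.barrier_height(
                p, tuple(DEFAULT_PMF_CONFIG["barrier_region"]),
                tuple(DEFAULT_PMF_CONFIG["reference_interval"]))
            barrier = (dg, z_at, dg / p.kT)

    report = ComparisonReport(
        salt_bridge_table=salt_t, adjacent_table=adj_t, cross_ca_table=cca_t,
        cross_cd_table=ccd_t, adjacent_mean_diff=adjacent_mean_diff,
        variants=results, threshold=threshold, pmf_profiles=pmf_profiles,
        barrier=barrier)
    if output_dir is not None:
        _write_outputs(report, blocks, cfg, Path(output_dir))
    return report


def run_pmf(config, output_dir=None, seed: int | None = None):
    """Standalone PMF reconstruction from a config dict or YAML path.

    Returns ``(profile, (barrier_kcal, z_at_max, barrier_kT), blocks)``.
    """
    if isinstance(config, (str, Path)):
        config = io.read_config(config)
    seed = int(config.get("seed", 0)) if seed is None else seed
    profile, (dg, z_at), blocks, pcfg = _run_pmf_stage(dict(config), seed)
    kt_mult = dg / profile.kT
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_report(list(zip(profile.bin_centers, profile.G)), out / "pmf.tsv")
        if blocks:
            for frac, prof in zip(pcfg["fractions"], blocks):
                io.write_report(list(zip(prof.bin_centers, prof.G)),
                                out / f"pmf_fraction_{frac:g}.tsv")
        with open(out / "barrier.txt", "w") as fh:
            fh.write(f"barrier_kcal_mol\t{dg:.3f}\n")
            fh.write(f"z_at_max_A\t{z_at:.2f}\n")
            fh.write(f"barrier_kT\t{kt_mult:.2f}\n")
        io.write_config(pcfg, out / "resolved_pmf_config.yaml")
    return profile, (dg, z_at, kt_mult), blocks


def _fmt(x: float, nd: int = 1) -> str:
    return f"{io.round_half_up(x, nd):.{nd}f}"


def _write_outputs(report: ComparisonReport, blocks: dict, cfg: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "table1_salt_bridges.tsv": report.salt_bridge_table,
        "table2_adjacent_IF_ca.tsv": report.adjacent_table,
        "table3_cross_ca.tsv": report.cross_ca_table,
        "table4_cross_cd.tsv": report.cross_cd_table,
    }
    for name, df in tables.items():
        rounded = df.copy()
        for col in rounded.columns:
            if col.endswith("_A"):
                rounded[col] = rounded[col].map(lambda v: io.round_half_up(v, 1))
            elif col.endswith("occupancy"):
                rounded[col] = rounded[col].map(lambda v: round(v, 3))
        rounded.to_csv(out / name, sep="\t", index=False)
    for variant, res in report.variants.items():
        io.write_report(
            {f"{variant} A-C Cd-Cd": (float(np.mean(res.gate.ac)), float(np.std(res.gate.ac))),
             f"{variant} B-D Cd-Cd": (float(np.mean(res.gate.bd)), float(np.std(res.gate.bd)))},
            out / f"gate_{variant}.tsv")
        with open(out / f"census_{variant}.tsv", "w") as fh:
            fh.write("state\tfraction\n")
            for state, frac in res.census.items():
                fh.write(f"{state}\t{frac:.4f}\n")
    for variant, profile in report.pmf_profiles.items():
        io.write_report(list(zip(profile.bin_centers, profile.G)),
                        out / f"pmf_{variant}.tsv")
    for variant, bl in blocks.items():
        for i, prof in enumerate(bl):
            io.write_report(list(zip(prof.bin_centers, prof.G)),
                            out / f"pmf_{variant}_block{i}.tsv")
    with open(out / "summary.txt", "w") as fh:
        fh.write(format_summary(report))
    io.write_config(cfg, out / "resolved_config.yaml")


def format_summary(report: ComparisonReport) -> str:
    """Human-readable comparison summary (also written as summary.txt)."""
    wt, mut = report.variants["wt"], report.variants["mutant"]
    lines = []
    lines.append("Kv7.4 WT vs dS269 comparison")
    lines.append("=" * 40)
    lines.append(f"gate passage threshold: {report.threshold:.1f} A (Cd-Cd)")
    lines.append(f"WT fraction open:      {wt.gate.fraction_open:.3f}")
    lines.append(f"mutant fraction open:  {mut.gate.fraction_open:.3f}")
    lines.append("")
    lines.append("cross Cd-Cd differences WT - mutant (A):")
    for _, row in report.cross_cd_table.iterrows():
        lines.append(f"  {row['pair']}: {_fmt(row['diff_A'])}")
    lines.append("cross Ca-Ca differences WT - mutant (A):")
    for _, row in report.cross_ca_table.iterrows():
        lines.append(f"  {row['pair']}: {_fmt(row['diff_A'])}")
    lines.append(f"adjacent I-F Ca-Ca mean difference: {_fmt(report.adjacent_mean_diff)} A")
    lines.append("")
    lines.append("salt bridges (mean N-O, formed = mean < cutoff):")
    for _, row in report.salt_bridge_table.iterrows():
        lines.append(
            f"  {row['pair']}: WT {_fmt(row['wt_mean_A'])} A "
            f"({'formed' if row['wt_formed'] else 'open'}), "
            f"mutant {_fmt(row['mut_mean_A'])} A "
            f"({'formed' if row['mut_formed'] else 'open'})")
    lines.append("")
    lines.append(f"cavity waters within 8 A of Ile: WT {wt.mean_waters:.1f}, "
                 f"mutant {mut.mean_waters:.1f}")
    lines.append("occupancy census (top states):")
    for variant, res in (("WT", wt), ("mutant", mut)):
        top = list(res.census.items())[:3]
        states = ", ".join(f"{s or '(empty)'}: {f:.2f}" for s, f in top)
        lines.append(f"  {variant}: {states}")
    if report.barrier is not None:
        dg, z_at, kt = report.barrier
        lines.append("")
        lines.append(f"PMF barrier: {dg:.2f} kcal/mol at z = {z_at:.1f} A "
                     f"(~{kt:.1f} kT)")
    return "\n".join(lines) + "\n"
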