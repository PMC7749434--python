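# Methods

## The analysis in one paragraph

Kv7.4 is a homotetrameric voltage-gated K⁺ channel; its pore axis is taken as
z, with the selectivity filter above the water-filled cavity and the
cytoplasm below (z < −9 Å). The package quantifies how the ΔS269 pore
deletion reshapes the cavity entrance — the "I-F ring" of Ile and Phe side
chains on adjacent S6 helices — and what that does to ion passage. Geometry
is summarized by cross-monomer distances; passage is judged by a purely
geometric criterion on the Ile Cδ ring; energetics come from umbrella
sampling unbiased with WHAM. All statistics are per-frame observables over a
trajectory, with no time-correlation modelling.

## Geometric observables

* **Distances** are Euclidean, in Å; per-series summaries are mean ± SD with
  the population denominator n, printed to one decimal as in structural
  tables.
* **Salt bridges**: the tables label Arg–Asp contacts only as "N–O", so the
  package uses the standard convention — the minimum over the six side-chain
  pairs {NE, NH1, NH2} × {OD1, OD2}. A bridge is *formed* when the series
  mean is strictly below 3 Å; the per-frame fraction below the cutoff is also
  reported so a reader can distinguish a marginal mean from a stable contact.
* **Torsions** follow the IUPAC sign convention (validated against mdtraj and
  MDAnalysis on reference configurations), wrapped to (−180°, 180°] with
  branch value +180°. Summaries use circular statistics; a linear mean would
  be wrong for the Tyr χ₁ population near ±180°. χ histograms recenter the
  domain on the circular mean before binning so a mode straddling ±180° is
  not split in two.
* **Kink angle**: the interior angle at the P314 backbone N between vectors
  toward the W294 and V325 backbone N atoms, computed with the
  atan2(‖v₁×v₂‖, v₁·v₂) form for stability near 0°/180°.
* **Water counts**: "within 8 Å of the Ile" is interpreted as any water
  oxygen whose minimum distance to *any* atom of the residue is ≤ 8 Å (a
  single-reference-atom reading would be an equally defensible alternative;
  the generator realizes the any-atom contract exactly, so the choice is
  self-consistent end to end).

## Gate criterion and occupancy states

A hydrated K⁺ ion is modelled as a sphere of radius 3.5 Å; adding the 1.7 Å
van der Waals radius of the Ile Cδ carbons on either side gives the passage
threshold 2·(3.5 + 1.7) = 10.4 Å, center-to-center across the pore. A frame
is *open* iff the smaller of the two cross distances (A–C, B–D) reaches the
threshold — the narrowest dimension limits passage. No desolvation energetics
are modelled; the criterion is deliberately geometric.

Filter sites are half-open z intervals. Only two anchors are physically
fixed: the S4 center at +4.8 Å and the cytoplasmic boundary at −9 Å.
S3…S0 follow at the canonical 3.3 Å site spacing (each interval ± half a
spacing), and the cavity C spans [−9.0, 3.15) Å. All intervals are
configurable, since different channels (or site conventions) shift them.
Each site's occupant is K if it holds ≥ 1 ion, else W if ≥ 1 water oxygen,
else empty; two ions in one filter site are flagged as an anomaly but the
state is still rendered. The canonical string lists S0→S4 (label when
K-occupied, "W" when water-occupied, omitted when empty) with a trailing "C"
iff the cavity holds an ion. States are per-frame; trajectory-level structure
is reported as a census of state fractions.

## WHAM

Umbrella windows carry harmonic biases w_i(z) = k/2 (z − c_i)², by default
k = 10 kcal/mol/Å² at 0.5 Å spacing. The self-consistent equations

    P(z_b) ∝ Σ_i n_i(b) / Σ_i N_i exp[(f_i − w_i(z_b))/kT]
    exp(−f_i/kT) = Σ_b P(z_b) exp(−w_i(z_b)/kT)

are iterated synchronously from f_i = 0, in log space (log-sum-exp), until
the largest offset change is below 10⁻⁶ kcal/mol (configurable; cap 10⁵
iterations — non-convergence is reported on the profile, not raised).
Numerical choices:

* Temperature defaults to 300 K (k_B = 1.987204×10⁻³ kcal/mol/K, so
  kT = 0.596 kcal/mol; a 3 kcal/mol barrier is ~5 kT). The MD protocol
  behind the original profiles does not pin the thermostat temperature;
  310 K would also round to 5 kT.
* Bin width defaults to 0.1 Å — five bins per window spacing, fine enough to
  resolve the bias curvature without starving counts.
* Bins with zero total counts have undefined G (NaN). They are excluded from
  anchoring, barrier searches and convergence metrics, never interpolated.
* Adjacent windows with no shared occupied bin trigger a warning; if no
  adjacent pair overlaps at all, reconstruction fails.
* Sample weights are uniform: the synthetic sampler draws independent points,
  so statistical-inefficiency weighting would be a no-op here (and is out of
  scope for real data).

Profiles are anchored so the far-cytoplasmic interval averages zero; the
default [−15, −12] Å sits inside the cytoplasmic region but clear of the
barrier flank (a Gaussian barrier at −8 Å with width 1.5 Å still carries
~2.4 kcal/mol at z = −9, so anchoring right up against −9 would understate
the barrier). Barrier height is max G over the barrier region (default
[−10, −5] Å, first-bin tie-break) minus the reference mean. The convergence
diagnostic re-solves WHAM on leading fractions of every window and reports
max |ΔG| over shared defined bins.

## The synthetic generator

The generator emulates exactly the features the analysis measures, and no
more:

* **Targeted distances** (cross Cα–Cα and Cδ–Cδ, adjacent Ile–Phe Cα–Cα,
  Arg–Asp minimum N–O) are drawn per frame from their target Gaussian and
  realized *exactly* by placing the endpoint atoms along fixed directions in
  an ideal four-fold frame. This is the zero-transverse-noise limit of
  calibrated coordinate noise: isotropic endpoint jitter of SD σ would bias a
  distance mean by ≈ 2σ²/d, which at the larger table SDs (0.8–0.9 Å) is
  comparable to the 3-standard-error recovery bound the tests enforce, so the
  transverse components are dropped rather than approximately compensated.
  Untargeted atoms carry small (0.05 Å) isotropic jitter.
* **Torsions**: Tyr χ₁ and Phe χ₂ are sampled from wrapped normals around
  configurable modes (the deletion shifts the Tyr χ₁ mode and tightens Phe
  χ₂) and realized by internal-coordinate (NeRF) placement. Ile χ₁/χ₂ are
  *emergent*: the Ile Cδ position is owned by the cross-distance targets, so
  its torsions cannot be dialed independently and are only guaranteed to be
  well-defined, not mode-controlled.
* **Solvent**: ions/waters sit at site centers (±0.3 Å clipped jitter, always
  inside the interval) per the variant's site plan — `S0-W-S2-W-S4` for WT,
  `S0-W-S2-W-S4-C` for the mutant. The hydration shell places exactly
  `shell_waters` oxygens 3–6.5 Å from the monomer-A Ile Cδ (inside the 8 Å
  count by construction: WT 50, mutant 30) and decoys far outside every site
  and cutoff.
* **Mutant numbering**: the deletion shifts author numbers ≥ 270 by −1 via an
  explicit map (I308→I307 etc.); nothing is silently renumbered.
* **Umbrella windows** are drawn by inverse-CDF sampling of the exact biased
  Boltzmann density on a ≤ 0.01 Å grid. There is no dynamics: samples are
  i.i.d., so WHAM tests are pure parameter-recovery tests, uncontaminated by
  equilibration or autocorrelation. Reference profiles are a flat baseline
  (WT-like) and a Gaussian barrier (mutant-like; default 3 kcal/mol at −8 Å,
  width 1.5 Å). Windows default to 10⁴ samples each — the per-window
  simulation length of the original protocol is stated only in ns, so the
  count is a free choice sized for sub-minute test runs.

What passing tests therefore show: the estimators are unbiased and correctly
calibrated under ideal, uncorrelated, exactly-Gaussian conditions at the
published means/SDs. What they do not show: robustness to autocorrelated MD
data, anharmonic or multimodal distance distributions, incomplete umbrella
overlap from slow orthogonal degrees of freedom, or force-field adequacy.

## Study conditions and problem sizes

Fixtures default to 2000 frames (the recovery criterion "mean within 3
standard errors" is evaluated at this length); the flat-profile WHAM check
uses a single window of 10⁵ exact samples, and barrier recovery uses 29
windows × 10⁴ samples (heights 1–5 kcal/mol recovered within
max(0.15, 5 %) kcal/mol). All randomness flows from explicit integer seeds;
identical seeds give bit-identical trajectories, windows and TSV outputs.

## Known limitations

* The toy channel realizes only targeted observables; incidental geometry
  (e.g. Phe ring packing, untargeted inter-residue distances) is
  unconstrained and should not be measured for meaning.
* Occupancy assignment is purely z-interval based; no radial gating, so an
  off-axis water at filter height would count. The generator keeps solvent
  either on-axis or far away, and real K⁺-channel filter geometry is narrow
  enough that the simplification is conventional.
* The WHAM solver is 1-D with uniform weights; no MBAR, no 2-D reaction
  coordinates, no bootstrap error bars (block convergence is the only
  uncertainty diagnostic).
* PDB is the only trajectory format (MODEL/ENDMDL frames); binary formats
  (DCD/XTC) and mmCIF are out of scope.
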