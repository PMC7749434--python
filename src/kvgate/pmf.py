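"""Umbrella-sampling free-energy reconstruction (WHAM).

Biased samples of the pore-axis coordinate z of a K+ ion, collected in
overlapping harmonic windows (bias ``w_i(z) = k/2 (z - c_i)^2``), are combined
into one unbiased profile by the weighted histogram analysis method: the
self-consistent equations

    P(z_b) = sum_i n_i(b) / sum_i N_i exp[(f_i - w_i(z_b)) / kT]
    exp(-f_i / kT) = sum_b P(z_b) exp(-w_i(z_b) / kT)

are iterated from f_i = 0 until the largest change in any window offset f_i
falls below the tolerance.  The potential of mean force is
``G(z) = -kT ln P(z)``, anchored so the cytoplasmic region (z <= -9 Å by
default) averages to zero, matching how the channel profiles are read.

Numerical choices: the denominator is evaluated with log-sum-exp so far-away
windows underflow harmlessly; bins with zero total counts yield an undefined
(NaN) G and are excluded from anchoring and barrier searches rather than
interpolated - free energies are never invented.  Sample weights are uniform
(no autocorrelation correction); convergence-block profiles on leading
fractions of each window are the convergence diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .errors import ReconstructionError

#: Boltzmann constant in kcal/mol/K
BOLTZMANN_KCAL = 1.987204e-3
DEFAULT_TEMPERATURE = 300.0   # K (thermostat temperature; configurable)
DEFAULT_BIN_WIDTH = 0.1       # Å: 5 bins per 0.5 Å window spacing
DEFAULT_TOLERANCE = 1e-6      # kcal/mol on the largest offset change
DEFAULT_MAX_ITERATIONS = 100_000
#: default cytoplasmic reference interval for anchoring, Å
CYTOPLASM_REFERENCE = (-np.inf, -9.0)


def thermal_energy(temperature: float) -> float:
    """k_B * T in kcal/mol (0.59616 at 300 K)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return BOLTZMANN_KCAL * temperature


def harmonic_bias(z, center: float, force_constant: float):
    """Umbrella bias ``k/2 (z - center)^2`` in kcal/mol."""
    if force_constant <= 0:
        raise ValueError("force_constant must be > 0")
    z = np.asarray(z, dtype=float)
    out = 0.5 * force_constant * (z - center) ** 2
    return float(out) if out.ndim == 0 else out


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias parameters plus its z samples (Å).

    ``bias_offset`` adds a constant to the bias; it is physically irrelevant
    (WHAM offsets absorb it) and exists so gauge invariance is testable.
    """

    center: float
    force_constant: float
    samples: np.ndarray
    bias_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 1:
            raise ValueError("an umbrella window needs at least one sample")
        if self.force_constant <= 0:
            raise ValueError("force_constant must be > 0")

    def bias(self, z):
        return harmonic_bias(z, self.center, self.force_constant) + self.bias_offset


@dataclass
class WhamConfig:
    """Binning, temperature and iteration controls for :func:`wham_solve`."""

    bin_edges: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    tolerance: float = DEFAULT_TOLERANCE
    max_iterations: int = DEFAULT_MAX_ITERATIONS

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.bin_edges.size < 2 or not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin_edges must be >= 2 strictly increasing values")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")

    @classmethod
    def for_windows(cls, windows, bin_width: float = DEFAULT_BIN_WIDTH,
                    **kwargs) -> "WhamConfig":
        """Bins covering the sampled range of all windows at ``bin_width``."""
        lo = min(float(w.samples.min()) for w in windows)
        hi = max(float(w.samples.max()) for w in windows)
        lo = np.floor(lo / bin_width) * bin_width
        hi = np.ceil(hi / bin_width) * bin_width
        n = max(1, int(round((hi - lo) / bin_width)))
        return cls(bin_edges=lo + bin_width * np.arange(n + 1), **kwargs)


@dataclass
class PmfProfile:
    """A reconstructed free-energy profile G(z) in kcal/mol.

    ``G`` is NaN on bins with zero counts.  ``anchor`` records the reference:
    either "min" (global minimum at zero) or a z interval whose mean is zero.
    """

    bin_centers: np.ndarray
    G: np.ndarray
    kT: float
    anchor: str | tuple[float, float]
    iterations_used: int
    converged: bool
    counts: np.ndarray | None = None
    window_offsets: np.ndarray | None = None

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.G)


def _bias_matrix(windows, centers: np.ndarray) -> np.ndarray:
    return np.stack([w.bias(centers) for w in windows])


def _check_overlap(count_matrix: np.ndarray, windows) -> None:
    """Warn on empty adjacent histogram overlaps; error if none overlap at all."""
    if len(windows) < 2:
        return
    order = np.argsort([w.center for w in windows])
    occupied = count_matrix > 0
    empty_pairs = 0
    for a, b in zip(order, order[1:]):
        if not np.any(occupied[a] & occupied[b]):
            empty_pairs += 1
            warnings.warn(
                f"umbrella windows centered at {windows[a].center:g} and "
                f"{windows[b].center:g} share no occupied histogram bin",
                stacklevel=3,
            )
    if empty_pairs == len(order) - 1:
        raise ReconstructionError(
            "no histogram overlap between any adjacent umbrella windows"
        )


def wham_solve(windows, config: WhamConfig) -> PmfProfile:
    """Self-consistent WHAM solution over the configured bins.

    Iterates the window free-energy offsets from zero until the largest change
    is below ``config.tolerance`` (kcal/mol) or ``max_iterations`` is reached;
    a non-converged result is returned with ``converged=False``.  The profile
    is anchored at its global minimum ("min"); use :func:`anchor_pmf` to
    re-reference to the cytoplasmic interval.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one umbrella window")
    kT = thermal_energy(config.temperature)
    edges = config.bin_edges
    centers = (edges[:-1] + edges[1:]) / 2.0
    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows]).astype(float)
    _check_overlap(counts, windows)
    n_samples = counts.sum(axis=1)  # in-range samples per window
    if np.any(n_samples == 0):
        bad = [windows[i].center for i in np.flatnonzero(n_samples == 0)]
        raise ReconstructionError(f"window(s) centered at {bad} have no in-range samples")
    total = counts.sum(axis=0)
    defined = total > 0
    log_total = np.full(centers.shape, -np.inf)
    log_total[defined] = np.log(total[defined])
    bias = _bias_matrix(windows, centers)  # (nw, nb), kcal/mol
    log_n = np.log(n_samples)

    f = np.zeros(len(windows))
    iterations = 0
    converged = False
    for iterations in range(1, config.max_iterations + 1):
        # denominator: logsumexp_i [ ln N_i + (f_i - w_ib)/kT ]
        log_denom = logsumexp(log_n[:, None] + (f[:, None] - bias) / kT, axis=0)
        log_p = log_total - log_denom
        log_p -= logsumexp(log_p[defined])
        with np.errstate(divide="ignore"):
            new_f = -kT * logsumexp(log_p[None, defined] - bias[:, defined] / kT, axis=1)
        new_f -= new_f[0]  # gauge: first window at zero
        delta = float(np.max(np.abs(new_f - f)))
        f = new_f
        if delta < config.tolerance:
            converged = True
            break

    log_denom = logsumexp(log_n[:, None] + (f[:, None] - bias) / kT, axis=0)
    log_p = log_total - log_denom
    log_p -= logsumexp(log_p[defined])
    G = np.full(centers.shape, np.nan)
    G[defined] = -kT * log_p[defined]
    G[defined] -= np.nanmin(G[defined])
    return PmfProfile(
        bin_centers=centers, G=G, kT=kT, anchor="min",
        iterations_used=iterations, converged=converged,
        counts=total, window_offsets=f,
    )


def unbiased_probability(profile: PmfProfile) -> np.ndarray:
    """P(z) on the profile's bins, normalized over defined bins (NaN elsewhere)."""
    p = np.exp(-np.where(profile.defined, profile.G, np.inf) / profile.kT)
    p /= p[profile.defined].sum()
    return np.where(profile.defined, p, np.nan)


def anchor_pmf(profile: PmfProfile,
               reference_interval: tuple[float, float] = CYTOPLASM_REFERENCE) -> PmfProfile:
    """Shift G so its mean over the reference z interval is zero.

    The default interval is the cytoplasmic region z <= -9 Å.  Anchoring is
    idempotent and only uses defined bins; an interval with no defined bins is
    an error.
    """
    lo, hi = reference_interval
    mask = profile.defined & (profile.bin_centers >= lo) & (profile.bin_centers <= hi)
    if not np.any(mask):
        raise ReconstructionError(
            f"no defined bins in reference interval [{lo}, {hi}]"
        )
    shift = float(np.mean(profile.G[mask]))
    return replace(profile, G=profile.G - shift, anchor=(float(lo), float(hi)))


def barrier_height(profile: PmfProfile, barrier_region: tuple[float, float],
                   reference_region: tuple[float, float]) -> tuple[float, float]:
    """(max G in barrier region - mean G in reference region, z at the max).

    Ties on the maximum break to the first (lowest-z) bin.  Regions without
    any defined bin are an error.
    """
    z = profile.bin_centers
    bmask = profile.defined & (z >= barrier_region[0]) & (z <= barrier_region[1])
    rmask = profile.defined & (z >= reference_region[0]) & (z <= reference_region[1])
    if not np.any(bmask):
        raise ReconstructionError(f"no defined bins in barrier region {barrier_region}")
    if not np.any(rmask):
        raise ReconstructionError(f"no defined bins in reference region {reference_region}")
    ref = float(np.mean(profile.G[rmask]))
    idx = np.flatnonzero(bmask)
    gvals = profile.G[idx]
    imax = idx[int(np.argmax(gvals))]  # argmax returns the first maximum
    return float(profile.G[imax] - ref), float(z[imax])


def convergence_blocks(windows, config: WhamConfig, fractions) -> list[PmfProfile]:
    """WHAM profiles from the leading fraction of every window's samples.

    ``fractions`` must be increasing values in (0, 1]; a fraction leaving any
    window with fewer than 2 samples is an error.
    """
    fractions = list(fractions)
    if not fractions or any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if any(b <= a for a, b in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be increasing")
    profiles = []
    for frac in fractions:
        truncated = []
        for w in windows:
            n = int(np.ceil(frac * w.samples.size))
            if n < 2:
                raise ValueError(
                    f"fraction {frac} leaves {n} sample(s) in the window at {w.center:g}"
                )
            truncated.append(replace(w, samples=w.samples[:n]))
        profiles.append(wham_solve(truncated, config))
    return profiles


def convergence_metric(full: PmfProfile, partial: PmfProfile) -> float:
    """max |G_full - G_partial| over bins defined in both profiles."""
    if full.bin_centers.shape != partial.bin_centers.shape or not np.allclose(
        full.bin_centers, partial.bin_centers
    ):
        raise ValueError("profiles must share the same bins")
    mask = full.defined & partial.defined
    if not np.any(mask):
        raise ReconstructionError("profiles share no defined bins")
    return float(np.max(np.abs(full.G[mask] - partial.G[mask])))
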