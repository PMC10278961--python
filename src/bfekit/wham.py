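"""Umbrella-sampling bookkeeping and WHAM reconstruction of the PMF.

Each window carries a harmonic bias ``w_i(xi) = (K/2)(xi - xi_ref)^2``.  The
weighted-histogram equations are iterated self-consistently on the window
free-energy offsets f_i:

    P(b)  = sum_i n_i(b) / sum_i N_i exp[-(w_i(b) - f_i)/kT]
    f_i   = -kT ln sum_b P(b) exp(-w_i(b)/kT)

until the largest offset change falls below tolerance.  The PMF is
``-kT ln P`` anchored so its minimum is zero.  Round-averaged PMFs (the
last-n-rounds mean) and bulk-minus-bound dG extraction mirror how converged
umbrella series are usually reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB

__all__ = ["UmbrellaWindow", "PMFProfile", "bias_potential", "wham",
           "average_pmf", "pmf_delta", "WHAMConvergenceError"]


class WHAMConvergenceError(RuntimeError):
    def __init__(self, offsets, delta, max_iter):
        self.offsets = offsets
        super().__init__(f"WHAM did not converge in {max_iter} iterations "
                         f"(last max offset change {delta:.3e} kcal/mol)")


@dataclass
class UmbrellaWindow:
    """Reference position (A), elastic constant (kcal/(mol A^2)), samples (A)."""

    xi_ref: float
    K: float
    samples: np.ndarray

    def __post_init__(self):
        if self.K < 0:
            raise ValueError("elastic constant must be >= 0")
        self.samples = np.atleast_1d(np.asarray(self.samples, float))
        if self.samples.size == 0:
            raise ValueError(f"window at xi_ref={self.xi_ref} has no samples")


@dataclass
class PMFProfile:
    bin_centers: np.ndarray     # A
    free_energy: np.ndarray     # kcal/mol, min anchored to 0 (NaN where empty)
    counts: np.ndarray
    temperature: float

    def anchored(self) -> "PMFProfile":
        fe = self.free_energy - np.nanmin(self.free_energy)
        return PMFProfile(self.bin_centers, fe, self.counts, self.temperature)


def bias_potential(xi, xi_ref: float, K: float):
    """Harmonic window bias ``(K/2)(xi - xi_ref)^2`` in kcal/mol."""
    xi = np.asarray(xi, float)
    return 0.5 * K * (xi - xi_ref) ** 2


def wham(windows, bin_width: float = 0.1, T: float = 300.0,
         tolerance: float = 1e-6, max_iter: int = 100000,
         bin_range: tuple[float, float] | None = None) -> PMFProfile:
    """Reconstruct the unbiased PMF from umbrella windows.

    Bins span the sampled range (or ``bin_range``); empty interior bins are
    reported as NaN.  Raises :class:`WHAMConvergenceError` carrying the last
    offsets on failure.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one window")
    kt = KB * T
    all_samples = np.concatenate([w.samples for w in windows])
    lo, hi = bin_range if bin_range else (all_samples.min(), all_samples.max())
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.zeros((len(windows), n_bins))
    for i, w in enumerate(windows):
        counts[i], _ = np.histogram(w.samples, bins=edges)
    n_per_window = counts.sum(axis=1)
    total_counts = counts.sum(axis=0)

    bias = np.stack([bias_potential(centers, w.xi_ref, w.K) for w in windows])
    boltz = np.exp(-bias / kt)                     # (W, B)
    f = np.zeros(len(windows))
    for _ in range(max_iter):
        denom = (n_per_window[:, None] * boltz * np.exp(f[:, None] / kt)).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total_counts / denom, 0.0)
        z = (boltz * p[None, :]).sum(axis=1)
        f_new = -kt * np.log(z)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tolerance:
            break
    else:
        raise WHAMConvergenceError(f, delta, max_iter)

    p_sum = p.sum()
    if p_sum <= 0:
        raise ValueError("no probability mass in any bin")
    p = p / p_sum
    with np.errstate(divide="ignore"):
        fe = np.where(total_counts > 0, -kt * np.log(np.where(p > 0, p, 1.0)), np.nan)
    fe = fe - np.nanmin(fe)
    return PMFProfile(centers, fe, total_counts, T)


def average_pmf(round_profiles, last_n: int = 10) -> tuple[PMFProfile, np.ndarray]:
    """Per-bin mean of the last ``last_n`` round profiles (after anchoring).

    Returns ``(mean_profile, per_bin_sd)``.  All rounds must share bins.
    """
    profiles = list(round_profiles)
    if len(profiles) < last_n:
        raise ValueError(f"need at least last_n={last_n} rounds, got {len(profiles)}")
    ref_bins = profiles[0].bin_centers
    for p in profiles[1:]:
        if p.bin_centers.shape != ref_bins.shape or \
                not np.allclose(p.bin_centers, ref_bins):
            raise ValueError("round profiles are on different bins")
    use = [p.anchored() for p in profiles[-last_n:]]
    stack = np.stack([p.free_energy for p in use])
    mean = np.nanmean(stack, axis=0)
    sd = np.nanstd(stack, axis=0, ddof=1) if last_n > 1 else np.full_like(mean, np.nan)
    mean = mean - np.nanmin(mean)
    counts = np.sum([p.counts for p in use], axis=0)
    return PMFProfile(ref_bins, mean, counts, use[0].temperature), sd


def pmf_delta(profile: PMFProfile, bound_region: tuple[float, float],
              bulk_region: tuple[float, float]) -> float:
    """dG = mean(free energy over bulk) - min(free energy over bound).

    The difference of two profiles' dG values is the mutation ddG; vertical
    anchoring cancels.
    """
    x = profile.bin_centers
    fe = profile.free_energy
    bound = (x >= bound_region[0]) & (x <= bound_region[1]) & np.isfinite(fe)
    bulk = (x >= bulk_region[0]) & (x <= bulk_region[1]) & np.isfinite(fe)
    if not bound.any() or not bulk.any():
        raise ValueError("empty bound or bulk region")
    return float(np.mean(fe[bulk]) - np.min(fe[bound]))
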