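"""Umbrella-sampling free-energy profiles: window planning, WHAM, errors.

The bias on the reaction coordinate r (Å) is harmonic with the ½-convention,
``U_bias(r) = 0.5 k (r - r0)^2`` with k in kcal/mol/Å².  WHAM iterates the
self-consistent equations

    p(b) ∝ Σ_i n_i(b)  /  Σ_i N_i exp(β [f_i - U_i(r_b)])
    exp(-β f_i) = Σ_b exp(-β U_i(r_b)) p(b)

until the window constants f_i change by less than ``tol``; the profile is
G(b) = -kB T ln p(b), min-shifted to zero.  Errors come from Monte-Carlo
bootstrap over decorrelated sample blocks; diagnostics cover adjacent-window
histogram overlap and a half-vs-all data convergence check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KB",
    "UmbrellaWindow",
    "PMFProfile",
    "WhamError",
    "plan_umbrella_windows",
    "wham_pmf",
    "bootstrap_pmf_errors",
    "histogram_overlap",
    "convergence_split",
    "integrated_autocorrelation_time",
]

KB = 0.0019872041  # kcal/mol/K
DEFAULT_TEMPERATURE = 300.0
DEFAULT_BIN_WIDTH = 0.2  # Å
DEFAULT_EQUILIBRATION_FRACTION = 0.05


class WhamError(RuntimeError):
    pass


@dataclass
class UmbrellaWindow:
    """One biased simulation window.

    ``equilibration_cut`` is the initial time span (same units as ``times``)
    discarded before analysis; if None, the first
    ``DEFAULT_EQUILIBRATION_FRACTION`` of the span is dropped.
    """

    r0: float
    k: float  # kcal/mol/Å², ½ k (r-r0)² convention
    times: np.ndarray
    samples: np.ndarray
    equilibration_cut: float | None = None

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("force constant must be non-negative (0 = unbiased window)")
        self.times = np.asarray(self.times, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.times.shape != self.samples.shape:
            raise ValueError("times and samples must align")
        if self.production_samples().size == 0:
            raise ValueError("no samples remain after the equilibration cut")

    def _cut_time(self) -> float:
        if self.equilibration_cut is not None:
            return self.times[0] + self.equilibration_cut
        span = self.times[-1] - self.times[0]
        return self.times[0] + DEFAULT_EQUILIBRATION_FRACTION * span

    def production_samples(self) -> np.ndarray:
        return self.samples[self.times >= self._cut_time()] if self.samples.size else self.samples

    def bias_energy(self, r: np.ndarray) -> np.ndarray:
        return 0.5 * self.k * (np.asarray(r) - self.r0) ** 2


@dataclass
class PMFProfile:
    """Free-energy profile with optional per-bin bootstrap SD."""

    bin_centers: np.ndarray
    free_energy: np.ndarray  # kcal/mol, min-shifted to 0
    window_constants: np.ndarray  # f_i
    temperature: float
    bootstrap_sd: np.ndarray | None = None
    n_iterations: int = 0

    def __post_init__(self):
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bins must be strictly increasing")
        if abs(float(np.min(self.free_energy))) > 1e-9:
            raise ValueError("free energy must be min-shifted to zero")
        if self.bootstrap_sd is not None and np.any(self.bootstrap_sd < 0):
            raise ValueError("bootstrap SD must be non-negative")

    def interp(self, r: np.ndarray) -> np.ndarray:
        return np.interp(r, self.bin_centers, self.free_energy)


def plan_umbrella_windows(rmin: float, rmax: float, spacing: float, k: float = 1.0) -> list[dict]:
    """Window specs at rmin, rmin+spacing, ..., rmax (inclusive).

    Returns dicts with ``r0`` and ``k``; count = floor((rmax-rmin)/spacing)+1.
    """
    if rmax <= rmin:
        raise ValueError("rmax must exceed rmin")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > rmax - rmin:
        import warnings

        warnings.warn("spacing exceeds the range: planning a single window")
    n = int(math.floor((rmax - rmin) / spacing + 1e-9)) + 1
    return [{"r0": round(rmin + i * spacing, 9), "k": k} for i in range(n)]


def _histograms(windows, bin_width, data=None, edges=None):
    """Common grid + per-window counts. ``data`` overrides production samples."""
    if data is None:
        data = [w.production_samples() for w in windows]
    if edges is None:
        lo = min(d.min() for d in data)
        hi = max(d.max() for d in data)
        lo = math.floor(lo / bin_width) * bin_width
        hi = math.ceil(hi / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width * 0.5, bin_width)
        if len(edges) < 2:
            edges = np.array([lo, lo + bin_width])
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.stack([np.histogram(d, bins=edges)[0] for d in data]).astype(float)
    return edges, centers, counts


def _check_support(windows, centers, counts, sliver_fraction=0.005):
    """Validate connected sampling support.

    Occupied bins must form one connected run; disconnected regions holding a
    non-negligible sample mass raise :class:`WhamError` (the free energies of
    the two regions cannot be placed on a common scale), while isolated
    slivers below ``sliver_fraction`` of the total mass (stray excursions)
    are trimmed with a warning.
    """
    total = counts.sum(axis=0)
    occupied = total > 0
    idx = np.flatnonzero(occupied)
    runs: list[np.ndarray] = []
    start = 0
    breaks = np.flatnonzero(np.diff(idx) > 1)
    for b in list(breaks) + [len(idx) - 1]:
        runs.append(idx[start : b + 1])
        start = b + 1
    if len(runs) > 1:
        masses = np.array([total[r].sum() for r in runs])
        main = int(np.argmax(masses))
        for r_i, run in enumerate(runs):
            if r_i == main:
                continue
            if masses[r_i] >= sliver_fraction * masses.sum():
                lo = centers[min(runs[main][-1], run[-1])]
                hi = centers[max(runs[main][0], run[0])]
                raise WhamError(
                    "disconnected sampling support: no samples between "
                    f"r = {lo:.3f} and r = {hi:.3f} Å; add overlapping windows in that gap"
                )
            occupied[run] = False
        import warnings

        warnings.warn("trimmed isolated sparsely-sampled bins outside the main support")
    return occupied


def _solve_wham(windows, centers, counts, beta, tol, max_iter, f_init=None):
    n_samples = counts.sum(axis=1)
    bias = np.stack([w.bias_energy(centers) for w in windows])  # (W, B)
    numer = counts.sum(axis=0)  # (B,)
    occupied = numer > 0
    log_boltz_bias = -beta * bias
    f = np.zeros(len(windows)) if f_init is None else np.array(f_init, dtype=float)
    for iteration in range(1, max_iter + 1):
        # log denominator per bin: log Σ_i N_i exp(β f_i - β U_i)
        log_terms = np.log(n_samples)[:, None] + beta * f[:, None] + log_boltz_bias
        m = log_terms.max(axis=0)
        log_denom = m + np.log(np.exp(log_terms - m).sum(axis=0))
        with np.errstate(divide="ignore"):
            log_p = np.where(occupied, np.log(numer) - log_denom, -np.inf)
        # f_i = -kT log Σ_b exp(-β U_i) p_b
        log_terms_f = log_boltz_bias + log_p[None, :]
        mf = log_terms_f.max(axis=1)
        new_f = -(mf + np.log(np.exp(log_terms_f - mf[:, None]).sum(axis=1))) / beta
        new_f -= new_f[0]
        delta = np.max(np.abs(new_f - f))
        f = new_f
        if delta < tol:
            return f, log_p, iteration
    raise WhamError(f"WHAM failed to converge within {max_iter} iterations (|Δf| = {delta:.3g})")


def wham_pmf(
    windows: list[UmbrellaWindow],
    temperature: float = DEFAULT_TEMPERATURE,
    bin_width: float = DEFAULT_BIN_WIDTH,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    _data_override: list[np.ndarray] | None = None,
    _f_init: np.ndarray | None = None,
    _edges: np.ndarray | None = None,
    _check: bool = True,
) -> PMFProfile:
    """Weighted-histogram estimate of the PMF along the reaction coordinate.

    Bins of ``bin_width`` Å cover the sampled support; only occupied bins are
    reported.  Raises :class:`WhamError` on disconnected support or failure
    to converge.
    """
    if not windows:
        raise ValueError("need at least one window")
    beta = 1.0 / (KB * temperature)
    _, centers, counts = _histograms(windows, bin_width, data=_data_override, edges=_edges)
    if _check:
        occupied = _check_support(windows, centers, counts)
    else:
        occupied = counts.sum(axis=0) > 0
    f, log_p, n_iter = _solve_wham(windows, centers, counts, beta, tol, max_iter, f_init=_f_init)
    g = -log_p[occupied] / beta
    g -= g.min()
    return PMFProfile(centers[occupied], g, f, temperature, n_iterations=n_iter)


def integrated_autocorrelation_time(x: np.ndarray) -> float:
    """1 + 2 Σ ρ_t, summed to the first non-positive autocorrelation."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return 1.0
    d = x - x.mean()
    var = float(np.dot(d, d))
    if var == 0:
        return 1.0
    tau = 1.0
    for lag in range(1, min(n - 1, 1000)):
        rho = float(np.dot(d[:-lag], d[lag:])) / var
        if rho <= 0:
            break
        tau += 2.0 * rho
    return tau


def bootstrap_pmf_errors(
    windows: list[UmbrellaWindow],
    n_trials: int = 200,
    seed: int = 0,
    temperature: float = DEFAULT_TEMPERATURE,
    bin_width: float = DEFAULT_BIN_WIDTH,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> PMFProfile:
    """PMF with per-bin SD over ``n_trials`` block-bootstrap WHAM solutions.

    Resampling unit: contiguous blocks of length equal to the window's
    integrated autocorrelation time estimate (minimum 1 sample), drawn with
    replacement per window.  Deterministic for a fixed seed.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 bootstrap trials")
    rng = np.random.default_rng(seed)
    data = [w.production_samples() for w in windows]
    edges, _, _ = _histograms(windows, bin_width, data=data)
    full = wham_pmf(windows, temperature, bin_width, tol, max_iter, _edges=edges)
    blocks = [max(1, int(round(integrated_autocorrelation_time(d)))) for d in data]
    profiles = np.full((n_trials, len(full.bin_centers)), np.nan)
    for t in range(n_trials):
        resampled = [_block_resample(d, b, rng) for d, b in zip(data, blocks)]
        # trials share the full-data grid; bins a trial misses stay NaN there
        prof = wham_pmf(windows, temperature, bin_width, tol, max_iter,
                        _data_override=resampled, _f_init=full.window_constants,
                        _edges=edges, _check=False)
        pos = np.searchsorted(prof.bin_centers, full.bin_centers)
        ok = (pos < len(prof.bin_centers)) & np.isclose(
            np.take(prof.bin_centers, pos, mode="clip"), full.bin_centers
        )
        profiles[t, ok] = prof.free_energy[pos[ok]]
    sd = np.nanstd(profiles, axis=0, ddof=1)
    return replace(full, bootstrap_sd=np.nan_to_num(sd))


def sd_at_references(profile: PMFProfile, windows: list[UmbrellaWindow]) -> np.ndarray:
    """Bootstrap SD interpolated at the window reference points within support.

    Errors are conventionally quoted at the umbrella reference positions;
    references outside the sampled support are skipped.
    """
    if profile.bootstrap_sd is None:
        raise ValueError("profile carries no bootstrap SD")
    lo, hi = profile.bin_centers[0], profile.bin_centers[-1]
    refs = np.array(sorted(w.r0 for w in windows))
    refs = refs[(refs >= lo) & (refs <= hi)]
    return np.interp(refs, profile.bin_centers, profile.bootstrap_sd)


def _block_resample(d: np.ndarray, block: int, rng: np.random.Generator) -> np.ndarray:
    n = len(d)
    n_blocks = max(1, math.ceil(n / block))
    starts = rng.integers(0, max(1, n - block + 1), size=n_blocks)
    out = np.concatenate([d[s : s + block] for s in starts])
    return out[:n]


def histogram_overlap(windows: list[UmbrellaWindow], bin_width: float = 0.05) -> np.ndarray:
    """Overlap coefficient Σ_b min(p_i, p_j) for adjacent windows (by r0)."""
    if len(windows) < 2:
        raise ValueError("need at least two windows")
    order = np.argsort([w.r0 for w in windows])
    ordered = [windows[i] for i in order]
    _, centers, counts = _histograms(ordered, bin_width)
    probs = counts / counts.sum(axis=1, keepdims=True)
    return np.array([
        float(np.minimum(probs[i], probs[i + 1]).sum()) for i in range(len(ordered) - 1)
    ])


def convergence_split(
    windows: list[UmbrellaWindow],
    temperature: float = DEFAULT_TEMPERATURE,
    bin_width: float = DEFAULT_BIN_WIDTH,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    min_count: int = 10,
) -> float:
    """Max |G_half − G_full| over common bins (both profiles min-shifted).

    The half profile uses the first half of each window's production samples
    by time; a small value indicates converged sampling.  Bins with fewer
    than ``min_count`` samples in the half data are excluded — their
    difference measures shot noise, not drift.
    """
    full_data = [w.production_samples() for w in windows]
    half_data = [d[: max(2, len(d) // 2)] for d in full_data]
    edges, _, _ = _histograms(windows, bin_width, data=full_data)
    full = wham_pmf(windows, temperature, bin_width, tol, max_iter,
                    _data_override=full_data, _edges=edges)
    half = wham_pmf(windows, temperature, bin_width, tol, max_iter,
                    _data_override=half_data, _f_init=full.window_constants,
                    _edges=edges, _check=False)
    _, _, half_counts = _histograms(windows, bin_width, data=half_data, edges=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    solid = centers[half_counts.sum(axis=0) >= min_count]
    common, ia, ib = np.intersect1d(
        np.round(full.bin_centers, 9), np.round(half.bin_centers, 9), return_indices=True
    )
    keep = np.isin(common, np.round(solid, 9))
    ia, ib = ia[keep], ib[keep]
    common = common[keep]
    if common.size == 0:
        raise WhamError("half and full profiles share no bins")
    ga = full.free_energy[ia] - full.free_energy[ia].min()
    gb = half.free_energy[ib] - half.free_energy[ib].min()
    return float(np.max(np.abs(ga - gb)))
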