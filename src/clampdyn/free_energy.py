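"""Well-tempered metadynamics free-energy reconstruction and reweighting.

The bias potential accumulated from the deposited (already-tempered) hills
yields the free-energy surface up to the well-tempered scale factor
−(T+ΔT)/ΔT.  An independent estimate comes from the reweighted histogram of
the biased collective variables; agreement of the two is the pipeline's
internal consistency check.  The 2D surface is marginalized over the contact
CV to a 1D unbinding profile, from which ΔG_unb is read off as the height of
the unbound plateau above the bound minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .io_formats import CVTrajectory, HillsSeries

#: Boltzmann constant, kcal/(mol·K)
KB = 0.0019872041
DEFAULT_T = 300.0       # K
DEFAULT_DELTA_T = 3300.0  # bias temperature ΔT, K (bias factor 12 at 300 K)

REWEIGHT_SCHEMES = ("final_bias", "time_dependent", "balanced_exponential")


# ---------------------------------------------------------------------------
# grids and surfaces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Uniform 2D grid over (d_com, n_contacts)."""

    d_centers: np.ndarray
    n_centers: np.ndarray

    @property
    def d_width(self) -> float:
        if len(self.d_centers) < 2:
            return 1.0
        return float(self.d_centers[1] - self.d_centers[0])

    @property
    def n_width(self) -> float:
        if len(self.n_centers) < 2:
            return 1.0
        return float(self.n_centers[1] - self.n_centers[0])

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.d_centers), len(self.n_centers)

    def d_edges(self) -> np.ndarray:
        w = self.d_width
        return np.concatenate([self.d_centers - w / 2, [self.d_centers[-1] + w / 2]])

    def n_edges(self) -> np.ndarray:
        w = self.n_width
        return np.concatenate([self.n_centers - w / 2, [self.n_centers[-1] + w / 2]])

    @classmethod
    def from_ranges(cls, d_range, n_range, d_width=0.125, n_width=0.25) -> "Grid":
        """Grid with bin width defaulting to the hill widths (σ_d, σ_n)."""
        d = np.arange(d_range[0] + d_width / 2, d_range[1], d_width)
        n = np.arange(n_range[0] + n_width / 2, n_range[1], n_width)
        return cls(d_centers=d, n_centers=n)


@dataclass(frozen=True)
class BiasGrid:
    """Accumulated metadynamics bias V(s) on a grid, kcal/mol."""

    grid: Grid
    V: np.ndarray  # (n_d, n_n)
    T: float = DEFAULT_T
    delta_T: float = DEFAULT_DELTA_T

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.V)):
            raise ValueError("bias potential contains non-finite values")


@dataclass(frozen=True)
class FreeEnergySurface:
    """G(s) on a grid, min-shifted to 0; unsampled bins carry an explicit mask."""

    grid: Grid
    G: np.ndarray
    sampled: np.ndarray  # bool mask; G is meaningful only where True
    T: float = DEFAULT_T

    def __post_init__(self) -> None:
        if self.sampled.any():
            g_min = np.min(self.G[self.sampled])
            if abs(g_min) > 1e-9:
                raise ValueError("surface not min-shifted to 0")


@dataclass(frozen=True)
class Profile:
    """1D free-energy profile over the distance CV, min-shifted to 0."""

    d_centers: np.ndarray
    G: np.ndarray
    sampled: np.ndarray
    T: float = DEFAULT_T


@dataclass(frozen=True)
class UnbindingResult:
    """Per-run ΔG_unb values and their mean ± SEM."""

    values: np.ndarray
    mean: float
    sem: float
    n_runs: int
    single_run: bool = False


# ---------------------------------------------------------------------------
# bias accumulation and direct FES
# ---------------------------------------------------------------------------

def accumulate_bias(
    hills: HillsSeries, grid: Grid, T: float = DEFAULT_T,
    delta_T: float = DEFAULT_DELTA_T, n_hills: int | None = None,
) -> BiasGrid:
    """Sum the recorded Gaussians onto the grid.

    Heights are used as recorded (they already carry the well-tempered
    damping).  ``n_hills`` restricts to the first hills, which gives the
    time-dependent bias V(s, t) at intermediate epochs.
    """
    nk = len(hills) if n_hills is None else int(n_hills)
    V = np.zeros(grid.shape)
    if nk == 0:
        return BiasGrid(grid=grid, V=V, T=T, delta_T=delta_T)
    dmin, dmax = grid.d_edges()[0], grid.d_edges()[-1]
    nmin, nmax = grid.n_edges()[0], grid.n_edges()[-1]
    for k in range(nk):
        cd, cn = hills.center_d[k], hills.center_nc[k]
        sd, sn = hills.width_d[k], hills.width_nc[k]
        if cd - 5 * sd < dmin or cd + 5 * sd > dmax or \
           cn - 5 * sn < nmin or cn + 5 * sn > nmax:
            raise ValueError(
                f"grid does not cover hill {k} center ± 5σ at ({cd:.3f}, {cn:.3f})"
            )
        gd = np.exp(-((grid.d_centers - cd) ** 2) / (2 * sd**2))
        gn = np.exp(-((grid.n_centers - cn) ** 2) / (2 * sn**2))
        V += hills.height[k] * np.outer(gd, gn)
    return BiasGrid(grid=grid, V=V, T=T, delta_T=delta_T)


def fes_from_bias(bias: BiasGrid, sampled_threshold: float = 0.0) -> FreeEnergySurface:
    """FES from the converged bias: G = −((T+ΔT)/ΔT)·V, min-shifted to 0.

    Bins whose accumulated bias is below ``sampled_threshold``·max(V) were
    never visited by the walker and are marked unsampled (the bias-derived
    G is meaningless there); the default 0 keeps every bin.
    """
    if bias.delta_T <= 0:
        raise ValueError("bias temperature ΔT must be > 0")
    scale = (bias.T + bias.delta_T) / bias.delta_T
    v_max = bias.V.max()
    if sampled_threshold > 0 and v_max > 0:
        sampled = bias.V > sampled_threshold * v_max
    else:
        sampled = np.ones_like(bias.V, dtype=bool)
    G = -scale * bias.V
    G = G - G[sampled].min()
    return FreeEnergySurface(grid=bias.grid, G=G, sampled=sampled, T=bias.T)


# ---------------------------------------------------------------------------
# reweighting
# ---------------------------------------------------------------------------

def _hill_times(hills: HillsSeries, dt: float) -> np.ndarray:
    return hills.step * dt


def _instantaneous_bias_at_frames(cv: CVTrajectory, hills: HillsSeries, dt: float):
    """V(s_t, t): bias felt by each frame from hills deposited before it."""
    V = np.zeros(len(cv))
    t_dep = _hill_times(hills, dt)
    # hills and frames are both time-ordered: hill k contributes to the
    # suffix of frames with time >= its deposition time
    start = np.searchsorted(cv.time, t_dep, side="left")
    for k in range(len(hills)):
        s = start[k]
        if s >= len(cv):
            continue
        gd = np.exp(-((cv.d_com[s:] - hills.center_d[k]) ** 2)
                    / (2 * hills.width_d[k] ** 2))
        gn = np.exp(-((cv.n_contacts[s:] - hills.center_nc[k]) ** 2)
                    / (2 * hills.width_nc[k] ** 2))
        V[s:] += hills.height[k] * gd * gn
    return V


def _final_bias_at_frames(cv: CVTrajectory, hills: HillsSeries):
    V = np.zeros(len(cv))
    for k in range(len(hills)):
        gd = np.exp(-((cv.d_com - hills.center_d[k]) ** 2)
                    / (2 * hills.width_d[k] ** 2))
        gn = np.exp(-((cv.n_contacts - hills.center_nc[k]) ** 2)
                    / (2 * hills.width_nc[k] ** 2))
        V += hills.height[k] * gd * gn
    return V


def _running_offset_at_frames(
    cv: CVTrajectory, hills: HillsSeries, grid: Grid, dt: float,
    T: float, delta_T: float,
):
    """c(t) per frame: running bias offset from the grid estimate of the FES.

    With the well-tempered estimate F(s,t) = −γ'·V(s,t), γ' = (T+ΔT)/ΔT,
    c(t) = RT·ln[ Σ_s e^{β γ' V} / Σ_s e^{β (T/ΔT) V} ].
    """
    beta = 1.0 / (KB * T)
    gamma_p = (T + delta_T) / delta_T
    t_dep = _hill_times(hills, dt)
    epoch_of_frame = np.searchsorted(t_dep, cv.time, side="right")
    c_by_epoch = np.zeros(len(hills) + 1)
    V = np.zeros(grid.shape)
    for k in range(len(hills)):
        gd = np.exp(-((grid.d_centers - hills.center_d[k]) ** 2)
                    / (2 * hills.width_d[k] ** 2))
        gn = np.exp(-((grid.n_centers - hills.center_nc[k]) ** 2)
                    / (2 * hills.width_nc[k] ** 2))
        V += hills.height[k] * np.outer(gd, gn)
        flat = V.ravel()
        c_by_epoch[k + 1] = KB * T * (
            logsumexp(beta * gamma_p * flat) - logsumexp(beta * (T / delta_T) * flat)
        )
    return c_by_epoch[epoch_of_frame]


def reweight(
    cv: CVTrajectory, hills: HillsSeries, scheme: str = "balanced_exponential",
    grid: Grid | None = None, dt: float = 1.0, T: float = DEFAULT_T,
    delta_T: float = DEFAULT_DELTA_T,
) -> np.ndarray:
    """Per-frame unbiasing weights (non-negative, summing to 1).

    Schemes
    -------
    ``final_bias``
        w_t ∝ exp(V(s_t, t_final)/RT): all frames unbiased with the converged
        bias, ignoring its time dependence.
    ``time_dependent``
        w_t ∝ exp((V(s_t, t) − c(t))/RT) with the running offset c(t)
        estimated from the bias grid at each deposition epoch.
    ``balanced_exponential``
        Geometric mean of the two exponential weights above, balancing the
        early-frame bias of the final-bias scheme against the noise of the
        instantaneous one.

    ``dt`` converts hill deposition steps to the CV trajectory's ps times.
    """
    if scheme not in REWEIGHT_SCHEMES:
        raise ValueError(f"unknown reweighting scheme {scheme!r}; "
                         f"choose from {REWEIGHT_SCHEMES}")
    rt = KB * T
    if len(hills) == 0:
        return np.full(len(cv), 1.0 / len(cv))
    if scheme == "final_bias":
        log_w = _final_bias_at_frames(cv, hills) / rt
    else:
        if grid is None:
            grid = default_grid_for(hills)
        v_inst = _instantaneous_bias_at_frames(cv, hills, dt)
        c_t = _running_offset_at_frames(cv, hills, grid, dt, T, delta_T)
        log_w_td = (v_inst - c_t) / rt
        if scheme == "time_dependent":
            log_w = log_w_td
        else:
            log_w = 0.5 * (log_w_td + _final_bias_at_frames(cv, hills) / rt)
    log_w = log_w - logsumexp(log_w)
    return np.exp(log_w)


def default_grid_for(hills: HillsSeries, pad_sigma: float = 6.0) -> Grid:
    """Grid covering all hill centers ± pad, bin widths = median hill widths."""
    sd = float(np.median(hills.width_d))
    sn = float(np.median(hills.width_nc))
    d_lo = hills.center_d.min() - pad_sigma * sd
    d_hi = hills.center_d.max() + pad_sigma * sd
    n_lo = hills.center_nc.min() - pad_sigma * sn
    n_hi = hills.center_nc.max() + pad_sigma * sn
    return Grid.from_ranges((d_lo, d_hi), (n_lo, n_hi), d_width=sd, n_width=sn)


# ---------------------------------------------------------------------------
# histogram FES, marginal profile, ΔG_unb
# ---------------------------------------------------------------------------

def fes_from_histogram(
    cv: CVTrajectory, weights: np.ndarray, grid: Grid, T: float = DEFAULT_T,
) -> FreeEnergySurface:
    """FES as −RT·ln of the weighted CV histogram, min-shifted to 0."""
    weights = np.asarray(weights, float)
    if abs(weights.sum() - 1.0) > 1e-6 or np.any(weights < 0):
        raise ValueError("weights must be non-negative and normalized")
    hist, _, _ = np.histogram2d(
        cv.d_com, cv.n_contacts, bins=[grid.d_edges(), grid.n_edges()],
        weights=weights,
    )
    sampled = hist > 0
    if sampled.sum() == 1:
        warnings.warn("all frames fall into a single bin: degenerate FES")
    G = np.full(grid.shape, np.inf)
    G[sampled] = -KB * T * np.log(hist[sampled])
    G[sampled] -= G[sampled].min()
    return FreeEnergySurface(grid=grid, G=G, sampled=sampled, T=T)


def fes_rmse(fes_a: FreeEnergySurface, fes_b: FreeEnergySurface,
             align: str = "mean") -> float:
    """RMSE between two surfaces on mutually sampled bins (kcal/mol).

    A free-energy surface is defined up to an additive constant; with
    ``align="mean"`` (default) the mean difference over the mutual bins is
    removed before the RMSE so the comparison measures shape, not the noise
    of each surface's own min anchor.  ``align="none"`` compares the
    min-shifted surfaces as stored.
    """
    both = fes_a.sampled & fes_b.sampled
    if not both.any():
        raise ValueError("no mutually sampled bins")
    diff = fes_a.G[both] - fes_b.G[both]
    if align == "mean":
        diff = diff - diff.mean()
    return float(np.sqrt(np.mean(diff**2)))


def marginalize_distance_profile(fes: FreeEnergySurface) -> Profile:
    """Integrate out the contact CV: G(d) = −RT·ln Σ_n e^{−G(d,n)/RT}·Δn."""
    rt = KB * fes.T
    dn = fes.grid.n_width
    n_d = fes.grid.shape[0]
    G = np.full(n_d, np.inf)
    sampled = np.zeros(n_d, dtype=bool)
    for i in range(n_d):
        cols = fes.sampled[i]
        if not cols.any():
            continue
        sampled[i] = True
        G[i] = -rt * (logsumexp(-fes.G[i, cols] / rt) + np.log(dn))
    if sampled.any():
        G[sampled] -= G[sampled].min()
    return Profile(d_centers=fes.grid.d_centers, G=G, sampled=sampled, T=fes.T)


def smooth_profile(profile: Profile, sigma_bins: float = 3.0) -> Profile:
    """Suppress bias-deposition noise in a marginal profile.

    The hills-derived profile carries discreteness noise on the scale of the
    hill width (one grid bin); landscape features are an order of magnitude
    wider.  A Gaussian kernel a few bins wide removes that noise — which
    would otherwise bias min-statistics over flat regions downward — without
    touching the physical shape.  Disjoint sampled segments are smoothed
    independently.
    """
    from scipy.ndimage import gaussian_filter1d
    if sigma_bins <= 0:
        return profile
    G = profile.G.copy()
    idx = np.flatnonzero(profile.sampled)
    if len(idx):
        splits = np.flatnonzero(np.diff(idx) != 1) + 1
        for seg in np.split(idx, splits):
            G[seg] = gaussian_filter1d(G[seg], sigma_bins, mode="nearest")
        G[idx] -= G[idx].min()
    return Profile(d_centers=profile.d_centers, G=G, sampled=profile.sampled,
                   T=profile.T)


def delta_g_unb(
    profile: Profile, bound_region: tuple[float, float] | None = None,
    unbound_region: tuple[float, float] | None = None,
) -> float:
    """ΔG_unb = mean G over the unbound plateau − min G over the bound region.

    Without explicit regions the bound region is the full sampled range (its
    global minimum is the bound state) and the unbound plateau is the last
    20% of the sampled distance range.
    """
    d = profile.d_centers
    if not profile.sampled.any():
        raise ValueError("profile has no sampled bins")
    d_sampled = d[profile.sampled]
    if bound_region is None:
        bound_region = (d_sampled[0], d_sampled[-1])
    if unbound_region is None:
        span = d_sampled[-1] - d_sampled[0]
        unbound_region = (d_sampled[-1] - 0.2 * span, d_sampled[-1])
    masks = []
    for lo, hi in (bound_region, unbound_region):
        m = profile.sampled & (d >= lo) & (d <= hi)
        if not m.any():
            raise ValueError(f"region ({lo}, {hi}) contains no sampled bins")
        masks.append(m)
    g_bound = float(np.min(profile.G[masks[0]]))
    g_unbound = float(np.mean(profile.G[masks[1]]))
    return g_unbound - g_bound


# ---------------------------------------------------------------------------
# termination detection and replicate aggregation
# ---------------------------------------------------------------------------

def detect_detachment(
    time: np.ndarray, nc: np.ndarray, window_ps: float = 200.0, eps: float = 0.01,
) -> float | None:
    """Earliest time t* with N_c ≤ eps for every sample in [t*, t*+window].

    Mirrors the run-termination rule: the contact count must fully zero out
    and stay there for the whole window.  Returns ``None`` when no such
    window exists or the series is shorter than the window.
    """
    time = np.asarray(time, float)
    nc = np.asarray(nc, float)
    if window_ps <= 0:
        raise ValueError("window_ps must be > 0")
    if len(time) == 0 or time[-1] - time[0] < window_ps:
        warnings.warn("series shorter than the detachment window")
        return None
    below = nc <= eps
    for i in np.flatnonzero(below):
        t_star = time[i]
        if time[-1] < t_star + window_ps:
            break
        in_win = (time >= t_star) & (time <= t_star + window_ps)
        if below[in_win].all():
            return float(t_star)
    return None


def aggregate_runs(values) -> UnbindingResult:
    """Mean and standard error (sample sd / √n) over replicate ΔG values."""
    values = np.asarray(list(values), float)
    if len(values) == 0:
        raise ValueError("need at least one run")
    mean = float(values.mean())
    if len(values) == 1:
        warnings.warn("single run: SEM reported as 0 by convention")
        return UnbindingResult(values=values, mean=mean, sem=0.0, n_runs=1,
                               single_run=True)
    sem = float(values.std(ddof=1) / np.sqrt(len(values)))
    return UnbindingResult(values=values, mean=mean, sem=sem, n_runs=len(values))
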