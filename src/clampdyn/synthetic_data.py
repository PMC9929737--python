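"""Synthetic study systems with known ground truth.

Every input the pipeline consumes can be generated here at desk scale:

* 2-CV overdamped Langevin dynamics under a well-tempered metadynamics bias
  on an analytic potential whose free-energy surface is known by quadrature
  — the stand-in for the unbinding simulations;
* Cartesian trajectories of a toy two-domain Cα complex with a planted
  interface contact set and a planted detachment schedule;
* a two-lobe "tuning-fork" dimer with a planted anti-phase swing-out mode;
* mutant panels drawn from the two-state current model with noise.

Every generator is a pure function of its parameters and seed, and each
planted ground truth is returned (and exportable as JSON) alongside the
data so downstream tests never re-derive it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .collective_variables import (
    DEFAULT_CONTACT_CUTOFF, ContactSet, CVSpec, com_distance, contact_set,
)
from .free_energy import (
    KB, DEFAULT_T, DEFAULT_DELTA_T, Grid, Profile, delta_g_unb,
)
from .io_formats import CVTrajectory, HillsSeries, Structure, Trajectory

CA_SPACING = 3.8  # Å, consecutive-Cα distance used for all toy lattices


# ---------------------------------------------------------------------------
# analytic 2-CV potential
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyticPotential:
    """U(d, n) = W(d) + (k_n/2)·(n − n0(d))², kcal/mol.

    W(d) is a sum of Gaussian wells (negative) and barriers (positive) on a
    reflecting domain ``d_range``; the contact coordinate n is harmonically
    tethered (constant stiffness, so the n-marginal adds only a constant to
    the distance profile) to a center n0(d) that decays smoothly from
    ``nc_bound`` in the bound basin to ``nc_base`` on the unbound plateau.
    n is reflected at 0; ``nc_base`` keeps the tether center several thermal
    widths above the wall so the reflection is thermodynamically negligible.
    """

    wells: tuple = ((3.0, 8.0, 1.5),)       # (depth, center, σ) in d
    barriers: tuple = ((1.0, 12.5, 1.2),)   # (height, center, σ) in d
    d_range: tuple = (3.0, 22.0)
    k_n: float = 3.0          # kcal/mol per unit², tether stiffness
    nc_bound: float = 6.0     # n0 at small d (bound)
    nc_base: float = 1.5      # n0 on the plateau
    nc_mid: float = 12.0      # Å, midpoint of the n0(d) switch
    nc_width: float = 1.5     # Å, width of the switch
    n_max: float = 10.0       # reflecting wall for n

    def n0(self, d):
        return self.nc_base + (self.nc_bound - self.nc_base) * 0.5 * (
            1.0 - np.tanh((np.asarray(d, float) - self.nc_mid) / self.nc_width)
        )

    def w(self, d):
        d = np.asarray(d, float)
        out = np.zeros_like(d)
        for depth, c, s in self.wells:
            out = out - depth * np.exp(-((d - c) ** 2) / (2 * s**2))
        for h, c, s in self.barriers:
            out = out + h * np.exp(-((d - c) ** 2) / (2 * s**2))
        return out if out.ndim else float(out)

    def energy(self, d, n):
        return self.w(d) + 0.5 * self.k_n * (np.asarray(n, float) - self.n0(d)) ** 2

    def marginal_profile(self, T: float = DEFAULT_T, d_width: float = 0.05,
                         n_points: int = 400) -> Profile:
        """Quadrature ground truth: G(d) = −RT·ln ∫₀^n_max e^{−βU} dn, min 0."""
        from scipy.special import logsumexp
        rt = KB * T
        d = np.arange(self.d_range[0] + d_width / 2, self.d_range[1], d_width)
        n = np.linspace(0.0, self.n_max, n_points)
        U = self.energy(d[:, None], n[None, :])
        G = -rt * logsumexp(-U / rt, axis=1)
        G -= G.min()
        return Profile(d_centers=d, G=G, sampled=np.ones_like(d, bool), T=T)

    def planted_delta_g(self, bound_region=None, unbound_region=None,
                        T: float = DEFAULT_T) -> float:
        """ΔG between bound minimum and unbound plateau, by quadrature.

        Regions default to the potential's own :attr:`bound_region` /
        :attr:`unbound_region`.
        """
        return delta_g_unb(
            self.marginal_profile(T=T),
            bound_region or self.bound_region,
            unbound_region or self.unbound_region,
        )

    def analysis_grid(self, d_width: float = 0.125, n_width: float = 0.25,
                      pad: float = 0.75) -> Grid:
        """Grid for bias accumulation: d_range padded by 5 hill widths."""
        return Grid.from_ranges(
            (self.d_range[0] - pad, self.d_range[1] + pad),
            (-1.5, self.n_max + 1.5), d_width=d_width, n_width=n_width,
        )

    @property
    def bound_region(self) -> tuple[float, float]:
        """Distance interval containing the bound basin (wall to barrier)."""
        if self.barriers:
            first = min(c for _, c, _ in self.barriers)
            s = next(s for _, c, s in self.barriers if c == first)
            return (self.d_range[0], first - s)
        return (self.d_range[0], 0.5 * sum(self.d_range))

    @property
    def unbound_region(self) -> tuple[float, float]:
        """Unbound plateau: past the last barrier by 3σ, inset 1 Å from the
        reflecting wall (bias deposition loses Gaussian mass beyond a wall,
        which would otherwise read as a spurious free-energy rise there)."""
        hi = self.d_range[1] - 1.0
        if self.barriers:
            last = max(c for _, c, _ in self.barriers)
            s = next(s for _, c, s in self.barriers if c == last)
            return (last + 3 * s, hi)
        return (0.5 * sum(self.d_range), hi)

    @classmethod
    def double_well(cls, delta_u: float = 3.0, barrier: float = 1.0,
                    **kw) -> "AnalyticPotential":
        """Bound well ``delta_u`` deep below a flat unbound plateau."""
        return cls(wells=((delta_u, 8.0, 1.5),),
                   barriers=((barrier, 12.5, 1.2),), **kw)

    @classmethod
    def symmetric(cls, barrier: float = 1.5, **kw) -> "AnalyticPotential":
        """Two flat basins of equal depth separated by a central barrier."""
        return cls(wells=(), barriers=((barrier, 12.5, 1.2),), **kw)


@dataclass(frozen=True)
class MetadParams:
    """Well-tempered deposition parameters (defaults: the study protocol)."""

    h0: float = 0.3           # initial hill height, kcal/mol
    stride: int = 1000        # steps between depositions
    sigma_d: float = 0.125    # hill width in d, Å
    sigma_n: float = 0.25     # hill width in n
    T: float = DEFAULT_T
    delta_T: float = DEFAULT_DELTA_T


def simulate_langevin_metad(
    potential: AnalyticPotential, params: MetadParams | None = None,
    steps: int = 2_000_000, dt: float = 0.005, T: float | None = None,
    seed: int = 0, record_stride: int = 20, diffusion: float = 1.0,
) -> tuple[CVTrajectory, HillsSeries]:
    """Overdamped Langevin sampling of (d, n) under U + V_bias.

    Hills are deposited every ``params.stride`` steps at the walker position
    with well-tempered heights h0·exp(−V(s,t)/(kB·ΔT)).  The bias force is
    tabulated on a fine grid and patched analytically at each deposition, so
    the integration loop costs O(1) per step.  Reflecting boundaries apply
    at the edges of ``d_range`` and at n = 0 / n_max.  Deterministic per
    seed; ``h0 = 0`` gives plain (unbiased) Langevin dynamics.

    Returns the recorded CV trajectory (time in ps) and the hills series.
    """
    params = params or MetadParams()
    if T is not None:
        params = replace(params, T=T)
    rt = KB * params.T
    kb_dT = KB * params.delta_T
    d_lo, d_hi = potential.d_range
    n_lo, n_hi = 0.0, potential.n_max

    # force-grid tabulation of the bias
    gd, gn = 0.0625, 0.125
    d_ax = np.arange(d_lo - 1.0, d_hi + 1.0 + gd, gd)
    n_ax = np.arange(n_lo - 1.0, n_hi + 1.0 + gn, gn)
    V = np.zeros((len(d_ax), len(n_ax)))
    Fd = [[0.0] * len(n_ax) for _ in range(len(d_ax))]
    Fn = [[0.0] * len(n_ax) for _ in range(len(d_ax))]
    inv_gd, inv_gn = 1.0 / gd, 1.0 / gn
    ax_d0, ax_n0 = float(d_ax[0]), float(n_ax[0])
    i_max, j_max = len(d_ax) - 1, len(n_ax) - 1

    # analytic force parameters, unpacked to plain floats for the inner loop
    wells = [(float(a), float(c), float(2 * s * s)) for a, c, s in potential.wells]
    barrs = [(float(a), float(c), float(2 * s * s)) for a, c, s in potential.barriers]
    k_n = potential.k_n
    nc_lo, nc_span = potential.nc_base, potential.nc_bound - potential.nc_base
    nc_mid, nc_w = potential.nc_mid, potential.nc_width

    rng = np.random.default_rng(seed)
    mob = diffusion / rt          # mobility D/RT
    noise_scale = math.sqrt(2.0 * diffusion * dt)
    exp, tanh = math.exp, math.tanh

    d = float(np.clip(potential.wells[0][1] if potential.wells else
                      0.5 * (d_lo + d_hi), d_lo, d_hi))
    n = float(np.clip(potential.n0(d), n_lo, n_hi))

    times, d_rec, n_rec = [], [], []
    h_step, h_d, h_n, h_sd, h_sn, h_h = [], [], [], [], [], []
    sig_d, sig_n = params.sigma_d, params.sigma_n
    stride = params.stride
    step = 0
    while step < steps:
        chunk = min(stride, steps - step)
        noise = (noise_scale * rng.standard_normal((chunk, 2))).tolist()
        for t in range(chunk):
            # analytic forces
            fd = 0.0
            for a, c, s2 in wells:
                dd = d - c
                fd -= a * dd * 2.0 / s2 * exp(-dd * dd / s2)
            for a, c, s2 in barrs:
                dd = d - c
                fd += a * dd * 2.0 / s2 * exp(-dd * dd / s2)
            th = tanh((d - nc_mid) / nc_w)
            n0 = nc_lo + nc_span * 0.5 * (1.0 - th)
            dn0 = -nc_span * 0.5 * (1.0 - th * th) / nc_w
            dev = n - n0
            fd += k_n * dev * dn0
            fn = -k_n * dev
            # bias force, nearest grid bin
            i = int((d - ax_d0) * inv_gd + 0.5)
            j = int((n - ax_n0) * inv_gn + 0.5)
            fd += Fd[i][j]
            fn += Fn[i][j]
            nt = noise[t]
            d += mob * fd * dt + nt[0]
            n += mob * fn * dt + nt[1]
            if d < d_lo:
                d = 2.0 * d_lo - d
            elif d > d_hi:
                d = 2.0 * d_hi - d
            if n < n_lo:
                n = 2.0 * n_lo - n
            elif n > n_hi:
                n = 2.0 * n_hi - n
            if not (d_lo - 1.0 < d < d_hi + 1.0):
                raise RuntimeError(f"trajectory diverged at step {step + t}")
            step_abs = step + t + 1
            if step_abs % record_stride == 0:
                times.append(step_abs * dt)
                d_rec.append(d)
                n_rec.append(n)
        step += chunk
        if params.h0 > 0.0 and step % stride == 0 and step < steps:
            i = int(round((d - ax_d0) * inv_gd))
            j = int(round((n - ax_n0) * inv_gn))
            h = params.h0 * exp(-V[i, j] / kb_dT)
            # patch V and the force tables on the ±5σ window
            i0, i1 = max(0, i - int(5 * sig_d * inv_gd)), \
                min(i_max, i + int(5 * sig_d * inv_gd))
            j0, j1 = max(0, j - int(5 * sig_n * inv_gn)), \
                min(j_max, j + int(5 * sig_n * inv_gn))
            dd = d_ax[i0:i1 + 1] - d
            nn = n_ax[j0:j1 + 1] - n
            ed = np.exp(-dd**2 / (2 * sig_d**2))
            en = np.exp(-nn**2 / (2 * sig_n**2))
            patch = h * np.outer(ed, en)
            V[i0:i1 + 1, j0:j1 + 1] += patch
            fd_patch = patch * (dd / sig_d**2)[:, None]
            fn_patch = patch * (nn / sig_n**2)[None, :]
            for a, row in enumerate(range(i0, i1 + 1)):
                frow_d, frow_n = Fd[row], Fn[row]
                prow_d, prow_n = fd_patch[a], fn_patch[a]
                for b, col in enumerate(range(j0, j1 + 1)):
                    frow_d[col] += prow_d[b]
                    frow_n[col] += prow_n[b]
            h_step.append(step)
            h_d.append(d)
            h_n.append(n)
            h_sd.append(sig_d)
            h_sn.append(sig_n)
            h_h.append(h)

    cv = CVTrajectory(time=np.asarray(times), d_com=np.asarray(d_rec),
                      n_contacts=np.asarray(n_rec))
    hills = HillsSeries(step=np.asarray(h_step, int),
                        center_d=np.asarray(h_d), center_nc=np.asarray(h_n),
                        width_d=np.asarray(h_sd), width_nc=np.asarray(h_sn),
                        height=np.asarray(h_h))
    return cv, hills


# ---------------------------------------------------------------------------
# toy two-domain complex with planted interface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyComplexTruth:
    """A ladder complex with an exactly known cross-domain interface.

    Domain A is a bead rod at y = 0 plus one designated control residue
    displaced far from every domain-B bead (its binding score is exactly 0
    over any trajectory of the complex).  The first ``n_interface`` beads of
    domain B sit within the binary contact cutoff of their domain-A
    partners at seed-spread gaps, which fixes the order in which contacts
    break as the domains separate.
    """

    structure: Structure
    reference_contacts: ContactSet
    interface_gaps: dict       # pair (res_a, res_b) -> initial Cα gap, Å
    control_residue: int       # the non-interface "K285 analogue"
    cv_spec: CVSpec
    seed: int

    def break_threshold(self, pair, d_cut: float = DEFAULT_CONTACT_CUTOFF):
        """Extra rigid-body separation at which a pair leaves the cutoff."""
        return d_cut - self.interface_gaps[pair]

    def as_dict(self) -> dict:
        return {
            "reference_contacts": sorted(self.reference_contacts.pairs),
            "interface_gaps": {f"{i}-{j}": g for (i, j), g in
                               sorted(self.interface_gaps.items())},
            "control_residue": self.control_residue,
            "seed": self.seed,
        }


def gen_toy_complex(
    n_res_a: int = 10, n_res_b: int = 8, n_interface: int = 6, seed: int = 0,
    jitter_sd: float = 0.03, d_cut: float = DEFAULT_CONTACT_CUTOFF,
) -> ToyComplexTruth:
    """Two Cα rods with exactly ``n_interface`` planted cross-domain contacts.

    Residues 1..n_res_a are domain "A" (the last one is the far-displaced
    control residue), residues n_res_a+1..n_res_a+n_res_b domain "B".
    """
    if n_interface > min(n_res_a - 1, n_res_b):
        raise ValueError("n_interface exceeds available residues")
    rng = np.random.default_rng(seed)
    for attempt in range(4):
        jit = jitter_sd / (2**attempt)
        truth = _build_ladder(n_res_a, n_res_b, n_interface, rng, jit, d_cut, seed)
        observed = contact_set(truth.structure, truth.structure.positions,
                               truth.cv_spec)
        if observed.pairs == truth.reference_contacts.pairs:
            return truth
    raise RuntimeError("could not realize the planted interface geometry")


def _build_ladder(n_res_a, n_res_b, n_interface, rng, jitter, d_cut, seed):
    gaps = np.linspace(0.82 * d_cut, 0.96 * d_cut, n_interface)
    gaps = gaps[rng.permutation(n_interface)]
    pos = []
    n_rod_a = n_res_a - 1
    for i in range(n_rod_a):
        pos.append([i * CA_SPACING, 0.0, 0.0])
    pos.append([0.5 * (n_rod_a - 1) * CA_SPACING, -15.0, 0.0])  # control
    for j in range(n_res_b):
        y = gaps[j] if j < n_interface else 3.2 * d_cut
        pos.append([j * CA_SPACING, y, 0.0])
    pos = np.asarray(pos) + jitter * rng.standard_normal((len(pos), 3))
    res_a = np.arange(1, n_res_a + 1)
    res_b = np.arange(n_res_a + 1, n_res_a + n_res_b + 1)
    structure = Structure(
        residue_index=np.concatenate([res_a, res_b]),
        residue_name=np.array(["ALA"] * (n_res_a + n_res_b)),
        chain_id=np.array(["A"] * n_res_a + ["B"] * n_res_b),
        domain_label=np.array(["A"] * n_res_a + ["B"] * n_res_b),
        positions=pos,
    )
    spec = CVSpec(group_a=res_a.tolist(), group_b=res_b.tolist(), d_cut=d_cut)
    pairs = {}
    for j in range(n_interface):
        pair = (int(res_a[j]), int(res_b[j]))
        pairs[pair] = float(np.linalg.norm(pos[j] - pos[n_res_a + j]))
    return ToyComplexTruth(
        structure=structure,
        reference_contacts=ContactSet(pairs=frozenset(pairs), frame_index=0),
        interface_gaps=pairs,
        control_residue=int(res_a[-1]),
        cv_spec=spec,
        seed=seed,
    )


@dataclass(frozen=True)
class DetachmentTruth:
    """Cartesian detachment trajectory plus its planted break schedule."""

    trajectory: Trajectory
    d_series: np.ndarray               # driving com-distance per frame, Å
    broken_pairs: list                 # per frame, tuple of broken ref pairs
    last_break_frame: int | None      # first frame with all pairs broken
    complex_truth: ToyComplexTruth


def linear_separation(d_start: float, d_end: float, n_frames: int) -> np.ndarray:
    """Monotone rigid-separation schedule for the distance CV."""
    return np.linspace(d_start, d_end, n_frames)


def gen_detachment_traj(
    truth: ToyComplexTruth, cv_or_d, seed: int = 0, jitter_sd: float = 0.05,
    dt: float = 50.0,
) -> DetachmentTruth:
    """Rigid-body separation of domain B along +y tracking a distance series.

    ``cv_or_d`` is a :class:`CVTrajectory` (its d_com drives the separation)
    or a plain distance array.  Per frame, domain B is translated along the
    y axis so the two domains' Cα centroid distance equals the driving
    value exactly (before jitter); interface pairs therefore break in the
    order of their planted gap thresholds as the distance grows.
    """
    if isinstance(cv_or_d, CVTrajectory):
        d_series = np.asarray(cv_or_d.d_com, float)
        if len(cv_or_d) > 1:
            dt = float(cv_or_d.time[1] - cv_or_d.time[0])
    else:
        d_series = np.asarray(cv_or_d, float)
    rng = np.random.default_rng(seed)
    st = truth.structure
    base = st.positions
    is_b = st.domain_label == "B"
    ia = st.atom_indices(truth.cv_spec.residues_a())
    ib = st.atom_indices(truth.cv_spec.residues_b())
    r0 = base[ib].mean(axis=0) - base[ia].mean(axis=0)
    perp2 = r0[0] ** 2 + r0[2] ** 2
    if np.any(d_series**2 < perp2):
        raise ValueError(
            f"driving distance below the in-plane centroid offset "
            f"({math.sqrt(perp2):.2f} Å)"
        )
    shifts = -r0[1] + np.sqrt(d_series**2 - perp2)

    frames = np.repeat(base[None, :, :], len(d_series), axis=0)
    frames[:, is_b, 1] += shifts[:, None]
    frames += jitter_sd * rng.standard_normal(frames.shape)

    broken: list = []
    last_break = None
    for t, s in enumerate(shifts):
        b = tuple(sorted(p for p, gap in truth.interface_gaps.items()
                         if gap + s >= truth.cv_spec.d_cut))
        broken.append(b)
        if last_break is None and len(b) == len(truth.interface_gaps):
            last_break = t
    traj = Trajectory(structure=st, frames=frames, dt=dt,
                      metadata={"seed": seed, "kind": "detachment"})
    return DetachmentTruth(trajectory=traj, d_series=d_series,
                           broken_pairs=broken, last_break_frame=last_break,
                           complex_truth=truth)


# ---------------------------------------------------------------------------
# two-lobe dimer with planted anti-phase swing-out mode
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DimerTruth:
    """Tuning-fork dimer: scaffold plate, two arms, two toy-complex lobes."""

    structure: Structure
    planted_mode: np.ndarray   # unit 3N anti-phase swing field
    lobe_atoms: tuple          # (indices lobe 1, indices lobe 2)
    anm_cutoff: float          # Å, recommended elastic-network cutoff
    seed: int


def _block_sites(nx, ny, nz):
    g = np.array([[i, j, k] for i in range(nx) for j in range(ny)
                  for k in range(nz)], float) * CA_SPACING
    return g - g.mean(axis=0)


def _cuboid_dims(n):
    """Smallest reasonably isotropic cuboid with at least n lattice sites."""
    best = None
    for nx in range(1, n + 1):
        for ny in range(1, nx + 1):
            nz = math.ceil(n / (nx * ny))
            if nz > ny:
                continue
            vol, aspect = nx * ny * nz, nx / nz
            if best is None or (vol, aspect) < best[:2]:
                best = (vol, aspect, (nx, ny, nz))
    return best[2]


def gen_dimer_breathing(
    truth_a: ToyComplexTruth, truth_b: ToyComplexTruth, amplitude: float = 2.0,
    n_frames: int = 200, noise_sd: float = 0.2, seed: int = 0,
    period: int = 40, arm_x: float = 11.4, jitter_sd: float = 0.1,
) -> tuple[Trajectory, DimerTruth]:
    """Anti-phase swing-out trajectory of a two-lobe dimer.

    The two toy complexes are repacked into compact lattice lobes hung from
    a shared scaffold plate via two vertical arms — a tuning-fork whose
    softest elastic mode is, by construction, the lobes swinging apart
    along ±x with a flexure amplitude growing linearly with depth below the
    plate.  Frames oscillate along exactly that planted field (plus
    isotropic Gaussian noise), so trajectory PCA and the network model can
    both be benchmarked against one known direction.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    rng = np.random.default_rng(seed)

    plate = _block_sites(7, 2, 2)
    arm_template = _block_sites(2, 2, 3)
    positions, chains, labels = [plate], ["S"] * len(plate), ["scaffold"] * len(plate)
    arm_top = -1.5 * CA_SPACING
    for side, (s, truth) in enumerate(((+1, truth_a), (-1, truth_b))):
        arm = arm_template + [s * arm_x, 0.0, arm_top - CA_SPACING]
        positions.append(arm)
        chains += ["S"] * len(arm)
        labels += ["arm"] * len(arm)
        n_lobe = truth.structure.n_atoms
        dims = _cuboid_dims(n_lobe)
        lobe = _block_sites(*dims)[:n_lobe][:, [2, 1, 0]]  # long axis vertical
        lobe = lobe - lobe.mean(axis=0)
        lobe += [s * arm_x, 0.0,
                 arm_top - 3.5 * CA_SPACING - 0.5 * (dims[0] - 1) * CA_SPACING]
        positions.append(lobe)
        chains += [chr(ord("C") + side)] * n_lobe
        labels += list(truth.structure.domain_label)
    pos = np.vstack(positions)
    pos += jitter_sd * rng.standard_normal(pos.shape)
    n_atoms = len(pos)

    # stacking order: plate, arm1, lobe1, arm2, lobe2
    n1, n2 = truth_a.structure.n_atoms, truth_b.structure.n_atoms
    o = len(plate)
    arm1 = np.arange(o, o + len(arm_template)); o += len(arm_template)
    lobe1 = np.arange(o, o + n1); o += n1
    arm2 = np.arange(o, o + len(arm_template)); o += len(arm_template)
    lobe2 = np.arange(o, o + n2); o += n2

    scaffold_idx = np.concatenate([np.arange(len(plate)), arm1, arm2])
    ri = np.empty(n_atoms, int)
    ri[scaffold_idx] = np.arange(1, len(scaffold_idx) + 1)
    ri[lobe1] = truth_a.structure.residue_index
    ri[lobe2] = truth_b.structure.residue_index

    structure = Structure(
        residue_index=ri,
        residue_name=np.array(["GLY"] * n_atoms),
        chain_id=np.array(chains),
        domain_label=np.array(labels),
        positions=pos,
    )

    # planted field: anti-phase x displacement, linear in depth below plate
    mode = np.zeros((n_atoms, 3))
    depth = np.clip(-pos[:, 2], 0.0, None)
    for s, idx in ((+1, np.concatenate([arm1, lobe1])),
                   (-1, np.concatenate([arm2, lobe2]))):
        mode[idx, 0] = s * depth[idx]
    mode /= np.linalg.norm(mode)

    phases = np.sin(2 * np.pi * np.arange(n_frames) / period)
    scale = amplitude / np.abs(mode).max()
    frames = (pos[None, :, :]
              + phases[:, None, None] * scale * mode[None, :, :]
              + noise_sd * rng.standard_normal((n_frames, n_atoms, 3)))
    traj = Trajectory(structure=structure, frames=frames, dt=1.0,
                      metadata={"seed": seed, "kind": "dimer_breathing"})
    return traj, DimerTruth(structure=structure, planted_mode=mode.ravel(),
                            lobe_atoms=(lobe1, lobe2), anm_cutoff=7.7,
                            seed=seed)


# ---------------------------------------------------------------------------
# end-to-end free-energy recovery benchmark
# ---------------------------------------------------------------------------

def recover_delta_g(
    potential: AnalyticPotential, n_runs: int = 7, steps: int = 3_000_000,
    seed: int = 0, sampled_threshold: float = 0.05,
    smooth_sigma_bins: float = 3.0, **sim_kw,
):
    """Full unbinding-free-energy pipeline on replicate biased runs.

    For each replicate: simulate under the well-tempered bias, accumulate
    the recorded hills onto the analysis grid, convert to a free-energy
    surface, marginalize out the contact CV, smooth the marginal on the
    sub-feature scale, and read off ΔG between the potential's declared
    bound and unbound regions.  Returns the replicate aggregate
    (mean ± SEM) as an :class:`~clampdyn.free_energy.UnbindingResult`.
    """
    from .free_energy import (
        accumulate_bias, aggregate_runs, fes_from_bias,
        marginalize_distance_profile, smooth_profile,
    )
    grid = potential.analysis_grid()
    values = []
    for r in range(n_runs):
        _, hills = simulate_langevin_metad(potential, steps=steps,
                                           seed=seed + r, **sim_kw)
        fes = fes_from_bias(accumulate_bias(hills, grid),
                            sampled_threshold=sampled_threshold)
        profile = smooth_profile(marginalize_distance_profile(fes),
                                 smooth_sigma_bins)
        values.append(delta_g_unb(profile, potential.bound_region,
                                  potential.unbound_region))
    return aggregate_runs(values)
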