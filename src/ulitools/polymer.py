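"""Bead-and-spring chromatin with diffusing multivalent binding factors.

The model: a chromatin fiber of N beads (3 kb / ~30 nm per bead; sigma = one
bead diameter is the length unit, k_B T the energy unit) connected by stiff
harmonic bonds, with excluded volume between all particles via a purely
repulsive (WCA) core. A subset of beads are high-affinity binding sites, each
labeled with one of ``n_types`` colors. Diffusing binder beads of matching
colors are attracted to every chromatin bead with depth ``eps_nonspecific``
and to own-color site beads with depth ``eps_specific``; binders never
attract each other. Binders stochastically switch between an interacting
"on" state and a purely repulsive "off" state, implementing binding
turnover. This is the bridging-induced clustering regime: multivalent
binding loops chromatin, locally concentrating binding sites, which recruits
further binders without any binder-binder affinity.

Dynamics are overdamped (Brownian) with unit friction and temperature, in a
non-periodic cubic box with soft harmonic walls whose volume sets the
chromatin number density. A per-pair force cap softens the WCA core so the
integrator stays stable at the default timestep; this acts as a soft-core
excluded volume, standard for coarse-grained chromatin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PolymerConfig",
    "BindingSiteMap",
    "SimulationState",
    "Trajectory",
    "scaled_config",
    "full_scale_config",
    "assign_binding_sites",
    "init_random_walk",
    "simulate",
    "run_simulation",
    "detect_clusters",
    "largest_cluster_size",
    "chromatin_bound_fraction",
]


@dataclass
class PolymerConfig:
    """All tunable model parameters (reduced units: sigma, k_B T, tau)."""

    n_beads: int = 5000
    bp_per_bead: int = 3000
    sigma_nm: float = 30.0
    n_site_beads: int = 172
    n_types: int = 5
    n_binders: int = 200
    eps_specific: float = 8.0       # k_B T, binder at own-color site
    eps_nonspecific: float = 3.0    # k_B T, binder at any chromatin bead
    attraction_cutoff: float = 1.8  # sigma
    rep_eps: float = 1.0            # WCA core strength
    bond_k: float = 50.0            # k_B T / sigma^2
    bond_r0: float = 1.0            # sigma
    bend_k: float = 0.0             # k_B T; 0 = fully flexible chain
    density: float = 0.1            # chromatin beads / sigma^3 -> box size
    dt: float = 0.005               # tau
    n_steps: int = 2_000_000
    sample_every: int = 10_000
    k_on: float = 0.02              # 1 / tau, off -> on
    k_off: float = 0.002            # 1 / tau, on -> off
    switching: bool = True
    force_cap: float = 50.0         # per-pair force magnitude cap
    wall_k: float = 100.0

    def __post_init__(self):
        if self.eps_nonspecific < 0 or self.eps_specific < self.eps_nonspecific:
            raise ValueError("need eps_specific >= eps_nonspecific >= 0")
        if self.n_site_beads > self.n_beads:
            raise ValueError("more site beads than chromatin beads")

    @property
    def box_size(self) -> float:
        return (self.n_beads / self.density) ** (1.0 / 3.0)

    @property
    def n_total(self) -> int:
        return self.n_beads + self.n_binders

    def binder_threshold_sigma(self, nm: float) -> float:
        return nm / self.sigma_nm


def scaled_config(**overrides) -> PolymerConfig:
    """Scaled-down preset used by the test suite: 500 beads, 20 sites,
    2 types, 20 binders, run length sized for desk-scale ensembles."""
    base = dict(n_beads=500, n_site_beads=20, n_types=2, n_binders=20,
                n_steps=100_000, sample_every=1_000)
    base.update(overrides)
    return PolymerConfig(**base)


def full_scale_config(**overrides) -> PolymerConfig:
    """The full 5000-bead / 172-site / 5-type / 200-binder configuration."""
    return PolymerConfig(**overrides)


@dataclass
class BindingSiteMap:
    indices: np.ndarray  # site bead indices, unique, sorted
    types: np.ndarray    # 1..n_types per site

    def site_type_array(self, n_beads: int) -> np.ndarray:
        out = np.zeros(n_beads, dtype=np.int64)
        out[self.indices] = self.types
        return out


def assign_binding_sites(config: PolymerConfig, seed: int) -> BindingSiteMap:
    """Uniform random site beads; types round-robin over a shuffled order,
    so per-type counts differ by at most one."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(config.n_beads, size=config.n_site_beads, replace=False)
    rng.shuffle(idx)
    types = (np.arange(config.n_site_beads) % config.n_types) + 1
    order = np.argsort(idx, kind="stable")
    return BindingSiteMap(indices=idx[order], types=types[order])


@dataclass
class SimulationState:
    pos: np.ndarray            # (n_beads + n_binders, 3), chromatin first
    site_type: np.ndarray      # (n_beads,) 0 or 1..n_types
    binder_type: np.ndarray    # (n_binders,) 1..n_types
    binder_on: np.ndarray      # (n_binders,) uint8
    config: PolymerConfig
    time: float = 0.0


@dataclass
class Trajectory:
    frames: np.ndarray         # (n_frames, n_total, 3)
    times: np.ndarray          # (n_frames,)
    on_states: np.ndarray      # (n_frames, n_binders)
    config: PolymerConfig
    site_map: BindingSiteMap

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def second_half(self) -> "Trajectory":
        """Frames with time >= n_steps * dt / 2 (the analysis window)."""
        t_half = self.config.n_steps * self.config.dt / 2.0
        keep = self.times >= t_half
        return Trajectory(self.frames[keep], self.times[keep],
                          self.on_states[keep], self.config, self.site_map)

    def chromatin(self, frame: int) -> np.ndarray:
        return self.frames[frame, : self.config.n_beads]

    def binders(self, frame: int) -> np.ndarray:
        return self.frames[frame, self.config.n_beads:]


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _step_chunk(pos, is_binder, stype, on_state, n_beads, box,
                dt, bond_k, bond_r0, bend_k, rep_eps, eps_s, eps_ns,
                att_cut, force_cap, wall_k, koff_dt, kon_dt, switching,
                noise, sw_u):
    n = pos.shape[0]
    n_binders = n - n_beads
    n_steps = noise.shape[0]
    wca_cut2 = 2.0 ** (1.0 / 3.0)          # (2^(1/6))^2
    att_cut2 = att_cut * att_cut
    r_core = 2.0 ** (1.0 / 6.0)
    well_w = att_cut - r_core              # attractive well width
    half_pi = 0.5 * np.pi
    ncell = max(3, int(box / att_cut))
    cell_w = box / ncell
    n_cells = ncell * ncell * ncell
    head = np.empty(n_cells, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    forces = np.empty((n, 3))

    for step in range(n_steps):
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0

        # --- cell list ---
        for c in range(n_cells):
            head[c] = -1
        for i in range(n):
            cx = int(pos[i, 0] / cell_w)
            cy = int(pos[i, 1] / cell_w)
            cz = int(pos[i, 2] / cell_w)
            if cx < 0:
                cx = 0
            elif cx >= ncell:
                cx = ncell - 1
            if cy < 0:
                cy = 0
            elif cy >= ncell:
                cy = ncell - 1
            if cz < 0:
                cz = 0
            elif cz >= ncell:
                cz = ncell - 1
            c = (cx * ncell + cy) * ncell + cz
            nxt[i] = head[c]
            head[c] = i

        # --- nonbonded pair forces (each pair once via j > i) ---
        for i in range(n):
            cx = int(pos[i, 0] / cell_w)
            cy = int(pos[i, 1] / cell_w)
            cz = int(pos[i, 2] / cell_w)
            if cx < 0:
                cx = 0
            elif cx >= ncell:
                cx = ncell - 1
            if cy < 0:
                cy = 0
            elif cy >= ncell:
                cy = ncell - 1
            if cz < 0:
                cz = 0
            elif cz >= ncell:
                cz = ncell - 1
            for ox in range(-1, 2):
                nx = cx + ox
                if nx < 0 or nx >= ncell:
                    continue
                for oy in range(-1, 2):
                    ny = cy + oy
                    if ny < 0 or ny >= ncell:
                        continue
                    for oz in range(-1, 2):
                        nz = cz + oz
                        if nz < 0 or nz >= ncell:
                            continue
                        j = head[(nx * ncell + ny) * ncell + nz]
                        while j >= 0:
                            if j > i:
                                dx = pos[i, 0] - pos[j, 0]
                                dy = pos[i, 1] - pos[j, 1]
                                dz = pos[i, 2] - pos[j, 2]
                                r2 = dx * dx + dy * dy + dz * dz
                                if r2 < att_cut2 and r2 > 1e-12:
                                    bi = is_binder[i]
                                    bj = is_binder[j]
                                    eps = 0.0
                                    attractive = False
                                    if bi != bj:
                                        # chromatin-binder pair
                                        if bi:
                                            bidx = i - n_beads
                                            ctype = stype[j]
                                        else:
                                            bidx = j - n_beads
                                            ctype = stype[i]
                                        if on_state[bidx] == 1:
                                            if ctype != 0 and ctype == stype[n_beads + bidx]:
                                                eps = eps_s
                                            else:
                                                eps = eps_ns
                                            attractive = eps > 0.0
                                    # repulsive WCA core for every pair
                                    fmag = 0.0
                                    if r2 < wca_cut2:
                                        inv_r2 = 1.0 / r2
                                        inv_r6 = inv_r2 * inv_r2 * inv_r2
                                        fmag = 24.0 * rep_eps * (2.0 * inv_r6 * inv_r6 - inv_r6) * inv_r2
                                    if attractive:
                                        # smooth cosine-squared well, flat at
                                        # depth eps inside the core radius;
                                        # bounded curvature keeps the deep
                                        # wells stable at this timestep
                                        r = np.sqrt(r2)
                                        if r > r_core:
                                            theta = half_pi * (r - r_core) / well_w
                                            fmag += (-eps * half_pi / well_w
                                                     * np.sin(2.0 * theta)) / r
                                    if fmag != 0.0:
                                        r = np.sqrt(r2)
                                        f_abs = fmag * r  # |F|
                                        if f_abs > force_cap:
                                            fmag = force_cap / r
                                        elif f_abs < -force_cap:
                                            fmag = -force_cap / r
                                        forces[i, 0] += fmag * dx
                                        forces[i, 1] += fmag * dy
                                        forces[i, 2] += fmag * dz
                                        forces[j, 0] -= fmag * dx
                                        forces[j, 1] -= fmag * dy
                                        forces[j, 2] -= fmag * dz
                            j = nxt[j]

        # --- chain bonds ---
        for k in range(n_beads - 1):
            dx = pos[k + 1, 0] - pos[k, 0]
            dy = pos[k + 1, 1] - pos[k, 1]
            dz = pos[k + 1, 2] - pos[k, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > 1e-12:
                fmag = bond_k * (r - bond_r0) / r
                forces[k, 0] += fmag * dx
                forces[k, 1] += fmag * dy
                forces[k, 2] += fmag * dz
                forces[k + 1, 0] -= fmag * dx
                forces[k + 1, 1] -= fmag * dy
                forces[k + 1, 2] -= fmag * dz

        # --- bending (Kratky-Porod, U = bend_k * (1 - cos theta)) ---
        if bend_k > 0.0:
            for k in range(1, n_beads - 1):
                ax = pos[k, 0] - pos[k - 1, 0]
                ay = pos[k, 1] - pos[k - 1, 1]
                az = pos[k, 2] - pos[k - 1, 2]
                bx = pos[k + 1, 0] - pos[k, 0]
                by = pos[k + 1, 1] - pos[k, 1]
                bz = pos[k + 1, 2] - pos[k, 2]
                a2 = ax * ax + ay * ay + az * az
                b2 = bx * bx + by * by + bz * bz
                if a2 < 1e-12 or b2 < 1e-12:
                    continue
                ia = 1.0 / np.sqrt(a2)
                ib = 1.0 / np.sqrt(b2)
                c = (ax * bx + ay * by + az * bz) * ia * ib
                # F = bend_k * dc/dp
                gpm_x = c * ax * ia * ia - bx * ia * ib
                gpm_y = c * ay * ia * ia - by * ia * ib
                gpm_z = c * az * ia * ia - bz * ia * ib
                gpp_x = ax * ia * ib - c * bx * ib * ib
                gpp_y = ay * ia * ib - c * by * ib * ib
                gpp_z = az * ia * ib - c * bz * ib * ib
                forces[k - 1, 0] += bend_k * gpm_x
                forces[k - 1, 1] += bend_k * gpm_y
                forces[k - 1, 2] += bend_k * gpm_z
                forces[k + 1, 0] += bend_k * gpp_x
                forces[k + 1, 1] += bend_k * gpp_y
                forces[k + 1, 2] += bend_k * gpp_z
                forces[k, 0] -= bend_k * (gpm_x + gpp_x)
                forces[k, 1] -= bend_k * (gpm_y + gpp_y)
                forces[k, 2] -= bend_k * (gpm_z + gpp_z)

        # --- soft walls ---
        for i in range(n):
            for d in range(3):
                x = pos[i, d]
                if x < 0.0:
                    forces[i, d] -= wall_k * x
                elif x > box:
                    forces[i, d] -= wall_k * (x - box)

        # --- Brownian update (noise pre-scaled by sqrt(2 dt)) ---
        for i in range(n):
            pos[i, 0] += forces[i, 0] * dt + noise[step, i, 0]
            pos[i, 1] += forces[i, 1] * dt + noise[step, i, 1]
            pos[i, 2] += forces[i, 2] * dt + noise[step, i, 2]

        # --- binder on/off turnover ---
        if switching:
            for b in range(n_binders):
                u = sw_u[step, b]
                if on_state[b] == 1:
                    if u < koff_dt:
                        on_state[b] = 0
                else:
                    if u < kon_dt:
                        on_state[b] = 1


# ---------------------------------------------------------------------------
# Setup and driver
# ---------------------------------------------------------------------------

def _fold_into_box(x: np.ndarray, box: float) -> np.ndarray:
    """Reflect coordinates into [0, box] (triangular-wave fold)."""
    period = 2.0 * box
    y = np.mod(x, period)
    return box - np.abs(y - box)


def init_random_walk(config: PolymerConfig, seed: int,
                     site_map: BindingSiteMap | None = None,
                     n_relax: int = 2000) -> SimulationState:
    """Chromatin as a random walk (step = bond rest length) folded into the
    box, binders uniform; overlaps relaxed by a short capped-force push-off
    phase with attractions off. Reproducible given the seed."""
    packing = config.n_total * (np.pi / 6.0) / config.box_size ** 3
    if packing > 0.4:
        raise ValueError(f"packing fraction {packing:.2f} too high to place beads")
    rng = np.random.default_rng(seed)
    box = config.box_size
    steps = rng.standard_normal((config.n_beads, 3))
    steps *= config.bond_r0 / np.linalg.norm(steps, axis=1, keepdims=True)
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0) + box / 2.0
    chromatin = _fold_into_box(walk, box)
    binders = rng.uniform(0.0, box, size=(config.n_binders, 3))
    pos = np.ascontiguousarray(np.vstack([chromatin, binders]))

    if site_map is None:
        site_map = assign_binding_sites(config, seed)
    site_type = site_map.site_type_array(config.n_beads)
    binder_type = (np.arange(config.n_binders) % config.n_types) + 1
    binder_on = np.ones(config.n_binders, dtype=np.uint8)

    state = SimulationState(pos=pos, site_type=site_type,
                            binder_type=binder_type, binder_on=binder_on,
                            config=config, time=0.0)
    if n_relax > 0:
        relax_cfg = replace(config, eps_specific=0.0, eps_nonspecific=0.0,
                            force_cap=10.0, switching=False)
        _run_steps(state, relax_cfg, n_relax, np.random.default_rng((seed, 1)))
        state.time = 0.0
    return state


def _run_steps(state: SimulationState, config: PolymerConfig, n_steps: int,
               rng: np.random.Generator, chunk: int = 2_000) -> None:
    n = config.n_total
    is_binder = np.zeros(n, dtype=np.uint8)
    is_binder[config.n_beads:] = 1
    stype = np.concatenate([state.site_type, state.binder_type]).astype(np.int64)
    scale = np.sqrt(2.0 * config.dt)
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        noise = rng.standard_normal((m, n, 3)) * scale
        sw_u = rng.random((m, config.n_binders))
        _step_chunk(state.pos, is_binder, stype, state.binder_on,
                    config.n_beads, config.box_size, config.dt,
                    config.bond_k, config.bond_r0, config.bend_k,
                    config.rep_eps, config.eps_specific, config.eps_nonspecific,
                    config.attraction_cutoff, config.force_cap, config.wall_k,
                    config.k_off * config.dt, config.k_on * config.dt,
                    config.switching, noise, sw_u)
        done += m
        state.time += m * config.dt
    if not np.all(np.isfinite(state.pos)):
        raise FloatingPointError("non-finite positions: simulation diverged")


def simulate(state: SimulationState, seed: int,
             config: PolymerConfig | None = None) -> Trajectory:
    """Run n_steps of overdamped dynamics, sampling every sample_every steps."""
    config = config or state.config
    rng = np.random.default_rng((seed, 2))
    frames, times, ons = [], [], []
    n_samples = config.n_steps // config.sample_every
    for _ in range(n_samples):
        _run_steps(state, config, config.sample_every, rng)
        frames.append(state.pos.copy())
        times.append(state.time)
        ons.append(state.binder_on.copy())
    return Trajectory(frames=np.array(frames), times=np.array(times),
                      on_states=np.array(ons), config=config,
                      site_map=BindingSiteMap(
                          indices=np.flatnonzero(state.site_type > 0),
                          types=state.site_type[state.site_type > 0]))


def run_simulation(config: PolymerConfig, seed: int) -> Trajectory:
    """Initialize (sites, random walk, push-off) and simulate, all from one seed."""
    site_map = assign_binding_sites(config, seed)
    state = init_random_walk(config, seed, site_map=site_map)
    return simulate(state, seed)


# ---------------------------------------------------------------------------
# Cluster statistics
# ---------------------------------------------------------------------------

def detect_clusters(binder_pos: np.ndarray, cutoff: float = 1.3) -> np.ndarray:
    """Single-linkage cluster labels over binder-binder distances < cutoff."""
    n = len(binder_pos)
    if n == 0:
        return np.array([], dtype=int)
    d = squareform(pdist(binder_pos))
    adj = coo_matrix((d < cutoff).astype(np.int8))
    _, labels = connected_components(adj, directed=False)
    return labels


def largest_cluster_size(binder_pos: np.ndarray, cutoff: float = 1.3) -> int:
    labels = detect_clusters(binder_pos, cutoff)
    if len(labels) == 0:
        return 0
    return int(np.bincount(labels).max())


def chromatin_bound_fraction(traj: Trajectory, frame: int,
                             cutoff: float | None = None) -> float:
    """Fraction of 'on' binders within the attraction cutoff of any chromatin bead."""
    cfg = traj.config
    cutoff = cutoff if cutoff is not None else cfg.attraction_cutoff
    chrom = traj.chromatin(frame)
    binders = traj.binders(frame)
    on = traj.on_states[frame].astype(bool)
    if not on.any():
        return 0.0
    tree = cKDTree(chrom)
    d, _ = tree.query(binders[on], k=1)
    return float(np.mean(d < cutoff))
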