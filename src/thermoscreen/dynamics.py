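"""Desk-scale elastic-network Langevin simulator.

A Cα elastic network (harmonic springs within a cutoff) evolved with
overdamped Brownian dynamics provides multi-temperature trajectories whose
fluctuation statistics mirror what the screening stage assumes about
all-atom MD: mean-square fluctuations grow linearly with temperature, and
an engineered crosslink (the coarse-grained stand-in for a disulfide bond)
can only damp them. The force is the linearized network force
``F = −H (x − x0)`` with ``H`` the ANM Hessian, so the stationary
distribution is exactly Gaussian and the per-bead mean-square fluctuation
has the closed form ``kB·T · tr(H⁺)ᵢ`` — the module's analytic oracle.

Units: kcal/mol, Å, K; kB = 0.0019872 kcal/mol/K. Time is opaque (the
friction coefficient sets the clock; only stationary statistics matter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .structure import Atom, Structure, Trajectory, select

__all__ = [
    "KB",
    "Spring",
    "ElasticNetwork",
    "SimSpec",
    "build_network",
    "simulate",
    "simulate_single",
    "DisconnectedNetworkError",
    "UnstableTimestepError",
]

KB = 0.0019872  # kcal/mol/K


class DisconnectedNetworkError(ValueError):
    """Network has internal zero modes beyond the six rigid-body ones."""


class UnstableTimestepError(ValueError):
    """Euler–Maruyama step too large for the stiffest network mode."""


@dataclass(frozen=True)
class Spring:
    i: int
    j: int
    k: float  # kcal/mol/Å²
    r0: float  # Å
    crosslink: bool = False

    def __post_init__(self):
        if self.k < 0 or self.r0 <= 0:
            raise ValueError("spring needs k >= 0 and r0 > 0")
        if self.i == self.j:
            raise ValueError("spring endpoints must differ")


@dataclass
class ElasticNetwork:
    """Bead positions + springs (+ optional isotropic tethers to anchors)."""

    positions: np.ndarray
    springs: list[Spring]
    tethers: list[tuple[int, float]] = field(default_factory=list)
    friction: float = 1.0
    kB: float = KB

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        canon = []
        for s in self.springs:
            canon.append(replace(s, i=min(s.i, s.j), j=max(s.i, s.j)))
        self.springs = canon

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def hessian(self) -> np.ndarray:
        """3N×3N linearized (ANM) Hessian about the reference positions."""
        n = self.n_beads
        h = np.zeros((3 * n, 3 * n))
        for s in self.springs:
            d = self.positions[s.j] - self.positions[s.i]
            r = np.linalg.norm(d)
            e = d / r
            block = s.k * np.outer(e, e)
            si, sj = 3 * s.i, 3 * s.j
            h[si : si + 3, si : si + 3] += block
            h[sj : sj + 3, sj : sj + 3] += block
            h[si : si + 3, sj : sj + 3] -= block
            h[sj : sj + 3, si : si + 3] -= block
        for i, k in self.tethers:
            h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += k * np.eye(3)
        return h

    def analytic_msf(self, temperature: float) -> np.ndarray:
        """Per-bead equilibrium mean-square fluctuation (Å²) at T (K).

        ``MSF_i = kB·T · tr(H⁺)_ii`` with rigid-body null modes projected
        out of the pseudo-inverse. Raises
        :class:`DisconnectedNetworkError` when more than six zero modes
        exist (disconnected or mechanically floppy network).
        """
        h = self.hessian()
        w, v = np.linalg.eigh(h)
        tol = max(w[-1], 1.0) * 1e-9
        null = w < tol
        if null.sum() > 6:
            raise DisconnectedNetworkError(
                f"{int(null.sum())} zero modes (> 6): network is "
                "disconnected or internally floppy"
            )
        vv = v[:, ~null]
        diag = (vv**2 / w[~null]).sum(axis=1)
        return self.kB * temperature * diag.reshape(-1, 3).sum(axis=1)

    def add_crosslink(self, i: int, j: int, k_ss: float = 10.0) -> "ElasticNetwork":
        """New network with one extra (crosslink-flagged) spring; self unmodified."""
        if i == j:
            raise ValueError("crosslink endpoints must differ")
        if not (0 <= i < self.n_beads and 0 <= j < self.n_beads):
            raise IndexError("crosslink bead index out of range")
        r0 = float(np.linalg.norm(self.positions[j] - self.positions[i]))
        new = Spring(min(i, j), max(i, j), k_ss, r0, crosslink=True)
        return ElasticNetwork(
            self.positions.copy(),
            [*self.springs, new],
            list(self.tethers),
            self.friction,
            self.kB,
        )

    def remove_crosslinks(self) -> "ElasticNetwork":
        return ElasticNetwork(
            self.positions.copy(),
            [s for s in self.springs if not s.crosslink],
            list(self.tethers),
            self.friction,
            self.kB,
        )

    def to_structure(self) -> Structure:
        """One-CA-per-bead Structure (ALA, chain A), for PDB round-tripping."""
        atoms = [
            Atom(
                serial=i + 1, name="CA", element="C", res_name="ALA",
                res_id=i + 1, chain="A", coords=self.positions[i].copy(),
            )
            for i in range(self.n_beads)
        ]
        return Structure(atoms)


def compact_cluster(
    n_beads: int = 50, spacing: float = 3.8, jitter: float = 0.4, seed: int = 7
) -> Structure:
    """Globular Cα-only test protein: a jittered cubic-lattice blob.

    Beads sit on a cubic lattice at Cα-like spacing, trimmed to the
    ``n_beads`` sites closest to the center (roughly spherical, like a
    folded domain) and jittered to break lattice symmetry. At the default
    8 Å cutoff the resulting elastic network is densely connected and
    stiff, with fluctuation amplitudes in the regime real proteins show —
    the geometry the screening pipeline is meant for. Elongated,
    filament-like bead chains are deliberately not used as fixtures:
    their near-zero bending modes have fluctuations larger than the
    structure itself, outside any harmonic model's validity.
    """
    rng = np.random.default_rng(seed)
    side = int(np.ceil(n_beads ** (1.0 / 3.0)))
    pts = np.array(
        [(i, j, k) for i in range(side) for j in range(side) for k in range(side)],
        dtype=float,
    )
    center = pts.mean(axis=0)
    order = np.argsort(((pts - center) ** 2).sum(axis=1))
    pts = pts[order[:n_beads]] * spacing
    pts += jitter * rng.standard_normal(pts.shape)
    atoms = [
        Atom(serial=i + 1, name="CA", element="C", res_name="ALA",
             res_id=i + 1, chain="A", coords=p)
        for i, p in enumerate(pts)
    ]
    return Structure(atoms)


def mobile_loop_protein(
    n_core: int = 20,
    n_loop: int = 8,
    bulge: float = 7.0,
    spacing: float = 3.8,
    seed: int = 7,
) -> Structure:
    """Globular core with one mobile surface loop — the screening test case.

    A :func:`compact_cluster` core carries a loop of ``n_loop`` beads that
    arcs ``bulge`` Å out from the surface between two anchor beads,
    mimicking a flexible solvent-exposed loop: anchored at both ends
    (no zero modes) but markedly more mobile than the core. Crosslinking
    the loop to the core — the coarse-grained analogue of an engineered
    disulfide — visibly lowers the structure's thermal-sensitivity slope,
    which is the signal the screening pipeline detects.
    """
    core = compact_cluster(n_core, spacing=spacing, seed=seed)
    pts = core.coords
    center = pts.mean(axis=0)
    surf = np.argsort(((pts - center) ** 2).sum(axis=1))[::-1]
    a_idx = int(surf[0])
    candidates = [
        int(i) for i in surf[1:15]
        if 7.0 < np.linalg.norm(pts[i] - pts[a_idx]) < 13.0
    ]
    if not candidates:
        raise ValueError("no suitable loop anchor pair on the core surface")
    b_idx = candidates[0]
    a, b = pts[a_idx], pts[b_idx]
    out = 0.5 * (a + b) - center
    out /= np.linalg.norm(out)
    perp = np.cross(out, (b - a) / np.linalg.norm(b - a))
    loop = []
    for s in range(1, n_loop + 1):
        f = s / (n_loop + 1)
        loop.append(
            a + f * (b - a)
            + out * bulge * np.sin(np.pi * f)
            + perp * 1.2 * np.sin(2 * np.pi * f)
        )
    pts_all = np.vstack([pts, loop])
    atoms = [
        Atom(serial=i + 1, name="CA", element="C", res_name="ALA",
             res_id=i + 1, chain="A", coords=p)
        for i, p in enumerate(pts_all)
    ]
    return Structure(atoms)


def suggest_crosslink(
    network: ElasticNetwork,
    min_distance: float = 2.0,
    max_distance: float = 12.0,
    temperature: float = 300.0,
) -> tuple[int, int]:
    """Bead pair whose crosslink damps fluctuations the most.

    A harmonic crosslink only restrains motion along its bond axis, so
    the most effective placement maximizes the equilibrium variance of
    the *relative* displacement of the pair projected on their connecting
    line, ``Var[(u_i − u_j)·ê]``, computed from the Hessian
    pseudo-inverse. Searches all pairs with separation inside
    [min_distance, max_distance] Å.
    """
    h = network.hessian()
    w, v = np.linalg.eigh(h)
    tol = max(w[-1], 1.0) * 1e-9
    nz = w > tol
    cov = network.kB * temperature * ((v[:, nz] / w[nz]) @ v[:, nz].T)
    pts = network.positions
    n = network.n_beads
    best_var, best_pair = -1.0, None
    for i in range(n):
        ci = cov[3 * i : 3 * i + 3, 3 * i : 3 * i + 3]
        for j in range(i + 1, n):
            d = pts[j] - pts[i]
            r = np.linalg.norm(d)
            if not (min_distance < r < max_distance):
                continue
            e = d / r
            cj = cov[3 * j : 3 * j + 3, 3 * j : 3 * j + 3]
            cij = cov[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]
            var = float(e @ (ci + cj - cij - cij.T) @ e)
            if var > best_var:
                best_var, best_pair = var, (i, j)
    if best_pair is None:
        raise ValueError("no bead pair inside the distance window")
    return best_pair


def build_network(
    structure: Structure, cutoff: float = 8.0, k: float = 1.0
) -> ElasticNetwork:
    """Cα elastic network: springs between all Cα pairs within ``cutoff`` Å.

    Spring rest lengths are the current distances, so the reference
    structure is the energy minimum. Raises
    :class:`DisconnectedNetworkError` naming the components when the
    cutoff leaves the graph disconnected.
    """
    ca_idx = select(structure, "name CA")
    if len(ca_idx) < 3:
        raise ValueError("need at least 3 CA atoms to build a network")
    pos = structure.coords[ca_idx]
    n = len(pos)
    springs = []
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(pos[j] - pos[i]))
            if r <= cutoff:
                springs.append(Spring(i, j, k, r))
                g.add_edge(i, j)
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise DisconnectedNetworkError(
            f"network disconnected at cutoff {cutoff} Å: components {comps}"
        )
    return ElasticNetwork(pos, springs)


@dataclass(frozen=True)
class SimSpec:
    """Simulation protocol: one trajectory per temperature, shared length."""

    temperatures: tuple[float, ...] = (273.0, 300.0, 340.0)
    n_steps: int = 20000
    dt: float = 0.05
    seed: int = 0
    save_stride: int = 10

    def __post_init__(self):
        temps = tuple(self.temperatures)
        object.__setattr__(self, "temperatures", temps)
        if len(temps) < 2 or any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly increasing, >= 2 values")
        if self.n_steps < 1 or self.dt <= 0 or self.save_stride < 1:
            raise ValueError("n_steps, dt, save_stride must be positive")


def simulate_single(
    network: ElasticNetwork,
    temperature: float,
    n_steps: int,
    dt: float,
    seed,
    save_stride: int = 10,
) -> Trajectory:
    """Overdamped Langevin (Euler–Maruyama) run at one temperature.

    Integrates ``dx = −(dt/γ) H (x − x0) + √(2 kB T dt/γ) P ξ`` from the
    reference positions, where ``P`` projects the noise onto the internal
    (non-rigid) subspace: exciting the *linearized* rigid-body null modes
    would deform the structure along straight lines in configuration
    space (a linearized rotation is not a rotation at finite amplitude),
    so they are excluded and frames fluctuate about the reference. Frames
    are saved every ``save_stride`` steps. Deterministic for a given
    ``seed`` (an int or seed sequence).
    """
    h = network.hessian()
    gamma = network.friction
    w, v = np.linalg.eigh(h)
    tol = max(w[-1], 1.0) * 1e-9
    null_basis = v[:, w < tol]  # rigid-body (and tether-free) zero modes
    lam_max = float(w[-1])
    if lam_max > 0 and dt >= gamma / lam_max:
        raise UnstableTimestepError(
            f"dt={dt} too large: need dt < friction/lambda_max = {gamma / lam_max:.4g}"
        )
    rng = np.random.default_rng(seed)
    x0 = network.positions.ravel().copy()
    x = x0.copy()
    sigma = np.sqrt(2.0 * network.kB * max(temperature, 0.0) * dt / gamma)
    frames = []
    for step in range(1, n_steps + 1):
        x = x - (dt / gamma) * (h @ (x - x0))
        if sigma > 0:
            xi = rng.standard_normal(x.shape)
            if null_basis.shape[1]:
                xi = xi - null_basis @ (null_basis.T @ xi)
            x = x + sigma * xi
        if step % save_stride == 0:
            if np.max(np.abs(x)) > 1e6:
                raise UnstableTimestepError(
                    "coordinates diverged (>1e6 Å); reduce dt"
                )
            frames.append(x.reshape(-1, 3).copy())
    if not frames:
        frames.append(x.reshape(-1, 3).copy())
    return Trajectory(
        np.array(frames), network.to_structure(), temperature=temperature,
        frame_spacing=dt * save_stride,
    )


def simulate(network: ElasticNetwork, spec: SimSpec) -> dict[float, Trajectory]:
    """Run one trajectory per temperature in ``spec``; keyed by temperature.

    Each temperature gets an independent, reproducible random stream
    derived from ``spec.seed``.
    """
    out = {}
    for idx, t in enumerate(spec.temperatures):
        out[t] = simulate_single(
            network, t, spec.n_steps, spec.dt, seed=[spec.seed, idx],
            save_stride=spec.save_stride,
        )
    return out
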