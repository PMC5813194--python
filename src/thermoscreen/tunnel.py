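"""Grid-based substrate-tunnel bottleneck detection.

A clearance grid stores, per voxel, the distance from the voxel center to
the nearest atom *surface* (center distance minus vdW radius), capped at
``max_probe`` so oversized surface pockets do not dominate. The widest
access path from a buried start point (e.g. the flavin N5 atom) to bulk
solvent — defined as the boundary of the padded box — is the maximin path
over 6-connected voxels, found with a bottleneck variant of Dijkstra's
algorithm. The path's minimum clearance is the bottleneck radius; over a
trajectory the per-frame bottlenecks are summarized as mean ± SD.

This is a deliberately simplified single-tunnel method: no Voronoi
machinery, no tunnel clustering, no curvature/throughput metrics.
"""

from __future__ import annotations

import heapq
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure import Structure, Trajectory, select

__all__ = [
    "TunnelConfig",
    "ClearanceGrid",
    "TunnelResult",
    "build_clearance_grid",
    "widest_path",
    "bottleneck_structure",
    "bottleneck_trajectory",
]

logger = logging.getLogger(__name__)

_NEIGHBORS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass(frozen=True)
class TunnelConfig:
    """Grid resolution and probe parameters (all Å)."""

    spacing: float = 0.5
    padding: float = 5.0
    max_probe: float = 4.0
    probe_radius: float = 1.4  # reporting floor; paths below it are flagged

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.padding < 0 or self.max_probe <= 0 or self.probe_radius < 0:
            raise ValueError("padding/max_probe/probe_radius out of range")


@dataclass
class ClearanceGrid:
    origin: np.ndarray  # Å, center of voxel (0,0,0)
    spacing: float
    dims: tuple[int, int, int]
    clearance: np.ndarray  # (nx, ny, nz), Å; negative inside atoms

    def voxel_center(self, ijk) -> np.ndarray:
        return self.origin + np.asarray(ijk, float) * self.spacing

    def index_of(self, point) -> tuple[int, int, int]:
        ijk = np.rint((np.asarray(point, float) - self.origin) / self.spacing).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= self.dims):
            raise ValueError(f"point {point} outside grid")
        return tuple(int(v) for v in ijk)

    def boundary_voxels(self) -> np.ndarray:
        """Flat indices of all voxels on the box faces (the bulk exits)."""
        nx, ny, nz = self.dims
        mask = np.zeros(self.dims, bool)
        mask[0, :, :] = mask[-1, :, :] = True
        mask[:, 0, :] = mask[:, -1, :] = True
        mask[:, :, 0] = mask[:, :, -1] = True
        return np.flatnonzero(mask)


@dataclass
class TunnelResult:
    start_atom: int | None
    bottleneck_radius: float
    path: list[tuple[int, int, int]]
    per_frame_radii: list[float] = field(default_factory=list)
    mean_radius: float = float("nan")
    sd_radius: float = float("nan")
    passes_probe: bool = True
    skipped_frames: list[int] = field(default_factory=list)


def _clearance_field(
    coords: np.ndarray, radii: np.ndarray, config: TunnelConfig
) -> ClearanceGrid:
    lo = coords.min(axis=0) - config.padding
    hi = coords.max(axis=0) + config.padding
    dims = tuple(int(np.ceil((hi[i] - lo[i]) / config.spacing)) + 1 for i in range(3))
    axes = [lo[i] + config.spacing * np.arange(dims[i]) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    clearance = np.empty(len(centers))
    chunk = max(1, int(2e7 // max(len(coords), 1)))
    for start in range(0, len(centers), chunk):
        block = centers[start : start + chunk]
        d = cdist(block, coords) - radii[None, :]
        clearance[start : start + chunk] = d.min(axis=1)
    clearance = np.minimum(clearance, config.max_probe)
    return ClearanceGrid(lo, config.spacing, dims, clearance.reshape(dims))


def build_clearance_grid(
    structure: Structure, spacing: float = 0.5, padding: float = 5.0,
    max_probe: float = 4.0,
) -> ClearanceGrid:
    """Exact clearance grid over the structure's padded bounding box.

    Every voxel's value equals the brute-force minimum over all atoms of
    (center distance − vdW radius), capped at ``max_probe``.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    cfg = TunnelConfig(spacing=spacing, padding=padding, max_probe=max_probe)
    return _clearance_field(structure.coords, structure.vdw_radii, cfg)


def widest_path(
    grid: ClearanceGrid,
    start: tuple[int, int, int],
    exits: np.ndarray | set | None = None,
) -> tuple[list[tuple[int, int, int]], float]:
    """Maximin (widest) 6-connected path from ``start`` to any exit voxel.

    Maximizes the minimum clearance along the path (bottleneck Dijkstra;
    deterministic lexicographic tie-break on the flat voxel index).
    Voxels with clearance ≤ 0 are impassable. Returns ``([], 0.0)`` when
    no positive-clearance path exists.
    """
    clearance = grid.clearance.ravel()
    dims = grid.dims
    start_flat = int(np.ravel_multi_index(start, dims))
    if clearance[start_flat] <= 0:
        raise ValueError("start voxel has non-positive clearance (buried)")
    exit_set = (
        set(int(i) for i in grid.boundary_voxels()) if exits is None else set(int(i) for i in exits)
    )
    if not exit_set:
        raise ValueError("exit set is empty")

    nx, ny, nz = dims
    syz = ny * nz
    clr = clearance.tolist()  # python floats: faster scalar access
    best = np.full(clearance.shape, -np.inf)
    best[start_flat] = clearance[start_flat]
    parent: dict[int, int] = {}
    heap = [(-best[start_flat], start_flat)]
    target = None
    while heap:
        neg, flat = heapq.heappop(heap)
        width = -neg
        if width < best[flat]:
            continue
        if flat in exit_set:
            target = flat
            break
        i, rem = divmod(flat, syz)
        j, k = divmod(rem, nz)
        for nflat, ok in (
            (flat - syz, i > 0),
            (flat + syz, i < nx - 1),
            (flat - nz, j > 0),
            (flat + nz, j < ny - 1),
            (flat - 1, k > 0),
            (flat + 1, k < nz - 1),
        ):
            if not ok:
                continue
            c = clr[nflat]
            if c <= 0:
                continue
            cand = width if width < c else c
            if cand > best[nflat]:
                best[nflat] = cand
                parent[nflat] = flat
                heapq.heappush(heap, (-cand, nflat))
    if target is None:
        return [], 0.0
    path = [target]
    while path[-1] != start_flat:
        path.append(parent[path[-1]])
    path.reverse()
    return [tuple(int(v) for v in np.unravel_index(p, dims)) for p in path], float(best[target])


def _free_start_voxel(
    grid: ClearanceGrid, point: np.ndarray, search_radius: float = 3.0
) -> tuple[int, int, int]:
    """Voxel for the start point; if buried, hop to the highest-clearance
    voxel within ``search_radius`` Å (the usual start-point optimization
    of tunnel software). Raises when no free voxel exists nearby."""
    ijk = grid.index_of(point)
    if grid.clearance[ijk] > 0:
        return ijk
    r = int(np.ceil(search_radius / grid.spacing))
    lo = [max(0, ijk[d] - r) for d in range(3)]
    hi = [min(grid.dims[d], ijk[d] + r + 1) for d in range(3)]
    window = grid.clearance[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    if window.max() <= 0:
        raise ValueError("start point buried and no free voxel within search radius")
    local = np.unravel_index(int(np.argmax(window)), window.shape)
    new = tuple(int(lo[d] + local[d]) for d in range(3))
    logger.info("start voxel %s buried; moved to %s", ijk, new)
    return new


def bottleneck_structure(
    structure: Structure, start_selector: str, config: TunnelConfig = TunnelConfig()
) -> TunnelResult:
    """Widest tunnel from one start atom of a single structure to bulk."""
    idx = select(structure, start_selector)
    if len(idx) != 1:
        raise ValueError(
            f"start selector {start_selector!r} matched {len(idx)} atoms (need exactly 1)"
        )
    atom = int(idx[0])
    keep = np.arange(len(structure)) != atom  # the start atom is not an obstacle
    grid = _clearance_field(structure.coords[keep], structure.vdw_radii[keep], config)
    start = _free_start_voxel(grid, structure.atoms[atom].coords)
    path, bneck = widest_path(grid, start)
    return TunnelResult(
        start_atom=int(idx[0]),
        bottleneck_radius=bneck,
        path=path,
        per_frame_radii=[bneck],
        mean_radius=bneck,
        sd_radius=0.0,
        passes_probe=bneck >= config.probe_radius,
    )


def bottleneck_trajectory(
    traj: Trajectory, start_selector: str, config: TunnelConfig = TunnelConfig()
) -> TunnelResult:
    """Per-frame widest-tunnel bottleneck over a trajectory, mean ± SD.

    Frames where the start atom is buried (non-positive clearance) are
    skipped with a log message, not fatal. The reported path is the one
    from the first usable frame; ``mean_radius``/``sd_radius`` summarize
    the per-frame bottlenecks (sample SD, 0 for a single frame).
    """
    idx = select(traj.topology, start_selector)
    if len(idx) != 1:
        raise ValueError(
            f"start selector {start_selector!r} matched {len(idx)} atoms (need exactly 1)"
        )
    atom = int(idx[0])
    keep = np.arange(traj.n_atoms) != atom
    radii = traj.topology.vdw_radii[keep]
    radii_list: list[float] = []
    first_path: list[tuple[int, int, int]] = []
    skipped: list[int] = []
    for f in range(traj.n_frames):
        coords = traj.coords[f]
        grid = _clearance_field(coords[keep], radii, config)
        try:
            start = _free_start_voxel(grid, coords[atom])
            path, bneck = widest_path(grid, start)
        except ValueError as exc:
            logger.warning("frame %d skipped: %s", f, exc)
            skipped.append(f)
            continue
        if not first_path:
            first_path = path
        radii_list.append(bneck)
    if not radii_list:
        return TunnelResult(
            start_atom=atom, bottleneck_radius=0.0, path=[], per_frame_radii=[],
            mean_radius=float("nan"), sd_radius=float("nan"),
            passes_probe=False, skipped_frames=skipped,
        )
    mean = float(np.mean(radii_list))
    sd = float(np.std(radii_list, ddof=1)) if len(radii_list) > 1 else 0.0
    return TunnelResult(
        start_atom=atom,
        bottleneck_radius=mean,
        path=first_path,
        per_frame_radii=radii_list,
        mean_radius=mean,
        sd_radius=sd,
        passes_probe=mean >= config.probe_radius,
        skipped_frames=skipped,
    )


def result_to_json(result: TunnelResult, path) -> None:
    payload = {
        "start_atom": result.start_atom,
        "bottleneck_radius_A": result.bottleneck_radius,
        "mean_radius_A": result.mean_radius,
        "sd_radius_A": result.sd_radius,
        "per_frame_radii_A": result.per_frame_radii,
        "passes_probe": result.passes_probe,
        "skipped_frames": result.skipped_frames,
        "path_voxels": [list(p) for p in result.path],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
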