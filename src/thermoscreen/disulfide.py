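"""Geometric disulfide-bond design scan.

Enumerates residue pairs that, once mutated to cysteine, could form a
low-strain S–S bond. For every pair whose (real or idealized) Cβ atoms are
close enough, Sγ positions are scanned on a χ1 grid for both residues and
scored with a harmonic strain energy about ideal disulfide geometry
(S–S 2.02 Å, Cβ–Sγ–Sγ′ 104.15°, χss ±87°, χ1 rotamers at −60/60/180°).
Candidates above the energy cutoff, or closer than the exclusion radius to
a protected site (typically the FAD cofactor and the substrate pocket), are
dropped; the survivors are ranked by ascending strain energy.

χ2-type terms are deliberately omitted from the default functional; the
dihedral grid already fixes Sγ placement given χ1 and the remaining
freedom is absorbed by the scored terms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .geometry import place_atom, wrap_angle
from .structure import Residue, Structure

__all__ = [
    "ScanConfig",
    "DisulfideCandidate",
    "build_cbeta",
    "strain_energy",
    "model_disulfide",
    "scan",
    "candidates_to_tsv",
    "candidates_to_json",
]

logger = logging.getLogger(__name__)

# Ideal disulfide internal coordinates (Å / degrees)
SS_BOND = 2.02
CB_SG_BOND = 1.81
CA_CB_SG_ANGLE = 114.0
CB_SG_SG_ANGLE = 104.15
CHI_SS_IDEAL = 87.0
CHI1_ROTAMERS = (-60.0, 60.0, 180.0)
CA_CB_BOND = 1.53
# Cβ construction internal coordinates (L-amino-acid chirality); the
# torsion is dihedral(C, N, CA, CB) matching this module's conventions.
N_CA_CB_ANGLE = 110.4
C_N_CA_CB_TORSION = 57.6


@dataclass(frozen=True)
class ScanConfig:
    """Knobs of the disulfide scan.

    ``energy_cutoff`` (kcal/mol) and ``site_exclusion_radius`` (Å) are the
    two published screening thresholds; the remaining fields bound the
    pair enumeration and define the harmonic force constants.
    """

    energy_cutoff: float = 10.0
    site_exclusion_radius: float = 10.0
    cb_cb_max: float = 5.0
    min_sequence_separation: int = 3
    chi1_step: float = 10.0
    k_distance: float = 100.0  # kcal/mol/Å²
    k_angle: float = 0.02  # kcal/mol/deg²
    k_dihedral: float = 0.005  # kcal/mol/deg²

    def __post_init__(self):
        for name in (
            "energy_cutoff",
            "site_exclusion_radius",
            "cb_cb_max",
            "chi1_step",
            "k_distance",
            "k_angle",
            "k_dihedral",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_sequence_separation < 1:
            raise ValueError("min_sequence_separation must be >= 1")
        if abs(360.0 / self.chi1_step - round(360.0 / self.chi1_step)) > 1e-9:
            raise ValueError("chi1_step must divide 360")


@dataclass
class DisulfideCandidate:
    res_i: tuple[str, int, str]
    res_j: tuple[str, int, str]
    chi1_i: float
    chi1_j: float
    chi_ss: float
    ss_distance: float
    cb_distance: float
    strain_energy: float
    min_site_distance: float = float("inf")

    def __post_init__(self):
        if self.ss_distance <= 0:
            raise ValueError("ss_distance must be positive")
        if self.strain_energy < 0:
            raise ValueError("strain_energy must be non-negative")
        if abs(self.chi_ss) > 180.0 + 1e-9:
            raise ValueError("chi_ss out of range")


def build_cbeta(residue: Residue) -> np.ndarray:
    """Return the residue's Cβ position, constructing an ideal one if absent.

    Glycines (and any residue stripped to its backbone) get a Cβ built from
    N/CA/C with tetrahedral L-amino-acid geometry, CA–CB = 1.53 Å.
    """
    cb = residue.atom("CB")
    if cb is not None:
        return cb.coords.copy()
    n, ca, c = (residue.atom(x) for x in ("N", "CA", "C"))
    if n is None or ca is None or c is None:
        raise ValueError(
            f"residue {residue.chain}/{residue.res_id} lacks backbone atoms"
        )
    return place_atom(c.coords, n.coords, ca.coords, CA_CB_BOND, N_CA_CB_ANGLE, C_N_CA_CB_TORSION)


def strain_energy(
    ss_distance: float,
    angle_i: float,
    angle_j: float,
    chi_ss: float,
    chi1_i: float,
    chi1_j: float,
    config: ScanConfig = ScanConfig(),
):
    """Harmonic strain energy (kcal/mol) of a modeled disulfide.

    Zero at ideal geometry; each term grows quadratically with deviation
    from its ideal value. ``chi_ss`` is penalized about the nearer of
    ±87°; each χ1 about the nearest of the three staggered rotamers.
    Accepts scalars or broadcastable arrays.
    """
    ss_distance = np.asarray(ss_distance, float)
    e = config.k_distance * (ss_distance - SS_BOND) ** 2
    e = e + config.k_angle * (
        (np.asarray(angle_i, float) - CB_SG_SG_ANGLE) ** 2
        + (np.asarray(angle_j, float) - CB_SG_SG_ANGLE) ** 2
    )
    dss = np.minimum(
        np.abs(wrap_angle(np.asarray(chi_ss, float) - CHI_SS_IDEAL)),
        np.abs(wrap_angle(np.asarray(chi_ss, float) + CHI_SS_IDEAL)),
    )
    e = e + config.k_dihedral * dss**2
    for chi1 in (chi1_i, chi1_j):
        d = np.min(
            np.abs(wrap_angle(np.asarray(chi1, float)[..., None] - np.array(CHI1_ROTAMERS))),
            axis=-1,
        )
        e = e + config.k_dihedral * d**2
    return e if e.ndim else float(e)


def _sg_positions(residue: Residue, cb: np.ndarray, chi1_grid: np.ndarray) -> np.ndarray:
    """Sγ position for every χ1 on the grid (χ1 = dihedral N–CA–CB–Sγ)."""
    n = residue.atom("N").coords
    ca = residue.atom("CA").coords
    return np.array(
        [place_atom(n, ca, cb, CB_SG_BOND, CA_CB_SG_ANGLE, chi) for chi in chi1_grid]
    )


def _pair_geometry(cb_i, sg_i, cb_j, sg_j):
    """Vectorized (len_i, len_j) geometry of all Sγ placements of a pair."""
    diff = sg_i[:, None, :] - sg_j[None, :, :]
    dss = np.linalg.norm(diff, axis=-1)

    def _angles(cb, sg, other_sg, axis):
        v1 = cb - sg  # (n, 3)
        v1n = v1 / np.linalg.norm(v1, axis=-1, keepdims=True)
        v2 = other_sg[None, :, :] - sg[:, None, :] if axis == 0 else other_sg[:, None, :] - sg[None, :, :]
        v2n = v2 / np.linalg.norm(v2, axis=-1, keepdims=True)
        if axis == 0:
            cosang = np.einsum("ik,ijk->ij", v1n, v2n)
        else:
            cosang = np.einsum("jk,ijk->ij", v1n, v2n)
        return np.degrees(np.arccos(np.clip(cosang, -1, 1)))

    ang_i = _angles(cb_i, sg_i, sg_j, axis=0)
    ang_j = _angles(cb_j, sg_j, sg_i, axis=1)

    # dihedral CBi–SGi–SGj–CBj, vectorized over the grid pair
    b0 = sg_i - cb_i  # (ni, 3)
    b1 = -diff  # sg_j - sg_i, (ni, nj, 3)
    b2 = cb_j - sg_j  # (nj, 3)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0[:, None, :] - np.einsum("ik,ijk->ij", b0, b1n)[..., None] * b1n
    w = b2[None, :, :] - np.einsum("jk,ijk->ij", b2, b1n)[..., None] * b1n
    x = np.einsum("ijk,ijk->ij", v, w)
    y = np.einsum("ijk,ijk->ij", np.cross(b1n, v), w)
    chi_ss = np.degrees(np.arctan2(y, x))
    return dss, ang_i, ang_j, chi_ss


def model_disulfide(
    res_i: Residue, res_j: Residue, config: ScanConfig = ScanConfig()
) -> DisulfideCandidate | None:
    """Scan χ1 × χ1 for the lowest-strain disulfide between two residues.

    Returns ``None`` when the pair fails the Cβ-distance or sequence
    separation preconditions, lacks backbone atoms, or when the optimum
    exceeds the energy cutoff. Tie-break on the grid is first-encountered
    (row-major, res_i's χ1 outer), which is deterministic.
    """
    if (res_i.chain, res_i.res_id) > (res_j.chain, res_j.res_id):
        res_i, res_j = res_j, res_i
    try:
        cb_i = build_cbeta(res_i)
        cb_j = build_cbeta(res_j)
    except ValueError as exc:
        logger.info("skipping pair %s/%s: %s", res_i.res_id, res_j.res_id, exc)
        return None
    cb_dist = float(np.linalg.norm(cb_i - cb_j))
    if cb_dist > config.cb_cb_max:
        return None
    if (
        res_i.chain == res_j.chain
        and abs(res_i.res_id - res_j.res_id) < config.min_sequence_separation
    ):
        return None

    grid = np.arange(-180.0, 180.0, config.chi1_step)
    sg_i = _sg_positions(res_i, cb_i, grid)
    sg_j = _sg_positions(res_j, cb_j, grid)
    dss, ang_i, ang_j, chi_ss = _pair_geometry(cb_i, sg_i, cb_j, sg_j)
    energies = strain_energy(
        dss, ang_i, ang_j, chi_ss, grid[:, None], grid[None, :], config
    )
    flat = int(np.argmin(energies))
    i, j = np.unravel_index(flat, energies.shape)
    e_min = float(energies[i, j])
    if e_min > config.energy_cutoff:
        return None
    return DisulfideCandidate(
        res_i=res_i.key,
        res_j=res_j.key,
        chi1_i=float(grid[i]),
        chi1_j=float(grid[j]),
        chi_ss=float(chi_ss[i, j]),
        ss_distance=float(dss[i, j]),
        cb_distance=cb_dist,
        strain_energy=e_min,
        min_site_distance=float("inf"),
    )


def scan(
    structure: Structure,
    site_atoms: np.ndarray | list[int] | None = None,
    config: ScanConfig = ScanConfig(),
) -> list[DisulfideCandidate]:
    """Full pairwise disulfide scan of a structure.

    ``site_atoms`` are atom indices of the protected site (cofactor,
    substrate pocket); candidates any of whose residue atoms approach the
    site closer than ``config.site_exclusion_radius`` are removed. Returned
    list is sorted by (strain energy, chain/res_id of both partners).
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    residues = [r for r in structure.residues if r.has_backbone()]
    if not residues:
        raise ValueError("structure has no residues with complete backbone")

    cbetas = []
    usable = []
    for r in residues:
        try:
            cbetas.append(build_cbeta(r))
            usable.append(r)
        except ValueError as exc:
            logger.info("residue %s/%s skipped: %s", r.chain, r.res_id, exc)
    cbetas = np.array(cbetas)
    tree = cKDTree(cbetas)
    pairs = sorted(tree.query_pairs(config.cb_cb_max))

    site_coords = None
    if site_atoms is not None and len(site_atoms) > 0:
        all_coords = structure.coords
        site_coords = all_coords[np.asarray(site_atoms, int)]

    out: list[DisulfideCandidate] = []
    for a, b in pairs:
        ri, rj = usable[a], usable[b]
        if (ri.chain, ri.res_id) > (rj.chain, rj.res_id):
            ri, rj = rj, ri
        cand = model_disulfide(ri, rj, config)
        if cand is None:
            continue
        if site_coords is not None:
            res_coords = np.vstack([ri.coords, rj.coords])
            cand.min_site_distance = float(cdist(res_coords, site_coords).min())
            if cand.min_site_distance <= config.site_exclusion_radius:
                continue
        out.append(cand)
    out.sort(key=lambda c: (c.strain_energy, c.res_i[0], c.res_i[1], c.res_j[0], c.res_j[1]))
    return out


_TSV_COLUMNS = [
    "rank", "chain_i", "resid_i", "resname_i", "chain_j", "resid_j", "resname_j",
    "ss_distance", "chi1_i", "chi1_j", "chi_ss", "energy_kcal_mol", "min_site_distance",
]


def candidates_to_rows(candidates: list[DisulfideCandidate]) -> list[dict]:
    rows = []
    for rank, c in enumerate(candidates, start=1):
        rows.append(
            {
                "rank": rank,
                "chain_i": c.res_i[0], "resid_i": c.res_i[1], "resname_i": c.res_i[2],
                "chain_j": c.res_j[0], "resid_j": c.res_j[1], "resname_j": c.res_j[2],
                "ss_distance": round(c.ss_distance, 3),
                "chi1_i": round(c.chi1_i, 1),
                "chi1_j": round(c.chi1_j, 1),
                "chi_ss": round(c.chi_ss, 1),
                "energy_kcal_mol": round(c.strain_energy, 3),
                "min_site_distance": (
                    round(c.min_site_distance, 2) if np.isfinite(c.min_site_distance) else None
                ),
            }
        )
    return rows


def candidates_to_tsv(candidates: list[DisulfideCandidate], path: str | Path) -> None:
    rows = candidates_to_rows(candidates)
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in _TSV_COLUMNS) + "\n")


def candidates_to_json(candidates: list[DisulfideCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(candidates_to_rows(candidates), fh, indent=2)
        fh.write("\n")
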