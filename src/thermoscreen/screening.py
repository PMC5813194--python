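"""Thermal-sensitivity screening of trajectory ensembles.

The screening statistic: per-residue RMSF is computed for each trajectory
(after discarding an equilibration fraction and removing rigid-body motion
by Kabsch superposition onto an iterated mean structure), averaged over a
trimmed residue range (avg-RMSF), and regressed against simulation
temperature. The slope λ (Å/K) measures how steeply a variant's
flexibility grows with temperature; a variant whose λ exceeds the
reference (wild type) is rejected, a poor linear fit (low R²) is rejected
for fit quality, anything else is selected for experimental follow-up.
Slope differences are tested with the classical two-regression
equality-of-slopes t-test (pooled residual variance, df = n₁ + n₂ − 4).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.transform import Rotation

from .structure import Trajectory, select

__all__ = [
    "ScreenConfig",
    "RmsfProfile",
    "LambdaFit",
    "ScreeningResult",
    "kabsch_superpose",
    "rmsf",
    "avg_rmsf",
    "fit_lambda",
    "compare_slopes",
    "screen",
    "results_to_dataframe",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Screening parameters.

    ``residue_trim`` is the inclusive (lo, hi) residue-id window kept for
    avg-RMSF (``None`` = all residues); ``discard_fraction`` drops the
    initial equilibration part of each trajectory; ``n_blocks`` is how
    many contiguous blocks a single per-temperature trajectory is split
    into, each contributing one regression point (gives the slope test
    its degrees of freedom); ``r2_threshold`` is the fit-quality floor
    below which a variant is rejected regardless of λ.
    """

    residue_trim: tuple[int, int] | None = None
    discard_fraction: float = 0.2
    n_blocks: int = 3
    r2_threshold: float = 0.80
    alpha: float = 0.05
    superpose: bool = True
    atom_selector: str = "name CA"

    def __post_init__(self):
        if not 0.0 <= self.discard_fraction < 1.0:
            raise ValueError("discard_fraction must be in [0, 1)")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")


@dataclass
class RmsfProfile:
    """Per-residue RMSF of one trajectory at one temperature."""

    res_ids: np.ndarray
    rmsf: np.ndarray
    temperature: float | None = None
    variant_id: str | None = None
    atom_subset: np.ndarray | None = None
    discard_fraction: float = 0.0

    def __post_init__(self):
        self.res_ids = np.asarray(self.res_ids, int)
        self.rmsf = np.asarray(self.rmsf, float)
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF values must be non-negative")
        if len(self.res_ids) != len(self.rmsf):
            raise ValueError("res_ids and rmsf length mismatch")


@dataclass
class LambdaFit:
    """OLS fit of avg-RMSF against temperature."""

    slope: float  # λ, Å/K
    intercept: float  # Å
    r_squared: float
    temps: np.ndarray
    values: np.ndarray
    degenerate: bool = False  # R² undefined (flat response), reported as 0

    @property
    def n(self) -> int:
        return len(self.temps)

    @property
    def residual_ss(self) -> float:
        pred = self.intercept + self.slope * self.temps
        return float(np.sum((self.values - pred) ** 2))

    @property
    def sxx(self) -> float:
        return float(np.sum((self.temps - self.temps.mean()) ** 2))


@dataclass
class ScreeningResult:
    variant_id: str
    temps: list[float]
    avg_rmsf: list[float]  # per-temperature means, Å
    lam: float
    intercept: float
    r_squared: float
    p_vs_ref: float
    significant: bool
    decision: str  # selected | rejected_slope | rejected_fit
    mutated_residues: str = ""


def kabsch_superpose(
    traj: Trajectory, reference: np.ndarray, atom_subset: np.ndarray | None = None
) -> Trajectory:
    """Least-squares superpose every frame onto ``reference``.

    The optimal proper rotation is computed over ``atom_subset`` (all
    atoms when ``None``) and applied to the whole frame. ``reference``
    may be a full frame or just the subset coordinates.
    """
    subset = np.arange(traj.n_atoms) if atom_subset is None else np.asarray(atom_subset, int)
    if len(subset) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    ref = np.asarray(reference, float)
    ref_sub = ref[subset] if len(ref) == traj.n_atoms else ref
    if len(ref_sub) != len(subset):
        raise ValueError("reference size does not match atom subset")
    ref_centered = ref_sub - ref_sub.mean(axis=0)
    if np.linalg.matrix_rank(ref_centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) superposition subset")
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        sub = frame[subset]
        cm = sub.mean(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # align_vectors warns on exact fits
            rot, _ = Rotation.align_vectors(ref_centered, sub - cm)
        out[f] = (frame - cm) @ rot.as_matrix().T + ref_sub.mean(axis=0)
    return Trajectory(out, traj.topology, traj.temperature, traj.frame_spacing)


def rmsf(
    traj: Trajectory,
    atom_subset: np.ndarray | None = None,
    discard_fraction: float = 0.2,
    superpose: bool = True,
    variant_id: str | None = None,
) -> RmsfProfile:
    """Per-atom RMSF over the retained part of a trajectory.

    The first ``discard_fraction`` of frames is dropped; the remainder is
    superposed onto an iterated mean structure (two passes: align to the
    first retained frame, re-align to the resulting mean), and
    ``RMSF_i = sqrt(mean_f |x_fi − <x_i>|²)`` is reported per subset atom.
    """
    subset = np.arange(traj.n_atoms) if atom_subset is None else np.asarray(atom_subset, int)
    n_discard = int(np.floor(discard_fraction * traj.n_frames))
    kept = traj.coords[n_discard:]
    if len(kept) < 2:
        raise ValueError("fewer than 2 frames remain after discard")
    work = Trajectory(kept, traj.topology, traj.temperature)
    if superpose:
        reference = kept[0]
        for _ in range(2):
            work = kabsch_superpose(work, reference, subset)
            reference = work.coords.mean(axis=0)
    sub_coords = work.coords[:, subset, :]
    mean = sub_coords.mean(axis=0)
    msf = ((sub_coords - mean) ** 2).sum(axis=2).mean(axis=0)
    res_ids = np.array([traj.topology.atoms[i].res_id for i in subset])
    return RmsfProfile(
        res_ids=res_ids,
        rmsf=np.sqrt(msf),
        temperature=traj.temperature,
        variant_id=variant_id,
        atom_subset=subset,
        discard_fraction=discard_fraction,
    )


def avg_rmsf(profile: RmsfProfile, residue_trim: tuple[int, int] | None = None) -> float:
    """Mean RMSF over the (inclusive) trimmed residue-id range."""
    mask = np.ones(len(profile.res_ids), bool)
    if residue_trim is not None:
        lo, hi = residue_trim
        mask = (profile.res_ids >= lo) & (profile.res_ids <= hi)
        if not mask.any():
            raise ValueError(f"residue trim {residue_trim} excludes every residue")
    return float(profile.rmsf[mask].mean())


def fit_lambda(temps, avg_rmsfs) -> LambdaFit:
    """Ordinary least squares of avg-RMSF on temperature.

    R² is the squared Pearson correlation; a perfectly flat response has
    undefined R², reported as 0 with ``degenerate=True``.
    """
    x = np.asarray(temps, float)
    y = np.asarray(avg_rmsfs, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 (temperature, avg-RMSF) points")
    if np.ptp(x) == 0:
        raise ValueError("all temperatures identical; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    if np.ptp(y) == 0:
        return LambdaFit(0.0, float(y[0]), 0.0, x, y, degenerate=True)
    r = np.corrcoef(x, y)[0, 1]
    return LambdaFit(float(slope), float(intercept), float(r**2), x, y)


def compare_slopes(fit_a: LambdaFit, fit_b: LambdaFit) -> float:
    """Two-sided t-test for equality of two regression slopes.

    Pooled residual variance, df = n₁ + n₂ − 4. Degenerate cases: zero
    pooled variance with equal slopes → p = 1 (identical lines); with
    unequal slopes → p = 0 (with a warning).
    """
    if fit_a.n < 3 or fit_b.n < 3:
        raise ValueError("slope comparison needs >= 3 points per fit")
    df = fit_a.n + fit_b.n - 4
    s2 = (fit_a.residual_ss + fit_b.residual_ss) / df
    se = np.sqrt(s2 * (1.0 / fit_a.sxx + 1.0 / fit_b.sxx))
    diff = fit_a.slope - fit_b.slope
    # residuals at machine-rounding level count as an exact fit
    y_scale = max(
        float(np.max(np.abs(fit_a.values)) or 1.0),
        float(np.max(np.abs(fit_b.values)) or 1.0),
    )
    if se <= 1e-12 * y_scale:
        if diff == 0.0:
            return 1.0
        warnings.warn("zero residual variance with unequal slopes; p = 0")
        return 0.0
    t = diff / se
    return float(2.0 * stats.t.sf(abs(t), df))


def _variant_points(
    trajs, config: ScreenConfig, subset_cache: dict
) -> tuple[list[float], list[float]]:
    """Collect (temperature, avg-RMSF) regression points for one variant.

    Each temperature maps to a single Trajectory (split into
    ``config.n_blocks`` contiguous blocks after discard) or to an explicit
    list of replicate trajectories (one point each).
    """
    xs: list[float] = []
    ys: list[float] = []
    for t in sorted(trajs):
        entry = trajs[t]
        reps: list[Trajectory] = []
        if isinstance(entry, Trajectory):
            n_discard = int(np.floor(config.discard_fraction * entry.n_frames))
            kept = entry.coords[n_discard:]
            bounds = np.linspace(0, len(kept), config.n_blocks + 1).astype(int)
            for b in range(config.n_blocks):
                block = kept[bounds[b] : bounds[b + 1]]
                if len(block) < 2:
                    raise ValueError(
                        f"trajectory at {t} K too short for {config.n_blocks} blocks"
                    )
                reps.append(Trajectory(block, entry.topology, entry.temperature))
        else:
            reps = list(entry)
        for rep in reps:
            key = id(rep.topology)
            if key not in subset_cache:
                subset_cache[key] = select(rep.topology, config.atom_selector)
            prof = rmsf(
                rep,
                atom_subset=subset_cache[key],
                discard_fraction=0.0 if isinstance(entry, Trajectory) else config.discard_fraction,
                superpose=config.superpose,
            )
            xs.append(float(t))
            ys.append(avg_rmsf(prof, config.residue_trim))
    return xs, ys


def screen(
    variants: dict[str, dict[float, Trajectory | list[Trajectory]]],
    reference_id: str,
    config: ScreenConfig = ScreenConfig(),
    labels: dict[str, str] | None = None,
) -> list[ScreeningResult]:
    """Run the full λ-screen for a set of variants against a reference.

    ``variants`` maps variant id → {temperature: trajectory or replicate
    list}. Every variant must be simulated at the reference's temperature
    list. Returns one :class:`ScreeningResult` per variant (reference
    first, then sorted by id) with the accept/reject decision:
    ``rejected_fit`` when R² < threshold, ``rejected_slope`` when
    λ > λ_ref (strictly), else ``selected``.
    """
    if reference_id not in variants:
        raise ValueError(f"reference {reference_id!r} missing from variants")
    temp_sets = {vid: tuple(sorted(trajs)) for vid, trajs in variants.items()}
    ref_temps = temp_sets[reference_id]
    bad = [vid for vid, ts in temp_sets.items() if ts != ref_temps]
    if bad:
        raise ValueError(
            f"temperature lists differ from reference {ref_temps}: {sorted(bad)}"
        )

    subset_cache: dict = {}
    fits: dict[str, LambdaFit] = {}
    for vid in variants:
        xs, ys = _variant_points(variants[vid], config, subset_cache)
        fits[vid] = fit_lambda(xs, ys)

    ref_fit = fits[reference_id]
    order = [reference_id] + sorted(v for v in variants if v != reference_id)
    results = []
    for vid in order:
        fit = fits[vid]
        p = 1.0 if vid == reference_id else compare_slopes(fit, ref_fit)
        if fit.r_squared < config.r2_threshold:
            decision = "rejected_fit"
        elif fit.slope > ref_fit.slope:
            decision = "rejected_slope"
        else:
            decision = "selected"
        per_t = [
            float(np.mean([y for x, y in zip(fit.temps, fit.values) if x == t]))
            for t in ref_temps
        ]
        results.append(
            ScreeningResult(
                variant_id=vid,
                temps=list(ref_temps),
                avg_rmsf=per_t,
                lam=fit.slope,
                intercept=fit.intercept,
                r_squared=fit.r_squared,
                p_vs_ref=p,
                significant=p < config.alpha,
                decision=decision,
                mutated_residues=(labels or {}).get(vid, ""),
            )
        )
    return results


def results_to_dataframe(results: list[ScreeningResult]) -> pd.DataFrame:
    """Screening report in the published table shape."""
    return pd.DataFrame(
        {
            "variant": [r.variant_id for r in results],
            "mutated_residues": [r.mutated_residues for r in results],
            "lambda": [r.lam for r in results],
            "r_squared": [r.r_squared for r in results],
            "p_value": [r.p_vs_ref for r in results],
            "significant": [r.significant for r in results],
            "decision": [r.decision for r in results],
        }
    )


def results_to_json(results: list[ScreeningResult], path: str | Path) -> None:
    payload = [
        {
            "variant": r.variant_id,
            "mutated_residues": r.mutated_residues,
            "temps_K": r.temps,
            "avg_rmsf_A": r.avg_rmsf,
            "lambda_A_per_K": r.lam,
            "intercept_A": r.intercept,
            "r_squared": r.r_squared,
            "p_value": r.p_vs_ref,
            "significant": r.significant,
            "decision": r.decision,
        }
        for r in results
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
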