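"""Enzymatic assay curves: Michaelis–Menten kinetics and thermal inactivation.

Two models cover the experimental characterization of candidate enzymes:

* hyperbolic substrate kinetics, ``v = Vmax·S / (Km + S)``, fitted by
  nonlinear least squares with standard errors from the fit covariance;
  ``kcat = Vmax / [E]``;
* Boltzmann sigmoid thermal inactivation,
  ``A(T) = A_bottom + (A_top − A_bottom) / (1 + exp((T − T50)/s))``,
  whose midpoint T50 is the thermostability readout; ΔT50 against a
  reference fit carries the quadrature-propagated SE.

Temperatures are handled in °C end-to-end (as the inactivation curves are
reported); no Kelvin conversion. A seeded synthetic-data generator draws
replicate datasets from either model with multiplicative Gaussian noise,
emulating the published experimental designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "KineticsDataset",
    "KineticsFit",
    "ThermalDataset",
    "ThermalFit",
    "michaelis_menten",
    "boltzmann",
    "absorbance_to_rate",
    "fit_michaelis_menten",
    "fit_boltzmann",
    "normalize_residual_activity",
    "normalize_ph_profile",
    "delta_t50",
    "generate_synthetic_assay",
]

#: Default substrate design: levels spanning the published 0.05–2 mM range.
DEFAULT_SUBSTRATE_MM = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0)
#: Default thermal design: 25→100 °C in 5 °C steps.
DEFAULT_TEMPS_C = tuple(float(t) for t in range(25, 101, 5))


def michaelis_menten(s, vmax, km):
    """Hyperbolic rate law v = Vmax·S/(Km + S)."""
    s = np.asarray(s, float)
    return vmax * s / (km + s)


def boltzmann(t, a_top, a_bottom, t50, s):
    """Sigmoid inactivation A(T); A(T50) is midway between the asymptotes."""
    t = np.asarray(t, float)
    return a_bottom + (a_top - a_bottom) / (1.0 + np.exp((t - t50) / s))


@dataclass
class KineticsDataset:
    """Substrate-saturation measurements (possibly replicated)."""

    substrate_mM: np.ndarray
    rate: np.ndarray
    replicate: np.ndarray | None = None
    enzyme_conc_uM: float | None = None

    def __post_init__(self):
        self.substrate_mM = np.asarray(self.substrate_mM, float)
        self.rate = np.asarray(self.rate, float)
        if len(self.substrate_mM) != len(self.rate):
            raise ValueError("substrate and rate length mismatch")
        if np.any(self.substrate_mM <= 0):
            raise ValueError("substrate concentrations must be positive")
        if len(np.unique(self.substrate_mM)) < 4:
            raise ValueError("need >= 4 distinct substrate concentrations")
        if self.replicate is None:
            self.replicate = np.zeros(len(self.rate), int)


@dataclass
class KineticsFit:
    Km: float  # mM
    Km_se: float
    Vmax: float  # same units as the input rates
    Vmax_se: float
    kcat: float | None = None  # Vmax / [E], per input time unit
    kcat_se: float | None = None
    kcat_over_Km: float | None = None
    r_squared: float = float("nan")
    unidentifiable: bool = False


@dataclass
class ThermalDataset:
    """Residual activity (%) after 10-min incubation at each temperature."""

    temperature_C: np.ndarray
    residual_activity_pct: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self):
        self.temperature_C = np.asarray(self.temperature_C, float)
        self.residual_activity_pct = np.asarray(self.residual_activity_pct, float)
        if len(self.temperature_C) != len(self.residual_activity_pct):
            raise ValueError("temperature and activity length mismatch")
        if len(np.unique(self.temperature_C)) < 5:
            raise ValueError("need >= 5 distinct temperatures spanning the transition")
        if self.replicate is None:
            self.replicate = np.zeros(len(self.temperature_C), int)


@dataclass
class ThermalFit:
    T50: float  # °C
    T50_se: float
    s: float  # steepness, °C
    s_se: float
    A_top: float  # %
    A_bottom: float  # %
    r_squared: float = float("nan")
    extrapolated: bool = False
    no_inactivation: bool = False


@dataclass
class ActivityRate:
    """Beer–Lambert conversion of an absorbance slope."""

    conc_rate_uM_per_min: float
    units_U: float | None = None  # µmol product / min
    specific_activity_U_per_mg: float | None = None


def absorbance_to_rate(
    dA_dt_per_min: float,
    epsilon_M_cm: float,
    pathlength_cm: float = 1.0,
    volume_L: float | None = None,
    enzyme_mg: float | None = None,
) -> ActivityRate:
    """Convert an absorbance slope (1/min) into a product-formation rate.

    Concentration rate = (dA/dt)/(ε·l); with a reaction volume this
    becomes enzyme units U (µmol/min), and with the enzyme mass a
    specific activity (U/mg).
    """
    if epsilon_M_cm <= 0 or pathlength_cm <= 0:
        raise ValueError("epsilon and pathlength must be positive")
    rate_M_min = dA_dt_per_min / (epsilon_M_cm * pathlength_cm)
    rate_uM_min = rate_M_min * 1e6
    units = rate_M_min * volume_L * 1e6 if volume_L is not None else None
    spec = (
        units / enzyme_mg if (units is not None and enzyme_mg) else None
    )
    return ActivityRate(rate_uM_min, units, spec)


def rate_to_absorbance(
    rate_uM_per_min: float, epsilon_M_cm: float, pathlength_cm: float = 1.0
) -> float:
    """Inverse of :func:`absorbance_to_rate` (concentration part)."""
    return rate_uM_per_min * 1e-6 * epsilon_M_cm * pathlength_cm


def _r_squared(y, pred) -> float:
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def fit_michaelis_menten(data: KineticsDataset) -> KineticsFit:
    """Nonlinear least-squares Michaelis–Menten fit (pooled replicates).

    Initializers: Vmax ← max rate, Km ← substrate level nearest half-max.
    A Km estimate above 50× the largest substrate concentration is flagged
    unidentifiable (curve is effectively linear over the design).
    """
    s, v = data.substrate_mM, data.rate
    if np.any(v < 0):
        raise ValueError("rates must be non-negative")
    vmax0 = float(v.max())
    if vmax0 <= 0:
        raise ValueError("all rates are zero; nothing to fit")
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2))])
    try:
        popt, pcov = curve_fit(
            michaelis_menten, s, v, p0=[vmax0, km0],
            bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Michaelis-Menten fit failed to converge (p0: Vmax={vmax0:.4g}, "
            f"Km={km0:.4g}): {exc}"
        ) from exc
    vmax, km = (float(p) for p in popt)
    vmax_se, km_se = (float(np.sqrt(pcov[i, i])) for i in range(2))
    fit = KineticsFit(
        Km=km, Km_se=km_se, Vmax=vmax, Vmax_se=vmax_se,
        r_squared=_r_squared(v, michaelis_menten(s, vmax, km)),
        unidentifiable=km > 50.0 * float(s.max()),
    )
    if data.enzyme_conc_uM:
        fit.kcat = vmax / data.enzyme_conc_uM
        fit.kcat_se = vmax_se / data.enzyme_conc_uM
        fit.kcat_over_Km = fit.kcat / km
    return fit


def fit_boltzmann(data: ThermalDataset) -> ThermalFit:
    """Nonlinear least-squares Boltzmann inactivation fit (pooled replicates).

    Initializers: A_top/A_bottom ← max/min activity, T50 ← temperature
    nearest the half-range activity, s ← 3 °C. A monotone-increasing
    activity profile (no inactivation) is flagged; the fitted T50 outside
    the data range is flagged extrapolated.
    """
    t, a = data.temperature_C, data.residual_activity_pct
    order = np.argsort(t)
    t_means = np.array([a[t == tv].mean() for tv in np.unique(t)])
    no_inact = bool(np.all(np.diff(t_means) >= 0)) and t_means[-1] > t_means[0]
    a_top0, a_bot0 = float(a.max()), float(a.min())
    half = (a_top0 + a_bot0) / 2.0
    t50_0 = float(t[np.argmin(np.abs(a - half))])
    try:
        popt, pcov = curve_fit(
            boltzmann, t, a, p0=[a_top0, a_bot0, t50_0, 3.0], maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Boltzmann fit failed to converge (p0: A_top={a_top0:.4g}, "
            f"A_bottom={a_bot0:.4g}, T50={t50_0:.4g}, s=3.0): {exc}"
        ) from exc
    a_top, a_bot, t50, steep = (float(p) for p in popt)
    ses = np.sqrt(np.diag(pcov))
    return ThermalFit(
        T50=t50, T50_se=float(ses[2]), s=steep, s_se=float(ses[3]),
        A_top=a_top, A_bottom=a_bot,
        r_squared=_r_squared(a, boltzmann(t, *popt)),
        extrapolated=not (t.min() <= t50 <= t.max()),
        no_inactivation=no_inact,
    )


def normalize_residual_activity(
    temperatures, raw_activities, reference_T: float = 25.0
):
    """Scale raw activities to percent of the reference-temperature value."""
    t = np.asarray(temperatures, float)
    raw = np.asarray(raw_activities, float)
    ref_mask = t == reference_T
    if not ref_mask.any():
        raise ValueError(f"reference temperature {reference_T} not in data")
    ref = raw[ref_mask].mean()
    if ref <= 0:
        raise ValueError("reference activity must be positive")
    return raw * 100.0 / ref


def normalize_ph_profile(activities):
    """Scale a pH-activity profile to its maximum (max maps to 1)."""
    a = np.asarray(activities, float)
    if a.size == 0:
        raise ValueError("empty activity profile")
    m = a.max()
    if m <= 0:
        raise ValueError("maximum activity must be positive")
    return a / m


def delta_t50(fit: ThermalFit, ref: ThermalFit) -> tuple[float, float]:
    """ΔT50 = T50 − T50_ref (°C) with quadrature-propagated SE."""
    return fit.T50 - ref.T50, float(np.hypot(fit.T50_se, ref.T50_se))


def generate_synthetic_assay(
    kind: str,
    params: dict,
    design: dict | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
):
    """Draw a replicated synthetic dataset from either assay model.

    ``kind`` is ``"kinetics"`` (params Vmax, Km, optionally
    enzyme_conc_uM) or ``"thermal"`` (params T50, s, A_top, A_bottom).
    ``design`` overrides the measurement grid (``substrate_mM`` /
    ``temperatures_C``) and ``replicates`` (default 3, matching the
    published triplicate protocol). Noise is additive Gaussian with SD
    equal to ``noise_sd`` × the local curve value, truncated at zero;
    ``noise_sd=0`` returns the exact curve. Reproducible given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = dict(design or {})
    replicates = int(design.get("replicates", 3))
    if replicates < 1:
        raise ValueError("need at least one replicate")

    if kind == "kinetics":
        s_levels = np.asarray(design.get("substrate_mM", DEFAULT_SUBSTRATE_MM), float)
        s = np.repeat(s_levels, replicates)
        truth = michaelis_menten(s, params["Vmax"], params["Km"])
        noisy = np.clip(truth + noise_sd * truth * rng.standard_normal(len(s)), 0.0, None)
        return KineticsDataset(
            substrate_mM=s,
            rate=noisy,
            replicate=np.tile(np.arange(replicates), len(s_levels)),
            enzyme_conc_uM=params.get("enzyme_conc_uM"),
        )
    if kind == "thermal":
        t_levels = np.asarray(design.get("temperatures_C", DEFAULT_TEMPS_C), float)
        t = np.repeat(t_levels, replicates)
        truth = boltzmann(t, params["A_top"], params["A_bottom"], params["T50"], params["s"])
        noisy = np.clip(truth + noise_sd * truth * rng.standard_normal(len(t)), 0.0, None)
        return ThermalDataset(
            temperature_C=t,
            residual_activity_pct=noisy,
            replicate=np.tile(np.arange(replicates), len(t_levels)),
        )
    raise ValueError(f"unknown assay kind {kind!r}")


def kinetics_fit_to_dict(fit: KineticsFit) -> dict:
    return {
        "Km_mM": fit.Km, "Km_se": fit.Km_se,
        "Vmax": fit.Vmax, "Vmax_se": fit.Vmax_se,
        "kcat": fit.kcat, "kcat_se": fit.kcat_se,
        "kcat_over_Km": fit.kcat_over_Km,
        "r_squared": fit.r_squared,
        "unidentifiable": fit.unidentifiable,
    }


def thermal_fit_to_dict(fit: ThermalFit) -> dict:
    return {
        "T50_C": fit.T50, "T50_se": fit.T50_se,
        "s_C": fit.s, "s_se": fit.s_se,
        "A_top_pct": fit.A_top, "A_bottom_pct": fit.A_bottom,
        "r_squared": fit.r_squared,
        "extrapolated": fit.extrapolated,
        "no_inactivation": fit.no_inactivation,
    }
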