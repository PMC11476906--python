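"""Porewater geochemistry: gradients, diffusive fluxes, penetration depths.

Benthic solute fluxes follow Fick's first law for sediments,

    J = -phi * Ds * dC/dz,    Ds = D0 / (1 - ln(phi^2)),

with porosity ``phi``, free-solution diffusivity ``D0`` and the Boudreau
tortuosity correction.  Depth is positive downward with the sediment-water
interface (SWI) at 0, so a solute decreasing into the sediment (negative
gradient) yields a positive flux *into* the sediment and an upward-diffusing
solute (NH4+) a negative flux (efflux) — the Table-2 style sign convention.

Units: depths in cm (microprofiles in mm), concentrations in uM
(= mmol m^-3), gradients in mmol m^-4, fluxes in mmol m^-2 d^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PorewaterProfile",
    "OxygenMicroprofile",
    "GradientFit",
    "FluxResult",
    "PenetrationResult",
    "fit_gradient",
    "o2_gradient",
    "fick_flux",
    "o2_penetration",
    "cn_molar_ratio",
    "correlation_screen",
    "D0_5C",
    "POROSITY_DEFAULT",
    "DETECTION_LIMIT_O2",
    "GRADIENT_WINDOW",
]

#: Free-solution diffusivities at 5 degC (m^2 s^-1), standard tabulations.
D0_5C = {
    "O2": 1.27e-9,
    "NO3": 0.98e-9,
    "NH4": 1.03e-9,
    "SO4": 0.56e-9,
}
POROSITY_DEFAULT = 0.9
DETECTION_LIMIT_O2 = 1.0  # uM
GRADIENT_WINDOW = 3  # porewater points below the SWI used for the OLS slope

SECONDS_PER_DAY = 86400.0
# molar masses (g/mol) for the C/N molar ratio
_M_C = 12.011
_M_N = 14.007


@dataclass
class PorewaterProfile:
    """Depth-indexed porewater concentrations for one solute.

    Depth is in cm, positive downward, SWI at 0; a bottom-water sample at
    -1.0 cm is allowed.  Depths must be strictly increasing.
    """

    solute: str
    depth_cm: np.ndarray
    conc_uM: np.ndarray

    def __post_init__(self) -> None:
        self.depth_cm = np.asarray(self.depth_cm, dtype=float)
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        if self.depth_cm.shape != self.conc_uM.shape:
            raise ValueError("depth and concentration arrays differ in length")
        if np.any(np.diff(self.depth_cm) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.conc_uM < 0):
            raise ValueError("concentrations must be non-negative")

    def below_swi(self) -> "PorewaterProfile":
        # the SWI point (depth 0) belongs to the sediment side; only the
        # bottom-water sample (negative depth) is excluded
        mask = self.depth_cm >= 0
        return PorewaterProfile(self.solute, self.depth_cm[mask], self.conc_uM[mask])


@dataclass
class OxygenMicroprofile:
    """Fine-resolution O2 profile (depth in mm) with its detection limit."""

    depth_mm: np.ndarray
    conc_uM: np.ndarray
    detection_limit_uM: float = DETECTION_LIMIT_O2

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        if self.depth_mm.shape != self.conc_uM.shape:
            raise ValueError("depth and concentration arrays differ in length")
        if self.depth_mm.size == 0:
            raise ValueError("empty microprofile")


@dataclass
class GradientFit:
    slope_mmol_m4: float  # dC/dz in mmol m^-4 (SI)
    r_squared: float
    n_points: int
    window_cm: tuple[float, float]


@dataclass
class FluxResult:
    """Diffusive flux with its ingredients; positive = into the sediment."""

    solute: str
    J_mmol_m2_d: float
    gradient_mmol_m4: float
    porosity: float
    D0_m2_s: float
    Ds_m2_s: float


@dataclass
class PenetrationResult:
    depth_mm: float
    censored: bool  # True if O2 never fell below the detection limit


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and R^2; a perfectly flat fit reports R^2 = 1 by convention."""
    if np.ptp(x) == 0:
        raise ValueError("zero depth variance in gradient window")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float(slope), 1.0
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(slope), r2


def fit_gradient(
    profile: PorewaterProfile, *, window: int = GRADIENT_WINDOW
) -> GradientFit:
    """OLS concentration gradient over the first ``window`` points below the SWI.

    The bottom-water point (negative depth) never enters the fit.  The
    slope is converted from uM/cm to SI (mmol m^-4; 1 uM cm^-1 = 100
    mmol m^-4).
    """
    below = profile.below_swi()
    if below.depth_cm.size < 2 or window < 2:
        raise ValueError("need at least 2 porewater points below the SWI")
    k = min(window, below.depth_cm.size)
    x = below.depth_cm[:k]
    y = below.conc_uM[:k]
    slope_uM_cm, r2 = _ols(x, y)
    return GradientFit(
        slope_mmol_m4=slope_uM_cm * 100.0,
        r_squared=r2,
        n_points=k,
        window_cm=(float(x[0]), float(x[-1])),
    )


def o2_gradient(profile: OxygenMicroprofile) -> GradientFit:
    """O2 gradient from the upper linear half of the oxic zone.

    The oxic zone runs from the SWI to the O2 penetration depth; the OLS
    slope is fit over the points in its upper 50%.
    """
    pen = o2_penetration(profile)
    mask = (profile.depth_mm >= 0) & (profile.depth_mm <= pen.depth_mm / 2.0)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 points in the upper oxic zone")
    x_mm = profile.depth_mm[mask]
    y = profile.conc_uM[mask]
    slope_uM_mm, r2 = _ols(x_mm, y)
    return GradientFit(
        slope_mmol_m4=slope_uM_mm * 1000.0,  # 1 uM mm^-1 = 1000 mmol m^-4
        r_squared=r2,
        n_points=int(mask.sum()),
        window_cm=(float(x_mm[0]) / 10.0, float(x_mm[-1]) / 10.0),
    )


def fick_flux(
    gradient: GradientFit | float,
    *,
    solute: str = "",
    porosity: float = POROSITY_DEFAULT,
    D0: float | None = None,
) -> FluxResult:
    """Fickian diffusive flux from a concentration gradient.

    ``gradient`` is a :class:`GradientFit` or a raw dC/dz in mmol m^-4.
    ``D0`` defaults to the 5 degC tabulated value for ``solute``.
    """
    if not 0.0 < porosity < 1.0:
        raise ValueError(f"porosity must be in (0, 1), got {porosity}")
    if D0 is None:
        if solute not in D0_5C:
            raise ValueError(f"no default D0 for solute {solute!r}; pass D0=")
        D0 = D0_5C[solute]
    if D0 <= 0:
        raise ValueError("D0 must be positive")
    dcdz = gradient.slope_mmol_m4 if isinstance(gradient, GradientFit) else float(gradient)
    theta2 = 1.0 - np.log(porosity**2)
    Ds = D0 / theta2
    J = -porosity * Ds * dcdz * SECONDS_PER_DAY
    return FluxResult(
        solute=solute,
        J_mmol_m2_d=float(J),
        gradient_mmol_m4=float(dcdz),
        porosity=porosity,
        D0_m2_s=float(D0),
        Ds_m2_s=float(Ds),
    )


def o2_penetration(profile: OxygenMicroprofile) -> PenetrationResult:
    """Depth where O2 first falls below the detection limit.

    Linear interpolation between the bracketing points; if the profile
    never crosses the limit the maximum depth is returned with a censored
    flag.  On non-monotone (noisy) profiles the *first* crossing is taken.
    """
    z = profile.depth_mm
    c = profile.conc_uM
    limit = profile.detection_limit_uM
    below = c < limit
    if not below.any():
        return PenetrationResult(float(z.max()), censored=True)
    i = int(np.argmax(below))
    if i == 0:
        return PenetrationResult(float(z[0]), censored=False)
    z0, z1 = z[i - 1], z[i]
    c0, c1 = c[i - 1], c[i]
    frac = (c0 - limit) / (c0 - c1) if c0 != c1 else 0.0
    return PenetrationResult(float(z0 + frac * (z1 - z0)), censored=False)


def cn_molar_ratio(toc_percent, tn_percent):
    """Molar C/N ratio from TOC and TN weight percent.

    (TOC/12.011) / (TN/14.007); the Redfield reference is 6.6.
    Accepts scalars or arrays; TN must be positive.
    """
    toc = np.asarray(toc_percent, dtype=float)
    tn = np.asarray(tn_percent, dtype=float)
    if np.any(tn <= 0):
        raise ValueError("TN must be positive to form a C/N ratio")
    ratio = (toc / _M_C) / (tn / _M_N)
    return float(ratio) if ratio.ndim == 0 else ratio


def correlation_screen(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations across lake-level variables.

    ``table`` is variables x observations (rows = variables).  Each pair is
    correlated on pairwise-complete observations with the two-sided
    t-distribution p-value; zero-variance pairs report NaN with a reason.
    Returns a long-form frame (var_a, var_b, r, p, n, note).
    """
    rows = []
    for a, b in combinations(table.index, 2):
        x = table.loc[a].astype(float)
        y = table.loc[b].astype(float)
        mask = x.notna() & y.notna()
        n = int(mask.sum())
        if n < 3:
            rows.append((a, b, np.nan, np.nan, n, "fewer than 3 paired observations"))
            continue
        xv, yv = x[mask].to_numpy(), y[mask].to_numpy()
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            rows.append((a, b, np.nan, np.nan, n, "zero variance"))
            continue
        r, p = stats.pearsonr(xv, yv)
        rows.append((a, b, float(r), float(p), n, ""))
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "p", "n", "note"])
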