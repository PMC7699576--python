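"""Solution thermodynamics of mixed drug aggregates from ultrasound data.

From density/sound-velocity series in aqueous solution:

* adiabatic compressibility by the Laplace relation k_S = 1/(rho u^2) (SI),
* apparent molal compressibility
      K_phi = -10^3 (k_S - k_S0)/(m rho_0) + k_S0 V_phi,
* critical aggregation concentration (cac) as the breakpoint of a
  continuous two-segment linear fit of velocity vs molality,
* Rubingh regular-solution analysis of a binary mixture: the aggregate
  mole fraction X1 solves

      X1^2 ln(a1 cmc_m / (X1 cmc1))
      --------------------------------------------- = 1
      (1-X1)^2 ln((1-a1) cmc_m / ((1-X1) cmc2))

  and the interaction parameter is
      beta = ln(a1 cmc_m / (X1 cmc1)) / (1 - X1)^2   (k_B T units).

Negative beta marks synergistic attraction between the two drugs in the
mixed aggregate, the solution-phase counterpart of a drug-drug
interaction at a binding site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

KB = 1.380649e-23  # J/K
NA = 6.02214076e23  # 1/mol
J_PER_KCAL = 4184.0
T_DEFAULT = 310.0  # K, physiological
F_RATIO_DEFAULT = 4.0


class NoBreakError(ValueError):
    """Raised when the two-segment fit does not beat a single line."""


@dataclass
class UltrasoundSeries:
    temperature: float  # K
    alpha1: float  # mole ratio of component 1 in (0, 1)
    molality: np.ndarray  # mol/kg, nondecreasing
    density: np.ndarray  # g/cm^3
    velocity: np.ndarray  # m/s
    rho0: float  # solvent density, g/cm^3
    ks0: float  # solvent adiabatic compressibility, 1/Pa

    def __post_init__(self):
        self.molality = np.asarray(self.molality, float)
        self.density = np.asarray(self.density, float)
        self.velocity = np.asarray(self.velocity, float)
        if np.any(np.diff(self.molality) < 0):
            raise ValueError("molality must be nondecreasing")
        if np.any(self.density <= 0) or np.any(self.velocity <= 0):
            raise ValueError("density and velocity must be > 0")
        if not (0 < self.alpha1 < 1):
            raise ValueError("alpha1 must lie in (0, 1)")


@dataclass(frozen=True)
class MixedAggregationResult:
    x1: float  # mole fraction of component 1 in the aggregate
    beta_kbt: float  # interaction parameter, k_B T units
    cmc1: float
    cmc2: float
    cmc_m: float


def adiabatic_compressibility(rho_gcm3: float, u_ms: float) -> float:
    """k_S = 1/(rho u^2) in 1/Pa, with rho converted from g/cm^3 to kg/m^3."""
    rho = np.asarray(rho_gcm3, float)
    u = np.asarray(u_ms, float)
    if np.any(rho <= 0) or np.any(u <= 0):
        raise ValueError("density and velocity must be > 0")
    out = 1.0 / (1e3 * rho * u * u)
    return float(out) if out.ndim == 0 else out


def apparent_molal_compressibility(
    ks: float, ks0: float, m: float, rho0: float, v_phi: float
) -> float:
    """K_phi = -10^3 (k_S - k_S0)/(m rho_0) + k_S0 V_phi (m > 0)."""
    if np.any(np.asarray(m) <= 0):
        raise ValueError("molality must be > 0 for an apparent molal quantity")
    return -1e3 * (ks - ks0) / (m * rho0) + ks0 * v_phi


def apparent_molal_volume(
    molar_mass: float, rho: float, rho0: float, m: float
) -> float:
    """V_phi = M/rho - 10^3 (rho - rho0)/(m rho rho0), cm^3/mol."""
    if m <= 0:
        raise ValueError("molality must be > 0")
    return molar_mass / rho - 1e3 * (rho - rho0) / (m * rho * rho0)


def _two_segment_ssr(x: np.ndarray, y: np.ndarray, b: float) -> float:
    """SSR of the continuous two-segment (hinge) least-squares fit."""
    design = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - b)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid)


def detect_cac(
    series: UltrasoundSeries, f_ratio: float = F_RATIO_DEFAULT
) -> float:
    """Breakpoint of velocity vs molality (the critical aggregation conc.).

    Candidate breakpoints are the midpoints between consecutive interior
    abscissae; the best candidate is refined by bounded minimization of the
    two-segment SSR.  The fit must beat a single line by the F-ratio
    (default 4.0), else :class:`NoBreakError`.  Invariant under affine
    rescaling of the velocity axis.
    """
    x, y = series.molality, series.velocity
    n = len(x)
    if n < 6:
        raise ValueError("need >= 6 points spanning the break")
    # single-line fit
    design1 = np.column_stack([np.ones_like(x), x])
    coef1, *_ = np.linalg.lstsq(design1, y, rcond=None)
    ssr1 = float(np.sum((y - design1 @ coef1) ** 2))
    mids = 0.5 * (x[1:-2] + x[2:-1])  # keep >= 2 points on each side
    if len(mids) == 0:
        raise ValueError("not enough interior points for a breakpoint search")
    ssrs = [_two_segment_ssr(x, y, b) for b in mids]
    k = int(np.argmin(ssrs))
    lo = mids[max(0, k - 1)]
    hi = mids[min(len(mids) - 1, k + 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda b: _two_segment_ssr(x, y, b), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10 * max(1.0, hi)},
        )
        best_b, ssr2 = float(res.x), float(res.fun)
    else:
        best_b, ssr2 = float(mids[k]), float(ssrs[k])
    scale = float(np.var(y)) * n
    if ssr2 <= 1e-20 * max(scale, 1.0):
        if ssr1 <= 1e-20 * max(scale, 1.0):
            raise NoBreakError("data are collinear: no detectable break")
        return best_b
    f = ((ssr1 - ssr2) / 1.0) / (ssr2 / max(n - 3, 1))
    if not np.isfinite(f) or f < f_ratio:
        raise NoBreakError(
            f"two-segment fit does not beat a single line (F = {f:.2f} < {f_ratio})"
        )
    return best_b


def _rubingh_g(x1: float, cmc1: float, cmc2: float, cmc_m: float, a1: float) -> float:
    return (x1 * x1) * np.log(a1 * cmc_m / (x1 * cmc1)) - ((1 - x1) ** 2) * np.log(
        (1 - a1) * cmc_m / ((1 - x1) * cmc2)
    )


def solve_mixed_composition(
    cmc1: float, cmc2: float, cmc_m: float, alpha1: float, tol: float = 1e-10
) -> float:
    """Aggregate mole fraction X1 in (0, 1) from the Rubingh equation."""
    if min(cmc1, cmc2, cmc_m) <= 0:
        raise ValueError("all concentrations must be > 0")
    if not (0 < alpha1 < 1):
        raise ValueError("alpha1 must lie in (0, 1)")
    eps = 1e-12
    f = lambda x: _rubingh_g(x, cmc1, cmc2, cmc_m, alpha1)  # noqa: E731
    a, b = eps, 1 - eps
    fa, fb = f(a), f(b)
    if fa * fb > 0:
        raise ValueError(
            "no sign change on (0, 1): cmc_m outside the mixing-consistent range"
        )
    return float(optimize.brentq(f, a, b, xtol=tol))


def beta_interaction(cmc1: float, cmc_m: float, alpha1: float, x1: float) -> float:
    """beta = ln(alpha1 cmc_m / (X1 cmc1)) / (1 - X1)^2, in k_B T units."""
    if not (0 < x1 < 1):
        raise ValueError("X1 must lie strictly inside (0, 1)")
    return float(np.log(alpha1 * cmc_m / (x1 * cmc1)) / (1 - x1) ** 2)


def mixed_aggregation_analysis(
    cmc1: float, cmc2: float, cmc_m: float, alpha1: float
) -> MixedAggregationResult:
    x1 = solve_mixed_composition(cmc1, cmc2, cmc_m, alpha1)
    return MixedAggregationResult(
        x1=x1,
        beta_kbt=beta_interaction(cmc1, cmc_m, alpha1, x1),
        cmc1=cmc1,
        cmc2=cmc2,
        cmc_m=cmc_m,
    )


def ideal_mixing_cmc(cmc1: float, cmc2: float, alpha1: float) -> float:
    """Clint ideal-mixing cmc: 1/cmc_m = alpha1/cmc1 + (1-alpha1)/cmc2."""
    return 1.0 / (alpha1 / cmc1 + (1 - alpha1) / cmc2)


def kbt_to_kcal(value_kbt: float, temperature: float = T_DEFAULT) -> float:
    """Convert k_B T units to kcal/mol at the given temperature."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return value_kbt * KB * NA * temperature / J_PER_KCAL
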