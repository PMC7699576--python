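"""Heterogeneous two-ligand Monod-Wyman-Changeux fractional occupancy.

The receptor region is modeled as a two-state (relaxed R / tense T)
allosteric unit carrying n1 site-slots accessible to ligand A and n2
accessible to ligand B.  Each slot s has an R-state half-saturation
constant K_s (concentration units) and a T/R scaling factor c_s in (0, 1]:
in the T state the slot binds with constant K_s / c_s.  L_iso = [T0]/[R0]
is the isomerization constant of the empty receptor.

With x_s = X/K_s (R state) and c_s * x_s (T state), the grand partition
function is

    Z = Z_R + L_iso * Z_T,
    Z_R = prod_s (1 + x_s),    Z_T = prod_s (1 + c_s x_s),

and the fractional occupancy of slot s is the Boltzmann-weighted bound
fraction

    delta_s = [ x_s/(1+x_s) * Z_R + L_iso * c_s x_s/(1+c_s x_s) * Z_T ] / Z.

Limits: L_iso = 0 recovers independent-site (Langmuir/Adair) binding;
c_s = 1 everywhere makes delta independent of L_iso.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MWCSiteModel",
    "LigandDose",
    "state_partition",
    "fractional_occupancy",
    "occupancy_curve",
]


@dataclass
class MWCSiteModel:
    """Per-slot R-state constants and T/R scalings for two ligands.

    ``k_r_a``/``k_r_b`` list the half-saturation constants of the slots
    accessible to ligand A and B respectively; ``c_a``/``c_b`` the matching
    T/R scaling factors (default 1.0 for every slot).
    """

    k_r_a: Sequence[float]
    k_r_b: Sequence[float]
    c_a: Sequence[float] | None = None
    c_b: Sequence[float] | None = None
    l_iso: float = 0.0

    def __post_init__(self):
        self.k_r_a = np.asarray(self.k_r_a, float)
        self.k_r_b = np.asarray(self.k_r_b, float)
        if len(self.k_r_a) < 1 or len(self.k_r_b) < 1:
            raise ValueError("need n1 >= 1 and n2 >= 1 site slots")
        if np.any(self.k_r_a <= 0) or np.any(self.k_r_b <= 0):
            raise ValueError("all K_R must be > 0")
        self.c_a = (
            np.ones_like(self.k_r_a) if self.c_a is None else np.asarray(self.c_a, float)
        )
        self.c_b = (
            np.ones_like(self.k_r_b) if self.c_b is None else np.asarray(self.c_b, float)
        )
        for c in (self.c_a, self.c_b):
            if np.any((c <= 0) | (c > 1)):
                raise ValueError("c factors must lie in (0, 1]")
        if self.l_iso < 0:
            raise ValueError("L_iso must be >= 0")

    @property
    def n1(self) -> int:
        return len(self.k_r_a)

    @property
    def n2(self) -> int:
        return len(self.k_r_b)


@dataclass(frozen=True)
class LigandDose:
    conc_a: float
    conc_b: float

    def __post_init__(self):
        if self.conc_a < 0 or self.conc_b < 0:
            raise ValueError("concentrations must be >= 0")


def _slot_arrays(m: MWCSiteModel, d: LigandDose):
    x = np.concatenate([d.conc_a / m.k_r_a, d.conc_b / m.k_r_b])
    c = np.concatenate([m.c_a, m.c_b])
    return x, c


def state_partition(m: MWCSiteModel, d: LigandDose, state: Literal["R", "T"]) -> float:
    """Binding polynomial of one conformational state (>= 1).

    R: prod_s (1 + x_s); T: prod_s (1 + c_s x_s) — the T state binds every
    slot with its affinity scaled down by c_s.
    """
    x, c = _slot_arrays(m, d)
    if state == "R":
        return float(np.prod(1.0 + x))
    if state == "T":
        return float(np.prod(1.0 + c * x))
    raise ValueError(f"state must be 'R' or 'T', got {state!r}")


def fractional_occupancy(
    m: MWCSiteModel, d: LigandDose, prefactor_n: int | None = None
) -> tuple[np.ndarray, float]:
    """Per-slot occupancies delta_s and their 1/n mean.

    ``prefactor_n`` overrides the n of the 1/n prefactor (default
    n1 + n2, i.e. the mean over all site slots).
    Returns ``(delta_per_slot, mean_delta)``; every value lies in [0, 1].
    """
    x, c = _slot_arrays(m, d)
    z_r = np.prod(1.0 + x)
    z_t = np.prod(1.0 + c * x)
    z = z_r + m.l_iso * z_t
    occ_r = x / (1.0 + x)
    occ_t = (c * x) / (1.0 + c * x)
    delta = (occ_r * z_r + m.l_iso * occ_t * z_t) / z
    n = prefactor_n if prefactor_n is not None else (m.n1 + m.n2)
    return delta, float(np.sum(delta) / n)


def occupancy_curve(
    m: MWCSiteModel, doses: Iterable[LigandDose], prefactor_n: int | None = None
) -> pd.DataFrame:
    """Pointwise occupancy table over a dose grid.

    Monotone nondecreasing along any ray of increasing doses; approaches 1
    per slot as both doses grow without bound.
    """
    doses = list(doses)
    if not doses:
        raise ValueError("empty dose grid")
    rows = []
    for d in doses:
        delta, mean = fractional_occupancy(m, d, prefactor_n)
        row = {"conc_a": d.conc_a, "conc_b": d.conc_b, "delta_mean": mean}
        row.update({f"delta_slot{i+1}": v for i, v in enumerate(delta)})
        rows.append(row)
    return pd.DataFrame(rows)
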