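"""Tunnel throughput and two-ligand transport-trajectory overlap.

A tunnel with radius profile r(l) along its arclength has throughput

    T = exp( - integral_0^L r(l)^(-n) dl ),    T in [0, 1],

so narrow bottlenecks penalize transport exponentially (default n = 2).
Paired binding-energy trajectories of two ligands pulled through the same
tunnel reveal drug-drug interaction (DDI) windows: intervals where both
ligands bind spontaneously (dG < 0) in the same biophysical environment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

MIN_TRAPEZOIDS = 8
MAX_GRID_SPACING = 0.1  # Angstrom, upper bound on trapezoid width
TARGET_GRID_SPACING = 0.05  # Angstrom, default spacing actually used


@dataclass
class TunnelProfile:
    site_id: str
    tunnel_id: str
    samples: Sequence[tuple[float, float]]  # (arclength l, radius r), Angstrom
    n: int = 2

    def __post_init__(self):
        ls = np.asarray([s[0] for s in self.samples], float)
        rs = np.asarray([s[1] for s in self.samples], float)
        if len(ls) < 2:
            raise ValueError("tunnel profile needs >= 2 samples")
        if ls[0] != 0 or np.any(np.diff(ls) <= 0):
            raise ValueError("arclength must start at 0 and strictly increase")
        if np.any(rs <= 0):
            raise ValueError("tunnel radius must be > 0 everywhere")
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError("exponent n must be a positive integer")
        self.l = ls
        self.r = rs

    @property
    def length(self) -> float:
        return float(self.l[-1])


@dataclass
class TransportTrajectory:
    ligand_id: str
    samples: Sequence[tuple[float, float, float]]  # (position, radius, dG)

    def __post_init__(self):
        pos = np.asarray([s[0] for s in self.samples], float)
        if len(pos) and np.any(np.diff(pos) <= 0):
            raise ValueError("positions must strictly increase")
        dg = np.asarray([s[2] for s in self.samples], float)
        if not np.all(np.isfinite(dg)):
            raise ValueError("dG must be finite")
        self.pos = pos
        self.radius = np.asarray([s[1] for s in self.samples], float)
        self.dg = dg


@dataclass(frozen=True)
class DDISegment:
    start: float  # Angstrom
    end: float
    mean_dg_a: float  # kcal/mol
    mean_dg_b: float


def pathway_cost(t: TunnelProfile, spacing: float = TARGET_GRID_SPACING) -> float:
    """Trapezoidal integral of r(l)^(-n) on a uniform grid.

    At least MIN_TRAPEZOIDS trapezoids and spacing never above
    MAX_GRID_SPACING; the default target spacing is finer (0.05 A) so that
    smooth profiles converge well below 1e-3.  Radius is linearly
    interpolated between profile samples.
    """
    L = t.length
    if L == 0:
        return 0.0
    spacing = min(spacing, MAX_GRID_SPACING)
    n_trap = max(MIN_TRAPEZOIDS, int(np.ceil(L / spacing)))
    grid = np.linspace(0.0, L, n_trap + 1)
    r = np.interp(grid, t.l, t.r)
    integrand = r ** (-float(t.n))
    return float(np.trapezoid(integrand, grid))


def throughput(t: TunnelProfile, spacing: float = TARGET_GRID_SPACING) -> float:
    """T = exp(-cost), in [0, 1]; 1 means an unobstructed pathway."""
    return float(np.exp(-pathway_cost(t, spacing)))


def trajectory_extrema(a: TransportTrajectory) -> tuple[float, float]:
    """Most negative dG and its position (ties -> smallest position)."""
    if len(a.pos) == 0:
        raise ValueError("empty trajectory")
    i = int(np.argmin(a.dg))  # argmin returns the first minimum
    return float(a.dg[i]), float(a.pos[i])


def detect_ddi_segments(
    a: TransportTrajectory, b: TransportTrajectory, min_length: float = 0.5
) -> list[DDISegment]:
    """Maximal intervals where both ligands bind spontaneously.

    Both trajectories are resampled by linear interpolation onto the union
    of their position grids restricted to the intersection of supports;
    within it, a DDI segment is a maximal run of grid points where both
    dG < 0, kept if its span is >= min_length.  Disjoint supports yield an
    empty list.  Symmetric in (a, b) up to the mean-dG labels.
    """
    if min_length <= 0:
        raise ValueError("min_length must be > 0")
    if len(a.pos) == 0 or len(b.pos) == 0:
        raise ValueError("trajectories must be non-empty")
    lo = max(a.pos[0], b.pos[0])
    hi = min(a.pos[-1], b.pos[-1])
    if lo >= hi:
        return []
    grid = np.union1d(a.pos, b.pos)
    grid = grid[(grid >= lo) & (grid <= hi)]
    ga = np.interp(grid, a.pos, a.dg)
    gb = np.interp(grid, b.pos, b.dg)
    ok = (ga < 0) & (gb < 0)
    segments: list[DDISegment] = []
    i = 0
    while i < len(grid):
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(grid) and ok[j + 1]:
            j += 1
        if grid[j] - grid[i] >= min_length:
            segments.append(
                DDISegment(
                    start=float(grid[i]),
                    end=float(grid[j]),
                    mean_dg_a=float(np.mean(ga[i : j + 1])),
                    mean_dg_b=float(np.mean(gb[i : j + 1])),
                )
            )
        i = j + 1
    return segments


def mutual_overlap_criterion(
    ligand_atoms: np.ndarray,
    alpha_sphere_centers: np.ndarray,
    cutoff: float = 3.0,
    fraction: float = 0.5,
) -> bool:
    """True iff strictly more than ``fraction`` of ligand atoms lie within
    ``cutoff`` Angstrom of some alpha-sphere center (the site's DDI
    relevance rule: > 50% of atoms within 3 A)."""
    ligand_atoms = np.atleast_2d(np.asarray(ligand_atoms, float))
    centers = np.atleast_2d(np.asarray(alpha_sphere_centers, float))
    if ligand_atoms.size == 0:
        raise ValueError("empty ligand atom list")
    if centers.size == 0:
        raise ValueError("empty alpha-sphere center list")
    d, _ = cKDTree(centers).query(ligand_atoms)
    return bool(np.count_nonzero(d <= cutoff) / len(ligand_atoms) > fraction)


def load_tunnel_profiles_csv(path: str) -> list[TunnelProfile]:
    """CSV columns: site_id, tunnel_id, l_angstrom, r_angstrom."""
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for (site, tun), grp in df.groupby(["site_id", "tunnel_id"], sort=False):
        grp = grp.sort_values("l_angstrom")
        out.append(
            TunnelProfile(
                str(site), str(tun), list(zip(grp.l_angstrom, grp.r_angstrom))
            )
        )
    return out


def load_trajectories_csv(path: str) -> list[TransportTrajectory]:
    """CSV columns: ligand_id, position_angstrom, radius_angstrom, dG_kcal_mol."""
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for lig, grp in df.groupby("ligand_id", sort=False):
        grp = grp.sort_values("position_angstrom")
        out.append(
            TransportTrajectory(
                str(lig),
                list(zip(grp.position_angstrom, grp.radius_angstrom, grp.dG_kcal_mol)),
            )
        )
    return out
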