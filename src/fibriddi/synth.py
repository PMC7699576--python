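"""Seeded synthetic-data generators for every pipeline stage.

The docking, tunnel-geometry, electronic-structure, and ultrasound
instruments that feed the real study are external; these generators emit
inputs with the same statistical structure — a tunnel profile with one
bottleneck, paired binding-energy trajectories sharing a co-interaction
window, residue chains whose geometry perturbation lowers depth by a known
amount, pose ensembles with hot/cold occurrence statistics, and
density/velocity series with a slope break at a critical aggregation
concentration generated under a known regular-solution beta.  Each
generator is deterministic given its seed and attaches the ground truth
needed to verify the consuming stage without re-running it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from fibriddi.depth import AA20, DepthChain
from fibriddi.energetics import PoseEnsemble
from fibriddi.structure import Atom, Structure
from fibriddi.thermo import UltrasoundSeries
from fibriddi.transport import TransportTrajectory, TunnelProfile

WATER_RHO0 = 0.997047  # g/cm^3 at 25 C
WATER_U0 = 1496.7  # m/s at 25 C
WATER_KS0 = 1.0 / (1e3 * WATER_RHO0 * WATER_U0**2)  # 1/Pa


# ---------------------------------------------------------------- tunnels


def gen_tunnel_profile(
    seed: int,
    length: float = 15.0,
    mean_radius: float = 3.5,
    bottleneck_radius: float = 2.4,
    bottleneck_position: float = 0.5,
    site_id: str = "site1",
    tunnel_id: str = "tunnel2",
) -> TunnelProfile:
    """Smooth radius profile with a single Gaussian bottleneck.

    The default bottleneck (2.4 A under a ~3.5 A ambient radius) mirrors
    the critical constriction at which drug-drug coupling peaks in the
    studied tunnel.  The sampled minimum lies within 1% of the requested
    bottleneck radius.
    """
    if mean_radius <= 0 or bottleneck_radius <= 0:
        raise ValueError("radii must be > 0")
    if bottleneck_radius > mean_radius:
        raise ValueError("bottleneck radius must not exceed the mean radius")
    rng = np.random.default_rng(seed)
    n = int(round(length / 0.1)) + 1
    l = np.linspace(0.0, length, n)
    l0 = bottleneck_position * length
    sigma = max(length / 6.0, 1e-6)
    dip = np.exp(-(((l - l0) / sigma) ** 2))
    depth = mean_radius - bottleneck_radius
    # gentle seeded corrugation, suppressed near the bottleneck so the
    # minimum stays at the requested value
    phases = rng.uniform(0, 2 * np.pi, size=3)
    wiggle = sum(
        np.sin(2 * np.pi * (k + 1) * l / length + phases[k]) for k in range(3)
    )
    r = mean_radius - depth * dip + 0.004 * depth * wiggle * (1.0 - dip)
    return TunnelProfile(site_id, tunnel_id, list(zip(l, r)))


# ----------------------------------------------------- trajectory pairs


@dataclass(frozen=True)
class TrajectoryPairTruth:
    window: tuple[float, float]
    well_depths: tuple[float, float]
    seed: int


def gen_trajectory_pair(
    seed: int,
    support: float = 15.0,
    window: tuple[float, float] = (5.0, 10.0),
    well_depths: tuple[float, float] = (-7.7, -6.5),
    divergence_amplitude: float = 1.0,
    dx: float = 0.1,
) -> tuple[TransportTrajectory, TransportTrajectory, TrajectoryPairTruth]:
    """Paired ligand trajectories with a shared co-interaction window.

    Inside the window both ligands bind spontaneously with strongly
    correlated profiles reaching the requested well depths; outside it the
    second ligand's affinity collapses above zero (scaled by
    ``divergence_amplitude``), emulating trajectories that become abruptly
    independent past the bottleneck.  ``divergence_amplitude = 0`` with
    equal well depths yields identical trajectories.
    """
    w0, w1 = window
    if not (0 <= w0 < w1 <= support):
        raise ValueError("window must lie within the support")
    rng = np.random.default_rng(seed)
    x = np.arange(0.0, support + dx / 2, dx)
    inside = (x >= w0) & (x <= w1)
    bump = np.zeros_like(x)
    bump[inside] = np.sin(np.pi * (x[inside] - w0) / (w1 - w0))
    base = 0.75 + 0.25 * bump  # in [0.75, 1]; peaks mid-window
    da, db = well_depths
    amp = divergence_amplitude
    noise_a = rng.normal(0, 0.015, size=x.shape)
    noise_b = rng.normal(0, 0.015, size=x.shape)
    wig = rng.normal(0, 0.1, size=x.shape)
    dg_a = da * base + amp * noise_a
    dg_b = db * base + amp * noise_b
    outside = ~inside
    dg_b = dg_b + amp * outside * (-db * base + 0.5 + np.abs(wig))
    # radius column mirrors a bottlenecked tunnel centred on the window
    l0 = 0.5 * (w0 + w1)
    r = 3.5 - 1.1 * np.exp(-(((x - l0) / (support / 6.0)) ** 2))
    traj_a = TransportTrajectory("A", list(zip(x, r, dg_a)))
    traj_b = TransportTrajectory("P", list(zip(x, r, dg_b)))
    return traj_a, traj_b, TrajectoryPairTruth(window, well_depths, seed)


# ----------------------------------------------------------- depth chains


@dataclass(frozen=True)
class DepthChainsTruth:
    per_chain_drop: dict[str, float]
    mean_depth_before: float
    seed: int


def gen_depth_chains(
    seed: int,
    chain_count: int = 6,
    chain_length: int = 20,
    depth_drop: tuple[float, float] = (1.0, 2.0),
    s_max: float = 100.0,
    w: float = 0.1,
    l_max: int = 2,
    mean_depth: float = 4.0,
) -> tuple[list[DepthChain], list[DepthChain], DepthChainsTruth]:
    """Before/after residue chains with a known per-chain depth decrease.

    Chains carry random residue types on a jittered linear backbone in
    normalized coordinate units; the geometry is scaled so that the mean
    residue depth before binding equals ``mean_depth`` (in the S_max scale)
    exactly, and the after-chain coordinates are expanded so the realized
    mean per-residue depth drop equals a value drawn from ``depth_drop``.
    A wider geometry means larger sequence-order coupling tau, hence a
    smaller descriptor q and a shallower depth — the mechanism by which
    ligand binding perturbs depth in the consuming stage.
    """
    lo, hi = depth_drop
    if lo < 0 or hi < lo:
        raise ValueError("depth drop range must satisfy 0 <= lo <= hi")
    if mean_depth - hi <= 0.05:
        raise ValueError("drop range too large for the baseline mean depth")
    rng = np.random.default_rng(seed)
    chain_ids = [chr(ord("N") + k) for k in range(chain_count)]
    before, after = [], []
    drops: dict[str, float] = {}
    for cid in chain_ids:
        types = list(rng.choice(AA20, size=chain_length))
        coords_unit = np.column_stack(
            [
                np.arange(chain_length, dtype=float),
                rng.normal(0, 0.15, chain_length),
                rng.normal(0, 0.15, chain_length),
            ]
        )
        coords_unit -= coords_unit[0]
        proto = DepthChain(cid, types, coords_unit, w=w, l_max=l_max, s_max=s_max)
        tau_unit = sum(
            float(np.sum((coords_unit[d:] - coords_unit[:-d]) ** 2))
            for d in range(1, l_max + 1)
        )
        f_bar = float(np.mean([proto.frequencies[t] for t in types]))

        def scale_for(target_mean_depth: float) -> float:
            tau_target = (f_bar * s_max / target_mean_depth - 1.0) / w
            if tau_target <= 0:
                raise ValueError("target mean depth unreachable for this chain")
            return float(np.sqrt(tau_target / tau_unit))

        drop = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        s_before = scale_for(mean_depth)
        s_after = scale_for(mean_depth - drop)
        before.append(
            DepthChain(cid, types, coords_unit * s_before, w=w, l_max=l_max, s_max=s_max)
        )
        after.append(
            DepthChain(cid, types, coords_unit * s_after, w=w, l_max=l_max, s_max=s_max)
        )
        drops[cid] = drop
    return before, after, DepthChainsTruth(drops, mean_depth, seed)


# ---------------------------------------------------------- pose ensembles


def gen_pose_ensemble(
    seed: int, site_profile: str = "hot", pose_count: int = 100
) -> PoseEnsemble:
    """Docked-pose affinity ensemble with hot or cold occurrence statistics.

    ``hot`` emulates a reproducible deep pose cluster (one dominant
    affinity bin, like the k = 100 cluster of the top site); ``cold``
    emulates dispersed shallow binding (k spread over many bins, like the
    k = 10-13 minor sites).
    """
    if pose_count <= 0:
        raise ValueError("pose count must be > 0")
    rng = np.random.default_rng(seed)
    if site_profile == "hot":
        aff = rng.normal(-7.7, 0.04, size=pose_count)
        docked = rng.random(pose_count) < 0.95
    elif site_profile == "cold":
        aff = rng.uniform(-7.0, -4.0, size=pose_count)
        docked = rng.random(pose_count) < 0.5
    else:
        raise ValueError("site_profile must be 'hot' or 'cold'")
    poses = [
        (f"pose{i+1}", float(a), bool(d)) for i, (a, d) in enumerate(zip(aff, docked))
    ]
    return PoseEnsemble(poses)


# ------------------------------------------------- mixed-aggregate series


@dataclass(frozen=True)
class UltrasoundTruth:
    beta: float
    x1: float
    cmc_m: float
    cmc1: float
    cmc2: float
    alpha1: float
    seed: int


def forward_mixed_cmc(
    beta: float, cmc1: float, cmc2: float, alpha1: float
) -> tuple[float, float]:
    """Regular-solution forward model: (X1, cmc_m) from beta.

    Activity coefficients f1 = exp(beta (1-X1)^2), f2 = exp(beta X1^2);
    the aggregate composition solves
    alpha1 / (X1 f1 cmc1) = (1-alpha1) / ((1-X1) f2 cmc2), then
    cmc_m = X1 f1 cmc1 / alpha1.  beta = 0 reduces to Clint ideal mixing.
    """
    if not (0 < alpha1 < 1):
        raise ValueError("alpha1 must lie in (0, 1)")
    if min(cmc1, cmc2) <= 0:
        raise ValueError("cmc values must be > 0")

    def g(x1: float) -> float:
        f1 = np.exp(beta * (1 - x1) ** 2)
        f2 = np.exp(beta * x1**2)
        return np.log(alpha1 / (x1 * f1 * cmc1)) - np.log(
            (1 - alpha1) / ((1 - x1) * f2 * cmc2)
        )

    x1 = float(optimize.brentq(g, 1e-12, 1 - 1e-12, xtol=1e-14))
    cmc_m = float(x1 * np.exp(beta * (1 - x1) ** 2) * cmc1 / alpha1)
    return x1, cmc_m


def gen_ultrasound_series(
    seed: int,
    beta_true: float = -0.8,
    cmc1: float = 10.0,
    cmc2: float = 2.0,
    alpha1: float = 0.5,
    noise_rel: float = 0.001,
    temperature: float = 298.15,
    n_points: int = 48,
    slope_pre: float = 50.0,
    slope_post: float = 20.0,
) -> tuple[UltrasoundSeries, UltrasoundTruth]:
    """Density/velocity-vs-molality series with a break at the mixed cac.

    The mixed cac comes from the regular-solution forward model under
    ``beta_true``; sound velocity is piecewise-linear in molality with the
    aggregation slope change at the cac (pre/post slopes in m/s per unit
    molality, instrument-scale values) plus multiplicative Gaussian noise
    of relative width ``noise_rel``.  Density rises gently and linearly.
    """
    if noise_rel < 0:
        raise ValueError("noise must be >= 0")
    x1, cmc_m = forward_mixed_cmc(beta_true, cmc1, cmc2, alpha1)
    rng = np.random.default_rng(seed)
    m = np.linspace(0.02 * cmc_m, 2.0 * cmc_m, n_points)
    u = WATER_U0 + slope_pre * np.minimum(m, cmc_m) + slope_post * np.maximum(
        0.0, m - cmc_m
    )
    u = u * (1.0 + rng.normal(0, noise_rel, size=m.shape))
    rho = WATER_RHO0 + 0.004 * m
    series = UltrasoundSeries(
        temperature=temperature,
        alpha1=alpha1,
        molality=m,
        density=rho,
        velocity=u,
        rho0=WATER_RHO0,
        ks0=WATER_KS0,
    )
    return series, UltrasoundTruth(beta_true, x1, cmc_m, cmc1, cmc2, alpha1, seed)


# --------------------------------------------- synthetic receptor stand-in

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# backbone internal coordinates (Angstrom / degrees), ideal trans peptide
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N = 121.7, 111.2, 116.2


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position a fourth atom from three anchors and internal coordinates."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phis: Sequence[float], psis: Sequence[float], origin=(0.0, 0.0, 0.0)
) -> list[np.ndarray]:
    """N/CA/C coordinates of a chain with the prescribed dihedrals.

    ``phis[0]`` and ``psis[-1]`` are unused (terminal angles are
    undefined); omega is fixed trans (180 deg).  Returns a flat list
    [N1, CA1, C1, N2, ...].
    """
    nres = len(phis)
    if len(psis) != nres:
        raise ValueError("phis and psis must have equal length")
    o = np.asarray(origin, float)
    coords = [
        o + np.array([0.0, 0.0, 0.0]),
        o + np.array([_B_N_CA, 0.0, 0.0]),
    ]
    ang = np.radians(_A_N_CA_C)
    coords.append(
        coords[1] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    )
    for i in range(1, nres):
        n_prev, ca_prev, c_prev = coords[-3], coords[-2], coords[-1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psis[i - 1])
        ca_i = _place_atom(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, 180.0)
        c_i = _place_atom(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phis[i])
        coords.extend([n_i, ca_i, c_i])
    return coords


def gen_synthetic_eregion(seed: int = 0) -> Structure:
    """Synthetic stand-in for the fibrinogen E-region receptor.

    This is NOT the deposited crystal structure: it is a constructed
    six-chain (N, O, P, Q, R, S) backbone whose residue numbering covers
    the three binding-site residue lists, built from internal coordinates
    with phi/psi drawn from favored helical and extended regions.  It
    exercises the parse -> dihedral -> Ramachandran pipeline with the
    study's chain/site layout when the deposited entry is unavailable.
    """
    import json
    from importlib import resources

    sites = json.loads(
        resources.files("fibriddi.data").joinpath("binding_sites.json").read_text()
    )
    spans: dict[str, list[int]] = {}
    for key in ("site1", "site2", "site3"):
        for chain, num in sites[key]:
            spans.setdefault(chain, []).append(int(num))
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    for k, (chain_id, nums) in enumerate(sorted(spans.items())):
        first, last = min(nums) - 1, max(nums) + 1
        resnums = list(range(first, last + 1))
        nres = len(resnums)
        helical = rng.random(nres) < 0.6
        phis = np.where(
            helical, rng.normal(-63, 6, nres), rng.normal(-120, 10, nres)
        )
        psis = np.where(
            helical, rng.normal(-43, 6, nres), rng.normal(130, 10, nres)
        )
        coords = build_backbone(phis, psis, origin=(0.0, 40.0 * k, 0.0))
        types = rng.choice(AA20, size=nres)
        for i, resnum in enumerate(resnums):
            res3 = _ONE_TO_THREE[types[i]]
            for j, (name, elem) in enumerate((("N", "N"), ("CA", "C"), ("C", "C"))):
                xyz = coords[3 * i + j]
                atoms.append(
                    Atom(
                        chain_id=chain_id,
                        res_seq=resnum,
                        icode="",
                        res_name=res3,
                        atom_name=name,
                        element=elem,
                        coord=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
                    )
                )
    return Structure(atoms)


def write_pdb(s: Structure, path: str) -> None:
    """Write a Structure to PDB format via gemmi."""
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple, gemmi.Residue] = {}
    for a in s.atoms:
        ch = chains.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id)
            chains[a.chain_id] = ch
            model.add_chain(ch)
            ch = model[len(model) - 1]
            chains[a.chain_id] = ch
        rid = a.residue_id
        res = residues.get(rid)
        if res is None:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, a.icode or " ")
            ch.add_residue(res)
            res = ch[len(ch) - 1]
            residues[rid] = res
        at = gemmi.Atom()
        at.name = a.atom_name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.coord)
        at.occ = a.occupancy
        res.add_atom(at)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
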