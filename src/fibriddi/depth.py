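"""Residue-depth quasi-sequence-order descriptors and perturbation analysis.

A chain's geometry enters through the rank-d sequence-order coupling

    tau_d = sum_{i=1}^{N-d} d(i, i+d)^2        (squared Calpha distances)

and the per-residue depth descriptor

    q_ic = f_r / ( sum_r f_r + w * sum_{d=1}^{L_max} tau_d ),

where f_r is the normalized frequency of the target residue's type in the
chain (the 20 frequencies sum to 1, so the denominator is 1 + w*sum tau).
Scaling by the maximum solvent accessibility S_max gives the residue depth
D = q_ic * S_max; a multi-chain tunnel context is summarized with the
noisy-OR aggregate D = [1 - prod_c (1 - q_ic)] * S_max.  Ligand binding
perturbs Calpha geometry, raising tau and therefore lowering q and D; the
study's signature is a 1-2 A drop in D at DDI-relevant residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AA20 = [
    "A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
    "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V",
]

W_DEFAULT = 0.1  # sequence-order weighting factor


@dataclass
class DepthChain:
    chain_id: str
    res_types: Sequence[str]  # one-letter codes, length N
    coords: np.ndarray  # (N, 3) Calpha coordinates
    target_index: int = 0  # 0-based index of the target residue
    w: float = W_DEFAULT
    l_max: int | None = None  # default N - 1
    s_max: float = 100.0  # maximum solvent accessibility (percent-like, > 0)
    frequencies: Mapping[str, float] | None = None  # default: from sequence

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        n = len(self.res_types)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (N, 3) matching res_types")
        if n < 2:
            raise ValueError("chain needs >= 2 residues")
        if not (0 <= self.target_index < n):
            raise ValueError("target index outside chain")
        if self.l_max is None:
            self.l_max = n - 1
        if not (1 <= self.l_max <= n - 1):
            raise ValueError("L_max must lie in [1, N-1]")
        if self.s_max <= 0:
            raise ValueError("S_max must be > 0")
        if self.frequencies is None:
            counts = {aa: 0 for aa in AA20}
            for t in self.res_types:
                if t not in counts:
                    raise ValueError(f"unknown residue type {t!r}")
                counts[t] += 1
            self.frequencies = {aa: counts[aa] / n for aa in AA20}
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type frequencies must sum to 1 (got {total})")

    @property
    def n(self) -> int:
        return len(self.res_types)


def sequence_order_coupling(chain: DepthChain, d: int) -> float:
    """tau_d: sum of squared Calpha distances between residues d apart."""
    if not (1 <= d <= chain.n - 1):
        raise ValueError(f"rank d must lie in [1, N-1], got {d}")
    diff = chain.coords[d:] - chain.coords[: chain.n - d]
    return float(np.sum(diff * diff))


def _tau_sum(chain: DepthChain) -> float:
    return sum(sequence_order_coupling(chain, d) for d in range(1, chain.l_max + 1))


def depth_qso_descriptor(chain: DepthChain, target_index: int | None = None) -> float:
    """q_ic in (0, 1] for the chain's target residue.

    Strictly decreasing in every inter-residue distance and in w; equals
    the target-type frequency when the chain is geometrically collapsed
    (all tau_d = 0).
    """
    idx = chain.target_index if target_index is None else target_index
    fr = chain.frequencies[chain.res_types[idx]]
    if fr <= 0:
        raise ValueError("target residue type has zero frequency")
    denom = sum(chain.frequencies.values()) + chain.w * _tau_sum(chain)
    return float(fr / denom)


@dataclass
class DepthProfile:
    """Per-(chain, residue) depth values under one condition."""

    condition: str  # e.g. "unbound" / "ligand-bound"
    values: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.values.items():
            if v < 0:
                raise ValueError(f"depth must be >= 0 at {k}")


def residue_depth(
    chains: Sequence[DepthChain], condition: str = "unbound"
) -> tuple[DepthProfile, float]:
    """Per-chain depth profile plus the multi-chain noisy-OR aggregate.

    Per residue of each chain: D = q_ic * S_max (chains are independent —
    editing one chain never changes another's values).  The aggregate uses
    each chain's target residue: D_agg = [1 - prod_c (1 - q_target_c)] *
    S_max, with S_max taken from the first chain; it is a labeled
    tunnel-level summary, not a per-residue quantity.
    """
    if not chains:
        raise ValueError("need >= 1 chain")
    profile = DepthProfile(condition=condition)
    for ch in chains:
        for i in range(ch.n):
            profile.values[(ch.chain_id, i + 1)] = (
                depth_qso_descriptor(ch, i) * ch.s_max
            )
    q_targets = [depth_qso_descriptor(ch) for ch in chains]
    agg = (1.0 - float(np.prod([1.0 - q for q in q_targets]))) * chains[0].s_max
    return profile, agg


def depth_perturbation(
    before: DepthProfile, after: DepthProfile
) -> tuple[dict[tuple[str, int], float], dict[str, float]]:
    """Per-residue dD = D_before - D_after and a {mean, max_abs} summary."""
    missing = set(before.values) ^ set(after.values)
    if missing:
        raise ValueError(f"profiles cover different residues: {sorted(missing)[:5]}")
    dd = {k: before.values[k] - after.values[k] for k in before.values}
    arr = np.asarray(list(dd.values()))
    return dd, {"mean": float(arr.mean()), "max_abs": float(np.abs(arr).max())}


def chain_relevance(c: int) -> str:
    """Binding relevance of a tunnel from the number of chains it involves:
    >= 6 high, 3-5 medium, 1-2 low."""
    if c < 1:
        raise ValueError("chain count must be >= 1")
    if c >= 6:
        return "high"
    if c >= 3:
        return "medium"
    return "low"


def profile_table(profile: DepthProfile) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chain": k[0], "pos": k[1], "D": v, "condition": profile.condition}
            for k, v in sorted(profile.values.items())
        ]
    )
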