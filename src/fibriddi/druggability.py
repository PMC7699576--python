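"""Binding-pocket druggability scoring and ranking.

The druggability degree D_g estimates the maximum intrinsic affinity a
pocket can offer a drug-like ligand from its nonpolar (desolvation) area,
a reference drug-like contact area, and its normalized maximum
solvent-accessible surface area:

    D_g = gamma * A_nonpolar * A_druglike / S_max + C

with gamma the solvent surface-tension constant (0.024 kcal/mol) and C an
empirical offset.  D_g is reported as the positive magnitude of the
maximum site affinity; the corresponding free energy is dG_max = -D_g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GAMMA_DEFAULT = 0.024  # kcal/mol, solvent surface tension constant
A_DRUGLIKE_DEFAULT = 300.0  # A^2, drug-like contact size
DRUGGABLE_CUTOFF_DEFAULT = 0.2  # separates the study's worst site (0.08) from ranked sites


@dataclass
class PocketDescriptor:
    site_id: str
    a_nonpolar: float  # A^2
    s_max: float  # normalized maximum SASA, dimensionless > 0
    gamma: float = GAMMA_DEFAULT
    a_druglike: float = A_DRUGLIKE_DEFAULT
    c: float = 0.0
    curvature_radius: float | None = None  # metadata only
    dg: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.a_nonpolar < 0:
            raise ValueError("A_nonpolar must be >= 0")
        if self.a_druglike <= 0 or self.gamma <= 0:
            raise ValueError("A_druglike and gamma must be > 0")
        if self.s_max <= 0:
            raise ValueError(
                f"S_max must be > 0 (got {self.s_max}): the normalized maximum "
                "solvent-accessible area divides the score"
            )


def druggability_score(p: PocketDescriptor) -> float:
    """D_g for one pocket (dimensionless, positive-magnitude convention)."""
    return p.gamma * p.a_nonpolar * p.a_druglike / p.s_max + p.c


def max_site_affinity(p: PocketDescriptor) -> float:
    """dG_max = -D_g, the maximum intrinsic site affinity as a free energy."""
    return -druggability_score(p)


def rank_pockets(pockets: list[PocketDescriptor]) -> list[PocketDescriptor]:
    """Descending by D_g; stable, so ties keep input order."""
    if not pockets:
        raise ValueError("need at least one pocket")
    scored = []
    for p in pockets:
        p.dg = druggability_score(p) if p.dg is None else p.dg
        scored.append(p)
    return sorted(scored, key=lambda q: -q.dg)


def classify_druggable(dg: float, cutoff: float = DRUGGABLE_CUTOFF_DEFAULT) -> str:
    """'druggable' iff D_g >= cutoff (inclusive boundary)."""
    return "druggable" if dg >= cutoff else "undruggable"


def load_pockets_csv(path: str) -> list[PocketDescriptor]:
    """CSV columns: site_id, A_nonpolar, S_max [, gamma, A_druglike, C]."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            PocketDescriptor(
                site_id=str(row["site_id"]),
                a_nonpolar=float(row["A_nonpolar"]),
                s_max=float(row["S_max"]),
                gamma=float(row.get("gamma", GAMMA_DEFAULT)),
                a_druglike=float(row.get("A_druglike", A_DRUGLIKE_DEFAULT)),
                c=float(row.get("C", 0.0)),
            )
        )
    return out


def ranking_table(
    pockets: list[PocketDescriptor], cutoff: float = DRUGGABLE_CUTOFF_DEFAULT
) -> pd.DataFrame:
    ranked = rank_pockets(pockets)
    return pd.DataFrame(
        {
            "site_id": [p.site_id for p in ranked],
            "Dg": [p.dg for p in ranked],
            "dG_max_kcal_mol": [-p.dg for p in ranked],
            "class": [classify_druggable(p.dg, cutoff) for p in ranked],
            "rank": range(1, len(ranked) + 1),
        }
    )
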