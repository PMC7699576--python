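"""Ranking of quantum-chemistry dimer configurations.

Electronic-structure calculations on the isolated drug-drug dimer yield,
per candidate configuration, a binding energy

    E_b = -(E_total[A+P] - E[A] - E[P])    (eV, positive = stabilizing),

a HOMO-LUMO gap, and the shortest inter-drug contact distance.
Configurations are ranked by |E_b|; gaps between ranks quantify how
decisive the top pose is, and E_b below 2.50 eV indicates a purely
non-covalent (no shared electrons) interaction regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

NONCOVALENT_THRESHOLD_EV = 2.50


@dataclass(frozen=True)
class ConfigurationRecord:
    config_id: str  # Roman numeral label
    eb_ev: float  # |E_b|, eV
    dhl_ev: float  # HOMO-LUMO gap, eV
    d_angstrom: float  # shortest inter-drug contact distance
    contact: str  # e.g. "O-H"

    def __post_init__(self):
        if self.eb_ev < 0 or self.dhl_ev < 0 or self.d_angstrom <= 0:
            raise ValueError("E_b, dHL must be >= 0 and distance > 0")


def binding_energy(e_total: float, e_a: float, e_b: float) -> float:
    """E_b = -(E_total - E_A - E_B); symmetric in the two parts."""
    return -(e_total - e_a - e_b)


def rank_configurations(
    records: list[ConfigurationRecord],
) -> list[tuple[int, ConfigurationRecord]]:
    """Stable descending sort by E_b magnitude; rank 1 = largest.

    Ties keep input order (the published table's own order is the only
    stated rule for its tied rows).
    """
    if not records:
        raise ValueError("need >= 1 configuration record")
    ids = [r.config_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate configuration ids")
    ranked = sorted(records, key=lambda r: -r.eb_ev)
    return list(enumerate(ranked, start=1))


def rank_gap(
    records: list[ConfigurationRecord], rank_i: int, rank_j: int
) -> float:
    """E_b(rank i) - E_b(rank j), eV."""
    ranked = rank_configurations(records)
    by_rank = dict(ranked)
    if rank_i not in by_rank or rank_j not in by_rank:
        raise ValueError(f"rank out of range: {rank_i}, {rank_j} (n={len(ranked)})")
    return by_rank[rank_i].eb_ev - by_rank[rank_j].eb_ev


def classify_bond_regime(
    eb_ev: float, threshold: float = NONCOVALENT_THRESHOLD_EV
) -> str:
    """'non-covalent' iff E_b < threshold (strict); else 'covalent-capable'."""
    if eb_ev < 0:
        raise ValueError("E_b magnitude must be >= 0")
    return "non-covalent" if eb_ev < threshold else "covalent-capable"


def load_configurations_csv(path: str | None = None) -> list[ConfigurationRecord]:
    """Read configuration records; default is the packaged 15-row table of
    beta-blocker dimer results."""
    if path is None:
        with resources.as_file(
            resources.files("fibriddi.data").joinpath("dft_configurations.csv")
        ) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return [
        ConfigurationRecord(
            config_id=str(r.config_id),
            eb_ev=float(r.Eb_eV),
            dhl_ev=float(r.dHL_eV),
            d_angstrom=float(r.d_angstrom),
            contact=str(r.contact),
        )
        for r in df.itertuples()
    ]


def ranking_table(records: list[ConfigurationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": rank,
                "config_id": r.config_id,
                "Eb_eV": r.eb_ev,
                "dHL_eV": r.dhl_ev,
                "d_angstrom": r.d_angstrom,
                "contact": r.contact,
                "regime": classify_bond_regime(r.eb_ev),
            }
            for rank, r in rank_configurations(records)
        ]
    )
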