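import itertools

import numpy as np
import pytest

from fibriddi import mwc, synth

# Hand-written minimal PDB text: two chains, one altloc pair (B has the
# higher occupancy), one insertion-code residue and one HETATM water.
MINI_PDB = """\
ATOM      1  N   ALA P   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA P   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA P   1      10.729   6.768  -4.123  1.00  0.00           C
ATOM      4  N   GLY P   2       9.580   6.121  -3.839  1.00  0.00           N
ATOM      5  CA AGLY P   2       8.585   6.665  -2.915  0.40  0.00           C
ATOM      6  CA BGLY P   2       8.612   6.701  -2.901  0.60  0.00           C
ATOM      7  C   GLY P   2       7.173   6.182  -3.232  1.00  0.00           C
ATOM      8  N   SER P   2A      6.297   7.067  -3.711  1.00  0.00           N
ATOM      9  CA  SER P   2A      4.903   6.693  -3.973  1.00  0.00           C
ATOM     10  C   SER P   2A      4.685   6.099  -5.363  1.00  0.00           C
ATOM     11  N   THR Q   1       3.905   5.021  -5.453  1.00  0.00           N
ATOM     12  CA  THR Q   1       3.615   4.367  -6.727  1.00  0.00           C
ATOM     13  C   THR Q   1       2.375   4.956  -7.391  1.00  0.00           C
HETATM   14  O   HOH Q 101       0.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def mini_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINI_PDB)
    return p


@pytest.fixture(scope="session")
def eregion():
    """Synthetic stand-in of the six-chain E-region receptor."""
    return synth.gen_synthetic_eregion(0)


def brute_force_occupancy(m: mwc.MWCSiteModel, d: mwc.LigandDose) -> np.ndarray:
    """Independent grand-partition enumeration over all R/T micro-states."""
    x = np.concatenate([d.conc_a / m.k_r_a, d.conc_b / m.k_r_b])
    c = np.concatenate([m.c_a, m.c_b])
    n = len(x)
    z = 0.0
    bound = np.zeros(n)
    for state_weight, fac in ((1.0, np.ones(n)), (m.l_iso, c)):
        for occ in itertools.product((0, 1), repeat=n):
            w = state_weight
            for i in range(n):
                if occ[i]:
                    w *= fac[i] * x[i]
            z += w
            bound += w * np.asarray(occ, float)
    return bound / z
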