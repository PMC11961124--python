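"""Shared fixtures: small hand-written coordinate texts and seeded toys."""

import numpy as np
import pytest

from redoxstruct.sasa import shrake_rupley
from redoxstruct.synthetic_data import CysPlacement, make_toy_structure

#: A single alanine with five atoms and hand-readable coordinates.
SINGLE_ALA_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 20.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 21.00           C
ATOM      3  C   ALA A   1      13.132   6.350  -5.128  1.00 22.00           C
ATOM      4  O   ALA A   1      13.687   6.788  -4.121  1.00 23.00           O
ATOM      5  CB  ALA A   1      10.912   7.055  -4.233  1.00 24.00           C
END
"""

#: Alternate locations A (occ 0.60) and B (occ 0.40) on the CB atom.
ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.000   1.420   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.250   2.390   0.000  1.00 10.00           O
ATOM      5  CB AALA A   1       2.000  -0.800   1.200  0.60 10.00           C
ATOM      6  CB BALA A   1       2.000  -0.900   1.100  0.40 10.00           C
END
"""

#: Two residues plus a crystallographic water numbered 401.
WATER_PDB = """\
ATOM      1  N   GLY A  10       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  GLY A  10       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   GLY A  10       2.000   1.420   0.000  1.00 10.00           C
ATOM      4  O   GLY A  10       1.250   2.390   0.000  1.00 10.00           O
ATOM      5  N   ALA A  11       3.320   1.540   0.000  1.00 10.00           N
ATOM      6  CA  ALA A  11       4.000   2.800   0.200  1.00 10.00           C
ATOM      7  C   ALA A  11       5.500   2.600   0.300  1.00 10.00           C
ATOM      8  O   ALA A  11       6.100   1.550   0.100  1.00 10.00           O
ATOM      9  CB  ALA A  11       3.700   3.700   1.400  1.00 10.00           C
TER      10      ALA A  11
HETATM   11  O   HOH A 401      10.000  10.000  10.000  1.00 30.00           O
END
"""


@pytest.fixture(scope="session")
def two_chain_toy():
    """Two separated chains with a disulfide, a free thiol, a buried thiol."""
    return make_toy_structure(
        n_chains=2, residues_per_chain=24,
        cys_placements=[
            CysPlacement("A", 105, partner=("A", 106), distance=2.05),
            CysPlacement("A", 112),
            CysPlacement("A", 118, occluded=True),
        ])


@pytest.fixture(scope="session")
def redox_constellation():
    """A chain emulating the studied cysteine constellation.

    Ten cysteines: one disulfide pair at 2.05 Å (115-120), four exposed
    free thiols (149, 153, 231, 355), four buried free thiols
    (169, 222, 340, 362), on a 270-residue single-chain scaffold.
    """
    placements = [CysPlacement("A", 115, partner=("A", 120), distance=2.05)]
    placements += [CysPlacement("A", n) for n in (149, 153, 231, 355)]
    placements += [CysPlacement("A", n, occluded=True)
                   for n in (169, 222, 340, 362)]
    return make_toy_structure(n_chains=1, residues_per_chain=270,
                              cys_placements=placements)


@pytest.fixture(scope="session")
def redox_constellation_sasa(redox_constellation):
    return shrake_rupley(redox_constellation)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
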