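"""Shared fixtures: small chemical fixtures and a compact synthetic benchmark."""

import numpy as np
import pytest

from sfbench.synthdata import SyntheticConfig, make_benchmark

# --- inline structure fixtures (V2000 MOL blocks, PDB snippets) ---------

METHANE_SDF = """methane
  test

  5  4  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6300    0.6300    0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6300   -0.6300    0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6300    0.6300   -0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.6300   -0.6300   -0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
  1  3  1  0  0  0  0
  1  4  1  0  0  0  0
  1  5  1  0  0  0  0
M  END
$$$$
"""

BENZENE_SDF = """benzene
  test

 12 12  0  0  0  0  0  0  0  0999 V2000
    1.3950    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6975    1.2081    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6975    1.2081    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3950    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6975   -1.2081    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6975   -1.2081    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.4800    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.2400    2.1476    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2400    2.1476    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.4800    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2400   -2.1476    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.2400   -2.1476    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  4  0  0  0  0
  2  3  4  0  0  0  0
  3  4  4  0  0  0  0
  4  5  4  0  0  0  0
  5  6  4  0  0  0  0
  6  1  4  0  0  0  0
  1  7  1  0  0  0  0
  2  8  1  0  0  0  0
  3  9  1  0  0  0  0
  4 10  1  0  0  0  0
  5 11  1  0  0  0  0
  6 12  1  0  0  0  0
M  END
$$$$
"""

# hydrogens interleaved between the heavy atoms so bond re-indexing is exercised
NBUTANE_SDF = """n-butane
  test

  8  7  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.5000    0.8000    0.5000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.5300    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0400    1.4500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5000    2.0000    0.8000 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.5700    1.4500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.9500    0.9000    0.8600 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.9500    2.4700    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
  1  3  1  0  0  0  0
  3  4  1  0  0  0  0
  4  5  1  0  0  0  0
  4  6  1  0  0  0  0
  6  7  1  0  0  0  0
  6  8  1  0  0  0  0
M  END
$$$$
"""

ETHANE_SDF = """ethane
  test

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5400    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
M  END
$$$$
"""

def _pdb_line(serial, name, res, seq, x, y, z, element=""):
    """Build one fixed-column ATOM record (element columns optional)."""
    tail = f"          {element:>2s}" if element else ""
    return (f"ATOM  {serial:5d} {name:<4s} {res:<3s} A{seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00{tail}\n")


# five records mixing present/absent element columns; expected elements are
# N, C (from columns 77-78) then O, S, CL (inferred from the atom names)
PDB_MIXED = (
    _pdb_line(1, " N", "ALA", 1, 11.104, 6.134, -6.504, "N")
    + _pdb_line(2, " CA", "ALA", 1, 12.560, 6.071, -6.342, "C")
    + _pdb_line(3, " O", "ALA", 1, 13.200, 7.500, -6.100)
    + _pdb_line(4, " SD", "MET", 2, 9.000, 4.000, -2.000)
    + _pdb_line(5, "CL1", "LIG", 3, 8.000, 3.000, -1.000)
)


@pytest.fixture(scope="session")
def small_config():
    """A compact benchmark: same structure as the default, desk-scale sizes."""
    return SyntheticConfig(
        n_families=12, test_per_family=3, n_extra_families=5, n_train=160,
        ligand_size_range=(6, 16), protein_size_range=(20, 40),
    )


@pytest.fixture(scope="session")
def small_benchmark(small_config):
    return make_benchmark(small_config, master_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
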