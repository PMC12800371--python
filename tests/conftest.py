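import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from rna3dseg import DomainDecomposition


MINIMAL_PDB = """\
ATOM      1  C3'   G A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  C4'   G A   1       1.000   0.500   0.000  1.00  0.00           C
ATOM      3  C3'   A A   2       5.900   0.000   0.000  1.00  0.00           C
ATOM      4  C4'   A A   2       6.900   0.500   0.000  1.00  0.00           C
ATOM      5  C3'   U A   3      11.800   0.000   0.000  1.00  0.00           C
ATOM      6  C4'   U A   3      12.800   0.500   0.000  1.00  0.00           C
END
"""

@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def minimal_cif(tmp_path, minimal_pdb):
    """Same content as the PDB fixture, re-encoded as mmCIF."""
    import gemmi
    path = tmp_path / "minimal.cif"
    st = gemmi.read_structure(str(minimal_pdb))
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def decomposition(chain_length, domains, linkers=()):
    """Shorthand decomposition builder for tests."""
    from rna3dseg import Domain
    doms = tuple(Domain(lab, tuple(segs)) for lab, segs in domains)
    return DomainDecomposition(chain_length, doms, tuple(linkers))


def from_labels(label_array):
    return DomainDecomposition.from_label_array(label_array)
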