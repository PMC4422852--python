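import numpy as np
import pytest

import phosbridge as pb
from phosbridge import reference as ref
from phosbridge.constants import H3PO4
from phosbridge.fragments import ION_TYPES


@pytest.fixture(scope="session")
def r6ps4():
    return pb.build_peptide(ref.SEQUENCES["R6pS4"])


@pytest.fixture(scope="session")
def full_ion_set():
    """All singly charged ion species, with and without H3PO4 loss."""

    def make(pep):
        return pb.theoretical_ions(pep, ION_TYPES, (1,), (0.0, H3PO4))

    return make


@pytest.fixture(scope="session")
def table2_coverage(full_ion_set):
    """Coverage maps computed from peak lists realizing the printed
    abundance tables, for every study peptide."""

    def make(key):
        pep = pb.build_peptide(ref.SEQUENCES[key])
        peaks = pb.gen_peaklist(pep, ref.TABLE2_ABUNDANCE[key], seed=0)
        asn = pb.relative_abundance(
            pb.assign_peaks(peaks, full_ion_set(pep), tol_ppm=3.0)
        )
        return pep, asn, pb.coverage_map(asn, pep)

    return make


def single_atom(radius_element="C"):
    return pb.Structure(
        np.array([radius_element]),
        np.zeros((1, 3)),
        np.array([1]),
        np.array(["ALA"]),
        np.array(["CA"]),
        "one_atom",
    )


@pytest.fixture
def one_atom_structure():
    return single_atom()
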