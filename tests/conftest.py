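import numpy as np
import pytest

from cilffa.chem import DEFAULT_BOUNDS, MONOISOTOPIC_MASS, Formula
from cilffa.feature_io import read_library


@pytest.fixture(scope="session")
def library():
    return read_library()


class BruteForceGrid:
    """Exhaustive C/H/N/O enumeration oracle for formula generation.

    Materializes every composition within the bounds once, then answers
    mass-window queries by direct filtering.  Deliberately independent of
    cilffa.chem.generate_formulas (only the atomic masses are shared, since
    they define the problem).
    """

    def __init__(self, bounds=DEFAULT_BOUNDS):
        c = np.arange(bounds.c[0], bounds.c[1] + 1)
        h = np.arange(bounds.h[0], bounds.h[1] + 1)
        n = np.arange(bounds.n[0], bounds.n[1] + 1)
        o = np.arange(bounds.o[0], bounds.o[1] + 1)
        C, H, N, O = np.meshgrid(c, h, n, o, indexing="ij")
        self.C, self.H = C.ravel(), H.ravel()
        self.N, self.O = N.ravel(), O.ravel()
        self.mass = (12.0 * self.C + MONOISOTOPIC_MASS["H"] * self.H
                     + MONOISOTOPIC_MASS["N"] * self.N
                     + MONOISOTOPIC_MASS["O"] * self.O)
        rdbe2 = 2 * self.C - self.H + self.N + 2  # 2*RDBE, integral check = parity
        self.rdbe_ok = (rdbe2 >= 0) & (rdbe2 % 2 == 0)
        self.nonempty = (self.C + self.H + self.N + self.O) > 0

    def query(self, target, tolerance_mda=5.0, rdbe_filter=True):
        sel = (np.abs(self.mass - target) <= tolerance_mda / 1000.0) & self.nonempty
        if rdbe_filter:
            sel &= self.rdbe_ok
        idx = np.flatnonzero(sel)
        return {
            str(Formula({"C": int(self.C[i]), "H": int(self.H[i]),
                         "N": int(self.N[i]), "O": int(self.O[i])}))
            for i in idx
        }


@pytest.fixture(scope="session")
def brute_force_grid():
    return BruteForceGrid()
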