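import numpy as np
import pytest
from Bio.Align import substitution_matrices

from wedgemap import classify, interactions, structio, synthetic_data, wedge


@pytest.fixture(scope="session")
def blosum62():
    return substitution_matrices.load("BLOSUM62")


@pytest.fixture(scope="session")
def gotoh_oracle(blosum62):
    """Independent brute-force affine-gap DP (Gotoh) returning the optimal
    global alignment score; gap of length L costs open + (L-1)*extend."""

    def score(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5):
        n, m = len(a), len(b)
        NEG = -1e9
        M = [[NEG] * (m + 1) for _ in range(n + 1)]
        X = [[NEG] * (m + 1) for _ in range(n + 1)]
        Y = [[NEG] * (m + 1) for _ in range(n + 1)]
        M[0][0] = 0.0
        for i in range(1, n + 1):
            X[i][0] = -gap_open - (i - 1) * gap_extend
        for j in range(1, m + 1):
            Y[0][j] = -gap_open - (j - 1) * gap_extend
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                s = blosum62[a[i - 1], b[j - 1]]
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
                X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
                Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
        return max(M[n][m], X[n][m], Y[n][m])

    return score


class SpeciesBundle:
    """A species toy complex with everything downstream pre-computed."""

    def __init__(self, species, omit=(), pose="normal", **kwargs):
        self.species = species
        self.model, _ = synthetic_data.make_toy_complex(
            species, omit=omit, pose=pose, **kwargs
        )
        self.ligand = structio.extract_ligand(self.model, ["LIG"])
        self.frame = wedge.define_wedge(
            self.model, synthetic_data.anchors_for(species, omit)
        )
        self.report = interactions.phosphate_environment(self.model, self.ligand)

    @property
    def call(self):
        return classify.call_activity(
            self.report, self.frame, self.ligand, m=self.model,
            species=self.species,
        )


@pytest.fixture(scope="session")
def bundle():
    cache = {}

    def get(species, omit=(), pose="normal"):
        key = (species, omit, pose)
        if key not in cache:
            cache[key] = SpeciesBundle(species, omit=omit, pose=pose)
        return cache[key]

    return get


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a bounded translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-30, 30, 3)
    return R, t
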