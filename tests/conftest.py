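import numpy as np
import pytest

from scaffoldcall.align import ScoringScheme, SeedIndex
from scaffoldcall.fixtures import cbs_synthetic_scaffolds, rare_insertion
from scaffoldcall.simulate import SimParams, make_haplotypes, simulate_pairs


@pytest.fixture(scope="session")
def scaffolds():
    return cbs_synthetic_scaffolds()


@pytest.fixture(scope="session")
def index(scaffolds):
    return SeedIndex(scaffolds)


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def simulate_genotype(scaffolds):
    """Simulate a genotype at reduced (but still site-saturating) coverage."""

    def _sim(label, seed=0, coverage=80.0, error_rate=0.001, **kw):
        rare = rare_insertion() if kw.pop("rare", False) else None
        haps = make_haplotypes(scaffolds, label, rare_insertion=rare)
        params = SimParams(
            coverage=coverage, base_error_rate=error_rate, seed=seed, **kw
        )
        return simulate_pairs(haps, params)

    return _sim


def sw_oracle(q: str, r: str, match=1, mismatch=-4, gap_open=-6, gap_extend=-1) -> int:
    """Exhaustive O(nm) affine-gap local-alignment score (test-only oracle,
    independent of the package's aligner)."""
    n, m = len(q), len(r)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if qi == r[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
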