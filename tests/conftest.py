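"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from repcons.alignment import AlignScoring

NEG = float("-inf")


def rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        out[i] = "ACGT"[("ACGT".index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def ref_fit_score(q: str, t: str, s: AlignScoring = AlignScoring()) -> float:
    """Independent O(nm) Gotoh fit-alignment score (free end gaps on target).

    Deliberately written as plain nested loops over explicit state lists so
    it shares nothing with the production kernel.
    """
    n, m = len(q), len(t)
    go, ge = s.gap_open, s.gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        M[0][j] = 0.0  # start anywhere on the target for free
    for i in range(1, n + 1):
        for j in range(m + 1):
            x_cands = [M[i - 1][j] + go + ge, X[i - 1][j] + ge]
            X[i][j] = max(x_cands)
            if j >= 1:
                sub = s.match if q[i - 1] == t[j - 1] else s.mismatch
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub
                Y[i][j] = max(M[i][j - 1] + go + ge, Y[i][j - 1] + ge)
    return max(max(M[n][j], X[n][j]) for j in range(m + 1))


def chain_base_map(chain) -> dict:
    """Brute-force genome-base -> consensus-base map implied by a chain."""
    mapping = {}
    t = chain.t_start
    qp = chain.q_start
    for size, dt, dq in chain.blocks:
        for off in range(size):
            g = t + off
            if chain.q_strand == "+":
                c = qp + off
            else:
                c = chain.q_size - 1 - (qp + off)
            mapping[g] = c
        t += size + dt
        qp += size + dq
    return mapping


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_family():
    """A small noiseless family with one planted deletion, fully aligned."""
    from repcons.pipeline import align_family, simulate_dataset
    from repcons.simulate import DeletionSpec, FamilySimSpec

    spec = FamilySimSpec(
        name="L1TEST",
        consensus_len=2000,
        n_instances=40,
        truncation_geom_p=1.0 / 1000.0,
        mut_rate=0.0,
        deletions=(DeletionSpec("d1", 400, 60, 0.6),),
        seed=42,
    )
    ds = simulate_dataset(spec)
    cs = align_family(ds.consensus, ds.genome, ds.annotations)
    return ds, cs
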