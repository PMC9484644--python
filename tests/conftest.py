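"""Shared builders for small in-memory genotype fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from rohpipe.detect import ROH, ROHParams, ROHSet
from rohpipe.io import GenotypeDataset, MarkerMap


def make_map(positions, chrom=None, prefix="m") -> MarkerMap:
    """MarkerMap from a position list (single chromosome by default)."""
    positions = np.asarray(positions, dtype=np.int64)
    if chrom is None:
        chrom = np.ones(len(positions), dtype=np.int64)
    else:
        chrom = np.asarray(chrom, dtype=np.int64)
    ids = np.array([f"{prefix}{k}" for k in range(len(positions))], dtype=object)
    return MarkerMap(chrom, ids, positions)


def make_dataset(calls, positions=None, chrom=None, animal_ids=None) -> GenotypeDataset:
    calls = np.asarray(calls, dtype=np.int8)
    if calls.ndim == 1:
        calls = calls[None, :]
    n, m = calls.shape
    if positions is None:
        positions = (np.arange(m) + 1) * 100_000
    mm = make_map(positions, chrom=chrom)
    if animal_ids is None:
        animal_ids = [f"a{k}" for k in range(n)]
    return GenotypeDataset(animal_ids, mm, calls)


def make_rohset(entries, positions=None, animal_ids=None, params=None) -> ROHSet:
    """ROHSet from (animal, chrom, start_bp, end_bp[, start_idx, end_idx]) tuples."""
    rohs = []
    for e in entries:
        animal, chrom, s, ebp = e[:4]
        si, ei = (e[4], e[5]) if len(e) > 4 else (0, 1)
        rohs.append(
            ROH(animal_id=animal, chrom=int(chrom), start_bp=int(s), end_bp=int(ebp),
                start_idx=int(si), end_idx=int(ei), n_snps=max(ei - si + 1, 2),
                n_het=0, n_miss=0)
        )
    if animal_ids is None:
        animal_ids = sorted({r.animal_id for r in rohs})
    return ROHSet(rohs=rohs, params=params or ROHParams(), map_fingerprint="test",
                  animal_ids=list(animal_ids))


@pytest.fixture
def rng():
    return np.random.default_rng(20220919)


def random_instance(rng, n_max=300, pos_span=30_000_000):
    """A random single-chromosome calls/positions pair for scanner tests."""
    n = int(rng.integers(5, n_max + 1))
    pos = np.unique(rng.integers(1, pos_span, size=n))
    calls = rng.choice(
        np.array([0, 1, 2, -1], dtype=np.int8), size=len(pos), p=[0.38, 0.22, 0.28, 0.12]
    )
    return calls, pos


def random_params(rng) -> ROHParams:
    return ROHParams(
        min_length_bp=int(rng.choice([1, 300_000, 1_000_000])),
        min_snps=int(rng.integers(2, 16)),
        max_het=int(rng.integers(0, 4)),
        max_miss=int(rng.integers(0, 7)),
    )
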