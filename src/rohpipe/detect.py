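"""Run-of-homozygosity detection.

A run of homozygosity (ROH) is a contiguous stretch of homozygous
genotype calls along one chromosome of one animal.  The window semantics
implemented here are deterministic and order-free:

* a candidate window ``[i, j]`` over the chromosome's markers is *valid*
  iff the endpoint calls ``i`` and ``j`` are homozygous and non-missing,
  the window contains at most ``max_het`` heterozygous and at most
  ``max_miss`` missing calls, spans at least ``min_length_bp``
  (``pos[j] - pos[i]``) and contains at least ``min_snps`` markers;
* candidates are the *inclusion-maximal* valid windows (no valid window
  strictly contains them);
* overlapping candidates are resolved by repeatedly keeping the longest
  in bp (ties to the leftmost) and discarding whatever overlaps it.

Heterozygous/missing allowances are therefore interior-only: a run can
never start or end on a heterozygous or missing call, which stops
trailing non-homozygous calls from inflating run length.

``scan_chromosome`` is the production scanner (linear-time, vectorised);
``brute_force_scan`` enumerates every O(n^2) window and applies the same
rules literally, serving as an independent oracle in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeDataset, ROH_TABLE_COLUMNS

logger = logging.getLogger(__name__)

# default calling parameters: >= 1 Mb, >= 10 SNPs, <= 1 het, <= 5 missing
DEFAULT_MIN_LENGTH_BP = 1_000_000
DEFAULT_MIN_SNPS = 10
DEFAULT_MAX_HET = 1
DEFAULT_MAX_MISS = 5


@dataclass(frozen=True)
class ROHParams:
    """Thresholds defining a callable run of homozygosity."""

    min_length_bp: int = DEFAULT_MIN_LENGTH_BP
    min_snps: int = DEFAULT_MIN_SNPS
    max_het: int = DEFAULT_MAX_HET
    max_miss: int = DEFAULT_MAX_MISS

    def __post_init__(self) -> None:
        if min(self.min_length_bp, self.min_snps, self.max_het, self.max_miss) < 0:
            raise ValueError("ROH parameters must be non-negative")
        if self.min_snps < 2:
            raise ValueError("min_snps must be >= 2 (a run needs two homozygous endpoints)")


@dataclass(frozen=True)
class ROH:
    """One detected run: 1-based inclusive bp interval on one chromosome."""

    animal_id: str
    chrom: int
    start_bp: int
    end_bp: int
    start_idx: int
    end_idx: int
    n_snps: int
    n_het: int
    n_miss: int

    @property
    def length_bp(self) -> int:
        """Span between first and last marker of the run."""
        return self.end_bp - self.start_bp

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6

    def key(self) -> tuple:
        return (self.chrom, self.start_idx, self.end_idx)


@dataclass
class ROHSet:
    """All runs detected in a population with the parameters used."""

    rohs: list[ROH]
    params: ROHParams
    map_fingerprint: str
    animal_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rohs)

    def __iter__(self):
        return iter(self.rohs)

    def to_frame(self):
        import pandas as pd

        rows = sorted(self.rohs, key=lambda r: (r.animal_id, r.chrom, r.start_bp))
        return pd.DataFrame(
            [
                (r.animal_id, r.chrom, r.start_bp, r.end_bp, r.length_bp,
                 r.n_snps, r.n_het, r.n_miss)
                for r in rows
            ],
            columns=ROH_TABLE_COLUMNS,
        )


def _check_inputs(calls: np.ndarray, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    calls = np.asarray(calls)
    positions = np.asarray(positions, dtype=np.int64)
    if calls.shape != positions.shape or calls.ndim != 1:
        raise ValueError("calls and positions must be 1-D arrays of equal length")
    if len(positions) > 1 and np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    return calls, positions


def _resolve_overlaps_greedy(cands: list[tuple[int, int]], positions: np.ndarray) -> list[tuple[int, int]]:
    """Longest-in-bp-first greedy selection; ties break to the leftmost."""
    order = sorted(cands, key=lambda w: (-(positions[w[1]] - positions[w[0]]), w[0]))
    kept: list[tuple[int, int]] = []
    for i, j in order:
        if all(j < ki or i > kj for ki, kj in kept):
            kept.append((i, j))
    kept.sort()
    return kept


def _window_rohs(
    windows: list[tuple[int, int]],
    positions: np.ndarray,
    het_cum: np.ndarray,
    miss_cum: np.ndarray,
    animal_id: str,
    chrom: int,
) -> list[ROH]:
    out = []
    for i, j in windows:
        out.append(
            ROH(
                animal_id=animal_id,
                chrom=chrom,
                start_bp=int(positions[i]),
                end_bp=int(positions[j]),
                start_idx=i,
                end_idx=j,
                n_snps=j - i + 1,
                n_het=int(het_cum[j + 1] - het_cum[i]),
                n_miss=int(miss_cum[j + 1] - miss_cum[i]),
            )
        )
    return out


def scan_chromosome(
    calls: np.ndarray,
    positions: np.ndarray,
    p: ROHParams,
    animal_id: str = "",
    chrom: int = 1,
) -> list[ROH]:
    """Detect ROH on one animal-chromosome.

    Linear-time construction of the inclusion-maximal valid windows:
    for each start marker the heterozygous/missing budgets give a
    furthest admissible end (monotone in the start, hence computable
    with prefix sums and ``searchsorted``); pulling that end back to the
    last homozygous marker and keeping, for each distinct end, the
    smallest homozygous start yields exactly the maximal windows.
    Overlaps are then resolved longest-first.
    """
    calls, positions = _check_inputs(calls, positions)
    n = len(calls)
    if n == 0:
        return []

    hom = (calls == 0) | (calls == 2)
    het_cum = np.concatenate([[0], np.cumsum(calls == 1)])
    miss_cum = np.concatenate([[0], np.cumsum(calls == -1)])
    hom_idx = np.flatnonzero(hom)
    if len(hom_idx) == 0:
        return []

    # furthest end index admissible from each start under both budgets
    j_het = np.searchsorted(het_cum, het_cum[:-1] + p.max_het, side="right") - 2
    j_miss = np.searchsorted(miss_cum, miss_cum[:-1] + p.max_miss, side="right") - 2
    j_budget = np.minimum(j_het, j_miss)

    starts = hom_idx
    r = np.searchsorted(hom_idx, j_budget[starts], side="right") - 1
    ok = r >= 0
    starts, r = starts[ok], r[ok]
    jstar = hom_idx[r]
    ok = jstar >= starts
    starts, jstar = starts[ok], jstar[ok]
    if len(starts) == 0:
        return []

    # smallest homozygous start per distinct maximal end
    first = np.ones(len(starts), dtype=bool)
    first[1:] = jstar[1:] != jstar[:-1]
    starts, jstar = starts[first], jstar[first]

    span = positions[jstar] - positions[starts]
    snps = jstar - starts + 1
    ok = (span >= p.min_length_bp) & (snps >= p.min_snps)
    cands = list(zip(starts[ok].tolist(), jstar[ok].tolist()))
    kept = _resolve_overlaps_greedy(cands, positions)
    return _window_rohs(kept, positions, het_cum, miss_cum, animal_id, chrom)


def brute_force_scan(
    calls: np.ndarray,
    positions: np.ndarray,
    p: ROHParams,
    animal_id: str = "",
    chrom: int = 1,
) -> list[ROH]:
    """Reference scanner: enumerate all O(n^2) windows literally.

    Keeps every valid window, discards windows contained in another
    valid window, then resolves overlaps by repeatedly popping the
    longest-in-bp survivor (ties to the leftmost).  No attention is paid
    to efficiency; this exists as an independent oracle.
    """
    calls, positions = _check_inputs(calls, positions)
    n = len(calls)
    if n == 0:
        return []

    hom = (calls == 0) | (calls == 2)
    het_cum = np.concatenate([[0], np.cumsum(calls == 1)])
    miss_cum = np.concatenate([[0], np.cumsum(calls == -1)])

    # validity of every window [i, j], j >= i
    het_w = het_cum[None, 1:] - het_cum[:-1, None]
    miss_w = miss_cum[None, 1:] - miss_cum[:-1, None]
    span_w = positions[None, :] - positions[:, None]
    snps_w = np.arange(n)[None, :] - np.arange(n)[:, None] + 1
    valid = (
        (snps_w >= 1)
        & hom[:, None]
        & hom[None, :]
        & (het_w <= p.max_het)
        & (miss_w <= p.max_miss)
        & (span_w >= p.min_length_bp)
        & (snps_w >= p.min_snps)
    )
    if not valid.any():
        return []

    # window (i, j) is dominated iff some *other* valid window (i', j')
    # has i' <= i and j' >= j
    min_start = np.where(valid.any(axis=0), valid.argmax(axis=0), n)  # per end j
    # strictly-after-j minimum of min_start
    suffix_after = np.concatenate(
        [np.minimum.accumulate(min_start[::-1])[::-1][1:], [n]]
    )
    ii = np.arange(n)
    mask = valid & (ii[:, None] == min_start[None, :]) & (ii[:, None] < suffix_after[None, :])
    maximal = [(int(i), int(j)) for i, j in zip(*np.nonzero(mask))]

    # overlap resolution, written as the literal repeatedly-pop-longest loop
    pool = list(maximal)
    kept: list[tuple[int, int]] = []
    while pool:
        best = min(pool, key=lambda w: (-(positions[w[1]] - positions[w[0]]), w[0]))
        kept.append(best)
        pool = [w for w in pool if w[1] < best[0] or w[0] > best[1]]
    kept.sort()
    return _window_rohs(kept, positions, het_cum, miss_cum, animal_id, chrom)


def call_roh(ds: GenotypeDataset, p: ROHParams | None = None) -> ROHSet:
    """Detect ROH for every animal on every autosome of a (QC'd) dataset."""
    if p is None:
        p = ROHParams()
    rohs: list[ROH] = []
    per_chrom: dict[int, int] = {}
    for c, sl in ds.markers.iter_chromosomes():
        positions = ds.markers.pos_bp[sl]
        block = ds.calls[:, sl]
        n_c = 0
        for a, animal in enumerate(ds.animal_ids):
            found = scan_chromosome(block[a], positions, p, animal_id=animal, chrom=c)
            rohs.extend(found)
            n_c += len(found)
        per_chrom[c] = n_c
        logger.info("call_roh: chromosome %d -> %d ROH", c, n_c)
    return ROHSet(
        rohs=rohs,
        params=p,
        map_fingerprint=ds.markers.fingerprint(),
        animal_ids=list(ds.animal_ids),
    )
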