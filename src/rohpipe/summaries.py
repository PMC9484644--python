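"""Descriptive ROH statistics and the genomic inbreeding coefficient.

Froh follows McQuillan's covered-genome convention: the fraction of the
SNP-covered autosomal span (sum over chromosomes of last-minus-first
marker bp) lying inside an animal's ROH.  The denominator is identical
for every animal genotyped on one map, and is *not* a fixed 2.5 Gb
constant, so the coefficient is invariant to array redesigns.

Length classes are left-closed, right-open Mb bins with an unbounded
last bin.  Two presets are provided: the nine descriptive classes
(1-2, 2-4, ..., 14-16, >16) and the six classes used by the
association model (1-2, 2-4, 4-6, 6-8, 8-16, >16).

"Identical ROH" across animals means identical first and last marker
index on the same chromosome (exact coordinate sharing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import ROHSet
from .io import MarkerMap


@dataclass(frozen=True)
class FrohTable:
    """Per-animal Froh with its numerator and (shared) denominator."""

    table: pd.DataFrame  # animal_id, sum_roh_bp, l_aut_bp, froh

    def __post_init__(self) -> None:
        t = self.table
        needed = {"animal_id", "sum_roh_bp", "l_aut_bp", "froh"}
        if not needed <= set(t.columns):
            raise ValueError(f"FrohTable requires columns {sorted(needed)}")
        if len(t) and t["l_aut_bp"].nunique() != 1:
            raise ValueError("l_aut_bp must be identical for all animals")

    def froh(self) -> pd.Series:
        return pd.Series(
            self.table["froh"].to_numpy(),
            index=pd.Index(self.table["animal_id"], name="animal_id"),
            name="froh",
        )


@dataclass(frozen=True)
class LengthClassScheme:
    """Ordered Mb bin edges; bin k is [edge_k, edge_{k+1}), last unbounded."""

    edges_mb: tuple[float, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        e = self.edges_mb
        if len(e) < 1 or any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("edges must be non-empty and strictly increasing")

    @property
    def labels(self) -> list[str]:
        e = self.edges_mb
        out = [f"{_fmt(a)}-{_fmt(b)}" for a, b in zip(e, e[1:])]
        out.append(f">{_fmt(e[-1])}")
        return out

    def assign(self, lengths_mb: np.ndarray) -> np.ndarray:
        """Class index per length; raises below the first edge."""
        lengths_mb = np.asarray(lengths_mb, dtype=float)
        if len(lengths_mb) and lengths_mb.min() < self.edges_mb[0]:
            raise ValueError(
                f"ROH shorter than the first class edge ({self.edges_mb[0]} Mb)"
            )
        return np.searchsorted(np.asarray(self.edges_mb), lengths_mb, side="right") - 1


def _fmt(x: float) -> str:
    return f"{x:g}"


#: nine descriptive length classes
TABLE_SCHEME = LengthClassScheme((1, 2, 4, 6, 8, 10, 12, 14, 16), name="table2")
#: six classes used in the association model
MODEL_SCHEME = LengthClassScheme((1, 2, 4, 6, 8, 16), name="model")

SCHEMES = {"table2": TABLE_SCHEME, "model": MODEL_SCHEME}


@dataclass(frozen=True)
class DistinctROH:
    """One exact ROH coordinate shared by one or more carrier animals."""

    chrom: int
    start_bp: int
    end_bp: int
    start_idx: int
    end_idx: int
    carrier_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.carrier_ids) < 1:
            raise ValueError("a distinct ROH needs at least one carrier")
        if len(set(self.carrier_ids)) != len(self.carrier_ids):
            raise ValueError("carrier ids must be unique")

    @property
    def carrier_count(self) -> int:
        return len(self.carrier_ids)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


def compute_froh(rohs: ROHSet, marker_map: MarkerMap) -> FrohTable:
    """Froh per animal: sum of its ROH lengths over the covered autosome span.

    Animals carried in ``rohs.animal_ids`` but without any ROH get 0.
    """
    l_aut = marker_map.l_aut_bp()
    sums: dict[str, int] = {a: 0 for a in rohs.animal_ids}
    for r in rohs:
        sums.setdefault(r.animal_id, 0)
        sums[r.animal_id] += r.length_bp
    animals = list(sums)
    sum_bp = np.array([sums[a] for a in animals], dtype=np.int64)
    table = pd.DataFrame(
        {
            "animal_id": animals,
            "sum_roh_bp": sum_bp,
            "l_aut_bp": l_aut,
            "froh": sum_bp / l_aut,
        }
    )
    return FrohTable(table)


def bin_by_length(rohs: ROHSet, scheme: LengthClassScheme) -> pd.DataFrame:
    """Count, percentage and mean length (Mb) of ROH per length class."""
    lengths = np.array([r.length_mb for r in rohs], dtype=float)
    idx = scheme.assign(lengths)
    n_classes = len(scheme.labels)
    counts = np.bincount(idx, minlength=n_classes) if len(lengths) else np.zeros(n_classes, int)
    mean_len = np.full(n_classes, np.nan)
    for k in range(n_classes):
        in_k = lengths[idx == k] if len(lengths) else np.array([])
        if len(in_k):
            mean_len[k] = in_k.mean()
    total = counts.sum()
    pct = counts / total * 100.0 if total else np.zeros(n_classes)
    return pd.DataFrame(
        {
            "length_class": scheme.labels,
            "count": counts,
            "percentage": pct,
            "mean_length_mb": mean_len,
        }
    )


def per_animal_summary(rohs: ROHSet) -> tuple[pd.DataFrame, dict]:
    """Per-animal ROH count and length stats plus population mean/SD.

    Animals with no ROH appear with ``n_roh`` 0 and NaN length fields.
    """
    per: dict[str, list[float]] = {a: [] for a in rohs.animal_ids}
    for r in rohs:
        per.setdefault(r.animal_id, [])
        per[r.animal_id].append(r.length_mb)
    rows = []
    for a, lens in per.items():
        arr = np.asarray(lens)
        rows.append(
            {
                "animal_id": a,
                "n_roh": len(arr),
                "mean_length_mb": arr.mean() if len(arr) else np.nan,
                "min_length_mb": arr.min() if len(arr) else np.nan,
                "max_length_mb": arr.max() if len(arr) else np.nan,
                "sum_length_mb": arr.sum(),
            }
        )
    df = pd.DataFrame(rows)
    n_roh = df["n_roh"].to_numpy(dtype=float) if len(df) else np.array([])
    all_lengths = np.array([r.length_mb for r in rohs])
    pop = {
        "n_animals": len(df),
        "n_animals_with_roh": int((n_roh > 0).sum()) if len(df) else 0,
        "mean_roh_per_animal": float(n_roh.mean()) if len(df) else 0.0,
        "sd_roh_per_animal": float(n_roh.std(ddof=1)) if len(df) > 1 else 0.0,
        "mean_length_mb": float(all_lengths.mean()) if len(all_lengths) else np.nan,
        "sd_length_mb": float(all_lengths.std(ddof=1)) if len(all_lengths) > 1 else np.nan,
        "min_length_mb": float(all_lengths.min()) if len(all_lengths) else np.nan,
        "max_length_mb": float(all_lengths.max()) if len(all_lengths) else np.nan,
    }
    return df, pop


def _union_bp(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by a union of closed intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def per_chromosome_summary(rohs: ROHSet, marker_map: MarkerMap) -> pd.DataFrame:
    """Per-chromosome ROH count, share of total, mean length and coverage.

    ``pct_covered`` is the population-level proportion of the chromosome
    in ROH: the mean over animals of (per-animal union of ROH bp on the
    chromosome / chromosome SNP-covered span) x 100.
    """
    chroms_present = sorted({r.chrom for r in rohs})
    map_chroms = set(int(c) for c in marker_map.chromosomes())
    missing = [c for c in chroms_present if c not in map_chroms]
    if missing:
        raise ValueError(f"chromosomes {missing} present in ROHSet but absent from map")
    animals = rohs.animal_ids or sorted({r.animal_id for r in rohs})
    n_animals = len(animals)
    total = len(rohs)
    rows = []
    for c in sorted(map_chroms):
        on_c = [r for r in rohs if r.chrom == c]
        span = marker_map.chrom_span_bp(c)
        by_animal: dict[str, list[tuple[int, int]]] = {}
        for r in on_c:
            by_animal.setdefault(r.animal_id, []).append((r.start_bp, r.end_bp))
        if n_animals:
            cov = sum(_union_bp(v) / span for v in by_animal.values()) / n_animals * 100.0
        else:
            cov = 0.0
        lengths = np.array([r.length_mb for r in on_c])
        rows.append(
            {
                "chrom": c,
                "n_roh": len(on_c),
                "pct_of_total": len(on_c) / total * 100.0 if total else 0.0,
                "mean_length_mb": lengths.mean() if len(lengths) else np.nan,
                "pct_covered": cov,
            }
        )
    return pd.DataFrame(rows)


def group_identical_roh(rohs: ROHSet) -> tuple[list[DistinctROH], dict]:
    """Group ROH shared at identical (chrom, start_idx, end_idx) coordinates.

    Returns the distinct coordinates with their carriers, plus instance
    counts: ``n_unique`` ROH occur in exactly one animal, ``n_repeated``
    belong to coordinates carried by two or more animals.
    """
    groups: dict[tuple, list] = {}
    for r in rohs:
        groups.setdefault(r.key(), []).append(r)
    distinct = []
    n_unique = n_repeated = 0
    for key in sorted(groups):
        members = groups[key]
        carriers = tuple(dict.fromkeys(m.animal_id for m in members))
        if len(carriers) != len(members):
            # same animal cannot carry one coordinate twice (runs are
            # non-overlapping within an animal-chromosome)
            raise ValueError(f"duplicate ROH for one animal at {key}")
        r0 = members[0]
        distinct.append(
            DistinctROH(
                chrom=r0.chrom,
                start_bp=r0.start_bp,
                end_bp=r0.end_bp,
                start_idx=r0.start_idx,
                end_idx=r0.end_idx,
                carrier_ids=carriers,
            )
        )
        if len(members) == 1:
            n_unique += 1
        else:
            n_repeated += len(members)
    return distinct, {"n_unique": n_unique, "n_repeated": n_repeated}


def distinct_to_frame(distinct: list[DistinctROH]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom,
                "start_bp": d.start_bp,
                "end_bp": d.end_bp,
                "length_bp": d.length_bp,
                "length_mb": d.length_mb,
                "carrier_count": d.carrier_count,
            }
            for d in distinct
        ],
        columns=["chrom", "start_bp", "end_bp", "length_bp", "length_mb", "carrier_count"],
    )
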