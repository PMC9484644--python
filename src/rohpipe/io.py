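"""PLINK text-format genotype I/O and result-table writers.

Genotypes are held in memory as an animals x markers matrix of small
integer codes:

====  =========================================
code  meaning
====  =========================================
 0    homozygous for the per-marker major allele
 1    heterozygous
 2    homozygous for the minor allele
-1    missing call
====  =========================================

Allele polarity (which homozygote is coded 0) never matters downstream:
ROH calling and quality control only look at hom/het/missing status and
at the folded allele frequency.  ``read_plink`` canonicalises polarity to
major-allele-as-0, so ``read(write(read(f))) == read(f)`` always holds;
a dataset constructed by hand with the minor allele coded 0 at some
marker comes back polarity-flipped at that marker.

Only autosomes BTA 1..29 are retained; markers on any other chromosome
are dropped at read time with a logged count.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterator, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .detect import ROHSet

logger = logging.getLogger(__name__)

AUTOSOMES = frozenset(range(1, 30))

ROH_TABLE_COLUMNS = [
    "animal_id",
    "chrom",
    "start_bp",
    "end_bp",
    "length_bp",
    "n_snps",
    "n_het",
    "n_miss",
]


class PlinkParseError(ValueError):
    """Raised when a PED/MAP file pair is malformed."""


@dataclass(frozen=True)
class MarkerMap:
    """Marker map for autosomes 1..29, globally sorted by (chrom, bp).

    Positions are 1-based bp and strictly increasing within each
    chromosome; marker ids are unique.
    """

    chrom: np.ndarray
    marker_id: np.ndarray
    pos_bp: np.ndarray

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chrom, dtype=np.int64)
        pos = np.asarray(self.pos_bp, dtype=np.int64)
        ids = np.asarray(self.marker_id, dtype=object)
        if not (len(chrom) == len(pos) == len(ids)):
            raise ValueError("chrom, marker_id and pos_bp must have equal length")
        if len(chrom) and not set(np.unique(chrom)) <= AUTOSOMES:
            raise ValueError("marker map may only contain autosomes 1..29")
        if len(pos) and pos.min() < 1:
            raise ValueError("positions must be >= 1 (1-based bp)")
        # global (chrom, pos) sort order with strict increase within chrom
        if len(chrom) > 1:
            same = chrom[1:] == chrom[:-1]
            if np.any(chrom[1:] < chrom[:-1]) or np.any(same & (pos[1:] <= pos[:-1])):
                raise ValueError(
                    "markers must be sorted by (chrom, pos) with strictly "
                    "increasing positions within each chromosome"
                )
        if len(ids) != len(set(ids)):
            raise ValueError("marker ids must be unique")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos_bp", pos)
        object.__setattr__(self, "marker_id", ids)

    @property
    def n_markers(self) -> int:
        return len(self.chrom)

    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chrom)

    def chrom_slice(self, c: int) -> slice:
        """Index slice of chromosome ``c`` in the globally sorted arrays."""
        lo = int(np.searchsorted(self.chrom, c, side="left"))
        hi = int(np.searchsorted(self.chrom, c, side="right"))
        return slice(lo, hi)

    def iter_chromosomes(self) -> Iterator[tuple[int, slice]]:
        for c in self.chromosomes():
            yield int(c), self.chrom_slice(int(c))

    def chrom_span_bp(self, c: int) -> int:
        """SNP-covered span of chromosome ``c``: last minus first marker bp."""
        s = self.chrom_slice(c)
        if s.start == s.stop:
            raise ValueError(f"chromosome {c} absent from map")
        return int(self.pos_bp[s.stop - 1] - self.pos_bp[s.start])

    def l_aut_bp(self) -> int:
        """Total SNP-covered autosome length (Froh denominator)."""
        if self.n_markers == 0:
            raise ValueError("empty marker map")
        return sum(self.chrom_span_bp(int(c)) for c in self.chromosomes())

    def fingerprint(self) -> str:
        h = hashlib.sha1()
        h.update(self.chrom.tobytes())
        h.update(self.pos_bp.tobytes())
        return h.hexdigest()[:16]

    def take(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.chrom[idx], self.marker_id[idx], self.pos_bp[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "marker_id": self.marker_id.astype(str),
                "pos_bp": self.pos_bp,
            }
        )


@dataclass
class GenotypeDataset:
    """Animals x markers genotype call matrix plus its marker map."""

    animal_ids: list[str]
    markers: MarkerMap
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=np.int8)
        self.animal_ids = [str(a) for a in self.animal_ids]
        if len(self.animal_ids) != len(set(self.animal_ids)):
            raise ValueError("animal ids must be unique")
        if calls.shape != (len(self.animal_ids), self.markers.n_markers):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.animal_ids)} animals x {self.markers.n_markers} markers"
            )
        bad = ~np.isin(calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        self.calls = calls

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return self.markers.n_markers

    def take_animals(self, idx: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeDataset(
            [self.animal_ids[i] for i in idx], self.markers, self.calls[idx]
        )

    def take_markers(self, idx: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeDataset(self.animal_ids, self.markers.take(idx), self.calls[:, idx])

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.animal_ids == other.animal_ids
            and np.array_equal(self.markers.chrom, other.markers.chrom)
            and np.array_equal(self.markers.pos_bp, other.markers.pos_bp)
            and list(self.markers.marker_id) == list(other.markers.marker_id)
            and np.array_equal(self.calls, other.calls)
        )


def _read_map(map_path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        dtype=str,
        comment=None,
    )
    if df.shape[1] != 4:
        raise PlinkParseError(
            f"{map_path}: expected 4 whitespace-separated MAP columns "
            f"(chrom, id, cM, bp), found {df.shape[1]}"
        )
    df.columns = ["chrom", "marker_id", "cm", "pos_bp"]
    return df


def read_plink(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read a PED/MAP pair into a :class:`GenotypeDataset`.

    The MAP file has 4 whitespace-separated columns (chrom, id, cM, bp);
    the PED file has 6 leading columns then two allele columns per
    marker, with "0" denoting a missing allele.  Markers are returned
    sorted by (chromosome, position); non-autosomal markers are dropped.
    Per marker, the major allele is mapped to code 0 (frequency ties
    break to the lexicographically smaller allele).
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    raw = _read_map(map_path)

    chrom_num = pd.to_numeric(raw["chrom"], errors="coerce")
    keep = chrom_num.isin(list(AUTOSOMES))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_plink: dropped %d non-autosomal markers", n_dropped)
    raw = raw[keep].copy()
    raw["chrom"] = chrom_num[keep].astype(np.int64)
    raw["pos_bp"] = pd.to_numeric(raw["pos_bp"]).astype(np.int64)
    # remember original file column for each retained marker, then sort
    raw["file_idx"] = np.arange(len(keep))[keep.to_numpy()]
    raw = raw.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)

    n_map_markers = len(keep)  # markers as listed in the MAP file
    expected_tokens = 6 + 2 * n_map_markers

    animal_ids: list[str] = []
    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != expected_tokens:
                raise PlinkParseError(
                    f"{ped_path} line {lineno}: expected {expected_tokens} "
                    f"fields (6 + 2 x {n_map_markers} markers), found {len(tokens)}"
                )
            animal_ids.append(tokens[1])
            rows.append(tokens[6:])

    n_animals = len(animal_ids)
    M = len(raw)
    calls = np.full((n_animals, M), -1, dtype=np.int8)
    if n_animals and M:
        tok = np.asarray(rows, dtype=object)
        a1_all = tok[:, 0::2]
        a2_all = tok[:, 1::2]
        for out_col, file_idx, marker_id in zip(
            range(M), raw["file_idx"].to_numpy(), raw["marker_id"].to_numpy()
        ):
            a1 = a1_all[:, file_idx]
            a2 = a2_all[:, file_idx]
            miss = (a1 == "0") | (a2 == "0")
            obs = np.concatenate([a1[~miss], a2[~miss]])
            alleles, counts = np.unique(obs, return_counts=True)
            if len(alleles) > 2:
                raise PlinkParseError(
                    f"marker {marker_id}: more than 2 distinct alleles "
                    f"({', '.join(map(str, alleles))})"
                )
            if len(alleles) == 0:
                continue  # all missing
            # major allele -> code 0; ties -> lexicographically smaller
            order = np.lexsort((alleles, -counts))
            major = alleles[order[0]]
            code = (a1 != major).astype(np.int8) + (a2 != major).astype(np.int8)
            code[miss] = -1
            calls[:, out_col] = code

    markers = MarkerMap(
        raw["chrom"].to_numpy(),
        raw["marker_id"].to_numpy(dtype=object),
        raw["pos_bp"].to_numpy(),
    )
    return GenotypeDataset(animal_ids, markers, calls)


_CODE_TO_ALLELES = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B"), -1: ("0", "0")}


def write_plink(ds: GenotypeDataset, ped_path: str | Path, map_path: str | Path) -> None:
    """Write a dataset as a PED/MAP pair re-readable by :func:`read_plink`.

    Code 0 is written as allele "A", code 2 as "B" and missing as "0 0".
    """
    with open(map_path, "w") as fh:
        for c, mid, pos in zip(ds.markers.chrom, ds.markers.marker_id, ds.markers.pos_bp):
            fh.write(f"{c}\t{mid}\t0\t{pos}\n")
    pair = np.empty((4, 2), dtype=object)
    for code, alleles in _CODE_TO_ALLELES.items():
        pair[code] = alleles
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(ds.animal_ids):
            lead = [animal, animal, "0", "0", "0", "-9"]
            geno = pair[ds.calls[i]].ravel()
            fh.write(" ".join(lead) + (" " if len(geno) else "") + " ".join(geno) + "\n")


def write_roh_table(rohs: "ROHSet", path: str | Path) -> None:
    """Write a ROH collection as TSV (1-based inclusive bp coordinates)."""
    rohs.to_frame().to_csv(path, sep="\t", index=False)


def read_roh_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_roh_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
    missing = [c for c in ROH_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing ROH table columns {missing}")
    return df
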