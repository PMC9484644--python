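"""Genotype quality control: animal call rate, SNP call rate / MAF / HWE.

Filters follow the usual SNP-array protocol for this kind of study:
animals with call rate < 0.90 are removed first, then SNP metrics are
recomputed on the retained animals and SNPs failing call rate < 0.90,
minor allele frequency < 0.02 or a Hardy-Weinberg exact-test p-value
< 1e-4 are removed, in a single (non-iterated) pass.

The Hardy-Weinberg test is the conditional exact test with probability
ordering: conditional on the observed allele counts, the two-sided
p-value is the total conditional probability of every heterozygote
count whose probability does not exceed that of the observed count.
It is computed in exact integer arithmetic so that ties in the
conditional distribution are handled without floating-point ambiguity.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import accumulate
from math import comb

import numpy as np
import pandas as pd

from .io import GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Inclusion thresholds; records failing any are removed."""

    min_animal_call_rate: float = 0.90
    min_snp_call_rate: float = 0.90
    min_maf: float = 0.02
    min_hwe_p: float = 1e-4

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    """What was removed and why; counts reconcile with dataset shapes."""

    animals_removed: pd.DataFrame  # animal_id, call_rate
    snps_removed: pd.DataFrame  # marker_id, reason, value
    n_animals_before: int
    n_animals_after: int
    n_snps_before: int
    n_snps_after: int
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def summary(self) -> dict:
        return {
            "n_animals_before": self.n_animals_before,
            "n_animals_after": self.n_animals_after,
            "n_animals_removed": int(len(self.animals_removed)),
            "n_snps_before": self.n_snps_before,
            "n_snps_after": self.n_snps_after,
            "n_snps_removed": int(len(self.snps_removed)),
            "snps_removed_by_reason": {
                k: int(v)
                for k, v in self.snps_removed["reason"].value_counts().items()
            },
            "thresholds": dict(self.thresholds.__dict__),
        }

    def to_tsv(self, path) -> None:
        rows = [
            {"record": "animal", "id": r.animal_id, "reason": "call_rate", "value": r.call_rate}
            for r in self.animals_removed.itertuples()
        ] + [
            {"record": "snp", "id": r.marker_id, "reason": r.reason, "value": r.value}
            for r in self.snps_removed.itertuples()
        ]
        pd.DataFrame(rows, columns=["record", "id", "reason", "value"]).to_csv(
            path, sep="\t", index=False
        )


def compute_animal_call_rates(ds: GenotypeDataset) -> pd.Series:
    """Fraction of non-missing calls per animal."""
    if ds.n_markers == 0:
        raise ValueError("cannot compute call rates on a dataset with zero markers")
    rates = (ds.calls >= 0).mean(axis=1)
    return pd.Series(rates, index=pd.Index(ds.animal_ids, name="animal_id"), name="call_rate")


@lru_cache(maxsize=None)
def _hwe_pvalues(n: int, n_minor: int) -> dict[int, float]:
    """Exact-test p-value for every heterozygote count compatible with
    ``n`` genotyped individuals carrying ``n_minor`` minor alleles.

    Conditional weights w(h) = n! * 2^h / (n_AA! * h! * n_aa!) are built
    by the exact integer recurrence w(h-2) = w(h)*h*(h-1) // (4*(n_AA+1)*(n_aa+1))
    from the largest compatible h downward; p(h) is the tie-inclusive
    lower tail of the weight ordering.
    """
    h_max = min(n_minor, 2 * n - n_minor)
    hs = list(range(h_max, -1, -2))  # same parity as n_minor, descending
    # start weight at h_max
    a = (2 * n - n_minor - h_max) // 2  # major homozygotes
    c = (n_minor - h_max) // 2  # minor homozygotes
    w = comb(n, a) * comb(n - a, h_max) * (1 << h_max)
    weights = {h_max: w}
    for h in hs[:-1]:
        a = (2 * n - n_minor - h) // 2
        c = (n_minor - h) // 2
        w = w * h * (h - 1) // (4 * (a + 1) * (c + 1))
        weights[h - 2] = w
    total = sum(weights.values())
    ordered = sorted(weights.values())
    prefix = list(accumulate(ordered))
    out = {}
    for h, wh in weights.items():
        k = bisect_right(ordered, wh)
        out[h] = prefix[k - 1] / total
    return out


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided conditional exact Hardy-Weinberg test.

    Returns the summed conditional probability, given the allele counts,
    of all heterozygote counts at most as probable as the observed one.
    The result is in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotyped individual is required")
    n_minor = min(2 * n_AA + n_Aa, n_Aa + 2 * n_aa)
    return _hwe_pvalues(n, n_minor)[n_Aa]


def compute_snp_metrics(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-marker call rate, folded minor allele frequency and HWE p.

    Markers with zero non-missing calls get call_rate 0, maf 0, hwe_p 1.
    """
    if ds.n_animals == 0:
        raise ValueError("cannot compute SNP metrics on a dataset with zero animals")
    calls = ds.calls
    n0 = (calls == 0).sum(axis=0)
    n1 = (calls == 1).sum(axis=0)
    n2 = (calls == 2).sum(axis=0)
    n_obs = n0 + n1 + n2
    call_rate = n_obs / ds.n_animals
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.where(n_obs > 0, (2 * n0 + n1) / np.maximum(2 * n_obs, 1), 0.0)
    maf = np.where(n_obs > 0, np.minimum(p0, 1.0 - p0), 0.0)
    hwe_p = np.ones(ds.n_markers)
    for m in range(ds.n_markers):
        if n_obs[m] > 0:
            hwe_p[m] = hwe_exact_test(int(n0[m]), int(n1[m]), int(n2[m]))
    return pd.DataFrame(
        {"call_rate": call_rate, "maf": maf, "hwe_p": hwe_p},
        index=pd.Index(ds.markers.marker_id.astype(str), name="marker_id"),
    )


def apply_qc(
    ds: GenotypeDataset, t: QCThresholds | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Animal filter, then SNP filter on the retained animals.

    SNP removal reasons are assigned in the order call_rate, maf, hwe
    (the first failing rule wins).  Raises if no animal survives.
    """
    if t is None:
        t = QCThresholds()
    animal_rates = compute_animal_call_rates(ds)
    keep_animals = animal_rates.to_numpy() >= t.min_animal_call_rate
    animals_removed = pd.DataFrame(
        {
            "animal_id": [a for a, k in zip(ds.animal_ids, keep_animals) if not k],
            "call_rate": animal_rates.to_numpy()[~keep_animals],
        }
    )
    if not keep_animals.any():
        raise ValueError("empty dataset after QC: all animals removed")
    ds_a = ds.take_animals(np.flatnonzero(keep_animals))

    metrics = compute_snp_metrics(ds_a)
    reasons = np.full(ds_a.n_markers, "", dtype=object)
    values = np.zeros(ds_a.n_markers)
    cr = metrics["call_rate"].to_numpy()
    maf = metrics["maf"].to_numpy()
    hwe = metrics["hwe_p"].to_numpy()
    fail_cr = cr < t.min_snp_call_rate
    fail_maf = maf < t.min_maf
    fail_hwe = hwe < t.min_hwe_p
    reasons[fail_hwe] = "hwe"
    values[fail_hwe] = hwe[fail_hwe]
    reasons[fail_maf] = "maf"
    values[fail_maf] = maf[fail_maf]
    reasons[fail_cr] = "call_rate"
    values[fail_cr] = cr[fail_cr]
    fail_any = fail_cr | fail_maf | fail_hwe
    snps_removed = pd.DataFrame(
        {
            "marker_id": ds_a.markers.marker_id[fail_any].astype(str),
            "reason": reasons[fail_any],
            "value": values[fail_any],
        }
    )
    ds_qc = ds_a.take_markers(np.flatnonzero(~fail_any))
    report = QCReport(
        animals_removed=animals_removed,
        snps_removed=snps_removed,
        n_animals_before=ds.n_animals,
        n_animals_after=ds_qc.n_animals,
        n_snps_before=ds.n_markers,
        n_snps_after=ds_qc.n_markers,
        thresholds=t,
    )
    logger.info(
        "apply_qc: animals %d -> %d, SNPs %d -> %d",
        ds.n_animals, ds_qc.n_animals, ds.n_markers, ds_qc.n_markers,
    )
    return ds_qc, report
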