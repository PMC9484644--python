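"""Synthetic genotypes with planted autozygous segments, and phenotypes
generated from the association model with known truth.

The generator emulates a Holstein-style SNP-array cohort: per-marker
minor allele frequencies are uniform on (0.05, 0.5) and background
genotypes are drawn at Hardy-Weinberg proportions, so the background
carries no linkage disequilibrium.  Autozygosity is planted explicitly:
each animal receives a Poisson number of non-overlapping segments with
exponential lengths (mean 4.8 Mb, truncated to 1-100 Mb), inside which
genotypes are homozygous -- the homozygote allele drawn once per
segment-marker by the marker's frequency, approximating a single
inherited haplotype -- apart from a small heterozygous genotyping-error
rate.  Missing calls are applied genome-wide.  The default genome
(5 chromosomes x 100 Mb, 4,000 markers each, 2.4 segments per animal of
truncated-exponential mean 5.8 Mb) gives a true autozygous fraction near
0.028, matching a moderately inbred Holstein cohort.

Phenotypes follow

    y = mu + HY + month + alpha * age + beta1 * Froh
        + sum beta2 * carrier + u + e,

with u ~ N(0, G sigma_a^2) through the genomic relationship matrix and
PTAs simulated as half the genetic value plus independent noise.  Every
realised effect is recorded in the :class:`TruthSet`, so each pipeline
stage can be checked against known truth.

One seed fixes map, genotypes and phenotypes bit-for-bit; the three
stages draw from independently spawned child generators so they can be
re-run separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import build_grm
from .io import GenotypeDataset, MarkerMap
from .summaries import FrohTable

TRAIT_NAMES = ["milk_305d", "fat_305d", "protein_305d", "scs", "final_score"]


@dataclass(frozen=True)
class ChromSpec:
    chrom: int
    length_bp: int
    n_markers: int


@dataclass(frozen=True)
class SegmentLengthDist:
    """Planted-segment length distribution in Mb."""

    dist: str = "exponential"  # or "fixed"
    mean_mb: float = 4.8
    min_mb: float = 1.0
    max_mb: float = 100.0

    def __post_init__(self) -> None:
        if self.dist not in ("exponential", "fixed"):
            raise ValueError("dist must be 'exponential' or 'fixed'")
        if not 0 < self.min_mb <= self.mean_mb <= self.max_mb:
            raise ValueError("need 0 < min_mb <= mean_mb <= max_mb")


@dataclass(frozen=True)
class EffectTemplate:
    """A segment planted in a random carrier subset, with a trait effect."""

    chrom: int
    start_bp: int
    end_bp: int
    carrier_freq: float
    beta2: float
    trait: str = "milk_305d"

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start_bp}-{self.end_bp}"

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class TraitEffects:
    """Generative parameters of one trait (units of the trait)."""

    mu: float
    hy_sd: float
    month_sd: float
    alpha: float  # per month of age at calving
    beta1: float  # per unit Froh
    sigma_a2: float
    sigma_e2: float


def _default_traits() -> dict[str, TraitEffects]:
    # scaled-down dispersions; means follow typical first-lactation
    # Holstein 305-day records
    return {
        "milk_305d": TraitEffects(12743.0, 300.0, 100.0, 15.0, -2500.0, 250_000.0, 250_000.0),
        "fat_305d": TraitEffects(386.0, 10.0, 4.0, 0.5, -80.0, 625.0, 625.0),
        "protein_305d": TraitEffects(356.0, 8.0, 3.0, 0.4, -70.0, 400.0, 400.0),
        "scs": TraitEffects(3.0, 0.15, 0.05, 0.005, 2.0, 0.09, 0.16),
        "final_score": TraitEffects(80.5, 1.0, 0.3, 0.03, -10.0, 2.0, 4.0),
    }


def _default_chromosomes() -> tuple[ChromSpec, ...]:
    return tuple(ChromSpec(c, 100_000_000, 4_000) for c in range(1, 6))


@dataclass(frozen=True)
class SimConfig:
    """Complete, seeded description of one synthetic cohort."""

    seed: int
    n_animals: int = 200
    chromosomes: tuple[ChromSpec, ...] = field(default_factory=_default_chromosomes)
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    segments_per_animal_mean: float = 2.4
    segment_length: SegmentLengthDist = field(default_factory=SegmentLengthDist)
    het_error_rate: float = 0.002
    missing_rate: float = 0.01
    n_herd_years: int = 10
    n_months: int = 12
    age_range_months: tuple[float, float] = (22.0, 40.0)
    trait_effects: dict[str, TraitEffects] = field(default_factory=_default_traits)
    planted_roh_effects: tuple[EffectTemplate, ...] = ()

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        lo, hi = self.allele_freq_range
        if not 0 < lo < hi <= 0.5:
            raise ValueError("allele_freq_range must satisfy 0 < lo < hi <= 0.5")
        for r in (self.het_error_rate, self.missing_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        for t in self.planted_roh_effects:
            lens = {c.chrom: c.length_bp for c in self.chromosomes}
            if t.chrom not in lens or not (1 <= t.start_bp < t.end_bp <= lens[t.chrom]):
                raise ValueError(f"effect template {t.key} outside chromosome bounds")

    def genome_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    def _children(self) -> list[np.random.SeedSequence]:
        return np.random.SeedSequence(self.seed).spawn(3)


@dataclass
class TruthSet:
    """Ground truth of one simulated cohort."""

    animal_ids: list[str]
    segments: dict[str, list[tuple[int, int, int]]]  # animal -> (chrom, start, end)
    true_fraction: dict[str, float]
    effect_carriers: pd.DataFrame  # animals x template keys, bool
    genome_bp: int
    realized: dict = field(default_factory=dict)

    def to_froh_table(self) -> FrohTable:
        """True autozygous fraction presented as a Froh table (denominator =
        full chromosome lengths, not the SNP-covered span)."""
        sums = np.array(
            [sum(e - s for _, s, e in self.segments[a]) for a in self.animal_ids],
            dtype=np.int64,
        )
        return FrohTable(
            pd.DataFrame(
                {
                    "animal_id": self.animal_ids,
                    "sum_roh_bp": sums,
                    "l_aut_bp": self.genome_bp,
                    "froh": sums / self.genome_bp,
                }
            )
        )


def simulate_marker_map(cfg: SimConfig) -> MarkerMap:
    """Uniform marker positions without replacement, sorted, per chromosome."""
    rng = np.random.default_rng(cfg._children()[0])
    chroms, ids, pos = [], [], []
    for spec in sorted(cfg.chromosomes, key=lambda c: c.chrom):
        if spec.n_markers > spec.length_bp:
            raise ValueError(
                f"chromosome {spec.chrom}: {spec.n_markers} markers exceed "
                f"{spec.length_bp} bp"
            )
        if spec.n_markers == 0:
            continue
        chosen = np.unique(rng.integers(1, spec.length_bp + 1, size=spec.n_markers))
        while len(chosen) < spec.n_markers:  # top up rejection-sampled collisions
            extra = rng.integers(1, spec.length_bp + 1, size=spec.n_markers - len(chosen))
            chosen = np.unique(np.concatenate([chosen, extra]))
        chroms.append(np.full(spec.n_markers, spec.chrom, dtype=np.int64))
        pos.append(np.sort(chosen))
        ids.extend(f"snp{spec.chrom}_{k}" for k in range(spec.n_markers))
    if not chroms:
        return MarkerMap(np.array([], int), np.array([], object), np.array([], int))
    return MarkerMap(
        np.concatenate(chroms), np.array(ids, dtype=object), np.concatenate(pos)
    )


def _draw_length_bp(rng: np.random.Generator, d: SegmentLengthDist) -> int:
    if d.dist == "fixed":
        return int(d.mean_mb * 1e6)
    for _ in range(1000):
        x = rng.exponential(d.mean_mb)
        if d.min_mb <= x <= d.max_mb:
            return int(x * 1e6)
    raise RuntimeError("could not draw a segment length inside the truncation bounds")


def _overlaps(s: int, e: int, taken: list[tuple[int, int]]) -> bool:
    return any(s <= te and ts <= e for ts, te in taken)


def simulate_genotypes(
    marker_map: MarkerMap, cfg: SimConfig
) -> tuple[GenotypeDataset, TruthSet]:
    """Hardy-Weinberg background plus planted homozygous segments.

    Effect-template segments are placed first in their drawn carriers;
    each animal then receives its Poisson number of random segments,
    placed without overlap (bounded retries, then an error advising
    smaller segments).  Heterozygous errors are applied inside segments
    at ``het_error_rate``; missing calls genome-wide at ``missing_rate``.
    """
    rng = np.random.default_rng(cfg._children()[1])
    n = cfg.n_animals
    M = marker_map.n_markers
    animals = [f"a{k:04d}" for k in range(n)]
    q = rng.uniform(*cfg.allele_freq_range, size=M)  # minor-allele frequency
    calls = rng.binomial(2, q[None, :], size=(n, M)).astype(np.int8)

    chrom_specs = {c.chrom: c for c in cfg.chromosomes}
    chrom_ids = sorted(c.chrom for c in cfg.chromosomes)
    chrom_lens = np.array([chrom_specs[c].length_bp for c in chrom_ids], dtype=float)
    chrom_w = chrom_lens / chrom_lens.sum()

    carriers = {
        t.key: rng.random(n) < t.carrier_freq for t in cfg.planted_roh_effects
    }
    segments: dict[str, list[tuple[int, int, int]]] = {a: [] for a in animals}
    for i, a in enumerate(animals):
        taken: dict[int, list[tuple[int, int]]] = {}
        for t in cfg.planted_roh_effects:
            if carriers[t.key][i]:
                if _overlaps(t.start_bp, t.end_bp, taken.get(t.chrom, [])):
                    raise ValueError(f"effect templates overlap on chromosome {t.chrom}")
                taken.setdefault(t.chrom, []).append((t.start_bp, t.end_bp))
                segments[a].append((t.chrom, t.start_bp, t.end_bp))
        k = rng.poisson(cfg.segments_per_animal_mean)
        for _ in range(k):
            placed = False
            for _try in range(100):
                length = _draw_length_bp(rng, cfg.segment_length)
                c = int(rng.choice(chrom_ids, p=chrom_w))
                L = chrom_specs[c].length_bp
                if length >= L:
                    continue
                s = int(rng.integers(1, L - length + 1))
                e = s + length
                if not _overlaps(s, e, taken.get(c, [])):
                    taken.setdefault(c, []).append((s, e))
                    segments[a].append((c, s, e))
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    "could not place a planted segment without overlap after 100 "
                    "retries; use smaller or fewer segments"
                )
        segments[a].sort()

    # overwrite in-segment calls with single-haplotype homozygotes
    seg_mask = np.zeros((n, M), dtype=bool)
    for i, a in enumerate(animals):
        for c, s, e in segments[a]:
            sl = marker_map.chrom_slice(c)
            pos = marker_map.pos_bp[sl]
            lo = sl.start + int(np.searchsorted(pos, s, side="left"))
            hi = sl.start + int(np.searchsorted(pos, e, side="right"))
            if hi > lo:
                idx = np.arange(lo, hi)
                calls[i, idx] = np.where(rng.random(hi - lo) < q[idx], 2, 0).astype(np.int8)
                seg_mask[i, idx] = True

    if cfg.het_error_rate > 0:
        flip = (rng.random((n, M)) < cfg.het_error_rate) & seg_mask
        calls[flip] = 1
    if cfg.missing_rate > 0:
        calls[rng.random((n, M)) < cfg.missing_rate] = -1

    true_fraction = {
        a: sum(e - s for _, s, e in segments[a]) / cfg.genome_bp() for a in animals
    }
    effect_carriers = pd.DataFrame(
        {k: v for k, v in carriers.items()},
        index=pd.Index(animals, name="animal_id"),
        dtype=bool,
    )
    ds = GenotypeDataset(animals, marker_map, calls)
    truth = TruthSet(
        animal_ids=animals,
        segments=segments,
        true_fraction=true_fraction,
        effect_carriers=effect_carriers,
        genome_bp=cfg.genome_bp(),
    )
    return ds, truth


def simulate_phenotypes(
    ds: GenotypeDataset,
    truth: TruthSet,
    froh: FrohTable,
    cfg: SimConfig,
    G: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Generate 305-day records and PTAs from the association model.

    ``froh`` supplies the inbreeding covariate entering the generative
    model -- pass the called-ROH table or ``truth.to_froh_table()``.
    Genetic values are u = chol(G) z sigma_a per trait; PTAs are half
    the genetic value plus independent noise.  All realised effects are
    stored in ``truth.realized``.
    """
    rng = np.random.default_rng(cfg._children()[2])
    animals = list(ds.animal_ids)
    n = len(animals)
    froh_vals = froh.froh().reindex(animals)
    if froh_vals.isna().any():
        missing = froh_vals[froh_vals.isna()].index.tolist()
        raise ValueError(f"animals without Froh: {missing[:5]}")
    froh_arr = froh_vals.to_numpy(dtype=float)

    if G is None:
        G = build_grm(ds)
    L = np.linalg.cholesky(G + 1e-8 * np.eye(n))

    hy = rng.integers(0, cfg.n_herd_years, size=n)
    month = rng.integers(1, cfg.n_months + 1, size=n)
    age = rng.uniform(*cfg.age_range_months, size=n)

    ph = pd.DataFrame(
        {
            "cow_id": animals,
            "herd_year": [f"HY{h:02d}" for h in hy],
            "calving_month": month,
            "age_at_calving": age,
        }
    )
    realized: dict = {"hy": hy, "month": month, "age": age, "u": {}, "e": {},
                      "hy_effects": {}, "month_effects": {}}
    u_by_trait: dict[str, np.ndarray] = {}
    for trait in TRAIT_NAMES:
        eff = cfg.trait_effects[trait]
        hy_eff = rng.normal(0.0, eff.hy_sd, size=cfg.n_herd_years) if eff.hy_sd > 0 else np.zeros(cfg.n_herd_years)
        mo_eff = rng.normal(0.0, eff.month_sd, size=cfg.n_months) if eff.month_sd > 0 else np.zeros(cfg.n_months)
        z = rng.standard_normal(n)
        u = (L @ z) * np.sqrt(eff.sigma_a2)
        e = rng.normal(0.0, np.sqrt(eff.sigma_e2), size=n) if eff.sigma_e2 > 0 else np.zeros(n)
        y = (
            eff.mu
            + hy_eff[hy]
            + mo_eff[month - 1]
            + eff.alpha * age
            + eff.beta1 * froh_arr
            + u
            + e
        )
        for t in cfg.planted_roh_effects:
            if t.trait == trait:
                y = y + t.beta2 * truth.effect_carriers[t.key].reindex(animals).to_numpy(float)
        ph[trait] = y
        u_by_trait[trait] = u
        realized["u"][trait] = u
        realized["e"][trait] = e
        realized["hy_effects"][trait] = hy_eff
        realized["month_effects"][trait] = mo_eff

    pta = pd.DataFrame({"animal_id": animals})
    pta_sources = {
        "pta_milk": ("milk_305d", None),
        "pta_fat": ("fat_305d", None),
        "pta_protein": ("protein_305d", None),
        "pta_fat_pct": (None, 0.10),
        "pta_protein_pct": (None, 0.08),
        "pta_final_score": ("final_score", None),
    }
    for col, (src, scale) in pta_sources.items():
        if src is not None:
            u = u_by_trait[src]
            sd_a = np.sqrt(cfg.trait_effects[src].sigma_a2)
        else:
            u = (L @ rng.standard_normal(n)) * scale  # component traits without records
            sd_a = scale
        pta[col] = 0.5 * u + rng.normal(0.0, 0.5 * sd_a, size=n)
        realized["u"].setdefault("pta", {})[col] = u

    truth.realized = realized
    return ph, pta, truth
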