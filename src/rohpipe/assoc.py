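"""ROH-trait association.

Two layers are implemented:

1. ``pta_regression`` -- per distinct ROH and per trait, ordinary least
   squares of the predicted transmitting ability (PTA) on a 0/1 carrier
   indicator.  With a lone indicator the slope is exactly the carrier
   minus non-carrier mean difference; the t-test uses n - 2 residual df.

2. ``fit_trait_class_models`` -- for each 305-day trait and each ROH
   length class, the animal model

       y = mu + HY_i + month_j + alpha * age + beta1 * Froh
           + sum_l beta2_l * Lroh_l + cow + e

   with herd-year and calving-month fixed classes, age-at-calving and
   Froh covariates, one 0/1 indicator per eligible distinct ROH in the
   class, and a random genetic cow effect.  With a single first-lactation
   record per cow an i.i.d. cow effect is unidentifiable, so the random
   effect has covariance G * sigma_a^2 where G is the VanRaden method-1
   genomic relationship matrix.  The system is solved through
   Henderson's mixed-model equations

       [ X'X      X'Z          ] [b]   [X'y]
       [ Z'X  Z'Z + G^-1 lambda] [u] = [Z'y],   lambda = sigma_e^2 / sigma_a^2,

   and each beta2 is tested with t = estimate / SE on n - rank(X)
   residual df.  The variance ratio defaults to lambda = 1 and can be
   re-estimated by EM-REML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .io import GenotypeDataset
from .summaries import MODEL_SCHEME, DistinctROH, FrohTable, LengthClassScheme

logger = logging.getLogger(__name__)

TRAITS_305D = ["milk_305d", "fat_305d", "protein_305d", "scs", "final_score"]
PTA_TRAITS = ["pta_milk", "pta_fat", "pta_protein", "pta_fat_pct", "pta_protein_pct", "pta_final_score"]

ASSOC_COLUMNS = [
    "analysis", "trait", "length_class", "chrom", "start_bp", "end_bp",
    "length_mb", "carrier_count", "carrier_pct", "beta", "se", "t", "p",
    "df", "significant", "p_bh", "degenerate",
]


@dataclass
class ModelSpec:
    """One trait x length-class model: which ROH terms enter, and lambda."""

    trait: str
    length_class: str
    roh_terms: list[DistinctROH]
    lambda_: float = 1.0
    min_carriers: int = 50

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda must be > 0")
        scheme = MODEL_SCHEME
        if self.length_class not in scheme.labels:
            raise ValueError(f"unknown model length class {self.length_class!r}")
        k = scheme.labels.index(self.length_class)
        for term in self.roh_terms:
            if int(scheme.assign(np.array([term.length_mb]))[0]) != k:
                raise ValueError(
                    f"ROH {term.chrom}:{term.start_bp} ({term.length_mb:.2f} Mb) "
                    f"is outside class {self.length_class!r}"
                )
            if term.carrier_count < self.min_carriers:
                raise ValueError("all roh_terms must meet min_carriers")


@dataclass
class MMEResult:
    """Solved mixed-model equations with fixed-effect inference."""

    beta: np.ndarray
    beta_names: list[str]
    u: np.ndarray
    sigma_e2: float
    se_beta: np.ndarray
    t_beta: np.ndarray
    p_beta: np.ndarray
    df_resid: int
    rank_x: int
    solution_residual: float  # max |M s - rhs| of the solved system

    def fixed_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.beta_names,
                "estimate": self.beta,
                "se": self.se_beta,
                "t": self.t_beta,
                "p": self.p_beta,
            }
        )


@dataclass(frozen=True)
class AssocConfig:
    traits: tuple[str, ...] = tuple(TRAITS_305D)
    min_carriers: int = 50
    lambda_: float = 1.0
    reml: bool = False
    sig_level: float = 0.05


def pta_regression(
    pta: pd.DataFrame,
    distinct: list[DistinctROH],
    min_carriers: int = 50,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """OLS of each PTA on each distinct ROH's carrier indicator.

    ``pta`` must have an ``animal_id`` column; every carrier id must be
    present.  ROH carried by fewer than ``min_carriers`` animals are not
    tested; ROH carried by all or no animals are skipped with a logged
    reason (the indicator is non-informative).
    """
    if min_carriers < 1:
        raise ValueError("min_carriers must be >= 1")
    if "animal_id" not in pta.columns:
        raise ValueError("PTA table requires an animal_id column")
    if traits is None:
        traits = [c for c in pta.columns if c != "animal_id"]
    ids = pta["animal_id"].astype(str).to_numpy()
    id_set = set(ids)
    n = len(ids)
    rows = []
    for d in distinct:
        if d.carrier_count < min_carriers:
            continue
        missing = [c for c in d.carrier_ids if c not in id_set]
        if missing:
            raise ValueError(
                f"carriers of ROH {d.chrom}:{d.start_bp} absent from PTA table: {missing[:5]}"
            )
        x = np.isin(ids, list(d.carrier_ids)).astype(float)
        n1 = int(x.sum())
        if n1 == 0 or n1 == n:
            logger.info(
                "pta_regression: ROH %d:%d skipped (indicator non-informative, %d/%d carriers)",
                d.chrom, d.start_bp, n1, n,
            )
            continue
        n0 = n - n1
        for trait in traits:
            y = pta[trait].to_numpy(dtype=float)
            mean1 = y[x == 1].mean()
            mean0 = y[x == 0].mean()
            beta = mean1 - mean0
            resid = y - np.where(x == 1, mean1, mean0)
            df = n - 2
            s2 = float(resid @ resid) / df if df > 0 else np.nan
            se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n0))
            if se > 0:
                t = beta / se
                p = 2.0 * stats.t.sf(abs(t), df)
            else:  # zero-residual degenerate fit: report the limit
                t = np.inf * np.sign(beta) if beta != 0 else 0.0
                p = 0.0 if beta != 0 else 1.0
            rows.append(
                {
                    "analysis": "pta_ols",
                    "trait": trait,
                    "length_class": "",
                    "chrom": d.chrom,
                    "start_bp": d.start_bp,
                    "end_bp": d.end_bp,
                    "length_mb": d.length_mb,
                    "carrier_count": d.carrier_count,
                    "carrier_pct": 100.0 * n1 / n,
                    "beta": beta,
                    "se": se,
                    "t": t,
                    "p": p,
                    "df": df,
                    "significant": bool(p < 0.05) if np.isfinite(p) else False,
                    "p_bh": np.nan,
                    "degenerate": False,
                }
            )
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def build_grm(ds: GenotypeDataset) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    Codes are treated as minor-allele dosages; missing calls are imputed
    to the marker mean 2p.  Monomorphic markers are excluded.  With W
    the centred dosage matrix, G = W W' / (2 * sum p(1-p)).
    """
    if ds.n_animals < 2:
        raise ValueError("GRM needs at least 2 animals")
    d = ds.calls.astype(float)
    d[d < 0] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic markers: cannot build GRM")
    d = d[:, poly]
    p = p[poly]
    inds = np.where(np.isnan(d))
    d[inds] = (2.0 * p)[inds[1]]
    w = d - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    g = (w @ w.T) / denom
    return (g + g.T) / 2.0


def incidence_matrices(
    ph: pd.DataFrame,
    froh: FrohTable,
    spec: ModelSpec,
    grm_animal_ids: list[str] | None = None,
) -> dict:
    """Assemble y, X and Z for one trait x class model.

    X columns: intercept, herd-year dummies (first observed level as
    reference), calving-month dummies (reference likewise), age at
    calving, Froh, then one 0/1 column per ROH term.  Z maps records to
    cows (identity when every cow has one record and G is indexed by the
    same cows).  Rank-deficient X is reduced to an estimable basis by a
    greedy orthogonalisation sweep; dropped columns are logged.
    """
    needed = {"cow_id", spec.trait, "herd_year", "calving_month", "age_at_calving"}
    if not needed <= set(ph.columns):
        raise ValueError(f"phenotype table requires columns {sorted(needed)}")
    cows = ph["cow_id"].astype(str).to_numpy()
    froh_map = froh.froh()
    missing = [c for c in cows if c not in froh_map.index]
    if missing:
        raise ValueError(f"cows without Froh: {missing[:5]}")
    y = ph[spec.trait].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite values in trait {spec.trait}")
    n = len(y)

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["mu"]
    for var, prefix in (("herd_year", "hy"), ("calving_month", "month")):
        levels = list(dict.fromkeys(ph[var].tolist()))  # first observed = reference
        for lev in levels[1:]:
            cols.append((ph[var] == lev).to_numpy(dtype=float))
            names.append(f"{prefix}:{lev}")
    cols.append(ph["age_at_calving"].to_numpy(dtype=float))
    names.append("age")
    cols.append(froh_map.loc[cows].to_numpy(dtype=float))
    names.append("froh")
    for term in spec.roh_terms:
        ind = np.isin(cows, list(term.carrier_ids)).astype(float)
        if ind.sum() == 0:
            logger.info(
                "incidence_matrices: ROH %d:%d dropped (no carriers among phenotyped cows)",
                term.chrom, term.start_bp,
            )
            continue
        cols.append(ind)
        names.append(f"roh:{term.chrom}:{term.start_bp}-{term.end_bp}")
    X = np.column_stack(cols)

    X, names, dropped = _estimable_basis(X, names)
    if dropped:
        logger.info("incidence_matrices: dropped non-estimable columns %s", dropped)

    if grm_animal_ids is None:
        grm_animal_ids = list(dict.fromkeys(cows))
    pos = {a: k for k, a in enumerate(grm_animal_ids)}
    unknown = [c for c in cows if c not in pos]
    if unknown:
        raise ValueError(f"cows absent from the relationship matrix: {unknown[:5]}")
    Z = np.zeros((n, len(grm_animal_ids)))
    Z[np.arange(n), [pos[c] for c in cows]] = 1.0
    return {"y": y, "X": X, "X_names": names, "Z": Z, "dropped": dropped}


def _estimable_basis(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedy left-to-right sweep keeping columns that increase rank."""
    n = X.shape[0]
    Q = np.zeros((n, 0))
    keep, dropped = [], []
    for k in range(X.shape[1]):
        c = X[:, k]
        r = c - Q @ (Q.T @ c)
        nrm = np.linalg.norm(r)
        if nrm > 1e-8 * max(1.0, np.linalg.norm(c)):
            Q = np.column_stack([Q, r / nrm])
            keep.append(k)
        else:
            dropped.append(names[k])
    return X[:, keep], [names[k] for k in keep], dropped


def _ols(y: np.ndarray, X: np.ndarray) -> MMEResult:
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    df = n - rank
    sigma_e2 = float(resid @ resid) / df if df > 0 else np.nan
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma_e2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, np.nan)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return MMEResult(
        beta=b, beta_names=[f"b{k}" for k in range(p)], u=np.zeros(0),
        sigma_e2=sigma_e2, se_beta=se, t_beta=t, p_beta=pvals,
        df_resid=df, rank_x=int(rank),
        solution_residual=float(np.max(np.abs(X.T @ X @ b - X.T @ y))),
    )


def _inv_psd(G: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Inverse of a (near-)PSD matrix, ridging the diagonal if needed."""
    try:
        c, low = linalg.cho_factor(G)
    except np.linalg.LinAlgError:
        logger.info("G not positive definite; adding ridge %g to diagonal", ridge)
        try:
            c, low = linalg.cho_factor(G + ridge * np.eye(len(G)))
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"G singular even after ridge {ridge}; cond={np.linalg.cond(G):.3g}"
            ) from err
    return linalg.cho_solve((c, low), np.eye(len(G)))


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray | None,
    G: np.ndarray | None,
    lambda_: float,
    beta_names: list[str] | None = None,
) -> MMEResult:
    """Solve Henderson's mixed-model equations.

    With ``Z`` (or ``G``) absent the model collapses to OLS.  The
    residual variance is the generalised residual sum of squares
    (y'y - b'X'y - u'Z'y) over n - rank(X); fixed-effect standard errors
    come from the corresponding diagonal of the inverse coefficient
    matrix scaled by that variance, and each t-test uses n - rank(X) df.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X are not conformable")
    if Z is None or G is None:
        res = _ols(y, X)
        if beta_names is not None:
            res.beta_names = beta_names
        return res
    Z = np.asarray(Z, dtype=float)
    G = np.asarray(G, dtype=float)
    q = Z.shape[1]
    if Z.shape[0] != n or G.shape != (q, q):
        raise ValueError("Z / G dimensions are not conformable")
    if lambda_ <= 0:
        raise ValueError("lambda must be > 0")

    Ginv = _inv_psd(G)
    M = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + Ginv * lambda_]])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        Mr = M + 1e-8 * np.eye(len(M)) * max(1.0, np.trace(M) / len(M))
        try:
            sol = np.linalg.solve(Mr, rhs)
            logger.info("solve_mme: coefficient matrix ridged for solvability")
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular mixed-model equations; cond={np.linalg.cond(M):.3g}"
            ) from err
    b, u = sol[:p], sol[p:]
    rank = int(np.linalg.matrix_rank(X))
    df = n - rank
    rss_gen = float(y @ y - b @ (X.T @ y) - u @ (Z.T @ y))
    sigma_e2 = rss_gen / df if df > 0 else np.nan
    Minv = np.linalg.inv(M)
    se = np.sqrt(np.maximum(np.diag(Minv)[:p] * sigma_e2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, np.nan)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return MMEResult(
        beta=b,
        beta_names=beta_names or [f"b{k}" for k in range(p)],
        u=u,
        sigma_e2=sigma_e2,
        se_beta=se,
        t_beta=t,
        p_beta=pvals,
        df_resid=df,
        rank_x=rank,
        solution_residual=float(np.max(np.abs(M @ sol - rhs))),
    )


def reml_loglik(y: np.ndarray, X: np.ndarray, Z: np.ndarray, G: np.ndarray,
                sigma_a2: float, sigma_e2: float) -> float:
    """Restricted log-likelihood under V = Z G Z' sa2 + I se2 (dense)."""
    n = len(y)
    V = Z @ G @ Z.T * sigma_a2 + np.eye(n) * sigma_e2
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtVX)
    P = Vinv - Vinv @ X @ np.linalg.solve(XtVX, X.T @ Vinv)
    return float(-0.5 * (ld_v + ld_x + y @ P @ y))


def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    G: np.ndarray,
    start: tuple[float, float] = (1.0, 1.0),
    max_iter: int = 50,
    tol: float = 1e-6,
) -> dict:
    """EM-REML for the one-random-effect animal model.

    ``start`` is (sigma_a2, sigma_e2); with ``max_iter`` 0 the start
    values are returned unchanged.  Standard EM updates: with C22 the
    u-block of the inverse MME coefficient matrix,

        sigma_a2 <- (u' G^-1 u + tr(G^-1 C22) * sigma_e2) / q
        sigma_e2 <- (y'y - b'X'y - u'Z'y) / (n - rank(X)).
    """
    sa2, se2 = float(start[0]), float(start[1])
    if sa2 <= 0 or se2 <= 0:
        raise ValueError("start variances must be positive")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    G = np.asarray(G, dtype=float)
    n, p = X.shape
    q = Z.shape[1]
    rank = int(np.linalg.matrix_rank(X))
    Ginv = _inv_psd(G)
    XtX, XtZ, ZtZ = X.T @ X, X.T @ Z, Z.T @ Z
    Xty, Zty = X.T @ y, Z.T @ y
    yty = float(y @ y)
    history = []
    for _ in range(max_iter):
        lam = se2 / sa2
        M = np.block([[XtX, XtZ], [XtZ.T, ZtZ + Ginv * lam]])
        Minv = np.linalg.inv(M)
        sol = Minv @ np.concatenate([Xty, Zty])
        b, u = sol[:p], sol[p:]
        C22 = Minv[p:, p:]
        sa2_new = float(u @ Ginv @ u + np.trace(Ginv @ C22) * se2) / q
        se2_new = (yty - float(b @ Xty) - float(u @ Zty)) / (n - rank)
        history.append((sa2, se2))
        change = max(abs(sa2_new - sa2) / sa2, abs(se2_new - se2) / se2)
        sa2, se2 = sa2_new, se2_new
        if change < tol:
            break
    return {"sigma_a2": sa2, "sigma_e2": se2, "lambda": se2 / sa2, "history": history}


def fit_trait_class_models(
    ph: pd.DataFrame,
    froh: FrohTable,
    distinct: list[DistinctROH],
    ds: GenotypeDataset | None = None,
    config: AssocConfig | None = None,
    G: np.ndarray | None = None,
    grm_animal_ids: list[str] | None = None,
    scheme: LengthClassScheme = MODEL_SCHEME,
) -> pd.DataFrame:
    """Fit the animal model per trait and per ROH length class.

    Eligible ROH terms in a class are those with at least
    ``config.min_carriers`` carriers and a length falling in the class.
    Classes with no eligible ROH are skipped with a log line.  Returns
    one row per ROH term x trait with its beta2 inference, a raw
    significance flag at ``config.sig_level`` and a Benjamini-Hochberg
    adjusted p-value column (per trait).
    """
    config = config or AssocConfig()
    if G is None:
        if ds is None:
            raise ValueError("either a genotype dataset or a precomputed G is required")
        G = build_grm(ds)
        grm_animal_ids = list(ds.animal_ids)
    if grm_animal_ids is None:
        raise ValueError("grm_animal_ids must accompany a precomputed G")

    eligible = [d for d in distinct if d.carrier_count >= config.min_carriers]
    lengths = np.array([d.length_mb for d in eligible])
    classes = scheme.assign(lengths) if len(eligible) else np.array([], dtype=int)

    all_rows: list[dict] = []
    for trait in config.traits:
        y_all = ph[trait].to_numpy(dtype=float)
        degenerate = bool(np.ptp(y_all) == 0.0)
        for k, label in enumerate(scheme.labels):
            terms = [d for d, c in zip(eligible, classes) if c == k]
            if not terms:
                logger.info("fit_trait_class_models: %s / class %s skipped (no eligible ROH)",
                            trait, label)
                continue
            if degenerate:
                for d in terms:
                    all_rows.append(_assoc_row(trait, label, d, ph, 0.0, np.nan, np.nan,
                                               np.nan, 0, config, degenerate=True))
                continue
            spec = ModelSpec(trait=trait, length_class=label, roh_terms=terms,
                             lambda_=config.lambda_, min_carriers=config.min_carriers)
            mats = incidence_matrices(ph, froh, spec, grm_animal_ids=grm_animal_ids)
            lam = config.lambda_
            if config.reml:
                est = em_reml(mats["y"], mats["X"], mats["Z"], G)
                lam = est["lambda"]
            res = solve_mme(mats["y"], mats["X"], mats["Z"], G, lam,
                            beta_names=mats["X_names"])
            for d in terms:
                name = f"roh:{d.chrom}:{d.start_bp}-{d.end_bp}"
                if name not in res.beta_names:
                    continue  # dropped (no carriers / inestimable), already logged
                i = res.beta_names.index(name)
                all_rows.append(
                    _assoc_row(trait, label, d, ph, float(res.beta[i]),
                               float(res.se_beta[i]), float(res.t_beta[i]),
                               float(res.p_beta[i]), res.df_resid, config)
                )
    df = pd.DataFrame(all_rows, columns=ASSOC_COLUMNS)
    if len(df):
        from statsmodels.stats.multitest import multipletests

        for trait in df["trait"].unique():
            m = (df["trait"] == trait) & df["p"].notna()
            if m.any():
                df.loc[m, "p_bh"] = multipletests(df.loc[m, "p"], method="fdr_bh")[1]
    return df


def _assoc_row(trait, label, d: DistinctROH, ph, beta, se, t, p, df, config,
               degenerate: bool = False) -> dict:
    n_ph = len(ph)
    n_carr = sum(1 for c in ph["cow_id"].astype(str) if c in set(d.carrier_ids))
    return {
        "analysis": "mme",
        "trait": trait,
        "length_class": label,
        "chrom": d.chrom,
        "start_bp": d.start_bp,
        "end_bp": d.end_bp,
        "length_mb": d.length_mb,
        "carrier_count": d.carrier_count,
        "carrier_pct": 100.0 * n_carr / n_ph if n_ph else np.nan,
        "beta": beta,
        "se": se,
        "t": t,
        "p": p,
        "df": df,
        "significant": bool(np.isfinite(p) and p < config.sig_level),
        "p_bh": np.nan,
        "degenerate": degenerate,
    }
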