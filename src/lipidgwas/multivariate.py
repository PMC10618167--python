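"""Summary-statistic multivariate association via canonical correlation.

Given per-trait GWAS summary statistics for a cluster of correlated traits,
each per-trait effect is standardized to the genotype-phenotype correlation
scale, ``b_stand = beta / (sqrt(N) * se)``, the trait-trait correlation
``S_YY`` is estimated (from the null-dominated genome-wide standardized
effects, or directly from phenotypes), and the canonical correlation between
the variant and the trait set is

    r^2 = b' S_YY^{-1} b,

tested with Bartlett's chi-square ``-(N - 1 - (1 + q + 1)/2) ln(1 - r^2)``
on ``q`` degrees of freedom, where N is the mean per-trait GWAS sample size
at the variant.  For rare variants the chi-square can be mildly inflated in
finite samples; a permutation-based genomic-control factor (median permuted
chi-square over the theoretical median) corrects it.  The optimal combination
weights ``a ~ S_YY^{-1} b`` define the linear combination phenotype (LCP)
used for region-wise fine-mapping of multivariate signals, and a BIC-guided
decremental search decomposes a multivariate association into driver traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardizedEffects",
    "TraitCorrelation",
    "MvTestResult",
    "InflationEstimate",
    "DriverDecomposition",
    "standardize_effects",
    "standardized_effects_from_phenotypes",
    "estimate_syy",
    "cca_test",
    "permutation_lambda",
    "needs_permutation_correction",
    "lcp_construct",
    "driver_traits",
    "MultivariateGwasModel",
    "MultivariateGwasResults",
]


@dataclass
class StandardizedEffects:
    """Per-variant x trait standardized effects b = beta/(sqrt(N) se)."""

    beta_stand: pd.DataFrame  # variants x traits
    mean_n: pd.Series  # per-variant mean N across traits


@dataclass
class TraitCorrelation:
    """Trait-trait correlation estimate for a cluster, shrunk to be invertible."""

    syy: pd.DataFrame
    shrinkage: float
    source: str


@dataclass
class MvTestResult:
    variant_id: str
    cluster_id: int
    r: float
    chisq: float
    df: int
    p: float
    p_corrected: float
    weights: np.ndarray
    lam: float = 1.0


@dataclass
class InflationEstimate:
    variant_id: str
    n_perm: int
    lam: float
    seed: int


@dataclass
class DriverDecomposition:
    cluster_id: int
    variant_id: str
    path: list[dict] = field(default_factory=list)
    optimal_set: list[str] = field(default_factory=list)
    drivers: list[str] = field(default_factory=list)
    note: str = "metaphat-like"


def standardize_effects(
    sumstats: dict[str, pd.DataFrame]
) -> StandardizedEffects:
    """Standardize per-trait summary statistics to the correlation scale.

    ``sumstats`` maps trait name to a records table with columns
    (id, beta, se, n), aligned on variant id across traits.  Records with
    ``se <= 0`` are skipped with a warning column of NaN.
    """
    traits = list(sumstats)
    base_ids = sumstats[traits[0]]["id"]
    bs = {}
    ns = {}
    for t in traits:
        df = sumstats[t].set_index("id")
        df = df.loc[base_ids]
        se = df["se"].to_numpy(float)
        n = df["n"].to_numpy(float)
        beta = df["beta"].to_numpy(float)
        bad = ~(se > 0) | ~(n > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            b = beta / (np.sqrt(n) * se)
        b[bad] = np.nan
        bs[t] = b
        ns[t] = n
    beta_stand = pd.DataFrame(bs, index=base_ids.to_numpy())
    mean_n = pd.DataFrame(ns, index=base_ids.to_numpy()).mean(axis=1)
    return StandardizedEffects(beta_stand=beta_stand, mean_n=mean_n)


def _shrink_to_invertible(S: np.ndarray, min_eig: float = 1e-3) -> tuple[np.ndarray, float]:
    ev = np.linalg.eigvalsh(S)
    mu = float(ev.min())
    if mu >= min_eig:
        return S, 0.0
    alpha = (min_eig - mu) / (1.0 - mu)
    out = (1.0 - alpha) * S + alpha * np.eye(S.shape[0])
    return out, float(alpha)


def estimate_syy(
    effects: StandardizedEffects | None = None,
    phenotypes: pd.DataFrame | None = None,
    min_variants: int = 500,
    min_eig: float = 1e-3,
) -> TraitCorrelation:
    """Estimate the cluster's trait-trait correlation matrix S_YY.

    From summary statistics, S_YY is the Pearson correlation of the
    standardized-effect columns across the (null-dominated) genome; from
    phenotypes it is the pairwise-complete trait correlation.  Either way the
    estimate is shrunk toward the identity with the smallest coefficient
    making the minimum eigenvalue at least ``min_eig``.
    """
    if (effects is None) == (phenotypes is None):
        raise ValueError("provide exactly one of effects / phenotypes")
    if effects is not None:
        B = effects.beta_stand.dropna()
        if len(B) < min_variants:
            raise ValueError(
                f"need at least {min_variants} variants to estimate S_YY "
                f"from summary statistics (got {len(B)})"
            )
        S = np.corrcoef(B.to_numpy(float), rowvar=False)
        cols = list(B.columns)
        source = "summary_stats"
    else:
        S = phenotypes.corr(method="pearson").to_numpy(float)
        cols = list(phenotypes.columns)
        source = "phenotypes"
    np.fill_diagonal(S, 1.0)
    S, alpha = _shrink_to_invertible(S, min_eig)
    return TraitCorrelation(
        syy=pd.DataFrame(S, index=cols, columns=cols),
        shrinkage=alpha,
        source=source,
    )


def cca_test(
    b: np.ndarray,
    syy: np.ndarray | pd.DataFrame | TraitCorrelation,
    n: float,
    variant_id: str = "",
    cluster_id: int = 0,
    lam: float = 1.0,
) -> MvTestResult:
    """Single-variant canonical-correlation test from standardized effects.

    ``r^2 = b' S_YY^{-1} b`` (clamped below 1); Bartlett's statistic
    ``chi2 = -(N - 1 - (1 + q + 1)/2) ln(1 - r^2)`` with ``df = q``.  The
    optimal combination weights satisfy ``a' S_YY a = 1`` with sign fixed so
    ``a'b >= 0``.  A genomic-control factor ``lam > 1`` divides the
    chi-square before the p-value ("p_corrected").
    """
    if isinstance(syy, TraitCorrelation):
        S = syy.syy.to_numpy(float)
    elif isinstance(syy, pd.DataFrame):
        S = syy.to_numpy(float)
    else:
        S = np.asarray(syy, float)
    b = np.asarray(b, float).ravel()
    q = b.size
    if S.shape != (q, q):
        raise ValueError("S_YY shape does not match effect vector")
    if n <= q + 2:
        raise ValueError("underdetermined: N must exceed cluster size + 2")
    Sb = np.linalg.solve(S, b)
    r2 = float(b @ Sb)
    r2 = min(max(r2, 0.0), 1.0 - 1e-12)
    factor = n - 1.0 - (1.0 + q + 1.0) / 2.0
    chisq = -factor * np.log1p(-r2)
    p = float(stats.chi2.sf(chisq, q))
    if lam > 1.0:
        p_corr = float(stats.chi2.sf(chisq / lam, q))
    else:
        p_corr = p
    if r2 > 0:
        scale = float(Sb @ S @ Sb)
        a = Sb / np.sqrt(scale)
        if a @ b < 0:
            a = -a
    else:
        a = np.zeros(q)
    return MvTestResult(
        variant_id=variant_id,
        cluster_id=cluster_id,
        r=float(np.sqrt(r2)),
        chisq=float(chisq),
        df=q,
        p=max(p, 1e-320),
        p_corrected=max(p_corr, 1e-320),
        weights=a,
        lam=lam,
    )


def _cca_chisq_from_corr(R: np.ndarray, syy_inv_chol: np.ndarray, n: int,
                         q: int) -> np.ndarray:
    """Vectorized Bartlett chi-square for rows of genotype-trait correlations.

    ``R`` is (n_tests, q) of standardized effects; ``syy_inv_chol`` is the
    Cholesky factor L with S_YY = L L'.
    """
    w = np.linalg.solve(syy_inv_chol, R.T)  # L^{-1} R'
    r2 = np.einsum("ij,ij->j", w, w)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
    factor = n - 1.0 - (1.0 + q + 1.0) / 2.0
    return -factor * np.log1p(-r2)


def standardized_effects_from_phenotypes(g: np.ndarray,
                                         Y: np.ndarray) -> np.ndarray:
    """Exact OLS beta/se -> b_stand for one genotype against each trait column."""
    n = g.size
    gc = g - g.mean()
    sxx = gc @ gc
    Yc = Y - Y.mean(axis=0)
    sxy = gc @ Yc
    beta = sxy / sxx
    rss = np.einsum("ij,ij->j", Yc, Yc) - beta * sxy
    se = np.sqrt(np.clip(rss, 0, None) / (n - 2) / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = beta / (np.sqrt(n) * se)
    return b


_per_trait_bstand = standardized_effects_from_phenotypes


def permutation_lambda(
    genotype: np.ndarray,
    phenotypes: pd.DataFrame | np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    syy: TraitCorrelation | None = None,
    variant_id: str = "",
    batch: int = 2000,
) -> InflationEstimate:
    """Permutation-based genomic-control factor for the multivariate test.

    The genotype vector is permuted ``n_perm`` times (phenotypes fixed, so
    the trait correlation is preserved); for each permutation the per-trait
    standardized effects are recomputed exactly and the canonical-correlation
    chi-square evaluated.  Lambda is the median permuted chi-square divided
    by the theoretical chi-square median at ``df = q``.
    """
    if n_perm < 1000:
        raise ValueError("need at least 1000 permutations")
    Y = np.asarray(phenotypes, float)
    g = np.asarray(genotype, float)
    ok = ~np.isnan(Y).any(axis=1) & ~np.isnan(g)
    Y, g = Y[ok], g[ok]
    if np.var(g) <= 0:
        raise ValueError("constant genotype")
    n, q = Y.shape
    if syy is None:
        S = np.corrcoef(Y, rowvar=False)
        S, _ = _shrink_to_invertible(S)
    else:
        S = syy.syy.to_numpy(float)
    L = np.linalg.cholesky(S)
    rng = np.random.default_rng(seed)

    # exact b_stand for a permuted genotype equals t/sqrt(n) with
    # t = r sqrt((n-2)/(1-r^2)), computable from correlations alone
    Ys = (Y - Y.mean(axis=0)) / Y.std(axis=0)
    gs = (g - g.mean()) / g.std()
    chis = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(batch, n_perm - done)
        P = np.empty((n, k))
        for j in range(k):
            P[:, j] = rng.permutation(gs)
        R = P.T @ Ys / n  # (k, q) Pearson correlations
        tt = R * np.sqrt((n - 2) / np.clip(1.0 - R**2, 1e-12, None))
        B = tt / np.sqrt(n)
        chis[done:done + k] = _cca_chisq_from_corr(B, L, n, q)
        done += k
    lam = float(np.median(chis) / stats.chi2.ppf(0.5, q))
    return InflationEstimate(variant_id=variant_id, n_perm=n_perm, lam=lam,
                             seed=seed)


def needs_permutation_correction(
    maf: float,
    p_multivariate: float,
    univariate_ps: np.ndarray,
    gws: float = 5e-8,
) -> bool:
    """The trigger rule: rare/low-frequency variant (MAF < 0.05) reaching
    genome-wide significance in the multivariate test but in no univariate
    test."""
    return (maf < 0.05 and p_multivariate < gws
            and not bool((np.asarray(univariate_ps, float) < gws).any()))


def lcp_construct(
    phenotypes: pd.DataFrame, weights: np.ndarray
) -> pd.Series:
    """Linear combination phenotype: weighted trait sum, re-standardized.

    Weights come from the cluster's lead variant's optimal combination; rows
    with any missing member trait are dropped.
    """
    w = np.asarray(weights, float)
    if not np.any(w != 0):
        raise ValueError("degenerate combination: all weights zero")
    sub = phenotypes.dropna()
    y = sub.to_numpy(float) @ w
    sd = y.std()
    if sd <= 0:
        raise ValueError("degenerate combination: zero variance")
    return pd.Series((y - y.mean()) / sd, index=sub.index)


def driver_traits(
    b: pd.Series | np.ndarray,
    syy: pd.DataFrame | np.ndarray,
    n: float,
    cluster_id: int = 0,
    variant_id: str = "",
) -> DriverDecomposition:
    """BIC-guided decremental decomposition of a multivariate association.

    From the full cluster, iteratively remove the trait whose exclusion
    yields the smallest multivariate p-value (the least-contributing trait),
    recording ``BIC(S) = -chi2(S) + |S| ln N`` at each subset; the optimal
    set is the minimum-BIC subset on the path and its members are the driver
    traits.
    """
    if isinstance(b, pd.Series):
        names = list(b.index)
        bv = b.to_numpy(float)
    else:
        bv = np.asarray(b, float)
        names = [f"trait{i}" for i in range(bv.size)]
    S = syy.to_numpy(float) if isinstance(syy, pd.DataFrame) else np.asarray(syy, float)
    if bv.size < 2:
        raise ValueError("cluster size must be >= 2")

    current = list(range(bv.size))
    path = []
    best = None
    while current:
        idx = np.array(current)
        res = cca_test(bv[idx], S[np.ix_(idx, idx)], n)
        bic = -res.chisq + len(current) * np.log(n)
        step = {
            "subset": [names[i] for i in current],
            "chisq": res.chisq,
            "p": res.p,
            "bic": bic,
        }
        path.append(step)
        if best is None or bic < best[0]:
            best = (bic, [names[i] for i in current])
        if len(current) == 1:
            break
        # find the member whose removal keeps the strongest (smallest-p) signal
        best_p, victim = None, None
        for i in current:
            rest = [j for j in current if j != i]
            ridx = np.array(rest)
            sub = cca_test(bv[ridx], S[np.ix_(ridx, ridx)], n)
            if best_p is None or sub.p < best_p:
                best_p, victim = sub.p, i
        current.remove(victim)
    return DriverDecomposition(
        cluster_id=cluster_id,
        variant_id=variant_id,
        path=path,
        optimal_set=best[1],
        drivers=best[1],
    )


class MultivariateGwasModel:
    """Cluster-level multivariate GWAS over a set of variants.

    Built from standardized effects and a trait correlation; ``fit()``
    evaluates the canonical-correlation test for every variant and returns a
    results object with the association table.
    """

    def __init__(self, effects: StandardizedEffects, syy: TraitCorrelation,
                 cluster_id: int = 0):
        self.effects = effects
        self.syy = syy
        self.cluster_id = cluster_id

    def fit(self, lam: float | dict[str, float] = 1.0) -> "MultivariateGwasResults":
        S = self.syy.syy.to_numpy(float)
        L = np.linalg.cholesky(S)
        B = self.effects.beta_stand
        q = B.shape[1]
        rows = []
        for vid, brow in B.iterrows():
            bv = brow.to_numpy(float)
            n = float(self.effects.mean_n.loc[vid])
            if np.isnan(bv).any():
                continue
            l = lam.get(vid, 1.0) if isinstance(lam, dict) else lam
            res = cca_test(bv, S, n, variant_id=str(vid),
                           cluster_id=self.cluster_id, lam=l)
            rows.append({
                "id": res.variant_id, "cluster": self.cluster_id,
                "r": res.r, "chisq": res.chisq, "df": res.df,
                "p": res.p, "p_corrected": res.p_corrected, "lambda": res.lam,
                "weights": ",".join(f"{w:.6g}" for w in res.weights),
            })
        return MultivariateGwasResults(pd.DataFrame(rows), q=q,
                                       shrinkage=self.syy.shrinkage)


@dataclass
class MultivariateGwasResults:
    records: pd.DataFrame
    q: int
    shrinkage: float

    def lambda_gc(self) -> float:
        if len(self.records) < 100:
            raise ValueError("need at least 100 variants")
        med = float(np.median(self.records["chisq"]))
        return med / float(stats.chi2.ppf(0.5, self.q))

    def significant(self, threshold: float) -> pd.DataFrame:
        return self.records[self.records["p_corrected"] < threshold]

    def summary(self) -> str:
        r = self.records
        out = [f"multivariate GWAS: {len(r)} variants, q = {self.q}, "
               f"S_YY shrinkage = {self.shrinkage:.3g}"]
        if len(r):
            out.append(f"min p = {r['p'].min():.3g} at "
                       f"{r.loc[r['p'].idxmin(), 'id']}")
        return "\n".join(out)
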