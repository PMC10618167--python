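"""Phenotype preparation: covariate adjustment, inverse-normal transform and
the PCA-based effective-test-count / Bonferroni scaffolding.

Lipid-species levels are regressed on covariates per species (complete cases
per species), the residuals are inverse-normal transformed (Blom offset), and
multiple-testing thresholds are derived from the number of principal
components needed to explain >90% of the variance of the mean-imputed
phenotype matrix.  Mean imputation is used only for the PCA step; association
testing always uses per-species complete cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "PreparedPhenotypes",
    "TestBudget",
    "adjust_covariates",
    "inverse_normal_transform",
    "effective_test_count",
    "components_for_share",
    "bonferroni_threshold",
    "prepare_phenotypes",
]


@dataclass
class PreparedPhenotypes:
    """Analysis-ready phenotypes: covariate-adjusted, inverse-normal residuals."""

    residuals: pd.DataFrame
    n_per_species: pd.Series
    covariates_removed: list[str]


@dataclass
class TestBudget:
    """Multiple-testing scaffolding derived from the lipidome's dimensionality.

    ``n_components_90`` is the number of principal components explaining >90%
    of the variance of the mean-imputed phenotype matrix; it is the effective
    number of independent traits used as a Bonferroni denominator.
    """

    n_components_90: int
    n_species: int
    alpha_gw: float = 5e-8
    alpha_nominal: float = 0.05
    explained_share: float = 0.0

    @property
    def bfs_threshold(self) -> float:
        """Genome-wide level corrected for the effective trait count."""
        return bonferroni_threshold(self.alpha_gw, [self.n_components_90])

    @property
    def nominal_threshold(self) -> float:
        return bonferroni_threshold(self.alpha_nominal, [self.n_components_90])

    def marginal_threshold(self, n_loci: int) -> float:
        """Nominal level corrected for a locus count and the trait count."""
        return bonferroni_threshold(self.alpha_nominal,
                                    [n_loci, self.n_components_90])

    def save(self, path: str | Path) -> None:
        lines = [
            f"n_components_90\t{self.n_components_90}",
            f"n_species\t{self.n_species}",
            f"alpha_gw\t{self.alpha_gw!r}",
            f"alpha_nominal\t{self.alpha_nominal!r}",
            f"explained_share\t{self.explained_share!r}",
            f"bfs_threshold\t{self.bfs_threshold!r}",
            f"nominal_threshold\t{self.nominal_threshold!r}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TestBudget":
        kv = dict(line.split("\t") for line in
                  Path(path).read_text().strip().splitlines())
        return cls(
            n_components_90=int(kv["n_components_90"]),
            n_species=int(kv["n_species"]),
            alpha_gw=float(kv["alpha_gw"]),
            alpha_nominal=float(kv["alpha_nominal"]),
            explained_share=float(kv["explained_share"]),
        )


def adjust_covariates(
    phenotypes: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Residualize each species on the covariates by least squares.

    The covariate table must be row-aligned with the phenotypes and complete;
    an intercept is always included.  For each species, the fit uses that
    species' non-missing samples, and missing entries stay missing in the
    output.  Raises if the covariate design is rank deficient, naming the
    collinear columns.
    """
    if not phenotypes.index.equals(covariates.index):
        raise ValueError("covariate table is not row-aligned with phenotypes")
    if covariates.isna().any().any():
        raise ValueError("missing covariate values are not allowed")

    X = np.column_stack(
        [np.ones(len(covariates))] + [covariates[c].to_numpy(float)
                                      for c in covariates.columns]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, list(covariates.columns))
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {bad}")

    out = {}
    for sp in phenotypes.columns:
        y = phenotypes[sp].to_numpy(float)
        ok = ~np.isnan(y)
        if ok.sum() == 0:
            raise ValueError(f"species {sp!r}: no complete observations")
        if ok.sum() <= X.shape[1]:
            raise ValueError(
                f"species {sp!r}: fewer complete observations than covariates"
            )
        beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
        resid = np.full_like(y, np.nan)
        resid[ok] = y[ok] - X[ok] @ beta
        out[sp] = resid
    return pd.DataFrame(out, index=phenotypes.index)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # a covariate column (excluding the intercept) is collinear if it lies in
    # the span of the remaining columns
    bad = []
    for j in range(1, X.shape[1]):
        others = np.delete(X, j, axis=1)
        proj, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        if np.allclose(others @ proj, X[:, j], atol=1e-8 * max(1.0, np.abs(X[:, j]).max())):
            bad.append(names[j - 1])
    return bad


def inverse_normal_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Maps value with (average) rank r among n non-missing observations to the
    standard-normal quantile at ``(r - 3/8) / (n + 1/4)``.  Strictly monotone
    in the input ranks; missing values are preserved.
    """
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    x = arr[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.all(x == x[0]):
        raise ValueError("degenerate phenotype: constant input")
    ranks = stats.rankdata(x, method="average")
    out[ok] = special.ndtri((ranks - 0.375) / (n + 0.25))
    return out


def components_for_share(eigenvalues: np.ndarray, share: float = 0.9) -> int:
    """Smallest k whose top-k eigenvalue mass strictly exceeds ``share``."""
    ev = np.sort(np.asarray(eigenvalues, float))[::-1]
    ev = np.clip(ev, 0.0, None)
    total = ev.sum()
    if total <= 0:
        raise ValueError("eigenvalue mass is zero")
    cum = np.cumsum(ev) / total
    # strict exceedance with a small guard so that an exact tie (e.g. equal
    # eigenvalues) does not flip on float rounding
    k = int(np.searchsorted(cum, share + 1e-10, side="left")) + 1
    return min(k, len(ev))


def effective_test_count(
    phenotypes: pd.DataFrame,
    share: float = 0.9,
    alpha_gw: float = 5e-8,
    alpha_nominal: float = 0.05,
) -> TestBudget:
    """Effective number of independent traits via PCA of the mean-imputed matrix.

    Missing entries are replaced by the species mean; the covariance matrix's
    eigenvalues give the smallest component count whose cumulative explained
    variance strictly exceeds ``share`` (default 0.9).
    """
    if phenotypes.shape[1] < 2:
        raise ValueError("need at least 2 species")
    if phenotypes.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    M = phenotypes.to_numpy(float)
    col_mean = np.nanmean(M, axis=0)
    M = np.where(np.isnan(M), col_mean, M)
    M = M - M.mean(axis=0)
    cov = M.T @ M / (M.shape[0] - 1)
    eig = np.linalg.eigvalsh(cov)
    k = components_for_share(eig, share)
    k = min(k, phenotypes.shape[0] - 1, phenotypes.shape[1])
    ev = np.sort(np.clip(eig, 0, None))[::-1]
    explained = float(ev[:k].sum() / ev.sum())
    return TestBudget(
        n_components_90=k,
        n_species=phenotypes.shape[1],
        alpha_gw=alpha_gw,
        alpha_nominal=alpha_nominal,
        explained_share=explained,
    )


def bonferroni_threshold(alpha: float, denominators: list[int]) -> float:
    """``alpha`` divided by the product of the correction denominators."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    prod = 1.0
    for d in denominators:
        if d < 1:
            raise ValueError("denominators must be >= 1")
        prod *= d
    return alpha / prod


def prepare_phenotypes(
    phenotypes: pd.DataFrame, covariates: pd.DataFrame
) -> PreparedPhenotypes:
    """Covariate adjustment followed by per-species inverse-normal transform."""
    resid = adjust_covariates(phenotypes, covariates)
    transformed = resid.apply(
        lambda col: inverse_normal_transform(col.to_numpy()), axis=0,
        result_type="broadcast",
    )
    return PreparedPhenotypes(
        residuals=transformed,
        n_per_species=transformed.notna().sum(),
        covariates_removed=list(covariates.columns),
    )
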