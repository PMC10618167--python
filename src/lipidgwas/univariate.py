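"""Per-variant association of a prepared phenotype with genotype dosages.

The default model is ordinary least squares of the inverse-normal-transformed
residual phenotype on dosage (intercept included), with a Wald two-sided
p-value from the normal approximation — appropriate for unrelated samples at
GWAS sample sizes.  A one-variance-component linear mixed model (``lmm``) is
available for cohorts with relatedness structure: the genetic variance share
is estimated once on the null model through the GRM eigenbasis and each
variant is then tested by generalized least squares in that basis.

The module follows the statsmodels convention: :class:`GwasModel` is built
from data and ``fit()`` returns :class:`GwasResults` carrying the summary
statistics table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

__all__ = [
    "VariantFilter",
    "filter_variants",
    "GwasModel",
    "GwasResults",
    "gwas",
    "lambda_gc",
]

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # ~0.4549


@dataclass(frozen=True)
class VariantFilter:
    """MAF and imputation-INFO inclusion filter (boundaries kept)."""

    maf_min: float = 0.002
    info_min: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if not (0.0 <= self.info_min <= 1.0):
            raise ValueError("info_min must be in [0, 1]")


def filter_variants(
    variants: pd.DataFrame, flt: VariantFilter = VariantFilter()
) -> pd.Index:
    """Indices of variants with MAF >= maf_min and INFO >= info_min."""
    for col in ("maf", "info"):
        if col not in variants.columns:
            raise ValueError(f"variant table lacks column {col!r}")
    keep = (variants["maf"] >= flt.maf_min) & (variants["info"] >= flt.info_min)
    return variants.index[keep]


class GwasModel:
    """Single-trait GWAS: phenotype vector against a dosage matrix.

    Parameters
    ----------
    phenotype : array-like, already covariate-adjusted and INT'd; NaN marks
        missing samples, which are excluded (per-trait complete cases).
    genotypes : (n_samples, n_variants) dosage matrix.
    variants : variant table aligned with the genotype columns
        (chrom, pos, id, ref, alt, maf, info).
    grm_eig : optional ``(eigenvalues, eigenvectors)`` of a GRM, enabling the
        ``lmm`` model.
    """

    def __init__(self, phenotype, genotypes, variants: pd.DataFrame,
                 grm_eig: tuple[np.ndarray, np.ndarray] | None = None):
        self.phenotype = np.asarray(phenotype, dtype=float)
        self.genotypes = np.asarray(genotypes, dtype=float)
        if self.genotypes.shape[0] != self.phenotype.shape[0]:
            raise ValueError("phenotype/genotype sample mismatch")
        if len(variants) != self.genotypes.shape[1]:
            raise ValueError("variant table/genotype column mismatch")
        self.variants = variants.reset_index(drop=True)
        self.grm_eig = grm_eig

    def fit(self, model: str = "ols") -> "GwasResults":
        if model == "ols":
            table = self._fit_ols()
        elif model == "lmm":
            table = self._fit_lmm()
        else:
            raise ValueError(f"unknown model {model!r}")
        key = table["chrom"].str.replace("chr", "", regex=False)
        table = (table.assign(_ck=pd.to_numeric(key, errors="coerce"))
                 .sort_values(["_ck", "chrom", "pos"], kind="mergesort")
                 .drop(columns="_ck").reset_index(drop=True))
        return GwasResults(table, model=model)

    # -- OLS: vectorized simple regression per variant ------------------------
    def _fit_ols(self) -> pd.DataFrame:
        ok = ~np.isnan(self.phenotype)
        y = self.phenotype[ok]
        G = self.genotypes[ok]
        n = y.size
        yc = y - y.mean()
        gm = G.mean(axis=0)
        gc = G - gm
        sxx = np.einsum("ij,ij->j", gc, gc)
        sxy = yc @ gc
        degenerate = sxx <= 0
        sxx_safe = np.where(degenerate, 1.0, sxx)
        beta = sxy / sxx_safe
        rss = yc @ yc - beta * sxy
        rss = np.clip(rss, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(rss / (n - 2) / sxx_safe)
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
        p = 2.0 * ndtr(-np.abs(z))
        p = np.where(degenerate | (se <= 0), 1.0, np.clip(p, 1e-320, 1.0))
        beta = np.where(degenerate, 0.0, beta)
        se = np.where(degenerate, np.nan, se)
        return self._table(beta, se, p, n, G)

    # -- LMM: GLS through the GRM eigenbasis -----------------------------------
    def _fit_lmm(self) -> pd.DataFrame:
        if self.grm_eig is None:
            raise ValueError("lmm model requires grm_eig")
        lam, U = self.grm_eig
        ok = ~np.isnan(self.phenotype)
        if not ok.all():
            raise ValueError("lmm requires a complete phenotype vector "
                             "(subset samples and the GRM first)")
        y = self.phenotype
        n = y.size
        yt = U.T @ y
        ones_t = U.T @ np.ones(n)

        def negll(h2: float) -> float:
            d = h2 * lam + (1.0 - h2)
            # profile out the intercept and total variance
            mu = (ones_t * yt / d).sum() / (ones_t**2 / d).sum()
            r = yt - mu * ones_t
            s2 = (r**2 / d).mean()
            return 0.5 * (np.log(d).sum() + n * np.log(s2))

        res = optimize.minimize_scalar(negll, bounds=(0.0, 0.999),
                                       method="bounded")
        h2 = float(res.x)
        d = h2 * lam + (1.0 - h2)
        Gt = U.T @ self.genotypes
        w = 1.0 / d
        # GLS of y on [1, g] with weight w in the rotated basis
        sw = w.sum()
        swx = w @ Gt
        swy = w @ yt
        swxy = (w * yt) @ Gt
        swxx = np.einsum("i,ij,ij->j", w, Gt, Gt)
        det = sw * swxx - swx**2
        degenerate = det <= 0
        det_safe = np.where(degenerate, 1.0, det)
        beta = (sw * swxy - swx * swy) / det_safe
        alpha = (swy - beta * swx) / sw
        resid = yt[:, None] - alpha[None, :] - Gt * beta[None, :]
        rss = np.einsum("i,ij,ij->j", w, resid, resid)
        s2 = rss / (n - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(s2 * sw / det_safe)
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
        p = 2.0 * ndtr(-np.abs(z))
        p = np.where(degenerate | (se <= 0), 1.0, np.clip(p, 1e-320, 1.0))
        beta = np.where(degenerate, 0.0, beta)
        se = np.where(degenerate, np.nan, se)
        return self._table(beta, se, p, n, self.genotypes)

    def _table(self, beta, se, p, n, G) -> pd.DataFrame:
        eaf = G.mean(axis=0) / 2.0
        return pd.DataFrame(
            {
                "chrom": self.variants["chrom"],
                "pos": self.variants["pos"],
                "id": self.variants["id"],
                "effect_allele": self.variants["alt"],
                "other_allele": self.variants["ref"],
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "p": p,
                "n": n,
                "info": self.variants["info"],
            }
        )


@dataclass
class GwasResults:
    """Summary-statistics table plus diagnostics for one trait's GWAS."""

    records: pd.DataFrame
    model: str = "ols"

    def lambda_gc(self) -> float:
        return lambda_gc(self.records["p"].to_numpy())

    def significant(self, threshold: float) -> pd.DataFrame:
        return self.records[self.records["p"] < threshold]

    def summary(self) -> str:
        r = self.records
        lines = [
            f"GWAS ({self.model}); {len(r)} variants, N = {int(r['n'].iloc[0])}",
            f"lambda_GC = {self.lambda_gc():.3f}" if len(r) >= 100 else
            "lambda_GC: n/a (<100 variants)",
            f"min p = {r['p'].min():.3g} at {r.loc[r['p'].idxmin(), 'id']}",
        ]
        return "\n".join(lines)


def gwas(
    phenotype,
    genotypes,
    variants: pd.DataFrame,
    model: str = "ols",
    grm_eig=None,
) -> pd.DataFrame:
    """Functional wrapper: fit :class:`GwasModel` and return the records table."""
    return GwasModel(phenotype, genotypes, variants, grm_eig).fit(model).records


def lambda_gc(p_values=None, chi_squares=None) -> float:
    """Genomic inflation factor: median observed 1-df chi-square over ~0.4549.

    Accepts either two-sided p-values (converted through the chi-square
    quantile function) or 1-df chi-square statistics directly.
    """
    if chi_squares is None:
        if p_values is None:
            raise ValueError("provide p_values or chi_squares")
        p = np.asarray(p_values, float)
        if p.size < 100:
            raise ValueError("need at least 100 values")
        chi_squares = stats.chi2.isf(np.clip(p, 1e-320, 1.0), 1)
    chi_squares = np.asarray(chi_squares, float)
    if chi_squares.size < 100:
        raise ValueError("need at least 100 values")
    return float(np.median(chi_squares) / CHI2_1_MEDIAN)
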