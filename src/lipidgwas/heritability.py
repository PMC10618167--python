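"""GRM construction with LD pruning, SNP-heritability estimation, genetic PCs.

The genetic relationship matrix is ``A = Z Z' / m`` over LD-pruned,
frequency- and quality-filtered variants, with each dosage column
standardized to mean 0, variance 1.  Heritability is estimated either by
Haseman-Elston regression (regress the off-diagonal phenotype products
``y_i * y_j`` on ``A_ij``; the slope is h2) or by single-component maximum
likelihood on the GRM eigenbasis ("reml" method), with a standard error from
the expected information.  The top GRM eigenvectors double as genetic PCs
for covariate adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "GrmSpec",
    "HeritabilityEstimate",
    "Grm",
    "ld_prune",
    "grm",
    "estimate_h2",
    "HeritabilityModel",
]


@dataclass(frozen=True)
class GrmSpec:
    """Variant filters and LD-pruning parameters for GRM construction."""

    maf_min: float = 0.01
    info_min: float = 0.95
    missing_max: float = 0.03
    prune_window_kb: float = 1000.0
    prune_step: int = 1
    prune_r2: float = 0.7
    excluded_regions: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.prune_r2 <= 1.0):
            raise ValueError("prune r2 must be in (0, 1]")
        if self.prune_window_kb <= 0:
            raise ValueError("prune window must be positive")


@dataclass
class HeritabilityEstimate:
    """SNP-heritability estimate with its uncertainty."""

    h2: float
    se: float
    method: str
    clamped: bool = False
    raw: float = 0.0

    def summary(self) -> str:
        note = " (clamped to [0,1])" if self.clamped else ""
        return f"h2 = {self.h2:.3f} (SE {self.se:.3f}, {self.method}){note}"


def ld_prune(
    genotypes: np.ndarray, variants: pd.DataFrame, spec: GrmSpec = GrmSpec()
) -> list[int]:
    """Greedy windowed LD pruning; returns kept variant row indices.

    A window of ``prune_window_kb`` advances by ``prune_step`` variants; for
    any in-window pair with r^2 above the threshold one variant is dropped —
    the one with lower MAF, ties broken toward the later position.  Variants
    failing the MAF/INFO/missingness filters or inside an excluded region are
    dropped up front.  Deterministic.
    """
    n, m = genotypes.shape
    pos = variants["pos"].to_numpy()
    chrom = variants["chrom"].to_numpy()
    maf = variants["maf"].to_numpy()
    info = variants["info"].to_numpy() if "info" in variants else np.ones(m)
    miss = np.isnan(genotypes).mean(axis=0)

    alive = (maf >= spec.maf_min) & (info >= spec.info_min) & (miss <= spec.missing_max)
    for c, lo, hi in spec.excluded_regions:
        alive &= ~((chrom == c) & (pos >= lo) & (pos <= hi))
    alive = alive.copy()

    window_bp = spec.prune_window_kb * 1000.0
    order = np.lexsort((pos, chrom))
    Gs = genotypes - np.nanmean(genotypes, axis=0)
    sd = np.nanstd(Gs, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Gs = np.where(np.isnan(Gs), 0.0, Gs / sd)

    for start_i in range(0, m, max(1, spec.prune_step)):
        i = order[start_i]
        if not alive[i]:
            continue
        in_win = [j for j in order
                  if alive[j] and chrom[j] == chrom[i]
                  and pos[i] <= pos[j] <= pos[i] + window_bp]
        for a_idx in range(len(in_win)):
            a = in_win[a_idx]
            if not alive[a]:
                continue
            for b in in_win[a_idx + 1:]:
                if not alive[b]:
                    continue
                r = float(Gs[:, a] @ Gs[:, b]) / n
                if r * r > spec.prune_r2:
                    if maf[a] < maf[b]:
                        victim = a
                    elif maf[b] < maf[a]:
                        victim = b
                    else:
                        victim = a if pos[a] > pos[b] else b
                    alive[victim] = False
                    if victim == a:
                        break
    return [int(i) for i in np.flatnonzero(alive)]


@dataclass
class Grm:
    """A genetic relationship matrix with its eigen-structure.

    ``matrix`` is ``Z Z'/m``; ``eigenvalues``/``eigenvectors`` give the full
    spectrum (computed from the SVD of Z, so zero eigenvalues are exact for
    m < n), and ``pcs`` holds the top-10 eigenvectors as genetic PCs.
    """

    matrix: np.ndarray
    eigenvalues: np.ndarray  # nonzero part of the spectrum (length <= rank)
    eigenvectors: np.ndarray  # matching columns; the null space is implicit
    n_variants: int

    @property
    def pcs(self) -> np.ndarray:
        return self.eigenvectors[:, : min(10, self.eigenvectors.shape[1])]

    def save(self, path_prefix: str) -> None:
        n = self.matrix.shape[0]
        ii, jj = np.tril_indices(n)
        pd.DataFrame({"i": ii + 1, "j": jj + 1,
                      "value": self.matrix[ii, jj]}).to_csv(
            f"{path_prefix}.grm.tsv", sep="\t", index=False)
        pd.DataFrame(self.pcs).to_csv(f"{path_prefix}.pcs.tsv", sep="\t",
                                      index=False, header=False)


def grm(genotypes: np.ndarray, kept: list[int] | None = None) -> Grm:
    """Build the GRM from (a pruned subset of) the dosage matrix.

    Monomorphic variants are dropped with a warning.  Eigen-structure comes
    from the SVD of the standardized dosage matrix, cheap when the variant
    count is below the sample count.
    """
    G = genotypes if kept is None else genotypes[:, kept]
    mu = np.nanmean(G, axis=0)
    sd = np.nanstd(G, axis=0)
    mono = sd <= 0
    if mono.any():
        warnings.warn(f"dropping {int(mono.sum())} monomorphic variants",
                      stacklevel=2)
        G = G[:, ~mono]
        mu, sd = mu[~mono], sd[~mono]
    m = G.shape[1]
    if m < 10:
        raise ValueError("need at least 10 variants after pruning")
    Z = (G - mu) / sd
    Z = np.where(np.isnan(Z), 0.0, Z)
    A = Z @ Z.T / m
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    return Grm(matrix=A, eigenvalues=s**2 / m, eigenvectors=U, n_variants=m)


class HeritabilityModel:
    """Single-trait SNP-heritability model against a GRM."""

    def __init__(self, phenotype, grm_obj: Grm):
        y = np.asarray(phenotype, float)
        ok = ~np.isnan(y)
        if not ok.all():
            raise ValueError("phenotype must be complete for the supplied GRM; "
                             "subset samples first")
        if np.var(y) <= 0:
            raise ValueError("zero phenotype variance")
        self.y = y
        self.grm = grm_obj

    def fit(self, method: str = "haseman_elston") -> HeritabilityEstimate:
        if method == "haseman_elston":
            return self._fit_he()
        if method == "reml":
            return self._fit_reml()
        raise ValueError(f"unknown method {method!r}")

    def _fit_he(self) -> HeritabilityEstimate:
        # slope of y_i y_j on A_ij over pairs i<j; pairs sharing a sample are
        # dependent, so the SE is a delete-one-sample jackknife rather than
        # the (anti-conservative) naive regression SE
        y = self.y
        ys = (y - y.mean()) / y.std()
        n = y.size
        A = self.grm.matrix
        diag = np.diag(A)
        Ay = A @ ys
        T = ys.sum()

        row_a = A.sum(axis=1) - diag
        row_aa = (A * A).sum(axis=1) - diag**2
        row_p = ys * (T - ys)
        row_ap = ys * (Ay - diag * ys)

        N = n * (n - 1) / 2.0
        Sa, Saa = row_a.sum() / 2.0, row_aa.sum() / 2.0
        Sp, Sap = row_p.sum() / 2.0, row_ap.sum() / 2.0

        def slope_of(Np, sa, saa, sp, sap):
            den = Np * saa - sa**2
            return (Np * sap - sa * sp) / den

        slope = float(slope_of(N, Sa, Saa, Sp, Sap))
        Nl = (n - 1) * (n - 2) / 2.0
        loo = slope_of(Nl, Sa - row_a, Saa - row_aa, Sp - row_p,
                       Sap - row_ap)
        se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
        return _clamped(slope, se, "haseman_elston")

    def _fit_reml(self) -> HeritabilityEstimate:
        # the stored eigen-structure covers the nonzero spectrum; the GRM's
        # null space contributes eigenvalue 0 with multiplicity n - r, whose
        # sufficient statistic is the residual sum of squares
        lam = self.grm.eigenvalues
        U = self.grm.eigenvectors
        y = self.y - self.y.mean()
        n = y.size
        r = lam.size
        yt = U.T @ y
        resid_ss = max(float(y @ y - yt @ yt), 0.0)

        def parts(h2: float):
            d = h2 * lam + (1.0 - h2)
            d0 = 1.0 - h2
            s2 = ((yt**2 / d).sum() + resid_ss / d0) / n
            logdet = np.log(d).sum() + (n - r) * np.log(d0)
            return d, d0, s2, logdet

        def negll(h2: float) -> float:
            _, _, s2, logdet = parts(h2)
            return 0.5 * (logdet + n * np.log(s2) + n)

        res = optimize.minimize_scalar(negll, bounds=(1e-6, 1 - 1e-6),
                                       method="bounded",
                                       options={"xatol": 1e-8})
        h2 = float(res.x)
        d, d0, s2, _ = parts(h2)
        # expected information for (h2, s2); SE is sqrt of the (h2, h2)
        # entry of its inverse
        c = np.concatenate([(lam - 1.0) / d, np.full(n - r, -1.0 / d0)])
        i11 = 0.5 * np.sum(c**2)
        i12 = 0.5 * np.sum(c) / s2
        i22 = 0.5 * n / s2**2
        det = i11 * i22 - i12**2
        var_h2 = i22 / det if det > 0 else np.inf
        return _clamped(h2, float(np.sqrt(var_h2)), "reml")


def _clamped(raw: float, se: float, method: str) -> HeritabilityEstimate:
    h2 = min(max(raw, 0.0), 1.0)
    return HeritabilityEstimate(h2=h2, se=se, method=method,
                                clamped=(h2 != raw), raw=raw)


def estimate_h2(
    phenotype, grm_obj: Grm, method: str = "haseman_elston"
) -> HeritabilityEstimate:
    """Functional wrapper over :class:`HeritabilityModel`."""
    return HeritabilityModel(phenotype, grm_obj).fit(method)
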