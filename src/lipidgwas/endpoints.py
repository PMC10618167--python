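"""PheWAS-style endpoint association and credible-set colocalization.

Selected variants (GWAS leads and credible-set representatives) are tested
against binary disease endpoints with per-endpoint logistic regression
(dosage plus covariates, Wald two-sided p), reported at two tiers: the
nominal level and the genome-wide level, each Bonferroni-corrected for the
endpoint count.  The effective case-control sample size is
``N_eff = N * theta * (1 - theta)`` with theta the case proportion; it is
also the sample size handed to endpoint fine-mapping on logistic z-scores.
Colocalization between a lipid-trait credible set and an endpoint credible
set is the colocalization posterior probability

    CLPP = sum over shared variants of PIP_trait(s) * PIP_endpoint(s),

called colocalized when CLPP > 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .finemap import CredibleSet

__all__ = [
    "EndpointDefinition",
    "ColocPair",
    "neff",
    "phewas",
    "logistic_assoc",
    "clpp",
    "variant_lookup",
    "phewas_coloc_summary",
]


@dataclass
class EndpointDefinition:
    """A binary endpoint with its effective sample size."""

    endpoint_id: str
    status: np.ndarray  # 0/1 per sample
    group: str = ""

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status)
        self.n = int(self.status.size)
        self.theta = float(self.status.mean())
        if not (0.0 < self.theta < 1.0):
            raise ValueError("endpoint has no cases or no controls")
        self.n_eff = neff(self.n, self.theta)
        self.n_cases = int(self.status.sum())

    @property
    def included(self) -> bool:
        return self.n_cases >= 50


@dataclass
class ColocPair:
    trait_signal: int
    endpoint_signal: int
    clpp: float
    colocalized: bool


def neff(n: float, theta: float) -> float:
    """Effective case-control sample size N * theta * (1 - theta)."""
    if n < 1:
        raise ValueError("N must be >= 1")
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must be in [0, 1]")
    return float(n) * theta * (1.0 - theta)


def logistic_assoc(
    status: np.ndarray, dosage: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, float, bool]:
    """Logistic regression of case status on dosage (+ covariates).

    Returns (beta, se, p, penalized_flag); falls back to an L2-penalized fit
    when the plain fit fails to converge (e.g. complete separation).
    """
    X = [np.ones_like(dosage, dtype=float), np.asarray(dosage, float)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != len(dosage):
            cov = cov.T
        X.extend(cov.T)
    X = np.column_stack(X)
    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(status, X).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", True) or \
                    not np.isfinite(fit.bse[1]) or fit.bse[1] > 100:
                raise RuntimeError("non-converged")
        except Exception:
            penalized = True
            fit = sm.Logit(status, X).fit_regularized(
                alpha=1e-3, L1_wt=0.0, disp=0, maxiter=500)
    beta = float(fit.params[1])
    try:
        se = float(fit.bse[1])
    except Exception:
        se = float("nan")
    if np.isfinite(se) and se > 0:
        from scipy.special import ndtr
        p = float(2.0 * ndtr(-abs(beta / se)))
    else:
        p = 1.0
    return beta, se, p, penalized


def phewas(
    variants: dict[str, np.ndarray],
    endpoints: list[EndpointDefinition],
    covariates: np.ndarray | None = None,
    n_endpoints_total: int | None = None,
    alpha_nominal: float = 0.05,
    alpha_gw: float = 5e-8,
) -> pd.DataFrame:
    """Per variant x endpoint logistic association table with tier flags.

    Endpoints failing the >= 50 cases rule are excluded with a warning.
    Tiers: nominal-corrected (alpha_nominal / n_endpoints) and GWS-corrected
    (alpha_gw / n_endpoints); the divisor defaults to the number of included
    endpoints but can be fixed (e.g. a catalogue size) via
    ``n_endpoints_total``.
    """
    usable = []
    for ep in endpoints:
        if not ep.included:
            warnings.warn(
                f"endpoint {ep.endpoint_id!r} has {ep.n_cases} cases (< 50); "
                "excluded", stacklevel=2)
            continue
        usable.append(ep)
    n_ep = n_endpoints_total if n_endpoints_total is not None else len(usable)
    if n_ep == 0:
        return pd.DataFrame(columns=["variant", "endpoint", "beta", "se", "p",
                                     "penalized", "nominal_corrected",
                                     "gws_corrected", "n_eff"])
    thr_nom = alpha_nominal / n_ep
    thr_gws = alpha_gw / n_ep
    rows = []
    for vid, dosage in variants.items():
        for ep in usable:
            beta, se, p, pen = logistic_assoc(ep.status, dosage, covariates)
            rows.append({
                "variant": vid, "endpoint": ep.endpoint_id,
                "beta": beta, "se": se, "p": p, "penalized": pen,
                "nominal_corrected": p < thr_nom,
                "gws_corrected": p < thr_gws,
                "n_eff": ep.n_eff,
            })
    return pd.DataFrame(rows)


def clpp(
    cs_trait: CredibleSet, cs_endpoint: CredibleSet, threshold: float = 0.01
) -> ColocPair:
    """Colocalization posterior probability between two credible sets.

    Sums, over variants in both sets, the product of the two per-signal
    PIPs.  Zero when the member sets are disjoint.
    """
    shared = set(cs_trait.members) & set(cs_endpoint.members)
    value = sum(cs_trait.pips.get(s, 0.0) * cs_endpoint.pips.get(s, 0.0)
                for s in shared)
    return ColocPair(
        trait_signal=cs_trait.signal_index,
        endpoint_signal=cs_endpoint.signal_index,
        clpp=float(value),
        colocalized=value > threshold,
    )


def variant_lookup(
    external: pd.DataFrame,
    sumstats: dict[str, pd.DataFrame],
    ld,
    tier_nominal: float,
    tier_gws: float = 5e-8,
    tier_gws_corrected: float | None = None,
    proxy_r2: float = 0.8,
    proxy_window: int = 500_000,
) -> pd.DataFrame:
    """Tiered lookup of external (e.g. CAD) risk variants in the lipid stats.

    ``external`` needs columns (id, chrom, pos, risk_allele).  A variant
    absent from the data is replaced by the in-sample variant with the
    highest r^2 > proxy_r2 within the proxy window, else dropped (logged in
    the 'note' column of the returned table via a sentinel row).  Effects
    are aligned to the risk allele; each association is labeled with the
    highest tier it reaches.
    """
    rows = []
    any_stats = next(iter(sumstats.values()))
    pos_of = dict(zip(any_stats["id"], any_stats["pos"]))
    chrom_of = dict(zip(any_stats["id"], any_stats["chrom"]))
    for row in external.itertuples():
        target, note = row.id, ""
        if target not in pos_of:
            target = _best_proxy(row, ld, pos_of, chrom_of, proxy_r2,
                                 proxy_window)
            if target is None:
                rows.append({"external_id": row.id, "variant": "", "trait": "",
                             "beta": np.nan, "p": np.nan, "tier": "",
                             "note": "dropped: no proxy"})
                continue
            note = f"proxy for {row.id}"
        for trait, stats in sumstats.items():
            rec = stats[stats["id"] == target]
            if not len(rec):
                continue
            rec = rec.iloc[0]
            beta, p = float(rec["beta"]), float(rec["p"])
            if ("effect_allele" in rec.index
                    and getattr(row, "risk_allele", None) is not None
                    and row.risk_allele == rec.get("other_allele")):
                beta = -beta
            if p < (tier_gws_corrected or 0.0):
                tier = "GWS-corrected"
            elif p < tier_gws:
                tier = "GWS"
            elif p < tier_nominal:
                tier = "nominal-corrected"
            else:
                tier = ""
            rows.append({"external_id": row.id, "variant": target,
                         "trait": trait, "beta": beta, "p": p, "tier": tier,
                         "note": note})
    return pd.DataFrame(rows)


def _best_proxy(row, ld, pos_of, chrom_of, proxy_r2, proxy_window):
    best, best_r2 = None, proxy_r2
    if ld is None or row.id not in getattr(ld, "variant_ids", []):
        # proxy search needs LD with the external variant itself; when the
        # variant is absent from the LD panel fall back to proximity alone
        return None
    for vid in ld.variant_ids:
        if vid == row.id or vid not in pos_of:
            continue
        if chrom_of[vid] != row.chrom or abs(pos_of[vid] - row.pos) > proxy_window:
            continue
        r2 = ld.r2(row.id, vid)
        if r2 > best_r2:
            best, best_r2 = vid, r2
    return best


def phewas_coloc_summary(
    phewas_table: pd.DataFrame,
    coloc_table: pd.DataFrame,
) -> pd.DataFrame:
    """Disease-group heatmap rule: flag (trait, endpoint) pairs that are both
    GWS-corrected in the PheWAS and colocalized (CLPP > 0.01)."""
    ph = phewas_table[phewas_table["gws_corrected"]]
    merged = ph.merge(coloc_table, on=["variant", "endpoint"], how="inner")
    out = (merged[merged["colocalized"]]
           .groupby(["trait", "endpoint"], as_index=False)
           .agg(best_p=("p", "min"), best_clpp=("clpp", "max")))
    return out
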