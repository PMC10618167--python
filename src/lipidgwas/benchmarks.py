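"""End-to-end verification benchmarks for the pipeline.

Each function simulates its own inputs from a seed, runs the relevant stage
of the pipeline, and returns the measured quantities as a plain dict.  The
test suite asserts on these numbers; the reproduction script reports them.
Independent oracles (generic canonical-correlation eigen-computation,
brute-force configuration enumeration via multivariate-normal densities,
brute-force CLPP) live here, outside the implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .endpoints import clpp, logistic_assoc
from .finemap import CredibleSet, FinemapConfig, LdMatrix, finemap_region
from .heritability import HeritabilityModel, grm
from .multivariate import (_cca_chisq_from_corr, _per_trait_bstand,
                           _shrink_to_invertible, cca_test,
                           permutation_lambda)
from .phenotypes import bonferroni_threshold
from .univariate import gwas, lambda_gc

__all__ = [
    "threshold_suite",
    "cca_oracle_check",
    "null_calibration",
    "rare_variant_inflation",
    "multivariate_power_gain",
    "finemap_oracle_check",
    "finemap_recovery",
    "finemap_calibration",
    "clpp_checks",
    "locus_handtrace_check",
    "h2_recovery",
]


# ---------------------------------------------------------------------------
# Printed multiple-testing thresholds
# ---------------------------------------------------------------------------

def threshold_suite() -> dict[str, float]:
    """The Bonferroni-derived significance thresholds of the analysis plan.

    68 effective lipidome dimensions (PCs explaining >90% variance), 11
    multivariate clusters, 85 genome-wide-significant loci, 953 PheWAS
    endpoints.
    """
    return {
        "bfs_univariate": bonferroni_threshold(5e-8, [68]),
        "bfs_multivariate": bonferroni_threshold(5e-8, [11]),
        "marginal_uv": bonferroni_threshold(0.05, [85, 68]),
        "phewas_nominal": bonferroni_threshold(0.05, [953]),
        "phewas_gws": bonferroni_threshold(5e-8, [953]),
        "cad_lookup_uv": bonferroni_threshold(0.05, [68]),
        "cad_lookup_mv": bonferroni_threshold(0.05, [11]),
    }


# ---------------------------------------------------------------------------
# Canonical-correlation test vs a generic CCA eigen-computation
# ---------------------------------------------------------------------------

def _random_correlation(rng: np.random.Generator, q: int) -> np.ndarray:
    A = rng.standard_normal((q, q + 2))
    S = np.corrcoef(A)
    S, _ = _shrink_to_invertible(S, 1e-2)
    return S


def generic_cca_r2(b: np.ndarray, syy: np.ndarray) -> float:
    """Largest eigenvalue of S_XX^{-1} S_XY S_YY^{-1} S_YX for a single
    genotype variable (S_XX = 1, S_XY = b')."""
    M = np.outer(b, b) @ np.linalg.inv(syy)  # S_YX S_XX^{-1} S_XY S_YY^{-1}
    ev = np.linalg.eigvals(np.linalg.inv(syy) @ np.outer(b, b))
    return float(np.max(ev.real))


def cca_oracle_check(seed: int = 0, n_instances: int = 100) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_instances):
        q = int(rng.integers(1, 7))
        S = _random_correlation(rng, q) if q > 1 else np.eye(1)
        b = rng.normal(0.0, 0.03, q)
        n = float(rng.integers(1000, 8000))
        res = cca_test(b, S, n)
        r2_oracle = generic_cca_r2(b, S)
        max_diff = max(max_diff, abs(res.r**2 - r2_oracle))
    # q = 1 small-r equivalence: chi2 vs the univariate z^2 = N b^2
    res1 = cca_test(np.array([0.05]), np.eye(1), 1000.0)
    rel = abs(res1.chisq - 1000.0 * 0.05**2) / (1000.0 * 0.05**2)
    return {"cca_oracle_max_abs_diff": max_diff, "cca_q1_rel_err": rel}


# ---------------------------------------------------------------------------
# Null calibration of the univariate and multivariate tests
# ---------------------------------------------------------------------------

def _correlated_traits(rng: np.random.Generator, n: int, q: int,
                       rho: float = 0.4) -> np.ndarray:
    f = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, q))
    return np.sqrt(rho) * f + np.sqrt(1 - rho) * eps


def _mv_chisq_for_genotypes(G: np.ndarray, Y: np.ndarray,
                            S: np.ndarray) -> np.ndarray:
    """Exact per-variant multivariate chi-square from phenotype-level data."""
    n, q = Y.shape
    Ys = (Y - Y.mean(axis=0)) / Y.std(axis=0)
    Gs = (G - G.mean(axis=0)) / G.std(axis=0)
    R = Gs.T @ Ys / n
    tt = R * np.sqrt((n - 2) / np.clip(1.0 - R**2, 1e-12, None))
    B = tt / np.sqrt(n)
    L = np.linalg.cholesky(S)
    return _cca_chisq_from_corr(B, L, n, q)


def null_calibration(seed: int = 0, n_samples: int = 5000,
                     n_variants: int = 10_000, q: int = 5,
                     alpha: float = 0.05) -> dict[str, float]:
    """Type-I error and genomic inflation on independent null common variants."""
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.05, 0.5, n_variants)
    G = rng.binomial(2, maf, size=(n_samples, n_variants)).astype(np.float64)
    Y = _correlated_traits(rng, n_samples, q)

    # univariate: trait 1 against every variant
    variants = pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(1, n_variants + 1) * 1000,
        "id": [f"v{i}" for i in range(n_variants)], "ref": "A", "alt": "G",
        "maf": np.minimum(maf, 1 - maf), "info": 1.0,
    })
    uv = gwas(Y[:, 0], G, variants)
    uv_p = uv["p"].to_numpy()

    S = np.corrcoef(Y, rowvar=False)
    S, _ = _shrink_to_invertible(S)
    chis = _mv_chisq_for_genotypes(G, Y, S)
    mv_p = stats.chi2.sf(chis, q)
    return {
        "uv_type1": float((uv_p < alpha).mean()),
        "mv_type1": float((mv_p < alpha).mean()),
        "uv_lambda": lambda_gc(uv_p),
        "mv_lambda": float(np.median(chis) / stats.chi2.ppf(0.5, q)),
    }


# ---------------------------------------------------------------------------
# Rare-variant inflation and permutation-based correction
# ---------------------------------------------------------------------------

def rare_variant_inflation(seed: int = 0, maf: float = 0.005, q: int = 10,
                           n_samples: int = 2000, n_perm: int = 10_000,
                           n_null: int = 2000) -> dict[str, float]:
    """Permutation lambda for a rare variant and calibration of corrected
    p-values on an independent set of null rare variants of the same MAF."""
    rng = np.random.default_rng(seed)
    Y = _correlated_traits(rng, n_samples, q)
    g_ref = rng.binomial(2, maf, n_samples).astype(float)
    while g_ref.std() == 0:
        g_ref = rng.binomial(2, maf, n_samples).astype(float)
    est = permutation_lambda(g_ref, Y, n_perm=n_perm, seed=seed)

    G = rng.binomial(2, maf, size=(n_samples, n_null)).astype(float)
    keep = G.std(axis=0) > 0
    G = G[:, keep]
    S = np.corrcoef(Y, rowvar=False)
    S, _ = _shrink_to_invertible(S)
    chis = _mv_chisq_for_genotypes(G, Y, S)
    raw_p = stats.chi2.sf(chis, q)
    corr_p = stats.chi2.sf(chis / est.lam, q)
    return {
        "perm_lambda": est.lam,
        "raw_lambda": float(np.median(chis) / stats.chi2.ppf(0.5, q)),
        "ks_p_raw": float(stats.kstest(raw_p, "uniform").pvalue),
        "ks_p_corrected": float(stats.kstest(corr_p, "uniform").pvalue),
    }


# ---------------------------------------------------------------------------
# Multivariate power gain on sign-canceling effects
# ---------------------------------------------------------------------------

def multivariate_power_gain(seed: int = 0, n_rep: int = 50,
                            n_samples: int = 5000, q: int = 5,
                            effect: float = 0.05, rho: float = 0.5,
                            maf: float = 0.3) -> dict[str, float]:
    """Fraction of replicates where the multivariate p beats the best
    Bonferroni-adjusted univariate p for a planted sign-canceling effect."""
    rng = np.random.default_rng(seed)
    wins = 0
    for _ in range(n_rep):
        g = rng.binomial(2, maf, n_samples).astype(float)
        gs = (g - g.mean()) / g.std()
        Y = _correlated_traits(rng, n_samples, q, rho)
        Y[:, 0] += effect * gs
        Y[:, 1] -= effect * gs
        b = _per_trait_bstand(g, Y)
        uv_t = b * np.sqrt(n_samples)
        uv_p = 2 * stats.norm.sf(np.abs(uv_t))
        S = np.corrcoef(Y, rowvar=False)
        S, _ = _shrink_to_invertible(S)
        res = cca_test(b, S, float(n_samples))
        if res.p < min(float(uv_p.min()) * q, 1.0):
            wins += 1
    return {"mv_power_win_fraction": wins / n_rep}


# ---------------------------------------------------------------------------
# Fine-mapping: brute-force oracle, recovery and calibration
# ---------------------------------------------------------------------------

def bruteforce_posteriors(z: np.ndarray, R: np.ndarray, n: float,
                          k_max: int, sigma: float = 0.05,
                          pi: float | None = None) -> dict[tuple[int, ...], float]:
    """Independent enumeration using multivariate-normal log-densities."""
    m = z.size
    pi = pi if pi is not None else 1.0 / m
    logs = {}
    logs[()] = m * np.log1p(-pi)
    for k in range(1, k_max + 1):
        lp = k * np.log(pi) + (m - k) * np.log1p(-pi)
        for idx in itertools.combinations(range(m), k):
            Rc = R[np.ix_(idx, idx)]
            zc = z[list(idx)]
            s1 = Rc + n * sigma**2 * Rc @ Rc
            l1 = stats.multivariate_normal.logpdf(zc, cov=s1,
                                                  allow_singular=True)
            l0 = stats.multivariate_normal.logpdf(zc, cov=Rc,
                                                  allow_singular=True)
            logs[idx] = lp + l1 - l0
    vals = np.array(list(logs.values()))
    norm = np.log(np.exp(vals - vals.max()).sum()) + vals.max()
    return {k: float(np.exp(v - norm)) for k, v in logs.items()}


def _ld_region(rng: np.random.Generator, n: int, m: int, rho: float = 0.5,
               maf_range=(0.1, 0.4)) -> np.ndarray:
    """AR(1)-copula genotypes for one region."""
    maf = rng.uniform(*maf_range, m)
    thr = stats.norm.ppf(maf)
    eps = rng.standard_normal((n, 2, m))
    z = np.empty_like(eps)
    z[:, :, 0] = eps[:, :, 0]
    for t in range(1, m):
        z[:, :, t] = rho * z[:, :, t - 1] + np.sqrt(1 - rho**2) * eps[:, :, t]
    return (z < thr).sum(axis=1).astype(float)


def finemap_oracle_check(seed: int = 0, n_regions: int = 8,
                         m: int = 10, k_max: int = 3) -> dict[str, float]:
    """Max abs posterior difference vs the brute-force oracle."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_regions):
        G = _ld_region(rng, 800, m)
        keep = G.std(axis=0) > 0
        G = G[:, keep]
        mm = G.shape[1]
        causal = int(rng.integers(mm))
        gs = (G - G.mean(0)) / G.std(0)
        y = 0.12 * gs[:, causal] + rng.standard_normal(800)
        n = y.size
        r = gs.T @ ((y - y.mean()) / y.std()) / n
        z = r * np.sqrt(n)
        ld = LdMatrix.from_dosages(G, [f"v{i}" for i in range(mm)])
        res = finemap_region(z, ld, n, FinemapConfig(k_max=k_max))
        oracle = bruteforce_posteriors(z, res.model.R, n, k_max)
        for cfg_key, pv in oracle.items():
            worst = max(worst, abs(res.posteriors.get(cfg_key, 0.0) - pv))
    return {"finemap_oracle_max_abs_diff": worst}


def finemap_recovery(seed: int = 0, n_samples: int = 3000, m: int = 30,
                     z_target: float = 9.0) -> dict[str, float]:
    """PIP of a strong, weakly-linked planted causal variant."""
    rng = np.random.default_rng(seed)
    G = _ld_region(rng, n_samples, m, rho=0.15)
    gs = (G - G.mean(0)) / G.std(0)
    causal = m // 2
    beta = z_target / np.sqrt(n_samples)
    y = beta * gs[:, causal] + rng.standard_normal(n_samples)
    r = gs.T @ ((y - y.mean()) / y.std()) / n_samples
    z = r * np.sqrt(n_samples)
    ld = LdMatrix.from_dosages(G, [f"v{i}" for i in range(m)])
    res = finemap_region(z, ld, n_samples, FinemapConfig(k_max=2))
    return {"strong_causal_pip": float(res.pips.iloc[causal]),
            "z_at_causal": float(abs(z[causal]))}


def finemap_calibration(seed: int = 0, n_regions: int = 200,
                        n_samples: int = 1200, m: int = 15) -> dict[str, float]:
    """Among variants with PIP in [0.8, 1], the fraction truly causal."""
    rng = np.random.default_rng(seed)
    hits = total = 0
    for _ in range(n_regions):
        G = _ld_region(rng, n_samples, m, rho=0.4)
        keep = G.std(axis=0) > 0
        G = G[:, keep]
        mm = G.shape[1]
        gs = (G - G.mean(0)) / G.std(0)
        causal = int(rng.integers(mm))
        beta = rng.uniform(0.10, 0.20)
        y = beta * gs[:, causal] + rng.standard_normal(n_samples)
        r = gs.T @ ((y - y.mean()) / y.std()) / n_samples
        z = r * np.sqrt(n_samples)
        ld = LdMatrix.from_dosages(G, [f"v{i}" for i in range(mm)])
        res = finemap_region(z, ld, n_samples, FinemapConfig(k_max=2))
        sel = res.pips[(res.pips >= 0.8)]
        for vid, _pip in sel.items():
            total += 1
            hits += int(vid == f"v{causal}")
    frac = hits / total if total else float("nan")
    return {"pip80_true_fraction": frac, "pip80_count": float(total)}


# ---------------------------------------------------------------------------
# Colocalization
# ---------------------------------------------------------------------------

def _finemap_trait(y, G, ids, n, k_max=2):
    gs = (G - G.mean(0)) / G.std(0)
    r = gs.T @ ((y - y.mean()) / y.std()) / len(y)
    z = r * np.sqrt(len(y))
    ld = LdMatrix.from_dosages(G, ids)
    res = finemap_region(z, ld, len(y), FinemapConfig(k_max=k_max))
    css = res.credible_sets()
    return [cs for cs in css if cs.informative]


def _finemap_endpoint(status, G, ids, k_max=2):
    n = len(status)
    theta = status.mean()
    n_eff = n * theta * (1 - theta)
    zs = np.empty(G.shape[1])
    for j in range(G.shape[1]):
        beta, se, p, _ = logistic_assoc(status, G[:, j])
        zs[j] = beta / se if np.isfinite(se) and se > 0 else 0.0
    ld = LdMatrix.from_dosages(G, ids)
    res = finemap_region(zs, ld, n_eff, FinemapConfig(k_max=k_max))
    return [cs for cs in res.credible_sets() if cs.informative]


def clpp_bruteforce(cs_a: CredibleSet, cs_b: CredibleSet) -> float:
    total = 0.0
    for va in cs_a.members:
        for vb in cs_b.members:
            if va == vb:
                total += cs_a.pips[va] * cs_b.pips[vb]
    return total


def clpp_checks(seed: int = 0, n_seeds: int = 20, n_samples: int = 2500,
                m: int = 24) -> dict[str, float]:
    """Eq.-level brute-force agreement plus shared- vs distinct-causal rates."""
    rng = np.random.default_rng(seed)
    shared_hits = distinct_hits = shared_tot = distinct_tot = 0
    bf_diff = 0.0
    ids = [f"v{i}" for i in range(m)]
    for _ in range(n_seeds):
        G = _ld_region(rng, n_samples, m, rho=0.3)
        if (G.std(axis=0) <= 0).any():
            G = G + 0.0
            G[:, G.std(axis=0) <= 0] += rng.binomial(
                2, 0.3, (n_samples, int((G.std(axis=0) <= 0).sum())))
        gs = (G - G.mean(0)) / G.std(0)
        causal = m // 3
        far = m - 2  # low LD with `causal` under AR(1) decay
        y = 0.15 * gs[:, causal] + rng.standard_normal(n_samples)

        from scipy.special import expit
        # shared endpoint
        eta = -1.5 + 0.45 * G[:, causal]
        status_shared = (rng.random(n_samples) < expit(eta)).astype(int)
        # distinct endpoint
        eta2 = -1.5 + 0.45 * G[:, far]
        status_distinct = (rng.random(n_samples) < expit(eta2)).astype(int)

        trait_css = _finemap_trait(y, G, ids, n_samples)
        ep_shared = _finemap_endpoint(status_shared, G, ids)
        ep_distinct = _finemap_endpoint(status_distinct, G, ids)
        if trait_css and ep_shared:
            pair = clpp(trait_css[0], ep_shared[0])
            bf_diff = max(bf_diff, abs(
                pair.clpp - clpp_bruteforce(trait_css[0], ep_shared[0])))
            shared_tot += 1
            shared_hits += int(pair.colocalized)
        if trait_css and ep_distinct:
            pair = clpp(trait_css[0], ep_distinct[0])
            distinct_tot += 1
            distinct_hits += int(not pair.colocalized)
    return {
        "clpp_bruteforce_max_abs_diff": bf_diff,
        "clpp_shared_rate": shared_hits / shared_tot if shared_tot else float("nan"),
        "clpp_distinct_rate": distinct_hits / distinct_tot if distinct_tot else float("nan"),
        "clpp_shared_n": float(shared_tot),
        "clpp_distinct_n": float(distinct_tot),
    }


# ---------------------------------------------------------------------------
# Locus-definition hand-traces
# ---------------------------------------------------------------------------

def locus_handtrace_check() -> dict[str, float]:
    """Hand-traceable scenarios for region building, signal merging, novelty
    and naming; returns the fraction of checks that agree."""
    from .finemap import LdMatrix
    from .loci import (GwasRegion, call_novelty, find_regions, merge_signals,
                       name_locus)

    checks = []

    # two peaks 2 Mb apart -> one combined region; lower-p peak leads
    stats_df = pd.DataFrame({
        "chrom": "chr1",
        "pos": [10_000_000, 12_000_000, 30_000_000],
        "id": ["peakA", "peakB", "null"],
        "p": [1e-12, 1e-10, 0.5],
    })
    regions = find_regions(stats_df)
    checks.append(len(regions) == 1)
    checks.append(regions[0].lead == "peakA"
                  and regions[0].secondary_leads == ["peakB"])

    # five chained peaks spanning 7 Mb -> shrink loop, width < 6 Mb, leads kept
    pos = [10_000_000 + i * 1_750_000 for i in range(5)]
    chain = pd.DataFrame({
        "chrom": "chr2", "pos": pos,
        "id": [f"c{i}" for i in range(5)],
        "p": [1e-20, 1e-15, 1e-14, 1e-13, 1e-12],
    })
    regions = find_regions(chain)
    widths_ok = all(r.width < 6_000_000 for r in regions)
    leads = set()
    for r in regions:
        leads.add(r.lead)
        leads.update(r.secondary_leads)
    checks.append(widths_ok)
    checks.append(leads == {f"c{i}" for i in range(5)})

    # signal merging at r2 >= 0.1 and never across chromosomes
    ld = LdMatrix(["r1", "r2", "r3"],
                  np.array([[1.0, 0.5, 0.0],
                            [0.5, 1.0, 0.0],
                            [0.0, 0.0, 1.0]]))
    reg = lambda chrom, lead, lo, hi: GwasRegion(
        trait="t", chrom=chrom, lead=lead, lead_pos=(lo + hi) // 2,
        lead_p=1e-12, start=lo, end=hi)
    reps = [("r1", "t1", reg("chr1", "r1", 100, 200)),
            ("r2", "t2", reg("chr1", "r2", 150, 300)),
            ("r3", "t3", reg("chr2", "r3", 100, 200))]
    signals, loci_list = merge_signals(reps, ld)
    checks.append(len(signals) == 2 and len(loci_list) == 2)
    merged = [s for s in signals if len(s.representatives) == 2]
    checks.append(len(merged) == 1 and merged[0].representatives == ["r1", "r2"])

    # novelty: r2 < 0.1 with knowns -> novel; proximity fallback -> not novel
    known = pd.DataFrame({"id": ["k1"], "chrom": ["chr1"], "pos": [150]})
    ld2 = LdMatrix(["r1", "k1"], np.array([[1.0, 0.05], [0.05, 1.0]]))
    locus = loci_list[0]
    checks.append(call_novelty(locus, known, ld2) is True)
    absent_known = pd.DataFrame({"id": ["kx"], "chrom": ["chr1"],
                                 "pos": [locus.leads[0][1] + 1_000_000]})
    checks.append(call_novelty(locus, absent_known, ld2) is False)

    # naming: missense representative wins over the closest gene
    genes = pd.DataFrame({
        "chrom": ["chr1", "chr1"], "start": [100, 5_000],
        "end": [1_000, 6_000], "strand": ["+", "+"],
        "symbol": ["NEAR", "FARMIS"],
    })
    ann = pd.DataFrame({"id": ["r1", "r2"],
                        "consequence": ["intron_variant", "missense_variant"],
                        "gene": ["NEAR", "FARMIS"]})
    checks.append(name_locus(locus, genes, ann) == "FARMIS")
    ann2 = pd.DataFrame({"id": ["r1", "r2"],
                         "consequence": ["intron_variant", "intron_variant"],
                         "gene": ["", ""]})
    checks.append(name_locus(locus, genes, ann2) == "NEAR")

    return {"locus_handtrace_agreement": sum(checks) / len(checks)}


# ---------------------------------------------------------------------------
# Heritability recovery
# ---------------------------------------------------------------------------

def h2_recovery(seed: int = 0, n_seeds: int = 20, n_samples: int = 4000,
                n_snps: int = 800,
                h2_values=(0.0, 0.15, 0.35)) -> dict[str, float]:
    """Coverage of 2-SE intervals for both estimators under an
    infinitesimal architecture on the GRM variants."""
    rng = np.random.default_rng(seed)
    cover = {("haseman_elston", h): 0 for h in h2_values}
    cover.update({("reml", h): 0 for h in h2_values})
    for _ in range(n_seeds):
        maf = rng.uniform(0.05, 0.5, n_snps)
        G = rng.binomial(2, maf, size=(n_samples, n_snps)).astype(float)
        A = grm(G)
        Z = (G - G.mean(0)) / G.std(0)
        for h2 in h2_values:
            # components scaled to their exact variance shares, matching the
            # synthetic-lipidome convention (realized h2 = target)
            e = rng.standard_normal(n_samples)
            e = e / e.std()
            if h2 > 0:
                gvals = Z @ rng.standard_normal(n_snps)
                gvals = gvals / gvals.std()
                y = np.sqrt(h2) * gvals + np.sqrt(1 - h2) * e
            else:
                y = e
            model = HeritabilityModel(y, A)
            for method in ("haseman_elston", "reml"):
                est = model.fit(method)
                if abs(est.raw - h2) <= 2 * est.se:
                    cover[(method, h2)] += 1
    out = {}
    for (method, h2), c in cover.items():
        out[f"h2_cover_{method}_{h2:g}"] = c / n_seeds
    return out
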