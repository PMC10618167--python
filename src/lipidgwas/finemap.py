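"""Bayesian fine-mapping from summary statistics and in-sample LD.

Causal configurations of up to ``K_max`` variants are enumerated exhaustively
in a region.  For a configuration C the z-scores restricted to C follow

    z_C ~ N(0, R_C + N * sigma^2 * R_C R_C)    under C,
    z_C ~ N(0, R_C)                            under the null,

with R the signed in-sample dosage correlation matrix, N the GWAS sample
size and sigma^2 the prior variance of a standardized causal effect.  The
prior over configurations is independent inclusion at pi per variant
(default 1/m), truncated at K_max.  Posteriors are normalized over all
enumerated configurations; the marginal posterior inclusion probability
PIP(v) sums the posterior over configurations containing v; the MAP causal
count k* maximizes the posterior mass per configuration size.

Per-signal 95% credible sets are built from the MAP configuration by a swap
construction: fix the other MAP variants and let one slot range over all
candidates; the renormalized posteriors of those configurations are the
signal's per-variant PIPs, of which the smallest descending-PIP prefix with
mass >= 0.95 is the credible set.  A set is informative when the minimum
pairwise r^2 among its members is at least 0.1; an informative set's
representative is the top-PIP variant unless a functional variant in the
set has r^2 > 0.95 with it.  Regions overlapping the MHC (chr6:25-34 Mb by
default) are excluded and fall back to the GWAS lead variant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "LdMatrix",
    "CredibleSet",
    "FinemapConfig",
    "FineMapModel",
    "FineMapResults",
    "finemap_region",
    "build_credible_sets",
    "write_credible_sets",
    "representative_variant",
    "apply_region_exclusions",
    "FUNCTIONAL_CLASSES",
]

# deleteriousness-ordered functional consequence classes (most severe first)
FUNCTIONAL_CLASSES = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_region_variant",
)


@dataclass
class LdMatrix:
    """Signed in-sample dosage correlation for a region."""

    variant_ids: list[str]
    r: np.ndarray

    @classmethod
    def from_dosages(cls, genotypes: np.ndarray, variant_ids: list[str]) -> "LdMatrix":
        R = np.corrcoef(np.asarray(genotypes, float), rowvar=False)
        R = np.atleast_2d(R)
        np.fill_diagonal(R, 1.0)
        return cls(variant_ids=list(variant_ids), r=R)

    def r2(self, a: str, b: str) -> float:
        i, j = self.variant_ids.index(a), self.variant_ids.index(b)
        return float(self.r[i, j] ** 2)

    def save(self, path) -> None:
        pd.DataFrame(self.r, index=self.variant_ids,
                     columns=self.variant_ids).to_csv(path, sep="\t")

    @classmethod
    def load(cls, path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(variant_ids=list(df.columns), r=df.to_numpy(float))


@dataclass
class CredibleSet:
    """A 95% credible set for one association signal."""

    signal_index: int
    members: list[str]  # sorted by descending PIP
    pips: dict[str, float]  # per-signal PIPs over all candidates
    mass: float
    purity: float
    informative: bool
    representative: str


@dataclass
class FinemapConfig:
    k_max: int = 3
    prior_sigma: float = 0.05  # prior SD of a standardized causal effect
    prior_pi: float | None = None  # default 1/m
    mhc: tuple[str, int, int] = ("chr6", 25_000_000, 34_000_000)
    excluded_regions: tuple[tuple[str, int, int], ...] = ()
    functional_r2: float = 0.95
    enumeration_budget: dict = field(
        default_factory=lambda: {1: 5000, 2: 2000, 3: 200}
    )

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if not (0.0 < self.functional_r2 <= 1.0):
            raise ValueError("functional r2 threshold must be in (0, 1]")

    @property
    def all_exclusions(self) -> tuple[tuple[str, int, int], ...]:
        return (self.mhc, *self.excluded_regions) if self.mhc else self.excluded_regions


class FineMapModel:
    """Exhaustive-enumeration fine-mapping model for one region."""

    def __init__(self, z: np.ndarray, ld: LdMatrix, n: float,
                 config: FinemapConfig = None):
        self.z = np.asarray(z, float).ravel()
        self.ld = ld
        self.n = float(n)
        self.config = config or FinemapConfig()
        m = self.z.size
        if len(ld.variant_ids) != m:
            raise ValueError("z/LD size mismatch")
        budget = self.config.enumeration_budget.get(min(self.config.k_max, 3), 200)
        if m > budget:
            raise ValueError(
                f"region size {m} exceeds enumeration budget {budget} for "
                f"K_max = {self.config.k_max}"
            )
        R = 0.5 * (ld.r + ld.r.T)
        ev_min = float(np.linalg.eigvalsh(R).min())
        self.ridge_repaired = ev_min < -1e-8
        if self.ridge_repaired:
            R = R + (1e-6 - ev_min) * np.eye(m)
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
        self.R = R

    # -- likelihood ------------------------------------------------------------
    def _log_bf(self, idx: tuple[int, ...]) -> float:
        """log Bayes factor of configuration idx against the null."""
        k = len(idx)
        Rc = self.R[np.ix_(idx, idx)]
        zc = self.z[list(idx)]
        s = self.n * self.config.prior_sigma**2
        # Sigma1 = Rc + s Rc Rc; Sigma0 = Rc.  Using Rc = E V E':
        # log BF = -0.5 [ logdet(I + s Rc) + z' (Sigma1^{-1} - Sigma0^{-1}) z ]
        ev, V = np.linalg.eigh(Rc)
        ev = np.clip(ev, 1e-10, None)
        zt = V.T @ zc
        logdet = float(np.log1p(s * ev).sum())
        quad = float((zt**2 / ev * (1.0 / (1.0 + s * ev) - 1.0)).sum())
        return -0.5 * (logdet + quad)

    def _log_prior(self, k: int, m: int, pi: float) -> float:
        return k * math.log(pi) + (m - k) * math.log1p(-pi)

    def fit(self) -> "FineMapResults":
        m = self.z.size
        cfg = self.config
        pi = cfg.prior_pi if cfg.prior_pi is not None else 1.0 / m
        pi = min(pi, 0.999)  # keep the null configuration supportable
        log_posts: dict[tuple[int, ...], float] = {(): self._log_prior(0, m, pi)}
        for k in range(1, min(cfg.k_max, m) + 1):
            lp = self._log_prior(k, m, pi)
            for idx in itertools.combinations(range(m), k):
                log_posts[idx] = lp + self._log_bf(idx)
        keys = list(log_posts)
        vals = np.array([log_posts[c] for c in keys])
        log_norm = float(logsumexp(vals))
        post = {c: math.exp(v - log_norm) for c, v in zip(keys, vals)}

        pips = np.zeros(m)
        size_mass = np.zeros(min(cfg.k_max, m) + 1)
        for c, pval in post.items():
            size_mass[len(c)] += pval
            for i in c:
                pips[i] += pval
        k_star = int(np.argmax(size_mass))
        map_config: tuple[int, ...] = ()
        if k_star >= 1:
            best = None
            for c, pval in post.items():
                if len(c) == k_star and (best is None or pval > best[1]):
                    best = (c, pval)
            map_config = best[0]
        return FineMapResults(
            model=self,
            posteriors=post,
            log_norm=log_norm,
            pips=pd.Series(pips, index=self.ld.variant_ids),
            k_star=k_star,
            map_config=map_config,
            prior_pi=pi,
            ridge_repaired=self.ridge_repaired,
        )


@dataclass
class FineMapResults:
    model: FineMapModel
    posteriors: dict[tuple[int, ...], float]
    log_norm: float
    pips: pd.Series
    k_star: int
    map_config: tuple[int, ...]
    prior_pi: float
    ridge_repaired: bool

    def credible_sets(self, coverage: float = 0.95,
                      purity_min: float = 0.1) -> list[CredibleSet]:
        return build_credible_sets(self, self.model.ld, self.k_star,
                                   coverage=coverage, purity_min=purity_min)

    def summary(self) -> str:
        lines = [
            f"fine-mapping: m = {self.pips.size}, K_max = "
            f"{self.model.config.k_max}, MAP causal count k* = {self.k_star}",
            "top PIPs: " + ", ".join(
                f"{v}={p:.3f}" for v, p in
                self.pips.sort_values(ascending=False).head(3).items()),
        ]
        if self.ridge_repaired:
            lines.append("note: LD matrix ridge-repaired")
        return "\n".join(lines)


def finemap_region(
    z: np.ndarray, ld: LdMatrix, n: float, config: FinemapConfig | None = None
) -> FineMapResults:
    """Functional wrapper: enumerate configurations and return posteriors."""
    return FineMapModel(z, ld, n, config).fit()


def build_credible_sets(
    results: FineMapResults,
    ld: LdMatrix,
    k_star: int | None = None,
    coverage: float = 0.95,
    purity_min: float = 0.1,
) -> list[CredibleSet]:
    """Per-signal credible sets via the swap construction on the MAP config."""
    if k_star is None:
        k_star = results.k_star
    if k_star < 1:
        return []
    model = results.model
    m = results.pips.size
    ids = ld.variant_ids
    sets: list[CredibleSet] = []
    pi = results.prior_pi
    lp_k = results.model._log_prior(k_star, m, pi)
    for sig, vi in enumerate(results.map_config, start=1):
        fixed = tuple(j for j in results.map_config if j != vi)
        cand = [v for v in range(m) if v not in fixed]
        logp = np.empty(len(cand))
        for c_i, v in enumerate(cand):
            idx = tuple(sorted(fixed + (v,)))
            post = results.posteriors.get(idx)
            if post is None:
                logp[c_i] = lp_k + model._log_bf(idx) - results.log_norm
            else:
                logp[c_i] = math.log(post) if post > 0 else -np.inf
        w = np.exp(logp - logsumexp(logp))
        order = np.argsort(-w, kind="stable")
        mass = 0.0
        members: list[int] = []
        for oi in order:
            members.append(cand[oi])
            mass += w[oi]
            if mass >= coverage:
                break
        purity = 1.0
        if len(members) > 1:
            sub = model.R[np.ix_(members, members)] ** 2
            purity = float(sub[np.triu_indices(len(members), 1)].min())
        pips = {ids[cand[i]]: float(w[i]) for i in range(len(cand))}
        member_ids = [ids[i] for i in members]
        informative = purity >= purity_min
        sets.append(CredibleSet(
            signal_index=sig,
            members=member_ids,
            pips=pips,
            mass=float(mass),
            purity=purity,
            informative=informative,
            representative=member_ids[0],
        ))
    return sets


def representative_variant(
    cs: CredibleSet,
    annotations: pd.DataFrame | dict[str, str],
    ld: LdMatrix,
    functional_r2: float = 0.95,
) -> str:
    """Choose the variant that stands for a signal.

    The top-PIP member, unless the set contains a functional variant
    (consequence in the severity-ordered functional list) with r^2 above the
    threshold to it — then the functional variant with the largest r^2 wins.
    """
    if isinstance(annotations, pd.DataFrame):
        ann = dict(zip(annotations["id"], annotations["consequence"]))
    else:
        ann = dict(annotations)
    top = cs.members[0]
    best_r2, best = -1.0, None
    for v in cs.members:
        if v == top:
            continue
        if ann.get(v) in FUNCTIONAL_CLASSES:
            r2 = ld.r2(top, v)
            if r2 > functional_r2 and r2 > best_r2:
                best_r2, best = r2, v
    if ann.get(top) in FUNCTIONAL_CLASSES:
        return top
    return best if best is not None else top


def write_credible_sets(
    sets: list[CredibleSet], path, region_id: str = "", trait: str = ""
) -> None:
    """Tab-delimited credible-set export, one row per candidate variant."""
    rows = []
    for cs in sets:
        for vid, pip in sorted(cs.pips.items(), key=lambda kv: -kv[1]):
            rows.append({
                "region_id": region_id, "trait": trait,
                "signal_index": cs.signal_index, "variant": vid,
                "pip": pip, "in_cs95": vid in cs.members,
                "purity": cs.purity, "informative": cs.informative,
                "representative": cs.representative,
            })
    pd.DataFrame(rows, columns=["region_id", "trait", "signal_index",
                                "variant", "pip", "in_cs95", "purity",
                                "informative", "representative"]).to_csv(
        path, sep="\t", index=False)


def apply_region_exclusions(
    region: tuple[str, int, int],
    config: FinemapConfig,
) -> bool:
    """True if the region must skip fine-mapping (MHC or custom exclusion),
    in which case the GWAS lead variant is the sole representative."""
    chrom, start, end = region
    for c, lo, hi in config.all_exclusions:
        if chrom == c and start <= hi and end >= lo:
            return True
    return False
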