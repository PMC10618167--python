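"""Synthetic cohort generator for lipidome GWAS.

Emulates, at the statistical level, a Finnish-style biobank cohort with a
measured plasma lipidome: blockwise-LD genotype dosages over a realistic
minor-allele-frequency spectrum (floor 0.002), a correlated lipidome with
lipid-class factor structure and controllable per-species heritability,
planted causal variants of three kinds (single-trait, sign-canceling
multi-trait, rare large-effect), and binary disease endpoints sharing causal
variants with lipid species.  Every planted parameter is recorded in a
:class:`TruthLedger` so downstream estimators can be tested for parameter
recovery.

The LD model is a Gaussian copula: each haplotype's allele indicators arise
by thresholding a latent AR(1) process at the allele-frequency quantile, and
two independent haplotypes are summed into a genotype.  Imputation quality is
emulated by blending the genotype toward its expectation, ``dosage =
(1-e) * g + e * 2 * maf``, and reporting INFO as the ratio of dosage variance
to ``2 * maf * (1 - maf)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "MafClass",
    "PlantedEffect",
    "EndpointSpec",
    "LipidClassSpec",
    "SimConfig",
    "TruthLedger",
    "SimConfigError",
    "simulate_genotypes",
    "simulate_lipidome",
    "simulate_endpoints",
    "simulate_cohort",
    "default_config",
]

# covariate effects are deliberately nonzero but small so that covariate
# adjustment has real work to do
COVARIATE_SLOPES = {"age": 0.10, "sex": 0.20, "site": 0.05}


class SimConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class MafClass:
    """One allele-frequency stratum of the MAF spectrum."""

    weight: float
    low: float
    high: float

    def validate(self) -> None:
        if not (0.0 < self.low <= self.high <= 0.5):
            raise SimConfigError(
                f"MAF class range ({self.low}, {self.high}) outside (0, 0.5]"
            )
        if self.weight < 0:
            raise SimConfigError("MAF class weight must be non-negative")


@dataclass(frozen=True)
class PlantedEffect:
    """A causal variant acting on one or more lipid species.

    ``effect_sizes`` are standardized slopes: change of the (unit-variance)
    species level per standard deviation of dosage.  ``kind`` is one of
    ``univariate`` (single trait), ``multivariate_cancel`` (opposing signs
    across traits, detectable mainly by the multivariate test) and
    ``rare_large`` (attached to a variant with MAF < 0.05).
    """

    variant_index: int
    trait_targets: tuple[int, ...]
    effect_sizes: tuple[float, ...]
    kind: str = "univariate"

    def validate(self) -> None:
        if len(self.trait_targets) != len(self.effect_sizes):
            raise SimConfigError("trait_targets and effect_sizes length mismatch")
        if self.kind not in ("univariate", "multivariate_cancel", "rare_large"):
            raise SimConfigError(f"unknown planted-effect kind {self.kind!r}")
        if self.kind == "multivariate_cancel":
            total = abs(sum(self.effect_sizes))
            peak = max(abs(e) for e in self.effect_sizes)
            if not total < peak:
                raise SimConfigError(
                    "multivariate_cancel effect does not cancel: "
                    f"|sum|={total:.3g} >= max|effect|={peak:.3g}"
                )


@dataclass(frozen=True)
class EndpointSpec:
    """A binary endpoint under a logistic liability model.

    ``causal`` maps variant index -> per-dosage log-odds ratio; shared causal
    variants with lipid species are simply indices that also appear in a
    :class:`PlantedEffect`.
    """

    name: str
    prevalence: float
    causal: tuple[tuple[int, float], ...] = ()

    def validate(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise SimConfigError("endpoint prevalence must be in (0, 1)")


@dataclass(frozen=True)
class LipidClassSpec:
    """A lipid class: how many species it contains and their shared-factor loading."""

    name: str
    n_species: int
    loading: float = 0.6


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort."""

    n_samples: int = 5000
    n_variants: int = 2000
    block_size: int = 20
    ld_rho: float = 0.6
    maf_spectrum: tuple[MafClass, ...] = (
        MafClass(0.60, 0.05, 0.50),
        MafClass(0.25, 0.01, 0.05),
        MafClass(0.15, 0.002, 0.01),
    )
    n_species: int = 24
    class_structure: tuple[LipidClassSpec, ...] = ()
    h2_targets: tuple[float, ...] = ()
    planted_effects: tuple[PlantedEffect, ...] = ()
    endpoint_specs: tuple[EndpointSpec, ...] = ()
    missing_rate: float = 0.02
    seed: int = 0
    # layout / nuisance parameters
    blocks_per_chrom: int = 25
    bp_spacing: int = 10_000
    info_noise_max: float = 0.10
    n_background_variants: int = 200

    def __post_init__(self) -> None:
        if not self.class_structure:
            self.class_structure = _default_classes(self.n_species)
        if not self.h2_targets:
            self.h2_targets = _default_h2(self.class_structure)
        if sum(c.n_species for c in self.class_structure) != self.n_species:
            raise SimConfigError("class_structure species counts != n_species")
        if len(self.h2_targets) != self.n_species:
            raise SimConfigError("h2_targets length != n_species")

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_variants < 1:
            raise SimConfigError("need n_samples >= 2 and n_variants >= 1")
        if not (0.0 <= self.ld_rho < 1.0):
            raise SimConfigError("ld_rho must be in [0, 1)")
        if not (0.0 <= self.missing_rate <= 0.3):
            raise SimConfigError("missing_rate must be in [0, 0.3]")
        for cls in self.maf_spectrum:
            cls.validate()
        if sum(c.weight for c in self.maf_spectrum) <= 0:
            raise SimConfigError("maf_spectrum weights sum to zero")
        for eff in self.planted_effects:
            eff.validate()
            if eff.variant_index >= self.n_variants:
                raise SimConfigError(
                    f"planted variant index {eff.variant_index} out of range"
                )
            for t in eff.trait_targets:
                if t >= self.n_species:
                    raise SimConfigError(f"planted trait index {t} out of range")
        for ep in self.endpoint_specs:
            ep.validate()
        cov_var = sum(s**2 for s in COVARIATE_SLOPES.values())
        for j, h2 in enumerate(self.h2_targets):
            if not (0.0 <= h2 < 1.0):
                raise SimConfigError(f"h2 target {h2} for species {j} outside [0, 1)")
            loading = self._species_loading(j)
            if h2 + loading**2 + cov_var > 1.0:
                raise SimConfigError(
                    f"species {j}: h2 ({h2}) + shared variance "
                    f"({loading ** 2 + cov_var:.3f}) exceeds 1"
                )

    # -- species/class bookkeeping -------------------------------------------------
    def species_class(self, j: int) -> LipidClassSpec:
        k = 0
        for cls in self.class_structure:
            if j < k + cls.n_species:
                return cls
            k += cls.n_species
        raise IndexError(j)

    def _species_loading(self, j: int) -> float:
        return self.species_class(j).loading

    @property
    def species_names(self) -> list[str]:
        names = []
        for cls in self.class_structure:
            names.extend(f"{cls.name}_{i + 1}" for i in range(cls.n_species))
        return names

    @property
    def class_labels(self) -> list[str]:
        labels = []
        for cls in self.class_structure:
            labels.extend([cls.name] * cls.n_species)
        return labels


def _default_classes(n_species: int) -> tuple[LipidClassSpec, ...]:
    # emulate a lipidome with several classes of unequal size; loadings give
    # a visible within-class correlation block (r ~ loading^2)
    base = ["TAG", "DAG", "PC", "PE", "PI", "SM", "CER", "CE", "LPC", "PCO"]
    sizes, classes = [], []
    remaining = n_species
    i = 0
    while remaining > 0:
        take = min(max(2, n_species // len(base)), remaining)
        if remaining - take == 1:
            take = remaining
        classes.append(LipidClassSpec(base[i % len(base)] + ("" if i < len(base) else str(i)), take, 0.6))
        remaining -= take
        i += 1
    return tuple(classes)


def _default_h2(classes: tuple[LipidClassSpec, ...]) -> tuple[float, ...]:
    # per-class heritability levels spanning the 0-0.45 range reported for
    # plasma lipid species, sphingolipid-like classes at the top
    level = {"SM": 0.35, "CER": 0.34, "CE": 0.30, "TAG": 0.25, "DAG": 0.25,
             "PC": 0.22, "PE": 0.20, "PI": 0.22, "LPC": 0.18, "PCO": 0.12}
    out: list[float] = []
    for cls in classes:
        h2 = level.get(cls.name.rstrip("0123456789"), 0.2)
        out.extend([h2] * cls.n_species)
    return tuple(out)


def default_config(**overrides) -> SimConfig:
    """A ready-to-run cohort emulating the study conditions at desk scale."""
    cfg = SimConfig(**overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------


@dataclass
class TruthLedger:
    """Ground truth of a simulated cohort, for parameter-recovery tests.

    Three tables: ``planted`` (one row per planted effect x trait),
    ``species`` (per-species target and realized heritability) and
    ``endpoints`` (per endpoint x causal variant true log-odds, plus
    prevalence and exclusion flag).  Round-trips losslessly through
    :meth:`save`/:meth:`load`.
    """

    planted: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["effect_id", "variant_id", "species", "slope", "maf", "kind"]
        )
    )
    species: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["species", "h2_target", "h2_realized"]
        )
    )
    endpoints: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["endpoint", "variant_id", "log_or", "prevalence", "excluded"]
        )
    )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.planted.to_csv(directory / "planted.tsv", sep="\t", index=False)
        self.species.to_csv(directory / "species.tsv", sep="\t", index=False)
        self.endpoints.to_csv(directory / "endpoints.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "TruthLedger":
        directory = Path(directory)

        def read(name):
            # empty strings are data (e.g. an endpoint without causal
            # variants), not missing values
            return pd.read_csv(directory / name, sep="\t",
                               keep_default_na=False, na_values=[])

        return cls(planted=read("planted.tsv"), species=read("species.tsv"),
                   endpoints=read("endpoints.tsv"))

    def equals(self, other: "TruthLedger") -> bool:
        def close(a: pd.DataFrame, b: pd.DataFrame) -> bool:
            if list(a.columns) != list(b.columns) or len(a) != len(b):
                return False
            for c in a.columns:
                if a[c].dtype.kind in "fc":
                    if not np.allclose(a[c].to_numpy(float), b[c].to_numpy(float),
                                       rtol=1e-12, atol=1e-12, equal_nan=True):
                        return False
                elif not a[c].astype(str).equals(b[c].astype(str)):
                    return False
            return True

        return (close(self.planted, other.planted)
                and close(self.species, other.species)
                and close(self.endpoints, other.endpoints))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

_GENO_STREAM, _PHENO_STREAM, _ENDPOINT_STREAM = 11, 13, 17


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def simulate_genotypes(config: SimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate genotype dosages with blockwise AR(1) linkage disequilibrium.

    Returns ``(dosages, variants)`` where ``dosages`` is an
    ``(n_samples, n_variants)`` float array in [0, 2] and ``variants`` is a
    table with 1-based positions, alleles, realized MAF and a simulated INFO
    imputation-quality score.
    """
    config.validate()
    rng = _rng(config, _GENO_STREAM)
    n, m = config.n_samples, config.n_variants

    weights = np.array([c.weight for c in config.maf_spectrum], float)
    weights = weights / weights.sum()
    cls_idx = rng.choice(len(weights), size=m, p=weights)
    lows = np.array([c.low for c in config.maf_spectrum])
    highs = np.array([c.high for c in config.maf_spectrum])
    target_maf = rng.uniform(lows[cls_idx], highs[cls_idx])
    thresholds = special.ndtri(target_maf)

    dosage = np.empty((n, m), dtype=np.float64)
    rho = config.ld_rho
    innov_scale = np.sqrt(1.0 - rho**2)
    for start in range(0, m, config.block_size):
        stop = min(start + config.block_size, m)
        width = stop - start
        eps = rng.standard_normal((n, 2, width))
        z = np.empty_like(eps)
        z[:, :, 0] = eps[:, :, 0]
        for t in range(1, width):
            z[:, :, t] = rho * z[:, :, t - 1] + innov_scale * eps[:, :, t]
        alleles = (z < thresholds[start:stop]).sum(axis=1)  # (n, width) in {0,1,2}
        dosage[:, start:stop] = alleles

    # imputation-noise blend; INFO = var(dosage) / (2 p (1-p))
    e = rng.uniform(0.0, config.info_noise_max, size=m)
    dosage *= 1.0 - e
    dosage += e * 2.0 * target_maf

    freq = dosage.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    denom = 2.0 * freq * (1.0 - freq)
    with np.errstate(divide="ignore", invalid="ignore"):
        info = np.where(denom > 0, dosage.var(axis=0) / denom, 0.0)
    info = np.clip(info, 0.0, 1.0)

    blocks = np.arange(m) // config.block_size
    chrom_idx = blocks // config.blocks_per_chrom
    pos = np.empty(m, dtype=np.int64)
    for c in np.unique(chrom_idx):
        sel = chrom_idx == c
        pos[sel] = (np.arange(sel.sum()) + 1) * config.bp_spacing

    variants = pd.DataFrame(
        {
            "chrom": [f"chr{c + 1}" for c in chrom_idx],
            "pos": pos,
            "id": [f"chr{c + 1}_{p}_A_G" for c, p in zip(chrom_idx, pos)],
            "ref": "A",
            "alt": "G",
            "maf": maf,
            "info": info,
        }
    )
    return dosage, variants


# ---------------------------------------------------------------------------
# Lipidome
# ---------------------------------------------------------------------------


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def simulate_lipidome(
    genotypes: np.ndarray,
    config: SimConfig,
    variants: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthLedger]:
    """Simulate correlated lipid-species levels with planted genetic effects.

    Each species is a sum of a lipid-class factor, planted genetic effects,
    an optional polygenic background filling the heritability target, fixed
    covariate effects (age 0.10, sex 0.20, site 0.05 standardized slopes) and
    independent noise, with variance shares chosen so the realized
    heritability matches ``h2_targets`` in expectation.  Missing values are
    missing completely at random at ``missing_rate``.

    Returns ``(phenotypes, covariates, ledger)``; phenotype/covariate tables
    are indexed by sample id.
    """
    config.validate()
    rng = _rng(config, _PHENO_STREAM)
    n, m = genotypes.shape
    if n != config.n_samples:
        raise SimConfigError("genotype matrix does not match config.n_samples")
    for eff in config.planted_effects:
        if eff.variant_index >= m:
            raise SimConfigError("planted variant index outside genotype matrix")
        if eff.kind == "rare_large":
            maf = min(genotypes[:, eff.variant_index].mean() / 2,
                      1 - genotypes[:, eff.variant_index].mean() / 2)
            if maf >= 0.05:
                raise SimConfigError(
                    f"rare_large effect at variant {eff.variant_index} has MAF "
                    f"{maf:.3f} >= 0.05"
                )

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    x_std = _standardize_columns(genotypes)

    # covariates (standardized internally when effects are applied)
    age = rng.normal(55.0, 6.0, size=n)
    sex = rng.integers(0, 2, size=n)
    site = rng.integers(0, 3, size=n)
    covariates = pd.DataFrame({"age": age, "sex": sex, "site": site}, index=sample_ids)
    cov_std = np.column_stack(
        [_standardize_columns(covariates[c].to_numpy(float)[:, None])[:, 0]
         for c in ("age", "sex", "site")]
    )
    slopes = np.array([COVARIATE_SLOPES["age"], COVARIATE_SLOPES["sex"],
                       COVARIATE_SLOPES["site"]])
    cov_effect = cov_std @ slopes
    cov_var = float(np.sum(slopes**2))

    factors = {cls.name: rng.standard_normal(n) for cls in config.class_structure}

    # background variant pool for polygenic make-up variance
    n_bg = min(config.n_background_variants, m)
    bg_pool = rng.choice(m, size=n_bg, replace=False)

    planted_by_species: dict[int, list[tuple[int, float, str, int]]] = {}
    for eid, eff in enumerate(config.planted_effects):
        for t, b in zip(eff.trait_targets, eff.effect_sizes):
            planted_by_species.setdefault(t, []).append(
                (eff.variant_index, b, eff.kind, eid)
            )

    names = config.species_names
    labels = config.class_labels
    pheno = np.empty((n, config.n_species))
    h2_real = np.empty(config.n_species)
    planted_rows = []
    for j in range(config.n_species):
        h2 = config.h2_targets[j]
        loading = config._species_loading(j)
        genetic = np.zeros(n)
        planted_var = 0.0
        for vi, b, kind, eid in planted_by_species.get(j, []):
            genetic += b * x_std[:, vi]
            planted_var += b * b
        if planted_var > h2 + 1e-9:
            raise SimConfigError(
                f"species {j}: planted effect variance {planted_var:.3f} exceeds "
                f"h2 target {h2:.3f}"
            )
        bg_share = h2 - planted_var
        if bg_share > 1e-12:
            w = rng.standard_normal(n_bg)
            bg = x_std[:, bg_pool] @ w
            sd = bg.std()
            if sd > 0:
                genetic += np.sqrt(bg_share) * bg / sd
        noise_share = 1.0 - h2 - loading**2 - cov_var
        y = (genetic
             + loading * factors[labels[j]]
             + cov_effect
             + np.sqrt(noise_share) * rng.standard_normal(n))
        pheno[:, j] = y
        vg = genetic.var()
        h2_real[j] = vg / y.var() if y.var() > 0 else 0.0

    if config.missing_rate > 0:
        mask = rng.random(pheno.shape) < config.missing_rate
        pheno = np.where(mask, np.nan, pheno)

    variant_ids = (variants["id"].to_numpy() if variants is not None
                   else np.array([f"v{i}" for i in range(m)]))
    freq = genotypes.mean(axis=0) / 2.0
    maf_all = np.minimum(freq, 1.0 - freq)
    for eid, eff in enumerate(config.planted_effects):
        for t, b in zip(eff.trait_targets, eff.effect_sizes):
            planted_rows.append(
                {
                    "effect_id": eid,
                    "variant_id": variant_ids[eff.variant_index],
                    "species": names[t],
                    "slope": b,
                    "maf": maf_all[eff.variant_index],
                    "kind": eff.kind,
                }
            )

    ledger = TruthLedger(
        planted=pd.DataFrame(
            planted_rows,
            columns=["effect_id", "variant_id", "species", "slope", "maf", "kind"],
        ),
        species=pd.DataFrame(
            {"species": names, "h2_target": list(config.h2_targets),
             "h2_realized": h2_real}
        ),
    )
    phenotypes = pd.DataFrame(pheno, index=sample_ids, columns=names)
    return phenotypes, covariates, ledger


# ---------------------------------------------------------------------------
# Endpoints
# ---------------------------------------------------------------------------


def simulate_endpoints(
    genotypes: np.ndarray,
    config: SimConfig,
    ledger: TruthLedger | None = None,
    variants: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, TruthLedger]:
    """Simulate binary endpoints under a logistic liability model.

    Case probability is ``expit(alpha + sum_k gamma_k * dosage_k)`` with the
    intercept solved so the mean probability equals the target prevalence, so
    planted per-dosage log-odds ratios are exact.  Endpoints whose expected
    case count falls below 50 are flagged excluded (with a warning) but still
    generated.
    """
    config.validate()
    rng = _rng(config, _ENDPOINT_STREAM)
    n, m = genotypes.shape
    if ledger is None:
        ledger = TruthLedger()

    variant_ids = (variants["id"].to_numpy() if variants is not None
                   else np.array([f"v{i}" for i in range(m)]))

    data = {}
    rows = []
    for spec in config.endpoint_specs:
        spec.validate()
        score = np.zeros(n)
        for vi, log_or in spec.causal:
            score += log_or * genotypes[:, vi]

        def mean_prob(alpha: float) -> float:
            return float(special.expit(alpha + score).mean()) - spec.prevalence

        alpha = optimize.brentq(mean_prob, -30.0, 30.0)
        p = special.expit(alpha + score)
        status = (rng.random(n) < p).astype(np.int8)

        excluded = spec.prevalence * n < 50
        if excluded:
            warnings.warn(
                f"endpoint {spec.name!r}: expected cases "
                f"{spec.prevalence * n:.1f} < 50; flagged excluded",
                stacklevel=2,
            )
        data[spec.name] = status
        if spec.causal:
            for vi, log_or in spec.causal:
                rows.append({"endpoint": spec.name, "variant_id": variant_ids[vi],
                             "log_or": log_or, "prevalence": spec.prevalence,
                             "excluded": excluded})
        else:
            rows.append({"endpoint": spec.name, "variant_id": "", "log_or": 0.0,
                         "prevalence": spec.prevalence, "excluded": excluded})

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    endpoints = pd.DataFrame(data, index=sample_ids, dtype=np.int8)
    ledger.endpoints = pd.DataFrame(
        rows, columns=["endpoint", "variant_id", "log_or", "prevalence", "excluded"]
    )
    return endpoints, ledger


def simulate_cohort(config: SimConfig):
    """Run the full generator: genotypes, lipidome, covariates, endpoints, truth.

    Returns a dict with keys ``genotypes``, ``variants``, ``phenotypes``,
    ``covariates``, ``endpoints``, ``ledger``.
    """
    genotypes, variants = simulate_genotypes(config)
    phenotypes, covariates, ledger = simulate_lipidome(genotypes, config, variants)
    endpoints, ledger = simulate_endpoints(genotypes, config, ledger, variants)
    return {
        "genotypes": genotypes,
        "variants": variants,
        "phenotypes": phenotypes,
        "covariates": covariates,
        "endpoints": endpoints,
        "ledger": ledger,
    }
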