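"""Trait clustering for the multivariate GWAS.

Builds clusters of correlated lipid species: pairwise-complete Pearson
correlations, iterative exclusion of one member of every pair with |r| above
0.8, average-linkage hierarchical clustering (each trait represented by its
row of the |r| matrix, Euclidean dissimilarity between rows), and an
iterative variance-inflation-factor prune within each cluster until the
maximum VIF is below 5.  Highly collinear trait sets destabilize the
canonical-correlation test; the pruning guarantees an invertible
within-cluster correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "TraitCluster",
    "correlation_matrix",
    "prune_high_pairs",
    "hierarchical_clusters",
    "vif_prune",
    "standard_lipid_profile",
    "build_clusters",
    "write_cluster_file",
]


@dataclass
class TraitCluster:
    """A pruned set of correlated lipid species used as one multivariate trait."""

    cluster_id: int
    members: list[str]
    removed_pairwise: list[str] = field(default_factory=list)
    removed_vif: list[str] = field(default_factory=list)
    correlations: pd.DataFrame | None = None


def correlation_matrix(
    phenotypes: pd.DataFrame, absolute: bool = True, min_obs: int = 3
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between species.

    Symmetric with unit diagonal; absolute values if ``absolute``.  Raises,
    naming the offending pair, if any pair has fewer than ``min_obs``
    complete observations.
    """
    if phenotypes.shape[1] < 2:
        raise ValueError("need at least 2 species")
    notna = phenotypes.notna().to_numpy()
    counts = notna.T.astype(np.int64) @ notna
    if (counts < min_obs).any():
        i, j = np.argwhere(counts < min_obs)[0]
        raise ValueError(
            f"pair ({phenotypes.columns[i]!r}, {phenotypes.columns[j]!r}) has "
            f"fewer than {min_obs} complete observations"
        )
    corr = phenotypes.corr(method="pearson", min_periods=min_obs)
    np.fill_diagonal(corr.values, 1.0)
    return corr.abs() if absolute else corr


def prune_high_pairs(
    correlations: pd.DataFrame, threshold: float = 0.8
) -> tuple[list[str], list[str]]:
    """Iteratively remove one member of every pair with |r| above ``threshold``.

    At each step the pair with the largest |r| is taken and the member with
    the larger mean |r| against all remaining traits is dropped (tie broken
    toward the lexicographically later id).  Returns ``(kept, removed)`` in
    the original column order / removal order respectively.
    """
    C = correlations.abs().copy()
    np.fill_diagonal(C.values, 0.0)
    removed: list[str] = []
    while True:
        vals = C.to_numpy()
        if vals.size == 0 or np.nanmax(vals) <= threshold:
            break
        i, j = np.unravel_index(np.nanargmax(vals), vals.shape)
        a, b = C.index[i], C.index[j]
        mean_a = C.loc[a].drop(a).mean()
        mean_b = C.loc[b].drop(b).mean()
        if np.isclose(mean_a, mean_b):
            victim = max(a, b)
        else:
            victim = a if mean_a > mean_b else b
        removed.append(victim)
        C = C.drop(index=victim, columns=victim)
    kept = [c for c in correlations.columns if c not in removed]
    return kept, removed


def hierarchical_clusters(
    correlations: pd.DataFrame,
    n_clusters: int | dict[str, int],
    partition: pd.Series | None = None,
) -> list[list[str]]:
    """Average-linkage clustering of traits by their correlation profiles.

    Each trait's feature vector is its row of the |r| matrix; dissimilarity
    is the Euclidean distance between rows.  When a ``partition`` (trait ->
    group label) is given, clustering runs independently within each group
    and ``n_clusters`` may be a per-group dict.  The dendrogram is cut at the
    requested cluster count.
    """
    if partition is None:
        partition = pd.Series("all", index=correlations.index)
    groups = sorted(partition.unique())
    out: list[list[str]] = []
    for g in groups:
        traits = [t for t in correlations.index if partition[t] == g]
        k = n_clusters[g] if isinstance(n_clusters, dict) else n_clusters
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        if k > len(traits):
            raise ValueError(
                f"n_clusters={k} exceeds the {len(traits)} traits in group {g!r}"
            )
        if len(traits) == 1:
            out.append(traits)
            continue
        X = correlations.loc[traits].abs().to_numpy()
        Z = hierarchy.linkage(X, method="average", metric="euclidean")
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        for lab in sorted(set(labels)):
            out.append([t for t, l in zip(traits, labels) if l == lab])
    return out


def _vifs(phenotypes: pd.DataFrame, members: list[str]) -> pd.Series:
    """VIF_j = 1/(1 - R^2_j) from regressing member j on the other members,
    on complete cases across the cluster."""
    sub = phenotypes[members].dropna()
    vals = {}
    X = sub.to_numpy(float)
    n = X.shape[0]
    for idx, mj in enumerate(members):
        if len(members) == 1:
            vals[mj] = 1.0
            continue
        y = X[:, idx]
        others = np.delete(X, idx, axis=1)
        A = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        tss = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 1.0
        vals[mj] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(vals)


def vif_prune(
    phenotypes: pd.DataFrame,
    cluster: list[str],
    vif_max: float = 5.0,
    cluster_id: int = 0,
    removed_pairwise: list[str] | None = None,
) -> TraitCluster:
    """Iteratively remove the member with the largest VIF until max VIF < vif_max.

    Ties break toward the lexicographically later id; a perfectly collinear
    member has infinite VIF and is removed first.  Singletons are unchanged
    (VIF defined as 1).
    """
    if len(cluster) < 1:
        raise ValueError("cluster must have at least one member")
    members = list(cluster)
    removed: list[str] = []
    while len(members) > 1:
        v = _vifs(phenotypes, members)
        vmax = v.max()
        if vmax < vif_max:
            break
        worst = sorted(v.index[np.isclose(v, vmax) | np.isinf(v) & np.isinf(vmax)])[-1]
        removed.append(worst)
        members.remove(worst)
    corr = (correlation_matrix(phenotypes[members], absolute=False)
            if len(members) > 1 else
            pd.DataFrame([[1.0]], index=members, columns=members))
    return TraitCluster(
        cluster_id=cluster_id,
        members=members,
        removed_pairwise=list(removed_pairwise or []),
        removed_vif=removed,
        correlations=corr,
    )


def standard_lipid_profile(
    phenotypes: pd.DataFrame,
    standard_lipids: pd.DataFrame,
    flagged_species: list[str] | None = None,
) -> tuple[pd.Series, float | None]:
    """Per-species max |r| against the standard lipids (HDL-C, LDL-C, TC, TG).

    Returns the maxCor series and, when a flagged subset is given, the
    difference between the flagged species' mean maxCor and the rest's.
    """
    if not phenotypes.index.equals(standard_lipids.index):
        raise ValueError("standard lipid table is not row-aligned")
    maxcor = pd.Series(0.0, index=phenotypes.columns)
    for sp in phenotypes.columns:
        best = 0.0
        for sl in standard_lipids.columns:
            pair = pd.concat([phenotypes[sp], standard_lipids[sl]], axis=1).dropna()
            if len(pair) < 3:
                raise ValueError(f"pair ({sp!r}, {sl!r}) has fewer than 3 "
                                 "complete observations")
            r = abs(pair.iloc[:, 0].corr(pair.iloc[:, 1]))
            best = max(best, r)
        maxcor[sp] = best
    diff = None
    if flagged_species is not None:
        rest = [s for s in phenotypes.columns if s not in flagged_species]
        diff = float(maxcor[flagged_species].mean() - maxcor[rest].mean())
    return maxcor, diff


def build_clusters(
    phenotypes: pd.DataFrame,
    n_clusters: int | dict[str, int],
    partition: pd.Series | None = None,
    pair_threshold: float = 0.8,
    vif_max: float = 5.0,
) -> list[TraitCluster]:
    """Full clustering pipeline: pair pruning, clustering, VIF pruning."""
    corr = correlation_matrix(phenotypes, absolute=True)
    kept, removed_pairs = prune_high_pairs(corr, pair_threshold)
    sub = corr.loc[kept, kept]
    part = partition.loc[kept] if partition is not None else None
    prelim = hierarchical_clusters(sub, n_clusters, part)
    clusters = []
    for cid, members in enumerate(prelim, start=1):
        dropped_here = [t for t in removed_pairs
                        if _best_match(t, members, corr)]
        clusters.append(
            vif_prune(phenotypes, members, vif_max, cluster_id=cid,
                      removed_pairwise=dropped_here)
        )
    return clusters


def _best_match(trait: str, members: list[str], corr: pd.DataFrame) -> bool:
    # attribute a pair-pruned trait to the cluster holding its strongest partner
    row = corr.loc[trait].drop(trait)
    return row.idxmax() in members


def write_cluster_file(clusters: list[TraitCluster], path: str | Path) -> None:
    rows = []
    for cl in clusters:
        for sp in cl.members:
            rows.append((cl.cluster_id, sp, "member"))
        for sp in cl.removed_pairwise:
            rows.append((cl.cluster_id, sp, "removed_pairwise"))
        for sp in cl.removed_vif:
            rows.append((cl.cluster_id, sp, "removed_vif"))
    pd.DataFrame(rows, columns=["cluster_id", "species_id", "status"]).to_csv(
        path, sep="\t", index=False
    )
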