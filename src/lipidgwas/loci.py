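"""Iterative lead-variant/GWAS-region definition, cross-trait signal merging
into physical loci, novelty calls and locus naming.

Regions are found per trait by repeatedly taking the lowest-p uncovered
variant, opening a +/-1.5 Mb window around it, and stopping once no uncovered
variant is genome-wide significant; overlapping regions merge, and a merged
region wider than 6 Mb has its per-lead half-windows shrunk by 10% repeatedly
until it fits or the pieces separate.  Signals are connected components of
fine-mapping representative variants linked at LD r^2 >= 0.1; their region
unions, merged where overlapping, are the physical loci.  A locus is novel
when every lead is in low LD (r^2 < 0.1) with all known variants (with a
+/-1.5 Mb proximity fallback for known variants absent from the data), and it
is named by the gene of a missense representative if any, else the closest
gene to the lowest-p lead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .finemap import LdMatrix

__all__ = [
    "GwasRegion",
    "Signal",
    "Locus",
    "find_regions",
    "mv_uv_overlap",
    "merge_signals",
    "call_novelty",
    "name_locus",
    "export_loci",
]

GWS = 5e-8
MAX_REGION_BP = 6_000_000
DEFAULT_WINDOW_BP = 1_500_000


@dataclass
class GwasRegion:
    trait: str
    chrom: str
    lead: str
    lead_pos: int
    lead_p: float
    start: int
    end: int
    secondary_leads: list[str] = field(default_factory=list)
    tier: str = "GWS"

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class Signal:
    representatives: list[str]
    contributions: list[tuple[str, GwasRegion]]
    chrom: str
    start: int
    end: int


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    signals: list[Signal]
    name: str = "NA"
    novel: bool = False

    @property
    def traits(self) -> list[str]:
        seen = []
        for s in self.signals:
            for t, _ in s.contributions:
                if t not in seen:
                    seen.append(t)
        return seen

    @property
    def leads(self) -> list[tuple[str, int, float]]:
        """(lead id, position, p) of every contributing region."""
        out = []
        for s in self.signals:
            for _, reg in s.contributions:
                out.append((reg.lead, reg.lead_pos, reg.lead_p))
        return out


def _tie_break_order(stats: pd.DataFrame) -> pd.DataFrame:
    # identical minimum p: break by position then allele order (id)
    return stats.sort_values(["p", "pos", "id"], kind="mergesort")


def find_regions(
    stats: pd.DataFrame,
    trait: str = "",
    stop_p: float = GWS,
    tier_threshold: float | None = None,
    window: int = DEFAULT_WINDOW_BP,
    max_width: int = MAX_REGION_BP,
) -> list[GwasRegion]:
    """Iterative lead-variant search on a summary-statistics table.

    ``stats`` needs columns (chrom, pos, id, p), sorted by position within
    chromosome.  Leads are taken in ascending p until no uncovered variant
    has ``p < stop_p``; the tier label marks leads below ``tier_threshold``
    (default: the stop threshold) as the stricter class.
    """
    df = _tie_break_order(stats[stats["p"] < stop_p])
    leads: list[tuple[str, int, str, float]] = []  # (chrom, pos, id, p)
    regions: list[GwasRegion] = []
    # the stopping rule checks against the final (possibly shrunk) regions,
    # so shrinking can expose new lead variants on a later pass
    while True:
        new_lead = None
        for row in df.itertuples():
            if any(r.chrom == row.chrom and r.start <= row.pos <= r.end
                   for r in regions):
                continue
            new_lead = (row.chrom, int(row.pos), row.id, float(row.p))
            break
        if new_lead is None:
            break
        leads.append(new_lead)
        regions = _combine_leads(leads, trait, window, max_width)
    for r in regions:
        r.tier = ("BFS" if tier_threshold is not None and r.lead_p < tier_threshold
                  else "GWS")
    return regions


def _combine_leads(
    leads: list[tuple[str, int, str, float]],
    trait: str,
    window: int,
    max_width: int,
) -> list[GwasRegion]:
    """Merge overlapping lead windows; shrink 10% while a merged region is
    too wide (or until the shrunk pieces separate)."""
    per_lead_window = {lid: float(window) for _, _, lid, _ in leads}
    while True:
        # build intervals and merge overlaps per chromosome
        intervals = []
        for chrom, pos, lid, p in leads:
            w = per_lead_window[lid]
            intervals.append((chrom, pos - w, pos + w, lid, pos, p))
        intervals.sort(key=lambda t: (t[0], t[1]))
        groups: list[list] = []
        group_end = -np.inf
        for iv in intervals:
            if groups and groups[-1][0][0] == iv[0] and iv[1] <= group_end:
                groups[-1].append(iv)
                group_end = max(group_end, iv[2])
            else:
                groups.append([iv])
                group_end = iv[2]
        oversized = [g for g in groups
                     if (max(x[2] for x in g) - min(x[1] for x in g)) > max_width]
        if not oversized:
            break
        shrunk = False
        for g in oversized:
            for iv in g:
                if per_lead_window[iv[3]] > 1.0:
                    per_lead_window[iv[3]] *= 0.9
                    shrunk = True
        if not shrunk:
            break
    regions = []
    for g in groups:
        g_sorted = sorted(g, key=lambda t: (t[5], t[4], t[3]))
        lead = g_sorted[0]
        regions.append(GwasRegion(
            trait=trait,
            chrom=lead[0],
            lead=lead[3],
            lead_pos=int(lead[4]),
            lead_p=float(lead[5]),
            start=int(max(1, round(min(x[1] for x in g)))),
            end=int(round(max(x[2] for x in g))),
            secondary_leads=[x[3] for x in g_sorted[1:]],
        ))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def mv_uv_overlap(
    mv_region: GwasRegion,
    uv_stats: dict[str, pd.DataFrame],
    ld: LdMatrix,
    tier_threshold: float = GWS,
    r2_min: float = 0.1,
) -> bool:
    """Does any univariate analysis of a member trait confirm the
    multivariate region?  True iff some variant with r^2 > r2_min to the
    multivariate lead reaches the tier threshold in a member trait."""
    if mv_region.lead not in ld.variant_ids:
        return False
    for trait, stats in uv_stats.items():
        hits = stats[stats["p"] < tier_threshold]
        for vid in hits["id"]:
            if vid in ld.variant_ids and ld.r2(mv_region.lead, vid) > r2_min:
                return True
    return False


def merge_signals(
    representatives: list[tuple[str, str, GwasRegion]],
    ld: LdMatrix,
    r2_min: float = 0.1,
) -> tuple[list[Signal], list[Locus]]:
    """Merge representative variants into signals, and signals into loci.

    ``representatives`` is a list of (variant id, trait, region).  Variants
    on the same chromosome with pairwise LD r^2 >= r2_min join one signal
    (connected components); each signal's span is the union of its
    contributing GWAS regions; overlapping signal spans on a chromosome form
    one locus.
    """
    n = len(representatives)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(n):
        vi, _, ri = representatives[i]
        for j in range(i + 1, n):
            vj, _, rj = representatives[j]
            if ri.chrom != rj.chrom:
                continue
            if vi == vj:
                union(i, j)
                continue
            if (vi in ld.variant_ids and vj in ld.variant_ids
                    and ld.r2(vi, vj) >= r2_min):
                union(i, j)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    signals = []
    for members in comps.values():
        reps, contribs = [], []
        for i in members:
            vid, trait, reg = representatives[i]
            if vid not in reps:
                reps.append(vid)
            contribs.append((trait, reg))
        chrom = contribs[0][1].chrom
        signals.append(Signal(
            representatives=sorted(reps),
            contributions=contribs,
            chrom=chrom,
            start=min(r.start for _, r in contribs),
            end=max(r.end for _, r in contribs),
        ))
    signals.sort(key=lambda s: (s.chrom, s.start))

    loci: list[Locus] = []
    for sig in signals:
        if loci and loci[-1].chrom == sig.chrom and sig.start <= loci[-1].end:
            loc = loci[-1]
            loc.end = max(loc.end, sig.end)
            loc.signals.append(sig)
        else:
            loci.append(Locus(chrom=sig.chrom, start=sig.start, end=sig.end,
                              signals=[sig]))
    return signals, loci


def call_novelty(
    locus: Locus,
    known: pd.DataFrame,
    ld: LdMatrix,
    r2_max: float = 0.1,
    proximity_bp: int = DEFAULT_WINDOW_BP,
) -> bool:
    """Novelty call for a locus against a known-variant list.

    A lead is novel iff r^2 < r2_max with every known variant present
    in-sample, and (fallback) no absent known variant lies within
    +/-proximity_bp of it.  The locus is novel iff all its leads are novel.
    ``known`` needs columns (id, chrom, pos).
    """
    in_sample = known[known["id"].isin(ld.variant_ids)]
    absent = known[~known["id"].isin(ld.variant_ids)]
    for lead_id, lead_pos, _ in locus.leads:
        if (known["id"] == lead_id).any():
            locus.novel = False
            return False
        if lead_id in ld.variant_ids:
            for kid in in_sample["id"]:
                if ld.r2(lead_id, kid) >= r2_max:
                    locus.novel = False
                    return False
        near = absent[(absent["chrom"] == locus.chrom)
                      & (np.abs(absent["pos"] - lead_pos) <= proximity_bp)]
        if len(near):
            locus.novel = False
            return False
    locus.novel = True
    return True


def name_locus(
    locus: Locus,
    genes: pd.DataFrame,
    annotations: pd.DataFrame | dict[str, str],
    variant_positions: pd.DataFrame | None = None,
) -> str:
    """Name a locus by gene symbol.

    If any representative/top variant is a missense variant, its gene wins;
    otherwise the gene overlapping the lowest-p lead, else the nearest gene
    by edge distance (ties break toward the upstream gene — smaller start).
    ``genes`` needs columns (chrom, start, end, strand, symbol);
    ``annotations`` maps variant -> (consequence, gene).
    """
    if len(genes) == 0:
        locus.name = "NA"
        return "NA"
    if isinstance(annotations, pd.DataFrame):
        cons = dict(zip(annotations["id"], annotations["consequence"]))
        gene_of = dict(zip(annotations["id"], annotations.get(
            "gene", pd.Series([""] * len(annotations)))))
    else:
        cons = {k: v[0] for k, v in annotations.items()}
        gene_of = {k: v[1] for k, v in annotations.items()}

    candidates = []
    for sig in locus.signals:
        candidates.extend(sig.representatives)
    for lead_id, _, _ in locus.leads:
        if lead_id not in candidates:
            candidates.append(lead_id)
    for vid in candidates:
        if cons.get(vid) == "missense_variant" and gene_of.get(vid):
            locus.name = gene_of[vid]
            return locus.name

    leads = sorted(locus.leads, key=lambda t: t[2])
    lead_id, lead_pos, _ = leads[0]
    if variant_positions is not None and lead_id in set(variant_positions["id"]):
        row = variant_positions[variant_positions["id"] == lead_id].iloc[0]
        lead_pos = int(row["pos"])
    sub = genes[genes["chrom"] == locus.chrom]
    if len(sub) == 0:
        sub = genes
    overlap = sub[(sub["start"] <= lead_pos) & (lead_pos <= sub["end"])]
    if len(overlap):
        locus.name = str(overlap.iloc[0]["symbol"])
        return locus.name
    dist = np.minimum(np.abs(sub["start"] - lead_pos), np.abs(sub["end"] - lead_pos))
    sub = sub.assign(_d=dist).sort_values(["_d", "start"], kind="mergesort")
    locus.name = str(sub.iloc[0]["symbol"])
    return locus.name


def export_loci(loci: list[Locus], bed_path: str | Path,
                tsv_path: str | Path) -> None:
    """BED (0-based half-open) plus a detail TSV."""
    bed_rows, tsv_rows = [], []
    for loc in loci:
        min_p = min(p for _, _, p in loc.leads)
        score = min(1000, int(round(-np.log10(max(min_p, 1e-320)))))
        bed_rows.append((loc.chrom, loc.start - 1, loc.end, loc.name, score, "."))
        tsv_rows.append((
            loc.name, loc.chrom, loc.start, loc.end, len(loc.signals),
            ";".join(loc.traits),
            ";".join(l for l, _, _ in loc.leads),
            loc.novel,
        ))
    pd.DataFrame(bed_rows).to_csv(bed_path, sep="\t", header=False, index=False)
    pd.DataFrame(tsv_rows, columns=[
        "locus", "chrom", "start", "end", "n_signals", "traits", "leads",
        "novel"]).to_csv(tsv_path, sep="\t", index=False)
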