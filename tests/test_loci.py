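"""Locus definition: region building, merging, novelty and naming."""

import numpy as np
import pandas as pd
import pytest

from lipidgwas.finemap import LdMatrix
from lipidgwas.loci import (GwasRegion, call_novelty, export_loci,
                            find_regions, merge_signals, mv_uv_overlap,
                            name_locus)


def _stats(pos, p, chrom="chr1", ids=None):
    return pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "id": ids or [f"s{i}" for i in range(len(pos))], "p": p,
    })


class TestFindRegions:
    def test_no_significant_variants(self):
        df = _stats([100, 200], [0.5, 1e-6])
        assert find_regions(df) == []

    def test_single_peak_window(self):
        df = _stats([10_000_000, 10_500_000, 14_000_000],
                    [1e-12, 1e-9, 0.2])
        regions = find_regions(df)
        assert len(regions) == 1
        r = regions[0]
        assert r.lead == "s0" and r.secondary_leads == []
        assert r.start == 8_500_000 and r.end == 11_500_000

    def test_two_peaks_merge(self):
        df = _stats([10_000_000, 12_000_000], [1e-12, 1e-10])
        regions = find_regions(df)
        assert len(regions) == 1
        assert regions[0].lead == "s0"
        assert regions[0].secondary_leads == ["s1"]
        assert regions[0].width <= 6_000_000

    def test_chained_peaks_shrink_below_cap(self):
        pos = [10_000_000 + i * 1_750_000 for i in range(5)]
        df = _stats(pos, [1e-20, 1e-15, 1e-14, 1e-13, 1e-12])
        regions = find_regions(df)
        assert all(r.width < 6_000_000 for r in regions)
        leads = set()
        for r in regions:
            leads.add(r.lead)
            leads.update(r.secondary_leads)
        assert leads == {f"s{i}" for i in range(5)}

    def test_partition_property_every_hit_covered(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.integers(1, 80_000_000, 300))
        p = 10.0 ** rng.uniform(-15, 0, 300)
        df = _stats(pos, p)
        regions = find_regions(df)
        for row in df[df["p"] < 5e-8].itertuples():
            assert any(r.start <= row.pos <= r.end for r in regions)

    def test_tier_labels(self):
        df = _stats([1_000_000, 40_000_000], [1e-12, 1e-8])
        regions = find_regions(df, tier_threshold=7.352941e-10)
        tiers = {r.lead: r.tier for r in regions}
        assert tiers["s0"] == "BFS" and tiers["s1"] == "GWS"

    def test_different_chromosomes_never_merge(self):
        df = pd.concat([
            _stats([10_000_000], [1e-12], chrom="chr1", ids=["a"]),
            _stats([10_000_000], [1e-12], chrom="chr2", ids=["b"]),
        ])
        assert len(find_regions(df)) == 2


class TestMvUvOverlap:
    ld = LdMatrix(["lead", "linked", "far"],
                  np.array([[1.0, 0.6, 0.1],
                            [0.6, 1.0, 0.1],
                            [0.1, 0.1, 1.0]]))

    def _region(self):
        return GwasRegion(trait="c1", chrom="chr1", lead="lead",
                          lead_pos=1000, lead_p=1e-12, start=1, end=2000)

    def test_same_lead_confirms(self):
        uv = {"t1": _stats([1000], [1e-12], ids=["lead"])}
        assert mv_uv_overlap(self._region(), uv, self.ld)

    def test_low_ld_hit_is_mv_only(self):
        uv = {"t1": _stats([1500], [1e-12], ids=["far"])}
        assert not mv_uv_overlap(self._region(), uv, self.ld)

    def test_no_univariate_hit(self):
        uv = {"t1": _stats([1000], [1e-4], ids=["linked"])}
        assert not mv_uv_overlap(self._region(), uv, self.ld)


def _reg(chrom, lead, lo, hi, trait="t", p=1e-12):
    return GwasRegion(trait=trait, chrom=chrom, lead=lead,
                      lead_pos=(lo + hi) // 2, lead_p=p, start=lo, end=hi)


class TestMergeSignals:
    ld = LdMatrix(["a", "b", "c"],
                  np.array([[1.0, np.sqrt(0.2), 0.0],
                            [np.sqrt(0.2), 1.0, 0.0],
                            [0.0, 0.0, 1.0]]))

    def test_single_representative(self):
        signals, loci = merge_signals(
            [("a", "t1", _reg("chr1", "a", 100, 200))], self.ld)
        assert len(signals) == 1 and len(loci) == 1

    def test_r2_above_threshold_merges(self):
        reps = [("a", "t1", _reg("chr1", "a", 100, 300)),
                ("b", "t2", _reg("chr1", "b", 250, 500))]
        signals, loci = merge_signals(reps, self.ld)
        assert len(signals) == 1
        assert signals[0].representatives == ["a", "b"]
        assert (signals[0].start, signals[0].end) == (100, 500)

    def test_chromosomes_never_merge(self):
        reps = [("a", "t1", _reg("chr1", "a", 100, 300)),
                ("c", "t2", _reg("chr2", "c", 100, 300))]
        signals, _ = merge_signals(reps, self.ld)
        assert len(signals) == 2

    def test_overlapping_signals_one_locus(self):
        reps = [("a", "t1", _reg("chr1", "a", 100, 400)),
                ("c", "t2", _reg("chr1", "c", 300, 700))]
        signals, loci = merge_signals(reps, self.ld)
        assert len(signals) == 2  # a and c unlinked
        assert len(loci) == 1  # but their regions overlap
        assert (loci[0].start, loci[0].end) == (100, 700)

    def test_idempotent(self):
        reps = [("a", "t1", _reg("chr1", "a", 100, 300)),
                ("b", "t2", _reg("chr1", "b", 250, 500)),
                ("c", "t3", _reg("chr1", "c", 10_000, 10_500))]
        signals, loci = merge_signals(reps, self.ld)
        again_reps = [(s.representatives[0], "t",
                       _reg(s.chrom, s.representatives[0], s.start, s.end))
                      for s in signals]
        signals2, loci2 = merge_signals(again_reps, self.ld)
        assert len(signals2) == len(signals)
        assert [(l.start, l.end) for l in loci2] == \
            [(l.start, l.end) for l in loci]


class TestNovelty:
    ld = LdMatrix(["lead", "known_far"],
                  np.array([[1.0, np.sqrt(0.05)], [np.sqrt(0.05), 1.0]]))

    def _locus(self):
        _, loci = merge_signals(
            [("lead", "t", _reg("chr1", "lead", 1_000_000, 2_000_000))],
            self.ld)
        return loci[0]

    def test_lead_is_known(self):
        known = pd.DataFrame({"id": ["lead"], "chrom": ["chr1"],
                              "pos": [1_500_000]})
        assert call_novelty(self._locus(), known, self.ld) is False

    def test_low_ld_with_knowns_is_novel(self):
        known = pd.DataFrame({"id": ["known_far"], "chrom": ["chr1"],
                              "pos": [1_400_000]})
        assert call_novelty(self._locus(), known, self.ld) is True

    def test_absent_known_proximity_fallback(self):
        locus = self._locus()
        lead_pos = locus.leads[0][1]
        known = pd.DataFrame({"id": ["unseen"], "chrom": ["chr1"],
                              "pos": [lead_pos + 1_000_000]})
        assert call_novelty(locus, known, self.ld) is False
        far = pd.DataFrame({"id": ["unseen"], "chrom": ["chr1"],
                            "pos": [lead_pos + 2_000_000]})
        assert call_novelty(locus, far, self.ld) is True


class TestNaming:
    genes = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr1"],
        "start": [1_400_000, 1_600_000, 1_900_000],
        "end": [1_550_000, 1_640_000, 1_950_000],
        "strand": ["+", "+", "-"],
        "symbol": ["INSIDE", "NEARBY", "FARAWAY"],
    })

    def _locus(self, lead_pos):
        ld = LdMatrix(["lead"], np.array([[1.0]]))
        _, loci = merge_signals(
            [("lead", "t", GwasRegion("t", "chr1", "lead", lead_pos, 1e-12,
                                      lead_pos - 1000, lead_pos + 1000))], ld)
        return loci[0]

    def test_overlapping_gene(self):
        ann = {"lead": ("intron_variant", "INSIDE")}
        assert name_locus(self._locus(1_500_000), self.genes, ann) == "INSIDE"

    def test_nearest_edge_gene(self):
        ann = {"lead": ("intergenic_variant", "")}
        # 1,590,000: 40 kb from INSIDE's end, 10 kb from NEARBY's start
        assert name_locus(self._locus(1_590_000), self.genes, ann) == "NEARBY"

    def test_missense_priority(self):
        ann = {"lead": ("missense_variant", "FARAWAY")}
        assert name_locus(self._locus(1_500_000), self.genes, ann) == "FARAWAY"

    def test_empty_gene_table(self):
        ann = {"lead": ("intron_variant", "")}
        assert name_locus(self._locus(1_500_000),
                          self.genes.iloc[:0], ann) == "NA"


def test_export_bed_is_zero_based(tmp_path):
    ld = LdMatrix(["lead"], np.array([[1.0]]))
    _, loci = merge_signals(
        [("lead", "t", _reg("chr1", "lead", 1_000, 2_000))], ld)
    loci[0].name = "GENE"
    export_loci(loci, tmp_path / "loci.bed", tmp_path / "loci.tsv")
    bed = pd.read_csv(tmp_path / "loci.bed", sep="\t", header=None)
    assert bed.iloc[0, 1] == 999 and bed.iloc[0, 2] == 2_000
    tsv = pd.read_csv(tmp_path / "loci.tsv", sep="\t")
    assert tsv.iloc[0]["locus"] == "GENE"
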