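"""Exhaustive fine-mapping: posteriors, credible sets, representatives."""

import numpy as np
import pandas as pd
import pytest

from lipidgwas.benchmarks import _ld_region, bruteforce_posteriors
from lipidgwas.finemap import (FinemapConfig, FineMapModel, LdMatrix,
                               apply_region_exclusions, finemap_region,
                               representative_variant)


def _region_from_effect(rng, n, m, causal, beta, rho=0.3):
    G = _ld_region(rng, n, m, rho=rho)
    keep = G.std(axis=0) > 0
    G = G[:, keep]
    gs = (G - G.mean(0)) / G.std(0)
    y = rng.standard_normal(n)
    if causal is not None:
        y = beta * gs[:, causal] + y
    r = gs.T @ ((y - y.mean()) / y.std()) / n
    z = r * np.sqrt(n)
    ld = LdMatrix.from_dosages(G, [f"v{i}" for i in range(G.shape[1])])
    return z, ld, G.shape[1]


class TestPosteriors:
    def test_single_variant_forced(self):
        ld = LdMatrix(["v0"], np.array([[1.0]]))
        res = finemap_region(np.array([8.0]), ld, 5000,
                             FinemapConfig(k_max=1))
        assert res.pips.iloc[0] > 0.99
        assert res.k_star == 1

    def test_perfect_ld_splits_mass(self):
        ld = LdMatrix(["v0", "v1"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        res = finemap_region(np.array([7.0, 7.0]), ld, 5000,
                             FinemapConfig(k_max=1))
        assert res.pips.iloc[0] == pytest.approx(0.5, abs=0.05)
        assert res.pips.iloc[1] == pytest.approx(0.5, abs=0.05)

    def test_bruteforce_equivalence_m10_k2(self):
        rng = np.random.default_rng(0)
        z, ld, m = _region_from_effect(rng, 800, 10, 4, 0.12)
        res = finemap_region(z, ld, 800, FinemapConfig(k_max=2))
        assert len(res.posteriors) == 1 + m + m * (m - 1) // 2  # 56 at m=10
        oracle = bruteforce_posteriors(z, res.model.R, 800, 2)
        for cfg_key, pv in oracle.items():
            assert res.posteriors[cfg_key] == pytest.approx(pv, abs=1e-10)

    def test_posterior_normalized_and_pips_bounded(self):
        rng = np.random.default_rng(1)
        z, ld, _ = _region_from_effect(rng, 600, 8, 2, 0.15)
        res = finemap_region(z, ld, 600, FinemapConfig(k_max=3))
        assert sum(res.posteriors.values()) == pytest.approx(1.0, abs=1e-10)
        assert (res.pips >= 0).all() and (res.pips <= 1 + 1e-12).all()

    def test_pip_monotone_in_z(self):
        rng = np.random.default_rng(2)
        z, ld, m = _region_from_effect(rng, 600, 6, None, 0.0)
        pips = []
        for zc in [2.0, 4.0, 6.0, 8.0]:
            z2 = z.copy()
            z2[3] = zc
            res = finemap_region(z2, ld, 600, FinemapConfig(k_max=2))
            pips.append(res.pips.iloc[3])
        assert np.all(np.diff(pips) >= -1e-12)

    def test_enumeration_budget_enforced(self):
        rng = np.random.default_rng(3)
        cfg = FinemapConfig(k_max=3, enumeration_budget={1: 50, 2: 50, 3: 10})
        with pytest.raises(ValueError, match="budget"):
            FineMapModel(np.zeros(20), LdMatrix([f"v{i}" for i in range(20)],
                                                np.eye(20)), 1000, cfg)


class TestCredibleSets:
    def test_high_pip_singleton_set(self):
        rng = np.random.default_rng(4)
        z, ld, _ = _region_from_effect(rng, 3000, 12, 6, 0.2, rho=0.1)
        res = finemap_region(z, ld, 3000, FinemapConfig(k_max=2))
        css = res.credible_sets()
        assert len(css) == res.k_star >= 1
        top = css[0]
        if top.pips[top.members[0]] >= 0.95:
            assert len(top.members) == 1

    def test_low_purity_not_informative(self):
        r = np.sqrt(0.05)
        ld = LdMatrix(["v0", "v1"], np.array([[1.0, r], [r, 1.0]]))
        res = finemap_region(np.array([5.0, 5.0]), ld, 3000,
                             FinemapConfig(k_max=1))
        cs = res.credible_sets()[0]
        assert set(cs.members) == {"v0", "v1"}
        assert cs.purity == pytest.approx(0.05, abs=1e-6)
        assert not cs.informative

    def test_two_independent_causals_recovered(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            G1 = _ld_region(rng, 2500, 8, rho=0.3)
            G2 = _ld_region(rng, 2500, 8, rho=0.3)
            G = np.column_stack([G1, G2])
            keep = G.std(axis=0) > 0
            G = G[:, keep]
            gs = (G - G.mean(0)) / G.std(0)
            c1, c2 = 3, 11
            y = 0.15 * gs[:, c1] + 0.15 * gs[:, c2] + \
                rng.standard_normal(2500)
            r = gs.T @ ((y - y.mean()) / y.std()) / 2500
            z = r * np.sqrt(2500)
            ld = LdMatrix.from_dosages(G, [f"v{i}" for i in range(G.shape[1])])
            res = finemap_region(z, ld, 2500, FinemapConfig(k_max=2))
            if res.k_star != 2:
                continue
            css = [cs for cs in res.credible_sets() if cs.informative]
            found = set()
            for cs in css:
                found.update(cs.members)
            disjoint = (len(css) == 2
                        and not (set(css[0].members) & set(css[1].members)))
            if disjoint and f"v{c1}" in found and f"v{c2}" in found:
                hits += 1
        assert hits >= int(0.9 * n_seeds)

    def test_members_sorted_by_pip_and_mass(self):
        rng = np.random.default_rng(5)
        z, ld, _ = _region_from_effect(rng, 1000, 10, 5, 0.12)
        res = finemap_region(z, ld, 1000, FinemapConfig(k_max=2))
        for cs in res.credible_sets():
            vals = [cs.pips[v] for v in cs.members]
            assert vals == sorted(vals, reverse=True)
            assert cs.mass >= 0.95


class TestRepresentative:
    ld = LdMatrix(["top", "mis", "far"],
                  np.array([[1.0, 0.985, 0.3],
                            [0.985, 1.0, 0.3],
                            [0.3, 0.3, 1.0]]))

    def _cs(self):
        from lipidgwas.finemap import CredibleSet
        return CredibleSet(1, ["top", "mis", "far"],
                           {"top": 0.6, "mis": 0.3, "far": 0.06},
                           0.96, 0.09, True, "top")

    def test_no_functional_keeps_top(self):
        ann = {"top": "intron_variant", "mis": "intron_variant"}
        assert representative_variant(self._cs(), ann, self.ld) == "top"

    def test_functional_in_high_ld_substituted(self):
        ann = {"top": "intron_variant", "mis": "missense_variant"}
        assert representative_variant(self._cs(), ann, self.ld) == "mis"

    def test_largest_r2_functional_wins(self):
        ld = LdMatrix(["top", "f1", "f2"],
                      np.array([[1.0, np.sqrt(0.97), np.sqrt(0.96)],
                                [np.sqrt(0.97), 1.0, 0.9],
                                [np.sqrt(0.96), 0.9, 1.0]]))
        from lipidgwas.finemap import CredibleSet
        cs = CredibleSet(1, ["top", "f1", "f2"],
                         {"top": 0.5, "f1": 0.3, "f2": 0.2},
                         1.0, 0.9, True, "top")
        ann = {"f1": "missense_variant", "f2": "missense_variant"}
        assert representative_variant(cs, ann, ld) == "f1"


class TestRegionExclusions:
    def test_mhc_overlap_excluded(self):
        cfg = FinemapConfig()
        assert apply_region_exclusions(("chr6", 26_000_000, 28_000_000), cfg)

    def test_outside_mhc_kept(self):
        cfg = FinemapConfig()
        assert not apply_region_exclusions(("chr6", 24_000_000, 24_900_000),
                                           cfg)

    def test_custom_empty_exclusions(self):
        cfg = FinemapConfig(mhc=None)
        assert not apply_region_exclusions(("chr6", 26_000_000, 28_000_000),
                                           cfg)


def test_ld_matrix_roundtrip(tmp_path):
    rng = np.random.default_rng(6)
    G = rng.binomial(2, 0.3, (200, 5)).astype(float)
    ld = LdMatrix.from_dosages(G, [f"v{i}" for i in range(5)])
    ld.save(tmp_path / "ld.tsv")
    loaded = LdMatrix.load(tmp_path / "ld.tsv")
    assert loaded.variant_ids == ld.variant_ids
    assert np.allclose(loaded.r, ld.r, atol=1e-12)


def test_credible_set_tsv_export(tmp_path):
    from lipidgwas.finemap import write_credible_sets
    rng = np.random.default_rng(7)
    z, ld, _ = _region_from_effect(rng, 1500, 8, 4, 0.15)
    res = finemap_region(z, ld, 1500, FinemapConfig(k_max=2))
    path = tmp_path / "cs.tsv"
    write_credible_sets(res.credible_sets(), path, region_id="r1", trait="PC_1")
    table = pd.read_csv(path, sep="\t")
    assert set(table.columns) == {"region_id", "trait", "signal_index",
                                  "variant", "pip", "in_cs95", "purity",
                                  "informative", "representative"}
    assert table["in_cs95"].any()
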