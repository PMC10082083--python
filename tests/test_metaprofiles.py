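"""Metaprofile binning: orientation, pooling, region classes."""

import numpy as np
import pandas as pd
import pytest

from pinemeth.config import PipelineConfig
from pinemeth import metaprofiles as mp
from pinemeth.core import site_levels
from pinemeth.io import GeneModel, GenomeAnnotation


def uniform_sites(chrom, start, end, level, every=7, cov=20):
    rows = []
    for pos in range(start, end, every):
        mc = int(round(level * cov))
        rows.append((chrom, pos, "+", mc, cov - mc, "CG", "CGA"))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "mc", "uc",
                                       "context", "subcontext"])


@pytest.fixture
def cfg():
    return PipelineConfig()


class TestGeneProfile:
    def test_uniform_gene_flat_everywhere(self, cfg):
        gene = GeneModel("g1", "chr1", "+", 5000, 9000, exons=[(5000, 9000)])
        ann = GenomeAnnotation({"chr1": 20000}, genes=[gene])
        sites = uniform_sites("chr1", 2000, 12000, 0.5, every=3)
        prof = mp.gene_te_profile(site_levels(sites, cfg), ann, "gene", cfg)
        cg = prof[prof["context"] == "CG"]
        assert len(cg) == 60
        assert np.allclose(cg["level"], 0.5)

    def test_minus_gene_mirrors_plus(self, cfg):
        # same states, opposite strands: the minus profile is the bin-reversed
        # plus profile in every section
        ann_p = GenomeAnnotation({"chr1": 30000}, genes=[
            GeneModel("g", "chr1", "+", 10000, 14000, exons=[(10000, 14000)])])
        ann_m = GenomeAnnotation({"chr1": 30000}, genes=[
            GeneModel("g", "chr1", "-", 10000, 14000, exons=[(10000, 14000)])])
        rng = np.random.default_rng(0)
        rows = []
        for pos in range(7000, 17000, 5):
            lv = rng.uniform(0.1, 0.9)
            rows.append(("chr1", pos, "+", int(round(lv * 20)),
                         20 - int(round(lv * 20)), "CG", "CGA"))
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "mc", "uc",
                                            "context", "subcontext"])
        lv = site_levels(sites, cfg)
        prof_p = mp.gene_te_profile(lv, ann_p, "gene", cfg)
        prof_m = mp.gene_te_profile(lv, ann_m, "gene", cfg)
        for sec_p, sec_m in (("body", "body"), ("up", "down"), ("down", "up")):
            a = prof_p[(prof_p.context == "CG") & (prof_p.section == sec_p)] \
                .sort_values("bin")["level"].to_numpy()
            b = prof_m[(prof_m.context == "CG") & (prof_m.section == sec_m)] \
                .sort_values("bin")["level"].to_numpy()
            assert np.allclose(a, b[::-1], equal_nan=True)

    def test_pooling_invariance(self, cfg):
        # profile of a union of disjoint gene sets equals the count-weighted
        # combination of the per-set profiles
        g1 = GeneModel("g1", "chr1", "+", 3000, 5000, exons=[(3000, 5000)])
        g2 = GeneModel("g2", "chr1", "+", 12000, 14000, exons=[(12000, 14000)])
        ann = GenomeAnnotation({"chr1": 20000}, genes=[g1, g2])
        rng = np.random.default_rng(1)
        rows = []
        for pos in range(0, 20000, 9):
            lv = rng.uniform(0, 1)
            rows.append(("chr1", pos, "+", int(round(lv * 30)),
                         30 - int(round(lv * 30)), "CG", "CGA"))
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "mc", "uc",
                                            "context", "subcontext"])
        lv = site_levels(sites, cfg)
        both = mp.gene_te_profile(lv, ann, "gene", cfg)
        only1 = mp.gene_te_profile(lv, ann, "gene", cfg, subset=["g1"])
        only2 = mp.gene_te_profile(lv, ann, "gene", cfg, subset=["g2"])
        key = ["context", "section", "bin"]
        merged = (only1.set_index(key)[["mc", "total"]]
                  + only2.set_index(key)[["mc", "total"]])
        combined = (merged["mc"] / merged["total"]).rename("level")
        got = both.set_index(key)["level"]
        pd.testing.assert_series_equal(got.sort_index(), combined.sort_index(),
                                       check_names=False)

    def test_short_features_skipped(self, cfg):
        gene = GeneModel("tiny", "chr1", "+", 100, 110, exons=[(100, 110)])
        ann = GenomeAnnotation({"chr1": 1000}, genes=[gene])
        sites = uniform_sites("chr1", 0, 1000, 0.5)
        prof = mp.gene_te_profile(site_levels(sites, cfg), ann, "gene", cfg)
        assert prof.attrs["n_skipped"] == 1


class TestExonOnlyProfile:
    def test_uniform_skew_zero(self, cfg):
        gene = GeneModel("g", "chr1", "+", 1000, 9000,
                         exons=[(1000, 3000), (7000, 9000)])
        ann = GenomeAnnotation({"chr1": 10000}, genes=[gene])
        sites = uniform_sites("chr1", 0, 10000, 0.4, every=3)
        _, skew = mp.exon_only_profile(site_levels(sites, cfg), ann, cfg)
        row = skew[(skew["context"] == "CG") & (skew["group"] == "1-2")]
        assert row["skew_3prime"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_planted_3prime_skew_detected(self, cfg):
        # exon methylation rises along the transcript -> positive skew
        gene = GeneModel("g", "chr1", "+", 1000, 9000,
                         exons=[(1000, 3000), (7000, 9000)])
        ann = GenomeAnnotation({"chr1": 10000}, genes=[gene])
        rows = []
        for pos in range(1000, 3000, 4):
            rows.append(("chr1", pos, "+", 4, 16, "CG", "CGA"))   # 5' exon 0.2
        for pos in range(7000, 9000, 4):
            rows.append(("chr1", pos, "+", 16, 4, "CG", "CGA"))   # 3' exon 0.8
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "mc", "uc",
                                            "context", "subcontext"])
        _, skew = mp.exon_only_profile(site_levels(sites, cfg), ann, cfg)
        row = skew[(skew["context"] == "CG") & (skew["group"] == "1-2")]
        assert row["skew_3prime"].iloc[0] == pytest.approx(0.6, abs=0.02)

    def test_empty_group_present_as_na(self, cfg):
        gene = GeneModel("g", "chr1", "+", 1000, 2000, exons=[(1000, 2000)])
        ann = GenomeAnnotation({"chr1": 3000}, genes=[gene])
        sites = uniform_sites("chr1", 0, 3000, 0.5)
        profiles, skew = mp.exon_only_profile(site_levels(sites, cfg), ann, cfg)
        assert ">=6" in set(skew["group"])  # group exists even with no genes
        na_rows = profiles[(profiles["group"] == ">=6") & (profiles.context == "CG")]
        assert na_rows["level"].isna().all()


class TestIntronPanels:
    def test_step_between_exon_and_intron(self, cfg):
        gene = GeneModel("g", "chr1", "+", 1000, 9000,
                         exons=[(1000, 2000), (8000, 9000)])
        ann = GenomeAnnotation({"chr1": 10000}, genes=[gene])
        rows = []
        for pos in range(1000, 9000, 4):
            level = 0.8 if 2000 <= pos < 8000 else 0.3
            mc = int(round(level * 20))
            rows.append(("chr1", pos, "+", mc, 20 - mc, "CG", "CGA"))
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "mc", "uc",
                                            "context", "subcontext"])
        panels = mp.intron_length_profiles(site_levels(sites, cfg), ann, cfg)
        panel = panels[(panels["length_group"] == "5000-20000bp")
                       & (panels["intron_ordinal"] == 1)
                       & (panels["context"] == "CG")]
        assert np.allclose(panel[panel.section == "intron"]["level"], 0.8)
        assert np.allclose(panel[panel.section == "exon5"]["level"], 0.3)
        assert np.allclose(panel[panel.section == "exon3"]["level"], 0.3)

    def test_group_without_introns_is_na(self, cfg):
        gene = GeneModel("g", "chr1", "+", 1000, 2000, exons=[(1000, 2000)])
        ann = GenomeAnnotation({"chr1": 3000}, genes=[gene])
        sites = uniform_sites("chr1", 0, 3000, 0.5)
        panels = mp.intron_length_profiles(site_levels(sites, cfg), ann, cfg)
        assert panels["level"].isna().all()  # intronless gene feeds no panel


class TestRegionMethylation:
    def _setup(self, cfg, strand="+"):
        gene = GeneModel("g", "chr1", strand, 5000, 8000,
                         exons=[(5000, 6000), (7000, 8000)])
        ann = GenomeAnnotation({"chr1": 20000}, genes=[gene])
        sites = uniform_sites("chr1", 0, 20000, 0.5, every=3)
        return ann, mp.region_methylation(site_levels(sites, cfg), ann, cfg)

    def test_exon_level_weighted(self, cfg):
        gene = GeneModel("g", "chr1", "+", 100, 300, exons=[(100, 300)])
        ann = GenomeAnnotation({"chr1": 1000}, genes=[gene])
        sites = pd.DataFrame([
            ("chr1", 150, "+", 5, 5, "CG", "CGA"),
            ("chr1", 200, "+", 10, 0, "CG", "CGA"),
        ], columns=["chrom", "pos", "strand", "mc", "uc", "context", "subcontext"])
        out = mp.region_methylation(site_levels(sites, cfg), ann, cfg)
        row = out[(out.region == "exon") & (out.context == "CG")]
        assert row["level"].iloc[0] == 0.75

    def test_upstream_nesting(self, cfg):
        ann, out = self._setup(cfg)
        cg = out[out.context == "CG"].set_index("region")
        assert cg.loc["up500", "total"] <= cg.loc["up1000", "total"] \
            <= cg.loc["up2000", "total"]

    def test_strand_aware_upstream(self, cfg):
        _, plus = self._setup(cfg, "+")
        _, minus = self._setup(cfg, "-")
        # for the '-' gene "up500" lies genomically right of the gene
        p = plus[(plus.region == "up500") & (plus.context == "CG")]["total"].iloc[0]
        m = minus[(minus.region == "up500") & (minus.context == "CG")]["total"].iloc[0]
        assert p > 0 and m > 0  # both resolve; coordinates differ

    def test_intronless_gene_body_equals_exon(self, cfg):
        gene = GeneModel("g", "chr1", "+", 100, 300, exons=[(100, 300)])
        ann = GenomeAnnotation({"chr1": 1000}, genes=[gene])
        sites = uniform_sites("chr1", 0, 1000, 0.6)
        out = mp.region_methylation(site_levels(sites, cfg), ann, cfg)
        cg = out[out.context == "CG"].set_index("region")
        assert cg.loc["body", "level"] == cg.loc["exon", "level"]
        assert np.isnan(cg.loc["intron", "level"])

    def test_clipping_at_chromosome_start(self, cfg):
        gene = GeneModel("g", "chr1", "+", 100, 400, exons=[(100, 400)])
        ann = GenomeAnnotation({"chr1": 1000}, genes=[gene])
        sites = uniform_sites("chr1", 0, 1000, 0.5)
        out = mp.region_methylation(site_levels(sites, cfg), ann, cfg)
        up2000 = out[(out.region == "up2000") & (out.context == "CG")]
        assert up2000["total"].iloc[0] > 0  # clipped to [0, 100), not negative
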