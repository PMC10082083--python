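"""Generator contracts: determinism, planted structure, count conservation."""

import io as _io

import numpy as np
import pytest

from conftest import tiny_config
from pinemeth.config import ConfigError, SimConfig
from pinemeth import io as pio
from pinemeth.simulate import (
    generate_genome, make_sample_sheet, simulate_bs_counts, simulate_dataset,
    simulate_expression, simulate_methylation_states,
)


def small_genome_config(**kw):
    base = dict(seed=0, n_chromosomes=1, chrom_length_bp=200_000, n_genes=8,
                lambda_genome_bp=5_000)
    base.update(kw)
    return SimConfig(**base)


class TestGenerateGenome:
    def test_empty_gene_set_still_draws_tes(self):
        genome, ann = generate_genome(small_genome_config(n_genes=0))
        assert ann.genes == []
        assert len(ann.tes) > 0

    def test_deterministic_given_seed(self):
        cfg = small_genome_config()
        g1, a1 = generate_genome(cfg)
        g2, a2 = generate_genome(cfg)
        assert g1 == g2
        buf1, buf2 = _io.StringIO(), _io.StringIO()
        a1.tes.to_csv(buf1)
        a2.tes.to_csv(buf2)
        assert buf1.getvalue() == buf2.getvalue()
        assert [(g.gene_id, g.start, g.exons) for g in a1.genes] == \
               [(g.gene_id, g.start, g.exons) for g in a2.genes]

    def test_te_fraction_target(self):
        cfg = SimConfig(seed=0, n_chromosomes=1, chrom_length_bp=2_000_000,
                        n_genes=10, te_fraction=0.6)
        _, ann = generate_genome(cfg)
        frac = (ann.tes["end"] - ann.tes["start"]).sum() / 2_000_000
        assert frac == pytest.approx(0.6, abs=0.05)

    def test_annotation_within_bounds_and_exon_structure(self):
        _, ann = generate_genome(small_genome_config())
        for g in ann.genes:
            assert len(g.exons) >= 1
            assert 0 <= g.start < g.end <= ann.chrom_lengths[g.chrom]
        assert (ann.tes["end"] <= ann.tes["chrom"].map(ann.chrom_lengths)).all()

    def test_sizing_error(self):
        with pytest.raises(ConfigError, match="too short"):
            generate_genome(small_genome_config(chrom_length_bp=50_000, n_genes=20))

    def test_long_intron_fractions_controllable(self):
        cfg = small_genome_config(chrom_length_bp=2_000_000, n_genes=30,
                                  n_introns_range=(3, 6),
                                  intron_frac_gt_5kb=0.4, intron_frac_gt_20kb=0.1)
        _, ann = generate_genome(cfg)
        lengths = np.array([e - s for g in ann.genes for s, e in g.introns])
        assert (lengths > 5000).mean() == pytest.approx(0.5, abs=0.12)
        assert (lengths > 20000).mean() == pytest.approx(0.1, abs=0.08)


class TestStates:
    def test_planted_levels_linear_over_ages(self, tiny_ds):
        b = tiny_ds.truth.planted_dmr_bins[0]
        assert b["levels"] == [0.4, 0.5, 0.6, 0.7]

    def test_hypo_is_reversed(self):
        cfg = small_genome_config(n_planted_age_dmrs={("CG", "hypo"): 5})
        genome, ann = generate_genome(cfg)
        _, truth = simulate_methylation_states(genome, ann, cfg)
        assert truth.planted_dmr_bins[0]["levels"] == [0.7, 0.6, 0.5, 0.4]

    def test_no_planting_empty_truth(self):
        cfg = small_genome_config()
        genome, ann = generate_genome(cfg)
        _, truth = simulate_methylation_states(genome, ann, cfg)
        assert truth.planted_dmr_bins == []
        assert truth.replicate_variable_bins == []

    def test_marker_truth_anticorrelates_before_noise(self, tiny_ds):
        m = tiny_ds.truth.marker_segments[0]
        r = np.corrcoef(m["levels"], m["tpm"])[0, 1]
        assert r < -0.95  # strictly decreasing vs strictly increasing

    def test_planted_and_replicate_bins_disjoint_on_grid(self, tiny_ds):
        planted = {(b["chrom"], b["start"]) for b in tiny_ds.truth.planted_dmr_bins}
        repvar = {(b["chrom"], b["start"]) for b in tiny_ds.truth.replicate_variable_bins}
        assert not planted & repvar
        assert all(s % 1000 == 0 for _, s in planted | repvar)

    def test_marker_segment_inside_gene_with_upstream_offset(self, tiny_ds):
        for m in tiny_ds.truth.marker_segments:
            g = tiny_ds.annotation.gene_by_id(m["gene_id"])
            assert m["start"] == max(g.start - tiny_ds.config.marker_upstream_bp, 0)
            assert m["end"] <= g.end

    def test_effect_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(planted_baseline=0.9, planted_effect=0.3).validate()

    def test_background_mean_matches_base_level(self):
        # intergenic CG sites with no planting: observed site-level mean
        # converges to the configured background within 3 binomial SE
        cfg = small_genome_config(n_genes=0, te_fraction=0.0,
                                  conversion_failure_rate=0.0)
        ds = simulate_dataset(cfg)
        t = ds.tables["y2_r1"]
        cg = t[t["context"] == "CG"]
        mc, tot = cg["mc"].sum(), (cg["mc"] + cg["uc"]).sum()
        level = mc / tot
        expected = cfg.base_levels["CG"]["intergenic"]
        se = np.sqrt(expected * (1 - expected) / tot)
        assert abs(level - expected) < 3 * se


class TestCounts:
    def test_conservation_and_degenerate_binomial(self):
        cfg = small_genome_config(conversion_failure_rate=0.0)
        genome, ann = generate_genome(cfg)
        states, _ = simulate_methylation_states(genome, ann, cfg)
        states.p[:] = 1.0  # fully methylated
        tables, _ = simulate_bs_counts(states, cfg)
        t = tables["y2_r1"]
        assert (t["uc"] == 0).all()  # p=1 with zero failure: mc == coverage

    def test_mean_coverage(self):
        ds = simulate_dataset(small_genome_config())
        cov = ds.tables["y5_r2"]["mc"] + ds.tables["y5_r2"]["uc"]
        assert cov.mean() == pytest.approx(20.0, abs=1.0)

    def test_lambda_pooled_level_matches_failure_rate(self, tiny_ds):
        lam = tiny_ds.lambda_tables
        mc = sum(t["mc"].sum() for t in lam.values())
        tot = sum((t["mc"] + t["uc"]).sum() for t in lam.values())
        level = mc / tot
        se = np.sqrt(0.005 * 0.995 / tot)
        assert level == pytest.approx(0.005, abs=max(3 * se, 5e-4))

    def test_byte_identical_reports(self, tmp_path):
        cfg = small_genome_config()
        for sub in ("a", "b"):
            ds = simulate_dataset(cfg)
            pio.write_cytosine_report(ds.tables["y35_r1"], tmp_path / f"{sub}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


class TestExpression:
    def test_zero_coupling_zero_noise_constant(self):
        cfg = small_genome_config(expression_slope=0.0,
                                  expression_gene_noise_sd=0.0,
                                  expression_sample_noise_sd=0.0,
                                  zero_tpm_fraction=0.0)
        genome, ann = generate_genome(cfg)
        states, _ = simulate_methylation_states(genome, ann, cfg)
        tpm = simulate_expression(ann, states, cfg)
        assert np.ptp(tpm.to_numpy()) == pytest.approx(0.0)

    def test_marker_tpm_strictly_increasing(self, tiny_ds):
        for m in tiny_ds.truth.marker_segments:
            per_age = [tiny_ds.tpm.loc[m["gene_id"], f"y{a}_r1"]
                       for a in (2, 5, 14, 35)]
            assert all(a < b for a, b in zip(per_age, per_age[1:]))

    def test_negative_coupling_recovered(self, expr_ds):
        from scipy.stats import spearmanr
        meth = expr_ds.states.gene_meth.reindex(expr_ds.tpm.index)
        r, p = spearmanr(meth, expr_ds.tpm.mean(axis=1))
        assert r < 0 and p < 1e-6

    def test_sample_sheet_layout(self):
        sheet = make_sample_sheet(SimConfig())
        assert len(sheet) == 8
        assert not sheet.duplicated(["age_years", "replicate"]).any()
        assert sorted(sheet["age_years"].unique()) == [2, 5, 14, 35]


class TestDatasetRoundTrip:
    def test_write_then_load(self, tiny_ds, tmp_path):
        from pinemeth.simulate import load_dataset, write_dataset
        write_dataset(tiny_ds, tmp_path)
        back = load_dataset(tmp_path)
        assert back.sheet["sample_id"].tolist() == tiny_ds.sheet["sample_id"].tolist()
        assert len(back.annotation.genes) == len(tiny_ds.annotation.genes)
        s = "y14_r1"
        assert back.tables[s]["mc"].sum() == tiny_ds.tables[s]["mc"].sum()
        assert back.truth.planted_dmr_bins == tiny_ds.truth.planted_dmr_bins
        assert np.allclose(back.tpm.to_numpy(), tiny_ds.tpm.to_numpy())
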