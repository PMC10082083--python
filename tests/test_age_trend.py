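"""Replicate exclusion, consensus rules, trajectories and trend clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pinemeth.config import PipelineConfig
from pinemeth import age_trend
from pinemeth.io import GeneModel, GenomeAnnotation


def dmr_frame(rows):
    """rows: (chrom, start, context, direction)"""
    return pd.DataFrame(
        [{"chrom": c, "start": s, "end": s + 1000, "context": ctx,
          "direction": d} for c, s, ctx, d in rows])


class TestReplicateExclusion:
    def test_context_matched_exclusion(self):
        age = {"35v2": dmr_frame([("chr1", 1000, "CG", "hyper"),
                                  ("chr1", 2000, "CG", "hyper")])}
        reps = {14: dmr_frame([("chr1", 1000, "CG", "hyper")])}
        reserved, stats, _ = age_trend.replicate_dmr_exclusion(age, reps)
        assert reserved["35v2"]["start"].tolist() == [2000]
        cg = stats[stats.context == "CG"].iloc[0]
        assert cg["replicate_overlap_fraction"] == 1.0
        assert cg["reserved_fraction"] == 0.5

    def test_other_context_not_excluded(self):
        age = {"35v2": dmr_frame([("chr1", 1000, "CG", "hyper")])}
        reps = {2: dmr_frame([("chr1", 1000, "CHG", "hyper")])}
        reserved, _, _ = age_trend.replicate_dmr_exclusion(age, reps)
        assert len(reserved["35v2"]) == 1

    def test_missing_replicates_error(self):
        with pytest.raises(ValueError):
            age_trend.replicate_dmr_exclusion({"35v2": dmr_frame([])}, {})

    def test_planted_replicate_bins_detected(self, main_ds, main_dmr):
        # replicate-variable bins must appear in the within-age replicate
        # DMR sets (and would therefore be excluded from any age list)
        rep_bins = set()
        for recs in main_dmr["replicate_dmrs"].values():
            rep_bins |= set(map(tuple, recs[["chrom", "start", "context"]]
                                .itertuples(index=False)))
        planted = {(b["chrom"], b["start"], b["context"])
                   for b in main_ds.truth.replicate_variable_bins}
        assert len(planted & rep_bins) / len(planted) >= 0.9


class TestConsensus:
    def test_two_of_three_rule(self, pcfg):
        reserved = {
            "35v2": dmr_frame([("chr1", 0, "CG", "hyper"),
                               ("chr1", 1000, "CG", "hyper")]),
            "35v5": dmr_frame([]),
            "14v2": dmr_frame([("chr1", 0, "CG", "hyper")]),
        }
        out = age_trend.consensus_dmrs(reserved, pcfg)
        assert out["start"].tolist() == [0]  # bin 1000 seen only once

    def test_conflicting_directions_dropped(self, pcfg):
        reserved = {
            "35v2": dmr_frame([("chr1", 0, "CG", "hyper")]),
            "35v5": dmr_frame([("chr1", 0, "CG", "hypo")]),
            "14v2": dmr_frame([("chr1", 0, "CG", "hyper")]),
        }
        out = age_trend.consensus_dmrs(reserved, pcfg)
        assert len(out) == 0
        assert out.attrs["n_conflicted"] == 1

    @given(st.lists(st.tuples(st.integers(0, 5), st.sampled_from(["hyper", "hypo"]),
                              st.booleans(), st.booleans(), st.booleans()),
                    max_size=12))
    @settings(derandomize=True, max_examples=40)
    def test_raising_threshold_shrinks_consensus(self, spec):
        reserved = {c: [] for c in ("35v2", "35v5", "14v2")}
        for start, direction, in1, in2, in3 in spec:
            for flag, comp in zip((in1, in2, in3), reserved):
                if flag:
                    reserved[comp].append(("chr1", start * 1000, "CG", direction))
        reserved = {c: dmr_frame(rows) for c, rows in reserved.items()}
        lo = age_trend.consensus_dmrs(reserved, PipelineConfig(min_consensus_comparisons=2))
        hi = age_trend.consensus_dmrs(reserved, PipelineConfig(min_consensus_comparisons=3))
        keys = lambda df: set(map(tuple, df[["chrom", "start", "context"]]
                                  .itertuples(index=False)))
        assert keys(hi) <= keys(lo)


class TestTrajectories:
    def test_flat_bin_flat_trajectory(self, main_dmr, main_ds):
        bins = main_dmr["bins"]
        some = bins.mc.index.to_frame(index=False).iloc[:50]
        traj = age_trend.trajectories(bins, some, main_ds.sheet)
        assert set(traj.columns) >= {"level_2", "level_5", "level_14", "level_35"}

    def test_planted_bins_recover_linear_series(self, main_ds, main_dmr):
        truth = pd.DataFrame(main_ds.truth.planted_dmr_bins)
        truth = truth.rename(columns={"direction": "dir"})
        traj = age_trend.trajectories(main_dmr["bins"], truth, main_ds.sheet)
        levels = traj[["level_2", "level_5", "level_14", "level_35"]].to_numpy()
        # planted series 0.4 -> 0.7 (+ non-conversion inflation), binomial noise
        assert np.allclose(levels.mean(axis=0), [0.4, 0.5, 0.6, 0.7], atol=0.02)
        assert ((levels[:, 1:] - levels[:, :-1]) > -0.05).all()


class TestStemCluster:
    def _traj(self, series):
        rows = []
        for i, s in enumerate(series):
            rows.append({"chrom": "chr1", "start": i * 1000, "context": "CG",
                         **{f"level_{a}": v for a, v in zip((2, 5, 14, 35), s)}})
        return pd.DataFrame(rows)

    def test_linear_series_assignments(self, pcfg):
        traj = self._traj([(0.1, 0.3, 0.5, 0.7), (0.7, 0.5, 0.3, 0.1),
                           (0.5, 0.5, 0.5, 0.5)])
        profiles, assign = age_trend.stem_cluster(traj, n_permutations=50, seed=0,
                                                  config=pcfg)
        table = profiles.set_index("profile")
        up = assign.iloc[0]["profile_id"]
        down = assign.iloc[1]["profile_id"]
        assert profiles.loc[up, "profile"] == "0,1,2,3"
        assert profiles.loc[down, "profile"] == "0,-1,-2,-3"
        # flat trajectory goes to the zero reference profile, excluded from tests
        flat = assign.iloc[2]["profile_id"]
        assert profiles.loc[flat, "profile"] == "0,0,0,0"
        assert np.isnan(profiles.loc[flat, "p"])

    def test_profile_space(self):
        profs = age_trend.model_profiles(4, 1)
        assert profs.shape == (27, 4)
        assert (profs[:, 0] == 0).all()
        assert np.abs(np.diff(profs, axis=1)).max() <= 1

    def test_null_calibration(self, pcfg):
        # pure-noise trajectories: the clustering should find no significant
        # profile (BH 0.05) in nearly all seeded runs
        n_sig = 0
        runs = 10
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            base = rng.uniform(0.3, 0.7, size=200)
            noise = rng.normal(0, 0.03, size=(200, 4))
            series = np.clip(base[:, None] + noise, 0, 1)
            traj = self._traj(list(series))
            profiles, _ = age_trend.stem_cluster(traj, n_permutations=200,
                                                 seed=seed, config=pcfg)
            if (profiles["p_adj"].dropna() < 0.05).any():
                n_sig += 1
        assert n_sig <= 1

    def test_planted_linear_trend_most_significant(self, main_trend):
        profiles = main_trend["profiles"].dropna(subset=["p_adj"])
        best = profiles.sort_values("p_adj").iloc[0]
        assert best["profile"] == "0,1,2,3"


class TestElements:
    def _annotation(self):
        genes = [GeneModel("g1", "chr1", "+", 10000, 20000,
                           exons=[(10000, 12000), (18000, 20000)])]
        tes = pd.DataFrame([{"chrom": "chr1", "start": 13000, "end": 14000,
                             "name": "TE1", "score": ".", "strand": "+"}])
        return GenomeAnnotation({"chr1": 50000}, genes=genes, tes=tes)

    def test_priority_te_inside_intron(self, pcfg):
        bins = dmr_frame([("chr1", 13000, "CG", "hyper")])
        out = age_trend.assign_elements(bins, self._annotation(), pcfg)
        assert out["element"].iloc[0] == "te"

    def test_promoter_upstream_bin(self, pcfg):
        bins = dmr_frame([("chr1", 9000, "CG", "hyper")])  # 1 kb upstream of TSS
        out = age_trend.assign_elements(bins, self._annotation(), pcfg)
        assert out["element"].iloc[0] == "promoter"

    def test_partition_sums(self, pcfg):
        bins = dmr_frame([("chr1", s, "CG", "hyper")
                          for s in range(0, 30000, 1000)])
        out = age_trend.assign_elements(bins, self._annotation(), pcfg)
        assert len(out) == len(bins)
        assert out["element"].isin(age_trend.ELEMENTS).all()


class TestGeneLinks:
    def _annotation(self):
        genes = [GeneModel("g1", "chr1", "+", 10000, 20000,
                           exons=[(10000, 20000)])]
        return GenomeAnnotation({"chr1": 50000}, genes=genes)

    @pytest.mark.parametrize("start,linked", [
        (8500, True),    # 1.5 kb upstream: within the 2-kb flank
        (7000, False),   # bin [7000,8000) ends exactly at the flank edge
        (15000, True),   # inside the body
        (21500, True),   # downstream flank
        (23000, False),  # past the flank
    ])
    def test_distance_rule(self, start, linked):
        bins = dmr_frame([("chr1", start, "CG", "hyper")])
        out = age_trend.genes_with_dmrs(bins, self._annotation())
        assert bool(out["CG_hyper"].iloc[0]) is linked

    def test_overlapping_genes_both_linked(self):
        genes = [GeneModel("a", "chr1", "+", 10000, 20000, exons=[(10000, 20000)]),
                 GeneModel("b", "chr1", "-", 15000, 25000, exons=[(15000, 25000)])]
        ann = GenomeAnnotation({"chr1": 50000}, genes=genes)
        bins = dmr_frame([("chr1", 16000, "CHG", "hypo")])
        out = age_trend.genes_with_dmrs(bins, ann).set_index("gene_id")
        assert out.loc["a", "CHG_hypo"] and out.loc["b", "CHG_hypo"]
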