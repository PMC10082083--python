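"""End-to-end orchestration of the methylome pipeline.

The stages mirror the analysis design: site-level QC (conversion rate,
replicate correlation), metaprofiles, fixed-grid DMR detection for the
wide-gap age comparisons, the replicate-exclusion/consensus procedure with
model-profile clustering, and the methylation-expression linkage.  Each
stage is a plain function over in-memory tables so it can be driven from
the CLI, from tests, or programmatically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import age_trend, core, dmr, expression, metaprofiles
from .config import PipelineConfig
from .dmr import dmr_records
from .expression import MarkerSegment

#: The wide-gap age comparisons used for age-DMR detection (older, younger).
AGE_COMPARISONS = (("35v2", 35, 2), ("35v5", 35, 5), ("14v2", 14, 2))


def samples_for_age(sheet: pd.DataFrame, age: int) -> list:
    return sheet.loc[sheet["age_years"] == age, "sample_id"].tolist()


def pool_tables(tables: dict) -> pd.DataFrame:
    """Sum counts over samples into one pooled site table."""
    stacked = pd.concat(tables.values(), ignore_index=True)
    grouped = stacked.groupby(["chrom", "pos", "strand", "context", "subcontext"],
                              observed=True, as_index=False)
    return grouped.agg(mc=("mc", "sum"), uc=("uc", "sum"))


def qc_stage(ds, pcfg: PipelineConfig) -> dict:
    """Conversion rate (pooled lambda) and replicate correlations per age."""
    lam = pd.concat(ds.lambda_tables.values(), ignore_index=True)
    conv = core.conversion_rate(lam)
    levels = {s: core.site_levels(t, pcfg) for s, t in ds.tables.items()}
    corr_rows = []
    for age in sorted(ds.sheet["age_years"].unique()):
        reps = samples_for_age(ds.sheet, age)
        if len(reps) < 2:
            continue
        r = core.replicate_correlation(levels[reps[0]], levels[reps[1]],
                                       ds.annotation.chrom_lengths, pcfg)
        corr_rows.append({"age_years": age, **{f"r_{k}": v for k, v in r.items()}})
    return {"conversion": conv, "replicate_correlation": pd.DataFrame(corr_rows),
            "levels_by_sample": levels}


def profile_stage(pooled_levels: pd.DataFrame, annotation, pcfg: PipelineConfig) -> dict:
    arrays = metaprofiles.SiteArrays(pooled_levels)
    gene_prof = metaprofiles.gene_te_profile(arrays, annotation, "gene", pcfg)
    te_prof = metaprofiles.gene_te_profile(arrays, annotation, "te", pcfg)
    exon_prof, skew = metaprofiles.exon_only_profile(arrays, annotation, pcfg)
    intron_prof = metaprofiles.intron_length_profiles(arrays, annotation, pcfg)
    regions = metaprofiles.region_methylation(arrays, annotation, pcfg)
    return {"gene_profile": gene_prof, "te_profile": te_prof,
            "exon_only_profile": exon_prof, "exon_skew": skew,
            "intron_profiles": intron_prof, "region_methylation": regions}


def dmr_stage(ds, pcfg: PipelineConfig) -> dict:
    """Bin counting plus age-comparison and within-age replicate DMR calls."""
    bins = dmr.bin_counts(ds.tables, ds.annotation.chrom_lengths, pcfg)
    age_tables, age_dmrs = {}, {}
    for name, older, younger in AGE_COMPARISONS:
        table = dmr.call_dmrs(bins, samples_for_age(ds.sheet, older),
                              samples_for_age(ds.sheet, younger), pcfg, name)
        age_tables[name] = table
        age_dmrs[name] = dmr_records(table)
    rep_dmrs = {}
    for age in sorted(ds.sheet["age_years"].unique()):
        reps = samples_for_age(ds.sheet, age)
        if len(reps) < 2:
            continue
        table = dmr.call_dmrs(bins, [reps[0]], [reps[1]], pcfg, f"rep_y{age}")
        rep_dmrs[age] = dmr_records(table)
    return {"bins": bins, "age_tables": age_tables, "age_dmrs": age_dmrs,
            "replicate_dmrs": rep_dmrs}


def trend_stage(dmr_out: dict, sheet: pd.DataFrame, annotation,
                pcfg: PipelineConfig, seed: int = 0) -> dict:
    """Replicate exclusion, consensus, trajectories, model-profile clustering,
    element assignment and gene association."""
    reserved, excl_stats, rep_bins = age_trend.replicate_dmr_exclusion(
        dmr_out["age_dmrs"], dmr_out["replicate_dmrs"])
    consensus = age_trend.consensus_dmrs(reserved, pcfg)
    reserved_union = (pd.concat(reserved.values(), ignore_index=True)
                      [["chrom", "start", "end", "context", "direction"]]
                      .drop_duplicates(["chrom", "start", "context"])
                      .reset_index(drop=True))
    traj = age_trend.trajectories(dmr_out["bins"], reserved_union, sheet)
    profiles, assignments = age_trend.stem_cluster(traj, config=pcfg, seed=seed)
    elements = age_trend.assign_elements(consensus, annotation, pcfg)
    element_counts = (elements.groupby(["context", "direction", "element"], observed=True)
                      .size().rename("n_bins").reset_index())
    gene_links = age_trend.genes_with_dmrs(consensus, annotation, pcfg.flank_bp)
    return {"reserved": reserved, "exclusion_stats": excl_stats,
            "replicate_dmr_bins": rep_bins, "consensus": consensus,
            "trajectories": traj, "profiles": profiles,
            "assignments": assignments, "element_counts": element_counts,
            "gene_links": gene_links}


def expression_stage(ds, levels_by_sample: dict, pooled_levels: pd.DataFrame,
                     region_meth: pd.DataFrame, pcfg: PipelineConfig) -> dict:
    groups = expression.expression_groups(ds.tpm, mode="mean", config=pcfg)
    summary, pairs = expression.group_region_comparison(region_meth, groups, pcfg)
    flank = expression.two_group_flank_profiles(levels_by_sample, ds.annotation,
                                                ds.tpm, pcfg)
    segments = [MarkerSegment(gene_id=m["gene_id"], chrom=m["chrom"],
                              start=m["start"], end=m["end"], context=m["context"])
                for m in ds.truth.marker_segments]
    markers = (expression.marker_correlation(levels_by_sample, segments, ds.tpm,
                                             ds.sheet, pcfg)
               if segments else pd.DataFrame())
    return {"expression_groups": groups, "group_summary": summary,
            "group_pairs": pairs, "two_group_profiles": flank,
            "marker_correlation": markers}


def run_pipeline(ds, pcfg: PipelineConfig | None = None, seed: int = 0) -> dict:
    """Run every stage on a (simulated or loaded) dataset."""
    pcfg = (pcfg or PipelineConfig()).validate()
    results = {}
    qc = qc_stage(ds, pcfg)
    results["qc"] = qc
    pooled = pool_tables(ds.tables)
    pooled_levels = core.site_levels(pooled, pcfg)
    results["global"] = {
        ctx: core.global_weighted_level(pooled_levels, context=ctx,
                                        conversion=qc["conversion"].conversion_rate,
                                        config=pcfg)
        for ctx in ("CG", "CHG", "CHH")
    }
    results["profiles"] = profile_stage(pooled_levels, ds.annotation, pcfg)
    dmr_out = dmr_stage(ds, pcfg)
    results["dmr"] = dmr_out
    results["trend"] = trend_stage(dmr_out, ds.sheet, ds.annotation, pcfg, seed=seed)
    results["expression"] = expression_stage(
        ds, qc["levels_by_sample"], pooled_levels,
        results["profiles"]["region_methylation"], pcfg)
    if ds.srna:
        results["srna_correlation"] = core.track_methylation_correlation(
            ds.srna, pooled_levels, ds.annotation.chrom_lengths,
            next(iter(ds.srna.values()))["end"].sub(
                next(iter(ds.srna.values()))["start"]).max(), pcfg)
    return results


def summarize(results: dict) -> dict:
    """Flat numeric summary of a pipeline run (for logs and reports)."""
    out = {}
    conv = results["qc"]["conversion"]
    out["conversion_rate"] = conv.conversion_rate
    rc = results["qc"]["replicate_correlation"]
    if len(rc):
        out["replicate_r_combined_min"] = float(rc["r_combined"].min())
    for ctx, g in results["global"].items():
        out[f"global_level_{ctx}"] = g.weighted_level
        out[f"mc_fraction_{ctx}"] = g.mc_fraction
    for name, recs in results["dmr"]["age_dmrs"].items():
        for ctx in ("CG", "CHG", "CHH"):
            out[f"n_dmr_{name}_{ctx}"] = int((recs["context"] == ctx).sum())
    cons = results["trend"]["consensus"]
    for ctx in ("CG", "CHG", "CHH"):
        for direction in ("hyper", "hypo"):
            out[f"n_consensus_{direction}_{ctx}"] = int(
                ((cons["context"] == ctx) & (cons["direction"] == direction)).sum())
    prof = results["trend"]["profiles"]
    ranked = prof.dropna(subset=["p_adj"]).sort_values("p_adj")
    if len(ranked):
        out["top_profile"] = ranked.iloc[0]["profile"]
        out["top_profile_p_adj"] = float(ranked.iloc[0]["p_adj"])
    mk = results["expression"]["marker_correlation"]
    if len(mk):
        out["marker_r_level_tpm_max"] = float(mk["r_level_tpm"].max())
    return out
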