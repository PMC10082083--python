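"""Age-DMR consensus procedure and model-profile trend clustering.

Pipeline for separating developmental-age methylation change from
replicate-to-replicate drift:

1. DMRs are called between age groups with large gaps (35v2, 35v5, 14v2)
   and, with the same test and thresholds, between the two replicates
   *within* each age.
2. Any age-DMR bin that is also a replicate-DMR bin of the same context in
   any age is excluded ("reserved" DMRs remain).
3. A bin is a consensus hyper-(hypo-)DMR when called hyper (hypo) in at
   least two of the age comparisons; bins called in both directions are
   dropped.
4. Reserved/consensus bins get 4-point trajectories (per-age pooled levels)
   which are clustered against the 27 integer model profiles reachable from
   0 with per-step changes in {-1, 0, 1} (the short-time-series model-profile
   approach); profile significance comes from permuting the time order of
   every trajectory.

All DMR sets live on the same fixed 1000-bp grid, so "overlap" between sets
is bin identity.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONTEXTS, PipelineConfig
from .dmr import BinCounts, adjust_fdr
from .io import GenomeAnnotation

__all__ = [
    "replicate_dmr_exclusion", "consensus_dmrs", "trajectories",
    "model_profiles", "stem_cluster", "assign_elements", "genes_with_dmrs",
]

BIN_KEY = ["chrom", "start", "context"]


def _key_index(df: pd.DataFrame) -> pd.MultiIndex:
    return pd.MultiIndex.from_frame(df[BIN_KEY])


def replicate_dmr_exclusion(age_dmrs: dict, replicate_dmrs: dict):
    """Remove age-DMR bins that recur as within-age replicate DMRs.

    *age_dmrs*: ``{comparison: DMR frame}``; *replicate_dmrs*:
    ``{age: DMR frame}`` from the rep1-vs-rep2 comparisons.  Exclusion is
    context-matched and age-agnostic: a bin flagged between replicates at
    any age is removed from every age comparison for that context.

    Returns ``(reserved, stats, replicate_bins)`` where *stats* reports, per
    context, the fraction of replicate DMRs overlapping age DMRs and the
    fraction of age DMRs reserved.
    """
    if not replicate_dmrs:
        raise ValueError("no replicate DMR sets supplied")
    rep_all = (pd.concat(replicate_dmrs.values(), ignore_index=True)
               if len(replicate_dmrs) else pd.DataFrame(columns=BIN_KEY))
    rep_bins = set(map(tuple, rep_all[BIN_KEY].itertuples(index=False))) \
        if len(rep_all) else set()

    reserved = {}
    age_bins = set()
    for comp, df in age_dmrs.items():
        keys = list(map(tuple, df[BIN_KEY].itertuples(index=False)))
        age_bins.update(keys)
        keep = np.array([k not in rep_bins for k in keys], dtype=bool) \
            if len(df) else np.zeros(0, dtype=bool)
        reserved[comp] = df.loc[keep].reset_index(drop=True)

    rows = []
    for ctx in CONTEXTS:
        age_ctx = {k for k in age_bins if k[2] == ctx}
        rep_ctx = {k for k in rep_bins if k[2] == ctx}
        overlap = age_ctx & rep_ctx
        rows.append({
            "context": ctx,
            "n_age_dmr_bins": len(age_ctx),
            "n_replicate_dmr_bins": len(rep_ctx),
            "n_overlap": len(overlap),
            "replicate_overlap_fraction": (len(overlap) / len(rep_ctx)
                                           if rep_ctx else np.nan),
            "reserved_fraction": (1.0 - len(overlap) / len(age_ctx)
                                  if age_ctx else np.nan),
        })
    return reserved, pd.DataFrame(rows), rep_bins


def consensus_dmrs(reserved: dict, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Direction-consistent bins recurring in >= ``min_consensus_comparisons``
    age comparisons.  Bins hyper in one comparison and hypo in another are
    conflicted and dropped (tallied in ``attrs["n_conflicted"]``)."""
    cfg = config or PipelineConfig()
    if len(reserved) < cfg.min_consensus_comparisons:
        raise ValueError("fewer comparisons than min_consensus_comparisons")
    counts = {}
    for comp, df in reserved.items():
        for row in df.itertuples(index=False):
            key = (row.chrom, row.start, row.context)
            entry = counts.setdefault(key, {"hyper": 0, "hypo": 0, "end": row.end})
            if row.direction in ("hyper", "hypo"):
                entry[row.direction] += 1
    rows, n_conflicted = [], 0
    for (chrom, start, ctx), entry in counts.items():
        if entry["hyper"] > 0 and entry["hypo"] > 0:
            n_conflicted += 1
            continue
        direction = "hyper" if entry["hyper"] else "hypo"
        n = entry[direction]
        if n >= cfg.min_consensus_comparisons:
            rows.append({"chrom": chrom, "start": start, "end": entry["end"],
                         "context": ctx, "direction": direction,
                         "n_comparisons": n})
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "context",
                                      "direction", "n_comparisons"])
    out = out.sort_values(["context", "chrom", "start"]).reset_index(drop=True)
    out.attrs["n_conflicted"] = n_conflicted
    return out


def trajectories(bins: BinCounts, bin_set: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-age pooled methylation trajectories for a set of grid bins.

    Replicate counts are summed within each age before the ratio is taken.
    Bins with zero coverage at any age are dropped.  Columns: the bin key
    plus ``level_<age>`` ordered by age.
    """
    ages = sorted(sheet["age_years"].unique())
    idx = _key_index(bin_set).drop_duplicates()
    out = bin_set[BIN_KEY].drop_duplicates().reset_index(drop=True)
    ok = np.ones(len(out), dtype=bool)
    for age in ages:
        samples = sheet.loc[sheet["age_years"] == age, "sample_id"].tolist()
        mc = bins.mc[samples].sum(axis=1).reindex(idx)
        uc = bins.uc[samples].sum(axis=1).reindex(idx)
        total = (mc + uc).to_numpy()
        level = np.divide(mc.to_numpy(), total, out=np.full(len(idx), np.nan),
                          where=total > 0)
        out[f"level_{age}"] = level
        ok &= np.isfinite(level)
    return out.loc[ok].reset_index(drop=True)


# ---------------------------------------------------------------------------
# model-profile (STEM-like) clustering
# ---------------------------------------------------------------------------

def model_profiles(n_timepoints: int = 4, c: int = 1) -> np.ndarray:
    """All integer model profiles: step vectors starting at 0 with per-step
    unit changes in {-c..c}.  For 4 time points and c=1 there are 27,
    including the flat reference profile."""
    steps = itertools.product(range(-c, c + 1), repeat=n_timepoints - 1)
    return np.array([np.concatenate([[0], np.cumsum(s)]) for s in steps], dtype=float)


def _standardize(x: np.ndarray):
    """Subtract the first value and scale by the range; flags degenerate rows."""
    v = x - x[:, [0]]
    rng = x.max(axis=1) - x.min(axis=1)
    flat = rng <= 0
    v = v / np.where(flat, 1.0, rng)[:, None]
    return v, flat


def _assign(values: np.ndarray, z_profiles: np.ndarray, profile_sd_ok: np.ndarray):
    """Pearson-correlation assignment of each row to a model profile.

    Ties go to the lower profile index; degenerate (flat) rows return -1.
    """
    v, flat = _standardize(values)
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    flat |= (sd[:, 0] == 0)
    zv = (v - mu) / np.where(sd == 0, 1.0, sd)
    corr = zv @ z_profiles.T / values.shape[1]
    corr[:, ~profile_sd_ok] = -np.inf
    corr = np.round(corr, 12)  # make mirror-symmetry ties exact
    assigned = np.argmax(corr, axis=1)
    assigned[flat] = -1
    return assigned


def stem_cluster(
    traj: pd.DataFrame,
    c: int | None = None,
    n_permutations: int | None = None,
    seed: int = 0,
    config: PipelineConfig | None = None,
):
    """Cluster 4-point trajectories against integer model profiles.

    Each trajectory is standardized (first value subtracted, scaled by its
    range) and assigned to the profile with the highest Pearson correlation.
    Profile significance: the expected assignment rate is estimated by
    ``n_permutations`` full passes in which the time order of every
    trajectory is independently permuted; the one-sided binomial tail
    p-value of the observed count is BH-adjusted across the non-flat
    profiles.  Flat trajectories are assigned to the zero profile and
    excluded from the significance computation.

    Returns ``(profiles, assignments)``.
    """
    cfg = config or PipelineConfig()
    c = c if c is not None else cfg.stem_max_unit_change
    n_permutations = n_permutations or cfg.stem_permutations
    level_cols = [col for col in traj.columns if col.startswith("level_")]
    values = traj[level_cols].to_numpy(dtype=float)
    n_t = values.shape[1]
    profiles = model_profiles(n_t, c)
    sd = profiles.std(axis=1)
    profile_sd_ok = sd > 0
    zp = (profiles - profiles.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1, sd)[:, None]

    assigned = _assign(values, zp, profile_sd_ok)
    active = assigned >= 0
    n_active = int(active.sum())
    observed = np.bincount(assigned[active], minlength=len(profiles))

    rng = np.random.default_rng(seed)
    perm_counts = np.zeros(len(profiles), dtype=np.int64)
    n_perm_assigned = 0
    if n_active and n_permutations:
        vals = values[active]
        # all permutation passes in one batch: each row independently reordered
        rep = np.repeat(vals, n_permutations, axis=0)
        order = np.argsort(rng.random(rep.shape), axis=1)
        permuted = np.take_along_axis(rep, order, axis=1)
        pa = _assign(permuted, zp, profile_sd_ok)
        pa = pa[pa >= 0]
        n_perm_assigned = len(pa)
        perm_counts = np.bincount(pa, minlength=len(profiles))

    rows = []
    for i, prof in enumerate(profiles):
        is_flat = not profile_sd_ok[i]
        if n_perm_assigned:
            rate = perm_counts[i] / n_perm_assigned
            rate = max(rate, 0.5 / n_perm_assigned)  # avoid zero-rate degeneracy
        else:
            rate = np.nan
        expected = rate * n_active if n_perm_assigned else np.nan
        if is_flat or not n_perm_assigned:
            p = np.nan
        else:
            p = float(stats.binom.sf(observed[i] - 1, n_active, min(rate, 1.0)))
        rows.append({
            "profile_id": i,
            "profile": ",".join(str(int(v)) for v in prof),
            "is_flat_reference": is_flat,
            "n_assigned": int(observed[i]),
            "expected": expected,
            "p": p,
        })
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    testable = table["p"].notna()
    if testable.any():
        table.loc[testable, "p_adj"] = adjust_fdr(table.loc[testable, "p"].to_numpy())

    assignments = traj[BIN_KEY].copy() if set(BIN_KEY) <= set(traj.columns) else pd.DataFrame(index=traj.index)
    assignments["profile_id"] = np.where(active, assigned, _flat_profile_id(profiles))
    return table, assignments


def _flat_profile_id(profiles: np.ndarray) -> int:
    return int(np.flatnonzero((profiles == 0).all(axis=1))[0])


# ---------------------------------------------------------------------------
# genomic-element assignment & gene association
# ---------------------------------------------------------------------------

ELEMENTS = ["te", "gene_body", "promoter", "downstream", "intergenic"]
_PRIORITY = {"te": 4, "gene_body": 3, "promoter": 2, "downstream": 1, "intergenic": 0}


def assign_elements(
    dmr_bins: pd.DataFrame,
    annotation: GenomeAnnotation,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Assign each DMR bin to exactly one genomic element.

    Per-basepair priority TE > gene body > promoter (2 kb upstream of the
    TSS, strand-aware) > downstream (2 kb past the TES) > intergenic; the
    bin takes the highest-priority element it overlaps by >= 1 bp.  Counts
    over elements partition the DMR set.
    """
    cfg = config or PipelineConfig()
    paint = {c: np.zeros(l, dtype=np.int8) for c, l in annotation.chrom_lengths.items()}

    def mark(chrom, s, e, code):
        arr = paint.get(chrom)
        if arr is None:
            return
        s, e = max(0, s), min(len(arr), e)
        if e > s:
            arr[s:e] = np.maximum(arr[s:e], code)

    for g in annotation.genes:
        if g.strand == "+":
            mark(g.chrom, g.start - cfg.flank_bp, g.start, _PRIORITY["promoter"])
            mark(g.chrom, g.end, g.end + cfg.flank_bp, _PRIORITY["downstream"])
        else:
            mark(g.chrom, g.end, g.end + cfg.flank_bp, _PRIORITY["promoter"])
            mark(g.chrom, g.start - cfg.flank_bp, g.start, _PRIORITY["downstream"])
        mark(g.chrom, g.start, g.end, _PRIORITY["gene_body"])
    for r in annotation.tes.itertuples():
        mark(r.chrom, int(r.start), int(r.end), _PRIORITY["te"])

    code_to_name = {v: k for k, v in _PRIORITY.items()}
    out = dmr_bins.copy()
    elements = []
    for row in out.itertuples(index=False):
        arr = paint.get(row.chrom)
        end = getattr(row, "end", row.start + 1000)
        code = int(arr[row.start:end].max()) if arr is not None and end > row.start else 0
        elements.append(code_to_name[code])
    out["element"] = elements
    return out


def genes_with_dmrs(dmr_bins: pd.DataFrame, annotation: GenomeAnnotation,
                    flank_bp: int = 2000) -> pd.DataFrame:
    """Per-gene hyper/hypo DMR linkage per context.

    A gene is linked to a DMR when the bin overlaps the gene body or its
    2-kb flanks; linkage is not exclusive (overlapping genes may share one
    DMR, and one gene may be both hyper- and hypo-linked).
    """
    rows = []
    by_chrom = {}
    for key, grp in dmr_bins.groupby(["chrom", "context", "direction"], observed=True):
        order = np.argsort(grp["start"].to_numpy())
        starts = grp["start"].to_numpy()[order]
        ends = grp["end"].to_numpy()[order]
        by_chrom[key] = (starts, ends)
    for g in annotation.genes:
        lo, hi = g.start - flank_bp, g.end + flank_bp
        row = {"gene_id": g.gene_id}
        for ctx in CONTEXTS:
            for direction in ("hyper", "hypo"):
                starts, ends = by_chrom.get((g.chrom, ctx, direction), (None, None))
                linked = False
                if starts is not None and len(starts):
                    i = np.searchsorted(starts, hi)
                    linked = bool((ends[:i] > lo).any())
                row[f"{ctx}_{direction}"] = linked
        rows.append(row)
    return pd.DataFrame(rows)
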