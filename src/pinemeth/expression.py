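"""Methylation-expression linkage.

Genes are stratified into five expression groups (TPM = 0, 0 < TPM <= 1,
1 < TPM <= 10, 10 < TPM <= 50, TPM > 50) and their regional methylation is
compared with two-sided Mann-Whitney tests, summarized as a compact letter
display: two groups share a letter iff they are not significantly
different at the chosen alpha.  A per-sample two-group variant contrasts
flank metaprofiles of lowly (0 < TPM <= 1) and actively (TPM > 1)
expressed genes.  Age-marker segments (DAL1-style) are scored by the
Pearson correlation of their per-age pooled methylation level with the
gene's per-age expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONTEXTS, PipelineConfig
from .io import GenomeAnnotation
from .metaprofiles import SiteArrays, gene_te_profile

__all__ = [
    "EXPRESSION_GROUP_LABELS", "expression_groups", "mannwhitney_p",
    "compact_letter_display", "group_region_comparison",
    "two_group_flank_profiles", "MarkerSegment", "marker_correlation",
]

EXPRESSION_GROUP_LABELS = ["TPM=0", "0<TPM<=1", "1<TPM<=10", "10<TPM<=50", "TPM>50"]


def expression_groups(
    tpm: pd.DataFrame,
    mode: str = "mean",
    sample: str | None = None,
    config: PipelineConfig | None = None,
) -> pd.Series:
    """Five-group expression stratification with half-open breaks.

    *mode* "mean" averages TPM over samples; "sample" uses one column.
    Breaks are (0, 1, 10, 50]: TPM = 0 is its own group and each interval
    is closed on the right.
    """
    cfg = config or PipelineConfig()
    if mode == "mean":
        values = tpm.mean(axis=1)
    elif mode == "sample":
        if sample is None:
            raise ValueError("mode='sample' requires a sample id")
        values = tpm[sample]
    else:
        raise ValueError("mode must be 'mean' or 'sample'")
    v = values.to_numpy(dtype=float)
    if (v < 0).any():
        raise ValueError("negative TPM")
    breaks = cfg.expression_breaks  # (0, 1, 10, 50)
    codes = np.searchsorted(np.asarray(breaks[1:], dtype=float), v, side="left") + 1
    codes[v == 0] = 0
    return pd.Series(
        pd.Categorical.from_codes(codes, categories=EXPRESSION_GROUP_LABELS),
        index=values.index, name="expression_group",
    )


def mannwhitney_p(x, y) -> float:
    """Two-sided Mann-Whitney p-value.

    Exact null distribution when both groups have <= 8 observations and no
    ties; otherwise the normal approximation with continuity and tie
    correction (group sizes in practice are large).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def compact_letter_display(labels: list, p: dict, alpha: float) -> dict:
    """Insert-and-absorb compact letter display.

    *p* maps unordered label pairs to p-values.  Returns ``{label: letters}``
    such that two labels share a letter iff their pair is **not** significant
    (p >= alpha).
    """
    def pval(a, b):
        return p.get((a, b), p.get((b, a), 1.0))

    letter_sets = [set(labels)]
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if pval(a, b) >= alpha:
                continue  # not significant: may share letters
            new_sets = []
            for s in letter_sets:
                if a in s and b in s:
                    new_sets.extend([s - {a}, s - {b}])
                else:
                    new_sets.append(s)
            # absorb subsets, drop empties
            letter_sets = []
            for s in sorted(new_sets, key=len, reverse=True):
                if s and not any(s <= t for t in letter_sets):
                    letter_sets.append(s)
    # stable ordering: by first member's position in labels
    letter_sets.sort(key=lambda s: min(labels.index(m) for m in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, s in zip(alphabet, letter_sets):
        for lab in labels:
            if lab in s:
                out[lab] += letter
    return out


def group_region_comparison(
    region_meth: pd.DataFrame,
    groups: pd.Series,
    config: PipelineConfig | None = None,
):
    """Per region class x context: group medians, pairwise Mann-Whitney
    p-values and a compact letter display.

    Groups with fewer than 2 genes are excluded (noted in the summary).
    Returns ``(summary, pairs)``.
    """
    cfg = config or PipelineConfig()
    df = region_meth.merge(groups.rename("group"), left_on="gene_id", right_index=True)
    summary_rows, pair_rows = [], []
    for (region, ctx), sub in df.groupby(["region", "context"], observed=True, sort=False):
        data = {}
        for lab in EXPRESSION_GROUP_LABELS:
            vals = sub.loc[sub["group"] == lab, "level"].dropna().to_numpy()
            if len(vals) >= 2:
                data[lab] = vals
        labels = [lab for lab in EXPRESSION_GROUP_LABELS if lab in data]
        pmap = {}
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                pv = mannwhitney_p(data[a], data[b])
                pmap[(a, b)] = pv
                pair_rows.append({"region": region, "context": ctx,
                                  "group_a": a, "group_b": b, "p": pv})
        letters = compact_letter_display(labels, pmap, cfg.group_test_alpha)
        for lab in EXPRESSION_GROUP_LABELS:
            summary_rows.append({
                "region": region, "context": ctx, "group": lab,
                "n_genes": len(data.get(lab, [])),
                "median_level": (float(np.median(data[lab])) if lab in data else np.nan),
                "letters": letters.get(lab, ""),
                "excluded": lab not in data,
            })
    return pd.DataFrame(summary_rows), pd.DataFrame(pair_rows)


def two_group_flank_profiles(
    levels_by_sample: dict,
    annotation: GenomeAnnotation,
    tpm: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-sample gene metaprofiles for lowly (0<TPM<=1) vs actively
    (TPM>1) expressed genes.  Empty groups yield NA profiles."""
    cfg = config or PipelineConfig()
    parts = []
    for sample, levels in levels_by_sample.items():
        arrays = levels if isinstance(levels, SiteArrays) else SiteArrays(levels)
        t = tpm[sample]
        groups = {
            "0<TPM<=1": t[(t > 0) & (t <= 1)].index.tolist(),
            "TPM>1": t[t > 1].index.tolist(),
        }
        for label, members in groups.items():
            prof = gene_te_profile(arrays, annotation, "gene", cfg,
                                   subset=members, group=label)
            prof.insert(0, "sample", sample)
            parts.append(prof)
    return pd.concat(parts, ignore_index=True)


@dataclass
class MarkerSegment:
    """A genomic segment of an age-marker gene, scored in one context."""

    gene_id: str
    chrom: str
    start: int
    end: int
    context: str = "CHG"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: empty marker segment")
        if self.context not in CONTEXTS:
            raise ValueError(f"{self.gene_id}: bad context {self.context}")


def marker_correlation(
    tables: dict,
    segments: list,
    tpm: pd.DataFrame,
    sheet: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-age segment methylation vs expression for age-marker genes.

    For each segment the replicate counts are pooled per age and the
    weighted level taken over the segment's cytosines of its context.
    Pearson correlations of level against per-age mean TPM and against age
    rank are reported; NA (with a flag) when fewer than 3 ages are covered
    or the series is constant.
    """
    ages = sorted(sheet["age_years"].unique())
    arrays = {s: (t if isinstance(t, SiteArrays) else SiteArrays(t))
              for s, t in tables.items()}
    rows = []
    for seg in segments:
        levels, tpms = [], []
        for age in ages:
            samples = sheet.loc[sheet["age_years"] == age, "sample_id"]
            mc = tot = 0.0
            for s in samples:
                _, m, t, ctx = arrays[s].slice(seg.chrom, seg.start, seg.end)
                sel = ctx == CONTEXTS.index(seg.context)
                mc += m[sel].sum()
                tot += t[sel].sum()
            levels.append(mc / tot if tot > 0 else np.nan)
            cols = [s for s in samples if s in tpm.columns]
            tpms.append(float(tpm.loc[seg.gene_id, cols].mean()) if cols else np.nan)
        row = {"gene_id": seg.gene_id, "chrom": seg.chrom, "start": seg.start,
               "end": seg.end, "context": seg.context}
        for age, lv, tp in zip(ages, levels, tpms):
            row[f"level_{age}"] = lv
            row[f"tpm_{age}"] = tp
        lv = np.asarray(levels)
        tp = np.asarray(tpms)
        valid = np.isfinite(lv) & np.isfinite(tp)
        if valid.sum() < 3 or np.ptp(lv[valid]) == 0 or np.ptp(tp[valid]) == 0:
            row["r_level_tpm"] = np.nan
            row["r_level_age"] = np.nan
            row["degenerate"] = True
        else:
            row["r_level_tpm"] = float(stats.pearsonr(lv[valid], tp[valid])[0])
            rank = np.arange(len(ages), dtype=float)[valid]
            row["r_level_age"] = (float(stats.pearsonr(lv[valid], rank)[0])
                                  if np.ptp(rank) > 0 else np.nan)
            row["degenerate"] = False
        rows.append(row)
    return pd.DataFrame(rows)
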