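"""Fixed-grid differential methylation testing.

The genome is tiled with 1000-bp bins; methylated and unmethylated read
counts are summed per bin, sample and context.  For a two-group comparison
the replicate counts are pooled within each group and a two-sided Fisher's
exact test is applied to the 2x2 table ``[[m1, u1], [m2, u2]]``.  P-values
are Benjamini-Hochberg adjusted separately per context within each
comparison, and a bin is called a DMR when the adjusted p-value is below
0.01 *and* the absolute pooled-level difference reaches the context-specific
floor (0.2 / 0.15 / 0.1 for CG / CHG / CHH by default).

"hyper" means higher methylation in the first (older) group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .config import CONTEXTS, PipelineConfig

__all__ = [
    "BinCounts", "bin_counts", "fisher_exact_two_sided", "test_bin",
    "adjust_fdr", "call_dmrs", "filter_dmrs",
]


# ---------------------------------------------------------------------------
# Fisher's exact test, vectorized
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(m1, u1, m2, u2) -> np.ndarray:
    """Two-sided Fisher's exact p-value for arrays of 2x2 tables.

    The two-sided p is the total hypergeometric probability of all tables
    with the same margins that are no more likely than the observed one.
    Tables sharing margins are evaluated together: the pmf over the shared
    support is computed once (log-space, via ``gammaln``) and every observed
    cell is scored against its sorted prefix sums.  The tie window in
    log-pmf space scales with the floating-point error of the log-gamma
    sums, so exact pmf ties (e.g. symmetric tables) are always included.
    """
    m1 = np.atleast_1d(np.asarray(m1, dtype=np.int64))
    u1 = np.atleast_1d(np.asarray(u1, dtype=np.int64))
    m2 = np.atleast_1d(np.asarray(m2, dtype=np.int64))
    u2 = np.atleast_1d(np.asarray(u2, dtype=np.int64))
    if np.any(m1 < 0) or np.any(u1 < 0) or np.any(m2 < 0) or np.any(u2 < 0):
        raise ValueError("counts must be non-negative")

    n1 = m1 + u1
    n2 = m2 + u2
    K = m1 + m2
    M = n1 + n2

    p = np.ones(len(m1), dtype=np.float64)
    ok = (n1 > 0) & (n2 > 0) & (K > 0) & (K < M)  # else the table is degenerate, p = 1
    if not ok.any():
        return p

    lg = gammaln(np.arange(int(M.max()) + 2, dtype=np.float64))

    def lchoose(n, k):
        return lg[n + 1] - lg[k + 1] - lg[n - k + 1]

    idx_ok = np.flatnonzero(ok)
    margins = np.stack([n1[idx_ok], n2[idx_ok], K[idx_ok]], axis=1)
    uniq, inv = np.unique(margins, axis=0, return_inverse=True)
    obs = m1[idx_ok]

    # flatten the supports of all unique margin groups
    lo = np.maximum(0, uniq[:, 2] - uniq[:, 1])
    hi = np.minimum(uniq[:, 2], uniq[:, 0])
    lens = hi - lo + 1
    starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
    total = int(lens.sum())
    grp = np.repeat(np.arange(len(uniq)), lens)
    k = np.arange(total) - starts[grp] + lo[grp]

    gn1, gn2, gK = uniq[grp, 0], uniq[grp, 1], uniq[grp, 2]
    gM = gn1 + gn2
    logpmf = (lchoose(gn1, k) + lchoose(gn2, gK - k) - lchoose(gM, gK))

    # tie tolerance: float error of the gammaln sums grows with the margins
    Mu = uniq[:, 0] + uniq[:, 1]
    delta = 1e-11 + 2e-15 * Mu * (np.log(Mu + 1.0) + 1.0)

    out = np.empty(len(idx_ok), dtype=np.float64)
    # per-group: sort pmf, prefix-sum, score each observed table of the group
    order = np.lexsort((logpmf, grp))
    logpmf_sorted = logpmf[order]
    pmf_sorted = np.exp(logpmf_sorted)
    for g in range(len(uniq)):
        s, e = starts[g], starts[g] + lens[g]
        lp = logpmf_sorted[s:e]
        prefix = np.cumsum(pmf_sorted[s:e])
        norm = prefix[-1]
        members = np.flatnonzero(inv == g)
        obs_lp = logpmf[starts[g] + (obs[members] - lo[g])]
        pos = np.searchsorted(lp, obs_lp + delta[g], side="right")
        out[members] = prefix[pos - 1] / norm
    p[idx_ok] = np.minimum(out, 1.0)
    return p


def test_bin(m1: int, u1: int, m2: int, u2: int):
    """Pooled-count bin test: ``(diff, p)``.

    ``diff`` is the level of group 1 minus group 2; ``p`` the two-sided
    Fisher's exact p-value; ``(nan, nan)`` when a group has no reads.
    """
    if (m1 + u1) == 0 or (m2 + u2) == 0:
        return float("nan"), float("nan")
    diff = m1 / (m1 + u1) - m2 / (m2 + u2)
    p = float(fisher_exact_two_sided([m1], [u1], [m2], [u2])[0])
    return diff, p


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# bin counting
# ---------------------------------------------------------------------------

@dataclass
class BinCounts:
    """Methylated/unmethylated read counts per (bin, context) and sample.

    ``mc`` and ``uc`` are frames indexed by (chrom, start, context) with one
    column per sample.  Rows exist only for bins containing at least one
    cytosine of the context; the last bin of a chromosome may be short.
    """

    mc: pd.DataFrame
    uc: pd.DataFrame
    bin_size: int
    chrom_lengths: dict

    @property
    def samples(self) -> list:
        return list(self.mc.columns)

    def pooled(self, samples: list):
        return self.mc[samples].sum(axis=1), self.uc[samples].sum(axis=1)


def bin_counts(tables: dict, chrom_lengths: dict, config: PipelineConfig) -> BinCounts:
    """Sum per-cytosine counts onto the fixed DMR grid, per sample/context."""
    size = config.bin_size_dmr
    mc_cols, uc_cols = {}, {}
    for sample, df in tables.items():
        start = (df["pos"] // size) * size
        grouped = df.groupby([df["chrom"], start, df["context"]], observed=True)
        mc_cols[sample] = grouped["mc"].sum()
        uc_cols[sample] = grouped["uc"].sum()
    mc = pd.DataFrame(mc_cols).fillna(0).astype(np.int64)
    uc = pd.DataFrame(uc_cols).fillna(0).astype(np.int64)
    mc.index.names = uc.index.names = ["chrom", "start", "context"]
    mc = mc.sort_index()
    uc = uc.reindex(mc.index)
    return BinCounts(mc=mc, uc=uc, bin_size=size, chrom_lengths=dict(chrom_lengths))


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

def call_dmrs(
    bins: BinCounts,
    group_older: list,
    group_younger: list,
    config: PipelineConfig,
    comparison: str = "",
) -> pd.DataFrame:
    """Test every eligible bin and call DMRs for one two-group comparison.

    Eligibility: total read coverage >= ``coverage_min`` in at least one of
    the involved samples.  Returns the full tested-bin table (one row per
    bin x context) with pooled levels, diff, p, BH-adjusted p (per context),
    direction and a ``called`` flag; DMRs are the rows with ``called``.
    """
    for s in group_older + group_younger:
        if s not in bins.samples:
            raise KeyError(f"unknown sample {s!r}")
    involved = group_older + group_younger
    cov = (bins.mc[involved] + bins.uc[involved])
    eligible = (cov >= config.coverage_min).any(axis=1)

    m1, u1 = bins.pooled(group_older)
    m2, u2 = bins.pooled(group_younger)
    df = pd.DataFrame({
        "m1": m1, "u1": u1, "m2": m2, "u2": u2,
    }).loc[eligible].reset_index()
    df["end"] = np.minimum(
        df["start"] + bins.bin_size,
        df["chrom"].map(bins.chrom_lengths).astype(np.int64),
    )
    t1 = df["m1"] + df["u1"]
    t2 = df["m2"] + df["u2"]
    testable = (t1 > 0) & (t2 > 0)
    df["level_older"] = np.where(t1 > 0, df["m1"] / t1.replace(0, 1), np.nan)
    df["level_younger"] = np.where(t2 > 0, df["m2"] / t2.replace(0, 1), np.nan)
    df["diff"] = df["level_older"] - df["level_younger"]
    df["p"] = np.nan
    idx = np.flatnonzero(testable.to_numpy())
    if len(idx):
        df.loc[df.index[idx], "p"] = fisher_exact_two_sided(
            df["m1"].to_numpy()[idx], df["u1"].to_numpy()[idx],
            df["m2"].to_numpy()[idx], df["u2"].to_numpy()[idx],
        )
    # BH family: per context within this comparison
    df["p_adj"] = np.nan
    for ctx in CONTEXTS:
        sel = (df["context"] == ctx) & df["p"].notna()
        if sel.any():
            df.loc[sel, "p_adj"] = adjust_fdr(df.loc[sel, "p"].to_numpy())
    df["direction"] = np.where(df["diff"] > 0, "hyper", "hypo")
    df.loc[df["diff"].isna() | (df["diff"] == 0), "direction"] = "none"
    df["comparison"] = comparison
    return filter_dmrs(df, config)


def filter_dmrs(table: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Apply the DMR thresholds: adjusted p strictly below ``dmr_p_adj_max``
    and |diff| at or above the context-specific minimum."""
    diff_min = table["context"].map(config.dmr_diff_min).astype(float)
    table = table.copy()
    table["called"] = (
        table["p_adj"].notna()
        & (table["p_adj"] < config.dmr_p_adj_max)
        & (table["diff"].abs() >= diff_min)
    )
    return table


def dmr_records(table: pd.DataFrame) -> pd.DataFrame:
    """The called rows of a tested-bin table, in the emitted DMR layout."""
    cols = ["chrom", "start", "end", "context", "comparison",
            "level_older", "level_younger", "diff", "p", "p_adj", "direction"]
    return table.loc[table["called"], cols].reset_index(drop=True)
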