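"""Site-level methylation computations.

The bisulfite read-out of a cytosine is a pair of counts (reads calling the
base methylated / unmethylated).  The methylation ratio of a site is
``mc / (mc + uc)`` and is only reported for sites covered by at least
``coverage_min`` reads.  Regional "weighted" levels are count-weighted:
``sum(mc) / sum(mc + uc)`` over the covered sites of the region, never a mean
of per-site ratios (a flag exists to switch for sensitivity analyses).

Context classification follows plant convention: CG, CHG, CHH with H in
{A, C, T}; the trinucleotide starting at the cytosine (read on the reverse
complement for minus-strand cytosines) refines each context into
sub-contexts (4 CG + 3 CHG + 9 CHH).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONTEXTS, PipelineConfig

_BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)  # everything else -> N(4)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

#: subcontext code -> trinucleotide, code = second_base * 4 + third_base
SUBCONTEXTS = ["C" + a + b for a in _BASES for b in _BASES]

CONTEXT_OF_SUB = [
    "CG" if a == "G" else ("CHG" if b == "G" else "CHH")
    for a in _BASES for b in _BASES
]


def seq_to_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def classify_codes(codes: np.ndarray):
    """Vectorized context classification of one chromosome.

    Returns ``(pos, strand_code, sub_code, n_ambiguous)`` with strand_code 0
    for '+', 1 for '-'; ``sub_code`` indexes :data:`SUBCONTEXTS`.  Cytosines
    within 2 bp of either chromosome end are excluded, as are those whose
    trinucleotide contains an ambiguous base (counted in ``n_ambiguous``).
    """
    n = len(codes)
    if n < 3:
        return (np.empty(0, np.int64), np.empty(0, np.int8),
                np.empty(0, np.int16), 0)
    # plus strand: C at i, trinucleotide codes[i:i+3]
    plus = np.flatnonzero(codes[: n - 2] == 1)
    b1p, b2p = codes[plus + 1], codes[plus + 2]
    okp = (b1p < 4) & (b2p < 4)
    n_amb = int((~okp).sum())
    plus, b1p, b2p = plus[okp], b1p[okp], b2p[okp]
    # minus strand: G at i (i >= 2), trinucleotide = revcomp(codes[i-2:i+1])
    minus = np.flatnonzero(codes[2:] == 2) + 2
    b1m, b2m = codes[minus - 1], codes[minus - 2]
    okm = (b1m < 4) & (b2m < 4)
    n_amb += int((~okm).sum())
    minus, b1m, b2m = minus[okm], 3 - b1m[okm], 3 - b2m[okm]

    pos = np.concatenate([plus, minus])
    strand = np.concatenate([np.zeros(len(plus), np.int8), np.ones(len(minus), np.int8)])
    sub = np.concatenate([b1p.astype(np.int16) * 4 + b2p,
                          b1m.astype(np.int16) * 4 + b2m])
    order = np.lexsort((strand, pos))
    return pos[order], strand[order], sub[order], n_amb


def classify_contexts(seq: str, chrom: str | None = None):
    """Per-cytosine (strand, context, subcontext) for a chromosome sequence.

    Returns ``(frame, n_ambiguous)`` where the frame has columns
    ``pos`` (0-based), ``strand`` ('+'/'-'), ``context``, ``subcontext``.
    """
    pos, strand, sub, n_amb = classify_codes(seq_to_codes(seq))
    ctx_of_sub = np.array([CONTEXTS.index(c) for c in CONTEXT_OF_SUB], dtype=np.int8)
    df = pd.DataFrame({
        "pos": pos,
        "strand": pd.Categorical.from_codes(strand, categories=["+", "-"]),
        "context": pd.Categorical.from_codes(ctx_of_sub[sub], categories=list(CONTEXTS)),
        "subcontext": pd.Categorical.from_codes(sub, categories=SUBCONTEXTS),
    })
    if chrom is not None:
        df.insert(0, "chrom", chrom)
    return df, n_amb


# ---------------------------------------------------------------------------
# site levels & conversion QC
# ---------------------------------------------------------------------------

def site_levels(table: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Drop under-covered sites and attach the methylation ratio.

    Sites with ``mc + uc < coverage_min`` are removed; the remaining rows get
    a ``level`` column equal to ``mc / (mc + uc)``.
    """
    cov = table["mc"] + table["uc"]
    out = table.loc[cov >= config.coverage_min].copy()
    total = (out["mc"] + out["uc"]).to_numpy()
    out["level"] = out["mc"].to_numpy() / total
    return out


@dataclass
class ConversionStats:
    lambda_methylated: int
    lambda_total: int

    @property
    def conversion_rate(self) -> float:
        return 1.0 - self.lambda_methylated / self.lambda_total


def conversion_rate(lambda_table: pd.DataFrame) -> ConversionStats:
    """Bisulfite conversion rate from an unmethylated lambda spike-in.

    Counts are pooled over all lambda cytosines (summed, not site-averaged).
    """
    mc = int(lambda_table["mc"].sum())
    total = mc + int(lambda_table["uc"].sum())
    if total == 0:
        raise ValueError("lambda spike-in has zero coverage")
    return ConversionStats(lambda_methylated=mc, lambda_total=total)


# ---------------------------------------------------------------------------
# global statistics
# ---------------------------------------------------------------------------

@dataclass
class GlobalMethylation:
    weighted_level: float
    mc_fraction: float
    n_sites: int


def weighted_level(df: pd.DataFrame) -> float:
    total = int(df["mc"].sum() + df["uc"].sum())
    return float("nan") if total == 0 else float(df["mc"].sum() / total)


def call_methylated(levels: pd.DataFrame, conversion: float, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of sites called methylated.

    A site is methylated when its methylated count exceeds what bisulfite
    non-conversion alone would produce: one-sided binomial test of ``mc`` out
    of ``mc+uc`` against the non-conversion rate ``1 - conversion``, BH FDR
    across sites at *alpha*.
    """
    from statsmodels.stats.multitest import multipletests

    mc = levels["mc"].to_numpy()
    total = mc + levels["uc"].to_numpy()
    p0 = max(1.0 - conversion, 1e-12)
    pvals = stats.binom.sf(mc - 1, total, p0)
    if len(pvals) == 0:
        return np.zeros(0, dtype=bool)
    rejected, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return rejected


def global_weighted_level(
    levels: pd.DataFrame,
    context: str | None = None,
    regions: pd.DataFrame | None = None,
    conversion: float = 1.0,
    config: PipelineConfig | None = None,
) -> GlobalMethylation:
    """Global (or regional) weighted level and methylated-site fraction.

    ``weighted_level``: sum(mc) / sum(mc+uc) over covered sites.
    ``mc_fraction``: fraction of covered sites called methylated (see
    :func:`call_methylated`).  *regions* is an optional BED-like frame used
    to restrict the site set.
    """
    config = config or PipelineConfig()
    df = levels
    if context is not None:
        df = df[df["context"] == context]
    if regions is not None:
        df = _restrict(df, regions)
    if len(df) == 0:
        return GlobalMethylation(float("nan"), float("nan"), 0)
    called = call_methylated(df, conversion, alpha=config.mc_call_alpha)
    return GlobalMethylation(
        weighted_level=weighted_level(df),
        mc_fraction=float(called.mean()),
        n_sites=int(len(df)),
    )


def _restrict(df: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    keep = np.zeros(len(df), dtype=bool)
    pos = df["pos"].to_numpy()
    for chrom, grp in regions.groupby("chrom", observed=True):
        in_chrom = (df["chrom"] == chrom).to_numpy()
        for s, e in zip(grp["start"], grp["end"]):
            keep |= in_chrom & (pos >= s) & (pos < e)
    return df[keep]


def site_level_histogram(levels: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Histogram of site-level ratios per context (masses sum to site count)."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for ctx in CONTEXTS:
        sub = levels.loc[levels["context"] == ctx, "level"].to_numpy()
        counts, _ = np.histogram(sub, bins=edges)  # level 1.0 falls in the last bin
        for i, c in enumerate(counts):
            rows.append({"context": ctx, "bin_low": edges[i], "bin_high": edges[i + 1],
                         "n_sites": int(c)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binned levels, replicate correlation, chromosome tracks
# ---------------------------------------------------------------------------

def binned_levels(
    levels: pd.DataFrame,
    chrom_lengths: dict,
    bin_size: int,
    context: str | None = None,
    site_mean: bool = False,
) -> pd.DataFrame:
    """Weighted methylation level per fixed genomic bin.

    Returns a frame indexed by (chrom, start) with ``mc``, ``total`` and
    ``level`` columns.  With ``site_mean`` the level is the unweighted mean
    of site ratios instead.
    """
    df = levels if context is None else levels[levels["context"] == context]
    if len(df) == 0:
        return pd.DataFrame(columns=["mc", "total", "level"])
    start = (df["pos"] // bin_size) * bin_size
    grouped = df.groupby([df["chrom"], start], observed=True)
    mc = grouped["mc"].sum()
    total = mc + grouped["uc"].sum()
    out = pd.DataFrame({"mc": mc, "total": total})
    if site_mean:
        ratio = df["mc"] / (df["mc"] + df["uc"])
        out["level"] = ratio.groupby([df["chrom"], start], observed=True).mean()
    else:
        out["level"] = out["mc"] / out["total"]
    out.index.names = ["chrom", "start"]
    return out


def replicate_correlation(
    levels_a: pd.DataFrame,
    levels_b: pd.DataFrame,
    chrom_lengths: dict,
    config: PipelineConfig | None = None,
) -> dict:
    """Pearson correlation of 5-kb-bin methylation levels between replicates.

    Bins lacking covered sites in either sample are dropped.  Returns
    ``{context: r, ..., "combined": r}``; NA when fewer than 3 shared bins.
    """
    config = config or PipelineConfig()
    out = {}
    for key in list(CONTEXTS) + ["combined"]:
        ctx = None if key == "combined" else key
        a = binned_levels(levels_a, chrom_lengths, config.bin_size_corr, ctx,
                          site_mean=config.site_mean_bins)
        b = binned_levels(levels_b, chrom_lengths, config.bin_size_corr, ctx,
                          site_mean=config.site_mean_bins)
        joined = a.join(b, how="inner", lsuffix="_a", rsuffix="_b").dropna()
        if len(joined) < 3 or joined["level_a"].std() == 0 or joined["level_b"].std() == 0:
            out[key] = float("nan")
        else:
            out[key] = float(stats.pearsonr(joined["level_a"], joined["level_b"])[0])
    return out


def chromosome_tracks(
    levels: pd.DataFrame,
    annotation,
    srna_tracks: dict | None = None,
    bin_size: int | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-bin genome tracks: repeat coverage, gene density, methylation
    level per context and per sub-context, and sRNA density per length class.

    Bins at chromosome ends may be short; they are kept and flagged
    (``short_bin``).
    """
    config = config or PipelineConfig()
    bin_size = bin_size or config.chrom_track_bin
    rows = []
    for chrom, length in annotation.chrom_lengths.items():
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "short_bin": end - start < bin_size})
    track = pd.DataFrame(rows)

    def frac_overlap(intervals: pd.DataFrame) -> np.ndarray:
        vals = np.zeros(len(track))
        for i, r in track.iterrows():
            sub = intervals[intervals["chrom"] == r["chrom"]]
            if len(sub):
                ov = np.minimum(sub["end"], r["end"]) - np.maximum(sub["start"], r["start"])
                vals[i] = np.clip(ov, 0, None).sum() / (r["end"] - r["start"])
        return vals

    track["repeat_fraction"] = frac_overlap(annotation.tes)
    genes_bed = pd.DataFrame(
        [{"chrom": g.chrom, "start": g.start, "end": g.end} for g in annotation.genes]
    ) if annotation.genes else pd.DataFrame(columns=["chrom", "start", "end"])
    track["gene_density"] = frac_overlap(genes_bed)

    key = pd.MultiIndex.from_arrays([track["chrom"], track["start"]])
    for ctx in CONTEXTS:
        b = binned_levels(levels, annotation.chrom_lengths, bin_size, ctx,
                          site_mean=config.site_mean_bins)
        track[f"level_{ctx}"] = b["level"].reindex(key).to_numpy()
    for sub_code, sub in enumerate(SUBCONTEXTS):
        df = levels[levels["subcontext"] == sub]
        if len(df) == 0:
            track[f"level_{sub}"] = np.nan
            continue
        b = binned_levels(df, annotation.chrom_lengths, bin_size,
                          site_mean=config.site_mean_bins)
        track[f"level_{sub}"] = b["level"].reindex(key).to_numpy()
    if srna_tracks:
        for name, bg in srna_tracks.items():
            start = (bg["start"] // bin_size) * bin_size
            dens = bg.groupby([bg["chrom"], start], observed=True)["value"].mean()
            track[f"srna_{name}"] = dens.reindex(key).to_numpy()
    return track


def track_methylation_correlation(
    srna_tracks: dict,
    levels: pd.DataFrame,
    chrom_lengths: dict,
    bin_size: int,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Pearson and Spearman correlation between sRNA density and methylation
    level, per sRNA length class and context.  NA for degenerate tracks."""
    config = config or PipelineConfig()
    rows = []
    for name, bg in srna_tracks.items():
        start = (bg["start"] // bin_size) * bin_size
        dens = bg.groupby([bg["chrom"], start], observed=True)["value"].mean()
        for ctx in CONTEXTS:
            b = binned_levels(levels, chrom_lengths, bin_size, ctx,
                              site_mean=config.site_mean_bins)
            joined = pd.DataFrame({"density": dens, "level": b["level"]}).dropna()
            row = {"srna": name, "context": ctx, "n_bins": len(joined)}
            if len(joined) < 3 or joined["density"].std() == 0 or joined["level"].std() == 0:
                row.update({"pearson_r": np.nan, "pearson_p": np.nan,
                            "spearman_r": np.nan, "spearman_p": np.nan})
            else:
                pr = stats.pearsonr(joined["density"], joined["level"])
                sr = stats.spearmanr(joined["density"], joined["level"])
                row.update({"pearson_r": float(pr[0]), "pearson_p": float(pr[1]),
                            "spearman_r": float(sr[0]), "spearman_p": float(sr[1])})
            rows.append(row)
    return pd.DataFrame(rows)
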