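"""Positional aggregation of methylation over genomic features.

Bodies are proportionally divided into ``n_body_bins`` bins; flanks are a
fixed 2 kb split into fixed-width bins (standard metaplot practice).
Orientation follows the feature strand, so upstream is always the 5' side.
Pooling across features is read-count-weighted: each bin reports
``sum(mc) / sum(mc + uc)`` over every covered cytosine that falls into it,
for every feature of the set (``site_mean_bins`` switches to an unweighted
mean of site ratios).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CONTEXTS, PipelineConfig
from .io import GenomeAnnotation

__all__ = [
    "SiteArrays", "gene_te_profile", "exon_only_profile",
    "intron_length_profiles", "region_methylation",
]


class SiteArrays:
    """Per-chromosome sorted arrays of covered sites, for fast region slicing."""

    def __init__(self, levels: pd.DataFrame):
        self.chroms = {}
        ctx_codes = pd.Categorical(levels["context"], categories=list(CONTEXTS)).codes
        for chrom, idx in levels.groupby("chrom", observed=True).indices.items():
            pos = levels["pos"].to_numpy()[idx]
            order = np.argsort(pos, kind="mergesort")
            sl = idx[order]
            mc = levels["mc"].to_numpy()[sl].astype(np.float64)
            tot = mc + levels["uc"].to_numpy()[sl]
            self.chroms[str(chrom)] = (
                pos[order], mc, tot, ctx_codes[sl].astype(np.int8),
            )

    def slice(self, chrom: str, start: int, end: int):
        entry = self.chroms.get(chrom)
        if entry is None:
            z = np.empty(0)
            return z.astype(np.int64), z, z, z.astype(np.int8)
        pos, mc, tot, ctx = entry
        i, j = np.searchsorted(pos, [start, end])
        return pos[i:j], mc[i:j], tot[i:j], ctx[i:j]


class _Accumulator:
    """(context, bin) -> pooled mc / total, with optional site-ratio mode."""

    def __init__(self, n_bins: int, site_mean: bool = False):
        self.mc = np.zeros((len(CONTEXTS), n_bins))
        self.tot = np.zeros((len(CONTEXTS), n_bins))
        self.ratio_sum = np.zeros((len(CONTEXTS), n_bins))
        self.n_sites = np.zeros((len(CONTEXTS), n_bins), dtype=np.int64)
        self.site_mean = site_mean

    def add(self, ctx, bins, mc, tot):
        np.add.at(self.mc, (ctx, bins), mc)
        np.add.at(self.tot, (ctx, bins), tot)
        np.add.at(self.ratio_sum, (ctx, bins), mc / tot)
        np.add.at(self.n_sites, (ctx, bins), 1)

    def frame(self, bin_labels) -> pd.DataFrame:
        rows = []
        for ci, ctx in enumerate(CONTEXTS):
            for bi, label in enumerate(bin_labels):
                tot = self.tot[ci, bi]
                if self.site_mean:
                    level = (self.ratio_sum[ci, bi] / self.n_sites[ci, bi]
                             if self.n_sites[ci, bi] else np.nan)
                else:
                    level = self.mc[ci, bi] / tot if tot > 0 else np.nan
                rows.append({
                    "context": ctx, **label,
                    "mc": self.mc[ci, bi], "total": tot,
                    "n_sites": int(self.n_sites[ci, bi]), "level": level,
                })
        return pd.DataFrame(rows)


def _body_bins(pos, start, end, n_bins, minus):
    rel = pos - start
    bins = (rel * n_bins) // (end - start)
    bins = np.clip(bins, 0, n_bins - 1).astype(np.int64)
    return (n_bins - 1) - bins if minus else bins


def _add_feature(acc_body, acc_up, acc_down, arrays, chrom, start, end, strand, cfg):
    minus = strand == "-"
    nb, nf = cfg.n_body_bins, cfg.n_flank_bins
    fw = cfg.flank_bp // nf
    pos, mc, tot, ctx = arrays.slice(chrom, start, end)
    if len(pos):
        acc_body.add(ctx, _body_bins(pos, start, end, nb, minus), mc, tot)
    # genomic-left flank
    pos, mc, tot, ctx = arrays.slice(chrom, start - cfg.flank_bp, start)
    if len(pos):
        bins = (pos - (start - cfg.flank_bp)) // fw
        bins = np.clip(bins, 0, nf - 1)
        if minus:  # this is the downstream side of a '-' feature
            acc_down.add(ctx, (nf - 1) - bins, mc, tot)
        else:
            acc_up.add(ctx, bins, mc, tot)
    # genomic-right flank
    pos, mc, tot, ctx = arrays.slice(chrom, end, end + cfg.flank_bp)
    if len(pos):
        bins = np.clip((pos - end) // fw, 0, nf - 1)
        if minus:
            acc_up.add(ctx, (nf - 1) - bins, mc, tot)
        else:
            acc_down.add(ctx, bins, mc, tot)


def gene_te_profile(
    levels: pd.DataFrame,
    annotation: GenomeAnnotation,
    feature: str = "gene",
    config: PipelineConfig | None = None,
    subset: list | None = None,
    group: str = "",
) -> pd.DataFrame:
    """Body + flank metaprofile pooled over genes or TEs.

    Returns a tidy frame with columns (group, context, section, bin, mc,
    total, n_sites, level); sections are ``up``/``body``/``down`` with bins
    1..20 each.  Features with a body shorter than ``n_body_bins`` bp are
    skipped (tallied in the frame's ``attrs["n_skipped"]``).
    """
    cfg = (config or PipelineConfig())
    arrays = levels if isinstance(levels, SiteArrays) else SiteArrays(levels)
    if feature == "gene":
        feats = [(g.chrom, g.start, g.end, g.strand) for g in annotation.genes
                 if subset is None or g.gene_id in subset]
    elif feature == "te":
        feats = [(r.chrom, int(r.start), int(r.end), r.strand)
                 for r in annotation.tes.itertuples()]
    else:
        raise ValueError("feature must be 'gene' or 'te'")
    acc_body = _Accumulator(cfg.n_body_bins, cfg.site_mean_bins)
    acc_up = _Accumulator(cfg.n_flank_bins, cfg.site_mean_bins)
    acc_down = _Accumulator(cfg.n_flank_bins, cfg.site_mean_bins)
    n_skipped = 0
    for chrom, start, end, strand in feats:
        if end - start < cfg.n_body_bins:
            n_skipped += 1
            continue
        _add_feature(acc_body, acc_up, acc_down, arrays, chrom, start, end, strand, cfg)
    parts = []
    for section, acc, nb in (("up", acc_up, cfg.n_flank_bins),
                             ("body", acc_body, cfg.n_body_bins),
                             ("down", acc_down, cfg.n_flank_bins)):
        labels = [{"section": section, "bin": b + 1} for b in range(nb)]
        parts.append(acc.frame(labels))
    out = pd.concat(parts, ignore_index=True)
    out.insert(0, "group", group or feature)
    out.attrs["n_skipped"] = n_skipped
    order = {"up": 0, "body": 1, "down": 2}
    out = out.sort_values(["context", "section", "bin"],
                          key=lambda s: s.map(order) if s.name == "section" else s)
    return out.reset_index(drop=True)


def exon_only_profile(
    levels: pd.DataFrame,
    annotation: GenomeAnnotation,
    config: PipelineConfig | None = None,
    intron_count_breaks: tuple | None = None,
) -> tuple:
    """Metaprofile over intron-less virtual transcripts, by intron count.

    Exons are concatenated in transcript order into a virtual body which is
    proportionally divided into ``n_body_bins`` bins.  Genes are grouped by
    their intron count (default breaks 0 / 1-2 / 3-5 / >=6).  Returns
    ``(profiles, skew)`` where skew per (group, context) is
    mean(last 5 bins) - mean(first 5 bins) — the 3'-skew statistic.
    """
    cfg = config or PipelineConfig()
    breaks = intron_count_breaks or cfg.intron_count_breaks
    arrays = levels if isinstance(levels, SiteArrays) else SiteArrays(levels)
    group_labels = _count_group_labels(breaks)
    accs = {lab: _Accumulator(cfg.n_body_bins, cfg.site_mean_bins) for lab in group_labels}
    nb = cfg.n_body_bins
    for g in annotation.genes:
        lab = _count_group(len(g.exons) - 1, breaks, group_labels)
        total_len = sum(e - s for s, e in g.exons)
        if total_len < nb:
            continue
        cum = 0
        for (s, e) in g.exons_transcript_order():
            pos, mc, tot, ctx = arrays.slice(g.chrom, s, e)
            if len(pos):
                off = (cum + (pos - s)) if g.strand == "+" else (cum + (e - 1 - pos))
                bins = np.clip((off * nb) // total_len, 0, nb - 1)
                accs[lab].add(ctx, bins, mc, tot)
            cum += e - s
    parts = []
    for lab in group_labels:
        frame = accs[lab].frame([{"section": "body", "bin": b + 1} for b in range(nb)])
        frame.insert(0, "group", lab)
        parts.append(frame)
    profiles = pd.concat(parts, ignore_index=True)
    skew_rows = []
    for (lab, ctx), grp in profiles.groupby(["group", "context"], observed=True, sort=False):
        grp = grp.sort_values("bin")
        head = grp["level"].to_numpy()[:5]
        tail = grp["level"].to_numpy()[-5:]
        skew = (np.nanmean(tail) - np.nanmean(head)
                if not (np.all(np.isnan(head)) or np.all(np.isnan(tail))) else np.nan)
        skew_rows.append({"group": lab, "context": ctx, "skew_3prime": skew})
    return profiles, pd.DataFrame(skew_rows)


def _count_group_labels(breaks: tuple) -> list:
    labels = [f"{breaks[0]}"]
    for lo, hi in zip(breaks, breaks[1:]):
        labels.append(f"{lo + 1}-{hi}" if lo + 1 < hi else f"{hi}")
    labels.append(f">={breaks[-1] + 1}")
    return labels


def _count_group(n: int, breaks: tuple, labels: list) -> str:
    if n <= breaks[0]:
        return labels[0]
    for i, hi in enumerate(breaks[1:], 1):
        if n <= hi:
            return labels[i]
    return labels[-1]


def intron_length_profiles(
    levels: pd.DataFrame,
    annotation: GenomeAnnotation,
    config: PipelineConfig | None = None,
    length_breaks: tuple | None = None,
    max_ordinal: int = 3,
) -> pd.DataFrame:
    """Intron + flanking-exon panels stratified by intron length.

    For each intron ordinal (first/second/third in transcript order) and
    each intron-length group (default <=1 kb / 1-5 kb / 5-20 kb / >20 kb),
    the 5' exon, the intron and the 3' exon are proportionally divided into
    5 / 10 / 5 bins.  Groups with no qualifying introns yield NA panels.
    """
    cfg = config or PipelineConfig()
    breaks = length_breaks or cfg.intron_length_breaks
    arrays = levels if isinstance(levels, SiteArrays) else SiteArrays(levels)
    length_labels = _length_group_labels(breaks)
    panels = {
        (lab, ordinal): {
            "exon5": _Accumulator(cfg.exon_bins, cfg.site_mean_bins),
            "intron": _Accumulator(cfg.intron_bins, cfg.site_mean_bins),
            "exon3": _Accumulator(cfg.exon_bins, cfg.site_mean_bins),
        }
        for lab in length_labels for ordinal in range(1, max_ordinal + 1)
    }
    for g in annotation.genes:
        exons_t = g.exons_transcript_order()
        introns_t = g.introns_transcript_order()
        minus = g.strand == "-"
        for ordinal in range(1, min(len(introns_t), max_ordinal) + 1):
            intron = introns_t[ordinal - 1]
            lab = _length_group(intron[1] - intron[0], breaks, length_labels)
            panel = panels[(lab, ordinal)]
            for part, (s, e), nb in (
                ("exon5", exons_t[ordinal - 1], cfg.exon_bins),
                ("intron", intron, cfg.intron_bins),
                ("exon3", exons_t[ordinal], cfg.exon_bins),
            ):
                pos, mc, tot, ctx = arrays.slice(g.chrom, s, e)
                if len(pos):
                    panel[part].add(ctx, _body_bins(pos, s, e, nb, minus), mc, tot)
    rows = []
    for (lab, ordinal), panel in panels.items():
        for part, nb in (("exon5", cfg.exon_bins), ("intron", cfg.intron_bins),
                         ("exon3", cfg.exon_bins)):
            frame = panel[part].frame([{"section": part, "bin": b + 1} for b in range(nb)])
            frame.insert(0, "intron_ordinal", ordinal)
            frame.insert(0, "length_group", lab)
            rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def _length_group_labels(breaks: tuple) -> list:
    labels = [f"<={breaks[0]}bp"]
    labels += [f"{lo}-{hi}bp" for lo, hi in zip(breaks, breaks[1:])]
    labels.append(f">{breaks[-1]}bp")
    return labels


def _length_group(length: int, breaks: tuple, labels: list) -> str:
    for i, hi in enumerate(breaks):
        if length <= hi:
            return labels[i]
    return labels[-1]


REGION_CLASSES = ["up500", "up1000", "up2000", "exon", "intron", "body",
                  "down500", "down1000", "down2000"]


def region_methylation(
    levels: pd.DataFrame,
    annotation: GenomeAnnotation,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-gene weighted methylation for the standard region classes.

    Regions: strand-aware upstream/downstream windows of 500/1000/2000 bp
    (clipped at chromosome bounds), exon union, intron union, and the whole
    body (exon + intron).  Level is NA when a region has no covered site;
    intron-less genes have an NA intron region and body == exon.
    """
    cfg = config or PipelineConfig()
    arrays = levels if isinstance(levels, SiteArrays) else SiteArrays(levels)
    rows = []
    for g in annotation.genes:
        chrom_len = annotation.chrom_lengths.get(g.chrom)
        regions = _gene_regions(g, chrom_len)
        for region, intervals in regions.items():
            mc = np.zeros(len(CONTEXTS))
            tot = np.zeros(len(CONTEXTS))
            ratio = np.zeros(len(CONTEXTS))
            ns = np.zeros(len(CONTEXTS), dtype=int)
            for (s, e) in intervals:
                pos, m, t, ctx = arrays.slice(g.chrom, s, e)
                np.add.at(mc, ctx, m)
                np.add.at(tot, ctx, t)
                if len(pos):
                    np.add.at(ratio, ctx, m / t)
                    np.add.at(ns, ctx, 1)
            for ci, ctx_name in enumerate(CONTEXTS):
                if cfg.site_mean_bins:
                    level = ratio[ci] / ns[ci] if ns[ci] else np.nan
                else:
                    level = mc[ci] / tot[ci] if tot[ci] > 0 else np.nan
                rows.append({"gene_id": g.gene_id, "region": region,
                             "context": ctx_name, "mc": mc[ci], "total": tot[ci],
                             "level": level})
    return pd.DataFrame(rows)


def _gene_regions(g, chrom_len: int | None) -> dict:
    def clip(s, e):
        s = max(0, s)
        if chrom_len is not None:
            e = min(e, chrom_len)
        return (s, e) if e > s else None

    regions = {}
    for d in (500, 1000, 2000):
        if g.strand == "+":
            up, down = clip(g.start - d, g.start), clip(g.end, g.end + d)
        else:
            up, down = clip(g.end, g.end + d), clip(g.start - d, g.start)
        regions[f"up{d}"] = [up] if up else []
        regions[f"down{d}"] = [down] if down else []
    regions["exon"] = list(g.exons)
    regions["intron"] = list(g.introns)
    regions["body"] = [(g.start, g.end)]
    return regions
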