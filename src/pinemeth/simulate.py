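"""Synthetic age-structured bisulfite methylome generator.

Every downstream stage of the pipeline is exercised against data from this
module, which plants known structure and returns the ground truth alongside:

* a random genome with gene models (occasionally very long introns) and TEs
  preferentially inserted into long introns and intergenic space;
* per-cytosine true methylation levels drawn per feature class, with a
  per-gene random effect on exons and flanks that couples methylation to
  expression;
* planted 1000-bp bins whose CG/CHG level changes linearly over the four
  ages (hyper or hypo), age-independent bins that differ between the two
  replicates of every age, and age-marker genes whose CHG level in a
  defined segment declines with age while their expression rises;
* overdispersed (gamma-Poisson) read coverage, binomial methylated counts
  with bisulfite non-conversion inflating the observed level, and a fully
  unmethylated lambda spike-in;
* a TPM table with log-expression decreasing in exon+downstream
  methylation, and sRNA density tracks.

All randomness flows from ``SimConfig.seed`` through named child streams,
so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CONTEXTS, FEATURE_CLASSES, ConfigError, SimConfig, to_yaml, from_yaml
from .core import CONTEXT_OF_SUB, SUBCONTEXTS, classify_codes
from . import io as pio

__all__ = [
    "GroundTruth", "SiteStates", "SimulatedDataset",
    "generate_genome", "simulate_methylation_states", "simulate_bs_counts",
    "simulate_expression", "simulate_srna_tracks", "simulate_dataset",
    "write_dataset", "load_dataset",
]

_STREAM = {"genome": 0, "states": 1, "counts": 2, "expression": 3,
           "srna": 4, "lambda": 5}

DMR_GRID = 1000  # planted bins land on the pipeline's fixed DMR grid

_KLASS = {name: i for i, name in enumerate(FEATURE_CLASSES)}


def _rng(config: SimConfig, stream: str, *extra) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAM[stream], *extra])


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    planted_dmr_bins: list = field(default_factory=list)
    replicate_variable_bins: list = field(default_factory=list)
    marker_segments: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "planted_dmr_bins": self.planted_dmr_bins,
            "replicate_variable_bins": self.replicate_variable_bins,
            "marker_segments": self.marker_segments,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**{k: d.get(k, []) for k in
                      ("planted_dmr_bins", "replicate_variable_bins", "marker_segments")})


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

_ASCII = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _ASCII[codes].tobytes().decode("ascii")


def _draw_gene_structure(rng, config: SimConfig, marker: bool):
    lo, hi = config.n_introns_range
    n_introns = int(rng.integers(lo, hi + 1))
    if marker:
        n_introns = max(n_introns, 1)
    exon_lo, exon_hi = config.exon_length_range
    exons = rng.integers(exon_lo, exon_hi + 1, size=n_introns + 1)
    introns = []
    for i in range(n_introns):
        u = rng.random()
        if u < config.intron_frac_gt_20kb:
            introns.append(int(rng.integers(20_001, 30_001)))
        elif u < config.intron_frac_gt_20kb + config.intron_frac_gt_5kb:
            introns.append(int(rng.integers(5_001, 20_001)))
        else:
            s_lo, s_hi = config.short_intron_length_range
            introns.append(int(rng.integers(s_lo, s_hi + 1)))
    if marker:
        introns[0] = max(introns[0], config.marker_first_intron_min)
    return [int(e) for e in exons], introns


def generate_genome(config: SimConfig):
    """Random genome sequence plus gene/TE annotation.

    Marker genes (the first ``n_marker_genes``) are forced onto the plus
    strand with a long first intron so their marker segment fits.  Raises
    :class:`ConfigError` when the requested genes cannot be placed.
    """
    config.validate()
    rng = _rng(config, "genome")
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {}
    for chrom in chrom_names:
        codes = rng.choice(4, size=config.chrom_length_bp, p=probs).astype(np.uint8)
        genome[chrom] = _codes_to_str(codes)
    chrom_lengths = {c: config.chrom_length_bp for c in chrom_names}

    # gene structures, then placement
    structures = []
    for gi in range(config.n_genes):
        exons, introns = _draw_gene_structure(rng, config, gi < config.n_marker_genes)
        structures.append((exons, introns))
    per_chrom = {c: [] for c in chrom_names}
    for gi, s in enumerate(structures):
        per_chrom[chrom_names[gi % len(chrom_names)]].append((gi, s))

    margin = 2000
    gap = config.min_intergenic_gap
    genes = [None] * config.n_genes
    for chrom, items in per_chrom.items():
        total = sum(sum(e) + sum(i) for _, (e, i) in items)
        n = len(items)
        budget = config.chrom_length_bp - 2 * margin - total - (n + 1) * gap
        if budget < 0:
            raise ConfigError(
                f"{chrom} too short for its {n} genes (need {-budget} more bp)")
        extra = (rng.dirichlet(np.ones(n + 1)) * budget).astype(int) if n else []
        cursor = margin
        for slot, (gi, (exons, introns)) in enumerate(items):
            cursor += gap + int(extra[slot])
            start = cursor
            ex_iv = []
            p = start
            for k, el in enumerate(exons):
                ex_iv.append((p, p + el))
                p += el
                if k < len(introns):
                    p += introns[k]
            strand = "+" if gi < config.n_marker_genes else ("+" if rng.random() < 0.5 else "-")
            genes[gi] = pio.GeneModel(
                gene_id=f"gene{gi + 1:04d}", chrom=chrom, strand=strand,
                start=start, end=p, exons=ex_iv,
            )
            cursor = p

    genes = [g for g in genes if g is not None]
    tes = _place_tes(rng, config, chrom_lengths, genes)
    annotation = pio.GenomeAnnotation(chrom_lengths=chrom_lengths, genes=genes, tes=tes)
    return genome, annotation


def _place_tes(rng, config: SimConfig, chrom_lengths: dict, genes: list) -> pd.DataFrame:
    total_bp = sum(chrom_lengths.values())
    target = config.te_fraction * total_bp
    if target <= 0:
        return pio._empty_bed()
    # hosts: intergenic space (outside gene flanks) and long introns
    hosts = []
    flank = 2000
    for chrom, length in chrom_lengths.items():
        spans = sorted((g.start - flank, g.end + flank) for g in genes if g.chrom == chrom)
        cursor = 0
        for s, e in spans:
            if s > cursor:
                hosts.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if cursor < length:
            hosts.append((chrom, cursor, length))
    for g in genes:
        for s, e in g.introns:
            if e - s >= config.te_min_host_intron:
                hosts.append((g.chrom, s + 100, e - 100))
    capacity = sum(e - s for _, s, e in hosts)
    if capacity <= 0 or target / capacity > 0.92:
        raise ConfigError("te_fraction too high for the available host space")
    lo, hi = config.te_length_range
    mean_len = (lo + hi) / 2
    # solve the fill ratio against the edge-corrected capacity: every host
    # loses roughly one gap+TE cycle at its end
    r = min(target / capacity, 0.9)
    for _ in range(8):
        cycle = mean_len / r
        eff = sum(max(0.0, e - s - cycle) for _, s, e in hosts)
        if eff <= 0:
            break
        r = min(target / eff, 0.9)
    mean_gap = mean_len * (1 - r) / r
    rows = []
    i = 0
    for chrom, s, e in hosts:
        cursor = s
        while True:
            cursor += rng.exponential(mean_gap)
            te_len = int(rng.integers(lo, hi + 1))
            if cursor + te_len > e:
                break
            start = int(cursor)
            rows.append({"chrom": chrom, "start": start, "end": start + te_len,
                         "name": f"TE{i + 1:05d}:LTR", "score": ".",
                         "strand": "+" if rng.random() < 0.5 else "-"})
            cursor = start + te_len
            i += 1
    if not rows:
        return pio._empty_bed()
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# methylation states
# ---------------------------------------------------------------------------

@dataclass
class SiteStates:
    """True methylation per cytosine per sample, plus bookkeeping."""

    sites: pd.DataFrame          # chrom, pos, strand, context, subcontext
    klass: np.ndarray            # feature class code per site
    p: np.ndarray                # (n_sites, n_samples) true levels
    p_base: np.ndarray           # sample-independent background
    samples: list
    sheet: pd.DataFrame
    gene_meth: pd.Series         # per-gene coupling methylation
    chrom_slices: dict           # chrom -> (start, stop) row range in `sites`


def make_sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = [
        {"sample_id": f"y{age}_r{rep}", "age_years": age, "replicate": rep}
        for age in config.ages
        for rep in range(1, config.replicates_per_age + 1)
    ]
    return pd.DataFrame(rows)


def simulate_methylation_states(genome: dict, annotation: pio.GenomeAnnotation,
                                config: SimConfig):
    """Assign every cytosine a true methylation level per sample.

    Background levels come from the feature class (TE > exon/intron >
    intergenic); the per-gene effect shifts exon and flank levels; planted
    age bins, replicate-variable bins and marker segments override per
    sample.  Returns ``(SiteStates, GroundTruth)``.
    """
    config.validate()
    rng = _rng(config, "states")
    sheet = make_sample_sheet(config)
    samples = sheet["sample_id"].tolist()
    ages = list(config.ages)
    age_index = {a: i for i, a in enumerate(ages)}

    frames, klass_parts, slices = [], [], {}
    offset = 0
    ctx_of_sub = np.array([CONTEXTS.index(c) for c in CONTEXT_OF_SUB], dtype=np.int8)
    for chrom, seq in genome.items():
        from .core import seq_to_codes
        codes = seq_to_codes(seq)
        pos, strand, sub, _ = classify_codes(codes)
        paint = np.zeros(len(codes), dtype=np.int8)
        for g in annotation.genes:
            if g.chrom == chrom:
                paint[g.start:g.end] = _KLASS["intron"]
                for s, e in g.exons:
                    paint[s:e] = _KLASS["exon"]
        for r in annotation.tes.itertuples():
            if r.chrom == chrom:
                paint[int(r.start):int(r.end)] = _KLASS["te"]
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "strand": pd.Categorical.from_codes(strand, categories=["+", "-"]),
            "context": pd.Categorical.from_codes(ctx_of_sub[sub], categories=list(CONTEXTS)),
            "subcontext": pd.Categorical.from_codes(sub, categories=SUBCONTEXTS),
        }))
        klass_parts.append(paint[pos])
        slices[chrom] = (offset, offset + len(pos))
        offset += len(pos)
    sites = pd.concat(frames, ignore_index=True)
    klass = np.concatenate(klass_parts) if klass_parts else np.empty(0, np.int8)
    ctx = sites["context"].cat.codes.to_numpy()
    pos_all = sites["pos"].to_numpy()

    base_matrix = np.array([[config.base_levels[c][k] for k in FEATURE_CLASSES]
                            for c in CONTEXTS])
    p_base = base_matrix[ctx, klass]

    # per-gene effect on exons and flanks: couples methylation to expression
    spread = np.array([config.gene_level_spread.get(c, 0.0) for c in CONTEXTS])
    gene_factor = rng.random(len(annotation.genes))
    gene_meth = {}
    for f, g in zip(gene_factor, annotation.genes):
        lo, hi = slices[g.chrom]
        cpos, cctx, ckl = pos_all[lo:hi], ctx[lo:hi], klass[lo:hi]
        sel_parts = []
        for s, e in g.exons:
            i, j = np.searchsorted(cpos, [s, e])
            sel_parts.append(np.arange(i, j))
        down_parts = []
        for s, e in ((g.start - 2000, g.start), (g.end, g.end + 2000)):
            i, j = np.searchsorted(cpos, [max(s, 0), e])
            idx = np.arange(i, j)
            idx = idx[ckl[idx] == _KLASS["intergenic"]]
            sel_parts.append(idx)
            is_down = (g.strand == "+" and s == g.end) or (g.strand == "-" and e == g.start)
            if is_down:
                down_parts.append(idx)
        sel = np.concatenate(sel_parts) if sel_parts else np.empty(0, int)
        p_base[lo + sel] += (f - 0.5) * spread[cctx[sel]]
        # coupling methylation: exon + downstream, CG/CHG only, true background
        exon_idx = np.concatenate(
            [np.arange(*np.searchsorted(cpos, [s, e])) for s, e in g.exons])
        couple = np.concatenate([exon_idx] + down_parts)
        couple = couple[cctx[couple] < 2]
        gene_meth[g.gene_id] = float(np.clip(p_base[lo + couple], 0, 1).mean()) \
            if len(couple) else np.nan
    p_base = np.clip(p_base, 0.0, 1.0)

    p = np.repeat(p_base[:, None], len(samples), axis=1)
    truth = GroundTruth()

    # candidate grid bins for planting, away from marker genes
    bin_ids = np.empty(len(sites), dtype=np.int64)
    chrom_index = {c: k for k, c in enumerate(genome)}
    marker_genes = annotation.genes[: config.n_marker_genes]
    excluded_bins = set()
    for g in marker_genes:
        lo_bp = g.start - config.marker_upstream_bp - DMR_GRID
        hi_bp = g.end + DMR_GRID
        for b in range(max(lo_bp, 0) // DMR_GRID, hi_bp // DMR_GRID + 1):
            excluded_bins.add((g.chrom, b * DMR_GRID))
    for chrom, (lo, hi) in slices.items():
        bin_ids[lo:hi] = chrom_index[chrom] * (2 ** 32) + pos_all[lo:hi] // DMR_GRID

    used = set()

    def pick_bins(context: str, n: int) -> list:
        ci = CONTEXTS.index(context)
        mask = ctx == ci
        ids, counts = np.unique(bin_ids[mask], return_counts=True)
        chroms = list(genome)
        cand = []
        for bid, cnt in zip(ids, counts):
            if cnt < 5:
                continue
            key = (chroms[int(bid >> 32)], int(bid & (2 ** 32 - 1)) * DMR_GRID)
            if key in excluded_bins or key in used:
                continue
            cand.append((bid, key))
        if len(cand) < n:
            raise ConfigError(f"not enough candidate {context} bins to plant {n}")
        chosen = rng.choice(len(cand), size=n, replace=False)
        out = [cand[i] for i in sorted(chosen)]
        for _, key in out:
            used.add(key)
        return out

    n_ages = len(ages)
    steps = np.arange(n_ages) / (n_ages - 1)
    for (context, direction), n in sorted(config.n_planted_age_dmrs.items()):
        if n == 0:
            continue
        levels = config.planted_baseline + config.planted_effect * steps
        if direction == "hypo":
            levels = levels[::-1]
        chosen = pick_bins(context, n)
        sel = np.isin(bin_ids, [bid for bid, _ in chosen]) & (ctx == CONTEXTS.index(context))
        for j, sid in enumerate(samples):
            a = age_index[int(sheet.loc[j, "age_years"])]
            p[sel, j] = levels[a]
        for _, (chrom, start) in chosen:
            truth.planted_dmr_bins.append({
                "chrom": chrom, "start": start, "context": context,
                "direction": direction, "levels": [float(v) for v in levels],
            })

    if config.n_replicate_variable_bins:
        context = config.replicate_variable_context
        chosen = pick_bins(context, config.n_replicate_variable_bins)
        sel = np.isin(bin_ids, [bid for bid, _ in chosen]) & (ctx == CONTEXTS.index(context))
        lo_level = config.replicate_variable_low
        hi_level = lo_level + config.replicate_variable_delta
        for j in range(len(samples)):
            p[sel, j] = lo_level if int(sheet.loc[j, "replicate"]) == 1 else hi_level
        for _, (chrom, start) in chosen:
            truth.replicate_variable_bins.append({
                "chrom": chrom, "start": start, "context": context,
                "delta": config.replicate_variable_delta,
            })

    for g in marker_genes:
        seg_start = max(g.start - config.marker_upstream_bp, 0)
        seg_end = g.start + config.marker_segment_bp
        lo, hi = slices[g.chrom]
        i, j = np.searchsorted(pos_all[lo:hi], [seg_start, seg_end])
        idx = np.arange(lo + i, lo + j)
        idx = idx[ctx[idx] == CONTEXTS.index("CHG")]
        for sj in range(len(samples)):
            a = age_index[int(sheet.loc[sj, "age_years"])]
            p[idx, sj] = config.marker_chg_levels[a]
        truth.marker_segments.append({
            "gene_id": g.gene_id, "chrom": g.chrom,
            "start": int(seg_start), "end": int(seg_end), "context": "CHG",
            "levels": [float(v) for v in config.marker_chg_levels],
            "tpm": [float(v) for v in config.marker_tpm],
        })

    states = SiteStates(
        sites=sites, klass=klass, p=np.clip(p, 0.0, 1.0).astype(np.float32),
        p_base=p_base, samples=samples, sheet=sheet,
        gene_meth=pd.Series(gene_meth, dtype=float), chrom_slices=slices,
    )
    return states, truth


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------

def _draw_coverage(rng, n: int, config: SimConfig) -> np.ndarray:
    if config.coverage_dispersion > 0:
        shape = 1.0 / config.coverage_dispersion
        lam = rng.gamma(shape, config.mean_coverage / shape, size=n)
        return rng.poisson(lam)
    return rng.poisson(config.mean_coverage, size=n)


def simulate_bs_counts(states: SiteStates, config: SimConfig):
    """Draw per-site read counts for every sample, plus the lambda spike-in.

    Coverage is gamma-Poisson with mean ``mean_coverage``; the methylated
    count is Binomial(coverage, p + (1-p) * conversion_failure_rate), so
    incomplete conversion inflates the observed level.  Lambda cytosines
    are fully unmethylated (p = 0).
    """
    tables = {}
    n = len(states.sites)
    for j, sample in enumerate(states.samples):
        rng = _rng(config, "counts", j)
        cov = _draw_coverage(rng, n, config)
        p_obs = states.p[:, j].astype(np.float64)
        p_obs = p_obs + (1.0 - p_obs) * config.conversion_failure_rate
        mc = rng.binomial(cov, p_obs)
        df = states.sites.copy()
        df["mc"] = mc
        df["uc"] = cov - mc
        tables[sample] = df[["chrom", "pos", "strand", "mc", "uc", "context", "subcontext"]]

    lam_rng = _rng(config, "lambda")
    lam_codes = lam_rng.choice(4, size=config.lambda_genome_bp,
                               p=[0.25, 0.25, 0.25, 0.25]).astype(np.uint8)
    pos, strand, sub, _ = classify_codes(lam_codes)
    ctx_of_sub = np.array([CONTEXTS.index(c) for c in CONTEXT_OF_SUB], dtype=np.int8)
    lam_base = pd.DataFrame({
        "chrom": "lambda", "pos": pos,
        "strand": pd.Categorical.from_codes(strand, categories=["+", "-"]),
        "context": pd.Categorical.from_codes(ctx_of_sub[sub], categories=list(CONTEXTS)),
        "subcontext": pd.Categorical.from_codes(sub, categories=SUBCONTEXTS),
    })
    lambda_tables = {}
    for j, sample in enumerate(states.samples):
        rng = _rng(config, "lambda", j)
        cov = _draw_coverage(rng, len(pos), config)
        mc = rng.binomial(cov, config.conversion_failure_rate)
        df = lam_base.copy()
        df["mc"] = mc
        df["uc"] = cov - mc
        lambda_tables[sample] = df[["chrom", "pos", "strand", "mc", "uc",
                                    "context", "subcontext"]]
    return tables, lambda_tables


# ---------------------------------------------------------------------------
# expression & sRNA
# ---------------------------------------------------------------------------

def simulate_expression(annotation: pio.GenomeAnnotation, states: SiteStates,
                        config: SimConfig) -> pd.DataFrame:
    """TPM table with log-expression decreasing in exon+downstream
    methylation; the lowest ``zero_tpm_fraction`` of genes fall below the
    detection floor (TPM = 0); marker genes carry the planted increasing
    per-age series."""
    rng = _rng(config, "expression")
    gene_ids = [g.gene_id for g in annotation.genes]
    n_genes = len(gene_ids)
    samples = states.samples
    if n_genes == 0:
        return pd.DataFrame(columns=samples)
    m = states.gene_meth.reindex(gene_ids).fillna(0.5).to_numpy()
    log_gene = (config.expression_intercept - config.expression_slope * m
                + rng.normal(0, config.expression_gene_noise_sd, n_genes))
    log_tpm = log_gene[:, None] + rng.normal(
        0, config.expression_sample_noise_sd, (n_genes, len(samples)))
    tpm = np.exp(log_tpm)
    if config.zero_tpm_fraction > 0:
        floor = np.quantile(tpm.mean(axis=1), config.zero_tpm_fraction)
        tpm[tpm.mean(axis=1) <= floor, :] = 0.0
    table = pd.DataFrame(tpm, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    age_index = {a: i for i, a in enumerate(config.ages)}
    for g in annotation.genes[: config.n_marker_genes]:
        for _, row in states.sheet.iterrows():
            table.loc[g.gene_id, row["sample_id"]] = \
                config.marker_tpm[age_index[int(row["age_years"])]]
    return table


def simulate_srna_tracks(states: SiteStates, annotation: pio.GenomeAnnotation,
                         config: SimConfig) -> dict:
    """Binned sRNA density tracks per length class (21/22/24 nt).

    Densities are lognormal noise, optionally coupled to the bin's true CHH
    level via ``srna_coupling`` (0 = independent, the conifer-like default).
    """
    rng = _rng(config, "srna")
    pos = states.sites["pos"].to_numpy()
    ctx = states.sites["context"].cat.codes.to_numpy()
    out = {}
    for length in config.srna_lengths:
        rows = []
        for chrom, total in annotation.chrom_lengths.items():
            lo, hi = states.chrom_slices[chrom]
            chh = ctx[lo:hi] == CONTEXTS.index("CHH")
            cpos = pos[lo:hi][chh]
            cp = states.p_base[lo:hi][chh]
            for start in range(0, total, config.srna_bin_bp):
                end = min(start + config.srna_bin_bp, total)
                noise = float(np.exp(rng.normal(0, 0.5)))
                value = noise
                if config.srna_coupling != 0:
                    i, j = np.searchsorted(cpos, [start, end])
                    level = float(cp[i:j].mean()) if j > i else 0.0
                    value = noise + config.srna_coupling * level
                rows.append({"chrom": chrom, "start": start, "end": end, "value": value})
        out[f"{length}nt"] = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# dataset bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: dict
    annotation: pio.GenomeAnnotation
    states: SiteStates | None
    truth: GroundTruth
    tables: dict
    lambda_tables: dict
    tpm: pd.DataFrame
    sheet: pd.DataFrame
    srna: dict


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: genome, states, counts, expression, sRNA."""
    genome, annotation = generate_genome(config)
    states, truth = simulate_methylation_states(genome, annotation, config)
    tables, lambda_tables = simulate_bs_counts(states, config)
    tpm = simulate_expression(annotation, states, config)
    srna = simulate_srna_tracks(states, annotation, config)
    return SimulatedDataset(
        config=config, genome=genome, annotation=annotation, states=states,
        truth=truth, tables=tables, lambda_tables=lambda_tables, tpm=tpm,
        sheet=states.sheet, srna=srna,
    )


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Emit the dataset in standard on-disk formats (FASTA/GFF3/BED/TSV/JSON)."""
    outdir = Path(outdir)
    (outdir / "cx").mkdir(parents=True, exist_ok=True)
    (outdir / "lambda").mkdir(exist_ok=True)
    (outdir / "srna").mkdir(exist_ok=True)
    pio.write_fasta(ds.genome, outdir / "genome.fa")
    pio.write_gff3(ds.annotation, outdir / "genes.gff3")
    pio.write_bed(ds.annotation.tes, outdir / "tes.bed")
    pio.write_sample_sheet(ds.sheet, outdir / "samples.tsv")
    pio.write_tpm_table(ds.tpm, outdir / "tpm.tsv")
    pio.write_ground_truth(ds.truth, outdir / "ground_truth.json")
    to_yaml(ds.config, outdir / "sim_config.yaml")
    for sample, df in ds.tables.items():
        pio.write_cytosine_report(df, outdir / "cx" / f"{sample}.tsv")
    for sample, df in ds.lambda_tables.items():
        pio.write_cytosine_report(df, outdir / "lambda" / f"{sample}.tsv")
    for name, df in ds.srna.items():
        pio.write_bedgraph(df, outdir / "srna" / f"{name}.bedgraph")


def load_dataset(indir) -> SimulatedDataset:
    """Read a written dataset back (without the internal state matrix)."""
    indir = Path(indir)
    config = from_yaml(SimConfig, indir / "sim_config.yaml")
    genome = pio.read_fasta(indir / "genome.fa")
    annotation = pio.read_gff3(indir / "genes.gff3")
    annotation.tes = pio.read_bed(indir / "tes.bed")
    sheet = pio.read_sample_sheet(indir / "samples.tsv")
    tpm = pio.read_tpm_table(indir / "tpm.tsv", sheet=sheet)
    truth = GroundTruth.from_dict(pio.read_ground_truth(indir / "ground_truth.json"))
    tables = {s: pio.read_cytosine_report(indir / "cx" / f"{s}.tsv")
              for s in sheet["sample_id"]}
    lambda_tables = {s: pio.read_cytosine_report(indir / "lambda" / f"{s}.tsv")
                     for s in sheet["sample_id"]}
    srna = {p.stem: pio.read_bedgraph(p) for p in sorted((indir / "srna").glob("*.bedgraph"))}
    return SimulatedDataset(
        config=config, genome=genome, annotation=annotation, states=None,
        truth=truth, tables=tables, lambda_tables=lambda_tables, tpm=tpm,
        sheet=sheet, srna=srna,
    )
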