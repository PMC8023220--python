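"""Synthetic runs with known ground truth for every downstream classifier.

The generator emulates the study design — two inbred parents and their F1
hybrid, three assays (mRNA input, m6A IP, polysome), two biological
replicates — with negative-binomial counts, planted heterosis patterns per
layer, planted cis/trans allelic architectures, and replicate peak sets
with partial overlap. Truth labels are recorded before noise is applied.

Default proportions follow the study's reported layer structure: roughly
5.7% / 44.3% / 10.2% non-additive genes at the mRNA / m6A / TE layers with
their up:down splits, m6A peak segments dominated by the 3'UTR and the
stop-codon window, and cis/trans architecture fractions near the reported
mRNA-layer table. Effect sizes are set so that a planted pattern is
recoverable at the simulated depth (strong parental divergence for HP/LP
genes — the high/low-parent patterns are undefined when the parents do not
separate).
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import (
    ExpressionMatrix,
    GeneModel,
    PeakRecord,
    SampleMeta,
    write_allele_counts,
    write_counts,
    write_gene_models,
    write_parental_counts,
    write_peaks,
    write_sample_sheet,
)

GENOTYPES = ("P1", "P2", "F1")
PATTERN_ORDER = ("AHP", "HP", "LP", "BLP")
ARCHITECTURES = (
    "cis_only",
    "trans_only",
    "enhancing",
    "compensating",
    "fully_compensatory",
    "conserved",
)

# study-like defaults
DEFAULT_HETEROSIS_FRACTIONS = {
    # non-additive totals ~5.7% (mRNA), ~44.3% (m6A), ~10.2% (TE) with
    # the reported up:down splits
    "mrna": {"AHP": 0.013, "HP": 0.013, "LP": 0.015, "BLP": 0.016},
    "m6a": {"AHP": 0.14, "HP": 0.14, "LP": 0.08, "BLP": 0.083},
    "te": {"AHP": 0.036, "HP": 0.036, "LP": 0.015, "BLP": 0.015},
}
DEFAULT_CIS_TRANS_FRACTIONS = {
    "cis_only": 0.041,
    "trans_only": 0.037,
    "enhancing": 0.016,
    "compensating": 0.016,
    "fully_compensatory": 0.01,
}
DEFAULT_SEGMENT_FRACTIONS = {
    "utr3": 0.699,
    "stop": 0.211,
    "cds": 0.032,
    "start": 0.002,
    "utr5": 0.006,
    "intron": 0.05,
}


@dataclasses.dataclass
class SimulationDesign:
    """Parameters of one synthetic run.

    ``baseline_log_mean``/``baseline_log_sd`` parameterize the log-normal
    distribution of baseline expression (expected counts per replicate).
    ``heterosis_effect`` multiplies the higher-parent value for AHP genes
    (and divides the lower-parent value for BLP); ``parental_fold_strong``
    is the parental divergence planted under HP/LP genes,
    ``parental_fold`` the milder divergence planted elsewhere with
    probability ``parental_divergence_fraction``.
    """

    n_genes: int = 5000
    replicates: int = 2
    baseline_log_mean: float = 5.5  # median ~ 245 counts
    baseline_log_sd: float = 0.8
    dispersion_range: tuple[float, float] = (0.01, 0.1)
    library_size_range: tuple[float, float] = (0.85, 1.15)
    parental_divergence_fraction: float = 0.3
    parental_fold: float = 2.5
    parental_fold_strong: float = 8.0
    heterosis_effect: float = 3.0
    heterosis_fractions: dict = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_HETEROSIS_FRACTIONS.items()}
    )
    te_base_log_sd: float = 0.3
    m6a_gene_fraction: float = 0.6
    m6a_gain_fraction: float = 0.05
    m6a_level_log_mean: float = 1.4  # median fold enrichment ~ 4
    m6a_level_log_sd: float = 0.3
    m6a_parental_fold: float = 4.0
    m6a_effect: float = 2.0
    m6a_level_noise: float = 0.05
    segment_fractions: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_FRACTIONS)
    )
    peak_halfwidth: int = 75
    peak_jitter: int = 20
    false_peak_fraction: float = 0.1
    cis_trans_fractions: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CIS_TRANS_FRACTIONS)
    )
    cis_log2: float = 1.0
    allele_depth: dict = dataclasses.field(
        default_factory=lambda: {"mrna_input": 500, "m6a_ip": 100, "polysome": 150}
    )
    window_nt: int = 200
    rng_seed: int = 1

    def __post_init__(self) -> None:
        for layer, fr in self.heterosis_fractions.items():
            if sum(fr.values()) > 1:
                raise ValueError(f"heterosis fractions for {layer} sum to > 1")
        if sum(self.cis_trans_fractions.values()) > 1:
            raise ValueError("cis/trans fractions sum to > 1")
        tot = sum(self.segment_fractions.values())
        if not np.isclose(tot, 1.0, atol=1e-6):
            raise ValueError(f"segment fractions must sum to 1, got {tot}")
        if not 0 < self.m6a_gene_fraction <= 1:
            raise ValueError("m6a_gene_fraction must be in (0, 1]")


@dataclasses.dataclass
class SimulatedRun:
    design: SimulationDesign
    counts: ExpressionMatrix
    models: list[GeneModel]
    peaks: dict[tuple[str, int], list[PeakRecord]]  # (genotype, replicate)
    alleles: pd.DataFrame
    parental_snp_counts: pd.DataFrame
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _draw_patterns(rng: np.random.Generator, n: int, fractions: dict) -> np.ndarray:
    probs = [fractions.get(p, 0.0) for p in PATTERN_ORDER]
    probs.append(1.0 - sum(probs))
    return rng.choice(list(PATTERN_ORDER) + ["additive"], size=n, p=probs)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """NB counts with var = mean + disp * mean^2 (gamma-Poisson mixture)."""
    mean = np.maximum(mean, 1e-8)
    shape = 1.0 / np.maximum(disp, 1e-8)
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def _layer_values(
    rng: np.random.Generator,
    base: np.ndarray,
    patterns: np.ndarray,
    effect: float,
    fold: float,
    fold_strong: float,
    div_fraction: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-genotype expected values for one layer given planted patterns.

    Returns (p1, p2, f1, parent_divergent). HP/LP genes always receive the
    strong parental fold (the pattern is meaningless without parental
    separation); other genes diverge with probability ``div_fraction``.
    """
    n = base.size
    div = rng.random(n) < div_fraction
    strong = np.isin(patterns, ("HP", "LP"))
    div |= strong
    fold_arr = np.where(strong, fold_strong, fold)
    direction = rng.choice([-0.5, 0.5], size=n)  # which parent is higher
    logf = np.log(fold_arr) * div
    p1 = base * np.exp(logf * direction)
    p2 = base * np.exp(-logf * direction)
    hp = np.maximum(p1, p2)
    lp = np.minimum(p1, p2)
    mpv = (p1 + p2) / 2.0
    f1 = mpv.copy()
    f1[patterns == "AHP"] = hp[patterns == "AHP"] * effect
    f1[patterns == "HP"] = hp[patterns == "HP"]
    f1[patterns == "LP"] = lp[patterns == "LP"]
    f1[patterns == "BLP"] = lp[patterns == "BLP"] / effect
    return p1, p2, f1, div


def _make_models(rng: np.random.Generator, gene_ids: Sequence[str]) -> list[GeneModel]:
    """Three-exon gene models with UTR/CDS geometry wide enough for every
    peak segment class."""
    models = []
    offsets: dict[str, int] = {}
    for i, gid in enumerate(gene_ids):
        chrom = f"chr{(i % 10) + 1}"
        utr5 = int(rng.integers(150, 400))
        cds = int(rng.integers(300, 600)) * 3
        utr3 = int(rng.integers(400, 900))
        mature = utr5 + cds + utr3
        # split mature length into 3 exons with 2 introns
        b1 = int(rng.integers(mature // 5, 2 * mature // 5))
        b2 = int(rng.integers(3 * mature // 5, 4 * mature // 5))
        i1 = int(rng.integers(300, 1000))
        i2 = int(rng.integers(300, 1000))
        start = offsets.get(chrom, 1000)
        exons = [
            (start, start + b1),
            (start + b1 + i1, start + b2 + i1),
            (start + b2 + i1 + i2, start + mature + i1 + i2),
        ]
        offsets[chrom] = exons[-1][1] + 2000
        strand = "+" if rng.random() < 0.5 else "-"
        # CDS occupies transcript interval [utr5, utr5+cds) on the 5'->3' axis
        m = GeneModel(gid, chrom, strand, exons, exons[0][0], exons[0][0] + 1)
        # placeholder CDS replaced below via transcript geometry
        t_lo, t_hi = utr5, utr5 + cds - 1
        g_lo = m.from_transcript(t_lo)
        g_hi = m.from_transcript(t_hi)
        cds_start, cds_end = min(g_lo, g_hi), max(g_lo, g_hi) + 1
        models.append(GeneModel(gid, chrom, strand, exons, cds_start, cds_end))
    return models


def _segment_tpos(
    rng: np.random.Generator, model: GeneModel, segment: str, half: int
) -> int | None:
    """Draw a transcript (or intronic genomic) summit position inside the
    requested segment; returns None-marked genomic draw for introns."""
    start_c, stop_c = model.transcript_landmarks()
    L = model.mature_length
    if segment == "start":
        lo, hi = max(0, start_c - half), min(L - 1, start_c + half)
    elif segment == "stop":
        lo, hi = max(0, stop_c - half), min(L - 1, stop_c + half)
    elif segment == "utr5":
        lo, hi = 0, start_c - half - 1
    elif segment == "cds":
        lo, hi = start_c + half + 1, stop_c - half - 1
    elif segment == "utr3":
        lo, hi = stop_c + half + 1, L - 1
    else:
        return None
    if hi < lo:
        return None
    return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate_run(design: SimulationDesign) -> SimulatedRun:
    """Generate one complete synthetic run (deterministic given the seed)."""
    d = design
    rng = np.random.default_rng(d.rng_seed)
    gene_ids = [f"G{i:05d}" for i in range(d.n_genes)]
    models = _make_models(rng, gene_ids)
    by_id = {m.gene_id: m for m in models}

    base = np.exp(rng.normal(d.baseline_log_mean, d.baseline_log_sd, d.n_genes))
    disp = rng.uniform(*d.dispersion_range, d.n_genes)

    # --- layer means -------------------------------------------------------
    pat_mrna = _draw_patterns(rng, d.n_genes, d.heterosis_fractions["mrna"])
    mrna_p1, mrna_p2, mrna_f1, mrna_div = _layer_values(
        rng, base, pat_mrna, d.heterosis_effect, d.parental_fold,
        d.parental_fold_strong, d.parental_divergence_fraction,
    )
    pat_te = _draw_patterns(rng, d.n_genes, d.heterosis_fractions["te"])
    te_base = np.exp(rng.normal(0.0, d.te_base_log_sd, d.n_genes))
    te_p1, te_p2, te_f1, te_div = _layer_values(
        rng, te_base, pat_te, d.heterosis_effect, d.parental_fold,
        d.parental_fold_strong, d.parental_divergence_fraction,
    )
    mrna_mean = {"P1": mrna_p1, "P2": mrna_p2, "F1": mrna_f1}
    te_val = {"P1": te_p1, "P2": te_p2, "F1": te_f1}
    poly_mean = {g: mrna_mean[g] * te_val[g] for g in GENOTYPES}

    # --- m6A levels --------------------------------------------------------
    modified = rng.random(d.n_genes) < d.m6a_gene_fraction
    gain_only = modified & (rng.random(d.n_genes) < d.m6a_gain_fraction)
    pat_m6a_all = _draw_patterns(rng, d.n_genes, d.heterosis_fractions["m6a"])
    level_base = np.exp(rng.normal(d.m6a_level_log_mean, d.m6a_level_log_sd, d.n_genes)) + 1.0
    m6a_p1, m6a_p2, m6a_f1, m6a_div = _layer_values(
        rng, level_base, pat_m6a_all, d.m6a_effect, d.m6a_parental_fold,
        d.m6a_parental_fold, 0.3,
    )
    m6a_level = {"P1": m6a_p1.copy(), "P2": m6a_p2.copy(), "F1": m6a_f1.copy()}
    # gain-only genes: modified in the hybrid, absent from both parents
    for g in ("P1", "P2"):
        m6a_level[g][gain_only] = 0.0
        m6a_level[g][~modified] = 0.0
    m6a_level["F1"][~modified] = 0.0
    pat_m6a = np.where(modified, np.where(gain_only, "AHP", pat_m6a_all), "NA")

    # IP assay counts scale with input mean and modification level
    ip_mean = {
        g: mrna_mean[g] * np.where(m6a_level[g] > 0, m6a_level[g] / 4.0, 0.25)
        for g in GENOTYPES
    }

    # --- counts ------------------------------------------------------------
    samples: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    assay_means = {"mrna_input": mrna_mean, "m6a_ip": ip_mean, "polysome": poly_mean}
    for geno in GENOTYPES:
        for assay in ("mrna_input", "m6a_ip", "polysome"):
            for rep in range(1, d.replicates + 1):
                sid = f"{geno}_{assay}_rep{rep}"
                lib = rng.uniform(*d.library_size_range)
                samples.append(SampleMeta(sid, geno, assay, rep))
                columns[sid] = _nb_draw(rng, assay_means[assay][geno] * lib, disp)
    counts = ExpressionMatrix(
        pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id")), samples
    )

    # --- peaks -------------------------------------------------------------
    seg_names = list(d.segment_fractions)
    seg_probs = np.array([d.segment_fractions[s] for s in seg_names])
    half = d.window_nt // 2
    peaks: dict[tuple[str, int], list[PeakRecord]] = {}
    segment_truth = np.full(d.n_genes, "NA", dtype=object)
    for geno in GENOTYPES:
        for rep in (1, 2):
            peaks[(geno, rep)] = []
    for i, gid in enumerate(gene_ids):
        gm = by_id[gid]
        for geno in GENOTYPES:
            lvl = m6a_level[geno][i]
            if lvl <= 0:
                continue
            seg = rng.choice(seg_names, p=seg_probs)
            tpos = _segment_tpos(rng, gm, seg, half)
            if seg == "intron" or tpos is None:
                seg = "intron"
                intr = gm.introns()[int(rng.integers(0, len(gm.introns())))]
                summit = int(rng.integers(intr[0] + 5, intr[1] - 5))
            else:
                summit = gm.from_transcript(tpos)
            if geno == "F1":
                segment_truth[i] = seg
            for rep in (1, 2):
                j1 = int(rng.integers(-d.peak_jitter, d.peak_jitter + 1))
                j2 = int(rng.integers(-d.peak_jitter, d.peak_jitter + 1))
                start = max(0, summit - d.peak_halfwidth + j1)
                end = summit + d.peak_halfwidth + j2
                fe = lvl * float(np.exp(rng.normal(0.0, d.m6a_level_noise)))
                peaks[(geno, rep)].append(
                    PeakRecord(
                        chrom=gm.chrom,
                        start=start,
                        end=max(end, start + 10),
                        summit=min(max(summit, start), max(end, start + 10) - 1),
                        fold_enrichment=fe,
                        qvalue=float(10 ** -rng.uniform(3, 10)),
                        replicate=rep,
                        name=f"{gid}_{geno}_r{rep}",
                    )
                )
    # single-replicate false peaks exercise the consensus filter
    n_false = int(d.false_peak_fraction * d.n_genes)
    for geno in GENOTYPES:
        idx = rng.choice(d.n_genes, size=n_false, replace=False)
        for i in idx:
            gm = by_id[gene_ids[i]]
            summit = int(rng.integers(gm.start, gm.end))
            peaks[(geno, 1)].append(
                PeakRecord(
                    chrom=gm.chrom,
                    start=max(0, summit - d.peak_halfwidth),
                    end=summit + d.peak_halfwidth,
                    summit=summit,
                    fold_enrichment=float(np.exp(rng.normal(d.m6a_level_log_mean, 0.3))),
                    qvalue=float(10 ** -rng.uniform(2, 4)),
                    replicate=1,
                    name=f"{gene_ids[i]}_{geno}_false",
                )
            )
    for key in peaks:
        peaks[key].sort(key=lambda p: (p.chrom, p.start))

    # --- allele counts and parental SNP counts -----------------------------
    arch_names = list(ARCHITECTURES)
    probs = [d.cis_trans_fractions.get(a, 0.0) for a in arch_names[:-1]]
    probs.append(1.0 - sum(probs))
    arch = rng.choice(arch_names, size=d.n_genes, p=probs)
    sign = rng.choice([-1.0, 1.0], size=d.n_genes)
    delta = d.cis_log2 * sign
    A = np.select(
        [arch == "cis_only", arch == "trans_only", arch == "enhancing",
         arch == "compensating", arch == "fully_compensatory"],
        [delta, delta, 2 * delta, -delta, np.zeros_like(delta)],
        default=0.0,
    )
    B = np.select(
        [arch == "cis_only", arch == "trans_only", arch == "enhancing",
         arch == "compensating", arch == "fully_compensatory"],
        [delta, np.zeros_like(delta), delta, delta, delta],
        default=0.0,
    )
    allele_rows = []
    parental_rows = []
    for assay, depth in d.allele_depth.items():
        tot_f1 = rng.poisson(depth, d.n_genes)
        tot_par = rng.poisson(depth, d.n_genes)
        pB = 2.0 ** B / (1.0 + 2.0 ** B)
        pA = 2.0 ** A / (1.0 + 2.0 ** A)
        a1 = rng.binomial(tot_f1, pB)
        p1c = rng.binomial(tot_par, pA)
        for i, gid in enumerate(gene_ids):
            allele_rows.append((gid, assay, int(a1[i]), int(tot_f1[i] - a1[i])))
            parental_rows.append((gid, assay, int(p1c[i]), int(tot_par[i] - p1c[i])))
    alleles = (
        pd.DataFrame(allele_rows, columns=["gene_id", "assay", "a1_count", "a2_count"])
        .set_index(["gene_id", "assay"]).sort_index()
    )
    parental = (
        pd.DataFrame(parental_rows, columns=["gene_id", "assay", "p1_count", "p2_count"])
        .set_index(["gene_id", "assay"]).sort_index()
    )

    arch_category = np.select(
        [arch == "cis_only", arch == "trans_only", arch == "conserved"],
        ["cis_only", "trans_only", "conserved"],
        default="cis_and_trans",
    )
    truth = pd.DataFrame(
        {
            "pattern_mrna": pat_mrna,
            "pattern_te": pat_te,
            "pattern_m6a": pat_m6a,
            "mrna_parent_divergent": mrna_div,
            "te_parent_divergent": te_div,
            "m6a_modified_f1": m6a_level["F1"] > 0,
            "m6a_level_f1": m6a_level["F1"],
            "segment_f1": segment_truth,
            "te_ratio_f1": te_f1 / ((te_p1 + te_p2) / 2.0),
            "cis_trans_architecture": arch,
            "cis_trans_category": arch_category,
            "A_log2_true": A,
            "B_log2_true": B,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SimulatedRun(d, counts, models, peaks, alleles, parental, truth)


def write_fixture(run: SimulatedRun, outdir: str | Path) -> Path:
    """Write a run to disk in the pipeline's input dialects (plus truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(run.counts, outdir / "counts.tsv")
    write_sample_sheet(run.counts.samples, outdir / "samples.tsv")
    write_gene_models(run.models, outdir / "genes.gff3")
    for (geno, rep), plist in sorted(run.peaks.items()):
        write_peaks(plist, outdir / f"peaks_{geno}_rep{rep}.bed")
    write_allele_counts(run.alleles, outdir / "alleles.tsv")
    write_parental_counts(run.parental_snp_counts, outdir / "parental_snp_counts.tsv")
    run.truth.to_csv(outdir / "truth.tsv", sep="\t")
    RunConfig(rng_seed=run.design.rng_seed, window_nt=run.design.window_nt).to_yaml(
        outdir / "config.yaml"
    )
    return outdir
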