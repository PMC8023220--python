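"""Quantification: FPKM, translational efficiency, consensus m6A peaks,
per-gene m6A levels and peak-to-segment assignment.

FPKM is fragments per kilobase of mature transcript per million mapped
fragments, computed over the genes present in the matrix. Translational
efficiency (TE) for a genotype is the ratio of mean-replicate polysome FPKM
to mean-replicate input FPKM, defined only where the gene passes the
expression floor in the input assay.

High-confidence m6A peaks are those reproduced across the two biological
replicates: each replicate-1 peak is paired with the overlapping
replicate-2 peak of largest overlap (each peak used at most once), and the
consensus interval is the union of the pair. The per-gene m6A level is the
maximum consensus-peak level (mean of the two replicate fold enrichments)
over the gene's peaks.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import ExpressionMatrix, GeneModel, PeakRecord

SEGMENTS = ("utr5", "start", "cds", "stop", "utr3", "intron", "intergenic")


# ---------------------------------------------------------------------------
# FPKM / TE
# ---------------------------------------------------------------------------

def compute_fpkm(m: ExpressionMatrix, models: Mapping[str, GeneModel] | Sequence[GeneModel]) -> pd.DataFrame:
    """FPKM matrix: ``count * 1e9 / (library_size * mature_length)``.

    Library sizes are per-sample totals over the genes in the matrix.
    Raises if any gene lacks a model or any sample has zero total counts.
    """
    if not isinstance(models, Mapping):
        models = {g.gene_id: g for g in models}
    missing = [g for g in m.gene_ids if g not in models]
    if missing:
        raise ValueError(f"genes without a gene model: {missing[:5]}")
    lengths = np.array([models[g].mature_length for g in m.gene_ids], dtype=float)
    totals = m.counts.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        zero = m.counts.columns[totals == 0][0]
        raise ValueError(f"sample {zero!r} has zero total counts")
    fpkm = m.counts.to_numpy(dtype=float) * 1e9 / (totals[None, :] * lengths[:, None])
    return pd.DataFrame(fpkm, index=m.counts.index, columns=m.counts.columns)


def group_mean_fpkm(fpkm: pd.DataFrame, m: ExpressionMatrix) -> pd.DataFrame:
    """Mean replicate FPKM per (genotype, assay) group; columns are tuples."""
    cols = {}
    for (genotype, assay), metas in m.groups().items():
        cols[(genotype, assay)] = fpkm[[s.sample_id for s in metas]].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["genotype", "assay"])
    return out


def expressed_filter(fpkm: pd.DataFrame, m: ExpressionMatrix, threshold: float) -> dict[tuple[str, str], set[str]]:
    """Genes whose mean replicate FPKM reaches ``threshold`` per (genotype, assay)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    means = group_mean_fpkm(fpkm, m)
    out: dict[tuple[str, str], set[str]] = {}
    for key in means.columns:
        col = means[key]
        out[key] = set(col.index[col >= threshold])
    return out


def compute_te(
    fpkm: pd.DataFrame,
    m: ExpressionMatrix,
    expressed: Mapping[tuple[str, str], set[str]],
) -> pd.DataFrame:
    """Translational efficiency per gene and genotype.

    ``te = mean polysome FPKM / mean input FPKM``; NaN where the gene fails
    the expression floor in the input assay for that genotype.
    """
    means = group_mean_fpkm(fpkm, m)
    genotypes = sorted({g for g, _ in means.columns})
    out = {}
    for geno in genotypes:
        if (geno, "polysome") not in means.columns or (geno, "mrna_input") not in means.columns:
            raise ValueError(f"genotype {geno!r}: needs both polysome and mrna_input assays")
        poly = means[(geno, "polysome")]
        inp = means[(geno, "mrna_input")]
        ok = poly.index.isin(expressed.get((geno, "mrna_input"), set()))
        te = np.where(ok & (inp.to_numpy() > 0), poly.to_numpy() / np.where(inp > 0, inp, 1.0), np.nan)
        out[geno] = pd.Series(te, index=poly.index)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# consensus peaks
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConsensusPeak:
    """A replicate-reproducible m6A peak.

    Interval is the union of the two paired replicate peaks; the summit
    comes from the replicate with larger fold enrichment; ``m6a_level`` is
    the mean of the two replicate fold enrichments.
    """

    chrom: str
    start: int
    end: int
    summit: int
    m6a_level: float
    gene_id: str | None = None
    segment: str | None = None


def consensus_peaks(rep1: Sequence[PeakRecord], rep2: Sequence[PeakRecord]) -> list[ConsensusPeak]:
    """Pair overlapping peaks across two replicates and emit union intervals.

    Candidate pairs (>= 1 bp overlap) are matched greedily by decreasing
    overlap length so that each peak is used at most once; a peak with
    multiple partners keeps the one it overlaps most.
    """
    pairs: list[tuple[int, int, int]] = []  # (overlap, i, j)
    by_chrom2: dict[str, list[tuple[int, PeakRecord]]] = {}
    for j, p in enumerate(rep2):
        by_chrom2.setdefault(p.chrom, []).append((j, p))
    for i, p in enumerate(rep1):
        for j, q in by_chrom2.get(p.chrom, []):
            ov = min(p.end, q.end) - max(p.start, q.start)
            if ov >= 1:
                pairs.append((ov, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used1: set[int] = set()
    used2: set[int] = set()
    out: list[ConsensusPeak] = []
    for ov, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        p, q = rep1[i], rep2[j]
        top = p if p.fold_enrichment >= q.fold_enrichment else q
        out.append(
            ConsensusPeak(
                chrom=p.chrom,
                start=min(p.start, q.start),
                end=max(p.end, q.end),
                summit=top.summit,
                m6a_level=(p.fold_enrichment + q.fold_enrichment) / 2.0,
            )
        )
    out.sort(key=lambda c: (c.chrom, c.start))
    return out


# ---------------------------------------------------------------------------
# segment assignment
# ---------------------------------------------------------------------------

def assign_segment(summit_tpos: int | None, model: GeneModel, window_nt: int) -> str:
    """Classify a summit's transcript position into a gene segment.

    ``summit_tpos`` is the spliced-transcript offset of the peak summit (None
    when the summit is intronic). Priority: start-codon window, stop-codon
    window (both inclusive, half-width ``window_nt/2``), then 5'UTR / CDS /
    3'UTR by position, then intron.
    """
    if window_nt % 2 != 0:
        raise ValueError("window_nt must be even")
    if summit_tpos is None:
        return "intron"
    half = window_nt // 2
    start_c, stop_c = model.transcript_landmarks()
    if abs(summit_tpos - start_c) <= half:
        return "start"
    if abs(summit_tpos - stop_c) <= half:
        return "stop"
    if summit_tpos < start_c:
        return "utr5"
    if summit_tpos <= stop_c:
        return "cds"
    return "utr3"


def annotate_peaks(
    peaks: Iterable[ConsensusPeak],
    models: Sequence[GeneModel],
    window_nt: int,
) -> list[ConsensusPeak]:
    """Assign each consensus peak to a gene and segment (in place).

    A peak is assigned to the gene whose span contains its summit; with
    several candidates the one whose transcript contains the summit exonic
    position wins, ties broken by smallest gene span. Peaks outside every
    gene are ``intergenic``.
    """
    trees: dict[str, IntervalTree] = {}
    for gm in models:
        trees.setdefault(gm.chrom, IntervalTree()).addi(gm.start, gm.end, gm)
    peaks = list(peaks)
    for p in peaks:
        tree = trees.get(p.chrom)
        hits = sorted(tree[p.summit], key=lambda iv: iv.end - iv.begin) if tree else []
        if not hits:
            p.gene_id, p.segment = None, "intergenic"
            continue
        chosen = None
        for iv in hits:
            if iv.data.to_transcript(p.summit) is not None:
                chosen = iv.data
                break
        if chosen is None:
            chosen = hits[0].data
        p.gene_id = chosen.gene_id
        p.segment = assign_segment(chosen.to_transcript(p.summit), chosen, window_nt)
    return peaks


def gene_m6a_level(peaks: Iterable[ConsensusPeak]) -> pd.Series:
    """Per-gene m6A level: the maximum consensus-peak level over its peaks.

    Genes without any consensus peak are absent (unmodified).
    """
    levels: dict[str, float] = {}
    for p in peaks:
        if p.gene_id is None:
            continue
        levels[p.gene_id] = max(levels.get(p.gene_id, 0.0), p.m6a_level)
    return pd.Series(levels, dtype=float).sort_index()


def segment_distribution(peaks: Sequence[ConsensusPeak]) -> dict[str, float]:
    """Fraction of gene-assigned peaks per segment (sums to 1)."""
    assigned = [p for p in peaks if p.segment is not None and p.segment != "intergenic"]
    if not assigned:
        raise ValueError("no gene-assigned peaks")
    counts: dict[str, int] = {}
    for p in assigned:
        counts[p.segment] = counts.get(p.segment, 0) + 1
    n = len(assigned)
    return {seg: counts.get(seg, 0) / n for seg in SEGMENTS if seg != "intergenic"}


def write_consensus_peaks(peaks: Iterable[ConsensusPeak], path) -> None:
    rows = [
        {
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "summit": p.summit,
            "m6a_level": p.m6a_level,
            "gene_id": p.gene_id if p.gene_id else "NA",
            "segment": p.segment,
        }
        for p in peaks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
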