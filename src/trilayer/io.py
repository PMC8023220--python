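"""Shared data model and readers/writers for all external formats.

Conventions
-----------
* Internal genomic coordinates are 0-based half-open (BED convention).
  GFF3 (1-based inclusive) is converted at the boundary.
* Count tables are TSV: first column ``gene_id``, remaining columns sample
  ids. The sample sheet is TSV with columns ``sample_id``, ``genotype``,
  ``assay``, ``replicate``.
* Peak tables are 7-column BED-like TSV:
  ``chrom  start  end  name  fold_enrichment  summit_offset  qvalue``.
* Allele count tables are TSV: ``gene_id  assay  a1_count  a2_count``
  (a1 = reads of P1 origin, a2 = P2 origin).

All readers reject malformed input with an error naming the offending
record; nothing is silently coerced.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger("trilayer")

GENOTYPES = ("P1", "P2", "F1")
ASSAYS = ("mrna_input", "m6a_ip", "polysome")

PEAK_COLUMNS = ["chrom", "start", "end", "name", "fold_enrichment", "summit_offset", "qvalue"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# sample metadata and count matrices
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequencing library: genotype x assay x replicate."""

    sample_id: str
    genotype: str
    assay: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise FormatError(
                f"sample {self.sample_id!r}: genotype must be one of {GENOTYPES}, "
                f"got {self.genotype!r}"
            )
        if self.assay not in ASSAYS:
            raise FormatError(
                f"sample {self.sample_id!r}: assay must be one of {ASSAYS}, got {self.assay!r}"
            )
        if self.replicate < 1:
            raise FormatError(f"sample {self.sample_id!r}: replicate must be >= 1")


class ExpressionMatrix:
    """Gene x sample integer counts with aligned sample metadata.

    The substrate for all quantification and differential testing. Gene
    order is preserved from the input file; gene ids must be unique.
    """

    def __init__(self, counts: pd.DataFrame, samples: Sequence[SampleMeta]):
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene_ids: {dups[:5]}")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample_ids in sample metadata")
        if list(counts.columns) != ids:
            raise FormatError("count matrix columns do not match sample metadata order")
        arr = counts.to_numpy()
        if not np.isfinite(arr).all():
            raise FormatError("counts contain non-finite values")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count for gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
            )
        self.counts = counts.astype(np.int64)
        self.samples = list(samples)

    # -- basic accessors ----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def select(self, genotype: str | None = None, assay: str | None = None) -> "ExpressionMatrix":
        """Sub-matrix restricted to one genotype and/or assay (replicates kept)."""
        keep = [
            s for s in self.samples
            if (genotype is None or s.genotype == genotype)
            and (assay is None or s.assay == assay)
        ]
        if not keep:
            raise KeyError(f"no samples with genotype={genotype!r} assay={assay!r}")
        keep.sort(key=lambda s: s.replicate)
        return ExpressionMatrix(self.counts[[s.sample_id for s in keep]], keep)

    def groups(self) -> dict[tuple[str, str], list[SampleMeta]]:
        out: dict[tuple[str, str], list[SampleMeta]] = {}
        for s in self.samples:
            out.setdefault((s.genotype, s.assay), []).append(s)
        return out


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read the TSV sample sheet (sample_id, genotype, assay, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genotype", "assay", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet {path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        try:
            rep = int(row["replicate"])
        except ValueError as exc:
            raise FormatError(
                f"sample sheet {path}: non-integer replicate for sample {row['sample_id']!r}"
            ) from exc
        out.append(SampleMeta(row["sample_id"], row["genotype"], row["assay"], rep))
    return out


def read_counts(path: str | Path, meta: Sequence[SampleMeta]) -> ExpressionMatrix:
    """Read a gene x sample count TSV and align it with the sample sheet.

    Every column in the table must appear in the sheet; cells must be
    non-negative integers. Row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    by_id = {s.sample_id: s for s in meta}
    unknown = [c for c in df.columns if c not in by_id]
    if unknown:
        raise FormatError(f"count table {path}: samples not in sample sheet: {unknown}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 0)
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"count table {path}: non-integer or negative value for gene "
                f"{gene!r}, sample {col!r}"
            )
    return ExpressionMatrix(df, [by_id[c] for c in df.columns])


def write_counts(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_sample_sheet(samples: Iterable[SampleMeta], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in samples]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GeneModel:
    """One representative transcript geometry per gene.

    Coordinates are genomic, 0-based half-open. ``exons`` are sorted and
    non-overlapping; ``cds_start``/``cds_end`` are the genomic extremes of
    the coding region and fall inside exons. ``utr5``/``utr3`` are derived
    exonic interval lists on the 5'/3' side of the CDS with respect to
    ``strand``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    utr5: list[tuple[int, int]] = dataclasses.field(init=False)
    utr3: list[tuple[int, int]] = dataclasses.field(init=False)
    mature_length: int = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        exons = sorted(self.exons)
        for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
            if a2 < b1:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")
        if any(b <= a for a, b in exons):
            raise FormatError(f"gene {self.gene_id}: empty exon interval")
        self.exons = exons
        self.mature_length = sum(b - a for a, b in exons)
        if self.mature_length <= 0:
            raise FormatError(f"gene {self.gene_id}: zero mature length")
        if not (self._contains(self.cds_start) and self._contains(self.cds_end - 1)):
            raise FormatError(f"gene {self.gene_id}: CDS outside exons")
        # upstream/downstream exonic pieces; orientation decides which is 5'
        left = _clip(exons, None, self.cds_start)
        right = _clip(exons, self.cds_end, None)
        self.utr5, self.utr3 = (left, right) if self.strand == "+" else (right, left)

    def _contains(self, pos: int) -> bool:
        return any(a <= pos < b for a, b in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    # -- spliced-transcript coordinates ------------------------------------
    def to_transcript(self, gpos: int) -> int | None:
        """Map a genomic position to spliced 5'->3' transcript offset, or None
        if the position is intronic/outside."""
        off = 0
        for a, b in self.exons:
            if a <= gpos < b:
                plus = off + (gpos - a)
                if self.strand == "+":
                    return plus
                return self.mature_length - 1 - plus
            off += b - a
        return None

    def from_transcript(self, tpos: int) -> int:
        """Inverse of :meth:`to_transcript`: spliced offset -> genomic position."""
        if not 0 <= tpos < self.mature_length:
            raise ValueError(f"transcript position {tpos} outside [0, {self.mature_length})")
        plus = tpos if self.strand == "+" else self.mature_length - 1 - tpos
        off = 0
        for a, b in self.exons:
            if plus < off + (b - a):
                return a + (plus - off)
            off += b - a
        raise AssertionError("unreachable")

    def introns(self) -> list[tuple[int, int]]:
        return [(b1, a2) for (_, b1), (a2, _) in zip(self.exons, self.exons[1:])]

    def transcript_landmarks(self) -> tuple[int, int]:
        """(start_codon, stop_codon) positions in transcript coordinates.

        The start codon is the CDS base closest to the 5' end; the stop codon
        the CDS base closest to the 3' end.
        """
        if self.strand == "+":
            start = self.to_transcript(self.cds_start)
            stop = self.to_transcript(self.cds_end - 1)
        else:
            start = self.to_transcript(self.cds_end - 1)
            stop = self.to_transcript(self.cds_start)
        assert start is not None and stop is not None
        return start, stop


def _clip(exons: list[tuple[int, int]], lo: int | None, hi: int | None) -> list[tuple[int, int]]:
    out = []
    for a, b in exons:
        a2 = a if lo is None else max(a, lo)
        b2 = b if hi is None else min(b, hi)
        if b2 > a2:
            out.append((a2, b2))
    return out


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 into one :class:`GeneModel` per gene (longest mRNA).

    Genes without a CDS, or whose CDS falls outside the exons, are skipped
    with a logged warning.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            logger.warning("gene %s: no mRNA feature, skipped", gene.id)
            continue
        best, best_len = None, -1
        for t in mrnas:
            exons = [(e.start - 1, e.end) for e in db.children(t, featuretype="exon")]
            length = sum(b - a for a, b in exons)
            if length > best_len:
                best, best_len, best_exons = t, length, exons
        cds = [(c.start - 1, c.end) for c in db.children(best, featuretype="CDS")]
        if not cds:
            logger.warning("gene %s: no CDS feature, skipped", gene.id)
            continue
        cds_start = min(a for a, _ in cds)
        cds_end = max(b for _, b in cds)
        try:
            models.append(
                GeneModel(
                    gene_id=gene.id,
                    chrom=gene.seqid,
                    strand=gene.strand,
                    exons=sorted(best_exons),
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
        except FormatError as exc:
            logger.warning("gene %s skipped: %s", gene.id, exc)
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write models back to GFF3 (1-based inclusive), one mRNA per gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            g0, g1 = m.start, m.end
            fh.write(
                f"{m.chrom}\ttrilayer\tgene\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            tid = f"{m.gene_id}_T001"
            fh.write(
                f"{m.chrom}\ttrilayer\tmRNA\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\t"
                f"ID={tid};Parent={m.gene_id}\n"
            )
            for i, (a, b) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\ttrilayer\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
            for a, b in _clip(m.exons, m.cds_start, m.cds_end):
                fh.write(
                    f"{m.chrom}\ttrilayer\tCDS\t{a + 1}\t{b}\t.\t{m.strand}\t0\t"
                    f"ID={tid}.cds;Parent={tid}\n"
                )


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PeakRecord:
    """One called m6A interval from a single replicate.

    ``fold_enrichment`` is the peak caller's IP/input fold change — the
    working definition of the m6A level. ``summit`` is genomic (0-based).
    """

    chrom: str
    start: int
    end: int
    summit: int
    fold_enrichment: float
    qvalue: float
    replicate: int
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(f"peak {self.name or self.chrom}: start >= end")
        if not self.start <= self.summit < self.end:
            raise FormatError(
                f"peak {self.name or self.chrom}:{self.start}-{self.end}: "
                f"summit {self.summit} outside [start, end)"
            )
        if self.fold_enrichment <= 0:
            raise FormatError(f"peak {self.name!r}: fold_enrichment must be > 0")


def read_peaks(path: str | Path, replicate: int = 1) -> list[PeakRecord]:
    """Read a 7-column BED-like peak table into validated records.

    ``summit = start + summit_offset``. Malformed rows raise with the line
    number; an empty file yields an empty list.
    """
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                chrom, start, end, name, fe, off, q = parts
                peaks.append(
                    PeakRecord(
                        chrom=chrom,
                        start=int(start),
                        end=int(end),
                        summit=int(start) + int(off),
                        fold_enrichment=float(fe),
                        qvalue=float(q),
                        replicate=replicate,
                        name=name,
                    )
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


def write_peaks(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.fold_enrichment:g}\t"
                f"{p.summit - p.start}\t{p.qvalue:g}\n"
            )


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------

def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read the F1 allele count TSV (gene_id, assay, a1_count, a2_count).

    Returns a DataFrame indexed by (gene_id, assay). a1 = P1-origin reads.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "assay": str})
    required = {"gene_id", "assay", "a1_count", "a2_count"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"allele table {path}: missing columns {sorted(missing)}")
    bad_assay = ~df["assay"].isin(ASSAYS)
    if bad_assay.any():
        raise FormatError(
            f"allele table {path}: unknown assay {df.loc[bad_assay, 'assay'].iloc[0]!r}"
        )
    for col in ("a1_count", "a2_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            gene = df.loc[bad.to_numpy().nonzero()[0][0], "gene_id"]
            raise FormatError(f"allele table {path}: bad {col} for gene {gene!r}")
        df[col] = vals.astype(np.int64)
    return df.set_index(["gene_id", "assay"]).sort_index()


def write_allele_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.reset_index().to_csv(path, sep="\t", index=False)


def read_parental_counts(path: str | Path) -> pd.DataFrame:
    """Read per-gene SNP-covered parental read totals.

    TSV columns: gene_id, assay, p1_count, p2_count. Returns a DataFrame
    indexed by (gene_id, assay).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "assay": str})
    required = {"gene_id", "assay", "p1_count", "p2_count"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"parental count table {path}: missing columns {sorted(missing)}")
    for col in ("p1_count", "p2_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            gene = df.loc[bad.to_numpy().nonzero()[0][0], "gene_id"]
            raise FormatError(f"parental count table {path}: bad {col} for gene {gene!r}")
        df[col] = vals.astype(np.int64)
    return df.set_index(["gene_id", "assay"]).sort_index()


def write_parental_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.reset_index().to_csv(path, sep="\t", index=False)
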