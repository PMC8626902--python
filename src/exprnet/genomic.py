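"""Genomic feature extraction.

Parses gene annotations (GTF/BED), ChIP-seq peak files (ENCODE narrowPeak) and
methylation probe tables; derives strand-aware promoter and extended
methylation windows around each transcription start site (TSS); maps
transcription-factor binding into candidate regulators per gene; and
aggregates per-sample promoter methylation as the mean beta value of all
probes falling in a gene's methylation windows.

All coordinates are 0-based half-open.  GTF input (1-based closed) is
converted on read.  Default window extents: promoters span 2000 bp upstream
to 1000 bp downstream of a TSS; methylation areas span 4000 bp upstream to
1000 bp downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ._util import logger

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 1000
METHYL_UPSTREAM = 4000
METHYL_DOWNSTREAM = 1000

#: prefix distinguishing a gene's methylation feature from its expression node
METHYL_PREFIX = "METH:"


class AnnotationParseError(ValueError):
    """Raised when an annotation file contains a malformed record."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its strand and the deduplicated TSSs of its transcripts."""

    gene_symbol: str
    chrom: str
    strand: str  # "+" or "-"
    tss_list: tuple[int, ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_symbol}")
        if not self.tss_list:
            raise ValueError(f"gene {self.gene_symbol} has no TSS")
        if any(t < 0 for t in self.tss_list):
            raise ValueError(f"negative TSS for {self.gene_symbol}")


@dataclass(frozen=True)
class PromoterRegion:
    """A strand-aware window anchored at one TSS of a gene.

    ``region_kind`` is ``"promoter"`` (TF-binding window) or ``"methyl_area"``
    (extended window for methylation aggregation).
    """

    gene_symbol: str
    chrom: str
    start: int
    end: int
    tss: int
    region_kind: str = "promoter"

    def __post_init__(self):
        if not (self.start <= self.tss < self.end):
            raise ValueError(
                f"region [{self.start},{self.end}) of {self.gene_symbol} "
                f"does not contain its TSS {self.tss}"
            )


@dataclass(frozen=True)
class TFPeak:
    """A ChIP-seq binding peak of a transcription factor."""

    tf_symbol: str
    chrom: str
    start: int
    end: int
    signal: float | None = None
    summit_offset: int | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"peak of {self.tf_symbol} has end <= start")


_GENE_NAME_RE = re.compile(r'gene_name "([^"]+)"')
_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def read_annotation(path: str | Path, format: str = "gtf") -> list[GeneAnnotation]:
    """Read gene annotations and collapse them to one record per gene symbol.

    GTF: transcript records are used (gene records if the file has no
    transcripts); the TSS of a + strand transcript is its start, of a − strand
    transcript its last base.  BED6: one TSS per row, ``name`` = gene symbol.
    Duplicate TSSs of a gene are collapsed.  Records without a usable strand
    are rejected with a warning; malformed lines raise
    :class:`AnnotationParseError` naming the line number.
    """
    path = Path(path)
    if format == "gtf":
        raw = _read_gtf_tss(path)
    elif format == "bed":
        raw = _read_bed_tss(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    genes: dict[str, dict] = {}
    for symbol, chrom, strand, tss in raw:
        rec = genes.setdefault(symbol, {"chrom": chrom, "strand": strand, "tss": set()})
        if rec["chrom"] != chrom or rec["strand"] != strand:
            logger.warning(
                "gene %s: conflicting chrom/strand record (%s%s vs %s%s); "
                "keeping the first and skipping",
                symbol, chrom, strand, rec["chrom"], rec["strand"],
            )
            continue
        rec["tss"].add(tss)
    return [
        GeneAnnotation(sym, rec["chrom"], rec["strand"], tuple(sorted(rec["tss"])))
        for sym, rec in sorted(genes.items())
    ]


def _read_gtf_tss(path: Path):
    out = []
    records: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"{path}: malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            records.append((lineno, fields))
    feature_types = {f[2] for _, f in records}
    use = "transcript" if "transcript" in feature_types else "gene"
    for lineno, f in records:
        if f[2] != use:
            continue
        chrom, start_s, end_s, strand, attrs = f[0], f[3], f[4], f[6], f[8]
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise AnnotationParseError(
                f"{path}: malformed GTF line {lineno}: non-integer coordinates"
            ) from None
        if strand not in ("+", "-"):
            logger.warning("%s line %d: missing strand, record rejected", path, lineno)
            continue
        m = _GENE_NAME_RE.search(attrs) or _GENE_ID_RE.search(attrs)
        if m is None:
            logger.warning("%s line %d: no gene_name/gene_id, record rejected", path, lineno)
            continue
        # GTF is 1-based closed; 0-based TSS is start-1 (+) or end-1 (-)
        tss = start1 - 1 if strand == "+" else end1 - 1
        out.append((m.group(1), chrom, strand, tss))
    return out


def _read_bed_tss(path: Path):
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationParseError(
                    f"{path}: malformed BED line {lineno}: expected >=6 fields"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationParseError(
                    f"{path}: malformed BED line {lineno}: non-integer coordinates"
                ) from None
            if strand not in ("+", "-"):
                logger.warning("%s line %d: missing strand, record rejected", path, lineno)
                continue
            tss = start if strand == "+" else end - 1
            out.append((name, chrom, strand, tss))
    return out


def derive_regions(
    gene: GeneAnnotation,
    upstream: int,
    downstream: int,
    kind: str = "promoter",
) -> list[PromoterRegion]:
    """Build one strand-aware window per TSS of ``gene``.

    On the + strand a window is ``[tss - upstream, tss + downstream)``; on the
    − strand it is mirrored, ``[tss - downstream + 1, tss + upstream + 1)``.
    Starts are clamped at 0 (windows near a chromosome start may be shorter).
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be non-negative")
    regions = []
    for tss in gene.tss_list:
        if gene.strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream + 1, tss + upstream + 1
        regions.append(
            PromoterRegion(gene.gene_symbol, gene.chrom, max(start, 0), end, tss, kind)
        )
    return regions


def promoter_regions(
    genes: Iterable[GeneAnnotation],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> list[PromoterRegion]:
    return [r for g in genes for r in derive_regions(g, upstream, downstream, "promoter")]


def methyl_area_regions(
    genes: Iterable[GeneAnnotation],
    upstream: int = METHYL_UPSTREAM,
    downstream: int = METHYL_DOWNSTREAM,
) -> list[PromoterRegion]:
    return [r for g in genes for r in derive_regions(g, upstream, downstream, "methyl_area")]


def read_narrowpeak(path: str | Path) -> list[TFPeak]:
    """Read an ENCODE narrowPeak (BED6+4) file; the name column is the TF symbol."""
    names = ["chrom", "start", "end", "name", "score", "strand",
             "signalValue", "pValue", "qValue", "peak"]
    df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    peaks = []
    for row in df.itertuples(index=False):
        summit = int(row.peak) if row.peak is not None and int(row.peak) >= 0 else None
        peaks.append(
            TFPeak(str(row.name), str(row.chrom), int(row.start), int(row.end),
                   signal=float(row.signalValue), summit_offset=summit)
        )
    return peaks


def map_tf_candidates(
    peaks: Iterable[TFPeak],
    promoters: Iterable[PromoterRegion],
) -> dict[str, set[str]]:
    """Map each gene to the TFs with >=1 bp of peak overlap in any of its promoters.

    A TF appears at most once per gene, however many of the gene's promoters
    it binds.  Overlap is on the same chromosome, half-open intervals.
    """
    trees: dict[str, IntervalTree] = {}
    for region in promoters:
        if region.region_kind != "promoter":
            raise ValueError("map_tf_candidates expects promoter regions")
        if region.end > region.start:
            trees.setdefault(region.chrom, IntervalTree()).addi(
                region.start, region.end, region.gene_symbol
            )
    result: dict[str, set[str]] = {}
    for peak in peaks:
        tree = trees.get(peak.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(peak.start, peak.end):
            result.setdefault(hit.data, set()).add(peak.tf_symbol)
    return result


class MissingMethylationError(ValueError):
    """A gene has no probes in any of its methylation areas."""


def read_methyl_probes(path: str | Path) -> pd.DataFrame:
    """Read a methylation probe table: probe_id, chrom, position, one column per sample."""
    df = pd.read_csv(path, sep="\t")
    required = ("probe_id", "chrom", "position")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: probe table lacks columns {missing}")
    _validate_betas(df)
    return df


def _validate_betas(probes: pd.DataFrame) -> None:
    sample_cols = [c for c in probes.columns if c not in ("probe_id", "chrom", "position")]
    if sample_cols:
        vals = probes[sample_cols].to_numpy(dtype=float)
        bad = ((vals < 0) | (vals > 1)) & ~pd.isna(vals)
        if bad.any():
            raise ValueError("beta values outside [0, 1] found in probe table")


def aggregate_methylation(
    probes: pd.DataFrame,
    methyl_areas: Sequence[PromoterRegion],
) -> pd.Series:
    """Mean beta per sample over the distinct probes in a gene's methylation areas.

    A probe covered by several (overlapping) TSS areas of the gene is counted
    once; missing betas are skipped per sample; a sample with no usable probe
    gets NaN.  Raises :class:`MissingMethylationError` if no probe falls in
    any area.
    """
    if any(r.region_kind != "methyl_area" for r in methyl_areas):
        raise ValueError("aggregate_methylation expects methyl_area regions")
    _validate_betas(probes)
    mask = pd.Series(False, index=probes.index)
    for r in methyl_areas:
        mask |= (
            (probes["chrom"] == r.chrom)
            & (probes["position"] >= r.start)
            & (probes["position"] < r.end)
        )
    sel = probes.loc[mask].drop_duplicates(subset="probe_id")
    if sel.empty:
        gene = methyl_areas[0].gene_symbol if methyl_areas else "?"
        raise MissingMethylationError(f"gene {gene}: no probes in any methylation area")
    sample_cols = [c for c in probes.columns if c not in ("probe_id", "chrom", "position")]
    return sel[sample_cols].astype(float).mean(axis=0, skipna=True)


def methylation_matrix(
    probes: pd.DataFrame,
    areas_by_gene: Mapping[str, Sequence[PromoterRegion]],
) -> tuple[pd.DataFrame, list[str]]:
    """Aggregate methylation for many genes.

    Returns a samples × genes DataFrame of mean betas plus the list of genes
    with no probes in any area (flagged "no methylation feature" and omitted
    from the matrix).
    """
    columns: dict[str, pd.Series] = {}
    no_feature: list[str] = []
    for gene in sorted(areas_by_gene):
        try:
            columns[gene] = aggregate_methylation(probes, areas_by_gene[gene])
        except MissingMethylationError:
            logger.warning("gene %s has no methylation feature (no probes in areas)", gene)
            no_feature.append(gene)
    if not columns:
        sample_cols = [c for c in probes.columns if c not in ("probe_id", "chrom", "position")]
        return pd.DataFrame(index=pd.Index(sample_cols)), no_feature
    return pd.DataFrame(columns), no_feature
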