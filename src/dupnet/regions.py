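"""Mapping genomic duplication coordinates to protein-coding gene seed sets.

Duplication breakpoints come from chromosomal microarray reports as region
strings like ``"Chr8:126,397,316-143,577,971"`` (1-based inclusive, UCSC
browser convention). Gene annotations arrive in BED convention (0-based
half-open); both are converted to 1-based inclusive spans before overlap
testing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from .io import GeneAnnotation, normalize_chrom

__all__ = ["GenomicRegion", "parse_region", "genes_in_region", "map_regions"]

# "chrN:start-end" with optional thousands separators; accepts hyphen,
# en dash, or em dash between the coordinates.
_REGION_RE = re.compile(
    r"^\s*(?P<chrom>[A-Za-z0-9_]+)\s*:\s*(?P<start>[\d,]+)\s*[-–—]\s*(?P<end>[\d,]+)\s*$"
)


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval, 1-based inclusive at both ends."""

    chrom: str
    start: int
    end: int
    assembly: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("1-based region start must be >= 1")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))


def parse_region(text: str, assembly: str = "", label: str = "") -> GenomicRegion:
    """Parse a ``"chrN:start-end"`` region string (1-based inclusive).

    Thousands separators and en/em dashes are accepted, e.g.
    ``"Chr8:126,397,316-143,577,971"``.
    """
    m = _REGION_RE.match(text)
    if m is None:
        raise ValueError(f"malformed region string {text!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    return GenomicRegion(m.group("chrom"), start, end, assembly=assembly, label=label)


def genes_in_region(
    annotation: Iterable[GeneAnnotation],
    region: GenomicRegion,
    rule: str = "any_overlap",
    protein_coding_only: bool = True,
    annotation_assembly: str = "",
    ignore_assembly_mismatch: bool = False,
) -> set:
    """Gene symbols from ``annotation`` falling in ``region``.

    ``any_overlap`` (default) includes a gene whose span intersects the region
    by at least one base; ``full_containment`` requires the whole gene inside.
    A gene with several annotation rows (isoforms) counts once, by symbol.

    Raises on an assembly label mismatch between region and annotation unless
    ``ignore_assembly_mismatch`` is set; empty labels compare as compatible.
    """
    if rule not in {"any_overlap", "full_containment"}:
        raise ValueError(f"unknown overlap rule {rule!r}")
    if (
        region.assembly
        and annotation_assembly
        and region.assembly != annotation_assembly
        and not ignore_assembly_mismatch
    ):
        raise ValueError(
            f"assembly mismatch: region is {region.assembly!r}, "
            f"annotation is {annotation_assembly!r}"
        )
    hits: set = set()
    for gene in annotation:
        if protein_coding_only and gene.biotype != "protein_coding":
            continue
        if gene.chrom != region.chrom:
            continue
        # BED half-open [start, end) -> 1-based inclusive [start+1, end]
        g_start, g_end = gene.start + 1, gene.end
        if rule == "any_overlap":
            if g_start <= region.end and g_end >= region.start:
                hits.add(gene.symbol)
        else:
            if g_start >= region.start and g_end <= region.end:
                hits.add(gene.symbol)
    return hits


def map_regions(
    annotation: Iterable[GeneAnnotation],
    regions: Iterable[GenomicRegion],
    rule: str = "any_overlap",
    protein_coding_only: bool = True,
) -> dict:
    """Per-region seed sets: ``{region label: set of gene symbols}``.

    Regions without a label are keyed by their ``chrom:start-end`` string.
    Empty seed sets are kept (callers decide whether that is fatal).
    """
    annotation = list(annotation)
    out: dict[str, set] = {}
    for region in regions:
        key = region.label or f"{region.chrom}:{region.start}-{region.end}"
        out[key] = genes_in_region(
            annotation, region, rule=rule, protein_coding_only=protein_coding_only
        )
    return out
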