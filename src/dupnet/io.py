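"""Readers and writers for the standard files the pipeline touches.

Formats handled: scored protein-protein interaction edge lists (the HIPPIE
tab-delimited dialect and a generic 3-column TSV), GMT gene-set libraries,
BED-like gene annotations, gene-disease association tables, and network
exports (GraphML / SIF / edge TSV).

All parsers are strict: a malformed field raises :class:`ParseError` naming
the offending line; lines that are *skipped* by design (e.g. rows with an
empty gene symbol) are counted on the returned container, never dropped
silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "EdgeRecord",
    "EdgeList",
    "GeneSetTerm",
    "GeneSetLibrary",
    "GeneAnnotation",
    "GeneDiseaseRecord",
    "read_scored_edge_list",
    "write_scored_edge_list",
    "read_gmt",
    "write_gmt",
    "read_bed_genes",
    "write_bed_genes",
    "read_gene_disease",
    "write_gene_disease",
    "write_graph",
    "read_graphml",
    "normalize_chrom",
]


class ParseError(ValueError):
    """A file violated its format contract; message names the line number."""


@dataclass
class EdgeRecord:
    """One scored, undirected interaction between two gene symbols."""

    gene_a: str
    gene_b: str
    score: float
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_a = self.gene_a.strip()
        self.gene_b = self.gene_b.strip()
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score!r} outside [0, 1]")

    def key(self) -> tuple:
        return (self.gene_a, self.gene_b, self.score)


class EdgeList(list):
    """A list of :class:`EdgeRecord` that remembers how many rows were skipped."""

    def __init__(self, records: Iterable[EdgeRecord] = (), skipped: int = 0):
        super().__init__(records)
        self.skipped = skipped


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the ``chrN`` / ``chrX`` form.

    ``"8" -> "chr8"``, ``"Chrx" -> "chrX"``, ``"chr8" -> "chr8"``.
    """
    s = name.strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if not s:
        raise ValueError("empty chromosome name")
    if s.lower() in {"x", "y", "m", "mt"}:
        s = s.upper() if s.lower() != "mt" else "MT"
    return "chr" + s


def _parse_score(text: str, path, lineno: int) -> float:
    try:
        score = float(text)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: malformed score {text!r}") from None
    if not 0.0 <= score <= 1.0:
        raise ParseError(f"{path}:{lineno}: score {score} outside [0, 1]")
    return score


def read_scored_edge_list(path, dialect: str = "generic") -> EdgeList:
    """Read a scored edge list.

    Parameters
    ----------
    path
        Tab-separated input file.
    dialect
        ``"hippie"``: columns (symbol_a, entrez_a, symbol_b, entrez_b, score,
        metadata); gene identity is the symbol column. ``"generic"``: three
        columns (gene_a, gene_b, score) with an optional header line.

    Rows with an empty gene symbol are skipped and counted on the returned
    :class:`EdgeList`; no cleaning (self-loop or duplicate removal) happens
    here.
    """
    if dialect not in {"hippie", "generic"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    records: list[EdgeRecord] = []
    skipped = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if dialect == "generic":
                if len(cols) != 3:
                    raise ParseError(
                        f"{path}:{lineno}: expected 3 columns, got {len(cols)}"
                    )
                if lineno == 1 and cols[2].strip().lower() == "score":
                    continue  # header
                a, b, score_text = cols
                attrs: dict = {}
            else:
                if len(cols) < 5:
                    raise ParseError(
                        f"{path}:{lineno}: expected >=5 columns, got {len(cols)}"
                    )
                a, entrez_a, b, entrez_b, score_text = cols[:5]
                attrs = {"entrez_a": entrez_a.strip(), "entrez_b": entrez_b.strip()}
                if len(cols) > 5 and cols[5].strip():
                    attrs["metadata"] = cols[5].strip()
            if not a.strip() or not b.strip():
                skipped += 1
                logger.warning("%s:%d: empty gene symbol, row skipped", path, lineno)
                continue
            score = _parse_score(score_text.strip(), path, lineno)
            records.append(EdgeRecord(a, b, score, attrs))
    if skipped:
        logger.warning("%s: skipped %d rows with empty symbols", path, skipped)
    return EdgeList(records, skipped=skipped)


def write_scored_edge_list(records: Iterable[EdgeRecord], path, dialect: str = "generic") -> None:
    """Write records in the given dialect (inverse of :func:`read_scored_edge_list`)."""
    if dialect not in {"hippie", "generic"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with path.open("w") as fh:
        if dialect == "generic":
            fh.write("gene_a\tgene_b\tscore\n")
            for r in records:
                fh.write(f"{r.gene_a}\t{r.gene_b}\t{r.score!r}\n")
        else:
            for r in records:
                ea = r.attributes.get("entrez_a", "-")
                eb = r.attributes.get("entrez_b", "-")
                meta = r.attributes.get("metadata", "-")
                fh.write(f"{r.gene_a}\t{ea}\t{r.gene_b}\t{eb}\t{r.score!r}\t{meta}\n")


# ---------------------------------------------------------------------------
# GMT gene-set libraries


@dataclass(frozen=True)
class GeneSetTerm:
    description: str
    genes: frozenset


@dataclass
class GeneSetLibrary:
    """A named collection of annotation terms, each with a gene set."""

    name: str
    terms: dict  # term_id -> GeneSetTerm

    def __len__(self) -> int:
        return len(self.terms)

    def gene_universe(self) -> frozenset:
        out: set = set()
        for t in self.terms.values():
            out |= t.genes
        return frozenset(out)


def read_gmt(path, name: str | None = None) -> GeneSetLibrary:
    """Read a GMT library: one ``term<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a line are collapsed; a line with fewer than three
    fields (i.e. no genes) is a parse error, as is a repeated term id.
    """
    path = Path(path)
    terms: dict[str, GeneSetTerm] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has <3 fields")
            term_id, desc = cols[0].strip(), cols[1].strip()
            genes = frozenset(g.strip() for g in cols[2:] if g.strip())
            if not genes:
                raise ParseError(f"{path}:{lineno}: term {term_id!r} has no genes")
            if term_id in terms:
                raise ParseError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            terms[term_id] = GeneSetTerm(desc, genes)
    return GeneSetLibrary(name=name or path.stem, terms=terms)


def write_gmt(library: GeneSetLibrary, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for term_id, term in library.terms.items():
            genes = "\t".join(sorted(term.genes))
            fh.write(f"{term_id}\t{term.description}\t{genes}\n")


# ---------------------------------------------------------------------------
# BED-like gene annotations


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene span in BED convention: 0-based, half-open ``[start, end)``."""

    chrom: str
    start: int
    end: int
    symbol: str
    biotype: str = "protein_coding"


def read_bed_genes(path) -> list[GeneAnnotation]:
    """Read gene annotations from a BED-like file.

    Columns: chrom, start, end, symbol[, biotype]. Coordinates are 0-based
    half-open; the biotype column defaults to ``protein_coding`` when absent;
    chromosome names are normalized to the ``chrN`` form.
    """
    path = Path(path)
    out: list[GeneAnnotation] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates {cols[1]!r}/{cols[2]!r}"
                ) from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            biotype = cols[4].strip() if len(cols) > 4 and cols[4].strip() else "protein_coding"
            out.append(
                GeneAnnotation(
                    chrom=normalize_chrom(cols[0]),
                    start=start,
                    end=end,
                    symbol=cols[3].strip(),
                    biotype=biotype,
                )
            )
    return out


def write_bed_genes(annotations: Iterable[GeneAnnotation], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for a in annotations:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.symbol}\t{a.biotype}\n")


# ---------------------------------------------------------------------------
# Gene-disease association tables


@dataclass(frozen=True)
class GeneDiseaseRecord:
    gene: str
    disease: str
    score: float


def read_gene_disease(path) -> list[GeneDiseaseRecord]:
    """Read a gene-disease TSV with a required ``gene, disease, score`` header.

    Duplicate (gene, disease) pairs are collapsed keeping the maximum score.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "disease": str})
    required = {"gene", "disease", "score"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: header must contain columns {sorted(required)}")
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise ParseError(f"{path}: association scores must lie in [0, 1]")
    df = (
        df.groupby(["gene", "disease"], as_index=False)["score"]
        .max()
        .sort_values(["gene", "disease"])
    )
    return [
        GeneDiseaseRecord(r.gene, r.disease, float(r.score))
        for r in df.itertuples(index=False)
    ]


def write_gene_disease(records: Iterable[GeneDiseaseRecord], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene\tdisease\tscore\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.disease}\t{r.score!r}\n")


# ---------------------------------------------------------------------------
# Network exports


def write_graph(network: nx.Graph, path, format: str = "graphml") -> None:
    """Export a network.

    ``graphml`` preserves all node/edge attributes (round-trips exactly via
    :func:`read_graphml`); ``sif`` keeps topology only, one ``A pp B`` line
    per edge; ``edge-tsv`` writes gene_a/gene_b/score columns.
    """
    path = Path(path)
    if format == "graphml":
        if isinstance(network.graph.get("provenance"), list):
            network = network.copy()
            network.graph["provenance"] = " | ".join(network.graph["provenance"])
        nx.write_graphml(network, path, named_key_ids=True)
    elif format == "sif":
        with path.open("w") as fh:
            for u, v in network.edges():
                fh.write(f"{u} pp {v}\n")
            for node in nx.isolates(network):
                fh.write(f"{node}\n")
    elif format == "edge-tsv":
        with path.open("w") as fh:
            fh.write("gene_a\tgene_b\tscore\n")
            for u, v, d in network.edges(data=True):
                fh.write(f"{u}\t{v}\t{d.get('score', 1.0)!r}\n")
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(Path(path), node_type=str)
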