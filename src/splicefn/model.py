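"""Domain types and file I/O shared by every pipeline stage.

The analysis works on three nested objects: a :class:`ProteinRecord` is one
splice-variant protein with its set of annotation keywords; a
:class:`TranscriptionalUnit` (TU) groups the protein isoforms produced by a
single genomic locus; an :class:`OrganismDataset` holds all TUs of one
organism together with its catalogue of functional labels (FLs).

A functional label is a unique, deduplicated, sorted combination of keywords
and serves as the unit of "protein function" throughout the pipeline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

MONOFORM = "monoform"
POLYFORM = "polyform"
UNANNOTATED = "unannotated"
UNCLASSIFIED = "unclassified"


class AnnotationTableError(ValueError):
    """Raised for malformed or inconsistent annotation tables."""


@dataclass
class ProteinRecord:
    """One splice-variant protein and its keyword annotation.

    ``keywords`` is stored as a frozenset: redundant keyword IDs are removed
    on ingestion. Keywords are opaque, case-sensitive strings. ``fl_id`` is
    filled in once a catalogue is built (None for unannotated proteins).
    """

    protein_id: str
    tu_id: str
    keywords: frozenset[str]
    fl_id: Optional[str] = None

    @property
    def annotated(self) -> bool:
        return len(self.keywords) > 0


@dataclass
class TranscriptionalUnit:
    """A genomic locus with its splice-variant protein records.

    ``fls`` (the distinct FLs of its proteins) and ``tu_class`` are derived
    when a catalogue is built. A TU is *monoform* when all its annotated
    isoforms carry the same single FL, *polyform* when they carry two or
    more distinct FLs, and *unannotated* when no isoform has keywords.
    """

    tu_id: str
    proteins: list[ProteinRecord] = field(default_factory=list)
    fls: set[str] = field(default_factory=set)
    tu_class: str = UNCLASSIFIED

    @property
    def n_sv(self) -> int:
        """Number of splice variants (protein records) of this TU."""
        return len(self.proteins)

    def annotated_proteins(self) -> list[ProteinRecord]:
        return [p for p in self.proteins if p.annotated]


@dataclass(frozen=True)
class FunctionalLabel:
    """A unique combination of keywords with its catalogue identifier."""

    fl_id: str
    keywords: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("a functional label must carry >=1 keyword")
        if list(self.keywords) != sorted(set(self.keywords)):
            raise ValueError("keywords must be sorted and unique")


class FLCatalogue:
    """Bijection between canonical keyword tuples and FL identifiers.

    Identifiers follow the scheme ``FL{scope}{n}`` where *scope* is an
    organism mnemonic (``h``, ``m``, ``c`` or any code) and *n* is the
    1-based rank of the tuple in lexicographic order.
    """

    def __init__(self, scope: str, tuples: Iterable[tuple[str, ...]]):
        if not scope:
            raise ValueError("catalogue scope must be a nonempty string")
        self.scope = scope
        ordered = sorted(set(tuples))
        for t in ordered:
            if not t:
                raise ValueError("empty keyword tuple has no functional label")
        self._tuple_to_id: dict[tuple[str, ...], str] = {}
        self._id_to_tuple: dict[str, tuple[str, ...]] = {}
        for n, t in enumerate(ordered, start=1):
            fl_id = f"FL{scope}{n}"
            self._tuple_to_id[t] = fl_id
            self._id_to_tuple[fl_id] = t

    def __len__(self) -> int:
        return len(self._tuple_to_id)

    def __contains__(self, keywords: tuple[str, ...]) -> bool:
        return tuple(keywords) in self._tuple_to_id

    def id_of(self, keywords: tuple[str, ...]) -> str:
        return self._tuple_to_id[tuple(keywords)]

    def keywords_of(self, fl_id: str) -> tuple[str, ...]:
        return self._id_to_tuple[fl_id]

    @property
    def tuples(self) -> list[tuple[str, ...]]:
        return list(self._tuple_to_id)

    @property
    def ids(self) -> list[str]:
        return list(self._id_to_tuple)

    def labels(self) -> list[FunctionalLabel]:
        return [FunctionalLabel(i, t) for t, i in self._tuple_to_id.items()]


@dataclass
class OrganismDataset:
    """All TUs of one organism plus (after labelling) its FL catalogue."""

    organism: str
    tus: list[TranscriptionalUnit]
    catalogue: Optional[FLCatalogue] = None

    def tu_by_id(self, tu_id: str) -> TranscriptionalUnit:
        for tu in self.tus:
            if tu.tu_id == tu_id:
                return tu
        raise KeyError(tu_id)

    @property
    def proteins(self) -> list[ProteinRecord]:
        return [p for tu in self.tus for p in tu.proteins]

    def annotated_tus(self) -> list[TranscriptionalUnit]:
        return [tu for tu in self.tus if any(p.annotated for p in tu.proteins)]


def read_annotation_table(
    path, organism: str, skip_header: bool = False
) -> OrganismDataset:
    """Read a protein→keyword annotation table into an :class:`OrganismDataset`.

    The table is tab-separated UTF-8 with three columns and no header by
    default: protein ID, TU ID, and a ';'-joined keyword list (the third
    field may be empty for unannotated proteins). Duplicate keywords within
    a protein are dropped; proteins are grouped into TUs in order of first
    appearance. The catalogue is not built here.

    Raises
    ------
    AnnotationTableError
        On a line without exactly three tab-separated fields (the message
        names the 1-based line number) or on a duplicate protein ID.
    """
    tus: dict[str, TranscriptionalUnit] = {}
    seen_proteins: set[str] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if skip_header and lineno == 1:
                continue
            line = raw.rstrip("\n").rstrip("\r")
            if not line and lineno > 1:
                continue  # trailing blank line
            fields = line.split("\t")
            if len(fields) != 3:
                raise AnnotationTableError(
                    f"line {lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            protein_id, tu_id, kw_field = fields
            if not protein_id or not tu_id:
                raise AnnotationTableError(
                    f"line {lineno}: empty protein or TU identifier"
                )
            if protein_id in seen_proteins:
                raise AnnotationTableError(
                    f"line {lineno}: duplicate protein id {protein_id!r}"
                )
            seen_proteins.add(protein_id)
            keywords = frozenset(k for k in kw_field.split(";") if k)
            rec = ProteinRecord(protein_id, tu_id, keywords)
            tus.setdefault(tu_id, TranscriptionalUnit(tu_id)).proteins.append(rec)
    return OrganismDataset(organism=organism, tus=list(tus.values()))


def write_annotation_table(dataset: OrganismDataset, path) -> None:
    """Write a dataset back to the standard three-column annotation TSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for tu in dataset.tus:
            for p in tu.proteins:
                w.writerow([p.protein_id, p.tu_id, ";".join(sorted(p.keywords))])


# --- network file I/O ---------------------------------------------------

SIF_RELATION = "sw"  # "shared with": FL pair linked by >=1 shared polyform TU


def write_network(graph: nx.Graph, path, format: str = "sif") -> None:
    """Write an FL network for Cytoscape as SIF or GraphML.

    SIF lines are ``node1<TAB>sw<TAB>node2``; isolated nodes are written as
    bare-name lines. Because SIF itself carries no attributes, edge weights
    go to a Cytoscape edge-attribute sidecar ``<path>.eda``, so a read-back
    recovers the weighted edge set. GraphML stores ``weight`` as a numeric
    edge attribute directly.
    """
    fmt = format.lower()
    if fmt == "sif":
        path = str(path)
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
                fh.write(f"{u}\t{SIF_RELATION}\t{v}\n")
            for n in sorted(nx.isolates(graph)):
                fh.write(f"{n}\n")
        with open(path + ".eda", "w", encoding="utf-8") as fh:
            fh.write(f"{SIF_RELATION} weight\n")
            for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
                w = graph[u][v].get("weight", 1)
                fh.write(f"{u} ({SIF_RELATION}) {v} = {w}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(graph.nodes())
        for u, v, data in graph.edges(data=True):
            g.add_edge(u, v, weight=int(data.get("weight", 1)))
        nx.write_graphml(g, str(path))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "sif") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    fmt = format.lower()
    if fmt == "sif":
        path = str(path)
        g = nx.Graph()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1 and parts[0]:
                    g.add_node(parts[0])
                elif len(parts) == 3:
                    g.add_edge(parts[0], parts[2], weight=1)
                elif any(parts):
                    raise ValueError(f"malformed SIF line: {line!r}")
        try:
            with open(path + ".eda", encoding="utf-8") as fh:
                next(fh, None)  # header
                for line in fh:
                    line = line.strip()
                    if not line:
                        continue
                    lhs, w = line.rsplit("=", 1)
                    u, _, v = lhs.strip().split(" ", 2)
                    g.add_edge(u, v.strip(), weight=int(w))
        except FileNotFoundError:
            pass
        return g
    if fmt == "graphml":
        g = nx.read_graphml(str(path))
        out = nx.Graph()
        out.add_nodes_from(g.nodes())
        for u, v, data in g.edges(data=True):
            out.add_edge(u, v, weight=int(data.get("weight", 1)))
        return out
    raise ValueError(f"unknown network format {format!r}")
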