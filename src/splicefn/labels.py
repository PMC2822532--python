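"""Functional-label catalogues: construction, assignment, and intersection.

A functional label (FL) is the unique combination of annotation keywords
carried by a protein, used as a proxy for its molecular function. This
module builds the per-organism FL catalogue, assigns an FL to every
annotated protein and the derived FL set to every TU, and intersects
catalogues across organisms to find the shared functional core.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass

from .model import (
    MONOFORM,
    POLYFORM,
    UNANNOTATED,
    FLCatalogue,
    FunctionalLabel,
    OrganismDataset,
)


def canonicalize(keywords) -> tuple[str, ...]:
    """Return the canonical form of a keyword collection.

    Canonical form is a sorted tuple of the unique keywords; an empty
    collection canonicalizes to the empty tuple. Keywords are opaque,
    case-sensitive strings and are never normalized.
    """
    return tuple(sorted(set(keywords)))


def build_catalogue(dataset: OrganismDataset, scope: str) -> FLCatalogue:
    """Build the FL catalogue of a dataset and label its proteins and TUs.

    One FL is created per distinct nonempty canonical keyword tuple found
    across all proteins; identifiers are ``FL{scope}{n}`` with *n* the
    1-based lexicographic rank of the tuple, so the catalogue is invariant
    to protein input order. Side effects on the dataset: each annotated
    protein gets its ``fl_id``; each TU gets its distinct-FL set and its
    monoform / polyform / unannotated class.
    """
    if not scope:
        raise ValueError("scope must be a nonempty string")
    tuples = {
        canonicalize(p.keywords)
        for tu in dataset.tus
        for p in tu.proteins
        if p.keywords
    }
    catalogue = FLCatalogue(scope, tuples)
    for tu in dataset.tus:
        fls: set[str] = set()
        for p in tu.proteins:
            if p.keywords:
                p.fl_id = catalogue.id_of(canonicalize(p.keywords))
                fls.add(p.fl_id)
            else:
                p.fl_id = None
        tu.fls = fls
        if not fls:
            tu.tu_class = UNANNOTATED
        elif len(fls) == 1:
            tu.tu_class = MONOFORM
        else:
            tu.tu_class = POLYFORM
    dataset.catalogue = catalogue
    return catalogue


@dataclass
class SharedFLReport:
    """FLs common to every catalogue of a cross-organism comparison."""

    common_count: int
    common_labels: list[FunctionalLabel]
    keyword_frequency: dict[str, int]


def intersect_catalogues(catalogues: list[FLCatalogue]) -> SharedFLReport:
    """Intersect >=2 FL catalogues into a common-scope ("c") report.

    A label is common when its canonical keyword tuple occurs in every
    catalogue; common labels are re-issued with scope ``c``. The keyword
    frequency map counts, for each keyword, how many common labels contain
    it — the basis of top-keyword summaries of the shared functional core.
    """
    if len(catalogues) < 2:
        raise ValueError("need at least 2 catalogues to intersect")
    common = set(catalogues[0].tuples)
    for cat in catalogues[1:]:
        common &= set(cat.tuples)
    common_cat = FLCatalogue("c", common)
    labels = common_cat.labels()
    freq = Counter(kw for lab in labels for kw in lab.keywords)
    return SharedFLReport(
        common_count=len(labels),
        common_labels=labels,
        keyword_frequency=dict(freq),
    )


def top_keywords(report: SharedFLReport, n: int) -> list[tuple[str, int]]:
    """Top-*n* keywords of a shared-FL report by common-label membership.

    Sorted by count descending, ties broken lexicographically; returns at
    most *n* entries (fewer when the vocabulary is smaller).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(report.keyword_frequency.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


def write_catalogue(dataset: OrganismDataset, path) -> None:
    """Export a built catalogue as TSV: fl_id, ';'-joined keywords, count.

    The count is the number of protein records mapped to the FL.
    """
    if dataset.catalogue is None:
        raise ValueError("catalogue not built")
    occ = Counter(p.fl_id for p in dataset.proteins if p.fl_id is not None)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for fl_id in dataset.catalogue.ids:
            kws = ";".join(dataset.catalogue.keywords_of(fl_id))
            w.writerow([fl_id, kws, occ.get(fl_id, 0)])
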