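"""TU classification, functional-switch detection, and cross-organism stats.

A TU is monoform when all its annotated isoforms carry the same functional
label and polyform when they carry at least two. Within polyform TUs, an
isoform pair with *disjoint* keyword sets (Jaccard index 0) is a candidate
functional switch — the isoforms share no annotated function at all, as in
a locus whose products switch from protease activity to oxygen transport.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

from scipy import stats

from .model import MONOFORM, POLYFORM, UNANNOTATED, OrganismDataset


@dataclass
class ClassificationSummary:
    organism: str
    n_poly: int
    n_mono: int
    n_unannotated: int
    poly_over_mono_pct: Optional[float]  # 100 * n_poly / n_mono; None if n_mono=0
    mean_sv_per_tu: float  # over classified (annotated) TUs

    @property
    def poly_fraction(self) -> Optional[float]:
        """Fraction of annotated TUs that are polyform."""
        n = self.n_poly + self.n_mono
        return self.n_poly / n if n else None


@dataclass
class SwitchCandidate:
    tu_id: str
    protein_pair: tuple[str, str]
    jaccard_index: float
    jaccard_distance: float


def jaccard(a, b) -> tuple[float, float]:
    """Jaccard index and distance between two keyword sets.

    index = |a ∩ b| / |a ∪ b|, distance = 1 − index. Undefined (raises)
    when both sets are empty.
    """
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    index = len(a & b) / len(union)
    return index, 1.0 - index


def detect_switches(
    dataset: OrganismDataset, denominator: str = "annotated"
) -> tuple[list[SwitchCandidate], float]:
    """Find functional-switch candidates and the switch-TU fraction.

    Scans every unordered pair of annotated proteins within each polyform
    TU; a pair is a candidate when its keyword sets are disjoint (Jaccard
    index 0). Pairs involving an unannotated protein are skipped. The
    fraction (in percent) counts TUs with >=1 candidate pair over the
    chosen denominator: "annotated" (default), "all", or "polyform" TUs.

    Requires the catalogue to be built (TU classes assigned).
    """
    if dataset.catalogue is None:
        raise ValueError("catalogue not built")
    candidates: list[SwitchCandidate] = []
    switch_tus: set[str] = set()
    counts = {MONOFORM: 0, POLYFORM: 0, UNANNOTATED: 0}
    for tu in dataset.tus:
        counts[tu.tu_class] += 1
        if tu.tu_class != POLYFORM:
            continue
        for p, q in combinations(tu.annotated_proteins(), 2):
            idx, dist = jaccard(p.keywords, q.keywords)
            if idx == 0.0:
                candidates.append(
                    SwitchCandidate(tu.tu_id, (p.protein_id, q.protein_id), idx, dist)
                )
                switch_tus.add(tu.tu_id)
    denom = {
        "annotated": counts[MONOFORM] + counts[POLYFORM],
        "all": len(dataset.tus),
        "polyform": counts[POLYFORM],
    }[denominator]
    fraction = 100.0 * len(switch_tus) / denom if denom else 0.0
    return candidates, fraction


def summarize(dataset: OrganismDataset) -> ClassificationSummary:
    """Per-organism class counts, poly/mono percentage and mean SV count.

    The percentage is 100·n_poly/n_mono (full precision kept; display
    rounds to 2 decimals); it is None when there are no monoform TUs.
    Mean SV per TU is taken over annotated (classified) TUs.
    """
    if dataset.catalogue is None:
        raise ValueError("catalogue not built")
    n_poly = sum(1 for tu in dataset.tus if tu.tu_class == POLYFORM)
    n_mono = sum(1 for tu in dataset.tus if tu.tu_class == MONOFORM)
    n_un = sum(1 for tu in dataset.tus if tu.tu_class == UNANNOTATED)
    pct = 100.0 * n_poly / n_mono if n_mono > 0 else None
    classified = [tu for tu in dataset.tus if tu.tu_class in (MONOFORM, POLYFORM)]
    mean_sv = (
        sum(tu.n_sv for tu in classified) / len(classified) if classified else 0.0
    )
    return ClassificationSummary(
        organism=dataset.organism,
        n_poly=n_poly,
        n_mono=n_mono,
        n_unannotated=n_un,
        poly_over_mono_pct=pct,
        mean_sv_per_tu=mean_sv,
    )


def complexity_correlation(
    summaries: list[ClassificationSummary], exclude: list[str] = ()
) -> float:
    """Pearson r between mean SV count and polyform fraction across organisms.

    Each summary contributes one point: x = mean splice variants per TU,
    y = fraction of polyform TUs. ``exclude`` drops named organisms before
    the fit (e.g. to treat an outlier organism separately). Needs >=3
    points after exclusion and nonzero variance in both coordinates.
    """
    pts = [s for s in summaries if s.organism not in set(exclude)]
    if len(pts) < 3:
        raise ValueError("need >=3 summaries after exclusion")
    x = [s.mean_sv_per_tu for s in pts]
    y = [s.poly_fraction for s in pts]
    if any(v is None for v in y):
        raise ValueError("polyform fraction undefined for some organism")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("zero variance in one of the variables")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def write_summary(summaries: list[ClassificationSummary], path) -> None:
    """TSV report, one organism per row, percentages at 2 decimals."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["organism", "n_poly", "n_mono", "n_unannotated",
             "poly_over_mono_pct", "mean_sv_per_tu"]
        )
        for s in summaries:
            pct = "" if s.poly_over_mono_pct is None else f"{s.poly_over_mono_pct:.2f}"
            w.writerow(
                [s.organism, s.n_poly, s.n_mono, s.n_unannotated, pct,
                 f"{s.mean_sv_per_tu:.4f}"]
            )


def write_switches(candidates: list[SwitchCandidate], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["tu_id", "protein_a", "protein_b", "jaccard_index",
                    "jaccard_distance"])
        for c in candidates:
            w.writerow([c.tu_id, *c.protein_pair, c.jaccard_index,
                        c.jaccard_distance])
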