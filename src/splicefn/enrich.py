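"""Keyword over-representation in TU groups (hypergeometric test).

Tests whether a keyword occurs in a study set of TUs (e.g. the polyform
group) more often than expected from its frequency among all annotated
TUs. The unit of counting is the TU: a keyword counts once per TU if any
of the TU's proteins carries it. Raw upper-tail hypergeometric p-values
are corrected by the modified Bonferroni rule of GeneMerge: multiply by
the number of distinct keywords represented in the study set, cap at 1.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass

from scipy import stats

from .model import OrganismDataset

DEFAULT_THRESHOLD = 1e-4


@dataclass
class EnrichmentResult:
    keyword: str
    x: int  # study-set TUs carrying the keyword
    n: int  # study-set size
    K: int  # population TUs carrying the keyword
    N: int  # population size
    p_raw: float
    p_adj: float
    rank: int


def hypergeom_upper(x: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x).

    X counts marked items in a draw of *n* from a population of *N*
    containing *K* marked items. Computed through the survival function of
    the hypergeometric distribution (stable log-space evaluation).
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= x <= min(n, K)):
        raise ValueError(
            f"inconsistent counts: x={x}, n={n}, K={K}, N={N}"
        )
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def _tu_keywords(tu) -> set[str]:
    return {kw for p in tu.proteins for kw in p.keywords}


def enrich(
    study: set[str],
    dataset: OrganismDataset,
    threshold: float = DEFAULT_THRESHOLD,
    population: str = "annotated",
) -> list[EnrichmentResult]:
    """Over-represented keywords in a study set of TU ids.

    ``population`` selects the background: all annotated TUs (default) or
    all TUs. Returns keywords with corrected p-value below ``threshold``,
    ranked by corrected p-value ascending (ties by keyword).
    """
    if not study:
        raise ValueError("study set must be nonempty")
    if population == "annotated":
        pop_tus = dataset.annotated_tus()
    elif population == "all":
        pop_tus = dataset.tus
    else:
        raise ValueError(f"unknown population {population!r}")
    pop_ids = {tu.tu_id for tu in pop_tus}
    missing = set(study) - pop_ids
    if missing:
        raise ValueError(
            f"study TUs not in the population: {sorted(missing)[:5]}"
        )
    N = len(pop_tus)
    pop_counts: Counter[str] = Counter()
    study_counts: Counter[str] = Counter()
    for tu in pop_tus:
        kws = _tu_keywords(tu)
        pop_counts.update(kws)
        if tu.tu_id in study:
            study_counts.update(kws)
    n = len(study)
    T = len(study_counts)  # keywords represented in the study set
    results = []
    for kw, x in study_counts.items():
        p_raw = hypergeom_upper(x, n, pop_counts[kw], N)
        p_adj = min(1.0, p_raw * T)
        if p_adj < threshold:
            results.append(
                EnrichmentResult(kw, x, n, pop_counts[kw], N, p_raw, p_adj, 0)
            )
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.keyword))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    """TSV report: rank, corrected p, keyword and the contingency margins."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["rank", "p_adj", "p_raw", "keyword", "x", "n", "K", "N"])
        for r in results:
            w.writerow([r.rank, f"{r.p_adj:.6g}", f"{r.p_raw:.6g}",
                        r.keyword, r.x, r.n, r.K, r.N])
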