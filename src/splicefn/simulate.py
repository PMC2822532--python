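"""Synthetic organism datasets with realistic annotation statistics.

The generator emulates the statistical structure of FANTOM-style
TU/splice-variant annotation data: splice-variant counts per TU follow a
two-component mixture (discretized exponential body below a breakpoint,
generalized-discrete-Pareto tail at and above it); the number of distinct
FLs per TU is 1 for monoform TUs and exponentially distributed above 2 for
polyform TUs, capped at 9; FL popularity is Zipf-weighted so the
TUs-per-FL relation is heavy-tailed with slope ~2; a configurable fraction
of TUs carries no annotation at all. Exact degenerate fixtures matching
printed marginal counts are built separately by ``fixture_from_counts``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .labels import build_catalogue
from .model import OrganismDataset, ProteinRecord, TranscriptionalUnit
from .distfit import FrequencyDistribution, gdp_pmf


@dataclass
class SVModel:
    """Mixture model for splice-variant counts per TU.

    With probability ``s`` the count comes from a discretized exponential
    with rate ``exp_b`` truncated to 1..breakpoint-1, otherwise from a GDP
    with shape ``gdp_k`` and shift ``gdp_b`` on breakpoint..J. Defaults are
    the best-fit human splice-variant model (exponential rate 0.49; GDP
    k=4.16, b=8.75; tail beyond 9 variants) with the body weight set from
    the observed share of TUs below the breakpoint (280 of 18260 human TUs
    produce 10+ variants, hence s ~ 0.985).
    """

    s: float = 0.985
    exp_b: float = 0.49
    gdp_k: float = 4.16
    gdp_b: float = 8.75
    breakpoint: int = 10
    J: int = 73


@dataclass
class SimConfig:
    """Generator configuration; defaults emulate the human FANTOM dataset.

    ``polyform_target`` is the fraction of annotated TUs that are polyform
    (human: 2315 polyform / 18259 classified ~ 0.127); ``fl_per_tu_exp_b``
    sets the exponential decay of extra FLs in polyform TUs (rate 2.2
    reproduces the ~87-89% singleton share of the FLs-per-TU relation);
    ``unannotated_fraction`` mirrors the ~30% of proteins that receive no
    keywords. ``fl_pool_size`` sets the Zipf-weighted FL prototype pool;
    ``switch_fraction`` the share of annotated TUs that carry a
    disjoint-keyword (functional-switch) isoform pair — about 0.8% in the
    mammalian data. All other polyform TUs draw their FLs around a shared
    anchor keyword, so isoform keyword sets overlap as they do in real
    annotations.
    """

    organism: str = "syn"
    n_tus: int = 20000
    keyword_vocab_size: int = 800
    mean_keywords_per_fl: float = 2.5
    sv_model: SVModel = field(default_factory=SVModel)
    fl_per_tu_exp_b: float = 2.2
    polyform_target: float = 0.127
    unannotated_fraction: float = 0.3
    seed: int = 2010
    fl_pool_size: int = 5000
    switch_fraction: float = 0.008
    max_fls_per_tu: int = 9

    def validate(self) -> None:
        for name in ("polyform_target", "unannotated_fraction", "switch_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_tus < 1:
            raise ValueError("n_tus must be >= 1")
        if self.fl_per_tu_exp_b <= 0 or self.sv_model.exp_b <= 0:
            raise ValueError("exponential rates must be > 0")
        if not 0.0 <= self.sv_model.s <= 1.0:
            raise ValueError("mixture weight s must lie in [0, 1]")
        if not 2 <= self.sv_model.breakpoint <= self.sv_model.J:
            raise ValueError("breakpoint must lie in [2, J]")


def load_config(path) -> SimConfig:
    """Read a SimConfig from a flat YAML mapping (sv_model keys nested)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sv = SVModel(**raw.pop("sv_model", {}))
    cfg = SimConfig(sv_model=sv, **raw)
    cfg.validate()
    return cfg


def save_config(cfg: SimConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


# --------------------------------------------------------------------------
# Samplers
# --------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_gdp(n: int, k: float, b: float, J: int, seed) -> np.ndarray:
    """n i.i.d. draws from GDP(k, b) on 1..J by inverse-CDF; seedable."""
    rng = _as_rng(seed)
    if J < 1:
        raise ValueError("J must be >= 1")
    pmf = gdp_pmf(np.arange(1, J + 1), k, b, J=J)  # validates k, b
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0
    u = rng.random(int(n))
    return np.searchsorted(cdf, u, side="left").astype(np.int64) + 1


def _sample_disc_exp(rng, n, rate, lo, hi) -> np.ndarray:
    """Discretized exponential on the integers lo..hi: P(m) ∝ exp(-rate·m)."""
    m = np.arange(lo, hi + 1, dtype=float)
    w = np.exp(-rate * m)
    cdf = np.cumsum(w / w.sum())
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(int(n)), side="left") + lo


def _sample_gdp_range(rng, n, k, b, lo, hi) -> np.ndarray:
    """GDP draws on the integers lo..hi: P(m) ∝ (m+b)^-(k+1)."""
    pmf = gdp_pmf(np.arange(lo, hi + 1), k, b, J=hi, m_min=lo)
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(int(n)), side="left") + lo


def sample_sv_counts(n: int, model: SVModel, seed) -> np.ndarray:
    """Splice-variant counts from the body+tail mixture."""
    rng = _as_rng(seed)
    from_body = rng.random(int(n)) < model.s
    out = np.empty(int(n), dtype=np.int64)
    n_body = int(from_body.sum())
    if n_body:
        out[from_body] = _sample_disc_exp(
            rng, n_body, model.exp_b, 1, model.breakpoint - 1
        )
    n_tail = int(n) - n_body
    if n_tail:
        out[~from_body] = _sample_gdp_range(
            rng, n_tail, model.gdp_k, model.gdp_b, model.breakpoint, model.J
        )
    return out


def mixture_pmf(model: SVModel) -> np.ndarray:
    """The configured mixture pmf on 1..J (for goodness-of-fit checks)."""
    m_body = np.arange(1, model.breakpoint, dtype=float)
    w = np.exp(-model.exp_b * m_body)
    body = model.s * w / w.sum()
    tail = (1.0 - model.s) * gdp_pmf(
        np.arange(model.breakpoint, model.J + 1),
        model.gdp_k, model.gdp_b, J=model.J, m_min=model.breakpoint,
    )
    return np.concatenate([body, tail])


# --------------------------------------------------------------------------
# Organism generator
# --------------------------------------------------------------------------


def _make_fl_pool(rng, cfg: SimConfig) -> list[tuple[str, ...]]:
    """Distinct keyword-set prototypes; sizes ~ 1 + Poisson(mean-1)."""
    vocab = np.array([f"KW-{i:04d}" for i in range(cfg.keyword_vocab_size)])
    pool: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    lam = max(cfg.mean_keywords_per_fl - 1.0, 0.0)
    attempts = 0
    while len(pool) < cfg.fl_pool_size:
        attempts += 1
        if attempts > 50 * cfg.fl_pool_size:
            raise RuntimeError(
                "could not build a pool of distinct keyword sets; "
                "increase keyword_vocab_size or mean_keywords_per_fl"
            )
        size = int(1 + rng.poisson(lam))
        size = min(size, cfg.keyword_vocab_size)
        t = tuple(sorted(rng.choice(vocab, size=size, replace=False)))
        if t not in seen:
            seen.add(t)
            pool.append(t)
    return pool


def _draw_anchored(rng, pool, cdf, by_keyword, anchor_cdf, n_fl: int,
                   max_tries: int = 200) -> list[int]:
    """FL prototype indices for one polyform TU, pairwise-overlapping.

    The first prototype is Zipf-drawn from the full pool; an anchor keyword
    (its keyword with the widest pool membership) then restricts the
    remaining draws, so every pair of the TU's FLs shares the anchor.
    """
    for _ in range(max_tries):
        first = int(np.searchsorted(cdf, rng.random(), side="left"))
        # widest-membership keyword of the first prototype
        anchor = max(pool[first], key=lambda kw: len(by_keyword[kw]))
        if len(by_keyword[anchor]) >= n_fl:
            idxs = by_keyword[anchor]
            chosen = {first} if first in idxs else set()
            acdf = anchor_cdf[anchor]
            tries = 0
            while len(chosen) < n_fl:
                tries += 1
                if tries > max_tries * n_fl:
                    break
                j = idxs[int(np.searchsorted(acdf, rng.random(), side="left"))]
                chosen.add(j)
            if len(chosen) == n_fl:
                return sorted(chosen)
    raise RuntimeError(
        "could not draw overlapping FL prototypes; increase fl_pool_size "
        "or mean_keywords_per_fl"
    )


def _weighted_distinct(rng, cdf, n: int, max_tries: int = 200) -> list[int]:
    """n distinct indices from a Zipf-weighted pool (rejection on duplicates)."""
    chosen: list[int] = []
    seen: set[int] = set()
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > max_tries * n:
            raise RuntimeError("could not draw distinct FL prototypes")
        i = int(np.searchsorted(cdf, rng.random(), side="left"))
        if i not in seen:
            seen.add(i)
            chosen.append(i)
    return chosen


def generate_organism(config: SimConfig) -> OrganismDataset:
    """Generate a synthetic organism dataset and build its FL catalogue.

    Splice-variant counts are drawn i.i.d. from the configured mixture for
    every TU, so the empirical SVs-per-TU relation matches the model
    marginal. An exact ``round(unannotated_fraction · n_tus)`` subset is
    left unannotated; among annotated TUs an exact
    ``round(polyform_target · n_annotated)`` subset (restricted to TUs
    with >=2 variants) is made polyform. Deterministic under the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_tus
    sv_counts = sample_sv_counts(n, config.sv_model, rng)

    n_unannot = int(round(config.unannotated_fraction * n))
    order = rng.permutation(n)
    unannot_idx = set(order[:n_unannot].tolist())
    annotated = [i for i in range(n) if i not in unannot_idx]

    eligible = [i for i in annotated if sv_counts[i] >= 2]
    n_poly = int(round(config.polyform_target * len(annotated)))
    if n_poly > len(eligible):
        raise ValueError(
            "infeasible config: polyform target exceeds the share of TUs "
            "with >=2 splice variants"
        )
    poly_idx = set(
        np.array(eligible)[rng.permutation(len(eligible))[:n_poly]].tolist()
    ) if n_poly else set()

    n_switch = int(round(config.switch_fraction * len(annotated)))
    if n_switch > len(poly_idx):
        raise ValueError("infeasible config: more switch TUs than polyform TUs")
    switch_idx = set(sorted(poly_idx)[:n_switch])

    pool = _make_fl_pool(rng, config)
    weights = 1.0 / np.arange(1, len(pool) + 1, dtype=float)  # Zipf, slope ~2
    cdf = np.cumsum(weights / weights.sum())
    cdf[-1] = 1.0
    # keyword -> prototype indices containing it (anchored polyform drawing)
    by_keyword: dict[str, list[int]] = {}
    for idx, t in enumerate(pool):
        for kw in t:
            by_keyword.setdefault(kw, []).append(idx)
    anchor_cdf: dict[str, np.ndarray] = {}
    for kw, idxs in by_keyword.items():
        w = weights[np.array(idxs)]
        c = np.cumsum(w / w.sum())
        c[-1] = 1.0
        anchor_cdf[kw] = c

    vocab_n = config.keyword_vocab_size
    tus: list[TranscriptionalUnit] = []
    for i in range(n):
        tu_id = f"{config.organism}TU{i + 1:06d}"
        n_sv = int(sv_counts[i])
        tu = TranscriptionalUnit(tu_id)
        if i in unannot_idx:
            kw_sets = [frozenset()] * n_sv
        else:
            if i in poly_idx:
                cap = min(config.max_fls_per_tu, n_sv)
                extra = int(_sample_disc_exp(
                    rng, 1, config.fl_per_tu_exp_b, 0, cap - 2
                )[0])
                n_fl = 2 + extra
                idxs = _draw_anchored(rng, pool, cdf, by_keyword,
                                      anchor_cdf, n_fl)
                fls = [pool[j] for j in idxs]
            else:
                n_fl = 1
                fls = [pool[_weighted_distinct(rng, cdf, 1)[0]]]
            if i in switch_idx:
                # force one disjoint pair: two fresh sets from disjoint vocab halves
                a = tuple(sorted(
                    f"KW-{v:04d}" for v in rng.choice(
                        vocab_n // 2, size=2, replace=False)
                ))
                bset = tuple(sorted(
                    f"KW-{v:04d}" for v in rng.choice(
                        np.arange(vocab_n // 2, vocab_n), size=2, replace=False)
                ))
                fls[0], fls[1] = a, bset
            # each FL realized by >=1 splice variant, rest reuse existing FLs
            assignment = list(range(n_fl)) + [
                int(rng.integers(0, n_fl)) for _ in range(n_sv - n_fl)
            ]
            kw_sets = [frozenset(fls[j]) for j in assignment]
        for j, kws in enumerate(kw_sets, start=1):
            tu.proteins.append(ProteinRecord(f"{tu_id}_sv{j}", tu_id, kws))
        tus.append(tu)

    dataset = OrganismDataset(organism=config.organism, tus=tus)
    build_catalogue(dataset, scope=config.organism)
    return dataset


# --------------------------------------------------------------------------
# Exact fixtures from printed marginal counts
# --------------------------------------------------------------------------


def fixture_histogram(
    total_events: int, total_objects: int, n1: int, J: int
) -> FrequencyDistribution:
    """Histogram whose (total_events, total_objects, n1, J) are exact.

    ``n1`` objects sit at m=1; one object is pinned at m=J; the remaining
    objects are spread over 2..J as evenly as feasible (greedy fill).
    Raises on an infeasible specification.
    """
    if not (0 <= n1 <= total_objects):
        raise ValueError("need 0 <= n1 <= total_objects")
    R = total_objects - n1  # objects with m >= 2
    S = total_events - n1  # their event mass
    if R == 0:
        if S != 0 or J != 1 or n1 == 0:
            raise ValueError("all-singleton spec requires J=1 and events=objects")
        return FrequencyDistribution({1: n1})
    if J < 2:
        raise ValueError("J must be >= 2 when non-singleton objects exist")
    if not (2 * (R - 1) <= S - J <= (R - 1) * J):
        raise ValueError("infeasible spec: event total out of range for J")
    counts: dict[int, int] = {}
    if n1:
        counts[1] = n1
    counts[J] = 1
    rem = S - J - 2 * (R - 1)  # extra mass to lift objects above m=2
    q, r = (divmod(rem, J - 2) if J > 2 else (0, rem))
    if J == 2 and rem != 0:
        raise ValueError("infeasible spec at J=2")
    counts[J] += q
    left = R - 1 - q
    if r:
        counts[2 + r] = counts.get(2 + r, 0) + 1
        left -= 1
    if left < 0:
        raise ValueError("infeasible spec: not enough objects for event total")
    if left:
        counts[2] = counts.get(2, 0) + left
    freq = FrequencyDistribution(counts)
    assert freq.M == total_objects and freq.total_events == total_events
    assert freq.J == J and freq.n1 == n1
    return freq


def fixture_dataset(
    n_poly: int, n_mono: int, n_unannotated: int = 0,
    organism: str = "fixture", n_switch: int = 0,
) -> OrganismDataset:
    """Minimal dataset with exact monoform/polyform/unannotated counts.

    Monoform TUs carry one single-FL protein; polyform TUs two proteins
    with overlapping two-FL annotation; the first ``n_switch`` polyform
    TUs instead carry a disjoint (functional-switch) pair.
    """
    if n_switch > n_poly:
        raise ValueError("n_switch cannot exceed n_poly")
    tus: list[TranscriptionalUnit] = []
    idx = 0
    for i in range(n_poly):
        idx += 1
        tu = TranscriptionalUnit(f"{organism}P{idx}")
        if i < n_switch:
            sets = [frozenset({"SwitchA"}), frozenset({"SwitchB"})]
        else:
            sets = [frozenset({"Common", "Alpha"}), frozenset({"Common", "Beta"})]
        for j, s in enumerate(sets, 1):
            tu.proteins.append(ProteinRecord(f"{tu.tu_id}_sv{j}", tu.tu_id, s))
        tus.append(tu)
    for _ in range(n_mono):
        idx += 1
        tu = TranscriptionalUnit(f"{organism}M{idx}")
        tu.proteins.append(
            ProteinRecord(f"{tu.tu_id}_sv1", tu.tu_id, frozenset({"Mono"}))
        )
        tus.append(tu)
    for _ in range(n_unannotated):
        idx += 1
        tu = TranscriptionalUnit(f"{organism}U{idx}")
        tu.proteins.append(ProteinRecord(f"{tu.tu_id}_sv1", tu.tu_id, frozenset()))
        tus.append(tu)
    dataset = OrganismDataset(organism=organism, tus=tus)
    build_catalogue(dataset, scope=organism)
    return dataset


def fixture_from_counts(spec: dict):
    """Build an exact fixture from a dict of printed marginal counts.

    Histogram mode keys: total_events, total_objects, n1, J. Dataset mode
    keys: n_poly, n_mono (optional n_unannotated, n_switch, organism).
    """
    if {"total_events", "total_objects", "n1", "J"} <= set(spec):
        return fixture_histogram(
            spec["total_events"], spec["total_objects"], spec["n1"], spec["J"]
        )
    if {"n_poly", "n_mono"} <= set(spec):
        return fixture_dataset(
            spec["n_poly"], spec["n_mono"],
            spec.get("n_unannotated", 0),
            spec.get("organism", "fixture"),
            spec.get("n_switch", 0),
        )
    raise ValueError(f"unrecognized fixture spec keys: {sorted(spec)}")
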