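"""Gene-set enrichment and list-overlap statistics.

A gene set (pathway) is enriched in a query list when the list contains
more of the set's members than expected by chance given the universe of
detectable genes; the members that drive the enrichment — the "found
entities" — are recorded with each result, because the same pathway can be
enriched in different lists through the same, distinct or partially
overlapping found-entity sets.  The p-value is the exact upper tail of the
hypergeometric distribution.  Disease-gene enrichment against a published
background proportion is phrased as a one-sided binomial test instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from retorg.datatypes import GeneList, ValidationError

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets, optionally carrying a hierarchy path per set."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    hierarchy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]


@dataclass
class EnrichmentResult:
    set_name: str
    query_name: str
    universe_size: int
    set_size: int
    query_size: int
    found_entities: frozenset[str]
    p_value: float
    q_value: float = float("nan")

    @property
    def overlap(self) -> int:
        return len(self.found_entities)


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` successes observed when drawing ``n`` items from a universe of
    ``N`` that contains ``K`` marked items.  Exact and computed through the
    survival function, which scipy evaluates stably in log space.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValidationError(
            f"inconsistent hypergeometric counts k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_collection(
    query: GeneList,
    sets: GeneSetCollection,
    universe: GeneList,
    keep_p: float = 0.01,
) -> list[EnrichmentResult]:
    """Test every set for over-representation in ``query``.

    Query genes absent from the universe are dropped with a logged count;
    each set is restricted to the universe before testing.  BH q-values are
    computed across the whole collection and results with p <= ``keep_p``
    are returned, ordered by increasing p.
    """
    from retorg.diffexp import adjust_fdr

    uni = set(universe.genes)
    if not uni:
        raise ValidationError("empty gene universe")
    q_genes = set(query.genes) & uni
    dropped = len(query.genes) - len(q_genes)
    if dropped:
        log.warning(
            "%d/%d query genes absent from the universe were ignored",
            dropped, len(query.genes),
        )
    results = []
    for name in sorted(sets.sets):
        members = sets[name] & uni
        if not members:
            continue
        found = frozenset(q_genes & members)
        p = hypergeom_upper(len(found), len(q_genes), len(members), len(uni))
        results.append(
            EnrichmentResult(
                set_name=name,
                query_name=query.name,
                universe_size=len(uni),
                set_size=len(members),
                query_size=len(q_genes),
                found_entities=found,
                p_value=p,
            )
        )
    if results:
        qvals = adjust_fdr(np.array([r.p_value for r in results]))
        for r, q in zip(results, qvals):
            r.q_value = float(q)
    kept = [r for r in results if r.p_value <= keep_p]
    kept.sort(key=lambda r: (r.p_value, r.set_name))
    return kept


def overlap_test(size_a: int, size_b: int, overlap: int, universe_size: int) -> float:
    """Significance of the overlap between two lists drawn from one universe.

    Hypergeometric upper tail with ``overlap`` successes among ``size_a``
    draws when ``size_b`` of the ``universe_size`` items are marked.  Used
    e.g. for the overlap between cell-type-specifying TFs and
    condition-responsive TFs out of a catalogue of ~1500 TFs.
    """
    if overlap > min(size_a, size_b):
        raise ValidationError("overlap cannot exceed either list size")
    if max(size_a, size_b) > universe_size:
        raise ValidationError("list larger than universe")
    return hypergeom_upper(overlap, size_a, size_b, universe_size)


def proportion_enrichment(
    hits: int,
    trials: int,
    background_rate: float,
    round_to_integer: bool = False,
) -> tuple[float, float]:
    """Percentage of hits plus a one-sided binomial test against a background.

    Returns ``(percent, p_value)`` where percent is 100*hits/trials rounded
    to one decimal (or to the nearest integer when ``round_to_integer``)
    and p is P(X >= hits) for X ~ Binomial(trials, background_rate).
    """
    if not 0 <= hits <= trials:
        raise ValidationError("hits must lie in [0, trials]")
    if not 0 < background_rate < 1:
        raise ValidationError("background_rate must lie in (0, 1)")
    pct = 100.0 * hits / trials
    percent = float(round(pct)) if round_to_integer else round(pct, 1)
    if hits == 0:
        return percent, 1.0
    p = stats.binomtest(hits, trials, background_rate, alternative="greater").pvalue
    return percent, float(p)
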