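"""Over-representation analysis of candidate gene lists.

Observed-vs-expected category counts with a hypergeometric upper-tail
p-value: given a universe of U genes (all annotated genes on the chip), a
category of K genes and a selected list of n genes with k overlapping the
category,

    expected = n * K / U
    p = P(X >= k),  X ~ Hypergeometric(U, K, n)

One-sided (enrichment only). Duplicate symbols collapse to one gene
before counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from scipy import stats

from .data import GeneSetCollection, ValidationError
from .de import bh_adjust


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    source: Optional[str]
    observed: int
    expected: float
    p_value: float
    category_size: int
    selected_size: int
    universe_size: int


def ora_test(
    selected: Iterable[str],
    category: Iterable[str],
    universe: Iterable[str],
    name: str = "",
    source: Optional[str] = None,
) -> EnrichmentResult:
    """Hypergeometric over-representation test of one category.

    ``selected`` must be a subset of ``universe``; ``category`` is
    intersected with the universe before testing. An empty selected list
    gives observed 0, p = 1; an empty universe is an error.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    sel = set(selected)
    stray = sel - uni
    if stray:
        raise ValidationError(
            f"selected gene {sorted(stray)[0]!r} not in the universe"
        )
    cat = set(category) & uni
    k = len(sel & cat)
    expected = len(sel) * len(cat) / len(uni)
    # upper tail P(X >= k); sf(k-1) = P(X > k-1)
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(cat), len(sel)))
    p = min(max(p, 0.0), 1.0) if k > 0 else 1.0
    return EnrichmentResult(
        category=name,
        source=source,
        observed=k,
        expected=expected,
        p_value=p,
        category_size=len(cat),
        selected_size=len(sel),
        universe_size=len(uni),
    )


def enrich_all(
    selected: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_category: int = 3,
) -> pd.DataFrame:
    """Test every category of a collection; one row per category, sorted by p.

    Categories smaller than ``min_category`` after universe intersection
    are dropped. A BH-adjusted column across the tested categories is
    included alongside the raw p.
    """
    uni = set(universe)
    sel = set(selected)
    rows = []
    for name, members in collection.items():
        res = ora_test(sel, members, uni, name=name, source=collection.source)
        if res.category_size < min_category:
            continue
        rows.append(res)
    if not rows:
        return pd.DataFrame(
            columns=["category", "source", "observed", "expected", "p_value", "padj",
                     "category_size", "selected_size", "universe_size"]
        )
    table = pd.DataFrame([r.__dict__ for r in rows])
    table["padj"] = bh_adjust(table["p_value"].to_numpy())
    table = table.sort_values(["p_value", "category"], kind="stable").reset_index(drop=True)
    cols = ["category", "source", "observed", "expected", "p_value", "padj",
            "category_size", "selected_size", "universe_size"]
    return table[cols]
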