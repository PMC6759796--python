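"""Hypergeometric over-representation analysis against GMT gene sets.

For a query set of n genes drawn from a universe of N genes, a term
annotating K genes and overlapping the query in k, the one-sided
p-value is the hypergeometric upper tail P(X >= k); the two-sided
p-value doubles the smaller tail, capped at 1.  Two significance
regimes mirror common practice for herbal-formula target sets:
p <= 0.01 for biological-process terms and p <= 0.05 for pathway terms,
both on raw p-values (Benjamini-Hochberg adjustment is opt-in).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .symbols import TargetSet, normalize_symbol

#: Default significance cutoffs (inclusive) per annotation regime.
ALPHA_BIOLOGICAL_PROCESS = 0.01
ALPHA_PATHWAY = 0.05

RESULT_COLUMNS = ["term_id", "term_name", "k", "K", "n", "N", "p_value", "significant"]


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    term_name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id!r} has no members")
        object.__setattr__(self, "members",
                           frozenset(normalize_symbol(m) for m in self.members))


def terms_from_gmt(rows) -> list[AnnotationTerm]:
    """Adapt (term, description, members) tuples (e.g. from io.read_gmt)."""
    return [AnnotationTerm(t, d, m) for t, d, m in rows]


def hypergeometric_p(k: int, K: int, n: int, N: int, sided: str = "two") -> float:
    """Hypergeometric tail probability for an overlap of k.

    X ~ Hypergeom(N, K, n).  ``sided="one"`` gives the upper tail
    P(X >= k); ``sided="two"`` gives min(1, 2*min(P(X >= k), P(X <= k))).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    rv = hypergeom(N, K, n)
    upper = float(rv.sf(k - 1))  # P(X >= k)
    if sided == "one":
        return min(upper, 1.0)
    if sided == "two":
        lower = float(rv.cdf(k))  # P(X <= k)
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")


def enrich(query: TargetSet, terms, universe: TargetSet | None = None,
           alpha: float = ALPHA_BIOLOGICAL_PROCESS, sided: str = "two",
           adjust: bool = False) -> pd.DataFrame:
    """Over-representation of ``query`` in each annotation term.

    The universe defaults to the union of all term members.  Query
    symbols outside the universe are dropped with a warning.  Terms with
    zero overlap are excluded.  Results are sorted by p ascending, ties
    by term_id; ``significant`` means p <= alpha (inclusive) on the raw
    p-value, or on the BH-adjusted q-value when ``adjust`` is on (the
    q-values are added as a ``q_value`` column).
    """
    import warnings

    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    terms = list(terms)
    if universe is None:
        members = frozenset().union(*(t.members for t in terms)) if terms else frozenset()
        universe = TargetSet("universe", members, provenance="union of term members")
    if len(universe) == 0:
        raise ValueError("empty universe")
    qs = query.symbols & universe.symbols
    dropped = query.symbols - universe.symbols
    if dropped:
        warnings.warn(f"{len(dropped)} query symbols outside the universe were dropped",
                      stacklevel=2)
    N, n = len(universe), len(qs)
    rows = []
    for t in terms:
        members = t.members & universe.symbols
        k = len(members & qs)
        if k == 0:
            continue
        p = hypergeometric_p(k, len(members), n, N, sided=sided)
        rows.append((t.term_id, t.term_name, k, len(members), n, N, p))
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    if adjust and not df.empty:
        from statsmodels.stats.multitest import multipletests
        _, q, _, _ = multipletests(df["p_value"], method="fdr_bh")
        df["q_value"] = q
        df["significant"] = df["q_value"] <= alpha
    else:
        df["significant"] = df["p_value"] <= alpha
    return df


def write_enrichment_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
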