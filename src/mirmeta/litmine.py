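"""Literature co-citation scoring for gene–disease association.

Given a corpus of N articles in which the disease appears in n articles, a
gene in m, and both together in k, the association score is the upper-tail
hypergeometric probability

    p = P(X >= k),   X ~ Hypergeometric(N, n, m),

i.e. the chance of observing at least k co-citations if the gene's articles
were drawn at random from the corpus.  Counting is at the document level:
an article contributes at most one unit to each of n, m, k.

The tail is evaluated in log space (log-pmf + logsumexp over the upper
range), which stays finite at corpus scale where the factorial form of the
pmf overflows.  An alias table maps free-text gene mentions to canonical
symbols before counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "CocitationQuery",
    "CocitationScore",
    "AliasMap",
    "hypergeom_upper_tail",
    "cocitation_pvalue",
    "normalize_mentions",
    "score_corpus",
    "read_alias_tsv",
    "read_counts_tsv",
]


@dataclass(frozen=True)
class CocitationQuery:
    """Corpus counts (N, n, m, k) for one gene–disease pair."""

    N: int
    n: int
    m: int
    k: int

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError(f"corpus size N must be positive, got {self.N}")
        if not 0 <= self.n <= self.N:
            raise ValueError(f"need 0 <= n <= N, got n={self.n}, N={self.N}")
        if not 0 <= self.m <= self.N:
            raise ValueError(f"need 0 <= m <= N, got m={self.m}, N={self.N}")
        if not 0 <= self.k <= min(self.n, self.m):
            raise ValueError(
                f"need 0 <= k <= min(n, m), got k={self.k}, n={self.n}, m={self.m}"
            )
        if self.n + self.m - self.k > self.N:
            raise ValueError("n + m − k exceeds corpus size N")


@dataclass(frozen=True)
class CocitationScore:
    query: CocitationQuery
    p: float


def hypergeom_upper_tail(N: int, n: int, m: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population N, successes n, draws m).

    Computed as exp(logsumexp(log pmf)) over the support [k, min(n, m)], so
    it equals 1 − Σ_{i<k} pmf(i) to floating precision while remaining
    stable for corpus-scale N.
    """
    if k <= 0:
        return 1.0
    hi = min(n, m)
    if k > hi:
        return 0.0
    # support below also bounded by max(0, m - (N - n))
    i = np.arange(k, hi + 1)
    p = float(np.exp(logsumexp(stats.hypergeom.logpmf(i, N, n, m))))
    return min(1.0, max(0.0, p))


def cocitation_pvalue(q: CocitationQuery) -> CocitationScore:
    """Score one gene–disease pair by its upper-tail co-citation probability."""
    return CocitationScore(query=q, p=hypergeom_upper_tail(q.N, q.n, q.m, q.k))


class AliasMap:
    """Case-insensitive many-to-one map from mention strings to gene symbols."""

    def __init__(self, mapping: Mapping[str, str]):
        self._map = {k.strip().lower(): v.strip().upper() for k, v in mapping.items()}

    def __len__(self) -> int:
        return len(self._map)

    def lookup(self, mention: str) -> str | None:
        return self._map.get(mention.strip().lower())


def read_alias_tsv(path) -> AliasMap:
    """Load an alias table (columns: mention, symbol)."""
    df = pd.read_csv(path, sep="\t")
    if not {"mention", "symbol"} <= set(df.columns):
        raise ValueError("alias TSV needs columns mention, symbol")
    return AliasMap(dict(zip(df["mention"], df["symbol"])))


def normalize_mentions(
    mentions: Iterable[str], aliases: AliasMap
) -> tuple[list[str], list[str]]:
    """Canonicalize one document's gene mentions.

    Returns ``(symbols, unknown)``: the unique canonical symbols (first-seen
    order, one per document however often mentioned) and the unrecognized
    mentions, passed through verbatim so no signal is silently dropped.
    """
    symbols: list[str] = []
    unknown: list[str] = []
    seen: set[str] = set()
    for mention in mentions:
        canon = aliases.lookup(mention)
        if canon is None:
            unknown.append(mention)
            continue
        if canon not in seen:
            seen.add(canon)
            symbols.append(canon)
    return symbols, unknown


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "m", "k"} <= set(df.columns):
        raise ValueError("count TSV needs columns gene, m, k")
    return df


def score_corpus(
    counts: pd.DataFrame,
    N: int,
    n: int,
    alpha: float = 0.05,
    bh: bool = False,
) -> pd.DataFrame:
    """Score a (gene, m, k) count table against a disease with n articles.

    Rows are ranked ascending by p, ties broken by descending k then gene
    symbol; rows with p <= alpha are flagged as disease-related.  Malformed
    rows are reported in the ``error`` column and excluded from ranking
    rather than aborting the run.  ``bh=True`` adds Benjamini–Hochberg
    adjusted values in a ``q`` column (off by default: the original analysis
    reported raw per-gene p).
    """
    rows = []
    errors = []
    for idx, row in counts.iterrows():
        try:
            q = CocitationQuery(N=int(N), n=int(n), m=int(row["m"]), k=int(row["k"]))
            rows.append(
                {"gene": str(row["gene"]), "m": q.m, "k": q.k, "p": cocitation_pvalue(q).p}
            )
        except (ValueError, KeyError) as exc:
            errors.append({"row": int(idx), "gene": str(row.get("gene", "?")), "error": str(exc)})
    out = pd.DataFrame(rows, columns=["gene", "m", "k", "p"])
    if not out.empty:
        out = out.sort_values(
            ["p", "k", "gene"], ascending=[True, False, True], kind="mergesort"
        ).reset_index(drop=True)
        out["flagged"] = out["p"] <= alpha
        if bh:
            p = out["p"].to_numpy()
            order = np.argsort(p, kind="mergesort")
            q = np.empty_like(p)
            ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
            q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
            out["q"] = np.minimum(q, 1.0)
    else:
        out["flagged"] = pd.Series(dtype=bool)
    out.attrs["errors"] = errors
    return out
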