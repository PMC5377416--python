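"""Seeded synthetic-data generators for every pipeline stage.

Each generator produces inputs with exactly the statistical structure the
corresponding analysis stage assumes, so the full pipeline can be exercised
and validated without any external download:

* Gaussian two-group cohorts with specified per-arm n / mean / SD;
* study panels drawn from a random-effects model (a true SMD plus
  between-study heterogeneity tau);
* literature corpora whose co-citation counts follow the hypergeometric
  null, with optional planted gene–disease associations;
* prediction matrices with planted consensus targets and sub-threshold
  decoys;
* pathway collections with one planted enriched set;
* interaction networks realizing a prescribed degree sequence exactly.

All generators are bit-reproducible given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import GroupSummary, StudySummary, summarize_samples
from .network import GeneSet
from .voting import DEFAULT_PLATFORMS, PredictionMatrix

__all__ = [
    "CohortSpec",
    "MetaPanelSpec",
    "CorpusSpec",
    "gen_cohort",
    "gen_meta_panel",
    "gen_corpus",
    "gen_predictions",
    "gen_pathways",
    "gen_network",
]


@dataclass(frozen=True)
class CohortSpec:
    """Two-arm Gaussian cohort: per-arm size, mean and SD, plus a seed."""

    n_case: int
    n_control: int
    mean_case: float
    mean_control: float
    sd_case: float
    sd_control: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("arm sizes must be >= 2")
        if self.sd_case <= 0 or self.sd_control <= 0:
            raise ValueError("arm SDs must be positive")


@dataclass(frozen=True)
class MetaPanelSpec:
    """Random-effects panel: K studies around a true SMD with spread tau."""

    K: int
    true_smd: float
    tau: float
    n_range: tuple[int, int] = (20, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.n_range[0] < 2 or self.n_range[1] < self.n_range[0]:
            raise ValueError("invalid per-arm size range")


@dataclass(frozen=True)
class CorpusSpec:
    """Hypergeometric-null corpus with optional planted associations.

    ``enrichment_factors`` multiplies each gene's *expected* co-citation
    count: factor 1 is the exact null, factor 5 plants a strong
    association.  A scalar applies to every gene.
    """

    N: int
    n: int
    gene_count: int
    enrichment_factors: float | Sequence[float] = 1.0
    m_range: tuple[int, int] = (50, 500)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n <= self.N:
            raise ValueError("need 0 < n <= N")
        if self.gene_count < 0:
            raise ValueError("gene_count must be >= 0")
        factors = np.atleast_1d(np.asarray(self.enrichment_factors, dtype=float))
        if np.any(factors < 0):
            raise ValueError("enrichment factors must be >= 0")
        if factors.size not in (1, self.gene_count):
            raise ValueError("enrichment_factors must be scalar or one per gene")
        if self.m_range[0] < 0 or self.m_range[1] > self.N or self.m_range[1] < self.m_range[0]:
            raise ValueError("invalid m_range for corpus size")


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample-level two-group table (sample_id, group, value)."""
    rng = np.random.default_rng(spec.seed)
    case = rng.normal(spec.mean_case, spec.sd_case, spec.n_case)
    control = rng.normal(spec.mean_control, spec.sd_control, spec.n_control)
    return pd.DataFrame(
        {
            "sample_id": [f"CASE{i+1:04d}" for i in range(spec.n_case)]
            + [f"CTRL{i+1:04d}" for i in range(spec.n_control)],
            "group": ["case"] * spec.n_case + ["control"] * spec.n_control,
            "value": np.concatenate([case, control]),
        }
    )


def gen_meta_panel(spec: MetaPanelSpec) -> list[StudySummary]:
    """Panel of study summaries from the random-effects generating model.

    Per study, a latent effect theta_i ~ Normal(true_smd, tau²) shifts the
    case arm of a unit-variance Gaussian cohort; the emitted summaries are
    the empirical per-arm n / mean / SD, so sampling error enters exactly as
    the SMD machinery assumes.
    """
    rng = np.random.default_rng(spec.seed)
    studies = []
    for i in range(spec.K):
        theta = rng.normal(spec.true_smd, spec.tau)
        n1 = int(rng.integers(spec.n_range[0], spec.n_range[1] + 1))
        n2 = int(rng.integers(spec.n_range[0], spec.n_range[1] + 1))
        case = summarize_samples(rng.normal(theta, 1.0, n1))
        control = summarize_samples(rng.normal(0.0, 1.0, n2))
        studies.append(
            StudySummary(study_id=f"SYN{i+1:03d}", case=case, control=control, source="synthetic")
        )
    return studies


def gen_corpus(spec: CorpusSpec) -> pd.DataFrame:
    """Co-citation count table (gene, m, k) under the (possibly tilted) null.

    Per gene, m is uniform on ``m_range`` and k is drawn hypergeometrically
    (corpus N, disease n, gene m); a factor f ≠ 1 then shifts k by
    (f − 1)·E[k], capped at min(n, m) — so f = 1 reproduces the null
    exactly and f = 5 plants a gene whose co-citations are ~5× expectation.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.gene_count == 0:
        return pd.DataFrame(columns=["gene", "m", "k"])
    factors = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.enrichment_factors, dtype=float)), (spec.gene_count,)
    )
    m = rng.integers(spec.m_range[0], spec.m_range[1] + 1, size=spec.gene_count)
    k_null = rng.hypergeometric(spec.n, spec.N - spec.n, m)
    expected = spec.n * m / spec.N
    k = k_null + np.rint((factors - 1.0) * expected).astype(int)
    k = np.clip(k, 0, np.minimum(spec.n, m))
    return pd.DataFrame(
        {"gene": [f"G{i+1:05d}" for i in range(spec.gene_count)], "m": m, "k": k}
    )


def gen_predictions(
    n_targets: int,
    n_decoys: int,
    platforms: Sequence[str] = DEFAULT_PLATFORMS,
    seed: int = 0,
    threshold: int = 4,
) -> PredictionMatrix:
    """Prediction matrix with planted consensus targets.

    Targets receive between ``threshold`` and all platforms' votes; decoys
    receive between 0 and ``threshold − 1``, so consensus voting at
    ``threshold`` recovers exactly the planted targets.
    """
    if not 1 <= threshold <= len(platforms):
        raise ValueError("threshold out of range for platform count")
    rng = np.random.default_rng(seed)
    n_plat = len(platforms)
    genes = [f"TARGET{i+1:04d}" for i in range(n_targets)] + [
        f"DECOY{i+1:04d}" for i in range(n_decoys)
    ]
    votes = np.zeros((len(genes), n_plat), dtype=bool)
    for row in range(n_targets):
        n_votes = int(rng.integers(threshold, n_plat + 1))
        votes[row, rng.choice(n_plat, size=n_votes, replace=False)] = True
    for row in range(n_targets, len(genes)):
        n_votes = int(rng.integers(0, threshold))
        if n_votes:
            votes[row, rng.choice(n_plat, size=n_votes, replace=False)] = True
    return PredictionMatrix(genes=tuple(genes), platforms=tuple(platforms), votes=votes)


def gen_pathways(
    query: Sequence[str],
    background: Sequence[str],
    n_pathways: int = 10,
    pathway_size: int = 20,
    planted_frac: float = 0.8,
    seed: int = 0,
) -> list[GeneSet]:
    """Pathway collection with one planted enriched set (``PLANTED``).

    The planted pathway draws ``planted_frac`` of its members from the
    query set and the rest from the background; decoy pathways
    (``DECOY01`` …) are uniform draws from the background.
    """
    if not 0 <= planted_frac <= 1:
        raise ValueError("planted_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    query = sorted({str(g).upper() for g in query})
    background = sorted({str(g).upper() for g in background} | set(query))
    n_from_query = min(int(round(planted_frac * pathway_size)), len(query))
    planted = list(rng.choice(query, size=n_from_query, replace=False))
    rest_pool = sorted(set(background) - set(planted))
    planted += list(rng.choice(rest_pool, size=pathway_size - n_from_query, replace=False))
    sets = [GeneSet.from_iterable("PLANTED", planted)]
    for i in range(n_pathways - 1):
        members = rng.choice(background, size=pathway_size, replace=False)
        sets.append(GeneSet.from_iterable(f"DECOY{i+1:02d}", members))
    return sets


def gen_network(degree_plan: Mapping[str, int], seed: int = 0) -> pd.DataFrame:
    """Edge table realizing ``degree_plan`` exactly (Havel–Hakimi pairing).

    The construction repeatedly connects the highest-remaining-degree node
    to the next-highest ones; ties are broken by a seeded shuffle, which
    never affects realizability.  Non-graphical plans (odd degree sum, or
    failing the Erdős–Gallai condition) raise ``ValueError``.
    """
    degrees = {str(g): int(d) for g, d in degree_plan.items()}
    if any(d < 0 for d in degrees.values()):
        raise ValueError("degrees must be non-negative")
    if sum(degrees.values()) % 2 != 0:
        raise ValueError("degree plan has odd sum: not graphical (handshake lemma)")
    rng = np.random.default_rng(seed)
    order = list(degrees)
    rng.shuffle(order)
    remaining = {g: degrees[g] for g in order}
    edges: list[tuple[str, str]] = []
    while True:
        active = sorted(
            (g for g, d in remaining.items() if d > 0),
            key=lambda g: (-remaining[g], order.index(g)),
        )
        if not active:
            break
        head, rest = active[0], active[1:]
        need = remaining[head]
        if need > len(rest):
            raise ValueError("degree plan is not graphical")
        for partner in rest[:need]:
            edges.append(tuple(sorted((head, partner))))
            remaining[partner] -= 1
        remaining[head] = 0
    df = pd.DataFrame(sorted(edges), columns=["source_symbol", "target_symbol"])
    df.attrs["degree_plan"] = degrees
    return df
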