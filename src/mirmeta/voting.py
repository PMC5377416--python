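"""Consensus microRNA target prediction by cross-platform voting.

Each of several prediction platforms nominates a set of candidate target
genes for the microRNA; a gene is accepted as a consensus target when at
least ``threshold`` platforms nominate it (default 4, out of the 11
platforms the original analysis combined).  Nominations are binary — the
platforms' internal scores are not modeled.  Symbols are upper-cased (and
optionally alias-normalized) before tallying so that the same gene reported
under different names is merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .litmine import AliasMap

__all__ = [
    "DEFAULT_PLATFORMS",
    "PredictionMatrix",
    "tally_votes",
    "consensus_targets",
    "read_predictions_tsv",
    "write_votes_tsv",
]

# the 11 platforms combined in the original analysis
DEFAULT_PLATFORMS = (
    "TargetScan",
    "MirTarget2",
    "DIANA-microT",
    "PicTar",
    "PITA",
    "MicroInspector",
    "miRanda",
    "RNA22",
    "miTarget",
    "RNAhybrid",
    "NBmiRTar",
)


@dataclass(frozen=True)
class PredictionMatrix:
    """Boolean gene × platform nomination matrix with ordered labels."""

    genes: tuple[str, ...]
    platforms: tuple[str, ...]
    votes: np.ndarray  # bool, shape (len(genes), len(platforms))

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene labels in prediction matrix")
        if len(set(self.platforms)) != len(self.platforms):
            raise ValueError("duplicate platform labels in prediction matrix")
        if self.votes.shape != (len(self.genes), len(self.platforms)):
            raise ValueError("votes shape does not match labels")

    @classmethod
    def from_platform_lists(
        cls,
        nominations: Mapping[str, Iterable[str]],
        aliases: AliasMap | None = None,
    ) -> "PredictionMatrix":
        """Build a matrix from one nominated-gene list per platform.

        Symbols are upper-cased; with an alias map, mentions are first
        resolved to canonical symbols (unknowns kept upper-cased as-is).
        """
        platforms = tuple(nominations.keys())
        per_platform: dict[str, set[str]] = {}
        for plat, genes in nominations.items():
            canon = set()
            for gene in genes:
                sym = aliases.lookup(gene) if aliases is not None else None
                canon.add(sym if sym is not None else str(gene).strip().upper())
            per_platform[plat] = canon
        all_genes = tuple(sorted(set().union(*per_platform.values()) if per_platform else set()))
        votes = np.zeros((len(all_genes), len(platforms)), dtype=bool)
        index = {g: i for i, g in enumerate(all_genes)}
        for j, plat in enumerate(platforms):
            for gene in per_platform[plat]:
                votes[index[gene], j] = True
        return cls(genes=all_genes, platforms=platforms, votes=votes)


def read_predictions_tsv(path, aliases: AliasMap | None = None) -> PredictionMatrix:
    """Read a long-format (gene, platform) nomination table."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "platform"} <= set(df.columns):
        raise ValueError("prediction TSV needs columns gene, platform")
    nominations: dict[str, list[str]] = {}
    for plat, sub in df.groupby("platform", sort=False):
        nominations[str(plat)] = [str(g) for g in sub["gene"]]
    return PredictionMatrix.from_platform_lists(nominations, aliases=aliases)


def tally_votes(matrix: PredictionMatrix) -> pd.DataFrame:
    """Per-gene count of nominating platforms (columns: gene, vote_count)."""
    return pd.DataFrame(
        {"gene": list(matrix.genes), "vote_count": matrix.votes.sum(axis=1).astype(int)}
    )


def consensus_targets(matrix: PredictionMatrix, threshold: int = 4) -> list[str]:
    """Sorted genes nominated by at least ``threshold`` platforms."""
    if not 1 <= threshold <= len(matrix.platforms):
        raise ValueError(
            f"threshold must be in [1, {len(matrix.platforms)}], got {threshold}"
        )
    counts = matrix.votes.sum(axis=1)
    return sorted(g for g, c in zip(matrix.genes, counts) if c >= threshold)


def write_votes_tsv(matrix: PredictionMatrix, path, threshold: int = 4) -> None:
    df = tally_votes(matrix)
    df["accepted"] = df["vote_count"] >= threshold
    df.sort_values("gene", kind="mergesort").to_csv(path, sep="\t", index=False)
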