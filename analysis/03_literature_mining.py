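#!/usr/bin/env python
"""Literature co-citation scoring on a synthetic corpus.

The original disease-gene list came from scoring article co-occurrence
counts against a hypergeometric null; the raw corpus is not
redistributable, so this driver scores a seeded synthetic corpus (2000
genes, one planted association at 5x the expected co-citation count) and
shows the planted gene is recovered at the top of the ranking.

Writes results/cocitation_scores.tsv.
"""

from pathlib import Path

from mirmeta.litmine import score_corpus
from mirmeta.synth import CorpusSpec, gen_corpus

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    spec = CorpusSpec(
        N=1_000_000,           # corpus size
        n=64_577,              # disease-related articles (published entry count)
        gene_count=2000,
        enrichment_factors=[5.0] + [1.0] * 1999,
        seed=1,
    )
    scored = score_corpus(gen_corpus(spec), N=spec.N, n=spec.n, alpha=0.05)
    scored.to_csv(OUT / "cocitation_scores.tsv", sep="\t", index=False)
    top = scored.iloc[0]
    print(f"top-ranked gene: {top.gene} (m={top.m}, k={top.k}, p={top.p:.3g})")
    print(f"flagged at alpha=0.05: {int(scored.flagged.sum())}/{len(scored)} "
          f"({100 * scored.flagged.mean():.1f}%; null genes alone would give ~<5%)")
    assert top.gene == "G00001", "planted association should rank first"


if __name__ == "__main__":
    main()
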