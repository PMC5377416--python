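"""End-to-end orchestration of the integrative analysis.

``run_pipeline`` executes the stages in dependency order — cohort statistics
→ meta-analysis, literature scoring + consensus voting → integration →
enrichment / connectivity / network export — writing one TSV per stage plus
a JSON run manifest (package version, seed, config hash, per-stage
summaries).  Identical config + seed produces byte-identical stage TSVs;
wall-clock timestamps live only in the manifest.

Published-cohort stages (stats, meta, connect, network) default to the
packaged fixtures; corpus, prediction, and pathway stages are fed by the
seeded synthetic generators since their upstream raw inputs (article texts,
platform outputs) are outside the package's scope.  All stage seeds are
derived deterministically from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .cohort import StudySummary, fold_change, read_summary_tsv, welch_t
from .datasets import HUB_GENES, load_hub_network, load_study_table
from .litmine import score_corpus
from .meta import begg_test, egger_test, forest_table, funnel_points, hedges_g, leave_one_out, select_model
from .network import (
    GeneSet,
    Network,
    connectivity_ztest,
    export_network,
    import_network,
    intersect_sets,
    pathway_enrichment,
    write_gmt,
)
from .synth import CorpusSpec, gen_corpus, gen_pathways, gen_predictions
from .voting import consensus_targets, tally_votes

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "derive_seed"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "stages": {
        "stats": True,
        "meta": True,
        "cocite": True,
        "vote": True,
        "integrate": True,
        "enrich": True,
        "connect": True,
        "network": True,
    },
    "inputs": {
        # null → packaged fixture
        "study_table": None,
        "hub_network": None,
        "hub_genes": None,
    },
    "thresholds": {
        "vote_threshold": 4,
        "alpha": 0.05,
        "fc_low": 0.5,
        "fc_high": 2.0,
    },
    "synthetic": {
        "corpus": {"N": 1_000_000, "n": 60_000, "gene_count": 2000, "planted_factor": 5.0},
        "predictions": {"n_targets": 251, "n_decoys": 600},
        "nlp_list_size": 1800,
        "overlap_size": 104,
        "pathways": {"n_pathways": 12, "pathway_size": 20, "planted_frac": 0.8},
    },
}

_STAGE_SEED_OFFSET = {
    "cocite": 11,
    "vote": 23,
    "integrate": 37,
    "enrich": 53,
}


def derive_seed(base: int, stage: str) -> int:
    """Per-stage seed derived from the single config seed (stable, < 2^31)."""
    digest = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class PipelineConfigError(ValueError):
    """Configuration failed validation before any stage ran."""


class StageError(RuntimeError):
    """A stage failed; partial outputs from earlier stages are retained."""


def _merge(base: Mapping, override: Mapping) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def validate_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    cfg = _merge(DEFAULT_CONFIG, config or {})
    thr = cfg["thresholds"]
    if not 0 < thr["alpha"] < 1:
        raise PipelineConfigError(f"alpha must be in (0,1), got {thr['alpha']}")
    if not 1 <= int(thr["vote_threshold"]):
        raise PipelineConfigError("vote_threshold must be >= 1")
    if not 0 < thr["fc_low"] < 1 < thr["fc_high"]:
        raise PipelineConfigError("fold-change bounds must satisfy 0 < low < 1 < high")
    for key, path in cfg["inputs"].items():
        if path is not None and not Path(path).exists():
            raise PipelineConfigError(f"input path for {key!r} does not exist: {path}")
    if int(cfg["seed"]) < 0:
        raise PipelineConfigError("seed must be non-negative")
    return cfg


def _config_hash(cfg: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: Mapping[str, Any] | None, outdir) -> dict[str, Any]:
    """Run the configured stages; return (and write) the manifest."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = cfg["stages"]
    manifest: dict[str, Any] = {
        "package": "mirmeta",
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "started_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        "stages": {},
    }

    current = "setup"
    try:
        # ------------------------------------------------------ cohort stats
        studies: list[StudySummary] = (
            read_summary_tsv(cfg["inputs"]["study_table"])
            if cfg["inputs"]["study_table"]
            else load_study_table()
        )
        if stages["stats"]:
            current = "stats"
            rows = []
            for s in studies:
                res = welch_t(s.case, s.control)
                fc = fold_change(s.case, s.control, scale="log2", p=res.p)
                rows.append(
                    {
                        "study_id": s.study_id,
                        "source": s.source,
                        "t": res.t,
                        "df": res.df,
                        "p": res.p,
                        "fc_log2_assumed": fc.fc,
                    }
                )
            pd.DataFrame(rows).to_csv(outdir / "cohort_stats.tsv", sep="\t", index=False)
            manifest["stages"]["stats"] = {"n_studies": len(rows)}

        # ------------------------------------------------------ meta-analysis
        if stages["meta"]:
            current = "meta"
            effects = [hedges_g(s) for s in studies]
            panels = {"all": effects}
            geo = [hedges_g(s) for s in studies if s.source == "GEO"]
            if 2 <= len(geo) < len(effects):
                panels["geo"] = geo
            summary_rows = []
            for label, panel in panels.items():
                res = select_model(panel)
                forest_table(panel, res).to_csv(
                    outdir / f"meta_forest_{label}.tsv", sep="\t", index=False
                )
                funnel_points(panel).to_csv(
                    outdir / f"meta_funnel_{label}.tsv", sep="\t", index=False
                )
                if len(panel) >= 3:
                    leave_one_out(panel).to_csv(
                        outdir / f"meta_loo_{label}.tsv", sep="\t", index=False
                    )
                row = {
                    "panel": label,
                    "k": len(panel),
                    "pooled_smd": res.pooled,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "Q": res.Q,
                    "p_Q": res.p_Q,
                    "I2": res.I2,
                    "tau2": res.tau2,
                    "model": res.model,
                }
                if len(panel) >= 3:
                    row["egger_p"] = egger_test(panel).p
                    row["begg_p"] = begg_test(panel).p
                summary_rows.append(row)
            pd.DataFrame(summary_rows).to_csv(outdir / "meta_summary.tsv", sep="\t", index=False)
            manifest["stages"]["meta"] = {
                r["panel"]: {
                    "pooled_smd": r["pooled_smd"],
                    "I2": r["I2"],
                    "model": r["model"],
                }
                for r in summary_rows
            }

        # ------------------------------------------- literature co-citation
        flagged_genes: list[str] = []
        if stages["cocite"]:
            current = "cocite"
            c = cfg["synthetic"]["corpus"]
            gene_count = int(c["gene_count"])
            factors = [float(c.get("planted_factor", 5.0))] + [1.0] * (gene_count - 1)
            spec = CorpusSpec(
                N=int(c["N"]),
                n=int(c["n"]),
                gene_count=gene_count,
                enrichment_factors=factors,
                seed=derive_seed(seed, "cocite"),
            )
            scored = score_corpus(
                gen_corpus(spec), N=spec.N, n=spec.n, alpha=float(cfg["thresholds"]["alpha"])
            )
            scored.to_csv(outdir / "cocitation_scores.tsv", sep="\t", index=False)
            flagged_genes = scored.loc[scored["flagged"], "gene"].tolist()
            manifest["stages"]["cocite"] = {
                "n_genes": int(len(scored)),
                "n_flagged": int(len(flagged_genes)),
                "top_gene": scored["gene"].iloc[0] if len(scored) else None,
            }

        # ------------------------------------------------- consensus voting
        accepted: list[str] = []
        if stages["vote"]:
            current = "vote"
            p = cfg["synthetic"]["predictions"]
            matrix = gen_predictions(
                n_targets=int(p["n_targets"]),
                n_decoys=int(p["n_decoys"]),
                seed=derive_seed(seed, "vote"),
                threshold=int(cfg["thresholds"]["vote_threshold"]),
            )
            votes = tally_votes(matrix)
            threshold = int(cfg["thresholds"]["vote_threshold"])
            votes["accepted"] = votes["vote_count"] >= threshold
            votes.to_csv(outdir / "target_votes.tsv", sep="\t", index=False)
            accepted = consensus_targets(matrix, threshold=threshold)
            manifest["stages"]["vote"] = {"n_accepted": len(accepted)}

        # ----------------------------------------------------- integration
        overlap = None
        if stages["integrate"] and accepted:
            current = "integrate"
            rng_seed = derive_seed(seed, "integrate")
            import numpy as np

            rng = np.random.default_rng(rng_seed)
            n_overlap = min(int(cfg["synthetic"]["overlap_size"]), len(accepted))
            nlp_size = int(cfg["synthetic"]["nlp_list_size"])
            shared = list(rng.choice(accepted, size=n_overlap, replace=False))
            extra = [f"NLPONLY{i+1:05d}" for i in range(nlp_size - n_overlap)]
            nlp_set = GeneSet.from_iterable("disease_literature", shared + extra)
            target_set = GeneSet.from_iterable("consensus_targets", accepted)
            overlap = intersect_sets(nlp_set, target_set)
            pd.DataFrame({"gene": sorted(overlap.members)}).to_csv(
                outdir / "overlap_genes.tsv", sep="\t", index=False
            )
            manifest["stages"]["integrate"] = {"n_overlap": len(overlap)}

        # ------------------------------------------------------- enrichment
        if stages["enrich"] and overlap is not None and len(overlap) > 0:
            current = "enrich"
            pw = cfg["synthetic"]["pathways"]
            background = sorted(
                set(accepted) | {f"BG{i+1:05d}" for i in range(2000)}
            )
            pathways = gen_pathways(
                query=sorted(overlap.members),
                background=background,
                n_pathways=int(pw["n_pathways"]),
                pathway_size=int(pw["pathway_size"]),
                planted_frac=float(pw["planted_frac"]),
                seed=derive_seed(seed, "enrich"),
            )
            write_gmt(pathways, outdir / "pathways.gmt")
            enr = pathway_enrichment(overlap, pathways)
            enr.to_csv(outdir / "pathway_enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrich"] = {
                "top_pathway": enr["pathway"].iloc[0],
                "top_p": float(enr["p"].iloc[0]),
            }

        # ----------------------------------------------------- connectivity
        net: Network | None = None
        if stages["connect"] or stages["network"]:
            net = (
                import_network(cfg["inputs"]["hub_network"], format="sif")
                if cfg["inputs"]["hub_network"]
                else load_hub_network()
            )
        if stages["connect"]:
            current = "connect"
            hub_genes = (
                [g.strip().upper() for g in Path(cfg["inputs"]["hub_genes"]).read_text().split()]
                if cfg["inputs"]["hub_genes"]
                else list(HUB_GENES)
            )
            conn = connectivity_ztest(net, hub_genes)
            conn.to_csv(outdir / "connectivity.tsv", sep="\t", index=False)
            manifest["stages"]["connect"] = {
                "top_gene": conn["gene"].iloc[0],
                "top_degree": int(conn["degree"].iloc[0]),
                "top_p": float(conn["p"].iloc[0]),
            }

        # ---------------------------------------------------------- network
        if stages["network"]:
            current = "network"
            export_network(net, outdir / "network.sif", format="sif")
            export_network(net, outdir / "network.graphml", format="graphml")
            manifest["stages"]["network"] = {
                "n_nodes": len(net),
                "n_edges": len(net.edges),
            }
    except Exception as exc:
        raise StageError(f"pipeline stage {current!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
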