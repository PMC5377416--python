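"""Packaged fixtures: the published cohort summaries, hub network, and
overlap gene list shipped with the package.

* ``load_study_table()`` — the 11 two-group cohort summaries (9 GEO
  microarray cohorts, one combined qRT-PCR cohort, one TCGA RNA-seq
  cohort) used for the meta-analysis.
* ``load_hub_network()`` — the 20-hub-gene interaction network (34
  undirected edges) behind the connectivity z-test.
* ``load_overlap_genes()`` — the 104 genes in the overlap of the
  literature-derived disease gene list and the consensus target list.
"""

from __future__ import annotations

from importlib import resources

from .cohort import StudySummary, read_summary_tsv
from .network import Network, import_network, read_gene_list

__all__ = ["load_study_table", "load_hub_network", "load_overlap_genes", "HUB_GENES"]

# the 20-gene hub population of the connectivity test
HUB_GENES = (
    "ELAVL1", "ERBB4", "HEYL", "IL17A", "IQGAP1", "IRAK1", "NOTCH2", "NOVA1",
    "NRAS", "OTUD7B", "PARK2", "PTGS2", "PTPRE", "RAC1", "RACGAP1", "ROBO1",
    "SMAD4", "SORT1", "TRAF6", "YES1",
)


def _data_path(name: str):
    return resources.files("mirmeta.data") / name


def load_study_table() -> list[StudySummary]:
    with resources.as_file(_data_path("study_summaries.tsv")) as path:
        return read_summary_tsv(path)


def load_hub_network() -> Network:
    with resources.as_file(_data_path("hub_interactions.sif")) as path:
        return import_network(path, format="sif")


def load_overlap_genes() -> list[str]:
    with resources.as_file(_data_path("overlap_genes.txt")) as path:
        return read_gene_list(path)
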