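"""Bipartite drug-target interaction networks and degree analysis.

Networks are held as ``networkx.Graph`` objects with typed nodes (drugs
carry modality, development stage and ICD disease codes; targets carry a
cohort label) and typed edges (activation or inhibition).  Analysis
follows standard network pharmacology practice: node degree counts a
drug's primary targets or a target's acting drugs regardless of
interaction sign, "popular" targets are those above a degree threshold,
and multitarget drugs are those of degree >= 2.  Disease-class subnetworks
are induced by ICD code category ranges (e.g. C51-C58, the malignant
neoplasms of female genital organs).  Export formats are Cytoscape
compatible (SIF, GraphML, attribute tables).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "DrugRecord",
    "InteractionRecord",
    "build_network",
    "network_from_tables",
    "degree_histogram",
    "popular_nodes",
    "multitarget_drugs",
    "subnetwork_by_icd",
    "export_sif",
    "export_graphml",
    "export_attribute_tables",
]

MODALITIES = ("small_molecule", "monoclonal_antibody", "biologic")
STAGES = ("approved", "phase3", "phase2", "phase1")
MODES = ("activation", "inhibition")

_ICD_CODE = re.compile(r"^[A-Z]\d{2}(\.\d+)?$")
_ICD_RANGE = re.compile(r"^([A-Z])(\d{2})-([A-Z])(\d{2})$")


@dataclass(frozen=True)
class DrugRecord:
    """One drug node: modality, development stage, and ICD disease codes."""

    drug_id: str
    name: str = ""
    modality: str = "small_molecule"
    development_stage: str = "approved"
    icd_codes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"invalid modality {self.modality!r}")
        if self.development_stage not in STAGES:
            raise ValueError(f"invalid stage {self.development_stage!r}")
        bad = [c for c in self.icd_codes if not _ICD_CODE.match(c)]
        if bad:
            raise ValueError(f"malformed ICD codes: {sorted(bad)}")


@dataclass(frozen=True)
class InteractionRecord:
    """One drug-target edge with its interaction mode."""

    drug_id: str
    target_id: str
    mode: str = "inhibition"
    primary: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"invalid interaction mode {self.mode!r}")


def build_network(
    drugs: Iterable[DrugRecord],
    targets: Mapping[str, str],
    interactions: Iterable[InteractionRecord],
) -> nx.Graph:
    """Assemble a strictly bipartite drug-target graph.

    ``targets`` maps target id to its cohort label (``"established"`` or
    ``"clinical_trial"``).  Referential integrity is enforced: every edge
    endpoint must exist, and duplicate (drug, target) pairs are rejected.
    """
    g = nx.Graph()
    drug_list = list(drugs)
    for d in drug_list:
        g.add_node(d.drug_id, node_class="drug", name=d.name,
                   modality=d.modality, stage=d.development_stage,
                   icd_codes=",".join(sorted(d.icd_codes)))
    for tid, cohort in targets.items():
        if tid in g:
            raise ValueError(f"id {tid!r} used for both a drug and a target")
        g.add_node(tid, node_class="target", cohort=cohort)
    dangling = []
    seen = set()
    for rec in interactions:
        if rec.drug_id not in g or g.nodes[rec.drug_id]["node_class"] != "drug":
            dangling.append(rec.drug_id)
            continue
        if rec.target_id not in g or g.nodes[rec.target_id]["node_class"] != "target":
            dangling.append(rec.target_id)
            continue
        pair = (rec.drug_id, rec.target_id)
        if pair in seen:
            raise ValueError(f"duplicate interaction {pair}")
        seen.add(pair)
        g.add_edge(rec.drug_id, rec.target_id, mode=rec.mode,
                   primary=rec.primary)
    if dangling:
        raise ValueError(f"interactions reference unknown ids: {sorted(set(dangling))}")
    return g


def network_from_tables(
    drugs: pd.DataFrame, targets: pd.DataFrame, interactions: pd.DataFrame
) -> nx.Graph:
    """Build a network from the three delimited tables.

    Expected columns — drugs: drug_id, name, modality, development_stage,
    icd_codes (semicolon-separated, may be empty); targets: target_id,
    cohort; interactions: drug_id, target_id, mode.
    """
    drug_records = [
        DrugRecord(
            drug_id=row.drug_id,
            name=getattr(row, "name", "") or "",
            modality=getattr(row, "modality", "small_molecule"),
            development_stage=getattr(row, "development_stage", "approved"),
            icd_codes=frozenset(
                c for c in str(getattr(row, "icd_codes", "") or "").split(";") if c
            ),
        )
        for row in drugs.itertuples(index=False)
    ]
    target_map = dict(zip(targets["target_id"], targets["cohort"]))
    interaction_records = [
        InteractionRecord(
            drug_id=row.drug_id, target_id=row.target_id,
            mode=getattr(row, "mode", "inhibition"),
        )
        for row in interactions.itertuples(index=False)
    ]
    return build_network(drug_records, target_map, interaction_records)


def _class_nodes(g: nx.Graph, node_class: str) -> list[str]:
    if node_class not in ("drug", "target"):
        raise ValueError(f"node_class must be 'drug' or 'target', got {node_class!r}")
    key = "node_class" if any("node_class" in d for _, d in g.nodes(data=True)) \
        else "bipartite"
    return [n for n, d in g.nodes(data=True) if d.get(key) == node_class]


def degree_histogram(g: nx.Graph, node_class: str) -> dict[int, int]:
    """Degree -> node count for one side of the bipartite graph.

    Degree is the undirected edge count regardless of interaction mode.
    Isolated nodes (degree 0) are included under key 0 so histogram totals
    equal class node counts.
    """
    return dict(sorted(Counter(g.degree(n) for n in _class_nodes(g, node_class)).items()))


def popular_nodes(
    g: nx.Graph, node_class: str, min_degree_exclusive: int = 8
) -> list[tuple[str, int]]:
    """Nodes of one class with degree strictly above a threshold.

    Sorted by degree descending, ties by id ascending.  With threshold 0
    this returns every non-isolated node of the class.
    """
    if min_degree_exclusive < 0:
        raise ValueError("threshold must be >= 0")
    hits = [(n, g.degree(n)) for n in _class_nodes(g, node_class)
            if g.degree(n) > min_degree_exclusive]
    return sorted(hits, key=lambda item: (-item[1], item[0]))


def multitarget_drugs(g: nx.Graph) -> list[str]:
    """Drugs acting on at least two targets (degree >= 2), sorted by id."""
    return sorted(n for n in _class_nodes(g, "drug") if g.degree(n) >= 2)


def _parse_icd_range(code_range: str) -> tuple[str, int, int]:
    m = _ICD_RANGE.match(code_range.strip().upper().replace("–", "-"))
    if not m:
        raise ValueError(
            f"malformed ICD range {code_range!r}; expected e.g. 'C51-C58'"
        )
    letter, lo, letter2, hi = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
    if letter != letter2:
        raise ValueError(f"ICD range endpoints use different letters: {code_range!r}")
    if lo > hi:
        raise ValueError(f"ICD range lower bound exceeds upper: {code_range!r}")
    return letter, lo, hi


def _code_in_range(code: str, letter: str, lo: int, hi: int) -> bool:
    # match on the 3-character category prefix: C54.1 falls in C51-C58
    category = code.split(".")[0]
    return category[0] == letter and lo <= int(category[1:]) <= hi


def subnetwork_by_icd(
    g: nx.Graph, code_range: str, drop_isolated: bool = True
) -> nx.Graph:
    """Induced subgraph of drugs whose ICD codes fall in a category range.

    Retains every drug with at least one code in the range plus all of
    their targets; edges are those of the parent between retained nodes.
    Targets left without any retained drug are dropped by default (the
    subnetwork shows connected entities only); pass ``drop_isolated=False``
    to keep them.
    """
    letter, lo, hi = _parse_icd_range(code_range)
    keep_drugs = set()
    for n in _class_nodes(g, "drug"):
        codes = [c for c in g.nodes[n].get("icd_codes", "").split(",") if c]
        if any(_code_in_range(c, letter, lo, hi) for c in codes):
            keep_drugs.add(n)
    keep_targets = {t for d in keep_drugs for t in g.neighbors(d)}
    if not drop_isolated:
        keep_targets |= set(_class_nodes(g, "target"))
    return g.subgraph(keep_drugs | keep_targets).copy()


_SIF_RELATION = {"activation": "activates", "inhibition": "inhibits"}


def export_sif(g: nx.Graph, path: str | Path) -> None:
    """Write the network as Cytoscape SIF: ``drug<TAB>relation<TAB>target``."""
    lines = []
    for d in sorted(_class_nodes(g, "drug")):
        for t in sorted(g.neighbors(d)):
            rel = _SIF_RELATION.get(g.edges[d, t].get("mode", "inhibition"))
            lines.append(f"{d}\t{rel}\t{t}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def export_graphml(g: nx.Graph, path: str | Path) -> None:
    """Write GraphML with node attributes (class, modality, stage, cohort)
    and the edge interaction mode."""
    nx.write_graphml(g, str(path))


def export_attribute_tables(
    g: nx.Graph, node_path: str | Path, edge_path: str | Path
) -> None:
    """Write Cytoscape-style node and edge attribute tables (TSV)."""
    node_rows = [
        {"id": n, **{k: v for k, v in d.items()}}
        for n, d in sorted(g.nodes(data=True))
    ]
    pd.DataFrame(node_rows).to_csv(node_path, sep="\t", index=False)
    edge_rows = [
        {"source": a, "target": b, **{k: v for k, v in d.items()}}
        for a, b, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(edge_rows).to_csv(edge_path, sep="\t", index=False)
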