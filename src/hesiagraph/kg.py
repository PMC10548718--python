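"""Typed drug-disease knowledge graph (DDKG) construction and validation.

The graph couples drugs and diseases to their feature entities: chemical
substructures, target proteins, protein domains, side effects, and ATC codes
on the drug side; disease types, MeSH-style classes, genes, and UMLS semantic
types on the disease side. Edges are typed triplets ``<head, relation, tail>``
with a fixed signature table (which node type may head or tail each relation).

Four nested graph *versions* select relation subsets:

* ``V1`` — all 14 relation types;
* ``V2`` — the 10 baseline types (drug features, disease features, treatment);
* ``V3`` — V2 plus the intra-domain interaction types
  (protein-protein, target-domain, gene-gene);
* ``V4`` — V2 plus the gene→target ``has_encoded`` inter type.

Node identifiers are namespaced as ``"<node_type>:<local_id>"`` so that, e.g.,
a side-effect term and a disease that share a vocabulary identifier remain
distinct graph nodes while staying linkable by their local id. That identity
mapping is what lets the adverse-reaction negative rule fire.
"""

from __future__ import annotations

import enum
import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "NodeType",
    "RelationGroup",
    "RelationType",
    "Triplet",
    "KnowledgeGraph",
    "ValidationReport",
    "SchemaError",
    "KGValidationError",
    "VERSION_RELATIONS",
    "build_kg",
    "derive_drug_domain_edges",
    "remove_treatment_edges",
    "validate_kg",
    "node_key",
    "split_key",
    "atc_levels",
    "expand_atc_edges",
    "read_table",
    "save_kg",
    "load_kg",
]


class SchemaError(ValueError):
    """An input row names an unknown node type or relation type."""


class KGValidationError(ValueError):
    """Input rows violate the relation signature table."""

    def __init__(self, errors: Sequence[tuple]):
        self.errors = list(errors)
        lines = "; ".join(f"{row}: {rule}" for row, rule in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{len(self.errors)} invalid edge row(s): {lines}{more}")


class NodeType(str, enum.Enum):
    DRUG = "drug"
    CHEMICAL_SUBSTRUCTURE = "chemical_substructure"
    TARGET_PROTEIN = "target_protein"
    PROTEIN_DOMAIN = "protein_domain"
    SIDE_EFFECT = "side_effect"
    ATC_CODE = "atc_code"
    DISEASE = "disease"
    DISEASE_TYPE = "disease_type"
    DISEASE_CLASS = "disease_class"
    GENE = "gene"
    SEMANTIC_TYPE = "semantic_type"


class RelationGroup(str, enum.Enum):
    INTRA_DRUG = "intra_drug"
    INTRA_DISEASE = "intra_disease"
    INTER = "inter"


class RelationType(str, enum.Enum):
    HAS_CHEMICAL_SUBSTRUCTURE = "has_chemical_substructure"
    HAS_TARGET = "has_target"
    HAS_DOMAIN = "has_domain"
    HAS_SIDE_EFFECT = "has_side_effect"
    HAS_ATC_CODE = "has_ATC_code"
    HAS_INTERACTION = "has_interaction"
    HAS_DOMAIN_TARGET = "has_domain_target"
    HAS_TYPE = "has_type"
    HAS_CLASS = "has_class"
    HAS_GENE = "has_gene"
    HAS_SEMANTIC_TYPE = "has_semantic_type"
    HAS_GENE_INTERACTION = "has_gene_interaction"
    HAS_TREATMENT = "has_treatment"
    HAS_ENCODED = "has_encoded"

    @property
    def domain(self) -> NodeType:
        return _SIGNATURES[self][0]

    @property
    def range(self) -> NodeType:
        return _SIGNATURES[self][1]

    @property
    def group(self) -> RelationGroup:
        return _SIGNATURES[self][2]

    @property
    def symmetric(self) -> bool:
        """Self-relations (protein-protein, gene-gene) forbid self-loops."""
        return self in (RelationType.HAS_INTERACTION, RelationType.HAS_GENE_INTERACTION)


_SIGNATURES: dict[RelationType, tuple[NodeType, NodeType, RelationGroup]] = {
    RelationType.HAS_CHEMICAL_SUBSTRUCTURE: (
        NodeType.DRUG, NodeType.CHEMICAL_SUBSTRUCTURE, RelationGroup.INTRA_DRUG),
    RelationType.HAS_TARGET: (
        NodeType.DRUG, NodeType.TARGET_PROTEIN, RelationGroup.INTRA_DRUG),
    RelationType.HAS_DOMAIN: (
        NodeType.DRUG, NodeType.PROTEIN_DOMAIN, RelationGroup.INTRA_DRUG),
    RelationType.HAS_SIDE_EFFECT: (
        NodeType.DRUG, NodeType.SIDE_EFFECT, RelationGroup.INTRA_DRUG),
    RelationType.HAS_ATC_CODE: (
        NodeType.DRUG, NodeType.ATC_CODE, RelationGroup.INTRA_DRUG),
    RelationType.HAS_INTERACTION: (
        NodeType.TARGET_PROTEIN, NodeType.TARGET_PROTEIN, RelationGroup.INTRA_DRUG),
    RelationType.HAS_DOMAIN_TARGET: (
        NodeType.TARGET_PROTEIN, NodeType.PROTEIN_DOMAIN, RelationGroup.INTRA_DRUG),
    RelationType.HAS_TYPE: (
        NodeType.DISEASE, NodeType.DISEASE_TYPE, RelationGroup.INTRA_DISEASE),
    RelationType.HAS_CLASS: (
        NodeType.DISEASE, NodeType.DISEASE_CLASS, RelationGroup.INTRA_DISEASE),
    RelationType.HAS_GENE: (
        NodeType.DISEASE, NodeType.GENE, RelationGroup.INTRA_DISEASE),
    RelationType.HAS_SEMANTIC_TYPE: (
        NodeType.DISEASE, NodeType.SEMANTIC_TYPE, RelationGroup.INTRA_DISEASE),
    RelationType.HAS_GENE_INTERACTION: (
        NodeType.GENE, NodeType.GENE, RelationGroup.INTRA_DISEASE),
    RelationType.HAS_TREATMENT: (
        NodeType.DRUG, NodeType.DISEASE, RelationGroup.INTER),
    RelationType.HAS_ENCODED: (
        NodeType.GENE, NodeType.TARGET_PROTEIN, RelationGroup.INTER),
}

_V2 = frozenset({
    RelationType.HAS_CHEMICAL_SUBSTRUCTURE,
    RelationType.HAS_TARGET,
    RelationType.HAS_DOMAIN,
    RelationType.HAS_SIDE_EFFECT,
    RelationType.HAS_ATC_CODE,
    RelationType.HAS_TYPE,
    RelationType.HAS_CLASS,
    RelationType.HAS_GENE,
    RelationType.HAS_SEMANTIC_TYPE,
    RelationType.HAS_TREATMENT,
})

#: Relation subsets of the four graph versions. V2 is the baseline; V3 adds
#: the within-domain interaction relations, V4 adds the gene→target link, and
#: V1 is their union (all 14).
VERSION_RELATIONS: dict[str, frozenset[RelationType]] = {
    "V1": frozenset(RelationType),
    "V2": _V2,
    "V3": _V2 | {RelationType.HAS_INTERACTION,
                 RelationType.HAS_DOMAIN_TARGET,
                 RelationType.HAS_GENE_INTERACTION},
    "V4": _V2 | {RelationType.HAS_ENCODED},
}


def node_key(ntype: NodeType, local_id: str) -> str:
    return f"{ntype.value}:{local_id}"


def split_key(key: str) -> tuple[NodeType, str]:
    type_name, _, local = key.partition(":")
    return NodeType(type_name), local


@dataclass(frozen=True, order=True)
class Triplet:
    """One typed fact ``<head, relation, tail>``; endpoints are node keys."""

    head: str
    relation: RelationType
    tail: str


@dataclass(frozen=True)
class KnowledgeGraph:
    nodes: Mapping[str, NodeType]
    triplets: frozenset[Triplet]
    version: str = "V1"

    def __post_init__(self):
        if self.version not in VERSION_RELATIONS:
            raise SchemaError(f"unknown version {self.version!r}")

    def __len__(self) -> int:
        return len(self.triplets)

    def relation_counts(self) -> Counter:
        return Counter(t.relation for t in self.triplets)

    def node_type_counts(self) -> Counter:
        return Counter(self.nodes.values())

    def nodes_of_type(self, ntype: NodeType) -> list[str]:
        """Local ids of every node of ``ntype``, sorted."""
        return sorted(split_key(key)[1] for key, nt in self.nodes.items()
                      if nt is ntype)

    def subset(self, version: str) -> "KnowledgeGraph":
        """Restrict to the relation set of ``version`` (nodes unchanged)."""
        allowed = VERSION_RELATIONS[version]
        kept = frozenset(t for t in self.triplets if t.relation in allowed)
        return KnowledgeGraph(self.nodes, kept, version)


@dataclass
class ValidationReport:
    errors: list[tuple[Triplet, str]] = field(default_factory=list)
    node_type_counts: Counter = field(default_factory=Counter)
    relation_counts: Counter = field(default_factory=Counter)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_json(self) -> str:
        return json.dumps({
            "n_errors": len(self.errors),
            "errors": [
                {"head": t.head, "relation": t.relation.value, "tail": t.tail,
                 "rule": rule}
                for t, rule in self.errors],
            "node_type_counts": {k.value: v for k, v in self.node_type_counts.items()},
            "relation_counts": {k.value: v for k, v in self.relation_counts.items()},
        }, indent=2)


def _iter_rows(table, columns) -> Iterable[tuple]:
    if isinstance(table, pd.DataFrame):
        return list(table[list(columns)].itertuples(index=False, name=None))
    return [tuple(row) for row in table]


def build_kg(node_table, edge_table, version: str = "V1") -> KnowledgeGraph:
    """Assemble a validated knowledge graph from node and edge rows.

    Parameters
    ----------
    node_table
        Rows of ``(node_id, node_type)`` or a DataFrame with those columns.
    edge_table
        Rows of ``(head_id, relation, tail_id)`` or a DataFrame with those
        columns; identifiers are *local* (un-namespaced) and are resolved
        against the node table through each relation's type signature.
    version
        Which relation subset to keep; edges of relation types outside the
        subset are silently dropped (they are facts of another version).

    The result is order-independent and duplicate rows collapse to one
    node/triplet. Unknown node or relation names raise :class:`SchemaError`;
    edges whose endpoints are missing or of the wrong type raise
    :class:`KGValidationError` listing every offending row.
    """
    if version not in VERSION_RELATIONS:
        raise SchemaError(f"unknown version {version!r}")
    node_rows = _iter_rows(node_table, ("node_id", "node_type"))
    edge_rows = _iter_rows(edge_table, ("head_id", "relation", "tail_id"))
    if not node_rows or not edge_rows:
        raise ValueError("node and edge tables must be non-empty")

    nodes: dict[str, NodeType] = {}
    for local, type_name in node_rows:
        try:
            ntype = NodeType(str(type_name))
        except ValueError:
            raise SchemaError(f"unknown node type {type_name!r} for node {local!r}")
        nodes[node_key(ntype, str(local))] = ntype

    allowed = VERSION_RELATIONS[version]
    triplets: set[Triplet] = set()
    errors: list[tuple[tuple, str]] = []
    for head, rel_name, tail in edge_rows:
        try:
            rel = RelationType(str(rel_name))
        except ValueError:
            raise SchemaError(f"unknown relation type {rel_name!r}")
        if rel not in allowed:
            continue
        hkey = node_key(rel.domain, str(head))
        tkey = node_key(rel.range, str(tail))
        row = (head, rel.value, tail)
        if hkey not in nodes:
            errors.append((row, f"head must be a {rel.domain.value} node"))
            continue
        if tkey not in nodes:
            errors.append((row, f"tail must be a {rel.range.value} node"))
            continue
        if rel.symmetric and hkey == tkey:
            errors.append((row, "self-loop forbidden"))
            continue
        triplets.add(Triplet(hkey, rel, tkey))
    if errors:
        raise KGValidationError(errors)
    return KnowledgeGraph(dict(nodes), frozenset(triplets), version)


def derive_drug_domain_edges(kg: KnowledgeGraph) -> KnowledgeGraph:
    """Materialize drug→domain edges through drug→target→domain paths.

    For every pair ``(r, has_target, t)`` and ``(t, has_domain_target, d)``
    add ``(r, has_domain, d)``. Union semantics with any directly supplied
    drug→domain edges; idempotent by construction.
    """
    drugs_by_target: dict[str, list[str]] = {}
    for t in kg.triplets:
        if t.relation is RelationType.HAS_TARGET:
            drugs_by_target.setdefault(t.tail, []).append(t.head)
    derived = {
        Triplet(drug, RelationType.HAS_DOMAIN, t.tail)
        for t in kg.triplets if t.relation is RelationType.HAS_DOMAIN_TARGET
        for drug in drugs_by_target.get(t.head, ())
    }
    if not derived - kg.triplets:
        return kg
    return KnowledgeGraph(kg.nodes, kg.triplets | derived, kg.version)


def remove_treatment_edges(
    kg: KnowledgeGraph, pairs: Sequence[tuple[str, str]]
) -> KnowledgeGraph:
    """Strip the edges that would leak listed drug-disease pairs.

    For every ``(drug, disease)`` pair the ``has_treatment`` triplet is
    removed (positive-pair leak) and so is the ``has_side_effect`` triplet
    whose side-effect term is identity-mapped to the disease id (the
    adverse-reaction edge that defines negative pairs). The node set is never
    changed. Pairs referencing unknown drug or disease nodes raise.
    """
    doomed: set[Triplet] = set()
    for drug, disease in pairs:
        dkey = node_key(NodeType.DRUG, drug)
        pkey = node_key(NodeType.DISEASE, disease)
        if dkey not in kg.nodes or pkey not in kg.nodes:
            raise KeyError(f"unknown pair ({drug!r}, {disease!r})")
        doomed.add(Triplet(dkey, RelationType.HAS_TREATMENT, pkey))
        doomed.add(Triplet(dkey, RelationType.HAS_SIDE_EFFECT,
                           node_key(NodeType.SIDE_EFFECT, disease)))
    kept = kg.triplets - doomed
    if kept == kg.triplets:
        return kg
    return KnowledgeGraph(kg.nodes, kept, kg.version)


def validate_kg(kg: KnowledgeGraph) -> ValidationReport:
    """Audit a graph against the signature table; errors are data, not raises."""
    report = ValidationReport(
        node_type_counts=kg.node_type_counts(),
        relation_counts=kg.relation_counts(),
    )
    for t in sorted(kg.triplets):
        if t.head not in kg.nodes:
            report.errors.append((t, "missing head node"))
            continue
        if t.tail not in kg.nodes:
            report.errors.append((t, "missing tail node"))
            continue
        if kg.nodes[t.head] is not t.relation.domain:
            report.errors.append(
                (t, f"head type {kg.nodes[t.head].value} != {t.relation.domain.value}"))
        if kg.nodes[t.tail] is not t.relation.range:
            report.errors.append(
                (t, f"tail type {kg.nodes[t.tail].value} != {t.relation.range.value}"))
        if t.relation.symmetric and t.head == t.tail:
            report.errors.append((t, "self-loop"))
    return report


# ATC codes are hierarchical: level prefixes of length 1, 3, 4, 5, 7.
_ATC_PREFIX_LENGTHS = (1, 3, 4, 5, 7)


def atc_levels(code: str) -> list[str]:
    """Hierarchy-level prefixes of an ATC code, e.g. N02BE01 → N, N02, N02B, N02BE, N02BE01."""
    code = code.strip()
    if not code:
        raise ValueError("empty ATC code")
    return [code[:n] for n in _ATC_PREFIX_LENGTHS if n <= len(code)]


def expand_atc_edges(edge_rows) -> tuple[list[tuple], list[tuple]]:
    """Expand full ATC codes into one edge (and node row) per hierarchy level.

    Returns ``(node_rows, edge_rows)`` where non-ATC edges pass through
    untouched and each ``has_ATC_code`` row is replaced by one row per level
    prefix of its tail code.
    """
    rows = _iter_rows(edge_rows, ("head_id", "relation", "tail_id"))
    out_edges: list[tuple] = []
    out_nodes: set[tuple] = set()
    for head, rel, tail in rows:
        if str(rel) == RelationType.HAS_ATC_CODE.value:
            for level in atc_levels(str(tail)):
                out_edges.append((head, rel, level))
                out_nodes.add((level, NodeType.ATC_CODE.value))
        else:
            out_edges.append((head, rel, tail))
    return sorted(out_nodes), out_edges


def read_table(path) -> pd.DataFrame:
    """Read a UTF-8 tab-separated table with a header row."""
    return pd.read_csv(path, sep="\t", dtype=str)


def save_kg(kg: KnowledgeGraph, edges_path, nodes_path=None) -> None:
    """Re-export the graph in the input TSV dialect (local ids + node table)."""
    edge_rows = sorted(
        (split_key(t.head)[1], t.relation.value, split_key(t.tail)[1])
        for t in kg.triplets
    )
    pd.DataFrame(edge_rows, columns=["head_id", "relation", "tail_id"]).to_csv(
        edges_path, sep="\t", index=False)
    if nodes_path is not None:
        node_rows = sorted((split_key(k)[1], v.value) for k, v in kg.nodes.items())
        pd.DataFrame(node_rows, columns=["node_id", "node_type"]).to_csv(
            nodes_path, sep="\t", index=False)


def load_kg(nodes_path, edges_path, version: str = "V1") -> KnowledgeGraph:
    return build_kg(read_table(nodes_path), read_table(edges_path), version)
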