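"""Synthetic knowledge graphs and association tables with a planted signal.

The generator emulates the structure of a real drug-disease knowledge graph —
11 node types, 14 relation types, side-effect terms sharing identifiers with
diseases — at desk scale, with a *controllable* mechanism signal rather than
realistic marginals. Drugs and diseases are assigned to latent mechanism
clusters; every feature relation (substructures, targets, genes, ...) picks
within-cluster vocabulary items with probability ``p_in`` and cross-cluster
items with probability ``p_out``. Treatment associations appear at rate
``treat_prob_in`` within clusters and ``treat_prob_out`` across them, and
gene→target ``has_encoded`` edges wire drug targets to disease genes inside
each cluster — the planted mechanism connecting the two sides of the graph.

Side-effect vocabulary: a fraction ``sidefx_disease_overlap`` of terms is
identity-mapped to disease ids (same local identifier), so the
adverse-reaction negative rule can fire. Each drug's side effects draw
preferentially from disease-mapped terms of *other* clusters, making the
resulting label-0 pairs truly non-associated.

Setting ``p_in == p_out`` and ``treat_prob_in == treat_prob_out`` removes
every cluster dependence: labels become independent of the graph features and
a correct end-to-end pipeline scores chance-level AUC. The
:func:`null_config` helper builds that matched no-signal configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import FeatureBlock
from .kg import NodeType, RelationType

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "default_config",
    "null_config",
    "generate",
    "make_separable_fixture",
]


@dataclass(frozen=True)
class SyntheticConfig:
    n_drugs: int = 60
    n_diseases: int = 25
    n_clusters: int = 4
    # feature vocabulary sizes
    n_substructures: int = 40
    n_targets: int = 24
    n_domains: int = 12
    n_side_effects: int = 30
    n_atc: int = 12
    n_disease_types: int = 6
    n_disease_classes: int = 6
    n_genes: int = 24
    n_semantic_types: int = 6
    # edge probabilities (within- vs cross-cluster)
    p_in: float = 0.35
    p_out: float = 0.05
    treat_prob_in: float = 0.45
    treat_prob_out: float = 0.02
    # side effects
    sidefx_disease_overlap: float = 0.6
    sidefx_per_drug: int = 8
    cross_cluster_sidefx_bias: float = 0.8
    # sparse intra-vocabulary interactions
    interaction_prob: float = 0.3
    encoded_prob: float = 0.25
    nonapproved_frac: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_out <= self.p_in <= 1:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if not 0 <= self.sidefx_disease_overlap <= 1:
            raise ValueError("sidefx_disease_overlap must be in [0, 1]")
        if min(self.n_drugs, self.n_diseases, self.n_clusters) < 1:
            raise ValueError("counts must be positive")

    def replace(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


def default_config(seed: int = 0) -> SyntheticConfig:
    """The desk-scale planted-signal study condition."""
    return SyntheticConfig(seed=seed)


def null_config(seed: int = 0) -> SyntheticConfig:
    """Matched no-signal condition: all cluster dependence removed.

    Edge and treatment rates are flattened to values chosen so the expected
    numbers of feature edges and positive pairs match the planted condition's
    marginals.
    """
    base = default_config(seed)
    k = base.n_clusters
    flat_p = base.p_in / k + base.p_out * (k - 1) / k
    flat_treat = base.treat_prob_in / k + base.treat_prob_out * (k - 1) / k
    return base.replace(p_in=flat_p, p_out=flat_p,
                        treat_prob_in=flat_treat, treat_prob_out=flat_treat,
                        cross_cluster_sidefx_bias=0.0)


@dataclass
class SyntheticTruth:
    drug_clusters: dict[str, int]
    disease_clusters: dict[str, int]
    associations: set[tuple[str, str]] = field(default_factory=set)


def _assign_clusters(ids, n_clusters, rng) -> dict[str, int]:
    # round-robin after a shuffle: every cluster is populated
    order = list(ids)
    rng.shuffle(order)
    return {x: i % n_clusters for i, x in enumerate(order)}


def _bernoulli_edges(heads, head_cl, tails, tail_cl, p_in, p_out, rng):
    """Sample head→tail links with cluster-dependent probabilities."""
    out = []
    for h in heads:
        for t in tails:
            p = p_in if head_cl[h] == tail_cl[t] else p_out
            if rng.random() < p:
                out.append((h, t))
    return out


def generate(config: SyntheticConfig):
    """Emit (node_table, edge_table, association_table, side_effect_table, truth).

    All tables are DataFrames in the TSV dialects the graph and dataset
    builders consume; identical configs (including seed) produce identical
    tables.
    """
    rng = np.random.default_rng(config.seed)
    n_mapped = int(round(config.sidefx_disease_overlap * config.n_side_effects))
    if n_mapped == 0:
        raise ValueError(
            "sidefx_disease_overlap leaves no disease-mapped side-effect "
            "terms; the adverse-reaction negative rule could never fire")

    drugs = [f"r{i:03d}" for i in range(config.n_drugs)]
    diseases = [f"p{i:03d}" for i in range(config.n_diseases)]
    subs = [f"c{i:03d}" for i in range(config.n_substructures)]
    targets = [f"t{i:03d}" for i in range(config.n_targets)]
    domains = [f"d{i:03d}" for i in range(config.n_domains)]
    atcs = [f"a{i:03d}" for i in range(config.n_atc)]
    dtypes = [f"ty{i:02d}" for i in range(config.n_disease_types)]
    dclasses = [f"cl{i:02d}" for i in range(config.n_disease_classes)]
    genes = [f"g{i:03d}" for i in range(config.n_genes)]
    semantics = [f"se{i:02d}" for i in range(config.n_semantic_types)]
    # disease-mapped side-effect terms share the disease local ids
    mapped_terms = [diseases[i % config.n_diseases] for i in range(n_mapped)]
    mapped_terms = sorted(set(mapped_terms))
    plain_terms = [f"s{i:03d}" for i in range(config.n_side_effects - n_mapped)]
    side_terms = mapped_terms + plain_terms

    kc = config.n_clusters
    drug_cl = _assign_clusters(drugs, kc, rng)
    dis_cl = _assign_clusters(diseases, kc, rng)
    sub_cl = _assign_clusters(subs, kc, rng)
    tgt_cl = _assign_clusters(targets, kc, rng)
    dom_cl = _assign_clusters(domains, kc, rng)
    atc_cl = _assign_clusters(atcs, kc, rng)
    dty_cl = _assign_clusters(dtypes, kc, rng)
    dcl_cl = _assign_clusters(dclasses, kc, rng)
    gene_cl = _assign_clusters(genes, kc, rng)
    sem_cl = _assign_clusters(semantics, kc, rng)

    edges: list[tuple[str, str, str]] = []

    def add(rel: RelationType, links):
        edges.extend((h, rel.value, t) for h, t in links)

    p_in, p_out = config.p_in, config.p_out
    add(RelationType.HAS_CHEMICAL_SUBSTRUCTURE,
        _bernoulli_edges(drugs, drug_cl, subs, sub_cl, p_in, p_out, rng))
    drug_targets = _bernoulli_edges(drugs, drug_cl, targets, tgt_cl,
                                    p_in, p_out, rng)
    # guarantee every drug has at least one target (the mechanism anchor)
    covered = {h for h, _ in drug_targets}
    for drug in drugs:
        if drug not in covered:
            pool = [t for t in targets if tgt_cl[t] == drug_cl[drug]] or targets
            drug_targets.append((drug, pool[rng.integers(len(pool))]))
    add(RelationType.HAS_TARGET, drug_targets)
    add(RelationType.HAS_ATC_CODE,
        _bernoulli_edges(drugs, drug_cl, atcs, atc_cl, p_in, p_out, rng))

    # target→domain (drug→domain edges are derived downstream via rule composition)
    add(RelationType.HAS_DOMAIN_TARGET,
        _bernoulli_edges(targets, tgt_cl, domains, dom_cl, p_in, p_out, rng))

    # disease features
    add(RelationType.HAS_GENE,
        _bernoulli_edges(diseases, dis_cl, genes, gene_cl, p_in, p_out, rng))
    for rel, vocab, vcl in ((RelationType.HAS_TYPE, dtypes, dty_cl),
                            (RelationType.HAS_CLASS, dclasses, dcl_cl),
                            (RelationType.HAS_SEMANTIC_TYPE, semantics, sem_cl)):
        links = []
        for p in diseases:
            same = [v for v in vocab if vcl[v] == dis_cl[p]]
            other = [v for v in vocab if vcl[v] != dis_cl[p]]
            pool = same if (same and rng.random() < p_in / (p_in + p_out)) else \
                (other or same)
            links.append((p, pool[rng.integers(len(pool))]))
        add(rel, links)

    # sparse symmetric interactions inside clusters (directed storage, no loops)
    for rel, vocab, vcl in ((RelationType.HAS_INTERACTION, targets, tgt_cl),
                            (RelationType.HAS_GENE_INTERACTION, genes, gene_cl)):
        links = []
        for i, a in enumerate(vocab):
            for b in vocab[i + 1:]:
                if vcl[a] == vcl[b] and rng.random() < config.interaction_prob:
                    links.append((a, b))
        add(rel, links)

    # planted mechanism: genes encode targets of the same cluster
    add(RelationType.HAS_ENCODED,
        [(g, t) for g in genes for t in targets
         if gene_cl[g] == tgt_cl[t] and rng.random() < config.encoded_prob])

    # treatment associations
    assoc_rows, positives = [], set()
    for r in drugs:
        for p in diseases:
            rate = (config.treat_prob_in if drug_cl[r] == dis_cl[p]
                    else config.treat_prob_out)
            if rng.random() < rate:
                positives.add((r, p))
                assoc_rows.append((r, p, "approved"))
            elif rng.random() < config.nonapproved_frac:
                assoc_rows.append((r, p, "investigational"))
    edges.extend((r, RelationType.HAS_TREATMENT.value, p) for r, p in sorted(positives))

    # side effects: biased toward disease-mapped terms of other clusters
    sidefx_rows = []
    mapped_other = {r: [s for s in mapped_terms if dis_cl[s] != drug_cl[r]]
                    for r in drugs}
    for r in drugs:
        chosen: set[str] = set()
        for _ in range(config.sidefx_per_drug):
            pool = mapped_other[r]
            if pool and rng.random() < config.cross_cluster_sidefx_bias:
                chosen.add(pool[rng.integers(len(pool))])
            else:
                chosen.add(side_terms[rng.integers(len(side_terms))])
        sidefx_rows.extend((r, s) for s in sorted(chosen))
    edges.extend((r, RelationType.HAS_SIDE_EFFECT.value, s)
                 for r, s in sidefx_rows)

    node_rows = (
        [(x, NodeType.DRUG.value) for x in drugs]
        + [(x, NodeType.DISEASE.value) for x in diseases]
        + [(x, NodeType.CHEMICAL_SUBSTRUCTURE.value) for x in subs]
        + [(x, NodeType.TARGET_PROTEIN.value) for x in targets]
        + [(x, NodeType.PROTEIN_DOMAIN.value) for x in domains]
        + [(x, NodeType.SIDE_EFFECT.value) for x in side_terms]
        + [(x, NodeType.ATC_CODE.value) for x in atcs]
        + [(x, NodeType.DISEASE_TYPE.value) for x in dtypes]
        + [(x, NodeType.DISEASE_CLASS.value) for x in dclasses]
        + [(x, NodeType.GENE.value) for x in genes]
        + [(x, NodeType.SEMANTIC_TYPE.value) for x in semantics]
    )
    node_table = pd.DataFrame(sorted(node_rows), columns=["node_id", "node_type"])
    edge_table = pd.DataFrame(sorted(set(edges)),
                              columns=["head_id", "relation", "tail_id"])
    association_table = pd.DataFrame(sorted(assoc_rows),
                                     columns=["drug_id", "disease_id", "status"])
    side_effect_table = pd.DataFrame(sorted(set(sidefx_rows)),
                                     columns=["drug_id", "term_id"])
    truth = SyntheticTruth(drug_clusters=dict(drug_cl),
                           disease_clusters=dict(dis_cl),
                           associations=positives)
    return node_table, edge_table, association_table, side_effect_table, truth


def make_separable_fixture(n: int, dim: int, margin: float,
                           seed: int = 0) -> FeatureBlock:
    """A linearly separable drug/disease pair block for trainer smoke tests.

    ``n/2`` positive pairs whose disease vector nearly equals the drug vector
    (small within-pair difference) and ``n/2`` negative pairs whose disease
    vector is offset by at least ``margin`` along a fixed direction, so the
    classes are separable by a threshold in ``|eps_r - eps_p|`` space.
    """
    if n % 2:
        raise ValueError("n must be even")
    if margin <= 0:
        raise ValueError("margin must be positive")
    rng = np.random.default_rng(seed)
    half = n // 2
    offset = np.zeros(dim)
    offset[0] = margin
    drug_pos = rng.standard_normal((half, dim))
    drug_neg = rng.standard_normal((half, dim))
    noise = 0.05 * min(margin, 1.0)
    dis_pos = drug_pos + noise * rng.standard_normal((half, dim))
    dis_neg = drug_neg + offset + noise * rng.standard_normal((half, dim))
    X = np.vstack([np.hstack([drug_pos, dis_pos]),
                   np.hstack([drug_neg, dis_neg])])
    y = np.concatenate([np.ones(half, dtype=int), np.zeros(half, dtype=int)])
    order = rng.permutation(n)
    return FeatureBlock(X[order], y[order], None)
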