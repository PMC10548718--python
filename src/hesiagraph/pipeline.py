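"""End-to-end pipeline: graph build → leak removal → embedding → dataset →
rebalanced training → fixed-test-set evaluation, plus the ablation grid over
graph versions × weight modes × imbalance strategies.

The stage order implements the fixed-test-set protocol: the test pairs are
drawn first, their treatment (and, for negatives, adverse-reaction) edges are
removed from the graph *before* the embedding is trained, and every
cross-validation fold's model is scored on that same test set. Rerunning with
an identical configuration reproduces the report exactly.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field, replace

import pandas as pd

from . import kg as kgmod
from .dataset import (AssociationRecord, build_negative_set,
                      build_positive_set, make_pairset, split_test)
from .embedding import EmbeddingConfig, train_cbow, triplets_to_corpus
from .evaluation import CVReport, cross_validate
from .hesianet import ChannelConfig, ModelConfig, TrainConfig
from .kg import NodeType, build_kg, derive_drug_domain_edges, \
    remove_treatment_edges, validate_kg
from .synthetic import SyntheticConfig, generate

__all__ = ["PipelineConfig", "desk_config", "run_pipeline", "run_ablation_grid"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; file paths or a synthetic config as source."""

    # data source: either the four table paths, or a synthetic generator config
    nodes_path: str | None = None
    edges_path: str | None = None
    associations_path: str | None = None
    side_effects_path: str | None = None
    synthetic: SyntheticConfig | None = None

    version: str = "V1"
    status_filter: str = "approved"
    derive_domain_edges: bool = True
    test_fraction: float = 0.1
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    balance: str = "SORU"
    smote_ratio: float = 0.9
    k_neighbors: int = 5
    folds: int = 5
    repeats: int = 4
    seed: int = 7

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            return str(obj)

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2)


def desk_config(seed: int = 7, synthetic: SyntheticConfig | None = None
                ) -> PipelineConfig:
    """Desk-scale preset: small embedding and network, 2-fold single-repeat CV.

    These are the package's study conditions for synthetic end-to-end runs;
    the methods note documents the choices.
    """
    if synthetic is None:
        synthetic = SyntheticConfig(seed=seed)
    return PipelineConfig(
        synthetic=synthetic,
        embedding=EmbeddingConfig(vector_size=32, epochs=100, alpha=0.05,
                                  seed=seed),
        model=ModelConfig(channel=ChannelConfig(
            input_dim=32, layer_widths=(64, 32, 16, 16), dropout_rate=0.1),
            head_width=8),
        train=TrainConfig(learning_rate=3e-3, max_epochs=300,
                          early_stop_patience=60, lr_reduce_patience=25,
                          seed=seed),
        folds=2, repeats=1, seed=seed)


def _load_tables(config: PipelineConfig):
    if config.synthetic is not None:
        nodes, edges, assoc, sidefx, _ = generate(config.synthetic)
        return nodes, edges, assoc, sidefx
    for name in ("nodes_path", "edges_path", "associations_path",
                 "side_effects_path"):
        path = getattr(config, name)
        if path is None or not os.path.exists(path):
            raise FileNotFoundError(f"{name} missing or not found: {path}")
    return (kgmod.read_table(config.nodes_path),
            kgmod.read_table(config.edges_path),
            kgmod.read_table(config.associations_path),
            kgmod.read_table(config.side_effects_path))


def run_pipeline(config: PipelineConfig, outdir=None
                 ) -> tuple[CVReport, dict]:
    """Execute the full pipeline; returns the CV report and stage artifacts.

    With ``outdir`` given, writes ``kg.tsv``/``nodes.tsv``, ``corpus.txt``,
    ``emb.w2v``, ``pairs.tsv``, ``report.csv`` and a ``config.json`` echo
    under it.
    """
    t0 = time.time()
    log: dict = {"stages": {}}

    def stage(name, fn):
        t = time.time()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log["stages"][name] = round(time.time() - t, 3)
        return out

    nodes, edges, assoc, sidefx = stage("load", lambda: _load_tables(config))

    def build_pairs():
        records = [AssociationRecord(r.drug_id, r.disease_id, r.status)
                   for r in assoc.itertuples(index=False)]
        positives = build_positive_set(records, config.status_filter)
        sidefx_map: dict[str, set] = {}
        for r in sidefx.itertuples(index=False):
            sidefx_map.setdefault(r.drug_id, set()).add(r.term_id)
        diseases = set(nodes.loc[nodes.node_type == NodeType.DISEASE.value,
                                 "node_id"])
        negatives = build_negative_set(sidefx_map, diseases, positives)
        return make_pairset(positives, negatives)

    pairset = stage("pairs", build_pairs)
    train_ps, test_ps = stage(
        "split", lambda: split_test(pairset, config.test_fraction, config.seed))

    def build_graph():
        graph = build_kg(nodes, edges, "V1")
        if config.derive_domain_edges:
            graph = derive_drug_domain_edges(graph)
        graph = graph.subset(config.version)
        report = validate_kg(graph)
        if not report.ok:
            raise ValueError(f"graph failed validation: {len(report.errors)} errors")
        leak_pairs = [(p.drug, p.disease) for p in test_ps.pairs]
        return remove_treatment_edges(graph, leak_pairs)

    graph = stage("graph", build_graph)
    corpus = stage("corpus",
                   lambda: triplets_to_corpus(graph, config.embedding.seed))
    table = stage("embed", lambda: train_cbow(corpus, config.embedding))

    full = type(pairset)(train_ps.pairs + test_ps.pairs, dict(train_ps.provenance))
    report = stage("cv", lambda: cross_validate(
        full, table, config.model, config.train, folds=config.folds,
        repeats=config.repeats, seed=config.seed, balance=config.balance,
        smote_ratio=config.smote_ratio, k_neighbors=config.k_neighbors))
    log["total_seconds"] = round(time.time() - t0, 3)
    log["version"] = config.version

    artifacts = {"kg": graph, "corpus": corpus, "table": table,
                 "pairs": full, "log": log}
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        kgmod.save_kg(graph, os.path.join(outdir, "kg.tsv"),
                      os.path.join(outdir, "nodes.tsv"))
        corpus.save(os.path.join(outdir, "corpus.txt"))
        table.save(os.path.join(outdir, "emb.w2v"))
        full.to_frame().to_csv(os.path.join(outdir, "pairs.tsv"),
                               sep="\t", index=False)
        report.to_csv(os.path.join(outdir, "report.csv"))
        with open(os.path.join(outdir, "config.json"), "w") as fh:
            fh.write(config.to_json())
        with open(os.path.join(outdir, "log.json"), "w") as fh:
            json.dump(log, fh, indent=2)
    return report, artifacts


def run_ablation_grid(base: PipelineConfig, versions, modes, strategies,
                      outdir=None) -> pd.DataFrame:
    """One CV report per (version, weight mode, balance strategy) grid cell.

    Returns a long-format frame with mean and std per metric per cell.
    """
    versions, modes, strategies = list(versions), list(modes), list(strategies)
    if not versions or not modes or not strategies:
        raise ValueError("every grid axis must be non-empty")
    rows = []
    for version in versions:
        for mode in modes:
            for strategy in strategies:
                cfg = base.replace(
                    version=version, balance=strategy,
                    model=base.model.replace(weight_mode=mode))
                report, _ = run_pipeline(cfg)
                mu, sd = report.mean(), report.std()
                for metric in mu.index:
                    rows.append({"version": version, "weight_mode": mode,
                                 "balance": strategy, "metric": metric,
                                 "mean": mu[metric], "std": sd[metric]})
    frame = pd.DataFrame(rows)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        frame.to_csv(os.path.join(outdir, "ablation.csv"), index=False)
    return frame
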