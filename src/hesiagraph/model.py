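"""Model/Results front-end for the siamese link predictor.

`DrugDiseaseLinkModel` is built from data (feature blocks, or labelled pairs
plus an embedding table) and configuration; `fit()` trains the network and
returns a `LinkPredictionResults` carrying the trained network, the training
history, and evaluation helpers including a text `summary()`.
"""

from __future__ import annotations

import numpy as np

from .dataset import FeatureBlock, PairSet, pairs_to_features, rebalance
from .embedding import EmbeddingTable
from .evaluation import MetricReport, metrics
from .hesianet import (ChannelConfig, ModelConfig, SiameseModel, TrainConfig,
                       init_model, train)

__all__ = ["DrugDiseaseLinkModel", "LinkPredictionResults"]


class DrugDiseaseLinkModel:
    """Siamese drug-disease association classifier, statsmodels-style.

    Parameters
    ----------
    train_block, val_block
        Feature blocks of concatenated ``[E_drug || E_disease]`` rows with
        0/1 labels. The validation block monitors training (early stopping,
        learning-rate schedule); it is never rebalanced.
    model_config, train_config
        Architecture and optimization settings; defaults follow the
        reference architecture (1024-dim inputs, 512/256/128/64 channels,
        32-unit head, dropout 0.2, Adam at 5e-5).
    balance
        Optional imbalance strategy (IMB/RUS/ROS/OSMOTE/SORU) applied to the
        training block only, at fit time.
    """

    def __init__(self, train_block: FeatureBlock, val_block: FeatureBlock,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None,
                 balance: str = "IMB", smote_ratio: float = 0.9,
                 k_neighbors: int = 5):
        k2 = train_block.X.shape[1]
        if k2 % 2:
            raise ValueError("feature rows must have even width 2k")
        if model_config is None:
            model_config = ModelConfig(channel=ChannelConfig(input_dim=k2 // 2))
        if model_config.channel.input_dim * 2 != k2:
            raise ValueError(
                f"model input_dim {model_config.channel.input_dim} does not "
                f"match feature width {k2}")
        self.train_block = train_block
        self.val_block = val_block
        self.model_config = model_config
        self.train_config = train_config or TrainConfig()
        self.balance = balance
        self.smote_ratio = smote_ratio
        self.k_neighbors = k_neighbors

    @classmethod
    def from_pairs(cls, train_pairs: PairSet, val_pairs: PairSet,
                   table: EmbeddingTable, **kwargs) -> "DrugDiseaseLinkModel":
        return cls(pairs_to_features(train_pairs, table),
                   pairs_to_features(val_pairs, table), **kwargs)

    def fit(self, seed: int = 0) -> "LinkPredictionResults":
        tb = rebalance(self.train_block, self.balance,
                       smote_ratio=self.smote_ratio,
                       k_neighbors=self.k_neighbors, seed=seed)
        network = init_model(self.model_config, seed=seed)
        network, history = train(network, tb, self.val_block,
                                 self.train_config.replace(seed=seed))
        return LinkPredictionResults(self, network, history)


class LinkPredictionResults:
    """Fitted-state container returned by :meth:`DrugDiseaseLinkModel.fit`."""

    def __init__(self, model: DrugDiseaseLinkModel, network: SiameseModel,
                 history):
        self.model = model
        self.network = network
        self.history = history

    @property
    def n_params(self) -> int:
        return self.network.num_params()

    @property
    def best_val_acc(self) -> float:
        return float(self.history["val_acc"].max())

    def predict(self, block: FeatureBlock) -> np.ndarray:
        """Association probabilities for a feature block, inference mode."""
        k = self.network.config.channel.input_dim
        probs, _, _ = self.network.forward_batch(block.X[:, :k], block.X[:, k:])
        return probs

    def evaluate(self, block: FeatureBlock, threshold: float = 0.5) -> MetricReport:
        return metrics(block.y, self.predict(block), threshold)

    def summary(self) -> str:
        cfg = self.network.config
        val = self.model.val_block
        lines = [
            "Drug-Disease Link Prediction Results",
            "=" * 44,
            f"{'weight mode:':<24}{cfg.weight_mode}",
            f"{'channel widths:':<24}{cfg.channel.layer_widths}",
            f"{'head width:':<24}{cfg.head_width}",
            f"{'dropout rate:':<24}{cfg.channel.dropout_rate}",
            f"{'KL weight (lambda):':<24}{cfg.kl_weight}",
            f"{'trainable parameters:':<24}{self.n_params:,}",
            f"{'balance strategy:':<24}{self.model.balance}",
            f"{'train pairs:':<24}{len(self.model.train_block)}",
            f"{'validation pairs:':<24}{len(val)}",
            f"{'epochs run:':<24}{len(self.history)}",
            f"{'best val accuracy:':<24}{self.best_val_acc:.4f}",
        ]
        rep = self.evaluate(val)
        lines.append("-" * 44)
        lines.append("validation metrics at threshold 0.5:")
        for name in ("acc", "auc_roc", "auc_pr", "brier", "mcc", "f1"):
            lines.append(f"  {name:<10}{getattr(rep, name):.4f}")
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Loss/accuracy curves per epoch (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.history
        ax.plot(h["epoch"], h["train_loss"], label="train loss")
        ax.plot(h["epoch"], h["val_loss"], label="val loss")
        ax.plot(h["epoch"], h["val_acc"], label="val acc")
        ax.set_xlabel("epoch")
        ax.legend()
        return ax
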