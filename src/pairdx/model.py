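"""Model/Results interface for the gene-pair SDSAE classifier.

`GenePairClassifier` is constructed from a binary pair-feature matrix and
labels (or directly from a genes x samples expression frame via
:meth:`GenePairClassifier.from_expression`, which performs the pair
featurization and correlation filtering).  `fit()` runs greedy layerwise
pretraining followed by supervised fine-tuning and returns a
`GenePairClassifierResults` carrying the trained parameters, the training
log, the retained-pair vocabulary, and prediction / evaluation / summary
methods.  Results objects serialize to a single ``.npz`` container whose
manifest records every hyperparameter; save -> load -> predict is
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import sdsae
from .metrics import DiagnosticReport
from .pairs import (
    FilterResult,
    PairFeatureMatrix,
    filter_pairs,
    make_pair_index,
    restrict_to,
    score_pairs,
)

__all__ = ["GenePairClassifier", "GenePairClassifierResults"]


class GenePairClassifier:
    """Stacked denoising sparse autoencoder over binary gene-pair features.

    Parameters
    ----------
    features : PairFeatureMatrix or (n_samples, n_features) binary array
        Training features; typically the retained gene-pair indicators.
    labels : array of 0/1
        1 = malignant, 0 = benign.
    hidden_dims : widths of the stacked hidden layers (three layers of 20
        units by default).
    corruption : fraction of input coordinates zeroed during pretraining.
    sparsity_target : target mean activation of each hidden unit.
    sparsity_weight : weight of the KL sparsity penalty.
    """

    def __init__(
        self,
        features,
        labels,
        hidden_dims: tuple[int, ...] = (20, 20, 20),
        corruption: float = 0.5,
        sparsity_target: float = 0.1,
        sparsity_weight: float = 0.1,
        recon_loss: str = "bce",
        tied: bool = False,
        threshold: float = 0.5,
        retained_pairs: pd.DataFrame | None = None,
    ):
        if isinstance(features, PairFeatureMatrix):
            if retained_pairs is None:
                names = features.pair_index.pair_names()
                retained_pairs = pd.DataFrame(names, columns=["geneI", "geneII"])
            features = features.values
        self.exog = np.asarray(features, dtype=float)
        self.endog = np.asarray(labels, dtype=int)
        if self.exog.ndim != 2 or self.exog.shape[0] != len(self.endog):
            raise ValueError(
                f"features {self.exog.shape} and labels ({len(self.endog)},) are misaligned"
            )
        if not np.isin(self.endog, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        self.hidden_dims = tuple(int(h) for h in hidden_dims)
        self.corruption = corruption
        self.sparsity_target = sparsity_target
        self.sparsity_weight = sparsity_weight
        self.recon_loss = recon_loss
        self.tied = tied
        self.threshold = threshold
        self.retained_pairs = retained_pairs
        self.filter_result: FilterResult | None = None
        if self.exog.shape[0] < 3 * max(self.hidden_dims, default=1):
            import warnings

            warnings.warn(
                f"only {self.exog.shape[0]} samples for hidden width "
                f"{max(self.hidden_dims)}; pretraining may be unstable",
                stacklevel=2,
            )

    @classmethod
    def from_expression(
        cls,
        expr: pd.DataFrame,
        labels,
        roster=None,
        r_threshold: float = 0.4,
        p_threshold: float = 0.05,
        signed_r: bool = False,
        **kwargs,
    ) -> "GenePairClassifier":
        """Featurize a genes x samples expression frame and select pairs.

        Builds all C(n, 2) gene-pair indicators over ``roster`` (default: all
        genes in ``expr``), applies the correlation filter against ``labels``,
        and constructs the model on the retained features.  The fitted results
        carry the retained-pair vocabulary so held-out expression data can be
        featurized consistently.
        """
        idx = make_pair_index(roster if roster is not None else expr.index)
        feat = score_pairs(expr, idx)
        result = filter_pairs(feat, labels, r_threshold, p_threshold, signed=signed_r)
        kept = restrict_to(feat, result)
        model = cls(kept, labels, retained_pairs=result.retained_pairs(idx), **kwargs)
        model.filter_result = result
        return model

    def fit(
        self,
        epochs_pretrain: int = 100,
        epochs_finetune: int = 200,
        learning_rate: float = 0.1,
        batch_size: int = 32,
        val_fraction: float = 0.20,
        patience: int = 10,
        seed: int = 0,
    ) -> "GenePairClassifierResults":
        """Greedy layerwise pretraining, then fine-tuning with early stopping."""
        cfg = sdsae.TrainConfig(
            epochs_pretrain=epochs_pretrain,
            epochs_finetune=epochs_finetune,
            learning_rate=learning_rate,
            batch_size=batch_size,
            val_fraction=val_fraction,
            patience=patience,
            seed=seed,
        )
        layers = sdsae.build_stack(
            self.exog,
            cfg,
            hidden_dims=self.hidden_dims,
            q=self.corruption,
            rho=self.sparsity_target,
            beta=self.sparsity_weight,
            recon_loss=self.recon_loss,
            tied=self.tied,
        )
        params, log = sdsae.finetune(layers, self.exog, self.endog, cfg)
        log["pretrain_loss"] = [list(layer.loss_trace) for layer in layers]
        return GenePairClassifierResults(self, params, cfg, log)


class GenePairClassifierResults:
    """Fitted gene-pair SDSAE: parameters, training log, prediction, evaluation."""

    def __init__(self, model: GenePairClassifier | None, params, train_config, training_log):
        self.model = model
        self.params = params  # [(W1,b1), (W2,b2), (W3,b3), (W_soft,b_soft)]
        self.train_config = train_config
        self.training_log = training_log
        self.threshold = model.threshold if model is not None else 0.5
        self.retained_pairs = model.retained_pairs if model is not None else None

    # -- prediction ---------------------------------------------------------

    def _features(self, data) -> np.ndarray:
        if isinstance(data, PairFeatureMatrix):
            if self.retained_pairs is not None:
                have = set(map(tuple, data.pair_index.pair_names()))
                want = list(map(tuple, self.retained_pairs[["geneI", "geneII"]].to_numpy()))
                missing = [p for p in want if p not in have]
                if missing:
                    raise KeyError(f"feature matrix lacks {len(missing)} retained pairs, e.g. {missing[:3]}")
                pos = {p: k for k, p in enumerate(data.pair_index.pair_names())}
                data = data.values[:, [pos[p] for p in want]]
            else:
                data = data.values
        X = np.asarray(data, dtype=float)
        expected = self.params[0][0].shape[0]
        if X.ndim != 2 or X.shape[1] != expected:
            raise ValueError(f"expected {expected} features, got shape {X.shape}")
        return X

    def predict_proba(self, data) -> np.ndarray:
        """Probability of the malignant class per sample."""
        X = self._features(data)
        return sdsae.stack_forward(self.params, X)[:, 1]

    def predict(self, data) -> np.ndarray:
        """Binary call: 1 iff malignancy probability >= threshold (boundary inclusive)."""
        return (self.predict_proba(data) >= self.threshold).astype(int)

    def featurize_expression(self, expr: pd.DataFrame) -> np.ndarray:
        """Score only the retained pairs on held-out expression data."""
        if self.retained_pairs is None:
            raise ValueError("results carry no retained-pair vocabulary")
        gi = self.retained_pairs["geneI"].to_numpy()
        gj = self.retained_pairs["geneII"].to_numpy()
        missing = sorted(set(np.concatenate([gi, gj])) - set(expr.index))
        if missing:
            raise KeyError(f"expression matrix lacks retained-pair genes: {missing[:5]}")
        vi = expr.loc[list(gi)].to_numpy(dtype=float)
        vj = expr.loc[list(gj)].to_numpy(dtype=float)
        return (vi > vj).T.astype(np.uint8)

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, data, labels) -> DiagnosticReport:
        """Full diagnostic report (incl. AUC from probabilities) on held-out data."""
        proba = self.predict_proba(data)
        calls = (proba >= self.threshold).astype(int)
        return DiagnosticReport.from_calls(calls, np.asarray(labels, dtype=int), scores=proba)

    def summary(self, data=None, labels=None) -> str:
        """Human-readable fit summary; optionally with held-out diagnostics."""
        cfg = self.train_config
        lines = [
            "Gene-pair SDSAE classifier",
            "=" * 42,
            f"architecture        {self.params[0][0].shape[0]} -> "
            + " -> ".join(str(W.shape[1]) for W, _ in self.params[:-1])
            + " -> softmax(2)",
            f"corruption q        {self.model.corruption if self.model else 'n/a'}",
            f"sparsity target     {self.model.sparsity_target if self.model else 'n/a'}",
            f"sparsity weight     {self.model.sparsity_weight if self.model else 'n/a'}",
            f"train/val split     {self.training_log.get('n_train')}/{self.training_log.get('n_val')}"
            f" (val_fraction {cfg.val_fraction})",
            f"best epoch          {self.training_log.get('best_epoch')}"
            f" (val loss {self.training_log.get('best_val_loss'):.6f})",
            f"decision threshold  {self.threshold}",
        ]
        if self.retained_pairs is not None:
            lines.append(f"retained pairs      {len(self.retained_pairs)}")
        if data is not None and labels is not None:
            lines += ["", "Held-out diagnostics", "-" * 42, str(self.evaluate(data, labels))]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> Path:
        """Serialize to one .npz: JSON manifest + parameter arrays (+ vocabulary)."""
        path = Path(path)
        manifest = {
            "format": "pairdx-sdsae-v1",
            "n_layers": len(self.params) - 1,
            "threshold": self.threshold,
            "train_config": asdict(self.train_config),
            "training_log": {
                k: v for k, v in self.training_log.items() if k not in ("pretrain_loss",)
            },
            "hyperparameters": {
                "corruption": self.model.corruption,
                "sparsity_target": self.model.sparsity_target,
                "sparsity_weight": self.model.sparsity_weight,
                "recon_loss": self.model.recon_loss,
                "tied": self.model.tied,
                "hidden_dims": list(self.model.hidden_dims),
            }
            if self.model is not None
            else {},
        }
        blobs = {"manifest": np.array(json.dumps(manifest))}
        for k, (W, b) in enumerate(self.params):
            blobs[f"W_{k}"] = W
            blobs[f"b_{k}"] = b
        if self.retained_pairs is not None:
            blobs["geneI"] = self.retained_pairs["geneI"].to_numpy(dtype=str)
            blobs["geneII"] = self.retained_pairs["geneII"].to_numpy(dtype=str)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        np.savez(path, **blobs)
        return path

    @classmethod
    def load(cls, path) -> "GenePairClassifierResults":
        with np.load(path, allow_pickle=False) as z:
            manifest = json.loads(str(z["manifest"]))
            params = [
                (z[f"W_{k}"], z[f"b_{k}"]) for k in range(manifest["n_layers"] + 1)
            ]
            retained = None
            if "geneI" in z:
                retained = pd.DataFrame({"geneI": z["geneI"], "geneII": z["geneII"]})
        res = cls(None, params, sdsae.TrainConfig(**manifest["train_config"]), manifest["training_log"])
        res.threshold = manifest["threshold"]
        res.retained_pairs = retained
        return res
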