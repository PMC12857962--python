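"""Data splitting, the three-phase training protocol, and evaluation.

Splits
------
* ``transductive`` — pair-level random partition (default 60/20/20).
* ``inductive_random`` — drug-level partition; test pairs touch at least one
  held-out drug, train pairs use training drugs only, validation pairs touch
  a validation drug but no test drug.
* ``inductive_scaffold`` — identical, but drugs are grouped by Murcko
  scaffold first so no scaffold spans train and test.

Training
--------
Phase 1 optimizes the contrastive objective alone (augmentation-based
pretraining); phase 2 optimizes the joint objective L_DDI + alpha *
L_contrastive + beta * L_reg; phase 3 fine-tunes the joint objective at a
reduced learning rate with the spatial-bias table frozen.  AdamW, cosine
annealing per phase, gradient-norm clipping, early stopping on validation
loss.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .augmentation import Scaffold, build_scaffold_pool, sample_view
from .autodiff import Tensor, default_dtype, no_grad
from .chem import scaffold_smiles
from .config import ABLATION_VARIANTS, RunConfig
from .contrastive import EmbeddingBatch, batch_contrastive_loss
from .mol_io import DrugTable, MolecularGraph, PairRecord, featurize
from .model import DDIModel
from .nn import AdamW, clip_grad_norm, cosine_lr
from .prediction import total_loss

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass
class Split:
    train: list[int]
    val: list[int]
    test: list[int]


def make_split(pairs: list[PairRecord], drugs: DrugTable,
               cfg: RunConfig, seed: int | None = None) -> Split:
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = len(pairs)
    if cfg.split_mode == "transductive":
        f_train, f_val, _ = cfg.pair_fractions
        order = rng.permutation(n)
        n_train = int(round(f_train * n))
        n_val = int(round(f_val * n))
        return Split(train=order[:n_train].tolist(),
                     val=order[n_train:n_train + n_val].tolist(),
                     test=order[n_train + n_val:].tolist())
    if cfg.split_mode not in ("inductive_random", "inductive_scaffold"):
        raise ValueError(f"unknown split mode {cfg.split_mode!r}")
    ids = drugs.ids()
    f_train, f_val, f_test = cfg.drug_fractions
    if cfg.split_mode == "inductive_scaffold":
        groups: dict[str, list[str]] = {}
        for d in ids:
            key = scaffold_smiles(drugs.graph(d)) or f"acyclic::{d}"
            groups.setdefault(key, []).append(d)
        keys = list(groups)
        rng.shuffle(keys)
        buckets: list[list[str]] = [[], [], []]
        targets = [f_train * len(ids), f_val * len(ids), f_test * len(ids)]
        for key in keys:
            # greedy: most under-filled bucket relative to target
            deficit = [targets[k] - len(buckets[k]) for k in range(3)]
            buckets[int(np.argmax(deficit))].extend(groups[key])
        train_d, val_d, test_d = map(set, buckets)
    else:
        order = list(ids)
        rng.shuffle(order)
        n_train = int(round(f_train * len(order)))
        n_val = int(round(f_val * len(order)))
        train_d = set(order[:n_train])
        val_d = set(order[n_train:n_train + n_val])
        test_d = set(order[n_train + n_val:])
    if min(len(train_d), len(test_d)) < 2:
        raise ValueError(
            f"too few drugs for inductive split: train={len(train_d)}, "
            f"val={len(val_d)}, test={len(test_d)}")
    train, val, test = [], [], []
    for k, r in enumerate(pairs):
        in_test = r.drug_a in test_d or r.drug_b in test_d
        in_val = r.drug_a in val_d or r.drug_b in val_d
        if in_test:
            test.append(k)
        elif in_val:
            val.append(k)
        else:
            train.append(k)
    return Split(train=train, val=val, test=test)


def sample_negatives(positives: list[PairRecord], drugs: DrugTable,
                     rng: np.random.Generator,
                     ratio: float = 1.0) -> list[PairRecord]:
    """Uniform random non-positive pairs at the given ratio (1:1 default)."""
    known = {(min(r.drug_a, r.drug_b), max(r.drug_a, r.drug_b))
             for r in positives}
    ids = drugs.ids()
    want = int(round(ratio * len(positives)))
    out: list[PairRecord] = []
    guard = 0
    while len(out) < want:
        guard += 1
        if guard > 100 * want:
            raise RuntimeError("negative sampling exhausted attempts")
        a, b = rng.choice(len(ids), size=2, replace=False)
        key = (min(ids[a], ids[b]), max(ids[a], ids[b]))
        if key in known:
            continue
        known.add(key)
        out.append(PairRecord(ids[a], ids[b], label=0))
    return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    acc: float
    auc: float
    f1: float
    precision: float
    recall: float
    ap: float
    tp: int
    tn: int
    fp: int
    fn: int
    threshold: float
    n: int

    def as_dict(self) -> dict:
        return dict(vars(self))


def compute_metrics(y_true: np.ndarray, y_prob: np.ndarray,
                    threshold: float = 0.5) -> MetricsReport:
    """Confusion-matrix metrics at a threshold plus ranking metrics.

    AUC is the probability a random positive outranks a random negative
    (ties count one half); AP is the step-interpolated area under the
    precision-recall curve.  Both are NaN for single-class label sets.
    """
    y_true = np.asarray(y_true).astype(int).reshape(-1)
    y_prob = np.asarray(y_prob, dtype=np.float64).reshape(-1)
    pred = (y_prob >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    n = len(y_true)
    acc = (tp + tn) / n if n else float("nan")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class label set: AUC/AP undefined")
        auc = ap = float("nan")
    else:
        auc = float(roc_auc_score(y_true, y_prob))
        ap = float(average_precision_score(y_true, y_prob))
    return MetricsReport(acc=acc, auc=auc, f1=f1, precision=precision,
                         recall=recall, ap=ap, tp=tp, tn=tn, fp=fp, fn=fn,
                         threshold=threshold, n=n)


def evaluate(model: DDIModel, pairs: list[PairRecord], drugs: DrugTable,
             threshold: float | None = None,
             batch_size: int = 64) -> MetricsReport:
    """Metrics of symmetrized model predictions on labeled pairs."""
    threshold = model.cfg.threshold if threshold is None else threshold
    probs, labels = [], []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        ga = [drugs.graph(r.drug_a) for r in chunk]
        gb = [drugs.graph(r.drug_b) for r in chunk]
        probs.append(model.infer_pairs(ga, gb))
        labels.extend(r.label for r in chunk)
    return compute_metrics(np.asarray(labels), np.concatenate(probs),
                           threshold)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainLog:
    phase: int
    epoch: int
    loss: float
    val_loss: float | None = None
    lr: float = 0.0


@dataclass
class TrainResult:
    model: DDIModel
    logs: list[TrainLog] = field(default_factory=list)
    split: Split | None = None
    metrics: dict[str, MetricsReport] = field(default_factory=dict)


class Trainer:
    def __init__(self, model: DDIModel, drugs: DrugTable,
                 scaffold_pool: list[Scaffold] | None = None):
        self.model = model
        self.cfg = model.cfg
        self.drugs = drugs
        if scaffold_pool is None:
            scaffold_pool = build_scaffold_pool(
                [drugs.graph(d) for d in drugs.ids()])
        self.scaffold_pool = scaffold_pool
        ss = np.random.SeedSequence(self.cfg.seed)
        s_opt, s_aug, s_drop, s_batch = ss.spawn(4)
        self.rng_aug = np.random.default_rng(s_aug)
        self.rng_drop = np.random.default_rng(s_drop)
        self.rng_batch = np.random.default_rng(s_batch)
        self.optimizer = AdamW(model.parameters(),
                               lr=self.cfg.learning_rate)
        self._dtype = model._dtype

    # -- helpers -------------------------------------------------------------
    def _augmented(self, drug_id: str) -> MolecularGraph:
        view = sample_view(self.drugs.graph(drug_id), self.cfg,
                           self.rng_aug, self.scaffold_pool)
        g = view.view
        if g.atom_features is None:
            featurize(g)
        return g

    def _contrastive_term(self, drug_ids: list[str],
                          h_orig: Tensor | None = None) -> Tensor | None:
        if len(drug_ids) < 2:
            return None
        views = [self._augmented(d) for d in drug_ids]
        if h_orig is None:
            enc = self.model.encode([self.drugs.graph(d) for d in drug_ids],
                                    self.rng_drop, training=True)
            h_orig = enc.h_final
        enc_v = self.model.encode(views, self.rng_drop, training=True)
        batch = EmbeddingBatch(Z=self.model.project(h_orig),
                               Z_plus=self.model.project(enc_v.h_final),
                               drug_ids=drug_ids)
        return batch_contrastive_loss(batch, self.cfg)

    def _step(self, loss: Tensor, lr: float) -> float:
        self.optimizer.zero_grad()
        loss.backward()
        if not math.isfinite(loss.item()):
            raise FloatingPointError("training diverged: non-finite loss")
        clip_grad_norm(self.optimizer.params, self.cfg.grad_clip)
        self.optimizer.step(lr=lr)
        return loss.item()

    # -- phase 1: contrastive pretraining ------------------------------------
    def run_phase1(self, train_drugs: list[str], epochs: int | None = None
                   ) -> list[TrainLog]:
        epochs = self.cfg.phase1_epochs if epochs is None else epochs
        logs: list[TrainLog] = []
        if epochs == 0 or not self.cfg.use_contrastive:
            return logs
        bs = min(self.cfg.batch_size, max(2, len(train_drugs)))
        steps_per_epoch = max(1, len(train_drugs) // bs)
        total_steps = epochs * steps_per_epoch
        step = 0
        lr = self.cfg.learning_rate
        with default_dtype(self._dtype):
            for epoch in range(epochs):
                order = self.rng_batch.permutation(len(train_drugs))
                epoch_losses = []
                for s in range(steps_per_epoch):
                    batch_ids = [train_drugs[k]
                                 for k in order[s * bs:(s + 1) * bs]]
                    if len(batch_ids) < 2:
                        continue
                    term = self._contrastive_term(batch_ids)
                    lr = cosine_lr(self.cfg.learning_rate, step, total_steps)
                    epoch_losses.append(self._step(term, lr))
                    step += 1
                logs.append(TrainLog(1, epoch, float(np.mean(epoch_losses)),
                                     lr=lr))
        return logs

    # -- phases 2 & 3: joint objective ---------------------------------------
    def _joint_epochs(self, phase: int, pairs: list[PairRecord],
                      val_pairs: list[PairRecord], epochs: int,
                      lr_base: float, frozen: set[int]) -> list[TrainLog]:
        logs: list[TrainLog] = []
        if epochs == 0 or not pairs:
            return logs
        bs = min(self.cfg.batch_size, len(pairs))
        steps_per_epoch = max(1, len(pairs) // bs)
        total_steps = epochs * steps_per_epoch
        step = 0
        best_val = math.inf
        best_state = None
        patience_left = self.cfg.early_stop_patience
        for epoch in range(epochs):
            order = self.rng_batch.permutation(len(pairs))
            epoch_losses = []
            lr = lr_base
            with default_dtype(self._dtype):
                for s in range(steps_per_epoch):
                    chunk = [pairs[k] for k in order[s * bs:(s + 1) * bs]]
                    loss = self._joint_loss(chunk)
                    lr = cosine_lr(lr_base, step, total_steps)
                    self.optimizer.zero_grad()
                    loss.backward()
                    if not math.isfinite(loss.item()):
                        raise FloatingPointError("training diverged")
                    for pi in frozen:
                        self.optimizer.params[pi].grad = None
                    clip_grad_norm(self.optimizer.params, self.cfg.grad_clip)
                    self.optimizer.step(lr=lr)
                    epoch_losses.append(loss.item())
                    step += 1
            val_loss = None
            if val_pairs:
                val_loss = self._val_loss(val_pairs)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_state = self.model.state_dict()
                    patience_left = self.cfg.early_stop_patience
                else:
                    patience_left -= 1
            logs.append(TrainLog(phase, epoch, float(np.mean(epoch_losses)),
                                 val_loss, lr))
            if val_pairs and patience_left <= 0:
                logger.info("phase %d early stop at epoch %d", phase, epoch)
                break
        if best_state is not None:
            self.model.load_state_dict(best_state)
        return logs

    def _encode_pairs(self, chunk: list[PairRecord], training: bool
                      ) -> tuple[Tensor, Tensor, Tensor, list[str]]:
        drug_ids = sorted({d for r in chunk for d in (r.drug_a, r.drug_b)})
        pos = {d: i for i, d in enumerate(drug_ids)}
        graphs = [self.drugs.graph(d) for d in drug_ids]
        enc = self.model.encode(graphs, self.rng_drop, training=training)
        idx_a = np.asarray([pos[r.drug_a] for r in chunk], dtype=np.intp)
        idx_b = np.asarray([pos[r.drug_b] for r in chunk], dtype=np.intp)
        return enc.h_final[idx_a], enc.h_final[idx_b], enc.h_final, drug_ids

    def _joint_loss(self, chunk: list[PairRecord]) -> Tensor:
        h_a, h_b, h_all, drug_ids = self._encode_pairs(chunk, training=True)
        preds = self.model.predict_pairs(h_a, h_b, self.rng_drop,
                                         training=True)
        labels = np.asarray([r.label for r in chunk])
        term = None
        if self.cfg.use_contrastive and self.cfg.alpha > 0:
            term = self._contrastive_term(drug_ids, h_orig=h_all)
        loss, _ = total_loss(preds, labels, term,
                             self.optimizer.params, self.cfg)
        return loss

    def _val_loss(self, val_pairs: list[PairRecord],
                  batch_size: int = 128) -> float:
        total, count = 0.0, 0
        from .prediction import bce_loss
        with no_grad(), default_dtype(self._dtype):
            for start in range(0, len(val_pairs), batch_size):
                chunk = val_pairs[start:start + batch_size]
                h_a, h_b, _, _ = self._encode_pairs(chunk, training=False)
                preds = self.model.predict_pairs(h_a, h_b)
                labels = np.asarray([r.label for r in chunk])
                total += bce_loss(preds, labels, "sum").item()
                count += len(chunk)
        return total / max(count, 1)

    def run_phase2(self, pairs, val_pairs, epochs: int | None = None):
        epochs = self.cfg.phase2_epochs if epochs is None else epochs
        return self._joint_epochs(2, pairs, val_pairs, epochs,
                                  self.cfg.learning_rate, frozen=set())

    def run_phase3(self, pairs, val_pairs, epochs: int | None = None):
        """Fine-tune at a reduced learning rate with the spatial-bias
        embedding table frozen."""
        epochs = self.cfg.phase3_epochs if epochs is None else epochs
        bias = self.model.spatial_bias
        frozen = {i for i, p in enumerate(self.optimizer.params)
                  if bias is not None and p is bias.table}
        return self._joint_epochs(3, pairs, val_pairs, epochs,
                                  self.cfg.learning_rate
                                  * self.cfg.phase3_lr_factor, frozen)


def train_full(drugs: DrugTable, pairs: list[PairRecord], cfg: RunConfig,
               split: Split | None = None) -> TrainResult:
    """Split, run all three phases, and evaluate on every partition."""
    if split is None:
        split = make_split(pairs, drugs, cfg)
    model = DDIModel(cfg, np.random.default_rng(cfg.seed))
    trainer = Trainer(model, drugs)
    train_pairs = [pairs[k] for k in split.train]
    val_pairs = [pairs[k] for k in split.val]
    test_pairs = [pairs[k] for k in split.test]
    train_drugs = sorted({d for r in train_pairs
                          for d in (r.drug_a, r.drug_b)})
    logs = []
    logs += trainer.run_phase1(train_drugs)
    logs += trainer.run_phase2(train_pairs, val_pairs)
    logs += trainer.run_phase3(train_pairs, val_pairs)
    metrics = {
        "train": evaluate(model, train_pairs, drugs),
        "test": evaluate(model, test_pairs, drugs),
    }
    if val_pairs:
        metrics["val"] = evaluate(model, val_pairs, drugs)
    return TrainResult(model=model, logs=logs, split=split, metrics=metrics)


def run_ablation(drugs: DrugTable, pairs: list[PairRecord],
                 base_cfg: RunConfig,
                 variants: list[str] | None = None) -> "pd.DataFrame":
    """Train every ablation variant on the same split and seed; report
    metrics and parameter counts."""
    import pandas as pd
    names = variants or list(ABLATION_VARIANTS)
    unknown = set(names) - set(ABLATION_VARIANTS)
    if unknown:
        raise ValueError(f"unknown ablation variants: {sorted(unknown)}")
    split = make_split(pairs, drugs, base_cfg)
    rows = []
    for name in names:
        cfg = base_cfg.with_overrides(**ABLATION_VARIANTS[name])
        result = train_full(drugs, pairs, cfg, split=split)
        test = result.metrics["test"]
        rows.append({"variant": name,
                     "n_parameters": result.model.num_parameters(),
                     **{k: getattr(test, k)
                        for k in ("acc", "auc", "f1", "precision", "recall",
                                  "ap")}})
    return pd.DataFrame(rows)
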