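"""Uncertainty-aware antigen classification with OOD detection.

A small feed-forward classifier (dropout, dense 128 ReLU, dropout, dense
128 ReLU, dropout, softmax over classes) is trained on latent TCR
representations with the joint loss

    L = E_in[ -sum_c I(y=c) w_c log P(c|x) ] + alpha * E_out[ KL(U || P(.|x)) ]

where the first term is class-weighted cross-entropy on labeled
in-distribution (ID) TCRs and the second pushes predictions on unlabeled
background TCRs towards the uniform distribution U.  Class weights follow
the balanced heuristic w_c = n_total / (n_classes * n_c).

OOD detection scores a sample by the classifier confidence
N * max(P) / (N-1); AUROC of ID-vs-OOD on this score measures detection.
The "25%/40% retention" dropout figures are read as drop rates by
default (the Keras Dropout convention); a config switch selects the
literal keep-probability reading instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from . import nn
from .nn.autodiff import Tensor


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierConfig:
    n_classes: int = 8
    input_dim: int = 16
    alpha: float = 1.0
    labeled_batch: int = 32
    unlabeled_batch: int = 512
    patience: int = 5
    splits: tuple[float, float, float] = (0.75, 0.125, 0.125)
    n_mc_splits: int = 10
    max_epochs: int = 200
    learning_rate: float = 1e-3
    # "25%/40% retention": False (default) reads the figures as drop rates
    # (keep 0.75/0.60), the convention of Keras Dropout(0.25); True reads
    # them literally as keep-probabilities, which drops 75% of a 16-d input
    # and collapses in-distribution learning at small scale.
    retention_is_keep_prob: bool = False
    seed: int = 0

    def __post_init__(self):
        if not np.isclose(sum(self.splits), 1.0):
            raise InputError("splits must sum to 1")
        if self.labeled_batch < 1 or self.unlabeled_batch < 1:
            raise InputError("batch sizes must be >= 1")
        if self.alpha < 0:
            raise InputError("alpha must be >= 0")


class OODClassifier(nn.Module):
    """dropout -> dense(128, ReLU) -> dropout -> dense(128, ReLU)
    -> dropout -> dense(n_classes, softmax)."""

    def __init__(self, config: ClassifierConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        drop_rng = np.random.default_rng(config.seed + 7)
        if config.retention_is_keep_prob:
            keep = (0.25, 0.40, 0.40)
        else:
            keep = (0.75, 0.60, 0.60)
        self.drop0 = nn.Dropout(keep[0], drop_rng)
        self.fc1 = nn.Dense(config.input_dim, 128, rng)
        self.drop1 = nn.Dropout(keep[1], drop_rng)
        self.fc2 = nn.Dense(128, 128, rng)
        self.drop2 = nn.Dropout(keep[2], drop_rng)
        self.out = nn.Dense(128, config.n_classes, rng)

    def logits(self, x: Tensor) -> Tensor:
        h = self.drop0(x)
        h = self.drop1(self.fc1(h).relu())
        h = self.drop2(self.fc2(h).relu())
        return self.out(h)

    def log_probs(self, x: Tensor) -> Tensor:
        return self.logits(x).log_softmax(axis=-1)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        self.eval()
        lp = self.log_probs(Tensor(np.asarray(x, dtype=nn.get_dtype())))
        return np.exp(lp.data.astype(np.float64))


def build_classifier(input_dim: int = 16, n_classes: int = 8,
                     **kwargs) -> OODClassifier:
    return OODClassifier(ClassifierConfig(n_classes=n_classes,
                                          input_dim=input_dim, **kwargs))


def balanced_class_weights(y: np.ndarray, n_classes: int) -> np.ndarray:
    """w_c = n_total / (n_classes * n_c) over the training labels."""
    counts = np.bincount(np.asarray(y, dtype=int), minlength=n_classes)
    if (counts == 0).any():
        raise InputError("class absent from training portion")
    return len(y) / (n_classes * counts)


def classifier_loss(log_probs_id: Tensor, labels_id: np.ndarray,
                    log_probs_ood: Tensor | None, alpha: float,
                    class_weights: np.ndarray) -> Tensor:
    """Weighted cross-entropy plus alpha * mean KL(Uniform || P_theta)."""
    n = log_probs_id.shape[-1]
    onehot = np.zeros(log_probs_id.shape, dtype=log_probs_id.data.dtype)
    onehot[np.arange(len(labels_id)), np.asarray(labels_id, dtype=int)] = 1.0
    w = np.asarray(class_weights, dtype=log_probs_id.data.dtype)
    ce = -(log_probs_id * Tensor(onehot * w[None, :])).sum(axis=-1).mean()
    if alpha == 0.0 or log_probs_ood is None:
        return ce
    # KL(U || P) = sum_c (1/N) [log(1/N) - log P_c]
    u = 1.0 / n
    kl = ((log_probs_ood * (-u)).sum(axis=-1) + np.log(u)).mean()
    return ce + alpha * kl


def classifier_loss_from_probs(probs_id: np.ndarray, labels_id: np.ndarray,
                               probs_ood: np.ndarray | None, alpha: float,
                               class_weights: np.ndarray,
                               clip: float = 1e-12) -> float:
    """Numpy evaluation of the loss from probability rows (no gradients)."""
    for probs in (probs_id, probs_ood):
        if probs is not None and not np.allclose(probs.sum(axis=-1), 1.0,
                                                 atol=1e-5):
            raise InputError("probability rows must sum to 1")
    lp_id = Tensor(np.log(np.clip(probs_id, clip, None)))
    lp_ood = None if probs_ood is None else Tensor(
        np.log(np.clip(probs_ood, clip, None)))
    return float(classifier_loss(lp_id, labels_id, lp_ood, alpha,
                                 class_weights).data)


def confidence(probs: np.ndarray) -> np.ndarray:
    """Classifier confidence N * max(P) / (N - 1) per row."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    if np.any(np.abs(probs.sum(axis=-1) - 1.0) > 1e-6):
        raise InputError("probability rows must sum to 1")
    n = probs.shape[-1]
    return n * probs.max(axis=-1) / (n - 1)


def ood_auroc(confidences_id, confidences_ood) -> float:
    """AUROC of ID-vs-OOD with confidence as score (ID positive, ties 0.5)."""
    cid = np.asarray(confidences_id, dtype=float)
    cood = np.asarray(confidences_ood, dtype=float)
    if cid.size == 0 or cood.size == 0:
        raise InputError("both confidence groups must be non-empty")
    y = np.concatenate([np.ones(cid.size), np.zeros(cood.size)])
    return float(roc_auc_score(y, np.concatenate([cid, cood])))


def mannwhitney_compare(scores_a, scores_b) -> tuple[float, float, float]:
    """(U, two-sided p, effect size U/(n1*n2)).

    Exact p by enumeration for small tie-free samples; tie-corrected
    normal approximation otherwise.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("empty sample")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "asymptotic" if has_ties else "exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)
    return u, float(res.pvalue), u / (a.size * b.size)


def _train_one(model: OODClassifier, x_train, y_train, x_val, y_val,
               unlabeled: np.ndarray | None, config: ClassifierConfig,
               rng: np.random.Generator) -> OODClassifier:
    weights = balanced_class_weights(y_train, config.n_classes)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    alpha = config.alpha
    use_ood = alpha > 0 and unlabeled is not None and len(unlabeled) > 0
    # fixed unlabeled validation batch for a stable early-stopping signal
    if use_ood:
        val_ood_idx = rng.choice(len(unlabeled),
                                 size=min(config.unlabeled_batch, len(unlabeled)),
                                 replace=False)
        x_val_ood = unlabeled[val_ood_idx]
    best_val = np.inf
    best_state = None
    wait = 0
    n = len(x_train)
    for _epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(n)
        for start in range(0, n, config.labeled_batch):
            idx = order[start:start + config.labeled_batch]
            lp_id = model.log_probs(Tensor(x_train[idx]))
            lp_ood = None
            if use_ood:
                uidx = rng.choice(len(unlabeled), size=config.unlabeled_batch,
                                  replace=len(unlabeled) < config.unlabeled_batch)
                lp_ood = model.log_probs(Tensor(unlabeled[uidx]))
            loss = classifier_loss(lp_id, y_train[idx], lp_ood, alpha, weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
        model.eval()
        lp_val = model.log_probs(Tensor(x_val))
        lp_val_ood = model.log_probs(Tensor(x_val_ood)) if use_ood else None
        val_loss = float(classifier_loss(lp_val, y_val, lp_val_ood, alpha,
                                         weights).data)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return model


def train_classifier(id_latents: np.ndarray, id_labels,
                     unlabeled_latents: np.ndarray | None,
                     config: ClassifierConfig | None = None) -> list[dict]:
    """Monte Carlo cross-validation: one trained model per stratified split.

    Returns a list of dicts with keys ``model``, ``test_x``, ``test_y``
    (per-split held-out test partition) and ``split`` index.
    """
    config = config or ClassifierConfig()
    x = np.asarray(id_latents, dtype=nn.get_dtype())
    y_raw = np.asarray(id_labels)
    classes, y = np.unique(y_raw, return_inverse=True)
    if len(classes) < 2:
        raise InputError("need at least 2 ID classes")
    if len(classes) != config.n_classes:
        config = ClassifierConfig(**{**config.__dict__,
                                     "n_classes": len(classes)})
    unlabeled = (None if unlabeled_latents is None
                 else np.asarray(unlabeled_latents, dtype=nn.get_dtype()))
    f_train, f_val, f_test = config.splits
    results = []
    for split in range(config.n_mc_splits):
        seed = config.seed + 1000 * split
        x_tr, x_rest, y_tr, y_rest = train_test_split(
            x, y, train_size=f_train, stratify=y, random_state=seed)
        x_val, x_te, y_val, y_te = train_test_split(
            x_rest, y_rest, train_size=f_val / (f_val + f_test),
            stratify=y_rest, random_state=seed)
        cfg = ClassifierConfig(**{**config.__dict__, "seed": seed})
        model = OODClassifier(cfg)
        rng = np.random.default_rng(seed + 13)
        _train_one(model, x_tr, y_tr, x_val, y_val, unlabeled, cfg, rng)
        results.append({"split": split, "model": model, "test_x": x_te,
                        "test_y": y_te, "classes": classes})
    return results


def evaluate_ood(splits: list[dict], ood_latents: np.ndarray) -> pd.DataFrame:
    """Per-split ID classification AUROC (weighted OvR) and OOD AUROC."""
    ood_latents = np.asarray(ood_latents, dtype=nn.get_dtype())
    rows = []
    for res in splits:
        model = res["model"]
        p_id = model.predict_proba(res["test_x"])
        p_ood = model.predict_proba(ood_latents)
        n_classes = p_id.shape[1]
        if len(np.unique(res["test_y"])) == n_classes:
            id_auroc = float(roc_auc_score(res["test_y"], p_id,
                                           multi_class="ovr",
                                           average="weighted"))
        else:
            id_auroc = np.nan
        rows.append({"split": res["split"], "id_test_auroc_ovr": id_auroc,
                     "ood_auroc": ood_auroc(confidence(p_id),
                                            confidence(p_ood))})
    return pd.DataFrame(rows)
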