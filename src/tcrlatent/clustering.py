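"""Antigen-specificity clustering evaluation.

Latent embeddings are clustered with density-based clustering (DBSCAN,
Euclidean) over a sweep of the radius eps, and clusters are scored for
antigen purity: a cluster of at least ``min_cluster_size`` TCRs is *pure*
iff its modal antigen label covers strictly more than ``purity_threshold``
of its members.  Members of pure clusters are clustering true positives
(c-TP), members of retained impure clusters are c-FP, and everything else
(noise and members of sub-threshold clusters) is c-FN, so that
c-TP + c-FP + c-FN = n always.  The summary metrics are

    c-Precision = c-TP / (c-TP + c-FP)
    c-CSI       = c-TP / (c-TP + c-FP + c-FN).

The spike-in protocol appends irrelevant TCRs with unique labels at folds
1-5x the reference size and tracks the decay of these metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .simulate import spike_in

NOISE = -1


@dataclass
class ClusterEvaluation:
    eps: float
    n_clusters_scored: int
    c_tp: int
    c_fp: int
    c_fn: int
    c_precision: float
    c_csi: float
    per_cluster: list[dict] = field(default_factory=list)


def cluster_latents(latents: np.ndarray, eps: float,
                    min_samples: int = 2) -> np.ndarray:
    """DBSCAN labels (Euclidean); noise points get label -1."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    latents = np.asarray(latents)
    if not np.isfinite(latents).all():
        raise ValueError("non-finite latents")
    return DBSCAN(eps=eps, min_samples=min_samples).fit_predict(latents)


def score_clusters(labels: np.ndarray, antigen_labels,
                   min_cluster_size: int = 3,
                   purity_threshold: float = 0.9,
                   eps: float = np.nan) -> ClusterEvaluation:
    """Score a clustering against antigen labels (strict >threshold purity)."""
    labels = np.asarray(labels)
    antigens = np.asarray(antigen_labels)
    if len(labels) != len(antigens):
        raise ValueError("labels and antigen_labels are misaligned")
    n = len(labels)
    c_tp = c_fp = 0
    n_scored = 0
    per_cluster = []
    for cid in np.unique(labels):
        if cid == NOISE:
            continue
        members = antigens[labels == cid]
        size = len(members)
        if size < min_cluster_size:
            continue  # members fall through to c-FN
        n_scored += 1
        _, counts = np.unique(members, return_counts=True)
        modal = counts.max()
        purity = modal / size
        is_pure = purity > purity_threshold
        if is_pure:
            c_tp += size
        else:
            c_fp += size
        per_cluster.append({"cluster": int(cid), "size": int(size),
                            "purity": float(purity), "is_pure": bool(is_pure)})
    c_fn = n - c_tp - c_fp
    precision = c_tp / (c_tp + c_fp) if (c_tp + c_fp) > 0 else 0.0
    csi = c_tp / n if n > 0 else 0.0
    return ClusterEvaluation(eps=float(eps), n_clusters_scored=n_scored,
                             c_tp=c_tp, c_fp=c_fp, c_fn=c_fn,
                             c_precision=precision, c_csi=csi,
                             per_cluster=per_cluster)


def radius_sweep(latents: np.ndarray, antigen_labels, eps_grid,
                 min_cluster_size: int = 3, min_samples: int = 2
                 ) -> pd.DataFrame:
    """One evaluation per eps, ascending; columns eps, c_precision, c_csi."""
    eps_grid = sorted(eps_grid)
    if not eps_grid:
        raise ValueError("empty eps grid")
    rows = []
    for eps in eps_grid:
        labels = cluster_latents(latents, eps, min_samples)
        ev = score_clusters(labels, antigen_labels, min_cluster_size, eps=eps)
        rows.append({"eps": eps, "c_precision": ev.c_precision,
                     "c_csi": ev.c_csi, "c_tp": ev.c_tp, "c_fp": ev.c_fp,
                     "c_fn": ev.c_fn,
                     "n_clusters_scored": ev.n_clusters_scored})
    return pd.DataFrame(rows)


def correct_multi_assignment(assignments: dict) -> dict:
    """Resolve TCRs placed in several clusters (GLIPH2-style output).

    Each multi-assigned TCR keeps only its largest cluster (ties: lowest
    cluster id); clusters reduced to a single member afterwards become
    unclustered (value ``None``).
    """
    sizes: dict = {}
    for cids in assignments.values():
        for cid in cids:
            sizes[cid] = sizes.get(cid, 0) + 1
    chosen = {}
    for tcr, cids in assignments.items():
        if not cids:
            chosen[tcr] = None
            continue
        chosen[tcr] = min(sorted(cids), key=lambda c: (-sizes[c], c))
    new_sizes: dict = {}
    for cid in chosen.values():
        if cid is not None:
            new_sizes[cid] = new_sizes.get(cid, 0) + 1
    return {tcr: (cid if cid is not None and new_sizes[cid] > 1 else None)
            for tcr, cid in chosen.items()}


def spike_in_decay(latents_fn, labeled: pd.DataFrame,
                   irrelevant: pd.DataFrame, folds=range(0, 6),
                   replicates: int = 10, eps_grid=None,
                   min_cluster_size: int = 3, seed: int = 0) -> pd.DataFrame:
    """Clustering-metric decay under irrelevant-TCR spike-in.

    ``latents_fn`` maps a feature table (with feature_text) to an (n, d)
    latent array.  For each fold x replicate the labeled reference is
    spiked, embedded, swept over eps, and scored; per (fold, replicate) the
    row reports the evaluation at the eps with the best c-CSI, plus the
    full sweep eps for reference.
    """
    if eps_grid is None:
        eps_grid = np.round(np.arange(0.1, 2.01, 0.1), 3)
    rng = np.random.default_rng(seed)
    rows = []
    for fold in folds:
        n_rep = 1 if fold == 0 else replicates
        for rep in range(n_rep):
            spiked = spike_in(labeled, irrelevant, fold,
                              seed=int(rng.integers(2**31)), replicate=rep)
            latents = latents_fn(spiked)
            sweep = radius_sweep(latents, spiked["antigen_label"], eps_grid,
                                 min_cluster_size)
            best = sweep.iloc[int(sweep["c_csi"].idxmax())]
            rows.append({"fold": fold, "replicate": rep,
                         "eps": float(best["eps"]),
                         "c_precision": float(best["c_precision"]),
                         "c_csi": float(best["c_csi"]),
                         "n": len(spiked)})
    return pd.DataFrame(rows)
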