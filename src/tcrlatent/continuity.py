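"""Latent-traversal continuity metrics.

Two TCRs sharing a CDR3 but differing in CDR2 are embedded, the straight
line between their latent vectors is decoded at N points, and each decoded
array is scored by (i) its CDR2 region's distance to the nearest true
germline CDR2 and (ii) its CDR3 region's distance to the true shared CDR3.
The per-trajectory summaries are

    mean_d_cdr2 = (1/N) sum_i D_i,cdr2
    mean_d_cdr3 = (1/N) * 2 / (D_0,cdr3 + D_{N-1},cdr3} * sum_i D_i,cdr3

where the second is normalized by the reconstruction error at the two
trajectory endpoints so models of different capacity are comparable.

The distance d between equal-shape physicochemical arrays is the sum over
positions of the L1 distances between the per-position 8-vectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cvae import CVAE, decode_latents, embed
from .physchem import AminoAcidFeatureTable, default_feature_table, encode_batch


def interpolate(z1: np.ndarray, z2: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Equally spaced points z_i = i/(N-1) z1 + (N-1-i)/(N-1) z2.

    Note the printed convention: the path runs from z2 (i = 0) to z1
    (i = N-1).
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("latent widths differ")
    if n_points < 2:
        raise ValueError("need at least 2 interpolation points")
    w = np.arange(n_points) / (n_points - 1)
    return w[:, None] * z1[None, :] + (1.0 - w)[:, None] * z2[None, :]


def physchem_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Sum over positions of per-position L1 feature distances."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    return float(np.abs(x - y).sum())


def d_cdr2(decoded_region: np.ndarray, reference_encodings: np.ndarray) -> float:
    """Distance to the nearest true CDR2 encoding (min over the reference set)."""
    refs = np.asarray(reference_encodings)
    if refs.size == 0:
        raise ValueError("empty reference CDR2 set")
    dists = np.abs(refs - decoded_region[None]).sum(axis=(1, 2))
    return float(dists.min())


def _split_regions(arrays: np.ndarray, cdr2_len: int, cdr3_len: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """CDR2 occupies the first cdr2_len rows; CDR3 follows the gap row."""
    cdr2 = arrays[:, :cdr2_len, :]
    cdr3 = arrays[:, cdr2_len + 1:cdr2_len + 1 + cdr3_len, :]
    return cdr2, cdr3


def traversal_scores(model: CVAE, cdr2_a: str, cdr2_b: str, cdr3: str,
                     reference_cdr2s: list[str], n_points: int = 100,
                     table: AminoAcidFeatureTable | None = None
                     ) -> dict:
    """Score one traversal between ``cdr2_a-cdr3`` and ``cdr2_b-cdr3``.

    Both endpoint TCRs must share the CDR3; the decoded arrays are split
    into regions by the fixed feature-string layout of the endpoints
    (requires len(cdr2_a) == len(cdr2_b)).
    """
    if cdr2_a == cdr2_b:
        raise ValueError("endpoint CDR2s must differ")
    if len(cdr2_a) != len(cdr2_b):
        raise ValueError("endpoint CDR2s must have equal length")
    table = table or default_feature_table()
    l_max = model.config.l_max
    feats = [f"{cdr2_a}-{cdr3}", f"{cdr2_b}-{cdr3}"]
    x = encode_batch(feats, l_max, table)
    z = embed(model, x)
    zs = interpolate(z[0], z[1], n_points)
    decoded = decode_latents(model, zs)
    cdr2_len, cdr3_len = len(cdr2_a), len(cdr3)
    dec2, dec3 = _split_regions(decoded, cdr2_len, cdr3_len)
    refs = encode_batch(reference_cdr2s, cdr2_len, table)
    x0_cdr3 = encode_batch([cdr3], cdr3_len, table)[0]
    d2 = np.array([d_cdr2(dec2[i], refs) for i in range(n_points)])
    d3 = np.array([physchem_distance(x0_cdr3, dec3[i]) for i in range(n_points)])
    denom = d3[0] + d3[-1]
    mean_d3 = (2.0 / denom) * d3.sum() / n_points if denom > 0 else np.nan
    return {"d_cdr2_per_point": d2, "d_cdr3_per_point": d3,
            "mean_d_cdr2": float(d2.mean()), "mean_d_cdr3": float(mean_d3)}


def monte_carlo_traversals(model: CVAE, test_features: pd.DataFrame,
                           reference_cdr2s: list[str],
                           n_cdr3: int = 31, n_pairs_per_cdr3: int = 10,
                           cdr2_length: int = 6, n_points: int = 100,
                           seed: int = 0,
                           table: AminoAcidFeatureTable | None = None
                           ) -> pd.DataFrame:
    """The Monte Carlo traversal protocol.

    Samples ``n_cdr3`` distinct CDR3s from the test set and, for each,
    ``n_pairs_per_cdr3`` random pairs of reference CDR2s of the required
    length; one traversal (row) per (CDR3, CDR2 pair).
    """
    rng = np.random.default_rng(seed)
    if "feature_text" in test_features:
        cdr3s = (test_features["feature_text"].str.split("-").str[-1]
                 .drop_duplicates())
    else:
        cdr3s = pd.Series(test_features).drop_duplicates()
    if len(cdr3s) < n_cdr3:
        raise ValueError(f"need >= {n_cdr3} distinct CDR3s, have {len(cdr3s)}")
    cdr2_pool = sorted({c for c in reference_cdr2s if len(c) == cdr2_length})
    if len(cdr2_pool) < 2:
        raise ValueError(f"need >= 2 distinct CDR2s of length {cdr2_length}")
    chosen = rng.choice(cdr3s.to_numpy(), size=n_cdr3, replace=False)
    rows = []
    for cdr3 in chosen:
        for _ in range(n_pairs_per_cdr3):
            a, b = rng.choice(len(cdr2_pool), size=2, replace=False)
            scores = traversal_scores(model, cdr2_pool[a], cdr2_pool[b],
                                      cdr3, cdr2_pool, n_points, table)
            rows.append({"cdr3": cdr3, "cdr2_a": cdr2_pool[a],
                         "cdr2_b": cdr2_pool[b],
                         "mean_d_cdr2": scores["mean_d_cdr2"],
                         "mean_d_cdr3": scores["mean_d_cdr3"]})
    return pd.DataFrame(rows)
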