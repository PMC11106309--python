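"""Representation baselines for clustering comparisons.

Both flatten a fixed-length per-position encoding of the feature string
and reduce it to the latent dimensionality with PCA, mirroring the
comparison representations used alongside the learned embedding: raw
physicochemical arrays and one-hot residue encodings.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA

from .physchem import ALPHABET, AminoAcidFeatureTable, encode_batch


def physchem_flat(features, l_max: int = 28,
                  table: AminoAcidFeatureTable | None = None) -> np.ndarray:
    """Flattened (n, l_max*8) physicochemical representation."""
    x = encode_batch(list(features), l_max, table)
    return x.reshape(len(x), -1)


def onehot_flat(features, l_max: int = 28) -> np.ndarray:
    """Flattened (n, l_max*21) one-hot encoding over residues + gap."""
    idx = {c: i for i, c in enumerate(ALPHABET)}
    out = np.zeros((len(features), l_max, len(ALPHABET)), dtype=np.float32)
    for r, seq in enumerate(features):
        if len(seq) > l_max:
            raise ValueError(f"sequence length {len(seq)} exceeds {l_max}")
        for i in range(l_max):
            out[r, i, idx[seq[i]] if i < len(seq) else idx["-"]] = 1.0
    return out.reshape(len(features), -1)


def pca_embedding(flat: np.ndarray, n_components: int = 16,
                  fit_on: np.ndarray | None = None,
                  seed: int = 0) -> np.ndarray:
    """PCA reduction; optionally fit on a background set and project."""
    pca = PCA(n_components=n_components, random_state=seed)
    pca.fit(flat if fit_on is None else fit_on)
    return pca.transform(flat)
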