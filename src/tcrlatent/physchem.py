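"""Physicochemical encoding of amino-acid sequences and PWM back-projection.

A residue is represented by 8 numbers: 7 z-scored physicochemical
descriptors plus a gap-indicator flag.  A sequence becomes an
``L_max x 8`` array, padded at the end with the gap vector.  Any real-valued
array in this space projects back to a position weight matrix (PWM) over
the 20 amino acids plus the gap symbol through the inverse-L1 similarity

    delta(f, f_a) = 1 / (||f - f_a||_1 + eps),        eps = 1e-6,

normalized per position to a probability distribution.

The default descriptor set is the 7-parameter table of Meiler et al. (2001)
(steric parameter, polarizability, volume, hydrophobicity, isoelectric
point, helix and sheet propensity); any user-supplied 20x7 table may be
substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP  # 21 symbols; gap last
N_FEATURES = 8
DEFAULT_EPSILON = 1e-6


class EncodingError(ValueError):
    """Raised for malformed sequences or descriptor tables."""


@dataclass(frozen=True)
class AminoAcidFeatureTable:
    """Per-residue 8-vectors: 7 z-scored descriptors + gap flag.

    ``vectors`` has 21 rows ordered as ``ALPHABET`` (gap last).  The 7
    descriptor columns are z-scored over the 20 amino acids (mean 0,
    sample s.d. 1); the gap row is all-zero on descriptors with flag 1.
    """

    vectors: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self):
        if self.vectors.shape != (21, N_FEATURES):
            raise EncodingError(f"feature table must be 21x{N_FEATURES}, "
                                f"got {self.vectors.shape}")

    def vector(self, residue: str) -> np.ndarray:
        i = ALPHABET.find(residue)
        if i < 0:
            raise EncodingError(f"unknown residue {residue!r}")
        return self.vectors[i]

    @property
    def gap_vector(self) -> np.ndarray:
        return self.vectors[-1]


@dataclass(frozen=True)
class PhysicochemicalArray:
    """Fixed-length encoding of one sequence: ``values`` is L_max x 8."""

    values: np.ndarray
    true_length: int


@dataclass(frozen=True)
class PWM:
    """Row-stochastic L_max x 21 matrix over ``ALPHABET`` (gap last)."""

    probs: np.ndarray

    def __post_init__(self):
        if self.probs.ndim != 2 or self.probs.shape[1] != len(ALPHABET):
            raise EncodingError("PWM must have 21 columns")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, columns=list(ALPHABET))

    def to_tsv(self, path) -> None:
        """Plain-text position x residue table consumable by logo tools."""
        df = self.to_frame()
        df.index.name = "position"
        df.to_csv(path, sep="\t")


def load_default_descriptors() -> pd.DataFrame:
    """The bundled 20x7 descriptor table, indexed by residue."""
    with resources.files("tcrlatent.data").joinpath(
            "meiler_descriptors.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="residue")
    return df.loc[list(AMINO_ACIDS)]


def build_feature_table(raw: pd.DataFrame | np.ndarray | None = None
                        ) -> AminoAcidFeatureTable:
    """Z-score a 20x7 descriptor table and append the gap row.

    Parameters
    ----------
    raw:
        20x7 numeric table, rows ordered/indexed by the 20 standard amino
        acids.  ``None`` uses the bundled default.
    """
    if raw is None:
        raw = load_default_descriptors()
    if isinstance(raw, pd.DataFrame):
        if set(raw.index) == set(AMINO_ACIDS):
            raw = raw.loc[list(AMINO_ACIDS)]
        names = tuple(str(c) for c in raw.columns)
        values = raw.to_numpy()
    else:
        values = np.asarray(raw)
        names = tuple(f"descriptor_{i}" for i in range(values.shape[-1] if values.ndim == 2 else 0))
    if values.shape != (20, 7):
        raise EncodingError(f"descriptor table must be 20x7, got {values.shape}")
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise EncodingError("descriptor table contains non-finite entries")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise EncodingError("constant descriptor column cannot be z-scored")
    z = (values - mean) / sd
    vectors = np.zeros((21, N_FEATURES))
    vectors[:20, :7] = z
    vectors[20, 7] = 1.0  # gap flag
    return AminoAcidFeatureTable(vectors=vectors,
                                 feature_names=names + ("is_gap",))


_DEFAULT_TABLE: AminoAcidFeatureTable | None = None


def default_feature_table() -> AminoAcidFeatureTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = build_feature_table()
    return _DEFAULT_TABLE


def encode_sequence(seq: str, l_max: int,
                    table: AminoAcidFeatureTable | None = None
                    ) -> PhysicochemicalArray:
    """Encode ``seq`` (may contain '-') into an l_max x 8 array, gap-padded."""
    if table is None:
        table = default_feature_table()
    if len(seq) > l_max:
        raise EncodingError(f"sequence length {len(seq)} exceeds L_max={l_max}")
    idx = np.empty(l_max, dtype=int)
    for i, ch in enumerate(seq):
        j = ALPHABET.find(ch)
        if j < 0:
            raise EncodingError(f"unknown character {ch!r} at position {i}")
        idx[i] = j
    idx[len(seq):] = len(ALPHABET) - 1  # gap padding
    return PhysicochemicalArray(values=table.vectors[idx].copy(),
                                true_length=len(seq))


def encode_batch(seqs, l_max: int,
                 table: AminoAcidFeatureTable | None = None) -> np.ndarray:
    """Stack encodings of many sequences into (n, l_max, 8)."""
    return np.stack([encode_sequence(s, l_max, table).values for s in seqs])


def array_to_pwm(arr: PhysicochemicalArray | np.ndarray,
                 table: AminoAcidFeatureTable | None = None,
                 epsilon: float = DEFAULT_EPSILON) -> PWM:
    """Project an arbitrary L x 8 array onto a PWM over residues + gap."""
    if table is None:
        table = default_feature_table()
    if epsilon <= 0:
        raise EncodingError("epsilon must be positive")
    values = arr.values if isinstance(arr, PhysicochemicalArray) else np.asarray(arr)
    if values.ndim != 2 or values.shape[1] != N_FEATURES:
        raise EncodingError(f"array must be L x {N_FEATURES}")
    if not np.isfinite(values).all():
        raise EncodingError("array contains non-finite entries")
    # L1 distance of every position to every candidate residue: (L, 21)
    dist = np.abs(values[:, None, :] - table.vectors[None, :, :]).sum(axis=2)
    delta = 1.0 / (dist + epsilon)
    probs = delta / delta.sum(axis=1, keepdims=True)
    return PWM(probs=probs)


def pwm_consensus(pwm: PWM) -> str:
    """Per-position argmax residue; trailing gaps stripped.

    Ties break to the alphabetically first symbol; the gap sorts after all
    amino acids.
    """
    probs = pwm.probs
    # reorder columns alphabetically (gap last already; AMINO_ACIDS is sorted)
    best = probs.argmax(axis=1)  # first max wins; ALPHABET is sorted, gap last
    chars = [ALPHABET[i] for i in best]
    return "".join(chars).rstrip(GAP)
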