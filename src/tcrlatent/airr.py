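"""Quality control and feature assembly for AIRR-schema TCR rearrangements.

Input tables follow the AIRR rearrangement schema (1-based inclusive
nucleotide coordinates).  The pipeline is:

1. ``qc_filter``       — flag/junction/v_call quality rules;
2. ``annotate_cdrs``   — CDR1/CDR2 lookup from the resolved V gene;
3. ``extract_insert``  — translation of CDR3 codons containing at least one
   non-germline (neither V- nor J-encoded) nucleotide;
4. ``assemble_feature``— gap-joined CDR feature strings per chain format;
5. ``dedup_and_split`` — deduplicated, seeded train/val/test partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .physchem import AminoAcidFeatureTable, default_feature_table

QC_COLUMNS = ["locus", "productive", "vj_in_frame", "stop_codon",
              "junction_aa", "v_call", "j_call", "cdr3",
              "cdr3_start", "cdr3_end", "v_sequence_end", "j_sequence_start"]

# feature-string length caps (strings of this length or longer are dropped)
LENGTH_CAPS = {"CDR3": 28, "CDR2+3": 28, "CDR1+2+3": 35}


class CoordinateError(ValueError):
    pass


class AnnotationError(KeyError):
    pass


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().upper() in {"T", "TRUE", "1"}
    return bool(x)


def resolve_v_gene(v_call: str) -> str | None:
    """Collapse a v_call to its single V gene, or None if ambiguous.

    Multiple *alleles* of one gene are allowed and collapse to the gene
    (assumed allele *01); multiple genes disqualify the record.
    """
    if not isinstance(v_call, str) or not v_call.strip():
        return None
    genes = {part.split("*")[0].strip()
             for part in v_call.replace(";", ",").split(",") if part.strip()}
    if len(genes) != 1:
        return None
    return genes.pop()


def qc_filter(records: pd.DataFrame,
              min_len: int = 7, max_len: int = 24
              ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply junction/flag/v_call quality rules; return (passing, rejection log).

    Rules: productive, vj_in_frame true and stop_codon false;
    ``min_len <= len(junction_aa) < max_len``; junction starts with C, ends
    with F, contains none of X/*/U; v_call names exactly one V gene; the
    nucleotide coordinate fields are non-null.  Missing fields fail.
    """
    df = records.copy()
    n = len(df)
    log: dict[str, int] = {}
    for col in QC_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    def apply_rule(name: str, mask: pd.Series) -> None:
        nonlocal df
        mask = mask.astype(bool)
        log[name] = int((~mask).sum())
        df = df[mask]

    flags = (df["productive"].map(_as_bool, na_action="ignore").fillna(False)
             & df["vj_in_frame"].map(_as_bool, na_action="ignore").fillna(False)
             & ~df["stop_codon"].map(_as_bool, na_action="ignore").fillna(True))
    apply_rule("flags", flags.astype(bool))

    junc = df["junction_aa"].astype("string")
    apply_rule("junction_length",
               junc.str.len().ge(min_len).fillna(False)
               & junc.str.len().lt(max_len).fillna(False))
    junc = df["junction_aa"].astype("string")
    apply_rule("junction_bounds",
               (junc.str.startswith("C") & junc.str.endswith("F")).fillna(False))
    junc = df["junction_aa"].astype("string")
    apply_rule("junction_characters",
               ~junc.str.contains(r"[XU*]", regex=True).fillna(True))

    apply_rule("v_call_ambiguous",
               df["v_call"].map(lambda v: resolve_v_gene(v) is not None))

    coords = ["v_sequence_end", "cdr3_end", "j_sequence_start", "cdr3_start"]
    apply_rule("null_coordinates", df[coords].notna().all(axis=1))

    df = df.copy()
    df["v_gene"] = df["v_call"].map(resolve_v_gene)
    df["j_gene"] = df["j_call"].map(
        lambda j: j.split("*")[0].split(",")[0].strip()
        if isinstance(j, str) else j)
    log["input"] = n
    log["passed"] = len(df)
    return df, log


def load_germline_table(path_or_df) -> pd.DataFrame:
    """Germline V-gene table with columns v_gene, cdr1_aa, cdr2_aa."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep="\t")
    required = {"v_gene", "cdr1_aa", "cdr2_aa"}
    if not required.issubset(df.columns):
        raise AnnotationError(f"germline table needs columns {sorted(required)}")
    return df.set_index("v_gene") if df.index.name != "v_gene" else df


def annotate_cdrs(records: pd.DataFrame, germline: pd.DataFrame) -> pd.DataFrame:
    """Set cdr1_aa/cdr2_aa from the *01-allele germline entry of the V gene."""
    germ = load_germline_table(germline)
    out = records.copy()
    if "v_gene" not in out.columns:
        out["v_gene"] = out["v_call"].map(resolve_v_gene)
    missing = sorted(set(out["v_gene"]) - set(germ.index))
    if missing:
        raise AnnotationError(
            f"V genes absent from germline table: {', '.join(missing)}")
    out["cdr1_aa"] = out["v_gene"].map(germ["cdr1_aa"])
    out["cdr2_aa"] = out["v_gene"].map(germ["cdr2_aa"])
    return out


def extract_insert(record: pd.Series | dict) -> str:
    """Translate the CDR3 codons carrying >=1 non-germline nucleotide.

    Coordinates are 1-based inclusive; a nucleotide position p is
    non-germline iff ``v_sequence_end < p < j_sequence_start``.  Codons are
    the consecutive triplets of the cdr3 nucleotide sequence starting at
    ``cdr3_start``.
    """
    cdr3_start = int(record["cdr3_start"])
    cdr3_end = int(record["cdr3_end"])
    v_end = int(record["v_sequence_end"])
    j_start = int(record["j_sequence_start"])
    nt = str(record["cdr3"])
    if cdr3_start > cdr3_end:
        raise CoordinateError("cdr3_start > cdr3_end")
    length = cdr3_end - cdr3_start + 1
    if length % 3 != 0:
        raise CoordinateError("CDR3 nucleotide length not divisible by 3")
    if len(nt) < length:
        raise CoordinateError("cdr3 nucleotide sequence shorter than coordinates")
    codons_aa = str(Seq(nt[:length]).translate())
    out = []
    for k in range(length // 3):
        lo = cdr3_start + 3 * k          # first nt position of codon k
        hi = lo + 2                      # last nt position
        # any integer position p of the codon with v_end < p < j_start?
        if max(lo, v_end + 1) <= min(hi, j_start - 1):
            out.append(codons_aa[k])
    return "".join(out)


def assemble_feature(record: pd.Series | dict, chains: str = "TRB",
                     feature: str = "CDR2+3",
                     record_tra: pd.Series | dict | None = None) -> str | None:
    """Gap-joined CDR feature string; None if over the length cap.

    ``chains``: TRB, TRA or paired (paired joins TRB then TRA with a gap).
    ``feature``: CDR3, CDR2+3 or CDR1+2+3; CDRs are joined in the order
    CDR1-CDR2-CDR3 with '-'.
    """
    if feature not in LENGTH_CAPS:
        raise ValueError(f"unknown feature format {feature!r}")

    def one_chain(rec) -> str:
        parts = []
        if feature == "CDR1+2+3":
            parts.append(_require(rec, "cdr1_aa"))
        if feature in ("CDR2+3", "CDR1+2+3"):
            parts.append(_require(rec, "cdr2_aa"))
        parts.append(_require(rec, "junction_aa"))
        return "-".join(parts)

    cap = LENGTH_CAPS[feature]  # applies per chain
    if chains == "paired":
        if record_tra is None:
            raise ValueError("paired assembly needs both chain records")
        trb, tra = one_chain(record), one_chain(record_tra)
        if len(trb) >= cap or len(tra) >= cap:
            return None
        return trb + "-" + tra
    text = one_chain(record)
    if len(text) >= cap:
        return None
    return text


def _require(rec, key: str) -> str:
    val = rec[key] if key in rec else None
    if not isinstance(val, str) or not val:
        raise AnnotationError(f"missing CDR annotation {key!r}")
    return val


def assemble_features(records: pd.DataFrame, chains: str = "TRB",
                      feature: str = "CDR2+3") -> pd.DataFrame:
    """Vectorized single-chain assembly; returns rows that pass the cap.

    Output columns: feature_text, v_gene, j_gene and (if present) insert_aa.
    """
    texts = records.apply(
        lambda r: assemble_feature(r, chains=chains, feature=feature), axis=1)
    keep = texts.notna()
    out = records.loc[keep, [c for c in ("v_gene", "j_gene", "insert_aa")
                             if c in records.columns]].copy()
    out.insert(0, "feature_text", texts[keep])
    return out.reset_index(drop=True)


def dedup_and_split(features: pd.DataFrame, fractions=(0.8, 0.1, 0.1),
                    seed: int = 0,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Drop duplicate feature strings, then split train/val/test by seed.

    Rounding: floor for val and test, remainder to train.
    """
    if len(features) == 0:
        raise ValueError("empty feature table")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    df = features.drop_duplicates(subset="feature_text").reset_index(drop=True)
    n = len(df)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    return (df.iloc[np.sort(idx_train)].reset_index(drop=True),
            df.iloc[np.sort(idx_val)].reset_index(drop=True),
            df.iloc[np.sort(idx_test)].reset_index(drop=True))


def mean_insert_physchem(insert_aa: str,
                         table: AminoAcidFeatureTable | None = None
                         ) -> np.ndarray | None:
    """Mean of the 7 descriptor values over insert residues; None if empty."""
    if not insert_aa:
        return None
    if table is None:
        table = default_feature_table()
    vecs = np.stack([table.vector(a)[:7] for a in insert_aa])
    return vecs.mean(axis=0)


@dataclass(frozen=True)
class PreparedDataset:
    """Feature strings plus factor annotations and split assignment."""

    train: pd.DataFrame
    val: pd.DataFrame
    test: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for name, df in (("train", self.train), ("val", self.val),
                         ("test", self.test)):
            d = df.copy()
            d["split"] = name
            frames.append(d)
        return pd.concat(frames, ignore_index=True)


def prepare(records: pd.DataFrame, germline, chains: str = "TRB",
            feature: str = "CDR2+3", seed: int = 0) -> PreparedDataset:
    """Full pipeline: QC -> CDR annotation -> insert -> assembly -> split."""
    passed, _ = qc_filter(records)
    annotated = annotate_cdrs(passed, germline)
    annotated["insert_aa"] = annotated.apply(extract_insert, axis=1)
    feats = assemble_features(annotated, chains=chains, feature=feature)
    train, val, test = dedup_and_split(feats, seed=seed)
    return PreparedDataset(train=train, val=val, test=test)
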