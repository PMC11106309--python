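"""Synthetic V(D)J-recombined TCR repertoires with known generative factors.

The generator emulates beta-chain V(D)J recombination: a V gene contributes
germline CDR1/CDR2 and the conserved start of the CDR3 (ending in the
cysteine-anchored V tail), a quasi-random non-templated insert follows, and
a J gene contributes the phenylalanine-anchored CDR3 suffix.  Nucleotide
coordinates are constructed to be mutually consistent with the sampled
insert, so the AIRR pipeline (QC, CDR annotation, insert extraction)
round-trips every record.  D genes are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .physchem import AMINO_ACIDS

# reverse codon table: aa -> tuple of codons (stop codons excluded)
_CODONS: dict[str, tuple[str, ...]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, ())
    _CODONS[aa] += (codon,)


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class GermlineSet:
    """Toy germline: V entries (gene, cdr1, cdr2, v_tail) and J entries
    (gene, j_suffix).  V tails start with the conserved C; J suffixes end
    with the conserved F."""

    v_entries: tuple[tuple[str, str, str, str], ...]
    j_entries: tuple[tuple[str, str], ...]

    def __post_init__(self):
        names = [v[0] for v in self.v_entries] + [j[0] for j in self.j_entries]
        if len(set(names)) != len(names):
            raise SpecError("germline gene names must be unique")

    def v_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.v_entries,
                            columns=["v_gene", "cdr1_aa", "cdr2_aa",
                                     "v_tail_aa"]).set_index("v_gene")

    def cdr2_set(self, length: int | None = None) -> list[str]:
        cdr2s = [v[2] for v in self.v_entries]
        if length is not None:
            cdr2s = [c for c in cdr2s if len(c) == length]
        return sorted(set(cdr2s))


def toy_germline() -> GermlineSet:
    """Bundled toy germline: 8 V genes with distinct length-6 CDR2s, 4 Js."""
    v = (
        ("TRBV5-1", "SGHRS", "YFSETQ", "CASS"),
        ("TRBV6-5", "MNHEY", "SVGAGI", "CASR"),
        ("TRBV7-9", "SGHDY", "FNNNVP", "CAST"),
        ("TRBV9",   "SGDLS", "YYNGEE", "CASG"),
        ("TRBV19",  "LNHDA", "SQIVND", "CASQ"),
        ("TRBV20-1", "DFQAT", "SNEGSK", "CSAR"),
        ("TRBV27",  "MNHNS", "SASEGT", "CASN"),
        ("TRBV28",  "MDHEN", "SYDVKM", "CAWS"),
    )
    j = (
        ("TRBJ1-1", "TEAFF"),
        ("TRBJ1-2", "YGYTF"),
        ("TRBJ2-1", "NEQFF"),
        ("TRBJ2-7", "YEQYF"),
    )
    return GermlineSet(v_entries=v, j_entries=j)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic repertoire."""

    n_records: int = 1000
    insert_length: tuple[int, int, float] = (0, 10, 4.0)  # (min, max, mean)
    v_usage: tuple[float, ...] | None = None  # None = uniform
    j_usage: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        lo, hi, mean = self.insert_length
        if lo < 0 or hi < lo or not (lo <= mean <= hi):
            raise SpecError("insert_length must satisfy min <= mean <= max")
        for usage in (self.v_usage, self.j_usage):
            if usage is not None and not np.isclose(sum(usage), 1.0):
                raise SpecError("usage vector must sum to 1")


def _usage(usage, n: int, what: str) -> np.ndarray:
    if usage is None:
        return np.full(n, 1.0 / n)
    p = np.asarray(usage, dtype=float)
    if p.shape != (n,):
        raise SpecError(f"{what} usage vector length {p.size} != {n} genes")
    return p


def _rev_translate(aa: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[a][rng.integers(len(_CODONS[a]))] for a in aa)


def _sample_insert_length(spec: SyntheticSpec, rng) -> int:
    lo, hi, mean = spec.insert_length
    if hi == lo:
        return lo
    p = (mean - lo) / (hi - lo)
    return lo + int(rng.binomial(hi - lo, p))


def generate_repertoire(germline: GermlineSet | None = None,
                        spec: SyntheticSpec | None = None) -> pd.DataFrame:
    """Sample an AIRR-schema table of QC-clean beta-chain rearrangements.

    Ground-truth columns ``v_gene_true``, ``j_gene_true``, ``insert_true``
    record the sampled generative factors.
    """
    germline = germline or toy_germline()
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    pv = _usage(spec.v_usage, len(germline.v_entries), "V")
    pj = _usage(spec.j_usage, len(germline.j_entries), "J")
    aa_list = list(AMINO_ACIDS)

    rows = []
    for _ in range(spec.n_records):
        vi = rng.choice(len(germline.v_entries), p=pv)
        ji = rng.choice(len(germline.j_entries), p=pj)
        v_gene, _cdr1, _cdr2, v_tail = germline.v_entries[vi]
        j_gene, j_suffix = germline.j_entries[ji]
        ins_len = _sample_insert_length(spec, rng)
        insert = "".join(rng.choice(aa_list) for _ in range(ins_len))
        cdr3_aa = v_tail + insert + j_suffix
        nt = (_rev_translate(v_tail, rng) + _rev_translate(insert, rng)
              + _rev_translate(j_suffix, rng))
        cdr3_start = 10  # arbitrary offset on the rearrangement
        v_end = cdr3_start - 1 + 3 * len(v_tail)
        j_start = v_end + 3 * len(insert) + 1
        cdr3_end = cdr3_start + 3 * len(cdr3_aa) - 1
        rows.append({
            "locus": "TRB", "productive": True, "vj_in_frame": True,
            "stop_codon": False, "junction_aa": cdr3_aa,
            "v_call": f"{v_gene}*01", "j_call": f"{j_gene}*01",
            "cdr3": nt, "cdr3_start": cdr3_start, "cdr3_end": cdr3_end,
            "v_sequence_end": v_end, "j_sequence_start": j_start,
            "v_gene_true": v_gene, "j_gene_true": j_gene,
            "insert_true": insert,
        })
    return pd.DataFrame(rows)


def generate_labeled_clusters(n_antigens: int, tcrs_per_antigen: int,
                              motif_length: int = 6,
                              noise_substitutions: int = 1,
                              seed: int = 0,
                              min_separation: int = 3,
                              germline: GermlineSet | None = None,
                              ) -> tuple[pd.DataFrame, pd.Series]:
    """Antigen-labeled CDR2+3 feature strings with per-antigen shared motifs.

    Each antigen is assigned a fixed (V gene, J gene, CDR3 motif) triple;
    motifs of distinct antigens differ at >= ``min_separation`` positions.
    Members of an antigen carry the motif with at most
    ``noise_substitutions`` random substitutions.

    Returns the labeled table (feature_text, antigen_label) and the
    ground-truth partition (antigen label per row).
    """
    if tcrs_per_antigen < 3:
        raise SpecError("need at least 3 TCRs per antigen")
    germline = germline or toy_germline()
    rng = np.random.default_rng(seed)
    aa = list(AMINO_ACIDS)
    v_tail_len = len(germline.v_entries[0][3])
    j_len = len(germline.j_entries[0][1])
    if v_tail_len + motif_length + j_len >= 24:
        raise SpecError("motif too long for the CDR3 length budget")

    motifs: list[str] = []
    for _ in range(n_antigens):
        for _attempt in range(1000):
            cand = "".join(rng.choice(aa) for _ in range(motif_length))
            if all(sum(a != b for a, b in zip(cand, m)) >= min_separation
                   for m in motifs):
                motifs.append(cand)
                break
        else:
            raise SpecError("could not place motifs at the requested separation")

    rows = []
    for ai in range(n_antigens):
        v_gene, _c1, cdr2, v_tail = germline.v_entries[ai % len(germline.v_entries)]
        _j_gene, j_suffix = germline.j_entries[ai % len(germline.j_entries)]
        motif = motifs[ai]
        for _ in range(tcrs_per_antigen):
            m = list(motif)
            n_sub = int(rng.integers(0, noise_substitutions + 1))
            for pos in rng.choice(motif_length, size=n_sub, replace=False):
                m[pos] = aa[rng.integers(len(aa))]
            cdr3 = v_tail + "".join(m) + j_suffix
            rows.append({"feature_text": f"{cdr2}-{cdr3}",
                         "antigen_label": f"antigen_{ai}"})
    df = pd.DataFrame(rows)
    return df, df["antigen_label"].copy()


def spike_in(labeled: pd.DataFrame, irrelevant: pd.DataFrame, fold: int,
             seed: int = 0, replicate: int = 0) -> pd.DataFrame:
    """Append ``fold x len(labeled)`` irrelevant TCRs with unique labels.

    Spiked rows get labels ``spike_<replicate>_<index>`` that can never
    collide with antigen labels or each other, so they count against the
    purity of any cluster they join and cannot form pure clusters.
    """
    if fold < 0:
        raise SpecError("fold must be >= 0")
    if fold == 0:
        return labeled.copy()
    if len(irrelevant) == 0:
        raise ValueError("fold > 0 requires a non-empty irrelevant pool")
    rng = np.random.default_rng(seed)
    n_add = fold * len(labeled)
    idx = rng.choice(len(irrelevant), size=n_add,
                     replace=n_add > len(irrelevant))
    spiked = irrelevant.iloc[idx][["feature_text"]].copy()
    spiked["antigen_label"] = [f"spike_{replicate}_{i}" for i in range(n_add)]
    return pd.concat([labeled, spiked], ignore_index=True)
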