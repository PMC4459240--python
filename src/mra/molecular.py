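"""Kimura 2-parameter distances on labelled alignments.

The K2P model distinguishes transitions (A<->G, C<->T; proportion P) from
transversions (proportion Q) and estimates the substitution distance

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Sites where either sequence of a pair has a gap or an ambiguity code are
excluded for that pair ("pairwise deletion").  The module summarises
intraspecific and interspecific divergences from a species-labelled
alignment, the standard evidence table for a DNA-supported species split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "LabeledAlignment",
    "DistanceSummary",
    "read_fasta",
    "write_fasta",
    "k2p_distance",
    "k2p_matrix",
    "distance_summary",
]

_VALID = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class LabeledAlignment:
    """Aligned sequences with species labels.

    All sequences share one alignment length; headers follow the
    pipe-delimited dialect ``>sequence_id|species_label``.
    """

    ids: list[str]
    labels: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.seqs) < 2:
            raise ValueError("alignment needs at least 2 records")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def __len__(self) -> int:
        return len(self.seqs)


def read_fasta(path) -> LabeledAlignment:
    """Read an aligned FASTA with ``id|species`` headers.

    A header without the species token gets the label "unknown"; ragged
    lengths or an empty file raise ``ValueError``.
    """
    ids, labels, seqs = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        if "|" in header:
            sid, label = header.split("|", 1)
            sid, label = sid.strip(), label.strip()
        else:
            sid, label = header.strip(), "unknown"
        ids.append(sid)
        labels.append(label or "unknown")
        seqs.append(str(rec.seq).upper())
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return LabeledAlignment(ids, labels, seqs)


def write_fasta(aln: LabeledAlignment, path) -> None:
    """Write an alignment back with ``id|species`` headers."""
    records = [
        SeqRecord(Seq(s), id=f"{i}|{lab}", description="")
        for i, lab, s in zip(aln.ids, aln.labels, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """K2P distance between two equal-length aligned sequences.

    Gaps and ambiguity codes are pairwise-deleted before counting.  Returns
    NaN when the log arguments are non-positive (saturation); raises
    ``ValueError`` when no site survives pairwise deletion.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES and y in _PURINES) or \
           (x in _PYRIMIDINES and y in _PYRIMIDINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no sites remain after pairwise deletion")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return float("nan")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_matrix(aln: LabeledAlignment) -> pd.DataFrame:
    """Symmetric matrix of pairwise K2P distances (NaN where saturated)."""
    n = len(aln)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_distance(aln.seqs[i], aln.seqs[j])
            M[i, j] = M[j, i] = d
    return pd.DataFrame(M, index=aln.ids, columns=aln.ids)


@dataclass
class DistanceSummary:
    """Intra- and interspecific K2P divergence summaries."""

    matrix: pd.DataFrame
    intraspecific: pd.DataFrame   # index species; columns n_pairs, min, mean, max
    interspecific: pd.DataFrame   # index (species_1, species_2); same columns

    def to_tsv(self) -> str:
        out = ["# intraspecific K2P divergences",
               self.intraspecific.to_csv(sep="\t"),
               "# interspecific K2P divergences",
               self.interspecific.to_csv(sep="\t")]
        return "\n".join(out)


def distance_summary(aln: LabeledAlignment) -> DistanceSummary:
    """Per-species and per-species-pair K2P divergence ranges and means.

    Species with a single record get an intraspecific row of NaNs
    (not applicable).  Saturated (NaN) pairwise distances are excluded from
    the summaries.
    """
    M = k2p_matrix(aln)
    labels = np.array(aln.labels)
    vals = M.to_numpy()
    species = list(dict.fromkeys(aln.labels))  # stable order

    def summarize(d: np.ndarray) -> tuple[int, float, float, float]:
        d = d[~np.isnan(d)]
        if d.size == 0:
            return 0, float("nan"), float("nan"), float("nan")
        return int(d.size), float(d.min()), float(d.mean()), float(d.max())

    intra_rows = {}
    for sp in species:
        idx = np.where(labels == sp)[0]
        if len(idx) < 2:
            intra_rows[sp] = (0, float("nan"), float("nan"), float("nan"))
            continue
        pairs = vals[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)]
        intra_rows[sp] = summarize(pairs)
    intra = pd.DataFrame.from_dict(
        intra_rows, orient="index", columns=["n_pairs", "min", "mean", "max"])
    intra.index.name = "species"

    inter_rows = {}
    for i, sp1 in enumerate(species):
        for sp2 in species[i + 1:]:
            idx1 = np.where(labels == sp1)[0]
            idx2 = np.where(labels == sp2)[0]
            pairs = vals[np.ix_(idx1, idx2)].ravel()
            inter_rows[(sp1, sp2)] = summarize(pairs)
    inter = pd.DataFrame.from_dict(
        inter_rows, orient="index", columns=["n_pairs", "min", "mean", "max"])
    inter.index = pd.MultiIndex.from_tuples(
        inter_rows.keys(), names=["species_1", "species_2"]) if inter_rows else inter.index
    return DistanceSummary(M, intra, inter)


def label_agreement(labels_a: dict[str, str], labels_b: dict[str, str]) -> pd.DataFrame:
    """Cross-tabulate two cluster/label assignments over shared ids.

    A simple agreement table for comparing cluster memberships across two
    markers (e.g. a mitochondrial and a nuclear gene): perfect agreement
    puts all counts on a one-to-one block structure.
    """
    shared = sorted(set(labels_a) & set(labels_b))
    if not shared:
        raise ValueError("no shared sequence ids")
    df = pd.DataFrame({"a": [labels_a[s] for s in shared],
                       "b": [labels_b[s] for s in shared]})
    return pd.crosstab(df["a"], df["b"])
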