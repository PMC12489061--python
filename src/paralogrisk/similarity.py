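"""Pairwise paralog similarity: match-count global alignment and filtering.

Similarity between two gene sequences is the maximum number of identical
aligned pairs under global alignment with match = 1, mismatch = 0, gap = 0 —
which equals the length of the longest common subsequence (LCS) — divided by
a normalizer (the longer sequence length by default, so 1.0 iff identical).
Pairs scoring below a retention threshold (0.7 by default) are discarded; the
genes belonging to at least one retained pair form the "highly similar
paralog" set fed to the rearrangement-risk model.

The DP runs in O(|a|*|b|) time with an O(|b|) rolling row, vectorized across
the row: with candidates c[j] = max(prev[j], prev[j-1] + eq[j]), the current
row is the running maximum of c (rows are non-decreasing in j), so each row
is one ``numpy.maximum.accumulate``.  Comparison is case-insensitive and 'N'
matches nothing.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSequence",
    "ParalogFamilySet",
    "SimilarityMatrix",
    "match_count_alignment",
    "normalized_similarity",
    "family_matrix",
    "filter_pairs",
    "lcs_brute_force",
    "read_fasta",
    "read_family_table",
]

DEFAULT_THRESHOLD = 0.7
_N = ord("N")


@dataclass(frozen=True)
class GeneSequence:
    """A named nucleotide sequence (alphabet ACGTN, case-insensitive)."""

    gene_id: str
    sequence: str
    chromosome: str = ""


@dataclass
class ParalogFamilySet:
    """family ID -> member gene IDs."""

    families: dict[str, list[str]]

    def members(self) -> list[str]:
        return [g for genes in self.families.values() for g in genes]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def match_count_alignment(a: str | GeneSequence, b: str | GeneSequence) -> int:
    """Maximum number of identical aligned pairs under match=1/mismatch=0/gap=0
    global alignment; equals the LCS length.  Empty input returns 0."""
    sa = a.sequence if isinstance(a, GeneSequence) else a
    sb = b.sequence if isinstance(b, GeneSequence) else b
    if not sa or not sb:
        return 0
    A, B = _encode(sa), _encode(sb)
    if len(A) < len(B):  # roll the shorter row
        A, B = B, A
    prev = np.zeros(len(B) + 1, dtype=np.int32)
    cur = np.empty_like(prev)
    for ai in A:
        if ai == _N:
            eq = np.zeros(len(B), dtype=np.int32)
        else:
            eq = (B == ai).astype(np.int32)
        cand = np.maximum(prev[1:], prev[:-1] + eq)
        cur[0] = 0
        np.maximum.accumulate(cand, out=cur[1:])
        prev, cur = cur, prev
    return int(prev[-1])


def lcs_brute_force(a: str, b: str) -> int:
    """Exhaustive common-subsequence enumeration (oracle; lengths <= ~12)."""
    a, b = a.upper(), b.upper()
    short, other = (a, b) if len(a) <= len(b) else (b, a)
    best = 0
    for r in range(len(short), 0, -1):
        if r <= best:
            break
        for combo in itertools.combinations(short, r):
            if "N" in combo:
                continue
            it = iter(other)
            if all(c in it for c in combo):
                best = r
                break
    return best


def normalized_similarity(a: str | GeneSequence, b: str | GeneSequence,
                          norm: str = "max") -> float:
    """Match count normalized to [0, 1].

    norm='max' divides by the longer length (1.0 iff identical); 'min' by the
    shorter; 'alignment' by the global alignment length |a|+|b|-LCS.
    """
    sa = a.sequence if isinstance(a, GeneSequence) else a
    sb = b.sequence if isinstance(b, GeneSequence) else b
    if not sa or not sb:
        raise ValueError("similarity undefined for empty sequences")
    m = match_count_alignment(sa, sb)
    la, lb = len(sa), len(sb)
    if norm == "max":
        denom = max(la, lb)
    elif norm == "min":
        denom = min(la, lb)
    elif norm == "alignment":
        denom = la + lb - m
    else:
        raise ValueError(f"unknown normalization {norm!r} (use max|min|alignment)")
    return m / denom


@dataclass
class SimilarityMatrix:
    """Symmetric normalized-similarity matrix over an ordered gene set.

    Cells for pairs that were not scored (cross-family, unless all_pairs was
    requested) are NaN; the diagonal is 1.  ``threshold`` records the
    retention cutoff the matrix is meant to be filtered at.
    """

    gene_ids: list[str]
    values: pd.DataFrame
    threshold: float = DEFAULT_THRESHOLD
    norm: str = "max"

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.shape != (len(self.gene_ids),) * 2:
            raise ValueError("matrix shape does not match gene list")
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                raise ValueError("similarity values must lie in [0, 1]")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")

    def to_tsv(self, path: str | os.PathLike, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# threshold={self.threshold} norm={self.norm}\n")
            self.values.to_csv(fh, sep="\t", float_format="%.6g")

    def plot_heatmap(self, path: str | os.PathLike) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(max(4, len(self.gene_ids) * 0.2),) * 2)
        im = ax.imshow(self.values.to_numpy(dtype=float), vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(self.gene_ids)))
        ax.set_yticks(range(len(self.gene_ids)))
        ax.set_xticklabels(self.gene_ids, rotation=90, fontsize=5)
        ax.set_yticklabels(self.gene_ids, fontsize=5)
        fig.colorbar(im, ax=ax, label="normalized similarity")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def family_matrix(genes: Mapping[str, str] | Iterable[GeneSequence],
                  families: ParalogFamilySet | Mapping[str, list[str]],
                  norm: str = "max",
                  threshold: float = DEFAULT_THRESHOLD,
                  all_pairs: bool = False) -> SimilarityMatrix:
    """Score every within-family gene pair (all pairs with ``all_pairs``).

    ``genes`` maps gene ID -> sequence.  A family member without a sequence
    raises ``KeyError`` naming the gene.  Cross-family cells are NaN unless
    ``all_pairs``; the diagonal is 1.
    """
    if not isinstance(genes, Mapping):
        genes = {g.gene_id: g.sequence for g in genes}
    fams = families.families if isinstance(families, ParalogFamilySet) else families
    ordered: list[str] = []
    fam_of: dict[str, str] = {}
    for fam, members in fams.items():
        for g in members:
            if g not in genes:
                raise KeyError(f"no sequence for family member {g!r} (family {fam!r})")
            if g not in fam_of:
                fam_of[g] = fam
                ordered.append(g)
    n = len(ordered)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            if not all_pairs and fam_of[ordered[i]] != fam_of[ordered[j]]:
                continue
            sim = normalized_similarity(genes[ordered[i]], genes[ordered[j]], norm=norm)
            mat[i, j] = mat[j, i] = sim
    values = pd.DataFrame(mat, index=ordered, columns=ordered)
    return SimilarityMatrix(gene_ids=ordered, values=values, threshold=threshold, norm=norm)


def filter_pairs(matrix: SimilarityMatrix, threshold: float | None = None
                 ) -> tuple[list[tuple[str, str, float]], set[str]]:
    """Apply the retention filter: keep pairs with similarity >= threshold.

    Returns the retained (gene_a, gene_b, similarity) list and the set of
    genes appearing in at least one retained pair.
    """
    theta = matrix.threshold if threshold is None else threshold
    if not (0 < theta <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {theta}")
    ids = matrix.gene_ids
    v = matrix.values.to_numpy(dtype=float)
    pairs = []
    retained: set[str] = set()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if np.isnan(v[i, j]) or v[i, j] < theta:
                continue
            pairs.append((ids[i], ids[j], float(v[i, j])))
            retained.update((ids[i], ids[j]))
    return pairs, retained


def write_pairs_tsv(pairs: list[tuple[str, str, float]], path: str | os.PathLike,
                    header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("gene_a\tgene_b\tsimilarity\n")
        for a, b, s in pairs:
            fh.write(f"{a}\t{b}\t{s:.6g}\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Gene ID -> sequence from a FASTA file."""
    from Bio import SeqIO
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def read_family_table(path: str | os.PathLike) -> ParalogFamilySet:
    """TSV with columns family_id, gene_id (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "family_id" not in df.columns:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["family_id", "gene_id"], dtype=str)
    fams: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        fams.setdefault(row.family_id, []).append(row.gene_id)
    return ParalogFamilySet(families=fams)
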