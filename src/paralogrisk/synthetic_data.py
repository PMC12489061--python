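"""Synthetic genomes with planted paralog families, and noisy assay tables.

The generator plants gene families on a multi-chromosome genome: each family
descends from one random ancestral sequence, and every copy independently
accumulates per-base substitutions (uniform over the three alternative bases)
and single-base indels (insertion/deletion equally likely).  Two copies
derived at substitution rate ``s`` therefore agree per site with probability
``(1-s)^2 + s^2/3``.  Families are placed either dispersed (uniformly at
random, rejecting overlaps, chromosomes weighted by length) or tandem
(consecutive copies separated by a fixed spacer), which exercises interval
merging downstream.  Intergenic sequence is i.i.d. uniform ACGT.

Replicate assay measurements are emulated as multiplicative lognormal noise
around known true signal levels: a measurement with truth ``mu`` and
coefficient of variation ``cv`` is ``mu * exp(Z)`` with
``Z ~ N(-sigma^2/2, sigma^2)``, ``sigma^2 = ln(1 + cv^2)``, so the *expected
value* equals the truth and the ratio of group means is a consistent
estimator of the true ratio.

All randomness flows from one ``numpy.random.default_rng(seed)`` stream:
identical spec + seed gives byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .resection_risk import GenomeAnnotation, INTERVAL_COLUMNS

__all__ = [
    "FamilySpec",
    "GenomeSpec",
    "SyntheticTruth",
    "generate_genome",
    "generate_assay_replicates",
    "expected_pairwise_identity",
    "yeast_like_spec",
    "toy_spec",
    "write_fasta",
    "write_bed",
    "write_chrom_sizes",
    "write_truth_tsv",
    "SACCER_CHROM_SIZES",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: S. cerevisiae S288C (sacCer3) nuclear chromosome lengths, bp.
SACCER_CHROM_SIZES: dict[str, int] = {
    "chrI": 230218, "chrII": 813184, "chrIII": 316620, "chrIV": 1531933,
    "chrV": 576874, "chrVI": 270161, "chrVII": 1090940, "chrVIII": 562643,
    "chrIX": 439888, "chrX": 745751, "chrXI": 666816, "chrXII": 1078177,
    "chrXIII": 924431, "chrXIV": 784333, "chrXV": 1091291, "chrXVI": 948066,
}


@dataclass
class FamilySpec:
    """One planted paralog family."""

    n_copies: int = 2
    gene_length: int = 1300
    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    placement: str = "dispersed"          # dispersed | tandem
    tandem_spacer: int = 500
    name: str | None = None

    def __post_init__(self) -> None:
        if self.n_copies < 1 or self.gene_length < 1:
            raise ValueError("copy number and gene length must be >= 1")
        if not (0 <= self.substitution_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise ValueError("mutation rates must lie in [0, 1]")
        if self.placement not in ("dispersed", "tandem"):
            raise ValueError(f"unknown placement mode {self.placement!r}")
        if self.tandem_spacer < 0:
            raise ValueError("tandem spacer must be >= 0")


@dataclass
class GenomeSpec:
    """Chromosome lengths, family specs and the master seed."""

    chromosome_lengths: Sequence[int]
    families: Sequence[FamilySpec]
    seed: int = 0
    chromosome_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be > 0")
        if self.chromosome_names is None:
            self.chromosome_names = [f"chr{i + 1}" for i in range(len(self.chromosome_lengths))]
        if len(self.chromosome_names) != len(self.chromosome_lengths):
            raise ValueError("chromosome_names length mismatch")
        total_genes = sum(f.n_copies * f.gene_length for f in self.families)
        if total_genes > sum(self.chromosome_lengths):
            raise ValueError("total planted gene length exceeds genome length")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator.

    ``pair_identity``: per within-family gene pair, the expected per-site
    identity under the substitution process (exact for indel rate 0).
    ``assay_ratios``: per condition, the true sample/control ratio and the
    noise CV used.
    """

    pair_identity: pd.DataFrame   # gene_a, gene_b, family, expected_identity
    assay_ratios: pd.DataFrame    # condition, true_ratio, cv


def expected_pairwise_identity(substitution_rate: float) -> float:
    """Expected per-site identity between two copies that each mutated
    independently from the ancestor: both intact, or both substituted to the
    same base (probability 1/3 given both substituted)."""
    s = substitution_rate
    return (1 - s) ** 2 + s ** 2 / 3


def _mutate(seq: np.ndarray, sub_rate: float, indel_rate: float,
            rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    if sub_rate > 0:
        mask = rng.random(out.size) < sub_rate
        if mask.any():
            # shift by 1..3 in base space: always a different base
            idx = np.searchsorted(_BASES, out[mask])
            shift = rng.integers(1, 4, size=int(mask.sum()))
            out[mask] = _BASES[(idx + shift) % 4]
    if indel_rate > 0:
        r = rng.random(out.size)
        pieces: list[np.ndarray] = []
        for i, base in enumerate(out):
            if r[i] < indel_rate / 2:
                continue  # deletion
            pieces.append(out[i:i + 1])
            if r[i] < indel_rate:
                pieces.append(_BASES[rng.integers(0, 4, size=1)])  # insertion after
        out = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
    return out


def _place_dispersed(lengths: list[int], occupied: list[list[tuple[int, int]]],
                     gene_len: int, rng: np.random.Generator,
                     names: Sequence[str]) -> tuple[int, int]:
    """Pick (chromosome index, start) uniformly, rejecting overlaps."""
    weights = np.asarray(lengths, dtype=float)
    weights /= weights.sum()
    for _ in range(2000):
        ci = int(rng.choice(len(lengths), p=weights))
        if lengths[ci] < gene_len:
            continue
        start = int(rng.integers(0, lengths[ci] - gene_len + 1))
        if all(start >= e or start + gene_len <= s for s, e in occupied[ci]):
            occupied[ci].append((start, start + gene_len))
            return ci, start
    raise ValueError(
        f"cannot place a {gene_len}-bp gene without overlap (tried chromosomes "
        f"including {names[ci]!r}); genome too crowded"
    )


def _place_tandem(lengths: list[int], occupied: list[list[tuple[int, int]]],
                  block_len: int, rng: np.random.Generator,
                  names: Sequence[str]) -> tuple[int, int]:
    fitting = [i for i, ln in enumerate(lengths) if ln >= block_len]
    if not fitting:
        raise ValueError(
            f"no chromosome can hold a {block_len}-bp tandem block "
            f"(longest is {names[int(np.argmax(lengths))]!r} at {max(lengths)} bp)"
        )
    weights = np.asarray([lengths[i] for i in fitting], dtype=float)
    weights /= weights.sum()
    for _ in range(2000):
        ci = int(rng.choice(fitting, p=weights))
        start = int(rng.integers(0, lengths[ci] - block_len + 1))
        if all(start >= e or start + block_len <= s for s, e in occupied[ci]):
            occupied[ci].append((start, start + block_len))
            return ci, start
    raise ValueError(
        f"cannot place a {block_len}-bp tandem block without overlap "
        f"(last tried chromosome {names[ci]!r})"
    )


def generate_genome(spec: GenomeSpec) -> tuple[GenomeAnnotation, dict[str, str], SyntheticTruth]:
    """Plant the families of ``spec`` and return annotation, sequences, truth.

    Gene intervals record the *planted* length; with a non-zero indel rate the
    returned sequence length can differ by the net indel balance (the interval
    keeps the planted footprint — downstream interval math only needs
    coordinates).
    """
    rng = np.random.default_rng(spec.seed)
    lengths = [int(c) for c in spec.chromosome_lengths]
    names = list(spec.chromosome_names)
    occupied: list[list[tuple[int, int]]] = [[] for _ in lengths]
    records = []
    seqs: dict[str, str] = {}
    truth_rows = []
    for fi, fam in enumerate(spec.families):
        fam_name = fam.name or f"fam{fi:03d}"
        ancestor = _BASES[rng.integers(0, 4, size=fam.gene_length)]
        copies = [_mutate(ancestor, fam.substitution_rate, fam.indel_rate, rng)
                  for _ in range(fam.n_copies)]
        gene_ids = [f"{fam_name}_g{k}" for k in range(fam.n_copies)]
        if fam.placement == "tandem":
            block = fam.n_copies * fam.gene_length + (fam.n_copies - 1) * fam.tandem_spacer
            ci, start = _place_tandem(lengths, occupied, block, rng, names)
            for k, gid in enumerate(gene_ids):
                s = start + k * (fam.gene_length + fam.tandem_spacer)
                strand = "+" if rng.random() < 0.5 else "-"
                records.append((names[ci], s, s + fam.gene_length, gid, strand))
        else:
            for gid in gene_ids:
                ci, s = _place_dispersed(lengths, occupied, fam.gene_length, rng, names)
                strand = "+" if rng.random() < 0.5 else "-"
                records.append((names[ci], s, s + fam.gene_length, gid, strand))
        for gid, seq in zip(gene_ids, copies):
            seqs[gid] = seq.tobytes().decode("ascii")
        exp_id = expected_pairwise_identity(fam.substitution_rate)
        for i in range(fam.n_copies):
            for j in range(i + 1, fam.n_copies):
                truth_rows.append((gene_ids[i], gene_ids[j], fam_name, exp_id))
    ann = GenomeAnnotation(
        chrom_sizes=dict(zip(names, lengths)),
        intervals=pd.DataFrame(records, columns=INTERVAL_COLUMNS),
    )
    truth = SyntheticTruth(
        pair_identity=pd.DataFrame(truth_rows,
                                   columns=["gene_a", "gene_b", "family", "expected_identity"]),
        assay_ratios=pd.DataFrame(columns=["condition", "true_ratio", "cv"]),
    )
    return ann, seqs, truth


def family_table(spec: GenomeSpec) -> pd.DataFrame:
    """family_id/gene_id table matching generate_genome's gene naming."""
    rows = []
    for fi, fam in enumerate(spec.families):
        fam_name = fam.name or f"fam{fi:03d}"
        for k in range(fam.n_copies):
            rows.append((fam_name, f"{fam_name}_g{k}"))
    return pd.DataFrame(rows, columns=["family_id", "gene_id"])


# ---------------------------------------------------------------------------
# Assay replicate generator
# ---------------------------------------------------------------------------

def generate_assay_replicates(true_ratio: float, cv: float, n: int, seed: int,
                              strain: str = "sample", condition: str = "cond",
                              kind: str = "dlc_signal",
                              control_level: float = 1.0) -> pd.DataFrame:
    """``n`` paired sample/control measurements with lognormal noise.

    Sample truth = ``true_ratio * control_level``, control truth =
    ``control_level``; each measurement is truth * lognormal(mean 1, given
    CV), so E[sample]/E[control] = true_ratio.  Returns an AssayTable
    DataFrame (strain, condition, replicate, kind, value, pair_id).
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n < 2:
        raise ValueError("need n >= 2 replicates")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv ** 2)
    noise = lambda size: np.exp(rng.normal(-sigma2 / 2, np.sqrt(sigma2), size=size))
    sample_vals = true_ratio * control_level * noise(n)
    control_vals = control_level * noise(n)
    rows = []
    for i in range(n):
        pair = f"{condition}_r{i}"
        rows.append((strain, condition, i, kind, sample_vals[i], pair))
        rows.append((f"{strain}_ctrl", condition, i, kind, control_vals[i], pair))
    return pd.DataFrame(rows, columns=["strain", "condition", "replicate",
                                       "kind", "value", "pair_id"])


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def toy_spec(seed: int = 42) -> GenomeSpec:
    """Small two-chromosome fixture: one tandem and two dispersed families."""
    return GenomeSpec(
        chromosome_lengths=[60_000, 40_000],
        families=[
            FamilySpec(n_copies=3, gene_length=800, substitution_rate=0.05,
                       placement="tandem", tandem_spacer=400, name="tandemA"),
            FamilySpec(n_copies=2, gene_length=1200, substitution_rate=0.02, name="dispB"),
            FamilySpec(n_copies=2, gene_length=600, substitution_rate=0.15, name="dispC"),
        ],
        seed=seed,
    )


def yeast_like_spec(seed: int = 0) -> GenomeSpec:
    """Synthetic stand-in for the curated budding-yeast paralog set.

    Emulates the published summary features of the real list — ~270 genes in
    families covering ~3% of the ~12.07-Mb, 16-chromosome nuclear genome, with
    within-family similarity mostly above 70% — on the real sacCer3
    chromosome lengths.  Composition: 100 two-copy families (whole-genome-
    duplication-like), 10 three-copy and 5 four-copy families, and 2 ten-copy
    tandem arrays (subtelomeric-family-like), totalling 270 genes.  Gene
    lengths are lognormal (median ~1.2 kb); substitution rates are uniform on
    [0.02, 0.12].  This is a synthetic emulation, not the curated list.
    """
    rng = np.random.default_rng(seed)
    sizes = [(2, "dispersed")] * 100 + [(3, "dispersed")] * 10 + \
            [(4, "dispersed")] * 5 + [(10, "tandem")] * 2
    families = []
    for i, (n_copies, placement) in enumerate(sizes):
        glen = int(np.clip(rng.lognormal(np.log(1200), 0.45), 300, 6000))
        families.append(FamilySpec(
            n_copies=n_copies,
            gene_length=glen,
            substitution_rate=float(rng.uniform(0.02, 0.12)),
            placement=placement,
            tandem_spacer=int(rng.integers(200, 1500)),
            name=f"yfam{i:03d}",
        ))
    return GenomeSpec(
        chromosome_lengths=list(SACCER_CHROM_SIZES.values()),
        chromosome_names=list(SACCER_CHROM_SIZES.keys()),
        families=families,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Writers (plain-text, deterministic)
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord
    records = [SeqRecord(Seq(s), id=gid, description="") for gid, s in seqs.items()]
    seqio_write(records, str(path), "fasta")


def write_bed(ann: GenomeAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for row in ann.intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t0\t{row.strand}\n")


def write_chrom_sizes(ann: GenomeAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in ann.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def write_truth_tsv(truth: SyntheticTruth, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# synthetic ground truth\n")
        truth.pair_identity.to_csv(fh, sep="\t", index=False, float_format="%.6g")
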