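import numpy as np
import pandas as pd
import pytest

from paralogrisk import GenomeAnnotation


def make_annotation(chrom_sizes, intervals):
    """intervals: list of (chrom, start, end[, name[, strand]])."""
    rows = []
    for i, iv in enumerate(intervals):
        chrom, start, end = iv[:3]
        name = iv[3] if len(iv) > 3 else f"g{i}"
        strand = iv[4] if len(iv) > 4 else "+"
        rows.append((chrom, start, end, name, strand))
    return GenomeAnnotation(
        chrom_sizes=dict(chrom_sizes),
        intervals=pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"]),
    )


def random_annotation(rng, max_chrom=60_000, max_repeats=8):
    """Random small genome with dispersed, tandem-overlapping and
    edge-clipped repeats, for oracle-equivalence checks."""
    n_chroms = int(rng.integers(1, 4))
    sizes = {f"c{i}": int(rng.integers(5_000, max_chrom)) for i in range(n_chroms)}
    rows = []
    gid = 0
    for chrom, size in sizes.items():
        for _ in range(int(rng.integers(0, max_repeats))):
            length = int(rng.integers(50, 3_000))
            if length >= size:
                continue
            if rng.random() < 0.2:  # edge-hugging repeat
                start = 0 if rng.random() < 0.5 else size - length
            else:
                start = int(rng.integers(0, size - length))
            rows.append((chrom, start, start + length, f"r{gid}", "+"))
            gid += 1
            if rng.random() < 0.3:  # overlapping/tandem partner
                off = int(rng.integers(1, max(2, length)))
                s2 = min(start + off, size - 1)
                e2 = min(s2 + length, size)
                if e2 > s2:
                    rows.append((chrom, s2, e2, f"r{gid}", "-"))
                    gid += 1
    return GenomeAnnotation(
        chrom_sizes=sizes,
        intervals=pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
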