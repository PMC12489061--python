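"""Ratio statistics for recombination assay quantification.

Implements the replicate-level quantities reported for the D-loop capture
(DLC) / D-loop extension (DLE), ectopic-recombination and MIR-translocation
assays: matched-control relative levels, fold inhibition, intra/inter donor
preference, circularization-normalized non-crossover/crossover frequencies,
plating viability, and break-dependent Lys+ recombinant frequencies — plus
the significance-testing rule used throughout (two-tailed Mann-Whitney-
Wilcoxon, falling back to a two-tailed Student t-test when either group has
fewer than 4 replicates).

Group summaries are arithmetic means with SEM.  Ratios are computed
per-replicate when a pairing is available (sample and control scored in
parallel), otherwise as the ratio of group means.  All quantities are
invariant under rescaling every signal by a common positive factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RatioSummary",
    "MirResult",
    "TestResult",
    "relative_level",
    "fold_inhibition",
    "donor_preference",
    "recombinant_frequency",
    "plating_viability",
    "mir_frequency",
    "rank_sum_compare",
    "get_values",
]

MEASUREMENT_KINDS = frozenset({
    "dlc_signal", "dle_signal", "junction_NCO", "junction_CO",
    "circ_control", "loading_control", "colonies_selective", "colonies_total",
})

SMALL_N_T_TEST = 4  # below this replicate count the t-test is used


def _as_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    if (arr < 0).any():
        raise ValueError(f"{name} contains negative values")
    return arr


def _sem(arr: np.ndarray) -> float:
    return float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")


@dataclass
class RatioSummary:
    """Per-replicate ratios (when paired) with mean and SEM."""

    ratios: np.ndarray | None   # None when only a ratio of means is defined
    mean: float                 # mean of per-replicate ratios, or ratio of means
    sem: float
    n: int
    ratio_of_means: float

    def __float__(self) -> float:
        return self.mean


def relative_level(samples: Sequence[float], matched_controls: Sequence[float]) -> RatioSummary:
    """Signal relative to a matched control scored in parallel.

    Per-replicate ratios sample_i / control_i with their mean and SEM; the
    ratio of group means is reported alongside.
    """
    s = _as_array(samples, "samples")
    c = _as_array(matched_controls, "matched_controls")
    if s.size != c.size:
        raise ValueError("samples and matched controls must pair one-to-one")
    if (c == 0).any():
        raise ValueError("zero control signal: relative level undefined")
    ratios = s / c
    return RatioSummary(ratios=ratios, mean=float(ratios.mean()), sem=_sem(ratios),
                        n=ratios.size, ratio_of_means=float(s.mean() / c.mean()))


def fold_inhibition(inactive: Sequence[float], active: Sequence[float]) -> float:
    """Fold suppression of a signal by a condition: mean(inactive)/mean(active).

    Values > 1 mean the condition (e.g. donor transcription) suppresses the
    signal.  A zero active-group mean is reported as +inf with a warning.
    """
    ina = _as_array(inactive, "inactive")
    act = _as_array(active, "active")
    if ina.mean() <= 0:
        raise ValueError("inactive group mean must be > 0")
    if act.mean() == 0:
        warnings.warn("active group mean is zero; fold inhibition is infinite")
        return float("inf")
    return float(ina.mean() / act.mean())


def donor_preference(intra: Sequence[float], inter: Sequence[float],
                     paired: bool = True) -> RatioSummary:
    """Fold preference for the intra- over the inter-chromosomal donor."""
    a = _as_array(intra, "intra")
    b = _as_array(inter, "inter")
    if b.mean() == 0:
        raise ValueError("inter-donor mean must be > 0")
    rom = float(a.mean() / b.mean())
    if paired and a.size == b.size and not (b == 0).any():
        ratios = a / b
        return RatioSummary(ratios=ratios, mean=float(ratios.mean()), sem=_sem(ratios),
                            n=a.size, ratio_of_means=rom)
    return RatioSummary(ratios=None, mean=rom, sem=float("nan"), n=a.size, ratio_of_means=rom)


def recombinant_frequency(junction: Sequence[float], circ_control: Sequence[float],
                          loading: Sequence[float]) -> RatioSummary:
    """Repair-product frequency as percent of broken molecules.

    Junction signal (NCO or CO chimeric circles) normalized onto the
    circularization-efficiency control, per replicate:
    100 * (junction/loading) / (circ_control/loading).
    """
    j = _as_array(junction, "junction")
    c = _as_array(circ_control, "circ_control")
    l = _as_array(loading, "loading")
    if not (j.size == c.size == l.size):
        raise ValueError("junction, circularization and loading vectors must pair one-to-one")
    if (c == 0).any() or (l == 0).any():
        raise ValueError("zero circularization/loading control: frequency undefined")
    freq = 100.0 * (j / l) / (c / l)
    return RatioSummary(ratios=freq, mean=float(freq.mean()), sem=_sem(freq),
                        n=freq.size, ratio_of_means=float(100.0 * j.mean() / c.mean()))


def plating_viability(colonies_dsb: float, colonies_no_dsb: float,
                      dilution_factor: float = 1.0) -> float:
    """Percent survival of break induction: colonies on inducing vs
    non-inducing plates, corrected for the relative dilution plated."""
    if colonies_dsb < 0 or colonies_no_dsb < 0:
        raise ValueError("colony counts must be non-negative")
    corrected = colonies_no_dsb * dilution_factor
    if corrected <= 0:
        raise ValueError("no-DSB colony count must be > 0 after dilution correction")
    return float(100.0 * colonies_dsb / corrected)


@dataclass
class MirResult:
    """Lys+ translocation frequencies with and without break induction."""

    frequency_dsb: float        # Lys+ per viable cell, galactose (DSB)
    frequency_no_dsb: float     # Lys+ per viable cell, glucose (no DSB)
    dsb_dependent: float        # difference, floored at 0


def mir_frequency(lys_plus_gal: float, viable_gal: float,
                  lys_plus_glu: float, viable_glu: float) -> MirResult:
    """Break-dependent multi-invasion-induced rearrangement frequency.

    The background recombinant frequency without break induction (glucose) is
    subtracted from the induced frequency (galactose); both raw frequencies
    are always reported.
    """
    if viable_gal <= 0 or viable_glu <= 0:
        raise ValueError("viable colony counts must be > 0")
    f_gal = lys_plus_gal / viable_gal
    f_glu = lys_plus_glu / viable_glu
    return MirResult(frequency_dsb=float(f_gal), frequency_no_dsb=float(f_glu),
                     dsb_dependent=float(max(0.0, f_gal - f_glu)))


@dataclass
class TestResult:
    p_value: float
    test_used: str              # mann-whitney | wilcoxon | t-unpaired | t-paired
    n_a: int
    n_b: int

    def __float__(self) -> float:
        return self.p_value


def rank_sum_compare(group_a: Sequence[float], group_b: Sequence[float],
                     paired: bool = False) -> TestResult:
    """Two-tailed group comparison with the small-sample fallback rule.

    Default: Mann-Whitney-Wilcoxon rank-sum (exact null when tie-free), or
    the Wilcoxon signed-rank test when paired.  When either group has fewer
    than 4 replicates, a two-tailed Student t-test is used instead (paired or
    unpaired to match).  Identical constant groups return p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal group sizes")
    degenerate = (a.size == b.size and np.array_equal(np.sort(a), np.sort(b))
                  and np.ptp(a) == 0)
    if degenerate:
        test = ("t-paired" if paired else "t-unpaired") \
            if min(a.size, b.size) < SMALL_N_T_TEST \
            else ("wilcoxon" if paired else "mann-whitney")
        return TestResult(p_value=1.0, test_used=test, n_a=a.size, n_b=b.size)
    if min(a.size, b.size) < SMALL_N_T_TEST:
        if paired:
            stat = stats.ttest_rel(a, b)
            return TestResult(float(stat.pvalue), "t-paired", a.size, b.size)
        stat = stats.ttest_ind(a, b, equal_var=True)
        return TestResult(float(stat.pvalue), "t-unpaired", a.size, b.size)
    if paired:
        diff = a - b
        if np.all(diff == 0):
            return TestResult(1.0, "wilcoxon", a.size, b.size)
        res = stats.wilcoxon(a, b, alternative="two-sided")
        return TestResult(float(res.pvalue), "wilcoxon", a.size, b.size)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(float(res.pvalue), "mann-whitney", a.size, b.size)


def get_values(table, *, strain: str | None = None, condition: str | None = None,
               kind: str | None = None) -> np.ndarray:
    """Select replicate values from an AssayTable DataFrame, ordered by
    replicate index so parallel selections pair up."""
    sub = table
    for col, want in (("strain", strain), ("condition", condition), ("kind", kind)):
        if want is not None:
            sub = sub[sub[col] == want]
    sub = sub.sort_values("replicate")
    return sub["value"].to_numpy(dtype=float)
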