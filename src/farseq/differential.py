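"""Proportion-based tests of equal transcription and fold-change classes.

For each ORF the quantity compared between two conditions is its share of
the mRNA-mapping reads: p = c / N. The condition ratio is
r_other / r_baseline. Equality of transcription is tested on the pooled
counts with the two-proportion z-test when the baseline condition has
replicates, and with the Pearson chi-square test on the 2x2 table
[[c1, N1-c1], [c2, N2-c2]] when both conditions are single samples. No
continuity correction is applied, which preserves the classical identity
chi2 = z**2 on every table.

Genes are then binned by fold thresholds: >= 10-fold and >= 2-fold
increases, and <= 50% and <= 10% of baseline (i.e. 50% and 90%
reductions). Thresholds are inclusive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .counting import CountTable

PSEUDOCOUNT_POLICIES = (None, "none", "haldane")
Z_MODES = ("pooled", "replicate")


@dataclass(frozen=True)
class ThresholdScheme:
    """Fold thresholds for change classification.

    ``up_levels`` are fold factors (strictly increasing, all > 1);
    ``down_levels`` are remaining fractions of baseline (strictly
    decreasing, in (0, 1)). The defaults encode a 2-fold/10-fold increase
    and a 50%/90% reduction. Boundaries are inclusive by default.
    """

    up_levels: tuple[float, ...] = (2.0, 10.0)
    down_levels: tuple[float, ...] = (0.5, 0.1)
    boundary_inclusive: bool = True

    def __post_init__(self) -> None:
        if any(u <= 1 for u in self.up_levels) or list(self.up_levels) != sorted(
            self.up_levels
        ):
            raise ValueError("up_levels must be strictly increasing and > 1")
        if any(not 0 < d < 1 for d in self.down_levels) or list(
            self.down_levels
        ) != sorted(self.down_levels, reverse=True):
            raise ValueError("down_levels must be strictly decreasing, in (0,1)")

    def up_class(self, level: float) -> str:
        return f"up_{level:g}x"

    def down_class(self, level: float) -> str:
        return f"down_{round((1 - level) * 100):g}pct"

    def classes(self) -> list[str]:
        ups = [self.up_class(u) for u in self.up_levels]
        downs = [self.down_class(d) for d in self.down_levels]
        return ups + ["unchanged"] + downs + ["undefined"]


@dataclass
class SampleGroup:
    """All count tables for one condition; replicated when >= 2 samples."""

    condition_id: str
    samples: list[CountTable]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError(f"condition {self.condition_id!r} has no samples")
        universe = set(self.samples[0].counts)
        for tab in self.samples[1:]:
            if set(tab.counts) != universe:
                bad = sorted(set(tab.counts) ^ universe)
                raise ValueError(
                    f"sample {tab.sample_id!r} disagrees on feature universe: "
                    f"{bad[:10]}"
                )

    @property
    def replicated(self) -> bool:
        return len(self.samples) >= 2

    def pooled(self) -> tuple[dict[str, int], int]:
        """Replicate-summed counts and pooled N."""
        pooled: dict[str, int] = {fid: 0 for fid in self.samples[0].counts}
        n = 0
        for tab in self.samples:
            for fid, c in tab.counts.items():
                pooled[fid] += c
            n += tab.total_mrna_counts
        return pooled, n


def fold_ratio(
    r1: float, r2: float, pseudocount: str | None = None, **_ignored
) -> float:
    """r2 / r1; NaN marks an undefined ratio (r1 = 0, no pseudocount).

    The Haldane variant is applied at the count level (see
    :func:`compare_conditions`); calling it here with plain abundances is
    a validation error.
    """
    if r1 < 0 or r2 < 0:
        raise ValueError("relative abundances must be non-negative")
    if r1 == 0:
        return math.nan
    return r2 / r1


def z_test_equal_transcription(
    c1: int, n1: int, c2: int, n2: int
) -> tuple[float, float]:
    """Two-proportion pooled z-test on replicate-summed counts.

    z = (c1/N1 - c2/N2) / sqrt(phat (1-phat) (1/N1 + 1/N2)) with
    phat = (c1+c2)/(N1+N2); two-sided p from the standard normal.
    Degenerate pooled proportions (phat of 0 or 1) give z = 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals must be positive")
    phat = (c1 + c2) / (n1 + n2)
    if phat <= 0.0 or phat >= 1.0:
        return 0.0, 1.0
    se = math.sqrt(phat * (1.0 - phat) * (1.0 / n1 + 1.0 / n2))
    z = (c1 / n1 - c2 / n2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return z, min(p, 1.0)


def chi_square_equal_transcription(
    c1: int, n1: int, c2: int, n2: int
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2
    table [[c1, N1-c1], [c2, N2-c2]].

    A degenerate table (both margins in one column) yields chi2 = 0,
    p = 1 with a warning.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals must be positive")
    if c1 > n1 or c2 > n2:
        raise ValueError("count exceeds its total")
    m = c1 + c2
    if m == 0 or m == n1 + n2:
        warnings.warn(
            "degenerate 2x2 table (a zero expected cell); chi2=0, p=1",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0, 1.0
    # closed form for the 2x2 Pearson statistic
    num = (n1 + n2) * (c1 * (n2 - c2) - c2 * (n1 - c1)) ** 2
    den = m * (n1 + n2 - m) * n1 * n2
    chi2 = num / den
    return chi2, float(sps.chi2.sf(chi2, df=1))


def classify_change(ratio: float, scheme: ThresholdScheme | None = None) -> str:
    """Bin a condition ratio by the fold thresholds; highest class wins.

    NaN (undefined ratio) maps to ``undefined``. With the default scheme:
    ratio >= 10 -> up_10x; >= 2 -> up_2x; <= 0.1 -> down_90pct;
    <= 0.5 -> down_50pct; otherwise unchanged.
    """
    scheme = scheme or ThresholdScheme()
    if ratio is None or (isinstance(ratio, float) and math.isnan(ratio)):
        return "undefined"
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    inc = scheme.boundary_inclusive
    for level in reversed(scheme.up_levels):
        if ratio >= level if inc else ratio > level:
            return scheme.up_class(level)
    for level in reversed(scheme.down_levels):
        if ratio <= level if inc else ratio < level:
            return scheme.down_class(level)
    return "unchanged"


def _replicate_z(
    group1: SampleGroup, group2: SampleGroup, fid: str
) -> tuple[float, float]:
    """Replicate-dispersion z (non-default): difference of mean per-replicate
    abundances over the combined standard error. Singleton groups fall back
    to the binomial standard error of their single proportion."""

    def mean_se(group: SampleGroup) -> tuple[float, float]:
        rs = [t.counts[fid] / t.total_mrna_counts for t in group.samples]
        mean = float(np.mean(rs))
        if len(rs) >= 2:
            se = float(np.std(rs, ddof=1) / math.sqrt(len(rs)))
        else:
            n = group.samples[0].total_mrna_counts
            se = math.sqrt(max(mean * (1 - mean), 0.0) / n)
        return mean, se

    m1, se1 = mean_se(group1)
    m2, se2 = mean_se(group2)
    denom = math.hypot(se1, se2)
    if denom == 0.0:
        return 0.0, 1.0
    z = (m1 - m2) / denom
    return z, min(2.0 * sps.norm.sf(abs(z)), 1.0)


def compare_conditions(
    baseline: SampleGroup,
    other: SampleGroup,
    scheme: ThresholdScheme | None = None,
    pseudocount: str | None = None,
    z_mode: str = "pooled",
) -> pd.DataFrame:
    """Per-ORF differential-transcription table for one condition pair.

    Counts are replicate-summed within each group before abundances are
    formed. The z-test is used when the baseline condition is replicated,
    the chi-square test otherwise. Benjamini-Hochberg q-values are
    computed over all tested ORFs. Rows keep the feature order of the
    first baseline sample (annotation order). An undefined ratio
    (r_baseline = 0 without pseudocount) is still tested and classified
    ``undefined``; the Haldane option shifts every count by +0.5 (and each
    N by +0.5) before abundances and ratios are formed, leaving the test
    counts untouched.
    """
    if pseudocount not in PSEUDOCOUNT_POLICIES:
        raise ValueError(f"unknown pseudocount policy {pseudocount!r}")
    if z_mode not in Z_MODES:
        raise ValueError(f"unknown z mode {z_mode!r}")
    scheme = scheme or ThresholdScheme()

    base_counts, n_base = baseline.pooled()
    other_counts, n_other = other.pooled()
    if set(base_counts) != set(other_counts):
        bad = sorted(set(base_counts) ^ set(other_counts))
        raise ValueError(f"feature universes differ between conditions: {bad[:10]}")
    if n_base <= 0 or n_other <= 0:
        raise ValueError("both conditions need mRNA-mapping reads")

    use_z = baseline.replicated
    haldane = pseudocount == "haldane"

    rows = []
    for fid in baseline.samples[0].counts:
        c1, c2 = base_counts[fid], other_counts[fid]
        if haldane:
            r1 = (c1 + 0.5) / (n_base + 0.5)
            r2 = (c2 + 0.5) / (n_other + 0.5)
        else:
            r1 = c1 / n_base
            r2 = c2 / n_other
        ratio = fold_ratio(r1, r2)
        if use_z:
            # statistic sign: positive when baseline proportion is higher
            if z_mode == "replicate":
                stat, p = _replicate_z(baseline, other, fid)
            else:
                stat, p = z_test_equal_transcription(c1, n_base, c2, n_other)
            test_used = "z_test"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                stat, p = chi_square_equal_transcription(c1, n_base, c2, n_other)
            test_used = "chi_square"
        rows.append(
            {
                "feature_id": fid,
                "c_baseline": c1,
                "c_other": c2,
                "N_baseline": n_base,
                "N_other": n_other,
                "r_baseline": r1,
                "r_other": r2,
                "ratio": ratio,
                "statistic": stat,
                "test_used": test_used,
                "p_value": p,
                "change_class": classify_change(ratio, scheme),
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df[
        [
            "feature_id",
            "c_baseline",
            "c_other",
            "N_baseline",
            "N_other",
            "r_baseline",
            "r_other",
            "ratio",
            "statistic",
            "test_used",
            "p_value",
            "q_value",
            "change_class",
        ]
    ]


def write_comparison_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")
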