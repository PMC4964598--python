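"""Cross-individual and cross-group variant sharing analysis.

Each group of individuals yields an incidence matrix (variant x individual
presence), from which a sharing spectrum — how many variants occur in
exactly k of the N individuals — is computed.  Groups are compared per
sharing level with a 2x2 chi-square (no continuity correction, 1 df) of
level counts against group totals, and the individualized (k = 1) and
common-in-all (k = N) strata are partitioned into group-private and shared
variant sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import PromoterWindow
from .variants import PromoterVariant, mine_variants, read_vcf

Key = tuple[str, int, str, str]

__all__ = [
    "IncidenceMatrix",
    "SharingSpectrum",
    "GroupTestResult",
    "build_incidence",
    "sharing_spectrum",
    "chi_square_2x2",
    "compare_groups",
    "partition_shared",
    "known_fraction",
]


@dataclass
class IncidenceMatrix:
    """Boolean variant-by-individual presence for one group."""

    group: str
    data: pd.DataFrame  # index: variant keys, columns: individual ids, bool
    variants: dict[Key, PromoterVariant]

    @property
    def n_individuals(self) -> int:
        return self.data.shape[1]

    @property
    def n_variants(self) -> int:
        return self.data.shape[0]


@dataclass
class SharingSpectrum:
    """counts[k] = number of variants present in exactly k individuals."""

    group: str
    n_individuals: int
    counts: dict[int, int]

    def __post_init__(self) -> None:
        self.counts = {
            k: int(self.counts.get(k, 0))
            for k in range(1, self.n_individuals + 1)
        }

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, name=self.group)


@dataclass(frozen=True)
class GroupTestResult:
    level: int | str
    count_a: int
    total_a: int
    count_b: int
    total_b: int
    chi2: float
    p_value: float


def build_incidence(
    vcfs: Mapping[str, str] | Mapping[str, Iterable],
    windows: Sequence[PromoterWindow],
    min_depth: int = 4,
    core_only: bool = True,
    group: str = "",
    depth_source=None,
) -> IncidenceMatrix:
    """Mine each individual's VCF and assemble the union incidence matrix.

    *vcfs* maps individual id to a VCF path (or an iterable of records);
    every VCF is passed through the promoter mining rules so incidence
    reflects only depth-qualified promoter variants.  Duplicate individual
    ids are rejected by the mapping type itself.
    """
    if not vcfs:
        raise ValueError("need at least one individual")
    individuals = list(vcfs)
    per_ind: dict[str, list[PromoterVariant]] = {}
    variants: dict[Key, PromoterVariant] = {}
    for ind, source in vcfs.items():
        mined = mine_variants(source, windows, depth_source=depth_source,
                              min_depth=min_depth, core_only=core_only)
        per_ind[ind] = mined
        for v in mined:
            variants.setdefault(v.key, v)
    keys = sorted(variants)
    data = pd.DataFrame(
        False, index=pd.Index(keys, tupleize_cols=False), columns=individuals
    )
    for ind, mined in per_ind.items():
        for v in mined:
            data.at[v.key, ind] = True
    return IncidenceMatrix(group, data, variants)


def sharing_spectrum(matrix: IncidenceMatrix) -> SharingSpectrum:
    row_sums = matrix.data.sum(axis=1)
    vc = row_sums.value_counts()
    counts = {int(k): int(n) for k, n in vc.items() if k >= 1}
    return SharingSpectrum(matrix.group, matrix.n_individuals, counts)


def chi_square_2x2(a: int, n_a: int, b: int, n_b: int) -> tuple[float, float]:
    """Closed-form 2x2 chi-square without continuity correction, 1 df.

    Compares proportions a/n_a vs b/n_b via the table
    [[a, n_a - a], [b, n_b - b]].  Returns (statistic, p).  A table with a
    zero margin has statistic 0 and p = 1 (no evidence of difference).
    """
    if not (0 <= a <= n_a and 0 <= b <= n_b):
        raise ValueError("require 0 <= count <= total in each group")
    if n_a == 0 or n_b == 0:
        raise ValueError("group totals must be > 0")
    c, d = n_a - a, n_b - b
    n = n_a + n_b
    col1, col2 = a + b, c + d
    if col1 == 0 or col2 == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / (n_a * n_b * col1 * col2)
    return float(stat), float(stats.chi2.sf(stat, df=1))


def compare_groups(
    spec_a: SharingSpectrum, spec_b: SharingSpectrum
) -> list[GroupTestResult]:
    """Per-sharing-level 2x2 chi-square of level counts vs group totals.

    Each level k tests counts[k] against (total - counts[k]) between the
    two groups; a final row labelled 'total' compares the grand totals
    against the pooled total.  No multiple-testing correction is applied
    (a Bonferroni-adjusted column is trivial to add downstream).
    """
    n_a, n_b = spec_a.total, spec_b.total
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups need a positive variant total")
    results: list[GroupTestResult] = []
    levels = sorted(set(spec_a.counts) | set(spec_b.counts))
    for k in levels:
        a = spec_a.counts.get(k, 0)
        b = spec_b.counts.get(k, 0)
        stat, p = chi_square_2x2(a, n_a, b, n_b)
        results.append(GroupTestResult(k, a, n_a, b, n_b, stat, p))
    pooled = n_a + n_b
    stat, p = chi_square_2x2(n_a, pooled, n_b, pooled)
    results.append(GroupTestResult("total", n_a, pooled, n_b, pooled, stat, p))
    return results


def results_frame(results: Sequence[GroupTestResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    n_levels = (df["level"] != "total").sum()
    df["p_bonferroni"] = (df["p_value"] * n_levels).clip(upper=1.0)
    return df


def _stratum_keys(matrix: IncidenceMatrix, level: str) -> set[Key]:
    row_sums = matrix.data.sum(axis=1)
    if level == "individualized":
        want = 1
    elif level == "common-in-all":
        want = matrix.n_individuals
    else:
        raise ValueError("level must be 'individualized' or 'common-in-all'")
    return set(row_sums.index[row_sums == want])


def partition_shared(
    matrix_a: IncidenceMatrix,
    matrix_b: IncidenceMatrix,
    level: str = "individualized",
) -> tuple[set[Key], set[Key], set[Key]]:
    """Partition one sharing stratum across two groups by variant key.

    Returns (only_a, only_b, both) for the selected stratum —
    'individualized' (present in exactly one individual) or
    'common-in-all' (present in every individual of the group).
    """
    sa = _stratum_keys(matrix_a, level)
    sb = _stratum_keys(matrix_b, level)
    return sa - sb, sb - sa, sa & sb


def known_fraction(
    variants: Iterable[PromoterVariant] | Iterable[Key],
    catalog: str | Iterable,
    position_only: bool = False,
) -> float:
    """Fraction of variant keys present in a known-variant catalog VCF.

    Matching is by exact (chrom, pos, ref, alt) key, or by (chrom, pos)
    when *position_only*.  An empty variant list yields 0.0.
    """
    keys = []
    for v in variants:
        keys.append(v.key if isinstance(v, PromoterVariant) else tuple(v))
    if not keys:
        return 0.0
    records = read_vcf(catalog) if isinstance(catalog, str) else catalog
    cat = set()
    for r in records:
        cat.add((r.chrom, r.pos) if position_only else r.key)
    if position_only:
        hits = sum((k[0], k[1]) in cat for k in keys)
    else:
        hits = sum(k in cat for k in keys)
    return hits / len(keys)
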