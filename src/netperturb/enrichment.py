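"""Enrichment and comparison statistics for structural mutation analysis.

Covers the three statistical procedures used around the classifier:
Fisher exact odds ratios for the 3D location of mutations (core vs surface,
and interface vs non-interface among surface-exposed residues), pairwise
Mann–Whitney group comparisons with optional Bonferroni correction, and
Pearson feature-correlation matrices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import Mutation, NetworkFeaturizer, NotScoreableError
from .interactome import ResidueLocation, StructurallyResolvedNetwork

__all__ = [
    "EnrichmentResult",
    "fisher_or",
    "location_enrichment",
    "group_compare",
    "feature_correlations",
]


@dataclass
class EnrichmentResult:
    """Odds ratio with a 95% confidence interval and exact p-value."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    table: tuple[tuple[int, int], tuple[int, int]]

    def to_dict(self) -> dict:
        return {
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "table": [list(self.table[0]), list(self.table[1])],
        }


def fisher_or(table) -> EnrichmentResult:
    """Fisher exact test on a 2x2 table ``[[a, b], [c, d]]``.

    The odds ratio is the sample ratio ``ad / bc`` (+inf when ``bc`` is 0
    and ``ad`` positive); p comes from the exact two-sided hypergeometric
    test; the 95% CI is the normal approximation on the log odds ratio,
    with the Haldane–Anscombe 0.5 correction when any cell is empty.
    """
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("contingency counts must be non-negative")
    if sum(cells) == 0:
        raise ValueError("contingency table is all zero")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    # CI on log OR with zero-cell correction
    if min(cells) == 0:
        a_, b_, c_, d_ = (x + 0.5 for x in cells)
    else:
        a_, b_, c_, d_ = cells
    log_or = math.log((a_ * d_) / (b_ * c_))
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    ci_low = math.exp(log_or - 1.96 * se)
    ci_high = math.exp(log_or + 1.96 * se)
    return EnrichmentResult(
        odds_ratio=float(odds),
        ci_low=ci_low,
        ci_high=ci_high,
        p=float(p),
        table=((a, b), (c, d)),
    )


def _locations(
    mutations: Sequence[Mutation], net: StructurallyResolvedNetwork
) -> list[tuple[Mutation, ResidueLocation]]:
    featurizer = NetworkFeaturizer(net)
    out = []
    for mut in mutations:
        try:
            out.append((mut, featurizer.location(mut)))
        except NotScoreableError:
            continue
    return out


def location_enrichment(
    mutations: Sequence[Mutation],
    net: StructurallyResolvedNetwork,
    groups: Mapping | None = None,
) -> dict[str, EnrichmentResult]:
    """Structural-location enrichment of one mutation group over another.

    Mutations are split into two groups (by their labels, positive vs
    negative, unless ``groups`` maps mutation -> group truthiness).  Two
    comparisons are run:

    * ``surface_vs_core`` — solvent-exposed (surface or interface) versus
      core; OR > 1 means group-1 mutations sit more often at the surface.
    * ``interface_vs_surface`` — restricted to solvent-exposed residues,
      interface versus plain surface; OR > 1 means group-1 mutations sit
      more often at interfaces.

    Residues in the ambiguous RSA band (and unscoreable mutations) are
    excluded.
    """
    annotated = _locations(mutations, net)

    def in_group_1(mut: Mutation) -> bool:
        if groups is not None:
            return bool(groups[mut])
        if mut.label is None:
            raise ValueError(f"mutation {mut.key} has no label or group")
        return mut.label == 1

    exposed = {ResidueLocation.SURFACE, ResidueLocation.INTERFACE}
    # surface vs core
    a = sum(1 for m, loc in annotated if in_group_1(m) and loc in exposed)
    b = sum(1 for m, loc in annotated if in_group_1(m) and loc is ResidueLocation.CORE)
    c = sum(1 for m, loc in annotated if not in_group_1(m) and loc in exposed)
    d = sum(
        1 for m, loc in annotated if not in_group_1(m) and loc is ResidueLocation.CORE
    )
    surface_vs_core = fisher_or([[a, b], [c, d]])
    # interface vs plain surface, among exposed residues
    a = sum(
        1
        for m, loc in annotated
        if in_group_1(m) and loc is ResidueLocation.INTERFACE
    )
    b = sum(
        1 for m, loc in annotated if in_group_1(m) and loc is ResidueLocation.SURFACE
    )
    c = sum(
        1
        for m, loc in annotated
        if not in_group_1(m) and loc is ResidueLocation.INTERFACE
    )
    d = sum(
        1
        for m, loc in annotated
        if not in_group_1(m) and loc is ResidueLocation.SURFACE
    )
    interface_vs_surface = fisher_or([[a, b], [c, d]])
    return {
        "surface_vs_core": surface_vs_core,
        "interface_vs_surface": interface_vs_surface,
    }


def group_compare(
    values_by_group: Mapping[str, Sequence[float]],
    correction: str = "none",
) -> dict[tuple[str, str], tuple[float, float]]:
    """Pairwise two-sided Mann–Whitney U tests between named groups.

    Exact enumeration is used when both samples have at most 20
    observations, the tie-corrected normal approximation otherwise.  With
    ``correction="bonferroni"`` each p is multiplied by the number of
    pairwise comparisons (capped at 1).
    """
    if correction not in {"none", "bonferroni"}:
        raise ValueError(f"unknown correction {correction!r}")
    names = list(values_by_group)
    for name in names:
        if len(values_by_group[name]) == 0:
            raise ValueError(f"group {name!r} is empty")
    pairs = list(itertools.combinations(names, 2))
    results = {}
    for g1, g2 in pairs:
        x = np.asarray(values_by_group[g1], dtype=float)
        y = np.asarray(values_by_group[g2], dtype=float)
        method = "exact" if (x.size <= 20 and y.size <= 20) else "asymptotic"
        if method == "exact" and (
            np.unique(np.concatenate([x, y])).size < x.size + y.size
        ):
            method = "asymptotic"  # scipy exact enumeration requires no ties
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=False
        )
        p = float(res.pvalue)
        if correction == "bonferroni":
            p = min(1.0, p * len(pairs))
        results[(g1, g2)] = (float(res.statistic), p)
    return results


def feature_correlations(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix over feature columns.

    Constant columns have undefined correlations and are reported as NaN
    (never coerced to 0); the diagonal is 1 for non-constant columns.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two rows to correlate features")
    return matrix.corr(method="pearson")


def correlation_long_format(
    corr: pd.DataFrame,
    gate: float = 0.3,
    display_floor: float = 0.1,
) -> pd.DataFrame:
    """Long-format export of notable correlations.

    Keeps features with at least one off-diagonal |r| above ``gate`` and
    reports pairs with |r| above ``display_floor`` (off-diagonal only).
    """
    off = corr.where(~np.eye(len(corr), dtype=bool))
    keep = off.abs().max(axis=1) > gate
    kept = corr.loc[keep, keep]
    rows = []
    for i, fi in enumerate(kept.index):
        for j, fj in enumerate(kept.columns):
            if j <= i:
                continue
            r = kept.iloc[i, j]
            if pd.notna(r) and abs(r) > display_floor:
                rows.append((fi, fj, float(r)))
    return pd.DataFrame(rows, columns=["feature_i", "feature_j", "r"])
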