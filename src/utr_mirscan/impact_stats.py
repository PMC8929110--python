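"""Per-variant impact statistics and candidate prioritization.

For each variant and each prediction route, two statistics compare the ALT
allele with the REF allele over the retained, whitelisted sites:

* dN = n_alt - n_ref : change in the number of distinct interacting miRNAs;
* dW = w_alt - w_ref : change in the summed hybridization energies
  (kcal/mol), where each miRNA contributes its best (lowest-energy) retained
  site per allele (``sum_mode='best'``) or all its retained sites
  (``sum_mode='all'``).

Negative dW means stronger overall binding on ALT — predicted
downregulation.  Variants whose dW falls below the lower Tukey fence
(Q1 - k*IQR) or whose dN exceeds the upper fence (Q3 + k*IQR), computed per
route across all variants, are flagged as statistical outliers; candidates
are outliers that gain at least one miRNA and lower the energy sum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .duplex_energy import InteractionSite

#: below this many variants Tukey fences are not meaningful
MIN_IMPACTS_FOR_FENCES = 8


@dataclass(frozen=True)
class AlleleSummary:
    """Interaction summary for one variant + allele + method."""

    n: int
    w: float
    mirnas: frozenset[str]


@dataclass(frozen=True)
class VariantImpact:
    variant_id: str
    method: str
    n_ref: int
    n_alt: int
    delta_n: int
    w_ref: float
    w_alt: float
    delta_w: float
    gained: frozenset[str]
    lost: frozenset[str]
    outlier_n: bool = False
    outlier_w: bool = False
    candidate: bool = False
    max_population_allele_frequency: float = math.nan


def summarize_allele(
    sites: Iterable[InteractionSite], sum_mode: str = "best"
) -> AlleleSummary:
    """Summarize retained sites for one variant + allele + method.

    ``n`` counts distinct miRNA names; ``w`` sums, per miRNA, either its
    minimum site energy (``best``) or all site energies (``all``).  The
    result is invariant under reordering of ``sites``.
    """
    if sum_mode not in ("best", "all"):
        raise ValueError(f"sum_mode must be 'best' or 'all', got {sum_mode!r}")
    per_mirna: dict[str, list[float]] = {}
    for s in sites:
        per_mirna.setdefault(s.mirna_name, []).append(s.energy)
    if sum_mode == "best":
        w = sum(min(v) for v in per_mirna.values())
    else:
        w = sum(sum(v) for v in per_mirna.values())
    return AlleleSummary(n=len(per_mirna), w=w, mirnas=frozenset(per_mirna))


def variant_impact(
    ref_summary: AlleleSummary,
    alt_summary: AlleleSummary,
    variant_id: str,
    method: str,
) -> VariantImpact:
    """Combine per-allele summaries into dN/dW; outlier and candidate flags
    stay unset until the cross-variant pass."""
    return VariantImpact(
        variant_id=variant_id,
        method=method,
        n_ref=ref_summary.n,
        n_alt=alt_summary.n,
        delta_n=alt_summary.n - ref_summary.n,
        w_ref=ref_summary.w,
        w_alt=alt_summary.w,
        delta_w=alt_summary.w - ref_summary.w,
        gained=alt_summary.mirnas - ref_summary.mirnas,
        lost=ref_summary.mirnas - alt_summary.mirnas,
    )


def flag_outliers(
    impacts: Sequence[VariantImpact], k: float = 1.5
) -> list[VariantImpact]:
    """Set outlier flags across one method's impacts using Tukey fences.

    ``outlier_w`` iff dW < Q1(dW) - k*IQR(dW); ``outlier_n`` iff
    dN > Q3(dN) + k*IQR(dN); quartiles use numpy's linear-interpolation
    convention.  With fewer than 8 impacts the fences are degenerate, so
    flags fall back to the sign of the statistic (with a warning).
    """
    impacts = list(impacts)
    methods = {imp.method for imp in impacts}
    if len(methods) > 1:
        raise ValueError(f"flag_outliers expects a single method, got {sorted(methods)}")
    if not impacts:
        return []
    if len(impacts) < MIN_IMPACTS_FOR_FENCES:
        warnings.warn(
            f"only {len(impacts)} impacts: outlier fences degenerate, "
            "flagging any nonzero effect in the downregulating direction"
        )
        return [
            replace(imp, outlier_n=imp.delta_n > 0, outlier_w=imp.delta_w < 0)
            for imp in impacts
        ]

    dn = np.array([imp.delta_n for imp in impacts], dtype=float)
    dw = np.array([imp.delta_w for imp in impacts], dtype=float)
    q1w, q3w = np.percentile(dw, [25, 75], method="linear")
    q1n, q3n = np.percentile(dn, [25, 75], method="linear")
    w_fence = q1w - k * (q3w - q1w)
    n_fence = q3n + k * (q3n - q1n)
    return [
        replace(imp, outlier_n=imp.delta_n > n_fence, outlier_w=imp.delta_w < w_fence)
        for imp in impacts
    ]


def select_candidates(impacts: Sequence[VariantImpact]) -> list[VariantImpact]:
    """Mark and return the downregulation candidates, sorted within method
    by ascending dW (most stabilizing first).

    A candidate gains at least one miRNA (dN >= 1), lowers the energy sum
    (dW < 0), and is a statistical outlier in at least one statistic.
    """
    out: list[VariantImpact] = []
    for imp in impacts:
        is_cand = (
            imp.delta_n >= 1
            and imp.delta_w < 0
            and (imp.outlier_n or imp.outlier_w)
        )
        if is_cand:
            out.append(replace(imp, candidate=True))
    method_order: list[str] = []
    for imp in out:
        if imp.method not in method_order:
            method_order.append(imp.method)
    out.sort(key=lambda imp: (method_order.index(imp.method), imp.delta_w))
    return out
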