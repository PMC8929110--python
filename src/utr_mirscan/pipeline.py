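"""End-to-end orchestration: scan -> classify -> filter -> impact.

For every variant the pipeline extracts the 50-nt REF/ALT windows, predicts
interaction sites per miRNA by both routes (seed-anchored scan rescored in
its exact hybrid configuration, and the seed-constrained MFE hybrid),
classifies and filters the sites, and reduces them to per-variant dN/dW
impact statistics with per-method outlier flags and a ranked candidate
list.  Identical inputs and config produce byte-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .duplex_energy import InteractionSite, _HybridDP, duplex_mfe, rescore_seed_hit
from .energy_params import EnergyModel
from .impact_stats import (
    VariantImpact,
    flag_outliers,
    select_candidates,
    summarize_allele,
    variant_impact,
)
from .io_formats import FrequencyAnnotation, MiRNA, UTRSequence, UTRVariant
from .seed_scan import find_seed_matches
from .site_filters import ClassifyConfig, FilterConfig, classify_sites, filter_sites
from .windowing import extract_window_pair

logger = logging.getLogger("utr_mirscan")

METHODS = ("seed_scan", "energy_scan")


@dataclass(frozen=True)
class RunConfig:
    """Resolved pipeline settings; the defaults are the reference
    conditions (50-nt windows, 6-nt minimum seed with wobbles, -8.5
    kcal/mol retention cutoff, Tukey fence k = 1.5)."""

    window_len: int = 50
    min_seed: int = 6
    allow_wobble: bool = True
    energy_cutoff: float = -8.5
    fence_k: float = 1.5
    sum_mode: str = "best"            # {"best", "all"}
    methods: tuple[str, ...] = METHODS
    require_seed: bool = True
    max_internal_unpaired: int = 15
    rng_seed: int = 0
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    allowed_classes: tuple[str, ...] = (
        "canonical_8", "canonical_7", "canonical_6", "centered", "compensatory"
    )

    def energy_model(self) -> EnergyModel:
        return EnergyModel(max_internal_unpaired=self.max_internal_unpaired)

    def filter_config(self, whitelist: frozenset[str]) -> FilterConfig:
        return FilterConfig(
            energy_cutoff=self.energy_cutoff,
            whitelist=frozenset(whitelist),
            allowed_classes=frozenset(self.allowed_classes),
            classify=self.classify,
        )


@dataclass(frozen=True)
class ScanResult:
    sites: list[InteractionSite]          # retained (classified + filtered)
    impacts: list[VariantImpact]          # one per variant x method
    candidates: list[VariantImpact]       # sorted downregulation candidates
    stage_counts: dict[str, int]


def predict_sites(
    utr: UTRSequence,
    variants: Sequence[UTRVariant],
    mirnas: Sequence[MiRNA],
    cfg: RunConfig,
) -> list[InteractionSite]:
    """Unfiltered, unclassified interaction sites for every
    variant x allele x miRNA x method."""
    if not mirnas:
        raise ValueError("empty miRNA library")
    model = cfg.energy_model()
    longest = max(len(m) for m in mirnas)
    sites: list[InteractionSite] = []
    for v in variants:
        wp = extract_window_pair(utr, v, cfg.window_len, longest_mirna=longest)
        for allele, window in (("REF", wp.ref_window), ("ALT", wp.alt_window)):
            for mir in mirnas:
                dp = None
                if "energy_scan" in cfg.methods:
                    dp = _HybridDP(window, mir.sequence, model)
                    site = duplex_mfe(
                        window, mir, model, require_seed=cfg.require_seed,
                        variant_id=v.variant_id, allele=allele, dp=dp,
                    )
                    if site is not None:
                        sites.append(site)
                if "seed_scan" in cfg.methods:
                    matches = find_seed_matches(
                        window, mir, cfg.min_seed, allow_wobble=cfg.allow_wobble
                    )
                    if matches and dp is None:
                        dp = _HybridDP(window, mir.sequence, model)
                    for match in matches:
                        sites.append(
                            rescore_seed_hit(
                                match, window, mir, model,
                                variant_id=v.variant_id, allele=allele, dp=dp,
                            )
                        )
    return sites


def compute_impacts(
    sites: Sequence[InteractionSite],
    variants: Sequence[UTRVariant],
    cfg: RunConfig,
    frequencies: Mapping[str, FrequencyAnnotation] | None = None,
) -> tuple[list[VariantImpact], list[VariantImpact]]:
    """Reduce retained sites to per-variant impacts (every variant x method
    present, even with no sites), flag outliers per method, and select the
    sorted candidate list."""
    by_key: dict[tuple[str, str, str], list[InteractionSite]] = {}
    for s in sites:
        by_key.setdefault((s.method, s.variant_id, s.allele), []).append(s)

    impacts: list[VariantImpact] = []
    for method in cfg.methods:
        method_impacts = []
        for v in variants:
            ref = summarize_allele(
                by_key.get((method, v.variant_id, "REF"), []), cfg.sum_mode
            )
            alt = summarize_allele(
                by_key.get((method, v.variant_id, "ALT"), []), cfg.sum_mode
            )
            method_impacts.append(variant_impact(ref, alt, v.variant_id, method))
        impacts.extend(flag_outliers(method_impacts, cfg.fence_k))

    candidates = select_candidates(impacts)
    cand_keys = {(c.method, c.variant_id) for c in candidates}
    impacts = [
        replace(imp, candidate=(imp.method, imp.variant_id) in cand_keys)
        for imp in impacts
    ]
    if frequencies:
        def with_af(imp: VariantImpact) -> VariantImpact:
            ann = frequencies.get(imp.variant_id)
            af = ann.max_population_allele_frequency if ann else math.nan
            return replace(imp, max_population_allele_frequency=af)

        impacts = [with_af(i) for i in impacts]
        candidates = [with_af(c) for c in candidates]
    return impacts, candidates


def run_scan(
    utr: UTRSequence,
    variants: Sequence[UTRVariant],
    mirnas: Sequence[MiRNA],
    whitelist: frozenset[str] | set[str],
    cfg: RunConfig,
    frequencies: Mapping[str, FrequencyAnnotation] | None = None,
) -> ScanResult:
    """Full pipeline; logs monotone stage counts (predicted, pattern-valid,
    energy-retained, whitelisted, candidates)."""
    raw = predict_sites(utr, variants, mirnas, cfg)
    classified = classify_sites(raw, cfg.classify)
    fcfg = cfg.filter_config(frozenset(whitelist))

    with_class = [s for s in classified if s.seed_class in fcfg.allowed_classes]
    with_energy = [s for s in with_class if s.energy <= fcfg.energy_cutoff]
    retained = filter_sites(classified, fcfg)

    impacts, candidates = compute_impacts(retained, variants, cfg, frequencies)
    counts = {
        "variants": len(variants),
        "mirnas": len(mirnas),
        "sites_predicted": len(raw),
        "sites_pattern_valid": len(with_class),
        "sites_energy_retained": len(with_energy),
        "sites_whitelisted": len(retained),
        "candidates": len(candidates),
    }
    for k, v in counts.items():
        logger.info("%s: %d", k, v)
    return ScanResult(retained, impacts, candidates, counts)
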