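"""Site validation: seed-pattern taxonomy, energy cutoff, tissue whitelist.

A retained site must (a) bind at least as strongly as the -8.5 kcal/mol
suboptimal-duplex threshold (boundary inclusive: exactly -8.5 is kept),
(b) involve a miRNA present in the tissue-specific whitelist, and (c) match
one of the recognized interaction patterns:

* canonical_6/7/8 — an uninterrupted complementary run of >= 6/7/8 pairs
  covering the miRNA's first 8 positions (the seed);
* centered       — >= 11 contiguous pairs whose miRNA interval starts at
  position 3-6, pairing the middle of the miRNA with no seed requirement;
* compensatory   — the seed region (miRNA 2-8) paired except exactly one
  wobble or mismatch, offset by >= 4 contiguous pairs within miRNA 13-17.

The centered/compensatory thresholds are operational constants exposed in
config, since the pattern definitions in the literature are prose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .duplex_energy import InteractionSite

SEED_CLASSES = ("canonical_8", "canonical_7", "canonical_6",
                "centered", "compensatory", "none")

DEFAULT_ENERGY_CUTOFF = -8.5


@dataclass(frozen=True)
class ClassifyConfig:
    """Operational constants of the seed-pattern taxonomy.

    ``wobble_in_canonical`` is off by default: canonical classes demand pure
    Watson-Crick seed runs, so a seed carrying one G-U wobble falls through
    to the compensatory pattern (which is defined by exactly that wobble,
    offset by 3' pairing) instead of outranking it.
    """

    wobble_in_canonical: bool = False
    seed_span_end: int = 8           # canonical runs must sit within [1, this]
    centered_min_run: int = 11
    centered_start_range: tuple[int, int] = (3, 6)
    compensatory_seed: tuple[int, int] = (2, 8)
    compensatory_3p_region: tuple[int, int] = (13, 17)
    compensatory_3p_min_pairs: int = 4


@dataclass(frozen=True)
class FilterConfig:
    """Retention gates applied to classified sites."""

    energy_cutoff: float = DEFAULT_ENERGY_CUTOFF
    whitelist: frozenset[str] = frozenset()
    allowed_classes: frozenset[str] = frozenset(SEED_CLASSES) - {"none"}
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)

    def __post_init__(self) -> None:
        if self.energy_cutoff >= 0:
            raise ValueError("energy_cutoff must be negative (kcal/mol)")


def _decode_runs(site: InteractionSite) -> tuple[list[dict], dict[int, str]]:
    """Decode the pairing string into maximal stacked runs and a per-miRNA-
    position status map ('P' WC pair, 'W' wobble, absent = unpaired).

    Each run dict has miRNA span [lo, hi], run length, and wobble positions.
    Runs are contiguous in both strands by construction of the structure.
    """
    m_lo, m_hi = site.mirna_interval
    mpos = m_hi
    status: dict[int, str] = {}
    runs: list[dict] = []
    current: dict | None = None
    after_gap = False
    for code in site.pairing_string:
        if code in "PW":
            status[mpos] = code
            if current is None or after_gap:
                current = {"lo": mpos, "hi": mpos, "len": 1,
                           "wobbles": {mpos} if code == "W" else set()}
                runs.append(current)
                after_gap = False
            else:
                current["lo"] = mpos  # miRNA index decreases along the walk
                current["len"] += 1
                if code == "W":
                    current["wobbles"].add(mpos)
            mpos -= 1
        elif code == "M":
            mpos -= 1
            after_gap = True
        elif code == "T":
            after_gap = True
    return runs, status


def _canonical_len(run: dict, cfg: ClassifyConfig) -> int:
    """Longest contiguous stretch of the run lying within the seed span,
    optionally excluding wobble pairs."""
    lo = max(run["lo"], 1)
    hi = min(run["hi"], cfg.seed_span_end)
    if hi < lo:
        return 0
    if cfg.wobble_in_canonical:
        return hi - lo + 1
    best = cur = 0
    for p in range(lo, hi + 1):
        if p in run["wobbles"]:
            cur = 0
        else:
            cur += 1
            best = max(best, cur)
    return best


def classify_site(site: InteractionSite, cfg: ClassifyConfig | None = None) -> str:
    """Assign exactly one seed class, first match in priority order
    canonical_8 > canonical_7 > canonical_6 > centered > compensatory > none.
    """
    cfg = cfg or ClassifyConfig()
    runs, status = _decode_runs(site)

    best_seed = max((_canonical_len(r, cfg) for r in runs), default=0)
    if best_seed >= 8:
        return "canonical_8"
    if best_seed == 7:
        return "canonical_7"
    if best_seed == 6:
        return "canonical_6"

    lo_start, hi_start = cfg.centered_start_range
    for r in runs:
        if r["len"] >= cfg.centered_min_run and lo_start <= r["lo"] <= hi_start:
            return "centered"

    s_lo, s_hi = cfg.compensatory_seed
    bad = [p for p in range(s_lo, s_hi + 1) if status.get(p) != "P"]
    if len(bad) == 1:
        r_lo, r_hi = cfg.compensatory_3p_region
        for r in runs:
            overlap = min(r["hi"], r_hi) - max(r["lo"], r_lo) + 1
            if overlap >= cfg.compensatory_3p_min_pairs:
                return "compensatory"

    return "none"


def classify_sites(
    sites: Iterable[InteractionSite], cfg: ClassifyConfig | None = None
) -> list[InteractionSite]:
    """Return sites with ``seed_class`` assigned."""
    cfg = cfg or ClassifyConfig()
    return [replace(s, seed_class=classify_site(s, cfg)) for s in sites]


def filter_sites(
    sites: Sequence[InteractionSite], cfg: FilterConfig
) -> list[InteractionSite]:
    """Retain sites with energy <= cutoff (boundary inclusive), a
    whitelisted miRNA and an allowed seed class; order preserved."""
    return [
        s
        for s in sites
        if s.energy <= cfg.energy_cutoff
        and s.mirna_name in cfg.whitelist
        and s.seed_class in cfg.allowed_classes
    ]
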