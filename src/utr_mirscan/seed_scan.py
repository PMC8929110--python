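"""Seed-anchored target scanning ("canonical" route).

A candidate site is an uninterrupted antiparallel complementary run of at
least 6 nt starting from the miRNA 5' end (position 1 or 2 — the seed is
conventionally nucleotides 2-8), optionally admitting G-U wobble pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import MiRNA

WATSON_CRICK = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
WOBBLE = {("G", "U"), ("U", "G")}


def pairs(a: str, b: str, allow_wobble: bool = True) -> bool:
    """True iff bases ``a`` and ``b`` form a Watson-Crick pair, or a G-U
    wobble when ``allow_wobble`` is set."""
    if (a, b) in WATSON_CRICK:
        return True
    return allow_wobble and (a, b) in WOBBLE


@dataclass(frozen=True)
class SeedMatch:
    """One seed-anchored complementary run.

    ``target_start``/``target_end`` are 1-based closed window offsets;
    ``mirna_start`` records which 5' anchor (1 or 2) produced the run;
    ``match_len`` is the full uninterrupted run length (>= 6, may exceed 8).
    """

    mirna_name: str
    target_start: int
    target_end: int
    mirna_start: int
    match_len: int
    wobble_count: int


def find_seed_matches(
    window: str,
    mirna: MiRNA,
    min_len: int = 6,
    max_len: int = 8,
    allow_wobble: bool = True,
) -> list[SeedMatch]:
    """Report every maximal seed-anchored run of length >= ``min_len``.

    For each target offset and each miRNA anchor in {1, 2} the run is
    extended base by base (antiparallel: the miRNA 5' end pairs the 3'-most
    target base of the site).  Runs are maximal; a run whose target interval
    is wholly contained in another reported run with the same anchor is
    dropped.  Output order is (target_start, mirna_start) lexicographic.

    ``max_len`` caps the *classified* canonical length downstream, not the
    recorded run length.
    """
    if min_len < 6:
        raise ValueError("min_len must be >= 6")
    m = mirna.sequence
    n = len(window)
    raw: dict[int, list[SeedMatch]] = {1: [], 2: []}
    if n < min_len:
        return []

    for anchor in (1, 2):
        for e in range(1, n + 1):  # target position paired with m[anchor]
            length = 0
            wob = 0
            while (
                e - length >= 1
                and anchor + length <= len(m)
                and pairs(window[e - length - 1], m[anchor + length - 1], allow_wobble)
            ):
                if (window[e - length - 1], m[anchor + length - 1]) in WOBBLE:
                    wob += 1
                length += 1
            if length >= min_len:
                raw[anchor].append(
                    SeedMatch(
                        mirna_name=mirna.name,
                        target_start=e - length + 1,
                        target_end=e,
                        mirna_start=anchor,
                        match_len=length,
                        wobble_count=wob,
                    )
                )

    kept: list[SeedMatch] = []
    for anchor in (1, 2):
        ms = raw[anchor]
        for cand in ms:
            contained = any(
                other is not cand
                and other.target_start <= cand.target_start
                and cand.target_end <= other.target_end
                and other.match_len >= cand.match_len
                and (other.target_start, other.target_end)
                != (cand.target_start, cand.target_end)
                for other in ms
            )
            if not contained:
                kept.append(cand)
    kept.sort(key=lambda s: (s.target_start, s.mirna_start))
    return kept
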