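"""Build the 50-nt reference/alternate target subsequences around a variant.

Scanning miRNA hybridization against short windows in the variant vicinity,
rather than the whole UTR, avoids long-range intramolecular structure from
masking binding sites.  Windows are centered on the variant with
``window_len/2`` context on each side and truncated at the UTR ends; for
indels the alternate window is re-extracted at nominal length from the
edited sequence so both alleles present a comparable search space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .io_formats import UTRSequence, UTRVariant


@dataclass(frozen=True)
class AlleleWindowPair:
    """The paired REF/ALT target subsequences around one variant.

    ``ref_start`` is the 1-based UTR offset of ``ref_window``; ``alt_anchor``
    is the 1-based offset of the variant position inside ``alt_window``.
    """

    variant_id: str
    ref_window: str
    alt_window: str
    ref_start: int
    alt_anchor: int
    window_len: int = 50


def apply_variant(utr: UTRSequence, v: UTRVariant) -> str:
    """Return the full UTR sequence with the variant applied.

    The ref allele at ``position`` is replaced by the alt allele; sequence
    length changes by ``len(alt) - len(ref)``.
    """
    p = v.position
    return (
        utr.sequence[: p - 1]
        + v.alt_allele
        + utr.sequence[p - 1 + len(v.ref_allele) :]
    )


def _slice_window(seq: str, center: int, window_len: int) -> tuple[str, int]:
    """Closed-interval slice [center - w/2, center + w/2 - 1] clipped to
    [1, len(seq)]; returns (window, 1-based start)."""
    half = window_len // 2
    start = max(1, center - half)
    end = min(len(seq), center + half - 1)
    return seq[start - 1 : end], start


def extract_window_pair(
    utr: UTRSequence,
    v: UTRVariant,
    window_len: int = 50,
    *,
    longest_mirna: int | None = None,
) -> AlleleWindowPair:
    """Extract the REF and ALT windows of nominal length ``window_len``
    centered on the variant position.

    For SNP/MNV the ALT window is the REF window with the substitution
    applied; for indels it is re-extracted at nominal length around the
    edited locus.  Windows are shorter than ``window_len`` only when the
    variant lies within ``window_len/2`` of a UTR end.
    """
    if window_len < 20 or window_len % 2:
        raise ValueError("window_len must be even and >= 20")
    if longest_mirna is not None and window_len < longest_mirna:
        warnings.warn(
            f"window ({window_len} nt) shorter than the longest whitelisted "
            f"miRNA ({longest_mirna} nt); some sites become undetectable"
        )

    ref_window, ref_start = _slice_window(utr.sequence, v.position, window_len)

    if len(v.ref_allele) == len(v.alt_allele):
        offset = v.position - ref_start
        alt_window = (
            ref_window[:offset]
            + v.alt_allele
            + ref_window[offset + len(v.ref_allele) :]
        )
        # substitution can run past the window's right edge on long MNVs
        alt_window = alt_window[: len(ref_window)]
        alt_start = ref_start
    else:
        edited = apply_variant(utr, v)
        alt_window, alt_start = _slice_window(edited, v.position, window_len)

    return AlleleWindowPair(
        variant_id=v.variant_id,
        ref_window=ref_window,
        alt_window=alt_window,
        ref_start=ref_start,
        alt_anchor=v.position - alt_start + 1,
        window_len=window_len,
    )
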