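"""Embedded nearest-neighbor free-energy parameters at 37 degC.

"reduced-nn-1": Turner-2004-style helix stacking values for the six RNA
pair types (Watson-Crick plus G-U wobble), a single duplex-initiation
penalty, and affine interior-loop/bulge penalties.  The full tabulated
interior-loop matrices, dangling ends and terminal-mismatch corrections of
the complete Turner set are deliberately not included: the model scores
intermolecular hybridization only, and ships self-contained.

A pair is written from the target strand, e.g. "GU" means target G paired
to miRNA U.  A stack key ``(p1, p2)`` is the motif 5'-x1 x2-3' (target) over
3'-y1 y2-5' (miRNA) with p1 = x1y1, p2 = x2y2.  Physical consistency
requires STACK[p1, p2] == STACK[reverse(p2), reverse(p1)] (the same stacked
motif read from the other strand); the table below satisfies it.  The two
wobble-on-wobble steps that are destabilizing in the full Turner set are
clamped to a weakly favorable -0.25 kcal/mol so that every helix extension
is favorable in the reduced model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

PAIR_TYPES = ("AU", "UA", "CG", "GC", "GU", "UG")

#: kcal/mol at 37 degC, keyed (pair1, pair2).
STACK_37: dict[tuple[str, str], float] = {
    ("AU", "AU"): -0.93, ("AU", "UA"): -1.10, ("AU", "CG"): -2.24,
    ("AU", "GC"): -2.08, ("AU", "GU"): -1.36, ("AU", "UG"): -0.55,
    ("UA", "AU"): -1.33, ("UA", "UA"): -0.93, ("UA", "CG"): -2.35,
    ("UA", "GC"): -2.11, ("UA", "GU"): -1.27, ("UA", "UG"): -1.00,
    ("CG", "AU"): -2.11, ("CG", "UA"): -2.08, ("CG", "CG"): -3.26,
    ("CG", "GC"): -2.36, ("CG", "GU"): -2.11, ("CG", "UG"): -1.41,
    ("GC", "AU"): -2.35, ("GC", "UA"): -2.24, ("GC", "CG"): -3.42,
    ("GC", "GC"): -3.26, ("GC", "GU"): -2.51, ("GC", "UG"): -1.53,
    ("GU", "AU"): -1.00, ("GU", "UA"): -0.55, ("GU", "CG"): -1.53,
    ("GU", "GC"): -1.41, ("GU", "GU"): -0.50, ("GU", "UG"): -0.25,
    ("UG", "AU"): -1.27, ("UG", "UA"): -1.36, ("UG", "CG"): -2.51,
    ("UG", "GC"): -2.11, ("UG", "GU"): -0.25, ("UG", "UG"): -0.50,
}


def reverse_pair(p: str) -> str:
    return p[::-1]


@dataclass(frozen=True)
class EnergyModel:
    """Additive nearest-neighbor hybridization model at 37 degC.

    energy = init_penalty + sum(stack terms over adjacent pair-steps)
           + sum(loop/bulge penalties over unpaired stretches between helices)
    """

    stack_energy: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(STACK_37)
    )
    init_penalty: float = 4.09
    loop_open: float = 1.70
    loop_extend_per_nt: float = 0.35
    bulge_open: float = 3.80
    bulge_extend_per_nt: float = 0.35
    max_internal_unpaired: int = 15
    version: str = "reduced-nn-1"

    def __post_init__(self) -> None:
        for p1 in PAIR_TYPES:
            for p2 in PAIR_TYPES:
                if (p1, p2) not in self.stack_energy:
                    raise ValueError(f"stack table missing step ({p1}, {p2})")
                if self.stack_energy[(p1, p2)] >= 0:
                    raise ValueError(f"stack energy for ({p1}, {p2}) must be negative")
        for name in ("init_penalty", "loop_open", "loop_extend_per_nt",
                     "bulge_open", "bulge_extend_per_nt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def gap_cost(self, a: int, b: int) -> float:
        """Penalty for an internal gap with ``a`` unpaired target nt and
        ``b`` unpaired miRNA nt between two helices."""
        if a == 0 and b == 0:
            return 0.0
        if a > 0 and b > 0:
            return self.loop_open + (a + b) * self.loop_extend_per_nt
        return self.bulge_open + (a + b) * self.bulge_extend_per_nt


DEFAULT_MODEL = EnergyModel()
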