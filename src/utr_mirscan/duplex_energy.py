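"""Minimum-free-energy RNA-RNA hybridization ("energy" route).

Computes the best single-site, co-linear (non-crossing) intermolecular
hybrid between a target window and a miRNA under the embedded
nearest-neighbor model: no intramolecular structure, no accessibility term.
A dynamic program over (window position, miRNA position) carries a stacking
recurrence with bounded interior loops/bulges; the seed constraint
(an uninterrupted helix of >= 6 pairs covering miRNA positions 1-8) can be
enforced, mirroring seed-anchored interaction predictors.

The alignment is antiparallel: the miRNA 5' end pairs the 3'-most target
base of the site, so the DP walks the target 5'->3' while walking the miRNA
3'->5'.

``enumerate_mfe`` is a brute-force reference scorer over *all* co-linear
pairings, tractable only for tiny sequences; it exists to validate the DP
and is never used by the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .energy_params import DEFAULT_MODEL, EnergyModel, PAIR_TYPES
from .io_formats import MiRNA
from .seed_scan import SeedMatch, WOBBLE

INF = math.inf

#: run lengths are tracked capped at 8: seed qualification saturates there.
_CMAX = 8

#: seed helix requirement: >= _SEED_MIN_RUN contiguous pairs within miRNA
#: positions [1, _SEED_SPAN_END].
_SEED_MIN_RUN = 6
_SEED_SPAN_END = 8


class StructureError(ValueError):
    """Raised when a pairing string is inconsistent with its sequences."""


@dataclass(frozen=True)
class InteractionSite:
    """One miRNA-target hybrid.

    ``pairing_string`` reads along the alignment from the target 5' end
    (= miRNA 3' end): 'P' Watson-Crick pair, 'W' G-U wobble pair,
    'T' unpaired target base, 'M' unpaired miRNA base.  Intervals are
    1-based closed; ``target_interval`` is in window coordinates.
    ``energy`` (kcal/mol, negative = favorable) is recomputable from the
    structure via :func:`score_structure`.
    """

    variant_id: str
    allele: str  # {"REF", "ALT"}
    mirna_name: str
    target_interval: tuple[int, int]
    mirna_interval: tuple[int, int]
    pairing_string: str
    energy: float
    seed_class: str = "none"
    method: str = "energy_scan"


def _pair_code(t: str, m: str) -> str | None:
    p = t + m
    return p if p in PAIR_TYPES else None


def _qualifies(j: int, c: int) -> bool:
    """Does a run of ``c`` contiguous pairs covering miRNA [j, j+c-1]
    contain >= 6 pairs within miRNA positions [1, 8]?"""
    if j > _SEED_SPAN_END:
        return False
    return min(_SEED_SPAN_END, j + c - 1) - j + 1 >= _SEED_MIN_RUN


def score_structure(
    pairing_string: str,
    target_sub: str,
    mirna_sub: str,
    model: EnergyModel = DEFAULT_MODEL,
) -> float:
    """Score a decoded hybrid: initiation + stacks + loop/bulge penalties.

    ``target_sub`` is the target subsequence covered by the site (5'->3');
    ``mirna_sub`` the covered miRNA subsequence (5'->3').  The walk consumes
    the target forward and the miRNA backward.  A structure with zero pairs
    scores +inf (no interaction); anything inconsistent raises
    :class:`StructureError`.
    """
    if not pairing_string:
        return INF
    if pairing_string[0] not in "PW" or pairing_string[-1] not in "PW":
        raise StructureError("structure must start and end with a base pair")

    tpos = 0
    mpos = len(mirna_sub) - 1
    energy = model.init_penalty
    prev_pair: str | None = None
    gap_t = gap_m = 0
    npairs = 0
    for code in pairing_string:
        if code in "PW":
            if tpos >= len(target_sub) or mpos < 0:
                raise StructureError("pairing string overruns a sequence")
            p = _pair_code(target_sub[tpos], mirna_sub[mpos])
            if p is None:
                raise StructureError(
                    f"bases {target_sub[tpos]}-{mirna_sub[mpos]} cannot pair"
                )
            is_wobble = (target_sub[tpos], mirna_sub[mpos]) in WOBBLE
            if (code == "W") != is_wobble:
                raise StructureError("pair code disagrees with base identities")
            if prev_pair is not None:
                if gap_t == 0 and gap_m == 0:
                    energy += model.stack_energy[(prev_pair, p)]
                else:
                    energy += model.gap_cost(gap_t, gap_m)
            prev_pair = p
            gap_t = gap_m = 0
            npairs += 1
            tpos += 1
            mpos -= 1
        elif code == "T":
            gap_t += 1
            tpos += 1
        elif code == "M":
            gap_m += 1
            mpos -= 1
        else:
            raise StructureError(f"unknown pairing code {code!r}")
    if tpos != len(target_sub) or mpos != -1:
        raise StructureError("pairing string does not cover both subsequences")
    if npairs == 0:
        return INF
    return energy


class _HybridDP:
    """DP over pairs (i, j): best co-linear hybrid whose last (3'-most in
    target) pair is target i / miRNA j, with run length (capped) and
    seed-satisfied flag as extra state."""

    def __init__(self, window: str, mirna_seq: str, model: EnergyModel):
        self.window = window
        self.mirna_seq = mirna_seq
        self.model = model
        n, M = len(window), len(mirna_seq)
        self.n, self.M = n, M
        pt = [[None] * (M + 1)]
        for i in range(1, n + 1):
            row: list[str | None] = [None]
            for j in range(1, M + 1):
                row.append(_pair_code(window[i - 1], mirna_seq[j - 1]))
            pt.append(row)
        self.pt = pt

        maxg = model.max_internal_unpaired
        stack = model.stack_energy
        # E[(i,j)][c][s], parent[(i,j,c,s)] = previous state or None (first pair)
        E: dict[tuple[int, int], list[list[float]]] = {}
        parent: dict[tuple[int, int, int, int], tuple | None] = {}
        # per-cell minima over c for loop transitions: (energy, c)
        bestc: dict[tuple[int, int], list[tuple[float, int]]] = {}

        cells: list[tuple[int, int]] = []
        for i in range(1, n + 1):
            for j in range(M, 0, -1):
                if pt[i][j] is None:
                    continue
                cells.append((i, j))
                e = [[INF, INF] for _ in range(_CMAX + 1)]
                # open a new duplex with this as the only pair
                e[1][0] = model.init_penalty
                parent[(i, j, 1, 0)] = None
                # loop/bulge transitions from earlier cells (c resets to 1)
                for k in range(max(1, i - 1 - maxg), i):
                    ptk = pt[k]
                    a = i - k - 1
                    for l in range(j + 1, min(M, j + 1 + maxg) + 1):
                        if ptk[l] is None or (a == 0 and l == j + 1):
                            continue
                        b = l - j - 1
                        cost = model.gap_cost(a, b)
                        bc = bestc.get((k, l))
                        if bc is None:
                            continue
                        for s_prev in (0, 1):
                            be, c_prev = bc[s_prev]
                            if be == INF:
                                continue
                            cand = be + cost
                            s_new = s_prev  # new run of length 1 cannot qualify
                            if cand < e[1][s_new] - 1e-12:
                                e[1][s_new] = cand
                                parent[(i, j, 1, s_new)] = (k, l, c_prev, s_prev)
                # stacking transition from the adjacent cell
                k, l = i - 1, j + 1
                if k >= 1 and l <= M and pt[k][l] is not None:
                    sc = stack[(pt[k][l], pt[i][j])]
                    eprev = E[(k, l)]
                    for c_prev in range(1, _CMAX + 1):
                        c_new = min(c_prev + 1, _CMAX)
                        q = _qualifies(j, c_new)
                        for s_prev in (0, 1):
                            if eprev[c_prev][s_prev] == INF:
                                continue
                            cand = eprev[c_prev][s_prev] + sc
                            s_new = 1 if (s_prev or q) else 0
                            if cand < e[c_new][s_new] - 1e-12:
                                e[c_new][s_new] = cand
                                parent[(i, j, c_new, s_new)] = (k, l, c_prev, s_prev)
                E[(i, j)] = e
                mins = []
                for s in (0, 1):
                    bc_e, bc_c = INF, 0
                    for c in range(1, _CMAX + 1):
                        if e[c][s] < bc_e:
                            bc_e, bc_c = e[c][s], c
                    mins.append((bc_e, bc_c))
                bestc[(i, j)] = mins
        self.E = E
        self.parent = parent
        self.bestc = bestc
        self.cells = cells

    def best_state(self, require_seed: bool) -> tuple[float, tuple | None]:
        best_e, best_state = INF, None
        for (i, j) in self.cells:
            e = self.E[(i, j)]
            for c in range(1, _CMAX + 1):
                for s in ((1,) if require_seed else (0, 1)):
                    if e[c][s] < best_e - 1e-12:
                        best_e, best_state = e[c][s], (i, j, c, s)
        return best_e, best_state

    def traceback(self, state: tuple) -> list[tuple[int, int]]:
        chain: list[tuple[int, int]] = []
        cur: tuple | None = state
        while cur is not None:
            chain.append((cur[0], cur[1]))
            cur = self.parent[cur]
        chain.reverse()
        return chain

    def extend_from(self, i0: int, j0: int) -> tuple[float, tuple | None]:
        """Best (energy-including-initiation + junction cost) of a chain
        ending strictly before pair (i0, j0); (inf, None) if no extension."""
        model = self.model
        maxg = model.max_internal_unpaired
        p0 = self.pt[i0][j0]
        best_e, best_state = INF, None
        for k in range(max(1, i0 - 1 - maxg), i0):
            a = i0 - k - 1
            for l in range(j0 + 1, min(self.M, j0 + 1 + maxg) + 1):
                if self.pt[k][l] is None:
                    continue
                b = l - j0 - 1
                if a == 0 and b == 0:
                    junction = model.stack_energy[(self.pt[k][l], p0)]
                else:
                    junction = model.gap_cost(a, b)
                for s in (0, 1):
                    be, c = self.bestc[(k, l)][s]
                    if be == INF:
                        continue
                    cand = be + junction
                    if cand < best_e - 1e-12:
                        best_e, best_state = cand, (k, l, c, s)
        return best_e, best_state


def _chain_to_site(
    chain: list[tuple[int, int]],
    window: str,
    mirna: MiRNA,
    energy: float,
    method: str,
    variant_id: str = "",
    allele: str = "",
) -> InteractionSite:
    """Build an InteractionSite from an ascending-target pair chain."""
    codes: list[str] = []
    for idx, (i, j) in enumerate(chain):
        if idx > 0:
            pi, pj = chain[idx - 1]
            codes.append("T" * (i - pi - 1))
            codes.append("M" * (pj - j - 1))
        wob = (window[i - 1], mirna.sequence[j - 1]) in WOBBLE
        codes.append("W" if wob else "P")
    t_lo, t_hi = chain[0][0], chain[-1][0]
    m_lo, m_hi = chain[-1][1], chain[0][1]
    return InteractionSite(
        variant_id=variant_id,
        allele=allele,
        mirna_name=mirna.name,
        target_interval=(t_lo, t_hi),
        mirna_interval=(m_lo, m_hi),
        pairing_string="".join(codes),
        energy=energy,
        method=method,
    )


def duplex_mfe(
    window: str,
    mirna: MiRNA,
    model: EnergyModel = DEFAULT_MODEL,
    require_seed: bool = True,
    *,
    variant_id: str = "",
    allele: str = "",
    dp: Optional[_HybridDP] = None,
) -> InteractionSite | None:
    """Minimum-free-energy co-linear hybrid, or None when the optimum is not
    favorable (>= 0 kcal/mol) or, with ``require_seed``, when no hybrid
    contains an uninterrupted helix of >= 6 pairs within miRNA positions
    1-8."""
    if len(window) < 6:
        return None
    if dp is None:
        dp = _HybridDP(window, mirna.sequence, model)
    energy, state = dp.best_state(require_seed)
    if state is None or energy >= 0.0:
        return None
    chain = dp.traceback(state)
    return _chain_to_site(chain, window, mirna, energy, "energy_scan",
                          variant_id, allele)


def rescore_seed_hit(
    match: SeedMatch,
    window: str,
    mirna: MiRNA,
    model: EnergyModel = DEFAULT_MODEL,
    *,
    variant_id: str = "",
    allele: str = "",
    dp: Optional[_HybridDP] = None,
) -> InteractionSite:
    """Score a seed-scan hit in its exact hybrid configuration.

    The seed helix is fixed to the matched run; the remaining miRNA 3'
    portion is extended by the DP over the target 5' flank when that lowers
    the energy.  The returned energy equals :func:`score_structure` of the
    assembled structure.
    """
    if dp is None:
        dp = _HybridDP(window, mirna.sequence, model)
    e, anchor, L = match.target_end, match.mirna_start, match.match_len
    # ascending-target helix pairs: (e-L+1, anchor+L-1) ... (e, anchor)
    helix = [(e - L + 1 + k, anchor + L - 1 - k) for k in range(L)]
    stack_sum = 0.0
    for (i1, j1), (i2, j2) in zip(helix, helix[1:]):
        stack_sum += model.stack_energy[(dp.pt[i1][j1], dp.pt[i2][j2])]

    energy = model.init_penalty + stack_sum
    chain = helix
    i0, j0 = helix[0]
    ext_e, ext_state = dp.extend_from(i0, j0)
    if ext_state is not None and ext_e + stack_sum < energy - 1e-12:
        energy = ext_e + stack_sum
        chain = dp.traceback(ext_state) + helix
    site = _chain_to_site(chain, window, mirna, energy, "seed_scan",
                          variant_id, allele)
    return site


def enumerate_mfe(
    window: str,
    mirna: MiRNA,
    model: EnergyModel = DEFAULT_MODEL,
    require_seed: bool = False,
) -> tuple[float, list[tuple[int, int]] | None]:
    """Exhaustive-enumeration reference: score every non-crossing set of
    intermolecular pairs (gap-bounded like the DP) and return the best
    (energy, chain).  Exponential; intended for sequences of <= ~10 nt."""
    n, M = len(window), len(mirna.sequence)
    pt = [[None] * (M + 1)] + [
        [None] + [_pair_code(window[i - 1], mirna.sequence[j - 1]) for j in range(1, M + 1)]
        for i in range(1, n + 1)
    ]
    maxg = model.max_internal_unpaired
    best: list = [INF, None]

    def rec(i: int, j: int, energy: float, run: int, seen: bool, chain: list) -> None:
        seen = seen or _qualifies(j, run)
        if (seen or not require_seed) and energy < best[0] - 1e-9:
            best[0] = energy
            best[1] = list(chain)
        for i2 in range(i + 1, min(n, i + 1 + maxg) + 1):
            a = i2 - i - 1
            for j2 in range(max(1, j - 1 - maxg), j):
                if pt[i2][j2] is None:
                    continue
                b = j - j2 - 1
                if a == 0 and b == 0:
                    step = model.stack_energy[(pt[i][j], pt[i2][j2])]
                    run2 = run + 1
                else:
                    step = model.gap_cost(a, b)
                    run2 = 1
                chain.append((i2, j2))
                rec(i2, j2, energy + step, run2, seen, chain)
                chain.pop()

    for i in range(1, n + 1):
        for j in range(1, M + 1):
            if pt[i][j] is not None:
                rec(i, j, model.init_penalty, 1, False, [(i, j)])
    return best[0], best[1]


def site_subsequences(site: InteractionSite, window: str, mirna: MiRNA) -> tuple[str, str]:
    """The (target, miRNA) subsequences covered by a site, for rescoring."""
    t_lo, t_hi = site.target_interval
    m_lo, m_hi = site.mirna_interval
    return window[t_lo - 1 : t_hi], mirna.sequence[m_lo - 1 : m_hi]


def verify_site_energy(
    site: InteractionSite,
    window: str,
    mirna: MiRNA,
    model: EnergyModel = DEFAULT_MODEL,
    tol: float = 1e-6,
) -> bool:
    """True iff score_structure on the site's own pairing string reproduces
    its reported energy within ``tol``."""
    t_sub, m_sub = site_subsequences(site, window, mirna)
    return abs(score_structure(site.pairing_string, t_sub, m_sub, model) - site.energy) <= tol
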