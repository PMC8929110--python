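"""Ground-truth synthetic fixtures: UTRs with planted miRNA sites and
variants that create, destroy, or leave sites untouched.

Planting writes the exact antiparallel complement demanded by the site
class into a random background (uniform over {A,C,G,U} by default, with an
optional AU-rich mode mimicking real 3'-UTR composition).  A
``create_on_alt`` plant is written with one seed-critical pair broken — the
matching variant restores it; ``destroy_on_alt`` plants the intact site and
the variant breaks the same pair.  The broken pair is the partner of miRNA
position 4, which splits the seed into runs of at most 3 and at most 4
pairs, below every recognition gate.

The generator *verifies* its own ground truth at plant time: the planted
site must be recoverable through the default gates, and neither allele may
carry a competing seed-qualifying run for the planted miRNA elsewhere in
the scan window.  When a random background violates this, the context is
re-rolled.  All randomness flows from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .duplex_energy import duplex_mfe, _pair_code
from .energy_params import DEFAULT_MODEL, EnergyModel
from .io_formats import MiRNA, UTRSequence, UTRVariant
from .seed_scan import pairs
from .site_filters import ClassifyConfig, DEFAULT_ENERGY_CUTOFF, classify_site
from .windowing import extract_window_pair

_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}
_WOBBLE_PARTNER = {"G": "U", "U": "G"}
_BASES = "ACGU"

#: miRNA position whose target partner is broken/restored by effect variants
_CRITICAL_MIRNA_POS = 4

#: planted miRNAs are re-sampled until the 8-mer seed helix alone reaches
#: this energy, 1 kcal/mol below the retention cutoff, so planted canonical
#: sites are retainable by construction.
PLANT_SEED_ENERGY_MAX = DEFAULT_ENERGY_CUTOFF - 1.0

_MAX_CONTEXT_REROLLS = 80


class PlantError(RuntimeError):
    """Raised when plants overlap or a valid context cannot be generated."""


@dataclass(frozen=True)
class PlantSpec:
    mirna: MiRNA
    site_class: str           # canonical_6/7/8, centered, compensatory
    position: int             # 1-based UTR offset of the planted subsequence
    effect: str = "neutral"   # {create_on_alt, destroy_on_alt, neutral}


@dataclass(frozen=True)
class PlantTruth:
    """One verified planted site: where it is and what the paired variant
    (if any) does to it."""

    mirna: MiRNA
    interval: tuple[int, int]
    site_class: str
    effect: str
    variant_position: int | None = None
    ref_base: str | None = None
    alt_base: str | None = None


def revcomp_target(mirna_sub: str) -> str:
    """Target subsequence (5'->3') perfectly pairing a miRNA subsequence."""
    return "".join(_COMP[b] for b in reversed(mirna_sub))


def seed_helix_energy(
    mirna: MiRNA, k: int = 8, model: EnergyModel = DEFAULT_MODEL
) -> float:
    """Helix-only energy of a perfect k-pair seed duplex for this miRNA."""
    m = mirna.sequence
    energy = model.init_penalty
    for j in range(k, 1, -1):  # ascending target = descending miRNA position
        p1 = _COMP[m[j - 1]] + m[j - 1]
        p2 = _COMP[m[j - 2]] + m[j - 2]
        energy += model.stack_energy[(p1, p2)]
    return energy


def random_mirna(
    rng: np.random.Generator,
    length: int = 22,
    name: str = "sim-miR",
    max_seed_energy: float | None = PLANT_SEED_ENERGY_MAX,
    model: EnergyModel = DEFAULT_MODEL,
) -> MiRNA:
    """A random mature miRNA; when ``max_seed_energy`` is set, re-sample
    until the perfect 8-mer seed helix reaches that energy."""
    for _ in range(500):
        seq = "".join(rng.choice(list(_BASES), size=length))
        mir = MiRNA(name, seq)
        if max_seed_energy is None or seed_helix_energy(mir, 8, model) <= max_seed_energy:
            return mir
    raise PlantError("could not sample a miRNA with a strong enough seed")


def _non_pairing_base(rng: np.random.Generator, mirna_base: str, exclude: str) -> str:
    """A base that neither WC- nor wobble-pairs ``mirna_base``."""
    options = [
        b for b in _BASES
        if b != exclude and not pairs(b, mirna_base, allow_wobble=True)
    ]
    return str(rng.choice(options))


def _site_sequence(spec: PlantSpec) -> str:
    """The intact target subsequence for a plant."""
    m = spec.mirna.sequence
    if spec.site_class.startswith("canonical_"):
        k = int(spec.site_class.split("_")[1])
        return revcomp_target(m[:k])
    if spec.site_class == "centered":
        return revcomp_target(m[2:13])  # miRNA positions 3-13, 11 pairs
    if spec.site_class == "compensatory":
        seed = list(revcomp_target(m[1:8]))  # miRNA 2-8
        # wobble at miRNA position 5: seed target index for m5 is 8-5=3
        m5 = m[4]
        if m5 in _WOBBLE_PARTNER:
            seed[3] = _WOBBLE_PARTNER[m5]
        else:  # no wobble partner exists: plant a mismatch instead
            seed[3] = "A" if m5 != "U" else "C"
        three_prime = revcomp_target(m[12:16])  # miRNA 13-16, 4 pairs
        return three_prime + "ACAC" + "".join(seed)
    raise ValueError(f"unknown site_class {spec.site_class!r}")


def _site_interval(spec: PlantSpec) -> tuple[int, int]:
    return spec.position, spec.position + len(_site_sequence(spec)) - 1


def _critical_target_pos(spec: PlantSpec) -> int:
    """UTR position pairing miRNA position 4 in a canonical plant."""
    k = int(spec.site_class.split("_")[1])
    return spec.position + k - _CRITICAL_MIRNA_POS


def _max_runs(window: str, mirna: MiRNA) -> list[tuple[int, int, int, int]]:
    """All maximal antiparallel complementary runs (wobble allowed) as
    (target_start, target_end, mirna_lo, mirna_hi), 1-based in the window."""
    n, m = len(window), mirna.sequence
    M = len(m)
    runs = []
    for i in range(1, n + 1):
        for j in range(M, 0, -1):
            if not pairs(window[i - 1], m[j - 1], True):
                continue
            if i > 1 and j < M and pairs(window[i - 2], m[j], True):
                continue  # not a run start
            length = 1
            while (
                i + length <= n
                and j - length >= 1
                and pairs(window[i + length - 1], m[j - length - 1], True)
            ):
                length += 1
            runs.append((i, i + length - 1, j - length + 1, j))
    return runs


def _seed_qualifying_runs(window: str, mirna: MiRNA) -> list[tuple[int, int, int, int]]:
    """Maximal runs carrying >= 6 contiguous pairs within miRNA [1, 8]."""
    out = []
    for (ts, te, ml, mh) in _max_runs(window, mirna):
        if ml <= 8 and min(8, mh) - ml + 1 >= 6:
            out.append((ts, te, ml, mh))
    return out


def _window_around(seq: str, center: int, width: int = 50) -> tuple[str, int]:
    half = width // 2
    start = max(1, center - half)
    end = min(len(seq), center + half - 1)
    return seq[start - 1 : end], start


def _intact_sequence_for(spec: PlantSpec, rng: np.random.Generator) -> tuple[str, PlantTruth]:
    """The planted subsequence as written into the REF UTR, plus truth."""
    intact = _site_sequence(spec)
    interval = _site_interval(spec)
    if spec.effect != "neutral" and not spec.site_class.startswith("canonical_"):
        raise ValueError(
            f"effect {spec.effect!r} is only supported for canonical plants"
        )
    if spec.effect == "neutral":
        return intact, PlantTruth(spec.mirna, interval, spec.site_class, spec.effect)

    crit = _critical_target_pos(spec)
    offset = crit - spec.position
    good = intact[offset]
    broken = _non_pairing_base(rng, spec.mirna.sequence[_CRITICAL_MIRNA_POS - 1], good)
    if spec.effect == "destroy_on_alt":
        return intact, PlantTruth(
            spec.mirna, interval, spec.site_class, spec.effect,
            variant_position=crit, ref_base=good, alt_base=broken,
        )
    if spec.effect == "create_on_alt":
        written = intact[:offset] + broken + intact[offset + 1 :]
        return written, PlantTruth(
            spec.mirna, interval, spec.site_class, spec.effect,
            variant_position=crit, ref_base=broken, alt_base=good,
        )
    raise ValueError(f"unknown effect {spec.effect!r}")


def _plant_ok(
    utr_seq: str, truth: PlantTruth, model: EnergyModel, cutoff: float
) -> bool:
    """Verify one plant's ground truth against the default gates."""
    mir = truth.mirna
    lo, hi = truth.interval
    center = (lo + hi) // 2
    # width 62 covers the pipeline's variant-centered 50-nt window even when
    # the effect variant sits a few nt off the site center
    window, wstart = _window_around(utr_seq, center, width=62)

    def local(iv: tuple[int, int]) -> tuple[int, int]:
        return iv[0] - wstart + 1, iv[1] - wstart + 1

    plant_lo, plant_hi = local(truth.interval)

    if truth.site_class.startswith("canonical_"):
        # which allele carries the intact site?
        if truth.effect == "create_on_alt":
            crit = truth.variant_position - wstart  # 0-based in window
            intact_window = window[:crit] + truth.alt_base + window[crit + 1 :]
            broken_window = window
        elif truth.effect == "destroy_on_alt":
            crit = truth.variant_position - wstart
            intact_window = window
            broken_window = window[:crit] + truth.alt_base + window[crit + 1 :]
        else:
            intact_window = window
            broken_window = None

        # the intact allele: exactly one qualifying run, sitting on the plant
        q = _seed_qualifying_runs(intact_window, mir)
        on_site = [r for r in q if not (r[1] < plant_lo or r[0] > plant_hi)]
        if len(on_site) != len(q) or not on_site:
            return False
        # retention through the default gates (energy + class)
        k = int(truth.site_class.split("_")[1])
        if seed_helix_energy(mir, k, model) <= cutoff:
            site = duplex_mfe(intact_window, mir, model, require_seed=True)
            if site is None or site.energy > cutoff:
                return False
            if classify_site(site, ClassifyConfig()) == "none":
                return False
            ts, te = site.target_interval
            if te < plant_lo or ts > plant_hi:
                return False
        # the broken allele (if any): no qualifying run at all
        if broken_window is not None and _seed_qualifying_runs(broken_window, mir):
            return False
    else:
        # non-canonical plants: require the written pairing to be present
        q = _max_runs(window, mir)
        if truth.site_class == "centered":
            if not any(te - ts + 1 >= 11 and 3 <= ml <= 6 for (ts, te, ml, _) in q):
                return False
    return True


def generate_utr(
    length: int,
    plants: Sequence[PlantSpec],
    rng_seed: int,
    au_rich: bool = False,
    model: EnergyModel = DEFAULT_MODEL,
    energy_cutoff: float = DEFAULT_ENERGY_CUTOFF,
    record_id: str = "sim-utr",
) -> tuple[UTRSequence, list[PlantTruth]]:
    """Generate a random UTR with the requested plants and return it with a
    verified truth table.  Reproducible for a fixed ``rng_seed``; raises
    :class:`PlantError` on overlapping plants or persistent context failure.
    """
    intervals = sorted((_site_interval(p), i) for i, p in enumerate(plants))
    for ((lo1, hi1), _), ((lo2, hi2), _) in zip(intervals, intervals[1:]):
        if lo2 <= hi1:
            raise PlantError(f"plants overlap: [{lo1},{hi1}] and [{lo2},{hi2}]")
    for (lo, hi), _ in intervals:
        if lo < 1 or hi > length:
            raise PlantError(f"plant [{lo},{hi}] outside UTR [1,{length}]")

    rng = np.random.default_rng(rng_seed)
    probs = [0.35, 0.15, 0.15, 0.35] if au_rich else None  # A C G U

    for _ in range(_MAX_CONTEXT_REROLLS):
        background = rng.choice(list(_BASES), size=length, p=probs)
        truths: list[PlantTruth] = []
        seq_arr = background.copy()
        for spec in plants:
            written, truth = _intact_sequence_for(spec, rng)
            lo, hi = truth.interval
            seq_arr[lo - 1 : hi] = list(written)
            truths.append(truth)
        seq = "".join(seq_arr)
        if all(_plant_ok(seq, t, model, energy_cutoff) for t in truths):
            return UTRSequence(record_id, seq), truths
    raise PlantError("no valid context after re-rolls; adjust plants or seed")


def generate_variant_set(
    utr: UTRSequence,
    truth: Sequence[PlantTruth],
    n_neutral: int,
    rng_seed: int,
) -> tuple[list[UTRVariant], dict[str, int]]:
    """Materialize the effect variants recorded in the truth table plus
    ``n_neutral`` SNPs outside any planted site; returns (variants,
    expected dN sign per variant_id: +1, -1 or 0)."""
    rng = np.random.default_rng(rng_seed)
    variants: list[UTRVariant] = []
    expected: dict[str, int] = {}

    for idx, t in enumerate(truth):
        if t.variant_position is None:
            continue
        vid = f"{t.effect}_{idx}"
        variants.append(UTRVariant(vid, t.variant_position, t.ref_base, t.alt_base))
        expected[vid] = +1 if t.effect == "create_on_alt" else -1

    mirnas = [t.mirna for t in truth]
    blocked = [t.interval for t in truth]
    made = 0
    for attempt in range(200 * max(1, n_neutral)):
        if made >= n_neutral:
            break
        pos = int(rng.integers(1, len(utr) + 1))
        if any(lo - 30 <= pos <= hi + 30 for lo, hi in blocked):
            continue
        ref = utr.sequence[pos - 1]
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        window, wstart = _window_around(utr.sequence, pos)
        local = pos - wstart + 1
        alt_window = window[: local - 1] + alt + window[local:]
        clean = True
        for mir in mirnas:
            for w in (window, alt_window):
                if any(
                    ts <= local <= te for (ts, te, _, _) in _seed_qualifying_runs(w, mir)
                ):
                    clean = False
                    break
            if not clean:
                break
        if not clean:
            continue
        vid = f"neutral_{made}"
        variants.append(UTRVariant(vid, pos, ref, alt))
        expected[vid] = 0
        made += 1
    if made < n_neutral:
        raise PlantError(f"placed only {made}/{n_neutral} neutral variants")
    return variants, expected


@dataclass(frozen=True)
class SimulatedCase:
    """A self-contained one-variant scenario with known ground truth."""

    utr: UTRSequence
    mirna: MiRNA
    variant: UTRVariant
    whitelist: frozenset[str]
    expected_sign: int


def generate_effect_case(
    effect: str,
    rng_seed: int,
    utr_length: int = 200,
    site_class: str = "canonical_8",
    model: EnergyModel = DEFAULT_MODEL,
) -> SimulatedCase:
    """One UTR + one miRNA + one variant with effect in
    {create_on_alt, destroy_on_alt, neutral}."""
    rng = np.random.default_rng(rng_seed)
    for _ in range(50):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        mir = random_mirna(rng, name=f"sim-miR-{effect}", model=model)
        pos = int(rng.integers(60, utr_length - 60))
        spec = PlantSpec(mir, site_class, pos,
                         effect if effect != "neutral" else "neutral")
        try:
            utr, truths = generate_utr(utr_length, [spec], sub_seed, model=model)
            if effect == "neutral":
                variants, expected = generate_variant_set(utr, truths, 1, sub_seed)
            else:
                variants, expected = generate_variant_set(utr, truths, 0, sub_seed)
        except PlantError:
            continue
        if not variants:
            continue
        v = variants[0]
        return SimulatedCase(utr, mir, v, frozenset({mir.name}), expected[v.variant_id])
    raise PlantError(f"could not generate a {effect} case from seed {rng_seed}")
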