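"""Readers and writers for every external file the pipeline touches.

All sequences are normalized to the RNA alphabet {A, C, G, U} internally
(DNA input is accepted and T is mapped to U).  Coordinates are 1-based,
fully closed, and local to the supplied 3'-UTR record; genomic coordinates
are out of scope.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

#: Mature miRNAs are typically 17-22 nt; accept a safety margin around that.
MIRNA_MIN_LEN = 16
MIRNA_MAX_LEN = 28


class FormatError(ValueError):
    """Raised when an input file violates its contract."""


@dataclass(frozen=True)
class UTRSequence:
    """A 3'-UTR target sequence, 5'->3', internal RNA alphabet."""

    record_id: str
    sequence: str
    source_alphabet: str = "RNA"  # {"DNA", "RNA"}

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5'->3', RNA alphabet."""

    name: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UTRVariant:
    """One substitution or indel in UTR-local 1-based coordinates.

    ``ref_allele`` is always non-empty: indels use the VCF-style anchor-base
    convention (e.g. deletion ``CG>C``, insertion ``C>CAA``).
    ``variant_class`` is derived from allele lengths, never user-supplied.
    """

    variant_id: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_class: str = field(init=False)

    def __post_init__(self) -> None:
        nr, na = len(self.ref_allele), len(self.alt_allele)
        if nr == 0 or na == 0:
            raise FormatError(
                f"variant {self.variant_id}: empty allele (use anchor-base convention)"
            )
        if nr == 1 and na == 1:
            cls = "SNP"
        elif na > nr:
            cls = "INS"
        elif na < nr:
            cls = "DEL"
        else:
            cls = "MNV"
        object.__setattr__(self, "variant_class", cls)


@dataclass(frozen=True)
class FrequencyAnnotation:
    """Maximum population allele frequency for one variant; NaN = missing."""

    variant_id: str
    max_population_allele_frequency: float  # in [0, 1], or NaN when missing

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.max_population_allele_frequency)


def normalize_rna(raw: str, *, record_id: str = "?") -> tuple[str, str]:
    """Uppercase, map T->U; return (sequence, source_alphabet).

    Raises :class:`FormatError` naming the record and 1-based offset of the
    first character outside {A, C, G, U} after normalization.
    """
    upper = raw.upper()
    source = "DNA" if "T" in upper else "RNA"
    seq = upper.replace("T", "U")
    for i, ch in enumerate(seq, start=1):
        if ch not in RNA_ALPHABET:
            raise FormatError(
                f"record {record_id}: invalid character {ch!r} at offset {i}"
            )
    return seq, source


def read_fasta(path: str | Path, kind: str) -> list[UTRSequence] | list[MiRNA]:
    """Read a FASTA file as UTR targets (``kind='utr'``) or a mature miRNA
    library (``kind='mirna'``).

    Record ids are the FASTA header up to the first whitespace.  Record order
    is preserved.  For miRNA libraries, duplicated names with an identical
    sequence are deduplicated; the same name with a conflicting sequence is an
    error, as is a length outside [16, 28] nt.
    """
    if kind not in ("utr", "mirna"):
        raise ValueError(f"kind must be 'utr' or 'mirna', got {kind!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")

    if kind == "utr":
        out_utr: list[UTRSequence] = []
        for rec in records:
            seq, source = normalize_rna(str(rec.seq), record_id=rec.id)
            if not seq:
                raise FormatError(f"record {rec.id}: empty sequence")
            out_utr.append(UTRSequence(rec.id, seq, source))
        return out_utr

    seen: dict[str, str] = {}
    out_mir: list[MiRNA] = []
    for rec in records:
        seq, _ = normalize_rna(str(rec.seq), record_id=rec.id)
        if not (MIRNA_MIN_LEN <= len(seq) <= MIRNA_MAX_LEN):
            raise FormatError(
                f"miRNA {rec.id}: length {len(seq)} outside "
                f"[{MIRNA_MIN_LEN}, {MIRNA_MAX_LEN}]"
            )
        if rec.id in seen:
            if seen[rec.id] != seq:
                raise FormatError(f"miRNA {rec.id}: duplicate name, conflicting sequence")
            continue
        seen[rec.id] = seq
        out_mir.append(MiRNA(rec.id, seq))
    return out_mir


def _validate_variant(v: UTRVariant, utr: UTRSequence) -> None:
    if not (1 <= v.position <= len(utr)):
        raise FormatError(
            f"variant {v.variant_id}: position {v.position} outside UTR "
            f"[1, {len(utr)}]"
        )
    end = v.position + len(v.ref_allele) - 1
    if end > len(utr):
        raise FormatError(f"variant {v.variant_id}: ref allele runs past the UTR end")
    observed = utr.sequence[v.position - 1 : end]
    if observed != v.ref_allele:
        raise FormatError(
            f"variant {v.variant_id}: ref allele {v.ref_allele!r} does not match "
            f"UTR {observed!r} at position {v.position}"
        )


def _read_variants_tsv(path: Path, utr: UTRSequence) -> list[UTRVariant]:
    out: list[UTRVariant] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"variant_id", "position", "ref", "alt"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(
                f"{path}: variant TSV needs columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            vid = row["variant_id"].strip()
            ref, _ = normalize_rna(row["ref"].strip(), record_id=vid)
            alt, _ = normalize_rna(row["alt"].strip(), record_id=vid)
            out.append(UTRVariant(vid, int(row["position"]), ref, alt))
    return out


def _read_variants_vcf(path: Path, utr: UTRSequence) -> list[UTRVariant]:
    from cyvcf2 import VCF

    out: list[UTRVariant] = []
    for rec in VCF(str(path)):
        if rec.CHROM != utr.record_id:
            raise FormatError(
                f"VCF CHROM {rec.CHROM!r} does not match UTR record "
                f"{utr.record_id!r}"
            )
        vid = rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}"
        ref, _ = normalize_rna(rec.REF, record_id=vid)
        for alt_raw in rec.ALT:
            alt, _ = normalize_rna(alt_raw, record_id=vid)
            out.append(UTRVariant(vid, rec.POS, ref, alt))
    return out


def read_variants(path: str | Path, utr: UTRSequence, dialect: str = "tsv") -> list[UTRVariant]:
    """Read a variant list (TSV or minimal VCF) and validate each record
    against the UTR sequence.  Positions are UTR-local and 1-based."""
    path = Path(path)
    if dialect == "tsv":
        variants = _read_variants_tsv(path, utr)
    elif dialect == "vcf":
        variants = _read_variants_vcf(path, utr)
    else:
        raise ValueError(f"dialect must be 'tsv' or 'vcf', got {dialect!r}")
    for v in variants:
        _validate_variant(v, utr)
    return variants


def write_variants_tsv(variants: Sequence[UTRVariant], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variant_id", "position", "ref", "alt"])
        for v in variants:
            w.writerow([v.variant_id, v.position, v.ref_allele, v.alt_allele])


def read_whitelist(path: str | Path) -> set[str]:
    """Read a tissue-specific miRNA whitelist: one mature name per line,
    ``#`` comments allowed, duplicates collapsed, case preserved."""
    names: set[str] = set()
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                names.add(entry)
    if not names:
        warnings.warn(f"{path}: empty whitelist; whitelist filtering will pass nothing")
    return names


def read_frequencies(path: str | Path) -> dict[str, FrequencyAnnotation]:
    """Read a two-column TSV (variant_id, max_af); empty/NA fields are missing."""
    out: dict[str, FrequencyAnnotation] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "variant_id" not in reader.fieldnames or "max_af" not in reader.fieldnames:
            raise FormatError(f"{path}: frequency TSV needs columns variant_id, max_af")
        for row in reader:
            raw = (row["max_af"] or "").strip()
            if raw in ("", "NA", "NaN", "nan", "."):
                af = math.nan
            else:
                af = float(raw)
                if not (0.0 <= af <= 1.0):
                    raise FormatError(
                        f"variant {row['variant_id']}: allele frequency {af} not in [0, 1]"
                    )
            out[row["variant_id"]] = FrequencyAnnotation(row["variant_id"], af)
    return out


def _format_af(value: float | None) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return repr(float(value))


def write_results(impacts, sites, out_prefix: str | Path) -> dict[str, Path]:
    """Write the three pipeline outputs under ``out_prefix``:

    * ``<prefix>.impacts.tsv`` — per-variant rows grouped by method with
      columns method, variant_id, delta_n, delta_w,
      max_population_allele_frequency, candidate_flag;
    * ``<prefix>.sites.json`` — every retained interaction site keyed by
      variant then allele (round-trippable, field-exact);
    * ``<prefix>.energy_summary.tsv`` — count/min/median of site energies per
      method x allele (a tabular stand-in for an energy-distribution plot).
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    impacts_path = out_prefix.with_suffix(out_prefix.suffix + ".impacts.tsv")
    sites_path = out_prefix.with_suffix(out_prefix.suffix + ".sites.json")
    summary_path = out_prefix.with_suffix(out_prefix.suffix + ".energy_summary.tsv")

    method_order = []
    for imp in impacts:
        if imp.method not in method_order:
            method_order.append(imp.method)
    with open(impacts_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["method", "variant_id", "delta_n", "delta_w",
             "max_population_allele_frequency", "candidate_flag"]
        )
        for method in method_order:
            for imp in impacts:
                if imp.method != method:
                    continue
                w.writerow(
                    [imp.method, imp.variant_id, imp.delta_n,
                     f"{imp.delta_w:.2f}",
                     _format_af(imp.max_population_allele_frequency),
                     int(imp.candidate)]
                )

    keyed: dict[str, dict[str, list[dict]]] = {}
    for site in sites:
        keyed.setdefault(site.variant_id, {}).setdefault(site.allele, []).append(
            asdict(site)
        )
    with open(sites_path, "w") as fh:
        json.dump(keyed, fh, indent=1, sort_keys=True)
        fh.write("\n")

    groups: dict[tuple[str, str], list[float]] = {}
    for site in sites:
        groups.setdefault((site.method, site.allele), []).append(site.energy)
    with open(summary_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["method", "allele", "count", "min_energy", "median_energy"])
        import numpy as np

        for (method, allele) in sorted(groups):
            vals = groups[(method, allele)]
            w.writerow(
                [method, allele, len(vals),
                 f"{min(vals):.2f}", f"{float(np.median(vals)):.2f}"]
            )

    return {"impacts": impacts_path, "sites": sites_path, "summary": summary_path}


def read_sites_json(path: str | Path):
    """Re-read a sites JSON written by :func:`write_results` into
    :class:`~utr_mirscan.duplex_energy.InteractionSite` objects."""
    from .duplex_energy import InteractionSite

    with open(path) as fh:
        keyed = json.load(fh)
    sites = []
    for variant_id in keyed:
        for allele in keyed[variant_id]:
            for rec in keyed[variant_id][allele]:
                rec = dict(rec)
                rec["target_interval"] = tuple(rec["target_interval"])
                rec["mirna_interval"] = tuple(rec["mirna_interval"])
                sites.append(InteractionSite(**rec))
    return sites
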