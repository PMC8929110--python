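"""Bundled published reference tables of downregulation-candidate variants.

Two machine-readable tables ship with the package: the reported
most-effective expression-downregulating 3'-UTR variants of DROSHA (20
rows) and DICER1 (64 rows) in mesenchymal stromal cells, with the reporting
route (seed-anchored scan vs. energy scan), the per-variant change in the
number of interacting miRNAs (dN), the change in the summed hybridization
energies (dW, kcal/mol), and the maximum population allele frequency (empty
where none was provided — parsed as missing, never 0).  They serve as
ground truth for output formatting and as external benchmarks for the
statistics this package computes.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

_CHECKSUMS = {
    "drosha_msc_candidates.tsv":
        "7f95eaaa0ab4abc2e9564fd41cef9749327cbb605fbf642076bfe0d2ad797f4d",
    "dicer1_msc_candidates.tsv":
        "0f355e9c918ada75a603ce46b81f640a822a797dc141122aa30f0572d4fc4916",
}

EXPECTED_ROWS = {"DROSHA": 20, "DICER1": 64}


@dataclass(frozen=True)
class CandidateRow:
    gene: str
    method: str        # {"seed_scan", "energy_scan"}
    variant_name: str
    delta_n: int
    delta_w: float
    max_af: float      # NaN = not provided


class ChecksumError(RuntimeError):
    """A bundled fixture does not match its recorded checksum."""


def _load_one(gene: str, filename: str) -> list[CandidateRow]:
    blob = resources.files("utr_mirscan.data").joinpath(filename).read_bytes()
    digest = hashlib.sha256(blob).hexdigest()
    if digest != _CHECKSUMS[filename]:
        raise ChecksumError(f"{filename}: checksum mismatch ({digest})")
    df = pd.read_csv(
        resources.files("utr_mirscan.data").joinpath(filename), sep="\t"
    )
    rows = []
    for rec in df.itertuples(index=False):
        af = float(rec.max_af) if not pd.isna(rec.max_af) else math.nan
        rows.append(
            CandidateRow(gene, rec.method, rec.variant_name,
                         int(rec.delta_n), float(rec.delta_w), af)
        )
    return rows


def load_reference_tables() -> list[CandidateRow]:
    """Load both bundled candidate tables (DROSHA then DICER1), verifying
    checksums; raises :class:`ChecksumError` on corruption."""
    out = _load_one("DROSHA", "drosha_msc_candidates.tsv")
    out += _load_one("DICER1", "dicer1_msc_candidates.tsv")
    for gene, n in EXPECTED_ROWS.items():
        got = sum(1 for r in out if r.gene == gene)
        if got != n:
            raise ChecksumError(f"{gene} table: expected {n} rows, got {got}")
    return out
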