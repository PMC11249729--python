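"""Codon-usage counting and initial-window vs gene-body enrichment ratios."""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .genetic_code import CODON_TO_AA, SENSE_CODONS, STOP_CODONS
from .io_formats import CodingGene

REGIONS = ("initial_window", "rest", "whole")


@dataclass(frozen=True)
class UsageTable:
    """Pooled codon counts for one region of a gene set.

    Regions follow the window convention of the speed statistics: position 1
    (the initiator ATG) and the stop codon are never counted, so
    ``initial_window`` covers positions 2..W, ``rest`` covers W+1..N-1, and
    ``whole`` is their codon-wise sum.
    """

    counts: Mapping[str, int]
    region: str
    window: int = 40

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")
        bad = set(self.counts) - set(SENSE_CODONS)
        if bad:
            raise ValueError(f"non-sense codons in usage table: {sorted(bad)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative codon count")
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequency(self, codon: str) -> float:
        return self.counts.get(codon, 0) / self.total


def count_usage(
    genes: Sequence[CodingGene], region: str = "whole", window: int = 40
) -> UsageTable:
    """Pool codon counts over the requested region of every gene."""
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}")
    if not genes:
        raise ValueError("empty gene list")
    counts: Counter[str] = Counter()
    for gene in genes:
        sense = gene.sense_codons
        if region == "initial_window":
            segment = sense[1:window]
        elif region == "rest":
            segment = sense[window:]
        else:
            segment = sense[1:]
        counts.update(c for c in segment if c not in STOP_CODONS)
    return UsageTable(dict(counts), region=region, window=window)


def enrichment_ratios(
    initial: UsageTable, rest: UsageTable
) -> dict[str, float]:
    """Relative frequency in the initial window over relative frequency in
    the gene body, per codon; > 1 means enriched near the terminus.

    Codons never seen in the body have an undefined ratio and are reported
    as NaN rather than infinity — no pseudocount is applied.
    """
    if initial.total == 0 or rest.total == 0:
        raise ValueError("usage tables must be non-empty")
    ratios: dict[str, float] = {}
    for codon in SENSE_CODONS:
        f_rest = rest.frequency(codon)
        if f_rest == 0:
            ratios[codon] = math.nan
        else:
            ratios[codon] = initial.frequency(codon) / f_rest
    return ratios


def per_aa_frequencies(
    usage: UsageTable,
    genetic_code: Mapping[str, str] = CODON_TO_AA,
) -> dict[str, dict[str, float]]:
    """Within-amino-acid codon fractions; they sum to 1 for each amino acid
    that occurs at all in the table."""
    by_aa: dict[str, dict[str, float]] = {}
    synonyms: dict[str, list[str]] = {}
    for codon, aa in genetic_code.items():
        synonyms.setdefault(aa, []).append(codon)
    for aa, codons in synonyms.items():
        total = sum(usage.counts.get(c, 0) for c in codons)
        if total == 0:
            by_aa[aa] = {c: 0.0 for c in sorted(codons)}
        else:
            by_aa[aa] = {c: usage.counts.get(c, 0) / total for c in sorted(codons)}
    return by_aa


def write_usage_report(
    initial: UsageTable, rest: UsageTable, path
) -> None:
    """TSV: codon, amino acid, initial count, rest count, enrichment ratio."""
    ratios = enrichment_ratios(initial, rest)
    with open(path, "w") as fh:
        fh.write("codon\tamino_acid\tinitial_count\trest_count\tratio\n")
        for codon in SENSE_CODONS:
            ratio = ratios[codon]
            text = "NA" if math.isnan(ratio) else f"{ratio:.6f}"
            fh.write(
                f"{codon}\t{CODON_TO_AA[codon]}\t{initial.counts.get(codon, 0)}\t"
                f"{rest.counts.get(codon, 0)}\t{text}\n"
            )


def rarest_codons(usage: UsageTable, n: int = 7) -> list[str]:
    """The n least-used codons in a usage table (ties by codon string)."""
    return sorted(SENSE_CODONS, key=lambda c: (usage.counts.get(c, 0), c))[:n]
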