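"""Readers, writers and validated domain containers for the pipeline inputs.

Four input families are handled:

* a codon -> ribosome residence time (RRT) table, two-column delimited text
  covering exactly the 61 sense codons;
* in-frame coding sequences (CDS) as FASTA, with an optional plain-text
  exclusion list (one gene id per line) for dubious/pseudogene annotations;
* protein BLAST tabular output (``-outfmt 6``) plus a subject -> species map;
* two-column gene -> value TSV tables (mRNA read counts, ribosome density).

Loaders apply the analysis inclusion filters (minimum ORF length, read-count
floor) and report what they dropped, so filter accounting is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .genetic_code import SENSE_CODONS, STOP_CODONS, normalize_codon

#: default neutral residence time used when a codon's speed is masked out
DEFAULT_NEUTRAL_RRT = 1.0189

#: minimum ORF length in nucleotides (100 codons + stop) for all analyses
DEFAULT_MIN_ORF_NT = 303

VALUE_KINDS = ("read_count", "ribosome_density", "other")


@dataclass(frozen=True)
class RRTTable:
    """Codon -> ribosome residence time map over the 61 sense codons.

    RRT is a dimensionless per-codon measure of ribosome occupancy with the
    codon in the A-site; larger values mean slower translation. Lookup of a
    stop codon fails: stops are never part of a speed profile.
    """

    entries: Mapping[str, float]
    neutral_value: float = DEFAULT_NEUTRAL_RRT

    def __post_init__(self) -> None:
        entries = dict(self.entries)
        missing = set(SENSE_CODONS) - set(entries)
        extra = set(entries) - set(SENSE_CODONS)
        if missing:
            raise ValueError(f"RRT table missing sense codons: {sorted(missing)}")
        if extra:
            raise ValueError(f"RRT table has non-sense codons: {sorted(extra)}")
        bad = {c: v for c, v in entries.items() if not v > 0}
        if bad:
            raise ValueError(f"RRT values must be positive, got: {bad}")
        if not self.neutral_value > 0:
            raise ValueError("neutral_value must be positive")
        object.__setattr__(self, "entries", entries)

    def __getitem__(self, codon: str) -> float:
        if codon in STOP_CODONS:
            raise KeyError(f"stop codon {codon} has no residence time")
        return self.entries[codon]

    def lookup(self, codon: str) -> float:
        return self[codon]

    def __contains__(self, codon: str) -> bool:
        return codon in self.entries

    def scaled(self, factor: float) -> "RRTTable":
        """Return a copy with every RRT multiplied by ``factor`` (> 0)."""
        if not factor > 0:
            raise ValueError("scale factor must be positive")
        return RRTTable(
            {c: v * factor for c, v in self.entries.items()}, self.neutral_value
        )


def load_rrt_table(
    path: str | Path, neutral_value: float = DEFAULT_NEUTRAL_RRT
) -> RRTTable:
    """Load a two-column (codon, RRT) delimited text file.

    A single header line is tolerated (detected by a non-numeric second
    field). Codons are upper-cased and RNA U is mapped to T. Missing,
    duplicate or non-positive entries are hard errors naming the codon.
    """
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            rows.append((parts[0], parts[1]))
    if rows:
        try:
            float(rows[0][1])
        except ValueError:
            rows = rows[1:]  # header line
    entries: dict[str, float] = {}
    for codon_raw, value_raw in rows:
        codon = normalize_codon(codon_raw)
        if codon in entries:
            raise ValueError(f"duplicate codon in RRT table: {codon}")
        try:
            value = float(value_raw)
        except ValueError as exc:
            raise ValueError(f"non-numeric RRT for codon {codon}: {value_raw!r}") from exc
        if not value > 0:
            raise ValueError(f"non-positive RRT for codon {codon}: {value}")
        entries[codon] = value
    missing = set(SENSE_CODONS) - set(entries)
    if missing:
        raise ValueError(f"RRT table missing sense codons: {sorted(missing)}")
    return RRTTable(entries, neutral_value=neutral_value)


def write_rrt_table(table: RRTTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("codon\trrt\n")
        for codon in SENSE_CODONS:
            fh.write(f"{codon}\t{table.entries[codon]!r}\n")


@dataclass(frozen=True)
class CodingGene:
    """A validated, codon-partitioned ORF including its stop codon.

    ``codons`` holds every codon in frame; the final codon is expected to be
    a stop. Violations of the coding-sequence conventions (no terminal stop,
    internal stops, non-ATG start) are recorded in ``flags`` rather than
    rejected, so the caller decides what is fatal.
    """

    gene_id: str
    codons: tuple[str, ...]
    annotation: str = "other"
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.codons) < 2:
            raise ValueError(f"{self.gene_id}: ORF must be at least 6 nt")
        bad = [c for c in self.codons if len(c) != 3 or set(c) - set("ACGT")]
        if bad:
            raise ValueError(f"{self.gene_id}: invalid codons {bad[:3]}")
        flags = set(self.flags)
        if self.codons[-1] not in STOP_CODONS:
            flags.add("no_terminal_stop")
        if any(c in STOP_CODONS for c in self.codons[:-1]):
            flags.add("internal_stop")
        if self.codons[0] != "ATG":
            flags.add("non_atg_start")
        object.__setattr__(self, "flags", frozenset(flags))

    @classmethod
    def from_sequence(
        cls, gene_id: str, sequence: str, annotation: str = "other"
    ) -> "CodingGene":
        seq = normalize_codon(sequence) if len(sequence) == 3 else (
            sequence.strip().upper().replace("U", "T")
        )
        if len(seq) % 3:
            raise ValueError(f"{gene_id}: length {len(seq)} not divisible by 3")
        codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
        return cls(gene_id, codons, annotation=annotation)

    @property
    def length_nt(self) -> int:
        return 3 * len(self.codons)

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    @property
    def n_sense(self) -> int:
        """Number of codon positions before the stop slot (positions 1..N-1)."""
        return len(self.codons) - 1

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return self.codons[:-1]

    @property
    def sequence(self) -> str:
        return "".join(self.codons)


@dataclass
class LoadReport:
    """Accounting of a CDS load: kept + sum(dropped) == n_input."""

    n_input: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


def load_cds(
    path: str | Path,
    exclusions: Iterable[str] | None = None,
    min_nt: int = DEFAULT_MIN_ORF_NT,
) -> tuple[list[CodingGene], LoadReport]:
    """Load in-frame coding sequences from FASTA, applying inclusion filters.

    Records whose id is in ``exclusions`` (e.g. dubious ORFs, pseudogenes)
    or whose length is below ``min_nt`` are dropped; sequences whose length
    is not a multiple of 3 are skipped with a warning. The boundary length
    ``min_nt`` itself is kept (the filter is strictly "shorter than").
    """
    excluded = set(exclusions or ())
    genes: list[CodingGene] = []
    report = LoadReport()
    for record in SeqIO.parse(str(path), "fasta"):
        report.n_input += 1
        if record.id in excluded:
            report.drop("excluded")
            continue
        seq = str(record.seq).upper().replace("U", "T")
        if len(seq) % 3:
            warnings.warn(
                f"{record.id}: length {len(seq)} not divisible by 3, skipped",
                stacklevel=2,
            )
            report.drop("frame")
            continue
        if len(seq) < min_nt:
            report.drop("length")
            continue
        genes.append(CodingGene.from_sequence(record.id, seq))
        report.n_kept += 1
    if report.n_input == 0:
        raise ValueError(f"no FASTA records in {path}")
    return genes, report


def load_exclusion_list(path: str | Path) -> set[str]:
    """One gene id per line; blank lines and # comments ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.split()[0])
    return out


def write_cds(genes: Iterable[CodingGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            fh.write(f">{gene.gene_id}\n{gene.sequence}\n")


@dataclass(frozen=True)
class GeneValueTable:
    """Gene -> scalar map (expression read counts, ribosome density, ...)."""

    values: Mapping[str, float]
    kind: str = "other"
    min_count: int = 10

    def __post_init__(self) -> None:
        if self.kind not in VALUE_KINDS:
            raise ValueError(f"kind must be one of {VALUE_KINDS}")
        values = dict(self.values)
        if self.kind == "read_count":
            low = {g: v for g, v in values.items() if v < self.min_count}
            if low:
                raise ValueError(
                    f"read_count values below min_count={self.min_count}: {low}"
                )
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, gene_id: str) -> float:
        return self.values[gene_id]

    def gene_ids(self) -> set[str]:
        return set(self.values)


def load_gene_values(
    path: str | Path, kind: str = "other", min_count: int = 10
) -> GeneValueTable:
    """Load a two-column (gene_id, value) TSV.

    ``read_count`` tables are filtered at ``min_count`` (values strictly
    below the floor are dropped); other kinds are unfiltered. Counts and
    densities must be non-negative; any non-numeric value is a hard error
    with its line number.
    """
    if kind not in VALUE_KINDS:
        raise ValueError(f"kind must be one of {VALUE_KINDS}")
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            gene_id, raw = parts[0], parts[1]
            if lineno == 1:
                try:
                    float(raw)
                except ValueError:
                    continue  # header
            try:
                value = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value {raw!r} for {gene_id}"
                ) from exc
            if gene_id in values:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene_id}")
            if kind in ("read_count", "ribosome_density") and value < 0:
                raise ValueError(
                    f"{path}:{lineno}: negative {kind} value {value} for {gene_id}"
                )
            values[gene_id] = value
    if kind == "read_count":
        values = {g: v for g, v in values.items() if v >= min_count}
    return GeneValueTable(values, kind=kind, min_count=min_count)


def write_gene_values(table: GeneValueTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tvalue\n")
        for gene_id in sorted(table.values):
            fh.write(f"{gene_id}\t{table.values[gene_id]!r}\n")


# --- BLAST tabular ---------------------------------------------------------

BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def load_species_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping subject id -> species name."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    return dict(zip(df[0], df[1]))


def load_blast_hits(
    path: str | Path, species_map: Mapping[str, str], half: str = "first"
):
    """Parse BLAST ``-outfmt 6`` tabular output into :class:`BlastHSP` rows.

    Subjects absent from ``species_map`` are dropped with a warning. Query
    coordinates stay 1-based inclusive, exactly as BLAST reports them.
    """
    from .conservation import BlastHSP  # deferred: conservation owns the type

    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=BLAST6_COLUMNS)
    hits: list[BlastHSP] = []
    unmapped: set[str] = set()
    for row in df.itertuples(index=False):
        species = species_map.get(row.sseqid)
        if species is None:
            unmapped.add(row.sseqid)
            continue
        hits.append(
            BlastHSP(
                query_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                species=species,
                bit_score=float(row.bitscore),
                query_start=int(row.qstart),
                query_end=int(row.qend),
                half=half,
            )
        )
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} subject ids without species mapping dropped "
            f"(e.g. {sorted(unmapped)[:3]})",
            stacklevel=2,
        )
    return hits
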