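"""Windowed terminal Conservation Scores from BLAST hit geometry.

Each query protein is split into two halves which are BLASTed separately
(splitting keeps the aligner honest: for the middle window it must find
homology at the *end* of a query, just as it must for the true termini).
Three 40-residue windows are scored per protein:

* N-terminal window, residues 1..40, from first-half hits;
* middle window, residues floor(M/2)+1 .. floor(M/2)+40 (displaced 20
  residues C-terminal of the exact middle), from second-half hits;
* C-terminal window, residues M-39..M, from second-half hits.

A subject species *qualifies* if any of its HSPs reaches the qualifying
bit-score (default 50). For each qualified species the window coverage is
the number of window positions covered by the union of that species' HSP
query intervals whose bit-score reaches the strong-homology threshold
(default 200, the "red" band of the BLAST graphic summary). The
Conservation Score is the mean coverage over qualified species — 0 when no
qualified species has strong homology in the window, 40 when every one
covers it completely. Scores are only trusted ('ok') when at least
``min_species`` (default 40) species qualify.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

QUAL_BITS = 50.0
REGION_BITS = 200.0
MIN_SPECIES = 40
WINDOW_AA = 40

STATUS_OK = "ok"
STATUS_TOO_FEW = "too_few_species"
STATUS_TOO_SHORT = "too_short"


@dataclass(frozen=True)
class BlastHSP:
    """One high-scoring segment pair on query coordinates (1-based inclusive)."""

    query_id: str
    subject_id: str
    species: str
    bit_score: float
    query_start: int
    query_end: int
    half: str = "first"

    def __post_init__(self) -> None:
        if not 1 <= self.query_start <= self.query_end:
            raise ValueError(
                f"{self.query_id}/{self.subject_id}: bad interval "
                f"[{self.query_start}, {self.query_end}]"
            )
        if not self.bit_score > 0:
            raise ValueError("bit_score must be positive")

    def shifted(self, offset: int) -> "BlastHSP":
        """Copy with query coordinates shifted by ``offset`` residues."""
        return BlastHSP(
            self.query_id,
            self.subject_id,
            self.species,
            self.bit_score,
            self.query_start + offset,
            self.query_end + offset,
            half=self.half,
        )


class ProteinTooShortError(ValueError):
    """Raised for proteins below the 100-residue scoring floor."""


@dataclass(frozen=True)
class WindowScheme:
    """The three 40-aa scoring windows for a protein of M residues."""

    protein_length: int
    n_window: tuple[int, int]
    mid_window: tuple[int, int]
    c_window: tuple[int, int]

    @property
    def half_split(self) -> int:
        """Length of the first half, floor(M/2)."""
        return self.protein_length // 2


def window_scheme(protein_length: int) -> WindowScheme:
    """Scoring windows for a protein; halves are [1, floor(M/2)] and
    [floor(M/2)+1, M]. E.g. M=709 gives (1,40), (355,394), (670,709)."""
    if protein_length < 100:
        raise ProteinTooShortError(
            f"protein of {protein_length} aa is below the 100 aa floor"
        )
    half = protein_length // 2
    return WindowScheme(
        protein_length=protein_length,
        n_window=(1, WINDOW_AA),
        mid_window=(half + 1, half + WINDOW_AA),
        c_window=(protein_length - WINDOW_AA + 1, protein_length),
    )


def alt_mid_window(scheme: WindowScheme) -> tuple[int, int]:
    """Variant middle window: the last 40 residues of the *first* half
    (scored from first-half hits); gives near-identical results."""
    half = scheme.half_split
    return (half - WINDOW_AA + 1, half)


@dataclass(frozen=True)
class ConservationRecord:
    query_id: str
    window: tuple[int, int]
    score: float
    n_species: int
    status: str = STATUS_OK

    def __post_init__(self) -> None:
        width = self.window[1] - self.window[0] + 1
        if self.status in (STATUS_OK, STATUS_TOO_FEW) and not (
            0.0 <= self.score <= width + 1e-9
        ):
            raise ValueError(f"score {self.score} outside [0, {width}]")


def dedupe_by_species(hits: Sequence[BlastHSP]) -> list[BlastHSP]:
    """Keep, per (query, half, species), only the best subject's HSPs.

    The best subject is the one whose strongest HSP bit-score is maximal
    for that species; ties go to the lexicographically smallest subject id.
    Collapses duplicate database submissions of the same species.
    """
    best_subject: dict[tuple[str, str, str], tuple[float, str]] = {}
    for hsp in hits:
        key = (hsp.query_id, hsp.half, hsp.species)
        cand = (hsp.bit_score, hsp.subject_id)
        prev = best_subject.get(key)
        if prev is None:
            best_subject[key] = cand
            continue
        # higher bit wins; equal bit -> smaller subject id wins
        if cand[0] > prev[0] or (cand[0] == prev[0] and cand[1] < prev[1]):
            best_subject[key] = cand
    return [
        hsp
        for hsp in hits
        if best_subject[(hsp.query_id, hsp.half, hsp.species)][1] == hsp.subject_id
    ]


def _covered_positions(
    intervals: Iterable[tuple[int, int]], window: tuple[int, int]
) -> int:
    """Positions of the closed window covered by a union of closed intervals."""
    lo, hi = window
    clipped = sorted(
        (max(s, lo), min(e, hi)) for s, e in intervals if s <= hi and e >= lo
    )
    covered = 0
    cur_start = cur_end = None
    for s, e in clipped:
        if cur_end is None or s > cur_end + 1:
            if cur_end is not None:
                covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start + 1
    return covered


def conservation_score(
    hits: Sequence[BlastHSP],
    window: tuple[int, int],
    qual_bits: float = QUAL_BITS,
    region_bits: float = REGION_BITS,
    min_species: int = MIN_SPECIES,
    query_id: str | None = None,
) -> ConservationRecord:
    """Mean window coverage over qualified species (the Conservation Score).

    ``hits`` must already be species-deduplicated and on the same coordinate
    system as ``window``. A species qualifies with any HSP at
    ``bit >= qual_bits`` even if none reaches ``region_bits``; such species
    contribute coverage 0 and pull the mean down.
    """
    if window[0] < 1 or window[1] < window[0]:
        raise ValueError(f"bad window {window}")
    if query_id is None:
        query_id = hits[0].query_id if hits else ""
    by_species: dict[str, list[BlastHSP]] = {}
    for hsp in hits:
        if hsp.bit_score >= qual_bits:
            by_species.setdefault(hsp.species, []).append(hsp)
    if not by_species:
        return ConservationRecord(query_id, window, 0.0, 0, STATUS_TOO_FEW)
    coverages = []
    for species_hits in by_species.values():
        strong = [
            (h.query_start, h.query_end)
            for h in species_hits
            if h.bit_score >= region_bits
        ]
        coverages.append(_covered_positions(strong, window))
    score = sum(coverages) / len(coverages)
    status = STATUS_OK if len(coverages) >= min_species else STATUS_TOO_FEW
    return ConservationRecord(query_id, window, score, len(coverages), status)


def score_all_windows(
    hits_first_half: Sequence[BlastHSP],
    hits_second_half: Sequence[BlastHSP],
    scheme: WindowScheme,
    qual_bits: float = QUAL_BITS,
    region_bits: float = REGION_BITS,
    min_species: int = MIN_SPECIES,
    query_id: str | None = None,
) -> tuple[ConservationRecord, ConservationRecord, ConservationRecord]:
    """Score the N, middle and C windows of one protein.

    First-half hits are already on full-protein coordinates (the first half
    starts at residue 1). Second-half hits arrive on second-half-local query
    coordinates and are offset by +floor(M/2) before scoring the middle and
    C windows; first-half evidence never reaches those windows.
    """
    offset = scheme.half_split
    shifted = [h.shifted(offset) for h in hits_second_half]
    kwargs = dict(
        qual_bits=qual_bits,
        region_bits=region_bits,
        min_species=min_species,
        query_id=query_id,
    )
    n_rec = conservation_score(hits_first_half, scheme.n_window, **kwargs)
    mid_rec = conservation_score(shifted, scheme.mid_window, **kwargs)
    c_rec = conservation_score(shifted, scheme.c_window, **kwargs)
    return n_rec, mid_rec, c_rec


def write_conservation_records(
    records: Sequence[tuple[str, ConservationRecord]], path
) -> None:
    """TSV: query_id, window label, window, score, n_species, status."""
    with open(path, "w") as fh:
        fh.write("query_id\tlabel\tstart\tend\tscore\tn_species\tstatus\n")
        for label, rec in records:
            fh.write(
                f"{rec.query_id}\t{label}\t{rec.window[0]}\t{rec.window[1]}\t"
                f"{rec.score:.6f}\t{rec.n_species}\t{rec.status}\n"
            )
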