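"""Synonymous recoding of leader windows and collision-pair insertion.

Designs slow / medium / fast encodings of the first ``window`` codons of a
source ORF without changing its protein sequence, mirroring how reporter
leaders are engineered: per position, the synonym with maximal RRT (slow),
minimal RRT (fast), or RRT closest to the neutral value (medium). Because
the objective is separable over positions, the per-position choice is
globally optimal for the window mean. A putative ribosome collision site —
the rare codon pair CGA-CGG — can be dropped into a construct downstream of
the leader; that substitution does change two amino acids (Asn-Asp becomes
Arg-Arg), deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    START_LIKE_CODONS,
    STOP_CODONS,
    translate_codons,
)
from .io_formats import CodingGene, RRTTable
from .speed_metrics import rit as compute_rit

TARGETS = ("slow", "medium", "fast")
COLLISION_PAIR = ("CGA", "CGG")
DEFAULT_WINDOW = 41


@dataclass(frozen=True)
class RecodedConstruct:
    name: str
    codons: tuple[str, ...]
    target: str
    window: int
    mean_rrt_window: float
    rit: float
    pcs_position: int | None = None

    def to_gene(self) -> CodingGene:
        return CodingGene(self.name, self.codons)


def _pick_synonym(
    aa: str, rrt: RRTTable, target: str, avoid_starts: bool
) -> str:
    candidates = AA_TO_CODONS[aa]
    if avoid_starts:
        kept = tuple(c for c in candidates if c not in START_LIKE_CODONS)
        if kept:
            candidates = kept
    if target == "fast":
        key = lambda c: (rrt[c], c)
        return min(candidates, key=key)
    if target == "slow":
        return min(candidates, key=lambda c: (-rrt[c], c))
    if target == "medium":
        return min(candidates, key=lambda c: (abs(rrt[c] - rrt.neutral_value), c))
    raise ValueError(f"target must be one of {TARGETS}, got {target!r}")


def recode_window(
    source: CodingGene,
    rrt: RRTTable,
    target: str,
    window: int = DEFAULT_WINDOW,
    avoid_starts: bool = True,
    name: str | None = None,
) -> RecodedConstruct:
    """Replace codons at positions 2..window with target-speed synonyms.

    Position 1 (the initiator) and everything beyond the window, including
    the stop codon, are untouched. With ``avoid_starts`` (default), the
    Start-like codons ATG/ATT/TTG/ATA are skipped whenever the amino acid
    has another synonym, emulating their depletion in natural leaders.
    Synonym ties break to the lexicographically smallest codon, so the
    design is deterministic.
    """
    if window > source.n_sense:
        raise ValueError(
            f"window {window} exceeds the {source.n_sense} sense codons of "
            f"{source.gene_id}"
        )
    codons = list(source.codons)
    for i in range(1, window):
        aa = CODON_TO_AA[codons[i]]
        codons[i] = _pick_synonym(aa, rrt, target, avoid_starts)
    codons = tuple(codons)
    profile = np.array([rrt[c] for c in codons[:window]])
    gene = CodingGene(name or f"{source.gene_id}:{target}", codons)
    record = compute_rit(gene, rrt, window=window)
    return RecodedConstruct(
        name=gene.gene_id,
        codons=codons,
        target=target,
        window=window,
        mean_rrt_window=float(profile.mean()),
        rit=record.rit,
    )


def insert_collision_pair(
    gene: CodingGene,
    position: int,
    pair: tuple[str, str] = COLLISION_PAIR,
) -> CodingGene:
    """Replace the codons at 1-based positions (position, position+1).

    The stop codon may not be touched, so ``position + 1`` must be at most
    N-1. Length is unchanged; the encoded amino acids do change (for the
    default pair, Asn-Asp -> Arg-Arg).
    """
    if position < 1 or position + 1 > gene.n_sense:
        raise ValueError(
            f"pair at positions {position},{position + 1} overlaps the stop "
            f"codon or falls outside {gene.gene_id} ({gene.n_sense} sense codons)"
        )
    if any(c in STOP_CODONS for c in pair):
        raise ValueError("collision pair may not contain a stop codon")
    codons = list(gene.codons)
    codons[position - 1] = pair[0]
    codons[position] = pair[1]
    return CodingGene(gene.gene_id, tuple(codons), annotation=gene.annotation)


def construct_report(
    constructs: Sequence[CodingGene],
    rrt: RRTTable,
    window: int = DEFAULT_WINDOW,
    include_first: bool = True,
) -> pd.DataFrame:
    """Mean leader RRT and RIT for each construct.

    ``include_first`` averages the RRT of codon positions 1..window (the
    whole recoded leader, initiator included); set it False to average
    positions 2..window instead. The RIT always follows the statistic's own
    convention (numerator = positions 2..window).
    """
    rows = []
    start = 0 if include_first else 1
    for gene in constructs:
        profile = np.array([rrt[c] for c in gene.codons[:window]])
        record = compute_rit(gene, rrt, window=window)
        rows.append(
            {
                "name": gene.gene_id,
                "mean_rrt_window": float(profile[start:].mean()),
                "rit": record.rit,
            }
        )
    return pd.DataFrame(rows, columns=["name", "mean_rrt_window", "rit"])


def verify_translation(source: CodingGene, construct: RecodedConstruct) -> bool:
    """True iff source and recoded construct encode the same protein."""
    return translate_codons(source.sense_codons) == translate_codons(
        construct.codons[: len(construct.codons) - 1]
    )
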