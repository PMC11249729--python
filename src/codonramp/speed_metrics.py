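"""Per-codon speed profiles and the relative initial translation (RIT) statistic.

The RIT of a gene compares the encoded translation speed of a terminal codon
window against the rest of the same gene, on the ribosome-residence-time
(RRT) scale:

    RIT = log2( mean RRT(codons 2..W) / mean RRT(codons W+1..N-1) )

for the 5' end, where position 1 (the invariant, unusually fast ATG) and the
stop codon at position N are both omitted. Positive RIT means the initial
window is *slower* than the gene body; this sign convention matches the
designed reporter constructs (a slow leader scores +0.208-ish, a fast one
negative). For the 3' end the numerator is the last W sense codons
(positions N-W..N-1) and the denominator is positions 2..N-W-1.

Genome-wide summaries average the per-gene window/body RRT ratio and test
the paired difference with a two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genetic_code import SENSE_CODONS, STOP_CODONS
from .io_formats import CodingGene, RRTTable

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


@dataclass(frozen=True)
class RITRecord:
    """Per-gene terminal speed statistic with its window metadata."""

    gene_id: str
    window: int
    rit: float
    n_numerator: int
    n_denominator: int
    end: str = FIVE_PRIME

    def __post_init__(self) -> None:
        if self.n_numerator < 1 or self.n_denominator < 1:
            raise ValueError("numerator and denominator need >= 1 codon each")
        if not np.isfinite(self.rit):
            raise ValueError(f"{self.gene_id}: non-finite RIT")


@dataclass(frozen=True)
class SlowdownSummary:
    """Genome-wide terminal slowdown: mean % RRT excess plus a paired test."""

    window: int
    mean_ratio_pct: float
    p_value: float
    n_genes: int
    end: str = FIVE_PRIME
    scale: str = "rrt"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")


def speed_profile(gene: CodingGene, rrt: RRTTable) -> np.ndarray:
    """One RRT value per sense codon (positions 1..N-1); stop omitted."""
    values = np.empty(gene.n_sense)
    for i, codon in enumerate(gene.sense_codons):
        if codon in STOP_CODONS:
            raise ValueError(
                f"{gene.gene_id}: internal stop codon {codon} at position {i + 1}"
            )
        values[i] = rrt[codon]
    return values


def _window_slices(n_sense: int, window: int, end: str):
    """(numerator, denominator) 0-based slices into a sense-codon profile."""
    if end == FIVE_PRIME:
        # positions 2..W and W+1..N-1 (1-based codon positions)
        return slice(1, window), slice(window, n_sense)
    if end == THREE_PRIME:
        # positions N-W..N-1 and 2..N-W-1
        return slice(n_sense - window, n_sense), slice(1, n_sense - window)
    raise ValueError(f"end must be {FIVE_PRIME!r} or {THREE_PRIME!r}, got {end!r}")


def window_means(
    profile: np.ndarray, window: int, end: str = FIVE_PRIME
) -> tuple[float, float, int, int]:
    """Mean RRT of the terminal window and of the rest of the gene."""
    n_sense = len(profile)
    if n_sense < window + 2:
        raise ValueError(
            f"gene has {n_sense} sense codons; window {window} needs >= {window + 2}"
        )
    num, den = _window_slices(n_sense, window, end)
    return (
        float(profile[num].mean()),
        float(profile[den].mean()),
        num.stop - num.start,
        den.stop - den.start,
    )


def rit(
    gene: CodingGene, rrt: RRTTable, window: int = 40, end: str = FIVE_PRIME
) -> RITRecord:
    """Relative initial (or terminal) translation statistic for one gene."""
    profile = speed_profile(gene, rrt)
    num_mean, den_mean, n_num, n_den = window_means(profile, window, end)
    return RITRecord(
        gene_id=gene.gene_id,
        window=window,
        rit=float(np.log2(num_mean / den_mean)),
        n_numerator=n_num,
        n_denominator=n_den,
        end=end,
    )


def classify_rit(record: RITRecord, threshold: float = 0.0) -> str:
    """'SIT' (slow initial translation) iff rit > threshold, else 'FIT'."""
    return "SIT" if record.rit > threshold else "FIT"


def neutralize(rrt: RRTTable, codons: Iterable[str]) -> RRTTable:
    """Return a copy with the listed codons set to the neutral residence time.

    Used to ask how much of a terminal slowdown survives once particular
    codons (e.g. Start and alternative Start codons) are stripped of their
    speed signal. The input table is not modified.
    """
    codons = set(codons)
    stops = codons & STOP_CODONS
    if stops:
        raise ValueError(f"cannot neutralize stop codons: {sorted(stops)}")
    unknown = codons - set(SENSE_CODONS)
    if unknown:
        raise ValueError(f"not sense codons: {sorted(unknown)}")
    entries = dict(rrt.entries)
    for codon in codons:
        entries[codon] = rrt.neutral_value
    return RRTTable(entries, neutral_value=rrt.neutral_value)


def genomewide_slowdown(
    genes: Sequence[CodingGene],
    rrt: RRTTable,
    window: int = 40,
    end: str = FIVE_PRIME,
    scale: str = "rrt",
) -> SlowdownSummary:
    """Average terminal slowdown across a gene set, with a paired test.

    Per gene the window and body mean RRTs are compared; genes too short for
    the window are skipped. ``mean_ratio_pct`` is 100 x mean(window/body - 1)
    on the RRT scale (positive = initial window slower). ``scale='speed'``
    averages the inverse-RRT (speed) ratio body/window - 1 instead, which
    differs slightly because the two means do not commute.

    The p-value is a two-sided Wilcoxon signed-rank test of the per-gene
    paired (window mean, body mean) differences.
    """
    if scale not in ("rrt", "speed"):
        raise ValueError("scale must be 'rrt' or 'speed'")
    num_means: list[float] = []
    den_means: list[float] = []
    for gene in genes:
        profile = speed_profile(gene, rrt)
        if len(profile) < window + 2:
            continue
        if scale == "speed":
            profile = 1.0 / profile
        num_mean, den_mean, _, _ = window_means(profile, window, end)
        num_means.append(num_mean)
        den_means.append(den_mean)
    if len(num_means) < 2:
        raise ValueError("need at least 2 genes long enough for the window")
    num_arr = np.asarray(num_means)
    den_arr = np.asarray(den_means)
    if scale == "rrt":
        pct = 100.0 * float(np.mean(num_arr / den_arr - 1.0))
    else:  # speed scale: positive still means the window is slower
        pct = 100.0 * float(np.mean(den_arr / num_arr - 1.0))
    diffs = num_arr - den_arr
    if np.all(diffs == 0):
        p_value = 1.0
    else:
        p_value = float(stats.wilcoxon(num_arr, den_arr, alternative="two-sided").pvalue)
    return SlowdownSummary(
        window=window,
        mean_ratio_pct=pct,
        p_value=p_value,
        n_genes=len(num_means),
        end=end,
        scale=scale,
    )


def rit_table(
    genes: Sequence[CodingGene],
    rrt: RRTTable,
    window: int = 40,
    end: str = FIVE_PRIME,
) -> list[RITRecord]:
    """RIT for every gene long enough for the window (others skipped)."""
    out = []
    for gene in genes:
        if gene.n_sense < window + 2:
            continue
        out.append(rit(gene, rrt, window=window, end=end))
    return out


def sit_fraction(records: Sequence[RITRecord], threshold: float = 0.0) -> float:
    """Fraction of genes classified SIT (slow initial translation)."""
    if not records:
        raise ValueError("no RIT records")
    return sum(classify_rit(r, threshold) == "SIT" for r in records) / len(records)


def metaprofile(
    genes: Sequence[CodingGene],
    rrt: RRTTable,
    max_pos: int,
    smooth: int = 1,
) -> list[tuple[int, float, int]]:
    """Positional mean translation speed (inverse RRT) across genes.

    For each codon position p in 2..max_pos, averages 1/RRT over all genes
    whose sense region contains p; the per-position gene count n is
    non-increasing in p as shorter genes drop out. ``smooth`` applies a
    centered moving average of that odd width (1 = no smoothing), truncated
    at the profile edges.
    """
    if max_pos < 2:
        raise ValueError("max_pos must be >= 2")
    if smooth < 1 or smooth % 2 == 0:
        raise ValueError("smooth must be a positive odd integer")
    sums = np.zeros(max_pos + 1)
    counts = np.zeros(max_pos + 1, dtype=int)
    for gene in genes:
        profile = speed_profile(gene, rrt)
        upto = min(len(profile), max_pos)  # position upto = index upto-1
        if upto < 2:
            continue
        sums[2 : upto + 1] += 1.0 / profile[1:upto]
        counts[2 : upto + 1] += 1
    positions = [p for p in range(2, max_pos + 1) if counts[p] > 0]
    values = np.array([sums[p] / counts[p] for p in positions])
    if smooth > 1 and len(values):
        kernel = np.ones(smooth)
        values = np.convolve(values, kernel, mode="same") / np.convolve(
            np.ones_like(values), kernel, mode="same"
        )
    return [(p, float(v), int(counts[p])) for p, v in zip(positions, values)]


def write_rit_records(records: Sequence[RITRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\twindow\tend\trit\tclass\tn_numerator\tn_denominator\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.window}\t{r.end}\t{r.rit:.6f}\t"
                f"{classify_rit(r)}\t{r.n_numerator}\t{r.n_denominator}\n"
            )


def write_metaprofile(profile: Sequence[tuple[int, float, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tmean_inverse_rrt\tn\n")
        for pos, value, n in profile:
            fh.write(f"{pos}\t{value:.6f}\t{n}\n")
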