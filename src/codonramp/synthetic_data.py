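"""Synthetic inputs with the statistical structure the analyses assume.

The genome generator embodies a minimal *young-terminus turnover* model:
amino acids are drawn from a fixed composition, and within each amino acid
the body of a gene chooses codons under a one-parameter Boltzmann-style
selection against slow codons,

    P(codon c | aa) ∝ exp(-s · RRT(c)),

while a configurable terminal block of a gene is, with probability tau,
"young": its codons are drawn *uniformly* among synonyms, as if the
terminus formed recently from de novo sequence that selection has not yet
cleaned up. Because both per-codon distributions are known, the expected
terminal slowdown is available in closed form — for a turnover block
matching the analysis window,

    delta_expected = 100 · tau · (E_uniform[RRT] / E_selected[RRT] - 1)  (%)

— and the generator also records per-gene, per-position draw modes so the
exact expectation can be computed for any window. That makes parameter
recovery testable: the pipeline's measured slowdown must match what was
injected.

A companion generator emits BLAST-like hit tables with controlled
terminal-homology geometry (one homolog per species whose alignment block
starts some distance into the protein), plus gene-level expression/density
tables coupled to each gene's terminal selection state.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .conservation import BlastHSP
from .genetic_code import AA_TO_CODONS, AMINO_ACIDS, SENSE_CODONS
from .io_formats import CodingGene, GeneValueTable, RRTTable

STOPS = ("TAA", "TAG", "TGA")

#: study conditions emulated by the default model: a ~1.2% encoded slowdown
#: over the first 40 codons, and a ~0.19% slowdown over the last 100
DEFAULT_DELTA_5P_PCT = 1.2
DEFAULT_DELTA_3P_PCT = 0.19


def gen_rrt_table(seed: int = 0, sigma: float = 0.28) -> RRTTable:
    """A synthetic codon -> residence-time table (stand-in for measured RRTs).

    Values are lognormal around 1 with a ~3-fold range between the fastest
    and slowest codons at the default spread, the dynamic range reported
    for real per-codon residence times. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    values = np.exp(rng.normal(0.0, sigma, size=len(SENSE_CODONS)))
    values /= values.mean()
    return RRTTable(dict(zip(SENSE_CODONS, values.tolist())))


# --- codon-choice distributions -------------------------------------------


def _aa_weight_vector(aa_weights: Mapping[str, float] | None) -> np.ndarray:
    if aa_weights is None:
        return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    w = np.array([float(aa_weights.get(a, 0.0)) for a in AMINO_ACIDS])
    if w.sum() <= 0:
        raise ValueError("amino-acid weights must sum to a positive value")
    return w / w.sum()


def _codon_distributions(
    rrt: RRTTable, selection_s: float
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Per amino acid: synonym codon array, selected probs, uniform probs."""
    codon_arrays, p_sel, p_unif = [], [], []
    for aa in AMINO_ACIDS:
        codons = np.array(AA_TO_CODONS[aa])
        rrts = np.array([rrt[c] for c in codons])
        weights = np.exp(-selection_s * rrts)
        codon_arrays.append(codons)
        p_sel.append(weights / weights.sum())
        p_unif.append(np.full(len(codons), 1.0 / len(codons)))
    return codon_arrays, p_sel, p_unif


def expected_rrt(
    rrt: RRTTable,
    selection_s: float,
    aa_weights: Mapping[str, float] | None = None,
) -> float:
    """E[RRT] of one codon drawn under selection strength s."""
    w = _aa_weight_vector(aa_weights)
    codons, p_sel, _ = _codon_distributions(rrt, selection_s)
    per_aa = np.array(
        [float(np.dot(p, [rrt[c] for c in cs])) for cs, p in zip(codons, p_sel)]
    )
    return float(np.dot(w, per_aa))


def calibrate_selection(
    rrt: RRTTable,
    target_delta_pct: float,
    aa_weights: Mapping[str, float] | None = None,
) -> float:
    """Selection strength s such that a fully-young terminus is
    ``target_delta_pct`` percent slower than the selected body."""
    if target_delta_pct <= 0:
        raise ValueError("target slowdown must be positive")
    e_unif = expected_rrt(rrt, 0.0, aa_weights)

    def gap(s: float) -> float:
        return 100.0 * (e_unif / expected_rrt(rrt, s, aa_weights) - 1.0) - target_delta_pct

    return float(brentq(gap, 1e-9, 60.0))


@dataclass(frozen=True)
class SpandrelModel:
    """Parameters of the young-terminus turnover genome model.

    ``turnover_prob``/``turnover_len`` control the 5' young block (codon
    positions 2..K+1); the 3' block (last K codons before the stop) has its
    own probability and length. Gene lengths are total codon counts
    including the stop (minimum 101 = the 100-aa analysis floor).
    """

    n_genes: int
    selection_s: float = 1.0
    turnover_prob: float = 1.0
    turnover_len: int = 40
    turnover_prob_3p: float = 0.0
    turnover_len_3p: int = 100
    seed: int = 0
    length_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None
    aa_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.selection_s < 0:
            raise ValueError("selection_s must be >= 0")
        for tau in (self.turnover_prob, self.turnover_prob_3p):
            if not 0.0 <= tau <= 1.0:
                raise ValueError("turnover probabilities must lie in [0, 1]")

    def sample_lengths(self, rng: np.random.Generator) -> np.ndarray:
        if self.length_dist is not None:
            lengths = np.asarray(self.length_dist(rng, self.n_genes), dtype=int)
        else:
            lengths = rng.integers(101, 601, size=self.n_genes)
        if lengths.min() < 101:
            raise ValueError("gene lengths must be >= 101 codons")
        return lengths


def _joint_terminal_calibration(
    rrt: RRTTable,
    delta_5p_pct: float,
    delta_3p_pct: float,
    turnover_prob: float,
    turnover_len: int,
    window_3p: int,
    length_dist=None,
    aa_weights=None,
    n_length_sample: int = 2000,
) -> tuple[float, float]:
    """Solve for (selection_s, tau3) so the expected measured first-40 and
    last-``window_3p`` slowdowns hit their targets simultaneously.

    Works on the young-codon *fractions* of each statistic's numerator and
    denominator (which depend only on gene length and the turnover flags,
    not on s), then expresses both expectations as functions of the
    per-codon RRT ratio r = E_uniform/E_selected and tau3, and solves the
    2-D system by nested root finding. Fractions are averaged over a fixed
    deterministic sample of the model's length distribution.
    """
    rng = np.random.default_rng(12345)
    if length_dist is not None:
        lengths = np.asarray(length_dist(rng, n_length_sample), dtype=int)
    else:
        lengths = rng.integers(101, 601, size=n_length_sample)

    w5 = 40  # analysis window at the 5' end

    def mask_fracs(n_codons: int, t5: bool, t3: bool):
        """Young fractions (num, den) of the 5' and 3' statistics."""
        n_aa = n_codons - 2
        mask = np.zeros(n_aa, dtype=bool)
        if t5:
            mask[: min(turnover_len, n_aa)] = True
        if t3:
            mask[max(0, n_aa - window_3p):] = True
        f5 = (mask[: w5 - 1].mean(), mask[w5 - 1 :].mean())
        if n_aa >= window_3p + 1:
            f3 = (mask[n_aa - window_3p :].mean(), mask[: n_aa - window_3p].mean())
        else:
            f3 = None
        return f5, f3

    flag_states = [(t5, t3) for t5 in (False, True) for t3 in (False, True)]
    per_gene = [
        {flags: mask_fracs(int(n), *flags) for flags in flag_states}
        for n in lengths
    ]

    def expected_pcts(r: float, tau3: float) -> tuple[float, float]:
        def ratio(frac_pair):
            a_num, a_den = frac_pair
            return (a_num * r + 1 - a_num) / (a_den * r + 1 - a_den) - 1.0

        five, three = [], []
        for variants in per_gene:
            e5 = e3 = 0.0
            has3 = False
            for (t5, t3), (f5, f3) in variants.items():
                p = (turnover_prob if t5 else 1 - turnover_prob) * (
                    tau3 if t3 else 1 - tau3
                )
                e5 += p * ratio(f5)
                if f3 is not None:
                    has3 = True
                    e3 += p * ratio(f3)
            five.append(e5)
            if has3:
                three.append(e3)
        return 100.0 * float(np.mean(five)), 100.0 * float(np.mean(three))

    def r_for(tau3: float) -> float:
        return brentq(
            lambda r: expected_pcts(r, tau3)[0] - delta_5p_pct, 1.0 + 1e-9, 3.0
        )

    def gap3(tau3: float) -> float:
        return expected_pcts(r_for(tau3), tau3)[1] - delta_3p_pct

    tau3 = brentq(gap3, 0.0, 1.0)
    r_target = r_for(tau3)
    e_unif = expected_rrt(rrt, 0.0, aa_weights)
    s = brentq(
        lambda s: e_unif / expected_rrt(rrt, s, aa_weights) - r_target,
        1e-9,
        60.0,
    )
    return float(s), float(tau3)


def yeastlike_model(
    rrt: RRTTable,
    n_genes: int,
    seed: int = 0,
    delta_5p_pct: float = DEFAULT_DELTA_5P_PCT,
    delta_3p_pct: float = DEFAULT_DELTA_3P_PCT,
    turnover_prob: float = 1.0,
    **overrides,
) -> SpandrelModel:
    """The default study conditions: young terminal blocks sized so the
    *measured* first-40 slowdown is expected to be ``delta_5p_pct`` and the
    measured last-100 slowdown ``delta_3p_pct``.

    The two ends contaminate each other's statistics — each statistic's
    denominator ("rest of the gene") contains the other end's young block —
    so the per-codon young excess (via the selection strength s) and the 3'
    young-gene fraction tau3 are calibrated *jointly* against the exact
    expected window/body ratios, averaged over the model's gene-length
    distribution.
    """
    s, tau3 = _joint_terminal_calibration(
        rrt,
        delta_5p_pct,
        delta_3p_pct,
        turnover_prob=turnover_prob,
        turnover_len=40,
        window_3p=100,
        length_dist=overrides.get("length_dist"),
        aa_weights=overrides.get("aa_weights"),
    )
    return SpandrelModel(
        n_genes=n_genes,
        selection_s=s,
        turnover_prob=turnover_prob,
        turnover_len=40,
        turnover_prob_3p=tau3,
        turnover_len_3p=100,
        seed=seed,
        **overrides,
    )


@dataclass
class GenomeTruth:
    """What the generator actually did, for parameter-recovery checks."""

    model: SpandrelModel
    e_uniform: float
    e_selected: float
    delta_expected_pct: float
    gene_ids: list[str] = field(default_factory=list)
    turned_over_5p: dict[str, bool] = field(default_factory=dict)
    turned_over_3p: dict[str, bool] = field(default_factory=dict)
    expected_rit: dict[str, float] = field(default_factory=dict)
    #: per gene: bool array over sense positions 2..N-1, True = uniform draw
    uniform_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def expected_slowdown_pct(self, window: int, end: str = "five_prime") -> float:
        """Exact expected mean window/body RRT ratio for any analysis window,
        from the recorded per-position draw modes."""
        ratios = []
        for gene_id in self.gene_ids:
            mask = self.uniform_masks[gene_id]
            n_aa = len(mask)  # sense positions 2..N-1
            n_sense = n_aa + 1
            if n_sense < window + 2:
                continue
            if end == "five_prime":
                num_mask, den_mask = mask[: window - 1], mask[window - 1 :]
            elif end == "three_prime":
                num_mask = mask[n_aa - window :]
                den_mask = mask[: n_aa - window]
            else:
                raise ValueError(f"unknown end {end!r}")
            e_num = np.where(num_mask, self.e_uniform, self.e_selected).mean()
            e_den = np.where(den_mask, self.e_uniform, self.e_selected).mean()
            ratios.append(e_num / e_den - 1.0)
        if not ratios:
            raise ValueError("no gene long enough for this window")
        return 100.0 * float(np.mean(ratios))

    def to_jsonable(self) -> dict:
        return {
            "n_genes": self.model.n_genes,
            "selection_s": self.model.selection_s,
            "turnover_prob": self.model.turnover_prob,
            "turnover_len": self.model.turnover_len,
            "turnover_prob_3p": self.model.turnover_prob_3p,
            "turnover_len_3p": self.model.turnover_len_3p,
            "seed": self.model.seed,
            "e_uniform": self.e_uniform,
            "e_selected": self.e_selected,
            "delta_expected_pct": self.delta_expected_pct,
            "turned_over_5p": self.turned_over_5p,
            "turned_over_3p": self.turned_over_3p,
        }


def gen_genome(
    model: SpandrelModel, rrt: RRTTable
) -> tuple[list[CodingGene], GenomeTruth]:
    """Sample a genome under the turnover model; returns genes + truth.

    Every gene starts with ATG, ends with a random stop codon, and draws its
    internal codons per amino acid from the selected distribution — except
    inside young terminal blocks, where synonyms are equiprobable.
    """
    rng = np.random.default_rng(model.seed)
    lengths = model.sample_lengths(rng)
    n_aa_per_gene = lengths - 2  # sense positions 2..N-1
    total = int(n_aa_per_gene.sum())

    w = _aa_weight_vector(model.aa_weights)
    aa_idx = rng.choice(len(AMINO_ACIDS), size=total, p=w)

    t5 = rng.random(model.n_genes) < model.turnover_prob
    t3 = rng.random(model.n_genes) < model.turnover_prob_3p

    uniform_mask = np.zeros(total, dtype=bool)
    offsets = np.concatenate([[0], np.cumsum(n_aa_per_gene)])
    for g in range(model.n_genes):
        lo, hi = offsets[g], offsets[g + 1]
        n_aa = hi - lo
        if t5[g]:
            uniform_mask[lo : lo + min(model.turnover_len, n_aa)] = True
        if t3[g]:
            uniform_mask[hi - min(model.turnover_len_3p, n_aa) : hi] = True

    codon_arrays, p_sel, p_unif = _codon_distributions(rrt, model.selection_s)
    codons = np.empty(total, dtype="<U3")
    for a in range(len(AMINO_ACIDS)):
        for young in (False, True):
            sel = (aa_idx == a) & (uniform_mask == young)
            k = int(sel.sum())
            if k == 0:
                continue
            probs = p_unif[a] if young else p_sel[a]
            picks = rng.choice(len(codon_arrays[a]), size=k, p=probs)
            codons[sel] = codon_arrays[a][picks]

    stops = rng.choice(STOPS, size=model.n_genes)

    e_unif = expected_rrt(rrt, 0.0, model.aa_weights)
    e_sel = expected_rrt(rrt, model.selection_s, model.aa_weights)
    log2_ratio = float(np.log2(e_unif / e_sel))

    genes: list[CodingGene] = []
    truth = GenomeTruth(
        model=model,
        e_uniform=e_unif,
        e_selected=e_sel,
        delta_expected_pct=100.0 * model.turnover_prob * (e_unif / e_sel - 1.0),
    )
    for g in range(model.n_genes):
        gene_id = f"g{g:05d}"
        lo, hi = offsets[g], offsets[g + 1]
        gene = CodingGene(
            gene_id, ("ATG",) + tuple(codons[lo:hi]) + (stops[g],)
        )
        genes.append(gene)
        truth.gene_ids.append(gene_id)
        truth.turned_over_5p[gene_id] = bool(t5[g])
        truth.turned_over_3p[gene_id] = bool(t3[g])
        truth.expected_rit[gene_id] = log2_ratio if t5[g] else 0.0
        truth.uniform_masks[gene_id] = uniform_mask[lo:hi]
    return genes, truth


# --- BLAST hit geometry ----------------------------------------------------


@dataclass(frozen=True)
class HomologyModel:
    """Controls the per-species homology-block geometry.

    Each species contributes one subject protein per query half. Its
    alignment block on the first half starts ``offset`` residues in
    (terminal loss at the N-terminus) and runs to the half end; on the
    second half it starts at residue 1 and stops ``trim`` residues short of
    the protein end (terminal loss at the C-terminus). Bit scores are
    sampled around ``region_bits_mean``.
    """

    n_species: int = 60
    terminal_loss_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None
    cterm_loss_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None
    region_bits_mean: float = 400.0
    region_bits_sd: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")

    def sample_offsets(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.terminal_loss_dist is not None:
            return np.asarray(self.terminal_loss_dist(rng, n), dtype=int)
        return rng.geometric(1.0 / 20.0, size=n)  # mean ~20 aa lost

    def sample_trims(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.cterm_loss_dist is not None:
            return np.asarray(self.cterm_loss_dist(rng, n), dtype=int)
        return rng.geometric(1.0 / 15.0, size=n) - 1  # mean ~14 aa lost


def _interval_cover(
    start: int, end: int, window: tuple[int, int]
) -> int:
    return max(0, min(end, window[1]) - max(start, window[0]) + 1)


def gen_blast_hits(
    proteins: Sequence[tuple[str, int]],
    model: HomologyModel,
    region_bits: float = 200.0,
    qual_bits: float = 50.0,
) -> tuple[list[BlastHSP], list[BlastHSP], dict[str, dict[str, float]]]:
    """Per-half hit lists plus exact truth coverages per scoring window.

    Truth is computed by the generator's own single-interval arithmetic
    (mean over qualified species of the window positions each block covers),
    independently of :func:`codonramp.conservation.conservation_score`.
    """
    rng = np.random.default_rng(model.seed)
    hits_first: list[BlastHSP] = []
    hits_second: list[BlastHSP] = []
    truth: dict[str, dict[str, float]] = {}
    species = [f"species_{i:03d}" for i in range(model.n_species)]
    for query_id, length in proteins:
        if length < 100:
            raise ValueError(f"{query_id}: proteins must be >= 100 aa")
        half1 = length // 2
        half2 = length - half1
        offsets = np.clip(model.sample_offsets(rng, model.n_species), 1, half1)
        trims = np.clip(model.sample_trims(rng, model.n_species), 0, half2 - 1)
        bits1 = rng.normal(model.region_bits_mean, model.region_bits_sd,
                           model.n_species)
        bits2 = rng.normal(model.region_bits_mean, model.region_bits_sd,
                           model.n_species)
        bits1 = np.maximum(bits1, qual_bits + 1.0)
        bits2 = np.maximum(bits2, qual_bits + 1.0)
        n_window = (1, 40)
        mid_window = (half1 + 1, half1 + 40)
        c_window = (length - 39, length)
        cov_n, cov_mid, cov_c = [], [], []
        for i, sp in enumerate(species):
            subject = f"{sp}|{query_id}"
            start1, end1 = int(offsets[i]), half1
            hits_first.append(
                BlastHSP(query_id, subject, sp, float(bits1[i]),
                         start1, end1, half="first")
            )
            # second-half hits are on half-local coordinates
            start2_local, end2_local = 1, int(half2 - trims[i])
            hits_second.append(
                BlastHSP(query_id, subject, sp, float(bits2[i]),
                         start2_local, end2_local, half="second")
            )
            cov_n.append(
                _interval_cover(start1, end1, n_window)
                if bits1[i] >= region_bits else 0
            )
            start2, end2 = half1 + start2_local, half1 + end2_local
            strong2 = bits2[i] >= region_bits
            cov_mid.append(_interval_cover(start2, end2, mid_window) if strong2 else 0)
            cov_c.append(_interval_cover(start2, end2, c_window) if strong2 else 0)
        truth[query_id] = {
            "n": float(np.mean(cov_n)),
            "mid": float(np.mean(cov_mid)),
            "c": float(np.mean(cov_c)),
            "n_species": float(model.n_species),
        }
    return hits_first, hits_second, truth


# --- correlated gene-level values -----------------------------------------


def gen_gene_values(
    truth: GenomeTruth,
    kind: str = "read_count",
    coupling: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    baseline: float = 5.0,
    min_count: int = 10,
) -> GeneValueTable:
    """Gene-level values coupled to each gene's terminal selection state.

    The per-gene covariate is the *negated* expected terminal slowdown
    (young-terminus genes score low), so positive coupling makes
    well-selected genes high-expression, the structure the grouping and
    correlation analyses expect. Read counts are exp-transformed and
    rounded to integers, then the standard < ``min_count`` floor applies;
    densities are left on the linear scale, clipped at 0. Note the
    covariate only varies between genes when 0 < turnover_prob < 1.
    """
    rng = np.random.default_rng(seed)
    cov = np.array([-truth.expected_rit[g] for g in truth.gene_ids])
    spread = cov.std()
    if spread > 0:
        cov = (cov - cov.mean()) / spread
    raw = coupling * cov + rng.normal(0.0, noise_sd, size=len(cov))
    if kind == "read_count":
        counts = np.round(np.exp(baseline + raw)).astype(int)
        values = {
            g: float(c)
            for g, c in zip(truth.gene_ids, counts)
            if c >= min_count
        }
        return GeneValueTable(values, kind="read_count", min_count=min_count)
    if kind == "ribosome_density":
        dens = np.maximum(1.0 + raw, 0.0)
        return GeneValueTable(
            dict(zip(truth.gene_ids, dens.tolist())), kind="ribosome_density"
        )
    return GeneValueTable(dict(zip(truth.gene_ids, raw.tolist())), kind="other")


# --- writers (the exact formats io_formats reads) -------------------------


def write_blast_tabular(hits: Sequence[BlastHSP], path: str | Path) -> None:
    """Emit outfmt-6-style rows; alignment-derived columns are synthesized."""
    with open(path, "w") as fh:
        for h in hits:
            aln_len = h.query_end - h.query_start + 1
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t50.0\t{aln_len}\t0\t0\t"
                f"{h.query_start}\t{h.query_end}\t1\t{aln_len}\t1e-50\t"
                f"{h.bit_score:.1f}\n"
            )


def write_species_map(hits: Sequence[BlastHSP], path: str | Path) -> None:
    pairs = sorted({(h.subject_id, h.species) for h in hits})
    with open(path, "w") as fh:
        for subject, sp in pairs:
            fh.write(f"{subject}\t{sp}\n")


def write_truth_json(truth: GenomeTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1)
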