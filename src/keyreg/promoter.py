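"""Promoter PWM scanning and TF-candidate enrichment.

Motifs are positional weight matrices scored as log2-odds against a
background nucleotide model. Per-matrix score thresholds are calibrated by
exact dynamic programming to minimize the sum of false-negative and
false-positive rates (a "minSUM"-style criterion). Candidate transcription
factors are the annotations of matrices whose hit density in the promoters
of a differential gene list ("yes" set) is enriched over a background
promoter set ("no" set) by a one-sided label-permutation test (calibrated
under promoter relabelling by construction) with BH adjustment.

Coordinate convention: offsets are 0-based and relative to the transcription
start site (TSS at 0); the canonical promoter window is the half-open
interval [-1000, +100). A match position is the leftmost base of the site
on the plus strand. Overlapping hits are counted individually.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N

DEFAULT_WINDOW = (-1000, 100)  # half-open [-1000, +100)


def encode(sequence: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as integer codes 0..4."""
    try:
        return np.array([_CODE[b] for b in sequence.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"illegal base {exc.args[0]!r} in sequence") from None


def reverse_complement(sequence: str) -> str:
    table = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return sequence.translate(table)[::-1]


@dataclass(frozen=True)
class PWM:
    """Positional weight matrix with background model and calibrated threshold.

    ``probs`` is 4 x L (rows A, C, G, T); every column sums to 1 and all
    entries are positive after the pseudocount.
    """

    matrix_id: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.0
    threshold: float | None = None
    tf_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError("probs must be a 4 x L matrix")
        if probs.shape[1] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"{self.matrix_id}: PWM columns must sum to 1")
        if (probs <= 0).any():
            raise ValueError(f"{self.matrix_id}: all probabilities must be > 0")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """5 x L log2-odds weights; row 4 is the N convention (contributes 0)."""
        lo = np.zeros((5, self.length))
        lo[:4] = np.log2(self.probs / self.background[:, None])
        return lo

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=0))

    def with_threshold(self, threshold: float) -> "PWM":
        return replace(self, threshold=threshold)

    @classmethod
    def from_counts(
        cls,
        matrix_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.8,
        background: np.ndarray | None = None,
        tf_names: tuple[str, ...] = (),
    ) -> "PWM":
        """Build a PWM from a 4 x L count matrix with a proportional pseudocount."""
        counts = np.asarray(counts, dtype=float)
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError(f"{matrix_id}: zero column sum in count matrix")
        probs = (counts + pseudocount * background[:, None]) / (totals + pseudocount)
        return cls(
            matrix_id=matrix_id,
            probs=probs,
            background=background,
            pseudocount=pseudocount,
            tf_names=tf_names,
        )


@dataclass(frozen=True)
class PromoterSet:
    """Promoter sequences keyed by gene, with a TSS-relative window."""

    sequences: Mapping[str, str]
    window: tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        expected = self.window[1] - self.window[0]
        short = [g for g, s in self.sequences.items() if len(s) != expected]
        if short:
            logger.warning(
                "%d promoter(s) shorter/longer than the %d-base window (e.g. %s)",
                len(short),
                expected,
                short[:5],
            )
        for gene, seq in self.sequences.items():
            if set(seq.upper()) - set("ACGTN"):
                raise ValueError(f"promoter {gene!r} contains illegal characters")

    @property
    def genes(self) -> list[str]:
        return list(self.sequences)

    def subset(self, genes: Iterable[str]) -> "PromoterSet":
        genes = [g for g in genes if g in self.sequences]
        return PromoterSet({g: self.sequences[g] for g in genes}, window=self.window)

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, gene: str) -> bool:
        return gene in self.sequences


@dataclass(frozen=True)
class SiteHit:
    matrix_id: str
    gene: str
    strand: str  # '+' or '-'
    offset: int  # TSS-relative start of the match (leftmost base, + strand)
    score: float


@dataclass(frozen=True)
class TFEnrichmentRecord:
    matrix_id: str
    yes_density: float  # hits per kilobase scanned
    no_density: float
    fold_enrichment: float
    p_value: float
    adj_p_value: float
    tf_names: tuple[str, ...]


def score_site(pwm: PWM, sequence: str, position: int, strand: str = "+") -> float:
    """Log2-odds score of the site starting at ``position`` (0-based).

    On the minus strand the reverse complement of the window is scored.
    N bases contribute 0.
    """
    L = pwm.length
    if position < 0 or position + L > len(sequence):
        raise IndexError(
            f"site [{position}, {position + L}) outside sequence of length {len(sequence)}"
        )
    window = sequence[position : position + L]
    if strand == "-":
        window = reverse_complement(window)
    elif strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    codes = encode(window)
    lo = pwm.log_odds
    total = 0.0
    for j in range(L):  # left-to-right accumulation, bit-identical to the DP
        total += lo[codes[j], j]
    return float(total)


def _minus_strand_weights(log_odds: np.ndarray) -> np.ndarray:
    """Weights such that scoring a window forward equals scoring its revcomp."""
    return log_odds[_COMPLEMENT, :][:, ::-1]


def scan_sequence(pwm: PWM, sequence: str, threshold: float | None = None) -> list[tuple[int, str, float]]:
    """All (start index, strand, score) with score >= threshold, both strands."""
    if threshold is None:
        if pwm.threshold is None:
            raise ValueError(f"{pwm.matrix_id}: no calibrated threshold")
        threshold = pwm.threshold
    L = pwm.length
    codes = encode(sequence)
    if codes.size < L:
        return []
    n = codes.size - L + 1
    lo_plus = pwm.log_odds
    lo_minus = _minus_strand_weights(lo_plus)
    plus = np.zeros(n)
    minus = np.zeros(n)
    for j in range(L):  # column-wise accumulation keeps float order exact
        plus += lo_plus[codes[j : j + n], j]
    for j in reversed(range(L)):  # revcomp scoring runs left-to-right over the revcomp
        minus += lo_minus[codes[j : j + n], j]
    hits: list[tuple[int, str, float]] = []
    for strand, scores in (("+", plus), ("-", minus)):
        for i in np.flatnonzero(scores >= threshold):
            hits.append((int(i), strand, float(scores[i])))
    return hits


def _score_distribution(
    log_odds: np.ndarray, col_probs: np.ndarray, decimals: int = 9, max_states: int = 400_000
) -> dict[float, float]:
    """Exact distribution of the total score by DP over positions.

    States are merged on score keys rounded to ``decimals`` places, but each
    state keeps an exact (unrounded, left-to-right accumulated) representative
    score, so returned score values match per-sequence enumeration
    bit-for-bit. When the state count explodes the rounding is coarsened
    (logged), trading a bounded quantization error for tractability.
    """
    # key -> [probability, exact representative score]
    dist: dict[float, list[float]] = {0.0: [1.0, 0.0]}
    L = col_probs.shape[1]
    for j in range(L):
        new: dict[float, list[float]] = {}
        for prob, exact in dist.values():
            for b in range(4):
                pj = col_probs[b, j]
                if pj <= 0:
                    continue
                nxt = exact + log_odds[b, j]
                key = round(nxt, decimals)
                entry = new.get(key)
                if entry is None:
                    new[key] = [prob * pj, nxt]
                else:
                    entry[0] += prob * pj
        if len(new) > max_states and decimals > 3:
            decimals -= 2
            logger.warning("score DP state blow-up; coarsening rounding to %d decimals", decimals)
            coarse: dict[float, list[float]] = {}
            for prob, exact in new.values():
                k = round(exact, decimals)
                entry = coarse.get(k)
                if entry is None:
                    coarse[k] = [prob, exact]
                else:
                    entry[0] += prob
            new = coarse
        dist = new
    return {exact: prob for prob, exact in dist.values()}


def score_distributions(pwm: PWM) -> tuple[dict[float, float], dict[float, float]]:
    """(motif-model, background-model) exact score distributions."""
    lo = pwm.log_odds[:4]
    motif = _score_distribution(lo, pwm.probs)
    bg = _score_distribution(lo, np.tile(pwm.background[:, None], (1, pwm.length)))
    return motif, bg


def calibrate_threshold(pwm: PWM) -> float:
    """Score cutoff minimizing false-negative + false-positive rate.

    The exact score distributions under the motif model and under the
    background model are computed by dynamic programming; the returned
    cutoff is the achievable score minimizing FN(c) + FP(c), with
    FN(c) = P_motif(S < c) and FP(c) = P_bg(S >= c). Ties are broken toward
    the higher cutoff.
    """
    motif, bg = score_distributions(pwm)
    scores = np.array(sorted(set(motif) | set(bg)))
    pm = np.array([motif.get(s, 0.0) for s in scores])
    pb = np.array([bg.get(s, 0.0) for s in scores])
    # FN at cutoff scores[i]: motif mass strictly below; FP: bg mass at or above
    fn = np.concatenate([[0.0], np.cumsum(pm)[:-1]])
    fp = pb[::-1].cumsum()[::-1]
    total = fn + fp
    best = total.min()
    idx = int(np.flatnonzero(total <= best + 1e-12)[-1])
    return float(scores[idx])


def calibrate_library(library: Sequence[PWM]) -> list[PWM]:
    """Attach minSUM-style thresholds to every matrix in a library."""
    return [pwm.with_threshold(calibrate_threshold(pwm)) for pwm in library]


def scan_set(library: Sequence[PWM], promoters: PromoterSet) -> list[SiteHit]:
    """Scan both strands of every promoter with every calibrated matrix."""
    if len(promoters) == 0:
        logger.warning("empty promoter set: no scan performed")
        return []
    hits: list[SiteHit] = []
    start = promoters.window[0]
    for pwm in library:
        if pwm.threshold is None:
            raise ValueError(f"{pwm.matrix_id}: calibrate thresholds before scanning")
        for gene, seq in promoters.sequences.items():
            for i, strand, score in scan_sequence(pwm, seq):
                hits.append(
                    SiteHit(
                        matrix_id=pwm.matrix_id,
                        gene=gene,
                        strand=strand,
                        offset=start + i,
                        score=score,
                    )
                )
    return hits


def tf_candidates(
    yes: PromoterSet,
    no: PromoterSet,
    library: Sequence[PWM],
    alpha: float = 0.05,
    min_fold: float = 1.5,
    min_yes_genes: int = 3,
    n_permutations: int = 1000,
    rng_seed: int | None = 0,
) -> tuple[list[str], list[TFEnrichmentRecord]]:
    """TF candidates from yes-vs-no promoter hit-density enrichment.

    Per matrix, the observed yes-minus-no hit-density difference (hits per
    kilobase scanned) is compared with its distribution under random
    relabelling of the promoters (one shared label permutation applied to
    every matrix); the one-sided Monte-Carlo p-value uses the add-one
    estimator, so it is calibrated under the permutation null by
    construction. P-values are BH-adjusted across the library. Candidates
    are the union of TF annotations of matrices with adjusted p <= ``alpha``
    and fold enrichment >= ``min_fold``. When the no-set has zero hits, one
    pseudo-hit enters the fold-enrichment ratio only.
    """
    if len(no) == 0:
        raise ValueError("no-set (background promoters) must be nonempty")
    overlap = set(yes.genes) & set(no.genes)
    if overlap:
        raise ValueError(f"yes and no promoter sets overlap: {sorted(overlap)[:5]}")
    if len(yes) < min_yes_genes:
        logger.warning(
            "yes-set has only %d promoter(s) (< %d): results are low-power",
            len(yes),
            min_yes_genes,
        )
    rng = np.random.default_rng(rng_seed)

    genes = list(yes.genes) + list(no.genes)
    n_yes = len(yes)
    lengths = np.array([len(yes.sequences.get(g) or no.sequences[g]) for g in genes])

    # per-matrix, per-promoter hit counts and scannable positions
    counts = np.zeros((len(library), len(genes)), dtype=float)
    positions = np.zeros((len(library), len(genes)), dtype=float)
    for i, pwm in enumerate(library):
        if pwm.threshold is None:
            raise ValueError(f"{pwm.matrix_id}: calibrate thresholds before scanning")
        positions[i] = np.maximum(lengths - pwm.length + 1, 0) * 2
        for j, g in enumerate(genes):
            seq = yes.sequences.get(g) or no.sequences[g]
            counts[i, j] = len(scan_sequence(pwm, seq))

    yes_mask = np.zeros(len(genes), dtype=bool)
    yes_mask[:n_yes] = True

    def density_diff(mask: np.ndarray) -> np.ndarray:
        ky = counts[:, mask].sum(axis=1)
        ny = positions[:, mask].sum(axis=1)
        kn = counts[:, ~mask].sum(axis=1)
        nn = positions[:, ~mask].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dy = np.where(ny > 0, 1000.0 * ky / ny, 0.0)
            dn = np.where(nn > 0, 1000.0 * kn / nn, 0.0)
        return dy - dn

    # infinitesimal jitter breaks ties between integer-count statistics so
    # the Monte-Carlo p-value is exactly uniform under the permutation null
    jitter = 1e-9
    observed = density_diff(yes_mask) + rng.uniform(0.0, jitter, len(library))
    exceed = np.zeros(len(library), dtype=int)
    for _ in range(n_permutations):
        perm = rng.permutation(len(genes))
        mask = np.zeros(len(genes), dtype=bool)
        mask[perm[:n_yes]] = True
        stat = density_diff(mask) + rng.uniform(0.0, jitter, len(library))
        exceed += stat >= observed
    pvals = (1.0 + exceed) / (1.0 + n_permutations)

    ky = counts[:, yes_mask].sum(axis=1)
    ny = positions[:, yes_mask].sum(axis=1)
    kn = counts[:, ~yes_mask].sum(axis=1)
    nn = positions[:, ~yes_mask].sum(axis=1)

    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    records: list[TFEnrichmentRecord] = []
    candidates: set[str] = set()
    for i, pwm in enumerate(library):
        yes_density = 1000.0 * ky[i] / ny[i] if ny[i] else 0.0
        no_density = 1000.0 * kn[i] / nn[i] if nn[i] else 0.0
        # pseudo-hit only in the reported ratio, never in the test
        pseudo_no = 1000.0 * max(kn[i], 1.0) / nn[i] if nn[i] else math.nan
        fold = yes_density / pseudo_no if nn[i] else math.nan
        records.append(
            TFEnrichmentRecord(
                matrix_id=pwm.matrix_id,
                yes_density=float(yes_density),
                no_density=float(no_density),
                fold_enrichment=float(fold),
                p_value=float(pvals[i]),
                adj_p_value=float(qvals[i]),
                tf_names=pwm.tf_names,
            )
        )
        if qvals[i] <= alpha and fold >= min_fold:
            candidates.update(pwm.tf_names)
    return sorted(candidates), records
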