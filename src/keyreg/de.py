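"""Differential-expression calling for transcripts and proteins.

Transcripts: per-gene Welch t-test on replicated log2 ratios between the
high and low populations, Benjamini-Hochberg adjustment, and a fold-change
gate on the group-mean difference.

Proteins: label-free abundance via the exponentially modified protein
abundance index (emPAI), per-replicate normalization to the geometric mean
of observed significant peptide-match counts, a presence filter (detected
in at least two replicates of a population), and a fold-change gate on the
ratio of mean normalized abundances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

Direction = Literal["up", "down"]
Evidence = Literal["transcript", "protein"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Replicated log2-ratio expression values for one population.

    ``values`` is genes x replicates; entries are log2(sample / common
    reference) and may be NaN for missing measurements.
    """

    values: pd.DataFrame
    population: str
    cell_line: str = ""

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError(
                f"population {self.population!r} has {self.values.shape[1]} "
                "replicates; at least 2 are required"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate entity identifiers: {dups}")

    @property
    def entities(self) -> pd.Index:
        return self.values.index

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PeptideCountTable:
    """Observed significant peptide matches per protein per replicate.

    ``observed`` is proteins x replicates (integer counts >= 0);
    ``observable`` gives each protein's count of theoretically observable
    peptides (>= 1).
    """

    observed: pd.DataFrame
    observable: pd.Series
    population: str
    cell_line: str = ""

    def __post_init__(self) -> None:
        if not self.observed.index.equals(self.observable.index):
            raise ValueError("observed and observable must share the protein index")
        if (self.observable < 1).any():
            bad = self.observable.index[self.observable < 1].tolist()
            raise ValueError(f"observable peptide count < 1 for: {bad}")
        arr = self.observed.to_numpy()
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise ValueError("observed counts must be non-negative integers")

    @property
    def proteins(self) -> pd.Index:
        return self.observed.index

    @property
    def n_replicates(self) -> int:
        return self.observed.shape[1]


@dataclass(frozen=True)
class DifferentialEntry:
    """One differentially expressed entity."""

    entity: str
    log2_fold_change: float
    direction: Direction
    evidence: Evidence
    p_value: float | None = None
    adj_p_value: float | None = None
    unbounded: bool = False  # present in one population, absent in the other

    def __post_init__(self) -> None:
        if self.direction == "up" and self.log2_fold_change < 0:
            raise ValueError("direction 'up' inconsistent with negative fold change")
        if self.direction == "down" and self.log2_fold_change > 0:
            raise ValueError("direction 'down' inconsistent with positive fold change")


@dataclass
class DifferentialList:
    """Up- plus down-regulated entities for one cell line and evidence type."""

    cell_line: str
    evidence: Evidence
    entries: list[DifferentialEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.entity for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate entities in differential list")

    @property
    def entities(self) -> set[str]:
        return {e.entity for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def label(self) -> str:
        return f"{self.cell_line}/{self.evidence}"


def de_transcripts(
    high: ExpressionMatrix,
    low: ExpressionMatrix,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
) -> DifferentialList:
    """Call differentially expressed transcripts between two populations.

    A gene is reported when the absolute difference of group means on the
    log2 scale is at least ``log2(fold_threshold)`` and its BH-adjusted
    two-sided Welch t-test p-value is at most ``alpha``.

    Genes with fewer than two finite values in either group are skipped
    (and logged); adjustment is performed across all tested genes.
    """
    if fold_threshold <= 0 or not 0 < alpha <= 1:
        raise ValueError("fold_threshold must be > 0 and alpha in (0, 1]")
    if set(high.entities) != set(low.entities):
        raise ValueError("high and low matrices must share the entity universe")

    lo = low.values.loc[high.entities]
    hi = high.values
    log2_gate = math.log2(fold_threshold)

    hi_arr = hi.to_numpy(dtype=float)
    lo_arr = lo.to_numpy(dtype=float)
    genes: list[str] = []
    diffs: list[float] = []
    pvals: list[float] = []
    skipped: list[str] = []

    complete = np.isfinite(hi_arr).all(axis=1) & np.isfinite(lo_arr).all(axis=1)
    if complete.any():  # vectorized fast path for complete cases
        _, p_vec = stats.ttest_ind(hi_arr[complete], lo_arr[complete], axis=1, equal_var=False)
        d_vec = hi_arr[complete].mean(axis=1) - lo_arr[complete].mean(axis=1)
        for gene, d, p in zip(hi.index[complete], d_vec, p_vec):
            genes.append(gene)
            diffs.append(float(d))
            pvals.append(float(p) if np.isfinite(p) else 1.0)
    for i in np.flatnonzero(~complete):
        gene = hi.index[i]
        h = hi_arr[i][np.isfinite(hi_arr[i])]
        l = lo_arr[i][np.isfinite(lo_arr[i])]
        if h.size < 2 or l.size < 2:
            skipped.append(gene)
            continue
        _, p = stats.ttest_ind(h, l, equal_var=False)
        genes.append(gene)
        diffs.append(float(h.mean() - l.mean()))
        pvals.append(float(p) if np.isfinite(p) else 1.0)

    if skipped:
        logger.warning(
            "%d gene(s) skipped for < 2 finite values in a group (e.g. %s)",
            len(skipped),
            skipped[:5],
        )

    entries: list[DifferentialEntry] = []
    if genes:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for gene, d, p, q in zip(genes, diffs, pvals, qvals):
            if abs(d) >= log2_gate and q <= alpha:
                entries.append(
                    DifferentialEntry(
                        entity=gene,
                        log2_fold_change=d,
                        direction="up" if d > 0 else "down",
                        evidence="transcript",
                        p_value=p,
                        adj_p_value=float(q),
                    )
                )
    return DifferentialList(cell_line=high.cell_line, evidence="transcript", entries=entries)


def empai(observed: float, observable: float) -> float:
    """Exponentially modified protein abundance index: 10^(obs/observable) - 1."""
    if observable < 1:
        raise ValueError(f"observable must be >= 1, got {observable}")
    if observed < 0:
        raise ValueError(f"observed must be >= 0, got {observed}")
    return 10.0 ** (observed / observable) - 1.0


def normalize_abundance(table: PeptideCountTable) -> pd.DataFrame:
    """Per-replicate emPAI normalized to the geometric mean of observed counts.

    For each replicate, every protein's emPAI is divided by the geometric
    mean of observed significant peptide-match counts over proteins detected
    (observed >= 1) in that replicate.
    """
    obs = table.observed.to_numpy(dtype=float)
    observable = table.observable.to_numpy(dtype=float)[:, None]
    raw = 10.0 ** (obs / observable) - 1.0

    out = np.empty_like(raw)
    for j, col in enumerate(table.observed.columns):
        detected = obs[:, j] >= 1
        if not detected.any():
            raise ValueError(
                f"replicate {col!r} has no detected protein; normalizer undefined"
            )
        gm = float(np.exp(np.mean(np.log(obs[detected, j]))))
        out[:, j] = raw[:, j] / gm
    return pd.DataFrame(out, index=table.proteins, columns=table.observed.columns)


def _presence_mask(table: PeptideCountTable, min_replicates: int) -> pd.Series:
    detected = (table.observed >= 1).sum(axis=1)
    return detected >= min_replicates


def de_proteins(
    high: PeptideCountTable,
    low: PeptideCountTable,
    fold_threshold: float = 2.0,
) -> DifferentialList:
    """Call differentially expressed proteins from peptide-count tables.

    Proteins detected in at most one replicate of a population are treated
    as absent from it. Fold change is the ratio of across-replicate mean
    normalized emPAI (high / low); a protein is reported when the ratio is
    >= ``fold_threshold`` or <= 1/``fold_threshold``. Proteins present on one
    side only are reported with an unbounded fold change.
    """
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be > 0")
    if high.n_replicates != 3 or low.n_replicates != 3:
        logger.warning(
            "replicate count != 3 (high=%d, low=%d); applying generalized "
            "'present in >= 2 replicates' rule",
            high.n_replicates,
            low.n_replicates,
        )

    norm_high = normalize_abundance(high)
    norm_low = normalize_abundance(low)
    present_high = _presence_mask(high, 2)
    present_low = _presence_mask(low, 2)

    proteins = sorted(set(high.proteins) | set(low.proteins))
    mean_high = norm_high.mean(axis=1)
    mean_low = norm_low.mean(axis=1)

    entries: list[DifferentialEntry] = []
    for prot in proteins:
        ph = bool(present_high.get(prot, False))
        pl = bool(present_low.get(prot, False))
        if not ph and not pl:
            continue
        if ph and pl:
            ratio = float(mean_high[prot] / mean_low[prot])
            if ratio >= fold_threshold or ratio <= 1.0 / fold_threshold:
                entries.append(
                    DifferentialEntry(
                        entity=prot,
                        log2_fold_change=math.log2(ratio),
                        direction="up" if ratio > 1 else "down",
                        evidence="protein",
                    )
                )
        else:
            # present on one side only: direction from the present side,
            # fold change unbounded rather than pseudo-counted
            entries.append(
                DifferentialEntry(
                    entity=prot,
                    log2_fold_change=math.inf if ph else -math.inf,
                    direction="up" if ph else "down",
                    evidence="protein",
                    unbounded=True,
                )
            )
    return DifferentialList(cell_line=high.cell_line, evidence="protein", entries=entries)


def build_six_lists(
    per_cell_line: Mapping[str, tuple[DifferentialList, DifferentialList]],
) -> list[DifferentialList]:
    """Assemble the {cell line} x {transcript, protein} differential lists.

    Expects exactly three cell lines, each mapped to a (transcript, protein)
    pair; empty lists are tolerated. Returns six lists with unique labels.
    """
    if len(per_cell_line) != 3:
        raise ValueError(f"expected exactly 3 cell lines, got {len(per_cell_line)}")
    out: list[DifferentialList] = []
    for line, (transcripts, proteins) in per_cell_line.items():
        if transcripts.evidence != "transcript" or proteins.evidence != "protein":
            raise ValueError(f"cell line {line!r}: pair must be (transcript, protein)")
        for dl in (transcripts, proteins):
            if dl.cell_line != line:
                raise ValueError(
                    f"list labelled {dl.cell_line!r} supplied under cell line {line!r}"
                )
            out.append(dl)
    labels = [dl.label for dl in out]
    assert len(set(labels)) == 6
    return out
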