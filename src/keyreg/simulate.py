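"""Synthetic study generator with a planted key regulator.

Produces a complete input bundle — directed regulatory network, motif
library, promoter sequences, replicated expression matrices, and peptide
count tables for three cell lines — in which one regulator is planted:
its downstream cascade supplies the differential genes, its binding motif
is embedded in their promoters, and its protein targets carry the planted
abundance fold. Every generator is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .de import ExpressionMatrix, PeptideCountTable
from .mr import RegulatoryNetwork
from .promoter import PWM, PromoterSet

_BASES = np.array(list("ACGT"))

CELL_LINES = ("LINE1", "LINE2", "LINE3")
EVIDENCE = ("transcript", "protein")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_cell_lines: int = 3
    n_replicates: int = 3
    n_genes: int = 100                # gene universe size
    n_network_nodes: int = 80         # regulator + random gene nodes
    edge_prob: float = 0.006          # background edge density (subcritical)
    fanout: int = 5                   # planted cascade branching
    depth: int = 2                    # planted cascade depth (<= radius)
    n_de_genes: int = 20              # planted DE genes per line per evidence
    log2_effect: float = 2.0          # planted transcript shift
    noise_sd: float = 0.2
    protein_fold: float = 3.0         # planted detection-probability fold
    n_proteins: int = 80
    n_motifs: int = 10
    motif_length: int = 12
    plant_prob_de: float = 0.8        # motif planting prob in DE promoters
    plant_prob_bg: float = 0.05
    mutation_prob: float = 0.05       # per-base noise on planted sites
    n_background_promoters: int = 60
    gc_content: float = 0.5
    promoter_window: tuple[int, int] = (-1000, 100)

    def __post_init__(self) -> None:
        for name in (
            "n_cell_lines", "n_replicates", "n_genes", "n_network_nodes",
            "fanout", "depth", "n_de_genes", "n_proteins", "n_motifs",
            "motif_length", "n_background_promoters",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("plant_prob_de", "plant_prob_bg", "mutation_prob", "gc_content"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def cascade_size(self) -> int:
        return sum(self.fanout ** k for k in range(1, self.depth + 1))

    @property
    def promoter_length(self) -> int:
        return self.promoter_window[1] - self.promoter_window[0]


@dataclass(frozen=True)
class GroundTruth:
    regulator: str
    cascade: tuple[str, ...]
    de_genes: Mapping[tuple[str, str], tuple[str, ...]]  # (line, evidence) -> genes
    motif_id: str = ""

    @property
    def all_de_genes(self) -> set[str]:
        return {g for genes in self.de_genes.values() for g in genes}


@dataclass
class StudyBundle:
    config: SimulationConfig
    truth: GroundTruth
    network: RegulatoryNetwork
    pwm_library: list[PWM]
    promoters: PromoterSet
    background_genes: list[str]
    expression: dict[str, tuple[ExpressionMatrix, ExpressionMatrix]]  # line -> (high, low)
    peptides: dict[str, tuple[PeptideCountTable, PeptideCountTable]]

    @property
    def cell_lines(self) -> list[str]:
        return list(self.expression)


def gene_universe(config: SimulationConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(config.n_genes)]


def _plant_truth(config: SimulationConfig, cascade: list[str], rng: np.random.Generator) -> dict:
    lines = list(CELL_LINES[: config.n_cell_lines])
    de: dict[tuple[str, str], tuple[str, ...]] = {}
    n = min(config.n_de_genes, len(cascade))
    for line in lines:
        for evidence in EVIDENCE:
            picked = rng.choice(cascade, size=n, replace=False)
            de[(line, evidence)] = tuple(sorted(picked))
    return de


def simulate_network(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[RegulatoryNetwork, GroundTruth]:
    """Random directed graph plus a planted regulator wired to a gene cascade."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    genes = gene_universe(config)
    if config.n_network_nodes > config.n_genes:
        raise ValueError("network larger than the gene universe")
    if config.cascade_size > config.n_network_nodes - 1:
        raise ValueError("cascade larger than the gene universe of the network")

    regulator = "REG1"
    node_genes = list(rng.choice(genes, size=config.n_network_nodes - 1, replace=False))
    cascade_pool = [g for g in node_genes]
    if config.cascade_size > len(cascade_pool):
        raise ValueError("cascade larger than the available network gene nodes")
    cascade = list(rng.choice(cascade_pool, size=config.cascade_size, replace=False))

    edges: list[tuple[str, str]] = []
    level = [regulator]
    pos = 0
    for _ in range(config.depth):
        nxt: list[str] = []
        for parent in level:
            children = cascade[pos : pos + config.fanout]
            pos += config.fanout
            edges.extend((parent, c) for c in children)
            nxt.extend(children)
        level = nxt

    nodes = [regulator] + node_genes
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < config.edge_prob:
                edges.append((u, v))

    network = RegulatoryNetwork.from_edges(edges)
    # isolated gene nodes still belong to the universe of candidates
    network.graph.add_nodes_from(nodes)
    network.gene_map = {n: n for n in network.graph.nodes}

    de = _plant_truth(config, cascade, rng)
    truth = GroundTruth(regulator=regulator, cascade=tuple(cascade), de_genes=de)
    return network, truth


def _random_sequences(n: int, length: int, gc: float, rng: np.random.Generator) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=(n, length), p=p)
    return ["".join(_BASES[row]) for row in draws]


def _concentrated_pwm(
    matrix_id: str,
    consensus: str,
    concentration: float,
    tf_names: tuple[str, ...],
) -> PWM:
    # two-valued columns keep the threshold DP state space tiny
    L = len(consensus)
    probs = np.full((4, L), (1 - concentration) / 3)
    for j, b in enumerate(consensus):
        probs["ACGT".index(b), j] = concentration
    return PWM(matrix_id=matrix_id, probs=probs, tf_names=tf_names)


def _plant_site(seq: str, consensus: str, mutation_prob: float, rng: np.random.Generator) -> str:
    L = len(consensus)
    start = int(rng.integers(0, len(seq) - L + 1))
    site = list(consensus)
    for j in range(L):
        if rng.random() < mutation_prob:
            site[j] = str(rng.choice(_BASES))
    return seq[:start] + "".join(site) + seq[start + L :]


def simulate_promoters(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[PromoterSet, list[PWM]]:
    """Promoters for every universe gene plus dedicated background promoters.

    The planted motif's consensus is embedded (with per-base mutation noise)
    in DE-gene promoters with probability ``plant_prob_de`` and elsewhere
    with ``plant_prob_bg``; decoy matrices get their own random consensi.
    """
    rng = np.random.default_rng(config.seed + 1 if rng is None else rng)
    if config.motif_length > config.promoter_length:
        raise ValueError("motif longer than the promoter window")

    genes = gene_universe(config)
    bg_names = [f"BG{i:04d}" for i in range(config.n_background_promoters)]
    all_names = genes + bg_names
    seqs = dict(
        zip(all_names, _random_sequences(len(all_names), config.promoter_length, config.gc_content, rng))
    )

    consensi = _random_sequences(config.n_motifs, config.motif_length, 0.5, rng)
    network_free = [g for g in genes if g not in truth.cascade and g != truth.regulator]
    library: list[PWM] = []
    for i, cons in enumerate(consensi):
        if i == 0:
            # sharp planted motif: the minSUM cutoff then sits at a
            # low-false-positive score, as for a real well-defined TFBS
            concentration = 0.993
            names: tuple[str, ...] = (truth.regulator,)
        else:
            concentration = float(rng.uniform(0.88, 0.95))
            names = (str(rng.choice(network_free)),)
        library.append(
            _concentrated_pwm(f"M{i:03d}", cons, concentration, names)
        )
    planted = library[0]
    de_genes = truth.all_de_genes
    for name in all_names:
        prob = config.plant_prob_de if name in de_genes else config.plant_prob_bg
        if rng.random() < prob:
            seqs[name] = _plant_site(seqs[name], planted.consensus, config.mutation_prob, rng)

    promoters = PromoterSet(seqs, window=config.promoter_window)
    return promoters, library


def simulate_expression(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> dict[str, tuple[ExpressionMatrix, ExpressionMatrix]]:
    """Per cell line: (high, low) replicated log2-ratio matrices.

    Null genes are Normal(0, sd) in both populations; the planted DE genes
    are shifted by ``log2_effect`` in the high population.
    """
    rng = np.random.default_rng(config.seed + 2 if rng is None else rng)
    genes = gene_universe(config)
    cols_high = [f"high_{r + 1}" for r in range(config.n_replicates)]
    cols_low = [f"low_{r + 1}" for r in range(config.n_replicates)]
    out: dict[str, tuple[ExpressionMatrix, ExpressionMatrix]] = {}
    for line in CELL_LINES[: config.n_cell_lines]:
        shift = np.zeros(len(genes))
        planted = set(truth.de_genes.get((line, "transcript"), ()))
        for i, g in enumerate(genes):
            if g in planted:
                shift[i] = config.log2_effect
        high = rng.normal(0.0, config.noise_sd, (len(genes), config.n_replicates)) + shift[:, None]
        low = rng.normal(0.0, config.noise_sd, (len(genes), config.n_replicates))
        out[line] = (
            ExpressionMatrix(pd.DataFrame(high, index=genes, columns=cols_high), "high", line),
            ExpressionMatrix(pd.DataFrame(low, index=genes, columns=cols_low), "low", line),
        )
    return out


def simulate_peptides(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> dict[str, tuple[PeptideCountTable, PeptideCountTable]]:
    """Per cell line: (high, low) peptide-count tables.

    Observable counts are drawn uniformly from 5..40; observed counts are
    binomial with a per-protein detection probability, multiplied by the
    planted fold in the high population for planted proteins.
    """
    rng = np.random.default_rng(config.seed + 3 if rng is None else rng)
    genes = gene_universe(config)
    out: dict[str, tuple[PeptideCountTable, PeptideCountTable]] = {}
    cols_high = [f"high_{r + 1}" for r in range(config.n_replicates)]
    cols_low = [f"low_{r + 1}" for r in range(config.n_replicates)]
    for line in CELL_LINES[: config.n_cell_lines]:
        planted = list(truth.de_genes.get((line, "protein"), ()))
        others = [g for g in genes if g not in planted]
        n_other = max(config.n_proteins - len(planted), 0)
        proteins = sorted(planted + list(rng.choice(others, size=n_other, replace=False)))
        planted_set = set(planted)

        observable = pd.Series(
            rng.integers(5, 41, size=len(proteins)), index=proteins, name="observable"
        )
        base_p = pd.Series(rng.uniform(0.25, 0.55, size=len(proteins)), index=proteins)

        def draw(population: str, cols: list[str]) -> PeptideCountTable:
            obs = np.empty((len(proteins), config.n_replicates), dtype=int)
            for i, prot in enumerate(proteins):
                p = base_p[prot]
                if population == "high" and prot in planted_set:
                    p = min(p * config.protein_fold, 0.95)
                obs[i] = rng.binomial(int(observable[prot]), p, size=config.n_replicates)
            return PeptideCountTable(
                pd.DataFrame(obs, index=proteins, columns=cols), observable.copy(), population, line
            )

        out[line] = (draw("high", cols_high), draw("low", cols_low))
    return out


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Full input bundle feeding the entire pipeline, plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    network, truth = simulate_network(config, rng)
    promoters, library = simulate_promoters(config, truth, rng)
    truth = GroundTruth(
        regulator=truth.regulator,
        cascade=truth.cascade,
        de_genes=truth.de_genes,
        motif_id=library[0].matrix_id,
    )
    expression = simulate_expression(config, truth, rng)
    peptides = simulate_peptides(config, truth, rng)
    bg = [g for g in promoters.genes if g.startswith("BG")]
    return StudyBundle(
        config=config,
        truth=truth,
        network=network,
        pwm_library=library,
        promoters=promoters,
        background_genes=bg,
        expression=expression,
        peptides=peptides,
    )
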