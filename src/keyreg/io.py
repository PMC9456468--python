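"""File I/O for all pipeline formats.

Expression and peptide tables are TSV with an identifier column followed by
replicate columns named ``<population>_<replicate>``. Motif libraries are
read with Biopython from JASPAR PFM or TRANSFAC matrix text; promoters from
FASTA; networks from SIF or two-column edge TSV. All outputs are TSV with
fixed column order and float formatting so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .de import DifferentialList, ExpressionMatrix, PeptideCountTable
from .mr import MRCandidate, RegulatoryNetwork
from .promoter import PWM, DEFAULT_WINDOW, PromoterSet, TFEnrichmentRecord
from .rank import EvidenceRankTable, KeyRegulatorRecord

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0].startswith("Unnamed"):
        raise ValueError(f"{path}: missing identifier column header")
    return df


def _check_numeric(df: pd.DataFrame, path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna() & (df[col].str.lower() != "nan")]
        if len(bad):
            row = bad[0]
            raise ValueError(
                f"{path}: non-numeric cell at row {row + 2}, column {col!r}: {df.loc[row, col]!r}"
            )
        out[col] = converted
    return out


def _split_population_columns(columns: Sequence[str], path: str | Path) -> dict[str, list[str]]:
    pops: dict[str, list[str]] = {}
    for col in columns:
        if "_" not in col:
            raise ValueError(
                f"{path}: replicate column {col!r} not named <population>_<replicate>"
            )
        pop = col.rsplit("_", 1)[0]
        pops.setdefault(pop, []).append(col)
    return pops


def read_expression(
    path: str | Path, cell_line: str = ""
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Read a log2-ratio TSV; returns the (high, low) population matrices."""
    df = _read_tsv(path)
    id_col = df.columns[0]
    dups = df[id_col][df[id_col].duplicated()].unique().tolist()
    if dups:
        raise ValueError(f"{path}: duplicate entity identifiers: {dups}")
    value_cols = list(df.columns[1:])
    df = _check_numeric(df, path, value_cols)
    df = df.set_index(id_col)
    pops = _split_population_columns(value_cols, path)
    if set(pops) != {"high", "low"}:
        raise ValueError(f"{path}: expected populations {{high, low}}, found {sorted(pops)}")
    high = ExpressionMatrix(df[pops["high"]].astype(float), "high", cell_line)
    low = ExpressionMatrix(df[pops["low"]].astype(float), "low", cell_line)
    logger.info("%s: %d entities, %d+%d replicates", path, len(df), len(pops["high"]), len(pops["low"]))
    return high, low


def write_expression(path: str | Path, high: ExpressionMatrix, low: ExpressionMatrix) -> None:
    df = pd.concat([high.values, low.values], axis=1)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_peptides(
    path: str | Path, cell_line: str = ""
) -> tuple[PeptideCountTable, PeptideCountTable]:
    """Read a peptide-count TSV (protein, observable, <pop>_<rep> columns)."""
    df = _read_tsv(path)
    id_col = df.columns[0]
    if "observable" not in df.columns:
        raise ValueError(f"{path}: missing 'observable' column")
    dups = df[id_col][df[id_col].duplicated()].unique().tolist()
    if dups:
        raise ValueError(f"{path}: duplicate protein identifiers: {dups}")
    value_cols = [c for c in df.columns[1:]]
    df = _check_numeric(df, path, value_cols)
    df = df.set_index(id_col)
    observable = df["observable"].astype(int)
    rep_cols = [c for c in df.columns if c != "observable"]
    pops = _split_population_columns(rep_cols, path)
    if set(pops) != {"high", "low"}:
        raise ValueError(f"{path}: expected populations {{high, low}}, found {sorted(pops)}")
    high = PeptideCountTable(df[pops["high"]].astype(int), observable, "high", cell_line)
    low = PeptideCountTable(df[pops["low"]].astype(int), observable, "low", cell_line)
    return high, low


def write_peptides(path: str | Path, high: PeptideCountTable, low: PeptideCountTable) -> None:
    df = pd.concat([high.observable.rename("observable"), high.observed, low.observed], axis=1)
    df.index.name = "protein"
    df.to_csv(path, sep="\t")


def read_promoters(path: str | Path, window: tuple[int, int] = DEFAULT_WINDOW) -> PromoterSet:
    """Read promoter sequences from FASTA; record ids are gene identifiers."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"{path}: record {rec.id!r} contains illegal characters")
        seqs[rec.id] = seq
    logger.info("%s: %d promoter(s)", path, len(seqs))
    return PromoterSet(seqs, window=window)


def write_promoters(path: str | Path, promoters: PromoterSet) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene, description="")
        for gene, seq in promoters.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_pwms(
    path: str | Path,
    dialect: str = "jaspar-pfm",
    pseudocount: float = 0.8,
    background: np.ndarray | None = None,
) -> list[PWM]:
    """Read a motif library (JASPAR PFM or TRANSFAC matrix text) as PWMs."""
    fmt = {"jaspar-pfm": "jaspar", "transfac-text": "transfac"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown PWM dialect {dialect!r}")
    with open(path) as handle:
        parsed = bio_motifs.parse(handle, fmt)
    library: list[PWM] = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        matrix_id = (m.matrix_id if getattr(m, "matrix_id", None) else None) or m.name or f"PWM{len(library)}"
        names = tuple(str(m.name).upper().split("::")) if m.name else ()
        library.append(
            PWM.from_counts(
                matrix_id=str(matrix_id),
                counts=counts,
                pseudocount=pseudocount,
                background=background,
                tf_names=names,
            )
        )
    logger.info("%s: %d matrix(es) [%s]", path, len(library), dialect)
    return library


def write_pwms_jaspar(path: str | Path, library: Sequence[PWM], scale: int = 100) -> None:
    """Write PWMs as JASPAR PFM blocks (probabilities scaled to counts)."""
    with open(path, "w") as fh:
        for pwm in library:
            name = pwm.tf_names[0] if pwm.tf_names else pwm.matrix_id
            fh.write(f">{pwm.matrix_id} {name}\n")
            counts = np.round(pwm.probs * scale).astype(int)
            for i, base in enumerate("ACGT"):
                row = " ".join(str(c) for c in counts[i])
                fh.write(f"{base} [ {row} ]\n")


def read_network(path: str | Path, dialect: str = "sif") -> RegulatoryNetwork:
    """Read a directed network from SIF or two-column edge TSV."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if dialect == "sif":
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: SIF line needs source relation target")
                src, targets = parts[0], parts[2:]
            elif dialect == "edge-tsv":
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: edge line needs source and target")
                src, targets = parts[0], parts[1:2]
            else:
                raise ValueError(f"unknown network dialect {dialect!r}")
            edges.extend((src, t) for t in targets)
    net = RegulatoryNetwork.from_edges(edges)
    logger.info("%s: %d node(s), %d edge(s)", path, net.graph.number_of_nodes(), net.graph.number_of_edges())
    return net


def write_network_sif(path: str | Path, network: RegulatoryNetwork, relation: str = "regulates") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(network.graph.edges):
            fh.write(f"{u}\t{relation}\t{v}\n")


def write_differential_list(path: str | Path, dl: DifferentialList) -> None:
    with open(path, "w") as fh:
        fh.write("entity\tlog2_fold_change\tdirection\tevidence\tp_value\tadj_p_value\tunbounded\n")
        for e in sorted(dl.entries, key=lambda x: x.entity):
            p = "" if e.p_value is None else _FLOAT_FMT % e.p_value
            q = "" if e.adj_p_value is None else _FLOAT_FMT % e.adj_p_value
            fh.write(
                f"{e.entity}\t{_FLOAT_FMT % e.log2_fold_change}\t{e.direction}\t"
                f"{e.evidence}\t{p}\t{q}\t{int(e.unbounded)}\n"
            )


def write_enrichment_records(path: str | Path, records: Sequence[TFEnrichmentRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("matrix_id\tyes_density\tno_density\tfold_enrichment\tp_value\tadj_p_value\ttf_names\n")
        for r in sorted(records, key=lambda x: x.matrix_id):
            fh.write(
                f"{r.matrix_id}\t{_FLOAT_FMT % r.yes_density}\t{_FLOAT_FMT % r.no_density}\t"
                f"{_FLOAT_FMT % r.fold_enrichment}\t{_FLOAT_FMT % r.p_value}\t"
                f"{_FLOAT_FMT % r.adj_p_value}\t{','.join(r.tf_names)}\n"
            )


def write_mr_candidates(path: str | Path, candidates: Sequence[MRCandidate]) -> None:
    with open(path, "w") as fh:
        fh.write("node\tscore\tz_score\tp_value\tadj_p_value\tn_reached_hits\tdegenerate\n")
        for c in candidates:
            fh.write(
                f"{c.node}\t{_FLOAT_FMT % c.score}\t{_FLOAT_FMT % c.z_score}\t"
                f"{_FLOAT_FMT % c.p_value}\t{_FLOAT_FMT % c.adj_p_value}\t"
                f"{len(c.reached_hits)}\t{int(c.degenerate)}\n"
            )


def write_rank_table(path: str | Path, table: EvidenceRankTable) -> None:
    with open(path, "w") as fh:
        fh.write("entity\trank\n")
        for entity in sorted(table.ranks, key=lambda e: (-table.ranks[e], e)):
            fh.write(f"{entity}\t{table.ranks[entity]}\n")


def read_rank_table(path: str | Path, category: str, n_lists: int = 6) -> EvidenceRankTable:
    """Read a pre-made entity/rank TSV (the "ranks-only" mode input)."""
    df = _read_tsv(path)
    if list(df.columns[:2]) != ["entity", "rank"]:
        raise ValueError(f"{path}: expected columns 'entity' and 'rank'")
    df = _check_numeric(df, path, ["rank"])
    ranks = {str(e).upper(): int(r) for e, r in zip(df["entity"], df["rank"])}
    if len(ranks) != len(df):
        raise ValueError(f"{path}: duplicate entities after case normalization")
    return EvidenceRankTable(category=category, n_lists=n_lists, ranks=ranks)  # type: ignore[arg-type]


def write_kr_table(path: str | Path, records: Sequence[KeyRegulatorRecord]) -> None:
    """The final key-regulator table: entity, TF rank, MR rank, total rank."""
    with open(path, "w") as fh:
        fh.write("entity\ttf_rank\tmr_rank\ttotal_rank\n")
        for r in records:
            fh.write(f"{r.entity}\t{r.tf_rank}\t{r.mr_rank}\t{r.total_rank}\n")


def write_gene_list(path: str | Path, genes: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
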