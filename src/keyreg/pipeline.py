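"""Pipeline orchestration: DE -> six lists -> TF scan -> MR search -> ranks.

``run_study`` drives the full analysis on in-memory objects (as produced by
:mod:`keyreg.simulate` or assembled from files); ``run_pipeline`` is the
file-based entry point that reads a configuration, executes every stage,
and writes diff-able TSV reports plus a run log capturing every threshold,
seed and input digest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as kio
from .de import DifferentialList, build_six_lists, de_proteins, de_transcripts
from .mr import MRCandidate, RegulatoryNetwork, find_master_regulators
from .promoter import PromoterSet, PWM, TFEnrichmentRecord, calibrate_library, tf_candidates
from .rank import (
    EvidenceRankTable,
    KeyRegulatorRecord,
    discard_singletons,
    key_regulators,
    membership_ranks,
)
from .simulate import StudyBundle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """Every stated analysis threshold in one place."""

    fold_threshold: float = 2.0
    alpha: float = 0.05
    tf_alpha: float = 0.05
    tf_min_fold: float = 1.5
    radius: int = 10
    score_min: float = 0.2
    z_min: float = 1.0
    fdr_max: float = 0.05
    n_lists: int = 6
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fold_threshold", "alpha", "tf_alpha", "radius", "score_min", "fdr_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    six_lists: list[DifferentialList]
    tf_lists: dict[str, list[str]]                 # list label -> TF candidates
    mr_lists: dict[str, list[str]]                 # list label -> MR node ids
    enrichment: dict[str, list[TFEnrichmentRecord]]
    mr_candidates: dict[str, list[MRCandidate]]
    tf_table: EvidenceRankTable                    # singleton-discarded
    mr_table: EvidenceRankTable
    key_regulators: list[KeyRegulatorRecord]


def run_study(bundle: StudyBundle, params: PipelineParams | None = None) -> PipelineResult:
    """Run DE, promoter enrichment, MR search and rank integration end to end."""
    params = params or PipelineParams()

    per_line: dict[str, tuple[DifferentialList, DifferentialList]] = {}
    for line in bundle.cell_lines:
        ehigh, elow = bundle.expression[line]
        phigh, plow = bundle.peptides[line]
        per_line[line] = (
            de_transcripts(ehigh, elow, params.fold_threshold, params.alpha),
            de_proteins(phigh, plow, params.fold_threshold),
        )
    six = build_six_lists(per_line)

    library = calibrate_library(bundle.pwm_library)
    background = bundle.promoters.subset(bundle.background_genes)

    tf_lists: dict[str, list[str]] = {}
    mr_lists: dict[str, list[str]] = {}
    enrichment: dict[str, list[TFEnrichmentRecord]] = {}
    mr_candidates: dict[str, list[MRCandidate]] = {}
    for i, dl in enumerate(six):
        yes = bundle.promoters.subset(sorted(dl.entities - set(bundle.background_genes)))
        if len(yes) == 0:
            tfs: list[str] = []
            records: list[TFEnrichmentRecord] = []
        else:
            tfs, records = tf_candidates(
                yes,
                background,
                library,
                alpha=params.tf_alpha,
                min_fold=params.tf_min_fold,
                n_permutations=params.n_permutations,
                rng_seed=params.seed + 100 + i,
            )
        tf_lists[dl.label] = tfs
        enrichment[dl.label] = records

        if dl.entities:
            cands = find_master_regulators(
                bundle.network,
                dl,
                radius=params.radius,
                score_min=params.score_min,
                z_min=params.z_min,
                fdr_max=params.fdr_max,
                n_permutations=params.n_permutations,
                rng_seed=params.seed + i,
            )
        else:
            cands = []
        mr_candidates[dl.label] = cands
        mr_lists[dl.label] = [c.node for c in cands]

    tf_table = discard_singletons(
        membership_ranks(list(tf_lists.values()), "TF", n_lists=params.n_lists)
    )
    mr_table = discard_singletons(
        membership_ranks(list(mr_lists.values()), "MR", n_lists=params.n_lists)
    )
    krs = key_regulators(tf_table, mr_table)
    return PipelineResult(
        six_lists=six,
        tf_lists=tf_lists,
        mr_lists=mr_lists,
        enrichment=enrichment,
        mr_candidates=mr_candidates,
        tf_table=tf_table,
        mr_table=mr_table,
        key_regulators=krs,
    )


@dataclass
class PipelineConfig:
    """File-based run configuration (loadable from YAML)."""

    expression: dict[str, str] = field(default_factory=dict)  # cell line -> TSV path
    peptides: dict[str, str] = field(default_factory=dict)
    promoters: str = ""
    background_promoters: str = ""  # text file listing background promoter ids
    pwms: str = ""
    pwm_dialect: str = "jaspar-pfm"
    network: str = ""
    network_dialect: str = "sif"
    out_dir: str = "keyreg_out"
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = PipelineParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def input_paths(self) -> list[str]:
        paths = list(self.expression.values()) + list(self.peptides.values())
        paths += [self.promoters, self.background_promoters, self.pwms, self.network]
        return [p for p in paths if p]


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_bundle(config: PipelineConfig) -> StudyBundle:
    """Assemble a StudyBundle from the files named in a PipelineConfig."""
    if set(config.expression) != set(config.peptides):
        raise ValueError("expression and peptide inputs must cover the same cell lines")
    missing = [p for p in config.input_paths() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")

    expression = {
        line: kio.read_expression(path, cell_line=line)
        for line, path in sorted(config.expression.items())
    }
    peptides = {
        line: kio.read_peptides(path, cell_line=line)
        for line, path in sorted(config.peptides.items())
    }
    promoters = kio.read_promoters(config.promoters)
    background = kio.read_gene_list(config.background_promoters)
    library = kio.read_pwms(config.pwms, dialect=config.pwm_dialect)
    network = kio.read_network(config.network, dialect=config.network_dialect)
    return StudyBundle(
        config=None,  # type: ignore[arg-type]  # file-based runs carry no simulation config
        truth=None,  # type: ignore[arg-type]
        network=network,
        pwm_library=library,
        promoters=promoters,
        background_genes=background,
        expression=expression,
        peptides=peptides,
    )


def write_result(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for dl in result.six_lists:
        tag = dl.label.replace("/", "_")
        kio.write_differential_list(out / f"de_{tag}.tsv", dl)
        kio.write_gene_list(out / f"tf_candidates_{tag}.tsv", result.tf_lists[dl.label])
        kio.write_enrichment_records(out / f"tf_enrichment_{tag}.tsv", result.enrichment[dl.label])
        kio.write_mr_candidates(out / f"mr_candidates_{tag}.tsv", result.mr_candidates[dl.label])
    kio.write_rank_table(out / "tf_ranks.tsv", result.tf_table)
    kio.write_rank_table(out / "mr_ranks.tsv", result.mr_table)
    kio.write_kr_table(out / "key_regulators.tsv", result.key_regulators)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based end-to-end run: read inputs, execute stages, write reports.

    Any stage failure is re-raised with the stage name in the message.
    """
    stage = "load-inputs"
    try:
        bundle = load_bundle(config)
        stage = "analysis"
        result = run_study(bundle, config.params)
        stage = "write-outputs"
        write_result(result, config.out_dir)
        log = {
            "params": asdict(config.params),
            "inputs": {p: _digest(p) for p in sorted(config.input_paths())},
            "n_key_regulators": len(result.key_regulators),
        }
        with open(Path(config.out_dir) / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return result


def ranks_only(
    tf_path: str | Path, mr_path: str | Path, n_lists: int = 6
) -> list[KeyRegulatorRecord]:
    """Standalone rank-integration mode on pre-made TF/MR rank tables."""
    tf_table = discard_singletons(kio.read_rank_table(tf_path, "TF", n_lists))
    mr_table = discard_singletons(kio.read_rank_table(mr_path, "MR", n_lists))
    return key_regulators(tf_table, mr_table)
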