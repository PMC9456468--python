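"""Rank integration across evidence lists.

Each entity earns one point per evidence list that contains it (six lists by
default: three cell lines x two omics layers, per category). Entities present
in only one list are discarded. Key regulators are the intersection of the
TF and MR rank tables, ordered by total rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

logger = logging.getLogger(__name__)

Category = Literal["TF", "MR"]


@dataclass
class EvidenceRankTable:
    """Entity -> number of evidence lists containing it (membership rank)."""

    category: Category
    n_lists: int
    ranks: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {e: r for e, r in self.ranks.items() if not 0 < r <= self.n_lists}
        if bad:
            raise ValueError(f"ranks outside [1, {self.n_lists}]: {bad}")

    def __len__(self) -> int:
        return len(self.ranks)

    def __getitem__(self, entity: str) -> int:
        return self.ranks[entity]

    def __contains__(self, entity: str) -> bool:
        return entity in self.ranks


@dataclass(frozen=True)
class KeyRegulatorRecord:
    entity: str
    tf_rank: int
    mr_rank: int
    total_rank: int

    def __post_init__(self) -> None:
        if self.total_rank != self.tf_rank + self.mr_rank:
            raise ValueError("total rank must equal TF rank + MR rank")


def membership_ranks(
    lists: Sequence[Iterable[str]],
    category: Category,
    n_lists: int = 6,
) -> EvidenceRankTable:
    """One point per list membership; entities appearing nowhere are absent.

    Entity identifiers are upper-cased before counting; duplicates within a
    single list count once (logged).
    """
    if len(lists) != n_lists:
        raise ValueError(f"expected {n_lists} lists, got {len(lists)}")
    ranks: dict[str, int] = {}
    for i, lst in enumerate(lists):
        raw = [str(e).upper() for e in lst]
        members = set(raw)
        if len(raw) != len(members):
            logger.info("list %d: %d duplicate entr(ies) counted once", i, len(raw) - len(members))
        for entity in members:
            ranks[entity] = ranks.get(entity, 0) + 1
    return EvidenceRankTable(category=category, n_lists=n_lists, ranks=ranks)


def discard_singletons(table: EvidenceRankTable) -> EvidenceRankTable:
    """Remove entities present in only one list; other ranks unchanged."""
    kept = {e: r for e, r in table.ranks.items() if r >= 2}
    return EvidenceRankTable(category=table.category, n_lists=table.n_lists, ranks=kept)


def key_regulators(
    tf_table: EvidenceRankTable,
    mr_table: EvidenceRankTable,
) -> list[KeyRegulatorRecord]:
    """Intersection of the TF and MR tables, ranked by summed membership.

    Ordered by total rank descending, ties by TF rank descending, then
    entity identifier ascending. Both inputs are expected to be
    singleton-discarded already.
    """
    if tf_table.category != "TF" or mr_table.category != "MR":
        raise ValueError("expected a TF table and an MR table, in that order")
    shared = set(tf_table.ranks) & set(mr_table.ranks)
    if not shared:
        logger.warning("TF/MR intersection is empty")
    records = [
        KeyRegulatorRecord(
            entity=e,
            tf_rank=tf_table[e],
            mr_rank=mr_table[e],
            total_rank=tf_table[e] + mr_table[e],
        )
        for e in shared
    ]
    records.sort(key=lambda r: (-r.total_rank, -r.tf_rank, r.entity))
    return records
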