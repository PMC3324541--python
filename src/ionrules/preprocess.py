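"""Filtering and model/generalization splitting by LME group.

Neurons lacking any of the three defining labels are excluded. The rest are
grouped by their (layer, morphology, electrical-type) triple. Groups with at
least ``min_count`` neurons form the model set; smaller groups whose layer,
morphology and electrical type each occur somewhere in the model set — but
whose exact triple does not — form the generalization set (new combinations
of seen categorical values, the only kind a categorical model can be tested
on); everything else is discarded but retained for audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .data import MISSING, NeuronRecord

__all__ = [
    "LMEGroup",
    "DatasetSplit",
    "filter_complete",
    "group_by_lme",
    "split_model_generalization",
    "write_split_report",
]

LMEKey = tuple[str, str, str]


@dataclass(frozen=True)
class LMEGroup:
    key: LMEKey
    members: tuple[NeuronRecord, ...]

    def __post_init__(self) -> None:
        if MISSING in self.key:
            raise ValueError("LME group key has a missing component")
        if any(m.lme != self.key for m in self.members):
            raise ValueError("member label mismatch with group key")

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class DatasetSplit:
    model_groups: tuple[LMEGroup, ...]
    generalization_groups: tuple[LMEGroup, ...]
    discarded: tuple[NeuronRecord, ...]

    @property
    def model_records(self) -> list[NeuronRecord]:
        return [m for g in self.model_groups for m in g.members]

    @property
    def generalization_records(self) -> list[NeuronRecord]:
        return [m for g in self.generalization_groups for m in g.members]


def filter_complete(
    records: Iterable[NeuronRecord],
) -> tuple[list[NeuronRecord], list[NeuronRecord]]:
    """Split records into (complete-labeled, dropped), order preserved."""
    kept: list[NeuronRecord] = []
    dropped: list[NeuronRecord] = []
    for r in records:
        (kept if r.complete else dropped).append(r)
    return kept, dropped


def group_by_lme(records: Iterable[NeuronRecord]) -> list[LMEGroup]:
    """Group complete-labeled records by LME triple, first-seen order."""
    buckets: dict[LMEKey, list[NeuronRecord]] = {}
    for r in records:
        if not r.complete:
            raise ValueError(f"record {r.neuron_id!r} has missing labels")
        buckets.setdefault(r.lme, []).append(r)
    return [LMEGroup(key=k, members=tuple(v)) for k, v in buckets.items()]


def split_model_generalization(
    groups: Sequence[LMEGroup], min_count: int = 4
) -> DatasetSplit:
    """Partition LME groups into model / generalization / discarded sets."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    keys = [g.key for g in groups]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate LME group keys")

    model = [g for g in groups if g.count >= min_count]
    seen_l = {g.key[0] for g in model}
    seen_m = {g.key[1] for g in model}
    seen_e = {g.key[2] for g in model}

    generalization: list[LMEGroup] = []
    discarded: list[NeuronRecord] = []
    for g in groups:
        if g.count >= min_count:
            continue
        l, m, e = g.key
        if l in seen_l and m in seen_m and e in seen_e:
            generalization.append(g)
        else:
            discarded.extend(g.members)
    return DatasetSplit(
        model_groups=tuple(model),
        generalization_groups=tuple(generalization),
        discarded=tuple(discarded),
    )


def write_split_report(split: DatasetSplit, path: str | Path) -> None:
    """TSV report: one line per group (or discarded-neuron bucket)."""
    lines = ["layer\tmorphology\tetype\tcount\tassignment"]
    for g in split.model_groups:
        lines.append("\t".join([*g.key, str(g.count), "model"]))
    for g in split.generalization_groups:
        lines.append("\t".join([*g.key, str(g.count), "generalization"]))
    by_key: dict[LMEKey, int] = {}
    for r in split.discarded:
        by_key[r.lme] = by_key.get(r.lme, 0) + 1
    for key, n in by_key.items():
        lines.append("\t".join([*key, str(n), "discarded"]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
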