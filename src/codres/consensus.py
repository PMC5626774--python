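"""Inhibition-threshold filtering, tool/dataset consensus, and the
per-stage normalized inhibition component.

A raw connectivity record qualifies when its score is at or below the
inhibition threshold (default -0.5). Per dataset, a drug passes tool
consensus when qualifying records come from at least ``min_tools`` distinct
tools (the gene-selection method dimension is ignored for counting). Per
stage, a drug passes dataset consensus when it appears in at least
``min_datasets`` per-dataset sets. The inhibition component aggregates
magnitudes of qualifying scores across tools, methods and datasets of a
stage and divides by the per-stage maximum, so the strongest drug of each
stage scores exactly 1.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .errors import CodresError, InvalidRecordError
from .model import StageContrast

__all__ = [
    "ConsensusConfig",
    "filter_qualifying",
    "tool_consensus",
    "dataset_consensus",
    "aggregate_inhibition",
    "normalize_inhibition",
    "StageConsensusRow",
    "consensus_pipeline",
]


@dataclass(frozen=True)
class ConsensusConfig:
    """Thresholds of the consensus filter.

    ``score_max`` is the inhibition threshold: a record qualifies when
    ``score <= score_max`` (or strictly below, with ``strict=True``).
    """

    score_max: float = -0.5
    min_tools: int = 2
    min_datasets: int = 2
    strict: bool = False

    def __post_init__(self):
        if not self.score_max < 0:
            raise InvalidRecordError("score_max must be negative")
        if self.min_tools < 1 or self.min_datasets < 1:
            raise InvalidRecordError("min_tools and min_datasets must be >= 1")

    def qualifies(self, score: float) -> bool:
        return score < self.score_max if self.strict else score <= self.score_max


def filter_qualifying(records, cfg: ConsensusConfig = ConsensusConfig()) -> list:
    """Records at or below the inhibition threshold, input order preserved."""
    return [r for r in records if cfg.qualifies(r.score)]


def tool_consensus(records, cfg: ConsensusConfig = ConsensusConfig()) -> dict:
    """Per-dataset sets of drugs hit by >= min_tools distinct tools.

    ``records`` must already be threshold-filtered and belong to a single
    stage. A tool counts once per (drug, dataset) however many gene-selection
    methods produced a hit.
    """
    stages = {r.stage for r in records}
    if len(stages) > 1:
        raise CodresError(f"records span multiple stages: {sorted(s.label for s in stages)}")
    tools: dict[str, dict[str, set]] = defaultdict(lambda: defaultdict(set))
    for r in records:
        tools[r.dataset][r.drug].add(r.tool)
    return {
        dataset: {d for d, ts in per_drug.items() if len(ts) >= cfg.min_tools}
        for dataset, per_drug in tools.items()
    }


def dataset_consensus(dataset_sets: dict, cfg: ConsensusConfig = ConsensusConfig()) -> dict:
    """Drugs present in >= min_datasets of the per-dataset sets, with their
    support counts. Raises if fewer datasets than ``min_datasets`` are given."""
    if len(dataset_sets) < cfg.min_datasets:
        raise CodresError(
            f"min_datasets={cfg.min_datasets} exceeds the {len(dataset_sets)} "
            "dataset sets supplied"
        )
    support: dict[str, int] = defaultdict(int)
    for drugs in dataset_sets.values():
        for d in drugs:
            support[d] += 1
    return {d: c for d, c in support.items() if c >= cfg.min_datasets}


def aggregate_inhibition(records, stage: "StageContrast | str | None" = None) -> dict:
    """Sum of |score| per drug over qualifying records of one stage.

    ``records`` must already be threshold-filtered (all scores negative);
    the aggregate is therefore strictly positive for any drug present.
    """
    if stage is not None and not isinstance(stage, StageContrast):
        stage = StageContrast(stage)
    agg: dict[str, float] = defaultdict(float)
    for r in records:
        if stage is not None and r.stage != stage:
            continue
        agg[r.drug] += abs(r.score)
    return dict(agg)


def normalize_inhibition(aggregates: dict) -> dict:
    """Per-stage inhibition component: aggregate / max aggregate, in (0, 1].

    Normalization is always within one stage, never across stages.
    """
    if not aggregates:
        raise CodresError("cannot normalize an empty aggregate map")
    if any(v <= 0 for v in aggregates.values()):
        raise CodresError("aggregates must be strictly positive")
    top = max(aggregates.values())
    return {d: v / top for d, v in aggregates.items()}


@dataclass(frozen=True)
class StageConsensusRow:
    """One drug's consensus summary within a stage."""

    drug: str
    aggregate: float
    inhib_score: float
    n_tools: int
    n_datasets: int
    consensus: bool


def consensus_pipeline(records, cfg: ConsensusConfig = ConsensusConfig()) -> dict:
    """Full filter for every stage present in ``records``.

    Returns ``{stage_label: [StageConsensusRow, ...]}`` sorted by inhibition
    score descending (name ascending on ties). Consensus membership and the
    inhibition component are deliberately decoupled: every drug with at
    least one qualifying record in the stage is scored, and ``consensus``
    flags the drugs that additionally pass both consensus filters.
    """
    by_stage: dict[str, list] = defaultdict(list)
    for r in filter_qualifying(records, cfg):
        by_stage[r.stage.label].append(r)
    out = {}
    for stage, recs in by_stage.items():
        per_dataset = tool_consensus(recs, cfg)
        try:
            consensus = dataset_consensus(per_dataset, cfg)
        except CodresError:
            consensus = {}
        agg = aggregate_inhibition(recs)
        inhib = normalize_inhibition(agg)
        n_tools = defaultdict(set)
        n_datasets = defaultdict(set)
        for r in recs:
            n_tools[r.drug].add(r.tool)
            n_datasets[r.drug].add(r.dataset)
        rows = [
            StageConsensusRow(
                drug=d,
                aggregate=agg[d],
                inhib_score=inhib[d],
                n_tools=len(n_tools[d]),
                n_datasets=len(n_datasets[d]),
                consensus=d in consensus,
            )
            for d in agg
        ]
        rows.sort(key=lambda r: (-r.inhib_score, r.drug))
        out[stage] = rows
    return out
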