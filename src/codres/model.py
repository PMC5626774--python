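"""Domain types shared across the pipeline.

All drug names are canonicalized (lowercase, trimmed, internal whitespace
collapsed) at construction time, so every downstream module only ever sees
canonical names. Matching across tools is exact after canonicalization; no
fuzzy or synonym resolution is attempted.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidRecordError

__all__ = [
    "canonicalize_drug_name",
    "StageContrast",
    "PRESET_STAGES",
    "DrugScoreRecord",
    "SideEffectProfile",
    "ViolationCount",
    "FunctionalEvidence",
    "ComponentScores",
    "WeightVector",
    "DEFAULT_WEIGHTS",
    "RankedDrug",
    "DEGRecord",
    "GeneSignature",
    "Fingerprint",
    "TargetSet",
]

_WS = re.compile(r"\s+")


def canonicalize_drug_name(raw: str) -> str:
    """Canonical form of a drug name: lowercased, trimmed, internal
    whitespace collapsed to single spaces. Idempotent.

    Raises
    ------
    InvalidRecordError
        If ``raw`` is empty or whitespace-only.
    """
    name = _WS.sub(" ", raw.strip()).lower()
    if not name:
        raise InvalidRecordError("drug name is empty or whitespace-only")
    return name


@dataclass(frozen=True, order=True)
class StageContrast:
    """A disease-vs-reference comparison defining one scoring experiment."""

    label: str

    def __post_init__(self):
        if not self.label or not self.label.strip():
            raise InvalidRecordError("stage label must be nonempty")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: The four contrasts used throughout the reference study, as presets.
PRESET_STAGES = {
    "IPF_vs_Normal": StageContrast("IPF_vs_Normal"),
    "Stage1_vs_Normal": StageContrast("Stage1_vs_Normal"),
    "Stage2_vs_Normal": StageContrast("Stage2_vs_Normal"),
    "Stage2_vs_Stage1": StageContrast("Stage2_vs_Stage1"),
}


def _as_stage(stage: "StageContrast | str") -> StageContrast:
    return stage if isinstance(stage, StageContrast) else StageContrast(stage)


def _check_unit_interval(name: str, value: float, lo: float = 0.0, hi: float = 1.0):
    if math.isnan(value):
        raise InvalidRecordError(f"{name} is NaN")
    if not (lo <= value <= hi):
        raise InvalidRecordError(f"{name}={value!r} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class DrugScoreRecord:
    """One connectivity/inhibition score from one tool, gene-selection
    method, dataset and stage contrast, for one drug. ``score`` lies in
    [-1, 1]; negative values indicate reversal of the disease signature.
    """

    drug: str
    tool: str
    method: str
    dataset: str
    stage: StageContrast
    score: float

    def __post_init__(self):
        object.__setattr__(self, "drug", canonicalize_drug_name(self.drug))
        object.__setattr__(self, "stage", _as_stage(self.stage))
        for f in ("tool", "method", "dataset"):
            if not getattr(self, f).strip():
                raise InvalidRecordError(f"{f} must be nonempty")
        _check_unit_interval("score", self.score, -1.0, 1.0)

    @property
    def key(self) -> tuple:
        return (self.drug, self.tool, self.method, self.dataset, self.stage.label)


@dataclass(frozen=True)
class SideEffectProfile:
    """Per-drug side-effect counts in 8 severity classes (class weight =
    1-based index). If ``unknown`` is true the counts are ignored downstream
    and the drug receives the worst (zero) side-effect score."""

    drug: str
    counts: tuple
    unknown: bool = False

    def __post_init__(self):
        object.__setattr__(self, "drug", canonicalize_drug_name(self.drug))
        counts = tuple(int(c) for c in self.counts)
        if len(counts) != 8:
            raise InvalidRecordError(
                f"side-effect profile needs exactly 8 class counts, got {len(counts)}"
            )
        if any(c < 0 for c in counts):
            raise InvalidRecordError("side-effect counts must be >= 0")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class ViolationCount:
    """Number of druglikeness rules violated by a drug (upstream tool output)."""

    drug: str
    violations: int

    def __post_init__(self):
        object.__setattr__(self, "drug", canonicalize_drug_name(self.drug))
        if int(self.violations) != self.violations or self.violations < 0:
            raise InvalidRecordError("violations must be a non-negative integer")
        object.__setattr__(self, "violations", int(self.violations))


@dataclass(frozen=True)
class FunctionalEvidence:
    """Per-target-gene enrichment scores in [0, 1] for one drug; may be empty."""

    drug: str
    gene_scores: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "drug", canonicalize_drug_name(self.drug))
        scores = tuple(float(s) for s in self.gene_scores)
        for s in scores:
            _check_unit_interval("gene score", s)
        object.__setattr__(self, "gene_scores", scores)


@dataclass(frozen=True)
class ComponentScores:
    """The four normalized component scores of one drug, each in [0, 1]."""

    drug: str
    inhib: float
    struct: float
    func: float
    side: float

    def __post_init__(self):
        object.__setattr__(self, "drug", canonicalize_drug_name(self.drug))
        for f in ("inhib", "struct", "func", "side"):
            _check_unit_interval(f, getattr(self, f))


@dataclass(frozen=True)
class WeightVector:
    """Weights of the four components; non-negative, summing to 1."""

    w_is: float
    w_ss: float
    w_fs: float
    w_ses: float

    def __post_init__(self):
        ws = (self.w_is, self.w_ss, self.w_fs, self.w_ses)
        if any(math.isnan(w) or w < 0 for w in ws):
            raise InvalidRecordError("weights must be non-negative")
        if abs(sum(ws) - 1.0) > 1e-9:
            raise InvalidRecordError(f"weights must sum to 1, got {sum(ws)!r}")

    def as_tuple(self) -> tuple:
        return (self.w_is, self.w_ss, self.w_fs, self.w_ses)


#: Default weighting: inhibition 0.4, the three suitability components 0.2 each.
DEFAULT_WEIGHTS = WeightVector(0.4, 0.2, 0.2, 0.2)


@dataclass(frozen=True)
class RankedDrug:
    """A drug with its composite score, composite rank, inhibition-only
    rank, and the signed re-ranking shift (positive = promoted)."""

    drug: str
    codres: float
    codres_rank: int
    inhib_rank: int
    shift: int

    def __post_init__(self):
        object.__setattr__(self, "drug", canonicalize_drug_name(self.drug))
        _check_unit_interval("codres", self.codres)
        if self.codres_rank < 1 or self.inhib_rank < 1:
            raise InvalidRecordError("ranks must be positive integers")
        if self.shift != self.inhib_rank - self.codres_rank:
            raise InvalidRecordError(
                f"shift {self.shift} != inhib_rank - codres_rank "
                f"({self.inhib_rank} - {self.codres_rank})"
            )


@dataclass(frozen=True)
class DEGRecord:
    """One differential-expression row: gene, signed fold change, p-value."""

    gene: str
    fold_change: float
    p_value: float

    def __post_init__(self):
        if not self.gene.strip():
            raise InvalidRecordError("gene symbol must be nonempty")
        _check_unit_interval("p_value", self.p_value)
        if math.isnan(self.fold_change):
            raise InvalidRecordError("fold_change is NaN")


@dataclass(frozen=True)
class GeneSignature:
    """Ordered lists of top up- and down-regulated genes."""

    up: tuple = ()
    down: tuple = ()

    def __post_init__(self):
        up, down = tuple(self.up), tuple(self.down)
        if len(set(up)) != len(up) or len(set(down)) != len(down):
            raise InvalidRecordError("duplicate genes within a signature list")
        overlap = set(up) & set(down)
        if overlap:
            raise InvalidRecordError(f"genes in both up and down lists: {sorted(overlap)}")
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)


@dataclass(eq=False)
class Fingerprint:
    """Fixed-length binary structural fingerprint of one drug."""

    drug: str
    bits: np.ndarray

    def __post_init__(self):
        self.drug = canonicalize_drug_name(self.drug)
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1 or bits.size < 1:
            raise InvalidRecordError("fingerprint must be a nonempty 1-D bit vector")
        if not np.isin(bits, (0, 1)).all():
            raise InvalidRecordError("fingerprint bits must be 0/1")
        self.bits = bits

    def __len__(self) -> int:
        return int(self.bits.size)

    def __eq__(self, other):
        return (
            isinstance(other, Fingerprint)
            and self.drug == other.drug
            and np.array_equal(self.bits, other.bits)
        )


_DIRECTIONS = {"inhibits_disease", "induces_disease", "unknown"}
_ENTITY_KINDS = {"drug", "mirna"}


@dataclass(frozen=True)
class TargetSet:
    """Gene targets of one entity (a drug or a microRNA). For microRNAs the
    disease direction says whether the miRNA inhibits or induces the disease."""

    entity: str
    genes: frozenset
    entity_kind: str = "drug"
    direction: str | None = None

    def __post_init__(self):
        if not self.entity.strip():
            raise InvalidRecordError("entity identifier must be nonempty")
        if self.entity_kind not in _ENTITY_KINDS:
            raise InvalidRecordError(f"entity_kind must be one of {sorted(_ENTITY_KINDS)}")
        if self.entity_kind == "mirna":
            d = self.direction or "unknown"
            if d not in _DIRECTIONS:
                raise InvalidRecordError(f"direction must be one of {sorted(_DIRECTIONS)}")
            object.__setattr__(self, "direction", d)
        elif self.direction is not None:
            raise InvalidRecordError("direction applies to microRNAs only")
        object.__setattr__(self, "genes", frozenset(self.genes))
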