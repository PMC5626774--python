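"""Gene-signature construction and cross-method / cross-dataset consensus.

Signatures are the top-N up- and top-N down-regulated genes passing a strict
p-value filter, ranked by signed fold change. Two selection methods per
dataset are combined by union (discordant genes dropped with a warning),
and the per-stage consensus keeps genes present in at least ``min_datasets``
datasets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import CodresError, InvalidRecordError
from .model import DEGRecord, GeneSignature

__all__ = [
    "SignatureConfig",
    "select_top_genes",
    "combine_method_lists",
    "CombineResult",
    "ConsensusSignature",
    "stage_consensus_genes",
]


@dataclass(frozen=True)
class SignatureConfig:
    """Selection parameters: list sizes and the (strict) p-value cutoff."""

    n_up: int = 150
    n_down: int = 150
    p_max: float = 0.05

    def __post_init__(self):
        if self.n_up < 1 or self.n_down < 1:
            raise InvalidRecordError("n_up and n_down must be >= 1")
        if not (0 < self.p_max <= 1):
            raise InvalidRecordError("p_max must lie in (0, 1]")


def select_top_genes(table, cfg: SignatureConfig = SignatureConfig()) -> GeneSignature:
    """Top up-/down-regulated genes from a differential-expression table.

    Rows with ``p_value < cfg.p_max`` (strict) are kept; a gene appearing in
    several rows keeps its best-p row. Up-regulated genes (positive fold
    change) are sorted by fold change descending, down-regulated ascending
    (most negative first); ties break by gene symbol. Lists are truncated to
    ``n_up`` / ``n_down``. Genes with fold change exactly 0 are in neither
    list. An empty result is a valid (empty) signature.
    """
    best: dict[str, DEGRecord] = {}
    for rec in table:
        if not isinstance(rec, DEGRecord):
            rec = DEGRecord(*rec)
        if rec.p_value >= cfg.p_max:
            continue
        cur = best.get(rec.gene)
        if cur is None or rec.p_value < cur.p_value:
            best[rec.gene] = rec
    up = sorted(
        (r for r in best.values() if r.fold_change > 0),
        key=lambda r: (-r.fold_change, r.gene),
    )
    down = sorted(
        (r for r in best.values() if r.fold_change < 0),
        key=lambda r: (r.fold_change, r.gene),
    )
    return GeneSignature(
        up=tuple(r.gene for r in up[: cfg.n_up]),
        down=tuple(r.gene for r in down[: cfg.n_down]),
    )


@dataclass(frozen=True)
class CombineResult:
    """Union signature of two selection methods plus the genes dropped for
    being up in one method and down in the other."""

    signature: GeneSignature
    discordant: tuple


def combine_method_lists(a: GeneSignature, b: GeneSignature) -> CombineResult:
    """Union of two per-method signatures (order: a's genes first, then b's
    new ones). A gene up in one method and down in the other is discordant:
    it is excluded from both lists and reported."""
    discordant = (set(a.up) & set(b.down)) | (set(a.down) & set(b.up))
    def merged(xs, ys):
        seen = set()
        out = []
        for g in list(xs) + list(ys):
            if g in discordant or g in seen:
                continue
            seen.add(g)
            out.append(g)
        return tuple(out)

    return CombineResult(
        signature=GeneSignature(up=merged(a.up, b.up), down=merged(a.down, b.down)),
        discordant=tuple(sorted(discordant)),
    )


@dataclass(frozen=True)
class ConsensusSignature:
    """Stage-level consensus: genes in >= min_datasets datasets, with
    per-gene support counts and the subset present in every dataset."""

    signature: GeneSignature
    up_support: dict
    down_support: dict
    in_all: frozenset
    n_datasets: int
    min_datasets: int


def stage_consensus_genes(signatures, min_datasets: int = 2) -> ConsensusSignature:
    """Cross-dataset consensus of per-dataset signatures for one stage.

    A gene enters the consensus up (resp. down) list iff it appears in the
    up (resp. down) list of at least ``min_datasets`` datasets. Genes found
    in every dataset are flagged via ``in_all``.
    """
    signatures = list(signatures)
    if min_datasets < 1:
        raise CodresError("min_datasets must be >= 1")
    if len(signatures) < min_datasets:
        raise CodresError(
            f"need at least {min_datasets} signatures, got {len(signatures)}"
        )
    up_count = Counter(g for s in signatures for g in s.up)
    down_count = Counter(g for s in signatures for g in s.down)
    # A gene up in some datasets and down in others keeps only its majority
    # direction (an exact tie drops it); majority resolution keeps the
    # consensus monotone in min_datasets.
    def qualify(count, other):
        return tuple(sorted(
            (g for g, c in count.items() if c >= min_datasets and c > other.get(g, 0)),
            key=lambda g: (-count[g], g),
        ))

    up = qualify(up_count, down_count)
    down = qualify(down_count, up_count)
    n = len(signatures)
    in_all = frozenset(
        {g for g in up if up_count[g] == n} | {g for g in down if down_count[g] == n}
    )
    return ConsensusSignature(
        signature=GeneSignature(up=up, down=down),
        up_support={g: up_count[g] for g in up},
        down_support={g: down_count[g] for g in down},
        in_all=in_all,
        n_datasets=n,
        min_datasets=min_datasets,
    )
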