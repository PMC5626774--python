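"""Set-consensus utilities: pathway intersections across datasets and
stages, and common-gene-target analysis between drugs and microRNAs."""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

from .errors import CodresError

__all__ = [
    "normalize_pathway",
    "pathway_consensus",
    "cross_stage_intersection",
    "OverlapTriple",
    "common_targets",
    "suppressor_filter",
]


def normalize_pathway(name: str) -> str:
    """Lowercase/trim only; pathway names are compared verbatim otherwise."""
    return " ".join(name.split()).lower()


def pathway_consensus(dataset_lists: dict, min_datasets: int | None = None) -> set:
    """Consensus pathways across datasets.

    ``dataset_lists`` maps dataset -> iterable of per-method pathway lists
    (typically two, one per gene-selection method). Within a dataset the
    method lists are unioned; across datasets a pathway is kept when present
    in at least ``min_datasets`` dataset unions. The default (None) requires
    presence in every dataset, i.e. the full intersection.
    """
    if not dataset_lists:
        return set()
    unions = {
        ds: {normalize_pathway(p) for lst in lists for p in lst}
        for ds, lists in dataset_lists.items()
    }
    if min_datasets is None:
        min_datasets = len(unions)
    if min_datasets < 1:
        raise CodresError("min_datasets must be >= 1")
    count: dict[str, int] = defaultdict(int)
    for ps in unions.values():
        for p in ps:
            count[p] += 1
    return {p for p, c in count.items() if c >= min_datasets}


def cross_stage_intersection(stage_sets: dict) -> dict:
    """Exact Venn partition of >= 2 named sets.

    Returns ``{frozenset of stage names: set of members}`` for every
    nonempty region; region counts sum to the size of the overall union.
    """
    if len(stage_sets) < 2:
        raise CodresError("need at least 2 sets for an intersection diagram")
    regions: dict[frozenset, set] = defaultdict(set)
    universe = set().union(*stage_sets.values())
    for item in universe:
        member_of = frozenset(s for s, items in stage_sets.items() if item in items)
        regions[member_of].add(item)
    return dict(regions)


@dataclass(frozen=True)
class OverlapTriple:
    """One gene targeted by at least one drug and at least one microRNA."""

    gene: str
    drugs: frozenset
    mirnas: frozenset

    def __post_init__(self):
        if not self.drugs or not self.mirnas:
            raise CodresError("emitted triples must have nonempty drug and miRNA sets")
        object.__setattr__(self, "drugs", frozenset(self.drugs))
        object.__setattr__(self, "mirnas", frozenset(self.mirnas))


def common_targets(drug_targets, mirna_targets) -> list:
    """Genes targeted by >= 1 drug and >= 1 microRNA, with the entities
    hitting them. Complete and duplicate-free, sorted by gene."""
    by_gene_drugs: dict[str, set] = defaultdict(set)
    by_gene_mirnas: dict[str, set] = defaultdict(set)
    for ts in drug_targets:
        if ts.entity_kind != "drug":
            raise CodresError(f"{ts.entity}: expected a drug target set")
        for g in ts.genes:
            by_gene_drugs[g].add(ts.entity)
    for ts in mirna_targets:
        if ts.entity_kind != "mirna":
            raise CodresError(f"{ts.entity}: expected a miRNA target set")
        for g in ts.genes:
            by_gene_mirnas[g].add(ts.entity)
    return [
        OverlapTriple(g, frozenset(by_gene_drugs[g]), frozenset(by_gene_mirnas[g]))
        for g in sorted(set(by_gene_drugs) & set(by_gene_mirnas))
    ]


def suppressor_filter(triples, mirna_direction: dict, upregulated) -> list:
    """Keep triples whose gene is up-regulated and is targeted by at least
    one disease-inhibiting microRNA; disease-inducing (and unknown-direction)
    miRNAs are removed from the retained triples.

    A miRNA with no direction entry triggers a warning and is treated as
    unknown (excluded).
    """
    upregulated = set(upregulated)
    out = []
    for t in triples:
        if t.gene not in upregulated:
            continue
        keep = set()
        for m in t.mirnas:
            direction = mirna_direction.get(m)
            if direction is None:
                warnings.warn(f"miRNA {m} has no known disease direction; excluded")
                continue
            if direction == "inhibits_disease":
                keep.add(m)
        if keep:
            out.append(OverlapTriple(t.gene, t.drugs, frozenset(keep)))
    return out
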