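"""The three non-inhibition component scores, each normalized into [0, 1].

All three are batch-relative: the structural and side-effect maxima and the
functional maximum are taken over the supplied batch of drugs, not over
fixed constants. Adding a drug with a heavier penalty to a batch therefore
changes the other drugs' normalized scores -- that behavior is intended and
pinned by tests.
"""

from __future__ import annotations

import math

from .errors import CodresError
from .model import ComponentScores, SideEffectProfile

__all__ = [
    "structural_scores",
    "functional_scores",
    "side_effect_raw",
    "side_effect_scores",
    "assemble_components",
]


def structural_scores(violations) -> dict:
    """Druglikeness penalty score per drug.

    Each violated rule increments the drug's penalty; penalties are divided
    by the batch maximum and the score is that value's distance from 1:
    ``1 - v / v_max``. Drugs with no violations score exactly 1, the
    heaviest violator exactly 0. A batch with no violations anywhere
    (v_max = 0) scores all 1.
    """
    violations = list(violations)
    if not violations:
        raise CodresError("empty violation batch")
    v_max = max(v.violations for v in violations)
    if v_max == 0:
        return {v.drug: 1.0 for v in violations}
    return {v.drug: 1.0 - v.violations / v_max for v in violations}


def functional_scores(evidence) -> dict:
    """Disease-relevance score per drug: mean of its per-target-gene
    enrichment scores (0 for a drug with no targets), divided by the batch
    maximum mean. All-zero batches stay all zero."""
    evidence = list(evidence)
    if not evidence:
        raise CodresError("empty functional-evidence batch")
    means = {
        e.drug: (sum(e.gene_scores) / len(e.gene_scores) if e.gene_scores else 0.0)
        for e in evidence
    }
    top = max(means.values())
    if top == 0:
        return means
    return {d: m / top for d, m in means.items()}


def side_effect_raw(profile: SideEffectProfile) -> int:
    """Raw side-effect burden: sum over the 8 severity classes of
    count x class-index. Not defined for unknown profiles."""
    if profile.unknown:
        raise CodresError(f"{profile.drug}: side effects unknown, raw burden undefined")
    return sum(c * i for i, c in enumerate(profile.counts, start=1))


def side_effect_scores(profiles) -> dict:
    """Side-effect score per drug: ``1 - S / S_max`` over known profiles.

    Drugs with unknown side effects score exactly 0 (worst) -- deliberately
    harsher than a known drug with zero recorded side effects, which scores
    1. A batch whose known profiles all have zero burden scores all 1.
    """
    profiles = list(profiles)
    if not profiles:
        raise CodresError("empty side-effect batch")
    raw = {p.drug: side_effect_raw(p) for p in profiles if not p.unknown}
    s_max = max(raw.values(), default=0)
    out = {}
    for p in profiles:
        if p.unknown:
            out[p.drug] = 0.0
        elif s_max == 0:
            out[p.drug] = 1.0
        else:
            out[p.drug] = 1.0 - raw[p.drug] / s_max
    return out


def assemble_components(
    inhib: dict,
    struct: dict,
    func: dict,
    side: dict,
    drugs=None,
    *,
    default_struct: float | None = None,
    default_func: float | None = None,
    default_side: float | None = None,
) -> list:
    """Join the four per-drug component maps into ComponentScores rows.

    ``drugs`` defaults to the keys of ``inhib``. A missing inhibition entry
    is always an error; the other three components fall back to their
    explicit defaults when configured (e.g. ``default_side=0.0`` for the
    unknown-side-effects policy) and error otherwise. NaN anywhere is
    rejected.
    """
    drugs = list(drugs) if drugs is not None else sorted(inhib)
    out = []
    for d in drugs:
        if d not in inhib:
            raise CodresError(f"{d}: missing inhibition score (no default exists)")
        row = {"inhib": inhib[d]}
        for name, mapping, default in (
            ("struct", struct, default_struct),
            ("func", func, default_func),
            ("side", side, default_side),
        ):
            if d in mapping:
                row[name] = mapping[d]
            elif default is not None:
                row[name] = default
            else:
                raise CodresError(f"{d}: missing {name} score and no default configured")
        if any(isinstance(v, float) and math.isnan(v) for v in row.values()):
            raise CodresError(f"{d}: NaN component")
        out.append(ComponentScores(drug=d, **row))
    return out
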