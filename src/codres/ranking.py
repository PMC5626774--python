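"""The composite score, per-stage ranking, and re-ranking shifts.

The composite is the weighted sum of the four normalized components::

    score = w_is * inhib + w_ss * struct + w_fs * func + w_ses * side

with weights summing to 1, so the composite stays in [0, 1]. Ranks are
descending by score with alphabetical tie-breaking; the re-ranking shift of
a drug is its inhibition-only rank minus its composite rank (positive =
promoted by the composite).
"""

from __future__ import annotations

import math

from .errors import CodresError
from .model import DEFAULT_WEIGHTS, ComponentScores, RankedDrug, WeightVector

__all__ = ["compute_codres", "rank_by_score", "rank_shifts", "score_stage"]


def compute_codres(c: ComponentScores, w: WeightVector = DEFAULT_WEIGHTS) -> float:
    """Weighted sum of the four components of one drug."""
    return w.w_is * c.inhib + w.w_ss * c.struct + w.w_fs * c.func + w.w_ses * c.side


def rank_by_score(scores: dict) -> dict:
    """Dense ranks 1..N, descending by score, ties broken by canonical drug
    name ascending."""
    if not scores:
        raise CodresError("cannot rank an empty score map")
    if any(isinstance(v, float) and math.isnan(v) for v in scores.values()):
        raise CodresError("NaN score in ranking input")
    order = sorted(scores, key=lambda d: (-scores[d], d))
    return {d: i for i, d in enumerate(order, start=1)}


def rank_shifts(inhib: dict, codres: dict) -> list:
    """RankedDrug rows for a shared drug universe, sorted by composite rank.

    ``shift = inhib_rank - codres_rank``; shifts always sum to zero.
    """
    if set(inhib) != set(codres):
        only_i = sorted(set(inhib) - set(codres))
        only_c = sorted(set(codres) - set(inhib))
        raise CodresError(
            f"drug universes differ (inhibition-only: {only_i}, composite-only: {only_c})"
        )
    r_i = rank_by_score(inhib)
    r_c = rank_by_score(codres)
    rows = [
        RankedDrug(
            drug=d,
            codres=codres[d],
            codres_rank=r_c[d],
            inhib_rank=r_i[d],
            shift=r_i[d] - r_c[d],
        )
        for d in codres
    ]
    rows.sort(key=lambda r: r.codres_rank)
    return rows


def score_stage(components, w: WeightVector = DEFAULT_WEIGHTS) -> list:
    """Score and rank one stage's drugs: composite values from the component
    rows, ranks and shifts against the inhibition-only ordering."""
    components = list(components)
    if not components:
        raise CodresError("no component rows supplied")
    inhib = {c.drug: c.inhib for c in components}
    codres = {c.drug: compute_codres(c, w) for c in components}
    return rank_shifts(inhib, codres)
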