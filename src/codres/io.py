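"""Readers and writers for the delimited-table formats of the pipeline.

All tables are UTF-8 CSV or TSV with a header row; the dialect is
auto-detected from the header line (tab wins if present). Reals are
rendered at 3 decimal places (round-half-up) next to a full-precision
column, so rounding never propagates through round-trips.
"""

from __future__ import annotations

import csv
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from .errors import CodresError, TableParseError
from .model import (
    ComponentScores,
    DEGRecord,
    DrugScoreRecord,
    Fingerprint,
    FunctionalEvidence,
    RankedDrug,
    SideEffectProfile,
    TargetSet,
    ViolationCount,
    canonicalize_drug_name,
)

__all__ = [
    "format_3dp",
    "read_drug_scores",
    "write_score_table",
    "read_component_table",
    "read_ranked_table",
    "read_violations",
    "read_functional_evidence",
    "read_side_effects",
    "read_deg_table",
    "read_fingerprints",
    "read_pathway_list",
    "read_target_sets",
    "read_smiles",
]


def format_3dp(x: float) -> str:
    """Render ``x`` with exactly 3 decimal places, rounding half away
    from zero (0.6996 -> "0.700"), matching the printed precision of the
    reference tables."""
    return str(Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def _sniff_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _open_reader(path):
    path = Path(path)
    if not path.exists():
        raise TableParseError(f"input file not found: {path}")
    delim = _sniff_delimiter(path)
    fh = open(path, encoding="utf-8", newline="")
    return fh, csv.DictReader(fh, delimiter=delim)


def _require(reader: csv.DictReader, columns, path):
    have = [c.strip() for c in (reader.fieldnames or [])]
    missing = [c for c in columns if c not in have]
    if missing:
        raise TableParseError(f"{path}: missing column(s) {missing}; header is {have}", row=1)
    return have


def _parse_float(value: str, name: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise TableParseError(f"cannot parse {name}={value!r} as a real", row=row) from None


def read_drug_scores(path) -> list[DrugScoreRecord]:
    """Read a drug/tool/method/dataset/stage/score table.

    Duplicate (drug, tool, method, dataset, stage) keys after name
    canonicalization and out-of-range scores raise :class:`TableParseError`
    naming the offending row. Row order is preserved.
    """
    fh, reader = _open_reader(path)
    with fh:
        _require(reader, ["drug", "tool", "method", "dataset", "stage", "score"], path)
        records, seen = [], {}
        for i, row in enumerate(reader, start=2):
            score = _parse_float(row["score"], "score", i)
            try:
                rec = DrugScoreRecord(
                    drug=row["drug"],
                    tool=row["tool"].strip(),
                    method=row["method"].strip(),
                    dataset=row["dataset"].strip(),
                    stage=row["stage"].strip(),
                    score=score,
                )
            except CodresError as exc:
                raise TableParseError(str(exc), row=i) from exc
            if rec.key in seen:
                raise TableParseError(
                    f"duplicate key {rec.key} (first seen at row {seen[rec.key]})", row=i
                )
            seen[rec.key] = i
            records.append(rec)
    return records


_COMPONENT_COLS = ("inhib", "struct", "func", "side")


def write_score_table(records, path) -> None:
    """Write ComponentScores or RankedDrug records as a deterministic TSV.

    Each real column appears twice: rounded to 3 d.p. for eyeballing and at
    full precision (``*_full``) for lossless round-trips.
    """
    records = list(records)
    if not records:
        raise CodresError("refusing to write an empty score table")
    kinds = {type(r) for r in records}
    if len(kinds) != 1:
        raise CodresError(f"mixed record types: {sorted(k.__name__ for k in kinds)}")
    kind = kinds.pop()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        if kind is ComponentScores:
            writer.writerow(
                ["drug"]
                + [c for col in _COMPONENT_COLS for c in (col, f"{col}_full")]
            )
            for r in records:
                row = [r.drug]
                for col in _COMPONENT_COLS:
                    v = getattr(r, col)
                    row += [format_3dp(v), repr(float(v))]
                writer.writerow(row)
        elif kind is RankedDrug:
            writer.writerow(
                ["drug", "codres", "codres_full", "codres_rank", "inhib_rank", "shift"]
            )
            for r in records:
                writer.writerow(
                    [r.drug, format_3dp(r.codres), repr(float(r.codres)),
                     r.codres_rank, r.inhib_rank, r.shift]
                )
        else:
            raise CodresError(f"unsupported record type {kind.__name__}")


def read_component_table(path) -> list[ComponentScores]:
    fh, reader = _open_reader(path)
    with fh:
        have = _require(reader, ["drug"], path)
        # accept either full-precision or plain columns
        cols = {
            c: (f"{c}_full" if f"{c}_full" in have else c) for c in _COMPONENT_COLS
        }
        for c, src in cols.items():
            if src not in have:
                raise TableParseError(f"{path}: missing column {c}", row=1)
        out = []
        for i, row in enumerate(reader, start=2):
            try:
                out.append(
                    ComponentScores(
                        drug=row["drug"],
                        **{c: _parse_float(row[src], c, i) for c, src in cols.items()},
                    )
                )
            except CodresError as exc:
                raise TableParseError(str(exc), row=i) from exc
    return out


def read_ranked_table(path) -> list[RankedDrug]:
    fh, reader = _open_reader(path)
    with fh:
        have = _require(reader, ["drug", "codres_rank", "inhib_rank", "shift"], path)
        score_col = "codres_full" if "codres_full" in have else "codres"
        if score_col not in have:
            raise TableParseError(f"{path}: missing column codres", row=1)
        out = []
        for i, row in enumerate(reader, start=2):
            try:
                out.append(
                    RankedDrug(
                        drug=row["drug"],
                        codres=_parse_float(row[score_col], "codres", i),
                        codres_rank=int(row["codres_rank"]),
                        inhib_rank=int(row["inhib_rank"]),
                        shift=int(row["shift"]),
                    )
                )
            except CodresError as exc:
                raise TableParseError(str(exc), row=i) from exc
            except ValueError as exc:
                raise TableParseError(str(exc), row=i) from exc
    return out


def read_violations(path) -> list[ViolationCount]:
    """Table: drug, violations."""
    fh, reader = _open_reader(path)
    with fh:
        _require(reader, ["drug", "violations"], path)
        out = []
        for i, row in enumerate(reader, start=2):
            try:
                out.append(ViolationCount(row["drug"], int(row["violations"])))
            except (CodresError, ValueError) as exc:
                raise TableParseError(str(exc), row=i) from exc
    return out


def read_functional_evidence(path) -> list[FunctionalEvidence]:
    """Long-format table drug, gene, score -- one row per targeted gene.

    A drug listed with an empty gene field contributes an empty score list
    (functional mean 0).
    """
    fh, reader = _open_reader(path)
    with fh:
        _require(reader, ["drug", "gene", "score"], path)
        scores: dict[str, list] = {}
        for i, row in enumerate(reader, start=2):
            drug = canonicalize_drug_name(row["drug"])
            scores.setdefault(drug, [])
            if (row["gene"] or "").strip():
                scores[drug].append(_parse_float(row["score"], "score", i))
    return [FunctionalEvidence(d, tuple(v)) for d, v in scores.items()]


def read_side_effects(path) -> list[SideEffectProfile]:
    """Table: drug, c1..c8, unknown (true/false)."""
    cols = [f"c{i}" for i in range(1, 9)]
    fh, reader = _open_reader(path)
    with fh:
        _require(reader, ["drug"] + cols + ["unknown"], path)
        out = []
        for i, row in enumerate(reader, start=2):
            flag = row["unknown"].strip().lower()
            if flag not in {"true", "false", "0", "1"}:
                raise TableParseError(f"unknown flag must be boolean, got {flag!r}", row=i)
            try:
                out.append(
                    SideEffectProfile(
                        drug=row["drug"],
                        counts=tuple(int(row[c]) for c in cols),
                        unknown=flag in {"true", "1"},
                    )
                )
            except (CodresError, ValueError) as exc:
                raise TableParseError(str(exc), row=i) from exc
    return out


def read_deg_table(path, fc_scale: str = "log") -> list[DEGRecord]:
    """Differential-expression table with columns gene, logFC (or FC),
    p_value. If only a ratio-scale FC column is present, ``fc_scale`` must
    be "ratio" and values are converted to log2 scale.
    """
    fh, reader = _open_reader(path)
    with fh:
        have = _require(reader, ["gene", "p_value"], path)
        if "logFC" in have:
            fc_col, convert = "logFC", False
        elif "FC" in have:
            if fc_scale != "ratio":
                raise TableParseError(
                    f"{path}: FC column present but fc_scale={fc_scale!r}; "
                    "declare fc_scale='ratio' to convert", row=1
                )
            fc_col, convert = "FC", True
        else:
            raise TableParseError(f"{path}: need a logFC or FC column", row=1)
        out = []
        for i, row in enumerate(reader, start=2):
            fc = _parse_float(row[fc_col], fc_col, i)
            if convert:
                if fc <= 0:
                    raise TableParseError(f"ratio-scale FC must be > 0, got {fc}", row=i)
                fc = float(np.log2(fc))
            try:
                out.append(DEGRecord(row["gene"].strip(), fc, _parse_float(row["p_value"], "p_value", i)))
            except CodresError as exc:
                raise TableParseError(str(exc), row=i) from exc
    return out


def read_fingerprints(path) -> list[Fingerprint]:
    """Table: drug, bits -- bits as a 0/1 string, all rows equal length."""
    fh, reader = _open_reader(path)
    with fh:
        _require(reader, ["drug", "bits"], path)
        out = []
        for i, row in enumerate(reader, start=2):
            bits = row["bits"].strip()
            if not bits or set(bits) - {"0", "1"}:
                raise TableParseError(f"bits must be a nonempty 0/1 string, got {bits!r}", row=i)
            out.append(Fingerprint(row["drug"], np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")))
    if out and len({len(fp) for fp in out}) > 1:
        raise TableParseError("fingerprints have differing lengths")
    return out


def read_pathway_list(path) -> set[str]:
    """One pathway name per line; lowercased and trimmed, set semantics."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip().lower() for line in fh if line.strip()}


def read_target_sets(path) -> list[TargetSet]:
    """Long-format table entity, entity_kind, gene, direction (mirna only,
    may be empty for drugs)."""
    fh, reader = _open_reader(path)
    with fh:
        _require(reader, ["entity", "entity_kind", "gene"], path)
        acc: dict[tuple, set] = {}
        for i, row in enumerate(reader, start=2):
            kind = row["entity_kind"].strip().lower()
            direction = (row.get("direction") or "").strip().lower() or None
            if kind == "drug":
                direction = None
            key = (row["entity"].strip(), kind, direction)
            acc.setdefault(key, set()).add(row["gene"].strip())
        out = []
        for (entity, kind, direction), genes in acc.items():
            try:
                out.append(TargetSet(entity, frozenset(genes), kind, direction))
            except CodresError as exc:
                raise TableParseError(f"{entity}: {exc}") from exc
    return out


def read_smiles(path) -> list[tuple]:
    """SMILES file, one molecule per line: ``SMILES<TAB>drug``."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise TableParseError("expected SMILES<TAB>drug", row=i)
            out.append((parts[0].strip(), canonicalize_drug_name(parts[1])))
    return out
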