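"""Instrument crosswalk: the many-to-one fusion of assessment items.

A crosswalk bundles four pieces: a registry of instrument versions, the
items (one per question of each source instrument, identified by a short
subject label), the harmonized question bank, and the mappings that send
each source item — and each of its ordinal answer choices — to exactly one
harmonized question and answer code.

Answer codes are 1-based ordinal severities.  When several source scales
of different granularity feed one question, the consolidated scale keeps
the *smallest* source scale size (coarser responses cannot be refined),
and finer source scales collapse their most severe choices onto the top
code.

The translation engine turns a long-format response table into a
children x questions matrix of codes (:class:`RosettaMatrix`), and the
reporting helpers compute the per-leaf fusion summary and the
instrument-overlap matrix.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .hierarchy import Hierarchy

__all__ = [
    "AnswerScale",
    "InstrumentVersion",
    "InstrumentItem",
    "RosettaQuestion",
    "ItemMapping",
    "Crosswalk",
    "CrosswalkParseError",
    "RosettaMatrix",
    "TranslationError",
    "answer_code_count",
    "default_answer_map",
    "validate_crosswalk",
    "translate",
    "overlap_matrix",
    "fusion_summary",
]

Reporter = Literal["clinician", "parent", "teacher", "self"]
Policy = Literal["max", "mean", "first"]


class CrosswalkParseError(ValueError):
    """A crosswalk document that cannot be parsed (distinct from one that
    parses but violates invariants)."""


class TranslationError(ValueError):
    """A response row that the crosswalk cannot translate."""


@dataclass(frozen=True)
class AnswerScale:
    """An ordered answer scale, least to most severe.

    ``kind`` distinguishes descriptive quality-of-behavior scales
    (clinician-administered protocols) from Likert frequency scales
    (rating questionnaires); both are treated as ordinal.
    """

    labels: tuple[str, ...]
    kind: Literal["frequency", "quality"] = "frequency"

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ValueError("an answer scale needs at least 2 choices")

    @property
    def size(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class InstrumentVersion:
    instrument: str
    version: str
    reporter: Reporter
    n_items: int
    default_scale: AnswerScale

    def __post_init__(self):
        if self.n_items <= 0:
            raise ValueError("n_items must be positive")

    @property
    def key(self) -> tuple[str, str]:
        return (self.instrument, self.version)


@dataclass(frozen=True)
class InstrumentItem:
    instrument: str
    version: str
    item_number: str
    subject: str
    scale: AnswerScale

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.instrument, self.version, self.item_number)


@dataclass(frozen=True)
class RosettaQuestion:
    """A harmonized question: one behavioral concept under one leaf."""

    id: str
    leaf: str
    phrasing: str
    code_labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.code_labels) < 2:
            raise ValueError("a question needs at least 2 answer codes")

    @property
    def n_codes(self) -> int:
        return len(self.code_labels)


@dataclass(frozen=True)
class ItemMapping:
    item_key: tuple[str, str, str]
    question_id: str
    answer_map: tuple[int, ...]  # source answer index (1-based) -> code


def answer_code_count(mapped_scale_sizes: Iterable[int]) -> int:
    """Consolidated code count for a question: the minimum source scale
    size among the instruments mapped to it.

    A child assessed only with the coarsest instrument can still populate
    every code, and it cannot be inferred how a respondent would have
    answered had finer choices been offered.
    """
    sizes = list(mapped_scale_sizes)
    if not sizes:
        raise ValueError("no mapped scale sizes given")
    if any(s < 2 for s in sizes):
        raise ValueError("scale sizes must all be >= 2")
    return min(sizes)


def default_answer_map(k: int, m: int) -> tuple[int, ...]:
    """Default collapse of a k-choice source scale onto m codes (k >= m).

    The m-1 least severe source choices map one-to-one; the k-m+1 most
    severe choices all collapse onto the top code m.  No default exists for
    k < m: a coarser source cannot be refined, an explicit map is required.
    """
    if m < 2:
        raise ValueError("code count m must be >= 2")
    if k < m:
        raise ValueError(
            f"no default map from {k} source choices onto {m} codes; "
            "an explicit map is required when the source is coarser"
        )
    return tuple(range(1, m)) + (m,) * (k - m + 1)


class Crosswalk:
    """Registry + items + questions + mappings, with referential queries."""

    def __init__(
        self,
        registry: Iterable[InstrumentVersion],
        items: Iterable[InstrumentItem],
        questions: Iterable[RosettaQuestion],
        mappings: Iterable[ItemMapping],
    ):
        self.registry = list(registry)
        self.items = list(items)
        self.questions = list(questions)
        self.mappings = list(mappings)
        self._item_index = {it.key: it for it in self.items}
        self._question_index = {q.id: q for q in self.questions}
        self._map_index: dict[tuple[str, str, str], list[ItemMapping]] = {}
        for mp in self.mappings:
            self._map_index.setdefault(mp.item_key, []).append(mp)

    # -- lookups ------------------------------------------------------------
    @property
    def instruments(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.registry:
            seen.setdefault(v.instrument, None)
        return list(seen)

    def item(self, key: tuple[str, str, str]) -> InstrumentItem:
        return self._item_index[key]

    def question(self, qid: str) -> RosettaQuestion:
        return self._question_index[qid]

    def mapping_for_item(self, key: tuple[str, str, str]) -> ItemMapping | None:
        maps = self._map_index.get(key, [])
        return maps[0] if maps else None

    def items_for_question(self, qid: str) -> list[InstrumentItem]:
        return [
            self._item_index[mp.item_key]
            for mp in self.mappings
            if mp.question_id == qid and mp.item_key in self._item_index
        ]

    def instruments_for_question(self, qid: str) -> set[str]:
        return {it.instrument for it in self.items_for_question(qid)}

    def code_ranges(self) -> dict[str, int]:
        """question id -> number of codes m."""
        return {q.id: q.n_codes for q in self.questions}

    # -- validation ---------------------------------------------------------
    def validate(self, hierarchy: Hierarchy | None = None) -> list[str]:
        violations: list[str] = []
        version_keys = Counter(v.key for v in self.registry)
        for key, n in version_keys.items():
            if n > 1:
                violations.append(f"duplicate instrument version: {key}")
        item_keys = Counter(it.key for it in self.items)
        for key, n in item_keys.items():
            if n > 1:
                violations.append(f"duplicate item: {key}")
        qids = Counter(q.id for q in self.questions)
        for qid, n in qids.items():
            if n > 1:
                violations.append(f"duplicate question id: {qid}")
        known_versions = set(version_keys)
        for it in self.items:
            if (it.instrument, it.version) not in known_versions:
                violations.append(
                    f"item {it.key} references unregistered version"
                )
        if hierarchy is not None:
            for q in self.questions:
                if q.leaf not in hierarchy:
                    violations.append(
                        f"question {q.id!r} references unknown leaf {q.leaf!r}"
                    )
                elif not hierarchy.is_leaf(q.leaf):
                    violations.append(
                        f"question {q.id!r} hangs on internal node {q.leaf!r}"
                    )
        mapped = Counter(mp.item_key for mp in self.mappings)
        for key, n in mapped.items():
            if n > 1:
                violations.append(f"multiple mapping for item {key}")
        for mp in self.mappings:
            if mp.item_key not in self._item_index:
                violations.append(f"mapping references unknown item {mp.item_key}")
                continue
            if mp.question_id not in self._question_index:
                violations.append(
                    f"mapping of {mp.item_key} references unknown question "
                    f"{mp.question_id!r}"
                )
                continue
            item = self._item_index[mp.item_key]
            q = self._question_index[mp.question_id]
            amap = mp.answer_map
            if len(amap) != item.scale.size:
                violations.append(
                    f"answer map of {mp.item_key} has length {len(amap)}, "
                    f"item scale has {item.scale.size} choices"
                )
            if any(c < 1 or c > q.n_codes for c in amap):
                violations.append(
                    f"answer map of {mp.item_key} leaves code range 1..{q.n_codes}"
                )
            if any(b < a for a, b in zip(amap, amap[1:])):
                violations.append(f"non-monotone answer map for {mp.item_key}")
            if len(amap) >= q.n_codes and set(amap) != set(
                range(1, q.n_codes + 1)
            ):
                violations.append(
                    f"answer map of {mp.item_key} not surjective onto "
                    f"1..{q.n_codes}"
                )
        unmapped = [it.key for it in self.items if it.key not in mapped]
        for key in unmapped:
            violations.append(f"unmapped item: {key}")
        return violations

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        def scale_doc(s: AnswerScale) -> dict:
            return {"kind": s.kind, "labels": list(s.labels)}

        return {
            "format": "rosetta-crosswalk/1",
            "registry": [
                {
                    "instrument": v.instrument,
                    "version": v.version,
                    "reporter": v.reporter,
                    "n_items": v.n_items,
                    "scale": scale_doc(v.default_scale),
                }
                for v in self.registry
            ],
            "items": [
                {
                    "instrument": it.instrument,
                    "version": it.version,
                    "item": it.item_number,
                    "subject": it.subject,
                    "scale": scale_doc(it.scale),
                }
                for it in self.items
            ],
            "questions": [
                {
                    "id": q.id,
                    "leaf": q.leaf,
                    "phrasing": q.phrasing,
                    "code_labels": list(q.code_labels),
                }
                for q in self.questions
            ],
            "mappings": [
                {
                    "instrument": mp.item_key[0],
                    "version": mp.item_key[1],
                    "item": mp.item_key[2],
                    "question": mp.question_id,
                    "answer_map": list(mp.answer_map),
                }
                for mp in self.mappings
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "Crosswalk":
        if not isinstance(doc, dict):
            raise CrosswalkParseError("crosswalk document must be a mapping")
        for section in ("registry", "items", "questions", "mappings"):
            if section not in doc or not isinstance(doc[section], list):
                raise CrosswalkParseError(f"missing or malformed section {section!r}")

        def parse_scale(d: dict) -> AnswerScale:
            try:
                return AnswerScale(labels=tuple(d["labels"]), kind=d.get("kind", "frequency"))
            except (TypeError, KeyError, ValueError) as exc:
                raise CrosswalkParseError(f"malformed answer scale: {d!r}") from exc

        try:
            registry = [
                InstrumentVersion(
                    instrument=e["instrument"],
                    version=e["version"],
                    reporter=e["reporter"],
                    n_items=int(e["n_items"]),
                    default_scale=parse_scale(e["scale"]),
                )
                for e in doc["registry"]
            ]
            version_scale = {v.key: v.default_scale for v in registry}
            items = [
                InstrumentItem(
                    instrument=e["instrument"],
                    version=e["version"],
                    item_number=str(e["item"]),
                    subject=e.get("subject", ""),
                    scale=(
                        parse_scale(e["scale"])
                        if e.get("scale") is not None
                        else version_scale[(e["instrument"], e["version"])]
                    ),
                )
                for e in doc["items"]
            ]
            questions = [
                RosettaQuestion(
                    id=e["id"],
                    leaf=e["leaf"],
                    phrasing=e.get("phrasing", ""),
                    code_labels=tuple(e["code_labels"]),
                )
                for e in doc["questions"]
            ]
            mappings = [
                ItemMapping(
                    item_key=(e["instrument"], e["version"], str(e["item"])),
                    question_id=e["question"],
                    answer_map=tuple(int(c) for c in e["answer_map"]),
                )
                for e in doc["mappings"]
            ]
        except (TypeError, KeyError, ValueError) as exc:
            if isinstance(exc, CrosswalkParseError):
                raise
            raise CrosswalkParseError(f"malformed crosswalk entry: {exc}") from exc
        return cls(registry, items, questions, mappings)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Crosswalk":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CrosswalkParseError(f"not valid JSON: {exc}") from exc
        return cls.from_dict(doc)


def validate_crosswalk(
    cw: Crosswalk, hierarchy: Hierarchy | None = None
) -> list[str]:
    """Functional alias for :meth:`Crosswalk.validate`."""
    return cw.validate(hierarchy)


# ---------------------------------------------------------------------------
# RosettaMatrix and translation
# ---------------------------------------------------------------------------

RESPONSE_COLUMNS = ("child_id", "instrument", "version", "item", "raw")


class RosettaMatrix:
    """Children x harmonized-questions matrix of ordinal codes.

    ``codes`` is a float DataFrame where NaN marks missingness;
    ``code_ranges`` records each question's code count m so values can be
    range-checked and imputed values clamped.
    """

    def __init__(self, codes: pd.DataFrame, code_ranges: dict[str, int]):
        self.codes = codes
        self.code_ranges = dict(code_ranges)

    @property
    def children(self) -> list:
        return list(self.codes.index)

    @property
    def questions(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean observed-mask (True where a code is present)."""
        return self.codes.notna()

    def copy(self) -> "RosettaMatrix":
        return RosettaMatrix(self.codes.copy(), dict(self.code_ranges))

    def check(self) -> list[str]:
        violations = []
        for q in self.codes.columns:
            m = self.code_ranges.get(q)
            if m is None:
                violations.append(f"no code range recorded for {q!r}")
                continue
            col = self.codes[q].dropna()
            bad = col[(col < 1) | (col > m)]
            if len(bad):
                violations.append(
                    f"{len(bad)} value(s) outside 1..{m} in question {q!r}"
                )
        return violations

    def to_csv(self, path, ranges_path=None) -> None:
        self.codes.to_csv(path, index_label="child_id")
        if ranges_path is not None:
            with open(ranges_path, "w") as fh:
                json.dump(self.code_ranges, fh, indent=0)

    @classmethod
    def from_csv(cls, path, code_ranges: dict[str, int] | None = None,
                 ranges_path=None) -> "RosettaMatrix":
        codes = pd.read_csv(path, index_col="child_id")
        if code_ranges is None:
            if ranges_path is not None:
                with open(ranges_path) as fh:
                    code_ranges = {k: int(v) for k, v in json.load(fh).items()}
            else:
                # fall back on the observed maximum per question
                code_ranges = {
                    q: int(np.nanmax(codes[q])) if codes[q].notna().any() else 2
                    for q in codes.columns
                }
        return cls(codes, code_ranges)


def translate(
    cw: Crosswalk, responses: pd.DataFrame, policy: Policy = "max"
) -> RosettaMatrix:
    """Translate a long-format response table into a :class:`RosettaMatrix`.

    ``responses`` columns: child_id, instrument, version, item, raw (1-based
    source answer index).  Each child x question cell aggregates the mapped
    codes of every contributing item response under ``policy``:

    - ``max``: maximum severity (default; preserves the clinical signal and
      never produces fractional codes),
    - ``mean``: mean code rounded half-up to an integer,
    - ``first``: first response in table order.

    Cells with no contributing response stay missing.  Children are taken
    from the response table; questions span the full crosswalk bank.
    """
    if policy not in ("max", "mean", "first"):
        raise ValueError(f"unknown aggregation policy {policy!r}")
    missing_cols = [c for c in RESPONSE_COLUMNS if c not in responses.columns]
    if missing_cols:
        raise TranslationError(f"response table lacks columns {missing_cols}")

    children = list(pd.unique(responses["child_id"]))
    questions = [q.id for q in cw.questions]
    ranges = cw.code_ranges()

    # accumulate codes per (child, question)
    cell_codes: dict[tuple, list[int]] = {}
    for row in responses.itertuples(index=False):
        key = (row.instrument, row.version, str(row.item))
        mapping = cw.mapping_for_item(key)
        if mapping is None:
            raise TranslationError(
                f"unknown item {key} (child {row.child_id!r})"
            )
        item = cw.item(key)
        raw = int(row.raw)
        if not 1 <= raw <= item.scale.size:
            raise TranslationError(
                f"raw answer {raw} outside 1..{item.scale.size} for item "
                f"{key} (child {row.child_id!r})"
            )
        code = mapping.answer_map[raw - 1]
        cell_codes.setdefault((row.child_id, mapping.question_id), []).append(code)

    codes = pd.DataFrame(
        np.nan, index=pd.Index(children, name="child_id"), columns=questions
    )
    for (child, qid), vals in cell_codes.items():
        if policy == "max":
            agg = max(vals)
        elif policy == "mean":
            agg = int(np.floor(np.mean(vals) + 0.5))
        else:
            agg = vals[0]
        codes.at[child, qid] = float(agg)
    return RosettaMatrix(codes, ranges)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def overlap_matrix(cw: Crosswalk) -> tuple[pd.DataFrame, pd.Series]:
    """Instrument x instrument question-overlap counts.

    Off-diagonal (i, j): questions with mapped items from both i and j.
    Diagonal (i, i): questions whose items all come from i alone.  The
    totals series counts questions touching each instrument at all.
    Counting is at instrument level, not version level.
    """
    instruments = cw.instruments
    qsets = {q.id: cw.instruments_for_question(q.id) for q in cw.questions}
    mat = pd.DataFrame(0, index=instruments, columns=instruments, dtype=int)
    totals = pd.Series(0, index=instruments, dtype=int, name="total")
    for insts in qsets.values():
        for i in insts:
            totals[i] += 1
            if len(insts) == 1:
                mat.at[i, i] += 1
        for i in insts:
            for j in insts:
                if i != j:
                    mat.at[i, j] += 1
    return mat, totals


def fusion_summary(
    cw: Crosswalk, hierarchy: Hierarchy | None = None
) -> pd.DataFrame:
    """Per-leaf fusion counts: overlapping instruments, mapped items,
    resulting questions — with a TOTAL row.

    Instruments are counted at instrument level (a preschool and an
    adolescent form of one questionnaire count once).  When a hierarchy is
    given, its leaves with no mapped questions appear as (0, 0, 0) rows.
    """
    leaves: list[str] = []
    if hierarchy is not None:
        leaves = [leaf.id for leaf in hierarchy.leaves]
    for q in cw.questions:
        if q.leaf not in leaves:
            leaves.append(q.leaf)

    rows = []
    for leaf in leaves:
        qids = [q.id for q in cw.questions if q.leaf == leaf]
        insts: set[str] = set()
        n_items = 0
        for qid in qids:
            items = cw.items_for_question(qid)
            n_items += len(items)
            insts |= {it.instrument for it in items}
        rows.append((leaf, len(insts), n_items, len(qids)))
    out = pd.DataFrame(
        rows, columns=["leaf", "n_instruments", "n_items", "n_questions"]
    ).set_index("leaf")
    total = pd.DataFrame(
        {
            "n_instruments": [len({it.instrument for it in cw.items
                                   if cw.mapping_for_item(it.key) is not None})],
            "n_items": [out["n_items"].sum()],
            "n_questions": [out["n_questions"].sum()],
        },
        index=pd.Index(["TOTAL"], name="leaf"),
    )
    return pd.concat([out, total])
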