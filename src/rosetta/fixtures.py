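"""Packaged fixtures: the default hierarchy, the Generation-1 question
manifest, the instrument registry, the adaptability crosswalk excerpt and
the case-study feature list.

Item subject labels marked ``(synthetic)`` in the adaptability excerpt are
stand-ins constructed to fill out the counted item volume; the remaining
labels are abbreviated topic descriptions, never source item wording.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .crosswalk import AnswerScale, Crosswalk, InstrumentVersion
from .hierarchy import Hierarchy

__all__ = ["load_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "hierarchy",
    "question_manifest",
    "instrument_registry",
    "adaptability_excerpt",
    "case_study_features",
)

_FILES = {
    "hierarchy": "hierarchy.json",
    "question_manifest": "question_manifest.json",
    "instrument_registry": "instrument_registry.json",
    "adaptability_excerpt": "adaptability_excerpt.json",
    "case_study_features": "case_study_features.json",
}


def _read(name: str) -> dict:
    ref = resources.files("rosetta").joinpath("data", _FILES[name])
    return json.loads(ref.read_text())


def parse_registry(doc: dict) -> list[InstrumentVersion]:
    return [
        InstrumentVersion(
            instrument=e["instrument"],
            version=e["version"],
            reporter=e["reporter"],
            n_items=int(e["n_items"]),
            default_scale=AnswerScale(
                labels=tuple(e["scale"]["labels"]), kind=e["scale"]["kind"]
            ),
        )
        for e in doc["registry"]
    ]


def load_fixture(name: str):
    """Load a packaged fixture by name.

    Returns a :class:`~rosetta.hierarchy.Hierarchy` for ``"hierarchy"``, a
    :class:`~rosetta.crosswalk.Crosswalk` for ``"adaptability_excerpt"``, a
    list of :class:`~rosetta.crosswalk.InstrumentVersion` for
    ``"instrument_registry"``, a manifest dict (``total_questions`` plus a
    leaf -> question-id-list map) for ``"question_manifest"``, and a
    DataFrame (columns ``id``, ``subject``) for ``"case_study_features"``.
    """
    if name not in _FILES:
        raise KeyError(
            f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}"
        )
    doc = _read(name)
    if name == "hierarchy":
        return Hierarchy.from_dict(doc)
    if name == "question_manifest":
        return {"total_questions": doc["total_questions"],
                "leaves": doc["leaves"]}
    if name == "instrument_registry":
        return parse_registry(doc)
    if name == "adaptability_excerpt":
        return Crosswalk.from_dict(doc)
    return pd.DataFrame(doc["features"], columns=["id", "subject"])
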