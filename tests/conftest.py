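"""Shared fixtures: packaged objects, small simulated cohorts, and random
toy crosswalks for oracle comparisons."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import rosetta
from rosetta.crosswalk import (
    AnswerScale,
    Crosswalk,
    InstrumentItem,
    InstrumentVersion,
    ItemMapping,
    RosettaQuestion,
    default_answer_map,
)


@pytest.fixture(scope="session")
def hierarchy():
    return rosetta.build_default_hierarchy()


@pytest.fixture(scope="session")
def adaptability():
    return rosetta.load_fixture("adaptability_excerpt")


@pytest.fixture(scope="session")
def synth_cw():
    return rosetta.synthetic_crosswalk(seed=1)


@pytest.fixture(scope="session")
def small_cohort(synth_cw):
    """A 220-child cohort (110/55/55) with its translated matrix and
    aligned labels — shared by imputation and classification tests."""
    cfg = rosetta.CohortConfig(n_autism=110, n_adhd=55, n_neither=55, seed=11)
    cohort = rosetta.simulate_cohort(synth_cw, cfg)
    matrix = rosetta.translate(synth_cw, cohort.responses)
    labels = cohort.truth.set_index("child_id")["condition"].reindex(
        matrix.codes.index
    )
    return cohort, matrix, labels


def make_toy_crosswalk(rng: np.random.Generator) -> Crosswalk:
    """A small random complete crosswalk (3-5 instruments, 4-8 questions)
    with default severe-end answer maps."""
    n_inst = int(rng.integers(3, 6))
    scales = [AnswerScale(tuple(f"a{i}" for i in range(k))) for k in (3, 4, 5)]
    registry = [
        InstrumentVersion(
            instrument=f"I{i}", version="v1", reporter="parent",
            n_items=20, default_scale=scales[int(rng.integers(3))],
        )
        for i in range(n_inst)
    ]
    leaves = ["Somatic/Sleep", "Somatic/Fatigue", "Motor/Fine"]
    n_q = int(rng.integers(4, 9))
    questions, items, mappings = [], [], []
    counters = {v.key: 0 for v in registry}
    for q in range(n_q):
        cover = rng.random(n_inst) < 0.5
        if not cover.any():
            cover[int(rng.integers(n_inst))] = True
        versions = [v for v, c in zip(registry, cover) if c]
        m = min(v.default_scale.size for v in versions)
        questions.append(RosettaQuestion(
            id=f"Q{q}", leaf=leaves[q % len(leaves)], phrasing="",
            code_labels=tuple(f"c{i}" for i in range(m)),
        ))
        for v in versions:
            # one or two items from this version
            for _ in range(int(rng.integers(1, 3))):
                counters[v.key] += 1
                num = f"n{counters[v.key]}"
                items.append(InstrumentItem(
                    instrument=v.instrument, version=v.version,
                    item_number=num, subject="toy", scale=v.default_scale,
                ))
                mappings.append(ItemMapping(
                    item_key=(v.instrument, v.version, num), question_id=f"Q{q}",
                    answer_map=default_answer_map(v.default_scale.size, m),
                ))
    return Crosswalk(registry, items, questions, mappings)


def brute_force_overlap(cw: Crosswalk):
    """Exhaustive per-question instrument-set intersection oracle."""
    instruments = cw.instruments
    qsets = []
    for q in cw.questions:
        insts = set()
        for mp in cw.mappings:
            if mp.question_id == q.id:
                insts.add(mp.item_key[0])
        qsets.append(insts)
    mat = pd.DataFrame(0, index=instruments, columns=instruments, dtype=int)
    totals = pd.Series(0, index=instruments, dtype=int)
    for i in instruments:
        totals[i] = sum(1 for s in qsets if i in s)
        mat.loc[i, i] = sum(1 for s in qsets if s == {i})
        for j in instruments:
            if i != j:
                mat.loc[i, j] = sum(1 for s in qsets if i in s and j in s)
    return mat, totals


def brute_force_fusion(cw: Crosswalk):
    """Group-by oracle for per-leaf (instruments, items, questions)."""
    rows = {}
    for q in cw.questions:
        rec = rows.setdefault(q.leaf, {"insts": set(), "items": 0, "qs": 0})
        rec["qs"] += 1
        for mp in cw.mappings:
            if mp.question_id == q.id:
                rec["items"] += 1
                rec["insts"].add(mp.item_key[0])
    return {
        leaf: (len(r["insts"]), r["items"], r["qs"]) for leaf, r in rows.items()
    }
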