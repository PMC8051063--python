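"""Synthetic multi-instrument cohort simulator.

Emulates the data regime the harmonized-questionnaire case study assumes:
children carry a latent condition (autism, ADHD or neither) that shifts
leaf-level severities; each child completes only one or two instrument
versions (block missingness); each completed item yields an ordinal raw
answer on its native scale by thresholding the child's leaf severity at
equally spaced cut-points (a graded-response-style ordinal model).

The generator is a stand-in for unavailable clinical data: it reproduces
the structural features (class imbalance, 15 instrument versions with
little overlap, ordinal native scales) but makes no claim about real
symptom prevalence or instrument norms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crosswalk import (
    Crosswalk,
    InstrumentItem,
    ItemMapping,
    RosettaMatrix,
    RosettaQuestion,
    default_answer_map,
)
from .hierarchy import Hierarchy

__all__ = [
    "CohortConfig",
    "SimulatedCohort",
    "default_effects",
    "simulate_cohort",
    "mask_holdout",
    "synthetic_crosswalk",
]

CONDITIONS = ("autism", "adhd", "neither")

# latent severity range spanned by the ordinal cut-points; the range sits
# above the unaffected baseline (theta = 0) so that typical children
# concentrate in the least-severe codes, matching the right skew of
# symptom scales in general-population samples
_LATENT_LO, _LATENT_HI = 0.0, 3.0

# default severity shifts (latent SD units): a strong-contrast regime in
# which the latent classes are nearly separable, so downstream losses are
# attributable to harmonization, discretization and missingness
AUTISM_SHIFT = 2.0
ADHD_SHIFT = 2.0
AUTISM_ATTENTION_SHIFT = 0.3

_AUTISM_GROUPS = (
    "Cognitive/Behavioral/Social",
    "Cognitive/Behavioral/Sensory",
    "Cognitive/Language & Communication",
)
_ADHD_LEAF_NAMES = ("Attention", "Hyperactivity", "Impulsivity")


@dataclass
class CohortConfig:
    """Desk-scale default: 750 children split 588 / 69 / 89, preserving the
    case-study class ratios at roughly one fifth of its size."""

    n_autism: int = 588
    n_adhd: int = 69
    n_neither: int = 89
    effects: pd.DataFrame | None = None  # leaf x condition severity shifts
    noise_sd: float = 1.0
    item_noise_sd: float = 0.5
    instruments_per_child: tuple[int, int] = (1, 2)
    version_weights: dict[tuple[str, str], float] | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.n_autism, self.n_adhd, self.n_neither) < 0:
            raise ValueError("class counts must be >= 0")
        if self.noise_sd <= 0 or self.item_noise_sd <= 0:
            raise ValueError("noise standard deviations must be > 0")
        lo, hi = self.instruments_per_child
        if not 1 <= lo <= hi:
            raise ValueError("instruments_per_child must satisfy 1 <= lo <= hi")

    @property
    def n_total(self) -> int:
        return self.n_autism + self.n_adhd + self.n_neither


@dataclass
class SimulatedCohort:
    truth: pd.DataFrame        # child_id, condition
    theta: pd.DataFrame        # index child_id, columns leaf ids
    assignments: pd.DataFrame  # child_id, instrument, version
    responses: pd.DataFrame    # child_id, instrument, version, item, raw


def default_effects(leaves: list[str] | None = None) -> pd.DataFrame:
    """Leaf x condition table of latent severity shifts.

    Autism shifts the social, sensory and language/communication leaves by
    ``AUTISM_SHIFT`` (plus a small ``AUTISM_ATTENTION_SHIFT`` on the
    attention-related leaves, reflecting shared attentional load); ADHD
    shifts the executive-functioning attention / hyperactivity /
    impulsivity leaves by ``ADHD_SHIFT``; the neither class has all-zero
    shifts.
    """
    if leaves is None:
        from .fixtures import load_fixture

        hierarchy: Hierarchy = load_fixture("hierarchy")
        leaves = [n.id for n in hierarchy.leaves]
    eff = pd.DataFrame(0.0, index=pd.Index(leaves, name="leaf"),
                       columns=list(CONDITIONS))
    for leaf in leaves:
        name = leaf.rsplit("/", 1)[-1]
        if any(leaf.startswith(g + "/") for g in _AUTISM_GROUPS):
            eff.at[leaf, "autism"] = AUTISM_SHIFT
        if (leaf.startswith("Cognitive/Executive Functioning/")
                and name in _ADHD_LEAF_NAMES + ("Memory",)):
            eff.at[leaf, "adhd"] = ADHD_SHIFT
            eff.at[leaf, "autism"] = AUTISM_ATTENTION_SHIFT
    return eff


def _cutpoints(k: int) -> np.ndarray:
    """k-1 equally spaced thresholds over the latent range, for a k-point
    scale."""
    span = _LATENT_HI - _LATENT_LO
    return _LATENT_LO + span * np.arange(1, k) / k


def simulate_cohort(cw: Crosswalk, config: CohortConfig) -> SimulatedCohort:
    """Draw a full cohort: latent severities, instrument-version
    assignments, and long-format raw responses.

    Three independent random streams (severities, assignments, responses)
    are spawned from the single seed, so changing the assignment settings
    does not perturb the severity draws.
    """
    if not cw.questions or not cw.items:
        raise ValueError("cannot simulate from an empty crosswalk")
    leaves = sorted({q.leaf for q in cw.questions})
    effects = config.effects if config.effects is not None else default_effects(leaves)
    missing = [leaf for leaf in leaves if leaf not in effects.index]
    if missing:
        raise ValueError(f"effects table lacks leaves: {missing}")

    ss = np.random.SeedSequence(config.seed)
    theta_rng, assign_rng, resp_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    n = config.n_total
    conditions = np.array(
        ["autism"] * config.n_autism
        + ["adhd"] * config.n_adhd
        + ["neither"] * config.n_neither
    )
    child_ids = np.array([f"C{i:05d}" for i in range(1, n + 1)])
    truth = pd.DataFrame({"child_id": child_ids, "condition": conditions})

    shift = np.vstack([
        effects.loc[leaves, cond].to_numpy(dtype=float) for cond in conditions
    ])
    theta_vals = shift + theta_rng.normal(0.0, config.noise_sd, size=(n, len(leaves)))
    theta = pd.DataFrame(theta_vals, index=pd.Index(child_ids, name="child_id"),
                         columns=leaves)

    # ---- instrument-version assignment (block missingness) ---------------
    version_keys = [v.key for v in cw.registry]
    weights = np.ones(len(version_keys))
    if config.version_weights:
        weights = np.array(
            [config.version_weights.get(k, 1.0) for k in version_keys], float
        )
    weights = weights / weights.sum()
    lo, hi = config.instruments_per_child
    hi = min(hi, len(version_keys))
    counts = assign_rng.integers(lo, hi + 1, size=n)
    assigned: list[list[tuple[str, str]]] = []
    for i in range(n):
        idx = assign_rng.choice(len(version_keys), size=counts[i],
                                replace=False, p=weights)
        assigned.append([version_keys[j] for j in sorted(idx)])
    assignments = pd.DataFrame(
        [(cid, inst, ver) for cid, vs in zip(child_ids, assigned)
         for inst, ver in vs],
        columns=["child_id", "instrument", "version"],
    )

    # ---- ordinal responses ------------------------------------------------
    by_version: dict[tuple[str, str], list[int]] = {}
    for i, vs in enumerate(assigned):
        for key in vs:
            by_version.setdefault(key, []).append(i)
    leaf_pos = {leaf: j for j, leaf in enumerate(leaves)}

    rec_child, rec_inst, rec_ver, rec_item, rec_raw = [], [], [], [], []
    for key in version_keys:  # fixed registry order for determinism
        rows = by_version.get(key)
        if not rows:
            continue
        rows = np.array(rows)
        for item in cw.items:
            if (item.instrument, item.version) != key:
                continue
            mapping = cw.mapping_for_item(item.key)
            if mapping is None:
                continue
            leaf = cw.question(mapping.question_id).leaf
            z = theta_vals[rows, leaf_pos[leaf]] + resp_rng.normal(
                0.0, config.item_noise_sd, size=len(rows)
            )
            k = item.scale.size
            raw = 1 + (z[:, None] > _cutpoints(k)[None, :]).sum(axis=1)
            rec_child.extend(child_ids[rows])
            rec_inst.extend([item.instrument] * len(rows))
            rec_ver.extend([item.version] * len(rows))
            rec_item.extend([item.item_number] * len(rows))
            rec_raw.extend(raw.tolist())
    responses = pd.DataFrame({
        "child_id": rec_child, "instrument": rec_inst, "version": rec_ver,
        "item": rec_item, "raw": rec_raw,
    })
    return SimulatedCohort(truth=truth, theta=theta,
                           assignments=assignments, responses=responses)


def mask_holdout(
    matrix: RosettaMatrix, fraction: float, seed: int
) -> tuple[RosettaMatrix, pd.DataFrame]:
    """Hide ``floor(fraction * n_observed)`` observed cells uniformly at
    random, returning the masked matrix and the held-out cells
    (child_id, question, value) for later scoring."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    obs_rows, obs_cols = np.nonzero(matrix.mask.to_numpy())
    n_hide = int(np.floor(fraction * len(obs_rows)))
    pick = rng.choice(len(obs_rows), size=n_hide, replace=False)
    masked = matrix.copy()
    vals = masked.codes.to_numpy()
    records = []
    for p in pick:
        i, j = obs_rows[p], obs_cols[p]
        records.append((masked.codes.index[i], masked.codes.columns[j],
                        float(vals[i, j])))
        vals[i, j] = np.nan
    masked.codes = pd.DataFrame(vals, index=matrix.codes.index,
                                columns=matrix.codes.columns)
    heldout = pd.DataFrame(records, columns=["child_id", "question", "value"])
    return masked, heldout


# ---------------------------------------------------------------------------
# Synthetic complete crosswalk (pipeline input when no real crosswalk given)
# ---------------------------------------------------------------------------

# questions per leaf for the synthetic bank: condition-relevant leaves plus
# neutral background leaves
_SYNTH_BANK: tuple[tuple[str, int], ...] = (
    ("Cognitive/Behavioral/Social/Withdrawal", 2),
    ("Cognitive/Behavioral/Social/Eye Contact", 1),
    ("Cognitive/Behavioral/Social/Group Play", 1),
    ("Cognitive/Behavioral/Social/Shared Interests", 2),
    ("Cognitive/Behavioral/Social/Atypicality", 2),
    ("Cognitive/Behavioral/Sensory/Intrigued", 1),
    ("Cognitive/Language & Communication/Expressive", 2),
    ("Cognitive/Language & Communication/Receptive", 1),
    ("Cognitive/Language & Communication/Speech", 1),
    ("Cognitive/Executive Functioning/Attention", 3),
    ("Cognitive/Executive Functioning/Hyperactivity", 2),
    ("Cognitive/Executive Functioning/Impulsivity", 2),
    ("Cognitive/Executive Functioning/Memory", 1),
    ("Cognitive/Behavioral/Emotional/Mood", 1),
    ("Cognitive/Behavioral/Emotional/Anxiety", 1),
    ("Somatic/Sleep", 1),
    ("Somatic/Gastrointestinal", 1),
    ("Motor/Fine", 1),
)


def synthetic_crosswalk(seed: int = 0, coverage: float = 0.6) -> Crosswalk:
    """A deterministic synthetic complete crosswalk over the full packaged
    15-version registry.

    Each of the 26 bank questions receives one item from every version
    selected with probability ``coverage`` (at least three versions per
    question), so instruments overlap heavily on the bank — the regime the
    harmonization exists to create.  Answer maps follow the default
    severe-end collapse onto the minimum mapped scale size.
    """
    from .fixtures import load_fixture

    registry = load_fixture("instrument_registry")
    rng = np.random.default_rng(seed)

    questions: list[RosettaQuestion] = []
    items: list[InstrumentItem] = []
    mappings: list[ItemMapping] = []
    counters = {v.key: 0 for v in registry}

    qdefs = []
    for leaf, n_q in _SYNTH_BANK:
        prefix = "Cognoa_" + "_".join(
            "".join(p.split()).replace("&", "") for p in leaf.split("/")
        )
        for t in range(1, n_q + 1):
            qdefs.append((f"{prefix}_Syn{t}", leaf))

    for qid, leaf in qdefs:
        cover = rng.random(len(registry)) < coverage
        while cover.sum() < 3:
            cover[rng.integers(len(registry))] = True
        versions = [v for v, c in zip(registry, cover) if c]
        m = min(v.default_scale.size for v in versions)
        labels = tuple(f"code {c}" for c in range(1, m + 1))
        questions.append(
            RosettaQuestion(id=qid, leaf=leaf,
                            phrasing=f"synthetic question for {leaf}",
                            code_labels=labels)
        )
        for v in versions:
            counters[v.key] += 1
            num = f"S{counters[v.key]}"
            items.append(
                InstrumentItem(instrument=v.instrument, version=v.version,
                               item_number=num,
                               subject=f"{qid} (synthetic)",
                               scale=v.default_scale)
            )
            mappings.append(
                ItemMapping(item_key=(v.instrument, v.version, num),
                            question_id=qid,
                            answer_map=default_answer_map(v.default_scale.size, m))
            )
    return Crosswalk(registry, items, questions, mappings)
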