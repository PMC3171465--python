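"""ROC evaluation of a specialization ranking against annotated residues.

Two x-axis conventions are supported.  The ``non_positive`` mode counts every
scored residue outside the positive set — including residues never tested
experimentally — in the x-axis denominator; it is the honest convention when
true negatives are unknown.  The ``confirmed_negative`` mode is the standard
false-positive rate over experimentally confirmed non-specific residues only.

Positions fully conserved across all groups are excluded from the positive
set when the alignment is available: a residue identical in every group
cannot, by construction, confer group specificity.

Ties in the ranking are swept as a single threshold step, which makes the
trapezoid area equal to the probability that a random positive outranks a
random negative, counting ties as one half.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EvaluationError, InputError
from .msa_io import GroupedAlignment
from .specialization import (
    COMBINERS,
    ScorerSpec,
    rank_positions,
    rank_by_mutual_information,
)

MODES = ("non_positive", "confirmed_negative")


@dataclass(frozen=True)
class ResidueAnnotation:
    """Experimentally annotated positions (0-based) within a scored universe."""

    positives: frozenset[int]
    negatives: frozenset[int]
    universe: frozenset[int]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise InputError("positions annotated both positive and negative")
        if not (self.positives <= self.universe and self.negatives <= self.universe):
            raise InputError("annotated positions outside the scored universe")


def family_conserved_positions(ga: GroupedAlignment) -> set[int]:
    """Columns occupied by a single residue type across the whole family."""
    out = set()
    for pos in range(ga.n_positions):
        residues = {
            row[pos] for row in ga.rows if row[pos] not in ("-", "X")
        }
        if len(residues) == 1:
            out.add(pos)
    return out


def make_annotation(
    labels: Mapping[int, str],
    universe: Iterable[int],
    ga: GroupedAlignment | None = None,
) -> ResidueAnnotation:
    """Build an annotation from position→{positive,negative} labels.

    When the alignment is given, positions conserved across all groups are
    dropped from the positive set.
    """
    universe = frozenset(universe)
    pos = {p for p, lab in labels.items() if lab == "positive"} & universe
    neg = {p for p, lab in labels.items() if lab == "negative"} & universe
    if ga is not None:
        pos -= family_conserved_positions(ga)
    return ResidueAnnotation(frozenset(pos), frozenset(neg), universe)


@dataclass(frozen=True)
class ROCResult:
    points: tuple[tuple[float, float], ...]
    auc: float
    mode: str


def roc_curve(
    ranking: pd.DataFrame | Sequence[tuple[int, float]],
    annotation: ResidueAnnotation,
    mode: str = "non_positive",
) -> ROCResult:
    """Threshold sweep down a ranked position list.

    ``ranking`` is either the DataFrame from :func:`rank_positions` (columns
    ``position`` and ``score``, smaller = more specific) or a sequence of
    (position, score) pairs.  y is the true-positive rate; x is the fraction
    of non-positives (or of confirmed negatives) at or above the threshold.
    """
    if mode not in MODES:
        raise InputError(f"unknown ROC mode {mode!r}")
    if isinstance(ranking, pd.DataFrame):
        pairs = list(zip(ranking["position"].astype(int), ranking["score"].astype(float)))
    else:
        pairs = [(int(p), float(s)) for p, s in ranking]
    scored = {p for p, _ in pairs}
    if not annotation.universe <= scored:
        raise InputError("ranking does not cover the annotated universe")
    pairs = [(p, s) for p, s in pairs if p in annotation.universe]
    positives = annotation.positives
    if not positives:
        raise EvaluationError("positive set is empty")
    if mode == "confirmed_negative":
        denom_set = annotation.negatives
        if not denom_set:
            raise EvaluationError("confirmed_negative mode needs a non-empty negative set")
    else:
        denom_set = annotation.universe - positives

    pairs.sort(key=lambda ps: (ps[1], ps[0]))
    n_pos, n_den = len(positives), len(denom_set)
    points = [(0.0, 0.0)]
    tp = den = 0
    i = 0
    while i < len(pairs):
        j = i
        while j < len(pairs) and pairs[j][1] == pairs[i][1]:
            if pairs[j][0] in positives:
                tp += 1
            if pairs[j][0] in denom_set:
                den += 1
            j += 1
        points.append((den / n_den, tp / n_pos))
        i = j
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    area = float(np.trapezoid(ys, xs))
    return ROCResult(points=tuple(points), auc=area, mode=mode)


def auc(roc: ROCResult) -> float:
    """Trapezoid area under the curve; equals the pairwise-comparison
    probability that a random positive outranks a random negative (ties ½)."""
    return roc.auc


def method_sweep(
    ga: GroupedAlignment,
    annotation: ResidueAnnotation,
    conservation_ids: Sequence[str] = ("e", "r", "j", "0"),
    overlap_ids: Sequence[str] = ("o", "f", "r", "m"),
    combiners: Sequence[str] = COMBINERS,
    models: Sequence[str] = ("determinant", "discriminant"),
    target_group: str | None = None,
    mode: str = "non_positive",
    model_data=None,
    include_mi: bool = False,
) -> pd.DataFrame:
    """AUC for every scorer in a grid, sorted by decreasing area.

    The target for determinant scorers defaults to the family's first group.
    With ``include_mi`` the multi-group mutual-information baseline is added
    as one extra row.
    """
    from .msa_io import column_profiles
    from .rate_model import effective_time, load_rate_matrix

    if model_data is None:
        model_data = load_rate_matrix()
    if target_group is None:
        target_group = ga.groups[0]
    profiles = column_profiles(ga)
    t_eff = effective_time([p for p in profiles if not p.empty], model_data)

    rows = []
    for cid, oid, comb, mdl in itertools.product(
        conservation_ids, overlap_ids, combiners, models
    ):
        spec = ScorerSpec(
            cid, oid, comb, mdl, target_group if mdl == "determinant" else None
        )
        df = rank_positions(ga, spec, model_data, t_eff=t_eff, profiles=profiles)
        roc = roc_curve(df, annotation, mode)
        rows.append(
            {
                "scorer": spec.identifier,
                "model": mdl,
                "auc": roc.auc,
            }
        )
    if include_mi:
        df = rank_by_mutual_information(ga, profiles)
        roc = roc_curve(df, annotation, mode)
        rows.append({"scorer": "mi", "model": "mutual_information", "auc": roc.auc})
    out = pd.DataFrame(rows).sort_values(
        "auc", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    out.attrs["t_eff"] = t_eff
    out.attrs["mode"] = mode
    return out
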