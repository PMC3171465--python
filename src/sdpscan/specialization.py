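"""Combined specialization scores: the conservation/overlap cube made operational.

Each scored column carries a triplet of coordinates — one conservation value
per group (1 = fully conserved) and one overlap value per group pair (1 =
identical distributions).  The cube's corners name the behaviors of interest:
all-conserved same type (1,1,1), discriminant "constant but different"
(1,1,0), determinant of group g (conserved in g only, overlap with g low),
and the fully variable position (0,0,1).

A scorer is a point in a small grammar: a conservation id, an overlap id and
a combiner letter (``e`` Euclidean, ``l`` linear), e.g. ``"rol"``, plus an
evolutionary model that picks which penalty terms enter:

* ``discriminant`` — penalizes lack of conservation in EVERY group and
  overlap in EVERY pair (the constant-but-different assumption);
* ``determinant`` — penalizes lack of conservation only in the target group
  and overlap only for pairs involving the target; how the other groups
  evolve is immaterial;
* ``conservation_only`` — distance from the all-conserved corner;
* ``nonconserved_nonoverlap`` — proximity to the non-conserved,
  non-overlapping corner (kept for completeness; not a good strategy in
  practice).

Smaller combined score = more specific.  Both combiners divide by the number
of penalty terms (Euclidean: root-mean-square, linear: mean) so scores lie in
[0,1]; rankings — the contract here — are unaffected by such constants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .conservation import CONSERVATION_IDS, raw_conservation, rescale_within_group
from .errors import ConfigError, InputError
from .msa_io import ColumnProfile, GroupedAlignment, column_profiles, profiles_by_position
from .overlap import OVERLAP_IDS, orient_and_rescale, raw_overlap, mutual_information
from .rate_model import RateModel, ancestral_type, effective_time, load_rate_matrix

MODELS = ("determinant", "discriminant", "conservation_only", "nonconserved_nonoverlap")
COMBINERS = ("e", "l")


@dataclass(frozen=True)
class ScorerSpec:
    """One point in the scorer space, e.g. ScorerSpec.parse("rol", "determinant", "G1")."""

    conservation_id: str
    overlap_id: str
    combiner: str
    model: str
    target_group: str | None = None

    def __post_init__(self) -> None:
        if self.conservation_id not in CONSERVATION_IDS:
            raise ConfigError(f"unknown conservation id {self.conservation_id!r}")
        if self.overlap_id not in OVERLAP_IDS:
            raise ConfigError(f"unknown overlap id {self.overlap_id!r}")
        if self.combiner not in COMBINERS:
            raise ConfigError(f"unknown combiner {self.combiner!r}")
        if self.model not in MODELS:
            raise ConfigError(f"unknown model {self.model!r}")
        if self.model == "determinant" and self.target_group is None:
            raise ConfigError("determinant model requires a target group")

    @property
    def identifier(self) -> str:
        """Three-letter grammar string (conservation + overlap + combiner)."""
        ovl = self.overlap_id if len(self.overlap_id) == 1 else f"({self.overlap_id})"
        return f"{self.conservation_id}{ovl}{self.combiner}"

    @classmethod
    def parse(
        cls, identifier: str, model: str, target_group: str | None = None
    ) -> "ScorerSpec":
        if len(identifier) != 3:
            raise ConfigError(
                f"scorer identifier must be 3 characters (e.g. 'rol'), got {identifier!r}"
            )
        return cls(identifier[0], identifier[1], identifier[2], model, target_group)


@dataclass(frozen=True)
class ScoreTriplet:
    """Cube coordinates of one column, generalized to G groups."""

    position: int
    conservation: Mapping[str, float]
    overlap: Mapping[frozenset, float]
    high_gap: bool = field(default=False)


def combine(terms: np.ndarray, combiner: str) -> float:
    terms = np.asarray(terms, dtype=float)
    if combiner == "e":
        return float(np.sqrt((terms**2).mean()))
    if combiner == "l":
        return float(terms.mean())
    raise ConfigError(f"unknown combiner {combiner!r}")


def conservation_only_score(triplet: ScoreTriplet, combiner: str = "e") -> float:
    """Distance from the all-conserved corner, normalized to [0,1]."""
    terms = np.array([1.0 - c for c in triplet.conservation.values()])
    return combine(terms, combiner)


def discriminant_score(triplet: ScoreTriplet, combiner: str = "e") -> float:
    """Deviation from the constant-but-different corner; every group and pair counts."""
    terms = np.array(
        [1.0 - c for c in triplet.conservation.values()]
        + list(triplet.overlap.values())
    )
    return combine(terms, combiner)


def determinant_score(
    triplet: ScoreTriplet, target_group: str, combiner: str = "e"
) -> float:
    """Deviation from determinant-of-target behavior.

    Only the target group's conservation and the overlaps of pairs involving
    the target enter; the remaining groups' behavior never changes the score.
    """
    if target_group not in triplet.conservation:
        raise ConfigError(f"unknown target group {target_group!r}")
    terms = [1.0 - triplet.conservation[target_group]]
    for pair, v in triplet.overlap.items():
        if target_group in pair:
            terms.append(v)
    return combine(np.array(terms), combiner)


def nonconserved_nonoverlap_score(triplet: ScoreTriplet, combiner: str = "e") -> float:
    """Distance from the fully-variable, non-overlapping corner."""
    terms = np.array(
        list(triplet.conservation.values()) + list(triplet.overlap.values())
    )
    return combine(terms, combiner)


def _model_score(triplet: ScoreTriplet, spec: ScorerSpec) -> float:
    if spec.model == "determinant":
        return determinant_score(triplet, spec.target_group, spec.combiner)
    if spec.model == "discriminant":
        return discriminant_score(triplet, spec.combiner)
    if spec.model == "conservation_only":
        return conservation_only_score(triplet, spec.combiner)
    return nonconserved_nonoverlap_score(triplet, spec.combiner)


def score_triplets(
    ga: GroupedAlignment,
    spec: ScorerSpec,
    model: RateModel | None = None,
    t_eff: float | None = None,
    profiles: list[ColumnProfile] | None = None,
) -> tuple[list[ScoreTriplet], float]:
    """Per-position cube coordinates under one scorer spec.

    Returns the triplets (positions where any group's profile is empty are
    dropped) and the family-wide effective time actually used.  The same
    t_eff feeds every observed-minus-expected correction.
    """
    if model is None:
        model = load_rate_matrix()
    if profiles is None:
        profiles = column_profiles(ga)
    by_pos = profiles_by_position(profiles)
    scored = [
        pos
        for pos in sorted(by_pos)
        if all(not by_pos[pos][g].empty for g in ga.groups)
    ]
    if not scored:
        raise InputError("no position has a non-empty profile in every group")
    nonempty = [p for p in profiles if not p.empty]
    if t_eff is None:
        t_eff = effective_time(nonempty, model)

    needs_anc = spec.conservation_id == "r" or spec.overlap_id == "r"
    anc: dict[tuple[int, str], int] = {}
    if needs_anc:
        for p in nonempty:
            anc[(p.position, p.group)] = ancestral_type(p, model)

    # conservation: raw per (position, group), then min-max per group
    cons: dict[int, dict[str, float]] = {pos: {} for pos in scored}
    for g in ga.groups:
        raw = np.array(
            [
                raw_conservation(
                    by_pos[pos][g],
                    spec.conservation_id,
                    model,
                    anc.get((pos, g)),
                    t_eff,
                )
                for pos in scored
            ]
        )
        if spec.conservation_id == "0":
            resc = np.full(len(scored), 0.5)
            c_vals = resc
        else:
            resc = rescale_within_group(raw)
            from .conservation import _VARIABILITY_ORIENTED

            c_vals = 1.0 - resc if _VARIABILITY_ORIENTED[spec.conservation_id] else resc
        for pos, c in zip(scored, c_vals):
            cons[pos][g] = float(c)

    # overlap: raw per (position, pair), oriented/rescaled over positions per pair
    ovl: dict[int, dict[frozenset, float]] = {pos: {} for pos in scored}
    for ga_, gb in itertools.combinations(ga.groups, 2):
        pair = frozenset((ga_, gb))
        raw = np.array(
            [
                raw_overlap(
                    spec.overlap_id,
                    by_pos[pos][ga_],
                    by_pos[pos][gb],
                    model,
                    (anc.get((pos, ga_)), anc.get((pos, gb))) if needs_anc else None,
                    t_eff,
                )
                for pos in scored
            ]
        )
        vals = orient_and_rescale(spec.overlap_id, raw)
        for pos, v in zip(scored, vals):
            ovl[pos][pair] = float(np.clip(v, 0.0, 1.0))

    triplets = [
        ScoreTriplet(
            position=pos,
            conservation=cons[pos],
            overlap=ovl[pos],
            high_gap=any(by_pos[pos][g].high_gap for g in ga.groups),
        )
        for pos in scored
    ]
    return triplets, float(t_eff)


def rank_positions(
    ga: GroupedAlignment,
    spec: ScorerSpec,
    model: RateModel | None = None,
    t_eff: float | None = None,
    profiles: list[ColumnProfile] | None = None,
) -> pd.DataFrame:
    """Rank alignment columns by a combined specialization score.

    Returns a DataFrame sorted ascending by score (smaller = more specific;
    ties broken by position), with per-group conservation, per-pair overlap,
    the combined score, 1-based rank, and the high-gap flag.  The effective
    time used is stored in ``df.attrs["t_eff"]``.
    """
    triplets, t_used = score_triplets(ga, spec, model, t_eff, profiles)
    rows = []
    for tr in triplets:
        row: dict = {"position": tr.position}
        for g in ga.groups:
            row[f"conservation_{g}"] = tr.conservation[g]
        for pair, v in tr.overlap.items():
            a, b = sorted(pair)
            row[f"overlap_{a}_{b}"] = v
        row["score"] = _model_score(tr, spec)
        row["high_gap"] = tr.high_gap
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["score", "position"], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["t_eff"] = t_used
    df.attrs["scorer"] = spec.identifier
    df.attrs["model"] = spec.model
    return df


def rank_by_mutual_information(
    ga: GroupedAlignment, profiles: list[ColumnProfile] | None = None
) -> pd.DataFrame:
    """Baseline ranking by multi-group mutual information (higher MI first).

    Scores are the negated MI so that, as everywhere else, smaller = more
    specific.
    """
    if profiles is None:
        profiles = column_profiles(ga)
    by_pos = profiles_by_position(profiles)
    rows = []
    for pos in sorted(by_pos):
        profs = [by_pos[pos][g] for g in ga.groups]
        if any(p.empty for p in profs):
            continue
        counts = [p.freq * p.n_counted for p in profs]
        mi = mutual_information(counts)
        rows.append(
            {
                "position": pos,
                "mi": mi,
                "score": -mi,
                "high_gap": any(p.high_gap for p in profs),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["score", "position"], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["scorer"] = "mi"
    df.attrs["model"] = "mutual_information"
    return df
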