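"""Synthetic grouped alignments with planted column classes.

Columns are generated independently under the same free-evolution model the
scores assume: a star phylogeny in which every sequence descends directly
from a family ancestor, each column seeded with an ancestral type drawn from
the stationary distribution.  Four column classes are planted:

``conserved_all``
    every sequence carries the ancestral type;
``determinant`` (of a target group)
    the target group is frozen at the ancestral type; every other group's
    residues are drawn i.i.d. from the free distribution at the family
    divergence time (heterotachy: constraint in one group only);
``discriminant``
    each group frozen at its own type — the first group at the ancestral
    type, the rest at distinct types drawn uniformly without replacement
    ("constant but different");
``free``
    all residues drawn i.i.d. from the free distribution.

The star phylogeny and site independence are deliberate simplifications —
the scoring framework itself is phylogeny-free — so recovery results on
these families show scorer behavior under the model's own assumptions, not
robustness to tree structure or alignment error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .alphabet import AMINO_ACIDS
from .errors import InputError
from .evaluation import ResidueAnnotation
from .msa_io import GroupedAlignment
from .rate_model import RateModel, load_rate_matrix

CLASS_KINDS = ("conserved_all", "determinant", "discriminant", "free")


@dataclass(frozen=True)
class ColumnClass:
    """Planted behavior of one column."""

    kind: str
    target: str | None = None  # determinant target group
    fixed_types: Mapping[str, int] | None = None  # group → frozen type index
    ancestral: int = 0


@dataclass(frozen=True)
class SyntheticFamily:
    alignment: GroupedAlignment
    truth: Mapping[int, ColumnClass]
    params: Mapping


def _parse_mixture(class_mixture: Mapping[str, int], groups: tuple[str, ...]):
    """Expand a kind→count map into a per-column class plan.

    A bare ``"determinant"`` key targets the first group; ``"determinant:G2"``
    names its target explicitly.
    """
    plan: list[tuple[str, str | None]] = []
    for key, count in class_mixture.items():
        if count < 0:
            raise InputError(f"negative count for class {key!r}")
        if key.startswith("determinant"):
            kind = "determinant"
            target = key.split(":", 1)[1] if ":" in key else groups[0]
            if target not in groups:
                raise InputError(f"determinant target {target!r} not a group")
        else:
            kind, target = key, None
            if kind not in CLASS_KINDS:
                raise InputError(f"unknown column class {key!r}")
        plan.extend([(kind, target)] * count)
    return plan


def simulate_family(
    G: int = 2,
    n_per_group: int = 40,
    L: int = 200,
    class_mixture: Mapping[str, int] | None = None,
    t_free: float = 2.0,
    seed: int = 0,
    model: RateModel | None = None,
    shuffle_columns: bool = True,
) -> SyntheticFamily:
    """Simulate a grouped alignment with known column classes.

    Defaults mirror the benchmark family used throughout the tests: two
    groups of 40 sequences, 200 columns of which 20 are determinants of the
    first group, 20 discriminants, 80 free and 80 conserved, at divergence
    time 2.0 expected substitutions per site.
    """
    if G < 2:
        raise InputError("need at least two groups")
    if n_per_group < 2:
        raise InputError("need at least two sequences per group")
    if t_free <= 0:
        raise InputError("t_free must be positive")
    if model is None:
        model = load_rate_matrix()
    if class_mixture is None:
        class_mixture = {
            "determinant": 20,
            "discriminant": 20,
            "free": 80,
            "conserved_all": 80,
        }
    groups = tuple(f"G{i + 1}" for i in range(G))
    plan = _parse_mixture(class_mixture, groups)
    if len(plan) != L:
        raise InputError(f"class mixture totals {len(plan)} columns, expected L={L}")

    rng = np.random.default_rng(seed)
    if shuffle_columns:
        order = rng.permutation(L)
        plan = [plan[i] for i in order]

    P = model.transition_matrix(t_free)
    pi = model.pi
    n_seqs = G * n_per_group
    cols = np.empty((L, n_seqs), dtype=int)
    truth: dict[int, ColumnClass] = {}
    group_slices = {
        g: slice(k * n_per_group, (k + 1) * n_per_group) for k, g in enumerate(groups)
    }

    for pos, (kind, target) in enumerate(plan):
        anc = int(rng.choice(20, p=pi))
        free_p = P[anc]
        if kind == "conserved_all":
            cols[pos, :] = anc
            fixed = {g: anc for g in groups}
        elif kind == "determinant":
            fixed = {target: anc}
            for g in groups:
                sl = group_slices[g]
                if g == target:
                    cols[pos, sl] = anc
                else:
                    cols[pos, sl] = rng.choice(20, size=n_per_group, p=free_p)
        elif kind == "discriminant":
            others = [a for a in range(20) if a != anc]
            picks = [anc] + list(rng.choice(others, size=G - 1, replace=False))
            fixed = {g: int(a) for g, a in zip(groups, picks)}
            for g in groups:
                cols[pos, group_slices[g]] = fixed[g]
        else:  # free
            cols[pos, :] = rng.choice(20, size=n_seqs, p=free_p)
            fixed = None
        truth[pos] = ColumnClass(kind=kind, target=target, fixed_types=fixed, ancestral=anc)

    seq_ids = tuple(
        f"{g}_s{j + 1}" for g in groups for j in range(n_per_group)
    )
    rows = tuple(
        "".join(AMINO_ACIDS[cols[pos, i]] for pos in range(L)) for i in range(n_seqs)
    )
    group_of = {sid: sid.split("_")[0] for sid in seq_ids}
    ga = GroupedAlignment(
        sequence_ids=seq_ids, rows=rows, group_of=group_of, groups=groups
    )
    params = {
        "G": G,
        "n_per_group": n_per_group,
        "L": L,
        "class_mixture": dict(class_mixture),
        "t_free": t_free,
        "seed": seed,
        "matrix": model.name,
    }
    return SyntheticFamily(alignment=ga, truth=truth, params=params)


def planted_truth_to_annotation(
    family: SyntheticFamily, positive_kind: str, target: str | None = None
) -> ResidueAnnotation:
    """Annotation with the planted class as positives.

    Positives are the columns of ``positive_kind`` (``"determinant"`` may
    name a target group); confirmed negatives are the free and conserved
    columns.  Fully conserved columns can never be positives, consistent
    with how experimental positive sets are curated.
    """
    kind = positive_kind
    if kind.startswith("determinant") and ":" in kind:
        kind, target = kind.split(":", 1)
    if kind not in ("determinant", "discriminant"):
        raise InputError(f"positive class must be determinant or discriminant, got {kind!r}")
    positives = {
        pos
        for pos, cc in family.truth.items()
        if cc.kind == kind and (target is None or cc.target == target)
    }
    if not positives:
        raise InputError(f"no columns of class {positive_kind!r} in this family")
    negatives = {
        pos
        for pos, cc in family.truth.items()
        if cc.kind in ("free", "conserved_all")
    }
    universe = frozenset(family.truth)
    return ResidueAnnotation(frozenset(positives), frozenset(negatives), universe)


def write_family(family: SyntheticFamily, prefix: str | Path) -> dict[str, Path]:
    """Write FASTA alignment, group TSV and truth TSV next to *prefix*."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ga = family.alignment
    fasta = prefix.with_suffix(".fasta")
    with fasta.open("w") as fh:
        for sid, row in zip(ga.sequence_ids, ga.rows):
            fh.write(f">{sid}\n{row}\n")
    groups = prefix.parent / (prefix.name + "_groups.tsv")
    with groups.open("w") as fh:
        for sid in ga.sequence_ids:
            fh.write(f"{sid}\t{ga.group_of[sid]}\n")
    truth = prefix.parent / (prefix.name + "_truth.tsv")
    with truth.open("w") as fh:
        fh.write("# 1-based position\tclass\ttarget\tancestral\n")
        for pos in sorted(family.truth):
            cc = family.truth[pos]
            fh.write(
                f"{pos + 1}\t{cc.kind}\t{cc.target or '-'}\t{AMINO_ACIDS[cc.ancestral]}\n"
            )
    return {"fasta": fasta, "groups": groups, "truth": truth}
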