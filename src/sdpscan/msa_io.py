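"""Alignment and group-assignment input, and per-column per-group frequency profiles.

A family is a multiple sequence alignment whose sequences are partitioned into
groups of orthologues; every score in the package is computed per alignment
column, relative to this grouping.  Gaps ('-') and unknowns ('X') never enter a
frequency profile: counts are taken over canonical residues only and
renormalized.  Columns where any group is more than half gaps are flagged (they
are still scored, but the flag is carried through to reports).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO

from .alphabet import AA_INDEX, GAP, N_TYPES, UNKNOWN, VALID_CHARS
from .errors import AlignmentFormatError, InputError

#: fraction of gap/unknown characters within a group above which a column is flagged
HIGH_GAP_FRACTION = 0.5


@dataclass(frozen=True)
class RawAlignment:
    """An alignment as read from disk, before group assignment."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    @property
    def n_positions(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class GroupedAlignment:
    """Aligned sequences with a group label per sequence.

    Groups are ordered by first appearance in the alignment; every group has at
    least two members, so within-group frequencies are never a single draw.
    """

    sequence_ids: tuple[str, ...]
    rows: tuple[str, ...]
    group_of: Mapping[str, str]
    groups: tuple[str, ...]

    @property
    def n_positions(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def members(self, group: str) -> list[int]:
        """Row indices of the sequences belonging to *group*."""
        return [
            i for i, sid in enumerate(self.sequence_ids) if self.group_of[sid] == group
        ]

    def column(self, position: int, group: str) -> str:
        """The characters of one group at one column."""
        return "".join(self.rows[i][position] for i in self.members(group))


@dataclass(frozen=True)
class ColumnProfile:
    """Residue-type frequency distribution of one group at one column.

    ``freq`` is a length-20 vector in the canonical alphabet order, built from
    the ``n_counted`` non-gap, non-X residues and renormalized to sum to 1.
    An all-gap column yields an *empty* profile (``n_counted == 0``) which is
    excluded from scoring.
    """

    position: int
    group: str
    freq: np.ndarray
    n_counted: int
    high_gap: bool = field(default=False)

    @property
    def empty(self) -> bool:
        return self.n_counted == 0


def read_alignment(path: str | Path, format: str = "fasta") -> RawAlignment:
    """Read a FASTA or Stockholm alignment.

    Rows are uppercased and '.' gap characters normalized to '-'.  Ragged
    record lengths, duplicate identifiers, unknown characters and empty files
    are rejected.
    """
    if format not in ("fasta", "stockholm"):
        raise InputError(f"unsupported alignment format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"alignment file not found: {path}")
    try:
        records = list(AlignIO.read(str(path), format))
    except ValueError as exc:
        # AlignIO refuses ragged alignments and empty files with a ValueError
        msg = str(exc)
        if "equal length" in msg or "same length" in msg:
            raise AlignmentFormatError(f"{path}: {msg}") from exc
        raise InputError(f"{path}: {msg}") from exc
    if not records:
        raise InputError(f"{path}: no sequences found")
    ids = tuple(r.id for r in records)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"{path}: duplicate sequence ids {dupes}")
    rows = tuple(str(r.seq).upper().replace(".", GAP) for r in records)
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentFormatError(f"{path}: rows of differing length {sorted(lengths)}")
    if next(iter(lengths)) == 0:
        raise InputError(f"{path}: zero-length alignment")
    for sid, row in zip(ids, rows):
        bad = set(row) - VALID_CHARS
        if bad:
            raise AlignmentFormatError(
                f"{path}: sequence {sid!r} contains invalid characters {sorted(bad)}"
            )
    return RawAlignment(ids=ids, rows=rows)


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of sequence_id <tab> group_label."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"group file not found: {path}")
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InputError(f"{path}:{lineno}: expected 2 tab-separated fields")
        sid, label = parts[0].strip(), parts[1].strip()
        if sid in mapping:
            raise InputError(f"{path}:{lineno}: duplicate id {sid!r}")
        mapping[sid] = label
    if not mapping:
        raise InputError(f"{path}: empty group map")
    return mapping


def assign_groups(raw: RawAlignment, group_map: Mapping[str, str]) -> GroupedAlignment:
    """Attach group labels to an alignment.

    Every sequence must be mapped; extra map entries for absent sequences are
    ignored.  Groups are ordered by first appearance; singleton groups are
    rejected because a single sequence cannot define a frequency distribution.
    """
    missing = [sid for sid in raw.ids if sid not in group_map]
    if missing:
        raise InputError(f"sequences missing from group map: {missing}")
    group_of = {sid: group_map[sid] for sid in raw.ids}
    groups: list[str] = []
    for sid in raw.ids:
        g = group_of[sid]
        if g not in groups:
            groups.append(g)
    counts = {g: sum(1 for sid in raw.ids if group_of[sid] == g) for g in groups}
    singles = [g for g, c in counts.items() if c < 2]
    if singles:
        raise InputError(f"groups with fewer than 2 sequences: {singles}")
    return GroupedAlignment(
        sequence_ids=raw.ids, rows=raw.rows, group_of=group_of, groups=tuple(groups)
    )


def column_profiles(
    ga: GroupedAlignment, gap_policy: str = "exclude_renormalize"
) -> list[ColumnProfile]:
    """Per-(position, group) frequency profiles.

    Profiles are returned position-major, group order as in ``ga.groups``.
    """
    if gap_policy != "exclude_renormalize":
        raise InputError(f"unknown gap policy: {gap_policy!r}")
    member_idx = {g: ga.members(g) for g in ga.groups}
    profiles: list[ColumnProfile] = []
    for pos in range(ga.n_positions):
        for g in ga.groups:
            rows = member_idx[g]
            counts = np.zeros(N_TYPES)
            n_gapped = 0
            for i in rows:
                ch = ga.rows[i][pos]
                if ch == GAP or ch == UNKNOWN:
                    n_gapped += 1
                else:
                    counts[AA_INDEX[ch]] += 1
            n_counted = int(counts.sum())
            freq = counts / n_counted if n_counted else counts
            profiles.append(
                ColumnProfile(
                    position=pos,
                    group=g,
                    freq=freq,
                    n_counted=n_counted,
                    high_gap=n_gapped / len(rows) > HIGH_GAP_FRACTION,
                )
            )
    return profiles


def profiles_by_position(
    profiles: Iterable[ColumnProfile],
) -> dict[int, dict[str, ColumnProfile]]:
    """Index a flat profile list as position → group → profile."""
    out: dict[int, dict[str, ColumnProfile]] = {}
    for p in profiles:
        out.setdefault(p.position, {})[p.group] = p
    return out


def read_annotation(path: str | Path) -> dict[int, str]:
    """Read a residue-annotation TSV (1-based position <tab> positive|negative).

    Returns 0-based position → label.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    out: dict[int, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[1].strip() not in ("positive", "negative"):
            raise InputError(
                f"{path}:{lineno}: expected '<1-based position>\\t<positive|negative>'"
            )
        out[int(parts[0]) - 1] = parts[1].strip()
    return out
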