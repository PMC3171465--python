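"""Between-group overlap of residue-type distributions at one column.

The separating overlap (method id ``o``) is the normalized dot product

    o(p, q) = 2 p.q / (p.p + q.q),

which is 1 for identical distributions irrespective of their variability and
0 for disjoint supports — it measures overlap only, leaving conservation to
the conservation scores.  The alternatives do not separate the two features:

* the raw dot product (``eq9``) is 0 for disjoint supports but its value for
  identical distributions depends on their spread;
* the sum of squared differences (``f``) is 0 for identical distributions but
  its disjoint-support value depends on their variability;
* Kullback-Leibler between the groups (``klg``, floored to stay finite) and
  its symmetrized Jensen-Shannon cousin, known as sequence harmony (``sh``);
* mutual information between residue type and group membership (``m`` for the
  two-group restriction, :func:`mutual_information` over all groups), which
  rewards regular assortment of types into groups — the archetypal
  "constant-but-different" (discriminant) assumption;
* the exchangeability-corrected overlap (``r``): observed overlap minus the
  overlap expected for two freely evolving positions started at the two
  groups' ancestral types, after the family's effective time.

Before entering a combined score all ids are oriented so that LOWER = more
diverged, and mapped to [0,1] across positions (``o`` is used as is; ``r`` is
min-max rescaled; the rest are negated then rescaled).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .conservation import js_divergence
from .errors import ConfigError, InputError
from .rate_model import RateModel, free_distribution

OVERLAP_IDS = ("o", "f", "r", "m", "eq9", "klg", "sh")

#: floor applied to the reference distribution in kl_between_groups
KL_FLOOR = 1e-6


@dataclass(frozen=True)
class OverlapResult:
    position: int
    group_pair: frozenset[str]
    value: float
    method_id: str


def _check_dist(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.min() < -1e-12 or abs(p.sum() - 1) > 1e-6:
        raise InputError("argument is not a normalized distribution")
    return np.clip(p, 0.0, None)


def overlap_o(p: np.ndarray, q: np.ndarray) -> float:
    """Normalized dot-product overlap in [0,1]; symmetric."""
    p, q = _check_dist(p), _check_dist(q)
    denom = float(p @ p + q @ q)
    return float(2.0 * (p @ q) / denom)


def overlap_eq9(p: np.ndarray, q: np.ndarray) -> float:
    """Raw dot product p.q: 0 for disjoint supports, spread-dependent at p=q."""
    p, q = _check_dist(p), _check_dist(q)
    return float(p @ q)


def squared_difference(p: np.ndarray, q: np.ndarray) -> float:
    """Sum of squared frequency differences; 0 iff identical, at most 2."""
    p, q = _check_dist(p), _check_dist(q)
    return float(((p - q) ** 2).sum())


def kl_between_groups(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) with the reference floored at 1e-6 and renormalized.

    The floor keeps the divergence finite where p has mass but q has none;
    the measure is asymmetric.
    """
    p, q = _check_dist(p), _check_dist(q)
    qf = np.maximum(q, KL_FLOOR)
    qf = qf / qf.sum()
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / qf[nz])).sum())


def sequence_harmony(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence between the two group distributions.

    Symmetric; 0 for identical distributions; ln 2 for disjoint supports.
    """
    return js_divergence(_check_dist(p), _check_dist(q))


def mutual_information(
    counts: Sequence[np.ndarray] | np.ndarray,
) -> float:
    """MI (nats) between residue type and group membership at one column.

    ``counts`` holds one length-20 count vector per group (non-gap residues
    only, so gapped columns do not fake signal).  Joint frequencies are
    counts over the grand total; the group marginal is each group's counted
    share.  Zero iff type and grouping are independent.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise InputError("need counts for at least two groups")
    total = table.sum()
    if total <= 0:
        raise InputError("all group columns empty")
    if (table.sum(axis=1) <= 0).any():
        raise InputError("a group column is empty")
    joint = table / total
    type_marg = joint.sum(axis=0)
    group_marg = joint.sum(axis=1)
    nz = joint > 0
    prod = np.outer(group_marg, type_marg)
    return float((joint[nz] * np.log(joint[nz] / prod[nz])).sum())


def pairwise_mi(p_counts: np.ndarray, q_counts: np.ndarray) -> float:
    """Two-group restriction of :func:`mutual_information` (method 'm')."""
    return mutual_information([p_counts, q_counts])


def corrected_overlap(
    p: np.ndarray,
    q: np.ndarray,
    model: RateModel,
    ancestral_p: int,
    ancestral_q: int,
    t_eff: float,
) -> float:
    """Observed overlap minus the free-evolution expected overlap; in [-1,1].

    The expected overlap is the normalized dot product of the free
    distributions started at the two groups' ancestral types and evolved for
    the family's effective time, so two groups conserved as different but
    highly exchangeable types are treated as less diverged than two conserved
    as unrelated types.
    """
    if t_eff < 0:
        raise InputError("t_eff must be non-negative")
    pe = free_distribution(model, ancestral_p, t_eff).p
    qe = free_distribution(model, ancestral_q, t_eff).p
    return overlap_o(p, q) - overlap_o(pe, qe)


def raw_overlap(
    method_id: str,
    p_profile,
    q_profile,
    model: RateModel,
    ancestrals: tuple[int, int] | None,
    t_eff: float,
) -> float:
    """Raw value of one overlap method on a pair of column profiles."""
    p, q = p_profile.freq, q_profile.freq
    if method_id == "o":
        return overlap_o(p, q)
    if method_id == "f":
        return squared_difference(p, q)
    if method_id == "r":
        assert ancestrals is not None
        return corrected_overlap(p, q, model, ancestrals[0], ancestrals[1], t_eff)
    if method_id == "m":
        return pairwise_mi(
            p * p_profile.n_counted, q * q_profile.n_counted
        )
    if method_id == "eq9":
        return overlap_eq9(p, q)
    if method_id == "klg":
        return kl_between_groups(p, q)
    if method_id == "sh":
        return sequence_harmony(p, q)
    raise ConfigError(f"unknown overlap id: {method_id!r}")


#: True where the raw score already grows with overlap (lower = diverged)
OVERLAP_ORIENTED = {
    "o": True,
    "r": True,
    "eq9": True,
    "f": False,
    "m": False,
    "klg": False,
    "sh": False,
}

#: ids used raw (already in [0,1]); others are min-max rescaled over positions
PASS_THROUGH = {"o"}


def orient_and_rescale(method_id: str, values: np.ndarray) -> np.ndarray:
    """Map raw pair scores over positions to [0,1], 1 = identical distributions."""
    v = np.asarray(values, dtype=float)
    if not OVERLAP_ORIENTED[method_id]:
        v = -v
    if method_id in PASS_THROUGH:
        return v
    lo, hi = v.min(), v.max()
    if hi == lo:
        # featureless family: every pair equally overlapping
        return np.full_like(v, 1.0)
    return (v - lo) / (hi - lo)
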