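"""Within-group conservation (variability) scores for one alignment column.

Three measures, identified by the one-letter ids of the scorer grammar:

``e``
    plain information entropy of the observed type distribution (a
    variability measure, 0 for a monotypic column, ln 20 at the uniform);
``r``
    entropy corrected by its free-evolution expectation: observed entropy
    minus the entropy the column would have had evolving freely from its
    ancestral type for the family's effective time.  Negative values mean
    more conserved than free drift explains.  This is where residue-type
    exchangeability enters: a conserved isoleucine (quick to drift into
    valine or leucine) signals stronger constraint than a conserved
    tryptophan, and the correction scores it accordingly;
``j``
    Jensen-Shannon divergence of the observed distribution from the
    stationary distribution (a conservation measure: far from the background
    = conserved).  Kullback-Leibler from the stationary distribution is also
    provided as the prototype of this family; its preference for rare residue
    types (conserved W above conserved I) is the behavior the ``r`` score is
    designed to repair.

Raw values are min-max rescaled per group across positions; the rescaled
variability's complement C = 1 - v is the conservation coordinate used by the
combined scores (1 = fully conserved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InputError
from .msa_io import ColumnProfile
from .rate_model import RateModel, free_distribution

CONSERVATION_IDS = ("e", "r", "j", "0")

#: ids whose raw value grows with variability (vs. with conservation)
_VARIABILITY_ORIENTED = {"e": True, "r": True, "j": False}


@dataclass(frozen=True)
class ConservationResult:
    position: int
    group: str
    raw_value: float
    rescaled: float
    method_id: str

    @property
    def conservation(self) -> float:
        """C in [0,1], 1 = fully conserved (complement taken per orientation)."""
        if self.method_id == "0":
            return 0.5
        if _VARIABILITY_ORIENTED[self.method_id]:
            return 1.0 - self.rescaled
        return self.rescaled


def _checked(profile: ColumnProfile) -> np.ndarray:
    if profile.empty:
        raise InputError(f"empty profile at position {profile.position}")
    return profile.freq


def entropy_of(p: np.ndarray) -> float:
    """Shannon entropy in nats, with 0 ln 0 = 0."""
    p = np.asarray(p, dtype=float)
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def entropy(profile: ColumnProfile) -> float:
    """Observed column entropy (nats); in [0, ln 20]."""
    return entropy_of(_checked(profile))


def expected_entropy(model: RateModel, ancestral: int, t: float) -> float:
    """Entropy of the free distribution from ``ancestral`` at time t."""
    return entropy_of(free_distribution(model, ancestral, t).p)


def corrected_entropy(
    profile: ColumnProfile, model: RateModel, ancestral: int, t_eff: float
) -> float:
    """Observed minus free-evolution expected entropy (nats, may be negative)."""
    return entropy(profile) - expected_entropy(model, ancestral, t_eff)


def kl_from_stationary(profile: ColumnProfile, pi: np.ndarray) -> float:
    """Kullback-Leibler divergence of the column from the stationary background."""
    f = _checked(profile)
    nz = f > 0
    return float((f[nz] * np.log(f[nz] / pi[nz])).sum())


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence with the equal-weight mixture; in [0, ln 2]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = (p + q) / 2
    return 0.5 * (_kl(p, m) + _kl(q, m))


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / q[nz])).sum())


def js_from_stationary(profile: ColumnProfile, pi: np.ndarray) -> float:
    """JS divergence of the column from the stationary background (method 'j')."""
    return js_divergence(_checked(profile), pi)


def rescale_within_group(values: np.ndarray) -> np.ndarray:
    """Affine min-max map to [0,1]; a constant vector maps to all zeros."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or not np.isfinite(v).all():
        raise InputError("rescaling needs at least one finite value")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def raw_conservation(
    profile: ColumnProfile,
    method_id: str,
    model: RateModel,
    ancestral: int | None,
    t_eff: float,
) -> float:
    """Raw (unrescaled) value of one conservation method on one profile."""
    if method_id == "e":
        return entropy(profile)
    if method_id == "r":
        assert ancestral is not None
        return corrected_entropy(profile, model, ancestral, t_eff)
    if method_id == "j":
        return js_from_stationary(profile, model.pi)
    if method_id == "0":
        return 0.5
    raise ConfigError(f"unknown conservation id: {method_id!r}")
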