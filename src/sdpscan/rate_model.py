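"""Free-evolution model of a single alignment column.

A position free of structural and functional constraints starts from a single
ancestral residue type and drifts under a continuous-time Markov model of
amino-acid replacement: a 20x20 rate matrix Q whose matrix exponential
P(t) = exp(Qt) gives the probability of type i having been replaced by type j
after time t.  For long times every starting distribution relaxes to the
stationary distribution pi of Q.  Time is measured in expected substitutions
per site (Q is rescaled so that -sum_i pi_i Q_ii = 1).

The model supplies the "expected" term of every observed-minus-expected
correction in the conservation and overlap scores, and the family-wide
effective divergence time t_eff: for each column the time at which the free
distribution, seeded at the column's majority (ancestral) type, overlaps the
observed distribution best, averaged over all columns and groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.linalg import expm

from .alphabet import AMINO_ACIDS, N_TYPES, index_of
from .errors import InputError, RateMatrixFormatError, SdpscanError
from .msa_io import ColumnProfile

BUILTIN_MATRICES = {"wag": "wag.dat"}
DEFAULT_MATRIX = "wag"

#: time grid for the effective-time search: {0} plus 64 log-spaced points
T_GRID_MAX = 20.0
_T_GRID = np.concatenate([[0.0], np.logspace(np.log10(1e-3), np.log10(T_GRID_MAX), 64)])


@dataclass
class RateModel:
    """Amino-acid rate matrix with its stationary distribution.

    ``Q`` rows sum to zero; ``pi`` is the left null vector of Q normalized to
    sum 1.  When ``normalized`` the expected substitution rate at
    stationarity, -sum pi_i Q_ii, equals 1, so t is in expected substitutions
    per site.
    """

    Q: np.ndarray
    pi: np.ndarray
    name: str = "custom"
    normalized: bool = True
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.Q.shape != (N_TYPES, N_TYPES):
            raise InputError(f"rate matrix must be 20x20, got {self.Q.shape}")
        off = self.Q - np.diag(np.diag(self.Q))
        if (off < 0).any():
            raise InputError("negative off-diagonal rate")
        if np.abs(self.Q.sum(axis=1)).max() > 1e-10:
            raise InputError("rate-matrix rows do not sum to 0")
        if (self.pi <= 0).any() or abs(self.pi.sum() - 1) > 1e-10:
            raise InputError("stationary distribution must be positive and sum to 1")
        if np.abs(self.pi @ self.Q).max() > 1e-8:
            raise InputError("pi is not stationary for Q")

    # -- transition probabilities -------------------------------------------

    def _eigendecomposition(self):
        """Symmetrized eigendecomposition, valid for reversible Q.

        B = D^{1/2} Q D^{-1/2} with D = diag(pi) is symmetric when Q satisfies
        detailed balance; then P(t) = D^{-1/2} V exp(L t) V^T D^{1/2}.
        """
        if self._eig is None:
            d = np.sqrt(self.pi)
            B = (d[:, None] * self.Q) / d[None, :]
            if np.abs(B - B.T).max() > 1e-8:
                raise SdpscanError("rate matrix is not reversible")
            lam, V = np.linalg.eigh((B + B.T) / 2)
            self._eig = (lam, V, d)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); row-stochastic for any t >= 0."""
        if t < 0:
            raise InputError(f"time must be non-negative, got {t}")
        if t == 0:
            return np.eye(N_TYPES)
        try:
            lam, V, d = self._eigendecomposition()
            P = (V * np.exp(lam * t)) @ V.T
            P = P / d[:, None] * d[None, :]
        except SdpscanError:
            P = expm(self.Q * t)
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)


def stationary_distribution(model: RateModel) -> np.ndarray:
    """The long-time residue-type distribution pi implied by Q."""
    return model.pi.copy()


def transition_matrix(model: RateModel, t: float) -> np.ndarray:
    return model.transition_matrix(t)


@dataclass(frozen=True)
class FreeDistribution:
    """Type distribution of a freely evolving position after time t."""

    ancestral: int
    t: float
    p: np.ndarray


def free_distribution(model: RateModel, ancestral: int, t: float) -> FreeDistribution:
    """Row ``ancestral`` of P(t): an indicator at t=0, pi as t grows large."""
    if not 0 <= ancestral < N_TYPES:
        raise InputError(f"ancestral type index out of range: {ancestral}")
    p = model.transition_matrix(t)[ancestral]
    return FreeDistribution(ancestral=ancestral, t=t, p=p)


# -- PAML-dialect input ------------------------------------------------------


def _read_numbers(path: Path) -> list[float]:
    values: list[float] = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        for tok in line.split():
            try:
                values.append(float(tok))
            except ValueError:
                raise RateMatrixFormatError(f"{path}: non-numeric token {tok!r}") from None
    return values


def load_rate_matrix(source: str | Path = DEFAULT_MATRIX) -> RateModel:
    """Load a PAML-dialect rate matrix (builtin name or file path).

    The dialect is 190 lower-triangular exchangeabilities s_ij followed by 20
    equilibrium frequencies; '#' starts a comment.  Q is assembled as
    Q_ij = s_ij pi_j (i != j), the diagonal set so rows sum to zero, then
    globally rescaled so that -sum_i pi_i Q_ii = 1.
    """
    if isinstance(source, str) and source.lower() in BUILTIN_MATRICES:
        name = source.lower()
        ref = resources.files("sdpscan.data") / BUILTIN_MATRICES[name]
        with resources.as_file(ref) as p:
            values = _read_numbers(p)
    else:
        path = Path(source)
        if not path.exists():
            raise InputError(f"rate-matrix file not found: {path}")
        name = path.stem
        values = _read_numbers(path)
    if len(values) != 190 + 20:
        raise RateMatrixFormatError(
            f"expected 190 exchangeabilities + 20 frequencies, got {len(values)} numbers"
        )
    tri, freqs = values[:190], np.asarray(values[190:])
    if min(tri) < 0 or (freqs < 0).any():
        raise InputError("negative exchangeability or frequency")
    if freqs.sum() <= 0:
        raise InputError("frequencies sum to zero")
    pi = freqs / freqs.sum()
    S = np.zeros((N_TYPES, N_TYPES))
    k = 0
    for i in range(1, N_TYPES):
        for j in range(i):
            S[i, j] = S[j, i] = tri[k]
            k += 1
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    if rate <= 0:
        raise RateMatrixFormatError("degenerate rate matrix (zero total rate)")
    return RateModel(Q=Q / rate, pi=pi, name=name, normalized=True)


# -- effective time ----------------------------------------------------------


def _default_overlap(p: np.ndarray, q: np.ndarray) -> float:
    # normalized dot-product overlap; local copy avoids a module cycle
    denom = p @ p + q @ q
    return float(2.0 * (p @ q) / denom) if denom else 0.0


def ancestral_type(
    profile: ColumnProfile,
    model: RateModel,
    t_grid: Sequence[float] | None = None,
    overlap_fn: Callable[[np.ndarray, np.ndarray], float] = _default_overlap,
) -> int:
    """Ancestral type of a column: its majority type.

    Ties among the top frequency are resolved in favor of the type whose free
    distribution, maximized over the time grid, overlaps the observed
    distribution best; any remaining exact tie falls back to canonical
    alphabet order.
    """
    if profile.empty:
        raise InputError(f"empty profile at position {profile.position}")
    grid = _T_GRID if t_grid is None else np.asarray(t_grid)
    f = profile.freq
    top = f.max()
    tied = np.flatnonzero(f >= top - 1e-12)
    if len(tied) == 1:
        return int(tied[0])
    best, best_val = int(tied[0]), -np.inf
    for a in tied:
        val = max(
            overlap_fn(model.transition_matrix(t)[a], f) for t in grid
        )
        if val > best_val + 1e-15:
            best, best_val = int(a), val
    return best


def _golden_refine(
    fn: Callable[[float], float], lo: float, hi: float, tol: float = 1e-3
) -> tuple[float, float]:
    """Golden-section maximization on [lo, hi], tracking the best point seen
    (including the endpoints, so a boundary maximum is returned exactly)."""
    invphi = (np.sqrt(5) - 1) / 2
    pts = [(lo, fn(lo)), (hi, fn(hi))]
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fn(c), fn(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fn(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fn(d)
        pts.append((c, fc))
        pts.append((d, fd))
    return max(pts, key=lambda p: p[1])


def best_time(
    profile: ColumnProfile,
    model: RateModel,
    overlap_fn: Callable[[np.ndarray, np.ndarray], float] = _default_overlap,
) -> float:
    """Time at which the free distribution from the column's ancestral type
    best overlaps the observed distribution (grid search + golden refinement)."""
    a = ancestral_type(profile, model, overlap_fn=overlap_fn)
    f = profile.freq

    def score(t: float) -> float:
        return overlap_fn(model.transition_matrix(t)[a], f)

    vals = np.array([score(t) for t in _T_GRID])
    k = int(np.argmax(vals))
    lo = _T_GRID[max(k - 1, 0)]
    hi = _T_GRID[min(k + 1, len(_T_GRID) - 1)]
    if hi <= lo:
        return float(_T_GRID[k])
    t_star, _ = _golden_refine(score, lo, hi)
    return float(min(max(t_star, 0.0), T_GRID_MAX))


def effective_time(
    profiles: Iterable[ColumnProfile],
    model: RateModel,
    overlap_fn: Callable[[np.ndarray, np.ndarray], float] = _default_overlap,
) -> float:
    """Family-wide effective divergence time.

    Unweighted mean, over every non-empty (position, group) profile, of the
    per-profile best overlap time.  One family-wide value is used in all
    observed-minus-expected corrections.
    """
    times = [best_time(p, model, overlap_fn) for p in profiles if not p.empty]
    if not times:
        raise InputError("no non-empty profiles; cannot estimate effective time")
    return float(np.mean(times))


def aa_index(aa: str) -> int:
    """Convenience re-export: canonical index of a one-letter code."""
    return index_of(aa)


__all__ = [
    "RateModel",
    "FreeDistribution",
    "load_rate_matrix",
    "transition_matrix",
    "stationary_distribution",
    "free_distribution",
    "ancestral_type",
    "best_time",
    "effective_time",
    "BUILTIN_MATRICES",
    "DEFAULT_MATRIX",
    "AMINO_ACIDS",
]
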