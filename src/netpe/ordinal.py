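"""Ordinal-pattern symbolic dynamics: permutation entropy and joint permutation entropy.

A window of ``n`` samples spaced ``tau`` apart is reduced to its ordinal
pattern: the permutation of amplitude ranks, with the *highest* amplitude
receiving rank 1 and the lowest rank ``n``.  Note that this rank convention
(largest sample first) is the reverse of the argsort-based convention used
by several permutation-entropy libraries; symbol indices therefore differ
from those conventions even though entropy values do not.  Each pattern is
encoded as its lexicographic index among the ``n!`` permutations of
``(1, ..., n)``.

Local complexity is the Shannon entropy of the pattern distribution,
normalized by ``log(n!)`` (permutation entropy, PE).  Coupling between two
channels is measured on the joint distribution of simultaneous symbol
pairs.  To suppress spurious zero-lag coupling from volume conduction /
field spread, all pairs of identical or mirrored patterns (the mirror of a
pattern complements every rank, ``r -> n + 1 - r``, i.e. the pattern of the
amplitude-inverted signal) are excluded before the joint entropy is taken.
The inverted, normalized joint entropy ``JPE_inv = 1 - JPE`` is then an
undirected connectivity index in ``[0, 1]``: higher means stronger
(non-zero-lag) coupling.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "OrdinalConfig",
    "SymbolSequence",
    "JointPatternMatrix",
    "ConnectivityResult",
    "symbolize",
    "pattern_distribution",
    "shannon_entropy",
    "permutation_entropy",
    "mirror_symbol",
    "mirror_table",
    "joint_distribution",
    "jpe_inv",
    "jpe_inv_from_symbols",
    "connectivity_matrix",
]

#: Retained joint probability mass below this is treated as pure volume
#: conduction (all mass on identical/mirrored pairs) and scored as 0 coupling.
DEGENERATE_MASS = 1e-9


@dataclass(frozen=True)
class OrdinalConfig:
    """Embedding parameters of the ordinal symbolization.

    Parameters
    ----------
    n : int
        Embedding dimension: number of samples per ordinal pattern
        (``n!`` distinct patterns).  Must satisfy ``n! <= T / 10`` for the
        epochs it is applied to, so pattern statistics are reliable.
    tau : int
        Time delay in samples between successive elements of a pattern
        window.
    """

    n: int = 4
    tau: int = 1

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 2:
            raise ValueError(f"embedding dimension n must be an integer >= 2, got {self.n}")
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError(f"time delay tau must be an integer >= 1, got {self.tau}")

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.n)

    def min_length(self) -> int:
        """Shortest epoch this config can symbolize, from both the window
        requirement ``T >= (n-1)*tau + 1`` and the statistical requirement
        ``n! <= T/10``."""
        return max((self.n - 1) * self.tau + 1, 10 * self.n_patterns)


@dataclass(frozen=True)
class SymbolSequence:
    """Ordinal symbol codes of one epoch; codes lie in ``[0, n! - 1]``."""

    symbols: np.ndarray
    n: int
    tau: int

    def __len__(self) -> int:
        return self.symbols.shape[-1]


@dataclass(frozen=True)
class JointPatternMatrix:
    """Joint symbol-pair probabilities of two channels with the
    volume-conduction exclusion mask.

    ``probs`` is the full ``n! x n!`` joint distribution (sums to 1);
    ``mask`` marks the excluded cells — identical pairs ``(a, a)`` and
    mirrored pairs ``(a, mirror(a))`` — and ``retained_mass`` is the
    probability mass left after exclusion.
    """

    probs: np.ndarray
    mask: np.ndarray
    n: int

    @property
    def retained_mass(self) -> float:
        return float(self.probs[~self.mask].sum())


@dataclass(frozen=True)
class ConnectivityResult:
    """Pairwise JPE_inv over all channels of a multichannel epoch."""

    matrix: np.ndarray
    config: OrdinalConfig
    band: str = "raw"
    channel_labels: tuple[str, ...] | None = None

    @property
    def roi_profile(self) -> np.ndarray:
        """Mean JPE_inv of each channel with all other channels
        (diagonal excluded)."""
        m = self.matrix
        return (m.sum(axis=1) - np.diag(m)) / (m.shape[0] - 1)


def _as_finite_1d(x, name: str = "epoch") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite samples")
    return x


@lru_cache(maxsize=None)
def _factorials(n: int) -> tuple[int, ...]:
    return tuple(math.factorial(n - 1 - i) for i in range(n))


@lru_cache(maxsize=None)
def mirror_table(n: int) -> np.ndarray:
    """Lookup table mapping each symbol to its mirrored (amplitude-reversed)
    symbol, i.e. the pattern with every rank complemented ``r -> n + 1 - r``.

    Time-reversed patterns are *not* mirrored pairs under this definition.
    """
    perms = list(itertools.permutations(range(1, n + 1)))  # lexicographic
    index = {p: i for i, p in enumerate(perms)}
    table = np.empty(len(perms), dtype=np.int64)
    for i, p in enumerate(perms):
        table[i] = index[tuple(n + 1 - r for r in p)]
    table.setflags(write=False)
    return table


def mirror_symbol(symbol: int, n: int) -> int:
    """Mirrored symbol of ``symbol`` for embedding dimension ``n``."""
    nf = math.factorial(n)
    if not 0 <= symbol < nf:
        raise ValueError(f"symbol {symbol} out of range [0, {nf}) for n={n}")
    return int(mirror_table(n)[symbol])


def _rank_windows(x: np.ndarray, n: int, tau: int) -> np.ndarray:
    """Rank vectors (highest amplitude -> rank 1; ties broken by temporal
    order, earlier sample gets the better rank) of all sliding windows."""
    m = x.shape[0] - (n - 1) * tau
    # windows[i] = (x[i], x[i+tau], ..., x[i+(n-1)tau])
    idx = np.arange(m)[:, None] + tau * np.arange(n)[None, :]
    w = x[idx]
    # stable argsort of -w: descending amplitude, earlier index wins ties
    order = np.argsort(-w, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(1, n + 1)[None, :], axis=1)
    return ranks


def _lehmer_index(ranks: np.ndarray) -> np.ndarray:
    """Lexicographic index of each rank vector among the n! permutations."""
    m, n = ranks.shape
    fac = _factorials(n)
    out = np.zeros(m, dtype=np.int64)
    for i in range(n - 1):
        smaller_right = (ranks[:, i + 1 :] < ranks[:, i : i + 1]).sum(axis=1)
        out += smaller_right * fac[i]
    return out


def symbolize(epoch, config: OrdinalConfig) -> SymbolSequence:
    """Convert a time series to its ordinal symbol sequence.

    Returns ``T - (n - 1) * tau`` symbols, one per sliding window
    ``(x_t, x_{t+tau}, ..., x_{t+(n-1)tau})``.  Raises ``ValueError`` if the
    epoch is too short for a single window or contains non-finite samples.
    The statistical requirement ``n! <= T/10`` is enforced where epochs and
    config meet (pipeline configuration), not here, so that short diagnostic
    sequences remain symbolizable.
    """
    x = _as_finite_1d(epoch)
    T = x.shape[0]
    if T < (config.n - 1) * config.tau + 1:
        raise ValueError(
            f"epoch of length {T} too short for n={config.n}, tau={config.tau}: "
            f"needs at least {(config.n - 1) * config.tau + 1} samples"
        )
    ranks = _rank_windows(x, config.n, config.tau)
    return SymbolSequence(_lehmer_index(ranks), n=config.n, tau=config.tau)


def pattern_distribution(seq: SymbolSequence) -> np.ndarray:
    """Relative frequencies of the ``n!`` ordinal patterns."""
    if len(seq) == 0:
        raise ValueError("cannot form a pattern distribution from an empty sequence")
    counts = np.bincount(seq.symbols, minlength=math.factorial(seq.n))
    return counts / counts.sum()


def shannon_entropy(p) -> float:
    """Shannon entropy (natural log) of a probability vector; 0*log(0) := 0."""
    p = np.asarray(p, dtype=float).ravel()
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def permutation_entropy(epoch, config: OrdinalConfig) -> float:
    """Normalized permutation entropy PE = H / log(n!) in [0, 1].

    PE is invariant under strictly increasing transforms of the amplitudes
    and is exactly 0 for a strictly monotone epoch.
    """
    seq = symbolize(epoch, config)
    h = shannon_entropy(pattern_distribution(seq))
    return float(np.clip(h / math.log(config.n_patterns), 0.0, 1.0)) + 0.0


def _check_pair(sx: SymbolSequence, sy: SymbolSequence) -> None:
    if sx.n != sy.n:
        raise ValueError(f"embedding dimensions differ: {sx.n} vs {sy.n}")
    if len(sx) != len(sy):
        raise ValueError(f"symbol sequences differ in length: {len(sx)} vs {len(sy)}")


def _exclusion_mask(n: int) -> np.ndarray:
    nf = math.factorial(n)
    mask = np.zeros((nf, nf), dtype=bool)
    a = np.arange(nf)
    mask[a, a] = True
    mask[a, mirror_table(n)] = True
    return mask


def joint_distribution(sx: SymbolSequence, sy: SymbolSequence) -> JointPatternMatrix:
    """Joint distribution of simultaneous symbol pairs of two channels.

    Cell ``(a, b)`` is the fraction of time points at which channel x shows
    pattern ``a`` and channel y pattern ``b``; row sums are the marginal
    pattern distribution of x, column sums that of y.
    """
    _check_pair(sx, sy)
    if len(sx) == 0:
        raise ValueError("cannot form a joint distribution from empty sequences")
    nf = math.factorial(sx.n)
    counts = np.bincount(sx.symbols * nf + sy.symbols, minlength=nf * nf)
    probs = (counts / counts.sum()).reshape(nf, nf)
    return JointPatternMatrix(probs=probs, mask=_exclusion_mask(sx.n), n=sx.n)


def _jpe_inv_from_joint(
    joint: JointPatternMatrix, *, corrected: bool = True, renormalize: bool = True
) -> float:
    nf = math.factorial(joint.n)
    if corrected:
        # sort for a summation order invariant under channel swap (the mask
        # is a transpose-symmetric set), making jpe_inv bit-exactly symmetric
        retained = np.sort(joint.probs[~joint.mask])
        n_bins = retained.size  # n!^2 - |identical ∪ mirrored|
        mass = retained.sum()
        if mass < DEGENERATE_MASS:
            # all mass sits on identical/mirrored pairs — the exact signature
            # of volume conduction the exclusion targets
            logger.warning(
                "joint pattern mass entirely on identical/mirrored pairs "
                "(retained %.3g); JPE_inv set to 0", mass,
            )
            return 0.0
        p = retained / mass if renormalize else retained
    else:
        p = np.sort(joint.probs.ravel())
        n_bins = nf * nf
        mass = 1.0
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    jpe = h / math.log(n_bins)
    return float(np.clip(1.0 - jpe, 0.0, 1.0))


def jpe_inv_from_symbols(
    sx: SymbolSequence,
    sy: SymbolSequence,
    *,
    corrected: bool = True,
    renormalize: bool = True,
) -> float:
    """Inverted joint permutation entropy from pre-computed symbol sequences.

    With ``corrected=True`` (default) identical and mirrored symbol pairs
    are excluded, the retained cells renormalized to a distribution (unless
    ``renormalize=False``), and the joint entropy normalized by
    ``log(#retained bins)`` (``log(n!*n! - 2*n!)`` for n >= 2).  With
    ``corrected=False`` no exclusion is applied and the normalizer is
    ``log(n!*n!)``.
    """
    _check_pair(sx, sy)
    return _jpe_inv_from_joint(
        joint_distribution(sx, sy), corrected=corrected, renormalize=renormalize
    )


def jpe_inv(
    epoch_x,
    epoch_y,
    config: OrdinalConfig,
    *,
    corrected: bool = True,
    renormalize: bool = True,
) -> float:
    """Inverted joint permutation entropy of two time-aligned epochs.

    Symmetric in its arguments and bounded in [0, 1]; identical or
    amplitude-inverted channel pairs score exactly 0 (their mass is entirely
    on excluded cells), independent channels score near 0, and lagged
    coupling raises the value.
    """
    x = _as_finite_1d(epoch_x, "epoch_x")
    y = _as_finite_1d(epoch_y, "epoch_y")
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"epochs differ in length: {x.shape[0]} vs {y.shape[0]}")
    sx = symbolize(x, config)
    sy = symbolize(y, config)
    return jpe_inv_from_symbols(sx, sy, corrected=corrected, renormalize=renormalize)


def connectivity_matrix(
    data,
    config: OrdinalConfig,
    *,
    band: str = "raw",
    channel_labels=None,
    corrected: bool = True,
    renormalize: bool = True,
) -> ConnectivityResult:
    """Pairwise JPE_inv over all channel pairs of a ``channels x samples`` epoch.

    Each channel is symbolized once and reused across pairs; the result
    matrix is symmetric with a zero diagonal.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError(f"expected a channels x samples matrix, got shape {data.shape}")
    n_ch = data.shape[0]
    if n_ch < 2:
        raise ValueError("connectivity needs at least 2 channels")
    symbols = [symbolize(data[c], config) for c in range(n_ch)]
    nf = config.n_patterns
    mask = _exclusion_mask(config.n)
    matrix = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        si = symbols[i].symbols * nf
        for j in range(i + 1, n_ch):
            counts = np.bincount(si + symbols[j].symbols, minlength=nf * nf)
            joint = JointPatternMatrix(
                probs=(counts / counts.sum()).reshape(nf, nf), mask=mask, n=config.n
            )
            v = _jpe_inv_from_joint(joint, corrected=corrected, renormalize=renormalize)
            matrix[i, j] = matrix[j, i] = v
    labels = tuple(channel_labels) if channel_labels is not None else None
    return ConnectivityResult(matrix=matrix, config=config, band=band, channel_labels=labels)
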