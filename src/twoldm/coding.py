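"""Population-code primitives: binarization, interpulse intervals, renewal counts.

A likelihood series is recoded as a pulse train (the delta-code): a
pulse whenever the value strictly exceeds a threshold.  The lengths of
the zero runs between pulses are the empirical interpulse intervals
(IPIs), the observable analogue of first-passage times.  By the renewal
central limit theorem, the accumulated count N(t) of a renewal process
with interval mean mu and SD sigma is asymptotically Gaussian with mean
t/mu and variance t*sigma^2/mu^3; population count series are
reconstructed by averaging such Gaussians over a population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LikelihoodSeries",
    "BinaryCode",
    "IPISequence",
    "CountSeries",
    "binarize",
    "extract_ipi",
    "infomax_threshold",
    "reconstruct_counts",
    "rate",
    "renewal_pulse_code",
]


class InsufficientDataError(ValueError):
    """Raised when a series yields too few pulses or intervals to continue."""


@dataclass(frozen=True)
class LikelihoodSeries:
    """Bounded probability time series (y|x), sampled every ``dt`` seconds."""

    values: np.ndarray
    dt: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("likelihood series must be a nonempty 1-d array")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("likelihood values must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class BinaryCode:
    """0/1 pulse train together with the threshold that produced it."""

    bits: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=np.int8))
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0 or 1")

    def __len__(self) -> int:
        return self.bits.size


@dataclass(frozen=True)
class IPISequence:
    """Holding times (in samples) between consecutive pulses."""

    intervals: np.ndarray

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.int64)
        if iv.size == 0 or np.any(iv < 1):
            raise ValueError("intervals must be a nonempty array of integers >= 1")
        object.__setattr__(self, "intervals", iv)

    @property
    def mu(self) -> float:
        return float(np.mean(self.intervals))

    @property
    def sigma(self) -> float:
        return float(np.std(self.intervals, ddof=1)) if self.intervals.size > 1 else 0.0

    def __len__(self) -> int:
        return self.intervals.size


@dataclass(frozen=True)
class CountSeries:
    """Accumulated-evidence counts per sample, with the source IPI moments."""

    values: np.ndarray
    mu_src: float
    sigma_src: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("count series must be finite")

    def __len__(self) -> int:
        return self.values.size


def _series_values(y) -> np.ndarray:
    if isinstance(y, (LikelihoodSeries, CountSeries)):
        return y.values
    return np.asarray(y, dtype=float)


def binarize(y, threshold: float) -> BinaryCode:
    """Pulse-code a series: bit 1 iff value > threshold (strict)."""
    values = _series_values(y)
    if values.size == 0:
        raise ValueError("cannot binarize an empty series")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return BinaryCode(bits=(values > threshold).astype(np.int8), threshold=float(threshold))


def extract_ipi(code: BinaryCode) -> IPISequence:
    """Interpulse intervals: lengths of pulse-terminated maximal zero runs.

    The leading zero run counts if a pulse terminates it; the trailing run
    is censored (no terminating pulse) and is discarded, as are the empty
    gaps between immediately adjacent pulses — a holding time of zero is
    not a renewal interval.
    """
    pulse_idx = np.flatnonzero(code.bits == 1)
    if pulse_idx.size < 2:
        raise InsufficientDataError(
            f"need at least 2 pulses to form an interval; found {pulse_idx.size}"
        )
    gaps = np.diff(pulse_idx) - 1
    if pulse_idx[0] > 0:
        gaps = np.concatenate([[pulse_idx[0]], gaps])
    gaps = gaps[gaps >= 1]
    if gaps.size < 2:
        raise InsufficientDataError(
            f"need at least 2 complete nonzero intervals; found {gaps.size}"
        )
    return IPISequence(intervals=gaps)


def infomax_threshold(y) -> float:
    """Mean of the series, the infomax initialization delta_0 = E(y|x).

    For a unimodal, near-symmetric likelihood the mean sits close to the
    median, so thresholding at the mean yields a near-balanced binary
    code, approximately maximizing the entropy of the pulse train.
    """
    values = _series_values(y)
    if values.size == 0:
        raise ValueError("cannot take the mean of an empty series")
    return float(np.mean(values))


def reconstruct_counts(
    ipi: IPISequence | tuple[float, float],
    horizon: int,
    n_pop: int,
    seed,
) -> CountSeries:
    """Renewal-CLT reconstruction of the population count series N(t).

    At each 1-based sample t, the count is the average over ``n_pop``
    independent Gaussian draws with mean t/mu and variance t*sigma^2/mu^3.
    ``ipi`` may be an IPISequence or a precomputed (mu, sigma) pair.
    """
    if isinstance(ipi, IPISequence):
        mu, sigma = ipi.mu, ipi.sigma
    else:
        mu, sigma = float(ipi[0]), float(ipi[1])
    if mu <= 0 or sigma < 0:
        raise ValueError(f"need mu > 0 and sigma >= 0; got mu={mu}, sigma={sigma}")
    if horizon < 1 or n_pop < 1:
        raise ValueError("horizon and n_pop must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(1, horizon + 1, dtype=float)
    mean = t / mu
    sd = np.sqrt(t * sigma**2 / mu**3)
    draws = mean[:, None] + sd[:, None] * rng.standard_normal((horizon, n_pop))
    return CountSeries(values=draws.mean(axis=1), mu_src=mu, sigma_src=sigma)


def rate(N: CountSeries) -> np.ndarray:
    """Activity rate N(t)/t (t 1-based); stationary value 1/mu for a renewal count."""
    t = np.arange(1, len(N) + 1, dtype=float)
    return N.values / t


def renewal_pulse_code(N: CountSeries, threshold: float) -> BinaryCode:
    """Recode a count series as pulses of threshold crossings.

    Scans the increments of N (taking N(0) = 0), accumulating them; each
    time the accumulator reaches ``threshold`` a pulse is emitted and the
    accumulator resets, i.e. the count restarts as a renewal process.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    increments = np.diff(N.values, prepend=0.0)
    bits = np.zeros(len(N), dtype=np.int8)
    acc = 0.0
    for i, inc in enumerate(increments):
        acc += inc
        if acc >= threshold:
            bits[i] = 1
            acc = 0.0
    return BinaryCode(bits=bits, threshold=float(threshold))
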