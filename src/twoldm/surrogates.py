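"""Surrogate-data machinery: iAAFT resampling, noise injection, runs-test screening.

The null ensemble is built from iterated amplitude adjusted Fourier
transform (iAAFT) surrogates — exact permutations of the source values
whose power spectrum is iteratively matched to the original — perturbed
by Gaussian noise at a fixed number of random positions, and screened by
a Wald-Wolfowitz runs test so that only serially dependent
("realistic-structured") members are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "RunsTestResult",
    "SurrogateEnsemble",
    "iaaft",
    "add_noise_points",
    "runs_test",
    "generate_ensemble",
]


@dataclass(frozen=True)
class RunsTestResult:
    n_runs: int
    z: float
    p: float
    reject: bool


@dataclass(frozen=True)
class SurrogateEnsemble:
    members: list
    accepted: np.ndarray
    seed_map: np.ndarray
    clipped: np.ndarray

    @property
    def accepted_members(self) -> list:
        return [m for m, a in zip(self.members, self.accepted) if a]


def iaaft(y, max_iter: int = 100, tol: float = 1e-8, seed=None) -> np.ndarray:
    """Iterated amplitude adjusted Fourier transform surrogate.

    Alternates (i) imposing the target amplitude spectrum and (ii) rank
    remapping onto the original value distribution, until the relative
    change in the spectrum mismatch falls below ``tol`` or ``max_iter``
    is reached.  The rank remap runs last, so the surrogate is always an
    exact permutation of the source values.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2 or np.ptp(y) == 0.0:
        return y.copy()
    rng = np.random.default_rng(seed)
    sorted_y = np.sort(y)
    target_amp = np.abs(np.fft.rfft(y))
    x = rng.permutation(y)
    prev_err = np.inf
    for _ in range(max_iter):
        # (i) impose the target amplitude spectrum, keep current phases
        spec = np.fft.rfft(x)
        phases = np.angle(spec)
        x = np.fft.irfft(target_amp * np.exp(1j * phases), n=y.size)
        # (ii) rank remap to the original marginal distribution
        ranks = np.argsort(np.argsort(x))
        x = sorted_y[ranks]
        err = float(np.linalg.norm(np.abs(np.fft.rfft(x)) - target_amp))
        denom = float(np.linalg.norm(target_amp))
        if denom > 0 and abs(prev_err - err) / denom < tol:
            break
        prev_err = err
    return x


def add_noise_points(
    y,
    n_points: int = 30,
    c: float = 1.0,
    seed=None,
    clip_unit: bool = False,
) -> tuple[np.ndarray, bool]:
    """Perturb ``n_points`` distinct random positions with N(0, (c*SD(y))^2) noise.

    For probability-valued series pass ``clip_unit=True`` to clip the
    result to [0, 1]; the returned flag reports whether clipping changed
    any value.
    """
    y = np.asarray(y, dtype=float)
    if n_points > y.size:
        raise ValueError(f"n_points={n_points} exceeds series length {y.size}")
    out = y.copy()
    if n_points == 0:
        return out, False
    rng = np.random.default_rng(seed)
    idx = rng.choice(y.size, size=n_points, replace=False)
    sd = c * float(np.std(y))
    out[idx] = out[idx] + rng.normal(0.0, sd, size=n_points)
    clipped = False
    if clip_unit:
        clipped = bool(np.any(out < 0) or np.any(out > 1))
        np.clip(out, 0.0, 1.0, out=out)
    return out, clipped


def runs_test(y, alpha: float = 0.05) -> RunsTestResult:
    """Wald-Wolfowitz runs test for serial independence.

    Values are dichotomized about the median (exact ties dropped); the
    run count is compared with its null mean via the normal approximation
    with continuity correction.  Small p means the sequence has too few
    (clustering) or too many (alternation) runs to be independent.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 20:
        raise ValueError("runs test needs at least 20 samples")
    med = np.median(y)
    signs = np.sign(y - med)
    signs = signs[signs != 0]
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    if n1 == 0 or n2 == 0:
        raise ValueError("runs test undefined for a (near-)constant series")
    runs = int(1 + np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mean_r = 2.0 * n1 * n2 / n + 1.0
    var_r = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    diff = runs - mean_r
    cc = min(0.5, abs(diff))  # continuity correction, never across zero
    z = (abs(diff) - cc) / np.sqrt(var_r) * np.sign(diff) if var_r > 0 else 0.0
    p = float(2.0 * norm.sf(abs(z)))
    return RunsTestResult(n_runs=runs, z=float(z), p=p, reject=bool(p < alpha))


def generate_ensemble(
    y,
    n: int = 100,
    keep_target: int = 40,
    n_noise_points: int = 30,
    noise_c: float = 1.0,
    clip_unit: bool = True,
    alpha: float = 0.05,
    seed=None,
) -> SurrogateEnsemble:
    """Build the screened surrogate ensemble.

    Each member is an iAAFT surrogate with noise injected at
    ``n_noise_points`` positions; members are flagged accepted when the
    runs test rejects serial independence at level ``alpha``.  Fewer than
    ``keep_target`` accepted members triggers a warning, not an error.
    """
    y = np.asarray(y, dtype=float)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    seed_map = np.array([int(c.generate_state(1)[0] % (2**31)) for c in children])
    members, accepted, clipped = [], [], []
    for member_seed in seed_map:
        sub = np.random.SeedSequence(int(member_seed)).spawn(2)
        sur = iaaft(y, seed=sub[0])
        sur, was_clipped = add_noise_points(
            sur, n_points=n_noise_points, c=noise_c, seed=sub[1], clip_unit=clip_unit
        )
        members.append(sur)
        clipped.append(was_clipped)
        try:
            accepted.append(runs_test(sur, alpha=alpha).reject)
        except ValueError:
            accepted.append(False)
    accepted = np.asarray(accepted, dtype=bool)
    if int(accepted.sum()) < keep_target:
        warnings.warn(
            f"only {int(accepted.sum())} of {n} surrogates passed runs-test "
            f"screening (target {keep_target})",
            stacklevel=2,
        )
    return SurrogateEnsemble(
        members=members,
        accepted=accepted,
        seed_map=seed_map,
        clipped=np.asarray(clipped, dtype=bool),
    )
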