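"""Backward two-layer estimation of the diffusion parameters.

Layer 2 (the choice layer) is fitted first: the likelihood series is
pulse-coded at delta_0, and the ex-Wald CDF is matched against the
empirical CDF of the resulting interpulse intervals by minimizing the
RMSE between the two.  The fitted threshold theta_2 then recodes the
reconstructed count series N_2, whose intervals drive the layer-1
(valuation) fit in the same way.

Identifiability note: the Wald law is invariant under a common rescaling
of (v, s, theta), so holding times determine only the first-passage mean
mu_w = theta/v, the shape lambda = theta^2/s^2, and the exponential rate
gamma.  The search runs over those three identifiable quantities; the
drift is normalized to ``v_fixed`` (default 1 evidence unit per sample),
so theta = v*mu_w and the noise scale s = theta/sqrt(lambda) absorb the
estimated quantities.  Under this convention the comparatively
noise-sensitive shape estimate lands in s, while theta inherits the
well-determined first-passage mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .coding import (
    CountSeries,
    InsufficientDataError,
    IPISequence,
    LikelihoodSeries,
    binarize,
    extract_ipi,
    infomax_threshold,
    reconstruct_counts,
    renewal_pulse_code,
)
from .exwald import ExWaldParams, exwald_cdf

__all__ = [
    "SearchConfig",
    "LayerFit",
    "TwoLayerResult",
    "rmse_cdf",
    "fit_layer",
    "fit_two_layers",
]

MIN_INTERVALS = 5


@dataclass(frozen=True)
class SearchConfig:
    """Two-stage search settings for :func:`fit_layer`.

    ``grid_points`` log-spaced points per identifiable parameter around
    the moment-based initial guess (span ``grid_span`` on either side),
    followed by Nelder-Mead refinement in log-space.
    """

    grid_points: int = 8
    grid_span: float = 3.0
    nm_maxiter: int = 400
    v_fixed: float = 1.0


@dataclass(frozen=True)
class LayerFit:
    layer: int
    params: ExWaldParams
    rmse: float
    threshold_in: float
    clipped: bool = False


@dataclass(frozen=True)
class TwoLayerResult:
    fit2: LayerFit
    fit1: LayerFit
    N2: CountSeries
    N1: CountSeries
    delta0: float
    ipi2: IPISequence = None
    ipi1: IPISequence = None


def _deround(sorted_x: np.ndarray) -> np.ndarray:
    """Spread tied integer intervals uniformly over their one-sample bin.

    An interval recorded as j whole samples means a continuous passage
    time in (j-1, j]; the c ties at j are placed at j-1 + (l-0.5)/c,
    which removes the sawtooth mismatch between a step empirical CDF and
    the smooth model CDF.
    """
    out = np.empty_like(sorted_x)
    vals, counts = np.unique(sorted_x, return_counts=True)
    i = 0
    for v, c in zip(vals, counts):
        out[i : i + c] = v - 1.0 + (np.arange(1, c + 1) - 0.5) / c
        i += c
    return np.maximum(out, 0.0)


def rmse_cdf(ipi: IPISequence, p: ExWaldParams, deround: bool = True) -> float:
    """RMSE between the ex-Wald CDF and the empirical interval CDF.

    The empirical CDF uses Hazen plotting positions (i - 0.5)/n at the
    sorted observed intervals, which keeps both tails off 0 and 1.
    Because intervals are whole samples while the passage time is
    continuous, tied values are by default de-rounded uniformly within
    their sample bin (see :func:`_deround`); pass ``deround=False`` to
    evaluate at the raw integer values.
    """
    x = np.sort(np.asarray(ipi.intervals, dtype=float))
    if deround:
        x = _deround(x)
    n = x.size
    pp = (np.arange(1, n + 1) - 0.5) / n
    return float(np.sqrt(np.mean((exwald_cdf(x, p) - pp) ** 2)))


def _params_from_identifiable(mu_w: float, lam: float, gamma: float, v: float) -> ExWaldParams:
    # theta/v = mu_w, theta^2/s^2 = lam; drift normalized to v
    theta = v * mu_w
    return ExWaldParams(v=v, s=theta / np.sqrt(lam), theta=theta, gamma=gamma)


def _gamma_cap(mu_w: float, lam: float) -> float:
    # real-k constraint v^2 >= 2*gamma*s^2 in identifiable coordinates
    return lam / (2.0 * mu_w**2)


def _moment_init(ipi: IPISequence) -> tuple[float, float, float]:
    mu, sigma = ipi.mu, ipi.sigma
    # split the variance between the Wald and exponential stages; floors
    # guard degenerate (near-constant, integer-valued) interval samples
    inv_gamma = max(sigma / np.sqrt(2.0), 0.05 * mu)
    inv_gamma = min(inv_gamma, 0.8 * mu)
    mu_w = max(mu - inv_gamma, 0.1 * mu)
    var_w = max(sigma**2 - inv_gamma**2, 0.25 * sigma**2, 1.0 / 12.0)
    lam = mu_w**3 / var_w
    gamma = min(1.0 / inv_gamma, 0.99 * _gamma_cap(mu_w, lam))  # stay in the real-k region
    return mu_w, lam, gamma


def fit_layer(
    ipi: IPISequence,
    search: SearchConfig | None = None,
    seed=0,
    layer: int = 0,
    threshold_in: float = float("nan"),
) -> LayerFit:
    """Fit ex-Wald parameters to an interval sample by CDF-RMSE matching.

    Coarse log-spaced grid around moment-based initial guesses, then
    derivative-free (Nelder-Mead) refinement; the real-k constraint
    gamma <= lambda/(2*mu_w^2) is enforced by clipping with a penalty,
    and a fit that ends on the clip boundary is flagged.
    """
    if len(ipi) < MIN_INTERVALS:
        raise InsufficientDataError(
            f"layer fitting needs >= {MIN_INTERVALS} intervals; got {len(ipi)}"
        )
    cfg = search or SearchConfig()
    v = cfg.v_fixed
    x = _deround(np.sort(np.asarray(ipi.intervals, dtype=float)))
    pp = (np.arange(1, x.size + 1) - 0.5) / x.size

    clipped_flag = [False]

    def objective(log_q: np.ndarray) -> float:
        mu_w, lam, gamma = np.exp(log_q)
        cap = _gamma_cap(mu_w, lam)
        penalty = 0.0
        if gamma > 0.999 * cap:
            penalty = 1e-3 * np.log(gamma / (0.999 * cap) + 1.0)
            gamma = 0.999 * cap
        p = _params_from_identifiable(mu_w, lam, gamma, v)
        return float(np.sqrt(np.mean((exwald_cdf(x, p) - pp) ** 2))) + penalty

    mu_w0, lam0, gamma0 = _moment_init(ipi)
    gamma0 = min(gamma0, 0.99 * _gamma_cap(mu_w0, lam0))
    q0 = np.log([mu_w0, lam0, gamma0])

    # stage 1: coarse grid
    factors = np.log(np.geomspace(1.0 / cfg.grid_span, cfg.grid_span, cfg.grid_points))
    best_q, best_val = q0, objective(q0)
    for a in factors:
        for b in factors:
            for c in factors:
                q = q0 + np.array([a, b, c])
                val = objective(q)
                if val < best_val:
                    best_q, best_val = q, val

    # stage 2: local refinement
    res = minimize(
        objective,
        best_q,
        method="Nelder-Mead",
        options={"maxiter": cfg.nm_maxiter, "xatol": 1e-6, "fatol": 1e-10},
    )
    q_fin = res.x if res.fun <= best_val else best_q

    mu_w, lam, gamma = np.exp(q_fin)
    cap = _gamma_cap(mu_w, lam)
    if gamma > 0.999 * cap:
        gamma = 0.999 * cap
        clipped_flag[0] = True
    params = _params_from_identifiable(mu_w, lam, gamma, v)
    return LayerFit(
        layer=layer,
        params=params,
        rmse=rmse_cdf(ipi, params),
        threshold_in=float(threshold_in),
        clipped=clipped_flag[0],
    )


def fit_two_layers(
    y: LikelihoodSeries,
    delta0: float | str = "auto",
    n_pop: int = 50,
    seed=0,
    search: SearchConfig | None = None,
) -> TwoLayerResult:
    """Run the backward two-layer estimation pipeline.

    binarize(y, delta_0) -> IPI(delta_0) -> layer-2 fit -> reconstruct N_2
    -> recode at theta_2 -> IPI(theta_2) -> layer-1 fit -> reconstruct N_1.
    Stage failures raise :class:`InsufficientDataError` naming the stage.
    """
    if delta0 == "auto":
        delta0 = infomax_threshold(y)
    delta0 = float(delta0)
    ss = np.random.SeedSequence(seed)
    seed_n2, seed_n1 = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    horizon = len(y)

    try:
        ipi2 = extract_ipi(binarize(y, delta0))
    except InsufficientDataError as e:
        raise InsufficientDataError(f"stage binarize/extract_ipi(delta0): {e}") from e
    try:
        fit2 = fit_layer(ipi2, search=search, seed=seed, layer=2, threshold_in=delta0)
    except InsufficientDataError as e:
        raise InsufficientDataError(f"stage fit_layer(layer 2): {e}") from e

    N2 = reconstruct_counts(ipi2, horizon=horizon, n_pop=n_pop, seed=seed_n2)

    try:
        ipi1 = extract_ipi(renewal_pulse_code(N2, fit2.params.theta))
    except InsufficientDataError as e:
        raise InsufficientDataError(f"stage renewal_pulse_code/extract_ipi(theta2): {e}") from e
    try:
        fit1 = fit_layer(ipi1, search=search, seed=seed, layer=1, threshold_in=fit2.params.theta)
    except InsufficientDataError as e:
        raise InsufficientDataError(f"stage fit_layer(layer 1): {e}") from e

    N1 = reconstruct_counts(ipi1, horizon=horizon, n_pop=n_pop, seed=seed_n1)
    return TwoLayerResult(fit2=fit2, fit1=fit1, N2=N2, N1=N1, delta0=delta0, ipi2=ipi2, ipi1=ipi1)
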