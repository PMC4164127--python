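"""Synthetic likelihood series emulating a TAFC visual-targeting experiment.

The generator mimics the probability of gaze targeting the finally
chosen image over a 5 s trial sampled every 50 ms (100 samples): a
mildly rising logistic preference trend (gaze drifts toward the chosen
alternative late in the trial) plus AR(1) noise, affinely rescaled to
the target mean 0.66 and SD 0.095 and clipped into (0, 1).  The AR
structure is strong enough that a runs test rejects serial independence
for nearly every seed, which the downstream surrogate screening relies
on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coding import LikelihoodSeries, rate
from .fitting import SearchConfig, TwoLayerResult, fit_two_layers
from .ln_cascade import GainSeries, band_power, fit_gain_model, gain_series
from .surrogates import SurrogateEnsemble, generate_ensemble, iaaft
from .synchrony import SyncTestResult, hilbert_phase, sync_test, windowed_sync

__all__ = ["SynthConfig", "generate_likelihood", "generate_full_fixture", "FixtureBundle"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults reproduce the study conditions."""

    length: int = 100
    target_mean: float = 0.66
    target_sd: float = 0.095
    ar_coefficient: float = 0.8
    trend_gain: float = 1.0
    dt: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_mean < 1.0):
            raise ValueError("target_mean must lie in (0, 1)")
        if self.target_sd <= 0:
            raise ValueError("target_sd must be positive")
        if abs(self.ar_coefficient) >= 1.0:
            raise ValueError("|ar_coefficient| must be < 1 for stationarity")
        if self.length < 20:
            raise ValueError("length must be >= 20 for downstream fitting")


def generate_likelihood(cfg: SynthConfig | None = None, **kwargs) -> LikelihoodSeries:
    """Seeded likelihood series: logistic rising trend + AR(1) noise.

    The raw trend-plus-noise series is affinely rescaled to
    (target_mean, target_sd) and clipped to [0.01, 0.99]; with the
    default SD the clip is ~3.5 sigma away and essentially never binds.
    """
    cfg = replace(cfg, **kwargs) if cfg is not None else SynthConfig(**kwargs)
    rng = np.random.default_rng(cfg.seed)
    L = cfg.length
    t = np.arange(L, dtype=float)
    # preference consolidates in the last third of the trial
    trend = cfg.trend_gain / (1.0 + np.exp(-(t - 0.65 * L) / (0.08 * L)))
    phi = cfg.ar_coefficient
    innov = rng.standard_normal(L) * np.sqrt(1.0 - phi**2)
    noise = np.empty(L)
    noise[0] = rng.standard_normal()
    for i in range(1, L):
        noise[i] = phi * noise[i - 1] + innov[i]
    raw = trend + noise
    raw = (raw - raw.mean()) / raw.std() * cfg.target_sd + cfg.target_mean
    return LikelihoodSeries(values=np.clip(raw, 0.01, 0.99), dt=cfg.dt)


@dataclass(frozen=True)
class FixtureBundle:
    """All intermediate artifacts of one end-to-end run, for regression tests."""

    series: LikelihoodSeries
    two_layer: TwoLayerResult
    rates: dict
    gains: dict
    band_powers: dict
    ensemble: SurrogateEnsemble
    sync: SyncTestResult


def generate_full_fixture(
    cfg: SynthConfig | None = None,
    n_surrogates: int = 20,
    n_pop: int = 50,
    depth: int = 6,
    n_boot: int = 2000,
    search: SearchConfig | None = None,
) -> FixtureBundle:
    """Run the whole pipeline end-to-end on a generated series.

    Reduced ensemble size (default 20) keeps the fixture fast; every
    stage is seeded from ``cfg.seed`` so the bundle is bit-reproducible.
    """
    cfg = cfg or SynthConfig()
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]
    y = generate_likelihood(cfg)

    result = fit_two_layers(y, delta0="auto", n_pop=n_pop, seed=seeds[0], search=search)
    rates = {"N1": rate(result.N1), "N2": rate(result.N2)}

    # LN gain per layer: z is the pulse code each count series drives
    from .coding import binarize, renewal_pulse_code

    z2 = binarize(y, result.delta0)
    z1 = renewal_pulse_code(result.N2, result.fit2.params.theta)
    gains = {}
    band_powers = {}
    for name, (N, z) in {"P1": (result.N1, z1), "P2": (result.N2, z2)}.items():
        model = fit_gain_model(N, z)
        gs = gain_series(N, model, observed=z)
        gains[name] = GainSeries(z=gs.z, residual=gs.residual)
        band_powers[name] = band_power(gs, dt=cfg.dt)

    ensemble = generate_ensemble(
        y.values, n=n_surrogates, keep_target=max(2, n_surrogates // 3), seed=seeds[1]
    )

    phi1 = hilbert_phase(rates["N1"])
    phi2 = hilbert_phase(rates["N2"])
    eta = windowed_sync(phi1, phi2, depth=depth)
    sur1 = iaaft(rates["N1"], seed=np.random.SeedSequence(seeds[2]))
    sur2 = iaaft(rates["N2"], seed=np.random.SeedSequence(seeds[3]))
    eta_sur = windowed_sync(hilbert_phase(sur1), hilbert_phase(sur2), depth=depth)
    sync = sync_test(eta, eta_sur, n_boot=n_boot, seed=seeds[2])

    return FixtureBundle(
        series=y,
        two_layer=result,
        rates=rates,
        gains=gains,
        band_powers=band_powers,
        ensemble=ensemble,
        sync=sync,
    )
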