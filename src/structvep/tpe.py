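"""Seeded tree-structured Parzen estimator (TPE) for hyperparameter search.

Sequential model-based optimization with a suggest/observe loop: after a
random start-up phase, observed trials are split at the gamma quantile of the
objective into "good" and "bad" sets; per dimension a Parzen (Gaussian-kernel)
density l(x) is fitted to the good values and g(x) to the bad ones, candidates
are drawn from l, and the candidate maximizing sum(log l - log g) across
dimensions is suggested.  Integer dimensions are sampled in the reals and
rounded; log-uniform dimensions work in log space; categorical dimensions use
Laplace-smoothed frequencies.  All randomness flows from one seeded generator,
so suggestions are fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float


@dataclass(frozen=True)
class LogUniform:
    low: float
    high: float


@dataclass(frozen=True)
class Int:
    low: int
    high: int  # inclusive


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def __init__(self, choices):
        object.__setattr__(self, "choices", tuple(choices))


ParamSpec = Uniform | LogUniform | Int | Categorical


def _to_internal(spec: ParamSpec, value):
    if isinstance(spec, LogUniform):
        return np.log(value)
    if isinstance(spec, Categorical):
        return spec.choices.index(value)
    return float(value)


def _from_internal(spec: ParamSpec, value):
    if isinstance(spec, LogUniform):
        return float(np.exp(value))
    if isinstance(spec, Int):
        return int(np.clip(round(value), spec.low, spec.high))
    if isinstance(spec, Categorical):
        return spec.choices[int(value)]
    return float(np.clip(value, spec.low, spec.high))


def _bounds(spec: ParamSpec) -> tuple[float, float]:
    if isinstance(spec, LogUniform):
        return np.log(spec.low), np.log(spec.high)
    return float(spec.low), float(spec.high)


@dataclass
class TPEOptimizer:
    space: dict[str, ParamSpec]
    seed: int = 0
    n_startup: int = 8
    gamma: float = 0.25
    n_candidates: int = 24
    maximize: bool = True
    _params: list[dict] = field(default_factory=list, init=False)
    _values: list[float] = field(default_factory=list, init=False)

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    # -- sampling helpers --------------------------------------------------

    def _sample_prior(self, spec: ParamSpec):
        rng = self._rng
        if isinstance(spec, Categorical):
            return spec.choices[rng.integers(len(spec.choices))]
        lo, hi = _bounds(spec)
        return _from_internal(spec, rng.uniform(lo, hi))

    def _kde_sample(self, obs: np.ndarray, lo: float, hi: float) -> float:
        rng = self._rng
        bw = max((hi - lo) / max(len(obs), 1) ** 0.5, (hi - lo) / 25.0)
        center = obs[rng.integers(len(obs))]
        return float(np.clip(rng.normal(center, bw), lo, hi))

    @staticmethod
    def _kde_logpdf(x: float, obs: np.ndarray, lo: float, hi: float) -> float:
        if len(obs) == 0:
            return -np.log(hi - lo) if hi > lo else 0.0
        bw = max((hi - lo) / max(len(obs), 1) ** 0.5, (hi - lo) / 25.0)
        z = (x - obs) / bw
        dens = np.exp(-0.5 * z * z).sum() / (len(obs) * bw * np.sqrt(2 * np.pi))
        return float(np.log(dens + 1e-300))

    # -- public loop -------------------------------------------------------

    def suggest(self) -> dict[str, Any]:
        if len(self._values) < self.n_startup:
            return {k: self._sample_prior(spec) for k, spec in self.space.items()}
        order = np.argsort(self._values)
        if self.maximize:
            order = order[::-1]
        n_good = max(1, int(np.ceil(self.gamma * len(order))))
        good_idx, bad_idx = order[:n_good], order[n_good:]

        good = {
            k: np.array([_to_internal(s, self._params[i][k]) for i in good_idx])
            for k, s in self.space.items()
        }
        bad = {
            k: np.array([_to_internal(s, self._params[i][k]) for i in bad_idx])
            for k, s in self.space.items()
        }

        best_score, best_params = -np.inf, None
        for _ in range(self.n_candidates):
            cand, score = {}, 0.0
            for k, spec in self.space.items():
                if isinstance(spec, Categorical):
                    n_c = len(spec.choices)
                    cg = np.bincount(good[k].astype(int), minlength=n_c) + 1.0
                    cb = np.bincount(bad[k].astype(int), minlength=n_c) + 1.0
                    pg, pb = cg / cg.sum(), cb / cb.sum()
                    idx = self._rng.choice(n_c, p=pg)
                    cand[k] = spec.choices[idx]
                    score += np.log(pg[idx]) - np.log(pb[idx])
                else:
                    lo, hi = _bounds(spec)
                    x = self._kde_sample(good[k], lo, hi)
                    cand[k] = _from_internal(spec, x)
                    score += self._kde_logpdf(x, good[k], lo, hi)
                    score -= self._kde_logpdf(x, bad[k], lo, hi)
            if score > best_score:
                best_score, best_params = score, cand
        return best_params

    def observe(self, params: dict[str, Any], value: float) -> None:
        self._params.append(dict(params))
        self._values.append(float(value))

    @property
    def n_trials(self) -> int:
        return len(self._values)

    @property
    def best(self) -> tuple[dict[str, Any], float]:
        if not self._values:
            raise ValueError("no trials observed yet")
        i = int(np.argmax(self._values) if self.maximize else np.argmin(self._values))
        return dict(self._params[i]), self._values[i]
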