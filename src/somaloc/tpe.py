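"""A small tree-structured Parzen estimator (TPE) for box-bounded search.

Sequential model-based optimisation: after a uniform startup phase, the
observed trials are split at the gamma-quantile of the objective into a
"good" and a "rest" set; each set gets a per-dimension Parzen mixture
(Gaussian kernels at the observed values, bandwidth from neighbour
spacing, truncated to the search bounds).  Candidates are drawn from the
good-set mixture and the one maximising the density ratio l(x)/g(x) is
evaluated next.  Log-scaled dimensions are handled by optimising in log
space.  Fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SearchDim:
    name: str
    low: float
    high: float
    log: bool = False

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")
        if self.log and self.low <= 0:
            raise ValueError(f"{self.name}: log scale requires positive bounds")

    def to_internal(self, x):
        return np.log(x) if self.log else x

    def from_internal(self, u):
        return float(np.exp(u)) if self.log else float(u)

    @property
    def bounds_internal(self):
        return (self.to_internal(self.low), self.to_internal(self.high))


@dataclass
class Trial:
    number: int
    params: dict
    value: float


class TPEOptimizer:
    """Maximise a black-box objective over a box with TPE sampling."""

    def __init__(
        self,
        space: list[SearchDim],
        seed: int = 0,
        n_startup: int = 10,
        gamma: float = 0.25,
        n_candidates: int = 24,
    ):
        if not space:
            raise ValueError("empty search space")
        self.space = space
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self.trials: list[Trial] = []

    # -- sampling -------------------------------------------------------

    def _uniform(self) -> np.ndarray:
        return np.array([
            self.rng.uniform(*d.bounds_internal) for d in self.space
        ])

    @staticmethod
    def _bandwidths(points: np.ndarray, lo: float, hi: float) -> np.ndarray:
        """Per-kernel bandwidths: max gap to the nearest neighbour, floored."""
        if len(points) == 1:
            return np.array([(hi - lo) / 2.0])
        order = np.argsort(points)
        sorted_pts = points[order]
        gaps = np.diff(sorted_pts)
        bw_sorted = np.empty_like(sorted_pts)
        bw_sorted[0] = gaps[0]
        bw_sorted[-1] = gaps[-1]
        if len(points) > 2:
            bw_sorted[1:-1] = np.maximum(gaps[:-1], gaps[1:])
        bw = np.empty_like(bw_sorted)
        bw[order] = bw_sorted
        floor = (hi - lo) / max(len(points), 2) / 10.0
        return np.clip(bw, max(floor, 1e-12), hi - lo)

    def _parzen_logpdf(self, x: float, points: np.ndarray, bw: np.ndarray) -> float:
        z = (x - points) / bw
        comp = -0.5 * z**2 - np.log(bw) - 0.5 * np.log(2 * np.pi)
        return float(np.logaddexp.reduce(comp) - np.log(len(points)))

    def ask(self) -> dict:
        if len(self.trials) < self.n_startup:
            u = self._uniform()
            return {d.name: d.from_internal(u[k]) for k, d in enumerate(self.space)}

        values = np.array([t.value for t in self.trials])
        n_good = max(1, int(np.ceil(self.gamma * len(values))))
        order = np.argsort(-values, kind="stable")  # maximise
        good_idx, rest_idx = order[:n_good], order[n_good:]
        if len(rest_idx) == 0:
            rest_idx = order

        X = np.array([
            [d.to_internal(t.params[d.name]) for d in self.space] for t in self.trials
        ])
        best_u, best_score = None, -np.inf
        for _ in range(self.n_candidates):
            u = np.empty(len(self.space))
            score = 0.0
            for k, d in enumerate(self.space):
                lo, hi = d.bounds_internal
                gpts = X[good_idx, k]
                rpts = X[rest_idx, k]
                gbw = self._bandwidths(gpts, lo, hi)
                rbw = self._bandwidths(rpts, lo, hi)
                # draw from the good-set mixture, truncated to bounds
                for _try in range(100):
                    j = self.rng.integers(len(gpts))
                    cand = self.rng.normal(gpts[j], gbw[j])
                    if lo <= cand <= hi:
                        break
                else:
                    cand = self.rng.uniform(lo, hi)
                u[k] = cand
                score += self._parzen_logpdf(cand, gpts, gbw)
                score -= self._parzen_logpdf(cand, rpts, rbw)
            if score > best_score:
                best_u, best_score = u, score
        return {d.name: d.from_internal(best_u[k]) for k, d in enumerate(self.space)}

    def tell(self, params: dict, value: float) -> None:
        self.trials.append(Trial(len(self.trials), dict(params), float(value)))

    # -- driver ---------------------------------------------------------

    def optimize(self, objective, n_trials: int) -> Trial:
        """Run ``n_trials`` ask/tell rounds; return the best trial."""
        if n_trials < 1:
            raise ValueError("budget must be >= 1")
        for _ in range(n_trials):
            params = self.ask()
            self.tell(params, objective(params))
        return self.best_trial

    @property
    def best_trial(self) -> Trial:
        return max(self.trials, key=lambda t: (t.value, -t.number))
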