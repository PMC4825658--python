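"""Summaries of per-cell fluorescence samples.

Two operations mirror how flow-cytometry readouts are interpreted in a
reporter screen: median fold change between a sample and a reference
strain/condition (locations compared on the log10 axis, reported linear),
and detection of bimodal subpopulations (epigenetically switching mutants)
via a 1- vs 2-component Gaussian mixture fit on the log10 axis with
penalized-likelihood model selection.

EM is deliberately hand-rolled: the per-iteration log-likelihood monotonicity
is an asserted invariant, and initialization (quantile split plus fixed-seed
random restarts) is part of the contract for deterministic output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_LOG_2PI = math.log(2.0 * math.pi)


class FitError(RuntimeError):
    """EM failed to converge across all restarts."""


@dataclass(frozen=True)
class FluorSample:
    """Per-cell log10-fluorescence values for one strain under one condition."""

    strain: str
    condition: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MixtureFit:
    """A k in {1,2} Gaussian mixture on the log10 axis.

    Components are ordered by increasing location.  ``score_diff`` is the
    model-selection score of this fit minus the 1-component fit
    (BIC_1 - BIC_k; positive favors this model).  For k=1 it is 0.
    """

    k: int
    weights: tuple[float, ...]
    locations: tuple[float, ...]
    scales: tuple[float, ...]
    loglik: float
    score_diff: float
    n_iter: int

    def __post_init__(self) -> None:
        if self.k not in (1, 2):
            raise ValueError("k must be 1 or 2")
        if not math.isclose(sum(self.weights), 1.0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be > 0")

    @property
    def minor_weight(self) -> float:
        return min(self.weights)

    @property
    def separation(self) -> float:
        return max(self.locations) - min(self.locations)

    def bic(self, n: int) -> float:
        n_params = 3 * self.k - 1
        return n_params * math.log(n) - 2.0 * self.loglik


def median_fold_change(sample: FluorSample, reference: FluorSample) -> float:
    """Linear-scale fold change of medians: 10^(median(sample)-median(ref)).

    Medians (not means) on the log axis — robust to the heavy tails of
    cytometry distributions and exactly 1.0 for identical samples.
    """
    if len(sample) == 0 or len(reference) == 0:
        raise ValueError("samples must be non-empty")
    return float(10.0 ** (np.median(sample.values) - np.median(reference.values)))


# ---------------------------------------------------------------------------
# EM


def _loglik(x: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> float:
    comp = (
        np.log(w)
        - np.log(sd)
        - 0.5 * _LOG_2PI
        - 0.5 * ((x[:, None] - mu) / sd) ** 2
    )
    m = comp.max(axis=1)
    return float((m + np.log(np.exp(comp - m[:, None]).sum(axis=1))).sum())


def _em_once(
    x: np.ndarray,
    w: np.ndarray,
    mu: np.ndarray,
    sd: np.ndarray,
    tol: float,
    max_iter: int,
    min_scale: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, list[float]]:
    """Run EM from one start; returns params, loglik, iterations, trace."""
    n = len(x)
    prev = -np.inf
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        # E step (log domain for stability)
        logr = (
            np.log(w)
            - np.log(sd)
            - 0.5 * _LOG_2PI
            - 0.5 * ((x[:, None] - mu) / sd) ** 2
        )
        m = logr.max(axis=1)
        ll = float((m + np.log(np.exp(logr - m[:, None]).sum(axis=1))).sum())
        trace.append(ll)
        r = np.exp(logr - m[:, None])
        r /= r.sum(axis=1, keepdims=True)
        # M step
        nk = r.sum(axis=0)
        nk = np.clip(nk, 1e-12, None)
        w = nk / n
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.clip(var, min_scale**2, None))
        if (ll - prev) / n < tol and it > 1:  # mean per-cell improvement
            return w, mu, sd, ll, it, trace
        prev = ll
    return w, mu, sd, trace[-1], max_iter, trace


def fit_mixture(
    sample: FluorSample,
    k: int,
    seed: int = 0,
    *,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_random_starts: int = 4,
    min_scale: float = 1e-3,
) -> MixtureFit:
    """Fit a k-component (k=1 or 2) Gaussian mixture on the log10 axis.

    k=2 requires n >= 50 cells.  Starts: a deterministic quantile split
    (below/above the sample median) plus ``n_random_starts`` seeded random
    responsibility splits; the best final log-likelihood wins.  The
    log-likelihood trace of every run is checked to be non-decreasing.
    """
    x = sample.values
    n = len(x)
    if k == 1:
        mu = float(np.mean(x))
        sd = float(max(np.std(x), min_scale))
        ll = _loglik(x, np.array([1.0]), np.array([mu]), np.array([sd]))
        return MixtureFit(
            k=1, weights=(1.0,), locations=(mu,), scales=(sd,),
            loglik=ll, score_diff=0.0, n_iter=0,
        )
    if k != 2:
        raise ValueError("k must be 1 or 2")
    if n < 50:
        raise ValueError(f"k=2 requires n >= 50 cells (got {n})")

    rng = np.random.default_rng(seed)
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    starts: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = [(
        np.array([len(lo) / n, len(hi) / n]),
        np.array([np.mean(lo), np.mean(hi) if len(hi) else np.mean(lo) + 1.0]),
        np.array([max(np.std(lo), min_scale),
                  max(np.std(hi) if len(hi) else np.std(lo), min_scale)]),
    )]
    for _ in range(n_random_starts):
        pick = rng.choice(n, size=2, replace=False)
        mu0 = np.sort(x[pick])
        s0 = max(np.std(x) / 2, min_scale)
        starts.append((np.array([0.5, 0.5]), mu0.astype(float),
                       np.array([s0, s0])))

    best: tuple[float, np.ndarray, np.ndarray, np.ndarray, int] | None = None
    converged = False
    for w0, mu0, sd0 in starts:
        w, mu, sd, ll, it, trace = _em_once(x, w0.copy(), mu0.copy(), sd0.copy(),
                                            tol, max_iter, min_scale)
        diffs = np.diff(trace)
        if diffs.size and diffs.min() < -1e-6:
            raise AssertionError("EM log-likelihood decreased")
        if it < max_iter:
            converged = True
        if best is None or ll > best[0]:
            best = (ll, w, mu, sd, it)
    if not converged:
        assert best is not None
        raise FitError(
            f"EM did not converge within {max_iter} iterations in any of "
            f"{len(starts)} starts (best loglik {best[0]:.4f})"
        )
    ll, w, mu, sd, it = best
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    fit1 = fit_mixture(sample, 1, seed)
    fit2 = MixtureFit(
        k=2, weights=tuple(float(v) for v in w),
        locations=tuple(float(v) for v in mu),
        scales=tuple(float(v) for v in sd),
        loglik=ll, score_diff=0.0, n_iter=it,
    )
    score = fit1.bic(n) - fit2.bic(n)
    return MixtureFit(
        k=2, weights=fit2.weights, locations=fit2.locations, scales=fit2.scales,
        loglik=ll, score_diff=float(score), n_iter=it,
    )


@dataclass(frozen=True)
class BimodalityCriteria:
    """Thresholds for calling a two-subpopulation sample.

    ``min_score_diff`` is on the BIC scale (BIC_1 - BIC_2 must exceed it);
    ``min_weight`` bounds the minor component; ``min_separation`` is in
    log10 units.
    """

    min_score_diff: float = 10.0
    min_weight: float = 0.05
    min_separation: float = 0.5


def detect_bimodality(
    sample: FluorSample,
    criteria: BimodalityCriteria = BimodalityCriteria(),
    seed: int = 0,
) -> tuple[bool, MixtureFit]:
    """Call a sample bimodal iff the 2-component model wins decisively.

    All three criteria must hold: model-selection score difference above
    threshold, minor-component weight at least ``min_weight``, and location
    separation at least ``min_separation``.  Returns the 2-component fit
    either way.
    """
    fit2 = fit_mixture(sample, 2, seed)
    bimodal = (
        fit2.score_diff > criteria.min_score_diff
        and fit2.minor_weight >= criteria.min_weight
        and fit2.separation >= criteria.min_separation
    )
    return bimodal, fit2
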