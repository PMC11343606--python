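"""One-step adaptive regression on expression values.

Fits a single step function to the ascending-sorted values of a gene by
exhaustively evaluating every step position and keeping the one that
minimizes the sum of squared errors. The midpoint of the two fitted
segment means is the per-gene expression threshold used by downstream
normalization; values can then be labeled high/low around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateFitError, InputError

__all__ = [
    "StepFit",
    "fit_step",
    "step_statistic",
    "threshold",
    "binarize",
    "fit_matrix",
]

#: Default model degrees of freedom: low mean, high mean, step position.
DEFAULT_DOF = 3

# Relative slack used only to shortlist near-optimal step positions from the
# fast algebraic screen before they are re-scored exactly.
_SCREEN_RTOL = 1e-9


@dataclass(frozen=True)
class StepFit:
    """Result of fitting one step to one gene's values.

    All quantities refer to the ascending-sorted copy of the input.
    """

    k: int
    mu_low: float
    mu_high: float
    fitted: np.ndarray = field(repr=False)
    sse_step: float
    sse_null: float
    dof: int
    sorted_values: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.sorted_values.size

    @property
    def threshold(self) -> float:
        return threshold(self)

    @property
    def statistic(self) -> float:
        return step_statistic(self)


def _seq_sum(a: np.ndarray) -> float:
    # Strict left-to-right accumulation so the reported quantities are
    # bitwise-reproducible against a plain sequential loop. (numpy's own
    # reductions use blocked/pairwise summation and can differ by an ulp.)
    total = 0.0
    for v in a.tolist():
        total += v
    return total


def _exact_sse(x: np.ndarray, k: int) -> tuple[float, float, float]:
    """Segment means and step SSE at position ``k``, sequential arithmetic."""
    n = x.size
    mu_low = _seq_sum(x[:k]) / k
    mu_high = _seq_sum(x[k:]) / (n - k)
    # squared deviations via multiplication, not **: pow() can be off by
    # an ulp from x*x and would break bit-reproducibility
    d_low = x[:k] - mu_low
    d_high = x[k:] - mu_high
    devs = np.concatenate([d_low * d_low, d_high * d_high])
    return mu_low, mu_high, _seq_sum(devs)


def _as_clean_vector(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InputError(f"expected a 1-D vector, got shape {x.shape}")
    if x.size < 2:
        raise InputError(f"need at least 2 values to fit a step, got {x.size}")
    if not np.all(np.isfinite(x)):
        bad = np.flatnonzero(~np.isfinite(x))
        raise InputError(f"non-finite values at positions {bad.tolist()}")
    return x


def fit_step(values, dof: int = DEFAULT_DOF) -> StepFit:
    """Fit the SSE-minimizing single step to ``values``.

    Values are sorted ascending first; every step position ``k`` in
    ``1..n-1`` (at least one point on each side) is evaluated and the
    smallest ``k`` among SSE-minimizing positions is returned.
    """
    x = np.sort(_as_clean_vector(values))
    n = x.size

    # Algebraic screen over all positions: SSE(k) decomposes into the total
    # sum of squares minus the segment-mean terms.
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    ks = np.arange(1, n)
    left = cs2[ks - 1] - cs[ks - 1] ** 2 / ks
    right = (cs2[-1] - cs2[ks - 1]) - (cs[-1] - cs[ks - 1]) ** 2 / (n - ks)
    sse = left + right

    # Re-score near-optimal candidates exactly; smallest k wins ties.
    scale = max(float(cs2[-1]), 1.0)
    cutoff = sse.min() + _SCREEN_RTOL * scale
    best_k, best = 0, np.inf
    for k in (ks[sse <= cutoff]).tolist():
        exact = _exact_sse(x, k)[2]
        if exact < best:
            best_k, best = k, exact

    mu_low, mu_high, sse_step = _exact_sse(x, best_k)
    grand = _seq_sum(x) / n
    dev = x - grand
    sse_null = _seq_sum(dev * dev)
    fitted = np.concatenate(
        [np.full(best_k, mu_low), np.full(n - best_k, mu_high)]
    )
    return StepFit(
        k=best_k,
        mu_low=mu_low,
        mu_high=mu_high,
        fitted=fitted,
        sse_step=sse_step,
        sse_null=sse_null,
        dof=dof,
        sorted_values=x,
    )


def step_statistic(fit: StepFit) -> float:
    """F-like ratio of explained to residual error for a fitted step.

    ``((sse_null - sse_step)/(dof - 1)) / (sse_step/(n - dof))``. A fit
    explaining nothing returns 0; a zero-residual fit returns ``inf`` so
    downstream comparisons stay exact.
    """
    n, m = fit.n, fit.dof
    if n <= m:
        raise DegenerateFitError(
            f"n={n} must exceed model degrees of freedom m={m}"
        )
    if fit.sse_null == fit.sse_step:
        return 0.0
    if fit.sse_step == 0.0:
        return float("inf")
    return ((fit.sse_null - fit.sse_step) / (m - 1)) / (fit.sse_step / (n - m))


def threshold(fit: StepFit) -> float:
    """Expression threshold: midpoint of the two fitted segment means."""
    return (fit.mu_low + fit.mu_high) / 2.0


def binarize(values, thr: float, gap: float = 0.0) -> np.ndarray:
    """Label each value ``high``/``low``/``intermediate`` around ``thr``.

    A value above ``thr + gap`` is high, at or below ``thr - gap`` is low,
    anything between is intermediate. With the default ``gap = 0`` a value
    exactly at the threshold labels low and no value is intermediate.
    """
    if gap < 0:
        raise ConfigurationError(f"gap must be non-negative, got {gap}")
    if not np.isfinite(thr):
        raise InputError(f"threshold must be finite, got {thr}")
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, "intermediate", dtype=object)
    out[x > thr + gap] = "high"
    out[x <= thr - gap] = "low"
    return out


def fit_matrix(matrix: pd.DataFrame, dof: int = DEFAULT_DOF) -> pd.DataFrame:
    """Fit one step per gene row of an expression matrix.

    Returns a frame indexed by gene id with columns
    ``k, mu_low, mu_high, sthr, statistic, sse_step, sse_null``.
    """
    rows = []
    for gene, row in matrix.iterrows():
        fit = fit_step(row.to_numpy(), dof=dof)
        try:
            statistic = fit.statistic
        except DegenerateFitError:
            statistic = float("nan")  # too few samples for the F-like ratio
        rows.append(
            {
                "gene_id": gene,
                "k": fit.k,
                "mu_low": fit.mu_low,
                "mu_high": fit.mu_high,
                "sthr": fit.threshold,
                "statistic": statistic,
                "sse_step": fit.sse_step,
                "sse_null": fit.sse_null,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
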