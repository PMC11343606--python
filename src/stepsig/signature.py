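"""Threshold-centered normalization, composite scoring, and classification.

Expression is recentred on each gene's step threshold and scaled by three
per-gene standard deviations; the composite signature score of a sample is
the sum of these normalized values over the signature genes. Scores order
samples, classify cohorts via ROC AUC, and feed Welch group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "NormalizedMatrix",
    "SignatureScoreTable",
    "normalize_expression",
    "composite_score",
    "roc_auc",
    "group_compare",
]


@dataclass(frozen=True)
class NormalizedMatrix:
    """Genes x samples matrix in units of 3 standard deviations above SThr."""

    entries: pd.DataFrame
    sthr: pd.Series
    stddev: pd.Series
    degenerate_genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class SignatureScoreTable:
    """Per-sample composite score with the ascending ordering it induces."""

    table: pd.DataFrame  # columns: score, rank
    signature: tuple[str, ...]
    missing_genes: tuple[str, ...] = ()

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    def ordered_samples(self) -> list:
        return self.table.sort_values("rank").index.tolist()


def normalize_expression(matrix: pd.DataFrame, fits: pd.DataFrame) -> NormalizedMatrix:
    """Map expression to ``(expr - SThr) / (3 * stddev)`` per gene.

    ``fits`` is the per-gene table from :func:`stepsig.stepminer.fit_matrix`
    (only its ``sthr`` column is used). The standard deviation is the
    sample standard deviation (n-1 denominator) across all samples of this
    matrix. Genes with zero spread are flagged degenerate and set to 0
    rather than dropped, so signatures stay comparable across datasets.
    """
    missing = matrix.index.difference(fits.index)
    if len(missing):
        raise InputError(
            f"no step fit for gene(s): {', '.join(map(str, missing[:10]))}"
        )
    sthr = fits.loc[matrix.index, "sthr"]
    sd = matrix.std(axis=1, ddof=1)
    degenerate = tuple(sd.index[(sd == 0) | sd.isna()])
    safe_sd = sd.replace(0, np.nan)
    entries = matrix.sub(sthr, axis=0).div(3.0 * safe_sd, axis=0)
    if degenerate:
        entries.loc[list(degenerate)] = 0.0
    return NormalizedMatrix(
        entries=entries, sthr=sthr, stddev=sd, degenerate_genes=degenerate
    )


def composite_score(normalized: NormalizedMatrix, signature) -> SignatureScoreTable:
    """Sum normalized entries over the signature genes, per sample.

    Signature genes absent from the matrix are reported on the result and
    excluded; an empty effective signature is an error. The induced
    ordering is ascending score with ties broken by sample id.
    """
    signature = list(dict.fromkeys(signature))  # dedupe, keep order
    present = [g for g in signature if g in normalized.entries.index]
    missing = tuple(g for g in signature if g not in normalized.entries.index)
    if not present:
        raise InputError("no signature gene is present in the matrix")
    scores = normalized.entries.loc[present].sum(axis=0)
    if not np.all(np.isfinite(scores)):
        raise InputError("non-finite composite score encountered")
    order = scores.to_frame("score")
    order["_sid"] = order.index.astype(str)
    order = order.sort_values(["score", "_sid"], kind="stable")
    order["rank"] = np.arange(1, len(order) + 1)
    table = order.drop(columns="_sid").loc[scores.index]
    return SignatureScoreTable(
        table=table, signature=tuple(present), missing_genes=missing
    )


def roc_auc(scores, labels, positive) -> float:
    """AUC as P(random positive outscores random negative), ties at 0.5.

    ``positive`` declares which label is the positive class; there is no
    automatic orientation.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise InputError("scores and labels differ in length")
    pos = y == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("both classes must be present to compute AUC")
    ranks = stats.rankdata(s)  # midranks give the ties-at-0.5 convention
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def group_compare(scores, groups, pairs=None) -> pd.DataFrame:
    """Welch two-sided t-test on scores between comparator groups.

    ``pairs`` defaults to all unordered pairs of group labels (sorted).
    Returns one row per pair with the test plus violin-ready summaries
    (n, mean, sd per side).
    """
    s = pd.Series(np.asarray(scores, dtype=float))
    g = pd.Series(np.asarray(groups)).astype(str)
    if len(s) != len(g):
        raise InputError("scores and groups differ in length")
    levels = sorted(g.unique())
    counts = g.value_counts()
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    rows = []
    for a, b in pairs:
        for lab in (a, b):
            if lab not in counts.index:
                raise InputError(f"unknown group label '{lab}'")
            if counts[lab] < 2:
                raise InputError(f"group '{lab}' has fewer than 2 samples")
        xa, xb = s[g == a].to_numpy(), s[g == b].to_numpy()
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t),
                "p": float(p),
                "n_a": xa.size,
                "n_b": xb.size,
                "mean_a": float(xa.mean()),
                "mean_b": float(xb.mean()),
                "sd_a": float(xa.std(ddof=1)),
                "sd_b": float(xb.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)
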