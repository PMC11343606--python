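"""Two-arm differential expression with a fixed p/fold-change filter contract.

Counts are summarized to TPM and log2(TPM+1); genes are then tested with a
Welch t on log expression and filtered at raw P <= 0.05 and linear
fold-change >= 2. This is deliberately a light-weight stand-in for a
negative-binomial GLM engine: the downstream contract (which genes pass)
is what matters here, and the approximation is documented. BH-adjusted
p-values are always reported and can optionally drive selection.

Also provides BH adjustment and hypergeometric gene-set enrichment
against a user-supplied GMT collection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = [
    "tpm",
    "log_transform",
    "differential_expression",
    "bh_adjust",
    "gene_set_enrichment",
]

#: Pseudocount added to linear arm means so all-zero genes have a defined ratio.
FOLD_CHANGE_PSEUDOCOUNT = 1.0


def tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and gene lengths (bp).

    Per sample: length-normalized rates rescaled to sum to 1e6.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:10]
        raise InputError(f"no length for gene(s): {', '.join(map(str, missing))}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][:10]
        raise InputError(f"non-positive length for gene(s): {', '.join(map(str, bad))}")
    if (counts.to_numpy() < 0).any():
        raise InputError("counts must be non-negative")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise InputError(f"all-zero sample column(s): {', '.join(map(str, zero))}")
    return rates.div(totals, axis=1) * 1e6


def log_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """Entrywise log2(x + 1)."""
    arr = np.asarray(expr, dtype=float)
    if (arr < 0).any():
        raise InputError("expression values must be non-negative for log2(x+1)")
    if isinstance(expr, pd.DataFrame):
        return pd.DataFrame(np.log2(arr + 1.0), index=expr.index, columns=expr.columns)
    return np.log2(arr + 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise InputError("p-values must be a 1-D sequence")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix: pd.DataFrame,
    arm_labels,
    test_arm,
    p_cut: float = 0.05,
    fc_cut: float = 2.0,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Per-gene Welch t on log expression plus linear fold-change filter.

    Parameters
    ----------
    matrix
        Genes x samples log2(TPM+1) expression.
    arm_labels
        Per-sample arm label (two arms).
    test_arm
        The label whose direction defines "up".
    p_cut, fc_cut
        Selection thresholds: raw P <= p_cut and fold-change >= fc_cut
        (in either direction); the recorded direction says which.
    use_adjusted
        Select on BH-adjusted instead of raw p.

    Returns a frame indexed by gene id with columns
    ``fold_change, log2_fc, t, p, p_adj, direction, passes``.
    ``fold_change`` is the ratio of linear-scale arm means with a
    pseudocount of 1 on each mean.
    """
    labels = pd.Series(np.asarray(arm_labels), index=matrix.columns)
    arms = labels.unique()
    if len(arms) != 2:
        raise InputError(f"expected exactly 2 arms, got {list(arms)}")
    if test_arm not in arms:
        raise InputError(f"test arm '{test_arm}' not among labels {list(arms)}")
    control_arm = [a for a in arms if a != test_arm][0]
    test_cols = labels.index[labels == test_arm]
    ctrl_cols = labels.index[labels == control_arm]
    if len(test_cols) < 2 or len(ctrl_cols) < 2:
        raise InputError("each arm needs at least 2 samples")

    xt = matrix[test_cols].to_numpy(dtype=float)
    xc = matrix[ctrl_cols].to_numpy(dtype=float)

    t, p = stats.ttest_ind(xt, xc, axis=1, equal_var=False)
    # zero variance in both arms -> undefined t; no evidence of change
    flat = ~np.isfinite(t)
    t = np.where(flat, 0.0, t)
    p = np.where(flat, 1.0, p)

    c = FOLD_CHANGE_PSEUDOCOUNT
    lin_t = (2.0 ** xt - 1.0).mean(axis=1)
    lin_c = (2.0 ** xc - 1.0).mean(axis=1)
    fc = (lin_t + c) / (lin_c + c)

    p_adj = bh_adjust(p)
    p_sel = p_adj if use_adjusted else p
    direction = np.where(fc >= 1.0, "up", "down")
    fc_extreme = np.maximum(fc, 1.0 / fc)
    passes = (p_sel <= p_cut) & (fc_extreme >= fc_cut)

    return pd.DataFrame(
        {
            "fold_change": fc,
            "log2_fc": np.log2(fc),
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "direction": direction,
            "passes": passes,
        },
        index=matrix.index,
    )


def up_signature(deg: pd.DataFrame) -> list:
    """Gene ids passing the filters in the up direction, by ascending p."""
    hits = deg[deg["passes"] & (deg["direction"] == "up")]
    return hits.sort_values("p").index.tolist()


def gene_set_enrichment(hits, universe, sets: dict) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each gene set.

    ``sets`` maps set name -> iterable of member gene ids (GMT-style).
    Fold enrichment is the hit fraction inside the set relative to the
    set's share of the universe; p is the upper hypergeometric tail,
    BH-adjusted across sets.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    hits = list(dict.fromkeys(hits))
    outside = [h for h in hits if h not in uni]
    if outside:
        raise InputError(
            f"hit gene(s) absent from universe: {', '.join(map(str, outside[:10]))}"
        )
    if not sets:
        raise InputError("empty gene-set collection")
    n_uni, n_hits = len(uni), len(hits)
    hit_set = set(hits)
    rows = []
    for name, members in sets.items():
        members_in_uni = uni.intersection(members)
        k_set = len(members_in_uni)
        overlap = len(hit_set & members_in_uni)
        if k_set == 0 or n_hits == 0:
            fe, p = 0.0, 1.0
        else:
            fe = (overlap / n_hits) / (k_set / n_uni)
            p = float(stats.hypergeom.sf(overlap - 1, n_uni, k_set, n_hits))
        rows.append(
            {
                "set": name,
                "set_size": k_set,
                "overlap": overlap,
                "fold_enrichment": fe,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
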