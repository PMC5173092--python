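"""Expression preprocessing and Pearson co-expression filtering.

Candidate ceRNA pairs that share significantly many miRNAs are kept as
network edges only if the two transcripts are positively co-expressed:
Pearson r with an exact t-reference two-sided p-value, BH-adjusted over the
candidate family, FDR < 0.01 for the full network and additionally r > 0.5
for the high-competition sub-network.

Expression matrices are genes x samples on a log2 scale; quantile
normalization and log2 transform helpers match the standard array
preprocessing such matrices come from.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_FDR_THRESHOLD = 0.01
#: Pearson threshold (strict >) defining the high-competition sub-network.
SUB_NETWORK_R_MIN = 0.5
#: Minimum pairwise-complete samples for a correlation to be defined.
MIN_COMPLETE_SAMPLES = 10


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate sample ids in expression matrix")


def load_expression(path) -> pd.DataFrame:
    """Read a genes-x-samples TSV whose first column is the gene id."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    _check_matrix(matrix)
    return matrix


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the mean order-statistic distribution.

    After normalization the sorted values of all columns are identical (the
    across-sample mean of order statistics); ties within a column receive the
    average of the values their ranks span.
    """
    _check_matrix(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    order = np.sort(values, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, len(reference) + 1), reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """Elementwise log2(value + offset); every shifted value must be positive."""
    if offset < 0:
        raise ValueError("offset must be non-negative")
    shifted = matrix.to_numpy(dtype=float) + offset
    if (shifted <= 0).any():
        i, j = np.argwhere(shifted <= 0)[0]
        raise ValueError(
            f"non-positive value at gene {matrix.index[i]!r}, "
            f"sample {matrix.columns[j]!r} with offset {offset}"
        )
    return pd.DataFrame(np.log2(shifted), index=matrix.index, columns=matrix.columns)


def pearson_with_pvalue(x, y) -> tuple[float, float]:
    """Pearson r = cov(X,Y)/(sd_X sd_Y) with an exact two-sided t p-value.

    The p-value refers t = r*sqrt((n-2)/(1-r^2)) to a t distribution with
    n-2 degrees of freedom.  Zero-variance input yields (nan, nan): the pair
    is undefined and excluded downstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson_permutation_pvalue(x, y, n_permutations: int = 10000, seed: int = 0) -> tuple[float, float]:
    """Seeded permutation alternative to the t reference, for small n.

    Two-sided: fraction of label permutations with |r| at least as large as
    observed, with the +1 continuity correction so p is never 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs, _ = pearson_with_pvalue(x, y)
    if np.isnan(r_obs):
        return float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        r_perm = np.corrcoef(x, rng.permutation(y))[0, 1]
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    return r_obs, (hits + 1) / (n_permutations + 1)


def _pair_correlations(
    candidates: pd.DataFrame, lnc_matrix: pd.DataFrame, mrna_matrix: pd.DataFrame
) -> pd.DataFrame:
    if list(lnc_matrix.columns) != list(mrna_matrix.columns):
        raise ValueError("lncRNA and mRNA matrices must share sample ids and order")
    missing_l = set(candidates["lncrna_id"]) - set(lnc_matrix.index)
    missing_m = set(candidates["mrna_id"]) - set(mrna_matrix.index)
    if missing_l or missing_m:
        raise ValueError(
            f"genes absent from expression matrices: {sorted(missing_l | missing_m)[:5]}"
        )
    rows = []
    for lnc, mr in candidates[["lncrna_id", "mrna_id"]].itertuples(index=False):
        x = lnc_matrix.loc[lnc].to_numpy(dtype=float)
        y = mrna_matrix.loc[mr].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < max(MIN_COMPLETE_SAMPLES, 3):
            r, p = float("nan"), float("nan")
        else:
            r, p = pearson_with_pvalue(x[ok], y[ok])
        rows.append((lnc, mr, r, p))
    return pd.DataFrame(rows, columns=["lncrna_id", "mrna_id", "r", "p_value"])


def filter_coexpressed(
    candidates: pd.DataFrame,
    lnc_matrix: pd.DataFrame,
    mrna_matrix: pd.DataFrame,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    r_min: float = 0.0,
    require_positive: bool = True,
) -> pd.DataFrame:
    """Correlate every candidate pair and flag the co-expression filters.

    Returns one row per candidate with columns
    ``lncrna_id, mrna_id, r, p_value, fdr, passed_lmcn, passed_sub``:
    ``passed_lmcn`` marks fdr < ``fdr_threshold`` (and r > ``r_min``, 0 by
    default so competition implies positive co-expression);
    ``passed_sub`` additionally requires r > the 0.5 sub-network cut.
    Undefined correlations (zero variance, too few complete samples) fail
    both filters.  FDR is adjusted over the candidate family only.
    """
    from .pairs import bh_fdr

    if len(candidates) == 0:
        raise ValueError("no candidate pairs to correlate")
    out = _pair_correlations(candidates, lnc_matrix, mrna_matrix)
    defined = out["p_value"].notna()
    fdr = np.full(len(out), np.nan)
    fdr[defined.to_numpy()] = bh_fdr(out.loc[defined, "p_value"].to_numpy())
    out["fdr"] = fdr
    floor = -np.inf if (not require_positive and r_min <= 0) else r_min
    passed = defined & (out["fdr"] < fdr_threshold) & (out["r"] > floor)
    out["passed_lmcn"] = passed.astype(int)
    out["passed_sub"] = (passed & (out["r"] > SUB_NETWORK_R_MIN)).astype(int)
    logger.info(
        "co-expression: %d candidates -> %d network edges, %d sub-network edges",
        len(out),
        int(out["passed_lmcn"].sum()),
        int(out["passed_sub"].sum()),
    )
    return out
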