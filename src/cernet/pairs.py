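"""Shared-miRNA significance testing for candidate ceRNA pairs.

For every lncRNA-mRNA pair the number x of shared miRNAs is referred to a
hypergeometric null: of N miRNAs in the universe, the lncRNA interacts with
K and the mRNA with M; under independence the overlap X follows
Hypergeom(N, K, M).  Two upper tails are offered:

``at_least``
    P(X >= x) — the conventional enrichment p-value (default).
``greater_than``
    P(X > x) = 1 - sum_{t<=x} P(X = t) — the literal complement-of-CDF
    form sometimes printed in the ceRNA literature; it excludes the
    observed overlap and returns 0 when x = min(K, M).

p-values are adjusted across the whole pair family with Benjamini-Hochberg
and candidates selected at FDR < 0.01 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .interactions import InteractionSet

logger = logging.getLogger(__name__)

#: Candidate selection threshold (strict: fdr < threshold).
DEFAULT_FDR_THRESHOLD = 0.01

TAILS = ("at_least", "greater_than")


@dataclass(frozen=True)
class CandidatePairResult:
    """Shared-miRNA test result for one lncRNA-mRNA pair."""

    lncrna_id: str
    mrna_id: str
    N: int
    K: int
    M: int
    x: int
    p_value: float
    fdr: float = float("nan")


def shared_mirna_pvalue(N: int, K: int, M: int, x: int, tail: str = "at_least") -> float:
    """Exact hypergeometric upper-tail probability of the shared-miRNA count.

    Computed in log space via the survival function of
    ``scipy.stats.hypergeom`` — no normal approximation.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}, got {tail!r}")
    if not (0 <= K <= N and 0 <= M <= N):
        raise ValueError(f"require K, M <= N; got N={N}, K={K}, M={M}")
    if not (0 <= x <= min(K, M)):
        raise ValueError(f"require 0 <= x <= min(K, M); got x={x}, K={K}, M={M}")
    if tail == "at_least":
        if x == 0:
            return 1.0
        return float(hypergeom.sf(x - 1, N, K, M))
    return float(hypergeom.sf(x, N, K, M))


def test_all_pairs(iset: InteractionSet, tail: str = "at_least", min_shared: int = 1) -> pd.DataFrame:
    """Hypergeometric test of every eligible lncRNA-mRNA pair.

    Pairs where either gene has an empty miRNA set are skipped (the test is
    degenerate at K=0 or M=0).  Pairs with fewer than ``min_shared`` common
    miRNAs are excluded before FDR adjustment; the default 1 drops x=0 pairs,
    which have p=1 and can never pass a small FDR cut.  Pass ``min_shared=0``
    to test them anyway.

    Returns a DataFrame with columns
    ``lncrna_id, mrna_id, N, K, M, x, p_value, fdr``.
    """
    lnc_sets = {g: s for g, s in iset.mirna_sets("lncRNA").items() if s}
    mrna_sets = {g: s for g, s in iset.mirna_sets("mRNA").items() if s}
    if not lnc_sets or not mrna_sets:
        raise ValueError("need at least one lncRNA and one mRNA with miRNA interactions")
    N = iset.n_mirnas
    rows = []
    for (lnc, ls), (mr, ms) in product(sorted(lnc_sets.items()), sorted(mrna_sets.items())):
        x = len(ls & ms)
        if x < min_shared:
            continue
        rows.append((lnc, mr, N, len(ls), len(ms), x))
    if not rows:
        raise ValueError("no eligible lncRNA-mRNA pairs to test")
    df = pd.DataFrame(rows, columns=["lncrna_id", "mrna_id", "N", "K", "M", "x"])
    # vectorized over the pair family; both tails are plain sf calls
    shift = 1 if tail == "at_least" else 0
    shared_mirna_pvalue(N, 1, 1, 0, tail)  # validates tail
    df["p_value"] = hypergeom.sf(df["x"] - shift, N, df["K"], df["M"])
    df.loc[df["x"] - shift < 0, "p_value"] = 1.0
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    logger.info("tested %d candidate pairs (N=%d, tail=%s)", len(df), N, tail)
    return df


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_candidate_pairs(
    results: pd.DataFrame, fdr_threshold: float = DEFAULT_FDR_THRESHOLD
) -> pd.DataFrame:
    """Retain pairs with fdr strictly below the threshold."""
    selected = results[results["fdr"] < fdr_threshold].reset_index(drop=True)
    logger.info(
        "selected %d / %d pairs at FDR < %g", len(selected), len(results), fdr_threshold
    )
    return selected
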