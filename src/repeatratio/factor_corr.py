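"""Chromatin-factor correlation and mutation association with R/G ratios.

Each factor's expression is correlated with per-sample R/G ratios by Pearson's
r (two-sided p from the t reference with n-2 df), BH-adjusted across the
panel.  Binary mutation status is compared against R/G ratios with the
two-sided Wilcoxon rank-sum test — exact enumeration when the smaller group
has at most 8 samples and there are no ties (the regime where the study's
significant associations live), otherwise the normal approximation with tie
and continuity corrections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

#: Largest min-group size at which the rank-sum p-value is enumerated exactly.
EXACT_RANKSUM_MAX_N = 8

#: Default chromatin enzyme/factor panel: regulators of repeat silencing and
#: activation commonly profiled in AML (transcription factors, histone
#: methyltransferases/demethylases, remodelers, heterochromatin and DNA
#: methylation machinery).  Any user-supplied list is accepted.
DEFAULT_CHROMATIN_FACTORS = (
    "POU5F2", "ASH1L", "BAZ2B", "ATRX",          # strong positive correlates
    "SUV39H1", "EHMT2", "TRIM28", "DAXX",        # intermediate correlates
    "SETDB1", "CBX5", "DNMT1", "CHAF1A",         # uncorrelated controls
)


@dataclass
class CorrelationResult:
    factor: str
    pcc: float
    p: float
    padj: float
    n: int


def pearson_corr(
    rg: Sequence[float], expr: Sequence[float], factor: str = ""
) -> tuple[float, float]:
    """Pearson correlation of factor expression with R/G ratios.

    Returns (r, two-sided p).  Requires n >= 3 and nonzero variance in both
    series; the error names the degenerate series.
    """
    rg = np.asarray(rg, float)
    expr = np.asarray(expr, float)
    if rg.shape != expr.shape:
        raise ValueError("series length mismatch")
    if rg.size < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if np.ptp(rg) == 0:
        raise ValueError("R/G ratio series has zero variance")
    if np.ptp(expr) == 0:
        raise ValueError(
            f"expression series {factor or '(unnamed)'} has zero variance"
        )
    r, p = stats.pearsonr(rg, expr)
    return float(r), float(p)


def correlate_panel(
    rg: Sequence[float],
    expr_matrix: pd.DataFrame,
    factors: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Correlate every panel factor with the R/G ratios; BH across the panel.

    ``expr_matrix`` is factors x samples, columns aligned with ``rg``.
    Factors absent from the matrix are skipped with a logged warning.
    Returns a DataFrame indexed by factor with columns pcc, p, padj, n.
    """
    if factors is None:
        factors = list(DEFAULT_CHROMATIN_FACTORS)
    rg = np.asarray(rg, float)
    if expr_matrix.shape[1] != rg.size:
        raise ValueError("expression matrix columns must match ratio count")
    rows = []
    for factor in factors:
        if factor not in expr_matrix.index:
            logger.warning("factor %s missing from expression matrix; skipped",
                           factor)
            continue
        r, p = pearson_corr(rg, expr_matrix.loc[factor].to_numpy(), factor)
        rows.append({"factor": factor, "pcc": r, "p": p, "n": rg.size})
    result = pd.DataFrame(rows, columns=["factor", "pcc", "p", "n"])
    if result.empty:
        result["padj"] = []
    else:
        result["padj"] = bh_adjust(result["p"].to_numpy())
    return result.set_index("factor")[["pcc", "p", "padj", "n"]]


def mutation_association(
    rg: Sequence[float], mutation: Sequence[int]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of R/G ratio vs a binary mutation flag.

    Returns (U statistic for the mutated group, p).  Exact enumeration when
    the smaller group has <= %d samples and values are untied; otherwise the
    tie-corrected normal approximation with continuity correction.
    """ % EXACT_RANKSUM_MAX_N
    rg = np.asarray(rg, float)
    flags = np.asarray(mutation, int)
    if rg.shape != flags.shape:
        raise ValueError("length mismatch between ratios and mutation flags")
    if not set(np.unique(flags)) <= {0, 1}:
        raise ValueError("mutation flags must be 0/1")
    mut, wt = rg[flags == 1], rg[flags == 0]
    if mut.size == 0 or wt.size == 0:
        raise ValueError("both mutation classes must be nonempty")
    no_ties = np.unique(rg).size == rg.size
    small = min(mut.size, wt.size) <= EXACT_RANKSUM_MAX_N
    method = "exact" if (no_ties and small) else "asymptotic"
    res = stats.mannwhitneyu(mut, wt, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def mutation_association_table(
    rg: Sequence[float], flags: pd.DataFrame
) -> pd.DataFrame:
    """Rank-sum association for every mutation flag column with >=1 carrier.

    Rows with a missing flag are excluded per mutation.  Returns a DataFrame
    indexed by mutation with columns statistic, p, n_mut, n_wt.
    """
    rg = np.asarray(rg, float)
    rows = []
    for col in flags.columns:
        values = flags[col]
        present = values.notna().to_numpy()
        f = values[present].astype(int).to_numpy()
        if f.sum() == 0 or f.sum() == f.size:
            logger.warning("mutation %s has a single class; skipped", col)
            continue
        stat, p = mutation_association(rg[present], f)
        rows.append(
            {"mutation": col, "statistic": stat, "p": p,
             "n_mut": int(f.sum()), "n_wt": int(f.size - f.sum())}
        )
    return pd.DataFrame(
        rows, columns=["mutation", "statistic", "p", "n_mut", "n_wt"]
    ).set_index("mutation")
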