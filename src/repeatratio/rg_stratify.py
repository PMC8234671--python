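"""The R/G ratio statistic and equal-interval cohort stratification.

A sample's R/G ratio is the median of its normalized log-scale expression over
all repeat features divided by the median over all gene features.  Cohorts are
stratified by z-scoring the per-sample ratios and splitting the z-score range
into three equal-width intervals (equal *range*, not equal count), labelled
``low`` / ``mid`` / ``high``.  Because equal-range binning is invariant to
affine transforms, the z-scoring step does not change the labels — it is kept
for interpretability of the reported scores.

Medians over an even number of values are the mean of the two central values,
everywhere in this package.  By default the medians include every annotated
feature of the relevant kind, zero-count rows included; ``nonzero_only``
restricts to features with nonzero total, and the choice is recorded in
run provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_tables import GENE, REPEAT, CountTable
from .normalize import NormalizedMatrix

STRATA = ("low", "mid", "high")


@dataclass
class RGProfile:
    """Per-sample R/G statistics; z-score and stratum filled by stratification."""

    sample: str
    median_repeat_expr: float
    median_gene_expr: float
    rg_ratio: float
    zscore: Optional[float] = None
    stratum: Optional[str] = None


@dataclass
class ClassFractionProfile:
    """Per-sample repeat read composition (fractions of raw reads)."""

    sample: str
    class_fractions: dict[str, float]  # sums to 1 over repeat classes
    repeat_fraction_of_all: float


def _median(values: np.ndarray) -> float:
    return float(np.median(values))


def rg_ratio(
    norm: NormalizedMatrix, sample: str, *, nonzero_only: bool = False
) -> RGProfile:
    """R/G ratio for one sample: median repeat / median gene log2 expression.

    ``nonzero_only`` drops features whose normalized expression is at the
    pseudocount floor in every sample (i.e. all-zero count rows).
    """
    try:
        j = norm.samples.index(sample)
    except ValueError:
        raise KeyError(f"unknown sample {sample!r}") from None
    kinds = norm.kinds
    is_repeat = kinds == REPEAT
    is_gene = kinds == GENE
    if not is_repeat.any() or not is_gene.any():
        raise ValueError("need at least one repeat and one gene feature")
    if nonzero_only:
        floor = np.log2(norm.pseudocount)
        detected = (norm.values > floor + 1e-12).any(axis=1)
        is_repeat = is_repeat & detected
        is_gene = is_gene & detected
        if not is_repeat.any() or not is_gene.any():
            raise ValueError("nonzero_only filter removed all features of a kind")
    med_r = _median(norm.values[is_repeat, j])
    med_g = _median(norm.values[is_gene, j])
    if med_g == 0:
        raise ValueError(
            f"sample {sample!r}: median gene expression is zero; "
            "R/G ratio undefined (degenerate normalization)"
        )
    return RGProfile(
        sample=sample,
        median_repeat_expr=med_r,
        median_gene_expr=med_g,
        rg_ratio=med_r / med_g,
    )


def rg_profiles(
    norm: NormalizedMatrix, *, nonzero_only: bool = False
) -> list[RGProfile]:
    """R/G profiles for every sample in the matrix."""
    return [rg_ratio(norm, s, nonzero_only=nonzero_only) for s in norm.samples]


def zscore(values: Sequence[float]) -> np.ndarray:
    """(x - mean) / sd with sample sd (divisor n-1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("z-score requires at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("z-score undefined: zero standard deviation")
    return (x - x.mean()) / sd


def cut_interval(values: Sequence[float], n: int = 3) -> list[str]:
    """Split the value *range* into ``n`` equal-width right-closed bins.

    Bin k covers ``(min+(k-1)w, min+k*w]`` with ``w=(max-min)/n``; the first
    bin additionally includes the minimum.  For n=3 the labels are
    ``low``/``mid``/``high``; otherwise ``bin_1``..``bin_n``.  A degenerate
    input (max == min) carries no range information and every value is
    assigned the middle bin.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cut_interval on empty input")
    if not np.isfinite(x).all():
        raise ValueError("cut_interval requires finite values")
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = list(STRATA) if n == 3 else [f"bin_{k}" for k in range(1, n + 1)]
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return [labels[(n - 1) // 2]] * x.size
    edges = np.linspace(lo, hi, n + 1)
    # right=True: value equal to an interior edge goes to the lower bin,
    # matching cut_interval's right-closed / include-lowest convention.
    idx = np.digitize(x, edges[1:-1], right=True)
    return [labels[i] for i in idx]


def stratify_cohort(profiles: Sequence[RGProfile], n: int = 3) -> list[RGProfile]:
    """Assign strata from equal-range binning of z-scored R/G ratios.

    Strata need not be equal-sized: an extreme sample can occupy a bin alone.
    An all-equal cohort has no range and every sample is labelled ``mid``.
    """
    if len(profiles) < n:
        raise ValueError(f"need at least {n} samples to form {n} strata")
    ratios = np.array([p.rg_ratio for p in profiles])
    if np.ptp(ratios) == 0:
        z = np.full(ratios.size, np.nan)
        labels = ["mid" if n == 3 else f"bin_{(n + 1) // 2}"] * ratios.size
    else:
        z = zscore(ratios)
        labels = cut_interval(z, n)
    return [
        replace(p, zscore=(None if np.isnan(zi) else float(zi)), stratum=lab)
        for p, zi, lab in zip(profiles, z, labels)
    ]


def class_fractions(table: CountTable, sample: str) -> ClassFractionProfile:
    """Per-repeat-class fractions of raw repeat reads for one sample.

    Fractions use raw counts (fractions of reads), not normalized values.
    Every repeat class present in the table is reported; nothing is merged.
    """
    try:
        j = table.samples.index(sample)
    except ValueError:
        raise KeyError(f"unknown sample {sample!r}") from None
    col = table.counts[:, j].astype(float)
    total_all = col.sum()
    repeat_mask = table.kinds == REPEAT
    total_repeat = col[repeat_mask].sum()
    if total_repeat <= 0:
        raise ValueError(f"sample {sample!r}: zero repeat reads")
    classes = sorted({f.repeat_class for f in table.features if f.kind == REPEAT})
    fractions = {}
    for cls in classes:
        mask = np.array(
            [f.kind == REPEAT and f.repeat_class == cls for f in table.features]
        )
        fractions[cls] = float(col[mask].sum() / total_repeat)
    return ClassFractionProfile(
        sample=sample,
        class_fractions=fractions,
        repeat_fraction_of_all=float(total_repeat / total_all),
    )


def class_fraction_table(table: CountTable) -> pd.DataFrame:
    """Cohort-wide class-fraction table (one row per sample)."""
    rows = []
    for s in table.samples:
        prof = class_fractions(table, s)
        row = {"sample": s, "repeat_fraction_of_all": prof.repeat_fraction_of_all}
        row.update(prof.class_fractions)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def inter_patient_table(
    norm: NormalizedMatrix, feature_id: str
) -> tuple[pd.DataFrame, float]:
    """Per-sample normalized values for one feature plus the cohort median.

    The median (mean-of-central-two for even cohorts) is what the study plots
    as the horizontal reference line.
    """
    ids = [f.raw_id for f in norm.features]
    try:
        i = ids.index(feature_id)
    except ValueError:
        raise KeyError(f"unknown feature {feature_id!r}") from None
    values = norm.values[i, :]
    med = _median(values)
    df = pd.DataFrame({"sample": norm.samples, "value": values})
    df["cohort_median"] = med
    return df, med


def profiles_to_frame(profiles: Sequence[RGProfile]) -> pd.DataFrame:
    """Tabular export of RG profiles (ratios reported at full precision)."""
    return pd.DataFrame(
        {
            "sample": [p.sample for p in profiles],
            "median_repeat_expr": [p.median_repeat_expr for p in profiles],
            "median_gene_expr": [p.median_gene_expr for p in profiles],
            "rg_ratio": [p.rg_ratio for p in profiles],
            "zscore": [p.zscore for p in profiles],
            "stratum": [p.stratum for p in profiles],
        }
    ).set_index("sample")
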