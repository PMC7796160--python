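"""Long-RNA satellite quantification: counting, FPKM, normalization, fold change.

Per-sample reads mapped to the consensus dimers are counted once per read
(or fragment), scaled by median-of-ratios size factors to remove sequencing
depth, and compared between conditions as ratios of mean normalized counts.

The size factor of sample j is

    s_j = median_i ( K_ij / (prod_v K_iv)^(1/m) )

taken over features i whose counts are nonzero in every sample (the
geometric-mean reference is undefined otherwise). Fold changes are ratios of
pseudocount-stabilized group means of normalized counts; the accompanying
p-value is an explicitly approximate two-sample unequal-variance (Welch)
test on log2 normalized counts, not a negative-binomial Wald test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, NotComputableError

__all__ = [
    "count_reads",
    "fpkm",
    "size_factors",
    "fold_change",
    "ExpressionResult",
]

logger = logging.getLogger(__name__)


def count_reads(alignment_tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Feature x sample count matrix from per-sample alignment tables.

    Each table needs ``read_id`` and ``consensus`` columns (the mapper's TSV
    schema). A read is counted once: duplicate read_ids within a sample are
    collapsed with a warning (paired-end mates share a read_id, so fragments
    count once).
    """
    if not alignment_tables:
        raise InvalidParameterError("no alignment tables supplied")
    per_sample = {}
    features: set[str] = set()
    for sample, table in alignment_tables.items():
        if table.empty:
            per_sample[sample] = pd.Series(dtype=int)
            continue
        dups = table["read_id"].duplicated()
        if dups.any():
            logger.warning(
                "sample %s: %d duplicate read_ids collapsed to one count each",
                sample,
                int(dups.sum()),
            )
            table = table[~dups]
        counts = table.groupby("consensus")["read_id"].count()
        per_sample[sample] = counts
        features.update(counts.index)
    matrix = pd.DataFrame(
        {s: c.reindex(sorted(features), fill_value=0) for s, c in per_sample.items()},
        index=sorted(features),
        dtype=int,
    ).fillna(0)
    return matrix.astype(int)


def fpkm(count: int, feature_length_kb: float, mapped_total: int) -> float:
    """Fragments per kilobase of feature per million mapped reads."""
    if feature_length_kb <= 0:
        raise InvalidParameterError("feature_length_kb must be positive")
    if mapped_total <= 0:
        raise NotComputableError("mapped_total is zero; FPKM undefined")
    if count < 0:
        raise InvalidParameterError("count must be >= 0")
    return count / (feature_length_kb * mapped_total / 1e6)


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one positive scale per sample).

    Features containing any zero are excluded from the geometric-mean
    reference, the standard convention. Raises when no zero-free feature
    exists (a pseudo-reference over nonzero entries would then be needed;
    add a pseudocount or drop empty features before calling).
    """
    if matrix.shape[1] < 1:
        raise InvalidParameterError("count matrix needs at least one sample")
    counts = matrix.to_numpy(dtype=float)
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise NotComputableError(
            "every feature contains a zero count; no geometric-mean reference "
            "(consider a pseudo-reference or filtering)"
        )
    logs = np.log(counts[usable])
    log_ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_ref, axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


@dataclass
class ExpressionResult:
    """Per-feature group means, fold change and (approximate) significance."""

    table: pd.DataFrame  # index: feature; columns: mean_<a>, mean_<b>, fold_change, approx_p
    group_a: str
    group_b: str
    pseudocount: float
    p_is_approximate: bool = True


def fold_change(
    matrix: pd.DataFrame,
    factors: pd.Series,
    sample_groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    pseudocount: float = 0.5,
) -> ExpressionResult:
    """Treatment/control ratio of mean normalized counts per feature.

    fold = (mean normalized count in ``group_b`` + pseudocount)
         / (mean normalized count in ``group_a`` + pseudocount)

    ``approx_p`` is a Welch t-test on log2(normalized + pseudocount), only
    defined when both groups have >= 2 samples; it is an approximation and
    flagged as such on the result.
    """
    if pseudocount < 0:
        raise InvalidParameterError("pseudocount must be >= 0")
    samples_a = [s for s in matrix.columns if sample_groups.get(s) == group_a]
    samples_b = [s for s in matrix.columns if sample_groups.get(s) == group_b]
    if not samples_a or not samples_b:
        raise InvalidParameterError(f"both groups need >= 1 sample ({group_a}: "
                                    f"{len(samples_a)}, {group_b}: {len(samples_b)})")
    if (factors <= 0).any():
        raise InvalidParameterError("size factors must be positive")
    normalized = matrix.astype(float).div(factors.reindex(matrix.columns), axis=1)
    mean_a = normalized[samples_a].mean(axis=1)
    mean_b = normalized[samples_b].mean(axis=1)
    fold = (mean_b + pseudocount) / (mean_a + pseudocount)
    if len(samples_a) >= 2 and len(samples_b) >= 2:
        log_a = np.log2(normalized[samples_a] + pseudocount)
        log_b = np.log2(normalized[samples_b] + pseudocount)
        approx_p = pd.Series(
            stats.ttest_ind(log_b, log_a, axis=1, equal_var=False).pvalue,
            index=matrix.index,
        )
    else:
        approx_p = pd.Series(np.nan, index=matrix.index)
    table = pd.DataFrame(
        {
            f"mean_{group_a}": mean_a,
            f"mean_{group_b}": mean_b,
            "fold_change": fold,
            "approx_p": approx_p,
        }
    )
    return ExpressionResult(
        table=table, group_a=group_a, group_b=group_b, pseudocount=pseudocount
    )


def fpkm_matrix(matrix: pd.DataFrame, feature_lengths_kb: Mapping[str, float]) -> pd.DataFrame:
    """Per-sample FPKM for every feature (totals are per-sample column sums)."""
    totals = matrix.sum(axis=0)
    out = {}
    for sample in matrix.columns:
        total = int(totals[sample])
        out[sample] = [
            fpkm(int(matrix.loc[f, sample]), feature_lengths_kb[f], total) if total > 0 else np.nan
            for f in matrix.index
        ]
    return pd.DataFrame(out, index=matrix.index)


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df.astype(int)


def read_sample_sheet(path) -> dict[str, str]:
    """Sample sheet TSV with at least ``sample`` and ``group`` columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sample" not in df.columns or "group" not in df.columns:
        raise InvalidParameterError("sample sheet needs 'sample' and 'group' columns")
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))
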