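"""Intensity normalization and hierarchical aggregation of peak groups.

The quantity hierarchy runs peak group (precursor x run) -> glycopeptide
(same peptide sequence and glycan composition) -> site-specific glycan
(glycan composition on a protein glycosite group) -> protein glycosite.
Run intensities are median-normalized; the two middle levels sum their
three most intense members per sample, the glycosite level sums everything.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = ["median_normalize", "aggregate", "replicate_cv", "LEVELS"]

LEVELS = ("peak_group", "glycopeptide", "site_specific_glycan", "protein_glycosite")

#: members summed per sample at each aggregation step (None = all)
_TOP_N = {"glycopeptide": 3, "site_specific_glycan": 3, "protein_glycosite": None}


def median_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each run (column) so run medians over observed values coincide.

    The common level is the grand median of the per-run medians.  Missing
    values (NaN) are ignored by the medians and stay missing.  Idempotent.
    """
    medians = matrix.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"run(s) with no observed values: {bad}")
    target = float(np.median(medians.to_numpy()))
    return matrix * (target / medians)


def _top_n_sum(values: pd.Series, n: Optional[int]) -> float:
    v = values.dropna().to_numpy()
    if len(v) == 0:
        return np.nan
    if n is not None:
        v = np.sort(v)[::-1][:n]
    return float(v.sum())


def aggregate(matrix: pd.DataFrame, mapping: Mapping[str, str], level: str) -> pd.DataFrame:
    """Aggregate a (rows = analytes, columns = runs) matrix one level up.

    ``mapping`` sends each row key to its parent key at ``level``.  At the
    glycopeptide and site-specific-glycan levels the 3 most intense members
    are summed per sample (column-wise, so top-3 membership can differ
    between samples); at the protein-glycosite level all members are
    summed.  Rows with fewer members than 3 sum what is available; missing
    values never count as zero.
    """
    if level not in _TOP_N:
        raise ValueError(f"unknown aggregation level {level!r}")
    n = _TOP_N[level]
    parents = matrix.index.map(lambda k: mapping[k])
    out = matrix.groupby(parents).agg(lambda col: _top_n_sum(col, n))
    out.index.name = level
    return out


def replicate_cv(matrix: pd.DataFrame) -> pd.Series:
    """Coefficient of variation (sample sd / mean) per analyte across
    replicate runs; analytes with fewer than two observed values get NaN."""
    values = matrix.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(values), axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(values, axis=1)
        sd = np.array([
            np.nanstd(row[~np.isnan(row)], ddof=1) if c >= 2 else np.nan
            for row, c in zip(values, n_obs)
        ])
        cv = sd / mean
    cv[n_obs < 2] = np.nan
    return pd.Series(cv, index=matrix.index, name="cv")
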