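"""Volcano-style differential-abundance screen between MetS+ and MetS- groups.

Species are compared on raw (untransformed) abundances with the two-sided
Wilcoxon rank-sum (Mann-Whitney) test and a symmetric fold-change threshold:
a species is flagged when p < 0.05 and its MetS+/MetS- fold change exceeds
1.15 in either direction. No multiplicity correction is applied at this
exploratory stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lipid_matrix import LipidMatrix

FC_THRESHOLD = 1.15
ALPHA = 0.05


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U statistic, p-value).

    The null distribution is enumerated exactly when both samples have at
    most 8 observations and there are no ties; otherwise the normal
    approximation with tie-corrected variance and continuity correction is
    used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("samples must not contain missing values")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class VolcanoRow:
    species_id: str
    fold_change: float
    log2_fc: float
    p_value: float
    flagged: bool
    n_pos: int
    n_neg: int


def volcano_table(
    matrix: LipidMatrix,
    group_labels: pd.Series,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
    fc_stat: str = "mean",
) -> pd.DataFrame:
    """One volcano row per species: fold change MetS+/MetS-, Wilcoxon p, flag.

    ``group_labels`` is boolean (True = MetS+) indexed like the matrix
    subjects. Fold change is the ratio of group central abundances on the
    raw scale (``fc_stat``: 'mean' by convention, 'median' optional); the
    choice is recorded in ``DataFrame.attrs['fc_stat']``.
    """
    if fc_stat not in ("mean", "median"):
        raise ValueError("fc_stat must be 'mean' or 'median'")
    labels = group_labels.reindex(matrix.subjects).astype(bool)
    rows = []
    for sid in matrix.species:
        col = matrix.abundances[sid]
        pos = col[labels & col.notna()].to_numpy()
        neg = col[~labels & col.notna()].to_numpy()
        if pos.size < 2 or neg.size < 2:
            raise ValueError(f"species {sid!r}: need >=2 non-missing subjects per group")
        stat_fn = np.mean if fc_stat == "mean" else np.median
        fc = float(stat_fn(pos) / stat_fn(neg))
        _, p = wilcoxon_rank_sum(pos, neg)
        flagged = (fc > fc_threshold or fc < 1.0 / fc_threshold) and p < alpha
        rows.append(
            VolcanoRow(sid, fc, float(np.log2(fc)), p, bool(flagged), pos.size, neg.size)
        )
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("species_id")
    out.attrs["fc_stat"] = fc_stat
    out.attrs["fc_threshold"] = fc_threshold
    out.attrs["alpha"] = alpha
    return out


def selected_species(volcano: pd.DataFrame) -> list[str]:
    """Species flagged by the volcano screen (used for the network stage)."""
    return volcano.index[volcano["flagged"]].tolist()
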