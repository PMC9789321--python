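"""Alpha diversity, non-parametric group tests, and Bray-Curtis beta diversity.

Alpha indices follow the QIIME dialect the study used: observed taxa,
bias-corrected Chao1, Shannon entropy in bits, and Pielou-style evenness
``H / log2(S)``.  Group differences are assessed with the Kruskal-Wallis
rank test (the k-group generalization of the two-sample Wilcoxon test, with
a chi-square reference distribution).  Beta diversity is the Bray-Curtis
dissimilarity ``1 - 2 * sum(min) / (sum_i + sum_j)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountTable, DistanceMatrix

__all__ = [
    "alpha_indices",
    "alpha_group_tests",
    "kruskal_wallis",
    "bray_curtis",
    "aggregate_alpha",
    "aggregate_distance_matrices",
]

ALPHA_INDEX_NAMES = ("observed", "chao1", "shannon", "evenness")


def alpha_indices(table: CountTable) -> pd.DataFrame:
    """Per-sample observed richness, bias-corrected Chao1, Shannon (bits), evenness.

    Chao1 is ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` with F1/F2 the singleton
    and doubleton counts; evenness is ``H / log2(S_obs)``, defined as 1 for a
    single-taxon sample.
    """
    mat = table.counts.to_numpy()
    if mat.shape[0] == 0:
        raise ValueError("empty count table")
    totals = mat.sum(axis=1)
    zero = totals == 0
    if zero.any():
        raise ValueError(f"all-zero samples: {list(table.counts.index[zero])}")
    observed = (mat > 0).sum(axis=1)
    f1 = (mat == 1).sum(axis=1)
    f2 = (mat == 2).sum(axis=1)
    chao1 = observed + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    p = mat / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    shannon = -plogp.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        evenness = np.where(observed > 1, shannon / np.log2(np.maximum(observed, 2)), 1.0)
    return pd.DataFrame(
        {
            "observed": observed.astype(float),
            "chao1": chao1,
            "shannon": shannon,
            "evenness": np.clip(evenness, 0.0, 1.0),
        },
        index=table.counts.index,
    )


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Rank-based H statistic with tie correction; p from chi-square(k-1).

    All-tied data (zero rank variance) is reported as H = 0, p = 1 rather
    than an error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def alpha_group_tests(alpha: pd.DataFrame, metadata: pd.DataFrame, group_vars) -> pd.DataFrame:
    """Kruskal-Wallis test of each alpha index against each grouping variable."""
    meta = metadata.set_index("sample_id").loc[alpha.index]
    rows = []
    for var in group_vars:
        if var == "genus":
            from .io import missing_genus_placeholder

            labels = np.array(
                [
                    g if g is not None and pd.notna(g) else missing_genus_placeholder(f)
                    for g, f in zip(meta["genus"], meta["family"])
                ]
            )
        else:
            labels = meta[var].to_numpy()
        for index in alpha.columns:
            h, p = kruskal_wallis(alpha[index].to_numpy(), labels)
            rows.append({"variable": var, "index": index, "chi2": h, "p": p})
    return pd.DataFrame(rows)


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between all samples."""
    mat = table.counts.to_numpy(dtype=float)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    totals = mat.sum(axis=1)
    if (totals == 0).any():
        raise ValueError(f"all-zero samples: {list(table.counts.index[totals == 0])}")
    d = np.zeros((n, n))
    for i in range(n):
        # sum|x_i - x_j| = (T_i + T_j) - 2 sum(min); d = sum|.| / (T_i + T_j)
        diff = np.abs(mat[i + 1 :] - mat[i]).sum(axis=1)
        d[i, i + 1 :] = diff / (totals[i + 1 :] + totals[i])
    d = d + d.T
    return DistanceMatrix(list(table.counts.index), d)


def aggregate_alpha(frames: list[pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Element-wise mean and SD of alpha indices across rarefaction replicates."""
    idx = frames[0].index
    for f in frames[1:]:
        if not f.index.equals(idx):
            raise ValueError("replicates cover different sample sets")
    stack = np.stack([f.to_numpy() for f in frames])
    mean = pd.DataFrame(stack.mean(axis=0), index=idx, columns=frames[0].columns)
    sd = pd.DataFrame(stack.std(axis=0, ddof=0), index=idx, columns=frames[0].columns)
    return mean, sd


def aggregate_distance_matrices(dms: list[DistanceMatrix]) -> tuple[DistanceMatrix, np.ndarray]:
    """Element-wise mean distance matrix across replicates, plus the SD matrix."""
    ids = dms[0].ids
    for dm in dms[1:]:
        if dm.ids != ids:
            raise ValueError("replicates cover different sample sets")
    stack = np.stack([dm.data for dm in dms])
    return DistanceMatrix(ids, stack.mean(axis=0)), stack.std(axis=0, ddof=0)
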