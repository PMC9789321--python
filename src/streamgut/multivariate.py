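"""Ordination and permutation tests on community dissimilarities.

NMDS minimizes Kruskal stress-1 by alternating isotonic regression of
configuration distances on the input dissimilarity ranks with a Guttman
majorization update.  PERMANOVA compares among- vs within-group squared
dissimilarities through a pseudo-F ratio, with the null distribution built
by relabeling samples (sampled permutations, or exhaustive enumeration on
small instances).  PERMDISP tests homogeneity of multivariate dispersions
via distances to group centroids in principal-coordinate space, with the
standard correction subtracting imaginary-axis contributions.  Indicator
taxa are screened per taxon with Kruskal-Wallis tests under
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from statsmodels.stats.multitest import multipletests

from .diversity import kruskal_wallis
from .io import CountTable, DistanceMatrix

__all__ = [
    "OrdinationResult",
    "PermutationTestResult",
    "IndicatorResult",
    "nmds",
    "permanova",
    "permanova_exhaustive",
    "permdisp",
    "indicator_kw",
]


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    n_iterations: int
    converged: bool
    seed: int
    stress_history: list[float] = field(default_factory=list)


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, k))
    for a in range(min(k, n)):
        if vals[a] > 0:
            coords[:, a] = vecs[:, a] * np.sqrt(vals[a])
    return coords


def _config_distances(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _stress1_and_disparities(
    delta_flat: np.ndarray, order: np.ndarray
) -> tuple[float, np.ndarray]:
    """Stress-1 and monotone disparities for configuration distances.

    ``order`` sorts pairs by the input dissimilarity (stable, primary
    tie-breaking: tied dissimilarities may keep unordered fits).
    """
    fitted = np.empty_like(delta_flat)
    fitted[order] = isotonic_regression(delta_flat[order]).x
    denom = float((delta_flat**2).sum())
    if denom <= 0:
        return 0.0, fitted
    stress = np.sqrt(float(((fitted - delta_flat) ** 2).sum()) / denom)
    return stress, fitted


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    The best of ``n_starts`` runs is returned: the first starts from
    classical (metric) scaling of the dissimilarities, the rest from random
    configurations.  Updates are accepted only when stress-1 decreases, so
    each run's stress sequence is non-increasing.
    """
    n = len(dm.ids)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} dimensions")
    iu = np.triu_indices(n, k=1)
    d_flat = dm.data[iu]
    order = np.argsort(d_flat, kind="stable")
    rng = np.random.default_rng(seed)

    best = None
    for start in range(max(1, n_starts)):
        if start == 0:
            x = _classical_scaling(dm.data, k)
            if not np.any(x):
                x = rng.normal(size=(n, k))
        else:
            x = rng.normal(size=(n, k))
        delta = _config_distances(x)
        stress, fitted = _stress1_and_disparities(delta[iu], order)
        history = [stress]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            dhat = np.zeros_like(delta)
            dhat[iu] = fitted
            dhat = dhat + dhat.T
            # Guttman transform with disparities dhat
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(delta > 0, dhat / delta, 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x_new = (b @ x) / n
            delta_new = _config_distances(x_new)
            stress_new, fitted_new = _stress1_and_disparities(delta_new[iu], order)
            if stress_new > stress - 1e-15:
                converged = stress - stress_new < tol
                break
            x, delta, fitted = x_new, delta_new, fitted_new
            history.append(stress_new)
            if stress - stress_new < tol:
                stress = stress_new
                converged = True
                break
            stress = stress_new
        x = x - x.mean(axis=0)
        if best is None or stress < best[0]:
            best = (stress, x, it, converged, history)

    stress, x, it, converged, history = best
    coords = pd.DataFrame(x, index=dm.ids, columns=[f"NMDS{i + 1}" for i in range(k)])
    return OrdinationResult(
        coordinates=coords,
        stress=float(stress),
        n_iterations=it,
        converged=converged,
        seed=seed,
        stress_history=history,
    )


# ---------------------------------------------------------------------------
# PERMANOVA / PERMDISP
# ---------------------------------------------------------------------------


@dataclass
class PermutationTestResult:
    statistic: float
    p: float
    n_permutations: int
    seed: int
    group_sizes: dict[str, int]
    method: str = "sampled"
    degenerate: bool = False


def _group_codes(groups) -> tuple[np.ndarray, list]:
    labels = pd.unique(np.asarray(groups))
    code = {g: i for i, g in enumerate(labels)}
    return np.array([code[g] for g in groups]), list(labels)


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, k: int, sizes: np.ndarray) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    denom = ss_within / (n - k)
    if denom == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (k - 1)) / denom


def permanova(
    dm: DistanceMatrix, groups, n_permutations: int = 999, seed: int = 0
) -> PermutationTestResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    The p-value uses the add-one estimator
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)``.
    """
    codes, labels = _group_codes(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    n = len(codes)
    if n != len(dm.ids):
        raise ValueError("group labels do not match distance matrix")
    sizes = np.bincount(codes, minlength=k)
    d2 = dm.data**2
    f_obs = _pseudo_f(d2, codes, k, sizes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, k, sizes) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermutationTestResult(
        statistic=float(f_obs),
        p=float(p),
        n_permutations=n_permutations,
        seed=seed,
        group_sizes={str(g): int(s) for g, s in zip(labels, sizes)},
        method="sampled",
    )


def permanova_exhaustive(dm: DistanceMatrix, groups) -> PermutationTestResult:
    """Exact PERMANOVA p by enumerating all distinct label assignments.

    Intended for small instances (<= ~9 samples); the p-value is the plain
    fraction ``#{F_perm >= F_obs} / #assignments`` (the identity assignment
    is included in the enumeration).
    """
    codes, labels = _group_codes(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    n = len(codes)
    sizes = np.bincount(codes, minlength=k)
    d2 = dm.data**2
    f_obs = _pseudo_f(d2, codes, k, sizes)
    seen = set()
    count = 0
    total = 0
    for perm in itertools.permutations(codes):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if _pseudo_f(d2, np.array(perm), k, sizes) >= f_obs - 1e-12:
            count += 1
    return PermutationTestResult(
        statistic=float(f_obs),
        p=count / total,
        n_permutations=total,
        seed=0,
        group_sizes={str(g): int(s) for g, s in zip(labels, sizes)},
        method="exhaustive",
    )


def _pcoa_embedding(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates split into real (positive-eigenvalue) and
    imaginary (negative-eigenvalue) axes."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    tol = 1e-10 * max(1.0, np.abs(vals).max(initial=0.0))
    pos = vals > tol
    neg = vals < -tol
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag


def _centroid_distances(real: np.ndarray, imag: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    out = np.empty(len(codes))
    for g in range(k):
        idx = codes == g
        cr = real[idx].mean(axis=0)
        d2 = ((real[idx] - cr) ** 2).sum(axis=1)
        if imag.shape[1]:
            ci = imag[idx].mean(axis=0)
            d2 = d2 - ((imag[idx] - ci) ** 2).sum(axis=1)
        out[idx] = np.sqrt(np.clip(d2, 0.0, None))
    return out


def _anova_f(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = len(values)
    grand = values.mean()
    ss_b = ss_w = 0.0
    for g in range(k):
        v = values[codes == g]
        ss_b += len(v) * (v.mean() - grand) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
    if ss_w == 0:
        return np.inf if ss_b > 0 else np.nan
    return (ss_b / (k - 1)) / (ss_w / (n - k))


def permdisp(
    dm: DistanceMatrix, groups, n_permutations: int = 999, seed: int = 0
) -> PermutationTestResult:
    """Test homogeneity of multivariate dispersions (distance to centroid).

    Singleton groups are excluded with a warning (their dispersion is
    identically zero and would make the F ratio a degenerate artifact).
    When every centroid distance is zero the result is flagged degenerate
    with an undefined statistic.
    """
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    singles = labels[counts < 2]
    if len(singles):
        warnings.warn(
            f"excluding singleton groups from PERMDISP: {list(singles)}", UserWarning
        )
        keep = ~np.isin(groups, singles)
        ids = [s for s, k_ in zip(dm.ids, keep) if k_]
        dm = dm.filter(ids)
        groups = groups[keep]
    codes, labels = _group_codes(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("PERMDISP needs at least two non-singleton groups")
    real, imag = _pcoa_embedding(dm.data)
    dist = _centroid_distances(real, imag, codes, k)
    sizes = np.bincount(codes, minlength=k)
    if np.allclose(dist, 0.0):
        return PermutationTestResult(
            statistic=float("nan"),
            p=1.0,
            n_permutations=0,
            seed=seed,
            group_sizes={str(g): int(s) for g, s in zip(labels, sizes)},
            method="permdisp",
            degenerate=True,
        )
    f_obs = _anova_f(dist, codes, k)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        d_perm = _centroid_distances(real, imag, perm, k)
        f_perm = _anova_f(d_perm, perm, k)
        if np.isnan(f_perm):
            f_perm = 0.0
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermutationTestResult(
        statistic=float(f_obs),
        p=float(p),
        n_permutations=n_permutations,
        seed=seed,
        group_sizes={str(g): int(s) for g, s in zip(labels, sizes)},
        method="permdisp",
    )


# ---------------------------------------------------------------------------
# Indicator taxa
# ---------------------------------------------------------------------------


@dataclass
class IndicatorResult:
    table: pd.DataFrame  # per taxon: H, p, q
    significant: list[str]
    group_means: pd.DataFrame  # significant taxa x groups, mean rel. abundance
    q_threshold: float


def indicator_kw(
    table: CountTable, groups, q_threshold: float = 0.05
) -> IndicatorResult:
    """Per-taxon Kruskal-Wallis screen with Benjamini-Hochberg FDR control.

    Taxa with constant abundance across all samples get p = 1 by convention.
    Per-group mean relative abundances are reported for the significant set.
    """
    groups = np.asarray(groups)
    if len(pd.unique(groups)) < 2:
        raise ValueError("need at least two groups")
    rel = table.relative_abundance()
    rows = []
    for t in table.taxon_ids:
        v = rel[t].to_numpy()
        if np.all(v == v[0]):
            rows.append({"taxon": t, "H": 0.0, "p": 1.0})
        else:
            h, p = kruskal_wallis(v, groups)
            rows.append({"taxon": t, "H": h, "p": p})
    df = pd.DataFrame(rows).set_index("taxon")
    _, q, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["q"] = q
    significant = list(df.index[df["q"] <= q_threshold])
    labels = pd.unique(groups)
    means = pd.DataFrame(
        {str(g): rel.loc[groups == g, significant].mean(axis=0) for g in labels}
    ).T
    return IndicatorResult(
        table=df, significant=significant, group_means=means, q_threshold=q_threshold
    )
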