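"""Anxiety classification by consensus clustering of the seven phenotypes.

Monti-style consensus clustering: 80% of mice are subsampled 100 times,
k-means (Euclidean) is run on each subsample, and the consensus matrix
entry for a pair is the fraction of co-subsampled runs in which the pair
co-clustered.  Cluster-number stability is summarized by the CDF of
consensus values and its (delta-)area curve; the K=2 partition splits the
cohort into high-anxiety (HA, lower mean time in light) and low-anxiety
(LA) groups, which are then characterized by per-phenotype Mann-Whitney
tests with BH correction and a joint multivariate logistic regression.

Phenotypes are z-scored before clustering: raw Euclidean distance would be
dominated by the mm-scale distance phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .behavior import PHENOTYPE_NAMES
from .stats import bh_adjust, mann_whitney

__all__ = [
    "ConsensusResult",
    "consensus_cluster",
    "cdf_delta_area",
    "assign_anxiety",
    "group_tests",
    "multivariate_logit",
]


@dataclass
class ConsensusResult:
    """Per-K consensus matrices, stability curves and partitions."""

    ks: list[int]
    consensus: dict[int, np.ndarray]
    labels: dict[int, np.ndarray]  # cluster ids 0..K-1 per mouse
    areas: dict[int, float] = field(default_factory=dict)
    delta_areas: dict[int, float] = field(default_factory=dict)
    n_resamples: int = 0
    subsample_frac: float = 0.8
    seed: int | None = None


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(
            f"phenotype column {j} is constant; check the feature extraction"
        )
    return (X - mu) / sd


def consensus_cluster(
    X,
    k_max: int = 9,
    n_resamples: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
    n_init: int = 10,
    scale: bool = True,
) -> ConsensusResult:
    """Bootstrapped k-means consensus clustering over K = 2..k_max.

    For each of ``n_resamples`` draws, ``subsample_frac`` of the mice are
    sampled without replacement and k-means is run to convergence; the
    consensus entry for a pair is (times co-clustered) / (times
    co-sampled).  The same subsamples are reused across K so the stability
    curves compare like with like.  Final per-K partitions come from
    average-linkage hierarchical clustering of (1 - consensus).
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("phenotype matrix contains missing values")
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    n = X.shape[0]
    if n < 2 * k_max:
        raise ValueError(f"need at least {2 * k_max} mice for k_max={k_max}")
    Z = _zscore(X) if scale else X

    rng = np.random.default_rng(seed)
    m = max(2, int(np.ceil(subsample_frac * n)))
    subsamples = [rng.choice(n, size=m, replace=False) for _ in range(n_resamples)]
    km_seeds = rng.integers(0, 2**31 - 1, size=(n_resamples, k_max + 1))

    S = np.zeros((n, n))  # co-sample counts
    for idx in subsamples:
        S[np.ix_(idx, idx)] += 1

    ks = list(range(2, k_max + 1))
    consensus: dict[int, np.ndarray] = {}
    labels: dict[int, np.ndarray] = {}
    for K in ks:
        C = np.zeros((n, n))
        for r, idx in enumerate(subsamples):
            km = KMeans(n_clusters=K, n_init=n_init, tol=1e-6, random_state=int(km_seeds[r, K]))
            lab = km.fit_predict(Z[idx])
            same = lab[:, None] == lab[None, :]
            C[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(S > 0, C / np.where(S > 0, S, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        consensus[K] = M
        d = squareform(1.0 - M, checks=False)
        labels[K] = fcluster(linkage(d, method="average"), K, criterion="maxclust") - 1

    result = ConsensusResult(
        ks=ks,
        consensus=consensus,
        labels=labels,
        n_resamples=n_resamples,
        subsample_frac=subsample_frac,
        seed=seed,
    )
    cdf_delta_area(result)
    return result


def _cdf_area(values: np.ndarray) -> float:
    """Area under the empirical CDF of consensus values on [0, 1]."""
    x = np.sort(values)
    m = x.size
    grid = np.concatenate(([0.0], x, [1.0]))
    cdf = np.concatenate((np.arange(m + 1) / m, [1.0]))
    return float(np.sum(np.diff(grid) * cdf[:-1]))


def cdf_delta_area(result: ConsensusResult) -> dict[int, tuple[float, float]]:
    """Per-K CDF area and relative delta-area of the consensus values.

    ``delta(2) = area(2)``; for K > 2,
    ``delta(K) = (area(K) - area(K-1)) / area(K-1)``.
    """
    out: dict[int, tuple[float, float]] = {}
    prev = None
    for K in result.ks:
        M = result.consensus[K]
        iu = np.triu_indices_from(M, k=1)
        area = _cdf_area(M[iu])
        if prev is None:
            delta = area
        else:
            delta = (area - prev) / prev if prev > 0 else 0.0
        result.areas[K] = area
        result.delta_areas[K] = delta
        out[K] = (area, delta)
        prev = area
    return out


def assign_anxiety(result: ConsensusResult, phenotypes: pd.DataFrame) -> pd.Series:
    """Label the K=2 partition: lower mean time-in-light cluster = HA.

    Light avoidance is the assay's anxiety readout, so the cluster that
    spends less time in the light compartment is the high-anxiety one.
    Ties are broken on mean full-transition count (lower -> HA).
    """
    lab = result.labels[2]
    if len(set(lab)) < 2:
        raise ValueError("K=2 consensus partition has an empty cluster")
    tl = phenotypes["time_light"].to_numpy(dtype=float)
    means = [tl[lab == c].mean() for c in (0, 1)]
    if means[0] == means[1]:
        nf = phenotypes["n_full_transitions"].to_numpy(dtype=float)
        means = [nf[lab == c].mean() for c in (0, 1)]
    ha_cluster = 0 if means[0] < means[1] else 1
    return pd.Series(
        np.where(lab == ha_cluster, "HA", "LA"), index=phenotypes.index, name="anxiety"
    )


def group_tests(phenotypes: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-phenotype two-sided Mann-Whitney HA vs LA with BH adjustment."""
    ha = phenotypes.loc[labels == "HA"]
    la = phenotypes.loc[labels == "LA"]
    if len(ha) < 2 or len(la) < 2:
        raise ValueError("each anxiety group needs at least two mice")
    cols = [c for c in PHENOTYPE_NAMES if c in phenotypes.columns]
    stats, ps = [], []
    for c in cols:
        u, p = mann_whitney(ha[c].to_numpy(), la[c].to_numpy())
        stats.append(u)
        ps.append(p)
    return pd.DataFrame({"phenotype": cols, "U": stats, "p": ps, "q": bh_adjust(ps)})


def multivariate_logit(phenotypes: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Joint logistic regression of anxiety group on all seven phenotypes.

    Phenotypes are z-scored; coefficients are per-SD log-odds of being
    high-anxiety with Wald p-values.  Rank deficiency, perfect separation
    and non-convergence raise instead of being silently tolerated.
    """
    cols = [c for c in PHENOTYPE_NAMES if c in phenotypes.columns]
    X = _zscore(phenotypes[cols].to_numpy(dtype=float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient after standardization")
    y = (labels.reindex(phenotypes.index).to_numpy() == "HA").astype(float)
    Xc = sm.add_constant(X)
    try:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"logistic fit failed: {e}") from e
    if not fit.mle_retvals.get("converged", False):
        raise RuntimeError("logistic regression did not converge (possible separation)")
    if np.abs(fit.params).max() > 20:
        raise RuntimeError("coefficients diverged: perfect separation suspected")
    return pd.DataFrame(
        {
            "phenotype": ["intercept"] + cols,
            "coef": fit.params,
            "p": fit.pvalues,
        }
    ).reset_index(drop=True)
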