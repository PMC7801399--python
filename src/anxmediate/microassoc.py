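"""Microbiome association with anxiety group and HA/LA prediction.

Relative abundances (sample x OTU, rows closed to 1) are aggregated to
bacterial families, screened for differential abundance between anxiety
groups by Mann-Whitney with BH correction (FDR < 0.1 at family level,
< 0.05 at OTU level by default), quantified as per-SD odds ratios by
univariate logistic regression, and fed to a random-forest classifier
(1000 trees, 100 stratified 90/10 cross-validation iterations) whose
pooled held-out scores give the ROC/AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedShuffleSplit

from .stats import bh_adjust, mann_whitney

__all__ = [
    "family_abundance",
    "differential_abundance",
    "taxon_logistic",
    "RFResult",
    "rf_predict",
]

log = logging.getLogger(__name__)


def family_abundance(table: pd.DataFrame, taxonomy: pd.Series) -> pd.DataFrame:
    """Sum OTU relative abundances into family-level abundances.

    Mass is conserved: each sample's family abundances sum to the same
    total as its OTU abundances.
    """
    tax = taxonomy.reindex(table.columns)
    if tax.isna().any():
        missing = list(table.columns[tax.isna()][:3])
        raise ValueError(f"OTUs without family assignment: {missing}")
    return table.T.groupby(tax).sum().T


def differential_abundance(
    table: pd.DataFrame,
    labels: pd.Series,
    level: str = "family",
    taxonomy: pd.Series | None = None,
    fdr: float | None = None,
) -> pd.DataFrame:
    """Per-taxon Mann-Whitney HA vs LA with BH adjustment within the level.

    ``table`` holds OTU abundances; family-level testing aggregates member
    OTUs first (requires ``taxonomy``).  All-zero taxa are excluded with a
    log entry.  Default FDR threshold: 0.1 for families, 0.05 for OTUs.

    Returns a DataFrame with taxon, level, U, p, q, direction (+1 when the
    taxon is more abundant in HA) and a ``significant`` flag.
    """
    if level == "family":
        if taxonomy is None:
            raise ValueError("family-level testing requires a taxonomy map")
        data = family_abundance(table, taxonomy)
        thr = 0.1 if fdr is None else fdr
    elif level == "otu":
        data = table
        thr = 0.05 if fdr is None else fdr
    else:
        raise ValueError(f"unknown level {level!r}")

    lab = labels.reindex(data.index)
    ha = lab == "HA"
    la = lab == "LA"
    if not ha.any() or not la.any():
        raise ValueError("both anxiety groups must be non-empty")

    keep = []
    for taxon in data.columns:
        v = data[taxon].to_numpy(dtype=float)
        if not np.any(v > 0):
            log.info("excluding all-zero taxon %s", taxon)
            continue
        keep.append(taxon)
    rows = []
    for taxon in keep:
        v = data[taxon].to_numpy(dtype=float)
        u, p = mann_whitney(v[ha.to_numpy()], v[la.to_numpy()])
        direction = 1 if np.median(v[ha.to_numpy()]) >= np.median(v[la.to_numpy()]) else -1
        rows.append((taxon, level, u, p, direction))
    out = pd.DataFrame(rows, columns=["taxon", "level", "U", "p", "direction"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["q"] < thr
    return out


def taxon_logistic(
    table: pd.DataFrame,
    labels: pd.Series,
    taxa: list[str],
    taxonomy: pd.Series | None = None,
) -> pd.DataFrame:
    """Univariate logistic odds ratios per 1-SD abundance for chosen taxa.

    Each taxon's (family-aggregated when a taxonomy is given and the taxon
    is a family) abundance is z-scored and regressed against the anxiety
    label; OR = exp(coefficient) per SD, with a Wald 95% CI and BH across
    the fitted taxa.  Constant abundance and separated fits raise.
    """
    data = family_abundance(table, taxonomy) if taxonomy is not None else table
    lab = labels.reindex(data.index)
    y = (lab.to_numpy() == "HA").astype(float)
    rows = []
    for taxon in taxa:
        v = data[taxon].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            raise ValueError(f"abundance of {taxon} is constant across samples")
        z = (v - v.mean()) / sd
        fit = sm.Logit(y, sm.add_constant(z)).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", False) or abs(fit.params[1]) > 20:
            raise RuntimeError(f"separation or non-convergence fitting {taxon}")
        coef = fit.params[1]
        lo, hi = fit.conf_int()[1]
        rows.append((taxon, np.exp(coef), np.exp(lo), np.exp(hi), fit.pvalues[1]))
    out = pd.DataFrame(rows, columns=["taxon", "odds_ratio", "or_lo", "or_hi", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


@dataclass
class RFResult:
    """Random-forest cross-validation summary."""

    mean_accuracy: float
    auc: float
    roc: pd.DataFrame  # threshold, fpr, tpr (pooled held-out scores)
    importances: pd.Series  # mean decrease in impurity, sorted descending
    n_iterations: int
    pooled_scores: np.ndarray = field(repr=False, default=None)
    pooled_truth: np.ndarray = field(repr=False, default=None)


def rf_predict(
    table: pd.DataFrame,
    labels: pd.Series,
    taxa: list[str],
    taxonomy: pd.Series | None = None,
    n_trees: int = 1000,
    n_iterations: int = 100,
    train_frac: float = 0.9,
    seed: int = 0,
) -> RFResult:
    """Random-forest HA/LA prediction with repeated stratified 90/10 splits.

    Per iteration a stratified ``train_frac`` split is drawn, a forest of
    ``n_trees`` is trained, and held-out class-1 (HA) probabilities are
    recorded; accuracy is averaged over iterations while the ROC/AUC pools
    all held-out scores.  Splits leaving a class empty are re-drawn (at
    most 10 retries) with a log entry.
    """
    data = family_abundance(table, taxonomy) if taxonomy is not None else table
    X = data[list(taxa)].to_numpy(dtype=float)
    y = (labels.reindex(data.index).to_numpy() == "HA").astype(int)
    if min(np.bincount(y, minlength=2)) < 4:
        raise ValueError("need at least 4 samples per class")
    rng = np.random.default_rng(seed)
    accs = []
    pooled_scores: list[np.ndarray] = []
    pooled_truth: list[np.ndarray] = []
    imp = np.zeros(X.shape[1])
    for _ in range(n_iterations):
        tr = te = None
        for attempt in range(10):
            s = int(rng.integers(0, 2**31 - 1))
            split = StratifiedShuffleSplit(n_splits=1, train_size=train_frac, random_state=s)
            tr, te = next(split.split(X, y))
            if len(set(y[tr])) == 2 and len(set(y[te])) == 2:
                break
            log.info("re-drawing split (attempt %d): a class was absent", attempt + 1)
        else:
            raise RuntimeError("could not draw a split with both classes present")
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1
        )
        clf.fit(X[tr], y[tr])
        accs.append(clf.score(X[te], y[te]))
        pooled_scores.append(clf.predict_proba(X[te])[:, 1])
        pooled_truth.append(y[te])
        imp += clf.feature_importances_
    scores = np.concatenate(pooled_scores)
    truth = np.concatenate(pooled_truth)
    fpr, tpr, thr = roc_curve(truth, scores)
    auc = float(roc_auc_score(truth, scores))
    importances = pd.Series(imp / n_iterations, index=list(taxa)).sort_values(ascending=False)
    roc = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return RFResult(
        mean_accuracy=float(np.mean(accs)),
        auc=auc,
        roc=roc,
        importances=importances,
        n_iterations=n_iterations,
        pooled_scores=scores,
        pooled_truth=truth,
    )
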