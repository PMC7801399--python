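"""Causal mediation of allele effects on anxiety through taxon abundance.

For each candidate (SNP, taxon) pair the treatment T is the strain's
binary allele code, the mediator M is the (z-scored) taxon abundance and
the outcome Y is the anxiety label (HA = 1).  Two models are fitted:

* mediator:  ``M = alpha0 + alpha1 T + eps``, eps ~ N(0, sigma^2), least squares;
* outcome:   ``P(Y = 1) = Phi(beta0 + beta1 T + beta2 M)``, probit MLE.

Effects are composed on the outcome-probability scale via the
potential-outcomes definitions: the average causal mediation effect
(ACME) contrasts Phi(beta0 + beta1 t + beta2 M(1)) with M(0) at fixed
treatment t, with counterfactual mediator values drawn from the fitted
Normal mediator model; the average direct effect (ADE) contrasts the two
treatment arms at a fixed mediator distribution.  Both are averaged over
t in {0, 1}.  Inference is by nonparametric bootstrap over mice (or over
cages, which share microbiome profiles) with percentile intervals.

For Normal M and a probit link the composition has the closed form
``E[Phi(mu + sigma Z)] = Phi(mu / sqrt(1 + sigma^2))``, exposed as
:func:`closed_form_acme` and used as an independent oracle in the tests;
the estimator itself uses Monte-Carlo mediator draws so that it does not
depend on that identity.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .stats import bh_adjust, mann_whitney
from .genassoc import ALLELE_A, ALLELE_B, GenotypeMatrix

__all__ = [
    "ProbitFit",
    "probit_fit",
    "closed_form_acme",
    "MediationResult",
    "fit_mediation",
    "screen_pairs",
    "mediation_scan",
    "assign_loci",
]

log = logging.getLogger(__name__)

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass
class ProbitFit:
    params: np.ndarray
    converged: bool
    n_iter: int


def probit_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-9) -> ProbitFit:
    """Probit maximum likelihood by Fisher-scoring Newton iterations.

    Small, dependency-free and fast enough to refit inside every bootstrap
    draw.  Divergent coefficients (|beta| > 15 on standardized inputs) are
    reported as non-converged, which callers treat as separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    # start from the linear-probability fit scaled to the probit link
    try:
        beta = np.linalg.lstsq(X, (y - 0.5) * 2.5, rcond=None)[0]
    except np.linalg.LinAlgError:
        pass
    eps = 1e-10

    def loglik(b):
        Phi = np.clip(ndtr(X @ b), eps, 1 - eps)
        return float(y @ np.log(Phi) + (1 - y) @ np.log1p(-Phi))

    ll = loglik(beta)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        Phi = np.clip(ndtr(eta), eps, 1 - eps)
        phi = np.exp(-0.5 * eta * eta) / _SQRT2PI
        w = phi * phi / (Phi * (1 - Phi))
        score = X.T @ (phi * (y - Phi) / (Phi * (1 - Phi)))
        H = X.T @ (w[:, None] * X)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            return ProbitFit(beta, False, it)
        # step-halving line search keeps the ascent monotone
        new_beta, new_ll = beta + step, None
        for _ in range(20):
            cand = loglik(new_beta)
            if np.isfinite(cand) and cand >= ll - 1e-12:
                new_ll = cand
                break
            step = 0.5 * step
            new_beta = beta + step
        if new_ll is None:
            return ProbitFit(beta, False, it)
        beta, ll = new_beta, new_ll
        if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 15:
            return ProbitFit(beta, False, it)  # separation
        if np.abs(step).max() < tol:
            return ProbitFit(beta, True, it)
    return ProbitFit(beta, False, max_iter)


def closed_form_acme(
    alpha0: float, alpha1: float, sigma: float, beta0: float, beta1: float, beta2: float
) -> float:
    """Population ACME for Normal mediator + probit outcome, in closed form.

    Uses ``E[Phi(mu + sigma Z)] = Phi(mu / sqrt(1 + sigma^2))`` per
    treatment arm, averaged over both arms.
    """
    s = np.sqrt(1.0 + beta2**2 * sigma**2)
    vals = []
    for t in (0.0, 1.0):
        hi = ndtr((beta0 + beta1 * t + beta2 * (alpha0 + alpha1)) / s)
        lo = ndtr((beta0 + beta1 * t + beta2 * alpha0) / s)
        vals.append(hi - lo)
    return float(np.mean(vals))


@dataclass
class MediationResult:
    """Point estimates and bootstrap inference for one (SNP, taxon) pair."""

    acme: float
    ade: float
    total: float
    prop_mediated: float  # NaN (flagged) when total ~ 0
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    total_ci: tuple[float, float]
    p_acme: float
    n_boot: int
    n_discarded: int
    flags: list[str]
    mediator_params: tuple[float, float, float]  # alpha0, alpha1, sigma
    outcome_params: tuple[float, float, float]  # beta0, beta1, beta2


def _effects_from_params(
    a0: float, a1: float, sig: float, b: np.ndarray, z: np.ndarray
) -> tuple[float, float, float]:
    """(ACME, ADE, total) from fitted parameters using shared mediator draws.

    ``z`` are standard-normal draws realizing the counterfactual mediator
    distribution; sharing them across all four treatment/mediator
    combinations makes the decomposition total = ACME + ADE exact.
    """
    b0, b1, b2 = b
    m1 = a0 + a1 + sig * z
    m0 = a0 + sig * z
    f = lambda t, m: float(np.mean(ndtr(b0 + b1 * t + b2 * m)))
    acme = 0.5 * ((f(1, m1) - f(1, m0)) + (f(0, m1) - f(0, m0)))
    ade = 0.5 * ((f(1, m1) - f(0, m1)) + (f(1, m0) - f(0, m0)))
    total = f(1, m1) - f(0, m0)
    return acme, ade, total


def fit_mediation(
    T,
    M,
    Y,
    n_boot: int = 1000,
    seed: int = 0,
    n_draws_per_unit: int = 200,
    boot_draws: int = 2000,
    cage: np.ndarray | None = None,
    cage_bootstrap: bool = False,
) -> MediationResult:
    """Estimate ACME/ADE/total effect for one treatment-mediator-outcome triple.

    Point estimates use ``n_draws_per_unit`` counterfactual mediator draws
    per observation; bootstrap refits use ``boot_draws`` pooled draws
    (the mediator model has no covariates beyond T, so pooled draws are
    an identical estimator at far lower cost) with common random numbers
    across iterations.  Percentile CIs; the two-sided bootstrap sign test
    p-value is floored at 1/(n_boot + 1) so zero is never reported.

    With ``cage_bootstrap`` the resampling unit is the cage (all mice in a
    cage share their microbiome profile); the default resamples mice,
    matching a mouse-level n.
    """
    T = np.asarray(T, dtype=float)
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = T.size
    if set(np.unique(T)) - {0.0, 1.0}:
        raise ValueError("treatment must be coded 0/1")
    if len(np.unique(T)) < 2:
        raise ValueError("both treatment levels must be present")
    if len(np.unique(Y)) < 2:
        raise ValueError("both outcome classes must be present")

    rng = np.random.default_rng(seed)
    flags: list[str] = []

    def fit_models(t, m, y):
        Xm = np.column_stack([np.ones(t.size), t])
        coef, *_ = np.linalg.lstsq(Xm, m, rcond=None)
        resid = m - Xm @ coef
        dof = max(t.size - 2, 1)
        sig = float(np.sqrt(resid @ resid / dof))
        Xo = np.column_stack([np.ones(t.size), t, m])
        pf = probit_fit(Xo, y)
        return float(coef[0]), float(coef[1]), sig, pf

    a0, a1, sig, pf = fit_models(T, M, Y)
    if not pf.converged:
        flags.append("outcome_fit_nonconverged")
    z_point = rng.standard_normal(n * n_draws_per_unit)
    acme, ade, total = _effects_from_params(a0, a1, sig, pf.params, z_point)

    z_boot = rng.standard_normal(boot_draws)  # common random numbers
    boots = np.empty((n_boot, 3))
    discarded = 0
    if cage_bootstrap:
        if cage is None:
            raise ValueError("cage_bootstrap requires cage ids")
        cage = np.asarray(cage)
        groups = [np.flatnonzero(cage == c) for c in np.unique(cage)]
    kept = 0
    attempts = 0
    max_attempts = n_boot * 3
    while kept < n_boot and attempts < max_attempts:
        attempts += 1
        if cage_bootstrap:
            pick = rng.integers(0, len(groups), size=len(groups))
            idx = np.concatenate([groups[g] for g in pick])
        else:
            idx = rng.integers(0, n, size=n)
        t, m, y = T[idx], M[idx], Y[idx]
        if len(np.unique(t)) < 2 or len(np.unique(y)) < 2:
            discarded += 1
            continue
        ba0, ba1, bsig, bpf = fit_models(t, m, y)
        if not bpf.converged:
            discarded += 1
            continue
        boots[kept] = _effects_from_params(ba0, ba1, bsig, bpf.params, z_boot)
        kept += 1
    boots = boots[:kept]
    if kept < n_boot:
        flags.append("bootstrap_short")
    if discarded > 0.1 * max(kept, 1):
        flags.append("unreliable_bootstrap")
        log.warning("mediation bootstrap discarded %d draws (kept %d)", discarded, kept)

    def ci(col):
        return (float(np.percentile(boots[:, col], 2.5)), float(np.percentile(boots[:, col], 97.5)))

    if kept:
        frac_le = np.mean(boots[:, 0] <= 0)
        frac_ge = np.mean(boots[:, 0] >= 0)
        p = 2.0 * min(frac_le, frac_ge)
        p = float(min(1.0, max(p, 1.0 / (kept + 1))))
        acme_ci, ade_ci, total_ci = ci(0), ci(1), ci(2)
    else:
        p = float("nan")
        acme_ci = ade_ci = total_ci = (float("nan"), float("nan"))

    if abs(total) < 1e-12:
        prop = float("nan")
        flags.append("total_effect_zero")
    else:
        prop = acme / total
    return MediationResult(
        acme=acme,
        ade=ade,
        total=total,
        prop_mediated=prop,
        acme_ci=acme_ci,
        ade_ci=ade_ci,
        total_ci=total_ci,
        p_acme=p,
        n_boot=kept,
        n_discarded=discarded,
        flags=flags,
        mediator_params=(a0, a1, sig),
        outcome_params=tuple(map(float, pf.params)),
    )


def screen_pairs(
    G: GenotypeMatrix,
    family_table: pd.DataFrame,
    anxiety_snps,
    taxa: list[str],
    strain_of_mouse: pd.Series,
    p_threshold: float = 1e-9,
) -> pd.DataFrame:
    """Candidate (SNP, taxon) pairs: allele-abundance Mann-Whitney screen.

    Only SNPs already significant for anxiety are considered; a pair is
    kept when the taxon's abundance differs between the SNP's allele
    groups (mouse level) at p < ``p_threshold``.
    """
    anxiety_snps = list(anxiety_snps)
    snp_idx = pd.Index(G.snp_ids).get_indexer(anxiety_snps)
    if (snp_idx < 0).any():
        raise ValueError("anxiety SNPs absent from genotype matrix")
    strains = strain_of_mouse.reindex(family_table.index)
    strain_pos = pd.Index(G.strains).get_indexer(strains.to_numpy())
    rows = []
    for sid, si in zip(anxiety_snps, snp_idx):
        alleles = G.alleles[strain_pos, si]
        ok = (alleles == ALLELE_A) | (alleles == ALLELE_B)
        t = (alleles == ALLELE_B).astype(float)
        for taxon in taxa:
            v = family_table[taxon].to_numpy(dtype=float)
            g0 = v[ok & (t == 0)]
            g1 = v[ok & (t == 1)]
            if g0.size == 0 or g1.size == 0:
                log.info("skipping pair (%s, %s): empty allele group", sid, taxon)
                continue
            _, p = mann_whitney(g1, g0)
            if p < p_threshold:
                rows.append((sid, taxon, p))
    return pd.DataFrame(rows, columns=["snp_id", "taxon", "screen_p"])


def assign_loci(snps: pd.DataFrame, window_bp: int = 1_000_000) -> pd.Series:
    """Collapse SNPs within ``window_bp`` on a chromosome into loci.

    Input needs chrom and pos columns; returns locus ids ("locus1", ...)
    aligned with the input rows, assigned in genome order.
    """
    order = snps.sort_values(["chrom", "pos"]).index
    locus = pd.Series(index=snps.index, dtype=object)
    current = 0
    last_chrom, last_pos = None, None
    for i in order:
        c, p = snps.loc[i, "chrom"], snps.loc[i, "pos"]
        if c != last_chrom or (p - last_pos) > window_bp:
            current += 1
        locus.loc[i] = f"locus{current}"
        last_chrom, last_pos = c, p
    return locus


def mediation_scan(
    pairs: pd.DataFrame,
    G: GenotypeMatrix,
    family_table: pd.DataFrame,
    labels: pd.Series,
    strain_of_mouse: pd.Series,
    fdr: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
    locus_window: int = 1_000_000,
    cage_of_mouse: pd.Series | None = None,
    cage_bootstrap: bool = False,
) -> pd.DataFrame:
    """Fit mediation for every screened pair and BH-adjust ACME p-values.

    SNPs in perfect linkage share a strain allele pattern; pairs with an
    identical (pattern, taxon) signature are fitted once and the result is
    broadcast, which leaves the statistics unchanged.  Each unique fit
    gets its own child seed so the scan is deterministic under ``seed``.
    Significant SNPs are grouped into loci within ``locus_window`` bp.
    """
    if pairs.empty:
        return pd.DataFrame(
            columns=["snp_id", "chrom", "pos", "taxon", "acme", "acme_lo", "acme_hi",
                     "ade", "total", "prop_mediated", "p", "q", "significant", "locus"]
        )
    mice = family_table.index
    strains = strain_of_mouse.reindex(mice)
    strain_pos = pd.Index(G.strains).get_indexer(strains.to_numpy())
    snp_pos_map = {s: i for i, s in enumerate(G.snp_ids)}
    y = (labels.reindex(mice).to_numpy() == "HA").astype(float)
    cage = cage_of_mouse.reindex(mice).to_numpy() if cage_of_mouse is not None else None

    ss = np.random.SeedSequence(seed)
    signatures: dict[tuple, MediationResult] = {}
    results = []
    for row in pairs.itertuples(index=False):
        si = snp_pos_map[row.snp_id]
        alleles = G.alleles[strain_pos, si]
        ok = (alleles == ALLELE_A) | (alleles == ALLELE_B)
        t = (alleles == ALLELE_B).astype(float)
        key = (alleles.tobytes(), row.taxon)
        if key not in signatures:
            v = family_table[row.taxon].to_numpy(dtype=float)
            m = (v - v.mean()) / v.std(ddof=0)
            child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
            signatures[key] = fit_mediation(
                t[ok], m[ok], y[ok], n_boot=n_boot, seed=child_seed,
                cage=cage[ok] if cage is not None else None, cage_bootstrap=cage_bootstrap,
            )
        res = signatures[key]
        results.append(
            {
                "snp_id": row.snp_id,
                "chrom": str(G.chrom[si]),
                "pos": int(G.pos[si]),
                "taxon": row.taxon,
                "acme": res.acme,
                "acme_lo": res.acme_ci[0],
                "acme_hi": res.acme_ci[1],
                "ade": res.ade,
                "total": res.total,
                "prop_mediated": res.prop_mediated,
                "p": res.p_acme,
            }
        )
    out = pd.DataFrame(results)
    # pairs whose bootstrap collapsed entirely carry no evidence: p -> 1
    p_for_bh = out["p"].fillna(1.0).to_numpy()
    out["q"] = bh_adjust(p_for_bh)
    out["significant"] = (out["q"] < fdr) & out["p"].notna()
    sig = out.loc[out["significant"], ["chrom", "pos"]]
    out["locus"] = pd.NA
    if len(sig):
        out.loc[sig.index, "locus"] = assign_loci(sig, window_bp=locus_window)
    return out
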