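"""Cohort statistics for repeated-measures proteome data.

Within-subject one-way ANOVA (subject as blocking factor), Storey
q-values, paired period contrasts with log2 fold-differences, fuzzy
c-means clustering of standardized temporal profiles, Bonferroni pairwise
contrasts on compartment-summed synthesis rates, and hypergeometric
overrepresentation analysis against a user-supplied term collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AnovaResult:
    f: float
    p: float
    df_num: int
    df_den: int
    flags: set


def within_subject_anova(values: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x timepoints matrix.

    Subject is the blocking factor; F = MS_time / MS_(subject x time), with
    (T-1, (T-1)(S-1)) degrees of freedom. A degenerate zero error SS is
    reported at the boundary (p = 0 if there is a time effect, else 1)
    with a flag instead of raising.
    """
    values = np.asarray(values, float)
    if values.ndim != 2:
        raise ValueError("expected a subjects x timepoints matrix")
    s, t = values.shape
    if s < 2 or t < 2:
        raise ValueError("need >= 2 subjects and >= 2 timepoints")
    if not np.all(np.isfinite(values)):
        raise ValueError("complete cases required")
    grand = values.mean()
    ss_time = s * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_subj = t * ((values.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((values - grand) ** 2).sum()
    ss_err = ss_total - ss_time - ss_subj
    df_num, df_den = t - 1, (t - 1) * (s - 1)
    flags: set = set()
    if ss_err <= 1e-300:
        flags.add("degenerate_error")
        if ss_time <= 1e-300:
            return AnovaResult(0.0, 1.0, df_num, df_den, flags)
        return AnovaResult(np.inf, 0.0, df_num, df_den, flags)
    f = (ss_time / df_num) / (ss_err / df_den)
    p = float(scipy.stats.f.sf(f, df_num, df_den))
    return AnovaResult(float(f), p, df_num, df_den, flags)


@dataclass
class QValueResult:
    qvalues: np.ndarray
    pi0: float
    q_at_p05: float | None


def storey_qvalues(
    pvalues: np.ndarray, lambdas: np.ndarray | None = None
) -> QValueResult:
    """Storey q-values with the smoother estimate of pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the
    lambda grid, a cubic polynomial smoother is fit, and pi0 is its value
    at the largest lambda (clamped to (0, 1]). q_i is the usual
    min-accumulated pi0 * m * p_(j) / j. ``q_at_p05`` is the q-value at
    the p = 0.05 boundary (largest p <= 0.05), the scalar the study
    reports alongside unadjusted significance.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if m < 100:
        pi0 = 1.0  # too few tests for a stable smoother fit
    else:
        pi0_l = np.array(
            [(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas]
        )
        coef = np.polyfit(lambdas, pi0_l, 3)
        pi0 = float(np.polyval(coef, lambdas.max()))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p_sorted / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    below = p_sorted <= 0.05
    q_at = float(q_sorted[below][-1]) if below.any() else None
    return QValueResult(q, pi0, q_at)


def paired_contrast(
    values_a: pd.DataFrame,
    values_b: pd.DataFrame,
    method: str = "ttest",
) -> pd.DataFrame:
    """Per-protein paired contrast between two periods.

    Inputs are proteins x subjects tables of (positive) values for each
    period. Output columns: log2fc = log2(mean_b / mean_a), p from a
    paired t-test on the within-subject differences (or the exact
    sign-permutation distribution of the mean difference when
    ``method='permutation'``), and a flag for nonpositive means.
    """
    if not values_a.index.equals(values_b.index):
        raise ValueError("period tables must share the protein index")
    if method not in ("ttest", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    n_subj = values_a.shape[1]
    signs = None
    if method == "permutation":
        signs = np.array(list(product((1.0, -1.0), repeat=n_subj)))
    for acc in values_a.index:
        a = values_a.loc[acc].to_numpy(float)
        b = values_b.loc[acc].to_numpy(float)
        ma, mb = a.mean(), b.mean()
        flagged = ma <= 0 or mb <= 0
        log2fc = np.log2(mb / ma) if not flagged else np.nan
        d = b - a
        if np.allclose(d, 0):
            p = 1.0
        elif method == "ttest":
            p = float(scipy.stats.ttest_rel(b, a).pvalue)
        else:
            obs = abs(d.mean())
            perm = np.abs(signs @ d) / n_subj
            p = float((perm >= obs - 1e-12).mean())
        rows.append(
            {"accession": acc, "log2fc": log2fc, "p": p,
             "nonpositive_mean": flagged}
        )
    return pd.DataFrame(rows).set_index("accession")


@dataclass
class ClusterResult:
    centers: np.ndarray  # c x T standardized temporal profiles
    membership: np.ndarray  # n x c, rows sum to 1
    assignment: np.ndarray  # argmax cluster, -1 where below the floor
    objective_history: np.ndarray
    min_membership: float


def fuzzy_cmeans(
    profiles: np.ndarray,
    c: int,
    fuzzifier: float = 1.25,
    min_membership: float = 0.25,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> ClusterResult:
    """Fuzzy c-means on standardized temporal profiles.

    Classic alternating optimization: memberships from inverse squared
    distances with exponent 2/(m-1), centers as membership^m-weighted
    means, iterated until the largest center shift falls below ``tol``.
    The objective sum(u^m d^2) is recorded per iteration (non-increasing).
    A profile is assigned to its max-membership cluster only when that
    membership reaches ``min_membership``; otherwise assignment is -1.
    """
    x = np.asarray(profiles, float)
    n = x.shape[0]
    if c < 1:
        raise ValueError("need c >= 1")
    if c > n:
        raise ValueError("more clusters than profiles")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must exceed 1")
    rng = np.random.default_rng(seed)
    centers = x[rng.choice(n, size=c, replace=False)].copy()
    expo = 2.0 / (fuzzifier - 1.0)
    history = []
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-expo / 2.0)
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u**fuzzifier
        history.append(float((um * d2).sum()))
        new_centers = (um.T @ x) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    d2 = np.maximum(d2, 1e-12)
    inv = d2 ** (-expo / 2.0)
    u = inv / inv.sum(axis=1, keepdims=True)
    best = u.argmax(axis=1)
    assignment = np.where(u[np.arange(n), best] >= min_membership, best, -1)
    return ClusterResult(
        centers=centers,
        membership=u,
        assignment=assignment,
        objective_history=np.array(history),
        min_membership=min_membership,
    )


def standardize_profiles(profiles: np.ndarray) -> np.ndarray:
    """Per-row z-score across timepoints (the clustering input)."""
    x = np.asarray(profiles, float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def pairwise_period_contrasts(
    sums: pd.DataFrame, periods: tuple[str, ...] = ("FL", "EB", "ED")
) -> dict:
    """Omnibus RM-ANOVA plus Bonferroni paired contrasts across periods.

    ``sums`` is subjects x periods (e.g. compartment-summed ASR). Each of
    the three paired contrasts gets p x 3 (capped at 1).
    """
    for per in periods:
        if per not in sums.columns:
            raise ValueError(f"missing period {per!r}")
    mat = sums[list(periods)].to_numpy(float)
    omnibus = within_subject_anova(mat)
    n_pairs = len(periods) * (len(periods) - 1) // 2
    contrasts = {}
    for i in range(len(periods)):
        for j in range(i + 1, len(periods)):
            a, b = periods[i], periods[j]
            d = mat[:, j] - mat[:, i]
            if np.allclose(d, 0):
                raw = 1.0
            else:
                raw = float(scipy.stats.ttest_rel(mat[:, j], mat[:, i]).pvalue)
            contrasts[f"{b}_vs_{a}"] = {
                "p_raw": raw,
                "p_adj": min(1.0, n_pairs * raw),
                "mean_diff": float(d.mean()),
            }
    means = {
        per: {
            "mean": float(mat[:, i].mean()),
            "sem": float(mat[:, i].std(ddof=1) / np.sqrt(mat.shape[0])),
        }
        for i, per in enumerate(periods)
    }
    return {"omnibus": omnibus, "contrasts": contrasts, "means": means}


@dataclass
class EnrichmentResult:
    term_id: str
    k_fg: int  # term ∩ foreground
    k_bg: int  # term ∩ background
    n_fg: int
    n_bg: int
    p: float
    p_adj: float = np.nan
    significant: bool = False


def ora_hypergeometric(
    foreground: set,
    background: set,
    term_sets: dict[str, set],
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Overrepresentation analysis against the experiment background.

    Upper-tail hypergeometric p per term (terms first intersected with the
    background), Benjamini-Hochberg adjusted across terms; significance at
    adjusted p <= alpha.
    """
    if not foreground:
        raise ValueError("empty foreground")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    n_bg, n_fg = len(background), len(foreground)
    results = []
    for term_id in sorted(term_sets):
        members = term_sets[term_id] & background
        k_fg = len(members & foreground)
        p = float(scipy.stats.hypergeom.sf(k_fg - 1, n_bg, len(members), n_fg))
        results.append(
            EnrichmentResult(term_id, k_fg, len(members), n_fg, n_bg, min(p, 1.0))
        )
    if results:
        _, p_adj, _, _ = multipletests(
            [r.p for r in results], method="fdr_bh"
        )
        for r, pa in zip(results, p_adj):
            r.p_adj = float(pa)
            r.significant = pa <= alpha
    return results
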