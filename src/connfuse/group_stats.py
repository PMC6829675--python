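"""Univariate statistical arm.

Edge-wise two-sample t-tests (Student, pooled variance) with
Benjamini-Hochberg FDR control across the 4005-edge family; the four-edge
summation score; one-way ANOVA with Tukey-Kramer post hoc comparisons
(studentized-range CDF with unequal-n Kramer standard errors), available
both from raw scores and from printed (mean, SD, n) summaries; and partial
correlation with clinical covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectome import EdgeIndex


def pooled_ttest(features: np.ndarray, labels: np.ndarray, welch: bool = False):
    """Vectorized two-sample t-test per column (patients vs controls).

    Returns (t, p, mean_a, sd_a, mean_b, sd_b) with group A = labels > 0.
    Zero-pooled-variance columns give t = 0, p = 1 with a warning.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    a, b = x[labels > 0], x[labels <= 0]
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least two subjects per group")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    if welch:
        se2 = va / na + vb / nb
        df = se2**2 / (
            np.maximum((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1), 1e-300)
        )
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = np.full_like(se2, na + nb - 2, dtype=float)
    zero = se2 == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero-variance column(s): p set to 1", stacklevel=2
        )
    t = np.where(zero, 0.0, (ma - mb) / np.sqrt(np.where(zero, 1.0, se2)))
    p = np.where(zero, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return t, p, ma, np.sqrt(va), mb, np.sqrt(vb)


def ttest_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, float]:
    """Student two-sample t-test from printed summary statistics."""
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    _, adj, _, _ = multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")
    return adj


def edge_ttests(
    features: np.ndarray,
    labels: np.ndarray,
    edge_index: EdgeIndex | None = None,
    q: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Edge-wise group comparison table with BH-FDR adjustment.

    One row per edge: connection label, group means/SDs, t, two-tailed p,
    adjusted p, and the q < 0.05 significance flag.
    """
    x = np.asarray(features, dtype=float)
    idx = edge_index
    t, p, ma, sa, mb, sb = pooled_ttest(x, labels, welch=welch)
    adj = bh_adjust(p)
    labels_col = (
        idx.edge_labels() if idx is not None else [f"e{k}" for k in range(x.shape[1])]
    )
    return pd.DataFrame(
        {
            "connection": labels_col,
            "mean_patients": ma,
            "sd_patients": sa,
            "mean_controls": mb,
            "sd_controls": sb,
            "t": t,
            "p": p,
            "p_fdr": adj,
            "significant": adj < q,
        }
    )


def summation_score(
    features: np.ndarray, edges, edge_index: EdgeIndex | None = None
) -> np.ndarray:
    """Per-subject sum of the given edges' (corrected) Fisher-z values.

    ``edges`` may be vector positions or (i, j) region pairs (0-based) if an
    edge index is supplied.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    positions = []
    for e in edges:
        if np.isscalar(e):
            positions.append(int(e))
        else:
            if edge_index is None:
                raise ValueError("edge pairs require an edge_index")
            positions.append(edge_index.position(*e))
    return x[:, positions].sum(axis=1)


@dataclass
class AnovaResult:
    group_names: list
    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray
    f: float
    p: float
    tukey_p: dict  # (name_i, name_j) -> adjusted p


def _tukey_kramer(means, sds, ns, msw, dfw) -> dict:
    out = {}
    k = len(means)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            qstat = abs(means[i] - means[j]) / se if se > 0 else 0.0
            out[(i, j)] = float(stats.studentized_range.sf(qstat, k, dfw))
    return out


def anova_from_summary(means, sds, ns, group_names=None) -> AnovaResult:
    """Classical one-way F (and Tukey-Kramer) from (mean, SD, n) triples."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if np.any(ns < 2) or len(means) < 2:
        raise ValueError("need >= 2 groups with n >= 2 each")
    n_tot = ns.sum()
    k = len(means)
    grand = (ns * means).sum() / n_tot
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    dfb, dfw = k - 1, n_tot - k
    msb, msw = ssb / dfb, ssw / dfw
    if msw > 0:
        f = msb / msw
    else:
        f = 0.0 if msb == 0 else np.inf
    p = float(stats.f.sf(f, dfb, dfw)) if np.isfinite(f) else 0.0
    names = list(group_names) if group_names is not None else list(range(k))
    tk = {
        (names[i], names[j]): v
        for (i, j), v in _tukey_kramer(means, sds, ns, msw, dfw).items()
    }
    return AnovaResult(names, means, sds, ns, float(f), p, tk)


def oneway_anova(scores: np.ndarray, groups) -> AnovaResult:
    """One-way ANOVA with Tukey-Kramer post hoc on raw per-subject scores."""
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    names = list(pd.unique(groups))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    means, sds, ns = [], [], []
    for g in names:
        vals = scores[groups == g]
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        means.append(vals.mean())
        sds.append(vals.std(ddof=1))
        ns.append(vals.size)
    return anova_from_summary(means, sds, ns, group_names=names)


def partial_correlation(x, y, covariates) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Correlates the OLS residuals of both variables on [1, covariates]; the
    two-tailed p comes from the t transform with df = n - n_cov - 2.
    Collinear covariate columns are dropped (with a warning) before fitting.
    """
    from .connectome import residualize

    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    n = x.size
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), c]))
    n_cov = rank - 1
    if n <= n_cov + 2:
        raise ValueError("too few observations for the requested covariates")
    rx = residualize(x[:, None], c).ravel()
    ry = residualize(y[:, None], c).ravel()
    # a variable fully explained by the covariates has no residual variation
    if np.linalg.norm(rx) <= 1e-10 * np.linalg.norm(x - x.mean()) or np.linalg.norm(
        ry
    ) <= 1e-10 * np.linalg.norm(y - y.mean()):
        r = 0.0
    else:
        denom = np.sqrt((rx**2).sum() * (ry**2).sum())
        r = float((rx * ry).sum() / denom) if denom > 0 else 0.0
    df = n - n_cov - 2
    r_ = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p
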