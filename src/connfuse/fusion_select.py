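"""Two-stage feature reduction: overlap filtering, then k-support-norm
regression with an inter-modality distance penalty.

Filtering: the differential structural vector ``Delta M_S =
|M_S^patients - M_S^controls|`` is ranked descending and the functional
edges ascending by
two-sample-t p-value; the cutoff ``c`` is the number of ``Delta M_S``
entries at or above the vector's mean, and the selected set ``L`` is the
intersection of the two top-``c`` lists.

Selection: the label vector is regressed on the functional features of
``L`` under a k-support-norm penalty (sparse but correlated selection,
interpolating between the lasso at k = 1 and ridge-like behaviour at
k = d) plus an inter-modality term that shrinks features whose functional
and structural profiles disagree.  The inter-modality distance is realized
as the feature-weighted ridge ``lambda2 * sum_j d_j w_j**2`` with
``d_j = sum_i (x_ij - m_ij)**2``; the literal subject-level distance
``sum_i ||x_i - m_i||**2`` does not involve W and is kept only as an
audit mode (``intermodality="constant"``).

The proximal operator of the (first-power) k-support norm is computed via
the Moreau decomposition ``prox(v) = v - P(v)``, where ``P`` projects onto
the dual-norm ball ``{u : sum of the k largest u_i**2 <= theta**2}``.  The
projection's KKT system partitions the sorted magnitudes into a scaled
block, a tie block clamped at a common value t, and an untouched tail; the
solver enumerates candidate partitions in a vectorized sweep with bisection
for t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectome import EdgeIndex, structural_network
from .group_stats import pooled_ttest


class EmptySelectionError(ValueError):
    """Raised when the two top-c lists share no edge."""


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterResult:
    delta_s: np.ndarray  # |M_S^A - M_S^B| per edge
    structural_rank: np.ndarray  # edge positions, descending |delta|
    functional_rank: np.ndarray  # edge positions, ascending t-test p
    cutoff_c: int
    selected: np.ndarray  # ordered (ascending) edge positions in L
    functional_p: np.ndarray = None


def filter_cutoff(delta_s: np.ndarray) -> int:
    """The c-rule: number of entries at or above the mean of ``Delta M_S``."""
    delta_s = np.asarray(delta_s, dtype=float)
    return int(np.sum(delta_s >= delta_s.mean()))


def filter_features(
    ms_a: np.ndarray,
    ms_b: np.ndarray,
    functional_features: np.ndarray,
    labels: np.ndarray,
) -> FilterResult:
    """Overlap filtering of the two modalities (training data only).

    Ties in either ranking are broken by edge position, ascending.
    """
    ms_a = np.asarray(ms_a, dtype=float)
    ms_b = np.asarray(ms_b, dtype=float)
    delta = np.abs(ms_a - ms_b)
    d = delta.size
    positions = np.arange(d)

    c = filter_cutoff(delta)
    structural_rank = np.lexsort((positions, -delta))
    _, p, *_ = pooled_ttest(functional_features, labels)
    functional_rank = np.lexsort((positions, p))

    selected = np.intersect1d(structural_rank[:c], functional_rank[:c])
    if selected.size == 0:
        raise EmptySelectionError(
            "no overlap between structural and functional top-c lists; "
            "the cutoff c is too small for these data"
        )
    return FilterResult(
        delta_s=delta,
        structural_rank=structural_rank,
        functional_rank=functional_rank,
        cutoff_c=c,
        selected=selected,
        functional_p=p,
    )


def subject_structural_features(
    volumes: np.ndarray, groups: np.ndarray, edge_index: EdgeIndex | None = None
) -> np.ndarray:
    """Subject-level structural edge features via jackknife pseudo-values.

    The group structural network is a single correlation per edge; a
    subject's contribution is the jackknife pseudo-value
    ``m_i = n_g * r_g - (n_g - 1) * r_g^(-i)`` computed within the
    subject's own group, which reduces to ``r_g`` when every subject is
    exchangeable and isolates influential subjects otherwise.
    """
    v = np.asarray(volumes, dtype=float)
    groups = np.asarray(groups)
    idx = edge_index or EdgeIndex(v.shape[1])
    rows, cols = np.tril_indices(idx.n_regions, -1)
    out = np.empty((v.shape[0], idx.n_edges))
    for g in np.unique(groups):
        sel = np.flatnonzero(groups == g)
        n_g = sel.size
        if n_g < 5:
            raise ValueError(f"group {g!r} has fewer than 5 subjects")
        sub = v[sel]
        with np.errstate(invalid="ignore", divide="ignore"):
            r_full = np.nan_to_num(np.corrcoef(sub, rowvar=False))[rows, cols]
            # leave-one-out correlations from downdated sums
            s1 = sub.sum(axis=0)
            s2 = (sub**2).sum(axis=0)
            cross = sub.T @ sub
            np_ = n_g - 1
            for pos, i in enumerate(sel):
                x = sub[pos]
                s1_i = s1 - x
                s2_i = s2 - x * x
                num = np_ * (cross - np.outer(x, x)) - np.outer(s1_i, s1_i)
                var = np_ * s2_i - s1_i * s1_i
                den = np.sqrt(np.outer(var, var))
                r_loo = np.nan_to_num(np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0))
                out[i] = n_g * r_full - (n_g - 1) * r_loo[rows, cols]
    return out


@dataclass
class FusionDesign:
    x: np.ndarray  # subjects x |L| functional features
    m: np.ndarray  # subjects x |L| structural features, rescaled to X
    y: np.ndarray  # +1 / -1 labels
    d_weights: np.ndarray  # per-feature inter-modality squared distance
    selected: np.ndarray  # edge positions of the columns
    x_spectral_norm: float = None  # cached ||X||_2 for the step size


def build_design(
    functional_features: np.ndarray,
    structural_m: np.ndarray,
    labels: np.ndarray,
    selected: np.ndarray,
) -> FusionDesign:
    """Column-align both modalities to L and compute the distance weights.

    Structural columns are affinely rescaled to the matching functional
    column's mean and SD so the distance compares shapes, not units.
    """
    selected = np.asarray(selected, dtype=int)
    x = np.asarray(functional_features, dtype=float)[:, selected]
    m = np.asarray(structural_m, dtype=float)[:, selected]
    mu_x, sd_x = x.mean(axis=0), x.std(axis=0)
    mu_m, sd_m = m.mean(axis=0), m.std(axis=0)
    scale = np.where(sd_m > 0, sd_x / np.where(sd_m > 0, sd_m, 1.0), 0.0)
    m = (m - mu_m) * scale + mu_x
    d_weights = ((x - m) ** 2).sum(axis=0)
    return FusionDesign(
        x=x,
        m=m,
        y=np.asarray(labels, dtype=float),
        d_weights=d_weights,
        selected=selected,
        x_spectral_norm=float(np.linalg.norm(x, 2)),
    )


# ---------------------------------------------------------------------------
# k-support norm


def _sorted_abs(w: np.ndarray) -> np.ndarray:
    return np.sort(np.abs(np.asarray(w, dtype=float)))[::-1]


def ksupport_split(sorted_abs_w: np.ndarray, k: int) -> int:
    """The unique split index r of the k-support norm.

    r in {0, ..., k-1} satisfies (1-based sorted magnitudes, |w|_0 = +inf)

        |w|_{k-r-1}  >  (1/(r+1)) * sum_{i=k-r}^{d} |w|_i  >=  |w|_{k-r}.
    """
    p = np.asarray(sorted_abs_w, dtype=float)
    d = p.size
    if not 1 <= k <= d:
        raise ValueError("k must be in [1, d]")
    tail = np.concatenate([np.cumsum(p[::-1])[::-1], [0.0]])  # tail[i] = sum p[i:]
    # exact ties at the boundary make several r norm-equivalent; the relaxed
    # left comparison returns the smallest of them
    tol = 1e-12 * max(1.0, float(p[0]))
    for r in range(k):
        left = p[k - r - 2] if k - r - 1 >= 1 else np.inf
        mean_tail = tail[k - r - 1] / (r + 1)
        right = p[k - r - 1]
        if left > mean_tail - tol and mean_tail >= right - tol:
            return r
    return k - 1


def ksupport_norm(w: np.ndarray, k: int) -> float:
    """The k-support norm: l1 at k = 1, Euclidean at k = d."""
    p = _sorted_abs(w)
    if p.size == 0 or p[0] == 0.0:
        return 0.0
    r = ksupport_split(p, k)
    head = p[: k - r - 1]
    tail_sum = p[k - r - 1 :].sum()
    return float(np.sqrt((head**2).sum() + tail_sum**2 / (r + 1)))


def ksupport_dual_norm(u: np.ndarray, k: int) -> float:
    """Dual norm: Euclidean norm of the k largest magnitudes."""
    p = _sorted_abs(u)
    return float(np.sqrt((p[:k] ** 2).sum()))


def _project_topk_sorted(p: np.ndarray, theta: float, k: int, hint=None):
    """Project sorted nonnegative p onto {u: sum of k largest u_i^2 <= theta^2}.

    Returns (u_sorted, partition) with partition = (l, m): indices [0, l)
    scaled by a common factor, [l, m) clamped at t, [m, d) untouched;
    l = m = -1 encodes the pure-scaling solution (empty tie block).
    """
    d = p.size
    th2 = theta * theta
    cp = np.concatenate([[0.0], np.cumsum(p)])
    cp2 = np.concatenate([[0.0], np.cumsum(p * p)])
    if cp2[k] <= th2:
        return p.copy(), None
    tol = 1e-9 * (p[0] + theta)

    def try_scale_only():
        s = theta / np.sqrt(cp2[k])
        if k == d or s * p[k - 1] >= p[k] - tol:
            u = p.copy()
            u[:k] *= s
            # keep sorted: scaled block may dip below p[k] within tol only
            return u, (-1, -1)
        return None

    if hint is not None:
        got = _try_partition(p, cp, cp2, th2, k, tol, hint)
        if got is not None:
            return got
        if hint == (-1, -1):
            pass
    res = try_scale_only()
    if res is not None:
        return res

    ls = np.repeat(np.arange(k), d - k + 1)
    ms = np.tile(np.arange(k, d + 1), k)
    A = cp[ms] - cp[ls]
    B = cp2[ls]
    K = (k - ls).astype(float)
    q = (ms - ls).astype(float)
    p_mm1 = p[ms - 1]
    p_m = np.where(ms < d, p[np.minimum(ms, d - 1)], -np.inf)

    def f_eval(t):
        denom = A + (K - q) * t
        s = np.where(denom > 0, K * t / np.where(denom > 0, denom, 1.0), np.inf)
        return B * s * s + K * t * t - th2, s

    # the clamp level t lies in (p[m], p[m-1]] and below A/q (mu >= 0);
    # two bracket evaluations prune the candidate list before bisection
    ok = A > 0
    cap = np.where(ok, A / np.maximum(q, 1.0), 0.0)
    t_lo = np.maximum(np.where(ms < d, p_m, 0.0), 0.0)
    t_hi = np.minimum(p_mm1, cap)
    ok &= t_hi >= t_lo
    f_lo, _ = f_eval(t_lo)
    f_hi, _ = f_eval(t_hi)
    ok &= (f_lo <= tol) & (f_hi >= -tol)
    keep = np.flatnonzero(ok)
    if keep.size == 0:
        raise RuntimeError("k-support projection: no consistent KKT partition found")
    ls, ms, A, B, K, q = ls[keep], ms[keep], A[keep], B[keep], K[keep], q[keep]
    p_mm1, p_m = p_mm1[keep], p_m[keep]
    t_lo, t_hi = t_lo[keep], t_hi[keep]

    def f_sub(t):
        denom = A + (K - q) * t
        s = np.where(denom > 0, K * t / np.where(denom > 0, denom, 1.0), np.inf)
        return B * s * s + K * t * t - th2, s

    lo, hi_b = t_lo.copy(), t_hi.copy()
    for _ in range(38):
        t = 0.5 * (lo + hi_b)
        f, _ = f_sub(t)
        up = f > 0
        hi_b = np.where(up, t, hi_b)
        lo = np.where(up, lo, t)
    t = 0.5 * (lo + hi_b)
    _, s = f_sub(t)

    p_lm1 = np.where(ls > 0, p[np.maximum(ls - 1, 0)], np.inf)
    p_l = p[np.minimum(ls, d - 1)]
    valid = (
        (s * p_lm1 > t - tol)
        & (s * p_l <= t + tol)
        & (p_mm1 >= t - tol)
        & (p_m < t + tol)
    )
    if not np.any(valid):
        raise RuntimeError("k-support projection: no consistent KKT partition found")

    # squared distance to p, from the cumulative sums
    tie2 = cp2[ms] - cp2[ls]
    dist = (1.0 - s) ** 2 * B + tie2 - 2.0 * t * A + q * t * t
    dist = np.where(valid, dist, np.inf)
    best = int(np.argmin(dist))
    l, m = int(ls[best]), int(ms[best])
    u = p.copy()
    u[:l] *= s[best]
    u[l:m] = t[best]
    return u, (l, m)


def _try_partition(p, cp, cp2, th2, k, tol, part):
    """Re-validate a cached partition; scalar bisection for its t."""
    d = p.size
    if part == (-1, -1):
        Bk = cp2[k]
        if Bk <= th2:
            return None
        s = np.sqrt(th2 / Bk)
        if k == d or s * p[k - 1] >= p[k] - tol:
            u = p.copy()
            u[:k] *= s
            return u, (-1, -1)
        return None
    l, m = part
    if not (0 <= l < k <= m <= d):
        return None
    A = cp[m] - cp[l]
    B = cp2[l]
    K, q = float(k - l), float(m - l)
    if A <= 0:
        return None
    lo, hi = 0.0, A / q
    if B + K * hi * hi - th2 < -tol:
        return None
    for _ in range(60):
        t = 0.5 * (lo + hi)
        denom = A + (K - q) * t
        s = K * t / denom if denom > 0 else np.inf
        if B * s * s + K * t * t - th2 > 0:
            hi = t
        else:
            lo = t
    t = 0.5 * (lo + hi)
    denom = A + (K - q) * t
    s = K * t / denom if denom > 0 else np.inf
    p_lm1 = p[l - 1] if l > 0 else np.inf
    p_l = p[min(l, d - 1)]
    p_m = p[m] if m < d else -np.inf
    if (s * p_lm1 > t - tol) and (s * p_l <= t + tol) and (p[m - 1] >= t - tol) and (
        p_m < t + tol
    ):
        u = p.copy()
        u[:l] *= s
        u[l:m] = t
        return u, (l, m)
    return None


def ksupport_prox(v: np.ndarray, threshold: float, k: int, _hint=None, _return_hint=False):
    """prox of ``threshold * ||.||_ksp``: v minus the projection of v onto
    the dual-norm ball of radius ``threshold``.

    Preserves the sign pattern and magnitude ordering of v; entries whose
    magnitude falls below the partition's clamp level are zeroed.
    """
    v = np.asarray(v, dtype=float)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if threshold == 0 or v.size == 0 or not np.any(v):
        return (v.copy(), None) if _return_hint else v.copy()
    order = np.argsort(-np.abs(v), kind="stable")
    p = np.abs(v)[order]
    u_sorted, part = _project_topk_sorted(p, threshold, k, hint=_hint)
    u = np.empty_like(p)
    u[order] = u_sorted
    w = v - np.sign(v) * u
    return (w, part) if _return_hint else w


def _prox_squared(v: np.ndarray, c: float, k: int) -> np.ndarray:
    """prox of ``c * ||.||_ksp**2`` by scalar fixed point on the equivalent
    first-power threshold tau = 2 c * ||w*||_ksp."""
    if c == 0 or not np.any(v):
        return np.asarray(v, dtype=float).copy()
    hi = 2.0 * c * ksupport_norm(v, k)
    lo = 0.0
    for _ in range(60):
        tau = 0.5 * (lo + hi)
        w = ksupport_prox(v, tau, k)
        if tau > 2.0 * c * ksupport_norm(w, k):
            hi = tau
        else:
            lo = tau
    return ksupport_prox(v, 0.5 * (lo + hi), k)


# ---------------------------------------------------------------------------
# fusion fit


@dataclass
class FusionFit:
    w: np.ndarray
    lambda1: float
    lambda2: float
    k: int
    r: int  # active split index of the norm at the solution
    objective_trace: np.ndarray
    converged: bool
    n_iter: int


def default_k(n_features: int) -> int:
    """Default support parameter: 10% of the selected features."""
    return max(1, int(round(0.1 * n_features)))


def fit_fusion(
    design: FusionDesign,
    lambda1: float,
    lambda2: float,
    k: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    seed: int | None = None,
    penalty: str = "ksupport",
    intermodality: str = "weighted",
    w0: np.ndarray | None = None,
) -> FusionFit:
    """Monotone accelerated proximal-gradient fit of

        ||X w - y||^2 + lambda1 * Omega_k(w) + lambda2 * sum_j d_j w_j^2

    (``intermodality="constant"`` reproduces the W-free reading of the
    distance term: the quadratic is dropped and the constant
    ``sum_i ||x_i - m_i||^2`` is added to the reported objective; it has no
    effect on the solution.)
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be non-negative")
    if penalty not in ("ksupport", "ksupport_squared"):
        raise ValueError(f"unknown penalty {penalty!r}")
    if intermodality not in ("weighted", "constant"):
        raise ValueError(f"unknown intermodality mode {intermodality!r}")

    x, y = design.x, design.y
    n, d = x.shape
    if not np.all(np.isfinite(x)):
        raise ValueError("design contains non-finite values")
    if k is None:
        k = default_k(d)
    if not 1 <= k <= d:
        raise ValueError("k must be in [1, n_features]")

    if intermodality == "weighted":
        dw = design.d_weights
        const = 0.0
    else:
        dw = np.zeros(d)
        const = float(lambda2 * design.d_weights.sum())

    x_norm = (
        design.x_spectral_norm
        if design.x_spectral_norm is not None
        else float(np.linalg.norm(x, 2))
    )
    lip = 2.0 * (x_norm**2 + lambda2 * (dw.max() if d else 0.0))
    step = 1.0 / max(lip, 1e-12)

    def smooth_grad(w):
        return 2.0 * (x.T @ (x @ w - y)) + 2.0 * lambda2 * dw * w

    def objective(w):
        resid = x @ w - y
        pen = ksupport_norm(w, k)
        if penalty == "ksupport_squared":
            pen = pen * pen
        return float(resid @ resid + lambda1 * pen + lambda2 * (dw * w * w).sum() + const)

    def prox(v, hint):
        if penalty == "ksupport":
            return ksupport_prox(v, lambda1 * step, k, _hint=hint, _return_hint=True)
        return _prox_squared(v, lambda1 * step, k), None

    w = np.zeros(d) if w0 is None else np.asarray(w0, dtype=float).copy()
    w_prev = w.copy()
    yk = w.copy()
    t_mom = 1.0
    hint = None
    trace = [objective(w)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z, hint = prox(yk - step * smooth_grad(yk), hint)
        f_z = objective(z)
        # monotone variant: never accept an objective increase
        if f_z <= trace[-1]:
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
            yk = z + (t_mom / t_next) * (z - z) + ((t_mom - 1.0) / t_next) * (z - w)
            w_prev, w = w, z
            t_mom = t_next
            trace.append(f_z)
            if abs(trace[-2] - trace[-1]) <= tol * max(1.0, abs(trace[-1])):
                converged = True
                break
        else:
            # overshoot: keep the iterate, restart the momentum
            trace.append(trace[-1])
            if np.array_equal(yk, w):
                converged = True  # fixed point of the prox-gradient map
                break
            yk = w.copy()
            t_mom = 1.0
    if not converged:
        warnings.warn(
            f"fusion fit did not converge in {max_iter} iterations", stacklevel=2
        )
    r = ksupport_split(_sorted_abs(w), k) if np.any(w) else 0
    return FusionFit(
        w=w,
        lambda1=float(lambda1),
        lambda2=float(lambda2),
        k=int(k),
        r=int(r),
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
    )
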