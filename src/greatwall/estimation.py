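"""Shared statistical primitives for stages 2-3.

Beta posterior tails for the early-efficacy screen, matrix (bimonotone)
isotonic regression for toxicity smoothing under the partial order, the
row-wise MTD contour, mean-utility estimation, and the Kaplan-Meier
product-limit estimator at a landmark time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc


@dataclass(frozen=True)
class UtilityScores:
    """Desirability scores for the four joint (efficacy, toxicity) outcomes.

    ``u10`` (response, no DLT) is anchored at 100 and ``u01`` (no response,
    DLT) at 0; clinicians choose the two intermediate scores.  With the
    default scores the alternating sum -u10 + u11 + u00 - u01 vanishes, so
    the true mean utility depends on the marginals only — any association
    between the two binary outcomes cancels.
    """

    u10: float = 100.0
    u11: float = 60.0
    u00: float = 40.0
    u01: float = 0.0

    def __post_init__(self):
        for name in ("u10", "u11", "u00", "u01"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"utility score {name}={v} outside [0, 100]")


def beta_tail(x: int, l: int, threshold: float) -> float:
    """Posterior probability that a rate exceeds ``threshold``.

    Beta(1, 1) prior with ``x`` successes in ``l`` trials gives a
    Beta(1 + x, 1 + l - x) posterior; returns its upper-tail mass beyond
    ``threshold``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    if x < 0 or x > l:
        raise ValueError("need 0 <= x <= l")
    return float(1.0 - betainc(1.0 + x, 1.0 + l - x, threshold))


def _pava(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted least-squares projection onto non-decreasing sequences.

    Pool-adjacent-violators with a block stack; O(n).
    """
    n = y.shape[0]
    means = np.empty(n)
    weights = np.empty(n)
    sizes = np.empty(n, dtype=np.intp)
    top = -1
    for i in range(n):
        top += 1
        means[top] = y[i]
        weights[top] = w[i]
        sizes[top] = 1
        while top > 0 and means[top - 1] > means[top]:
            tw = weights[top - 1] + weights[top]
            if tw > 0:
                means[top - 1] = (
                    weights[top - 1] * means[top - 1] + weights[top] * means[top]
                ) / tw
            weights[top - 1] = tw
            sizes[top - 1] += sizes[top]
            top -= 1
    out = np.empty(n)
    pos = 0
    for b in range(top + 1):
        out[pos : pos + sizes[b]] = means[b]
        pos += sizes[b]
    return out


def isotonic_2d(
    values: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    tol: float = 1e-8,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Weighted projection onto matrices non-decreasing in both indices.

    Cells with NaN values or zero weight are masked (untried combinations)
    and returned as NaN; monotonicity is enforced between unmasked cells
    within each row and each column.  Uses Dykstra's alternating-projection
    scheme, cycling row-wise and column-wise PAVA with correction terms,
    which converges to the exact projection onto the intersection of the two
    monotone cones.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a 2-D matrix")
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != values.shape:
        raise ValueError("weights shape mismatch")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")

    mask = np.isfinite(values) & (weights > 0)
    if not mask.any():
        raise ValueError("all cells are masked")

    J, K = values.shape
    x = np.where(mask, values, 0.0)
    p_row = np.zeros_like(x)  # Dykstra increments for the row cone
    p_col = np.zeros_like(x)
    rows = [np.flatnonzero(mask[j]) for j in range(J)]
    cols = [np.flatnonzero(mask[:, k]) for k in range(K)]

    for _ in range(max_sweeps):
        x_prev = x
        y = x + p_row
        z = y.copy()
        for j, idx in enumerate(rows):
            if idx.size > 1:
                z[j, idx] = _pava(y[j, idx], weights[j, idx])
        p_row = y - z
        y = z + p_col
        x = y.copy()
        for k, idx in enumerate(cols):
            if idx.size > 1:
                x[idx, k] = _pava(y[idx, k], weights[idx, k])
        p_col = y - x
        if np.max(np.abs(x - x_prev)) < tol:
            break

    out = np.where(mask, x, np.nan)
    return out


def posterior_mean_toxicity(
    x_tox: np.ndarray, n: np.ndarray, prior: tuple[float, float] | None = (0.05, 0.05)
) -> np.ndarray:
    """Per-cell toxicity point estimates fed into the isotonic smoother.

    Posterior means under a diffuse Beta(a, b) prior (``prior=None`` gives
    raw proportions); untried cells (n == 0) come back NaN.
    """
    x_tox = np.asarray(x_tox, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        if prior is None:
            est = x_tox / n
        else:
            a, b = prior
            est = (x_tox + a) / (n + a + b)
    return np.where(n > 0, est, np.nan)


def mtd_contour(
    iso: np.ndarray,
    phi_t: float,
    rho: float | None = None,
    excluded: np.ndarray | None = None,
) -> np.ndarray:
    """Row-wise MTD column indices from isotonized toxicity estimates.

    For each row the MTD is the tried, non-excessive combination whose
    smoothed toxicity estimate is closest to the target ``phi_t``.  A
    combination is excessive when flagged in ``excluded`` (stage-1 walls
    and/or a safety-elimination rule chosen by the caller) or, when ``rho``
    is given, when its isotonized estimate reaches the over-toxic rate
    rho * phi_t.  Rows with no eligible combination get -1.

    Isotonic pooling routinely produces exactly tied estimates within a
    row; ties in |estimate - phi_t| follow the usual MTD-selection
    convention for isotonic estimates: take the higher dose when the tied
    estimates sit below the target (still room to escalate) and the lower
    dose when they sit above it.

    Parameters use 0-based array indexing; callers translate to 1-based
    dose labels.
    """
    iso = np.asarray(iso, dtype=float)
    J, K = iso.shape
    eligible = np.isfinite(iso)
    if rho is not None:
        eligible &= iso < rho * phi_t
    if excluded is not None:
        eligible &= ~np.asarray(excluded, dtype=bool)
    out = np.full(J, -1, dtype=int)
    dist = np.abs(iso - phi_t)
    for j in range(J):
        idx = np.flatnonzero(eligible[j])
        if not idx.size:
            continue
        d_min = dist[j, idx].min()
        tied = idx[dist[j, idx] <= d_min + 1e-12]
        below = tied[iso[j, tied] < phi_t]
        out[j] = below[-1] if below.size else tied[0]
    return out


def safety_elimination_mask(
    x_tox: np.ndarray,
    n: np.ndarray,
    phi_t: float,
    cutoff: float = 0.95,
    min_n: int = 3,
) -> np.ndarray:
    """Doses whose DLT rate is credibly above the target (BOIN-style rule).

    Eliminates dose d when Pr(p_T,d > phi_t | data) > ``cutoff`` under a
    Beta(1, 1) prior on the raw counts, requiring at least ``min_n``
    treated patients before the rule can fire.
    """
    x_tox = np.asarray(x_tox, dtype=float)
    n = np.asarray(n, dtype=float)
    tail = 1.0 - betainc(1.0 + x_tox, 1.0 + n - x_tox, phi_t)
    return (n >= min_n) & (tail > cutoff)


def below_contour_mask(mtd: np.ndarray, tried_mask: np.ndarray) -> np.ndarray:
    """Tried combinations at or below the row-wise MTD contour (AT,2)."""
    J, K = tried_mask.shape
    cols = np.arange(K)
    allowed = cols[None, :] <= np.asarray(mtd)[:, None]
    return np.asarray(tried_mask, dtype=bool) & allowed


def mean_utility_estimate(
    x10: float, x11: float, x00: float, x01: float, scores: UtilityScores
) -> float:
    """Plug-in mean utility from joint outcome counts, normalized to [0, 1]."""
    l = x10 + x11 + x00 + x01
    if l <= 0:
        raise ValueError("no data at dose")
    return (
        scores.u10 * x10 + scores.u11 * x11 + scores.u00 * x00 + scores.u01 * x01
    ) / (100.0 * l)


def true_mean_utility(p_eff, p_tox, scores: UtilityScores = UtilityScores()):
    """Population mean utility from marginal response/DLT probabilities.

    Exact whenever the alternating score sum vanishes (true for the
    defaults), since the joint-association term then cancels; otherwise it
    is the independence-model value.
    """
    p_eff = np.asarray(p_eff, dtype=float)
    p_tox = np.asarray(p_tox, dtype=float)
    val = (
        scores.u10 * p_eff * (1.0 - p_tox)
        + scores.u11 * p_eff * p_tox
        + scores.u00 * (1.0 - p_eff) * (1.0 - p_tox)
        + scores.u01 * (1.0 - p_eff) * p_tox
    ) / 100.0
    return val if val.ndim else float(val)


def km_survival(times, events, t0: float) -> float:
    """Kaplan-Meier product-limit estimate of S(t0).

    ``events`` flags progression/death (1) versus censoring (0).  Survival
    beyond the landmark means time strictly greater than ``t0``; with no
    censoring before ``t0`` the estimate reduces to the empirical fraction
    of times exceeding ``t0``.  Ties between events and censorings at the
    same time follow the usual convention (events first).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival sample")
    if times.shape != events.shape:
        raise ValueError("times/events length mismatch")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")

    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    surv = 1.0
    n_at_risk = t.size
    i = 0
    while i < t.size and t[i] <= t0:
        ti = t[i]
        d = 0
        c = 0
        while i < t.size and t[i] == ti:
            if e[i]:
                d += 1
            else:
                c += 1
            i += 1
        if d:
            surv *= 1.0 - d / n_at_risk
        n_at_risk -= d + c
    return float(surv)
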