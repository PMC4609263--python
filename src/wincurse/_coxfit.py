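"""Newton solvers for the Cox partial likelihood (Breslow ties).

Two engines:

``univariate_many``
    Fits the single-parameter model h(t|g) = h0(t) exp(beta * g) for every SNP
    column of a dosage matrix simultaneously. Because dosages take only the
    values {0, 1, 2}, the risk-set sums S0, S1, S2 at each event time are
    affine in (e^beta, e^(2 beta)) with coefficients that are beta-independent
    genotype counts; those counts are precomputed once per dataset, so each
    Newton iteration costs O(D * m) for D events and m SNPs. This is what
    makes full-panel bootstrap rescans affordable.

``general_fit``
    A conventional dense Newton for one SNP plus covariates (Breslow or Efron
    ties), used for covariate-adjusted fits and as the engine behind
    ``fit_cox``.

Both maximise the stratified partial likelihood when a stratum label is given
(independent risk sets per stratum, shared beta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MAX_ABS_BETA = 15.0  # beyond this we declare monotone likelihood / divergence


@dataclass
class _Precomp:
    """Per-stratum event-row genotype counts for the univariate engine."""

    e1: np.ndarray  # (D, m) count of g==1 in risk set at each event
    e2: np.ndarray  # (D, m) count of g==2 in risk set
    nrisk: np.ndarray  # (D,) risk-set size
    sum_g: np.ndarray  # (m,) sum of dosages over event rows
    n_events: int


def _precompute(
    G: np.ndarray, time: np.ndarray, event: np.ndarray, dtype=np.float64
) -> _Precomp:
    n, m = G.shape
    order = np.argsort(time, kind="stable")
    ts = time[order]
    ev = event[order]
    Gs = G[order]
    # first index of each tie group: the Breslow risk set for an event at t is
    # every individual with time >= t, i.e. the suffix starting at the first
    # occurrence of t in the sorted array
    first = np.searchsorted(ts, ts, side="left")
    is1 = (Gs == 1).astype(np.int32)
    is2 = (Gs == 2).astype(np.int32)
    c1 = np.cumsum(is1[::-1], axis=0)[::-1]
    c2 = np.cumsum(is2[::-1], axis=0)[::-1]
    eidx = np.nonzero(ev)[0]
    start = first[eidx]
    return _Precomp(
        e1=c1[start].astype(dtype),
        e2=c2[start].astype(dtype),
        nrisk=(n - start).astype(dtype),
        sum_g=Gs[eidx].sum(axis=0).astype(np.float64),
        n_events=int(eidx.size),
    )


def _precompute_strata(
    G: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    stratum: np.ndarray | None,
    dtype=np.float64,
) -> _Precomp:
    if stratum is None:
        return _precompute(G, time, event, dtype)
    parts = []
    for lab in sorted(set(stratum)):
        rows = stratum == lab
        if not event[rows].any():
            continue  # a stratum without events contributes nothing
        parts.append(_precompute(G[rows], time[rows], event[rows], dtype))
    if not parts:
        raise ValueError("no events in any stratum")
    return _Precomp(
        e1=np.concatenate([p.e1 for p in parts]),
        e2=np.concatenate([p.e2 for p in parts]),
        nrisk=np.concatenate([p.nrisk for p in parts]),
        sum_g=np.sum([p.sum_g for p in parts], axis=0),
        n_events=sum(p.n_events for p in parts),
    )


def _score_info_loglik(beta: np.ndarray, pc: _Precomp, cols=slice(None)):
    dt = pc.e1.dtype
    bb = np.asarray(beta, dtype=dt)
    c1 = np.exp(bb)
    c2 = np.exp(2.0 * bb)
    e1 = pc.e1[:, cols]
    e2 = pc.e2[:, cols]
    s0 = pc.nrisk[:, None] + e1 * (c1 - 1.0) + e2 * (c2 - 1.0)
    s1 = e1 * c1 + 2.0 * e2 * c2
    s2 = e1 * c1 + 4.0 * e2 * c2
    r1 = s1 / s0
    u = pc.sum_g[cols] - r1.sum(axis=0, dtype=np.float64)
    info = (s2 / s0 - r1 * r1).sum(axis=0, dtype=np.float64)
    ll = beta * pc.sum_g[cols] - np.log(s0).sum(axis=0, dtype=np.float64)
    return u, info, ll


def _loglik(beta: np.ndarray, pc: _Precomp, cols) -> np.ndarray:
    c1 = np.exp(beta)
    c2 = np.exp(2.0 * beta)
    e1 = pc.e1[:, cols]
    e2 = pc.e2[:, cols]
    s0 = pc.nrisk[:, None] + e1 * (c1 - 1.0) + e2 * (c2 - 1.0)
    return beta * pc.sum_g[cols] - np.log(s0).sum(axis=0)


def univariate_many(
    G: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    stratum: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
    beta0: np.ndarray | None = None,
    precision: str = "exact",
):
    """Fit a univariable Cox model per column of ``G`` (no missing values).

    Returns (beta, se, loglik, converged, n_events). Columns with no dosage
    variation get beta=NaN and converged=False; columns whose estimate runs
    away (|beta| > 15, monotone likelihood) are flagged non-converged.
    ``beta0`` warm-starts the Newton iteration (bootstrap rescans start at the
    original-sample estimates); converged columns leave the working set, so
    each iteration touches only the columns still moving. ``precision="fast"``
    accumulates risk-set sums in single precision (estimates accurate to
    ~1e-5, used for bootstrap replicate rescans where only selection and
    replicate-level estimates are needed).
    """
    G = np.ascontiguousarray(G)
    n, m = G.shape
    event = np.asarray(event, dtype=bool)
    if precision == "fast":
        dtype = np.float32
        tol = max(tol, 2e-6)
        ll_slack = 1e-3
    else:
        dtype = np.float64
        ll_slack = 1e-12
    pc = _precompute_strata(G, time, event, stratum, dtype)

    if beta0 is None:
        beta = np.zeros(m)
    else:
        beta = np.where(np.isfinite(beta0), beta0, 0.0).astype(float).copy()
        np.clip(beta, -MAX_ABS_BETA, MAX_ABS_BETA, out=beta)
    degenerate = G.max(axis=0) == G.min(axis=0)
    u, info, ll = _score_info_loglik(beta, pc)
    active = ~degenerate & (info > 1e-10)
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        work = active & ~converged
        if not work.any():
            break
        idx = np.nonzero(work)[0]
        step = u[idx] / np.maximum(info[idx], 1e-12)
        np.clip(step, -2.0, 2.0, out=step)
        # columns whose pending Newton step is already negligible are at the
        # optimum: mark converged without another risk-set pass
        tiny = np.abs(step) < tol * (np.abs(beta[idx]) + 1.0)
        converged[idx[tiny]] = True
        idx = idx[~tiny]
        if idx.size == 0:
            continue
        step = step[~tiny]
        newbeta = beta[idx] + step
        # one fused pass gives the next iteration's derivatives and the
        # loglik used for the step-halving acceptance check
        u2, i2, l2 = _score_info_loglik(newbeta, pc, idx)
        ll_old = ll[idx]
        for _half in range(30):
            worse = (l2 < ll_old - ll_slack) & np.isfinite(ll_old)
            if not worse.any():
                break
            step[worse] *= 0.5
            newbeta[worse] = beta[idx[worse]] + step[worse]
            ub, ib, lb = _score_info_loglik(newbeta[worse], pc, idx[worse])
            u2[worse], i2[worse], l2[worse] = ub, ib, lb
        beta[idx] = newbeta
        u[idx], info[idx], ll[idx] = u2, i2, l2
        done = np.abs(step) < tol * (np.abs(newbeta) + 1.0)
        converged[idx[done]] = True

    runaway = np.abs(beta) > MAX_ABS_BETA
    converged &= ~runaway & (info > 0)
    se = np.full(m, np.nan)
    ok = converged
    se[ok] = 1.0 / np.sqrt(info[ok])
    beta = np.where(degenerate, np.nan, beta)
    return beta, se, ll, converged, pc.n_events


def univariate_with_missing(
    G: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    stratum: np.ndarray | None = None,
    **kw,
):
    """As ``univariate_many`` but per-SNP complete-case for NaN dosages."""
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    has_na = np.isnan(G).any(axis=0)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    ll = np.full(m, np.nan)
    conv = np.zeros(m, dtype=bool)
    clean = ~has_na
    n_events = int(np.asarray(event, bool).sum())
    beta0 = kw.pop("beta0", None)
    if clean.any():
        b, s, l, c, n_events = univariate_many(
            G[:, clean].astype(np.int8), time, event, stratum,
            beta0=None if beta0 is None else beta0[clean], **kw,
        )
        beta[clean], se[clean], ll[clean], conv[clean] = b, s, l, c
    for j in np.nonzero(has_na)[0]:
        rows = ~np.isnan(G[:, j])
        if not np.asarray(event, bool)[rows].any():
            continue
        sub_strat = None if stratum is None else stratum[rows]
        b, s, l, c, _ = univariate_many(
            G[rows, j : j + 1].astype(np.int8), time[rows],
            np.asarray(event, bool)[rows], sub_strat, **kw,
        )
        beta[j], se[j], ll[j], conv[j] = b[0], s[0], l[0], c[0]
    return beta, se, ll, conv, n_events


# ---------------------------------------------------------------------------
# General dense Newton (SNP + covariates), Breslow or Efron ties
# ---------------------------------------------------------------------------


def _stratum_groups(time, event, stratum):
    if stratum is None:
        yield np.arange(time.shape[0])
    else:
        for lab in sorted(set(stratum)):
            yield np.nonzero(stratum == lab)[0]


def _general_derivs(beta, X, time, event, stratum, ties):
    n, d = X.shape
    ll = 0.0
    U = np.zeros(d)
    I = np.zeros((d, d))
    eta = X @ beta
    np.clip(eta, -500, 500, out=eta)
    w = np.exp(eta)
    for rows in _stratum_groups(time, event, stratum):
        t = time[rows]
        ev = event[rows]
        if not ev.any():
            continue
        order = rows[np.argsort(t, kind="stable")]
        ts = time[order]
        evs = event[order]
        Xs = X[order]
        ws = w[order]
        wx = ws[:, None] * Xs
        wxx = wx[:, :, None] * Xs[:, None, :]
        cs0 = np.cumsum(ws[::-1])[::-1]
        cs1 = np.cumsum(wx[::-1], axis=0)[::-1]
        cs2 = np.cumsum(wxx[::-1], axis=0)[::-1]
        first = np.searchsorted(ts, ts, side="left")
        # iterate over tie groups of events
        eidx = np.nonzero(evs)[0]
        k = 0
        while k < eidx.size:
            i0 = eidx[k]
            g0 = first[i0]
            # events tied at this time
            tied = eidx[(k <= np.arange(eidx.size)) & (first[eidx] == g0)]
            dsz = tied.size
            s0 = cs0[g0]
            s1 = cs1[g0]
            s2 = cs2[g0]
            if ties == "breslow":
                for i in tied:
                    ll += eta[order[i]] - np.log(s0)
                    U += Xs[i] - s1 / s0
                    I += s2 / s0 - np.outer(s1, s1) / s0**2
            else:  # efron
                d0 = ws[tied].sum()
                d1 = wx[tied].sum(axis=0)
                d2 = wxx[tied].sum(axis=0)
                for l, i in enumerate(tied):
                    f = l / dsz
                    a0 = s0 - f * d0
                    a1 = s1 - f * d1
                    a2 = s2 - f * d2
                    ll += eta[order[i]] - np.log(a0)
                    U += Xs[i] - a1 / a0
                    I += a2 / a0 - np.outer(a1, a1) / a0**2
            k += dsz
    return ll, U, I


def general_fit(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    stratum: np.ndarray | None = None,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
):
    """Newton fit of the Cox model with linear predictor X @ beta.

    Returns (beta, cov, loglik, converged). Raises ValueError for zero events
    or a constant column in X.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method: {ties!r}")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    event = np.asarray(event, dtype=bool)
    if not event.any():
        raise ValueError("no events in data")
    if np.any(X.max(axis=0) == X.min(axis=0)):
        raise ValueError("constant (degenerate) covariate column")
    d = X.shape[1]
    beta = np.zeros(d)
    ll, U, I = _general_derivs(beta, X, time, event, stratum, ties)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            break
        nrm = np.abs(step).max()
        if nrm > 2.0:
            step *= 2.0 / nrm
        newbeta = beta + step
        ll_new, U_new, I_new = _general_derivs(newbeta, X, time, event, stratum, ties)
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 30:
            step *= 0.5
            newbeta = beta + step
            ll_new, U_new, I_new = _general_derivs(newbeta, X, time, event, stratum, ties)
            halvings += 1
        beta, ll, U, I = newbeta, ll_new, U_new, I_new
        if np.abs(step).max() < tol * (np.abs(beta).max() + 1.0):
            converged = True
            break
    if np.abs(beta).max() > MAX_ABS_BETA:
        converged = False
    try:
        cov = np.linalg.inv(I)
    except np.linalg.LinAlgError:
        cov = np.full((d, d), np.nan)
        converged = False
    return beta, cov, ll, converged
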