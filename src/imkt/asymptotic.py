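"""Asymptotic MKT: fit alpha(x) across frequency classes, extrapolate to x=1.

Weakly deleterious variants depress alpha estimates most strongly in the
low-frequency classes; polarization errors contaminate the highest ones.
The asymptotic MKT computes alpha per derived-allele-frequency class x,

    alpha(x) = 1 - (Ds/Dn) * (Pn(x)/Ps(x)),

trims an x interval (default [0, 0.9]) and fits

    alpha(x) ~ a + b * exp(-c * x)

by least squares across a grid of restarts (the exponential surface is
multimodal). The bias-corrected estimate is the fitted value at x = 1,
``a + b*exp(-c)``. When no exponential restart converges — or when an
ordinary linear fit ``a + b*x`` outright beats the exponential, which the
exponential family can approach only in the c->0 limit — the linear model
is reported instead (asymptote ``a + b``).

The 95% CI is a parametric bootstrap: per-bin Pn and Ps counts are redrawn
Poisson around their observed values, the trajectory is refit per replicate,
and the 2.5/97.5 percentiles of the replicate asymptotes are reported. This
is one reasonable construction among several; see the methods note.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .types import (
    AlphaTrajectory,
    AsymptoticFit,
    DafTable,
    DivergenceSummary,
    ValidationError,
)

DEFAULT_X_INTERVAL = (0.0, 0.9)
DEFAULT_N_BOOT = 1000

_C_RESTARTS = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0)
_C_BOUNDS = (1e-9, 100.0)


def alpha_trajectory(
    daf: DafTable, div: DivergenceSummary, cumulative: bool = False
) -> AlphaTrajectory:
    """Per-frequency-class alpha(x) values.

    By default each bin uses its own counts (non-cumulative). With
    ``cumulative=True``, bin x uses all variants at frequency <= x. Bins
    where the synonymous count is zero are marked undefined, not dropped.
    """
    if div.dn == 0:
        raise ValidationError("no_selected_divergence: dn is 0")
    ratio = div.ds / div.dn
    points: list[tuple[float, float | None]] = []
    reasons: dict[float, str] = {}
    cum_pn = cum_ps = 0
    for b in daf.bins:
        pn, ps = b.pn, b.ps
        if cumulative:
            cum_pn += pn
            cum_ps += ps
            pn, ps = cum_pn, cum_ps
        if ps == 0:
            points.append((b.daf, None))
            reasons[b.daf] = "ps_zero"
        else:
            points.append((b.daf, 1.0 - ratio * pn / ps))
    return AlphaTrajectory(points=points, undefined_reasons=reasons)


def trim(
    traj: AlphaTrajectory, x_low: float = 0.0, x_high: float = 0.9
) -> AlphaTrajectory:
    """Restrict the trajectory to x_low <= x <= x_high (inclusive)."""
    if not (0.0 <= x_low < x_high <= 1.0):
        raise ValidationError(f"invalid trim interval [{x_low}, {x_high}]")
    points = [(x, a) for x, a in traj.points if x_low <= x <= x_high]
    kept = AlphaTrajectory(
        points=points,
        undefined_reasons={
            x: r for x, r in traj.undefined_reasons.items() if x_low <= x <= x_high
        },
    )
    if len(kept.defined_points) < 3:
        raise ValidationError(
            "insufficient_points: fewer than 3 defined trajectory points remain"
        )
    return kept


def _linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope/intercept for the linear fallback; returns (a, b) of a + b*x."""
    b, a = np.polyfit(x, y, 1)
    return float(a), float(b)


def _exp_model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, b, c = params
    return a + b * np.exp(-c * x)


def _exp_jac(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    _, b, c = params
    e = np.exp(-c * x)
    return np.column_stack([np.ones_like(x), e, -b * x * e])


def fit_asymptotic(
    traj: AlphaTrajectory, x_interval: tuple[float, float] = DEFAULT_X_INTERVAL
) -> AsymptoticFit:
    """Fit the exponential model to the (already trimmed) trajectory.

    Unit weights. Restarts over a grid of decay rates c, with a and b seeded
    from the linear fit conditional on each c (a linear subproblem); the
    restart with the smallest residual sum of squares wins. The straight-line
    fit is reported instead when it has strictly smaller SSE than every
    exponential candidate, or when no exponential restart converges.
    """
    defined = traj.defined_points
    if len(defined) < 3:
        raise ValidationError("insufficient_points: need >= 3 defined points to fit")
    x = np.array([p[0] for p in defined])
    y = np.array([p[1] for p in defined])
    notes: list[str] = []

    a_lin, b_lin = _linear_fit(x, y)

    best = None
    for c0 in _C_RESTARTS:
        # conditional-on-c linear solve for (a, b) gives the restart point
        e = np.exp(-c0 * x)
        design = np.column_stack([np.ones_like(x), e])
        (a0, b0), *_ = np.linalg.lstsq(design, y, rcond=None)
        try:
            sol = least_squares(
                lambda p: _exp_model(p, x) - y,
                x0=[a0, b0, c0],
                jac=lambda p: _exp_jac(p, x),
                bounds=([-np.inf, -np.inf, _C_BOUNDS[0]], [np.inf, np.inf, _C_BOUNDS[1]]),
                xtol=1e-8,
                ftol=1e-8,
                gtol=1e-8,
                max_nfev=120,
            )
        except Exception:
            continue
        # status 0 means the evaluation cap was hit; the candidate is still a
        # valid point in parameter space and competes on SSE like the others
        if sol.status < 0 or not np.all(np.isfinite(sol.x)):
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol.x)

    sse_lin = float(np.sum((a_lin + b_lin * x - y) ** 2))
    # the straight line is only the c->0 limit of the exponential family, so
    # it can genuinely fit better; prefer it when it does (ties go to the
    # exponential model)
    if best is not None and best[0] <= sse_lin:
        a, b, c = (float(v) for v in best[1])
        asymptote = a + b * np.exp(-c)
        model, cc = "exponential", c
        converged = True
    else:
        if not np.all(np.isfinite([a_lin, b_lin])):
            raise ValidationError("fit_failed: degenerate trajectory")
        a, b, cc = a_lin, b_lin, None
        asymptote = a + b
        model = "linear"
        converged = True
        notes.append("linear_fallback")

    if asymptote > 1.0:
        asymptote = 1.0
        notes.append("asymptote_capped")

    return AsymptoticFit(
        model=model,
        a=a,
        b=b,
        c=cc,
        alpha_asymptote=float(asymptote),
        ci_low=None,
        ci_high=None,
        x_interval=x_interval,
        converged=converged,
        notes=notes,
    )


def asymptote_ci(
    fit: AsymptoticFit,
    daf: DafTable,
    div: DivergenceSummary,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    cumulative: bool = False,
) -> tuple[float, float]:
    """Percentile 95% CI by parametric Poisson bootstrap of the bin counts.

    Each replicate redraws every bin's Pn and Ps from Poisson distributions
    centred on the observed counts, rebuilds and re-trims the trajectory and
    refits; replicates that fail to fit are dropped and counted. The fit is
    updated in place with the interval and diagnostic notes.
    """
    if not fit.converged:
        raise ValidationError("cannot bootstrap a non-converged fit")
    if n_boot == 0:
        fit.ci_low = fit.ci_high = fit.alpha_asymptote
        fit.notes.append("no_ci")
        return (fit.ci_low, fit.ci_high)

    x_low, x_high = fit.x_interval
    pn_obs = np.array([b.pn for b in daf.bins])
    ps_obs = np.array([b.ps for b in daf.bins])
    asymptotes = []
    n_failed = 0
    for rep in range(n_boot):
        rng = np.random.default_rng([seed, rep])
        pn_rep = rng.poisson(pn_obs)
        ps_rep = rng.poisson(ps_obs)
        rep_daf = DafTable(
            n_sample=daf.n_sample,
            bins=[
                (b.daf, int(pn_rep[i]), int(ps_rep[i]))
                for i, b in enumerate(daf.bins)
            ],
        )
        try:
            traj = alpha_trajectory(rep_daf, div, cumulative=cumulative)
            traj = trim(traj, x_low, x_high)
            rep_fit = fit_asymptotic(traj, (x_low, x_high))
        except ValidationError:
            n_failed += 1
            continue
        asymptotes.append(rep_fit.alpha_asymptote)

    if n_failed > 0.5 * n_boot or not asymptotes:
        fit.notes.append("ci_flagged")
    if asymptotes:
        lo, hi = np.percentile(asymptotes, [2.5, 97.5])
        fit.ci_low, fit.ci_high = float(lo), float(hi)
    else:
        fit.ci_low = fit.ci_high = fit.alpha_asymptote
    if n_failed:
        fit.notes.append(f"ci_failed_replicates:{n_failed}")
    return (fit.ci_low, fit.ci_high)


def amkt(
    daf: DafTable,
    div: DivergenceSummary,
    x_low: float = DEFAULT_X_INTERVAL[0],
    x_high: float = DEFAULT_X_INTERVAL[1],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    cumulative: bool = False,
) -> AsymptoticFit:
    """Convenience wrapper: trajectory -> trim -> fit -> bootstrap CI."""
    traj = alpha_trajectory(daf, div, cumulative=cumulative)
    traj = trim(traj, x_low, x_high)
    fit = fit_asymptotic(traj, (x_low, x_high))
    asymptote_ci(fit, daf, div, n_boot=n_boot, seed=seed, cumulative=cumulative)
    return fit
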