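"""Maximum-likelihood fits of the branch, episodic-mixture and
selection-intensity codon models, with likelihood ratio tests.

All fits optimize kappa, a single global branch-length scale multiplier,
and the model's omega parameters by bounded quasi-Newton search on
transformed coordinates (log for positive parameters, logits for simplex
weights and bounded ratios).  Alternative models are additionally
started from the null fit's optimum, which guarantees the nesting
inequality up to optimizer tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ..tree import PhyloTree
from .model import CodonAlignment, CodonLikelihood, CodonModelParams, MixtureParams

__all__ = [
    "FitResult",
    "LRTResult",
    "fit_branch_model",
    "lrt",
    "fit_busted_like",
    "fit_relax_like",
]

_LNL_TOL = 1e-4  # negative 2*dlnL beyond this is an optimizer failure


@dataclass
class FitResult:
    lnL: float
    params: CodonModelParams
    n_free: int
    converged: bool
    n_restarts_used: int


@dataclass
class LRTResult:
    statistic: float
    df: int | str
    p: float


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def _minimize(objective, starts, bounds, tol=1e-8):
    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol, "gtol": 1e-6, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best, n_used


def _require_foreground(tree: PhyloTree) -> None:
    if not tree.foreground_nodes():
        raise ValueError("tree has no foreground branches marked")


def fit_branch_model(
    tree: PhyloTree,
    alignment: CodonAlignment,
    two_ratio: bool = False,
    seed: int = 0,
    n_restarts: int = 3,
    init: CodonModelParams | None = None,
) -> FitResult:
    """Fit the one-ratio (single omega) or two-ratio (separate
    foreground/background omega) branch model.

    *init* seeds the first start (used to start the two-ratio fit from
    the one-ratio optimum).  Additional restarts jitter the start,
    deterministically under *seed*.
    """
    if two_ratio:
        _require_foreground(tree)
    engine = CodonLikelihood(tree, alignment)
    rng = np.random.default_rng(seed)

    if init is not None:
        k0 = np.log(init.kappa)
        s0 = np.log(init.branch_scale)
        wb = init.omega_by_class.get("background", 0.3)
        wf = init.omega_by_class.get("foreground", wb)
        w0 = np.log(max(wb, 1e-6))
        w1 = np.log(max(wf, 1e-6))
    else:
        k0, s0, w0, w1 = np.log(2.0), 0.0, np.log(0.3), np.log(0.3)

    if two_ratio:
        base = np.array([k0, w0, w1, s0])
        bounds = [(-3, 4), (-12, 4.5), (-12, 4.5), (-5, 5)]

        def objective(x):
            return -engine.loglik_branch(np.exp(x[0]), np.exp(x[3]),
                                         np.exp(x[1]), np.exp(x[2]))
    else:
        base = np.array([k0, w0, s0])
        bounds = [(-3, 4), (-12, 4.5), (-5, 5)]

        def objective(x):
            return -engine.loglik_branch(np.exp(x[0]), np.exp(x[2]), np.exp(x[1]))

    starts = [base] + [base + rng.normal(0, 0.5, size=base.size)
                       for _ in range(max(0, n_restarts - 1))]
    best, n_used = _minimize(objective, starts, bounds)

    x = best.x
    if two_ratio:
        omega = {"background": float(np.exp(x[1])), "foreground": float(np.exp(x[2]))}
        scale = float(np.exp(x[3]))
    else:
        omega = {"background": float(np.exp(x[1])), "foreground": float(np.exp(x[1]))}
        scale = float(np.exp(x[2]))
    params = CodonModelParams(
        kappa=float(np.exp(x[0])),
        codon_frequencies=engine.pi,
        omega_by_class=omega,
        branch_scale=scale,
    )
    if not best.success:
        warnings.warn("branch-model fit did not report convergence", stacklevel=2)
    return FitResult(-float(best.fun), params, 4 if two_ratio else 3,
                     bool(best.success), n_used)


def lrt(null: FitResult, alt: FitResult, df: int | str) -> LRTResult:
    """Likelihood ratio test of nested fits.

    *df* is a chi-square degrees-of-freedom integer, or the string
    ``"mixture01"`` for the 50:50 chi2_0/chi2_1 boundary null used by the
    episodic test.
    """
    delta = 2.0 * (alt.lnL - null.lnL)
    if delta < -_LNL_TOL:
        raise ValueError(
            f"alternative lnL below null lnL (2dlnL={delta:.6g}): optimizer failure"
        )
    statistic = max(0.0, delta)
    if df == "mixture01":
        p = 0.5 * stats.chi2.sf(statistic, 1) + (0.5 if statistic <= 0.0 else 0.0)
    else:
        if not (isinstance(df, int) and df > 0):
            raise ValueError(f"bad df {df!r}")
        p = stats.chi2.sf(statistic, df) if statistic > 0 else 1.0
    return LRTResult(statistic, df, float(p))


# -- three-class mixtures ------------------------------------------------

def _mixture_from_vector(x, fg_omega3=None, k=None):
    """Decode [w2_logit, ratio_logit, log(w3-1), l1, l2] style coordinates."""
    omega2 = _sigmoid(x[0])
    omega1 = omega2 * _sigmoid(x[1])
    omega3 = 1.0 + np.exp(x[2])
    ws = np.exp(np.array([x[3], x[4], 0.0]))
    ws = ws / ws.sum()
    return omega1, omega2, omega3, tuple(ws)


def _busted_components(x):
    """3x3 product mixture: foreground and background classes are drawn
    independently per site, sharing the class weights."""
    omega1, omega2, omega3_bg, ws = _mixture_from_vector(x)
    omega3_fg = 1.0 + np.exp(x[5])
    bg = (omega1, omega2, omega3_bg)
    fg = (omega1, omega2, omega3_fg)
    comps = [(ws[i] * ws[j], bg[i], fg[j]) for i in range(3) for j in range(3)]
    return comps, bg, omega3_fg, ws


def fit_busted_like(
    tree: PhyloTree,
    alignment: CodonAlignment,
    seed: int = 0,
    n_restarts: int = 2,
) -> tuple[FitResult, FitResult, LRTResult]:
    """Episodic positive-selection test with three omega classes
    (omega1 <= omega2 <= 1 <= omega3), shared weights across partitions
    and a separate foreground omega3; the null pins foreground omega3 = 1.

    Returns (unconstrained, constrained, LRT); the LRT p-value uses the
    conservative 50:50 chi2_0/chi2_1 boundary mixture.
    """
    _require_foreground(tree)
    engine = CodonLikelihood(tree, alignment)
    rng = np.random.default_rng(seed)

    # shared head: [log kappa, log scale]; mixture: [x_w2, x_ratio, x_w3bg, l1, l2]
    head0 = np.array([np.log(2.0), 0.0])
    mix0 = np.array([_logit(0.5), _logit(0.5), np.log(0.5), 1.0, 0.5])
    bounds_head = [(-3, 4), (-5, 5)]
    bounds_mix = [(-12, 12), (-12, 12), (-14, 5), (-8, 8), (-8, 8)]

    def null_obj(z):
        comps, _, _, _ = _busted_components(np.concatenate([z[2:], [-30.0]]))
        return -engine.loglik_mixture(np.exp(z[0]), np.exp(z[1]), comps)

    starts = [np.concatenate([head0, mix0])]
    starts += [starts[0] + rng.normal(0, 0.4, size=7) for _ in range(max(0, n_restarts - 1))]
    best_null, used_null = _minimize(null_obj, starts, bounds_head + bounds_mix)

    def alt_obj(z):
        comps, _, _, _ = _busted_components(z[2:])
        return -engine.loglik_mixture(np.exp(z[0]), np.exp(z[1]), comps)

    alt_starts = [np.concatenate([best_null.x, [np.log(0.5)]]),
                  np.concatenate([best_null.x, [-10.0]])]
    alt_starts += [alt_starts[0] + rng.normal(0, 0.4, size=8)
                   for _ in range(max(0, n_restarts - 1))]
    best_alt, used_alt = _minimize(alt_obj, alt_starts,
                                   bounds_head + bounds_mix + [(-14, 5)])

    def pack(res, constrained: bool) -> FitResult:
        z = res.x
        if constrained:
            comps, bg, _, ws = _busted_components(np.concatenate([z[2:], [-30.0]]))
            fg3 = 1.0
        else:
            comps, bg, fg3, ws = _busted_components(z[2:])
        params = CodonModelParams(
            kappa=float(np.exp(z[0])),
            codon_frequencies=engine.pi,
            mixture=MixtureParams(tuple(float(w) for w in bg),
                                  tuple(float(w) for w in ws),
                                  foreground_omega3=float(fg3)),
            branch_scale=float(np.exp(z[1])),
        )
        return FitResult(-float(res.fun), params, 7 if constrained else 8,
                         bool(res.success), used_null if constrained else used_alt)

    constrained = pack(best_null, True)
    unconstrained = pack(best_alt, False)
    if unconstrained.lnL < constrained.lnL:  # numerical guard at the boundary
        unconstrained = FitResult(constrained.lnL, unconstrained.params,
                                  8, unconstrained.converged, used_alt)
    return unconstrained, constrained, lrt(constrained, unconstrained, "mixture01")


def fit_relax_like(
    tree: PhyloTree,
    alignment: CodonAlignment,
    seed: int = 0,
    n_restarts: int = 2,
    k_max: float = 50.0,
    return_fits: bool = False,
):
    """Selection-intensity test: foreground omegas are the background
    three-class omegas raised to the power k (null k = 1, alternative
    k free in [0, k_max]); LRT with one degree of freedom.

    Returns (k_hat, LRTResult), or with *return_fits* also the null and
    alternative :class:`FitResult`.
    """
    _require_foreground(tree)
    engine = CodonLikelihood(tree, alignment)
    rng = np.random.default_rng(seed)

    head0 = np.array([np.log(2.0), 0.0])
    mix0 = np.array([_logit(0.5), _logit(0.5), np.log(0.5), 1.0, 0.5])
    bounds_head = [(-3, 4), (-5, 5)]
    bounds_mix = [(-12, 12), (-12, 12), (-14, 5), (-8, 8), (-8, 8)]

    def components(z, k):
        omega1, omega2, omega3, ws = _mixture_from_vector(z)
        bg = (omega1, omega2, omega3)
        return [(ws[c], bg[c], float(np.power(bg[c], k))) for c in range(3)], bg, ws

    def null_obj(z):
        comps, _, _ = components(z[2:], 1.0)
        return -engine.loglik_mixture(np.exp(z[0]), np.exp(z[1]), comps)

    starts = [np.concatenate([head0, mix0])]
    starts += [starts[0] + rng.normal(0, 0.4, size=7) for _ in range(max(0, n_restarts - 1))]
    best_null, used_null = _minimize(null_obj, starts, bounds_head + bounds_mix)

    log_k_bounds = (np.log(1e-3), np.log(k_max))

    def alt_obj(z):
        comps, _, _ = components(z[2:-1], np.exp(z[-1]))
        return -engine.loglik_mixture(np.exp(z[0]), np.exp(z[1]), comps)

    alt_starts = [np.concatenate([best_null.x, [0.0]]),
                  np.concatenate([best_null.x, [np.log(0.3)]]),
                  np.concatenate([best_null.x, [np.log(3.0)]])]
    alt_starts += [alt_starts[0] + rng.normal(0, 0.4, size=8)
                   for _ in range(max(0, n_restarts - 1))]
    best_alt, used_alt = _minimize(alt_obj, alt_starts,
                                   bounds_head + bounds_mix + [log_k_bounds])

    def pack(res, k, n_free, used) -> FitResult:
        z = res.x
        comps, bg, ws = components(z[2:7], k)
        params = CodonModelParams(
            kappa=float(np.exp(z[0])),
            codon_frequencies=engine.pi,
            mixture=MixtureParams(tuple(float(w) for w in bg),
                                  tuple(float(w) for w in ws)),
            k=float(k),
            branch_scale=float(np.exp(z[1])),
        )
        return FitResult(-float(res.fun), params, n_free, bool(res.success), used)

    null_fit = pack(best_null, 1.0, 7, used_null)
    alt_fit = pack(best_alt, float(np.exp(best_alt.x[-1])), 8, used_alt)
    if alt_fit.lnL < null_fit.lnL:
        alt_fit = FitResult(null_fit.lnL, alt_fit.params, 8, alt_fit.converged, used_alt)
    result = lrt(null_fit, alt_fit, 1)
    k_hat = alt_fit.params.k
    if return_fits:
        return k_hat, result, null_fit, alt_fit
    return k_hat, result
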