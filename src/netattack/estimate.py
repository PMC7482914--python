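"""Method-of-moments estimation of the actor-oriented model.

Given a two-wave panel, the estimator chooses coefficients beta so that
chains simulated forward from wave 1 reproduce, in expectation, the
observed wave-2 effect totals (one moment per effect), and a rate so
that the expected number of tie differences from wave 1 matches the
observed wave1->wave2 Hamming distance.  The moment equations are solved
by Robbins-Monro stochastic approximation in the conventional three
phases:

Simulation is *conditional* on the observed amount of change: chains
run until their tie Hamming distance from wave 1 reaches the observed
wave1->wave2 distance.  The rate parameter thereby drops out of the
moment system (it would otherwise trade off against the outdegree
coefficient along a badly identified ridge) and is recovered afterwards
as the mean number of opportunities per buyer the conditional chains
consumed.

* **Phase 1** — estimate the moment sensitivity matrix D = dE[S]/dbeta
  by finite-difference simulation with common random numbers across
  perturbations;
* **Phase 2** — iterate ``beta <- beta - a_t D^+ (S_sim - S_obs)`` over
  subphases with shrinking gains ``a_t = gain0 / subphase``, where D^+
  is a damped inverse (weakly identified directions move slowly rather
  than amplifying simulation noise); the estimate is the average of the
  final subphase's iterates;
* **Phase 3** — simulate ``n3`` chains at the final estimate;
  convergence t-ratios are mean(S_sim - S_obs)/sd(S_sim), and standard
  errors come from the delta method D^-1 Cov(S_sim) D^-T with D
  re-estimated locally.  A rejected fit re-enters Phase 2 from the
  current estimate up to ``max_restarts`` times.

Convergence is declared when every |t-ratio| < ``t_tol`` (0.1, the
established convention for this estimator family).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, IllConditionedError, ValidationError
from .network import MarketNetwork, NetworkPanel
from .saom import (
    ChainState,
    EffectSet,
    ParameterVector,
    default_effects,
    simulate_chain_conditional,
    simulate_chain_state,
)

__all__ = ["RMConfig", "FitResult", "target_statistics", "rate_moment_fit", "robbins_monro_fit"]

_MIN_RATE = 1e-3
_MAX_RATE = 100.0


@dataclass(frozen=True)
class RMConfig:
    """Robbins-Monro phase configuration.

    n1: chains per perturbation in Phase 1; n2: number of Phase-2
    subphases (each of ``iters_per_subphase`` single-chain iterations);
    n3: Phase-3 chains; gain0: initial gain; fd_scale: finite-difference
    step scale (per-effect steps are fd_scale divided by the per-buyer
    magnitude of the target statistic); t_tol: convergence threshold on
    |t-ratios|; max_restarts: extra Phase-2/3 rounds allowed when the
    t-ratio check fails.
    """

    n1: int = 50
    n2: int = 4
    n3: int = 250
    iters_per_subphase: int = 80
    gain0: float = 0.2
    fd_scale: float = 1.0
    t_tol: float = 0.1
    max_restarts: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.n1, self.n2, self.n3, self.iters_per_subphase) <= 0:
            raise ContractError("phase sizes must be positive")


@dataclass(frozen=True)
class FitResult:
    """Estimated parameters with convergence diagnostics.

    ``converged`` holds iff max |t_ratio| < the configured t_tol.
    Vectors align with the effect set used for the fit.
    ``rate_t_ratio`` is 0 by construction under conditional simulation
    (the change moment is matched exactly by the stopping rule).
    """

    beta_hat: np.ndarray
    rate_hat: float
    std_errors: np.ndarray
    t_ratios: np.ndarray
    n_phase3: int
    converged: bool
    rate_t_ratio: float = float("nan")
    effect_names: tuple[str, ...] = ()

    def params(self) -> ParameterVector:
        return ParameterVector(beta=self.beta_hat, rate=self.rate_hat)


def _hamming(a: ChainState, b: ChainState) -> int:
    return int(np.sum(a.adj != b.adj))


def _check_panel(panel: NetworkPanel) -> tuple[MarketNetwork, MarketNetwork]:
    w1, w2 = panel.waves[0], panel.waves[-1]
    if w1.buyers != w2.buyers or w1.vendors != w2.vendors:
        raise ValidationError("actor sets differ between waves")
    return w1, w2


def target_statistics(panel: NetworkPanel, effects: EffectSet | None = None) -> np.ndarray:
    """Observed moment targets: wave-2 effect totals (sum over buyers of
    each effect statistic), then the wave1->wave2 tie Hamming distance
    (the rate target) as the final element.

    Covariates (vendor reputations) are held at their wave-1 values when
    evaluating the wave-2 totals, matching the forward simulation, which
    freezes covariates at the start of the period: a moment computed on
    updated covariates would be unreachable by any simulated chain.
    """
    if effects is None:
        effects = default_effects()
    w1, w2 = _check_panel(panel)
    s2 = ChainState(w2)
    s1 = ChainState(w1)
    s2.rep = s1.rep
    totals = [e.total(s2) for e in effects]
    return np.array(totals + [float(_hamming(s1, s2))])


def rate_moment_fit(
    panel: NetworkPanel,
    params: ParameterVector | None = None,
    effects: EffectSet | None = None,
    seed: int = 0,
    n_iter: int = 8,
    n_chains: int = 10,
) -> float:
    """Moment estimate of the opportunity rate.

    With ``params=None`` (the choice model at beta = 0) the moment
    equation has the closed form ``rate = H / (n_buyers * V/(V+1))``:
    each opportunity toggles some tie with probability V/(V+1), and
    reversions are ignored.  With a fitted choice model the rate is
    refined by simulation, multiplicatively matching the simulated to
    the observed Hamming distance.  Returns a minimal rate (1e-3) with a
    warning when the waves are identical.
    """
    w1, _ = _check_panel(panel)
    if effects is None:
        effects = default_effects()
    s1 = ChainState(w1)
    h_obs = float(target_statistics(panel, effects)[-1])
    n_b = len(w1.buyers)
    n_v = len(w1.vendors)
    if h_obs == 0:
        warnings.warn("identical waves: returning minimal rate", stacklevel=2)
        return _MIN_RATE
    if params is None:
        return float(h_obs / (n_b * (n_v / (n_v + 1))))
    rng = np.random.default_rng(seed)
    rate = max(h_obs / n_b, _MIN_RATE)
    for _ in range(n_iter):
        pv = ParameterVector(beta=params.beta, rate=rate)
        h_sim = np.mean(
            [_hamming(simulate_chain_state(s1, pv, effects, rng), s1) for _ in range(n_chains)]
        )
        rate = float(np.clip(rate * h_obs / max(h_sim, 1.0), _MIN_RATE, _MAX_RATE))
    return rate


def _beta_init(panel: NetworkPanel, effects: EffectSet) -> np.ndarray:
    """Start beta at zero except the outdegree coefficient, set so that
    tie creations and dissolutions balance at the observed wave-2 mean
    degree: under logit choice the relative weights are (V - d)e^b for
    creation and d e^{-b} for dissolution, giving b = ln(d/(V-d))/2."""
    beta = np.zeros(len(effects))
    w2 = panel.waves[-1]
    n_v = len(w2.vendors)
    md = w2.tie_count() / max(len(w2.buyers), 1)
    md = min(max(md, 0.05), n_v - 0.05)
    for k, name in enumerate(effects.names):
        if name == "outdegree":
            beta[k] = 0.5 * np.log(md / (n_v - md))
    return beta


def robbins_monro_fit(
    panel: NetworkPanel,
    effects: EffectSet | None = None,
    config: RMConfig | None = None,
) -> FitResult:
    """Fit (beta, rate) to a panel by stochastic approximation.

    Estimation is *conditional* on the observed amount of change: each
    simulated chain runs micro-steps until its tie Hamming distance from
    wave 1 reaches the observed wave1->wave2 distance.  This removes the
    rate from the moment system (it would otherwise trade off against
    the outdegree coefficient along a badly identified ridge); the rate
    is recovered afterwards as the mean number of opportunities per
    buyer the conditional chains used.

    Deterministic given ``config.seed``.  Non-convergence is reported
    through ``FitResult.converged``, not an exception; a numerically
    singular sensitivity matrix raises IllConditionedError naming the
    offending effect.
    """
    if effects is None:
        effects = default_effects()
    if config is None:
        config = RMConfig()
    k = len(effects)
    w1, _ = _check_panel(panel)
    s1 = ChainState(w1)
    n_b = len(s1.buyers)
    obs_all = target_statistics(panel, effects)
    obs, h_obs = obs_all[:k], int(obs_all[k])

    beta = _beta_init(panel, effects)

    # Per-effect parameter scale: coefficients live on the inverse scale
    # of their statistic's per-buyer magnitude.
    pscale = 1.0 / np.maximum(1.0, np.abs(obs) / n_b)

    def moments(b_vec: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, int]:
        end, steps = simulate_chain_conditional(s1, b_vec, effects, rng, h_obs)
        return np.array([e.total(end) for e in effects]), steps

    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(config.n1) & 0x7FFFFFFF

    def estimate_d(b_vec: np.ndarray, strict: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Finite-difference dE[moments]/dbeta with common random
        numbers across perturbations; also returns the (floored)
        base-batch moment SDs, the scale on which t-ratios are judged.

        With ``strict=True`` (the initial Phase-1 estimate) a singular
        scaled matrix raises IllConditionedError naming the offending
        effect; later re-estimates leave error handling to the caller,
        which can fall back on the previous matrix.
        """
        eps = config.fd_scale * pscale

        def batch(v: np.ndarray) -> np.ndarray:
            return np.array([moments(v, np.random.default_rng(int(sd)))[0] for sd in seeds])

        base = batch(b_vec)
        base_mean = base.mean(axis=0)
        d_mat = np.empty((k, k))
        for j in range(k):
            pert = b_vec.copy()
            pert[j] += eps[j]
            d_mat[:, j] = (batch(pert).mean(axis=0) - base_mean) / eps[j]
        # floor the SD at a small fraction of the moment scale: a moment
        # with near-deterministic simulated value must not dominate the
        # scaled system through a vanishing denominator
        msd = np.maximum(base.std(axis=0, ddof=1), 1e-3 * np.maximum(np.abs(obs), 1.0))
        if strict:
            # conditioning is judged in scaled units (moments in SD
            # units, parameters on their natural scale); the raw matrix
            # mixes units and its condition number is meaningless
            d_tilde = (d_mat / msd[:, None]) * pscale[None, :]
            col_norm = np.linalg.norm(d_tilde, axis=0)
            if np.any(col_norm < 1e-9):
                raise IllConditionedError(effects.names[int(np.argmin(col_norm))])
            if np.linalg.cond(d_tilde) > 1e10:
                # blame the effect contributing least independent variation
                r_diag = np.abs(np.diag(np.linalg.qr(d_tilde)[1]))
                raise IllConditionedError(effects.names[int(np.argmin(r_diag))])
        return d_mat, msd

    def damped_inverse(d_mat: np.ndarray, msd: np.ndarray, rcond: float = 0.05) -> np.ndarray:
        """Regularized inverse of D for Phase-2 steps.  Working with
        moments in SD units and parameters on their natural scale,
        directions with singular value below ``rcond * s_max`` are
        Tikhonov-damped, and near-null directions (below 0.005 * s_max)
        are cut entirely: along such a ridge the exact Newton direction
        is amplified simulation noise, and when a moment is genuinely
        unreachable even a damped step drifts the iterates at constant
        velocity forever.  Phase-3 standard errors use the full inverse
        so ridge uncertainty is reported, not hidden."""
        d_tilde = (d_mat / msd[:, None]) * pscale[None, :]
        u, s, vt = np.linalg.svd(d_tilde)
        lam = rcond * s[0]
        s_inv = np.where(s > 0.005 * s[0], s / (s**2 + lam**2), 0.0)
        return (pscale[:, None] * vt.T) @ (s_inv[:, None] * u.T) / msd[None, :]

    # Phase 1: sensitivity at the initial point.
    d_mat, msd = estimate_d(beta, strict=True)
    d_inv = damped_inverse(d_mat, msd)

    # Phase 2: shrinking-gain iteration; estimate = mean of last subphase.
    # Steps are capped element-wise and iterates boxed around the start
    # point so a noisy D^-1 cannot launch the chain into a saturated
    # regime it cannot leave.  The sensitivity matrix is refreshed at the
    # subphase midpoint (the Phase-1 linearization goes stale once beta
    # has moved).  If Phase 3 rejects the fit, Phase 2 restarts from the
    # current estimate with the locally re-estimated sensitivity, up to
    # ``max_restarts`` times.
    rng = np.random.default_rng(int(ss.generate_state(1)[0] & 0x7FFFFFFF) + 1)
    step_cap = 1.0 * pscale
    box_lo, box_hi = beta - 20.0 * pscale, beta + 20.0 * pscale
    refresh_at = config.n2 // 2 + 1
    last_betas: list[np.ndarray] = []
    for round_ix in range(config.max_restarts + 1):
        for sub in range(1, config.n2 + 1):
            a = config.gain0 / sub
            if sub == refresh_at and round_ix == 0:
                d_inv = damped_inverse(*estimate_d(beta))
            last_betas.clear()
            for _ in range(config.iters_per_subphase):
                dev = moments(beta, rng)[0] - obs
                step = a * (d_inv @ dev)
                beta = np.clip(beta - np.clip(step, -step_cap, step_cap), box_lo, box_hi)
                last_betas.append(beta.copy())
        beta_hat = np.mean(last_betas, axis=0)

        # Phase 3: diagnostics at the final estimate, with D re-estimated
        # locally (the running D is stale once beta has moved); pinv
        # tolerates a transiently degenerate local sensitivity.
        d_final, msd_final = estimate_d(beta_hat)
        d_inv_final = np.linalg.pinv(d_final)
        out = [moments(beta_hat, rng) for _ in range(config.n3)]
        sims = np.array([m for m, _ in out])
        steps_used = np.array([st for _, st in out], dtype=float)
        sd = sims.std(axis=0, ddof=1)
        mean_dev = sims.mean(axis=0) - obs
        # zero simulated variance with nonzero deviation is a failure, not a fit
        t_ratios = np.where(
            sd > 0, mean_dev / np.where(sd > 0, sd, 1.0), np.where(mean_dev == 0, 0.0, np.inf)
        )
        converged = bool(np.max(np.abs(t_ratios)) < config.t_tol)
        if converged:
            break
        beta = beta_hat
        d_inv = damped_inverse(d_final, msd_final)

    rate_hat = max(float(steps_used.mean()) / n_b, _MIN_RATE)
    cov = np.cov(sims, rowvar=False).reshape(k, k)
    theta_cov = d_inv_final @ cov @ d_inv_final.T
    std_errors = np.sqrt(np.maximum(np.diag(theta_cov), 0.0))
    return FitResult(
        beta_hat=beta_hat,
        rate_hat=rate_hat,
        std_errors=std_errors,
        t_ratios=t_ratios,
        rate_t_ratio=0.0,
        n_phase3=config.n3,
        converged=converged,
        effect_names=tuple(effects.names),
    )
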