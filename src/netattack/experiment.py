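"""Full attack experiment: control + 3 strategies x 4 levels x R replicates.

For each condition the attack operator is applied to the wave-1 network
and R forward chains are simulated at the fitted (fixed) parameters;
each end network yields one tidy outcome row.  Seeds derive
hierarchically (master -> condition -> replicate), so any condition can
be re-run independently and the full results table is bit-reproducible
from (config, master seed).

Summaries mirror the analysis stage: proportion-of-control ratios,
OLS treatment effects with conventional standard errors, and
level-by-metric correlations per strategy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .attacks import LEVELS, STRATEGIES, AttackSpec, apply_attack
from .errors import ContractError, UndefinedMetricError, ValidationError
from .estimate import FitResult, RMConfig, robbins_monro_fit
from .metrics import outcome_record
from .network import MarketNetwork
from .saom import (
    AlterReputationEffect,
    ChainState,
    EffectSet,
    OutdegreeEffect,
    ParameterVector,
    default_effects,
    simulate_chain_state,
)

__all__ = [
    "design_conditions",
    "run_experiment",
    "run_synthetic_experiment",
    "pipeline_effects",
    "proportion_of_control",
    "ols_treatment_effect",
    "level_metric_correlation",
]


def design_conditions() -> list[AttackSpec]:
    """The 13-cell design: one control plus 3 strategies x 4 levels."""
    specs = [AttackSpec("control", 0)]
    specs += [AttackSpec(s, l) for s in STRATEGIES for l in LEVELS]
    return specs


def _condition_seeds(master_seed: int, n_conditions: int, replicates: int) -> list[list[int]]:
    root = np.random.SeedSequence(master_seed)
    return [
        [int(s) for s in (child.generate_state(replicates) & 0x7FFFFFFF)]
        for child in root.spawn(n_conditions)
    ]


def run_experiment(
    start: MarketNetwork,
    params: ParameterVector,
    effects: EffectSet | None = None,
    replicates: int = 30,
    seed: int = 0,
    conditions: list[AttackSpec] | None = None,
    fit: FitResult | None = None,
    force: bool = False,
    resume: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the full design and return the results table.

    One row per simulated network, keyed by (strategy, level, replicate).
    If ``fit`` is supplied and not converged, refuses to run unless
    ``force=True``.  ``resume`` may hold a partial results table from an
    interrupted run; completed keys are kept and skipped.
    """
    if replicates < 1:
        raise ContractError("replicates must be >= 1")
    if fit is not None and not fit.converged and not force:
        raise ContractError("estimation did not converge; pass force=True to run anyway")
    if effects is None:
        effects = default_effects()
    if conditions is None:
        conditions = design_conditions()
    done: set[tuple[str, int, int]] = set()
    rows: list[dict] = []
    if resume is not None and len(resume):
        rows = resume.to_dict("records")
        done = {(r["strategy"], int(r["level"]), int(r["replicate"])) for r in rows}

    seeds = _condition_seeds(seed, len(conditions), replicates)
    for spec, cond_seeds in zip(conditions, seeds):
        attacked = apply_attack(start, spec)
        chain0 = ChainState(attacked)
        for rep in range(replicates):
            key = (spec.strategy, spec.level, rep)
            if key in done:
                continue
            rng = np.random.default_rng(cond_seeds[rep])
            end = simulate_chain_state(chain0, params, effects, rng).to_network()
            rec = outcome_record(end, condition=(spec.strategy, spec.level), replicate=rep)
            rows.append(rec.to_row())
    df = pd.DataFrame(rows)
    key_cols = ["strategy", "level", "replicate"]
    if df.duplicated(subset=key_cols).any():
        raise ValidationError("duplicate (strategy, level, replicate) keys in results")
    return df.sort_values(key_cols).reset_index(drop=True)


def pipeline_effects() -> EffectSet:
    """Effect specification used for the end-to-end synthetic pipeline:
    outdegree plus summed alter reputation.

    On reputation-reinforced synthetic markets the cumulative rating is
    proportional to sales, so summed-rating attachment and
    degree-popularity attachment are observationally equivalent; fitting
    both would split one mechanism across two collinear effects and can
    zero out the reputation coefficient entirely, making reputation
    (signal) attacks inert for reasons of identification rather than
    substance.  The pipeline therefore fits the reputation
    specification, the mechanism the generator embodies.
    """
    return EffectSet((OutdegreeEffect(), AlterReputationEffect()))


def run_synthetic_experiment(
    gen_cfg=None,
    replicates: int = 30,
    seed: int = 0,
    effects: EffectSet | None = None,
    fit_config: RMConfig | None = None,
    force: bool = False,
) -> tuple[pd.DataFrame, FitResult]:
    """End-to-end pipeline on a synthetic market: generate a two-wave
    panel, fit the choice model to it, then run the full attack design
    forward from wave 1 at the fitted parameters.

    Returns the results table and the fit.  Refuses to run the design on
    a non-converged fit unless ``force=True``.
    """
    from .synth import MarketGenConfig, generate_market

    if gen_cfg is None:
        gen_cfg = MarketGenConfig.desk_scale(seed=seed)
    if effects is None:
        effects = pipeline_effects()
    if fit_config is None:
        fit_config = RMConfig(seed=seed)
    panel = generate_market(gen_cfg)
    fit = robbins_monro_fit(panel, effects, fit_config)
    results = run_experiment(
        panel.waves[0],
        fit.params(),
        effects=effects,
        replicates=replicates,
        seed=seed,
        fit=fit,
        force=force,
    )
    return results, fit


def proportion_of_control(results: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Each treatment replicate's metric divided by the control-group
    mean of that metric (the effect-size scale of the boxplot figures)."""
    control = results[results["strategy"] == "control"][metric].dropna()
    if len(control) == 0:
        raise ContractError("no control rows in results")
    c_mean = control.mean()
    if c_mean == 0:
        raise UndefinedMetricError("control mean is zero")
    out = results[results["strategy"] != "control"].copy()
    out["ratio"] = out[metric] / c_mean
    return out[["strategy", "level", "replicate", "ratio"]].reset_index(drop=True)


def ols_treatment_effect(
    results: pd.DataFrame, metric: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Mean effect of each attack strategy on ``metric``, holding the
    level of intervention constant (linear in level, control = reference
    at level 0).  Ordinary least squares with conventional standard
    errors; returns one row per coefficient with a 95% CI."""
    import statsmodels.api as sm

    df = results.dropna(subset=[metric]).copy()
    if df["strategy"].nunique() < 2:
        raise ContractError("need at least two conditions for a treatment contrast")
    x_cols = {}
    for s in STRATEGIES:
        x_cols[f"strategy[{s}]"] = (df["strategy"] == s).astype(float)
    x_cols["level"] = df["level"].astype(float)
    x = pd.DataFrame(x_cols)
    x = sm.add_constant(x)
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ContractError("collinear design: cannot separate strategy and level effects")
    model = sm.OLS(df[metric].astype(float), x).fit()
    ci = model.conf_int(alpha=alpha)
    return pd.DataFrame(
        {
            "term": model.params.index,
            "coef": model.params.to_numpy(),
            "std_err": model.bse.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p_value": model.pvalues.to_numpy(),
        }
    ).reset_index(drop=True)


def level_metric_correlation(results: pd.DataFrame, strategy: str, metric: str) -> float:
    """Pearson correlation between intervention level and the metric
    across one strategy's replicates."""
    df = results[(results["strategy"] == strategy)].dropna(subset=[metric])
    if df["level"].nunique() < 2:
        raise ContractError("need at least two levels")
    y = df[metric].astype(float)
    if y.nunique() == 1:
        raise UndefinedMetricError("metric is constant across replicates")
    r, _ = stats.pearsonr(df["level"].astype(float), y)
    return float(r)
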