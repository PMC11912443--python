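"""Risk diagnostics for fixed planting strategies.

A fixed strategy evaluated across the CER ensemble yields a discrete value
distribution; this module summarizes it: quantile summaries, empirical CVaR
(expected shortfall), loss probabilities at a stated threshold, per-species
aggregate NPVs and their covariance, and tail cost percentiles.

Two quantile conventions coexist deliberately and are documented:

* the CVaR tail quantile (VaR) uses the lower discrete quantile, which makes
  the empirical CVaR agree exactly with the Rockafellar-Uryasev program on
  atoms (for equal weights and integer tail count k it is minus the mean of
  the k smallest values);
* descriptive percentiles (cost tails, summary tables) use ordinary linear
  interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _check_dist(values, probs):
    values = np.asarray(values, dtype=float)
    if probs is None:
        probs = np.full(len(values), 1.0 / len(values))
    probs = np.asarray(probs, dtype=float)
    if len(values) != len(probs) or len(values) == 0:
        raise ValueError("values and probs must be equal-length and non-empty")
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be non-negative and sum to 1")
    return values, probs


def empirical_cvar(values, probs=None, beta: float = 0.9) -> float:
    """CVaR_beta of a discrete value distribution (positive = worse).

    Returns minus the expectation of the worst (1-beta) tail.  Atoms that
    straddle the tail boundary are split fractionally, so the result equals
    the Rockafellar-Uryasev inner minimization for any (values, probs, beta).
    """
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie in (0, 1)")
    values, probs = _check_dist(values, probs)
    order = np.argsort(values, kind="stable")
    v = values[order]
    p = probs[order]
    tail = 1.0 - beta
    cum = np.cumsum(p)
    # lower quantile: first value with cumulative probability >= tail
    k = int(np.searchsorted(cum, tail - 1e-15))
    q = v[k]
    below = v < q
    mass_below = float(p[below].sum())
    expectation = float((p[below] * v[below]).sum()) + q * (tail - mass_below)
    return -expectation / tail


def ru_cvar(values, probs=None, beta: float = 0.9) -> tuple[float, float]:
    """Evaluate the RU formula min_alpha alpha + E[max(-V-alpha, 0)]/(1-beta).

    The minimum is attained at alpha equal to the beta-quantile of the loss
    -V; all candidate kinks are checked explicitly.  Returns ``(cvar,
    alpha_star)``.  Kept alongside :func:`empirical_cvar` as a direct
    transcription of the linearized program for cross-checking.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie in (0, 1)")
    values, probs = _check_dist(values, probs)
    losses = -values
    best = (np.inf, np.nan)
    for alpha in np.unique(losses):
        obj = alpha + float(probs @ np.maximum(losses - alpha, 0.0)) / (1.0 - beta)
        if obj < best[0]:
            best = (obj, float(alpha))
    return best


def loss_probability(values, probs=None, threshold: float = 0.0) -> float:
    """Probability of losses strictly exceeding ``threshold``: P(V < -threshold)."""
    if threshold <= 0:
        raise ValueError("threshold must be a positive loss level")
    values, probs = _check_dist(values, probs)
    return float(probs[values < -threshold].sum())


def tail_cost_percentile(per_cer_cost, q: float) -> float:
    """q-th percentile of the cost distribution, linear interpolation."""
    if not 0.0 < q <= 100.0:
        raise ValueError("q must lie in (0, 100]")
    return float(np.percentile(np.asarray(per_cer_cost, dtype=float), q))


@dataclass
class StrategyDistribution:
    """Summary of one strategy's value distribution across the ensemble."""

    label: str
    per_cer_value: np.ndarray            # (S,) V(x, z | s), GBP
    per_cer_cost: np.ndarray             # (S,) -V'(x, z | s), GBP
    beta: float
    cvar_beta: float
    minimum: float
    p25: float
    mean: float
    p75: float
    maximum: float
    species_group_values: dict           # species -> (S,) aggregate NPV

    def summary_row(self) -> dict:
        return {
            "label": self.label,
            "min": self.minimum,
            "p25": self.p25,
            "mean": self.mean,
            "p75": self.p75,
            "max": self.maximum,
            "cvar_beta": self.cvar_beta,
            "cost_mean": float(np.mean(self.per_cer_cost)),
            "cost_p95": tail_cost_percentile(self.per_cer_cost, 95.0),
        }


def species_group_values(strategy, valuation) -> dict:
    """Per-CER aggregate NPV of the planted cells of each species; {name: (S,)}."""
    groups = {}
    id_to_row = {int(c): i for i, c in enumerate(valuation.cell_ids)}
    for j, name in enumerate(valuation.species_names):
        rows = [
            id_to_row[int(cell)]
            for cell, sp in strategy.assignment.items()
            if sp == name
        ]
        if rows:
            groups[name] = valuation.R[rows, j, :].sum(axis=0)
        else:
            groups[name] = np.zeros(valuation.n_cer)
    return groups


def species_group_covariance(strategy, valuation, units: float = 1.0) -> pd.DataFrame:
    """Sample covariance (divisor S-1) of per-species aggregate NPVs across CERs.

    ``units`` rescales money first (e.g. 1e9 to report in GBP billions, giving
    a covariance in billions squared).
    """
    if not strategy.assignment:
        raise ValueError("strategy plants no cells")
    groups = species_group_values(strategy, valuation)
    names = list(groups)
    data = np.vstack([groups[name] / units for name in names])
    cov = np.cov(data, ddof=1)
    cov = np.atleast_2d(cov)
    return pd.DataFrame(cov, index=names, columns=names)


def evaluate_strategy(strategy, valuation, spec, label: str | None = None) -> StrategyDistribution:
    """Full cross-CER evaluation of a fixed strategy under ``spec.value_form``.

    Deterministic given its inputs; the cost series is always the cost lens
    ``-V'`` regardless of the value form used for the value series.
    """
    import dataclasses

    from .optimize import per_cer_values

    values = per_cer_values(strategy, valuation, spec)
    cost_spec = dataclasses.replace(spec, value_form="V_prime")
    cost = -per_cer_values(strategy, valuation, cost_spec)
    return StrategyDistribution(
        label=label or strategy.label,
        per_cer_value=values,
        per_cer_cost=cost,
        beta=spec.beta,
        cvar_beta=empirical_cvar(values, valuation.probs, spec.beta),
        minimum=float(np.min(values)),
        p25=float(np.percentile(values, 25)),
        mean=float(valuation.probs @ values),
        p75=float(np.percentile(values, 75)),
        maximum=float(np.max(values)),
        species_group_values=species_group_values(strategy, valuation),
    )


def cross_evaluation_matrix(strategies: dict, valuation, spec) -> pd.DataFrame:
    """Strategy x CER value matrix V(x_label, z | s); rows are labels."""
    from .optimize import per_cer_values

    data = {
        label: per_cer_values(strategy, valuation, spec)
        for label, strategy in strategies.items()
    }
    return pd.DataFrame(data, index=[int(c) for c in valuation.cer_ids]).T


def regret_table(value_matrix: pd.DataFrame) -> pd.DataFrame:
    """Regret of each stored strategy under each CER vs the best stored strategy."""
    best = value_matrix.max(axis=0)
    return best - value_matrix
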