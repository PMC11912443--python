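"""Brute-force oracles for the portfolio optimizers.

Enumerate every assignment of {none, conifer, broadleaf} to every cell (3^N
combinations), optimize the continuous technology level z per assignment in
closed form (linear objectives: an endpoint; CVaR: endpoints plus the kinks
where the CER value ordering changes), and return the best objective.  The
oracles never call the MILP machinery.
"""

import numpy as np

from treefolio.config import T_PER_MT
from treefolio.evaluate import empirical_cvar
from treefolio.optimize import value_coefficients


def assignment_space(valuation, spec):
    """All feasible-species assignments: per-CER values and mean storage.

    Returns ``(values, seq)``: values has shape (M, S); seq (M,) is the
    ensemble-mean tree sequestration in tCO2e/yr.
    """
    coef, zcoef = value_coefficients(valuation, spec)
    pairs = np.argwhere(valuation.retained)
    n, s_count = valuation.n_cells, valuation.n_cer
    cell_options = []
    for i in range(n):
        opts = [(np.zeros(s_count), 0.0)]
        for p, (ii, j) in enumerate(pairs):
            if ii == i:
                opts.append((coef[p], float(valuation.mean_m[i, j])))
        cell_options.append(opts)

    values = [np.zeros(s_count)]
    seq = [0.0]
    for opts in cell_options:
        new_values, new_seq = [], []
        for v, m in zip(values, seq):
            for ov, om in opts:
                new_values.append(v + ov)
                new_seq.append(m + om)
        values, seq = new_values, new_seq
    return np.asarray(values), np.asarray(seq), zcoef


def _z_range(seq_t, spec):
    """Feasible z interval in tCO2e/yr for one assignment, or None."""
    target_t = spec.target_q * T_PER_MT
    z_upper_t = spec.z_upper * T_PER_MT
    z_min = max(0.0, target_t - seq_t)
    if z_min > z_upper_t + 1e-9:
        return None
    return z_min, z_upper_t


def oracle_linear(valuation, spec, weights, space=None):
    """Best CER-weighted value over all assignments; z at its better endpoint."""
    values, seq, zcoef = space if space is not None else assignment_space(valuation, spec)
    zc = float(weights @ zcoef) / T_PER_MT       # value per tCO2e of z
    best = -np.inf
    for v, s in zip(values, seq):
        rng = _z_range(s, spec)
        if rng is None:
            continue
        z = rng[1] if zc > 0 else rng[0]
        best = max(best, float(weights @ v) + zc * z)
    if best == -np.inf:
        raise ValueError("no feasible assignment")
    return best


def oracle_cvar(valuation, spec, space=None):
    """Minimum CVaR over all assignments; z checked at endpoints and kinks."""
    values, seq, zcoef = space if space is not None else assignment_space(valuation, spec)
    zc_s = zcoef / T_PER_MT                      # per-CER slope of V in z_t
    s_count = valuation.n_cer
    best = np.inf
    for v, s in zip(values, seq):
        rng = _z_range(s, spec)
        if rng is None:
            continue
        z_lo, z_hi = rng
        cands = {z_lo, z_hi}
        for a in range(s_count):
            for b in range(a + 1, s_count):
                d = zc_s[a] - zc_s[b]
                if abs(d) > 1e-15:
                    z = (v[b] - v[a]) / d
                    if z_lo < z < z_hi:
                        cands.add(float(z))
        for z in cands:
            c = empirical_cvar(v + zc_s * z, valuation.probs, spec.beta)
            best = min(best, c)
    if best == np.inf:
        raise ValueError("no feasible assignment")
    return best


def oracle_scenario(valuation, spec, cer_index):
    weights = np.zeros(valuation.n_cer)
    weights[cer_index] = 1.0
    return oracle_linear(valuation, spec, weights)


def oracle_expected_value(valuation, spec):
    return oracle_linear(valuation, spec, valuation.probs)
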