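"""Exploration and learning statistics.

Occupancy distributions (normalized mean place-cell activity) and their
Kullback-Leibler divergences, first-reward distributions against their
theoretical laws, learning curves with normal-approximation confidence
intervals, time-to-reward, bounce rates, action-change angles, old-reward
visit fractions and weight maps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

SMOOTH_EPS_FRACTION = 1e-12  # of total mass, added to the second KL argument


def occupancy_from_activity(mean_rates, eps: float = 0.0) -> np.ndarray:
    """Normalize per-cell mean activity to a probability distribution."""
    r = np.asarray(mean_rates, dtype=float)
    if np.any(r < 0):
        raise ValueError("activities must be nonnegative")
    total = r.sum()
    if total <= 0 and eps == 0.0:
        raise ValueError("all-zero activity cannot be normalized")
    r = r + eps
    return r / r.sum()


def kl_divergence(p, q, smooth_q: float = SMOOTH_EPS_FRACTION) -> float:
    """KL(P||Q) in nats, with 0*ln(0) := 0.

    ``smooth_q`` adds that fraction of Q's total mass to every bin of Q (then
    renormalizes) so the divergence stays finite when Q has empty bins; it is
    small enough (1e-12 by default) not to visibly shift values.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("support mismatch")
    if smooth_q > 0:
        q = q + smooth_q * q.sum() / q.size
        q = q / q.sum()
    mask = p > 0
    if np.any(q[mask] <= 0):
        return np.inf
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def theoretical_first_reward_cdf(model: str, k, p: float = None, n: int = None):
    """CDF of the first-rewarded-trial index under the two theoretical laws.

    Random exploration: Geometric(p) — P(first <= k) = 1 - (1-p)^k.
    Perfect systematic exploration: discrete Uniform{1..n} — min(k/n, 1).
    """
    k = np.asarray(k, dtype=float)
    if model == "geometric":
        return 1.0 - (1.0 - p) ** k
    if model == "uniform":
        return np.minimum(k / n, 1.0)
    raise ValueError(f"unknown model {model!r}")


def first_reward_trials(table: pd.DataFrame, last_trial: int | None = None):
    """Per-simulation first successful trial index; censored sims get NaN."""
    firsts = {}
    for sim, g in table.groupby("sim"):
        succ = g.loc[g["success"], "trial"]
        firsts[sim] = float(succ.min()) if len(succ) else np.nan
    s = pd.Series(firsts).sort_index()
    if last_trial is not None:
        s = s.where(s <= last_trial)
    return s


def learning_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trial fraction of successful simulations with a 95% CI."""
    out = []
    for tr, g in table.groupby("trial"):
        m = len(g)
        p_hat = g["success"].mean()
        half = 1.96 * np.sqrt(p_hat * (1 - p_hat) / m)
        out.append(dict(trial=tr, success=p_hat, ci_lo=p_hat - half,
                        ci_hi=p_hat + half, n=m))
    return pd.DataFrame(out)


def time_to_reward(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trial mean t_rew over successful trials (absent where none)."""
    g = table[table["success"]].groupby("trial")["t_rew"]
    out = g.agg(["mean", "count", "sem"]).reset_index()
    out["ci_lo"] = out["mean"] - 1.96 * out["sem"].fillna(0.0)
    out["ci_hi"] = out["mean"] + 1.96 * out["sem"].fillna(0.0)
    return out


def bounce_rate(table: pd.DataFrame) -> pd.Series:
    """Bounces per second of trial, one value per sim x trial."""
    return table["bounces"] / table["duration"]


def five_number_summary(x) -> dict:
    """Boxplot summary: median, quartiles, whiskers at 1.5 IQR."""
    x = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo = x[x >= q1 - 1.5 * iqr].min()
    hi = x[x <= q3 + 1.5 * iqr].max()
    return dict(whisker_lo=lo, q1=q1, median=med, q3=q3, whisker_hi=hi)


def action_change_angles(actions: np.ndarray) -> np.ndarray:
    """Absolute angle between consecutive action vectors, wrapped to [0, pi].

    Steps where either action is the zero vector are skipped.
    """
    a = np.asarray(actions, dtype=float)
    if a.shape[0] < 2:
        return np.empty(0)
    v1, v2 = a[:-1], a[1:]
    n1 = np.hypot(v1[:, 0], v1[:, 1])
    n2 = np.hypot(v2[:, 0], v2[:, 1])
    ok = (n1 > 0) & (n2 > 0)
    cosang = np.einsum("ij,ij->i", v1[ok], v2[ok]) / (n1[ok] * n2[ok])
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def old_reward_visits(table: pd.DataFrame, phase2_start: int) -> pd.DataFrame:
    """Per-trial fraction of simulations entering the old reward zone."""
    t2 = table[table["trial"] >= phase2_start]
    out = []
    for tr, g in t2.groupby("trial"):
        m = len(g)
        p_hat = g["entered_old"].mean()
        half = 1.96 * np.sqrt(p_hat * (1 - p_hat) / m)
        out.append(dict(trial=tr, visiting=p_hat, ci_lo=p_hat - half,
                        ci_hi=p_hat + half, n=m))
    return pd.DataFrame(out)


def weight_map(w: np.ndarray, mask: np.ndarray, grid_shape: tuple[int, int]):
    """Mean outgoing weight per place cell, arranged on the grid.

    ``w`` and ``mask`` are (action x place); masked (frozen-zero) synapses
    are excluded from the mean.  Cells with no unmasked synapse map to NaN.
    """
    w = np.asarray(w, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    counts = mask.sum(axis=0)
    sums = np.where(mask, w, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return mean.reshape(grid_shape)


def chi_square_gof(counts, probs) -> tuple[float, float]:
    """Chi-square goodness of fit of observed counts against a discrete law."""
    counts = np.asarray(counts, dtype=float)
    expected = np.asarray(probs, dtype=float) * counts.sum()
    stat, p = stats.chisquare(counts, expected)
    return float(stat), float(p)
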