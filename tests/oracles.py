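"""Independent brute-force oracles used to validate the implementation.

These re-derive results directly from the written rules with the simplest
possible code (day-by-day checks, explicit subset enumeration) and stay
deliberately independent of the package's algorithms.
"""

from __future__ import annotations

import itertools
import statistics

import numpy as np
from scipy.special import logsumexp


def brute_force_flares(pains: list, definition: str) -> list[tuple[int, int]]:
    """Enumerate flare episodes as (onset_index, end_index) day indices.

    ``pains[i]`` is the pain score on day i or None when unobserved.  Applies
    the written rules literally: definition-specific onset condition, global
    above-median rule, run collapsing to the first qualifying day, end at the
    first return to the median or lower, removal of later onsets sharing an
    end day, and censoring (no episode without an observed return; flares
    never span unobserved days).
    """
    obs = {i: p for i, p in enumerate(pains) if p is not None}
    if not obs:
        return []
    med = statistics.median(obs.values())

    def onset_condition(i: int) -> bool:
        if definition == "aa":
            return obs[i] > med
        if definition == "at":
            return obs[i] > 3
        if definition == "mat":
            return (i - 1) in obs and obs[i - 1] in (1, 2, 3) and obs[i] in (4, 5)
        raise ValueError(definition)

    candidates = []
    for i in sorted(obs):
        if not onset_condition(i):
            continue
        if definition in ("aa", "at"):
            # collapse runs: only the first day of a run of condition-days
            if (i - 1) in obs and onset_condition(i - 1):
                continue
        if obs[i] > med:  # global above-median rule
            candidates.append(i)

    episodes = []
    used_ends = set()
    for i in candidates:
        end = None
        j = i + 1
        while j in obs:
            if obs[j] <= med:
                end = j
                break
            j += 1
        if end is None:
            continue  # censored: gap or series end before any return
        if end in used_ends:
            continue  # same-end dedup keeps the first onset
        used_ends.add(end)
        episodes.append((i, end))
    return episodes


def enumeration_loglik(x, y, beta) -> float:
    """Conditional log-likelihood by explicit enumeration of size-k subsets."""
    x = np.atleast_2d(np.asarray(x, float))
    y = np.asarray(y, int)
    beta = np.atleast_1d(np.asarray(beta, float))
    m = x.shape[0]
    k = int(y.sum())
    if k == 0 or k == m:
        return 0.0
    eta = x @ beta
    log_terms = [eta[list(s)].sum() for s in itertools.combinations(range(m), k)]
    return float(eta[y.astype(bool)].sum() - logsumexp(log_terms))


def numeric_score_info(x, y, beta, h=1e-5):
    """Score and observed information by central finite differences of the
    enumeration log-likelihood."""
    beta = np.atleast_1d(np.asarray(beta, float))
    p = beta.size
    score = np.zeros(p)
    info = np.zeros((p, p))
    for a in range(p):
        e = np.zeros(p)
        e[a] = h
        score[a] = (enumeration_loglik(x, y, beta + e) - enumeration_loglik(x, y, beta - e)) / (
            2 * h
        )
    for a in range(p):
        for b in range(p):
            ea = np.zeros(p)
            eb = np.zeros(p)
            ea[a] = h
            eb[b] = h
            f_pp = enumeration_loglik(x, y, beta + ea + eb)
            f_pm = enumeration_loglik(x, y, beta + ea - eb)
            f_mp = enumeration_loglik(x, y, beta - ea + eb)
            f_mm = enumeration_loglik(x, y, beta - ea - eb)
            info[a, b] = -(f_pp - f_pm - f_mp + f_mm) / (4 * h * h)
    return score, info


def random_pain_series(rng: np.random.Generator, max_len: int = 35, missing_max: float = 0.2):
    """A random 1-5 pain series with 0-20% missing days (None)."""
    n = int(rng.integers(5, max_len + 1))
    pains = rng.integers(1, 6, size=n).astype(object)
    miss_rate = rng.uniform(0, missing_max)
    mask = rng.uniform(size=n) < miss_rate
    out = [None if m else int(v) for v, m in zip(pains, mask)]
    if all(v is None for v in out):
        out[0] = int(rng.integers(1, 6))
    return out
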