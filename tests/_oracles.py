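"""Independent reference implementations used only to cross-check tests.

These deliberately avoid the package's code paths: the burst oracle is a
state-machine re-derivation of the interval algorithm, the ANOVA oracle
computes sums of squares with explicit loops and the sphericity epsilon
from eigenvalues, and the random-train generator exercises mixed ISI
scales.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def brute_force_bursts(
    times,
    max_isi_start=0.020,
    max_isi_end=0.100,
    min_ibi=0.100,
    min_duration=0.020,
    min_spikes=2,
):
    """State-machine burst detector: runs, then merge, then filter.

    Returns a list of (start, end, n_spikes) tuples.
    """
    t = list(map(float, times))
    n = len(t)
    # enumerate maximal candidate runs
    candidates = []
    state = "idle"
    first = None
    for i in range(n - 1):
        isi = t[i + 1] - t[i]
        if state == "idle":
            if isi <= max_isi_start:
                state, first = "in_burst", i
        else:
            if isi > max_isi_end:
                candidates.append((first, i))
                state, first = "idle", None
    if state == "in_burst":
        candidates.append((first, n - 1))

    # merge candidates separated by less than min_ibi
    merged = []
    for c in candidates:
        if merged and t[c[0]] - t[merged[-1][1]] < min_ibi:
            merged[-1] = (merged[-1][0], c[1])
        else:
            merged.append(c)

    # duration and count filters
    out = []
    for a, b in merged:
        if t[b] - t[a] >= min_duration and (b - a + 1) >= min_spikes:
            out.append((t[a], t[b], b - a + 1))
    return out


def random_spike_train(rng, max_spikes=50):
    """Random strictly increasing train with mixed ISI scales."""
    n = int(rng.integers(0, max_spikes + 1))
    if n == 0:
        return np.empty(0)
    # ISIs drawn from short (burst-like), medium, and long scales
    scales = rng.choice([0.005, 0.03, 0.08, 0.5], size=n, p=[0.35, 0.25, 0.2, 0.2])
    isis = rng.exponential(scales) + 1e-4
    return np.cumsum(isis)


def rm_anova_oracle(X):
    """Step-by-step repeated-measures ANOVA with eigenvalue-based epsilon."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    g = X.sum() / (n * k)
    ss_cond = sum(n * (X[:, j].mean() - g) ** 2 for j in range(k))
    ss_subj = sum(k * (X[i, :].mean() - g) ** 2 for i in range(n))
    ss_tot = sum((X[i, j] - g) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    S = np.cov(X, rowvar=False)
    C = np.eye(k) - 1.0 / k
    lam = np.linalg.eigvalsh(C @ S @ C)
    eps = lam.sum() ** 2 / (df1 * np.sum(lam**2))
    p = stats.f.sf(F, eps * df1, eps * df2)
    ms_err = ss_err / df2
    qs = {}
    means = X.mean(axis=0)
    for i, j in itertools.combinations(range(k), 2):
        q = abs(means[i] - means[j]) / np.sqrt(ms_err / n)
        qs[(i, j)] = (q, stats.studentized_range.sf(q, k, df2))
    return {"F": F, "eps": eps, "p": p, "ms_err": ms_err, "tukey": qs}


# fixed 6x4 worked example used across the statistics tests
FIXTURE_6x4 = np.array(
    [
        [0.52, 0.61, 0.88, 0.50],
        [0.30, 0.42, 0.65, 0.33],
        [0.77, 0.80, 1.05, 0.74],
        [0.45, 0.58, 0.70, 0.49],
        [0.60, 0.66, 0.95, 0.58],
        [0.38, 0.50, 0.72, 0.41],
    ]
)

# frozen values from rm_anova_oracle(FIXTURE_6x4)
FIXTURE_6x4_EXPECTED = {
    "F": 134.9807427785,
    "eps": 0.5102357227,
    "p": 1.72723772542e-06,
    "ms_err": 0.00100972222222,
    "q_01": 7.0662029556,
    "q_02": 24.7959485531,
    "q_03": 0.3854292521,
}


def match_spike_times(true_times, detected_times, tol=1e-3):
    """Greedy one-to-one matching; returns (n_matched, n_true, n_detected)."""
    tt = np.sort(np.asarray(true_times, dtype=float))
    dd = np.sort(np.asarray(detected_times, dtype=float))
    used = np.zeros(len(dd), dtype=bool)
    matched = 0
    for t in tt:
        i = np.searchsorted(dd, t)
        best, best_err = None, tol
        for j in (i - 1, i):
            if 0 <= j < len(dd) and not used[j] and abs(dd[j] - t) <= best_err:
                best, best_err = j, abs(dd[j] - t)
        if best is not None:
            used[best] = True
            matched += 1
    return matched, len(tt), len(dd)
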