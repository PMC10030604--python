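"""Statistical battery for gravity-phase comparisons.

Units are the "subjects" of a complete within-subject design: every unit
contributes one (log) rate per gravity phase.  The omnibus test is a
repeated-measures one-way ANOVA with the Geisser-Greenhouse sphericity
correction, followed by Tukey pairwise comparisons on the studentized
range.  Waveform-shape parameters are screened for outliers with the ROUT
procedure (robust location/scale + FDR on residuals) and compared with the
nonparametric Friedman test.  Density profiles visualize how the firing
rate distribution shifts between phases, and subgroup deltas follow the
k lowest / middle / highest firing units individually across a phase
change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RMAnovaResult",
    "PairwiseComparison",
    "DensityProfile",
    "rm_anova_gg",
    "tukey_pairwise",
    "friedman_test",
    "rout_outliers",
    "density_profile",
    "subgroup_deltas",
]


@dataclass(frozen=True)
class RMAnovaResult:
    """Repeated-measures one-way ANOVA with Geisser-Greenhouse correction."""

    F: float
    df_num: float  # k - 1 (uncorrected)
    df_den: float  # (k - 1)(n - 1) (uncorrected)
    epsilon_gg: float  # sphericity correction in [1/(k-1), 1]
    p_gg: float  # p-value at epsilon-scaled degrees of freedom
    p_uncorrected: float
    grand_mean: float
    condition_means: np.ndarray
    ms_error: float
    n_subjects: int
    n_conditions: int


@dataclass(frozen=True)
class PairwiseComparison:
    """One Tukey comparison between two conditions."""

    a: str
    b: str
    mean_diff: float  # mean(a) - mean(b)
    q: float  # studentized range statistic
    p_adj: float  # family-wise adjusted p


@dataclass(frozen=True)
class DensityProfile:
    """Kernel density of a rate distribution on a linear Hz grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def peak(self) -> float:
        """Location (Hz) of the global density maximum."""
        return float(self.grid[np.argmax(self.density)])

    def local_maxima(self) -> np.ndarray:
        """Locations (Hz) of interior local maxima of the density."""
        d = self.density
        idx = np.flatnonzero((d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])) + 1
        return self.grid[idx]


def _as_matrix(data) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D subjects x conditions matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("data contains missing or non-finite cells; the design must be complete")
    return x


def rm_anova_gg(data) -> RMAnovaResult:
    """Repeated-measures one-way ANOVA with the Geisser-Greenhouse correction.

    ``data`` is an ``n x k`` matrix (subjects x conditions; here, units x
    gravity phases, typically of log10 rates).  The classical
    within-subject decomposition gives ``F = MS_condition / MS_error`` on
    ``(k-1, (k-1)(n-1))`` degrees of freedom; the Geisser-Greenhouse
    epsilon — computed from the double-centered condition covariance as
    ``tr(S)^2 / ((k-1) tr(S^2))`` — rescales both degrees of freedom to
    protect the test when sphericity fails (e.g. when phases of very
    different lengths are compared).
    """
    x = _as_matrix(data)
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if k < 2:
        raise ValueError("need at least 2 conditions")

    grand = x.mean()
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = ms_cond / ms_err if ms_err > 0 else (0.0 if ms_cond == 0 else np.inf)

    # Geisser-Greenhouse epsilon from the double-centered covariance
    S = np.cov(x, rowvar=False)
    C = np.eye(k) - np.ones((k, k)) / k
    Sd = C @ S @ C
    tr = np.trace(Sd)
    tr2 = np.trace(Sd @ Sd)
    eps = 1.0 if tr2 <= 0 else float(tr**2 / (df1 * tr2))
    eps = float(np.clip(eps, 1.0 / df1, 1.0))

    p_unc = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    p_gg = float(stats.f.sf(F, eps * df1, eps * df2)) if np.isfinite(F) else 0.0
    if F == 0.0:
        p_unc = p_gg = 1.0
    return RMAnovaResult(
        F=float(F),
        df_num=float(df1),
        df_den=float(df2),
        epsilon_gg=eps,
        p_gg=p_gg,
        p_uncorrected=p_unc,
        grand_mean=float(grand),
        condition_means=cond_means,
        ms_error=float(ms_err),
        n_subjects=n,
        n_conditions=k,
    )


def tukey_pairwise(
    data, anova: RMAnovaResult, labels: list[str] | None = None
) -> list[PairwiseComparison]:
    """Tukey multiple comparisons on the repeated-measures error term.

    For each condition pair, ``q = |mean_i - mean_j| / sqrt(MS_error / n)``
    is referred to the studentized range distribution with ``k`` groups and
    the uncorrected error degrees of freedom ``(k-1)(n-1)`` (the
    sphericity correction applies to the omnibus test only).
    """
    x = _as_matrix(data)
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if (n, k) != (anova.n_subjects, anova.n_conditions):
        raise ValueError("anova result does not match the data shape")
    if labels is None:
        labels = [f"cond{j}" for j in range(k)]
    se = np.sqrt(anova.ms_error / n)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(anova.condition_means[i] - anova.condition_means[j])
            if se == 0:
                q = 0.0 if diff == 0 else np.inf
            else:
                q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, anova.df_den)) if q > 0 else 1.0
            out.append(
                PairwiseComparison(a=labels[i], b=labels[j], mean_diff=diff, q=float(q), p_adj=min(p, 1.0))
            )
    return out


def friedman_test(data) -> tuple[float, float]:
    """Friedman's nonparametric test for a complete within-subject design.

    Conditions are mid-ranked within each subject; the tie-corrected
    chi-square statistic is referred to ``k - 1`` degrees of freedom.
    Returns ``(statistic, p)``.
    """
    x = _as_matrix(data)
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    R = ranks.sum(axis=0)
    chi = 12.0 / (n * k * (k + 1)) * np.sum(R**2) - 3.0 * n * (k + 1)
    # tie correction: scipy-consistent
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (k * (k * k - 1) * n)
    if c <= 0:
        return 0.0, 1.0  # every row fully tied
    chi /= c
    return float(chi), float(stats.chi2.sf(chi, k - 1))


def rout_outliers(values, Q: float = 0.01) -> np.ndarray:
    """ROUT outlier detection for a constant (location-only) model.

    Robust location is the median; robust scale is the RSDR — the 68.27th
    percentile of absolute residuals with the small-sample correction
    ``n / (n - 1)``.  Each point gets a two-tailed t-type p-value from its
    standardized residual (``df = n - 1``); points are flagged by
    Benjamini-Hochberg FDR at rate ``Q`` applied to the most extreme
    residuals.  Returns a boolean mask (True = outlier).

    ``n < 4`` yields an all-False mask (too few points to call outliers).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not 0 < Q < 1:
        raise ValueError("Q must be in (0, 1)")
    n = len(x)
    mask = np.zeros(n, dtype=bool)
    if n < 4:
        return mask
    resid = x - np.median(x)
    rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - 1)
    scale_floor = max(np.finfo(float).eps * max(np.max(np.abs(x)), 1.0), np.finfo(float).tiny)
    rsdr = max(rsdr, scale_floor)
    tvals = resid / rsdr
    p = 2.0 * stats.t.sf(np.abs(tvals), df=n - 1)
    # Benjamini-Hochberg step-up on the most extreme residuals
    order = np.argsort(p)
    thresh = Q * (np.arange(1, n + 1)) / n
    passed = p[order] <= thresh
    if passed.any():
        kmax = int(np.max(np.flatnonzero(passed)))
        mask[order[: kmax + 1]] = True
    return mask


def density_profile(rates, grid_max: float = 30.0, n_grid: int = 512) -> DensityProfile:
    """Gaussian kernel density of firing rates on a linear Hz grid.

    Scott's rule sets the bandwidth; the density is evaluated on
    ``[0, grid_max]``, clipped to that support, and renormalized so it
    integrates to one over the grid.  Identical rates (zero spread) fall
    back to a fixed minimum bandwidth of 0.25 Hz.
    """
    x = np.asarray(rates, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("need at least 2 finite rates")
    grid = np.linspace(0.0, grid_max, n_grid)
    std = np.std(x, ddof=1)
    if std > 0:
        bw = std * len(x) ** (-1.0 / 5.0)  # Scott's rule, 1-D
    else:
        bw = 0.25  # degenerate sample: documented fixed minimum bandwidth
    z = (grid[:, None] - x[None, :]) / bw
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (len(x) * bw * np.sqrt(2 * np.pi))
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise ValueError("density has no mass on the grid; increase grid_max")
    return DensityProfile(grid=grid, density=dens / area, bandwidth=float(bw))


def subgroup_deltas(
    firing: pd.DataFrame, ref_phase: str, target_phase: str, k: int = 10
) -> dict[str, pd.DataFrame]:
    """Paired rates of the k lowest / middle / highest firing units.

    Units are ranked by their ``ref_phase`` firing rate (ties broken by
    ascending unit id).  Returns a DataFrame per subgroup ("low", "mid",
    "high") with columns ``ref``, ``target`` and ``sign`` (+1 increase,
    -1 decrease, 0 unchanged), indexed by unit id.  The "mid" group is the
    k units centered on the median rank.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(firing) < 3 * k:
        raise ValueError(f"need at least {3 * k} units, have {len(firing)}")
    ranked = firing.loc[
        firing[ref_phase]
        .to_frame("r")
        .assign(uid=firing.index)
        .sort_values(["r", "uid"], kind="stable")
        .index
    ]
    n = len(ranked)
    mid_start = (n - k) // 2
    groups = {
        "low": ranked.iloc[:k],
        "mid": ranked.iloc[mid_start : mid_start + k],
        "high": ranked.iloc[n - k :],
    }
    out = {}
    for name, g in groups.items():
        ref = g[ref_phase]
        tgt = g[target_phase]
        out[name] = pd.DataFrame(
            {"ref": ref, "target": tgt, "sign": np.sign(tgt - ref).astype(int)}
        )
    return out
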