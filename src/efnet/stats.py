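"""Statistical engine: repeated-measures ANOVA, Tukey post hocs, paired t.

Engagement percentages form a subjects x networks repeated-measures
design with the single within-subject factor NETWORK (eight levels). The
classical decomposition removes the subject effect:

    SS_total = SS_subjects + SS_levels + SS_error
    F = MS_levels / MS_error,  df = (k - 1, (k - 1)(n - 1))

Partial eta squared is SS_levels / (SS_levels + SS_error). Pairwise level
differences are tested with the studentized-range distribution using
MS_error and df_error from the same decomposition (Tukey HSD for a
within-subject factor). No sphericity correction is applied by default; a
Greenhouse-Geisser epsilon adjustment is available behind a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_effect: float
    df_error: float
    p: float
    eta_sq: float  # partial: SS_effect / (SS_effect + SS_error)

    def __str__(self) -> str:
        return (
            f"F({self.df_effect:g}, {self.df_error:g}) = {self.F:.2f}, "
            f"p = {self.p:.3g}, partial eta^2 = {self.eta_sq:.2f}"
        )


@dataclass(frozen=True)
class PosthocResult:
    """All pairwise level comparisons with Tukey-adjusted p-values."""

    table: pd.DataFrame  # columns: level_a, level_b, mean_diff, p_raw,
    #          p_tukey, sig_tukey_05, sig_raw_05

    def n_pairs(self) -> int:
        return len(self.table)


def _as_matrix(m) -> np.ndarray:
    x = np.asarray(m, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D subjects x levels matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 levels")
    if not np.isfinite(x).all():
        raise ValueError("matrix contains non-finite entries")
    return x


def _rm_decomposition(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    ss_levels = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subjects = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_error = ss_total - ss_levels - ss_subjects
    # tiny negative residue from cancellation
    ss_error = max(ss_error, 0.0)
    return ss_levels, ss_subjects, ss_error


def _gg_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centered covariance."""
    k = x.shape[1]
    s = np.cov(x, rowvar=False)
    row = s.mean(axis=0)
    grand = s.mean()
    sc = s - row[:, None] - row[None, :] + grand
    num = np.trace(sc) ** 2
    den = (k - 1) * (sc**2).sum()
    return float(num / den) if den > 0 else 1.0


def rm_anova_network(
    m, levels: "list[str] | None" = None, gg_correction: bool = False
) -> AnovaResult:
    """One-way repeated-measures ANOVA over the level (network) factor.

    Parameters
    ----------
    m : array-like or DataFrame, shape (n_subjects, k_levels)
        Engagement percentages (or any within-subject scores).
    gg_correction : bool
        Apply the Greenhouse-Geisser epsilon to the degrees of freedom
        (off by default).
    """
    if isinstance(m, pd.DataFrame):
        m = m.to_numpy()
    x = _as_matrix(m)
    n, k = x.shape
    ss_levels, _, ss_error = _rm_decomposition(x)
    df_effect = float(k - 1)
    df_error = float((k - 1) * (n - 1))
    if ss_levels == 0.0:
        # no level effect at all (e.g. identical columns)
        return AnovaResult(0.0, df_effect, df_error, 1.0, 0.0)
    if ss_error == 0.0:
        warnings.warn(
            "zero within-subject error variance; F reported as +inf",
            stacklevel=2,
        )
        eta = 1.0 if ss_levels > 0 else 0.0
        return AnovaResult(np.inf, df_effect, df_error, 0.0, eta)
    ms_levels = ss_levels / df_effect
    ms_error = ss_error / df_error
    f = ms_levels / ms_error
    if gg_correction:
        eps = _gg_epsilon(x)
        df_effect *= eps
        df_error *= eps
    p = float(sps.f.sf(f, df_effect, df_error))
    eta = ss_levels / (ss_levels + ss_error)
    return AnovaResult(float(f), df_effect, df_error, p, float(eta))


def tukey_posthoc(m, levels: "list[str] | None" = None) -> PosthocResult:
    """Tukey-corrected pairwise comparisons of within-subject levels.

    q = |mean_i - mean_j| / sqrt(MS_error / n), referred to the
    studentized-range distribution with k levels and df_error degrees of
    freedom. Raw p comes from the paired-comparison t on the same pooled
    error term.
    """
    if isinstance(m, pd.DataFrame):
        if levels is None:
            levels = [str(c) for c in m.columns]
        m = m.to_numpy()
    x = _as_matrix(m)
    n, k = x.shape
    if levels is None:
        levels = [f"level{i}" for i in range(k)]
    if len(levels) != k:
        raise ValueError("levels length must match number of columns")
    ss_levels, _, ss_error = _rm_decomposition(x)
    df_error = (k - 1) * (n - 1)
    ms_error = ss_error / df_error if df_error else 0.0
    means = x.mean(axis=0)
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        if ms_error == 0.0:
            warnings.warn(
                "zero error variance in Tukey post hoc", stacklevel=2
            )
            p_t = 0.0 if diff != 0 else 1.0
            p_raw = p_t
        else:
            se = np.sqrt(ms_error / n)
            q = abs(diff) / se
            p_t = float(sps.studentized_range.sf(q, k, df_error))
            t = abs(diff) / (se * np.sqrt(2.0))
            p_raw = float(2.0 * sps.t.sf(t, df_error))
        p_t = min(max(p_t, 0.0), 1.0)
        rows.append(
            {
                "level_a": levels[i],
                "level_b": levels[j],
                "mean_diff": diff,
                "p_raw": p_raw,
                "p_tukey": p_t,
                "sig_tukey_05": p_t < 0.05,
                "sig_raw_05": p_raw < 0.05,
            }
        )
    return PosthocResult(table=pd.DataFrame(rows))


def paired_target_contrast(a, b) -> tuple[float, float]:
    """Two-sided paired t-test between the two targets' engagement.

    Returns (T, p). Degenerate zero-variance differences raise rather
    than reporting an infinite statistic.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        raise ValueError("differences have zero variance; t undefined")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def pearson_r(x, y) -> float:
    """Product-moment correlation; raises on degenerate input."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
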