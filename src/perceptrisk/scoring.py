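"""Risk scores, quartile groups and the descriptive/inferential tables.

The risk score of a respondent is the plain sum of their signed dummy risk
vector, so it ranges over [-m, +m] for m dummy columns.  Respondents are
then grouped into quartiles of the empirical score distribution (QR1 =
lowest perceived risk ... QR4 = highest); because scores are integers with
heavy ties, the four groups are similar but not equal in size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import RiskMatrix

QUARTILE_LABELS = (1, 2, 3, 4)


def risk_score(matrix: RiskMatrix | np.ndarray) -> np.ndarray:
    """Per-respondent risk perception value: the row sum of the risk vector."""
    values = matrix.values if isinstance(matrix, RiskMatrix) else np.asarray(matrix)
    return values.sum(axis=1).astype(int)


def assign_quartiles(scores) -> np.ndarray:
    """Quartile labels 1..4 against the empirical 25/50/75 percentiles.

    A score value never straddles two groups: every respondent with score
    <= Q1 gets label 1, <= median label 2, <= Q3 label 3, else 4 (boundary
    scores go to the lower group).  With heavily tied integer scores the
    groups are therefore similar, not identical, in size.
    """
    scores = np.asarray(scores)
    if scores.size < 4:
        raise ValueError(f"need at least 4 respondents to form quartiles, got {scores.size}")
    q1, q2, q3 = np.percentile(scores, [25, 50, 75])
    if scores.min() == scores.max():
        warnings.warn("all risk scores identical; every respondent falls in one group",
                      stacklevel=2)
    labels = np.full(scores.shape, 4, dtype=int)
    labels[scores <= q3] = 3
    labels[scores <= q2] = 2
    labels[scores <= q1] = 1
    return labels


def risk_histogram(scores, bin_width: int = 1) -> pd.DataFrame:
    """Contiguous integer-width bins covering [min, max]; counts sum to n.

    Bins are [left, left + width), the last bin closed on the right.
    Returns a DataFrame with columns bin_left, bin_right, count.
    """
    if bin_width < 1 or int(bin_width) != bin_width:
        raise ValueError("bin_width must be a positive integer")
    scores = np.asarray(scores)
    if scores.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    lo, hi = int(scores.min()), int(scores.max())
    edges = np.arange(lo, hi + bin_width + 1, bin_width)
    counts, _ = np.histogram(scores, bins=edges)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": counts,
    })


@dataclass
class BimodalityResult:
    is_bimodal: bool
    component_means: tuple
    component_weights: tuple = (np.nan, np.nan)
    separation: float = np.nan
    bic_one: float = np.nan
    bic_two: float = np.nan


def detect_bimodality(scores, random_state: int = 0) -> BimodalityResult:
    """Operational two-mode check on the score distribution.

    Fits one- and two-component univariate Gaussian mixtures and flags
    bimodality when the two-component model wins on BIC *and* the component
    means are separated by more than the pooled (weight-averaged) component
    standard deviation.  Degenerate (near-constant) scores return False with
    a warning.
    """
    from sklearn.mixture import GaussianMixture

    scores = np.asarray(scores, dtype=float)
    if scores.size < 50:
        raise ValueError("bimodality check needs n >= 50")
    if scores.std() < 1e-12:
        warnings.warn("degenerate (constant) score distribution; not bimodal",
                      stacklevel=2)
        return BimodalityResult(False, (scores.mean(), scores.mean()))

    X = scores.reshape(-1, 1)
    gm1 = GaussianMixture(1, random_state=random_state, n_init=1).fit(X)
    gm2 = GaussianMixture(2, random_state=random_state, n_init=5).fit(X)
    bic1, bic2 = gm1.bic(X), gm2.bic(X)

    means = gm2.means_.ravel()
    order = np.argsort(means)
    means = means[order]
    weights = gm2.weights_.ravel()[order]
    sds = np.sqrt(gm2.covariances_.ravel()[order])
    pooled_sd = float(np.sqrt(weights @ sds**2))
    separation = float(abs(means[1] - means[0]))

    is_bimodal = (bic2 < bic1) and (separation > pooled_sd)
    return BimodalityResult(
        bool(is_bimodal), tuple(means), tuple(weights), separation, bic1, bic2
    )


@dataclass
class ContingencyTable:
    """Counts with margins plus percent-of-grand-total, Table-1 style."""

    counts: pd.DataFrame        # rows x cols, no margins
    with_margins: pd.DataFrame  # includes row/col/grand totals
    percent_of_total: pd.DataFrame

    def formatted(self) -> pd.DataFrame:
        """Cells rendered as "n (pct)" with margins, like the printed table."""
        pct = self.percent_of_total
        out = self.with_margins.astype(object).copy()
        for r in out.index:
            for c in out.columns:
                out.loc[r, c] = f"{self.with_margins.loc[r, c]} ({pct.loc[r, c]:.1f})"
        return out


def contingency_table(rows, cols, row_name="row", col_name="col") -> ContingencyTable:
    """Cross-tabulate two equal-length categorical label vectors."""
    rows = pd.Series(rows, name=row_name)
    cols = pd.Series(cols, name=col_name)
    if len(rows) != len(cols):
        raise ValueError("label vectors must have equal length")
    counts = pd.crosstab(rows, cols)
    with_margins = pd.crosstab(rows, cols, margins=True, margins_name="Total")
    grand = len(rows)
    percent = with_margins / grand * 100 if grand else with_margins * np.nan
    return ContingencyTable(counts, with_margins, percent)


def chi_square_test(table) -> dict:
    """Pearson chi-square test of independence (no continuity correction).

    ``table`` is an r x c count matrix without margins.  df = (r-1)(c-1);
    the p-value is the upper tail of the chi-square distribution.
    """
    obs = np.asarray(table, dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal; expected counts undefined")
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return {"statistic": float(stat), "df": int(dof), "p_value": float(p)}


def frequency_profile(groups: pd.DataFrame, flags: pd.DataFrame) -> pd.DataFrame:
    """Per-group, per-flag counts and percentages, in long format.

    ``groups`` holds one or more categorical grouping columns (e.g. quartile
    and gender) aligned row-wise with the boolean ``flags`` frame.  Returns a
    tidy frame with one row per (group combination, flag): columns are the
    grouping keys plus flag, n_group, count, percent.  Empty groups report
    percent as NaN.
    """
    if len(groups) == 0:
        raise ValueError("groups must be nonempty")
    if len(groups) != len(flags):
        raise ValueError("groups and flags must align row-wise")
    keys = list(groups.columns)
    df = pd.concat([groups.reset_index(drop=True),
                    flags.reset_index(drop=True).astype(int)], axis=1)
    rows = []
    for key_vals, sub in df.groupby(keys, observed=True, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        n_group = len(sub)
        for flag in flags.columns:
            count = int(sub[flag].sum())
            percent = 100.0 * count / n_group if n_group else np.nan
            rows.append(dict(zip(keys, key_vals), flag=flag, n_group=n_group,
                             count=count, percent=percent))
    return pd.DataFrame(rows)


def plot_frequency_heatmap(profile: pd.DataFrame, key: str, ax=None):
    """Optional rendering of a frequency profile as a percentage heatmap."""
    import matplotlib.pyplot as plt

    wide = profile.pivot_table(index="flag", columns=key, values="percent")
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(wide.columns) + 2, 0.45 * len(wide) + 2))
    im = ax.imshow(wide.to_numpy(), cmap="Reds", aspect="auto", vmin=0, vmax=100)
    ax.set_xticks(range(len(wide.columns)), wide.columns)
    ax.set_yticks(range(len(wide.index)), wide.index)
    ax.figure.colorbar(im, ax=ax, label="% of group")
    return ax
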