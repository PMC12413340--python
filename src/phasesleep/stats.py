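"""Nonparametric stage-difference statistics.

Subject-level coupling values (one number per subject and stage: the grand
mean over all channel pairs and epochs) enter a Friedman test per metric and
band — 24 omnibus tests in the default analysis, Bonferroni-controlled at
alpha = 0.05 / 24.  Significant omnibus tests are followed by Nemenyi
post-hoc pairwise comparisons based on the studentized-range distribution.
A Shapiro-Wilk screen motivates the nonparametric route.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bands import BAND_NAMES
from .connectivity import METRICS, ConnectivityMatrix
from .recording import STAGES

__all__ = [
    "subject_stage_average",
    "friedman",
    "nemenyi",
    "bonferroni",
    "normality_screen",
    "stage_difference_analysis",
    "stage_tables_from_features",
]

#: Number of omnibus tests in the default analysis (6 metrics x 4 bands).
N_OMNIBUS_TESTS = len(METRICS) * len(BAND_NAMES)

#: Ordered stage-pair labels used in results tables.
STAGE_PAIRS = tuple(f"{a}-{b}" for a, b in itertools.combinations(STAGES, 2))


def subject_stage_average(
    matrices: list[ConnectivityMatrix],
    stages: tuple[str, ...] = STAGES,
) -> pd.DataFrame:
    """Subjects x stages table of pair-and-epoch grand means.

    Each cell is the flat mean of one metric over all channel pairs and all
    epochs of that subject's stage segment.  Every (subject, stage) cell
    must be covered by at least one matrix; incomplete subjects are a hard
    error (the analysis requires complete repeated measures).
    """
    if not matrices:
        raise ValueError("no connectivity matrices given")
    metrics = {m.metric for m in matrices}
    bands = {m.band for m in matrices}
    if len(metrics) != 1 or len(bands) != 1:
        raise ValueError("subject_stage_average expects a single metric and band")
    acc: dict[tuple[str, str], list[float]] = {}
    for m in matrices:
        acc.setdefault((m.subject_id, m.stage), []).extend(m.pair_values().tolist())
    subjects = sorted({m.subject_id for m in matrices})
    table = pd.DataFrame(index=subjects, columns=list(stages), dtype=float)
    for s in subjects:
        for g in stages:
            if (s, g) not in acc:
                raise ValueError(f"missing cell: subject {s}, stage {g}")
            table.loc[s, g] = float(np.mean(acc[(s, g)]))
    return table


def stage_tables_from_features(
    feature_tables: dict[str, pd.DataFrame],
    bands: tuple[str, ...] = BAND_NAMES,
    stages: tuple[str, ...] = STAGES,
) -> dict[tuple[str, str], pd.DataFrame]:
    """(metric, band) -> subjects x stages tables from per-epoch features.

    The grand mean over a band's feature columns and a subject's epochs
    equals the mean over pairs then epochs (flat mean over pair x epoch).
    """
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for metric, df in feature_tables.items():
        for band in bands:
            cols = [c for c in df.columns if c.startswith(f"{band}_")]
            if not cols:
                raise ValueError(f"no feature columns for band {band}")
            cell = df.groupby(["subject", "stage"], sort=True)[cols].mean().mean(axis=1)
            table = cell.unstack("stage")
            if table.isna().any().any():
                raise ValueError(f"missing (subject, stage) cells for {metric}/{band}")
            out[(metric, band)] = table[list(stages)]
    return out


def friedman(table: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Friedman rank test across stages (columns) with subjects as blocks.

    Average-rank tie handling with the standard tie correction.  A table
    whose rows are all constant carries no rank information and returns
    ``(0.0, 1.0)``.
    """
    values = np.asarray(table, dtype=float)
    n, k = values.shape
    if n < 2:
        raise ValueError("Friedman test needs at least 2 subjects")
    if k < 3:
        raise ValueError("Friedman test needs at least 3 conditions")
    if np.all(values == values[:, [0]]):
        return 0.0, 1.0
    stat, p = sps.friedmanchisquare(*[values[:, j] for j in range(k)])
    return float(stat), float(p)


def nemenyi(table: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Nemenyi post-hoc pairwise p-values for a Friedman design.

    Within-subject average ranks are compared via the studentized-range
    distribution: for conditions a, b with mean ranks R_a, R_b over n
    subjects and k conditions,

        q_ab = |R_a - R_b| / sqrt(k (k + 1) / (6 n)),
        p_ab = P(Q_{k, inf} > q_ab * sqrt(2)).

    Returns a symmetric k x k DataFrame with unit diagonal.
    """
    if isinstance(table, pd.DataFrame):
        cols = list(table.columns)
        values = table.to_numpy(dtype=float)
    else:
        values = np.asarray(table, dtype=float)
        cols = list(range(values.shape[1]))
    n, k = values.shape
    ranks = sps.rankdata(values, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pmat = np.ones((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            q = abs(mean_ranks[a] - mean_ranks[b]) / se
            p = float(sps.studentized_range.sf(q * np.sqrt(2.0), k, np.inf))
            pmat[a, b] = pmat[b, a] = min(1.0, p)
    return pd.DataFrame(pmat, index=cols, columns=cols)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    return alpha / m


def normality_screen(values: np.ndarray) -> float:
    """Shapiro-Wilk p-value used as the gate to the nonparametric route."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 3:
        raise ValueError("normality screen needs n >= 3")
    if np.ptp(values) == 0:
        raise ValueError("constant sample: normality undefined")
    # Shapiro-Wilk p-values are unreliable above n ~ 5000; subsample is not
    # needed here (scipy handles large n with a warning-free extension).
    return float(sps.shapiro(values).pvalue)


def stage_difference_analysis(
    stage_tables: dict[tuple[str, str], pd.DataFrame],
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Run all Friedman omnibus tests with Bonferroni control plus Nemenyi.

    ``stage_tables`` maps (metric, band) to a subjects x stages table.  The
    Bonferroni denominator defaults to the number of tables (24 in the full
    analysis).  Nemenyi p-values are filled only for significant omnibus
    tests; otherwise the pairwise columns are NaN.

    Returns a tidy DataFrame: metric, band, friedman_chi2, p, significant,
    then one column per stage pair (W-N1, ..., N2-N3).
    """
    if n_tests is None:
        n_tests = len(stage_tables)
    alpha_adj = bonferroni(alpha, n_tests)
    rows = []
    for (metric, band), table in stage_tables.items():
        stat, p = friedman(table)
        significant = bool(p < alpha_adj)
        pairwise = {pair: np.nan for pair in STAGE_PAIRS}
        if significant:
            pmat = nemenyi(table)
            for a, b in itertools.combinations(table.columns, 2):
                pairwise[f"{a}-{b}"] = float(pmat.loc[a, b])
        rows.append({"metric": metric, "band": band, "friedman_chi2": stat,
                     "p": p, "significant": significant, **pairwise})
    df = pd.DataFrame(rows)
    df.attrs["alpha"] = alpha
    df.attrs["n_tests"] = n_tests
    df.attrs["alpha_adjusted"] = alpha_adj
    return df
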