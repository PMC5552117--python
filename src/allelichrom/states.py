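"""Silent/bivalent/active chromatin-state classification and censuses.

States are defined in K4me3/K27me3 density space: silent promoters are
depleted of both marks, bivalent promoters carry high K27me3 with
moderate K4me3, and active promoters carry high K4me3 with low K27me3.
Genes falling between regions get an explicit ``intermediate`` label
rather than a forced 3-way call; alleles with too few allele-specific
reads are ``unclassifiable``.  Thresholds are either supplied or fitted
from the data (the region boundaries are a reconstruction, not a
measured constant — reports should label them as fitted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STATE_LABELS = ("silent", "bivalent", "active")
MIN_ALLELIC_READS_FOR_STATE = 5
_LOG_EPS = 1e-3


@dataclass(frozen=True)
class StateThresholds:
    """Log-space (natural log of density + eps) region boundaries."""

    k4_low: float
    k4_high: float
    k27_high: float

    def __post_init__(self):
        if not (np.isfinite(self.k4_low) and np.isfinite(self.k4_high)
                and np.isfinite(self.k27_high)):
            raise ValueError("thresholds must be finite")
        if self.k4_low >= self.k4_high:
            raise ValueError("k4_low must be below k4_high")


def _log_density(x):
    return np.log(np.asarray(x, dtype=float) + _LOG_EPS)


def classify_state(k4_density: float, k27_density: float,
                   thresholds: StateThresholds) -> str:
    """Classify one promoter from its K4me3/K27me3 densities."""
    if k4_density < 0 or k27_density < 0:
        raise ValueError("densities must be non-negative")
    k4 = float(_log_density(k4_density))
    k27 = float(_log_density(k27_density))
    if k27 >= thresholds.k27_high:
        if thresholds.k4_low <= k4 < thresholds.k4_high:
            return "bivalent"
        return "intermediate"
    if k4 < thresholds.k4_low:
        return "silent"
    if k4 >= thresholds.k4_high:
        return "active"
    return "intermediate"


def classify_states(k4_density, k27_density,
                    thresholds: StateThresholds) -> np.ndarray:
    """Vectorized :func:`classify_state`; NaN density -> unclassifiable."""
    k4d = np.asarray(k4_density, dtype=float)
    k27d = np.asarray(k27_density, dtype=float)
    missing = np.isnan(k4d) | np.isnan(k27d)
    k4 = _log_density(np.nan_to_num(k4d))
    k27 = _log_density(np.nan_to_num(k27d))
    high_k27 = k27 >= thresholds.k27_high
    out = np.where(
        high_k27,
        np.where((k4 >= thresholds.k4_low) & (k4 < thresholds.k4_high),
                 "bivalent", "intermediate"),
        np.where(k4 < thresholds.k4_low, "silent",
                 np.where(k4 >= thresholds.k4_high, "active", "intermediate")))
    out = out.astype(object)
    out[missing] = "unclassifiable"
    return out


def _otsu_split(values: np.ndarray) -> float:
    """Deterministic 2-class split of a 1-D sample.

    Exhaustive threshold search minimizing within-class variance over
    candidate midpoints between consecutive sorted unique values.
    """
    v = np.sort(np.asarray(values, dtype=float))
    uniq = np.unique(v)
    if uniq.size < 2:
        raise ValueError("degenerate (constant) densities; supply manual "
                         "thresholds instead of fitting")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_score = candidates[0], np.inf
    n = v.size
    csum = np.cumsum(v)
    csum2 = np.cumsum(v * v)
    idx = np.searchsorted(v, candidates, side="right")
    for t, i in zip(candidates, idx):
        if i == 0 or i == n:
            continue
        lo_var = csum2[i - 1] - csum[i - 1] ** 2 / i
        hi_sum = csum[-1] - csum[i - 1]
        hi_var = (csum2[-1] - csum2[i - 1]) - hi_sum ** 2 / (n - i)
        score = lo_var + hi_var
        if score < best_score:
            best_score, best_t = score, t
    return float(best_t)


def fit_thresholds(densities: pd.DataFrame,
                   min_genes: int = 100) -> StateThresholds:
    """Data-driven region boundaries from composite promoter densities.

    ``densities`` carries per-gene composite ``K4me3`` and ``K27me3``
    columns.  K4me3 log-densities are split twice (silent vs rest,
    then bivalent vs active within the upper class); K27me3 is split
    once for the high-K27 boundary.  Deterministic given input.
    """
    cols = {"K4me3", "K27me3"}
    if not cols.issubset(densities.columns):
        raise ValueError(f"densities must have columns {cols}")
    sub = densities[["K4me3", "K27me3"]].dropna()
    if len(sub) < min_genes:
        raise ValueError(f"need >= {min_genes} genes with defined densities")
    k4 = _log_density(sub["K4me3"].to_numpy())
    k27 = _log_density(sub["K27me3"].to_numpy())
    k4_low = _otsu_split(k4)
    upper = k4[k4 >= k4_low]
    if upper.size < 2 or np.unique(upper).size < 2:
        raise ValueError("degenerate K4me3 upper class; supply manual thresholds")
    k4_high = _otsu_split(upper)
    k27_high = _otsu_split(k27)
    return StateThresholds(k4_low=k4_low, k4_high=k4_high, k27_high=k27_high)


def classify_profiles(density_wide: pd.DataFrame,
                      thresholds: StateThresholds,
                      allelic_reads: pd.DataFrame | None = None,
                      min_allelic_reads: int = MIN_ALLELIC_READS_FOR_STATE,
                      ) -> pd.DataFrame:
    """State labels for composite, mus, and cas tracks of every gene.

    ``density_wide`` has one row per gene with columns
    ``K4me3_<track>`` and ``K27me3_<track>`` for track in composite/
    mus/cas.  ``allelic_reads`` (optional) carries per-gene total
    allele-specific reads over K4+K27 (columns ``n_mus``, ``n_cas``);
    alleles below ``min_allelic_reads`` are unclassifiable.
    """
    out = pd.DataFrame({"gene_id": density_wide["gene_id"]})
    for track in ("composite", "mus", "cas"):
        out[f"state_{track}"] = classify_states(
            density_wide[f"K4me3_{track}"], density_wide[f"K27me3_{track}"],
            thresholds)
    if allelic_reads is not None:
        merged = out.merge(allelic_reads[["gene_id", "n_mus", "n_cas"]],
                           on="gene_id", how="left")
        for allele in ("mus", "cas"):
            low = merged[f"n_{allele}"].fillna(0) < min_allelic_reads
            out.loc[low.to_numpy(), f"state_{allele}"] = "unclassifiable"
    return out


def combination_census(profiles: pd.DataFrame,
                       restrict_to=None) -> pd.DataFrame:
    """3x3 tally of (mus state, cas state) pairs over classified genes.

    Genes whose alleles both carry one of the three gross labels are
    tallied; the bivalent-silent cells are the rare ("unobserved")
    cross-type combination.  ``restrict_to`` optionally limits the
    census to a gene set (e.g. skewed genes).  Returns a DataFrame
    indexed by mus state with cas-state columns.
    """
    sub = profiles
    if restrict_to is not None:
        sub = sub[sub["gene_id"].isin(set(restrict_to))]
    ok = sub["state_mus"].isin(STATE_LABELS) & sub["state_cas"].isin(STATE_LABELS)
    sub = sub[ok]
    census = pd.DataFrame(0, index=list(STATE_LABELS),
                          columns=list(STATE_LABELS), dtype=int)
    grouped = sub.groupby(["state_mus", "state_cas"]).size()
    for (sm, sc), n in grouped.items():
        census.loc[sm, sc] = int(n)
    census.index.name = "state_mus"
    census.columns.name = "state_cas"
    return census


def census_gene_lists(profiles: pd.DataFrame) -> dict:
    """Gene lists per census cell, keyed by (state_mus, state_cas)."""
    ok = profiles["state_mus"].isin(STATE_LABELS) \
        & profiles["state_cas"].isin(STATE_LABELS)
    lists = {}
    for (sm, sc), sub in profiles[ok].groupby(["state_mus", "state_cas"]):
        lists[(sm, sc)] = sorted(sub["gene_id"])
    return lists


def skew_pair_analysis(calls_a: pd.DataFrame,
                       calls_b: pd.DataFrame) -> dict:
    """Partition genes by which of two marks is skewed; correlate co-skews.

    Returns counts of genes skewed in A only, B only, and both, plus
    the Spearman rank correlation of log2 skews over doubly skewed
    genes (NaN when fewer than 3).
    """
    a = calls_a.set_index("gene_id")
    b = calls_b.set_index("gene_id")
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    in_a = a["is_skewed"].to_numpy(dtype=bool)
    in_b = b["is_skewed"].to_numpy(dtype=bool)
    both = in_a & in_b
    rho = float("nan")
    if both.sum() >= 3:
        rho = float(stats.spearmanr(a.loc[both, "log2_ratio"],
                                    b.loc[both, "log2_ratio"]).statistic)
    return {"n_a_only": int((in_a & ~in_b).sum()),
            "n_b_only": int((in_b & ~in_a).sum()),
            "n_both": int(both.sum()),
            "spearman_rho": rho}


def state_conditioned_skew_distributions(profiles: pd.DataFrame,
                                         calls: pd.DataFrame,
                                         state_col: str = "state_composite",
                                         ) -> pd.DataFrame:
    """Boxplot statistics of log2 skew per composite state.

    For each gross state with members, reports n, median, Q1, Q3,
    Tukey whiskers, and the outlier gene list.  Empty state classes
    are omitted.
    """
    cols = ["gene_id", "log2_ratio"]
    sub_calls = calls
    if "passed_min_reads" in calls.columns:
        # skews are only meaningful with sufficient allele-specific reads
        sub_calls = calls[calls["passed_min_reads"]]
    merged = profiles[["gene_id", state_col]].merge(
        sub_calls[cols], on="gene_id").dropna()
    rows = []
    for state in STATE_LABELS:
        sub = merged[merged[state_col] == state]
        if len(sub) == 0:
            continue
        x = sub["log2_ratio"].to_numpy()
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lo_w = x[x >= q1 - 1.5 * iqr].min()
        hi_w = x[x <= q3 + 1.5 * iqr].max()
        outliers = sub.loc[(x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr),
                           "gene_id"].tolist()
        rows.append((state, len(sub), med, q1, q3, iqr, lo_w, hi_w,
                     ",".join(outliers)))
    return pd.DataFrame(rows, columns=["state", "n", "median", "q1", "q3",
                                       "iqr", "whisker_low", "whisker_high",
                                       "outliers"])
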