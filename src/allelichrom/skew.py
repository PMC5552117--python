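"""Allelic-skew statistics, FDR control, filters, and set summaries.

The skew statistic is the exact two-sided binomial test of the allelic
read split against p = 0.5; significance is controlled per assay with
Benjamini-Hochberg FDR, and a gene is called skewed when it has >= 15
total allele-specific reads, a more than 2-fold difference between the
allelic read numbers, and FDR < 0.05.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MIN_READS = 15
FOLD = 2.0
FDR_MAX = 0.05
PSEUDOCOUNT = 0.5

CONCORDANCE_CLASSES = ("genetic", "sequence_independent",
                       "other_discordant", "concordant_null")


def binomial_skew_test(n_mus: int, n_cas: int) -> float:
    """Exact two-sided binomial p-value for an allelic split at p = 0.5.

    Doubled smaller-tail probability (observed value included), capped
    at 1; symmetric in its arguments.
    """
    n_mus, n_cas = int(n_mus), int(n_cas)
    if n_mus < 0 or n_cas < 0:
        raise ValueError("counts must be non-negative")
    total = n_mus + n_cas
    if total == 0:
        raise ValueError("binomial test undefined for zero total reads")
    k = min(n_mus, n_cas)
    p = min(1.0, 2.0 * stats.binom.cdf(k, total, 0.5))
    # extreme splits underflow to 0; clamp so p stays in (0, 1]
    return max(p, np.finfo(float).tiny)


def binomial_skew_test_vec(n_mus, n_cas) -> np.ndarray:
    m = np.asarray(n_mus, dtype=np.int64)
    c = np.asarray(n_cas, dtype=np.int64)
    if (m < 0).any() or (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = m + c
    if (total == 0).any():
        raise ValueError("binomial test undefined for zero total reads")
    p = np.minimum(1.0, 2.0 * stats.binom.cdf(np.minimum(m, c), total, 0.5))
    return np.maximum(p, np.finfo(float).tiny)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_skew(n_mus, n_cas, pseudocount: float = PSEUDOCOUNT) -> float:
    """log2 mus:cas ratio; the pseudocount enters only on a zero count.

    Keeps ratios exact for nonzero counts while bounding the
    zero-count cases (which are flagged as less precise downstream).
    """
    if n_mus < 0 or n_cas < 0:
        raise ValueError("counts must be non-negative")
    if n_mus + n_cas == 0:
        raise ValueError("log2 skew undefined for zero total reads")
    if n_mus > 0 and n_cas > 0:
        return float(np.log2(n_mus / n_cas))
    return float(np.log2((n_mus + pseudocount) / (n_cas + pseudocount)))


def _log2_skew_vec(m, c, pseudocount):
    m = np.asarray(m, dtype=float)
    c = np.asarray(c, dtype=float)
    both = (m > 0) & (c > 0)
    out = np.empty(m.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[both] = np.log2(m[both] / c[both])
        out[~both] = np.log2((m[~both] + pseudocount) / (c[~both] + pseudocount))
    return out


def call_skewed(counts: pd.DataFrame, assay: str, *,
                min_reads: int = MIN_READS, fold: float = FOLD,
                fdr_max: float = FDR_MAX,
                pseudocount: float = PSEUDOCOUNT) -> pd.DataFrame:
    """Per-gene skew calls for one assay's allelic count table.

    A gene is testable when its total allele-specific reads reach
    ``min_reads``; the BH correction runs over testable genes only,
    within the assay.  ``is_skewed`` requires all of: testable, an
    observed fold above ``fold`` (a zero count against a positive count
    passes: infinite observed fold), and FDR below ``fdr_max``.
    Untestable genes carry NaN statistics and ``is_skewed=False``.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if fold < 1.0:
        raise ValueError("fold must be >= 1")
    if not 0 < fdr_max <= 1:
        raise ValueError("fdr_max must be in (0, 1]")
    required = {"gene_id", "n_mus", "n_cas"}
    if not required.issubset(counts.columns):
        raise ValueError(f"count table lacks columns {required - set(counts.columns)}")

    out = counts.copy()
    m = out["n_mus"].to_numpy(dtype=np.int64)
    c = out["n_cas"].to_numpy(dtype=np.int64)
    total = m + c
    testable = total >= min_reads

    log2r = np.full(len(out), np.nan)
    nz = total > 0
    log2r[nz] = _log2_skew_vec(m[nz], c[nz], pseudocount)

    hi = np.maximum(m, c).astype(float)
    lo = np.minimum(m, c).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_fold = np.where(lo > 0, hi / np.where(lo > 0, lo, 1.0),
                            np.where(hi > 0, np.inf, np.nan))
    passed_fold = obs_fold > fold

    p = np.full(len(out), np.nan)
    q = np.full(len(out), np.nan)
    if testable.any():
        p[testable] = binomial_skew_test_vec(m[testable], c[testable])
        q[testable] = bh_fdr(p[testable])
    passed_fdr = np.where(np.isnan(q), False, q < fdr_max)

    is_skewed = testable & passed_fold & passed_fdr
    direction = np.where(is_skewed & (log2r > 0), "mus",
                         np.where(is_skewed & (log2r < 0), "cas", "none"))

    out["assay"] = assay
    out["log2_ratio"] = log2r
    out["p_value"] = p
    out["fdr"] = q
    out["passed_min_reads"] = testable
    out["passed_fold"] = passed_fold & testable
    out["passed_fdr"] = passed_fdr & testable
    out["is_skewed"] = is_skewed
    out["direction"] = direction
    return out


def skewed_set_summary(calls_by_assay: dict) -> dict:
    """Per-assay tallies plus pairwise/triple skewed-set intersections.

    Returns a dict with ``per_assay`` (n_with_mark, n_with_allelic_info,
    n_skewed per assay), ``pairwise`` and ``triple`` intersection sizes
    keyed by assay tuples, and ``union_fraction`` of testable genes
    skewed in at least one assay.
    """
    per_assay = {}
    skewed_sets = {}
    testable_sets = {}
    for assay, calls in calls_by_assay.items():
        with_mark = calls["n_composite"] > 0 if "n_composite" in calls else \
            (calls["n_mus"] + calls["n_cas"]) > 0
        testable = set(calls.loc[calls["passed_min_reads"], "gene_id"])
        skewed = set(calls.loc[calls["is_skewed"], "gene_id"])
        per_assay[assay] = {"n_with_mark": int(with_mark.sum()),
                            "n_with_allelic_info": len(testable),
                            "n_skewed": len(skewed)}
        skewed_sets[assay] = skewed
        testable_sets[assay] = testable

    pairwise = {pair: len(skewed_sets[pair[0]] & skewed_sets[pair[1]])
                for pair in combinations(sorted(skewed_sets), 2)}
    triple = {trip: len(skewed_sets[trip[0]] & skewed_sets[trip[1]]
                        & skewed_sets[trip[2]])
              for trip in combinations(sorted(skewed_sets), 3)}
    union_skewed = set().union(*skewed_sets.values()) if skewed_sets else set()
    union_testable = set().union(*testable_sets.values()) if testable_sets else set()
    frac = len(union_skewed) / len(union_testable) if union_testable else float("nan")
    return {"per_assay": per_assay, "pairwise": pairwise, "triple": triple,
            "union_fraction": frac}


def hypergeometric_overlap(skewed, reference, universe) -> float:
    """Upper-tail hypergeometric p of the observed set overlap.

    P(overlap >= k) drawing |skewed| genes from a universe containing
    |reference| special genes.
    """
    universe = set(universe)
    skewed = set(skewed)
    reference = set(reference)
    if not universe:
        raise ValueError("universe must be non-empty")
    if not skewed <= universe or not reference <= universe:
        raise ValueError("skewed and reference sets must be within the universe")
    k = len(skewed & reference)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(reference),
                                    len(skewed)))


def classify_concordance(hybrid_calls: pd.DataFrame,
                         inbred: pd.DataFrame) -> pd.DataFrame:
    """Classify hybrid allelic skew against inbred-strain expression skew.

    ``hybrid_calls`` needs gene_id, log2_ratio, is_skewed;``inbred``
    needs gene_id, log2_ratio, significant.  Classes: genetic (both
    skewed, same direction), sequence_independent (hybrid-skewed,
    inbred-null), other_discordant (inbred-skewed, hybrid-null),
    concordant_null otherwise.  Genes present in only one input are
    excluded with a log note.
    """
    merged = hybrid_calls[["gene_id", "log2_ratio", "is_skewed"]].merge(
        inbred[["gene_id", "log2_ratio", "significant"]],
        on="gene_id", suffixes=("_hybrid", "_inbred"), how="inner")
    n_dropped = (len(hybrid_calls) - len(merged)) + (len(inbred) - len(merged))
    if n_dropped:
        logger.info("concordance: %d genes present in only one input excluded",
                    n_dropped)
    hyb = merged["is_skewed"].to_numpy(dtype=bool)
    inb = merged["significant"].to_numpy(dtype=bool)
    same_dir = (np.sign(merged["log2_ratio_hybrid"].to_numpy())
                == np.sign(merged["log2_ratio_inbred"].to_numpy()))
    cls = np.where(hyb & inb & same_dir, "genetic",
                   np.where(hyb & ~inb, "sequence_independent",
                            np.where(~hyb & inb, "other_discordant",
                                     "concordant_null")))
    return pd.DataFrame({"gene_id": merged["gene_id"], "concordance": cls})
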