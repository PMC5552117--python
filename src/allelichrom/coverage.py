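"""Allelic fragment assignment, deduplication, region counting, densities.

Coordinates are 0-based half-open throughout.  A fragment is assigned to
the haplotype on which it aligned with the strictly higher score;
ties and single-score fragments are neutral.  Counting attributes a
fragment to every promoter/body region it overlaps by at least 1 bp.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROMOTER_HALF_WIDTH = 1000
ALLELE_LABELS = ("mus", "cas", "neutral")


def assign_allele(score_mus, score_cas) -> str:
    """Label a fragment mus/cas/neutral from per-haplotype scores.

    The higher-scoring haplotype wins; an exact tie or a single present
    score gives no basis for assignment and is neutral.  Both scores
    missing is an upstream error (unaligned fragment).
    """
    m_missing = score_mus is None or (isinstance(score_mus, float) and np.isnan(score_mus))
    c_missing = score_cas is None or (isinstance(score_cas, float) and np.isnan(score_cas))
    if m_missing and c_missing:
        raise ValueError("fragment has no alignment score on either haplotype")
    if m_missing or c_missing:
        return "neutral"
    if score_mus > score_cas:
        return "mus"
    if score_cas > score_mus:
        return "cas"
    return "neutral"


def assign_alleles(fragments: pd.DataFrame) -> pd.DataFrame:
    """Vectorized allelic assignment; adds an ``allele`` column.

    Accepts either score columns (``score_mus``/``score_cas``) or a
    pre-assigned ``allele`` column, which is validated and passed
    through.
    """
    out = fragments.copy()
    if "allele" in out.columns:
        bad = ~out["allele"].isin(ALLELE_LABELS)
        if bad.any():
            raise ValueError(
                f"invalid allele labels: {sorted(out.loc[bad, 'allele'].unique())}")
        return out
    sm = out["score_mus"].to_numpy(dtype=float)
    sc = out["score_cas"].to_numpy(dtype=float)
    if (np.isnan(sm) & np.isnan(sc)).any():
        raise ValueError("fragments with no score on either haplotype")
    allele = np.where(sm > sc, "mus", np.where(sc > sm, "cas", "neutral"))
    allele[np.isnan(sm) | np.isnan(sc)] = "neutral"
    out["allele"] = allele
    return out


def deduplicate(fragments: pd.DataFrame) -> pd.DataFrame:
    """Keep one fragment per (chrom, start, end[, assay]) key.

    The key deliberately excludes the allele label so PCR duplicates
    cannot inflate one allele; the result is order-independent (the
    retained row is the one sorting first on the key).
    """
    key = ["chrom", "start", "end"]
    if "assay" in fragments.columns:
        key.append("assay")
    return (fragments.sort_values(key, kind="mergesort")
            .drop_duplicates(subset=key, keep="first")
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# regions

def build_regions(annotation: pd.DataFrame) -> pd.DataFrame:
    """Promoter (TSS +/- 1 kb) and gene-body intervals per gene.

    Returns one row per gene x region_type with columns ``gene_id,
    chrom, region_type, start, end, strand, length``.
    """
    rows = []
    for g in annotation.itertuples(index=False):
        rows.append((g.gene_id, g.chrom, "promoter",
                     g.tss - PROMOTER_HALF_WIDTH, g.tss + PROMOTER_HALF_WIDTH,
                     g.strand))
        rows.append((g.gene_id, g.chrom, "body", g.start, g.end, g.strand))
    regions = pd.DataFrame(rows, columns=["gene_id", "chrom", "region_type",
                                          "start", "end", "strand"])
    regions["length"] = regions["end"] - regions["start"]
    if (regions["length"] <= 0).any():
        raise ValueError("zero- or negative-length region in annotation")
    return regions


def count_fragments(fragments: pd.DataFrame,
                    regions: pd.DataFrame) -> pd.DataFrame:
    """Count deduplicated fragments over every overlapped region.

    A fragment contributes to a region when the intervals overlap by
    >= 1 bp (half-open adjacency does not count); a fragment spanning
    both the promoter and the body of a gene counts toward both.
    Fragments on chromosomes absent from the regions are ignored with a
    logged warning.  Returns ``gene_id, chrom, region_type,
    n_composite, n_mus, n_cas`` (composite = mus + cas + neutral).
    """
    frags = assign_alleles(fragments)
    counts = {(r.gene_id, r.region_type): [0, 0, 0]
              for r in regions.itertuples(index=False)}
    known_chroms = set(regions["chrom"])
    missing = set(frags["chrom"]) - known_chroms
    if missing:
        n_dropped = int(frags["chrom"].isin(missing).sum())
        logger.warning("ignoring %d fragments on chromosomes absent from "
                       "the annotation: %s", n_dropped, sorted(missing))

    by_chrom = {c: sub for c, sub in regions.groupby("chrom")}
    for chrom, sub in frags.groupby("chrom"):
        if chrom not in by_chrom:
            continue
        reg = by_chrom[chrom]
        r_start = reg["start"].to_numpy()
        r_end = reg["end"].to_numpy()
        f_start = sub["start"].to_numpy()
        f_end = sub["end"].to_numpy()
        allele = sub["allele"].to_numpy()
        # overlap >= 1 bp: f_start < r_end and f_end > r_start
        for ri, (gid, rtype) in enumerate(zip(reg["gene_id"], reg["region_type"])):
            hit = (f_start < r_end[ri]) & (f_end > r_start[ri])
            if not hit.any():
                continue
            cell = counts[(gid, rtype)]
            cell[0] += int((allele[hit] == "mus").sum())
            cell[1] += int((allele[hit] == "cas").sum())
            cell[2] += int(hit.sum())

    rows = []
    for r in regions.itertuples(index=False):
        mus, cas, comp = counts[(r.gene_id, r.region_type)]
        rows.append((r.gene_id, r.chrom, r.region_type, comp, mus, cas))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "region_type",
                                       "n_composite", "n_mus", "n_cas"])


# ---------------------------------------------------------------------------
# densities

def normalize_density(counts: pd.DataFrame, input_counts: pd.DataFrame,
                      regions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Input-normalized densities per gene x region, per track.

    density = (count / region_length_kb) / (input_count / region_length_kb),
    computed track-wise on composite counts; where the matched input
    composite count is 0 the density is missing (NaN), never infinite.
    Allelic densities are inferred from the composite density and the
    observed mus:cas split (see :func:`inferred_allelic_density`).
    Returns ``gene_id, chrom, region_type, composite, mus, cas``.
    """
    key = ["gene_id", "region_type"]
    merged = counts.merge(input_counts[key + ["n_composite"]], on=key,
                          how="left", suffixes=("", "_input"),
                          validate="one_to_one")
    if merged["n_composite_input"].isna().any():
        raise ValueError("input counts missing for some gene x region keys")
    if regions is not None:
        lengths = regions[key + ["length"]]
        merged = merged.merge(lengths, on=key, how="left")
        if (merged["length"] <= 0).any():
            raise ValueError("zero-length region")
        # lengths cancel between numerator and matched input; kept for clarity
    inp = merged["n_composite_input"].to_numpy(dtype=float)
    comp = merged["n_composite"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(inp > 0, comp / inp, np.nan)
    mus, cas = inferred_allelic_density(density,
                                        merged["n_mus"].to_numpy(),
                                        merged["n_cas"].to_numpy())
    return pd.DataFrame({"gene_id": merged["gene_id"],
                         "chrom": merged["chrom"],
                         "region_type": merged["region_type"],
                         "composite": density, "mus": mus, "cas": cas})


def inferred_allelic_density(composite_density, n_mus, n_cas):
    """Split composite density by the observed mus:cas read ratio.

    mus + cas always reconstruct the composite exactly; with zero
    allelic reads both allelic densities are missing (NaN).
    Accepts scalars or arrays.
    """
    comp = np.asarray(composite_density, dtype=float)
    m = np.asarray(n_mus, dtype=float)
    c = np.asarray(n_cas, dtype=float)
    if (m < 0).any() or (c < 0).any():
        raise ValueError("allelic counts must be non-negative")
    total = m + c
    with np.errstate(divide="ignore", invalid="ignore"):
        mus = np.where(total > 0, comp * m / total, np.nan)
        cas = np.where(total > 0, comp - comp * m / total, np.nan)
    if np.isscalar(composite_density) and np.isscalar(n_mus):
        return float(mus), float(cas)
    return mus, cas


def chromosome_balance(counts: pd.DataFrame,
                       pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-chromosome allelic read totals and log2 mus:cas ratio.

    Diagnostic for large-scale aberrations (aneuploidy, deletions): a
    balanced genome keeps every chromosome's ratio near 0.
    """
    if len(counts) == 0:
        return pd.DataFrame(columns=["chrom", "n_mus", "n_cas", "log2_ratio"])
    g = counts.groupby("chrom", sort=True)[["n_mus", "n_cas"]].sum().reset_index()
    m = g["n_mus"].to_numpy(dtype=float)
    c = g["n_cas"].to_numpy(dtype=float)
    zero = (m == 0) | (c == 0)
    ratio = np.empty(len(g))
    ratio[~zero] = np.log2(m[~zero] / c[~zero])
    ratio[zero] = np.log2((m[zero] + pseudocount) / (c[zero] + pseudocount))
    g["log2_ratio"] = ratio
    return g
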