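"""Seeded generator of synthetic allele-specific ChIP-seq/RNA-seq data.

Emulates the derived structure of clonal hybrid-fibroblast data: two
alleles per gene, three gross chromatin states (silent / bivalent /
active) with state-dependent mark densities, continuous within-state
allelic skew, rare cross-type allelic state combinations, ChIP allelic
read fraction ~0.37 and RNA ~0.17, and allelic expression driven
log-linearly by allelic mark densities.  Every draw flows from a single
:class:`numpy.random.Generator` seeded from the config, so identical
configs produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MARKS = ("K4me3", "K27me3", "K36me3", "POL2S2", "POL2S5")
ASSAYS = MARKS + ("RNA",)
STATES = ("silent", "bivalent", "active")
ALLELES = ("mus", "cas")

#: region over which each assay's enrichment is quantified
CANONICAL_REGION = {
    "K4me3": "promoter",
    "K27me3": "promoter",
    "POL2S5": "promoter",
    "K36me3": "body",
    "POL2S2": "body",
    "RNA": "body",
    "input": "promoter",  # input is simulated for both regions; this is unused
}

#: log-space (natural log) mean input-normalized density per state per mark.
#: Geometry: active = high K4/K36/POL2 + low K27; bivalent = moderate K4 +
#: high K27 + depleted K36/POL2; silent = concerted depletion of all marks.
STATE_TEMPLATES = {
    "active": {"K4me3": math.log(8.0), "K27me3": math.log(0.2),
               "K36me3": math.log(6.0), "POL2S2": math.log(5.0),
               "POL2S5": math.log(5.0)},
    "bivalent": {"K4me3": math.log(1.8), "K27me3": math.log(6.0),
                 "K36me3": math.log(0.08), "POL2S2": math.log(0.08),
                 "POL2S5": math.log(0.15)},
    "silent": {"K4me3": math.log(0.08), "K27me3": math.log(0.25),
               "K36me3": math.log(0.05), "POL2S2": math.log(0.05),
               "POL2S5": math.log(0.05)},
}

#: sign of the shared within-state skew applied to each mark: the active
#: marks move together while K27me3 moves against them, so that on doubly
#: skewed genes active-vs-active skews correlate and active-vs-repressive
#: skews anticorrelate.
SKEW_DIRECTION = {"K4me3": 1.0, "K27me3": -1.0, "K36me3": 1.0,
                  "POL2S2": 1.0, "POL2S5": 1.0}

#: relative amplitude of the within-state skew per gross state; bivalent
#: promoters have near-balanced alleles (narrow skew IQR).
STATE_SKEW_SCALE = {"silent": 0.6, "bivalent": 0.2, "active": 1.0}

CROSS_TYPE_PAIRS = (("active", "silent"), ("active", "bivalent"),
                    ("bivalent", "silent"))


def _normalized(weights: dict, keys) -> dict:
    return {k: float(weights[k]) for k in keys}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic generator.

    Defaults are documented choices, not measured facts: the emulated
    data constrain only the qualitative geometry (state templates) and
    the allelic read fractions (~0.37 ChIP, ~0.17 RNA).
    """

    n_genes: int = 1000
    state_mixture: dict = field(default_factory=lambda: {
        "silent": 0.35, "bivalent": 0.15, "active": 0.50})
    p_same_type: float = 0.90
    cross_type_weights: dict = field(default_factory=lambda: {
        ("active", "silent"): 0.59,
        ("active", "bivalent"): 0.39,
        ("bivalent", "silent"): 0.02})
    within_type_skew_sd: float = 0.8        # log2 units
    template_sd: float = 0.35               # natural-log units
    allelic_noise_sd: float = 0.40          # log2, independent per allele/mark
    depth_per_assay: float = 60.0
    dispersion: float = 0.1                 # NB dispersion; 0 -> Poisson
    allelic_fraction_chip: float = 0.37
    allelic_fraction_rna: float = 0.17
    expression_weights: dict = field(default_factory=lambda: {
        "K4me3": 0.9, "K36me3": 0.7, "POL2S2": 0.5,
        "POL2S5": 0.4, "K27me3": -0.8})
    expression_scale: float = 0.05
    noise_sd: float = 0.6                   # natural-log expression noise
    n_rna_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.depth_per_assay <= 0:
            raise ValueError("depth_per_assay must be > 0")
        for name, frac in (("allelic_fraction_chip", self.allelic_fraction_chip),
                           ("allelic_fraction_rna", self.allelic_fraction_rna),
                           ("p_same_type", self.p_same_type)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        for name, probs, keys in (
                ("state_mixture", self.state_mixture, STATES),
                ("cross_type_weights", self.cross_type_weights, CROSS_TYPE_PAIRS)):
            if set(probs) != set(keys):
                raise ValueError(f"{name} must have keys {keys}")
            vals = np.array([probs[k] for k in keys], dtype=float)
            if (vals < 0).any():
                raise ValueError(f"{name} entries must be non-negative")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 within 1e-9")
        for sd in (self.within_type_skew_sd, self.template_sd,
                   self.allelic_noise_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_rna_replicates < 1:
            raise ValueError("n_rna_replicates must be >= 1")

    def with_(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# annotation

def generate_annotation(n_genes: int, seed: int, *, n_chroms: int = 5,
                        min_body: int = 2000, max_body: int = 20000,
                        min_gap: int = 3000, max_gap: int = 9000) -> pd.DataFrame:
    """Non-overlapping gene models on a few named chromosomes.

    Genes are laid end to end with random gaps so bodies never overlap;
    TSS sits at the 5' body end given the strand.  Columns: ``gene_id,
    chrom, start, end, strand, tss``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_of = np.sort(rng.integers(0, n_chroms, size=n_genes))
    rows = []
    cursor = {}
    for i in range(n_genes):
        chrom = f"chr{chrom_of[i] + 1}"
        pos = cursor.get(chrom, 10_000)
        gap = int(rng.integers(min_gap, max_gap))
        body = int(rng.integers(min_body, max_body))
        start = pos + gap
        end = start + body
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else end
        rows.append((f"g{i:05d}", chrom, start, end, strand, tss))
        cursor[chrom] = end
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand", "tss"])


# ---------------------------------------------------------------------------
# allelic states and true densities

def draw_allelic_states(config: GeneratorConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-gene allelic gross states and true allelic densities.

    Returns the generator truth table with one row per gene: state
    labels for both alleles, true input-normalized density of every
    mark on every allele, true per-allele expression, the mus fraction
    of expression, and the true log2 mus:cas skew per assay.
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    n = config.n_genes

    mix = np.array([config.state_mixture[s] for s in STATES])
    cross_w = np.array([config.cross_type_weights[p] for p in CROSS_TYPE_PAIRS])

    same = rng.random(n) < config.p_same_type
    same_states = rng.choice(len(STATES), size=n, p=mix)
    cross_idx = rng.choice(len(CROSS_TYPE_PAIRS), size=n,
                           p=cross_w) if cross_w.sum() else np.zeros(n, int)
    flip = rng.random(n) < 0.5

    state_mus = np.empty(n, dtype=object)
    state_cas = np.empty(n, dtype=object)
    for i in range(n):
        if same[i]:
            state_mus[i] = state_cas[i] = STATES[same_states[i]]
        else:
            a, b = CROSS_TYPE_PAIRS[cross_idx[i]]
            state_mus[i], state_cas[i] = (a, b) if flip[i] else (b, a)

    skew = rng.normal(0.0, config.within_type_skew_sd, size=n)
    gene_noise = rng.normal(0.0, config.template_sd, size=(n, len(MARKS)))
    allele_noise = rng.normal(0.0, config.allelic_noise_sd * math.log(2),
                              size=(n, len(MARKS), 2))
    expr_noise = rng.normal(0.0, config.noise_sd, size=(n, 2))

    scale_of = np.array([[STATE_SKEW_SCALE[state_mus[i]],
                          STATE_SKEW_SCALE[state_cas[i]]] for i in range(n)])
    skew_scale = scale_of.mean(axis=1)

    out = {"gene_id": [f"g{i:05d}" for i in range(n)],
           "state_mus": state_mus, "state_cas": state_cas}
    dens = {}
    for j, mark in enumerate(MARKS):
        mu_mus = np.array([STATE_TEMPLATES[s][mark] for s in state_mus])
        mu_cas = np.array([STATE_TEMPLATES[s][mark] for s in state_cas])
        shift = SKEW_DIRECTION[mark] * skew * skew_scale * math.log(2) / 2.0
        d_mus = np.exp(mu_mus + gene_noise[:, j]
                       + allele_noise[:, j, 0] * scale_of[:, 0] + shift)
        d_cas = np.exp(mu_cas + gene_noise[:, j]
                       + allele_noise[:, j, 1] * scale_of[:, 1] - shift)
        dens[mark] = (d_mus, d_cas)
        out[f"d_{mark}_mus"] = d_mus
        out[f"d_{mark}_cas"] = d_cas
        out[f"true_log2_skew_{mark}"] = np.log2(d_mus / d_cas)

    w = config.expression_weights
    log_e = np.zeros((n, 2))
    for j, mark in enumerate(MARKS):
        for a in (0, 1):
            log_e[:, a] += w.get(mark, 0.0) * np.log1p(dens[mark][a])
    expr = config.expression_scale * np.exp(log_e + expr_noise)
    out["expr_mus"] = expr[:, 0]
    out["expr_cas"] = expr[:, 1]
    out["fpkm"] = expr.sum(axis=1)
    out["true_expression_proportion"] = expr[:, 0] / expr.sum(axis=1)
    out["true_log2_skew_RNA"] = np.log2(expr[:, 0] / expr[:, 1])
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# counts

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative-binomial (gamma-Poisson) counts; Poisson when dispersion=0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(truth: pd.DataFrame, config: GeneratorConfig,
                    annotation: pd.DataFrame | None = None,
                    rng: np.random.Generator | None = None) -> dict:
    """Simulate per-assay allelic count tables from a truth table.

    Composite counts are negative-binomial with mean proportional to
    the true composite density times ``depth_per_assay``; allelic counts
    are a binomial thinning of the composite at the assay's allelic
    fraction, split mus/cas at the true allelic proportion.  RNA is
    generated in ``n_rna_replicates`` replicates (assays ``RNA_rep1``,
    ...); a matched ``input`` table covers both region types.

    Returns a dict ``assay -> DataFrame(gene_id, chrom, region_type,
    n_composite, n_mus, n_cas)``.
    """
    config.validate()
    if annotation is not None and len(annotation) != len(truth):
        raise ValueError("truth and annotation describe different gene sets")
    if rng is None:
        # independent stream: counts may be regenerated without redrawing states
        rng = np.random.default_rng(config.seed + 1)
    n = len(truth)
    chrom = (annotation["chrom"].to_numpy() if annotation is not None
             else np.repeat("chrU", n))
    gene_id = truth["gene_id"].to_numpy()

    tables = {}

    def build(assay, region, d_mus, d_cas, p_mus, frac):
        mean = config.depth_per_assay * (d_mus + d_cas) / 2.0
        comp = _nb_draw(rng, mean, config.dispersion)
        allelic = rng.binomial(comp, frac)
        mus = rng.binomial(allelic, p_mus)
        tables[assay] = pd.DataFrame({
            "gene_id": gene_id, "chrom": chrom,
            "region_type": region, "n_composite": comp,
            "n_mus": mus, "n_cas": allelic - mus})

    for mark in MARKS:
        d_mus = truth[f"d_{mark}_mus"].to_numpy()
        d_cas = truth[f"d_{mark}_cas"].to_numpy()
        p_mus = d_mus / (d_mus + d_cas)
        build(mark, CANONICAL_REGION[mark], d_mus, d_cas, p_mus,
              config.allelic_fraction_chip)

    p_rna = truth["true_expression_proportion"].to_numpy()
    e_mus = truth["expr_mus"].to_numpy()
    e_cas = truth["expr_cas"].to_numpy()
    for rep in range(1, config.n_rna_replicates + 1):
        build(f"RNA_rep{rep}", "body", e_mus, e_cas, p_rna,
              config.allelic_fraction_rna)

    ones = np.ones(n)
    for region in ("promoter", "body"):
        build(f"input_{region}", region, ones, ones, np.full(n, 0.5),
              config.allelic_fraction_chip)

    return tables


def combine_rna_replicates(tables: dict) -> pd.DataFrame:
    """Sum composite and allelic counts across RNA replicate tables."""
    reps = [t for name, t in sorted(tables.items())
            if name.startswith("RNA_rep")]
    if not reps:
        raise ValueError("no RNA replicate tables found")
    out = reps[0].copy()
    for t in reps[1:]:
        for col in ("n_composite", "n_mus", "n_cas"):
            out[col] = out[col] + t[col].to_numpy()
    return out


def estimate_fpkm(tables: dict, config: GeneratorConfig) -> pd.DataFrame:
    """Composite expression estimate on the truth table's FPKM scale.

    The RNA count mean is depth * (expr_mus + expr_cas) / 2 per
    replicate, so fpkm_hat = 2 * mean-per-replicate / depth.
    """
    reps = [t for name, t in sorted(tables.items())
            if name.startswith("RNA_rep")]
    if not reps:
        raise ValueError("no RNA replicate tables found")
    comp = np.mean([t["n_composite"].to_numpy() for t in reps], axis=0)
    return pd.DataFrame({"gene_id": reps[0]["gene_id"],
                         "fpkm": 2.0 * comp / config.depth_per_assay})


# ---------------------------------------------------------------------------
# fragments

def simulate_fragments(truth: pd.DataFrame, config: GeneratorConfig,
                       annotation: pd.DataFrame, assay: str,
                       rng: np.random.Generator | None = None,
                       fragment_length: int = 400) -> pd.DataFrame:
    """Simulate assignable fragment intervals for one ChIP assay.

    Fragments are placed uniformly so that each overlaps its gene's
    canonical region; per-haplotype alignment scores encode the allelic
    label (mus fragments score higher on mus, neutral fragments tie).
    Columns: ``chrom, start, end, name, score, strand, score_mus,
    score_cas`` (extended BED, 0-based half-open).
    """
    config.validate()
    if assay not in MARKS:
        raise ValueError(f"unknown ChIP assay {assay!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    region = CANONICAL_REGION[assay]
    d_mus = truth[f"d_{assay}_mus"].to_numpy()
    d_cas = truth[f"d_{assay}_cas"].to_numpy()
    p_mus = d_mus / (d_mus + d_cas)
    mean = config.depth_per_assay * (d_mus + d_cas) / 2.0
    comp = _nb_draw(rng, mean, config.dispersion)

    rows = []
    k = 0
    for i in range(len(truth)):
        gene = annotation.iloc[i]
        if region == "promoter":
            lo, hi = gene.tss - 1000, gene.tss + 1000
        else:
            lo, hi = gene.start, gene.end
        n_frag = int(comp[i])
        starts = rng.integers(lo - fragment_length + 1, hi, size=n_frag)
        allelic = rng.random(n_frag) < config.allelic_fraction_chip
        is_mus = rng.random(n_frag) < p_mus[i]
        for s, al, m in zip(starts, allelic, is_mus):
            if al:
                sm, sc = (60, 50) if m else (50, 60)
            else:
                sm = sc = 37
            rows.append((gene.chrom, int(s), int(s) + fragment_length,
                         f"frag{k:07d}", 0, ".", sm, sc))
            k += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand",
                                       "score_mus", "score_cas"])


def uniform_skew_truth(n_genes: int, log2_skew: float,
                       pair_density: float = 5.0,
                       expression: float = 10.0) -> pd.DataFrame:
    """Truth table with a fixed mus:cas ratio on every mark and on RNA.

    All genes are active with combined allelic density ``pair_density``
    per mark split so that log2(d_mus/d_cas) = ``log2_skew``; expression
    follows the same ratio.  Useful as a positive control (recovery
    sensitivity, chromosome-balance diagnostics, X-like skew).
    """
    r = 2.0 ** log2_skew
    d_mus = pair_density * r / (1.0 + r)
    d_cas = pair_density / (1.0 + r)
    out = {"gene_id": [f"g{i:05d}" for i in range(n_genes)],
           "state_mus": ["active"] * n_genes,
           "state_cas": ["active"] * n_genes}
    for mark in MARKS:
        out[f"d_{mark}_mus"] = np.full(n_genes, d_mus)
        out[f"d_{mark}_cas"] = np.full(n_genes, d_cas)
        out[f"true_log2_skew_{mark}"] = np.full(n_genes, float(log2_skew))
    out["expr_mus"] = np.full(n_genes, expression * r / (1.0 + r))
    out["expr_cas"] = np.full(n_genes, expression / (1.0 + r))
    out["fpkm"] = np.full(n_genes, expression)
    out["true_expression_proportion"] = np.full(n_genes, r / (1.0 + r))
    out["true_log2_skew_RNA"] = np.full(n_genes, float(log2_skew))
    return pd.DataFrame(out)


def null_config(n_genes: int, seed: int, **overrides) -> GeneratorConfig:
    """Config with true allelic skew exactly 0 for every gene and assay.

    Both alleles share the gross type and the within-type multiplier,
    per-allele density and expression noise are off, so every allelic
    count is a fair Binomial(n, 1/2) split — the null for false-positive
    rate checks of the skew caller.
    """
    return GeneratorConfig(n_genes=n_genes, seed=seed, p_same_type=1.0,
                           within_type_skew_sd=0.0, allelic_noise_sd=0.0,
                           noise_sd=0.0, **overrides)


def generate_dataset(config: GeneratorConfig):
    """Convenience: annotation + truth + count tables from one config."""
    config.validate()
    annotation = generate_annotation(config.n_genes, config.seed)
    truth = draw_allelic_states(config)
    counts = simulate_counts(truth, config, annotation)
    return annotation, truth, counts
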