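"""Stage orchestration shared by the CLI and the test suite.

Each stage reads/writes the documented text formats and appends a
deterministic manifest entry, so a rerun with identical config and
seeds reproduces every output byte for byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import coverage, io, prediction, skew, states, synthetic
from .synthetic import CANONICAL_REGION, MARKS


def simulate_to_dir(config: io.RunConfig, outdir,
                    write_fragments_for=()) -> dict:
    """Run the generator and write annotation, truth, and count tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen = config.generator
    annotation, truth, counts = synthetic.generate_dataset(gen)
    outputs = {}
    outputs["annotation"] = io.write_annotation(annotation,
                                                outdir / "annotation.tsv")
    outputs["truth"] = io.write_table(truth, outdir / "truth.tsv")
    for assay, table in counts.items():
        outputs[f"counts_{assay}"] = io.write_count_table(
            table, outdir / f"counts_{assay}.tsv")
    for assay in write_fragments_for:
        frags = synthetic.simulate_fragments(truth, gen, annotation, assay)
        outputs[f"fragments_{assay}"] = io.write_fragments(
            frags, outdir / f"fragments_{assay}.bed")
    outputs["config"] = io.save_config(config, outdir / "config.yaml")
    io.write_manifest(outdir, "simulate", {}, outputs, config.to_dict())
    return outputs


def load_counts_dir(outdir) -> dict:
    """Read every counts_<assay>.tsv in a simulate output directory."""
    outdir = Path(outdir)
    tables = {}
    for path in sorted(outdir.glob("counts_*.tsv")):
        assay = path.stem[len("counts_"):]
        tables[assay] = io.read_count_table(path)
    if not tables:
        raise FileNotFoundError(f"no counts_*.tsv files in {outdir}")
    return tables


def density_tables(counts: dict, annotation: pd.DataFrame) -> dict:
    """Per-mark input-normalized density tables at canonical regions."""
    regions = coverage.build_regions(annotation)
    out = {}
    for mark in MARKS:
        if mark not in counts:
            continue
        region = CANONICAL_REGION[mark]
        inp = counts[f"input_{region}"]
        out[mark] = coverage.normalize_density(counts[mark], inp, regions)
    return out


def density_wide(counts: dict, annotation: pd.DataFrame):
    """Wide per-gene density matrices.

    Returns (composite, allelic): composite has one column per mark;
    allelic has ``<mark>_mus`` / ``<mark>_cas`` inferred allelic
    densities, plus ``K4me3_composite``-style columns used by the
    state classifier.
    """
    tables = density_tables(counts, annotation)
    composite = pd.DataFrame({"gene_id": annotation["gene_id"]})
    allelic = pd.DataFrame({"gene_id": annotation["gene_id"]})
    for mark, table in tables.items():
        aligned = composite[["gene_id"]].merge(table, on="gene_id", how="left")
        composite[mark] = aligned["composite"].to_numpy()
        allelic[f"{mark}_composite"] = aligned["composite"].to_numpy()
        allelic[f"{mark}_mus"] = aligned["mus"].to_numpy()
        allelic[f"{mark}_cas"] = aligned["cas"].to_numpy()
    return composite, allelic


def call_skew_all(counts: dict, config: io.RunConfig) -> dict:
    """Skew calls per ChIP mark plus replicate-summed RNA."""
    calls = {}
    for mark in MARKS:
        if mark in counts:
            calls[mark] = skew.call_skewed(
                counts[mark], mark, min_reads=config.min_reads,
                fold=config.fold, fdr_max=config.fdr_max,
                pseudocount=config.pseudocount)
    rna = synthetic.combine_rna_replicates(counts)
    calls["RNA"] = skew.call_skewed(
        rna, "RNA", min_reads=config.min_reads, fold=config.fold,
        fdr_max=config.fdr_max, pseudocount=config.pseudocount)
    return calls


def classify_all(counts: dict, annotation: pd.DataFrame,
                 config: io.RunConfig):
    """Fit (or take) state thresholds and classify all tracks.

    Returns (thresholds, profiles).  Thresholds are fitted from
    composite promoter K4me3/K27me3 densities unless the config
    supplies numeric ones; fitted boundaries are a reconstruction and
    are labeled as such in the profile table's attrs.
    """
    composite, allelic = density_wide(counts, annotation)
    if isinstance(config.state_thresholds, dict):
        thresholds = states.StateThresholds(**config.state_thresholds)
        fitted = False
    else:
        thresholds = states.fit_thresholds(composite)
        fitted = True
    k4 = counts["K4me3"][["gene_id", "n_mus", "n_cas"]]
    k27 = counts["K27me3"][["gene_id", "n_mus", "n_cas"]]
    reads = k4.merge(k27, on="gene_id", suffixes=("_k4", "_k27"))
    reads["n_mus"] = reads["n_mus_k4"] + reads["n_mus_k27"]
    reads["n_cas"] = reads["n_cas_k4"] + reads["n_cas_k27"]
    wide = allelic.rename(columns={"K4me3_composite": "K4me3_composite",
                                   "K27me3_composite": "K27me3_composite"})
    profiles = states.classify_profiles(wide, thresholds,
                                        allelic_reads=reads)
    profiles.attrs["thresholds_fitted"] = fitted
    return thresholds, profiles


def predict_and_evaluate(counts: dict, annotation: pd.DataFrame,
                         truth: pd.DataFrame | None,
                         config: io.RunConfig) -> dict:
    """Train the Bayes-factor model and evaluate predictions.

    Genes are split into equal train/validation halves; the model is
    fitted on training genes (expressed = composite FPKM above the
    config threshold) and evaluated on validation genes against the
    observed RNA skew calls.  Returns predictions, per-model ROC/AUC,
    the linear-model CV correlation, the variance decomposition, and
    the discordance census.
    """
    gen = config.generator
    composite, allelic = density_wide(counts, annotation)
    fpkm = synthetic.estimate_fpkm(counts, gen)
    rna_calls = skew.call_skewed(
        synthetic.combine_rna_replicates(counts), "RNA",
        min_reads=config.min_reads, fold=config.fold,
        fdr_max=config.fdr_max, pseudocount=config.pseudocount)

    train, validation = prediction.split_train_validation(
        composite["gene_id"], seed=config.seed)
    train_set = set(train)
    model = prediction.fit_bayes_factor_model(
        composite[composite["gene_id"].isin(train_set)],
        fpkm, expressed_threshold=config.expressed_fpkm)
    preds = prediction.predict_expression_skew(model, allelic)

    val = preds[preds["gene_id"].isin(set(validation))].merge(
        rna_calls[["gene_id", "log2_ratio", "is_skewed", "passed_min_reads"]],
        on="gene_id")
    val = val[val["passed_min_reads"]].dropna(subset=["log2_ratio"])
    pearson_r = float("nan")
    if len(val) >= 3:
        pearson_r = float(np.corrcoef(val["predicted_skew"],
                                      val["log2_ratio"])[0, 1])

    # per-mark linear models of RNA skew from observed mark skews
    mark_calls = {m: skew.call_skewed(counts[m], m,
                                      min_reads=config.min_reads,
                                      fold=config.fold,
                                      fdr_max=config.fdr_max,
                                      pseudocount=config.pseudocount)
                  for m in MARKS if m in counts}
    mark_skews = pd.DataFrame({"gene_id": annotation["gene_id"]})
    for m, calls in mark_calls.items():
        aligned = mark_skews[["gene_id"]].merge(
            calls[["gene_id", "log2_ratio"]], on="gene_id", how="left")
        mark_skews[m] = aligned["log2_ratio"].to_numpy()
    eval_df = mark_skews.merge(
        rna_calls.loc[rna_calls["passed_min_reads"],
                      ["gene_id", "log2_ratio", "is_skewed"]],
        on="gene_id").dropna()
    predictors = [m for m in MARKS if m in eval_df.columns]

    linear = prediction.linear_cv_model(eval_df[predictors],
                                        eval_df["log2_ratio"],
                                        seed=config.seed)
    decomposition = prediction.variance_decomposition(
        eval_df[predictors], eval_df["log2_ratio"])

    roc_inputs = {}
    y = eval_df["log2_ratio"].to_numpy()
    obs = eval_df["is_skewed"].to_numpy(dtype=bool)
    half = len(eval_df) // 2
    for name, cols in [("combined", predictors)] + [(m, [m]) for m in predictors]:
        x = eval_df[cols].to_numpy(dtype=float)
        fit = prediction._ols_fit_predict(x[:half], y[:half], x)
        roc_inputs[name] = fit
    roc = prediction.roc_over_cutoffs(
        {k: v[half:] for k, v in roc_inputs.items()}, obs[half:])

    merged = preds.merge(rna_calls[["gene_id", "log2_ratio", "is_skewed",
                                    "passed_min_reads"]], on="gene_id")
    merged = merged[merged["passed_min_reads"]].dropna(subset=["log2_ratio"])
    census = prediction.discordance_census(
        merged["predicted_skew"], merged["predicted_skew"].abs() >= 1.0,
        merged["log2_ratio"], merged["is_skewed"])

    return {"model": model, "predictions": preds, "pearson_r": pearson_r,
            "n_validation": len(val), "linear_cv": linear,
            "variance_decomposition": decomposition, "roc": roc,
            "discordance_census": census, "rna_calls": rna_calls,
            "train_genes": train, "validation_genes": validation}
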