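"""Bayes-factor prediction of allelic expression skew, and evaluation.

Per assay, reference distributions of enrichment are estimated from
training genes split into expressed and non-expressed classes; each
allele then gets a summed log Bayes factor (log likelihood ratio of its
enrichment under the expressed vs non-expressed reference) across
assays, and the predicted expression skew is the mus-cas difference of
these sums.  Evaluation covers Pearson correlation, 2-fold
cross-validated linear models, incremental variance decomposition, and
ROC sweeps over skew cutoffs.
"""

from __future__ import annotations

import hashlib
import json
import math

import numpy as np
import pandas as pd
from scipy import stats

DENSITY_FLOOR = 1e-6
EXPRESSED_FPKM = 1.0
ROC_CUTOFFS = np.round(np.arange(0.0, 6.01, 0.1), 10)
MODEL_FORMAT_VERSION = 1


def split_train_validation(gene_ids, seed: int):
    """Disjoint equal-sized (within one) train/validation gene sets."""
    genes = list(gene_ids)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    half = len(genes) // 2
    train = [genes[i] for i in order[:half]]
    validation = [genes[i] for i in order[half:]]
    return train, validation


class BayesFactorModel:
    """Expressed/non-expressed enrichment reference densities per assay.

    Reference densities are Gaussian KDEs (Silverman bandwidth) on
    log(1 + enrichment), floored at ``DENSITY_FLOOR`` so log ratios
    stay bounded.  Enrichment values are composite densities halved to
    the single-allele scale, so per-allele densities evaluate on the
    scale the model was trained on.
    """

    def __init__(self, training_values: dict,
                 expressed_threshold: float = EXPRESSED_FPKM,
                 training_genes=None):
        self.training_values = training_values
        self.expressed_threshold = float(expressed_threshold)
        self.training_genes = sorted(training_genes) if training_genes else []
        self._kdes = {}
        for assay, classes in training_values.items():
            exp = np.asarray(classes["expressed"], dtype=float)
            non = np.asarray(classes["non_expressed"], dtype=float)
            if exp.size == 0:
                raise ValueError(f"{assay}: expressed training class is empty")
            if non.size == 0:
                raise ValueError(f"{assay}: non_expressed training class is empty")
            self._kdes[assay] = {
                "expressed": stats.gaussian_kde(exp, bw_method="silverman"),
                "non_expressed": stats.gaussian_kde(non, bw_method="silverman")}

    @property
    def assays(self):
        return sorted(self._kdes)

    def log_bayes_factor(self, assay: str, enrichment: float) -> float:
        """log f_expressed(x) / f_non_expressed(x) at one enrichment value."""
        x = math.log1p(max(float(enrichment), 0.0))
        kde = self._kdes[assay]
        fe = max(float(kde["expressed"](x)[0]), DENSITY_FLOOR)
        fn = max(float(kde["non_expressed"](x)[0]), DENSITY_FLOOR)
        return math.log(fe / fn)

    def _log_bf_vec(self, assay: str, enrichment: np.ndarray) -> np.ndarray:
        x = np.log1p(np.maximum(np.asarray(enrichment, dtype=float), 0.0))
        kde = self._kdes[assay]
        fe = np.maximum(kde["expressed"](x), DENSITY_FLOOR)
        fn = np.maximum(kde["non_expressed"](x), DENSITY_FLOOR)
        return np.log(fe / fn)

    # -- serialization (versioned text format) -----------------------------

    def to_json(self) -> str:
        payload = {"format_version": MODEL_FORMAT_VERSION,
                   "expressed_threshold": self.expressed_threshold,
                   "training_genes": self.training_genes,
                   "training_values": {
                       a: {c: [round(float(v), 10) for v in vals]
                           for c, vals in classes.items()}
                       for a, classes in self.training_values.items()}}
        body = json.dumps(payload, sort_keys=True)
        digest = hashlib.sha256(body.encode()).hexdigest()
        payload["content_hash"] = digest
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "BayesFactorModel":
        payload = json.loads(text)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        return cls(payload["training_values"],
                   payload["expressed_threshold"],
                   payload.get("training_genes"))


def fit_bayes_factor_model(train_densities: pd.DataFrame,
                           train_fpkm: pd.DataFrame,
                           expressed_threshold: float = EXPRESSED_FPKM,
                           ) -> BayesFactorModel:
    """Fit per-assay reference distributions from composite densities.

    ``train_densities``: one row per gene, ``gene_id`` plus one
    composite-density column per assay.  ``train_fpkm``: ``gene_id,
    fpkm``.  Genes with FPKM above the threshold form the expressed
    class; an empty class is an error naming the class.
    """
    merged = train_densities.merge(train_fpkm[["gene_id", "fpkm"]],
                                   on="gene_id", validate="one_to_one")
    expressed = merged["fpkm"] > expressed_threshold
    if not expressed.any():
        raise ValueError("expressed training class is empty")
    if expressed.all():
        raise ValueError("non_expressed training class is empty")
    assay_cols = [c for c in train_densities.columns if c != "gene_id"]
    training_values = {}
    for assay in assay_cols:
        vals = merged[assay].to_numpy(dtype=float) / 2.0  # single-allele scale
        ok = ~np.isnan(vals)
        training_values[assay] = {
            "expressed": np.log1p(vals[ok & expressed.to_numpy()]).tolist(),
            "non_expressed": np.log1p(vals[ok & ~expressed.to_numpy()]).tolist()}
        if not training_values[assay]["expressed"]:
            raise ValueError(f"{assay}: expressed training class is empty")
        if not training_values[assay]["non_expressed"]:
            raise ValueError(f"{assay}: non_expressed training class is empty")
    # training values are stored in log1p space; queries are log1p-transformed
    training_values = {a: {c: list(np.round(v, 12)) for c, v in cl.items()}
                       for a, cl in training_values.items()}
    return BayesFactorModel(training_values, expressed_threshold,
                            training_genes=merged["gene_id"].tolist())


def allele_bayes_factor(model: BayesFactorModel, densities: dict):
    """Summed log Bayes factor for one allele.

    ``densities`` maps assay -> enrichment (NaN/missing skipped).
    Returns (sum, n_assays_used); no defined assay -> (nan, 0).
    """
    total, used = 0.0, 0
    for assay in model.assays:
        x = densities.get(assay)
        if x is None or (isinstance(x, float) and math.isnan(x)):
            continue
        # model stores log1p-space training samples; evaluate directly
        kde = model._kdes[assay]
        xv = math.log1p(max(float(x), 0.0))
        fe = max(float(kde["expressed"](xv)[0]), DENSITY_FLOOR)
        fn = max(float(kde["non_expressed"](xv)[0]), DENSITY_FLOOR)
        total += math.log(fe / fn)
        used += 1
    if used == 0:
        return float("nan"), 0
    return total, used


def predict_expression_skew(model: BayesFactorModel,
                            allelic_densities: pd.DataFrame) -> pd.DataFrame:
    """Per-gene predicted allelic expression skew.

    ``allelic_densities``: one row per gene with ``gene_id`` and
    ``<assay>_mus`` / ``<assay>_cas`` inferred allelic density columns.
    predicted_skew = bf_mus - bf_cas, signed like log2(mus:cas).  Genes
    with one allele entirely missing are skipped.
    """
    n = len(allelic_densities)
    bf = {"mus": np.zeros(n), "cas": np.zeros(n)}
    used = {"mus": np.zeros(n, dtype=int), "cas": np.zeros(n, dtype=int)}
    for assay in model.assays:
        for allele in ("mus", "cas"):
            col = f"{assay}_{allele}"
            if col not in allelic_densities.columns:
                continue
            vals = allelic_densities[col].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            if ok.any():
                bf[allele][ok] += model._log_bf_vec(assay, vals[ok])
                used[allele][ok] += 1
    keep = (used["mus"] > 0) & (used["cas"] > 0)
    out = pd.DataFrame({
        "gene_id": allelic_densities["gene_id"],
        "bf_mus": np.where(used["mus"] > 0, bf["mus"], np.nan),
        "bf_cas": np.where(used["cas"] > 0, bf["cas"], np.nan),
        "n_assays_mus": used["mus"], "n_assays_cas": used["cas"]})
    out["predicted_skew"] = out["bf_mus"] - out["bf_cas"]
    return out[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# linear-model evaluation

def _ols_fit_predict(x_train, y_train, x_test):
    xt = np.column_stack([np.ones(len(x_train)), x_train])
    xs = np.column_stack([np.ones(len(x_test)), x_test])
    beta, *_ = np.linalg.lstsq(xt, y_train, rcond=None)
    return xs @ beta


def linear_cv_model(predictors: pd.DataFrame, observed: np.ndarray,
                    folds: int = 2, repeats: int = 25,
                    seed: int = 0) -> dict:
    """Cross-validated linear prediction of expression skew.

    Least-squares fit (pseudo-inverse, rank-deficiency tolerated) on
    each training fold, Pearson r on the held-out fold, averaged over
    folds and repeats.  Returns ``{"mean_r", "per_fold_r"}``.
    """
    x = predictors.to_numpy(dtype=float)
    y = np.asarray(observed, dtype=float)
    ok = ~(np.isnan(x).any(axis=1) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(y) < 10:
        raise ValueError("need >= 10 genes with all predictors defined")
    rng = np.random.default_rng(seed)
    per_fold = []
    for _ in range(repeats):
        order = rng.permutation(len(y))
        fold_of = np.arange(len(y)) % folds
        fold_of = fold_of[np.argsort(order, kind="stable")]
        for f in range(folds):
            test = fold_of == f
            pred = _ols_fit_predict(x[~test], y[~test], x[test])
            if np.std(pred) == 0 or np.std(y[test]) == 0:
                per_fold.append(0.0)
            else:
                per_fold.append(float(np.corrcoef(pred, y[test])[0, 1]))
    return {"mean_r": float(np.mean(per_fold)), "per_fold_r": per_fold}


def _r2(x, y):
    pred = _ols_fit_predict(x, y, x)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def variance_decomposition(predictors: pd.DataFrame, observed,
                           order=("K4me3", "K36me3", "POL2S2", "K27me3"),
                           ) -> pd.DataFrame:
    """Individual R-squared per mark and sequential increments.

    Row ``individual``: R-squared of each single-predictor model.  Row
    ``increment``: gain from adding each mark in the stated order; the
    increments telescope to the full-model R-squared exactly.
    """
    order = [m for m in order if m in predictors.columns]
    x_all = predictors[list(order)].to_numpy(dtype=float)
    y = np.asarray(observed, dtype=float)
    ok = ~(np.isnan(x_all).any(axis=1) | np.isnan(y))
    x_all, y = x_all[ok], y[ok]
    if len(y) < 10:
        raise ValueError("need >= 10 genes with all predictors defined")
    individual, increments = [], []
    prev = 0.0
    for i, _mark in enumerate(order):
        individual.append(_r2(x_all[:, [i]], y))
        cum = _r2(x_all[:, :i + 1], y)
        increments.append(cum - prev)
        prev = cum
    out = pd.DataFrame([individual, increments],
                       index=["individual", "increment"], columns=list(order))
    out["full_model_r2"] = [prev, prev]
    return out


def roc_over_cutoffs(predicted: dict, observed_skewed,
                     cutoffs=ROC_CUTOFFS) -> dict:
    """ROC sweep of |predicted skew| cutoffs against observed calls.

    ``predicted`` maps predictor-set name -> predicted skew array;
    ``observed_skewed`` is the boolean observed classification.  For
    each predictor returns the (cutoff, tpr, fpr) table and trapezoid
    AUC; AUC is NaN when either class is empty.
    """
    obs = np.asarray(observed_skewed, dtype=bool)
    n_pos, n_neg = int(obs.sum()), int((~obs).sum())
    results = {}
    for name, pred in predicted.items():
        p = np.abs(np.asarray(pred, dtype=float))
        rows = []
        for c in cutoffs:
            called = p >= c
            tpr = float((called & obs).sum() / n_pos) if n_pos else float("nan")
            fpr = float((called & ~obs).sum() / n_neg) if n_neg else float("nan")
            rows.append((float(c), tpr, fpr))
        table = pd.DataFrame(rows, columns=["cutoff", "tpr", "fpr"])
        if n_pos == 0 or n_neg == 0:
            auc = float("nan")
        else:
            fpr_pts = np.concatenate([[0.0], table["fpr"].to_numpy()[::-1], [1.0]])
            tpr_pts = np.concatenate([[0.0], table["tpr"].to_numpy()[::-1], [1.0]])
            auc = float(np.trapezoid(tpr_pts, fpr_pts))
        results[name] = {"table": table, "auc": auc}
    return results


def discordance_census(predicted_skew, predicted_called,
                       observed_skew, observed_called) -> pd.Series:
    """Partition evaluated genes into four concordance classes.

    concordant: same call (both null, or both skewed with matching
    sign); anticorrelated: both skewed, opposite sign; chromatin_only:
    predicted-skewed, observed-null; expression_only: observed-skewed,
    predicted-null.
    """
    ps = np.asarray(predicted_skew, dtype=float)
    os_ = np.asarray(observed_skew, dtype=float)
    pc = np.asarray(predicted_called, dtype=bool)
    oc = np.asarray(observed_called, dtype=bool)
    cls = np.where(pc & oc & (np.sign(ps) == np.sign(os_)), "concordant",
                   np.where(pc & oc, "anticorrelated",
                            np.where(pc & ~oc, "chromatin_only",
                                     np.where(~pc & oc, "expression_only",
                                              "concordant"))))
    return pd.Series(cls).value_counts().reindex(
        ["concordant", "anticorrelated", "chromatin_only", "expression_only"],
        fill_value=0)


def qpcr_fold_difference(ct_mus: float, ct_cas: float) -> float:
    """Fold difference as printed: 2**(Ct_mus - Ct_cas).

    Note the likely inverted sign convention relative to expression
    (a lower Ct means more transcript); see :func:`qpcr_fold_report`
    for the companion conventional value.
    """
    if not (math.isfinite(ct_mus) and math.isfinite(ct_cas)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (ct_mus - ct_cas)


def qpcr_fold_report(ct_mus: float, ct_cas: float) -> dict:
    """Both sign conventions of the qPCR fold difference, with a note."""
    return {"fold_difference": qpcr_fold_difference(ct_mus, ct_cas),
            "fold_difference_conventional": 2.0 ** (ct_cas - ct_mus),
            "note": ("fold_difference follows the printed formula "
                     "2^(Ct_mus - Ct_cas); the conventional delta-Ct "
                     "expression ratio is 2^(Ct_cas - Ct_mus)")}
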