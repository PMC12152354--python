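"""Per-gene negative-binomial GLM association engine.

Serves two roles with one statistic contract:

* ``de_condition`` — differential expression of pseudobulk counts on a BMI
  group contrast or continuous BMI, per (cell_type, side) stratum, with
  sample-level covariates and a log-library-size offset;
* ``twas_phenotype`` — transcriptome-wide association of bulk expression
  (outcome) on a standardized phenotype score (predictor) with subject-level
  covariates; the per-gene signed Wald z doubles as a signature weight.

The model is a log-link NB GLM with fixed per-gene dispersion alpha
(variance mu + alpha*mu^2) estimated by method of moments on offset-adjusted
counts. Wald p-values use the normal reference. No shrinkage, independent
filtering, or outlier replacement: the downstream consumers need only a
per-gene signed statistic, and a simple estimator is transparent and
testable at the cost of some power.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import DesignMatrixError, ValidationError
from .qc import PseudobulkMatrix

log = logging.getLogger(__name__)

__all__ = [
    "bh_fdr",
    "estimate_dispersion",
    "fit_gene_glm",
    "build_design",
    "de_condition",
    "twas_phenotype",
    "NBAssociation",
]

ALPHA_FLOOR = 1e-8
ALPHA_CEIL = 10.0

DE_COLUMNS = ["gene_id", "coef", "se", "stat", "p", "fdr", "base_mean", "n_obs", "converged"]

LOG2E = np.log2(np.e)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def estimate_dispersion(y: np.ndarray, offset: np.ndarray | None = None) -> float:
    """Method-of-moments NB dispersion on offset-adjusted counts.

    alpha = max((s^2 - ybar) / ybar^2, floor), clipped to [1e-8, 10].
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValidationError(f"need >= 3 observations to estimate dispersion, got {len(y)}")
    if offset is not None:
        offset = np.asarray(offset, dtype=float)
        y = y * np.exp(offset.mean() - offset)
    ybar = y.mean()
    if ybar <= 0:
        return ALPHA_FLOOR
    s2 = y.var(ddof=1)
    alpha = (s2 - ybar) / ybar**2
    return float(np.clip(max(alpha, ALPHA_FLOOR), ALPHA_FLOOR, ALPHA_CEIL))


def fit_gene_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    coef_index: int = 1,
) -> dict:
    """NB GLM (log link, fixed alpha) of one gene; Wald test of one coefficient.

    Returns coef (natural-log scale), se, stat, p, converged. On
    non-convergence or separation the statistic and p are missing.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    offset = np.asarray(offset, dtype=float)
    if not (len(y) == X.shape[0] == len(offset)):
        raise ValidationError("y, X and offset must have equal length")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DesignMatrixError(_aliased_message(X))
    out = {"coef": np.nan, "se": np.nan, "stat": np.nan, "p": np.nan, "converged": False}
    if np.all(y == y[0]) and y[0] == 0:
        return out
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset)
            res = model.fit(maxiter=50, tol=1e-8, scale=1.0)
    except Exception:
        return out
    converged = bool(getattr(res, "converged", True))
    coef = res.params[coef_index]
    se = res.bse[coef_index]
    if not converged or not np.isfinite(coef) or not np.isfinite(se) or se <= 0 or se > 1e3:
        return out
    stat = coef / se
    from scipy.stats import norm

    out.update(
        coef=float(coef), se=float(se), stat=float(stat), p=float(2 * norm.sf(abs(stat))), converged=True
    )
    return out


def build_design(
    meta: pd.DataFrame,
    predictor: str,
    covariates: list[str],
    standardize_numeric: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, predictor, covariates...].

    Categorical covariates are one-hot encoded with the lexicographically
    first level as reference, so designs are deterministic. Numeric
    covariates are standardized (ddof=1) when requested.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(meta))}
    cols[predictor] = meta[predictor].to_numpy(dtype=float)
    for cov in covariates:
        if cov not in meta.columns:
            raise ValidationError(f"covariate {cov!r} missing from metadata")
        col = meta[cov]
        if np.issubdtype(col.dtype, np.number):
            v = col.to_numpy(dtype=float)
            if standardize_numeric:
                sd = v.std(ddof=1)
                if sd > 0:
                    v = (v - v.mean()) / sd
            cols[cov] = v
        else:
            levels = sorted(col.astype(str).unique())
            for lvl in levels[1:]:
                cols[f"{cov}[{lvl}]"] = (col.astype(str) == lvl).to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignMatrixError(_aliased_message(X, names))
    return X, names


def _aliased_message(X: np.ndarray, names: list[str] | None = None) -> str:
    names = names or [f"col{j}" for j in range(X.shape[1])]
    aliased = []
    for k in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : k + 1]) < k + 1:
            aliased.append(names[k])
    return f"rank-deficient design; aliased columns: {aliased}"


def _fit_table(
    counts: pd.DataFrame,
    X: np.ndarray,
    offset: np.ndarray,
    coef_index: int = 1,
) -> pd.DataFrame:
    """Fit every gene (row of counts) and assemble a DETable."""
    rows = []
    mat = counts.to_numpy()
    norm_mean = (mat / np.exp(offset)[None, :]).mean(axis=1)
    for i, gene in enumerate(counts.index):
        y = mat[i]
        alpha = estimate_dispersion(y, offset)
        fit = fit_gene_glm(y, X, offset, alpha, coef_index=coef_index)
        rows.append(
            {
                "gene_id": gene,
                "coef": fit["coef"] * LOG2E,  # report log2 fold change per unit predictor
                "se": fit["se"] * LOG2E,
                "stat": fit["stat"],
                "p": fit["p"],
                "base_mean": norm_mean[i] * np.exp(offset.mean()),
                "n_obs": len(y),
                "converged": fit["converged"],
                "alpha": alpha,
            }
        )
    de = pd.DataFrame(rows)
    de["fdr"] = np.nan
    ok = de["p"].notna()
    if ok.any():
        de.loc[ok, "fdr"] = bh_fdr(de.loc[ok, "p"].to_numpy())
    return de


def de_condition(
    pb: PseudobulkMatrix,
    samples: pd.DataFrame,
    predictor: str = "group",
    covariates: list[str] | None = None,
    min_samples: int = 3,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-stratum differential expression by BMI group or continuous BMI.

    predictor 'group' contrasts MO vs lean (samples labelled 'other' are
    dropped); 'bmi_continuous' uses standardized BMI. Offsets are the log
    total pseudobulk counts per sample within the stratum. BH-FDR is applied
    within each stratum.
    """
    covariates = covariates or []
    results: dict[tuple[str, str], pd.DataFrame] = {}
    for key, counts in pb.strata.items():
        meta = samples.loc[[s for s in counts.columns if s in samples.index]].copy()
        if predictor == "group":
            meta = meta[meta["group"].isin(["lean", "MO"])]
            meta["_pred"] = (meta["group"] == "MO").astype(float)
        elif predictor == "bmi_continuous":
            v = meta["bmi"].to_numpy(dtype=float)
            meta["_pred"] = (v - v.mean()) / v.std(ddof=1)
        else:
            raise ValidationError(f"unknown predictor {predictor!r}")
        counts = counts[list(meta.index)]
        if len(meta) < min_samples:
            log.warning("stratum %s skipped: %d samples < %d", key, len(meta), min_samples)
            continue
        X, _ = build_design(meta, "_pred", covariates)
        totals = counts.sum(axis=0).to_numpy(dtype=float)
        offset = np.log(totals)
        results[key] = _fit_table(counts, X, offset)
    return results


def twas_phenotype(
    bulk: pd.DataFrame,
    phenotypes: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Transcriptome-wide NB-GLM of expression on a standardized outcome.

    Subjects with a missing outcome are dropped (count logged). The reported
    coefficient is the outcome's; offset = log library size.
    """
    covariates = covariates or []
    meta = phenotypes.loc[[s for s in bulk.columns if s in phenotypes.index]].copy()
    n_missing = int(meta[outcome].isna().sum())
    if n_missing:
        log.warning("dropping %d subjects with missing %s", n_missing, outcome)
        meta = meta[meta[outcome].notna()]
    v = meta[outcome].to_numpy(dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValidationError(f"outcome {outcome!r} is constant")
    meta["_pred"] = (v - v.mean()) / sd
    counts = bulk[list(meta.index)]
    X, _ = build_design(meta, "_pred", covariates)
    offset = np.log(counts.sum(axis=0).to_numpy(dtype=float))
    return _fit_table(counts, X, offset)


class NBAssociation(BaseEstimator):
    """Sklearn-style facade over the per-gene NB-GLM engine.

    Parameters mirror the functional API; ``fit(counts, meta)`` runs the scan
    for a genes x observations count frame and observation metadata, leaving
    the association table in ``results_``.
    """

    def __init__(self, predictor: str = "_pred", covariates: tuple[str, ...] = ()):
        self.predictor = predictor
        self.covariates = covariates

    def fit(self, counts: pd.DataFrame, meta: pd.DataFrame):
        meta = meta.loc[list(counts.columns)].copy()
        X, names = build_design(meta, self.predictor, list(self.covariates))
        offset = np.log(counts.sum(axis=0).to_numpy(dtype=float))
        self.design_columns_ = names
        self.results_ = _fit_table(counts, X, offset)
        return self
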