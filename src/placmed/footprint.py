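"""Linear-model footprint scoring of gene programs.

A *program* is a signed gene-weight vector (e.g. a hypoxia response
signature, or a derived neurobehavioral-impairment signature). Its activity
in an expression profile (or its enrichment in a vector of per-gene
differential-expression statistics) is inferred by regressing the profile on
the weights:

* ``ulm`` — one program per regression: OLS of x_g on (1, w_g) over the gene
  intersection; the score is the t-value of the slope (df = n - 2).
* ``mlm`` — all programs jointly: OLS of x_g on intercept + all weight
  columns; score_k is the t-value of coefficient k (df = n - K - 1).

Scores below ``min_overlap`` shared genes are missing (NaN) with a recorded
reason, never silently zero. Perfect fits (SSR < 1e-12) return signed
infinity with p = 0.

``derive_signature_weights`` turns an association table into a program:
the top-n genes by p-value, weighted by their signed test statistic — the
transfer device that moves a phenotype association from a bulk cohort onto
single nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DesignMatrixError, ValidationError
from .io import WeightMatrix

__all__ = [
    "ActivityMatrix",
    "ulm_score",
    "mlm_score",
    "score_matrix",
    "enrich_de",
    "enrich_de_strata",
    "derive_signature_weights",
    "summarize_by_celltype",
    "FootprintScorer",
]

PERFECT_FIT_SSR = 1e-12

REASON_OVERLAP = "insufficient overlap"
REASON_DEGENERATE = "degenerate weights"


@dataclass
class ActivityMatrix:
    """Observations x programs activity scores with p-values.

    ``scores``/``p`` are observations x programs DataFrames; ``n_used`` gives
    genes used per program; ``reasons`` records why a score is missing.
    ``fdr`` is filled only where a caller applies multiple-testing correction
    (enrichment mode), not for descriptive per-nucleus scores.
    """

    scores: pd.DataFrame
    p: pd.DataFrame
    n_used: pd.Series
    reasons: dict[str, str] = field(default_factory=dict)
    fdr: pd.DataFrame | None = None

    @property
    def programs(self) -> list[str]:
        return list(self.scores.columns)

    def to_long(self) -> pd.DataFrame:
        s = self.scores.rename_axis("observation").reset_index().melt(
            id_vars="observation", var_name="program", value_name="score"
        )
        p = self.p.rename_axis("observation").reset_index().melt(
            id_vars="observation", var_name="program", value_name="p"
        )
        long = s.merge(p, on=["observation", "program"], validate="1:1")
        long["n_used"] = long["program"].map(self.n_used)
        return long


# ---------------------------------------------------------------------------
# core scorers
# ---------------------------------------------------------------------------


def _t_sf(t: np.ndarray, df: int) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(t), df)


def ulm_score(
    x: pd.Series, w: pd.Series, min_overlap: int = 5
) -> tuple[float, float, int, str | None]:
    """Univariate linear-model score of one program in one profile.

    Returns (score, p, n_used, reason); score/p are NaN when the gene overlap
    is below ``min_overlap`` or the weights are constant on the overlap.
    Explicit zero weights in ``w`` participate in the regression; genes absent
    from ``w`` do not (so adding unweighted genes to ``x`` changes nothing).
    """
    x = x.dropna()
    common = x.index.intersection(w.index)
    n = len(common)
    if n < min_overlap:
        return (np.nan, np.nan, n, REASON_OVERLAP)
    xv = x.loc[common].to_numpy(dtype=float)
    wv = w.loc[common].to_numpy(dtype=float)
    score, p = _ulm_core(xv[:, None], wv)
    return (float(score[0]), float(p[0]), n, None if np.isfinite(score[0]) or np.isinf(score[0]) else REASON_DEGENERATE)


def _ulm_core(X: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized simple regression of each column of X (genes x obs) on w.

    Returns (t-scores, p) per observation. Degenerate weights -> NaN.
    """
    n = len(w)
    wc = w - w.mean()
    sxx = float(wc @ wc)
    if sxx <= 0:
        k = X.shape[1]
        return np.full(k, np.nan), np.full(k, np.nan)
    xbar = X.mean(axis=0)
    slope = (wc @ X) / sxx
    # SSR = total SS - slope^2 * Sxx
    tss = (X * X).sum(axis=0) - n * xbar**2
    explained = slope**2 * sxx
    ssr = np.maximum(tss - explained, 0.0)
    df = n - 2
    zero_slope = explained < PERFECT_FIT_SSR  # no signal at float precision
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(ssr / df / sxx)
        t = np.where(zero_slope, 0.0, slope / se)
    perfect = ssr < PERFECT_FIT_SSR
    with np.errstate(invalid="ignore"):
        t = np.where(perfect & ~zero_slope, np.sign(slope) * np.inf, t)
    p = np.where(perfect, 0.0, _t_sf(np.where(np.isfinite(t), t, 0.0), df))
    # zero slope: score 0; p is 1 when the fit is also perfect (no evidence at all)
    p = np.where(perfect & zero_slope, 1.0, p)
    t = np.where(perfect & zero_slope, 0.0, t)
    return t, p


def mlm_score(
    y: pd.Series, W: WeightMatrix | pd.DataFrame, min_overlap: int = 5
) -> pd.DataFrame:
    """Multivariate linear-model scores of all programs jointly in one profile.

    Returns a DataFrame indexed by program with columns score, p, n_used.
    Raises DesignMatrixError when the weight columns are collinear.
    """
    wide = W.to_wide() if isinstance(W, WeightMatrix) else W
    y = y.dropna()
    common = y.index.intersection(wide.index)
    n = len(common)
    if n < min_overlap:
        return pd.DataFrame(
            {"score": np.nan, "p": np.nan, "n_used": n, "reason": REASON_OVERLAP},
            index=wide.columns.rename("program"),
        )
    yv = y.loc[common].to_numpy(dtype=float)
    Wv = wide.loc[common].to_numpy(dtype=float)
    scores, p = _mlm_core(yv[:, None], Wv, list(wide.columns))
    return pd.DataFrame(
        {"score": scores[:, 0], "p": p[:, 0], "n_used": n, "reason": None},
        index=pd.Index(wide.columns, name="program"),
    )


def _mlm_core(
    Y: np.ndarray, W: np.ndarray, program_names: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Joint regression of each column of Y (genes x obs) on [1, W].

    Returns (K x obs scores, K x obs p). Raises on rank deficiency, naming
    the collinear programs.
    """
    n, K = W.shape
    D = np.column_stack([np.ones(n), W])
    rank = np.linalg.matrix_rank(D)
    if rank < K + 1:
        bad = _collinear_columns(D, program_names)
        raise DesignMatrixError(f"collinear program weight columns: {bad}")
    df = n - K - 1
    if df <= 0:
        raise DesignMatrixError(f"not enough genes ({n}) for {K} programs")
    Q, R = np.linalg.qr(D)
    B = np.linalg.solve(R, Q.T @ Y)  # (K+1) x obs
    resid = Y - D @ B
    ssr = (resid * resid).sum(axis=0)
    XtX_inv_diag = np.sum(np.linalg.inv(R) ** 2, axis=1)  # diag of (D'D)^-1
    col_ss = (D * D).sum(axis=0)
    # a coefficient's contribution to the fit is negligible at float precision
    zero_coef = (B**2 * col_ss[:, None]) < PERFECT_FIT_SSR
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = ssr / df
        se = np.sqrt(np.outer(XtX_inv_diag, sigma2))
        t = np.where(zero_coef, 0.0, B / se)
    perfect = ssr < PERFECT_FIT_SSR
    coefs = B[1:]
    tt = t[1:]
    zc = zero_coef[1:]
    with np.errstate(invalid="ignore"):
        tt = np.where(perfect[None, :] & ~zc, np.sign(coefs) * np.inf, tt)
    p = np.where(
        perfect[None, :],
        np.where(zc, 1.0, 0.0),
        _t_sf(np.where(np.isfinite(tt), tt, 0.0), df),
    )
    tt = np.where(perfect[None, :] & zc, 0.0, tt)
    return tt, p


def _collinear_columns(D: np.ndarray, names: list[str]) -> list[str]:
    """Identify weight columns aliased with earlier columns (QR pivot scan)."""
    bad = []
    for k in range(1, D.shape[1]):
        sub = D[:, : k + 1]
        if np.linalg.matrix_rank(sub) < sub.shape[1]:
            bad.append(names[k - 1])
    return bad


# ---------------------------------------------------------------------------
# matrix-level scoring and enrichment
# ---------------------------------------------------------------------------


def score_matrix(
    norm_expr: pd.DataFrame | sp.spmatrix,
    W: WeightMatrix,
    gene_ids: list[str] | None = None,
    obs_ids: list[str] | None = None,
    method: str = "ulm",
    min_overlap: int = 5,
) -> ActivityMatrix:
    """Score every observation (column) of a genes x observations matrix.

    ``norm_expr`` is typically the log1p-CP10K matrix; any real matrix works.
    With ``method='ulm'`` each program is scored independently (the default,
    used for per-nucleus activity scores); ``'mlm'`` fits all programs jointly.
    """
    if isinstance(norm_expr, pd.DataFrame):
        gene_ids = list(norm_expr.index)
        obs_ids = list(norm_expr.columns)
        get_rows = lambda rows: norm_expr.to_numpy()[rows]  # noqa: E731
    else:
        if gene_ids is None or obs_ids is None:
            raise ValidationError("gene_ids and obs_ids required for sparse input")
        csr = norm_expr.tocsr()
        get_rows = lambda rows: np.asarray(csr[rows, :].todense())  # noqa: E731
    pos = {g: i for i, g in enumerate(gene_ids)}

    if method not in ("ulm", "mlm"):
        raise ValidationError(f"unknown scoring method {method!r}")

    n_obs = len(obs_ids)
    programs = W.programs
    scores = pd.DataFrame(np.nan, index=pd.Index(obs_ids, name="observation"), columns=programs)
    pvals = scores.copy()
    n_used = pd.Series(0, index=pd.Index(programs, name="program"), dtype=int)
    reasons: dict[str, str] = {}

    if method == "ulm":
        for prog in programs:
            w = W.program_weights(prog)
            common = [g for g in w.index if g in pos]
            n_used[prog] = len(common)
            if len(common) < min_overlap:
                reasons[prog] = REASON_OVERLAP
                continue
            X = get_rows([pos[g] for g in common])  # n_genes_int x n_obs
            t, p = _ulm_core(X, w.loc[common].to_numpy(dtype=float))
            if np.all(np.isnan(t)):
                reasons[prog] = REASON_DEGENERATE
            scores[prog] = t
            pvals[prog] = p
    else:
        wide = W.to_wide()
        common = [g for g in wide.index if g in pos]
        if len(common) < min_overlap:
            for prog in programs:
                reasons[prog] = REASON_OVERLAP
            return ActivityMatrix(scores, pvals, n_used, reasons)
        Y = get_rows([pos[g] for g in common])
        t, p = _mlm_core(Y, wide.loc[common].to_numpy(dtype=float), programs)
        for i, prog in enumerate(programs):
            scores[prog] = t[i]
            pvals[prog] = p[i]
            n_used[prog] = len(common)
    return ActivityMatrix(scores, pvals, n_used, reasons)


def enrich_de(
    de: pd.DataFrame,
    W: WeightMatrix,
    method: str = "mlm",
    min_overlap: int = 5,
    stat_col: str = "stat",
) -> pd.DataFrame:
    """Score programs against one differential-expression statistic vector.

    Returns a per-program DataFrame (score, p, n_used, reason). The caller is
    responsible for FDR across strata; see :func:`enrich_de_strata`.
    """
    x = pd.Series(de[stat_col].to_numpy(), index=de["gene_id"].to_numpy()).dropna()
    if method == "mlm":
        return mlm_score(x, W, min_overlap=min_overlap)
    rows = []
    for prog in W.programs:
        score, p, n, reason = ulm_score(x, W.program_weights(prog), min_overlap=min_overlap)
        rows.append({"program": prog, "score": score, "p": p, "n_used": n, "reason": reason})
    return pd.DataFrame(rows).set_index("program")


def enrich_de_strata(
    de_tables: dict[tuple[str, str], pd.DataFrame],
    W: WeightMatrix,
    method: str = "mlm",
    min_overlap: int = 5,
) -> pd.DataFrame:
    """Enrichment across every (cell_type, side) stratum with BH-FDR over the
    full stratum x program grid."""
    from .diffexp import bh_fdr

    rows = []
    for (ct, side), de in de_tables.items():
        res = enrich_de(de, W, method=method, min_overlap=min_overlap)
        res = res.reset_index()
        res.insert(0, "cell_type", ct)
        res.insert(1, "side", side)
        rows.append(res)
    out = pd.concat(rows, ignore_index=True)
    ok = out["p"].notna()
    out["fdr"] = np.nan
    out.loc[ok, "fdr"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# signature derivation and summaries
# ---------------------------------------------------------------------------


def derive_signature_weights(
    de: pd.DataFrame, program_name: str, top_n: int = 500
) -> WeightMatrix:
    """Select the top-n genes by p (ties: larger |stat|, then gene id) and use
    the signed test statistic as the program weight."""
    ok = de[de.get("converged", True) & de["p"].notna() & de["stat"].notna()].copy()
    if not len(ok):
        raise ValidationError("no converged genes to derive a signature from")
    ok["_abs"] = -ok["stat"].abs()
    ok = ok.sort_values(["p", "_abs", "gene_id"], kind="mergesort")
    sel = ok.head(min(top_n, len(ok)))
    return WeightMatrix(
        pd.DataFrame(
            {"program": program_name, "gene": sel["gene_id"].to_numpy(), "weight": sel["stat"].to_numpy()}
        )
    )


def summarize_by_celltype(am: ActivityMatrix, nucleus_meta: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary of each program per cell type, ranked by median."""
    ct = nucleus_meta.loc[am.scores.index, "cell_type"]
    rows = []
    for prog in am.programs:
        s = am.scores[prog]
        for cell_type, vals in s.groupby(ct.to_numpy()):
            v = vals.dropna().to_numpy()
            rows.append(
                {
                    "program": prog,
                    "cell_type": cell_type,
                    "n": len(v),
                    "min": np.min(v) if len(v) else np.nan,
                    "q1": np.percentile(v, 25) if len(v) else np.nan,
                    "median": np.median(v) if len(v) else np.nan,
                    "q3": np.percentile(v, 75) if len(v) else np.nan,
                    "max": np.max(v) if len(v) else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out["rank_by_median"] = out.groupby("program")["median"].rank(ascending=False, method="min").astype(int)
    return out.sort_values(["program", "rank_by_median"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------


class FootprintScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper around the ulm/mlm scorers.

    fit(W) accepts a WeightMatrix (or long DataFrame with program/gene/weight
    columns); transform(X) maps an observations x genes DataFrame to an
    observations x programs score DataFrame. Scores are t-values.
    """

    def __init__(self, method: str = "ulm", min_overlap: int = 5):
        self.method = method
        self.min_overlap = min_overlap

    def fit(self, W, y=None):
        if isinstance(W, pd.DataFrame):
            W = WeightMatrix(W)
        if not isinstance(W, WeightMatrix):
            raise ValidationError("fit expects a WeightMatrix or long weight DataFrame")
        self.weights_ = W
        self.programs_ = W.programs
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "weights_"):
            raise ValidationError("FootprintScorer is not fitted")
        am = score_matrix(X.T, self.weights_, method=self.method, min_overlap=self.min_overlap)
        self.activity_ = am
        return am.scores

    def fit_transform(self, X, W=None, **kwargs):  # X obs x genes, W weights
        # sklearn signature is fit_transform(X, y); here fit consumes weights.
        raise NotImplementedError("call fit(weights) then transform(expression)")
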