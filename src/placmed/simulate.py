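"""Synthetic single-nucleus and bulk cohorts with known causal structure.

The generator emulates the statistical skeleton of a term-placenta
case-control study of maternal obesity (MO): per-sample BMI is bimodal
(lean 18.5-25 vs MO >35) but kept continuous; each nucleus of cell type *k*
carries a latent hypoxia activity

    h_j = h0_k + a_k * z_s + eps_h,     eps_h ~ N(0, sd_h^2)

where ``z_s`` is the standardized BMI of its sample, and a neurobehavioral
impairment (NBI) activity

    m_j = m0_k + b * h_j + c' * z_s + eps_m,   eps_m ~ N(0, sd_m^2)

so the true proportion of the BMI -> NBI association mediated by hypoxia in
cell type k is ``a_k*b / (a_k*b + c')``. With the default a_EVT = 0.8,
b = 0.55, c' = 0.56 the EVT-like type has a true proportion mediated of 0.44.

Counts are negative binomial with per-gene dispersion: the log-mean of gene g
in nucleus j is baseline_g + celltype offset + s_h*w_h(g)*h_j + s_n*w_n(g)*m_j,
renormalized per nucleus and scaled by a log-normal library size. A configured
fraction of nuclei is made to fail QC by construction (few detected genes, or
mitochondrial fraction above threshold). An independent bulk cohort carries
the same two programs with a subject-level phenotype linked to the NBI
activity, so signature weights are recoverable by a transcriptome-wide scan.

One pseudo-random stream per output block (weights, activities, counts, bulk,
covariates, qc) is split from the master seed, so e.g. changing ``n_genes``
does not perturb the latent activities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError, DegenerateModelError
from .io import CountMatrix, WeightMatrix, derive_bmi_group

__all__ = [
    "CellTypeSpec",
    "SimConfig",
    "SyntheticTruth",
    "generate_cohort",
    "true_mediation_proportion",
]


@dataclass(frozen=True)
class CellTypeSpec:
    """One simulated cell type.

    a: BMI->hypoxia slope per SD of BMI; h0/m0: baseline activity intercepts
    (the EVT-like type gets the largest a and the highest NBI intercept,
    mirroring the biology: extravillous trophoblasts are the most
    hypoxia-responsive type and express NBI-associated genes most highly).
    """

    name: str
    proportion: float
    a: float
    h0: float = 0.0
    m0: float = 0.0


DEFAULT_CELL_TYPES = (
    CellTypeSpec("EVT", 0.20, 0.80, h0=0.40, m0=0.80),
    CellTypeSpec("SCT", 0.30, 0.45, h0=0.20, m0=0.20),
    CellTypeSpec("VCT", 0.20, 0.30, h0=0.00, m0=0.10),
    CellTypeSpec("FB", 0.15, 0.15, h0=0.00, m0=0.00),
    CellTypeSpec("Endo", 0.15, 0.05, h0=0.00, m0=0.00),
)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic cohort; defaults define the study conditions."""

    seed: int = 0
    n_samples: int = 20
    nuclei_per_sample: int = 500
    n_genes: int = 2000
    cell_types: tuple[CellTypeSpec, ...] = DEFAULT_CELL_TYPES

    # gene programs
    n_genes_hypoxia: int = 100
    hypoxia_scale: float = 0.75  # s_h: log-mean shift per unit activity per unit weight
    n_genes_nbi: int = 100
    nbi_scale: float = 0.75  # s_n
    program_overlap: float = 0.0  # fraction of NBI genes shared with hypoxia program

    # structural equation model
    b: float = 0.55  # hypoxia -> NBI
    c_prime: float = 0.56  # direct BMI -> NBI
    sd_h: float = 1.0
    sd_m: float = 1.0

    # baseline expression / technical model
    baseline_mean: float = 0.0
    baseline_sd: float = 1.2
    celltype_offset_sd: float = 0.3
    dispersion_median: float = 0.5  # per-gene NB dispersion ~ lognormal, clipped
    dispersion_sigma: float = 0.5
    dispersion_clip: tuple[float, float] = (0.05, 3.0)
    libsize_median: float = 1500.0
    libsize_sigma: float = 0.3
    libsize_min: float = 700.0
    n_mito_genes: int = 13
    mito_fraction: float = 0.015
    qc_fail_fraction: float = 0.05

    # bulk cohort
    n_subjects: int = 200
    bulk_libsize_median: float = 2e5
    bulk_libsize_sigma: float = 0.3
    bulk_dispersion: float = 0.1
    # correlation between subject-level hypoxia and NBI activity. Default 0:
    # the bulk cohort is a clean instrument for NBI weights. Setting it > 0
    # contaminates derived signatures with hypoxia genes (the phenotype then
    # tags both programs), which inflates the apparent mediated proportion —
    # useful as a controlled sensitivity experiment, not as a default.
    bulk_hypoxia_rho: float = 0.0
    phenotype_noise_sd: float = 1.0

    def validate(self) -> None:
        props = np.array([ct.proportion for ct in self.cell_types], dtype=float)
        if abs(props.sum() - 1.0) > 1e-8:
            raise ConfigError(f"cell type proportions sum to {props.sum()}, not 1")
        for name, val in [
            ("n_samples", self.n_samples),
            ("nuclei_per_sample", self.nuclei_per_sample),
            ("n_genes", self.n_genes),
            ("n_subjects", self.n_subjects),
        ]:
            if val <= 0:
                raise ConfigError(f"{name} must be > 0, got {val}")
        for name, val in [
            ("sd_h", self.sd_h),
            ("sd_m", self.sd_m),
            ("phenotype_noise_sd", self.phenotype_noise_sd),
        ]:
            if val < 0:
                raise ConfigError(f"{name} must be >= 0, got {val}")
        if not 0 <= self.qc_fail_fraction < 1:
            raise ConfigError("qc_fail_fraction must be in [0, 1)")
        if not 0 <= self.program_overlap <= 1:
            raise ConfigError("program_overlap must be in [0, 1]")
        n_prog = self.n_genes_hypoxia + self.n_genes_nbi + self.n_mito_genes
        if n_prog > self.n_genes:
            raise ConfigError(
                f"program + mito genes ({n_prog}) exceed n_genes ({self.n_genes})"
            )
        names = [ct.name for ct in self.cell_types]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate cell type names")


@dataclass
class SyntheticTruth:
    """Everything the recovery tests need about the generating model."""

    nuclei: pd.DataFrame  # index barcode: sample_id, cell_type, side, h, m, qc_fail
    gene_weights: pd.DataFrame  # index gene_id: w_h, w_n
    coefficients: pd.DataFrame  # index cell_type: a, b, c_prime, h0, m0, prop_mediated
    bulk: pd.DataFrame  # index subject_id: h, m, plus outcome columns
    config: SimConfig


def true_mediation_proportion(truth: SyntheticTruth, cell_type: str) -> float:
    """a_k*b / (a_k*b + c'); errors on unknown cell type or zero total path."""
    if cell_type not in truth.coefficients.index:
        raise KeyError(cell_type)
    row = truth.coefficients.loc[cell_type]
    total = row["a"] * row["b"] + row["c_prime"]
    if abs(total) < 1e-12:
        raise DegenerateModelError(
            f"total BMI->NBI path for {cell_type} is {total}; proportion undefined"
        )
    return float(row["a"] * row["b"] / total)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_cohort(cfg: SimConfig):
    """Generate (CountMatrix, sample table, bulk matrix, phenotype table,
    truth WeightMatrix, SyntheticTruth). Bit-identical under identical cfg."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_w, rng_act, rng_cnt, rng_bulk, rng_cov, rng_qc = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    gene_ids, mito_idx = _gene_ids(cfg)
    w_h, w_n, hyp_idx, nbi_idx = _program_weights(cfg, rng_w, mito_idx)
    samples = _sample_table(cfg, rng_cov)
    z = samples["bmi_z"].to_numpy()

    # --- nucleus-level latent activities -----------------------------------
    ct_names = [ct.name for ct in cfg.cell_types]
    props = np.array([ct.proportion for ct in cfg.cell_types])
    a_k = {ct.name: ct.a for ct in cfg.cell_types}
    h0 = {ct.name: ct.h0 for ct in cfg.cell_types}
    m0 = {ct.name: ct.m0 for ct in cfg.cell_types}

    n_total = cfg.n_samples * cfg.nuclei_per_sample
    sample_of = np.repeat(np.arange(cfg.n_samples), cfg.nuclei_per_sample)
    ct_of = rng_act.choice(len(ct_names), size=n_total, p=props)
    ct_labels = np.array(ct_names, dtype=object)[ct_of]
    a_vec = np.array([cfg.cell_types[i].a for i in range(len(ct_names))])[ct_of]
    h0_vec = np.array([cfg.cell_types[i].h0 for i in range(len(ct_names))])[ct_of]
    m0_vec = np.array([cfg.cell_types[i].m0 for i in range(len(ct_names))])[ct_of]
    z_vec = z[sample_of]
    h = h0_vec + a_vec * z_vec + cfg.sd_h * rng_act.normal(size=n_total)
    m = m0_vec + cfg.b * h + cfg.c_prime * z_vec + cfg.sd_m * rng_act.normal(size=n_total)

    # --- counts -------------------------------------------------------------
    baseline = rng_cnt.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    baseline[mito_idx] = _mito_baseline(cfg, baseline, mito_idx)
    ct_offsets = rng_cnt.normal(0.0, cfg.celltype_offset_sd, size=(len(ct_names), cfg.n_genes))
    ct_offsets[:, mito_idx] = 0.0
    alpha = np.exp(
        rng_cnt.normal(np.log(cfg.dispersion_median), cfg.dispersion_sigma, size=cfg.n_genes)
    ).clip(*cfg.dispersion_clip)
    libsize = np.maximum(
        np.exp(rng_cnt.normal(np.log(cfg.libsize_median), cfg.libsize_sigma, size=n_total)),
        cfg.libsize_min,
    )

    counts = np.empty((n_total, cfg.n_genes), dtype=np.int32)
    chunk = 1000
    for start in range(0, n_total, chunk):
        idx = slice(start, min(start + chunk, n_total))
        logmu = (
            baseline[None, :]
            + ct_offsets[ct_of[idx]]
            + cfg.hypoxia_scale * np.outer(h[idx], w_h)
            + cfg.nbi_scale * np.outer(m[idx], w_n)
        )
        rel = np.exp(logmu)
        rel /= rel.sum(axis=1, keepdims=True)
        mu = rel * libsize[idx, None]
        lam = rng_cnt.gamma(1.0 / alpha[None, :], alpha[None, :] * mu)
        counts[idx] = rng_cnt.poisson(lam).astype(np.int32)

    # --- constructed QC failures -------------------------------------------
    n_fail = int(round(cfg.qc_fail_fraction * n_total))
    fail_idx = np.sort(rng_qc.choice(n_total, size=n_fail, replace=False))
    for rank, j in enumerate(fail_idx):
        if rank % 2 == 0:  # too few detected genes
            keep = rng_qc.choice(cfg.n_genes, size=150, replace=False)
            mask = np.ones(cfg.n_genes, dtype=bool)
            mask[keep] = False
            counts[j, mask] = 0
        else:  # mitochondrial overload (> threshold by a wide margin)
            non_mito_total = counts[j].sum() - counts[j, mito_idx].sum()
            counts[j, mito_idx] = int(np.ceil(0.01 * max(non_mito_total, 1000)))
    qc_fail = np.zeros(n_total, dtype=bool)
    qc_fail[fail_idx] = True

    barcodes = [f"N{j:05d}" for j in range(n_total)]
    nucleus_meta = pd.DataFrame(
        {
            "sample_id": samples.index.to_numpy()[sample_of],
            "cell_type": ct_labels,
            "side": samples["side"].to_numpy()[sample_of],
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    cm = CountMatrix(
        counts=sp.csr_matrix(counts.T),
        gene_ids=gene_ids,
        gene_names=list(gene_ids),
        barcodes=barcodes,
        nucleus_meta=nucleus_meta,
    )

    # --- bulk cohort --------------------------------------------------------
    h_bulk = rng_bulk.normal(size=cfg.n_subjects)
    rho = cfg.bulk_hypoxia_rho
    m_bulk = rho * h_bulk + np.sqrt(1 - rho**2) * rng_bulk.normal(size=cfg.n_subjects)
    bulk_libsize = np.exp(
        rng_bulk.normal(np.log(cfg.bulk_libsize_median), cfg.bulk_libsize_sigma, size=cfg.n_subjects)
    )
    logmu = (
        baseline[None, :]
        + cfg.hypoxia_scale * np.outer(h_bulk, w_h)
        + cfg.nbi_scale * np.outer(m_bulk, w_n)
    )
    rel = np.exp(logmu)
    rel /= rel.sum(axis=1, keepdims=True)
    mu = rel * bulk_libsize[:, None]
    lam = rng_bulk.gamma(1.0 / cfg.bulk_dispersion, cfg.bulk_dispersion * mu)
    bulk_counts = rng_bulk.poisson(lam).astype(np.int64)
    subject_ids = [f"B{j:04d}" for j in range(cfg.n_subjects)]
    bulk_df = pd.DataFrame(bulk_counts.T, index=pd.Index(gene_ids, name="gene_id"), columns=subject_ids)

    outcomes = {}
    for name, noise in [("sdq3", 1.0), ("sdq5", 1.5), ("aseba5", 1.2)]:
        outcomes[name] = m_bulk + cfg.phenotype_noise_sd * noise * rng_bulk.normal(
            size=cfg.n_subjects
        )
    phenotypes = pd.DataFrame(
        {
            "subject_id": subject_ids,
            **outcomes,
            "maternal_age": rng_cov.uniform(20, 40, size=cfg.n_subjects).round(1),
            "maternal_education": rng_cov.choice(
                ["primary", "secondary", "tertiary"], size=cfg.n_subjects
            ),
            "delivery_mode": rng_cov.choice(["vaginal", "csection"], size=cfg.n_subjects),
            "fetal_sex": rng_cov.choice(["F", "M"], size=cfg.n_subjects),
            "batch": rng_cov.choice(["b1", "b2"], size=cfg.n_subjects),
        }
    ).set_index("subject_id", drop=False)

    # --- truth --------------------------------------------------------------
    truth_weights = WeightMatrix(
        pd.concat(
            [
                pd.DataFrame(
                    {"program": "hypoxia", "gene": [gene_ids[i] for i in hyp_idx], "weight": w_h[hyp_idx]}
                ),
                pd.DataFrame(
                    {"program": "nbi_true", "gene": [gene_ids[i] for i in nbi_idx], "weight": w_n[nbi_idx]}
                ),
            ],
            ignore_index=True,
        )
    )
    coeffs = pd.DataFrame(
        {
            "a": [a_k[n] for n in ct_names],
            "b": cfg.b,
            "c_prime": cfg.c_prime,
            "h0": [h0[n] for n in ct_names],
            "m0": [m0[n] for n in ct_names],
        },
        index=pd.Index(ct_names, name="cell_type"),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = coeffs["a"] * coeffs["b"] + coeffs["c_prime"]
        coeffs["prop_mediated"] = np.where(
            np.abs(denom) < 1e-12, np.nan, coeffs["a"] * coeffs["b"] / denom
        )
    truth = SyntheticTruth(
        nuclei=pd.DataFrame(
            {
                "sample_id": nucleus_meta["sample_id"],
                "cell_type": nucleus_meta["cell_type"],
                "side": nucleus_meta["side"],
                "h": h,
                "m": m,
                "qc_fail": qc_fail,
            },
            index=nucleus_meta.index,
        ),
        gene_weights=pd.DataFrame({"w_h": w_h, "w_n": w_n}, index=pd.Index(gene_ids, name="gene_id")),
        coefficients=coeffs,
        bulk=pd.DataFrame(
            {"h": h_bulk, "m": m_bulk, **outcomes}, index=pd.Index(subject_ids, name="subject_id")
        ),
        config=cfg,
    )
    return cm, samples, bulk_df, phenotypes, truth_weights, truth


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _gene_ids(cfg: SimConfig) -> tuple[list[str], np.ndarray]:
    n_reg = cfg.n_genes - cfg.n_mito_genes
    ids = [f"G{j:05d}" for j in range(n_reg)] + [f"MT-{j + 1}" for j in range(cfg.n_mito_genes)]
    mito_idx = np.arange(n_reg, cfg.n_genes)
    return ids, mito_idx


def _program_weights(cfg: SimConfig, rng: np.random.Generator, mito_idx: np.ndarray):
    eligible = np.setdiff1d(np.arange(cfg.n_genes), mito_idx)
    hyp_idx = np.sort(rng.choice(eligible, size=cfg.n_genes_hypoxia, replace=False))
    n_shared = int(round(cfg.program_overlap * cfg.n_genes_nbi))
    shared = rng.choice(hyp_idx, size=n_shared, replace=False) if n_shared else np.array([], dtype=int)
    remaining = np.setdiff1d(eligible, hyp_idx)
    fresh = rng.choice(remaining, size=cfg.n_genes_nbi - n_shared, replace=False)
    nbi_idx = np.sort(np.concatenate([shared, fresh]).astype(int))
    w_h = np.zeros(cfg.n_genes)
    w_n = np.zeros(cfg.n_genes)
    w_h[hyp_idx] = rng.normal(size=cfg.n_genes_hypoxia)
    w_n[nbi_idx] = rng.normal(size=cfg.n_genes_nbi)
    return w_h, w_n, hyp_idx, nbi_idx


def _sample_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_samples
    sample_ids = [f"S{j:02d}" for j in range(n)]
    # half maternal side, half fetal side; within each side half lean, half MO
    side = np.array(["maternal"] * (n // 2) + ["fetal"] * (n - n // 2), dtype=object)
    bmi = np.empty(n)
    for s in ("maternal", "fetal"):
        idx = np.flatnonzero(side == s)
        n_lean = len(idx) // 2
        bmi[idx[:n_lean]] = rng.uniform(18.5, 25.0, size=n_lean)
        bmi[idx[n_lean:]] = rng.uniform(35.0 + 1e-6, 45.0, size=len(idx) - n_lean)
    df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "bmi": bmi.round(2),
            "maternal_age": rng.uniform(19, 34, size=n).round(1),
            "fetal_sex": rng.choice(["F", "M"], size=n),
            "delivery_mode": rng.choice(["vaginal", "csection"], size=n),
            "batch": np.array(["b1", "b2", "b3"], dtype=object)[np.arange(n) % 3],
            "side": side,
        }
    ).set_index("sample_id", drop=False)
    df["group"] = [derive_bmi_group(b) for b in df["bmi"]]
    df["bmi_z"] = (df["bmi"] - df["bmi"].mean()) / df["bmi"].std(ddof=1)
    return df


def _mito_baseline(cfg: SimConfig, baseline: np.ndarray, mito_idx: np.ndarray) -> float:
    """Baseline for MT- genes so their expected mass fraction is ~mito_fraction."""
    non_mito = np.exp(np.delete(baseline, mito_idx)).sum()
    f = cfg.mito_fraction
    per_gene = f / (1 - f) * non_mito / len(mito_idx)
    return float(np.log(per_gene))


def config_to_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["cell_types"] = [dataclasses.asdict(ct) for ct in cfg.cell_types]
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "cell_types" in d:
        d["cell_types"] = tuple(CellTypeSpec(**ct) for ct in d["cell_types"])
    if "dispersion_clip" in d:
        d["dispersion_clip"] = tuple(d["dispersion_clip"])
    return SimConfig(**d)
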