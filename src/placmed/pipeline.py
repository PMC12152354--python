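"""End-to-end orchestration: simulate -> QC -> pseudobulk -> DE/TWAS ->
signature weights -> scoring -> correlation -> mediation.

One config drives everything; every stochastic stage derives a child seed by
stable hashing of (master seed, stage name), so stages are individually
reproducible and the whole run is deterministic: identical config (including
seed) gives byte-identical stage outputs and manifest hashes.

The manifest (manifest.json) records, per stage, the parameters used, the
files written with sha256 hashes, row/gene counts, and surfaced warnings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexp, footprint, mediation, qc, simulate
from .errors import ConfigError, PlacmedError
from .io import (
    CountMatrix,
    WeightMatrix,
    read_10x_mtx,
    read_bulk_matrix,
    read_phenotype_table,
    read_sample_table,
    read_weights,
    write_10x_mtx,
    write_bulk_matrix,
    write_weights,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "pseudobulk", "de", "weights", "score", "correlate", "mediate")

FLOAT_FMT = "%.10g"


def stage_seed(master: int, stage: str) -> int:
    """Stable child seed: first 4 bytes of sha256('master:stage'), < 2^31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline from one file.

    Either ``sim`` supplies a simulation config (self-generated cohort) or
    ``inputs`` points at on-disk files for the stages that need them.
    """

    seed: int = 0
    out_dir: str = "placmed_out"
    stages: tuple[str, ...] = ALL_STAGES
    sim: dict = field(default_factory=dict)  # SimConfig overrides; used when simulate enabled
    inputs: dict = field(default_factory=dict)  # matrix_dir, samples, bulk, phenotypes, hypoxia_weights
    qc_params: dict = field(default_factory=lambda: {"min_genes": 200, "min_umi": 500, "max_mito_pct": 5.0})
    de_params: dict = field(
        default_factory=lambda: {"predictor": "bmi_continuous", "covariates": ["maternal_age", "fetal_sex"]}
    )
    weights_params: dict = field(
        default_factory=lambda: {
            "outcomes": ["sdq3"],
            "top_n": 500,
            "covariates": ["maternal_age", "maternal_education", "delivery_mode", "fetal_sex", "batch"],
        }
    )
    score_params: dict = field(default_factory=lambda: {"method": "ulm", "min_overlap": 5})
    mediate_params: dict = field(
        default_factory=lambda: {
            "cell_type": "EVT",
            "side": "maternal",
            "mediator_program": "hypoxia",
            "outcome_program": "nbigs_sdq3",
            "n_boot": 1000,
            "ci_level": 0.95,
            "unit": "nucleus",
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)
        enabled = set(self.stages)
        simulated = "simulate" in enabled

        def need(stage: str, *input_keys: str) -> None:
            if stage in enabled and not simulated:
                missing = [k for k in input_keys if k not in self.inputs]
                if missing:
                    raise ConfigError(
                        f"stage {stage!r} requires inputs {missing} when 'simulate' is disabled"
                    )

        need("qc", "matrix_dir")
        need("pseudobulk", "matrix_dir")
        need("de", "matrix_dir", "samples")
        need("weights", "bulk", "phenotypes")
        need("score", "matrix_dir", "hypoxia_weights")
        need("correlate", "matrix_dir", "hypoxia_weights", "bulk", "phenotypes")
        need("mediate", "matrix_dir", "samples", "hypoxia_weights")
        deps = {
            "pseudobulk": "qc",
            "de": "pseudobulk",
            "score": "qc",
            "correlate": "score",
            "mediate": "score",
        }
        for stage, dep in deps.items():
            if stage in enabled and dep not in enabled:
                raise ConfigError(f"stage {stage!r} requires stage {dep!r} to be enabled")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
    return path


class _Manifest:
    def __init__(self, out_dir: Path, cfg: PipelineConfig):
        self.out_dir = out_dir
        self.data = {"seed": cfg.seed, "stages": {}, "status": "running"}

    def record(self, stage: str, params: dict, outputs: list[Path], info: dict, warnings: list[str], t0: float):
        self.data["stages"][stage] = {
            "params": params,
            "outputs": {str(p.relative_to(self.out_dir)): _sha256(p) for p in outputs},
            "info": info,
            "warnings": warnings,
            "elapsed_s": round(time.time() - t0, 3),
        }

    def fail(self, stage: str, exc: Exception):
        self.data["status"] = f"failed at {stage}: {exc}"
        self.write()

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True, default=str))
        return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute enabled stages in order; returns the manifest dict.

    On stage failure the run aborts with the stage name and cause; outputs of
    completed stages are retained and the manifest flags the failure.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir, cfg)
    state: dict = {}

    runners = {
        "simulate": _stage_simulate,
        "qc": _stage_qc,
        "pseudobulk": _stage_pseudobulk,
        "de": _stage_de,
        "weights": _stage_weights,
        "score": _stage_score,
        "correlate": _stage_correlate,
        "mediate": _stage_mediate,
    }
    for stage in cfg.stages:
        t0 = time.time()
        try:
            _load_missing_inputs(stage, cfg, state)
            params, outputs, info, warns = runners[stage](cfg, state, out_dir / stage)
        except Exception as exc:
            manifest.fail(stage, exc)
            raise PlacmedError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, params, outputs, info, warns, t0)
        log.info("stage %s done in %.1fs: %s", stage, time.time() - t0, info)
    manifest.data["status"] = "ok"
    manifest.write()
    return manifest.data


def _load_missing_inputs(stage: str, cfg: PipelineConfig, state: dict) -> None:
    """When running from files instead of the simulator, lazily read inputs."""
    ins = cfg.inputs
    if stage in ("qc", "pseudobulk", "de", "score", "correlate", "mediate") and "cm_raw" not in state and "cm" not in state:
        if "matrix_dir" in ins:
            d = Path(ins["matrix_dir"])
            state["cm_raw"] = read_10x_mtx(
                d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv", d / "nucleus_meta.csv"
            )
    if stage in ("de", "mediate") and "samples" not in state and "samples" in ins:
        state["samples"] = read_sample_table(ins["samples"])
    if stage in ("weights", "correlate") and "bulk" not in state and "bulk" in ins:
        state["bulk"] = read_bulk_matrix(ins["bulk"])
    if stage in ("weights", "correlate") and "phenotypes" not in state and "phenotypes" in ins:
        outcome_names = cfg.weights_params.get("outcomes", ["sdq3"])
        state["phenotypes"] = read_phenotype_table(ins["phenotypes"], outcome_names)
    if stage in ("score", "correlate", "mediate") and "hypoxia_weights" not in state and "hypoxia_weights" in ins:
        state["hypoxia_weights"] = read_weights(ins["hypoxia_weights"])


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, state: dict, out: Path):
    sim_cfg = simulate.config_from_dict({"seed": stage_seed(cfg.seed, "simulate"), **cfg.sim})
    cm, samples, bulk, phen, truth_w, truth = simulate.generate_cohort(sim_cfg)
    state.update(
        cm_raw=cm, samples=samples, bulk=bulk, phenotypes=phen, hypoxia_weights=truth_w, truth=truth
    )
    out.mkdir(parents=True, exist_ok=True)
    paths = list(write_10x_mtx(cm, out).values())
    p = out / "samples.csv"
    samples.to_csv(p, index=False)
    paths.append(p)
    paths.append(write_bulk_matrix(bulk, out / "bulk.tsv"))
    p = out / "phenotypes.csv"
    phen.to_csv(p, index=False)
    paths.append(p)
    paths.append(write_weights(truth_w, out / "truth_weights.tsv"))
    p = out / "truth_nuclei.csv"
    truth.nuclei.to_csv(p, float_format=FLOAT_FMT)
    paths.append(p)
    p = out / "truth.json"
    p.write_text(
        json.dumps(
            {
                "coefficients": truth.coefficients.round(10).to_dict(orient="index"),
                "config": simulate.config_to_dict(sim_cfg),
            },
            indent=2,
            sort_keys=True,
        )
    )
    paths.append(p)
    info = {"n_nuclei": cm.n_nuclei, "n_genes": cm.n_genes, "n_samples": len(samples), "n_subjects": bulk.shape[1]}
    return {"sim": simulate.config_to_dict(sim_cfg)}, paths, info, []


def _stage_qc(cfg: PipelineConfig, state: dict, out: Path):
    cm = state["cm_raw"]
    mito = qc.mito_gene_ids_by_prefix(cm)
    metrics = qc.qc_metrics(cm, mito)
    p = cfg.qc_params
    filtered = qc.filter_nuclei(
        cm, min_genes=p["min_genes"], min_umi=p["min_umi"], max_mito_pct=p["max_mito_pct"], mito_gene_ids=mito
    )
    state["cm"] = filtered
    metrics["pass"] = metrics.index.isin(filtered.barcodes)
    out.mkdir(parents=True, exist_ok=True)
    path = _write_tsv(metrics.reset_index(), out / "qc_report.tsv")
    info = {"n_input": cm.n_nuclei, "n_pass": filtered.n_nuclei, "n_mito_genes": len(mito)}
    return dict(p), [path], info, []


def _stage_pseudobulk(cfg: PipelineConfig, state: dict, out: Path):
    pb = qc.pseudobulk(state["cm"])
    pb = qc.filter_genes_pseudobulk(pb, min_total=10)
    state["pb"] = pb
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    sizes = []
    for (ct, side), df in pb.strata.items():
        paths.append(_write_tsv(df.reset_index(), out / f"pb_{ct}_{side}.tsv"))
        s = pb.group_sizes[(ct, side)].rename_axis("sample_id").reset_index()
        s.insert(0, "cell_type", ct)
        s.insert(1, "side", side)
        sizes.append(s)
    paths.append(_write_tsv(pd.concat(sizes, ignore_index=True), out / "group_sizes.tsv"))
    info = {"n_strata": len(pb.strata), "n_nuclei": pb.total_nuclei()}
    return {"min_total": 10}, paths, info, []


def _stage_de(cfg: PipelineConfig, state: dict, out: Path):
    p = cfg.de_params
    de_tables = diffexp.de_condition(
        state["pb"], state["samples"], predictor=p["predictor"], covariates=list(p["covariates"])
    )
    state["de_tables"] = de_tables
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for (ct, side), df in de_tables.items():
        paths.append(_write_tsv(df, out / f"de_{ct}_{side}.tsv"))
    warns = []
    if "hypoxia_weights" in state:
        enr = footprint.enrich_de_strata(de_tables, state["hypoxia_weights"], method="mlm")
        state["de_enrichment"] = enr
        paths.append(_write_tsv(enr, out / "enrichment.tsv"))
    else:
        warns.append("no hypoxia weights available; enrichment skipped")
    info = {"n_strata": len(de_tables)}
    return dict(p), paths, info, warns


def _stage_weights(cfg: PipelineConfig, state: dict, out: Path):
    p = cfg.weights_params
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    programs = []
    warns = []
    for outcome in p["outcomes"]:
        twas = diffexp.twas_phenotype(
            state["bulk"], state["phenotypes"], outcome, covariates=list(p["covariates"])
        )
        paths.append(_write_tsv(twas, out / f"twas_{outcome}.tsv"))
        wm = footprint.derive_signature_weights(twas, f"nbigs_{outcome}", top_n=p["top_n"])
        paths.append(write_weights(wm, out / f"nbigs_{outcome}.tsv"))
        programs.append(wm)
        state[f"twas_{outcome}"] = twas
    merged = WeightMatrix(pd.concat([w.table for w in programs], ignore_index=True))
    state["nbigs_weights"] = merged
    info = {"programs": [f"nbigs_{o}" for o in p["outcomes"]], "top_n": p["top_n"]}
    return dict(p), paths, info, warns


def _score_nuclei(cfg: PipelineConfig, state: dict) -> footprint.ActivityMatrix:
    cm = state["cm"]
    norm = qc.normalize_log1p_cp10k(cm)
    wtab = [state["hypoxia_weights"].table]
    if "nbigs_weights" in state:
        wtab.append(state["nbigs_weights"].table)
    W = WeightMatrix(pd.concat(wtab, ignore_index=True))
    sp = cfg.score_params
    return footprint.score_matrix(
        norm, W, gene_ids=cm.gene_ids, obs_ids=cm.barcodes,
        method=sp["method"], min_overlap=sp["min_overlap"],
    )


def _stage_score(cfg: PipelineConfig, state: dict, out: Path):
    am = _score_nuclei(cfg, state)
    state["activity"] = am
    summary = footprint.summarize_by_celltype(am, state["cm"].nucleus_meta)
    state["score_summary"] = summary
    out.mkdir(parents=True, exist_ok=True)
    paths = [
        _write_tsv(am.to_long(), out / "scores.tsv"),
        _write_tsv(summary, out / "summary_by_celltype.tsv"),
    ]
    info = {"n_obs": len(am.scores), "programs": am.programs}
    return dict(cfg.score_params), paths, info, list(am.reasons.values())


def _stage_correlate(cfg: PipelineConfig, state: dict, out: Path):
    am = state["activity"]
    meta = state["cm"].nucleus_meta
    rows = []
    nbigs_programs = [p for p in am.programs if p.startswith("nbigs_")]
    for prog in nbigs_programs:
        for ct, idx in am.scores.groupby(meta["cell_type"].to_numpy()).groups.items():
            hgs = am.scores.loc[idx, "hypoxia"].to_numpy()
            nb = am.scores.loc[idx, prog].to_numpy()
            ok = np.isfinite(hgs) & np.isfinite(nb)
            if ok.sum() < 4:
                continue
            res = mediation.spearman_test(hgs[ok], nb[ok])
            rows.append({"program": prog, "cell_type": ct, "rho": res.rho, "p": res.p, "n": res.n})
    ct_corr = pd.DataFrame(rows)
    if len(ct_corr):
        ct_corr["rank_by_rho"] = (
            ct_corr.groupby("program")["rho"].rank(ascending=False, method="min").astype(int)
        )
    state["celltype_correlations"] = ct_corr
    out.mkdir(parents=True, exist_ok=True)
    paths = [_write_tsv(ct_corr, out / "celltype_correlations.tsv")]

    warns = []
    if "bulk" in state and "phenotypes" in state:
        bulk = state["bulk"]
        L = bulk.sum(axis=0).to_numpy(dtype=float)
        norm = pd.DataFrame(
            np.log1p(1e4 * bulk.to_numpy() / L[None, :]), index=bulk.index, columns=bulk.columns
        )
        bulk_am = footprint.score_matrix(norm, state["hypoxia_weights"])
        hgs = bulk_am.scores["hypoxia"]
        outcome_names = cfg.weights_params.get("outcomes", ["sdq3"])
        all_outcomes = [c for c in state["phenotypes"].columns if c in ("sdq3", "sdq5", "aseba5")] or outcome_names
        bulk_corr = mediation.correlate_outcomes(hgs, state["phenotypes"], all_outcomes)
        state["bulk_correlations"] = bulk_corr
        paths.append(_write_tsv(bulk_corr, out / "bulk_outcome_correlations.tsv"))
    else:
        warns.append("bulk cohort unavailable; outcome correlations skipped")
    return {}, paths, {"n_celltype_rows": len(ct_corr)}, warns


def _stage_mediate(cfg: PipelineConfig, state: dict, out: Path):
    p = cfg.mediate_params
    am = state["activity"]
    meta = state["cm"].nucleus_meta
    samples = state["samples"]
    mask = (meta["cell_type"] == p["cell_type"]) & (meta["side"] == p["side"])
    if not mask.any():
        raise ConfigError(f"no nuclei for cell_type={p['cell_type']} side={p['side']}")
    sub = meta[mask]
    bmi = samples.loc[sub["sample_id"], "bmi"].to_numpy(dtype=float)
    hgs = am.scores.loc[sub.index, p["mediator_program"]].to_numpy()
    nb = am.scores.loc[sub.index, p["outcome_program"]].to_numpy()
    if p.get("unit", "nucleus") == "sample":
        df = pd.DataFrame({"sample_id": sub["sample_id"].to_numpy(), "bmi": bmi, "m": hgs, "y": nb})
        agg = df.groupby("sample_id").median()
        bmi, hgs, nb = agg["bmi"].to_numpy(), agg["m"].to_numpy(), agg["y"].to_numpy()
    log.warning(
        "mediation at unit=%s: nuclei share sample-level BMI; interpret inference "
        "with the pseudoreplication caveat in mind", p.get("unit", "nucleus"),
    )
    res = mediation.mediate(
        bmi, hgs, nb, n_boot=int(p["n_boot"]), ci_level=float(p.get("ci_level", 0.95)),
        seed=stage_seed(cfg.seed, "mediate"),
    )
    state["mediation"] = res
    out.mkdir(parents=True, exist_ok=True)
    path = out / "mediation.json"
    path.write_text(json.dumps(res.to_dict(), indent=2, sort_keys=True))
    info = {"n_obs": res.n_obs, "acme": res.acme, "prop_mediated": res.prop_mediated}
    return dict(p), [path], info, ["nucleus-level BMI is sample-level (pseudoreplication)"]


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def report(out_dir: str | Path, report_dir: str | Path | None = None) -> dict:
    """Render summary tables and figures from a completed run directory.

    The plot-data TSVs are self-sufficient: re-running report on them alone
    reproduces the tables byte-identically. Missing stage outputs are listed
    and the report is partial.
    """
    out_dir = Path(out_dir)
    report_dir = Path(report_dir) if report_dir else out_dir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    missing = []
    written = {}

    summary_path = out_dir / "score" / "summary_by_celltype.tsv"
    scores_path = out_dir / "score" / "scores.tsv"
    meta_path = out_dir / "simulate" / "nucleus_meta.csv"
    samples_path = out_dir / "simulate" / "samples.csv"
    med_path = out_dir / "mediate" / "mediation.json"

    if summary_path.exists():
        summary = pd.read_csv(summary_path, sep="\t")
        _write_tsv(summary, report_dir / "celltype_boxplot_data.tsv")
        written["celltype_boxplot_data.tsv"] = True
        _boxplot(summary, report_dir / "celltype_scores.png")
    else:
        missing.append(str(summary_path))

    if scores_path.exists() and meta_path.exists() and samples_path.exists():
        long = pd.read_csv(scores_path, sep="\t")
        wide = long.pivot(index="observation", columns="program", values="score")
        meta = pd.read_csv(meta_path).set_index("barcode")
        samples = pd.read_csv(samples_path).set_index("sample_id")
        nbigs = [c for c in wide.columns if c.startswith("nbigs_")]
        if "hypoxia" in wide.columns and nbigs:
            scatter = pd.DataFrame(
                {
                    "observation": wide.index,
                    "hgs": wide["hypoxia"].to_numpy(),
                    "nbigs": wide[nbigs[0]].to_numpy(),
                    "cell_type": meta.loc[wide.index, "cell_type"].to_numpy(),
                    "bmi": samples.loc[meta.loc[wide.index, "sample_id"], "bmi"].to_numpy(),
                }
            )
            _write_tsv(scatter, report_dir / "hgs_nbigs_scatter.tsv")
            written["hgs_nbigs_scatter.tsv"] = True
            _scatter(scatter, report_dir / "hgs_nbigs_scatter.png")
    else:
        missing.extend(str(p) for p in (scores_path, meta_path, samples_path) if not p.exists())

    if med_path.exists():
        med = json.loads(med_path.read_text())
        rows = [
            {"quantity": q, "estimate": med[q], "ci_lower": med["ci"][q][0],
             "ci_upper": med["ci"][q][1], "p": med["p"][q]}
            for q in ("acme", "ade", "total", "prop_mediated")
        ]
        _write_tsv(pd.DataFrame(rows), report_dir / "mediation_summary.tsv")
        written["mediation_summary.tsv"] = True
    else:
        missing.append(str(med_path))

    return {"written": sorted(written), "missing": missing, "report_dir": str(report_dir)}


def _boxplot(summary: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    progs = summary["program"].unique()
    fig, axes = plt.subplots(1, len(progs), figsize=(4 * len(progs), 3.5), squeeze=False)
    for ax, prog in zip(axes[0], progs):
        sub = summary[summary["program"] == prog].sort_values("rank_by_median")
        x = np.arange(len(sub))
        ax.errorbar(
            x, sub["median"],
            yerr=[sub["median"] - sub["q1"], sub["q3"] - sub["median"]],
            fmt="o", capsize=3,
        )
        ax.set_xticks(x, sub["cell_type"], rotation=45, ha="right")
        ax.set_title(prog)
        ax.set_ylabel("activity score (t)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _scatter(scatter: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(scatter["hgs"], scatter["nbigs"], c=scatter["bmi"], s=4, cmap="viridis", alpha=0.5)
    fig.colorbar(sc, label="maternal BMI")
    ax.set_xlabel("hypoxia gene score")
    ax.set_ylabel("NBI gene score")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
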