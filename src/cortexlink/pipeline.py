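"""End-to-end orchestration of the three analysis steps.

``run_all`` wires the stages together on plain TSV/JSON intermediates so
any stage can also be run standalone (mix real data for one block with
synthetic data for others); ``demo`` generates a synthetic cohort with
planted effects, runs the full pipeline on it and appends a
planted-vs-recovered report. Every random stage consumes a named substream
of the master seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ahba, cca, enrichment, phenotype, pls
from .atlas import left_regions, region_names
from .errors import ConfigError, DataError
from .synthetic import SyntheticConfig, generate_cohort, write_cohort

_STAGE_SEEDS = {"pls": 11, "cca": 13}


@dataclass
class PipelineConfig:
    """File paths and analysis parameters for a full run."""

    ct: str = ""
    panss: str = ""
    samples: str = ""
    probes: str = ""
    expression: str = ""
    background: str = ""            # optional
    dnam_0w: str = ""
    dnam_8w: str = ""
    manifest: str = ""
    euler: str = ""                 # optional
    gmt: str = ""                   # optional
    outdir: str = "cortexlink_out"
    n_perm_pls: int = 1000
    n_boot: int = 500
    n_perm_cca: int = 10_000
    z_thresh: float = 3.0
    fdr_alpha: float = 0.05
    ora_q: float = 0.01
    k_nn: int = 5
    s_features: int = 30
    min_background_fraction: float = 0.5
    n_regions: int = 68
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_perm_pls", "n_boot", "n_perm_cca", "k_nn", "s_features"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("z_thresh", "fdr_alpha", "ora_q"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def required_inputs(self) -> dict:
        req = {"ct": self.ct, "panss": self.panss, "samples": self.samples,
               "probes": self.probes, "expression": self.expression,
               "dnam_0w": self.dnam_0w, "dnam_8w": self.dnam_8w,
               "manifest": self.manifest}
        return req

    def preflight(self) -> None:
        missing = {k: v for k, v in self.required_inputs().items()
                   if not v or not Path(v).exists()}
        optional = {k: getattr(self, k) for k in ("background", "euler", "gmt")}
        missing.update({k: v for k, v in optional.items()
                        if v and not Path(v).exists()})
        if missing:
            raise ConfigError(f"missing input files: {missing}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seed, per-file checksums, warnings."""

    version: str
    seed: int
    config: dict
    started: str = ""
    finished: str = ""
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    recovery: dict | None = None

    def add_output(self, name: str, path: Path) -> None:
        self.outputs[name] = {"path": str(path), "sha256": _sha256(path)}

    def write(self, path) -> None:
        payload = asdict(self)
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(payload, indent=1, default=str),
                       encoding="utf-8")
        tmp.replace(path)


def _read_ct_groups(path) -> dict:
    ct = pd.read_csv(path, sep="\t")
    if "group" not in ct.columns:
        raise DataError("ct table needs a 'group' column")
    groups = {g: sub.drop(columns=[]).reset_index(drop=True)
              for g, sub in ct.groupby("group")}
    for needed in ("control", "patient_0w", "patient_8w"):
        if needed not in groups:
            raise DataError(f"ct table missing group '{needed}'")
    return groups


def _read_panss(path):
    panss = pd.read_csv(path, sep="\t")
    p0 = panss[panss["timepoint"] == "0W"].drop(columns="timepoint")
    p8 = panss[panss["timepoint"] == "8W"].drop(columns="timepoint")
    if p0.empty or p8.empty:
        raise DataError("panss table needs rows for timepoints 0W and 8W")
    return p0.reset_index(drop=True), p8.reset_index(drop=True)


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute step1 → expression prep → PLS → (ORA) → CCA, wiring outputs."""
    import warnings as _warnings

    from . import __version__

    config.preflight()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, seed=config.seed,
                           config=asdict(config),
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    stage_seed = {k: int(np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(v,))
    ).integers(0, 2 ** 31 - 1)) for k, v in _STAGE_SEEDS.items()}

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")

        # ---- step 1: phenotype maps --------------------------------------
        groups = _read_ct_groups(config.ct)
        resid_p = phenotype.residualize_ct(
            pd.concat([groups["patient_0w"], groups["control"]],
                      ignore_index=True))
        tmap_cc = phenotype.case_control_tmap(
            resid_p[resid_p["group"] == "patient_0w"],
            resid_p[resid_p["group"] == "control"])
        r0, r8 = phenotype.residualize_pair(groups["patient_0w"],
                                            groups["patient_8w"])
        tmap_long = phenotype.longitudinal_tmap(r0, r8)
        tmap_cc.to_tsv(out / "tmap_case_control.tsv")
        tmap_long.to_tsv(out / "tmap_longitudinal.tsv")
        p0, p8 = _read_panss(config.panss)
        rr = phenotype.reduction_rates(p0, p8)
        rr.to_csv(out / "reduction_rates.tsv", sep="\t", index=False)
        if config.euler:
            euler = pd.read_csv(config.euler, sep="\t")
            qc = phenotype.euler_qc(euler)
            (out / "qc_report.json").write_text(
                json.dumps(qc.to_dict(), indent=1), encoding="utf-8")
            manifest.add_output("qc_report", out / "qc_report.json")

        # ---- step 2a: expression preprocessing ---------------------------
        ds = ahba.read_probe_dataset(
            config.samples, config.probes, config.expression,
            config.background or None)
        atlas34 = left_regions(region_names(config.n_regions))
        expr = ahba.prepare_region_expression(
            ds, atlas34, min_background_fraction=config.min_background_fraction)
        expr.rename_axis("region").to_csv(out / "region_expression.tsv", sep="\t")

        # ---- step 2b: spatial PLS ----------------------------------------
        tmap34 = phenotype.subset_left_hemisphere(
            tmap_long, expected=config.n_regions // 2)
        model = pls.SpatialPLS(tmap34, expr)
        res = model.fit(n_perm=config.n_perm_pls, n_boot=config.n_boot,
                        seed=stage_seed["pls"])
        res.z_table.to_csv(out / "gene_z.tsv", sep="\t")
        pd.DataFrame({"null_r": res.null_r}).to_csv(
            out / "null_distribution.tsv", sep="\t", index=False)
        lists = res.gene_lists(z_thresh=config.z_thresh, alpha=config.fdr_alpha)
        (out / "gene_lists.json").write_text(
            json.dumps(lists.to_dict(), indent=1), encoding="utf-8")
        (out / "pls_model.json").write_text(json.dumps({
            "r": res.r, "r2": res.r2, "permutation_p": res.permutation_p,
            "n_perm": res.n_perm, "n_boot": res.n_boot,
            "n_regions": len(res.scores), "n_genes": len(res.weights),
        }, indent=1), encoding="utf-8")

        # ---- enrichment (optional) ---------------------------------------
        if config.gmt:
            sets = enrichment.GeneSetCollection.from_gmt(config.gmt)
            background = list(expr.columns)
            query = list(lists.combined) or background[:1]
            ora = enrichment.hypergeometric_ora(query, background, sets,
                                                q_thresh=config.ora_q)
            ora.to_csv(out / "enrichment.tsv", sep="\t")
            manifest.add_output("enrichment", out / "enrichment.tsv")

        # ---- step 3: methylation CCA -------------------------------------
        beta0 = pd.read_csv(config.dnam_0w, sep="\t", index_col="cpg_id")
        beta8 = pd.read_csv(config.dnam_8w, sep="\t", index_col="cpg_id")
        cpg_map = pd.read_csv(config.manifest, sep="\t")
        pls_genes = list(lists.combined) or list(res.weights.index)
        report = cca.run_step3(beta0, beta8, cpg_map, p0, p8, pls_genes,
                               s=config.s_features, k=config.k_nn,
                               n_perm=config.n_perm_cca,
                               seed=stage_seed["cca"],
                               alpha=config.fdr_alpha)
        report.longitudinal_loadings.to_csv(out / "loadings.tsv", sep="\t")
        (out / "cca_result.json").write_text(json.dumps({
            "baseline": {
                "rho": list(report.baseline.canonical_correlations),
                "p_fwe": list(report.baseline.p_fwe),
            },
            "longitudinal": {
                "rho": list(report.longitudinal.canonical_correlations),
                "p_fwe": list(report.longitudinal.p_fwe),
                "n_significant_loading_genes": int(
                    report.longitudinal_loadings["significant"].sum()),
                "selected_features": report.selected_longitudinal,
            },
            "n_subjects": report.n_subjects,
        }, indent=1), encoding="utf-8")
        (out / "summary.txt").write_text(
            res.summary() + "\n\n" + report.summary() + "\n", encoding="utf-8")

        manifest.warnings = [str(w.message) for w in caught]

    for name in ("tmap_case_control", "tmap_longitudinal", "reduction_rates",
                 "region_expression", "gene_z", "null_distribution",
                 "gene_lists", "pls_model", "loadings", "cca_result",
                 "summary"):
        suffix = ".json" if name in ("gene_lists", "pls_model", "cca_result") \
            else (".txt" if name == "summary" else ".tsv")
        manifest.add_output(name, out / f"{name}{suffix}")
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "run_manifest.json")
    return manifest


#: Demo analysis parameters: the cohort-sized feature count (s=15 keeps the
#: CCA well-posed at n=38) and permutation counts scaled for an interactive run.
DEMO_OVERRIDES = dict(n_perm_pls=1000, n_boot=500, n_perm_cca=2000,
                      s_features=15)


def demo(seed: int = 0, outdir: str = "cortexlink_demo",
         synthetic_config: SyntheticConfig | None = None,
         **param_overrides) -> RunManifest:
    """Generate a planted synthetic cohort, run the pipeline, report recovery.

    The recovery report compares the planted gene-weight vector with the
    fitted PLS weights, and the planted canonical correlation with the
    fitted first-mode correlation of the longitudinal CCA.
    """
    out = Path(outdir)
    inputs = out / "inputs"
    cfg = synthetic_config or SyntheticConfig(seed=seed)
    cohort = generate_cohort(cfg)
    paths = write_cohort(cohort, inputs)

    params = dict(DEMO_OVERRIDES)
    params.update(param_overrides)
    pconf = PipelineConfig(
        ct=paths["ct"], panss=paths["panss"], samples=paths["samples"],
        probes=paths["probes"], expression=paths["expression"],
        background=paths["background"], dnam_0w=paths["dnam_0w"],
        dnam_8w=paths["dnam_8w"], manifest=paths["manifest"],
        outdir=str(out / "results"), seed=seed, **params)
    manifest = run_all(pconf)

    results = Path(pconf.outdir)
    gene_z = pd.read_csv(results / "gene_z.tsv", sep="\t", index_col="gene")
    w_true = cohort.truth["expression"]["weight_vector"]
    common = [g for g in gene_z.index if g in w_true.index]
    w_corr = float(np.corrcoef(gene_z.loc[common, "weight"],
                               w_true.loc[common])[0, 1])
    cca_out = json.loads((results / "cca_result.json").read_text())
    pls_out = json.loads((results / "pls_model.json").read_text())
    recovery = {
        "weight_recovery_corr": w_corr,
        "pls_r": pls_out["r"],
        "pls_permutation_p": pls_out["permutation_p"],
        "planted_canonical_corr": cfg.planted_canonical_corr,
        "fitted_canonical_corr_mode1": cca_out["longitudinal"]["rho"][0],
        "cca_mode1_p_fwe": cca_out["longitudinal"]["p_fwe"][0],
        "baseline_mode1_p_fwe": cca_out["baseline"]["p_fwe"][0],
        "n_significant_loading_genes":
            cca_out["longitudinal"]["n_significant_loading_genes"],
    }
    manifest.recovery = recovery
    (results / "recovery.json").write_text(json.dumps(recovery, indent=1),
                                           encoding="utf-8")
    manifest.add_output("recovery", results / "recovery.json")
    manifest.write(results / "run_manifest.json")
    return manifest
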