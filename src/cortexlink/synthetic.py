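"""Synthetic cohorts with planted multi-omics effect structure.

Generates every input the pipeline consumes — regional cortical-thickness
tables for controls and for patients at baseline and after treatment,
a donor-based probe-level expression atlas, paired 450K-style methylation
beta matrices with a CpG→gene manifest, and PANSS symptom scores at two
timepoints — with *known* planted structure:

* a planted longitudinal cortical-thinning vector added to the follow-up
  scans;
* a planted gene weight vector w*: regional expression of gene j tracks the
  longitudinal t map with strength w*_j, so the spatial PLS has a known
  ground truth;
* a single latent treatment-response factor that drives both the
  methylation deltas of a known gene subset and the three PANSS reduction
  rates, calibrated so the *population* first canonical correlation between
  the blocks equals a requested value (block noise solved from
  c_x = c_y = sqrt(rho), the factor-correlation split across the two
  blocks).

Defaults mirror the reference cohort design: 42 patients at baseline, 4
follow-up dropouts (38 treated scans), 38 controls, 68 cortical regions
(34 per hemisphere), 6 expression donors sampled in the left hemisphere
only. Gene and probe counts default to a desk-scale panel (200 genes,
2 probes/gene). Every operation draws from a named substream of the master
seed, so the seed fully determines all outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import left_regions, region_names
from .errors import ConfigError, DataError
from .phenotype import TStatMap

_STREAMS = {"ct": 0, "thinning": 1, "weights": 2, "expr": 3, "dnam": 4,
            "panss": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic cohort; the defaults are the study conditions."""

    n_patients: int = 42
    n_controls: int = 38
    n_dropout: int = 4                 # patients without follow-up scans
    n_regions: int = 68                # 34 per hemisphere
    n_genes: int = 200
    probes_per_gene: int = 2
    unannotated_fraction: float = 0.05   # of all probes, no gene label
    low_intensity_fraction: float = 0.10  # of all probes, fail background QC
    n_donors: int = 6
    samples_per_region_per_donor: int = 2
    n_cpg_per_gene: int = 5
    n_driven_genes: int = 20             # genes loading on the response factor
    planted_weight_vector: np.ndarray | None = None  # length n_genes, or drawn
    planted_canonical_corr: float = 0.8
    # cortical thickness model (mm)
    thinning_mean: float = -0.05
    thinning_sd: float = 0.03
    ct_noise_sd: float = 0.05
    ct_longitudinal_noise_sd: float = 0.02
    cov_age: float = -0.005              # mm per year
    cov_sex: float = 0.03                # mm, male minus female
    cov_tiv: float = 2e-7                # mm per mm^3
    # expression model (log2-like units)
    expr_spatial_noise_sd: float = 1.0   # gene-specific regional structure
    expr_noise_sd: float = 0.6
    probe_noise_sd: float = 0.1
    donor_offset_sd: float = 0.2
    probe_offset_sd: float = 0.2
    # methylation / clinical model (beta units)
    dnam_effect: float = 0.03            # factor loading of driven gene deltas
    dnam_subject_sd: float = 0.02
    dnam_cpg_offset_sd: float = 0.05
    dnam_cpg_noise_sd: float = 0.005
    rr_base: tuple = (0.5, 0.15, 0.4)    # mean reduction rate (P, N, G)
    rr_scale: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_patients": self.n_patients, "n_controls": self.n_controls,
            "n_regions": self.n_regions, "n_genes": self.n_genes,
            "probes_per_gene": self.probes_per_gene, "n_donors": self.n_donors,
            "samples_per_region_per_donor": self.samples_per_region_per_donor,
            "n_cpg_per_gene": self.n_cpg_per_gene,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        if self.n_dropout < 0 or self.n_dropout >= self.n_patients:
            raise ConfigError("n_dropout must be in [0, n_patients)")
        if not 0.0 <= self.planted_canonical_corr <= 1.0:
            raise ConfigError("planted_canonical_corr must be in [0, 1]")
        if self.n_driven_genes < 1 or self.n_driven_genes > self.n_genes:
            raise ConfigError("n_driven_genes must be in [1, n_genes]")
        if self.planted_weight_vector is not None:
            w = np.asarray(self.planted_weight_vector, dtype=float)
            if w.shape != (self.n_genes,):
                raise ConfigError("planted_weight_vector length must equal n_genes")

    @property
    def gene_symbols(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def patient_ids(self) -> list[str]:
        return [f"P{i + 1:03d}" for i in range(self.n_patients)]

    @property
    def followup_ids(self) -> list[str]:
        return self.patient_ids[: self.n_patients - self.n_dropout]

    @property
    def control_ids(self) -> list[str]:
        return [f"C{i + 1:03d}" for i in range(self.n_controls)]


# ---------------------------------------------------------------------------
# cortical thickness
# ---------------------------------------------------------------------------

def _covariates(rng, ids):
    return pd.DataFrame({
        "subject_id": ids,
        "age": np.round(rng.uniform(18.0, 45.0, size=len(ids)), 1),
        "sex": rng.integers(0, 2, size=len(ids)),
        "tiv": np.round(rng.normal(1.45e6, 1.2e5, size=len(ids)), 0),
    })


def gen_ct_cohort(cfg: SyntheticConfig):
    """Cortical-thickness tables for controls, patients 0W and patients 8W.

    CT = region baseline mean + linear covariate effects (age, sex, TIV)
    + Gaussian noise; the follow-up table is the baseline table of retained
    subjects plus the planted thinning vector plus scan-rescan noise.
    Returns ``(ct_controls, ct_patients_0w, ct_patients_8w, truth)`` where
    ``truth`` holds the thinning vector, region means and coefficients.
    """
    regions = region_names(cfg.n_regions)
    rng = _rng(cfg.seed, "ct")
    region_mean = 2.5 + 0.3 * rng.standard_normal(cfg.n_regions)
    thin_rng = _rng(cfg.seed, "thinning")
    thinning = cfg.thinning_mean + cfg.thinning_sd * thin_rng.standard_normal(
        cfg.n_regions)

    def build(ids, group):
        cov = _covariates(rng, ids)
        base = (
            region_mean[None, :]
            + cfg.cov_age * cov["age"].to_numpy()[:, None]
            + cfg.cov_sex * cov["sex"].to_numpy()[:, None]
            + cfg.cov_tiv * cov["tiv"].to_numpy()[:, None]
        )
        ct = base + cfg.ct_noise_sd * rng.standard_normal(base.shape)
        tab = cov.copy()
        tab.insert(1, "group", group)
        return pd.concat(
            [tab, pd.DataFrame(ct, columns=regions, index=tab.index)], axis=1)

    controls = build(cfg.control_ids, "control")
    patients_0w = build(cfg.patient_ids, "patient_0w")
    kept = patients_0w[patients_0w["subject_id"].isin(cfg.followup_ids)].copy()
    kept["group"] = "patient_8w"
    noise8 = cfg.ct_longitudinal_noise_sd * rng.standard_normal(
        (len(kept), cfg.n_regions))
    kept[regions] = kept[regions].to_numpy() + thinning[None, :] + noise8
    patients_8w = kept.reset_index(drop=True)

    truth = {
        "thinning": pd.Series(thinning, index=regions),
        "region_mean": pd.Series(region_mean, index=regions),
        "covariate_coefficients": {
            "age": cfg.cov_age, "sex": cfg.cov_sex, "tiv": cfg.cov_tiv},
    }
    return controls, patients_0w, patients_8w, truth


# ---------------------------------------------------------------------------
# expression atlas
# ---------------------------------------------------------------------------

def _exact_flag_counts(rng, n_samples: int, fraction: float) -> np.ndarray:
    """Boolean vector with exactly round(fraction * n) True entries."""
    n_true = int(round(fraction * n_samples))
    flags = np.zeros(n_samples, dtype=bool)
    flags[rng.choice(n_samples, size=n_true, replace=False)] = True
    return flags


def gen_expression_atlas(cfg: SyntheticConfig, tmap):
    """Donor-based probe-level expression tracking a left-hemisphere t map.

    The gene-level regional profile is
    ``g_j(region) = base_j + w*_j · z(t_map)(region)`` plus donor offsets
    (constant across regions) and per-sample noise; each gene is expanded
    to ``probes_per_gene`` probes with constant probe offsets and probe
    noise. Extra unannotated probes and below-background probes are planted
    to exercise the preprocessing filters, as are right-hemisphere and
    unassigned samples. Returns ``(ProbeExpressionDataset, truth)``.
    """
    from .ahba import ProbeExpressionDataset

    t = tmap.t if isinstance(tmap, TStatMap) else pd.Series(tmap, dtype=float)
    lefts = left_regions(region_names(cfg.n_regions))
    if list(t.index) != lefts:
        if set(t.index) == set(lefts):
            t = t.loc[lefts]
        else:
            raise DataError(
                f"t map regions do not match the {len(lefts)} left-hemisphere "
                "atlas regions")
    tv = t.to_numpy(dtype=float)
    if np.ptp(tv) == 0:
        raise DataError("constant t map: cannot plant a spatial gradient")
    tnorm = (tv - tv.mean()) / tv.std()

    rng_w = _rng(cfg.seed, "weights")
    if cfg.planted_weight_vector is not None:
        w = np.asarray(cfg.planted_weight_vector, dtype=float)
    else:
        w = rng_w.standard_normal(cfg.n_genes)

    rng = _rng(cfg.seed, "expr")
    genes = cfg.gene_symbols
    base = rng.normal(6.0, 1.0, size=cfg.n_genes)
    donor_ids = [f"D{d + 1:02d}" for d in range(cfg.n_donors)]
    donor_offset = cfg.donor_offset_sd * rng.standard_normal(
        (cfg.n_donors, cfg.n_genes))

    # sample layout: left-hemisphere atlas samples + planted right/unassigned
    rows = []
    for d, donor in enumerate(donor_ids):
        for r, reg in enumerate(lefts):
            for s in range(cfg.samples_per_region_per_donor):
                rows.append((donor, "L", reg, r, d))
        rows.append((donor, "R", "R_" + lefts[0][2:], 0, d))
        rows.append((donor, "L", "unassigned", 0, d))
    sample_ids = [f"{r[0]}_s{i + 1:03d}" for i, r in enumerate(rows)]
    samples = pd.DataFrame(
        {"donor_id": [r[0] for r in rows], "hemisphere": [r[1] for r in rows],
         "region": [r[2] for r in rows]},
        index=pd.Index(sample_ids, name="sample_id"))
    region_idx = np.array([r[3] for r in rows])
    donor_idx = np.array([r[4] for r in rows])
    n_samples = len(rows)

    # gene-specific spatial residual: each gene's own regional expression
    # pattern, shared across donors and samples (biological, not measurement)
    spatial = cfg.expr_spatial_noise_sd * rng.standard_normal(
        (len(lefts), cfg.n_genes))

    # gene-level sample values
    gene_vals = (
        base[None, :]
        + np.outer(tnorm[region_idx], np.ones(cfg.n_genes)) * w[None, :]
        + spatial[region_idx, :]
        + donor_offset[donor_idx, :]
        + cfg.expr_noise_sd * rng.standard_normal((n_samples, cfg.n_genes))
    )

    # probe expansion
    n_annot = cfg.n_genes * cfg.probes_per_gene
    frac = cfg.unannotated_fraction
    n_unannot = int(round(frac / (1.0 - frac) * n_annot)) if frac < 1 else 0
    n_probes = n_annot + n_unannot
    probe_ids = [f"probe{i + 1:05d}" for i in range(n_probes)]
    gene_of = ([g for g in genes for _ in range(cfg.probes_per_gene)]
               + [""] * n_unannot)
    probe_offset = cfg.probe_offset_sd * rng.standard_normal(n_probes)
    expr = np.empty((n_samples, n_probes))
    for j in range(n_annot):
        gidx = j // cfg.probes_per_gene
        expr[:, j] = (gene_vals[:, gidx] + probe_offset[j]
                      + cfg.probe_noise_sd * rng.standard_normal(n_samples))
    if n_unannot:
        expr[:, n_annot:] = rng.normal(
            6.0, 1.0, size=(n_samples, n_unannot)) + probe_offset[n_annot:]

    # background flags: failing probes are above background in only 30% of
    # samples, passing probes in 95% (strict >0.5 filter downstream)
    failing = _exact_flag_counts(rng, n_probes, cfg.low_intensity_fraction)
    background = np.empty((n_samples, n_probes), dtype=bool)
    for j in range(n_probes):
        background[:, j] = _exact_flag_counts(
            rng, n_samples, 0.30 if failing[j] else 0.95)

    ds = ProbeExpressionDataset(
        expression=pd.DataFrame(expr, index=samples.index, columns=probe_ids),
        probes=pd.DataFrame({"gene_symbol": [g if g else np.nan for g in gene_of]},
                            index=pd.Index(probe_ids, name="probe_id")),
        samples=samples,
        background=pd.DataFrame(background, index=samples.index,
                                columns=probe_ids),
    )
    truth = {
        "weight_vector": pd.Series(w, index=genes),
        "tmap_z": pd.Series(tnorm, index=lefts),
        "n_unannotated": n_unannot,
        "n_low_intensity": int(failing.sum()),
        "failing_probes": [probe_ids[j] for j in np.flatnonzero(failing)],
    }
    return ds, truth


# ---------------------------------------------------------------------------
# methylation + clinical response
# ---------------------------------------------------------------------------

def gen_methylation_panss(cfg: SyntheticConfig, gene_list):
    """Paired methylation betas, CpG manifest and PANSS scores with a planted
    canonical correlation.

    A latent treatment-response factor z drives the methylation deltas of
    the first ``n_driven_genes`` genes and the three PANSS reduction rates.
    Block noise is solved so the population first canonical correlation
    equals ``planted_canonical_corr`` (``rho = 0`` plants independence).
    Returns ``(beta_0w, beta_8w, manifest, panss_0w, panss_8w, truth)``.
    """
    rho = cfg.planted_canonical_corr
    genes = list(gene_list)
    if cfg.n_driven_genes > len(genes):
        raise ConfigError("n_driven_genes exceeds the supplied gene list")
    driven = genes[: cfg.n_driven_genes]
    subjects = cfg.followup_ids
    n = len(subjects)
    rng = _rng(cfg.seed, "dnam")
    rng_p = _rng(cfg.seed, "panss")

    z = rng.standard_normal(n)
    alpha = cfg.dnam_effect
    s_driven = len(driven)
    # deltas: driven genes load on z with per-block noise from c_x = sqrt(rho)
    delta = np.zeros((n, len(genes)))
    if rho > 0:
        sx = alpha * np.sqrt(s_driven * (1.0 - rho) / rho)
        delta[:, :s_driven] = (alpha * z[:, None]
                               + sx * rng.standard_normal((n, s_driven)))
    else:
        delta[:, :s_driven] = alpha * rng.standard_normal((n, s_driven))
    delta[:, s_driven:] = alpha * rng.standard_normal((n, len(genes) - s_driven))

    # CpG-level betas
    n_cpg = len(genes) * cfg.n_cpg_per_gene
    cpg_ids = [f"cg{i + 1:08d}" for i in range(n_cpg)]
    manifest = pd.DataFrame({
        "cpg_id": cpg_ids,
        "gene": [g for g in genes for _ in range(cfg.n_cpg_per_gene)],
    })
    mu = rng.uniform(0.2, 0.8, size=len(genes))
    cpg_offset = cfg.dnam_cpg_offset_sd * rng.standard_normal(n_cpg)
    gene_idx = np.repeat(np.arange(len(genes)), cfg.n_cpg_per_gene)
    subj_gene = cfg.dnam_subject_sd * rng.standard_normal((n, len(genes)))
    beta0 = (mu[gene_idx][None, :] + cpg_offset[None, :]
             + subj_gene[:, gene_idx]
             + cfg.dnam_cpg_noise_sd * rng.standard_normal((n, n_cpg)))
    beta8 = (beta0 - delta[:, gene_idx]
             + cfg.dnam_cpg_noise_sd * rng.standard_normal((n, n_cpg)))
    beta0 = np.clip(beta0, 0.0, 1.0)
    beta8 = np.clip(beta8, 0.0, 1.0)
    beta_0w = pd.DataFrame(beta0.T, index=pd.Index(cpg_ids, name="cpg_id"),
                           columns=subjects)
    beta_8w = pd.DataFrame(beta8.T, index=pd.Index(cpg_ids, name="cpg_id"),
                           columns=subjects)

    # clinical block: reduction rates share the factor z
    t_dims = 3
    if rho > 0:
        sf = np.sqrt(t_dims * (1.0 - rho) / rho)
        y_latent = z[:, None] + sf * rng_p.standard_normal((n, t_dims))
    else:
        y_latent = rng_p.standard_normal((n, t_dims))
    rr = np.clip(np.asarray(cfg.rr_base)[None, :] + cfg.rr_scale * y_latent,
                 -0.8, 0.95)

    all_ids = cfg.patient_ids
    panss_0w = pd.DataFrame({
        "subject_id": all_ids,
        "panss_p": rng_p.integers(18, 34, size=len(all_ids)),
        "panss_n": rng_p.integers(16, 30, size=len(all_ids)),
        "panss_g": rng_p.integers(38, 65, size=len(all_ids)),
    })
    base = panss_0w.set_index("subject_id").loc[subjects]
    minima = np.array([7, 7, 16])
    maxima = np.array([49, 49, 112])
    s0 = base[["panss_p", "panss_n", "panss_g"]].to_numpy(dtype=float)
    s8 = np.clip(np.rint(s0 - rr * (s0 - minima[None, :])),
                 minima[None, :], maxima[None, :]).astype(int)
    panss_8w = pd.DataFrame({
        "subject_id": subjects,
        "panss_p": s8[:, 0], "panss_n": s8[:, 1], "panss_g": s8[:, 2],
    })

    truth = {
        "driven_genes": driven,
        "planted_canonical_corr": rho,
        "latent_factor": pd.Series(z, index=subjects),
        "gene_delta": pd.DataFrame(delta, index=subjects, columns=genes),
        "reduction_rates": pd.DataFrame(
            rr, index=subjects, columns=["rr_p", "rr_n", "rr_g"]),
    }
    return beta_0w, beta_8w, manifest, panss_0w, panss_8w, truth


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Everything the pipeline needs, plus the planted ground truth."""

    config: SyntheticConfig
    ct_controls: pd.DataFrame
    ct_patients_0w: pd.DataFrame
    ct_patients_8w: pd.DataFrame
    tmap_left: TStatMap
    probe_dataset: object
    beta_0w: pd.DataFrame
    beta_8w: pd.DataFrame
    cpg_manifest: pd.DataFrame
    panss_0w: pd.DataFrame
    panss_8w: pd.DataFrame
    truth: dict = field(default_factory=dict)


def generate_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """Generate the full synthetic study: CT → t map → expression → DNAm/PANSS.

    The longitudinal t map used to plant the expression gradient is computed
    from the generated CT tables exactly as the pipeline itself computes it
    (pooled residualization, paired t, left-hemisphere subset).
    """
    from .phenotype import longitudinal_tmap, residualize_pair, subset_left_hemisphere

    ct_c, ct_0, ct_8, ct_truth = gen_ct_cohort(cfg)
    r0, r8 = residualize_pair(ct_0, ct_8)
    tmap = subset_left_hemisphere(
        longitudinal_tmap(r0, r8), expected=cfg.n_regions // 2)
    ds, expr_truth = gen_expression_atlas(cfg, tmap)
    b0, b8, manifest, p0, p8, dnam_truth = gen_methylation_panss(
        cfg, cfg.gene_symbols)
    truth = {"ct": ct_truth, "expression": expr_truth, "dnam": dnam_truth}
    return SyntheticCohort(
        config=cfg, ct_controls=ct_c, ct_patients_0w=ct_0, ct_patients_8w=ct_8,
        tmap_left=tmap, probe_dataset=ds, beta_0w=b0, beta_8w=b8,
        cpg_manifest=manifest, panss_0w=p0, panss_8w=p8, truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write the standard pipeline input files; returns the path map."""
    import json
    from pathlib import Path

    from .ahba import write_probe_dataset

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in {
        "ct": "ct.tsv", "panss": "panss.tsv", "samples": "samples.tsv",
        "probes": "probes.tsv", "expression": "expression.tsv",
        "background": "background.tsv", "dnam_0w": "dnam_0w.tsv",
        "dnam_8w": "dnam_8w.tsv", "manifest": "cpg_manifest.tsv",
        "truth": "truth.json",
    }.items()}
    ct = pd.concat([cohort.ct_controls, cohort.ct_patients_0w,
                    cohort.ct_patients_8w], ignore_index=True)
    ct.to_csv(paths["ct"], sep="\t", index=False)
    panss = pd.concat([
        cohort.panss_0w.assign(timepoint="0W"),
        cohort.panss_8w.assign(timepoint="8W"),
    ], ignore_index=True)[["subject_id", "timepoint", "panss_p", "panss_n",
                           "panss_g"]]
    panss.to_csv(paths["panss"], sep="\t", index=False)
    write_probe_dataset(cohort.probe_dataset, paths["samples"], paths["probes"],
                        paths["expression"], paths["background"])
    cohort.beta_0w.to_csv(paths["dnam_0w"], sep="\t")
    cohort.beta_8w.to_csv(paths["dnam_8w"], sep="\t")
    cohort.cpg_manifest.to_csv(paths["manifest"], sep="\t", index=False)

    t = cohort.truth
    truth_json = {
        "seed": cohort.config.seed,
        "planted_canonical_corr": t["dnam"]["planted_canonical_corr"],
        "driven_genes": t["dnam"]["driven_genes"],
        "thinning": t["ct"]["thinning"].to_dict(),
        "weight_vector": t["expression"]["weight_vector"].to_dict(),
        "n_unannotated_probes": t["expression"]["n_unannotated"],
        "n_low_intensity_probes": t["expression"]["n_low_intensity"],
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth_json, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
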