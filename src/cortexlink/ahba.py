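"""Step 2a — probe-level expression to a 34-region × gene matrix.

Implements the five canonical preprocessing steps used for donor-based
regional microarray atlases:

1. annotate probes to genes (drop unannotated probes);
2. filter probes by above-background intensity fraction;
3. keep one representative probe per gene (differential stability);
4. assign samples to left-hemisphere atlas regions and aggregate per donor;
5. normalize per donor with a scaled robust sigmoid, then average donors.

The dataset container is :class:`ProbeExpressionDataset`; the final product
is a regions × genes DataFrame with values in [0, 1].
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class ProbeExpressionDataset:
    """Probe-level multi-donor expression with sample/probe metadata.

    Attributes
    ----------
    expression : DataFrame, samples × probes (log2-like scale), indexed by
        sample id with probe-id columns.
    probes : DataFrame indexed by probe id with a ``gene_symbol`` column
        (NaN/empty = unannotated).
    samples : DataFrame indexed by sample id with columns ``donor_id``,
        ``hemisphere`` (``L``/``R``), ``region`` (atlas label or
        ``unassigned``).
    background : optional DataFrame, same shape as ``expression``, boolean,
        True where the measurement is above background intensity.
    """

    expression: pd.DataFrame
    probes: pd.DataFrame
    samples: pd.DataFrame
    background: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.expression.index) != list(self.samples.index):
            raise DataError("expression rows and sample metadata do not match")
        if list(self.expression.columns) != list(self.probes.index):
            raise DataError("expression columns and probe metadata do not match")
        if self.background is not None and self.background.shape != self.expression.shape:
            raise DataError("background flag matrix shape mismatch")
        if self.samples["donor_id"].isna().any():
            raise DataError("empty donor ids in sample metadata")

    @property
    def n_probes(self) -> int:
        return self.expression.shape[1]

    def subset_probes(self, probe_ids) -> "ProbeExpressionDataset":
        probe_ids = list(probe_ids)
        return replace(
            self,
            expression=self.expression[probe_ids],
            probes=self.probes.loc[probe_ids],
            background=None if self.background is None else self.background[probe_ids],
        )


def annotate_probes(ds: ProbeExpressionDataset) -> ProbeExpressionDataset:
    """Drop probes without a gene annotation."""
    gene = ds.probes["gene_symbol"]
    keep = gene.notna() & (gene.astype(str).str.strip() != "")
    n_drop = int((~keep).sum())
    if n_drop:
        warnings.warn(f"dropping {n_drop} unannotated probe(s)")
    if not keep.any():
        raise DataError("no annotated probes remain")
    return ds.subset_probes(ds.probes.index[keep])


def filter_probes_by_intensity(ds: ProbeExpressionDataset,
                               min_fraction: float = 0.5) -> ProbeExpressionDataset:
    """Keep probes above background in strictly more than ``min_fraction`` of samples.

    Datasets without background flags pass through unchanged (warning).
    """
    if ds.background is None:
        warnings.warn("no background flags: intensity filter skipped")
        return ds
    frac = ds.background.to_numpy(dtype=float).mean(axis=0)
    keep = frac > min_fraction
    n_drop = int((~keep).sum())
    if n_drop:
        warnings.warn(f"dropping {n_drop} probe(s) at or below "
                      f"background fraction {min_fraction}")
    if not keep.any():
        raise DataError("no probes pass the intensity filter")
    return ds.subset_probes(ds.expression.columns[keep])


def _region_profiles(ds: ProbeExpressionDataset) -> dict[str, pd.DataFrame]:
    """Per-donor region-mean profiles (regions × probes), left hemisphere only."""
    meta = ds.samples
    usable = (meta["hemisphere"] == "L") & (meta["region"] != "unassigned")
    out: dict[str, pd.DataFrame] = {}
    for donor, sub in meta[usable].groupby("donor_id"):
        out[str(donor)] = ds.expression.loc[sub.index].groupby(sub["region"]).mean()
    return out


def differential_stability(ds: ProbeExpressionDataset) -> pd.Series:
    """Mean inter-donor Pearson correlation of each probe's regional profile.

    Computed over regions common to each donor pair; probes with an
    undefined correlation for every pair get NaN.
    """
    profiles = _region_profiles(ds)
    donors = sorted(profiles)
    if len(donors) < 2:
        raise DataError("differential stability needs at least 2 donors")
    sums = np.zeros(ds.n_probes)
    counts = np.zeros(ds.n_probes)
    for da, db in itertools.combinations(donors, 2):
        a, b = profiles[da], profiles[db]
        common = a.index.intersection(b.index)
        if len(common) < 3:
            continue
        xa = a.loc[common].to_numpy(dtype=float)
        xb = b.loc[common].to_numpy(dtype=float)
        xa = xa - xa.mean(axis=0)
        xb = xb - xb.mean(axis=0)
        denom = np.sqrt((xa ** 2).sum(axis=0) * (xb ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xa * xb).sum(axis=0) / denom
        ok = np.isfinite(r)
        sums[ok] += r[ok]
        counts[ok] += 1
    with np.errstate(invalid="ignore"):
        ds_score = sums / counts
    return pd.Series(ds_score, index=ds.expression.columns, name="differential_stability")


def select_representative_probes(ds: ProbeExpressionDataset) -> ProbeExpressionDataset:
    """One probe per gene: maximal differential stability across donors.

    With a single donor, falls back to the probe with highest mean
    expression. Exact ties are broken toward the lexicographically smaller
    probe id.
    """
    n_donors = ds.samples["donor_id"].nunique()
    if n_donors >= 2:
        score = differential_stability(ds)
    else:
        warnings.warn("single donor: selecting probes by mean expression")
        score = ds.expression.mean(axis=0)
    score = score.fillna(-np.inf)
    tab = pd.DataFrame({
        "probe_id": ds.probes.index,
        "gene_symbol": ds.probes["gene_symbol"].to_numpy(),
        "score": score.to_numpy(),
    })
    # stable sort: descending score, ascending probe id on ties
    tab = tab.sort_values(["score", "probe_id"], ascending=[False, True],
                          kind="mergesort")
    chosen = tab.drop_duplicates("gene_symbol", keep="first")["probe_id"]
    chosen = [p for p in ds.probes.index if p in set(chosen)]  # original order
    return ds.subset_probes(chosen)


def assign_and_aggregate(ds: ProbeExpressionDataset,
                         atlas: list[str]) -> dict[str, pd.DataFrame]:
    """Per-donor region × gene matrices over left-hemisphere atlas regions.

    Right-hemisphere and unassigned samples are excluded; each region's
    value is the mean over that donor's samples in the region. A region with
    no samples in any donor is an error. Columns are renamed from probe ids
    to gene symbols (one probe per gene expected at this stage).
    """
    profiles = _region_profiles(ds)
    if not profiles:
        raise DataError("no assigned left-hemisphere samples")
    covered: set[str] = set()
    gene_of = ds.probes["gene_symbol"]
    out: dict[str, pd.DataFrame] = {}
    for donor, prof in profiles.items():
        prof = prof.loc[[r for r in atlas if r in prof.index]]
        prof.columns = [gene_of[p] for p in prof.columns]
        covered.update(prof.index)
        out[donor] = prof
    missing = [r for r in atlas if r not in covered]
    if missing:
        raise DataError(f"atlas regions with no samples in any donor: {missing}")
    return out


def scaled_robust_sigmoid(x: np.ndarray) -> np.ndarray:
    """Robust sigmoid of a 1-d profile, rescaled to [0, 1].

    x' = 1 / (1 + exp(−(x − median) / (IQR / 1.35))); the result is then
    min-max rescaled. A zero IQR (flat profile) maps everything to 0.5.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        return np.full(x.shape, 0.5)
    s = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / 1.35)))
    lo, hi = s.min(), s.max()
    if hi == lo:
        return np.full(x.shape, 0.5)
    return (s - lo) / (hi - lo)


def normalize_expression(per_donor: dict[str, pd.DataFrame],
                         atlas: list[str]) -> pd.DataFrame:
    """Scaled-robust-sigmoid normalize each donor per gene, then average donors.

    Genes missing from any donor are dropped (complete-case across donors).
    Flat profiles within a donor normalize to 0.5 (warning). Returns the
    regions × genes matrix over ``atlas`` regions, values in [0, 1].
    """
    if not per_donor:
        raise DataError("no donor matrices to normalize")
    donors = sorted(per_donor)
    genes = set(per_donor[donors[0]].columns)
    for d in donors[1:]:
        genes &= set(per_donor[d].columns)
    if not genes:
        raise DataError("no genes shared across all donors")
    genes = [g for g in per_donor[donors[0]].columns if g in genes]
    n_flat = 0
    acc = pd.DataFrame(0.0, index=atlas, columns=genes)
    weight = pd.DataFrame(0.0, index=atlas, columns=genes)
    for d in donors:
        mat = per_donor[d][genes]
        vals = mat.to_numpy(dtype=float)
        normed = np.empty_like(vals)
        for j in range(vals.shape[1]):
            if np.ptp(vals[:, j]) == 0:
                n_flat += 1
            normed[:, j] = scaled_robust_sigmoid(vals[:, j])
        nd = pd.DataFrame(normed, index=mat.index, columns=genes)
        present = [r for r in atlas if r in nd.index]
        acc.loc[present] += nd.loc[present]
        weight.loc[present] += 1.0
    if n_flat:
        warnings.warn(f"{n_flat} flat gene profile(s) normalized to 0.5")
    if (weight == 0).any().any():
        raise DataError("some atlas regions covered by no donor after aggregation")
    return acc / weight


def prepare_region_expression(ds: ProbeExpressionDataset, atlas: list[str],
                              min_background_fraction: float = 0.5) -> pd.DataFrame:
    """Run the full five-step preprocessing chain; returns regions × genes."""
    ds = annotate_probes(ds)
    ds = filter_probes_by_intensity(ds, min_fraction=min_background_fraction)
    ds = select_representative_probes(ds)
    per_donor = assign_and_aggregate(ds, atlas)
    return normalize_expression(per_donor, atlas)


def read_probe_dataset(samples_path, probes_path, expression_path,
                       background_path=None) -> ProbeExpressionDataset:
    """Load the TSV triplet (samples, probes, expression [+ background flags])."""
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    probes = pd.read_csv(probes_path, sep="\t", index_col="probe_id")
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    background = None
    if background_path is not None:
        background = pd.read_csv(background_path, sep="\t", index_col=0).astype(bool)
    return ProbeExpressionDataset(expression=expr, probes=probes,
                                  samples=samples, background=background)


def write_probe_dataset(ds: ProbeExpressionDataset, samples_path, probes_path,
                        expression_path, background_path=None) -> None:
    ds.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t")
    ds.probes.rename_axis("probe_id").to_csv(probes_path, sep="\t")
    ds.expression.rename_axis("sample_id").to_csv(expression_path, sep="\t")
    if background_path is not None and ds.background is not None:
        ds.background.astype(int).rename_axis("sample_id").to_csv(
            background_path, sep="\t")
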