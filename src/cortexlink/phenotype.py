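"""Step 1 — cortical-thickness phenotype maps.

Residualizes region-level cortical thickness (CT) on nuisance covariates
(age, sex, total intracranial volume), builds case-control and longitudinal
t-statistic maps with BH-FDR correction across regions, computes PANSS
symptom reduction rates, and runs Euler-number quality-control comparisons
on externally supplied Euler numbers.

CT tables are pandas DataFrames with one row per subject, metadata columns
(``subject_id``, ``group``, ``age``, ``sex``, ``tiv``) and one column per
cortical region (hemisphere-prefixed names, see :mod:`cortexlink.atlas`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr
from .errors import DataError, NumericalError

CT_COVARIATES = ("age", "sex", "tiv")

#: PANSS subscale minima: 7 positive items, 7 negative items, 16 general items.
PANSS_MINIMA = {"panss_p": 7, "panss_n": 7, "panss_g": 16}


def region_columns(table: pd.DataFrame) -> list[str]:
    """Columns of ``table`` holding regional CT values (L_/R_ prefixed)."""
    return [c for c in table.columns if str(c).startswith(("L_", "R_"))]


@dataclass
class TStatMap:
    """Per-region t statistics for a group contrast.

    Attributes
    ----------
    table : DataFrame indexed by region with columns ``t``, ``p``, ``q``.
    contrast : ``"case_control"`` or ``"longitudinal"``.
    sign_convention : human-readable description of the t sign.
    """

    table: pd.DataFrame
    contrast: str
    sign_convention: str
    n_dropped: int = 0

    @property
    def regions(self) -> list[str]:
        return list(self.table.index)

    @property
    def t(self) -> pd.Series:
        return self.table["t"]

    def to_tsv(self, path) -> None:
        self.table.rename_axis("region").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, contrast: str = "unknown",
                 sign_convention: str = "unknown") -> "TStatMap":
        tab = pd.read_csv(path, sep="\t", index_col="region")
        return cls(table=tab, contrast=contrast, sign_convention=sign_convention)


def _design_matrix(table: pd.DataFrame, covariates) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in covariates]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which covariate columns are redundant given the others
        bad = []
        for j in range(1, X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(covariates[j - 1])
        raise NumericalError(
            f"rank-deficient covariate design; collinear columns: {bad or covariates}"
        )
    return X


def residualize_ct(table: pd.DataFrame, covariates=CT_COVARIATES) -> pd.DataFrame:
    """OLS-residualize every regional CT column on intercept + covariates.

    The model is fitted on all subjects present in ``table`` (pool the groups
    entering a comparison before calling this). Returns a copy of the table
    with region columns replaced by residuals; metadata columns are kept.
    """
    if table["subject_id"].duplicated().any():
        raise DataError("duplicate subject ids in CT table")
    if len(table) < 5:
        raise DataError(f"need at least 5 subjects to residualize, got {len(table)}")
    regions = region_columns(table)
    if not regions:
        raise DataError("no regional CT columns (expected L_/R_ prefixes)")
    X = _design_matrix(table, covariates)
    Y = table[regions].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    out = table.copy()
    out[regions] = Y - X @ beta
    return out


def residualize_pair(table_0w: pd.DataFrame, table_8w: pd.DataFrame,
                     covariates=CT_COVARIATES):
    """Residualize two timepoint tables with one pooled covariate fit.

    The paired comparison pools both timepoints (each subject appears once
    per timepoint) into a single OLS design, then splits the residuals back.
    Returns ``(resid_0w, resid_8w)``.
    """
    regions = _check_same_regions(table_0w, table_8w)
    pooled = pd.concat([table_0w, table_8w], ignore_index=True)
    if len(pooled) < 5:
        raise DataError("need at least 5 pooled records to residualize")
    X = _design_matrix(pooled, covariates)
    Y = pooled[regions].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    r0 = table_0w.copy()
    r0[regions] = resid[: len(table_0w)]
    r8 = table_8w.copy()
    r8[regions] = resid[len(table_0w):]
    return r0, r8


def _check_same_regions(a: pd.DataFrame, b: pd.DataFrame) -> list[str]:
    ra, rb = region_columns(a), region_columns(b)
    if ra != rb:
        raise DataError(
            "region sets differ between tables: "
            f"only-in-first={sorted(set(ra) - set(rb))}, "
            f"only-in-second={sorted(set(rb) - set(ra))}"
        )
    return ra


def case_control_tmap(resid_patients: pd.DataFrame, resid_controls: pd.DataFrame,
                      equal_var: bool = True) -> TStatMap:
    """Independent-samples t map, sign = mean(patients) − mean(controls).

    Pooled-variance (Student) t by default; set ``equal_var=False`` for Welch.
    BH-FDR across regions.
    """
    regions = _check_same_regions(resid_patients, resid_controls)
    if set(resid_patients["subject_id"]) & set(resid_controls["subject_id"]):
        raise DataError("patient and control subject sets overlap")
    if len(resid_patients) < 2 or len(resid_controls) < 2:
        raise DataError("each group needs at least 2 subjects")
    a = resid_patients[regions].to_numpy(dtype=float)
    b = resid_controls[regions].to_numpy(dtype=float)
    res = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # identical groups give 0/0 -> nan; define t=0, p=1 (no evidence either way)
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    tab = pd.DataFrame({"t": t, "p": p, "q": bh_fdr(p)}, index=regions)
    return TStatMap(tab, contrast="case_control",
                    sign_convention="positive = thicker in patients")


def longitudinal_tmap(resid_0w: pd.DataFrame, resid_8w: pd.DataFrame) -> TStatMap:
    """Paired t map on (8W − 0W) residual CT; cortical thinning gives t < 0.

    Subjects missing either timepoint are dropped (count recorded on the
    returned map). Regions with zero within-pair variance but a nonzero mean
    difference yield ±inf with p = 0 and a warning.
    """
    regions = _check_same_regions(resid_0w, resid_8w)
    common = [s for s in resid_0w["subject_id"] if s in set(resid_8w["subject_id"])]
    n_dropped = (len(resid_0w) - len(common)) + (len(resid_8w) - len(common))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} subject records missing a timepoint")
    if len(common) < 2:
        raise DataError(f"need at least 2 complete pairs, got {len(common)}")
    a0 = resid_0w.set_index("subject_id").loc[common, regions].to_numpy(dtype=float)
    a8 = resid_8w.set_index("subject_id").loc[common, regions].to_numpy(dtype=float)
    d = a8 - a0
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    zero_sd = sd == 0
    if zero_sd.any():
        shifted = zero_sd & (mean != 0)
        t[zero_sd & (mean == 0)] = 0.0
        p[zero_sd & (mean == 0)] = 1.0
        if shifted.any():
            warnings.warn(
                f"{int(shifted.sum())} region(s) with zero within-pair variance "
                "and nonzero shift: t set to +/-inf with p=0"
            )
            t[shifted] = np.where(mean[shifted] > 0, np.inf, -np.inf)
            p[shifted] = 0.0
    tab = pd.DataFrame({"t": t, "p": p, "q": bh_fdr(p)}, index=regions)
    return TStatMap(tab, contrast="longitudinal",
                    sign_convention="positive = thickening 8W vs 0W",
                    n_dropped=n_dropped)


def subset_left_hemisphere(tmap: TStatMap, expected: int | None = 34) -> TStatMap:
    """Restrict a t map to left-hemisphere (``L_``-prefixed) regions.

    Raises :class:`DataError` if the number of left regions found differs
    from ``expected`` (pass ``expected=None`` to accept any nonzero count).
    """
    left = [r for r in tmap.regions if str(r).startswith("L_")]
    if not left:
        raise DataError("no left-hemisphere (L_) regions in t map")
    if expected is not None and len(left) != expected:
        raise DataError(
            f"expected {expected} left-hemisphere regions, found {len(left)}: {left}"
        )
    return TStatMap(tmap.table.loc[left].copy(), contrast=tmap.contrast,
                    sign_convention=tmap.sign_convention, n_dropped=tmap.n_dropped)


def reduction_rates(panss_0w: pd.DataFrame, panss_8w: pd.DataFrame) -> pd.DataFrame:
    """PANSS reduction rates per symptom dimension.

    rr = (score_0W − score_8W) / (score_0W − minimum), with subscale minima
    7 (positive), 7 (negative) and 16 (general). rr = 1 means complete
    normalization to the scale floor; rr = 0 means no change; rr < 0 means
    worsening. A baseline score at the scale floor makes the rate undefined
    (NaN, with a warning).

    Both inputs have columns ``subject_id``, ``panss_p``, ``panss_n``,
    ``panss_g``; rows are matched on ``subject_id`` (inner join).
    """
    p0 = panss_0w.set_index("subject_id")
    p8 = panss_8w.set_index("subject_id")
    common = [s for s in p0.index if s in set(p8.index)]
    if not common:
        raise DataError("no subjects present at both PANSS timepoints")
    out = pd.DataFrame({"subject_id": common})
    for col, minimum in PANSS_MINIMA.items():
        s0 = p0.loc[common, col].to_numpy(dtype=float)
        s8 = p8.loc[common, col].to_numpy(dtype=float)
        if (s0 < minimum).any() or (s8 < minimum).any():
            raise DataError(f"{col} scores below scale minimum {minimum}")
        denom = s0 - minimum
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = (s0 - s8) / denom
        if (denom == 0).any():
            warnings.warn(
                f"{int((denom == 0).sum())} subject(s) at the {col} scale floor "
                "at baseline: reduction rate undefined (NaN)"
            )
            rr[denom == 0] = np.nan
        out["rr_" + col.split("_")[1]] = rr
    return out


@dataclass
class EulerQCReport:
    """Euler-number image-quality comparison outcomes."""

    case_control_t: float
    case_control_p: float
    longitudinal_t: float | None
    longitudinal_p: float | None
    alpha: float = 0.05
    warnings: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        """True when no comparison shows a significant quality difference."""
        ps = [self.case_control_p]
        if self.longitudinal_p is not None:
            ps.append(self.longitudinal_p)
        return all(p > self.alpha for p in ps)

    def to_dict(self) -> dict:
        return {
            "case_control": {"t": self.case_control_t, "p": self.case_control_p},
            "longitudinal": (
                None if self.longitudinal_t is None
                else {"t": self.longitudinal_t, "p": self.longitudinal_p}
            ),
            "alpha": self.alpha,
            "no_significant_differences": self.passed,
            "warnings": list(self.warnings),
        }


def euler_qc(euler: pd.DataFrame, alpha: float = 0.05) -> EulerQCReport:
    """QC t tests on per-scan Euler numbers (computed upstream of this package).

    ``euler`` has columns ``subject_id``, ``group`` (one of ``control``,
    ``patient_0w``, ``patient_8w``) and ``euler``. Runs the independent
    case-control test (patient_0w vs control) and the paired longitudinal
    test (patient_0w vs patient_8w matched on subject id).
    """
    notes: list[str] = []
    groups = {g: sub for g, sub in euler.groupby("group")}
    for needed in ("control", "patient_0w"):
        if needed not in groups:
            raise DataError(f"euler table missing group '{needed}'")
    cc = stats.ttest_ind(
        groups["patient_0w"]["euler"].to_numpy(dtype=float),
        groups["control"]["euler"].to_numpy(dtype=float),
        equal_var=True,
    )
    cc_t, cc_p = float(cc.statistic), float(cc.pvalue)
    if not np.isfinite(cc_t):  # identical constant groups
        cc_t, cc_p = 0.0, 1.0

    lt = lp = None
    if "patient_8w" in groups:
        g0 = groups["patient_0w"].set_index("subject_id")["euler"]
        g8 = groups["patient_8w"].set_index("subject_id")["euler"]
        common = [s for s in g0.index if s in set(g8.index)]
        if len(common) >= 2:
            d = g8.loc[common].to_numpy(dtype=float) - g0.loc[common].to_numpy(dtype=float)
            if d.std(ddof=1) == 0:
                lt, lp = (0.0, 1.0) if d.mean() == 0 else (np.inf * np.sign(d.mean()), 0.0)
            else:
                res = stats.ttest_rel(g8.loc[common], g0.loc[common])
                lt, lp = float(res.statistic), float(res.pvalue)
        else:
            notes.append("longitudinal Euler test skipped: fewer than 2 matched pairs")
            warnings.warn(notes[-1])
    else:
        notes.append("longitudinal Euler test skipped: no patient_8w group")
        warnings.warn(notes[-1])
    return EulerQCReport(cc_t, cc_p, lt, lp, alpha=alpha, warnings=notes)
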