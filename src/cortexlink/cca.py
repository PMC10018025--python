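"""Step 3 — DNA-methylation / clinical-symptom canonical correlation analysis.

Pipeline: CpG-level beta values are averaged per gene to give a subjects ×
genes methylation matrix per timepoint; longitudinal change is the
baseline-minus-follow-up delta. Because the gene panel is wide relative to
the cohort, unsupervised Laplacian-score feature selection (k-NN
heat-kernel graph over subjects) keeps the ``s`` most locality-preserving
gene features before fitting. Canonical correlation analysis then finds
paired linear combinations U_i = X a_i (methylation) and V_i = Y b_i
(clinical scores) maximizing corr(U_i, V_i); significance is assessed by a
max-statistic permutation test controlling family-wise error across modes,
and significant modes are interpreted through variate-to-variable Pearson
loadings with BH-FDR across genes.

Usage::

    model = SymptomCCA(dnam_delta, reduction_rates)   # subjects aligned
    res = model.fit(n_perm=10_000, seed=17)
    res.summary()
    res.loadings(mode=1)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from ._stats import bh_fdr
from .errors import ConfigError, DataError, NumericalError

# ---------------------------------------------------------------------------
# gene-level methylation
# ---------------------------------------------------------------------------

def aggregate_cpg_to_gene(beta: pd.DataFrame, manifest: pd.DataFrame,
                          genes) -> pd.DataFrame:
    """Average CpG beta values per gene; returns subjects × genes.

    ``beta`` is CpG × subject; ``manifest`` has columns ``cpg_id`` and
    ``gene`` (a CpG mapping to several genes contributes to each). Genes
    with no CpG in the manifest or the beta matrix are dropped with a
    warning. Missing betas are ignored in the per-subject mean; a gene with
    no observed CpG for a subject propagates NaN.
    """
    genes = list(genes)
    by_gene = manifest.groupby("gene")["cpg_id"]
    cols = {}
    missing = []
    cpg_index = set(beta.index)
    for g in genes:
        if g not in by_gene.groups:
            missing.append(g)
            continue
        cpgs = [c for c in by_gene.get_group(g) if c in cpg_index]
        if not cpgs:
            missing.append(g)
            continue
        cols[g] = beta.loc[cpgs].mean(axis=0, skipna=True)
    if missing:
        warnings.warn(f"{len(missing)} gene(s) without CpG coverage dropped: "
                      f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    if not cols:
        raise DataError("no requested gene has CpG coverage")
    out = pd.DataFrame(cols)
    out.index.name = "subject_id"
    return out


def compute_delta(m0: pd.DataFrame, m8: pd.DataFrame) -> pd.DataFrame:
    """Longitudinal methylation change, baseline minus follow-up (0W − 8W)."""
    if set(m0.columns) != set(m8.columns):
        raise DataError("gene sets differ between timepoints")
    common = [s for s in m0.index if s in set(m8.index)]
    if not common:
        raise DataError("no subjects shared between timepoints")
    if len(common) < len(m0) or len(common) < len(m8):
        warnings.warn(f"delta restricted to {len(common)} subjects present "
                      "at both timepoints")
    return m0.loc[common] - m8.loc[common, m0.columns]


# ---------------------------------------------------------------------------
# Laplacian-score feature selection
# ---------------------------------------------------------------------------

def _knn_heat_graph(X: np.ndarray, k: int):
    """Symmetric k-NN heat-kernel affinity over rows of X.

    Edge weights exp(−d²/σ) with σ = mean squared distance to the k nearest
    neighbours; an edge exists when either endpoint is among the other's k
    nearest (no self loops).
    """
    n = X.shape[0]
    if k >= n:
        raise ConfigError(f"k-NN graph needs k < n subjects (k={k}, n={n})")
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    order = np.argsort(d2, axis=1, kind="mergesort")
    neigh = order[:, 1:k + 1]  # first column is self (distance 0)
    sigma = float(np.mean(d2[np.arange(n)[:, None], neigh]))
    if sigma == 0:
        sigma = 1.0  # all subjects identical: uniform affinities
    adj = np.zeros((n, n), dtype=bool)
    adj[np.arange(n)[:, None], neigh] = True
    adj |= adj.T
    S = np.where(adj, np.exp(-d2 / sigma), 0.0)
    return S, sigma


def laplacian_scores(X: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Laplacian score of every feature column (smaller = more representative).

    Builds the k-NN heat-kernel graph on subjects from all features, then
    scores feature r as  L_r = x̃ᵀ L x̃ / x̃ᵀ D x̃  with L = D − S the graph
    Laplacian, D the degree matrix and x̃ the feature centered by its
    degree-weighted mean. Zero-variance features are flagged (NaN score)
    and ranked last. Returns a DataFrame (score, rank, constant) indexed by
    feature, plus graph parameters in ``attrs``.
    """
    vals = X.to_numpy(dtype=float)
    S, sigma = _knn_heat_graph(vals, k)
    deg = S.sum(axis=1)
    total = deg.sum()
    L = np.diag(deg) - S
    scores = np.full(vals.shape[1], np.nan)
    for j in range(vals.shape[1]):
        x = vals[:, j]
        if np.ptp(x) == 0:
            continue
        xt = x - (x @ deg) / total
        denom = xt @ (deg * xt)
        if denom <= 0:
            continue
        scores[j] = (xt @ L @ xt) / denom
    out = pd.DataFrame({"score": scores}, index=X.columns)
    out["constant"] = ~np.isfinite(scores)
    # ascending score; NaN (constant/degenerate) features rank last
    out["rank"] = out["score"].rank(method="first", na_option="bottom").astype(int)
    out.attrs["k"] = k
    out.attrs["sigma"] = sigma
    out.index.name = "feature"
    return out


def select_features(score_table: pd.DataFrame, s: int) -> list:
    """The ``s`` features with smallest Laplacian score; ties by feature name."""
    scored = score_table[np.isfinite(score_table["score"])]
    if s > len(scored):
        raise ConfigError(f"requested s={s} features but only {len(scored)} scored")
    ordered = scored.sort_index(kind="mergesort").sort_values(
        "score", kind="mergesort")
    return list(ordered.index[:s])


# ---------------------------------------------------------------------------
# canonical correlation analysis
# ---------------------------------------------------------------------------

def _center_scale(A: np.ndarray, standardize: bool) -> np.ndarray:
    A = A - A.mean(axis=0)
    if standardize:
        sd = A.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DataError(f"zero-variance columns at positions "
                            f"{list(np.flatnonzero(sd == 0))}")
        A = A / sd
    return A


class SymptomCCA:
    """CCA between a methylation block X (n × s) and a clinical block Y (n × t).

    Columns are z-scored by default. Canonical weights come from the SVD of
    the whitened cross-covariance (QR decompositions of the centered
    blocks); weights are scaled so every variate has unit variance.
    """

    def __init__(self, dnam: pd.DataFrame, clinical: pd.DataFrame,
                 standardize: bool = True):
        if list(dnam.index) != list(clinical.index):
            common = [i for i in dnam.index if i in set(clinical.index)]
            if len(common) != len(dnam) or len(common) != len(clinical):
                warnings.warn(f"restricting CCA to {len(common)} shared subjects")
            if len(common) < 3:
                raise DataError("CCA needs at least 3 shared subjects")
            dnam = dnam.loc[common]
            clinical = clinical.loc[common]
        n, s = dnam.shape
        t = clinical.shape[1]
        if s < 1 or t < 1:
            raise DataError("both blocks need at least one column")
        if n <= s + t:
            warnings.warn(f"n={n} subjects <= s+t={s + t} variables: canonical "
                          "correlations will be inflated; consider smaller s")
        self.subjects = list(dnam.index)
        self.x_names = list(dnam.columns)
        self.y_names = list(clinical.columns)
        self._Xc = _center_scale(dnam.to_numpy(dtype=float), standardize)
        self._Yc = _center_scale(clinical.to_numpy(dtype=float), standardize)
        self.n, self.s, self.t = n, s, t

    def _qr(self, A: np.ndarray, block: str):
        Q, R = np.linalg.qr(A)
        if np.min(np.abs(np.diag(R))) < 1e-10 * max(1.0, np.max(np.abs(np.diag(R)))):
            raise NumericalError(
                f"singular within-set covariance in the {block} block; "
                "reduce the number of selected features"
            )
        return Q, R

    def fit(self, n_perm: int = 10_000, seed=None) -> "SymptomCCAResults":
        """Fit all min(s, t) canonical modes; ``n_perm=0`` skips the FWE test."""
        Qx, Rx = self._qr(self._Xc, "methylation")
        Qy, Ry = self._qr(self._Yc, "clinical")
        U, sv, Vt = np.linalg.svd(Qx.T @ Qy)
        m = min(self.s, self.t)
        rho = np.clip(sv[:m], 0.0, 1.0)
        scale = np.sqrt(self.n - 1)
        a = np.linalg.solve(Rx, U[:, :m]) * scale
        b = np.linalg.solve(Ry, Vt.T[:, :m]) * scale
        x_var = self._Xc @ a
        y_var = self._Yc @ b

        p_fwe = max_null = None
        if n_perm:
            if n_perm < 100:
                raise ConfigError(f"n_perm must be >= 100, got {n_perm}")
            rng = np.random.default_rng(seed)
            max_null = np.empty(n_perm)
            for i in range(n_perm):
                perm = rng.permutation(self.n)
                max_null[i] = np.linalg.svd(Qx.T @ Qy[perm], compute_uv=False)[0]
            p_fwe = np.array([
                (1 + int((max_null >= r).sum())) / (n_perm + 1) for r in rho
            ])

        return SymptomCCAResults(
            model=self,
            canonical_correlations=rho,
            x_weights=pd.DataFrame(a, index=self.x_names,
                                   columns=[f"mode{i+1}" for i in range(m)]),
            y_weights=pd.DataFrame(b, index=self.y_names,
                                   columns=[f"mode{i+1}" for i in range(m)]),
            x_variates=pd.DataFrame(x_var, index=self.subjects,
                                    columns=[f"U{i+1}" for i in range(m)]),
            y_variates=pd.DataFrame(y_var, index=self.subjects,
                                    columns=[f"V{i+1}" for i in range(m)]),
            p_fwe=p_fwe, max_null=max_null, n_perm=n_perm,
        )


@dataclass
class SymptomCCAResults:
    """Fitted canonical modes with permutation FWE inference."""

    model: SymptomCCA
    canonical_correlations: np.ndarray
    x_weights: pd.DataFrame
    y_weights: pd.DataFrame
    x_variates: pd.DataFrame
    y_variates: pd.DataFrame
    p_fwe: np.ndarray | None
    max_null: np.ndarray | None = field(default=None, repr=False)
    n_perm: int = 0

    @property
    def n_modes(self) -> int:
        return len(self.canonical_correlations)

    def loadings(self, mode: int = 1, alpha: float = 0.05,
                 force: bool = False) -> pd.DataFrame:
        """Variate-to-variable Pearson loadings of X columns on V_mode.

        Correlates every (standardized) methylation feature with the
        clinical canonical variate of the requested mode; two-sided p from
        the exact t reference, BH-FDR across features, significance at
        ``q < alpha``. Warns when the mode itself is not FWE-significant
        (pass ``force=True`` to silence).
        """
        if not 1 <= mode <= self.n_modes:
            raise ConfigError(f"mode must be in 1..{self.n_modes}")
        if self.p_fwe is not None and self.p_fwe[mode - 1] >= alpha and not force:
            warnings.warn(
                f"mode {mode} is not FWE-significant "
                f"(P_FWE={self.p_fwe[mode - 1]:.4g}); loadings are exploratory"
            )
        v = self.y_variates.iloc[:, mode - 1].to_numpy()
        X = self.model._Xc
        n = len(v)
        vc = v - v.mean()
        denom = np.sqrt((X ** 2).sum(axis=0) * (vc ** 2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = X.T @ vc / denom
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = r * np.sqrt((n - 2) / (1 - r ** 2))
        p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
        p[np.abs(r) == 1.0] = 0.0
        q = bh_fdr(p)
        tab = pd.DataFrame({"r": r, "p": p, "q": q, "significant": q < alpha},
                           index=pd.Index(self.model.x_names, name="gene"))
        return tab.sort_values("q", kind="mergesort")

    def summary(self) -> str:
        lines = [
            "Symptom CCA",
            "=" * 45,
            f"n={self.model.n} subjects, s={self.model.s} methylation features, "
            f"t={self.model.t} clinical variables",
        ]
        for i, rho in enumerate(self.canonical_correlations):
            extra = ""
            if self.p_fwe is not None:
                extra = f"   P_FWE = {self.p_fwe[i]:.4g} ({self.n_perm} perms)"
            lines.append(f"mode {i + 1}: rho = {rho:.4f}{extra}")
        return "\n".join(lines)

    def plot_mode(self, mode: int = 1, ax=None):
        """Scatter of the paired canonical variates for one mode."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4))
        u = self.x_variates.iloc[:, mode - 1]
        v = self.y_variates.iloc[:, mode - 1]
        ax.scatter(u, v, s=18)
        ax.set_xlabel(f"methylation variate U{mode}")
        ax.set_ylabel(f"clinical variate V{mode}")
        rho = self.canonical_correlations[mode - 1]
        ax.set_title(f"mode {mode}: rho = {rho:.3f}")
        return ax


# -- thin functional wrappers ---------------------------------------------

def fit_cca(X: pd.DataFrame, Y: pd.DataFrame,
            standardize: bool = True) -> SymptomCCAResults:
    """Fit canonical modes only (no permutation inference)."""
    return SymptomCCA(X, Y, standardize=standardize).fit(n_perm=0)


def permutation_fwe(X: pd.DataFrame, Y: pd.DataFrame, n_perm: int = 10_000,
                    seed=None, standardize: bool = True) -> np.ndarray:
    """Max-statistic permutation P_FWE per canonical mode."""
    res = SymptomCCA(X, Y, standardize=standardize).fit(n_perm=n_perm, seed=seed)
    return res.p_fwe


def loading_correlations(cca: SymptomCCAResults, mode: int = 1,
                         alpha: float = 0.05, force: bool = False) -> pd.DataFrame:
    return cca.loadings(mode=mode, alpha=alpha, force=force)


# ---------------------------------------------------------------------------
# step-3 orchestration
# ---------------------------------------------------------------------------

@dataclass
class Step3Report:
    """Both step-3 analyses: baseline levels and longitudinal change."""

    baseline: SymptomCCAResults
    longitudinal: SymptomCCAResults
    baseline_loadings: pd.DataFrame
    longitudinal_loadings: pd.DataFrame
    selected_baseline: list
    selected_longitudinal: list
    n_subjects: int

    def summary(self) -> str:
        out = ["Step 3: DNAm / clinical-symptom CCA", "=" * 45,
               f"subjects with complete data: {self.n_subjects}", "",
               "[baseline DNAm vs baseline PANSS]"]
        out.append(self.baseline.summary())
        out += ["", "[DNAm change (0W-8W) vs PANSS reduction rates]"]
        out.append(self.longitudinal.summary())
        n_sig = int(self.longitudinal_loadings["significant"].sum())
        out.append(f"significant loading genes (mode 1, q<0.05): {n_sig}")
        return "\n".join(out)


def run_step3(beta_0w: pd.DataFrame, beta_8w: pd.DataFrame,
              manifest: pd.DataFrame, panss_0w: pd.DataFrame,
              panss_8w: pd.DataFrame, genes, s: int = 30, k: int = 5,
              n_perm: int = 10_000, seed=None, alpha: float = 0.05) -> Step3Report:
    """Full epigenetic arm: aggregation, feature selection, both CCAs.

    (a) baseline gene-level DNAm vs baseline PANSS positive/negative/general
    scores; (b) longitudinal DNAm change (0W − 8W) vs the three PANSS
    reduction rates. Subjects missing either methylation timepoint or either
    PANSS assessment are dropped pairwise. Loading tables are computed for
    mode 1 of each analysis (exploratory when the mode is not significant).
    """
    from .phenotype import reduction_rates  # local import avoids cycle

    m0 = aggregate_cpg_to_gene(beta_0w, manifest, genes)
    m8 = aggregate_cpg_to_gene(beta_8w, manifest, genes)
    rr = reduction_rates(panss_0w, panss_8w).set_index("subject_id")
    p0 = panss_0w.set_index("subject_id")

    common = [sid for sid in m0.index
              if sid in set(m8.index) and sid in set(rr.index)]
    rr = rr.loc[common].dropna()
    common = list(rr.index)
    if len(common) < max(8, k + 1):
        raise DataError(f"only {len(common)} subjects with complete data")

    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=2)

    # (a) baseline levels
    Xb = m0.loc[common]
    sel_b = select_features(laplacian_scores(Xb, k=k), s)
    Yb = p0.loc[common, ["panss_p", "panss_n", "panss_g"]].astype(float)
    res_b = SymptomCCA(Xb[sel_b], Yb).fit(n_perm=n_perm, seed=int(seeds[0]))
    load_b = res_b.loadings(mode=1, alpha=alpha, force=True)

    # (b) longitudinal change
    delta = compute_delta(m0.loc[common], m8.loc[common])
    sel_l = select_features(laplacian_scores(delta, k=k), s)
    Yl = rr.loc[common, ["rr_p", "rr_n", "rr_g"]]
    res_l = SymptomCCA(delta[sel_l], Yl).fit(n_perm=n_perm, seed=int(seeds[1]))
    load_l = res_l.loadings(mode=1, alpha=alpha, force=True)

    return Step3Report(
        baseline=res_b, longitudinal=res_l,
        baseline_loadings=load_b, longitudinal_loadings=load_l,
        selected_baseline=sel_b, selected_longitudinal=sel_l,
        n_subjects=len(common),
    )
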