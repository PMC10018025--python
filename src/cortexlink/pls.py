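"""Step 2b — spatial PLS of a cortical t map on regional gene expression.

The model regresses a per-region t-statistic map (response, one value per
left-hemisphere region) on a regions × genes expression matrix and keeps the
first partial-least-squares component (PLS1): the linear combination of gene
expression profiles maximizing covariance with the map. With a univariate
response the first-component weight vector has the closed form

    w  ∝  X_cᵀ y_c        (unit ℓ2 norm),

where X_c is the column-centered (and, by default, column-standardized)
predictor block and y_c the centered response. Inference follows the
permutation-and-bootstrap recipe standard in imaging transcriptomics:
significance of the spatial correlation r = Pearson(X_c w, y) by permuting
the map across regions, and per-gene Z scores from bootstrap resampling of
regions (Z = weight / bootstrap SE), referred to the standard normal and
BH-FDR corrected.

Usage::

    model = SpatialPLS(tmap, expression)          # regions aligned by name
    res = model.fit(n_perm=1000, n_boot=500, seed=17)
    res.summary()
    lists = res.gene_lists(z_thresh=3.0, alpha=0.05)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr
from .errors import DataError, NumericalError
from .phenotype import TStatMap


def _as_response(tmap) -> pd.Series:
    if isinstance(tmap, TStatMap):
        return tmap.t.copy()
    return pd.Series(tmap, dtype=float)


def _pls1_weights(Xc: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """Unit-norm first-component weights for a univariate response."""
    w = Xc.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise NumericalError("response orthogonal to every predictor column")
    return w / norm


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


class SpatialPLS:
    """First-component PLS of a regional t map on gene expression.

    Parameters
    ----------
    tmap : TStatMap or Series indexed by region (the response).
    expression : DataFrame, regions × genes (the predictor block).
    standardize : z-score predictor columns across regions (default True);
        zero-variance gene columns are dropped with a warning.
    """

    def __init__(self, tmap, expression: pd.DataFrame, standardize: bool = True):
        y = _as_response(tmap)
        if set(y.index) != set(expression.index):
            only_y = sorted(set(y.index) - set(expression.index))
            only_x = sorted(set(expression.index) - set(y.index))
            raise DataError(
                f"region mismatch between map and expression: "
                f"map-only={only_y}, expression-only={only_x}"
            )
        if len(y) < 3:
            raise DataError(f"need at least 3 regions, got {len(y)}")
        X = expression.loc[y.index]
        sd = X.std(axis=0, ddof=1)
        if standardize and (sd == 0).any():
            dropped = list(sd.index[sd == 0])
            warnings.warn(f"dropping {len(dropped)} constant gene column(s)")
            X = X.loc[:, sd > 0]
            sd = sd[sd > 0]
        if np.ptp(y.to_numpy(dtype=float)) == 0:
            raise DataError("constant response map: PLS undefined")

        self.regions = list(y.index)
        self.genes = list(X.columns)
        self.standardize = standardize
        self.y = y.to_numpy(dtype=float)
        Xv = X.to_numpy(dtype=float)
        Xc = Xv - Xv.mean(axis=0)
        if standardize:
            Xc = Xc / sd.to_numpy(dtype=float)
        self._Xc = Xc
        self._yc = self.y - self.y.mean()

    # -- fitting ---------------------------------------------------------

    def fit(self, n_perm: int = 1000, n_boot: int = 500,
            seed=None) -> "SpatialPLSResults":
        """Fit PLS1 and run permutation / bootstrap inference.

        ``n_perm=0`` or ``n_boot=0`` skips the corresponding stage.
        """
        rng = np.random.default_rng(seed)
        w = _pls1_weights(self._Xc, self._yc)
        scores = self._Xc @ w
        r = _corr(scores, self.y)
        if r < 0:  # cannot happen for the closed form, kept as a guard
            w, scores, r = -w, -scores, -r

        perm_p, null_r = None, None
        if n_perm:
            perm_p, null_r = self._permutation(n_perm, rng, r)
        ztab = None
        if n_boot:
            ztab = self._bootstrap(n_boot, rng, w)
        return SpatialPLSResults(
            model=self, weights=pd.Series(w, index=self.genes, name="weight"),
            scores=pd.Series(scores, index=self.regions, name="pls1_score"),
            r=r, permutation_p=perm_p, null_r=null_r, z_table=ztab,
            n_perm=n_perm, n_boot=n_boot,
        )

    def _permutation(self, n_perm: int, rng, r_obs: float):
        if n_perm < 100:
            raise DataError(f"n_perm must be >= 100, got {n_perm}")
        n = len(self.y)
        null = np.empty(n_perm)
        for i in range(n_perm):
            yp = self.y[rng.permutation(n)]
            ypc = yp - yp.mean()
            w = self._Xc.T @ ypc
            nw = np.linalg.norm(w)
            if nw == 0:
                null[i] = 0.0
                continue
            null[i] = abs(_corr(self._Xc @ (w / nw), yp))
        p = (1 + int((null >= r_obs).sum())) / (n_perm + 1)
        return p, null

    def _bootstrap(self, n_boot: int, rng, w_orig: np.ndarray) -> pd.DataFrame:
        if n_boot < 50:
            raise DataError(f"n_boot must be >= 50, got {n_boot}")
        n, g = self._Xc.shape
        W = np.empty((n_boot, g))
        for i in range(n_boot):
            for attempt in range(10):
                idx = rng.integers(0, n, size=n)
                yb = self.y[idx]
                if np.ptp(yb) > 0:
                    break
            else:
                raise NumericalError("bootstrap kept drawing constant responses")
            Xb = self._Xc[idx]
            Xb = Xb - Xb.mean(axis=0)
            if self.standardize:
                sd = Xb.std(axis=0, ddof=1)
                sd[sd == 0] = 1.0  # degenerate columns contribute zero weight
                Xb = Xb / sd
            wb = _pls1_weights(Xb, yb - yb.mean())
            if wb @ w_orig < 0:
                wb = -wb
            W[i] = wb
        se = W.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, w_orig / se, np.nan)
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"weight": w_orig, "se": se, "z": z, "p": p, "q": bh_fdr(p)},
            index=pd.Index(self.genes, name="gene"),
        )


@dataclass
class GeneList:
    """Thresholded PLS gene sets (positive and negative weights)."""

    positive: tuple
    negative: tuple
    z_thresh: float
    alpha: float

    @property
    def combined(self) -> tuple:
        return tuple(sorted(self.positive + self.negative))

    @property
    def counts(self) -> dict:
        n_pos, n_neg = len(self.positive), len(self.negative)
        return {"positive": n_pos, "negative": n_neg, "combined": n_pos + n_neg}

    def to_dict(self) -> dict:
        return {
            "positive": list(self.positive), "negative": list(self.negative),
            "z_thresh": self.z_thresh, "alpha": self.alpha, "counts": self.counts,
        }


@dataclass
class SpatialPLSResults:
    """Fitted PLS1 component with permutation and bootstrap inference."""

    model: SpatialPLS
    weights: pd.Series
    scores: pd.Series
    r: float
    permutation_p: float | None
    null_r: np.ndarray | None
    z_table: pd.DataFrame | None
    n_perm: int = 0
    n_boot: int = 0
    _extra: dict = field(default_factory=dict, repr=False)

    @property
    def r2(self) -> float:
        """Fraction of response variance explained by the PLS1 scores."""
        return self.r ** 2

    def gene_lists(self, z_thresh: float = 3.0, alpha: float = 0.05) -> GeneList:
        if self.z_table is None:
            raise DataError("no bootstrap Z table: fit with n_boot > 0")
        return threshold_genes(self.z_table, z_thresh=z_thresh, alpha=alpha)

    def summary(self) -> str:
        lines = [
            "Spatial PLS (first component)",
            "=" * 45,
            f"regions: {len(self.scores)}   genes: {len(self.weights)}",
            f"r(scores, map)        {self.r: .4f}",
            f"variance explained r2 {self.r2: .4f}",
        ]
        if self.permutation_p is not None:
            lines.append(
                f"permutation p         {self.permutation_p: .4g}   "
                f"({self.n_perm} permutations)"
            )
        if self.z_table is not None:
            gl = self.gene_lists()
            c = gl.counts
            lines.append(
                f"|Z| > 3 genes (q<0.05): {c['combined']} "
                f"({c['positive']} positive, {c['negative']} negative; "
                f"{self.n_boot} bootstraps)"
            )
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Scatter of PLS1 region scores against the t map."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4))
        ax.scatter(self.scores.to_numpy(), self.model.y, s=18)
        ax.set_xlabel("PLS1 region score")
        ax.set_ylabel("t statistic")
        ax.set_title(f"r = {self.r:.3f}")
        return ax


def threshold_genes(z_table: pd.DataFrame, z_thresh: float = 3.0,
                    alpha: float = 0.05) -> GeneList:
    """Split genes into positive / negative sets by |Z| > z_thresh and q < alpha.

    Non-finite Z rows (degenerate bootstrap SE) are excluded with a warning.
    """
    tab = z_table
    bad = ~np.isfinite(tab["z"].to_numpy(dtype=float))
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} gene(s) with non-finite Z")
        tab = tab[~bad]
    sig = tab["q"] < alpha
    pos = tuple(sorted(tab.index[(tab["z"] > z_thresh) & sig]))
    neg = tuple(sorted(tab.index[(tab["z"] < -z_thresh) & sig]))
    return GeneList(positive=pos, negative=neg, z_thresh=z_thresh, alpha=alpha)


# -- thin functional wrappers over the model ------------------------------

def fit_pls1(expression: pd.DataFrame, tmap,
             standardize: bool = True) -> SpatialPLSResults:
    """Fit the first PLS component only (no permutation/bootstrap)."""
    return SpatialPLS(tmap, expression, standardize=standardize).fit(
        n_perm=0, n_boot=0)


def permutation_test_pls(expression: pd.DataFrame, tmap, n_perm: int = 1000,
                         seed=None, standardize: bool = True):
    """Permutation p-value for the PLS1 spatial correlation; returns (p, null_r)."""
    res = SpatialPLS(tmap, expression, standardize=standardize).fit(
        n_perm=n_perm, n_boot=0, seed=seed)
    return res.permutation_p, res.null_r


def bootstrap_gene_z(expression: pd.DataFrame, tmap, n_boot: int = 500,
                     seed=None, standardize: bool = True) -> pd.DataFrame:
    """Bootstrap Z table (weight, se, z, p, q) for every gene."""
    res = SpatialPLS(tmap, expression, standardize=standardize).fit(
        n_perm=0, n_boot=n_boot, seed=seed)
    return res.z_table
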