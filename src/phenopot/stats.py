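"""Trait-evaluation statistics.

Implements the evaluation toolbox used on static/dynamic trait tables:

* tie-corrected Friedman rank test across varieties (blocks = traits,
  treatments = varieties; ascending average ranks),
* Pearson correlation matrix with two-sided significance stars,
* within-groups average-linkage hierarchical clustering of traits on
  squared Euclidean distances between standardized columns,
* PCA on the trait correlation matrix with the eigenvalue > 1 retention
  rule,
* kNN color grading with stratified four-fold cross-validation,
* color grading charts (varieties sorted by a color trait, five equal-height
  grade intervals),
* simple least-squares line fits with R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler

__all__ = [
    "FriedmanResult", "GradingResult", "ColorGradingChart", "ClusterResult",
    "PCAResult", "friedman_test", "correlation_matrix", "cluster_traits",
    "pca_traits", "knn_grading", "build_cgc", "plot_cgc", "fit_line",
    "pooled_rank_report",
]


# ---------------------------------------------------------------- Friedman

@dataclass
class FriedmanResult:
    mean_ranks: np.ndarray
    rank_sums: np.ndarray
    chi2_uncorrected: float
    chi2: float
    df: int
    pvalue: float
    n_blocks: int
    n_treatments: int
    tie_correction: float
    degenerate: bool = False
    treatments: tuple[str, ...] | None = None


def friedman_test(values: np.ndarray | pd.DataFrame) -> FriedmanResult:
    """Tie-corrected Friedman rank test on a blocks × treatments matrix.

    Within each block the treatments are ranked ascending (rank 1 =
    smallest) with average ranks for ties.  The uncorrected statistic
    χ² = 12/(n·k·(k+1))·ΣR_j² − 3n(k+1) is divided by the tie correction
    C = 1 − Σ(t³ − t)/(n·(k³ − k)); the p-value is the χ²(k−1) upper tail.
    If every block is a complete tie (C = 0) the statistic is defined as 0
    with p = 1 and the result flagged degenerate.
    """
    names = None
    if isinstance(values, pd.DataFrame):
        names = tuple(str(c) for c in values.columns)
        values = values.to_numpy(dtype=float)
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D blocks × treatments matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")

    ranks = np.vstack([sps.rankdata(row) for row in x])
    rank_sums = ranks.sum(axis=0)
    chi2_unc = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3 * n * (k + 1)

    tie_term = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    c = 1.0 - tie_term / (n * (k**3 - k))

    if c <= 0:
        return FriedmanResult(
            mean_ranks=rank_sums / n, rank_sums=rank_sums,
            chi2_uncorrected=0.0, chi2=0.0, df=k - 1, pvalue=1.0,
            n_blocks=n, n_treatments=k, tie_correction=0.0,
            degenerate=True, treatments=names)
    chi2 = chi2_unc / c
    return FriedmanResult(
        mean_ranks=rank_sums / n, rank_sums=rank_sums,
        chi2_uncorrected=float(chi2_unc), chi2=float(chi2), df=k - 1,
        pvalue=float(sps.chi2.sf(chi2, k - 1)), n_blocks=n, n_treatments=k,
        tie_correction=float(c), treatments=names)


def pooled_rank_report(tables: Sequence[pd.DataFrame],
                       tie_method: str = "average") -> pd.Series:
    """Optional per-trait rank report: rank all dynamic-trait columns pooled
    across the given tables within each variety row, then average ranks per
    column across varieties.  Tie handling is configurable because published
    variants of this summary do not follow the average-rank convention.
    """
    pooled = pd.concat(tables, axis=1)
    ranks = pooled.apply(
        lambda row: sps.rankdata(row.to_numpy(float), method=tie_method),
        axis=1, result_type="expand")
    ranks.columns = pooled.columns
    return ranks.mean(axis=0)


# ----------------------------------------------------------- correlations

def correlation_matrix(table: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson r matrix with two-sided p-values and significance stars.

    Stars: '*' for p < 0.05, '**' for p < 0.01.  Zero-variance columns get
    NaN against every partner.  Returns (r, p, stars) DataFrames.
    """
    num = table.select_dtypes("number")
    n = len(num)
    if n < 3:
        raise ValueError("need at least 3 rows")
    cols = list(num.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            xa, xb = num[a].to_numpy(float), num[b].to_numpy(float)
            if np.std(xa) == 0 or np.std(xb) == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = sps.pearsonr(xa, xb)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
        if np.std(num[a].to_numpy(float)) == 0:
            r.loc[a, a] = np.nan
    stars = p.map(lambda v: "**" if v < 0.01 else ("*" if v < 0.05 else ""))
    np.fill_diagonal(stars.values, "")
    return r, p, stars


# ------------------------------------------------------------- clustering

@dataclass
class ClusterResult:
    linkage: np.ndarray                 # scipy-style merge tree
    columns: tuple[str, ...]
    dropped: tuple[str, ...] = ()

    def cut(self, threshold: float) -> dict[str, int]:
        from scipy.cluster.hierarchy import fcluster
        labels = fcluster(self.linkage, t=threshold, criterion="distance")
        return dict(zip(self.columns, (int(v) for v in labels)))

    def cut_k(self, n_clusters: int) -> dict[str, int]:
        from scipy.cluster.hierarchy import fcluster
        labels = fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.columns, (int(v) for v in labels)))


def cluster_traits(table: pd.DataFrame) -> ClusterResult:
    """Within-groups average-linkage clustering of trait columns.

    Columns are standardized (z-scores); the dissimilarity between two
    traits is the squared Euclidean distance between their z-score vectors.
    At each step the pair of clusters whose merger minimizes the *average
    pairwise distance within the merged cluster* is joined — the
    within-groups variant of average linkage (the classical 'average'
    linkage minimizes only the between-cluster average).  The merge height
    recorded is that within-group average.
    """
    num = table.select_dtypes("number")
    dropped = tuple(c for c in num.columns if num[c].std() == 0)
    if dropped:
        warnings.warn(f"constant columns dropped: {dropped}", stacklevel=2)
        num = num.drop(columns=list(dropped))
    cols = tuple(str(c) for c in num.columns)
    m = len(cols)
    if m < 2:
        raise ValueError("need at least 2 non-constant columns")
    z = (num - num.mean()) / num.std(ddof=1)
    zt = z.to_numpy(float).T                       # traits × samples
    d = ((zt[:, None, :] - zt[None, :, :]) ** 2).sum(axis=2)

    # pairwise-sum bookkeeping: S[a][b] = Σ distances between members
    active = {i: [i] for i in range(m)}
    cross = {(i, j): d[i, j] for i in range(m) for j in range(i + 1, m)}
    within = {i: 0.0 for i in range(m)}
    node_id = {i: i for i in range(m)}
    next_id = m
    Z = np.zeros((m - 1, 4))
    for step in range(m - 1):
        best = None
        keys = sorted(active)
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                na, nb = len(active[a]), len(active[b])
                tot = within[a] + within[b] + cross[(a, b)]
                pairs = (na + nb) * (na + nb - 1) / 2
                h = tot / pairs
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        Z[step] = [node_id[a], node_id[b], h, len(active[a]) + len(active[b])]
        # merge b into a
        within[a] = within[a] + within[b] + cross.pop((a, b))
        active[a] = active[a] + active.pop(b)
        within.pop(b)
        for c in list(active):
            if c == a:
                continue
            key_ab = (min(a, c), max(a, c))
            key_bb = (min(b, c), max(b, c))
            cross[key_ab] = cross.get(key_ab, 0.0) + cross.pop(key_bb, 0.0)
        node_id[a] = next_id
        next_id += 1
    return ClusterResult(linkage=Z, columns=cols, dropped=dropped)


# -------------------------------------------------------------------- PCA

@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame              # traits × components, eigvec·√λ
    contributions: np.ndarray           # % of variance per component
    cumulative: np.ndarray
    n_retained: int                     # eigenvalue > 1 rule


def pca_traits(table: pd.DataFrame) -> PCAResult:
    """PCA on the correlation matrix of (internally standardized) traits.

    Eigenvalues sum to the number of columns; the variance contribution of
    component j is λ_j / m × 100%.  Components with eigenvalue > 1 are
    retained.  Loadings are eigenvectors scaled by √λ (component–trait
    correlations); each component's sign is set so its largest-magnitude
    loading is positive.
    """
    num = table.select_dtypes("number")
    corr = np.corrcoef(num.to_numpy(float), rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    for j in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] = -vecs[:, j]
    loadings = vecs * np.sqrt(vals)[None, :]
    m = corr.shape[0]
    contributions = vals / m * 100.0
    return PCAResult(
        eigenvalues=vals,
        loadings=pd.DataFrame(
            loadings, index=list(num.columns),
            columns=[f"PC{j + 1}" for j in range(m)]),
        contributions=contributions,
        cumulative=np.cumsum(contributions),
        n_retained=int(np.sum(vals > 1.0)),
    )


# ------------------------------------------------------------ kNN grading

@dataclass
class GradingResult:
    combo: str
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float


def knn_grading(features: pd.DataFrame, labels: Sequence[int],
                combos: Mapping[str, Sequence[str]],
                k: int = 5, folds: int = 4, seed: int = 0
                ) -> list[GradingResult]:
    """Mean kNN classification accuracy per feature combination.

    Stratified ``folds``-fold cross-validation (shuffled by ``seed``);
    features are standardized on each training fold; Euclidean kNN with
    majority vote.  Classes with fewer members than folds are an error.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if folds == len(y):
        from sklearn.model_selection import LeaveOneOut
        skf = LeaveOneOut()
    else:
        if counts.min() < folds:
            raise ValueError(
                f"every class needs at least {folds} members for "
                f"{folds}-fold CV")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    results = []
    for name, cols in combos.items():
        x = features[list(cols)].to_numpy(float)
        accs = []
        for tr, te in skf.split(x, y):
            scaler = StandardScaler().fit(x[tr])
            clf = KNeighborsClassifier(n_neighbors=k)
            clf.fit(scaler.transform(x[tr]), y[tr])
            accs.append(float(clf.score(scaler.transform(x[te]), y[te])))
        results.append(GradingResult(name, tuple(accs),
                                     float(np.mean(accs))))
    return results


# --------------------------------------------------- color grading charts

@dataclass
class ColorGradingChart:
    trait: str
    order: tuple[str, ...]              # varieties sorted ascending by value
    values: tuple[float, ...]           # sorted values
    vmin: float
    vmax: float
    boundaries: tuple[tuple[int, str, float], ...]   # (rank, variety, value)
    degenerate: bool = False


def build_cgc(values: pd.Series, trait: str | None = None,
              n_intervals: int = 5) -> ColorGradingChart:
    """Color grading chart: sort varieties by a trait, mark 5 grade levels.

    ``values`` maps variety id → trait value.  Varieties are sorted
    ascending (ties broken by variety id); interval boundaries sit at ranks
    ⌈j·N/n_intervals⌉ with the representative variety and value at each.
    """
    if len(values) < n_intervals:
        raise ValueError(f"need at least {n_intervals} varieties")
    if not np.isfinite(values.to_numpy(float)).all():
        raise ValueError("trait values must be finite")
    s = values.copy()
    s.index = s.index.map(str)
    # canonical order: ascending by value, ties broken by variety id
    s = s.iloc[np.lexsort((s.index.to_numpy(), s.to_numpy(float)))]
    n = len(s)
    bounds = []
    for j in range(1, n_intervals + 1):
        rank = int(np.ceil(j * n / n_intervals))
        bounds.append((rank, str(s.index[rank - 1]), float(s.iloc[rank - 1])))
    vmin, vmax = float(s.iloc[0]), float(s.iloc[-1])
    return ColorGradingChart(
        trait=trait or str(values.name or "trait"),
        order=tuple(s.index), values=tuple(float(v) for v in s),
        vmin=vmin, vmax=vmax, boundaries=tuple(bounds),
        degenerate=(vmax - vmin) == 0.0)


def plot_cgc(chart: ColorGradingChart, path: str) -> None:
    """Render the vertical color bar of a grading chart to PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.asarray(chart.values)[::-1, None]    # largest on top
    fig, ax = plt.subplots(figsize=(2.2, 6))
    ax.imshow(vals, aspect="auto", cmap="viridis",
              extent=(0, 1, 0.5, len(vals) + 0.5))
    ax.set_xticks([])
    for rank, variety, value in chart.boundaries:
        y = len(vals) - rank + 1
        ax.axhline(y - 0.5, color="w", lw=0.8)
        ax.annotate(f"{variety}: {value:.2f}", xy=(1.02, y),
                    xycoords=("axes fraction", "data"), fontsize=7,
                    va="center")
    ax.set_ylabel(f"varieties sorted by {chart.trait}")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


# --------------------------------------------------------------- line fit

def fit_line(x: Sequence[float], y: Sequence[float]
             ) -> tuple[float, float, float]:
    """Least-squares line fit; returns (slope, intercept, R²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0:
        raise ValueError("zero-variance x")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
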