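"""Classification of annotated loci: MCA + k-means with model selection.

The categorical feature table is expanded into a complete disjunctive
(indicator) matrix and analysed by correspondence analysis of that matrix:
standardised residuals of the relative-frequency table are decomposed by
SVD, eigenvalues are squared singular values, and loci receive principal
coordinates.  For a complete indicator over Q features with J levels in
total, the total inertia is J/Q - 1 (no Benzecri/Greenacre eigenvalue
correction is applied).  K-means runs on the leading principal
coordinates; the number of dimensions is chosen by bootstrap cluster
stability, the number of clusters by Tibshirani's gap statistic (with the
full curve returned so a more conservative choice can be made) and by
normalised mutual information against held-out annotation features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests


@dataclass
class MCAModel:
    categories: list[tuple[str, str]]      # (feature, level) per column
    eigenvalues: np.ndarray                # descending
    explained_variance: np.ndarray         # percentages, sums to 100
    row_coords: pd.DataFrame               # loci x dimensions, principal
    col_coords: pd.DataFrame               # categories x dimensions
    row_masses: np.ndarray
    col_masses: np.ndarray
    n_features: int

    @property
    def total_inertia(self) -> float:
        return float(self.eigenvalues.sum())


@dataclass
class Clustering:
    k: int
    dims: int
    assignments: pd.Series                 # locus -> "LC1".."LCk"
    centroids: np.ndarray                  # k x dims
    inertia: float


def build_indicator_matrix(
    feature_table: pd.DataFrame, include: list[str] | None = None
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Complete disjunctive coding of the feature table.

    ``include`` selects the covariate features (by default every column not
    starting with ``overlap_``, since annotation overlap is held out as a
    validation standard).  Features with a single observed level carry no
    information and are dropped with a warning.  Row sums equal the number
    of retained features.
    """
    if include is None:
        include = [c for c in feature_table.columns if not c.startswith("overlap_")]
    keep = []
    for c in include:
        if feature_table[c].nunique() < 2:
            warnings.warn(f"feature {c!r} has a single observed level; dropped")
        else:
            keep.append(c)
    blocks = []
    categories: list[tuple[str, str]] = []
    for c in keep:
        d = pd.get_dummies(feature_table[c].astype(str), dtype=float)
        d.columns = [str(level) for level in d.columns]
        blocks.append(d)
        categories.extend((c, level) for level in d.columns)
    Z = pd.concat(blocks, axis=1)
    Z.columns = pd.MultiIndex.from_tuples(categories, names=["feature", "level"])
    return Z, categories


def fit_mca(Z: pd.DataFrame | np.ndarray, n_features: int | None = None) -> MCAModel:
    """Correspondence analysis of an indicator matrix.

    With P = Z / N, row masses r and column masses c, the standardised
    residual matrix S = D_r^{-1/2} (P - r c^T) D_c^{-1/2} is decomposed by
    SVD; eigenvalues are squared singular values and row principal
    coordinates are D_r^{-1/2} U Sigma.
    """
    if isinstance(Z, pd.DataFrame):
        categories = (
            list(Z.columns) if isinstance(Z.columns, pd.MultiIndex) else
            [("", str(c)) for c in Z.columns]
        )
        index = Z.index
        M = Z.to_numpy(dtype=float)
    else:
        M = np.asarray(Z, dtype=float)
        categories = [("", str(j)) for j in range(M.shape[1])]
        index = pd.RangeIndex(M.shape[0])
    if n_features is None:
        rs = M.sum(axis=1)
        n_features = int(round(rs[0]))
    N = M.sum()
    P = M / N
    # a resampled matrix can lose a category entirely; empty columns carry
    # no mass and are dropped before the decomposition
    nz_col = P.sum(axis=0) > 0
    if not nz_col.all():
        M = M[:, nz_col]
        P = P[:, nz_col]
        categories = [cat for cat, keep in zip(categories, nz_col) if keep]
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    # drop numerically null dimensions
    nz = sv > 1e-12
    U, sv, Vt = U[:, nz], sv[nz], Vt[nz]
    eig = sv**2
    row_coords = (U * sv[None, :]) / np.sqrt(r)[:, None]
    col_coords = (Vt.T * sv[None, :]) / np.sqrt(c)[:, None]
    total = eig.sum()
    explained = 100.0 * eig / total if total > 0 else eig
    dims = [f"dim{i+1}" for i in range(len(eig))]
    return MCAModel(
        categories=categories,
        eigenvalues=eig,
        explained_variance=explained,
        row_coords=pd.DataFrame(row_coords, index=index, columns=dims),
        col_coords=pd.DataFrame(col_coords, index=pd.RangeIndex(len(c)), columns=dims),
        row_masses=r,
        col_masses=c,
        n_features=n_features,
    )


def kmeans_cluster(
    coords: pd.DataFrame | np.ndarray, k: int, seed: int = 0, restarts: int = 25
) -> Clustering:
    """K-means on the leading principal coordinates; the best of
    ``restarts`` k-means++ initialisations by inertia.  Class labels
    LC1..LCk are assigned by descending cluster size."""
    X = coords.to_numpy() if isinstance(coords, pd.DataFrame) else np.asarray(coords)
    index = coords.index if isinstance(coords, pd.DataFrame) else pd.RangeIndex(len(X))
    if k > len(X):
        raise ValueError("k exceeds the number of loci")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    # order by descending size, ties by original label for determinism
    order = np.lexsort((np.arange(k), -sizes))
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    labels = np.array([f"LC{rank[c] + 1}" for c in raw], dtype=object)
    centroids = km.cluster_centers_[order]
    return Clustering(
        k=k,
        dims=X.shape[1],
        assignments=pd.Series(labels, index=index, name="class"),
        centroids=centroids,
        inertia=float(km.inertia_),
    )


def _wk(X: np.ndarray, k: int, seed: int, restarts: int = 5) -> float:
    if k == 1:
        return float(((X - X.mean(axis=0)) ** 2).sum())
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    km.fit(X)
    return float(km.inertia_)


def gap_statistic(
    coords: pd.DataFrame | np.ndarray,
    k_range: range | list[int] = range(1, 11),
    B_ref: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Tibshirani's gap statistic with a uniform-bounding-box reference.

    Gap(k) = mean_b log W_k(reference_b) - log W_k(data); k_hat is the
    smallest k with Gap(k) >= Gap(k+1) - s_{k+1} (the one-standard-error
    rule).  The full curve is returned so a larger, more conservative k
    may be preferred.
    """
    X = coords.to_numpy() if isinstance(coords, pd.DataFrame) else np.asarray(coords)
    ks = list(k_range)
    if np.allclose(X, X[0]):
        curve = pd.DataFrame({"k": ks, "gap": 0.0, "sk": 0.0, "log_wk": 0.0})
        return curve, 1
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_wk = np.array([np.log(max(_wk(X, k, seed), 1e-300)) for k in ks])
    ref = np.empty((B_ref, len(ks)))
    for b in range(B_ref):
        Xb = rng.uniform(lo, hi, size=X.shape)
        ref[b] = [np.log(max(_wk(Xb, k, seed), 1e-300)) for k in ks]
    gap = ref.mean(axis=0) - log_wk
    sk = ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B_ref)
    k_hat = ks[-1]
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - sk[i + 1]:
            k_hat = ks[i]
            break
    curve = pd.DataFrame({"k": ks, "gap": gap, "sk": sk, "log_wk": log_wk})
    return curve, int(k_hat)


def nmi(labels_a, labels_b) -> float:
    """Normalised mutual information I(A;B) / sqrt(H(A) H(B)).

    Two identical constant labelings score 1; if either labeling is
    constant but they are not both constant and equal, the score is 0.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    ct = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy().astype(float)
    n = ct.sum()
    pij = ct / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    ha = -np.sum(pi * np.log(pi, where=pi > 0, out=np.zeros_like(pi)))
    hb = -np.sum(pj * np.log(pj, where=pj > 0, out=np.zeros_like(pj)))
    if ha == 0.0 and hb == 0.0:
        return 1.0 if np.array_equal(a, b) else 0.0
    if ha == 0.0 or hb == 0.0:
        return 0.0
    outer = np.outer(pi, pj)
    mask = pij > 0
    mi = float(np.sum(pij[mask] * np.log(pij[mask] / outer[mask])))
    return max(mi, 0.0) / np.sqrt(ha * hb)


def select_dimensions(
    Z: pd.DataFrame,
    k_range: list[int],
    dims_range: list[int],
    B: int = 20,
    seed: int = 0,
    stability_target: float = 0.8,
    target_k: int | None = None,
) -> tuple[pd.DataFrame, int | None]:
    """Bootstrap cluster-stability diagnostics over (dimensions, k).

    For each combination, B resamples of loci (with replacement) are
    refitted (MCA + k-means); resample clusters are matched to the
    reference clustering by maximum-agreement (Hungarian) assignment on
    the shared loci, and stability is the per-resample proportion of
    shared loci preserving their reference cluster.  The recommendation is
    the smallest dimensionality at which the target k (default: the
    largest k in ``k_range``) reaches a median stability of
    ``stability_target``.
    """
    if B < 1:
        raise ValueError("B must be positive")
    rng = np.random.default_rng(seed)
    model = fit_mca(Z)
    n = len(Z)
    rows = []
    target_k = target_k if target_k is not None else max(k_range)
    recommended = None
    for d in dims_range:
        d_eff = min(d, model.row_coords.shape[1])
        coords = model.row_coords.iloc[:, :d_eff]
        for k in k_range:
            if k > n:
                continue
            ref = kmeans_cluster(coords, k, seed=seed)
            ref_codes = ref.assignments.str.removeprefix("LC").astype(int).to_numpy() - 1
            stabs = []
            for b in range(B):
                idx = rng.integers(0, n, size=n)
                sub = Z.iloc[idx]
                bm = fit_mca(sub)
                bc = kmeans_cluster(bm.row_coords.iloc[:, : min(d_eff, bm.row_coords.shape[1])],
                                    k, seed=seed)
                bcodes = bc.assignments.str.removeprefix("LC").astype(int).to_numpy() - 1
                shared = np.unique(idx)
                # one representative resample row per shared locus
                first_pos = np.full(n, -1, dtype=int)
                first_pos[idx] = np.arange(n)
                rep = first_pos[shared]
                agree = np.zeros((k, k))
                np.add.at(agree, (ref_codes[shared], bcodes[rep]), 1)
                ri, ci = linear_sum_assignment(-agree)
                stabs.append(agree[ri, ci].sum() / len(shared))
            med = float(np.median(stabs))
            rows.append({"dims": d, "k": k, "median_stability": med,
                         "q1": float(np.percentile(stabs, 25)),
                         "q3": float(np.percentile(stabs, 75))})
            if k == target_k and med >= stability_target and recommended is None:
                recommended = d
    return pd.DataFrame(rows), recommended


def enrichment_tests(
    assignments: pd.Series, feature_table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per (class, feature level) enrichment by two-sided Fisher's exact
    test on the 2x2 contingency (in class vs not, has level vs not), with
    Benjamini-Hochberg adjustment across all pairs.  Sign follows the odds
    ratio."""
    rows = []
    classes = sorted(assignments.unique())
    for feat in feature_table.columns:
        col = feature_table[feat].astype(str)
        for level in sorted(col.unique()):
            has = (col == level).to_numpy()
            if has.sum() == 0:
                continue
            for cls in classes:
                inc = (assignments == cls).to_numpy()
                a = int((inc & has).sum())
                b = int((inc & ~has).sum())
                c = int((~inc & has).sum())
                d = int((~inc & ~has).sum())
                odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
                rows.append({"class": cls, "feature": feat, "level": level,
                             "odds_ratio": odds, "pvalue": p})
    res = pd.DataFrame(rows)
    if len(res) == 0:
        res["adjusted_p"] = []
        res["sign"] = []
        return res
    _, adj, _, _ = multipletests(res["pvalue"], alpha=alpha, method="fdr_bh")
    res["adjusted_p"] = adj
    res["sign"] = np.where(res["odds_ratio"] > 1, "enriched", "depleted")
    return res


def class_hierarchy(clusterings: dict[int, pd.Series]) -> pd.DataFrame:
    """Flow proportions between successive k levels.

    For each cluster at the higher k, the distribution of its members over
    the clusters at the next lower k; proportions per source cluster sum
    to 1.
    """
    ks = sorted(clusterings, reverse=True)
    rows = []
    for hi, lo in zip(ks, ks[1:]):
        a, b = clusterings[hi], clusterings[lo]
        if not a.index.equals(b.index):
            raise ValueError("clusterings must cover identical loci")
        ct = pd.crosstab(a, b)
        frac = ct.div(ct.sum(axis=1), axis=0)
        for src in frac.index:
            for dst in frac.columns:
                rows.append({"k_from": hi, "cluster_from": src, "k_to": lo,
                             "cluster_to": dst, "proportion": float(frac.at[src, dst])})
    return pd.DataFrame(rows)


def find_paragons(
    clustering: Clustering, coords: pd.DataFrame, n_per_class: int = 1
) -> dict[str, list]:
    """Per class, the n loci nearest (Euclidean) the class centroid in the
    clustering's reduced coordinates; ties broken by locus id.  Classes
    smaller than n return all their members."""
    X = coords.to_numpy()[:, : clustering.dims]
    out: dict[str, list] = {}
    for j in range(clustering.k):
        cls = f"LC{j + 1}"
        mask = (clustering.assignments == cls).to_numpy()
        ids = coords.index[mask]
        d = np.linalg.norm(X[mask] - clustering.centroids[j][None, :], axis=1)
        order = sorted(range(len(ids)), key=lambda i: (d[i], str(ids[i])))
        out[cls] = [ids[i] for i in order[: min(n_per_class, len(ids))]]
    return out
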