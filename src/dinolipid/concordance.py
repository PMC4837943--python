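"""Lipid-profile versus phylogeny concordance.

Building blocks: uncorrected genetic p-distance from an alignment
(pairwise deletion of gap/ambiguous sites), the Mantel permutation test
of the Pearson correlation between two distance matrices, non-metric
multidimensional scaling minimising Kruskal stress-1, and Ward
hierarchical clustering on correlation distances with bootstrap
bipartition support.

The chemotaxonomic question these answer: do taxa with similar membrane
lipid profiles (per class, as Euclidean distance on log/Pareto-scaled
relative areas or unsaturation indices) also sit close in the 28S LSU
phylogeny?
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

from .multivariate import ParetoScaler
from .quant import FeatureTable, ui

__all__ = [
    "DistanceMatrix",
    "p_distance",
    "mantel",
    "NMDS",
    "nmds",
    "NmdsResult",
    "ClusterTree",
    "ward_bootstrap",
    "concordance_report",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with taxon labels."""

    labels: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.isnan(self.D).any():
            raise ValueError("distance matrix contains NaN")
        if (self.D < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.D, checks=False)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.D[np.ix_(idx, idx)])

    def drop(self, label: str) -> "DistanceMatrix":
        keep = [l for l in self.labels if l != label]
        return self.reorder(keep)

    def to_csv(self, path: str | Path, sep: str = "\t") -> None:
        pd.DataFrame(self.D, index=self.labels, columns=self.labels).to_csv(
            path, sep=sep, index_label="taxon"
        )

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = "\t") -> "DistanceMatrix":
        df = pd.read_csv(path, sep=sep, index_col="taxon")
        return cls(list(df.index), df.to_numpy())


# ---------------------------------------------------------------------------
# uncorrected genetic distance


def _read_alignment(source) -> tuple[list[str], np.ndarray]:
    if isinstance(source, (str, Path)):
        records = list(SeqIO.parse(str(source), "fasta"))
        pairs = [(r.id, str(r.seq)) for r in records]
    elif hasattr(source, "__iter__") and not isinstance(source, dict):
        try:
            pairs = [(r.id, str(r.seq)) for r in source]  # SeqRecords / MSA
        except AttributeError:
            pairs = list(source)  # (name, sequence) tuples
    else:
        pairs = list(source.items())
    if len(pairs) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    lengths = {len(s) for _, s in pairs}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    labels = [name for name, _ in pairs]
    arr = np.array([list(s.upper()) for _, s in pairs])
    return labels, arr


def p_distance(alignment) -> DistanceMatrix:
    """Uncorrected p-distance: mismatches / comparable sites per pair.

    Sites with a gap (``-``) or ``N`` in either sequence of a pair are
    excluded pairwise.  A pair with zero comparable sites is rejected.
    ``alignment`` may be a FASTA path, Biopython records/alignment, or
    (name, sequence) pairs.
    """
    labels, arr = _read_alignment(alignment)
    valid = ~np.isin(arr, ["-", "N"])
    n = len(labels)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        m = int(both.sum())
        if m == 0:
            raise ValueError(
                f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
            )
        D[i, j] = D[j, i] = float((arr[i][both] != arr[j][both]).sum()) / m
    return DistanceMatrix(labels, D)


# ---------------------------------------------------------------------------
# Mantel test


def _triu(D: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(D.shape[0], k=1)
    return D[i, j]


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    alternative: Literal["greater", "two-sided"] = "greater",
    seed: Optional[int] = None,
    exact: Optional[bool] = None,
) -> tuple[float, float]:
    """Mantel test: Pearson r of off-diagonal entries, permutation p.

    Rows and columns of the second matrix are permuted jointly.  For
    n ≤ 6 taxa (or ``exact=True``) all n! permutations are enumerated;
    otherwise ``n_perm`` random permutations are drawn.  The default
    alternative is one-tailed positive (concordance); two-sided tests
    |r|.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels in the same order")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = d1.n
    v1 = _triu(d1.D)
    if v1.std() == 0:
        raise ValueError("first distance matrix is constant; r undefined")

    def corr(D2: np.ndarray) -> float:
        v2 = _triu(D2)
        if v2.std() == 0:
            return 0.0
        return float(np.corrcoef(v1, v2)[0, 1])

    r_obs = corr(d2.D)

    def extreme(r: float) -> bool:
        if alternative == "greater":
            return r >= r_obs - 1e-12
        return abs(r) >= abs(r_obs) - 1e-12

    if exact is None:
        exact = n <= 6
    if exact:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if extreme(corr(d2.D[np.ix_(perm, perm)])):
                count += 1
        return r_obs, count / total  # identity included: p in (0, 1]
    rng = np.random.default_rng(seed)
    b = sum(
        extreme(corr(d2.D[np.ix_(p, p)]))
        for p in (rng.permutation(n) for _ in range(n_perm))
    )
    return r_obs, (1 + b) / (1 + n_perm)


# ---------------------------------------------------------------------------
# non-metric multidimensional scaling (Kruskal stress-1)


@dataclass
class NmdsResult:
    coordinates: np.ndarray
    stress: float
    n_restarts: int
    converged: bool
    labels: list[str] = field(default_factory=list)
    shepard: Optional[np.ndarray] = None  # columns: dissimilarity, distance, disparity


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((d**2).sum())
    if denom == 0:
        return 0.0
    return math.sqrt(float(((d - dhat) ** 2).sum()) / denom)


class NMDS(BaseEstimator):
    """Non-metric MDS minimising Kruskal stress-1.

    Alternates monotone (isotonic) regression of embedded distances on
    the input dissimilarity ranks with Guttman-transform updates of the
    configuration.  Runs from a classical-scaling start plus
    ``n_restarts`` random starts and keeps the lowest-stress solution.
    """

    def __init__(
        self,
        n_components: int = 2,
        n_restarts: int = 4,
        max_iter: int = 300,
        tol: float = 1e-7,
        random_state: Optional[int] = None,
    ):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _classical_start(self, D: np.ndarray) -> np.ndarray:
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        vals, vecs = np.linalg.eigh(B)
        order = np.argsort(vals)[::-1][: self.n_components]
        lam = np.clip(vals[order], 0, None)
        return vecs[:, order] * np.sqrt(lam)

    def _run(self, D: np.ndarray, X0: np.ndarray) -> tuple[np.ndarray, float, bool]:
        n = D.shape[0]
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        delta = _triu(D)
        order = np.argsort(delta, kind="stable")
        X = X0.copy()
        last = np.inf
        converged = False
        for _ in range(self.max_iter):
            d = pdist(X)
            if d.max() == 0:
                break
            dhat = np.empty_like(d)
            dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
            s = _stress1(d, dhat)
            if last - s < self.tol:
                converged = True
                last = s
                break
            last = s
            # Guttman transform with disparities
            ratio = np.where(d > 1e-12, dhat / d, 0.0)
            Bm = -squareform(ratio)
            np.fill_diagonal(Bm, -Bm.sum(axis=1))
            X = Bm @ X / n
            X -= X.mean(axis=0)
        d = pdist(X)
        dhat = np.empty_like(d)
        if d.max() > 0:
            dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
        else:
            dhat[:] = 0.0
        return X, _stress1(d, dhat), converged

    def fit(self, D: DistanceMatrix | np.ndarray, y=None) -> "NMDS":
        if isinstance(D, DistanceMatrix):
            labels, M = D.labels, D.D
        else:
            M = np.asarray(D, dtype=float)
            labels = [str(i) for i in range(M.shape[0])]
        n = M.shape[0]
        if n < self.n_components + 2:
            raise ValueError(
                f"need at least n_components + 2 = {self.n_components + 2} taxa"
            )
        degenerate = np.allclose(_triu(M), _triu(M)[0])
        rng = np.random.default_rng(self.random_state)
        starts = [self._classical_start(M)] + [
            rng.normal(size=(n, self.n_components)) for _ in range(self.n_restarts)
        ]
        best = None
        for X0 in starts:
            X, s, conv = self._run(M, X0)
            if best is None or s < best[1]:
                best = (X, s, conv)
        X, s, conv = best
        d = pdist(X)
        delta = _triu(M)
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        order = np.argsort(delta, kind="stable")
        dhat = np.empty_like(d)
        dhat[order] = iso.fit_transform(np.arange(len(d)), d[order]) if d.max() > 0 else 0.0
        self.result_ = NmdsResult(
            coordinates=X,
            stress=s,
            n_restarts=len(starts),
            converged=conv and not degenerate,
            labels=labels,
            shepard=np.column_stack([delta, d, dhat]),
        )
        self.embedding_ = X
        self.stress_ = s
        return self


def nmds(
    D: DistanceMatrix | np.ndarray,
    k: int = 2,
    n_restarts: int = 4,
    seed: Optional[int] = None,
) -> NmdsResult:
    """Functional wrapper over :class:`NMDS`."""
    return NMDS(n_components=k, n_restarts=n_restarts, random_state=seed).fit(D).result_


# ---------------------------------------------------------------------------
# Ward clustering on correlation distances with bootstrap support


@dataclass
class ClusterTree:
    """Ward merge tree with per-node bootstrap bipartition support."""

    labels: list[str]
    linkage: np.ndarray
    support: dict[frozenset, float] = field(default_factory=dict)
    method: str = "ward/correlation"

    def bipartitions(self) -> list[frozenset]:
        return _bipartitions(self.linkage, self.labels)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            clade = frozenset(self.labels[i] for i in node.pre_order(lambda l: l.id))
            sup = self.support.get(clade)
            label = f"{sup:.2f}" if sup is not None else ""
            return f"({left},{right}){label}:{length:.6g}"

        root = tree
        inner = ",".join(
            rec(ch, root.dist) for ch in (root.left, root.right) if ch is not None
        )
        return f"({inner});"


def _bipartitions(Z: np.ndarray, labels: Sequence[str]) -> list[frozenset]:
    n = len(labels)
    clusters: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for k, (a, b, *_rest) in enumerate(Z):
        merged = clusters[int(a)] | clusters[int(b)]
        clusters[n + k] = merged
        if 1 < len(merged) < n:  # trivial splits carry no information
            out.append(merged)
    return out


def _corr_linkage(X: np.ndarray, mode: str) -> np.ndarray:
    r = np.corrcoef(X)
    r = np.clip(r, -1.0, 1.0)
    if mode == "sqrt":
        d = np.sqrt(np.maximum(2.0 * (1.0 - r), 0.0))
    else:
        d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return hierarchy.linkage(squareform(d, checks=False), method="ward")


def ward_bootstrap(
    X,
    labels: Optional[Sequence[str]] = None,
    B: int = 1000,
    seed: Optional[int] = None,
    distance_mode: Literal["sqrt", "raw"] = "sqrt",
) -> ClusterTree:
    """Ward clustering of taxa on correlation distances, bootstrap support.

    Distance between taxa profiles is 1 − Pearson r, converted to the
    Ward-compatible form sqrt(2(1−r)) by default.  Support of an
    internal node is the fraction of B variable-resampled (with
    replacement) trees containing the same taxon bipartition.  ``B=0``
    yields a tree without support values.
    """
    if isinstance(X, FeatureTable):
        X = X.data
    if isinstance(X, pd.DataFrame):
        labels = labels or list(X.index)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError("need >= 3 taxa and >= 2 variables")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = labels[int(np.argmin(sd))] if labels else int(np.argmin(sd))
        raise ValueError(f"constant profile for taxon {bad!r}: correlation undefined")
    labels = list(labels) if labels else [str(i) for i in range(n)]
    Z = _corr_linkage(X, distance_mode)
    tree = ClusterTree(labels=labels, linkage=Z)
    if B > 0:
        rng = np.random.default_rng(seed)
        counts = {bp: 0 for bp in _bipartitions(Z, labels)}
        for _ in range(B):
            cols = rng.integers(0, p, size=p)
            Xb = X[:, cols]
            if (Xb.std(axis=1) == 0).any():
                continue  # degenerate resample: no tree to count
            for bp in _bipartitions(_corr_linkage(Xb, distance_mode), labels):
                if bp in counts:
                    counts[bp] += 1
        tree.support = {bp: c / B for bp, c in counts.items()}
    return tree


# ---------------------------------------------------------------------------
# per-class concordance report


def concordance_report(
    table: FeatureTable,
    alignment,
    lipid_classes: Optional[Iterable[str]] = None,
    mode: Literal["%area", "UI"] = "%area",
    n_perm: int = 999,
    B: int = 1000,
    seed: Optional[int] = None,
) -> dict[str, dict]:
    """Per-class lipid/phylogeny concordance bundle.

    For each requested lipid class: Euclidean distance between taxa on
    the class's log/Pareto-preprocessed relative areas (or on the class
    UI in ``mode="UI"``) is tested against the genetic p-distance by a
    Mantel test, ordinated by NMDS, clustered by Ward bootstrap, and
    probed by leave-one-taxon-out Mantel influence diagnostics.
    """
    genetic = p_distance(alignment)
    shared = [t for t in table.samples if t in genetic.labels]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared taxa for Mantel, got {len(shared)}")
    genetic = genetic.reorder(shared)
    classes = list(lipid_classes) if lipid_classes else sorted(table.class_columns)
    out: dict[str, dict] = {}
    for cls in classes:
        cols = table.class_columns[cls]
        sub = table.data.loc[shared, cols]
        if mode == "UI":
            vals = np.array([[ui(sub.loc[t])] for t in shared])
            lipid_D = np.abs(vals - vals.T.reshape(1, -1))
            lipid_dm = DistanceMatrix(shared, np.abs(vals - vals.T))
            Xvars = vals
        else:
            scaler = ParetoScaler()
            try:
                Xp = scaler.fit(sub).transform(sub)
            except ValueError:
                continue  # class absent everywhere
            lipid_dm = DistanceMatrix(shared, squareform(pdist(Xp)))
            Xvars = Xp
        r, p = mantel(genetic, lipid_dm, n_perm=n_perm, seed=seed)
        entry: dict = {"mantel_r": r, "mantel_p": p, "n_taxa": len(shared)}
        entry["nmds"] = nmds(lipid_dm, k=2 if len(shared) >= 4 else 1, seed=seed)
        try:
            entry["tree"] = ward_bootstrap(
                Xvars, labels=shared, B=B, seed=seed
            )
        except ValueError:
            entry["tree"] = None
        influence = {}
        if len(shared) >= 5:
            for taxon in shared:
                keep = [t for t in shared if t != taxon]
                r_i, p_i = mantel(
                    genetic.reorder(keep), lipid_dm.reorder(keep),
                    n_perm=n_perm, seed=seed,
                )
                influence[taxon] = {"mantel_r": r_i, "mantel_p": p_i}
        entry["leave_one_out"] = influence
        out[cls] = entry
    return out
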