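"""Community-ecology statistics: dissimilarities, ANOSIM, PCoA, UPGMA,
richness and shared-genus fractions.

All routines are implemented here directly (the permutation test, the
double-centred eigendecomposition, the average-linkage agglomeration)
and are cross-checked against independent implementations in the test
suite; scipy supplies only numerical primitives (ranks, eigensolver,
the t distribution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .io import CountTable, relative_abundance

__all__ = [
    "DissimilarityMatrix",
    "jaccard",
    "bray_curtis",
    "anosim",
    "AnosimResult",
    "pcoa",
    "PCoAResult",
    "upgma",
    "richness",
    "compare_richness",
    "WelchResult",
    "shared_genus_fraction",
    "SharedFractionResult",
]


class DissimilarityMatrix:
    """Symmetric sample x sample dissimilarity matrix with zero diagonal,
    entries in [0, 1]."""

    def __init__(self, values: np.ndarray, ids: list[str]):
        values = np.asarray(values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if (values < -1e-12).any() or (values > 1 + 1e-12).any():
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.values = np.clip(values, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)
        self.ids = list(map(str, ids))

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path, provenance=None) -> None:
        with open(path, "wt", encoding="utf-8", newline="") as fh:
            for line in provenance or ():
                fh.write(f"# {line}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index_label="sample_id",
                                       lineterminator="\n")


def _check_samples(table: CountTable) -> None:
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    empty = table.column_sums() == 0
    if empty.any():
        raise ValueError(f"all-zero sample(s): {list(empty[empty].index)}")


def jaccard(table: CountTable) -> DissimilarityMatrix:
    """Presence/absence Jaccard dissimilarity, 1 - |A and B| / |A or B|."""
    _check_samples(table)
    p = (table.data.to_numpy() > 0).astype(float)
    inter = p.T @ p
    sizes = p.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        d = 1.0 - inter / union
    d[np.isnan(d)] = 0.0
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(0.5 * (d + d.T), table.sample_ids)


def bray_curtis(table: CountTable) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity on relative abundances,
    sum|x - y| / sum(x + y)."""
    _check_samples(table)
    x = relative_abundance(table).to_numpy()
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[:, i, None] - x[:, i + 1:]).sum(axis=0)
        tot = (x[:, i, None] + x[:, i + 1:]).sum(axis=0)
        d[i, i + 1:] = diff / tot
    d = d + d.T
    return DissimilarityMatrix(d, table.sample_ids)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnosimResult:
    r: float
    p: float
    n_permutations: int


def anosim(
    d: DissimilarityMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities (Clarke's R) with a permutation test.

    Ranks all pairwise dissimilarities (mid-ranks on ties) and compares
    the mean rank between groups with the mean rank within groups:

        R = (rbar_between - rbar_within) / (n(n-1)/4)

    R is 1 when every between-group dissimilarity exceeds every
    within-group one and ~0 under random labels.  The p-value is the
    inclusive permutation probability
    (1 + #{R_perm >= R_obs}) / (1 + n_permutations), deterministic for
    a given seed.
    """
    labels = np.asarray(list(groups))
    n = len(d)
    if len(labels) != n:
        raise ValueError("group labels do not match sample count")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"each group needs >= 2 samples (singleton group(s): {small})")

    iu = np.triu_indices(n, k=1)
    ranks = _stats.rankdata(d.condensed())
    denom = n * (n - 1) / 4.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if r_stat(rng.permutation(labels)) >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(r=float(r_obs), p=float(p), n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    #: samples x k coordinates, axes ordered by descending eigenvalue
    coordinates: pd.DataFrame
    #: all eigenvalues, descending; negative ones are reported, not dropped
    eigenvalues: np.ndarray

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = np.clip(self.eigenvalues, 0.0, None)
        return pos / pos.sum()


def pcoa(d: DissimilarityMatrix, k: int = 2) -> PCoAResult:
    """Classical (metric) multidimensional scaling.

    Eigendecomposition of the double-centred matrix ``-0.5 * J D^2 J``.
    Coordinates are eigenvectors scaled by sqrt(eigenvalue); axis signs
    are fixed so the largest-magnitude loading is positive.  ``k`` must
    not exceed the number of positive eigenvalues; negative eigenvalues
    (non-Euclidean input) are reported in full.
    """
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d.values**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-10 if n else 0.0
    n_pos = int((evals > tol).sum())
    if k > n_pos:
        raise ValueError(f"k={k} exceeds the {n_pos} positive eigenvalue(s)")
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for ax in range(k):
        col = coords[:, ax]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, ax] = -col
    frame = pd.DataFrame(
        coords, index=pd.Index(d.ids, name="sample_id"),
        columns=[f"PCo{i + 1}" for i in range(k)],
    )
    return PCoAResult(coordinates=frame, eigenvalues=evals)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(d: DissimilarityMatrix) -> str:
    """Average-linkage (UPGMA) dendrogram as a Newick string.

    Produces an ultrametric tree: every merge happens at half the
    average dissimilarity between the merged clusters, and branch
    lengths are height differences.  Ties in merge distance are broken
    lexicographically by the smallest member id of each cluster, and
    children are written in lexicographic order, so output is
    deterministic.
    """
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 samples")
    # cluster state: label -> (size, height, newick)
    clusters: dict[str, tuple[int, float, str]] = {
        sid: (1, 0.0, sid) for sid in d.ids
    }
    dist: dict[frozenset, float] = {}
    for i in range(n):
        for jj in range(i + 1, n):
            dist[frozenset((d.ids[i], d.ids[jj]))] = d.values[i, jj]

    def fmt(x: float) -> str:
        return f"{x:g}"

    while len(clusters) > 1:
        best = min(
            (
                (dist[frozenset((a, b))], a, b)
                for idx, a in enumerate(sorted(clusters))
                for b in sorted(clusters)[idx + 1:]
            ),
            key=lambda t: (t[0], t[1], t[2]),
        )
        dmin, a, b = best
        (na, ha, nwa), (nb, hb, nwb) = clusters[a], clusters[b]
        h = dmin / 2.0
        newick = f"({nwa}:{fmt(h - ha)},{nwb}:{fmt(h - hb)})"
        label = min(a, b)
        for other in list(clusters):
            if other in (a, b):
                continue
            dao = dist.pop(frozenset((a, other)))
            dbo = dist.pop(frozenset((b, other)))
            dist[frozenset((label, other))] = (na * dao + nb * dbo) / (na + nb)
        dist.pop(frozenset((a, b)))
        del clusters[a], clusters[b]
        clusters[label] = (na + nb, h, newick)
    (_, _, newick), = clusters.values()
    return newick + ";"


# ---------------------------------------------------------------------------
# richness
# ---------------------------------------------------------------------------

def richness(table: CountTable) -> pd.Series:
    """Observed features (count > 0) per sample.  Comparable across
    samples only after rarefaction to equal depth."""
    out = (table.data > 0).sum(axis=0)
    out.name = "richness"
    return out


@dataclass(frozen=True)
class WelchResult:
    statistic: float
    df: float
    p: float


def compare_richness(group_a, group_b) -> WelchResult:
    """Two-sided Welch (unequal-variance) t-test between two richness groups.

    Degenerate zero-variance inputs return p = 1.0 when the means are
    equal and p = 0.0 otherwise.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        equal = math.isclose(a.mean(), b.mean())
        return WelchResult(statistic=0.0 if equal else math.inf,
                           df=float(na + nb - 2), p=1.0 if equal else 0.0)
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * _stats.t.sf(abs(t), df)
    return WelchResult(statistic=float(t), df=float(df), p=float(p))


@dataclass
class SharedFractionResult:
    #: per-sample fraction of its observed genera belonging to the
    #: all-sample core set
    fractions: pd.Series
    mean: float
    sd: float
    core_size: int


def shared_genus_fraction(table: CountTable, sample_set=None) -> SharedFractionResult:
    """Fraction of each sample's observed genera shared by *all* samples.

    The core set is the intersection of detected genera over
    ``sample_set`` (default: all samples); each sample's fraction is
    |core| / (genera observed in that sample).  Reports mean and sample
    SD across samples.
    """
    ids = list(sample_set) if sample_set is not None else table.sample_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 samples")
    present = table.data.loc[:, ids] > 0
    core = present.all(axis=1)
    per_sample = present.sum(axis=0)
    fractions = core.sum() / per_sample
    fractions.name = "shared_fraction"
    return SharedFractionResult(
        fractions=fractions,
        mean=float(fractions.mean()),
        sd=float(fractions.std(ddof=1)),
        core_size=int(core.sum()),
    )
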