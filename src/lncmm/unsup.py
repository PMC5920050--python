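"""Variance-ranked feature selection, Pearson-distance hierarchical
clustering, and cluster-vs-molecular-feature association testing.

Clustering follows the study protocol: samples are compared by Pearson
correlation across the selected genes (distance 1 - r) and merged
agglomeratively.  Centroid linkage (the protocol's choice) is applied via
the Lance-Williams update on the squared 1 - r distances — geometrically
ill-posed on a correlation distance, so it may produce inversions; average
linkage (UPGMA) is available and is better behaved.  Merging is fully
deterministic: on equal distances the pair with the lowest (creation-order)
indices merges first, and no randomness is used anywhere in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Dendrogram",
    "AssociationReport",
    "top_variable",
    "pearson_distance",
    "hclust_pearson",
    "branch_fisher",
    "mantel_haenszel",
    "associate_features",
    "zscore_rows",
]


def top_variable(m: pd.DataFrame, n: int = 500) -> list[str]:
    """The *n* genes (rows) with the highest coefficient of variation.

    CV = sd / mean on the given expression values; genes with mean 0 are
    excluded beforehand.  Ties break lexicographically on the gene id.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    means = m.mean(axis=1)
    usable = m.loc[means > 0]
    cv = usable.std(axis=1, ddof=1) / usable.mean(axis=1)
    ranked = sorted(cv.index, key=lambda g: (-cv[g], str(g)))
    return ranked[:n]


def zscore_rows(m: pd.DataFrame) -> pd.DataFrame:
    """Per-gene standardization (mean 0, sd 1); constant rows become 0."""
    mu = m.mean(axis=1)
    sd = m.std(axis=1, ddof=1).replace(0.0, np.nan)
    return m.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)


def pearson_distance(m: pd.DataFrame) -> pd.DataFrame:
    """Sample-sample distance matrix d = 1 - r over the rows (genes) of *m*."""
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = m.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ValueError(f"sample {bad!r} has zero variance")
    r = np.corrcoef(m.to_numpy().T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=m.columns, columns=m.columns)


@dataclass
class Dendrogram:
    """Agglomerative merge history over a fixed set of leaves.

    ``merges`` lists (left_id, right_id, height, size) in merge order;
    leaves are ids 0..n-1 in ``leaf_ids`` order and internal nodes continue
    from n.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float, int]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def _members(self) -> dict[int, list[int]]:
        members = {i: [i] for i in range(self.n_leaves)}
        for k, (a, b, _h, _s) in enumerate(self.merges):
            members[self.n_leaves + k] = members[a] + members[b]
        return members

    def cut(self, k: int) -> dict[str, int]:
        """Partition the leaves into *k* clusters by undoing the last k-1
        merges; returns leaf id -> cluster label (0-based, by leaf order)."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        members = self._members()
        active = set(range(n))
        for j, (a, b, _h, _s) in enumerate(self.merges[: n - k]):
            active -= {a, b}
            active.add(n + j)
        labels: dict[str, int] = {}
        roots = sorted(active, key=lambda node: min(members[node]))
        for lab, node in enumerate(roots):
            for leaf in members[node]:
                labels[self.leaf_ids[leaf]] = lab
        return labels

    def clusters(self, k: int) -> list[list[str]]:
        labels = self.cut(k)
        out: list[list[str]] = [[] for _ in range(k)]
        for s, lab in labels.items():
            out[lab].append(s)
        return out

    def to_newick(self) -> str:
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        nodes = {i: self.leaf_ids[i] for i in range(n)}
        for j, (a, b, h, _s) in enumerate(self.merges):
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            nodes[n + j] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + j] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return nodes[root] + ";"

    def plot(self, ax=None):
        """Draw the dendrogram with matplotlib (optional dependency)."""
        from matplotlib import pyplot as plt
        from scipy.cluster import hierarchy as sch

        Z = np.array(
            [[a, b, max(h, 0.0), s] for a, b, h, s in self.merges], dtype=float
        )
        if ax is None:
            _fig, ax = plt.subplots(figsize=(8, 4))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sch.dendrogram(Z, labels=self.leaf_ids, ax=ax)
        return ax


def hclust_pearson(m: pd.DataFrame, linkage: str = "centroid") -> Dendrogram:
    """Agglomerative clustering of samples under 1 - Pearson distance.

    Supported linkages: ``centroid`` (Lance-Williams on squared distances),
    ``average`` (UPGMA), ``single``, ``complete``.  Deterministic given the
    input column order: ties merge the lowest-index pair first.
    """
    if linkage not in {"centroid", "average", "single", "complete"}:
        raise ValueError(f"unknown linkage {linkage!r}")
    dist = pearson_distance(m)
    n = dist.shape[0]
    dendro = Dendrogram(leaf_ids=list(dist.columns))
    if n == 1:
        return dendro

    # Working matrix; centroid updates operate on squared distances.
    d = dist.to_numpy().copy()
    work = d**2 if linkage == "centroid" else d
    ids = list(range(n))  # creation-order node ids of active clusters
    sizes = {i: 1 for i in range(n)}
    pos = {i: i for i in range(n)}  # node id -> row of `work`
    active = list(range(n))

    for step in range(n - 1):
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                dij = work[pos[a], pos[b]]
                if best is None or dij < best[0] - 1e-15:
                    best = (dij, a, b)
        dij, a, b = best
        na, nb = sizes[a], sizes[b]
        height = float(np.sqrt(max(dij, 0.0))) if linkage == "centroid" else float(dij)
        new_id = n + step
        dendro.merges.append((a, b, height, na + nb))

        ra, rb = pos[a], pos[b]
        for c in active:
            if c in (a, b):
                continue
            rc = pos[c]
            dac, dbc = work[ra, rc], work[rb, rc]
            if linkage == "average":
                dnew = (na * dac + nb * dbc) / (na + nb)
            elif linkage == "single":
                dnew = min(dac, dbc)
            elif linkage == "complete":
                dnew = max(dac, dbc)
            else:  # centroid, on squared distances
                tot = na + nb
                dnew = (na * dac + nb * dbc) / tot - na * nb * dij / tot**2
            work[ra, rc] = work[rc, ra] = dnew
        # New cluster reuses row ra; row rb is retired with cluster b.
        active = [c for c in active if c not in (a, b)] + [new_id]
        sizes[new_id] = na + nb
        pos[new_id] = ra
    return dendro


def branch_fisher(
    partition: Mapping[str, int], feature: Mapping[str, str]
) -> dict[int, float]:
    """Two-sided Fisher exact p per cluster for a three-valued feature.

    *partition* maps sample -> cluster label; *feature* maps sample ->
    "positive"/"negative"/"NA".  NA samples are excluded.  For each cluster
    the 2x2 table is (in/out of cluster) x (feature +/-).  A feature with no
    positive samples yields p = 1 for every cluster, with a warning.
    """
    samples = [s for s in partition if feature.get(s, "NA") != "NA"]
    n_pos = sum(feature[s] == "positive" for s in samples)
    labels = sorted(set(partition[s] for s in partition))
    if n_pos == 0:
        warnings.warn("feature has no positive samples after NA removal")
        return {lab: 1.0 for lab in labels}
    out: dict[int, float] = {}
    for lab in labels:
        in_pos = sum(partition[s] == lab and feature[s] == "positive" for s in samples)
        in_neg = sum(partition[s] == lab and feature[s] == "negative" for s in samples)
        out_pos = n_pos - in_pos
        out_neg = len(samples) - n_pos - in_neg
        _odds, p = stats.fisher_exact(
            [[in_pos, in_neg], [out_pos, out_neg]], alternative="two-sided"
        )
        out[lab] = float(p)
    return out


def mantel_haenszel(strata: Sequence[np.ndarray | Sequence[Sequence[int]]]) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel chi-squared over 2x2 strata (no continuity
    correction); returns (statistic, p) with p from chi-squared, 1 df.

    The Cochran variance r1*r2*c1*c2/n^3 is used, so on a single stratum
    the statistic reduces exactly to the ordinary Pearson 1-df chi-squared
    (the hypergeometric n^2*(n-1) form differs by a factor (n-1)/n).

    Strata with a zero margin carry no information and are dropped with a
    warning; if all are dropped a ValueError is raised.
    """
    if len(strata) == 0:
        raise ValueError("need at least one stratum")
    num = 0.0
    var = 0.0
    used = 0
    for t in strata:
        t = np.asarray(t, dtype=float)
        if t.shape != (2, 2):
            raise ValueError(f"stratum must be 2x2, got {t.shape}")
        a = t[0, 0]
        r1, r2 = t[0].sum(), t[1].sum()
        c1, c2 = t[:, 0].sum(), t[:, 1].sum()
        ntot = t.sum()
        if min(r1, r2, c1, c2) == 0 or ntot < 2:
            warnings.warn("dropping stratum with a zero margin")
            continue
        num += a - r1 * c1 / ntot
        var += r1 * r2 * c1 * c2 / ntot**3
        used += 1
    if used == 0:
        raise ValueError("all strata had zero margins")
    if var == 0:
        return 0.0, 1.0
    statistic = num**2 / var
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


@dataclass
class AssociationReport:
    """Dendrogram-vs-molecular-feature association summary.

    ``branch_p`` holds, per feature, the per-cluster Fisher p-values at the
    chosen cut; ``best_cluster`` the cluster maximizing that feature's
    enrichment (the stratum used for the stratified test, a convention of
    this package); ``mh_stat`` the stratified (Cochran-Mantel-Haenszel)
    chi-squared over those strata.  Because the stratum of each feature is
    chosen to maximize its enrichment, the chi-squared reference
    distribution would be anti-conservative; ``mh_p`` is therefore
    calibrated by permuting each feature's labels and repeating the whole
    selection + statistic computation (floor 1/(B+1)).
    """

    k: int
    branch_p: dict[str, dict[int, float]]
    best_cluster: dict[str, int]
    mh_stat: float
    mh_p: float

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "branch_fisher_p": {
                f: {str(c): p for c, p in d.items()} for f, d in self.branch_p.items()
            },
            "best_cluster": dict(self.best_cluster),
            "mantel_haenszel": {"stat": self.mh_stat, "p": self.mh_p},
        }


def _selected_stratum(
    status: np.ndarray, member: np.ndarray
) -> tuple[int, float, float] | None:
    """Pick the cluster with the largest standardized positive enrichment.

    *status* is a (n,) 0/1 vector (positives), *member* a (n, k) 0/1 cluster
    membership matrix.  Returns (cluster, a - E[a], Var[a]) with the Cochran
    variance, or None when a margin is degenerate.
    """
    n = status.size
    m1 = status.sum()
    sizes = member.sum(axis=0)
    if n < 2 or m1 == 0 or m1 == n:
        return None
    a = status @ member
    e = sizes * m1 / n
    var = sizes * (n - sizes) * m1 * (n - m1) / n**3
    ok = var > 0
    if not ok.any():
        return None
    z = np.where(ok, (a - e) / np.sqrt(np.where(ok, var, 1.0)), -np.inf)
    c = int(np.argmax(z))  # ties: argmax takes the lowest index
    return c, float(a[c] - e[c]), float(var[c])


def associate_features(
    dendro: Dendrogram,
    cohort: pd.DataFrame,
    k: int,
    n_permutations: int = 20_000,
    _perm_seed: int = 987_654_321,
) -> AssociationReport:
    """Cut the dendrogram at *k* clusters and test each molecular feature.

    Per feature: Fisher p for every cluster, and one stratum built from the
    cluster with the largest standardized positive enrichment (ties: lowest
    cluster label).  The stratified chi-squared over those strata is
    reported as ``mh_stat``; its p-value is calibrated by permuting each
    feature's (non-NA) labels *n_permutations* times and re-running the
    cluster selection, which accounts for the max-enrichment choice.  The
    permutation stream is fixed, so the report is deterministic.
    """
    partition = dendro.cut(k)
    samples = list(partition)
    labels = sorted(set(partition.values()))
    member = np.zeros((len(samples), len(labels)), dtype=float)
    for i, s in enumerate(samples):
        member[i, labels.index(partition[s])] = 1.0

    branch_p: dict[str, dict[int, float]] = {}
    best: dict[str, int] = {}
    per_feature: list[tuple[np.ndarray, np.ndarray]] = []  # (status, member)
    num = 0.0
    var = 0.0
    for feat in cohort.columns:
        feature = cohort[feat].to_dict()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            branch_p[feat] = branch_fisher(partition, feature)
        use = np.array([feature.get(s, "NA") != "NA" for s in samples])
        status = np.array(
            [1.0 if feature.get(s) == "positive" else 0.0 for s in samples]
        )[use]
        sel = _selected_stratum(status, member[use])
        if sel is None:
            continue
        c, d, v = sel
        best[feat] = labels[c]
        num += d
        var += v
        per_feature.append((status, member[use]))

    if not per_feature or var == 0:
        return AssociationReport(
            k=k, branch_p=branch_p, best_cluster=best, mh_stat=0.0, mh_p=1.0
        )
    mh_stat = num**2 / var

    # Permutation calibration of the selection + statistic pipeline.
    rng = np.random.default_rng(_perm_seed)
    B = int(n_permutations)
    num_b = np.zeros(B)
    var_b = np.zeros(B)
    for status, mem in per_feature:
        n = status.size
        # B independent permutations of the status labels
        order = np.argsort(rng.random((B, n)), axis=1)
        perm = status[order]  # (B, n)
        a = perm @ mem  # (B, k)
        m1 = status.sum()
        sizes = mem.sum(axis=0)
        e = sizes * m1 / n
        v = sizes * (n - sizes) * m1 * (n - m1) / n**3
        ok = v > 0
        z = np.where(ok, (a - e) / np.sqrt(np.where(ok, v, 1.0)), -np.inf)
        c_sel = np.argmax(z, axis=1)
        num_b += (a - e)[np.arange(B), c_sel]
        var_b += v[c_sel]
    stat_b = np.where(var_b > 0, num_b**2 / np.where(var_b > 0, var_b, 1.0), 0.0)
    mh_p = float((1 + np.sum(stat_b >= mh_stat - 1e-12)) / (B + 1))
    return AssociationReport(
        k=k, branch_p=branch_p, best_cluster=best, mh_stat=mh_stat, mh_p=mh_p
    )
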