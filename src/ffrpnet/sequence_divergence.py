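"""Functional-divergence distances and effector-preference clustering.

Type-I functional divergence (Gu's theta) between two members of a gene
family quantifies shifted site-specific evolutionary rates; theta = 0 means
no divergence.  Pairwise theta converts to an additive-style distance
d = -ln(1 - theta), which is clustered hierarchically (complete linkage for
the divergence trees, average linkage for effector-preference groups).

Effector-molecule preference of Lrp/AsnC-family regulators is encoded by
nine key residues of the RAM (effector-binding) domain; TFs are compared by
summing BLOSUM62 scores across the nine positions and clustering the derived
distance d_ij = (S_ii + S_jj)/2 - S_ij, which is zero iff two profiles are
score-identical.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
PROFILE_LENGTH = 9


@dataclass
class ThetaTable:
    """Square symmetric tables of theta (with SE and p) for a TF family."""

    theta: pd.DataFrame
    se: pd.DataFrame | None = None
    pvalue: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        t = self.theta
        if not t.index.equals(t.columns):
            raise ValueError("theta matrix must be square with matching labels")
        if not np.allclose(t.values, t.values.T, equal_nan=True):
            raise ValueError("theta matrix must be symmetric")
        vals = t.values[~np.eye(len(t), dtype=bool)]
        if np.any(vals < 0) or np.any(vals >= 1):
            raise ValueError("theta values must lie in [0, 1)")


@dataclass
class Dendrogram:
    """Agglomeration result: scipy linkage matrix plus leaf labels."""

    labels: list[str]
    linkage_matrix: np.ndarray
    method: str

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        """(cluster a, cluster b, height) per merge; leaves are 0..n-1."""
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage_matrix]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]

    def cut(self, k: int | None = None, height: float | None = None) -> dict[str, int]:
        if (k is None) == (height is None):
            raise ValueError("give exactly one of k or height")
        if k is not None:
            if not 1 <= k <= len(self.labels):
                raise ValueError("k must be in [1, n]")
            assign = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        else:
            assign = hierarchy.fcluster(self.linkage_matrix, t=height,
                                        criterion="distance")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left = walk(node.get_left())
            right = walk(node.get_right())
            bl = node.dist - node.get_left().dist
            br = node.dist - node.get_right().dist
            return f"({left}:{bl:g},{right}:{br:g})"

        return walk(tree) + ";"


def theta_to_distance(theta: ThetaTable | pd.DataFrame) -> pd.DataFrame:
    """d_ij = -ln(1 - theta_ij); strictly monotone in theta, d_ii = 0."""
    t = theta.theta if isinstance(theta, ThetaTable) else theta
    vals = t.values.astype(float)
    off = ~np.eye(len(t), dtype=bool)
    if np.any(vals[off] < 0) or np.any(vals[off] >= 1):
        raise ValueError("theta values must lie in [0, 1)")
    d = -np.log1p(-vals)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=t.index, columns=t.columns)


def hierarchical_cluster(dist: pd.DataFrame, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a square symmetric distance matrix."""
    if linkage not in ("complete", "average"):
        raise ValueError("linkage must be 'complete' or 'average'")
    vals = dist.values.astype(float)
    if vals.shape[0] != vals.shape[1] or not dist.index.equals(dist.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(vals, vals.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(vals < 0) or not np.all(np.isfinite(vals)):
        raise ValueError("distances must be finite and nonnegative")
    condensed = squareform(vals, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(list(dist.index), Z, linkage)


def load_blosum62() -> dict[tuple[str, str], float]:
    """BLOSUM62 as a symmetric dict over the 20-letter alphabet."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    table: dict[tuple[str, str], float] = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            table[(a, b)] = float(mat[a, b])
    return table


def _score(a: str, b: str, table: dict[tuple[str, str], float]) -> float:
    # a gap scores as the minimum value of the partner's row (conservative)
    if a == GAP and b == GAP:
        return min(table.values())
    if a == GAP:
        return min(table[(b, x)] for x in AMINO_ACIDS)
    if b == GAP:
        return min(table[(a, x)] for x in AMINO_ACIDS)
    return table[(a, b)]


def _validate_profile(tf: str, residues: str) -> None:
    if len(residues) != PROFILE_LENGTH:
        raise ValueError(f"profile of {tf} must have length {PROFILE_LENGTH}, "
                         f"got {len(residues)}")
    bad = set(residues) - set(AMINO_ACIDS) - {GAP}
    if bad:
        raise ValueError(f"profile of {tf} has invalid letters {sorted(bad)}")


def residue_similarity(profiles: dict[str, str],
                       table: dict[tuple[str, str], float] | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summed substitution scores over the nine positions, and the derived distance.

    S_ij = sum_k table[a_ik, a_jk]; d_ij = (S_ii + S_jj)/2 - S_ij.
    """
    if table is None:
        table = load_blosum62()
    tfs = sorted(profiles)
    for tf in tfs:
        _validate_profile(tf, profiles[tf])
    n = len(tfs)
    S = np.zeros((n, n))
    for i, a in enumerate(tfs):
        for j, b in enumerate(tfs):
            if j < i:
                continue
            s = sum(_score(x, y, table) for x, y in zip(profiles[a], profiles[b]))
            S[i, j] = S[j, i] = s
    D = (np.diag(S)[:, None] + np.diag(S)[None, :]) / 2 - S
    np.fill_diagonal(D, 0.0)
    sim = pd.DataFrame(S, index=tfs, columns=tfs)
    dist = pd.DataFrame(D, index=tfs, columns=tfs)
    return sim, dist


@dataclass
class EffectorClusters:
    assignment: dict[str, int]
    consensus: dict[int, str]
    dendrogram: Dendrogram


def effector_clusters(profiles: dict[str, str], k: int | None = None,
                      height: float | None = None,
                      table: dict[tuple[str, str], float] | None = None
                      ) -> EffectorClusters:
    """Average-linkage clusters of TFs by nine-residue effector profiles."""
    _, dist = residue_similarity(profiles, table)
    dend = hierarchical_cluster(dist, linkage="average")
    assignment = dend.cut(k=k, height=height)
    if len(set(assignment.values())) == 0:
        raise ValueError("cutoff yields zero clusters")
    consensus: dict[int, str] = {}
    for cid in sorted(set(assignment.values())):
        members = [profiles[tf] for tf, c in assignment.items() if c == cid]
        cons = []
        for pos in range(PROFILE_LENGTH):
            counts = Counter(p[pos] for p in members)
            top = max(counts.values())
            cons.append(sorted(a for a, c in counts.items() if c == top)[0])
        consensus[cid] = "".join(cons)
    return EffectorClusters(assignment, consensus, dend)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_theta(path) -> ThetaTable:
    """Read a long-format theta table (tf_a, tf_b, theta, se, pvalue)."""
    df = pd.read_csv(path, sep="\t")
    tfs = sorted(set(df["tf_a"]) | set(df["tf_b"]))
    theta = pd.DataFrame(0.0, index=tfs, columns=tfs)
    se = pd.DataFrame(np.nan, index=tfs, columns=tfs)
    pv = pd.DataFrame(np.nan, index=tfs, columns=tfs)
    for _, row in df.iterrows():
        a, b = row["tf_a"], row["tf_b"]
        theta.loc[a, b] = theta.loc[b, a] = row["theta"]
        if "se" in df.columns:
            se.loc[a, b] = se.loc[b, a] = row["se"]
        if "pvalue" in df.columns:
            pv.loc[a, b] = pv.loc[b, a] = row["pvalue"]
    return ThetaTable(theta, se, pv)


def load_ffrp_theta() -> ThetaTable:
    """The bundled pairwise theta table for the eight H. salinarum FFRPs."""
    with resources.as_file(
        resources.files("ffrpnet.data") / "ffrp_theta.tsv"
    ) as path:
        return read_theta(path)


def read_residue_profiles(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    profiles = dict(zip(df["tf"].astype(str), df["residues"].astype(str)))
    for tf, res in profiles.items():
        _validate_profile(tf, res)
    return profiles


def write_residue_profiles(profiles: dict[str, str], path) -> None:
    pd.DataFrame(sorted(profiles.items()), columns=["tf", "residues"]).to_csv(
        path, sep="\t", index=False)
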