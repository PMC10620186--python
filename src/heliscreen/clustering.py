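"""Sequence-family clustering and position-weight-matrix logos.

Hit peptides of equal length (staple cysteines aligned by position) are
grouped by average-linkage hierarchical clustering on a substitution-
matrix distance, and each family is summarized as a logo whose positions
are classified fixed / partial / free — the classification that drives the
focused-library design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genetics import AMINO_ACIDS

__all__ = [
    "Cluster",
    "ClusterLogo",
    "PositionClass",
    "pairwise_distance",
    "hcluster",
    "cluster_peptides",
    "build_logo",
    "classify_positions",
]

DEFAULT_CUT_HEIGHT = 0.55
DEFAULT_F_FIXED = 0.9
DEFAULT_F_CUM = 0.75

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class Cluster:
    cluster_id: int
    members: list[str]
    weights: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a cluster needs at least one member")
        if len({len(m) for m in self.members}) != 1:
            raise ValueError("cluster members must share one length")
        if not self.weights:
            self.weights = [1.0] * len(self.members)


@dataclass(frozen=True)
class PositionClass:
    """Classification of one logo position."""

    kind: str  # "fixed" | "partial" | "free"
    aas: str  # the fixed residue, the favored set, or "" for free


@dataclass
class ClusterLogo:
    """L x 20 per-position amino-acid frequencies for one family."""

    pwm: pd.DataFrame  # index 1..L, columns the 20 amino acids
    pseudocount: float
    classes: list[PositionClass] | None = None

    @property
    def length(self) -> int:
        return len(self.pwm)

    def to_tsv(self, path) -> None:
        self.pwm.to_csv(path, sep="\t", index_label="position")


def pairwise_distance(
    peptides: list[str], variable_positions: list[int] | None = None
) -> np.ndarray:
    """Symmetric distance matrix: 1 - normalized BLOSUM62 similarity.

    Similarity is summed position-wise over the variable positions
    (1-based; default all) and normalized by the geometric mean of each
    sequence's self-similarity, so identical peptides are at distance 0.
    No gaps: peptides must share one length.
    """
    if len({len(p) for p in peptides}) > 1:
        raise ValueError("peptides must be equal length (staples aligned)")
    length = len(peptides[0])
    cols = variable_positions or list(range(1, length + 1))
    idx = np.array([c - 1 for c in cols])
    aa_index = {a: i for i, a in enumerate(_BLOSUM62.alphabet)}
    enc = np.array([[aa_index[p[i]] for i in idx] for p in peptides])
    S = np.asarray(_BLOSUM62)
    # per-pair summed substitution scores over the selected positions
    raw = np.zeros((len(peptides), len(peptides)))
    for j in range(enc.shape[1]):
        raw += S[np.ix_(enc[:, j], enc[:, j])]
    self_sim = np.diag(raw)
    sim = raw / np.sqrt(np.outer(self_sim, self_sim))
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    return np.maximum(dist, 0.0)


def hcluster(
    distances: np.ndarray, peptides: list[str], cut_height: float = DEFAULT_CUT_HEIGHT
) -> list[Cluster]:
    """Average-linkage agglomeration cut at ``cut_height``.

    Determinism: callers should present peptides in lexicographic order
    (``cluster_peptides`` does) so equal-distance merges resolve
    identically regardless of the original input order. Cluster ids are
    assigned by each cluster's lexicographically smallest member.
    """
    if distances.shape != (len(peptides), len(peptides)):
        raise ValueError("distance matrix does not match peptide list")
    if len(peptides) == 1:
        return [Cluster(1, list(peptides))]
    Z = linkage(squareform(distances, checks=False), method="average")
    labels = fcluster(Z, t=cut_height, criterion="distance")
    groups: dict[int, list[str]] = {}
    for pep, lab in zip(peptides, labels):
        groups.setdefault(int(lab), []).append(pep)
    ordered = sorted(groups.values(), key=lambda members: min(members))
    return [Cluster(i, sorted(members)) for i, members in enumerate(ordered, start=1)]


def cluster_peptides(
    peptides: list[str],
    cut_height: float = DEFAULT_CUT_HEIGHT,
    variable_positions: list[int] | None = None,
) -> list[Cluster]:
    """Unique, sort, and cluster a peptide list (order-invariant)."""
    uniq = sorted(set(peptides))
    if not uniq:
        return []
    dist = pairwise_distance(uniq, variable_positions)
    return hcluster(dist, uniq, cut_height)


def build_logo(cluster: Cluster, pseudocount: float = 0.0) -> ClusterLogo:
    """Weighted per-position frequencies with a symmetric pseudocount.

    pwm[j][a] = (weight of a at j + pseudocount) / (n + 20*pseudocount);
    every column sums to 1.
    """
    length = len(cluster.members[0])
    counts = np.zeros((length, 20))
    aa_idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for pep, w in zip(cluster.members, cluster.weights):
        for j, aa in enumerate(pep):
            counts[j, aa_idx[aa]] += w
    n = sum(cluster.weights)
    pwm = (counts + pseudocount) / (n + 20 * pseudocount)
    df = pd.DataFrame(pwm, index=pd.RangeIndex(1, length + 1), columns=list(AMINO_ACIDS))
    return ClusterLogo(pwm=df, pseudocount=pseudocount)


def classify_positions(
    logo: ClusterLogo,
    f_fixed: float = DEFAULT_F_FIXED,
    f_cum: float = DEFAULT_F_CUM,
    forced_fixed: dict[int, str] | None = None,
) -> list[PositionClass]:
    """Classify each logo position as fixed / partial / free.

    A position is fixed when its top residue reaches ``f_fixed``;
    otherwise partial when the smallest residue set with cumulative
    frequency >= ``f_cum`` has 2-5 members (that set is the favored set);
    otherwise free. Residues tied in frequency with the last included one
    are also included, so e.g. frequencies .3/.3/.2/.2 yield a favored
    set of four, not three. Staple/scaffold positions (``forced_fixed``,
    position -> residue) are always fixed.
    """
    forced_fixed = forced_fixed or {}
    classes: list[PositionClass] = []
    for pos in logo.pwm.index:
        if pos in forced_fixed:
            classes.append(PositionClass("fixed", forced_fixed[pos]))
            continue
        col = logo.pwm.loc[pos]
        order = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
        top_aa, top_f = order[0]
        if top_f >= f_fixed:
            classes.append(PositionClass("fixed", top_aa))
            continue
        cum, chosen, last_f = 0.0, [], 0.0
        for aa, f in order:
            if cum >= f_cum and not np.isclose(f, last_f):
                break
            chosen.append(aa)
            cum += f
            last_f = f
        if 2 <= len(chosen) <= 5 and cum >= f_cum:
            classes.append(PositionClass("partial", "".join(sorted(chosen))))
        else:
            classes.append(PositionClass("free", ""))
    logo.classes = classes
    return classes


def plot_logo(logo: ClusterLogo, ax=None):
    """Minimal stacked-letter logo rendering (information-free heights:
    plain frequencies)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.5 * logo.length, 2.5))
    for pos in logo.pwm.index:
        col = logo.pwm.loc[pos].sort_values()
        y = 0.0
        for aa, f in col.items():
            if f < 0.01:
                continue
            ax.text(pos, y + f / 2, aa, ha="center", va="center", fontsize=6 + 14 * f)
            y += f
    ax.set_xlim(0.5, logo.length + 0.5)
    ax.set_ylim(0, 1)
    ax.set_xlabel("position")
    ax.set_ylabel("frequency")
    return ax
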