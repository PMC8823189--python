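"""Blinded subject-grouping inference.

In the study design the analysts knew which subjects formed an age/sex
matched pair and which biopsy was baseline vs post, but not which pair
member was the bed-rest-only (control) subject and which exercised.  The
blinded procedure recovers the grouping from expression alone:

1. per pair, collect *divergent* genes — one subject's |log2FC| crosses the
   threshold theta while the other shows no change or an opposite trend;
2. intersect the divergence lists across all pairs;
3. rank genes by *relative variance* (variance / mean of TPM within an
   analysis unit), take the top-k per unit, and intersect across units;
4. intersect the two consistent lists into a final blinded gene set;
5. hierarchically cluster post-intervention samples (1 - Pearson distance,
   UPGMA) and cut into two groups, repairing any pair whose two subjects
   land in one cluster (the formalization of the study's manual step);
6. call which group is which intervention by a signed vote over marker
   genes with expected directions.

The default threshold theta = 0.585 corresponds to a linear fold change of
1.5 (and its reciprocal ~0.66); the "no change" band is symmetric in log2
space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .datatypes import (
    ExpressionMatrix,
    FoldChangeTable,
    ValidationError,
    blinded_pairs,
    sample_of,
)
from .normalize import DEFAULT_EPSILON, compute_log2_fold_changes

DEFAULT_THETA = 0.585  # log2(1.5) to 3 d.p.; the study's divergence threshold
DEFAULT_TOP_K = 500

Change = Literal["up", "down", "no_change"]


@dataclass
class BlindedParams:
    """Tunables of the blinded procedure."""

    theta: float = DEFAULT_THETA
    top_k: int = DEFAULT_TOP_K
    markers: dict[str, int] = field(
        default_factory=lambda: {"XIRP1": 1, "TNFRSF12A": 1, "HSPB1": 1}
    )
    linkage_method: str = "average"
    variance_unit: Literal["pair", "subject"] = "pair"
    epsilon: float = DEFAULT_EPSILON
    log_distance: bool = True  # Pearson on log2(TPM+eps) for the grouping step

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def classify_change(log2fc, theta: float = DEFAULT_THETA):
    """Classify log2 fold changes into up / down / no_change.

    ``up`` iff log2fc >= theta (boundary inclusive), ``down`` iff
    log2fc <= -theta, otherwise ``no_change``.  Accepts scalars or arrays;
    non-finite input raises.
    """
    arr = np.asarray(log2fc, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("classify_change requires finite log2 fold changes")
    out = np.where(arr >= theta, "up", np.where(arr <= -theta, "down", "no_change"))
    return out.item() if np.isscalar(log2fc) or arr.ndim == 0 else out


def divergent_genes_for_pair(
    fc_subject1: pd.Series, fc_subject2: pd.Series, theta: float = DEFAULT_THETA
) -> set[str]:
    """Genes where the two pair members disagree post-intervention.

    A gene is included iff at least one subject is classified up or down
    while the other is no_change **or** changed with the opposite sign.
    Symmetric in subject order.  Both series must share the gene universe.
    """
    if not fc_subject1.index.equals(fc_subject2.index):
        common = fc_subject1.index.intersection(fc_subject2.index)
        fc_subject1 = fc_subject1.loc[common]
        fc_subject2 = fc_subject2.loc[common]
    c1 = classify_change(fc_subject1.to_numpy(), theta)
    c2 = classify_change(fc_subject2.to_numpy(), theta)
    changed1 = c1 != "no_change"
    changed2 = c2 != "no_change"
    opposite = changed1 & changed2 & (c1 != c2)
    one_sided = changed1 ^ changed2
    mask = opposite | one_sided
    return set(fc_subject1.index[mask])


def consistent_trend_genes(fc_table: pd.DataFrame, theta: float = DEFAULT_THETA) -> set[str]:
    """Genes classified the same way (all up, or all down) in every subject."""
    if fc_table.shape[1] < 2:
        raise ValueError("consistent_trend_genes needs >= 2 subjects")
    cls = np.stack([classify_change(fc_table[c].to_numpy(), theta) for c in fc_table.columns], axis=1)
    all_up = (cls == "up").all(axis=1)
    all_down = (cls == "down").all(axis=1)
    return set(fc_table.index[all_up | all_down])


def relative_variance(values: Sequence[float]) -> float:
    """Unbiased sample variance divided by the mean; NaN if the mean is 0.

    A NaN return is the "excluded" flag for degenerate genes (all-zero TPM
    within the analysis unit); such genes are never ranked.
    """
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean == 0:
        return float("nan")
    return float(arr.var(ddof=1) / mean)


def relative_variance_scores(matrix: pd.DataFrame, sample_ids: Sequence[str]) -> pd.Series:
    """Vectorized relative variance of every gene over ``sample_ids``."""
    sub = matrix[list(sample_ids)]
    mean = sub.mean(axis=1)
    var = sub.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = var / mean
    score[mean == 0] = np.nan
    return score


def top_k_by_relative_variance(
    matrix: pd.DataFrame, unit_samples: Sequence[str], k: int
) -> list[str]:
    """Top-k genes by relative variance within one analysis unit.

    Ties are broken lexicographically by gene_id; genes with undefined
    score (mean 0) are excluded before ranking.  Raises if fewer than k
    genes are scored.
    """
    scores = relative_variance_scores(matrix, unit_samples).dropna()
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} scored genes")
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return order[:k]


def intersect_gene_lists(lists: Iterable[Iterable[str]]) -> set[str]:
    """Set intersection of one or more gene lists."""
    sets = [set(lst) for lst in lists]
    if not sets:
        raise ValueError("need at least one gene list")
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def final_blinded_gene_set(divergence_consistent: Iterable[str], variance_consistent: Iterable[str]) -> set[str]:
    """Genes on both the divergence and relative-variance consistent lists."""
    return set(divergence_consistent) & set(variance_consistent)


def pearson_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """1 - Pearson correlation; in [0, 2].

    Requires equal-length vectors of length >= 3 with nonzero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson_distance needs equal-length 1-D vectors, length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("pearson_distance is undefined for zero-variance vectors")
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


def pairwise_pearson_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Symmetric (samples x samples) matrix of 1 - Pearson over gene vectors."""
    if matrix.shape[0] < 3:
        raise ValueError("need >= 3 genes for correlation distances")
    stds = matrix.std(axis=0, ddof=0)
    dead = stds[stds == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance sample columns: {dead}")
    corr = np.corrcoef(matrix.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return pd.DataFrame(dist, index=matrix.columns, columns=matrix.columns)


def hierarchical_cluster(
    distance: pd.DataFrame, method: str = "average"
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of a precomputed distance matrix.

    Returns the scipy linkage matrix and the leaf labels (the distance
    matrix's index order); leaf order within the tree is deterministic.
    """
    if distance.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    condensed = squareform(distance.to_numpy(), checks=False)
    linkage = sch.linkage(condensed, method=method)
    return linkage, list(distance.index)


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage, labels)
    return str(tree).strip()


@dataclass
class GroupPrediction:
    """Outcome of the constrained two-group cut and the intervention call."""

    group_a: list[str]
    group_b: list[str]
    pair_constraint_ok: dict[str, bool]      # pre-repair, per pair
    intervention_of: dict[str, str | None] = field(default_factory=dict)  # group -> label
    marker_votes: dict[str, float] = field(default_factory=dict)          # group -> vote
    uncalled: bool = False

    def group_of(self, subject: str) -> str:
        if subject in self.group_a:
            return "A"
        if subject in self.group_b:
            return "B"
        raise KeyError(subject)

    def partition(self) -> frozenset[frozenset[str]]:
        return frozenset((frozenset(self.group_a), frozenset(self.group_b)))


def predict_two_groups(
    distance: pd.DataFrame,
    sheet: pd.DataFrame,
    linkage_method: str = "average",
) -> GroupPrediction:
    """Cut the sample dendrogram into two groups, one pair member per group.

    ``distance`` is a subject-level distance matrix (index/columns are
    subject ids, typically from their post-intervention samples).  The tree
    is cut into two clusters; any pair whose two subjects land in the same
    cluster is repaired by moving whichever subject has the lower mean
    distance to the *other* cluster — the deterministic formalization of
    the study's manual reassignment of the outlier pair.
    """
    pairs = blinded_pairs(sheet)
    if not pairs:
        raise ValidationError("no two-subject male pairs available for blinded grouping")
    subjects = [s for members in pairs.values() for s in members]
    missing = [s for s in subjects if s not in distance.index]
    if missing:
        raise ValidationError(f"distance matrix lacks subjects: {missing}")
    dist = distance.loc[subjects, subjects]

    linkage, labels = hierarchical_cluster(dist, method=linkage_method)
    cut = sch.fcluster(linkage, t=2, criterion="maxclust")
    assign = {lab: int(c) for lab, c in zip(labels, cut)}

    constraint_ok = {
        pair: assign[m[0]] != assign[m[1]] for pair, m in pairs.items()
    }

    # repair: pairs violating the one-per-group constraint, in sorted order
    for pair in sorted(pairs):
        s1, s2 = pairs[pair]
        if assign[s1] != assign[s2]:
            continue
        src = assign[s1]
        dst = 1 if src == 2 else 2
        costs = {}
        for mover in (s1, s2):
            members = [s for s in subjects if assign[s] == dst and s != mover]
            if members:
                costs[mover] = float(dist.loc[mover, members].mean())
            else:
                costs[mover] = 0.0
        mover = min((s1, s2), key=lambda s: (costs[s], s))
        assign[mover] = dst

    group_a = sorted(s for s in subjects if assign[s] == 1)
    group_b = sorted(s for s in subjects if assign[s] == 2)
    return GroupPrediction(group_a=group_a, group_b=group_b, pair_constraint_ok=constraint_ok)


def predict_intervention(
    prediction: GroupPrediction,
    fc_table: FoldChangeTable,
    markers: Mapping[str, int],
    symbol_to_gene: Mapping[str, str] | None = None,
) -> GroupPrediction:
    """Label the two groups by a signed marker vote.

    For each group, vote = sum over markers of sign(mean group log2FC) x
    expected sign in control.  The group with the higher vote is labeled
    control.  An exact tie leaves both labels None with ``uncalled`` set.
    """
    gene_of = dict(symbol_to_gene or {})
    marker_genes = {}
    for sym, expected in markers.items():
        gid = gene_of.get(sym, sym)
        if gid in fc_table.values.index:
            marker_genes[gid] = expected
    if not marker_genes:
        raise ValidationError("no marker genes present in the fold-change table")

    votes = {}
    for name, members in (("A", prediction.group_a), ("B", prediction.group_b)):
        vote = 0.0
        for gid, expected in marker_genes.items():
            mean_fc = float(fc_table.values.loc[gid, members].mean())
            vote += float(np.sign(mean_fc)) * expected
        votes[name] = vote
    prediction.marker_votes = votes
    if votes["A"] == votes["B"]:
        prediction.intervention_of = {"A": None, "B": None}
        prediction.uncalled = True
    else:
        control = "A" if votes["A"] > votes["B"] else "B"
        other = "B" if control == "A" else "A"
        prediction.intervention_of = {control: "control", other: "exercise"}
        prediction.uncalled = False
    return prediction


class BlindedAnalysis(BaseEstimator):
    """End-to-end blinded procedure as a sklearn-style estimator.

    ``fit`` consumes a coding-renormalized :class:`ExpressionMatrix` and a
    sample sheet and populates fitted attributes; ``predict`` returns the
    subject -> group assignment (the :class:`GroupPrediction`).

    Attributes
    ----------
    fold_changes_ : FoldChangeTable
    divergent_lists_ : dict pair_id -> set of genes
    divergence_consistent_ : set — intersection of the per-pair lists
    trend_consistent_ : set — same-direction trend in every subject
    variance_lists_ : dict unit -> top-k list
    variance_consistent_ : set — intersection of top-k lists
    final_genes_ : set — divergence ∩ variance consistent lists
    prediction_ : GroupPrediction with intervention labels
    """

    def __init__(
        self,
        theta: float = DEFAULT_THETA,
        top_k: int = DEFAULT_TOP_K,
        markers: dict[str, int] | None = None,
        linkage_method: str = "average",
        variance_unit: str = "pair",
        epsilon: float = DEFAULT_EPSILON,
        log_distance: bool = True,
    ):
        self.theta = theta
        self.top_k = top_k
        self.markers = markers
        self.linkage_method = linkage_method
        self.variance_unit = variance_unit
        self.epsilon = epsilon
        self.log_distance = log_distance

    def _params(self) -> BlindedParams:
        markers = self.markers
        if markers is None:
            markers = {"XIRP1": 1, "TNFRSF12A": 1, "HSPB1": 1}
        return BlindedParams(
            theta=self.theta,
            top_k=self.top_k,
            markers=dict(markers),
            linkage_method=self.linkage_method,
            variance_unit=self.variance_unit,  # type: ignore[arg-type]
            epsilon=self.epsilon,
            log_distance=self.log_distance,
        )

    def fit(self, X: ExpressionMatrix, sheet: pd.DataFrame, catalog: pd.DataFrame | None = None):
        params = self._params()
        pairs = blinded_pairs(sheet)
        if not pairs:
            raise ValidationError("sample sheet contains no blinded-eligible pairs")
        male_subjects = sorted(s for m in pairs.values() for s in m)
        male_sheet = sheet[sheet["subject_id"].isin(male_subjects)]

        fc = compute_log2_fold_changes(X, male_sheet, epsilon=params.epsilon)
        self.fold_changes_ = fc

        # 1-2: divergence lists per pair, intersected
        self.divergent_lists_ = {}
        for pair, (s1, s2) in pairs.items():
            observed = ~(fc.unobserved[s1] | fc.unobserved[s2])
            genes = fc.values.index[observed]
            self.divergent_lists_[pair] = divergent_genes_for_pair(
                fc.values.loc[genes, s1], fc.values.loc[genes, s2], params.theta
            )
        self.divergence_consistent_ = intersect_gene_lists(self.divergent_lists_.values())

        # trend-consistent genes irrespective of intervention
        self.trend_consistent_ = consistent_trend_genes(
            fc.values[male_subjects], params.theta
        )

        # 3: relative-variance top-k per unit, intersected
        units: dict[str, list[str]] = {}
        if params.variance_unit == "pair":
            for pair, members in pairs.items():
                units[pair] = [
                    sample_of(male_sheet, s, tp) for s in members for tp in ("baseline", "post")
                ]
        else:
            for s in male_subjects:
                units[s] = [sample_of(male_sheet, s, tp) for tp in ("baseline", "post")]
        self.variance_lists_ = {
            unit: top_k_by_relative_variance(X.values, samples, params.top_k)
            for unit, samples in units.items()
        }
        self.variance_consistent_ = intersect_gene_lists(self.variance_lists_.values())

        # 4: final blinded gene set
        self.final_genes_ = final_blinded_gene_set(
            self.divergence_consistent_, self.variance_consistent_
        )

        # 5: cluster post samples on the divergence-consistent list and cut
        post_samples = {s: sample_of(male_sheet, s, "post") for s in male_subjects}
        gene_list = sorted(self.divergence_consistent_)
        if len(gene_list) < 3:
            gene_list = sorted(X.values.index)  # degenerate list: fall back to all genes
        sub = X.values.loc[gene_list, [post_samples[s] for s in male_subjects]]
        if params.log_distance:
            sub = np.log2(sub + params.epsilon)
        dist = pairwise_pearson_distance(sub)
        dist.index = dist.columns = pd.Index(male_subjects)
        self.distance_ = dist
        self.linkage_, self.leaf_labels_ = hierarchical_cluster(dist, params.linkage_method)
        prediction = predict_two_groups(dist, male_sheet, params.linkage_method)

        # 6: marker-based intervention call
        symbol_to_gene = None
        if catalog is not None:
            symbol_to_gene = catalog.set_index("symbol")["gene_id"].to_dict()
        self.prediction_ = predict_intervention(
            prediction, fc, params.markers, symbol_to_gene
        )
        return self

    def predict(self, X=None) -> GroupPrediction:
        if not hasattr(self, "prediction_"):
            raise ValidationError("BlindedAnalysis is not fitted")
        return self.prediction_
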