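"""Feature fusion and reduction: cascade fusion, OOB permutation importance, SFS.

Two fusion strategies are provided for combining the texton block X_MR and
the deep block X_CNN:

* **Direct (cascade) fusion** — plain concatenation,
  X_F = [X_MR, X_CNN], dim(X_F) = dim(X_MR) + dim(X_CNN).

* **Fusion after reduction** — each block is first reduced independently,
  then the reduced blocks are concatenated.  Reduction ranks features by
  random-forest out-of-bag (OOB) permutation importance

      D_i = (1/M) * sum_m ( A_m^oob - A_{m,i}^oob )

  where A_m^oob is tree m's accuracy on its out-of-bag rows and A_{m,i}^oob
  the same accuracy after permuting feature i's values *within those OOB
  rows* (a fresh seeded permutation per tree-feature pair).  Sequential
  forward selection (SFS) then walks the ranking in descending-importance
  order, keeping a candidate only if it improves mean stratified k-fold CV
  accuracy by at least a tolerance.

The per-tree OOB accuracies are retained on the result so D_i can be audited
exactly from first principles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .block import FeatureBlock
from .errors import AlignmentError, ConfigurationError, DegenerateLabelsError

__all__ = [
    "ImportanceRanking",
    "SelectionResult",
    "ReductionParams",
    "FusedSelection",
    "cascade_fuse",
    "oob_importance",
    "sfs_select",
    "fuse_after_reduction",
]


@dataclass
class ImportanceRanking:
    """Per-feature OOB permutation importances with their audit trail.

    ``importance[i]`` is D_i; ``ranking`` lists feature indices in descending
    D_i (ties broken by ascending index).  ``per_tree_acc[m]`` is A_m^oob and
    ``per_tree_perm_acc[m, i]`` is A_{m,i}^oob, so
    ``importance == (per_tree_acc[:, None] - per_tree_perm_acc).mean(axis=0)``
    holds exactly.
    """

    importance: np.ndarray
    ranking: np.ndarray
    m_trees: int
    per_tree_acc: np.ndarray
    per_tree_perm_acc: np.ndarray
    seed: int = 0

    @property
    def n_features(self) -> int:
        return self.importance.size

    def recompute_importance(self) -> np.ndarray:
        """D_i recomputed from the stored per-tree accuracies (audit path)."""
        return (self.per_tree_acc[:, None] - self.per_tree_perm_acc).mean(axis=0)


@dataclass
class SelectionResult:
    """Outcome of sequential forward selection along an importance ranking."""

    selected_indices: list[int]
    cv_curve: np.ndarray          # CV accuracy at each candidate considered
    considered: list[int]         # the ranked feature indices walked, in order
    seed: int = 0


@dataclass(frozen=True)
class ReductionParams:
    """Knobs of the fusion-after-reduction path (defaults favor stability)."""

    importance_trees: int = 500
    sfs_trees: int = 100
    k_folds: int = 5
    tolerance: float = 1e-4
    max_candidates: int | None = 50
    seed: int = 0


@dataclass
class FusedSelection:
    """Fused block plus the per-block reduction audit objects."""

    block: FeatureBlock
    rankings: dict = field(default_factory=dict)
    selections: dict = field(default_factory=dict)


def cascade_fuse(blocks: list[FeatureBlock], name: str = "fused") -> FeatureBlock:
    """Concatenate blocks column-wise in the given order, keeping provenance."""
    if not blocks:
        raise AlignmentError("cascade_fuse requires at least one block")
    if len(blocks) == 1:
        return blocks[0]
    n_rows = {b.n_images for b in blocks}
    if len(n_rows) != 1:
        raise AlignmentError(
            f"blocks disagree on image count: { {b.name: b.n_images for b in blocks} }")
    return FeatureBlock(
        name=name,
        values=np.hstack([b.values for b in blocks]),
        columns=[c for b in blocks for c in b.columns],
        provenance=[p for b in blocks for p in b.provenance],
    )


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("labels must contain two classes")
    return y


def oob_importance(X: np.ndarray, y, m_trees: int = 500, seed: int = 0,
                   max_features: str | int = "sqrt") -> ImportanceRanking:
    """OOB permutation importance of every feature over M bootstrap trees.

    Each tree is grown on a bootstrap sample of the rows (CART, per-split
    feature subsampling ``max_features``, unlimited depth); its OOB accuracy
    and, per feature, the OOB accuracy after permuting that feature's column
    within the OOB rows are recorded.  D_i is the mean accuracy drop.
    """
    X = np.asarray(X, dtype=np.float64)
    y = _check_labels(y)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise AlignmentError(f"X shape {X.shape} does not align with y ({y.size})")
    n, n_feat = X.shape
    if n_feat < 1:
        raise ConfigurationError("at least one feature is required")
    if m_trees < 1:
        raise ConfigurationError("m_trees must be >= 1")

    rng = np.random.default_rng(seed)
    per_tree_acc = np.empty(m_trees)
    per_tree_perm_acc = np.empty((m_trees, n_feat))

    for m in range(m_trees):
        # resample until the OOB set is non-empty (only matters at tiny n)
        while True:
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            if oob.size:
                break
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(2 ** 31)),
        ).fit(X[boot], y[boot])
        # float32 copy: lets tree.predict skip per-call input validation
        X_oob, y_oob = X[oob].astype(np.float32), y[oob]
        pred = tree.predict(X_oob, check_input=False)
        per_tree_acc[m] = np.mean(pred == y_oob)

        X_perm = X_oob.copy()
        for i in range(n_feat):
            saved = X_perm[:, i].copy()
            X_perm[:, i] = saved[rng.permutation(oob.size)]
            pred_i = tree.predict(X_perm, check_input=False)
            per_tree_perm_acc[m, i] = np.mean(pred_i == y_oob)
            X_perm[:, i] = saved

    importance = (per_tree_acc[:, None] - per_tree_perm_acc).mean(axis=0)
    # descending importance; stable sort breaks ties by ascending index
    ranking = np.argsort(-importance, kind="stable")
    return ImportanceRanking(importance=importance, ranking=ranking,
                             m_trees=m_trees, per_tree_acc=per_tree_acc,
                             per_tree_perm_acc=per_tree_perm_acc, seed=seed)


def _cv_accuracy(estimator, X: np.ndarray, y: np.ndarray,
                 k_folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        model = clone(estimator).fit(X[tr], y[tr])
        accs.append(np.mean(model.predict(X[te]) == y[te]))
    return float(np.mean(accs))


def sfs_select(ranking: ImportanceRanking, X, y, k_folds: int = 5,
               seed: int = 0, tolerance: float = 1e-4,
               estimator=None, max_candidates: int | None = None
               ) -> SelectionResult:
    """Sequential forward selection along the importance ranking.

    Candidates are tried in descending-importance order (optionally only the
    top ``max_candidates``).  The first candidate is always kept; each later
    one is kept iff it raises mean stratified k-fold CV accuracy by at least
    ``tolerance``.  The CV classifier defaults to a random forest.
    """
    X = np.asarray(X, dtype=np.float64)
    y = _check_labels(y)
    if ranking.n_features != X.shape[1]:
        raise AlignmentError("ranking does not match X's feature count")
    counts = np.bincount(np.unique(y, return_inverse=True)[1])
    if k_folds > counts.min():
        raise ConfigurationError(
            f"k_folds={k_folds} exceeds smallest class count {counts.min()}")
    if estimator is None:
        estimator = RandomForestClassifier(n_estimators=100, random_state=seed)

    candidates = list(ranking.ranking[:max_candidates]
                      if max_candidates else ranking.ranking)
    selected: list[int] = []
    curve = []
    best = -np.inf
    for feat in candidates:
        trial = selected + [int(feat)]
        acc = _cv_accuracy(estimator, X[:, trial], y, k_folds, seed)
        curve.append(acc)
        if not selected or acc >= best + tolerance:
            selected.append(int(feat))
            best = acc
    return SelectionResult(selected_indices=selected,
                           cv_curve=np.asarray(curve),
                           considered=[int(f) for f in candidates], seed=seed)


def fuse_after_reduction(texton_block: FeatureBlock, deep_block: FeatureBlock,
                         y, params: ReductionParams | None = None
                         ) -> FusedSelection:
    """Reduce each block independently (OOB importance + SFS), then fuse.

    Column provenance in the fused block records which source block each kept
    feature came from.  If one block ends up contributing nothing (possible
    only for a zero-width block), the other is returned with a warning.
    """
    params = params or ReductionParams()
    y = _check_labels(y)
    reduced: list[FeatureBlock] = []
    out = FusedSelection(block=None)  # type: ignore[arg-type]
    for offset, blk in enumerate((texton_block, deep_block)):
        if blk.length == 0:
            warnings.warn(f"block {blk.name!r} is empty; fusion degenerates "
                          "to the other block", stacklevel=2)
            out.selections[blk.name] = SelectionResult([], np.empty(0), [], params.seed)
            continue
        sub_seed = (params.seed * 2 + offset) % (2 ** 31)
        rank = oob_importance(blk.values, y, m_trees=params.importance_trees,
                              seed=sub_seed)
        sel = sfs_select(rank, blk.values, y, k_folds=params.k_folds,
                         seed=sub_seed, tolerance=params.tolerance,
                         estimator=RandomForestClassifier(
                             n_estimators=params.sfs_trees, random_state=sub_seed),
                         max_candidates=params.max_candidates)
        out.rankings[blk.name] = rank
        out.selections[blk.name] = sel
        reduced.append(blk.subset(sel.selected_indices))
    if not reduced:
        raise ConfigurationError("both blocks are empty; nothing to fuse")
    out.block = cascade_fuse(reduced, name="fused") if len(reduced) > 1 else reduced[0]
    return out
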