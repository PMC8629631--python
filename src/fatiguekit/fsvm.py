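"""Fast SVM via kernel-space distance pre-selection of candidate support vectors.

For a soft-margin kernel SVM the support vectors lie on the margin between the
two classes.  In the kernel feature space the distance between two points is

    d(x_i, x_j) = sqrt(K(x_i,x_i) - 2 K(x_i,x_j) + K(x_j,x_j))
                = sqrt(2 - 2 K(x_i,x_j))          (unit-diagonal kernels)

Boundary-like points are those whose mean kernel distance to their OWN class
is large while their mean distance to the OPPOSITE class is small.  Given a
ratio r in (0, 1], each class keeps the intersection of

  * the top ceil(l_c * r) points ranked by same-class mean distance
    (descending), and
  * the top ceil(l_c * r) points ranked by opposite-class mean distance
    (ascending),

and the union of the two per-class sets, T_BD, is handed to a standard
soft-margin SVM solver.  Because each per-class set is an intersection of two
size-ceil(l_c * r) sets, |T_BD| <= ceil(l+ * r) + ceil(l- * r): the solver
sees a reduced training set, cutting training time while the boundary
geometry — hence the learned decision function — is largely preserved.

Class convention: label 1 (fatigue) is the positive class G+, label 0 (awake)
the negative class G-.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics.pairwise import linear_kernel, rbf_kernel
from sklearn.svm import SVC

from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

POSITIVE_LABEL = 1  # fatigue
NEGATIVE_LABEL = 0  # awake


@dataclass
class LabeledDataset:
    """Feature matrix with binary labels {0 awake, 1 fatigue}."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise DataError("X must be 2-D (n_samples, n_features)")
        if self.y.shape != (self.X.shape[0],):
            raise DataError("y length must match number of rows of X")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise DataError("labels must be binary {0, 1}")

    @property
    def idx_pos(self) -> np.ndarray:
        """Original indices of the positive (fatigue) class I+."""
        return np.flatnonzero(self.y == POSITIVE_LABEL)

    @property
    def idx_neg(self) -> np.ndarray:
        return np.flatnonzero(self.y == NEGATIVE_LABEL)

    @property
    def l_pos(self) -> int:
        return int((self.y == POSITIVE_LABEL).sum())

    @property
    def l_neg(self) -> int:
        return int((self.y == NEGATIVE_LABEL).sum())

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel used both for distance statistics and the SVM itself.

    The default is the radial basis function kernel with gamma = 0.001,
    K(x, y) = exp(-gamma * ||x - y||^2).
    """

    kind: str = "rbf"
    gamma: float = 0.001

    def __post_init__(self) -> None:
        if self.kind not in ("rbf", "linear"):
            raise ConfigError(f"unsupported kernel {self.kind!r}")
        if self.kind == "rbf" and self.gamma <= 0:
            raise ConfigError("gamma must be positive")

    def gram(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        A = np.atleast_2d(np.asarray(A, dtype=float))
        B = np.atleast_2d(np.asarray(B, dtype=float))
        if self.kind == "rbf":
            return rbf_kernel(A, B, gamma=self.gamma)
        return linear_kernel(A, B)


@dataclass
class DistanceMatrix:
    """Pairwise kernel-space distances in positives-first ordering.

    ``order`` maps row/column position to the original dataset index; the
    first ``l_pos`` positions are the positive class, so the four class
    blocks D11 (+/+), D12 (+/-), D21 (-/+), D22 (-/-) are contiguous views.
    """

    D: np.ndarray
    order: np.ndarray
    l_pos: int
    l_neg: int

    @property
    def D11(self) -> np.ndarray:
        return self.D[: self.l_pos, : self.l_pos]

    @property
    def D12(self) -> np.ndarray:
        return self.D[: self.l_pos, self.l_pos :]

    @property
    def D21(self) -> np.ndarray:
        return self.D[self.l_pos :, : self.l_pos]

    @property
    def D22(self) -> np.ndarray:
        return self.D[self.l_pos :, self.l_pos :]


@dataclass
class MeanDistanceTable:
    """Per-point mean distances (d_k^+, d_k^-) to each class.

    V11/V22 are the same-class means of the positive/negative points;
    V12/V21 are their opposite-class means.  Self-distance (zero) is included
    in the same-class mean, i.e. the mean runs over all l_c class members.
    """

    V11: np.ndarray  # positives: mean distance to positives
    V12: np.ndarray  # positives: mean distance to negatives
    V21: np.ndarray  # negatives: mean distance to positives
    V22: np.ndarray  # negatives: mean distance to negatives
    pos_index: np.ndarray  # original indices of positives, aligned with V11/V12
    neg_index: np.ndarray


@dataclass
class SelectionResult:
    """Reduced training set T_BD = T+ ∪ T- with the rank thresholds used."""

    selected_pos: np.ndarray  # original indices, T+
    selected_neg: np.ndarray  # original indices, T-
    r: float
    c1_pos: float  # same-class mean at the rank cutoff, positive class
    c2_pos: float  # opposite-class mean at the rank cutoff, positive class
    c1_neg: float
    c2_neg: float
    fallback_pos: bool = False
    fallback_neg: bool = False

    @property
    def selected(self) -> np.ndarray:
        """T_BD as sorted original indices."""
        return np.sort(np.concatenate([self.selected_pos, self.selected_neg]))

    @property
    def n_selected(self) -> int:
        return self.selected_pos.size + self.selected_neg.size


def kernel_distance(x_i: np.ndarray, x_j: np.ndarray, kernel: KernelSpec) -> float:
    """Distance between two points in the kernel feature space.

    sqrt(K(x_i,x_i) - 2 K(x_i,x_j) + K(x_j,x_j)); for unit-diagonal kernels
    this is sqrt(2 - 2 K(x_i,x_j)).  A negative radicand from numerical error
    is clamped to zero.
    """
    x_i = np.atleast_2d(np.asarray(x_i, dtype=float))
    x_j = np.atleast_2d(np.asarray(x_j, dtype=float))
    if x_i.shape[1] != x_j.shape[1]:
        raise DataError("points must have equal dimension")
    kii = float(kernel.gram(x_i, x_i)[0, 0])
    kjj = float(kernel.gram(x_j, x_j)[0, 0])
    kij = float(kernel.gram(x_i, x_j)[0, 0])
    rad = kii - 2.0 * kij + kjj
    if rad < 0:
        if rad < -1e-9:
            log.warning("negative squared kernel distance %.3g clamped to 0", rad)
        rad = 0.0
    return math.sqrt(rad)


def pairwise_distance_matrix(ds: LabeledDataset, kernel: KernelSpec) -> DistanceMatrix:
    """Kernel-space distance matrix with positives-first block ordering."""
    if len(ds) < 2:
        raise DataError("need at least 2 points")
    order = np.concatenate([ds.idx_pos, ds.idx_neg])
    Xo = ds.X[order]
    K = kernel.gram(Xo, Xo)
    diag = np.diag(K)
    sq = diag[:, None] - 2.0 * K + diag[None, :]
    np.maximum(sq, 0.0, out=sq)
    D = np.sqrt(sq)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D=D, order=order, l_pos=ds.l_pos, l_neg=ds.l_neg)


def mean_distance_table(D: DistanceMatrix) -> MeanDistanceTable:
    """Per-point class-mean distances: V11 = D11·I_{l+}, V12 = D12·I_{l-}, etc.

    The self term (zero) is included in the same-class mean, so each mean is
    over the full class size.
    """
    if D.l_pos == 0 or D.l_neg == 0:
        raise DataError("both classes must be non-empty")
    return MeanDistanceTable(
        V11=D.D11.mean(axis=1),
        V12=D.D12.mean(axis=1),
        V21=D.D21.mean(axis=1),
        V22=D.D22.mean(axis=1),
        pos_index=D.order[: D.l_pos],
        neg_index=D.order[D.l_pos :],
    )


def _top_by(values: np.ndarray, n: int, descending: bool) -> np.ndarray:
    """Positions of the top-n values; ties broken by ascending position."""
    key = -values if descending else values
    order = np.lexsort((np.arange(values.size), key))
    return order[:n]


def select_candidates(
    V: MeanDistanceTable, r: float
) -> SelectionResult:
    """Pick likely support vectors per class at ratio ``r``.

    Per class c with l_c members, rank by same-class mean descending and by
    opposite-class mean ascending; keep the intersection of the two
    top-ceil(l_c * r) sets.  If the intersection is empty, fall back to the
    top-ceil(l_c * r) points by ascending opposite-class mean — proximity to
    the other class is the stronger boundary signal — so the result is never
    empty.
    """
    if not (0.0 < r <= 1.0):
        raise ConfigError(f"ratio r must be in (0, 1], got {r}")

    def _select(same: np.ndarray, opp: np.ndarray, index: np.ndarray):
        n = math.ceil(same.size * r)
        top_same = _top_by(same, n, descending=True)
        top_opp = _top_by(opp, n, descending=False)
        c1 = float(same[top_same[-1]])
        c2 = float(opp[top_opp[-1]])
        chosen = np.intersect1d(top_same, top_opp)
        fallback = chosen.size == 0
        if fallback:
            chosen = np.sort(top_opp)
        return np.sort(index[chosen]), c1, c2, fallback

    sel_pos, c1p, c2p, fb_p = _select(V.V11, V.V12, V.pos_index)
    sel_neg, c1n, c2n, fb_n = _select(V.V22, V.V21, V.neg_index)
    if fb_p or fb_n:
        log.info("empty ranking intersection; fell back to opposite-class ranking")
    return SelectionResult(
        selected_pos=sel_pos,
        selected_neg=sel_neg,
        r=r,
        c1_pos=c1p,
        c2_pos=c2p,
        c1_neg=c1n,
        c2_neg=c2n,
        fallback_pos=fb_p,
        fallback_neg=fb_n,
    )


def select_training_set(
    ds: LabeledDataset, kernel: KernelSpec, r: float
) -> SelectionResult:
    """Distance matrix → mean table → ratio-r selection, in one call."""
    D = pairwise_distance_matrix(ds, kernel)
    V = mean_distance_table(D)
    return select_candidates(V, r)


@dataclass
class TrainedModel:
    """A trained soft-margin kernel SVM plus selection provenance.

    The decision function is evaluated from the stored support vectors, dual
    coefficients and bias — f(x) = sum_i alpha_i y_i K(x_i, x) + b — so a
    serialized model reproduces predictions without the original solver
    object.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray  # alpha_i * y_i, shape (n_sv,)
    intercept: float
    kernel: KernelSpec
    C: float
    r: float = 1.0
    n_selected: int | None = None
    selected_indices: np.ndarray | None = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.support_vectors.shape[1]:
            raise DataError(
                f"expected {self.support_vectors.shape[1]} features, got {X.shape[1]}"
            )
        K = self.kernel.gram(X, self.support_vectors)
        return K @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels in {0 awake, 1 fatigue}: sign of the decision function."""
        return (self.decision_function(X) > 0).astype(int)

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "kernel": {"kind": self.kernel.kind, "gamma": self.kernel.gamma},
            "C": self.C,
            "r": self.r,
            "n_selected": self.n_selected,
            "selected_indices": None
            if self.selected_indices is None
            else self.selected_indices.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TrainedModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        obj = json.loads(text)
        return cls(
            support_vectors=np.asarray(obj["support_vectors"], dtype=float),
            dual_coef=np.asarray(obj["dual_coef"], dtype=float),
            intercept=float(obj["intercept"]),
            kernel=KernelSpec(**obj["kernel"]),
            C=float(obj["C"]),
            r=float(obj["r"]),
            n_selected=obj.get("n_selected"),
            selected_indices=None
            if obj.get("selected_indices") is None
            else np.asarray(obj["selected_indices"], dtype=int),
        )


def _fit_svc(X: np.ndarray, y: np.ndarray, kernel: KernelSpec, C: float) -> SVC:
    if kernel.kind == "rbf":
        svc = SVC(kernel="rbf", gamma=kernel.gamma, C=C)
    else:
        svc = SVC(kernel="linear", C=C)
    svc.fit(X, y)
    return svc


def _wrap_svc(
    svc: SVC, kernel: KernelSpec, C: float, r: float, sel: SelectionResult | None
) -> TrainedModel:
    # sklearn's dual_coef_ is alpha_i * y_i for classes_ = [0, 1] with 1 positive
    return TrainedModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        kernel=kernel,
        C=C,
        r=r,
        n_selected=None if sel is None else sel.n_selected,
        selected_indices=None if sel is None else sel.selected,
    )


def train_svm(
    ds: LabeledDataset, kernel: KernelSpec = KernelSpec(), C: float = 1.0
) -> TrainedModel:
    """Plain soft-margin kernel SVM on the full training set (the baseline)."""
    if ds.l_pos == 0 or ds.l_neg == 0:
        raise DataError("training set must contain both classes")
    if C <= 0:
        raise ConfigError("C must be positive")
    svc = _fit_svc(ds.X, ds.y, kernel, C)
    return _wrap_svc(svc, kernel, C, r=1.0, sel=None)


def train_fsvm(
    ds: LabeledDataset,
    kernel: KernelSpec = KernelSpec(),
    r: float = 0.5,
    C: float = 1.0,
) -> TrainedModel:
    """Select candidate support vectors at ratio ``r``, then train the SVM on them.

    At r = 1 the selection keeps every point and the model coincides with the
    plain SVM.  The set handed to the solver has at most
    ceil(l+ * r) + ceil(l- * r) points.
    """
    if ds.l_pos == 0 or ds.l_neg == 0:
        raise DataError("training set must contain both classes")
    if C <= 0:
        raise ConfigError("C must be positive")
    sel = select_training_set(ds, kernel, r)
    idx = sel.selected
    y_red = ds.y[idx]
    if len(set(y_red.tolist())) < 2:
        raise DataError("reduced training set lost a class; increase r")
    svc = _fit_svc(ds.X[idx], y_red, kernel, C)
    return _wrap_svc(svc, kernel, C, r=r, sel=sel)


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Module-level alias for :meth:`TrainedModel.predict`."""
    return model.predict(X)
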