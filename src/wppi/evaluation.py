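"""Scoring of predicted complex sets against a reference catalogue.

All measures are driven by the n x m overlap table ``T[i, j] = |R_i & P_j|``
between the ``n`` benchmark complexes R and the ``m`` predictions P, and by
two derived similarity tables:

* neighborhood affinity ``NA[i, j] = T[i, j]^2 / (|R_i| |P_j|)``
* Jaccard            ``J[i, j] = T[i, j] / |R_i U P_j|``

Battery:

* SN / PPV / ACC — protein-level sensitivity, positive predictive value and
  their geometric mean.
* precision / recall / f-measure — complex-level, a pair matches when its
  Jaccard similarity exceeds 0.5 (strictly).
* precision+ / recall+ / f-measure+ — same shape, a pair matches when its
  neighborhood affinity reaches the threshold ``t`` (default 0.2, inclusive).
* MMR — maximum matching ratio: total affinity of an optimal one-to-one
  benchmark-prediction assignment, divided by n.
* FRM — fraction of benchmark complexes with a prediction at NA >= 0.25.
* SEP — separation: geometric mean of complex-wise and cluster-wise averages
  of the row/column co-normalized overlap products.
* composites F_MMR = MMR + f-measure+ and CS = MMR + FRM + SEP + ACC + f.

Every ratio with a zero denominator is defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .io import ComplexSet

__all__ = [
    "MatchMatrix",
    "MetricReport",
    "build_match_matrix",
    "sn_ppv_acc",
    "jaccard_prf",
    "plus_prf",
    "mmr",
    "frm",
    "sep",
    "score_all",
]

FRM_THRESHOLD = 0.25


@dataclass(frozen=True)
class MatchMatrix:
    """Overlap counts and derived similarity tables between R (rows) and P (cols)."""

    T: np.ndarray  # (n, m) int
    NA: np.ndarray  # (n, m) float
    J: np.ndarray  # (n, m) float
    r_sizes: np.ndarray  # (n,) int
    p_sizes: np.ndarray  # (m,) int

    @property
    def n(self) -> int:
        return self.T.shape[0]

    @property
    def m(self) -> int:
        return self.T.shape[1]


@dataclass(frozen=True)
class MetricReport:
    sn: float
    ppv: float
    acc: float
    sep: float
    frm: float
    mmr: float
    precision: float
    recall: float
    f_measure: float
    precision_plus: float
    recall_plus: float
    f_measure_plus: float
    f_mmr: float
    cs: float
    t: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def build_match_matrix(R: ComplexSet, P: ComplexSet) -> MatchMatrix:
    """Exact overlap counts T plus the derived NA and Jaccard tables."""
    if len(R) == 0 or len(P) == 0:
        raise ValidationError("both complex sets must be non-empty to score")
    n, m = len(R), len(P)
    T = np.zeros((n, m), dtype=np.int64)
    for i, r in enumerate(R):
        for j, p in enumerate(P):
            T[i, j] = len(r & p)
    r_sizes = np.array([len(r) for r in R], dtype=np.int64)
    p_sizes = np.array([len(p) for p in P], dtype=np.int64)
    NA = T.astype(float) ** 2 / np.outer(r_sizes, p_sizes)
    union = r_sizes[:, None] + p_sizes[None, :] - T
    J = np.divide(T, union, out=np.zeros_like(NA), where=union > 0)
    return MatchMatrix(T=T, NA=NA, J=J, r_sizes=r_sizes, p_sizes=p_sizes)


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def sn_ppv_acc(mm: MatchMatrix) -> tuple[float, float, float]:
    """Protein-level sensitivity, positive predictive value, and accuracy.

    SN  = sum_i max_j T_ij / sum_i |R_i|
    PPV = sum_j max_i T_ij / sum_j sum_i T_ij   (0 when the table is empty)
    ACC = sqrt(SN * PPV)
    """
    sn = float(mm.T.max(axis=1).sum() / mm.r_sizes.sum())
    total = mm.T.sum()
    ppv = float(mm.T.max(axis=0).sum() / total) if total > 0 else 0.0
    return sn, ppv, float(np.sqrt(sn * ppv))


def jaccard_prf(mm: MatchMatrix) -> tuple[float, float, float]:
    """Complex-level precision/recall/F1 with a strict Jaccard > 0.5 match."""
    hit = mm.J > 0.5
    precision = float(hit.any(axis=0).sum() / mm.m)
    recall = float(hit.any(axis=1).sum() / mm.n)
    return precision, recall, _f1(precision, recall)


def plus_prf(mm: MatchMatrix, t: float = 0.2) -> tuple[float, float, float]:
    """Precision+/recall+/f-measure+ with an inclusive NA >= t match."""
    if not (0.0 < t <= 1.0):
        raise ValidationError(f"threshold t must be in (0, 1], got {t}")
    hit = mm.NA >= t
    precision = float(hit.any(axis=0).sum() / mm.m)
    recall = float(hit.any(axis=1).sum() / mm.n)
    return precision, recall, _f1(precision, recall)


def mmr(mm: MatchMatrix) -> float:
    """Maximum matching ratio: optimal one-to-one NA assignment weight over n.

    Solved exactly as a rectangular linear assignment problem on the NA
    table (each benchmark complex pairs with at most one prediction).
    """
    rows, cols = linear_sum_assignment(mm.NA, maximize=True)
    return float(mm.NA[rows, cols].sum() / mm.n)


def frm(mm: MatchMatrix, threshold: float = FRM_THRESHOLD) -> float:
    """Fraction of benchmark complexes matched by some prediction at NA >= threshold."""
    return float((mm.NA.max(axis=1) >= threshold).sum() / mm.n)


def sep(mm: MatchMatrix) -> float:
    """Separation score.

    Each overlap is co-normalized by its row and column sums,
    ``sep_ij = (T_ij / sum_j' T_ij') * (T_ij / sum_i' T_i'j)``, with 0 for
    zero denominators.  The grand total averaged per benchmark complex
    (complex-wise) and per prediction (cluster-wise) is combined by a
    geometric mean.
    """
    T = mm.T.astype(float)
    row = T.sum(axis=1, keepdims=True)
    col = T.sum(axis=0, keepdims=True)
    fr = np.divide(T, row, out=np.zeros_like(T), where=row > 0)
    fc = np.divide(T, col, out=np.zeros_like(T), where=col > 0)
    total = float((fr * fc).sum())
    return float(np.sqrt((total / mm.n) * (total / mm.m)))


def score_all(R: ComplexSet, P: ComplexSet, t: float = 0.2) -> MetricReport:
    """Compute the full metric battery for predictions P against benchmark R."""
    mm = build_match_matrix(R, P)
    sn, ppv, acc = sn_ppv_acc(mm)
    precision, recall, f_measure = jaccard_prf(mm)
    precision_plus, recall_plus, f_plus = plus_prf(mm, t)
    mmr_v = mmr(mm)
    frm_v = frm(mm)
    sep_v = sep(mm)
    return MetricReport(
        sn=sn,
        ppv=ppv,
        acc=acc,
        sep=sep_v,
        frm=frm_v,
        mmr=mmr_v,
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        precision_plus=precision_plus,
        recall_plus=recall_plus,
        f_measure_plus=f_plus,
        f_mmr=mmr_v + f_plus,
        cs=mmr_v + frm_v + sep_v + acc + f_measure,
        t=t,
    )
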