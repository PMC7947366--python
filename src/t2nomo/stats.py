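"""Cutoff selection, dichotomisation, univariate tests and reader agreement.

The analysis treats each orbit as an independent unit. For every histogram
feature the workflow is: rank AUC with a DeLong confidence interval ->
Youden-index cutoff (J = sensitivity + specificity - 1, maximised over an
exhaustive threshold scan) -> dichotomised flag -> Pearson chi-square
association with the therapy-response label. Inter-reader agreement uses
the two-way random-effects, absolute-agreement, single-measure intraclass
correlation coefficient, ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (DegenerateLabelsError, DegenerateTableError,
                     IncompleteDesignError, SchemaError)

__all__ = [
    "AucResult",
    "CutoffResult",
    "ContingencyTable2x2",
    "roc_auc",
    "youden_cutoff",
    "youden_index",
    "dichotomize",
    "chi_square_2x2",
    "table_from_flags",
    "icc_agreement",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    if y.min() == y.max():
        raise DegenerateLabelsError("both outcome classes must be present")
    return y


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties."""
    r = sps.rankdata(scores)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_lower: float
    ci_upper: float
    se: float
    p_value: float  # DeLong z-test of AUC = 0.5


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> AucResult:
    """Rank (Mann-Whitney) AUC with a DeLong 95% confidence interval.

    The variance is DeLong's, from the empirical placement values of the
    positive and negative score sets; the p-value tests AUC = 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    # placements: fraction of the other class each observation beats
    cmp_ = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_.mean(axis=1)          # per-positive placement
    v01 = cmp_.mean(axis=0)          # per-negative placement
    auc = float(cmp_.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    half = 1.959963984540054 * se
    if se > 0:
        p = float(2 * sps.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return AucResult(auc, max(0.0, auc - half), min(1.0, auc + half), se, p)


def youden_index(sensitivity_pct: float, specificity_pct: float) -> float:
    """J = (sensitivity + specificity)/100 - 1, reported to 3 decimals."""
    for v in (sensitivity_pct, specificity_pct):
        if not (0.0 <= v <= 100.0):
            raise ValueError("sensitivity/specificity must lie in [0, 100]")
    return round((sensitivity_pct + specificity_pct) / 100.0 - 1.0, 3)


@dataclass(frozen=True)
class CutoffResult:
    """A Youden-optimal dichotomisation of one continuous feature."""

    feature: str
    auc: float
    auc_ci: tuple[float, float]
    auc_p: float
    cutoff: float
    direction: str        # "greater": positive iff value > cutoff;
                          # "less_equal": positive iff value <= cutoff
    sensitivity: float    # percent
    specificity: float    # percent
    youden: float

    def flag(self, values: Sequence[float]) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.direction == "greater":
            return (v > self.cutoff).astype(int)
        return (v <= self.cutoff).astype(int)


def youden_cutoff(scores: Sequence[float], labels: Sequence[int],
                  feature: str = "") -> CutoffResult:
    """Exhaustive Youden-index cutoff scan.

    Candidate thresholds are the midpoints between adjacent distinct score
    values (plus sentinels outside the range). Both orientations are
    scanned; the returned direction puts the responder-enriched side on
    the positive class. Ties go to the smallest cutoff, then to the
    ``greater`` direction.
    """
    s = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    aucres = roc_auc(s, y)

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate(([uniq[0] - 1.0], mids))
    n1 = int(y.sum())
    n0 = len(y) - n1
    # orientation "greater": positive prediction iff score > t
    tp = ((s[None, :] > cands[:, None]) & (y == 1)).sum(axis=1)
    fp = ((s[None, :] > cands[:, None]) & (y == 0)).sum(axis=1)
    sens_g = 100.0 * tp / n1
    spec_g = 100.0 * (n0 - fp) / n0
    j_g = (sens_g + spec_g) / 100.0 - 1.0

    best = None  # (J, cutoff, direction, sens, spec)
    for i, t in enumerate(cands):
        for direction, j, se, sp in (("greater", j_g[i], sens_g[i], spec_g[i]),
                                     ("less_equal", -j_g[i],
                                      100.0 - sens_g[i], 100.0 - spec_g[i])):
            if best is None or j > best[0] + 1e-12:
                best = (j, t, direction, se, sp)
    j, t, direction, se, sp = best
    return CutoffResult(feature=feature, auc=aucres.auc,
                        auc_ci=(aucres.ci_lower, aucres.ci_upper),
                        auc_p=aucres.p_value, cutoff=float(t),
                        direction=direction, sensitivity=float(se),
                        specificity=float(sp),
                        youden=youden_index(float(se), float(sp)))


def dichotomize(features: pd.DataFrame,
                cutoffs: Mapping[str, CutoffResult] | Sequence[CutoffResult]
                ) -> pd.DataFrame:
    """Binary flag table from per-feature Youden cutoffs.

    Boundary semantics are strict: ``greater`` means value > cutoff -> 1,
    ``less_equal`` means value <= cutoff -> 1.
    """
    if not isinstance(cutoffs, Mapping):
        cutoffs = {c.feature: c for c in cutoffs}
    missing = [c for c in features.columns if c not in cutoffs]
    if missing:
        raise SchemaError(f"no cutoff configured for feature(s) {missing}")
    out = pd.DataFrame(index=features.index)
    for col in features.columns:
        out[col] = cutoffs[col].flag(features[col].to_numpy())
    return out


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = flag category (1 then 0), columns =
    (responsive, unresponsive)."""

    a: int  # flag=1, responsive
    b: int  # flag=1, unresponsive
    c: int  # flag=0, responsive
    d: int  # flag=0, unresponsive

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def row_percentages(self) -> np.ndarray:
        """Row-wise percentages (each row sums to 100)."""
        arr = self.to_array()
        tot = arr.sum(axis=1, keepdims=True)
        if np.any(tot == 0):
            raise DegenerateTableError("zero row margin")
        return 100.0 * arr / tot


def table_from_flags(flags: Sequence[int],
                     labels: Sequence[int]) -> ContingencyTable2x2:
    """Cross-tabulate a binary flag against the response label (1=responsive)."""
    f = np.asarray(flags).astype(int)
    y = np.asarray(labels).astype(int)
    if f.shape != y.shape:
        raise ValueError("flags and labels must align")
    return ContingencyTable2x2(
        a=int(((f == 1) & (y == 1)).sum()), b=int(((f == 1) & (y == 0)).sum()),
        c=int(((f == 0) & (y == 1)).sum()), d=int(((f == 0) & (y == 0)).sum()))


def chi_square_2x2(table: ContingencyTable2x2,
                   yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square with 1 df (uncorrected by default)."""
    arr = table.to_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DegenerateTableError("a zero margin leaves chi-square undefined")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=yates)
    return float(stat), float(p)


def icc_agreement(ratings: np.ndarray | pd.DataFrame,
                  form: str = "icc2") -> float:
    """Intraclass correlation of a subjects x raters matrix.

    Default form is ICC(2,1): two-way random effects, absolute agreement,
    single measure. ``form`` may also be ``"icc3"`` (two-way mixed,
    consistency).
    """
    import pingouin as pg  # deferred: slow import

    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix "
                         "with >= 2 raters")
    if m.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if np.any(~np.isfinite(m)):
        raise IncompleteDesignError("missing cells in the ratings matrix")
    n_subj, n_rat = m.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_subj), n_rat),
        "rater": np.tile(np.arange(n_rat), n_subj),
        "score": m.ravel(),
    })
    icc = pg.intraclass_corr(long, targets="subject", raters="rater",
                             ratings="score").set_index("Type")
    # pingouin labels vary across versions: ICC2 == ICC(A,1), ICC3 == ICC(C,1)
    keys = {"icc2": ("ICC2", "ICC(A,1)"), "icc3": ("ICC3", "ICC(C,1)")}
    if form.lower() not in keys:
        raise ValueError(f"unknown ICC form {form!r}")
    for key in keys[form.lower()]:
        if key in icc.index:
            return float(icc.loc[key, "ICC"])
    raise RuntimeError("unrecognised pingouin ICC output")
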