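"""Eyelid grading scales and inter-grader agreement.

Two 4-grade scales over the dropout-area percentage are provided:

* the legacy Meiboscore — grade 0 only for DOA = 0, then (0, 32],
  (32, 65], (65, 100] for grades 1-3; and
* an objective scale with limits derived by minimal-intraclass-variance
  clustering (multi-level Otsu) of measured DOA values — the published
  device calibration being [0, 16), [16, 32], (32, 59], (59, 100].

Agreement between graders is quantified with unweighted Cohen's kappa
and the conventional Landis-Koch verbal bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import DegenerateDataError, EmptyTableError, OutOfRangeError


@dataclass
class GradingScale:
    """An ordered DOA partition of [0, 100] into grades 0..n.

    ``boundaries`` are the interior cut points; ``upper_inclusive[i]``
    says whether DOA equal to ``boundaries[i]`` belongs to grade ``i``
    (True) or grade ``i + 1`` (False).
    """

    name: str
    boundaries: tuple[float, ...]
    upper_inclusive: tuple[bool, ...]

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if any(not 0.0 < x < 100.0 for x in b):
            raise ValueError("scale boundaries must lie strictly inside (0, 100)")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("scale boundaries must be strictly increasing")
        if len(self.upper_inclusive) != len(b):
            raise ValueError("one inclusivity flag per boundary required")
        self.boundaries = b
        self.upper_inclusive = tuple(bool(f) for f in self.upper_inclusive)

    @property
    def n_grades(self) -> int:
        return len(self.boundaries) + 1

    def to_dict(self) -> dict:
        return {"name": self.name, "boundaries": list(self.boundaries),
                "upper_inclusive": list(self.upper_inclusive)}


#: Legacy subjective scale: grade 0 requires a completely gland-covered
#: tarsus (DOA exactly 0); the zero boundary is handled in :func:`grade`.
MEIBOSCORE = GradingScale("meiboscore", (32.0, 65.0), (True, True))

#: Objective scale fitted on the device cohort by multi-level Otsu.
OBJECTIVE = GradingScale("objective", (16.0, 32.0, 59.0), (False, True, True))


def grade(doa_percent: float, scale: GradingScale = OBJECTIVE) -> int:
    """Grade a DOA percentage on a scale; monotone nondecreasing in DOA."""
    d = float(doa_percent)
    if not 0.0 <= d <= 100.0:
        raise OutOfRangeError(f"DOA {d} outside [0, 100]")
    g = 0
    for b, inclusive in zip(scale.boundaries, scale.upper_inclusive):
        if d > b or (d == b and not inclusive):
            g += 1
    if scale.name == "meiboscore":
        # Meiboscore reserves grade 0 for DOA exactly 0; any dropout at
        # all is at least grade 1
        return 0 if d == 0.0 else g + 1
    return g


def otsu_class_limits(doa_values, n_classes: int = 4,
                      n_bins: int = 101) -> GradingScale:
    """Fit class limits minimizing total within-class variance.

    DOA percentages are histogrammed on a 1-percentage-point grid
    (``n_bins`` bins over [0, 100]) and every combination of
    ``n_classes - 1`` thresholds is searched exhaustively — exact
    multi-level Otsu rather than a recursive approximation.  Returned
    boundaries use upper-inclusive intervals.
    """
    values = np.asarray(list(doa_values), dtype=float)
    if values.size == 0 or np.unique(values).size < n_classes:
        raise DegenerateDataError(
            f"need at least {n_classes} distinct values to fit {n_classes} classes")
    if np.any((values < 0) | (values > 100)):
        raise OutOfRangeError("DOA values outside [0, 100]")

    edges = np.linspace(0.0, 100.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts, _ = np.histogram(values, bins=edges)

    # prefix sums give O(1) within-class variance per candidate class
    c = np.concatenate([[0.0], np.cumsum(counts)])
    cv = np.concatenate([[0.0], np.cumsum(counts * centers)])
    cv2 = np.concatenate([[0.0], np.cumsum(counts * centers**2)])

    def within(lo: int, hi: int) -> float:
        """Sum of squared deviations for bins [lo, hi)."""
        n = c[hi] - c[lo]
        if n <= 0:
            return 0.0
        s, s2 = cv[hi] - cv[lo], cv2[hi] - cv2[lo]
        return s2 - s * s / n

    occupied = np.nonzero(counts)[0]
    cut_candidates = [i for i in range(occupied[0] + 1, occupied[-1] + 1)]
    best_cuts, best_score = None, np.inf
    for cuts in combinations(cut_candidates, n_classes - 1):
        idx = (0, *cuts, n_bins)
        score = sum(within(idx[k], idx[k + 1]) for k in range(n_classes))
        if score < best_score - 1e-12:
            best_score, best_cuts = score, cuts
    if best_cuts is None:
        raise DegenerateDataError("no admissible threshold combination")

    boundaries = tuple(float(edges[i]) for i in best_cuts)
    return GradingScale("otsu-fit", boundaries, (False,) * len(boundaries))


@dataclass
class KappaResult:
    """Cohen's kappa with chance-corrected agreement components."""

    kappa: float
    observed_agreement: float
    expected_agreement: float
    category: str

    def to_dict(self) -> dict:
        return {"kappa": self.kappa,
                "observed_agreement": self.observed_agreement,
                "expected_agreement": self.expected_agreement,
                "category": self.category}


def landis_koch_category(kappa: float) -> str:
    """Conventional verbal interpretation bands for kappa."""
    if kappa <= 0:
        return "poor"
    for limit, name in ((0.2, "slight"), (0.4, "fair"), (0.6, "moderate"),
                        (0.8, "substantial")):
        if kappa <= limit:
            return name
    return "almost perfect"


def cohen_kappa(confusion: np.ndarray) -> KappaResult:
    """Unweighted Cohen's kappa from a k x k confusion count table.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement ``p_o``
    (diagonal mass) and chance agreement ``p_e`` (product of marginals).
    """
    table = np.asarray(confusion, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("confusion table must be square")
    if np.any(table < 0):
        raise ValueError("confusion counts must be nonnegative")
    total = table.sum()
    if total <= 0:
        raise EmptyTableError("confusion table has no observations")
    p_o = np.trace(table) / total
    p_e = float((table.sum(axis=1) * table.sum(axis=0)).sum()) / total**2
    kappa = 1.0 if p_e >= 1.0 else (p_o - p_e) / (1.0 - p_e)
    return KappaResult(kappa=float(kappa), observed_agreement=float(p_o),
                       expected_agreement=float(p_e),
                       category=landis_koch_category(float(kappa)))


def kappa_from_marginals(marginals_a, marginals_b, n_agreements: float) -> KappaResult:
    """Kappa when only the two graders' marginal counts and the total
    number of agreements are known (as printed in study reports)."""
    a = np.asarray(marginals_a, float)
    b = np.asarray(marginals_b, float)
    if a.sum() != b.sum() or a.sum() <= 0:
        raise ValueError("marginals must be positive and consistent")
    n = a.sum()
    p_o = n_agreements / n
    p_e = float((a * b).sum()) / n**2
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(kappa=float(kappa), observed_agreement=float(p_o),
                       expected_agreement=float(p_e),
                       category=landis_koch_category(float(kappa)))
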