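"""Structure–activity landscape index (SALI) mathematics.

For a pair of compounds i, j with observed activities A_i, A_j and structural
similarity sim(i, j) in [0, 1],

    SALI_ij = |A_i - A_j| / (1 - sim(i, j)).

A large SALI marks an activity cliff: a large activity change across a small
structural change. Normalizing the SALI values by the landscape maximum and
sweeping an edge-detection threshold X over [0, 1] yields, at each X, a
directed graph whose edges are the pairs with normalized SALI >= X, oriented
from lower to higher observed activity. A prediction model is scored on each
graph by

    S(X) = (# edges predicted in the correct direction
            - # edges predicted in the reversed direction) / # edges,

so S(X) in [-1, 1]. S as a function of X is a step function; its exact
integral over [0, 1] is the SALI curve integral (SCI). S(0) is pairwise
concordance over the whole landscape (numerically a tie-free Kendall
coefficient) and S(1) is concordance on the largest cliff(s) alone.

Conventions taken here (the literature leaves them open):

* pairs with sim = 1 (indistinguishable structures) are excluded from the
  landscape rather than given infinite SALI;
* pairs with equal observed activity carry no orientation and are excluded
  from every edge set, including X = 0, so S(0) is a tie-free coefficient;
* a predicted tie on an edge scores 0 but stays in the denominator;
* the threshold test is closed (>=), so X = 1 retains the maximal pair(s);
* with an external reference maximum the normalized values may exceed 1;
  the curve domain stays [0, 1] and such pairs belong to every edge set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

# similarity this close to 1 counts as an identical structure
_SIM_ONE_TOL = 1e-12


@dataclass
class SaliMatrix:
    """Pairwise SALI values with an eligibility mask.

    `sali[i, j]` is meaningful only where `eligible[i, j]`; ineligible
    entries (diagonal, sim = 1 pairs) are stored as 0.
    """

    ids: list[str]
    sali: np.ndarray
    eligible: np.ndarray
    sali_max: float

    @property
    def n(self) -> int:
        return len(self.ids)

    def pair_values(self) -> np.ndarray:
        """SALI values of the eligible pairs (upper triangle, condensed)."""
        iu, ju = np.triu_indices(self.n, k=1)
        keep = self.eligible[iu, ju]
        return self.sali[iu[keep], ju[keep]]


@dataclass
class SaliGraph:
    """Edges of the thresholded SALI graph, oriented low -> high observed."""

    threshold: float
    ids: list[str]
    tail: np.ndarray  # index of the lower-activity endpoint
    head: np.ndarray  # index of the higher-activity endpoint

    @property
    def n_edges(self) -> int:
        return len(self.tail)

    def edge_ids(self) -> list[tuple[str, str]]:
        return [(self.ids[i], self.ids[j]) for i, j in zip(self.tail, self.head)]


@dataclass
class SaliCurve:
    """The step function S(X) on [0, 1] with its exact integral.

    `breakpoints` are the right endpoints of the constant intervals:
    S = s_values[0] on [0, breakpoints[0]] and
    S = s_values[k] on (breakpoints[k-1], breakpoints[k]].
    The last breakpoint is always 1.0.
    """

    breakpoints: np.ndarray
    s_values: np.ndarray
    sci: float
    s0: float
    s1: float
    method: str = "exact"
    grid_x: np.ndarray | None = None
    grid_s: np.ndarray | None = None

    def evaluate(self, x: float) -> float:
        """Exact S(x) for x in [0, 1]."""
        if not 0.0 <= x <= 1.0:
            raise ValidationError(f"threshold {x} outside [0, 1]")
        if x == 0.0:
            return float(self.s_values[0])
        k = int(np.searchsorted(self.breakpoints, x, side="left"))
        k = min(k, len(self.s_values) - 1)
        return float(self.s_values[k])

    def sample(self, step: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
        """Sample S on a regular grid (for CSV export and plotting)."""
        xs = np.arange(0.0, 1.0 + step / 2, step)
        xs[-1] = min(xs[-1], 1.0)
        return xs, np.array([self.evaluate(float(x)) for x in xs])


@dataclass
class SaliHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray


def sali_matrix(observed, sim: SimilarityMatrix) -> SaliMatrix:
    """All-pairs SALI values for one landscape.

    Pairs with sim = 1 are marked ineligible (and logged) rather than
    producing a division by zero. Raises if no pair is eligible or if every
    eligible pair has identical activity (the landscape maximum would be
    undefined).
    """
    observed = np.asarray(observed, dtype=float)
    n = sim.n
    if observed.shape != (n,):
        raise ValidationError("activities do not match the similarity matrix ids")
    if n < 2:
        raise DegenerateInputError("need at least 2 compounds")
    dup = sim.values >= 1.0 - _SIM_ONE_TOL
    eligible = ~dup
    np.fill_diagonal(eligible, False)
    n_dup_pairs = int((dup.sum() - n) // 2)
    if n_dup_pairs:
        logger.warning("%d pair(s) with similarity 1 excluded from the landscape", n_dup_pairs)
    if not eligible.any():
        raise DegenerateInputError("no eligible pairs: all structures are identical")
    diff = np.abs(observed[:, None] - observed[None, :])
    denom = 1.0 - sim.values
    sali = np.zeros((n, n))
    sali[eligible] = diff[eligible] / denom[eligible]
    sali_max = float(sali[eligible].max())
    if sali_max <= 0.0:
        raise DegenerateInputError(
            "no eligible pair with differing activities: SALI maximum undefined"
        )
    return SaliMatrix(list(sim.ids), sali, eligible, sali_max)


def normalize(m: SaliMatrix, reference_max: float | None = None) -> np.ndarray:
    """Divide eligible SALI values by the landscape maximum.

    With the internal maximum all values land in [0, 1] and the maximum maps
    to exactly 1. A `reference_max` from another landscape (typically the
    training set) may be supplied for cross-set comparability; values may
    then exceed 1, which is flagged in the log.
    """
    if reference_max is not None:
        if reference_max <= 0:
            raise ValidationError(f"reference_max must be positive, got {reference_max}")
        ref = float(reference_max)
    else:
        ref = m.sali_max
    out = np.zeros_like(m.sali)
    out[m.eligible] = m.sali[m.eligible] / ref
    n_over = int((out[m.eligible] > 1.0).sum() // 2)
    if n_over:
        logger.warning(
            "%d pair(s) exceed the reference maximum (normalized SALI > 1)", n_over
        )
    return out


def edge_set(
    normalized: np.ndarray,
    observed,
    threshold: float,
    eligible: np.ndarray,
    ids: list[str] | None = None,
) -> SaliGraph:
    """Edges of the SALI graph at threshold X.

    An eligible pair (i, j) is an edge iff its normalized SALI >= X and
    A_i != A_j; the edge runs from the lower- to the higher-activity
    compound. The threshold test is closed, so X = 1 keeps the maximal pair(s)
    under internal normalization.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold {threshold} outside [0, 1]")
    observed = np.asarray(observed, dtype=float)
    n = len(observed)
    iu, ju = np.triu_indices(n, k=1)
    keep = eligible[iu, ju] & (observed[iu] != observed[ju]) & (
        normalized[iu, ju] >= threshold
    )
    i, j = iu[keep], ju[keep]
    swap = observed[i] > observed[j]
    tail = np.where(swap, j, i)
    head = np.where(swap, i, j)
    return SaliGraph(threshold, list(ids) if ids is not None else [str(k) for k in range(n)], tail, head)


def orientation_score(graph: SaliGraph, predicted) -> float:
    """S for one edge set: (+1 concordant, -1 reversed, 0 tied) averaged."""
    if graph.n_edges == 0:
        raise DegenerateInputError("orientation score undefined on an empty edge set")
    predicted = np.asarray(predicted, dtype=float)
    scores = np.sign(predicted[graph.head] - predicted[graph.tail])
    return float(scores.sum() / graph.n_edges)


def _condensed_pairs(observed, predicted, normalized, eligible):
    """Condensed (norm, score) arrays over eligible, unequal-activity pairs."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    n = len(observed)
    iu, ju = np.triu_indices(n, k=1)
    keep = eligible[iu, ju] & (observed[iu] != observed[ju])
    i, j = iu[keep], ju[keep]
    norms = normalized[i, j]
    # orient low -> high observed, then score the predicted direction
    sgn = np.sign(observed[j] - observed[i])
    scores = np.sign(predicted[j] - predicted[i]) * sgn
    return norms, scores


class _StepScore:
    """S(X) evaluator over a fixed pair set, O(log m) per query.

    Precomputes suffix sums of the pair scores sorted by normalized SALI, so
    S at any threshold is a searchsorted plus two lookups. Thresholds with an
    empty edge set evaluate to 0 (logged once by the caller).
    """

    def __init__(self, norms: np.ndarray, scores: np.ndarray):
        order = np.argsort(norms)
        self.norms = norms[order]
        s = scores[order]
        self.suffix = np.concatenate([np.cumsum(s[::-1])[::-1], [0.0]])
        self.m = len(norms)

    def __call__(self, x: float) -> float:
        k = int(np.searchsorted(self.norms, x, side="left"))
        count = self.m - k
        if count == 0:
            return 0.0
        return float(self.suffix[k] / count)


def sali_curve(
    observed,
    predicted,
    sim: SimilarityMatrix,
    method: str = "exact",
    step: float = 0.01,
    reference_max: float | None = None,
) -> SaliCurve:
    """Compute the SALI curve S(X) and its integral for one prediction model.

    method="exact" evaluates S on each constant interval between consecutive
    distinct normalized SALI values and integrates the step function in
    closed form. method="grid" samples S at X = 0, step, ..., 1 and
    integrates by the trapezoidal rule; S(0) and S(1) are exact either way.
    """
    m = sali_matrix(observed, sim)
    normalized = normalize(m, reference_max)
    norms, scores = _condensed_pairs(observed, predicted, normalized, m.eligible)
    if len(norms) == 0:
        raise DegenerateInputError("no eligible pairs with differing activities")
    s_at = _StepScore(norms, scores)
    if not np.any(norms >= 1.0):
        logger.warning("no pair reaches the reference maximum: S = 0 near X = 1")
    s0 = s_at(0.0)
    s1 = s_at(1.0)
    # right endpoints of the constant intervals of the step function
    interior = np.unique(norms[(norms > 0.0) & (norms < 1.0)])
    bps = np.concatenate([interior, [1.0]])
    s_values = np.array([s_at(b) for b in bps])
    if method == "exact":
        widths = np.diff(np.concatenate([[0.0], bps]))
        sci = float(np.dot(s_values, widths))
        return SaliCurve(bps, s_values, sci, s0, s1, method="exact")
    if method == "grid":
        xs = np.arange(0.0, 1.0 + step / 2, step)
        xs[-1] = min(xs[-1], 1.0)
        if xs[-1] < 1.0:
            xs = np.append(xs, 1.0)
        ys = np.array([s_at(float(x)) for x in xs])
        sci = float(np.trapezoid(ys, xs))
        return SaliCurve(bps, s_values, sci, s0, s1, method=f"grid({step})", grid_x=xs, grid_s=ys)
    raise ValidationError(f"unknown integration method {method!r}")


def sci(curve: SaliCurve) -> float:
    """The SALI curve integral of an already-computed curve."""
    return curve.sci


def sali_histogram(m: SaliMatrix, n_bins: int = 20, bin_edges=None) -> SaliHistogram:
    """Histogram of the eligible pairwise SALI values."""
    if bin_edges is None:
        if n_bins < 1:
            raise ValidationError(f"n_bins must be >= 1, got {n_bins}")
        bins = n_bins
    else:
        bins = np.asarray(bin_edges, dtype=float)
    values = m.pair_values()
    if len(values) == 0:
        raise DegenerateInputError("no eligible pairs to histogram")
    counts, edges = np.histogram(values, bins=bins)
    return SaliHistogram(edges, counts)
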