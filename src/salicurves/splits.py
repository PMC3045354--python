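"""Training/test assignment procedures.

Two methods:

* `random_split` — each compound draws a uniform random number, the top
  `test_fraction` by draw become the test set, and the compounds carrying
  the maximum and minimum observed activity are anchored into the training
  set (swapping minimally if a draw put them in test) so the model is never
  asked to extrapolate beyond the trained activity range.

* `kohonen_split` — a self-organizing map (SOM) trained on a descriptor
  matrix stratifies descriptor space; test compounds are then sampled per
  occupied map cell in proportion to cell occupancy, so the test set covers
  the same descriptor regions as the training set. The SOM here is a
  standard rectangular-grid implementation (Gaussian neighborhood, linearly
  decaying learning rate and radius) written for this package; commercial
  QSAR suites use the same family of maps but their exact schedules are not
  public.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .io import ActivityTable


@dataclass
class Split:
    """A disjoint, exhaustive train/test partition of compound ids."""

    train: list[str]
    test: list[str]
    method: str
    seed: int

    def __post_init__(self) -> None:
        if set(self.train) & set(self.test):
            raise ValidationError("train and test sets overlap")

    @property
    def n(self) -> int:
        return len(self.train) + len(self.test)

    def assignment(self) -> dict[str, str]:
        out = {c: "train" for c in self.train}
        out.update({c: "test" for c in self.test})
        return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def random_split(table: ActivityTable, test_fraction: float, seed: int = 0) -> Split:
    """Random assignment with activity-range anchoring.

    round(n * test_fraction) compounds (half up) go to test. If a compound
    holding the maximum or minimum observed activity lands in test, it is
    swapped with the non-extreme training compound that drew the highest
    random number, perturbing the draw minimally.
    """
    if not 0.0 <= test_fraction < 1.0:
        raise ValidationError(f"test_fraction must be in [0, 1), got {test_fraction}")
    n = table.n
    if n < 3:
        raise DegenerateInputError("need at least 3 compounds to split")
    n_test = _round_half_up(n * test_fraction)
    if n - n_test < 2:
        raise ValidationError(
            f"test_fraction {test_fraction} leaves fewer than 2 training compounds"
        )
    rng = np.random.default_rng(seed)
    draws = rng.random(n)
    order = np.argsort(-draws, kind="stable")  # descending draw
    in_test = np.zeros(n, dtype=bool)
    in_test[order[:n_test]] = True
    extremes = {int(np.argmax(table.observed)), int(np.argmin(table.observed))}
    for ext in sorted(extremes):
        if in_test[ext]:
            candidates = [k for k in range(n) if not in_test[k] and k not in extremes]
            swap = max(candidates, key=lambda k: draws[k])
            in_test[ext] = False
            in_test[swap] = True
    train = [table.ids[k] for k in range(n) if not in_test[k]]
    test = [table.ids[k] for k in range(n) if in_test[k]]
    return Split(train, test, "random", seed)


class SelfOrganizingMap:
    """Rectangular-grid SOM with Gaussian neighborhood.

    Weights are initialized from random training samples. Learning rate and
    neighborhood radius decay linearly over the presentations; the default
    budget is 100 presentations per compound, the radius starts at half the
    larger grid dimension.
    """

    def __init__(self, shape: tuple[int, int], seed: int = 0):
        rows, cols = shape
        if rows * cols < 2:
            raise ValidationError("SOM needs at least 2 cells")
        self.shape = (rows, cols)
        self.seed = seed
        gr, gc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        self._grid = np.column_stack([gr.ravel(), gc.ravel()]).astype(float)
        self.weights: np.ndarray | None = None

    def fit(self, X: np.ndarray, n_presentations: int | None = None) -> "SelfOrganizingMap":
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        rng = np.random.default_rng(self.seed)
        n_cells = self.shape[0] * self.shape[1]
        T = n_presentations if n_presentations is not None else 100 * n
        w = X[rng.integers(0, n, size=n_cells)].astype(float).copy()
        r0 = max(self.shape) / 2.0
        lr0 = 0.5
        for t in range(T):
            frac = t / max(T - 1, 1)
            lr = lr0 * (1.0 - frac) + 0.01 * frac
            radius = r0 * (1.0 - frac) + 0.5 * frac
            x = X[rng.integers(0, n)]
            bmu = int(np.argmin(((w - x) ** 2).sum(axis=1)))
            gd2 = ((self._grid - self._grid[bmu]) ** 2).sum(axis=1)
            h = np.exp(-gd2 / (2.0 * radius**2))
            w += lr * h[:, None] * (x - w)
        self.weights = w
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.weights is None:
            raise ValidationError("SOM not fitted")
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


def kohonen_split(
    descriptors,
    ids: list[str],
    map_shape: tuple[int, int] = (4, 4),
    test_fraction: float = 0.3,
    seed: int = 0,
    n_presentations: int | None = None,
    per_cell: bool = False,
) -> Split:
    """SOM-stratified train/test assignment.

    Each compound is mapped to its best-matching unit; the test quota
    (round half up of n * test_fraction) is then apportioned across occupied
    cells proportionally to occupancy, largest fractional remainders first,
    and filled by uniform sampling within each cell. `per_cell=True` instead
    samples exactly one test compound from every occupied cell with >= 2
    members.
    """
    X = np.asarray(descriptors, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValidationError("descriptor matrix must be a non-empty 2-D array")
    n, d = X.shape
    if len(ids) != n:
        raise ValidationError("descriptor rows do not match ids")
    if not 0.0 <= test_fraction < 1.0:
        raise ValidationError(f"test_fraction must be in [0, 1), got {test_fraction}")
    n_cells = map_shape[0] * map_shape[1]
    if n < n_cells and n_cells > 1:
        raise ValidationError(f"{n} compounds cannot populate a {map_shape} map")
    rng = np.random.default_rng(seed)
    if n_cells == 1:
        cells = np.zeros(n, dtype=int)
    else:
        som = SelfOrganizingMap(map_shape, seed=seed).fit(X, n_presentations)
        cells = som.predict(X)
    occupied = np.unique(cells)
    members = {c: np.flatnonzero(cells == c) for c in occupied}
    test_idx: list[int] = []
    if per_cell:
        for c in occupied:
            m = members[c]
            if len(m) >= 2:
                test_idx.append(int(rng.choice(m)))
    else:
        target = _round_half_up(n * test_fraction)
        quotas = {c: len(members[c]) * test_fraction for c in occupied}
        base = {c: min(int(math.floor(q)), len(members[c]) - 1) for c, q in quotas.items()}
        remaining = target - sum(base.values())
        by_remainder = sorted(
            occupied, key=lambda c: (quotas[c] - base[c], len(members[c])), reverse=True
        )
        for c in by_remainder:
            if remaining <= 0:
                break
            if base[c] < len(members[c]) - 1:
                base[c] += 1
                remaining -= 1
        for c in occupied:
            if base[c] > 0:
                test_idx.extend(int(k) for k in rng.choice(members[c], base[c], replace=False))
    in_test = np.zeros(n, dtype=bool)
    in_test[test_idx] = True
    train = [ids[k] for k in range(n) if not in_test[k]]
    test = [ids[k] for k in range(n) if in_test[k]]
    return Split(train, test, "kohonen", seed)
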