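"""Self-contained synthetic activity landscapes with planted cliffs.

Real SALI analyses take structures plus a measured activity; here both are
replaced by a latent-space construction so the landscape mathematics can be
exercised (and stress-tested) without chemistry:

* compounds are points in a 2-D latent space, placed by dart throwing with a
  minimum separation so no background pair is accidentally near-identical;
* similarity is an exponential kernel of latent distance,
  sim = exp(-d / length_scale), which is 1 only at d = 0 and decays
  linearly near 0 — so background SALI values stay bounded;
* the observed activity is a smooth (linear) function of latent position,
  scaled onto `activity_range` — mimicking a log10-transformed efflux ratio;
* each planted cliff takes one background compound and adds a partner at a
  latent distance giving similarity >= cliff_sim_min, with its activity
  displaced by >= cliff_gap_min. These pairs dominate the SALI landscape by
  construction, so cliff-recovery is testable.

`simulate_predictions` then produces model outputs of tunable quality
spanning perfect (quality = 1), uninformative (0) and perfectly reversed
(-1) rank ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .io import ActivityTable
from .similarity import SimilarityMatrix

# kernel length scale and the background similarity ceiling that the
# dart-throwing separation enforces
_LENGTH_SCALE = 0.5
_BACKGROUND_SIM_MAX = 0.7


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of one synthetic landscape.

    n : total compound count (cliff partners included).
    n_cliffs : planted cliff pairs (each consumes 2 of the n compounds).
    cliff_sim_min : minimum structural similarity of a planted pair.
    cliff_gap_min : minimum activity difference of a planted pair, in
        activity units (log10 scale for the efflux use case).
    activity_range : (low, high) of the smooth background activity;
        default (0, 2) covers efflux ratios of 1–100 on the log10 scale.
    """

    n: int = 50
    n_cliffs: int = 5
    cliff_sim_min: float = 0.95
    cliff_gap_min: float = 1.5
    activity_range: tuple[float, float] = (0.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"n must be >= 2, got {self.n}")
        if not 0 <= self.n_cliffs <= self.n / 2:
            raise ValidationError(
                f"n_cliffs must be in [0, n/2], got {self.n_cliffs} for n={self.n}"
            )
        if not 0.0 <= self.cliff_sim_min < 1.0:
            raise ValidationError(f"cliff_sim_min must be in [0, 1), got {self.cliff_sim_min}")
        if self.cliff_gap_min <= 0:
            raise ValidationError("cliff_gap_min must be positive")
        low, high = self.activity_range
        if not low < high:
            raise ValidationError(f"activity_range low must be < high, got {self.activity_range}")


@dataclass
class SyntheticLandscape:
    """A generated landscape: similarity, activities and the planted truth."""

    ids: list[str]
    similarity: SimilarityMatrix
    observed: np.ndarray
    cliff_pairs: list[tuple[int, int]]
    spec: LandscapeSpec

    def cliff_id_pairs(self) -> list[tuple[str, str]]:
        return [(self.ids[i], self.ids[j]) for i, j in self.cliff_pairs]


def _dart_throw(rng: np.random.Generator, n: int, d_min: float) -> np.ndarray:
    """n points in a square with pairwise separation >= d_min."""
    side = 2.0 * d_min * np.sqrt(max(n, 4))
    points = np.empty((n, 2))
    count = 0
    for _ in range(500 * n):
        cand = rng.uniform(0.0, side, size=2)
        if count == 0 or np.min(((points[:count] - cand) ** 2).sum(axis=1)) >= d_min**2:
            points[count] = cand
            count += 1
            if count == n:
                return points
    raise DegenerateInputError(f"could not place {n} separated points; spec infeasible")


def generate_landscape(spec: LandscapeSpec | None = None, **kwargs) -> SyntheticLandscape:
    """Generate one landscape; deterministic for a given spec (seed included)."""
    if spec is None:
        spec = LandscapeSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    low, high = spec.activity_range
    n_background = spec.n - spec.n_cliffs
    d_min = -_LENGTH_SCALE * np.log(_BACKGROUND_SIM_MAX)
    pts = _dart_throw(rng, n_background, d_min)

    # smooth background activity: scaled linear projection of latent position
    w = rng.standard_normal(2)
    w /= np.linalg.norm(w)
    proj = pts @ w
    span = np.ptp(proj)
    if span == 0:
        proj = pts[:, 0]
        span = max(np.ptp(proj), 1.0)
    activity = low + (high - low) * (proj - proj.min()) / span

    # cliff partners: spatially adjacent, activity displaced past the gap
    cliff_pairs: list[tuple[int, int]] = []
    if spec.n_cliffs > 0:
        bases = rng.choice(n_background, size=spec.n_cliffs, replace=False)
        sim_hi = min(0.995, spec.cliff_sim_min + 0.04)
        extra_pts = np.empty((spec.n_cliffs, 2))
        extra_act = np.empty(spec.n_cliffs)
        for k, b in enumerate(bases):
            target_sim = rng.uniform(spec.cliff_sim_min, sim_hi)
            d = -_LENGTH_SCALE * np.log(target_sim)
            theta = rng.uniform(0.0, 2.0 * np.pi)
            extra_pts[k] = pts[b] + d * np.array([np.cos(theta), np.sin(theta)])
            gap = spec.cliff_gap_min * (1.0 + 0.25 * rng.random())
            sign = 1.0 if activity[b] <= (low + high) / 2.0 else -1.0
            extra_act[k] = activity[b] + sign * gap
            cliff_pairs.append((int(b), n_background + k))
        pts = np.vstack([pts, extra_pts])
        activity = np.concatenate([activity, extra_act])

    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    values = np.exp(-dist / _LENGTH_SCALE)
    np.fill_diagonal(values, 1.0)
    width = max(len(str(spec.n)), 3)
    ids = [f"C{k + 1:0{width}d}" for k in range(spec.n)]
    sim = SimilarityMatrix(ids, values)
    return SyntheticLandscape(ids, sim, activity, cliff_pairs, spec)


def simulate_predictions(
    observed,
    quality: float,
    noise_model: str = "additive-gaussian",
    seed: int = 0,
) -> np.ndarray:
    """Predictions of tunable rank-order quality.

    quality = 1 returns the observed activities; -1 their negation;
    intermediate values mix the (possibly negated) signal with
    seed-deterministic noise whose weight shrinks as |quality| grows, so the
    expected Kendall tau rises monotonically with quality and is ~0 at 0.

    noise_model="additive-gaussian" blends the standardized signal with
    Gaussian noise; "rank-swap" randomly permutes the values of a fraction
    (1 - |quality|) of the compounds.
    """
    observed = np.asarray(observed, dtype=float)
    if not -1.0 <= quality <= 1.0:
        raise ValidationError(f"quality must be in [-1, 1], got {quality}")
    base = observed if quality >= 0 else -observed
    if abs(quality) == 1.0:
        return base.astype(float).copy()
    rng = np.random.default_rng(seed)
    a = abs(quality)
    if noise_model == "additive-gaussian":
        scale = np.std(base)
        z = (base - np.mean(base)) / scale if scale > 0 else np.zeros_like(base)
        return a * z + (1.0 - a) * rng.standard_normal(observed.size)
    if noise_model == "rank-swap":
        pred = base.astype(float).copy()
        k = int(round((1.0 - a) * observed.size))
        if k >= 2:
            idx = rng.choice(observed.size, size=k, replace=False)
            pred[idx] = pred[rng.permutation(idx)]
        return pred
    raise ValidationError(f"unknown noise model {noise_model!r}")


def landscape_table(
    landscape: SyntheticLandscape,
    qualities: dict[str, float],
    noise_model: str = "additive-gaussian",
    seed: int = 0,
) -> ActivityTable:
    """Bundle a landscape with one simulated prediction column per model."""
    predictions = {
        name: simulate_predictions(landscape.observed, q, noise_model, seed + k)
        for k, (name, q) in enumerate(qualities.items())
    }
    return ActivityTable(list(landscape.ids), landscape.observed, predictions)
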