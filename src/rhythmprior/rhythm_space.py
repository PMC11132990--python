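"""Geometry of the three-interval rhythm simplex.

A three-interval rhythm is an ordered triple of inter-onset intervals
(s1, s2, s3) whose sum is the cycle period (2,000 ms by default).  Dividing
by the period gives a point on the 2-simplex, which we embed in an
equilateral triangle with vertices P1 = (0, 0), P2 = (1, 0) and
P3 = (1/2, sqrt(3)/2).  All distances used by the analysis are Euclidean
distances in this embedding (side length 1).

The module also enumerates the small-integer-ratio rhythms (ratios built
from the integers 1..3, optionally extended with 7:2:3), partitions them
into classes that are equivalent under cyclic permutation, and samples
uniform seed rhythms from the inner triangular region of producible
rhythms (all intervals above a floor, 300 ms at the 2,000 ms period).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "TRIANGLE_VERTICES",
    "IntervalPattern",
    "TrianglePoint",
    "IntegerRatioSet",
    "InvalidPatternError",
    "OutOfDomainError",
    "normalize_pattern",
    "project",
    "project_many",
    "unproject",
    "barycentric",
    "enumerate_integer_ratios",
    "cyclic_classes",
    "omega22",
    "omega25",
    "min_distance_to_set",
    "min_pairwise_distance",
    "in_inner_triangle",
    "inner_triangle_vertices",
    "sample_seed",
    "sample_simplex",
    "sample_triangle_points",
    "sample_inner_points",
]

SQRT3 = math.sqrt(3.0)

#: Vertices of the equilateral embedding triangle (rows: P1, P2, P3).
TRIANGLE_VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, SQRT3 / 2.0]])


class InvalidPatternError(ValueError):
    """Raised for interval patterns with non-positive intervals."""


class OutOfDomainError(ValueError):
    """Raised for triangle points outside the full rhythm triangle."""


class TrianglePoint(NamedTuple):
    """A point in the equilateral rhythm-triangle embedding."""

    x: float
    y: float


@dataclass(frozen=True)
class IntervalPattern:
    """One cycle of a three-interval rhythm, durations in ms."""

    s1: float
    s2: float
    s3: float
    period: float = 2000.0

    def __post_init__(self) -> None:
        if not (self.s1 > 0 and self.s2 > 0 and self.s3 > 0):
            raise InvalidPatternError(
                f"intervals must be positive, got {(self.s1, self.s2, self.s3)}"
            )
        total = self.s1 + self.s2 + self.s3
        if not math.isclose(total, self.period, rel_tol=1e-9, abs_tol=1e-6):
            raise InvalidPatternError(
                f"intervals sum to {total}, expected period {self.period}"
            )

    @property
    def intervals(self) -> np.ndarray:
        return np.array([self.s1, self.s2, self.s3])

    def proportions(self) -> np.ndarray:
        return normalize_pattern(self)

    def point(self) -> TrianglePoint:
        return project(self.proportions())

    @classmethod
    def from_proportions(
        cls, proportions: Sequence[float], period: float = 2000.0
    ) -> "IntervalPattern":
        p = np.asarray(proportions, dtype=float)
        p = p / p.sum()
        s = p * period
        return cls(float(s[0]), float(s[1]), float(s[2]), period=period)


def normalize_pattern(pattern) -> np.ndarray:
    """Return the proportion triple (s1, s2, s3) / (s1 + s2 + s3)."""
    if isinstance(pattern, IntervalPattern):
        s = pattern.intervals
    else:
        s = np.asarray(pattern, dtype=float)
    if s.shape != (3,):
        raise InvalidPatternError(f"expected 3 intervals, got shape {s.shape}")
    if np.any(s <= 0):
        raise InvalidPatternError(f"intervals must be positive, got {s}")
    return s / s.sum()


def project(proportions: Sequence[float]) -> TrianglePoint:
    """Map a proportion triple to its equilateral-triangle embedding."""
    p = np.asarray(proportions, dtype=float)
    xy = p @ TRIANGLE_VERTICES
    return TrianglePoint(float(xy[0]), float(xy[1]))


def project_many(proportions: np.ndarray) -> np.ndarray:
    """Vectorized :func:`project` for an (n, 3) proportion array."""
    return np.asarray(proportions, dtype=float) @ TRIANGLE_VERTICES


def barycentric(point: Sequence[float]) -> np.ndarray:
    """Recover the proportion triple from triangle coordinates.

    Inverts the affine embedding; does not check the simplex constraint,
    so components may be negative for points outside the triangle.
    """
    x, y = float(point[0]), float(point[1])
    p3 = 2.0 * y / SQRT3
    p2 = x - 0.5 * p3
    p1 = 1.0 - p2 - p3
    return np.array([p1, p2, p3])


def barycentric_many(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    p3 = 2.0 * pts[:, 1] / SQRT3
    p2 = pts[:, 0] - 0.5 * p3
    p1 = 1.0 - p2 - p3
    return np.column_stack([p1, p2, p3])


def unproject(point: Sequence[float], tol: float = 1e-9) -> np.ndarray:
    """Proportion triple for a point inside (or on) the full triangle."""
    p = barycentric(point)
    if np.any(p < -tol):
        raise OutOfDomainError(f"point {tuple(point)} lies outside the triangle")
    return np.clip(p, 0.0, None)


def _canonical_integers(member: tuple[Fraction, Fraction, Fraction]) -> tuple[int, ...]:
    """Smallest integer triple proportional to a proportion triple."""
    lcm = math.lcm(*(f.denominator for f in member))
    ints = tuple(int(f * lcm) for f in member)
    g = math.gcd(math.gcd(ints[0], ints[1]), ints[2])
    return tuple(i // g for i in ints)


def _class_label(ints: tuple[int, ...]) -> str:
    rotations = [ints[i:] + ints[:i] for i in range(3)]
    return "".join(str(i) for i in min(rotations))


@dataclass(frozen=True)
class IntegerRatioSet:
    """A set of integer-ratio rhythms as exact proportion triples.

    ``members`` are unique normalized proportion triples (exact rationals);
    ``cyclic_classes`` partitions member indices into classes equivalent
    under cyclic permutation, keyed by the canonical (lexicographically
    minimal rotation) integer label, e.g. ``"112"``.
    """

    label: str
    members: tuple[tuple[Fraction, Fraction, Fraction], ...]
    cyclic_classes: dict[str, tuple[int, ...]] = field(compare=False)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def proportions(self) -> np.ndarray:
        return np.array([[float(f) for f in m] for m in self.members])

    @property
    def points(self) -> np.ndarray:
        return project_many(self.proportions)

    def member_labels(self) -> list[str]:
        """Per-member integer labels in the member's own ordering, e.g. '332'."""
        return ["".join(str(i) for i in _canonical_integers(m)) for m in self.members]

    def class_of_member(self, index: int) -> str:
        for label, idx in self.cyclic_classes.items():
            if index in idx:
                return label
        raise KeyError(index)

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = []
        for i, m in enumerate(self.members):
            rows.append(
                {
                    "label": self.label,
                    "p1": float(m[0]),
                    "p2": float(m[1]),
                    "p3": float(m[2]),
                    "cyclic_class": self.class_of_member(i),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def cyclic_classes(
    members: Iterable[tuple[Fraction, Fraction, Fraction]]
) -> dict[str, tuple[int, ...]]:
    """Partition members into classes equivalent under cyclic rotation."""
    members = list(members)
    classes: dict[str, list[int]] = {}
    for i, m in enumerate(members):
        classes.setdefault(_class_label(_canonical_integers(m)), []).append(i)
    return {k: tuple(v) for k, v in classes.items()}


def enumerate_integer_ratios(
    max_int: int = 3, min_fraction: float = 0.15, label: str | None = None
) -> IntegerRatioSet:
    """All ratios over {1..max_int}, deduplicated as exact proportions.

    Triples are deduplicated by exact rational comparison of the normalized
    proportions (so e.g. 1:1:1, 2:2:2 and 3:3:3 coincide) and filtered so
    the minimum proportion is at least ``min_fraction``.
    """
    if max_int < 1:
        raise ValueError("max_int must be >= 1")
    if not 0 <= min_fraction < 1 / 3:
        raise ValueError("min_fraction must be in [0, 1/3)")
    seen: dict[tuple[Fraction, ...], None] = {}
    for triple in itertools.product(range(1, max_int + 1), repeat=3):
        s = sum(triple)
        member = tuple(Fraction(t, s) for t in triple)
        if min(member) < min_fraction:
            continue
        seen.setdefault(member, None)
    members = tuple(seen)
    name = label or f"ratios_{max_int}_{min_fraction:g}"
    return IntegerRatioSet(name, members, cyclic_classes(members))


def omega22() -> IntegerRatioSet:
    """The 22 unique ratios over {1, 2, 3} inside the inner region."""
    s = enumerate_integer_ratios(3, 0.15, label="omega22")
    return s


def omega25() -> IntegerRatioSet:
    """omega22 extended with the cyclic rotations of 7:2:3."""
    base = omega22()
    extra = []
    for triple in ((2, 3, 7), (7, 2, 3), (3, 7, 2)):
        s = sum(triple)
        extra.append(tuple(Fraction(t, s) for t in triple))
    members = base.members + tuple(extra)
    return IntegerRatioSet("omega25", members, cyclic_classes(members))


def min_distance_to_set(
    point: Sequence[float], ratio_set: IntegerRatioSet
) -> tuple[float, int]:
    """Euclidean distance (triangle coordinates) to the nearest member.

    Returns ``(distance, member_index)``.
    """
    if len(ratio_set) == 0:
        raise ValueError("ratio set is empty")
    pts = ratio_set.points
    d = np.hypot(pts[:, 0] - point[0], pts[:, 1] - point[1])
    i = int(np.argmin(d))
    return float(d[i]), i


def min_distances_to_points(points: np.ndarray, set_points: np.ndarray) -> np.ndarray:
    """Per-row minimum Euclidean distance from ``points`` to ``set_points``."""
    diff = points[:, None, :] - set_points[None, :, :]
    return np.min(np.hypot(diff[..., 0], diff[..., 1]), axis=1)


def min_pairwise_distance(ratio_set: IntegerRatioSet) -> float:
    """Minimum pairwise distance among projected members (d_min)."""
    pts = ratio_set.points
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    d[np.diag_indices_from(d)] = np.inf
    return float(d.min())


def inner_triangle_vertices(f: float = 0.15) -> np.ndarray:
    """Vertices of the inner region (all proportions equal to f on edges)."""
    return np.array(
        [
            [1.5 * f, SQRT3 / 2.0 * f],
            [1.0 - 1.5 * f, SQRT3 / 2.0 * f],
            [0.5, SQRT3 / 2.0 * (1.0 - 2.0 * f)],
        ]
    )


def in_inner_triangle(point: Sequence[float], f: float = 0.15) -> bool:
    """True iff all recovered proportions strictly exceed ``f``.

    Strict inequality mirrors the seed constraint (all intervals > 300 ms);
    points exactly on the inner boundary are excluded.
    """
    p = barycentric(point)
    return bool(np.all(p > f))


def in_inner_triangle_many(points: np.ndarray, f: float = 0.15) -> np.ndarray:
    return np.all(barycentric_many(points) > f, axis=1)


def sample_simplex(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform samples from the full 2-simplex, shape (n, 3)."""
    return rng.dirichlet((1.0, 1.0, 1.0), size=n)


def sample_seed(
    rng: np.random.Generator, period: float = 2000.0, min_interval: float = 300.0
) -> IntervalPattern:
    """Uniform random seed from the inner region of the rhythm simplex.

    A uniform simplex draw is mapped affinely onto the shrunken simplex
    {p : min(p) >= f}, f = min_interval / period, so every interval exceeds
    ``min_interval`` (almost surely strictly).
    """
    if 3.0 * min_interval >= period:
        raise ValueError("3 * min_interval must be smaller than the period")
    f = min_interval / period
    u = rng.dirichlet((1.0, 1.0, 1.0))
    p = f + (1.0 - 3.0 * f) * u
    s = p * period
    return IntervalPattern(float(s[0]), float(s[1]), float(s[2]), period=period)


def sample_triangle_points(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform points in the full embedding triangle, shape (n, 2)."""
    return project_many(sample_simplex(rng, n))


def sample_inner_points(
    rng: np.random.Generator, n: int, f: float = 0.15
) -> np.ndarray:
    """Uniform points in the inner region, shape (n, 2)."""
    u = sample_simplex(rng, n)
    return project_many(f + (1.0 - 3.0 * f) * u)
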