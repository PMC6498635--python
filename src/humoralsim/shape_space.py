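"""Discrete shape-space lattices and the binding geometry.

Receptors (TCR, BCR), peptides and antigens are represented as points of a
small planar integer grid, the *shape space*.  The ``x`` coordinate encodes a
"horizontal" feature of the binding profile, the ``y`` coordinate a "vertical"
one where positive values mean convexity and negative values concavity.  A
receptor ``(x, y)`` is perfectly complementary to a ligand ``(x, -y)`` (a
convex bump fits a concave pocket); imperfect complementarity is measured by
the l-infinity (maximum) distance between the receptor and the mirror image
of the ligand.  Two lattices of identical geometry are used: the *peptide*
lattice (TCR vs MHCII+peptide) and the *antigen* lattice (BCR/antibody vs
antigen).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, TextIO


class ShapePoint(NamedTuple):
    """A point of a shape-space lattice: an abstract binding profile."""

    x: int
    y: int


@dataclass(frozen=True)
class Lattice:
    """A closed grid ``{0..N} x {-N/2..N/2}``; ``kind`` labels its use."""

    N: int = 1000
    kind: str = "antigen"

    def __post_init__(self) -> None:
        if self.N < 2 or self.N % 2 != 0:
            raise ValueError(f"lattice size N must be even and >= 2, got {self.N}")
        if self.kind not in ("peptide", "antigen"):
            raise ValueError(f"lattice kind must be 'peptide' or 'antigen', got {self.kind!r}")

    def contains(self, z: ShapePoint) -> bool:
        half = self.N // 2
        return 0 <= z[0] <= self.N and -half <= z[1] <= half

    def clamp(self, x: int, y: int) -> ShapePoint:
        """Clamp raw coordinates to the nearest lattice point.

        Mutated offspring receptors that would fall off the grid are pulled
        back to the boundary so that repertoire mass is preserved near edges.
        """
        half = self.N // 2
        x = 0 if x < 0 else (self.N if x > self.N else x)
        y = -half if y < -half else (half if y > half else y)
        return ShapePoint(x, y)

    def n_points(self) -> int:
        return (self.N + 1) * (self.N + 1)


def linf_distance(z1: ShapePoint, z2: ShapePoint, lattice: Lattice | None = None) -> int:
    """Maximum (l-infinity) distance between two shape points.

    This is the single similarity metric of the model: the smaller the
    distance between a receptor and the mirror image of a ligand, the better
    the fit.
    """
    if lattice is not None:
        for z in (z1, z2):
            if not lattice.contains(ShapePoint(*z)):
                raise ValueError(f"point {z} is off the lattice (N={lattice.N})")
    dx = z2[0] - z1[0]
    dy = z2[1] - z1[1]
    if dx < 0:
        dx = -dx
    if dy < 0:
        dy = -dy
    return dx if dx > dy else dy


def mirror(z: ShapePoint) -> ShapePoint:
    """Mirror image ``(x, y) -> (x, -y)``: the perfectly complementary shape."""
    return ShapePoint(z[0], -z[1])


def binds_within(receptor: ShapePoint, ligand: ShapePoint, radius: int) -> bool:
    """True iff the receptor lies within ``radius`` of the ligand's mirror.

    Only complementary or nearly complementary shapes can bind; ``radius`` is
    the reach of the receptor in l-infinity balls.
    """
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    return linf_distance(receptor, mirror(ligand)) <= radius


def affinity_weight(distance: int, radius: int, alpha: float = 2.0) -> float:
    """Graded binding affinity on top of the hard ball test.

    Returns ``(1 - d/(radius+1)) ** alpha`` for ``d <= radius`` and 0 beyond:
    1.0 at perfect complementarity, decaying to ~0 at the edge of the action
    radius.  Interaction *success* (engulfment, killing) is drawn with this
    probability, so proximity in shape space behaves like affinity.
    """
    if distance > radius:
        return 0.0
    return (1.0 - distance / (radius + 1.0)) ** alpha


def random_shape(rng, lattice: Lattice) -> ShapePoint:
    """Uniform draw over the closed grid — the naive repertoire distribution."""
    half = lattice.N // 2
    return ShapePoint(rng.randint(0, lattice.N), rng.randint(-half, half))


def random_offset(rng, magnitude: int) -> tuple[int, int]:
    """Uniform point on the l-infinity sphere of radius ``magnitude``.

    Used for receptor mutation at division: the offspring receptor is the
    parent's displaced by such an offset (then clamped to the lattice).
    """
    if magnitude <= 0:
        return (0, 0)
    m = magnitude
    # 8*m points on the linf sphere of radius m, as four disjoint half-open
    # edges of 2*m points each; pick one uniformly.
    k = rng.randrange(8 * m)
    side, off = divmod(k, 2 * m)
    if side == 0:  # bottom edge
        return (-m + off, -m)
    if side == 1:  # right edge
        return (m, -m + off)
    if side == 2:  # top edge
        return (m - off, m)
    return (-m, m - off)  # left edge


def ball_points(center: ShapePoint, radius: int, lattice: Lattice) -> set[ShapePoint]:
    """All lattice points within l-infinity ``radius`` of ``center``.

    Brute-force enumeration helper for selection geometry (ball and annulus
    areas); intended for small radii / small lattices.
    """
    half = lattice.N // 2
    cx, cy = center
    pts = set()
    for x in range(max(0, cx - radius), min(lattice.N, cx + radius) + 1):
        for y in range(max(-half, cy - radius), min(half, cy + radius) + 1):
            pts.add(ShapePoint(x, y))
    return pts


def write_snapshot(rows: Iterable[tuple[str, int, int, int]], fh: TextIO) -> None:
    """Write a shape-space snapshot as TSV: kind (TCR|BCR|self|foreign), x, y, count."""
    fh.write("kind\tx\ty\tcount\n")
    for kind, x, y, count in rows:
        fh.write(f"{kind}\t{x}\t{y}\t{count}\n")
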