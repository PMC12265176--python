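"""Sublevel cubical persistence and Betti-curve vectorization.

The filtration is the nested family of binary images obtained by including
pixels with intensity <= t for an increasing threshold t. Pixels are the top
cells of a cubical complex, so connected components of the included pixels
(4-connectivity) are the 0-dimensional classes and bounded complementary
regions (holes) are the 1-dimensional classes.

H0 is computed by a union-find sweep over pixels in increasing intensity
order with the elder rule at merges. H1 uses the planar duality between
holes of the sublevel set and bounded 8-connected components of its
complement: a reversed (decreasing-intensity) union-find with a virtual
border node yields the (birth, death) pairs of the holes directly. Both
routes are exact at full 8-bit intensity resolution, so the stored diagrams
are independent of the threshold grid used to vectorize them.

The Betti curve counts, at each grid threshold t, the diagram points with
birth <= t < death; essential classes (death = infinity) count through the
last threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ChannelImage, ImageRecord, split_channels

DEFAULT_N_THRESHOLDS = 100

# offsets: 4-neighbourhood for included pixels, 8 for the complement
_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_N8 = _N4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass
class ThresholdGrid:
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size < 2:
            raise ValueError("threshold grid needs at least 2 values")
        if not np.all(np.diff(self.values) > 0):
            raise ValueError("threshold grid must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class PersistenceDiagram:
    """Multiset of (birth, death) pairs for one homology dimension.

    Deaths use ``np.inf`` for essential classes. Births and deaths are stored
    as intensity values, not grid indices, so a diagram can be re-vectorized
    on any grid.
    """

    dim: int
    points: np.ndarray  # (n, 2) float array, death may be inf

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if self.dim not in (0, 1):
            raise ValueError(f"homology dimension must be 0 or 1, got {self.dim}")
        if self.points.size and not np.all(self.points[:, 0] < self.points[:, 1]):
            raise ValueError("every diagram point needs birth < death")


@dataclass
class BettiCurve:
    dim: int
    counts: np.ndarray


def build_threshold_grid(n: int = DEFAULT_N_THRESHOLDS) -> ThresholdGrid:
    """n thresholds linearly spaced over the full 8-bit range [0, 255]."""
    if n < 2:
        raise ValueError(f"need at least 2 thresholds, got {n}")
    return ThresholdGrid(np.linspace(0.0, 255.0, n))


def sublevel_binary(channel: ChannelImage | np.ndarray, t: float) -> np.ndarray:
    """Binary mask of pixels with intensity <= t."""
    values = channel.values if isinstance(channel, ChannelImage) else np.asarray(channel)
    return values <= t


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:
            p[i], i = root, p[i]
        return root

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def _h0_diagram(values: np.ndarray) -> np.ndarray:
    """0-D persistence of the sublevel filtration, 4-connected pixels.

    Pixels enter in increasing intensity order; a pixel with no previously
    entered neighbour births a component at its value, and a merge kills the
    younger component (elder rule) at the merging pixel's value.
    """
    h, w = values.shape
    flat = values.ravel().astype(np.float64)
    order = np.argsort(flat, kind="stable")
    uf = _UnionFind(h * w)
    birth = np.full(h * w, np.inf)  # birth of the component rooted at index
    active = np.zeros(h * w, dtype=bool)
    pairs: list[tuple[float, float]] = []

    for idx in order:
        v = flat[idx]
        active[idx] = True
        birth[idx] = v
        r, c = divmod(int(idx), w)
        for dr, dc in _N4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                nidx = rr * w + cc
                if active[nidx]:
                    ra, rb = uf.find(int(idx)), uf.find(nidx)
                    if ra == rb:
                        continue
                    # elder rule: the earlier-born root survives
                    if birth[ra] < birth[rb] or (birth[ra] == birth[rb] and ra < rb):
                        ra, rb = rb, ra
                    if birth[ra] < v:  # drop zero-persistence pairs
                        pairs.append((birth[ra], v))
                    uf.parent[ra] = rb
    root = uf.find(0)
    pairs.append((birth[root], np.inf))
    return np.array(pairs, dtype=np.float64)


def _h1_diagram(values: np.ndarray) -> np.ndarray:
    """1-D persistence via duality with the complement.

    A hole of the sublevel set at threshold t is a bounded 8-connected
    component of the pixels with intensity > t. Running time backwards
    (adding pixels in decreasing intensity order, together with a virtual
    border node representing the unbounded outside), each merge at value v of
    a component whose maximum intensity is M corresponds to a hole alive for
    v <= t < M.
    """
    h, w = values.shape
    flat = values.ravel().astype(np.float64)
    order = np.argsort(-flat, kind="stable")
    n = h * w
    border = n  # virtual node for the unbounded outside region
    uf = _UnionFind(n + 1)
    comp_max = np.full(n + 1, -np.inf)
    comp_max[border] = np.inf
    active = np.zeros(n + 1, dtype=bool)
    active[border] = True
    pairs: list[tuple[float, float]] = []

    for idx in order:
        v = flat[idx]
        active[idx] = True
        comp_max[idx] = v
        r, c = divmod(int(idx), w)
        if r == 0 or r == h - 1 or c == 0 or c == w - 1:
            neighbours = [border]
        else:
            neighbours = []
        for dr, dc in _N8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                nidx = rr * w + cc
                if active[nidx]:
                    neighbours.append(nidx)
        for nidx in neighbours:
            ra, rb = uf.find(int(idx)), uf.find(int(nidx))
            if ra == rb:
                continue
            if comp_max[ra] > comp_max[rb] or (comp_max[ra] == comp_max[rb] and ra < rb):
                ra, rb = rb, ra
            # younger complement component (smaller max) dies: hole (v, M)
            if v < comp_max[ra]:
                pairs.append((v, comp_max[ra]))
            uf.parent[ra] = rb
            comp_max[rb] = max(comp_max[rb], comp_max[ra])
    return np.array(pairs, dtype=np.float64).reshape(-1, 2)


def cubical_persistence(
    channel: ChannelImage | np.ndarray, grid: ThresholdGrid | None = None, dim: int = 0
) -> PersistenceDiagram:
    """Persistence diagram of the sublevel filtration of a 2-D channel.

    ``grid`` is accepted for interface symmetry with :func:`betti_curve`; the
    diagram itself is computed at full intensity resolution and does not
    depend on it.
    """
    values = channel.values if isinstance(channel, ChannelImage) else np.asarray(channel)
    if values.ndim != 2:
        raise ValueError(f"cubical persistence needs a 2-D image, got shape {values.shape}")
    if dim == 0:
        return PersistenceDiagram(0, _h0_diagram(values))
    if dim == 1:
        return PersistenceDiagram(1, _h1_diagram(values))
    raise ValueError(f"homology dimension must be 0 or 1, got {dim}")


def betti_curve(pd: PersistenceDiagram, grid: ThresholdGrid) -> BettiCurve:
    """Count active classes per grid threshold: birth <= t < death."""
    t = grid.values
    if pd.points.size == 0:
        return BettiCurve(pd.dim, np.zeros(len(grid), dtype=np.int64))
    births = pd.points[:, 0][:, None]
    deaths = pd.points[:, 1][:, None]
    counts = ((births <= t[None, :]) & (t[None, :] < deaths)).sum(axis=0)
    return BettiCurve(pd.dim, counts.astype(np.int64))


@dataclass
class TDAFeatureVector:
    """Per-image topological descriptor: for each channel (R, G, B, GRAY) the
    beta_0 and beta_1 Betti curves on the default 100-threshold grid,
    concatenated to a length-800 vector."""

    values: np.ndarray
    source: str = field(default="TDA")


def extract_tda(rec: ImageRecord, n_thresholds: int = DEFAULT_N_THRESHOLDS) -> TDAFeatureVector:
    grid = build_threshold_grid(n_thresholds)
    parts = []
    for ch in split_channels(rec):
        for dim in (0, 1):
            pd = cubical_persistence(ch, grid, dim=dim)
            parts.append(betti_curve(pd, grid).counts)
    return TDAFeatureVector(np.concatenate(parts).astype(np.float64))
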