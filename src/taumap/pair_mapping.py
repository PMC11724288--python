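"""Greedy nearest-neighbor pairing of two particle populations.

Two independently refined subcomplex populations (tauA and tauB) co-occur
on the same micrographs whenever both lobes of a complex were picked.  To
recover which tauA and tauB particles belong to the same complex without
any image-level information, particles are paired per micrograph by an
iterative nearest-neighbor search: among all remaining cross pairs the
spatially closest A-B pair is matched first, both particles are removed,
and the search repeats.  The resulting inter-particle distance
distribution is compared against a null model in which particle counts
per micrograph are preserved but XY coordinates are redrawn uniformly
over the micrograph field, which destroys any physical linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .particle_io import ConfigurationError, ParticleRecord, ParticleTable

logger = logging.getLogger("taumap")

#: Default micrograph extent in A: Gatan K3 sensor (5760 x 4092 px) at the
#: 0.822 A effective pixel size used for data collection.
K3_FIELD_EXTENT = (5760 * 0.822, 4092 * 0.822)

MODE_UNDEFINED = float("nan")


@dataclass(frozen=True)
class ParticlePair:
    """A matched tauA/tauB particle pair on one micrograph."""

    micrograph_id: str
    idA: str
    idB: str
    distance: float
    rel_orientation: object | None = None
    eulerA: tuple[float, float, float] | None = None
    eulerB: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("pair distance must be >= 0")


@dataclass
class PairingResult:
    pairs: list[ParticlePair]
    unpaired_A: int
    unpaired_B: int


@dataclass
class DistanceDistribution:
    """Histogram of pair distances with the modal bin center."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n: int
    mode: float  # NaN when undefined (empty distribution)

    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class NullDistribution(DistanceDistribution):
    n_replicates: int = 0
    seed: int = 0


@dataclass
class EnrichmentReport:
    """Per-bin observed/null count ratio with called peak intervals."""

    bin_edges: np.ndarray
    ratio: np.ndarray          # +inf where null empty but observed > 0
    peak_intervals: list[tuple[float, float]]  # [start_A, end_A) intervals
    factor: float


def pair_particles_xy(
    xyA: np.ndarray,
    xyB: np.ndarray,
    idsA: list[str],
    idsB: list[str],
    max_distance: float | None = None,
) -> list[tuple[int, int, float]]:
    """Greedy global min-distance matching between two coordinate sets.

    Sorts all cross pairs by (distance, idA, idB) and sweeps, skipping
    already-used particles: equivalent to iteratively selecting the
    minimum-distance pair and removing both, with deterministic lexical
    tie-breaking.  Returns (iA, iB, distance) index triples.
    """
    if len(xyA) == 0 or len(xyB) == 0:
        return []
    dmat = cdist(xyA, xyB)
    order = sorted(
        ((dmat[i, j], idsA[i], idsB[j], i, j)
         for i in range(len(xyA)) for j in range(len(xyB))),
        key=lambda t: (t[0], t[1], t[2]),
    )
    usedA: set[int] = set()
    usedB: set[int] = set()
    out: list[tuple[int, int, float]] = []
    n_max = min(len(xyA), len(xyB))
    for d, _ia, _ib, i, j in order:
        if max_distance is not None and d > max_distance:
            break
        if i in usedA or j in usedB:
            continue
        out.append((i, j, float(d)))
        usedA.add(i)
        usedB.add(j)
        if len(out) == n_max:
            break
    return out


def pair_particles(
    tableA: ParticleTable,
    tableB: ParticleTable,
    max_distance: float | None = None,
) -> PairingResult:
    """Pair tauA and tauB particles per micrograph by iterative nearest-neighbor search.

    The spatially closest remaining A-B pair is matched first and both
    particles are excluded from later iterations.  Without a cutoff each
    micrograph yields min(nA, nB) pairs; micrographs present in only one
    table contribute zero pairs and count as unpaired.  Euler triplets of
    both particles are carried on each pair for the orientation stage.
    """
    groupsA = tableA.by_micrograph()
    groupsB = tableB.by_micrograph()
    pairs: list[ParticlePair] = []
    unpaired_A = unpaired_B = 0
    for mic in sorted(set(groupsA) | set(groupsB)):
        recsA = groupsA.get(mic, [])
        recsB = groupsB.get(mic, [])
        if not recsA or not recsB:
            unpaired_A += len(recsA)
            unpaired_B += len(recsB)
            continue
        xyA = np.array([[r.x, r.y] for r in recsA])
        xyB = np.array([[r.x, r.y] for r in recsB])
        matches = pair_particles_xy(
            xyA, xyB,
            [r.particle_id for r in recsA],
            [r.particle_id for r in recsB],
            max_distance=max_distance,
        )
        for i, j, d in matches:
            a, b = recsA[i], recsB[j]
            pairs.append(
                ParticlePair(
                    micrograph_id=mic,
                    idA=a.particle_id,
                    idB=b.particle_id,
                    distance=d,
                    eulerA=(a.rot, a.tilt, a.psi),
                    eulerB=(b.rot, b.tilt, b.psi),
                )
            )
        unpaired_A += len(recsA) - len(matches)
        unpaired_B += len(recsB) - len(matches)
    return PairingResult(pairs=pairs, unpaired_A=unpaired_A, unpaired_B=unpaired_B)


def distance_distribution(
    pairs: list[ParticlePair],
    bin_width: float = 8.0,
    range_: tuple[float, float] = (0.0, 600.0),
) -> DistanceDistribution:
    """Histogram pair distances on uniform half-open bins [lo, hi).

    The mode is the center of the maximum-count bin; on ties the lower bin
    wins (logged).  An empty pair list yields an all-zero histogram with a
    NaN mode sentinel.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lo, hi = range_
    edges = np.arange(lo, hi + bin_width, bin_width)
    distances = np.array([p.distance for p in pairs], dtype=float)
    counts, _ = np.histogram(distances, bins=edges)
    n = len(pairs)
    if n == 0 or counts.max() == 0:
        mode = MODE_UNDEFINED
    else:
        imax = int(np.argmax(counts))  # argmax returns first (lowest) on ties
        if np.count_nonzero(counts == counts[imax]) > 1:
            logger.info("distance_distribution: modal bin tie, lower bin reported")
        mode = float(0.5 * (edges[imax] + edges[imax + 1]))
    return DistanceDistribution(bin_edges=edges, counts=counts, n=n, mode=mode)


def randomized_null(
    tableA: ParticleTable,
    tableB: ParticleTable,
    n_replicates: int = 10,
    seed: int = 0,
    field_extent: tuple[float, float] | None = None,
    bin_width: float = 8.0,
    range_: tuple[float, float] = (0.0, 600.0),
    max_distance: float | None = None,
) -> NullDistribution:
    """Distance distribution of unrelated particles.

    For each replicate every particle's XY coordinates are redrawn
    uniformly over the micrograph field while the number of particles per
    micrograph is kept exactly as observed; the same pairing search is
    then rerun and distances accumulated.
    """
    if field_extent is None:
        field_extent = tableA.field_extent() or tableB.field_extent()
    if field_extent is None:
        raise ConfigurationError(
            "randomized_null requires a field extent (from tables or argument)"
        )
    w, h = field_extent
    rng = np.random.default_rng(seed)
    groupsA = tableA.by_micrograph()
    groupsB = tableB.by_micrograph()
    lo, hi = range_
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1, dtype=int)
    n_total = 0
    for _ in range(n_replicates):
        for mic in sorted(set(groupsA) | set(groupsB)):
            nA = len(groupsA.get(mic, []))
            nB = len(groupsB.get(mic, []))
            if nA == 0 or nB == 0:
                continue
            xyA = rng.uniform((0, 0), (w, h), size=(nA, 2))
            xyB = rng.uniform((0, 0), (w, h), size=(nB, 2))
            idsA = [f"nA{i}" for i in range(nA)]
            idsB = [f"nB{i}" for i in range(nB)]
            matches = pair_particles_xy(xyA, xyB, idsA, idsB, max_distance=max_distance)
            assert len(matches) <= min(nA, nB)
            d = np.array([m[2] for m in matches])
            c, _ = np.histogram(d, bins=edges)
            counts += c
            n_total += len(d)
    if n_total == 0 or counts.max() == 0:
        mode = MODE_UNDEFINED
    else:
        imax = int(np.argmax(counts))
        mode = float(0.5 * (edges[imax] + edges[imax + 1]))
    return NullDistribution(
        bin_edges=edges, counts=counts, n=n_total, mode=mode,
        n_replicates=n_replicates, seed=seed,
    )


def enrichment_report(
    observed: DistanceDistribution,
    null: DistanceDistribution,
    factor: float = 2.0,
    min_run: int = 2,
) -> EnrichmentReport:
    """Per-bin observed/null ratio with the null rescaled to the observed total.

    A peak is called where the ratio exceeds ``factor`` over at least
    ``min_run`` consecutive bins.  Bins where the null is empty but the
    observed count is positive get a +inf ratio sentinel (logged).
    """
    if observed.bin_edges.shape != null.bin_edges.shape or not np.allclose(
        observed.bin_edges, null.bin_edges
    ):
        raise ValueError("observed and null distributions must share binning")
    scale = observed.n / null.n if null.n > 0 else np.nan
    expected = null.counts * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = observed.counts / expected
    ratio = np.where((expected == 0) & (observed.counts > 0), np.inf, ratio)
    ratio = np.where((expected == 0) & (observed.counts == 0), 1.0, ratio)
    if np.isinf(ratio).any():
        logger.info("enrichment_report: empty null bin with observed counts (+inf)")

    peaks: list[tuple[float, float]] = []
    above = ratio > factor
    i = 0
    edges = observed.bin_edges
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            if j - i >= min_run:
                peaks.append((float(edges[i]), float(edges[j])))
            i = j
        else:
            i += 1
    return EnrichmentReport(
        bin_edges=edges, ratio=ratio, peak_intervals=peaks, factor=factor
    )
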