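"""Seeded generators for every input the pipeline consumes.

Three families of synthetic data emulate the study conditions:

* **Particle fields** — micrographs on which tauA/tauB particle pairs are
  planted at a mean separation of 168 A (with jitter) and with a fixed
  relative orientation (d_alpha, d_beta, d_gamma) ~ (15, 128, -103)
  degrees perturbed by small random rotations, on top of unpaired
  background particles with uniform positions and orientations.
* **Dwell times / traces** — TFIIIC-bound dwell durations drawn from one-
  or two-component exponential mixtures, observed at a 200 ms frame time
  (ceiling-quantized, hence left-truncated at one frame), and two-channel
  donor/acceptor fluorescence traces with Markovian FRET-state switching
  and single-step donor bleaching.
* **Gene sets** — tRNA-like genes with an instantiated A-box consensus
  (TNGNNNANNNG), a linker of variable length (31-93 bp, mode 32), a
  B-box, and background sequence drawn from the stated genomic base
  frequencies, with occasional planted upstream pseudo-A-boxes.

All generators are deterministic given their config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dwell_kinetics import DwellRecord, Trace
from .orientation import (
    EulerTriplet,
    RelativeOrientation,
    euler_to_matrix,
    matrix_to_euler,
)
from .pair_mapping import K3_FIELD_EXTENT
from .particle_io import ParticleRecord, ParticleTable
from .promoter_motifs import (
    A_BOX_CONSENSUS,
    TRNA_HIS_B_BOX,
    PromoterGene,
    index_to_pos,
)

#: Genomic background nucleotide frequencies (A, C, G, T) used throughout.
BACKGROUND_FREQS = (0.325, 0.176, 0.175, 0.324)

_BASES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class FieldSimConfig:
    """Planted particle-field geometry (defaults are the study conditions)."""

    n_micrographs: int = 100
    field_width: float = K3_FIELD_EXTENT[0]
    field_height: float = K3_FIELD_EXTENT[1]
    pairs_per_micrograph: int = 20
    mean_separation: float = 168.0
    separation_sd: float = 10.0
    planted_rel_orientation: RelativeOrientation = field(
        default_factory=lambda: RelativeOrientation(15.0, 128.0, -103.0)
    )
    angular_noise_sd: float = 15.0
    background_A: int = 10
    background_B: int = 10
    detection_rate: float = 1.0
    pixel_size: float = 0.822
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_micrographs, self.pairs_per_micrograph,
               self.background_A, self.background_B) < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.detection_rate <= 1.0:
            raise ValueError("detection_rate must be in [0, 1]")
        if min(self.field_width, self.field_height) <= 2 * self.mean_separation:
            raise ValueError("field extent must exceed 2x mean_separation")


@dataclass
class DwellSimConfig:
    """Exponential-mixture dwell model observed at a camera frame time.

    ``frame_time=None`` yields continuous (unquantized) durations.
    """

    n_dwells: int = 10_000
    lifetimes: Sequence[float] = (1.2, 49.0)
    weights: Sequence[float] = (0.615, 0.385)
    frame_time: float | None = 0.2
    censor_at: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lifetimes) != len(self.weights):
            raise ValueError("lifetimes and weights must have equal length")
        if any(t <= 0 for t in self.lifetimes):
            raise ValueError("lifetimes must be > 0")
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("weights must sum to 1")


@dataclass
class TraceSimConfig:
    """Two-channel donor/acceptor trace model with Markov FRET switching."""

    n_traces: int = 100
    trace_length: int = 600           # frames
    frame_time: float = 0.2           # s
    binding_rate: float = 0.05        # s^-1
    dwell_model: DwellSimConfig = field(
        default_factory=lambda: DwellSimConfig(frame_time=None)
    )
    fret_state_means: Sequence[float] = (0.3, 0.7)
    fret_state_sds: Sequence[float] = (0.05, 0.05)
    fret_transition_rate: float = 0.5  # s^-1
    donor_bleach_mean: float = 200.0   # s
    total_intensity: float = 1.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 <= m <= 1.0 for m in self.fret_state_means):
            raise ValueError("FRET state means must lie in [0, 1]")
        if self.binding_rate < 0 or self.fret_transition_rate < 0:
            raise ValueError("rates must be >= 0")


def default_linker_distribution() -> dict[int, float]:
    """Linker-length distribution over 31-93 bp, sharply peaked at 32.

    P(31) = 0.05, P(32) = 0.45 and a geometric-like tail over 33-93
    carrying the remaining mass, reflecting that 32 bp is by far the most
    common A/B-box distance while lengths up to 93 bp occur.
    """
    lengths = np.arange(33, 94)
    tail = np.exp(-(lengths - 33) / 10.0)
    tail = 0.5 * tail / tail.sum()
    dist = {31: 0.05, 32: 0.45}
    dist.update({int(l): float(p) for l, p in zip(lengths, tail)})
    return dist


@dataclass
class GeneSimConfig:
    """tRNA-like gene-set model with planted promoter boxes."""

    n_genes: int = 300
    a_box_consensus: str = A_BOX_CONSENSUS
    b_box: str = TRNA_HIS_B_BOX
    linker_lengths: dict[int, float] = field(default_factory=default_linker_distribution)
    upstream_length: int = 100
    leader_length: int = 7            # nt between the +1 TSS block start and the A-box
    downstream_length: int = 15
    pseudo_box_prob: float = 0.05
    base_frequencies: tuple[float, float, float, float] = BACKGROUND_FREQS
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.base_frequencies), 1.0):
            raise ValueError("base frequencies must sum to 1")
        total = sum(self.linker_lengths.values())
        if not np.isclose(total, 1.0):
            raise ValueError("linker length distribution must sum to 1")
        if any(not 31 <= l <= 93 for l in self.linker_lengths):
            raise ValueError("linker support must lie within [31, 93]")


# ---------------------------------------------------------------------------
# particle fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruePair:
    """Ground-truth record for one planted tauA/tauB pair."""

    micrograph_id: str
    idA: str
    idB: str
    separation: float        # sampled center-to-center distance, A
    detectedA: bool
    detectedB: bool


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _small_rotation(rng: np.random.Generator, magnitude_sd_deg: float) -> np.ndarray:
    """Rotation about a uniform random axis by an angle ~ N(0, sd) degrees."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(0.0, magnitude_sd_deg))
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _record_from_matrix(
    pid: str, mic: str, x: float, y: float, R: np.ndarray, subcomplex: str
) -> ParticleRecord:
    e, _ = matrix_to_euler(R)
    return ParticleRecord(
        particle_id=pid, micrograph_id=mic, x=x, y=y,
        rot=e.alpha, tilt=e.beta, psi=e.gamma, subcomplex=subcomplex,
    )


def gen_particle_fields(
    cfg: FieldSimConfig,
) -> tuple[ParticleTable, ParticleTable, list[TruePair]]:
    """Generate tauA/tauB particle tables with planted pair geometry.

    Per micrograph: each pair's tauB particle is placed uniformly in the
    field with a uniform in-plane direction angle; the tauA partner sits
    at a distance ~ N(mean_separation, separation_sd) along that
    direction (positions are redrawn until both particles fall inside the
    field).  tauB orientations are uniform on SO(3); the tauA orientation
    is R_r^-1 @ RB (so that RB @ RA^-1 equals the planted relative
    orientation) perturbed by a small random rotation of normally
    distributed magnitude.  Background particles are uniform in position
    and orientation.  Each planted particle is observed with probability
    ``detection_rate``; ground truth records every planted pair with the
    sampled separation and detection flags.
    """
    rng = np.random.default_rng(cfg.seed)
    planted = cfg.planted_rel_orientation
    Rr = euler_to_matrix(
        EulerTriplet(planted.d_alpha, planted.d_beta, planted.d_gamma)
    )
    w, h = cfg.field_width, cfg.field_height

    recsA: list[ParticleRecord] = []
    recsB: list[ParticleRecord] = []
    truth: list[TruePair] = []
    for m in range(cfg.n_micrographs):
        mic = f"mic{m:04d}.mrc"
        for p in range(cfg.pairs_per_micrograph):
            while True:
                xb, yb = rng.uniform(0, w), rng.uniform(0, h)
                theta = rng.uniform(0, 2 * np.pi)
                sep = rng.normal(cfg.mean_separation, cfg.separation_sd)
                xa = xb + sep * np.cos(theta)
                ya = yb + sep * np.sin(theta)
                if 0 <= xa <= w and 0 <= ya <= h and sep > 0:
                    break
            RB = _random_rotation(rng)
            RA = Rr.T @ RB
            if cfg.angular_noise_sd > 0:
                RA = _small_rotation(rng, cfg.angular_noise_sd) @ RA
            idA = f"tauA_{m:04d}_{p:04d}"
            idB = f"tauB_{m:04d}_{p:04d}"
            detA = bool(rng.random() < cfg.detection_rate)
            detB = bool(rng.random() < cfg.detection_rate)
            if detA:
                recsA.append(_record_from_matrix(idA, mic, xa, ya, RA, "tauA"))
            if detB:
                recsB.append(_record_from_matrix(idB, mic, xb, yb, RB, "tauB"))
            truth.append(TruePair(mic, idA, idB, float(sep), detA, detB))
        for b in range(cfg.background_A):
            recsA.append(_record_from_matrix(
                f"bgA_{m:04d}_{b:04d}", mic,
                rng.uniform(0, w), rng.uniform(0, h),
                _random_rotation(rng), "tauA",
            ))
        for b in range(cfg.background_B):
            recsB.append(_record_from_matrix(
                f"bgB_{m:04d}_{b:04d}", mic,
                rng.uniform(0, w), rng.uniform(0, h),
                _random_rotation(rng), "tauB",
            ))
    tableA = ParticleTable(recsA, pixel_size=cfg.pixel_size,
                           field_width=w, field_height=h)
    tableB = ParticleTable(recsB, pixel_size=cfg.pixel_size,
                           field_width=w, field_height=h)
    return tableA, tableB, truth


# ---------------------------------------------------------------------------
# dwells and traces
# ---------------------------------------------------------------------------

def gen_dwells(cfg: DwellSimConfig, construct: str = "A/B") -> list[DwellRecord]:
    """Draw dwell times from the configured exponential mixture.

    Components are chosen by weight; durations are exponential with the
    component lifetime.  With a frame time set, durations are rounded up
    to whole frames (every observed dwell spans at least one frame).
    Dwells exceeding ``censor_at`` are cut there and flagged censored.
    The generating component index is recorded on each dwell as ground
    truth.
    """
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.lifetimes)
    components = rng.choice(k, size=cfg.n_dwells, p=np.asarray(cfg.weights))
    durations = rng.exponential(np.asarray(cfg.lifetimes)[components])
    if cfg.frame_time is not None:
        durations = np.ceil(durations / cfg.frame_time) * cfg.frame_time
    censored = np.zeros(cfg.n_dwells, dtype=bool)
    if cfg.censor_at is not None:
        censored = durations > cfg.censor_at
        durations = np.minimum(durations, cfg.censor_at)
    return [
        DwellRecord(duration=float(d), construct=construct,
                    censored=bool(c), component=int(comp))
        for d, c, comp in zip(durations, censored, components)
    ]


def gen_traces(cfg: TraceSimConfig) -> list[Trace]:
    """Simulate two-channel (donor, acceptor) fluorescence traces.

    The molecule alternates between unbound intervals (exponential with
    ``binding_rate``) and bound dwells drawn from the dwell model.
    Within a bound dwell the FRET efficiency switches between the
    configured states at ``fret_transition_rate`` (Markovian, uniform
    among the other states); the state's efficiency E partitions a
    constant total intensity into donor (1-E) and acceptor (E) channels.
    Unbound frames emit full donor intensity and no acceptor signal.  A
    single-step donor bleach at an exponential time ends the usable
    trace; Gaussian noise is added to both channels throughout.
    """
    rng = np.random.default_rng(cfg.seed)
    n_states = len(cfg.fret_state_means)
    traces: list[Trace] = []
    for _ in range(cfg.n_traces):
        total_t = cfg.trace_length * cfg.frame_time
        efficiency = np.full(cfg.trace_length, np.nan)  # NaN = unbound
        bound_intervals: list[tuple[int, int]] = []
        t = 0.0
        while t < total_t and cfg.binding_rate > 0:
            t += rng.exponential(1.0 / cfg.binding_rate)
            if t >= total_t:
                break
            comp = rng.choice(len(cfg.dwell_model.lifetimes),
                              p=np.asarray(cfg.dwell_model.weights))
            dwell = rng.exponential(cfg.dwell_model.lifetimes[comp])
            start_f = int(t / cfg.frame_time)
            end_f = min(int(np.ceil((t + dwell) / cfg.frame_time)), cfg.trace_length)
            if end_f > start_f:
                bound_intervals.append((start_f, end_f))
                state = int(rng.integers(n_states))
                f = start_f
                while f < end_f:
                    if cfg.fret_transition_rate > 0 and n_states > 1:
                        run = rng.exponential(1.0 / cfg.fret_transition_rate)
                        run_f = max(1, int(np.ceil(run / cfg.frame_time)))
                    else:
                        run_f = end_f - f
                    stop = min(f + run_f, end_f)
                    e = float(np.clip(
                        rng.normal(cfg.fret_state_means[state],
                                   cfg.fret_state_sds[state]), 0.0, 1.0))
                    efficiency[f:stop] = e
                    if n_states > 1:
                        others = [s for s in range(n_states) if s != state]
                        state = int(rng.choice(others))
                    f = stop
            t += dwell
        bleach_t = rng.exponential(cfg.donor_bleach_mean)
        bleach_f = min(int(bleach_t / cfg.frame_time), cfg.trace_length)

        donor = np.where(np.isnan(efficiency),
                         cfg.total_intensity,
                         cfg.total_intensity * (1.0 - efficiency))
        acceptor = np.where(np.isnan(efficiency),
                            0.0,
                            cfg.total_intensity * efficiency)
        donor[bleach_f:] = 0.0
        acceptor[bleach_f:] = 0.0
        if cfg.noise_sd > 0:
            donor = donor + rng.normal(0, cfg.noise_sd, cfg.trace_length)
            acceptor = acceptor + rng.normal(0, cfg.noise_sd, cfg.trace_length)
        bound_intervals = [(s, min(e, bleach_f)) for s, e in bound_intervals
                           if s < bleach_f]
        traces.append(Trace(
            frame_time=cfg.frame_time,
            donor=donor,
            acceptor=acceptor,
            bound_intervals=bound_intervals,
            bleach_frame=bleach_f,
        ))
    return traces


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueGene:
    """Ground truth for one generated gene."""

    gene_id: str
    a_box: tuple[int, int]
    b_box: tuple[int, int]
    linker_length: int
    pseudo_planted: bool
    pseudo_interval: tuple[int, int] | None   # gene coords, None if not planted


def _random_seq(rng: np.random.Generator, n: int, freqs) -> str:
    return "".join(rng.choice(_BASES, size=n, p=np.asarray(freqs)))


def _instantiate_consensus(rng: np.random.Generator, consensus: str, freqs) -> str:
    return "".join(
        c if c != "N" else str(rng.choice(_BASES, p=np.asarray(freqs)))
        for c in consensus
    )


def gen_gene_set(
    cfg: GeneSimConfig,
) -> tuple[list[PromoterGene], list[TrueGene]]:
    """Generate tRNA-like genes with annotated promoter boxes.

    Layout of each gene (5'->3' on the non-template strand): upstream
    background (``upstream_length`` nt, optionally carrying a planted
    pseudo-A-box), the +1 transcription start (always G) and a short
    leader, the A-box instantiated from the consensus, a linker of
    sampled length, the B-box, and downstream background.  A planted
    pseudo-box is an instantiated consensus written into the region
    upstream of the A-box with a gap of 0-18 nt to the A-box start, so it
    always survives the <30 nt proximity filter.  Annotations record the
    true intervals in gene-internal coordinates.
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = np.array(sorted(cfg.linker_lengths), dtype=int)
    probs = np.array([cfg.linker_lengths[int(l)] for l in lengths])
    box_len = len(cfg.a_box_consensus)
    genes: list[PromoterGene] = []
    truth: list[TrueGene] = []
    for g in range(cfg.n_genes):
        gene_id = f"synth_tRNA_{g:04d}"
        linker_len = int(rng.choice(lengths, p=probs))
        a_box_seq = _instantiate_consensus(rng, cfg.a_box_consensus,
                                           cfg.base_frequencies)
        upstream = _random_seq(rng, cfg.upstream_length, cfg.base_frequencies)
        leader = "G" + _random_seq(rng, cfg.leader_length - 1, cfg.base_frequencies)
        linker = _random_seq(rng, linker_len, cfg.base_frequencies)
        downstream = _random_seq(rng, cfg.downstream_length, cfg.base_frequencies)
        seq = upstream + leader + a_box_seq + linker + cfg.b_box + downstream

        tss_index = cfg.upstream_length
        a_start_idx = tss_index + cfg.leader_length
        b_start_idx = a_start_idx + box_len + linker_len

        pseudo_planted = bool(rng.random() < cfg.pseudo_box_prob)
        pseudo_interval = None
        if pseudo_planted:
            gap = int(rng.integers(0, 19))
            p_end_idx = a_start_idx - gap - 1
            p_start_idx = p_end_idx - box_len + 1
            pseudo_seq = _instantiate_consensus(rng, cfg.a_box_consensus,
                                                cfg.base_frequencies)
            seq = seq[:p_start_idx] + pseudo_seq + seq[p_end_idx + 1:]
            pseudo_interval = (
                index_to_pos(p_start_idx, tss_index),
                index_to_pos(p_end_idx, tss_index),
            )
        a_box = (index_to_pos(a_start_idx, tss_index),
                 index_to_pos(a_start_idx + box_len - 1, tss_index))
        b_box = (index_to_pos(b_start_idx, tss_index),
                 index_to_pos(b_start_idx + box_len - 1, tss_index))
        genes.append(PromoterGene(
            gene_id=gene_id, sequence=seq, tss_index=tss_index,
            a_box=a_box, b_box=b_box,
        ))
        truth.append(TrueGene(
            gene_id=gene_id, a_box=a_box, b_box=b_box,
            linker_length=linker_len,
            pseudo_planted=pseudo_planted, pseudo_interval=pseudo_interval,
        ))
    return genes, truth
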