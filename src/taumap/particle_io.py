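"""STAR-format particle table I/O.

Cryo-EM pipelines exchange per-particle metadata (micrograph of origin,
picked coordinates, refined Euler angles) as STAR files.  This module reads
and writes the subset of the RELION particle-table dialect needed for
single-particle pair mapping and holds the shared in-memory data model.

Coordinates are stored internally in Angstroms: STAR ``rlnCoordinateX/Y``
values are in pixels and are converted at read time using the pixel size
from the optics table (RELION 3.1+) or an explicit override.  Euler angles
(rot, tilt, psi) stay in degrees and are canonicalized so every orientation
has a unique triplet representation: rot/psi in (-180, 180], tilt in
[0, 180].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger("taumap")

# Column names of the RELION particle-table dialect we consume/emit.
_COL_MICROGRAPH = "_rlnMicrographName"
_COL_X = "_rlnCoordinateX"
_COL_Y = "_rlnCoordinateY"
_COL_ROT = "_rlnAngleRot"
_COL_TILT = "_rlnAngleTilt"
_COL_PSI = "_rlnAnglePsi"
_COL_PIXEL_SIZE = "_rlnImagePixelSize"

PAIR_TSV_COLUMNS = [
    "micrograph_id",
    "idA",
    "idB",
    "distance_A",
    "d_alpha",
    "d_beta",
    "d_gamma",
]


class StarFormatError(ValueError):
    """Raised when a STAR file lacks a required column or particle loop."""


class ConfigurationError(ValueError):
    """Raised when required configuration (e.g. pixel size) is unavailable."""


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees into the canonical (-180, 180] range."""
    wrapped = float(np.mod(deg, 360.0))
    if wrapped > 180.0:
        wrapped -= 360.0
    # np.mod can return exactly -180.0 only via wrapped==180 path; ensure +180 kept
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


@dataclass(frozen=True)
class ParticleRecord:
    """One picked and refined particle of a single subcomplex population.

    ``x``/``y`` are in Angstroms; ``rot``/``tilt``/``psi`` are the RELION
    Euler angles alpha/beta/gamma in degrees.  ``subcomplex`` labels which
    lobe of the two-lobed complex the particle belongs to (``tauA`` binds
    the A-box, ``tauB`` the B-box).
    """

    particle_id: str
    micrograph_id: str
    x: float
    y: float
    rot: float
    tilt: float
    psi: float
    subcomplex: str = "tauA"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("particle coordinates must be finite")
        if not 0.0 <= self.tilt <= 180.0:
            raise ValueError(f"tilt {self.tilt} outside [0, 180]")

    def canonical(self) -> "ParticleRecord":
        """Return a copy with rot/psi wrapped into (-180, 180]."""
        return replace(self, rot=wrap_angle(self.rot), psi=wrap_angle(self.psi))


@dataclass
class ParticleTable:
    """A set of particles of one subcomplex population, grouped by micrograph."""

    records: list[ParticleRecord] = field(default_factory=list)
    pixel_size: float = 1.0
    field_width: float | None = None   # micrograph extent in A
    field_height: float | None = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.field_width is not None or self.field_height is not None:
            w = self.field_width if self.field_width is not None else np.inf
            h = self.field_height if self.field_height is not None else np.inf
            for r in self.records:
                if not (0.0 <= r.x <= w and 0.0 <= r.y <= h):
                    raise ValueError(
                        f"particle {r.particle_id} at ({r.x}, {r.y}) outside "
                        f"field extent ({w}, {h})"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def by_micrograph(self) -> dict[str, list[ParticleRecord]]:
        groups: dict[str, list[ParticleRecord]] = {}
        for r in self.records:
            groups.setdefault(r.micrograph_id, []).append(r)
        return groups

    @property
    def micrograph_ids(self) -> list[str]:
        return sorted(self.by_micrograph())

    def field_extent(self) -> tuple[float, float] | None:
        if self.field_width is None or self.field_height is None:
            return None
        return (self.field_width, self.field_height)


def _find_particle_block(doc: "gemmi.cif.Document") -> "gemmi.cif.Block":
    required = [_COL_MICROGRAPH, _COL_X, _COL_Y]
    for block in doc:
        if all(block.find_loop(tag) for tag in required):
            return block
        # A block can also contain the loop columns without values; find()
        # below handles missing columns explicitly.
        if block.find_loop(_COL_X):
            return block
    raise StarFormatError(
        "no particle data loop found (need micrograph name and X/Y coordinates)"
    )


def _read_pixel_size(doc: "gemmi.cif.Document") -> float | None:
    for block in doc:
        loop_vals = block.find_loop(_COL_PIXEL_SIZE)
        vals = list(loop_vals)
        if vals:
            return float(vals[0])
        item = block.find_value(_COL_PIXEL_SIZE)
        if item is not None:
            return float(item)
    return None


def read_star(
    path: str | Path,
    pixel_size_override: float | None = None,
    subcomplex: str = "tauA",
) -> ParticleTable:
    """Read a RELION-style particle STAR file into a :class:`ParticleTable`.

    Accepts both the legacy single-block layout and the RELION 3.1+ layout
    with a separate ``data_optics`` block.  Pixel size is taken from the
    optics table when present, else from ``pixel_size_override``.
    Coordinates are converted from pixels to Angstroms; angles are wrapped
    to canonical ranges.
    """
    path = Path(path)
    doc = gemmi.cif.read_file(str(path))
    pixel_size = _read_pixel_size(doc)
    if pixel_size is None:
        pixel_size = pixel_size_override
    if pixel_size is None:
        raise ConfigurationError(
            f"{path}: no pixel size in optics table and no override supplied"
        )

    block = _find_particle_block(doc)
    cols = [_COL_MICROGRAPH, _COL_X, _COL_Y, _COL_ROT, _COL_TILT, _COL_PSI]
    columns = {}
    n_rows = 0
    for tag in cols:
        col = block.find_loop(tag)
        if not col:  # distinguishes a missing column from an empty loop
            raise StarFormatError(f"{path}: missing required column {tag}")
        columns[tag] = list(col)
        n_rows = len(columns[tag])

    records = []
    for i in range(n_rows):
        records.append(
            ParticleRecord(
                particle_id=f"{subcomplex}_{i:06d}",
                micrograph_id=columns[_COL_MICROGRAPH][i],
                x=float(columns[_COL_X][i]) * pixel_size,
                y=float(columns[_COL_Y][i]) * pixel_size,
                rot=wrap_angle(float(columns[_COL_ROT][i])),
                tilt=float(columns[_COL_TILT][i]),
                psi=wrap_angle(float(columns[_COL_PSI][i])),
                subcomplex=subcomplex,
            )
        )
    if not records:
        warnings.warn(f"{path}: empty particle loop", stacklevel=2)
    return ParticleTable(records=records, pixel_size=pixel_size)


def write_star(table: ParticleTable, path: str | Path) -> None:
    """Write a :class:`ParticleTable` as a RELION 3.1+ style STAR file.

    Coordinates are converted back to pixels using ``table.pixel_size``.
    Rows are stable-sorted by (micrograph_id, particle_id) so output is
    deterministic; ``read_star(write_star(t))`` reproduces ``t`` up to
    float formatting (1e-6).
    """
    doc = gemmi.cif.Document()
    optics = doc.add_new_block("optics")
    loop = optics.init_loop("", ["_rlnOpticsGroup", _COL_PIXEL_SIZE])
    loop.add_row(["1", f"{table.pixel_size:.6f}"])

    particle_cols = [_COL_MICROGRAPH, _COL_X, _COL_Y, _COL_ROT, _COL_TILT, _COL_PSI]
    if not table.records:
        # gemmi omits zero-row loops on write; emit the header-only loop by hand
        text = doc.as_string() + "\ndata_particles\n\nloop_\n" + "\n".join(
            particle_cols) + "\n"
        try:
            Path(path).write_text(text)
        except OSError as exc:
            raise IOError(f"cannot write STAR file {path}: {exc}") from exc
        return

    particles = doc.add_new_block("particles")
    loop = particles.init_loop("", particle_cols)
    ordered = sorted(table.records, key=lambda r: (r.micrograph_id, r.particle_id))
    for r in ordered:
        loop.add_row(
            [
                r.micrograph_id,
                f"{r.x / table.pixel_size:.6f}",
                f"{r.y / table.pixel_size:.6f}",
                f"{r.rot:.6f}",
                f"{r.tilt:.6f}",
                f"{r.psi:.6f}",
            ]
        )
    try:
        doc.write_file(str(path))
    except (OSError, RuntimeError) as exc:
        raise IOError(f"cannot write STAR file {path}: {exc}") from exc


def write_pairs_tsv(pairs: Iterable, path: str | Path) -> None:
    """Write matched particle pairs (with optional relative orientation) as TSV."""
    rows = []
    for p in pairs:
        rel = p.rel_orientation
        rows.append(
            {
                "micrograph_id": p.micrograph_id,
                "idA": p.idA,
                "idB": p.idB,
                "distance_A": p.distance,
                "d_alpha": rel.d_alpha if rel is not None else np.nan,
                "d_beta": rel.d_beta if rel is not None else np.nan,
                "d_gamma": rel.d_gamma if rel is not None else np.nan,
            }
        )
    df = pd.DataFrame(rows, columns=PAIR_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)  # str(float) is shortest-repr, exact


def read_pairs_tsv(path: str | Path) -> list:
    """Read a pairs TSV written by :func:`write_pairs_tsv`."""
    from .pair_mapping import ParticlePair
    from .orientation import RelativeOrientation

    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed pairs TSV {path}: {exc}") from exc
    missing = [c for c in PAIR_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pair columns {missing}")
    pairs = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rel = None
            if not (pd.isna(row.d_alpha) or pd.isna(row.d_beta) or pd.isna(row.d_gamma)):
                rel = RelativeOrientation(
                    d_alpha=float(row.d_alpha),
                    d_beta=float(row.d_beta),
                    d_gamma=float(row.d_gamma),
                )
            pairs.append(
                ParticlePair(
                    micrograph_id=str(row.micrograph_id),
                    idA=str(row.idA),
                    idB=str(row.idB),
                    distance=float(row.distance_A),
                    rel_orientation=rel,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    return pairs
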