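"""A-box/B-box annotation and motif scanning on tRNA gene promoters.

RNA polymerase III type II genes carry their promoter inside the
transcribed region: an 11-bp A-box near the 5' end and a B-box further
downstream, separated by a linker of 31-93 bp (32 bp is by far the most
common distance).  This module annotates those boxes on non-template
strand sequences, scans for degenerate A-box consensus matches
(``TNGNNNANNNG``) under a genomic background model, applies the proximity
filter for upstream "pseudo"-A-boxes, and computes linker-length and GC
statistics.

Gene-internal coordinates follow the field convention: 1-based with no
position 0, the transcription start site at +1 and upstream positions
negative (-1 abuts +1).  Internal storage is 0-based; explicit converters
translate between the two.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils import gc_fraction

logger = logging.getLogger("taumap")

#: Degenerate A-box consensus: fixed T, G, A, G at positions 1, 3, 7, 11.
A_BOX_CONSENSUS = "TNGNNNANNNG"

#: tRNA-His B-box (non-template strand).
TRNA_HIS_B_BOX = "GGTTCGATTCT"

#: tRNA-His A-box (non-template strand), matching the consensus.
TRNA_HIS_A_BOX = "TAGTATAGTGG"

VALID_BASES = set("ACGT")
VALID_QUERY = VALID_BASES | {"N"}


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def pos_to_index(pos: int, tss_index: int) -> int:
    """Gene-internal position (1-based, no 0; negative upstream) -> 0-based index."""
    if pos == 0:
        raise ValueError("gene-internal coordinates have no position 0")
    return tss_index + pos - 1 if pos > 0 else tss_index + pos


def index_to_pos(index: int, tss_index: int) -> int:
    """0-based string index -> gene-internal position."""
    off = index - tss_index
    return off + 1 if off >= 0 else off


def interval_length(start: int, end: int) -> int:
    """Length of a gene-coordinate interval, accounting for the missing 0."""
    if start > end:
        raise ValueError("interval start must not exceed end")
    n = end - start + 1
    if start < 0 < end:
        n -= 1  # position 0 does not exist
    return n


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterGene:
    """A non-template strand gene sequence with promoter-box annotations.

    ``a_box``/``b_box`` are (start, end) gene-internal coordinate
    intervals, inclusive; ``tss_index`` is the 0-based index of the +1
    base within ``sequence``.
    """

    gene_id: str
    sequence: str
    tss_index: int
    a_box: tuple[int, int] | None = None
    b_box: tuple[int, int] | None = None
    isotype: str | None = None

    def __post_init__(self) -> None:
        if set(self.sequence) - VALID_BASES:
            raise ValueError("sequence must be over {A, C, G, T}")
        if not 0 <= self.tss_index < len(self.sequence):
            raise ValueError("tss_index outside sequence")
        for box in (self.a_box, self.b_box):
            if box is not None:
                i0 = pos_to_index(box[0], self.tss_index)
                i1 = pos_to_index(box[1], self.tss_index)
                if not (0 <= i0 <= i1 < len(self.sequence)):
                    raise ValueError(f"box {box} outside sequence")
        if self.a_box is not None and self.b_box is not None:
            if pos_to_index(self.a_box[1], self.tss_index) >= pos_to_index(
                self.b_box[0], self.tss_index
            ):
                raise ValueError("A-box must end before the B-box starts")

    def slice_box(self, box: tuple[int, int]) -> str:
        i0 = pos_to_index(box[0], self.tss_index)
        i1 = pos_to_index(box[1], self.tss_index)
        return self.sequence[i0: i1 + 1]


@dataclass(frozen=True)
class MotifQuery:
    """A degenerate DNA pattern over {A, C, G, T, N}."""

    pattern: str = A_BOX_CONSENSUS

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        if set(self.pattern) - VALID_QUERY:
            raise ValueError("pattern may contain only A, C, G, T, N")

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, window: str) -> bool:
        return len(window) == len(self.pattern) and all(
            q == "N" or q == b for q, b in zip(self.pattern, window)
        )

    def fixed_positions(self) -> list[int]:
        """1-based positions of non-N symbols."""
        return [i + 1 for i, c in enumerate(self.pattern) if c != "N"]


@dataclass(frozen=True)
class BackgroundModel:
    """I.i.d. nucleotide background (A, C, G, T frequencies)."""

    freq_A: float = 0.325
    freq_C: float = 0.176
    freq_G: float = 0.175
    freq_T: float = 0.324

    def __post_init__(self) -> None:
        freqs = (self.freq_A, self.freq_C, self.freq_G, self.freq_T)
        if any(f < 0 for f in freqs):
            raise ValueError("frequencies must be >= 0")
        if not math.isclose(sum(freqs), 1.0, abs_tol=1e-9):
            raise ValueError("frequencies must sum to 1")

    def freq(self, base: str) -> float:
        return {"A": self.freq_A, "C": self.freq_C,
                "G": self.freq_G, "T": self.freq_T}[base]

    def match_probability(self, query: MotifQuery) -> float:
        """Probability that a random background window matches the query."""
        p = 1.0
        for c in query.pattern:
            if c != "N":
                p *= self.freq(c)
        return p


@dataclass(frozen=True)
class MotifMatch:
    """One exact (wildcard) motif occurrence on a sequence."""

    gene_id: str
    start: int              # gene-internal coordinate (or 0-based if no TSS context)
    end: int
    matched: str
    distance_to_a_box: int | None = None   # nt strictly between match end and A-box start
    log_odds: float | None = None


# ---------------------------------------------------------------------------
# packaged tRNA-His fixtures
# ---------------------------------------------------------------------------

# Non-template strand sequences of the yeast tH(GUG)E2 (tRNA-His) gene
# constructs.  The 85-bp construct spans -9..+76; the 120-bp constructs span
# -44..+76.  The cryo-EM 120-bp oligo carries a 4-nt TATA-like substitution
# upstream; the WT/mA/mA*mA variants used in transcription assays differ only
# in the -44..+20 window, so their full sequences share the +21..+76 tail.
_SEQ_85 = (
    "TGAAAAGTCGCCATCTTAGTATAGTGGTTAGTACACATCGTTGTGGCCGATGAAACCCT"
    "GGTTCGATTCTAGGAGATGGCATTTT"
)
_SEQ_120_TATA = (
    "GTATTACTCGAGCCCGTATATAAACAGTTCTCCATTGAAAAGTCGCCATCTTAGTATAGTGGT"
    "TAGTACACATCGTTGTGGCCGATGAAACCCTGGTTCGATTCTAGGAGATGGCATTTT"
)
_FRAG_WT = "GTATTACTCGAGCCCGTAATACAACAGTTCTCCATTGAAAAGTCGCCATCTTAGTATAGTGGTT"
_FRAG_MA = "GTATTACTCGAGCCCGTAATACAACAGTTCTCCATTGAAAAGTCGCCATCTAACTATTGTCGTT"
_FRAG_MAMA = "GTATTACTCGAGCCCGTAATACAACAGTTCTCCAATCAAATGTCGCCATCTAACTATTGTCGTT"
_TAIL_21_76 = _SEQ_120_TATA[64:]   # +21..+76, shared by all 120-bp variants

#: Pseudo-A-box of the tRNA-His promoter: the 11-mer ending at the +1 G,
#: matching the consensus at the fixed positions 1, 3, 7 and 11.
TRNA_HIS_PSEUDO_A_BOX = "TTGAAAAGTCG"

_A_BOX_INTERVAL = (8, 18)    # derived by locating TAGTATAGTGG from the +1 G
_B_BOX_INTERVAL = (51, 61)   # derived by locating GGTTCGATTCT


def annotate_trnahis() -> dict[str, PromoterGene]:
    """Packaged tRNA-His promoter fixtures with box annotations.

    Returns the 85-bp construct (``85bp``), the 120-bp cryo-EM construct
    with the TATA-like substitution (``120bp_TATA``), and the full-length
    120-bp WT / mutated-A-box (``mA``) / doubly mutated (``mA*mA``)
    transcription-assay variants.  The A-box interval is +8..+18 and the
    B-box +51..+61 (derived by string search from the printed sequences;
    the mutant A-box keeps the same register).
    """
    fixtures = {
        "85bp": PromoterGene(
            gene_id="tRNA-His_85bp", sequence=_SEQ_85, tss_index=9,
            a_box=_A_BOX_INTERVAL, b_box=_B_BOX_INTERVAL, isotype="His",
        ),
        "120bp_TATA": PromoterGene(
            gene_id="tRNA-His_120bp_TATA", sequence=_SEQ_120_TATA, tss_index=44,
            a_box=_A_BOX_INTERVAL, b_box=_B_BOX_INTERVAL, isotype="His",
        ),
        "120bp_WT": PromoterGene(
            gene_id="tRNA-His_120bp_WT", sequence=_FRAG_WT + _TAIL_21_76,
            tss_index=44,
            a_box=_A_BOX_INTERVAL, b_box=_B_BOX_INTERVAL, isotype="His",
        ),
        "120bp_mA": PromoterGene(
            gene_id="tRNA-His_120bp_mA", sequence=_FRAG_MA + _TAIL_21_76,
            tss_index=44,
            a_box=_A_BOX_INTERVAL, b_box=_B_BOX_INTERVAL, isotype="His",
        ),
        "120bp_mA*mA": PromoterGene(
            gene_id="tRNA-His_120bp_mAmA", sequence=_FRAG_MAMA + _TAIL_21_76,
            tss_index=44,
            a_box=_A_BOX_INTERVAL, b_box=_B_BOX_INTERVAL, isotype="His",
        ),
    }
    # re-derive the hard-coded registers from the WT sequences
    assert fixtures["85bp"].slice_box(_A_BOX_INTERVAL) == TRNA_HIS_A_BOX
    assert fixtures["85bp"].slice_box(_B_BOX_INTERVAL) == TRNA_HIS_B_BOX
    assert fixtures["120bp_WT"].slice_box(_A_BOX_INTERVAL) == TRNA_HIS_A_BOX
    return fixtures


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def scan_motif(
    sequence: str,
    query: MotifQuery | str = A_BOX_CONSENSUS,
    background: BackgroundModel | None = None,
    tss_index: int | None = None,
    gene_id: str = "",
) -> list[MotifMatch]:
    """All windows of ``sequence`` that strictly match the wildcard query.

    Every window whose bases equal the query's non-N symbols is reported
    (forward, non-template strand).  When a background model is given, a
    log-odds score (log2 of the match likelihood ratio over the
    background, summed over fixed positions) is attached.  Coordinates
    are gene-internal when ``tss_index`` is given, else 0-based.
    """
    if isinstance(query, str):
        query = MotifQuery(query)
    background = background or BackgroundModel()
    L = len(query)
    matches: list[MotifMatch] = []
    for i in range(len(sequence) - L + 1):
        window = sequence[i: i + L]
        if query.matches(window):
            log_odds = sum(
                -math.log2(background.freq(c))
                for c in query.pattern if c != "N"
            )
            if tss_index is not None:
                start = index_to_pos(i, tss_index)
                end = index_to_pos(i + L - 1, tss_index)
            else:
                start, end = i, i + L - 1
            matches.append(MotifMatch(
                gene_id=gene_id, start=start, end=end,
                matched=window, log_odds=log_odds,
            ))
    return matches


def scan_gene(
    gene: PromoterGene,
    query: MotifQuery | str = A_BOX_CONSENSUS,
    background: BackgroundModel | None = None,
) -> list[MotifMatch]:
    """Scan a gene's full sequence; attaches the gap to the annotated A-box."""
    if isinstance(query, str):
        query = MotifQuery(query)
    matches = scan_motif(
        gene.sequence, query, background,
        tss_index=gene.tss_index, gene_id=gene.gene_id,
    )
    if gene.a_box is None:
        return matches
    a_start_idx = pos_to_index(gene.a_box[0], gene.tss_index)
    out = []
    for m in matches:
        end_idx = pos_to_index(m.end, gene.tss_index)
        gap = a_start_idx - end_idx - 1 if end_idx < a_start_idx else None
        out.append(MotifMatch(
            gene_id=m.gene_id, start=m.start, end=m.end, matched=m.matched,
            distance_to_a_box=gap, log_odds=m.log_odds,
        ))
    return out


@dataclass
class UpstreamScanSummary:
    matches: list[MotifMatch]
    n_genes_scanned: int
    n_genes_with_match: int           # >= 1 match within max_distance
    n_genes_with_match_secondary: int  # within the secondary threshold
    max_distance: int
    secondary_distance: int


def scan_upstream(
    genes: list[PromoterGene],
    query: MotifQuery | str = A_BOX_CONSENSUS,
    max_distance: int = 30,
    secondary_distance: int = 100,
    background: BackgroundModel | None = None,
) -> UpstreamScanSummary:
    """Pseudo-A-box search upstream of each gene's annotated A-box.

    A match survives when it lies entirely upstream of the A-box and the
    number of nucleotides strictly between the match end and the A-box
    start is < ``max_distance``.  Genes without an A-box annotation are
    skipped with a warning.  Summary counts report genes with at least
    one surviving match at both the primary and secondary thresholds.
    """
    if isinstance(query, str):
        query = MotifQuery(query)
    surviving: list[MotifMatch] = []
    n_scanned = 0
    n_primary = 0
    n_secondary = 0
    for gene in genes:
        if gene.a_box is None:
            warnings.warn(f"{gene.gene_id}: no A-box annotation, skipped",
                          stacklevel=2)
            continue
        n_scanned += 1
        a_start_idx = pos_to_index(gene.a_box[0], gene.tss_index)
        upstream_matches = [
            m for m in scan_gene(gene, query, background)
            if m.distance_to_a_box is not None
        ]
        primary = [m for m in upstream_matches
                   if m.distance_to_a_box < max_distance]
        secondary = [m for m in upstream_matches
                     if m.distance_to_a_box < secondary_distance]
        surviving.extend(primary)
        n_primary += bool(primary)
        n_secondary += bool(secondary)
    return UpstreamScanSummary(
        matches=surviving,
        n_genes_scanned=n_scanned,
        n_genes_with_match=n_primary,
        n_genes_with_match_secondary=n_secondary,
        max_distance=max_distance,
        secondary_distance=secondary_distance,
    )


# ---------------------------------------------------------------------------
# gene statistics
# ---------------------------------------------------------------------------

def linker_length(gene: PromoterGene) -> int:
    """Nucleotides strictly between the A-box end and the B-box start."""
    if gene.a_box is None or gene.b_box is None:
        raise ValueError(f"{gene.gene_id}: both boxes must be annotated")
    a_end = pos_to_index(gene.a_box[1], gene.tss_index)
    b_start = pos_to_index(gene.b_box[0], gene.tss_index)
    if b_start <= a_end:
        raise ValueError(f"{gene.gene_id}: overlapping boxes")
    return b_start - a_end - 1


def gc_content(region: str) -> float:
    """Fraction of G+C in a sequence region."""
    if not region:
        raise ValueError("empty region")
    return float(gc_fraction(region))


def gc_content_by_isotype(
    genes: list[PromoterGene], box: str = "a_box"
) -> dict[str, float]:
    """Mean GC content of the selected box, grouped by tRNA isotype."""
    groups: dict[str, list[float]] = {}
    for g in genes:
        interval = getattr(g, box)
        if interval is None:
            continue
        key = g.isotype or "unknown"
        groups.setdefault(key, []).append(gc_content(g.slice_box(interval)))
    return {k: float(np.mean(v)) for k, v in sorted(groups.items())}


@dataclass
class LinkerDistribution:
    lengths: np.ndarray        # sorted unique linker lengths
    counts: np.ndarray
    mode: int                  # lowest length on ties
    out_of_range: list[str]    # gene ids with linkers outside 31-93 bp


def linker_distribution(genes: list[PromoterGene]) -> LinkerDistribution:
    """Integer histogram of A/B-box linker lengths across genes.

    The mode is the most frequent length (lowest on ties); linkers
    outside the literature range 31-93 bp are included but flagged.
    """
    if not genes:
        raise ValueError("need at least one annotated gene")
    values = [(g.gene_id, linker_length(g)) for g in genes]
    lens = np.array([v for _, v in values])
    uniq, counts = np.unique(lens, return_counts=True)
    mode = int(uniq[np.argmax(counts)])   # argmax -> first (lowest) on ties
    out = [gid for gid, v in values if not 31 <= v <= 93]
    if out:
        logger.info("linker_distribution: %d genes outside 31-93 bp", len(out))
    return LinkerDistribution(lengths=uniq, counts=counts, mode=mode,
                              out_of_range=out)
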