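"""Zero-mismatch anchor mapping, 201-nt region assembly, unique-site catalog.

Coordinate convention
---------------------
Positions in the poly(A)-site region are counted relative to the site with
no position zero: the tail *attachment* base (last transcript-templated
base) is position -1 and the tail *starting* base (genomic base under the
first tail A) is position +1.  The assembled region spans positions
-100..-1 (the anchor / 3'UTR side), +1 (the site base, reported as-is from
the genome), and +2..+101 (the cleaved-off region, 3'COR), 201 nt total in
transcription orientation.  :func:`site_to_index` / :func:`index_to_site`
convert between these signed positions and 0-based array indices.

Genomic coordinates are 1-based inclusive; minus-strand regions are
reverse-complemented so the region string always reads 5'->3' along the
transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io import REGION_LEN, SequenceRecord, SiteTableRow
from .tail_screen import DEFAULT_ANCHOR_LEN, PolyATranscript

UPSTREAM_LEN = 100
DOWNSTREAM_LEN = 101  # site base + 100 nt of 3'COR

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def site_to_index(pos: int) -> int:
    """Signed site-relative position -> 0-based index into the 201-nt region.

    -100 -> 0, -1 -> 99, +1 -> 100, +5 -> 104, +101 -> 200.  Position 0 does
    not exist.
    """
    if pos == 0:
        raise ValueError("position 0 does not exist in the site coordinate system")
    if -UPSTREAM_LEN <= pos <= -1:
        return pos + UPSTREAM_LEN
    if 1 <= pos <= DOWNSTREAM_LEN:
        return pos + UPSTREAM_LEN - 1
    raise ValueError(f"position {pos} outside [-100,-1] U [1,101]")


def index_to_site(index: int) -> int:
    """Inverse of :func:`site_to_index`."""
    if not 0 <= index <= REGION_LEN - 1:
        raise ValueError(f"index {index} outside [0,{REGION_LEN - 1}]")
    if index < UPSTREAM_LEN:
        return index - UPSTREAM_LEN
    return index - UPSTREAM_LEN + 1


def site_positions(start: int, end: int) -> list[int]:
    """All valid site positions in the closed interval [start, end] (skips 0)."""
    if start > end:
        raise ValueError(f"empty window [{start},{end}]")
    return [p for p in range(start, end + 1) if p != 0 and -UPSTREAM_LEN <= p <= DOWNSTREAM_LEN]


@dataclass(frozen=True)
class Locus:
    """One verbatim genomic occurrence of an anchor.

    ``anchor_end_coord`` is the 1-based genomic coordinate of the anchor's
    3'-most base in transcription orientation (for '-' strand loci this is
    the *smallest* genomic coordinate of the match).
    """

    chrom: str
    strand: str
    anchor_end_coord: int


@dataclass(frozen=True)
class SiteRegion:
    """One poly(A) site with its 201-nt region and genomic locus."""

    site_id: str
    chrom: str
    strand: str
    tailstart_coord: int
    region201: str
    n_source_mrnas: int = 1
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if len(self.region201) != REGION_LEN:
            raise ValueError(f"region must be {REGION_LEN} nt, got {len(self.region201)}")

    @property
    def upstream100(self) -> str:
        return self.region201[:UPSTREAM_LEN]

    def to_table_row(self) -> SiteTableRow:
        return SiteTableRow(
            site_id=self.site_id,
            chrom=self.chrom,
            strand=self.strand,
            tailstart_coord=self.tailstart_coord,
            region201=self.region201,
            n_source_mrnas=self.n_source_mrnas,
        )


class GenomeIndex:
    """Exact-substring lookup over a set of chromosomes, both strands.

    Queries return all and only verbatim occurrences (no mismatches, no
    indels); a query containing N never matches anything.
    """

    def __init__(self, chroms: dict[str, str]):
        self.chroms = dict(chroms)

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "GenomeIndex":
        return cls({rec.id: rec.residues for rec in records})

    def find_all(self, query: str) -> list[Locus]:
        """All loci at which ``query`` occurs verbatim, on either strand.

        Deterministic order: chromosomes sorted by name; within a chromosome
        '+' hits by position then '-' hits by position.
        """
        if "N" in query:
            return []
        loci: list[Locus] = []
        rc = revcomp(query)
        for chrom in sorted(self.chroms):
            seq = self.chroms[chrom]
            start = seq.find(query)
            while start != -1:
                loci.append(Locus(chrom, "+", start + len(query)))
                start = seq.find(query, start + 1)
            start = seq.find(rc)
            while start != -1:
                # transcription runs right-to-left; anchor 3' end is the
                # match's leftmost base
                loci.append(Locus(chrom, "-", start + 1))
                start = seq.find(rc, start + 1)
        return loci


@dataclass
class MappingStats:
    """Counts at each mapping-stage filter."""

    n_anchors: int = 0
    n_unmapped: int = 0
    n_multi_locus: int = 0
    n_edge_dropped: int = 0
    n_regions: int = 0
    n_unique_sites: int = 0
    skipped_ids: list = field(default_factory=list)


def map_anchor(index: GenomeIndex, anchor: str, anchor_len: int = DEFAULT_ANCHOR_LEN) -> list[Locus]:
    """Map one anchor with zero tolerance for mismatches."""
    if len(anchor) != anchor_len:
        raise ValueError(f"anchor must be {anchor_len} nt, got {len(anchor)}")
    return index.find_all(anchor)


def assemble_region(
    genome: GenomeIndex, locus: Locus, n_source_mrnas: int = 1
) -> Optional[SiteRegion]:
    """Build the 201-nt region for a mapped locus, or None at contig edges.

    The region is the 100-nt anchor plus the 101 genomic bases that follow
    it in transcription orientation (site base + 100 nt of 3'COR); loci with
    fewer than 101 bases remaining before the contig end are dropped.
    """
    seq = genome.chroms[locus.chrom]
    if locus.strand == "+":
        end0 = locus.anchor_end_coord  # 0-based exclusive end of anchor
        if end0 - UPSTREAM_LEN < 0 or end0 + DOWNSTREAM_LEN > len(seq):
            return None
        region = seq[end0 - UPSTREAM_LEN : end0 + DOWNSTREAM_LEN]
        tailstart = end0 + 1
    else:
        e0 = locus.anchor_end_coord - 1  # 0-based position of anchor 3' base
        if e0 - DOWNSTREAM_LEN < 0 or e0 + UPSTREAM_LEN > len(seq):
            return None
        region = revcomp(seq[e0 - DOWNSTREAM_LEN : e0 + UPSTREAM_LEN])
        tailstart = e0  # 1-based coordinate of the base at site position +1
    site_id = f"{locus.chrom}:{tailstart}:{locus.strand}"
    return SiteRegion(
        site_id=site_id,
        chrom=locus.chrom,
        strand=locus.strand,
        tailstart_coord=tailstart,
        region201=region,
        n_source_mrnas=n_source_mrnas,
    )


def catalog_unique_sites(regions: Sequence[SiteRegion]) -> list[SiteRegion]:
    """Collapse regions sharing an identical upstream-100 sequence.

    One output per distinct upstream sequence; the representative locus is
    the lexicographically smallest (chrom, tailstart_coord, strand);
    n_source_mrnas are summed and the number of collapsed loci recorded as
    multiplicity.  Idempotent; output sorted by representative locus.
    """
    groups: dict[str, list[SiteRegion]] = {}
    for reg in regions:
        groups.setdefault(reg.upstream100, []).append(reg)
    out: list[SiteRegion] = []
    for members in groups.values():
        rep = min(members, key=lambda r: (r.chrom, r.tailstart_coord, r.strand))
        loci = {(r.chrom, r.strand, r.tailstart_coord) for r in members}
        out.append(
            SiteRegion(
                site_id=rep.site_id,
                chrom=rep.chrom,
                strand=rep.strand,
                tailstart_coord=rep.tailstart_coord,
                region201=rep.region201,
                n_source_mrnas=sum(r.n_source_mrnas for r in members),
                multiplicity=max(len(loci), max(r.multiplicity for r in members)),
            )
        )
    out.sort(key=lambda r: (r.chrom, r.tailstart_coord, r.strand))
    return out


def map_transcripts(
    genome: GenomeIndex,
    transcripts: Sequence[PolyATranscript],
    keep_multi_locus: bool = True,
) -> tuple[list[SiteRegion], MappingStats]:
    """Map deduplicated transcripts to regions, with per-stage accounting."""
    stats = MappingStats(n_anchors=len(transcripts))
    regions: list[SiteRegion] = []
    for t in transcripts:
        loci = map_anchor(genome, t.anchor, anchor_len=len(t.anchor))
        if not loci:
            stats.n_unmapped += 1
            stats.skipped_ids.append((t.id, "unmapped"))
            continue
        if len(loci) > 1:
            stats.n_multi_locus += 1
            if not keep_multi_locus:
                stats.skipped_ids.append((t.id, "multi_locus"))
                continue
        for locus in loci:
            reg = assemble_region(genome, locus, n_source_mrnas=t.n_copies)
            if reg is None:
                stats.n_edge_dropped += 1
                continue
            if len(loci) > 1:
                reg = SiteRegion(
                    site_id=reg.site_id,
                    chrom=reg.chrom,
                    strand=reg.strand,
                    tailstart_coord=reg.tailstart_coord,
                    region201=reg.region201,
                    n_source_mrnas=reg.n_source_mrnas,
                    multiplicity=len(loci),
                )
            regions.append(reg)
    stats.n_regions = len(regions)
    return regions, stats
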