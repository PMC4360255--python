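"""Synthetic genome + transcript generator with known ground truth.

Emulates the kind of input the pipeline consumes: a genome carrying genes
whose 201-nt poly(A)-site windows are drawn from a position-specific base
template (U-rich far upstream, an A-rich element with a sharp peak, a
U-rich element closer to the site, a strongly A-biased site base, and a
U-rich downstream region), with a signal hexamer planted at a fixed
distance upstream of the cleavage site in a configurable fraction of genes,
transcripts ending in poly(A) tails, optional transcript redundancy,
optional ORF/UTR structure (including -1/-2 stop/tail-overlap cases), and
an optional internal-priming artifact channel in which reads truncate at a
genomically A-rich stretch and acquire an artificial tail.

Every dataset is a pure function of its spec (seed included): the same spec
yields byte-identical genome, transcripts and truth.

Two template factories are provided: :func:`plant_like_template` (upstream
A peak at -21, U peak at -7, flat U-rich downstream) and
:func:`animal_like_template` (A peak at -18, U peak at -9, pointed
downstream U peak near +19); peak positions and heights are configurable.

The tail-attachment base (position -1) carries zero A probability in both
default templates -- real attachment bases are predominantly U or C -- so a
planted tail is exactly the maximal terminal A-run and the recorded truth
anchor equals what the tail screen recovers.  For configs that do allow A
at -1 the truth additionally records the *effective* anchor and tail start
(after absorbing templated terminal A's into the tail).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import SequenceRecord
from .site_mapper import revcomp, site_to_index

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

# discrete bump kernel: sharply peaked so the planted argmax is recoverable
# at moderate site counts
_KERNEL = {-2: 0.15, -1: 0.4, 0: 1.0, 1: 0.4, 2: 0.15}


@dataclass(frozen=True)
class Planting:
    """Plant ``motif`` with its first base at site coordinate ``position``
    in a ``fraction`` of genes."""

    motif: str
    position: int
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0,1]")
        start = site_to_index(self.position)
        if start + len(self.motif) > 201:
            raise ValueError("motif footprint extends past the region")


@dataclass(frozen=True)
class OrfSpec:
    """ORF/UTR layout planted in every gene.

    ``utr_lengths`` may be a single value or a per-gene sequence (cycled);
    -1 and -2 request stop codons completed by the poly(A) tail.
    """

    aa_length: int = 120
    utr_lengths: int | tuple[int, ...] = 150

    def utr_for(self, i: int) -> int:
        if isinstance(self.utr_lengths, int):
            return self.utr_lengths
        return self.utr_lengths[i % len(self.utr_lengths)]


def _bump(template: np.ndarray, base_idx: int, pos: int, height: float) -> None:
    for off, w in _KERNEL.items():
        p = pos + off
        if p == 0 or not -100 <= p <= 101:
            continue
        col = site_to_index(p)
        old = template[base_idx, col]
        new = old + w * (height - old)
        if new <= old:
            continue
        others = 1.0 - old
        template[:, col] *= (1.0 - new) / others
        template[base_idx, col] = new


def positional_template(
    a_peak: tuple[int, float] = (-21, 0.41),
    u_peak: tuple[int, float] = (-7, 0.56),
    site_a: float = 0.85,
    upstream_baseline: tuple[float, float, float, float] = (0.26, 0.14, 0.13, 0.47),
    downstream_baseline: tuple[float, float, float, float] = (0.25, 0.15, 0.14, 0.46),
    attachment: tuple[float, float, float, float] = (0.0, 0.30, 0.10, 0.60),
    downstream_u_peak: Optional[tuple[int, float]] = None,
) -> np.ndarray:
    """Build a (4, 201) per-position base-probability template.

    Baselines are (A, C, G, T) tuples; ``a_peak``/``u_peak`` are
    (position, height) for the upstream A-rich and U-rich elements,
    ``attachment`` the distribution at position -1 and ``site_a`` the A
    probability at position +1.
    """
    for tup in (upstream_baseline, downstream_baseline, attachment):
        if abs(sum(tup) - 1.0) > 1e-9 or min(tup) < 0:
            raise ValueError("baselines must be probability vectors")
    t = np.empty((4, 201))
    t[:, :100] = np.array(upstream_baseline)[:, None]
    t[:, 100:] = np.array(downstream_baseline)[:, None]
    t[:, site_to_index(-1)] = attachment
    rest = 1.0 - site_a
    t[:, site_to_index(1)] = (site_a, rest * 0.2, rest * 0.1, rest * 0.7)
    _bump(t, 0, *a_peak)
    _bump(t, 3, *u_peak)
    if downstream_u_peak is not None:
        _bump(t, 3, *downstream_u_peak)
    np.testing.assert_allclose(t.sum(axis=0), 1.0, atol=1e-9)
    return t


def plant_like_template() -> np.ndarray:
    """Upstream A peak at -21, sharp U peak at -7, flat U-rich downstream."""
    return positional_template()


def animal_like_template() -> np.ndarray:
    """Upstream A peak at -18, U peak at -9, pointed downstream U peak ~ +19."""
    return positional_template(
        a_peak=(-18, 0.54),
        u_peak=(-9, 0.43),
        upstream_baseline=(0.28, 0.19, 0.18, 0.35),
        downstream_baseline=(0.27, 0.16, 0.15, 0.42),
        attachment=(0.0, 0.37, 0.06, 0.57),
        downstream_u_peak=(19, 0.52),
    )


@dataclass
class SyntheticSpec:
    """Full description of one synthetic dataset."""

    seed: int = 0
    n_genes: int = 2000
    genome_length: Optional[int] = None
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    template: Optional[np.ndarray] = None  # default: plant_like_template()
    plantings: tuple[Planting, ...] = (Planting("AATAAA", -21, 0.55),)
    tail_min_length: int = 20
    tail_max_length: int = 40
    redundancy_rate: float = 0.0
    internal_priming_rate: float = 0.0
    min_genomic_a_run: int = 6
    five_prime_pad: int = 150
    orf: Optional[OrfSpec] = None
    minus_fraction: float = 0.5
    spacer: int = 60
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        if self.tail_min_length < 12:
            raise ValueError("tails shorter than 12 would fail the screen")
        if self.tail_max_length < self.tail_min_length:
            raise ValueError("tail_max_length < tail_min_length")
        for rate in (self.redundancy_rate, self.internal_priming_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0,1]")
        if self.template is None:
            self.template = plant_like_template()
        self.template = np.asarray(self.template, dtype=float)
        if self.template.shape != (4, 201):
            raise ValueError("template must have shape (4, 201)")
        if self.internal_priming_rate > 0 and self.five_prime_pad < 135:
            raise ValueError("internal priming needs five_prime_pad >= 135")

    @property
    def a_run_length(self) -> int:
        return max(self.min_genomic_a_run + 4, 10)

    @property
    def a_run_offset(self) -> Optional[int]:
        """0-based body offset of the planted genomic A-run, if any."""
        if self.internal_priming_rate <= 0:
            return None
        return self.five_prime_pad - self.a_run_length - 25


@dataclass
class GeneTruth:
    """Ground truth for one synthetic gene."""

    gene_id: str
    chrom: str
    strand: str
    tailstart_coord: int
    body: str
    window201: str
    plantings: tuple[tuple[str, int], ...] = ()
    utr_length: Optional[int] = None
    a_run_offset: Optional[int] = None
    effective_tail_extension: int = 0
    artifact: bool = False

    @property
    def anchor(self) -> str:
        return self.body[-100:]

    @property
    def effective_anchor(self) -> str:
        """Anchor after absorbing templated terminal A's into the tail."""
        s = self.effective_tail_extension
        body = self.body[: len(self.body) - s] if s else self.body
        return body[-100:]

    @property
    def effective_tailstart_coord(self) -> int:
        s = self.effective_tail_extension
        if s == 0:
            return self.tailstart_coord
        return self.tailstart_coord - s if self.strand == "+" else self.tailstart_coord + s


@dataclass
class SyntheticTruth:
    """Per-gene truth rows plus the planted global parameters."""

    genes: list[GeneTruth] = field(default_factory=list)
    spec: Optional[SyntheticSpec] = None

    def by_id(self, gene_id: str) -> GeneTruth:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "strand": g.strand,
                    "tailstart_coord": g.tailstart_coord,
                    "effective_tailstart_coord": g.effective_tailstart_coord,
                    "plantings": ";".join(f"{m}@{p}" for m, p in g.plantings),
                    "utr_length": g.utr_length if g.utr_length is not None else pd.NA,
                    "artifact": g.artifact,
                    "anchor": g.effective_anchor,
                }
                for g in self.genes
            ]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _draw_windows(rng: np.random.Generator, template: np.ndarray, n: int) -> list[str]:
    """Draw n 201-nt windows from the per-position template, vectorized."""
    cum = np.cumsum(template.T, axis=1)  # (201, 4)
    u = rng.random((n, 201))
    idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    chars = _BASES[idx]
    return ["".join(row) for row in chars]


def _random_seq(rng: np.random.Generator, n: int, background: Sequence[float]) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(_BASES, size=n, p=np.asarray(background)))


def _scan_last_qualifying_stop(body: str, min_aa: int = 110) -> Optional[tuple[int, int]]:
    """Generator-internal check: (stop_last_coord, aa) of the last qualifying
    ORF in ``body`` under the pipeline's reading rules, or None.

    Kept deliberately separate from the analysis implementation; used only
    to reject gene constructions whose planted ORF would not be the last
    qualifying one.
    """
    stops = {"TAA", "TAG", "TGA"}
    best: Optional[tuple[int, int]] = None
    B = len(body)
    for i in range(B - 2):
        if body[i : i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= B and body[j : j + 3] not in stops:
            j += 3
        if j + 3 <= B:
            stop_last, aa = j + 3, (j - i) // 3
        else:
            rem = B - j
            if rem == 2 and body[j : j + 2] in ("TA", "TG"):
                stop_last, aa = j + 3, (j - i) // 3
            elif rem == 1 and body[j] == "T":
                stop_last, aa = j + 3, (j - i) // 3
            else:
                continue
        if aa >= min_aa and (best is None or stop_last > best[0]):
            best = (stop_last, aa)
    return best


def _orf_block(rng: np.random.Generator, aa: int, utr: int) -> tuple[str, str]:
    """(orf_sequence, trailing) for a planted ORF; trailing is the body part
    after the stop (empty for utr <= 0)."""
    codons = "".join(rng.choice(_NONSTOP_CODONS, size=aa - 1))
    if utr >= 1:
        return "ATG" + codons + "TAA", ""
    if utr == 0:
        return "ATG" + codons + "TAG", ""  # ends in G: no tail ambiguity
    if utr == -1:
        return "ATG" + codons + "TG", ""  # TGA completed by one tail A
    if utr == -2:
        return "ATG" + codons + "T", ""  # TAA completed by two tail A's
    raise ValueError(f"utr_length {utr} below the -2 minimum")


def _build_body(
    rng: np.random.Generator, spec: SyntheticSpec, window: str, gene_index: int
) -> tuple[str, str, Optional[int]]:
    """Construct one gene's transcript body; returns (body, window, utr)."""
    pad = _random_seq(rng, spec.five_prime_pad, spec.background)
    run_off = spec.a_run_offset
    if run_off is not None:
        run = "A" * spec.a_run_length
        pad = pad[:run_off] + run + pad[run_off + len(run) :]
    if spec.orf is None:
        return pad + window[:100], window, None
    aa = spec.orf.aa_length
    utr = spec.orf.utr_for(gene_index)
    for _ in range(40):
        orf_seq, _trail = _orf_block(rng, aa, utr)
        if utr >= 100:
            filler = _random_seq(rng, utr - 100, spec.background)
            body = pad + orf_seq + filler + window[:100]
        else:
            filler = _random_seq(rng, max(utr, 0), spec.background)
            if utr >= 1:
                filler = filler[:-1] + "T"  # keep the tail boundary unambiguous
            body = pad + orf_seq + filler
        expected_stop_last = len(body) - utr
        found = _scan_last_qualifying_stop(body, min_aa=110)
        if found is not None and found[0] == expected_stop_last:
            if utr < 100:
                window = body[-100:] + window[100:]
            return body, window, utr
    raise RuntimeError("could not construct a clean ORF gene (rejection limit)")


def generate_genome(spec: SyntheticSpec) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Emit the genome FASTA records and per-gene truth for a spec.

    Genes are placed non-overlapping on both strands with background
    sequence between them and generous clearance from contig ends, so no
    site is lost to edge dropping.  Deterministic given the spec.
    """
    rng = np.random.default_rng([spec.seed, 0])
    windows = _draw_windows(rng, spec.template, spec.n_genes)
    plant_masks = [
        rng.random(spec.n_genes) < planting.fraction for planting in spec.plantings
    ]
    genes: list[tuple[str, GeneTruth]] = []
    for i in range(spec.n_genes):
        window = windows[i]
        planted: list[tuple[str, int]] = []
        for planting, mask in zip(spec.plantings, plant_masks):
            if mask[i]:
                start = site_to_index(planting.position)
                window = (
                    window[:start] + planting.motif + window[start + len(planting.motif) :]
                )
                planted.append((planting.motif, planting.position))
        body, window, utr = _build_body(rng, spec, window, i)
        ext = len(body) - len(body.rstrip("A"))
        gene_seq = body + window[100:]
        strand = "-" if rng.random() < spec.minus_fraction else "+"
        truth = GeneTruth(
            gene_id=f"g{i:05d}",
            chrom=spec.chrom_name,
            strand=strand,
            tailstart_coord=0,  # filled after placement
            body=body,
            window201=window,
            plantings=tuple(planted),
            utr_length=utr,
            a_run_offset=spec.a_run_offset,
            effective_tail_extension=ext,
        )
        genes.append((gene_seq, truth))

    margin = 250
    parts: list[str] = [_random_seq(rng, margin, spec.background)]
    offset = margin
    truth_rows: list[GeneTruth] = []
    for gene_seq, truth in genes:
        L = len(gene_seq)
        B = len(truth.body)
        if truth.strand == "+":
            parts.append(gene_seq)
            tailstart = offset + B + 1
        else:
            parts.append(revcomp(gene_seq))
            tailstart = offset + L - B
        truth.tailstart_coord = tailstart
        truth_rows.append(truth)
        offset += L
        spacer = _random_seq(rng, spec.spacer, spec.background)
        parts.append(spacer)
        offset += spec.spacer
    parts.append(_random_seq(rng, margin, spec.background))
    genome_seq = "".join(parts)
    if spec.genome_length is not None:
        if len(genome_seq) > spec.genome_length:
            raise ValueError(
                f"{spec.n_genes} genes need {len(genome_seq)} nt, "
                f"genome_length is {spec.genome_length}"
            )
        genome_seq += _random_seq(rng, spec.genome_length - len(genome_seq), spec.background)
    record = SequenceRecord(
        id=spec.chrom_name, description=f"{spec.chrom_name} synthetic", residues=genome_seq
    )
    return [record], SyntheticTruth(genes=truth_rows, spec=spec)


def generate_transcripts(
    spec: SyntheticSpec, genome: list[SequenceRecord], truth: SyntheticTruth
) -> list[SequenceRecord]:
    """Emit one poly(A)-tailed transcript per gene, plus redundant copies.

    Tail lengths are uniform on [tail_min_length, tail_max_length];
    ``redundancy_rate`` controls the fraction of genes emitted twice
    (appended after the primary transcripts, in gene order).
    """
    rng = np.random.default_rng([spec.seed, 1])
    records: list[SequenceRecord] = []
    for i, gene in enumerate(truth.genes):
        tail = int(rng.integers(spec.tail_min_length, spec.tail_max_length + 1))
        records.append(
            SequenceRecord(
                id=f"tx{i:05d}",
                description=f"tx{i:05d} gene={gene.gene_id}",
                residues=gene.body + "A" * tail,
            )
        )
    n_dup = int(round(spec.redundancy_rate * spec.n_genes))
    if n_dup:
        dup_idx = sorted(rng.choice(spec.n_genes, size=n_dup, replace=False).tolist())
        for i in dup_idx:
            tail = int(rng.integers(spec.tail_min_length, spec.tail_max_length + 1))
            gene = truth.genes[i]
            records.append(
                SequenceRecord(
                    id=f"tx{i:05d}_dup",
                    description=f"tx{i:05d}_dup gene={gene.gene_id}",
                    residues=gene.body + "A" * tail,
                )
            )
    return records


def inject_internal_priming(
    spec: SyntheticSpec,
    genome: list[SequenceRecord],
    transcripts: list[SequenceRecord],
    truth: SyntheticTruth,
) -> tuple[list[SequenceRecord], int]:
    """Replace a fraction of transcripts with internal-priming artifacts.

    For each selected gene the transcript is truncated at the gene's
    genomic A-run and an artificial tail appended, mimicking oligo(dT)
    priming inside an A-rich stretch; the fake tail start falls on genomic
    adenosines, so artifact site regions carry A at their first downstream
    positions.  Selection uses a fixed permutation of genes, so the sets
    selected at increasing rates are nested.  Returns the new transcript
    list and the number of genes skipped for lack of a qualifying A-run.
    Truth rows of affected genes are flagged as artifacts.
    """
    if spec.internal_priming_rate <= 0:
        return list(transcripts), 0
    rng = np.random.default_rng([spec.seed, 2])
    order = rng.permutation(spec.n_genes)
    target = int(round(spec.internal_priming_rate * spec.n_genes))
    selected: list[int] = []
    skipped = 0
    for i in order:
        if len(selected) >= target:
            break
        gene = truth.genes[i]
        off = gene.a_run_offset
        if off is None or off < 100:
            run = _find_a_run(gene.body, spec.min_genomic_a_run)
            if run is None:
                skipped += 1
                continue
            off = run
        # the genomic A-run effectively starts at its leftmost A: absorb any
        # background A's directly upstream so the observed anchor ends on a
        # non-A base
        while off > 0 and gene.body[off - 1] == "A":
            off -= 1
        if off < 100:
            skipped += 1
            continue
        selected.append(int(i))
        gene.a_run_offset = off
    selected_set = set(selected)
    by_gene = {g.gene_id: g for g in truth.genes}
    out: list[SequenceRecord] = []
    for rec in transcripts:
        gene_id = rec.description.split("gene=")[-1]
        gene = by_gene.get(gene_id)
        idx = int(gene.gene_id[1:]) if gene else -1
        if gene is None or idx not in selected_set:
            out.append(rec)
            continue
        tail = int(rng.integers(spec.tail_min_length, spec.tail_max_length + 1))
        out.append(replace(rec, residues=gene.body[: gene.a_run_offset] + "A" * tail))
        gene.artifact = True
    return out, skipped


def _find_a_run(body: str, min_run: int) -> Optional[int]:
    """Leftmost start of an A-run >= min_run with >= 100 nt upstream."""
    run = "A" * min_run
    start = body.find(run, 100)
    return start if start != -1 else None


def simulate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[SequenceRecord], list[SequenceRecord], SyntheticTruth]:
    """Generate (genome records, transcript records, truth) for a spec."""
    genome, truth = generate_genome(spec)
    transcripts = generate_transcripts(spec, genome, truth)
    transcripts, _ = inject_internal_priming(spec, genome, transcripts, truth)
    return genome, transcripts, truth
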