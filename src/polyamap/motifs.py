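"""Windowed k-mer motif statistics around poly(A) sites.

Counts, for every k-mer, the fraction of unique sites carrying at least one
copy whose *first base* starts inside a window of site coordinates (the
footprint may extend past the window's right edge and across the site),
profiles where along the 201-nt region a motif's first base lands, derives
whole-genome k-mer baselines with overlapping counting (so a run of seven
A's counts as two AAAAAA copies), scans known downstream elements against
the same-length k-mer background, and compares two runs' motif proportions
with a Pearson two-proportion chi-square.

Motifs are handled internally in DNA spelling (T); tables carry an RNA (U)
spelling column alongside, mirroring the dual notation used for
polyadenylation signals like AATAAA / AAUAAA.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import REGION_LEN
from .site_mapper import SiteRegion, site_positions, site_to_index

DNA = "ACGT"

#: known downstream elements reported for the 3' cleaved-off region, DNA spelling
DEFAULT_DOWNSTREAM_ELEMENTS = ["TTATTT", "CCTCCC", "TGTGTG", "GTGTGT", "TGTTTG", "ATGCGT"]


@dataclass(frozen=True)
class MotifWindow:
    """Interval of allowed first-base site coordinates for motif counting."""

    name: str
    start: int
    end: int

    def positions(self) -> list[int]:
        return site_positions(self.start, self.end)


#: canonical counting windows
WINDOW_PRESETS = {
    # hexamers whose first base starts within 50 nt upstream of the site
    "hexamer_up50": MotifWindow("hexamer_up50", -50, -1),
    # the 48-base region ending two bases upstream of the tail start
    "pentamer_up48": MotifWindow("pentamer_up48", -50, -3),
    # tetramer whose last base covers the tail starting position
    "tetramer_at_site": MotifWindow("tetramer_at_site", -3, -3),
    # first base within 50 bases downstream of the site
    "downstream50": MotifWindow("downstream50", 2, 51),
}


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in product(DNA, repeat=k)]


def to_rna(motif: str) -> str:
    return motif.replace("T", "U")


def _region_strings(regions: Sequence[SiteRegion] | Sequence[str]) -> list[str]:
    seqs = [r.region201 if isinstance(r, SiteRegion) else r for r in regions]
    if any(len(s) != REGION_LEN for s in seqs):
        raise ValueError(f"all regions must be {REGION_LEN} nt")
    return seqs


def _window_start_indices(window: MotifWindow, k: int) -> list[int]:
    """0-based region indices at which a k-mer may start in this window."""
    idx = [site_to_index(p) for p in window.positions()]
    return [i for i in idx if i + k <= REGION_LEN]


def count_sites_with_motif(
    regions: Sequence[SiteRegion] | Sequence[str],
    k: int,
    window: MotifWindow,
) -> pd.DataFrame:
    """At-least-one-copy site percentages for every k-mer in a window.

    Each site contributes at most once per motif regardless of copy number.
    The table enumerates all 4**k motifs (zero rows included), indexed by
    DNA spelling, with columns ``motif_rna``, ``n_sites_with_copy``,
    ``pct_sites`` and ``rank`` (descending pct, ties broken
    lexicographically by motif).
    """
    seqs = _region_strings(regions)
    starts = _window_start_indices(window, k)
    if not starts:
        raise ValueError(f"window {window.name} admits no {k}-mer start")
    hits: Counter[str] = Counter()
    for seq in seqs:
        present = {seq[i : i + k] for i in starts}
        for kmer in present:
            if "N" not in kmer:
                hits[kmer] += 1
    n = len(seqs)
    motifs = all_kmers(k)
    df = pd.DataFrame(
        {
            "motif_rna": [to_rna(m) for m in motifs],
            "n_sites_with_copy": [hits.get(m, 0) for m in motifs],
        },
        index=pd.Index(motifs, name="motif"),
    )
    df["pct_sites"] = 100.0 * df["n_sites_with_copy"] / n if n else 0.0
    order = df.sort_values(["pct_sites"], ascending=False, kind="mergesort")
    # stable sort on a lexicographically sorted index -> ties break by motif
    df["rank"] = pd.Series(range(1, len(order) + 1), index=order.index)
    df.attrs["n_sites"] = n
    df.attrs["k"] = k
    df.attrs["window"] = window.name
    return df


def motif_rank(table: pd.DataFrame, motif: str) -> int:
    """1-based rank of a motif among all 4**k motifs of its table."""
    if len(motif) != table.attrs.get("k", len(motif)):
        raise ValueError(f"motif length {len(motif)} != table k {table.attrs['k']}")
    return int(table.loc[motif.replace("U", "T"), "rank"])


@dataclass
class MotifPositionProfile:
    """Where along the region a motif's first base lands.

    ``pct[i]`` is the percentage of sites whose region carries the motif
    starting at ``positions[i]``; ``accumulated_pct`` counts all
    (overlapping) copies over the whole region per 100 sites and may exceed
    100.
    """

    motif: str
    positions: np.ndarray
    pct: np.ndarray
    accumulated_pct: float
    n_sites: int

    @property
    def peak_position(self) -> int:
        return int(self.positions[int(np.argmax(self.pct))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "pct_sites": self.pct, "motif": self.motif,
             "motif_rna": to_rna(self.motif)}
        )


def motif_position_profile(
    regions: Sequence[SiteRegion] | Sequence[str], motif: str
) -> MotifPositionProfile:
    """Per-position first-base frequencies of one motif over the region."""
    if not motif or set(motif) - set(DNA):
        raise ValueError(f"motif must be non-empty over {DNA}, got {motif!r}")
    seqs = _region_strings(regions)
    k = len(motif)
    positions = [p for p in site_positions(-100, 101) if site_to_index(p) + k <= REGION_LEN]
    idx = [site_to_index(p) for p in positions]
    counts = np.zeros(len(idx), dtype=int)
    total = 0
    for seq in seqs:
        for j, i in enumerate(idx):
            if seq[i : i + k] == motif:
                counts[j] += 1
                total += 1
    n = len(seqs)
    return MotifPositionProfile(
        motif=motif,
        positions=np.array(positions),
        pct=100.0 * counts / n,
        accumulated_pct=100.0 * total / n,
        n_sites=n,
    )


def site_tetramer_distribution(
    regions: Sequence[SiteRegion] | Sequence[str],
) -> pd.DataFrame:
    """Distribution of the 4-mer covering positions -3..+1 at each site.

    Each site contributes exactly one tetramer (its last base is the tail
    starting position); sites with an N in that span are excluded and
    reported in ``attrs['n_excluded']``.  Percentages sum to 100 over the
    256 motifs.
    """
    seqs = _region_strings(regions)
    lo = site_to_index(-3)
    hits: Counter[str] = Counter()
    excluded = 0
    for seq in seqs:
        tet = seq[lo : lo + 4]
        if "N" in tet:
            excluded += 1
        else:
            hits[tet] += 1
    n = len(seqs) - excluded
    motifs = all_kmers(4)
    df = pd.DataFrame(
        {
            "motif_rna": [to_rna(m) for m in motifs],
            "n_sites_with_copy": [hits.get(m, 0) for m in motifs],
        },
        index=pd.Index(motifs, name="motif"),
    )
    df["pct_sites"] = 100.0 * df["n_sites_with_copy"] / n if n else 0.0
    order = df.sort_values(["pct_sites"], ascending=False, kind="mergesort")
    df["rank"] = pd.Series(range(1, len(order) + 1), index=order.index)
    df.attrs.update(n_sites=n, n_excluded=excluded, k=4, window="tetramer_at_site")
    return df


def known_element_scan(
    regions: Sequence[SiteRegion] | Sequence[str],
    elements: Optional[Sequence[str]] = None,
    window: MotifWindow = WINDOW_PRESETS["downstream50"],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Frequencies of known downstream elements vs the same-length background.

    Each element's at-least-one-copy count is tested (two-sided exact
    binomial) against the mean with-copy probability of all 4**k motifs of
    its length in the same window; the verdict is ``enriched`` / ``depleted``
    when significant at ``alpha``, else ``ns``.
    """
    if elements is None:
        elements = DEFAULT_DOWNSTREAM_ELEMENTS
    elements = [e.upper().replace("U", "T") for e in elements]
    out = []
    tables: dict[int, pd.DataFrame] = {}
    for elem in elements:
        k = len(elem)
        if k not in tables:
            tables[k] = count_sites_with_motif(regions, k, window)
        table = tables[k]
        n = table.attrs["n_sites"]
        x = int(table.loc[elem, "n_sites_with_copy"])
        p0 = float(table["n_sites_with_copy"].mean()) / n
        test = stats.binomtest(x, n, p0, alternative="two-sided")
        signif = test.pvalue < alpha
        verdict = "ns"
        if signif:
            verdict = "enriched" if x / n > p0 else "depleted"
        out.append(
            {
                "element": elem,
                "element_rna": to_rna(elem),
                "n_sites_with_copy": x,
                "pct_sites": 100.0 * x / n,
                "background_mean_pct": 100.0 * p0,
                "p_value": test.pvalue,
                "verdict": verdict,
            }
        )
    return pd.DataFrame(out).set_index("element")


@dataclass
class GenomeKmerTable:
    """Overlapping k-mer occurrence counts over one strand of a genome.

    ``counts`` is a motif x chromosome frame; ``windows`` the number of
    sliding windows per chromosome (L - k + 1, N-containing windows are
    skipped in the counts but kept in the denominator, matching a
    whole-sequence sliding count).
    """

    k: int
    counts: pd.DataFrame
    windows: pd.Series
    overlapping: bool = True

    @property
    def pooled_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def pooled_freq(self) -> pd.Series:
        return self.pooled_counts / float(self.windows.sum())

    @property
    def freq(self) -> pd.DataFrame:
        return self.counts / self.windows

    def count(self, motif: str, chrom: Optional[str] = None) -> int:
        motif = motif.replace("U", "T")
        if chrom is None:
            return int(self.pooled_counts.get(motif, 0))
        return int(self.counts.loc[motif, chrom])


def genome_kmer_frequencies(
    records: Iterable, k: int, overlapping: bool = True
) -> GenomeKmerTable:
    """Sliding-window k-mer counts per chromosome and pooled.

    Overlapping counting conflates homopolymers (seven A's -> two AAAAAA
    copies), as whole-genome motif surveys traditionally do; pass
    ``overlapping=False`` for non-overlapping (left-greedy) counting.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    per_chrom: dict[str, Counter] = {}
    windows: dict[str, int] = {}
    for rec in records:
        name = getattr(rec, "id", None) or rec[0]
        seq = getattr(rec, "residues", None) or rec[1]
        c: Counter[str] = Counter()
        i = 0
        L = len(seq)
        while i <= L - k:
            kmer = seq[i : i + k]
            if "N" in kmer:
                i += 1
                continue
            c[kmer] += 1
            i += 1 if overlapping else k
        per_chrom[name] = c
        windows[name] = max(L - k + 1, 0)
    motifs = all_kmers(k)
    counts = pd.DataFrame(
        {name: [c.get(m, 0) for m in motifs] for name, c in per_chrom.items()},
        index=pd.Index(motifs, name="motif"),
    )
    return GenomeKmerTable(
        k=k,
        counts=counts,
        windows=pd.Series(windows),
        overlapping=overlapping,
    )


def enrichment_ratio(site_pct: float, genome_freq: float) -> float:
    """Fold enrichment of a motif around sites over its whole-genome rate.

    ``site_pct`` is the with-copy site percentage (0..100); ``genome_freq``
    the genome per-window fraction.  A zero genome frequency yields NaN (the
    ratio is undefined) rather than an error.
    """
    if genome_freq < 0 or not 0 <= site_pct <= 100:
        raise ValueError("site_pct must be in [0,100] and genome_freq >= 0")
    if genome_freq == 0:
        return float("nan")
    return (site_pct / 100.0) / genome_freq


def two_proportion_chisq(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table.

    Compares proportions x1/n1 vs x2/n2; returns (statistic, p_value).
    Raises if any margin of the 2x2 table is zero.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 <= 0 or n2 <= 0:
        raise ValueError("need 0 <= x <= n and n > 0")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("2x2 table has a zero margin")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    statistic = float(((table - expected) ** 2 / expected).sum())
    return statistic, float(stats.chi2.sf(statistic, df=1))
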