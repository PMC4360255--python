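"""Per-position base composition around poly(A) sites.

Builds position x base frequency matrices over the 201-nt site regions,
computes sequence-logo information content and letter heights, locates
base-abundance peaks, and summarizes the conserved
U-rich -- A-rich -- U-rich -- site-A -- U-rich (U-A-U-A-U) arrangement that
fungi, plants and animals share around the cleavage site.

Information content per position, in bits for a 4-letter alphabet:

    IC_w = log2(J) + sum_j p_jw * log2(p_jw),   J = 4,  0*log2(0) := 0

so IC is 0 at a uniform position and 2 where a single base always occurs.
Letter heights in a logo are p_jw * IC_w.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import REGION_LEN
from .site_mapper import SiteRegion, site_positions, site_to_index

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: default search windows for the U-A-U-A-U components, in site coordinates
DEFAULT_PATTERN_WINDOWS = {
    "first_uur": (-100, -35),
    "uar": (-30, -10),
    "second_uur": (-15, -2),
    "dur": (2, 40),
}


@dataclass
class BaseFrequencyMatrix:
    """Per-position base counts/frequencies over a window of the region.

    ``counts`` has shape (4, W) with rows A, C, G, T; ``denom[w]`` is the
    number of sites with a determinate (non-N) base at position ``w``;
    ``positions`` holds the signed site coordinates of the columns.
    Averaged matrices may carry fractional counts.
    """

    positions: np.ndarray
    counts: np.ndarray
    denom: np.ndarray

    J: int = 4

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        self.denom = np.asarray(self.denom, dtype=float)
        if self.counts.shape != (4, len(self.positions)):
            raise ValueError("counts must have shape (4, W)")
        if self.denom.shape != (len(self.positions),):
            raise ValueError("denom must have shape (W,)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def W(self) -> int:
        return len(self.positions)

    @property
    def freq(self) -> np.ndarray:
        """p_jw = counts / denom; columns with denom 0 are all-NaN."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.denom > 0, self.counts / self.denom, np.nan)

    def column(self, pos: int) -> np.ndarray:
        """Frequency vector (A,C,G,T) at one site position."""
        idx = np.flatnonzero(self.positions == pos)
        if idx.size == 0:
            raise ValueError(f"position {pos} not in matrix")
        return self.freq[:, idx[0]]

    def base_freq(self, base: str) -> np.ndarray:
        return self.freq[_BASE_INDEX[base], :]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq.T, columns=list(BASES))
        df.insert(0, "position", self.positions)
        df["denom"] = self.denom
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PeakSummary:
    """Argmax of one base's frequency over a search window."""

    base: str
    window: tuple[int, int]
    peak_position: int
    peak_frequency: float  # percent of sites
    plateau: bool = False


@dataclass(frozen=True)
class PatternSummary:
    """The U-A-U-A-U components: two U-rich flanks, the A-rich upstream
    element, the site-A frequency, and the downstream U-rich region."""

    first_uur: PeakSummary
    uar: PeakSummary
    second_uur: PeakSummary
    site_a_pct: float
    dur: PeakSummary


def position_base_frequencies(
    regions: Sequence[SiteRegion] | Sequence[str],
    window: tuple[int, int] = (-100, 101),
) -> BaseFrequencyMatrix:
    """Tally bases per position over the given site-coordinate window.

    Accepts site regions or bare 201-nt strings.  Ns are excluded from both
    numerator and denominator at their position.
    """
    seqs = [r.region201 if isinstance(r, SiteRegion) else r for r in regions]
    if not seqs:
        raise ValueError("no regions given")
    if any(len(s) != REGION_LEN for s in seqs):
        raise ValueError(f"all regions must be {REGION_LEN} nt")
    positions = site_positions(*window)
    cols = [site_to_index(p) for p in positions]
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), REGION_LEN)
    arr = arr[:, cols]
    counts = np.empty((4, len(cols)), dtype=float)
    for j, b in enumerate(BASES):
        counts[j] = (arr == b.encode()).sum(axis=0)
    denom = counts.sum(axis=0)
    return BaseFrequencyMatrix(positions=np.array(positions), counts=counts, denom=denom)


def information_content(freqs: Iterable[float], J: int = 4) -> float:
    """Sequence-logo information content of one position, in bits.

    ``freqs`` must be a probability vector (sums to 1 within 1e-9);
    0*log2(0) is taken as 0.  For J=4 the value lies in [0, 2].
    """
    p = np.asarray(list(freqs), dtype=float)
    if (p < 0).any():
        raise ValueError("negative probability")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    nz = p[p > 0]
    ic = np.log2(J) + float(np.sum(nz * np.log2(nz)))
    return max(ic, 0.0)


def seqlogo_heights(matrix: BaseFrequencyMatrix) -> np.ndarray:
    """Letter heights, shape (4, W): height_jw = p_jw * IC_w.

    Column sums equal the per-position information content.
    """
    freq = matrix.freq
    heights = np.zeros_like(freq)
    for w in range(matrix.W):
        col = freq[:, w]
        if np.isnan(col).any():
            heights[:, w] = np.nan
            continue
        heights[:, w] = col * information_content(col, J=matrix.J)
    return heights


def _distance_to_site(pos: int) -> int:
    return -pos if pos < 0 else pos - 1


def find_peak(
    matrix: BaseFrequencyMatrix,
    base: str,
    window: tuple[int, int],
    flatness_threshold: Optional[float] = None,
) -> PeakSummary:
    """Single-position argmax of one base's frequency over a window.

    Ties break toward the position nearest the site (largest coordinate for
    upstream windows, smallest for downstream).  If ``flatness_threshold``
    is given (percentage points), the plateau flag is set when
    max - median over the window falls below it.
    """
    positions = [p for p in site_positions(*window) if p in set(matrix.positions.tolist())]
    if not positions:
        raise ValueError(f"window {window} outside matrix")
    f = matrix.base_freq(base)
    pos_to_col = {p: i for i, p in enumerate(matrix.positions.tolist())}
    vals = np.array([f[pos_to_col[p]] for p in positions])
    best = np.nanmax(vals)
    tied = [p for p, v in zip(positions, vals) if v == best]
    peak_pos = min(tied, key=lambda p: (_distance_to_site(p), p > 0, -p if p < 0 else p))
    plateau = False
    if flatness_threshold is not None:
        plateau = (best - float(np.nanmedian(vals))) * 100.0 < flatness_threshold
    return PeakSummary(
        base=base,
        window=window,
        peak_position=peak_pos,
        peak_frequency=100.0 * float(best),
        plateau=plateau,
    )


def summarize_uauau(
    matrix: BaseFrequencyMatrix,
    windows: Optional[dict[str, tuple[int, int]]] = None,
    flatness_threshold: float = 5.0,
) -> PatternSummary:
    """Locate the U-A-U-A-U components in a 201-wide matrix.

    Each component is the peak of T (U in RNA) or A over its search window;
    a component whose max exceeds the window median by less than
    ``flatness_threshold`` percentage points is flagged as a plateau (U-rich
    stretch without a sharp peak, as in the plant downstream region).
    ``site_a_pct`` is the A frequency at position +1 in percent.
    """
    win = dict(DEFAULT_PATTERN_WINDOWS)
    if windows:
        win.update(windows)
    starts = [win[k][0] for k in ("first_uur", "uar", "second_uur", "dur")]
    if starts != sorted(starts):
        raise ValueError("component windows must be ordered 5'->3'")
    return PatternSummary(
        first_uur=find_peak(matrix, "T", win["first_uur"], flatness_threshold),
        uar=find_peak(matrix, "A", win["uar"], flatness_threshold),
        second_uur=find_peak(matrix, "T", win["second_uur"], flatness_threshold),
        site_a_pct=100.0 * float(matrix.column(1)[_BASE_INDEX["A"]]),
        dur=find_peak(matrix, "T", win["dur"], flatness_threshold),
    )


def average_matrices(
    matrices: Sequence[BaseFrequencyMatrix], mode: str = "species_mean"
) -> BaseFrequencyMatrix:
    """Combine matrices across species/groups.

    ``species_mean`` takes the unweighted mean of the per-matrix frequency
    matrices (every species counts equally regardless of site count);
    ``pooled`` sums counts and denominators element-wise (every site counts
    equally).
    """
    if not matrices:
        raise ValueError("no matrices given")
    W = matrices[0].W
    positions = matrices[0].positions
    if any(m.W != W or not np.array_equal(m.positions, positions) for m in matrices):
        raise ValueError("matrices must share the same positions")
    if mode == "species_mean":
        mean_freq = np.nanmean(np.stack([m.freq for m in matrices]), axis=0)
        return BaseFrequencyMatrix(
            positions=positions.copy(),
            counts=mean_freq,
            denom=np.ones(W),
        )
    if mode == "pooled":
        return BaseFrequencyMatrix(
            positions=positions.copy(),
            counts=np.sum(np.stack([m.counts for m in matrices]), axis=0),
            denom=np.sum(np.stack([m.denom for m in matrices]), axis=0),
        )
    raise ValueError(f"unknown mode {mode!r}")
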