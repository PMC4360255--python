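"""3'UTR length from the last qualifying open reading frame.

The 3'UTR length is the number of nucleotides between the stop codon and
the poly(A) site: ``tailstart_tx_coord - stop_last_coord - 1``.  Only
sense-strand, ATG-initiated ORFs terminating at the first in-frame stop are
considered; the last-ending ORF that could encode at least 110 amino acids
(stop codon excluded) determines the UTR.  An ORF may end with a stop codon
completed by the first one or two tail adenosines (TG+A -> TGA, T+AA ->
TAA), giving UTR lengths of -1 or -2 -- such transcripts are "UTR-less".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .tail_screen import PolyATranscript

DEFAULT_MIN_AA = 110
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfAnnotation:
    """One sense-strand ORF in transcript coordinates (1-based).

    ``aa_length`` counts codons from the ATG up to but excluding the stop;
    ``borrowed_tail_bases`` is how many stop-codon bases the poly(A) tail
    supplied (0-2).
    """

    frame: int
    start_coord: int
    stop_last_coord: int
    aa_length: int
    borrowed_tail_bases: int = 0


@dataclass(frozen=True)
class UtrResult:
    """UTR length for one transcript; ``utr_length`` is None when no ORF
    qualifies (flagged via ``determinable``)."""

    transcript_id: str
    utr_length: Optional[int]
    qualifying_orf: Optional[OrfAnnotation]
    utr_less: Optional[bool]

    @property
    def determinable(self) -> bool:
        return self.qualifying_orf is not None


def find_sense_orfs(transcript: PolyATranscript, require_atg: bool = True) -> list[OrfAnnotation]:
    """All ATG-to-first-in-frame-stop ORFs in the three sense frames.

    ORFs lacking an in-body stop are admitted when the tail's first one or
    two A's complete a stop codon at the body's 3' boundary (TA+A or T+AA
    read as TAA, TG+A as TGA).  ORFs with zero codons before the stop are
    discarded.  With ``require_atg=False`` each frame's longest stop-free
    reading frame from the frame start is used instead of ATG starts.
    """
    body = transcript.body
    B = len(body)
    orfs: list[OrfAnnotation] = []
    if require_atg:
        starts = [i for i in range(B - 2) if body[i : i + 3] == "ATG"]
    else:
        starts = [f for f in range(min(3, B))]
    for i in starts:
        j = i
        found = False
        while j + 3 <= B:
            codon = body[j : j + 3]
            if codon in _STOPS:
                if j > i:
                    orfs.append(
                        OrfAnnotation(
                            frame=i % 3,
                            start_coord=i + 1,
                            stop_last_coord=j + 3,
                            aa_length=(j - i) // 3,
                            borrowed_tail_bases=0,
                        )
                    )
                found = True
                break
            j += 3
        if found:
            continue
        # body exhausted without a stop: can the tail complete one?
        rem = B - j
        borrowed = None
        if rem == 2 and body[j : j + 2] in ("TA", "TG"):
            borrowed = 1  # TAA or TGA
        elif rem == 1 and body[j] == "T":
            borrowed = 2  # TAA
        if borrowed is not None and j > i:
            orfs.append(
                OrfAnnotation(
                    frame=i % 3,
                    start_coord=i + 1,
                    stop_last_coord=j + 3,
                    aa_length=(j - i) // 3,
                    borrowed_tail_bases=borrowed,
                )
            )
    return orfs


def last_qualifying_orf(
    orfs: Sequence[OrfAnnotation], min_aa: int = DEFAULT_MIN_AA
) -> Optional[OrfAnnotation]:
    """The last-ending ORF encoding at least ``min_aa`` residues.

    Ties on the stop coordinate break toward the greatest start coordinate.
    """
    qualifying = [o for o in orfs if o.aa_length >= min_aa]
    if not qualifying:
        return None
    return max(qualifying, key=lambda o: (o.stop_last_coord, o.start_coord))


def utr_length(transcript: PolyATranscript, orf: Optional[OrfAnnotation]) -> UtrResult:
    """Nucleotides between the stop codon and the poly(A) site.

    With a stop codon borrowing b tail bases the result is -b.  A missing
    qualifying ORF yields an indeterminable result (utr_length None).
    """
    if orf is None:
        return UtrResult(transcript.id, None, None, None)
    length = transcript.tailstart_tx_coord - orf.stop_last_coord - 1
    return UtrResult(transcript.id, length, orf, utr_less=length < 0)


def compute_utr(
    transcript: PolyATranscript,
    min_aa: int = DEFAULT_MIN_AA,
    require_atg: bool = True,
) -> UtrResult:
    """Full UTR determination for one screened transcript."""
    orfs = find_sense_orfs(transcript, require_atg=require_atg)
    return utr_length(transcript, last_qualifying_orf(orfs, min_aa=min_aa))


def utr_report(results: Sequence[UtrResult]) -> pd.DataFrame:
    """Tabulate per-transcript UTR results."""
    rows = []
    for r in results:
        orf = r.qualifying_orf
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "orf_start": orf.start_coord if orf else pd.NA,
                "orf_stop_last": orf.stop_last_coord if orf else pd.NA,
                "aa_length": orf.aa_length if orf else pd.NA,
                "borrowed_tail_bases": orf.borrowed_tail_bases if orf else pd.NA,
                "utr_length": r.utr_length if r.utr_length is not None else pd.NA,
                "utr_less": r.utr_less if r.utr_less is not None else pd.NA,
            }
        )
    return pd.DataFrame(rows)


def summarize_utr_lengths(
    results: Sequence[UtrResult], group_labels: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Unweighted mean/median/count of determinable UTR lengths per group.

    Indeterminable results are dropped; empty groups are excluded.
    """
    if group_labels is None:
        group_labels = ["all"] * len(results)
    if len(group_labels) != len(results):
        raise ValueError("one group label per result required")
    records = [
        {"group": g, "utr_length": r.utr_length}
        for g, r in zip(group_labels, results)
        if r.utr_length is not None
    ]
    if not records:
        raise ValueError("no determinable UTR lengths")
    df = pd.DataFrame(records)
    out = df.groupby("group")["utr_length"].agg(n="count", mean="mean", median="median")
    return out.reset_index()
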