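"""Poly(A)-tail screening and anchor deduplication.

A transcript qualifies as poly(A)-tailed when it ends in an uninterrupted
run of at least ``min_tail`` adenosines (default 12).  The tail is the
*maximal* terminal A-run; the 100 nt immediately upstream of it (the
*anchor*) identify the site and are later mapped to the genome with zero
mismatches.  Two transcripts with identical anchors are redundant copies of
the same site and are collapsed, keeping the first occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io import SequenceRecord

DEFAULT_MIN_TAIL = 12
DEFAULT_ANCHOR_LEN = 100


@dataclass(frozen=True)
class PolyATranscript:
    """A transcript that passed the tail screen.

    ``body`` is everything 5' of the tail, ``anchor`` its final
    ``anchor_len`` bases, and ``tailstart_tx_coord`` the 1-based transcript
    coordinate of the first tail A (== ``len(body) + 1``).  ``n_copies``
    counts input transcripts collapsed onto this anchor by
    :func:`dedupe_by_anchor`.
    """

    id: str
    body: str
    tail_length: int
    anchor: str
    tailstart_tx_coord: int
    n_copies: int = 1


@dataclass
class ScreenStats:
    """Per-stage rejection accounting for the tail screen."""

    n_input: int = 0
    n_no_tail: int = 0
    n_short_body: int = 0
    n_kept: int = 0
    rejected_ids: list = field(default_factory=list)


def find_terminal_tail(residues: str, min_tail: int = DEFAULT_MIN_TAIL) -> Optional[int]:
    """Length of the maximal terminal A-run, or None if shorter than ``min_tail``.

    The run must be anchored at the 3' end: internal A-runs followed by any
    non-A base never count.
    """
    n = len(residues)
    i = n
    while i > 0 and residues[i - 1] == "A":
        i -= 1
    run = n - i
    if run < min_tail:
        return None
    return run


def screen_transcripts(
    records: Iterable[SequenceRecord],
    min_tail: int = DEFAULT_MIN_TAIL,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
) -> tuple[list[PolyATranscript], ScreenStats]:
    """Keep poly(A)-tailed transcripts whose body can supply a full anchor.

    Records without a qualifying terminal A-run are counted as ``no_tail``;
    records whose body (sequence 5' of the tail) is shorter than
    ``anchor_len`` are counted as ``short_body``.  Rejections are tallied,
    never raised.
    """
    stats = ScreenStats()
    kept: list[PolyATranscript] = []
    for rec in records:
        stats.n_input += 1
        tail = find_terminal_tail(rec.residues, min_tail=min_tail)
        if tail is None:
            stats.n_no_tail += 1
            stats.rejected_ids.append((rec.id, "no_tail"))
            continue
        body = rec.residues[: len(rec.residues) - tail]
        if len(body) < anchor_len:
            stats.n_short_body += 1
            stats.rejected_ids.append((rec.id, "short_body"))
            continue
        kept.append(
            PolyATranscript(
                id=rec.id,
                body=body,
                tail_length=tail,
                anchor=body[-anchor_len:],
                tailstart_tx_coord=len(body) + 1,
            )
        )
    stats.n_kept = len(kept)
    return kept, stats


def dedupe_by_anchor(transcripts: Sequence[PolyATranscript]) -> list[PolyATranscript]:
    """Collapse transcripts sharing an identical anchor.

    The first occurrence (input order) is the representative; its
    ``n_copies`` accumulates the copies collapsed onto it.  Idempotent and
    order-preserving.
    """
    by_anchor: dict[str, PolyATranscript] = {}
    order: list[str] = []
    counts: dict[str, int] = {}
    for t in transcripts:
        if t.anchor in by_anchor:
            counts[t.anchor] += t.n_copies
        else:
            by_anchor[t.anchor] = t
            counts[t.anchor] = t.n_copies
            order.append(t.anchor)
    out = []
    for anchor in order:
        rep = by_anchor[anchor]
        if counts[anchor] != rep.n_copies:
            rep = PolyATranscript(
                id=rep.id,
                body=rep.body,
                tail_length=rep.tail_length,
                anchor=rep.anchor,
                tailstart_tx_coord=rep.tailstart_tx_coord,
                n_copies=counts[anchor],
            )
        out.append(rep)
    return out
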