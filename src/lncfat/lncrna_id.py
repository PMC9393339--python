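"""Candidate lncRNA calling by three-tool coding-potential consensus.

A transcript is a lncRNA candidate when all three coding-potential tools
(e.g. CNCI, CPC2 and PLEK, whose calls are supplied as input) agree it is
noncoding and its spliced length exceeds 200 nt. Transcripts missing a vote
from any tool are excluded and reported rather than assumed noncoding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .annotation import TranscriptModel

__all__ = [
    "CodingPotentialVote",
    "ConsensusResult",
    "consensus_noncoding",
    "flag_novel",
    "read_votes",
    "write_ids",
]

log = logging.getLogger(__name__)

TOOLS = ("CNCI", "CPC2", "PLEK")
MIN_LNCRNA_LENGTH = 200  # strict: length must exceed this


@dataclass(frozen=True)
class CodingPotentialVote:
    transcript_id: str
    tool: str
    call: str  # "coding" | "noncoding"

    def __post_init__(self) -> None:
        if self.call not in ("coding", "noncoding"):
            raise ValueError(f"call must be coding/noncoding, got {self.call!r}")


@dataclass
class ConsensusResult:
    """Candidate ids plus the transcripts excluded for missing votes."""

    candidates: set[str]
    missing_votes: set[str] = field(default_factory=set)
    too_short: set[str] = field(default_factory=set)


def consensus_noncoding(
    votes: list[CodingPotentialVote],
    transcripts: list[TranscriptModel],
    tools: tuple[str, ...] = TOOLS,
) -> ConsensusResult:
    """Return transcripts unanimously called noncoding and longer than 200 nt.

    Raises ``ValueError`` on conflicting duplicate votes for one
    (transcript, tool) pair; transcripts lacking a vote from any tool are
    excluded and listed in ``missing_votes`` with a logged warning.
    """
    table: dict[str, dict[str, str]] = {}
    for v in votes:
        calls = table.setdefault(v.transcript_id, {})
        if v.tool in calls and calls[v.tool] != v.call:
            raise ValueError(
                f"conflicting {v.tool} votes for transcript {v.transcript_id}"
            )
        calls[v.tool] = v.call

    result = ConsensusResult(candidates=set())
    for t in transcripts:
        calls = table.get(t.transcript_id, {})
        if any(tool not in calls for tool in tools):
            result.missing_votes.add(t.transcript_id)
            continue
        if all(calls[tool] == "noncoding" for tool in tools):
            if t.length > MIN_LNCRNA_LENGTH:
                result.candidates.add(t.transcript_id)
            else:
                result.too_short.add(t.transcript_id)
    if result.missing_votes:
        log.warning(
            "%d transcripts lacked votes from all %d tools and were excluded",
            len(result.missing_votes),
            len(tools),
        )
        warnings.warn(
            f"{len(result.missing_votes)} transcripts excluded for missing "
            "coding-potential votes",
            stacklevel=2,
        )
    return result


def flag_novel(candidates: set[str], reference_ids: set[str]) -> dict[str, bool]:
    """Flag each candidate as novel (True) iff absent from the reference id set."""
    return {c: c not in reference_ids for c in candidates}


def read_votes(path) -> list[CodingPotentialVote]:
    """Read votes from a TSV with columns transcript_id, tool, call."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"transcript_id", "tool", "call"}
    if not required.issubset(df.columns):
        raise ValueError(f"votes table needs columns {sorted(required)}")
    return [
        CodingPotentialVote(r.transcript_id, r.tool, r.call)
        for r in df.itertuples(index=False)
    ]


def write_ids(ids, path) -> None:
    """Write an id set as one-id-per-line text (sorted for determinism)."""
    with open(path, "w") as fh:
        for i in sorted(ids):
            fh.write(f"{i}\n")
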