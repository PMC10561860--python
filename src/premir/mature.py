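"""Mature-miRNA candidate extraction from precursor hairpins.

In insects, Dicer-1 excises a ~22 nt mature miRNA from one arm of the
precursor stem-loop. Lacking an enzyme offset model, candidates are taken
flush with the chosen hairpin loop: the 5p candidate ends immediately before
the loop's first unpaired base, the 3p candidate starts immediately after its
last. Coordinates are 1-based and inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .structure_io import RnaRecord, SecondaryStructure

__all__ = ["MatureCandidate", "mature_candidates"]


@dataclass(frozen=True)
class MatureCandidate:
    parent_id: str
    arm: str  # '5p' | '3p'
    start: int  # 1-based inclusive
    end: int
    sequence: str
    loop_index: int

    def fasta_header(self) -> str:
        return f"{self.parent_id}-{self.arm} pos={self.start}-{self.end} loop={self.loop_index}"


def mature_candidates(
    record: RnaRecord,
    structure: SecondaryStructure,
    arm: str = "5p",
    length: int = 22,
    loop_index: int = 1,
) -> MatureCandidate:
    """Extract the mature candidate on one arm of the chosen hairpin loop.

    ``loop_index`` selects among the structure's hairpin loops in 5'→3' order
    (1-based); multi-loop precursors therefore yield one candidate per
    (loop, arm) choice. The candidate is truncated with a warning when the
    arm is shorter than ``length``. Raises for unstructured input ("not a
    hairpin") or an out-of-range loop index.
    """
    if not 18 <= length <= 26:
        # mature miRNAs are ~22 nt; permit the documented 18-26 band only
        raise ValueError(f"mature length {length} outside the supported 18-26 range")
    if arm not in ("5p", "3p"):
        raise ValueError(f"arm must be '5p' or '3p', got {arm!r}")
    loops = structure.hairpin_loops
    if not loops:
        raise ValueError(f"record {record.id!r}: not a hairpin (no hairpin loop)")
    if not 1 <= loop_index <= len(loops):
        raise ValueError(
            f"record {record.id!r}: loop_index {loop_index} out of range "
            f"(structure has {len(loops)} hairpin loop(s))"
        )
    loop_start, loop_end = loops[loop_index - 1]
    if arm == "5p":
        end = loop_start - 1
        start = max(1, end - length + 1)
    else:
        start = loop_end + 1
        end = min(len(record), start + length - 1)
    if end - start + 1 < length:
        warnings.warn(
            f"record {record.id!r}: {arm} arm shorter than {length} nt; "
            f"candidate truncated to {end - start + 1} nt",
            stacklevel=2,
        )
    if end < start:
        raise ValueError(f"record {record.id!r}: {arm} arm has no sequence")
    return MatureCandidate(
        parent_id=record.id,
        arm=arm,
        start=start,
        end=end,
        sequence=record.sequence[start - 1 : end],
        loop_index=loop_index,
    )
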