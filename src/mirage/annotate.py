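"""Small-RNA read preprocessing and two-phase mature-miRNA annotation.

The workflow mirrors the standard small RNA-seq quantification recipe for
mature miRNAs:

1. drop every read containing an ``N``;
2. trim the 3' sequencing adapter, tolerating mismatches;
3. keep reads of 18-33 nt (the mature-miRNA size range);
4. annotate each read against a mature-miRNA reference in two phases:
   phase 1 places the whole read inside a reference (read <= reference,
   sense strand, ungapped, <= 2 mismatches); phase 2 rescues 3'-extended
   isomiRs by placing a whole mature sequence inside the read.

Both phases are exhaustive over (reference, offset) placements, so the
result is exact, not heuristic: the reported assignment is always the
mismatch-minimal placement under the documented tie-break.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import InputError

logger = logging.getLogger(__name__)

#: Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC"

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the read-cleanup stage.

    ``max_adapter_mismatches`` caps the mismatch budget of adapter
    detection; for a suffix/prefix overlap of length ``L`` the effective
    budget is ``min(max_adapter_mismatches, L // 8)`` and overlaps shorter
    than ``min_overlap`` are never trimmed, which prevents spurious 1-2 nt
    trims that a flat two-mismatch rule would allow.
    """

    adapter: str = DEFAULT_ADAPTER
    max_adapter_mismatches: int = 2
    min_len: int = 18
    max_len: int = 33
    min_overlap: int = 6

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise InputError(f"min_len {self.min_len} > max_len {self.max_len}")
        if not set(self.adapter) <= _DNA:
            raise InputError("adapter must be over the {A,C,G,T} alphabet")
        if self.max_adapter_mismatches < 0 or self.min_overlap < 1:
            raise InputError("negative mismatch budget or overlap")


@dataclass(frozen=True)
class Read:
    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise InputError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


class MatureReference:
    """Ordered id -> sequence mapping of mature miRNAs.

    Sequences are normalised to DNA (U -> T) on construction; file order is
    preserved because it is the final tie-break of the aligner.
    """

    def __init__(self, entries: Iterable[tuple[str, str]]):
        self.entries: dict[str, str] = {}
        for mirna_id, seq in entries:
            if mirna_id in self.entries:
                raise InputError(f"duplicate miRNA id {mirna_id!r} in reference")
            seq = seq.upper().replace("U", "T")
            if not seq:
                raise InputError(f"empty sequence for miRNA {mirna_id!r}")
            if not set(seq) <= _DNA:
                bad = sorted(set(seq) - _DNA)
                raise InputError(
                    f"miRNA {mirna_id!r}: non-ACGT characters {bad} in reference"
                )
            self.entries[mirna_id] = seq

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, mirna_id: str) -> str:
        return self.entries[mirna_id]

    def items(self):
        return self.entries.items()


@dataclass(frozen=True)
class Assignment:
    """A read placed against a mature sequence.

    ``offset`` is the 0-based start of the shorter sequence within the
    longer one: read-in-reference for phase 1, mature-in-read for phase 2.
    """

    read_id: str
    mirna_id: str
    phase: int
    mismatches: int
    offset: int


@dataclass
class CountTable:
    counts: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unassigned


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def filter_n(reads: Iterable[Read]) -> list[Read]:
    """Drop every read whose sequence contains an N; order preserved."""
    return [r for r in reads if "N" not in r.seq]


def _find_adapter_start(seq: str, params: PreprocessParams) -> Optional[int]:
    """Earliest position where the adapter (or a >= min_overlap prefix of it
    reaching the read's 3' end) matches within the mismatch budget."""
    adapter = params.adapter
    last = len(seq) - params.min_overlap
    for pos in range(0, last + 1):
        overlap = min(len(adapter), len(seq) - pos)
        budget = min(params.max_adapter_mismatches, overlap // 8)
        if _hamming(seq[pos : pos + overlap], adapter[:overlap]) <= budget:
            return pos
    return None


def trim_adapter(read: Read, params: PreprocessParams) -> Read:
    """Remove the 3' adapter and everything downstream of it.

    The earliest adapter occurrence wins, which is equivalent to removing
    the longest trimmable 3' portion. Iterated to a fixed point so the
    operation is idempotent. Quality is trimmed in lockstep. A read with no
    detectable adapter is returned unchanged.
    """
    seq, qual = read.seq, read.qual
    while True:
        pos = _find_adapter_start(seq, params)
        if pos is None:
            break
        seq, qual = seq[:pos], qual[:pos]
    if seq == read.seq:
        return read
    return Read(read.id, seq, qual)


def filter_length(reads: Iterable[Read], params: PreprocessParams) -> list[Read]:
    """Keep reads with min_len <= length <= max_len (18-33 nt by default)."""
    return [r for r in reads if params.min_len <= len(r.seq) <= params.max_len]


def preprocess(
    reads: Iterable[Read], params: PreprocessParams | None = None
) -> tuple[list[Read], dict[str, int]]:
    """Run N-filter -> adapter trim -> size filter; returns reads and stats."""
    params = params or PreprocessParams()
    reads = list(reads)
    no_n = filter_n(reads)
    trimmed = [trim_adapter(r, params) for r in no_n]
    kept = filter_length(trimmed, params)
    stats = {
        "input_reads": len(reads),
        "removed_n": len(reads) - len(no_n),
        "removed_length": len(no_n) - len(kept),
        "output_reads": len(kept),
    }
    return kept, stats


def _check_alignable(read: Read) -> None:
    if not set(read.seq) <= _DNA:
        raise InputError(
            f"read {read.id!r}: non-ACGT characters reached the aligner; "
            "run preprocessing first"
        )


def _best_hit(
    placements: Iterable[tuple[int, str, int, int]]
) -> Optional[tuple[str, int, int]]:
    """Pick the placement minimising (mismatches, offset, reference order).

    ``placements`` yields (ref_index, mirna_id, mismatches, offset) tuples
    already filtered to the mismatch budget. Ambiguity at the winning key's
    mismatch count (multi-mapping across miRNA family members) is logged.
    """
    best_key: Optional[tuple[int, int, int]] = None
    best_id = ""
    n_at_best_mm = 0
    for ref_index, mirna_id, mm, offset in placements:
        key = (mm, offset, ref_index)
        if best_key is None or key < best_key:
            if best_key is None or mm < best_key[0]:
                n_at_best_mm = 0
            best_key, best_id = key, mirna_id
        if mm == best_key[0]:
            n_at_best_mm += 1
    if best_key is None:
        return None
    if n_at_best_mm > 1:
        logger.debug(
            "ambiguous placement: %d candidates at %d mismatches; kept %s",
            n_at_best_mm, best_key[0], best_id,
        )
    return best_id, best_key[0], best_key[1]


def align_phase1(
    read: Read, ref: MatureReference, max_mm: int = 2
) -> Optional[Assignment]:
    """Place the whole read inside a mature sequence (read <= reference)."""
    _check_alignable(read)

    def placements():
        for ref_index, (mirna_id, mature) in enumerate(ref.items()):
            span = len(mature) - len(read.seq)
            for offset in range(span + 1):
                mm = _hamming(read.seq, mature[offset : offset + len(read.seq)])
                if mm <= max_mm:
                    yield ref_index, mirna_id, mm, offset

    hit = _best_hit(placements())
    if hit is None:
        return None
    mirna_id, mm, offset = hit
    return Assignment(read.id, mirna_id, phase=1, mismatches=mm, offset=offset)


def align_phase2(
    read: Read, ref: MatureReference, max_mm: int = 2
) -> Optional[Assignment]:
    """Place a whole mature sequence inside the read (read > reference).

    This rescues 3'-extended isomiRs that phase 1 cannot align because the
    read exceeds every compatible reference.
    """
    _check_alignable(read)

    def placements():
        for ref_index, (mirna_id, mature) in enumerate(ref.items()):
            if len(mature) >= len(read.seq):
                continue
            for offset in range(len(read.seq) - len(mature) + 1):
                mm = _hamming(mature, read.seq[offset : offset + len(mature)])
                if mm <= max_mm:
                    yield ref_index, mirna_id, mm, offset

    hit = _best_hit(placements())
    if hit is None:
        return None
    mirna_id, mm, offset = hit
    return Assignment(read.id, mirna_id, phase=2, mismatches=mm, offset=offset)


def annotate(
    reads: Iterable[Read],
    ref: MatureReference,
    max_mm: int = 2,
) -> tuple[list[Assignment], CountTable]:
    """Two-phase annotation: phase 1 first, phase 2 only on phase-1 failures.

    Every read contributes to exactly one tally, so per-miRNA counts plus
    the unassigned count always equal the number of input reads.
    """
    if len(ref) == 0:
        raise InputError("empty mature reference")
    assignments: list[Assignment] = []
    table = CountTable(counts={mirna_id: 0 for mirna_id in ref.entries})
    for read in reads:
        hit = align_phase1(read, ref, max_mm)
        if hit is None:
            hit = align_phase2(read, ref, max_mm)
        if hit is None:
            table.unassigned += 1
        else:
            assignments.append(hit)
            table.counts[hit.mirna_id] += 1
    return assignments, table
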