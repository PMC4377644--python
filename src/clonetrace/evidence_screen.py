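"""Site-specific screening of low-MAF mutant read evidence.

Reads putatively carrying a mutant allele are re-examined before they are
allowed to count toward presence of a mutation: each read is locally
realigned to the reference window around the site (a read whose best local
alignment restores the reference base was an alignment artefact), reads
where the variant base sits at a strict quality "valley" in a 5-bp window
are discarded as sequencing-error prone, and a site supported exclusively
by the overlapping portion of read pairs is treated as a PCR/fragment
artefact. A minimum of three surviving non-duplicate reads is required to
call the mutant allele present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

__all__ = [
    "ReadEvidence",
    "ScreenResult",
    "realign_read",
    "quality_valley_filter",
    "overlap_only_filter",
    "screen_site",
    "read_evidence_tsv",
]

#: Local-alignment scoring used for realignment. Chosen to prefer a single
#: gap over scattered mismatches, the artefact mode the filter targets.
SW_MATCH = 2
SW_MISMATCH = -1
SW_GAP_OPEN = -3
SW_GAP_EXTEND = -1

#: Cap on the number of co-optimal alignments examined per read.
_MAX_ALIGNMENTS = 256


@dataclass(frozen=True)
class ReadEvidence:
    """One read putatively supporting the mutant allele at a site."""

    read_id: str
    sequence: str
    base_qualities: tuple[int, ...]
    variant_offset: int
    orientation: str = "forward"
    duplicate: bool = False
    in_overlap_of_mates: bool = False

    def __post_init__(self) -> None:
        if len(self.base_qualities) != len(self.sequence):
            raise ValueError("qualities must match sequence length")
        if not (0 <= self.variant_offset < len(self.sequence)):
            raise ValueError("variant_offset must index into the read")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation: {self.orientation!r}")


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of screening all evidence at one site in one sample."""

    validated_mutant_count: int
    fail_reasons: dict[str, str]
    present: bool


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = SW_MATCH
    aligner.mismatch_score = SW_MISMATCH
    aligner.open_gap_score = SW_GAP_OPEN
    aligner.extend_gap_score = SW_GAP_EXTEND
    return aligner


def _read_base_at(alignment, target_pos: int) -> str | None:
    """Base of the aligned query at reference position, None if unaligned."""
    for (t_start, t_end), (q_start, q_end) in zip(*alignment.aligned):
        if t_start <= target_pos < t_end:
            return str(alignment.query[q_start + (target_pos - t_start)])
    return None


def realign_read(
    read_sequence: str, reference_window: str, variant_site: int
) -> str:
    """Locally realign a read against the reference window around a site.

    Returns ``"wildtype"`` if any best-scoring local alignment places the
    reference base at ``variant_site`` (or leaves the site uncovered), in
    which case the original mutant call was an alignment artefact;
    ``"supports_mutant"`` otherwise.
    """
    if not read_sequence or not reference_window:
        raise ValueError("read and reference sequences must be non-empty")
    if not (0 <= variant_site < len(reference_window)):
        raise ValueError("variant_site must index into the reference window")
    ref_base = reference_window[variant_site].upper()
    alignments = _aligner().align(
        reference_window.upper(), read_sequence.upper()
    )
    supports = False
    for i, aln in enumerate(alignments):
        if i >= _MAX_ALIGNMENTS:
            break
        base = _read_base_at(aln, variant_site)
        if base is None or base == ref_base:
            return "wildtype"
        supports = True
    return "supports_mutant" if supports else "wildtype"


def quality_valley_filter(evidence: ReadEvidence, window: int = 5) -> str:
    """Fail a read whose variant base is the strict quality minimum of a
    window centred on it (truncated at read ends). Ties pass: flat-quality
    reads carry no valley signal.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and positive")
    q = evidence.base_qualities
    off = evidence.variant_offset
    half = window // 2
    lo = max(0, off - half)
    hi = min(len(q), off + half + 1)
    neighbours = [q[i] for i in range(lo, hi) if i != off]
    if neighbours and q[off] < min(neighbours):
        return "fail"
    return "pass"


def overlap_only_filter(evidence_set: Sequence[ReadEvidence]) -> str:
    """Fail a site whose mutant evidence lies entirely within the
    overlapping portion of forward/reverse mate pairs."""
    if not evidence_set:
        raise ValueError("at least one mutant-supporting read is required")
    if all(e.in_overlap_of_mates for e in evidence_set):
        return "fail"
    return "pass"


def screen_site(
    evidence_set: Iterable[ReadEvidence],
    min_reads: int = 3,
    reference_window: str | None = None,
    variant_site: int | None = None,
) -> ScreenResult:
    """Run the full screening pipeline over the evidence at one site.

    Order: drop duplicates; realignment check (when a reference window is
    supplied); per-read quality-valley check; site-level overlap-only
    check. The validated mutant count is the number of survivors and the
    allele is called present when it reaches ``min_reads``.
    """
    fail_reasons: dict[str, str] = {}
    survivors: list[ReadEvidence] = []
    for ev in evidence_set:
        if ev.duplicate:
            fail_reasons[ev.read_id] = "duplicate"
            continue
        if reference_window is not None:
            if variant_site is None:
                raise ValueError(
                    "variant_site is required with reference_window"
                )
            verdict = realign_read(
                ev.sequence, reference_window, variant_site
            )
            if verdict == "wildtype":
                fail_reasons[ev.read_id] = "realign_wildtype"
                continue
        if quality_valley_filter(ev) == "fail":
            fail_reasons[ev.read_id] = "quality_valley"
            continue
        survivors.append(ev)
    if survivors and overlap_only_filter(survivors) == "fail":
        for ev in survivors:
            fail_reasons[ev.read_id] = "overlap_only"
        survivors = []
    count = len(survivors)
    return ScreenResult(
        validated_mutant_count=count,
        fail_reasons=fail_reasons,
        present=count >= min_reads,
    )


def read_evidence_tsv(path) -> list[ReadEvidence]:
    """Load evidence records from the plain-text fixture format.

    Columns (tab-separated, with header): read_id, sequence, qualities
    (comma-separated integers), offset, orientation, duplicate, overlap.
    """
    import csv

    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                ReadEvidence(
                    read_id=row["read_id"],
                    sequence=row["sequence"],
                    base_qualities=tuple(
                        int(x) for x in row["qualities"].split(",")
                    ),
                    variant_offset=int(row["offset"]),
                    orientation=row["orientation"],
                    duplicate=row["duplicate"].strip().lower()
                    in {"1", "true", "yes"},
                    in_overlap_of_mates=row["overlap"].strip().lower()
                    in {"1", "true", "yes"},
                )
            )
    return records
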