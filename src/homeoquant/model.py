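"""Core domain types shared across the package.

Conventions
-----------
* All internal coordinates are 0-based half-open.  GFF3 (1-based inclusive)
  and SAM (1-based) are converted at the I/O boundary only.
* A *subgenome* is identified by a short string label (e.g. ``"H"``/``"L"``
  for an allotetraploid, ``"A"``/``"B"``/``"D"`` for hexaploid wheat).  The
  label order declared for a run is fixed and used for deterministic
  tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Label for reads supported equally by all subgenomes (usable for
#: proportional distribution of counts).
COMMON = "COMMON"

#: Label for reads with conflicting or insufficient evidence (discarded).
UNKNOWN = "UNKNOWN"

CIGAR_OPS = frozenset("MIDNS")

_QUERY_CONSUMING = frozenset("MIS")
_REF_CONSUMING = frozenset("MDN")


def validate_subgenomes(labels) -> tuple[str, ...]:
    """Validate a subgenome label set: non-empty, unique, order preserved."""
    labels = tuple(labels)
    if not labels:
        raise ValueError("at least one subgenome label is required")
    if any(not s for s in labels):
        raise ValueError("subgenome labels must be non-empty strings")
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate subgenome labels: {labels}")
    return labels


@dataclass(frozen=True, slots=True)
class TranscriptModel:
    """A transcript (spliced gene model) on one subgenome.

    ``exons`` are genomic intervals in 0-based half-open coordinates, stored
    sorted in genomic order regardless of strand.
    """

    gene_id: str
    transcript_id: str
    subgenome: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if start < 0 or end <= start:
                raise ValueError(f"bad exon interval ({start}, {end})")
            if start < prev_end:
                raise ValueError(
                    f"exons of {self.transcript_id} overlap or are unsorted"
                )
            prev_end = end
        if self.spliced_length <= 0:
            raise ValueError(f"{self.transcript_id} has zero spliced length")

    @property
    def spliced_length(self) -> int:
        return sum(end - start for start, end in self.exons)


@dataclass(slots=True)
class SubgenomeAlignment:
    """One read's alignment against one subgenome reference.

    ``cigar`` uses ops from {M, I, D, N, S}; ``pos`` is 0-based.
    ``mismatches`` is an NM-style edit count (substitutions plus inserted and
    deleted bases; soft clips never count).  ``seq`` and ``base_quals`` are
    in reference orientation, as in SAM.
    """

    read_id: str
    mate: int  # 1, 2 or 0 (unpaired)
    subgenome: str
    contig: str
    pos: int
    cigar: tuple[tuple[str, int], ...]
    mismatches: int
    mapq: int
    seq: bytes = b""
    base_quals: bytes = b""
    is_secondary: bool = False
    is_reverse: bool = False

    def __post_init__(self):
        if self.mismatches < 0:
            raise ValueError("mismatch count must be >= 0")
        if not 0 <= self.mapq <= 255:
            raise ValueError("MAPQ must be in [0, 255]")
        for op, length in self.cigar:
            if op not in CIGAR_OPS or length <= 0:
                raise ValueError(f"bad CIGAR element ({op}, {length})")
        if self.seq:
            qlen = sum(n for op, n in self.cigar if op in _QUERY_CONSUMING)
            if qlen != len(self.seq):
                raise ValueError(
                    f"CIGAR consumes {qlen} query bases but read "
                    f"{self.read_id} has {len(self.seq)}"
                )

    @property
    def reference_span(self) -> int:
        """Number of reference bases consumed by the alignment."""
        return sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    @property
    def reference_end(self) -> int:
        return self.pos + self.reference_span

    def read_offset_at(self, ref_pos: int) -> Optional[int]:
        """Map a reference coordinate to an offset into ``seq``.

        Returns ``None`` when ``ref_pos`` falls in a deletion/skip or outside
        the aligned span.
        """
        # fast path: single-M (optionally soft-clipped) alignments
        if len(self.cigar) == 1 and self.cigar[0][0] == "M":
            off = ref_pos - self.pos
            return off if 0 <= off < self.cigar[0][1] else None
        ref = self.pos
        query = 0
        for op, length in self.cigar:
            if op == "M":
                if ref <= ref_pos < ref + length:
                    return query + (ref_pos - ref)
                ref += length
                query += length
            elif op in ("D", "N"):
                if ref <= ref_pos < ref + length:
                    return None
                ref += length
            else:  # I, S
                query += length
        return None


@dataclass(slots=True)
class ReadClassification:
    """Per-fragment classification outcome.

    ``posteriors`` maps each evaluable subgenome hypothesis to its posterior
    probability; they sum to 1 when at least one hypothesis was evaluable.
    ``label`` is a subgenome label, :data:`COMMON` or :data:`UNKNOWN`.
    """

    read_id: str
    posteriors: dict[str, float]
    label: str
    n_informative_sites: int = 0


# A truth table is simply read_id -> true subgenome of origin.
TruthTable = dict[str, str]
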