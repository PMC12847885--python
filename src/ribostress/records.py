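"""Domain record types.

All genomic intervals are stored internally as 0-based half-open
``(start, end)`` tuples; conversion from the 1-based inclusive convention
of GTF/GFF3 happens only at the I/O boundary (:mod:`ribostress.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import InputValidationError

Interval = tuple[int, int]

#: The 20 standard one-letter amino-acid codes, alphabetical.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class DERecord:
    """One row of a differential-results table.

    Parameters
    ----------
    feature_id : str
        Transcript, gene or protein identifier (join key).
    log2fc : float
        Log2 fold change, unitless and finite.
    pvalue : float
        Raw p-value in [0, 1].
    """

    feature_id: str
    log2fc: float
    pvalue: float

    def __post_init__(self) -> None:
        if not self.feature_id:
            raise InputValidationError("DERecord feature_id must be non-empty")
        if not (self.log2fc == self.log2fc and abs(self.log2fc) != float("inf")):
            raise InputValidationError(
                f"DERecord {self.feature_id!r}: log2fc must be finite, got {self.log2fc!r}"
            )
        if not 0.0 <= self.pvalue <= 1.0:
            raise InputValidationError(
                f"DERecord {self.feature_id!r}: pvalue {self.pvalue!r} outside [0, 1]"
            )


def _check_sorted_disjoint(ivals: list[Interval], what: str, tid: str) -> list[Interval]:
    ivals = sorted(ivals)
    prev_end = None
    for s, e in ivals:
        if e <= s:
            raise InputValidationError(f"transcript {tid!r}: empty/reversed {what} interval ({s}, {e})")
        if prev_end is not None and s < prev_end:
            raise InputValidationError(f"transcript {tid!r}: overlapping {what} intervals")
        prev_end = e
    return ivals


@dataclass
class TranscriptRecord:
    """Strand-aware exon/CDS interval set for one transcript.

    ``exons`` must be non-empty and pairwise non-overlapping; every CDS
    interval must lie inside the exon union.  ``utr5``/``utr3`` hold
    explicitly annotated UTR features when the source provides them.
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] | None = None
    utr3: list[Interval] | None = None

    def __post_init__(self) -> None:
        tid = self.transcript_id
        if not tid:
            raise InputValidationError("transcript_id must be non-empty")
        if self.strand not in ("+", "-"):
            raise InputValidationError(f"transcript {tid!r}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise InputValidationError(f"transcript {tid!r}: no exon features")
        self.exons = _check_sorted_disjoint(list(self.exons), "exon", tid)
        self.cds = _check_sorted_disjoint(list(self.cds), "CDS", tid)
        # CDS containment: walk both sorted lists in step.
        ei = 0
        for cs, ce in self.cds:
            while ei < len(self.exons) and self.exons[ei][1] <= cs:
                ei += 1
            if ei == len(self.exons) or cs < self.exons[ei][0] or ce > self.exons[ei][1]:
                raise InputValidationError(
                    f"transcript {tid!r}: CDS interval ({cs}, {ce}) not contained in the exon union"
                )
        if self.utr5 is not None:
            self.utr5 = _check_sorted_disjoint(list(self.utr5), "five_prime_utr", tid)
        if self.utr3 is not None:
            self.utr3 = _check_sorted_disjoint(list(self.utr3), "three_prime_utr", tid)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence keyed by its identifier.

    The sequence must be non-empty.  Residues outside the 20 standard
    codes are policed by the alphabet policy at composition time, not
    here, so that permissive mode can keep the raw record.
    """

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise InputValidationError("protein_id must be non-empty")
        if not self.sequence:
            raise InputValidationError(f"protein {self.protein_id!r}: empty sequence")
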