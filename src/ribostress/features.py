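"""Per-transcript architecture and per-protein composition features.

Transcript architecture: 5'UTR length, 3'UTR length and total exon length
(summed exon widths, i.e. mature transcript length — the mean exon width
is carried along as a secondary descriptor).  Protein composition: residue
counts and fractions over the 20 standard amino acids, sequence length,
average molecular weight, and the Ile/Val fractions and their quotient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, InputValidationError
from .records import AA_ALPHABET, ProteinRecord, TranscriptRecord

# Average (not monoisotopic) residue masses in daltons, Expasy values at
# 4-decimal precision; a free protein adds one water.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01528

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_MASS_VEC = np.array([RESIDUE_MASS[aa] for aa in AA_ALPHABET])
# byte-value -> alphabet index, 255 for anything outside the 20 codes
_BYTE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _aa, _i in _AA_INDEX.items():
    _BYTE_TO_IDX[ord(_aa)] = _i


@dataclass
class TranscriptFeatures:
    """Architecture features of one transcript (lengths in nucleotides).

    ``utr5_len``/``utr3_len`` are ``None`` when the transcript carries
    neither a CDS nor explicit UTR annotation.  For CDS-bearing
    transcripts ``utr5_len + cds_len + utr3_len == exon_len`` exactly.
    """

    transcript_id: str
    exon_len: int
    utr5_len: int | None
    utr3_len: int | None
    cds_len: int | None
    n_exons: int
    mean_exon_len: float


def transcript_architecture(t: TranscriptRecord) -> TranscriptFeatures:
    """Compute 5'UTR / 3'UTR / total exon length for one transcript.

    Explicit UTR features win when present; otherwise UTRs are derived
    strand-aware from the CDS span: the 5'UTR is the exonic sequence
    strictly upstream of the CDS start in transcript orientation.
    """
    exon_len = sum(e - s for s, e in t.exons)
    n_exons = len(t.exons)
    utr5 = utr3 = cds_len = None

    if t.utr5 is not None or t.utr3 is not None:
        utr5 = sum(e - s for s, e in t.utr5) if t.utr5 is not None else 0
        utr3 = sum(e - s for s, e in t.utr3) if t.utr3 is not None else 0
        if t.cds:
            cds_len = sum(e - s for s, e in t.cds)
        else:
            cds_len = exon_len - utr5 - utr3
    elif t.cds:
        cds_start = t.cds[0][0]
        cds_end = t.cds[-1][1]
        left = sum(max(0, min(e, cds_start) - s) for s, e in t.exons)
        right = sum(max(0, e - max(s, cds_end)) for s, e in t.exons)
        cds_len = exon_len - left - right
        utr5, utr3 = (left, right) if t.strand == "+" else (right, left)

    return TranscriptFeatures(
        transcript_id=t.transcript_id,
        exon_len=exon_len,
        utr5_len=utr5,
        utr3_len=utr3,
        cds_len=cds_len,
        n_exons=n_exons,
        mean_exon_len=exon_len / n_exons,
    )


@dataclass
class CompositionProfile:
    """Residue composition of one protein.

    ``counts`` and ``fraction`` are 20-vectors indexed by the alphabetised
    amino-acid order in :data:`ribostress.records.AA_ALPHABET`;
    ``ile_to_val`` is ``None`` when the protein contains no valine.
    """

    protein_id: str
    counts: np.ndarray
    aa_number: int
    mol_weight: float
    fraction: np.ndarray
    ile_fraction: float
    val_fraction: float
    ile_to_val: float | None


def _encode(sequence: str, protein_id: str, policy: str) -> np.ndarray:
    if policy not in ("strict", "permissive"):
        raise ConfigError(f"unknown alphabet policy {policy!r}")
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    idx = _BYTE_TO_IDX[raw]
    bad = idx == 255
    if bad.any():
        if policy == "strict":
            offending = sorted({sequence[i] for i in np.flatnonzero(bad)[:5]})
            raise InputValidationError(
                f"protein {protein_id!r}: residue(s) {offending} outside the 20 standard amino acids"
            )
        idx = idx[~bad]
    if idx.size == 0:
        raise InputValidationError(f"protein {protein_id!r}: no standard residues left to analyse")
    return idx


def molecular_weight(sequence: str, *, protein_id: str = "?", policy: str = "strict") -> float:
    """Average molecular weight of a peptide in daltons.

    Sum of average residue masses plus one water (18.01528 Da).  Under the
    permissive policy, non-standard residues contribute nothing.
    """
    if not sequence:
        raise InputValidationError("molecular_weight: empty sequence")
    idx = _encode(sequence, protein_id, policy)
    # count-then-dot keeps the sum independent of residue order
    counts = np.bincount(idx, minlength=20)
    return float(_MASS_VEC @ counts + WATER_MASS)


def aa_composition(p: ProteinRecord, *, policy: str = "strict") -> CompositionProfile:
    """Residue counts, fractions, length, weight and Ile/Val summary."""
    idx = _encode(p.sequence, p.protein_id, policy)
    counts = np.bincount(idx, minlength=20).astype(np.int64)
    n = int(counts.sum())
    fraction = counts / n
    ile = float(fraction[_AA_INDEX["I"]])
    val = float(fraction[_AA_INDEX["V"]])
    return CompositionProfile(
        protein_id=p.protein_id,
        counts=counts,
        aa_number=n,
        mol_weight=float(_MASS_VEC @ counts + WATER_MASS),
        fraction=fraction,
        ile_fraction=ile,
        val_fraction=val,
        ile_to_val=(ile / val) if val > 0 else None,
    )
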