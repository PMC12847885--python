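"""Readers and writers for the three standard inputs and the report.

GTF/GFF3 annotation, protein FASTA and tab-separated differential-results
tables come in; tab-separated comparison tables plus one YAML summary go
out.  External coordinates are 1-based inclusive (the GTF convention) and
are converted to 0-based half-open intervals here, at the boundary, and
nowhere else.
"""

from __future__ import annotations

import gzip
import hashlib
import os
import re
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .exceptions import ConfigError, InputValidationError
from .records import DERecord, ProteinRecord, TranscriptRecord

_FEATURE_TYPES = {"exon": "exon", "cds": "cds",
                  "five_prime_utr": "utr5", "three_prime_utr": "utr3"}
_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"([^=;\s]+)=([^;]*)")


def _open_text(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_attributes(attr_field: str, dialect: str, lineno: int) -> dict[str, str]:
    if dialect == "auto":
        dialect = "gff3" if ("=" in attr_field and '"' not in attr_field) else "gtf"
    pattern = _GTF_ATTR if dialect == "gtf" else _GFF3_ATTR
    attrs = dict(pattern.findall(attr_field))
    if not attrs:
        raise InputValidationError(f"line {lineno}: unparsable attribute field {attr_field!r}")
    return attrs


def _transcript_id_of(attrs: dict[str, str], lineno: int) -> str:
    tid = attrs.get("transcript_id")
    if tid is None:
        # GFF3 exon/CDS children point at their transcript via Parent
        tid = attrs.get("Parent", "").split(",")[0]
        tid = tid.removeprefix("transcript:")
    if not tid:
        raise InputValidationError(f"line {lineno}: no transcript identifier attribute")
    return tid


def read_gtf(path, dialect: str = "auto") -> list[TranscriptRecord]:
    """Read a GTF or GFF3 file into :class:`TranscriptRecord` objects.

    Only exon, CDS, five_prime_utr and three_prime_utr features are
    consulted; everything else (gene, transcript, start_codon, ...) is
    ignored.  ``dialect`` selects the attribute syntax (``key "value";``
    for GTF, ``key=value`` for GFF3) with per-line auto-detection by
    default.  Malformed lines raise with their line number.
    """
    if dialect not in ("auto", "gtf", "gff3"):
        raise ConfigError(f"unknown annotation dialect {dialect!r}")
    buckets: dict[str, dict] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise InputValidationError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            kind = _FEATURE_TYPES.get(cols[2].lower())
            if kind is None:
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise InputValidationError(f"line {lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise InputValidationError(f"line {lineno}: invalid coordinates {start}..{end}")
            strand = cols[6]
            if strand not in ("+", "-"):
                raise InputValidationError(f"line {lineno}: strand must be '+' or '-', got {strand!r}")
            attrs = _parse_attributes(cols[8], dialect, lineno)
            tid = _transcript_id_of(attrs, lineno)
            b = buckets.setdefault(tid, {"gene_id": attrs.get("gene_id", ""), "strand": strand,
                                         "exon": [], "cds": [], "utr5": [], "utr3": []})
            if b["strand"] != strand:
                raise InputValidationError(f"line {lineno}: transcript {tid!r} mixes strands")
            if not b["gene_id"]:
                b["gene_id"] = attrs.get("gene_id", "")
            b[kind].append((start - 1, end))  # to 0-based half-open

    out = []
    for tid in sorted(buckets):
        b = buckets[tid]
        if not b["exon"] and b["cds"]:
            raise InputValidationError(f"transcript {tid!r}: CDS features but no exon features")
        out.append(TranscriptRecord(
            transcript_id=tid, gene_id=b["gene_id"], strand=b["strand"],
            exons=b["exon"], cds=b["cds"],
            utr5=b["utr5"] or None, utr3=b["utr3"] or None,
        ))
    return out


def write_gtf(transcripts: list[TranscriptRecord], path) -> None:
    """Write transcripts back to GTF (1-based inclusive coordinates)."""
    with open(path, "wt") as fh:
        for t in transcripts:
            for kind, ivals in (("exon", t.exons), ("CDS", t.cds)):
                for s, e in ivals:
                    attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                    fh.write(f"chr1\tribostress\t{kind}\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n")


def read_protein_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA; first header token is the id, sequences uppercased."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            pid = rec.id
            if pid in seen:
                raise InputValidationError(f"duplicate protein id {pid!r}")
            seen.add(pid)
            seq = str(rec.seq).upper()
            if not seq:
                raise InputValidationError(f"protein {pid!r}: empty sequence")
            records.append(ProteinRecord(protein_id=pid, sequence=seq))
    return records


def write_fasta(proteins: list[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "wt") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


@dataclass
class DETableLoad:
    """A loaded DE table plus its load diagnostics."""

    records: list[DERecord]
    n_dropped: int = 0
    dropped_rows: list[int] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


DEFAULT_COLMAP = {"feature_id": "feature_id", "log2fc": "log2fc", "pvalue": "pvalue"}


def read_de_table(path, colmap: dict[str, str] | None = None) -> DETableLoad:
    """Read a tab-separated differential-results table.

    ``colmap`` maps the roles ``feature_id``/``log2fc``/``pvalue`` to the
    table's column names.  Rows whose numeric cells do not parse are
    dropped and counted; a p-value outside [0, 1] is a hard error naming
    the offending row (1-based, excluding the header).
    """
    colmap = {**DEFAULT_COLMAP, **(colmap or {})}
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise InputValidationError(f"DE table {path}: missing column(s) {missing} (have {list(df.columns)})")
    ids = df[colmap["feature_id"]]
    lfc = pd.to_numeric(df[colmap["log2fc"]], errors="coerce")
    pval = pd.to_numeric(df[colmap["pvalue"]], errors="coerce")

    bad_p = pval.notna() & ((pval < 0) | (pval > 1))
    if bad_p.any():
        row = int(bad_p.idxmax()) + 1
        raise InputValidationError(
            f"DE table {path}: p-value {pval[bad_p.idxmax()]} outside [0, 1] at data row {row}"
        )
    ok = lfc.notna() & pval.notna() & ids.notna() & (ids != "")
    dropped = [int(i) + 1 for i in df.index[~ok]]
    records = [
        DERecord(feature_id=i, log2fc=float(l), pvalue=float(p))
        for i, l, p in zip(ids[ok], lfc[ok], pval[ok])
    ]
    return DETableLoad(records=records, n_dropped=len(dropped), dropped_rows=dropped)


def write_de_table(records: list[DERecord], path) -> None:
    pd.DataFrame(
        {"feature_id": [r.feature_id for r in records],
         "log2fc": [r.log2fc for r in records],
         "pvalue": [r.pvalue for r in records]}
    ).to_csv(path, sep="\t", index=False)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# report writing

def _comparisons_frame(comps) -> pd.DataFrame:
    cols = ["feature", "label_a", "label_b", "n_a", "n_b", "method", "statistic",
            "pvalue", "adjusted_pvalue", "median_a", "median_b", "direction", "note"]
    rows = [{c: getattr(r, c) for c in cols} for r in comps]
    return pd.DataFrame(rows, columns=cols)


def write_report(results, out_dir) -> list[str]:
    """Write a fitted :class:`~ribostress.model.StressResults` to disk.

    One tab-separated file per analysis block plus ``summary.yaml`` with
    every test statistic, group size and the full run configuration.  The
    report is staged in a temporary directory and moved into place only
    when complete, so a failure never leaves a partial report behind.
    """
    out_dir = Path(out_dir)
    parent = out_dir.parent
    parent.mkdir(parents=True, exist_ok=True)
    if not os.access(parent, os.W_OK):
        raise InputValidationError(f"output location {parent} is not writable")
    staging = Path(tempfile.mkdtemp(prefix=".ribostress-", dir=parent))
    written: list[str] = []
    try:
        def emit(name: str, df: pd.DataFrame) -> None:
            df.to_csv(staging / name, sep="\t", index=False)
            written.append(name)

        tb, pb = results.transcript_block, results.protein_block
        if tb is not None:
            emit("decile_summary.tsv", tb.decile_summary)
            emit("decile_comparisons.tsv", _comparisons_frame(tb.decile_comparisons + tb.global_tests))
            emit("slice_comparisons.tsv", _comparisons_frame(tb.slice_comparisons))
        if pb is not None:
            emit("protein_comparisons.tsv", _comparisons_frame(pb.group_comparisons))
            emit("aa_fraction_comparisons.tsv", _comparisons_frame(pb.fraction_comparisons))
            emit("fc_slice_comparisons.tsv", _comparisons_frame(pb.slice_comparisons))

        with open(staging / "summary.yaml", "wt") as fh:
            yaml.safe_dump(results.summary_dict(), fh, sort_keys=False)
        written.append("summary.yaml")

        if out_dir.exists():
            shutil.rmtree(out_dir)
        os.replace(staging, out_dir)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    return written
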