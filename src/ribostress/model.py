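"""The ribosomal-stress selectivity model and its fitted results.

:class:`RibosomalStressModel` is built from a differential table plus
transcript annotation and/or protein sequences; ``fit()`` runs the whole
analysis and returns :class:`StressResults` carrying every comparison,
the decile summaries, the headline calls and a ``summary()`` table.

The analysis itself: the significant stratum (p < alpha) is ranked by
p-value and split into ten contiguous aliquots; architecture features
(5'UTR, 3'UTR, total exon length) are compared decile-1-vs-each-other
decile plus one global k-sample rank test, with top/bottom 2.5% slices
and the non-significant stratum as controls.  On the protein side,
significant vs non-significant proteins are compared on amino-acid
number, molecular weight and all 20 residue fractions (BH-adjusted), and
within the significant stratum the top vs bottom |log2FC| quarters are
compared on the Ile and Val fractions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as rio
from .exceptions import ConfigError, InputValidationError, JoinError
from .features import aa_composition, transcript_architecture
from .records import AA_ALPHABET, DERecord, ProteinRecord, TranscriptRecord
from .stats import (ComparisonResult, adjust_bh, compare_groups, kruskal_groups,
                    partition_aliquots, quantile_slice, rank_by_abs_lfc, rank_by_pvalue)

ARCH_FEATURES = ("utr5_len", "utr3_len", "exon_len")


@dataclass
class RunConfig:
    """Analysis configuration; the defaults are the study thresholds:
    significance at p < 0.05, ten aliquots, 2.5% extreme slices, 25%
    fold-change slices."""

    alpha: float = 0.05
    k_deciles: int = 10
    slice_frac_small: float = 0.025
    slice_frac_fc: float = 0.25
    test_method: str = "rank"
    seed: int = 0
    join_policy: str = "auto"
    alphabet_policy: str = "strict"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie strictly inside (0, 1), got {self.alpha!r}")
        if self.k_deciles < 1:
            raise ConfigError("k_deciles must be >= 1")
        if not 0.0 < self.slice_frac_small <= 0.5 or not 0.0 < self.slice_frac_fc <= 0.5:
            raise ConfigError("slice fractions must lie in (0, 0.5]")
        if self.test_method not in ("rank", "welch"):
            raise ConfigError(f"test_method must be 'rank' or 'welch', got {self.test_method!r}")
        if self.join_policy not in ("auto", "transcript", "gene"):
            raise ConfigError(f"unknown join_policy {self.join_policy!r}")
        if self.alphabet_policy not in ("strict", "permissive"):
            raise ConfigError(f"unknown alphabet_policy {self.alphabet_policy!r}")


def _not_computable(feature: str, label_a: str, label_b: str, n_a: int, n_b: int,
                    note: str) -> ComparisonResult:
    return ComparisonResult(
        label_a=label_a, label_b=label_b, n_a=n_a, n_b=n_b,
        statistic=float("nan"), pvalue=float("nan"),
        median_a=float("nan"), median_b=float("nan"),
        direction="none", feature=feature, note=note)


@dataclass
class TranscriptBlock:
    """Transcript-side results: decile summaries, decile-1-vs-others and
    global tests, extreme-slice comparisons, join diagnostics."""

    decile_summary: pd.DataFrame
    decile_comparisons: list[ComparisonResult]
    global_tests: list[ComparisonResult]
    slice_comparisons: list[ComparisonResult]
    headline: dict
    n_joined: int
    n_unjoined: int
    n_no_cds: int
    join_level: str
    stratum_sizes: dict
    decile_sizes: dict
    notes: list[str] = field(default_factory=list)


@dataclass
class ProteinBlock:
    """Protein-side results: significant-vs-nonsignificant size/weight and
    residue-fraction comparisons, T/B fold-change slice comparisons."""

    group_comparisons: list[ComparisonResult]
    fraction_comparisons: list[ComparisonResult]
    slice_comparisons: list[ComparisonResult]
    ile_to_val: dict
    headline: dict
    n_joined: int
    n_unjoined: int
    n_sig: int
    n_nonsig: int
    slice_size: int
    notes: list[str] = field(default_factory=list)


def _join(de_records, keys: set[str]):
    joined = [r for r in de_records if r.feature_id in keys]
    return joined, len(de_records) - len(joined)


def _transcript_join(de_records, transcripts, policy: str):
    """Join the DE table to the annotation at transcript or gene level.

    Gene-level tables are joined through a representative transcript per
    gene: the one with the longest total CDS, ties broken by id.
    """
    by_tid = {t.transcript_id: t for t in transcripts}
    tx_joined, tx_un = _join(de_records, set(by_tid))
    if policy == "transcript" or (policy == "auto" and tx_joined):
        return tx_joined, tx_un, by_tid, "transcript"

    rep: dict[str, TranscriptRecord] = {}
    for t in sorted(transcripts, key=lambda t: t.transcript_id):
        cds_len = sum(e - s for s, e in t.cds)
        cur = rep.get(t.gene_id)
        if cur is None or cds_len > sum(e - s for s, e in cur.cds):
            rep[t.gene_id] = t
    g_joined, g_un = _join(de_records, set(rep))
    if not g_joined:
        raise JoinError(
            "DE table matches no annotation ids at either transcript or gene level "
            f"(table n={len(de_records)}, annotation transcripts={len(by_tid)})")
    return g_joined, g_un, rep, "gene"


def run_transcript_analysis(de_records: list[DERecord],
                            transcripts: list[TranscriptRecord],
                            cfg: RunConfig) -> TranscriptBlock:
    """Decile / slice analysis of transcript architecture vs significance."""
    if not de_records or not transcripts:
        raise InputValidationError("transcript analysis needs DE records and annotation")
    joined, n_unjoined, lookup, join_level = _transcript_join(
        de_records, transcripts, cfg.join_policy)

    feats = {r.feature_id: transcript_architecture(lookup[r.feature_id]) for r in joined}
    n_no_cds = sum(1 for f in feats.values() if f.utr5_len is None)

    summary_rows: list[dict] = []
    decile_comps: list[ComparisonResult] = []
    global_tests: list[ComparisonResult] = []
    slice_comps: list[ComparisonResult] = []
    notes: list[str] = []
    stratum_sizes: dict = {}
    decile_sizes: dict = {}
    headline: dict = {}

    def fvalues(ids, feature):
        vals = [getattr(feats[i], feature) for i in ids]
        return np.array([v for v in vals if v is not None], dtype=float)

    for stratum in ("significant", "nonsignificant"):
        tag = "sig" if stratum == "significant" else "nonsig"
        try:
            ranked = rank_by_pvalue(joined, cfg.alpha, stratum)
        except InputValidationError as err:
            notes.append(f"{stratum} stratum skipped: {err}")
            stratum_sizes[stratum] = 0
            continue
        stratum_sizes[stratum] = len(ranked)

        # --- extreme 2.5% slices (run in both strata: the control check)
        top = quantile_slice(ranked, cfg.slice_frac_small, "top")
        bottom = quantile_slice(ranked, cfg.slice_frac_small, "bottom")
        for feature in ARCH_FEATURES:
            va, vb = fvalues(top, feature), fvalues(bottom, feature)
            la, lb = f"{tag}:top{100 * cfg.slice_frac_small:g}%", f"{tag}:bottom{100 * cfg.slice_frac_small:g}%"
            if va.size < 2 or vb.size < 2:
                slice_comps.append(_not_computable(feature, la, lb, va.size, vb.size,
                                                   "fewer than 2 values in a slice"))
            else:
                slice_comps.append(compare_groups(va, vb, cfg.test_method, la, lb, feature))

        # --- decile partition
        if len(ranked) < cfg.k_deciles:
            notes.append(f"{stratum} stratum too small for {cfg.k_deciles} aliquots")
            continue
        part = partition_aliquots(ranked, cfg.k_deciles)
        decile_sizes[stratum] = part.sizes
        for feature in ARCH_FEATURES:
            groups = [fvalues(g, feature) for g in part.groups]
            for label, g_ids, vals in zip(part.labels, part.groups, groups):
                q = (np.percentile(vals, [25, 50, 75]) if vals.size else [np.nan] * 3)
                summary_rows.append({
                    "stratum": stratum, "decile": label, "n": len(g_ids),
                    "feature": feature, "n_values": int(vals.size),
                    "q1": float(q[0]), "median": float(q[1]), "q3": float(q[2])})
            if min(g.size for g in groups) < 2:
                global_tests.append(_not_computable(
                    feature, f"{tag}:all-aliquots", "", len(ranked), 0,
                    "a decile holds fewer than 2 values"))
                extreme = None
            else:
                gt = kruskal_groups(groups, feature)
                gt.label_a = f"{tag}:all-aliquots"
                global_tests.append(gt)
                extreme = None
                for j in range(1, cfg.k_deciles):
                    comp = compare_groups(groups[0], groups[j], cfg.test_method,
                                          f"{tag}:{part.labels[0]}", f"{tag}:{part.labels[j]}",
                                          feature)
                    decile_comps.append(comp)
                    if j == cfg.k_deciles - 1:
                        extreme = comp
            if stratum == "significant":
                gt_ok = global_tests[-1].computable and global_tests[-1].pvalue < cfg.alpha
                ex_ok = extreme is not None and extreme.pvalue < cfg.alpha
                headline[feature] = {
                    "flag": bool(gt_ok and ex_ok),
                    "direction": ("decile1>decile10" if extreme is not None and extreme.direction == "a>b"
                                  else "decile1<decile10" if extreme is not None and extreme.direction == "a<b"
                                  else "none"),
                    "global_pvalue": global_tests[-1].pvalue,
                    "extreme_pvalue": extreme.pvalue if extreme is not None else float("nan"),
                }

    return TranscriptBlock(
        decile_summary=pd.DataFrame(summary_rows),
        decile_comparisons=decile_comps, global_tests=global_tests,
        slice_comparisons=slice_comps, headline=headline,
        n_joined=len(joined), n_unjoined=n_unjoined, n_no_cds=n_no_cds,
        join_level=join_level, stratum_sizes=stratum_sizes,
        decile_sizes=decile_sizes, notes=notes)


def run_protein_analysis(de_records: list[DERecord],
                         proteins: list[ProteinRecord],
                         cfg: RunConfig) -> ProteinBlock:
    """Composition analysis of significant vs non-significant proteins and
    of the top vs bottom |log2FC| quarters of the significant stratum."""
    if not de_records or not proteins:
        raise InputValidationError("protein analysis needs DE records and sequences")
    by_pid = {p.protein_id: p for p in proteins}
    joined, n_unjoined = _join(de_records, set(by_pid))
    if not joined:
        raise JoinError(
            f"protein DE table matches no FASTA ids (table n={len(de_records)}, "
            f"sequences={len(by_pid)})")

    profiles = {r.feature_id: aa_composition(by_pid[r.feature_id], policy=cfg.alphabet_policy)
                for r in joined}
    sig = [r for r in joined if r.pvalue < cfg.alpha]
    nonsig = [r for r in joined if r.pvalue >= cfg.alpha]
    notes: list[str] = []
    group_comps: list[ComparisonResult] = []
    fraction_comps: list[ComparisonResult] = []
    slice_comps: list[ComparisonResult] = []
    headline: dict = {}
    la, lb = f"P<{cfg.alpha:g}", f"P>={cfg.alpha:g}"

    def grab(records, attr):
        return np.array([getattr(profiles[r.feature_id], attr) for r in records], dtype=float)

    if len(sig) >= 2 and len(nonsig) >= 2:
        for attr in ("aa_number", "mol_weight"):
            comp = compare_groups(grab(sig, attr), grab(nonsig, attr),
                                  cfg.test_method, la, lb, attr)
            group_comps.append(comp)
            headline[attr] = {
                "flag": bool(comp.pvalue < cfg.alpha),
                "direction": ("sig>nonsig" if comp.direction == "a>b"
                              else "sig<nonsig" if comp.direction == "a<b" else "none"),
                "pvalue": comp.pvalue,
            }
        for i, aa in enumerate(AA_ALPHABET):
            va = np.array([profiles[r.feature_id].fraction[i] for r in sig])
            vb = np.array([profiles[r.feature_id].fraction[i] for r in nonsig])
            fraction_comps.append(compare_groups(va, vb, cfg.test_method, la, lb, f"frac_{aa}"))
        adjusted = adjust_bh([c.pvalue for c in fraction_comps])
        for comp, adj in zip(fraction_comps, adjusted):
            comp.adjusted_pvalue = adj
    else:
        notes.append("sig/nonsig comparison skipped: a stratum has fewer than 2 proteins")

    # --- T25% vs B25% of the significant stratum by |log2FC|
    m = 0
    if len(sig) >= 2:
        ranked = rank_by_abs_lfc(sig)
        top_ids = quantile_slice(ranked, cfg.slice_frac_fc, "top")
        bot_ids = quantile_slice(ranked, cfg.slice_frac_fc, "bottom")
        m = len(top_ids)
        lt = f"T{100 * cfg.slice_frac_fc:g}%"
        lbt = f"B{100 * cfg.slice_frac_fc:g}%"
        for attr, planted_dir in (("ile_fraction", "<"), ("val_fraction", ">")):
            va = np.array([profiles[i].fraction[AA_ALPHABET.index(attr[0].upper())] for i in top_ids])
            vb = np.array([profiles[i].fraction[AA_ALPHABET.index(attr[0].upper())] for i in bot_ids])
            if va.size < 2 or vb.size < 2:
                slice_comps.append(_not_computable(attr, lt, lbt, va.size, vb.size,
                                                   "slice smaller than 2"))
                continue
            comp = compare_groups(va, vb, cfg.test_method, lt, lbt, attr)
            slice_comps.append(comp)
            headline[attr] = {
                "flag": bool(comp.pvalue < cfg.alpha),
                "direction": (f"{lt}>{lbt}" if comp.direction == "a>b"
                              else f"{lt}<{lbt}" if comp.direction == "a<b" else "none"),
                "pvalue": comp.pvalue,
            }
    else:
        notes.append("fold-change slice analysis skipped: fewer than 2 significant proteins")

    def iv_summary(records):
        vals = [profiles[r.feature_id].ile_to_val for r in records]
        defined = [v for v in vals if v is not None]
        return {"n": len(vals), "n_undefined": len(vals) - len(defined),
                "median": float(np.median(defined)) if defined else float("nan")}

    return ProteinBlock(
        group_comparisons=group_comps, fraction_comparisons=fraction_comps,
        slice_comparisons=slice_comps,
        ile_to_val={"significant": iv_summary(sig), "nonsignificant": iv_summary(nonsig)},
        headline=headline, n_joined=len(joined), n_unjoined=n_unjoined,
        n_sig=len(sig), n_nonsig=len(nonsig), slice_size=m, notes=notes)


class RibosomalStressModel:
    """Selectivity model for ribosomal-stress differential data.

    Parameters
    ----------
    de_transcripts, transcripts :
        Transcript-level DE records and their annotation (either both or
        neither).
    de_proteins, proteins :
        Protein-level DE records and their sequences (either both or
        neither).
    config : RunConfig, optional
        Thresholds and policies; defaults to the study thresholds.
    """

    def __init__(self, de_transcripts=None, transcripts=None,
                 de_proteins=None, proteins=None,
                 config: RunConfig | None = None, provenance: dict | None = None):
        if (de_transcripts is None) != (transcripts is None):
            raise ConfigError("transcript analysis needs both a DE table and annotation")
        if (de_proteins is None) != (proteins is None):
            raise ConfigError("protein analysis needs both a DE table and sequences")
        if de_transcripts is None and de_proteins is None:
            raise ConfigError("nothing to analyse: provide transcript and/or protein inputs")
        self.de_transcripts = list(de_transcripts) if de_transcripts is not None else None
        self.transcripts = list(transcripts) if transcripts is not None else None
        self.de_proteins = list(de_proteins) if de_proteins is not None else None
        self.proteins = list(proteins) if proteins is not None else None
        self.config = config or RunConfig()
        self.provenance = provenance or {}

    @classmethod
    def from_files(cls, de=None, gtf=None, fasta=None, de_proteins=None,
                   colmap=None, config: RunConfig | None = None,
                   dialect: str = "auto") -> "RibosomalStressModel":
        """Build the model from a DE table plus GTF and/or FASTA paths.

        ``de`` pairs with ``gtf`` for the transcript side; the protein
        side uses ``de_proteins`` when given, else ``de``, paired with
        ``fasta``.
        """
        provenance: dict = {}
        de_tx = tx = de_pr = pr = None
        if gtf is not None:
            if de is None:
                raise ConfigError("--gtf given without a DE table")
            tx = rio.read_gtf(gtf, dialect=dialect)
            load = rio.read_de_table(de, colmap)
            de_tx = load.records
            provenance["gtf"] = rio.file_digest(gtf)
            provenance["de_transcripts"] = rio.file_digest(de)
            provenance["de_transcripts_dropped_rows"] = load.n_dropped
        if fasta is not None:
            prot_table = de_proteins if de_proteins is not None else de
            if prot_table is None:
                raise ConfigError("--fasta given without a DE table")
            pr = rio.read_protein_fasta(fasta)
            load = rio.read_de_table(prot_table, colmap)
            de_pr = load.records
            provenance["fasta"] = rio.file_digest(fasta)
            provenance["de_proteins"] = rio.file_digest(prot_table)
            provenance["de_proteins_dropped_rows"] = load.n_dropped
        return cls(de_transcripts=de_tx, transcripts=tx, de_proteins=de_pr,
                   proteins=pr, config=config, provenance=provenance)

    def fit(self) -> "StressResults":
        """Run the full analysis and return the results object."""
        tb = pb = None
        if self.de_transcripts is not None:
            tb = run_transcript_analysis(self.de_transcripts, self.transcripts, self.config)
        if self.de_proteins is not None:
            pb = run_protein_analysis(self.de_proteins, self.proteins, self.config)
        return StressResults(transcript_block=tb, protein_block=pb,
                             config=self.config, provenance=dict(self.provenance))


@dataclass
class StressResults:
    """Fitted results: comparison blocks, headline calls, config echo."""

    transcript_block: TranscriptBlock | None
    protein_block: ProteinBlock | None
    config: RunConfig
    provenance: dict

    @property
    def headline_calls(self) -> dict:
        calls: dict = {}
        if self.transcript_block is not None:
            calls.update({f: dict(v) for f, v in self.transcript_block.headline.items()})
        if self.protein_block is not None:
            calls.update({f: dict(v) for f, v in self.protein_block.headline.items()})
        return calls

    def summary_dict(self) -> dict:
        """Everything a rerun needs, as plain YAML-safe scalars."""
        d: dict = {
            "config": {k: (v if isinstance(v, str) else float(v) if isinstance(v, float) else int(v))
                       for k, v in dataclasses.asdict(self.config).items()},
            "provenance": dict(self.provenance),
            "headline_calls": _plain(self.headline_calls),
        }
        tb, pb = self.transcript_block, self.protein_block
        if tb is not None:
            d["transcripts"] = _plain({
                "n_joined": tb.n_joined, "n_unjoined": tb.n_unjoined,
                "n_no_cds": tb.n_no_cds, "join_level": tb.join_level,
                "stratum_sizes": tb.stratum_sizes, "decile_sizes": tb.decile_sizes,
                "notes": tb.notes})
        if pb is not None:
            d["proteins"] = _plain({
                "n_joined": pb.n_joined, "n_unjoined": pb.n_unjoined,
                "n_significant": pb.n_sig, "n_nonsignificant": pb.n_nonsig,
                "fc_slice_size": pb.slice_size, "ile_to_val": pb.ile_to_val,
                "notes": pb.notes})
        return d

    def summary(self) -> str:
        """Human-readable headline table."""
        lines = ["Ribosomal-stress selectivity analysis", "=" * 44]
        cfg = self.config
        lines.append(f"alpha={cfg.alpha:g}  deciles={cfg.k_deciles}  "
                     f"slices={cfg.slice_frac_small:g}/{cfg.slice_frac_fc:g}  test={cfg.test_method}")
        tb, pb = self.transcript_block, self.protein_block
        if tb is not None:
            sizes = tb.decile_sizes.get("significant", [])
            lines.append(f"\nTranscripts: joined={tb.n_joined} (level={tb.join_level}, "
                         f"unjoined={tb.n_unjoined}, no-CDS={tb.n_no_cds})")
            if sizes:
                lines.append(f"  significant deciles: n={min(sizes)}..{max(sizes)}")
        if pb is not None:
            lines.append(f"\nProteins: joined={pb.n_joined} "
                         f"(sig={pb.n_sig}, nonsig={pb.n_nonsig}, slice={pb.slice_size}/group)")
        lines.append("\nHeadline calls")
        lines.append(f"{'feature':<14}{'flag':<7}{'direction':<20}p-value")
        for feat, call in self.headline_calls.items():
            p = call.get("pvalue", call.get("extreme_pvalue", float("nan")))
            lines.append(f"{feat:<14}{str(call['flag']):<7}{call['direction']:<20}{p:.3g}")
        return "\n".join(lines)

    def save(self, out_dir) -> list[str]:
        """Write the tabular report blocks and summary.yaml (atomic)."""
        return rio.write_report(self, out_dir)


def _plain(obj):
    """Recursively convert numpy scalars for YAML serialisation."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    return obj


def run_full(cfg: RunConfig, de=None, gtf=None, fasta=None, de_proteins=None,
             colmap=None, dialect: str = "auto") -> StressResults:
    """One-call convenience: read the inputs, fit, return the results."""
    model = RibosomalStressModel.from_files(
        de=de, gtf=gtf, fasta=fasta, de_proteins=de_proteins,
        colmap=colmap, config=cfg, dialect=dialect)
    return model.fit()
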