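"""File formats: FASTA/FASTQ in, BED6/TSV/JSON out, minimal VCF-subset in.

All tables are tab-separated with a single header line beginning ``#``.
FASTA and FASTQ pass through Biopython's SeqIO; lowercase input is uppercased
on read and ``U`` is rejected (DNA only). Writers are atomic: content is
written to a temporary file in the destination directory and renamed into
place, so a failed run never leaves a partially written output.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .baseedit import CorrectabilityCall, VariantRecord
from .depletion import DepletionLogo, GuideSeqSummary, PamCountTable, PamWheelTable, PpdvTable, guideseq_summary
from .errors import ParameterError
from .pamscan import GenomeRecord, TargetSite


# ---------------------------------------------------------------------------
# atomic writing

def write_atomic(path: str | Path, content: str) -> Path:
    """Write text to *path* via a temp file + rename (never partial)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(content)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def write_json(path: str | Path, payload: object) -> Path:
    """JSON with stable key ordering."""
    return write_atomic(path, json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# sequences

def read_fasta(
    path: str | Path, circular: Iterable[str] | bool = False
) -> list[GenomeRecord]:
    """Read a (multi-)FASTA into :class:`GenomeRecord` objects.

    ``circular`` may be True (all records circular) or an iterable of record
    ids to mark circular.
    """
    circ_all = circular is True
    circ_ids = set() if isinstance(circular, bool) else set(circular)
    records = [
        GenomeRecord(rec.id, str(rec.seq).upper(), circ_all or rec.id in circ_ids)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return records


def write_fasta(records: Sequence[GenomeRecord], path: str | Path) -> Path:
    lines = []
    for rec in records:
        lines.append(f">{rec.id}")
        lines.extend(rec.seq[i : i + 70] for i in range(0, len(rec.seq), 70))
    return write_atomic(path, "\n".join(lines) + "\n")


def read_fastq_sequences(path: str | Path) -> list[str]:
    """Sequences only (merged reads) from a FASTQ file, uppercased."""
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# target sites

_SITE_COLUMNS = [
    "record_id", "strand", "proto_start", "proto_end", "pam_start", "pam_end",
    "spacer_len", "pam_seq", "protospacer_seq", "cut_pos", "record_len",
]


def sites_to_bed(sites: Sequence[TargetSite], path: str | Path) -> Path:
    """BED6 of protospacer intervals (name = PAM sequence, score = 0).

    On circular records a wrapped interval keeps ``end > record length``;
    reduce modulo the record length to recover positions.
    """
    rows = [
        f"{s.record_id}\t{s.protospacer[0]}\t{s.protospacer[1]}\t{s.pam_seq}\t0\t{s.strand}"
        for s in sites
    ]
    return write_atomic(path, "\n".join(rows) + ("\n" if rows else ""))


def sites_to_tsv(sites: Sequence[TargetSite], path: str | Path) -> Path:
    lines = ["#" + "\t".join(_SITE_COLUMNS)]
    for s in sites:
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    s.record_id, s.strand, s.protospacer[0], s.protospacer[1],
                    s.pam[0], s.pam[1], s.spacer_len, s.pam_seq,
                    s.protospacer_seq, s.cut_pos, s.record_len,
                )
            )
        )
    return write_atomic(path, "\n".join(lines) + "\n")


def sites_from_tsv(path: str | Path) -> list[TargetSite]:
    df = _read_table(path, _SITE_COLUMNS)
    return [
        TargetSite(
            record_id=str(row.record_id),
            strand=str(row.strand),
            protospacer=(int(row.proto_start), int(row.proto_end)),
            pam=(int(row.pam_start), int(row.pam_end)),
            spacer_len=int(row.spacer_len),
            pam_seq=str(row.pam_seq),
            cut_pos=int(row.cut_pos),
            protospacer_seq=str(row.protospacer_seq),
            record_len=int(row.record_len),
        )
        for row in df.itertuples(index=False)
    ]


def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = set(columns) - set(df.columns)
    if missing:
        raise ParameterError(f"{path}: missing column(s) {sorted(missing)!r}")
    return df


# ---------------------------------------------------------------------------
# depletion tables

def read_pam_counts(path: str | Path) -> PamCountTable:
    """PAM count TSV with columns ``pam`` and ``count``."""
    df = _read_table(path, ["pam", "count"])
    counts = {str(p): int(c) for p, c in zip(df["pam"], df["count"])}
    if not counts:
        raise ParameterError(f"{path}: empty PAM count table")
    k = len(next(iter(counts)))
    return PamCountTable(k, counts)


def write_pam_counts(table: PamCountTable, path: str | Path) -> Path:
    lines = ["#pam\tcount"]
    lines += [f"{p}\t{c}" for p, c in sorted(table.counts.items())]
    return write_atomic(path, "\n".join(lines) + "\n")


def count_pams_from_reads(reads: Iterable[str], pam_offset: int, k: int) -> PamCountTable:
    """Tally k-mer PAMs from fixed-layout reads (PAM at ``pam_offset``)."""
    counts: dict[str, int] = {}
    for read in reads:
        pam = read[pam_offset : pam_offset + k].upper()
        if len(pam) == k and "N" not in pam:
            counts[pam] = counts.get(pam, 0) + 1
    if not counts:
        raise ParameterError("no complete PAM sequences found in reads")
    return PamCountTable(k, counts)


def ppdv_to_tsv(table: PpdvTable, path: str | Path) -> Path:
    lines = ["#pam\tppdv\tefficacy_rank"]
    for pam in sorted(set(table.ppdv) | set(table.undefined)):
        if pam in table.undefined:
            lines.append(f"{pam}\tNA\tNA")
        else:
            lines.append(f"{pam}\t{table.ppdv[pam]:.6g}\t{table.efficacy_rank[pam]}")
    return write_atomic(path, "\n".join(lines) + "\n")


def logo_to_tsv(logo: DepletionLogo, path: str | Path) -> Path:
    pfm = logo.to_frame("pfm").add_prefix("pfm_")
    fc = logo.to_frame("log2fc").add_prefix("log2fc_")
    df = pd.concat([pfm, fc], axis=1).reset_index()
    return write_atomic(path, "#" + df.to_csv(sep="\t", index=False))


def wheel_to_tsv(wheel: PamWheelTable, path: str | Path) -> Path:
    lines = ["#trimer\tweight"]
    lines += [f"{k}\t{w:.6g}" for k, w in wheel.weights.items()]
    return write_atomic(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# variants

def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Variant TSV: variant_id, record_id, pos (0-based), ref, alt[, significance]."""
    df = _read_table(path, ["variant_id", "record_id", "pos", "ref", "alt"])
    sig = df["significance"] if "significance" in df.columns else [""] * len(df)
    return [
        VariantRecord(str(v), str(r), int(p), str(ref), str(alt), str(s))
        for v, r, p, ref, alt, s in zip(
            df["variant_id"], df["record_id"], df["pos"], df["ref"], df["alt"], sig
        )
    ]


def read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    """Minimal VCF subset: CHROM, POS (1-based), ID, REF, ALT; '#' lines skipped.

    Deliberately hand-parsed: the 'VCF-like' inputs accepted here need not
    carry the full header block htslib-based readers require.
    """
    variants = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParameterError(f"{path}:{line_no}: expected >= 5 VCF columns")
            chrom, pos, vid, ref, alt = fields[:5]
            variants.append(
                VariantRecord(vid, chrom, int(pos) - 1, ref.upper(), alt.upper())
            )
    return variants


def write_variants_tsv(variants: Sequence[VariantRecord], path: str | Path) -> Path:
    lines = ["#variant_id\trecord_id\tpos\tref\talt\tsignificance"]
    lines += [
        f"{v.variant_id}\t{v.record_id}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.significance}"
        for v in variants
    ]
    return write_atomic(path, "\n".join(lines) + "\n")


def calls_to_tsv(calls: Sequence[CorrectabilityCall], path: str | Path) -> Path:
    lines = ["#variant_id\teditor\tcorrectable\tprecise\tsupporting_sites"]
    lines += [
        "\t".join(
            (c.variant_id, c.editor, str(c.correctable), str(c.precise),
             ";".join(c.supporting_sites))
        )
        for c in calls
    ]
    return write_atomic(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GUIDE-seq summaries

def read_guideseq_tsv(path: str | Path) -> list[GuideSeqSummary]:
    """GUIDE-seq site summary TSV: site_id, on_reads, off_reads.

    ``off_reads`` is a semicolon-joined list of per-off-target read counts
    (empty field = no off-targets detected).
    """
    df = _read_table(path, ["site_id", "on_reads", "off_reads"])
    out = []
    for row in df.itertuples(index=False):
        raw = "" if pd.isna(row.off_reads) else str(row.off_reads)
        offs = [int(float(x)) for x in raw.split(";") if x != ""]
        out.append(guideseq_summary(str(row.site_id), int(row.on_reads), offs))
    return out


def guideseq_to_tsv(summaries: Sequence[GuideSeqSummary], path: str | Path) -> Path:
    lines = ["#site_id\ton_reads\toff_reads\tratio"]
    lines += [
        f"{s.site_id}\t{s.on_reads}\t{';'.join(map(str, s.off_reads))}\t{s.ratio:.6g}"
        for s in summaries
    ]
    return write_atomic(path, "\n".join(lines) + "\n")
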