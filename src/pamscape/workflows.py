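"""End-to-end, file-in/file-out pipelines over the library API.

One function per stage — scan, landscape, depletion, base-editor scoping,
amplicon indels, GUIDE-seq ratios, simulation — each validating its inputs
before computing, writing declared outputs atomically, and dropping a
machine-readable provenance record (config echo + package version) next to
them. These functions, together with the scripts in ``examples/``, are the
package's operational surface; there is no shell entry point.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import __version__
from . import io as pio
from .baseedit import BaseEditorModel, correctable_variants, scope_difference
from .depletion import compute_ppdv, depletion_logo, pam_wheel, top_depleted
from .errors import ParameterError
from .landscape import site_spacing, target_coverage, tata_box_targets
from .pamscan import GenomeRecord, find_pam_sites
from .ampindel import indel_rate
from .synth import (
    AmpliconSimConfig,
    DepletionSimConfig,
    VariantSimConfig,
    random_genome,
    simulate_amplicon,
    simulate_depletion,
    simulate_variants,
)

FRCAS9_MOTIF = "NNTA"
FRCAS9_SPACER = 22
SPCAS9_MOTIF = "NGG"
SPCAS9_SPACER = 20


def _provenance(out_dir: Path, stage: str, config: Mapping[str, object]) -> None:
    pio.write_json(
        out_dir / f"{stage}.provenance.json",
        {"tool": "pamscape", "version": __version__, "stage": stage, "config": dict(config)},
    )


def scan(
    fasta: str | Path,
    out_dir: str | Path,
    *,
    motif: str = FRCAS9_MOTIF,
    spacer_len: int = FRCAS9_SPACER,
    circular: Iterable[str] | bool = False,
    cut_offset: int = 3,
) -> dict[str, list]:
    """Enumerate target sites for every FASTA record; write BED6 + site TSV."""
    out_dir = Path(out_dir)
    records = pio.read_fasta(fasta, circular=circular)
    if not records:
        raise ParameterError(f"{fasta}: no FASTA records")
    all_sites = []
    per_record = {}
    for rec in records:
        sites = find_pam_sites(rec, motif, spacer_len, cut_offset=cut_offset)
        per_record[rec.id] = sites
        all_sites.extend(sites)
    pio.sites_to_bed(all_sites, out_dir / "sites.bed")
    pio.sites_to_tsv(all_sites, out_dir / "sites.tsv")
    _provenance(out_dir, "scan", {
        "fasta": str(fasta), "motif": motif, "spacer_len": spacer_len,
        "cut_offset": cut_offset, "n_sites": len(all_sites),
    })
    return per_record


def landscape_report(
    fasta: str | Path,
    out_dir: str | Path,
    *,
    motif: str = FRCAS9_MOTIF,
    spacer_len: int = FRCAS9_SPACER,
    circular: Iterable[str] | bool = False,
    tata_core: str | None = None,
) -> dict:
    """Coverage + spacing summary per record (and pooled), as JSON.

    Spacing never crosses record boundaries; the pooled mean is
    length-weighted. With ``tata_core`` set, TATA-box-anchored sites are
    also written as BED.
    """
    out_dir = Path(out_dir)
    records = pio.read_fasta(fasta, circular=circular)
    summary: dict = {"records": {}, "pooled": {}}
    pooled_cov = pooled_len = 0
    weighted_mean = weighted_len = 0.0
    tata_sites = []
    for rec in records:
        sites = find_pam_sites(rec, motif, spacer_len)
        cov = target_coverage(sites, rec)
        spacing = site_spacing(sites, rec)
        summary["records"][rec.id] = {
            "genome_len": len(rec),
            "n_sites": len(sites),
            "coverage": cov.fraction,
            "mean_spacing": spacing.mean if spacing.defined else None,
            "median_spacing": spacing.median if spacing.defined else None,
        }
        pooled_cov += cov.covered_positions
        pooled_len += len(rec)
        if spacing.defined:
            weighted_mean += spacing.mean * len(rec)
            weighted_len += len(rec)
        if tata_core:
            tata_sites.extend(tata_box_targets(rec, motif, spacer_len, tata_core))
    summary["pooled"] = {
        "coverage": pooled_cov / pooled_len if pooled_len else 0.0,
        "mean_spacing": weighted_mean / weighted_len if weighted_len else None,
    }
    pio.write_json(out_dir / "landscape.json", summary)
    if tata_core:
        pio.sites_to_bed(tata_sites, out_dir / "tata_sites.bed")
    _provenance(out_dir, "landscape", {
        "fasta": str(fasta), "motif": motif, "spacer_len": spacer_len,
        "tata_core": tata_core,
    })
    return summary


def depletion_report(
    selected_tsv: str | Path,
    control_tsv: str | Path,
    out_dir: str | Path,
    *,
    pseudocount: float = 0.0,
    quantile: float = 0.1,
    wheel_positions: tuple[int, int, int] = (2, 3, 4),
) -> dict:
    """PPDV table, top-decile logo matrices, and PAM wheel from count TSVs."""
    out_dir = Path(out_dir)
    selected = pio.read_pam_counts(selected_tsv)
    control = pio.read_pam_counts(control_tsv)
    table = compute_ppdv(selected, control, pseudocount)
    top = top_depleted(table, quantile)
    logo = depletion_logo(top) if top else None
    wheel = pam_wheel(table, wheel_positions)
    pio.ppdv_to_tsv(table, out_dir / "ppdv.tsv")
    if logo is not None:
        pio.logo_to_tsv(logo, out_dir / "logo.tsv")
    pio.wheel_to_tsv(wheel, out_dir / "wheel.tsv")
    summary = {
        "n_pams": len(table.ppdv),
        "n_undefined": len(table.undefined),
        "n_top_depleted": len(top),
        "min_ppdv": min(table.ppdv.values()) if table.ppdv else None,
        "wheel_empty": wheel.empty,
    }
    pio.write_json(out_dir / "depletion.json", summary)
    _provenance(out_dir, "depletion", {
        "selected": str(selected_tsv), "control": str(control_tsv),
        "pseudocount": pseudocount, "quantile": quantile,
    })
    return summary


def be_scope(
    fasta: str | Path,
    variants_path: str | Path,
    editors: Sequence[BaseEditorModel],
    out_dir: str | Path,
    *,
    motif: str = FRCAS9_MOTIF,
    spacer_len: int = FRCAS9_SPACER,
    circular: Iterable[str] | bool = False,
) -> dict:
    """Correctability calls per editor plus pairwise scope differences.

    Scopes are tallied both ways (the convention is emitted, not chosen for
    the caller): ``correctable`` = variant has >= 1 supporting window;
    ``precise`` = at least one supporting window is bystander-free.
    """
    out_dir = Path(out_dir)
    records = {r.id: r for r in pio.read_fasta(fasta, circular=circular)}
    variants_path = Path(variants_path)
    reader = pio.read_variants_vcf if variants_path.suffix == ".vcf" else pio.read_variants_tsv
    variants = reader(variants_path)
    missing = {v.record_id for v in variants} - set(records)
    if missing:
        raise ParameterError(f"variants reference unknown record(s): {sorted(missing)!r}")

    scopes: dict[str, dict[str, set]] = {}
    for editor in editors:
        calls = []
        for rec_id, rec in records.items():
            rec_variants = [v for v in variants if v.record_id == rec_id]
            calls.extend(
                correctable_variants(rec_variants, rec, motif, spacer_len, editor)
            )
        pio.calls_to_tsv(calls, out_dir / f"calls.{editor.name}.tsv")
        scopes[editor.name] = {
            "correctable": {c.variant_id for c in calls if c.correctable},
            "precise": {c.variant_id for c in calls if c.precise},
        }
    summary: dict = {"n_variants": len(variants), "editors": {}, "scope_differences": {}}
    for name, sets in scopes.items():
        summary["editors"][name] = {
            "n_correctable": len(sets["correctable"]),
            "n_precise": len(sets["precise"]),
        }
    for a in scopes:
        for b in scopes:
            if a != b:
                diff = scope_difference(scopes[a]["precise"], scopes[b]["precise"])
                summary["scope_differences"][f"{a}_vs_{b}"] = None if diff != diff else diff
    pio.write_json(out_dir / "be_scope.json", summary)
    _provenance(out_dir, "be_scope", {
        "fasta": str(fasta), "variants": str(variants_path),
        "editors": [asdict(e) for e in editors], "motif": motif,
        "spacer_len": spacer_len,
    })
    return summary


def amplicon_report(
    reads_path: str | Path,
    reference_fasta: str | Path,
    cut_offset: int,
    out_dir: str | Path,
    *,
    control_reads_path: str | Path | None = None,
    flank: int = 10,
    site_id: str = "site",
) -> dict:
    """Per-site indel rates from merged reads (FASTA or FASTQ)."""
    out_dir = Path(out_dir)

    def _reads(path: str | Path) -> list[str]:
        path = Path(path)
        if path.suffix in (".fq", ".fastq"):
            return pio.read_fastq_sequences(path)
        return [r.seq for r in pio.read_fasta(path)]

    reference = pio.read_fasta(reference_fasta)[0]
    reads = _reads(reads_path)
    control = _reads(control_reads_path) if control_reads_path else ()
    result = indel_rate(
        reads, reference.seq, cut_offset, control, site_id=site_id, flank=flank
    )
    row = (
        f"{result.site_id}\t{result.n_reads}\t{result.n_indel_reads}\t"
        f"{result.raw_rate:.6g}\t{result.control_rate:.6g}\t{result.corrected_rate:.6g}"
    )
    pio.write_atomic(
        out_dir / "indel_rates.tsv",
        "#site_id\tn_reads\tn_indel_reads\traw_rate\tcontrol_rate\tcorrected_rate\n"
        + row + "\n",
    )
    summary = {
        "site_id": result.site_id,
        "raw_rate": result.raw_rate,
        "control_rate": result.control_rate,
        "corrected_rate": result.corrected_rate,
        "n_reads": result.n_reads,
        "n_discarded": result.n_discarded,
    }
    pio.write_json(out_dir / "amplicon.json", summary)
    _provenance(out_dir, "amplicon", {
        "reads": str(reads_path), "reference": str(reference_fasta),
        "cut_offset": cut_offset, "flank": flank,
    })
    return summary


def guideseq_ratios(tsv_in: str | Path, out_dir: str | Path) -> list:
    """Recompute on:off ratios for a GUIDE-seq site summary table."""
    out_dir = Path(out_dir)
    summaries = pio.read_guideseq_tsv(tsv_in)
    pio.guideseq_to_tsv(summaries, out_dir / "guideseq_ratios.tsv")
    _provenance(out_dir, "guideseq", {"input": str(tsv_in), "n_sites": len(summaries)})
    return summaries


def simulate(
    out_dir: str | Path,
    *,
    seed: int = 0,
    genome_len: int = 5000,
    gc: float = 0.5,
    depletion: DepletionSimConfig | None = None,
    amplicon: AmpliconSimConfig | None = None,
    variants: VariantSimConfig | None = None,
    motif: str = FRCAS9_MOTIF,
    spacer_len: int = FRCAS9_SPACER,
    editor: BaseEditorModel | None = None,
) -> dict:
    """Generate a full synthetic input set (FASTA, count TSVs, reads, variants).

    Every sub-generator that is configured writes its outputs plus a truth
    table under *out_dir*; the returned dict lists what was produced.
    """
    out_dir = Path(out_dir)
    produced: dict = {}
    genome = random_genome(genome_len, gc=gc, seed=seed, record_id="synthgenome")
    pio.write_fasta([genome], out_dir / "genome.fasta")
    produced["genome"] = str(out_dir / "genome.fasta")
    if depletion is not None:
        control, selected, truth = simulate_depletion(depletion)
        pio.write_pam_counts(control, out_dir / "control_counts.tsv")
        pio.write_pam_counts(selected, out_dir / "selected_counts.tsv")
        pio.write_json(out_dir / "depletion_truth.json", {
            "rule": truth.rule, "retention": truth.retention,
            "n_matching": len(truth.matching_pams),
        })
        produced["depletion"] = [str(out_dir / "control_counts.tsv"),
                                 str(out_dir / "selected_counts.tsv")]
    if amplicon is not None:
        reads, labels = simulate_amplicon(amplicon, genome)
        pio.write_fasta(
            [GenomeRecord(f"read{i}", r) for i, r in enumerate(reads)],
            out_dir / "amplicon_reads.fasta",
        )
        pio.write_atomic(
            out_dir / "amplicon_truth.tsv",
            "#read_id\tplanted_indel\n"
            + "\n".join(f"read{i}\t{b}" for i, b in enumerate(labels)) + "\n",
        )
        produced["amplicon"] = str(out_dir / "amplicon_reads.fasta")
    if variants is not None:
        editor = editor or _default_editor()
        var_records, truth_pairs = simulate_variants(
            variants, genome, motif, spacer_len, editor
        )
        pio.write_variants_tsv(var_records, out_dir / "variants.tsv")
        pio.write_atomic(
            out_dir / "variants_truth.tsv",
            "#variant_id\tcorrectable\tprecise\n"
            + "\n".join(
                f"{v.variant_id}\t{c}\t{p}"
                for v, (c, p) in zip(var_records, truth_pairs)
            ) + "\n",
        )
        produced["variants"] = str(out_dir / "variants.tsv")
    _provenance(out_dir, "simulate", {"seed": seed, "genome_len": genome_len, "gc": gc})
    return produced


def _default_editor() -> BaseEditorModel:
    from .baseedit import FRCAS9_BE4GAM

    return FRCAS9_BE4GAM
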