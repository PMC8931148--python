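"""Base-editor models and correctable-variant scoping.

A base editor is a Cas9-nickase-deaminase fusion converting C->T (cytidine
base editors, CBE) or A->G (adenine base editors, ABE) inside an editing
window of protospacer positions, counted 1-based from the PAM-distal 5' end
of the protospacer — the standard convention. For the FrCas9 fusions the
windows are positions 6-10 (BE4Gam) and 6-8 (ABE7.10); the SpCas9
comparators default to the canonical literature windows on a 20-nt spacer.

A pathogenic SNV is *correctable* by an editor when some target site on the
patient (alt-carrying) sequence places the variant inside the editing window
with the site-strand base equal to the editor's substrate, such that the
conversion restores the reference allele. CBEs therefore correct T>C
transitions via a plus-strand site and A>G via the opposite strand; ABEs
correct the complementary pairs. A call is *precise* when at least one
supporting site has no bystander — no other substrate base inside its
window on the site strand.

The palindromic-core PAM gives divergent back-to-back site pairs, hence two
disjoint editing windows flanking the shared TA: :func:`double_window`
returns that geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan
from typing import Sequence

from .alphabet import complement, validate_dna
from .errors import DataError, ParameterError
from .pamscan import (
    BackToBackPair,
    GenomeRecord,
    PamMotif,
    TargetSite,
    find_pam_sites,
)

Interval = tuple[int, int]

_CONVERSIONS = {("C", "T"), ("A", "G")}


@dataclass(frozen=True)
class BaseEditorModel:
    """A deaminase chemistry plus its protospacer editing window.

    ``window_start``/``window_end`` are 1-based inclusive protospacer
    positions counted from the PAM-distal 5' end.
    """

    name: str
    from_base: str
    to_base: str
    window_start: int
    window_end: int

    def __post_init__(self) -> None:
        if (self.from_base, self.to_base) not in _CONVERSIONS:
            raise ParameterError(
                f"unsupported conversion {self.from_base}->{self.to_base}; "
                "base editors convert C->T (CBE) or A->G (ABE)"
            )
        if not 1 <= self.window_start <= self.window_end:
            raise ParameterError(
                f"invalid editing window {self.window_start}-{self.window_end}"
            )


#: FrCas9 cytidine editor: window measured at protospacer positions 6-10.
FRCAS9_BE4GAM = BaseEditorModel("FrCas9-BE4Gam", "C", "T", 6, 10)
#: FrCas9 adenine editor: window at positions 6-8.
FRCAS9_ABE710 = BaseEditorModel("FrCas9-ABE7.10", "A", "G", 6, 8)
#: Canonical SpCas9 comparators (literature windows, configurable).
SPCAS9_BE4GAM = BaseEditorModel("SpCas9-BE4Gam", "C", "T", 4, 8)
SPCAS9_ABE710 = BaseEditorModel("SpCas9-ABE7.10", "A", "G", 4, 7)


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant on the plus strand of a record."""

    variant_id: str
    record_id: str
    pos: int
    ref: str
    alt: str
    significance: str = ""

    def __post_init__(self) -> None:
        validate_dna(self.ref, context="ref allele")
        validate_dna(self.alt, context="alt allele")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ParameterError(f"variant {self.variant_id}: SNVs only")
        if self.ref == self.alt:
            raise ParameterError(f"variant {self.variant_id}: ref == alt")


@dataclass(frozen=True)
class CorrectabilityCall:
    """Whether (and how cleanly) one editor can revert one variant."""

    variant_id: str
    editor: str
    correctable: bool
    precise: bool
    supporting_sites: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.precise and not self.correctable:
            raise ParameterError("precise implies correctable")


def _window_coords(site: TargetSite, editor: BaseEditorModel) -> list[int]:
    """Plus-strand coordinates of window positions window_start..window_end."""
    if editor.window_end > site.spacer_len:
        raise ParameterError(
            f"editing window {editor.window_start}-{editor.window_end} exceeds "
            f"spacer length {site.spacer_len}"
        )
    a, b = site.protospacer
    L = site.record_len or None
    coords = []
    for j in range(editor.window_start, editor.window_end + 1):
        c = a + j - 1 if site.strand == "+" else b - j
        coords.append(c % L if L else c)
    return coords


def editable_positions(site: TargetSite, editor: BaseEditorModel) -> list[int]:
    """Plus-strand coordinates of substrate bases inside the editing window.

    A position qualifies when its *site-strand* base equals the editor's
    ``from_base``; coordinates are returned in window order (PAM-distal
    first).
    """
    coords = _window_coords(site, editor)
    out = []
    for j, coord in zip(range(editor.window_start, editor.window_end + 1), coords):
        if site.protospacer_seq[j - 1] == editor.from_base:
            out.append(coord)
    return out


def window_interval(site: TargetSite, editor: BaseEditorModel) -> Interval:
    """The editing window as one plus-strand half-open interval."""
    if editor.window_end > site.spacer_len:
        raise ParameterError("editing window exceeds spacer length")
    a, b = site.protospacer
    if site.strand == "+":
        return (a + editor.window_start - 1, a + editor.window_end)
    return (b - editor.window_end, b - editor.window_start + 1)


def double_window(
    pair: BackToBackPair, editor: BaseEditorModel
) -> tuple[Interval, Interval]:
    """The two genomic editing windows of a back-to-back site pair.

    Returns ``(plus_window, minus_window)`` as plus-strand intervals; they
    are disjoint and flank the shared 6-bp NNTANN core symmetrically.
    """
    return (
        window_interval(pair.plus_site, editor),
        window_interval(pair.minus_site, editor),
    )


def _site_strand_base(site: TargetSite, plus_base: str) -> str:
    return plus_base if site.strand == "+" else complement(plus_base)


def correctable_variants(
    variants: Sequence[VariantRecord],
    genome: GenomeRecord,
    motif: PamMotif | str,
    spacer_len: int,
    editor: BaseEditorModel,
    *,
    cut_offset: int = 3,
) -> list[CorrectabilityCall]:
    """Scope which SNVs the editor can revert on the patient sequence.

    *genome* is the reference; each variant's ``ref`` must match it at
    ``pos`` (violations are collected into one :class:`DataError`). Each
    variant is evaluated independently on the alt-carrying (patient)
    sequence, since the editor must revert alt -> ref in a patient genome:
    the variant is correctable iff some target site of the patient sequence
    places it in the editing window with site-strand alt == ``from_base``
    and site-strand ref == ``to_base``. Precise additionally requires a
    supporting site whose window contains no bystander substrate base.
    """
    if isinstance(motif, str):
        motif = PamMotif(motif)
    L = len(genome)
    mismatches = [
        f"{v.variant_id}@{v.pos}:{v.ref}!={genome.seq[v.pos]}"
        for v in variants
        if not 0 <= v.pos < L or genome.seq[v.pos] != v.ref
    ]
    if mismatches:
        raise DataError("variant ref alleles inconsistent with genome: " + ", ".join(mismatches))

    m = len(motif)
    span = spacer_len + m
    calls = []
    for variant in variants:
        patient = genome.seq[: variant.pos] + variant.alt + genome.seq[variant.pos + 1 :]
        if genome.circular or L <= 4 * span:
            region = GenomeRecord(genome.id, patient, genome.circular)
            offset = 0
        else:
            lo = max(0, variant.pos - span)
            hi = min(L, variant.pos + span + 1)
            region = GenomeRecord(genome.id, patient[lo:hi], False)
            offset = lo
        supporting = []
        precise = False
        for site in find_pam_sites(region, motif, spacer_len, cut_offset=cut_offset):
            if offset:
                site = TargetSite(
                    record_id=site.record_id,
                    strand=site.strand,
                    protospacer=(site.protospacer[0] + offset, site.protospacer[1] + offset),
                    pam=(site.pam[0] + offset, site.pam[1] + offset),
                    spacer_len=site.spacer_len,
                    pam_seq=site.pam_seq,
                    cut_pos=site.cut_pos + offset,
                    protospacer_seq=site.protospacer_seq,
                    record_len=L,
                )
            if editor.window_end > site.spacer_len:
                raise ParameterError("editing window exceeds spacer length")
            editable = editable_positions(site, editor)
            if variant.pos not in editable:
                continue
            if _site_strand_base(site, variant.ref) != editor.to_base:
                continue  # conversion would not restore the reference allele
            supporting.append(site.site_id)
            if len(editable) == 1:  # no bystander substrate in this window
                precise = True
        calls.append(
            CorrectabilityCall(
                variant_id=variant.variant_id,
                editor=editor.name,
                correctable=bool(supporting),
                precise=precise,
                supporting_sites=tuple(supporting),
            )
        )
    return calls


def scope_difference(scope_a: set[str], scope_b: set[str]) -> float:
    """Fraction of editor A's scope absent from editor B: |A \\ B| / |A|.

    Returns NaN (the undefined flag) for an empty ``scope_a``.
    """
    if not scope_a:
        return nan
    return len(scope_a - scope_b) / len(scope_a)
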