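"""Genome-scale target-landscape statistics.

Coverage (what fraction of a genome lies under at least one protospacer),
inter-site spacing (how densely guides tile the genome), raw dinucleotide
PAM-anchor spacing (TA vs. GG landscapes), and TATA-box targeting geometry.
These are the statistics used to compare a palindromic-core nuclease like
FrCas9 (NNTA, spacer 22) against SpCas9 (NGG, spacer 20) on viral and human
genomes.

Spacing conventions are documented and switchable because published figures
rarely state them: anchors are cut positions for target sites and word start
positions for dinucleotides; with both-strand counting a palindromic word
(TA) contributes two coincident anchors per locus (one per orientation),
which makes the circular-record mean exactly ``L / (2 * #TA)``. Means are
the calibrated statistic; medians are reported but convention-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alphabet import reverse_complement, validate_dna
from .errors import ConsistencyError, ParameterError
from .pamscan import GenomeRecord, PamMotif, TargetSite, find_pam_sites


@dataclass(frozen=True)
class SpacingSummary:
    """Distances between consecutive anchors along a record.

    ``defined`` is False when fewer than two anchor gaps exist (then ``mean``
    and ``median`` are NaN rather than an exception). On a circular record
    the wrap-around gap is included, so the distances sum to the record
    length exactly.
    """

    n_sites: int
    distances: tuple[int, ...]
    mean: float
    median: float
    defined: bool


@dataclass(frozen=True)
class CoverageResult:
    """Fraction of genome positions overlapped by >= 1 protospacer."""

    covered_positions: int
    genome_len: int
    fraction: float


def _summarize(distances: Sequence[int], n_anchors: int) -> SpacingSummary:
    if len(distances) == 0:
        return SpacingSummary(n_anchors, (), float("nan"), float("nan"), False)
    arr = np.asarray(distances)
    return SpacingSummary(
        n_sites=n_anchors,
        distances=tuple(int(d) for d in distances),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        defined=True,
    )


def spacing_from_positions(
    positions: Sequence[int], length: int, circular: bool
) -> SpacingSummary:
    """Spacing summary for sorted anchor positions on one record.

    Linear records need >= 2 anchors for any distance; circular records
    include the wrap-around gap, so a single anchor yields one distance of
    ``length`` and the distances always sum to ``length``.
    """
    pos = sorted(int(p) % length if circular else int(p) for p in positions)
    n = len(pos)
    if n == 0 or (not circular and n < 2):
        return _summarize((), n)
    gaps = [b - a for a, b in zip(pos, pos[1:])]
    if circular:
        gaps.append(length - pos[-1] + pos[0])
    return _summarize(gaps, n)


def target_coverage(sites: Sequence[TargetSite], genome: GenomeRecord) -> CoverageResult:
    """Fraction of the genome under >= 1 protospacer (PAM bases excluded).

    "Target coverage" counts editable sequence, i.e. the union of
    protospacer intervals over both strands; pass sites built with the PAM
    interval appended if a PAM-inclusive definition is wanted.
    """
    L = len(genome)
    if L == 0:
        return CoverageResult(0, 0, 0.0)
    mask = np.zeros(L, dtype=bool)
    for site in sites:
        if site.record_id != genome.id:
            raise ConsistencyError(f"site {site.site_id} is not from record {genome.id!r}")
        start, end = site.protospacer
        if not genome.circular and (start < 0 or end > L):
            raise ConsistencyError(
                f"site {site.site_id} protospacer {site.protospacer} outside linear record"
            )
        mask[np.arange(start, end) % L] = True
    covered = int(mask.sum())
    return CoverageResult(covered, L, covered / L)


def site_spacing(sites: Sequence[TargetSite], genome: GenomeRecord) -> SpacingSummary:
    """Distances between consecutive cut positions, both strands merged.

    Coincident cuts (e.g. the two members of a back-to-back pair falling on
    nearby coordinates, or duplicate anchors) contribute zero distances.
    """
    for site in sites:
        if site.record_id != genome.id:
            raise ConsistencyError(f"site {site.site_id} is not from record {genome.id!r}")
    return spacing_from_positions(
        [s.cut_pos for s in sites], len(genome), genome.circular
    )


def _word_starts(seq: str, word: str, circular: bool) -> np.ndarray:
    """Plus-strand start positions of a 2-mer, overlap-tolerant."""
    L = len(seq)
    if L < 2:
        return np.empty(0, dtype=np.int64)
    scan = seq + seq[0] if circular else seq
    arr = np.frombuffer(scan.encode("ascii"), dtype=np.uint8)
    hits = np.nonzero((arr[:-1] == ord(word[0])) & (arr[1:] == ord(word[1])))[0]
    return hits[hits < L] if circular else hits


def dinucleotide_spacing(
    genome: GenomeRecord, word: str, count_both_strands: bool = True
) -> SpacingSummary:
    """Spacing between occurrences of a dinucleotide PAM anchor.

    Anchors are plus-strand start positions of *word*. With
    ``count_both_strands``: a non-palindromic word also counts its reverse
    complement (GG also counts CC); a palindromic word (TA, GC, ...)
    contributes two coincident anchors per occurrence, one per strand
    orientation — the convention under which every anchor corresponds to one
    orientable PAM.
    """
    word = word.upper()
    if len(word) != 2:
        raise ParameterError(f"word must be a dinucleotide, got {word!r}")
    validate_dna(word, context="dinucleotide word")
    starts = _word_starts(genome.seq, word, genome.circular)
    if count_both_strands:
        rc = reverse_complement(word)
        if rc == word:
            anchors = np.repeat(starts, 2)
        else:
            anchors = np.concatenate([starts, _word_starts(genome.seq, rc, genome.circular)])
    else:
        anchors = starts
    return spacing_from_positions(anchors.tolist(), len(genome), genome.circular)


def tata_box_targets(
    promoter: GenomeRecord,
    motif: PamMotif | str,
    spacer_len: int,
    tata_core: str = "TATAAATAAT",
    *,
    cut_offset: int = 3,
) -> list[TargetSite]:
    """Target sites whose PAM TA core lies inside a TATA-box core occurrence.

    The default core, 5'-TATAAATAAT-3', carries three TA dinucleotides, so a
    TA-core PAM can engage a canonical TATA box from up to six sites (three
    anchors x two strands), flank length permitting. Returns the subset of
    :func:`find_pam_sites` output anchored within any occurrence of
    *tata_core* in the promoter; absent core -> empty list.
    """
    if isinstance(motif, str):
        motif = PamMotif(motif)
    core_off = motif.ta_core_offset()
    if core_off is None:
        raise ParameterError(f"motif {motif.iupac!r} has no literal TA core")
    tata_core = tata_core.upper()
    validate_dna(tata_core, context="tata_core")
    L = len(promoter)
    scan = promoter.seq * 2 if promoter.circular else promoter.seq
    covered = np.zeros(L, dtype=bool)
    start = scan.find(tata_core)
    while 0 <= start < L:
        covered[np.arange(start, start + len(tata_core)) % L] = True
        start = scan.find(tata_core, start + 1)
    if not covered.any():
        return []
    m = len(motif)
    out = []
    for site in find_pam_sites(promoter, motif, spacer_len, cut_offset=cut_offset):
        if site.strand == "+":
            ta = site.pam[0] + core_off
        else:
            ta = site.pam[0] + (m - core_off - 2)
        ta %= L
        if covered[ta] and covered[(ta + 1) % L]:
            out.append(site)
    return out
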