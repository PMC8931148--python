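"""Target-site enumeration for PAM-dependent nucleases.

The scanner enumerates every protospacer+PAM placement of an IUPAC PAM motif
on both strands of a (possibly circular) DNA record. The motif sits
immediately 3' of the protospacer on the protospacer's strand — the layout
used by Cas9-family nucleases. For a palindromic-core PAM such as FrCas9's
5'-NNTA-3', every TA dinucleotide anchors one site per strand, which yields
the divergent "back-to-back" guide pairs handled here as first-class objects.

Coordinate conventions
----------------------
All intervals are 0-based, half-open, reported on the plus strand
(BED-compatible). Minus-strand features store plus-strand intervals plus a
strand flag. On circular records a feature may wrap the origin; wrapped
intervals keep ``start`` in ``[0, record_len)`` and let ``end`` exceed
``record_len`` (reduce positions modulo ``record_len`` to recover bases).

The blunt cut is placed ``cut_offset`` nucleotides 5' of the PAM on the site
strand (default 3, the junction between protospacer positions -3 and -4
relative to the PAM; double-strand-break tagging data for both FrCas9 and
SpCas9 place incorporation at the 3rd or 4th base upstream of the PAM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .alphabet import (
    IUPAC_SETS,
    iupac_reverse_complement,
    reverse_complement,
    validate_dna,
)
from .errors import AlphabetError, ConsistencyError, ParameterError, UnsupportedMotifError

Interval = tuple[int, int]


@dataclass(frozen=True)
class GenomeRecord:
    """One DNA record: an identifier, an uppercase ACGTN sequence, a topology flag."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ParameterError("GenomeRecord id must be nonempty")
        seq = self.seq.upper()
        if "U" in seq:
            raise AlphabetError("RNA base U rejected: pamscape records are DNA only")
        validate_dna(seq, context=f"record {self.id!r}")
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PamMotif:
    """An IUPAC PAM motif, fixed immediately 3' of the protospacer.

    ``is_palindromic`` is the strict predicate: the motif's concrete match
    set is closed under reverse complement (true for TA or GGCC, false for
    NNTA, whose reverse-complemented match set is TANN-shaped).
    ``palindromic_core`` is the weaker geometric property that back-to-back
    pairing needs: a literal TA core whose flanking positions are all N, so
    that every genomic TA is a PAM anchor on *both* strands.
    """

    iupac: str

    def __post_init__(self) -> None:
        motif = self.iupac.upper()
        if not motif:
            raise ParameterError("PAM motif must be nonempty")
        bad = set(motif) - set(IUPAC_SETS)
        if bad:
            raise AlphabetError(f"invalid IUPAC code(s) {sorted(bad)!r} in motif {motif!r}")
        object.__setattr__(self, "iupac", motif)

    def __len__(self) -> int:
        return len(self.iupac)

    def __str__(self) -> str:
        return self.iupac

    @property
    def is_palindromic(self) -> bool:
        """Match set closed under reverse complement."""
        return iupac_reverse_complement(self.iupac) == self.iupac

    def ta_core_offset(self) -> int | None:
        """Offset of the first literal 5'-TA-3' within the motif, or None."""
        idx = self.iupac.find("TA")
        return idx if idx >= 0 else None

    def palindromic_core(self) -> int | None:
        """Offset of a literal TA core with all-N flanks, else None."""
        idx = self.ta_core_offset()
        if idx is None:
            return None
        flanks = self.iupac[:idx] + self.iupac[idx + 2 :]
        return idx if set(flanks) <= {"N"} else None


@dataclass(frozen=True)
class TargetSite:
    """One PAM-adjacent protospacer.

    ``protospacer`` and ``pam`` are plus-strand half-open intervals (wrapping
    allowed on circular records, see module docstring); ``pam_seq`` and
    ``protospacer_seq`` are read 5'->3' on the site strand; ``cut_pos`` is
    the plus-strand coordinate of the inferred blunt cut junction.
    """

    record_id: str
    strand: str
    protospacer: Interval
    pam: Interval
    spacer_len: int
    pam_seq: str
    cut_pos: int
    protospacer_seq: str = ""
    record_len: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-" or len(self.strand) != 1:
            raise ParameterError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.protospacer[1] - self.protospacer[0] != self.spacer_len:
            raise ConsistencyError("protospacer interval length != spacer_len")
        if self.pam[1] - self.pam[0] != len(self.pam_seq):
            raise ConsistencyError("pam interval length != pam_seq length")

    @property
    def site_id(self) -> str:
        return f"{self.record_id}:{self.cut_pos}:{self.strand}"


@dataclass(frozen=True)
class BackToBackPair:
    """Two divergent sites sharing one plus-strand TA of a palindromic-core PAM.

    ``ta_pos`` is the plus-strand coordinate of the shared TA's T;
    ``protospacer_gap`` is the distance in bp between the proximal ends of
    the two protospacers (6 for NNTA: the N N T A N N spacer between them).
    """

    plus_site: TargetSite
    minus_site: TargetSite
    ta_pos: int
    protospacer_gap: int

    def __post_init__(self) -> None:
        if self.plus_site.record_id != self.minus_site.record_id:
            raise ConsistencyError("paired sites must come from one record")
        if {self.plus_site.strand, self.minus_site.strand} != {"+", "-"}:
            raise ConsistencyError("paired sites must lie on opposite strands")


@dataclass(frozen=True)
class AntiRepeatHit:
    """An ungapped window complementary to a CRISPR direct repeat."""

    interval: Interval
    strand: str
    identity: float
    aligned_len: int


def find_pam_sites(
    genome: GenomeRecord,
    motif: PamMotif | str,
    spacer_len: int,
    *,
    cut_offset: int = 3,
    keep_n: bool = False,
) -> list[TargetSite]:
    """Enumerate every PAM-adjacent target site on both strands.

    Every plus- and minus-strand occurrence of *motif* with a full-length
    protospacer available (wrapping allowed iff the record is circular)
    yields exactly one :class:`TargetSite`. Sites whose protospacer or PAM
    overlaps an N are excluded unless ``keep_n`` (with ``keep_n`` an N in
    the PAM still only satisfies the code N). Output is sorted by
    ``(cut_pos, strand, protospacer start)`` and is deterministic.

    Circular records are scanned on an extended copy of the sequence and a
    site is kept iff its element (protospacer+PAM union) starts in the first
    copy, which deduplicates wrapped placements.
    """
    if isinstance(motif, str):
        motif = PamMotif(motif)
    if spacer_len < 1:
        raise ParameterError(f"spacer_len must be >= 1, got {spacer_len}")
    seq = genome.seq
    L = len(seq)
    m = len(motif)
    elen = spacer_len + m
    if L == 0 or (not genome.circular and L < elen):
        return []

    if genome.circular:
        reps = (elen - 1) // L + 2
        ext = (seq * reps)[: L + elen - 1]
        starts: Iterable[int] = range(L)
    else:
        ext = seq
        starts = range(L - elen + 1)

    # With keep_n, an N base is tolerated in the protospacer and satisfies a
    # PAM position only where the motif itself is fully degenerate (code N).
    def _sets(codes: str) -> list[frozenset[str]]:
        if keep_n:
            return [IUPAC_SETS[c] | {"N"} if c == "N" else IUPAC_SETS[c] for c in codes]
        return [IUPAC_SETS[c] for c in codes]

    fwd = _sets(motif.iupac)
    # a minus-strand element read on the plus strand is revcomp(motif) + protospacer
    rc = _sets(iupac_reverse_complement(motif.iupac))

    def _reduce(pos: int) -> int:
        return pos % L if genome.circular else pos

    sites: list[TargetSite] = []
    for s in starts:
        element = ext[s : s + elen]
        has_n = "N" in element
        if has_n and not keep_n:
            continue
        # plus strand: protospacer then PAM
        pam_region = element[spacer_len:]
        if all(b in allowed for b, allowed in zip(pam_region, fwd)):
            sites.append(
                TargetSite(
                    record_id=genome.id,
                    strand="+",
                    protospacer=(s, s + spacer_len),
                    pam=(s + spacer_len, s + elen),
                    spacer_len=spacer_len,
                    pam_seq=pam_region,
                    cut_pos=_reduce(s + spacer_len - cut_offset),
                    protospacer_seq=element[:spacer_len],
                    record_len=L,
                )
            )
        # minus strand: PAM (revcomp'd on plus) then protospacer
        pam_region = element[:m]
        if all(b in allowed for b, allowed in zip(pam_region, rc)):
            sites.append(
                TargetSite(
                    record_id=genome.id,
                    strand="-",
                    protospacer=(s + m, s + elen),
                    pam=(s, s + m),
                    spacer_len=spacer_len,
                    pam_seq=reverse_complement(pam_region),
                    cut_pos=_reduce(s + m + cut_offset),
                    protospacer_seq=reverse_complement(element[m:]),
                    record_len=L,
                )
            )
    sites.sort(key=lambda t: (t.cut_pos, t.strand, t.protospacer[0]))
    return sites


def find_back_to_back_pairs(
    sites: Sequence[TargetSite], motif: PamMotif | str
) -> list[BackToBackPair]:
    """Pair divergent sites anchored on the same plus-strand TA.

    Requires a motif with a palindromic TA core (literal TA, all other
    positions N; e.g. NNTA) so that every genomic TA dinucleotide is a PAM
    anchor on both strands. For NNTA the paired protospacers are separated
    by exactly 6 bp (N N T A N N between their proximal ends); in general
    the gap is ``2 * core_offset + 2``. Sites whose opposite-strand partner
    was truncated by a record end are left unpaired and omitted.
    """
    if isinstance(motif, str):
        motif = PamMotif(motif)
    core = motif.palindromic_core()
    if core is None:
        raise UnsupportedMotifError(
            f"motif {motif.iupac!r} has no palindromic TA core (all-N flanks "
            "around a literal TA are required for back-to-back pairing)"
        )
    if not sites:
        return []
    record_ids = {s.record_id for s in sites}
    if len(record_ids) > 1:
        raise ConsistencyError(f"sites span multiple records: {sorted(record_ids)!r}")
    m = len(motif)

    def _ta_of(site: TargetSite) -> int:
        if site.strand == "+":
            ta = site.pam[0] + core
        else:
            # plus-strand sequence of a minus PAM is revcomp(motif): the TA
            # core lands m - core - 2 into the interval
            ta = site.pam[0] + (m - core - 2)
        return ta % site.record_len if site.record_len else ta

    plus_by_ta: dict[int, TargetSite] = {}
    minus_by_ta: dict[int, TargetSite] = {}
    for site in sites:
        (plus_by_ta if site.strand == "+" else minus_by_ta)[_ta_of(site)] = site

    pairs = []
    for ta in sorted(set(plus_by_ta) & set(minus_by_ta)):
        pairs.append(
            BackToBackPair(
                plus_site=plus_by_ta[ta],
                minus_site=minus_by_ta[ta],
                ta_pos=ta,
                protospacer_gap=2 * core + 2,
            )
        )
    return pairs


def find_antirepeats(
    genome: GenomeRecord,
    direct_repeat: str,
    min_identity: float = 0.8,
    min_len: int = 15,
) -> list[AntiRepeatHit]:
    """Ungapped search for windows complementary to a CRISPR direct repeat.

    Slides a full-length window over both strands and keeps windows whose
    ungapped identity to the reverse complement of *direct_repeat* reaches
    ``min_identity``. Overlapping hits on the same strand are merged,
    keeping the best-identity window. Hits are sorted by identity
    descending (ties by coordinate). Ns never match.
    """
    if not 0 < min_identity <= 1:
        raise ParameterError(f"min_identity must be in (0, 1], got {min_identity}")
    direct_repeat = direct_repeat.upper()
    validate_dna(direct_repeat, context="direct repeat")
    n = len(direct_repeat)
    if n < min_len:
        raise ParameterError(f"direct repeat ({n} nt) shorter than min_len={min_len}")
    seq = genome.seq
    L = len(seq)
    if L < n:
        return []
    target_plus = reverse_complement(direct_repeat)  # anti-repeat on plus strand
    target_minus = direct_repeat  # window revcomp == anti-repeat

    raw: list[AntiRepeatHit] = []
    for strand, target in (("+", target_plus), ("-", target_minus)):
        for i in range(L - n + 1):
            window = seq[i : i + n]
            matches = sum(a == b and a != "N" for a, b in zip(window, target))
            identity = matches / n
            if identity >= min_identity:
                raw.append(AntiRepeatHit((i, i + n), strand, identity, n))

    merged: list[AntiRepeatHit] = []
    for strand in "+-":
        strand_hits = sorted(
            (h for h in raw if h.strand == strand), key=lambda h: h.interval
        )
        cluster: list[AntiRepeatHit] = []
        for hit in strand_hits:
            if cluster and hit.interval[0] < cluster[-1].interval[1]:
                cluster.append(hit)
            else:
                if cluster:
                    merged.append(max(cluster, key=lambda h: (h.identity, -h.interval[0])))
                cluster = [hit]
        if cluster:
            merged.append(max(cluster, key=lambda h: (h.identity, -h.interval[0])))
    merged.sort(key=lambda h: (-h.identity, h.interval, h.strand))
    return merged
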