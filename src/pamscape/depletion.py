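"""Randomized-PAM depletion-assay statistics and pooled-screen normalization.

A depletion assay transforms a library of constructs carrying a fixed
protospacer and a randomized k-mer PAM into cells expressing the nuclease;
constructs whose PAM is recognized are cleaved and drop out. Comparing
post-selection PAM frequencies against an unselected control library gives
the post-selection PAM depletion value (PPDV): the ratio of a PAM's
frequency in the selected population to its frequency in the control. PPDV
near 1 means no recognition; PPDV near 0 means efficient cleavage; depletion
efficacy ranks inversely with PPDV.

Downstream summaries implemented here: the sequence logo of the top decile
of depleted PAMs (position frequency matrix plus per-position log2
fold-change over the 0.25 random expectation), the PAM-wheel weights over a
position triple, the sgRNA evenness index used to normalize pooled-screen
indel rates, and the GUIDE-seq on:off read ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import DNA_BASES, validate_dna
from .errors import ConsistencyError, ParameterError

_BASE_INDEX = {b: i for i, b in enumerate(DNA_BASES)}


@dataclass(frozen=True)
class PamCountTable:
    """Read counts per PAM k-mer for one library."""

    k: int
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for pam, count in self.counts.items():
            if len(pam) != self.k:
                raise ConsistencyError(f"PAM {pam!r} is not length {self.k}")
            validate_dna(pam, context=f"PAM {pam!r}")
            if count < 0:
                raise ParameterError(f"negative count for PAM {pam!r}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class PpdvTable:
    """PPDV per PAM plus the induced depletion-efficacy ranking.

    ``ppdv`` holds only PAMs with a defined value; PAMs absent from the
    control (with zero pseudocount) land in ``undefined`` instead of raising.
    ``efficacy_rank`` ascends with PPDV (rank 1 = most depleted), ties broken
    lexicographically.
    """

    ppdv: Mapping[str, float]
    efficacy_rank: Mapping[str, int]
    undefined: frozenset[str] = frozenset()


@dataclass(frozen=True)
class DepletionLogo:
    """Per-position base composition of a PAM set.

    ``pfm`` is a positions x 4 (A, C, G, T) frequency matrix with rows
    summing to 1; ``log2fc`` is ``log2(pfm / 0.25)`` elementwise (``-inf``
    where a base is absent), i.e. enrichment over the uniform random-library
    expectation.
    """

    pfm: np.ndarray
    log2fc: np.ndarray
    alphabet: str = DNA_BASES

    def to_frame(self, which: str = "pfm") -> pd.DataFrame:
        mat = self.pfm if which == "pfm" else self.log2fc
        return pd.DataFrame(
            mat, columns=list(self.alphabet),
            index=pd.RangeIndex(1, mat.shape[0] + 1, name="position"),
        )


@dataclass(frozen=True)
class PamWheelTable:
    """Relative depletion weights of the 3-mers at chosen PAM positions."""

    weights: Mapping[str, float]
    positions: tuple[int, int, int] = (2, 3, 4)
    empty: bool = False


@dataclass(frozen=True)
class EvennessTable:
    """sgRNA evenness indices: total_reads / (N * reads_i) per guide.

    Algebraic identity of the formula: sum_i 1 / (N * index_i) == 1.
    """

    N: int
    index: Mapping[str, float]


@dataclass(frozen=True)
class GuideSeqSummary:
    """GUIDE-seq read tally for one target site and its on:off ratio."""

    site_id: str
    on_reads: int
    off_reads: tuple[int, ...]
    ratio: float


def compute_ppdv(
    selected: PamCountTable, control: PamCountTable, pseudocount: float = 0.0
) -> PpdvTable:
    """Post-selection PAM depletion value for every PAM in either library.

    With zero pseudocount (the raw-ratio default) this is exactly the
    frequency ratio ``(sel[p] / sel_total) / (ctl[p] / ctl_total)``, and a
    PAM missing from the control has no defined PPDV and is flagged rather
    than raised. A positive pseudocount ``c`` smooths depth-matched counts:
    ``PPDV(p) = (sel[p] * ctl_total / sel_total + c) / (ctl[p] + c)``, which
    keeps the identity PPDV == 1 on proportional libraries for *every*
    pseudocount (a naive count-space pseudocount breaks it whenever the two
    libraries were sequenced to different depths).
    """
    if selected.k != control.k:
        raise ConsistencyError(f"k mismatch: selected k={selected.k}, control k={control.k}")
    if pseudocount < 0:
        raise ParameterError("pseudocount must be nonnegative")
    if control.total <= 0:
        raise ParameterError("control library has zero total reads")
    if selected.total <= 0:
        raise ParameterError("selected library has zero total reads")
    universe = sorted(set(selected.counts) | set(control.counts))
    scale = control.total / selected.total
    ppdv: dict[str, float] = {}
    undefined = set()
    for pam in universe:
        ctl_num = control.counts.get(pam, 0) + pseudocount
        if ctl_num == 0:
            undefined.add(pam)
            continue
        sel_num = selected.counts.get(pam, 0) * scale + pseudocount
        ppdv[pam] = sel_num / ctl_num
    ranked = sorted(ppdv, key=lambda p: (ppdv[p], p))
    return PpdvTable(
        ppdv=ppdv,
        efficacy_rank={p: i + 1 for i, p in enumerate(ranked)},
        undefined=frozenset(undefined),
    )


def top_depleted(table: PpdvTable, quantile: float = 0.1) -> list[str]:
    """The floor(quantile * |PAMs|) most-depleted PAMs (smallest PPDV).

    Ties break lexicographically, so the selection is stable across runs.
    Only PAMs with a defined PPDV participate.
    """
    if not 0 < quantile <= 1:
        raise ParameterError(f"quantile must be in (0, 1], got {quantile}")
    n = math.floor(quantile * len(table.ppdv))
    ranked = sorted(table.ppdv, key=lambda p: (table.ppdv[p], p))
    return ranked[:n]


def depletion_logo(pams: Sequence[str]) -> DepletionLogo:
    """Position frequency matrix and log2 fold-change of a PAM set.

    The log2 fold-change is taken against the 0.25 uniform expectation of a
    fully randomized library, so a position fixed to one base scores
    ``log2(1 / 0.25) = 2`` and an unconstrained position scores ~0.
    """
    if not pams:
        raise ParameterError("cannot build a logo from an empty PAM set")
    k = len(pams[0])
    if any(len(p) != k for p in pams):
        raise ConsistencyError("logo input PAMs must all have equal length")
    counts = np.zeros((k, 4))
    for pam in pams:
        validate_dna(pam, context=f"PAM {pam!r}")
        for pos, base in enumerate(pam):
            counts[pos, _BASE_INDEX[base]] += 1
    pfm = counts / len(pams)
    with np.errstate(divide="ignore"):
        log2fc = np.log2(pfm / 0.25)
    return DepletionLogo(pfm=pfm, log2fc=log2fc)


def pam_wheel(
    table: PpdvTable, positions: tuple[int, int, int] = (2, 3, 4)
) -> PamWheelTable:
    """Relative depletion of the 3-mers at the given (1-based) PAM positions.

    The "positively depleted" PAMs (PPDV < 1) each contribute weight
    ``1 - PPDV`` to the 3-mer they carry at *positions*; weights are
    normalized to sum to 1. With no depleted PAM an empty, flagged table is
    returned.
    """
    if not table.ppdv:
        return PamWheelTable(weights={}, positions=tuple(positions), empty=True)
    k = len(next(iter(table.ppdv)))
    for pos in positions:
        if not 1 <= pos <= k:
            raise ParameterError(f"position {pos} outside PAM length {k}")
    raw: dict[str, float] = {}
    for pam, value in table.ppdv.items():
        if value < 1.0:
            key = "".join(pam[pos - 1] for pos in positions)
            raw[key] = raw.get(key, 0.0) + (1.0 - value)
    total = sum(raw.values())
    if total == 0:
        return PamWheelTable(weights={}, positions=tuple(positions), empty=True)
    return PamWheelTable(
        weights={k3: w / total for k3, w in sorted(raw.items())},
        positions=tuple(positions),
    )


def evenness_index(read_counts: Mapping[str, int]) -> EvennessTable:
    """Per-guide evenness index ``total_reads / (N * reads_i)``.

    A uniformly represented library has index 1 for every guide; guides
    under-represented in the plasmid pool get index > 1, which inflates
    their observed indel rate back to a per-construct scale.
    """
    if not read_counts:
        raise ParameterError("read_counts is empty")
    zeros = sorted(g for g, c in read_counts.items() if c <= 0)
    if zeros:
        raise ParameterError(f"sgRNA(s) with nonpositive read count: {zeros!r}")
    total = sum(read_counts.values())
    n = len(read_counts)
    return EvennessTable(N=n, index={g: total / (n * c) for g, c in read_counts.items()})


def corrected_indel(raw_rate: float, index: float) -> float:
    """Indel rate corrected by the evenness index, capped at 1."""
    if raw_rate < 0 or raw_rate > 1:
        raise ParameterError(f"raw_rate must be in [0, 1], got {raw_rate}")
    if index <= 0:
        raise ParameterError(f"evenness index must be positive, got {index}")
    return min(1.0, raw_rate * index)


def on_off_ratio(on_reads: int, off_reads: Sequence[int]) -> float:
    """GUIDE-seq on-target reads divided by total off-target reads.

    A site with zero off-target reads uses denominator 1 (documented
    policy), so perfectly specific sites remain plottable and rankable
    instead of dividing by zero.
    """
    if on_reads < 0 or any(x < 0 for x in off_reads):
        raise ParameterError("read counts must be nonnegative")
    denom = sum(off_reads)
    return on_reads / (denom if denom > 0 else 1)


def guideseq_summary(site_id: str, on_reads: int, off_reads: Sequence[int]) -> GuideSeqSummary:
    """Bundle one site's GUIDE-seq tallies with its on:off ratio."""
    return GuideSeqSummary(
        site_id=site_id,
        on_reads=on_reads,
        off_reads=tuple(off_reads),
        ratio=on_off_ratio(on_reads, off_reads),
    )
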