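"""Synthetic-data generators with first-class ground truth.

Every pipeline stage gets a generator whose output carries a truth table, so
tests and acceptance checks never re-derive the ground truth from the
generator's internals:

* random genomes with controlled GC content (i.i.d. bases);
* control/selected PAM count libraries under a hidden depletion rule
  (multinomial sampling; rule-matching PAMs survive selection with a given
  retention fraction, emulating a nuclease depletion assay on a fully
  randomized 4^k PAM library);
* amplicon read sets with indels planted near a cut site (clustered within
  +/-3 bp of the cut, mimicking NHEJ outcomes) plus i.i.d. substitution
  sequencing errors;
* variant tables whose correctability/preciseness under a given base editor
  is verified at construction time by an internal string-level brute-force
  checker, independent of the scanning code under test.

All generators take an explicit integer seed and draw from a single local
``numpy.random.Generator``; same seed, byte-identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .alphabet import DNA_BASES, complement, iupac_matches, reverse_complement
from .baseedit import BaseEditorModel, VariantRecord
from .depletion import PamCountTable
from .errors import ParameterError, PlacementError
from .pamscan import GenomeRecord, PamMotif


# ---------------------------------------------------------------------------
# configs

@dataclass(frozen=True)
class DepletionSimConfig:
    """Hidden-rule depletion assay: rule-matching PAMs survive selection
    with probability ``retention`` relative to non-matching PAMs."""

    k: int = 6
    rule: str = "NNTA"
    retention: float = 0.1
    depth: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.retention <= 1:
            raise ParameterError(f"retention must be in [0, 1], got {self.retention}")
        if self.depth <= 0:
            raise ParameterError("depth must be positive")
        if len(self.rule) > self.k:
            raise ParameterError("rule longer than PAM length k")


@dataclass(frozen=True)
class AmpliconSimConfig:
    """Planted-indel amplicon reads around one cut site."""

    cut_offset: int
    indel_fraction: float = 0.3
    indel_sizes: Mapping[int, float] = field(
        # NHEJ-like size spectrum: mostly small deletions (negative sizes),
        # occasional small insertions.
        default_factory=lambda: {
            -1: 0.35, -2: 0.15, -3: 0.10, -4: 0.05, -6: 0.05, -10: 0.05,
            1: 0.15, 2: 0.07, 3: 0.03,
        }
    )
    substitution_rate: float = 0.005
    depth: int = 1000
    jitter: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.indel_fraction <= 1:
            raise ParameterError("indel_fraction must be in [0, 1]")
        if not 0 <= self.substitution_rate <= 0.05:
            raise ParameterError("substitution_rate must be in [0, 0.05]")
        if self.depth <= 0:
            raise ParameterError("depth must be positive")
        if abs(sum(self.indel_sizes.values()) - 1) > 1e-9:
            raise ParameterError("indel size distribution must sum to 1")


@dataclass(frozen=True)
class VariantSimConfig:
    """Planted SNVs of one correctability category w.r.t. a given editor.

    ``category`` is "correctable" or "uncorrectable"; for correctable
    variants ``bystander`` decides whether the supporting windows carry an
    extra substrate base (making the correction imprecise).
    """

    n_variants: int
    category: str = "correctable"
    bystander: bool = False
    seed: int = 0
    max_tries: int = 2000

    def __post_init__(self) -> None:
        if self.category not in ("correctable", "uncorrectable"):
            raise ParameterError(f"unknown category {self.category!r}")
        if self.n_variants < 0:
            raise ParameterError("n_variants must be nonnegative")


@dataclass(frozen=True)
class DepletionTruth:
    """The hidden rule of a simulated depletion assay."""

    rule: str
    matching_pams: frozenset[str]
    retention: float


# ---------------------------------------------------------------------------
# generators

def random_genome(
    length: int,
    gc: float = 0.5,
    circular: bool = False,
    seed: int = 0,
    record_id: str = "synthetic",
) -> GenomeRecord:
    """An i.i.d. random genome with P(G) = P(C) = gc/2, P(A) = P(T) = (1-gc)/2."""
    if length < 0:
        raise ParameterError("length must be nonnegative")
    if not 0 <= gc <= 1:
        raise ParameterError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.frombuffer(DNA_BASES.encode("ascii"), dtype=np.uint8)
    seq = rng.choice(bases, size=length, p=probs).tobytes().decode("ascii")
    return GenomeRecord(record_id, seq, circular)


def all_pams(k: int) -> list[str]:
    """Every 4^k PAM k-mer in lexicographic order."""
    return ["".join(p) for p in itertools.product(DNA_BASES, repeat=k)]


def _rule_matches(pam: str, rule: str) -> bool:
    return all(iupac_matches(b, c) for b, c in zip(pam, rule))


def simulate_depletion(
    config: DepletionSimConfig,
) -> tuple[PamCountTable, PamCountTable, DepletionTruth]:
    """Control and selected libraries under a hidden PAM rule.

    Control counts are multinomial over the uniform 4^k library; selected
    counts reweight rule-matching PAMs by ``retention`` (renormalized).
    Returns ``(control, selected, truth)``.
    """
    rng = np.random.default_rng(config.seed)
    pams = all_pams(config.k)
    matching = np.array([_rule_matches(p, config.rule) for p in pams])
    uniform = np.full(len(pams), 1 / len(pams))
    control_counts = rng.multinomial(config.depth, uniform)
    weights = np.where(matching, config.retention, 1.0)
    weights = weights / weights.sum()
    selected_counts = rng.multinomial(config.depth, weights)
    control = PamCountTable(config.k, dict(zip(pams, map(int, control_counts))))
    selected = PamCountTable(config.k, dict(zip(pams, map(int, selected_counts))))
    truth = DepletionTruth(
        rule=config.rule,
        matching_pams=frozenset(p for p, hit in zip(pams, matching) if hit),
        retention=config.retention,
    )
    return control, selected, truth


def simulate_amplicon(
    config: AmpliconSimConfig, reference: GenomeRecord
) -> tuple[list[str], list[bool]]:
    """Reads from one amplicon with indels planted near the cut site.

    Each read is the reference carrying, with probability ``indel_fraction``,
    one indel of a size drawn from ``indel_sizes`` (negative = deletion)
    placed uniformly within ``+/-jitter`` bp of the cut, then i.i.d.
    substitution errors. Returns ``(reads, truth)`` with one planted-indel
    label per read.
    """
    ref = reference.seq
    flank = 10
    lo_margin = config.cut_offset - config.jitter
    max_del = max((-sz for sz in config.indel_sizes if sz < 0), default=0)
    if lo_margin - flank < 0 or config.cut_offset + config.jitter + max_del + flank > len(ref):
        raise ParameterError(
            "cut_offset too close to the reference ends for the configured "
            "jitter, indel sizes and +/-10 bp window"
        )
    rng = np.random.default_rng(config.seed)
    sizes = sorted(config.indel_sizes)
    size_probs = np.array([config.indel_sizes[s] for s in sizes], dtype=float)
    bases = np.array(list(DNA_BASES))

    reads: list[str] = []
    truth: list[bool] = []
    for _ in range(config.depth):
        planted = bool(rng.random() < config.indel_fraction)
        if planted:
            size = sizes[int(rng.choice(len(sizes), p=size_probs))]
            pos = config.cut_offset + int(rng.integers(-config.jitter, config.jitter + 1))
            if size < 0:
                read = ref[:pos] + ref[pos - size :]
            else:
                insert = "".join(rng.choice(bases, size=size))
                read = ref[:pos] + insert + ref[pos:]
        else:
            read = ref
        err = rng.random(len(read)) < config.substitution_rate
        if err.any():
            chars = list(read)
            for idx in np.nonzero(err)[0]:
                choices = [b for b in DNA_BASES if b != chars[idx]]
                chars[idx] = choices[int(rng.integers(3))]
            read = "".join(chars)
        reads.append(read)
        truth.append(planted)
    return reads, truth


# ---------------------------------------------------------------------------
# planted variants, verified by an independent brute-force checker

def _brute_call(
    patient: str,
    circular: bool,
    pos: int,
    ref_plus: str,
    motif: PamMotif,
    spacer_len: int,
    editor: BaseEditorModel,
) -> tuple[bool, bool]:
    """(correctable, precise) by explicit string enumeration.

    Deliberately avoids the pamscan/baseedit code paths: walks every
    protospacer placement on both strands with plain slicing so the
    simulator's truth labels do not depend on the code they validate.
    """
    L = len(patient)
    m = len(motif)
    elen = spacer_len + m
    ext = (patient * ((elen - 1) // L + 2))[: L + elen - 1] if circular else patient
    starts = range(L) if circular else range(max(0, L - elen + 1))
    ws, we = editor.window_start, editor.window_end
    correctable = precise = False
    for s in starts:
        element = ext[s : s + elen]
        if len(element) < elen or "N" in element:
            continue
        # plus strand
        if all(iupac_matches(b, c) for b, c in zip(element[spacer_len:], motif.iupac)):
            proto = element[:spacer_len]
            window = proto[ws - 1 : we]
            coords = [(s + jj) % L for jj in range(ws - 1, we)]
            if pos in coords and window[coords.index(pos)] == editor.from_base:
                if ref_plus == editor.to_base:
                    correctable = True
                    if window.count(editor.from_base) == 1:
                        precise = True
        # minus strand
        rc_elem = reverse_complement(element)
        if all(iupac_matches(b, c) for b, c in zip(rc_elem[spacer_len:], motif.iupac)):
            proto = rc_elem[:spacer_len]
            window = proto[ws - 1 : we]
            coords = [(s + elen - 1 - jj) % L for jj in range(ws - 1, we)]
            if pos in coords and window[coords.index(pos)] == editor.from_base:
                if complement(ref_plus) == editor.to_base:
                    correctable = True
                    if window.count(editor.from_base) == 1:
                        precise = True
    return correctable, precise


def simulate_variants(
    config: VariantSimConfig,
    genome: GenomeRecord,
    motif: PamMotif | str,
    spacer_len: int,
    editor: BaseEditorModel,
) -> tuple[list[VariantRecord], list[tuple[bool, bool]]]:
    """Plant SNVs whose correctability under *editor* is known by construction.

    Returns ``(variants, truth)`` where truth holds one
    ``(correctable, precise)`` pair per variant. Placement is rejection-
    sampled: a candidate position/allele pair is kept only when the internal
    brute-force checker confirms the intended category; after
    ``config.max_tries`` failed draws a :class:`PlacementError` is raised.
    """
    if isinstance(motif, str):
        motif = PamMotif(motif)
    rng = np.random.default_rng(config.seed)
    L = len(genome)
    if L < spacer_len + len(motif):
        raise ParameterError("genome too short to place any target site")
    want_correctable = config.category == "correctable"
    want_precise = want_correctable and not config.bystander

    variants: list[VariantRecord] = []
    truth: list[tuple[bool, bool]] = []
    used: set[int] = set()
    for i in range(config.n_variants):
        for _ in range(config.max_tries):
            pos = int(rng.integers(L))
            if pos in used:
                continue
            ref = genome.seq[pos]
            if ref == "N":
                continue
            if want_correctable:
                # patient must carry the editor substrate on one strand:
                # from_base on the plus strand or its complement.
                alt = editor.from_base if rng.random() < 0.5 else complement(editor.from_base)
            else:
                alt = DNA_BASES[int(rng.integers(4))]
            if alt == ref:
                continue
            patient = genome.seq[:pos] + alt + genome.seq[pos + 1 :]
            call = _brute_call(
                patient, genome.circular, pos, ref, motif, spacer_len, editor
            )
            if call == (want_correctable, want_precise):
                used.add(pos)
                variants.append(
                    VariantRecord(
                        variant_id=f"var{i:04d}",
                        record_id=genome.id,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        significance="Pathogenic",
                    )
                )
                truth.append(call)
                break
        else:
            raise PlacementError(
                f"could not place a {config.category}"
                f"{' bystander' if config.bystander else ''} variant after "
                f"{config.max_tries} tries (genome too short or unsuitable?)"
            )
    return variants, truth
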