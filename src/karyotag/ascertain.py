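"""Tag-SNP ascertainment: concordance scoring and platform-specific filters.

A candidate tag SNP is evaluated against specimens of known inversion
genotype by computing, within each inversion-genotype class (homozygous
standard, heterozygous, homozygous inverted), the simple fraction of
specimens whose SNP genotype matches their inversion genotype.  The minimum
across classes is the conservative genotypic concordance used for ranking.
Platform-specific filters then remove candidates unsuitable for assay
design: a high-frequency flanking-variant screen (array/probe chemistry), a
sequence-complexity screen, and positional pruning of over-abundant
candidates.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .panel import NUCLEOTIDES


class AscertainmentError(ValueError):
    pass


#: Per-inversion minimum-concordance presets.  2Rc_col / 2Rc_gam share the
#: 2Rc threshold.  The array preset tolerates lower concordance because the
#: flanking-variant screen leaves few candidates.
PRESETS: dict[str, dict[str, float]] = {
    "OA": {"2Rb": 0.7, "2Rc": 0.7, "2Ru": 0.7, "2Rd": 0.75, "2Rj": 0.9, "2La": 0.9925},
    "GTseq": {
        "2Rc": 0.8,
        "2Rd": 0.85,
        "2Rb": 0.9,
        "2Rj": 0.9,
        "2Ru": 0.9,
        "2La": 0.995,
    },
}


@dataclass
class AscertainmentConfig:
    """Filter parameters for candidate selection.

    The complexity-screen defaults (homopolymer run and dinucleotide-entropy
    threshold) are this tool's own defaults standing in for external
    primer-design rejection rules.
    """

    thresholds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in PRESETS.items()}
    )
    flank_window: int = 25
    flank_freq_threshold: float = 0.05
    flank_min_populations: int = 2
    prune_step: int = 3
    max_homopolymer_run: int = 5
    min_dinucleotide_entropy: float = 1.5  # bits

    def threshold_for(self, preset: str, inversion_id: str) -> float:
        if preset not in self.thresholds:
            raise AscertainmentError(
                f"unknown preset {preset!r}; know {sorted(self.thresholds)}"
            )
        # species-partitioned 2Rc tag sets share the 2Rc threshold
        key = "2Rc" if inversion_id.startswith("2Rc") else inversion_id
        try:
            return self.thresholds[preset][key]
        except KeyError:
            raise AscertainmentError(
                f"preset {preset!r} has no threshold for inversion {inversion_id!r}"
            ) from None


@dataclass(frozen=True)
class CandidateEvaluation:
    """Per-class concordances of one candidate SNP for one inversion."""

    snp_id: str
    concordance: tuple[float | None, float | None, float | None]
    class_sizes: tuple[int, int, int]
    min_concordance: float
    class_incomplete: bool = False
    position: int | None = None


@dataclass(frozen=True)
class FlankVariant:
    """A variant within the probe-annealing window around a candidate tag."""

    offset: int  # bases relative to the tag SNP, never 0
    class_freqs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pop_freqs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        freqs = list(self.class_freqs) + list(self.pop_freqs.values())
        if any(not 0.0 <= f <= 1.0 for f in freqs):
            raise AscertainmentError(f"flank variant at {self.offset}: frequency outside [0, 1]")


def evaluate_candidate(
    snp_genotypes: Sequence[float | int | None],
    inversion_genotypes: Sequence[int],
    snp_id: str = "",
    position: int | None = None,
    missing_as_mismatch: bool = True,
) -> CandidateEvaluation:
    """Score a candidate tag against known inversion genotypes.

    For each inversion-genotype class g, concordance c_g is the fraction of
    class-g specimens whose SNP genotype equals g.  By default specimens with
    a missing SNP call stay in the denominator and count as non-matching (the
    conservative reading); ``missing_as_mismatch=False`` drops them from the
    class instead.  The minimum over non-empty classes is the conservative
    genotypic concordance; empty classes are flagged, not scored as zero.
    """
    snp = np.asarray(
        [np.nan if g is None else float(g) for g in snp_genotypes], dtype=float
    )
    inv = np.asarray(inversion_genotypes, dtype=float)
    if snp.shape != inv.shape:
        raise AscertainmentError("snp and inversion genotype vectors differ in length")
    if np.isnan(inv).any() or not np.isin(inv, (0.0, 1.0, 2.0)).all():
        raise AscertainmentError("inversion genotypes must all be 0/1/2")

    conc: list[float | None] = []
    sizes: list[int] = []
    for g in (0.0, 1.0, 2.0):
        in_class = inv == g
        if not missing_as_mismatch:
            in_class &= ~np.isnan(snp)
        n = int(in_class.sum())
        sizes.append(n)
        if n == 0:
            conc.append(None)
        else:
            matches = int((snp[in_class] == g).sum())
            conc.append(matches / n)
    scored = [c for c in conc if c is not None]
    if not scored:
        raise AscertainmentError(f"{snp_id or 'candidate'}: all genotype classes empty")
    return CandidateEvaluation(
        snp_id=snp_id,
        concordance=tuple(conc),
        class_sizes=tuple(sizes),
        min_concordance=min(scored),
        class_incomplete=any(c is None for c in conc),
        position=position,
    )


def rank_and_threshold(
    evals: Iterable[CandidateEvaluation],
    inversion_id: str,
    config: AscertainmentConfig | None = None,
    preset: str = "GTseq",
) -> list[CandidateEvaluation]:
    """Drop candidates below the preset's per-inversion concordance floor and
    sort the survivors by descending min-concordance (position breaks ties).

    Idempotent: re-applying to its own output is a no-op.
    """
    config = config or AscertainmentConfig()
    floor = config.threshold_for(preset, inversion_id)
    kept = [e for e in evals if e.min_concordance >= floor]
    return sorted(
        kept,
        key=lambda e: (
            -e.min_concordance,
            e.position if e.position is not None else math.inf,
            e.snp_id,
        ),
    )


def flank_filter(
    flank_variants: Iterable[FlankVariant],
    config: AscertainmentConfig | None = None,
) -> tuple[bool, str]:
    """Reject candidates with high-frequency variants in the probe window.

    Fails when any variant within +/- ``flank_window`` bases exceeds the
    frequency threshold (default 5%) in at least one inversion-genotype class
    or in at least ``flank_min_populations`` population samples — such
    variants interfere with allele-specific probe annealing.  Returns
    (passed, reason).
    """
    config = config or AscertainmentConfig()
    for v in flank_variants:
        if v.offset == 0:
            raise AscertainmentError("offset 0 is the tag SNP itself, not a flank variant")
        if abs(v.offset) > config.flank_window:
            raise AscertainmentError(
                f"flank variant offset {v.offset} outside +/-{config.flank_window} window"
            )
        hot_classes = [
            g for g, f in enumerate(v.class_freqs) if f > config.flank_freq_threshold
        ]
        if hot_classes:
            return False, (
                f"variant at {v.offset:+d}: frequency >"
                f" {config.flank_freq_threshold} in genotype class {hot_classes[0]}"
            )
        hot_pops = [
            p for p, f in v.pop_freqs.items() if f > config.flank_freq_threshold
        ]
        if len(hot_pops) >= config.flank_min_populations:
            return False, (
                f"variant at {v.offset:+d}: frequency > {config.flank_freq_threshold}"
                f" in {len(hot_pops)} population samples ({', '.join(sorted(hot_pops))})"
            )
    return True, "no high-frequency flanking variants"


def complexity_screen(
    flanking_sequence: str, config: AscertainmentConfig | None = None
) -> tuple[bool, str]:
    """Screen the sequence around a candidate for primer-hostile composition.

    Fails on any homopolymer run longer than ``max_homopolymer_run`` or when
    the Shannon entropy of overlapping dinucleotides falls below
    ``min_dinucleotide_entropy`` bits.  The sequence must be odd-length with
    the tag SNP at its centre.
    """
    config = config or AscertainmentConfig()
    seq = flanking_sequence.upper()
    if any(b not in NUCLEOTIDES for b in seq):
        bad = next(b for b in seq if b not in NUCLEOTIDES)
        raise AscertainmentError(f"non-nucleotide character {bad!r} in flanking sequence")
    if len(seq) % 2 == 0:
        raise AscertainmentError("flanking sequence must be odd-length, tag at centre")

    run, longest = 1, 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        longest = max(longest, run)
    if longest > config.max_homopolymer_run:
        return False, f"homopolymer run of {longest} exceeds {config.max_homopolymer_run}"

    dinucs = Counter(seq[i : i + 2] for i in range(len(seq) - 1))
    total = sum(dinucs.values())
    entropy = -sum((c / total) * math.log2(c / total) for c in dinucs.values())
    if entropy < config.min_dinucleotide_entropy:
        return False, (
            f"dinucleotide entropy {entropy:.2f} bits below "
            f"{config.min_dinucleotide_entropy}"
        )
    return True, "passes complexity screen"


def prune_every_kth(candidates: Sequence, k: int = 3, key=None) -> list:
    """Thin an over-abundant, position-sorted candidate list.

    Keeps elements at indices 0, k, 2k, ... (the first candidate anchors the
    phase).  ``key`` extracts the position for the sort-order check; default
    is the ``position`` attribute when present.
    """
    if k < 1:
        raise AscertainmentError(f"prune step must be >= 1, got {k}")
    candidates = list(candidates)
    if key is None:
        key = lambda c: getattr(c, "position", None)
    positions = [key(c) for c in candidates]
    if all(p is not None for p in positions) and positions != sorted(positions):
        raise AscertainmentError("candidates must be sorted ascending by position")
    return candidates[::k]
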