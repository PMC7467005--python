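"""Allele counting in amplicon reads and ratio-based locus genotype calls.

Multiplexed amplicon sequencing (GT-seq style) genotypes a tag SNP by
counting, within one specimen's demultiplexed FASTQ, reads that contain a
short probe sequence carrying the reference allele versus the alternate
allele.  The genotype is then called from the ratio of reference to
alternate counts, provided total depth exceeds a minimum.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .panel import Panel

logger = logging.getLogger(__name__)


class ProbeError(ValueError):
    """Raised for malformed probe pairs or counts."""


@dataclass(frozen=True)
class ProbeSet:
    """Allele-discriminating probe pair for one locus.

    ``probe_ref`` and ``probe_alt`` are equal-length forward-strand sequences
    centred on the tag SNP, differing only at the SNP site.  ``fwd_primer``
    optionally assigns otherwise-unmatched reads to the locus.
    """

    snp_id: str
    probe_ref: str
    probe_alt: str
    fwd_primer: str | None = None

    def __post_init__(self) -> None:
        if len(self.probe_ref) != len(self.probe_alt):
            raise ProbeError(f"{self.snp_id}: probe pair of unequal length")
        diffs = [
            i for i, (a, b) in enumerate(zip(self.probe_ref, self.probe_alt)) if a != b
        ]
        if len(diffs) != 1:
            raise ProbeError(
                f"{self.snp_id}: probes must differ at exactly one position, "
                f"found {len(diffs)} differences"
            )


@dataclass
class AlleleCounts:
    """Per specimen x locus read counts by matched allele."""

    specimen_id: str
    snp_id: str
    count_ref: int = 0
    count_alt: int = 0
    count_other: int = 0

    def __post_init__(self) -> None:
        if min(self.count_ref, self.count_alt, self.count_other) < 0:
            raise ProbeError(f"{self.snp_id}: negative allele count")


@dataclass(frozen=True)
class CallThresholds:
    """Depth and allele-ratio cut-offs for the locus genotype call.

    Depth must strictly exceed ``min_depth``.  With r = count_ref/count_alt:
    r >= hom_ref_min_ratio calls homozygous reference (0); r <=
    hom_alt_max_ratio calls homozygous alternate (2); r inside
    ``het_ratio_range`` calls heterozygous (1); ratios in the dead zones
    between are left uncalled.
    """

    min_depth: int = 10
    hom_ref_min_ratio: float = 10.0
    hom_alt_max_ratio: float = 0.1
    het_ratio_range: tuple[float, float] = (0.2, 5.0)

    def __post_init__(self) -> None:
        lo, hi = self.het_ratio_range
        if not (self.hom_alt_max_ratio < lo <= hi < self.hom_ref_min_ratio):
            raise ProbeError(
                "thresholds must satisfy hom_alt_max_ratio < het_low <= het_high "
                "< hom_ref_min_ratio"
            )


@dataclass(frozen=True)
class LocusCall:
    specimen_id: str
    snp_id: str
    genotype: int | None
    depth: int
    ratio: float  # count_ref / count_alt; inf when count_alt == 0


def count_alleles(
    reads: Iterable,
    probes: Sequence[ProbeSet],
    specimen_id: str = "",
) -> list[AlleleCounts]:
    """Count probe occurrences per locus over one specimen's reads.

    A read increments ``count_ref`` if it contains the reference probe as an
    exact substring, ``count_alt`` for the alternate probe.  A read matching
    both probes of one locus is ambiguous: it increments ``count_other`` and
    is logged.  A read matching neither probe but containing the locus's
    forward primer is assigned to the locus as ``count_other``.  Matching is
    on the read sequence as given (no reverse complement); read order never
    affects the result.
    """
    out = {p.snp_id: AlleleCounts(specimen_id, p.snp_id) for p in probes}
    for read in reads:
        seq = str(read.seq) if hasattr(read, "seq") else str(read)
        for p in probes:
            counts = out[p.snp_id]
            has_ref = p.probe_ref in seq
            has_alt = p.probe_alt in seq
            if has_ref and has_alt:
                counts.count_other += 1
                logger.warning(
                    "%s: read matches both probes of %s", specimen_id, p.snp_id
                )
            elif has_ref:
                counts.count_ref += 1
            elif has_alt:
                counts.count_alt += 1
            elif p.fwd_primer and p.fwd_primer in seq:
                counts.count_other += 1
    return list(out.values())


def call_locus(
    counts: AlleleCounts, thresholds: CallThresholds | None = None
) -> LocusCall:
    """Call a genotype from allele counts by the depth and ratio rules.

    Depth counts only reads matching one of the two probes; it must be
    strictly greater than ``min_depth`` for any call.
    """
    thresholds = thresholds or CallThresholds()
    depth = counts.count_ref + counts.count_alt
    ratio = (
        math.inf if counts.count_alt == 0 else counts.count_ref / counts.count_alt
    )
    if depth <= thresholds.min_depth:
        genotype = None
    elif ratio >= thresholds.hom_ref_min_ratio:
        genotype = 0
    elif ratio <= thresholds.hom_alt_max_ratio:
        genotype = 2
    elif thresholds.het_ratio_range[0] <= ratio <= thresholds.het_ratio_range[1]:
        genotype = 1
    else:
        genotype = None  # dead zone between het range and homozygote cut-offs
    return LocusCall(counts.specimen_id, counts.snp_id, genotype, depth, ratio)


def matrix_from_calls(
    calls: Iterable[LocusCall],
    panel: Panel,
    specimens: pd.DataFrame | None = None,
):
    """Assemble per-locus calls into a specimens x tags GenotypeMatrix.

    ``specimens`` optionally supplies species / numeric_code metadata indexed
    by specimen_id; without it, species is unknown and numeric codes are
    assigned sequentially in order of first appearance.
    """
    from .karyotype import GenotypeMatrix

    calls = list(calls)
    for c in calls:
        if c.snp_id not in panel:
            raise ProbeError(f"call references snp_id not in panel: {c.snp_id}")
    specimen_ids = list(dict.fromkeys(c.specimen_id for c in calls))
    geno = pd.DataFrame(
        np.nan, index=pd.Index(specimen_ids, name="specimen_id"), columns=panel.snp_ids
    )
    for c in calls:
        if c.genotype is not None:
            geno.loc[c.specimen_id, c.snp_id] = float(c.genotype)
    if specimens is None:
        specimens = pd.DataFrame(
            {
                "species": [None] * len(specimen_ids),
                "numeric_code": pd.array(
                    range(1, len(specimen_ids) + 1), dtype="Int64"
                ),
            },
            index=geno.index,
        )
    else:
        specimens = specimens.reindex(geno.index)
    return GenotypeMatrix(geno, specimens)


def probes_from_panel(panel: Panel) -> list[ProbeSet]:
    """Build probe sets from a panel's probe_ref/probe_alt columns."""
    probes = []
    for tag in panel.tags:
        if tag.probe_ref is None or tag.probe_alt is None:
            continue
        probes.append(
            ProbeSet(
                snp_id=tag.snp_id,
                probe_ref=tag.probe_ref,
                probe_alt=tag.probe_alt,
                fwd_primer=tag.fwd_primer,
            )
        )
    return probes


def probes_from_context(
    panel: Panel, context: dict[str, tuple[str, int]], flank: int = 7
) -> list[ProbeSet]:
    """Build probes from amplicon sequence context.

    ``context`` maps snp_id to (amplicon sequence carrying the reference
    allele, 0-based index of the SNP within it).  Probes span the SNP plus
    ``flank`` bases either side (default 7).
    """
    probes = []
    for tag in panel.tags:
        if tag.snp_id not in context:
            continue
        seq, idx = context[tag.snp_id]
        if seq[idx] != tag.ref_allele:
            raise ProbeError(
                f"{tag.snp_id}: context base {seq[idx]!r} is not the ref allele"
            )
        lo, hi = max(0, idx - flank), min(len(seq), idx + flank + 1)
        probe_ref = seq[lo:hi]
        probe_alt = seq[lo:idx] + tag.alt_allele + seq[idx + 1 : hi]
        probes.append(
            ProbeSet(tag.snp_id, probe_ref, probe_alt, fwd_primer=tag.fwd_primer)
        )
    return probes


def read_fastq(path: str | Path):
    """Yield records from a plain or gzipped FASTQ file."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            yield from SeqIO.parse(fh, "fastq")
    else:
        with open(path) as fh:
            yield from SeqIO.parse(fh, "fastq")


def genotype_specimens(
    manifest: dict[str, str | Path],
    probes: Sequence[ProbeSet],
    thresholds: CallThresholds | None = None,
) -> list[LocusCall]:
    """Genotype each specimen's FASTQ at every probe locus.

    ``manifest`` maps specimen_id to its demultiplexed FASTQ path.
    """
    thresholds = thresholds or CallThresholds()
    calls: list[LocusCall] = []
    for specimen_id, fq in manifest.items():
        counts = count_alleles(read_fastq(fq), probes, specimen_id=specimen_id)
        calls.extend(call_locus(c, thresholds) for c in counts)
    return calls


def calls_to_frame(calls: Iterable[LocusCall]) -> pd.DataFrame:
    """Tabulate locus calls (`specimen_id snp_id depth ratio genotype`)."""
    rows = [
        {
            "specimen_id": c.specimen_id,
            "snp_id": c.snp_id,
            "depth": c.depth,
            "ratio": c.ratio,
            "genotype": np.nan if c.genotype is None else c.genotype,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["specimen_id", "snp_id", "depth", "ratio", "genotype"]
    )
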