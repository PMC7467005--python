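"""Call-rate filtering and multilocus inversion genotype (karyotype) calling.

Genotype matrices hold the count of alternate alleles per specimen and tag
SNP: 0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate,
NaN = missing.  Tags and specimens with call rates below 80% (default) are
removed; a specimen's karyotype at an inversion is the mean alternate-allele
count over that inversion's applicable tags, binned into thirds of [0, 2].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import Panel

logger = logging.getLogger(__name__)

#: Bin edges for the multilocus genotype: thirds of the possible range [0, 2].
#: Printed two-decimal renderings of these edges are 0.67 and 1.33.
BIN_EDGE_LOW = 2.0 / 3.0
BIN_EDGE_HIGH = 4.0 / 3.0


class MatrixError(ValueError):
    """Raised for malformed genotype matrices or empty filter results."""


@dataclass
class FilterConfig:
    """Call-rate thresholds for tag and specimen filtering.

    ``min_tags_per_inversion`` is the least number of non-missing tag
    genotypes required before a multilocus genotype is attempted.
    """

    min_snp_call_rate: float = 0.80
    min_specimen_call_rate: float = 0.80
    min_tags_per_inversion: int = 1

    def __post_init__(self) -> None:
        for name in ("min_snp_call_rate", "min_specimen_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_tags_per_inversion < 1:
            raise ValueError("min_tags_per_inversion must be >= 1")


@dataclass
class GenotypeMatrix:
    """Specimens x tag SNPs alternate-allele counts plus specimen metadata.

    ``genotypes``: float DataFrame indexed by specimen_id, columns snp_id,
    entries in {0, 1, 2, NaN}.  ``specimens``: DataFrame on the same index
    with at least ``species`` and ``numeric_code`` columns (species may be
    None/NaN when unknown).
    """

    genotypes: pd.DataFrame
    specimens: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = self.genotypes.astype(float)
        values = self.genotypes.to_numpy()
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = values[~ok].flat[0]
            raise MatrixError(f"genotype entries must be 0/1/2/NaN; found {bad!r}")
        if not self.genotypes.index.equals(self.specimens.index):
            self.specimens = self.specimens.reindex(self.genotypes.index)
        if self.genotypes.index.has_duplicates:
            raise MatrixError("duplicate specimen_id in matrix")
        if self.genotypes.columns.has_duplicates:
            raise MatrixError("duplicate snp_id column in matrix")

    @property
    def n_specimens(self) -> int:
        return len(self.genotypes)

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def species_of(self, specimen_id: str) -> str | None:
        sp = self.specimens.loc[specimen_id, "species"]
        return None if pd.isna(sp) else sp

    def applicability_mask(self, panel: Panel | None) -> pd.DataFrame:
        """Boolean specimens x tags frame: tag scoreable in specimen's species."""
        if panel is None:
            return pd.DataFrame(
                True, index=self.genotypes.index, columns=self.genotypes.columns
            )
        cols = {}
        species = self.specimens["species"]
        for snp_id in self.genotypes.columns:
            cols[snp_id] = species.map(lambda sp: panel.tag_applies(snp_id, _opt(sp)))
        return pd.DataFrame(cols, index=self.genotypes.index).astype(bool)


@dataclass
class FilterReport:
    """What the call-rate filters removed, with the offending rates."""

    dropped_snps: dict[str, float] = field(default_factory=dict)
    dropped_specimens: dict[str, float] = field(default_factory=dict)
    snp_rate_mean: float = float("nan")
    snp_rate_range: tuple[float, float] = (float("nan"), float("nan"))
    specimen_rate_mean: float = float("nan")
    specimen_rate_range: tuple[float, float] = (float("nan"), float("nan"))

    def to_dict(self) -> dict:
        return {
            "dropped_snps": self.dropped_snps,
            "dropped_specimens": self.dropped_specimens,
            "surviving": {
                "snp_call_rate_mean": self.snp_rate_mean,
                "snp_call_rate_range": list(self.snp_rate_range),
                "specimen_call_rate_mean": self.specimen_rate_mean,
                "specimen_call_rate_range": list(self.specimen_rate_range),
            },
        }


@dataclass(frozen=True)
class KaryotypeCall:
    """A specimen's multilocus genotype at one inversion, with audit fields."""

    specimen_id: str
    inversion_id: str
    n_tags_used: int
    mean_alt: float | None
    genotype: int | None


def snp_call_rates(matrix: GenotypeMatrix, panel: Panel | None = None) -> pd.Series:
    """Per-tag call rate: called specimens / specimens the tag applies to.

    With a panel, the denominator excludes specimens of species in which the
    tag's inversion is not scoreable; without one, all specimens count.
    """
    if matrix.n_specimens == 0 or matrix.n_snps == 0:
        raise MatrixError("cannot compute call rates on an empty matrix")
    mask = matrix.applicability_mask(panel)
    called = matrix.genotypes.notna() & mask
    denom = mask.sum(axis=0)
    return (called.sum(axis=0) / denom.where(denom > 0)).rename("snp_call_rate")


def specimen_call_rates(matrix: GenotypeMatrix, panel: Panel | None = None) -> pd.Series:
    """Per-specimen call rate over the tags applicable to its species."""
    if matrix.n_specimens == 0 or matrix.n_snps == 0:
        raise MatrixError("cannot compute call rates on an empty matrix")
    mask = matrix.applicability_mask(panel)
    called = matrix.genotypes.notna() & mask
    denom = mask.sum(axis=1)
    return (called.sum(axis=1) / denom.where(denom > 0)).rename("specimen_call_rate")


def filter_matrix(
    matrix: GenotypeMatrix,
    config: FilterConfig | None = None,
    panel: Panel | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop underperforming tags, then underperforming specimens.

    Tags with call rate below ``min_snp_call_rate`` are eliminated first;
    specimen call rates are then recomputed on the surviving tags, and
    specimens below ``min_specimen_call_rate`` are excluded.  The operation
    is idempotent.
    """
    config = config or FilterConfig()
    report = FilterReport()

    # Tag filter before specimen filter, specimen rates recomputed on the
    # surviving tags.  Because removing specimens can in turn push a tag's
    # call rate below threshold, the two passes repeat until stable, so the
    # whole operation is idempotent; on well-behaved data one pass suffices.
    out = matrix
    while True:
        changed = False
        rates = snp_call_rates(out, panel)
        keep_snps = rates[rates.fillna(0.0) >= config.min_snp_call_rate].index
        if len(keep_snps) < out.n_snps:
            changed = True
            report.dropped_snps.update(
                {s: float(r) for s, r in rates.items() if s not in set(keep_snps)}
            )
            if len(keep_snps) == 0:
                raise MatrixError(
                    "all tag SNPs fell below the call-rate threshold; "
                    "nothing to karyotype"
                )
            out = GenotypeMatrix(out.genotypes[list(keep_snps)], out.specimens)

        spec_rates = specimen_call_rates(out, panel)
        keep_spec = spec_rates[
            spec_rates.fillna(0.0) >= config.min_specimen_call_rate
        ].index
        if len(keep_spec) < out.n_specimens:
            changed = True
            report.dropped_specimens.update(
                {s: float(r) for s, r in spec_rates.items() if s not in set(keep_spec)}
            )
            if len(keep_spec) == 0:
                raise MatrixError(
                    "all specimens fell below the call-rate threshold; "
                    "nothing to karyotype"
                )
            out = GenotypeMatrix(
                out.genotypes.loc[list(keep_spec)], out.specimens.loc[list(keep_spec)]
            )
        if not changed:
            break

    final_snp = snp_call_rates(out, panel)
    final_spec = specimen_call_rates(out, panel)
    report.snp_rate_mean = float(final_snp.mean())
    report.snp_rate_range = (float(final_snp.min()), float(final_snp.max()))
    report.specimen_rate_mean = float(final_spec.mean())
    report.specimen_rate_range = (float(final_spec.min()), float(final_spec.max()))
    return out, report


def mean_alt_alleles(
    genotypes, min_tags: int = 1
) -> tuple[float | None, int]:
    """Mean alternate-allele count over non-missing entries.

    Returns ``(mean, n_used)``; mean is None when fewer than ``min_tags``
    entries are non-missing.
    """
    arr = np.asarray(genotypes, dtype=float)
    called = arr[~np.isnan(arr)]
    if called.size < min_tags:
        return None, int(called.size)
    return float(called.mean()), int(called.size)


def bin_genotype(mean_alt: float) -> int:
    """Bin a mean alternate-allele count into a multilocus genotype.

    Three equal bins over [0, 2]; boundaries belong to the lower bin:
    ``mean <= 2/3 -> 0``, ``2/3 < mean <= 4/3 -> 1``, ``mean > 4/3 -> 2``.
    """
    if not isinstance(mean_alt, (int, float)) or math.isnan(mean_alt):
        raise ValueError(f"mean_alt must be a number in [0, 2], got {mean_alt!r}")
    if not 0.0 <= mean_alt <= 2.0:
        raise ValueError(f"mean_alt out of range [0, 2]: {mean_alt}")
    if mean_alt <= BIN_EDGE_LOW:
        return 0
    if mean_alt <= BIN_EDGE_HIGH:
        return 1
    return 2


def call_karyotypes(
    matrix: GenotypeMatrix,
    panel: Panel,
    config: FilterConfig | None = None,
    apply_filters: bool = False,
) -> pd.DataFrame:
    """Call one multilocus inversion genotype per specimen x applicable inversion.

    Returns a long DataFrame with columns ``specimen_id, species, inversion_id,
    n_tags_used, mean_alt, genotype`` (genotype NaN when too few tags were
    called).  With ``apply_filters=True`` the call-rate filters run first.
    """
    config = config or FilterConfig()
    if apply_filters:
        matrix, report = filter_matrix(matrix, config, panel)
        logger.info(
            "filters dropped %d tags and %d specimens",
            len(report.dropped_snps),
            len(report.dropped_specimens),
        )
    snp_cols = set(matrix.genotypes.columns)
    inv_tags = {
        inv: [t.snp_id for t in panel.tags_for_inversion(inv) if t.snp_id in snp_cols]
        for inv in panel.registry
    }
    rows = []
    for specimen_id, geno in matrix.genotypes.iterrows():
        species = matrix.species_of(specimen_id)
        if species is None:
            applicable = list(panel.registry)
        else:
            applicable = panel.applicable_inversions(species)
        if not applicable:
            logger.warning("specimen %s: no applicable inversions", specimen_id)
        for inv in applicable:
            tag_ids = inv_tags[inv]
            if not tag_ids:
                continue
            mean, n_used = mean_alt_alleles(
                geno[tag_ids], min_tags=config.min_tags_per_inversion
            )
            rows.append(
                {
                    "specimen_id": specimen_id,
                    "species": species,
                    "inversion_id": inv,
                    "n_tags_used": n_used,
                    "mean_alt": np.nan if mean is None else mean,
                    "genotype": np.nan if mean is None else bin_genotype(mean),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "specimen_id",
            "species",
            "inversion_id",
            "n_tags_used",
            "mean_alt",
            "genotype",
        ],
    )


# ---------------------------------------------------------------------------
# CSV I/O: header `specimen_id,species,numeric_code,<snp_id...>`, entries
# 0/1/2/NA.

def load_matrix(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, na_values=["NA"])
    meta_cols = [c for c in ("specimen_id", "species", "numeric_code") if c in df.columns]
    if "specimen_id" not in meta_cols:
        raise MatrixError(f"{path}: missing specimen_id column")
    df = df.set_index("specimen_id")
    geno_cols = [c for c in df.columns if c not in ("species", "numeric_code")]
    specimens = pd.DataFrame(index=df.index)
    specimens["species"] = df["species"] if "species" in df.columns else None
    specimens["numeric_code"] = (
        df["numeric_code"].astype("Int64")
        if "numeric_code" in df.columns
        else pd.array(range(1, len(df) + 1), dtype="Int64")
    )
    return GenotypeMatrix(df[geno_cols].astype(float), specimens)


def save_matrix(matrix: GenotypeMatrix, path: str | Path) -> None:
    out = pd.concat([matrix.specimens, matrix.genotypes], axis=1)
    # keep integer rendering for genotype cells
    for c in matrix.genotypes.columns:
        out[c] = out[c].astype("Int64")
    out.index.name = "specimen_id"
    out.to_csv(path, na_rep="NA")


def save_karyotypes(calls: pd.DataFrame, path: str | Path) -> None:
    """Write karyotype calls as TSV; mean_alt rendered to 4 decimals."""
    out = calls.copy()
    out["mean_alt"] = out["mean_alt"].map(
        lambda v: "NA" if pd.isna(v) else f"{v:.4f}"
    )
    out["genotype"] = out["genotype"].astype("Int64")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def _opt(value):
    return None if pd.isna(value) else value
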