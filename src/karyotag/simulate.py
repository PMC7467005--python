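"""Synthetic cohorts with known inversion karyotypes for end-to-end testing.

The generative model works at the level of chromosome copies.  Each specimen
carries two copies per inversion; each copy is inverted independently with
the inversion's arrangement frequency f, so karyotype genotypes follow
Hardy-Weinberg proportions in expectation.  A tag SNP carries the alternate
allele on an inverted copy with probability ``p_inv`` and on a standard copy
with probability ``p_std``; each allele is flipped with error ``epsilon``.
This haplotype-level linkage yields closed-form per-class concordances
(e.g. the homozygous-standard class concordance is ``q**2`` with
``q = (1-p_std)(1-eps) + p_std*eps``) and naturally reproduces the downward
bias toward genotype 0 when tags uncorrelated with the inversion are applied
to the wrong taxon.  Read depths are negative-binomial with binomial allele
sampling; cytogenetic calls can be error-injected, optionally only in
even-coded specimens, to emulate one of two karyotyping teams mis-scoring.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .amplicon import AlleleCounts, ProbeSet
from .karyotype import GenotypeMatrix
from .panel import Panel, TagSNP, default_registry

NUCS = "ACGT"


@dataclass
class SimConfig:
    """Generative parameters of a synthetic cohort.

    Defaults mirror a West-African field collection genotyped on a
    multi-inversion tag panel: two species in roughly equal numbers,
    arrangement frequencies spanning rare (2Rj, 2Rd) to near-fixed (2La),
    strong but imperfect tag-inversion linkage, light missingness, and
    overdispersed amplicon depths.
    """

    n_specimens: int = 960
    species_proportions: dict[str, float] = field(
        default_factory=lambda: {"gambiae": 0.45, "coluzzii": 0.55}
    )
    inversion_freqs: dict[str, float] = field(
        default_factory=lambda: {
            "2La": 0.90,
            "2Rj": 0.05,
            "2Rb": 0.50,
            "2Rc_col": 0.45,
            "2Rc_gam": 0.15,
            "2Rd": 0.05,
            "2Ru": 0.10,
        }
    )
    n_tags_per_inversion: int = 10
    p_inv: float = 0.95  # P(alt allele | chromosome copy inverted)
    p_std: float = 0.02  # P(alt allele | standard copy)
    epsilon: float = 0.005  # per-allele flip error
    missing_rate: float = 0.02  # per genotype call
    depth_mean: float = 200.0
    depth_dispersion: float = 5.0  # negative-binomial size parameter
    seq_error: float = 0.005  # per-base miscall in allele counts
    cyt_error_rate: float = 0.0
    cyt_even_bias: bool = False  # restrict cytogenetic errors to even codes
    amplicon_length: int = 60
    probe_flank: int = 7

    def __post_init__(self) -> None:
        probs = [
            self.p_inv, self.p_std, self.epsilon, self.missing_rate,
            self.seq_error, self.cyt_error_rate,
            *self.inversion_freqs.values(), *self.species_proportions.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")
        if self.depth_mean < 0 or self.depth_dispersion <= 0:
            raise ValueError("depth model parameters invalid")


@dataclass
class SimTruth:
    """Ground truth: specimen metadata and true karyotypes.

    ``specimens``: DataFrame indexed by specimen_id with ``species`` and
    sequential ``numeric_code`` (1..n, so odd/even stratification is
    exercisable by construction).  ``karyotypes``: specimen x inversion
    frame of true inverted-copy counts (NaN where the inversion is not
    applicable to the specimen's species).
    """

    specimens: pd.DataFrame
    karyotypes: pd.DataFrame
    #: per specimen x inversion, the number of inverted copies of each
    #: chromosome (internal; used to correlate tag alleles within specimens)
    copies: pd.DataFrame | None = None


def build_panel(config: SimConfig | None = None, rng=None) -> tuple[Panel, dict]:
    """Generate a synthetic tag panel plus amplicon sequence context.

    Returns (panel, context) where context maps snp_id to (amplicon sequence
    carrying the reference allele, 0-based SNP index) for probe construction
    and FASTQ synthesis.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(rng)
    registry = default_registry()
    tags, context = [], {}
    pos = 1000
    for inv_id, inv in registry.items():
        for i in range(config.n_tags_per_inversion):
            snp_id = f"{inv_id}_tag{i:02d}"
            seq = "".join(rng.choice(list(NUCS), size=config.amplicon_length))
            centre = config.amplicon_length // 2
            ref = seq[centre]
            alt = rng.choice([n for n in NUCS if n != ref])
            lo = centre - config.probe_flank
            hi = centre + config.probe_flank + 1
            tags.append(
                TagSNP(
                    snp_id=snp_id,
                    inversion_id=inv_id,
                    arm=inv.arm,
                    position=pos,
                    ref_allele=ref,
                    alt_allele=str(alt),
                    platform="GTseq",
                    fwd_primer=seq[:18],
                    probe_ref=seq[lo:hi],
                    probe_alt=seq[lo:centre] + str(alt) + seq[centre + 1 : hi],
                )
            )
            context[snp_id] = (seq, centre)
            pos += 997
    return Panel(tags, registry), context


def simulate_karyotypes(config: SimConfig, rng=None) -> SimTruth:
    """Draw specimens, species, and true karyotypes under Hardy-Weinberg.

    Each chromosome copy is inverted independently with probability f, so
    genotype frequencies are (1-f)^2, 2f(1-f), f^2 in expectation.
    """
    rng = np.random.default_rng(rng)
    registry = default_registry()
    n = config.n_specimens
    species_labels = list(config.species_proportions)
    probs = np.array(list(config.species_proportions.values()), dtype=float)
    probs = probs / probs.sum()
    species = rng.choice(species_labels, size=n, p=probs)
    ids = [f"SIM{i:05d}" for i in range(1, n + 1)]
    specimens = pd.DataFrame(
        {"species": species, "numeric_code": pd.array(range(1, n + 1), dtype="Int64")},
        index=pd.Index(ids, name="specimen_id"),
    )
    karyotypes = pd.DataFrame(index=specimens.index, columns=list(registry), dtype=float)
    for inv_id, inv in registry.items():
        f = config.inversion_freqs.get(inv_id, 0.0)
        geno = rng.binomial(2, f, size=n).astype(float)
        applicable = np.array([sp in inv.species for sp in species])
        geno[~applicable] = np.nan
        karyotypes[inv_id] = geno
    return SimTruth(specimens=specimens, karyotypes=karyotypes)


def simulate_tag_matrix(
    truth: SimTruth, panel: Panel, config: SimConfig, rng=None
) -> GenotypeMatrix:
    """Generate tag-SNP genotypes linked to the true karyotypes.

    Per chromosome copy, the alt allele appears with probability ``p_inv`` on
    inverted copies and ``p_std`` on standard copies; each allele flips with
    probability ``epsilon``; the SNP genotype is the alt-allele count, set
    missing with probability ``missing_rate``.  Tags of inversions not
    applicable to a specimen's species are missing.
    """
    rng = np.random.default_rng(rng)
    n = len(truth.specimens)
    p_inv_eff = config.p_inv * (1 - config.epsilon) + (1 - config.p_inv) * config.epsilon
    p_std_eff = config.p_std * (1 - config.epsilon) + (1 - config.p_std) * config.epsilon
    geno = pd.DataFrame(
        np.nan, index=truth.specimens.index, columns=panel.snp_ids
    )
    for tag in panel.tags:
        k = truth.karyotypes[tag.inversion_id].to_numpy()  # inverted copies
        applicable = ~np.isnan(k)
        n_inv = np.where(applicable, k, 0).astype(int)
        alt = rng.binomial(n_inv, p_inv_eff) + rng.binomial(2 - n_inv, p_std_eff)
        out = alt.astype(float)
        out[rng.random(n) < config.missing_rate] = np.nan
        out[~applicable] = np.nan
        geno[tag.snp_id] = out
    return GenotypeMatrix(geno, truth.specimens.copy())


def simulate_allele_counts(
    matrix: GenotypeMatrix, config: SimConfig, rng=None
) -> list[AlleleCounts]:
    """Generate per-locus read counts from genotypes.

    Depth is negative-binomial (mean ``depth_mean``, size
    ``depth_dispersion``); the reference-read count is binomial with success
    probability ``(1 - g/2)(1-e) + (g/2)e`` for genotype g and per-base error
    e.  Missing genotypes get zero depth.
    """
    rng = np.random.default_rng(rng)
    size = config.depth_dispersion
    p_nb = size / (size + config.depth_mean) if config.depth_mean > 0 else 1.0
    counts = []
    values = matrix.genotypes
    for snp_id in values.columns:
        col = values[snp_id].to_numpy()
        for specimen_id, g in zip(values.index, col):
            if np.isnan(g):
                counts.append(AlleleCounts(specimen_id, snp_id, 0, 0, 0))
                continue
            depth = int(rng.negative_binomial(size, p_nb)) if config.depth_mean > 0 else 0
            pi_ref = (1 - g / 2) * (1 - config.seq_error) + (g / 2) * config.seq_error
            ref = int(rng.binomial(depth, pi_ref))
            counts.append(AlleleCounts(specimen_id, snp_id, ref, depth - ref, 0))
    return counts


def simulate_cytogenetic_calls(
    truth: SimTruth, config: SimConfig, rng=None
) -> pd.DataFrame:
    """Error-inject cytogenetic karyotype readings from the truth.

    Each call equals the true karyotype except with probability
    ``cyt_error_rate``, in which case it moves to a uniformly chosen
    different genotype class.  With ``cyt_even_bias`` the error rate applies
    only to even-numbered specimens, emulating a mis-scoring karyotyping
    team.
    """
    rng = np.random.default_rng(rng)
    calls = truth.karyotypes.copy()
    even = (truth.specimens["numeric_code"].astype(int) % 2 == 0).to_numpy()
    for inv in calls.columns:
        col = calls[inv].to_numpy()
        eligible = ~np.isnan(col)
        if config.cyt_even_bias:
            eligible &= even
        err = eligible & (rng.random(len(col)) < config.cyt_error_rate)
        for i in np.flatnonzero(err):
            others = [g for g in (0, 1, 2) if g != int(col[i])]
            col[i] = float(rng.choice(others))
        calls[inv] = col
    return calls


def simulate_triplicate_calls(
    config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, SimTruth, Panel]:
    """End-to-end cohort: truth, two molecular platforms, cytogenetics.

    Builds a panel, simulates two independent tag-genotype matrices (standing
    in for the array and sequencing platforms, whose tag sets in practice
    barely overlap), karyotypes each, injects cytogenetic error, and emits a
    long-format triplicate-calls frame emulating a published per-specimen
    genotype table (cytogenetic + two molecular calls per inversion, odd and
    even specimen codes, two species).
    """
    from .karyotype import FilterConfig, call_karyotypes

    rng = np.random.default_rng(seed)
    panel, _ = build_panel(config, rng)
    truth = simulate_karyotypes(config, rng)
    cyt = simulate_cytogenetic_calls(truth, config, rng)

    molecular = {}
    for platform in ("oa", "gt"):
        matrix = simulate_tag_matrix(truth, panel, config, rng)
        calls = call_karyotypes(matrix, panel, FilterConfig())
        molecular[platform] = calls.set_index(["specimen_id", "inversion_id"])[
            "genotype"
        ]

    rows = []
    for specimen_id, meta in truth.specimens.iterrows():
        for inv in truth.karyotypes.columns:
            if np.isnan(truth.karyotypes.loc[specimen_id, inv]):
                continue
            rows.append(
                {
                    "specimen_id": specimen_id,
                    "species": meta["species"],
                    "numeric_code": int(meta["numeric_code"]),
                    "inversion_id": inv,
                    "cyt": cyt.loc[specimen_id, inv],
                    "oa": molecular["oa"].get((specimen_id, inv), np.nan),
                    "gt": molecular["gt"].get((specimen_id, inv), np.nan),
                }
            )
    return pd.DataFrame(rows), truth, panel


def write_fastq(
    matrix: GenotypeMatrix,
    panel: Panel,
    context: dict[str, tuple[str, int]],
    config: SimConfig,
    out_dir: str | Path,
    rng=None,
) -> dict[str, Path]:
    """Synthesize per-specimen FASTQ files of amplicon reads.

    Reads are the amplicon sequence with the tag base substituted per the
    sampled allele counts; qualities are constant.  Returns the
    specimen -> path manifest.
    """
    rng = np.random.default_rng(rng)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = simulate_allele_counts(matrix, config, rng)
    by_specimen: dict[str, list[AlleleCounts]] = {}
    for c in counts:
        by_specimen.setdefault(c.specimen_id, []).append(c)
    manifest = {}
    for specimen_id, cs in by_specimen.items():
        path = out_dir / f"{specimen_id}.fastq"
        with open(path, "w") as fh:
            i = 0
            for c in cs:
                seq, idx = context[c.snp_id]
                tag = panel.snp(c.snp_id)
                ref_read = seq
                alt_read = seq[:idx] + tag.alt_allele + seq[idx + 1 :]
                for read, n_reads in ((ref_read, c.count_ref), (alt_read, c.count_alt)):
                    for _ in range(n_reads):
                        fh.write(
                            f"@{specimen_id}:{c.snp_id}:{i}\n{read}\n+\n"
                            f"{'I' * len(read)}\n"
                        )
                        i += 1
        manifest[specimen_id] = path
    return manifest
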