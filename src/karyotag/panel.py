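"""Tag-SNP panel definitions, loading, validation, and applicability queries.

A *tag SNP* is a polymorphism inside the rearranged region of a chromosomal
inversion whose allelic state is strongly correlated with inversion
orientation, making it a molecular proxy for the karyotype.  A panel groups
tag SNPs by the inversion they report on; an inversion registry records which
species each inversion's tags can be scored in.  In the *Anopheles gambiae*
complex, 2La, 2Rb and 2Ru tags perform in both *An. gambiae* and
*An. coluzzii*, 2Rj and 2Rd tags are *An. gambiae*-specific, and 2Rc tags
come in two species-partitioned sets (here ``2Rc_col`` and ``2Rc_gam``).

Coordinates are 1-based inclusive reference positions.  The panel format
records an assembly tag verbatim and does not interpret it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

NUCLEOTIDES = frozenset("ACGT")

#: Species labels known by the default registry.
DEFAULT_SPECIES = ("gambiae", "coluzzii")


class PanelError(ValueError):
    """Raised when a panel, registry, or tag fails validation."""


@dataclass(frozen=True)
class InversionDef:
    """An inversion and the species whose specimens its tags can genotype."""

    inversion_id: str
    arm: str
    species: frozenset[str]

    def applies_to(self, species: str) -> bool:
        return species in self.species


def default_registry() -> dict[str, InversionDef]:
    """Registry of the common 2L/2R inversion polymorphisms.

    2La, 2Rb and 2Ru tags perform in both species; 2Rj and 2Rd tags are
    *An. gambiae*-specific; the two 2Rc tag sets are species-partitioned.
    """
    both = frozenset(DEFAULT_SPECIES)
    gam = frozenset({"gambiae"})
    col = frozenset({"coluzzii"})
    defs = [
        InversionDef("2La", "2L", both),
        InversionDef("2Rj", "2R", gam),
        InversionDef("2Rb", "2R", both),
        InversionDef("2Rc_col", "2R", col),
        InversionDef("2Rc_gam", "2R", gam),
        InversionDef("2Rd", "2R", gam),
        InversionDef("2Ru", "2R", both),
    ]
    return {d.inversion_id: d for d in defs}


@dataclass(frozen=True)
class TagSNP:
    """A single tag SNP: alleles, coordinates, inversion membership.

    ``concordance_per_class`` holds the per-genotype-class concordances
    (homozygous standard, heterozygous, homozygous inverted) estimated during
    ascertainment; ``min_concordance`` is their minimum, the conservative
    genotypic concordance.
    """

    snp_id: str
    inversion_id: str
    arm: str
    position: int
    ref_allele: str
    alt_allele: str
    platform: str | None = None
    concordance_per_class: tuple[float, float, float] | None = None
    min_concordance: float | None = None
    fwd_primer: str | None = None
    rev_primer: str | None = None
    probe_ref: str | None = None
    probe_alt: str | None = None

    def __post_init__(self) -> None:
        if self.ref_allele not in NUCLEOTIDES:
            raise PanelError(
                f"{self.snp_id}: ref allele {self.ref_allele!r} is not a nucleotide"
            )
        if self.alt_allele not in NUCLEOTIDES:
            raise PanelError(
                f"{self.snp_id}: alt allele {self.alt_allele!r} is not a nucleotide"
            )
        if self.ref_allele == self.alt_allele:
            raise PanelError(f"{self.snp_id}: ref and alt alleles are identical")
        if self.position < 1:
            raise PanelError(f"{self.snp_id}: position must be >= 1 (1-based)")
        if self.platform is not None and self.platform not in ("OA", "GTseq", "both"):
            raise PanelError(f"{self.snp_id}: unknown platform {self.platform!r}")
        if self.concordance_per_class is not None:
            if any(not 0.0 <= c <= 1.0 for c in self.concordance_per_class):
                raise PanelError(f"{self.snp_id}: concordances must lie in [0, 1]")
            expected = min(self.concordance_per_class)
            if self.min_concordance is None:
                object.__setattr__(self, "min_concordance", expected)
            elif abs(self.min_concordance - expected) > 1e-9:
                raise PanelError(
                    f"{self.snp_id}: min_concordance {self.min_concordance} does not "
                    f"equal the class minimum {expected}"
                )


@dataclass
class Panel:
    """A validated collection of tag SNPs plus the inversion registry."""

    tags: list[TagSNP]
    registry: dict[str, InversionDef] = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for tag in self.tags:
            if tag.snp_id in seen:
                raise PanelError(f"duplicate snp_id: {tag.snp_id}")
            seen.add(tag.snp_id)
            if tag.inversion_id not in self.registry:
                raise PanelError(
                    f"{tag.snp_id}: unknown inversion {tag.inversion_id!r} "
                    f"(registry knows {sorted(self.registry)})"
                )
        self._by_id = {t.snp_id: t for t in self.tags}

    def __len__(self) -> int:
        return len(self.tags)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._by_id

    def snp(self, snp_id: str) -> TagSNP:
        try:
            return self._by_id[snp_id]
        except KeyError:
            raise PanelError(f"unknown snp_id: {snp_id}") from None

    @property
    def snp_ids(self) -> list[str]:
        return [t.snp_id for t in self.tags]

    def species_labels(self) -> frozenset[str]:
        out: set[str] = set()
        for inv in self.registry.values():
            out |= inv.species
        return frozenset(out)

    def counts_by_inversion(self) -> dict[str, int]:
        """Number of tags per inversion (inversions with no tags included as 0)."""
        counts = {inv: 0 for inv in self.registry}
        for tag in self.tags:
            counts[tag.inversion_id] += 1
        return counts

    def tags_for_inversion(self, inversion_id: str) -> list[TagSNP]:
        if inversion_id not in self.registry:
            raise PanelError(f"unknown inversion: {inversion_id}")
        return [t for t in self.tags if t.inversion_id == inversion_id]

    def applicable_inversions(self, species: str) -> list[str]:
        """Inversion ids whose tags can be scored in ``species`` (registry order)."""
        self._check_species(species)
        return [i for i, d in self.registry.items() if d.applies_to(species)]

    def applicable_tags(self, inversion_id: str, species: str) -> list[TagSNP]:
        """Tags of ``inversion_id`` usable in ``species``; empty if inapplicable.

        For every inversion the result over the two species is either the same
        list twice or one empty list — tag sets are never species-divergent
        within one inversion id.
        """
        self._check_species(species)
        tags = self.tags_for_inversion(inversion_id)
        if not self.registry[inversion_id].applies_to(species):
            return []
        return tags

    def tag_applies(self, snp_id: str, species: str | None) -> bool:
        """Whether a tag is scoreable in a specimen of ``species``.

        ``species=None`` (unknown) is treated as applicable everywhere, since
        applicability cannot be evaluated without a species label.
        """
        if species is None:
            return True
        self._check_species(species)
        return self.registry[self.snp(snp_id).inversion_id].applies_to(species)

    def _check_species(self, species: str) -> None:
        if species not in self.species_labels():
            raise PanelError(
                f"unknown species {species!r}; registry knows "
                f"{sorted(self.species_labels())}"
            )


# ---------------------------------------------------------------------------
# Panel TSV I/O
#
# Tab-separated with header:
#   snp_id  inversion  arm  position  ref  alt  [platform  conc0 conc1 conc2
#   min_conc  fwd_primer  rev_primer  probe_ref  probe_alt]
# "NA" marks an absent optional field.

_REQUIRED_COLUMNS = ["snp_id", "inversion", "arm", "position", "ref", "alt"]
_OPTIONAL_COLUMNS = [
    "platform",
    "conc0",
    "conc1",
    "conc2",
    "min_conc",
    "fwd_primer",
    "rev_primer",
    "probe_ref",
    "probe_alt",
]


def load_panel(
    path: str | Path,
    registry: Mapping[str, InversionDef] | None = None,
) -> Panel:
    """Load and validate a panel from a tab-separated file.

    Raises :class:`PanelError` on duplicate snp_ids, unknown inversions, or
    non-nucleotide alleles; the message names the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"{path}: missing required columns {missing}")
    tags = []
    for rec in df.to_dict("records"):
        conc = None
        if all(_present(rec.get(c)) for c in ("conc0", "conc1", "conc2")):
            conc = tuple(float(rec[c]) for c in ("conc0", "conc1", "conc2"))
        tags.append(
            TagSNP(
                snp_id=rec["snp_id"],
                inversion_id=rec["inversion"],
                arm=rec["arm"],
                position=int(rec["position"]),
                ref_allele=rec["ref"],
                alt_allele=rec["alt"],
                platform=_opt(rec.get("platform")),
                concordance_per_class=conc,
                min_concordance=(
                    float(rec["min_conc"]) if _present(rec.get("min_conc")) else None
                ),
                fwd_primer=_opt(rec.get("fwd_primer")),
                rev_primer=_opt(rec.get("rev_primer")),
                probe_ref=_opt(rec.get("probe_ref")),
                probe_alt=_opt(rec.get("probe_alt")),
            )
        )
    reg = dict(registry) if registry is not None else default_registry()
    return Panel(tags=tags, registry=reg)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel to TSV; :func:`load_panel` of the result is the identity."""
    rows = []
    for t in panel.tags:
        conc = t.concordance_per_class or (None, None, None)
        rows.append(
            {
                "snp_id": t.snp_id,
                "inversion": t.inversion_id,
                "arm": t.arm,
                "position": t.position,
                "ref": t.ref_allele,
                "alt": t.alt_allele,
                "platform": t.platform,
                "conc0": conc[0],
                "conc1": conc[1],
                "conc2": conc[2],
                "min_conc": t.min_concordance,
                "fwd_primer": t.fwd_primer,
                "rev_primer": t.rev_primer,
                "probe_ref": t.probe_ref,
                "probe_alt": t.probe_alt,
            }
        )
    df = pd.DataFrame(rows, columns=_REQUIRED_COLUMNS + _OPTIONAL_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def load_registry(path: str | Path) -> dict[str, InversionDef]:
    """Load an inversion registry from JSON.

    Format: ``{"2La": {"arm": "2L", "species": ["gambiae", "coluzzii"]}, ...}``.
    Editing this file generalises the tool beyond the two default species.
    """
    with open(path) as fh:
        raw = json.load(fh)
    out = {}
    for inv_id, spec in raw.items():
        out[inv_id] = InversionDef(
            inversion_id=inv_id,
            arm=spec["arm"],
            species=frozenset(spec["species"]),
        )
    return out


def write_registry(registry: Mapping[str, InversionDef], path: str | Path) -> None:
    raw = {
        inv_id: {"arm": d.arm, "species": sorted(d.species)}
        for inv_id, d in registry.items()
    }
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=2)


def _present(value) -> bool:
    return value is not None and value == value and value != ""


def _opt(value) -> str | None:
    return value if _present(value) else None
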