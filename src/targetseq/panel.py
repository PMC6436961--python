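"""Amplicon panel model: target variants, primers, molecule classes.

A TARGET-seq panel assays a small set of somatic mutations twice per cell:
once from a genomic-DNA amplicon (anchored in an intron) and once from a
cDNA amplicon (fully exonic).  Each :class:`AmpliconSpec` therefore carries
a molecule class, a primer pair and the variant(s) it covers; the same
mutation is linked across molecule classes through the variant ``name``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "ConfigurationError",
    "VariantSite",
    "AmpliconSpec",
    "Panel",
    "read_vcf_sites",
    "write_vcf_sites",
]

_DNA = set("ACGT")

Molecule = Literal["gDNA", "mRNA"]


class ConfigurationError(ValueError):
    """Raised when a panel, threshold or simulation configuration is invalid."""


@dataclass(frozen=True)
class VariantSite:
    """A target variant in 1-based VCF-style coordinates.

    ``name`` identifies the mutation across the gDNA and cDNA amplicons that
    assay it (e.g. ``"JAK2:V617F"``); coordinates may differ between the two
    because cDNA amplicons live in transcript space.
    ``zygosity_critical`` marks variants whose heterozygous/homozygous
    distinction matters downstream; only those get a not-determined (ND)
    allele-frequency window during calling.
    """

    name: str
    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity_critical: bool = False

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ConfigurationError(f"{self.name}: empty ref/alt allele")
        if self.pos < 1:
            raise ConfigurationError(f"{self.name}: pos must be 1-based positive")
        bad = (set(self.ref) | set(self.alt)) - _DNA
        if bad:
            raise ConfigurationError(f"{self.name}: non-ACGT allele characters {bad}")
        if self.ref == self.alt:
            raise ConfigurationError(f"{self.name}: ref equals alt")

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"


@dataclass(frozen=True)
class AmpliconSpec:
    """One PCR amplicon: primers, genomic interval and covered variants."""

    amplicon_id: str
    gene: str
    molecule: Molecule
    fwd_primer: str
    rev_primer: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    variants: tuple[VariantSite, ...] = ()

    def __post_init__(self) -> None:
        if self.molecule not in ("gDNA", "mRNA"):
            raise ConfigurationError(
                f"{self.amplicon_id}: molecule must be gDNA or mRNA, got {self.molecule!r}"
            )
        for primer in (self.fwd_primer, self.rev_primer):
            if not primer or set(primer) - _DNA:
                raise ConfigurationError(
                    f"{self.amplicon_id}: primers must be non-empty uppercase ACGT"
                )
        if self.end < self.start:
            raise ConfigurationError(f"{self.amplicon_id}: end < start")
        object.__setattr__(self, "variants", tuple(self.variants))
        for v in self.variants:
            if not (self.start <= v.pos <= self.end):
                raise ConfigurationError(
                    f"variant {v.name} at {v.chrom}:{v.pos} lies outside "
                    f"amplicon {self.amplicon_id} [{self.start}, {self.end}]"
                )


@dataclass
class Panel:
    """An ordered collection of amplicons; order fixes clone naming."""

    amplicons: list[AmpliconSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [a.amplicon_id for a in self.amplicons]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate amplicon_id in panel")

    def __iter__(self):
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def __getitem__(self, amplicon_id: str) -> AmpliconSpec:
        for a in self.amplicons:
            if a.amplicon_id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    @property
    def genes(self) -> list[str]:
        seen: list[str] = []
        for a in self.amplicons:
            if a.gene not in seen:
                seen.append(a.gene)
        return seen

    @property
    def variant_names(self) -> list[str]:
        """Unique variant names in panel order (the clone-naming order)."""
        seen: list[str] = []
        for a in self.amplicons:
            for v in a.variants:
                if v.name not in seen:
                    seen.append(v.name)
        return seen

    def variants_for(self, amplicon_id: str) -> tuple[VariantSite, ...]:
        return self[amplicon_id].variants

    def site(self, variant_name: str, molecule: Molecule) -> VariantSite | None:
        for a in self.amplicons:
            if a.molecule != molecule:
                continue
            for v in a.variants:
                if v.name == variant_name:
                    return v
        return None

    # ---- serialization -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        data = [
            {
                "amplicon_id": a.amplicon_id,
                "gene": a.gene,
                "molecule": a.molecule,
                "fwd_primer": a.fwd_primer,
                "rev_primer": a.rev_primer,
                "chrom": a.chrom,
                "start": a.start,
                "end": a.end,
                "variants": [
                    {
                        "name": v.name,
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "ref": v.ref,
                        "alt": v.alt,
                        "zygosity_critical": v.zygosity_critical,
                    }
                    for v in a.variants
                ],
            }
            for a in self.amplicons
        ]
        Path(path).write_text(json.dumps(data, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Panel":
        data = json.loads(Path(path).read_text())
        amps = []
        for d in data:
            variants = tuple(VariantSite(**v) for v in d.pop("variants", []))
            amps.append(AmpliconSpec(variants=variants, **d))
        return cls(amps)


def write_vcf_sites(sites: Iterable[VariantSite], path: str | Path) -> None:
    """Export variant sites as a minimal VCF (CHROM POS ID REF ALT)."""
    lines = ["##fileformat=VCFv4.2", "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    for s in sites:
        lines.append(f"{s.chrom}\t{s.pos}\t{s.name}\t{s.ref}\t{s.alt}\t.\t.\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_sites(path: str | Path) -> list[VariantSite]:
    """Import target variants from a minimal VCF; ID column becomes the name."""
    sites = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, pos, vid, ref, alt = line.split("\t")[:5]
        sites.append(VariantSite(name=vid, chrom=chrom, pos=int(pos), ref=ref, alt=alt))
    return sites
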