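"""Known editing-site catalogs.

A catalog is a TSV with header ``chrom  pos  strand  gene  region  repeat``
(RADAR-style): 1-based position, strand in {+,-}, region in
{CDS, UTR5, UTR3, intron, intergenic}, repeat in {rep, nonrep}.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import ParseError, ValidationError

REGIONS = ("CDS", "UTR5", "UTR3", "intron", "intergenic")
CATALOG_COLUMNS = ("chrom", "pos", "strand", "gene", "region", "repeat")


@dataclass(frozen=True)
class EditingSite:
    """One catalog entry: a known A-to-I editing locus."""

    chrom: str
    pos: int  # 1-based reference coordinate
    strand: str  # "+" or "-"
    gene: str = ""
    region: str = "intergenic"
    repeat: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"site position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region category {self.region!r}")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.strand}"


def load_site_catalog(path: str | Path) -> list[EditingSite]:
    """Read and validate a site catalog TSV, sorted by (chrom, pos).

    Raises :class:`ParseError` (with line number) on malformed rows and
    :class:`ValidationError` on duplicate (chrom, pos, strand) loci.
    """
    sites: list[EditingSite] = []
    seen: set[tuple[str, int, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() == "chrom":
                continue
            if len(fields) != len(CATALOG_COLUMNS):
                raise ParseError(
                    f"line {lineno}: expected {len(CATALOG_COLUMNS)} columns, got {len(fields)}"
                )
            chrom, pos_s, strand, gene, region, repeat_s = fields
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"line {lineno}: position {pos_s!r} is not an integer") from None
            if pos < 1:
                raise ParseError(f"line {lineno}: position must be >= 1 (1-based), got {pos}")
            if repeat_s not in ("rep", "nonrep"):
                raise ParseError(f"line {lineno}: repeat flag must be 'rep' or 'nonrep', got {repeat_s!r}")
            try:
                site = EditingSite(chrom, pos, strand, gene, region, repeat_s == "rep")
            except ValidationError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            key = (chrom, pos, strand)
            if key in seen:
                raise ValidationError(f"duplicate locus {chrom}:{pos}:{strand}")
            seen.add(key)
            sites.append(site)
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def write_site_catalog(sites: Iterable[EditingSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.strand}\t{s.gene}\t{s.region}\t"
                f"{'rep' if s.repeat else 'nonrep'}\n"
            )
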