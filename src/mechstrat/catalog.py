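"""Mechanism catalogue: gene sets, gene coordinates and the SNP→gene→mechanism map.

A *mechanism* is a named set of gene symbols (a literature-derived cause–effect
subgraph shared between the AD and PD disease maps). SNPs are attached to genes
either by genomic proximity (a symmetric window around the gene body) or by
precomputed eQTL pairs, and inherit every mechanism their gene belongs to. The
resulting per-mechanism SNP groups drive all downstream burden scoring.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "MechanismCatalog",
    "SnpGrouping",
    "load_catalog",
    "default_catalog",
    "map_snps_to_genes",
    "group_snps_by_mechanism",
    "DEFAULT_GROUP_SIZES",
]


class CatalogFormatError(ValueError):
    """Raised when a catalogue file violates the schema."""


#: SNP counts per mechanism in the packaged default design: 148 SNPs spread
#: unevenly (widths 4–20) over 15 mechanisms.
DEFAULT_GROUP_SIZES: tuple[int, ...] = (20, 4, 14, 6, 12, 8, 10, 10, 8, 12, 6, 14, 4, 10, 10)


@dataclass
class MechanismCatalog:
    """Named mechanism gene sets plus gene coordinates and the SNP→gene map.

    Attributes
    ----------
    mechanisms : dict of str -> list of str
        Ordered mechanism name → gene symbols. A gene may occur in several
        mechanisms.
    gene_annotations : dict of str -> (str, int, int)
        Gene symbol → (chromosome, start, end), 1-based closed coordinates.
    snp_map : dict of str -> list of (str, str)
        SNP id → [(gene, source)], source in {"proximity", "eqtl"}.
    snp_positions : dict of str -> (str, int)
        Optional SNP id → (chromosome, position).
    """

    mechanisms: dict[str, list[str]]
    gene_annotations: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    snp_map: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    snp_positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mechanisms:
            raise CatalogFormatError("catalogue defines no mechanisms")
        for name, genes in self.mechanisms.items():
            if not genes:
                raise CatalogFormatError(f"mechanism {name!r} has an empty gene set")
        covered = {g for genes in self.mechanisms.values() for g in genes}
        orphans = sorted(
            {g for pairs in self.snp_map.values() for g, _src in pairs} - covered
        )
        self.unassigned_genes: list[str] = orphans
        if orphans:
            warnings.warn(
                f"{len(orphans)} mapped gene(s) appear in no mechanism: {orphans[:5]}...",
                stacklevel=2,
            )

    @property
    def mechanism_names(self) -> list[str]:
        return list(self.mechanisms)

    @property
    def genes(self) -> list[str]:
        """Distinct gene symbols across all mechanisms, in first-seen order."""
        seen: dict[str, None] = {}
        for genes in self.mechanisms.values():
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)

    @property
    def n_mechanisms(self) -> int:
        return len(self.mechanisms)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)


@dataclass
class SnpGrouping:
    """Per-mechanism ordered SNP id lists (columns of a genotype matrix).

    A SNP mapped to genes in several mechanisms appears in each of their
    groups; groups are therefore not necessarily disjoint.
    """

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("grouping has no mechanisms")
        for name, snps in self.groups.items():
            if not snps:
                raise ValueError(f"group {name!r} is empty")

    @property
    def mechanism_names(self) -> list[str]:
        return list(self.groups)

    @property
    def all_snps(self) -> list[str]:
        seen: dict[str, None] = {}
        for snps in self.groups.values():
            for s in snps:
                seen.setdefault(s, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.groups)


def _load_gmt(path: Path) -> dict[str, list[str]]:
    mechanisms: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CatalogFormatError(
                    f"{path}:{lineno}: GMT lines need name, description and >=1 gene"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if name in mechanisms:
                raise CatalogFormatError(f"duplicate mechanism name {name!r}")
            if not genes:
                raise CatalogFormatError(f"mechanism {name!r} has an empty gene set")
            mechanisms[name] = genes
    if not mechanisms:
        raise CatalogFormatError(f"{path}: no mechanisms found")
    return mechanisms


def load_catalog(path: str | Path) -> MechanismCatalog:
    """Load a mechanism catalogue from a JSON schema file or a GMT gene-set file.

    JSON schema: ``{"mechanisms": {name: [genes]}, "gene_annotations":
    {gene: [chrom, start, end]}, "snp_map": {snp: [[gene, source], ...]},
    "snp_positions": {snp: [chrom, pos]}}`` — only ``mechanisms`` is required.
    GMT files (tab-separated: name, description, genes…) carry gene sets only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".gmt":
        return MechanismCatalog(mechanisms=_load_gmt(path))
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise CatalogFormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict) or "mechanisms" not in payload:
        raise CatalogFormatError(f"{path}: JSON catalogue needs a 'mechanisms' key")
    mechanisms = {str(k): [str(g) for g in v] for k, v in payload["mechanisms"].items()}
    annotations = {
        str(g): (str(c), int(s), int(e))
        for g, (c, s, e) in payload.get("gene_annotations", {}).items()
    }
    snp_map = {
        str(s): [(str(g), str(src)) for g, src in pairs]
        for s, pairs in payload.get("snp_map", {}).items()
    }
    snp_positions = {
        str(s): (str(c), int(p)) for s, (c, p) in payload.get("snp_positions", {}).items()
    }
    return MechanismCatalog(
        mechanisms=mechanisms,
        gene_annotations=annotations,
        snp_map=snp_map,
        snp_positions=snp_positions,
    )


def default_catalog() -> MechanismCatalog:
    """The packaged default catalogue: 15 mechanisms, 27 genes, 148 SNPs.

    Sixteen gene symbols are real AD/PD genes; the remainder are clearly
    labelled placeholders (``PLACEHOLDER_G17``…), as are the synthetic SNP
    ids — coordinates are synthetic but internally consistent with the
    10 kb proximity mapper.
    """
    with resources.as_file(
        resources.files("mechstrat.data").joinpath("default_catalog.json")
    ) as p:
        return load_catalog(p)


def map_snps_to_genes(
    snp_positions: Mapping[str, tuple[str, int]],
    gene_annotations: Mapping[str, tuple[str, int, int]],
    window_bp: int = 10_000,
    eqtl_pairs: Sequence[tuple[str, str]] | None = None,
) -> dict[str, list[tuple[str, str]]]:
    """Map SNPs to genes by proximity, optionally unioned with eQTL pairs.

    A SNP at position *p* maps to every gene whose closed interval
    ``[start - window_bp, end + window_bp]`` on the same chromosome contains
    *p* (1-based coordinates). eQTL pairs, if given, are added with source
    tag ``"eqtl"``; proximity hits carry ``"proximity"``.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    snp_map: dict[str, list[tuple[str, str]]] = {}
    for snp, (chrom, pos) in snp_positions.items():
        hits = []
        for gene, (g_chrom, start, end) in gene_annotations.items():
            if g_chrom == chrom and start - window_bp <= pos <= end + window_bp:
                hits.append((gene, "proximity"))
        if hits:
            snp_map[snp] = hits
    if eqtl_pairs:
        for snp, gene in eqtl_pairs:
            pairs = snp_map.setdefault(snp, [])
            if (gene, "proximity") not in pairs and (gene, "eqtl") not in pairs:
                pairs.append((gene, "eqtl"))
    return snp_map


def group_snps_by_mechanism(
    catalog: MechanismCatalog, snp_ids: Sequence[str]
) -> SnpGrouping:
    """Group genotype columns by mechanism via the catalogue's SNP→gene map.

    ``snp_ids`` is the genotype header (column order is preserved inside each
    group). SNPs whose genes span several mechanisms appear in each group.
    Mechanisms left without any mapped SNP are dropped with a warning; if all
    mechanisms end up empty the grouping is unusable and an error is raised.
    """
    available = set(snp_ids)
    gene_to_snps: dict[str, list[str]] = {}
    for snp in snp_ids:  # genotype order defines within-group order
        for gene, _src in catalog.snp_map.get(snp, []):
            gene_to_snps.setdefault(gene, []).append(snp)
    groups: dict[str, list[str]] = {}
    for name, genes in catalog.mechanisms.items():
        snps: dict[str, None] = {}
        for gene in genes:
            for snp in gene_to_snps.get(gene, []):
                snps.setdefault(snp, None)
        if snps:
            groups[name] = list(snps)
        else:
            warnings.warn(f"mechanism {name!r} has no mapped SNPs; dropped", stacklevel=2)
    if not groups:
        raise ValueError("no mechanism has any mapped SNPs in this genotype matrix")
    unknown = [s for s in catalog.snp_map if s not in available]
    if unknown and len(unknown) == len(catalog.snp_map):
        raise ValueError("none of the catalogue SNPs occur in the genotype header")
    return SnpGrouping(groups=groups)
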