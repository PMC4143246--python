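"""Reference-anchored partitioning of allotetraploid SSR products.

Each selected marker amplifies two discrete products in an amphidiploid: one
per homoeologous sub-genome.  The product nearer (in bp) to the allele pool
observed in a diploid reference-anchor taxon is assigned to sub-genome A,
the other to sub-genome B.  Diploid taxa then form one genome group each and
every tetraploid taxon forms two (A and B), giving the genome-group layout
over which diversity and distance statistics are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import pandas as pd

from .genotype import GenotypeTable

logger = logging.getLogger(__name__)


class AssignmentStatus(Enum):
    ASSIGNED = "assigned"
    TIED = "tied"
    SINGLE_PRODUCT = "single_product"
    MISSING = "missing"
    NO_REFERENCE = "no_reference"


@dataclass(frozen=True)
class SubgenomeAssignment:
    """A/B allele-size slots for one tetraploid call."""

    a: Optional[int]
    b: Optional[int]
    status: AssignmentStatus


@dataclass
class ReferenceProfile:
    """Per-marker allele-size sets observed in the reference-anchor taxon."""

    ref_taxon: str
    sizes: dict[str, frozenset[int]]
    markers_without_reference: list[str]


@dataclass
class PartitionedTable:
    """A genotype table plus sub-genome assignments of all tetraploid calls."""

    base: GenotypeTable
    ref_taxon: str
    assignments: dict[tuple[str, str], SubgenomeAssignment]

    def status_counts(self) -> dict[AssignmentStatus, int]:
        counts = {s: 0 for s in AssignmentStatus}
        for a in self.assignments.values():
            counts[a.status] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "accession_id": acc, "marker_id": mk,
                "allele_A": "" if a.a is None else a.a,
                "allele_B": "" if a.b is None else a.b,
                "status": a.status.value,
            }
            for (acc, mk), a in sorted(self.assignments.items())
        ]
        return pd.DataFrame(
            rows, columns=["accession_id", "marker_id", "allele_A", "allele_B", "status"]
        )


@dataclass(frozen=True)
class GenomeGroup:
    """One (sub-)genome group: a diploid taxon, or one sub-genome of a
    tetraploid taxon, optionally restricted to a labelled sub-group."""

    group_id: str
    taxon: str
    subgenome: Optional[str] = None  # "A" or "B" for tetraploids
    subtaxon_label: Optional[str] = None
    member_accessions: tuple[str, ...] = ()


def reference_profile(table: GenotypeTable, ref_taxon: str) -> ReferenceProfile:
    """Allele sizes observed per marker in the reference-anchor taxon.

    Only diploid taxa may anchor the partition.
    """
    accs = table.accessions_of_taxon(ref_taxon)
    if not accs:
        raise ValueError(f"reference taxon {ref_taxon!r} has no accessions")
    if any(a.ploidy != 2 for a in accs):
        raise ValueError(f"reference taxon {ref_taxon!r} must be diploid")
    sizes: dict[str, frozenset[int]] = {}
    missing: list[str] = []
    for mk in table.marker_ids:
        observed = {
            s for a in accs for s in table.sizes(a.accession_id, mk)
        }
        if observed:
            sizes[mk] = frozenset(observed)
        else:
            missing.append(mk)
    return ReferenceProfile(ref_taxon, sizes, missing)


def partition_call(
    products: Sequence[int], ref_sizes: frozenset[int] | set[int]
) -> SubgenomeAssignment:
    """Assign two discrete products to sub-genomes by nearest reference allele.

    The product with the smaller minimum bp distance to the reference pool is
    sub-genome A.  Equal distances give status TIED with the smaller size in
    slot A (deterministic fallback, never silent).  A single product fills
    both slots with status SINGLE_PRODUCT.
    """
    if not ref_sizes:
        raise ValueError("reference allele set is empty")
    products = sorted(set(products))
    if len(products) == 0:
        return SubgenomeAssignment(None, None, AssignmentStatus.MISSING)
    if len(products) == 1:
        s = products[0]
        return SubgenomeAssignment(s, s, AssignmentStatus.SINGLE_PRODUCT)
    if len(products) > 2:
        raise ValueError(f"expected at most two discrete products, got {products}")
    s1, s2 = products
    d1 = min(abs(s1 - r) for r in ref_sizes)
    d2 = min(abs(s2 - r) for r in ref_sizes)
    if d1 < d2:
        return SubgenomeAssignment(s1, s2, AssignmentStatus.ASSIGNED)
    if d2 < d1:
        return SubgenomeAssignment(s2, s1, AssignmentStatus.ASSIGNED)
    return SubgenomeAssignment(s1, s2, AssignmentStatus.TIED)


def partition_table(table: GenotypeTable, ref_taxon: str) -> PartitionedTable:
    """Partition every tetraploid call of the table; diploid calls pass
    through untouched.  Markers with no reference data get NO_REFERENCE for
    all tetraploid calls (excluded from partitioned statistics downstream).

    Tetraploid calls with more than two discrete products are recorded as
    MISSING (such markers fail selection and should not reach this stage).
    """
    tetras = table.tetraploid_accessions()
    if not tetras:
        raise ValueError("table contains no tetraploid accessions")
    profile = reference_profile(table, ref_taxon)
    assignments: dict[tuple[str, str], SubgenomeAssignment] = {}
    for acc in tetras:
        for mk in table.marker_ids:
            key = (acc.accession_id, mk)
            ref = profile.sizes.get(mk)
            if ref is None:
                assignments[key] = SubgenomeAssignment(
                    None, None, AssignmentStatus.NO_REFERENCE
                )
                continue
            products = table.products(acc.accession_id, mk)
            if len(products) > 2:
                logger.warning(
                    ">2 discrete products at %s; recorded missing", key
                )
                assignments[key] = SubgenomeAssignment(
                    None, None, AssignmentStatus.MISSING
                )
            else:
                assignments[key] = partition_call(products, ref)
    part = PartitionedTable(table, ref_taxon, assignments)
    counts = part.status_counts()
    if counts[AssignmentStatus.TIED]:
        logger.info("%d tied sub-genome assignments", counts[AssignmentStatus.TIED])
    return part


def build_genome_groups(
    table: GenotypeTable,
    subgroup_labels: Optional[Mapping[str, str]] = None,
) -> list[GenomeGroup]:
    """One group per diploid taxon, two (A and B) per tetraploid taxon.

    ``subgroup_labels`` (accession_id -> label) splits the labelled taxa into
    one group per label, e.g. dividing a diploid species complex into three
    sub-taxa; supplied from configuration or prior ordination inspection,
    never inferred here.  Group ids are stable and sorted by
    (taxon, label, subgenome).
    """
    if subgroup_labels:
        unknown = set(subgroup_labels) - set(table.accession_ids)
        if unknown:
            raise ValueError(f"subgroup labels reference unknown accessions: {sorted(unknown)}")
    groups: list[GenomeGroup] = []
    for taxon in sorted(table.taxa()):
        accs = table.accessions_of_taxon(taxon)
        ploidy = accs[0].ploidy
        labels: dict[Optional[str], list[str]] = {}
        for a in accs:
            lab = subgroup_labels.get(a.accession_id) if subgroup_labels else None
            labels.setdefault(lab, []).append(a.accession_id)
        has_labels = any(lab is not None for lab in labels)
        for lab in sorted(labels, key=lambda x: (x is None, x or "")):
            members = tuple(labels[lab])
            base = taxon if lab is None else f"{taxon} ({lab})"
            if not has_labels:
                base = taxon
            if ploidy == 4:
                for sub in ("A", "B"):
                    groups.append(GenomeGroup(
                        group_id=f"{base} ({sub})", taxon=taxon, subgenome=sub,
                        subtaxon_label=lab, member_accessions=members,
                    ))
            else:
                groups.append(GenomeGroup(
                    group_id=base, taxon=taxon, subgenome=None,
                    subtaxon_label=lab, member_accessions=members,
                ))
    return groups


def groups_frame(groups: Sequence[GenomeGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_id": g.group_id, "taxon": g.taxon,
                "subgenome": g.subgenome or "",
                "subtaxon_label": g.subtaxon_label or "",
                "n_accessions": len(g.member_accessions),
                "member_accessions": ";".join(g.member_accessions),
            }
            for g in groups
        ]
    )
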