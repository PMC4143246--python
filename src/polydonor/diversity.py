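"""Multi-allelic diversity statistics per genome group and per locus.

Gene diversity (expected heterozygosity) H = 1 - sum p_i^2; polymorphic
information content PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2 (the
Botstein convention); observed heterozygosity as the fraction of two-allele
calls with distinct sizes; and allelic richness by hypergeometric
rarefaction to a standard number of gene copies g.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .genotype import AlleleFrequencySpectrum, GenotypeTable, allele_frequencies
from .partition import AssignmentStatus, GenomeGroup, PartitionedTable

logger = logging.getLogger(__name__)


def gene_diversity(spectrum: AlleleFrequencySpectrum, unbiased: bool = False) -> float:
    """1 - sum p_i^2; the ``unbiased`` flag applies the n/(n-1) small-sample
    correction with n = gene copies counted."""
    if spectrum.is_empty:
        raise ValueError("gene diversity undefined for an empty spectrum")
    h = 1.0 - sum(p * p for p in spectrum.freqs.values())
    if unbiased:
        n = spectrum.n_copies
        if n < 2:
            raise ValueError("unbiased gene diversity needs n_copies >= 2")
        h *= n / (n - 1)
    return h


def pic(spectrum: AlleleFrequencySpectrum) -> float:
    """Polymorphic information content, 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    if spectrum.is_empty:
        raise ValueError("PIC undefined for an empty spectrum")
    ps = list(spectrum.freqs.values())
    cross = sum(2.0 * pi * pi * pj * pj for pi, pj in combinations(ps, 2))
    return 1.0 - sum(p * p for p in ps) - cross


def observed_heterozygosity(
    table: GenotypeTable, group: Iterable[str], marker_id: str
) -> Optional[float]:
    """Fraction of non-missing calls in the group with two distinct allele
    sizes.  Needs two-allele coding to be informative: under single-allele
    scoring every call is one size and the result is 0.  Returns None when
    the group has no data at the marker."""
    n = 0
    het = 0
    for acc in group:
        sizes = table.sizes(acc, marker_id)
        if not sizes:
            continue
        n += 1
        if len(set(sizes)) > 1:
            het += 1
    if n == 0:
        return None
    return het / n


def allelic_richness(allele_copy_counts: Mapping[object, int], g: int) -> float:
    """Expected number of distinct alleles in a random draw of g gene copies
    (without replacement) from the observed copies: hypergeometric
    rarefaction, sum_i [1 - C(N - N_i, g) / C(N, g)]."""
    if g < 1:
        raise ValueError("rarefaction size g must be >= 1")
    counts = [c for c in allele_copy_counts.values() if c > 0]
    n_total = sum(counts)
    if g > n_total:
        raise ValueError(f"g = {g} exceeds total copies N = {n_total}")
    denom = comb(n_total, g)
    return float(sum(1 - comb(n_total - ni, g) / denom for ni in counts))


# ---------------------------------------------------------------------------
# Group spectra (diploid groups from calls, tetraploid groups from slots)
# ---------------------------------------------------------------------------

_COUNTED = (AssignmentStatus.ASSIGNED, AssignmentStatus.TIED)


def group_spectrum(
    group: GenomeGroup,
    table: GenotypeTable,
    marker_id: str,
    partitioned: Optional[PartitionedTable] = None,
    copies_per_call: int = 1,
    include_single_product: bool = False,
) -> AlleleFrequencySpectrum:
    """Allele-frequency spectrum of one genome group at one marker.

    Diploid groups count copies from their calls (see
    :func:`polydonor.genotype.allele_frequencies`).  Tetraploid sub-genome
    groups count one copy per accession from the matching A/B slot of the
    partition; single-product calls (both homoeologs at one size, or allele
    dropout) are excluded unless ``include_single_product``.
    """
    if group.subgenome is None:
        return allele_frequencies(
            table, group.member_accessions, marker_id,
            copies_per_call=copies_per_call, group_id=group.group_id,
        )
    if partitioned is None:
        raise ValueError(
            f"group {group.group_id!r} is a tetraploid sub-genome; "
            "a PartitionedTable is required"
        )
    statuses = _COUNTED + ((AssignmentStatus.SINGLE_PRODUCT,) if include_single_product else ())
    counts: dict[int, int] = {}
    n = 0
    for acc in group.member_accessions:
        asg = partitioned.assignments.get((acc, marker_id))
        if asg is None or asg.status not in statuses:
            continue
        size = asg.a if group.subgenome == "A" else asg.b
        if size is None:
            continue
        counts[size] = counts.get(size, 0) + 1
        n += 1
    if n == 0:
        return AlleleFrequencySpectrum(group.group_id, marker_id, {}, 0)
    freqs = {s: c / n for s, c in sorted(counts.items())}
    return AlleleFrequencySpectrum(group.group_id, marker_id, freqs, n)


def group_spectra(
    groups: Sequence[GenomeGroup],
    table: GenotypeTable,
    partitioned: Optional[PartitionedTable] = None,
    copies_per_call: int = 1,
    include_single_product: bool = False,
) -> dict[tuple[str, str], AlleleFrequencySpectrum]:
    """Spectra for every (group, marker) pair; empty spectra included."""
    return {
        (g.group_id, mk): group_spectrum(
            g, table, mk, partitioned=partitioned,
            copies_per_call=copies_per_call,
            include_single_product=include_single_product,
        )
        for g in groups
        for mk in table.marker_ids
    }


def _copy_counts(spec: AlleleFrequencySpectrum) -> dict[int, int]:
    return {
        s: round(p * spec.n_copies) for s, p in spec.freqs.items()
    }


def rarefaction_sizes(
    spectra: Mapping[tuple[str, str], AlleleFrequencySpectrum],
    groups: Sequence[GenomeGroup],
    marker_ids: Sequence[str],
) -> dict[str, int]:
    """Default per-locus rarefaction size: the smallest per-group copy count
    at the locus across all groups with data (rarefaction-to-minimum, the
    only choice that makes the per-group columns comparable).  Loci with no
    data anywhere are omitted."""
    out: dict[str, int] = {}
    for mk in marker_ids:
        counts = [
            spectra[(g.group_id, mk)].n_copies
            for g in groups
            if spectra[(g.group_id, mk)].n_copies > 0
        ]
        if counts:
            out[mk] = min(counts)
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class DiversitySummary:
    """Per-group diversity row (the per-genome summary table)."""

    group_id: str
    n_accessions: int
    n_loci_typed: int
    n_alleles: int
    gene_diversity: float
    observed_heterozygosity: float
    mean_pic: float
    mean_allelic_richness: Optional[float]


def _mean(values: list[float]) -> float:
    return sum(values) / len(values) if values else float("nan")


def group_summary(
    groups: Sequence[GenomeGroup],
    table: GenotypeTable,
    partitioned: Optional[PartitionedTable] = None,
    copies_per_call: int = 1,
    unbiased: bool = False,
    rarefaction_g: Optional[Mapping[str, int]] = None,
    include_overall: bool = True,
) -> pd.DataFrame:
    """Per-group diversity summary plus an overall row over the pooled set.

    Per group: accessions, loci typed, distinct (marker, size) pairs, mean
    gene diversity, mean observed heterozygosity (0 for tetraploid
    sub-genome groups, which carry one allele slot per accession), mean PIC
    and mean rarefied allelic richness over loci.  Loci monomorphic within a
    group contribute H = PIC = 0; loci with no data in the group are
    excluded from the means.  The overall row pools all groups' gene copies.
    """
    marker_ids = table.marker_ids
    spectra = group_spectra(
        groups, table, partitioned=partitioned, copies_per_call=copies_per_call
    )
    if rarefaction_g is None:
        rarefaction_g = rarefaction_sizes(spectra, groups, marker_ids)

    def summarize(
        gid: str, n_acc: int,
        specs: Mapping[str, AlleleFrequencySpectrum],
        ho_values: list[float],
    ) -> DiversitySummary:
        nonempty = {mk: s for mk, s in specs.items() if not s.is_empty}
        h_vals = [gene_diversity(s, unbiased=unbiased) for s in nonempty.values()]
        pic_vals = [pic(s) for s in nonempty.values()]
        rich_vals = []
        for mk, s in nonempty.items():
            g = rarefaction_g.get(mk)
            if g is not None and s.n_copies >= g:
                rich_vals.append(allelic_richness(_copy_counts(s), g))
        n_alleles = sum(len(s.freqs) for s in nonempty.values())
        return DiversitySummary(
            group_id=gid,
            n_accessions=n_acc,
            n_loci_typed=len(nonempty),
            n_alleles=n_alleles,
            gene_diversity=_mean(h_vals),
            observed_heterozygosity=_mean(ho_values),
            mean_pic=_mean(pic_vals),
            mean_allelic_richness=_mean(rich_vals) if rich_vals else None,
        )

    rows: list[DiversitySummary] = []
    for g in groups:
        specs = {mk: spectra[(g.group_id, mk)] for mk in marker_ids}
        if g.subgenome is None:
            ho = [
                v
                for mk in marker_ids
                for v in [observed_heterozygosity(table, g.member_accessions, mk)]
                if v is not None
            ]
        else:
            # one allele slot per accession: heterozygosity not observable
            ho = [0.0 for mk in marker_ids if not specs[mk].is_empty]
        rows.append(summarize(g.group_id, len(g.member_accessions), specs, ho))

    if include_overall:
        # pooled spectra: sum gene-copy counts over groups per marker
        pooled: dict[str, AlleleFrequencySpectrum] = {}
        for mk in marker_ids:
            counts: dict[int, int] = {}
            n = 0
            for g in groups:
                s = spectra[(g.group_id, mk)]
                for size, c in _copy_counts(s).items():
                    counts[size] = counts.get(size, 0) + c
                n += s.n_copies
            if n:
                pooled[mk] = AlleleFrequencySpectrum(
                    "Total", mk, {s: c / n for s, c in sorted(counts.items())}, n
                )
            else:
                pooled[mk] = AlleleFrequencySpectrum("Total", mk, {}, 0)
        total_acc = sum(len(g.member_accessions) for g in groups)
        all_ho = []
        for g in groups:
            if g.subgenome is None:
                for mk in marker_ids:
                    v = observed_heterozygosity(table, g.member_accessions, mk)
                    if v is not None:
                        all_ho.append(v)
            else:
                all_ho.extend(
                    0.0 for mk in marker_ids
                    if not spectra[(g.group_id, mk)].is_empty
                )
        rows.append(summarize("Total", total_acc, pooled, all_ho))

    df = pd.DataFrame(
        [
            {
                "group_id": r.group_id,
                "n_accessions": r.n_accessions,
                "n_loci_typed": r.n_loci_typed,
                "n_alleles": r.n_alleles,
                "gene_diversity": r.gene_diversity,
                "observed_heterozygosity": r.observed_heterozygosity,
                "mean_PIC": r.mean_pic,
                "mean_allelic_richness": r.mean_allelic_richness,
            }
            for r in rows
        ]
    )
    return df


def locus_summary(
    groups: Sequence[GenomeGroup],
    table: GenotypeTable,
    partitioned: Optional[PartitionedTable] = None,
    copies_per_call: int = 1,
    rarefaction_g: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Per-locus row: total distinct alleles, size range (min-max and span),
    then PIC and rarefied allelic richness per genome group and overall."""
    marker_ids = table.marker_ids
    spectra = group_spectra(
        groups, table, partitioned=partitioned, copies_per_call=copies_per_call
    )
    if rarefaction_g is None:
        rarefaction_g = rarefaction_sizes(spectra, groups, marker_ids)
    rows = []
    for mk in marker_ids:
        sizes: set[int] = set()
        pooled_counts: dict[int, int] = {}
        n_pooled = 0
        for g in groups:
            s = spectra[(g.group_id, mk)]
            sizes.update(s.freqs)
            for size, c in _copy_counts(s).items():
                pooled_counts[size] = pooled_counts.get(size, 0) + c
            n_pooled += s.n_copies
        row: dict[str, object] = {
            "marker_id": mk,
            "n_alleles": len(sizes),
            "size_min": min(sizes) if sizes else None,
            "size_max": max(sizes) if sizes else None,
            "size_span": (max(sizes) - min(sizes)) if sizes else None,
        }
        g_rar = rarefaction_g.get(mk)
        for g in groups:
            s = spectra[(g.group_id, mk)]
            row[f"PIC ({g.group_id})"] = pic(s) if not s.is_empty else None
            ok = not s.is_empty and g_rar is not None and s.n_copies >= g_rar
            row[f"richness ({g.group_id})"] = (
                allelic_richness(_copy_counts(s), g_rar) if ok else None
            )
        if n_pooled:
            pooled = AlleleFrequencySpectrum(
                "Overall", mk,
                {s: c / n_pooled for s, c in sorted(pooled_counts.items())},
                n_pooled,
            )
            row["PIC (overall)"] = pic(pooled)
            row["richness (overall)"] = (
                allelic_richness(pooled_counts, g_rar) if g_rar is not None else None
            )
        else:
            row["PIC (overall)"] = None
            row["richness (overall)"] = None
        rows.append(row)
    return pd.DataFrame(rows)
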