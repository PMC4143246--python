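"""End-to-end donor-identification pipeline.

Genotype table -> marker selection -> sub-genome partition -> genome groups
-> diversity tables -> DA matrices -> NJ trees with bootstrap -> PCoA ->
donor report.  Every stage writes a plain-text artifact into the output
directory and the run is reproducible from (input, config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .distance import (
    DistanceMatrix,
    individual_spectra,
    pairwise_da,
    spectra_of_groups,
)
from .diversity import group_spectra, group_summary, locus_summary
from .genotype import (
    DEFAULT_RFU_WINDOW,
    GenotypeTable,
    MarkerCategory,
    selection_report,
)
from .ordination import PCoAResult, pcoa
from .partition import (
    AssignmentStatus,
    GenomeGroup,
    PartitionedTable,
    build_genome_groups,
    groups_frame,
    partition_table,
)
from .trees import bootstrap_support, write_newick

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration (flat key-value; loadable from YAML)."""

    reference_taxon: str
    copies_per_call: int = 1
    binning_tolerance: int = 0
    size_cap: int = 500
    rfu_window: tuple[float, float] = DEFAULT_RFU_WINDOW
    bootstrap_individual: int = 1000
    bootstrap_group: int = 400
    pcoa_axes: int = 3
    seed: int = 0
    subgroup_labels: Optional[dict[str, str]] = None
    include_single_product: bool = False
    #: optional taxon -> ploidy declaration; when given, accession ploidies
    #: are validated against it on ingest
    taxa_ploidy: Optional[dict[str, int]] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "rfu_window" in raw:
            raw["rfu_window"] = tuple(raw["rfu_window"])
        return cls(**raw)

    def echo(self) -> dict:
        d = dict(self.__dict__)
        d["rfu_window"] = list(self.rfu_window)
        return d


@dataclass
class DonorCall:
    """Nearest diploid group by DA for one tetraploid sub-genome group."""

    subgenome_group: str
    ranking: list[tuple[str, float]]  # (diploid group, DA) ascending
    call: Optional[str]
    margin: Optional[float]
    ranking_excluding_anchor: list[tuple[str, float]]


@dataclass
class DonorReport:
    anchor_taxon: str
    calls: list[DonorCall]
    tie_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "anchor_taxon": self.anchor_taxon,
            "tie_counts": self.tie_counts,
            "calls": [
                {
                    "subgenome_group": c.subgenome_group,
                    "call": c.call,
                    "margin": c.margin,
                    "ranking": [[g, round(v, 6)] for g, v in c.ranking],
                    "ranking_excluding_anchor": [
                        [g, round(v, 6)] for g, v in c.ranking_excluding_anchor
                    ],
                }
                for c in self.calls
            ],
        }


@dataclass
class PipelineResult:
    table: GenotypeTable
    selection: object
    partitioned: Optional[PartitionedTable]
    groups: list[GenomeGroup]
    group_table: pd.DataFrame
    locus_table: pd.DataFrame
    da_individual: DistanceMatrix
    da_groups: Optional[DistanceMatrix]
    tree_individual: object
    tree_groups: object
    pcoa_result: PCoAResult
    donor_report: Optional[DonorReport]
    timings: dict[str, float] = field(default_factory=dict)


def subset_markers(table: GenotypeTable, marker_ids) -> GenotypeTable:
    keep = set(marker_ids)
    markers = [m for m in table.markers if m.marker_id in keep]
    calls = {k: v for k, v in table.calls.items() if k[1] in keep}
    return GenotypeTable(table.accessions, markers, calls)


def donor_call(
    dm: DistanceMatrix,
    subgenome_group_ids: list[str],
    diploid_group_ids: list[str],
    anchor_group_ids: Optional[list[str]] = None,
    tie_counts: Optional[Mapping[str, int]] = None,
    anchor_taxon: str = "",
) -> DonorReport:
    """Rank diploid groups by DA for each tetraploid sub-genome group.

    The call is the nearest diploid group; on an exact tie both are listed
    and the call is None.  A second ranking excluding the anchor taxon's
    group(s) is reported to surface any anchor-induced circularity.
    """
    for gid in subgenome_group_ids + diploid_group_ids:
        if gid not in dm.labels:
            raise ValueError(f"group {gid!r} missing from distance matrix")
    anchor_group_ids = anchor_group_ids or []
    calls = []
    for sub in subgenome_group_ids:
        ranking = sorted(
            ((d, dm.value(sub, d)) for d in diploid_group_ids),
            key=lambda t: (t[1], t[0]),
        )
        if len(ranking) > 1 and ranking[0][1] == ranking[1][1]:
            call_g, margin = None, None
        else:
            call_g = ranking[0][0]
            margin = ranking[1][1] - ranking[0][1] if len(ranking) > 1 else None
        excl = [t for t in ranking if t[0] not in anchor_group_ids]
        calls.append(DonorCall(
            subgenome_group=sub, ranking=ranking, call=call_g,
            margin=margin, ranking_excluding_anchor=excl,
        ))
    return DonorReport(
        anchor_taxon=anchor_taxon, calls=calls, tie_counts=dict(tie_counts or {}),
    )


def _write_matrix(dm: DistanceMatrix, path: Path, within: Optional[dict] = None) -> None:
    df = dm.to_frame().copy()
    if within:
        for gid, v in within.items():
            if gid in df.index:
                df.loc[gid, gid] = v
    df.to_csv(path, sep="\t", float_format="%.6f")


def run_pipeline(
    table: GenotypeTable, config: PipelineConfig, outdir
) -> PipelineResult:
    """Run every analysis stage and write all artifacts under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("polydonor")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc_type is not None:
                    logger.error("stage %s: FAILED (%s)", name, exc)
                    return False
                logger.info("stage %s: done in %.2fs", name, timings[name])
                return False

        return _T()

    try:
        with stage("ingest"):
            if config.taxa_ploidy:
                for a in table.accessions:
                    declared = config.taxa_ploidy.get(a.taxon)
                    if declared is not None and declared != a.ploidy:
                        raise ValueError(
                            f"accession {a.accession_id!r}: ploidy {a.ploidy} "
                            f"but taxon {a.taxon!r} is declared {declared}"
                        )
            table = table.filter_peak_heights(config.rfu_window)
            if config.binning_tolerance:
                table = table.round_sizes(config.binning_tolerance)
            has_tetraploids = bool(table.tetraploid_accessions())
            sel_view = table.scored() if config.copies_per_call == 1 else table

        with stage("marker_selection"):
            sel = selection_report(sel_view, size_cap=config.size_cap)
            sel.per_marker.to_csv(out / "selection.tsv", sep="\t", index=False)
            if has_tetraploids:
                passing = sel.passing
            else:
                passing = [
                    m for m in table.marker_ids
                    if sel.per_marker.set_index("marker_id").loc[m, "category"]
                    in (MarkerCategory.POLYMORPHIC_DIPLOID.name,
                        MarkerCategory.MONOMORPHIC.name)
                ]
            logger.info(
                "marker selection: %d/%d markers pass",
                len(passing), len(table.marker_ids),
            )
            if not passing:
                raise ValueError("no markers pass selection")
            work = subset_markers(table, passing)

        partitioned = None
        if has_tetraploids:
            with stage("partition"):
                partitioned = partition_table(work, config.reference_taxon)
                partitioned.to_frame().to_csv(
                    out / "partition.tsv", sep="\t", index=False
                )
                counts = partitioned.status_counts()
                logger.info(
                    "partition statuses: %s",
                    {s.value: c for s, c in counts.items() if c},
                )
        else:
            logger.info(
                "no tetraploid accessions: partition and donor stages skipped"
            )

        with stage("groups"):
            groups = build_genome_groups(work, config.subgroup_labels)
            groups_frame(groups).to_csv(out / "groups.tsv", sep="\t", index=False)

        with stage("diversity"):
            gtab = group_summary(
                groups, work, partitioned=partitioned,
                copies_per_call=config.copies_per_call,
            )
            gtab.to_csv(out / "group_summary.tsv", sep="\t", index=False,
                        float_format="%.4f")
            ltab = locus_summary(
                groups, work, partitioned=partitioned,
                copies_per_call=config.copies_per_call,
            )
            ltab.to_csv(out / "locus_summary.tsv", sep="\t", index=False,
                        float_format="%.3f")

        with stage("distances_individual"):
            ind_spectra = individual_spectra(
                work, partitioned, include_single_product=config.include_single_product
            )
            da_ind = pairwise_da(ind_spectra, on_missing_pair="max")
            da_ind.to_frame().to_csv(out / "da_individual.tsv", sep="\t",
                                     float_format="%.6f")
            da_ind.r_frame().to_csv(out / "da_individual_r.tsv", sep="\t")

        with stage("tree_individual"):
            rng = np.random.default_rng([config.seed, 1])
            tree_ind, _ = bootstrap_support(
                ind_spectra, n_reps=config.bootstrap_individual, rng=rng
            )
            write_newick(tree_ind, out / "tree_individual.nwk")

        da_grp = None
        tree_grp = None
        with stage("distances_groups"):
            gspectra = group_spectra(
                groups, work, partitioned=partitioned,
                copies_per_call=config.copies_per_call,
                include_single_product=config.include_single_product,
            )
            by_group = spectra_of_groups(gspectra)
            da_grp = pairwise_da(by_group, on_missing_pair="max")
            # published convention: the diagonal of the group report shows
            # the mean pairwise individual-level DA within the group
            within = {}
            idx = {lab: i for i, lab in enumerate(da_ind.labels)}
            for g in groups:
                if g.subgenome is None:
                    members = [m for m in g.member_accessions if m in idx]
                else:
                    members = [
                        f"{m} ({g.subgenome})" for m in g.member_accessions
                        if f"{m} ({g.subgenome})" in idx
                    ]
                ii = [idx[m] for m in members]
                if len(ii) > 1:
                    sub = da_ind.d[np.ix_(ii, ii)]
                    within[g.group_id] = float(
                        sub[np.triu_indices(len(ii), k=1)].mean()
                    )
            _write_matrix(da_grp, out / "da_groups.tsv", within=within)
            da_grp.r_frame().to_csv(out / "da_groups_r.tsv", sep="\t")

        with stage("tree_groups"):
            if len(da_grp.labels) >= 3:
                rng = np.random.default_rng([config.seed, 2])
                tree_grp, _ = bootstrap_support(
                    by_group, n_reps=config.bootstrap_group, rng=rng
                )
                write_newick(tree_grp, out / "tree_groups.nwk")
            else:
                logger.info("fewer than 3 groups: group tree skipped")

        with stage("pcoa"):
            k = min(config.pcoa_axes, len(da_ind.labels) - 1)
            pres = pcoa(da_ind, k=k)
            pres.to_frame().to_csv(out / "pcoa_coordinates.tsv", sep="\t",
                                   float_format="%.6f")
            pres.eigen_frame().to_csv(out / "pcoa_eigen.tsv", sep="\t",
                                      float_format="%.6f")
            logger.info(
                "PCoA percent variance (first %d axes): %s",
                k, [round(float(p), 1) for p in pres.percent_variance],
            )

        report = None
        if has_tetraploids:
            with stage("donor_report"):
                sub_ids = [g.group_id for g in groups if g.subgenome is not None]
                dip_ids = [g.group_id for g in groups if g.subgenome is None]
                anchor_ids = [
                    g.group_id for g in groups if g.taxon == config.reference_taxon
                ]
                ties = {
                    "tied_assignments":
                        partitioned.status_counts()[AssignmentStatus.TIED],
                    "single_product":
                        partitioned.status_counts()[AssignmentStatus.SINGLE_PRODUCT],
                }
                report = donor_call(
                    da_grp, sub_ids, dip_ids, anchor_group_ids=anchor_ids,
                    tie_counts=ties, anchor_taxon=config.reference_taxon,
                )
                (out / "donor_report.json").write_text(
                    json.dumps(report.to_dict(), indent=2) + "\n"
                )

        (out / "config_echo.json").write_text(
            json.dumps(config.echo(), indent=2, default=str) + "\n"
        )
        logger.info("timings: %s", {k: round(v, 2) for k, v in timings.items()})
    finally:
        root.removeHandler(handler)
        handler.close()

    return PipelineResult(
        table=table, selection=sel, partitioned=partitioned, groups=groups,
        group_table=gtab, locus_table=ltab, da_individual=da_ind,
        da_groups=da_grp, tree_individual=tree_ind, tree_groups=tree_grp,
        pcoa_result=pres, donor_report=report, timings=timings,
    )
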