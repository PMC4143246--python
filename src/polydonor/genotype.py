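"""Genotype tables for multi-allelic SSR markers.

The central object is :class:`GenotypeTable`: allele-size calls (integer bp)
per accession x marker, with taxon/ploidy metadata.  A *call* is the list of
discrete PCR products recorded for one accession at one marker after fragment
analysis: zero products = missing, one product = a single peak (for a selfing
diploid this is the norm), two products = either a heterozygous diploid or the
two homoeologous products of an allotetraploid.

Also here: CSV I/O in a long and a wide dialect, allele-frequency spectra,
and the marker-quality categorisation used to select markers that amplify one
product in diploids and two discrete products in tetraploids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: default peak-height validity window (relative fluorescence units)
DEFAULT_RFU_WINDOW = (500.0, 10_000.0)


@dataclass(frozen=True)
class AccessionRecord:
    """One plant accession: identifier, taxon, ploidy (2 or 4), provenance."""

    accession_id: str
    taxon: str
    ploidy: int = 2
    subtaxon_label: Optional[str] = None
    origin: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise ValueError(
                f"accession {self.accession_id!r}: unknown ploidy {self.ploidy}"
            )


@dataclass(frozen=True)
class MarkerDef:
    """One SSR marker (primer pair)."""

    marker_id: str
    motif: Optional[str] = None
    expected_size_range: Optional[tuple[int, int]] = None
    fluor_label: Optional[str] = None

    def __post_init__(self) -> None:
        rng = self.expected_size_range
        if rng is not None:
            lo, hi = rng
            if not (90 <= lo <= hi <= 500):
                raise ValueError(
                    f"marker {self.marker_id!r}: expected_size_range {rng} "
                    "must satisfy 90 <= min <= max <= 500"
                )


@dataclass(frozen=True)
class AlleleCall:
    """One scored PCR product: fragment size in bp, optional peak height."""

    size: int
    peak_height: Optional[float] = None

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"allele size must be positive, got {self.size}")

    def height_in_window(self, window: tuple[float, float] = DEFAULT_RFU_WINDOW) -> bool:
        if self.peak_height is None:
            return True
        lo, hi = window
        return lo <= self.peak_height <= hi


Call = tuple[AlleleCall, ...]


@dataclass(frozen=True)
class AlleleFrequencySpectrum:
    """Allele-size -> frequency map for one group at one marker.

    ``n_copies`` is the number of gene copies counted; an empty spectrum with
    ``n_copies == 0`` marks a locus with no data in the group.
    """

    group_id: str
    marker_id: str
    freqs: Mapping[int, float]
    n_copies: int

    def __post_init__(self) -> None:
        if self.freqs:
            total = sum(self.freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"frequencies sum to {total}, not 1 "
                    f"({self.group_id}/{self.marker_id})"
                )
            if any(p <= 0 for p in self.freqs.values()):
                raise ValueError("all frequencies must be positive")
            if self.n_copies < 1:
                raise ValueError("non-empty spectrum requires n_copies >= 1")

    @property
    def is_empty(self) -> bool:
        return not self.freqs


class GenotypeTable:
    """Accession x marker allele-size calls with metadata.

    Calls are stored per ``(accession_id, marker_id)`` as a tuple of
    :class:`AlleleCall`, sorted by ascending size.  Missing cells are simply
    absent from the mapping.
    """

    def __init__(
        self,
        accessions: Sequence[AccessionRecord],
        markers: Sequence[MarkerDef],
        calls: Mapping[tuple[str, str], Sequence[AlleleCall]],
    ) -> None:
        self.accessions = list(accessions)
        self.markers = list(markers)
        acc_ids = [a.accession_id for a in self.accessions]
        if len(set(acc_ids)) != len(acc_ids):
            raise ValueError("duplicate accession_id in table")
        marker_ids = [m.marker_id for m in self.markers]
        if len(set(marker_ids)) != len(marker_ids):
            raise ValueError("duplicate marker_id in table")
        self._acc_index = {a.accession_id: a for a in self.accessions}
        self._marker_index = {m.marker_id: m for m in self.markers}
        self.calls: dict[tuple[str, str], Call] = {}
        for (acc, mk), alleles in calls.items():
            if acc not in self._acc_index:
                raise ValueError(f"call references unknown accession {acc!r}")
            if mk not in self._marker_index:
                raise ValueError(f"call references unknown marker {mk!r}")
            srt = tuple(sorted(alleles, key=lambda a: a.size))
            if srt:
                self.calls[(acc, mk)] = srt
        #: parse warnings accumulated by readers (unparseable cells -> missing)
        self.n_parse_warnings = 0

    # -- lookups ---------------------------------------------------------

    @property
    def accession_ids(self) -> list[str]:
        return [a.accession_id for a in self.accessions]

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def accession(self, accession_id: str) -> AccessionRecord:
        return self._acc_index[accession_id]

    def marker(self, marker_id: str) -> MarkerDef:
        if marker_id not in self._marker_index:
            raise KeyError(f"unknown marker {marker_id!r}")
        return self._marker_index[marker_id]

    def call(self, accession_id: str, marker_id: str) -> Call:
        """The call, or an empty tuple when missing."""
        return self.calls.get((accession_id, marker_id), ())

    def sizes(self, accession_id: str, marker_id: str) -> tuple[int, ...]:
        return tuple(a.size for a in self.call(accession_id, marker_id))

    def products(self, accession_id: str, marker_id: str) -> tuple[int, ...]:
        """Distinct product sizes of a call, ascending."""
        return tuple(sorted(set(self.sizes(accession_id, marker_id))))

    def accessions_of_taxon(self, taxon: str) -> list[AccessionRecord]:
        return [a for a in self.accessions if a.taxon == taxon]

    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.accessions:
            seen.setdefault(a.taxon, None)
        return list(seen)

    def tetraploid_accessions(self) -> list[AccessionRecord]:
        return [a for a in self.accessions if a.ploidy == 4]

    # -- transforms ------------------------------------------------------

    def scored(self) -> "GenotypeTable":
        """Single-allele view: each diploid call reduced to its scored size.

        The scored size is the strongest peak when heights are recorded,
        otherwise the smallest size.  Tetraploid calls pass through unchanged
        (their two products are the two homoeologous loci, not two alleles of
        one locus).
        """
        new_calls: dict[tuple[str, str], Call] = {}
        for (acc, mk), alleles in self.calls.items():
            if self._acc_index[acc].ploidy == 2 and len(alleles) > 1:
                if any(a.peak_height is not None for a in alleles):
                    best = max(
                        alleles,
                        key=lambda a: (
                            a.peak_height if a.peak_height is not None else -1.0,
                            -a.size,
                        ),
                    )
                else:
                    best = alleles[0]
                new_calls[(acc, mk)] = (best,)
            else:
                new_calls[(acc, mk)] = alleles
        out = GenotypeTable(self.accessions, self.markers, new_calls)
        return out

    def filter_peak_heights(
        self, window: tuple[float, float] = DEFAULT_RFU_WINDOW
    ) -> "GenotypeTable":
        """Drop alleles whose recorded peak height falls outside the validity
        window (default 500-10,000 RFU); heightless alleles are kept.  Calls
        left with no alleles become missing."""
        new_calls = {
            key: kept
            for key, alleles in self.calls.items()
            if (kept := tuple(a for a in alleles if a.height_in_window(window)))
        }
        return GenotypeTable(self.accessions, self.markers, new_calls)

    def round_sizes(self, binning_tolerance: int = 0) -> "GenotypeTable":
        """Merge allele sizes within +/- tolerance bp to the modal size.

        Tolerance 0 is the identity.  Binning is per marker, over the pooled
        size distribution, greedily from the most frequent size outward.
        """
        if binning_tolerance <= 0:
            return self
        mapping: dict[tuple[str, int], int] = {}
        for mk in self.marker_ids:
            counts: dict[int, int] = {}
            for acc in self.accession_ids:
                for a in self.call(acc, mk):
                    counts[a.size] = counts.get(a.size, 0) + 1
            for size in sorted(counts, key=lambda s: (-counts[s], s)):
                if (mk, size) in mapping:
                    continue
                for other in sorted(counts):
                    if (mk, other) not in mapping and abs(other - size) <= binning_tolerance:
                        mapping[(mk, other)] = size
        new_calls = {
            key: tuple(replace(a, size=mapping[(key[1], a.size)]) for a in alleles)
            for key, alleles in self.calls.items()
        }
        return GenotypeTable(self.accessions, self.markers, new_calls)

    # -- equality --------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.accessions == other.accessions
            and self.markers == other.markers
            and self.calls == other.calls
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeTable({len(self.accessions)} accessions, "
            f"{len(self.markers)} markers, {len(self.calls)} calls)"
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_LONG_META = ["accession_id", "taxon", "ploidy", "marker_id"]
_WIDE_META = ["accession_id", "taxon", "ploidy"]
_OPT_META = ["subtaxon_label", "origin"]


def _parse_size(value: object) -> Optional[int]:
    """Integer bp from a CSV cell; None for blank/unparseable."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    try:
        return int(round(float(s)))
    except ValueError:
        return None


def read_genotype_table(path, dialect: str = "long") -> GenotypeTable:
    """Read a genotype CSV.

    Long dialect: one row per (accession, marker) with columns
    ``accession_id, taxon, ploidy, marker_id, allele1[, allele2, peak1, peak2]``.
    Wide dialect: one row per accession with ``accession_id, taxon, ploidy``
    followed by two columns per marker named ``<marker>_1, <marker>_2``;
    blank cells are missing.  Optional metadata columns ``subtaxon_label``
    and ``origin`` are honoured in both dialects.
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    n_warnings = 0

    def meta_of(row, acc_id: str) -> AccessionRecord:
        try:
            ploidy = int(row["ploidy"])
        except ValueError as exc:
            raise ValueError(f"accession {acc_id!r}: unknown ploidy {row['ploidy']!r}") from exc
        return AccessionRecord(
            accession_id=acc_id,
            taxon=row["taxon"],
            ploidy=ploidy,
            subtaxon_label=(row.get("subtaxon_label") or None),
            origin=(row.get("origin") or None),
        )

    accessions: dict[str, AccessionRecord] = {}
    calls: dict[tuple[str, str], list[AlleleCall]] = {}

    if dialect == "long":
        missing_cols = [c for c in _LONG_META + ["allele1"] if c not in df.columns]
        if missing_cols:
            raise ValueError(f"long dialect requires columns {missing_cols}")
        markers: dict[str, MarkerDef] = {}
        for _, row in df.iterrows():
            acc_id = row["accession_id"]
            rec = meta_of(row, acc_id)
            if acc_id in accessions and accessions[acc_id] != rec:
                raise ValueError(f"conflicting metadata for accession {acc_id!r}")
            accessions.setdefault(acc_id, rec)
            mk = row["marker_id"]
            markers.setdefault(mk, MarkerDef(mk))
            alleles: list[AlleleCall] = []
            for a_col, p_col in (("allele1", "peak1"), ("allele2", "peak2")):
                raw = row.get(a_col, "")
                size = _parse_size(raw)
                if size is None:
                    if str(raw).strip():
                        n_warnings += 1
                        logger.warning(
                            "unparseable allele cell %r at (%s, %s); recorded missing",
                            raw, acc_id, mk,
                        )
                    continue
                peak_raw = str(row.get(p_col, "")).strip()
                peak = float(peak_raw) if peak_raw else None
                alleles.append(AlleleCall(size, peak))
            key = (acc_id, mk)
            new = sorted(alleles, key=lambda a: a.size)
            if key in calls:
                if calls[key] != new:
                    raise ValueError(
                        f"duplicate rows for {key} with conflicting sizes"
                    )
            elif new:
                calls[key] = new
        table = GenotypeTable(list(accessions.values()), list(markers.values()), calls)
    else:
        missing_cols = [c for c in _WIDE_META if c not in df.columns]
        if missing_cols:
            raise ValueError(f"wide dialect requires columns {missing_cols}")
        allele_cols = [
            c for c in df.columns if c not in _WIDE_META + _OPT_META
        ]
        marker_ids: list[str] = []
        for c in allele_cols:
            if not (c.endswith("_1") or c.endswith("_2")):
                raise ValueError(f"wide dialect: unexpected column {c!r}")
            mk = c[:-2]
            if mk not in marker_ids:
                marker_ids.append(mk)
        for _, row in df.iterrows():
            acc_id = row["accession_id"]
            if acc_id in accessions:
                raise ValueError(f"duplicate accession row {acc_id!r}")
            accessions[acc_id] = meta_of(row, acc_id)
            for mk in marker_ids:
                alleles = []
                for suffix in ("_1", "_2"):
                    raw = row.get(mk + suffix, "")
                    size = _parse_size(raw)
                    if size is None:
                        if str(raw).strip():
                            n_warnings += 1
                            logger.warning(
                                "unparseable allele cell %r at (%s, %s)",
                                raw, acc_id, mk,
                            )
                        continue
                    alleles.append(AlleleCall(size))
                if alleles:
                    calls[(acc_id, mk)] = alleles
        table = GenotypeTable(
            list(accessions.values()), [MarkerDef(m) for m in marker_ids], calls
        )
    table.n_parse_warnings = n_warnings
    return table


def write_genotype_table(table: GenotypeTable, path, dialect: str = "long") -> None:
    """Write a genotype CSV; inverse of :func:`read_genotype_table`.

    The wide dialect drops peak heights and any third-or-later allele of a
    call (it has two slots per marker); use the long dialect for lossless
    round trips of such tables.
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    has_sub = any(a.subtaxon_label for a in table.accessions)
    has_origin = any(a.origin for a in table.accessions)

    def meta_cells(a: AccessionRecord) -> dict[str, object]:
        row: dict[str, object] = {
            "accession_id": a.accession_id,
            "taxon": a.taxon,
            "ploidy": a.ploidy,
        }
        if has_sub:
            row["subtaxon_label"] = a.subtaxon_label or ""
        if has_origin:
            row["origin"] = a.origin or ""
        return row

    rows: list[dict[str, object]] = []
    if dialect == "long":
        has_peaks = any(
            a.peak_height is not None for c in table.calls.values() for a in c
        )
        for acc in table.accessions:
            for mk in table.marker_ids:
                call = table.call(acc.accession_id, mk)
                row = meta_cells(acc)
                row["marker_id"] = mk
                for i in range(2):
                    row[f"allele{i + 1}"] = call[i].size if i < len(call) else ""
                    if has_peaks:
                        peak = call[i].peak_height if i < len(call) else None
                        row[f"peak{i + 1}"] = "" if peak is None else peak
                rows.append(row)
    else:
        for acc in table.accessions:
            row = meta_cells(acc)
            for mk in table.marker_ids:
                call = table.call(acc.accession_id, mk)
                row[mk + "_1"] = call[0].size if len(call) >= 1 else ""
                row[mk + "_2"] = call[1].size if len(call) >= 2 else ""
            rows.append(row)
    if rows:
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        # header-only file for an empty table
        cols = _WIDE_META if dialect == "wide" else _LONG_META + ["allele1", "allele2"]
        pd.DataFrame(columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(
    table: GenotypeTable,
    group: Iterable[str],
    marker_id: str,
    copies_per_call: int = 1,
    group_id: str = "",
) -> AlleleFrequencySpectrum:
    """Allele-frequency spectrum of ``marker_id`` over a set of accessions.

    ``copies_per_call=1`` counts one gene copy per non-missing call (the
    scored allele: strongest peak if heights exist, else the smallest size),
    matching single-allele scoring of selfing taxa.  ``copies_per_call=2``
    counts both alleles of each call, a single-size call contributing two
    copies of that size (homozygote coding).
    """
    if copies_per_call not in (1, 2):
        raise ValueError("copies_per_call must be 1 or 2")
    group = list(group)
    if not group:
        raise ValueError("group must be nonempty")
    table.marker(marker_id)  # raises on unknown marker
    counts: dict[int, int] = {}
    n_copies = 0
    for acc in group:
        call = table.call(acc, marker_id)
        if not call:
            continue
        if copies_per_call == 1:
            if any(a.peak_height is not None for a in call):
                best = max(
                    call,
                    key=lambda a: (
                        a.peak_height if a.peak_height is not None else -1.0,
                        -a.size,
                    ),
                )
            else:
                best = call[0]
            chosen = [best.size]
        else:
            if len(call) == 1:
                chosen = [call[0].size, call[0].size]
            else:
                chosen = [a.size for a in call[:2]]
        for s in chosen:
            counts[s] = counts.get(s, 0) + 1
            n_copies += 1
    if n_copies == 0:
        return AlleleFrequencySpectrum(group_id, marker_id, {}, 0)
    freqs = {s: c / n_copies for s, c in sorted(counts.items())}
    return AlleleFrequencySpectrum(group_id, marker_id, freqs, n_copies)


# ---------------------------------------------------------------------------
# Marker-quality categorisation
# ---------------------------------------------------------------------------


class MarkerCategory(Enum):
    """Marker-quality categories for donor-analysis marker selection.

    Precedence (highest first): NOT_AMPLIFIED > AMPLIFIED_SOME > OVER_SIZE >
    MULTIPLE_PRODUCTS > MONOMORPHIC > SINGLE_IN_TETRAPLOID >
    TWO_IN_TETRAPLOID.  ``POLYMORPHIC_DIPLOID`` is only reachable on tables
    with no tetraploid accessions, where the tetraploid-based categories are
    undefined; it keeps the classifier total.
    """

    NOT_AMPLIFIED = "not amplified in any accession"
    AMPLIFIED_SOME = "amplified in some accessions"
    OVER_SIZE = "PCR product of more than the size cap"
    MULTIPLE_PRODUCTS = "multiple PCR products"
    MONOMORPHIC = "monomorphic PCR product"
    SINGLE_IN_TETRAPLOID = "single PCR product in tetraploid"
    TWO_IN_TETRAPLOID = "two PCR products in tetraploid"
    POLYMORPHIC_DIPLOID = "polymorphic (no tetraploids in table)"


#: report ordering for the selection table
CATEGORY_ORDER = [
    MarkerCategory.NOT_AMPLIFIED,
    MarkerCategory.AMPLIFIED_SOME,
    MarkerCategory.OVER_SIZE,
    MarkerCategory.MULTIPLE_PRODUCTS,
    MarkerCategory.MONOMORPHIC,
    MarkerCategory.SINGLE_IN_TETRAPLOID,
    MarkerCategory.TWO_IN_TETRAPLOID,
    MarkerCategory.POLYMORPHIC_DIPLOID,
]


def classify_marker(
    table: GenotypeTable, marker_id: str, size_cap: int = 500
) -> MarkerCategory:
    """Assign a marker to exactly one quality category (fixed precedence).

    A diploid accession showing more than one distinct product, or any
    accession showing more than two, makes the marker MULTIPLE_PRODUCTS: on
    highly selfing diploids a clean single-locus marker amplifies one product
    per accession.  Apply :meth:`GenotypeTable.scored` first to classify on
    the single-allele scored view instead.
    """
    table.marker(marker_id)
    accs = table.accessions
    products = {a.accession_id: table.products(a.accession_id, marker_id) for a in accs}
    amplified = [a for a in accs if products[a.accession_id]]
    if not amplified:
        return MarkerCategory.NOT_AMPLIFIED
    if len(amplified) < len(accs):
        return MarkerCategory.AMPLIFIED_SOME
    if any(s > size_cap for p in products.values() for s in p):
        return MarkerCategory.OVER_SIZE
    for a in accs:
        p = products[a.accession_id]
        if len(p) > 2 or (a.ploidy == 2 and len(p) > 1):
            return MarkerCategory.MULTIPLE_PRODUCTS
    all_sizes = {s for p in products.values() for s in p}
    if len(all_sizes) == 1:
        return MarkerCategory.MONOMORPHIC
    tetras = [a for a in accs if a.ploidy == 4]
    if not tetras:
        return MarkerCategory.POLYMORPHIC_DIPLOID
    if any(len(products[a.accession_id]) == 1 for a in tetras):
        return MarkerCategory.SINGLE_IN_TETRAPLOID
    return MarkerCategory.TWO_IN_TETRAPLOID


@dataclass
class SelectionReport:
    """Per-category marker counts and the donor-analysis pass list."""

    counts: dict[MarkerCategory, int]
    per_marker: pd.DataFrame  # marker_id, category, n_amplified
    passing: list[str] = field(default_factory=list)

    @property
    def n_markers(self) -> int:
        return sum(self.counts.values())


def selection_report(table: GenotypeTable, size_cap: int = 500) -> SelectionReport:
    """Classify every marker and list those suitable for donor analysis
    (one product in every diploid, two discrete products in every tetraploid,
    polymorphic)."""
    rows = []
    counts = {c: 0 for c in CATEGORY_ORDER}
    passing = []
    n_acc = len(table.accessions)
    for mk in table.marker_ids:
        cat = classify_marker(table, mk, size_cap=size_cap)
        counts[cat] += 1
        n_amp = sum(
            1 for a in table.accession_ids if table.products(a, mk)
        )
        rows.append({"marker_id": mk, "category": cat.name, "n_amplified": n_amp,
                     "n_accessions": n_acc})
        if cat is MarkerCategory.TWO_IN_TETRAPLOID:
            passing.append(mk)
    if not table.tetraploid_accessions():
        logger.info(
            "table has no tetraploid accessions: SINGLE/TWO_IN_TETRAPLOID "
            "categories are empty by construction"
        )
    return SelectionReport(counts=counts, per_marker=pd.DataFrame(rows), passing=passing)
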