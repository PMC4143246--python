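"""Nei's DA genetic distance over multi-allelic loci.

DA between two entities (accessions or genome groups) with allele-frequency
spectra x and y over r shared loci:

    DA = 1 - (1/r) * sum_j sum_i sqrt(x_ij * y_ij)

Each pair is averaged over its own shared loci, so r varies per pair and is
reported alongside the distance.  For individual-level distances an
accession is treated as a population of one: a single-allele call has
frequency 1, a heterozygote has two alleles at 0.5 each.

The per-locus square-root-frequency inner products are precomputed as dense
arrays so distance matrices and locus-bootstrap replicates reduce to
weighted averages (fast enough for a thousand bootstrap trees over a few
hundred tips).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotype import AlleleFrequencySpectrum, GenotypeTable
from .partition import AssignmentStatus, GenomeGroup, PartitionedTable

#: spectra keyed by locus for one entity
SpectraByLocus = Mapping[str, Mapping[int, float]]


@dataclass
class DistanceMatrix:
    """Symmetric labelled DA matrix with per-pair shared-locus counts."""

    labels: list[str]
    d: np.ndarray
    n_loci_used: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def r_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.n_loci_used, index=self.labels, columns=self.labels)


def da_distance(x: SpectraByLocus, y: SpectraByLocus) -> tuple[float, int]:
    """DA between two spectra maps; returns (DA, r = shared loci)."""
    shared = [k for k in x if k in y and x[k] and y[k]]
    r = len(shared)
    if r == 0:
        raise ValueError("no shared loci with data; DA undefined")
    total = 0.0
    for locus in shared:
        xs, ys = x[locus], y[locus]
        total += sum(
            (xs[a] * ys[a]) ** 0.5 for a in xs if a in ys
        )
    da = 1.0 - total / r
    return min(max(da, 0.0), 1.0), r


def _locus_arrays(
    spectra_by_label: Mapping[str, SpectraByLocus],
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Stack per-locus sqrt-frequency inner products.

    Returns (labels, loci, P, present): P[l] is the n x n matrix of
    sum_i sqrt(x_i y_i) at locus l (0 where either entity is missing) and
    present[l] the 0/1 availability matrix.  Labels and loci are sorted so
    downstream statistics are invariant to input ordering.
    """
    labels = sorted(spectra_by_label)
    loci = sorted({k for sp in spectra_by_label.values() for k in sp if sp[k]})
    n, L = len(labels), len(loci)
    P = np.zeros((L, n, n))
    avail = np.zeros((L, n), dtype=bool)
    for li, locus in enumerate(loci):
        alleles = sorted({
            a
            for lab in labels
            for a in spectra_by_label[lab].get(locus, {})
        })
        a_index = {a: i for i, a in enumerate(alleles)}
        X = np.zeros((n, len(alleles)))
        for ni, lab in enumerate(labels):
            freqs = spectra_by_label[lab].get(locus) or {}
            if freqs:
                avail[li, ni] = True
                for a, p in freqs.items():
                    X[ni, a_index[a]] = np.sqrt(p)
        P[li] = X @ X.T
    present = (avail[:, :, None] & avail[:, None, :]).astype(float)
    return labels, loci, P, present


def _da_from_arrays(
    P: np.ndarray, present: np.ndarray, weights: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """DA matrix and shared-locus counts from stacked locus arrays; optional
    per-locus weights implement the locus bootstrap."""
    if weights is None:
        num = P.sum(axis=0)
        r = present.sum(axis=0)
    else:
        num = np.tensordot(weights, P, axes=1)
        r = np.tensordot(weights, present, axes=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - num / r
    d = np.clip(d, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return d, r


def pairwise_da(
    spectra_by_label: Mapping[str, SpectraByLocus],
    on_missing_pair: str = "error",
) -> DistanceMatrix:
    """Full symmetric DA matrix over labelled entities.

    A pair with zero shared typed loci is an error by default;
    ``on_missing_pair="max"`` records DA = 1 for such pairs instead.
    """
    labels, _, P, present = _locus_arrays(spectra_by_label)
    d, r = _da_from_arrays(P, present)
    off = ~np.eye(len(labels), dtype=bool)
    if np.any(r[off] < 1):
        if on_missing_pair == "error":
            i, j = np.argwhere((r < 1) & off)[0]
            raise ValueError(
                f"pair ({labels[i]!r}, {labels[j]!r}) shares no typed loci"
            )
        d = np.where((r < 1) & off, 1.0, d)
    return DistanceMatrix(labels=labels, d=d, n_loci_used=r.astype(int))


# ---------------------------------------------------------------------------
# Building spectra for individuals and groups
# ---------------------------------------------------------------------------


def _call_freqs(sizes: Sequence[int]) -> dict[int, float]:
    """A single accession as a population of one."""
    if not sizes:
        return {}
    distinct = sorted(set(sizes[:2]))
    if len(distinct) == 1:
        return {distinct[0]: 1.0}
    return {distinct[0]: 0.5, distinct[1]: 0.5}


def individual_spectra(
    table: GenotypeTable,
    partitioned: Optional[PartitionedTable] = None,
    include_single_product: bool = False,
) -> dict[str, dict[str, dict[int, float]]]:
    """Per-individual spectra for individual-level DA.

    Diploid accessions appear under their own id.  When a partition is
    given, each tetraploid accession appears as two pseudo-individuals,
    ``"<id> (A)"`` and ``"<id> (B)"``, carrying its sub-genome allele at
    each assigned locus; without a partition tetraploids are skipped.
    """
    counted = (AssignmentStatus.ASSIGNED, AssignmentStatus.TIED) + (
        (AssignmentStatus.SINGLE_PRODUCT,) if include_single_product else ()
    )
    out: dict[str, dict[str, dict[int, float]]] = {}
    for acc in table.accessions:
        if acc.ploidy == 2:
            spectra = {
                mk: f
                for mk in table.marker_ids
                if (f := _call_freqs(table.sizes(acc.accession_id, mk)))
            }
            out[acc.accession_id] = spectra
        elif partitioned is not None:
            for sub in ("A", "B"):
                spectra = {}
                for mk in table.marker_ids:
                    asg = partitioned.assignments.get((acc.accession_id, mk))
                    if asg is None or asg.status not in counted:
                        continue
                    size = asg.a if sub == "A" else asg.b
                    if size is not None:
                        spectra[mk] = {size: 1.0}
                out[f"{acc.accession_id} ({sub})"] = spectra
    return out


def spectra_of_groups(
    spectra: Mapping[tuple[str, str], AlleleFrequencySpectrum],
) -> dict[str, dict[str, dict[int, float]]]:
    """Reshape (group, marker) spectra into per-group locus maps."""
    out: dict[str, dict[str, dict[int, float]]] = {}
    for (gid, mk), s in spectra.items():
        if not s.is_empty:
            out.setdefault(gid, {})[mk] = dict(s.freqs)
        else:
            out.setdefault(gid, {})
    return out


def within_group_mean_da(
    groups: Sequence[GenomeGroup],
    indiv_spectra: Mapping[str, SpectraByLocus],
) -> dict[str, float]:
    """Mean pairwise individual-level DA among members of each group (the
    diagonal of the published group matrices)."""
    out: dict[str, float] = {}
    for g in groups:
        if g.subgenome is None:
            members = list(g.member_accessions)
        else:
            members = [f"{m} ({g.subgenome})" for m in g.member_accessions]
        members = [m for m in members if m in indiv_spectra]
        vals = []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                try:
                    da, _ = da_distance(
                        indiv_spectra[members[i]], indiv_spectra[members[j]]
                    )
                except ValueError:
                    continue
                vals.append(da)
        out[g.group_id] = sum(vals) / len(vals) if vals else float("nan")
    return out
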