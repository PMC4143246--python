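import numpy as np
import pytest

from polydonor.genotype import AccessionRecord, AlleleCall, GenotypeTable, MarkerDef


def make_table(spec, ploidy=None):
    """Build a GenotypeTable from {accession: {marker: sizes}}.

    ``ploidy`` maps taxon -> ploidy (default 2).  Taxon is the accession-id
    prefix before the first '-', or the whole id.
    """
    ploidy = ploidy or {}
    acc_ids = list(spec)
    marker_ids = sorted({mk for calls in spec.values() for mk in calls})
    accessions = []
    for a in acc_ids:
        taxon = a.split("-")[0]
        accessions.append(
            AccessionRecord(a, taxon, ploidy=ploidy.get(taxon, 2))
        )
    markers = [MarkerDef(m) for m in marker_ids]
    calls = {}
    for a, per_marker in spec.items():
        for mk, sizes in per_marker.items():
            if sizes:
                calls[(a, mk)] = [AlleleCall(s) for s in sizes]
    return GenotypeTable(accessions, markers, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20140825)


def random_table(rng, n_acc=6, n_markers=4, missing_rate=0.15, with_peaks=False):
    """Random diploid genotype table for round-trip property tests."""
    accessions = [
        AccessionRecord(f"ACC{i:02d}", f"tax{i % 3}", ploidy=2,
                        origin=("somewhere" if i % 2 else None))
        for i in range(n_acc)
    ]
    markers = [MarkerDef(f"M{j:02d}") for j in range(n_markers)]
    calls = {}
    for a in accessions:
        for m in markers:
            if rng.random() < missing_rate:
                continue
            base = int(rng.integers(100, 400))
            sizes = [base] if rng.random() < 0.7 else [base, base + int(rng.integers(1, 10))]
            alleles = []
            for s in sizes:
                peak = float(rng.integers(500, 10000)) if with_peaks else None
                alleles.append(AlleleCall(s, peak))
            calls[(a.accession_id, m.marker_id)] = alleles
    return GenotypeTable(accessions, markers, calls)
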