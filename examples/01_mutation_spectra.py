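"""Build 96-channel mutation spectra from a simulated MAF + reference.

Simulates a tiny cohort, reads its MAF back through the catalog module,
and prints each sample's mutation burden and top trinucleotide channel.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

import numpy as np
from pyfaidx import Fasta

from apobecsig import (
    CHANNELS,
    CohortSpec,
    build_spectrum,
    read_maf,
    simulate_cohort,
    stack_catalog,
)
from apobecsig.catalog import group_records_by_sample

with TemporaryDirectory() as tmp:
    cohort = simulate_cohort(CohortSpec(seed=1, n_samples=5, genome_length=30_000), tmp)
    reference = Fasta(str(cohort.fasta))
    by_sample = group_records_by_sample(read_maf(cohort.maf))
    spectra = [build_spectrum(r, reference, sample_id=s) for s, r in by_sample.items()]
    catalog = stack_catalog(spectra)

print(f"catalog: {catalog.matrix.shape[0]} samples x {catalog.matrix.shape[1]} channels")
for sid, row in zip(catalog.sample_ids, catalog.matrix):
    top = CHANNELS[int(np.argmax(row))]
    print(f"  {sid}: {row.sum():4d} SNVs, top channel {top} ({row.max()} mutations)")
print("Each row is one tumor's substitution spectrum; the top channel hints at")
print("its dominant mutational process (T[C>T]A/T = APOBEC, C>A = smoking).")
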