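"""Shared fixtures: tiny references, record factories, synthetic catalogs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from pyfaidx import Fasta

from apobecsig.catalog import CatalogMatrix, MutationRecord
from apobecsig.simulate import default_signature_defs

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    """Test-local reverse complement, independent of the package's."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def write_fasta(path, sequences: dict[str, str]):
    """Write a FASTA and return an indexed pyfaidx handle."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
    return Fasta(str(path))


@pytest.fixture
def toy_reference(tmp_path):
    """Hand-written 60-base single-contig reference.

    Layout (1-based): TCA at 5-7, ACA at 15-17, TCT at 25-27,
    TCC at 35-37, TGA at 45-47 (= TCA on the minus strand).
    """
    seq = (
        "GGGG" + "TCA" + "GGGGGGG"      # 1-14: TCA centered at pos 6
        + "ACA" + "GGGGGGG"             # 15-24: ACA centered at pos 16
        + "TCT" + "GGGGGGG"             # 25-34: TCT centered at pos 26
        + "TCC" + "GGGGGGG"             # 35-44: TCC centered at pos 36
        + "TGA" + "GGGGGGGGGGGGG"       # 45-60: TGA centered at pos 46
    )
    assert len(seq) == 60
    assert seq[4:7] == "TCA" and seq[14:17] == "ACA" and seq[24:27] == "TCT"
    assert seq[34:37] == "TCC" and seq[44:47] == "TGA"
    return write_fasta(tmp_path / "toy.fa", {"chr1": seq}), seq


def make_record(pos, ref, alt, sample="S1", chrom="chr1", vc=None):
    return MutationRecord(
        sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
        variant_classification=vc,
    )


def make_three_signature_catalog(seed, n_samples=40, means=(70, 80, 50), disp=1.0):
    """Catalog of Poisson draws from the three default signatures.

    Per-signature per-sample loads are gamma-dispersed so mixture
    proportions vary across samples (required for identifiability).
    """
    rng = np.random.default_rng(seed)
    defs = default_signature_defs().to_numpy()
    X = np.zeros((n_samples, 96), dtype=int)
    truth = np.zeros((n_samples, len(means)))
    for i in range(n_samples):
        for k, mean in enumerate(means):
            lam = rng.gamma(disp, mean / disp)
            count = rng.poisson(lam)
            truth[i, k] = count
            if count:
                X[i] += rng.multinomial(count, defs[k])
    catalog = CatalogMatrix(
        sample_ids=[f"S{i:02d}" for i in range(n_samples)], matrix=X
    )
    return catalog, truth


@pytest.fixture
def three_signature_catalog():
    return make_three_signature_catalog(seed=42)
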