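"""Synthetic NSCLC-like cohorts for end-to-end pipeline testing.

Generates, from a single seed, a complete self-consistent cohort:

* a single-contig reference sequence with a controllable density of
  TCW motifs among its cytosines,
* per-sample somatic SNV catalogs drawn as mixtures of a small number
  of 96-channel signatures (APOBEC-like, smoking-like, mismatch-repair
  -like) with gamma-Poisson (negative binomial) mutation counts and
  mutations placed at reference positions matching each drawn channel's
  trinucleotide,
* binary DCB/NDB clinical labels from a logistic link on the sample's
  APOBEC-signature mutation load, and
* a log2-scale expression matrix in which an immune-gene module and an
  APOBEC3B gene co-vary with APOBEC exposure.

Default cohort conditions mirror a pembrolizumab-treated NSCLC cohort:
31 samples, a mean APOBEC (TCW) mutation load near 23 with strong
overdispersion (observed loads span roughly 0-200), a mean total
burden near 270, and a DCB prevalence near 45%. All randomness flows
from the spec seed through named substreams so each stage is
independently reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from apobecsig.catalog import BASES, CHANNELS, revcomp

logger = logging.getLogger(__name__)

_PYR = "CT"
_CONTIG = "chrSim"


def _substream(seed: int, stream: int) -> int:
    """Deterministic 31-bit child seed for a named substream."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def default_signature_defs() -> pd.DataFrame:
    """Three well-separated 96-channel signatures.

    APOBEC-like: C>T/C>G concentrated at TCA/TCT (the TCW motif).
    Smoking-like: broad C>A transversions. MMR-like: C>T at CpG plus
    diffuse T>C, resembling mismatch-repair deficiency spectra.
    """
    defs = pd.DataFrame(
        0.0, index=["APOBEC", "Smoking", "MMR"], columns=list(CHANNELS)
    )
    apobec_channels = [f"T[C>{alt}]{w}" for alt in "TG" for w in "AT"]
    defs.loc["APOBEC", apobec_channels] = 0.85 / len(apobec_channels)
    rest = [c for c in CHANNELS if c not in apobec_channels]
    defs.loc["APOBEC", rest] = 0.15 / len(rest)

    ca_channels = [c for c in CHANNELS if "[C>A]" in c]
    defs.loc["Smoking", ca_channels] = 0.80 / len(ca_channels)
    rest = [c for c in CHANNELS if c not in ca_channels]
    defs.loc["Smoking", rest] = 0.20 / len(rest)

    cpg_channels = [f"{left}[C>T]G" for left in BASES]
    tc_channels = [c for c in CHANNELS if "[T>C]" in c]
    defs.loc["MMR", cpg_channels] = 0.50 / len(cpg_channels)
    defs.loc["MMR", tc_channels] = 0.30 / len(tc_channels)
    rest = [c for c in CHANNELS if c not in cpg_channels + tc_channels]
    defs.loc["MMR", rest] = 0.20 / len(rest)
    return defs


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; the seed is mandatory."""

    seed: int
    n_samples: int = 31
    genome_length: int = 100_000
    tcw_density: float = 0.15
    signature_names: tuple[str, ...] = ("APOBEC", "Smoking", "MMR")
    exposure_means: tuple[float, ...] = (23.0, 170.0, 75.0)
    exposure_dispersions: tuple[float, ...] = (0.5, 1.5, 1.5)
    label_beta0: float = -1.5
    label_beta1: float = 0.08
    n_genes: int = 500
    immune_gene_count: int = 60
    effect_size: float = 1.0
    noise_sd: float = 1.0
    expr_baseline: float = 5.0
    apobec3b_effect: float = 1.0
    signature_defs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.signature_defs is None:
            self.signature_defs = default_signature_defs().loc[
                list(self.signature_names)
            ]
        if not (
            len(self.signature_names)
            == len(self.exposure_means)
            == len(self.exposure_dispersions)
            == len(self.signature_defs)
        ):
            raise ValueError("signature names, means and dispersions must align")
        if any(m < 0 for m in self.exposure_means):
            raise ValueError("exposure means must be nonnegative")
        rows = self.signature_defs.to_numpy().sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("signature rows must sum to 1")


@dataclass
class SyntheticCohort:
    """Paths of an emitted cohort plus the generating truth."""

    fasta: Path
    maf: Path
    clinical: Path
    expression: Path
    truth: Path


def realized_tcw_fraction(sequence: str) -> float:
    """Fraction of cytosines (both strands) sitting in a TCW motif."""
    tcw = c = 0
    n = len(sequence)
    for i, base in enumerate(sequence):
        if base == "C":
            c += 1
            if 0 < i < n - 1 and sequence[i - 1] == "T" and sequence[i + 1] in "AT":
                tcw += 1
        elif base == "G":
            c += 1
            if 0 < i < n - 1 and sequence[i + 1] == "A" and sequence[i - 1] in "TA":
                tcw += 1
    return tcw / c if c else 0.0


def _generate_sequence(length: int, knob: float, rng: np.random.Generator) -> str:
    """Random sequence; knob > 0 plants TCW motifs, knob < 0 destroys them."""
    parts: list[str] = []
    total = 0
    p_insert = max(knob, 0.0)
    while total < length:
        if p_insert > 0 and rng.random() < p_insert and total + 3 <= length:
            parts.append("TC" + ("A" if rng.random() < 0.5 else "T"))
            total += 3
        else:
            parts.append(BASES[rng.integers(4)])
            total += 1
    seq = list("".join(parts)[:length])
    if knob < 0:
        p_destroy = -knob
        for i in range(1, length - 1):
            if seq[i] == "C" and seq[i - 1] == "T" and seq[i + 1] in "AT":
                if rng.random() < p_destroy:
                    seq[i - 1] = "ACG"[rng.integers(3)]
            elif seq[i] == "G" and seq[i + 1] == "A" and seq[i - 1] in "TA":
                if rng.random() < p_destroy:
                    seq[i + 1] = "CGT"[rng.integers(3)]
    return "".join(seq)


def make_reference(
    genome_length: int,
    tcw_density: float,
    seed: int,
    out_path: str | Path | None = None,
    rel_tol: float = 0.10,
) -> str:
    """Single-contig reference with a target TCW-per-cytosine fraction.

    The realized fraction is tuned by bisection on a motif
    planting/destroying knob until within ``rel_tol`` relative of the
    target. Optionally writes a FASTA to ``out_path``. Returns the
    sequence.
    """
    if genome_length < 1000:
        raise ValueError("genome_length must be at least 1000")
    if not 0.0 < tcw_density <= 0.8:
        raise ValueError("tcw_density must lie in (0, 0.8]")
    lo, hi = -0.995, 0.9
    best_seq, best_err = "", np.inf
    for trial in range(40):
        knob = 0.0 if trial == 0 else (lo + hi) / 2.0
        rng = np.random.default_rng(np.random.SeedSequence([seed, trial]))
        seq = _generate_sequence(genome_length, knob, rng)
        frac = realized_tcw_fraction(seq)
        err = abs(frac - tcw_density) / tcw_density
        if err < best_err:
            best_seq, best_err = seq, err
        if err <= rel_tol * 0.5:
            break
        if frac < tcw_density:
            lo = knob
        else:
            hi = knob
    if best_err > rel_tol:
        raise ValueError(
            f"could not realize tcw_density {tcw_density} "
            f"(best relative error {best_err:.3f})"
        )
    if out_path is not None:
        write_fasta(best_seq, out_path)
    return best_seq


def write_fasta(sequence: str, path: str | Path, name: str = _CONTIG) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")
    return path


def _position_index(sequence: str) -> dict[str, np.ndarray]:
    """Map pyrimidine-normalized trinucleotide -> 0-based center positions."""
    index: dict[str, list[int]] = {}
    for i in range(1, len(sequence) - 1):
        base = sequence[i]
        tri = sequence[i - 1 : i + 2]
        if "N" in tri:
            continue
        key = tri if base in _PYR else revcomp(tri)
        index.setdefault(key, []).append(i)
    return {k: np.asarray(v, dtype=np.int64) for k, v in index.items()}


def _parse_channel(channel: str) -> tuple[str, str, str, str]:
    """'A[C>T]G' -> (left, ref, alt, right), pyrimidine strand."""
    left, rest = channel[0], channel[2:]
    ref, alt, right = rest[0], rest[2], rest[4]
    return left, ref, alt, right


def simulate_catalog(
    spec: CohortSpec, reference: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-sample mutation catalogs as signature mixtures.

    Per sample and signature, the mutation count is gamma-Poisson
    (shape = dispersion; pure Poisson when dispersion is 0 or None);
    each mutation samples a 96-channel from the signature row and lands
    uniformly on an unused reference position whose trinucleotide
    matches. Returns (MAF-layout DataFrame, true exposures DataFrame).
    """
    rng = np.random.default_rng(_substream(spec.seed, 1))
    index = _position_index(reference)
    sig_matrix = spec.signature_defs.to_numpy()
    parsed = [_parse_channel(c) for c in CHANNELS]
    rows: list[dict] = []
    exposures = np.zeros((spec.n_samples, len(spec.signature_names)), dtype=int)
    n_resampled = 0
    for s in range(spec.n_samples):
        sample_id = f"SYN{s + 1:03d}"
        used: set[int] = set()
        for k, (mean, disp) in enumerate(
            zip(spec.exposure_means, spec.exposure_dispersions)
        ):
            if mean == 0:
                continue
            lam = mean if not disp else rng.gamma(shape=disp, scale=mean / disp)
            count = rng.poisson(lam)
            placed = 0
            failures = 0
            while placed < count:
                ch = rng.choice(96, p=sig_matrix[k])
                left, ref, alt, right = parsed[ch]
                tri = left + ref + right
                positions = index.get(tri)
                if positions is None or len(positions) == 0:
                    n_resampled += 1
                    failures += 1
                    if failures > 100 * max(count, 1):
                        raise RuntimeError(
                            f"cannot place mutations for trinucleotide {tri}"
                        )
                    continue
                pos0 = int(positions[rng.integers(len(positions))])
                if pos0 in used:
                    failures += 1
                    if failures > 100 * max(count, 1):
                        raise RuntimeError("reference too saturated to place mutations")
                    continue
                used.add(pos0)
                plus_ref = reference[pos0]
                plus_alt = alt if plus_ref in _PYR else revcomp(alt)
                rows.append(
                    {
                        "Tumor_Sample_Barcode": sample_id,
                        "Chromosome": _CONTIG,
                        "Start_Position": pos0 + 1,
                        "End_Position": pos0 + 1,
                        "Reference_Allele": plus_ref,
                        "Tumor_Seq_Allele2": plus_alt,
                        "Variant_Classification": "Missense_Mutation",
                        "Variant_Type": "SNP",
                    }
                )
                placed += 1
            exposures[s, k] = placed
    if n_resampled:
        logger.info("resampled %d channel draw(s) without matching positions", n_resampled)
    maf = pd.DataFrame(
        rows,
        columns=[
            "Tumor_Sample_Barcode",
            "Chromosome",
            "Start_Position",
            "End_Position",
            "Reference_Allele",
            "Tumor_Seq_Allele2",
            "Variant_Classification",
            "Variant_Type",
        ],
    )
    truth = pd.DataFrame(
        exposures,
        index=pd.Index([f"SYN{s + 1:03d}" for s in range(spec.n_samples)],
                       name="sample_id"),
        columns=list(spec.signature_names),
    )
    return maf, truth


def simulate_labels(
    exposures: pd.DataFrame,
    beta0: float,
    beta1: float,
    seed: int,
    apobec_column: str = "APOBEC",
) -> pd.DataFrame:
    """DCB/NDB labels via a logistic link on APOBEC exposure.

    P(DCB) = logistic(beta0 + beta1 * apobec_exposure), Bernoulli
    draws under the given seed. Returns a per-sample table with the
    label and its generating probability.
    """
    rng = np.random.default_rng(seed)
    x = exposures[apobec_column].to_numpy(dtype=float)
    prob = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x)))
    dcb = rng.random(len(prob)) < prob
    out = pd.DataFrame(
        {
            "benefit": np.where(dcb, "DCB", "NDB"),
            "p_dcb_true": prob,
        },
        index=exposures.index,
    )
    logger.info("simulated labels: prevalence %.3f", dcb.mean())
    return out


def simulate_expression(
    spec: CohortSpec, exposures: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, list[str]]:
    """Log2-scale expression (genes x samples) tied to APOBEC exposure.

    Background genes are Normal(baseline, noise_sd); the immune-module
    genes gain ``effect_size`` times the standardized APOBEC exposure,
    and one gene named APOBEC3B tracks exposure with its own effect.
    Returns (matrix, immune gene names).
    """
    if spec.n_genes < spec.immune_gene_count + 1:
        raise ValueError("n_genes must exceed immune_gene_count")
    rng = np.random.default_rng(seed)
    n = len(exposures)
    x = exposures["APOBEC"].to_numpy(dtype=float)
    z = (x - x.mean()) / (x.std() if x.std() else 1.0)
    immune = [f"IMM{i + 1:03d}" for i in range(spec.immune_gene_count)]
    background = [
        f"GENE{i + 1:04d}"
        for i in range(spec.n_genes - spec.immune_gene_count - 1)
    ]
    genes = immune + ["APOBEC3B"] + background
    matrix = spec.expr_baseline + rng.normal(0.0, spec.noise_sd, size=(len(genes), n))
    matrix[: len(immune)] += spec.effect_size * z[None, :]
    matrix[len(immune)] += spec.apobec3b_effect * z
    df = pd.DataFrame(matrix, index=pd.Index(genes, name="gene"),
                      columns=exposures.index)
    return df, immune


def simulate_cohort(spec: CohortSpec, outdir: str | Path) -> SyntheticCohort:
    """Emit a complete synthetic cohort to ``outdir``.

    Writes reference FASTA, MAF, clinical TSV, expression TSV and a
    truth JSON from which every generated quantity is recomputable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequence = make_reference(
        spec.genome_length, spec.tcw_density, _substream(spec.seed, 0)
    )
    fasta = write_fasta(sequence, outdir / "reference.fa")
    maf, truth_exposures = simulate_catalog(spec, sequence)
    maf_path = outdir / "cohort.maf"
    maf.to_csv(maf_path, sep="\t", index=False)
    labels = simulate_labels(
        truth_exposures, spec.label_beta0, spec.label_beta1,
        _substream(spec.seed, 2),
        apobec_column=spec.signature_names[0],
    )
    clinical_path = outdir / "clinical.tsv"
    labels[["benefit"]].to_csv(clinical_path, sep="\t")
    expr, immune_genes = simulate_expression(
        spec, truth_exposures.rename(
            columns={spec.signature_names[0]: "APOBEC"}
        ), _substream(spec.seed, 3)
    )
    expr_path = outdir / "expression.tsv"
    expr.to_csv(expr_path, sep="\t")
    (outdir / "immune_genes.txt").write_text("\n".join(immune_genes) + "\n")
    truth = {
        "seed": spec.seed,
        "signature_names": list(spec.signature_names),
        "signature_defs": spec.signature_defs.to_numpy().tolist(),
        "true_exposures": truth_exposures.to_dict(orient="index"),
        "label_probabilities": labels["p_dcb_true"].to_dict(),
        "label_beta0": spec.label_beta0,
        "label_beta1": spec.label_beta1,
        "realized_tcw_fraction": realized_tcw_fraction(sequence),
        "immune_genes": immune_genes,
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return SyntheticCohort(
        fasta=fasta,
        maf=maf_path,
        clinical=clinical_path,
        expression=expr_path,
        truth=truth_path,
    )
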