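"""APOBEC TCW-motif mutation metrics.

APOBEC cytidine deaminases mutate cytosines in the TCW trinucleotide
(W = A or T), producing C>T transitions and C>G transversions. Per
sample this module computes:

* the TCW mutation count (TCA>TTA/TGA and TCT>TTT/TGT, read on the
  pyrimidine strand),
* the fold enrichment E of TCW mutations over the TCW content of the
  local reference context,

      E = [(TCW>TGW + TCW>TTW) / (C>G + C>T)] / [TCW / C]

  where the motif denominators TCW and C are counted over +/-``flank``
  reference windows around each mutated cytosine, and
* the minimum APOBEC mutation load,
  (TCW>TGW + TCW>TTW) * (E-1)/E, rounded to the nearest whole number
  and clamped below at zero — the number of TCW mutations in excess of
  random mutagenesis.

A per-sample one-sided Fisher exact test (mutations at TCW vs other C
against context TCW vs other context C) is reported as an auxiliary
significance measure; cohort-level q-values use Benjamini–Hochberg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta
from scipy import stats

from apobecsig.catalog import (
    MutationRecord,
    ReferenceMismatchError,
    extract_context,
    revcomp,
)
from apobecsig.stats import bh_adjust

logger = logging.getLogger(__name__)

#: Per-sample enrichment above this value implies that at least half of a
#: sample's TCW mutations were made by APOBEC enzymes ((E-1)/E >= 0.5).
APOBEC_ENRICHED_MIN = 2.0

#: MAF Variant_Classification values treated as non-synonymous.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Translation_Start_Site",
    }
)


@dataclass(frozen=True)
class TcwCount:
    """TCW (APOBEC-context) and total mutation counts for one sample."""

    sample_id: str
    tcw_count: int
    total_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.tcw_count <= self.total_count:
            raise ValueError("tcw_count must lie in [0, total_count]")


@dataclass(frozen=True)
class ApobecEnrichmentResult:
    """Motif/mutation counts, enrichment E, and minimum APOBEC load."""

    sample_id: str
    n_tcw_to_ttw: int
    n_tcw_to_tgw: int
    n_c_to_t: int
    n_c_to_g: int
    context_tcw: int
    context_c: int
    enrichment: float  # NaN when undefined
    min_load: int
    p_value: float  # NaN when undefined
    q_value: float = float("nan")

    @property
    def defined(self) -> bool:
        return not math.isnan(self.enrichment)

    @property
    def enriched(self) -> bool:
        return self.defined and self.enrichment > APOBEC_ENRICHED_MIN


def _pyrimidine_view(rec: MutationRecord, trinuc: str) -> tuple[str, str, str]:
    """(ref, alt, trinucleotide) with purine references reverse-complemented."""
    if rec.ref in "GA":
        return revcomp(rec.ref), revcomp(rec.alt), revcomp(trinuc)
    return rec.ref, rec.alt, trinuc


def _trinuc(rec: MutationRecord, reference: Fasta) -> str | None:
    """Plus-strand trinucleotide at a record's site, or None if rejected."""
    try:
        window = extract_context(rec, reference, flank=1)
    except ReferenceMismatchError as exc:
        logger.debug("rejected record: %s", exc)
        return None
    seq, off = window.sequence, window.offset_of_site
    if off == 0 or off == len(seq) - 1:
        return None
    trinuc = seq[off - 1 : off + 2]
    return None if "N" in trinuc else trinuc


def _is_nonsyn(rec: MutationRecord) -> bool:
    return rec.variant_classification in NONSYNONYMOUS_CLASSES


def count_tcw(
    records: Sequence[MutationRecord],
    reference: Fasta,
    nonsynonymous_only: bool = False,
) -> TcwCount:
    """Count TCW-context C>T/C>G mutations and total admitted mutations.

    A mutation qualifies as TCW when its pyrimidine-normalized
    trinucleotide is TCA or TCT and the substitution is C>T or C>G;
    purine-reference records are evaluated on the reverse complement.
    With ``nonsynonymous_only`` both counts are restricted to records
    whose MAF Variant_Classification is non-synonymous.
    """
    ids = {r.sample_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple samples: {sorted(ids)}")
    sample_id = next(iter(ids)) if ids else ""
    tcw = total = 0
    for rec in records:
        if nonsynonymous_only and not _is_nonsyn(rec):
            continue
        trinuc = _trinuc(rec, reference)
        if trinuc is None:
            continue
        total += 1
        ref, alt, tri = _pyrimidine_view(rec, trinuc)
        if ref == "C" and alt in "TG" and tri in ("TCA", "TCT"):
            tcw += 1
    return TcwCount(sample_id=sample_id, tcw_count=tcw, total_count=total)


def _window_motif_counts(sequence: str, lo: int, hi: int) -> tuple[int, int]:
    """(TCW cytosines, total cytosines) among ``sequence[lo:hi]``.

    Every C (plus strand) and G (a C on the minus strand) in the inner
    range counts toward the cytosine total; motif status is evaluated
    from ``sequence``, which extends one base past the inner range on
    each side where the contig allows, so a cytosine at the edge of the
    +/-flank window keeps its true trinucleotide. A cytosine whose
    neighbor falls off the contig has undefined context and is never
    TCW.
    """
    tcw = c = 0
    n = len(sequence)
    for i in range(lo, hi):
        base = sequence[i]
        if base == "C":
            c += 1
            if 0 < i < n - 1 and sequence[i - 1] == "T" and sequence[i + 1] in "AT":
                tcw += 1
        elif base == "G":
            c += 1
            # minus-strand TCW: plus-strand TGA (revcomp TCA) or AGA (revcomp TCT)
            if 0 < i < n - 1 and sequence[i + 1] == "A" and sequence[i - 1] in "TA":
                tcw += 1
    return tcw, c


def apobec_enrichment(
    records: Sequence[MutationRecord],
    reference: Fasta,
    flank: int = 20,
) -> ApobecEnrichmentResult:
    """APOBEC enrichment E and minimum APOBEC load for one sample.

    Only pyrimidine-normalized C>T and C>G mutations enter the mutation
    fraction, exactly as the printed formula reads. Context TCW and C
    are counted (both strands, pyrimidine-normalized) over the
    +/-``flank`` reference window around each such mutated cytosine;
    overlapping windows are counted once per window. When no qualifying
    mutations or no context cytosines exist, E and p are NaN and the
    minimum load is 0.
    """
    ids = {r.sample_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple samples: {sorted(ids)}")
    sample_id = next(iter(ids)) if ids else ""

    n_tcw_ttw = n_tcw_tgw = n_c_t = n_c_g = 0
    context_tcw = context_c = 0
    for rec in records:
        trinuc = _trinuc(rec, reference)
        if trinuc is None:
            continue
        ref, alt, tri = _pyrimidine_view(rec, trinuc)
        if ref != "C" or alt not in "TG":
            continue
        if alt == "T":
            n_c_t += 1
        else:
            n_c_g += 1
        if tri in ("TCA", "TCT"):
            if alt == "T":
                n_tcw_ttw += 1
            else:
                n_tcw_tgw += 1
        window = extract_context(rec, reference, flank=flank + 1)
        off = window.offset_of_site
        lo = max(0, off - flank)
        hi = min(len(window.sequence), off + flank + 1)
        w_tcw, w_c = _window_motif_counts(window.sequence, lo, hi)
        context_tcw += w_tcw
        context_c += w_c

    n_tcw = n_tcw_ttw + n_tcw_tgw
    n_mut = n_c_t + n_c_g
    if n_mut == 0 or context_c == 0 or context_tcw == 0:
        logger.info("sample %s: enrichment undefined (no qualifying mutations/context)", sample_id)
        enrichment = float("nan")
        min_load = 0
        p_value = float("nan")
    else:
        enrichment = (n_tcw / n_mut) / (context_tcw / context_c)
        if enrichment <= 1.0:
            min_load = 0
        else:
            raw = n_tcw * (enrichment - 1.0) / enrichment
            min_load = int(math.floor(raw + 0.5))  # half away from zero (raw >= 0)
        table = [[n_tcw, n_mut - n_tcw], [context_tcw, context_c - context_tcw]]
        _, p_value = stats.fisher_exact(table, alternative="greater")
    return ApobecEnrichmentResult(
        sample_id=sample_id,
        n_tcw_to_ttw=n_tcw_ttw,
        n_tcw_to_tgw=n_tcw_tgw,
        n_c_to_t=n_c_t,
        n_c_to_g=n_c_g,
        context_tcw=context_tcw,
        context_c=context_c,
        enrichment=enrichment,
        min_load=min_load,
        p_value=p_value,
    )


def cohort_enrichment(
    records_by_sample: Mapping[str, Sequence[MutationRecord]],
    reference: Fasta,
    flank: int = 20,
) -> pd.DataFrame:
    """Per-sample enrichment across a cohort with BH-adjusted q-values.

    Samples with undefined p-values are excluded from the correction and
    keep a NaN q-value.
    """
    if not records_by_sample:
        raise ValueError("cohort_enrichment requires at least one sample")
    results = [
        apobec_enrichment(recs, reference, flank=flank)
        for sid, recs in records_by_sample.items()
    ]
    df = pd.DataFrame([r.__dict__ for r in results]).set_index("sample_id")
    defined = df["p_value"].notna()
    if defined.any():
        df.loc[defined, "q_value"] = bh_adjust(df.loc[defined, "p_value"].to_numpy())
    return df
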