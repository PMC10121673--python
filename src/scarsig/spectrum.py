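"""SBS-96 trinucleotide mutation spectra.

Single-base substitutions are classified into 96 channels: six pyrimidine
substitution types (C>A, C>G, C>T, T>A, T>C, T>G) by the 4x4 flanking
bases. Purine-reference records are reverse-complemented (ref, alt and
both flanks) before labelling, so "T·G·A with G>T" and "T·C·A with C>A"
land in the same channel.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import VariantRecord, logger

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical SBS-96 channel labels, substitution-major then 5' then 3' flank.
SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in "ACGT"
    for three in "ACGT"
)

_SYSTEM_SIZES = {"SBS-96": 96, "DBS-78": 78, "ID-83": 83, "CN-48": 48}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass
class MutationSpectrum:
    """Sample x channel mutation-count matrix with a channel-system tag."""

    counts: pd.DataFrame
    system: str | None = "SBS-96"  # None: untagged/custom channel set

    def __post_init__(self) -> None:
        if self.system is not None:
            if self.system not in _SYSTEM_SIZES:
                raise ValueError(f"unknown channel system {self.system!r}")
            n = _SYSTEM_SIZES[self.system]
            if self.counts.shape[1] != n:
                raise ValueError(
                    f"{self.system} spectrum needs {n} channels, "
                    f"got {self.counts.shape[1]}"
                )
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate channel labels")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts in spectrum")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def channels(self) -> list[str]:
        return list(self.counts.columns)


class ReferenceMismatchError(ValueError):
    """The VCF REF allele disagrees with the reference sequence."""


def classify_sbs96(record: VariantRecord, reference: Mapping[str, object]) -> str | None:
    """SBS-96 channel label for a single-base substitution.

    `reference` maps chromosome name to an indexable sequence (a pyfaidx
    ``Fasta`` record or plain string). Returns ``None`` (caller logs/counts)
    when a flanking base is N or the variant sits on a contig edge.
    """
    if not record.is_snv:
        raise ValueError("classify_sbs96 requires a single-base substitution")
    chrom = reference[record.chrom]
    i = record.pos - 1  # 0-based centre
    if i < 1 or i + 1 >= len(chrom):
        return None
    triplet = str(chrom[i - 1:i + 2]).upper()
    ref_base, alt = record.ref, record.alt
    if triplet[1] != ref_base:
        raise ReferenceMismatchError(
            f"{record.chrom}:{record.pos} REF {ref_base} != reference {triplet[1]}"
        )
    if any(b not in "ACGT" for b in triplet):
        return None
    if ref_base in "AG":  # purine reference: flip to the pyrimidine strand
        triplet = reverse_complement(triplet)
        alt = alt.translate(_COMPLEMENT)
    return f"{triplet[0]}[{triplet[1]}>{alt}]{triplet[2]}"


def build_spectrum(records: Iterable[VariantRecord],
                   reference: Mapping[str, object],
                   samples: Sequence[str],
                   channels: Sequence[str] = SBS96_CHANNELS) -> MutationSpectrum:
    """Assemble the sample x 96-channel count matrix.

    Only nonsynonymous single-base substitutions are counted (spectra feed
    a coding-mutation burden analysis). Samples with no countable record
    are retained as all-zero rows. Records whose sample is not listed are
    an error; records with unclassifiable context (N flank, contig edge)
    are skipped and counted in the log.
    """
    counts = pd.DataFrame(0, index=list(samples), columns=list(channels), dtype=int)
    n_skipped = 0
    for rec in records:
        if rec.sample_id not in counts.index:
            raise KeyError(f"record sample {rec.sample_id!r} not in sample list")
        if not rec.is_nonsynonymous or not rec.is_snv:
            continue
        label = classify_sbs96(rec, reference)
        if label is None:
            n_skipped += 1
            continue
        counts.loc[rec.sample_id, label] += 1
    if n_skipped:
        logger.info("build_spectrum: skipped %d records with unusable context", n_skipped)
    empty = counts.index[counts.sum(axis=1) == 0]
    for sid in empty:
        logger.info("sample %s has no counted records (all-zero spectrum row)", sid)
    return MutationSpectrum(counts=counts, system="SBS-96")
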