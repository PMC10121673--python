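"""Readers and writers for the external formats the pipeline touches.

Variant calls enter as VCF 4.x, the reference as indexed FASTA, the
signature catalog as a COSMIC-style TSV (channel labels in a ``Type``
column, one column per signature), the clinical cohort as CSV, and
matrices (spectra, attributions) as TSV with samples as rows.

The durable-benefit label is *never* read from a file: it is derived from
progression-free survival and the event flag (``derive_db_label``), with
half a year taken as exactly 26 weeks.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("scarsig")

#: PFS cutoff (weeks) defining durable benefit: half a year, exactly.
DB_CUTOFF_WEEKS = 26.0

_VALID_BASES = frozenset("ACGT")


def setup_logging(level: int = logging.INFO) -> None:
    """Configure package logging to standard error."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """A single somatic variant call (one ALT allele)."""

    sample_id: str
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    is_nonsynonymous: bool = True
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if len(self.ref) == 1 and len(self.alt) == 1:
            if self.ref not in _VALID_BASES or self.alt not in _VALID_BASES:
                raise ValueError(
                    f"substitution alleles must be A/C/G/T, got {self.ref}>{self.alt}"
                )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclasses.dataclass
class RunConfig:
    """Tunable pipeline parameters with the study's defaults."""

    coverage_mb: float = 47.9
    db_cutoff_weeks: float = DB_CUTOFF_WEEKS
    threshold: float = 0.438
    nnls_tol: float = 1e-6
    nnls_max_iter: int = 10_000
    bootstrap_iterations: int = 1000
    permutation_iterations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nnls_tol <= 0:
            raise ValueError("nnls_tol must be > 0")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.coverage_mb <= 0:
            raise ValueError("coverage_mb must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Durable-benefit labelling
# ---------------------------------------------------------------------------

def derive_db_label(pfs_weeks: float, event: bool,
                    cutoff_weeks: float = DB_CUTOFF_WEEKS) -> str:
    """Durable-benefit label from PFS and the progression/death flag.

    ``yes`` when PFS reached the cutoff (censoring after the cutoff still
    proves benefit), ``no`` when progression occurred before it, and
    ``unknown`` when the patient was censored before the cutoff.
    """
    if pfs_weeks < 0:
        raise ValueError("pfs_weeks must be non-negative")
    if pfs_weeks >= cutoff_weeks:
        return "yes"
    return "no" if event else "unknown"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variants(path: str | Path, sample_id: str,
                  nonsyn_flag: str = "NONSYN",
                  gene_key: str = "GENE") -> list[VariantRecord]:
    """Read somatic variant calls for one sample from a VCF 4.x file.

    Multi-allelic sites are split into one record per ALT allele; records
    that carry a FILTER other than PASS/``.`` are excluded. The
    nonsynonymous status is taken from the INFO flag ``nonsyn_flag`` when
    that key is declared in the header; otherwise all records are treated
    as nonsynonymous (the input is assumed pre-filtered to coding calls).
    """
    import pysam

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed VCF header in {path}: {exc}") from exc

    flag_declared = nonsyn_flag in vcf.header.info
    gene_declared = gene_key in vcf.header.info
    records: list[VariantRecord] = []
    n_filtered = 0
    with vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                n_filtered += 1
                continue
            if rec.alts is None:
                continue
            nonsyn = bool(rec.info.get(nonsyn_flag, False)) if flag_declared else True
            gene = rec.info.get(gene_key) if gene_declared else None
            if isinstance(gene, tuple):
                gene = gene[0]
            for alt in rec.alts:
                records.append(VariantRecord(
                    sample_id=sample_id, chrom=rec.chrom, pos=rec.pos,
                    ref=rec.ref, alt=alt, is_nonsynonymous=nonsyn, gene=gene,
                ))
    if n_filtered:
        logger.info("%s: excluded %d non-PASS records", path.name, n_filtered)
    return records


# ---------------------------------------------------------------------------
# Signature catalog
# ---------------------------------------------------------------------------

def read_signature_catalog(path: str | Path, artefacts: Iterable[str] = (),
                           channel_column: str = "Type"):
    """Load a COSMIC-layout signature catalog TSV.

    The file has channel labels in `channel_column` and one column per
    signature; each signature's probabilities must sum to 1 within 1e-3
    (they are renormalised exactly). Channels are keyed by label string —
    downstream algebra joins on labels, never on column order, because
    the channel ordering of catalog releases varies.
    """
    from .refit import SignatureCatalog

    df = pd.read_csv(path, sep="\t")
    if channel_column not in df.columns:
        raise ValueError(f"catalog is missing the {channel_column!r} column")
    df = df.set_index(channel_column)
    if df.index.duplicated().any():
        raise ValueError("duplicate channel labels in catalog")
    if (df.values < 0).any():
        raise ValueError("negative entry in signature catalog")
    profiles = df.T  # signatures x channels
    sums = profiles.sum(axis=1)
    off = (sums - 1.0).abs()
    if (off > 1e-3).any():
        bad = sums[off > 1e-3]
        raise ValueError(f"signature columns do not sum to 1: {bad.to_dict()}")
    profiles = profiles.div(sums, axis=0)
    return SignatureCatalog(profiles=profiles, artefacts=frozenset(artefacts))


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path, cutoff_weeks: float = DB_CUTOFF_WEEKS) -> pd.DataFrame:
    """Read the clinical cohort CSV and derive the durable-benefit label.

    Required columns: ``sample_id``, ``pfs_weeks``, ``event``. Optional
    covariates (prior_therapy, smoking, purity, age, cohort) pass through.
    Records with missing PFS are rejected with a logged warning. Any
    ``db_label`` column in the file is ignored and re-derived.
    """
    df = pd.read_csv(path)
    for col in ("sample_id", "pfs_weeks", "event"):
        if col not in df.columns:
            raise ValueError(f"cohort table is missing required column {col!r}")
    missing = df["pfs_weeks"].isna()
    if missing.any():
        for sid in df.loc[missing, "sample_id"]:
            logger.warning("cohort record %s rejected: missing PFS", sid)
        df = df.loc[~missing].copy()
    df["event"] = df["event"].astype(bool)
    df["db_label"] = [
        derive_db_label(p, e, cutoff_weeks)
        for p, e in zip(df["pfs_weeks"].astype(float), df["event"])
    ]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def write_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    """Write a labelled matrix (samples as rows) as TSV, 12 significant digits."""
    matrix.to_csv(path, sep="\t", float_format="%.12g", index_label="sample")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_spectrum(path: str | Path, system: str = "SBS-96"):
    """Read a precomputed mutation-spectrum TSV (samples x channels)."""
    from .spectrum import MutationSpectrum

    return MutationSpectrum(counts=read_matrix(path), system=system)
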