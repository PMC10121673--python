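"""Fixed-catalog signature refitting, attribution normalisation and
per-variant signature responsibilities.

Given a mutation spectrum X (samples x channels) and a fixed catalog of
signature profiles H (signatures x channels, rows summing to 1), the
attribution W >= 0 minimising ||X - W.H||^2 is found per sample by cyclic
coordinate descent — the problem decouples across samples because H is
fixed, so each row is an independent non-negative least-squares fit.

Attributions and tumor mutational burden (TMB) are reported per megabase
of covered sequence, rounded half-away-from-zero to two decimals.
A variant's *responsibility* vector splits its channel's reconstructed
intensity across signatures; a signature is *dominant* for the variant
when it carries at least half of that mass.
"""

from __future__ import annotations

import dataclasses
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import logger
from .spectrum import MutationSpectrum

DOMINANCE_THRESHOLD = 0.5


def round_half_away(x, decimals: int = 2):
    """Round half away from zero (0.625 -> 0.63 at two decimals).

    Uses decimal arithmetic on the shortest repr so that values that are
    exact in decimal round by their printed digits, not their binary
    representation. Accepts scalars or arrays.
    """
    def _scalar(v: float) -> float:
        if not np.isfinite(v):
            return float(v)
        q = Decimal(1).scaleb(-decimals)
        d = Decimal(repr(float(v)))
        return float(d.copy_abs().quantize(q, rounding=ROUND_HALF_UP)
                     * (1 if v >= 0 else -1))

    if np.isscalar(x):
        return _scalar(x)
    arr = np.asarray(x, dtype=float)
    return np.frompyfunc(_scalar, 1, 1)(arr).astype(float)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SignatureCatalog:
    """Signature x channel probability matrix with per-signature artefact flags."""

    profiles: pd.DataFrame
    artefacts: frozenset = frozenset()

    def __post_init__(self) -> None:
        if (self.profiles.values < 0).any():
            raise ValueError("negative entry in signature profiles")
        sums = self.profiles.sum(axis=1)
        if ((sums - 1.0).abs() > 1e-6).any():
            raise ValueError("signature rows must sum to 1 (renormalise at load time)")

    @property
    def signatures(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def channels(self) -> list[str]:
        return list(self.profiles.columns)


@dataclasses.dataclass
class AttributionMatrix:
    """Per-sample signature activities, raw and per-megabase."""

    counts: pd.DataFrame            # samples x signatures, mutations attributed
    per_mb: pd.DataFrame            # counts / coverage, 2 decimals
    coverage_mb: pd.Series          # per sample
    tmb: pd.Series | None = None    # nonsynonymous mutations per Mb, 2 decimals


# ---------------------------------------------------------------------------
# Refitting
# ---------------------------------------------------------------------------

def _refit_row(x: np.ndarray, H: np.ndarray, G: np.ndarray,
               tol: float, max_iter: int) -> np.ndarray:
    """NNLS for one sample by cyclic coordinate descent.

    Minimises f(w) = ||x - wH||^2 over w >= 0. The coordinate update
    w_s <- max(0, w_s - g_s / G_ss) with g the half-gradient (wG - b) is
    the exact single-coordinate minimiser. Stops when the relative
    objective decrease over a full sweep falls below `tol`, or after
    `max_iter` sweeps. The objective is non-increasing by construction;
    this is asserted per sweep.
    """
    p = H.shape[0]
    b = H @ x
    # Unconstrained least-squares projection, clipped: affects speed only
    # (the problem is convex), but starts near the optimum.
    try:
        w = np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        w = np.linalg.pinv(G) @ b
    w = np.maximum(w, 0.0)

    xx = x @ x

    def objective(w: np.ndarray) -> float:
        return xx - 2.0 * (w @ b) + w @ G @ w

    f_prev = objective(w)
    for _ in range(max_iter):
        for s in range(p):
            g_s = w @ G[:, s] - b[s]
            w[s] = max(0.0, w[s] - g_s / G[s, s])
        f = objective(w)
        drop = f_prev - f
        assert drop >= -1e-9 * max(1.0, abs(f_prev)), "objective increased"
        if drop <= tol * max(abs(f_prev), 1e-300):
            break
        f_prev = f
    return w


def refit(spectrum: MutationSpectrum, catalog: SignatureCatalog,
          coverage_mb: float | pd.Series = 47.9,
          tol: float = 1e-6, max_iter: int = 10_000) -> AttributionMatrix:
    """Non-negative refit of a spectrum against a fixed catalog.

    Channels are aligned by label; the spectrum must provide every channel
    the catalog defines. `coverage_mb` may be a scalar or a per-sample
    Series (per-sample exome sizes).
    """
    missing = set(catalog.channels) - set(spectrum.channels)
    if missing:
        raise ValueError(f"spectrum lacks catalog channels: {sorted(missing)[:5]} ...")
    X = spectrum.counts[catalog.channels].to_numpy(dtype=float)
    H = catalog.profiles.to_numpy(dtype=float)
    G = H @ H.T
    if np.any(np.diag(G) == 0):
        zero = [catalog.signatures[i] for i in np.flatnonzero(np.diag(G) == 0)]
        raise ValueError(f"all-zero signature rows: {zero}")

    W = np.vstack([_refit_row(x, H, G, tol, max_iter) for x in X])
    counts = pd.DataFrame(W, index=spectrum.samples, columns=catalog.signatures)

    if np.isscalar(coverage_mb):
        coverage = pd.Series(float(coverage_mb), index=counts.index)
    else:
        coverage = coverage_mb.reindex(counts.index).astype(float)
        if coverage.isna().any():
            raise ValueError("coverage_mb missing for some samples")
    per_mb = normalise(counts, coverage)
    total = spectrum.counts.sum(axis=1)
    return AttributionMatrix(counts=counts, per_mb=per_mb,
                             coverage_mb=coverage, tmb=tmb(total, coverage))


def normalise(w_counts: pd.DataFrame, coverage_mb) -> pd.DataFrame:
    """Per-megabase attribution: counts / coverage, two decimals."""
    if np.isscalar(coverage_mb):
        if coverage_mb <= 0:
            raise ValueError("coverage_mb must be > 0")
        out = w_counts / float(coverage_mb)
    else:
        cov = pd.Series(coverage_mb).astype(float)
        if (cov <= 0).any():
            raise ValueError("coverage_mb must be > 0")
        out = w_counts.div(cov, axis=0)
    return out.apply(lambda col: round_half_away(col.to_numpy(), 2))


def tmb(variant_counts, coverage_mb):
    """Tumor mutational burden: nonsynonymous mutations per megabase."""
    counts = pd.Series(variant_counts, dtype=float)
    cov = (pd.Series(coverage_mb, index=counts.index, dtype=float)
           if np.isscalar(coverage_mb) else pd.Series(coverage_mb).astype(float))
    if (cov <= 0).any():
        raise ValueError("coverage_mb must be > 0")
    return (counts / cov).map(lambda v: round_half_away(v, 2))


# ---------------------------------------------------------------------------
# Signature filtering
# ---------------------------------------------------------------------------

def filter_signatures(attribution: AttributionMatrix, catalog: SignatureCatalog,
                      db_labels: pd.Series) -> tuple[AttributionMatrix, SignatureCatalog]:
    """Drop artefact-flagged signatures and those with zero variance in
    either durable-benefit stratum of the discovery labels.

    Samples with an unknown label are excluded from the variance
    computation. Each stratum needs at least two samples.
    """
    labels = db_labels.reindex(attribution.per_mb.index)
    keep: list[str] = []
    strata = {lab: attribution.per_mb.loc[labels == lab] for lab in ("yes", "no")}
    for lab, block in strata.items():
        if len(block) < 2:
            raise ValueError(f"stratum {lab!r} has < 2 samples; variance undefined")
    for sig in attribution.per_mb.columns:
        if sig in catalog.artefacts:
            logger.info("dropping artefact-flagged signature %s", sig)
            continue
        if any(strata[lab][sig].to_numpy().var() == 0.0 for lab in strata):
            logger.info("dropping zero-variance signature %s", sig)
            continue
        keep.append(sig)
    reduced = AttributionMatrix(
        counts=attribution.counts[keep],
        per_mb=attribution.per_mb[keep],
        coverage_mb=attribution.coverage_mb,
        tmb=attribution.tmb,
    )
    return reduced, SignatureCatalog(profiles=catalog.profiles.loc[keep],
                                     artefacts=catalog.artefacts)


# ---------------------------------------------------------------------------
# Per-variant responsibilities
# ---------------------------------------------------------------------------

def responsibilities(w_row: pd.Series, catalog: SignatureCatalog,
                     channel: str) -> tuple[pd.Series, list[str]] | None:
    """Split one variant's channel intensity across signatures.

    r_s = w_s * H[s, channel] / sum_t w_t * H[t, channel]. Signatures with
    r_s >= 0.5 are dominant; an exact tie at 0.5 reports both (logged).
    Returns ``None`` when the reconstructed intensity at the channel is
    zero (the variant is unattributable).
    """
    h_col = catalog.profiles[channel]
    mass = w_row.reindex(h_col.index).to_numpy() * h_col.to_numpy()
    total = mass.sum()
    if total <= 0:
        return None
    r = pd.Series(mass / total, index=h_col.index)
    dominant = list(r.index[r >= DOMINANCE_THRESHOLD])
    if len(dominant) > 1:
        logger.info("responsibility tie at channel %s: %s", channel, dominant)
    return r, dominant


def responsibility_table(records, reference, attribution: AttributionMatrix,
                         catalog: SignatureCatalog) -> pd.DataFrame:
    """Per-variant responsibilities for a list of SNV records.

    One row per attributable variant with the responsibility of each
    signature and the dominant signature(s) (comma-joined); variants whose
    channel has zero reconstructed intensity are flagged unattributed.
    """
    from .spectrum import classify_sbs96

    rows = []
    for rec in records:
        if not rec.is_snv:
            continue
        channel = classify_sbs96(rec, reference)
        if channel is None:
            continue
        entry = {"sample_id": rec.sample_id, "chrom": rec.chrom, "pos": rec.pos,
                 "channel": channel}
        result = responsibilities(attribution.counts.loc[rec.sample_id],
                                  catalog, channel)
        if result is None:
            entry["dominant"] = ""
            entry["attributed"] = False
        else:
            r, dominant = result
            entry.update(r.to_dict())
            entry["dominant"] = ",".join(dominant)
            entry["attributed"] = True
        rows.append(entry)
    return pd.DataFrame(rows)
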