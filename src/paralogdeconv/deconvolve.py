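"""Estimate per-copy expression shares from marker allele fractions.

The estimator mirrors the marker-averaging procedure used for multi-copy
gene deconvolution: at every diagnostic marker position the fraction of
aligned bases carrying a class's allele estimates that class's share of
total expression; shares are obtained by averaging a class's marker allele
fractions and renormalizing across classes to 100%.  Markers at positions
whose total read depth falls below a threshold (default 150) are excluded
before averaging.  Total-gene TPM (quantified externally, e.g. by Salmon)
is then partitioned among the classes in proportion to their shares.

A non-negative least-squares fit over the same marker matrix is provided
as an independent cross-check of the averaging estimator; it is not the
production path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .markers import AttributionClass, MarkerSet, MarkerSite, attribution_classes
from .pileup import BASES, PileupProfile

DEFAULT_MIN_DEPTH = 150


class EstimationError(RuntimeError):
    """Raised when no composition estimate can be formed."""


@dataclass(frozen=True)
class MarkerEvidence:
    """One (position, allele) observation feeding a class estimate."""

    position: int
    class_label: str
    allele: str
    depth: int
    allele_fraction: float
    passed_filter: bool


@dataclass
class CompositionEstimate:
    """Percent of total expression attributed to each class.

    ``per_class_percent`` maps class label to a percent in [0, 100], or to
    ``None`` ("missing") for classes with no marker above the depth
    threshold — distinct from an estimated zero.  ``raw_means`` holds the
    pre-normalization mean allele fractions; with overlapping classes
    (e.g. a shared group alongside one of its members) raw means need not
    sum to 1, and both views are kept.
    """

    per_class_percent: dict[str, float | None]
    evidence: list[MarkerEvidence]
    markers_used: int
    markers_filtered: int
    raw_means: dict[str, float | None]

    def present_classes(self) -> list[str]:
        return [c for c, v in self.per_class_percent.items() if v is not None]


@dataclass
class AbundancePartition:
    """Total-gene TPM split among attribution classes by composition."""

    total_tpm: float
    per_class_tpm: dict[str, float | None]


def filter_markers(
    ms: MarkerSet, p: PileupProfile, min_depth: int = DEFAULT_MIN_DEPTH
) -> tuple[list[MarkerSite], list[tuple[MarkerSite, int]]]:
    """Split marker sites into usable and rejected by total site depth.

    A site is usable iff the pileup depth at its position is >= min_depth;
    a site at exactly the threshold is kept ("fall below" reading).
    Rejected sites are returned with their observed depths.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    depth = p.depth
    usable: list[MarkerSite] = []
    rejected: list[tuple[MarkerSite, int]] = []
    for site in ms.sites:
        d = int(depth[site.position - 1]) if site.position <= p.length else 0
        if d >= min_depth:
            usable.append(site)
        else:
            rejected.append((site, d))
    return usable, rejected


def _allele_fraction(p: PileupProfile, position: int, base: str) -> tuple[int, float]:
    row = p.counts[position - 1]
    d = int(row.sum())
    if d == 0:
        return 0, 0.0
    return d, float(row[BASES.index(base)]) / d


def estimate_composition(
    ms: MarkerSet, p: PileupProfile, min_depth: int = DEFAULT_MIN_DEPTH
) -> CompositionEstimate:
    """Average marker allele fractions per class and renormalize to 100%.

    For each attribution class the raw mean is the arithmetic mean, over
    its usable diagnostic (position, base) pairs, of that base's fraction
    of the site depth.  Percents renormalize the raw means to sum to 100
    across classes with at least one usable marker; classes with none are
    reported as missing (``None``).  Evidence rows are retained for every
    marker, including filtered ones.
    """
    classes = attribution_classes(ms)
    usable, rejected = filter_markers(ms, p, min_depth)
    usable_pos = {s.position for s in usable}
    if not usable_pos:
        raise EstimationError(
            f"no markers above depth threshold (min_depth={min_depth}, "
            f"{len(rejected)} site(s) rejected)"
        )

    evidence: list[MarkerEvidence] = []
    raw_means: dict[str, float | None] = {}
    for cls in classes:
        fracs: list[float] = []
        for pos, base in cls.diagnostic_sites:
            d, f = _allele_fraction(p, pos, base)
            passed = pos in usable_pos
            evidence.append(
                MarkerEvidence(
                    position=pos,
                    class_label=cls.label,
                    allele=base,
                    depth=d,
                    allele_fraction=f,
                    passed_filter=passed,
                )
            )
            if passed:
                fracs.append(f)
        raw_means[cls.label] = float(np.mean(fracs)) if fracs else None

    total = sum(v for v in raw_means.values() if v is not None)
    if total <= 0:
        raise EstimationError(
            "all marker allele fractions are zero; cannot normalize composition"
        )
    per_class_percent = {
        label: (None if v is None else 100.0 * v / total)
        for label, v in raw_means.items()
    }
    return CompositionEstimate(
        per_class_percent=per_class_percent,
        evidence=evidence,
        markers_used=len(usable),
        markers_filtered=len(rejected),
        raw_means=raw_means,
    )


def nnls_oracle(
    ms: MarkerSet, p: PileupProfile, min_depth: int = DEFAULT_MIN_DEPTH
) -> dict[str, float | None]:
    """Independent composition estimate via non-negative least squares.

    Solves min ||A x - f||^2, x >= 0, where rows are usable (position,
    base) marker pairs, A[row, class] = 1 when that pair is diagnostic of
    the class, and f holds the observed allele fractions.  The solution is
    renormalized to 100.  Classes with no usable marker (an all-zero
    design column) are reported missing.
    """
    classes = attribution_classes(ms)
    usable, _ = filter_markers(ms, p, min_depth)
    usable_pos = {s.position for s in usable}

    rows: list[np.ndarray] = []
    fracs: list[float] = []
    for ci, cls in enumerate(classes):
        for pos, base in cls.diagnostic_sites:
            if pos not in usable_pos:
                continue
            _, f = _allele_fraction(p, pos, base)
            row = np.zeros(len(classes))
            row[ci] = 1.0
            rows.append(row)
            fracs.append(f)
    if not rows:
        raise EstimationError("no markers above depth threshold")
    A = np.vstack(rows)
    f = np.asarray(fracs)
    live = A.any(axis=0)
    x = np.zeros(len(classes))
    x[live], _ = nnls(A[:, live], f)
    total = x.sum()
    if total <= 0:
        raise EstimationError("NNLS solution is identically zero")
    out: dict[str, float | None] = {}
    for ci, cls in enumerate(classes):
        out[cls.label] = 100.0 * x[ci] / total if live[ci] else None
    return out


def partition_abundance(
    c: CompositionEstimate, total_tpm: float
) -> AbundancePartition:
    """Scale class percents by the sample's total-gene TPM."""
    if total_tpm < 0:
        raise ValueError(f"total_tpm must be >= 0, got {total_tpm}")
    per_class_tpm = {
        label: (None if pct is None else pct / 100.0 * total_tpm)
        for label, pct in c.per_class_percent.items()
    }
    return AbundancePartition(total_tpm=float(total_tpm), per_class_tpm=per_class_tpm)


def tpm_from_counts(counts, effective_lengths) -> np.ndarray:
    """Naive transcripts-per-million from read counts and effective lengths.

    rate_i = counts_i / eff_len_i; TPM_i = rate_i / sum(rates) * 1e6.
    Intended for fully synthetic end-to-end tests, not as a substitute for
    a real quantifier.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(effective_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be > 0")
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        warnings.warn("all-zero counts: TPM vector is all zero", stacklevel=2)
        return np.zeros_like(rates)
    return rates / total * 1e6
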