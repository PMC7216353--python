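"""Per-position base composition of reads aligned to one reference transcript.

All reads in the input were mapped against a single paralog's transcript,
so the pileup is a dense length x 4 count matrix over A/C/G/T.  Only
aligned match-state bases are counted: insertions, deletion-spanned
positions and soft clips contribute nothing, and ambiguous 'N' bases are
excluded from both counts and depth so that base fractions over the four
nucleotides sum to one.  No deduplication and, by default, no base- or
mapping-quality filtering is applied; thresholds are available as optional
arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class PileupConfigError(ValueError):
    """Raised when the requested reference is absent from the alignment header."""


class PileupMergeError(ValueError):
    """Raised when profiles over different references are merged."""


@dataclass
class PileupProfile:
    """Counts of aligned A/C/G/T bases at every reference position.

    ``counts`` has shape (length, 4), columns ordered A, C, G, T; row i is
    1-based position i+1.
    """

    reference_name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must have shape (length, 4)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class BaseFractionProfile:
    """Per-position fractions of each base among aligned reads.

    Rows sum to 1 wherever depth > 0 and are all-zero at uncovered
    positions (the ``depth`` vector flags which is which).
    """

    reference_name: str
    fractions: np.ndarray
    depth: np.ndarray


def build_pileup(
    alignments: str | Path,
    reference_name: str,
    reference_length: int | None = None,
    *,
    min_base_quality: int = 0,
    min_mapping_quality: int = 0,
) -> PileupProfile:
    """Tally aligned bases from a SAM/BAM file into a PileupProfile.

    Unmapped, secondary and supplementary records are skipped, as are
    records mapped to other references.  A record that cannot be processed
    is skipped with a warning naming it; the total skip count is logged.

    Parameters
    ----------
    alignments:
        Path to a SAM or BAM file (sorting and indexing not required).
    reference_name:
        Name of the reference transcript; must be present in the header.
    reference_length:
        Optional override; defaults to the header @SQ length.
    min_base_quality, min_mapping_quality:
        Optional thresholds, both 0 (off) by default.
    """
    path = str(alignments)
    with pysam.AlignmentFile(path, check_sq=False, require_index=False) as af:
        if reference_name not in (af.references or ()):
            raise PileupConfigError(
                f"reference {reference_name!r} not found in header of {path} "
                f"(has: {', '.join(af.references or ())})"
            )
        if reference_length is None:
            reference_length = af.get_reference_length(reference_name)
        counts = np.zeros((reference_length, 4), dtype=np.int64)
        tid = af.get_tid(reference_name)
        n_malformed = 0
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_id != tid:
                continue
            if min_mapping_quality and rec.mapping_quality < min_mapping_quality:
                continue
            try:
                pairs = rec.get_aligned_pairs(matches_only=True)
                seq = rec.query_sequence
            except (ValueError, TypeError) as exc:
                n_malformed += 1
                logger.warning("skipping record %s: %s", rec.query_name, exc)
                continue
            if seq is None or not pairs:
                n_malformed += 1
                logger.warning("skipping record %s: no sequence/CIGAR", rec.query_name)
                continue
            quals = rec.query_qualities if min_base_quality else None
            for qpos, rpos in pairs:
                if rpos >= reference_length:
                    continue
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                idx = _BASE_INDEX.get(seq[qpos])
                if idx is not None:  # 'N' and other ambiguity codes excluded
                    counts[rpos, idx] += 1
        if n_malformed:
            logger.warning("%d record(s) skipped as unprocessable in %s", n_malformed, path)
    return PileupProfile(reference_name=reference_name, counts=counts)


def base_fractions(p: PileupProfile) -> BaseFractionProfile:
    """Convert counts to per-position base fractions (0 rows where depth 0)."""
    depth = p.depth
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth[:, None] > 0, p.counts / depth[:, None], 0.0)
    return BaseFractionProfile(
        reference_name=p.reference_name, fractions=frac, depth=depth
    )


def merge_pileups(profiles: list[PileupProfile]) -> PileupProfile:
    """Element-wise sum of count matrices over identical references."""
    if not profiles:
        raise ValueError("no profiles to merge")
    first = profiles[0]
    for other in profiles[1:]:
        if (
            other.reference_name != first.reference_name
            or other.length != first.length
        ):
            raise PileupMergeError(
                f"cannot merge pileups over {first.reference_name!r} "
                f"(length {first.length}) and {other.reference_name!r} "
                f"(length {other.length})"
            )
    total = np.sum([p.counts for p in profiles], axis=0)
    return PileupProfile(reference_name=first.reference_name, counts=total)


def mean_depth(
    p: PileupProfile, interval: tuple[int, int] | None = None
) -> float:
    """Arithmetic mean depth over an inclusive 1-based interval (default: all)."""
    if interval is None:
        start, end = 1, p.length
    else:
        start, end = interval
    if start < 1 or end > p.length or end < start:
        raise ValueError(
            f"empty or out-of-range interval [{start}, {end}] on length {p.length}"
        )
    return float(p.depth[start - 1 : end].mean())


def variable_positions(
    p: PileupProfile, min_depth: int = 1, min_minor_count: int = 1
) -> list[int]:
    """1-based positions showing base variation among aligned reads.

    A position qualifies when its depth is >= ``min_depth`` and at least two
    distinct bases each reach ``min_minor_count`` reads.  Defaults are the
    most permissive (any second base at any covered position); the
    thresholds defining a real dataset's "variable" count are a user choice.
    """
    if min_depth < 0 or min_minor_count < 0:
        raise ValueError("thresholds must be >= 0")
    depth_ok = p.depth >= min_depth
    n_alleles = (p.counts >= min_minor_count).sum(axis=1)
    mask = depth_ok & (n_alleles >= 2)
    return [int(i) + 1 for i in np.nonzero(mask)[0]]


# ---------------------------------------------------------------------------
# TSV round trip

def write_pileup(p: PileupProfile, path: str | Path) -> None:
    """Write as TSV `position depth A C G T` with a ##reference pragma."""
    lines = [
        f"##reference={p.reference_name}",
        "position\tdepth\tA\tC\tG\tT",
    ]
    depth = p.depth
    for i in range(p.length):
        row = "\t".join(str(int(c)) for c in p.counts[i])
        lines.append(f"{i + 1}\t{int(depth[i])}\t{row}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pileup(path: str | Path) -> PileupProfile:
    reference = ""
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##reference="):
                reference = line.split("=", 1)[1]
                continue
            if not line or line.startswith("#") or line.startswith("position"):
                continue
            fields = line.split("\t")
            rows.append([int(x) for x in fields[2:6]])
    return PileupProfile(reference_name=reference, counts=np.array(rows, dtype=np.int64))


def write_fractions(f: BaseFractionProfile, path: str | Path) -> None:
    """Write base fractions as TSV with 6-decimal fixed-point values."""
    lines = [
        f"##reference={f.reference_name}",
        "position\tdepth\tA\tC\tG\tT",
    ]
    for i in range(f.fractions.shape[0]):
        row = "\t".join(f"{x:.6f}" for x in f.fractions[i])
        lines.append(f"{i + 1}\t{int(f.depth[i])}\t{row}")
    Path(path).write_text("\n".join(lines) + "\n")
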