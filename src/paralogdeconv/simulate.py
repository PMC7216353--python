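"""Synthetic paralog families and error-bearing reads with known truth.

The generator emulates the structure that makes multi-copy gene
deconvolution testable end to end: a reference transcript (paralog #1), a
family of near-identical copies differing only at diagnostic marker
positions, and reads drawn from a known mixture of copies at configurable
depth and per-base substitution error rate.  Reads are "truth-aligned" —
each is placed against the reference copy at its true start with a gapless
CIGAR, so a marker substitution in a read appears as a mismatch in the
pileup, exactly the signal the composition estimator consumes.  No aligner
runs in the loop; FASTQ output is available for users who want one.

Marker design: each site assigns a distinct base to every distinguishable
unit (each individually resolvable paralog, and a shared group as one
block), so the allele images at every site partition the family into the
same attribution classes.  At most four units can be separated at one site
(four nucleotides); requesting more is an error.  A ``shared_group``
configuration reserves a number of shared-only sites where the group is a
single block; any remaining sites separate the group members individually,
producing the group-vs-member overlap seen in real marker panels.

The error model is substitution-only, uniform over the three alternative
bases; no indels, no quality-dependent errors (base qualities are written
as constant Q30).  All randomness flows from a single integer seed through
one numpy Generator, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .markers import MarkerSet, MarkerSite, attribution_classes, save_markers

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_Q30 = "?"  # phred 30 in phred+33


@dataclass
class FamilyConfig:
    """Shape of a synthetic paralog family.

    shared_group, when given, is (group_size, n_shared_only_sites): the
    last ``group_size`` paralogs share an allele at ``n_shared_only_sites``
    of the marker sites and are separated individually at the rest.
    """

    n_paralogs: int = 4
    transcript_length: int = 600
    n_marker_sites: int = 8
    shared_group: tuple[int, int] | None = None
    gc_fraction: float = 0.5
    seed: int = 0
    paralog_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_paralogs < 2:
            raise ValueError("need at least 2 paralogs")
        if self.n_marker_sites > self.transcript_length:
            raise ValueError("more marker sites than transcript positions")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.shared_group is not None:
            g, s = self.shared_group
            if not 2 <= g <= self.n_paralogs - 1:
                raise ValueError("group size must be in [2, n_paralogs-1]")
            if not 0 <= s <= self.n_marker_sites:
                raise ValueError("shared-only site count out of range")


@dataclass
class ReadSimConfig:
    """Mixture, depth and error settings for one simulated sample."""

    proportions: dict[str, float]
    n_reads: int
    read_length: int = 50
    error_rate: float = 0.0
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        vals = np.array(list(self.proportions.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("proportions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {vals.sum()}")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.paired and self.n_reads % 2:
            raise ValueError("paired mode requires an even n_reads")


@dataclass
class SimulationFamily:
    """A generated paralog family: sequences plus the derived marker set."""

    reference_name: str
    sequences: dict[str, str]
    markers: MarkerSet
    group_members: frozenset[str] | None = None

    @property
    def transcript_length(self) -> int:
        return len(self.sequences[self.reference_name])

    def write_fasta(self, path: str | Path) -> None:
        lines: list[str] = []
        for name, seq in self.sequences.items():
            lines.append(f">{name}")
            lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class SimulationTruth:
    """Everything needed to score a synthetic run against ground truth.

    ``ledger`` has one row per emitted read record: name, mate (0 for
    unpaired, 1/2 for pairs), source paralog, 1-based start on the
    reference, and the introduced errors as (read offset, from, to) base
    triples on the reference-forward strand.  ``read_matrix`` /
    ``record_starts`` keep the final read bases in memory (base indices
    into "ACGT", 0-based starts) for fast exact pileup reconstruction.
    """

    family: SimulationFamily
    config: ReadSimConfig
    proportions: dict[str, float]
    ledger: list[dict] = field(default_factory=list)
    read_matrix: np.ndarray | None = None
    record_starts: np.ndarray | None = None

    def source_counts(self) -> dict[str, int]:
        out: dict[str, int] = {name: 0 for name in self.family.sequences}
        for row in self.ledger:
            out[row["source"]] += 1
        return out

    def total_errors(self) -> int:
        return sum(len(row["errors"]) for row in self.ledger)


# ---------------------------------------------------------------------------
# family generation

def _seq_to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy().view(np.uint8)


def _arr_from_indices(idx: np.ndarray) -> str:
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return lut[idx].tobytes().decode()


def _default_names(cfg: FamilyConfig) -> list[str]:
    n = cfg.n_paralogs
    if cfg.shared_group is None:
        return [f"copy{i + 1}" for i in range(n)]
    g, _ = cfg.shared_group
    base = [f"copy{i + 1}" for i in range(n - g)]
    stem = f"copy{n - g + 1}"
    letters = "ABCDEFGHIJ"
    return base + [f"{stem}{letters[j]}" for j in range(g)]


def generate_paralog_family(cfg: FamilyConfig) -> SimulationFamily:
    """Generate reference + paralog sequences and the exact marker set.

    The reference is paralog #1; every other copy differs from it only at
    marker sites, by substitutions.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    names = cfg.paralog_names or _default_names(cfg)
    if len(names) != cfg.n_paralogs or len(set(names)) != cfg.n_paralogs:
        raise ValueError("paralog_names must be unique and match n_paralogs")
    n = cfg.n_paralogs

    if cfg.shared_group is not None:
        g, n_shared = cfg.shared_group
        group = names[n - g :]
    else:
        g, n_shared = 0, 0
        group = []

    # distinguishable units at a shared-only site: non-group singletons + group
    if g:
        n_units_shared = (n - g) + 1
        if n_units_shared > 4:
            raise ValueError(
                f"shared-only sites would need {n_units_shared} distinct alleles; "
                "at most 4 are possible"
            )
    if n_shared < cfg.n_marker_sites and n > 4:
        raise ValueError(
            f"fully separating sites would need {n} distinct alleles; "
            "at most 4 are possible"
        )

    # reference sequence with the requested GC content
    p_base = np.array(
        [
            (1 - cfg.gc_fraction) / 2,
            cfg.gc_fraction / 2,
            cfg.gc_fraction / 2,
            (1 - cfg.gc_fraction) / 2,
        ]
    )
    L = cfg.transcript_length
    ref_idx = rng.choice(4, size=L, p=p_base)

    positions = np.sort(rng.choice(L, size=cfg.n_marker_sites, replace=False)) + 1
    shared_flags = np.zeros(cfg.n_marker_sites, dtype=bool)
    if g and n_shared:
        shared_flags[rng.choice(cfg.n_marker_sites, size=n_shared, replace=False)] = True

    seq_idx = {name: ref_idx.copy() for name in names}
    cds_lo, cds_hi = int(0.2 * L), int(0.8 * L)
    sites: list[MarkerSite] = []
    for k, pos in enumerate(positions):
        ref_base_i = int(ref_idx[pos - 1])
        if g and shared_flags[k]:
            blocks = [[nm] for nm in names[: n - g]] + [list(group)]
        else:
            blocks = [[nm] for nm in names]
        # block containing the reference copy keeps the reference base;
        # other blocks get distinct alternative bases
        alts = [b for b in range(4) if b != ref_base_i]
        order = rng.permutation(3)
        allele_map: dict[str, frozenset[str]] = {}
        alt_cursor = 0
        for block in blocks:
            if names[0] in block:
                base_i = ref_base_i
            else:
                base_i = alts[order[alt_cursor]]
                alt_cursor += 1
            allele_map[BASES[base_i]] = frozenset(block)
            for nm in block:
                seq_idx[nm][pos - 1] = base_i
        sites.append(
            MarkerSite(
                position=int(pos),
                allele_map=allele_map,
                in_coding=bool(cds_lo <= pos - 1 < cds_hi),
            )
        )

    markers = MarkerSet(
        reference_name=names[0],
        reference_length=L,
        paralogs=list(names),
        sites=sites,
    )
    sequences = {nm: _arr_from_indices(seq_idx[nm]) for nm in names}
    return SimulationFamily(
        reference_name=names[0],
        sequences=sequences,
        markers=markers,
        group_members=frozenset(group) if group else None,
    )


# ---------------------------------------------------------------------------
# read simulation

def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def simulate_reads(
    family: SimulationFamily,
    cfg: ReadSimConfig,
    out_dir: str | Path,
    prefix: str = "reads",
) -> SimulationTruth:
    """Draw reads from the mixture, write FASTQ + truth SAM, return truth.

    Each read chooses a source paralog with probability equal to its
    mixture proportion, a uniform start such that the read (or, paired,
    the zero-gap two-read fragment) fits, copies the paralog sequence, and
    applies independent per-base substitution errors.  The truth SAM
    places every record at its true start against the reference paralog
    with a gapless CIGAR.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    L = family.transcript_length
    rl = cfg.read_length
    span = 2 * rl if cfg.paired else rl
    if span > L:
        raise ValueError(f"read span {span} exceeds transcript length {L}")

    names = [nm for nm in family.sequences]
    p = np.array([cfg.proportions.get(nm, 0.0) for nm in names])
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must cover the family's paralogs and sum to 1")
    seq_arrs = {
        nm: np.array([BASES.index(b) for b in seq], dtype=np.uint8)
        for nm, seq in family.sequences.items()
    }

    n_frag = cfg.n_reads // 2 if cfg.paired else cfg.n_reads
    if n_frag:
        src = rng.choice(len(names), size=n_frag, p=p)
        starts = rng.integers(0, L - span + 1, size=n_frag)
    else:
        src = np.zeros(0, dtype=int)
        starts = np.zeros(0, dtype=int)

    segs = np.empty((n_frag, span), dtype=np.uint8)
    offsets = np.arange(span)
    for k, nm in enumerate(names):
        rows = np.nonzero(src == k)[0]
        if rows.size:
            segs[rows] = seq_arrs[nm][starts[rows, None] + offsets]

    orig = segs.copy()
    if cfg.error_rate > 0 and n_frag:
        mask = rng.random((n_frag, span)) < cfg.error_rate
        shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        segs[mask] = (segs[mask] + shifts) % 4
    else:
        mask = np.zeros((n_frag, span), dtype=bool)

    # assemble records
    ref = family.reference_name
    sam_lines = [
        "@HD\tVN:1.6\tSO:unknown",
        f"@SQ\tSN:{ref}\tLN:{L}",
    ]
    truth = SimulationTruth(
        family=family, config=cfg, proportions=dict(cfg.proportions)
    )
    qual = _Q30 * rl
    fastq1: list[str] = []
    fastq2: list[str] = []

    rec_seqs: list[np.ndarray] = []
    rec_starts: list[int] = []

    def _errors(i: int, lo: int, hi: int) -> list[list]:
        out = []
        for off in np.nonzero(mask[i, lo:hi])[0]:
            j = lo + int(off)
            out.append([int(off), BASES[int(orig[i, j])], BASES[int(segs[i, j])]])
        return out

    for i in range(n_frag):
        source = names[src[i]]
        start0 = int(starts[i])
        if not cfg.paired:
            name = f"read{i:06d}"
            seq = _arr_from_indices(segs[i])
            sam_lines.append(
                f"{name}\t0\t{ref}\t{start0 + 1}\t60\t{rl}M\t*\t0\t0\t{seq}\t{qual}"
            )
            fastq1.append(f"@{name}\n{seq}\n+\n{qual}")
            truth.ledger.append(
                {
                    "read": name,
                    "mate": 0,
                    "source": source,
                    "start": start0 + 1,
                    "errors": _errors(i, 0, rl),
                }
            )
            rec_seqs.append(segs[i])
            rec_starts.append(start0)
        else:
            name = f"frag{i:06d}"
            seq1 = _arr_from_indices(segs[i, :rl])
            seq2 = _arr_from_indices(segs[i, rl:])
            pos1, pos2 = start0 + 1, start0 + rl + 1
            sam_lines.append(
                f"{name}\t99\t{ref}\t{pos1}\t60\t{rl}M\t=\t{pos2}\t{span}\t{seq1}\t{qual}"
            )
            sam_lines.append(
                f"{name}\t147\t{ref}\t{pos2}\t60\t{rl}M\t=\t{pos1}\t{-span}\t{seq2}\t{qual}"
            )
            fastq1.append(f"@{name}/1\n{seq1}\n+\n{qual}")
            fastq2.append(f"@{name}/2\n{_revcomp(seq2)}\n+\n{qual}")
            truth.ledger.append(
                {
                    "read": name,
                    "mate": 1,
                    "source": source,
                    "start": pos1,
                    "errors": _errors(i, 0, rl),
                }
            )
            truth.ledger.append(
                {
                    "read": name,
                    "mate": 2,
                    "source": source,
                    "start": pos2,
                    "errors": _errors(i, rl, span),
                }
            )
            rec_seqs.append(segs[i, :rl])
            rec_seqs.append(segs[i, rl:])
            rec_starts.append(start0)
            rec_starts.append(start0 + rl)

    truth.read_matrix = (
        np.vstack(rec_seqs) if rec_seqs else np.zeros((0, rl), dtype=np.uint8)
    )
    truth.record_starts = np.array(rec_starts, dtype=np.int64)

    sam_path = out_dir / f"{prefix}.truth.sam"
    sam_path.write_text("\n".join(sam_lines) + "\n")
    if cfg.paired:
        (out_dir / f"{prefix}_1.fastq").write_text(
            "\n".join(fastq1) + ("\n" if fastq1 else "")
        )
        (out_dir / f"{prefix}_2.fastq").write_text(
            "\n".join(fastq2) + ("\n" if fastq2 else "")
        )
    else:
        (out_dir / f"{prefix}.fastq").write_text(
            "\n".join(fastq1) + ("\n" if fastq1 else "")
        )
    return truth


def pileup_counts_from_truth(truth: SimulationTruth) -> np.ndarray:
    """Exact (length x 4) pileup counts straight from the simulated reads.

    Equivalent to building a pileup from the truth SAM (reads are gapless
    and N-free), but without the file round trip; used for high-depth
    experiments.
    """
    L = truth.family.transcript_length
    counts = np.zeros((L, 4), dtype=np.int64)
    if truth.read_matrix is None or truth.read_matrix.size == 0:
        return counts
    rl = truth.read_matrix.shape[1]
    pos = truth.record_starts[:, None] + np.arange(rl)
    np.add.at(counts, (pos.ravel(), truth.read_matrix.ravel().astype(np.int64)), 1)
    return counts


# ---------------------------------------------------------------------------
# fixture battery

def write_truth_json(truth: SimulationTruth, path: str | Path) -> None:
    classes = attribution_classes(truth.family.markers)
    expected = {
        cls.label: float(
            sum(truth.proportions.get(m, 0.0) for m in cls.members)
        )
        for cls in classes
    }
    doc = {
        "reference": truth.family.reference_name,
        "transcript_length": truth.family.transcript_length,
        "paralogs": list(truth.family.sequences),
        "proportions": truth.proportions,
        "expected_class_shares": expected,
        "n_reads": truth.config.n_reads,
        "read_length": truth.config.read_length,
        "error_rate": truth.config.error_rate,
        "paired": truth.config.paired,
        "seed": truth.config.seed,
        "source_counts": truth.source_counts(),
        "total_errors": truth.total_errors(),
        "ledger": truth.ledger,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def _child_seed(seed: int, k: int) -> int:
    return (seed * 100003 + k) % (2**31)


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, dict]:
    """Write the standard synthetic battery used by the test suite.

    Four named fixtures, each in its own subdirectory with family FASTA,
    marker TSV, FASTQ, truth SAM and truth JSON:

    - ``single_copy``: four copies but all reads from one (the pattern of
      a pre-differentiation sample where a single ubiquitous copy accounts
      for 100% of reads).
    - ``mix_60_30_10``: three copies at 60/30/10, error-free, ~500x depth.
    - ``shared_group``: five copies of which three are only collectively
      distinguishable, ~1000x depth.
    - ``low_depth``: the 60/30/10 family at ~8x depth, below the default
      marker depth filter.
    """
    out_dir = Path(out_dir)
    specs: dict[str, tuple[FamilyConfig, ReadSimConfig]] = {
        "single_copy": (
            FamilyConfig(
                n_paralogs=4, transcript_length=600, n_marker_sites=8,
                seed=_child_seed(seed, 1),
            ),
            ReadSimConfig(
                proportions={"copy2": 1.0}, n_reads=2000, read_length=50,
                error_rate=0.0, seed=_child_seed(seed, 2),
            ),
        ),
        "mix_60_30_10": (
            FamilyConfig(
                n_paralogs=3, transcript_length=600, n_marker_sites=8,
                seed=_child_seed(seed, 3),
            ),
            ReadSimConfig(
                proportions={"copy1": 0.6, "copy2": 0.3, "copy3": 0.1},
                n_reads=6000, read_length=50, error_rate=0.0,
                seed=_child_seed(seed, 4),
            ),
        ),
        "shared_group": (
            FamilyConfig(
                n_paralogs=5, transcript_length=600, n_marker_sites=8,
                shared_group=(3, 8), seed=_child_seed(seed, 5),
            ),
            ReadSimConfig(
                proportions={
                    "copy1": 0.3, "copy2": 0.3,
                    "copy3A": 0.2, "copy3B": 0.1, "copy3C": 0.1,
                },
                n_reads=12000, read_length=50, error_rate=0.0,
                seed=_child_seed(seed, 6),
            ),
        ),
        "low_depth": (
            FamilyConfig(
                n_paralogs=3, transcript_length=600, n_marker_sites=8,
                seed=_child_seed(seed, 3),
            ),
            ReadSimConfig(
                proportions={"copy1": 0.6, "copy2": 0.3, "copy3": 0.1},
                n_reads=100, read_length=50, error_rate=0.0,
                seed=_child_seed(seed, 7),
            ),
        ),
    }
    manifest: dict[str, dict] = {}
    for name, (fam_cfg, read_cfg) in specs.items():
        fdir = out_dir / name
        fdir.mkdir(parents=True, exist_ok=True)
        family = generate_paralog_family(fam_cfg)
        family.write_fasta(fdir / "family.fasta")
        save_markers(family.markers, fdir / "markers.tsv")
        truth = simulate_reads(family, read_cfg, fdir)
        write_truth_json(truth, fdir / "truth.json")
        manifest[name] = {
            "dir": str(fdir),
            "fasta": str(fdir / "family.fasta"),
            "markers": str(fdir / "markers.tsv"),
            "sam": str(fdir / "reads.truth.sam"),
            "fastq": str(fdir / "reads.fastq"),
            "truth": str(fdir / "truth.json"),
        }
    return manifest
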