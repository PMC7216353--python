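"""Diagnostic single-nucleotide marker model for a multi-copy gene family.

A gene family of near-identical paralogs (e.g. the rat *Sry* copies) is
distinguished along a single reference transcript by a handful of
single-nucleotide variants.  A :class:`MarkerSet` records, for each marker
position, which base each paralog carries.  Because several paralogs may
share a base at every informative position, the unit of attribution is not
always a single copy: the distinct sets of paralogs appearing as allele
images form :class:`AttributionClass` objects, with multi-member classes
("other Sry3s"-style groups) covering copies the reads cannot separate.

Coordinates are 1-based on the reference transcript, inclusive; conversion
to 0-based happens only at the alignment-file boundary.  Only substitution
markers are modeled; indel alleles are rejected at load.
"""

from __future__ import annotations

import os.path
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

VALID_BASES = frozenset("ACGT")


class MarkerFormatError(ValueError):
    """Raised when a marker table cannot be parsed."""


class MarkerValidationError(ValueError):
    """Raised when a parsed marker table violates model invariants."""

    def __init__(self, findings: Sequence["Finding"]):
        self.findings = list(findings)
        super().__init__(
            "invalid marker set: " + "; ".join(str(f) for f in findings)
        )


@dataclass(frozen=True)
class Finding:
    """One invariant violation discovered by :func:`validate_markers`."""

    position: int | None
    message: str

    def __str__(self) -> str:
        if self.position is None:
            return self.message
        return f"position {self.position}: {self.message}"


@dataclass(frozen=True)
class MarkerSite:
    """One marker position with its base -> paralog-set allele map."""

    position: int  # 1-based on the reference transcript
    allele_map: Mapping[str, frozenset[str]]
    in_coding: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "allele_map",
            {b: frozenset(p) for b, p in dict(self.allele_map).items()},
        )

    @property
    def paralogs(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.allele_map.values():
            out |= members
        return frozenset(out)


@dataclass
class MarkerSet:
    """All diagnostic markers for one paralog family on one reference."""

    reference_name: str
    reference_length: int
    paralogs: list[str]
    sites: list[MarkerSite] = field(default_factory=list)

    def site_at(self, position: int) -> MarkerSite:
        for s in self.sites:
            if s.position == position:
                return s
        raise KeyError(f"no marker site at position {position}")


@dataclass(frozen=True)
class AttributionClass:
    """A distinguishable unit of expression: one paralog or a shared group.

    ``diagnostic_sites`` lists the (position, base) pairs whose allele image
    is exactly ``members``; their allele fractions are the evidence this
    class's share of expression is estimated from.
    """

    label: str
    members: frozenset[str]
    diagnostic_sites: tuple[tuple[int, str], ...]

    @property
    def is_group(self) -> bool:
        return len(self.members) > 1


# ---------------------------------------------------------------------------
# validation

def validate_markers(ms: MarkerSet) -> list[Finding]:
    """Check every model invariant; return one finding per violation.

    An empty list means the set is valid.  Findings carry the offending
    position where one exists.
    """
    findings: list[Finding] = []
    declared = set(ms.paralogs)

    if not ms.reference_name:
        findings.append(Finding(None, "empty reference name"))
    if ms.reference_length < 1:
        findings.append(
            Finding(None, f"non-positive reference length {ms.reference_length}")
        )
    if len(ms.paralogs) != len(declared):
        findings.append(Finding(None, "duplicate paralog names declared"))
    for name in ms.paralogs:
        if not name:
            findings.append(Finding(None, "empty paralog name declared"))

    prev = 0
    for site in ms.sites:
        pos = site.position
        if pos < 1 or pos > ms.reference_length:
            findings.append(Finding(pos, "position out of range"))
        if pos <= prev:
            findings.append(Finding(pos, "positions not strictly increasing"))
        prev = pos

        bases = list(site.allele_map)
        for b in bases:
            if b not in VALID_BASES:
                findings.append(Finding(pos, f"invalid allele {b!r}"))
        if len(bases) < 2:
            findings.append(Finding(pos, "fewer than two distinct bases"))
        seen: dict[str, str] = {}
        for b, members in site.allele_map.items():
            if not members:
                findings.append(Finding(pos, f"base {b} maps to no paralog"))
            for p in members:
                if p in seen:
                    findings.append(
                        Finding(pos, f"paralog {p} listed under bases {seen[p]} and {b}")
                    )
                seen[p] = b
                if p not in declared:
                    findings.append(
                        Finding(pos, f"paralog {p} not in declared paralog list")
                    )
        missing = declared - set(seen)
        for p in sorted(missing):
            findings.append(Finding(pos, f"paralog unassigned at site: {p}"))
        for b, members in site.allele_map.items():
            if declared and set(members) == declared:
                findings.append(
                    Finding(pos, f"non-discriminating site: base {b} covers all paralogs")
                )
    return findings


# ---------------------------------------------------------------------------
# attribution classes

def _group_label(members: frozenset[str]) -> str:
    prefix = os.path.commonprefix(sorted(members))
    if prefix:
        return f"other {prefix}s"
    return "group:" + ",".join(sorted(members))


def attribution_classes(ms: MarkerSet) -> list[AttributionClass]:
    """Derive the distinguishable units of expression from a marker set.

    The classes are the distinct paralog sets appearing as allele images
    across all sites; every (position, base) pair belongs to exactly one
    class.  Singleton classes are labeled by the paralog name; group classes
    by ``other <common-prefix>s`` when members share a name prefix (so a
    shared Sry3-family allele yields the label "other Sry3s"), else
    ``group:<sorted members>``.  Output is sorted by label.
    """
    findings = validate_markers(ms)
    if findings:
        raise MarkerValidationError(findings)

    images: dict[frozenset[str], list[tuple[int, str]]] = {}
    for site in ms.sites:
        for base in sorted(site.allele_map):
            members = site.allele_map[base]
            images.setdefault(members, []).append((site.position, base))

    used_labels: dict[str, frozenset[str]] = {}
    classes: list[AttributionClass] = []
    for members in sorted(images, key=lambda m: sorted(m)):
        if len(members) == 1:
            label = next(iter(members))
        else:
            label = _group_label(members)
        if label in used_labels and used_labels[label] != members:
            label = "group:" + ",".join(sorted(members))
        used_labels[label] = members
        classes.append(
            AttributionClass(
                label=label,
                members=members,
                diagnostic_sites=tuple(sorted(images[members])),
            )
        )
    classes.sort(key=lambda c: c.label)
    return classes


# ---------------------------------------------------------------------------
# TSV round trip
#
# Dialect: lines starting '##' are pragmas (##reference=<name>,
# ##length=<int>, ##paralogs=<comma list>); lines starting '#' are comments;
# the first non-comment line is the header
# `position<TAB>in_coding<TAB>base<TAB>paralogs`; one row per (position,
# base) with comma-separated paralogs.

_HEADER = ["position", "in_coding", "base", "paralogs"]
_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def load_markers(path: str | Path) -> MarkerSet:
    """Parse a marker TSV into a validated :class:`MarkerSet`.

    Raises :class:`MarkerFormatError` for parse-level problems (duplicate
    (position, base) rows, a paralog under two bases at one position,
    unknown paralogs, indel alleles) and :class:`MarkerValidationError`,
    listing every finding, when the parsed table violates model invariants.
    """
    path = Path(path)
    reference_name: str | None = None
    reference_length: int | None = None
    declared: list[str] | None = None
    rows: list[tuple[int, bool, str, list[str]]] = []
    header_seen = False

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().lower()
                if key == "reference":
                    reference_name = value.strip()
                elif key == "length":
                    try:
                        reference_length = int(value)
                    except ValueError:
                        raise MarkerFormatError(
                            f"{path}:{lineno}: ##length is not an integer: {value!r}"
                        ) from None
                elif key == "paralogs":
                    declared = [p.strip() for p in value.split(",") if p.strip()]
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip() for f in fields] != _HEADER:
                    raise MarkerFormatError(
                        f"{path}:{lineno}: expected header {_HEADER}, got {fields}"
                    )
                header_seen = True
                continue
            if len(fields) != 4:
                raise MarkerFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            pos_s, coding_s, base, paralogs_s = (f.strip() for f in fields)
            try:
                pos = int(pos_s)
            except ValueError:
                raise MarkerFormatError(
                    f"{path}:{lineno}: position is not an integer: {pos_s!r}"
                ) from None
            coding_l = coding_s.lower()
            if coding_l in _TRUE:
                coding = True
            elif coding_l in _FALSE:
                coding = False
            else:
                raise MarkerFormatError(
                    f"{path}:{lineno}: in_coding must be boolean-like, got {coding_s!r}"
                )
            base = base.upper()
            if base not in VALID_BASES:
                raise MarkerFormatError(
                    f"{path}:{lineno}: allele {base!r} at position {pos} is not a "
                    "single nucleotide A/C/G/T (indel markers are not supported)"
                )
            members = [p.strip() for p in paralogs_s.split(",") if p.strip()]
            if not members:
                raise MarkerFormatError(
                    f"{path}:{lineno}: base {base} at position {pos} maps to no paralog"
                )
            rows.append((pos, coding, base, members))

    if not header_seen:
        raise MarkerFormatError(f"{path}: missing header line")
    if reference_name is None or reference_length is None:
        raise MarkerFormatError(
            f"{path}: missing ##reference= and/or ##length= pragma"
        )

    # assemble per-position sites, catching row-level duplicates
    by_pos: dict[int, dict[str, object]] = {}
    for pos, coding, base, members in rows:
        site = by_pos.setdefault(pos, {"coding": coding, "alleles": {}})
        alleles: dict[str, list[str]] = site["alleles"]  # type: ignore[assignment]
        if base in alleles:
            raise MarkerFormatError(
                f"{path}: duplicate rows for position {pos} base {base}"
            )
        if declared is not None:
            unknown = [p for p in members if p not in declared]
            if unknown:
                raise MarkerFormatError(
                    f"{path}: position {pos}: paralog(s) {','.join(unknown)} "
                    "not in ##paralogs declaration"
                )
        seen_elsewhere = {p for b in alleles for p in alleles[b]}
        clash = seen_elsewhere & set(members)
        if clash:
            raise MarkerFormatError(
                f"{path}: position {pos}: paralog(s) {','.join(sorted(clash))} "
                "listed under more than one base"
            )
        alleles[base] = members

    sites = [
        MarkerSite(
            position=pos,
            allele_map={b: frozenset(m) for b, m in by_pos[pos]["alleles"].items()},  # type: ignore[union-attr]
            in_coding=bool(by_pos[pos]["coding"]),
        )
        for pos in sorted(by_pos)
    ]
    if declared is None:
        declared_set: set[str] = set()
        for s in sites:
            declared_set |= s.paralogs
        declared = sorted(declared_set)

    ms = MarkerSet(
        reference_name=reference_name,
        reference_length=reference_length,
        paralogs=list(declared),
        sites=sites,
    )
    findings = validate_markers(ms)
    if findings:
        raise MarkerValidationError(findings)
    return ms


def save_markers(ms: MarkerSet, path: str | Path) -> None:
    """Write a MarkerSet in the TSV dialect :func:`load_markers` reads."""
    path = Path(path)
    lines = [
        f"##reference={ms.reference_name}",
        f"##length={ms.reference_length}",
        "##paralogs=" + ",".join(ms.paralogs),
        "\t".join(_HEADER),
    ]
    for site in sorted(ms.sites, key=lambda s: s.position):
        for base in sorted(site.allele_map):
            members = ",".join(sorted(site.allele_map[base]))
            coding = "1" if site.in_coding else "0"
            lines.append(f"{site.position}\t{coding}\t{base}\t{members}")
    path.write_text("\n".join(lines) + "\n")
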