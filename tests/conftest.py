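import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from paralogdeconv import MarkerSet, MarkerSite, PileupProfile, make_fixture_suite

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """The standard synthetic battery, generated once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixture_suite(out, seed=0)


@pytest.fixture
def two_paralog_markers():
    """Minimal hand-built marker set: two copies, two diagnostic sites."""
    return MarkerSet(
        reference_name="geneA",
        reference_length=100,
        paralogs=["geneA", "geneB"],
        sites=[
            MarkerSite(position=10, allele_map={"A": {"geneA"}, "G": {"geneB"}}),
            MarkerSite(position=20, allele_map={"C": {"geneA"}, "T": {"geneB"}}),
        ],
    )


def make_profile(reference, length, site_counts):
    """Build a PileupProfile from {position: {base: count}} (1-based)."""
    counts = np.zeros((length, 4), dtype=np.int64)
    for pos, bases in site_counts.items():
        for base, c in bases.items():
            counts[pos - 1, "ACGT".index(base)] = c
    return PileupProfile(reference_name=reference, counts=counts)


def write_sam(path, records, reference="ref", length=100):
    """Write a minimal SAM file from (name, flag, pos, cigar, seq) tuples."""
    lines = ["@HD\tVN:1.6", f"@SQ\tSN:{reference}\tLN:{length}"]
    for name, flag, pos, cigar, seq in records:
        qual = "?" * len(seq)
        lines.append(
            f"{name}\t{flag}\t{reference}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t{qual}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
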