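"""Composition estimation, marker filtering and TPM partitioning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paralogdeconv import (
    EstimationError,
    FamilyConfig,
    MarkerSet,
    MarkerSite,
    PileupProfile,
    ReadSimConfig,
    estimate_composition,
    filter_markers,
    generate_paralog_family,
    nnls_oracle,
    partition_abundance,
    pileup_counts_from_truth,
    simulate_reads,
    tpm_from_counts,
)

from conftest import make_profile


def three_copy_markers():
    """Three copies, every site assigning each copy its own base."""
    sites = [
        MarkerSite(position=pos, allele_map={"A": {"c1"}, "C": {"c2"}, "G": {"c3"}})
        for pos in (10, 20, 30, 40)
    ]
    return MarkerSet(reference_name="c1", reference_length=100,
                     paralogs=["c1", "c2", "c3"], sites=sites)


def profile_from_fractions(ms, fractions, depth=1000):
    """Exact pileup whose allele counts realize the given class fractions."""
    site_counts = {}
    for site in ms.sites:
        row = {}
        for base, members in site.allele_map.items():
            share = sum(fractions[m] for m in members)
            row[base] = int(round(share * depth))
        site_counts[site.position] = row
    return make_profile(ms.reference_name, ms.reference_length, site_counts)


class TestFilterMarkers:
    @pytest.mark.parametrize("depth, usable", [(149, False), (150, True), (151, True)])
    def test_boundary_at_default_threshold(self, depth, usable, two_paralog_markers):
        ms = two_paralog_markers
        p = make_profile("geneA", 100, {10: {"A": depth}, 20: {"C": depth}})
        kept, rejected = filter_markers(ms, p, min_depth=150)
        if usable:
            assert {s.position for s in kept} == {10, 20} and not rejected
        else:
            assert not kept
            assert [(s.position, d) for s, d in rejected] == [(10, depth), (20, depth)]

    def test_empty_pileup_rejects_everything(self, two_paralog_markers):
        p = PileupProfile("geneA", np.zeros((100, 4), dtype=np.int64))
        kept, rejected = filter_markers(two_paralog_markers, p)
        assert not kept and len(rejected) == 2

    def test_raising_threshold_never_adds_markers(self, two_paralog_markers):
        p = make_profile("geneA", 100, {10: {"A": 200}, 20: {"C": 120}})
        sizes = [
            len(filter_markers(two_paralog_markers, p, min_depth=d)[0])
            for d in (0, 100, 150, 300)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestEstimateComposition:
    def test_noiseless_60_30_10(self):
        ms = three_copy_markers()
        p = profile_from_fractions(ms, {"c1": 0.6, "c2": 0.3, "c3": 0.1})
        comp = estimate_composition(ms, p)
        assert comp.per_class_percent["c1"] == pytest.approx(60.0, abs=1e-6)
        assert comp.per_class_percent["c2"] == pytest.approx(30.0, abs=1e-6)
        assert comp.per_class_percent["c3"] == pytest.approx(10.0, abs=1e-6)
        assert comp.markers_used == 4 and comp.markers_filtered == 0
        # evidence kept for every (position, base) marker pair
        assert len(comp.evidence) == 12

    def test_single_source_is_one_hundred_percent(self):
        ms = three_copy_markers()
        p = profile_from_fractions(ms, {"c1": 0.0, "c2": 1.0, "c3": 0.0})
        comp = estimate_composition(ms, p)
        assert comp.per_class_percent["c2"] == pytest.approx(100.0)
        assert comp.per_class_percent["c1"] == 0.0
        assert comp.per_class_percent["c3"] == 0.0

    def test_shared_alleles_pool_into_group_class(self):
        # two copies indistinguishable at both sites: their combined share
        # lands on the single group class
        ms = MarkerSet(
            reference_name="x", reference_length=50, paralogs=["x", "y1", "y2"],
            sites=[
                MarkerSite(position=5, allele_map={"A": {"x"}, "T": {"y1", "y2"}}),
                MarkerSite(position=15, allele_map={"C": {"x"}, "G": {"y1", "y2"}}),
            ],
        )
        p = profile_from_fractions(ms, {"x": 0.5, "y1": 0.3, "y2": 0.2})
        comp = estimate_composition(ms, p)
        assert comp.per_class_percent["other ys"] == pytest.approx(50.0, abs=1e-6)
        assert comp.per_class_percent["x"] == pytest.approx(50.0, abs=1e-6)

    def test_class_without_usable_markers_is_missing_not_zero(self):
        # c2 and c3 are separable only at position 20; with that site under
        # the depth filter their singleton classes are missing (None), while
        # the c2+c3 group class stays estimable from position 10
        ms = MarkerSet(
            reference_name="c1", reference_length=100, paralogs=["c1", "c2", "c3"],
            sites=[
                MarkerSite(position=10,
                           allele_map={"A": {"c1"}, "C": {"c2", "c3"}}),
                MarkerSite(position=20,
                           allele_map={"A": {"c1"}, "C": {"c2"}, "G": {"c3"}}),
            ],
        )
        p = make_profile("c1", 100,
                         {10: {"A": 300, "C": 200}, 20: {"A": 60, "C": 30, "G": 10}})
        comp = estimate_composition(ms, p, min_depth=150)
        assert comp.per_class_percent["c2"] is None
        assert comp.per_class_percent["c3"] is None
        assert comp.per_class_percent["other cs"] == pytest.approx(40.0, abs=1e-6)
        total = sum(v for v in comp.per_class_percent.values() if v is not None)
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_no_usable_markers_raises(self, two_paralog_markers):
        p = make_profile("geneA", 100, {10: {"A": 10}, 20: {"C": 10}})
        with pytest.raises(EstimationError, match="no markers above depth threshold"):
            estimate_composition(two_paralog_markers, p, min_depth=150)

    @given(seed=st.integers(0, 200))
    def test_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        ms = three_copy_markers()
        w = rng.integers(1, 100, size=3)
        p = profile_from_fractions(ms, dict(zip(["c1", "c2", "c3"], w / w.sum())),
                                   depth=int(w.sum()) * 10)
        k = int(rng.integers(2, 9))
        scaled = PileupProfile(p.reference_name, p.counts * k)
        a = estimate_composition(ms, p, min_depth=0)
        b = estimate_composition(ms, scaled, min_depth=0)
        for label in a.per_class_percent:
            assert a.per_class_percent[label] == pytest.approx(
                b.per_class_percent[label], abs=1e-9
            )


class TestNNLSOracle:
    def test_matches_averaging_on_noiseless_unique_markers(self):
        rng = np.random.default_rng(42)
        ms = three_copy_markers()
        for _ in range(20):
            w = rng.integers(1, 50, size=3)
            fr = dict(zip(["c1", "c2", "c3"], w / w.sum()))
            p = profile_from_fractions(ms, fr, depth=int(w.sum()) * 20)
            avg = estimate_composition(ms, p, min_depth=0).per_class_percent
            ora = nnls_oracle(ms, p, min_depth=0)
            for label in avg:
                assert avg[label] == pytest.approx(ora[label], abs=1e-6)

    def test_single_class_is_hundred(self):
        ms = MarkerSet(
            reference_name="a", reference_length=20, paralogs=["a", "b"],
            sites=[MarkerSite(position=5, allele_map={"A": {"a"}, "G": {"b"}})],
        )
        p = make_profile("a", 20, {5: {"A": 500}})
        ora = nnls_oracle(ms, p)
        assert ora["a"] == pytest.approx(100.0)
        assert ora["b"] == pytest.approx(0.0)

    def test_noisy_recovery_within_two_points(self, tmp_path):
        # Monte-Carlo: error 0.005, ~1000x marker depth, 20 fixed seeds
        fam = generate_paralog_family(FamilyConfig(n_paralogs=4, seed=3))
        truth_props = {"copy1": 0.4, "copy2": 0.3, "copy3": 0.2, "copy4": 0.1}
        n_reads = 1000 * fam.transcript_length // 50
        for seed in range(20):
            cfg = ReadSimConfig(proportions=truth_props, n_reads=n_reads,
                                read_length=50, error_rate=0.005, seed=seed)
            truth = simulate_reads(fam, cfg, tmp_path / str(seed))
            p = PileupProfile(fam.reference_name, pileup_counts_from_truth(truth))
            ora = nnls_oracle(fam.markers, p)
            for name, true_p in truth_props.items():
                assert ora[name] == pytest.approx(true_p * 100, abs=2.0)


class TestRecoveryVsDepth:
    def test_error_shrinks_with_depth(self, tmp_path):
        # median per-class error must fall as marker depth rises 100->1000->10000
        fam = generate_paralog_family(FamilyConfig(n_paralogs=4, seed=9))
        truth_props = {"copy1": 0.4, "copy2": 0.3, "copy3": 0.2, "copy4": 0.1}
        medians = []
        for depth in (100, 1000, 10000):
            n_reads = depth * fam.transcript_length // 50
            errs = []
            for seed in range(8):
                cfg = ReadSimConfig(proportions=truth_props, n_reads=n_reads,
                                    read_length=50, error_rate=0.005, seed=seed)
                truth = simulate_reads(fam, cfg, tmp_path / f"{depth}_{seed}")
                p = PileupProfile(fam.reference_name, pileup_counts_from_truth(truth))
                comp = estimate_composition(fam.markers, p, min_depth=50)
                errs.extend(
                    abs(comp.per_class_percent[n] - t * 100)
                    for n, t in truth_props.items()
                )
            medians.append(float(np.median(errs)))
        assert medians[0] > medians[1] > medians[2]


class TestPartitionAndTPM:
    def test_partition_examples(self):
        ms = three_copy_markers()
        comp = estimate_composition(
            ms, profile_from_fractions(ms, {"c1": 0.6, "c2": 0.3, "c3": 0.1})
        )
        part = partition_abundance(comp, 20.0)
        assert part.per_class_tpm["c1"] == pytest.approx(12.0, abs=1e-6)
        assert part.per_class_tpm["c2"] == pytest.approx(6.0, abs=1e-6)
        assert part.per_class_tpm["c3"] == pytest.approx(2.0, abs=1e-6)
        zero = partition_abundance(comp, 0.0)
        assert all(v == 0 for v in zero.per_class_tpm.values())
        with pytest.raises(ValueError):
            partition_abundance(comp, -1.0)

    def test_partition_preserves_missing(self):
        ms = three_copy_markers()
        comp = estimate_composition(
            ms, profile_from_fractions(ms, {"c1": 1.0, "c2": 0.0, "c3": 0.0})
        )
        comp.per_class_percent["c3"] = None
        part = partition_abundance(comp, 5.0)
        assert part.per_class_tpm["c3"] is None

    def test_tpm_closed_forms(self):
        assert tpm_from_counts([7], [100])[0] == pytest.approx(1e6)
        tpm = tpm_from_counts([10, 10], [100, 200])
        assert tpm[0] == pytest.approx(2e6 / 3)
        assert tpm[1] == pytest.approx(1e6 / 3)

    @given(
        counts=st.lists(st.integers(0, 10_000), min_size=1, max_size=8),
    )
    def test_tpm_normalization(self, counts):
        lengths = [100 + 10 * i for i in range(len(counts))]
        if sum(counts) == 0:
            with pytest.warns(UserWarning):
                tpm = tpm_from_counts(counts, lengths)
            assert tpm.sum() == 0
        else:
            tpm = tpm_from_counts(counts, lengths)
            assert tpm.sum() == pytest.approx(1e6, abs=1e-6 * 1e6)
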