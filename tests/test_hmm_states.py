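"""Binning, binarization, HMM learning/decoding, labeling, enrichment
and metaprofiles."""

import numpy as np
import pytest

from epireprog import (
    annotation_enrichment,
    binarize_counts_poisson,
    binarize_peaks,
    decode_states,
    label_states,
    learn_hmm,
    make_bins,
    metaprofile,
)
from epireprog.chromstates import poisson_threshold_count, segmentation_to_intervals
from epireprog.core import GenomicInterval
from epireprog.hmm import align_states, forward_backward, log_likelihood, posterior_marginals


def sample_hmm_data(rng, E, A, T):
    K = len(E)
    s = np.zeros(T, dtype=int)
    for t in range(1, T):
        s[t] = rng.choice(K, p=A[s[t - 1]])
    x = (rng.random((T, E.shape[1])) < E[s]).astype(float)
    return s, x


@pytest.fixture(scope="module")
def two_state_fixture():
    """50k bins from a known 2-state, 2-mark model."""
    rng = np.random.default_rng(42)
    E = np.array([[0.9, 0.1], [0.1, 0.8]])
    A = np.array([[0.95, 0.05], [0.05, 0.95]])
    s, x = sample_hmm_data(rng, E, A, 50_000)
    return E, A, s, x


class TestBins:
    def test_bin_counts(self):
        grid = make_bins({"chr1": 1000}, 200)
        assert grid.n_bins == 5
        grid = make_bins({"chr1": 1001}, 200)
        assert grid.n_bins == 6
        assert grid.bin_interval(5).width == 1

    def test_bins_partition_chromosome(self):
        grid = make_bins({"chr1": 1234, "chr2": 700}, 200)
        ivs = grid.intervals()
        covered = {}
        for iv in ivs:
            covered.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, size in grid.chrom_sizes.items():
            spans = sorted(covered[chrom])
            assert spans[0][0] == 0 and spans[-1][1] == size
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 == s2


class TestBinarize:
    def test_peak_overlap_semantics(self):
        grid = make_bins({"chr1": 1000}, 200)
        x = binarize_peaks(grid, {"m": [GenomicInterval("chr1", 0, 200)]})
        assert x["m"].tolist() == [1, 0, 0, 0, 0]
        x = binarize_peaks(grid, {"m": [GenomicInterval("chr1", 199, 201)]})
        assert x["m"].tolist() == [1, 1, 0, 0, 0]
        x = binarize_peaks(grid, {"m": []})
        assert x["m"].sum() == 0

    def test_unknown_chromosome_errors(self):
        grid = make_bins({"chr1": 1000}, 200)
        with pytest.raises(ValueError, match="unknown chromosome"):
            binarize_peaks(grid, {"m": [GenomicInterval("chrX", 0, 10)]})

    def test_poisson_threshold_matches_brute_force_tail(self):
        # brute-force tail sums independent of scipy.sf
        from math import exp, factorial

        def tail(k, lam):
            # P(X >= k) = 1 - sum_{i<k} e^-lam lam^i / i!
            return 1.0 - sum(exp(-lam) * lam**i / factorial(i) for i in range(k))

        assert poisson_threshold_count(1.0, 1e-4) == 7
        assert tail(6, 1.0) > 1e-4 >= tail(7, 1.0)
        for lam in (0.5, 2.0, 10.0):
            k = poisson_threshold_count(lam, 1e-4)
            assert tail(k, lam) <= 1e-4 < tail(k - 1, lam)

    def test_poisson_binarization_monotone_in_threshold(self):
        grid = make_bins({"chr1": 4000}, 200)
        counts = np.arange(20)
        loose = binarize_counts_poisson(grid, {"m": counts}, 1e-2)["m"]
        strict = binarize_counts_poisson(grid, {"m": counts}, 1e-4)["m"]
        assert ((loose - strict) >= 0).all()
        assert loose[0] == 0  # count 0 never flagged


class TestHMM:
    def test_single_state_degenerates_to_column_means(self):
        rng = np.random.default_rng(0)
        x = (rng.random((500, 3)) < [0.2, 0.5, 0.8]).astype(float)
        m = learn_hmm(x, 1, seed=0)
        assert np.allclose(m.emissions[0], x.mean(axis=0))
        assert m.transmat.shape == (1, 1) and m.transmat[0, 0] == 1.0
        assert (decode_states(m, x) == 0).all()

    def test_parameter_recovery_and_decoding(self, two_state_fixture):
        E, A, s, x = two_state_fixture
        model = learn_hmm(x, 2, seed=0, n_restarts=2)
        perm = align_states(E, model)
        assert np.abs(model.emissions[perm] - E).max() < 0.03
        assert np.abs(model.transmat[np.ix_(perm, perm)] - A).max() < 0.03
        inv = np.empty(2, dtype=int)
        inv[perm] = np.arange(2)
        decoded = decode_states(model, x)
        assert (inv[decoded] == s).mean() >= 0.95
        assert np.all(np.diff(model.loglik_trace) >= -1e-8)

    def test_two_states_beat_one_on_held_out_data(self, two_state_fixture):
        E, A, s, x = two_state_fixture
        train, held = x[:30_000], x[30_000:]
        m2 = learn_hmm(train, 2, seed=0, n_restarts=2)
        m1 = learn_hmm(train, 1, seed=0)
        assert log_likelihood(held, m2) > log_likelihood(held, m1)

    def test_posteriors_normalized_and_reproducible(self, two_state_fixture):
        _, _, _, x = two_state_fixture
        sub = x[:2_000]
        m_a = learn_hmm(sub, 2, seed=3, n_restarts=2)
        m_b = learn_hmm(sub, 2, seed=3, n_restarts=2)
        assert np.array_equal(m_a.emissions, m_b.emissions)
        gamma = posterior_marginals(sub, m_a)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_state_permutation_leaves_family_track_unchanged(self, two_state_fixture):
        """Relabeling HMM states permutes the decoded indices but not
        the per-bin family annotation."""
        from epireprog.hmm import ChromStateModel

        _, _, _, x = two_state_fixture
        sub = x[:3_000]
        model = learn_hmm(sub, 2, seed=1, n_restarts=2, marks=["H3K4me3", "H3K27me3"])
        perm = np.array([1, 0])
        permuted = ChromStateModel(
            startprob=model.startprob[perm],
            transmat=model.transmat[np.ix_(perm, perm)],
            emissions=model.emissions[perm],
            marks=model.marks,
        )
        fam_a = label_states(model)
        fam_b = label_states(permuted)
        track_a = [fam_a[s] for s in decode_states(model, sub)]
        track_b = [fam_b[s] for s in decode_states(permuted, sub)]
        assert track_a == track_b

    def test_input_validation(self):
        with pytest.raises(ValueError, match="binary"):
            learn_hmm(np.array([[0.5, 1.0]]), 1)
        with pytest.raises(ValueError, match="exceeds"):
            learn_hmm(np.ones((3, 2)), 5)


class TestLabeling:
    def make_model(self, emissions, marks):
        from epireprog.hmm import ChromStateModel

        E = np.asarray(emissions, dtype=float)
        K = len(E)
        return ChromStateModel(
            startprob=np.full(K, 1 / K),
            transmat=np.full((K, K), 1 / K),
            emissions=E,
            marks=marks,
        )

    def test_rule_table(self):
        marks = ["H3K4me3", "H3K27me3", "H3K4me1", "H3K27ac", "H3K36me3", "H3K9me3"]
        model = self.make_model(
            [
                [0.9, 0.05, 0.1, 0.8, 0.05, 0.05],  # promoter
                [0.7, 0.6, 0.1, 0.1, 0.05, 0.05],  # poised
                [0.05, 0.05, 0.05, 0.05, 0.05, 0.05],  # low
                [0.05, 0.8, 0.05, 0.05, 0.05, 0.05],  # Polycomb
                [0.1, 0.05, 0.8, 0.7, 0.05, 0.05],  # active enhancer
                [0.05, 0.05, 0.05, 0.05, 0.9, 0.05],  # transcribed
                [0.05, 0.05, 0.05, 0.05, 0.05, 0.9],  # heterochromatin
            ],
            marks,
        )
        labels = label_states(model)
        assert [labels[k] for k in range(7)] == [
            "TSS/promoter",
            "poised TSS",
            "low signal",
            "Polycomb",
            "active enhancer",
            "transcribed",
            "heterochromatin",
        ]

    def test_cell_line_mode_collapses_families(self):
        marks = ["H3K4me3", "H3K27me3", "H3K4me1", "H3K27ac"]
        model = self.make_model(
            [[0.9, 0.05, 0.1, 0.8], [0.7, 0.6, 0.1, 0.1], [0.05, 0.8, 0.05, 0.05]],
            marks,
        )
        labels = label_states(model, mode="cell_line")
        assert [labels[k] for k in range(3)] == [
            "active TSS",
            "bivalent TSS/enhancer",
            "Polycomb",
        ]


class TestEnrichmentAndProfiles:
    def test_whole_genome_annotation_fold_one(self):
        grid = make_bins({"chr1": 2000}, 200)
        states = np.array([0, 0, 1, 1, 1, 0, 2, 2, 1, 0])
        enr = annotation_enrichment(grid, states, [GenomicInterval("chr1", 0, 2000)])
        assert np.allclose(enr.values, 1.0)

    def test_annotation_equal_to_state_bins(self):
        grid = make_bins({"chr1": 2000}, 200)
        states = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        enr = annotation_enrichment(grid, states, [GenomicInterval("chr1", 0, 400)])
        assert enr[1] == pytest.approx(1 / 0.2)  # 1 / genome fraction
        # a state absent from the annotation
        assert enr[0] == pytest.approx(0.0)

    def test_segmentation_reassembles_grid(self):
        grid = make_bins({"chr1": 2000, "chr2": 600}, 200)
        states = np.array([0, 0, 1, 1, 1, 0, 2, 2, 1, 0, 0, 0, 1])
        seg = segmentation_to_intervals(grid, states)
        total = (seg["end"] - seg["start"]).sum()
        assert total == sum(grid.chrom_sizes.values())
        back = np.concatenate(
            [
                np.repeat(r.state, len(grid.bin_range(GenomicInterval(r.chrom, r.start, r.end))))
                for r in seg.itertuples()
            ]
        )
        assert np.array_equal(back, states)

    def test_metaprofile_constant_and_linearity(self):
        grid = make_bins({"chr1": 20_000}, 200)
        signal = np.full(grid.n_bins, 3.0)
        regions = [GenomicInterval("chr1", 9_000, 11_000)]
        prof = metaprofile(grid, signal, regions, flank=2000, n_points=21)
        assert np.allclose(prof["mean"], 3.0)
        rng = np.random.default_rng(5)
        signal = rng.random(grid.n_bins)
        p1 = metaprofile(grid, signal, regions, flank=2000, n_points=21)
        p2 = metaprofile(grid, 2 * signal, regions, flank=2000, n_points=21)
        assert np.allclose(p2["mean"], 2 * p1["mean"])

    def test_metaprofile_drops_edge_regions(self):
        grid = make_bins({"chr1": 10_000}, 200)
        signal = np.ones(grid.n_bins)
        prof = metaprofile(
            grid,
            signal,
            [GenomicInterval("chr1", 0, 400), GenomicInterval("chr1", 4000, 6000)],
            flank=2000,
        )
        assert prof.attrs["n_dropped"] == 1
        assert prof.attrs["n_regions"] == 1
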