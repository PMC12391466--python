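"""Windows, gene flags, set algebra and candidate ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from epireprog import (
    GeneModel,
    GenomicInterval,
    assign_gene_flags,
    define_combination_targets,
    final_candidates,
    gene_windows,
    overlap_sets,
    patient_marked_genes,
)
from epireprog.integrate import build_target_sets, normalize_gene_ids


def gene(gene_id, start, end, strand, chrom="chr1"):
    return GeneModel(gene_id, gene_id, GenomicInterval(chrom, start, end, strand))


class TestWindows:
    def test_plus_strand_promoter(self):
        w = gene_windows(gene("g", 100_000, 110_000, "+"))
        assert (w.promoter.start, w.promoter.end) == (97_500, 101_000)
        assert (w.body.start, w.body.end) == (97_500, 110_000)

    def test_minus_strand_promoter(self):
        w = gene_windows(gene("g", 90_000, 100_001, "-"))  # tss at 100,000
        assert (w.promoter.start, w.promoter.end) == (99_000, 102_500)
        assert (w.body.start, w.body.end) == (90_000, 102_500)

    def test_truncation_at_chromosome_start(self):
        w = gene_windows(gene("g", 1_000, 5_000, "+"))
        assert (w.promoter.start, w.promoter.end) == (0, 2_000)

    def test_promoter_width_exact(self, rng):
        for _ in range(200):
            start = int(rng.integers(5_000, 1_000_000))
            length = int(rng.integers(1_000, 50_000))
            strand = rng.choice(["+", "-"])
            w = gene_windows(gene("g", start, start + length, strand))
            assert w.promoter.width == 3_500
            # the body window contains the promoter's upstream edge
            assert w.body.start <= w.promoter.start < w.body.end or (
                w.body.start < w.promoter.end <= w.body.end
            )


def diff_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "call"])


def meth_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "call"])


class TestFlags:
    def setup_method(self):
        self.windows = [gene_windows(gene("g1", 100_000, 110_000, "+"))]

    def test_loss_peak_in_body_sets_flag(self):
        k27 = diff_table([("chr1", 105_000, 105_400, "loss")])
        prof = assign_gene_flags(self.windows, k27_result=k27)
        assert prof.loc["g1", "lost_k27me3"]
        assert not prof.loc["g1", "lost_dname"]

    def test_probe_one_bp_outside_promoter_not_counted(self):
        # promoter is [97500, 101000): position 101000 is outside
        meth = meth_table([("chr1", 101_000, "hypo")])
        prof = assign_gene_flags(self.windows, meth_result=meth)
        assert not prof.loc["g1", "lost_dname"]
        meth = meth_table([("chr1", 100_999, "hypo")])
        prof = assign_gene_flags(self.windows, meth_result=meth)
        assert prof.loc["g1", "lost_dname"]

    def test_no_evidence_all_false(self):
        prof = assign_gene_flags(self.windows)
        assert not prof[["lost_k27me3", "lost_dname", "gained_k4me3", "upregulated"]].any().any()

    def test_gain_call_does_not_set_loss_flag(self):
        k27 = diff_table([("chr1", 105_000, 105_400, "gain")])
        prof = assign_gene_flags(self.windows, k27_result=k27)
        assert not prof.loc["g1", "lost_k27me3"]


class TestTargetDefinition:
    def test_boolean_formula_exhaustive(self):
        rows = []
        for bits in itertools.product([False, True], repeat=4):
            rows.append(
                {
                    "gene_id": "g" + "".join(str(int(b)) for b in bits),
                    "lost_k27me3": bits[0],
                    "lost_dname": bits[1],
                    "gained_k4me3": bits[2],
                    "upregulated": bits[3],
                }
            )
        profiles = pd.DataFrame(rows).set_index("gene_id")
        got = define_combination_targets(profiles)
        oracle = {
            r.Index
            for r in profiles.itertuples()
            if r.lost_k27me3 or r.lost_dname or r.gained_k4me3
        }
        assert got == oracle
        assert "g0001" not in got  # expression alone is insufficient


class TestOverlapSets:
    def brute_force_regions(self, sets):
        names = list(sets)
        universe = set().union(*sets.values())
        counts = {}
        for el in universe:
            key = tuple(el in sets[n] for n in names)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def test_disjoint_and_identical(self):
        out = overlap_sets({"A": {"a"}, "B": {"b"}})
        assert out.loc["A&B", "count"] == 0
        out = overlap_sets({"A": {"x", "y"}, "B": {"x", "y"}})
        assert out.loc["A&B", "count"] == 2
        assert out.loc["A~B", "count"] == 0

    def test_matches_enumeration_oracle_on_random_sets(self, rng):
        universe = [f"g{i}" for i in range(200)]
        for _ in range(20):
            sets = {
                name: set(rng.choice(universe, size=rng.integers(0, 150), replace=False))
                for name in ("A", "B", "C")
            }
            out = overlap_sets(sets)
            oracle = self.brute_force_regions(sets)
            for key, count in oracle.items():
                inside = [n for n, b in zip(("A", "B", "C"), key) if b]
                outside = [n for n, b in zip(("A", "B", "C"), key) if not b]
                label = "&".join(inside) + ("~" + "~".join(outside) if outside else "")
                assert out.loc[label, "count"] == count
            assert out["count"].sum() == len(set().union(*sets.values()))

    def test_version_suffix_normalization(self):
        assert normalize_gene_ids(["ENSG1.4", "ENSG2"]) == {"ENSG1", "ENSG2"}


class TestPatientMarkedAndCandidates:
    def test_marking_requires_downregulation(self):
        windows = [gene_windows(gene("g1", 100_000, 110_000, "+"))]
        meth = meth_table([("chr1", 100_000, "hyper")])
        down = pd.Series({"g1": "down"})
        not_down = pd.Series({"g1": "none"})
        assert patient_marked_genes(windows, None, meth, down) == {"g1"}
        assert patient_marked_genes(windows, None, meth, not_down) == set()

    def test_candidate_table_ordering_and_intersection(self):
        sets = {
            "reactivated": {"g1", "g2", "g3"},
            "patient_marked": {"g2", "g3", "g4"},
        }
        out = final_candidates(sets, tsg_list=["g3"], survival_p={"g2": 0.01, "g3": 0.2})
        assert list(out["gene_id"]) == ["g3", "g2"]  # TSG first, then by p
        assert "g4" not in set(out["gene_id"])  # not reactivated
        assert "g1" not in set(out["gene_id"])  # not patient-marked
        again = final_candidates(sets, ["g3"], {"g2": 0.01, "g3": 0.2})
        pd.testing.assert_frame_equal(out, again)

    def test_set_identities_asserted(self):
        profiles = pd.DataFrame(
            {
                "lost_k27me3": [True, False],
                "lost_dname": [False, False],
                "gained_k4me3": [False, True],
                "upregulated": [True, False],
            },
            index=["g1", "g2"],
        )
        sets = build_target_sets(profiles, {"g1"}, set(), set(), {"g1"}, ["g1"])
        assert sets["reactivated"] == {"g1"}
        assert sets["final_candidates"] == {"g1"}
        assert sets["reactivated"] <= sets["epigenetic_map"]


class TestReflectionInvariance:
    """Mirroring the genome (x -> L - x, strands flipped) leaves flags
    and sets unchanged (evidence away from the 1-bp window boundaries)."""

    L = 1_000_000

    def reflect_interval(self, start, end):
        return self.L - end, self.L - start

    def test_flags_invariant_under_reflection(self, rng):
        genes, k27_rows, meth_rows = [], [], []
        r_genes, r_k27_rows, r_meth_rows = [], [], []
        for i in range(40):
            start = 12_000 * i + 6_000
            length = int(rng.integers(2_000, 6_000))
            strand = str(rng.choice(["+", "-"]))
            genes.append(gene(f"g{i}", start, start + length, strand))
            rs, re = self.reflect_interval(start, start + length)
            r_genes.append(gene(f"g{i}", rs, re, "-" if strand == "+" else "+"))
            if rng.random() < 0.5:
                mid = start + length // 2
                k27_rows.append(("chr1", mid - 200, mid + 200, "loss"))
                rms, rme = self.reflect_interval(mid - 200, mid + 200)
                r_k27_rows.append(("chr1", rms, rme, "loss"))
            if rng.random() < 0.5:
                pos = start + int(rng.integers(100, 900))
                meth_rows.append(("chr1", pos, "hypo"))
                r_meth_rows.append(("chr1", self.L - pos - 1, "hypo"))
        windows = [gene_windows(g) for g in genes]
        r_windows = [gene_windows(g) for g in r_genes]
        prof = assign_gene_flags(windows, diff_table(k27_rows), meth_result=meth_table(meth_rows))
        r_prof = assign_gene_flags(
            r_windows, diff_table(r_k27_rows), meth_result=meth_table(r_meth_rows)
        )
        cols = ["lost_k27me3", "lost_dname", "gained_k4me3"]
        pd.testing.assert_frame_equal(prof[cols], r_prof[cols])
        assert define_combination_targets(prof) == define_combination_targets(r_prof)
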