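import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exmirna.corrnet import (
    CorrelationSummary,
    MiRNALocus,
    bootstrap_pair_count_stability,
    chromosomal_cluster_flags,
    count_chromosome_pairs,
    cross_chromosome_enrichment,
    load_loci_gff3,
    masked_correlations,
    significant_pair_count,
    within_cross_partition,
    write_loci_gff3,
)


def _delta(rng, m=10, n=20):
    X = rng.standard_normal((m, n))
    return pd.DataFrame(X, index=[f"m{i}" for i in range(m)],
                        columns=[f"s{i}" for i in range(n)])


class TestMaskedCorrelations:
    def test_perfectly_correlated_pair_unmasked(self, rng):
        delta = _delta(rng, m=4)
        delta.loc["m1"] = 2.0 * delta.loc["m0"] + 1.0
        out = masked_correlations(delta)
        assert out.r.loc["m0", "m1"] == pytest.approx(1.0)
        assert out.p.loc["m0", "m1"] < 1e-10
        assert bool(out.mask.loc["m0", "m1"])

    def test_pvalues_match_scipy(self, rng):
        delta = _delta(rng, m=5, n=15)
        out = masked_correlations(delta)
        for a, b in [("m0", "m1"), ("m2", "m4")]:
            r, p = stats.pearsonr(delta.loc[a], delta.loc[b])
            assert out.p.loc[a, b] == pytest.approx(p, rel=1e-9)

    def test_constant_mirna_non_significant(self, rng):
        delta = _delta(rng, m=4)
        delta.loc["m2"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            out = masked_correlations(delta)
        assert not out.mask.loc["m2"].drop("m2").any()

    def test_group_selection(self, rng):
        delta = _delta(rng, m=4, n=12)
        groups = pd.Series(["control"] * 6 + ["exposed"] * 6, index=delta.columns)
        out = masked_correlations(delta, groups, "control")
        assert out.n_subjects == 6

    def test_minimum_subjects(self, rng):
        with pytest.raises(ValueError, match="4 subjects"):
            masked_correlations(_delta(rng, m=4, n=3))

    def test_order_is_permutation_and_counts_unchanged(self, rng):
        delta = _delta(rng, m=8)
        out = masked_correlations(delta)
        assert sorted(out.order) == sorted(delta.index)
        reordered = delta.loc[out.order]
        assert significant_pair_count(reordered) == out.n_significant

    def test_null_data_pair_count_near_alpha(self, rng):
        # expected significant pairs under independence ≈ 0.05·C(m,2)
        counts = []
        for _ in range(30):
            counts.append(significant_pair_count(_delta(rng, m=12, n=25)))
        n_pairs = 12 * 11 / 2
        expected = 0.05 * n_pairs
        se = np.sqrt(0.05 * 0.95 * n_pairs / 30)
        assert abs(np.mean(counts) - expected) < 3 * max(se, 1.0)


class TestBootstrapStability:
    def test_near_deterministic_data_tight_ci(self, rng):
        subject_pattern = rng.standard_normal(30)
        coef = rng.uniform(0.5, 2.0, 6)
        X = np.outer(coef, subject_pattern) + rng.normal(0, 1e-6, (6, 30))
        delta = pd.DataFrame(X, index=[f"m{i}" for i in range(6)])
        out = bootstrap_pair_count_stability(delta, n_boot=200, seed=0)
        assert out["ci"][1] - out["ci"][0] <= 1e-9   # every resample: all 15 pairs

    def test_seeded_reproducibility(self, rng):
        delta = _delta(rng, m=6, n=15)
        a = bootstrap_pair_count_stability(delta, n_boot=150, seed=3)
        b = bootstrap_pair_count_stability(delta, n_boot=150, seed=3)
        assert a["ci"] == b["ci"]
        np.testing.assert_array_equal(a["distribution"], b["distribution"])

    def test_shared_factor_raises_pair_count(self, rng):
        # a common factor (exposure-like co-regulation) yields more
        # significant pairs than independent noise, with separated CIs
        m, n = 12, 30
        f = rng.standard_normal(n)
        corr = pd.DataFrame(
            0.8 * f + 0.6 * rng.standard_normal((m, n)),
            index=[f"m{i}" for i in range(m)],
        )
        indep = _delta(rng, m=m, n=n)
        b_corr = bootstrap_pair_count_stability(corr, n_boot=200, seed=1)
        b_ind = bootstrap_pair_count_stability(indep, n_boot=200, seed=1)
        assert b_corr["ci"][0] > b_ind["ci"][1]

    def test_minimum_boot(self, rng):
        with pytest.raises(ValueError, match="≥ 100"):
            bootstrap_pair_count_stability(_delta(rng), n_boot=10)


GFF = """##gff-version 3
chr1\t.\tmiRNA\t1000\t1021\t.\t+\t.\tID=MIMAT0000001;Alias=MIMAT0000001;Name=syn-miR-1
chr2\t.\tmiRNA\t5000\t5021\t.\t-\t.\tID=MIMAT0000001_1;Alias=MIMAT0000001;Name=syn-miR-1
chr1\t.\tmiRNA_primary_transcript\t900\t1100\t.\t+\t.\tID=MI0000001;Name=syn-mir-1
chr3\t.\tmiRNA\t7000\t7020\t.\t+\t.\tID=MIMAT0000002;Alias=MIMAT0000002;Name=syn-miR-2
"""


class TestGff3:
    def test_duplicated_mimat_gets_copy_index(self, tmp_path):
        p = tmp_path / "t.gff3"
        p.write_text(GFF)
        loci = load_loci_gff3(p)
        assert len(loci) == 3                 # primary transcript line skipped
        dup = [l for l in loci if l.mimat_id == "MIMAT0000001"]
        assert [l.copy_index for l in dup] == [0, 1]
        assert {l.chromosome for l in dup} == {"chr1", "chr2"}
        assert dup[1].strand == "-"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.gff3"
        p.write_text("##gff-version 3\n")
        assert load_loci_gff3(p) == []

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\nchr1\tonly\tthree\n")
        with pytest.raises(ValueError, match="line 2"):
            load_loci_gff3(p)

    def test_non_integer_coordinates(self, tmp_path):
        p = tmp_path / "bad2.gff3"
        p.write_text("chr1\t.\tmiRNA\txx\t10\t.\t+\t.\tID=M1\n")
        with pytest.raises(ValueError, match="line 1"):
            load_loci_gff3(p)

    def test_write_then_read(self, tmp_path):
        loci = [
            MiRNALocus("MIMAT0000009", "syn-miR-9", "chr5", 100, 121, "+", 0),
            MiRNALocus("MIMAT0000009", "syn-miR-9", "chr7", 900, 921, "-", 1),
        ]
        p = tmp_path / "w.gff3"
        write_loci_gff3(loci, p)
        assert load_loci_gff3(p) == loci


class TestClusterFlags:
    def test_neighbors_within_window(self):
        loci = [MiRNALocus("A", "a", "chr1", 1000, 1020),
                MiRNALocus("B", "b", "chr1", 9000, 9020)]
        flags = chromosomal_cluster_flags(loci)
        assert flags[("A", 0)] and flags[("B", 0)]

    def test_different_chromosomes_never_cluster(self):
        loci = [MiRNALocus("A", "a", "chr1", 1000, 1020),
                MiRNALocus("B", "b", "chr2", 1000, 1020)]
        flags = chromosomal_cluster_flags(loci)
        assert not flags[("A", 0)] and not flags[("B", 0)]

    def test_chain_flags_by_nearest_neighbor(self):
        loci = [MiRNALocus("A", "a", "chr1", 1, 21),
                MiRNALocus("B", "b", "chr1", 9000, 9020),
                MiRNALocus("C", "c", "chr1", 18000, 18020)]
        flags = chromosomal_cluster_flags(loci)
        assert all(flags.values())            # 1↔9k and 9k↔18k within 10 kb


def _summary_from_mask(mask: pd.DataFrame, n_subjects=20) -> CorrelationSummary:
    ids = list(mask.index)
    m = len(ids)
    return CorrelationSummary(
        r=pd.DataFrame(np.eye(m), index=ids, columns=ids),
        p=pd.DataFrame(np.where(mask, 0.01, 0.5), index=ids, columns=ids),
        mask=mask,
        n_significant=int(mask.to_numpy()[np.triu_indices(m, 1)].sum()),
        order=ids,
        n_subjects=n_subjects,
    )


class TestCrossChromosomeEnrichment:
    def _loci(self, assignment):
        return [MiRNALocus(m, m.lower(), c, 1000 * (i + 1), 1000 * (i + 1) + 20)
                for i, (m, c) in enumerate(assignment.items())]

    def test_identical_groups_unit_fold(self):
        ids = ["A", "B", "C", "D"]
        mask = pd.DataFrame(True, index=ids, columns=ids)
        loci = self._loci({"A": "chr1", "B": "chr2", "C": "chr1", "D": "chr3"})
        s = _summary_from_mask(mask)
        out = cross_chromosome_enrichment(s, s, loci)
        assert (out["fold_change"] == 1.0).all()

    def test_constructed_fold_change_recovered_exactly(self):
        # 23 exposed-only pairs and 1 shared pair across chr16–chr1
        chr16 = [f"S{i}" for i in range(6)]
        chr1 = [f"T{i}" for i in range(4)]
        ids = chr16 + chr1
        exp_mask = pd.DataFrame(False, index=ids, columns=ids)
        ctl_mask = pd.DataFrame(False, index=ids, columns=ids)
        pairs = [(a, b) for a in chr16 for b in chr1]
        for a, b in pairs[:23]:
            exp_mask.loc[a, b] = exp_mask.loc[b, a] = True
        a, b = pairs[0]
        ctl_mask.loc[a, b] = ctl_mask.loc[b, a] = True
        loci = self._loci({**{m: "chr16" for m in chr16}, **{m: "chr1" for m in chr1}})
        out = cross_chromosome_enrichment(
            _summary_from_mask(exp_mask), _summary_from_mask(ctl_mask), loci
        )
        row = out[(out.chrom_a == "chr1") & (out.chrom_b == "chr16")].iloc[0]
        assert row["fold_change"] == pytest.approx(23.0)

    def test_zero_control_count_flagged_infinite(self):
        ids = ["A", "B"]
        exp_mask = pd.DataFrame([[False, True], [True, False]], index=ids, columns=ids)
        ctl_mask = pd.DataFrame(False, index=ids, columns=ids)
        loci = self._loci({"A": "chr1", "B": "chr2"})
        out = cross_chromosome_enrichment(
            _summary_from_mask(exp_mask), _summary_from_mask(ctl_mask), loci
        )
        assert bool(out.iloc[0]["infinite"])

    def test_fully_masked_matrix_zero_counts(self):
        ids = ["A", "B", "C"]
        mask = pd.DataFrame(False, index=ids, columns=ids)
        loci = self._loci({"A": "chr1", "B": "chr2", "C": "chr3"})
        counts = count_chromosome_pairs(_summary_from_mask(mask), loci)
        assert counts.empty

    def test_partition_within_plus_cross_equals_total(self, rng):
        delta = _delta(rng, m=10, n=25)
        out = masked_correlations(delta)
        loci = self._loci({f"m{i}": f"chr{1 + i % 3}" for i in range(10)})
        part = within_cross_partition(out, loci)
        assert part["within"] + part["cross"] == part["total"] == out.n_significant

    def test_unannotated_mirnas_excluded_with_warning(self, rng):
        delta = _delta(rng, m=5, n=25)
        loci = self._loci({f"m{i}": "chr1" for i in range(3)})
        out = masked_correlations(delta)
        with pytest.warns(UserWarning, match="without genomic annotation"):
            count_chromosome_pairs(out, loci)
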