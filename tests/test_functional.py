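import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpgmeth import functional as fn
from cpgmeth.dinucleotide import InsufficientDataError
from cpgmeth.seq_io import AnnotationTable
from tests.conftest import make_profile


def annotation_table(rows, slim_map):
    return AnnotationTable(
        rows=pd.DataFrame(rows, columns=["sequence_id", "go_id"]),
        slim_map=slim_map,
    )


class TestBinBySlim:
    def test_multiple_terms_one_membership_per_bin(self):
        # two GO terms map to X, one to Y: sequence appears once in each
        table = annotation_table(
            [("s1", "GO:1"), ("s1", "GO:2"), ("s1", "GO:3")],
            {"GO:1": "X", "GO:2": "X", "GO:3": "Y"},
        )
        profiles = [make_profile("s1", 0.5)]
        bins, unbinned = fn.bin_by_slim(profiles, table)
        assert bins == {"X": {"s1"}, "Y": {"s1"}}
        assert unbinned == set()

    def test_unannotated_sequence_reported_unbinned(self):
        table = annotation_table([("s1", "GO:1")], {"GO:1": "X"})
        profiles = [make_profile("s1", 0.5), make_profile("s2", 0.6)]
        bins, unbinned = fn.bin_by_slim(profiles, table)
        assert unbinned == {"s2"}

    def test_bin_sizes_count_members(self):
        table = annotation_table([("s1", "GO:1"), ("s2", "GO:1")],
                                 {"GO:1": "X"})
        profiles = [make_profile("s1", 0.4), make_profile("s2", 0.6)]
        bins, _ = fn.bin_by_slim(profiles, table)
        assert len(bins["X"]) == 2

    def test_no_duplicate_sequence_bin_pairs(self, rng):
        terms = [f"GO:{i}" for i in range(6)]
        slim = {t: f"slim{i % 3}" for i, t in enumerate(terms)}
        rows = [(f"s{rng.integers(10)}", terms[rng.integers(6)])
                for _ in range(100)]
        profiles = [make_profile(f"s{i}", 0.5 + i / 100) for i in range(10)]
        bins, _ = fn.bin_by_slim(profiles, annotation_table(rows, slim))
        for term, members in bins.items():
            assert len(members) == len(set(members))


class TestCategorySummary:
    def test_mean_and_se_hand_computed(self):
        profiles = [make_profile("a", 0.4), make_profile("b", 0.6)]
        (s,) = fn.category_summary({"X": {"a", "b"}}, profiles)
        assert s.mean_cpg_oe == pytest.approx(0.5)
        assert s.se == pytest.approx(np.std([0.4, 0.6], ddof=1) / np.sqrt(2))
        assert s.se == pytest.approx(0.1)

    def test_singleton_bin_has_na_se(self):
        (s,) = fn.category_summary({"X": {"a"}}, [make_profile("a", 0.7)])
        assert s.n == 1 and s.mean_cpg_oe == 0.7 and s.se is None

    def test_constant_bin_has_zero_se(self):
        profiles = [make_profile(i, 0.5) for i in "abc"]
        (s,) = fn.category_summary({"X": {"a", "b", "c"}}, profiles)
        assert s.se == 0.0

    def test_bin_emptied_by_undefined_ratios_dropped(self, caplog):
        profiles = [make_profile("a", None)]
        with caplog.at_level("WARNING"):
            out = fn.category_summary({"X": {"a"}}, profiles)
        assert out == [] and "dropped" in caplog.text


def bins_from_values(**groups):
    """Build (bins, profiles) from named value arrays."""
    bins, profiles = {}, []
    for name, values in groups.items():
        ids = set()
        for i, v in enumerate(values):
            sid = f"{name}_{i}"
            profiles.append(make_profile(sid, float(v)))
            ids.add(sid)
        bins[name] = ids
    return bins, profiles


class TestAnovaTukey:
    def test_two_groups_match_pooled_t_test(self, rng):
        a, b = rng.normal(0.5, 0.1, 30), rng.normal(0.6, 0.1, 45)
        bins, profiles = bins_from_values(g1=a, g2=b)
        mat = fn.anova_tukey(bins, profiles)
        t = stats.ttest_ind(a, b, equal_var=True)
        assert mat.p_values.loc["g1", "g2"] == pytest.approx(t.pvalue, abs=1e-6)

    def test_matches_statsmodels_tukeyhsd(self, rng):
        sm_stats = pytest.importorskip("statsmodels.stats.multicomp")
        groups = {f"g{i}": rng.normal(0.4 + 0.1 * i, 0.1, 20 + 7 * i)
                  for i in range(3)}
        bins, profiles = bins_from_values(**groups)
        mat = fn.anova_tukey(bins, profiles)
        data = np.concatenate(list(groups.values()))
        labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
        ref = sm_stats.pairwise_tukeyhsd(data, labels)
        ref_p = {(a, b): p for (a, b), p in
                 zip([(r[0], r[1]) for r in ref.summary().data[1:]],
                     ref.pvalues)}
        for (a, b), p_ref in ref_p.items():
            assert mat.p_values.loc[a, b] == pytest.approx(p_ref, abs=1e-4)

    def test_matrix_symmetric_with_empty_diagonal(self, rng):
        bins, profiles = bins_from_values(
            a=rng.normal(0.4, 0.1, 10), b=rng.normal(0.5, 0.1, 12),
            c=rng.normal(0.6, 0.1, 14))
        mat = fn.anova_tukey(bins, profiles)
        pv = mat.p_values
        assert np.allclose(pv.to_numpy(), pv.to_numpy().T, equal_nan=True)
        assert np.isnan(np.diag(pv.to_numpy())).all()

    def test_identical_bins_not_significant(self):
        vals = [0.4, 0.5, 0.6, 0.7]
        bins, profiles = bins_from_values(a=vals, b=vals, c=vals)
        mat = fn.anova_tukey(bins, profiles)
        assert np.nanmax(np.abs(mat.mean_diffs.to_numpy())) < 1e-12
        assert np.nanmin(mat.p_values.to_numpy()) == pytest.approx(1.0)
        assert mat.significant == []

    def test_power_at_component_separation(self):
        # geometry of the two fitted methylation classes
        rng = np.random.default_rng(99)
        bins, profiles = bins_from_values(
            hyper=rng.normal(0.40, 0.12, 200),
            hypo=rng.normal(0.70, 0.21, 200))
        mat = fn.anova_tukey(bins, profiles)
        assert mat.p_values.loc["hyper", "hypo"] < 0.001
        assert ("hyper", "hypo") in mat.significant

    def test_undefined_ratios_excluded(self, rng):
        bins, profiles = bins_from_values(a=rng.normal(0.4, 0.1, 10),
                                          b=rng.normal(0.6, 0.1, 10))
        profiles.append(make_profile("a_nan", None))
        bins["a"].add("a_nan")
        mat = fn.anova_tukey(bins, profiles)  # must not raise
        assert 0 <= mat.p_values.loc["a", "b"] <= 1

    def test_fewer_than_two_usable_bins_raises(self):
        bins, profiles = bins_from_values(a=[0.4, 0.5])
        with pytest.raises(InsufficientDataError):
            fn.anova_tukey(bins, profiles)
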