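import numpy as np
import pytest

from cpgmeth import dinucleotide as dn
from cpgmeth import synthetic as syn
from cpgmeth.seq_io import write_fasta


def population(decay_mean, decay_sd=0.0, n=1000, length=600, seed=0):
    cfg = syn.SyntheticConfig(
        seed=seed, n_sequences=n, length_range=(length, length),
        mixture=[syn.MixtureClass(1.0, decay_mean, decay_sd)],
    )
    return syn.generate_population(cfg)


class TestConfigValidation:
    def test_valid_default_config(self):
        syn.SyntheticConfig().validate()

    def test_errors_list_offending_fields(self):
        cfg = syn.SyntheticConfig(
            n_sequences=0, gc_content=1.5,
            mixture=[syn.MixtureClass(0.7, 0.5, 0.1)],
        )
        with pytest.raises(syn.ConfigValidationError) as exc:
            cfg.validate()
        msg = str(exc.value)
        assert "n_sequences" in msg and "gc_content" in msg and "sum to 1" in msg


class TestGeneratePopulation:
    def test_deterministic_fasta_bytes(self, tmp_path):
        cfg = syn.SyntheticConfig(seed=42, n_sequences=30,
                                  length_range=(100, 200))
        a, b = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(syn.generate_population(cfg)[0], a)
        write_fasta(syn.generate_population(cfg)[0], b)
        assert a.read_bytes() == b.read_bytes()

    def test_truth_table_matches_records(self):
        records, truth = population(0.3, 0.05, n=50)
        assert list(truth["sequence_id"]) == [r.id for r in records]
        assert truth["decay"].between(0, 0.98).all()

    def test_no_decay_keeps_expected_ratio_one(self):
        records, _ = population(0.0, n=1000, length=600, seed=7)
        vals = dn.defined_cpg_oe(dn.profile_collection(records))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.03)

    def test_half_decay_matches_analytic_expectation(self):
        # conversions also deplete C from the denominator, so the
        # expected ratio is (1-d)*l/(l-(l-1)*pG*d) ~ 0.571 at d=0.5,
        # not 1-d; the analytic oracle is expected_cpg_oe
        records, _ = population(0.5, n=1000, length=600, seed=8)
        vals = dn.defined_cpg_oe(dn.profile_collection(records))
        target = syn.expected_cpg_oe(0.5, gc_content=0.5, length=600)
        assert target == pytest.approx(0.571, abs=0.002)
        assert np.mean(vals) == pytest.approx(target, abs=0.03)

    def test_mean_ratio_monotone_in_decay_and_gpc_stable(self):
        means_cpg, means_gpc = [], []
        for d in (0.0, 0.35, 0.7):
            records, _ = population(d, n=400, length=600, seed=3)
            profiles = dn.profile_collection(records)
            means_cpg.append(np.mean(dn.defined_cpg_oe(profiles)))
            means_gpc.append(np.mean([p.gpc_oe for p in profiles
                                      if p.gpc_oe is not None]))
        assert means_cpg[0] > means_cpg[1] > means_cpg[2]
        assert all(0.95 <= g <= 1.05 for g in means_gpc)

    def test_decay_for_target_mean_inverts_expected_ratio(self):
        for mu in (0.4, 0.7, 0.9):
            d = syn.decay_for_target_mean(mu, gc_content=0.5)
            # long-sequence limit of the analytic expectation
            assert syn.expected_cpg_oe(d, 0.5, length=100000) == \
                pytest.approx(mu, abs=1e-4)


class TestGenerateAnnotations:
    def test_membership_counts_and_no_within_category_duplicates(self):
        records, truth = population(0.3, 0.05, n=60)
        cfg = syn.SyntheticConfig(
            n_sequences=60, mixture=[syn.MixtureClass(1.0, 0.3, 0.05)],
            go_categories=[syn.GoCategory("X", 0, 20),
                           syn.GoCategory("Y", 0, 30)],
        )
        table = syn.generate_annotations(truth, cfg)
        assert len(table.rows) == 50
        assert not table.rows.duplicated().any()
        assert set(table.slim_map.values()) == {"X", "Y"}

    def test_zero_categories_give_empty_table(self):
        _, truth = population(0.3, n=10)
        table = syn.generate_annotations(truth, syn.SyntheticConfig(
            n_sequences=10, mixture=[syn.MixtureClass(1.0, 0.3, 0.0)]))
        assert table.rows.empty

    def test_oversized_category_rejected(self):
        _, truth = population(0.3, n=10)
        cfg = syn.SyntheticConfig(
            n_sequences=10, mixture=[syn.MixtureClass(1.0, 0.3, 0.0)],
            go_categories=[syn.GoCategory("X", 0, 11)])
        with pytest.raises(syn.ConfigValidationError, match="exceeds"):
            syn.generate_annotations(truth, cfg)

    def test_category_means_follow_class_decay(self):
        cfg = syn.SyntheticConfig(
            seed=1, n_sequences=600, length_range=(600, 600),
            mixture=[syn.MixtureClass(0.5, 0.667, 0.05),
                     syn.MixtureClass(0.5, 0.0, 0.0)],
            go_categories=[syn.GoCategory("high_decay", 0, 100),
                           syn.GoCategory("low_decay", 1, 100)],
        )
        records, truth = syn.generate_population(cfg)
        table = syn.generate_annotations(truth, cfg)
        from cpgmeth import functional as fn
        profiles = dn.profile_collection(records)
        bins, _ = fn.bin_by_slim(profiles, table)
        stats = {s.slim_term: s.mean_cpg_oe
                 for s in fn.category_summary(bins, profiles)}
        assert stats["high_decay"] < stats["low_decay"]


class TestGenerateBisulfiteSet:
    def test_reference_has_exactly_requested_sites(self):
        from cpgmeth.bisulfite import cpg_positions
        ref, _, _ = syn.generate_bisulfite_set(
            methylation_probs=(0.5,) * 7, seed=4)
        assert len(ref) == 180
        assert len(cpg_positions(ref)) == 7

    def test_prob_one_sites_always_called_methylated(self):
        from cpgmeth.bisulfite import summarize_calls
        ref, _, clones = syn.generate_bisulfite_set(
            methylation_probs=(1.0, 1.0, 1.0), seed=5)
        cs = summarize_calls(ref, clones)
        assert all(f == 1.0 for f in cs.fractions.values())
        assert cs.conversion_rate == 1.0

    def test_quarter_probability_site_binomial(self):
        # expected fraction 0.25 over clones at the p=0.25 site
        fracs = []
        for seed in range(30):
            ref, _, clones = syn.generate_bisulfite_set(
                methylation_probs=(0.25, 0.0), n_clones=4, seed=seed)
            from cpgmeth.bisulfite import summarize_calls
            cs = summarize_calls(ref, clones)
            fracs.append(cs.fractions[cs.cpg_positions[0]])
        se = np.sqrt(0.25 * 0.75 / (30 * 4))
        assert abs(np.mean(fracs) - 0.25) < 3 * se

    def test_too_few_sites_rejected(self):
        with pytest.raises(syn.ConfigValidationError):
            syn.generate_bisulfite_set(methylation_probs=(0.5,))


class TestSampleMixtureValues:
    def test_deterministic_and_labelled(self):
        v1, l1 = syn.sample_mixture_values(100, [0.5, 0.5], [0.3, 0.9],
                                           [0.05, 0.05], seed=1)
        v2, l2 = syn.sample_mixture_values(100, [0.5, 0.5], [0.3, 0.9],
                                           [0.05, 0.05], seed=1)
        assert np.array_equal(v1, v2) and np.array_equal(l1, l2)
        assert set(np.unique(l1)) <= {0, 1}

    def test_component_moments(self):
        v, l = syn.sample_mixture_values(20000, [0.45, 0.55], [0.40, 0.70],
                                         [0.12, 0.21], seed=2)
        assert np.mean(l == 0) == pytest.approx(0.45, abs=0.02)
        assert np.mean(v[l == 0]) == pytest.approx(0.40, abs=0.01)
        assert np.std(v[l == 1]) == pytest.approx(0.21, abs=0.01)
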