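"""Synthetic genome generator: determinism, planted effects, orthogonality."""

import numpy as np
import pytest

import extremosig as es
from extremosig.synthetic import _transition_matrix, _tilt
from extremosig.signatures import revcomp


def mean_set_freq(contigsets, kmers, k=3):
    """Mean summed frequency of a canonical k-mer set across genomes."""
    sig = es.signatures_from_contigsets(contigsets, k=k, target_len=50_000,
                                        seed=0)
    return sig[list(kmers)].sum(axis=1).to_numpy()


class TestDeterminism:
    def test_same_seed_identical_dataset(self):
        cfg = es.GeneratorConfig(seed=5, n_genera_per_domain=2,
                                 samples_per_genus=2, genome_length=60_000)
        cs1, meta1, truth1 = es.generate_dataset(cfg)
        cs2, meta2, truth2 = es.generate_dataset(cfg)
        assert all(a.contigs == b.contigs for a, b in zip(cs1, cs2))
        assert [m.ogt for m in meta1] == [m.ogt for m in meta2]
        assert truth1.category_sets == truth2.category_sets

    def test_different_seed_differs(self):
        mk = lambda s: es.generate_dataset(es.GeneratorConfig(
            seed=s, n_genera_per_domain=1, samples_per_genus=1,
            genome_length=60_000))[0][0].contigs
        assert mk(1) != mk(2)


class TestBookkeeping:
    def test_plan_counts_and_metadata(self):
        cfg = es.GeneratorConfig(seed=0, n_genera_per_domain=5,
                                 samples_per_genus=3, genome_length=60_000)
        cs, meta, truth = es.generate_dataset(cfg)
        assert len(cs) == len(meta) == 2 * 5 * 3
        genera = {}
        for m in meta:
            genera.setdefault(m.genus, []).append(m)
        assert all(len(v) == 3 for v in genera.values())
        assert len(genera) == 10
        assert {m.domain for m in meta} == {"Bacteria", "Archaea"}
        assert truth.samples == meta

    def test_ogt_consistent_with_category(self):
        cfg = es.GeneratorConfig(seed=1, n_genera_per_domain=3,
                                 samples_per_genus=4, genome_length=60_000)
        _, meta, _ = es.generate_dataset(cfg)
        for m in meta:
            assert es.label_from_ogt(m.ogt) == m.temp_category

    def test_planted_sets_disjoint(self):
        cfg = es.GeneratorConfig(seed=2, n_genera_per_domain=1,
                                 samples_per_genus=1, genome_length=60_000)
        _, _, truth = es.generate_dataset(cfg)
        all_sets = list(truth.domain_sets.values()) + \
            list(truth.category_sets.values())
        flat = [w for s in all_sets for w in s]
        assert len(flat) == len(set(flat))

    def test_convergent_organism_recorded(self):
        cfg = es.GeneratorConfig(seed=3, n_convergent=1, n_genera_per_domain=2,
                                 samples_per_genus=1, genome_length=60_000)
        cs, meta, truth = es.generate_dataset(cfg)
        assert len(truth.convergent_ids) == 1
        cand = next(m for m in meta if m.assembly_id == truth.convergent_ids[0])
        assert cand.domain == "Bacteria"
        assert cand.temp_category == "hyperthermophile"

    def test_invalid_enrichment_rejected(self):
        with pytest.raises(ValueError):
            es.GeneratorConfig(tau=-1.0)


class TestPlantedEffects:
    def test_untilted_model_is_uniform(self):
        """tau=eps=1 and no fields: 3-mer frequencies uniform within 3 SE."""
        cfg = es.GeneratorConfig(seed=4, tau=1.0, epsilon=1.0, genus_sigma=0.0,
                                 sample_sigma=0.0, n_genera_per_domain=5,
                                 samples_per_genus=1, genome_length=60_000,
                                 n_run_rate=0.0)
        cs, _, _ = es.generate_dataset(cfg)
        sig = es.signatures_from_contigsets(cs, k=3, target_len=50_000, seed=0)
        # canonical 3-mers are pairs: expected freq 2/64 each, 32 of them
        expected = 1 / 32
        se = np.sqrt(expected * (1 - expected) / 50_000)
        mean_freqs = sig.mean(axis=0)
        assert np.all(np.abs(mean_freqs - expected) < 3 * se + 1e-3)

    def test_strong_environment_tilt_enriches_planted_set(self):
        from scipy import stats
        base_cfg = dict(tau=1.0, genus_sigma=0.0, sample_sigma=0.0,
                        n_genera_per_domain=5, samples_per_genus=2,
                        genome_length=60_000,
                        env_categories=("mesophile", "thermophile"))
        cfg0 = es.GeneratorConfig(seed=5, epsilon=1.0, **base_cfg)
        cfg3 = es.GeneratorConfig(seed=5, epsilon=3.0, **base_cfg)
        cs0, _, truth = es.generate_dataset(cfg0)
        cs3, meta3, _ = es.generate_dataset(cfg3)
        planted = truth.category_sets["thermophile"]
        thermo = [c for c, m in zip(cs3, meta3)
                  if m.temp_category == "thermophile"]
        f_tilted = mean_set_freq(thermo, planted)
        f_base = mean_set_freq(cs0, planted)
        t = stats.ttest_ind(f_tilted, f_base, alternative="greater")
        assert t.pvalue < 0.01

    def test_tilt_preserves_strand_symmetry_of_signal(self):
        T = np.full((16, 4), 0.25)
        _tilt(T, ["AAA"], 2.0)
        code = {b: i for i, b in enumerate("ACGT")}
        w, rc = "AAA", revcomp("AAA")
        assert T[code[w[0]] * 4 + code[w[1]], code[w[2]]] == 0.5
        assert T[code[rc[0]] * 4 + code[rc[1]], code[rc[2]]] == 0.5

    def test_transition_matrix_rows_normalized(self):
        T = _transition_matrix(["ACG"], ["TTA"], 1.5, 1.2,
                               [np.zeros((16, 4))])
        assert np.allclose(T.sum(axis=1), 1.0)


class TestOrthogonality:
    def test_environment_enrichment_independent_of_genus(self):
        """The planted environmental effect carries no genus structure: with
        the genus nuisance field off, planted-set frequencies show no genus
        effect (one-way ANOVA); with it on, the within-genus environmental
        contrast still points the same way in every genus."""
        from scipy import stats
        cfg = es.GeneratorConfig(seed=6, n_genera_per_domain=10,
                                 samples_per_genus=10, genome_length=60_000,
                                 genus_sigma=0.0,
                                 env_categories=("mesophile", "thermophile"))
        cs, meta, truth = es.generate_dataset(cfg)
        planted = truth.category_sets["thermophile"]
        thermo = [(c, m) for c, m in zip(cs, meta)
                  if m.temp_category == "thermophile"]
        freqs = mean_set_freq([c for c, _ in thermo], planted)
        genera = np.array([m.genus for _, m in thermo])
        groups = [freqs[genera == g] for g in np.unique(genera)]
        f = stats.f_oneway(*groups)
        assert f.pvalue > 0.01  # no genus effect on the environmental signal

    def test_environmental_contrast_positive_in_every_genus(self):
        cfg = es.GeneratorConfig(seed=8, n_genera_per_domain=5,
                                 samples_per_genus=8, genome_length=60_000,
                                 env_categories=("mesophile", "thermophile"))
        cs, meta, truth = es.generate_dataset(cfg)
        planted = truth.category_sets["thermophile"]
        freqs = mean_set_freq(cs, planted)
        for g in {m.genus for m in meta}:
            hot = [f for f, m in zip(freqs, meta)
                   if m.genus == g and m.temp_category == "thermophile"]
            cold = [f for f, m in zip(freqs, meta)
                    if m.genus == g and m.temp_category == "mesophile"]
            assert np.mean(hot) > np.mean(cold)


class TestFragmentBranchCoverage:
    def test_both_selection_modes_occur(self):
        cfg = es.GeneratorConfig(seed=7, n_genera_per_domain=8,
                                 samples_per_genus=2, genome_length=60_000)
        cs, _, _ = es.generate_dataset(cfg)
        modes = {es.select_fragment(c, target_len=50_000, seed=0).selection_mode
                 for c in cs}
        assert modes == {"single-contig-window", "concatenation"}
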