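"""End-to-end estimator behaviour on simulated genes."""

import numpy as np
import pytest
from sklearn.base import clone

from isospace.decomposition import SpaceDecomposition, TranscriptCountEstimator
from isospace.model import align_to_reference
from isospace.synthetic import NoiseParams, SimulationConfig, simulate_gene

from .conftest import probeset_indices


def _clean_cfg(n_samples=20):
    return SimulationConfig(n_samples=n_samples, noise=NoiseParams(0.0, 0.0))


class TestTranscriptCountEstimator:
    def test_single_transcript_noiseless(self, clean_gene):
        cfg = _clean_cfg()
        gene = simulate_gene("single", 1, cfg, seed=5)
        est = TranscriptCountEstimator(n_resamples=60, random_state=0).fit(gene.intensities)
        assert est.n_transcripts_ == 1

    def test_two_transcript_noiseless(self, clean_gene):
        est = TranscriptCountEstimator(n_resamples=60, random_state=0).fit(
            clean_gene.intensities
        )
        assert est.n_transcripts_ == 2

    def test_error_table_shape(self, clean_gene):
        est = TranscriptCountEstimator(n_resamples=25, random_state=0).fit(
            clean_gene.intensities
        )
        assert est.error_table_.shape == (25, 6)

    def test_sklearn_params_round_trip(self):
        est = TranscriptCountEstimator(alpha=0.01, n_resamples=50)
        cloned = clone(est)
        assert cloned.get_params()["alpha"] == 0.01
        cloned.set_params(alpha=0.1)
        assert cloned.alpha == 0.1


class TestSpaceDecomposition:
    def test_exact_recovery_on_clean_identifiable_genes(self):
        """Noiseless pipeline identity on identifiable genes.

        Identifiable here means the factorization is unique: each transcript
        has an anchor probe (hybridizing only to it) and an anchor sample
        (where only it is expressed).  Under these conditions the thresholded
        structure must equal the truth up to column order and each
        concentration row must correlate with the truth at r > 0.999.
        """
        from isospace.synthetic import (
            simulate_affinities,
            simulate_probe_signal,
            simulate_structure,
        )

        def separable(G):
            return all(
                any(row[j] == 1 and row.sum() == 1 for row in G)
                for j in range(G.shape[1])
            )

        n_tested = i = 0
        while n_tested < 10 and i < 300:
            gen_rng = np.random.default_rng(300 + i)
            i += 1
            G, _ = simulate_structure(8, (3, 4), 2, gen_rng)
            if not separable(G):
                continue
            n_tested += 1
            A = simulate_affinities(G.shape[0], gen_rng)
            T = np.hstack([np.eye(2) * 0.8, gen_rng.uniform(size=(2, 22))])
            Y = simulate_probe_signal(A, G, T, NoiseParams(0.0, 0.0), gen_rng)
            est = SpaceDecomposition(
                n_transcripts=2,
                outlier_correction=False,
                coherence=False,
                n_restarts=5,
                n_iter=6000,
                random_state=i,
            ).fit(Y)
            G_al, T_al = align_to_reference(
                est.structure_, G, est.concentrations_
            )
            np.testing.assert_array_equal(G_al, G)
            for j in range(2):
                assert np.corrcoef(T_al[j], T[j])[0, 1] > 0.999
        assert n_tested == 10

    def test_single_transcript_gene(self):
        cfg = _clean_cfg()
        gene = simulate_gene("single", 1, cfg, seed=8)
        est = SpaceDecomposition(n_resamples=40, random_state=0).fit(
            gene.intensities, probesets=probeset_indices(gene)
        )
        assert est.n_transcripts_ == 1
        np.testing.assert_array_equal(est.structure_, np.ones_like(est.structure_))

    def test_determinism_with_seed(self, noisy_gene):
        kwargs = dict(n_transcripts=3, n_resamples=40, n_iter=300, random_state=77)
        ps = probeset_indices(noisy_gene)
        a = SpaceDecomposition(**kwargs).fit(noisy_gene.intensities, probesets=ps)
        b = SpaceDecomposition(**kwargs).fit(noisy_gene.intensities, probesets=ps)
        np.testing.assert_array_equal(a.structure_, b.structure_)
        np.testing.assert_array_equal(a.concentrations_, b.concentrations_)
        assert a.loss_ == b.loss_

    def test_continuous_structure_in_unit_interval(self, noisy_gene):
        est = SpaceDecomposition(
            n_transcripts=3, n_resamples=40, n_iter=300, random_state=1
        ).fit(noisy_gene.intensities, probesets=probeset_indices(noisy_gene))
        G = est.continuous_structure_
        assert G.min() >= 0 and G.max() <= 1 + 1e-12

    def test_coherence_gives_identical_probeset_rows(self, noisy_gene):
        ps = probeset_indices(noisy_gene)
        est = SpaceDecomposition(
            n_transcripts=3, n_resamples=40, n_iter=300, random_state=1
        ).fit(noisy_gene.intensities, probesets=ps)
        for rows in ps:
            block = est.continuous_structure_[rows]
            assert len(np.unique(block, axis=0)) == 1

    def test_transform_deconvolves_new_samples(self, clean_gene):
        est = SpaceDecomposition(
            n_transcripts=2, outlier_correction=False, n_restarts=5, random_state=3
        ).fit(clean_gene.intensities, probesets=probeset_indices(clean_gene))
        T = est.transform(clean_gene.intensities)
        assert T.shape == (est.structure_.shape[1], clean_gene.intensities.shape[1])
        assert (T >= 0).all()

    def test_adapt_improves_concentration_error(self):
        """Direction check: gauge fixing lowers the mean concentration MAE."""
        from isospace.experiments import concentration_experiment

        res = concentration_experiment(n_genes=10, seed=7, n_iter=1500)
        assert res["mae_with_adapt"] <= res["mae_without_adapt"]
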