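"""Clustering, Eq.-style centroid-directed remodeling and generation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinomanifold.chemstore import CanonicalMolecule
from kinomanifold.latent_core import DecodePolicy
from kinomanifold.neighborhood import (
    ClusterModel,
    GeneratedSet,
    KSelection,
    RemodelConfig,
    diversity_score,
    generate_neighborhood,
    kmeans_fit,
    remodel,
    select_k,
)
from kinomanifold.synthkit import MixtureSpec, generate_latent_fixture


class TestRemodel:
    def test_s_zero_no_noise_is_identity(self):
        x, c = np.array([1.0, 2.0]), np.array([5.0, 5.0])
        out = remodel(x, c, RemodelConfig(s=0.0, noise_sd=0.0))
        np.testing.assert_array_equal(out, x)

    def test_s_one_no_noise_lands_on_centroid(self):
        x, c = np.array([1.0, 2.0]), np.array([5.0, 5.0])
        out = remodel(x, c, RemodelConfig(s=1.0, noise_sd=0.0))
        np.testing.assert_array_equal(out, c)

    def test_interpolation_arithmetic(self):
        out = remodel(np.zeros(2), np.array([10.0, 10.0]),
                      RemodelConfig(s=0.8, noise_sd=0.0))
        np.testing.assert_allclose(out, [8.0, 8.0])

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        st.floats(0, 1),
    )
    @settings(deadline=None, max_examples=80)
    def test_contraction_identity(self, xs, cs, s):
        """Without noise, ||x* - c|| = (1 - s) ||x - c|| exactly."""
        d = min(len(xs), len(cs))
        x, c = np.array(xs[:d]), np.array(cs[:d])
        out = remodel(x, c, RemodelConfig(s=s, noise_sd=0.0))
        np.testing.assert_allclose(
            np.linalg.norm(out - c), (1 - s) * np.linalg.norm(x - c), atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            remodel(np.zeros(2), np.zeros(3), RemodelConfig())

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RemodelConfig(s=1.5)
        with pytest.raises(ValueError):
            RemodelConfig(noise_sd=-1.0)

    def test_noise_is_seeded(self):
        cfg = RemodelConfig(s=0.5, noise_sd=1.0, seed=4)
        a = remodel(np.zeros(3), np.ones(3), cfg)
        b = remodel(np.zeros(3), np.ones(3), cfg)
        np.testing.assert_array_equal(a, b)


class TestKmeans:
    def test_k_one_centroid_is_mean(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(0, 1, (40, 3))
        cm = kmeans_fit(Z, 1, seed=0)
        np.testing.assert_allclose(cm.centroids[0], Z.mean(axis=0), atol=1e-9)

    def test_separated_blobs_recovered_exactly(self):
        spec = MixtureSpec(means=[[0, 0], [30, 0], [0, 30]], sds=1.0,
                           weights=[1 / 3] * 3, n=150, seed=2)
        Z, labels = generate_latent_fixture(spec)
        cm = kmeans_fit(Z, 3, seed=0)
        # assignments must be a relabeling of the generating partition
        mapping = {}
        for lab, assign in zip(labels, cm.assignments):
            mapping.setdefault(lab, assign)
            assert mapping[lab] == assign
        assert len(set(mapping.values())) == 3

    def test_points_assigned_to_nearest_centroid(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(0, 1, (60, 2))
        cm = kmeans_fit(Z, 4, seed=1)
        np.testing.assert_array_equal(cm.assign(Z), cm.assignments)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_fit(np.zeros((3, 2)), 5)


class TestSelectK:
    def _Z(self):
        return np.random.default_rng(0).normal(0, 1, (40, 4))

    def test_stub_favoring_three(self):
        def evaluator(cm):
            return {"validity": 1.0 if cm.k == 3 else 0.5, "diversity": 0.5}
        sel = select_k(self._Z(), [2, 3, 4, 5], evaluator)
        assert sel.k == 3
        assert len(sel.table) == 4

    def test_tie_goes_to_smallest_k(self):
        def evaluator(cm):
            return {"validity": 0.7, "diversity": 0.4}
        sel = select_k(self._Z(), [2, 3, 4, 5], evaluator)
        assert sel.k == 2

    def test_failing_k_excluded(self):
        def evaluator(cm):
            if cm.k == 2:
                raise RuntimeError("boom")
            return {"validity": cm.k / 10, "diversity": 0.0}
        sel = select_k(self._Z(), [2, 3, 4], evaluator)
        assert sel.k == 4
        assert "error" in sel.table[0]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_k(self._Z(), [], lambda cm: {})


class _HashEmbedding:
    """Stub embedding with scripted decoding behavior per molecule."""

    def __init__(self, dim=4, outputs=None):
        self.dim = dim
        self.outputs = outputs or []
        self.calls = 0

    def encode(self, mol):
        rng = np.random.default_rng(abs(hash(mol.smiles)) % 2**31)
        return rng.normal(0, 1, self.dim)

    def sample_smiles(self, z, rng, temperature=1.0):
        if not self.outputs:
            return "xx("
        out = self.outputs[self.calls % len(self.outputs)]
        self.calls += 1
        return out


def _inputs(n=6):
    base = ["CC(=O)Nc1ccc(O)cc1", "c1ccc2ncncc2c1", "CCOC(=O)c1ccccc1",
            "Cc1ccccc1N", "OCCOc1ccccc1", "NCCc1ccccc1"]
    return [CanonicalMolecule(smiles=s, family=f"fam{i % 2}")
            for i, s in enumerate(base[:n])]


def _cluster(dim=4):
    return ClusterModel(centroids=np.zeros((1, dim)),
                        assignments=np.zeros(1, dtype=int), inertia=0.0, seed=0)


class TestGenerateNeighborhood:
    def test_never_decoding_stub_conserves_inputs(self):
        vae = _HashEmbedding()
        cfg = RemodelConfig(s=0.8, noise_sd=0.0,
                            decode_policy=DecodePolicy(max_attempts=3), seed=0)
        gen = generate_neighborhood(_inputs(), vae, None, _cluster(), cfg)
        assert gen.molecules == []
        assert gen.losses["decode_failed"] == 6
        assert gen.conservation_holds()

    def test_scripted_decode_trace(self):
        # every molecule decodes to the same valid string on the first try
        vae = _HashEmbedding(outputs=["CC(=O)Nc1ccc(O)cc1"])
        cfg = RemodelConfig(s=0.8, noise_sd=0.0,
                            decode_policy=DecodePolicy(max_attempts=3), seed=0)
        gen = generate_neighborhood(_inputs(), vae, None, _cluster(), cfg)
        assert gen.n_generated == 6  # all inputs accounted as one molecule
        assert len(gen.molecules) == 1  # deduplicated
        assert gen.molecules[0].multiplicity == 6
        assert gen.conservation_holds()

    def test_deterministic_under_seed(self, toy_vae, vae_corpus, kal_model):
        Z = np.stack([toy_vae.encode(m) for m in vae_corpus])
        cluster = kmeans_fit(Z, 3, seed=1)
        cfg = RemodelConfig(s=0.8, noise_sd=0.2,
                            decode_policy=DecodePolicy(max_attempts=20), seed=9)
        a = generate_neighborhood(vae_corpus, toy_vae, kal_model, cluster, cfg)
        b = generate_neighborhood(vae_corpus, toy_vae, kal_model, cluster, cfg)
        assert [(m.molecule.smiles, m.kal, m.attempts) for m in a.molecules] == \
            [(m.molecule.smiles, m.kal, m.attempts) for m in b.molecules]
        assert a.losses == b.losses

    def test_end_to_end_conservation(self, toy_vae, vae_corpus, kal_model):
        Z = np.stack([toy_vae.encode(m) for m in vae_corpus])
        cluster = kmeans_fit(Z, 3, seed=1)
        cfg = RemodelConfig(s=0.8, noise_sd=0.2,
                            decode_policy=DecodePolicy(max_attempts=20), seed=9)
        gen = generate_neighborhood(vae_corpus, toy_vae, kal_model, cluster, cfg)
        assert gen.conservation_holds()

    def test_qualification_threshold(self):
        from kinomanifold.neighborhood import GeneratedMolecule
        g = GeneratedMolecule(
            molecule=CanonicalMolecule("CC(=O)Nc1ccc(O)cc1"),
            origin_family="LCK", source_smiles="C", kal=0.72, attempts=1,
            qualifies=0.72 > 0.7)
        assert g.qualifies


class TestDiversity:
    def test_identical_set_zero(self):
        m = CanonicalMolecule("c1ccccc1O")
        assert diversity_score([m, m]) == 0.0

    def test_singleton_zero(self):
        assert diversity_score([CanonicalMolecule("CCO")]) == 0.0
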