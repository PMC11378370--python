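"""Marginal ancestral reconstruction against explicit-summation oracles."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from denovoscenario import (
    MSA,
    SpeciesTree,
    SubstitutionModel,
    build_msa,
    confidence_filter,
    marginal_posteriors,
    reconstruct_ancestors,
)
from denovoscenario.ancestors import AncestralSequence

from conftest import RECOVERY_TREE
from oracles import brute_two_node_posteriors

BASES = "ACGT"


def _tree(newick):
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


class TestMarginalPosteriors:
    def test_vanishing_branches_pin_the_ancestor(self):
        tree = SpeciesTree(
            "((cerevisiae:1e-9,paradoxus:1e-9)A1:1e-9,mikatae:1e-9)A2;"
        )
        msa = MSA(rows={sp: "AAAA" for sp in ("cerevisiae", "paradoxus", "mikatae")})
        anc = reconstruct_ancestors(msa, tree)
        for node in ("A1", "A2"):
            assert anc[node].sequence == "AAAA"
            assert anc[node].posteriors[:, 0].min() > 0.999

    def test_two_tip_symmetry(self):
        # tips A and G at equal distance, kappa=1, uniform frequencies:
        # the ancestor is equally likely A or G, and either beats C/T
        tree = _tree("(a:0.2,b:0.2)anc;")
        model = SubstitutionModel(kappa=1.0)
        result = marginal_posteriors({"a": "A", "b": "G"}, tree, model)
        post = result["anc"].posteriors[0]
        assert post[0] == pytest.approx(post[2])
        assert post[1] == pytest.approx(post[3])
        assert post[0] > post[1]

    @given(
        codes=st.lists(
            st.tuples(*[st.integers(0, 3)] * 3), min_size=1, max_size=5
        ),
        bls=st.tuples(*[st.floats(0.01, 0.5)] * 4),
        kappa=st.floats(0.5, 4.0),
        gc=st.floats(0.2, 0.8),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_explicit_state_summation(self, codes, bls, kappa, gc):
        """Pruning posteriors equal brute-force summation over all 4^2
        internal state assignments on a 3-tip tree."""
        model = SubstitutionModel.from_gc(gc, kappa=kappa)
        t0, t1, t2, tin = bls
        tree = _tree(f"((a:{t0},b:{t1})inner:{tin},c:{t2})root;")
        rows = {
            name: "".join(BASES[col[i]] for col in codes)
            for i, name in enumerate("abc")
        }
        result = marginal_posteriors(rows, tree, model)
        for j, col in enumerate(codes):
            oracle_inner, oracle_root = brute_two_node_posteriors(
                col, (t0, t1, t2), tin, model
            )
            np.testing.assert_allclose(
                result["inner"].posteriors[j], oracle_inner, atol=1e-9
            )
            np.testing.assert_allclose(
                result["root"].posteriors[j], oracle_root, atol=1e-9
            )

    def test_posteriors_normalised_and_confidence_bounded(self, small_pipeline):
        _, sim, _ = small_pipeline
        tree = SpeciesTree(RECOVERY_TREE)
        truth = sim.truth.loci[0]
        msa = build_msa(
            {sp: truth.node_seqs[sp]["core"] for sp in
             ("cerevisiae", "paradoxus", "mikatae")},
            tree,
        )
        anc = reconstruct_ancestors(msa, tree)
        for node in ("A1", "A2"):
            sums = anc[node].posteriors.sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)
            assert 0.25 <= anc[node].confidence <= 1.0

    def test_longer_branches_lower_posterior_certainty(self):
        model = SubstitutionModel()
        rows = {"a": "A", "b": "G", "c": "C"}  # fully discordant column
        certainties = []
        for scale in (1.0, 2.0):
            tree = _tree(
                f"((a:{0.1*scale},b:{0.1*scale})inner:{0.05*scale},"
                f"c:{0.2*scale})root;"
            )
            post = marginal_posteriors(rows, tree, model)["inner"].posteriors[0]
            certainties.append(post.max())
        assert certainties[1] < certainties[0]

    def test_missing_required_leaf_rejected(self):
        tree = SpeciesTree()
        msa = MSA(rows={"cerevisiae": "ACGT", "paradoxus": "ACGT"})
        with pytest.raises(ValueError):
            reconstruct_ancestors(msa, tree)


class TestConfidenceFilter:
    def _anc(self, maxima):
        n = len(maxima)
        post = np.zeros((n, 4))
        for i, m in enumerate(maxima):
            post[i, 0] = m
            post[i, 1:] = (1 - m) / 3
        return AncestralSequence(
            node="A1",
            sequence="A" * n,
            posteriors=post,
            base_columns=np.ones(n, dtype=bool),
        )

    def test_perfect_posteriors_kept(self):
        assert confidence_filter(self._anc([1.0, 1.0, 1.0]))

    def test_mean_below_threshold_discarded(self):
        anc = self._anc([0.9, 0.7, 0.8, 0.6])
        assert anc.confidence == pytest.approx(0.75)
        assert not confidence_filter(anc)

    def test_default_threshold_is_080(self):
        import inspect

        sig = inspect.signature(confidence_filter)
        assert sig.parameters["threshold"].default == 0.80


class TestRecoveryFromSimulation:
    def test_argmax_ancestor_matches_truth(self):
        """With short branches and no indels, the reconstructed A1
        matches the true ancestor at >= 95% of sites with high mean
        confidence."""
        from denovoscenario import SimConfig, simulate_catalogue

        config = SimConfig(
            tree_spec=RECOVERY_TREE,
            n_loci_per_class={"S0+": 0, "S1": 0, "S2": 0, "intergene": 40},
            locus_length=300,
            flank_length=0,
            indel_rate=0.0,
            seed=9,
        )
        sim = simulate_catalogue(config)
        tree = SpeciesTree(RECOVERY_TREE)
        matches = total = 0
        confidences = []
        for truth in sim.truth.loci:
            rows = {
                sp: truth.node_seqs[sp]["core"]
                for sp in ("cerevisiae", "paradoxus", "mikatae")
            }
            msa = build_msa(rows, tree)
            anc = reconstruct_ancestors(msa, tree)["A1"]
            true_a1 = truth.node_seqs["A1"]["core"]
            assert len(anc.sequence) == len(true_a1)  # no indels anywhere
            matches += sum(a == b for a, b in zip(anc.sequence, true_a1))
            total += len(true_a1)
            confidences.append(anc.confidence)
        assert matches / total >= 0.95
        assert np.mean(confidences) >= 0.90
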