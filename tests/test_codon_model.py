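import numpy as np
import pytest

from orfstat import (
    CodonUsage,
    GeneticCodeConfig,
    codon_usage,
    extract_aorfs,
    frame_minus1_usage,
    frame_probabilities,
    frame_shift_stationary,
    stationary_distribution,
    transition_matrix,
)
from orfstat._codons import CODON_INDEX, codon_indices, encode_sequence
from orfstat.codon_model import TransitionMatrix
from orfstat.genome_io import GeneAnnotation, GenomeRecord
from orfstat.rcodon import RcodonSpec, simulate


def usage_from(weights: dict[str, float]) -> CodonUsage:
    p = np.zeros(64)
    for codon, w in weights.items():
        p[CODON_INDEX[codon]] = w
    return CodonUsage(p / p.sum())


class TestGeneticCodeConfig:
    def test_defaults(self):
        code = GeneticCodeConfig.standard()
        assert code.stop_set == {"TAA", "TAG", "TGA"}
        assert code.start_set == {"ATG", "GTG", "TTG", "CTG"}

    def test_mollicute_drops_tga(self):
        assert GeneticCodeConfig.mollicute().stop_set == {"TAA", "TAG"}

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            GeneticCodeConfig(stop_set=frozenset({"ATG"}))


class TestCodonUsage:
    def test_single_gene(self):
        rec = GenomeRecord("X", "ATGAAATAA")
        aorfs = extract_aorfs(rec, [GeneAnnotation("g", 1, 9, "+")])
        u = codon_usage(aorfs, rec.sequence)
        assert u["ATG"] == u["AAA"] == u["TAA"] == pytest.approx(1 / 3)
        assert u.probabilities.sum() == pytest.approx(1.0)

    def test_two_genes_denominator(self):
        rec = GenomeRecord("X", "ATGTAAATGAAAGGGTAA")
        genes = [GeneAnnotation("a", 1, 6, "+"), GeneAnnotation("b", 7, 18, "+")]
        aorfs = extract_aorfs(rec, genes)
        u = codon_usage(aorfs, rec.sequence)
        assert u["ATG"] == pytest.approx(2 / 6)
        assert u["TAA"] == pytest.approx(2 / 6)

    def test_minus_strand_counted_on_coding_strand(self):
        rec = GenomeRecord("X", "TTACATCAT")  # revcomp ATGATGTAA
        aorfs = extract_aorfs(rec, [GeneAnnotation("g", 1, 9, "-")])
        u = codon_usage(aorfs, rec.sequence)
        assert u["ATG"] == pytest.approx(2 / 3)
        assert u["TAA"] == pytest.approx(1 / 3)

    def test_rho_plus1_matches_mean_gene_length(self, toy_genome):
        """rho_+1 ~ 1/(mean annotated gene length in codons + 1): every gene
        contributes exactly one stop codon to the concatenated usage."""
        from orfstat import filter_genes

        genes = filter_genes(toy_genome)
        aorfs = extract_aorfs(toy_genome, genes)
        u = codon_usage(aorfs, toy_genome.sequence)
        fp = frame_probabilities(u)
        mean_codons = np.mean([g.span // 3 - 1 for g in genes])
        assert fp.rho[1] == pytest.approx(1 / (mean_codons + 1), rel=1e-9)

    def test_tsv_round_trip(self, tmp_path, skewed_usage):
        p = tmp_path / "usage.tsv"
        skewed_usage.to_tsv(p)
        again = CodonUsage.from_tsv(p)
        np.testing.assert_allclose(again.probabilities, skewed_usage.probabilities)


class TestFrameMinus1Usage:
    def test_reverse_complement_mapping(self):
        u = usage_from({"CTA": 0.2, "AAA": 0.8})
        q = frame_minus1_usage(u)
        assert q["TAG"] == pytest.approx(0.2)  # revcomp(CTA) = TAG
        assert q["TTT"] == pytest.approx(0.8)

    def test_uniform_fixed_point(self, uniform_usage):
        q = frame_minus1_usage(uniform_usage)
        np.testing.assert_allclose(q.probabilities, uniform_usage.probabilities)

    def test_no_minus1_stops_without_rc_stop_codons(self):
        u = usage_from({"ATG": 1 / 3, "AAA": 1 / 3, "TAA": 1 / 3})
        fp_rho = frame_probabilities(u).rho
        assert fp_rho[-1] == 0  # TTA, CTA, TCA all absent from the usage

    def test_involution(self, skewed_usage):
        twice = frame_minus1_usage(frame_minus1_usage(skewed_usage))
        np.testing.assert_allclose(twice.probabilities, skewed_usage.probabilities)


class TestTransitionMatrix:
    @pytest.mark.parametrize("frame", [2, 3, -2, -3])
    def test_uniform_usage_gives_uniform_matrix(self, uniform_usage, frame):
        tm = transition_matrix(uniform_usage, frame)
        np.testing.assert_allclose(tm.matrix, np.full((64, 64), 1 / 64))

    @pytest.mark.parametrize("frame", [2, 3])
    def test_degenerate_single_codon_absorbs(self, frame):
        u = usage_from({"AAA": 1.0})
        tm = transition_matrix(u, frame)
        i = CODON_INDEX["AAA"]
        assert tm.matrix[i, i] == pytest.approx(1.0)

    @pytest.mark.parametrize("frame", [2, 3, -2, -3])
    def test_rows_stochastic(self, skewed_usage, frame):
        tm = transition_matrix(skewed_usage, frame)
        np.testing.assert_allclose(tm.matrix.sum(axis=1), 1.0, atol=1e-12)
        assert (tm.matrix >= 0).all()

    def test_invalid_frame_rejected(self, uniform_usage):
        with pytest.raises(ValueError):
            transition_matrix(uniform_usage, 1)

    def test_matches_empirical_dicodons(self):
        """Transition law agrees with empirical frame +2 dicodon statistics
        of an IID codon simulation, within 4 standard errors per cell."""
        u = usage_from({"ATG": 0.5, "TAA": 0.3, "GGC": 0.2})
        tm = transition_matrix(u, 2)
        seq = simulate(RcodonSpec(u, 600_000, seed=5))
        cods = codon_indices(encode_sequence(seq), offset=1)
        visits = np.bincount(cods[:-1], minlength=64).astype(float)
        trans = np.zeros((64, 64))
        np.add.at(trans, (cods[:-1], cods[1:]), 1)
        for c in np.flatnonzero(visits >= 500):
            emp = trans[c] / visits[c]
            se = np.sqrt(tm.matrix[c] * (1 - tm.matrix[c]) / visits[c])
            dev = np.abs(emp - tm.matrix[c]) / np.maximum(se, 1e-12)
            assert dev.max() < 4.0


class TestStationaryDistribution:
    def test_uniform_matrix(self):
        d = stationary_distribution(TransitionMatrix(np.full((64, 64), 1 / 64), 2))
        np.testing.assert_allclose(d, 1 / 64)

    def test_doubly_stochastic_gives_uniform(self):
        # a circulant permutation-mixture is doubly stochastic
        Q = np.zeros((64, 64))
        for i in range(64):
            Q[i, (i + 1) % 64] = 0.5
            Q[i, (i + 7) % 64] = 0.5
        d = stationary_distribution(TransitionMatrix(Q, 2))
        np.testing.assert_allclose(d, 1 / 64, atol=1e-9)

    def test_reducible_chain_rejected(self):
        Q = np.eye(64)
        with pytest.raises(ValueError, match="closed classes"):
            stationary_distribution(TransitionMatrix(Q, 2))

    @pytest.mark.parametrize("frame", [2, 3, -2, -3])
    def test_fixed_point_and_closed_form(self, skewed_usage, frame):
        """The linear-solve stationary distribution is a fixed point and
        equals the product-form closed form of the shifted process."""
        tm = transition_matrix(skewed_usage, frame)
        d = stationary_distribution(tm)
        assert np.abs(d @ tm.matrix - d).sum() < 1e-10
        assert d.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(d, frame_shift_stationary(skewed_usage, frame), atol=1e-10)

    def test_matches_simulation(self):
        u = usage_from({"ATG": 0.5, "TAA": 0.3, "GGC": 0.2})
        d = stationary_distribution(transition_matrix(u, 2))
        seq = simulate(RcodonSpec(u, 600_000, seed=5))
        cods = codon_indices(encode_sequence(seq), offset=1)
        emp = np.bincount(cods, minlength=64) / len(cods)
        se = np.sqrt(d * (1 - d) / len(cods))
        assert (np.abs(emp - d) / np.maximum(se, 1e-12)).max() < 4.0


class TestFrameProbabilities:
    def test_uniform_standard_code(self, uniform_usage):
        fp = frame_probabilities(uniform_usage)
        for f in (1, 2, 3, -1, -2, -3):
            assert fp.rho[f] == pytest.approx(3 / 64, abs=1e-12)
            assert fp.tau[f] == pytest.approx(4 / 64, abs=1e-12)

    def test_uniform_mollicute_code(self, uniform_usage):
        fp = frame_probabilities(uniform_usage, GeneticCodeConfig.mollicute())
        for f in (1, 2, 3, -1, -2, -3):
            assert fp.rho[f] == pytest.approx(2 / 64, abs=1e-12)

    def test_toy_usage_direct_sums(self):
        u = usage_from({"ATG": 1 / 3, "AAA": 1 / 3, "TAA": 1 / 3})
        fp = frame_probabilities(u)
        assert fp.rho[1] == pytest.approx(1 / 3)
        assert fp.tau[1] == pytest.approx(1 / 3)

    def test_strictly_positive_usage_gives_interior_probs(self, skewed_usage):
        fp = frame_probabilities(skewed_usage)
        rho, tau = fp.as_arrays()
        assert ((rho > 0) & (rho < 1)).all()
        assert ((tau > 0) & (tau < 1)).all()

    def test_minus2_equals_plus2_of_minus1_usage(self, skewed_usage):
        """Frame symmetry: the -2 construction is the +2 construction
        applied to the -1 usage."""
        via_minus1 = stationary_distribution(
            transition_matrix(frame_minus1_usage(skewed_usage), 2)
        )
        fp = frame_probabilities(skewed_usage)
        np.testing.assert_allclose(fp.distributions[-2], via_minus1, atol=1e-12)

    def test_product_form_usage_collapses_frames(self):
        """When the three codon positions are independent, all six frames
        share one codon distribution only if the factors are reverse-
        complement symmetric; at minimum the shifted frames agree with
        their closed forms and rho varies smoothly. Use a palindromic
        factorization so the collapse is exact."""
        f = np.array([0.3, 0.2, 0.2, 0.3])  # complement-symmetric
        p = np.einsum("a,b,c->abc", f, f, f).reshape(64)
        fp = frame_probabilities(CodonUsage(p))
        base = fp.distributions[1]
        for fr in (2, 3, -1, -2, -3):
            np.testing.assert_allclose(fp.distributions[fr], base, atol=1e-12)
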