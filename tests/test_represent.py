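import json
import math
from importlib import resources

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepforge.peptide_io import AMINO_ACIDS, Peptide, PeptideDataset
from pepforge.represent import (
    BackendUnavailableError,
    EmbeddingCache,
    MockPLMBackend,
    OneHotBackend,
    compare_distributions,
    embed,
    get_backend,
    isoelectric_point,
    mean_pool,
    net_charge,
    one_hot_matrix,
    property_profile,
)

seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=30)


class TestOneHot:
    def test_rows_are_unit_vectors(self):
        m = one_hot_matrix("ACD")
        assert m.shape == (3, 20)
        assert np.allclose(m.sum(axis=1), 1.0)
        assert len({tuple(r) for r in m}) == 3

    @given(seq=seq_strategy)
    @settings(max_examples=40, deadline=None)
    def test_pooled_one_hot_is_composition(self, seq):
        vec = mean_pool(one_hot_matrix(seq))
        assert vec.sum() == pytest.approx(1.0)
        for i, aa in enumerate(AMINO_ACIDS):
            assert vec[i] == pytest.approx(seq.count(aa) / len(seq))

    def test_mean_pool_of_single_residue_is_identity(self):
        m = one_hot_matrix("W")
        assert np.array_equal(mean_pool(m), m[0])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            mean_pool(np.zeros((0, 20)))


class TestBackends:
    def test_mock_backend_deterministic(self):
        b = MockPLMBackend(seed=3)
        v1 = embed("ACDEFGHIKL", b)
        v2 = embed("ACDEFGHIKL", b)
        assert np.array_equal(v1, v2)
        assert v1.shape == (32,)

    def test_mock_backend_position_sensitive(self):
        b = MockPLMBackend(seed=3)
        assert not np.allclose(embed("ACDEFGHIKL", b), embed("LKIHGFEDCA", b))

    def test_onehot_backend_equals_direct_pipeline(self):
        p = Peptide("x", "ACDEFG")
        via_backend = embed(p, OneHotBackend())
        direct = mean_pool(one_hot_matrix(p))
        assert np.array_equal(via_backend, direct)

    def test_cache_hit_bit_identical(self, tmp_path):
        cache = EmbeddingCache(tmp_path)
        b = MockPLMBackend(seed=1)
        cold = embed("ACDEFGHIKL", b, cache)
        warm = embed("ACDEFGHIKL", b, cache)
        assert np.array_equal(cold, warm)
        fresh_cache = EmbeddingCache(tmp_path)  # forces disk read
        assert np.array_equal(fresh_cache.get(b.name, "ACDEFGHIKL"), cold)

    def test_real_plm_names_raise_actionable_error(self):
        with pytest.raises(BackendUnavailableError, match="install"):
            get_backend("esm2-8m")
        with pytest.raises(BackendUnavailableError):
            get_backend("nonsense-backend")


def _scales():
    with resources.files("pepforge.data").joinpath("scales.json").open() as fh:
        return json.load(fh)


def brute_force_profile(seq: str, ph: float = 7.0) -> dict:
    """Independent re-derivation of every descriptor with explicit loops."""
    scales = _scales()
    n = len(seq)
    ai = 100.0 * (
        seq.count("A") / n
        + 2.9 * seq.count("V") / n
        + 3.9 * (seq.count("I") / n + seq.count("L") / n)
    )
    boman = sum(scales["boman"][c] for c in seq) / n
    pka = scales["pka"]

    def charge(at_ph):
        total = 1.0 / (1.0 + 10 ** (at_ph - pka["n_terminus"]))
        total -= 1.0 / (1.0 + 10 ** (pka["c_terminus"] - at_ph))
        for c in seq:
            if c in pka["positive_side_chains"]:
                total += 1.0 / (1.0 + 10 ** (at_ph - pka["positive_side_chains"][c]))
            if c in pka["negative_side_chains"]:
                total -= 1.0 / (1.0 + 10 ** (pka["negative_side_chains"][c] - at_ph))
        return total

    re_im = [0.0, 0.0]
    for j, c in enumerate(seq):
        h = scales["hydrophobicity_eisenberg"][c]
        re_im[0] += h * math.cos(math.radians(100.0) * j)
        re_im[1] += h * math.sin(math.radians(100.0) * j)
    hm = math.hypot(*re_im) / n
    return {
        "aliphatic_index": ai,
        "boman_index": boman,
        "net_charge": charge(ph),
        "hydrophobic_moment": hm,
    }


class TestProperties:
    def test_poly_alanine_aliphatic_index(self):
        assert property_profile("AAAAA").aliphatic_index == pytest.approx(100.0)

    def test_lysine_charge_at_low_ph_approaches_two(self):
        # N-terminus + side chain fully protonated, C-terminus mostly neutral
        assert net_charge("K", ph=1.0) == pytest.approx(2.0, abs=0.01)

    def test_pi_satisfies_solver_contract(self):
        for seq in ("KKKDDD", "ACDEFGHIKL", "RRRR", "DDDD"):
            pi = isoelectric_point(seq)
            assert 0.0 <= pi <= 14.0
            assert abs(net_charge(seq, pi)) < 1e-4

    def test_charge_decreases_with_ph(self):
        phs = np.linspace(0, 14, 30)
        charges = [net_charge("ACKDEH", p) for p in phs]
        assert all(a >= b for a, b in zip(charges, charges[1:]))

    def test_profile_matches_brute_force_on_random_peptides(self):
        rng = np.random.default_rng(23)
        aa = list(AMINO_ACIDS)
        for _ in range(20):
            seq = "".join(rng.choice(aa, size=rng.integers(3, 40)))
            got = property_profile(seq)
            want = brute_force_profile(seq)
            assert got.aliphatic_index == pytest.approx(
                want["aliphatic_index"], abs=1e-9)
            assert got.boman_index == pytest.approx(
                want["boman_index"], abs=1e-9)
            assert got.net_charge == pytest.approx(
                want["net_charge"], abs=1e-9)
            assert got.hydrophobic_moment == pytest.approx(
                want["hydrophobic_moment"], abs=1e-9)
            assert got.hydrophobic_moment >= 0.0


class TestCompareDistributions:
    def _ds(self, lengths, prefix):
        return PeptideDataset(
            [Peptide(f"{prefix}{i}", "A" * n) for i, n in enumerate(lengths)]
        )

    def test_self_distance_zero(self):
        a = self._ds([10, 12, 14], "a")
        assert compare_distributions(a, a, "length")["wasserstein"] == 0.0

    def test_point_masses_distance_is_shift(self):
        a = self._ds([10, 10], "a")
        b = self._ds([11, 11], "b")
        assert compare_distributions(a, b, "length")["wasserstein"] == 1.0

    def test_shift_property(self):
        a = self._ds([10, 12, 20], "a")
        b = self._ds([13, 15, 23], "b")
        assert compare_distributions(a, b, "length")["wasserstein"] == (
            pytest.approx(3.0))

    def test_unknown_property_rejected(self):
        a = self._ds([10], "a")
        with pytest.raises(ValueError, match="unknown property"):
            compare_distributions(a, a, "molecular_weight")
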