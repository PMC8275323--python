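import numpy as np
import pytest

from tcrbind import (AttentionMatrix, TCRBindingModel, attention_variances,
                     compress_epitopes, extract_attention)
from tcrbind.records import BindingRecord, ConfigurationError


@pytest.fixture(scope="module")
def fitted_shim(tiny_config):
    """An initialized (untrained) model over a toy dataset."""
    records = [BindingRecord("GILGFVFT", "CASSLGQAYEQY", 1),
               BindingRecord("NLVPMVAT", "CASSIRSSYEQF", 0)]
    return TCRBindingModel(records, config=tiny_config, rng_seed=1)


class TestExtractAttention:
    def test_rows_sum_to_one_and_align_with_pairs(self, fitted_shim):
        pairs = [("CASSLGQAYEQY", "GILGFVFT"), ("CASSIRSSYEQF", "NLVPMVAT")]
        tcr_mat, epi_mat = extract_attention(fitted_shim, pairs)
        assert tcr_mat.values.shape == (2, fitted_shim.config.tcr_len)
        assert epi_mat.values.shape == (2, fitted_shim.config.epitope_len)
        assert np.allclose(tcr_mat.values.sum(axis=1), 1.0)
        assert tcr_mat.reference_ids == [p[0] for p in pairs]
        assert epi_mat.reference_ids == [p[1] for p in pairs]

    def test_same_pair_twice_gives_identical_rows(self, fitted_shim):
        pairs = [("CASSLGQAYEQY", "GILGFVFT")] * 2
        tcr_mat, _ = extract_attention(fitted_shim, pairs)
        assert np.array_equal(tcr_mat.values[0], tcr_mat.values[1])

    def test_zeroed_embeddings_give_uniform_attention(self, fitted_shim):
        import copy

        model = copy.deepcopy(fitted_shim)
        for stream in ("tcr", "epi"):
            model.network.params[f"{stream}.embedding"].data[:] = 0.0
        tcr_mat, epi_mat = extract_attention(
            model, [("CASSLGQAYEQY", "GILGFVFT")])
        T, U = model.config.tcr_len, model.config.epitope_len
        assert np.allclose(tcr_mat.values, 1 / T)
        assert np.allclose(epi_mat.values, 1 / U)

    def test_matrix_rejects_unnormalized_rows(self):
        with pytest.raises(ValueError):
            AttentionMatrix(np.array([[0.5, 0.2]]))

    def test_tsv_round_trip(self, fitted_shim, tmp_path):
        import pandas as pd

        tcr_mat, _ = extract_attention(fitted_shim,
                                       [("CASSLGQAYEQY", "GILGFVFT")])
        p = tmp_path / "att.tsv"
        tcr_mat.to_tsv(p)
        df = pd.read_csv(p, sep="\t")
        assert np.allclose(df.iloc[:, 2:].to_numpy(), tcr_mat.values)


class TestAttentionVariances:
    def test_identical_rows_give_zero_variances(self):
        rows = np.tile(np.full(4, 0.25), (6, 1))
        mat = AttentionMatrix(rows, reference_ids=list("aabbcc"),
                              context_ids=list("xyxyxy"))
        out = attention_variances(mat, group_by="reference")
        assert out["inter"] == 0.0 and out["intra"] == 0.0

    def test_constant_but_distinct_groups(self):
        a = np.array([0.7, 0.1, 0.1, 0.1])
        b = np.array([0.1, 0.1, 0.1, 0.7])
        mat = AttentionMatrix(np.stack([a, a, b, b]),
                              reference_ids=list("aabb"),
                              context_ids=list("xyxy"))
        out = attention_variances(mat)
        assert out["intra"] == 0.0 and out["inter"] > 0.0

    def test_hand_computed_toy_matrix(self):
        rows = np.array([[0.5, 0.3, 0.2],
                         [0.3, 0.5, 0.2],
                         [0.2, 0.2, 0.6]])
        mat = AttentionMatrix(rows, reference_ids=["a", "a", "b"],
                              context_ids=["x", "y", "x"])
        out = attention_variances(mat, group_by="reference")
        # group means: a=(0.4,0.4,0.2), b=(0.2,0.2,0.6)
        # inter per token: var([0.4,0.2]), var([0.4,0.2]), var([0.2,0.6])
        expected_inter = np.mean([0.01, 0.01, 0.04])
        # intra: only group a has 2 rows -> per-token var [0.01,0.01,0]
        expected_intra = np.mean([0.01, 0.01, 0.0])
        assert out["inter"] == pytest.approx(expected_inter)
        assert out["intra"] == pytest.approx(expected_intra)

    def test_sample_variance_option(self):
        rows = np.array([[0.6, 0.4], [0.4, 0.6]])
        mat = AttentionMatrix(rows, reference_ids=["a", "b"],
                              context_ids=["x", "x"])
        pop = attention_variances(mat)["inter"]
        samp = attention_variances(mat, ddof=1)["inter"]
        assert samp == pytest.approx(2 * pop)

    def test_single_group_rejected(self):
        mat = AttentionMatrix(np.full((2, 2), 0.5),
                              reference_ids=["a", "a"], context_ids=["x", "y"])
        with pytest.raises(ConfigurationError):
            attention_variances(mat, group_by="reference")


class TestCompressEpitopes:
    def test_all_below_threshold_gives_empty_string(self):
        out, n, _ = compress_epitopes(["GILGF", "NLVPM"],
                                      np.full((2, 5), 0.05))
        assert out == ["", ""]
        assert n == 0  # the two empty compressions collide

    def test_threshold_zero_is_identity(self):
        epis = ["GILGF", "NLVPM", "GILGF"]
        rows = np.full((3, 5), 0.2)
        out, n, frac = compress_epitopes(epis, rows, threshold=0.0)
        assert out == epis
        assert n == 1  # only NLVPM is unique among originals
        assert frac == pytest.approx(1 / 3)

    def test_constructed_collision_counts_unique(self):
        epis = ["ABCD", "ABXD", "EFGH", "IJKL", "MNOP"]
        # keep positions 0,1,3 for the first two -> "ABD" collides
        row_013 = np.array([0.3, 0.3, 0.05, 0.3])
        row_all = np.full(4, 0.25)
        rows = np.stack([row_013, row_013, row_all, row_all, row_all])
        out, n, frac = compress_epitopes(epis, rows, threshold=0.1)
        assert out[:2] == ["ABD", "ABD"]
        assert n == 3 and frac == pytest.approx(0.6)

    def test_raising_threshold_never_increases_uniqueness_on_fixture(self):
        rng = np.random.default_rng(8)
        epis = ["".join("ACDEFGHIKL"[i] for i in rng.integers(10, size=8))
                for _ in range(12)]
        rows = rng.dirichlet(np.ones(8), size=12)
        uniques = [compress_epitopes(epis, rows, threshold=th)[1]
                   for th in (0.05, 0.1, 0.2, 0.4)]
        assert all(a >= b for a, b in zip(uniques, uniques[1:]))

    def test_per_class_attention_keeps_epitopes_identifiable(self):
        # each epitope gets its own concentrated attention profile: the
        # compressed strings should stay (nearly) unique, the implicit
        # epitope-classifier signature
        rng = np.random.default_rng(9)
        epis = []
        while len(epis) < 20:
            e = "".join(AA20[i] for i in rng.integers(20, size=9))
            if e not in epis:
                epis.append(e)
        rows = np.zeros((20, 9))
        for i in range(20):
            keep = rng.choice(9, size=3, replace=False)
            rows[i, keep] = 1 / 3
        _, n, frac = compress_epitopes(epis, rows, threshold=0.1)
        assert frac > 0.9


AA20 = "ACDEFGHIKLMNPQRSTVWY"
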