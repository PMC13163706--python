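import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sagedriver.preprocess import (
    PPINetwork,
    build_dataset,
    compute_zscores,
    filter_mutated_genes,
    flag_aberrant,
    load_driver_genes,
    load_ppi_edges,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadPPI:
    def test_threshold_keeps_edges_at_or_above(self, tmp_path):
        p = _write(tmp_path, "ppi.tsv", "A\tB\t0.4\nB\tC\t0.5\nC\tD\t0.9\n")
        net = load_ppi_edges(p, min_confidence=0.5)
        assert net.n_edges == 2

    def test_strict_threshold_drops_boundary(self, tmp_path):
        p = _write(tmp_path, "ppi.tsv", "A\tB\t0.4\nB\tC\t0.5\nC\tD\t0.9\n")
        net = load_ppi_edges(p, min_confidence=0.5, strict_greater=True)
        assert net.n_edges == 1

    def test_self_loops_dropped(self, tmp_path):
        p = _write(tmp_path, "ppi.tsv", "TP53\tTP53\t0.99\nTP53\tMDM2\t0.9\n")
        net = load_ppi_edges(p, min_confidence=0.5)
        assert net.edges() == [("TP53", "MDM2", 0.9)]

    def test_duplicate_pairs_keep_max_confidence(self, tmp_path):
        p = _write(tmp_path, "ppi.tsv", "A\tB\t0.6\nB\tA\t0.8\n")
        net = load_ppi_edges(p, min_confidence=0.5)
        assert net.n_edges == 1
        (u, v, c), = net.edges()
        assert {u, v} == {"A", "B"} and c == 0.8

    def test_missing_confidence_treated_as_one(self, tmp_path):
        p = _write(tmp_path, "ppi.tsv", "A\tB\n")
        assert load_ppi_edges(p, min_confidence=0.99).n_edges == 1

    def test_malformed_rows_raise(self, tmp_path):
        with pytest.raises(ValueError):
            load_ppi_edges(_write(tmp_path, "a.tsv", "ONLYONE\n"))
        with pytest.raises(ValueError):
            load_ppi_edges(_write(tmp_path, "b.tsv", "A\tB\tnotanumber\n"))

    @given(thresh=st.floats(min_value=0, max_value=1))
    @settings(max_examples=25, deadline=None)
    def test_edge_count_monotone_in_threshold(self, tmp_path_factory, thresh):
        tmp = tmp_path_factory.mktemp("ppi")
        confs = [0.1, 0.3, 0.5, 0.5, 0.7, 0.9]
        rows = "".join(f"g{i}\th{i}\t{c}\n" for i, c in enumerate(confs))
        p = _write(tmp, "ppi.tsv", rows)
        n_lo = load_ppi_edges(p, min_confidence=thresh).n_edges
        n_hi = load_ppi_edges(p, min_confidence=min(thresh + 0.2, 1.0)).n_edges
        assert n_hi <= n_lo


class TestZScores:
    def test_constant_row_is_zero(self):
        expr = pd.DataFrame([[5.0, 5.0, 5.0]], index=["g"], columns=list("abc"))
        assert (compute_zscores(expr).to_numpy() == 0).all()

    def test_population_sigma_hand_value(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        z = compute_zscores(expr).to_numpy()[0]
        np.testing.assert_allclose(z, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_single_sample_rejected(self):
        expr = pd.DataFrame([[1.0]], index=["g"], columns=["a"])
        with pytest.raises(ValueError):
            compute_zscores(expr)

    @given(a=st.floats(min_value=0.1, max_value=10), b=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_flags_invariant_under_affine_rescaling(self, a, b):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(
            rng.normal(size=(5, 8)), index=[f"g{i}" for i in range(5)]
        )
        flags = flag_aberrant(compute_zscores(expr))
        flags2 = flag_aberrant(compute_zscores(expr * a + b))
        pd.testing.assert_frame_equal(flags, flags2)


class TestFlagAberrant:
    @pytest.mark.parametrize(
        "z,two_sided,expected",
        [(2.0, False, 1), (1.999, False, 0), (-3.0, False, 0), (-3.0, True, 1)],
    )
    def test_threshold_and_sign_convention(self, z, two_sided, expected):
        df = pd.DataFrame([[z]], index=["g"], columns=["s"])
        assert flag_aberrant(df, two_sided=two_sided).iloc[0, 0] == expected


class TestFilterMutatedGenes:
    @staticmethod
    def _toy(mut_rows, ab_rows):
        genes = ["g1", "g2", "g3"]
        cols = ["s1", "s2"]
        mut = pd.DataFrame(mut_rows, index=genes, columns=cols)
        ab = pd.DataFrame(ab_rows, index=genes, columns=cols)
        ppi = PPINetwork.from_edges([("g1", "g2", 1.0), ("g2", "g3", 1.0)])
        return mut, ab, ppi

    def test_same_sample_coupling_retains(self):
        # g1 mutated in s1; neighbor g2 aberrant in s1
        mut, ab, ppi = self._toy([[1, 0], [0, 0], [0, 0]], [[0, 0], [1, 0], [0, 0]])
        assert filter_mutated_genes(mut, ab, ppi) == ["g1"]

    def test_cross_sample_aberration_not_coupled(self):
        # g1 mutated only in s1, neighbor aberrant only in s2
        mut, ab, ppi = self._toy([[1, 0], [0, 0], [0, 0]], [[0, 0], [0, 1], [0, 0]])
        assert filter_mutated_genes(mut, ab, ppi) == []
        assert filter_mutated_genes(mut, ab, ppi, same_sample=False) == ["g1"]

    def test_never_mutated_gene_excluded(self):
        mut, ab, ppi = self._toy([[1, 0], [0, 0], [0, 0]], [[1, 1], [1, 1], [1, 1]])
        retained = filter_mutated_genes(mut, ab, ppi)
        assert "g2" not in retained and "g3" not in retained

    def test_monotone_in_ppi_edges(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(8)]
        mut = pd.DataFrame(rng.integers(0, 2, (8, 5)), index=genes)
        ab = pd.DataFrame(rng.integers(0, 2, (8, 5)), index=genes)
        small = [("g0", "g1", 1.0), ("g2", "g3", 1.0)]
        extra = small + [("g4", "g5", 1.0), ("g1", "g6", 1.0)]
        r_small = set(filter_mutated_genes(mut, ab, PPINetwork.from_edges(small)))
        r_big = set(filter_mutated_genes(mut, ab, PPINetwork.from_edges(extra)))
        assert r_small <= r_big


class TestBuildDataset:
    def _frames(self):
        genes = ["g1", "g2", "g3"]
        expr = pd.DataFrame(
            np.arange(9, dtype=float).reshape(3, 3), index=genes, columns=list("abc")
        )
        mut = pd.DataFrame(
            [[1, 0, 1], [0, 1, 0], [1, 1, 1]], index=genes, columns=list("abc")
        )
        return expr, mut

    def test_association_requires_driver_and_mutation(self):
        expr, mut = self._frames()
        ds = build_dataset(expr, mut, ["g1", "g2", "g3"], {"g1"})
        assert ds.A[0, 0] == 1  # driver + mutated
        assert ds.A[1, 1] == 0 and ds.Xg[1, 1] == 1  # mutated non-driver
        assert ds.A[0, 1] == 0  # driver but unmutated

    def test_association_bounded_by_mutation(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(10)]
        expr = pd.DataFrame(rng.normal(size=(10, 6)), index=genes)
        mut = pd.DataFrame(rng.integers(0, 2, (10, 6)), index=genes)
        ds = build_dataset(expr, mut, genes, set(rng.choice(genes, 4)))
        assert (ds.A <= ds.Xg).all()

    def test_orientation_and_sorted_gene_order(self):
        expr, mut = self._frames()
        ds = build_dataset(expr, mut, ["g3", "g1"], {"g1"})
        assert ds.genes == ["g1", "g3"]
        assert ds.Xg.shape == (2, 3) and ds.Xs.shape == (3, 2)
        np.testing.assert_array_equal(ds.Xs, expr.loc[["g1", "g3"]].to_numpy().T)

    def test_empty_retained_set_rejected(self):
        expr, mut = self._frames()
        with pytest.raises(ValueError):
            build_dataset(expr, mut, [], {"g1"})


def test_driver_list_parses_comments(tmp_path):
    p = tmp_path / "drivers.txt"
    p.write_text("# header\nTP53\nPIK3CA  # hormone\n\nGATA3\n")
    assert load_driver_genes(p) == {"TP53", "PIK3CA", "GATA3"}
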