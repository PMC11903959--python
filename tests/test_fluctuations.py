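import numpy as np
import pytest

from dfconn import (
    build_toy_dimer,
    compute_df,
    connectivity_profile,
    delta_connectivity,
    local_fluctuation_threshold,
    percent_delta_df,
    project_column,
)
from dfconn.errors import InsufficientDataError, RangeError, ValidationError
from dfconn.fluctuations import DFMatrix, MeanDistanceMatrix, matrix_to_tsv
from dfconn.topology import AxisMap

from ._oracles import df_naive, eta_naive, lf_naive, pct_naive
from .conftest import meta_from_frames


def _line_structure(n, spacing=6.0):
    """Collinear Cα-only chain; distances easy to reason about."""
    from dfconn.topology import StructureModel

    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    return StructureModel(
        atom_names=np.array(["CA"] * n),
        elements=np.array(["C"] * n),
        resids=np.arange(1, n + 1),
        resnames=np.array(["ALA"] * n),
        chains=np.array(["A"] * n),
        coords=coords,
    )


class TestComputeDF:
    def test_constant_distances_zero_df(self):
        s = _line_structure(5)
        meta = meta_from_frames(np.repeat(s.coords[None], 10, axis=0))
        df, _ = compute_df(meta, s)
        assert np.all(df.values == 0)

    def test_two_point_variance(self):
        s = _line_structure(2)
        frames = np.zeros((2, 2, 3))
        frames[0, 1, 0] = 1.0   # d = 1 Å
        frames[1, 1, 0] = 3.0   # d = 3 Å
        df, dist = compute_df(meta_from_frames(frames), s)
        assert df.values[0, 1] == pytest.approx(1.0)   # population variance
        assert dist.values[0, 1] == pytest.approx(2.0)

    def test_matches_naive_oracle(self, toy_ensemble):
        structure, _, meta = toy_ensemble
        df, dist = compute_df(meta, structure)
        ca = meta.coords[:, structure.ca_indices(), :]
        df_ref, dist_ref = df_naive(ca)
        np.testing.assert_allclose(df.values, df_ref, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(dist.values, dist_ref, rtol=1e-10)

    def test_insufficient_frames(self):
        s = _line_structure(3)
        with pytest.raises(InsufficientDataError):
            compute_df(meta_from_frames(s.coords[None]), s)

    def test_rigid_motion_invariance(self, toy_ensemble):
        structure, _, meta = toy_ensemble
        df, _ = compute_df(meta, structure)
        rng = np.random.default_rng(42)
        moved = meta.coords.copy()
        for k in range(moved.shape[0]):
            q = rng.standard_normal(4)
            q /= np.linalg.norm(q)
            w, a, b, c = q
            rot = np.array([
                [1 - 2 * (b * b + c * c), 2 * (a * b - c * w), 2 * (a * c + b * w)],
                [2 * (a * b + c * w), 1 - 2 * (a * a + c * c), 2 * (b * c - a * w)],
                [2 * (a * c - b * w), 2 * (b * c + a * w), 1 - 2 * (a * a + b * b)],
            ])
            moved[k] = moved[k] @ rot.T + rng.normal(scale=5.0, size=3)
        df2, _ = compute_df(meta_from_frames(moved), structure)
        assert np.max(np.abs(df2.values - df.values)) <= 1e-8

    def test_amplitude_scaling_law(self):
        # distance deviations scale with displacement amplitude only for
        # collinear motion, so the exact alpha^2 law is checked on a line toy
        alpha = 1.7
        s = _line_structure(4, spacing=10.0)
        rng = np.random.default_rng(7)
        dev = np.zeros((200, 4, 3))
        dev[:, :, 0] = rng.normal(scale=0.3, size=(200, 4))  # along the line
        frames = s.coords[None] + dev
        frames_a = s.coords[None] + alpha * dev
        df1, _ = compute_df(meta_from_frames(frames), s)
        df2, _ = compute_df(meta_from_frames(frames_a), s)
        np.testing.assert_allclose(df2.values[np.triu_indices(4, 1)],
                                   alpha ** 2 * df1.values[np.triu_indices(4, 1)],
                                   rtol=1e-6)


class TestLocalFluctuation:
    def _df_from(self, values, n):
        axis = AxisMap([("A", i + 1) for i in range(n)])
        return DFMatrix(values=values, axis=axis)

    def test_constant_offdiagonal(self):
        n = 6
        v = np.full((n, n), 3.5)
        np.fill_diagonal(v, 0.0)
        lf, lf_i = local_fluctuation_threshold(self._df_from(v, n))
        np.testing.assert_allclose(lf_i, 3.5)
        assert lf == pytest.approx(3.5)

    def test_rigid_zero(self):
        n = 5
        lf, _ = local_fluctuation_threshold(self._df_from(np.zeros((n, n)), n))
        assert lf == 0.0

    @pytest.mark.parametrize("mode", ["window", "exact"])
    def test_matches_oracle(self, toy_df, mode):
        df, _ = toy_df
        lf, lf_i = local_fluctuation_threshold(df, mode=mode)
        lf_ref, lf_i_ref = lf_naive(df.values, df.axis.residues, mode=mode)
        np.testing.assert_allclose(lf_i, lf_i_ref, rtol=1e-12)
        assert lf == pytest.approx(lf_ref, rel=1e-12)

    def test_short_chain_rejected(self):
        axis = AxisMap([("A", 1), ("A", 2)])
        df = DFMatrix(values=np.zeros((2, 2)), axis=axis)
        with pytest.raises(ValidationError):
            local_fluctuation_threshold(df)

    def test_termini_clipped(self):
        # residue 1 has only +1/+2 neighbors
        n = 5
        rng = np.random.default_rng(0)
        v = np.abs(rng.normal(size=(n, n)))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        _, lf_i = local_fluctuation_threshold(self._df_from(v, n))
        assert lf_i[0] == pytest.approx((v[0, 1] + v[0, 2]) / 2)


class TestConnectivity:
    def test_rigid_strict_inequality(self):
        s = _line_structure(6, spacing=8.0)
        meta = meta_from_frames(np.repeat(s.coords[None], 5, axis=0))
        df, dist = compute_df(meta, s)
        prof = connectivity_profile(df, dist, lf=0.0)
        assert np.all(prof.eta == 0)  # DF < LF is strict: 0 < 0 fails

    def test_matches_oracle(self, toy_ensemble, toy_df):
        df, dist = toy_df
        lf, _ = local_fluctuation_threshold(df)
        prof = connectivity_profile(df, dist)
        eta_ref = eta_naive(df.values, dist.values, lf)
        np.testing.assert_array_equal(prof.eta, eta_ref)

    def test_two_stiff_clusters(self):
        # two rigid 10-residue clusters far apart, mutually uncoupled:
        # eta counts exactly the same-cluster residues beyond the gate
        rng = np.random.default_rng(9)
        from dfconn.topology import StructureModel

        n = 20
        base = np.zeros((n, 3))
        base[:10, 0] = np.arange(10) * 6.0
        base[10:, 0] = np.arange(10) * 6.0
        base[10:, 1] = 500.0  # far-away second cluster
        s = StructureModel(
            atom_names=np.array(["CA"] * n), elements=np.array(["C"] * n),
            resids=np.concatenate([np.arange(1, 11), np.arange(1, 11)]),
            resnames=np.array(["ALA"] * n),
            chains=np.array(["A"] * 10 + ["B"] * 10), coords=base)
        frames = []
        for _ in range(60):
            f = base.copy()
            # each cluster moves rigidly but independently
            f[:10] += rng.normal(scale=4.0, size=3)
            f[10:] += rng.normal(scale=4.0, size=3)
            frames.append(f)
        df, dist = compute_df(meta_from_frames(frames), s)
        prof = connectivity_profile(df, dist, lf=1e-6)
        for i in range(n):
            cluster = range(0, 10) if i < 10 else range(10, 20)
            expected = sum(1 for j in cluster
                           if j != i and dist.values[i, j] > 5.0)
            assert prof.eta[i] == expected
        # intra- vs inter-cluster DF signature
        intra = df.values[:10, :10][np.triu_indices(10, 1)]
        inter = df.values[:10, 10:]
        assert inter.mean() >= 10 * max(intra.mean(), 1e-12)

    def test_flexible_far_pair_not_counted(self):
        s = _line_structure(3, spacing=20.0)
        rng = np.random.default_rng(1)
        frames = s.coords[None] + rng.normal(scale=3.0, size=(50, 3, 3))
        df, dist = compute_df(meta_from_frames(frames), s)
        prof = connectivity_profile(df, dist, lf=1e-9)
        assert np.all(prof.eta == 0)

    def test_axis_mismatch(self, toy_df):
        df, _ = toy_df
        other = MeanDistanceMatrix(
            values=np.zeros((3, 3)), axis=AxisMap([("A", 1), ("A", 2), ("A", 3)]))
        with pytest.raises(ValidationError):
            connectivity_profile(df, other, lf=1.0)


class TestDeltaAndPercent:
    def test_identical_systems_zero(self, toy_df):
        df, dist = toy_df
        prof = connectivity_profile(df, dist)
        delta = delta_connectivity(prof, prof)
        assert np.all(delta.values == 0)
        pct = percent_delta_df(df, df)
        assert np.nanmax(np.abs(pct.values)) == 0.0

    def test_simple_difference(self, toy_df):
        df, dist = toy_df
        wt = connectivity_profile(df, dist)
        mut = connectivity_profile(df, dist)
        mut.eta = wt.eta - 3
        delta = delta_connectivity(mut, wt)
        assert np.all(delta.values == -3)

    def test_doubled_deviations_plus_300(self):
        s = _line_structure(2, spacing=10.0)
        rng = np.random.default_rng(2)
        dev = np.zeros((500, 2, 3))
        dev[:, 1, 0] = rng.normal(scale=0.5, size=500)
        df_wt, _ = compute_df(meta_from_frames(s.coords[None] + dev), s)
        df_mut, _ = compute_df(meta_from_frames(s.coords[None] + 2 * dev), s)
        pct = percent_delta_df(df_mut, df_wt)
        assert pct.values[0, 1] == pytest.approx(300.0, rel=1e-9)

    def test_mask_guards_small_wt(self, toy_df):
        df, _ = toy_df
        zero_axis = df.axis
        wt = DFMatrix(values=np.zeros_like(df.values), axis=zero_axis)
        pct = percent_delta_df(df, wt)
        assert np.all(pct.mask)
        assert np.all(np.isnan(pct.values))
        assert not np.any(np.isinf(pct.values))

    def test_diagonal_masked(self, toy_df):
        df, _ = toy_df
        pct = percent_delta_df(df, df)
        assert np.all(np.diag(pct.mask))

    def test_matches_oracle(self, toy_ensemble, toy_df):
        structure, _, meta = toy_ensemble
        df, _ = toy_df
        rng = np.random.default_rng(3)
        bump = np.abs(rng.normal(size=df.values.shape)) * 0.01
        bump = (bump + bump.T) / 2
        np.fill_diagonal(bump, 0.0)
        mut = DFMatrix(values=df.values + bump, axis=df.axis)
        pct = percent_delta_df(mut, df)
        ref = pct_naive(mut.values, df.values)
        np.testing.assert_allclose(pct.values, ref, rtol=1e-9, equal_nan=True)


class TestProjection:
    def test_column_extraction(self):
        axis = AxisMap([("A", 1), ("A", 2), ("B", 1)])
        values = np.array([[np.nan, 1.0, 2.0],
                           [1.0, np.nan, 3.0],
                           [2.0, 3.0, np.nan]])
        mask = np.isnan(values)
        from dfconn.fluctuations import DiffMatrix

        diff = DiffMatrix(values=values, mask=mask, axis=axis)
        track = project_column(diff, ("A", 2))
        assert track.label == "P_mutA"
        np.testing.assert_allclose(track.values[[0, 2]], [1.0, 3.0])
        assert np.isnan(track.values[1])

    def test_symmetric_column_equals_row(self, toy_df):
        df, _ = toy_df
        pct = percent_delta_df(df, df)
        track = project_column(pct, df.axis.residues[4])
        col = pct.values[:, 4]
        np.testing.assert_allclose(track.values, col, equal_nan=True)

    def test_unknown_position(self, toy_df):
        df, _ = toy_df
        pct = percent_delta_df(df, df)
        with pytest.raises(RangeError):
            project_column(pct, ("Z", 999))

    def test_protomer_b_label(self, toy_df):
        df, _ = toy_df
        pct = percent_delta_df(df, df)
        bpos = next(r for r in df.axis.residues if r[0] == "B")
        assert project_column(pct, bpos).label == "P_mutB"


class TestExports:
    def test_matrix_tsv_masked_cells_empty(self, tmp_path, toy_df):
        df, _ = toy_df
        pct = percent_delta_df(df, df)
        path = tmp_path / "pct.tsv"
        matrix_to_tsv(pct.values, pct.axis, path, mask=pct.mask)
        lines = path.read_text().splitlines()
        assert len(lines) == len(pct.axis) + 1
        first_row = lines[1].split("\t")
        assert first_row[1] == ""  # masked diagonal exported empty

    def test_track_tsv(self, tmp_path, toy_df, toy_ensemble):
        _, spec, _ = toy_ensemble
        df, dist = toy_df
        prof = connectivity_profile(df, dist)
        from dfconn import PerResidueScalar

        track = PerResidueScalar(values=prof.eta.astype(float), axis=df.axis,
                                 label="eta")
        path = tmp_path / "eta.tsv"
        track.to_tsv(path, topology=spec)
        lines = path.read_text().splitlines()
        assert lines[0] == "chain\tresid_model\tresid_human\tdomain\tvalue"
        assert len(lines) == len(df.axis) + 1
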