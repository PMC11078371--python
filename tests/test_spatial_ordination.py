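import numpy as np
import pandas as pd
import pytest

from taxodist.beta_decay import geo_distance_matrix, theta_matrix
from taxodist.spatial_ordination import (
    adjusted_r2,
    build_dbmem,
    dbrda,
    forward_select,
    partial_dbrda,
    pcoa_embed,
    variation_partition,
)

from _oracles import rda_axis_percents


def _transect(n=10, spacing_deg=0.3):
    lon = -96.0 + spacing_deg * np.arange(n)
    return pd.DataFrame(
        {"latitude": np.full(n, 20.0), "longitude": lon},
        index=[f"t{i}" for i in range(n)],
    )


def _euclid_frame(points):
    d = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
    ids = [f"p{i}" for i in range(len(points))]
    return pd.DataFrame(d, index=ids, columns=ids)


def _sign_changes(v):
    s = np.sign(v[np.abs(v) > 1e-10])
    return int((np.diff(s) != 0).sum())


class TestDbmem:
    def test_transect_sign_change_ordering(self):
        basis = build_dbmem(_transect())
        v1 = basis.vectors["MEM1"].to_numpy()
        assert _sign_changes(v1) == 1
        changes = [
            _sign_changes(basis.vectors[m].to_numpy()) for m in basis.retained
        ]
        assert changes == sorted(changes)
        assert changes[-1] > changes[0]

    def test_orthonormal(self, small_dataset):
        basis = build_dbmem(small_dataset["stations"])
        v = basis.vectors.to_numpy()
        assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-10)

    def test_columns_centered(self, small_dataset):
        basis = build_dbmem(small_dataset["stations"])
        assert np.allclose(basis.vectors.to_numpy().sum(axis=0), 0.0, atol=1e-9)

    def test_eigenvalue_count(self, small_dataset):
        basis = build_dbmem(small_dataset["stations"])
        n = len(small_dataset["stations"])
        assert basis.n_positive + basis.n_negative == n - 1

    def test_morans_i_ordering(self, small_dataset):
        basis = build_dbmem(small_dataset["stations"])
        names = list(basis.vectors.columns)
        i_first = basis.morans_i[names.index(basis.retained[0])]
        i_last = basis.morans_i[names.index(basis.retained[-1])]
        assert i_first > i_last

    def test_retained_have_positive_eigenvalues(self, small_dataset):
        basis = build_dbmem(small_dataset["stations"])
        names = list(basis.vectors.columns)
        for m in basis.retained:
            assert basis.eigenvalues[names.index(m)] > 0

    def test_too_few_stations(self):
        st = _transect(3)
        with pytest.raises(ValueError, match="at least 4"):
            build_dbmem(st)

    def test_duplicate_coordinates_warn(self):
        st = _transect(6)
        st.iloc[1] = st.iloc[0]
        with pytest.warns(UserWarning, match="duplicate"):
            build_dbmem(st)


class TestPcoa:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(9, 2))
        emb = pcoa_embed(_euclid_frame(pts))
        coords = emb.coordinates.to_numpy()
        d_in = _euclid_frame(pts).to_numpy()
        d_out = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        assert np.allclose(d_in, d_out, atol=1e-8)

    def test_two_station_single_axis(self):
        d = pd.DataFrame([[0.0, 3.0], [3.0, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        emb = pcoa_embed(d)
        assert emb.coordinates.shape[1] == 1
        c = emb.coordinates.to_numpy().ravel()
        assert abs(c[0] - c[1]) == pytest.approx(3.0)

    def test_theta_reconstruction_bound(self, small_dataset):
        th = theta_matrix(
            small_dataset["community"].iloc[:5], small_dataset["omega"]
        )
        emb = pcoa_embed(th)
        coords = emb.coordinates.to_numpy()
        d_out = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        neg = emb.eigenvalues[emb.eigenvalues < 0]
        bound = np.sqrt(2 * abs(neg.sum())) + 1e-8
        assert np.abs(d_out - th.to_numpy()).max() <= bound

    def test_lingoes_removes_negative_eigenvalues(self, small_dataset):
        th = theta_matrix(small_dataset["community"], small_dataset["omega"])
        emb = pcoa_embed(th, correction="lingoes")
        assert emb.eigenvalues.min() > -1e-6 * abs(emb.eigenvalues).max()

    def test_matches_skbio(self, small_dataset):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        skbio_dm = pytest.importorskip("skbio")
        th = theta_matrix(small_dataset["community"].iloc[:8], small_dataset["omega"])
        ours = pcoa_embed(th)
        ref = skbio_ord.pcoa(skbio_dm.DistanceMatrix(th.to_numpy(), ids=list(th.index)))
        n_pos = ours.coordinates.shape[1]
        ref_eig = np.sort(ref.eigvals.to_numpy())[::-1]
        assert np.allclose(
            ours.eigenvalues[:n_pos], ref_eig[:n_pos], atol=1e-8
        )


class TestDbrda:
    def test_binary_constraint_matches_anova_share(self):
        rng = np.random.default_rng(3)
        groups = np.array([0] * 6 + [1] * 6)
        pts = rng.normal(size=(12, 3)) + 4.0 * groups[:, None]
        d = _euclid_frame(pts)
        x = pd.DataFrame({"g": groups.astype(float)}, index=d.index)
        res = dbrda(d, x)
        yc = pts - pts.mean(axis=0)
        fitted = np.array([yc[groups == g].mean(axis=0) for g in groups])
        share = 100 * (fitted**2).sum() / (yc**2).sum()
        assert res.axis_percent[0] == pytest.approx(share, abs=1e-8)
        s1 = res.site_scores.iloc[:, 0].to_numpy()
        assert len(np.unique(np.round(s1[groups == 0], 6))) == 1

    def test_random_orthogonal_constraints_near_zero(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(15, 2))
        d = _euclid_frame(pts)
        emb = pcoa_embed(d)
        y = emb.coordinates.to_numpy()
        raw = rng.normal(size=(15, 2))
        raw = raw - raw.mean(0)
        # residualize on the embedding -> exactly orthogonal constraints
        coef, *_ = np.linalg.lstsq(y, raw, rcond=None)
        ortho = raw - y @ coef
        res = dbrda(d, pd.DataFrame(ortho, index=d.index, columns=["a", "b"]))
        assert res.r2 == pytest.approx(0.0, abs=1e-10)

    def test_saturating_constraints_reach_100(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 2))
        d = _euclid_frame(pts)
        emb = pcoa_embed(d)
        with pytest.warns(UserWarning, match="saturate"):
            res = dbrda(d, emb.coordinates)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)
        assert res.axis_percent.sum() == pytest.approx(100.0, abs=1e-8)

    def test_cross_oracle_classical_rda(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(14, 3))
        x = rng.normal(size=(14, 2))
        d = _euclid_frame(pts)
        res = dbrda(d, pd.DataFrame(x, index=d.index, columns=["u", "v"]))
        expected = rda_axis_percents(pts, x)
        assert np.allclose(res.axis_percent, expected, atol=1e-8)

    def test_identity_constraints_reproduce_pcoa(self, small_dataset):
        th = theta_matrix(small_dataset["community"], small_dataset["omega"])
        emb = pcoa_embed(th)
        res = dbrda(th, emb.coordinates)
        pct_pcoa = 100 * emb.eigenvalues[: res.eigenvalues.size] / emb.total_inertia
        assert np.allclose(res.axis_percent, pct_pcoa, atol=1e-8)

    def test_too_many_constraints(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(5, 2))
        d = _euclid_frame(pts)
        x = pd.DataFrame(rng.normal(size=(5, 5)), index=d.index)
        with pytest.raises(ValueError, match="constraints"):
            dbrda(d, x)

    def test_axis_percent_invariants(self, small_dataset):
        th = theta_matrix(small_dataset["community"], small_dataset["omega"])
        env = small_dataset["stations"][["depth", "temperature"]]
        env = (env - env.mean()) / env.std(ddof=0)
        res = dbrda(th, env, n_perm=49, seed=0)
        assert (res.axis_percent >= 0).all()
        assert res.axis_percent.sum() <= 100 + 1e-9
        assert res.adj_r2 <= res.r2
        assert 0 < res.p <= 1


def _signal_response(n, x, noise_sd, seed, scale=3.0):
    rng = np.random.default_rng(seed)
    pts = np.column_stack(
        [scale * x, rng.normal(scale=noise_sd, size=(n, 2))]
    )
    return _euclid_frame(pts)


class TestForwardSelect:
    def test_single_true_driver_recovered(self):
        hits, extra = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 20
            cands = pd.DataFrame(
                rng.normal(size=(n, 4)), columns=list("abcd"),
                index=[f"s{i}" for i in range(n)],
            )
            d = _signal_response(n, cands["b"].to_numpy(), 0.8, seed)
            d.index = d.columns = cands.index
            sel = forward_select(d, cands, alpha=0.05, n_perm=99, seed=seed)
            if sel.selected[:1] == ["b"]:
                hits += 1
            if len(sel.selected) > 1:
                extra += 1
        assert hits >= 18
        assert extra <= 3

    def test_pure_noise_mostly_empty(self):
        empties = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            n = 18
            cands = pd.DataFrame(
                rng.normal(size=(n, 4)), columns=list("abcd"),
                index=[f"s{i}" for i in range(n)],
            )
            pts = rng.normal(size=(n, 3))
            d = _euclid_frame(pts)
            d.index = d.columns = cands.index
            sel = forward_select(d, cands, alpha=0.05, n_perm=99, seed=seed)
            empties += not sel.selected
        assert empties >= 15

    def test_alpha_one_no_cap_selects_all(self):
        rng = np.random.default_rng(9)
        n = 15
        cands = pd.DataFrame(
            rng.normal(size=(n, 3)), columns=list("abc"),
            index=[f"s{i}" for i in range(n)],
        )
        pts = rng.normal(size=(n, 3))
        d = _euclid_frame(pts)
        d.index = d.columns = cands.index
        sel = forward_select(
            d, cands, alpha=1.0, n_perm=9, seed=0, use_adj_r2_cap=False
        )
        assert sorted(sel.selected) == ["a", "b", "c"]

    def test_collinear_candidate_skipped(self):
        rng = np.random.default_rng(11)
        n = 16
        base = rng.normal(size=n)
        cands = pd.DataFrame(
            {"x": base, "x_copy": base * 2.0, "y": rng.normal(size=n)},
            index=[f"s{i}" for i in range(n)],
        )
        d = _signal_response(n, base, 0.5, 3)
        d.index = d.columns = cands.index
        with pytest.warns(UserWarning, match="collinear"):
            sel = forward_select(
                d, cands, alpha=1.0, n_perm=9, seed=0, use_adj_r2_cap=False
            )
        assert "x_copy" not in sel.selected


class TestPartition:
    def _setup_blocks(self, n=24, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        x1 = pd.DataFrame(rng.normal(size=(n, 2)), columns=["e1", "e2"], index=ids)
        x2 = pd.DataFrame(rng.normal(size=(n, 2)), columns=["lon", "lat"], index=ids)
        x3 = pd.DataFrame(rng.normal(size=(n, 1)), columns=["m1"], index=ids)
        return ids, x1, x2, x3

    def test_fractions_sum_to_one(self):
        ids, x1, x2, x3 = self._setup_blocks()
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(len(ids), 3))
        d = _euclid_frame(pts)
        d.index = d.columns = ids
        part = variation_partition(
            d, {"env": x1, "coords": x2, "mem": x3}, n_perm=9, seed=0
        )
        assert part.fractions["adj_r2"].sum() == pytest.approx(1.0, abs=1e-10)

    def test_pure_env_signal_dominates(self):
        ids, x1, x2, x3 = self._setup_blocks(seed=2)
        d = _signal_response(len(ids), x1["e1"].to_numpy(), 0.4, 5, scale=4.0)
        d.index = d.columns = ids
        part = variation_partition(
            d, {"env": x1, "coords": x2, "mem": x3}, n_perm=49, seed=0
        )
        uniques = {b: part.unique(b) for b in ("env", "coords", "mem")}
        assert max(uniques, key=uniques.get) == "env"
        assert part.fractions.loc["env", "p"] <= 0.05

    def test_duplicated_block_shared_fraction(self):
        ids, x1, x2, _ = self._setup_blocks(seed=3)
        d = _signal_response(len(ids), x1["e1"].to_numpy(), 0.4, 6, scale=4.0)
        d.index = d.columns = ids
        part = variation_partition(
            d, {"env": x1, "twin": x1.copy()}, n_perm=9, seed=0
        )
        assert abs(part.unique("env")) < 1e-6
        assert abs(part.unique("twin")) < 1e-6
        assert part.fractions.loc["env&twin", "adj_r2"] > 0.3

    def test_station_order_invariance(self):
        ids, x1, x2, x3 = self._setup_blocks(seed=4)
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(len(ids), 3))
        d = _euclid_frame(pts)
        d.index = d.columns = ids
        part1 = variation_partition(d, {"env": x1, "coords": x2}, n_perm=9, seed=0)
        perm = rng.permutation(len(ids))
        ids2 = [ids[i] for i in perm]
        part2 = variation_partition(
            d.loc[ids2, ids2], {"env": x1.loc[ids2], "coords": x2.loc[ids2]},
            n_perm=9, seed=0,
        )
        assert np.allclose(
            part1.fractions["adj_r2"].sort_index(),
            part2.fractions["adj_r2"].sort_index(),
            atol=1e-9,
        )


class TestPartialDbrda:
    def test_no_conditioning_equals_dbrda(self, small_dataset):
        th = theta_matrix(small_dataset["community"], small_dataset["omega"])
        env = small_dataset["stations"][["depth"]]
        plain = dbrda(th, env)
        partial = partial_dbrda(th, env, None)
        assert partial.r2 == pytest.approx(plain.r2, abs=1e-12)
        assert np.allclose(partial.axis_percent, plain.axis_percent)

    def test_focal_in_span_of_conditioning(self):
        rng = np.random.default_rng(12)
        n = 14
        ids = [f"s{i}" for i in range(n)]
        z = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"], index=ids)
        focal = pd.DataFrame({"f": z["a"] * 2 - z["b"]}, index=ids)
        pts = rng.normal(size=(n, 3))
        d = _euclid_frame(pts)
        d.index = d.columns = ids
        with pytest.warns(UserWarning, match="collinear"):
            res = partial_dbrda(d, focal, z)
        assert res.r2 == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_signals_match_unique_fractions(self):
        rng = np.random.default_rng(13)
        n = 30
        ids = [f"s{i}" for i in range(n)]
        u = rng.normal(size=n)
        v = rng.normal(size=n)
        v = v - u * (u @ v) / (u @ u)  # orthogonalize
        pts = np.column_stack([2 * u, 2 * v, rng.normal(scale=0.5, size=(n, 1)).ravel()])
        d = _euclid_frame(pts)
        d.index = d.columns = ids
        bu = pd.DataFrame({"u": u}, index=ids)
        bv = pd.DataFrame({"v": v}, index=ids)
        part = variation_partition(d, {"bu": bu, "bv": bv}, n_perm=9, seed=0)
        pu = partial_dbrda(d, bu, {"bv": bv})
        pv = partial_dbrda(d, bv, {"bu": bu})
        assert pu.adj_r2 == pytest.approx(part.unique("bu"), abs=1e-10)
        assert pv.adj_r2 == pytest.approx(part.unique("bv"), abs=1e-10)


class TestAdjustedR2:
    def test_formula(self):
        assert adjusted_r2(0.5, 21, 4) == pytest.approx(1 - 0.5 * 20 / 16)

    def test_no_dof_nan(self):
        assert np.isnan(adjusted_r2(0.9, 5, 4))
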