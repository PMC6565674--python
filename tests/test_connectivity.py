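import numpy as np
import pandas as pd
import pytest

from conftest import make_sv
from zfscreen.atlas import generate_atlas
from zfscreen.connectivity import (
    _cross_correlations,
    area_pairs,
    assemble_fingerprint,
    divergence_map,
    inter_area_correlation,
    larva_metrics,
    metric_index,
    per_larva_table,
    significant_wt_pairs,
)
from zfscreen.protocol import StateWindows


def _corr_sv(traces_i, traces_j, T=None):
    return make_sv({1: np.asarray(traces_i), 2: np.asarray(traces_j)})


WINDOW = [(0.0, 50.0)]  # 1000 frames at 20 Hz


class TestInterAreaCorrelation:
    def test_identical_traces_give_one(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=1000)
        sv = _corr_sv([t, t], [t, t, t])
        assert inter_area_correlation(sv, (1, 2), WINDOW) == pytest.approx(1.0)

    def test_anticorrelated_traces_give_one(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=1000)
        sv = _corr_sv([t], [-t])
        assert inter_area_correlation(sv, (1, 2), WINDOW) == pytest.approx(1.0)

    def test_independent_traces_near_chance_level(self):
        """mean |r| of independent Gaussians matches E|r| = sqrt(2/(pi (T-1)))."""
        rng = np.random.default_rng(2)
        T = 1000
        sv = _corr_sv(rng.normal(size=(5, T)), rng.normal(size=(5, T)))
        got = inter_area_correlation(sv, (1, 2), WINDOW)
        expect = np.sqrt(2.0 / (np.pi * (T - 1)))
        # Monte-Carlo band: 25 pair samples of a folded normal.
        assert abs(got - expect) < 4 * expect / np.sqrt(25)

    def test_short_window_is_missing(self):
        rng = np.random.default_rng(3)
        sv = _corr_sv(rng.normal(size=(2, 1000)), rng.normal(size=(2, 1000)))
        assert np.isnan(inter_area_correlation(sv, (1, 2), [(0.0, 2.0)]))

    def test_empty_area_is_missing(self):
        rng = np.random.default_rng(4)
        sv = _corr_sv(rng.normal(size=(2, 1000)), rng.normal(size=(2, 1000)))
        sv.active[2:] = False  # deactivate all of area 2
        assert np.isnan(inter_area_correlation(sv, (1, 2), WINDOW))


@pytest.mark.parametrize("n_regions, n_states, expected", [(11, 3, 165), (4, 3, 18), (2, 1, 1)])
def test_fingerprint_dimensionality(n_regions, n_states, expected):
    idx = metric_index(n_regions, tuple(["pre", "early", "late"][:n_states]))
    assert len(idx) == expected
    assert len(area_pairs(n_regions)) == n_regions * (n_regions - 1) // 2


def test_pearson_matches_brute_force_oracle():
    """Vectorized cross-correlations agree with a two-pass covariance oracle."""
    rng = np.random.default_rng(5)
    X, Y = rng.normal(size=(4, 200)), rng.normal(size=(3, 200))
    R = _cross_correlations(X, Y)
    for i in range(4):
        for j in range(3):
            x, y = X[i], Y[j]
            mx, my = x.mean(), y.mean()
            num = np.sum((x - mx) * (y - my))
            den = np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))
            assert abs(R[i, j] - num / den) < 1e-10


class TestAssembleFingerprint:
    def _larva_series(self, rng, n_regions=4, missing=None):
        idx = metric_index(n_regions)
        vals = rng.random(len(idx))
        s = pd.Series(vals, index=idx)
        if missing:
            s.loc[missing] = np.nan
        return s

    def test_group_average_ignores_missing(self):
        rng = np.random.default_rng(6)
        a = self._larva_series(rng)
        b = self._larva_series(rng)
        key = (1, 2, "pre")
        b_missing = b.copy()
        b_missing.loc[key] = np.nan
        fp = assemble_fingerprint([a, b_missing], min_larvae=1)
        assert fp.values.loc[key] == pytest.approx(a.loc[key])
        assert fp.n_larvae == 2

    def test_all_missing_stays_missing(self):
        rng = np.random.default_rng(7)
        key = (1, 3, "late")
        larvae = [self._larva_series(rng, missing=[key]) for _ in range(3)]
        fp = assemble_fingerprint(larvae, min_larvae=1)
        assert np.isnan(fp.values.loc[key])

    def test_missing_region_affects_exactly_its_metrics(self):
        """Removing one region's supervoxels blanks (R-1)*S metrics."""
        rng = np.random.default_rng(8)
        atlas = generate_atlas((3, 16, 16), 4, seed=0)
        traces = {rid: rng.normal(size=(3, 4000)) for rid in range(1, 5)}
        windows = StateWindows(pre=(0.0, 60.0), early=[(70.0, 120.0)], late=[(120.0, 180.0)])
        sv_full = make_sv(traces)
        m_full = larva_metrics(sv_full, atlas, windows)
        sv_cut = make_sv(traces)
        sv_cut.active[sv_cut.region_of == 3] = False
        m_cut = larva_metrics(sv_cut, atlas, windows)
        changed = m_cut.isna() & ~m_full.isna()
        assert changed.sum() == 3 * 3  # (R-1) pairs x S states
        for (i, j, _s) in m_cut.index[changed]:
            assert 3 in (i, j)


class TestSignificantWtPairs:
    def _larvae(self, rho, n_larvae=10, T=4000, seed=0):
        out = []
        for k in range(n_larvae):
            rng = np.random.default_rng(seed + k)
            shared = rng.normal(size=T)
            mk = lambda n, r: np.sqrt(r) * shared + np.sqrt(1 - r) * rng.normal(size=(n, T))
            out.append(make_sv({
                1: mk(4, rho), 2: mk(4, rho),
                3: rng.normal(size=(4, T)), 4: rng.normal(size=(4, T)),
            }))
        return out

    def test_planted_pair_found_null_pairs_controlled(self):
        atlas = generate_atlas((3, 16, 16), 4, seed=0)
        svs = self._larvae(rho=0.6)
        sig = significant_wt_pairs(svs, atlas, (0.0, 200.0), seed=1)
        assert (1, 2) in sig
        # pairs not involving the shared latent should mostly be absent
        null_pairs = {(3, 4)}
        assert not null_pairs & set(sig)

    def test_type_i_control_on_null(self):
        """With no planted structure the null pair is returned at ~alpha rate."""
        atlas = generate_atlas((3, 16, 16), 4, seed=0)
        hits = 0
        n_runs = 20
        for run in range(n_runs):
            svs = self._larvae(rho=0.0, n_larvae=6, T=2000, seed=100 * run)
            sig = significant_wt_pairs(svs, atlas, (0.0, 100.0), seed=run)
            hits += (3, 4) in sig
        assert hits <= 4  # alpha = 0.05; generous binomial bound

    def test_needs_three_larvae(self):
        atlas = generate_atlas((3, 16, 16), 4, seed=0)
        with pytest.raises(ValueError):
            significant_wt_pairs(self._larvae(0.5, n_larvae=2), atlas, (0.0, 200.0))


class TestDivergenceMap:
    def test_identical_groups_no_change(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.random((6, 3)), columns=[(1, 2), (1, 3), (2, 3)])
        out = divergence_map(df, df.copy())
        assert (out["direction"] == "no change").all()
        assert np.allclose(out["magnitude"], 0.0)

    def test_planted_decrease_recovered(self):
        rng = np.random.default_rng(10)
        wt = pd.DataFrame({(1, 2): 0.5 + 0.02 * rng.standard_normal(10)})
        mut = pd.DataFrame({(1, 2): 0.3 + 0.02 * rng.standard_normal(10)})
        out = divergence_map(mut, wt)
        assert out.loc[0, "direction"] == "decrease"
        assert out.loc[0, "magnitude"] == pytest.approx(-0.2, abs=0.03)

    def test_direction_antisymmetric(self):
        rng = np.random.default_rng(11)
        a = pd.DataFrame({(1, 2): 0.6 + 0.02 * rng.standard_normal(8)})
        b = pd.DataFrame({(1, 2): 0.4 + 0.02 * rng.standard_normal(8)})
        ab = divergence_map(a, b)
        ba = divergence_map(b, a)
        assert ab.loc[0, "magnitude"] == pytest.approx(-ba.loc[0, "magnitude"])
        assert {ab.loc[0, "direction"], ba.loc[0, "direction"]} == {"increase", "decrease"}


def test_per_larva_table_shape():
    rng = np.random.default_rng(12)
    idx = metric_index(4)
    larvae = [pd.Series(rng.random(len(idx)), index=idx) for _ in range(5)]
    table = per_larva_table(larvae, state="pre")
    assert table.shape == (5, 6)
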