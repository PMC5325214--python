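"""OC1 (supF change point) and OC2 (template correlation) scoring.

Both criteria are checked against slow independent oracles: OC1 against
per-candidate least-squares fits built from explicit design matrices, OC2
against an exhaustive per-template correlation loop.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoroi.criteria import default_bank, make_template, oc1, oc2
from phenoroi.greenness import GreennessSeries


def _series(values):
    return GreennessSeries(values=np.asarray(values, dtype=float), source_size=1)


def _full_series_from(fn, missing=None):
    doys = np.arange(1, 366)
    values = fn(doys.astype(float))
    if missing is not None:
        values = values.copy()
        values[missing] = np.nan
    return _series(values)


# ---------------------------------------------------------------------------
# independent oracles

def oc1_oracle(series, window_end=240, cand_lo=30, cand_hi=210, min_side=5):
    """Brute force: solve both regressions via design matrices at every
    candidate change DOY, return (f_max, change_doy)."""
    vals = series.values[:window_end]
    obs = np.nonzero(~np.isnan(vals))[0]
    t = (obs + 1).astype(float)
    y = vals[obs]
    n = t.size
    x0 = np.column_stack([np.ones(n), t])
    beta = np.linalg.lstsq(x0, y, rcond=None)[0]
    rss0 = float(np.sum((y - x0 @ beta) ** 2))
    best_f, best_s = -np.inf, None
    for s in range(cand_lo, cand_hi + 1):
        left = t < s
        if left.sum() < min_side or (~left).sum() < min_side:
            continue
        rss1 = 0.0
        for idx in (left, ~left):
            xs = np.column_stack([np.ones(int(idx.sum())), t[idx]])
            b = np.linalg.lstsq(xs, y[idx], rcond=None)[0]
            rss1 += float(np.sum((y[idx] - xs @ b) ** 2))
        f = ((rss0 - rss1) / 2.0) / (rss1 / (n - 4))
        if f > best_f:
            best_f, best_s = f, s
    return best_f, best_s


def oc2_oracle(series, bank):
    """Exhaustive loop over every template with np.corrcoef."""
    obs = ~np.isnan(series.values)
    y = series.values[obs]
    best = (-np.inf, None, None)
    for (a, b), tpl in zip(bank.params, bank.values):
        x = tpl[obs]
        if np.ptp(x) == 0:
            continue
        rho = float(np.corrcoef(x, y)[0, 1])
        if rho > best[0]:
            best = (rho, int(a), int(b))
    return best


# ---------------------------------------------------------------------------
# OC1

class TestOC1:
    def test_two_segment_exact_fit(self):
        """Flat level then a rising line: exact segmented fit at the break."""

        def shape(t):
            return np.where(t < 120, 0.3, 0.3 + 0.3 * (t - 120) / 120.0)

        res = oc1(_full_series_from(shape))
        assert res.change_doy == 120
        assert np.isinf(res.f_max)
        assert res.exact_fit
        assert res.rss0 > 0 and res.rss1 == pytest.approx(0.0, abs=1e-10)

    def test_straight_line_is_zero_by_convention(self):
        res = oc1(_full_series_from(lambda t: 0.2 + 0.001 * t))
        assert res.f_max == 0.0
        assert not res.exact_fit

    def test_n_used_counts_observed_days_only(self):
        missing = np.arange(0, 365, 3)
        res = oc1(_full_series_from(lambda t: np.clip(0.3 + 0.002 * t, 0, 1), missing=missing))
        assert res.n_used == int(np.sum(~np.isnan(_full_series_from(
            lambda t: np.clip(0.3 + 0.002 * t, 0, 1), missing=missing).values[:240])))
        assert res.k_params == 2

    def test_too_few_observations_rejected(self):
        values = np.full(365, np.nan)
        values[:8] = 0.5
        with pytest.raises(ValueError, match="observed DOYs"):
            oc1(_series(values))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_design_matrix_oracle(self, seed):
        """supF scan equals per-candidate normal-equation fits (rel 1e-8)."""
        rng = np.random.default_rng(seed)
        t = np.arange(1, 366, dtype=float)
        shift = rng.uniform(80, 180)
        values = 0.35 + 0.25 / (1 + np.exp(-(t - shift) / rng.uniform(5, 20)))
        values += rng.normal(0, 0.02, 365)
        missing = rng.choice(365, size=40, replace=False)
        values[missing] = np.nan
        series = _series(np.clip(values, 0, 1))
        res = oc1(series)
        f_ref, s_ref = oc1_oracle(series)
        assert res.f_max == pytest.approx(f_ref, rel=1e-8)
        assert res.change_doy == s_ref

    def test_monotone_in_planted_shift(self):
        """Doubling a planted level shift never lowers f_max (same noise)."""
        rng = np.random.default_rng(11)
        noise = rng.normal(0, 0.02, 365)
        t = np.arange(1, 366, dtype=float)
        for delta in (0.05, 0.1, 0.15):
            lo = _series(np.clip(0.4 + noise + np.where(t >= 120, delta, 0), 0, 1))
            hi = _series(np.clip(0.4 + noise + np.where(t >= 120, 2 * delta, 0), 0, 1))
            assert oc1(hi).f_max >= oc1(lo).f_max


# ---------------------------------------------------------------------------
# templates

class TestTemplate:
    def test_peak_and_rise_midpoint(self):
        tpl = make_template(100, 300)
        assert tpl.values[tpl.c - 1] == 1.0
        mid = (100 + tpl.c) // 2
        assert tpl.values[mid - 1] == pytest.approx(0.5)

    def test_matches_hand_rolled_piecewise(self):
        tpl = make_template(100, 300)
        a, c, d, e, b, pl = tpl.a, tpl.c, tpl.d, tpl.e, tpl.b, tpl.plateau_level
        for doy in range(1, 366):
            if doy <= a or doy >= b:
                expected = 0.0
            elif doy <= c:
                expected = (doy - a) / (c - a)
            elif doy <= d:
                expected = 1.0 + (pl - 1.0) * (doy - c) / (d - c)
            elif doy <= e:
                expected = pl
            else:
                expected = pl * (b - doy) / (b - e)
            assert tpl.values[doy - 1] == pytest.approx(expected, abs=1e-12), doy

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError, match="knots"):
            make_template(100, 300, c=90)
        with pytest.raises(ValueError, match="knots"):
            make_template(300, 100)

    @given(a=st.integers(50, 150), b=st.integers(265, 365))
    @settings(max_examples=50, derandomize=True)
    def test_grid_templates_bounded_and_flat_outside_season(self, a, b):
        tpl = make_template(a, b)
        assert tpl.values.min() >= 0.0 and tpl.values.max() == 1.0
        assert np.all(tpl.values[: a - 1] == 0.0)
        assert np.all(tpl.values[b - 1 :] == 0.0)

    def test_default_bank_grid(self):
        bank = default_bank()
        assert len(bank) == 101 * 101
        assert bank.params[0].tolist() == [50, 265]
        assert bank.params[-1].tolist() == [150, 365]


# ---------------------------------------------------------------------------
# OC2

@pytest.fixture(scope="module")
def bank():
    return default_bank()


class TestOC2:
    def test_self_template_is_exact(self, bank):
        series = _series(make_template(100, 300).values)
        res = oc2(series, bank)
        assert res.rho_max == pytest.approx(1.0, abs=1e-12)
        assert (res.a_hat, res.b_hat) == (100, 300)

    def test_affine_invariance(self, bank):
        tpl = make_template(80, 330).values
        res = oc2(_series(0.2 + 0.3 * tpl), bank)
        assert res.rho_max == pytest.approx(1.0, abs=1e-12)
        assert (res.a_hat, res.b_hat) == (80, 330)
        shifted = oc2(_series(0.25 + 0.3 * tpl), bank)
        assert (shifted.a_hat, shifted.b_hat) == (80, 330)

    def test_noisy_template_matches_exhaustive_loop(self, bank):
        rng = np.random.default_rng(4)
        values = np.clip(0.05 + 0.9 * make_template(95, 310).values + rng.normal(0, 0.05, 365), 0, 1)
        series = _series(values)
        res = oc2(series, bank)
        rho_ref, a_ref, b_ref = oc2_oracle(series, bank)
        assert res.rho_max == pytest.approx(rho_ref, rel=1e-10)
        assert (res.a_hat, res.b_hat) == (a_ref, b_ref)

    def test_restricted_to_observed_days(self, bank):
        tpl = make_template(100, 300).values
        values = tpl.copy()
        values[::2] = np.nan  # keep every other day
        res = oc2(_series(values), bank)
        assert res.rho_max == pytest.approx(1.0, abs=1e-12)
        assert (res.a_hat, res.b_hat) == (100, 300)

    def test_constant_series_rejected(self, bank):
        with pytest.raises(ValueError, match="constant"):
            oc2(_series(np.full(365, 0.4)), bank)

    def test_too_few_observations_rejected(self, bank):
        values = np.full(365, np.nan)
        values[10] = 0.4
        values[20] = 0.6
        with pytest.raises(ValueError, match="at least 3"):
            oc2(_series(values), bank)

    def test_bounded_in_unit_interval(self, bank):
        rng = np.random.default_rng(9)
        for _ in range(5):
            res = oc2(_series(rng.uniform(0.2, 0.8, 365)), bank)
            assert -1.0 <= res.rho_max <= 1.0

    def test_onset_recovery_under_noise(self, bank):
        """(a, b) within +-5 days of truth in >=95% of 100 noisy replicates."""
        rng = np.random.default_rng(123)
        truth = make_template(100, 300).values
        hits = 0
        for _ in range(100):
            values = np.clip(truth + rng.normal(0, 0.02, 365), 0, 1)
            res = oc2(_series(values), bank)
            hits += abs(res.a_hat - 100) <= 5 and abs(res.b_hat - 300) <= 5
        assert hits >= 95
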