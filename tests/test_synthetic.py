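"""The two-group generator: published defaults, reproducibility, moment
convergence, Likert discretization, planted non-invariance."""

import numpy as np
import pandas as pd
import pytest

from mgcfa.estimation import implied_moments
from mgcfa.model_spec import builtin_spec
from mgcfa.synthetic import (
    GeneratorConfig,
    default_cesd_params,
    default_config,
    generate,
    invariant_config,
    planted_noninvariance,
)


class TestDefaults:
    def test_published_parameter_values(self):
        ps1, ps2, sizes = default_cesd_params()
        spec = builtin_spec("four_factor")
        items = list(spec.battery.item_names)
        fac = list(spec.factors)

        def lam(ps, it):
            return ps.Lambda[items.index(it), fac.index(spec.loading_pattern[it])]

        assert sizes == (4903, 1903)
        assert lam(ps1, "Happy") == lam(ps2, "Happy") == 2.30
        assert (ps1.nu[items.index("Good")], ps2.nu[items.index("Good")]) == (1.54, 0.68)
        assert (ps1.nu[items.index("Failure")], ps2.nu[items.index("Failure")]) == (0.57, 0.30)
        assert (ps1.Theta[items.index("Depressed")],
                ps2.Theta[items.index("Depressed")]) == (0.30, 0.13)
        assert (ps1.Theta[items.index("Failure")],
                ps2.Theta[items.index("Failure")]) == (0.41, 0.09)
        # markers fixed at 1 in both groups
        for f in fac:
            assert lam(ps1, spec.markers[f]) == 1.0
        # latent means / SDs
        assert np.allclose(ps1.kappa, 0)
        assert np.allclose(ps2.kappa, [-0.261, -0.259, -0.125, -0.323])
        assert np.allclose(np.sqrt(np.diag(ps1.Phi)), [0.482, 0.570, 0.354, 0.574])
        assert np.allclose(np.sqrt(np.diag(ps2.Phi)), [0.324, 0.318, 0.329, 0.184])

    def test_invariant_variant_shares_measurement_model(self):
        cfg = invariant_config(seed=0)
        ps1, ps2 = cfg.params
        assert np.array_equal(ps1.Lambda, ps2.Lambda)
        assert np.array_equal(ps1.nu, ps2.nu)
        assert np.array_equal(ps1.Theta, ps2.Theta)
        assert not np.array_equal(ps1.kappa, ps2.kappa)


class TestGenerate:
    def test_reproducible_from_seed(self):
        t1 = generate(default_config(seed=123, sizes=(50, 40)))
        t2 = generate(default_config(seed=123, sizes=(50, 40)))
        pd.testing.assert_frame_equal(t1.data, t2.data)
        t3 = generate(default_config(seed=124, sizes=(50, 40)))
        assert not t1.data.equals(t3.data)

    def test_moments_converge_to_implied(self):
        cfg = default_config(seed=6, sizes=(200_000, 25), missing_rate=0.0)
        table = generate(cfg)
        sub = table.data[table.data["group"] == "chinese"]
        vals = sub[list(table.battery.item_names)].to_numpy()
        Sigma, mu = implied_moments(cfg.params[0])
        assert np.max(np.abs(vals.mean(axis=0) - mu)) < 0.01
        assert np.max(np.abs(np.cov(vals, rowvar=False) - Sigma)) < 0.015

    def test_likert_output_domain_and_missingness(self):
        cfg = default_config(seed=8, sizes=(4000, 3000), likert=True,
                             missing_rate=0.02)
        table = generate(cfg)
        vals = table.data[list(table.battery.item_names)].to_numpy()
        obs = vals[~np.isnan(vals)]
        assert set(np.unique(obs)) <= {1.0, 2.0, 3.0, 4.0}
        frac = np.isnan(vals).mean()
        assert frac == pytest.approx(0.02, abs=0.005)

    def test_likert_is_monotone_in_latent_response(self):
        # same seed => same underlying draws, so the Likert table must be a
        # monotone per-item discretization of the continuous table
        cont = generate(default_config(seed=9, sizes=(500, 100), missing_rate=0.0))
        lik = generate(default_config(seed=9, sizes=(500, 100), missing_rate=0.0,
                                      likert=True))
        for it in ("Bothered", "Happy", "Dislike"):
            x = cont.data[it].to_numpy()
            y = lik.data[it].to_numpy()
            order = np.argsort(x)
            assert np.all(np.diff(y[order]) >= 0)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError, match="missing_rate"):
            default_config(seed=0, missing_rate=0.2)
        with pytest.raises(ValueError, match="p \\+ 1"):
            default_config(seed=0, sizes=(10, 1000))


class TestPlantedNoninvariance:
    def test_single_edit_changes_only_that_entry(self):
        base = default_config(seed=0)
        edited = planted_noninvariance(base, [("intercept", "Sad", "dutch", 0.5)])
        items = list(base.spec.battery.item_names)
        i = items.index("Sad")
        diff = edited.params[1].nu - base.params[1].nu
        assert diff[i] == pytest.approx(0.5)
        assert np.count_nonzero(diff) == 1
        assert np.array_equal(edited.params[0].nu, base.params[0].nu)
        assert np.array_equal(edited.params[1].Lambda, base.params[1].Lambda)
        assert edited.edit_log == [("intercept", "Sad", "dutch", 0.5)]

    def test_empty_edit_list_is_identity(self):
        base = default_config(seed=0)
        same = planted_noninvariance(base, [])
        for a, b in zip(base.params, same.params):
            assert np.array_equal(a.Lambda, b.Lambda)
            assert np.array_equal(a.nu, b.nu)
            assert np.array_equal(a.Theta, b.Theta)
        assert same.edit_log == []

    def test_edit_log_round_trips_serialization(self):
        base = planted_noninvariance(
            default_config(seed=0),
            [("uniqueness", "Talk", "chinese", 0.3)],
        )
        again = GeneratorConfig.from_dict(base.to_dict())
        assert again.edit_log == base.edit_log
        assert np.allclose(again.params[0].Theta, base.params[0].Theta)
        assert again.sizes == base.sizes

    def test_unknown_targets_rejected(self):
        base = default_config(seed=0)
        with pytest.raises(ValueError, match="unknown item"):
            planted_noninvariance(base, [("intercept", "Nope", "dutch", 0.5)])
        with pytest.raises(ValueError, match="unknown parameter class"):
            planted_noninvariance(base, [("variance", "Sad", "dutch", 0.5)])
        with pytest.raises(ValueError, match="unknown group"):
            planted_noninvariance(base, [("intercept", "Sad", "german", 0.5)])
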