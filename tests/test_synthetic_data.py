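"""Statistical behaviour of the synthetic dataset generator."""

import numpy as np
import pandas as pd
import pytest

from dsbrepair import generate_cenpf_dataset, generate_foci_dataset, summarize
from dsbrepair.synthetic import (
    GeneratorConfig,
    GeneratorConfigError,
    cenpf_true_fraction,
    model_means,
)

SMALL = dict(doses_mgy=(80.0,), timepoints_h=(0.5, 6.0), n_cells=50, n_replicates=3)


class TestGeneratorConfig:
    def test_defaults_follow_study_design(self):
        cfg = GeneratorConfig()
        assert cfg.doses_mgy == (20.0, 40.0, 80.0, 160.0, 250.0, 500.0, 1000.0)
        assert cfg.timepoints_h == (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 16.0, 24.0)
        assert cfg.n_cells == 200 and cfg.n_replicates == 3

    def test_invalid_configs_rejected(self):
        with pytest.raises(GeneratorConfigError):
            GeneratorConfig(n_cells=0)
        with pytest.raises(GeneratorConfigError):
            GeneratorConfig(doses_mgy=(10.0, 10.0))
        with pytest.raises(GeneratorConfigError):
            GeneratorConfig(noise="negative_binomial", dispersion=0.0)


def test_zero_mean_produces_all_zero_counts(params):
    p = params.with_updates(
        {"alpha": 1e-12, "gamma_h2ax_background": 0.0, "rad51_background": 0.0}
    )
    ds, cells = generate_foci_dataset(p, GeneratorConfig(seed=3, **SMALL))
    assert (cells["count"] == 0).all()
    assert (ds.df["mean"] == 0).all()


def test_sample_mean_converges_to_model_mean(params):
    """CLT check at n_cells = 1e5 for a single design point."""
    cfg = GeneratorConfig(seed=11, doses_mgy=(250.0,), timepoints_h=(1.0,),
                          n_cells=100_000, n_replicates=1)
    means = model_means(params, cfg)
    ds, cells = generate_foci_dataset(params, cfg)
    for channel in ("gammaH2AX", "Rad51"):
        mu = float(means[means.channel == channel]["mean"].iloc[0])
        sample = cells[cells.channel == channel]["count"].mean()
        assert abs(sample - mu) < 3.0 * np.sqrt(mu / 100_000)


def test_generator_is_seed_deterministic(params):
    a, cells_a = generate_foci_dataset(params, GeneratorConfig(seed=5, **SMALL))
    b, cells_b = generate_foci_dataset(params, GeneratorConfig(seed=5, **SMALL))
    c, cells_c = generate_foci_dataset(params, GeneratorConfig(seed=6, **SMALL))
    pd.testing.assert_frame_equal(cells_a, cells_b)
    pd.testing.assert_frame_equal(a.df, b.df)
    assert not cells_a["count"].equals(cells_c["count"])


def test_negative_binomial_is_overdispersed(params):
    pois, cp = generate_foci_dataset(params, GeneratorConfig(seed=9, **SMALL))
    nb, cn = generate_foci_dataset(
        params, GeneratorConfig(seed=9, noise="negative_binomial", dispersion=1.0, **SMALL)
    )
    key = (cn.dose_mGy == 80.0) & (cn.time_h == 6.0) & (cn.channel == "gammaH2AX")
    assert cn[key]["count"].var() > cp[key]["count"].var()


class TestCenpf:
    def test_no_decay_no_bump_is_flat(self):
        cfg = GeneratorConfig(seed=1, cenpf_decay_per_mgy=0.0, cenpf_bump_amplitude=0.0)
        for dose in (0.0, 80.0, 1000.0):
            assert cenpf_true_fraction(dose, cfg) == cfg.cenpf_baseline_fraction

    def test_fold_decrease_matches_decay_model(self):
        cfg = GeneratorConfig(seed=1, cenpf_bump_amplitude=0.0)
        fold = cenpf_true_fraction(0.0, cfg) / cenpf_true_fraction(1000.0, cfg)
        assert fold == pytest.approx(np.exp(cfg.cenpf_decay_per_mgy * 1000.0))

    def test_binomial_se_matches_analytic(self):
        """Replicate SE of the fraction vs sqrt(p(1-p)/n) over 1000 seeds."""
        n = 200
        collected = []
        p_true = None
        for seed in range(1000):
            cfg = GeneratorConfig(seed=seed, doses_mgy=(250.0,), n_cells=n,
                                  n_replicates=2)
            ds = generate_cenpf_dataset(cfg)
            row = ds.df[ds.df.dose_mGy == 250.0].iloc[0]
            collected.append(row["mean"])
            p_true = cenpf_true_fraction(250.0, cfg)
        sd = np.std(collected, ddof=1)
        expect = np.sqrt(p_true * (1 - p_true) / n) / np.sqrt(2)  # 2 replicates
        assert sd == pytest.approx(expect, rel=0.12)

    def test_fraction_outside_unit_interval_rejected(self):
        cfg = GeneratorConfig(seed=0, cenpf_baseline_fraction=0.95,
                              cenpf_bump_amplitude=0.2)
        with pytest.raises(GeneratorConfigError):
            cenpf_true_fraction(80.0, cfg)


class TestSummarize:
    @staticmethod
    def _table(rep_values, dose=100.0, time=1.0):
        rows = []
        for rep, vals in enumerate(rep_values, start=1):
            for cid, v in enumerate(vals, start=1):
                rows.append((dose, time, rep, cid, "gammaH2AX", v))
        return pd.DataFrame(
            rows,
            columns=["dose_mGy", "time_h", "replicate", "cell_id", "channel", "count"],
        )

    def test_replicate_mean_and_se(self):
        ds = summarize(self._table([[2, 2], [4, 4], [6, 6]]))
        row = ds.df.iloc[0]
        assert row["mean"] == pytest.approx(4.0)
        assert row["se"] == pytest.approx(2.0 / np.sqrt(3))
        assert row["se_kind"] == "across_replicates"

    def test_single_replicate_flagged_with_within_se(self):
        ds = summarize(self._table([[1, 2, 3, 4]]))
        row = ds.df.iloc[0]
        assert row["se_kind"] == "within_replicate"
        expect = np.std([1, 2, 3, 4], ddof=1) / 2.0
        assert row["se"] == pytest.approx(expect)

    def test_se_scales_with_replicate_count(self, params):
        """SE ~ 1/sqrt(n_replicates) over {3, 12, 48} within MC tolerance."""
        ses = {}
        for n_rep in (3, 12, 48):
            vals = []
            for seed in range(40):
                cfg = GeneratorConfig(seed=seed, doses_mgy=(250.0,),
                                      timepoints_h=(1.0,), n_cells=30,
                                      n_replicates=n_rep)
                ds, _ = generate_foci_dataset(params, cfg)
                vals.append(ds.df[ds.df.channel == "gammaH2AX"]["se"].iloc[0])
            ses[n_rep] = np.mean(vals)
        assert ses[12] == pytest.approx(ses[3] / 2.0, rel=0.25)
        assert ses[48] == pytest.approx(ses[12] / 2.0, rel=0.25)
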