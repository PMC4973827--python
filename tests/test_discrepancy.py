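"""Deviance flagging, reassignment bookkeeping and the rank correlation."""

import numpy as np
import pytest
from scipy import stats

import varclm as v
from varclm.inference import PosteriorDraws
from varclm.io import Dataset, VariantRecord


def _point_draws(params, config=None):
    """A one-draw posterior concentrated at the given parameters."""
    cfg = config or v.SamplerConfig(seed=0, n_chains=1, n_iter=2, n_burnin=1)
    return PosteriorDraws(
        theta=params.theta[None, None, :], beta=params.beta[None, None, :], config=cfg
    )


class TestMeanDeviances:
    def test_flag_fraction_bounded(self, emulated_ds, emulated_fit):
        profile = v.mean_deviances(emulated_fit, emulated_ds)
        n = len(emulated_ds)
        assert 0 <= profile.n_flagged / n <= 0.05 + 1 / n
        assert np.all(
            profile.table["flagged"]
            == (profile.table["mean_deviance"] > profile.threshold)
        )

    def test_identical_records_flag_nothing(self, simple_params):
        ds = Dataset(
            records=[VariantRecord(f"v{i}", 0.0, expert_class=3) for i in range(50)],
            n_classes=5,
        )
        profile = v.mean_deviances(_point_draws(simple_params), ds)
        assert profile.n_flagged == 0  # all equal, none strictly above

    def test_single_draw_equals_point_deviance(self, simple_params, rng):
        records = [
            VariantRecord(f"v{i}", float(s), expert_class=int(c))
            for i, (s, c) in enumerate(zip(rng.normal(0, 3, 30), rng.integers(1, 6, 30)))
        ]
        ds = Dataset(records=records, n_classes=5)
        profile = v.mean_deviances(_point_draws(simple_params), ds)
        expected = [v.deviance(simple_params, r) for r in records]
        np.testing.assert_allclose(profile.table["mean_deviance"], expected, rtol=1e-12)

    def test_point_estimate_switch(self, emulated_ds, emulated_fit):
        prof_pt = v.mean_deviances(emulated_fit, emulated_ds, point_estimate=True)
        pm = emulated_fit.posterior_mean()
        expected = [v.deviance(pm, r) for r in emulated_ds.records[:10]]
        np.testing.assert_allclose(
            prof_pt.table["mean_deviance"][:10], expected, rtol=1e-10
        )


class TestReassign:
    def test_column_sums_reproduce_class_counts(self, emulated_ds, emulated_fit):
        profile = v.mean_deviances(emulated_fit, emulated_ds)
        report = v.reassign(profile, emulated_fit, emulated_ds)
        assert report.matrix.sum(axis=0).tolist() == [151, 84, 751, 181, 1043]

    def test_unflagged_stay_on_diagonal(self, emulated_ds, emulated_fit):
        profile = v.mean_deviances(emulated_fit, emulated_ds)
        report = v.reassign(profile, emulated_fit, emulated_ds)
        a = report.assignments
        unflagged = a.loc[~a["flagged"]]
        assert (unflagged["model_class"] == unflagged["expert_class"]).all()

    def test_discordance_bookkeeping(self, emulated_ds, emulated_fit):
        profile = v.mean_deviances(emulated_fit, emulated_ds)
        report = v.reassign(profile, emulated_fit, emulated_ds)
        off_diag = report.matrix.sum() - np.trace(report.matrix)
        assert report.n_discordant == off_diag
        assert report.n_discordant <= profile.n_flagged
        J = emulated_ds.n_classes
        assert len(report.false_positives) == report.matrix[J - 1, 0]
        assert len(report.false_negatives) == report.matrix[0, J - 1]

    def test_no_flags_gives_diagonal_matrix(self, simple_params):
        rng = np.random.default_rng(3)
        records = [
            VariantRecord(f"v{i}", 0.0, expert_class=int(c))
            for i, c in enumerate(rng.integers(1, 6, 40))
        ]
        ds = Dataset(records=records, n_classes=5)
        profile = v.mean_deviances(_point_draws(simple_params), ds)
        report = v.reassign(profile, _point_draws(simple_params), ds)
        assert profile.n_flagged == 0
        assert report.n_discordant == 0
        assert np.all(report.matrix == np.diag(np.diag(report.matrix)))

    def test_flagged_but_concordant_record_stays_diagonal(self, simple_params):
        # one record is surprising (off-center score) yet its expert class
        # still matches the model argmax: it must not count as discordant
        records = [VariantRecord(f"v{i}", 0.0, expert_class=3) for i in range(30)]
        records.append(VariantRecord("odd", 3.0, expert_class=3))
        params = v.CLMParameters(theta=[-2.0, -1.0, 1.0, 2.0], beta=[0.3])
        ds = Dataset(records=records, n_classes=5)
        profile = v.mean_deviances(_point_draws(params), ds)
        report = v.reassign(profile, _point_draws(params), ds)
        assert profile.table.loc[profile.table["variant_id"] == "odd", "flagged"].item()
        assert report.n_discordant == 0


class TestSpearman:
    def test_perfectly_monotone(self):
        records = [
            VariantRecord(f"v{i}", float(i), expert_class=1 + i % 5) for i in range(5)
        ]
        ds = Dataset(records=sorted(records, key=lambda r: r.expert_class), n_classes=5)
        for i, r in enumerate(ds.records):
            r.score = float(i)
        rho, p = v.spearman_class_score(ds)
        assert rho == pytest.approx(1.0)

    def test_against_rank_then_pearson_oracle(self, rng):
        classes = rng.integers(1, 6, 50)
        scores = rng.normal(15, 8, 50)
        ds = Dataset(
            records=[
                VariantRecord(f"v{i}", float(s), expert_class=int(c))
                for i, (s, c) in enumerate(zip(scores, classes))
            ],
            n_classes=5,
        )
        rho, _ = v.spearman_class_score(ds)
        oracle = stats.pearsonr(
            stats.rankdata(classes), stats.rankdata(scores)
        ).statistic
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        ds = Dataset(
            records=[VariantRecord(f"v{i}", 1.0, expert_class=3) for i in range(5)],
            n_classes=5,
        )
        with pytest.raises(ValueError, match="variance"):
            v.spearman_class_score(ds)
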