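"""Probe filtering, platform restriction, and median imputation."""

import numpy as np
import pandas as pd
import pytest

from gaclock.io import BetaMatrix, ValidationError, make_annotation_frame
from gaclock.preprocess import filter_probes, impute_missing, restrict_to_platform


def _bm(n_probes, n_samples=4, seed=0, detection_p=None):
    rng = np.random.default_rng(seed)
    ids = [f"cg{i:04d}" for i in range(n_probes)]
    cols = [f"S{j}" for j in range(n_samples)]
    vals = pd.DataFrame(rng.uniform(0, 1, (n_probes, n_samples)), index=ids, columns=cols)
    dp = None
    if detection_p is not None:
        dp = pd.DataFrame(detection_p, index=ids, columns=cols)
    return BetaMatrix(vals, dp)


class TestFilterProbes:
    def test_no_flags_is_identity(self, random_beta_matrix):
        bm = random_beta_matrix()
        out, rep = filter_probes(
            bm, drop_cross_reactive=False, drop_snp_overlap=False
        )
        assert out.values.equals(bm.values)
        assert (rep.removed_cross_reactive, rep.removed_detection_p,
                rep.removed_snp_overlap, rep.removed_non_autosomal) == (0, 0, 0, 0)

    def test_planted_disjoint_flags_counted_per_stage(self):
        n = 100
        dp = np.full((n, 4), 0.001)
        dp[10:15] = 0.5  # detection failures on probes 10-14
        bm = _bm(n, detection_p=dp)
        cross = np.zeros(n, bool)
        cross[:10] = True
        snp = np.zeros(n, bool)
        snp[20:23] = True
        ann = make_annotation_frame(bm.probe_ids, cross_reactive=cross, snp_overlap=snp)
        out, rep = filter_probes(bm, ann)
        assert out.shape[0] == 82
        assert (rep.removed_cross_reactive, rep.removed_detection_p,
                rep.removed_snp_overlap, rep.removed_non_autosomal) == (10, 5, 3, 0)

    def test_overlapping_flags_match_set_algebra_recount(self):
        rng = np.random.default_rng(42)
        n = 200
        dp = np.where(rng.random((n, 4)) < 0.03, 0.5, 0.001)
        bm = _bm(n, detection_p=dp)
        cross = rng.random(n) < 0.15
        snp = rng.random(n) < 0.1
        autosomal = rng.random(n) > 0.05
        ann = make_annotation_frame(
            bm.probe_ids, cross_reactive=cross, snp_overlap=snp, autosomal=autosomal
        )
        out, rep = filter_probes(bm, ann, autosomal_only=True)

        # independent sequential recount with plain sets
        ids = list(bm.probe_ids)
        remaining = set(ids)
        c1 = len(remaining & {p for p, f in zip(ids, cross) if f})
        remaining -= {p for p, f in zip(ids, cross) if f}
        detp_fail = {p for p, row in zip(ids, dp) if (row > 0.01).any()}
        c2 = len(remaining & detp_fail)
        remaining -= detp_fail
        c3 = len(remaining & {p for p, f in zip(ids, snp) if f})
        remaining -= {p for p, f in zip(ids, snp) if f}
        c4 = len(remaining & {p for p, f in zip(ids, autosomal) if not f})
        remaining -= {p for p, f in zip(ids, autosomal) if not f}

        assert (rep.removed_cross_reactive, rep.removed_detection_p,
                rep.removed_snp_overlap, rep.removed_non_autosomal) == (c1, c2, c3, c4)
        assert set(out.probe_ids) == remaining

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        n = 120
        dp = np.where(rng.random((n, 4)) < 0.05, 0.5, 0.001)
        bm = _bm(n, detection_p=dp)
        ann = make_annotation_frame(
            bm.probe_ids,
            cross_reactive=rng.random(n) < 0.1,
            snp_overlap=rng.random(n) < 0.1,
        )
        once, _ = filter_probes(bm, ann)
        twice, rep2 = filter_probes(once, ann)
        assert twice.values.equals(once.values)
        assert rep2.n_input == rep2.n_output

    def test_detp_fraction_dialect(self):
        # probe 0 fails in 1/4 samples, probe 1 in 2/4
        dp = np.full((3, 4), 0.001)
        dp[0, 0] = 0.5
        dp[1, :2] = 0.5
        bm = _bm(3, detection_p=dp)
        ann = make_annotation_frame(bm.probe_ids)
        out_any, _ = filter_probes(bm, ann)
        assert out_any.shape[0] == 1
        out_frac, _ = filter_probes(bm, ann, detp_fraction=0.5)
        assert out_frac.shape[0] == 2

    def test_unannotated_probe_is_error(self, random_beta_matrix):
        bm = random_beta_matrix(n_probes=5)
        ann = make_annotation_frame(list(bm.probe_ids[:3]))
        with pytest.raises(ValidationError, match="missing from annotation"):
            filter_probes(bm, ann)


class TestRestrictToPlatform:
    def test_superset_is_identity(self, random_beta_matrix):
        bm = random_beta_matrix()
        out = restrict_to_platform(bm, set(bm.probe_ids) | {"cgX"})
        assert out.values.equals(bm.values)

    def test_subset_retained_in_order(self, random_beta_matrix):
        bm = random_beta_matrix(n_probes=10)
        half = list(bm.probe_ids[::2])
        out = restrict_to_platform(bm, set(half))
        assert list(out.probe_ids) == half

    def test_random_subsets_match_intersection(self, random_beta_matrix):
        bm = random_beta_matrix(n_probes=40)
        rng = np.random.default_rng(3)
        for _ in range(5):
            subset = set(rng.choice(list(bm.probe_ids), size=15, replace=False))
            subset |= {"cg_not_present"}
            out = restrict_to_platform(bm, subset)
            assert len(out.probe_ids) == len(subset & set(bm.probe_ids))

    def test_empty_intersection_is_error(self, random_beta_matrix):
        with pytest.raises(ValidationError, match="no probes in common"):
            restrict_to_platform(random_beta_matrix(), {"cgZZZ"})


class TestImputeMissing:
    def test_no_missing_is_identity(self, random_beta_matrix):
        bm = random_beta_matrix()
        assert impute_missing(bm) is bm

    def test_median_of_three_values(self):
        vals = pd.DataFrame(
            [[0.2, np.nan, 0.4, 0.6]], index=["cg1"], columns=list("ABCD")
        )
        out = impute_missing(BetaMatrix(vals))
        assert out.values.loc["cg1", "B"] == pytest.approx(0.4)

    def test_every_imputed_cell_matches_independent_median(self, random_beta_matrix):
        bm = random_beta_matrix(n_probes=50, n_samples=12, seed=9, missing_rate=0.1)
        out = impute_missing(bm)
        assert not out.values.isna().any().any()
        raw = bm.values.to_numpy()
        for i, probe in enumerate(bm.probe_ids):
            row = raw[i]
            expected = np.median(row[~np.isnan(row)])
            for j, sample in enumerate(bm.sample_ids):
                if np.isnan(row[j]):
                    assert out.values.iloc[i, j] == pytest.approx(expected)
                else:
                    assert out.values.iloc[i, j] == row[j]

    def test_fully_missing_probe_needs_fallback(self):
        vals = pd.DataFrame(
            [[np.nan, np.nan], [0.2, 0.4]], index=["cg1", "cg2"], columns=["A", "B"]
        )
        with pytest.raises(ValidationError, match="cg1"):
            impute_missing(BetaMatrix(vals))
        out = impute_missing(BetaMatrix(vals), fallback_medians={"cg1": 0.7})
        assert (out.values.loc["cg1"] == 0.7).all()

    def test_output_stays_in_unit_interval(self, random_beta_matrix):
        bm = random_beta_matrix(n_probes=30, n_samples=10, seed=2, missing_rate=0.2)
        out = impute_missing(bm)
        arr = out.values.to_numpy()
        assert (arr >= 0).all() and (arr <= 1).all()
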