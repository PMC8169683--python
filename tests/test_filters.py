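"""Filter cascades: boundary behavior, oracle equivalence, swap QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ithkit.filters import (
    SOMATIC_THRESHOLDS,
    apply_germline_filters,
    apply_somatic_filters,
    compare_artifact_profiles,
    swap_artifact_scan,
)
from ithkit.simulate import SimConfig, simulate_patient

from conftest import make_germline_records, make_somatic_records


def _record(**kw) -> pd.DataFrame:
    base = dict(
        depth=100, alt_count=40, af=0.4, in_1000g=False, in_esp=False,
        matched_normal_af=0.0, gq=99, vqsr=90.0, is_multiallelic=False, in_segdup=False,
    )
    base.update(kw)
    return pd.DataFrame([base], index=["r0"])


# independent re-statements of the printed criteria, used as oracles
def somatic_oracle(row, has_normal: bool) -> bool:
    af = row["af"] if row["depth"] > 0 else 0.0
    ok = row["depth"] > 25 and af > 0.05 and not row["in_1000g"] and not row["in_esp"]
    if has_normal:
        ok = ok and row["matched_normal_af"] < 0.01
    return ok


def germline_oracle(row) -> bool:
    af = row["af"] if row["depth"] > 0 else 0.0
    gq = row["gq"] if not np.isnan(row["gq"]) else -1
    return (
        row["depth"] >= 50
        and gq >= 30
        and 0.3 <= af <= 0.7
        and not row["is_multiallelic"]
        and row["vqsr"] <= 97.00
        and not row["in_segdup"]
    )


class TestSomaticBoundaries:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(depth=26, af=0.06), True),
            (dict(depth=25, af=0.5), False),  # strict >
            (dict(depth=26, af=0.05), False),  # strict >
            (dict(depth=26, af=0.051), True),
            (dict(matched_normal_af=0.01), False),  # strict <
            (dict(matched_normal_af=0.009), True),
            (dict(in_1000g=True), False),
            (dict(in_esp=True), False),
            (dict(depth=0, alt_count=0, af=np.nan), False),
        ],
    )
    def test_printed_inequalities(self, kw, expected):
        report = apply_somatic_filters(_record(**kw), has_matched_normal=True)
        assert (report.n_surviving == 1) is expected

    def test_missing_matched_normal_af_is_an_error(self):
        rec = _record().drop(columns=["matched_normal_af"])
        with pytest.raises(KeyError):
            apply_somatic_filters(rec, has_matched_normal=True)

    def test_without_matched_normal_criterion_not_applied(self):
        rec = _record(matched_normal_af=0.5).drop(columns=["matched_normal_af"])
        report = apply_somatic_filters(rec, has_matched_normal=False)
        assert report.n_surviving == 1


class TestGermlineBoundaries:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(depth=50, alt_count=15, af=0.3, gq=30, vqsr=97.00), True),  # all inclusive
            (dict(depth=49, af=0.5), False),
            (dict(af=0.7), True),
            (dict(af=0.71), False),
            (dict(af=0.29), False),
            (dict(gq=29), False),
            (dict(vqsr=97.01), False),
            (dict(is_multiallelic=True), False),
            (dict(in_segdup=True), False),
            (dict(gq=np.nan), False),  # absent GQ fails criterion 2 only
        ],
    )
    def test_printed_inequalities(self, kw, expected):
        report = apply_germline_filters(_record(**kw))
        assert (report.n_surviving == 1) is expected


class TestOracleEquivalence:
    def test_somatic_matches_bruteforce_record_by_record(self, rng):
        records = make_somatic_records(1000, rng)
        report = apply_somatic_filters(records, has_matched_normal=True)
        survivors = set(report.surviving_ids)
        for rid, row in records.iterrows():
            assert (rid in survivors) == somatic_oracle(row, True), rid

    def test_germline_matches_bruteforce_record_by_record(self, rng):
        records = make_germline_records(1000, rng)
        report = apply_germline_filters(records)
        survivors = set(report.surviving_ids)
        for rid, row in records.iterrows():
            assert (rid in survivors) == germline_oracle(row), rid

    @given(
        depth=st.integers(0, 200),
        alt=st.integers(0, 200),
        normal_af=st.floats(0, 1),
        flags=st.tuples(st.booleans(), st.booleans()),
    )
    @settings(max_examples=200, deadline=None)
    def test_somatic_agrees_with_oracle_on_arbitrary_records(self, depth, alt, normal_af, flags):
        alt = min(alt, depth)
        rec = _record(
            depth=depth, alt_count=alt, af=alt / depth if depth else 0.0,
            matched_normal_af=normal_af, in_1000g=flags[0], in_esp=flags[1],
        )
        report = apply_somatic_filters(rec, has_matched_normal=True)
        assert (report.n_surviving == 1) == somatic_oracle(rec.iloc[0], True)


class TestCascadeProperties:
    def test_idempotence(self, rng):
        records = make_somatic_records(500, rng)
        first = apply_somatic_filters(records, True)
        second = apply_somatic_filters(records.loc[first.surviving_ids], True)
        assert second.surviving_ids == first.surviving_ids
        grec = make_germline_records(500, rng)
        gfirst = apply_germline_filters(grec)
        gsecond = apply_germline_filters(grec.loc[gfirst.surviving_ids])
        assert gsecond.surviving_ids == gfirst.surviving_ids

    def test_raising_depth_threshold_shrinks_survivors(self, rng, monkeypatch):
        records = make_somatic_records(500, rng)
        baseline = set(apply_somatic_filters(records, True).surviving_ids)
        for stricter in (30, 50, 80):
            monkeypatch.setitem(SOMATIC_THRESHOLDS, "min_depth", stricter)
            assert set(apply_somatic_filters(records, True).surviving_ids) <= baseline

    def test_report_accounting(self, rng):
        records = make_somatic_records(200, rng)
        report = apply_somatic_filters(records, True)
        assert report.n_surviving + report.n_failed == report.n_input == 200


class TestSwapQc:
    def test_clean_normals_give_zero_artifacts(self):
        data = simulate_patient(SimConfig(seed=21, artifact_rate=0.0))
        report = swap_artifact_scan(data.tumor_variants, data.normal_variants)
        assert report.artifact_ids == []

    def test_normal_signal_declared_artifactual(self):
        tumor = _record(depth=30, alt_count=0, af=0.0)
        normal = _record(depth=30, alt_count=2, af=0.06)
        report = swap_artifact_scan(tumor, normal)
        assert report.artifact_ids == ["r0"]

    def test_missing_normal_is_unsupported(self):
        with pytest.raises(ValueError):
            swap_artifact_scan(_record(), _record().iloc[0:0])

    def test_symmetric_variant_requires_low_tumor_af(self):
        # with the fully symmetric cascade, a shared-AF artifact is masked
        tumor = _record(depth=170, alt_count=12, af=0.07, chrom="1", pos=100, ref="C", alt="T")
        normal = _record(depth=170, alt_count=12, af=0.07, chrom="1", pos=100, ref="C", alt="T")
        default = swap_artifact_scan(tumor, normal)
        symmetric = swap_artifact_scan(tumor, normal, use_matched_normal=True)
        assert default.artifact_ids == ["r0"]
        assert symmetric.artifact_ids == []

    def test_simulated_recall_against_truth(self):
        cfg = SimConfig(
            n_clusters=5, mutations_per_cluster=200, artifact_rate=0.05,
            artifact_af_range=(0.05, 0.1), seed=31,
        )
        data = simulate_patient(cfg)
        report = swap_artifact_scan(data.tumor_variants, data.normal_variants)
        found = set(data.normal_variants.loc[report.artifact_ids, "mutation_id"])
        injected = {m for m, f in data.truth.artifact_flags.items() if f}
        assert injected, "simulation must inject artifacts"
        recall = len(found & injected) / len(injected)
        assert recall >= 0.9


class TestArtifactProfiles:
    def test_constructed_contrast(self):
        artifacts = _record(depth=80, alt_count=5, af=0.06)
        somatic = _record(depth=170, alt_count=68, af=0.4)
        out = compare_artifact_profiles(artifacts, somatic)
        assert out["artifact_af_lower"]
        assert out["artifact_mean_af"] < out["somatic_mean_af"]

    def test_identical_groups_flag_false(self):
        rec = _record()
        out = compare_artifact_profiles(rec, rec.copy())
        assert out["artifact_mean_af"] == out["somatic_mean_af"]
        assert not out["artifact_af_lower"]

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            compare_artifact_profiles(_record().iloc[0:0], _record())

    def test_simulated_artifacts_have_lower_af(self):
        lower = 0
        for seed in range(100):
            cfg = SimConfig(n_clusters=2, mutations_per_cluster=30, artifact_rate=0.2, seed=seed)
            data = simulate_patient(cfg)
            art_ids = {m for m, f in data.truth.artifact_flags.items() if f}
            if not art_ids:
                lower += 1  # vacuously fine draw
                continue
            tumor = data.tumor_variants
            art = tumor[tumor["mutation_id"].isin(art_ids)]
            som = tumor[~tumor["mutation_id"].isin(art_ids)]
            out = compare_artifact_profiles(art, som)
            lower += out["artifact_af_lower"]
        assert lower >= 99
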