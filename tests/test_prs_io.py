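import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prsalpha import (
    CHEK2_LINKED_VARIANTS,
    GenotypeMatrix,
    PRSWeightSet,
    exclude_variants,
    parse_weights,
    score_prs,
    standardize,
    summarize_prs,
)
from prsalpha.errors import DomainError, FormatError

from .conftest import make_weight_lines
from .oracles import double_loop_prs, newton_logistic


def write_lines(tmp_path, lines, name="weights.tsv"):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


class TestParseWeights:
    def test_parses_313_variant_file(self, weight_file_313):
        ws = parse_weights(weight_file_313)
        assert len(ws) == 313
        assert ws.name == "PRS313_SYNTH"

    def test_empty_file_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            parse_weights(write_lines(tmp_path, ["variant\teffect_allele\tweight"]))
        with pytest.raises(FormatError):
            parse_weights(write_lines(tmp_path, [""], name="blank.tsv"))

    def test_duplicate_key_named_in_error(self, tmp_path):
        lines = [
            "variant\teffect_allele\tweight",
            "1_100_A_G\tG\t0.1",
            "1_100_A_G\tA\t0.2",
        ]
        with pytest.raises(FormatError, match="1_100_A_G"):
            parse_weights(write_lines(tmp_path, lines))

    def test_unparseable_weight_rejected(self, tmp_path):
        lines = ["variant\teffect_allele\tweight", "1_100_A_G\tG\tnot_a_number"]
        with pytest.raises(FormatError, match="weight"):
            parse_weights(write_lines(tmp_path, lines))

    def test_effect_allele_must_match_key(self, tmp_path):
        lines = ["variant\teffect_allele\tweight", "1_100_A_G\tT\t0.1"]
        with pytest.raises(FormatError, match="effect allele"):
            parse_weights(write_lines(tmp_path, lines))

    def test_canrisk_metadata_header(self, tmp_path):
        lines = ["# name=MYPRS alpha=0.44", "variant,effect_allele,weight", "2_500_C_T,T,0.05"]
        ws = parse_weights(write_lines(tmp_path, lines, name="w.csv"))
        assert ws.name == "MYPRS"
        assert ws.metadata["alpha"] == "0.44"


class TestExcludeVariants:
    def test_default_pair_drops_313_to_311(self, weight_file_313):
        ws = parse_weights(weight_file_313)
        out = exclude_variants(ws)
        assert len(out) == 311
        assert not set(CHEK2_LINKED_VARIANTS) & set(out.variant_keys)

    def test_empty_exclusion_is_identity(self, weight_file_313):
        ws = parse_weights(weight_file_313)
        assert exclude_variants(ws, []) == ws

    def test_set_containing_one_of_pair(self, tmp_path):
        lines = make_weight_lines(306, include_chek2_pair=False, seed=2)
        lines.insert(2, "22_29203724_C_T\tT\t0.05")
        ws = parse_weights(write_lines(tmp_path, lines[:2] + lines[2:-1]))
        assert len(ws) == 306
        assert len(exclude_variants(ws)) == 305

    def test_idempotent_and_order_independent(self, weight_file_313):
        ws = parse_weights(weight_file_313)
        once = exclude_variants(ws)
        assert exclude_variants(once) == once
        reversed_order = exclude_variants(ws, list(reversed(CHEK2_LINKED_VARIANTS)))
        assert reversed_order == once


class TestScorePrs:
    def make_matrix(self, rng, keys, n_samples):
        return GenotypeMatrix(
            sample_ids=[f"S{i}" for i in range(n_samples)],
            variant_keys=list(keys),
            dosage=rng.integers(0, 3, size=(n_samples, len(keys))).astype(float),
        )

    def test_all_zero_dosages_score_zero(self):
        gm = GenotypeMatrix(["a", "b"], ["1_10_A_G"], np.zeros((2, 1)))
        ws = PRSWeightSet("w", ("1_10_A_G",), ("G",), (0.3,))
        assert np.all(score_prs(gm, ws) == 0.0)

    def test_single_variant_arithmetic(self):
        gm = GenotypeMatrix(["a"], ["1_10_A_G"], np.array([[2.0]]))
        ws = PRSWeightSet("w", ("1_10_A_G",), ("G",), (0.1,))
        assert score_prs(gm, ws).iloc[0] == pytest.approx(0.2)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        lines = make_weight_lines(10, include_chek2_pair=False, seed=4)
        keys = [ln.split("\t")[0] for ln in lines[2:]]
        alleles = [ln.split("\t")[1] for ln in lines[2:]]
        weights = [float(ln.split("\t")[2]) for ln in lines[2:]]
        # orient every weight to the alt allele so no flips occur
        alts = [k.split("_")[3] for k in keys]
        ws = PRSWeightSet("w", tuple(keys), tuple(alts), tuple(weights))
        gm = self.make_matrix(rng, keys, 5)
        expected = double_loop_prs(gm.dosage, np.array(weights))
        assert np.array_equal(score_prs(gm, ws).to_numpy(), expected)
        assert alleles  # silence unused warning

    def test_reference_effect_allele_flips_dosage(self):
        gm = GenotypeMatrix(["a"], ["1_10_A_G"], np.array([[2.0]]))
        ws = PRSWeightSet("w", ("1_10_A_G",), ("A",), (0.1,))
        assert score_prs(gm, ws).iloc[0] == pytest.approx(0.0)  # 2 - 2 = 0 copies of A

    def test_missing_dosage_policies(self):
        gm = GenotypeMatrix(["a", "b", "c"], ["1_10_A_G"], np.array([[1.0], [np.nan], [2.0]]))
        ws = PRSWeightSet("w", ("1_10_A_G",), ("G",), (1.0,))
        with pytest.raises(FormatError, match="1_10_A_G"):
            score_prs(gm, ws, missing_policy="fail")
        scored = score_prs(gm, ws, missing_policy="mean_impute")
        assert scored.loc["b"] == pytest.approx(1.5)

    def test_absent_variant_under_fail(self):
        gm = GenotypeMatrix(["a"], ["1_10_A_G"], np.array([[1.0]]))
        ws = PRSWeightSet("w", ("1_10_A_G", "2_20_C_T"), ("G", "T"), (0.1, 0.2))
        with pytest.raises(FormatError, match="2_20_C_T"):
            score_prs(gm, ws)

    def test_dosage_outside_range_rejected(self):
        with pytest.raises(FormatError):
            GenotypeMatrix(["a"], ["1_10_A_G"], np.array([[2.5]]))


class TestStandardize:
    def test_reference_mean_maps_to_zero(self):
        assert standardize(np.array([-0.424]), -0.424, 0.611)[0] == 0.0

    def test_one_sd_above_published_control_mean(self):
        z = standardize(np.array([-0.424 + 0.611]), -0.424, 0.611)
        assert z[0] == pytest.approx(1.0)

    def test_self_standardization_gives_unit_scale(self):
        rng = np.random.default_rng(5)
        raw = rng.normal(3.0, 2.0, size=500)
        z = standardize(raw, raw.mean(), raw.std(ddof=1))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(DomainError):
            standardize(np.array([1.0]), 0.0, 0.0)


class TestSummarizePrs:
    def test_null_cohort_effect_near_zero(self, null_cohort):
        s = summarize_prs(null_cohort)
        se = (s.ci_high - s.ci_low) / (2 * 1.96)
        assert abs(s.log_or_per_sd) < 3 * se

    def test_effect_matches_newton_raphson_oracle(self, medium_cohort):
        s = summarize_prs(medium_cohort)
        df = medium_cohort.df
        sd = df.loc[df.status == 0, "prs_raw"].std(ddof=1)
        X = np.column_stack([np.ones(len(df)), df.prs_raw.to_numpy() / sd])
        coefs = newton_logistic(X, df.status.to_numpy())
        assert s.log_or_per_sd == pytest.approx(coefs[1], abs=1e-6)
        assert s.log_or_per_sd > 0  # risk-increasing PRS

    def test_location_invariance(self, medium_cohort):
        shifted = medium_cohort.df.copy()
        shifted["prs_raw"] = shifted["prs_raw"] + 4.2
        a = summarize_prs(medium_cohort)
        b = summarize_prs(shifted)
        assert a.log_or_per_sd == pytest.approx(b.log_or_per_sd, abs=1e-8)
        assert b.mean_controls == pytest.approx(a.mean_controls + 4.2)

    def test_single_status_cohort_rejected(self, medium_cohort):
        cases_only = medium_cohort.df[medium_cohort.df.status == 1]
        with pytest.raises(DomainError):
            summarize_prs(cases_only)

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(shift=st.floats(-2, 2))
    def test_group_stats_shift_equivariance(self, shift, medium_cohort):
        df = medium_cohort.df.copy()
        df["prs_raw"] = df["prs_raw"] + shift
        s = summarize_prs(df)
        base = summarize_prs(medium_cohort)
        assert s.sd_controls == pytest.approx(base.sd_controls)
        assert s.mean_cases - s.mean_controls == pytest.approx(
            base.mean_cases - base.mean_controls, abs=1e-9
        )
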