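import math

import pytest
from hypothesis import given, settings, strategies as st

from jjdq.errors import EmptyExtractError
from jjdq.records import DecisionPoint, Extract, ResponseValue
from jjdq.rules import (
    RULE_PRIORITY,
    RuleId,
    audit,
    check_conformance,
    completeness_profile,
    detect_all,
    first_inconsistency,
    percent,
)
from jjdq.synthetic import GeneratorConfig, generate

from conftest import make_case, make_extract
from _oracle import all_assignments, oracle_fired, oracle_first

D = DecisionPoint


def _case_from_tokens(tokens):
    return make_case(**tokens)


class TestDetectAll:
    def test_diverted_and_petitioned_is_inconsistent_petition(self):
        flags = detect_all(make_case(diverted="yes", petitioned="yes"))
        assert {f.rule for f in flags} == {RuleId.INCONSISTENT_PETITION}
        (f,) = flags
        assert f.anchor_position == 3
        assert f.involved_points == frozenset({D.DIVERTED, D.PETITIONED})

    def test_detention_does_not_rescue_an_implausible_case(self):
        # a courtesy detention: held here, court processing elsewhere
        flags = detect_all(make_case(detained="yes"))
        assert {f.rule for f in flags} == {RuleId.IMPLAUSIBLE_CASE}

    def test_missing_never_matches_a_no_literal(self):
        assert detect_all(make_case(diverted="missing", petitioned="no")) == set()

    def test_missing_never_matches_a_yes_literal(self):
        assert detect_all(make_case(diverted="missing", adjudicated="yes", petitioned="yes")) == set()

    def test_two_rules_can_fire_on_one_case(self):
        flags = detect_all(
            make_case(diverted="yes", petitioned="yes", adjudicated="missing", confined="yes")
        )
        assert {f.rule for f in flags} == {
            RuleId.INCONSISTENT_PETITION,
            RuleId.EXCESS_INFORMATION,
        }

    def test_excess_anchor_is_earliest_offending_yes(self):
        flags = detect_all(make_case(diverted="yes", petitioned="missing", adjudicated="missing",
                                     confined="yes", waived="yes"))
        (f,) = [f for f in flags if f.rule is RuleId.EXCESS_INFORMATION]
        assert f.anchor_position == D.CONFINED.canonical_position
        assert f.involved_points == frozenset({D.DIVERTED, D.CONFINED, D.WAIVED})

    def test_adjudication_missing_counts_switch(self):
        case = make_case(petitioned="yes", adjudicated="missing", probation="yes")
        assert detect_all(case) == set()
        flags = detect_all(case, adjudication_missing_counts=True)
        assert {f.rule for f in flags} == {RuleId.INCONSISTENT_ADJUDICATION}


class TestFirstInconsistency:
    def test_petition_recorded_before_waiver(self):
        # the worked example: both an inconsistent petition and an
        # inconsistent waiver on one arrest — petition (anchor 3) wins
        case = make_case(diverted="yes", petitioned="yes", adjudicated="yes", waived="yes")
        fired = {f.rule for f in detect_all(case)}
        assert RuleId.INCONSISTENT_PETITION in fired and RuleId.INCONSISTENT_WAIVER in fired
        assert first_inconsistency(case).rule is RuleId.INCONSISTENT_PETITION

    def test_no_rule_fires_returns_none(self):
        assert first_inconsistency(make_case(diverted="yes")) is None

    def test_exhaustive_agreement_with_truth_table_oracle(self):
        """detect_all and first_inconsistency vs the literal transcription, all 3^7."""
        for tokens in all_assignments():
            case = _case_from_tokens(tokens)
            got = {f.rule.name: f.anchor_position for f in detect_all(case)}
            assert got == oracle_fired(tokens), tokens
            first = first_inconsistency(case)
            assert (first.rule.name if first else None) == oracle_first(tokens), tokens


class TestCompleteness:
    def test_all_missing_field_reports_100(self):
        ex = make_extract(*[make_case(confined="missing") for _ in range(4)])
        assert completeness_profile(ex)[D.CONFINED] == 100.0

    def test_no_missing_reports_all_zero(self, simple_extract):
        assert set(completeness_profile(simple_extract).values()) == {0.0}

    def test_empty_extract_is_an_error(self):
        with pytest.raises(EmptyExtractError):
            completeness_profile(Extract(records=[]))

    def test_rates_recovered_within_3se_on_generator_output(self):
        rates = {p: 0.0 for p in DecisionPoint}
        rates[D.DIVERTED] = 0.1
        rates[D.PETITIONED] = 0.2
        extract, _ = generate(GeneratorConfig(
            n_youth=4000, arrests_per_youth_mean=1.0, seed=17, missingness_rates=rates,
        ))
        profile = completeness_profile(extract)
        n = extract.n_cases
        for p in DecisionPoint:
            se = math.sqrt(rates[p] * (1 - rates[p]) / n) * 100
            assert abs(profile[p] - rates[p] * 100) <= 3 * se + 0.05  # 0.05 = rounding grain

    def test_percent_rounds_half_up(self):
        assert percent(1, 16) == 6.3  # 6.25 rounds up, not to even
        assert percent(1, 8) == 12.5


class TestConformance:
    def test_zero_violations(self, simple_extract):
        assert check_conformance(simple_extract).count == 0

    def test_violations_grouped_by_field(self):
        import io
        from jjdq.records import COLUMNS, read_extract

        header = ",".join(COLUMNS)
        rows = [
            "c1,y1,CMS1,CMS1-C1,pre,male,White,15,Misdemeanor A,Y3S,no,no,no,no,no,no",
            "c2,y1,CMS1,CMS1-C1,pre,male,White,15,Misdemeanor A,yes,no,no,no,no,no,true",
        ]
        ex = read_extract(io.StringIO("\n".join([header, *rows]) + "\n"))
        report = check_conformance(ex)
        assert report.count == 2
        assert {p.column for p in report.by_field} == {"diverted", "waived"}

    def test_noise_rate_recovered_within_3se(self):
        # ~1429 cases x 7 fields = ~10,000 token draws at 5%
        extract, truth = generate(GeneratorConfig(
            n_youth=1429, arrests_per_youth_mean=1.0, seed=23, conformance_noise_rate=0.05,
        ))
        n_fields = extract.n_cases * 7
        count = check_conformance(extract).count
        assert count == sum(len(t.injected_nonconforming) for t in truth.per_case.values())
        se = math.sqrt(0.05 * 0.95 * n_fields)
        assert abs(count - 0.05 * n_fields) <= 3 * se


class TestAudit:
    def test_at_least_one_percentage(self):
        cases = [make_case(diverted="yes", petitioned="yes") for _ in range(2)]
        cases += [make_case(diverted="yes") for _ in range(8)]
        result = audit(make_extract(*cases))
        assert result.at_least_one_count == 2
        assert result.at_least_one_pct == 20.0

    def test_per_rule_counts_partition_flagged_cases(self):
        extract, _ = generate(GeneratorConfig(
            n_youth=2000, arrests_per_youth_mean=1.0, seed=31,
            injection_rates={r: 0.04 for r in RuleId},
            missingness_rates={p: 0.05 for p in DecisionPoint},
        ))
        result = audit(extract)
        assert sum(result.per_rule_counts.values()) == result.at_least_one_count

    def test_empty_extract_is_an_error(self):
        with pytest.raises(EmptyExtractError):
            audit(Extract(records=[]))

    def test_zero_rates_audit_is_silent(self):
        extract, _ = generate(GeneratorConfig(n_youth=300, seed=7))
        result = audit(extract)
        assert result.at_least_one_count == 0
        assert set(result.completeness.values()) == {0.0}
        assert result.conformance_count == 0

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(min_value=0, max_value=3 ** 7 - 1))
    def test_adding_a_clean_case_never_increases_percentages(self, index):
        tokens = []
        for _ in range(7):
            index, r = divmod(index, 3)
            tokens.append(["yes", "no", "missing"][r])
        names = ["diverted", "detained", "petitioned", "adjudicated", "probation",
                 "confined", "waived"]
        base = make_extract(make_case(**dict(zip(names, tokens))), make_case(diverted="yes"))
        before = audit(base)
        grown = make_extract(*base.records, make_case(petitioned="yes", adjudicated="yes",
                                                      probation="yes"))
        after = audit(grown)
        for rule in RuleId:
            assert after.per_rule_pct(rule) <= before.per_rule_pct(rule)
        assert after.at_least_one_pct <= before.at_least_one_pct

    def test_json_shape(self, simple_extract):
        payload = audit(simple_extract).to_dict()
        assert payload["n_cases"] == 4
        assert set(payload["per_rule"]) == {r.value for r in RuleId}
        assert payload["at_least_one"] == {"count": 0, "pct": 0.0}
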