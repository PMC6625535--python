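import io

import pytest

from jjdq.cleaning import (
    DEFAULT_STRATEGIES,
    EXCLUDED,
    ResolutionPolicy,
    Strategy,
    clean_extract,
    resolve_case,
    write_action_log,
)
from jjdq.errors import PolicyError
from jjdq.records import DecisionPoint, ResponseValue
from jjdq.rules import RuleId, audit, detect_all, first_inconsistency
from jjdq.synthetic import GeneratorConfig, generate

from conftest import make_case, make_extract

D = DecisionPoint
YES, NO, MISSING = ResponseValue.YES, ResponseValue.NO, ResponseValue.MISSING


def _resolve(case, strategy):
    flag = first_inconsistency(case)
    assert flag is not None
    policy = ResolutionPolicy(overrides={case.case_id: strategy})
    return resolve_case(case, flag, policy)


class TestResolveCase:
    def test_overturned_diversion(self):
        case = make_case(diverted="yes", petitioned="yes")
        out, action = _resolve(case, Strategy.OVERTURNED)
        assert out.points[D.DIVERTED] is NO and out.points[D.PETITIONED] is YES
        assert RuleId.INCONSISTENT_PETITION not in {f.rule for f in detect_all(out)}
        assert dict((p, (o, n)) for p, o, n in action.field_edits) == {D.DIVERTED: (YES, NO)}

    def test_violated_agreement(self):
        case = make_case(diverted="yes", petitioned="yes")
        out, _ = _resolve(case, Strategy.VIOLATED_AGREEMENT)
        assert out.points[D.DIVERTED] is YES and out.points[D.PETITIONED] is NO
        assert detect_all(out) == set()

    def test_courtesy_detention_excludes_without_edits(self):
        case = make_case(detained="yes")
        out, action = _resolve(case, Strategy.COURTESY_DETENTION)
        assert out is EXCLUDED
        assert action.excluded_from_county and action.field_edits == ()

    def test_clerical_leaves_case_flagged(self):
        case = make_case()
        out, action = _resolve(case, Strategy.CLERICAL)
        assert out.points == case.points
        assert not action.resolved
        assert first_inconsistency(out).rule is RuleId.IMPLAUSIBLE_CASE

    def test_unlink_clears_offending_values_to_missing(self):
        case = make_case(diverted="yes", confined="yes", waived="yes")
        out, _ = _resolve(case, Strategy.UNLINK)
        assert out.points[D.CONFINED] is MISSING and out.points[D.WAIVED] is MISSING
        assert RuleId.EXCESS_INFORMATION not in {f.rule for f in detect_all(out)}

    def test_fix_diversion_can_surface_an_implausible_case(self):
        # correcting the diversion field on a never-petitioned case leaves
        # no+no: the new flag is expected and caught by the post re-audit
        case = make_case(diverted="yes", adjudicated="missing", confined="yes")
        out, _ = _resolve(case, Strategy.FIX_DIVERSION)
        assert out.points[D.DIVERTED] is NO
        fired = {f.rule for f in detect_all(out)}
        assert RuleId.EXCESS_INFORMATION not in fired
        assert fired == {RuleId.IMPLAUSIBLE_CASE}

    def test_waiver_fix_sets_offenders_to_no(self):
        case = make_case(petitioned="yes", waived="yes", adjudicated="yes", probation="yes")
        out, _ = _resolve(case, Strategy.FIX)
        assert out.points[D.ADJUDICATED] is NO and out.points[D.PROBATION] is NO
        assert RuleId.INCONSISTENT_WAIVER not in {f.rule for f in detect_all(out)}

    def test_backfill_adjudication(self):
        case = make_case(petitioned="yes", adjudicated="no", probation="yes")
        out, _ = _resolve(case, Strategy.BACKFILL)
        assert out.points[D.ADJUDICATED] is YES
        assert RuleId.INCONSISTENT_ADJUDICATION not in {f.rule for f in detect_all(out)}

    def test_strategy_outside_rule_menu_is_policy_error(self):
        case = make_case(diverted="yes", petitioned="yes")
        flag = first_inconsistency(case)
        policy = ResolutionPolicy(overrides={case.case_id: Strategy.BACKFILL})
        with pytest.raises(PolicyError, match="INCONSISTENT_PETITION"):
            resolve_case(case, flag, policy)

    def test_per_rule_default_used_without_override(self):
        case = make_case(diverted="yes", petitioned="yes")
        out, action = resolve_case(case, first_inconsistency(case), ResolutionPolicy())
        assert action.strategy is DEFAULT_STRATEGIES[RuleId.INCONSISTENT_PETITION]


@pytest.fixture
def flagged_world():
    config = GeneratorConfig(
        n_youth=800,
        arrests_per_youth_mean=1.0,
        seed=101,
        injection_rates={r: 0.06 for r in RuleId},
        missingness_rates={p: 0.05 for p in DecisionPoint},
    )
    extract, truth = generate(config)
    policy = ResolutionPolicy(
        overrides={cid: truth.per_case[cid].injected_scenario for cid in truth.injected_cases()}
    )
    return extract, truth, policy


class TestCleanExtract:
    def test_zero_flags_is_identity(self, simple_extract):
        result = clean_extract(simple_extract, audit(simple_extract), ResolutionPolicy())
        assert result.actions == [] and result.excluded == []
        assert [r.points for r in result.post.records] == [r.points for r in simple_extract.records]

    def test_conservation_of_records(self, flagged_world):
        extract, _, policy = flagged_world
        result = clean_extract(extract, audit(extract), policy)
        assert result.post.n_cases + len(result.excluded) == extract.n_cases
        pre_ids = {r.case_id for r in extract.records}
        post_ids = {r.case_id for r in result.post.records} | {r.case_id for r in result.excluded}
        assert pre_ids == post_ids

    def test_resolved_rules_never_refire(self, flagged_world):
        extract, _, policy = flagged_world
        pre_audit = audit(extract)
        result = clean_extract(extract, pre_audit, policy)
        unresolved = set(result.unresolved)
        for rec in result.post.records:
            flag = pre_audit.first_error[rec.case_id]
            if flag is None or rec.case_id in unresolved:
                continue
            assert flag.rule not in {f.rule for f in detect_all(rec)}

    def test_action_log_covers_exactly_flagged_non_clerical_cases(self, flagged_world):
        extract, _, policy = flagged_world
        pre_audit = audit(extract)
        result = clean_extract(extract, pre_audit, policy)
        flagged = {cid for cid, f in pre_audit.first_error.items() if f is not None}
        assert {a.case_id for a in result.actions} == flagged - set(result.unresolved)

    def test_post_at_least_one_never_exceeds_pre(self, flagged_world):
        extract, _, policy = flagged_world
        pre_audit = audit(extract)
        result = clean_extract(extract, pre_audit, policy)
        assert audit(result.post).at_least_one_pct <= pre_audit.at_least_one_pct

    def test_idempotent_under_fixed_policy(self, flagged_world):
        extract, _, policy = flagged_world
        first = clean_extract(extract, audit(extract), policy)
        second = clean_extract(first.post, audit(first.post), policy)
        assert second.excluded == [] and second.actions == []
        assert [r.points for r in second.post.records] == [r.points for r in first.post.records]
        assert sorted(second.unresolved) == sorted(first.unresolved)

    def test_truth_scenario_resolution_restores_original_fields(self, flagged_world):
        extract, truth, policy = flagged_world
        pre_audit = audit(extract)
        by_id = {r.case_id: r for r in extract.records}
        for cid in truth.injected_cases():
            t = truth.per_case[cid]
            if t.injected_scenario in (Strategy.COURTESY_DETENTION, Strategy.CLERICAL):
                continue
            out, _ = resolve_case(by_id[cid], pre_audit.first_error[cid], policy)
            assert out.points == t.original.points, cid


class TestPolicyIO:
    def test_yaml_round_trip(self, tmp_path):
        policy = ResolutionPolicy(
            per_rule={**DEFAULT_STRATEGIES, RuleId.IMPLAUSIBLE_CASE: Strategy.CLERICAL},
            overrides={"case-000001": Strategy.VIOLATED_AGREEMENT},
            seed=7,
        )
        path = tmp_path / "policy.yaml"
        policy.to_yaml(path)
        back = ResolutionPolicy.from_yaml(path)
        assert back.per_rule == policy.per_rule
        assert back.overrides == policy.overrides

    def test_invalid_menu_in_constructor(self):
        with pytest.raises(PolicyError):
            ResolutionPolicy(per_rule={RuleId.INCONSISTENT_WAIVER: Strategy.BACKFILL})

    def test_action_log_csv_shape(self):
        case = make_case(diverted="yes", petitioned="yes")
        _, action = resolve_case(case, first_inconsistency(case), ResolutionPolicy())
        out = io.StringIO()
        write_action_log([action], out)
        lines = out.getvalue().strip().splitlines()
        assert lines[0] == "case_id,rule,strategy,field,old,new,excluded"
        assert lines[1].startswith(f"{case.case_id},inconsistent_petition,overturned,diverted,yes,no")
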