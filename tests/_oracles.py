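"""Independent oracles used across the test suite.

These deliberately re-derive expected values by brute force -- exhaustive
enumeration of the one-cycle decision tree, and pairwise/blend dominance
checks for the frontier -- without touching the implementation paths they
validate.
"""

from __future__ import annotations

from depscreen_cea.parameters import REFERENCE_SCREENING_COST


def enumerate_cycle(strategy, params, prevalence, age):
    """Exhaustive decision-tree expectation for one annual cycle.

    Walks every branch of depression x screening-stage results x
    fallback diagnosis x treatment entry x adequacy x remission and
    accumulates probability-weighted cost and utility per living cohort
    member, plus the remitted fraction.  Returns (cost, utility,
    remitted_fraction).
    """
    pw = params.pathway
    u = params.utilities
    c = params.costs
    scale = c.c_screening_two_stage / REFERENCE_SCREENING_COST
    gate = pw.p_treatment_if_diagnosed
    screen_gate = gate if params.screen_positive_treatment_gate else 1.0
    adequate = pw.p_adequate_cc if strategy.care == "cc" else pw.p_adequate_uc
    c_treat = c.c_treatment_cc if strategy.care == "cc" else c.c_treatment_uc
    cap_ok = params.productivity_age_cap is None or age <= params.productivity_age_cap

    nurse = c.wage_rn * c.minutes_rn / 60.0
    gp2 = c.wage_gp * c.minutes_gp_phq2 / 60.0
    gp9 = c.wage_gp * c.minutes_gp_phq9 / 60.0

    total_cost = 0.0
    total_util = 0.0
    total_remit = 0.0

    for dep, p_dep in ((True, prevalence), (False, 1.0 - prevalence)):
        if p_dep == 0.0:
            continue
        # Screening-stage branches: (probability, screening cost, screen positive)
        if strategy.screening == "none":
            stage_branches = [(1.0, 0.0, False)]
        elif strategy.screening == "two_stage":
            p2 = params.phq2.sensitivity if dep else 1.0 - params.phq2.specificity
            p9 = params.phq9.sensitivity if dep else 1.0 - params.phq9.specificity
            base_cost = (nurse + gp2) * scale
            stage_branches = [
                (1.0 - p2, base_cost, False),
                (p2 * (1.0 - p9), base_cost + gp9 * scale, False),
                (p2 * p9, base_cost + gp9 * scale, True),
            ]
        elif strategy.screening == "phq9_only":
            p9 = params.phq9.sensitivity if dep else 1.0 - params.phq9.specificity
            base_cost = (nurse + gp9) * scale
            stage_branches = [(1.0 - p9, base_cost, False), (p9, base_cost, True)]
        else:  # pragma: no cover
            raise AssertionError(strategy.screening)

        for p_stage, screen_cost, positive in stage_branches:
            if p_stage == 0.0:
                continue
            # Detection branches: (probability, entry probability)
            if positive:
                detect_branches = [(1.0, screen_gate)]
            elif dep and (strategy.screening == "none" or params.fn_fallback):
                detect_branches = [
                    (pw.p_diagnosis_status_quo, gate),
                    (1.0 - pw.p_diagnosis_status_quo, 0.0),
                ]
            else:
                detect_branches = [(1.0, 0.0)]

            for p_detect, p_entry in detect_branches:
                if p_detect == 0.0:
                    continue
                for entered, p_ent in ((True, p_entry), (False, 1.0 - p_entry)):
                    if p_ent == 0.0:
                        continue
                    adequacy_branches = (
                        ((True, adequate), (False, 1.0 - adequate))
                        if entered
                        else ((False, 1.0),)
                    )
                    for adequate_tx, p_a in adequacy_branches:
                        if p_a == 0.0:
                            continue
                        p_remit_branch = (
                            pw.p_treatable if (dep and entered and adequate_tx) else 0.0
                        )
                        for remitted, p_r in (
                            (True, p_remit_branch),
                            (False, 1.0 - p_remit_branch),
                        ):
                            if p_r == 0.0:
                                continue
                            prob = p_dep * p_stage * p_detect * p_ent * p_a * p_r
                            cost = screen_cost
                            if entered:
                                cost += c_treat
                            if dep and not remitted and cap_ok:
                                cost += c.c_productivity_total
                            if dep:
                                util = u.u_remission if remitted else u.u_depressed
                            else:
                                util = u.u_well
                            total_cost += prob * cost
                            total_util += prob * util
                            if dep and remitted:
                                total_remit += prob
    return total_cost, total_util, total_remit


def brute_force_frontier(entries):
    """Strategies undominated by any single alternative or two-way blend.

    ``entries`` are (name, cost, qalys) triples with generic (tie-free)
    values.  A strategy is off the frontier if a single alternative is
    no costlier and no less effective (strictly better somewhere), or if
    a convex combination of two alternatives delivers its effectiveness
    at strictly lower cost.
    """
    frontier = set()
    for i, (name_i, c_i, q_i) in enumerate(entries):
        dominated = False
        for j, (_, c_j, q_j) in enumerate(entries):
            if j == i:
                continue
            if c_j <= c_i and q_j >= q_i and (c_j < c_i or q_j > q_i):
                dominated = True
                break
        if not dominated:
            for j, (_, c_j, q_j) in enumerate(entries):
                for k, (_, c_k, q_k) in enumerate(entries):
                    if i in (j, k) or j == k or not (q_j < q_i < q_k):
                        continue
                    lam = (q_i - q_j) / (q_k - q_j)
                    if c_j + lam * (c_k - c_j) < c_i:
                        dominated = True
        if not dominated:
            frontier.add(name_i)
    return frontier
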