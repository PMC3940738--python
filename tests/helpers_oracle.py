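"""Independent brute-force oracle: exhaustive state-path enumeration.

Re-derives cohort expectations by recursing over every individual-level
path through the treatment model, weighting utilities and costs by path
probability.  Written against the model definition (events per year),
not against the engine's matrix propagation, so agreement is a real check.
"""

from __future__ import annotations


def enumerate_expectations(arm, params, utilities, costs, life_table, timing,
                           start_age, horizon, setting="overall"):
    """Expected discounted (qaly, direct_cost) by path enumeration."""
    rate = timing.discount_rate
    exp = {"cycle_start": lambda t: t, "cycle_end": lambda t: t + 1,
           "half_cycle": lambda t: t + 0.5}
    df_u = [(1 + rate) ** -exp[timing.utilities](t) for t in range(horizon)]
    df_c = [(1 + rate) ** -exp[timing.annual_costs](t) for t in range(horizon)]
    df_e = [(1 + rate) ** -t for t in range(horizon)]
    surgery = costs.surgery_cost(setting)
    annual = (costs.annual_medical_cost_surgical if arm == "surgical"
              else costs.annual_medical_cost_nonsurgical)
    m = params.surgical_mortality
    acc = {"q": 0.0, "c": 0.0}

    def util(state):
        kind = state[0]
        return {"sat": utilities.satisfactory, "unsat": utilities.unsatisfactory,
                "rev": utilities.revision, "dead": utilities.dead}[kind]

    def visit(state, t, prob):
        """Accrue cycle t for a path occupying `state`, then branch."""
        if t >= horizon or prob == 0.0:
            return
        acc["q"] += prob * util(state) * df_u[t]
        if state[0] != "dead":
            acc["c"] += prob * annual * df_c[t]
        if state[0] == "rev":
            acc["c"] += prob * surgery * df_e[t]
        if arm == "surgical" and t == 0:
            acc["c"] += prob * surgery  # initial operation, undiscounted
        kind, r = state
        if kind == "dead":
            visit(state, t + 1, prob)
            return
        q = life_table.q(start_age + t)
        visit(("dead", 0), t + 1, prob * q)
        live = prob * (1 - q)
        if kind == "rev":
            p = params.p_satisfactory_after_revision
            visit(("sat", r), t + 1, live * p)
            visit(("unsat", r), t + 1, live * (1 - p))
            return
        if arm == "surgical" and r < params.max_revisions:
            rr = params.revision_rate_subsequent
            visit(("rev", r + 1), t + 1, live * rr * (1 - m))
            visit(("dead", 0), t + 1, live * rr * m)
            live *= (1 - rr)
        visit((kind, r), t + 1, live)

    if arm == "nonsurgical":
        p = params.p_satisfactory_nonsurgical
        visit(("sat", 0), 0, p)
        visit(("unsat", 0), 0, 1 - p)
    else:
        p = params.p_satisfactory_surgical
        r1 = params.revision_rate_year1
        visit(("dead", 0), 0, m)
        alive = 1 - m
        if params.max_revisions >= 1:
            visit(("rev", 1), 0, alive * r1 * (1 - m))
            visit(("dead", 0), 0, alive * r1 * m)
            alive *= (1 - r1)
        visit(("sat", 0), 0, alive * p)
        visit(("unsat", 0), 0, alive * (1 - p))
    return acc["q"], acc["c"]
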