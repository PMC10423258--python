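"""Independent reference implementations used only to check the package.

These deliberately share no code with the library: the QP oracle solves the
Karush-Kuhn-Tucker system by exhaustive active-set enumeration with dense
linear algebra, and the GPR oracle evaluates rules through expansion to
disjunctive normal form.
"""

from __future__ import annotations

import itertools

import numpy as np

FREE, AT_LB, AT_UB = 0, 1, 2


def kkt_qp_oracle(S, q, lb, ub, tol=1e-7):
    """Solve  min 1/2 v'v + q'v  s.t.  Sv = 0, lb <= v <= ub  exactly.

    Enumerates every assignment of variables to {free, at lb, at ub}, solves
    the resulting equality-constrained KKT system densely, and returns the
    first point satisfying primal and dual feasibility.  The objective is
    strictly convex, so any KKT point is the unique optimum.  Exponential in
    the number of variables; use only on tiny problems.
    """
    S = np.asarray(S.todense() if hasattr(S, "todense") else S, dtype=float)
    q = np.asarray(q, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = S.shape
    scale = max(1.0, np.abs(q).max())

    states_per_var = []
    for i in range(n):
        if ub[i] - lb[i] <= 1e-15:
            states_per_var.append((AT_LB,))  # fixed variable
        else:
            states_per_var.append((FREE, AT_LB, AT_UB))

    for states in itertools.product(*states_per_var):
        states = np.array(states)
        free = states == FREE
        v = np.where(states == AT_UB, ub, lb)
        nf = int(free.sum())
        Sf = S[:, free]
        # KKT: [I Sf'; Sf 0] [v_f; lam] = [-q_f; -S_a v_a]
        K = np.block(
            [[np.eye(nf), Sf.T], [Sf, np.zeros((m, m))]]
        )
        rhs = np.concatenate([-q[free], -S[:, ~free] @ v[~free]])
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        if np.abs(K @ sol - rhs).max() > tol * scale:
            continue  # inconsistent equality rows for this active set
        v[free] = sol[:nf]
        lam = sol[nf:]
        if (v < lb - tol).any() or (v > ub + tol).any():
            continue
        r = v + q + S.T @ lam  # bound multipliers by stationarity
        ok = True
        for i in range(n):
            if states[i] == FREE or ub[i] - lb[i] <= 1e-15:
                continue
            if states[i] == AT_LB and r[i] < -tol * scale:
                ok = False
                break
            if states[i] == AT_UB and r[i] > tol * scale:
                ok = False
                break
        if ok:
            return v
    raise RuntimeError("active-set enumeration found no KKT point")


def dnf_gpr_oracle(rule_text, expr, weights):
    """Evaluate a GPR rule by expansion to disjunctive normal form.

    Parses with a tiny shunting-yard-free recursive splitter, expands
    OR-of-AND clauses, and scores sum-over-clauses of min-over-genes of
    expr/weight.  Only meant for rules with a handful of genes.
    """
    tokens = rule_text.replace("(", " ( ").replace(")", " ) ").split()

    def parse(pos):
        # returns (list of clauses, next position); clause = tuple of genes
        clauses, current, op_pending = None, None, None

        def combine(left, right, op):
            if left is None:
                return right
            if op == "or":
                return left + right
            return [tuple(sorted(set(a + b))) for a in left for b in right]

        while pos < len(tokens):
            t = tokens[pos]
            if t == ")":
                return combine(clauses, current, "or"), pos
            if t == "(":
                sub, pos = parse(pos + 1)
                assert tokens[pos] == ")"
                operand = sub
            elif t.lower() in ("and", "or"):
                if t.lower() == "or":
                    clauses = combine(clauses, current, "or")
                    current = None
                op_pending = t.lower()
                pos += 1
                continue
            else:
                operand = [(t,)]
            if current is None:
                current = operand
            else:
                current = combine(current, operand, "and")
            op_pending = None
            pos += 1
        return combine(clauses, current, "or"), pos

    clauses, _ = parse(0)
    total = 0.0
    for clause in clauses:
        total += min(expr.get(g, 0.0) / weights[g] for g in clause)
    return total
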