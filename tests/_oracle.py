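"""Independent brute-force LP oracle for flux ranges.

Builds dense equality/inequality matrices straight from a
``CommunityModel``'s reaction dictionaries — a deliberately separate code
path from the package's sparse GLPK assembly — and solves each
single-reaction objective with ``scipy.optimize.linprog`` (HiGHS).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def oracle_flux_range(model, reaction_id):
    """(min, max) flux of ``reaction_id`` under all model constraints."""
    rids = sorted(model.reactions)
    mids = sorted(model.metabolite_ids)
    ridx = {r: j for j, r in enumerate(rids)}
    midx = {m: i for i, m in enumerate(mids)}
    n, m = len(rids), len(mids)

    A_eq = np.zeros((m, n))
    bounds = []
    for r in rids:
        rxn = model.reactions[r]
        for met, coef in rxn.stoichiometry.items():
            A_eq[midx[met], ridx[r]] = coef
        bounds.append((rxn.lower_bound, rxn.upper_bound))

    A_ub_rows = []
    if model.config.coupling_enabled:
        c = model.config.coupling_factor
        eps = model.config.coupling_relax
        for r in rids:
            rxn = model.reactions[r]
            if rxn.strain_id is None or rxn.kind == "biomass":
                continue
            jb = ridx[model.biomass_reaction_id(rxn.strain_id)]
            for sign in (1.0, -1.0):
                row = np.zeros(n)
                row[ridx[r]] = sign
                row[jb] = -c
                A_ub_rows.append(row)
    A_ub = np.array(A_ub_rows) if A_ub_rows else None
    b_ub = (
        np.full(len(A_ub_rows), model.config.coupling_relax)
        if A_ub_rows
        else None
    )

    out = []
    for sense in (1.0, -1.0):  # min then max
        cvec = np.zeros(n)
        cvec[ridx[reaction_id]] = sense
        res = linprog(
            cvec, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(m),
            bounds=bounds, method="highs",
        )
        if res.status == 2:
            return None  # infeasible
        if res.status == 3:
            out.append(np.inf * -sense)
        else:
            out.append(sense * res.fun)
    return out[0], out[1]
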