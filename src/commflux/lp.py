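"""Low-level linear-programming core.

Every flux computation in this package reduces to linear programmes of the
form

    S v = 0,   lb <= v <= ub,   optionally  |v_j| <= c * v_bio(j) + eps,

optimising single reaction fluxes.  This module wraps GLPK (via ``swiglpk``)
behind a small, deterministic interface: the problem is loaded once and a
warm-started simplex is re-run for each objective, which is the standard way
flux-variability loops are made fast.  Nothing here knows about metabolites
or communities; callers hand in index-based sparse columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import swiglpk as glp

glp.glp_term_out(glp.GLP_OFF)  # GLPK writes basis chatter to stdout otherwise

__all__ = ["LPStatus", "LPResult", "StoichiometricLP", "UNBOUNDED_CAP"]

#: Cap substituted (with status "unbounded") when a flux maximum is unbounded.
UNBOUNDED_CAP = 1.0e4


class LPStatus:
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


@dataclass
class LPResult:
    objective: Optional[float]
    status: str
    fluxes: Optional[np.ndarray] = None


def _set_col_bounds(lp, j: int, lb: float, ub: float) -> None:
    lo_inf = np.isneginf(lb)
    up_inf = np.isposinf(ub)
    if lo_inf and up_inf:
        glp.glp_set_col_bnds(lp, j, glp.GLP_FR, 0.0, 0.0)
    elif lo_inf:
        glp.glp_set_col_bnds(lp, j, glp.GLP_UP, 0.0, float(ub))
    elif up_inf:
        glp.glp_set_col_bnds(lp, j, glp.GLP_LO, float(lb), 0.0)
    elif lb == ub:
        glp.glp_set_col_bnds(lp, j, glp.GLP_FX, float(lb), float(lb))
    else:
        glp.glp_set_col_bnds(lp, j, glp.GLP_DB, float(lb), float(ub))


class StoichiometricLP:
    """A steady-state flux polytope with optional biomass-coupling rows.

    Parameters
    ----------
    n_metabolites:
        Number of steady-state (equality) rows.
    columns:
        One sparse column per reaction: list of ``(row_index, coefficient)``
        pairs with 0-based row indices.
    bounds:
        ``(lb, ub)`` per reaction; ``±inf`` allowed.
    coupling:
        Optional list of ``(j, j_bio, c, eps)`` tuples adding the two rows
        ``v_j - c*v_bio <= eps`` and ``-v_j - c*v_bio <= eps``.
    """

    def __init__(
        self,
        n_metabolites: int,
        columns: Sequence[Sequence[Tuple[int, float]]],
        bounds: Sequence[Tuple[float, float]],
        coupling: Optional[Sequence[Tuple[int, int, float, float]]] = None,
    ) -> None:
        coupling = list(coupling or [])
        self.n_reactions = len(columns)
        self.n_metabolites = n_metabolites
        n_rows = n_metabolites + 2 * len(coupling)

        lp = glp.glp_create_prob()
        glp.glp_set_obj_dir(lp, glp.GLP_MAX)
        if n_rows:
            glp.glp_add_rows(lp, n_rows)
        glp.glp_add_cols(lp, self.n_reactions)
        for i in range(1, n_metabolites + 1):
            glp.glp_set_row_bnds(lp, i, glp.GLP_FX, 0.0, 0.0)

        entries: List[Tuple[int, int, float]] = []
        for j0, col in enumerate(columns):
            j = j0 + 1
            lb, ub = bounds[j0]
            if lb > ub:
                raise ValueError(f"reaction column {j0}: lb {lb} > ub {ub}")
            _set_col_bounds(lp, j, lb, ub)
            for i0, coef in col:
                if coef != 0.0:
                    entries.append((i0 + 1, j, float(coef)))

        row = n_metabolites
        for (j0, jb0, c, eps) in coupling:
            if c <= 0:
                raise ValueError("coupling factor must be positive")
            for sign in (1.0, -1.0):
                row += 1
                glp.glp_set_row_bnds(lp, row, glp.GLP_UP, 0.0, float(eps))
                entries.append((row, j0 + 1, sign))
                entries.append((row, jb0 + 1, -float(c)))

        nnz = len(entries)
        ia = glp.intArray(nnz + 1)
        ja = glp.intArray(nnz + 1)
        ar = glp.doubleArray(nnz + 1)
        for k, (i, j, a) in enumerate(entries, start=1):
            ia[k] = i
            ja[k] = j
            ar[k] = a
        glp.glp_load_matrix(lp, nnz, ia, ja, ar)

        parm = glp.glp_smcp()
        glp.glp_init_smcp(parm)
        parm.msg_lev = glp.GLP_MSG_OFF
        self._lp = lp
        self._parm = parm
        self._obj_j: Optional[int] = None
        self._basis_ready = False

    def __del__(self):  # pragma: no cover - finaliser
        try:
            glp.glp_delete_prob(self._lp)
        except Exception:
            pass

    # -- internal ---------------------------------------------------------

    def _set_objective(self, j0: int) -> None:
        j = j0 + 1
        if self._obj_j is not None and self._obj_j != j:
            glp.glp_set_obj_coef(self._lp, self._obj_j, 0.0)
        glp.glp_set_obj_coef(self._lp, j, 1.0)
        self._obj_j = j

    def _simplex(self) -> int:
        ret = glp.glp_simplex(self._lp, self._parm)
        status = glp.glp_get_status(self._lp)
        if ret != 0 or status == glp.GLP_UNDEF:
            # fall back to a fresh advanced basis; warm bases very rarely
            # go numerically stale over thousands of re-solves
            glp.glp_adv_basis(self._lp, 0)
            glp.glp_simplex(self._lp, self._parm)
            status = glp.glp_get_status(self._lp)
        return status

    def _solve(self, j0: int, maximise: bool) -> Tuple[Optional[float], str]:
        self._set_objective(j0)
        glp.glp_set_obj_dir(self._lp, glp.GLP_MAX if maximise else glp.GLP_MIN)
        if not self._basis_ready:
            glp.glp_adv_basis(self._lp, 0)
            self._basis_ready = True
        status = self._simplex()
        if status == glp.GLP_OPT:
            return glp.glp_get_obj_val(self._lp), LPStatus.OPTIMAL
        if status == glp.GLP_UNBND:
            return None, LPStatus.UNBOUNDED
        return None, LPStatus.INFEASIBLE

    # -- public -----------------------------------------------------------

    def set_bounds(self, j0: int, lb: float, ub: float) -> None:
        _set_col_bounds(self._lp, j0 + 1, lb, ub)

    def get_bounds(self, j0: int) -> Tuple[float, float]:
        lb = glp.glp_get_col_lb(self._lp, j0 + 1)
        ub = glp.glp_get_col_ub(self._lp, j0 + 1)
        typ = glp.glp_get_col_type(self._lp, j0 + 1)
        if typ in (glp.GLP_FR, glp.GLP_UP):
            lb = -np.inf
        if typ in (glp.GLP_FR, glp.GLP_LO):
            ub = np.inf
        return lb, ub

    def optimize(self, j0: int, maximise: bool = True) -> Tuple[Optional[float], str]:
        """Optimise flux of reaction ``j0``; returns ``(value, status)``."""
        return self._solve(j0, maximise)

    def fba(self, j0: int, maximise: bool = True) -> LPResult:
        """Optimise reaction ``j0`` and return the full flux vector."""
        value, status = self._solve(j0, maximise)
        if status != LPStatus.OPTIMAL:
            return LPResult(None, status)
        v = np.array(
            [glp.glp_get_col_prim(self._lp, j + 1) for j in range(self.n_reactions)]
        )
        return LPResult(value, status, v)

    def is_feasible(self) -> bool:
        # feasibility probe: maximise the constant-0 objective
        if self._obj_j is not None:
            glp.glp_set_obj_coef(self._lp, self._obj_j, 0.0)
            self._obj_j = None
        glp.glp_set_obj_dir(self._lp, glp.GLP_MAX)
        glp.glp_adv_basis(self._lp, 0)
        self._basis_ready = True
        status = self._simplex()
        return status in (glp.GLP_OPT, glp.GLP_FEAS)

    def flux_range(
        self, j0: int, cap: float = UNBOUNDED_CAP
    ) -> Tuple[float, float, str]:
        """Min and max flux of reaction ``j0``.

        Unbounded directions are replaced by ``∓/±cap`` and the range is
        flagged ``unbounded``; an infeasible programme yields
        ``(nan, nan, "infeasible")``.
        """
        vmin, smin = self._solve(j0, maximise=False)
        vmax, smax = self._solve(j0, maximise=True)
        if LPStatus.INFEASIBLE in (smin, smax):
            return np.nan, np.nan, LPStatus.INFEASIBLE
        status = LPStatus.OPTIMAL
        if smin == LPStatus.UNBOUNDED:
            vmin, status = -cap, LPStatus.UNBOUNDED
        if smax == LPStatus.UNBOUNDED:
            vmax, status = cap, LPStatus.UNBOUNDED
        return float(vmin), float(vmax), status
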