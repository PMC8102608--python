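"""Min/max exchange-flux profiling of community models.

For every dietary, faecal and strain-level exchange (transporter) reaction,
two LPs are solved — minimising and maximising that reaction's flux
subject to the full model constraints — the flux-variability profile that
defines a sample's metabolic potential:

* secretion potential of a metabolite = maximal faecal exchange flux,
* uptake potential = maximal diet exchange flux,
* a strain's contribution to a metabolite = maximal flux of its
  strain -> lumen transporter.

Raw potentials are reported; any netting of uptake against secretion is
left to downstream analyses.  Results are deterministic and independent of
worker count and reaction ordering: per-reaction LPs are independent
tasks, so any scheduling is allowed as long as each reaction's result is
bit-identical.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lp import LPStatus, StoichiometricLP, UNBOUNDED_CAP
from .community_builder import (
    COMMUNITY_BIOMASS_ID,
    CommunityModel,
    DIET_PREFIX,
    FAECAL_PREFIX,
)

__all__ = [
    "FluxRange",
    "MetaboliteProfile",
    "ContributionTable",
    "InfeasibleModelError",
    "compute_exchange_flux_ranges",
    "compute_metabolite_profile",
    "compute_strain_contributions",
    "default_profiled_reactions",
]


class InfeasibleModelError(RuntimeError):
    """The community LP admits no feasible flux vector.

    ``binding`` names the constraint class found responsible: ``"biomass
    bounds"`` if relaxing the community-biomass lower bound restores
    feasibility, else ``"diet"``.
    """

    def __init__(self, sample_id: str, binding: str):
        self.sample_id = sample_id
        self.binding = binding
        super().__init__(
            f"sample {sample_id}: model infeasible (binding constraint class: "
            f"{binding})"
        )


@dataclass(frozen=True)
class FluxRange:
    reaction_id: str
    min_flux: float
    max_flux: float
    status: str  # optimal | infeasible | unbounded

    def __post_init__(self):
        if self.status == LPStatus.OPTIMAL and not (
            self.min_flux <= self.max_flux + 1e-9
        ):
            raise ValueError(
                f"{self.reaction_id}: min {self.min_flux} > max {self.max_flux}"
            )


@dataclass
class MetaboliteProfile:
    """Per-sample secretion/uptake potentials and qualitative classes.

    ``table`` is indexed by metabolite id with columns
    ``secretion_potential``, ``uptake_potential`` and ``origin_class``
    (``microbial_only`` / ``dietary_only`` / ``both`` / ``neither``).
    """

    sample_id: str
    table: pd.DataFrame
    tolerance: float = 1e-6

    def secreted_metabolites(self, tau: Optional[float] = None) -> List[str]:
        tau = self.tolerance if tau is None else tau
        mask = self.table["secretion_potential"] > tau
        return list(self.table.index[mask])


@dataclass
class ContributionTable:
    """Strain × metabolite maximal secretion contributions (long format)."""

    records: pd.DataFrame  # columns: sample_id, strain_id, metabolite_id, contribution

    def to_wide(self) -> pd.DataFrame:
        """Samples × (strain, metabolite) wide matrix, absent keys = 0."""
        return self.records.pivot_table(
            index="sample_id",
            columns=["strain_id", "metabolite_id"],
            values="contribution",
            fill_value=0.0,
            aggfunc="sum",
        )


def default_profiled_reactions(model: CommunityModel) -> List[str]:
    """All dietary, faecal, and strain-level exchange reactions."""
    return (
        model.reaction_ids("diet")
        + model.reaction_ids("faecal")
        + model.reaction_ids("transporter")
    )


def _check_feasible(model: CommunityModel, lp: StoichiometricLP, order) -> None:
    if lp.is_feasible():
        return
    # diagnose: relax community biomass lower bound
    j = order.index(COMMUNITY_BIOMASS_ID)
    lb, ub = lp.get_bounds(j)
    lp.set_bounds(j, 0.0, ub)
    relaxed_ok = lp.is_feasible()
    lp.set_bounds(j, lb, ub)
    binding = "biomass bounds" if relaxed_ok else "diet"
    raise InfeasibleModelError(model.sample_id, binding)


def _ranges_serial(
    model: CommunityModel, reaction_ids: Sequence[str]
) -> List[FluxRange]:
    lp, order = model.build_lp()
    index = {r: j for j, r in enumerate(order)}
    for rid in reaction_ids:
        if rid not in index:
            raise KeyError(f"reaction {rid!r} absent from model")
    _check_feasible(model, lp, order)
    out = []
    for rid in reaction_ids:
        vmin, vmax, status = lp.flux_range(index[rid], cap=UNBOUNDED_CAP)
        # report at 1e-9 resolution (below LP tolerance) so results are
        # independent of solve order and worker count
        out.append(FluxRange(rid, round(vmin, 9), round(vmax, 9), status))
    return out


def _worker(args) -> List[Tuple[str, float, float, str]]:
    model, chunk = args
    return [
        (fr.reaction_id, fr.min_flux, fr.max_flux, fr.status)
        for fr in _ranges_serial(model, chunk)
    ]


def compute_exchange_flux_ranges(
    model: CommunityModel,
    reaction_ids: Optional[Sequence[str]] = None,
    workers: int = 1,
) -> List[FluxRange]:
    """Min/max flux for each requested reaction under all model constraints.

    ``reaction_ids`` defaults to every diet, faecal and transporter
    reaction.  Results are returned in request order and are identical for
    any ``workers`` count.  Unbounded maxima are capped at ``1e4`` and
    flagged; an infeasible model raises :class:`InfeasibleModelError`
    naming the binding constraint class.
    """
    if reaction_ids is None:
        reaction_ids = default_profiled_reactions(model)
    reaction_ids = list(reaction_ids)
    for rid in reaction_ids:
        if rid not in model.reactions:
            raise KeyError(f"reaction {rid!r} absent from model")
    if workers <= 1 or len(reaction_ids) < 2:
        return _ranges_serial(model, reaction_ids)
    chunks = [
        [str(r) for r in c]
        for c in np.array_split(reaction_ids, workers)
        if len(c)
    ]
    results: Dict[str, FluxRange] = {}
    with ProcessPoolExecutor(max_workers=workers) as pool:
        for part in pool.map(_worker, [(model, chunk) for chunk in chunks]):
            for rid, vmin, vmax, status in part:
                results[rid] = FluxRange(rid, vmin, vmax, status)
    return [results[rid] for rid in reaction_ids]


def compute_metabolite_profile(
    model: CommunityModel,
    ranges: Sequence[FluxRange],
    tau: float = 1e-6,
) -> MetaboliteProfile:
    """Classify each lumen metabolite from its diet/faecal flux ranges.

    secretion > tau and uptake <= tau  -> ``microbial_only``;
    secretion <= tau and uptake > tau  -> ``dietary_only``;
    both > tau -> ``both``; else ``neither``.
    """
    by_id = {fr.reaction_id: fr for fr in ranges}
    rows = []
    for met in model.lumen_metabolites:
        fid = model.faecal_exchange_id(met)
        did = model.diet_exchange_id(met)
        if fid not in by_id or did not in by_id:
            raise ValueError(
                f"sample {model.sample_id}: missing exchange pair for "
                f"lumen metabolite {met!r}"
            )
        secretion = max(0.0, by_id[fid].max_flux)
        uptake = max(0.0, by_id[did].max_flux)
        if secretion > tau and uptake <= tau:
            cls = "microbial_only"
        elif secretion <= tau and uptake > tau:
            cls = "dietary_only"
        elif secretion > tau and uptake > tau:
            cls = "both"
        else:
            cls = "neither"
        rows.append((met, secretion, uptake, cls))
    table = pd.DataFrame(
        rows,
        columns=["metabolite_id", "secretion_potential", "uptake_potential",
                 "origin_class"],
    ).set_index("metabolite_id")
    return MetaboliteProfile(model.sample_id, table, tolerance=tau)


def compute_strain_contributions(
    model: CommunityModel,
    ranges: Sequence[FluxRange],
    tau: float = 1e-6,
) -> ContributionTable:
    """One record per (strain, metabolite) with positive maximal export.

    The contribution is the maximal flux of the strain -> lumen
    transporter; under the secretion-positive convention it is clipped at
    zero, and pairs at or below ``tau`` yield no record.
    """
    by_id = {fr.reaction_id: fr for fr in ranges}
    rows = []
    for rid in model.reaction_ids("transporter"):
        if rid not in by_id:
            continue
        rxn = model.reactions[rid]
        contribution = max(0.0, by_id[rid].max_flux)
        if contribution > tau:
            rows.append(
                (model.sample_id, rxn.strain_id, rxn.metabolite_id, contribution)
            )
    records = pd.DataFrame(
        rows, columns=["sample_id", "strain_id", "metabolite_id", "contribution"]
    )
    return ContributionTable(records)
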