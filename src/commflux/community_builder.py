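"""Personalised, diet-constrained community model construction.

One community model per sample is assembled by compartment-tagging every
member strain's reactions, connecting each strain exchange to a shared
lumen through a transporter, adding diet (inflow) and faecal (outflow)
exchanges on the lumen, and formulating a community biomass reaction that
consumes each strain's biomass metabolite with a stoichiometric coefficient
equal to that strain's relative abundance.  Because each strain's biomass
metabolite is produced only by its own biomass reaction and consumed only
by the community biomass reaction, every feasible flux vector satisfies

    v_biomass,k = a_k * v_community_biomass          (exactly)

so all strains grow at the measured ratios.  The allowed flux through the
community biomass reaction defaults to [0.4, 1] mmol/person/day,
corresponding to faecal emptying between once every three days and once a
day.

Sign convention: diet exchanges flow *into* the lumen with non-negative
flux and faecal exchanges flow *out* of the lumen with non-negative flux,
so uptake and secretion never share a sign axis (this deviates from the
COBRA negative-uptake convention; the SBML export keeps the model's own
convention).

Optional coupling constraints tie every strain reaction to its host
strain's growth, |v| <= c * v_biomass,k + eps (c = 400, eps = 0.01 by
default), preventing strains from carrying flux without growing.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .lp import StoichiometricLP
from .model_io import (
    DietSpec,
    Reaction,
    StrainReconstruction,
    ValidationError,
)

__all__ = [
    "CommunityConfig",
    "CommunityReaction",
    "CommunityModel",
    "build_community_model",
    "apply_diet",
    "community_to_cobra",
    "COMMUNITY_BIOMASS_ID",
    "DIET_PREFIX",
    "FAECAL_PREFIX",
]

COMMUNITY_BIOMASS_ID = "communityBiomass"
DIET_PREFIX = "DIET_EX_"
FAECAL_PREFIX = "FAECAL_EX_"
LUMEN = "lumen"


@dataclass
class CommunityConfig:
    """Construction and simulation settings for community models."""

    biomass_lb: float = 0.4  # mmol/person/day
    biomass_ub: float = 1.0
    coupling_enabled: bool = True
    coupling_factor: float = 400.0
    coupling_relax: float = 0.01
    diet_scale: float = 1.0  # conversion multiplier on DietSpec amounts
    host_bound: float = 10.0  # default uptake bound for host metabolites

    def validate(self) -> None:
        if not 0 <= self.biomass_lb <= self.biomass_ub:
            raise ValidationError("need 0 <= biomass_lb <= biomass_ub")
        if self.coupling_factor <= 0 or self.coupling_relax < 0:
            raise ValidationError("coupling_factor > 0 and coupling_relax >= 0")
        if self.diet_scale <= 0:
            raise ValidationError("diet_scale must be positive")


@dataclass
class CommunityReaction:
    """A reaction of the community model.

    ``kind`` is one of ``strain`` (compartment-tagged strain reaction),
    ``biomass`` (a strain biomass reaction), ``transporter``
    (strain <-> lumen), ``diet``, ``faecal`` or ``community_biomass``.
    ``strain_id`` is set for all strain-owned kinds.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float
    upper_bound: float
    kind: str
    strain_id: Optional[str] = None
    metabolite_id: Optional[str] = None  # lumen metabolite for exchanges


@dataclass
class CommunityModel:
    """A per-sample multi-compartment model with a shared lumen."""

    sample_id: str
    members: List[Tuple[str, float]]  # (strain_id, relative abundance)
    metabolite_ids: List[str]
    reactions: Dict[str, CommunityReaction]
    objective_id: str = COMMUNITY_BIOMASS_ID
    config: CommunityConfig = field(default_factory=CommunityConfig)
    lumen_metabolites: List[str] = field(default_factory=list)

    def reaction_ids(self, kind: Optional[str] = None) -> List[str]:
        if kind is None:
            return list(self.reactions)
        return [r.id for r in self.reactions.values() if r.kind == kind]

    @property
    def abundances(self) -> Dict[str, float]:
        return dict(self.members)

    def diet_exchange_id(self, met: str) -> str:
        return f"{DIET_PREFIX}{met}"

    def faecal_exchange_id(self, met: str) -> str:
        return f"{FAECAL_PREFIX}{met}"

    def transporter_id(self, strain_id: str, met: str) -> str:
        return f"TR_{strain_id}_{met}"

    def biomass_reaction_id(self, strain_id: str) -> str:
        return f"{strain_id}__BIOMASS"

    # -- LP construction --------------------------------------------------

    def build_lp(self) -> Tuple[StoichiometricLP, List[str]]:
        """Assemble the steady-state LP; returns ``(lp, reaction_order)``."""
        met_index = {m: i for i, m in enumerate(self.metabolite_ids)}
        order = list(self.reactions)
        ridx = {r: j for j, r in enumerate(order)}
        columns = []
        bounds = []
        for rid in order:
            rxn = self.reactions[rid]
            columns.append(
                [(met_index[m], c) for m, c in rxn.stoichiometry.items()]
            )
            bounds.append((rxn.lower_bound, rxn.upper_bound))
        coupling = []
        if self.config.coupling_enabled:
            c = self.config.coupling_factor
            eps = self.config.coupling_relax
            for rid in order:
                rxn = self.reactions[rid]
                if rxn.strain_id is not None and rxn.kind != "biomass":
                    jb = ridx[self.biomass_reaction_id(rxn.strain_id)]
                    coupling.append((ridx[rid], jb, c, eps))
        lp = StoichiometricLP(len(met_index), columns, bounds, coupling)
        return lp, order

    def validate(self) -> None:
        n_cb = sum(
            1 for r in self.reactions.values() if r.kind == "community_biomass"
        )
        if n_cb != 1:
            raise ValidationError("exactly one community biomass reaction required")
        total = sum(a for _, a in self.members)
        if abs(total - 1.0) > 1e-8:
            raise ValidationError(f"abundances sum to {total}, expected 1")
        mets = set(self.metabolite_ids)
        for rxn in self.reactions.values():
            for m in rxn.stoichiometry:
                if m not in mets:
                    raise ValidationError(
                        f"reaction {rxn.id} references unknown metabolite {m}"
                    )
        for m in self.lumen_metabolites:
            if self.faecal_exchange_id(m) not in self.reactions:
                raise ValidationError(f"missing faecal exchange for {m}")


def _cmet(met: str, compartment: str) -> str:
    return f"{met}[{compartment}]"


def build_community_model(
    strains: Mapping[str, StrainReconstruction],
    abundances: Mapping[str, float],
    config: Optional[CommunityConfig] = None,
    sample_id: str = "sample",
) -> CommunityModel:
    """Join member strains into one community model for a sample.

    ``abundances`` maps strain ids (with non-zero relative abundance) to
    values summing to one.  Strain exchange bounds carry over to the
    corresponding strain <-> lumen transporters unchanged.  Diet exchanges
    are created closed ([0, 0]) for every lumen metabolite and opened by
    :func:`apply_diet`; faecal exchanges are irreversible outflows.
    """
    config = config or CommunityConfig()
    config.validate()
    members = [(k, float(a)) for k, a in abundances.items() if a > 0]
    if not members:
        raise ValidationError(f"sample {sample_id}: no strains with abundance > 0")
    total = sum(a for _, a in members)
    if abs(total - 1.0) > 1e-8:
        raise ValidationError(
            f"sample {sample_id}: abundances sum to {total:.10f}, expected 1"
        )
    for sid, _ in members:
        if sid not in strains:
            raise ValidationError(f"unknown strain id {sid!r}")
    seen = set()
    for sid, _ in members:
        if sid in seen:
            raise ValidationError(f"duplicate strain {sid!r} in sample")
        seen.add(sid)

    metabolite_ids: List[str] = []
    reactions: Dict[str, CommunityReaction] = {}
    lumen: List[str] = []
    lumen_seen = set()

    def add_met(mid: str) -> str:
        if mid not in met_seen:
            met_seen.add(mid)
            metabolite_ids.append(mid)
        return mid

    met_seen: set = set()

    biomass_stoich: Dict[str, float] = {}
    for sid, a in members:
        strain = strains[sid]
        comp = f"{sid}__c"
        exchanges = set(strain.exchange_reaction_ids)
        biomass_met = None
        # locate the biomass metabolite: the product of the biomass reaction
        bio = strain.reactions[strain.biomass_reaction_id]
        products = [m for m, c in bio.stoichiometry.items() if c > 0]
        if len(products) != 1:
            raise ValidationError(
                f"strain {sid}: biomass reaction must produce exactly one "
                f"biomass metabolite, got {products}"
            )
        biomass_met = products[0]

        for rid, rxn in strain.reactions.items():
            if rid in exchanges:
                met = strain.exchanged_metabolite(rid)
                if met == biomass_met:
                    continue  # community biomass replaces the biomass sink
                cin = add_met(_cmet(met, comp))
                cout = add_met(_cmet(met, LUMEN))
                if met not in lumen_seen:
                    lumen_seen.add(met)
                    lumen.append(met)
                # exchange stoich {met: -1}: positive flux exports to lumen
                coef = rxn.stoichiometry[met]
                tid = f"TR_{sid}_{met}"
                reactions[tid] = CommunityReaction(
                    id=tid,
                    stoichiometry={cin: coef, cout: -coef},
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                    kind="transporter",
                    strain_id=sid,
                    metabolite_id=met,
                )
            else:
                tagged = {
                    add_met(_cmet(m, comp)): c
                    for m, c in rxn.stoichiometry.items()
                }
                rid_tagged = f"{sid}__{rid}"
                kind = (
                    "biomass" if rid == strain.biomass_reaction_id else "strain"
                )
                if kind == "biomass":
                    rid_tagged = f"{sid}__BIOMASS"
                reactions[rid_tagged] = CommunityReaction(
                    id=rid_tagged,
                    stoichiometry=tagged,
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                    kind=kind,
                    strain_id=sid,
                )
        biomass_stoich[_cmet(biomass_met, comp)] = -a

    for met in lumen:
        cmid = _cmet(met, LUMEN)
        reactions[f"{DIET_PREFIX}{met}"] = CommunityReaction(
            id=f"{DIET_PREFIX}{met}",
            stoichiometry={cmid: 1.0},
            lower_bound=0.0,
            upper_bound=0.0,  # closed until apply_diet
            kind="diet",
            metabolite_id=met,
        )
        reactions[f"{FAECAL_PREFIX}{met}"] = CommunityReaction(
            id=f"{FAECAL_PREFIX}{met}",
            stoichiometry={cmid: -1.0},
            lower_bound=0.0,
            upper_bound=np.inf,
            kind="faecal",
            metabolite_id=met,
        )

    reactions[COMMUNITY_BIOMASS_ID] = CommunityReaction(
        id=COMMUNITY_BIOMASS_ID,
        stoichiometry=biomass_stoich,
        lower_bound=config.biomass_lb,
        upper_bound=config.biomass_ub,
        kind="community_biomass",
    )

    model = CommunityModel(
        sample_id=sample_id,
        members=members,
        metabolite_ids=metabolite_ids,
        reactions=reactions,
        config=config,
        lumen_metabolites=lumen,
    )
    model.validate()
    return model


def apply_diet(
    model: CommunityModel,
    diet: DietSpec,
    config: Optional[CommunityConfig] = None,
) -> CommunityModel:
    """Constrain a community model's boundary with a diet.

    Diet exchange upper bounds are set to ``diet_scale * amount``; host
    metabolites are opened at ``config.host_bound``; every other diet
    exchange is closed.  Community biomass bounds are (re)set to
    ``[biomass_lb, biomass_ub]``.  Diet metabolites absent from the lumen
    are logged as warnings, not errors.  Returns a new model.
    """
    config = config or model.config
    config.validate()
    diet.validate()
    model = copy.deepcopy(model)
    model.config = config
    lumen = set(model.lumen_metabolites)
    opened = {}
    for met, amount in diet.uptake_limits.items():
        if met not in lumen:
            warnings.warn(
                f"diet metabolite {met!r} absent from lumen of sample "
                f"{model.sample_id}; ignored"
            )
            continue
        opened[met] = config.diet_scale * amount
    for met in diet.host_metabolites:
        if met not in lumen:
            warnings.warn(
                f"host metabolite {met!r} absent from lumen of sample "
                f"{model.sample_id}; ignored"
            )
            continue
        opened[met] = max(opened.get(met, 0.0), config.host_bound)
    for met in model.lumen_metabolites:
        rxn = model.reactions[model.diet_exchange_id(met)]
        rxn.lower_bound = 0.0
        rxn.upper_bound = opened.get(met, 0.0)
    cb = model.reactions[COMMUNITY_BIOMASS_ID]
    cb.lower_bound = config.biomass_lb
    cb.upper_bound = config.biomass_ub
    return model


def community_to_cobra(model: CommunityModel):
    """Export a community model as a cobra model (for SBML interchange)."""
    import cobra

    cm = cobra.Model(model.sample_id)
    mets = {}
    for mid in model.metabolite_ids:
        base, comp = mid.rsplit("[", 1)
        comp = comp.rstrip("]")
        m = cobra.Metabolite(mid.replace("[", "__").rstrip("]"), compartment=comp)
        mets[mid] = m
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for rxn in model.reactions.values():
        r = cobra.Reaction(rxn.id)
        r.lower_bound = rxn.lower_bound
        r.upper_bound = min(rxn.upper_bound, 1e6)  # SBML needs finite bounds
        rxns.append(r)
    cm.add_reactions(rxns)
    for rxn in model.reactions.values():
        cm.reactions.get_by_id(rxn.id).add_metabolites(
            {mets[m]: c for m, c in rxn.stoichiometry.items()}
        )
    cm.objective = model.objective_id
    return cm
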