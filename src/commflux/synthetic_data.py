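"""Synthetic pan-reactome, strains, diets and three-group cohorts.

The generator emulates the statistical structure the downstream analysis
assumes about real gut metagenomes mapped to strain reconstructions:

* a pan-reactome with subsystem structure (fermentation, amino-acid
  biosynthesis, B-vitamin biosynthesis, sulfur metabolism, host-glycan
  degradation) and a sulfur family of >= 11 distinct species;
* strain repertoires nested in a taxonomy, with phylum-level trait
  profiles (Bacteroidetes carry host-glycan degradation, Proteobacteria
  are amino-acid- and sulfur-reduction-heavy, Firmicutes ferment,
  Actinobacteria synthesise B-vitamins);
* three-group cohorts (healthy / IBD_nondysbiotic / IBD_dysbiotic) in
  which the dysbiotic group has reduced strain richness, Proteobacteria
  enrichment, Bacteroidetes depletion, and depleted glycan degraders.

The sulfur sub-network is built so that sulfate and its derivatives
(sulfite, thiosulfate, isethionate) can only enter a community through the
degradation of host glycans (chondroitin sulfate, heparan sulfate): the
presence of a glycan-degrading strain therefore gates part of the
community's sulfur secretion repertoire, which is the causal structure the
mediation analysis downstream is meant to detect.  All non-exchange,
non-biomass reactions conserve sulfur atoms exactly.

Everything is deterministic given the seed and is written through
``model_io`` writers, so downstream stages cannot distinguish synthetic
from real inputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model_io import (
    GROUPS,
    AbundanceTable,
    DietSpec,
    Metabolite,
    Reaction,
    StrainReconstruction,
    Taxonomy,
    ValidationError,
)

__all__ = [
    "PanReactome",
    "CohortDesign",
    "generate_pan_reactome",
    "generate_strain_set",
    "generate_cohort",
    "generate_metabolomic_reference",
    "default_diet",
    "cross_feeding_pair",
    "is_glycan_degrader",
    "GLYCAN_DEGRADATION_IDS",
]

# ---------------------------------------------------------------------------
# pan-reactome backbone
# ---------------------------------------------------------------------------

# (id, name, formula) — formulas are real where a real species exists;
# only sulfur counts are load-bearing (sulfur-atom conservation is checked).
_CORE_METS = [
    ("glc_D", "D-glucose", "C6H12O6"),
    ("nh4", "ammonium", "H4N"),
    ("pi", "phosphate", "HO4P"),
    ("h2o", "water", "H2O"),
    ("h", "proton", "H"),
    ("pyr", "pyruvate", "C3H3O3"),
    ("co2", "carbon dioxide", "CO2"),
    ("biomass", "biomass", ""),
]

_FERMENTATION_METS = [
    ("lac_L", "L-lactate", "C3H5O3"),
    ("but", "butyrate", "C4H7O2"),
    ("ac", "acetate", "C2H3O2"),
    ("ppa", "propionate", "C3H5O2"),
    ("etoh", "ethanol", "C2H6O"),
    ("for", "formate", "CHO2"),
    ("succ", "succinate", "C4H4O4"),
]

# 18 sulfur-free proteinogenic amino acids (cysteine and methionine live in
# the sulfur family below).
_AA_METS = [
    ("ala_L", "L-alanine", "C3H7NO2"),
    ("arg_L", "L-arginine", "C6H15N4O2"),
    ("asn_L", "L-asparagine", "C4H8N2O3"),
    ("asp_L", "L-aspartate", "C4H6NO4"),
    ("gln_L", "L-glutamine", "C5H10N2O3"),
    ("glu_L", "L-glutamate", "C5H8NO4"),
    ("gly", "glycine", "C2H5NO2"),
    ("his_L", "L-histidine", "C6H9N3O2"),
    ("ile_L", "L-isoleucine", "C6H13NO2"),
    ("leu_L", "L-leucine", "C6H13NO2"),
    ("lys_L", "L-lysine", "C6H15N2O2"),
    ("phe_L", "L-phenylalanine", "C9H11NO2"),
    ("pro_L", "L-proline", "C5H9NO2"),
    ("ser_L", "L-serine", "C3H7NO3"),
    ("thr_L", "L-threonine", "C4H9NO3"),
    ("trp_L", "L-tryptophan", "C11H12N2O2"),
    ("tyr_L", "L-tyrosine", "C9H11NO3"),
    ("val_L", "L-valine", "C5H11NO2"),
]

_SULFUR_METS = [
    ("cys_L", "L-cysteine", "C3H7NO2S"),
    ("met_L", "L-methionine", "C5H11NO2S"),
    ("taur", "taurine", "C2H7NO3S"),
    ("h2s", "hydrogen sulfide", "H2S"),
    ("so4", "sulfate", "O4S"),
    ("so3", "sulfite", "O3S"),
    ("tsul", "thiosulfate", "O3S2"),
    ("ch4s", "methanethiol", "CH4S"),
    ("dms", "dimethyl sulfide", "C2H6S"),
    ("gthrd", "reduced glutathione", "C10H17N3O6S"),
    ("cyst_L", "L-cystathionine", "C7H14N2O4S"),
    ("isetac", "isethionate", "C2H5O4S"),
]

_GLYCAN_METS = [
    ("cspg", "chondroitin sulfate", "C14H21NO14S"),
    ("hspg", "heparan sulfate", "C12H19NO13S"),
    ("glyc1", "chondroitin disaccharide", "C14H21NO11"),
    ("glyc2", "heparan disaccharide", "C12H19NO10"),
]

# thiamine and biotin genuinely contain sulfur; their synthesis consumes
# cysteine so that sulfur atoms balance.
_BVIT_METS = [
    ("ribflv", "riboflavin", "C17H20N4O6"),
    ("ncam", "nicotinamide", "C6H6N2O"),
    ("thm", "thiamine", "C12H17N4OS"),
    ("pnto_R", "pantothenate", "C9H16NO5"),
    ("btn", "biotin", "C10H16N2O3S"),
    ("fol", "folate", "C19H19N7O6"),
]

#: Reactions whose presence makes a strain a host-glycan degrader.
GLYCAN_DEGRADATION_IDS = ("CSPGDEG", "HSPGDEG")

# internal (non-exchange) reactions: id -> (stoichiometry, subsystem)
_INTERNAL_RXNS: Dict[str, Tuple[Dict[str, float], str]] = {
    "GLYCOLYSIS": ({"glc_D": -1, "pyr": 2}, "Core"),
    "BIOMASS": (
        {"glc_D": -0.5, "nh4": -0.3, "pi": -0.1, "pyr": -0.2, "biomass": 1},
        "Core",
    ),
    # fermentation
    "LACF": ({"pyr": -1, "lac_L": 1}, "Fermentation"),
    "BUTF": ({"pyr": -2, "but": 1, "co2": 1}, "Fermentation"),
    "ACF": ({"pyr": -1, "ac": 1, "co2": 1}, "Fermentation"),
    "PPAF": ({"pyr": -1, "ppa": 1}, "Fermentation"),
    "ETOHF": ({"pyr": -1, "etoh": 1, "co2": 1}, "Fermentation"),
    "FORF": ({"pyr": -1, "for": 1, "ac": 1}, "Fermentation"),
    "SUCCF": ({"pyr": -1, "co2": -1, "succ": 1}, "Fermentation"),
    # sulfur metabolism (S atoms conserved in every reaction)
    "CYSDS": ({"cys_L": -1, "h2s": 1, "pyr": 1, "nh4": 1}, "Sulfur metabolism"),
    "METGL": ({"met_L": -1, "ch4s": 1, "nh4": 1}, "Sulfur metabolism"),
    "DMSSYN": ({"ch4s": -2, "dms": 1, "h2s": 1}, "Sulfur metabolism"),
    "TAURSYN": ({"cys_L": -1, "h2o": -1, "taur": 1, "co2": 1}, "Sulfur metabolism"),
    "SO4RED": ({"so4": -1, "h": -2, "so3": 1, "h2o": 1}, "Sulfur metabolism"),
    "SO3RED": ({"so3": -1, "h": -6, "h2s": 1, "h2o": 3}, "Sulfur metabolism"),
    "TSULSYN": ({"so3": -1, "h2s": -1, "tsul": 1, "h2o": 1}, "Sulfur metabolism"),
    "CYSSYN": ({"so4": -1, "pyr": -1, "nh4": -1, "cys_L": 1, "h2o": 2}, "Sulfur metabolism"),
    "CYSTSYN": ({"cys_L": -1, "pyr": -1, "nh4": -1, "cyst_L": 1}, "Sulfur metabolism"),
    "METSYN": ({"cyst_L": -1, "met_L": 1, "pyr": 1}, "Sulfur metabolism"),
    "GSHSYN": ({"cys_L": -1, "glu_L": -1, "gly": -1, "gthrd": 1}, "Sulfur metabolism"),
    "ISESYN": ({"so3": -1, "pyr": -1, "isetac": 1, "co2": 1}, "Sulfur metabolism"),
    # host-glycan degradation releases sulfate plus a fermentable sugar
    "CSPGDEG": ({"cspg": -1, "h2o": -1, "so4": 1, "glyc1": 1, "h": 1}, "Glycan degradation"),
    "HSPGDEG": ({"hspg": -1, "h2o": -1, "so4": 1, "glyc2": 1, "h": 1}, "Glycan degradation"),
    "GLYC1CAT": ({"glyc1": -1, "pyr": 3, "co2": 2}, "Glycan degradation"),
    "GLYC2CAT": ({"glyc2": -1, "pyr": 3, "co2": 1}, "Glycan degradation"),
}
for _aa, _, _ in _AA_METS:
    _INTERNAL_RXNS[f"AASYN_{_aa}"] = (
        {"pyr": -1, "nh4": -1, _aa: 1},
        "Amino acid biosynthesis",
    )
for _v, _, _ in _BVIT_METS:
    stoich = {"glc_D": -1, _v: 1}
    if _v in ("thm", "btn"):  # sulfur-containing vitamins draw on cysteine
        stoich["cys_L"] = -1
    _INTERNAL_RXNS[f"BVSYN_{_v}"] = (stoich, "B-vitamin biosynthesis")

#: Reactions every strain carries (plus the core uptake exchanges).
_CORE_RXN_IDS = ("GLYCOLYSIS", "BIOMASS")
_CORE_EX_METS = ("glc_D", "nh4", "pi", "h2o", "h", "co2", "pyr", "biomass")


@dataclass
class PanReactome:
    """Universe of metabolites and reactions strains are sampled from."""

    metabolites: Dict[str, Metabolite]
    reactions: Dict[str, Reaction]
    core_reaction_ids: List[str]
    host_glycans: Tuple[str, ...] = ("cspg", "hspg")

    @property
    def sulfur_metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites.values() if m.is_sulfur]

    @property
    def internal_reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions.values() if not r.is_exchange]

    def exchange_id(self, met_id: str) -> str:
        return f"EX_{met_id}"

    def stable_hash(self) -> str:
        payload = {
            "metabolites": [
                (m.id, m.name, m.formula) for m in self.metabolites.values()
            ],
            "reactions": [
                (r.id, sorted(r.stoichiometry.items()), r.lower_bound,
                 r.upper_bound, r.subsystem)
                for r in self.reactions.values()
            ],
            "core": self.core_reaction_ids,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


def _exchange(met_id: str) -> Reaction:
    return Reaction(
        id=f"EX_{met_id}",
        stoichiometry={met_id: -1.0},
        lower_bound=-1000.0,
        upper_bound=1000.0,
        subsystem="Exchange",
    )


def generate_pan_reactome(
    n_metabolites: int = 64, n_reactions: int = 140, seed: int = 0
) -> PanReactome:
    """Build the pan-reactome: curated backbone plus generic filler.

    The backbone (55 metabolites, 104 reactions) hosts the mandatory
    pathways; requested sizes below the backbone raise.  Filler metabolites
    ``gmet_XX`` with generic synthesis/catabolism reactions pad the universe
    to the requested size, deterministically given ``seed``.
    """
    backbone_mets = (
        _CORE_METS + _FERMENTATION_METS + _AA_METS + _SULFUR_METS
        + _GLYCAN_METS + _BVIT_METS
    )
    metabolites = {mid: Metabolite(mid, name, formula) for mid, name, formula in backbone_mets}
    reactions: Dict[str, Reaction] = {}
    for rid, (stoich, subsystem) in _INTERNAL_RXNS.items():
        lb = 0.0
        reactions[rid] = Reaction(rid, dict(stoich), lb, 1000.0, subsystem)
    for mid in metabolites:
        reactions[f"EX_{mid}"] = _exchange(mid)

    n_backbone_m, n_backbone_r = len(metabolites), len(reactions)
    if n_metabolites < n_backbone_m or n_reactions < n_backbone_r:
        raise ValueError(
            f"pan-reactome needs >= {n_backbone_m} metabolites and "
            f">= {n_backbone_r} reactions to host the mandatory pathways"
        )

    rng = np.random.default_rng(seed)
    fillers = []
    for i in range(n_metabolites - n_backbone_m):
        mid = f"gmet{i:02d}"
        c = int(rng.integers(4, 12))
        h = int(rng.integers(c, 2 * c + 2))
        o = int(rng.integers(1, 7))
        metabolites[mid] = Metabolite(mid, f"generic metabolite {i}", f"C{c}H{h}O{o}")
        fillers.append(mid)
        reactions[f"GENSYN_{mid}"] = Reaction(
            f"GENSYN_{mid}", {"glc_D": -1.0, mid: 1.0}, 0.0, 1000.0,
            "Generic metabolism",
        )
        reactions[f"EX_{mid}"] = _exchange(mid)
    # extra generic reactions (catabolic and alternative routes) up to size
    extra = 0
    while len(reactions) < n_reactions:
        if not fillers:
            raise ValueError(
                "cannot reach requested reaction count without filler metabolites"
            )
        mid = fillers[extra % len(fillers)]
        if extra < len(fillers):
            rid, stoich = f"GENCAT_{mid}", {mid: -1.0, "pyr": 2.0}
        else:
            rid, stoich = f"GENALT{extra}_{mid}", {"pyr": -2.0, mid: 1.0}
        reactions[rid] = Reaction(rid, stoich, 0.0, 1000.0, "Generic metabolism")
        extra += 1

    core = list(_CORE_RXN_IDS) + [f"EX_{m}" for m in _CORE_EX_METS]
    pan = PanReactome(metabolites, reactions, core)
    assert len(pan.sulfur_metabolite_ids) >= 11
    return pan


def sulfur_imbalance(pan: PanReactome, reaction: Reaction) -> float:
    """Net sulfur atoms produced by a reaction (0 for balanced)."""
    from .model_io import parse_formula

    total = 0.0
    for met_id, coef in reaction.stoichiometry.items():
        counts = parse_formula(pan.metabolites[met_id].formula)
        total += coef * counts.get("S", 0)
    return total


# ---------------------------------------------------------------------------
# strains
# ---------------------------------------------------------------------------

_PHYLA = ("Bacteroidetes", "Firmicutes", "Proteobacteria", "Actinobacteria")
_DEFAULT_TAXONOMY_SHAPE = {
    "Bacteroidetes": 0.30,
    "Firmicutes": 0.40,
    "Proteobacteria": 0.20,
    "Actinobacteria": 0.10,
}
_CLASS_OF = {
    "Bacteroidetes": "Bacteroidia",
    "Firmicutes": "Clostridia",
    "Proteobacteria": "Gammaproteobacteria",
    "Actinobacteria": "Actinomycetia",
}

# per-phylum probability that a strain carries a reaction of a given
# subsystem (individual reactions are sampled independently)
_TRAIT_PROFILES: Dict[str, Dict[str, float]] = {
    "Bacteroidetes": {
        "Fermentation": 0.55,
        "Amino acid biosynthesis": 0.40,
        "B-vitamin biosynthesis": 0.35,
        "Sulfur metabolism": 0.35,
        "Glycan degradation": 0.80,
        "Generic metabolism": 0.30,
    },
    "Firmicutes": {
        "Fermentation": 0.85,
        "Amino acid biosynthesis": 0.30,
        "B-vitamin biosynthesis": 0.45,
        "Sulfur metabolism": 0.30,
        "Glycan degradation": 0.08,
        "Generic metabolism": 0.30,
    },
    "Proteobacteria": {
        "Fermentation": 0.45,
        "Amino acid biosynthesis": 0.80,
        "B-vitamin biosynthesis": 0.30,
        "Sulfur metabolism": 0.70,
        "Glycan degradation": 0.02,
        "Generic metabolism": 0.30,
    },
    "Actinobacteria": {
        "Fermentation": 0.40,
        "Amino acid biosynthesis": 0.35,
        "B-vitamin biosynthesis": 0.80,
        "Sulfur metabolism": 0.25,
        "Glycan degradation": 0.05,
        "Generic metabolism": 0.30,
    },
}


def is_glycan_degrader(strain: StrainReconstruction) -> bool:
    """A strain is a glycan degrader iff it carries a chondroitin/heparan
    degradation reaction."""
    return any(rid in strain.reactions for rid in GLYCAN_DEGRADATION_IDS)


def _build_strain(
    pan: PanReactome,
    strain_id: str,
    taxonomy: Taxonomy,
    internal_ids: Iterable[str],
) -> StrainReconstruction:
    internal = set(internal_ids) | set(_CORE_RXN_IDS)
    touched = set()
    reactions: Dict[str, Reaction] = {}
    for rid in sorted(internal):
        rxn = pan.reactions[rid]
        reactions[rid] = Reaction(
            rxn.id, dict(rxn.stoichiometry), rxn.lower_bound, rxn.upper_bound,
            rxn.subsystem,
        )
        touched.update(rxn.stoichiometry)
    for mid in sorted(touched):
        ex = pan.reactions[pan.exchange_id(mid)]
        reactions[ex.id] = Reaction(
            ex.id, dict(ex.stoichiometry), ex.lower_bound, ex.upper_bound,
            ex.subsystem,
        )
    metabolites = {mid: pan.metabolites[mid] for mid in sorted(touched)}
    return StrainReconstruction(
        strain_id=strain_id,
        taxonomy=taxonomy,
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id="BIOMASS",
    )


def generate_strain_set(
    pan: PanReactome,
    n_strains: int = 40,
    taxonomy_shape: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    max_attempts: int = 100,
) -> List[StrainReconstruction]:
    """Sample strains as core reactions plus a phylum-biased repertoire.

    Each strain's biomass is verified feasible by LP with all exchanges
    open; an infeasible strain is resampled (at most ``max_attempts``
    times — with this backbone the core alone guarantees growth, so
    resampling is a safety net, not an expected path).  The set is
    guaranteed to contain at least one glycan degrader and one complete
    sulfate-reducer (both forced into a suitable phylum if sampling missed
    them).
    """
    if n_strains < 10:
        raise ValueError("n_strains must be >= 10")
    shape = dict(taxonomy_shape or _DEFAULT_TAXONOMY_SHAPE)
    phyla = sorted(shape)
    probs = np.array([shape[p] for p in phyla], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)

    by_subsystem: Dict[str, List[str]] = {}
    for rid in sorted(pan.internal_reaction_ids):
        if rid in _CORE_RXN_IDS:
            continue
        by_subsystem.setdefault(pan.reactions[rid].subsystem, []).append(rid)

    strains: List[StrainReconstruction] = []
    counts = rng.multinomial(n_strains, probs)
    idx = 0
    for phylum, count in zip(phyla, counts):
        profile = _TRAIT_PROFILES.get(phylum, _TRAIT_PROFILES["Firmicutes"])
        n_genera = max(1, count // 3)
        for i in range(count):
            idx += 1
            genus = f"{phylum[:4]}_gen{i % n_genera + 1}"
            taxonomy = Taxonomy(
                phylum=phylum,
                class_=_CLASS_OF.get(phylum, f"{phylum}_cls"),
                order=f"{phylum[:4]}ales",
                family=f"{phylum[:4]}aceae",
                genus=genus,
                species=f"{genus}_sp{i + 1}",
                strain=f"S{idx:03d}",
            )
            for attempt in range(max_attempts):
                chosen: List[str] = []
                for subsystem, rids in by_subsystem.items():
                    p = profile.get(subsystem, 0.2)
                    mask = rng.random(len(rids)) < p
                    chosen.extend(r for r, m in zip(rids, mask) if m)
                strain = _build_strain(pan, f"S{idx:03d}", taxonomy, chosen)
                if strain.max_biomass_open_exchanges() > 1e-6:
                    break
            else:
                raise ValidationError(
                    f"strain {idx} infeasible after {max_attempts} attempts"
                )
            strains.append(strain)

    def _force(reaction_ids: Sequence[str], phylum: str) -> None:
        candidates = [s for s in strains if s.taxonomy.phylum == phylum] or strains
        target = candidates[0]
        extra = set(target.reactions) | set(reaction_ids)
        rebuilt = _build_strain(
            pan, target.strain_id, target.taxonomy,
            [r for r in extra if not pan.reactions[r].is_exchange],
        )
        strains[strains.index(target)] = rebuilt

    if not any(is_glycan_degrader(s) for s in strains):
        _force(list(GLYCAN_DEGRADATION_IDS) + ["GLYC1CAT", "GLYC2CAT"], "Bacteroidetes")
    if not any({"SO4RED", "SO3RED"} <= set(s.reactions) for s in strains):
        _force(["SO4RED", "SO3RED"], "Proteobacteria")
    return strains


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortDesign:
    """Parameters of the synthetic three-group cohort generator.

    Defaults mirror the modelled study conditions: 25 healthy, 63
    non-dysbiotic and 20 dysbiotic samples, with the dysbiotic group at
    reduced strain richness, Proteobacteria enrichment, Bacteroidetes
    depletion, and depleted glycan degraders.
    """

    n_per_group: Dict[str, int] = field(
        default_factory=lambda: {
            "healthy": 25,
            "IBD_nondysbiotic": 63,
            "IBD_dysbiotic": 20,
        }
    )
    richness_mean: Dict[str, float] = field(
        default_factory=lambda: {
            "healthy": 16.0,
            "IBD_nondysbiotic": 12.0,
            "IBD_dysbiotic": 6.0,
        }
    )
    phylum_bias: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "healthy": {},
            "IBD_nondysbiotic": {"Proteobacteria": 1.5, "Bacteroidetes": 0.8},
            "IBD_dysbiotic": {"Proteobacteria": 4.0, "Bacteroidetes": 0.25},
        }
    )
    glycan_degrader_prob: Dict[str, float] = field(
        default_factory=lambda: {
            "healthy": 0.90,
            "IBD_nondysbiotic": 0.60,
            "IBD_dysbiotic": 0.15,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        for g in GROUPS:
            if self.n_per_group.get(g, 0) < 2:
                raise ValidationError(f"need >= 2 samples in group {g}")
            p = self.glycan_degrader_prob.get(g, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ValidationError("glycan_degrader_prob must be in [0, 1]")
        if (
            self.richness_mean["IBD_dysbiotic"]
            >= self.richness_mean["healthy"]
        ):
            raise ValidationError(
                "default design requires dysbiotic richness below healthy"
            )


_GROUP_PREFIX = {"healthy": "H", "IBD_nondysbiotic": "N", "IBD_dysbiotic": "D"}


def generate_cohort(
    strains: Sequence[StrainReconstruction], design: CohortDesign
) -> AbundanceTable:
    """Draw a three-group cohort of compositional samples.

    Per sample: richness is Poisson around the group mean (minimum 2),
    strains are sampled without replacement with phylum-biased weights,
    abundances are Dirichlet(1) over the chosen strains, and
    glycan-degrader membership is forced or suppressed according to the
    group's ``glycan_degrader_prob``.  Deterministic given ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    strain_ids = [s.strain_id for s in strains]
    phylum = {s.strain_id: s.taxonomy.phylum for s in strains}
    degraders = [s.strain_id for s in strains if is_glycan_degrader(s)]
    non_degraders = [s for s in strain_ids if s not in set(degraders)]

    rows = []
    groups = []
    sample_ids = []
    for group in GROUPS:
        n = design.n_per_group[group]
        bias = design.phylum_bias.get(group, {})
        weights = np.array([bias.get(phylum[s], 1.0) for s in strain_ids])
        weights = weights / weights.sum()
        for i in range(n):
            richness = max(2, int(rng.poisson(design.richness_mean[group])))
            if richness > len(strain_ids):
                raise ValidationError(
                    f"requested richness {richness} exceeds {len(strain_ids)} strains"
                )
            chosen = list(
                rng.choice(strain_ids, size=richness, replace=False, p=weights)
            )
            want_degrader = rng.random() < design.glycan_degrader_prob[group]
            have = [s for s in chosen if s in set(degraders)]
            if want_degrader and not have and degraders:
                # swap one non-degrader for a random degrader
                swap_out = [s for s in chosen if s not in set(degraders)]
                if swap_out:
                    chosen.remove(swap_out[int(rng.integers(len(swap_out)))])
                chosen.append(degraders[int(rng.integers(len(degraders)))])
            elif not want_degrader and have:
                pool = [s for s in non_degraders if s not in set(chosen)]
                for s in have:
                    chosen.remove(s)
                    if pool:
                        pick = pool.pop(int(rng.integers(len(pool))))
                        chosen.append(pick)
                if len(chosen) < 2 and pool:
                    chosen.append(pool.pop(int(rng.integers(len(pool)))))
            abundances = rng.dirichlet(np.ones(len(chosen)))
            row = pd.Series(0.0, index=strain_ids)
            row[chosen] = abundances
            rows.append(row / row.sum())
            groups.append(group)
            sample_ids.append(f"{_GROUP_PREFIX[group]}{i + 1:03d}")

    values = pd.DataFrame(rows, index=sample_ids)
    table = AbundanceTable(values=values, group=pd.Series(groups, index=sample_ids))
    table.validate()
    return table


# ---------------------------------------------------------------------------
# diet & fixtures
# ---------------------------------------------------------------------------


def default_diet(pan: Optional[PanReactome] = None) -> DietSpec:
    """The default simulated diet (mmol/person/day).

    Carbon, nitrogen, phosphorus and water plus organic sulfur (cysteine,
    methionine) and a little glycine.  Inorganic sulfate is deliberately
    absent: in these communities sulfate only enters through host-glycan
    degradation, which is what makes glycan degraders gate part of the
    sulfur secretion repertoire.  Host glycans are always permitted.
    """
    limits = {
        "glc_D": 10.0,
        "nh4": 10.0,
        "pi": 10.0,
        "h2o": 100.0,
        "h": 10.0,
        "cys_L": 5.0,
        "met_L": 5.0,
        "gly": 2.0,
    }
    return DietSpec(uptake_limits=limits, host_metabolites=["cspg", "hspg"])


def cross_feeding_pair(
    pan: Optional[PanReactome] = None,
) -> Tuple[StrainReconstruction, StrainReconstruction, str, DietSpec]:
    """The documented cross-feeding fixture.

    Strain A (a Bacteroidetes glycan degrader) releases sulfate from
    chondroitin/heparan sulfate; strain B (a Proteobacteria sulfate
    reducer) reduces sulfate via sulfite to hydrogen sulfide.  Under the
    returned diet (no organic or inorganic sulfur, host glycans allowed),
    hydrogen sulfide is community-secretable by the pair but by neither
    strain alone.

    Returns ``(strain_a, strain_b, "h2s", diet)``.
    """
    pan = pan or generate_pan_reactome()
    tax_a = Taxonomy(
        "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae",
        "Bact_genX", "Bact_genX_spA", "XF_A",
    )
    tax_b = Taxonomy(
        "Proteobacteria", "Gammaproteobacteria", "Enterobacterales",
        "Enterobacteriaceae", "Prot_genX", "Prot_genX_spB", "XF_B",
    )
    strain_a = _build_strain(
        pan, "XF_A", tax_a, ["CSPGDEG", "HSPGDEG", "GLYC1CAT", "GLYC2CAT"]
    )
    strain_b = _build_strain(pan, "XF_B", tax_b, ["SO4RED", "SO3RED"])
    diet = DietSpec(
        uptake_limits={
            "glc_D": 10.0, "nh4": 10.0, "pi": 10.0, "h2o": 100.0, "h": 10.0,
        },
        host_metabolites=["cspg", "hspg"],
    )
    return strain_a, strain_b, "h2s", diet


# ---------------------------------------------------------------------------
# metabolomic reference
# ---------------------------------------------------------------------------


def generate_metabolomic_reference(
    metabolite_ids: Sequence[str],
    true_directions: Sequence[str],
    noise_rate: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Noisy stand-in for an external faecal-metabolomics direction table.

    Each true direction (``up``/``down``) is flipped independently with
    probability ``noise_rate``; deterministic given ``seed``.
    """
    if not 0.0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must be in [0, 0.5)")
    directions = list(true_directions)
    if len(directions) != len(metabolite_ids):
        raise ValueError("metabolite_ids and true_directions differ in length")
    for d in directions:
        if d not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {d!r}")
    rng = np.random.default_rng(seed)
    flips = rng.random(len(directions)) < noise_rate
    flipped = [
        ("down" if d == "up" else "up") if f else d
        for d, f in zip(directions, flips)
    ]
    return pd.Series(flipped, index=list(metabolite_ids), name="direction")
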