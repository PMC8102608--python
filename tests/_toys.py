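"""Random toy strains and communities for oracle-equivalence tests."""

from __future__ import annotations

import numpy as np

from commflux.community_builder import (
    CommunityConfig,
    apply_diet,
    build_community_model,
)
from commflux.model_io import (
    DietSpec,
    Metabolite,
    Reaction,
    StrainReconstruction,
    Taxonomy,
)

MET_POOL = [f"m{i}" for i in range(8)]


def toy_taxonomy(sid: str) -> Taxonomy:
    return Taxonomy(
        "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae",
        "Toygenus", f"Toygenus_sp_{sid}", sid,
    )


def random_toy_strain(rng: np.random.Generator, sid: str) -> StrainReconstruction:
    n_ex = int(rng.integers(3, len(MET_POOL) + 1))
    exchanged = list(rng.choice(MET_POOL, size=n_ex, replace=False))
    reactions = {}
    touched = set(exchanged)
    for i in range(int(rng.integers(1, 4))):
        subs = rng.choice(exchanged, size=int(rng.integers(1, 3)), replace=False)
        prods = [m for m in rng.choice(MET_POOL, size=1) if m not in subs]
        stoich = {s: -float(rng.integers(1, 3)) for s in subs}
        for p in prods:
            stoich[p] = float(rng.integers(1, 3))
        if len(stoich) < 2:
            continue
        lb = 0.0 if rng.random() < 0.7 else -10.0
        reactions[f"R{i}"] = Reaction(f"R{i}", stoich, lb, 10.0, "Core")
        touched.update(stoich)
    food = exchanged[0]
    reactions["BIOMASS"] = Reaction(
        "BIOMASS", {food: -0.1, "biomass": 1.0}, 0.0, 100.0, "Core"
    )
    touched.add("biomass")
    for met in sorted(touched):
        reactions[f"EX_{met}"] = Reaction(
            f"EX_{met}", {met: -1.0}, -10.0, 10.0, "Exchange"
        )
    metabolites = {m: Metabolite(m, m, "") for m in sorted(touched)}
    return StrainReconstruction(
        strain_id=sid,
        taxonomy=toy_taxonomy(sid),
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id="BIOMASS",
    )


def random_toy_community(seed: int, coupling: bool = True):
    """A feasible random community of <= 5 toy strains plus its diet."""
    rng = np.random.default_rng(seed)
    for attempt in range(50):
        n = int(rng.integers(2, 6))
        strains = {f"T{k}": random_toy_strain(rng, f"T{k}") for k in range(n)}
        a = rng.dirichlet(np.ones(n))
        abundances = {f"T{k}": float(a[k]) for k in range(n)}
        abundances[f"T{n-1}"] += 1.0 - sum(abundances.values())
        config = CommunityConfig(coupling_enabled=coupling)
        model = build_community_model(strains, abundances, config, f"toy{seed}")
        limits = {
            m: float(rng.integers(1, 11))
            for m in MET_POOL
            if rng.random() < 0.8 and m in model.lumen_metabolites
        }
        model = apply_diet(model, DietSpec(uptake_limits=limits))
        lp, order = model.build_lp()
        if lp.is_feasible():
            return model
    raise RuntimeError(f"no feasible toy community for seed {seed}")
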