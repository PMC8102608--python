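"""Domain types and I/O for strain reconstructions, abundances and diets.

A :class:`StrainReconstruction` is a single-compartment genome-scale
metabolic network in the AGORA style: metabolites with elemental formulas,
reactions with stoichiometry/bounds/subsystem, one biomass reaction, and
exchange reactions that trade exactly one metabolite with the strain's
exterior.  Two serialisations are supported: SBML Level 3 with FBC bounds
(the interchange standard, written through cobrapy) and a 1:1 JSON dialect
used for fast fixtures.

Cohort inputs are plain TSV: a sample × strain relative-abundance table with
a ``group`` column, and a two-column diet file of per-metabolite maximal
daily uptakes (mmol/person/day).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lp import LPStatus, StoichiometricLP

__all__ = [
    "GROUPS",
    "SUBSYSTEMS",
    "Metabolite",
    "Reaction",
    "Taxonomy",
    "StrainReconstruction",
    "AbundanceTable",
    "DietSpec",
    "ValidationError",
    "FormatError",
    "parse_formula",
    "read_strain_reconstruction",
    "write_strain_reconstruction",
    "read_abundance_table",
    "write_abundance_table",
    "read_diet_file",
    "write_diet_file",
]

#: Study-group labels, ordered from healthy to dysbiotic.
GROUPS = ("healthy", "IBD_nondysbiotic", "IBD_dysbiotic")

#: Declared subsystem vocabulary.
SUBSYSTEMS = frozenset(
    {
        "Core",
        "Exchange",
        "Fermentation",
        "Amino acid biosynthesis",
        "B-vitamin biosynthesis",
        "Sulfur metabolism",
        "Glycan degradation",
        "Generic metabolism",
        "Community",
    }
)


class ValidationError(ValueError):
    """A structural invariant of a model or table is violated."""


class FormatError(ValueError):
    """A file could not be parsed in its declared format."""


_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse an elemental formula into element counts.

    Two-letter element symbols take precedence over one-letter ones, so
    ``"Se"`` and ``"Sn"`` contribute no sulfur while ``"S"``, ``"S2"`` or
    ``"CH4S"`` do.  An empty formula parses to an empty mapping.
    """
    counts: Dict[str, int] = {}
    pos = 0
    for m in _ELEMENT_RE.finditer(formula):
        if m.start() != pos:
            raise FormatError(f"unparseable formula {formula!r} at position {pos}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula):
        raise FormatError(f"unparseable formula {formula!r} at position {pos}")
    return counts


@dataclass(frozen=True)
class Metabolite:
    """One chemical species, identified by a VMH-style short id."""

    id: str
    name: str = ""
    formula: str = ""

    @property
    def is_sulfur(self) -> bool:
        """True iff the elemental formula contains sulfur (element S)."""
        return parse_formula(self.formula).get("S", 0) > 0


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds in mmol/person/day."""

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    subsystem: str = "Core"

    def validate(self) -> None:
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.subsystem not in SUBSYSTEMS:
            raise ValidationError(
                f"reaction {self.id}: unknown subsystem {self.subsystem!r}"
            )

    @property
    def is_exchange(self) -> bool:
        """Exchange reactions trade exactly one metabolite with the exterior."""
        return len(self.stoichiometry) == 1


_RANKS = ("phylum", "class_", "order", "family", "genus", "species", "strain")


@dataclass(frozen=True)
class Taxonomy:
    phylum: str
    class_: str
    order: str
    family: str
    genus: str
    species: str
    strain: str

    def validate(self) -> None:
        for rank in _RANKS:
            if not getattr(self, rank):
                raise ValidationError(f"taxonomy rank {rank!r} is empty")

    def rank(self, level: str) -> str:
        level = "class_" if level == "class" else level
        return getattr(self, level)


@dataclass
class StrainReconstruction:
    """A single strain's metabolic network.

    ``exchange_reaction_ids`` are auto-detected on validation as the
    reactions with exactly one metabolite in their stoichiometry; the sign
    convention is ``{met: -1}`` with positive flux exporting the metabolite.
    """

    strain_id: str
    taxonomy: Taxonomy
    metabolites: Dict[str, Metabolite]
    reactions: Dict[str, Reaction]
    biomass_reaction_id: str
    exchange_reaction_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exchange_reaction_ids:
            self.exchange_reaction_ids = [
                r.id for r in self.reactions.values() if r.is_exchange
            ]

    # -- structure --------------------------------------------------------

    def exchanged_metabolite(self, reaction_id: str) -> str:
        rxn = self.reactions[reaction_id]
        if not rxn.is_exchange:
            raise ValidationError(f"reaction {reaction_id} is not an exchange")
        return next(iter(rxn.stoichiometry))

    def validate(self, check_growth: bool = True) -> None:
        """Check all structural invariants; optionally the growth LP.

        The growth check opens every exchange to ``(-1000, 1000)`` and
        requires maximal biomass flux above ``1e-6``.
        """
        self.taxonomy.validate()
        ids = set()
        for met in self.metabolites.values():
            if met.id in ids:
                raise ValidationError(f"duplicate metabolite id {met.id}")
            ids.add(met.id)
            met.is_sulfur  # parses the formula; raises on bad input
        if self.biomass_reaction_id not in self.reactions:
            raise ValidationError(
                f"strain {self.strain_id}: missing biomass reaction "
                f"{self.biomass_reaction_id!r}"
            )
        for rxn in self.reactions.values():
            rxn.validate()
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ValidationError(
                        f"reaction {rxn.id} references unknown metabolite "
                        f"{met_id!r}"
                    )
        for ex_id in self.exchange_reaction_ids:
            if ex_id not in self.reactions:
                raise ValidationError(f"unknown exchange reaction {ex_id!r}")
            if not self.reactions[ex_id].is_exchange:
                raise ValidationError(
                    f"exchange reaction {ex_id} must have exactly one metabolite"
                )
        if check_growth and self.max_biomass_open_exchanges() <= 1e-6:
            raise ValidationError(
                f"strain {self.strain_id}: biomass reaction cannot carry flux "
                "with all exchanges open"
            )

    def max_biomass_open_exchanges(self) -> float:
        """Maximal biomass flux with every exchange opened to (-1000, 1000)."""
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        rxn_ids = list(self.reactions)
        exchanges = set(self.exchange_reaction_ids)
        columns = []
        bounds = []
        for rid in rxn_ids:
            rxn = self.reactions[rid]
            columns.append([(met_index[m], c) for m, c in rxn.stoichiometry.items()])
            if rid in exchanges:
                bounds.append((-1000.0, 1000.0))
            else:
                bounds.append((rxn.lower_bound, rxn.upper_bound))
        lp = StoichiometricLP(len(met_index), columns, bounds)
        value, status = lp.optimize(rxn_ids.index(self.biomass_reaction_id))
        return value if status == LPStatus.OPTIMAL else 0.0


@dataclass
class DietSpec:
    """Per-metabolite maximal daily uptakes plus always-permitted host species."""

    uptake_limits: Dict[str, float] = field(default_factory=dict)
    host_metabolites: List[str] = field(default_factory=list)

    def validate(self) -> None:
        for met, amount in self.uptake_limits.items():
            if not math.isfinite(amount) or amount < 0:
                raise ValidationError(
                    f"diet limit for {met!r} must be finite and non-negative, "
                    f"got {amount}"
                )


@dataclass
class AbundanceTable:
    """Sample × strain relative abundances with per-sample group labels."""

    values: pd.DataFrame  # rows: samples, columns: strain ids
    group: pd.Series  # index: sample ids, values in GROUPS

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def strain_ids(self) -> List[str]:
        return list(self.values.columns)

    def sample(self, sample_id: str) -> Dict[str, float]:
        """Non-zero strain abundances of one sample."""
        row = self.values.loc[sample_id]
        return {k: float(v) for k, v in row.items() if v > 0}

    def validate(self) -> None:
        if (self.values.values < 0).any():
            raise ValidationError("negative abundance")
        sums = self.values.sum(axis=1)
        bad = sums[(sums - 1.0).abs() > 1e-8]
        if len(bad):
            raise ValidationError(
                f"sample rows must sum to 1: {list(bad.index[:5])}"
            )
        unknown = set(self.group) - set(GROUPS)
        if unknown:
            raise ValidationError(f"unknown group labels: {sorted(unknown)}")
        if list(self.group.index) != list(self.values.index):
            raise ValidationError("group index does not match sample index")


# ---------------------------------------------------------------------------
# strain reconstruction serialisation
# ---------------------------------------------------------------------------


def _strain_to_dict(model: StrainReconstruction) -> dict:
    return {
        "strain_id": model.strain_id,
        "taxonomy": {r.rstrip("_"): getattr(model.taxonomy, r) for r in _RANKS},
        "metabolites": [
            {"id": m.id, "name": m.name, "formula": m.formula}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
            }
            for r in model.reactions.values()
        ],
        "biomass_reaction_id": model.biomass_reaction_id,
    }


def _strain_from_dict(data: dict) -> StrainReconstruction:
    try:
        tax = data["taxonomy"]
        taxonomy = Taxonomy(
            phylum=tax["phylum"],
            class_=tax.get("class", tax.get("class_", "")),
            order=tax["order"],
            family=tax["family"],
            genus=tax["genus"],
            species=tax["species"],
            strain=tax["strain"],
        )
        metabolites = {
            m["id"]: Metabolite(m["id"], m.get("name", ""), m.get("formula", ""))
            for m in data["metabolites"]
        }
        reactions = {
            r["id"]: Reaction(
                r["id"],
                {k: float(v) for k, v in r["stoichiometry"].items()},
                float(r["lower_bound"]),
                float(r["upper_bound"]),
                r.get("subsystem", "Core"),
            )
            for r in data["reactions"]
        }
        return StrainReconstruction(
            strain_id=data["strain_id"],
            taxonomy=taxonomy,
            metabolites=metabolites,
            reactions=reactions,
            biomass_reaction_id=data["biomass_reaction_id"],
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed strain JSON: missing {exc}") from exc


_TAX_SEP = "|"


def _strain_to_cobra(model: StrainReconstruction):
    import cobra

    cm = cobra.Model(model.strain_id)
    mets = {}
    for met in model.metabolites.values():
        m = cobra.Metabolite(
            met.id, name=met.name, formula=met.formula or None, compartment="c"
        )
        mets[met.id] = m
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for rxn in model.reactions.values():
        r = cobra.Reaction(rxn.id)
        r.lower_bound = rxn.lower_bound
        r.upper_bound = rxn.upper_bound
        r.subsystem = rxn.subsystem
        rxns.append(r)
    cm.add_reactions(rxns)
    for rxn in model.reactions.values():
        cm.reactions.get_by_id(rxn.id).add_metabolites(
            {mets[m]: c for m, c in rxn.stoichiometry.items()}
        )
        cm.reactions.get_by_id(rxn.id).notes["subsystem"] = rxn.subsystem
    cm.notes["taxonomy"] = _TAX_SEP.join(
        getattr(model.taxonomy, r) for r in _RANKS
    )
    cm.notes["biomass_reaction_id"] = model.biomass_reaction_id
    cm.objective = model.biomass_reaction_id
    return cm


def _strain_from_cobra(cm) -> StrainReconstruction:
    tax_note = cm.notes.get("taxonomy", "")
    parts = tax_note.split(_TAX_SEP)
    if len(parts) != len(_RANKS):
        raise FormatError(
            f"SBML model {cm.id}: missing or malformed taxonomy note {tax_note!r}"
        )
    taxonomy = Taxonomy(*parts)
    metabolites = {
        m.id: Metabolite(m.id, m.name or "", m.formula or "")
        for m in cm.metabolites
    }
    reactions = {}
    for r in cm.reactions:
        reactions[r.id] = Reaction(
            r.id,
            {m.id: float(c) for m, c in r.metabolites.items()},
            float(r.lower_bound),
            float(r.upper_bound),
            r.notes.get("subsystem", r.subsystem or "Core"),
        )
    biomass = cm.notes.get("biomass_reaction_id")
    if not biomass:
        raise ValidationError(f"SBML model {cm.id}: no biomass reaction declared")
    return StrainReconstruction(
        strain_id=cm.id,
        taxonomy=taxonomy,
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=biomass,
    )


def read_strain_reconstruction(
    path, format: str = "json", validate: bool = True
) -> StrainReconstruction:
    """Read a strain reconstruction from ``path`` in ``{"json", "sbml"}``."""
    path = Path(path)
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc
        model = _strain_from_dict(data)
    elif format == "sbml":
        import cobra

        try:
            cm = cobra.io.read_sbml_model(str(path))
        except Exception as exc:
            raise FormatError(f"{path}: SBML parse failure: {exc}") from exc
        model = _strain_from_cobra(cm)
    else:
        raise ValueError(f"unknown format {format!r}")
    if validate:
        model.validate()
    return model


def write_strain_reconstruction(
    model: StrainReconstruction, path, format: str = "json"
) -> None:
    """Write ``model`` so that reading it back is structurally identical."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_strain_to_dict(model), indent=1, sort_keys=True))
    elif format == "sbml":
        import cobra

        cobra.io.write_sbml_model(_strain_to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_abundance_table(path, cutoff: float = 1e-6) -> AbundanceTable:
    """Read a sample × strain TSV with a ``group`` column.

    Strains below ``cutoff`` relative abundance are dropped per sample and
    the remaining abundances are renormalised to sum to one.  Strains at
    numerical-noise abundance would otherwise produce near-singular
    community-biomass coefficients.
    """
    df = _read_tsv(path)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise FormatError(f"{path}: expected 'sample_id' and 'group' columns")
    df = df.set_index("sample_id")
    group = df.pop("group")
    values = df.astype(float)
    if (values.values < 0).any():
        raise ValidationError(f"{path}: negative abundance")
    arr = values.values.copy()
    arr[arr < cutoff] = 0.0
    sums = arr.sum(axis=1)
    dead = np.flatnonzero(sums <= 0)
    if dead.size:
        raise ValidationError(
            f"{path}: samples sum to zero after cutoff: "
            f"{list(values.index[dead][:5])}"
        )
    arr = arr / sums[:, None]
    table = AbundanceTable(
        values=pd.DataFrame(arr, index=values.index, columns=values.columns),
        group=group,
    )
    table.validate()
    return table


def write_abundance_table(table: AbundanceTable, path) -> None:
    out = table.values.copy()
    out.insert(0, "group", table.group)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# diet files
# ---------------------------------------------------------------------------


def read_diet_file(path, host_metabolites: Sequence[str] = ()) -> DietSpec:
    """Read a two-column TSV (metabolite id, max daily uptake).

    Duplicate metabolite rows are summed.  Lines starting with ``#`` are
    ignored; an empty file yields an empty (valid) diet.
    """
    limits: Dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
        met, raw = parts
        try:
            amount = float(raw)
        except ValueError as exc:
            raise FormatError(
                f"{path}:{lineno}: unparseable amount {raw!r}"
            ) from exc
        if amount < 0 or not math.isfinite(amount):
            raise ValidationError(
                f"{path}:{lineno}: negative or non-finite amount for {met!r}"
            )
        limits[met] = limits.get(met, 0.0) + amount
    diet = DietSpec(uptake_limits=limits, host_metabolites=list(host_metabolites))
    diet.validate()
    return diet


def write_diet_file(diet: DietSpec, path) -> None:
    lines = ["# metabolite\tmax_daily_uptake_mmol_per_person_per_day"]
    for met, amount in diet.uptake_limits.items():
        lines.append(f"{met}\t{amount!r}")
    Path(path).write_text("\n".join(lines) + "\n")
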