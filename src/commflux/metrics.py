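"""Network- and cohort-level descriptors.

Reaction presence/abundance by taxon level, flux–taxon Spearman
correlations, secreted-metabolite counts, independent sulfur species
(perfect-coupling collapse), and principal-coordinates ordination of the
strain-to-metabolite contribution vectors.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .model_io import AbundanceTable, Metabolite, StrainReconstruction
from .flux_profiler import ContributionTable, MetaboliteProfile

__all__ = [
    "reaction_presence_and_abundance",
    "correlate_flux_with_taxa",
    "count_secreted_metabolites",
    "count_independent_sulfur_species",
    "collapse_coupled_columns",
    "pcoa_contributions",
    "species_abundance",
    "secretion_matrix",
]


def reaction_presence_and_abundance(
    strains: Mapping[str, StrainReconstruction],
    abundances: AbundanceTable,
    level: str = "community",
):
    """Absolute reaction presence and abundance-weighted reaction content.

    Presence: a reaction is present in a sample iff >= 1 member strain's
    reconstruction contains it.  Abundance at community level is
    ``sum_k a_k * 1[reaction in strain k]``; at ``phylum``/``genus`` level
    one matrix slice per taxon restricts the sum, and the slices partition
    the community value exactly.

    Returns ``(presence, abundance)`` where ``abundance`` is a DataFrame
    at community level and a ``dict taxon -> DataFrame`` otherwise.
    """
    if level not in ("community", "phylum", "genus"):
        raise ValueError(f"unknown level {level!r}")
    all_rxns = sorted({rid for s in strains.values() for rid in s.reactions})
    strain_ids = abundances.strain_ids
    carries = pd.DataFrame(
        {
            sid: [rid in strains[sid].reactions for rid in all_rxns]
            for sid in strain_ids
        },
        index=all_rxns,
    ).T.astype(float)  # strains × reactions

    values = abundances.values  # samples × strains
    presence = (values.values > 0) @ (carries.values > 0) > 0
    presence = pd.DataFrame(presence, index=values.index, columns=all_rxns)

    if level == "community":
        abundance = pd.DataFrame(
            values.values @ carries.values, index=values.index, columns=all_rxns
        )
        return presence, abundance

    taxa = {sid: strains[sid].taxonomy.rank(level) for sid in strain_ids}
    slices: Dict[str, pd.DataFrame] = {}
    for taxon in sorted(set(taxa.values())):
        mask = np.array([taxa[sid] == taxon for sid in strain_ids], dtype=float)
        weighted = values.values * mask[None, :]
        slices[taxon] = pd.DataFrame(
            weighted @ carries.values, index=values.index, columns=all_rxns
        )
    return presence, slices


def species_abundance(
    strains: Mapping[str, StrainReconstruction], abundances: AbundanceTable
) -> pd.DataFrame:
    """Aggregate strain abundances to species level by summation."""
    species = {sid: strains[sid].taxonomy.species for sid in abundances.strain_ids}
    return abundances.values.T.groupby(species).sum().T


def secretion_matrix(profiles: Sequence[MetaboliteProfile]) -> pd.DataFrame:
    """Samples × metabolites secretion-potential matrix (absent = 0)."""
    cols = {
        p.sample_id: p.table["secretion_potential"] for p in profiles
    }
    return pd.DataFrame(cols).T.fillna(0.0)


def correlate_flux_with_taxa(
    flux: pd.DataFrame,
    species: pd.DataFrame,
    threshold: float = 0.75,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation of each metabolite flux with each species.

    ``flux``: samples × metabolites, ``species``: samples × species
    abundances.  Constant vectors yield a missing correlation with a
    reason.  Returns ``(table, strong)`` where ``strong`` is the subset
    with |rho| > ``threshold``.
    """
    if len(flux) < 5:
        raise ValueError("need >= 5 samples for correlation analysis")
    common = flux.index.intersection(species.index)
    flux = flux.loc[common]
    species = species.loc[common]
    rows = []
    for met in flux.columns:
        x = flux[met].values
        x_const = np.all(x == x[0])
        for sp in species.columns:
            y = species[sp].values
            if x_const or np.all(y == y[0]):
                rows.append((met, sp, np.nan, "constant vector"))
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = spearmanr(x, y).statistic
            rows.append((met, sp, rho, ""))
    table = pd.DataFrame(
        rows, columns=["metabolite_id", "species", "rho", "reason"]
    )
    strong = table[table["rho"].abs() > threshold].reset_index(drop=True)
    return table, strong


def count_secreted_metabolites(
    profile: MetaboliteProfile, tau: float = 1e-6
) -> int:
    """Number of metabolites with secretion potential above ``tau``."""
    return int((profile.table["secretion_potential"] > tau).sum())


def collapse_coupled_columns(binary: pd.DataFrame) -> Tuple[pd.DataFrame, List[List[str]]]:
    """Collapse perfectly coupled (identical) binary columns.

    Columns with identical values across all samples are merged into one
    representative (the lexicographically first member).  Returns the
    collapsed matrix and the list of coupled groups.  The operation is
    idempotent and column-order-invariant.
    """
    binary = binary.astype(bool)
    groups: Dict[Tuple[bool, ...], List[str]] = {}
    for col in sorted(binary.columns):
        groups.setdefault(tuple(binary[col].values), []).append(col)
    coupled = sorted(groups.values(), key=lambda g: g[0])
    reps = [g[0] for g in coupled]
    return binary[reps], coupled


def count_independent_sulfur_species(
    secretion: pd.DataFrame,
    metabolites: Mapping[str, Metabolite],
    tau: float = 1e-6,
) -> Tuple[pd.Series, List[List[str]]]:
    """Per-sample count of independently secreted sulfur species.

    The cohort-wide binary secretion matrix is restricted to
    sulfur-containing metabolites; metabolites with identical binary
    columns (perfectly coupled in their occurrence) are collapsed to one
    representative, and each sample's count runs over representatives it
    secretes.  Returns ``(counts, coupled_groups)``.
    """
    if len(secretion) < 2:
        raise ValueError("need >= 2 samples")
    sulfur = [
        m for m in secretion.columns
        if m in metabolites and metabolites[m].is_sulfur
    ]
    if not sulfur:
        raise ValueError("no sulfur-containing metabolites in the universe")
    binary = secretion[sulfur] > tau
    collapsed, coupled = collapse_coupled_columns(binary)
    counts = collapsed.sum(axis=1).astype(int)
    counts.name = "n_independent_sulfur_species"
    return counts, coupled


def pcoa_contributions(
    contributions: ContributionTable,
    distance: str = "euclidean",
    k: int = 2,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Classical metric ordination (PCoA) of contribution vectors.

    Samples are embedded from the distance matrix over their
    (strain, metabolite) contribution vectors (absent keys = 0) by
    double-centring the squared distances and eigen-decomposing the Gram
    matrix.  Eigenvalues are returned non-increasing, negative ones
    included (a Euclidean distance matrix has none; Bray–Curtis may).
    Coordinates are produced only for positive eigenvalues; ``k`` beyond
    the positive rank is truncated with a warning.
    """
    if distance not in ("euclidean", "braycurtis"):
        raise ValueError(f"unknown distance {distance!r}")
    wide = contributions.to_wide()
    if len(wide) < 3:
        raise ValueError("need >= 3 samples for ordination")
    d = squareform(pdist(wide.values, metric=distance))
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ (d ** 2) @ j
    gram = (gram + gram.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos_rank = int((eigvals > max(1e-12, 1e-9 * abs(eigvals[0]))).sum())
    if k > pos_rank:
        warnings.warn(
            f"requested {k} axes but positive rank is {pos_rank}; truncating"
        )
        k = pos_rank
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    coords = pd.DataFrame(
        coords, index=wide.index, columns=[f"axis{i + 1}" for i in range(k)]
    )
    return coords, eigvals
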