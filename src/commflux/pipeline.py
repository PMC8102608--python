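"""End-to-end orchestration: inputs -> models -> fluxes -> metrics -> stats.

``run_pipeline`` drives the whole analysis on either synthetic or on-disk
inputs, writing per-sample flux tables (the per-sample checkpoint used for
resuming interrupted runs), profile/contribution tables, metric matrices,
statistics reports and a manifest with the configuration hash and seeds.
Re-running with the same configuration and seed reproduces identical
outputs; samples whose flux tables already exist are not re-solved.
Per-sample failures (e.g. an infeasible diet) are recorded and the
remaining samples continue.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import synthetic_data
from .community_builder import CommunityConfig, apply_diet, build_community_model
from .flux_profiler import (
    ContributionTable,
    InfeasibleModelError,
    compute_exchange_flux_ranges,
    compute_metabolite_profile,
    compute_strain_contributions,
    FluxRange,
)
from .metrics import (
    correlate_flux_with_taxa,
    count_independent_sulfur_species,
    count_secreted_metabolites,
    pcoa_contributions,
    reaction_presence_and_abundance,
    secretion_matrix,
    species_abundance,
)
from .model_io import (
    GROUPS,
    AbundanceTable,
    DietSpec,
    StrainReconstruction,
    read_abundance_table,
    read_diet_file,
    read_strain_reconstruction,
    write_abundance_table,
    write_diet_file,
    write_strain_reconstruction,
)
from .stats import (
    classify_auc,
    direction_agreement,
    directions_from_screen,
    fisher_secretion_screen,
    mediation_analysis,
    rf_stratify,
    secreted_count_regression,
    wilcoxon_fdr_screen,
)
from .synthetic_data import (
    CohortDesign,
    cross_feeding_pair,
    default_diet,
    generate_cohort,
    generate_metabolomic_reference,
    generate_pan_reactome,
    generate_strain_set,
    is_glycan_degrader,
)

__all__ = ["RunConfig", "run_pipeline", "profile_sample"]

logger = logging.getLogger("commflux.pipeline")

#: Final breakdown products of bacterial sulfur metabolism whose secretion
#: patterns are compared across groups.
SULFUR_END_PRODUCTS = ("h2s", "so4", "so3", "tsul", "ch4s")

#: Amino-acid metabolite family used in the metabolomic comparison.
AA_METABOLITES = (
    "ala_L", "arg_L", "asn_L", "asp_L", "gln_L", "glu_L", "gly", "his_L",
    "ile_L", "leu_L", "lys_L", "phe_L", "pro_L", "ser_L", "thr_L", "trp_L",
    "tyr_L", "val_L", "cys_L", "met_L",
)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    out_dir: Path = Path("results/run")
    seed: int = 0
    # synthetic inputs (used when no input paths are given)
    design: CohortDesign = field(default_factory=CohortDesign)
    n_pan_metabolites: int = 64
    n_pan_reactions: int = 140
    n_strains: int = 40
    reference_noise_rate: float = 0.3
    # on-disk inputs (override synthetic generation)
    strain_dir: Optional[Path] = None
    abundance_path: Optional[Path] = None
    diet_path: Optional[Path] = None
    abundance_cutoff: float = 1e-6
    # modelling
    community: CommunityConfig = field(default_factory=CommunityConfig)
    tau: float = 1e-6
    workers: int = 1
    # analysis thresholds
    fdr_alpha: float = 0.05
    correlation_threshold: float = 0.75
    n_boot: int = 1000
    n_trees: int = 5000

    def validate(self) -> None:
        self.community.validate()
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.tau < 0 or self.n_boot < 1 or self.n_trees < 1:
            raise ValueError("invalid thresholds")
        for p in (self.strain_dir, self.abundance_path, self.diet_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def content_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            return str(o)

        fields = dataclasses.asdict(self)
        fields.pop("out_dir")  # a run is identified by its content, not location
        payload = json.dumps(fields, default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sub_seed(seed: int, k: int) -> int:
    return int((seed * 1000003 + k) % (2**31 - 1))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def load_or_generate_inputs(
    config: RunConfig, input_dir: Path
) -> Tuple[Dict[str, StrainReconstruction], AbundanceTable, DietSpec]:
    """Stage 1: read inputs from disk or generate the synthetic cohort."""
    if config.abundance_path is not None:
        strain_dir = Path(config.strain_dir)
        strains = {}
        for path in sorted(strain_dir.glob("*.json")):
            s = read_strain_reconstruction(path, "json")
            strains[s.strain_id] = s
        table = read_abundance_table(config.abundance_path, config.abundance_cutoff)
        diet = read_diet_file(config.diet_path) if config.diet_path else default_diet()
        if not diet.host_metabolites:
            diet.host_metabolites = ["cspg", "hspg"]
        return strains, table, diet

    pan = generate_pan_reactome(
        config.n_pan_metabolites, config.n_pan_reactions, _sub_seed(config.seed, 0)
    )
    strain_list = generate_strain_set(
        pan, config.n_strains, seed=_sub_seed(config.seed, 1)
    )
    design = dataclasses.replace(config.design, seed=_sub_seed(config.seed, 2))
    table = generate_cohort(strain_list, design)
    diet = default_diet(pan)

    input_dir.mkdir(parents=True, exist_ok=True)
    strain_sub = input_dir / "strains"
    strain_sub.mkdir(exist_ok=True)
    for s in strain_list:
        write_strain_reconstruction(s, strain_sub / f"{s.strain_id}.json", "json")
    write_abundance_table(table, input_dir / "abundance.tsv")
    write_diet_file(diet, input_dir / "diet.tsv")
    return {s.strain_id: s for s in strain_list}, table, diet


def profile_sample(
    strains: Dict[str, StrainReconstruction],
    abundances: Dict[str, float],
    diet: DietSpec,
    config: RunConfig,
    sample_id: str,
):
    """Build, constrain and flux-profile one sample's community model."""
    model = build_community_model(
        strains, abundances, config.community, sample_id=sample_id
    )
    model = apply_diet(model, diet)
    ranges = compute_exchange_flux_ranges(model, workers=config.workers)
    return model, ranges


def _ranges_to_frame(ranges: Sequence[FluxRange]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.reaction_id, r.min_flux, r.max_flux, r.status) for r in ranges],
        columns=["reaction_id", "min_flux", "max_flux", "status"],
    )


def _frame_to_ranges(df: pd.DataFrame) -> List[FluxRange]:
    return [
        FluxRange(r.reaction_id, float(r.min_flux), float(r.max_flux), r.status)
        for r in df.itertuples()
    ]


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the run directory.

    Layout of the run directory::

        inputs/            strain JSONs, abundance.tsv, diet.tsv
        fluxes/            per-sample flux-range TSVs (checkpoints)
        profiles.tsv       per-sample metabolite potentials and classes
        contributions.tsv  strain x metabolite contributions (long)
        metrics/ stats/    cohort matrices and statistical reports
        manifest.json      config hash, seeds, timings, failures
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    config_hash = config.content_hash()
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_hash") != config_hash:
            logger.warning("config changed; clearing stale checkpoints")
            for f in (out / "fluxes").glob("*.tsv"):
                f.unlink()

    t_start = time.time()
    strains, table, diet = load_or_generate_inputs(config, out / "inputs")
    flux_dir = out / "fluxes"
    flux_dir.mkdir(exist_ok=True)

    profiles = []
    contrib_frames = []
    failures: Dict[str, str] = {}
    n_lp = 0
    for sample_id in table.sample_ids:
        abundances = table.sample(sample_id)
        checkpoint = flux_dir / f"{sample_id}.tsv"
        try:
            model = build_community_model(
                strains, abundances, config.community, sample_id=sample_id
            )
            model = apply_diet(model, diet)
            if checkpoint.exists():
                ranges = _frame_to_ranges(pd.read_csv(checkpoint, sep="\t"))
            else:
                t0 = time.time()
                ranges = compute_exchange_flux_ranges(model, workers=config.workers)
                _ranges_to_frame(ranges).to_csv(checkpoint, sep="\t", index=False)
                n_lp += 2 * len(ranges)
                logger.info(
                    "sample=%s stage=profile n_exchanges=%d seconds=%.2f",
                    sample_id, len(ranges), time.time() - t0,
                )
            profiles.append(compute_metabolite_profile(model, ranges, config.tau))
            contrib_frames.append(
                compute_strain_contributions(model, ranges, config.tau).records
            )
        except InfeasibleModelError as exc:
            failures[sample_id] = str(exc)
            logger.error("sample=%s stage=profile failure=%s", sample_id, exc)
    if not profiles:
        raise RuntimeError(
            f"all samples failed: {json.dumps(failures, indent=1)}"
        )

    ok_samples = [p.sample_id for p in profiles]
    group = table.group.loc[ok_samples]

    # ---- tables ----------------------------------------------------------
    prof_long = pd.concat(
        [p.table.assign(sample_id=p.sample_id).reset_index() for p in profiles]
    )[["sample_id", "metabolite_id", "secretion_potential", "uptake_potential",
       "origin_class"]]
    prof_long.to_csv(out / "profiles.tsv", sep="\t", index=False)
    contributions = ContributionTable(
        pd.concat(contrib_frames, ignore_index=True)
        if contrib_frames else pd.DataFrame(
            columns=["sample_id", "strain_id", "metabolite_id", "contribution"])
    )
    contributions.records.to_csv(out / "contributions.tsv", sep="\t", index=False)

    # ---- metrics ---------------------------------------------------------
    metrics_dir = out / "metrics"
    metrics_dir.mkdir(exist_ok=True)
    sub_table = AbundanceTable(
        values=table.values.loc[ok_samples], group=group
    )
    presence, abundance = reaction_presence_and_abundance(
        strains, sub_table, "community"
    )
    presence.to_csv(metrics_dir / "reaction_presence.tsv", sep="\t")
    abundance.to_csv(metrics_dir / "reaction_abundance_community.tsv", sep="\t")

    secretion = secretion_matrix(profiles)
    secretion.to_csv(metrics_dir / "secretion_fluxes.tsv", sep="\t")
    counts = pd.Series(
        {p.sample_id: count_secreted_metabolites(p, config.tau) for p in profiles},
        name="n_secreted",
    )
    n_strains_per_sample = (sub_table.values > 0).sum(axis=1)
    pd.DataFrame(
        {"n_secreted": counts, "n_strains": n_strains_per_sample, "group": group}
    ).to_csv(metrics_dir / "secreted_counts.tsv", sep="\t")

    pan_mets = {}
    for s in strains.values():
        pan_mets.update(s.metabolites)
    sulfur_counts, coupled = count_independent_sulfur_species(
        secretion, pan_mets, config.tau
    )
    degrader_ids = {s.strain_id for s in strains.values() if is_glycan_degrader(s)}
    has_degrader = (
        (sub_table.values[sorted(degrader_ids & set(sub_table.strain_ids))] > 0)
        .any(axis=1)
        .astype(int)
        if degrader_ids
        else pd.Series(0, index=ok_samples)
    )
    pd.DataFrame(
        {
            "n_independent_sulfur": sulfur_counts,
            "has_glycan_degrader": has_degrader,
            "group": group,
        }
    ).to_csv(metrics_dir / "sulfur_counts.tsv", sep="\t")

    species = species_abundance(strains, sub_table)
    corr, strong = correlate_flux_with_taxa(
        secretion, species, config.correlation_threshold
    )
    strong.to_csv(metrics_dir / "strong_correlations.tsv", sep="\t", index=False)

    if len(contributions.records):
        coords, eigvals = pcoa_contributions(contributions, "euclidean", k=2)
        coords.to_csv(metrics_dir / "pcoa_coordinates.tsv", sep="\t")
        pd.Series(eigvals, name="eigenvalue").to_csv(
            metrics_dir / "pcoa_eigenvalues.tsv", sep="\t", index=False
        )

    # ---- statistics ------------------------------------------------------
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    report: Dict[str, object] = {}

    pooled = group.replace(
        {"IBD_nondysbiotic": "IBD", "IBD_dysbiotic": "IBD"}
    )
    screen_ibd = wilcoxon_fdr_screen(
        secretion, pooled, ("healthy", "IBD"), config.fdr_alpha
    )
    screen_ibd.to_csv(stats_dir / "wilcoxon_ibd_vs_healthy.tsv", sep="\t",
                      index=False)
    screen_dys = wilcoxon_fdr_screen(
        secretion, group, ("IBD_nondysbiotic", "IBD_dysbiotic"), config.fdr_alpha
    )
    screen_dys.to_csv(stats_dir / "wilcoxon_dys_vs_nondys.tsv", sep="\t",
                      index=False)
    report["n_significant_ibd_vs_healthy"] = int(screen_ibd["significant"].sum())
    report["n_significant_dys_vs_nondys"] = int(screen_dys["significant"].sum())

    fisher, skipped = fisher_secretion_screen(
        secretion > config.tau, group, config.fdr_alpha
    )
    fisher.to_csv(stats_dir / "fisher_secretion.tsv", sep="\t", index=False)
    report["n_fisher_significant"] = (
        int(fisher["significant"].sum()) if len(fisher) else 0
    )
    report["n_independent_secretions_tested"] = int(len(fisher))

    dys_indicator = pd.Series(
        np.where(group == "IBD_dysbiotic", "IBD_dysbiotic", "other"),
        index=group.index,
    )
    reg = secreted_count_regression(
        counts, n_strains_per_sample, dys_indicator,
        effect_level="IBD_dysbiotic", reference_level="other",
    )
    report["regression"] = {
        "b": reg.b, "ci": reg.ci, "t": reg.t, "p": reg.p,
        "df_resid": reg.df_resid, "chosen_power": reg.chosen_power,
        "form_p": reg.form_p, "n": reg.n,
    }

    report["mean_secreted_by_group"] = {
        g: float(counts[group == g].mean()) for g in GROUPS if (group == g).any()
    }
    report["mean_sulfur_by_group"] = {
        g: float(sulfur_counts[group == g].mean())
        for g in GROUPS
        if (group == g).any()
    }
    count_screen = wilcoxon_fdr_screen(
        pd.DataFrame({"n_secreted": counts, "n_sulfur": sulfur_counts}),
        group,
        ("healthy", "IBD_dysbiotic"),
        config.fdr_alpha,
    )
    report["secreted_count_q_healthy_vs_dysbiotic"] = float(
        count_screen.set_index("feature_id").loc["n_secreted", "q_value"]
    )
    report["sulfur_count_q_healthy_vs_dysbiotic"] = float(
        count_screen.set_index("feature_id").loc["n_sulfur", "q_value"]
    )

    hd = group[group.isin(["healthy", "IBD_dysbiotic"])]
    if hd.nunique() == 2 and len(hd) >= 20:
        auc = classify_auc(sulfur_counts.loc[hd.index], hd)
        report["sulfur_auc_healthy_vs_dysbiotic"] = auc.auc
        exposure = (hd == "IBD_dysbiotic").astype(float)
        med = mediation_analysis(
            sulfur_counts.loc[hd.index].astype(float),
            exposure,
            has_degrader.loc[hd.index].astype(float),
            n_boot=config.n_boot,
            seed=_sub_seed(config.seed, 4),
        )
        report["mediation"] = {
            "proportion_mediated": med.proportion_mediated,
            "proportion_ci": med.proportion_ci,
            "indirect": med.indirect, "indirect_ci": med.ci,
            "total": med.total, "direct": med.direct,
            "z": med.z, "p": med.p, "n_bootstrap": med.n_bootstrap, "n": med.n,
        }

    end_products = [m for m in SULFUR_END_PRODUCTS if m in secretion.columns]
    if end_products:
        pattern, _ = fisher_secretion_screen(
            secretion[end_products] > config.tau, group, config.fdr_alpha
        )
        pattern.to_csv(stats_dir / "sulfur_end_products.tsv", sep="\t", index=False)

    dn = group[group.isin(["IBD_nondysbiotic", "IBD_dysbiotic"])]
    secreted_any = secretion.columns[(secretion > config.tau).any(axis=0)]
    if dn.nunique() == 2 and len(secreted_any):
        rf = rf_stratify(
            secretion.loc[dn.index, secreted_any], dn,
            n_trees=config.n_trees, seed=_sub_seed(config.seed, 5),
        )
        report["rf_oob_error"] = rf.oob_error
        rf.feature_ranking.head(15).to_csv(
            stats_dir / "rf_top_features.tsv", sep="\t"
        )

    aa_cols = [m for m in AA_METABOLITES if m in secretion.columns]
    in_silico = directions_from_screen(
        screen_dys[screen_dys["feature_id"].isin(aa_cols)], config.fdr_alpha
    )
    sig = in_silico[in_silico.isin(["up", "down"])]
    if len(sig) >= 2:
        reference = generate_metabolomic_reference(
            list(sig.index), list(sig.values),
            noise_rate=config.reference_noise_rate,
            seed=_sub_seed(config.seed, 3),
        )
        agreement = direction_agreement(in_silico, reference)
        report["direction_agreement"] = {
            "n_agree": agreement.n_agree,
            "n_disagree": agreement.n_disagree,
            "percent": agreement.percent_agreement,
            "binomial_p": agreement.binomial_p,
            "fisher_p": agreement.fisher_p,
            "reported": agreement.reported,
        }

    with open(stats_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)

    manifest = {
        "config_hash": config_hash,
        "seed": config.seed,
        "n_samples": len(table.sample_ids),
        "n_profiled": len(profiles),
        "failures": failures,
        "n_lp_solved": n_lp,
        "elapsed_seconds": round(time.time() - t_start, 2),
        "n_contributions": int(len(contributions.records)),
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
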