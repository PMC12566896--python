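"""End-to-end orchestration: tables in, signal/cluster artifacts out.

Stages, mirroring the analysis flow: read DRUG/REAC(/DEMO/THER) -> integrate
-> deduplicate -> monotherapy filter -> steroid cohort (SMARTS + allowlist,
optional market filter) -> term set -> ROR/Fisher screen -> stratified and
class summaries -> drug x term ln-ROR matrix -> PCA -> Ward clustering ->
exports.  Per-stage row counts are logged and returned so the reduction
chain can be audited.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from thrombosignal import cohort as cohort_mod
from thrombosignal import io, profiles, signals, terms

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and switches for one pipeline run."""

    drug_path: str
    reac_path: str
    demo_path: str | None = None
    ther_path: str | None = None
    smiles_path: str | None = None
    classes_path: str | None = None
    terms_path: str | None = None
    allowlist_path: str | None = None
    out_dir: str = "out"
    dialect: str = "$"
    alpha: float = 0.05
    min_drug_reports: int = 1000
    min_pt_reports: int = 2000
    n_components: int = 3
    n_clusters: int = 4
    monotherapy: bool = True
    bh: bool = False
    covariance_pca: bool = False
    market_cutoff_year: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for v, label in [(self.min_drug_reports, "min_drug_reports"),
                         (self.min_pt_reports, "min_pt_reports"),
                         (self.n_components, "n_components"),
                         (self.n_clusters, "n_clusters")]:
            if v <= 0:
                raise ValueError(f"{label} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class PipelineResult:
    """In-memory artifacts of a run plus the stage row-count chain."""

    results: pd.DataFrame
    strata: pd.DataFrame | None
    age: signals.AgeComparison | None
    class_table: pd.DataFrame | None
    matrix: pd.DataFrame | None
    pca: profiles.ScaledPCA | None
    tree: profiles.ClusterTree | None
    counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)

    counts: dict[str, int] = {}

    drug = io.read_table(config.drug_path, "drug", config.dialect)
    reac = io.read_table(config.reac_path, "reac", config.dialect)
    counts["drug_rows"] = len(drug)
    counts["reac_rows"] = len(reac)

    rows = io.integrate(drug, reac)
    counts["integrated_rows"] = len(rows)
    rows = io.deduplicate(rows)
    counts["deduplicated_rows"] = len(rows)
    if config.monotherapy:
        rows = io.monotherapy_filter(rows)
    counts["monotherapy_rows"] = len(rows)
    for stage, n in counts.items():
        logger.info("stage %s: %d rows", stage, n)

    # --- cohort -----------------------------------------------------------
    names = set(rows["drug_name"].unique())
    if config.smiles_path:
        smiles = cohort_mod.load_smiles_dictionary(config.smiles_path)
        allow = (cohort_mod.load_allowlist(config.allowlist_path)
                 if config.allowlist_path else set())
        cohort_result = cohort_mod.build_cohort(names, smiles,
                                                allowlist=allow)
        cohort = cohort_result.cohort
        cohort_result.to_frame().to_csv(out / "cohort.csv", index=False)
    else:
        cohort = names
    if config.market_cutoff_year and config.ther_path:
        ther = io.read_table(config.ther_path, "ther", config.dialect)
        recent = cohort_mod.market_filter(ther, config.market_cutoff_year)
        cohort &= recent
    counts["cohort_drugs"] = len(cohort)
    if not cohort:
        raise ValueError("steroid cohort is empty; nothing to screen")

    term_set = (terms.load_term_set(config.terms_path)
                if config.terms_path else terms.default_term_set())

    # --- screen -----------------------------------------------------------
    screen = signals.RorSignalScreen(
        term_set=term_set, cohort=sorted(cohort), alpha=config.alpha,
        min_drug_reports=config.min_drug_reports, bh=config.bh).fit(rows)
    results = screen.results_
    results.to_csv(out / "signals.csv", index=False)
    signals.volcano_plot(results, out / "volcano.png", alpha=config.alpha)
    counts["flagged_drugs"] = len(screen.flagged_drugs_)
    logger.info("flagged %d of %d cohort drugs",
                counts["flagged_drugs"], counts["cohort_drugs"])

    # --- demographics / strata --------------------------------------------
    strata_df = None
    age = None
    if config.demo_path:
        demo = io.read_table(config.demo_path, "demo", config.dialect)
        cohort_rows = rows[rows["drug_name"].isin(cohort)]
        sex_map = demo.set_index("case_id")["sex"]
        sex_map = sex_map[sex_map.isin(["F", "M"])]
        strata_df = signals.stratified_ror(cohort_rows, sex_map, term_set)
        strata_df.insert(0, "stratifier", "sex")
        if "age_years" in demo.columns:
            try:
                age = signals.age_comparison(cohort_rows, demo, term_set)
            except ValueError:
                logger.warning("age comparison skipped: a group is empty")
        strata_df.to_csv(out / "strata.csv", index=False)

    class_table = None
    class_map = (cohort_mod.load_class_map(config.classes_path)
                 if config.classes_path else cohort_mod.default_class_map())
    if len(results):
        class_table = signals.class_summary(results, class_map)
        class_table.to_csv(out / "class_summary.csv", index=False)

    # --- multivariate ------------------------------------------------------
    matrix = model = tree = None
    flagged = screen.flagged_drugs_
    if len(flagged) >= 2:
        pts = sorted(term_set.pts & set(rows["pt"].unique()))
        try:
            matrix = profiles.build_matrix(rows, flagged, pts,
                                           config.min_pt_reports)
        except ValueError as exc:
            logger.warning("signal matrix skipped: %s", exc)
        if matrix is not None and matrix.shape[1] >= 2:
            matrix.to_csv(out / "matrix.csv")
            k = min(config.n_components, *matrix.shape)
            model = profiles.pca(matrix, k=k,
                                 scale=not config.covariance_pca)
            model.scores_.to_csv(out / "pca_scores.csv")
            model.loadings_.to_csv(out / "pca_loadings.csv")
            pd.DataFrame({"component": model.scores_.columns,
                          "explained_ratio": model.explained_ratio_}
                         ).to_csv(out / "explained.csv", index=False)
            n_clusters = min(config.n_clusters, len(flagged))
            clusterer = profiles.WardClusterer(
                n_clusters=n_clusters,
                n_components=config.n_components).fit(model.scores_)
            tree = clusterer.tree_
            profiles.export_dendrogram(tree, model.scores_, out,
                                       n_clusters=n_clusters)
    else:
        logger.warning("fewer than 2 flagged drugs; multivariate stage "
                       "skipped")

    io.write_integrated(rows, out / "integrated.csv")
    with open(out / "run_log.txt", "w") as fh:
        for stage, n in counts.items():
            fh.write(f"{stage}\t{n}\n")
    return PipelineResult(results=results, strata=strata_df, age=age,
                          class_table=class_table, matrix=matrix,
                          pca=model, tree=tree, counts=counts)
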