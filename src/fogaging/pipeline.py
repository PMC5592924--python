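"""End-to-end pipeline: simulate/load -> fit -> classify -> epistasis -> enrich.

Every stage writes its table under the configured output directory and a
plain-text manifest records versions, parameters and the seed, so a run can
be reproduced exactly from the manifest alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

import fogaging
from fogaging import enrichment, epistasis, glm, io, signatures, simulate

log = logging.getLogger("fogaging")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; flags of the CLI mirror these fields."""

    output_dir: str = "results"
    expression_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    feature_map_path: str | None = None
    q_threshold: float = 0.1
    pseudocount: float = 0.5
    tolerance: float = 0.25
    n_bootstrap: int = 1000
    seed: int = 0
    # simulation settings, used when no expression path is given
    n_features: int = 2000
    replicates_per_cell: int = 3
    effect_scale: float = 1.5
    dispersion: float = 0.05
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(simulate.DEFAULT_PROPORTIONS)
    )

    def __post_init__(self) -> None:
        if not (0 < self.q_threshold < 1):
            raise ValueError(f"q_threshold must be in (0, 1), got {self.q_threshold!r}")
        if self.pseudocount < 0:
            raise ValueError(f"pseudocount must be >= 0, got {self.pseudocount!r}")
        if not (0 <= self.tolerance < 1):
            raise ValueError(f"tolerance must be in [0, 1), got {self.tolerance!r}")
        if self.n_bootstrap < 0:
            raise ValueError(f"n_bootstrap must be >= 0, got {self.n_bootstrap!r}")
        if (self.expression_path is None) != (self.design_path is None):
            raise ValueError("expression_path and design_path must be given together")


def _stage(name):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate failures with the stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return run

    return wrap


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and return a name -> path map of written outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def save(name: str, table: pd.DataFrame, index_label: str | None = None) -> None:
        path = out / f"{name}.tsv"
        io.write_table(table, path, index_label=index_label)
        written[name] = path

    feature_map = (
        io.read_feature_map(config.feature_map_path) if config.feature_map_path else None
    )

    truth = None
    if config.expression_path is None:
        log.info("simulating %d features (seed %d)", config.n_features, config.seed)
        sim_config = simulate.SimulationConfig(
            n_features=config.n_features,
            replicates_per_cell=config.replicates_per_cell,
            class_proportions=config.class_proportions,
            effect_scale=config.effect_scale,
            dispersion=config.dispersion,
            seed=config.seed,
        )
        expression, design, truth = _stage("simulate")(simulate.simulate_dataset)(sim_config)
        save("expression", expression)
        save("design", design, index_label="sample")
        save("truth", truth)
    else:
        expression = _stage("load")(io.read_expression)(config.expression_path)
        design = _stage("load")(io.read_design)(config.design_path)

    log.info("fitting GLM for %d features", len(expression))
    coeffs = _stage("fit")(glm.fit_all)(expression, design, config.pseudocount)
    save("coefficients", coeffs)

    sets = _stage("signatures")(glm.call_signatures)(
        coeffs, config.q_threshold, feature_map
    )
    sig_table = pd.DataFrame(
        {
            "signature": ["aging", "genotype", "interaction"],
            "n_features": [
                len(sets.aging_features),
                len(sets.genotype_features),
                len(sets.interaction_features),
            ],
            "n_genes": [
                len(sets.aging_genes),
                len(sets.genotype_genes),
                len(sets.interaction_genes),
            ],
        }
    ).set_index("signature")
    save("signatures", sig_table)

    labels = _stage("classify")(signatures.classify_table)(
        coeffs, config.q_threshold, config.tolerance
    )
    save("classification", labels.to_frame())
    selection = _stage("classify")(signatures.select_female_state)(
        coeffs, config.q_threshold, feature_map
    )
    io.write_gene_list(selection.features, out / "female_state_features.txt")
    written["female_state_features"] = out / "female_state_features.txt"

    fit = None
    try:
        points = _stage("epistasis")(epistasis.build_epistasis_points)(
            coeffs, q_threshold=config.q_threshold
        )
    except RuntimeError as exc:
        log.warning("%s; skipping the epistasis stage", exc)
    else:
        fit = _stage("epistasis")(epistasis.fit_epistasis_line)(
            points, n_bootstrap=config.n_bootstrap, seed=config.seed
        )
        save("epistasis_points", points)
        summary = pd.DataFrame(
            [
                {
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "slope_se": fit.slope_se,
                    "n_points": fit.n_points,
                    "n_bootstrap": fit.n_bootstrap,
                    "seed": config.seed,
                }
            ]
        ).set_index(pd.Index(["fit"], name="name"))
        save("epistasis_fit", summary)
        _stage("epistasis")(epistasis.plot_epistasis)(fit, out / "epistasis_plot.png")
        written["epistasis_plot"] = out / "epistasis_plot.png"

    if config.annotation_path:
        annotations = _stage("enrich")(enrichment.read_gmt)(config.annotation_path)
        table = _stage("enrich")(enrichment.enrich)(selection.genes, annotations)
        save("enrichment", table)

    manifest = out / "manifest.txt"
    with open(manifest, "w", encoding="utf-8") as fh:
        fh.write(f"fogaging_version\t{fogaging.__version__}\n")
        fh.write(f"pandas_version\t{pd.__version__}\n")
        for key, value in asdict(config).items():
            fh.write(f"{key}\t{value}\n")
    written["manifest"] = manifest
    return written
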