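"""Pipeline orchestration: config validation, stage composition, logging.

Ties the stages into the two analysis tracks of a tracer-metabolomics
study: the steady-state comparison track (normalize → fold change →
t-tests → PCA → lactate–2HG correlation) and the flux track (natural-
abundance correction → tracked enrichment → flux estimation → group
comparison).  A run is driven by a single :class:`PipelineConfig`; every
random draw flows from its seed, and the run log records the package
version, a hash of the resolved config, and per-stage record counts so
each output row is traceable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correction import (
    CorrectionMatrix,
    IsotopeTable,
    build_correction_matrix,
    correct_mid,
    load_isotope_table,
    parse_formula,
    tracked_label_fraction,
)
from .errors import ComputationError, ValidationError
from .io import (
    read_mid_table,
    read_pool_table,
    read_sample_table,
    write_mid_table,
    write_pool_table,
    write_sample_table,
)
from .kinetics import TracerProtocol, compare_flux_groups, estimate_cohort_flux
from .simulate import (
    ScenarioConfig,
    generate_cohort,
    generate_labeling_experiment,
    get_scenario,
)
from .stats import (
    SampleTable,
    compare_to_control,
    fold_change_vs_control,
    normalize_table,
    pca_scores,
    pearson_correlation,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "correct_mid_table",
    "load_pipeline_config",
]

log = logging.getLogger(__name__)

_KNOWN_TOP = {
    "seed", "scenario", "inputs", "output_dir", "protocol",
    "statistics", "correction",
}
_KNOWN_INPUTS = {"sample_table", "sample_table_dialect", "mid_table", "pool_table"}
_KNOWN_STATS = {"alpha", "m", "scaling", "control_group", "correlate"}
_KNOWN_CORRECTION = {"method", "purity", "isotope_file"}


@dataclass
class PipelineConfig:
    """Validated full-pipeline configuration."""

    output_dir: Path
    seed: int = 0
    scenario: str | None = None
    sample_table: Path | None = None
    sample_table_dialect: str = "wide"
    mid_table: Path | None = None
    pool_table: Path | None = None
    protocol: TracerProtocol = field(default_factory=TracerProtocol)
    alpha: float = 0.05
    m: int | None = None
    scaling: str = "autoscale"
    control_group: str | None = None
    correlate: tuple[str, str] = ("lactate", "2HG")
    method: str = "nnls"
    purity: float = 1.0
    isotope_file: Path | None = None

    @classmethod
    def from_dict(cls, d: dict, base_dir: Path | None = None) -> "PipelineConfig":
        base = Path(base_dir) if base_dir else Path.cwd()
        if unknown := set(d) - _KNOWN_TOP:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        inputs = d.get("inputs") or {}
        if unknown := set(inputs) - _KNOWN_INPUTS:
            raise ValidationError(f"unknown inputs keys: {sorted(unknown)}")
        stats = d.get("statistics") or {}
        if unknown := set(stats) - _KNOWN_STATS:
            raise ValidationError(f"unknown statistics keys: {sorted(unknown)}")
        corr = d.get("correction") or {}
        if unknown := set(corr) - _KNOWN_CORRECTION:
            raise ValidationError(f"unknown correction keys: {sorted(unknown)}")
        if "output_dir" not in d:
            raise ValidationError("config requires output_dir")
        proto = d.get("protocol") or {}
        protocol = TracerProtocol(**proto) if proto else TracerProtocol()

        def _path(val):
            if val is None:
                return None
            p = Path(val)
            return p if p.is_absolute() else base / p

        cfg = cls(
            output_dir=_path(d["output_dir"]),
            seed=int(d.get("seed", 0)),
            scenario=d.get("scenario"),
            sample_table=_path(inputs.get("sample_table")),
            sample_table_dialect=inputs.get("sample_table_dialect", "wide"),
            mid_table=_path(inputs.get("mid_table")),
            pool_table=_path(inputs.get("pool_table")),
            protocol=protocol,
            alpha=float(stats.get("alpha", 0.05)),
            m=stats.get("m"),
            scaling=stats.get("scaling", "autoscale"),
            control_group=stats.get("control_group"),
            correlate=tuple(stats.get("correlate", ("lactate", "2HG"))),
            method=corr.get("method", "nnls"),
            purity=float(corr.get("purity", 1.0)),
            isotope_file=_path(corr.get("isotope_file")),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.scenario is None and self.sample_table is None:
            raise ValidationError(
                "config must name a scenario or provide inputs.sample_table"
            )
        if self.scenario is not None and self.sample_table is not None:
            raise ValidationError("provide either a scenario or input files, not both")
        for name in ("sample_table", "mid_table", "pool_table", "isotope_file"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{name} does not exist: {p}")
        if (self.mid_table is None) != (self.pool_table is None):
            raise ValidationError("mid_table and pool_table must be given together")
        if self.scaling not in ("autoscale", "center_only"):
            raise ValidationError(f"unknown scaling {self.scaling!r}")
        if self.method not in ("nnls", "pinv"):
            raise ValidationError(f"unknown correction method {self.method!r}")
        if not 0 < self.purity <= 1:
            raise ValidationError("purity must be in (0, 1]")

    def resolved_dict(self) -> dict:
        return {
            "seed": self.seed,
            "scenario": self.scenario,
            "inputs": {
                "sample_table": str(self.sample_table) if self.sample_table else None,
                "sample_table_dialect": self.sample_table_dialect,
                "mid_table": str(self.mid_table) if self.mid_table else None,
                "pool_table": str(self.pool_table) if self.pool_table else None,
            },
            "output_dir": str(self.output_dir),
            "protocol": {
                "p": self.protocol.p,
                "t": self.protocol.t,
                "tracer_element": self.protocol.tracer_element,
                "tracked_m": dict(self.protocol.tracked_m),
            },
            "statistics": {
                "alpha": self.alpha,
                "m": self.m,
                "scaling": self.scaling,
                "control_group": self.control_group,
                "correlate": list(self.correlate),
            },
            "correction": {
                "method": self.method,
                "purity": self.purity,
                "isotope_file": str(self.isotope_file) if self.isotope_file else None,
            },
        }

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.resolved_dict(), sort_keys=True)
        return hashlib.sha256(text.encode("utf-8")).hexdigest()[:16]


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValidationError(f"{path.name}: config must be a mapping")
    return PipelineConfig.from_dict(d, base_dir=path.parent)


def correct_mid_table(
    mid_df: pd.DataFrame,
    protocol: TracerProtocol,
    isotopes: IsotopeTable | None = None,
    method: str = "nnls",
    purity: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Natural-abundance-correct every (sample, metabolite) MID in a table.

    Returns (corrected long table with fraction per m_shift and the fit
    residual, enrichment table with the tracked-isotopologue fraction per
    sample and metabolite).
    """
    if isotopes is None:
        isotopes = load_isotope_table()
    matrices: dict[str, CorrectionMatrix] = {}
    corrected_rows, enrich_rows = [], []
    for (sample_id, metab), grp in mid_df.groupby(
        ["sample_id", "metabolite"], sort=True
    ):
        if metab not in protocol.tracked_m:
            raise ValidationError(f"no tracked isotopologue configured for {metab!r}")
        n_label = protocol.tracked_m[metab]
        formula = str(grp["fragment_formula"].iloc[0])
        tracer_el = str(grp["tracer_element"].iloc[0])
        key = f"{metab}|{formula}|{tracer_el}"
        if key not in matrices:
            matrices[key] = build_correction_matrix(
                parse_formula(formula), tracer_el, n_label, isotopes,
                tracer_purity=purity,
            )
        A = matrices[key]
        grp = grp.sort_values("m_shift")
        shifts = grp["m_shift"].to_numpy()
        if not np.array_equal(shifts, np.arange(A.max_shift + 1)):
            raise ValidationError(
                f"sample {sample_id!r} metabolite {metab!r}: expected "
                f"m_shift 0..{A.max_shift}, got {shifts.tolist()}"
            )
        corrected = correct_mid(grp["intensity"].to_numpy(), A, method=method)
        group = str(grp["group"].iloc[0]) if "group" in grp else ""
        for shift, frac in enumerate(corrected.values):
            corrected_rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "metabolite": metab,
                    "m_shift": shift,
                    "fraction": frac,
                    "residual": corrected.residual,
                }
            )
        enrich_rows.append(
            {
                "sample_id": sample_id,
                "group": group,
                "metabolite": metab,
                "enrichment": tracked_label_fraction(corrected, n_label),
            }
        )
    return pd.DataFrame(corrected_rows), pd.DataFrame(enrich_rows)


def _write(df: pd.DataFrame, path: Path, counts: dict, name: str) -> None:
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    counts[name] = len(df)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the configured tracks and write all result tables.

    Returns a mapping of output name to written path.  Any stage failure
    aborts with the stage name attached; outputs are deterministic given
    the config (byte-identical across reruns).
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    outputs: dict[str, Path] = {}
    stage = "setup"
    isotopes = load_isotope_table(config.isotope_file)
    try:
        # ---- inputs ----------------------------------------------------
        stage = "inputs"
        scenario_cfg: ScenarioConfig | None = None
        mid_df = pool_df = None
        if config.scenario:
            scenario_cfg = get_scenario(config.scenario, seed=config.seed)
            table = generate_cohort(scenario_cfg)
            write_sample_table(table, out_dir / "sample_table.csv")
            outputs["sample_table"] = out_dir / "sample_table.csv"
            counts["sample_table"] = len(table.data)
            if scenario_cfg.flux_f:
                mid_df, pool_df = generate_labeling_experiment(
                    scenario_cfg, isotopes=isotopes
                )
                write_mid_table(mid_df, out_dir / "mid_table.csv")
                write_pool_table(pool_df, out_dir / "pool_table.csv")
                outputs["mid_table"] = out_dir / "mid_table.csv"
                outputs["pool_table"] = out_dir / "pool_table.csv"
        else:
            table = read_sample_table(
                config.sample_table, dialect=config.sample_table_dialect
            )
            if config.mid_table:
                mid_df = read_mid_table(config.mid_table)
                pool_df = read_pool_table(config.pool_table)
        control = config.control_group or (
            scenario_cfg.control_group if scenario_cfg else None
        )
        if not control:
            raise ValidationError("no control group configured")

        # ---- comparison track ------------------------------------------
        stage = "normalize"
        normalized = normalize_table(table)
        df = normalized.data.reset_index()
        _write(df, out_dir / "normalized_table.csv", counts, "normalized_table")
        outputs["normalized_table"] = out_dir / "normalized_table.csv"

        stage = "fold_change"
        rel = fold_change_vs_control(normalized, control)
        _write(
            rel.reset_index(), out_dir / "relative_abundance.csv",
            counts, "relative_abundance",
        )
        outputs["relative_abundance"] = out_dir / "relative_abundance.csv"

        stage = "ttests"
        comparisons = []
        for group in normalized.groups:
            if group == control:
                continue
            comparisons.append(
                compare_to_control(
                    normalized, control, test_group=group,
                    m=config.m, alpha=config.alpha,
                )
            )
        comparison = pd.concat(comparisons, ignore_index=True)
        _write(comparison, out_dir / "comparison.csv", counts, "comparison")
        outputs["comparison"] = out_dir / "comparison.csv"

        stage = "pca"
        pca = pca_scores(normalized, scaling=config.scaling)
        _write(
            pca.scores.reset_index(), out_dir / "pca_scores.csv",
            counts, "pca_scores",
        )
        loadings = pca.loadings.reset_index(names="metabolite")
        _write(loadings, out_dir / "pca_loadings.csv", counts, "pca_loadings")
        variance = pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in
                              range(len(pca.explained_variance_ratio))],
                "explained_variance_ratio": pca.explained_variance_ratio,
            }
        )
        _write(variance, out_dir / "pca_variance.csv", counts, "pca_variance")
        outputs["pca_scores"] = out_dir / "pca_scores.csv"
        outputs["pca_loadings"] = out_dir / "pca_loadings.csv"
        outputs["pca_variance"] = out_dir / "pca_variance.csv"

        stage = "correlation"
        x_name, y_name = config.correlate
        if x_name in normalized.metabolites and y_name in normalized.metabolites:
            r, p = pearson_correlation(
                normalized.data[x_name].to_numpy(float),
                normalized.data[y_name].to_numpy(float),
            )
            corr = pd.DataFrame(
                [{"x": x_name, "y": y_name, "r": r, "p": p,
                  "n": len(normalized.data)}]
            )
            _write(corr, out_dir / "correlation.csv", counts, "correlation")
            outputs["correlation"] = out_dir / "correlation.csv"

        # ---- flux track -------------------------------------------------
        if mid_df is not None:
            stage = "correction"
            corrected, enrichments = correct_mid_table(
                mid_df, config.protocol, isotopes=isotopes,
                method=config.method, purity=config.purity,
            )
            _write(corrected, out_dir / "corrected_mids.csv", counts, "corrected_mids")
            outputs["corrected_mids"] = out_dir / "corrected_mids.csv"

            stage = "flux_estimation"
            flux = estimate_cohort_flux(enrichments, pool_df, config.protocol)
            _write(flux, out_dir / "flux_estimates.csv", counts, "flux_estimates")
            outputs["flux_estimates"] = out_dir / "flux_estimates.csv"

            stage = "flux_comparison"
            flux_cmp = compare_flux_groups(
                flux, control, alpha=config.alpha, m=config.m
            )
            _write(
                flux_cmp, out_dir / "flux_comparison.csv", counts, "flux_comparison"
            )
            outputs["flux_comparison"] = out_dir / "flux_comparison.csv"
    except ValidationError:
        raise
    except Exception as exc:  # attach the failing stage
        raise ComputationError(f"stage {stage!r} failed: {exc}") from exc

    # ---- provenance -----------------------------------------------------
    resolved = config.resolved_dict()
    with open(out_dir / "resolved_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    outputs["resolved_config"] = out_dir / "resolved_config.yaml"
    log_lines = [
        f"midflux version: {__version__}",
        f"config hash: {config.config_hash()}",
        f"seed: {config.seed}",
    ] + [f"records[{k}]: {v}" for k, v in sorted(counts.items())]
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    outputs["run_log"] = out_dir / "run_log.txt"
    log.info("pipeline finished: %d outputs in %s", len(outputs), out_dir)
    return outputs
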