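"""Synthetic cohorts and labeling experiments with controlled structure.

The generator emulates targeted GC-MS studies of pooled *Drosophila*
larval samples: two-genotype cohorts of 5–6 biological replicates, each a
pool of ~15 mid-L3 larvae, with multiplicative group effects and
log-normal measurement noise, plus single-timepoint 13C6-glucose labeling
experiments (50% tracer enrichment, 2 h) whose raw isotopologue vectors
carry natural-abundance convolution.  Scenario presets mirror the
experimental designs the analysis pipeline is meant for: a mitochondrial
citrate-carrier (sea/CIC) mutant against its control, glycolysis
knockdown, citrate feeding, Ldh knockdown and an L2HGDH-null double
mutant.

Every sampled number flows from the single scenario seed, so identical
configs produce byte-identical tables.  Lactate and 2HG are linked by a
phenomenological linear-in-logs coupling (2HG log-intensity follows the
lactate log-deviation plus independent residual noise), reproducing the
high lactate–2HG correlation seen in larval extracts with an analytically
known Pearson r.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .correction import (
    IsotopeTable,
    build_correction_matrix,
    load_isotope_table,
    parse_formula,
)
from .errors import ValidationError
from .kinetics import TracerProtocol, forward_labeled_fraction
from .stats import SampleTable

__all__ = [
    "ScenarioConfig",
    "generate_cohort",
    "generate_labeling_experiment",
    "list_scenarios",
    "get_scenario",
    "analytic_coupling_r",
    "SCENARIOS",
]

#: underivatized carbon-skeleton formulas of the GC-MS fragments; real
#: fragments may carry TMS derivatization atoms — supply your own formulas
#: for instrument-matched correction
DEFAULT_FORMULAS = {
    "pyruvate": "C3H4O3",
    "lactate": "C3H6O3",
    "2HG": "C5H8O5",
    "citrate": "C6H8O7",
}

#: baseline peak intensities (arbitrary units) for a larval-pool panel
DEFAULT_BASELINES = {
    "pyruvate": 800.0,
    "lactate": 5000.0,
    "2HG": 1500.0,
    "citrate": 2500.0,
    "2OG": 600.0,
    "succinate": 900.0,
    "fumarate": 700.0,
    "malate": 1800.0,
}


def _cv_to_sigma(cv: float) -> float:
    """Log-space sd of a log-normal with the given coefficient of variation."""
    return math.sqrt(math.log1p(cv * cv))


@dataclass
class ScenarioConfig:
    """Full description of a synthetic study.

    ``multipliers[group][metabolite]`` scales that group's mean away from
    ``baselines[metabolite]`` (unlisted entries default to 1).  ``cv`` is
    the multiplicative measurement noise of metabolite intensities;
    ``mass_cv`` and ``response_cv`` are the spreads of the larval-pool wet
    mass and of the per-sample instrument response factor (which scales
    metabolite and internal-standard intensities alike, making IS
    normalization meaningful).  ``coupling_slope``/``coupling_resid_sd``
    control the lactate→2HG log-space coupling; ``flux_f``, ``pools`` and
    ``protocol`` parameterize labeling experiments.
    """

    name: str = "custom"
    description: str = ""
    groups: dict[str, int] = field(default_factory=dict)
    control_group: str = ""
    baselines: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    cv: float = 0.10
    coupling_slope: float = 1.0
    coupling_resid_sd: float = 0.0237
    nominal_mass_mg: float = 25.0
    mass_cv: float = 0.10
    is_nominal_intensity: float = 1e5
    response_cv: float = 0.05
    flux_f: dict[str, dict[str, float]] = field(default_factory=dict)
    pools: dict[str, float] = field(default_factory=dict)
    formulas: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_FORMULAS))
    protocol: TracerProtocol = field(default_factory=TracerProtocol)
    tracer_purity: float = 1.0
    mid_intensity_scale: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("scenario must declare at least one group")
        if any(n < 2 for n in self.groups.values()):
            raise ValidationError("each group needs n >= 2 samples")
        if self.cv < 0 or self.mass_cv < 0 or self.response_cv < 0:
            raise ValidationError("noise CVs must be >= 0")
        if self.control_group and self.control_group not in self.groups:
            raise ValidationError(
                f"control group {self.control_group!r} not among groups "
                f"{sorted(self.groups)}"
            )
        for group in self.multipliers:
            if group not in self.groups:
                raise ValidationError(
                    f"multipliers reference unknown group {group!r}"
                )
        for group, mults in self.multipliers.items():
            for metab, x in mults.items():
                if metab not in self.baselines:
                    raise ValidationError(
                        f"multiplier for unknown metabolite {metab!r}"
                    )
                if not x > 0:
                    raise ValidationError("multipliers must be positive")
        if self.seed is None:
            raise ValidationError("a seed is mandatory for reproducibility")

    def multiplier(self, group: str, metabolite: str) -> float:
        return self.multipliers.get(group, {}).get(metabolite, 1.0)

    # -- plain-dict round trip (for YAML provenance files) ------------------
    def to_dict(self) -> dict:
        d = {
            k: copy.deepcopy(getattr(self, k))
            for k in self.__dataclass_fields__
            if k != "protocol"
        }
        d["protocol"] = {
            "p": self.protocol.p,
            "t": self.protocol.t,
            "tracer_element": self.protocol.tracer_element,
            "tracked_m": dict(self.protocol.tracked_m),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = copy.deepcopy(d)
        known = set(cls.__dataclass_fields__)
        if unknown := set(d) - known:
            raise ValidationError(f"unknown scenario config keys: {sorted(unknown)}")
        if isinstance(d.get("protocol"), dict):
            d["protocol"] = TracerProtocol(**d["protocol"])
        return cls(**d)


def analytic_coupling_r(config: ScenarioConfig) -> float:
    """Within-group Pearson r between log lactate and log 2HG implied by
    the configured coupling slope and residual sd."""
    s = config.coupling_slope
    sigma_l = _cv_to_sigma(config.cv)
    denom = math.hypot(s * sigma_l, config.coupling_resid_sd)
    if denom == 0:
        raise ValidationError("coupling correlation undefined at zero noise")
    return s * sigma_l / denom


def _iter_samples(config: ScenarioConfig) -> Iterator[tuple[str, str]]:
    for group, n in config.groups.items():
        for i in range(n):
            yield group, f"{group}_{i + 1}"


def generate_cohort(
    config: ScenarioConfig, with_latent: bool = False
) -> SampleTable | tuple[SampleTable, pd.DataFrame]:
    """Draw a steady-state cohort as a wide sample table.

    Per sample: wet mass and instrument response are log-normal around
    their nominals; each metabolite intensity is baseline x group
    multiplier x (mass / nominal mass) x response x log-normal noise.  2HG
    replaces its independent noise with ``slope x (lactate log-deviation) +
    residual``, giving a controllable lactate–2HG correlation.  With
    ``with_latent=True`` also returns the latent per-sample metabolite
    amounts (before mass/response scaling), useful for verifying the
    generator itself.
    """
    rng = np.random.default_rng(config.seed)
    metabolites = list(config.baselines)
    couple = "lactate" in metabolites and "2HG" in metabolites
    sigma = _cv_to_sigma(config.cv)
    sigma_mass = _cv_to_sigma(config.mass_cv)
    sigma_resp = _cv_to_sigma(config.response_cv)
    rows, latents = [], []
    for group, sample_id in _iter_samples(config):
        mass = config.nominal_mass_mg * math.exp(sigma_mass * rng.standard_normal())
        response = math.exp(sigma_resp * rng.standard_normal())
        z = {m: rng.standard_normal() for m in metabolites}
        log_dev = {m: sigma * z[m] for m in metabolites}
        if couple:
            eps = config.coupling_resid_sd * rng.standard_normal()
            log_dev["2HG"] = config.coupling_slope * log_dev["lactate"] + eps
        latent = {
            m: config.baselines[m]
            * config.multiplier(group, m)
            * math.exp(log_dev[m])
            for m in metabolites
        }
        row = {
            "sample_id": sample_id,
            "group": group,
            "mass_mg": mass,
            "is_intensity": config.is_nominal_intensity * response,
        }
        scale = (mass / config.nominal_mass_mg) * response
        row.update({m: latent[m] * scale for m in metabolites})
        rows.append(row)
        latents.append({"sample_id": sample_id, "group": group, **latent})
    data = pd.DataFrame(rows).set_index("sample_id")
    table = SampleTable(data=data, normalized=False)
    if with_latent:
        return table, pd.DataFrame(latents).set_index("sample_id")
    return table


def generate_labeling_experiment(
    config: ScenarioConfig,
    isotopes: IsotopeTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a single-timepoint tracer experiment.

    For every sample and every metabolite with a configured flux: the
    sample's pool is log-normal around the configured ``X_T``; the true
    enrichment follows the exponential labeling model at that pool; the
    true labeling state puts all label mass in the tracked isotopologue;
    the observed raw MID is the natural-abundance correction matrix applied
    to that state, scaled and perturbed by per-channel log-normal noise.
    Returns (raw isotopologue long table, pool long table) — exactly the
    inputs the correction and flux stages consume.
    """
    if not config.flux_f:
        raise ValidationError("scenario has no flux parameters configured")
    if isotopes is None:
        isotopes = load_isotope_table()
    protocol = config.protocol
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sigma = _cv_to_sigma(config.cv)
    matrices = {}
    for group, fluxes in config.flux_f.items():
        if group not in config.groups:
            raise ValidationError(f"flux parameters reference unknown group {group!r}")
        for metab in fluxes:
            if metab not in protocol.tracked_m:
                raise ValidationError(
                    f"tracked isotopologue index missing for {metab!r}"
                )
            if metab not in config.pools:
                raise ValidationError(f"pool size missing for {metab!r}")
            if metab not in matrices:
                if metab not in config.formulas:
                    raise ValidationError(f"fragment formula missing for {metab!r}")
                matrices[metab] = build_correction_matrix(
                    parse_formula(config.formulas[metab]),
                    protocol.tracer_element,
                    protocol.tracked_m[metab],
                    isotopes,
                    tracer_purity=config.tracer_purity,
                )
    mid_rows, pool_rows = [], []
    for group, sample_id in _iter_samples(config):
        fluxes = config.flux_f.get(group, {})
        for metab in fluxes:
            A = matrices[metab]
            n_label = protocol.tracked_m[metab]
            X_T = config.pools[metab] * math.exp(sigma * rng.standard_normal())
            e = forward_labeled_fraction(fluxes[metab], protocol.t, X_T, protocol.p)
            true_state = np.zeros(n_label + 1)
            true_state[0] = 1.0 - e
            true_state[n_label] = e
            observed = A.matrix @ true_state * config.mid_intensity_scale
            noise = np.exp(sigma * rng.standard_normal(observed.shape[0]))
            observed = observed * noise
            for shift, intensity in enumerate(observed):
                mid_rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "metabolite": metab,
                        "fragment_formula": config.formulas[metab],
                        "tracer_element": protocol.tracer_element,
                        "m_shift": shift,
                        "intensity": intensity,
                    }
                )
            pool_rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "metabolite": metab,
                    "pool": X_T,
                }
            )
    return pd.DataFrame(mid_rows), pd.DataFrame(pool_rows)


def _make_scenarios() -> dict[str, ScenarioConfig]:
    panel = dict(DEFAULT_BASELINES)
    scenarios = {}
    scenarios["sea_mutant_vs_control"] = ScenarioConfig(
        name="sea_mutant_vs_control",
        description=(
            "Citrate-carrier (sea/CIC) hypomorph vs precise-excision "
            "control: glycolytic end products and L-2HG elevated, citrate "
            "depleted, 2OG and succinate unchanged."
        ),
        groups={"sea_prec_df": 5, "sea_d24_df": 5},
        control_group="sea_prec_df",
        baselines=panel,
        multipliers={
            "sea_d24_df": {
                "pyruvate": 2.0,
                "lactate": 2.5,
                "2HG": 3.0,
                "citrate": 0.5,
                "fumarate": 2.0,
                "malate": 2.0,
            }
        },
        cv=0.05,
        # residual sd tuned so the within-group log-space lactate-2HG
        # Pearson r is 0.973 at cv=0.05
        coupling_slope=1.0,
        coupling_resid_sd=0.0118544,
        seed=0,
    )
    scenarios["glucose_labeling_flux"] = ScenarioConfig(
        name="glucose_labeling_flux",
        description=(
            "50% 13C6-glucose feeding for 2 h, n=4 per genotype: mutant "
            "lactate flux 1.6x control, modest pyruvate/2HG increases, "
            "slight citrate decrease."
        ),
        groups={"sea_prec_df": 4, "sea_d24_df": 4},
        control_group="sea_prec_df",
        baselines=panel,
        multipliers={},
        cv=0.05,
        flux_f={
            "sea_prec_df": {"pyruvate": 20.0, "lactate": 30.0, "2HG": 6.0, "citrate": 25.0},
            "sea_d24_df": {"pyruvate": 24.0, "lactate": 48.0, "2HG": 7.5, "citrate": 20.0},
        },
        pools={"pyruvate": 40.0, "lactate": 100.0, "2HG": 60.0, "citrate": 120.0},
        seed=0,
    )
    scenarios["pfk_rnai"] = ScenarioConfig(
        name="pfk_rnai",
        description=(
            "Phosphofructokinase knockdown in the sea mutant background: "
            "~50% drops in pyruvate and lactate, ~75% drop in 2HG."
        ),
        groups={"sea_d24_df": 6, "sea_d24_df_pfk_rnai": 6},
        control_group="sea_d24_df",
        baselines=panel,
        multipliers={
            "sea_d24_df_pfk_rnai": {"pyruvate": 0.5, "lactate": 0.5, "2HG": 0.25}
        },
        seed=0,
    )
    scenarios["citrate_feeding"] = ScenarioConfig(
        name="citrate_feeding",
        description=(
            "Citrate-supplemented diet fed to sea mutants for 24 h: "
            "citrate accumulates while pyruvate, lactate and 2HG fall."
        ),
        groups={"sea_d24_df_control_diet": 6, "sea_d24_df_citrate_diet": 6},
        control_group="sea_d24_df_control_diet",
        baselines=panel,
        multipliers={
            "sea_d24_df_citrate_diet": {
                "citrate": 2.5,
                "pyruvate": 0.5,
                "lactate": 0.5,
                "2HG": 0.5,
            }
        },
        seed=0,
    )
    scenarios["dldh_rnai"] = ScenarioConfig(
        name="dldh_rnai",
        description=(
            "Lactate dehydrogenase knockdown in the sea mutant background: "
            "~60% reduction of both lactate and 2HG."
        ),
        groups={"sea_d24_df": 6, "sea_d24_df_dldh_rnai": 6},
        control_group="sea_d24_df",
        baselines=panel,
        multipliers={
            "sea_d24_df_dldh_rnai": {"lactate": 0.4, "2HG": 0.4}
        },
        seed=0,
    )
    scenarios["dl2hgdh_double_mutant"] = ScenarioConfig(
        name="dl2hgdh_double_mutant",
        description=(
            "L2HGDH-null single mutant vs L2HGDH-null; sea double mutant: "
            "pyruvate and lactate rise and citrate falls in the double "
            "mutant while 2HG stays level (degradation, not synthesis, "
            "drives 2HG accumulation)."
        ),
        groups={"dl2hgdh_single": 6, "dl2hgdh_sea_double": 6},
        control_group="dl2hgdh_single",
        baselines=panel,
        multipliers={
            "dl2hgdh_sea_double": {
                "pyruvate": 2.0,
                "lactate": 2.5,
                "citrate": 0.5,
                "2HG": 1.0,
            }
        },
        seed=0,
    )
    return scenarios


SCENARIOS = _make_scenarios()


def list_scenarios() -> pd.DataFrame:
    """Catalog of preset scenarios: name, group structure, design notes."""
    return pd.DataFrame(
        [
            {
                "name": cfg.name,
                "groups": ", ".join(f"{g} (n={n})" for g, n in cfg.groups.items()),
                "control_group": cfg.control_group,
                "has_labeling": bool(cfg.flux_f),
                "description": cfg.description,
            }
            for cfg in SCENARIOS.values()
        ]
    )


def get_scenario(name: str, seed: int | None = None, **overrides) -> ScenarioConfig:
    """Fetch a deep copy of a preset, optionally re-seeded or overridden."""
    if name not in SCENARIOS:
        raise ValidationError(
            f"unknown scenario {name!r}; valid names: {sorted(SCENARIOS)}"
        )
    cfg = copy.deepcopy(SCENARIOS[name])
    d = cfg.to_dict()
    if seed is not None:
        d["seed"] = seed
    d.update(overrides)
    return ScenarioConfig.from_dict(d)
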