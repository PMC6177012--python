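"""Single-pool exponential labeling model and per-sample flux estimation.

In a constant-pool, constant-flux tracer experiment with dietary tracer
enrichment ``p``, the labeled fraction of a metabolite pool follows

    X_L / X_T = p * (1 - exp(-f_x * t / X_T))

where ``X_L`` is the amount of the tracked labeled isotopologue, ``X_T``
the total pool, ``t`` the labeling time and ``f_x`` the flux through the
pool.  The model has a unique closed-form inverse for ``f_x`` as long as
enrichment stays below the asymptote ``p``; at or beyond ``p`` the model
admits no finite flux and the sample is flagged saturated instead of being
clipped (clipping would bias group means).

Pools are accepted in normalized-intensity units, so the estimated flux is
a relative flux (intensity per hour), not an absolute rate.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "TracerProtocol",
    "FluxEstimate",
    "forward_labeled_fraction",
    "estimate_flux",
    "estimate_cohort_flux",
    "compare_flux_groups",
    "SATURATION_TOL",
]

log = logging.getLogger(__name__)

#: enrichment within this distance of p counts as saturated
SATURATION_TOL = 1e-9

#: tracked isotopologue per metabolite for a 13C6-glucose tracer: glycolytic
#: three-carbon products arrive fully labeled (m+3); 2HG and citrate acquire
#: two tracer carbons per turn via acetyl-CoA/2OG
DEFAULT_TRACKED_M = {"pyruvate": 3, "lactate": 3, "2HG": 2, "citrate": 2}


@dataclass(frozen=True)
class TracerProtocol:
    """Tracer feeding protocol: enrichment, duration and tracked shifts.

    Defaults follow a 2 h feeding of medium containing 50% U-13C6 glucose.
    """

    p: float = 0.5
    t: float = 2.0
    tracer_element: str = "C"
    tracked_m: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TRACKED_M)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValidationError("tracer enrichment p must be in (0, 1]")
        if self.t <= 0:
            raise ValidationError("labeling duration t must be positive")
        if any(m < 1 for m in self.tracked_m.values()):
            raise ValidationError("tracked isotopologue indices must be >= 1")


@dataclass(frozen=True)
class FluxEstimate:
    """Per-sample flux estimate with saturation/validity flags."""

    sample_id: str
    metabolite: str
    f_x: float
    enrichment: float
    valid: bool
    saturated: bool
    group: str | None = None


def forward_labeled_fraction(f_x, t: float, X_T, p: float):
    """Labeled fraction X_L/X_T predicted by the exponential pool model.

    Accepts scalars or arrays for ``f_x`` and ``X_T``; the result lies in
    ``[0, p)`` and increases strictly with ``f_x`` and ``t``.
    """
    f_x = np.asarray(f_x, dtype=float)
    X_T = np.asarray(X_T, dtype=float)
    if np.any(X_T <= 0):
        raise ValidationError("total pool X_T must be positive")
    if np.any(f_x < 0):
        raise ValidationError("flux must be non-negative")
    if t < 0:
        raise ValidationError("time must be non-negative")
    if not 0.0 < p <= 1.0:
        raise ValidationError("p must be in (0, 1]")
    out = p * -np.expm1(-f_x * t / X_T)
    return out.item() if out.ndim == 0 else out


def estimate_flux(
    X_L: float,
    X_T: float,
    protocol: TracerProtocol,
    sample_id: str = "",
    metabolite: str = "",
    group: str | None = None,
) -> FluxEstimate:
    """Invert the labeling model: f_x = -(X_T/t) * ln(1 - (X_L/X_T)/p).

    Enrichment at or above ``p`` (within :data:`SATURATION_TOL`) yields a
    saturated, invalid estimate with ``f_x = inf`` rather than a clipped
    finite value.
    """
    if X_T <= 0:
        raise ValidationError(f"total pool must be positive (sample {sample_id!r})")
    if X_L < 0:
        raise ValidationError(f"labeled amount must be >= 0 (sample {sample_id!r})")
    e = X_L / X_T
    if e >= 1.0:
        raise ValidationError(
            f"labeled amount exceeds total pool (sample {sample_id!r}, "
            f"enrichment {e:.4g})"
        )
    if e >= protocol.p - SATURATION_TOL:
        return FluxEstimate(
            sample_id=sample_id,
            metabolite=metabolite,
            f_x=math.inf,
            enrichment=e,
            valid=False,
            saturated=True,
            group=group,
        )
    f = -(X_T / protocol.t) * math.log1p(-e / protocol.p)
    return FluxEstimate(
        sample_id=sample_id,
        metabolite=metabolite,
        f_x=f,
        enrichment=e,
        valid=True,
        saturated=False,
        group=group,
    )


def estimate_cohort_flux(
    enrichments: pd.DataFrame,
    pools: pd.DataFrame,
    protocol: TracerProtocol,
) -> pd.DataFrame:
    """Estimate per-sample fluxes for a cohort.

    ``enrichments`` is long-format with columns sample_id, metabolite,
    enrichment (corrected tracked-isotopologue fraction) and optionally
    group; ``pools`` has columns sample_id, metabolite, pool.  Returns one
    row per (sample, metabolite) with f_x and validity flags; saturated
    samples are counted in the log and excluded from downstream statistics
    by the ``valid`` flag.
    """
    required = {"sample_id", "metabolite", "enrichment"}
    if missing := required - set(enrichments.columns):
        raise ValidationError(f"enrichment table missing columns {sorted(missing)}")
    if missing := {"sample_id", "metabolite", "pool"} - set(pools.columns):
        raise ValidationError(f"pool table missing columns {sorted(missing)}")
    if enrichments.empty:
        warnings.warn("empty cohort: no enrichments to estimate", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "sample_id", "group", "metabolite", "f_x",
                "enrichment", "valid", "saturated",
            ]
        )
    pool_map = pools.set_index(["sample_id", "metabolite"])["pool"]
    rows = []
    for rec in enrichments.itertuples(index=False):
        key = (rec.sample_id, rec.metabolite)
        if key not in pool_map.index:
            raise ValidationError(
                f"missing pool measurement for sample {rec.sample_id!r}, "
                f"metabolite {rec.metabolite!r}"
            )
        X_T = float(pool_map.loc[key])
        est = estimate_flux(
            X_L=float(rec.enrichment) * X_T,
            X_T=X_T,
            protocol=protocol,
            sample_id=str(rec.sample_id),
            metabolite=str(rec.metabolite),
            group=getattr(rec, "group", None),
        )
        rows.append(est)
    out = pd.DataFrame(
        {
            "sample_id": [e.sample_id for e in rows],
            "group": [e.group for e in rows],
            "metabolite": [e.metabolite for e in rows],
            "f_x": [e.f_x for e in rows],
            "enrichment": [e.enrichment for e in rows],
            "valid": [e.valid for e in rows],
            "saturated": [e.saturated for e in rows],
        }
    )
    n_sat = int(out["saturated"].sum())
    if n_sat:
        log.warning("%d of %d estimates saturated (enrichment >= p)", n_sat, len(out))
    return out


def compare_flux_groups(
    estimates: pd.DataFrame,
    reference_group: str,
    alpha: float = 0.05,
    m: int | None = None,
) -> pd.DataFrame:
    """Compare valid flux estimates of each non-reference group vs reference.

    Per (group, metabolite): ratio of group mean flux to the reference mean
    plus a two-tailed equal-variance t-test, Bonferroni-adjusted over the
    number of metabolites tested (``m`` defaults to that count).  A group
    with fewer than two valid estimates for a metabolite is skipped with a
    warning.
    """
    from .stats import ttest_bonferroni

    valid = estimates[estimates["valid"]]
    if reference_group not in set(valid["group"]):
        raise ValidationError(f"reference group {reference_group!r} has no valid estimates")
    results = []
    for group in sorted(set(valid["group"]) - {reference_group}):
        pairs = {}
        ratios = {}
        for metab in sorted(valid["metabolite"].unique()):
            ref = valid.query("group == @reference_group and metabolite == @metab")["f_x"].to_numpy()
            test = valid.query("group == @group and metabolite == @metab")["f_x"].to_numpy()
            if len(ref) < 2 or len(test) < 2:
                warnings.warn(
                    f"skipping {metab!r} for group {group!r}: fewer than 2 "
                    "valid estimates in a group",
                    stacklevel=2,
                )
                continue
            pairs[metab] = (test, ref)
            ratios[metab] = float(np.mean(test) / np.mean(ref))
        if not pairs:
            continue
        tt = ttest_bonferroni(pairs, m=m, alpha=alpha)
        tt.insert(0, "group", group)
        tt.insert(1, "reference_group", reference_group)
        tt.insert(3, "flux_ratio", [ratios[mb] for mb in tt["metabolite"]])
        results.append(tt)
    if not results:
        return pd.DataFrame()
    return pd.concat(results, ignore_index=True)
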