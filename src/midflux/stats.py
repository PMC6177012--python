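"""Steady-state cohort statistics for targeted GC-MS metabolomics.

Implements the comparison track of the analysis: per-sample normalization
to sample mass and a spiked internal standard (d4-succinate), fold change
relative to a control group, two-tailed Student's t-tests with Bonferroni
family-wise correction, Pearson correlation between metabolite pools, and
PCA of the normalized profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA

from .errors import ValidationError

__all__ = [
    "SampleTable",
    "ComparisonResult",
    "PCAResult",
    "normalize_table",
    "fold_change_vs_control",
    "ttest_bonferroni",
    "compare_to_control",
    "pearson_correlation",
    "pca_scores",
]

log = logging.getLogger(__name__)

#: non-metabolite columns of a wide sample table, in canonical order
META_COLUMNS = ("group", "mass_mg", "is_intensity")


@dataclass
class SampleTable:
    """A cohort of samples: metadata plus one intensity column per metabolite.

    ``data`` is indexed by sample_id and carries ``group``, ``mass_mg`` and
    (until normalization consumes it) ``is_intensity``, followed by one
    column per metabolite.  ``normalized`` records whether mass/IS
    normalization has been applied.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id(s): {dupes}")
        if "group" not in self.data.columns:
            raise ValidationError("sample table missing required column 'group'")

    @property
    def metabolites(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    def intensities(self) -> pd.DataFrame:
        """Metabolite columns only, as floats."""
        return self.data[self.metabolites].astype(float)

    def group_rows(self, group: str) -> pd.DataFrame:
        return self.data[self.data["group"] == group]


@dataclass(frozen=True)
class ComparisonResult:
    metabolite: str
    fold_change: float
    t: float
    df: float
    p: float
    p_adj: float
    significant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class PCAResult:
    """Scores (samples x PCs), loadings (metabolites x PCs), variance shares."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    dropped_metabolites: list[str] = field(default_factory=list)
    scaling: str = "autoscale"


def normalize_table(
    raw: SampleTable, is_reference_intensity: float | None = None
) -> SampleTable:
    """Normalize intensities to sample mass and the internal standard.

    Each metabolite intensity is divided by the sample's mass (mg) and by
    its internal-standard response factor ``is_intensity /
    is_reference_intensity``.  The reference defaults to the cohort median
    IS intensity, which makes normalized units cohort-relative; pass a
    fixed reference to pin units across cohorts.  The IS column is consumed
    and not propagated.
    """
    if raw.normalized:
        raise ValidationError("table is already normalized")
    for col in ("mass_mg", "is_intensity"):
        if col not in raw.data.columns:
            raise ValidationError(f"sample table missing required column {col!r}")
    mass = raw.data["mass_mg"].astype(float)
    is_int = raw.data["is_intensity"].astype(float)
    for sid, m_val, i_val in zip(raw.data.index, mass, is_int):
        if not m_val > 0:
            raise ValidationError(f"non-positive sample mass for sample {sid!r}")
        if not i_val > 0:
            raise ValidationError(
                f"non-positive internal-standard intensity for sample {sid!r}"
            )
    if is_reference_intensity is None:
        is_reference_intensity = float(is_int.median())
    if not is_reference_intensity > 0:
        raise ValidationError("is_reference_intensity must be positive")
    factor = mass * (is_int / is_reference_intensity)
    out = raw.data.drop(columns=["is_intensity"]).copy()
    metabolites = [c for c in out.columns if c not in META_COLUMNS]
    out[metabolites] = out[metabolites].astype(float).div(factor, axis=0)
    return SampleTable(data=out, normalized=True)


def fold_change_vs_control(
    normalized: SampleTable, control_group: str
) -> pd.DataFrame:
    """Per-sample abundances relative to the control-group mean.

    Every value is divided by the control mean of its metabolite, so the
    control group centers on 1.  Metabolites whose control mean is zero are
    excluded with a log entry.
    """
    if control_group not in normalized.groups:
        raise ValidationError(f"control group {control_group!r} not in table")
    control = normalized.group_rows(control_group)
    means = control[normalized.metabolites].astype(float).mean(axis=0)
    bad = [m for m in normalized.metabolites if not means[m] > 0]
    if bad:
        log.warning("excluding metabolites with zero control mean: %s", bad)
    keep = [m for m in normalized.metabolites if m not in bad]
    rel = normalized.intensities()[keep].div(means[keep], axis=1)
    rel.insert(0, "group", normalized.data["group"])
    return rel


def _student_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, bool]:
    """Equal-variance two-sample t. Returns (t, df, p, degenerate)."""
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / df
    if pooled == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, df, 1.0, False
        # zero within-group variance but distinct means: infinitely strong
        # evidence under the model; flagged degenerate
        sign = 1.0 if np.mean(a) > np.mean(b) else -1.0
        return sign * np.inf, df, 0.0, True
    t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(df), float(p), False


def ttest_bonferroni(
    groups: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    m: int | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-tailed two-sample t-tests with Bonferroni correction.

    ``groups`` maps metabolite -> (test values, reference values).  The
    default is the equal-variance Student's t; Welch's correction is
    available via ``equal_var=False``.  ``m`` is the Bonferroni family size
    and defaults to the number of metabolites tested; it is echoed in the
    output for auditability.  ``p_adj = min(1, m * p)``; significance is
    declared at ``p_adj < alpha``.
    """
    tested = {}
    for metab, (a, b) in groups.items():
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(
                f"skipping {metab!r}: fewer than 2 values in a group",
                stacklevel=2,
            )
            continue
        tested[metab] = (a, b)
    if m is None:
        m = len(tested)
    if m < len(tested):
        raise ValidationError(
            f"Bonferroni family size m={m} smaller than the {len(tested)} "
            "tests performed"
        )
    rows = []
    for metab, (a, b) in tested.items():
        if equal_var:
            t, df, p, degenerate = _student_t(a, b)
        else:
            res = scipy.stats.ttest_ind(a, b, equal_var=False)
            t, df, p, degenerate = (
                float(res.statistic), float(res.df), float(res.pvalue), False,
            )
        p_adj = min(1.0, m * p)
        fc = float(np.mean(a) / np.mean(b)) if np.mean(b) != 0 else np.nan
        rows.append(
            {
                "metabolite": metab,
                "fold_change": fc,
                "t": t,
                "df": df,
                "p": p,
                "p_adj": p_adj,
                "m": m,
                "significant": bool(p_adj < alpha),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def compare_to_control(
    normalized: SampleTable,
    control_group: str,
    test_group: str | None = None,
    m: int | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Full comparison of one test group against the control group.

    Builds the per-metabolite value pairs from a normalized table (samples
    with a missing value for a metabolite are dropped pairwise for that
    test) and delegates to :func:`ttest_bonferroni`.  With more than two
    groups, ``test_group`` selects which one to compare.
    """
    groups = normalized.groups
    if control_group not in groups:
        raise ValidationError(f"control group {control_group!r} not in table")
    others = [g for g in groups if g != control_group]
    if test_group is None:
        if len(others) != 1:
            raise ValidationError(
                f"table has groups {groups}; specify test_group explicitly"
            )
        test_group = others[0]
    elif test_group not in groups:
        raise ValidationError(f"test group {test_group!r} not in table")
    ctrl = normalized.group_rows(control_group)
    test = normalized.group_rows(test_group)
    pairs = {}
    for metab in normalized.metabolites:
        a = test[metab].astype(float).dropna().to_numpy()
        b = ctrl[metab].astype(float).dropna().to_numpy()
        pairs[metab] = (a, b)
    out = ttest_bonferroni(pairs, m=m, alpha=alpha, equal_var=equal_var)
    out.insert(0, "test_group", test_group)
    out.insert(1, "control_group", control_group)
    return out


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and its two-tailed p (t transform, n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValidationError("Pearson correlation requires at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for constant input")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def pca_scores(
    normalized: SampleTable,
    scaling: str = "autoscale",
    n_components: int | None = None,
) -> PCAResult:
    """PCA of the metabolite matrix via singular-value decomposition.

    Columns are mean-centered and, with the default ``autoscale``, divided
    by their standard deviation (unit variance), the common choice for
    targeted metabolomics panels; ``center_only`` skips the scaling.
    Zero-variance metabolites are dropped with a log entry.  Component
    signs follow a deterministic convention: the largest-magnitude loading
    of each component is made positive.
    """
    if scaling not in ("autoscale", "center_only"):
        raise ValidationError(f"unknown scaling {scaling!r}")
    X = normalized.intensities()
    if X.isna().any().any():
        n_before = len(X)
        X = X.dropna(axis=0)
        log.warning("PCA listwise deletion: %d of %d samples dropped",
                    n_before - len(X), n_before)
    if len(X) < 2:
        raise ValidationError("PCA requires at least 2 complete samples")
    sd = X.std(axis=0, ddof=1)
    dropped = [m for m in X.columns if sd[m] == 0]
    if dropped:
        log.warning("PCA dropped zero-variance metabolites: %s", dropped)
        X = X.drop(columns=dropped)
    if X.shape[1] < 2:
        raise ValidationError("PCA requires at least 2 non-constant metabolites")
    M = X.to_numpy(dtype=float)
    M = M - M.mean(axis=0)
    if scaling == "autoscale":
        M = M / np.std(X.to_numpy(dtype=float), axis=0, ddof=1)
    k = min(M.shape) if n_components is None else n_components
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(M)
    loadings = pca.components_.T  # metabolites x components
    # deterministic sign convention: largest-|loading| entry positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    pc_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    scores_df = pd.DataFrame(scores, index=X.index, columns=pc_names)
    scores_df.insert(0, "group", normalized.data.loc[X.index, "group"])
    loadings_df = pd.DataFrame(loadings, index=list(X.columns), columns=pc_names)
    return PCAResult(
        scores=scores_df,
        loadings=loadings_df,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        dropped_metabolites=dropped,
        scaling=scaling,
    )
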