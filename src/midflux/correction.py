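"""Natural-abundance correction of GC-MS mass-isotopomer distributions.

A measured isotopologue vector (MID) for a metabolite fragment mixes two
signals: tracer-derived labeling and naturally occurring heavy isotopes
(1.07% 13C, 0.2% 18O, ...).  This module builds the column-stochastic
correction matrix ``A`` whose entry ``A[i, j]`` is the probability that a
molecule carrying exactly ``j`` tracer atoms is observed at nominal mass
shift ``m+i``, and deconvolves measured vectors against it to recover the
pure tracer-labeling distribution.

Only nominal (unit-Da) mass shifts are modeled; high-resolution fine
structure that separates, say, 13C from 15N at the same nominal shift is
out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.optimize
import scipy.stats

from .errors import ComputationError, FormulaError, ValidationError

__all__ = [
    "ElementCounts",
    "IsotopeTable",
    "IsotopologueVector",
    "CorrectionMatrix",
    "parse_formula",
    "format_formula",
    "load_isotope_table",
    "natural_mid",
    "build_correction_matrix",
    "correct_mid",
    "tracked_label_fraction",
    "DEFAULT_EXTRA_SHIFTS",
]

ElementCounts = dict[str, int]

#: extra rows kept above the highest labeled state; captures >= 1 - 1e-6 of
#: the natural-abundance mass per column for CHNOPS fragments up to 30
#: carbons (the fully-labeled column only keeps these extra rows, so the
#: headroom must cover the whole residual fragment's heavy-isotope tail)
DEFAULT_EXTRA_SHIFTS = 6

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementCounts:
    """Parse a molecular formula such as ``"C3H6O3"`` into atom counts.

    Grammar: a sequence of element tokens, each a capital letter with an
    optional lowercase letter, followed by an optional positive integer
    count (default 1). Repeated elements accumulate.

    Raises :class:`FormulaError` naming the offending position for any
    character that does not fit the grammar.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: ElementCounts = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.end() == pos:
            raise FormulaError(
                f"malformed formula {text!r}: unexpected character "
                f"{text[pos]!r} at position {pos}"
            )
        element, digits = m.groups()
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(
                f"malformed formula {text!r}: zero count for {element} "
                f"at position {pos}"
            )
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return counts


def format_formula(counts: ElementCounts) -> str:
    """Write atom counts back to a canonical (Hill-order) formula string."""
    if any(n < 0 for n in counts.values()):
        raise FormulaError("negative atom count")
    symbols = [s for s, n in counts.items() if n > 0]
    ordered: list[str] = []
    if "C" in symbols:
        ordered.append("C")
        if "H" in symbols:
            ordered.append("H")
        ordered += sorted(s for s in symbols if s not in ("C", "H"))
    else:
        ordered = sorted(symbols)
    return "".join(f"{s}{counts[s] if counts[s] != 1 else ''}" for s in ordered)


#: element -> [(mass shift, abundance), ...], shifts strictly increasing from 0
IsotopeTable = dict[str, list[tuple[int, float]]]


def load_isotope_table(path: str | Path | None = None) -> IsotopeTable:
    """Load an isotope abundance table, defaulting to the packaged file.

    The file is tab-separated with columns element / shift / abundance and
    ``#`` comments.  Per-element abundances must sum to 1 within 1e-9 and
    shifts must be strictly increasing starting at 0.
    """
    if path is None:
        ref = resources.files("midflux").joinpath("data/isotopes.tsv")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    table: IsotopeTable = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "element":
            continue
        if len(parts) != 3:
            raise ValidationError(f"isotope table line {lineno}: expected 3 fields")
        element, shift_s, ab_s = parts
        try:
            shift, abundance = int(shift_s), float(ab_s)
        except ValueError as exc:
            raise ValidationError(f"isotope table line {lineno}: {exc}") from None
        table.setdefault(element, []).append((shift, abundance))
    validate_isotope_table(table)
    return table


def validate_isotope_table(table: IsotopeTable) -> None:
    for element, pairs in table.items():
        shifts = [s for s, _ in pairs]
        if shifts[0] != 0 or any(b <= a for a, b in zip(shifts, shifts[1:])):
            raise ValidationError(
                f"isotope table for {element}: shifts must be strictly "
                f"increasing starting at 0, got {shifts}"
            )
        total = sum(a for _, a in pairs)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"isotope table for {element}: abundances sum to {total!r}, not 1"
            )
        if any(a < 0 for _, a in pairs):
            raise ValidationError(f"isotope table for {element}: negative abundance")


def _atom_vector(element: str, isotopes: IsotopeTable, max_shift: int) -> np.ndarray:
    pairs = isotopes[element]
    top = max(s for s, _ in pairs)
    v = np.zeros(max(top, max_shift) + 1)
    for shift, abundance in pairs:
        v[shift] = abundance
    return v


def natural_mid(
    counts: ElementCounts, isotopes: IsotopeTable, max_shift: int
) -> np.ndarray:
    """Mass-shift distribution of a fragment under natural abundance alone.

    Convolves the single-atom isotope distributions of every atom in
    ``counts`` and truncates the result at ``max_shift``; entry ``k`` is the
    probability of observing the fragment at nominal shift ``m+k``.  The
    untruncated distribution sums to 1, so the returned vector sums to
    ``1 - (truncated tail mass)``.
    """
    if max_shift < 0:
        raise ValidationError("max_shift must be >= 0")
    out = np.zeros(max_shift + 1)
    out[0] = 1.0
    for element, n in counts.items():
        if n == 0:
            continue
        if n < 0:
            raise ValidationError(f"negative atom count for {element}")
        if element not in isotopes:
            raise ValidationError(f"element {element!r} missing from isotope table")
        atom = _atom_vector(element, isotopes, 0)
        # exponentiation by squaring on the truncated polynomial; truncation
        # is exact for the retained coefficients since all shifts are >= 0
        power = atom
        k = n
        while True:
            if k & 1:
                out = np.convolve(out, power)[: max_shift + 1]
            k >>= 1
            if k == 0:
                break
            power = np.convolve(power, power)[: max_shift + 1]
    return out


@dataclass(frozen=True)
class CorrectionMatrix:
    """Column-stochastic map from tracer-labeling states to observed shifts.

    ``matrix[i, j]`` = probability that a molecule with exactly ``j`` tracer
    atoms appears at mass shift ``m+i``.  Columns sum to 1 up to the mass
    truncated beyond row ``max_shift``; ``column_deficits`` records that
    truncated tail per column.
    """

    matrix: np.ndarray
    fragment: ElementCounts = field(default_factory=dict)
    tracer_element: str = "C"
    tracer_purity: float = 1.0

    @property
    def n_label(self) -> int:
        return self.matrix.shape[1] - 1

    @property
    def max_shift(self) -> int:
        return self.matrix.shape[0] - 1

    @property
    def column_deficits(self) -> np.ndarray:
        return 1.0 - self.matrix.sum(axis=0)


def build_correction_matrix(
    counts: ElementCounts,
    tracer_element: str,
    n_label: int,
    isotopes: IsotopeTable,
    tracer_purity: float = 1.0,
    max_shift: int | None = None,
) -> CorrectionMatrix:
    """Build the natural-abundance correction matrix for one fragment.

    Column ``j`` models a molecule whose ``j`` tracer positions came from
    the tracer: each is heavy with probability ``tracer_purity`` (otherwise
    light, with no natural abundance — its isotopic origin is the tracer
    batch, not nature), contributing a Binomial(j, purity) mass shift, while
    the remaining atoms (including the other ``counts[tracer] - j`` tracer-
    element atoms) contribute their natural-abundance distribution.

    ``max_shift`` defaults to ``n_label + DEFAULT_EXTRA_SHIFTS``.
    """
    if not 0.0 < tracer_purity <= 1.0:
        raise ValidationError("tracer_purity must be in (0, 1]")
    n_tracer = counts.get(tracer_element, 0)
    if n_label <= 0:
        raise ValidationError("n_label must be positive")
    if n_label > n_tracer:
        raise ValidationError(
            f"n_label={n_label} exceeds the {n_tracer} {tracer_element} "
            f"atoms in fragment {format_formula(counts)}"
        )
    if max_shift is None:
        max_shift = n_label + DEFAULT_EXTRA_SHIFTS
    if max_shift < n_label:
        raise ValidationError("max_shift must be >= n_label")
    A = np.zeros((max_shift + 1, n_label + 1))
    for j in range(n_label + 1):
        residual = dict(counts)
        residual[tracer_element] = n_tracer - j
        base = natural_mid(residual, isotopes, max_shift)
        if tracer_purity == 1.0:
            col = np.concatenate([np.zeros(j), base])[: max_shift + 1]
        else:
            purity_pmf = scipy.stats.binom.pmf(np.arange(j + 1), j, tracer_purity)
            col = np.convolve(base, purity_pmf)[: max_shift + 1]
        A[:, j] = col
    return CorrectionMatrix(
        matrix=A,
        fragment=dict(counts),
        tracer_element=tracer_element,
        tracer_purity=tracer_purity,
    )


@dataclass
class IsotopologueVector:
    """A metabolite fragment's mass-isotopomer distribution, raw or corrected."""

    metabolite: str
    values: np.ndarray
    fragment: ElementCounts = field(default_factory=dict)
    tracer_element: str = "C"
    status: str = "raw"  # raw | corrected
    residual: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("isotopologue values must be a 1-D vector")
        if np.any(self.values < 0):
            raise ValidationError(
                f"negative isotopologue intensity for {self.metabolite}"
            )
        if self.status not in ("raw", "corrected"):
            raise ValidationError(f"unknown status {self.status!r}")

    @property
    def max_shift(self) -> int:
        return len(self.values) - 1


def correct_mid(
    raw: IsotopologueVector | Sequence[float] | np.ndarray,
    A: CorrectionMatrix,
    method: str = "nnls",
) -> IsotopologueVector:
    """Deconvolve a raw MID against a correction matrix.

    Solves ``A @ x ~= raw`` for the tracer-labeling distribution ``x``.
    The default ``nnls`` solver constrains ``x >= 0`` (negative
    isotopologue fractions are unphysical); ``pinv`` applies the
    Moore–Penrose pseudo-inverse and clips small negative round-off to
    zero, warning when the matrix is ill-conditioned.  The solution is
    renormalized to sum 1 and returned with status ``corrected`` and the
    residual norm of the fit (on the sum-normalized raw vector).
    """
    if isinstance(raw, IsotopologueVector):
        vec = raw
    else:
        vec = IsotopologueVector(metabolite="", values=np.asarray(raw, float))
    b = vec.values
    if b.shape[0] != A.matrix.shape[0]:
        raise ValidationError(
            f"raw vector length {b.shape[0]} does not match correction "
            f"matrix rows {A.matrix.shape[0]}"
        )
    total = b.sum()
    if total <= 0:
        raise ValidationError(f"all-zero raw MID for {vec.metabolite or 'fragment'}")
    b = b / total
    if method == "nnls":
        x, residual = scipy.optimize.nnls(A.matrix, b)
    elif method == "pinv":
        cond = np.linalg.cond(A.matrix)
        if cond > 1e8:
            import warnings

            warnings.warn(
                f"correction matrix is ill-conditioned (cond={cond:.3g}); "
                "pinv solution may be unstable",
                RuntimeWarning,
                stacklevel=2,
            )
        x = np.linalg.pinv(A.matrix) @ b
        residual = float(np.linalg.norm(A.matrix @ x - b))
        x = np.clip(x, 0.0, None)
    else:
        raise ValidationError(f"unknown correction method {method!r}")
    s = x.sum()
    if s <= 0:
        raise ComputationError(
            f"correction produced an all-zero solution for {vec.metabolite!r}"
        )
    return IsotopologueVector(
        metabolite=vec.metabolite,
        values=x / s,
        fragment=dict(A.fragment),
        tracer_element=A.tracer_element,
        status="corrected",
        residual=float(residual),
    )


def tracked_label_fraction(
    corrected: IsotopologueVector, tracked_m: int
) -> float:
    """Fraction of the pool carrying the tracked isotopologue (e.g. m+3)."""
    if corrected.status != "corrected":
        raise ValidationError(
            "tracked_label_fraction requires a corrected MID; got status "
            f"{corrected.status!r}"
        )
    if not 0 <= tracked_m <= corrected.max_shift:
        raise ValidationError(
            f"tracked_m={tracked_m} out of bounds for a vector of length "
            f"{corrected.max_shift + 1}"
        )
    return float(corrected.values[tracked_m])
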