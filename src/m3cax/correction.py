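"""Natural-abundance and tracer-purity correction of isotopologue intensities.

Measured mass-shift intensities of a tracer experiment are a linear mixture
of the true tracer-labelling states: naturally occurring heavy isotopes of
every element shift mass upward, and imperfect tracer purity shifts it
downward.  The low-resolution correction builds, for each possible number j
of tracer-derived labels, the expected measured mass-shift distribution, and
inverts the resulting (C+1)x(C+1) linear system by non-negative least
squares.  This is the regime appropriate for MS1 data where isotopic fine
structure is not resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .constants import NATURAL_ABUNDANCE
from .datatypes import IsotopologueSet, parse_formula


@dataclass(frozen=True)
class CorrectionModel:
    """Correction parameters for one metabolite.

    Parameters
    ----------
    formula:
        Hill-notation elemental formula of the unlabelled species.
    tracer_element:
        Element carrying the tracer label (default ``"C"``).
    tracer_purity:
        Isotopic purity of the tracer, i.e. the probability that a
        nominally labelled position actually carries the heavy isotope.
    isotope_abundances:
        Element -> natural isotope abundance vector (mass shift order);
        defaults to the standard terrestrial table.
    """

    formula: str
    tracer_element: str = "C"
    tracer_purity: float = 1.0
    isotope_abundances: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(NATURAL_ABUNDANCE)
    )

    def __post_init__(self) -> None:
        counts = parse_formula(self.formula)
        if counts.get(self.tracer_element, 0) < 1:
            raise ValueError(
                f"formula {self.formula} contains no {self.tracer_element} atom"
            )
        if not 0.0 < self.tracer_purity <= 1.0:
            raise ValueError("tracer_purity must be in (0, 1]")
        for element, vec in self.isotope_abundances.items():
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"abundance vector for {element} does not sum to 1")

    @property
    def n_tracer_atoms(self) -> int:
        return parse_formula(self.formula)[self.tracer_element]


@dataclass(frozen=True)
class MDV:
    """Mass isotopomer distribution vector: fractional abundances of
    M+0..M+C for one metabolite in one sample."""

    fractions: np.ndarray
    metabolite_id: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        frac = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", frac)
        if np.any(frac < -1e-12):
            raise ValueError("MDV fractions must be non-negative")
        if abs(frac.sum() - 1.0) > 1e-6:
            raise ValueError(f"MDV fractions must sum to 1, got {frac.sum()}")


def _convolve_power(dist: np.ndarray, n: int) -> np.ndarray:
    """n-fold self-convolution of a probability vector (n >= 0)."""
    out = np.array([1.0])
    base = np.asarray(dist, dtype=float)
    while n > 0:
        if n & 1:
            out = np.convolve(out, base)
        base = np.convolve(base, base)
        n >>= 1
    return out


def build_correction_matrix(model: CorrectionModel) -> np.ndarray:
    """Build the (C+1)x(C+1) measurement matrix of the correction model.

    Column j is the expected measured mass-shift distribution of a species
    carrying exactly j tracer-derived labels: the convolution of the
    natural-abundance distributions of all non-tracer elements, of the C-j
    unlabelled tracer-element positions, and of the binomial purity
    distribution of the j labelled positions.  Mass shifts beyond C are
    truncated, so columns sum to <= 1.
    """
    counts = parse_formula(model.formula)
    n_c = counts[model.tracer_element]
    abundances = model.isotope_abundances

    # Mass-shift distribution contributed by non-tracer elements.
    non_tracer = np.array([1.0])
    for element, n_atoms in sorted(counts.items()):
        if element == model.tracer_element:
            continue
        if element not in abundances:
            raise ValueError(f"no natural-abundance table for element {element!r}")
        non_tracer = np.convolve(
            non_tracer, _convolve_power(np.asarray(abundances[element]), n_atoms)
        )

    tracer_nat = np.asarray(abundances[model.tracer_element], dtype=float)
    purity = np.array([1.0 - model.tracer_purity, model.tracer_purity])

    mat = np.zeros((n_c + 1, n_c + 1))
    for j in range(n_c + 1):
        col = np.convolve(non_tracer, _convolve_power(tracer_nat, n_c - j))
        col = np.convolve(col, _convolve_power(purity, j))
        # labelled positions contribute a baseline shift of j handled by the
        # purity binomial (support 0..j); total support starts at 0
        mat[:, j] = col[: n_c + 1]
    return mat


def correct_mdv(raw_intensities: np.ndarray, model: CorrectionModel,
                metabolite_id: str = "", sample_id: str = "") -> MDV:
    """Correct one measured isotopologue vector to a tracer-labelling MDV.

    Solves ``raw = M @ x`` for ``x >= 0`` by non-negative least squares and
    normalizes the solution to sum 1.  The result is invariant to uniform
    scaling of the input intensities.
    """
    raw = np.asarray(raw_intensities, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw isotopologue intensities must be non-negative")
    total = raw.sum()
    if total <= 0:
        raise ValueError("all-zero isotopologue vector cannot be corrected")
    mat = build_correction_matrix(model)
    if len(raw) != mat.shape[0]:
        raise ValueError(
            f"expected {mat.shape[0]} intensities for {model.formula}, got {len(raw)}"
        )
    x, _ = nnls(mat, raw / total)
    s = x.sum()
    if s <= 0:
        raise ValueError("correction produced an all-zero solution")
    return MDV(x / s, metabolite_id, sample_id)


def correct_isotopologue_set(
    iso: IsotopologueSet,
    tracer_purity: float = 1.0,
    tracer_element: str = "C",
) -> list[MDV]:
    """Correct every (metabolite, sample) vector of an IsotopologueSet."""
    out = []
    for (met_id, sample_id) in sorted(iso.entries):
        meta = iso.metabolites.get(met_id)
        if meta is None:
            raise ValueError(f"no metadata (formula) for metabolite {met_id!r}")
        model = CorrectionModel(meta.formula, tracer_element, tracer_purity)
        out.append(correct_mdv(iso.entries[(met_id, sample_id)], model,
                               met_id, sample_id))
    return out


def mean_enrichment(mdv: MDV) -> float:
    """Average fractional labelling: sum_k k*f_k / C."""
    n_c = len(mdv.fractions) - 1
    if n_c == 0:
        return 0.0
    k = np.arange(n_c + 1)
    return float(np.dot(k, mdv.fractions) / n_c)


def percent_isotopologues(mdv: MDV) -> np.ndarray:
    """MDV fractions expressed as percentages of total metabolite level."""
    return mdv.fractions * 100.0
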