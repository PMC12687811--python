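"""Natural-abundance and tracer-purity correction of mass-isotopomer vectors.

A measured isotopologue distribution mixes tracer-derived labeling with the
background of naturally occurring heavy isotopes (1.07% 13C, 0.0115% 2H, ...)
and with the tracer's own isotopic impurity.  The correction builds the
forward matrix A whose column j is the raw distribution expected from a
species truly carrying j tracer atoms, then inverts the measurement by
non-negative least squares, so corrected fractions are guaranteed ≥ 0 without
clamping.

Two resolution modes are provided.  In ``high`` mode (default, appropriate to
orbitrap-class resolving power where isotopologues of different elements are
mass-resolved) only the tracer element is convolved.  In ``nominal`` mode all
elements contribute to the nominal-mass envelope, including the +2 isotopes
of O and S.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

__all__ = [
    "NATURAL_ABUNDANCE",
    "CorrectionModel",
    "MIDVector",
    "build_correction_matrix",
    "forward_convolve",
    "correct_mid",
    "correct_peak_table",
]

#: default natural heavy-isotope abundances; for O and S the two entries are
#: the +1 and +2 isotopes (17O/18O, 33S/34S)
NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.0107,),
    "H": (0.000115,),
    "N": (0.00364,),
    "O": (0.00038, 0.00205),
    "S": (0.0075, 0.0421),
    "P": (0.0,),
}


@dataclass(frozen=True)
class CorrectionModel:
    """Parameters of the natural-abundance / purity correction.

    ``abundances`` maps element -> heavy fraction of the +1 isotope (a scalar);
    multi-isotope elements use the module default in nominal mode.
    """

    formula: Mapping[str, int]
    tracer_element: str
    abundances: Mapping[str, float] = field(
        default_factory=lambda: {"C": 0.0107, "H": 0.000115}
    )
    purity: float = 1.0
    resolution_mode: str = "high"

    def __post_init__(self) -> None:
        if self.tracer_element not in self.formula:
            raise ValueError(
                f"formula lacks tracer element {self.tracer_element!r}"
            )
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if any(not 0 <= a < 0.5 for a in self.abundances.values()):
            raise ValueError("abundances must lie in [0, 0.5)")
        if self.resolution_mode not in ("high", "nominal"):
            raise ValueError("resolution_mode must be 'high' or 'nominal'")

    @property
    def n(self) -> int:
        return int(self.formula[self.tracer_element])


@dataclass
class MIDVector:
    """Intensities or fractions over M+0..M+n of one metabolite in one sample."""

    metabolite: str
    values: np.ndarray
    kind: str = "raw"  # {"raw", "corrected"}
    flagged: bool = False
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("MID values must be one-dimensional")


def _single_atom_poly(element: str, abundance: float | None) -> np.ndarray:
    """Nominal-mass shift distribution of one natural atom of ``element``."""
    heavies = (
        (abundance,) if abundance is not None else NATURAL_ABUNDANCE[element]
    )
    return np.array([1.0 - sum(heavies), *heavies])


def _natural_poly(model: CorrectionModel, n_light_tracer: int) -> np.ndarray:
    """Shift distribution from natural isotopes given n light tracer positions."""
    elem = model.tracer_element
    p = model.abundances.get(elem, 0.0)
    poly = np.array([1.0])
    base = np.array([1.0 - p, p])
    for _ in range(n_light_tracer):
        poly = np.convolve(poly, base)
    if model.resolution_mode == "nominal":
        for other, count in model.formula.items():
            if other == elem or count == 0:
                continue
            ab = model.abundances.get(other)
            atom = _single_atom_poly(other, ab)
            if atom[1:].sum() == 0:
                continue
            for _ in range(int(count)):
                poly = np.convolve(poly, atom)
    return poly


def build_correction_matrix(model: CorrectionModel) -> np.ndarray:
    """Forward matrix over shifts 0..n for the model's tracer element.

    Column j is the expected raw distribution (truncated at M+n) of a species
    truly M+j: the j heavy positions independently retain the label with
    probability ``purity``, and every light tracer position (plus, in nominal
    mode, every atom of the other elements) may be naturally heavy.
    """
    n = model.n
    size = n + 1
    A = np.zeros((size, size))
    for j in range(size):
        pur = binom.pmf(np.arange(j + 1), j, model.purity)
        for i in range(j + 1):
            if pur[i] == 0.0:
                continue
            nat = _natural_poly(model, n - i)
            top = min(size - i, nat.size)
            A[i:i + top, j] += pur[i] * nat[:top]
    return A


def forward_convolve(true_mid: MIDVector, model: CorrectionModel) -> MIDVector:
    """Expected raw vector for a true MID: brute-force ``A @ true``.

    This is the independent oracle against which :func:`correct_mid` is
    round-trip tested, and the forward model used by the synthetic-data
    generator to emulate what the LC-MS observes.
    """
    A = build_correction_matrix(model)
    if true_mid.values.size != A.shape[1]:
        raise ValueError(
            f"{true_mid.metabolite}: MID length {true_mid.values.size} != "
            f"{A.shape[1]} (tracer-element count + 1)"
        )
    return MIDVector(true_mid.metabolite, A @ true_mid.values, kind="raw")


def correct_mid(
    raw: MIDVector, model: CorrectionModel, residual_tol: float = 1e-3
) -> MIDVector:
    """Invert the forward model by NNLS and renormalize to fractions.

    The corrected vector sums to one; a relative fit residual above
    ``residual_tol`` sets the ``flagged`` attribute rather than raising.
    """
    A = build_correction_matrix(model)
    y = raw.values
    if y.size != A.shape[0]:
        raise ValueError(
            f"{raw.metabolite}: raw length {y.size} != matrix size {A.shape[0]}"
        )
    norm = float(np.linalg.norm(y))
    if norm == 0.0:
        raise ValueError(f"{raw.metabolite}: empty measurement (all-zero raw)")
    x, rnorm = nnls(A, y / norm)
    total = x.sum()
    if total == 0.0:
        raise ValueError(f"{raw.metabolite}: correction annihilated the signal")
    rel_res = rnorm  # y was scaled to unit norm
    return MIDVector(
        raw.metabolite,
        x / total,
        kind="corrected",
        flagged=rel_res > residual_tol,
        residual=rel_res,
    )


def correct_peak_table(peaks, pmap, tracer, *, abundances=None,
                       resolution_mode: str = "high", residual_tol: float = 1e-3):
    """Correct every (sample, metabolite) MID of a long-format peak table.

    Parameters
    ----------
    peaks : pandas.DataFrame
        Columns ``sample_id, metabolite, isotopologue ("M+k"), intensity``.
    pmap : PathwayMap
        Supplies molecular formulas.
    tracer : TracerSpec
        Supplies tracer element and purity.

    Returns a tidy DataFrame with one row per (sample, metabolite, shift) and
    columns ``fraction``, ``flagged``, ``residual``.
    """
    import pandas as pd

    ab = dict(abundances) if abundances is not None else None
    rows = []
    for (sample, met), grp in peaks.groupby(["sample_id", "metabolite"],
                                            sort=False):
        spec = pmap.metabolite(met)
        model = CorrectionModel(
            formula=spec.element_counts,
            tracer_element=tracer.element,
            abundances=ab if ab is not None
            else {"C": 0.0107, "H": 0.000115},
            purity=tracer.purity,
            resolution_mode=resolution_mode,
        )
        n = model.n
        vec = np.zeros(n + 1)
        shifts = grp["isotopologue"].str.removeprefix("M+").astype(int)
        vec[shifts.to_numpy()] = grp["intensity"].to_numpy()
        corrected = correct_mid(MIDVector(met, vec), model,
                                residual_tol=residual_tol)
        for k, frac in enumerate(corrected.values):
            rows.append((sample, met, k, frac, corrected.flagged,
                         corrected.residual))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "metabolite", "shift", "fraction", "flagged",
                 "residual"],
    )


def identity_model(model: CorrectionModel) -> CorrectionModel:
    """The same model with no natural abundance and perfect purity."""
    return replace(model, abundances={model.tracer_element: 0.0}, purity=1.0)
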