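"""Ball-and-stick morphology reduction scored against reference f-I curves.

The reduction replaces a full-morphology interneuron by a soma plus two
cylindrical dendrites.  Dendrite length is searched in two stages — a coarse
grid (default 50–750 um, step 50) followed by a fine grid (+/- 75 um, step
1 um) around the coarse minimum — while the dendrite diameter is adjusted at
every candidate length so the summed lateral area of the cylinders equals the
full model's total dendritic area.  Candidates are scored by the summed
absolute difference between their f-I curve and the reference curve.  A second
search then minimizes the number of sub-compartments per dendrite (small odd
integers) against the 19-segment model's f-I curve.

Reference curves are consumed as two-column text tables (nA, Hz) so the module
never needs the original full-morphology models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .cells import CellSpec, CurrentClampProtocol, FICurve, compute_fi_curve
from .exceptions import AlignmentError, ValidationError

__all__ = [
    "ReductionSearchConfig",
    "area_preserving_diameter",
    "fi_error",
    "two_stage_length_search",
    "segment_count_search",
    "LengthSearchResult",
    "SegmentSearchResult",
    "ReductionReport",
]

N_DENDRITES = 2  # ball-and-stick with two dendritic sections
REFERENCE_NSEG = 19  # segments per dendrite during the length search


@dataclass
class ReductionSearchConfig:
    reference_fi: FICurve
    total_dendritic_area: float  # um2
    coarse_lengths: np.ndarray = field(
        default_factory=lambda: np.arange(50.0, 750.0 + 1e-9, 50.0)
    )
    fine_halfwidth: float = 75.0  # um
    fine_step: float = 1.0  # um
    segment_candidates: tuple[int, ...] = (1, 3, 5, 7, 9)
    adequacy_threshold: float | None = None  # Hz; default 1 Hz per amplitude point

    def __post_init__(self) -> None:
        self.coarse_lengths = np.asarray(self.coarse_lengths, dtype=float)
        if self.coarse_lengths.size == 0 or len(self.segment_candidates) == 0:
            raise ValidationError("empty search grid")
        coarse_step = (
            np.min(np.diff(self.coarse_lengths)) if self.coarse_lengths.size > 1
            else np.inf
        )
        if self.fine_step > coarse_step:
            raise ValidationError("fine_step must not exceed the coarse grid step")
        if any(n < 1 or n % 2 == 0 for n in self.segment_candidates):
            raise ValidationError("segment candidates must be odd integers >= 1")
        if self.total_dendritic_area <= 0:
            raise ValidationError("total_dendritic_area must be positive")


def area_preserving_diameter(total_area: float, length: float, n_dendrites: int = N_DENDRITES) -> float:
    """Cylinder diameter (um) such that n dendrites of this length carry ``total_area``.

    d = A / (n * pi * L); the product L*d is invariant, so doubling the length
    halves the diameter.
    """
    if total_area <= 0 or length <= 0 or n_dendrites <= 0:
        raise ValueError("total_area, length and n_dendrites must all be positive")
    return total_area / (n_dendrites * math.pi * length)


def fi_error(candidate: FICurve, reference: FICurve) -> float:
    """Summed absolute frequency difference (Hz) over a shared amplitude grid."""
    if candidate.amplitudes.shape != reference.amplitudes.shape or not np.allclose(
        candidate.amplitudes, reference.amplitudes
    ):
        raise AlignmentError("candidate and reference amplitude grids differ")
    return float(np.sum(np.abs(candidate.frequencies - reference.frequencies)))


def _candidate_cell(template: CellSpec, cfg: ReductionSearchConfig,
                    length: float, nseg: int) -> CellSpec:
    diam = area_preserving_diameter(cfg.total_dendritic_area, length)
    return template.with_dendrite_geometry(length, diam, nseg=nseg)


@dataclass
class LengthSearchResult:
    best_length: float  # um
    best_error: float  # Hz
    coarse_lengths: np.ndarray
    coarse_errors: np.ndarray
    fine_lengths: np.ndarray
    fine_errors: np.ndarray


@dataclass
class SegmentSearchResult:
    best_nseg: int
    candidates: tuple[int, ...]
    errors: np.ndarray  # Hz, vs the 19-segment curve
    threshold: float
    adequate: bool  # False if no candidate met the threshold


def two_stage_length_search(
    cell_template: CellSpec,
    cfg: ReductionSearchConfig,
    protocol: CurrentClampProtocol,
    dt: float = 0.025,
    nseg: int = REFERENCE_NSEG,
    fi_fn=None,
) -> LengthSearchResult:
    """Coarse-then-fine dendrite-length search against the reference f-I curve.

    ``fi_fn(cell) -> FICurve`` may replace the simulated f-I computation (used
    by tests with analytic surrogates); by default each candidate is simulated
    with ``protocol``.  Ties break toward the smallest length.
    """
    if fi_fn is None:
        fi_fn = lambda cell: compute_fi_curve(cell, protocol, dt=dt)

    def errs(lengths: np.ndarray) -> np.ndarray:
        out = np.empty(lengths.shape)
        for i, L in enumerate(lengths):
            out[i] = fi_error(fi_fn(_candidate_cell(cell_template, cfg, L, nseg)),
                              cfg.reference_fi)
        return out

    coarse_err = errs(cfg.coarse_lengths)
    coarse_best = float(cfg.coarse_lengths[int(np.argmin(coarse_err))])
    lo = coarse_best - cfg.fine_halfwidth
    if lo < 1.0:
        warnings.warn("fine search window clipped at 1 um")
        lo = 1.0
    fine_lengths = np.arange(lo, coarse_best + cfg.fine_halfwidth + 1e-9, cfg.fine_step)
    fine_err = errs(fine_lengths)
    i_best = int(np.argmin(fine_err))
    return LengthSearchResult(
        best_length=float(fine_lengths[i_best]),
        best_error=float(fine_err[i_best]),
        coarse_lengths=cfg.coarse_lengths.copy(),
        coarse_errors=coarse_err,
        fine_lengths=fine_lengths,
        fine_errors=fine_err,
    )


def segment_count_search(
    cell_at_best_length: CellSpec,
    cfg: ReductionSearchConfig,
    protocol: CurrentClampProtocol,
    dt: float = 0.025,
    fi_fn=None,
) -> SegmentSearchResult:
    """Smallest odd sub-compartment count whose f-I matches the 19-segment model.

    The internal reference is the same cell at 19 segments per dendrite; the
    adequacy threshold defaults to 1 Hz per amplitude point.  If no candidate
    is adequate the 19-segment model is returned with a warning.
    """
    if fi_fn is None:
        fi_fn = lambda cell: compute_fi_curve(cell, protocol, dt=dt)
    length = next(
        s.length for s in cell_at_best_length.sections if s.name != "soma"
    )
    diam = next(
        s.diameter for s in cell_at_best_length.sections if s.name != "soma"
    )
    reference = fi_fn(
        cell_at_best_length.with_dendrite_geometry(length, diam, nseg=REFERENCE_NSEG)
    )
    threshold = (
        cfg.adequacy_threshold
        if cfg.adequacy_threshold is not None
        else 1.0 * reference.amplitudes.size
    )
    candidates = tuple(sorted(cfg.segment_candidates))
    errors = np.empty(len(candidates))
    best = None
    for i, n in enumerate(candidates):
        cand = fi_fn(cell_at_best_length.with_dendrite_geometry(length, diam, nseg=n))
        errors[i] = fi_error(cand, reference)
        if best is None and errors[i] <= threshold:
            best = n
    if best is None:
        warnings.warn("no segment candidate met the adequacy threshold; keeping 19")
        return SegmentSearchResult(REFERENCE_NSEG, candidates, errors, threshold, False)
    return SegmentSearchResult(int(best), candidates, errors, threshold, True)


@dataclass
class ReductionReport:
    """Persistable record of a full reduction (both searches)."""

    cell_class: str
    length: LengthSearchResult
    segments: SegmentSearchResult
    total_dendritic_area: float

    def chosen_geometry(self) -> dict:
        return {
            "length_um": self.length.best_length,
            "diameter_um": area_preserving_diameter(
                self.total_dendritic_area, self.length.best_length
            ),
            "nseg_per_dendrite": self.segments.best_nseg,
            "n_dendrites": N_DENDRITES,
        }

    def save(self, path) -> None:
        doc = {
            "cell_class": self.cell_class,
            "error_metric": "sum over amplitudes of |f_candidate - f_reference| (Hz)",
            "chosen_geometry": self.chosen_geometry(),
            "length_search": {
                "coarse": {
                    "lengths_um": self.length.coarse_lengths.tolist(),
                    "errors_Hz": self.length.coarse_errors.tolist(),
                },
                "fine": {
                    "lengths_um": self.length.fine_lengths.tolist(),
                    "errors_Hz": self.length.fine_errors.tolist(),
                },
                "best_length_um": self.length.best_length,
                "best_error_Hz": self.length.best_error,
            },
            "segment_search": {
                "candidates": list(self.segments.candidates),
                "errors_Hz": self.segments.errors.tolist(),
                "threshold_Hz": self.segments.threshold,
                "best_nseg": self.segments.best_nseg,
                "adequate": self.segments.adequate,
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
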