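"""Metabolite quantification from 1D NMR spectra and intensity normalization.

A spectrum is an intensity trace over a chemical-shift (ppm) axis. Each
metabolite is described by a static template: a list of peaks
(center ppm, relative area, linewidth as full width at half maximum) with a
Lorentzian or Gaussian lineshape, multiplet fine structure baked into the
peak list. Quantification is a constrained template regression: the observed
spectrum is modelled as

    y(d) = sum_m c_m * T_m(d - D_m) + poly(d)

and solved for nonnegative intensities ``c_m``, per-metabolite shifts
``D_m`` (coordinate grid search within ``+-max_shift``), and a sign-free
polynomial baseline. This is a deterministic desk-scale stand-in for Bayesian
spectral deconvolution tools; the fitted intensity of a metabolite is the
scale of its unit-area template, i.e. proportional to concentration.

Spectra are calibrated beforehand by pinning the lactate methyl apex to
1.310 ppm, and fitted intensity matrices are normalized in two steps:
per-sample DNA concentration (tissue-amount correction), then median-based
scaling to a common reference.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

__all__ = [
    "Spectrum",
    "MetaboliteTemplate",
    "TemplateLibrary",
    "FitResult",
    "FitConfig",
    "MetaboliteMatrix",
    "template_profile",
    "load_template_library",
    "default_template_library",
    "read_spectrum",
    "write_spectrum",
    "calibrate_to_lactate",
    "fit_spectrum",
    "quantify_spectra",
    "normalize_dna",
    "normalize_median",
]


class SpectrumParseError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


class FitError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass
class Spectrum:
    """An intensity trace on a strictly monotone ppm axis.

    The axis is normalized to ascending order on construction; descending
    input is accepted and reversed together with its intensities.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise SpectrumParseError("ppm and intensity must be 1-D and equal length")
        d = np.diff(self.ppm)
        if len(d) and np.all(d < 0):
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif len(d) and not np.all(d > 0):
            raise SpectrumParseError("ppm axis must be strictly monotone")


@dataclass
class MetaboliteTemplate:
    """Peak list of one metabolite; relative areas sum to 1."""

    name: str
    peaks: list[tuple[float, float, float]]  # (center ppm, relative area, fwhm ppm)
    lineshape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown lineshape {self.lineshape!r}")
        total = sum(a for _, a, _ in self.peaks)
        if not self.peaks or total <= 0:
            raise ValueError(f"template {self.name!r} has no peak area")
        if any(w <= 0 for _, _, w in self.peaks):
            raise ValueError(f"template {self.name!r} has non-positive linewidth")
        # normalize so fitted coefficients are on a common (unit-area) scale
        self.peaks = [(c, a / total, w) for c, a, w in self.peaks]


TemplateLibrary = dict[str, MetaboliteTemplate]


def template_profile(
    template: MetaboliteTemplate, ppm: np.ndarray, shift: float = 0.0
) -> np.ndarray:
    """Evaluate a unit-area template on a ppm grid, shifted by ``shift``."""
    ppm = np.asarray(ppm, dtype=float)
    out = np.zeros_like(ppm)
    for center, area, fwhm in template.peaks:
        c = center + shift
        if template.lineshape == "lorentzian":
            gamma = fwhm / 2.0
            out += area * (gamma / math.pi) / ((ppm - c) ** 2 + gamma**2)
        else:
            sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            out += (
                area
                / (sigma * math.sqrt(2.0 * math.pi))
                * np.exp(-0.5 * ((ppm - c) / sigma) ** 2)
            )
    return out


def load_template_library(path: str | Path) -> TemplateLibrary:
    """Read a JSON template library: array of {name, lineshape, peaks:[...]}."""
    with open(path) as fh:
        raw = json.load(fh)
    lib: TemplateLibrary = {}
    for entry in raw:
        tmpl = MetaboliteTemplate(
            name=entry["name"],
            peaks=[
                (p["center"], p["relative_area"], p["linewidth"])
                for p in entry["peaks"]
            ],
            lineshape=entry.get("lineshape", "lorentzian"),
        )
        lib[tmpl.name] = tmpl
    return lib


def default_template_library() -> TemplateLibrary:
    """Bundled library: lactate, creatine, glycine, choline, phosphocholine,
    myo-inositol, with literature chemical shifts."""
    return load_template_library(
        Path(__file__).parent / "templates" / "default_templates.json"
    )


def read_spectrum(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Read a two-column (ppm, intensity) whitespace/tab text file.

    A single non-numeric header row is tolerated; any later ragged or
    non-numeric row is a parse error reporting its line number.
    """
    path = Path(path)
    ppm, inten = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            try:
                if len(parts) != 2:
                    raise ValueError
                a, b = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1 and not ppm:  # header row
                    continue
                raise SpectrumParseError(
                    f"{path}: cannot parse line {lineno}: {line.strip()!r}"
                ) from None
            ppm.append(a)
            inten.append(b)
    if not ppm:
        raise SpectrumParseError(f"{path}: no numeric data rows")
    return Spectrum(
        ppm=np.array(ppm),
        intensity=np.array(inten),
        sample_id=sample_id if sample_id is not None else path.stem,
    )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as a two-column TSV with full precision."""
    with open(path, "w") as fh:
        fh.write("ppm\tintensity\n")
        for p, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{float(p)!r}\t{float(y)!r}\n")


def calibrate_to_lactate(
    spectrum: Spectrum,
    reference: float = 1.310,
    window: tuple[float, float] = (1.2, 1.45),
) -> tuple[Spectrum, float]:
    """Shift the ppm axis so the window's apex sits at the reference.

    The maximum-intensity point within ``window`` is taken as the lactate
    methyl apex; the returned offset is ``reference - located_position``
    and the whole axis is shifted by it. A window with no strict interior
    maximum (flat signal) is a calibration error.
    """
    lo, hi = min(window), max(window)
    if lo > reference or hi < reference:
        raise CalibrationError("window must contain the reference position")
    mask = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if not mask.any():
        raise CalibrationError("window lies outside the ppm axis")
    seg = spectrum.intensity[mask]
    if np.ptp(seg) == 0:
        raise CalibrationError("flat spectrum in calibration window: no unique apex")
    pos = spectrum.ppm[mask]
    # candidate apexes: the maximum of each contiguous run of points within
    # 80% of the window maximum -- an equal doublet yields one candidate per
    # line, and noise cannot swap the choice between near-equal lines
    floor = seg.min()
    high = (seg - floor) >= 0.8 * (seg.max() - floor)
    candidates = []
    start = None
    for i, flag in enumerate(np.append(high, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            run = slice(start, i)
            candidates.append(pos[run][np.argmax(seg[run])])
            start = None
    candidates = np.asarray(candidates)
    # the apex requiring the smallest axis shift wins
    apex = candidates[np.argmin(np.abs(reference - candidates))]
    offset = reference - apex
    shifted = Spectrum(
        ppm=spectrum.ppm + offset,
        intensity=spectrum.intensity.copy(),
        sample_id=spectrum.sample_id,
    )
    return shifted, float(offset)


@dataclass
class FitConfig:
    max_shift: float = 0.01  # ppm, half-width of the per-metabolite shift search
    shift_grid_step: float = 0.001  # ppm
    baseline_degree: int = 3
    qc_threshold: float = 0.25  # relative residual above which a fit fails QC


@dataclass
class FitResult:
    intensities: dict[str, float]
    shifts: dict[str, float]
    baseline_coeffs: np.ndarray
    relative_residual: float
    passed_qc: bool
    sample_id: str = ""


def _design_columns(
    spectrum: Spectrum,
    library: TemplateLibrary,
    shifts: dict[str, float],
    degree: int,
) -> np.ndarray:
    cols = [
        template_profile(library[name], spectrum.ppm, shift=shifts[name])
        for name in library
    ]
    # Legendre-style scaled polynomial baseline, numerically well conditioned
    t = np.linspace(-1.0, 1.0, spectrum.ppm.size)
    cols.extend(t**d for d in range(degree + 1))
    return np.column_stack(cols)


def _solve(
    y: np.ndarray, design: np.ndarray, n_templates: int
) -> tuple[np.ndarray, float]:
    n_base = design.shape[1] - n_templates
    lb = np.concatenate([np.zeros(n_templates), np.full(n_base, -np.inf)])
    ub = np.full(design.shape[1], np.inf)
    res = lsq_linear(design, y, bounds=(lb, ub), method="bvls")
    resid = y - design @ res.x
    return res.x, float(np.linalg.norm(resid))


def fit_spectrum(
    spectrum: Spectrum,
    library: TemplateLibrary,
    config: FitConfig | None = None,
) -> FitResult:
    """Quantify library metabolites in a spectrum by constrained regression.

    Minimizes ``||y - (sum_m c_m T_m(d - D_m) + poly(d))||_2`` with
    ``c_m >= 0``. Shifts are optimized by one pass of per-metabolite
    coordinate search over the grid ``+-max_shift`` (step
    ``shift_grid_step``), refitting all coefficients at each candidate;
    ties prefer the smaller |shift|, so the objective is non-increasing
    across the pass. QC passes when the relative residual
    ``||y - fit|| / ||y||`` is at or below ``qc_threshold``.
    """
    config = config or FitConfig()
    if not np.isfinite(spectrum.intensity).all():
        raise FitError("spectrum contains non-finite intensities")
    y = spectrum.intensity
    y_norm = float(np.linalg.norm(y))
    if y_norm == 0:
        raise FitError("all-zero spectrum")
    lo, hi = spectrum.ppm[0], spectrum.ppm[-1]
    for name, tmpl in library.items():
        if not any(lo <= c <= hi for c, _, _ in tmpl.peaks):
            raise FitError(f"template {name!r} does not overlap the ppm range")

    names = list(library)
    shifts = {name: 0.0 for name in names}
    n_steps = max(1, int(round(config.max_shift / config.shift_grid_step)))
    grid = config.shift_grid_step * np.arange(-n_steps, n_steps + 1)
    grid = grid[np.argsort(np.abs(grid), kind="stable")]  # prefer small |shift|

    design = _design_columns(spectrum, library, shifts, config.baseline_degree)
    coef, best_obj = _solve(y, design, len(names))
    for i, name in enumerate(names):
        best_shift = shifts[name]
        for delta in grid:
            if delta == best_shift:
                continue
            trial = dict(shifts, **{name: float(delta)})
            trial_design = _design_columns(
                spectrum, library, trial, config.baseline_degree
            )
            trial_coef, obj = _solve(y, trial_design, len(names))
            if obj < best_obj - 1e-12 * y_norm:
                best_obj, best_shift, coef = obj, float(delta), trial_coef
        shifts[name] = best_shift

    rel = best_obj / y_norm
    return FitResult(
        intensities={name: float(max(coef[i], 0.0)) for i, name in enumerate(names)},
        shifts=dict(shifts),
        baseline_coeffs=coef[len(names):].copy(),
        relative_residual=rel,
        passed_qc=rel <= config.qc_threshold,
        sample_id=spectrum.sample_id,
    )


@dataclass
class MetaboliteMatrix:
    """Metabolites x samples intensities plus the normalization stage."""

    values: pd.DataFrame
    stage: str = "raw"  # raw | dna_normalized | median_normalized

    def __post_init__(self) -> None:
        if self.stage == "raw" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw intensities must be nonnegative")


def quantify_spectra(
    spectra: list[Spectrum],
    library: TemplateLibrary,
    config: FitConfig | None = None,
    calibrate: bool = True,
) -> tuple[MetaboliteMatrix, list[FitResult]]:
    """Calibrate, fit and assemble a raw metabolite matrix.

    Spectra failing QC are excluded from the matrix (their FitResult is
    still returned, flagged), mirroring quality gating of unfittable
    spectra in practice.
    """
    fits = []
    for s in spectra:
        if calibrate:
            s, _ = calibrate_to_lactate(s)
        fits.append(fit_spectrum(s, library, config))
    passed = [f for f in fits if f.passed_qc]
    if not passed:
        values = pd.DataFrame(index=list(library), columns=[], dtype=float)
    else:
        values = pd.DataFrame(
            {f.sample_id: f.intensities for f in passed}
        ).reindex(list(library))
    return MetaboliteMatrix(values=values, stage="raw"), fits


def normalize_dna(
    matrix: MetaboliteMatrix, dna_conc: pd.Series | dict[str, float]
) -> MetaboliteMatrix:
    """Divide each sample column by its DNA concentration (tissue amount)."""
    if matrix.stage != "raw":
        raise NormalizationError(f"expected raw matrix, got stage {matrix.stage!r}")
    conc = pd.Series(dna_conc)
    missing = [s for s in matrix.values.columns if s not in conc.index]
    if missing:
        raise NormalizationError(f"missing DNA concentration for samples: {missing}")
    conc = conc.loc[matrix.values.columns]
    if (conc <= 0).any():
        bad = list(conc.index[conc <= 0])
        raise NormalizationError(f"non-positive DNA concentration for: {bad}")
    return MetaboliteMatrix(
        values=matrix.values.div(conc, axis=1), stage="dna_normalized"
    )


def normalize_median(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Scale each sample so all column medians equal the median of medians."""
    values = matrix.values
    medians = values.median(axis=0)
    if (medians <= 0).any():
        bad = list(medians.index[medians <= 0])
        raise NormalizationError(f"non-positive column median for: {bad}")
    reference = float(medians.median())
    scaled = values.mul(reference / medians, axis=1)
    return MetaboliteMatrix(values=scaled, stage="median_normalized")
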