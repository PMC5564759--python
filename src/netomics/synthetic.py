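"""Synthetic cohorts with planted cross-omic structure.

Every downstream stage of the pipeline (network construction, module
detection, module-metabolite integration, enrichment, survival) is exercised
on cohorts generated here, where the ground truth -- module memberships,
metabolite-module associations, subtype labels, group hazards -- is known
exactly.

The generative model is deliberately simple: each co-expression module m has
an independent latent factor ``E_m`` (one standard-normal value per sample);
a gene of module m is a noisy loading on that factor,

    x_g = u_g * E_m + sqrt(1 - u_g**2) * eps,   eps ~ N(0, 1),

with the loading ``u_g`` drawn uniformly from a configurable range, so that
``u_g`` is also the population correlation between the gene and its factor.
Metabolites tied to a module reuse the *same* per-sample factor values,

    y_j = r * E_k + sqrt(1 - r**2) * eps,

which guarantees the cross-omic correlation the integration stage must
recover. Background genes and unassociated metabolites are pure noise.
All randomness flows through an explicit :func:`numpy.random.default_rng`
seed; two calls with the same configuration are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nmr import Spectrum, TemplateLibrary, template_profile

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_expression",
    "simulate_metabolites",
    "simulate_spectra",
    "simulate_survival",
    "simulate_subtype_cohort",
    "simulate_cohort",
]


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of a planted-module cohort.

    ``metabolite_spec`` entries are ``(metabolite_id, module_label, r)``
    where ``module_label`` is the 1-based label of the target module
    (0 denotes background and is not a valid target) and ``r`` is the
    planted metabolite-eigengene correlation, |r| < 1.
    """

    n_samples: int = 60
    n_modules: int = 6
    genes_per_module: int = 50
    n_background_genes: int = 700
    loading_range: tuple[float, float] = (0.6, 0.95)
    metabolite_spec: list[tuple[str, int, float]] = field(
        default_factory=lambda: [
            ("creatine", 1, 0.8),
            ("choline", 2, 0.8),
            ("glycine", 3, 0.8),
            ("lactate", 4, 0.8),
        ]
    )
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 3:
            raise InvalidConfigError("n_samples must be >= 3")
        for name, value in [
            ("n_modules", self.n_modules),
            ("genes_per_module", self.genes_per_module),
        ]:
            if value <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.n_background_genes < 0:
            raise InvalidConfigError("n_background_genes must be >= 0")
        lo, hi = self.loading_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise InvalidConfigError("loading_range must satisfy 0 <= lo <= hi <= 1")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be positive")
        for met, module, r in self.metabolite_spec:
            if module != 0 and not (1 <= module <= self.n_modules):
                raise InvalidConfigError(
                    f"metabolite {met!r} targets module {module}, "
                    f"but modules are labelled 1..{self.n_modules}"
                )
            if abs(r) >= 1:
                raise InvalidConfigError(f"metabolite {met!r}: |r| must be < 1")


@dataclass
class SyntheticCohort:
    """A generated cohort together with its ground truth."""

    expression: pd.DataFrame  # genes x samples
    true_module_labels: pd.Series  # gene -> module label, 0 = background
    factors: pd.DataFrame  # module x samples latent factors
    metabolites: pd.DataFrame  # metabolites x samples
    true_associations: dict[str, tuple[int, float]]
    survival: pd.DataFrame  # sample, time, event, group
    subtype_labels: pd.Series  # sample -> label


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Generate a genes x samples matrix with planted co-expression modules.

    Returns ``(expression, true_module_labels, factors)``. Rows are
    standardized to mean 0, sd 1 after noise injection, so planted loadings
    are interpretable as gene-factor correlations. Module labels are
    1..n_modules; background genes carry label 0.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m, g = config.n_samples, config.n_modules, config.genes_per_module
    lo, hi = config.loading_range

    factors = rng.standard_normal((m, n))
    rows, labels = [], []
    for k in range(m):
        u = rng.uniform(lo, hi, size=g)
        eps = rng.standard_normal((g, n))
        rows.append(u[:, None] * factors[k] + np.sqrt(1.0 - u[:, None] ** 2) * eps)
        labels.extend([k + 1] * g)
    if config.n_background_genes:
        rows.append(
            config.noise_sd * rng.standard_normal((config.n_background_genes, n))
        )
        labels.extend([0] * config.n_background_genes)

    x = _standardize_rows(np.vstack(rows))
    genes = [f"gene{i + 1:05d}" for i in range(x.shape[0])]
    samples = [f"S{j + 1:03d}" for j in range(n)]
    expr = pd.DataFrame(x, index=genes, columns=samples)
    lab = pd.Series(labels, index=genes, name="module")
    fdf = pd.DataFrame(
        factors, index=[f"M{k + 1}" for k in range(m)], columns=samples
    )
    return expr, lab, fdf


def simulate_metabolites(
    factors: pd.DataFrame,
    metabolite_spec: list[tuple[str, int, float]],
    seed: int,
    n_samples: int | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[int, float]]]:
    """Metabolite intensities correlated with chosen module factors.

    ``factors`` is the module x samples latent-factor matrix returned by
    :func:`simulate_expression` (reusing it is what plants the cross-omic
    correlation). Entries with module label 0 or r == 0 are pure noise.
    """
    rng = np.random.default_rng(seed)
    n = factors.shape[1] if n_samples is None else n_samples
    values, names, truth = [], [], {}
    for met, module, r in metabolite_spec:
        if abs(r) >= 1:
            raise InvalidConfigError(f"metabolite {met!r}: |r| must be < 1")
        eps = rng.standard_normal(n)
        if module == 0 or r == 0.0:
            y = eps
            truth[met] = (0, 0.0)
        else:
            label = f"M{module}"
            if label not in factors.index:
                raise InvalidConfigError(f"metabolite {met!r} targets unknown module {module}")
            y = r * factors.loc[label].to_numpy() + np.sqrt(1.0 - r * r) * eps
            truth[met] = (module, r)
        values.append(y)
        names.append(met)
    metab = pd.DataFrame(np.vstack(values), index=names, columns=factors.columns[:n])
    return metab, truth


def simulate_spectra(
    concentrations: dict[str, float],
    library: TemplateLibrary,
    snr: float | None = 50.0,
    shift_jitter: float = 0.0,
    seed: int = 0,
    ppm_min: float = 0.5,
    ppm_max: float = 4.5,
    ppm_step: float = 0.001,
    sample_id: str = "synthetic",
) -> tuple[Spectrum, dict[str, float]]:
    """A 1D spectrum as a noisy mixture of known metabolite templates.

    Each template is shifted by an independent uniform offset in
    ``+-shift_jitter`` ppm and scaled by its concentration; Gaussian noise
    is added so that (clean peak max) / (noise sd) equals ``snr``
    (``snr=None`` disables noise). Returns the spectrum and the true
    per-metabolite shifts.
    """
    rng = np.random.default_rng(seed)
    for met, c in concentrations.items():
        if c < 0:
            raise InvalidConfigError(f"negative concentration for {met!r}")
        if met not in library:
            raise InvalidConfigError(f"metabolite {met!r} not in template library")
    ppm = np.arange(ppm_min, ppm_max + ppm_step / 2, ppm_step)
    clean = np.zeros_like(ppm)
    shifts: dict[str, float] = {}
    for met, c in concentrations.items():
        delta = rng.uniform(-shift_jitter, shift_jitter) if shift_jitter > 0 else 0.0
        shifts[met] = delta
        clean += c * template_profile(library[met], ppm, shift=delta)
    intensity = clean
    if snr is not None:
        noise_sd = clean.max() / snr
        intensity = clean + rng.normal(0.0, noise_sd, size=ppm.size)
    return Spectrum(ppm=ppm, intensity=intensity, sample_id=sample_id), shifts


def simulate_survival(
    groups: pd.Series,
    hazard_by_group: dict[str, float],
    censor_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times with independent exponential censoring.

    ``censor_rate`` is the expected censored fraction per group: censoring
    hazard is ``h * c / (1 - c)`` so that P(censored) = c. Returns a table
    of (sample, time, event, group) with event = 1 when the event precedes
    censoring.
    """
    if not 0.0 <= censor_rate < 1.0:
        raise InvalidConfigError("censor_rate must be in [0, 1)")
    for g in pd.unique(groups):
        if g not in hazard_by_group:
            raise InvalidConfigError(f"unknown group label {g!r}")
        if hazard_by_group[g] <= 0:
            raise InvalidConfigError(f"hazard for group {g!r} must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, g in groups.items():
        h = hazard_by_group[g]
        t_event = rng.exponential(1.0 / h)
        if censor_rate > 0:
            hc = h * censor_rate / (1.0 - censor_rate)
            t_cens = rng.exponential(1.0 / hc)
        else:
            t_cens = np.inf
        rows.append(
            {
                "sample": sample,
                "time": min(t_event, t_cens),
                "event": int(t_event <= t_cens),
                "group": g,
            }
        )
    return pd.DataFrame(rows)


def simulate_subtype_cohort(
    n_samples: int = 200,
    n_subtypes: int = 4,
    markers_per_subtype: int = 40,
    n_noise_genes: int = 200,
    shift: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Labelled cohort with mean-shifted marker genes per subtype.

    Serves as training/evaluation data for the subtype classifier: each
    subtype has its own block of marker genes elevated by ``shift`` standard
    deviations in samples of that subtype.
    """
    if n_subtypes < 2:
        raise InvalidConfigError("need >= 2 subtypes")
    rng = np.random.default_rng(seed)
    labels = np.array(
        [f"subtype{i % n_subtypes + 1}" for i in range(n_samples)]
    )
    rng.shuffle(labels)
    n_genes = n_subtypes * markers_per_subtype + n_noise_genes
    x = rng.standard_normal((n_genes, n_samples))
    for k in range(n_subtypes):
        block = slice(k * markers_per_subtype, (k + 1) * markers_per_subtype)
        x[block, labels == f"subtype{k + 1}"] += shift
    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    return (
        pd.DataFrame(x, index=genes, columns=samples),
        pd.Series(labels, index=samples, name="subtype"),
    )


def simulate_cohort(
    config: SimulationConfig,
    hazard_by_group: dict[str, float] | None = None,
    censor_rate: float = 0.3,
    n_subtypes: int = 4,
) -> SyntheticCohort:
    """Full cohort: expression, metabolites, subtype labels and survival.

    Subtype labels are assigned round-robin; survival groups are the
    subtype labels with group-specific hazards (default: hazard doubles
    between the first and last subtype, linear in between — emulating
    prognostically distinct expression subgroups).
    """
    expr, labels, factors = simulate_expression(config)
    metab, truth = simulate_metabolites(
        factors, config.metabolite_spec, seed=config.seed + 1
    )
    rng = np.random.default_rng(config.seed + 2)
    subtype = np.array(
        [f"subtype{i % n_subtypes + 1}" for i in range(config.n_samples)]
    )
    rng.shuffle(subtype)
    subtypes = pd.Series(subtype, index=expr.columns, name="subtype")
    if hazard_by_group is None:
        hazards = np.linspace(1.0, 2.0, n_subtypes)
        hazard_by_group = {
            f"subtype{k + 1}": float(h) for k, h in enumerate(hazards)
        }
    survival = simulate_survival(
        subtypes, hazard_by_group, censor_rate=censor_rate, seed=config.seed + 3
    )
    return SyntheticCohort(
        expression=expr,
        true_module_labels=labels,
        factors=factors,
        metabolites=metab,
        true_associations=truth,
        survival=survival,
        subtype_labels=subtypes,
    )
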