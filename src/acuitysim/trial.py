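"""Virtual acuity trials, neural-parameter calibration and sensitivity.

A trial mirrors the reference measurement protocol: 14 letter sizes from
0.3 to -0.35 logMAR in 0.05 steps, all 26 letters presented once per
size, each with a fresh cone-noise realization.  Per size the noiseless
filtered letters double as the template set; recognition produces a guess
set per presentation, Optotype-Correlation scoring turns the guesses into
a Rate of Recognition curve, and the logistic psychometric fit thresholds
it at RR0 = 0.68 to yield the acuity V.

Ablation variants: M0 is the full model; M1 sets the discrimination
range to zero (pure maximum-correlation decision); M2 replaces the
polychromatic PSF with the monochromatic 555 nm PSF; M3 additionally
fixes the pupil at 6 mm.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass, replace

import numpy as np

from .eye import ChromaticModel, chromatic_model, monochromatic_weighting
from .neural import ConeLattice, NeuralParams, build_ntf
from .psf import (DEFAULT_GRID, GridSpec, PSFImage, TransferFunction,
                  best_focus, otf_from_psf, polychromatic_psf)
from .recognition import TemplateMatcher, TemplateSet, make_templates
from .scoring import (OCMatrix, PsychometricFit, fit_psychometric, oc_matrix,
                      rate_of_recognition, score_letter)
from .wavefront import SubjectRecord, defocus_coefficient

#: The 14 tested letter sizes, logMAR.
TRIAL_SIZES = tuple(np.round(np.arange(0.30, -0.351, -0.05), 10))

VARIANTS = ("M0", "M1", "M2", "M3")


@dataclass(frozen=True)
class TrialResult:
    """One simulated acuity test."""

    subject_id: str
    variant: str
    sigma: float
    delta_rho: float
    seed: int
    sizes: tuple[float, ...]
    rr: np.ndarray               # (14,) rate of recognition per size
    scores: np.ndarray           # (14, 26) per-letter OC scores
    fit: PsychometricFit
    acuity: float                # V, logMAR
    pupil_mm: float
    extra_defocus: float         # best-focus Z_2^0, lambda0 units
    rhos: np.ndarray | None = None  # (size, displayed, template) if kept


# ---------------------------------------------------------------------------
# trial kernel: everything that does not depend on (sigma, delta_rho, seed)

@dataclass
class TrialKernel:
    """Noise-independent part of a trial: PSF, filtered templates and the
    correlation engines for every size."""

    subject: SubjectRecord
    variant: str
    pupil_mm: float
    extra_defocus: float
    psf: PSFImage
    templates: dict[float, TemplateSet]
    matchers: dict[float, TemplateMatcher]
    # per size: (26, side, side) deviation images and, per letter, the
    # factorized cone-lattice map (flat cell index per pixel, cell count)
    devs: dict[float, np.ndarray]
    noise_maps: dict[float, list[tuple[np.ndarray, int]]]
    oc: OCMatrix
    grid: GridSpec


_NTF_CACHE: dict[int, TransferFunction] = {}
_OC_CACHE: dict[float, OCMatrix] = {}
_CHROM_CACHE: dict[str, ChromaticModel] = {}


def default_ntf(grid: GridSpec = DEFAULT_GRID) -> TransferFunction:
    if grid.n not in _NTF_CACHE:
        _NTF_CACHE[grid.n] = build_ntf(grid=grid)
    return _NTF_CACHE[grid.n]


def default_oc() -> OCMatrix:
    if 0 not in _OC_CACHE:
        _OC_CACHE[0] = oc_matrix()
    return _OC_CACHE[0]


def default_chromatic() -> ChromaticModel:
    if "poly" not in _CHROM_CACHE:
        _CHROM_CACHE["poly"] = chromatic_model()
    return _CHROM_CACHE["poly"]


def build_kernel(subject: SubjectRecord, variant: str = "M0",
                 pupil_mm: float | None = None,
                 extra_defocus_D: float = 0.0,
                 grid: GridSpec = DEFAULT_GRID,
                 sizes=TRIAL_SIZES,
                 ntf: TransferFunction | None = None,
                 oc: OCMatrix | None = None,
                 chrom: ChromaticModel | None = None) -> TrialKernel:
    """Prepare the deterministic stages of a trial.

    ``extra_defocus_D`` perturbs the wavefront *after* best-focus
    optimization (artificial refractive error, used by the sensitivity
    analysis).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    d = 6.0 if variant == "M3" else float(pupil_mm if pupil_mm is not None
                                          else subject.d_m_mm)
    if chrom is None:
        chrom = (monochromatic_weighting() if variant in ("M2", "M3")
                 else default_chromatic())
    extra = best_focus(subject, d, chrom)
    c20 = extra + defocus_coefficient(extra_defocus_D, d, subject.lambda0_nm)
    psf = polychromatic_psf(subject, d, chrom, c20, grid)
    ntf = ntf or default_ntf(grid)
    oc = oc or default_oc()
    combined = (otf_from_psf(psf).rhalf * ntf.rhalf).astype(np.complex64)

    lattice = ConeLattice(grid)
    templates: dict[float, TemplateSet] = {}
    matchers: dict[float, TemplateMatcher] = {}
    devs: dict[float, np.ndarray] = {}
    noise_maps: dict[float, list[tuple[np.ndarray, int]]] = {}
    for s in sizes:
        ts = make_templates(psf, ntf, s, grid, combined_rhalf=combined)
        templates[s] = ts
        dev = (1.0 - ts.crops).astype(np.float32)
        devs[s] = dev
        matchers[s] = TemplateMatcher(dev, (ts.side, ts.side))
        maps = []
        for (r0, c0) in ts.origins:
            ids = lattice.window_ids(r0, r0 + ts.side, c0, c0 + ts.side)
            _, inv = np.unique(ids, return_inverse=True)
            maps.append((inv.astype(np.int32).reshape(ids.shape),
                         int(inv.max()) + 1))
        noise_maps[s] = maps
    return TrialKernel(subject, variant, d, float(extra), psf,
                       templates, matchers, devs, noise_maps, oc, grid)


class KernelCache:
    """Small LRU cache of trial kernels (they are expensive to build and
    reusable across seeds and neural-parameter settings)."""

    def __init__(self, capacity: int = 3):
        self.capacity = capacity
        self._store: OrderedDict[tuple, TrialKernel] = OrderedDict()

    def get(self, subject: SubjectRecord, variant: str = "M0",
            pupil_mm: float | None = None, extra_defocus_D: float = 0.0,
            grid: GridSpec = DEFAULT_GRID) -> TrialKernel:
        key = (subject.id, tuple(sorted(subject.coeffs.items())), variant,
               pupil_mm, extra_defocus_D, grid.n)
        if key not in self._store:
            kern = build_kernel(subject, variant, pupil_mm, extra_defocus_D, grid)
            self._store[key] = kern
            while len(self._store) > self.capacity:
                self._store.popitem(last=False)
        else:
            self._store.move_to_end(key)
        return self._store[key]


KERNELS = KernelCache()


# ---------------------------------------------------------------------------
# stochastic stages

def simulate_rhos(kernel: TrialKernel, sigma: float, seed: int) -> np.ndarray:
    """Peak-correlation tensor (size, displayed, template) for one trial.

    Presentation order is fixed (sizes large to small, letters A..Z);
    every presentation draws fresh per-cell cone noise from the
    seed-derived stream, so the result is deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n_sizes = len(kernel.templates)
    rhos = np.empty((n_sizes, 26, 26))
    for si, s in enumerate(kernel.templates):
        matcher = kernel.matchers[s]
        dev = kernel.devs[s]
        maps = kernel.noise_maps[s]
        for li in range(26):
            stim_dev = dev[li]
            if sigma > 0:
                inv, n_cells = maps[li]
                noise = rng.normal(0.0, sigma, n_cells).astype(np.float32)
                stim_dev = stim_dev - noise[inv]
            rhos[si, li] = matcher.rho(stim_dev)
    return rhos


def score_rhos(rhos: np.ndarray, delta_rho: float, oc: OCMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Guess sets and OC scores from a correlation tensor.

    Returns (rr per size, per-letter scores)."""
    n_sizes = rhos.shape[0]
    scores = np.empty((n_sizes, 26))
    for si in range(n_sizes):
        for li in range(26):
            rho = rhos[si, li]
            guesses = np.flatnonzero(rho >= rho.max() - delta_rho)
            scores[si, li] = oc.values[li, guesses].mean()
    rr = scores.mean(axis=1)
    return rr, scores


def run_trial(subject: SubjectRecord, params: NeuralParams, seed: int,
              variant: str = "M0", pupil_mm: float | None = None,
              kernel: TrialKernel | None = None,
              use_cache: bool = True, keep_rhos: bool = False) -> TrialResult:
    """Simulate one full acuity test and fit the psychometric function."""
    if kernel is None:
        if use_cache:
            kernel = KERNELS.get(subject, variant, pupil_mm)
        else:
            kernel = build_kernel(subject, variant, pupil_mm)
    delta_rho = 0.0 if variant in ("M1", "M2", "M3") else params.delta_rho
    sizes = tuple(kernel.templates)
    rhos = simulate_rhos(kernel, params.sigma, seed)
    rr, scores = score_rhos(rhos, delta_rho, kernel.oc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # extrapolation warning handled by caller
        fit = fit_psychometric(sizes, rr)
    return TrialResult(subject.id, variant, params.sigma, delta_rho, seed,
                       sizes, rr, scores, fit, fit.acuity,
                       kernel.pupil_mm, kernel.extra_defocus,
                       rhos if keep_rhos else None)


# ---------------------------------------------------------------------------
# fitting error and calibration

def delta_rr(sim_rr, meas_rr, mean: bool = False) -> float:
    """Fitting error between simulated and measured RR curves:
    sqrt(sum_i (RR_s(s_i) - RR_m(s_i))^2), the plain sum over the 14
    sizes; ``mean=True`` divides the sum by the number of sizes first."""
    a = np.asarray(sim_rr, dtype=float)
    b = np.asarray(meas_rr, dtype=float)
    if a.shape != b.shape:
        raise ValueError("RR curves must have matching sizes")
    ss = float(((a - b) ** 2).sum())
    if mean:
        ss /= a.size
    return float(np.sqrt(ss))


@dataclass(frozen=True)
class CalibrationResult:
    """Optimal neural parameters over the searched grid."""

    sigma: float
    delta_rho: float
    objective: float             # (mean) delta-RR at the optimum
    mode: str                    # "individual" or "pooled"
    sigmas: np.ndarray
    delta_rhos: np.ndarray
    table: np.ndarray            # (n_subjects, n_sigma, n_delta) delta-RR
    per_subject: dict[str, tuple[float, float, float]] | None = None


def calibration_grid(sigma_max: float = 0.15, sigma_step: float = 0.025,
                     delta_max: float = 0.005, delta_step: float = 0.0005):
    sigmas = np.round(np.arange(0.0, sigma_max + 1e-12, sigma_step), 6)
    deltas = np.round(np.arange(0.0, delta_max + 1e-12, delta_step), 6)
    return sigmas, deltas


def calibrate(references: dict[str, np.ndarray],
              kernels: dict[str, TrialKernel],
              sigmas=None, delta_rhos=None,
              seeds=(0,), mode: str = "pooled") -> CalibrationResult:
    """Grid-search the (sigma, delta_rho) plane against reference RR curves.

    ``references`` maps subject id to a measured (or surrogate) RR curve at
    the 14 trial sizes.  Per grid cell the fitting error is averaged over
    the seeds; ``individual`` mode minimizes per subject, ``pooled`` mode
    minimizes the subject-average error with common parameters.
    """
    if sigmas is None or delta_rhos is None:
        g_sig, g_del = calibration_grid()
        sigmas = g_sig if sigmas is None else np.asarray(sigmas, dtype=float)
        delta_rhos = g_del if delta_rhos is None else np.asarray(delta_rhos, dtype=float)
    sigmas = np.atleast_1d(np.asarray(sigmas, dtype=float))
    delta_rhos = np.atleast_1d(np.asarray(delta_rhos, dtype=float))
    if sigmas.size == 0 or delta_rhos.size == 0:
        raise ValueError("empty calibration grid")
    if mode not in ("pooled", "individual"):
        raise ValueError(f"unknown calibration mode {mode!r}")
    sids = list(references)
    table = np.zeros((len(sids), sigmas.size, delta_rhos.size))
    for ci, sid in enumerate(sids):
        kern = kernels[sid]
        ref = np.asarray(references[sid], dtype=float)
        for gi, sig in enumerate(sigmas):
            for seed in seeds:
                rhos = simulate_rhos(kern, float(sig), seed)
                for di, dr in enumerate(delta_rhos):
                    rr, _ = score_rhos(rhos, float(dr), kern.oc)
                    table[ci, gi, di] += delta_rr(rr, ref)
    table /= len(seeds)

    per_subject = None
    if mode == "individual":
        per_subject = {}
        objs = []
        for ci, sid in enumerate(sids):
            gi, di = np.unravel_index(np.argmin(table[ci]), table[ci].shape)
            per_subject[sid] = (float(sigmas[gi]), float(delta_rhos[di]),
                                float(table[ci, gi, di]))
            objs.append(table[ci, gi, di])
        # headline numbers: the mean of the individual optima
        sig_best = float(np.mean([v[0] for v in per_subject.values()]))
        dr_best = float(np.mean([v[1] for v in per_subject.values()]))
        return CalibrationResult(sig_best, dr_best, float(np.mean(objs)),
                                 mode, sigmas, delta_rhos, table, per_subject)
    pooled = table.mean(axis=0)
    gi, di = np.unravel_index(np.argmin(pooled), pooled.shape)
    return CalibrationResult(float(sigmas[gi]), float(delta_rhos[di]),
                             float(pooled[gi, di]), mode, sigmas, delta_rhos,
                             table, None)


# ---------------------------------------------------------------------------
# sensitivity analysis

@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    required_change: float
    magnitudes: np.ndarray
    mean_abs_dv: np.ndarray
    target_dv: float


SENSITIVITY_PARAMS = ("pupil", "RE", "sigma", "delta_rho")


def sensitivity(subjects, parameter: str, params: NeuralParams,
                magnitudes, seeds=(0,), target_dv: float = 0.05,
                two_sided: bool = True,
                cache: KernelCache | None = None) -> SensitivityResult:
    """Inverse-sensitivity analysis: the parameter change producing a
    ``target_dv`` (default 0.05 logMAR) acuity shift.

    For each perturbation magnitude the acuity change |V' - V| is averaged
    over subjects, seeds and (optionally) both perturbation signs; the
    required change interpolates the crossing of ``target_dv`` on the
    piecewise-linear |dV|(magnitude) curve anchored at (0, 0).
    """
    if parameter not in SENSITIVITY_PARAMS:
        raise ValueError(f"unknown parameter {parameter!r}")
    if target_dv == 0:
        return SensitivityResult(parameter, 0.0, np.asarray(magnitudes, float),
                                 np.zeros(len(magnitudes)), 0.0)
    cache = cache or KERNELS
    mags = np.sort(np.abs(np.asarray(magnitudes, dtype=float)))
    signs = (+1.0, -1.0) if two_sided else (+1.0,)

    base_v: dict[tuple[str, int], float] = {}
    for subj in subjects:
        kern = cache.get(subj)
        for seed in seeds:
            base_v[(subj.id, seed)] = run_trial(subj, params, seed,
                                                kernel=kern).acuity
    mean_abs = np.zeros(mags.size)
    for mi, mag in enumerate(mags):
        dvs = []
        for subj in subjects:
            for sign in signs:
                pert = sign * mag
                for seed in seeds:
                    v = _perturbed_acuity(subj, parameter, pert, params, seed, cache)
                    if v is None:
                        continue
                    dvs.append(abs(v - base_v[(subj.id, seed)]))
        mean_abs[mi] = np.mean(dvs)
    x = np.concatenate([[0.0], mags])
    y = np.concatenate([[0.0], mean_abs])
    if target_dv > y.max():
        warnings.warn("target acuity change not reached within the scanned "
                      "range; extrapolating linearly", stacklevel=2)
        required = x[-1] * target_dv / y[-1]
    else:
        required = float(np.interp(target_dv, y, x))
    return SensitivityResult(parameter, float(required), mags, mean_abs, target_dv)


def _perturbed_acuity(subj: SubjectRecord, parameter: str, pert: float,
                      params: NeuralParams, seed: int,
                      cache: KernelCache) -> float | None:
    if parameter == "pupil":
        d = subj.d_m_mm + pert
        if not 1.0 < d < 9.0:
            return None
        kern = cache.get(subj, pupil_mm=d)
        return run_trial(subj, params, seed, kernel=kern).acuity
    if parameter == "RE":
        kern = cache.get(subj, extra_defocus_D=pert)
        return run_trial(subj, params, seed, kernel=kern).acuity
    if parameter == "sigma":
        sig = params.sigma + pert
        if sig < 0:
            return None
        kern = cache.get(subj)
        return run_trial(subj, replace(params, sigma=sig), seed, kernel=kern).acuity
    dr = params.delta_rho + pert
    if dr < 0:
        return None
    kern = cache.get(subj)
    return run_trial(subj, replace(params, delta_rho=dr), seed, kernel=kern).acuity
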