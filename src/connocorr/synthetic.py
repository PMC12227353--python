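"""Synthetic longitudinal multimodal regional data with known ground truth.

The generator emulates the structure of two longitudinal neuroimaging
designs — a densely-sampled single subject (~70 sessions over 16 years) and
an aging cohort (~70 subjects, 5–9 sessions each, first-session ages in the
60s–80s) — with regional values produced from three separable variance
sources plus measurement noise:

``value(subject, session, roi) = cubic_age(roi) + trait(roi) + state(roi) + noise``

* the **age** component is a per-ROI cubic trajectory whose subject-level
  coefficient perturbations are coupled across ROIs by a network-modular
  correlation matrix (slow, smooth within-person change);
* the **trait** component is a stable per-subject offset drawn once from its
  own modular covariance (between-person differences);
* the **state** component is an independent per-session draw (session-to-
  session fluctuations of sustained activity);
* **noise** is i.i.d. measurement error.

Because each source has its own correlation target, every downstream
correlation-matrix construction has a parameter-recovery test: with only one
source active, the matching empirical matrix converges to that source's
target. Modality presets encode the qualitative contrast the pipeline is
built to expose — volume-like data dominated by slow age effects, ReHo-like
and PET-like data dominated by state variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.ndimage import gaussian_filter

from .connmat import RegionalMeasureTable
from .measures import LabelVolume

__all__ = [
    "AtlasSpec",
    "CovSpec",
    "ExplicitCov",
    "random_factor_correlation",
    "LongitudinalDesign",
    "GenerativeParams",
    "make_atlas",
    "default_atlas",
    "make_network_covariance",
    "simulate_measures",
    "simulate_roi_timeseries",
    "simulate_voxel_session",
    "make_label_volume",
    "preset_params",
    "preset_design",
]

CORTICAL_NETWORKS = ("Vis", "SomMot", "DorsAttn", "SalVentAttn",
                     "Limbic", "Cont", "Default")
SUBCORTICAL_STRUCTURES = ("Hippocampus", "ParaHippocampal", "Amygdala",
                          "Caudate", "Putamen", "Pallidum", "Thalamus")

# Relative weight of the linear/quadratic/cubic coefficient perturbations in
# the age component, and the variance of u^k for u ~ U(-1, 1) used to put the
# component's across-session variance on the scale of CovSpec.variance_scale.
_AGE_POWER_WEIGHTS = (0.5, 0.3, 0.2)
_U_POWER_VAR = (1.0 / 3.0, 4.0 / 45.0, 1.0 / 7.0)


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtlasSpec:
    """ROI labels, network assignment and homotopic (left/right) pairing.

    The default layout follows the common 114-region convention: ROIs 1–50
    left cortex, 51–100 right cortex (seven networks per hemisphere, mirror
    ordered), 101–114 bilateral subcortical structures. Indices here are
    0-based.
    """

    roi_names: tuple
    network_labels: tuple
    homotopic_pairs: tuple

    def __post_init__(self):
        if len(self.roi_names) != len(self.network_labels):
            raise ValueError("every ROI needs exactly one network label")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("ROI names must be unique")
        seen = set()
        for a, b in self.homotopic_pairs:
            if not (0 <= a < self.n_roi and 0 <= b < self.n_roi) or a == b:
                raise ValueError(f"invalid homotopic pair ({a}, {b})")
            if a in seen or b in seen:
                raise ValueError("homotopic pairs must be disjoint")
            seen.update((a, b))

    @property
    def n_roi(self) -> int:
        return len(self.roi_names)


def make_atlas(n_cortical_per_hemi: int = 50,
               networks: tuple = CORTICAL_NETWORKS,
               subcortical: tuple = SUBCORTICAL_STRUCTURES) -> AtlasSpec:
    """Build an atlas with mirror-ordered hemispheres and bilateral
    subcortical structures.

    The ``n_cortical_per_hemi`` regions per hemisphere are split near-equally
    over the given networks; homotopic pairs are (i, i + n_cortical_per_hemi)
    for cortex and left/right subcortical counterparts.
    """
    if n_cortical_per_hemi < len(networks):
        raise ValueError("need at least one cortical ROI per network per hemisphere")
    base, extra = divmod(n_cortical_per_hemi, len(networks))
    sizes = [base + (1 if i < extra else 0) for i in range(len(networks))]

    names, nets = [], []
    for hemi in ("LH", "RH"):
        for net, size in zip(networks, sizes):
            for k in range(size):
                names.append(f"{hemi}_{net}_{k + 1}")
                nets.append(net)
    for hemi in ("LH", "RH"):
        for s in subcortical:
            names.append(f"{hemi}_{s}")
            nets.append("Subcortical")

    nsub = len(subcortical)
    pairs = [(i, i + n_cortical_per_hemi) for i in range(n_cortical_per_hemi)]
    pairs += [(2 * n_cortical_per_hemi + k, 2 * n_cortical_per_hemi + nsub + k)
              for k in range(nsub)]
    return AtlasSpec(tuple(names), tuple(nets), tuple(pairs))


@lru_cache(maxsize=1)
def default_atlas() -> AtlasSpec:
    """The standard 114-ROI atlas (100 cortical + 14 subcortical)."""
    return make_atlas()


# ---------------------------------------------------------------------------
# Covariance construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovSpec:
    """Block-structured correlation target plus a per-ROI variance scale.

    ``within_network_r`` applies to same-network pairs, ``homotopic_r`` to
    configured left/right pairs (overrides), ``between_network_r`` elsewhere.
    ``variance_scale`` is the per-ROI variance (scalar or length-n_roi array)
    applied when the correlation target is turned into a covariance.
    """

    within_network_r: float = 0.0
    homotopic_r: float = 0.0
    between_network_r: float = 0.0
    variance_scale: float | np.ndarray = 1.0

    def __post_init__(self):
        for name in ("within_network_r", "homotopic_r"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not (-1.0 < self.between_network_r < 1.0):
            raise ValueError("between_network_r must be in (-1, 1)")
        if np.any(np.asarray(self.variance_scale, dtype=float) < 0):
            raise ValueError("variance_scale must be non-negative")


def make_network_covariance(atlas: AtlasSpec, spec: CovSpec) -> np.ndarray:
    """Network-modular correlation matrix for an atlas.

    Entries are ``within_network_r`` for same-network pairs, ``homotopic_r``
    at the configured (left, right) index pairs and ``between_network_r``
    otherwise, with unit diagonal. If the result is indefinite it is repaired
    by clipping negative eigenvalues at zero and re-normalizing to unit
    diagonal (entries may shrink slightly from the requested values); a spec
    that cannot be repaired raises, naming the offending minimum eigenvalue.
    """
    p = atlas.n_roi
    nets = np.asarray(atlas.network_labels)
    C = np.full((p, p), float(spec.between_network_r))
    same = nets[:, None] == nets[None, :]
    C[same] = spec.within_network_r
    for a, b in atlas.homotopic_pairs:
        C[a, b] = C[b, a] = spec.homotopic_r
    np.fill_diagonal(C, 1.0)

    w = np.linalg.eigvalsh(C)
    if w[0] < -1e-10:
        wc, V = np.linalg.eigh(C)
        repaired = (V * np.clip(wc, 0.0, None)) @ V.T
        d = np.diag(repaired).copy()
        if d.min() <= 1e-10:
            raise ValueError(
                "covariance spec is not PSD-repairable: minimum eigenvalue "
                f"{w[0]:.6g} leaves a zero-variance ROI after clipping")
        C = repaired / np.sqrt(np.outer(d, d))
        np.fill_diagonal(C, 1.0)
        C = (C + C.T) / 2.0
    return C


@dataclass(frozen=True)
class ExplicitCov:
    """An explicit correlation-matrix target for a variance source, for
    studies whose ground truth is not block-structured (e.g. graded
    factor-model correlations, where every ROI pair has a distinct target
    value and rank-agreement recovery is meaningful)."""

    matrix: np.ndarray
    variance_scale: float | np.ndarray = 1.0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"need a square matrix, got shape {m.shape}")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        object.__setattr__(self, "matrix", m)


def random_factor_correlation(n_roi: int, n_factors: int = 10,
                              unique_var: float = 1.0,
                              seed: int = 0) -> np.ndarray:
    """Graded correlation matrix from a random k-factor model.

    cov = L L' + unique_var * I with Gaussian loadings L, normalized to unit
    diagonal. Unlike the block targets, the entries are continuously
    distributed, so rank-based recovery of the structure is well posed.
    """
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((n_roi, n_factors))
    cov = L @ L.T + unique_var * np.eye(n_roi)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def _source_correlation(spec, atlas: AtlasSpec) -> np.ndarray:
    if isinstance(spec, ExplicitCov):
        if spec.matrix.shape[0] != atlas.n_roi:
            raise ValueError(
                f"explicit covariance has {spec.matrix.shape[0]} ROIs, "
                f"atlas has {atlas.n_roi}")
        return spec.matrix
    return make_network_covariance(atlas, spec)


def _cov_factor(corr: np.ndarray, variance: float | np.ndarray) -> np.ndarray:
    """Factor F with F F' = diag(sd) corr diag(sd); tiny negative eigenvalues
    of a numerically PSD input are clipped."""
    sd = np.sqrt(np.broadcast_to(np.asarray(variance, dtype=float),
                                 (corr.shape[0],)))
    cov = corr * np.outer(sd, sd)
    w, V = np.linalg.eigh((cov + cov.T) / 2.0)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError(f"covariance is not PSD (min eigenvalue {w.min():.6g})")
    return V * np.sqrt(np.clip(w, 0.0, None))


# ---------------------------------------------------------------------------
# Longitudinal design and generative parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LongitudinalDesign:
    """Sampling design: how many subjects, sessions per subject, first-visit
    age range (years) and follow-up duration (years)."""

    n_subjects: int = 1
    sessions_per_subject: int | tuple[int, int] = 70
    age_at_first: tuple[float, float] = (30.0, 31.0)
    follow_up_years: float = 16.0
    modality_tag: str = "volume-like"

    def __post_init__(self):
        lo, hi = self.session_range
        if lo < 2:
            raise ValueError(
                "fewer than 2 sessions per subject: no within-subject "
                "correlation is possible")
        if hi < lo:
            raise ValueError("sessions_per_subject range is inverted")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        a0, a1 = self.age_at_first
        if not (a1 >= a0):
            raise ValueError("age_at_first range is inverted")
        if self.follow_up_years <= 0:
            raise ValueError("follow_up_years must be positive")

    @property
    def session_range(self) -> tuple[int, int]:
        s = self.sessions_per_subject
        return (s, s) if isinstance(s, int) else (int(s[0]), int(s[1]))


@dataclass(frozen=True)
class GenerativeParams:
    """Variance-source parameters of the generative model.

    ``age_coeffs_mean`` is an (n_roi, 4) array of shared cubic coefficients
    on the raw-age basis (measure units per year^k); None means no common
    trend. Each of ``age_cov``/``trait_cov``/``state_cov`` is a
    :class:`CovSpec` (None disables that source); its ``variance_scale``
    sets the component's variance in measure units squared. ``noise_sd`` is
    independent measurement noise, and ``seed`` the root of all randomness.
    """

    age_coeffs_mean: np.ndarray | None = None
    age_cov: CovSpec | None = None
    trait_cov: CovSpec | None = None
    state_cov: CovSpec | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def preset_params(modality: str, atlas: AtlasSpec | None = None,
                  seed: int = 0) -> GenerativeParams:
    """Default generative parameters per modality.

    ``volume-like``: strong, network-coupled age trajectories with weak state
    fluctuation (slow structural change dominates). ``reho-like`` and
    ``pet-like``: strong state covariance with weak age coupling (sustained-
    activity fluctuation dominates); the PET preset adds a larger trait
    share. These are declared defaults expressing the qualitative contrast
    the generator emulates, not estimates of real variance shares.
    """
    if modality == "volume-like":
        return GenerativeParams(
            age_cov=CovSpec(0.6, 0.7, 0.15, variance_scale=1.0),
            trait_cov=CovSpec(0.5, 0.6, 0.1, variance_scale=0.08),
            state_cov=CovSpec(0.5, 0.6, 0.05, variance_scale=0.08),
            noise_sd=0.05, seed=seed)
    if modality == "reho-like":
        return GenerativeParams(
            age_cov=CovSpec(0.5, 0.6, 0.1, variance_scale=0.08),
            trait_cov=CovSpec(0.4, 0.5, 0.05, variance_scale=0.08),
            state_cov=CovSpec(0.5, 0.6, 0.05, variance_scale=1.0),
            noise_sd=0.1, seed=seed)
    if modality == "pet-like":
        return GenerativeParams(
            age_cov=CovSpec(0.5, 0.6, 0.1, variance_scale=0.1),
            trait_cov=CovSpec(0.5, 0.6, 0.05, variance_scale=0.5),
            state_cov=CovSpec(0.5, 0.6, 0.05, variance_scale=0.6),
            noise_sd=0.1, seed=seed)
    raise ValueError(f"unknown modality preset {modality!r}")


def preset_design(experiment: str, modality: str = "volume-like") -> LongitudinalDesign:
    """Study-structure presets: a single subject with 70 sessions over 16
    years from age ~30 (``simon-like``), or 70 subjects with 5–9 sessions
    each, first-session ages 62–86, ~8-year follow-up (``adni-like``)."""
    if experiment == "simon-like":
        return LongitudinalDesign(1, 70, (30.0, 31.0), 16.0, modality)
    if experiment == "adni-like":
        return LongitudinalDesign(70, (5, 9), (62.0, 86.0), 8.0, modality)
    raise ValueError(f"unknown experiment preset {experiment!r}")


# ---------------------------------------------------------------------------
# Measure simulation
# ---------------------------------------------------------------------------

def _age_coeff_sds(spec: CovSpec, p: int) -> list[np.ndarray]:
    """Per-power standard deviations of the cubic-coefficient perturbations,
    chosen so the age component's expected across-session variance (for
    scaled age u ~ U(-1,1)) equals variance_scale."""
    v = np.broadcast_to(np.asarray(spec.variance_scale, dtype=float), (p,))
    return [np.sqrt(v * w / uv)
            for w, uv in zip(_AGE_POWER_WEIGHTS, _U_POWER_VAR)]


def simulate_measures(design: LongitudinalDesign, params: GenerativeParams,
                      atlas: AtlasSpec | None = None,
                      return_components: bool = False):
    """Simulate a longitudinal regional-measure table.

    Per subject, sessions are placed from a uniform first-visit age with
    inter-session gaps of follow_up/(n_sessions − 1) jittered by ±20%. The
    value of ROI i at a session is the shared cubic trend plus the subject's
    coupled cubic perturbation (age source), a stable trait offset, a
    per-session state draw and i.i.d. noise.

    Randomness is hierarchical: one root seed spawns an independent stream
    per subject, so enlarging the cohort never perturbs existing subjects.
    Identical (design, params, atlas) inputs reproduce the table bit for bit.

    With ``return_components=True`` also returns a dict of the realized
    latent component tables (``age``, ``trait``, ``state``) for parameter-
    recovery analyses.
    """
    atlas = atlas or default_atlas()
    p = atlas.n_roi

    if params.age_coeffs_mean is not None:
        beta = np.asarray(params.age_coeffs_mean, dtype=float)
        if beta.shape != (p, 4):
            raise ValueError(
                f"age_coeffs_mean must be ({p}, 4), got {beta.shape}")
    else:
        beta = np.zeros((p, 4))

    def factor(spec):
        if spec is None:
            return None
        corr = _source_correlation(spec, atlas)
        return _cov_factor(corr, 1.0), spec   # unit-variance factor + spec

    Fa = factor(params.age_cov)
    Ft = factor(params.trait_cov)
    Fs = factor(params.state_cov)

    a_lo, a_hi = design.age_at_first
    age_top = a_hi + design.follow_up_years
    mid = (a_lo + age_top) / 2.0
    half = max((age_top - a_lo) / 2.0, 1e-9)

    root = np.random.SeedSequence(params.seed)
    children = root.spawn(design.n_subjects)
    lo, hi = design.session_range

    rows, ages_all, subj_ids, sess_ids = [], [], [], []
    comp_age, comp_trait, comp_state = [], [], []
    for si, child in enumerate(children):
        rng = np.random.default_rng(child)
        n_sess = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        first = rng.uniform(a_lo, a_hi)
        mean_gap = design.follow_up_years / (n_sess - 1)
        gaps = rng.uniform(0.8, 1.2, n_sess - 1) * mean_gap
        ages = first + np.concatenate([[0.0], np.cumsum(gaps)])

        if Fa is not None:
            sds = _age_coeff_sds(Fa[1], p)
            deltas = [sd * (Fa[0] @ rng.standard_normal(p)) for sd in sds]
        else:
            deltas = None
        if Ft is not None:
            sd_t = np.sqrt(np.broadcast_to(
                np.asarray(Ft[1].variance_scale, dtype=float), (p,)))
            trait = sd_t * (Ft[0] @ rng.standard_normal(p))
        else:
            trait = np.zeros(p)

        for ti, a in enumerate(ages):
            trend = beta[:, 0] + beta[:, 1] * a + beta[:, 2] * a ** 2 + beta[:, 3] * a ** 3
            u = (a - mid) / half
            agec = trend.copy()
            if deltas is not None:
                for k, d in enumerate(deltas, start=1):
                    agec += d * u ** k
            if Fs is not None:
                sd_s = np.sqrt(np.broadcast_to(
                    np.asarray(Fs[1].variance_scale, dtype=float), (p,)))
                state = sd_s * (Fs[0] @ rng.standard_normal(p))
            else:
                state = np.zeros(p)
            eps = params.noise_sd * rng.standard_normal(p) if params.noise_sd else 0.0
            rows.append(agec + trait + state + eps)
            comp_age.append(agec)
            comp_trait.append(trait)
            comp_state.append(state)
            subj_ids.append(f"sub-{si + 1:03d}")
            sess_ids.append(f"ses-{ti + 1:03d}")
            ages_all.append(a)

    def table(vals):
        return RegionalMeasureTable.from_arrays(
            subj_ids, sess_ids, ages_all, design.modality_tag,
            np.asarray(vals), list(atlas.roi_names))

    out = table(rows)
    if return_components:
        return out, {"age": table(comp_age), "trait": table(comp_trait),
                     "state": table(comp_state)}
    return out


# ---------------------------------------------------------------------------
# Time-series and voxel-level fixtures
# ---------------------------------------------------------------------------

def simulate_roi_timeseries(cov: np.ndarray, n_timepoints: int,
                            seed) -> np.ndarray:
    """ROI x timepoint draw from a zero-mean multivariate normal with the
    given (PSD) covariance; the sample correlation converges to ``cov``."""
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints for a correlation")
    cov = np.asarray(cov, dtype=float)
    w, V = np.linalg.eigh((cov + cov.T) / 2.0)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError(f"covariance is not PSD (min eigenvalue {w.min():.6g})")
    F = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    return F @ rng.standard_normal((cov.shape[0], n_timepoints))


def make_label_volume(shape: tuple[int, int, int] = (12, 12, 12),
                      n_roi: int = 4,
                      roi_names: list[str] | None = None) -> LabelVolume:
    """Small slab-partitioned label volume (labels 1..n_roi along the last
    axis) for voxel-level fixtures."""
    nx, ny, nz = shape
    if n_roi > nz:
        raise ValueError(f"cannot fit {n_roi} slabs into {nz} planes")
    data = np.zeros(shape, dtype=np.int16)
    edges = np.linspace(0, nz, n_roi + 1).astype(int)
    for lab in range(1, n_roi + 1):
        data[:, :, edges[lab - 1]:edges[lab]] = lab
    names = roi_names or [f"ROI_{i}" for i in range(1, n_roi + 1)]
    return LabelVolume(data, np.eye(4), {i + 1: names[i] for i in range(n_roi)})


def simulate_voxel_session(atlas_volume: LabelVolume, roi_cov: np.ndarray,
                           n_timepoints: int, local_smoothness: float,
                           seed, latent_amplitude: float = 1.0,
                           noise_sd: float = 1.0) -> np.ndarray:
    """4-D voxel time series: each voxel carries its ROI's latent series plus
    spatially correlated local noise.

    The noise field is white Gaussian noise smoothed per timepoint with a
    Gaussian kernel of width ``local_smoothness`` voxels (0 = independent)
    and rescaled to unit variance, so higher smoothness yields higher
    within-neighborhood concordance without changing marginal noise power.
    """
    roi_cov = np.asarray(roi_cov, dtype=float)
    labels = atlas_volume.data
    labs = sorted(atlas_volume.labels)
    if roi_cov.shape[0] != len(labs):
        raise ValueError(
            f"roi_cov has {roi_cov.shape[0]} ROIs, atlas has {len(labs)}")
    root = np.random.SeedSequence(seed)
    s_lat, s_noise = root.spawn(2)
    latent = simulate_roi_timeseries(roi_cov, n_timepoints, s_lat)

    rng = np.random.default_rng(s_noise)
    noise = rng.standard_normal(labels.shape + (n_timepoints,))
    if local_smoothness > 0:
        for t in range(n_timepoints):
            noise[..., t] = gaussian_filter(noise[..., t],
                                            sigma=local_smoothness)
        sd = noise.std()
        if sd > 0:
            noise /= sd
    ts = noise_sd * noise
    for i, lab in enumerate(labs):
        ts[labels == lab] += latent_amplitude * latent[i]
    return ts
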