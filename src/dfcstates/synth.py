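"""Synthetic two-modality data with planted connectivity ground truth.

Real simultaneous EEG-fMRI recordings are not distributable, so every
downstream stage is exercised on synthetic data that emulates their
structure: a latent multivariate parcel series whose instantaneous
covariance switches among a small set of planted "connectivity states"
(community-structured correlation matrices) is observed twice — once
HRF-convolved and decimated to the scanner's TR (the hemodynamic modality)
and once block-averaged to 1 Hz (the electrophysiological source-strength
modality). The module also fabricates blobby 3-D spatial maps (network
templates and noisy "independent components", optionally with one
hemisphere suppressed to mimic lateralized electrophysiological networks),
block task designs, and voxel-level task data for the GLM stage.

Every generator is bit-reproducible given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dfc import (
    ELECTROPHYSIOLOGICAL,
    HEMODYNAMIC,
    ParcelTimeSeries,
)
from .glm import HRFParams, TaskDesign, boxcar_regressor, convolve_regressor, hrf_kernel
from .matching import MapSet

__all__ = [
    "GroundTruth",
    "PlantedFactorProblem",
    "community_matrix",
    "gen_state_set",
    "dwell_weight_course",
    "gen_latent_series",
    "gen_fmri_modality",
    "gen_eeg_modality",
    "gen_map_set",
    "gen_ic_maps",
    "gen_task_design",
    "gen_voxel_data",
    "gen_sparse_factor_problem",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def community_matrix(R: int, communities: list[list[int]], r_within: float = 0.8) -> np.ndarray:
    """Correlation-like matrix with unit diagonal and elevated within-community blocks."""
    S = np.eye(R)
    for comm in communities:
        idx = np.asarray(comm)
        for i in idx:
            for j in idx:
                if i != j:
                    S[i, j] = r_within
    return S


def _shrink(S: np.ndarray, factor: float) -> np.ndarray:
    R = S.shape[0]
    return factor * S + (1 - factor) * np.eye(R)


def gen_state_set(
    R: int,
    k_true: int,
    block_size: int = 4,
    n_communities: int = 2,
    r_within: float = 0.8,
    max_corr: float = 0.3,
    shrink: float = 0.9,
    seed=0,
    max_retries: int = 500,
) -> list[np.ndarray]:
    """Draw ``k_true`` distinct community-structured state matrices.

    Each state elevates the correlation within ``n_communities`` random
    disjoint parcel groups of ``block_size`` parcels. States are shrunk
    toward the identity (``shrink * S + (1 - shrink) * I``) so every convex
    combination is a valid, samplable covariance. Candidate states whose
    vectorized off-diagonal pattern correlates above ``max_corr`` with an
    already accepted state are redrawn.
    """
    if R < 2 or k_true < 1:
        raise ValueError("need R >= 2 and k_true >= 1")
    if n_communities * block_size > R:
        raise ValueError("communities do not fit in R parcels")
    rng = _rng(seed)
    iu = np.triu_indices(R, k=1)
    states: list[np.ndarray] = []
    patterns: list[np.ndarray] = []
    retries = 0
    while len(states) < k_true:
        parcels = rng.permutation(R)[: n_communities * block_size]
        comms = [list(parcels[i * block_size : (i + 1) * block_size]) for i in range(n_communities)]
        S = community_matrix(R, comms, r_within)
        pat = S[iu]
        ok = True
        for prev in patterns:
            denom = np.std(pat) * np.std(prev)
            if denom > 0 and abs(np.corrcoef(pat, prev)[0, 1]) > max_corr:
                ok = False
                break
        if ok:
            states.append(_shrink(S, shrink))
            patterns.append(pat)
        else:
            retries += 1
            if retries > max_retries:
                raise RuntimeError(
                    f"could not draw {k_true} states with pairwise correlation "
                    f"below {max_corr} after {max_retries} retries"
                )
    return states


def dwell_weight_course(
    k: int,
    n_samples: int,
    dwell_samples: int,
    seed=0,
    order: str = "random",
) -> np.ndarray:
    """One-hot (k, n_samples) activation course with fixed-length dwells.

    ``order="random"`` draws the active state per dwell uniformly, never
    repeating the previous dwell's state; ``order="cyclic"`` cycles 0..k-1.
    """
    if dwell_samples < 1:
        raise ValueError("dwell must be at least one sample")
    rng = _rng(seed)
    n_dwells = int(np.ceil(n_samples / dwell_samples))
    seq = np.empty(n_dwells, dtype=int)
    for d in range(n_dwells):
        if order == "cyclic":
            seq[d] = d % k
        else:
            choices = [s for s in range(k) if d == 0 or s != seq[d - 1]] or [0]
            seq[d] = rng.choice(choices)
    W = np.zeros((k, n_samples))
    for d, s in enumerate(seq):
        W[s, d * dwell_samples : (d + 1) * dwell_samples] = 1.0
    return W


@dataclass
class GroundTruth:
    """Planted generative truth shared by the two synthetic modalities."""

    state_matrices: list[np.ndarray]
    weight_course: np.ndarray  # (k_true, n_native_samples), nonnegative
    seed: int
    native_rate_hz: float = 1.0
    tr_s: float = 2.0
    eeg_rate_hz: float = 1.0
    noise_sd: dict = field(
        default_factory=lambda: {HEMODYNAMIC: 0.05, ELECTROPHYSIOLOGICAL: 0.05}
    )

    def __post_init__(self) -> None:
        self.weight_course = np.asarray(self.weight_course, dtype=float)
        if np.any(self.weight_course < 0):
            raise ValueError("weight_course must be nonnegative")
        if self.weight_course.shape[0] != len(self.state_matrices):
            raise ValueError("weight_course rows must match the number of states")

    @property
    def k_true(self) -> int:
        return len(self.state_matrices)

    @property
    def R(self) -> int:
        return self.state_matrices[0].shape[0]

    @classmethod
    def with_dwell_states(
        cls,
        R: int = 20,
        k_true: int = 5,
        duration_s: float = 600.0,
        dwell_s: float = 60.0,
        native_rate_hz: float = 1.0,
        seed: int = 0,
        **state_kwargs,
    ) -> "GroundTruth":
        """Convenience truth: random dwell switching among ``k_true`` states.

        The 60-s default dwell keeps each ~40-s analysis window mostly
        within a single state, so windowed correlation can recover it.
        """
        n = int(round(duration_s * native_rate_hz))
        states = gen_state_set(R, k_true, seed=seed, **state_kwargs)
        course = dwell_weight_course(
            k_true, n, int(round(dwell_s * native_rate_hz)), seed=seed + 1
        )
        return cls(
            state_matrices=states, weight_course=course, seed=seed, native_rate_hz=native_rate_hz
        )


def gen_latent_series(truth: GroundTruth, seed=None) -> ParcelTimeSeries:
    """Sample the latent native-rate series from the planted truth.

    At each sample the series draws independently from a zero-mean
    multivariate normal whose covariance is the weight-course mixture of the
    planted state matrices, with any remaining mass on the identity:
    ``cov = sum_i w_i S_i + (1 - sum_i w_i) I`` after normalizing the
    weights to sum at most 1. An all-zero weight column therefore yields an
    identity-covariance (unstructured) sample.
    """
    rng = _rng(truth.seed if seed is None else seed)
    W = truth.weight_course
    k, n = W.shape
    R = truth.R
    out = np.empty((n, R))
    # factorize once per run of identical weight columns (dwell segments)
    boundaries = [0] + [t for t in range(1, n) if not np.array_equal(W[:, t], W[:, t - 1])] + [n]
    stack = np.stack(truth.state_matrices)
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        w = W[:, a].copy()
        total = w.sum()
        if total > 1:
            w /= total
            total = 1.0
        cov = np.tensordot(w, stack, axes=1) + (1.0 - total) * np.eye(R)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            warnings.warn("non-PSD instantaneous covariance; shrinking toward identity")
            L = np.linalg.cholesky(_shrink(cov, 0.95))
        out[a:b] = rng.standard_normal((b - a, R)) @ L.T
    return ParcelTimeSeries(
        values=out, sample_interval=1.0 / truth.native_rate_hz, modality="latent"
    )


def _block_decimate(values: np.ndarray, factor: int) -> np.ndarray:
    n_blocks = values.shape[0] // factor
    return values[: n_blocks * factor].reshape(n_blocks, factor, -1).mean(axis=1)


def gen_fmri_modality(
    latent: ParcelTimeSeries,
    TR_s: float = 2.0,
    noise_sd: float = 0.05,
    seed=0,
    hrf_params: HRFParams = HRFParams(),
) -> ParcelTimeSeries:
    """Hemodynamic observation: HRF-convolve, decimate to TR, add noise.

    Convolution happens at the latent native rate; decimation is a
    non-overlapping block mean (one block per TR), which avoids aliasing
    without committing to any particular anti-aliasing filter.
    """
    factor = TR_s * latent.rate_hz
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError("TR must be an integer multiple of the latent sample interval")
    kernel = hrf_kernel(hrf_params, dt=latent.sample_interval)
    conv = np.apply_along_axis(lambda s: convolve_regressor(s, kernel), 0, latent.values)
    decimated = _block_decimate(conv, int(round(factor)))
    rng = _rng(seed)
    noisy = decimated + noise_sd * rng.standard_normal(decimated.shape)
    return ParcelTimeSeries(
        values=noisy,
        sample_interval=TR_s,
        modality=HEMODYNAMIC,
        participant_id=latent.participant_id,
    )


def gen_eeg_modality(
    latent: ParcelTimeSeries,
    rate_hz: float = 1.0,
    noise_sd: float = 0.05,
    seed=0,
) -> ParcelTimeSeries:
    """Electrophysiological observation: block-mean decimate to ``rate_hz``, add noise."""
    factor = latent.rate_hz / rate_hz
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError("target rate must divide the latent rate")
    decimated = _block_decimate(latent.values, int(round(factor)))
    rng = _rng(seed)
    noisy = decimated + noise_sd * rng.standard_normal(decimated.shape)
    return ParcelTimeSeries(
        values=noisy,
        sample_interval=1.0 / rate_hz,
        modality=ELECTROPHYSIOLOGICAL,
        participant_id=latent.participant_id,
    )


# ---------------------------------------------------------------------------
# spatial maps


def _pseudo_z(volume: np.ndarray) -> np.ndarray:
    """Scale a map so background voxels have unit robust SD (MAD-based)."""
    mad = np.median(np.abs(volume - np.median(volume)))
    sd = 1.4826 * mad
    if sd <= 0:
        sd = volume.std() or 1.0
    return volume / sd


def _blob_map(
    grid_dims: tuple[int, int, int],
    rng: np.random.Generator,
    blob_sigma_vox: float,
    n_blobs: int,
    bilateral: bool,
) -> np.ndarray:
    """Sum of Gaussian blobs; mirrored across the x midline when bilateral."""
    vol = np.zeros(grid_dims)
    nx = grid_dims[0]
    for _ in range(n_blobs):
        # keep blob centres away from edges; one hemisphere when bilateral
        x_hi = nx // 2 if bilateral else nx
        cx = rng.integers(1, max(2, x_hi - 1))
        cy = rng.integers(1, grid_dims[1] - 1)
        cz = rng.integers(1, grid_dims[2] - 1)
        vol[cx, cy, cz] += 1.0
    vol = ndimage.gaussian_filter(vol, blob_sigma_vox)
    if bilateral:
        vol = vol + vol[::-1, :, :]
    return vol


def gen_map_set(
    grid_dims: tuple[int, int, int] = (20, 22, 20),
    n_templates: int = 10,
    blob_sigma_vox: float = 1.5,
    bilateral: bool = True,
    seed=0,
    n_blobs: int = 2,
    peak_z: float = 8.0,
) -> MapSet:
    """Synthetic network template maps: blobby pseudo-Z volumes.

    Templates mimic canonical resting-state network maps; with
    ``bilateral=True`` every blob is mirrored across the first-axis midline.
    Being noise-free by construction, templates are put on a pseudo-Z scale
    directly (peak value ``peak_z``), so thresholding at Z = 3.0 keeps the
    blob cores and yields a non-empty mask.
    """
    rng = _rng(seed)
    maps = []
    for i in range(n_templates):
        vol = _blob_map(grid_dims, rng, blob_sigma_vox, n_blobs, bilateral)
        vol = peak_z * vol / vol.max()
        if not (vol > 3.0).any():
            raise RuntimeError("could not produce a supra-threshold template map")
        maps.append(vol)
    return MapSet(
        maps=maps,
        names=[f"template_{i + 1:02d}" for i in range(n_templates)],
        kind="templates",
    )


def gen_ic_maps(
    templates: MapSet,
    n_ics: int = 40,
    noise_sd: float = 1.0,
    split_fraction: float = 0.0,
    seed=0,
) -> tuple[MapSet, np.ndarray]:
    """Noisy "independent component" maps derived from the templates.

    Each template spawns one IC — the template plus voxel noise of SD
    ``noise_sd`` (in the template's pseudo-Z units), re-scaled so its
    background has unit robust SD; with probability ``split_fraction`` one
    hemisphere of that IC is suppressed, emulating the unilateral network
    variants seen in electrophysiological decompositions. The remaining
    ``n_ics - n_templates`` maps are unrelated blob maps. Returns the
    shuffled MapSet and the IC index of each template's true counterpart.
    """
    n_templates = len(templates.maps)
    if n_ics < n_templates:
        raise ValueError("need at least one IC per template")
    rng = _rng(seed)
    grid = templates.maps[0].shape
    raw: list[np.ndarray] = []
    for tmpl in templates.maps:
        sd = noise_sd if noise_sd > 0 else 0.0
        for attempt in range(20):
            signal = tmpl
            if split_fraction > 0 and rng.random() < split_fraction:
                # unilateral variant: suppress the network (not the noise) in
                # one hemisphere, as an IC with a lateralized network would be
                half = np.ones(grid)
                side = rng.random() < 0.5
                mid = grid[0] // 2
                if side:
                    half[mid:] = 0.0
                else:
                    half[:mid] = 0.0
                signal = tmpl * half
            ic = signal + sd * rng.standard_normal(grid) if sd else signal.copy()
            if sd:
                ic = _pseudo_z(ic)
            if (ic > 3.0).any():
                break
            sd *= 0.7  # lower noise until the template survives thresholding
        else:
            raise RuntimeError("could not produce a supra-threshold IC for a template")
        raw.append(ic)
    for _ in range(n_ics - n_templates):
        bg = _blob_map(grid, rng, 1.5, 2, False)
        bg = templates.maps[0].max() * bg / bg.max() + noise_sd * rng.standard_normal(grid)
        raw.append(_pseudo_z(bg) if noise_sd else bg)
    order = rng.permutation(n_ics)
    maps = [raw[i] for i in order]
    true_idx = np.array([int(np.flatnonzero(order == i)[0]) for i in range(n_templates)])
    ms = MapSet(maps=maps, names=[f"ic_{i + 1:02d}" for i in range(n_ics)], kind="components")
    return ms, true_idx


# ---------------------------------------------------------------------------
# task designs and voxel data

LOCALIZER_CONDITIONS = ["happy", "sad", "mixed", "neutral", "motion"]
EXPRESSION_CONDITIONS = ("happy", "sad", "mixed")


def gen_task_design(style: str = "localizer", n_cycles: int = 8, seed=0) -> TaskDesign:
    """Block task timing.

    ``localizer``: the five facial-expression conditions (happy / sad /
    mixed expressions vs. static neutral face and moving dots) in 8-s
    blocks, cycled ``n_cycles`` times (8 cycles -> 320 s, i.e. 160 volumes
    at TR = 2 s), with the order pseudo-randomized within each cycle (a
    strictly periodic order would alias against analysis windows whose
    length matches the 40-s cycle). ``nf``: alternating 24-s up/down
    regulation blocks.
    """
    conditions: list[tuple[str, float, float]] = []
    if style == "localizer":
        rng = _rng(seed)
        t = 0.0
        for _ in range(n_cycles):
            for label in (LOCALIZER_CONDITIONS[i] for i in rng.permutation(5)):
                conditions.append((label, t, 8.0))
                t += 8.0
    elif style == "nf":
        t = 0.0
        for c in range(n_cycles):
            for label in ("up", "down"):
                conditions.append((label, t, 24.0))
                t += 24.0
    else:
        raise ValueError(f"unknown task style {style!r}")
    return TaskDesign(conditions=conditions, run_length=t)


def expression_contrast_series(design: TaskDesign, sample_interval: float) -> np.ndarray:
    """Indicator of the facial-expression conditions on the sample grid."""
    out = None
    for label in EXPRESSION_CONDITIONS:
        if label in design.labels:
            reg = boxcar_regressor(design, label, sample_interval)
            out = reg if out is None else out + reg
    if out is None:
        raise ValueError("design has no expression conditions")
    return np.clip(out, 0, 1)


def gen_voxel_data(
    design: TaskDesign,
    active_mask: np.ndarray,
    amplitude: float = 1.0,
    noise_sd: float = 1.0,
    TR_s: float = 2.0,
    hrf: bool = True,
    seed=0,
    hrf_params: HRFParams = HRFParams(),
) -> np.ndarray:
    """4-D voxel data with task activation planted inside ``active_mask``.

    Active voxels carry ``amplitude`` times the expression-condition
    regressor (HRF-convolved when ``hrf``); all voxels get iid Gaussian
    noise of SD ``noise_sd``.
    """
    active_mask = np.asarray(active_mask, dtype=bool)
    reg = expression_contrast_series(design, TR_s)
    if hrf:
        reg = convolve_regressor(reg, hrf_kernel(hrf_params, dt=TR_s))
    n_t = reg.shape[0]
    rng = _rng(seed)
    data = noise_sd * rng.standard_normal((*active_mask.shape, n_t))
    data[active_mask] += amplitude * reg
    return data


# ---------------------------------------------------------------------------
# direct dictionary-learning fixtures


@dataclass
class PlantedFactorProblem:
    """C = D_true @ A_true + noise, for state-recovery experiments."""

    C: np.ndarray
    D_true: np.ndarray
    A_true: np.ndarray
    noise_sd: float
    seed: int


def gen_sparse_factor_problem(
    M: int = 190,
    T: int = 300,
    k: int = 5,
    noise_sd: float = 0.05,
    dwell_cols: int = 10,
    amp_range: tuple[float, float] = (0.8, 1.2),
    seed=0,
) -> PlantedFactorProblem:
    """Planted sparse factorization with dwell-structured one-hot weights.

    Dictionary columns are random unit-norm patterns; the weight matrix
    activates one state per dwell of ``dwell_cols`` consecutive columns with
    a per-dwell amplitude drawn from ``amp_range``.
    """
    rng = _rng(seed)
    D = rng.standard_normal((M, k))
    D /= np.linalg.norm(D, axis=0)
    seq = dwell_weight_course(k, T, dwell_cols, seed=rng.integers(2**31))
    amps = rng.uniform(*amp_range, size=T)
    A = seq * amps
    C = D @ A + noise_sd * rng.standard_normal((M, T))
    return PlantedFactorProblem(C=C, D_true=D, A_true=A, noise_sd=noise_sd, seed=int(np.asarray(seed).item()) if np.isscalar(seed) else 0)
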