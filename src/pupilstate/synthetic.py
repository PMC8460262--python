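"""Synthetic cohorts of simultaneous fMRI + pupillometry trials with planted structure.

Every trial is driven by a small set of latent spatial components whose
band-limited time courses feed both the voxel signals and the pupil trace.
Trials belong to "states" that differ in their component-to-pupil coupling
weights and in the frequency of an ultra-slow pupil oscillation, so the
clustering, decoding and mapping stages all have a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter

__all__ = [
    "BrainGeometry",
    "ComponentAtlas",
    "StateProfile",
    "Trial",
    "GroundTruth",
    "generate_geometry",
    "generate_component_maps",
    "generate_cohort",
    "generate_landmark_track",
    "default_state_profiles",
    "trial_rng",
]

#: FWHM of a Gaussian = _FWHM_TO_SIGMA * sigma
_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: low-pass cutoff (Hz) applied to latent time courses; inside the 0.002-0.15 Hz
#: band used for fMRI preprocessing
LATENT_CUTOFF_HZ = 0.1


@dataclass(frozen=True)
class BrainGeometry:
    """A masked 3-D voxel grid.

    Attributes
    ----------
    shape : tuple of int
        Voxels per axis.
    mask : ndarray of bool, shape ``shape``
        In-brain cells.
    coords : ndarray of int, shape ``(n_voxels, 3)``
        Grid coordinates of in-mask voxels in scan order (x fastest).
    """

    shape: tuple[int, int, int]
    mask: np.ndarray
    coords: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(self.coords.shape[0])

    def embed(self, values: np.ndarray) -> np.ndarray:
        """Scatter a flat per-voxel vector into a 3-D volume (zeros outside)."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_voxels:
            raise ValueError(
                f"expected {self.n_voxels} voxel values, got {values.shape[-1]}"
            )
        vol = np.zeros(values.shape[:-1] + self.shape, dtype=float)
        vol[..., self.mask] = values
        return vol

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Gather in-mask values of a 3-D volume into a flat vector."""
        if volume.shape[-3:] != self.shape:
            raise ValueError(f"volume shape {volume.shape} != geometry {self.shape}")
        return np.asarray(volume)[..., self.mask]


@dataclass(frozen=True)
class ComponentAtlas:
    """Ground-truth spatial components: ``maps[k]`` is one loading per voxel."""

    maps: np.ndarray  # (K, n_voxels)

    @property
    def n_components(self) -> int:
        return int(self.maps.shape[0])


@dataclass(frozen=True)
class StateProfile:
    """One brain state: coupling weights to pupil plus its slow oscillation."""

    state_id: int
    coupling: np.ndarray  # (K,)
    oscillation_freq: float  # Hz

    def __post_init__(self) -> None:
        w = np.asarray(self.coupling, dtype=float)
        object.__setattr__(self, "coupling", w)
        if not np.any(w != 0):
            raise ValueError("state needs at least one nonzero coupling weight")
        if self.oscillation_freq <= 0:
            raise ValueError("oscillation_freq must be positive")


@dataclass
class Trial:
    """One recording session: voxel x time fMRI plus a pupil trace."""

    subject_id: str
    fmri: np.ndarray  # (n_voxels, T)
    pupil: np.ndarray  # (T,)
    tr: float
    geometry: BrainGeometry | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.fmri.shape[1] != self.pupil.shape[0]:
            raise ValueError(
                f"fmri has {self.fmri.shape[1]} frames but pupil has "
                f"{self.pupil.shape[0]} samples"
            )
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(self.pupil)) or not np.all(np.isfinite(self.fmri)):
            raise ValueError("trial contains non-finite values")

    @property
    def n_frames(self) -> int:
        return int(self.pupil.shape[0])


@dataclass
class GroundTruth:
    """Book-keeping record that lets every planted quantity be reconstructed."""

    atlas: ComponentAtlas
    profiles: list[StateProfile]
    state_labels: np.ndarray  # (n_trials,) state_id per trial
    latent_timecourses: list[np.ndarray]  # per trial (K, T), pupil-aligned
    pupil_noise: list[np.ndarray]  # per trial (T,)
    noise_sd_fmri: float
    noise_sd_pupil: float
    pupil_lag_frames: int = 0

    def reconstruct_pupil(self, i: int) -> np.ndarray:
        """Coupling-weighted latent sum plus the stored noise realisation."""
        prof = self.profile_of(i)
        return prof.coupling @ self.latent_timecourses[i] + self.pupil_noise[i]

    def profile_of(self, i: int) -> StateProfile:
        sid = int(self.state_labels[i])
        for p in self.profiles:
            if p.state_id == sid:
                return p
        raise KeyError(f"no profile with state_id {sid}")

    def state_map(self, state_id: int) -> np.ndarray:
        """Coupling-weighted sum of component maps — the planted coupling map."""
        for p in self.profiles:
            if p.state_id == state_id:
                return p.coupling @ self.atlas.maps
        raise KeyError(f"no profile with state_id {state_id}")


def trial_rng(seed: int, index: int) -> np.random.Generator:
    """Counter-based substream: stream ``index`` of master ``seed``.

    Adding trials never perturbs the streams of earlier ones.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_geometry(
    shape: Sequence[int], mask_rule: str = "ellipsoid", seed: int = 0
) -> BrainGeometry:
    """Build a masked voxel grid; ``mask_rule`` is ``'ellipsoid'`` or ``'full'``."""
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 4 for s in shape):
        raise ValueError(f"shape must be a triple with every axis >= 4, got {shape}")
    if mask_rule == "full":
        mask = np.ones(shape, dtype=bool)
    elif mask_rule == "ellipsoid":
        centers = [(s - 1) / 2.0 for s in shape]
        radii = [s / 2.0 for s in shape]
        ax = [np.arange(s) for s in shape]
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        mask = (
            ((xx - centers[0]) / radii[0]) ** 2
            + ((yy - centers[1]) / radii[1]) ** 2
            + ((zz - centers[2]) / radii[2]) ** 2
        ) <= 1.0
    else:
        raise ValueError(f"unknown mask_rule {mask_rule!r}")
    coords = np.argwhere(mask)
    # scan order: x fastest, then y, then z (0-based flat indices)
    order = np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2]))
    coords = coords[order]
    return BrainGeometry(shape=shape, mask=mask, coords=coords)


def _standardize_map(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        raise ValueError("degenerate (constant) component map")
    return (values - values.mean()) / sd


def _blob_field(
    geom: BrainGeometry, center: np.ndarray, radius: float, rng: np.random.Generator
) -> np.ndarray:
    d2 = np.sum((geom.coords - center) ** 2, axis=1)
    blob = np.exp(-d2 / (2.0 * radius**2))
    return blob + 0.35 * rng.standard_normal(geom.n_voxels)


def generate_component_maps(
    geom: BrainGeometry,
    K: int,
    smoothness_fwhm: float = 2.0,
    seed: int = 0,
    overlap_bound: float = 0.3,
    max_retries: int = 50,
) -> ComponentAtlas:
    """K smoothed random blob fields with bounded pairwise spatial correlation.

    Each map is a Gaussian blob at a random in-mask centre plus white noise,
    optionally Gaussian-smoothed (``smoothness_fwhm`` in voxels; 0 = identity),
    standardised to zero spatial mean / unit spatial variance.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if smoothness_fwhm < 0:
        raise ValueError("smoothness_fwhm must be >= 0")
    rng = np.random.default_rng(seed)
    radius = max(1.5, min(geom.shape) / 5.0)
    sigma = smoothness_fwhm / _FWHM_TO_SIGMA

    def one_map() -> np.ndarray:
        center = geom.coords[rng.integers(geom.n_voxels)]
        flat = _blob_field(geom, center, radius, rng)
        if sigma > 0:
            vol = geom.embed(flat)
            sm = gaussian_filter(vol, sigma)
            norm = gaussian_filter(geom.mask.astype(float), sigma)
            with np.errstate(invalid="ignore", divide="ignore"):
                vol = np.where(norm > 1e-12, sm / norm, 0.0)
            flat = geom.extract(vol)
        return _standardize_map(flat)

    maps: list[np.ndarray] = []
    for _ in range(K):
        for attempt in range(max_retries + 1):
            cand = one_map()
            if all(abs(float(np.corrcoef(cand, m)[0, 1])) <= overlap_bound for m in maps):
                maps.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place {K} components with pairwise |r| <= {overlap_bound} "
                f"after {max_retries} retries"
            )
    return ComponentAtlas(maps=np.asarray(maps))


def default_state_profiles(K: int = 6) -> list[StateProfile]:
    """Four states with distinct coupling vectors and slow spectral peaks.

    Oscillation frequencies mirror the ultra-slow (<0.02 Hz) regime; coupling
    vectors are pairwise far apart so planted states are separable.
    """
    if K < 4:
        raise ValueError("default profiles need K >= 4")
    base = np.zeros((4, K))
    base[0, 0] = 1.5
    base[1, 1] = 1.2
    base[2, 2] = 1.0
    base[3, 3] = 1.3
    if K >= 6:
        base[0, 4] = 0.5
        base[1, 4] = -0.6
        base[2, 5] = 0.7
        base[3, 5] = -0.5
    freqs = [0.018, 0.008, 0.006, 0.011]
    return [
        StateProfile(state_id=i, coupling=base[i], oscillation_freq=freqs[i])
        for i in range(4)
    ]


def _lowpass_sos(tr: float) -> np.ndarray:
    fs = 1.0 / tr
    return signal.butter(4, LATENT_CUTOFF_HZ, btype="low", fs=fs, output="sos")


def _latent_timecourses(
    K: int,
    T: int,
    tr: float,
    profile: StateProfile,
    sin_amplitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited smooth noise; pupil-driving rows get the state sinusoid."""
    sos = _lowpass_sos(tr)
    white = rng.standard_normal((K, T))
    s = signal.sosfiltfilt(sos, white, axis=1)
    s = (s - s.mean(axis=1, keepdims=True)) / s.std(axis=1, keepdims=True)
    t = np.arange(T) * tr
    phase = rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * profile.oscillation_freq * t + phase)
    for k in np.flatnonzero(profile.coupling != 0):
        row = s[k] + sin_amplitude * wave
        s[k] = (row - row.mean()) / row.std()
    return s


def generate_cohort(
    geom: BrainGeometry,
    atlas: ComponentAtlas,
    profiles: Sequence[StateProfile],
    n_trials_per_state: Sequence[int],
    T: int = 925,
    tr: float = 1.0,
    noise_sd_fmri: float = 1.0,
    noise_sd_pupil: float = 0.2,
    seed: int = 0,
    sin_amplitude: float = 1.0,
    pupil_lag_frames: int = 0,
    fmri_dtype: type = np.float32,
) -> tuple[list[Trial], GroundTruth]:
    """Generate a cohort of trials with planted state structure.

    Per trial: ``fmri(v, t) = sum_k C_k(v) s_k(t) + eps(v, t)`` and
    ``pupil(t) = sum_k w_k s_k(t) + eta(t)``.  With ``pupil_lag_frames = L > 0``
    the fMRI leads the pupil by L frames (the pupil-aligned latents are the
    ones stored in the ground truth, so the bookkeeping invariant holds
    bit-exactly regardless of L).
    """
    if T < 64:
        raise ValueError("T must be >= 64")
    if noise_sd_fmri < 0 or noise_sd_pupil < 0:
        raise ValueError("noise standard deviations must be >= 0")
    nyquist = 0.5 / tr
    for p in profiles:
        if p.oscillation_freq >= nyquist:
            raise ValueError(
                f"state {p.state_id} oscillation_freq {p.oscillation_freq} Hz "
                f">= Nyquist {nyquist} Hz"
            )
        if p.coupling.shape[0] != atlas.n_components:
            raise ValueError("coupling length must equal atlas component count")
    if len(n_trials_per_state) != len(profiles):
        raise ValueError("need one trial count per state profile")
    lag = int(pupil_lag_frames)
    if abs(lag) >= T // 4:
        raise ValueError("pupil_lag_frames too large for trial length")

    trials: list[Trial] = []
    labels: list[int] = []
    latents: list[np.ndarray] = []
    etas: list[np.ndarray] = []
    idx = 0
    K = atlas.n_components
    for profile, n_state in zip(profiles, n_trials_per_state):
        for _ in range(int(n_state)):
            rng = trial_rng(seed, idx)
            s_ext = _latent_timecourses(
                K, T + abs(lag), tr, profile, sin_amplitude, rng
            )
            if lag >= 0:
                s_pupil = s_ext[:, :T]
                s_fmri = s_ext[:, lag : lag + T]
            else:
                s_pupil = s_ext[:, -lag:]
                s_fmri = s_ext[:, :T]
            eta = noise_sd_pupil * rng.standard_normal(T)
            pupil = profile.coupling @ s_pupil + eta
            fmri = atlas.maps.T @ s_fmri
            if noise_sd_fmri > 0:
                fmri = fmri + noise_sd_fmri * rng.standard_normal(fmri.shape)
            trials.append(
                Trial(
                    subject_id=f"sub-{idx:03d}",
                    fmri=np.asarray(fmri, dtype=fmri_dtype),
                    pupil=pupil,
                    tr=tr,
                    geometry=geom,
                    meta={"state_id": profile.state_id, "trial_index": idx},
                )
            )
            labels.append(profile.state_id)
            latents.append(s_pupil)
            etas.append(eta)
            idx += 1
    truth = GroundTruth(
        atlas=atlas,
        profiles=list(profiles),
        state_labels=np.asarray(labels),
        latent_timecourses=latents,
        pupil_noise=etas,
        noise_sd_fmri=float(noise_sd_fmri),
        noise_sd_pupil=float(noise_sd_pupil),
        pupil_lag_frames=lag,
    )
    return trials, truth


def generate_landmark_track(
    trial: Trial, eye_size: float = 100.0, fps: float = 29.97, seed: int = 0
):
    """Emit per-frame 4-point pupil-edge landmarks that invert to the trial's pupil.

    The two chords both equal ``pupil * eye_size`` pixels in every frame; a
    random rigid motion (rotation + translation) is applied per frame, which
    the diameter formula is invariant to.  Each TR value is held for
    ``round(fps * tr)`` video frames so that TR binning recovers the trace
    exactly.
    """
    from pupilstate.pupil import LandmarkSeries

    if eye_size <= 0:
        raise ValueError("eye_size must be positive")
    if fps < 1.0 / trial.tr:
        raise ValueError("fps must be at least one frame per TR")
    p = trial.pupil
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("trial pupil must lie in (0, 1] to invert the normalization")
    rng = trial_rng(seed, 0)
    n_per = int(round(fps * trial.tr))
    d_px = np.repeat(p * eye_size, n_per)
    n = d_px.shape[0]
    half = d_px / 2.0
    # chord 1 along local x, chord 2 along local y, both centred at the origin
    pts = np.zeros((n, 4, 2))
    pts[:, 0, 0] = -half
    pts[:, 1, 0] = half
    pts[:, 2, 1] = -half
    pts[:, 3, 1] = half
    theta = rng.uniform(0, 2 * np.pi, size=n)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.empty((n, 2, 2))
    rot[:, 0, 0] = c
    rot[:, 0, 1] = -s
    rot[:, 1, 0] = s
    rot[:, 1, 1] = c
    pts = np.einsum("nij,nkj->nki", rot, pts)
    pts += rng.uniform(50, 150, size=(n, 1, 2))
    return LandmarkSeries(points=pts, fps=fps, eye_size=float(eye_size))
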