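"""Binaural speech-intelligibility model: better-ear listening + binaural unmasking.

Predicts the spatial-unmasking advantage of a head orientation from binaural
room impulse responses of the target and the interferer.  Per gammatone band,
the model combines

* the better-ear target-to-interferer ratio (head-shadow component), and
* the binaural masking level difference (BMLD) given by the
  equalization–cancellation limit, driven by the target/interferer interaural
  phases and the interferer's interaural coherence,

and sums the band advantages with SII band-importance weights.  Sweeping head
yaw over the full circle yields a head-orientation benefit map, referenced to
yaw 0 (facing the interferer); the acoustically optimal region is the set of
yaws within a margin (default 1 dB) of the map's peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .room import (
    SPEED_OF_SOUND,
    HeadModel,
    ImageSet,
    ImpulseResponsePair,
    RoomScene,
    _accumulate_impulses,
    enumerate_images,
    eyring_t30,
    scattered_tail_sigma,
)  # noqa: F401

__all__ = [
    "ModelConstants",
    "BandDecomposition",
    "BenefitMap",
    "OptimalRegion",
    "band_parameters",
    "bmld",
    "effective_tir",
    "benefit_map",
    "optimal_region",
    "trajectory_benefit",
]

# ANSI S3.5-1997 one-third-octave band importance function for average speech.
_SII_FREQS = np.array(
    [160, 200, 250, 315, 400, 500, 630, 800, 1000, 1250,
     1600, 2000, 2500, 3150, 4000, 5000, 6300, 8000], dtype=float
)
_SII_WEIGHTS = np.array(
    [0.0083, 0.0095, 0.0150, 0.0289, 0.0440, 0.0578, 0.0653, 0.0711, 0.0818,
     0.0844, 0.0882, 0.0898, 0.0868, 0.0844, 0.0771, 0.0527, 0.0364, 0.0185]
)


def _erb_space(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    """Center frequencies equally spaced on the ERB-rate scale."""
    erb = lambda f: 21.4 * np.log10(1.0 + 0.00437 * f)
    inv = lambda e: (10.0 ** (e / 21.4) - 1.0) / 0.00437
    return inv(np.linspace(erb(f_lo), erb(f_hi), n))


def sii_weights(band_centers: np.ndarray) -> np.ndarray:
    """SII band-importance weights interpolated (log-frequency) and renormalized."""
    w = np.interp(np.log(band_centers), np.log(_SII_FREQS), _SII_WEIGHTS)
    return w / w.sum()


@dataclass
class ModelConstants:
    """Internal-noise constants and band weighting of the binaural model.

    ``sigma_eps`` is the monaural amplitude-jitter factor and ``sigma_delta``
    the internal interaural time jitter (s); both enter the EC-limit factor
    k = (1 + sigma_eps^2) exp((2 pi f)^2 sigma_delta^2) that caps the BMLD.
    """

    sigma_eps: float = 0.25
    sigma_delta: float = 105e-6
    band_centers: np.ndarray = field(default_factory=lambda: _erb_space(100.0, 8000.0, 16))
    band_weights: np.ndarray | None = None
    max_lag_s: float = 1e-3

    def __post_init__(self) -> None:
        self.band_centers = np.asarray(self.band_centers, float)
        if np.any(np.diff(self.band_centers) <= 0):
            raise ValueError("band centers must be strictly increasing")
        if self.band_weights is None:
            self.band_weights = sii_weights(self.band_centers)
        self.band_weights = np.asarray(self.band_weights, float)
        if np.any(self.band_weights < 0):
            raise ValueError("band weights must be non-negative")
        if abs(self.band_weights.sum() - 1.0) > 1e-9:
            raise ValueError("band weights must sum to 1")

    @classmethod
    def uniform(cls, n_bands: int = 16) -> "ModelConstants":
        centers = _erb_space(100.0, 8000.0, n_bands)
        return cls(band_centers=centers, band_weights=np.full(n_bands, 1.0 / n_bands))


@dataclass
class BandDecomposition:
    """Per-band binaural inputs of the model (arrays over gammatone bands)."""

    band_centers: np.ndarray
    target_energy: np.ndarray  # (2, n_bands) left/right
    interferer_energy: np.ndarray  # (2, n_bands)
    phase_target: np.ndarray  # rad
    phase_interferer: np.ndarray  # rad
    coherence_interferer: np.ndarray  # [0, 1]
    valid: np.ndarray  # bands with usable energies


def _gammatone_sos(fc: float, fs: float) -> np.ndarray:
    """4th-order all-pole gammatone as a cascade of four identical biquads.

    Pole radius follows the ERB bandwidth (1.019 ERB); the cascade is
    normalized to unit magnitude at the center frequency.  A biquad cascade is
    numerically stable at low fc/fs where the expanded 8th-order transfer
    function is not.
    """
    erb = 24.7 * (4.37 * fc / 1000.0 + 1.0)
    r = np.exp(-2.0 * np.pi * 1.019 * erb / fs)
    theta = 2.0 * np.pi * fc / fs
    section = [1.0, 0.0, 0.0, 1.0, -2.0 * r * np.cos(theta), r * r]
    sos = np.array([section] * 4)
    _, h = signal.sosfreqz(sos, worN=[theta])
    sos[0, :3] /= np.abs(h[0])
    return sos


def _gammatone_bank(band_centers: np.ndarray, fs: float) -> list[np.ndarray]:
    return [_gammatone_sos(fc, fs) for fc in band_centers]


def _best_lag_and_coherence(
    x: np.ndarray, y: np.ndarray, fs: float, max_lag_s: float
) -> tuple[float, float]:
    """Lag (s, y relative to x) of the maximum of the normalized cross-correlation
    within +/- max_lag, with parabolic sub-sample refinement, and its value."""
    denom = np.sqrt(np.dot(x, x) * np.dot(y, y))
    if denom == 0.0:
        return 0.0, 0.0
    full = signal.fftconvolve(x, y[::-1])
    mid = y.size - 1
    m = int(round(max_lag_s * fs))
    lo, hi = mid - m, mid + m + 1
    seg = full[lo:hi] / denom
    i = int(np.argmax(seg))
    lag = i - m
    # parabolic peak interpolation on the interior
    if 0 < i < seg.size - 1:
        a, b, c = seg[i - 1], seg[i], seg[i + 1]
        denom2 = a - 2 * b + c
        if denom2 < 0:
            frac = 0.5 * (a - c) / denom2
            lag += float(np.clip(frac, -0.5, 0.5))
    # y delayed re x by lag samples when peak right of center
    return -lag / fs, float(np.clip(seg[i], -1.0, 1.0))


def band_parameters(
    brir_target: ImpulseResponsePair,
    brir_interferer: ImpulseResponsePair,
    constants: ModelConstants | None = None,
) -> BandDecomposition:
    """Gammatone-band energies, interaural phases and interferer coherence.

    Interaural phase is 2 pi f_c times the best-correlation lag between the
    ear signals; coherence is the cross-correlation maximum within +/- 1 ms.
    Bands with zero energy on either source are flagged invalid (and a warning
    issued for interferer-silent bands).
    """
    constants = constants or ModelConstants()
    if brir_target.sample_rate != brir_interferer.sample_rate:
        raise ValueError("target and interferer BRIRs must share a sample rate")
    fs = brir_target.sample_rate
    bank = _gammatone_bank(constants.band_centers, fs)
    signals_t, signals_i = [], []
    for sos in bank:
        signals_t.append(np.stack([
            signal.sosfilt(sos, brir_target.left),
            signal.sosfilt(sos, brir_target.right),
        ]))
        signals_i.append(np.stack([
            signal.sosfilt(sos, brir_interferer.left),
            signal.sosfilt(sos, brir_interferer.right),
        ]))
    return _decompose(signals_t, signals_i, fs, constants)


def _interp_alpha(band_absorption: dict[float, float], fc: float) -> float:
    freqs = np.array(sorted(band_absorption), dtype=float)
    alphas = np.array([band_absorption[f] for f in freqs])
    return float(np.interp(np.log(fc), np.log(freqs), alphas))


def _diffuse_coherence(fc: float, ear_distance_m: float = 0.17) -> float:
    """Interaural coherence of an ideal diffuse field: sinc(k d), clipped at 0."""
    x = 2.0 * np.pi * fc * ear_distance_m / SPEED_OF_SOUND
    return float(max(np.sin(x) / x if x > 0 else 1.0, 0.0))


class _SceneBandRenderer:
    """Per-gammatone-band ear signals of one source, evaluated at head yaws.

    Head-shadow gain, interaural delay and (log-interpolated) wall absorption
    are evaluated at each gammatone center frequency, so the band analysis is
    free of octave-crossover artifacts.  The diffuse tail (surface scattering)
    is yaw-independent: it is synthesized and gammatone-filtered once, with
    interaural coherence following the diffuse-field sinc law.
    """

    def __init__(
        self,
        images: ImageSet,
        head: HeadModel,
        listener_position,
        sample_rate: float,
        constants: ModelConstants,
        tail_seed: int = 0,
    ) -> None:
        self.head = head
        self.fs = sample_rate
        self.constants = constants
        lst = np.asarray(listener_position, float)
        vec = images.positions - lst
        self.dist = np.linalg.norm(vec, axis=1)
        self.unit = vec / self.dist[:, None]
        self.base_delay = self.dist / SPEED_OF_SOUND
        self.k = images.reflection_counts
        self.n = int(np.ceil((self.base_delay.max() + 0.01) * sample_rate))
        self.bank = _gammatone_bank(constants.band_centers, sample_rate)

        s = images.scattering
        spec_keep = np.sqrt(1.0 - s) ** self.k if s > 0 else np.ones_like(self.dist)
        self.band_amp0 = []  # wall+scattering specular amplitude per band
        self.tails = []  # gammatone-filtered diffuse tails, (2, n) or None
        rng = np.random.default_rng(np.random.SeedSequence([int(tail_seed) & 0x7FFFFFFF]))
        for sos, fc in zip(self.bank, constants.band_centers):
            alpha = _interp_alpha(images.band_absorption, fc)
            r = np.sqrt(max(1.0 - alpha, 0.0))
            wall = np.power(r, self.k, dtype=float)
            self.band_amp0.append(wall * spec_keep / self.dist)
            tail = None
            if s > 0 and images.room_dims is not None and alpha < 1.0:
                amp2 = (wall / self.dist) ** 2
                total = float(np.sum(amp2 * (1.0 - (1.0 - s) ** self.k)))
                source = np.where(self.k >= 1, amp2 * (1.0 - s) ** self.k, 0.0)
                sigma = scattered_tail_sigma(
                    source, self.base_delay, eyring_t30(images.room_dims, alpha),
                    total, self.n, sample_rate,
                )
                if sigma is not None:
                    ic = _diffuse_coherence(fc)
                    common = rng.standard_normal(self.n)
                    left = np.sqrt(ic) * common + np.sqrt(1.0 - ic) * rng.standard_normal(self.n)
                    right = np.sqrt(ic) * common + np.sqrt(1.0 - ic) * rng.standard_normal(self.n)
                    tail = np.stack([
                        signal.sosfilt(sos, left * sigma),
                        signal.sosfilt(sos, right * sigma),
                    ])
            self.tails.append(tail)

    def band_signals(self, yaw_deg: float) -> list[np.ndarray]:
        """List over bands of (2, n) ear signals at this head yaw."""
        out = []
        ears = [self.head.ear_vector(yaw_deg, side) for side in ("left", "right")]
        cos_t = [self.unit @ e for e in ears]
        delays = [self.base_delay + self.head.ear_delay(ct) for ct in cos_t]
        for bi, (sos, fc) in enumerate(zip(self.bank, self.constants.band_centers)):
            sig = np.empty((2, self.n))
            for ei in range(2):
                amps = self.band_amp0[bi] * self.head.shadow_gain(cos_t[ei], fc)
                train = _accumulate_impulses(delays[ei], amps, self.n, self.fs)
                sig[ei] = signal.sosfilt(sos, train)
            if self.tails[bi] is not None:
                sig = sig + self.tails[bi]
            out.append(sig)
        return out


def _decompose(
    signals_t: list[np.ndarray],
    signals_i: list[np.ndarray],
    fs: float,
    constants: ModelConstants,
) -> BandDecomposition:
    """BandDecomposition from per-band (2, n) ear signals of target/interferer."""
    n_bands = constants.band_centers.size
    te = np.zeros((2, n_bands))
    ie = np.zeros((2, n_bands))
    ph_t = np.zeros(n_bands)
    ph_i = np.zeros(n_bands)
    coh = np.zeros(n_bands)
    valid = np.ones(n_bands, dtype=bool)
    for bi, fc in enumerate(constants.band_centers):
        tl, tr = signals_t[bi]
        il, ir = signals_i[bi]
        te[:, bi] = [np.dot(tl, tl), np.dot(tr, tr)]
        ie[:, bi] = [np.dot(il, il), np.dot(ir, ir)]
        if np.any(ie[:, bi] == 0.0):
            warnings.warn(f"interferer band at {fc:.0f} Hz has zero energy; excluded")
            valid[bi] = False
            continue
        if np.any(te[:, bi] == 0.0):
            valid[bi] = False
            continue
        lag_t, _ = _best_lag_and_coherence(tl, tr, fs, constants.max_lag_s)
        lag_i, c = _best_lag_and_coherence(il, ir, fs, constants.max_lag_s)
        ph_t[bi] = 2.0 * np.pi * fc * lag_t
        ph_i[bi] = 2.0 * np.pi * fc * lag_i
        coh[bi] = max(c, 0.0)
    return BandDecomposition(constants.band_centers, te, ie, ph_t, ph_i, coh, valid)


def bmld(
    phase_target: float,
    phase_interferer: float,
    coherence_interferer: float,
    f_c: float,
    constants: ModelConstants | None = None,
) -> float:
    """Binaural masking level difference (dB) in the equalization–cancellation limit.

    max(0, 10 log10[(k - cos(dphi)) / (k - rho)]) with
    k = (1 + sigma_eps^2) exp((2 pi f_c sigma_delta)^2); k > 1, so the
    expression is defined for any coherence rho <= 1.
    """
    constants = constants or ModelConstants()
    if not (0.0 <= coherence_interferer <= 1.0):
        raise ValueError("coherence must be in [0, 1]")
    k = (1.0 + constants.sigma_eps**2) * float(
        np.exp((2.0 * np.pi * f_c * constants.sigma_delta) ** 2)
    )
    if k <= coherence_interferer:
        raise ValueError("internal-noise factor k must exceed coherence (k > 1)")
    num = k - np.cos(phase_target - phase_interferer)
    return max(0.0, 10.0 * float(np.log10(num / (k - coherence_interferer))))


def effective_tir(bd: BandDecomposition, constants: ModelConstants | None = None) -> float:
    """SII-weighted effective target-to-interferer ratio (dB).

    Per band: better-ear ratio (max over ears of the band TIR in dB) plus the
    BMLD; the weighted sum renormalizes the SII weights over valid bands.
    """
    constants = constants or ModelConstants()
    if not np.any(bd.valid):
        raise ValueError("all bands degenerate; cannot compute effective TIR")
    v = bd.valid
    with np.errstate(divide="ignore"):
        ratios = 10.0 * np.log10(bd.target_energy[:, v] / bd.interferer_energy[:, v])
    better_ear = ratios.max(axis=0)
    bmlds = np.array(
        [
            bmld(pt, pi, c, fc, constants)
            for pt, pi, c, fc in zip(
                bd.phase_target[v], bd.phase_interferer[v],
                bd.coherence_interferer[v], bd.band_centers[v],
            )
        ]
    )
    w = constants.band_weights[v]
    w = w / w.sum()
    return float(np.sum(w * (better_ear + bmlds)))


@dataclass
class BenefitMap:
    """Head-orientation benefit (dB) on a yaw grid.

    ``benefit_db`` is referenced to yaw 0 (facing the interferer at trial
    start) and is 0 dB there by construction.  ``unmasking_db`` is the same
    curve referenced to the co-located target/interferer configuration — i.e.
    the spatial unmasking itself, since co-located target and interferer share
    a BRIR and give 0 dB effective TIR.
    """

    yaw_deg: np.ndarray
    benefit_db: np.ndarray
    scene_id: str = ""
    unmasking_db: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.yaw_deg.size != self.benefit_db.size:
            raise ValueError("grid and benefit arrays must match")

    def _lookup(self, values: np.ndarray, yaw) -> np.ndarray:
        step = 360.0 / self.yaw_deg.size
        idx = np.rint(np.asarray(yaw, float) / step).astype(int) % self.yaw_deg.size
        return values[idx]

    def benefit_at(self, yaw: float | np.ndarray) -> np.ndarray:
        """Nearest-grid-point lookup, wrapping around the circle."""
        return self._lookup(self.benefit_db, yaw)

    def unmasking_at(self, yaw: float | np.ndarray) -> np.ndarray:
        if self.unmasking_db is None:
            raise ValueError("map carries no unmasking reference")
        return self._lookup(self.unmasking_db, yaw)

    @property
    def peak_db(self) -> float:
        return float(self.benefit_db.max())

    @property
    def peak_unmasking_db(self) -> float:
        if self.unmasking_db is None:
            raise ValueError("map carries no unmasking reference")
        return float(self.unmasking_db.max())

    @property
    def peak_yaw_deg(self) -> float:
        return float(self.yaw_deg[int(np.argmax(self.benefit_db))])


@dataclass
class OptimalRegion:
    """Yaws within ``margin_db`` of the benefit-map peak."""

    yaw_deg: np.ndarray
    margin_db: float = 1.0

    def contains(self, yaw: float | np.ndarray, tol_deg: float = 0.5) -> np.ndarray:
        y = np.mod(np.asarray(yaw, float), 360.0)
        d = np.abs(y[..., None] - self.yaw_deg[None, ...])
        d = np.minimum(d, 360.0 - d)
        return d.min(axis=-1) <= tol_deg


def benefit_map(
    scene: RoomScene,
    target_index: int,
    interferer_index: int,
    head: HeadModel | None = None,
    grid_step_deg: float = 1.0,
    time_limit_s: float = 0.3,
    sample_rate: float = 44100.0,
    constants: ModelConstants | None = None,
    scene_id: str = "",
) -> BenefitMap:
    """Head-orientation benefit map for one target/interferer pair.

    The image sets are enumerated once (they do not depend on head yaw); the
    binaural rendering and band analysis are repeated per yaw.  Benefit is
    effective_tir(yaw) - effective_tir(0), so the reference yaw maps to 0 dB
    exactly.
    """
    if target_index == interferer_index:
        raise ValueError("target and interferer must be distinct sources")
    head = head or HeadModel()
    constants = constants or ModelConstants()
    t_pl = scene.sources[target_index]
    i_pl = scene.sources[interferer_index]
    if (t_pl.azimuth_deg % 360.0, t_pl.distance_m) == (i_pl.azimuth_deg % 360.0, i_pl.distance_m):
        warnings.warn("target and interferer are co-located; benefit map will be flat")

    imgs_t = enumerate_images(scene, target_index, time_limit_s)
    imgs_i = enumerate_images(scene, interferer_index, time_limit_s)
    rend_t = _SceneBandRenderer(
        imgs_t, head, scene.listener_position, sample_rate, constants, tail_seed=target_index
    )
    rend_i = _SceneBandRenderer(
        imgs_i, head, scene.listener_position, sample_rate, constants, tail_seed=interferer_index
    )
    yaws = np.arange(0.0, 360.0, grid_step_deg)
    tir = np.empty(yaws.size)
    for i, yaw in enumerate(yaws):
        bd = _decompose(rend_t.band_signals(yaw), rend_i.band_signals(yaw), sample_rate, constants)
        tir[i] = effective_tir(bd, constants)
    return BenefitMap(yaws, tir - tir[0], scene_id=scene_id, unmasking_db=tir)


def optimal_region(bmap: BenefitMap, margin_db: float = 1.0) -> OptimalRegion:
    """All yaws whose benefit is within ``margin_db`` of the map maximum."""
    keep = bmap.benefit_db >= bmap.benefit_db.max() - margin_db
    return OptimalRegion(yaw_deg=bmap.yaw_deg[keep], margin_db=margin_db)


def trajectory_benefit(
    bmap: BenefitMap, traj, windows, scale: str = "benefit"
) -> np.ndarray:
    """Per-word median head-orientation benefit along a trajectory.

    ``traj`` provides ``timestamps`` and ``yaw_deg``; ``windows`` the five word
    (onset, offset) intervals.  Each word's value is the median over in-window
    samples of the map value at the nearest grid yaw; ``scale`` selects the
    yaw-0-referenced benefit or the co-located-referenced unmasking.
    """
    values = bmap.benefit_db if scale == "benefit" else None
    if scale == "unmasking":
        if bmap.unmasking_db is None:
            raise ValueError("map carries no unmasking reference")
        values = bmap.unmasking_db
    if values is None:
        raise ValueError("scale must be 'benefit' or 'unmasking'")
    t = np.asarray(traj.timestamps, float)
    out = np.empty(len(windows.words))
    for wi, (onset, offset) in enumerate(windows.words):
        sel = (t >= onset) & (t < offset)
        if not np.any(sel):
            raise ValueError(f"word window {wi + 1} [{onset}, {offset}) contains no samples")
        out[wi] = float(np.median(bmap._lookup(values, np.asarray(traj.yaw_deg)[sel])))
    return out
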