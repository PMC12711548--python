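"""Synthetic block-design EEG cohorts with known band-specific phase coupling.

No public recordings exist for the breathing paradigm studied here, so every
downstream stage is validated against cohorts generated by this module with
a fully known ground truth: per (condition, band) pairwise coupling
matrices, band amplitudes, and a lung-capacity covariate (FVC) planted with
a chosen population correlation against one connectivity edge.

Generative model
----------------
For each frequency band ``b`` a single shared oscillator phase evolves as a
random-frequency walk centred on the band:

    Theta_b(t+1) = Theta_b(t) + 2*pi*f_b/fs + jitter * eps_t

Channel ``i`` observes this oscillator through stationary AR(1)
wrapped-Gaussian phase noise ``d_ib(t)`` whose cross-channel correlation is
the coupling matrix ``kappa`` of the active (condition, band):

    phi_ib(t) = Theta_b(t) + d_ib(t),     d_.b ~ AR(1), N(0, sigma^2 * R(kappa))

so a pair with kappa = 1 shares identical noise (perfect locking) and a
pair with kappa = 0 has independent noise.  For wrapped-Gaussian noise the
population phase-locking value of a pair follows the monotone calibration
curve ``PLV ~= exp(-sigma^2 * (1 - kappa))`` (see :func:`plv_calibration`);
the curve observed after band filtering is checked empirically, not assumed.
The recorded signal is ``sum_b a_b * g_cb * cos(phi_ib) + sensor noise``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _signal

from .preprocessing import (
    CONDITIONS,
    DEFAULT_BANDS,
    DEFAULT_CHANNELS,
    Annotation,
    Recording,
)

BAND_NAMES = tuple(b.name for b in DEFAULT_BANDS)

#: Band-centre frequencies (Hz) for the shared oscillators.
DEFAULT_BAND_CENTERS: dict[str, float] = {
    "delta": 2.5,
    "theta": 6.0,
    "alpha": 10.5,
    "beta": 21.5,
}

#: Band amplitudes in microvolts, roughly matching scalp EEG magnitudes.
DEFAULT_AMPLITUDES: dict[str, float] = {
    "delta": 20.0,
    "theta": 12.0,
    "alpha": 15.0,
    "beta": 6.0,
}


@dataclass(frozen=True)
class ParadigmSpec:
    """Block layout of one continuous run.

    ``blocks`` is an ordered list of (condition, duration-s) pairs; the
    default layout interleaves all three conditions in one 330-s run:
    50 s of breathing alternating with 20 s of breath-holds (four holds),
    closing with a final 50-s breathing block.
    """

    blocks: tuple[tuple[str, float], ...]
    sampling_rate: float = 500.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")
        for cond, dur in self.blocks:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition label {cond!r}")
            if dur <= 0:
                raise ValueError("block durations must be positive")

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.blocks)

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sampling_rate))

    def annotations(self) -> list[Annotation]:
        anns, cursor = [], 0
        for cond, dur in self.blocks:
            n = int(round(dur * self.sampling_rate))
            anns.append(Annotation(cond, cursor, cursor + n))
            cursor += n
        return anns


def default_paradigm(
    layout: str = "mixed",
    sampling_rate: float = 500.0,
    channel_names: Sequence[str] = DEFAULT_CHANNELS,
    block_scale: float = 1.0,
) -> ParadigmSpec:
    """Standard 330-s run: breathing blocks alternating with four 20-s holds.

    ``layout`` selects how the 50-s breathing blocks are labelled:
    ``"mixed"`` alternates SB and PB within the run (self-paced first),
    ``"sb"`` labels them all SB, ``"pb"`` starts self-paced then paces the
    rest.  ``block_scale`` shrinks every block proportionally (useful for
    fast tests); the default 1.0 gives the full 330-s run.
    """
    b, h = 50.0 * block_scale, 20.0 * block_scale
    if layout == "mixed":
        breathe = ["SB", "PB", "SB", "PB", "SB"]
    elif layout == "sb":
        breathe = ["SB"] * 5
    elif layout == "pb":
        breathe = ["SB", "PB", "PB", "PB", "PB"]
    else:
        raise ValueError(f"unknown layout {layout!r}")
    blocks: list[tuple[str, float]] = []
    for i, cond in enumerate(breathe):
        blocks.append((cond, b))
        if i < 4:
            blocks.append(("BH", h))
    if layout == "mixed":
        # a mixed run must still contain every condition
        assert {c for c, _ in blocks} == set(CONDITIONS)
    return ParadigmSpec(tuple(blocks), sampling_rate, tuple(channel_names))


@dataclass
class CouplingSpec:
    """Ground-truth coupling for every (condition, band).

    ``coupling[(cond, band)]`` is a symmetric n x n matrix with zero
    diagonal and entries in [0, 1] giving the pairwise shared-phase
    fraction.  ``condition_gain[(cond, band)]`` scales band amplitude per
    condition (drives PSD contrasts).  ``phase_noise_sd`` (radians) sets the
    marginal private-phase noise, hence the baseline PLV exp(-sd^2) at
    kappa = 0; ``phase_noise_ac`` is the per-sample AR(1) coefficient of
    that noise; ``freq_jitter`` (rad/sqrt(sample)) is the oscillator
    frequency-walk scale; ``sensor_noise_sd`` is additive white noise in
    microvolts.
    """

    coupling: dict[tuple[str, str], np.ndarray]
    amplitudes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    band_centers: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_CENTERS))
    condition_gain: dict[tuple[str, str], float] = field(default_factory=dict)
    phase_noise_sd: float = 1.4
    phase_noise_ac: float = 0.995
    freq_jitter: float = 0.08
    sensor_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        for key, k in self.coupling.items():
            k = np.asarray(k, dtype=float)
            if k.ndim != 2 or k.shape[0] != k.shape[1]:
                raise ValueError(f"coupling[{key}] must be square")
            if not np.allclose(k, k.T):
                raise ValueError(f"coupling[{key}] must be symmetric")
            if np.any(k < 0) or np.any(k > 1):
                raise ValueError(f"coupling[{key}] entries must lie in [0, 1]")
            if np.any(np.diag(k) != 0):
                raise ValueError(f"coupling[{key}] must have zero diagonal")
            self.coupling[key] = k
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("amplitudes must be non-negative")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor noise SD must be non-negative")

    def bands(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(band for _, band in self.coupling))

    def gain(self, cond: str, band: str) -> float:
        return self.condition_gain.get((cond, band), 1.0)


def _edge_matrix(n: int, base: float, edges: Mapping[tuple[int, int], float]) -> np.ndarray:
    k = np.full((n, n), base)
    np.fill_diagonal(k, 0.0)
    for (i, j), v in edges.items():
        k[i, j] = k[j, i] = v
    return k


def default_coupling(channel_names: Sequence[str] = DEFAULT_CHANNELS) -> CouplingSpec:
    """Condition effects mirroring the qualitative group differences under study.

    Self-paced breathing carries stronger low-frequency (delta/theta)
    coupling over frontal channels than breath-holding; breath-holding
    carries stronger high-frequency (alpha/beta) coupling broadly than
    paced breathing, with three distinct alpha levels across conditions so
    alpha is the most discriminative band.  Amplitude gains follow the same
    directions for spectral power.
    """
    names = list(channel_names)
    n = len(names)
    frontal = [names.index(c) for c in ("Fp1", "Fp2", "F3", "F4", "F7", "F8") if c in names]
    frontal_edges = {
        (i, j): 1.0 for a, i in enumerate(frontal) for j in frontal[a + 1 :]
    }
    base = 0.2

    def frontal_k(v: float) -> np.ndarray:
        return _edge_matrix(n, base, {e: v for e in frontal_edges})

    def flat_k(v: float) -> np.ndarray:
        return _edge_matrix(n, v, {})

    coupling = {
        ("SB", "delta"): frontal_k(0.65),
        ("BH", "delta"): flat_k(base),
        ("PB", "delta"): flat_k(0.25),
        ("SB", "theta"): frontal_k(0.5),
        ("BH", "theta"): flat_k(base),
        ("PB", "theta"): flat_k(base),
        ("SB", "alpha"): flat_k(0.35),
        ("BH", "alpha"): flat_k(0.55),
        ("PB", "alpha"): flat_k(base),
        ("SB", "beta"): flat_k(0.45),
        ("BH", "beta"): flat_k(0.5),
        ("PB", "beta"): flat_k(0.35),
    }
    condition_gain = {
        ("SB", "delta"): 1.3,
        ("SB", "theta"): 1.3,
        ("BH", "alpha"): 1.3,
        ("BH", "beta"): 1.3,
    }
    return CouplingSpec(coupling=coupling, condition_gain=condition_gain)


@dataclass
class FvcAssociation:
    """Planted linear association between FVC and one connectivity edge.

    The per-subject coupling at ``edge`` (within ``band`` and ``condition``)
    varies across the cohort with SD ``kappa_sd`` around its base value, and
    FVC (litres) is constructed so its population correlation with that
    coupling equals ``target_r`` exactly (before the negligible clipping of
    kappa to [0, 1]).
    """

    edge: tuple[str, str]
    band: str = "alpha"
    condition: str = "PB"
    target_r: float = 0.5
    fvc_mean: float = 3.5
    fvc_sd: float = 0.8
    kappa_sd: float = 0.1

    def __post_init__(self) -> None:
        if not abs(self.target_r) < 1:
            raise ValueError("|target_r| must be < 1")
        if self.fvc_sd <= 0 or self.kappa_sd <= 0:
            raise ValueError("spread parameters must be positive")


@dataclass
class SyntheticSubject:
    recording: Recording
    fvc: float | None
    subject_id: str
    ground_truth: CouplingSpec

    def __post_init__(self) -> None:
        if self.fvc is not None and self.fvc <= 0:
            raise ValueError("FVC must be positive (litres)")


def plv_calibration(kappa: np.ndarray | float, phase_noise_sd: float = 1.4) -> np.ndarray | float:
    """Population PLV implied by a coupling value under wrapped-Gaussian noise.

    ``PLV = exp(-sd^2 * (1 - kappa))``: monotone in kappa, exactly 1 at
    kappa = 1, exp(-sd^2) at kappa = 0.  The curve measured after band
    filtering and Hilbert phase extraction sits slightly above this
    (filtering smooths phase noise); use it as a design guide, not an
    identity.
    """
    return np.exp(-(phase_noise_sd**2) * (1.0 - np.asarray(kappa, dtype=float)))


def _correlation_root(kappa: np.ndarray) -> np.ndarray:
    """Factor L with L @ L.T = R where R is kappa + I projected to PSD."""
    r = kappa + np.eye(kappa.shape[0])
    vals, vecs = np.linalg.eigh(r)
    vals = np.clip(vals, 1e-10, None)
    r_psd = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(r_psd))
    r_psd = r_psd / np.outer(d, d)
    vals, vecs = np.linalg.eigh(r_psd)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def _ar1_noise(
    rng: np.random.Generator, n_samples: int, root: np.ndarray, sd: float, ac: float
) -> np.ndarray:
    """Stationary AR(1) noise, shape (n_samples, n_channels), marginal N(0, sd^2 R)."""
    n_ch = root.shape[0]
    eps = rng.standard_normal((n_samples, n_ch)) @ root.T
    innov = sd * np.sqrt(1.0 - ac**2) * eps
    innov[0] = sd * eps[0]  # start in the stationary distribution
    return _signal.lfilter([1.0], [1.0, -ac], innov, axis=0)


def generate_subject(
    paradigm: ParadigmSpec,
    coupling: CouplingSpec,
    seed: int,
    subject_id: str | None = None,
    fvc: float | None = None,
) -> SyntheticSubject:
    """Render one continuous multichannel run from the generative model.

    Deterministic given ``seed``.  Block boundaries are annotated; the
    coupling matrix switches with the annotated condition while each band's
    shared oscillator runs continuously through the whole recording.
    """
    rng = np.random.default_rng(seed)
    n_ch = len(paradigm.channel_names)
    n_samples = paradigm.n_samples
    fs = paradigm.sampling_rate
    bands = coupling.bands()
    for (cond, band), k in coupling.coupling.items():
        if k.shape[0] != n_ch:
            raise ValueError(
                f"coupling[{(cond, band)}] is {k.shape[0]}x{k.shape[0]} for {n_ch} channels"
            )

    data = np.zeros((n_ch, n_samples))
    anns = paradigm.annotations()
    roots = {key: _correlation_root(k) for key, k in coupling.coupling.items()}
    for band in bands:
        f_c = coupling.band_centers[band]
        inc = 2.0 * np.pi * f_c / fs + coupling.freq_jitter * rng.standard_normal(n_samples)
        theta = np.cumsum(inc)
        for ann in anns:
            key = (ann.condition, band)
            if key not in coupling.coupling:
                raise ValueError(f"coupling spec missing entry for {key}")
            n_blk = ann.stop - ann.start
            noise = _ar1_noise(
                rng, n_blk, roots[key], coupling.phase_noise_sd, coupling.phase_noise_ac
            )
            phase = theta[ann.start : ann.stop][:, None] + noise
            amp = coupling.amplitudes[band] * coupling.gain(ann.condition, band)
            data[:, ann.start : ann.stop] += amp * np.cos(phase).T
    if coupling.sensor_noise_sd > 0:
        data += coupling.sensor_noise_sd * rng.standard_normal(data.shape)

    rec = Recording(data, fs, paradigm.channel_names, anns)
    return SyntheticSubject(rec, fvc, subject_id or f"sub-{seed:05d}", coupling)


def draw_cohort_params(
    n_subjects: int,
    assoc: FvcAssociation,
    base_kappa: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-subject (edge coupling, FVC) with the planted correlation.

    The construction is linear-Gaussian: kappa_i ~ N(base, kappa_sd^2)
    clipped to [0, 1], and FVC_i = mean + sd * (r z_kappa_i +
    sqrt(1 - r^2) z_i) with independent standard normal z_i, so the
    population correlation equals ``target_r`` exactly before clipping.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    rng = np.random.default_rng(seed)
    z_k = rng.standard_normal(n_subjects)
    z_n = rng.standard_normal(n_subjects)
    kappa = np.clip(base_kappa + assoc.kappa_sd * z_k, 0.0, 1.0)
    r = assoc.target_r
    fvc = assoc.fvc_mean + assoc.fvc_sd * (r * z_k + np.sqrt(1.0 - r**2) * z_n)
    fvc = np.clip(fvc, 0.5, None)  # litres; keep physically plausible
    return kappa, fvc


def generate_cohort(
    n_subjects: int,
    paradigm: ParadigmSpec,
    coupling: CouplingSpec,
    fvc_assoc: FvcAssociation | None = None,
    seed: int = 0,
) -> list[SyntheticSubject]:
    """Generate a cohort; optionally plant an FVC-edge association.

    Each subject gets an independent sub-seed.  With ``fvc_assoc`` the
    coupling at the chosen edge (in the chosen condition and band) is
    subject-specific and linearly tied to FVC at the target correlation;
    all other edges are identical across subjects and independent of FVC.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    names = list(paradigm.channel_names)
    kappas = fvcs = None
    idx = None
    if fvc_assoc is not None:
        for ch in fvc_assoc.edge:
            if ch not in names:
                raise ValueError(f"edge channel {ch!r} not in the montage")
        idx = (names.index(fvc_assoc.edge[0]), names.index(fvc_assoc.edge[1]))
        key = (fvc_assoc.condition, fvc_assoc.band)
        if key not in coupling.coupling:
            raise ValueError(f"coupling spec missing entry for {key}")
        base = float(coupling.coupling[key][idx])
        kappas, fvcs = draw_cohort_params(n_subjects, fvc_assoc, base, seed)

    ss = np.random.SeedSequence(seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_subjects)]
    cohort = []
    for s in range(n_subjects):
        spec = coupling
        fvc = None
        if fvc_assoc is not None:
            spec = copy.deepcopy(coupling)
            k = spec.coupling[(fvc_assoc.condition, fvc_assoc.band)]
            k[idx[0], idx[1]] = k[idx[1], idx[0]] = kappas[s]
            fvc = float(fvcs[s])
        cohort.append(
            generate_subject(paradigm, spec, sub_seeds[s], subject_id=f"sub-{s + 1:03d}", fvc=fvc)
        )
    return cohort


def simulate_plv_cohort(
    n_subjects: int,
    coupling: CouplingSpec,
    bands: Sequence[str] = BAND_NAMES,
    conditions: Sequence[str] = CONDITIONS,
    est_noise_sd: float = 0.03,
    fvc_assoc: FvcAssociation | None = None,
    seed: int = 0,
    channel_names: Sequence[str] = DEFAULT_CHANNELS,
) -> tuple[dict[tuple[str, str], np.ndarray], np.ndarray | None]:
    """Feature-level twin of the signal generator: PLV edge features directly.

    Maps each (condition, band) coupling matrix through the calibration
    curve and adds independent Gaussian estimation noise of SD
    ``est_noise_sd`` (clipped to [0, 1]), emulating finite-sample PLV
    estimates without rendering time series.  Returns
    ``features[(condition, band)]`` of shape (n_subjects, n_edges) over the
    strictly-upper-triangle edge ordering, plus the FVC vector when an
    association is planted.  Intended for large-replicate statistical
    studies (error rates, power) where signal-level rendering is
    unnecessary.
    """
    rng = np.random.default_rng(seed)
    names = list(channel_names)
    n = len(names)
    iu = np.triu_indices(n, k=1)
    kappas = fvc = idx_edge = None
    if fvc_assoc is not None:
        i, j = sorted((names.index(fvc_assoc.edge[0]), names.index(fvc_assoc.edge[1])))
        edge_ids = list(zip(*iu))
        idx_edge = edge_ids.index((i, j))
        key = (fvc_assoc.condition, fvc_assoc.band)
        base = float(coupling.coupling[key][i, j])
        kappas, fvc = draw_cohort_params(
            n_subjects, fvc_assoc, base, int(rng.integers(2**31))
        )
    feats: dict[tuple[str, str], np.ndarray] = {}
    for cond in conditions:
        for band in bands:
            k_edges = np.tile(coupling.coupling[(cond, band)][iu], (n_subjects, 1))
            if fvc_assoc is not None and (cond, band) == (fvc_assoc.condition, fvc_assoc.band):
                k_edges[:, idx_edge] = kappas
            plv = plv_calibration(k_edges, coupling.phase_noise_sd)
            plv = plv + est_noise_sd * rng.standard_normal(plv.shape)
            feats[(cond, band)] = np.clip(plv, 0.0, 1.0)
    return feats, fvc
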