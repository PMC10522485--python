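"""Synthetic data generators with known ground truth.

Every generator draws from its own ``numpy.random.Generator`` seeded
explicitly, so outputs are bit-reproducible and independent of global
state. Noise is i.i.d. Gaussian throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "KineticTrace",
    "MeltCurve",
    "BindingIsotherm",
    "DispersionCurve",
    "DiscreteTrajectorySet",
    "FeatureTrajectory",
    "MultipleAlignment",
    "AMINO_ACIDS",
    "gen_kinetic_trace",
    "gen_melt_curve",
    "gen_isotherm",
    "gen_cpmg_profile",
    "gen_markov_trajectories",
    "gen_feature_trajectory",
    "gen_alignment",
    "fraction_bound_depletion",
    "cpmg_two_state",
    "stationary_distribution",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class KineticTrace:
    """Fluorescence-polarization time course.

    times are minutes; signal is polarization in arbitrary units.
    """

    times: np.ndarray
    signal: np.ndarray
    mode: str  # "dissociation" | "association"
    allotype: str = ""
    dm_conc: float = 0.0  # µM
    temperature: float = 37.0  # °C

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.mode not in ("dissociation", "association"):
            raise InvalidParameterError(f"unknown trace mode {self.mode!r}")
        if self.times.size != self.signal.size:
            raise InvalidParameterError("times and signal must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")


@dataclass
class MeltCurve:
    """Thermal-shift fluorescence curve (temperature in °C)."""

    temperatures: np.ndarray
    fluorescence: np.ndarray
    allotype: str = ""

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise InvalidParameterError("temperatures must be strictly increasing")


@dataclass
class BindingIsotherm:
    """Equilibrium titration: fraction of probe bound vs receptor concentration (nM)."""

    receptor_concs: np.ndarray
    fraction_bound: np.ndarray
    probe_conc: float  # nM
    temperature: float = 298.15  # K

    def __post_init__(self):
        self.receptor_concs = np.asarray(self.receptor_concs, dtype=float)
        self.fraction_bound = np.asarray(self.fraction_bound, dtype=float)
        if self.probe_conc <= 0:
            raise InvalidParameterError("probe_conc must be positive")


@dataclass
class DispersionCurve:
    """CPMG relaxation-dispersion profile for one methyl group."""

    freqs: np.ndarray  # ν_CPMG, Hz; strictly positive
    r2eff: np.ndarray  # s⁻¹
    t_cpmg: float = 0.04  # constant-time delay, s
    group_id: str = ""

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        if self.t_cpmg <= 0:
            raise InvalidParameterError("t_cpmg must be positive")
        if np.any(self.freqs <= 0):
            raise InvalidParameterError("frequencies must be positive (0 Hz is the reference)")


@dataclass
class DiscreteTrajectorySet:
    """Integer microstate sequences."""

    trajectories: list[np.ndarray]
    n_states: int
    frame_stride: float = 1.0  # physical time per frame

    def __post_init__(self):
        self.trajectories = [np.asarray(t, dtype=np.int64) for t in self.trajectories]


@dataclass
class FeatureTrajectory:
    """Real-valued feature time series (frames × features)."""

    data: np.ndarray
    frame_stride: float = 1.0
    hidden_states: np.ndarray | None = None  # ground truth when synthetic
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise InvalidParameterError("feature trajectory contains non-finite values")


@dataclass
class MultipleAlignment:
    """Equal-length aligned sequences over amino acids plus gap '-'."""

    sequences: list[str]
    identifiers: list[str]

    def __post_init__(self):
        if len(self.sequences) != len(self.identifiers):
            raise InvalidParameterError("sequences and identifiers must align")
        if len({len(s) for s in self.sequences}) > 1:
            raise InvalidParameterError("all sequences must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{s}\n" for i, s in zip(self.identifiers, self.sequences))


# ---------------------------------------------------------------------------
# Model functions (shared with the fitters' round-trip tests)
# ---------------------------------------------------------------------------

def fraction_bound_depletion(receptor: np.ndarray, kd: float, probe: float) -> np.ndarray:
    """Exact ligand-depletion fraction bound.

    bound = ((R+L+Kd) − sqrt((R+L+Kd)² − 4·R·L)) / 2, fraction = bound / L.
    """
    r = np.asarray(receptor, dtype=float)
    s = r + probe + kd
    bound = (s - np.sqrt(s * s - 4.0 * r * probe)) / 2.0
    return bound / probe


def cpmg_two_state(freqs: np.ndarray, r2_0: float, phi: float, kex: float) -> np.ndarray:
    """Fast-exchange (Luz–Meiboom) two-site dispersion model.

    R2eff(ν) = R2_0 + (φ/kex)·(1 − (4ν/kex)·tanh(kex/(4ν)))
    """
    nu = np.asarray(freqs, dtype=float)
    x = 4.0 * nu / kex
    return r2_0 + (phi / kex) * (1.0 - x * np.tanh(1.0 / x))


def melt_sigmoid(temps: np.ndarray, lower: float, upper: float, tm: float,
                 slope: float) -> np.ndarray:
    """Four-parameter Boltzmann sigmoid."""
    t = np.asarray(temps, dtype=float)
    return lower + (upper - lower) / (1.0 + np.exp(-(t - tm) / slope))


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left Perron vector)."""
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _check_stochastic(T: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise InvalidParameterError("transition matrix must be square")
    if np.any(T < -tol):
        raise InvalidParameterError("transition matrix has negative entries")
    if np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-8:
        raise InvalidParameterError("transition matrix rows must sum to 1")
    return T


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_kinetic_trace(mode: str, time_grid, seed: int, *, k_off: float | None = None,
                      amplitude: float = 100.0, baseline: float = 0.0,
                      v0: float | None = None, plateau: float | None = None,
                      noise: float = 0.0, allotype: str = "", dm_conc: float = 0.0,
                      temperature: float = 37.0) -> KineticTrace:
    """Simulate a fluorescence-polarization trace.

    Dissociation: baseline + amplitude·exp(−k_off·t).
    Association: saturating exponential parameterized by its initial
    velocity v0 and plateau, i.e. plateau·(1 − exp(−(v0/plateau)·t)),
    whose slope at t=0 equals v0 exactly.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.size == 0:
        raise InvalidParameterError("empty time grid")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise InvalidParameterError("time grid must be nonnegative and strictly increasing")

    if mode == "dissociation":
        if k_off is None or k_off <= 0:
            raise InvalidParameterError("dissociation requires k_off > 0")
        if amplitude <= 0:
            raise InvalidParameterError("amplitude must be positive")
        clean = baseline + amplitude * np.exp(-k_off * t)
    elif mode == "association":
        if v0 is None or v0 <= 0:
            raise InvalidParameterError("association requires v0 > 0")
        pl = plateau if plateau is not None else amplitude
        if pl <= 0:
            raise InvalidParameterError("plateau must be positive")
        clean = baseline + pl * (1.0 - np.exp(-(v0 / pl) * t))
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    signal = clean + (rng.normal(0.0, noise, t.size) if noise > 0 else 0.0)
    return KineticTrace(times=t, signal=signal, mode=mode, allotype=allotype,
                        dm_conc=dm_conc, temperature=temperature)


def gen_melt_curve(tm: float, slope: float, temp_grid, seed: int, *,
                   lower: float = 0.0, upper: float = 1.0, noise: float = 0.0,
                   allotype: str = "") -> MeltCurve:
    """Simulate a sigmoidal thermal-shift curve."""
    if slope <= 0:
        raise InvalidParameterError("slope must be positive")
    t = np.asarray(temp_grid, dtype=float)
    clean = melt_sigmoid(t, lower, upper, tm, slope)
    rng = np.random.default_rng(seed)
    fl = clean + (rng.normal(0.0, noise, t.size) if noise > 0 else 0.0)
    return MeltCurve(temperatures=t, fluorescence=fl, allotype=allotype)


def gen_isotherm(kd: float, probe_conc: float, receptor_concs, seed: int, *,
                 noise: float = 0.0, temperature: float = 298.15) -> BindingIsotherm:
    """Simulate a ligand-depletion binding isotherm."""
    if kd <= 0 or probe_conc <= 0:
        raise InvalidParameterError("kd and probe_conc must be positive")
    r = np.asarray(receptor_concs, dtype=float)
    if np.any(r < 0):
        raise InvalidParameterError("receptor concentrations must be nonnegative")
    clean = fraction_bound_depletion(r, kd, probe_conc)
    rng = np.random.default_rng(seed)
    frac = clean + (rng.normal(0.0, noise, r.size) if noise > 0 else 0.0)
    return BindingIsotherm(receptor_concs=r, fraction_bound=frac,
                           probe_conc=probe_conc, temperature=temperature)


def gen_cpmg_profile(r2_0: float, phi: float, kex: float, freqs, seed: int, *,
                     noise: float = 0.0, t_cpmg: float = 0.04,
                     group_id: str = "") -> DispersionCurve:
    """Simulate a two-site fast-exchange CPMG dispersion profile.

    0 Hz entries are reference planes and are excluded from the curve.
    """
    if kex <= 0:
        raise InvalidParameterError("kex must be positive")
    nu = np.asarray(freqs, dtype=float)
    nu = nu[nu > 0]
    if nu.size == 0:
        raise InvalidParameterError("no positive CPMG frequencies")
    clean = cpmg_two_state(nu, r2_0, phi, kex)
    rng = np.random.default_rng(seed)
    r2 = clean + (rng.normal(0.0, noise, nu.size) if noise > 0 else 0.0)
    return DispersionCurve(freqs=nu, r2eff=r2, t_cpmg=t_cpmg, group_id=group_id)


def gen_markov_trajectories(T, n_steps: int, n_traj: int, seed: int, *,
                            start_state: int | None = None,
                            frame_stride: float = 1.0) -> DiscreteTrajectorySet:
    """Sample discrete trajectories from a row-stochastic transition matrix."""
    T = _check_stochastic(T)
    if n_steps < 2:
        raise InvalidParameterError("n_steps must be at least 2")
    n = T.shape[0]
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(T, axis=1)
    pi = stationary_distribution(T)
    trajs = []
    for _ in range(n_traj):
        s = np.empty(n_steps, dtype=np.int64)
        if start_state is None:
            s[0] = rng.choice(n, p=pi)
        else:
            s[0] = start_state
        u = rng.random(n_steps - 1)
        for i in range(1, n_steps):
            s[i] = np.searchsorted(cdf[s[i - 1]], u[i - 1], side="right")
        trajs.append(s)
    return DiscreteTrajectorySet(trajectories=trajs, n_states=n,
                                 frame_stride=frame_stride)


def gen_feature_trajectory(metastable_T, emission_centers, emission_sd: float,
                           fast_noise_dims: int, n_steps: int, seed: int, *,
                           fast_noise_sd: float = 1.0,
                           frame_stride: float = 1.0) -> FeatureTrajectory:
    """Hidden metastable jump process emitted into feature space.

    Each frame's features are the hidden state's emission center plus
    isotropic Gaussian scatter; extra dimensions of i.i.d. (fast) noise
    are appended. The hidden state sequence is returned as ground truth.
    """
    T = _check_stochastic(metastable_T)
    if T.shape[0] < 2:
        raise InvalidParameterError("need at least 2 metastable states")
    centers = np.atleast_2d(np.asarray(emission_centers, dtype=float))
    if centers.shape[0] != T.shape[0]:
        raise InvalidParameterError("one emission center per metastable state required")
    if len({tuple(c) for c in centers}) != centers.shape[0]:
        raise InvalidParameterError("emission centers must be distinct")
    if emission_sd < 0:
        raise InvalidParameterError("emission_sd must be nonnegative")

    hidden = gen_markov_trajectories(T, n_steps, 1, seed).trajectories[0]
    rng = np.random.default_rng(seed + 1)
    slow = centers[hidden]
    if emission_sd > 0:
        slow = slow + rng.normal(0.0, emission_sd, slow.shape)
    if fast_noise_dims > 0:
        fast = rng.normal(0.0, fast_noise_sd, (n_steps, fast_noise_dims))
        data = np.hstack([slow, fast])
    else:
        data = slow
    return FeatureTrajectory(data=data, frame_stride=frame_stride, hidden_states=hidden)


def gen_alignment(column_frequency_profiles, n_seqs: int, seed: int) -> MultipleAlignment:
    """Sample an alignment with controlled per-column residue frequencies."""
    profiles = np.atleast_2d(np.asarray(column_frequency_profiles, dtype=float))
    if profiles.shape[1] != len(AMINO_ACIDS):
        raise InvalidParameterError(f"profiles must have length {len(AMINO_ACIDS)}")
    if np.any(np.abs(profiles.sum(axis=1) - 1.0) > 1e-9):
        raise InvalidParameterError("each profile must sum to 1 within 1e-9")
    if np.any(profiles < 0):
        raise InvalidParameterError("profile frequencies must be nonnegative")
    rng = np.random.default_rng(seed)
    cols = []
    for p in profiles:
        idx = rng.choice(len(AMINO_ACIDS), size=n_seqs, p=p / p.sum())
        cols.append([AMINO_ACIDS[i] for i in idx])
    seqs = ["".join(row) for row in zip(*cols)]
    ids = [f"seq{i + 1}" for i in range(n_seqs)]
    return MultipleAlignment(sequences=seqs, identifiers=ids)
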