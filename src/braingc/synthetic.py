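"""Synthetic multichannel EEG from stable MVAR processes with known causal structure.

The generator emulates resting/task EEG as a multivariate autoregressive (MVAR)
process: each channel carries oscillatory self-dynamics (AR poles placed at mu
and/or beta frequencies) and directed cross-channel coupling at a short lag.
Because the coupling graph is known exactly, the Granger-causality pipeline can
be validated against ground truth, and condition blocks in which coupling is
weakened reproduce the sparser task-state networks seen in motor-imagery EEG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .recording import Recording

__all__ = [
    "CouplingGraph",
    "MVARSpec",
    "StateSpec",
    "ScenarioSpec",
    "band_peaked_ar_coeffs",
    "multi_peak_ar_coeffs",
    "generate_mvar",
    "generate_scenario",
    "default_scenario",
    "scale_edges_incident",
    "derive_seed",
    "DEFAULT_LABELS_8",
    "STANDARD_LABELS_62",
]

DEFAULT_LABELS_8 = ("Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4")

# 62 scalp positions from the extended 10-20 layout, frontal to occipital.
STANDARD_LABELS_62 = (
    "Fp1", "Fpz", "Fp2",
    "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2", "CB1", "CB2",
)


def derive_seed(master: int, *indices: int) -> int:
    """Deterministically derive a child seed (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(int(master), spawn_key=tuple(int(i) for i in indices))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class CouplingGraph:
    """Directed coupling structure: which channels drive which, and how strongly.

    ``edges`` are ordered (source, target) index pairs; ``weights`` align with
    ``edges``. This is the ground truth the GCI estimator is asked to recover.
    """

    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    weights: tuple[float, ...]
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        object.__setattr__(self, "edges", tuple((int(s), int(t)) for s, t in self.edges))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        if len(self.node_labels) != self.n_nodes:
            raise ValueError("node_labels length must equal n_nodes")
        if len(self.weights) != len(self.edges):
            raise ValueError("one weight per edge required")
        for (s, t) in self.edges:
            if s == t:
                raise ValueError(f"self-loop edge ({s}, {t}) not allowed")
            if not (0 <= s < self.n_nodes and 0 <= t < self.n_nodes):
                raise ValueError(f"edge ({s}, {t}) references invalid node")
        if not all(math.isfinite(w) for w in self.weights):
            raise ValueError("edge weights must be finite")

    def coupling_matrix(self) -> np.ndarray:
        """Dense (target, source) coupling matrix W, W[t, s] = weight of s -> t."""
        w = np.zeros((self.n_nodes, self.n_nodes))
        for (s, t), wt in zip(self.edges, self.weights):
            w[t, s] += wt
        return w

    def edge_set(self) -> set[tuple[int, int]]:
        return set(self.edges)


def band_peaked_ar_coeffs(
    center_hz: float,
    sample_rate: float,
    bandwidth_hz: float | None = None,
    pole_radius: float = 0.95,
) -> tuple[float, float]:
    """AR(2) coefficients whose spectral density peaks at ``center_hz``.

    A conjugate pole pair at radius r and angle theta gives
    ``a1 = 2 r cos(theta)``, ``a2 = -r**2``. The spectral peak of an AR(2)
    process sits below the pole angle (cos w_peak = (1+r^2) cos(theta) /
    (2r)), noticeably so at EEG frequencies relative to a 1000 Hz rate, so
    theta is solved from the requested peak rather than set to it. If
    ``bandwidth_hz`` is given the radius is ``exp(-pi * bw / fs)``
    (half-power heuristic), otherwise ``pole_radius`` is used.
    """
    if not 0 < center_hz < sample_rate / 2:
        raise ValueError(
            f"center {center_hz} Hz outside (0, Nyquist={sample_rate / 2} Hz)"
        )
    r = pole_radius if bandwidth_hz is None else math.exp(-math.pi * bandwidth_hz / sample_rate)
    if not 0 < r < 1:
        raise ValueError(f"pole radius {r} outside (0, 1)")
    omega = 2 * math.pi * center_hz / sample_rate
    cos_theta = 2 * r * math.cos(omega) / (1 + r * r)
    theta = math.acos(min(1.0, cos_theta))
    return 2 * r * math.cos(theta), -r * r


def multi_peak_ar_coeffs(
    centers_hz: tuple[float, ...],
    sample_rate: float,
    pole_radius: float = 0.95,
) -> tuple[float, ...]:
    """AR coefficients with one spectral peak per centre (order = 2 per peak).

    Obtained by multiplying the AR(2) characteristic polynomials of the
    individual resonances; stability of each factor implies stability of the
    product.
    """
    poly = np.array([1.0])
    for c in centers_hz:
        a1, a2 = band_peaked_ar_coeffs(c, sample_rate, pole_radius=pole_radius)
        poly = np.convolve(poly, np.array([1.0, -a1, -a2]))
    return tuple(-poly[1:])


@dataclass(frozen=True)
class MVARSpec:
    """A stationary MVAR process: per-node oscillatory AR dynamics plus
    directed cross-coupling from ``coupling`` acting at ``coupling_lag``."""

    coupling: CouplingGraph
    self_dynamics: tuple[tuple[float, ...], ...]
    noise_sd: tuple[float, ...]
    sample_rate: float
    seed: int
    coupling_lag: int = 1
    observation_noise_sd: float = 0.0
    observation_noise_alpha: float = 1.0  # spectral exponent: 0 white, 1 pink

    def __post_init__(self) -> None:
        n = self.coupling.n_nodes
        if self.observation_noise_sd < 0:
            raise ValueError("observation_noise_sd must be >= 0")
        if self.observation_noise_alpha < 0:
            raise ValueError("observation_noise_alpha must be >= 0")
        object.__setattr__(
            self, "self_dynamics", tuple(tuple(map(float, c)) for c in self.self_dynamics)
        )
        if len(self.self_dynamics) != n:
            raise ValueError("one self-dynamics coefficient tuple per node required")
        sd = self.noise_sd
        if np.isscalar(sd):
            sd = (float(sd),) * n
        object.__setattr__(self, "noise_sd", tuple(float(s) for s in sd))
        if len(self.noise_sd) != n or any(s <= 0 for s in self.noise_sd):
            raise ValueError("noise_sd must be positive, one per node")
        if self.coupling_lag < 1:
            raise ValueError("coupling_lag must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_nodes(self) -> int:
        return self.coupling.n_nodes

    @property
    def order(self) -> int:
        p_self = max((len(c) for c in self.self_dynamics), default=0)
        return max(p_self, self.coupling_lag, 1)

    def coefficient_tensor(self) -> np.ndarray:
        """Lag coefficient matrices A, shape (order, n, n);
        x[t] = sum_l A[l-1] @ x[t-l] + e[t]."""
        p, n = self.order, self.n_nodes
        a = np.zeros((p, n, n))
        for i, coeffs in enumerate(self.self_dynamics):
            for l, c in enumerate(coeffs):
                a[l, i, i] += c
        a[self.coupling_lag - 1] += self.coupling.coupling_matrix()
        return a

    def companion_matrix(self) -> np.ndarray:
        a = self.coefficient_tensor()
        p, n = a.shape[0], a.shape[1]
        comp = np.zeros((p * n, p * n))
        comp[:n] = np.concatenate(list(a), axis=1)
        if p > 1:
            comp[n:, : (p - 1) * n] = np.eye((p - 1) * n)
        return comp

    def spectral_radius(self, n_squarings: int = 16) -> float:
        """Spectral radius of the companion matrix; < 1 iff stationary.

        Computed by Gelfand's formula, ``||A**k||**(1/k)`` for ``k = 2**16``
        via repeated squaring with norm renormalisation. Direct eigenvalue
        routines misreport the radius of this matrix when many nodes share
        near-identical poles (the companion is then defective and its
        eigenvalues are ill-conditioned); the norm-based limit is robust.
        """
        m = self.companion_matrix()
        norm = np.linalg.norm(m)
        if norm == 0:
            return 0.0
        log_scale = float(np.log(norm))
        m = m / norm
        for _ in range(n_squarings):
            m = m @ m
            norm = np.linalg.norm(m)
            if norm == 0:
                return 0.0
            log_scale = 2.0 * log_scale + float(np.log(norm))
            m = m / norm
        return float(np.exp(log_scale / 2.0**n_squarings))


def _colored(white: np.ndarray, alpha: float) -> np.ndarray:
    """Shape white noise (channels x samples) to a 1/f^alpha spectrum with
    unit variance per channel."""
    if alpha == 0:
        return white
    n = white.shape[-1]
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.empty_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    scale[0] = scale[1]
    shaped = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    return shaped / np.where(sd > 0, sd, 1.0)


def generate_mvar(spec: MVARSpec, n_samples: int) -> Recording:
    """Simulate ``n_samples`` of the MVAR process after a burn-in.

    The first ``max(1000, 10 * order)`` samples are discarded so the returned
    block is near-stationary. Identical spec (including seed) gives
    bit-identical output. Raises if the process is non-stationary.
    """
    radius = spec.spectral_radius()
    if radius >= 1.0:
        raise ValueError(
            f"MVAR process is non-stationary: companion spectral radius "
            f"{radius:.4f} >= 1"
        )
    if n_samples <= 10 * spec.order:
        raise ValueError(f"n_samples must exceed 10 x order = {10 * spec.order}")
    p, n = spec.order, spec.n_nodes
    burn = max(1000, 10 * p)
    total = burn + n_samples
    a = spec.coefficient_tensor()
    # One (n, n*p) matrix applied to the reversed window of the last p samples.
    a_stack = np.concatenate(list(a), axis=1)
    rng = np.random.default_rng(spec.seed)
    e = rng.normal(0.0, 1.0, size=(total, n)) * np.asarray(spec.noise_sd)
    x = np.zeros((total + p, n))
    for t in range(total):
        window = x[t : t + p][::-1].reshape(-1)  # lags 1..p
        x[t + p] = a_stack @ window + e[t]
    data = x[p + burn :].T
    if spec.observation_noise_sd > 0:
        # Broadband 1/f^alpha background on top of the oscillatory state,
        # emulating the continuous spectrum of real EEG. Without it a
        # band-pass filter leaves a (numerically) deterministic signal,
        # which no real recording is.
        white = rng.normal(0.0, 1.0, size=data.shape)
        data = data + spec.observation_noise_sd * _colored(
            white, spec.observation_noise_alpha
        )
    return Recording(
        data=data,
        sample_rate=spec.sample_rate,
        channel_labels=spec.coupling.node_labels,
    )


@dataclass(frozen=True)
class StateSpec:
    """One condition block: a name, a duration, and per-edge coupling scale
    factors (edges absent from ``edge_scale`` are left unchanged)."""

    name: str
    duration_s: float
    edge_scale: tuple[tuple[tuple[int, int], float], ...] = ()

    def scale_for(self, edge: tuple[int, int]) -> float:
        for e, f in self.edge_scale:
            if tuple(e) == tuple(edge):
                return f
        return 1.0


@dataclass(frozen=True)
class ScenarioSpec:
    """An ordered sequence of condition blocks generated from a base MVAR
    process with per-state coupling modifications (rest / task / rest)."""

    base: MVARSpec
    states: tuple[StateSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.states]
        if len(names) != len(set(names)):
            raise ValueError("state names must be unique")
        if not self.states:
            raise ValueError("at least one state required")


def _modified_spec(base: MVARSpec, state: StateSpec, seed: int) -> MVARSpec:
    graph = base.coupling
    new_weights = tuple(
        w * state.scale_for(e) for e, w in zip(graph.edges, graph.weights)
    )
    keep = [i for i, w in enumerate(new_weights) if w != 0.0]
    new_graph = CouplingGraph(
        n_nodes=graph.n_nodes,
        edges=tuple(graph.edges[i] for i in keep),
        weights=tuple(new_weights[i] for i in keep),
        node_labels=graph.node_labels,
    )
    return replace(base, coupling=new_graph, seed=seed)


def generate_scenario(spec: ScenarioSpec) -> list[tuple[str, Recording]]:
    """One Recording per state, from the correspondingly modified process.

    Noise streams are independent across states but deterministically derived
    from the base seed, so the whole scenario is reproducible from one number.
    """
    out: list[tuple[str, Recording]] = []
    for k, state in enumerate(spec.states):
        if state.duration_s <= 0:
            raise ValueError(f"state '{state.name}' has non-positive duration")
        n_samples = int(round(state.duration_s * spec.base.sample_rate))
        mspec = _modified_spec(spec.base, state, derive_seed(spec.base.seed, k))
        rec = generate_mvar(mspec, n_samples)
        out.append((state.name, rec.with_data(rec.data, state_tag=state.name)))
    return out


def _frontal_central(labels: tuple[str, ...]) -> set[str]:
    """Labels over frontal and central (sensorimotor) scalp regions."""
    sel = set()
    for lab in labels:
        u = lab.upper()
        if u.startswith(("FP", "AF", "F", "FC", "FT", "C")) and not u.startswith("CB"):
            sel.add(lab)
        if u.startswith("CP") or u.startswith("TP"):
            sel.discard(lab)
    return sel


def scale_edges_incident(
    graph: CouplingGraph, labels: set[str] | tuple[str, ...], factor: float
) -> tuple[tuple[tuple[int, int], float], ...]:
    """Per-edge scale map: ``factor`` for every edge touching one of ``labels``."""
    labset = set(labels)
    idx = {i for i, lab in enumerate(graph.node_labels) if lab in labset}
    return tuple(
        (e, factor) for e in graph.edges if e[0] in idx or e[1] in idx
    )


def _ar_gain(coeffs: tuple[float, ...], freq_hz: float, sample_rate: float) -> float:
    """Steady-state gain |1 / A(e^{i omega})| of an AR filter at one frequency."""
    omega = 2 * math.pi * freq_hz / sample_rate
    lags = np.arange(1, len(coeffs) + 1)
    a = 1.0 - np.sum(np.asarray(coeffs) * np.exp(-1j * omega * lags))
    return float(1.0 / abs(a))


def _unit_noise_rms(coeffs: tuple[float, ...], n_impulse: int = 32768) -> float:
    """Stationary RMS of a stable AR process driven by unit-variance noise,
    from the energy of its impulse response."""
    from scipy import signal as _signal

    impulse = np.zeros(n_impulse)
    impulse[0] = 1.0
    h = _signal.lfilter([1.0], np.r_[1.0, -np.asarray(coeffs)], impulse)
    return float(np.sqrt(np.sum(h**2)))


def stationary_channel_sd(spec: MVARSpec) -> np.ndarray:
    """Exact stationary standard deviation per channel (state part only).

    Solves the companion-form discrete Lyapunov equation S = A S A' + Q; the
    channel variances are the leading diagonal block of S.
    """
    from scipy import linalg as _linalg

    comp = spec.companion_matrix()
    n = spec.n_nodes
    q = np.zeros_like(comp)
    q[:n, :n] = np.diag(np.square(spec.noise_sd))
    s = _linalg.solve_discrete_lyapunov(comp, q)
    return np.sqrt(np.clip(np.diag(s)[:n], 0.0, None))


def _normalize_output_rms(spec: MVARSpec, target_rms: float, n_iter: int = 6) -> MVARSpec:
    """Rescale innovation SDs so every channel's stationary RMS hits the
    target. Coupling mixes channels, so this is a (rapidly converging)
    fixed-point iteration rather than a per-node division."""
    current = spec
    floor = tuple(0.01 * s for s in spec.noise_sd)
    for _ in range(n_iter):
        sd_out = stationary_channel_sd(current)
        factors = target_rms / np.where(sd_out > 0, sd_out, 1.0)
        # A strongly driven node's output cannot fall below the power it
        # receives from upstream; keep its own innovation positive.
        new_noise = tuple(
            float(max(s * f, lo))
            for s, f, lo in zip(current.noise_sd, factors, floor)
        )
        current = replace(current, noise_sd=new_noise)
    return current


def _default_edges(n_channels: int) -> tuple[tuple[str, ...], tuple[tuple[int, int], ...]]:
    # The coupling graph is feed-forward (acyclic). With oscillatory node
    # dynamics, any feedback cycle's loop gain is amplified by the resonance
    # peak of each node's transfer function and destabilises the process at
    # physiologically sensible weights; an acyclic graph keeps the companion
    # spectrum equal to the self-dynamics poles, so stability is independent
    # of coupling strength.
    if n_channels == 8:
        labels = DEFAULT_LABELS_8
        # Primary edges form the anterior -> posterior backbone; with a
        # right-hand imagery task the left-hemisphere prefrontal drive is
        # dominant, so the right prefrontal link is a weaker secondary edge,
        # as are the interhemispheric links.
        primary = [
            ("Fp1", "F3"),
            ("F3", "C3"), ("F4", "C4"),
            ("C3", "P3"), ("C4", "P4"),
        ]
        secondary = [
            ("Fp1", "Fp2"), ("Fp2", "F4"),
            ("F3", "F4"), ("C3", "C4"), ("P3", "P4"),
        ]
        ix = {lab: i for i, lab in enumerate(labels)}
        edges = tuple((ix[s], ix[t]) for s, t in primary + secondary)
        is_primary = (True,) * len(primary) + (False,) * len(secondary)
    else:
        if n_channels > len(STANDARD_LABELS_62):
            raise ValueError(f"at most {len(STANDARD_LABELS_62)} channels supported")
        labels = STANDARD_LABELS_62[:n_channels]
        # Anterior-to-posterior chain (primary) plus weaker skip links
        # (secondary), all forward in index order so the graph stays acyclic.
        edges = []
        is_primary = []
        for i in range(n_channels - 1):
            edges.append((i, i + 1))
            is_primary.append(True)
        for i in range(0, n_channels - 2, 2):
            edges.append((i, i + 2))
            is_primary.append(False)
        edges = tuple(edges)
        is_primary = tuple(is_primary)
    return labels, edges, tuple(is_primary)


def default_scenario(
    n_channels: int = 8,
    sample_rate: float = 1000.0,
    duration_s: float = 60.0,
    seed: int = 0,
    coupling_weight: float = 0.8,
    task_scale: float = 0.4,
    post_scale: float = 0.7,
    pole_radius: float = 0.95,
    channel_rms_uv: float = 10.0,
    background_fraction: float = 0.2,
) -> ScenarioSpec:
    """The desk-scale study scenario: rest-before / task / rest-after.

    Each node mixes a mu (10 Hz) and a beta (20 Hz) resonance so both bands
    carry signal. During "task" every edge incident to a frontal or central
    channel is scaled by ``task_scale`` (default 0.4), emulating reduced
    effective connectivity over frontal/sensorimotor cortex during motor
    imagery; the after-task block recovers only partially (``post_scale``).
    """
    labels, edges, is_primary = _default_edges(n_channels)
    # Individual peak frequencies vary a little from channel to channel, as
    # they do across scalp sites; every node carries one mu and one beta
    # resonance so both band analyses see signal.
    mu_peaks = np.linspace(9.5, 11.5, n_channels)
    beta_peaks = np.linspace(18.0, 22.0, n_channels)
    dyn = tuple(
        multi_peak_ar_coeffs((mu_peaks[i], beta_peaks[i]), sample_rate, pole_radius=pole_radius)
        for i in range(n_channels)
    )
    # Gain-normalised coupling: near 10/20 Hz every node's AR dynamics have a
    # large steady-state gain, so a raw lag-1 weight would be re-amplified by
    # the receiver and compound down chains. Dividing each edge weight by the
    # receiver's gain at the sender's peak frequencies makes
    # ``coupling_weight`` the approximate amplitude ratio of transmitted to
    # intrinsic oscillation, independent of where the edge sits.
    # Coupling strengths are heterogeneous, as cortical pathways are:
    # backbone edges carry the full coupling_weight, secondary links half of
    # it. Under the task-state scaling the weak links drop below the network
    # threshold first, thinning the estimated network without shattering it.
    weights = []
    for (s, t), prim in zip(edges, is_primary):
        g = max(
            _ar_gain(dyn[t], mu_peaks[s], sample_rate),
            _ar_gain(dyn[t], beta_peaks[s], sample_rate),
        )
        weights.append(coupling_weight * (1.0 if prim else 0.5) / g)
    graph = CouplingGraph(n_channels, edges, tuple(weights), labels)
    # Innovation SDs are set so each channel's stationary RMS lands at a
    # resting-EEG-like level (default 10 uV), keeping normal samples well
    # below the 50 uV artifact threshold. The task state, with its weakened
    # coupling, then shows slightly reduced power — as desynchronisation does.
    noise_sd = tuple(
        channel_rms_uv / _unit_noise_rms(dyn[i]) for i in range(n_channels)
    )
    base = MVARSpec(
        coupling=graph,
        self_dynamics=dyn,
        noise_sd=noise_sd,
        sample_rate=sample_rate,
        seed=seed,
        observation_noise_sd=background_fraction * channel_rms_uv,
    )
    base = _normalize_output_rms(base, channel_rms_uv)
    targets = _frontal_central(graph.node_labels)
    states = (
        StateSpec("rest_before", duration_s),
        StateSpec("task", duration_s, scale_edges_incident(graph, targets, task_scale)),
        StateSpec("rest_after", duration_s, scale_edges_incident(graph, targets, post_scale)),
    )
    return ScenarioSpec(base=base, states=states)
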