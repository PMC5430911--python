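"""Generative simulation of subjects' choices and ROI BOLD.

Choices are drawn by inverting the analysis chain: a memory-decay observer
with a known decay parameter produces trial-by-trial priors, the
standardized prior/evidence/interaction terms enter a logistic model with
known coefficients, and correctness is Bernoulli (with an optional lapse
mixing in uniform guessing).  ROI BOLD is either a linear combination of
design-matrix columns plus slow drift and AR(1) Gaussian noise, or —
for connectivity analyses — the HRF-convolved states of coupled bilinear
neural dynamics.  Recovery tests run the full analysis on these simulations
and compare estimates to the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import glm as _glm
from .connectivity import DCMInputs, DCMModel, DCMParams, simulate_dcm, states_to_bold
from .observer import ObserverConfig, prior_trace
from .task_design import SessionDesign

__all__ = [
    "SubjectParams",
    "BoldSimConfig",
    "CouplingStudy",
    "simulate_subject",
    "simulate_bold",
    "simulate_coupled_rois",
    "coupling_study",
    "noise_sd_for_snr",
    "ar1_noise",
]


@dataclass(frozen=True)
class SubjectParams:
    """Generative behavioural parameters of one simulated subject.

    ``beta_true`` is (b0, b_prior, b_evidence, b_interaction) on the
    standardized-predictor scale.  The defaults mirror the qualitative
    pattern the tasks are built to elicit: strong evidence and prior effects
    and a negative interaction (prior reliance grows as evidence shrinks).
    """

    alpha_true: float = 1.5
    beta_true: tuple[float, float, float, float] = (0.0, 1.0, 1.0, -0.5)
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha_true < 1.0:
            raise ValueError(f"alpha_true must be >= 1, got {self.alpha_true}")
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError(f"lapse must lie in [0, 0.5], got {self.lapse}")


@dataclass(frozen=True)
class BoldSimConfig:
    """Acquisition and noise parameters for simulated ROI time series.

    Defaults follow the acquisition protocol (TR 2.5 s, 290 volumes with
    the first 5 discarded).  ``noise_sd`` is the innovation standard
    deviation of the AR(1) noise; ``drift_amplitude`` scales a slow cosine
    drift (period ~ twice the run) that the 128 s high-pass must absorb.
    """

    tr: float = 2.5
    n_volumes: int = 290
    n_discard: int = 5
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError(f"|ar1_rho| must be < 1, got {self.ar1_rho}")
        if self.n_discard < 0 or self.n_discard >= self.n_volumes:
            raise ValueError("n_discard must lie in [0, n_volumes)")

    @property
    def usable_volumes(self) -> int:
        return self.n_volumes - self.n_discard


def simulate_subject(
    design: SessionDesign, params: SubjectParams, seed: int
) -> pd.DataFrame:
    """Draw one subject's choices from the generative observer + logistic model.

    Per non-control trial: the observer prior (decay ``alpha_true``) of the
    enacted intention is computed from the trial history, prior and evidence
    are z-scored within the session, and the probability of a correct
    response is lapse/2 + (1 - lapse) * logistic(linear predictor).  Returns
    a per-trial table with the generative probability, the drawn
    correctness, and the emitted response.
    """
    trials = design.task_trials()
    events = [t.intention for t in trials]
    contexts = None
    if design.config.task_type == "social":
        contexts = [t.first_actor_move for t in trials]
    trace = prior_trace(
        events,
        ObserverConfig(alpha=params.alpha_true),
        labels=design.config.intentions,
        contexts=contexts,
    )
    prior = trace.prob_of(events)
    evidence = np.array([t.evidence_level for t in trials], dtype=float)
    zp = (prior - prior.mean()) / prior.std()
    ze = (evidence - evidence.mean()) / evidence.std()
    b0, bp, be, bpe = params.beta_true
    eta = b0 + bp * zp + be * ze + bpe * zp * ze
    p_correct = params.lapse / 2.0 + (1.0 - params.lapse) / (1.0 + np.exp(-eta))

    rng = np.random.default_rng(seed)
    correct = (rng.random(len(trials)) < p_correct).astype(int)
    pair = design.config.intentions
    other = {pair[0]: pair[1], pair[1]: pair[0]}
    response = [e if c else other[e] for e, c in zip(events, correct)]
    return pd.DataFrame(
        {
            "trial_index": [t.index for t in trials],
            "phase": [t.phase for t in trials],
            "intention": events,
            "is_likely": [t.is_likely for t in trials],
            "evidence_level": [t.evidence_level for t in trials],
            "first_actor_move": [t.first_actor_move for t in trials],
            "prior": prior,
            "p_correct": p_correct,
            "correct": correct,
            "response": response,
        }
    )


def ar1_noise(
    n: int, rho: float, innovation_sd: float, rng: np.random.Generator, n_cols: int = 1
) -> np.ndarray:
    """Stationary AR(1) noise: x_t = rho x_{t-1} + e_t, e ~ N(0, sd^2)."""
    e = rng.normal(0.0, innovation_sd, size=(n, n_cols))
    x = np.empty_like(e)
    # stationary start so the marginal variance is constant from t=0
    x[0] = e[0] / np.sqrt(1.0 - rho**2) if abs(rho) < 1 else e[0]
    for t in range(1, n):
        x[t] = rho * x[t - 1] + e[t]
    return x if n_cols > 1 else x[:, 0]


def _drift(n: int, tr: float, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) * tr
    period = 2.0 * n * tr  # slower than the 128 s cutoff
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return amplitude * np.cos(2.0 * np.pi * t / period + phase)


def simulate_bold(
    X: "_glm.DesignMatrix | np.ndarray",
    betas: "dict[str, float] | np.ndarray",
    cfg: BoldSimConfig = BoldSimConfig(),
    seed: Optional[int] = None,
) -> np.ndarray:
    """One ROI series: y = X beta + drift + AR(1) noise.

    ``betas`` is either a dense vector over all design columns or a
    {column name: effect size} mapping (unnamed columns get zero).  The row
    count of ``X`` must equal the usable volume count.
    """
    if isinstance(X, _glm.DesignMatrix):
        frame = X.frame
        Xm = frame.to_numpy(dtype=float)
        if isinstance(betas, dict):
            b = np.zeros(Xm.shape[1])
            for name, w in betas.items():
                b[frame.columns.get_loc(name)] = w
        else:
            b = np.asarray(betas, dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if isinstance(betas, dict):
            raise TypeError("named betas require a DesignMatrix")
        b = np.asarray(betas, dtype=float)
    if Xm.shape[1] != len(b):
        raise ValueError(f"betas length {len(b)} != design columns {Xm.shape[1]}")
    if Xm.shape[0] != cfg.usable_volumes:
        raise ValueError(
            f"design rows {Xm.shape[0]} != usable volumes {cfg.usable_volumes}"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = Xm.shape[0]
    y = Xm @ b
    y = y + _drift(n, cfg.tr, cfg.drift_amplitude, rng)
    if cfg.noise_sd > 0:
        y = y + ar1_noise(n, cfg.ar1_rho, cfg.noise_sd, rng)
    return y


def simulate_coupled_rois(
    model: DCMModel,
    inputs: DCMInputs,
    params: DCMParams,
    cfg: BoldSimConfig = BoldSimConfig(),
    seed: Optional[int] = None,
    hrf: Optional[_glm.HRFSpec] = None,
) -> pd.DataFrame:
    """Multi-ROI BOLD from coupled bilinear neural dynamics.

    Integrates the DCM state equation on the microtime grid, convolves each
    region's state with the canonical HRF, samples at the TR, and adds
    independent AR(1) noise per region.  Columns follow the DCM region
    order (prep, mpfc, tpj).
    """
    from .connectivity import REGIONS

    hrf = hrf if hrf is not None else _glm.HRFSpec(dt=inputs.dt)
    n_vol = cfg.usable_volumes
    states = simulate_dcm(model, inputs, params)
    bold = states_to_bold(states, n_vol, cfg.tr, hrf)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if cfg.noise_sd > 0:
        bold = bold + ar1_noise(n_vol, cfg.ar1_rho, cfg.noise_sd, rng, n_cols=bold.shape[1])
    return pd.DataFrame(bold, columns=list(REGIONS))


def noise_sd_for_snr(bold: np.ndarray, snr: float, rho: float) -> float:
    """AR(1) innovation sd giving marginal noise sd = signal sd / snr.

    Signal sd is the mean per-region standard deviation of the noiseless
    BOLD; the innovation sd is scaled by sqrt(1 - rho^2) so the stationary
    AR(1) marginal variance matches the requested signal-to-noise ratio.
    """
    sig_sd = float(np.asarray(bold, dtype=float).std(axis=0).mean())
    return sig_sd / snr * np.sqrt(1.0 - rho**2)


@dataclass(frozen=True)
class CouplingStudy:
    """A generative connectivity experiment: model, inputs and true parameters.

    ``psych`` is the signed intention-type contrast on the microtime grid
    (+1 during inference events of one condition, -1 in the other, 0
    elsewhere) — the psychological series the PPI analysis uses.
    """

    model: DCMModel
    inputs: DCMInputs
    params: DCMParams
    psych: np.ndarray


#: f2_* model ids by backward-modulator set (family 2: prep<->mPFC and
#: mPFC<->TPJ bilateral, no prep<->TPJ)
_BACKWARD_MODEL_IDS = {
    ("INT",): "f2_m5",
    ("PE",): "f2_m6",
    ("INT", "PE"): "f2_m7",
    ("INT", "PE", "PExINT"): "f2_m8",
}


def coupling_study(
    n_volumes: int = 120,
    tr: float = 2.5,
    dt: float = 0.1,
    seed: int = 0,
    modulators: tuple[str, ...] = ("INT", "PE"),
    b_backward: float = 1.0,
    b_prep_int: float = 0.3,
    block_s: float = 25.0,
    event_interval_s: float = 7.0,
) -> CouplingStudy:
    """Generative study for the connectivity analyses.

    The paradigm alternates the two intention-type conditions in
    ``block_s``-second blocks; trials recur every ``event_interval_s`` s,
    each with a 1.2 s preparation event and a 2 s inference event.  The
    intention-type modulator INT is the +/-1 condition sign gated to
    inference events; the prior modulator PE varies uniformly in [-1, 1]
    over inference events (a mean-centered prior trace).  The generating
    model lives in family 2 (prep<->mPFC and mPFC<->TPJ bilateral): the
    ``modulators`` act on the backward mPFC->TPJ connection with strength
    ``b_backward`` each, and INT additionally gates the forward prep->mPFC
    connection with strength ``b_prep_int``.  Driving inputs enter at prep
    (preparation events) and TPJ (inference events).
    """
    from .connectivity import enumerate_models

    key = tuple(m for m in ("INT", "PE", "PExINT") if m in modulators)
    if key not in _BACKWARD_MODEL_IDS:
        raise ValueError(f"unsupported modulator set {modulators}")
    model = next(
        m for m in enumerate_models() if m.id == _BACKWARD_MODEL_IDS[key]
    )
    rng = np.random.default_rng(seed)
    n_micro = int(np.round(n_volumes * tr / dt))
    tgrid = np.arange(n_micro) * dt
    condition = np.where(((tgrid // block_s).astype(int) % 2) == 0, 1.0, -1.0)
    u_prep = np.zeros(n_micro)
    u_inf = np.zeros(n_micro)
    for t_on in np.arange(3.0, n_volumes * tr - 15.0, event_interval_s):
        i = int(round(t_on / dt))
        u_prep[i : i + int(round(1.2 / dt))] = 1.0
        j = i + int(round(1.5 / dt))
        u_inf[j : j + int(round(2.0 / dt))] = 1.0
    u_int = u_inf * condition
    u_pe = u_inf * rng.uniform(-1.0, 1.0, size=n_micro)
    inputs = DCMInputs(
        u_drive=np.column_stack([u_prep, u_inf]),
        u_mod=np.column_stack([u_int, u_pe, u_int * u_pe]),
        mod_names=("INT", "PE", "PExINT"),
        dt=dt,
    )
    A = np.array(
        [[-1.0, 0.2, 0.0], [0.4, -1.0, 0.3], [0.0, 0.4, -1.0]]
    )
    B = {name: np.zeros((3, 3)) for name in ("INT", "PE", "PExINT")}
    B["INT"][1, 0] = b_prep_int  # INT gates the forward prep->mPFC connection
    for name in key:
        B[name][2, 1] = b_backward  # modulation of backward mPFC->TPJ
    C = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
    params = DCMParams(A=A, B=B, C=C)
    return CouplingStudy(model=model, inputs=inputs, params=params, psych=u_int)
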