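"""ROI-level parametric GLM: canonical HRF, design matrix, OLS fits.

The design matrix mirrors the study's subject-level model (two task
conditions per experiment): per condition a *preparation* boxcar (resting
hand / first actor's move), an *inference* boxcar spanning movement onset to
the response screen, a *control*-trial boxcar and a motor stick function — 8
categorical regressors — plus 8 parametric modulators: the observer prior on
the preparation regressor, and evidence (coded 1-4), prior, and their
interaction on the inference regressor.  Modulator amplitudes are
mean-centered, everything is convolved with a canonical double-gamma HRF on
a microtime grid and sampled at the TR, and the inference modulators are
hierarchically orthogonalized in the fixed order evidence -> prior ->
evidence-by-prior, so shared variance is credited to the earlier regressor.
Low-frequency drift is absorbed by a 128 s high-pass DCT basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HRFSpec",
    "DesignMatrix",
    "GLMFit",
    "canonical_hrf",
    "serial_orthogonalize",
    "build_design_matrix",
    "dct_highpass_basis",
    "motion_expansion",
    "fit_glm",
]


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma canonical HRF parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    dt: float = 0.1
    length: float = 32.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.length <= self.undershoot_delay:
            raise ValueError("kernel length must cover the undershoot")


def canonical_hrf(spec: HRFSpec = HRFSpec()) -> np.ndarray:
    """Difference-of-gammas kernel sampled at ``spec.dt``, peak-normalized.

    Peak gamma has shape ``peak_delay/peak_dispersion`` and scale
    ``peak_dispersion`` (mode near 5 s with the defaults); the undershoot
    gamma is subtracted at ``undershoot_ratio``.
    """
    t = np.arange(0.0, spec.length + spec.dt / 2, spec.dt)
    peak = stats.gamma.pdf(
        t, spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion
    )
    under = stats.gamma.pdf(
        t,
        spec.undershoot_delay / spec.undershoot_dispersion,
        scale=spec.undershoot_dispersion,
    )
    h = peak - spec.undershoot_ratio * under
    return h / np.max(h)


def serial_orthogonalize(columns: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Successively residualize each column against all earlier ones.

    Column k is replaced by its residual after projection onto columns
    1..k-1 (already-orthogonalized versions); the first column is returned
    unchanged.  Zero-norm earlier columns are skipped with a warning.
    """
    if len(columns) == 0:
        raise ValueError("need at least one column")
    out: list[np.ndarray] = []
    n = len(columns[0])
    for col in columns:
        col = np.asarray(col, dtype=float).copy()
        if len(col) != n:
            raise ValueError("columns must have equal length")
        for prev in out:
            nrm = prev @ prev
            if nrm <= 1e-300:
                warnings.warn("skipping zero-norm column in orthogonalization")
                continue
            col -= (prev @ col) / nrm * prev
        out.append(col)
    return out


def dct_highpass_basis(n_volumes: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis for a high-pass filter at ``cutoff_s``.

    Returns the non-constant DCT-II basis functions with period longer than
    ``cutoff_s`` (the convention used by SPM-style 128 s filters).
    """
    order = int(np.floor(2.0 * n_volumes * tr / cutoff_s))
    t = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * t + 1) * k / (2.0 * n_volumes))
        for k in range(1, max(order, 0) + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


def motion_expansion(motion: np.ndarray) -> np.ndarray:
    """Second-degree polynomial expansion of motion parameters: [m, m^2]."""
    m = np.asarray(motion, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    return np.column_stack([m, m**2])


@dataclass(frozen=True)
class DesignMatrix:
    """Named regressor matrix plus its construction record."""

    frame: pd.DataFrame  # volumes x regressors
    task_columns: tuple[str, ...]
    orthogonalization: dict[str, tuple[str, ...]] = field(default_factory=dict)
    tr: float = 2.5
    highpass_s: Optional[float] = 128.0

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def n_volumes(self) -> int:
        return len(self.frame)

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        """Dense contrast vector from a {column name: weight} mapping."""
        c = np.zeros(self.frame.shape[1])
        for name, w in weights.items():
            c[self.frame.columns.get_loc(name)] = w
        return c


def _microtime_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    n_micro: int,
    dt: float,
) -> np.ndarray:
    """Amplitude-weighted boxcars (sticks when duration is 0) at microtime."""
    x = np.zeros(n_micro)
    for on, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(np.round(on / dt))
        i1 = max(int(np.round((on + dur) / dt)), i0 + 1)
        if i0 >= n_micro:
            continue
        x[i0 : min(i1, n_micro)] += amp
    return x


def build_design_matrix(
    events: pd.DataFrame,
    modulators: pd.DataFrame,
    hrf: HRFSpec = HRFSpec(),
    tr: float = 2.5,
    n_volumes: int = 285,
    highpass_s: Optional[float] = 128.0,
    nuisance: Optional[np.ndarray] = None,
    condition_col: str = "condition",
) -> DesignMatrix:
    """Assemble the condition-wise categorical + parametric design matrix.

    ``events`` is a long event table (:func:`intentprior.task_design.events_frame`
    or :func:`~intentprior.task_design.assemble_session` output) with columns
    ``onset, duration, trial_type, trial_index, phase`` and a condition
    column; ``modulators`` has one row per non-control trial with columns
    ``trial_index, evidence, prior`` (plus the condition column when several
    conditions are present).  An ``interaction`` column is the product of the
    mean-centered evidence and prior modulators unless supplied explicitly.

    All events must end before the scan does; missing modulator rows raise.
    """
    dt = hrf.dt
    n_micro = int(np.round(n_volumes * tr / dt))
    kernel = canonical_hrf(hrf)
    scan_end = n_volumes * tr

    ev = events.copy()
    if condition_col not in ev.columns:
        ev[condition_col] = "task"
    late = ev[ev["onset"] + ev["duration"] > scan_end + 1e-9]
    if len(late):
        bad = sorted(late["trial_index"].unique().tolist())
        raise ValueError(
            f"events beyond scan end ({scan_end:g} s): trials {bad}"
        )

    mod = modulators.copy()
    if condition_col not in mod.columns:
        mod[condition_col] = "task"

    def convolve_and_sample(x_micro: np.ndarray) -> np.ndarray:
        conv = np.convolve(x_micro, kernel)[:n_micro]
        vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
        return conv[np.clip(vol_idx, 0, n_micro - 1)]

    columns: dict[str, np.ndarray] = {}
    ortho_record: dict[str, tuple[str, ...]] = {}
    task_cols: list[str] = []

    conditions = list(pd.unique(ev.loc[ev["phase"] != "control", condition_col]))
    for cond in conditions:
        sub = ev[ev[condition_col] == cond]
        task = sub[sub["phase"] != "control"]
        ctrl = sub[sub["phase"] == "control"]
        m = mod[mod[condition_col] == cond].set_index("trial_index")

        trials = task[task["trial_type"] == "action"].sort_values("trial_index")
        missing = [i for i in trials["trial_index"] if i not in m.index]
        if missing:
            raise ValueError(f"missing modulators for trials {missing} ({cond})")
        m = m.loc[trials["trial_index"]]
        evid = m["evidence"].to_numpy(dtype=float)
        prior = m["prior"].to_numpy(dtype=float)
        evid_c = evid - evid.mean()
        prior_c = prior - prior.mean()
        if "interaction" in m.columns:
            inter_c = m["interaction"].to_numpy(dtype=float)
            inter_c = inter_c - inter_c.mean()
        else:
            inter_c = evid_c * prior_c
            inter_c = inter_c - inter_c.mean()

        prep = task[task["trial_type"] == "preparation"].sort_values("trial_index")
        resp = task[task["trial_type"] == "response"].sort_values("trial_index")
        delay = task[task["trial_type"] == "delay"].sort_values("trial_index")

        # inference interval: movement onset to response-screen onset
        infer_on = trials["onset"].to_numpy()
        infer_dur = (
            resp["onset"].to_numpy() - infer_on
            if len(resp) == len(trials)
            else trials["duration"].to_numpy() + delay["duration"].to_numpy()
        )
        prep_on = prep["onset"].to_numpy()
        prep_dur = prep["duration"].to_numpy()
        ones_t = np.ones(len(trials))

        def reg(on, dur, amp):
            return convolve_and_sample(
                _microtime_regressor(np.asarray(on), np.asarray(dur), np.asarray(amp), n_micro, dt)
            )

        columns[f"prep_{cond}"] = reg(prep_on, prep_dur, ones_t)
        columns[f"infer_{cond}"] = reg(infer_on, infer_dur, ones_t)
        if len(ctrl):
            c_first = ctrl[ctrl["trial_type"] == "preparation"].sort_values("trial_index")
            c_resp = ctrl[ctrl["trial_type"] == "response"].sort_values("trial_index")
            c_on = c_first["onset"].to_numpy()
            c_dur = c_resp["onset"].to_numpy() + c_resp["duration"].to_numpy() - c_on
            columns[f"control_{cond}"] = reg(c_on, c_dur, np.ones(len(c_first)))
        else:
            columns[f"control_{cond}"] = np.zeros(n_volumes)
        motor_on = resp["onset"].to_numpy()
        columns[f"motor_{cond}"] = reg(motor_on, np.zeros(len(motor_on)), ones_t)

        # parametric modulators: prior on preparation; evidence, prior,
        # interaction on inference, serially orthogonalized in that order
        columns[f"prep_{cond}_x_prior"] = reg(prep_on, prep_dur, prior_c)
        raw = {
            f"infer_{cond}_x_evidence": reg(infer_on, infer_dur, evid_c),
            f"infer_{cond}_x_prior": reg(infer_on, infer_dur, prior_c),
            f"infer_{cond}_x_evidence_x_prior": reg(infer_on, infer_dur, inter_c),
        }
        names = list(raw)
        const = np.ones(n_volumes)
        stack = [const, columns[f"infer_{cond}"]] + [raw[n] for n in names]
        ortho = serial_orthogonalize(stack)
        for k, name in enumerate(names):
            columns[name] = ortho[2 + k]
            ortho_record[name] = tuple(["constant", f"infer_{cond}"] + names[:k])
        task_cols += [
            f"prep_{cond}",
            f"infer_{cond}",
            f"control_{cond}",
            f"motor_{cond}",
            f"prep_{cond}_x_prior",
        ] + names

    frame = pd.DataFrame(columns)
    frame = frame[task_cols]  # stable order: per condition, categorical then parametric
    if nuisance is not None:
        nuis = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuis.shape[0] != n_volumes:
            nuis = nuis.T
        if nuis.shape[0] != n_volumes:
            raise ValueError("nuisance rows must match n_volumes")
        for j in range(nuis.shape[1]):
            frame[f"nuisance_{j}"] = nuis[:, j]
    if highpass_s is not None:
        dct = dct_highpass_basis(n_volumes, tr, highpass_s)
        for j in range(dct.shape[1]):
            frame[f"dct_{j + 1}"] = dct[:, j]
    frame["constant"] = 1.0
    return DesignMatrix(
        frame=frame,
        task_columns=tuple(task_cols),
        orthogonalization=ortho_record,
        tr=tr,
        highpass_s=highpass_s,
    )


@dataclass(frozen=True)
class GLMFit:
    """OLS estimates for one ROI time series."""

    betas: pd.Series
    sigma2: float
    df: int
    t_stats: np.ndarray
    contrast_estimates: np.ndarray
    contrast_ses: np.ndarray
    residuals: np.ndarray
    ar1_rho: Optional[float] = None

    def p_values(self) -> np.ndarray:
        return 2.0 * stats.t.sf(np.abs(self.t_stats), self.df)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        warnings.warn("rank-deficient design; using minimum-norm solution")
        pinv = np.linalg.pinv(X)
        beta = pinv @ y
        xtx_inv = pinv @ pinv.T
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        xtx_inv = np.linalg.inv(X.T @ X)
    return beta, xtx_inv, rank


def fit_glm(
    y: np.ndarray,
    X: DesignMatrix | pd.DataFrame | np.ndarray,
    contrasts: Optional[Sequence[np.ndarray]] = None,
    prewhiten: bool = False,
) -> GLMFit:
    """OLS fit with per-contrast t statistics.

    ``contrasts`` are dense weight vectors over the design columns.  With
    ``prewhiten=True`` a single Cochrane-Orcutt pass estimates the lag-1
    residual autocorrelation and refits on the quasi-differenced data.
    """
    if isinstance(X, DesignMatrix):
        frame = X.frame
    elif isinstance(X, pd.DataFrame):
        frame = X
    else:
        arr = np.asarray(X, dtype=float)
        frame = pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])
    Xm = frame.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) != Xm.shape[0]:
        raise ValueError("y length must match design rows")

    beta, xtx_inv, rank = _ols(Xm, y)
    resid = y - Xm @ beta
    rho = None
    if prewhiten:
        num = resid[1:] @ resid[:-1]
        den = resid @ resid
        rho = float(num / den) if den > 0 else 0.0
        ys = y[1:] - rho * y[:-1]
        Xs = Xm[1:] - rho * Xm[:-1]
        beta, xtx_inv, rank = _ols(Xs, ys)
        resid = ys - Xs @ beta
        n_eff = len(ys)
    else:
        n_eff = len(y)
    df = n_eff - rank
    sigma2 = float(resid @ resid / df) if df > 0 else np.nan

    ts, est, ses = [], [], []
    for c in contrasts or []:
        c = np.asarray(c, dtype=float)
        var = sigma2 * (c @ xtx_inv @ c)
        se = np.sqrt(var) if var > 0 else np.nan
        e = float(c @ beta)
        est.append(e)
        ses.append(se)
        ts.append(e / se if se and np.isfinite(se) and se > 0 else np.nan)
    return GLMFit(
        betas=pd.Series(beta, index=frame.columns),
        sigma2=sigma2,
        df=df,
        t_stats=np.array(ts),
        contrast_estimates=np.array(est),
        contrast_ses=np.array(ses),
        residuals=resid,
        ar1_rho=rho,
    )
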