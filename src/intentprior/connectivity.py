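"""Condition-dependent connectivity: PPI regressors and a bilinear DCM space.

Two complementary analyses of the same question — does the coupling between
the medial prefrontal cortex (mPFC) and the temporo-parietal junction (TPJ)
change with the type of intention being inferred?

*PPI.*  A seed BOLD series is deconvolved with the canonical HRF (ridge-
regularized least squares on the microtime grid), multiplied by a signed
psychological contrast (+1 in one condition, -1 in the other), and
reconvolved.  In a regression of a target region on [seed, psychological
term, PPI term] the PPI coefficient is half the difference between the two
condition-specific regression slopes.

*DCM.*  Bilinear neural dynamics over three regions — a preparatory area
(SMA/dACC), mPFC, and TPJ:

    dz/dt = (A + sum_j u_j B_j) z + C u

with modulators INT (intention type), PE (observer priors) and PE*INT.  The
model space is 5 anatomically nested families (full bilateral connectivity
down to a lone prep->mPFC forward connection) x 8 modulatory configurations
= 40 models.  Model evidence is approximated by -BIC/2 from a nonlinear
least-squares fit of the HRF-convolved simulated states, and models and
families are compared with random-effects Bayesian model selection
(variational Dirichlet posterior over model frequencies; exceedance
probabilities by Monte-Carlo sampling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, special

from .glm import HRFSpec, canonical_hrf

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


__all__ = [
    "PPIResult",
    "DCMFamily",
    "DCMModel",
    "DCMParams",
    "DCMInputs",
    "DCMFitResult",
    "BMSResult",
    "REGIONS",
    "MODULATORS",
    "extract_first_pc",
    "deconvolve_hrf",
    "build_ppi_regressor",
    "estimate_ppi",
    "enumerate_families",
    "enumerate_models",
    "simulate_dcm",
    "fit_dcm_bic",
    "bms_exceedance",
]

REGIONS = ("prep", "mpfc", "tpj")
MODULATORS = ("INT", "PE", "PExINT")


# ---------------------------------------------------------------------------
# PPI
# ---------------------------------------------------------------------------


def extract_first_pc(series: np.ndarray) -> np.ndarray:
    """First principal-component score series of a time x units matrix.

    The matrix is column-centered; the sign is fixed so the component
    correlates positively with the mean of the columns (SVD leaves the sign
    arbitrary).
    """
    X = np.asarray(series, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix: first PC undefined")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    pc = U[:, 0] * s[0]
    ref = Xc.mean(axis=1)
    if pc @ ref < 0:
        pc = -pc
    return pc


_conv_cache: dict = {}


def _conv_operator(
    n_volumes: int, tr: float, hrf: HRFSpec, ridge_lambda: float
) -> tuple[np.ndarray, tuple]:
    """Convolution matrix K (volumes x microtime) and a cached Cholesky
    factorization of (K K' + lambda I) for its ridge inverse."""
    kernel = canonical_hrf(hrf)
    key = (n_volumes, round(tr, 9), round(hrf.dt, 9), len(kernel), float(ridge_lambda))
    if key in _conv_cache:
        return _conv_cache[key]
    dt = hrf.dt
    n_micro = int(np.round(n_volumes * tr / dt))
    vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    K = np.zeros((n_volumes, n_micro))
    for v, iv in enumerate(vol_idx):
        j0 = max(iv - len(kernel) + 1, 0)
        K[v, j0 : iv + 1] = kernel[iv - j0 :: -1]
    G = K @ K.T + ridge_lambda * np.eye(n_volumes)
    cho = sla.cho_factor(G)
    _conv_cache[key] = (K, cho)
    return K, cho


def deconvolve_hrf(
    y: np.ndarray,
    hrf: HRFSpec = HRFSpec(),
    ridge_lambda: float = 1e-2,
    tr: float = 2.5,
) -> np.ndarray:
    """Ridge-regularized deconvolution of a BOLD series to the microtime grid.

    Solves min_x ||K x - y||^2 + lambda ||x||^2 where K maps a neural series
    on the microtime grid (spacing ``hrf.dt``) to BOLD samples at the TR;
    the solution K'(KK' + lambda I)^(-1) y equals the primal ridge solution
    but only requires a volumes-sized solve.
    """
    if ridge_lambda < 0:
        raise ValueError(f"ridge_lambda must be >= 0, got {ridge_lambda}")
    y = np.asarray(y, dtype=float)
    K, cho = _conv_operator(len(y), tr, hrf, ridge_lambda)
    return K.T @ sla.cho_solve(cho, y)


def _reconvolve(x_micro: np.ndarray, n_volumes: int, tr: float, hrf: HRFSpec) -> np.ndarray:
    kernel = canonical_hrf(hrf)
    dt = hrf.dt
    n_micro = int(np.round(n_volumes * tr / dt))
    conv = np.convolve(x_micro, kernel)[:n_micro]
    vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return conv[np.clip(vol_idx, 0, n_micro - 1)]


def _psych_to_microtime(psych: np.ndarray, n_micro: int) -> np.ndarray:
    psych = np.asarray(psych, dtype=float)
    if len(psych) == n_micro:
        return psych
    # upsample a TR-resolution contrast by sample-and-hold
    reps = int(np.round(n_micro / len(psych)))
    out = np.repeat(psych, reps)
    if len(out) < n_micro:
        out = np.concatenate([out, np.full(n_micro - len(out), psych[-1])])
    return out[:n_micro]


def build_ppi_regressor(
    physio: np.ndarray,
    psych: np.ndarray,
    hrf: HRFSpec = HRFSpec(),
    tr: float = 2.5,
    ridge_lambda: float = 1e-2,
) -> np.ndarray:
    """Deconvolve-multiply-reconvolve PPI regressor at TR resolution.

    ``physio`` is the seed BOLD series (one value per volume); ``psych`` the
    signed psychological contrast (+1/-1/0), given either on the microtime
    grid or per volume (then upsampled by sample-and-hold).  The returned
    regressor is mean-centered.
    """
    physio = np.asarray(physio, dtype=float)
    n_vol = len(physio)
    n_micro = int(np.round(n_vol * tr / hrf.dt))
    psych_m = _psych_to_microtime(psych, n_micro)
    if np.allclose(psych_m, 0):
        raise ValueError("psychological contrast is all zero")
    neural = deconvolve_hrf(physio, hrf, ridge_lambda, tr)
    ppi = _reconvolve(neural * psych_m, n_vol, tr, hrf)
    return ppi - ppi.mean()


@dataclass(frozen=True)
class PPIResult:
    """Condition-specific coupling slopes and their difference."""

    slopes: dict[str, float]  # per condition (+1 / -1 coded)
    interaction: float  # slope(+1) - slope(-1), i.e. 2 * b_ppi
    t: float
    p: float
    df: int
    coefficients: pd.Series
    ppi_regressor: np.ndarray


def estimate_ppi(
    target: np.ndarray,
    seed_series: np.ndarray,
    psych: np.ndarray,
    hrf: HRFSpec = HRFSpec(),
    tr: float = 2.5,
    ridge_lambda: float = 1e-2,
    nuisance: Optional[np.ndarray] = None,
    condition_names: tuple[str, str] = ("cond_pos", "cond_neg"),
    prewhiten: bool = True,
) -> PPIResult:
    """Joint PPI regression of a target region on a seed region.

    Fits target ~ const + seed + psych + PPI (+ nuisance).  With +1/-1
    psychological coding the condition-specific slopes are
    b_seed + b_ppi and b_seed - b_ppi, and their difference (2 b_ppi) is the
    psychophysiological interaction, reported with its t statistic.
    ``prewhiten`` applies a Cochrane-Orcutt AR(1) correction so the t test
    stays calibrated under temporally autocorrelated noise.
    """
    from .glm import fit_glm  # local import to avoid cycle at module load

    target = np.asarray(target, dtype=float)
    n_vol = len(target)
    ppi = build_ppi_regressor(seed_series, psych, hrf, tr, ridge_lambda)
    n_micro = int(np.round(n_vol * tr / hrf.dt))
    psych_m = _psych_to_microtime(psych, n_micro)
    psych_conv = _reconvolve(psych_m, n_vol, tr, hrf)
    cols = {
        "constant": np.ones(n_vol),
        "seed": np.asarray(seed_series, dtype=float),
        "psych": psych_conv - psych_conv.mean(),
        "ppi": ppi,
    }
    frame = pd.DataFrame(cols)
    if nuisance is not None:
        nuis = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuis.shape[0] != n_vol:
            nuis = nuis.T
        for j in range(nuis.shape[1]):
            frame[f"nuisance_{j}"] = nuis[:, j]
    c = np.zeros(frame.shape[1])
    c[frame.columns.get_loc("ppi")] = 1.0
    fit = fit_glm(target, frame, contrasts=[c], prewhiten=prewhiten)
    b_seed = float(fit.betas["seed"])
    b_ppi = float(fit.betas["ppi"])
    t = float(fit.t_stats[0])
    p = float(fit.p_values()[0])
    return PPIResult(
        slopes={condition_names[0]: b_seed + b_ppi, condition_names[1]: b_seed - b_ppi},
        interaction=2.0 * b_ppi,
        t=t,
        p=p,
        df=fit.df,
        coefficients=fit.betas,
        ppi_regressor=ppi,
    )


# ---------------------------------------------------------------------------
# DCM model space
# ---------------------------------------------------------------------------


def _mask_from_edges(edges: Sequence[tuple[str, str]]) -> np.ndarray:
    m = np.zeros((3, 3), dtype=bool)
    for src, dst in edges:
        m[REGIONS.index(dst), REGIONS.index(src)] = True
    return m


@dataclass(frozen=True)
class DCMFamily:
    """A set of intrinsic (A-matrix) connections shared by 8 models."""

    id: int
    name: str
    edges: tuple[tuple[str, str], ...]

    @property
    def a_mask(self) -> np.ndarray:
        return _mask_from_edges(self.edges)


#: nested family progression: full bilateral connectivity down to a single
#: prep->mPFC forward connection (edge lists are (source, destination))
_FAMILY_TABLE: tuple[tuple[str, tuple[tuple[str, str], ...]], ...] = (
    (
        "full bilateral (prep<->mPFC, mPFC<->TPJ, prep<->TPJ)",
        (
            ("prep", "mpfc"),
            ("mpfc", "prep"),
            ("mpfc", "tpj"),
            ("tpj", "mpfc"),
            ("prep", "tpj"),
            ("tpj", "prep"),
        ),
    ),
    (
        "no prep<->TPJ (prep<->mPFC, mPFC<->TPJ)",
        (("prep", "mpfc"), ("mpfc", "prep"), ("mpfc", "tpj"), ("tpj", "mpfc")),
    ),
    (
        "prep<->mPFC bilateral, mPFC->TPJ forward",
        (("prep", "mpfc"), ("mpfc", "prep"), ("mpfc", "tpj")),
    ),
    (
        "prep->mPFC forward, mPFC<->TPJ bilateral",
        (("prep", "mpfc"), ("mpfc", "tpj"), ("tpj", "mpfc")),
    ),
    ("prep->mPFC only", (("prep", "mpfc"),)),
)


def enumerate_families(
    table: Optional[Sequence[tuple[str, Sequence[tuple[str, str]]]]] = None,
) -> list[DCMFamily]:
    """The anatomical family progression (5 families by default).

    Connections are progressively removed from the fully connected network
    (family 1) down to a minimal network with only the prep->mPFC forward
    connection (family 5).  A custom table may be substituted.
    """
    table = table if table is not None else _FAMILY_TABLE
    return [
        DCMFamily(id=k + 1, name=name, edges=tuple((s, d) for s, d in edges))
        for k, (name, edges) in enumerate(table)
    ]


@dataclass(frozen=True)
class DCMModel:
    """One bilinear DCM: intrinsic mask + per-modulator B masks + C mask."""

    id: str
    family_id: int
    a_mask_flat: tuple[bool, ...]  # row-major 3x3
    b_masks_flat: tuple[tuple[str, tuple[bool, ...]], ...]
    c_mask_flat: tuple[bool, ...]  # 3 x n_inputs row-major
    n_inputs: int = 2
    description: str = ""

    @property
    def a_mask(self) -> np.ndarray:
        return np.array(self.a_mask_flat, dtype=bool).reshape(3, 3)

    @property
    def b_masks(self) -> dict[str, np.ndarray]:
        return {
            name: np.array(flat, dtype=bool).reshape(3, 3)
            for name, flat in self.b_masks_flat
        }

    @property
    def c_mask(self) -> np.ndarray:
        return np.array(self.c_mask_flat, dtype=bool).reshape(3, self.n_inputs)

    @property
    def n_free_parameters(self) -> int:
        nb = sum(int(np.sum(m)) for m in self.b_masks.values())
        return int(np.sum(self.a_mask)) + nb + int(np.sum(self.c_mask))


#: the 8 modulatory configurations applied within every family:
#: (mPFC-TPJ connection carrying the modulation, modulator set).
#: "forward" is the bottom-up TPJ->mPFC connection, "backward" the top-down
#: mPFC->TPJ connection (mPFC sits above TPJ in the inference hierarchy).
_MODEL_GRID: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("forward", ("INT",)),
    ("forward", ("PE",)),
    ("forward", ("INT", "PE")),
    ("forward", ("INT", "PE", "PExINT")),
    ("backward", ("INT",)),
    ("backward", ("PE",)),
    ("backward", ("INT", "PE")),
    ("backward", ("INT", "PE", "PExINT")),
)

#: driving-input entry points, identical in every model: the preparation
#: input enters the preparatory region, the inference (stimulus) input
#: enters TPJ
_C_MASK_DEFAULT = np.array([[True, False], [False, False], [False, True]])


def enumerate_models(families: Optional[Sequence[DCMFamily]] = None) -> list[DCMModel]:
    """The 5 x 8 = 40 model space with stable, reproducible ids.

    Within each family the 8 models cross the modulated mPFC-TPJ connection
    (forward mPFC->TPJ vs. backward TPJ->mPFC) with the modulator set (INT;
    PE; INT+PE; INT+PE+PE*INT); in every model INT additionally modulates
    the prep->mPFC forward connection.  B entries are masked by the family's
    A mask, so a modulation of a connection a family lacks is dropped.
    """
    families = families if families is not None else enumerate_families()
    models: list[DCMModel] = []
    for fam in families:
        a = fam.a_mask
        for m_idx, (direction, mods) in enumerate(_MODEL_GRID, start=1):
            edge = ("tpj", "mpfc") if direction == "forward" else ("mpfc", "tpj")
            b_masks: dict[str, np.ndarray] = {
                name: np.zeros((3, 3), dtype=bool) for name in MODULATORS
            }
            b_masks["INT"][REGIONS.index("mpfc"), REGIONS.index("prep")] = True
            for name in mods:
                b_masks[name][REGIONS.index(edge[1]), REGIONS.index(edge[0])] = True
            for name in MODULATORS:
                b_masks[name] &= a  # B only where an intrinsic connection exists
            models.append(
                DCMModel(
                    id=f"f{fam.id}_m{m_idx}",
                    family_id=fam.id,
                    a_mask_flat=tuple(a.ravel().tolist()),
                    b_masks_flat=tuple(
                        (name, tuple(b_masks[name].ravel().tolist()))
                        for name in MODULATORS
                        if b_masks[name].any()
                    ),
                    c_mask_flat=tuple(_C_MASK_DEFAULT.ravel().tolist()),
                    description=f"{direction} mPFC-TPJ modulation by {'+'.join(mods)}",
                )
            )
    return models


# ---------------------------------------------------------------------------
# DCM forward model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DCMParams:
    """Actual connection strengths (Hz): A with negative self-decay on the
    diagonal, per-modulator B matrices, input weights C."""

    A: np.ndarray
    B: dict[str, np.ndarray] = field(default_factory=dict)
    C: np.ndarray = field(default_factory=lambda: np.zeros((3, 2)))


@dataclass(frozen=True)
class DCMInputs:
    """Microtime input time courses: driving inputs and bilinear modulators."""

    u_drive: np.ndarray  # steps x n_inputs
    u_mod: np.ndarray  # steps x n_modulators
    mod_names: tuple[str, ...] = ()
    dt: float = 0.1

    @property
    def n_steps(self) -> int:
        return self.u_drive.shape[0]


@njit(cache=False)
def _rk4_loop(M: np.ndarray, Cu: np.ndarray, z0: np.ndarray, dt: float) -> np.ndarray:
    n_steps = M.shape[0]
    n = z0.shape[0]
    Z = np.empty((n_steps + 1, n))
    Z[0] = z0
    z = z0.copy()
    for t in range(n_steps):
        Mt = M[t]
        ct = Cu[t]
        k1 = Mt @ z + ct
        k2 = Mt @ (z + 0.5 * dt * k1) + ct
        k3 = Mt @ (z + 0.5 * dt * k2) + ct
        k4 = Mt @ (z + dt * k3) + ct
        z = z + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        Z[t + 1] = z
    return Z


def _rk4_loop_py(M, Cu, z0, dt):  # reference implementation (no JIT)
    n_steps = M.shape[0]
    Z = np.empty((n_steps + 1, z0.shape[0]))
    Z[0] = z0
    z = z0.copy()
    for t in range(n_steps):
        Mt, ct = M[t], Cu[t]
        k1 = Mt @ z + ct
        k2 = Mt @ (z + 0.5 * dt * k1) + ct
        k3 = Mt @ (z + 0.5 * dt * k2) + ct
        k4 = Mt @ (z + dt * k3) + ct
        z = z + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        Z[t + 1] = z
    return Z


class DCMInstabilityError(RuntimeError):
    """Raised when the neural dynamics diverge or A is unstable."""


def simulate_dcm(
    model: DCMModel,
    inputs: DCMInputs,
    params: DCMParams,
    dt: Optional[float] = None,
    z0: Optional[np.ndarray] = None,
    check_stability: bool = True,
    use_numba: bool = True,
) -> np.ndarray:
    """Integrate dz/dt = (A + sum_j u_j B_j) z + C u with fixed-step RK4.

    Inputs are piecewise-constant over each microtime step.  Masked-out
    entries of A (off-diagonal), B and C are forced to zero; the diagonal of
    A (self-decay) is always retained.  Returns states sampled at step
    boundaries, shape (n_steps, n_regions).
    """
    dt = inputs.dt if dt is None else dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = len(REGIONS)
    A = np.asarray(params.A, dtype=float).copy()
    off = ~np.eye(n, dtype=bool)
    A[off & ~model.a_mask] = 0.0
    if check_stability and np.any(np.real(np.linalg.eigvals(A)) >= 0):
        raise DCMInstabilityError(
            f"model {model.id}: intrinsic matrix A has a non-negative eigenvalue"
        )
    b_masks = model.b_masks
    B_list = []
    for j, name in enumerate(inputs.mod_names):
        Bj = np.asarray(params.B.get(name, np.zeros((n, n))), dtype=float).copy()
        Bj[~b_masks.get(name, np.zeros((n, n), dtype=bool))] = 0.0
        B_list.append(Bj)
    C = np.asarray(params.C, dtype=float).copy()
    C[~model.c_mask] = 0.0

    u_mod = np.asarray(inputs.u_mod, dtype=float)
    u_drive = np.asarray(inputs.u_drive, dtype=float)
    n_steps = inputs.n_steps
    M = np.broadcast_to(A, (n_steps, n, n)).copy()
    for j, Bj in enumerate(B_list):
        if np.any(Bj):
            M += u_mod[:, j, None, None] * Bj
    Cu = u_drive @ C.T
    z0 = np.zeros(n) if z0 is None else np.asarray(z0, dtype=float)

    loop = _rk4_loop if (use_numba and _HAVE_NUMBA) else _rk4_loop_py
    Z = loop(np.ascontiguousarray(M), np.ascontiguousarray(Cu), z0, float(dt))
    if not np.all(np.isfinite(Z)) or np.max(np.abs(Z)) > 1e6:
        raise DCMInstabilityError(f"model {model.id}: state norm diverged")
    return Z[1:]


def states_to_bold(
    states: np.ndarray,
    n_volumes: int,
    tr: float,
    hrf: HRFSpec = HRFSpec(),
) -> np.ndarray:
    """Convolve each region's neural state with the HRF and sample at the TR."""
    out = np.empty((n_volumes, states.shape[1]))
    for r in range(states.shape[1]):
        out[:, r] = _reconvolve(states[:, r], n_volumes, tr, hrf)
    return out


# ---------------------------------------------------------------------------
# DCM estimation (BIC evidence)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DCMFitResult:
    model_id: str
    params: DCMParams
    rss: float
    n_free: int
    log_evidence: float  # -BIC/2
    converged: bool


def _pack_masks(model: DCMModel) -> tuple[np.ndarray, list[tuple[str, np.ndarray]], np.ndarray]:
    n = len(REGIONS)
    a_free = model.a_mask & ~np.eye(n, dtype=bool)
    b_free = [(name, mask) for name, mask in model.b_masks.items() if mask.any()]
    return a_free, b_free, model.c_mask


def fit_dcm_bic(
    data: np.ndarray,
    model: DCMModel,
    inputs: DCMInputs,
    tr: float = 2.5,
    hrf: HRFSpec = HRFSpec(),
    self_decay: float = -1.0,
    x0_scale: float = 0.1,
    max_nfev: int = 400,
) -> DCMFitResult:
    """Estimate free A/B/C entries by nonlinear least squares; score by BIC.

    ``data`` is the observed (volumes x regions) BOLD matrix, mean-centered
    per region before fitting.  Self-connections are fixed at ``self_decay``
    (Hz); the free parameters are the masked off-diagonal A entries, masked
    B entries and masked C entries.  The log evidence is approximated as
    -BIC/2 with Gaussian residuals: BIC = N log(RSS/N) + k log N.
    """
    data = np.asarray(data, dtype=float)
    n_vol = data.shape[0]
    data_c = data - data.mean(axis=0)
    n = len(REGIONS)
    a_free, b_free, c_mask = _pack_masks(model)
    n_a, n_c = int(a_free.sum()), int(c_mask.sum())
    n_b = sum(int(m.sum()) for _, m in b_free)
    k_free = n_a + n_b + n_c

    def unpack(x: np.ndarray) -> DCMParams:
        A = np.diag(np.full(n, self_decay))
        A[a_free] = x[:n_a]
        pos = n_a
        B = {}
        for name, mask in b_free:
            nm = int(mask.sum())
            Bn = np.zeros((n, n))
            Bn[mask] = x[pos : pos + nm]
            B[name] = Bn
            pos += nm
        C = np.zeros(c_mask.shape)
        C[c_mask] = x[pos : pos + n_c]
        return DCMParams(A=A, B=B, C=C)

    def residuals(x: np.ndarray) -> np.ndarray:
        params = unpack(x)
        try:
            Z = simulate_dcm(model, inputs, params, check_stability=False)
        except DCMInstabilityError:
            return np.full(data_c.size, 1e3)
        if not np.all(np.isfinite(Z)) or np.max(np.abs(Z)) > 1e6:
            return np.full(data_c.size, 1e3)
        pred = states_to_bold(Z, n_vol, tr, hrf)
        pred = pred - pred.mean(axis=0)
        return (pred - data_c).ravel()

    x0 = np.concatenate(
        [np.full(n_a, x0_scale), np.zeros(n_b), np.full(n_c, 0.5)]
    )
    sol = optimize.least_squares(residuals, x0, method="lm", max_nfev=max_nfev)
    rss = float(2.0 * sol.cost)
    N = data_c.size
    sigma2 = max(rss / N, 1e-300)
    bic = N * np.log(sigma2) + k_free * np.log(N)
    converged = bool(sol.success)
    log_ev = -0.5 * bic if converged else -np.inf
    if not converged:
        warnings.warn(f"model {model.id}: optimizer did not converge; evidence -inf")
    return DCMFitResult(
        model_id=model.id,
        params=unpack(sol.x),
        rss=rss,
        n_free=k_free,
        log_evidence=log_ev,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Random-effects Bayesian model selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BMSResult:
    """Dirichlet posterior over model frequencies and exceedance probabilities."""

    model_names: tuple[str, ...]
    alpha: np.ndarray  # posterior Dirichlet concentrations
    expected_p: np.ndarray
    exceedance_p: np.ndarray
    n_samples: int
    seed: int
    family_names: Optional[tuple[str, ...]] = None
    family_alpha: Optional[np.ndarray] = None
    family_expected_p: Optional[np.ndarray] = None
    family_exceedance_p: Optional[np.ndarray] = None


def _vb_dirichlet(log_evidence: np.ndarray, alpha0: float = 1.0, tol: float = 1e-8,
                  max_iter: int = 2000) -> np.ndarray:
    """Variational posterior concentrations of the random-effects model."""
    L = np.asarray(log_evidence, dtype=float)
    n_subj, k = L.shape
    alpha = np.full(k, alpha0)
    for _ in range(max_iter):
        logu = L + special.digamma(alpha) - special.digamma(alpha.sum())
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha


def _exceedance(alpha: np.ndarray, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    r = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(r, axis=1)
    return np.bincount(winners, minlength=len(alpha)) / n_samples


def bms_exceedance(
    log_evidence: np.ndarray,
    model_names: Optional[Sequence[str]] = None,
    grouping: Optional[Sequence[int]] = None,
    n_samples: int = 100_000,
    seed: int = 0,
    alpha0: float = 1.0,
) -> BMSResult:
    """Random-effects BMS with Monte-Carlo exceedance probabilities.

    ``log_evidence`` is subjects x models; -inf entries mark excluded fits
    (a model that failed for a subject simply gets zero posterior weight for
    that subject).  ``grouping`` optionally maps each model to a family id;
    family-level evidences aggregate member models under a uniform
    within-family prior (log-sum-exp minus log family size) and family
    exceedance probabilities are computed from a second Dirichlet posterior
    over families.
    """
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim == 1:
        L = L[None, :]
    if np.isnan(L).any() or np.isposinf(L).any():
        raise ValueError("log evidences must be finite or -inf")
    if np.any(np.all(np.isneginf(L), axis=1)):
        raise ValueError("a subject has -inf evidence for every model")
    n_subj, k = L.shape
    names = tuple(model_names) if model_names else tuple(f"m{j}" for j in range(k))
    if len(names) != k:
        raise ValueError("model_names length mismatch")
    rng = np.random.default_rng(seed)
    if k == 1:
        warnings.warn("single model: exceedance probability is trivially 1")
        return BMSResult(
            model_names=names,
            alpha=np.array([alpha0 + n_subj]),
            expected_p=np.array([1.0]),
            exceedance_p=np.array([1.0]),
            n_samples=n_samples,
            seed=seed,
        )
    alpha = _vb_dirichlet(L, alpha0=alpha0)
    ep = _exceedance(alpha, n_samples, rng)
    fam_names = fam_alpha = fam_exp = fam_ep = None
    if grouping is not None:
        grouping = np.asarray(list(grouping))
        if grouping.size != k:
            raise ValueError("grouping must assign a family to every model")
        fam_ids = sorted(set(grouping.tolist()))
        fam_L = np.empty((n_subj, len(fam_ids)))
        for j, f in enumerate(fam_ids):
            members = np.flatnonzero(grouping == f)
            fam_L[:, j] = special.logsumexp(L[:, members], axis=1) - np.log(len(members))
        fam_alpha = _vb_dirichlet(fam_L, alpha0=alpha0)
        fam_ep = _exceedance(fam_alpha, n_samples, rng)
        fam_exp = fam_alpha / fam_alpha.sum()
        fam_names = tuple(str(f) for f in fam_ids)
    return BMSResult(
        model_names=names,
        alpha=alpha,
        expected_p=alpha / alpha.sum(),
        exceedance_p=ep,
        n_samples=n_samples,
        seed=seed,
        family_names=fam_names,
        family_alpha=fam_alpha,
        family_expected_p=fam_exp,
        family_exceedance_p=fam_ep,
    )
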