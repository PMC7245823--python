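"""Synthetic balanced panels with known lagged-effect structure.

The generator emulates a longitudinal health survey: N subjects observed at
T waves, J binary time-dependent covariates that persist within subject
(first-order Markov chains), one binary time-independent covariate, and a
binary outcome whose marginal logit is a linear function of current and
lagged covariate values with known coefficients.  Two realism knobs:

* ``rho`` — exchangeable within-subject outcome correlation, induced by a
  Gaussian copula that thresholds equicorrelated latent normals at the
  per-cell quantile, so marginal means are preserved exactly;
* ``feedback`` — a per-covariate log-odds shift of the covariate's Markov
  transition at wave t by the subject's outcome at wave t-1.  Nonzero
  feedback makes the covariate non-exogenous, which is exactly what
  invalidates the moment conditions pairing later covariate measurements
  with earlier residuals.

With ``rho = 0`` and ``feedback = 0`` the fitted marginal model is exactly
true, giving a clean parameter-recovery surface.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Union

import numpy as np
import yaml
from scipy.special import expit, logit, ndtri
from scipy.optimize import brentq

from .errors import ParameterError
from .panel import PanelDataset

# Default true coefficients for J=2, T=4: one covariate with effects at every
# lag (lag-3 nonzero), one with a negative immediate effect and no lag-2/3
# effect — echoing the sparse long-lag significance seen in survey practice.
_DEFAULT_BETA_LAG = ((1.0, 0.4, 0.2, 0.3), (-0.6, 0.25, 0.0, 0.0))


def _per_cov(value, j, name, dtype=float):
    arr = np.asarray(value, dtype=dtype)
    if arr.ndim == 0:
        arr = np.full(j, float(arr))
    if arr.shape != (j,):
        raise ParameterError(f"{name} must be scalar or length J={j}, got shape {arr.shape}")
    return arr


@dataclasses.dataclass
class SyntheticSpec:
    """Generator parameters; every output is a pure function of this spec.

    ``beta_lag[j, k]`` is the true lag-k coefficient of covariate j (lag 0 =
    cross-sectional).  ``beta0`` may be a scalar or per-wave sequence.
    ``p01``/``p11`` are per-covariate Markov transition probabilities
    P(x_t=1 | x_{t-1}=0/1); ``init_prev`` the wave-1 prevalence.
    """

    n_subjects: int = 2000
    n_waves: int = 4
    n_td: int = 2
    beta0: Union[float, Sequence[float]] = 0.5
    beta_fixed: float = 0.3
    beta_lag: Optional[Sequence[Sequence[float]]] = None
    init_prev: Union[float, Sequence[float]] = 0.5
    p01: Union[float, Sequence[float]] = 0.3
    p11: Union[float, Sequence[float]] = 0.7
    fixed_prev: float = 0.5
    rho: float = 0.0
    feedback: Union[float, Sequence[float]] = 0.0
    seed: int = 0
    td_names: Optional[Sequence[str]] = None
    fixed_name: str = "x_fixed"

    def __post_init__(self):
        n, t, j = self.n_subjects, self.n_waves, self.n_td
        if n < 1 or t < 1 or j < 1:
            raise ParameterError("need n_subjects >= 1, n_waves >= 1, n_td >= 1")
        if self.beta_lag is None:
            base = np.array(_DEFAULT_BETA_LAG)
            self.beta_lag = np.zeros((j, t))
            for jj in range(j):
                self.beta_lag[jj] = base[jj % base.shape[0], :t] if t <= base.shape[1] else 0.0
                if t > base.shape[1]:
                    self.beta_lag[jj, : base.shape[1]] = base[jj % base.shape[0]]
        self.beta_lag = np.asarray(self.beta_lag, dtype=float)
        if self.beta_lag.shape != (j, t):
            raise ParameterError(
                f"beta_lag must have shape (J, T) = ({j}, {t}), got {self.beta_lag.shape}"
            )
        self.beta0 = np.asarray(self.beta0, dtype=float)
        if self.beta0.ndim == 0:
            self.beta0 = np.full(t, float(self.beta0))
        if self.beta0.shape != (t,):
            raise ParameterError("beta0 must be scalar or length T")
        self.init_prev = _per_cov(self.init_prev, j, "init_prev")
        self.p01 = _per_cov(self.p01, j, "p01")
        self.p11 = _per_cov(self.p11, j, "p11")
        self.feedback = _per_cov(self.feedback, j, "feedback")
        for name, arr in (("init_prev", self.init_prev), ("p01", self.p01), ("p11", self.p11)):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ParameterError(f"{name} entries must be probabilities in [0, 1]")
        if not 0.0 <= self.fixed_prev <= 1.0:
            raise ParameterError("fixed_prev must be in [0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise ParameterError("rho must be in [0, 1)")
        if self.td_names is None:
            self.td_names = [f"x{jj + 1}" for jj in range(j)]
        self.td_names = list(self.td_names)
        if len(self.td_names) != j:
            raise ParameterError("td_names length must equal J")

    @property
    def true_beta(self) -> np.ndarray:
        """Truth aligned with the default design column order (constant intercept)."""
        return np.concatenate([[float(self.beta0[0])], [self.beta_fixed], self.beta_lag.reshape(-1)])

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ParameterError("spec file must contain a mapping")
        try:
            return cls(**d)
        except TypeError as exc:
            raise ParameterError(f"invalid spec file: {exc}") from exc


def _linear_predictor(spec: SyntheticSpec, x_td: np.ndarray, x_fixed: np.ndarray, t: int) -> np.ndarray:
    """Marginal logit at wave t (1-based): lag-k terms use x at wave t-k."""
    eta = np.full(x_td.shape[0], spec.beta0[t - 1]) + spec.beta_fixed * x_fixed[:, 0]
    for k in range(t):
        eta += x_td[:, t - 1 - k, :] @ spec.beta_lag[:, k]
    return eta


def generate_covariates(
    spec: SyntheticSpec, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (x_td, x_fixed) for an exogenous spec (feedback must be 0).

    With feedback, covariates depend on past outcomes and must be generated
    interleaved — use :func:`generate_panel`.
    """
    if np.any(spec.feedback != 0):
        raise ParameterError(
            "generate_covariates requires feedback == 0; use generate_panel for feedback"
        )
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n, t, j = spec.n_subjects, spec.n_waves, spec.n_td
    x = np.empty((n, t, j))
    x[:, 0, :] = rng.random((n, j)) < spec.init_prev
    for tt in range(1, t):
        stay = np.where(x[:, tt - 1, :] == 1.0, spec.p11, spec.p01)
        x[:, tt, :] = rng.random((n, j)) < stay
    x_fixed = (rng.random((n, 1)) < spec.fixed_prev).astype(float)
    return x, x_fixed


def generate_outcomes(
    spec: SyntheticSpec,
    x_td: np.ndarray,
    x_fixed: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw outcomes given covariates.

    rho = 0: y_it ~ Bernoulli(mu_it) independently across waves given the
    covariates (the marginal model holds exactly).  rho > 0: a Gaussian
    copula — equicorrelated latent normals thresholded at the normal
    quantile of mu_it — which preserves each marginal mean exactly.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n, t = x_td.shape[0], x_td.shape[1]
    z = _latent_normals(spec.rho, n, t, rng)
    y = np.empty((n, t))
    for tt in range(1, t + 1):
        mu = expit(_linear_predictor(spec, x_td, x_fixed, tt))
        y[:, tt - 1] = z[:, tt - 1] < ndtri(mu)
    return y


def _latent_normals(rho: float, n: int, t: int, rng: np.random.Generator) -> np.ndarray:
    b = rng.standard_normal((n, t))
    if rho == 0.0:
        return b
    a = rng.standard_normal((n, 1))
    return np.sqrt(rho) * a + np.sqrt(1.0 - rho) * b


def generate_panel(spec: SyntheticSpec, rng: Optional[np.random.Generator] = None) -> PanelDataset:
    """Generate a full PanelDataset, interleaving covariates and outcomes.

    Interleaving is required when feedback is nonzero: the transition
    probability of covariate j at wave t is shifted on the log-odds scale by
    feedback_j * y_{i,t-1}.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n, t, j = spec.n_subjects, spec.n_waves, spec.n_td
    x = np.empty((n, t, j))
    y = np.empty((n, t))
    x_fixed = (rng.random((n, 1)) < spec.fixed_prev).astype(float)
    z = _latent_normals(spec.rho, n, t, rng)

    x[:, 0, :] = rng.random((n, j)) < spec.init_prev
    mu = expit(_linear_predictor(spec, x, x_fixed, 1))
    y[:, 0] = z[:, 0] < ndtri(mu)
    eps = 1e-12
    for tt in range(1, t):
        stay = np.where(x[:, tt - 1, :] == 1.0, spec.p11, spec.p01)
        if np.any(spec.feedback != 0):
            shifted = logit(np.clip(stay, eps, 1 - eps)) + np.outer(y[:, tt - 1], spec.feedback)
            stay = expit(shifted)
        x[:, tt, :] = rng.random((n, j)) < stay
        mu = expit(_linear_predictor(spec, x, x_fixed, tt + 1))
        y[:, tt] = z[:, tt] < ndtri(mu)

    return PanelDataset(
        subject_ids=np.arange(1, n + 1),
        y=y,
        x_td=x,
        td_names=list(spec.td_names),
        x_fixed=x_fixed,
        fixed_names=[spec.fixed_name],
        wave_labels=list(range(1, t + 1)),
    )


# ---------------------------------------------------------------------------
# Survey-like demonstration fixture
# ---------------------------------------------------------------------------

# Per-wave prevalence targets (%) for the demonstration fixture: a declining
# binary health outcome and six persistent binary covariates over four waves,
# with magnitudes typical of an elderly-cohort survey.  SYNTHETIC: these are
# tuning targets for generated data, not survey measurements.
FIXTURE_OUTCOME_TARGETS = {"health": (94.76, 94.41, 91.98, 86.69)}
FIXTURE_COVARIATE_TARGETS = {
    "own_decision": (90.20, 87.38, 89.36, 87.33),
    "vegetables": (89.56, 91.69, 92.53, 90.95),
    "exercise": (38.05, 42.70, 48.79, 39.53),
    "transfer": (99.70, 99.46, 98.17, 95.10),
    "visual_difficulties": (19.40, 19.54, 23.80, 29.54),
    "pick_book": (91.98, 91.64, 85.85, 77.04),
}
# Cross-sectional log odds ratios used for the fixture's outcome model,
# with small lag-1/lag-2 effects on mobility measures.
_FIXTURE_BETA_XS = {
    "own_decision": 0.24,
    "vegetables": 0.53,
    "exercise": 0.71,
    "transfer": 1.29,
    "visual_difficulties": -0.45,
    "pick_book": 1.41,
}
_FIXTURE_BETA_LAG1 = {"exercise": 0.33, "transfer": 0.57}
_FIXTURE_BETA_LAG2 = {"transfer": -0.82}
_FIXTURE_PERSISTENCE_GAP = 0.35  # p11 - p01, before clamping


def _calibrated_transition(prev_x: np.ndarray, target: float, gap: float, rng) -> np.ndarray:
    """One Markov step whose expected prevalence hits ``target`` exactly."""
    pi_prev = prev_x.mean()
    p01 = target - gap * pi_prev
    p11 = p01 + gap
    if p01 < 0.0:
        p01, p11 = 0.0, target / max(pi_prev, 1e-12)
    if p11 > 1.0:
        p11 = 1.0
        p01 = (target - pi_prev) / max(1.0 - pi_prev, 1e-12)
    p01, p11 = np.clip(p01, 0, 1), np.clip(p11, 0, 1)
    stay = np.where(prev_x == 1.0, p11, p01)
    return (rng.random(prev_x.shape) < stay).astype(float)


def make_clhls_like_fixture(seed: int = 20050) -> PanelDataset:
    """A deterministic 2021-subject, 4-wave, 6-covariate demonstration panel.

    SYNTHETIC stand-in for a restricted-access survey extract: covariate
    chains are calibrated wave by wave to the prevalence targets above, and
    per-wave intercepts are solved so the outcome's marginal prevalence
    tracks its declining targets.  Same seed, same bytes.
    """
    rng = np.random.default_rng(seed)
    n, t = 2021, 4
    names = list(FIXTURE_COVARIATE_TARGETS)
    j = len(names)

    x = np.empty((n, t, j))
    for jj, name in enumerate(names):
        targets = np.asarray(FIXTURE_COVARIATE_TARGETS[name]) / 100.0
        x[:, 0, jj] = rng.random(n) < targets[0]
        for tt in range(1, t):
            x[:, tt, jj] = _calibrated_transition(
                x[:, tt - 1, jj], targets[tt], _FIXTURE_PERSISTENCE_GAP, rng
            )
    x_fixed = (rng.random((n, 1)) < 0.45).astype(float)

    beta_lag = np.zeros((j, t))
    for jj, name in enumerate(names):
        beta_lag[jj, 0] = _FIXTURE_BETA_XS[name]
        beta_lag[jj, 1] = _FIXTURE_BETA_LAG1.get(name, 0.0)
        beta_lag[jj, 2] = _FIXTURE_BETA_LAG2.get(name, 0.0)

    spec = SyntheticSpec(
        n_subjects=n,
        n_waves=t,
        n_td=j,
        beta0=0.0,
        beta_fixed=-0.05,
        beta_lag=beta_lag,
        rho=0.3,
        seed=seed,
        td_names=names,
        fixed_name="male",
    )
    # solve the per-wave intercept so mean(mu) hits the outcome target
    out_targets = np.asarray(FIXTURE_OUTCOME_TARGETS["health"]) / 100.0
    beta0 = np.empty(t)
    for tt in range(1, t + 1):
        eta = _linear_predictor(spec, x, x_fixed, tt)  # beta0 contribution is 0
        beta0[tt - 1] = brentq(
            lambda b: expit(b + eta).mean() - out_targets[tt - 1], -20, 20, xtol=1e-12
        )
    spec.beta0 = beta0
    y = generate_outcomes(spec, x, x_fixed, rng)

    return PanelDataset(
        subject_ids=np.arange(1, n + 1),
        y=y,
        x_td=x,
        td_names=names,
        x_fixed=x_fixed,
        fixed_names=["male"],
        wave_labels=[2005, 2008, 2011, 2014],
        outcome_name="health",
    )
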