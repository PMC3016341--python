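"""Metropolis MCMC calibration of the free model parameters.

Most model constants are fixed from prior data; the basal thermogenesis
rate K and the four physical-activity coefficients {lambda_C0, lambda_C1,
lambda_C2, lambda_H} are estimated from longitudinal group-mean body
weight and fat mass.  The sampler is a random-walk Metropolis chain with a
diagonal Gaussian proposal whose overall scale is adapted toward a target
acceptance rate of about 0.25 during burn-in (Robbins-Monro on the
log-scale) and frozen afterwards, which preserves detailed balance for the
retained draws.

Intake measurement uncertainty is propagated by treating each observed
per-interval energy intake as a nuisance parameter with a Gaussian prior
centered on the measurement at the group's stated standard error; these
nuisances are sampled jointly with the free parameters, so posterior
predictive energy-expenditure bands reflect intake error as well as
parameter uncertainty.  Priors on the free parameters are flat on the
positive half-line.  Several observation groups may be fitted jointly with
shared parameters (the default); per-group fits are just calls with a
single group.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._fastsim import SegmentedModel
from .core import BodyState, ModelParameters
from .expenditure import lambda_at, resolve_energy_balance
from .schedules import ActivitySchedule, IntakeSchedule

#: Names and order of the free parameters in every draw matrix.
THETA_NAMES = ("K", "lambda_C0", "lambda_C1", "lambda_C2", "lambda_H")

#: Default starting point: the published calibrated values.
DEFAULT_THETA = np.array([2.1, 0.22, 0.27, 0.19, 0.13])


@dataclass
class ObservationSet:
    """Longitudinal group-mean observations for one experimental group.

    ``times`` (d), ``BW_mean``/``FM_mean`` (g) and their standard errors;
    ``intake`` carries the measured per-interval energy intakes and the
    fed diets; ``EI_se`` is the group's intake standard error (kcal/d);
    ``switches`` is the diet-switch protocol driving physical activity;
    ``init`` the measured body composition at t = 0.  Rows are sorted by
    time on construction, so the likelihood is invariant to input order.
    """

    times: np.ndarray
    BW_mean: np.ndarray
    FM_mean: np.ndarray
    BW_se: np.ndarray
    FM_se: np.ndarray
    intake: IntakeSchedule
    EI_se: float
    switches: tuple[tuple[float, str], ...]
    init: BodyState
    group: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        n = len(self.times)
        for name in ("BW_mean", "FM_mean", "BW_se", "FM_se"):
            arr = np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), (n,)
            ).copy()
            setattr(self, name, arr)
        if len(np.unique(self.times)) != n:
            raise ValueError("observation times must be unique")
        order = np.argsort(self.times)
        self.times = self.times[order]
        for name in ("BW_mean", "FM_mean", "BW_se", "FM_se"):
            setattr(self, name, getattr(self, name)[order])
        if np.any(self.BW_se <= 0) or np.any(self.FM_se <= 0) or self.EI_se <= 0:
            raise ValueError("all standard errors must be strictly positive")


@dataclass
class PosteriorSample:
    """Retained (post burn-in, thinned) draws of a Metropolis chain."""

    param_names: tuple[str, ...]
    draws: np.ndarray                 # (n_draws, 5) free parameters
    ei_draws: np.ndarray              # (n_draws, n_nuisance) intake nuisances
    log_post: np.ndarray              # (n_draws,)
    ee_pred: dict                     # group -> (n_draws, n_times) EE kcal/d
    ee_times: dict                    # group -> observation times (d)
    n_iter: int
    burn_in: int
    thin: int

    def median(self) -> dict:
        med = np.median(self.draws, axis=0)
        return dict(zip(self.param_names, med))

    def ci(self, lo: float = 2.5, hi: float = 97.5) -> dict:
        lower = np.percentile(self.draws, lo, axis=0)
        upper = np.percentile(self.draws, hi, axis=0)
        return {
            name: (lower[i], upper[i]) for i, name in enumerate(self.param_names)
        }

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(self.param_names))
        df["log_post"] = self.log_post
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ChainDiagnostics:
    """Acceptance and convergence summaries of one chain."""

    acceptance_rate: float            # post burn-in
    acceptance_rate_burnin: float
    geweke_z: dict
    proposal_scale: np.ndarray = field(repr=False)

    def to_json(self, path=None) -> str:
        obj = {
            "acceptance_rate": self.acceptance_rate,
            "acceptance_rate_burnin": self.acceptance_rate_burnin,
            "geweke_z": {k: float(v) for k, v in self.geweke_z.items()},
        }
        s = json.dumps(obj, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


class _Posterior:
    """Joint log-posterior over (free parameters, intake nuisances)."""

    def __init__(self, obs_list, p: ModelParameters, dt: float, sample_EI: bool):
        self.obs = list(obs_list)
        self.p = p
        self.sample_EI = sample_EI
        self.models = [
            SegmentedModel(o.intake, o.switches, o.times, dt=dt) for o in self.obs
        ]
        self.ei_meas = [o.intake.EI.copy() for o in self.obs]
        sizes = [len(e) for e in self.ei_meas]
        self.n_nuis = sum(sizes) if sample_EI else 0
        self.slices = []
        start = 5
        for s in sizes:
            self.slices.append(slice(start, start + s))
            start += s

    def x0(self, theta0: np.ndarray) -> np.ndarray:
        if self.sample_EI:
            return np.concatenate([theta0] + self.ei_meas)
        return np.asarray(theta0, dtype=float).copy()

    def scales(self, theta0: np.ndarray, frac: float) -> np.ndarray:
        s_theta = frac * np.abs(theta0)
        if not self.sample_EI:
            return s_theta
        s_ei = np.concatenate(
            [np.full(len(e), o.EI_se) for e, o in zip(self.ei_meas, self.obs)]
        )
        return np.concatenate([s_theta, s_ei])

    def split(self, x: np.ndarray):
        theta = x[:5]
        if self.sample_EI:
            ei = [x[sl] for sl in self.slices]
        else:
            ei = self.ei_meas
        return theta, ei

    def __call__(self, x: np.ndarray):
        """Return (log posterior, per-group (FM, FFM) states at obs times)."""
        theta, ei = self.split(x)
        if np.any(theta <= 0) or any(np.any(e < 0) for e in ei):
            return -np.inf, None
        K, lC0, lC1, lC2, lH = theta
        p = self.p.replace(K=float(K))
        lp = 0.0
        states = []
        for o, m, e, e_meas in zip(self.obs, self.models, ei, self.ei_meas):
            out = m.run(o.init, p, lC0, lC1, lC2, lH, self.p.tau, EI_values=e)
            if out is None:
                return -np.inf, None
            FM, FFM = out
            BW = FM + FFM
            lp -= 0.5 * np.sum(((BW - o.BW_mean) / o.BW_se) ** 2)
            lp -= 0.5 * np.sum(((FM - o.FM_mean) / o.FM_se) ** 2)
            if self.sample_EI:
                lp -= 0.5 * np.sum(((e - e_meas) / o.EI_se) ** 2)
            states.append((FM, FFM))
        if not np.isfinite(lp):
            return -np.inf, None
        return lp, states

    def ee_at_obs(self, x: np.ndarray, states) -> list:
        """Predicted EE (kcal/d) at each group's observation times."""
        theta, ei = self.split(x)
        K, lC0, lC1, lC2, lH = theta
        p = self.p.replace(K=float(K))
        out = []
        for o, e, (FM, FFM) in zip(self.obs, ei, states):
            act = ActivitySchedule(
                lambda_C0=lC0, lambda_C1=lC1, lambda_C2=lC2, lambda_H=lH,
                tau=self.p.tau, switches=o.switches,
            )
            ee = np.empty(len(o.times))
            for i, t in enumerate(o.times):
                idx = o.intake.index_at(t)
                EI = float(e[idx])
                dEI = EI - o.intake.baseline_EI
                lam = lambda_at(t, act)
                st = BodyState(FM[i], FFM[i])
                ee[i] = resolve_energy_balance(st, EI, dEI, lam, p).EE
            out.append(ee)
        return out


def log_posterior(
    theta,
    obs,
    p: ModelParameters | None = None,
    EI_values=None,
    dt: float = 1.0,
) -> float:
    """Joint log posterior density (up to an additive constant).

    Gaussian log-likelihood of the observed BW and FM given the simulated
    trajectory at ``theta`` (order :data:`THETA_NAMES`), plus Gaussian
    terms tying the intake nuisances ``EI_values`` (defaults to the
    measured intakes) to the measurements at the stated intake standard
    errors; flat priors on the positive support.  Returns ``-inf`` for
    non-positive parameters or if the simulation leaves its domain.
    """
    if p is None:
        p = ModelParameters()
    obs_list = [obs] if isinstance(obs, ObservationSet) else list(obs)
    post = _Posterior(obs_list, p, dt, sample_EI=True)
    theta = np.asarray(theta, dtype=float)
    if EI_values is None:
        x = post.x0(theta)
    else:
        ei = [np.asarray(e, float) for e in EI_values]
        x = np.concatenate([theta] + ei)
    lp, _ = post(x)
    return float(lp)


def run_metropolis(
    obs,
    p: ModelParameters | None = None,
    n_iter: int = 100_000,
    burn_in: int = 30_000,
    thin: int = 5,
    seed: int | None = None,
    init_theta=None,
    sample_EI: bool = True,
    target_accept: float = 0.25,
    init_scale_frac: float = 0.05,
    adapt_power: float = 0.6,
    adapt_cov: bool = True,
    dt: float = 1.0,
):
    """Run a random-walk Metropolis chain; return (PosteriorSample, ChainDiagnostics).

    The proposal is a Gaussian random walk.  During burn-in (only) two
    things are adapted and then frozen, preserving detailed balance for
    the retained draws: a global step scale, tuned toward
    ``target_accept`` by Robbins-Monro on the log-scale, and (with
    ``adapt_cov``) the proposal covariance, re-estimated periodically from
    the burn-in history so that proposals follow the posterior's
    correlation structure — the free parameters and the intake nuisances
    are strongly correlated through the energy-balance constraint, and a
    diagonal proposal mixes too slowly along that ridge to converge at
    practical chain lengths.  Draws are retained after ``burn_in``,
    keeping every ``thin``-th iteration, so the retained count is
    (n_iter - burn_in)/thin when that division is exact.  The chain is
    reproducible bit-for-bit under a fixed ``seed``.
    """
    if p is None:
        p = ModelParameters()
    obs_list = [obs] if isinstance(obs, ObservationSet) else list(obs)
    if not (0 <= burn_in < n_iter):
        raise ValueError("need 0 <= burn_in < n_iter")
    rng = np.random.default_rng(seed)
    post = _Posterior(obs_list, p, dt, sample_EI=sample_EI)
    theta0 = DEFAULT_THETA if init_theta is None else np.asarray(init_theta, float)
    x = post.x0(theta0)
    scales = post.scales(theta0, init_scale_frac)
    log_s = 0.0
    lp, states = post(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has zero posterior density")

    n_keep = len(range(burn_in, n_iter, thin))
    dim = len(x)
    # proposal geometry: Cholesky factor of the (possibly adapted) covariance
    chol = np.diag(scales)
    hist_stride = max(burn_in // 1000, 1)
    history = []
    refresh = max(burn_in // 10, 1)
    draws = np.empty((n_keep, 5))
    ei_draws = np.empty((n_keep, max(post.n_nuis, 0)))
    log_post = np.empty(n_keep)
    ee_pred = {
        o.group or str(i): np.empty((n_keep, len(o.times)))
        for i, o in enumerate(obs_list)
    }
    keys = list(ee_pred)
    acc_burn = 0
    acc_main = 0
    kept = 0
    for it in range(n_iter):
        prop = x + math.exp(log_s) * (chol @ rng.standard_normal(dim))
        lp_prop, states_prop = post(prop)
        accept = math.log(rng.random()) < lp_prop - lp
        if accept:
            x, lp, states = prop, lp_prop, states_prop
        if it < burn_in:
            acc_burn += accept
            log_s += (it + 1) ** (-adapt_power) * (float(accept) - target_accept)
            if adapt_cov:
                if it % hist_stride == 0:
                    history.append(x.copy())
                if it and it % refresh == 0 and len(history) >= 2 * dim:
                    recent = np.asarray(history[len(history) // 2:])
                    cov = np.cov(recent, rowvar=False)
                    cov += np.diag((1e-6 * scales) ** 2)
                    try:
                        chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass
        else:
            acc_main += accept
            if (it - burn_in) % thin == 0:
                draws[kept] = x[:5]
                if post.n_nuis:
                    ei_draws[kept] = x[5:]
                log_post[kept] = lp
                for key, ee in zip(keys, post.ee_at_obs(x, states)):
                    ee_pred[key][kept] = ee
                kept += 1

    rate_main = acc_main / (n_iter - burn_in)
    rate_burn = acc_burn / burn_in if burn_in else float("nan")
    if rate_main < 0.02 or rate_main > 0.98:
        warnings.warn(
            f"post-adaptation acceptance rate {rate_main:.3f} collapsed toward "
            "0 or 1; the chain is unlikely to have mixed",
            RuntimeWarning,
            stacklevel=2,
        )
    gz = {}
    for i, name in enumerate(THETA_NAMES):
        col = draws[:, i]
        try:
            gz[name] = geweke_z(col)
        except ValueError:
            gz[name] = float("nan")
    sample = PosteriorSample(
        param_names=THETA_NAMES,
        draws=draws,
        ei_draws=ei_draws,
        log_post=log_post,
        ee_pred=ee_pred,
        ee_times={k: o.times.copy() for k, o in zip(keys, obs_list)},
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
    )
    diag = ChainDiagnostics(
        acceptance_rate=rate_main,
        acceptance_rate_burnin=rate_burn,
        geweke_z=gz,
        proposal_scale=math.exp(log_s) * np.sqrt(np.diag(chol @ chol.T)),
    )
    return sample, diag


def _long_run_variance(seg: np.ndarray) -> float:
    """Spectral density at frequency zero via a Bartlett-tapered
    autocovariance sum (lag window of length sqrt(n))."""
    seg = seg - seg.mean()
    m = len(seg)
    L = int(math.sqrt(m))
    s = float(np.dot(seg, seg)) / m
    for j in range(1, L + 1):
        cj = float(np.dot(seg[:-j], seg[j:])) / m
        s += 2.0 * (1.0 - j / (L + 1.0)) * cj
    return max(s, np.finfo(float).tiny)


def geweke_z(chain, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score for a single-parameter chain.

    Compares the mean of the first ``first`` fraction of the chain with
    the mean of the last ``last`` fraction, standardized by the
    spectral-density-estimated variances of the two segments.  Values of
    |z| well above ~2-3 indicate the early chain had not yet reached the
    stationary distribution.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("need a chain of at least 100 draws")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) chain; z undefined")
    a = x[: max(int(first * n), 2)]
    b = x[n - max(int(last * n), 2):]
    var = _long_run_variance(a) / len(a) + _long_run_variance(b) / len(b)
    return float((a.mean() - b.mean()) / math.sqrt(var))


def predict_EE_interval(
    post: PosteriorSample,
    group: str | None = None,
    lo: float = 2.5,
    hi: float = 97.5,
):
    """Pointwise credible band of predicted energy expenditure.

    Returns ``(times, lower, upper)`` in days and kcal/d for the requested
    group (the only group if there is just one), computed as the ``lo``-th
    and ``hi``-th percentiles across retained draws.  Requires at least
    100 retained draws.
    """
    if group is None:
        if len(post.ee_pred) != 1:
            raise ValueError(
                f"specify a group; available: {sorted(post.ee_pred)}"
            )
        group = next(iter(post.ee_pred))
    ee = post.ee_pred[group]
    if ee.shape[0] < 100:
        raise ValueError(
            f"need at least 100 retained draws for a stable band, have {ee.shape[0]}"
        )
    lower = np.percentile(ee, lo, axis=0)
    upper = np.percentile(ee, hi, axis=0)
    return post.ee_times[group], lower, upper
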