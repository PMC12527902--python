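"""Conditional and mixed logit estimation for panel choice data.

The choice model follows random utility: respondent i's utility for
alternative j in task t is U_itj = beta_i' x_itj + asc * optout_itj +
e_itj with i.i.d. Gumbel errors, so task-level choice probabilities are
multinomial logit.  The conditional logit fixes beta_i = beta; the mixed
logit lets the coefficients flagged random vary across respondents as
independent normals, and its log-likelihood is simulated with
quasi-random (Halton) normal draws, averaging the product of a
respondent's task probabilities over draws (panel structure).

Both likelihoods carry analytic gradients; standard errors come from the
inverse (finite-difference) Hessian of the simulated likelihood at the
optimum, or the exact Hessian for the conditional logit.  Model choice
between the two is by AIC/BIC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, ndtri

from .schema import AttributeSchema, encode_profile
from .synthetic_data import OPT_OUT, SurveyDataset

__all__ = [
    "LongFormatData",
    "ModelSpec",
    "EstimationResult",
    "build_long_format",
    "conditional_logit_loglik",
    "fit_conditional_logit",
    "halton_sequence",
    "make_normal_draws",
    "mixed_logit_simulated_loglik",
    "fit_mixed_logit",
    "information_criteria",
]

logger = logging.getLogger(__name__)

_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59, 61, 67, 71)


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class LongFormatData:
    """Long-format choice rows: one row per alternative of each scored task.

    ``frame`` columns: respondent_id, task_id, alt_id (1, 2 or 0 for
    opt-out), chosen (0/1), opt_out (0/1), then the design columns.  The
    panel must be regular: every respondent faces the same number of tasks
    and every task the same number of alternatives (always 3 here).
    """

    frame: pd.DataFrame
    design_columns: list[str]

    def __post_init__(self) -> None:
        per_task = self.frame.groupby(["respondent_id", "task_id"])["chosen"].sum()
        bad = per_task[per_task != 1]
        if len(bad):
            rid, tid = bad.index[0]
            raise ValueError(
                f"each respondent-task needs exactly one chosen row "
                f"(respondent {rid}, task {tid} has {int(bad.iloc[0])})"
            )

    @property
    def n_obs(self) -> int:
        """Number of rows (alternatives x tasks x respondents)."""
        return len(self.frame)

    def tensors(self) -> dict:
        """Reshape to regular (N, T, J) arrays, sorted for order invariance."""
        df = self.frame.sort_values(["respondent_id", "task_id", "alt_id"], kind="mergesort")
        sizes = df.groupby(["respondent_id", "task_id"]).size()
        j = int(sizes.iloc[0])
        if not (sizes == j).all():
            raise ValueError("irregular panel: tasks have differing numbers of alternatives")
        tasks_per = df.groupby("respondent_id")["task_id"].nunique()
        t = int(tasks_per.iloc[0])
        if not (tasks_per == t).all():
            raise ValueError("irregular panel: respondents have differing numbers of tasks")
        n = tasks_per.size
        x = df[self.design_columns].to_numpy(dtype=float).reshape(n, t, j, -1)
        optout = df["opt_out"].to_numpy(dtype=float).reshape(n, t, j)
        chosen = df["chosen"].to_numpy(dtype=float).reshape(n, t, j)
        return {
            "X": x,
            "optout": optout,
            "chosen": chosen,
            "respondent_ids": df["respondent_id"].to_numpy()[:: t * j],
            "n": n,
            "t": t,
            "j": j,
        }

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, design_columns: list[str]) -> "LongFormatData":
        return cls(frame=pd.read_csv(path), design_columns=design_columns)


def build_long_format(
    dataset: SurveyDataset,
    schema: AttributeSchema | None = None,
    drop_consistency_repeat: bool = True,
) -> LongFormatData:
    """Expand a survey into estimation rows: 3 rows per scored task.

    With the default flag the repeated consistency task is excluded, so a
    filtered survey of 69 respondents with 10 unique tasks yields
    69 x 10 x 3 = 2,070 rows.  Opt-out rows have a zero design vector and
    opt_out = 1.
    """
    if not dataset.records:
        raise ValueError("dataset has no respondents")
    schema = schema or dataset.schema
    cols = schema.design_columns
    encode_cache: dict[tuple, np.ndarray] = {}

    def enc(profile: dict) -> np.ndarray:
        key = tuple(sorted(profile.items()))
        if key not in encode_cache:
            encode_cache[key] = encode_profile(profile, schema)
        return encode_cache[key]

    rows = []
    for rec in dataset.records:
        q = dataset.questionnaire_for(rec)
        positions = q.scored_positions if drop_consistency_repeat else range(q.n_tasks)
        for pos in positions:
            task = q.tasks[pos]
            choice = rec.choices[pos]
            task_id = rec.respondent_id * 1000 + pos
            for alt_no, alt in enumerate(task.alternatives, start=1):
                rows.append(
                    (rec.respondent_id, task_id, alt_no, int(choice == alt_no), 0, *enc(alt))
                )
            rows.append(
                (rec.respondent_id, task_id, OPT_OUT, int(choice == OPT_OUT), 1, *np.zeros(len(cols)))
            )
    frame = pd.DataFrame(
        rows, columns=["respondent_id", "task_id", "alt_id", "chosen", "opt_out", *cols]
    )
    return LongFormatData(frame=frame, design_columns=cols)


# ---------------------------------------------------------------------------
# model specification and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Which coefficients are random in the mixed logit.

    The default — all twelve categorical dummies random, cost and the
    opt-out ASC fixed — gives 26 parameters (14 means + 12 SDs), the
    parameter count consistent with the published information criteria.
    """

    random_columns: tuple[str, ...] | None = None  # None -> all non-cost design columns
    asc_included: bool = True
    mixing: str = "normal"

    def resolve_random(self, design_columns: list[str]) -> list[str]:
        if self.random_columns is None:
            return [c for c in design_columns if c != "cost_10k"]
        unknown = set(self.random_columns) - set(design_columns)
        if unknown:
            raise ValueError(f"random columns not in design: {sorted(unknown)}")
        return [c for c in design_columns if c in self.random_columns]

    def n_parameters(self, design_columns: list[str]) -> int:
        return len(design_columns) + int(self.asc_included) + len(self.resolve_random(design_columns))


@dataclass
class EstimationResult:
    means: pd.Series
    mean_se: pd.Series
    asc: float
    asc_se: float | None
    sds: pd.Series
    sd_se: pd.Series
    log_likelihood: float
    k: int
    n_obs: int
    aic: float
    bic: float
    n_draws: int
    seed: int | None
    converged: bool
    model: str
    cov: np.ndarray | None = None
    param_names: list[str] | None = None

    def coefficient(self, name: str) -> float:
        if name == "asc_opt_out":
            return self.asc
        return float(self.means[name])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model": self.model,
            "means": self.means.to_dict(),
            "mean_se": self.mean_se.to_dict(),
            "asc_opt_out": self.asc,
            "asc_se": self.asc_se,
            "sds": self.sds.to_dict(),
            "sd_se": self.sd_se.to_dict(),
            "log_likelihood": self.log_likelihood,
            "k": self.k,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "bic": self.bic,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "converged": self.converged,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def information_criteria(log_likelihood: float, k: int, n_obs: int = 1) -> tuple[float, float]:
    """AIC = 2k - 2 ll;  BIC = k ln(n_obs) - 2 ll."""
    if k < 0 or n_obs < 1:
        raise ValueError("k must be >= 0 and n_obs >= 1")
    aic = 2 * k - 2 * log_likelihood
    bic = k * float(np.log(n_obs)) - 2 * log_likelihood
    return aic, bic


# ---------------------------------------------------------------------------
# conditional logit
# ---------------------------------------------------------------------------


def _clogit_parts(params: np.ndarray, tensors: dict) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-likelihood, gradient and per-row probabilities for the MNL."""
    x, optout, chosen = tensors["X"], tensors["optout"], tensors["chosen"]
    k = x.shape[-1]
    beta, asc = params[:k], params[k]
    u = x @ beta + asc * optout
    lse = logsumexp(u, axis=-1, keepdims=True)
    logp = u - lse
    ll = float((chosen * logp).sum())
    p = np.exp(logp)
    resid = chosen - p  # (N, T, J)
    grad_beta = np.einsum("ntj,ntjk->k", resid, x)
    grad_asc = float((resid * optout).sum())
    return ll, np.concatenate([grad_beta, [grad_asc]]), p


def conditional_logit_loglik(
    params: np.ndarray, data: LongFormatData, tensors: dict | None = None
) -> tuple[float, np.ndarray]:
    """Fixed-coefficient MNL log-likelihood and its analytic gradient.

    ``params`` stacks the design coefficients followed by the opt-out ASC.
    """
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite parameters")
    tensors = tensors or data.tensors()
    expected = tensors["X"].shape[-1] + 1
    if params.size != expected:
        raise ValueError(f"expected {expected} parameters, got {params.size}")
    ll, grad, _ = _clogit_parts(params, tensors)
    return ll, grad


def _clogit_hessian(params: np.ndarray, tensors: dict) -> np.ndarray:
    """Exact Hessian of the conditional-logit log-likelihood."""
    x, optout = tensors["X"], tensors["optout"]
    k = x.shape[-1]
    xfull = np.concatenate([x, optout[..., None]], axis=-1)  # (N, T, J, K+1)
    beta, asc = params[:k], params[k]
    u = x @ beta + asc * optout
    u = u - u.max(axis=-1, keepdims=True)
    p = np.exp(u)
    p /= p.sum(axis=-1, keepdims=True)
    xbar = np.einsum("ntj,ntjk->ntk", p, xfull)
    centred = xfull - xbar[:, :, None, :]
    return -np.einsum("ntj,ntjk,ntjl->kl", p, centred, centred)


def fit_conditional_logit(
    data: LongFormatData, start: np.ndarray | None = None, maxiter: int = 500
) -> EstimationResult:
    """Maximize the conditional-logit likelihood (BFGS with analytic gradient).

    Standard errors come from the inverse of the exact observed
    information; non-convergence is flagged on the result rather than
    raised.
    """
    tensors = data.tensors()
    kx = tensors["X"].shape[-1]
    n_par = kx + 1
    x0 = np.zeros(n_par) if start is None else np.asarray(start, dtype=float)

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        ll, grad, _ = _clogit_parts(theta, tensors)
        return -ll, -grad

    res = minimize(objective, x0, jac=True, method="BFGS", options={"maxiter": maxiter, "gtol": 1e-6})
    theta = res.x
    # Newton polish with the exact Hessian; convergence judged on the gradient
    ll, grad, _ = _clogit_parts(theta, tensors)
    converged = False
    for _ in range(50):
        if np.abs(grad).max() < 1e-7 * (1.0 + abs(ll)):
            converged = True
            break
        hess = _clogit_hessian(theta, tensors)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _half in range(30):
            ll_new, grad_new, _ = _clogit_parts(theta - scale * step, tensors)
            if ll_new >= ll:
                theta = theta - scale * step
                ll, grad = ll_new, grad_new
                break
            scale /= 2
        else:
            break
    hess = _clogit_hessian(theta, tensors)
    se, cov = _se_from_hessian(-hess)
    names = list(data.design_columns) + ["asc_opt_out"]
    aic, bic = information_criteria(ll, n_par, data.n_obs)
    return EstimationResult(
        means=pd.Series(theta[:kx], index=data.design_columns),
        mean_se=pd.Series(se[:kx] if se is not None else np.nan, index=data.design_columns),
        asc=float(theta[kx]),
        asc_se=float(se[kx]) if se is not None else None,
        sds=pd.Series(dtype=float),
        sd_se=pd.Series(dtype=float),
        log_likelihood=ll,
        k=n_par,
        n_obs=data.n_obs,
        aic=aic,
        bic=bic,
        n_draws=0,
        seed=None,
        converged=converged,
        model="conditional logit",
        cov=cov,
        param_names=names,
    )


def _se_from_hessian(info: np.ndarray) -> tuple[np.ndarray | None, np.ndarray | None]:
    """SEs from an information (negative Hessian) matrix; None when singular."""
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None, None
    diag = np.diag(cov)
    if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
        return None, None
    return np.sqrt(diag), cov


# ---------------------------------------------------------------------------
# Halton draws
# ---------------------------------------------------------------------------


def _van_der_corput(n: int, base: int, start: int = 1) -> np.ndarray:
    out = np.empty(n)
    for i in range(n):
        k = start + i
        f, r = 1.0, 0.0
        while k > 0:
            f /= base
            r += f * (k % base)
            k //= base
        out[i] = r
    return out


def halton_sequence(
    dimension: int, n: int, burn: int = 0, seed_scramble: bool = False, seed: int = 0
) -> np.ndarray:
    """n x dimension Halton points in (0, 1).

    Successive dimensions use van der Corput sequences in successive
    primes; the first ``burn`` points are discarded.  Optional scrambling
    applies a seeded Cranley-Patterson rotation (uniform shift modulo 1)
    per dimension.
    """
    if dimension > len(_PRIMES):
        raise ValueError(f"at most {len(_PRIMES)} dimensions supported")
    pts = np.column_stack(
        [_van_der_corput(n, _PRIMES[d], start=1 + burn) for d in range(dimension)]
    )
    if seed_scramble:
        shift = np.random.default_rng(seed).uniform(size=dimension)
        pts = (pts + shift) % 1.0
    return pts


def make_normal_draws(
    n_respondents: int, n_draws: int, n_dims: int, burn: int = 100, seed: int = 0
) -> np.ndarray:
    """Standard-normal Halton draws shaped (respondents, draws, dims).

    One long scrambled Halton stream is inverse-normal transformed and
    partitioned across respondents, the usual construction for maximum
    simulated likelihood.
    """
    total = n_respondents * n_draws
    u = halton_sequence(n_dims, total, burn=burn, seed_scramble=True, seed=seed)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return ndtri(u).reshape(n_respondents, n_draws, n_dims)


# ---------------------------------------------------------------------------
# mixed logit
# ---------------------------------------------------------------------------


def _mixl_parts(
    params: np.ndarray, tensors: dict, draws: np.ndarray, random_idx: np.ndarray
) -> tuple[float, np.ndarray]:
    """Simulated log-likelihood and analytic gradient of the panel mixed logit.

    ``params`` = [design means..., asc, sds of the random columns...].
    ``draws`` must be standard-normal, shaped (N, R, n_random).
    """
    x, optout, chosen = tensors["X"], tensors["optout"], tensors["chosen"]
    n, t, j, kx = x.shape
    r = draws.shape[1]
    kr = random_idx.size
    means, asc, sds = params[:kx], params[kx], params[kx + 1 :]
    u0 = x @ means + asc * optout  # (N, T, J)
    xr = x[..., random_idx].reshape(n, t * j, kr)
    delta = sds * draws  # (N, R, Kr)
    u = u0.reshape(n, t * j, 1) + xr @ delta.transpose(0, 2, 1)  # (N, T*J, R)
    u = u.reshape(n, t, j, r)
    lse = logsumexp(u, axis=2, keepdims=True)
    logp = u - lse
    lp_panel = np.einsum("ntj,ntjr->nr", chosen, logp)  # log prod_t P_chosen
    m = lp_panel.max(axis=1, keepdims=True)
    w_unnorm = np.exp(lp_panel - m)  # (N, R)
    mean_p = w_unnorm.mean(axis=1)
    ll = float((m[:, 0] + np.log(mean_p)).sum())
    w = w_unnorm / w_unnorm.sum(axis=1, keepdims=True)  # draw weights per respondent
    resid = (chosen[..., None] - np.exp(logp)).reshape(n, t * j, r)
    xfull = np.concatenate([x.reshape(n, t * j, kx), optout.reshape(n, t * j, 1)], axis=2)
    g_fixed = resid.transpose(0, 2, 1) @ xfull  # (N, R, Kx+1)
    grad_fixed = np.einsum("nr,nrk->k", w, g_fixed)
    g_rand = resid.transpose(0, 2, 1) @ xr  # (N, R, Kr)
    grad_sd = np.einsum("nr,nrk,nrk->k", w, g_rand, draws)
    return ll, np.concatenate([grad_fixed, grad_sd])


def mixed_logit_simulated_loglik(
    params: np.ndarray,
    data: LongFormatData,
    draws: np.ndarray,
    spec: ModelSpec | None = None,
    tensors: dict | None = None,
) -> tuple[float, np.ndarray]:
    """Panel simulated log-likelihood sum_i log((1/R) sum_r prod_t P_itr)."""
    spec = spec or ModelSpec()
    tensors = tensors or data.tensors()
    random_cols = spec.resolve_random(data.design_columns)
    random_idx = np.asarray([data.design_columns.index(c) for c in random_cols], dtype=int)
    if draws.ndim != 3 or draws.shape[2] != random_idx.size or draws.shape[0] != tensors["n"]:
        raise ValueError(
            f"draws must be shaped (n_respondents={tensors['n']}, n_draws, "
            f"n_random={random_idx.size}); got {draws.shape}"
        )
    if draws.shape[1] == 0:
        raise ValueError("need at least one draw")
    params = np.asarray(params, dtype=float)
    expected = len(data.design_columns) + 1 + random_idx.size
    if params.size != expected:
        raise ValueError(f"expected {expected} parameters, got {params.size}")
    return _mixl_parts(params, tensors, np.asarray(draws, dtype=float), random_idx)


def fit_mixed_logit(
    data: LongFormatData,
    spec: ModelSpec | None = None,
    n_draws: int = 500,
    seed: int = 0,
    start_sd: float = 0.1,
    maxiter: int = 400,
    compute_se: bool = True,
) -> EstimationResult:
    """Maximum simulated likelihood fit of the panel mixed logit.

    Starts from the conditional-logit estimates with small positive SDs,
    uses scrambled-Halton normal draws (recorded with the seed), and
    normalizes the reported SDs to non-negative.  Standard errors are from
    a central-difference Hessian of the simulated likelihood; when that
    Hessian is singular SEs are reported absent rather than fabricated.
    """
    spec = spec or ModelSpec()
    tensors = data.tensors()
    kx = tensors["X"].shape[-1]
    random_cols = spec.resolve_random(data.design_columns)
    random_idx = np.asarray([data.design_columns.index(c) for c in random_cols], dtype=int)
    kr = random_idx.size
    draws = make_normal_draws(tensors["n"], n_draws, max(kr, 1), seed=seed)[:, :, :kr]

    clogit = fit_conditional_logit(data)
    x0 = np.concatenate(
        [clogit.means.to_numpy(), [clogit.asc], np.full(kr, start_sd)]
    )

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        ll, grad = _mixl_parts(theta, tensors, draws, random_idx)
        return -ll, -grad

    res = minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
    )
    theta = res.x.copy()
    # a negative sd is observationally equivalent to its absolute value
    theta[kx + 1 :] = np.abs(theta[kx + 1 :])
    ll = -float(res.fun)

    se = cov = None
    if compute_se:
        info = -_fd_hessian(lambda th: _mixl_parts(th, tensors, draws, random_idx)[1], theta)
        se, cov = _se_from_hessian(info)
    if se is None and compute_se:
        logger.warning("mixed logit Hessian singular; standard errors not reported")

    names = list(data.design_columns) + ["asc_opt_out"] + [f"sd_{c}" for c in random_cols]
    n_par = theta.size
    aic, bic = information_criteria(ll, n_par, data.n_obs)
    nan = float("nan")
    return EstimationResult(
        means=pd.Series(theta[:kx], index=data.design_columns),
        mean_se=pd.Series(se[:kx] if se is not None else nan, index=data.design_columns),
        asc=float(theta[kx]),
        asc_se=float(se[kx]) if se is not None else None,
        sds=pd.Series(theta[kx + 1 :], index=random_cols),
        sd_se=pd.Series(se[kx + 1 :] if se is not None else nan, index=random_cols),
        log_likelihood=ll,
        k=n_par,
        n_obs=data.n_obs,
        aic=aic,
        bic=bic,
        n_draws=n_draws,
        seed=seed,
        converged=bool(res.success),
        model="mixed logit",
        cov=cov,
        param_names=names,
    )


def _fd_hessian(grad_fn, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Jacobian of an analytic gradient, symmetrized."""
    k = theta.size
    h = rel_step * np.maximum(1.0, np.abs(theta))
    jac = np.empty((k, k))
    for i in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h[i]
        tm[i] -= h[i]
        jac[i] = (grad_fn(tp) - grad_fn(tm)) / (2 * h[i])
    return 0.5 * (jac + jac.T)
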