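"""MAP fitting, Laplace model evidence, and random-effects model comparison.

Each model is fitted per subject by maximizing the log posterior in
unconstrained parameter space under independent N(0, 6.25) priors, with
multiple seeded restarts (the likelihoods are multimodal).  Model evidence
is the Laplace approximation at the mode.  Cohort-level comparison follows
the variational random-effects scheme of Stephan et al. (2009): a Dirichlet
posterior over model frequencies estimated by iterating per-subject model
responsibilities, with exceedance probabilities by Monte Carlo over that
posterior.  Subjects are classified into strategy groups by their highest
responsibility.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, logsumexp
from statsmodels.tools.numdiff import approx_hess

from .models import ModelSpec, get_model, model_nll, MODEL_ORDER
from .session import Session

logger = logging.getLogger(__name__)

__all__ = [
    "Prior", "FitConfig", "FitResult", "CohortComparison",
    "map_fit", "aic", "oos_accuracy", "fit_cohort", "cohort_compare",
    "classify_groups",
]


@dataclass(frozen=True)
class Prior:
    """Independent normal prior on each unconstrained parameter."""

    mean: float = 0.0
    variance: float = 6.25

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("prior variance must be > 0")

    def logpdf(self, x: np.ndarray) -> float:
        k = len(x)
        return float(-0.5 * k * np.log(2 * np.pi * self.variance)
                     - 0.5 * np.sum((x - self.mean) ** 2) / self.variance)

    def sample(self, k: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mean, np.sqrt(self.variance), size=k)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for MAP fitting.

    ``n_restarts`` includes one deterministic start at the prior mean; the
    rest are prior draws.  The quasi-Newton runs converge to 1e-6 on the
    objective.
    """

    n_restarts: int = 6
    tol: float = 1e-6
    maxiter: int = 400
    seed: int = 0


@dataclass
class FitResult:
    """Per-subject, per-model MAP fit summary."""

    model: str
    params: Dict[str, float]           # constrained space
    x: np.ndarray                      # unconstrained MAP
    nll: float                         # negative log likelihood at MAP
    log_evidence: float                # Laplace approximation
    aic: float
    oos_accuracy: Optional[float] = None
    n_restarts_ok: int = 0
    best_objective: float = np.nan
    subject_id: str = ""
    warnings: List[str] = field(default_factory=list)


def _objective(x, model: ModelSpec, arr, prior: Prior, mask=None) -> float:
    params = model.to_constrained(x)
    try:
        nll = model_nll(arr, model, params, mask=mask)
    except FloatingPointError:
        return 1e10
    return nll - prior.logpdf(np.asarray(x))


def _nearest_pd(h: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Symmetrize and clip eigenvalues so the Hessian is positive definite."""
    h = 0.5 * (h + h.T)
    w, v = np.linalg.eigh(h)
    w = np.clip(w, eps, None)
    return (v * w) @ v.T


def map_fit(session: Session, model, prior: Prior = Prior(),
            config: FitConfig = FitConfig(),
            rng: Optional[np.random.Generator] = None,
            mask: Optional[np.ndarray] = None) -> FitResult:
    """MAP estimate + Laplace log evidence for one model on one session.

    ``mask`` restricts the scored trials (used by leave-one-block-out
    cross-validation); latent updates always see the full sequence.
    """
    if isinstance(model, str):
        model = get_model(model)
    arr = session.arrays()
    usable = arr.choice >= 0
    if mask is not None:
        usable = usable & mask
    if not np.any(usable):
        raise ValueError("no usable (non-missing) choices to fit")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    k = model.k
    if k == 0:  # degenerate parameter-free model: evidence == log likelihood
        nll = model_nll(arr, model, {}, mask=mask)
        return FitResult(model=model.name, params={}, x=np.zeros(0),
                         nll=nll, log_evidence=-nll, aic=aic_score(0, nll),
                         best_objective=nll, subject_id=session.subject_id)
    best = None
    n_ok = 0
    msgs: List[str] = []
    starts = [np.zeros(k)] + [prior.sample(k, rng)
                              for _ in range(config.n_restarts - 1)]
    for x0 in starts:
        try:
            res = minimize(_objective, x0, args=(model, arr, prior, mask),
                           method="L-BFGS-B", tol=config.tol,
                           options={"maxiter": config.maxiter})
        except Exception as err:  # pragma: no cover
            msgs.append(f"restart failed: {err}")
            continue
        if not np.isfinite(res.fun):
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {config.n_restarts} restarts failed for model "
            f"{model.name} on {session.subject_id}: {msgs}")

    x = np.asarray(best.x)
    params = model.to_constrained(x)
    nll = model_nll(arr, model, params, mask=mask)
    logpost = -best.fun  # = loglik + logprior at the mode
    hess = approx_hess(x, _objective, args=(model, arr, prior, mask))
    sign, logdet = np.linalg.slogdet(hess)
    if sign <= 0 or not np.isfinite(logdet):
        msgs.append("non-positive-definite Hessian repaired")
        logger.warning("nearest-PD repair of Hessian (%s, %s)",
                       model.name, session.subject_id)
        _, logdet = np.linalg.slogdet(_nearest_pd(hess))
    log_evidence = logpost + 0.5 * k * np.log(2 * np.pi) - 0.5 * logdet
    return FitResult(
        model=model.name, params=params, x=x, nll=nll,
        log_evidence=float(log_evidence), aic=aic_score(k, nll),
        n_restarts_ok=n_ok, best_objective=float(best.fun),
        subject_id=session.subject_id, warnings=msgs)


def aic_score(k: int, nll: float) -> float:
    return 2.0 * k + 2.0 * nll


def aic(fit: FitResult) -> float:
    """Akaike information criterion of a fit (lower is better)."""
    return aic_score(get_model(fit.model).k, fit.nll)


def oos_accuracy(session: Session, model, prior: Prior = Prior(),
                 config: FitConfig = FitConfig(),
                 rng: Optional[np.random.Generator] = None,
                 hard: bool = False) -> float:
    """Leave-one-block-out predictive accuracy.

    For each held-out block the model is fitted on the remaining blocks,
    latents are run over the full session, and the held-out block's choices
    are scored.  By default the score is the mean probability assigned to
    each observed choice; ``hard=True`` scores the fraction of choices
    predicted with probability > 0.5.
    """
    if isinstance(model, str):
        model = get_model(model)
    arr = session.arrays()
    blocks = np.unique(arr.block)
    if len(blocks) < 2:
        raise ValueError("leave-one-block-out needs >= 2 blocks")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    scores = []
    for b in blocks:
        held = arr.block == b
        scorable = held & (arr.choice >= 0)
        if not np.any(scorable):
            warnings.warn(f"block {b} has no usable choices; skipped")
            continue
        fit = map_fit(session, model, prior, config, rng=rng, mask=~held)
        _, p = model_nll(arr, model, fit.params, return_probs=True)
        p_choice = np.where(arr.choice == 1, p, 1.0 - p)[scorable]
        scores.append(np.mean(p_choice > 0.5) if hard
                      else float(np.mean(p_choice)))
    return float(np.mean(scores))


def fit_cohort(sessions: Sequence[Session],
               models: Optional[Sequence[str]] = None,
               prior: Prior = Prior(), config: FitConfig = FitConfig(),
               seed: int = 0, with_oos: bool = False) -> pd.DataFrame:
    """Fit every model to every session; one row per subject x model."""
    if models is None:
        models = MODEL_ORDER
    rows = []
    ss = np.random.SeedSequence(seed)
    for session, child in zip(sessions, ss.spawn(len(sessions))):
        rngs = [np.random.default_rng(s) for s in child.spawn(len(models))]
        for name, rng in zip(models, rngs):
            fit = map_fit(session, name, prior, config, rng=rng)
            if with_oos:
                fit.oos_accuracy = oos_accuracy(session, name, prior, config,
                                                rng=rng)
            row = {"subject_id": session.subject_id, "model": name,
                   "nll": fit.nll, "log_evidence": fit.log_evidence,
                   "aic": fit.aic, "oos_accuracy": fit.oos_accuracy,
                   "true_model": session.true_model}
            row.update({f"param_{p}": v for p, v in fit.params.items()})
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CohortComparison:
    """Random-effects model comparison over a cohort."""

    models: List[str]
    responsibilities: pd.DataFrame   # subjects x models, rows sum to 1
    frequencies: pd.Series           # expected model frequencies, sum to 1
    exceedance: pd.Series            # P(model is the most frequent)
    alpha: np.ndarray                # Dirichlet posterior counts
    groups: pd.Series = None         # argmax-responsibility label


def cohort_compare(log_evidence: pd.DataFrame,
                   n_mc: int = 100_000, seed: int = 0,
                   max_iter: int = 500, tol: float = 1e-8) -> CohortComparison:
    """Variational random-effects model selection over log evidences.

    ``log_evidence``: subjects (rows) x models (columns).  Responsibilities
    are posterior model probabilities under estimated population
    frequencies; exceedance probabilities come from Monte-Carlo sampling of
    the Dirichlet posterior.
    """
    if log_evidence.isna().any().any():
        bad = log_evidence.index[log_evidence.isna().any(axis=1)].tolist()
        raise ValueError(f"missing model evidence for subjects {bad}")
    lme = log_evidence.to_numpy(dtype=float)
    n_sub, n_mod = lme.shape
    alpha0 = np.ones(n_mod)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))
        log_r = log_u - logsumexp(log_u, axis=1, keepdims=True)
        r = np.exp(log_r)
        alpha_new = alpha0 + r.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    freq = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_mc)
    exceed = np.bincount(np.argmax(draws, axis=1),
                         minlength=n_mod) / n_mc
    models = list(log_evidence.columns)
    resp = pd.DataFrame(r, index=log_evidence.index, columns=models)
    comp = CohortComparison(
        models=models, responsibilities=resp,
        frequencies=pd.Series(freq, index=models),
        exceedance=pd.Series(exceed, index=models), alpha=alpha)
    comp.groups = classify_groups(comp)
    return comp


def classify_groups(comparison: CohortComparison) -> pd.Series:
    """Assign each subject to the model with highest responsibility.

    Exact ties go to the simpler model (fewer free parameters), with a
    logged warning.
    """
    resp = comparison.responsibilities
    ks = np.array([get_model(m).k for m in resp.columns])
    labels = []
    for sub, row in resp.iterrows():
        vals = row.to_numpy()
        top = np.flatnonzero(vals == vals.max())
        if len(top) > 1:
            logger.warning("responsibility tie for %s; choosing simpler model",
                           sub)
            top = top[np.argsort(ks[top], kind="stable")]
        labels.append(resp.columns[top[0]])
    return pd.Series(labels, index=resp.index, name="group")
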