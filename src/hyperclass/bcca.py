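"""Two-view Bayesian CCA (group factor analysis) for functional realignment.

The model couples the actor's and the observer's multivoxel activity through
a common low-rank latent space:

    x_m(n) = W_m z(n) + eps_m(n),      m in {actor, observer}
    z(n) ~ N(0, I_K)
    W_m[:, k] ~ N(0, alpha_mk^{-1} I)   (group-wise ARD per view x component)
    alpha_mk ~ Gamma(a0, b0),  tau_m ~ Gamma(a0, b0)
    eps_m(n) ~ N(0, tau_m^{-1} I)

The group-wise automatic relevance determination (ARD) prior lets each
component switch off independently per view, so a converged fit sorts the K
components into three kinds: *shared* (active loadings in both views),
*actor-specific* / *observer-specific* (active in one view), and *inactive*
(pruned everywhere).  The shared components define a linear map from the
observer's voxel space to the actor's, which is what hyperclassification
consumes: realigned observer activity can be decoded by a classifier trained
purely on the actor.

Inference is mean-field variational Bayes with the standard closed-form
coordinate updates; the fit is deterministic given the seed.  Fitting uses
unlabeled data only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import digamma, gammaln
from sklearn.utils.extmath import randomized_svd

from .data_model import SampleSet

VIEWS = ("actor", "observer")

#: Relative ARD relevance (expected squared loading norm) below which a
#: component counts as switched off in a view.
ARD_REL_TOL = 1e-3

#: Absolute floor: a component must explain at least this fraction of
#: per-voxel variance (standardized units) to count as present in a view.
#: Below ~0.2% per voxel a component is indistinguishable from sampling noise.
ARD_ABS_TOL = 2e-3

#: Hyperprior shape/rate for the Gamma priors on alpha and tau.  Effectively
#: flat; irrelevant components are then pruned by the ARD mechanism itself.
GAMMA_PRIOR = 1e-12


class BccaError(ValueError):
    pass


@dataclass
class BccaModel:
    """Converged variational fit of the two-view model.

    Loadings and latent statistics live on the standardized (per-voxel
    z-scored, training statistics) data scale.  ``component_type[k]`` is one
    of ``shared``, ``actor_specific``, ``observer_specific``, ``inactive``.
    """

    K: int
    W_actor: np.ndarray
    W_observer: np.ndarray
    alpha: np.ndarray              # 2 x K  (view x component ARD precisions)
    tau: np.ndarray                # per-view noise precision
    z_stats: dict                  # posterior moments over training samples
    component_type: np.ndarray     # length-K array of strings
    relevance: np.ndarray          # 2 x K expected squared loading norms
    mean_: dict = field(default_factory=dict)   # per-view training means
    std_: dict = field(default_factory=dict)    # per-view training stds
    converged: bool = False
    n_iter: int = 0
    elbo: float = np.nan
    seed: int = 0

    @property
    def shared_components(self) -> np.ndarray:
        return np.flatnonzero(self.component_type == "shared")

    @property
    def n_shared(self) -> int:
        return len(self.shared_components)

    def standardize_actor(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean_["actor"]) / self.std_["actor"]

    def standardize_observer(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean_["observer"]) / self.std_["observer"]


def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    return (x - mean) / std, mean, std


def _gamma_elbo(a_q: np.ndarray, b_q: np.ndarray, a0: float, b0: float) -> float:
    """E_q[log p(g)] + H[q(g)] for independent Gamma factors."""
    a_q = np.atleast_1d(np.asarray(a_q, dtype=float))
    b_q = np.atleast_1d(np.asarray(b_q, dtype=float))
    e_log = digamma(a_q) - np.log(b_q)
    e_val = a_q / b_q
    logp = a0 * np.log(b0) - gammaln(a0) + (a0 - 1.0) * e_log - b0 * e_val
    ent = a_q - np.log(b_q) + gammaln(a_q) + (1.0 - a_q) * digamma(a_q)
    return float(np.sum(logp + ent))


def fit_bcca(
    actor: SampleSet,
    observer: SampleSet,
    K: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> BccaModel:
    """Fit the two-view model on temporally paired, unlabeled data.

    Parameters
    ----------
    actor, observer:
        Paired sample sets: row n of both views must come from the same
        experimental time point.  Labels are ignored entirely.
    K:
        Total number of latent components (upper bound; ARD prunes excess).
    seed:
        Controls initialization (randomized SVD + jitter); the fit is a
        deterministic function of (data, K, seed).
    max_iter, tol:
        Variational updates stop when the relative change of the evidence
        lower bound falls below ``tol`` or after ``max_iter`` sweeps.
    """
    if actor.n_samples != observer.n_samples:
        raise BccaError(
            f"views are not paired: {actor.n_samples} vs {observer.n_samples} samples"
        )
    n = actor.n_samples
    if K < 1:
        raise BccaError("K must be >= 1")
    if K > n:
        raise BccaError(f"K={K} exceeds sample count {n}")

    xs, means, stds = {}, {}, {}
    for name, view in zip(VIEWS, (actor, observer)):
        xs[name], means[name], stds[name] = _standardize_fit(view.x)
    x_a, x_o = xs["actor"], xs["observer"]
    d = {"actor": x_a.shape[1], "observer": x_o.shape[1]}

    # --- initialization: randomized SVD of the concatenated views ----------
    rng = np.random.default_rng(seed)
    concat = np.hstack([x_a, x_o])
    u, s, _ = randomized_svd(
        concat, n_components=K, random_state=int(rng.integers(0, 2**31 - 1))
    )
    m_z = u * np.sqrt(s)                       # N x K latent means
    m_z = m_z + 0.01 * rng.standard_normal(m_z.shape)
    sigma_z = np.eye(K) * 1e-3
    ezz = m_z.T @ m_z + n * sigma_z

    w = {v: np.zeros((d[v], K)) for v in VIEWS}
    sigma_w = {v: np.eye(K) * 1e-3 for v in VIEWS}
    alpha_a = {v: np.full(K, GAMMA_PRIOR + d[v] / 2.0) for v in VIEWS}
    alpha_b = {v: np.ones(K) for v in VIEWS}
    tau_a = {v: GAMMA_PRIOR + n * d[v] / 2.0 for v in VIEWS}
    tau_b = {v: 1.0 for v in VIEWS}
    xsq = {"actor": float(np.sum(x_a**2)), "observer": float(np.sum(x_o**2))}
    xdata = {"actor": x_a, "observer": x_o}

    a0 = b0 = GAMMA_PRIOR
    elbo_prev = -np.inf
    elbo = -np.inf
    converged = False
    it = 0
    resid = {v: 0.0 for v in VIEWS}

    for it in range(1, max_iter + 1):
        # --- q(W_m): common row covariance per view ------------------------
        for v in VIEWS:
            alpha_mean = alpha_a[v] / alpha_b[v]
            tau_mean = tau_a[v] / tau_b[v]
            prec = np.diag(alpha_mean) + tau_mean * ezz
            c = cho_factor(prec, lower=True)
            sigma_w[v] = cho_solve(c, np.eye(K))
            w[v] = tau_mean * (xdata[v].T @ m_z) @ sigma_w[v]

        # --- q(alpha_mk) ---------------------------------------------------
        for v in VIEWS:
            ew2 = np.sum(w[v] ** 2, axis=0) + d[v] * np.diag(sigma_w[v])
            alpha_b[v] = b0 + 0.5 * ew2

        # --- q(tau_m) --------------------------------------------------------
        for v in VIEWS:
            ewtw = w[v].T @ w[v] + d[v] * sigma_w[v]
            resid[v] = (
                xsq[v]
                - 2.0 * float(np.sum((xdata[v] @ w[v]) * m_z))
                + float(np.sum(ewtw * ezz))
            )
            tau_b[v] = b0 + 0.5 * resid[v]

        # --- q(Z) ------------------------------------------------------------
        prec_z = np.eye(K)
        proj = np.zeros((n, K))
        for v in VIEWS:
            tau_mean = tau_a[v] / tau_b[v]
            ewtw = w[v].T @ w[v] + d[v] * sigma_w[v]
            prec_z += tau_mean * ewtw
            proj += tau_mean * (xdata[v] @ w[v])
        c = cho_factor(prec_z, lower=True)
        sigma_z = cho_solve(c, np.eye(K))
        m_z = proj @ sigma_z
        ezz = m_z.T @ m_z + n * sigma_z

        # --- evidence lower bound -------------------------------------------
        elbo = 0.5 * (n * K - np.trace(ezz))
        sign, logdet_z = np.linalg.slogdet(sigma_z)
        elbo += 0.5 * n * logdet_z
        for v in VIEWS:
            tau_mean = tau_a[v] / tau_b[v]
            e_log_tau = digamma(tau_a[v]) - np.log(tau_b[v])
            # recompute residual with the fresh q(Z)
            ewtw = w[v].T @ w[v] + d[v] * sigma_w[v]
            resid[v] = (
                xsq[v]
                - 2.0 * float(np.sum((xdata[v] @ w[v]) * m_z))
                + float(np.sum(ewtw * ezz))
            )
            elbo += 0.5 * n * d[v] * (e_log_tau - np.log(2 * np.pi))
            elbo -= 0.5 * tau_mean * resid[v]
            alpha_mean = alpha_a[v] / alpha_b[v]
            e_log_alpha = digamma(alpha_a[v]) - np.log(alpha_b[v])
            ew2 = np.sum(w[v] ** 2, axis=0) + d[v] * np.diag(sigma_w[v])
            sign, logdet_w = np.linalg.slogdet(sigma_w[v])
            elbo += 0.5 * d[v] * np.sum(e_log_alpha)
            elbo -= 0.5 * float(alpha_mean @ ew2)
            elbo += 0.5 * d[v] * logdet_w + 0.5 * d[v] * K
            elbo += _gamma_elbo(alpha_a[v], alpha_b[v], a0, b0)
            elbo += _gamma_elbo(tau_a[v], tau_b[v], a0, b0)

        if it > 1 and abs(elbo - elbo_prev) < tol * abs(elbo_prev):
            converged = True
            break
        elbo_prev = elbo

    relevance = np.vstack(
        [np.sum(w[v] ** 2, axis=0) + d[v] * np.diag(sigma_w[v]) for v in VIEWS]
    )
    component_type = _classify_components(relevance, (d["actor"], d["observer"]))

    return BccaModel(
        K=K,
        W_actor=w["actor"],
        W_observer=w["observer"],
        alpha=np.vstack([alpha_a[v] / alpha_b[v] for v in VIEWS]),
        tau=np.array([tau_a[v] / tau_b[v] for v in VIEWS]),
        z_stats={"mean": m_z, "cov": sigma_z},
        component_type=component_type,
        relevance=relevance,
        mean_={v: means[v] for v in VIEWS},
        std_={v: stds[v] for v in VIEWS},
        converged=converged,
        n_iter=it,
        elbo=float(elbo),
        seed=seed,
    )


def _classify_components(relevance: np.ndarray, d_m: tuple[int, int]) -> np.ndarray:
    """Sort components into shared / view-specific / inactive by ARD relevance.

    ``relevance[m, k]`` is the expected squared loading norm of component k
    in view m (this includes the ARD shrinkage of the posterior covariance,
    so a pruned component's relevance decays towards zero).  A component is
    present in a view when its relevance exceeds ``ARD_REL_TOL`` times the
    view's maximum AND it explains at least ``ARD_ABS_TOL`` of per-voxel
    variance; the absolute floor keeps near-null fits (where every
    component is noise-level and the relative criterion degenerates) from
    being declared shared.
    """
    out = np.empty(relevance.shape[1], dtype=object)
    present = np.zeros_like(relevance, dtype=bool)
    for m in range(2):
        ceiling = relevance[m].max()
        rel_ok = relevance[m] > ARD_REL_TOL * ceiling if ceiling > 0 else False
        abs_ok = relevance[m] / d_m[m] > ARD_ABS_TOL
        present[m] = rel_ok & abs_ok
    for k in range(relevance.shape[1]):
        a, o = present[0, k], present[1, k]
        if a and o:
            out[k] = "shared"
        elif a:
            out[k] = "actor_specific"
        elif o:
            out[k] = "observer_specific"
        else:
            out[k] = "inactive"
    return out


# ---------------------------------------------------------------------------
# Realignment
# ---------------------------------------------------------------------------

@dataclass
class RealignmentTransform:
    """Linear observer-voxels -> actor-voxels map through shared components.

    ``map`` has shape (actor voxels, observer voxels) and acts on
    standardized observer data; outputs are in standardized actor units.
    Its rank is at most the number of shared components.
    """

    map: np.ndarray
    n_shared: int
    provenance: dict = field(default_factory=dict)


def realignment_transform(model: BccaModel) -> RealignmentTransform:
    """Build the plug-in posterior-mean realignment operator.

    Given new observer activity ``x_o`` the latent posterior mean is
    ``E[z | x_o] = S tau_o W_o' x_o`` with ``S = (I + tau_o W_o' W_o)^{-1}``;
    the predicted actor activity keeps only the shared coordinates:
    ``x_a_hat = W_a[:, shared] E[z | x_o][shared]``.  The view-specific
    components still participate in the posterior, explaining away
    observer-specific variance before the shared part is read out.
    """
    k = model.K
    tau_o = model.tau[1]
    w_o = model.W_observer
    s = np.linalg.solve(np.eye(k) + tau_o * (w_o.T @ w_o), np.eye(k))
    encode = tau_o * s @ w_o.T                        # K x D_obs
    shared = model.shared_components
    t = model.W_actor[:, shared] @ encode[shared, :]  # D_act x D_obs
    return RealignmentTransform(
        map=t,
        n_shared=len(shared),
        provenance={"seed": model.seed, "K": model.K, "n_iter": model.n_iter},
    )


def realign(model: BccaModel, observer_new: SampleSet) -> SampleSet:
    """Predict actor-space activity for new observer samples.

    Returns a :class:`SampleSet` in standardized actor units with the
    observer's labels/run/trial metadata passed through unchanged.  With
    zero shared components the prediction is identically zero and a warning
    is emitted (downstream decoding then sits at chance).
    """
    if observer_new.n_voxels != model.W_observer.shape[0]:
        raise BccaError(
            f"observer voxel count {observer_new.n_voxels} does not match "
            f"model ({model.W_observer.shape[0]})"
        )
    t = realignment_transform(model)
    if t.n_shared == 0:
        warnings.warn(
            "model has zero shared components; realigned data are all-zero",
            stacklevel=2,
        )
        pred = np.zeros((observer_new.n_samples, model.W_actor.shape[0]))
    else:
        x_std = model.standardize_observer(observer_new.x)
        pred = x_std @ t.map.T
    return SampleSet(
        pred, observer_new.y, observer_new.run, observer_new.trial,
        voxel_index=None,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_bcca(model: BccaModel, path) -> None:
    """Write the model as <path>.npz (arrays) + <path>.json (hyperparameters)."""
    path = Path(path)
    np.savez(
        path.with_suffix(".npz"),
        W_actor=model.W_actor,
        W_observer=model.W_observer,
        alpha=model.alpha,
        tau=model.tau,
        z_mean=model.z_stats["mean"],
        z_cov=model.z_stats["cov"],
        relevance=model.relevance,
        component_type=model.component_type.astype(str),
        mean_actor=model.mean_["actor"],
        mean_observer=model.mean_["observer"],
        std_actor=model.std_["actor"],
        std_observer=model.std_["observer"],
    )
    sidecar = {
        "K": model.K,
        "seed": model.seed,
        "converged": bool(model.converged),
        "n_iter": model.n_iter,
        "elbo": model.elbo,
        "n_shared": int(model.n_shared),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_bcca(path) -> BccaModel:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"), allow_pickle=False)
    meta = json.loads(path.with_suffix(".json").read_text())
    return BccaModel(
        K=meta["K"],
        W_actor=arrays["W_actor"],
        W_observer=arrays["W_observer"],
        alpha=arrays["alpha"],
        tau=arrays["tau"],
        z_stats={"mean": arrays["z_mean"], "cov": arrays["z_cov"]},
        component_type=arrays["component_type"].astype(object),
        relevance=arrays["relevance"],
        mean_={"actor": arrays["mean_actor"], "observer": arrays["mean_observer"]},
        std_={"actor": arrays["std_actor"], "observer": arrays["std_observer"]},
        converged=meta["converged"],
        n_iter=meta["n_iter"],
        elbo=meta["elbo"],
        seed=meta["seed"],
    )
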