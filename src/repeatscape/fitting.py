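"""Boltzmann-machine learning of the Potts variants.

Each iteration samples an ensemble from the current model, measures its
observables, and moves the parameters along the likelihood gradient, which for
a maximum-entropy model is the difference between data and model averages:

    h_i(s)      += eps_m  * (f_i(s)   - f_i^model(s))
    lambda_ID   -= eps_ID * (P(ID)    - P^model(ID))       (lambda enters E with +)
    J_ij(s, t)   : L1-proximal step of strength gamma (four cases: a zero
                   coupling stays zero while the empirical gradient is inside
                   the gamma tube; it is released along the soft-thresholded
                   gradient when outside; an active coupling moves along the
                   soft-thresholded gradient and is clamped to zero if the
                   step crosses sign).

Learning stops when the largest discrepancy — max over |df1|, |df2| on masked
pairs, and id_penalty * |dP(ID)| when lambda is fitted — drops below tol.

The tied-repeat variants (single-repeat models extended to the pair) are fit
by symmetrizing both the data targets and the per-iteration model observables
across the two halves; with a repeat-symmetric initialization the parameter
ties then hold at every iteration by induction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import ObservableSet
from .potts import (
    InteractionMask,
    PottsModel,
    independent_model,
    make_mask_3d,
    make_mask_empty,
    make_mask_full,
    make_mask_intra_repeat,
    make_mask_linear,
    symmetrize_single_repeat,
)
from .sampling import ensemble_observables, metropolis_sample


@dataclass
class FitConfig:
    """Gradient-ascent hyperparameters (defaults follow the published protocol)."""

    eps_m: float = 0.1      # field step
    eps_j: float = 0.05     # coupling step
    eps_id: float = 10.0    # overlap-multiplier step
    gamma: float = 0.001    # L1 strength on couplings
    tol: float = 0.02       # convergence threshold on the max observable error
    id_penalty: float = 5.0  # weighting of the P(ID) error in the criterion
    n_samples: int = 80000  # MC sequences per iteration
    thinning: int = 1000    # proposals between kept sequences
    burn_in: int | None = None  # default 10 x thinning
    max_iters: int = 500
    seed: int = 0

    def __post_init__(self):
        if min(self.eps_m, self.eps_j, self.eps_id) <= 0:
            raise ValueError("step sizes must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FitReport:
    iterations: int
    converged: bool
    max_err_f1: float
    max_err_f2: float
    max_err_pid: float
    error_trace: list = field(default_factory=list)  # per-iteration max error

    @property
    def max_error(self) -> float:
        return max(self.max_err_f1, self.max_err_f2, self.max_err_pid)


def _symmetrize_model_obs(f1: np.ndarray, f2: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Average model observables over the two repeat halves (intra-repeat blocks)."""
    f1 = f1.copy()
    f1[:L] = f1[L:] = 0.5 * (f1[:L] + f1[L:])
    f2 = f2.copy()
    intra = 0.5 * (f2[:L, :L] + f2[L:, L:])
    f2[:L, :L] = intra
    f2[L:, L:] = intra
    return f1, f2


def _coupling_update(J: np.ndarray, grad: np.ndarray, eps_j: float, gamma: float) -> np.ndarray:
    """The four-case L1-proximal coupling step, vectorized over one (q, q) view."""
    out = np.zeros_like(J)
    zero = J == 0.0
    # zero couplings: stay zero inside the gamma tube, else released soft-thresholded
    release = zero & (np.abs(grad) > gamma)
    out[release] = eps_j * (grad[release] - gamma * np.sign(grad[release]))
    # active couplings: soft-thresholded step, clamped to zero on sign crossing
    act = ~zero
    cand = J[act] + eps_j * (grad[act] - gamma * np.sign(J[act]))
    cand[cand * J[act] < 0] = 0.0
    out[act] = cand
    return out


def fit_model(
    obs: ObservableSet,
    init: PottsModel,
    cfg: FitConfig,
    fit_J: bool = True,
    fit_lambda: bool = True,
    tie_repeats: bool = False,
) -> tuple[PottsModel, FitReport]:
    """Fit fields, couplings (within init's mask), and overlap multipliers to obs.

    Non-convergence at max_iters is reported, not raised. The returned model is
    the first whose sampled observables meet the criterion (or the last
    iterate).
    """
    if (init.L, init.q) != (obs.L, obs.q):
        raise ValueError("init model and observables must share (L, q)")
    L, q, n = obs.L, obs.q, 2 * obs.L
    mask = init.mask
    triu_mask = np.triu(mask.allowed, 1)
    pairs = np.argwhere(triu_mask)
    target_f1, target_f2 = obs.f1, obs.f2
    if tie_repeats:
        sym = symmetrize_single_repeat(obs)
        target_f1, target_f2 = sym.f1, sym.f2
        if mask.allowed[:L, L:].any():
            raise ValueError("tied-repeat fits require an intra-repeat mask")

    model = PottsModel(init.h.copy(), init.J.copy(), init.lam.copy(), mask)
    seeds = np.random.default_rng(cfg.seed).integers(0, 2**31, size=cfg.max_iters)
    burn_in = cfg.burn_in if cfg.burn_in is not None else 10 * cfg.thinning
    trace: list[float] = []
    err_f1 = err_f2 = err_pid = np.inf
    converged = False
    it = 0
    for it in range(1, cfg.max_iters + 1):
        ens = metropolis_sample(
            model, cfg.n_samples, alpha=1.0, thinning=cfg.thinning,
            burn_in=burn_in, seed=int(seeds[it - 1]),
        )
        mobs = ensemble_observables(ens)
        mf1, mf2 = mobs.f1, mobs.f2
        if tie_repeats:
            mf1, mf2 = _symmetrize_model_obs(mf1, mf2, L)

        d1 = target_f1 - mf1
        err_f1 = float(np.abs(d1).max())
        if fit_J and len(pairs):
            d2 = target_f2 - mf2
            err_f2 = float(np.abs(d2[triu_mask]).max())
        else:
            d2 = None
            err_f2 = 0.0
        dpid = obs.p_id - mobs.p_id
        err_pid = float(cfg.id_penalty * np.abs(dpid).max()) if fit_lambda else 0.0
        trace.append(max(err_f1, err_f2, err_pid))
        if trace[-1] < cfg.tol:
            converged = True
            break

        model.h = model.h + cfg.eps_m * d1
        if fit_lambda:
            model.lam = model.lam - cfg.eps_id * dpid
        if fit_J and len(pairs):
            for i, j in pairs:
                blk = _coupling_update(model.J[i, j], d2[i, j], cfg.eps_j, cfg.gamma)
                model.J[i, j] = blk
                model.J[j, i] = blk.T
    report = FitReport(
        iterations=it,
        converged=converged,
        max_err_f1=err_f1,
        max_err_f2=err_f2,
        max_err_pid=err_pid,
        error_trace=trace,
    )
    return model, report


VARIANTS = ("E_rand", "E_1", "E_ir", "E_ir_lambda", "E_2", "E_full")


def fit_variant_suite(
    obs: ObservableSet, cfg: FitConfig, variants=VARIANTS, pseudocount: float = 1e-6
) -> tuple[dict, dict]:
    """Fit the standard model hierarchy; returns (models, reports).

    E_rand: all parameters zero. E_1: closed-form independent model (no
    sampling). E_ir / E_ir_lambda: tied single-repeat models without/with the
    overlap constraint (E_ir_lambda seeded from E_ir). E_full: full couplings
    plus overlap constraint. E_2: full couplings without the overlap
    constraint, seeded from E_full.
    """
    n = 2 * obs.L
    models: dict[str, PottsModel] = {}
    reports: dict[str, FitReport | None] = {}
    need = set(variants)
    if "E_2" in need:
        need.add("E_full")

    if "E_rand" in need:
        models["E_rand"] = PottsModel.zero(obs.L, obs.q)
        reports["E_rand"] = None
    if "E_1" in need:
        models["E_1"] = independent_model(obs, pseudocount)
        reports["E_1"] = None
    if "E_ir" in need or "E_ir_lambda" in need:
        sym = symmetrize_single_repeat(obs)
        init = independent_model(sym, pseudocount)
        init = PottsModel(init.h, np.zeros((n, n, obs.q, obs.q)), init.lam,
                          make_mask_intra_repeat(n))
        m_ir, r_ir = fit_model(obs, init, cfg, fit_J=True, fit_lambda=False,
                               tie_repeats=True)
        if "E_ir" in need:
            models["E_ir"], reports["E_ir"] = m_ir, r_ir
        if "E_ir_lambda" in need:
            models["E_ir_lambda"], reports["E_ir_lambda"] = fit_model(
                obs, m_ir, cfg, fit_J=True, fit_lambda=True, tie_repeats=True
            )
    if "E_full" in need:
        init = independent_model(obs, pseudocount)
        init = PottsModel(init.h, np.zeros((n, n, obs.q, obs.q)), init.lam,
                          make_mask_full(n))
        models["E_full"], reports["E_full"] = fit_model(
            obs, init, cfg, fit_J=True, fit_lambda=True
        )
    if "E_2" in need:
        init = models["E_full"].with_lambda_zero()
        models["E_2"], reports["E_2"] = fit_model(
            obs, init, cfg, fit_J=True, fit_lambda=False
        )
    models = {k: v for k, v in models.items() if k in set(variants)}
    reports = {k: v for k, v in reports.items() if k in set(variants)}
    return models, reports


def fit_range_sweep(
    obs: ObservableSet,
    cfg: FitConfig,
    ranges,
    mode: str = "linear",
    d3: np.ndarray | None = None,
    fit_lambda: bool = True,
    pseudocount: float = 1e-6,
) -> tuple[list[PottsModel], list[FitReport]]:
    """Fit a nested sequence of range-restricted models, each seeded from the last.

    `ranges` is an ascending list of linear ranges W (mode="linear") or 3D
    cutoffs in Angstrom (mode="3d", requires d3). Model k+1 starts from model
    k's parameters with the newly unmasked couplings at zero.
    """
    if list(ranges) != sorted(ranges):
        raise ValueError("ranges must be sorted ascending")
    if mode not in ("linear", "3d"):
        raise ValueError("mode must be 'linear' or '3d'")
    if mode == "3d" and d3 is None:
        raise ValueError("mode='3d' requires a distance matrix")
    n = 2 * obs.L
    prev = independent_model(obs, pseudocount)
    prev = PottsModel(prev.h, np.zeros((n, n, obs.q, obs.q)), prev.lam,
                      make_mask_empty(n))
    models: list[PottsModel] = []
    reports: list[FitReport] = []
    for k, r in enumerate(ranges):
        mask = make_mask_linear(n, int(r)) if mode == "linear" else make_mask_3d(d3, float(r))
        if not (mask.allowed | ~prev.mask.allowed).all():
            raise ValueError("masks must be nested: each range must contain the previous")
        init = PottsModel(prev.h.copy(), prev.J.copy(), prev.lam.copy(), mask)
        cfg_k = FitConfig(**{**cfg.__dict__, "seed": cfg.seed + k})
        m, rep = fit_model(obs, init, cfg_k, fit_J=mask.n_pairs > 0,
                           fit_lambda=fit_lambda)
        models.append(m)
        reports.append(rep)
        prev = m
    return models, reports
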