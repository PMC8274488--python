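"""Alternating optimization of codes, projections, dictionary and mu.

One iteration updates, in order: the sparse codes (l1 coding in each band's
subspace), the projections (per-band eigen-solution of the quadratic weighted
subproblem), the dictionary (gradient step with backtracking), and the
adaptive weight mu (closed form).  The monitored objective is the quadratic
weighted Fisher term plus the coding term; training stops when its relative
change falls below ``tol`` or after ``max_iters`` iterations.  Everything is
deterministic given ``config.seed``.
"""

from __future__ import annotations

import math

import numpy as np

from .coding import code_dataset, coding_objective
from .data_model import (
    MultiBandDataset,
    OpfddlModel,
    ProjectionSet,
    TrainConfig,
    standardize_apply,
    standardize_fit,
)
from .dictionary import dictionary_gradient, update_dictionary
from .ksvd import init_dictionary, init_projections
from .projection import qwo_objective, trace_sums, update_mu, update_projection
from .scatter import compute_scatters

__all__ = ["fit", "objective"]


def objective(dataset, D, projections, codes, mu, lam) -> tuple[float, float]:
    """(qwo_term, coding_term) of the current state; their sum drives stopping."""
    scatters = compute_scatters(dataset, D, codes)
    return (
        qwo_objective(projections, scatters, mu),
        coding_objective(dataset, projections, D, codes, lam),
    )


def fit(dataset: MultiBandDataset, config: TrainConfig) -> OpfddlModel:
    """Train a model on a multi-band dataset (Fisher discriminative dictionary
    learning with optimized per-band projections)."""
    rng = np.random.default_rng(config.seed)
    means = scales = None
    if config.standardize:
        means, scales = standardize_fit(dataset)
        dataset = standardize_apply(dataset, means, scales)

    m = dataset.n_features
    d = config.subspace_dim(m)
    n_total = dataset.n_samples * dataset.n_bands
    lam = config.sparsity_weight

    D, codes = init_dictionary(dataset, config, rng=rng)
    projections = ProjectionSet(init_projections(m, d, dataset.n_bands, rng))
    mu = 1.0

    qwo0, code0 = objective(dataset, D, projections, codes, mu, lam)
    prev_obj = qwo0 + code0
    trace: list[float] = []
    diagnostics: list[dict] = [{"iteration": 0, "objective": prev_obj,
                                "qwo_term": qwo0, "coding_term": code0, "mu": mu}]

    for it in range(1, config.max_iters + 1):
        # S-step: l1 coding in the current subspaces
        codes = code_dataset(dataset, projections, D, lam)
        scatters = compute_scatters(dataset, D, codes)

        # Q-step: per-band eigen-solution; never increases the QWO term
        qwo_before_q = qwo_objective(projections, scatters, mu)
        projections = ProjectionSet(
            [update_projection(p.W_w, p.W_b, mu, d) for p in scatters]
        )
        qwo_after_q = qwo_objective(projections, scatters, mu)

        # D-step: gradient with backtracking on the QWO term
        grad = dictionary_gradient(dataset, D, codes, projections, mu, config.dict_variant)
        step = config.dict_step
        base = qwo_after_q
        accepted = False
        for _ in range(config.max_backtracks + 1):
            D_try = update_dictionary(D, grad, step, n_total)
            sc_try = compute_scatters(dataset, D_try, codes)
            if qwo_objective(projections, sc_try, mu) <= base + 1e-12:
                D, scatters = D_try, sc_try
                accepted = True
                break
            step *= 0.5
        # if every halving still increases the objective, keep the old D

        # mu-step: closed form; never increases the QWO term
        qwo_before_mu = qwo_objective(projections, scatters, mu)
        mu = update_mu(projections, scatters, config.mu_ceiling)
        qwo_after_mu = qwo_objective(projections, scatters, mu)

        J_w, J_b = trace_sums(projections, scatters)
        coding_term = coding_objective(dataset, projections, D, codes, lam)
        obj = qwo_after_mu + coding_term
        if not math.isfinite(obj):
            raise FloatingPointError(f"divergence error at iteration {it}")
        trace.append(obj)
        diagnostics.append({
            "iteration": it,
            "objective": obj,
            "qwo_term": qwo_after_mu,
            "coding_term": coding_term,
            "mu": mu,
            "J_w": J_w,
            "J_b": J_b,
            "qwo_before_q": qwo_before_q,
            "qwo_after_q": qwo_after_q,
            "qwo_before_mu": qwo_before_mu,
            "qwo_after_mu": qwo_after_mu,
            "dict_step_used": step if accepted else 0.0,
        })
        rel = abs(obj - prev_obj) / max(abs(prev_obj), 1.0)
        prev_obj = obj
        if rel < config.tol:
            break

    return OpfddlModel(
        dictionary=D,
        projections=projections,
        mu=mu,
        config=config,
        objective_trace=np.array(trace),
        band_names=list(dataset.band_names),
        diagnostics=diagnostics,
        feature_means=means,
        feature_scales=scales,
    )
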