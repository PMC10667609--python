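"""Adaptive blockwise random-walk Metropolis sampler, vectorised across chains.

All chains advance in lockstep: every state component carries a leading
chain axis, proposals are drawn for all chains at once, and the accept /
reject step is a per-chain mask.  Proposal step sizes adapt per block and
per chain during burn-in (Robbins–Monro on the log step scale, targeting
the usual 0.44 / 0.3 acceptance rates for scalar / vector blocks) and are
frozen afterwards so the post-burn-in kernel is a valid MCMC kernel.

The retained-draw bookkeeping is exact by construction: with ``n_chains``
chains, ``n_iterations`` post-burn-in iterations and thinning ``thin``,
exactly ``n_chains * n_iterations // thin`` draws per quantity are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BlockSpec", "BlockModel", "run_sampler", "SamplerResult"]


@dataclass
class BlockSpec:
    """One Metropolis update block: a named group of parameters.

    ``base_scale`` sets the relative proposal scale of each component
    (units of the parameter); the adaptive per-chain multiplier rides on
    top of it.
    """

    name: str
    base_scale: np.ndarray

    def __post_init__(self) -> None:
        self.base_scale = np.atleast_1d(np.asarray(self.base_scale, dtype=float))
        if np.any(self.base_scale <= 0):
            raise ValueError(f"block {self.name!r}: base_scale must be positive")

    @property
    def size(self) -> int:
        return self.base_scale.size


class BlockModel:
    """Interface a model must implement to be sampled by :func:`run_sampler`.

    Subclasses provide the state container (any object whose arrays have a
    leading chain axis), the block list, and per-block log-posterior
    evaluations.  ``block_logpost`` must return every log-posterior term
    that depends on the block's parameters, evaluated at ``values`` with
    all other components taken from ``state``; terms that do not involve
    the block may be omitted (they cancel in the Metropolis ratio).
    """

    def init_state(self, n_chains: int, rng: np.random.Generator):
        raise NotImplementedError

    def blocks(self) -> list[BlockSpec]:
        raise NotImplementedError

    def block_values(self, state, name: str) -> np.ndarray:
        raise NotImplementedError

    def block_logpost(self, state, name: str, values: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def set_block(self, state, name: str, values: np.ndarray, accept: np.ndarray) -> None:
        raise NotImplementedError

    def extract(self, state) -> dict[str, np.ndarray]:
        """Map state to named scalar quantities, each of shape (n_chains,)."""
        raise NotImplementedError


@dataclass
class SamplerResult:
    draws: dict[str, np.ndarray]  # each (n_chains, n_retained)
    acceptance: dict[str, float]
    n_chains: int
    n_retained_per_chain: int

    @property
    def n_retained(self) -> int:
        return self.n_chains * self.n_retained_per_chain


def run_sampler(
    model: BlockModel,
    *,
    n_chains: int,
    n_burnin: int,
    n_iterations: int,
    thin: int,
    seed: int,
    adapt_gamma: float = 0.05,
) -> SamplerResult:
    """Run the blockwise Metropolis sampler.

    Parameters follow the usual schedule semantics: ``n_burnin`` adaptive
    warm-up iterations are discarded, then ``n_iterations`` iterations are
    run with frozen step sizes and every ``thin``-th is retained.
    """
    if n_iterations % thin != 0:
        raise ValueError("thin must divide n_iterations evenly")
    if min(n_chains, n_burnin + 1, n_iterations, thin) < 1:
        raise ValueError("all schedule counts must be positive")

    rng = np.random.default_rng(seed)
    state = model.init_state(n_chains, rng)
    blocks = model.blocks()
    targets = {b.name: (0.44 if b.size == 1 else 0.30) for b in blocks}
    log_step = {b.name: np.zeros(n_chains) for b in blocks}
    acc_count = {b.name: 0.0 for b in blocks}

    n_retained = n_iterations // thin
    sample0 = model.extract(state)
    store = {
        k: np.empty((n_chains, n_retained), dtype=float) for k in sample0
    }
    kept = 0

    total = n_burnin + n_iterations
    for it in range(total):
        adapting = it < n_burnin
        if adapting:
            gamma = adapt_gamma * min(1.0, 100.0 / (1.0 + it))
            gamma = max(gamma, 0.005)
        for b in blocks:
            cur = model.block_values(state, b.name)
            step = np.exp(log_step[b.name])[:, None] * b.base_scale[None, :]
            prop = cur + step * rng.standard_normal(cur.shape)
            lp_cur = model.block_logpost(state, b.name, cur)
            lp_prop = model.block_logpost(state, b.name, prop)
            with np.errstate(invalid="ignore"):
                delta = lp_prop - lp_cur
            accept = np.log(rng.random(n_chains)) < delta
            accept &= np.isfinite(lp_prop)
            if accept.any():
                model.set_block(state, b.name, prop, accept)
            if adapting:
                log_step[b.name] += gamma * (accept.astype(float) - targets[b.name])
            else:
                acc_count[b.name] += accept.mean()
        if not adapting:
            it_post = it - n_burnin
            if (it_post + 1) % thin == 0:
                sample = model.extract(state)
                for k, v in sample.items():
                    store[k][:, kept] = v
                kept += 1

    assert kept == n_retained
    acceptance = {k: v / n_iterations for k, v in acc_count.items()}
    return SamplerResult(
        draws=store,
        acceptance=acceptance,
        n_chains=n_chains,
        n_retained_per_chain=n_retained,
    )
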