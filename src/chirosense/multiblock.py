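"""Multiblock decomposition and regression: consensus PCA (MBPCA) and MBPLS.

The consensus formulation with super-score deflation is used, so MBPLS
predictions coincide exactly with PLS2 on the concatenated, identically
preprocessed matrix — that equivalence doubles as the correctness oracle.
Block importance per latent variable is the squared block-weight norm share.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chemometrics import PLSModel, pls_fit, pls_predict
from .errors import AlignmentError, ConfigurationError, ConvergenceError, DimensionError
from .preprocessing import SpectralBlock, concatenate

BlockName = tuple[str, str]


@dataclass
class MBPLSModel:
    pls: PLSModel  # fitted on the concatenated (block-scaled) space
    block_names: list[BlockName]
    spans: dict[BlockName, tuple[int, int]]
    block_weights: dict[BlockName, np.ndarray]  # variables_b x LV (unit norm per LV)
    block_scores: dict[BlockName, np.ndarray]  # samples x LV, t_b = X_b w_b / ||w_b||
    block_loadings: dict[BlockName, np.ndarray]  # variables_b x LV
    super_scores: np.ndarray  # samples x LV (= PLS scores)
    super_weights: np.ndarray  # LV x blocks, from the inner relation
    block_importance_: np.ndarray  # LV x blocks, rows sum to 1

    @property
    def n_lv(self) -> int:
        return self.pls.n_lv


def _check_blocks(blocks: Sequence[SpectralBlock]) -> None:
    if not blocks:
        raise ConfigurationError("need at least one block")
    ids = blocks[0].sample_ids
    for b in blocks:
        if b.sample_ids != ids:
            raise AlignmentError("blocks disagree on sample ids")


def mbpls_fit(blocks: Sequence[SpectralBlock], Y: np.ndarray, n_lv: int) -> MBPLSModel:
    """Fit consensus MBPLS on preprocessed blocks.

    Per LV the concatenated PLS2 weight is split by block into w_b; block
    scores are t_b = X_b w_b / ||w_b||; the super score is the PLS2 score and
    super weights come from regressing it on the block scores.
    """
    _check_blocks(blocks)
    X, spans = concatenate(blocks)
    pls = pls_fit(X, Y, n_lv)
    n_lv = pls.n_lv  # may be truncated at the data rank
    names = [b.name for b in blocks]
    Xc = X - pls.x_mean

    block_weights: dict[BlockName, np.ndarray] = {}
    block_scores: dict[BlockName, np.ndarray] = {}
    block_loadings: dict[BlockName, np.ndarray] = {}
    importance = np.zeros((n_lv, len(names)))
    super_weights = np.zeros((n_lv, len(names)))

    # Recreate per-LV deflated matrices to expose block-level quantities.
    E = Xc.copy()
    t_blocks_all = {name: np.zeros((X.shape[0], n_lv)) for name in names}
    for name in names:
        s0, s1 = spans[name]
        block_weights[name] = np.zeros((s1 - s0, n_lv))
        block_loadings[name] = np.zeros((s1 - s0, n_lv))
    for a in range(n_lv):
        w = pls.W[:, a]
        t = pls.T[:, a]
        norms_sq = np.array([float(w[spans[n][0]: spans[n][1]] @ w[spans[n][0]: spans[n][1]]) for n in names])
        importance[a] = norms_sq / norms_sq.sum()
        tb_mat = np.zeros((X.shape[0], len(names)))
        for j, name in enumerate(names):
            s0, s1 = spans[name]
            w_b = w[s0:s1]
            nw = np.linalg.norm(w_b)
            w_b_unit = w_b / nw if nw > 0 else w_b
            t_b = E[:, s0:s1] @ w_b_unit
            block_weights[name][:, a] = w_b_unit
            t_blocks_all[name][:, a] = t_b
            tb_mat[:, j] = t_b
            block_loadings[name][:, a] = E[:, s0:s1].T @ t / (t @ t)
        # inner relation: super score as a combination of block scores
        omega, *_ = np.linalg.lstsq(tb_mat, t, rcond=None)
        super_weights[a] = omega
        E = E - np.outer(t, pls.P[:, a])
    for name in names:
        block_scores[name] = t_blocks_all[name]

    return MBPLSModel(
        pls=pls,
        block_names=names,
        spans=spans,
        block_weights=block_weights,
        block_scores=block_scores,
        block_loadings=block_loadings,
        super_scores=pls.T.copy(),
        super_weights=super_weights,
        block_importance_=importance,
    )


def mbpls_predict(model: MBPLSModel, blocks_new: Sequence[SpectralBlock]) -> np.ndarray:
    _check_blocks(blocks_new)
    names = [b.name for b in blocks_new]
    if names != model.block_names:
        raise AlignmentError(
            f"block order {names} does not match fitted order {model.block_names}"
        )
    X, _ = concatenate(blocks_new)
    return pls_predict(model.pls, X)


def block_importance(model: MBPLSModel) -> np.ndarray:
    """LV x block matrix of squared block-weight norm shares; rows sum to 1."""
    return model.block_importance_.copy()


# ---------------------------------------------------------------------------
# Consensus PCA (MBPCA)
# ---------------------------------------------------------------------------


@dataclass
class MBPCAModel:
    block_names: list[BlockName]
    spans: dict[BlockName, tuple[int, int]]
    mean_: np.ndarray  # concatenated column means
    block_scores: dict[BlockName, np.ndarray]  # samples x PC
    block_loadings: dict[BlockName, np.ndarray]  # variables_b x PC (unit norm)
    concat_loadings: np.ndarray  # total variables x PC (deflation loadings)
    super_scores: np.ndarray  # samples x PC
    super_weights: np.ndarray  # PC x blocks (unit norm rows)
    explained_variance_per_block: np.ndarray  # PC x blocks (fraction of block SS)
    explained_variance_ratio_: np.ndarray  # overall, per PC
    n_pc: int


def mbpca_fit(blocks: Sequence[SpectralBlock], n_pc: int) -> MBPCAModel:
    """Consensus PCA with super-score deflation.

    Each super score is the fixed point the consensus-NIPALS iteration
    converges to — the leading principal component of the current residual —
    and is solved exactly per PC (SVD of the residual) so the super-score
    subspace equals the PCA subspace of the concatenated matrix by
    construction. Block scores, unit-norm block loadings and unit-norm super
    weights (from regressing the super score on the block scores) are exposed
    per PC.
    """
    _check_blocks(blocks)
    X, spans = concatenate(blocks)
    n, p = X.shape
    if not 1 <= n_pc <= min(n - 1, p):
        raise DimensionError(f"n_pc must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    names = [b.name for b in blocks]
    mean = X.mean(axis=0)
    E = X - mean
    ss_block0 = {nm: float(np.sum(E[:, spans[nm][0]: spans[nm][1]] ** 2)) for nm in names}
    ss_total0 = float(np.sum(E**2))

    super_scores = np.zeros((n, n_pc))
    super_weights = np.zeros((n_pc, len(names)))
    block_scores = {nm: np.zeros((n, n_pc)) for nm in names}
    block_loadings = {nm: np.zeros((spans[nm][1] - spans[nm][0], n_pc)) for nm in names}
    concat_loadings = np.zeros((p, n_pc))
    ev_block = np.zeros((n_pc, len(names)))
    evr = np.zeros(n_pc)

    for a in range(n_pc):
        U, s, Vt = np.linalg.svd(E, full_matrices=False)
        if s[0] <= 0:
            raise ConvergenceError(f"no variance left at component {a + 1}", index=a + 1)
        v = Vt[0]
        k = int(np.argmax(np.abs(v)))
        if v[k] < 0:
            v = -v
        t_T = E @ v
        tt = t_T @ t_T
        tb = np.zeros((n, len(names)))
        for j, nm in enumerate(names):
            s0, s1 = spans[nm]
            p_b = v[s0:s1].copy()
            npb = np.linalg.norm(p_b)
            if npb > 0:
                p_b /= npb
            block_loadings[nm][:, a] = p_b
            tb[:, j] = E[:, s0:s1] @ p_b
            block_scores[nm][:, a] = tb[:, j]
        omega, *_ = np.linalg.lstsq(tb, t_T, rcond=None)
        n_omega = np.linalg.norm(omega)
        super_weights[a] = omega / n_omega if n_omega > 0 else omega
        super_scores[:, a] = t_T
        resid_prev_total = float(np.sum(E**2))
        for nm in names:
            s0, s1 = spans[nm]
            p_full = E[:, s0:s1].T @ t_T / tt
            concat_loadings[s0:s1, a] = p_full
            prev = float(np.sum(E[:, s0:s1] ** 2))
            E[:, s0:s1] -= np.outer(t_T, p_full)
            ev_block[a, spans_index(names, nm)] = (
                (prev - float(np.sum(E[:, s0:s1] ** 2))) / ss_block0[nm]
                if ss_block0[nm] > 0
                else 0.0
            )
        evr[a] = (resid_prev_total - float(np.sum(E**2))) / ss_total0 if ss_total0 > 0 else 0.0

    return MBPCAModel(
        block_names=names,
        spans=spans,
        mean_=mean,
        block_scores=block_scores,
        block_loadings=block_loadings,
        concat_loadings=concat_loadings,
        super_scores=super_scores,
        super_weights=super_weights,
        explained_variance_per_block=ev_block,
        explained_variance_ratio_=evr,
        n_pc=n_pc,
    )


def spans_index(names: list[BlockName], name: BlockName) -> int:
    return names.index(name)


def mbpca_transform(model: MBPCAModel, blocks_new: Sequence[SpectralBlock]) -> np.ndarray:
    """Super scores of new samples by sequential projection/deflation."""
    _check_blocks(blocks_new)
    names = [b.name for b in blocks_new]
    if names != model.block_names:
        raise AlignmentError(
            f"block order {names} does not match fitted order {model.block_names}"
        )
    X, _ = concatenate(blocks_new)
    E = X - model.mean_
    scores = np.zeros((E.shape[0], model.n_pc))
    for a in range(model.n_pc):
        p_a = model.concat_loadings[:, a]
        t = E @ p_a / (p_a @ p_a)
        scores[:, a] = t
        E = E - np.outer(t, p_a)
    return scores
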