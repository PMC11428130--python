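"""Forward noising and the reverse ancestral sampler for ligand generation.

Only the coordinates ``r`` and atom types ``h_a`` of masked-ligand atoms are
diffused; the conditioning channel h_Lc and every context atom (metal +
unmasked ligands) stay fixed throughout.  The forward marginal at step t is
``x_t = alpha_t x_0 + sigma_t eps`` (variance-preserving); the reverse chain
is standard ancestral sampling from the learned noise prediction, with the
categorical ``h_a`` treated as a continuous one-hot vector and decoded by
argmax after the final step (ties break to the lowest channel index).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .complexes import TMComplex
from .config import DEFAULTS, Config
from .embedding import Context, PointCloudEmbedding, build_embedding, embedding_to_complex
from .gvp import DenoiserGVP
from .masking import LDgSpec, MaskingSample
from .schedule import NoiseSchedule, make_schedule


@dataclass
class DiffusionState:
    """Snapshot of the chain at step t (context block invariant by contract)."""

    embedding: PointCloudEmbedding
    t: int


def forward_diffuse(
    x: PointCloudEmbedding,
    t: int,
    rng: np.random.Generator,
    schedule: NoiseSchedule,
) -> tuple[PointCloudEmbedding, tuple[np.ndarray, np.ndarray]]:
    """Noise the masked block to step t; returns the noised embedding and the
    injected noise ``(eps_r, eps_h)`` for loss computation.

    ``t = 0`` is the identity (alpha=1, sigma=0).  Context atoms and h_Lc are
    untouched.
    """
    if not 0 <= t <= schedule.T:
        raise ValueError(f"step t={t} outside [0, {schedule.T}]")
    masked = x.masked_indices
    if masked.size == 0:
        raise ValueError("embedding has no masked atoms to diffuse")
    out = x.copy()
    a, s = schedule.alpha[t], schedule.sigma[t]
    eps_r = rng.standard_normal((masked.size, 3))
    eps_h = rng.standard_normal((masked.size, x.h_a.shape[1]))
    out.r[masked] = a * x.r[masked] + s * eps_r
    out.h_a[masked] = a * x.h_a[masked] + s * eps_h
    return out, (eps_r, eps_h)


def training_loss(
    batch: Sequence[tuple[TMComplex, MaskingSample]],
    model: DenoiserGVP,
    rng: np.random.Generator,
    schedule: Optional[NoiseSchedule] = None,
    config: Config = DEFAULTS,
    with_grad: bool = True,
) -> float:
    """Mean noise-prediction MSE over a batch of masked samples.

    For each (complex, masking) pair a step t is drawn uniformly from 1..T,
    the masked block is noised to t, and the model's prediction is scored
    against the injected noise over the masked atoms' r and h_a channels.
    Gradients (if requested) are accumulated on the model.
    """
    if not batch:
        raise ValueError("empty batch")
    schedule = schedule or make_schedule(config.steps, config.schedule)
    if with_grad:
        model.zero_grad()
    total = 0.0
    n = 0
    for cx, sample in batch:
        emb = build_embedding(cx, sample.masked_ligands, config=config)
        if emb.masked_indices.size == 0:
            raise ValueError(f"sample on {cx.source_id} has zero masked atoms")
        t = int(rng.integers(1, schedule.T + 1))
        noised, (eps_r, eps_h) = forward_diffuse(emb, t, rng, schedule)
        if with_grad:
            total += model.loss_and_grad(noised, t, eps_r, eps_h,
                                         T=schedule.T, accumulate=True)
        else:
            pr, ph = model.predict_noise(noised, t, T=schedule.T)
            k = emb.masked_indices.size
            total += float(np.sum((pr - eps_r) ** 2) + np.sum((ph - eps_h) ** 2)) / (
                k * (3 + model.m)
            )
        n += 1
    if with_grad:
        for _, _, g, k in model.named_params():
            g[k] /= n
    return total / n


def sample_ligands(
    context: Context,
    ldg: LDgSpec,
    sizes: Sequence[int],
    model: DenoiserGVP,
    seed: int,
    schedule: Optional[NoiseSchedule] = None,
    config: Config = DEFAULTS,
    noise_transform: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    total_cn: int = 6,
) -> TMComplex:
    """Generate the missing ligands of a context by reverse diffusion.

    The placeholder atoms of each generated ligand are initialised from a
    standard normal, then denoised over T reverse steps; only masked r and
    h_a change.  Per-ligand random substreams are spawned from ``seed`` so
    adding a ligand never perturbs an earlier ligand's draws, and draws are
    consumed in a fixed, rotation-independent order (``noise_transform``, if
    given, maps each coordinate-noise draw, e.g. to rotate it alongside a
    rotated context when checking equivariance).

    Returns the assembled complex; context atoms are byte-identical to the
    input for any seed.
    """
    schedule = schedule or make_schedule(config.steps, config.schedule)
    cx = context.complex
    if cx.ligands is None:
        raise ValueError("context complex must be partitioned")
    cn_g = total_cn - context.cn_c
    if sum(ldg.partition) != cn_g:
        raise ValueError(
            f"denticity budget mismatch: sum(LD_g)={sum(ldg.partition)} != CN_g={cn_g}"
        )
    # context ligands all kept; generated ligands appended as placeholders
    emb = build_embedding(cx, masked_ligands=[], ldg=ldg, sizes=sizes,
                          config=config, total_cn=total_cn)
    ctx_idx = emb.context_indices
    ctx_r0 = emb.r[ctx_idx].copy()
    ctx_h0 = emb.h_a[ctx_idx].copy()

    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(seed).spawn(len(emb.generated_codes))
    ]
    m = emb.h_a.shape[1]

    def draw(shape, k):
        z = streams[k].standard_normal(shape)
        return z

    def draw_r(shape, k):
        z = streams[k].standard_normal(shape)
        return noise_transform(z) if noise_transform is not None else z

    # initialise masked block from the prior
    for k, code in enumerate(emb.generated_codes):
        atoms = list(emb.ligand_atoms[code])
        emb.r[atoms] = draw_r((len(atoms), 3), k)
        emb.h_a[atoms] = draw((len(atoms), m), k)

    al, sig = schedule.alpha, schedule.sigma
    for t in range(schedule.T, 0, -1):
        eps_r, eps_h = model.predict_noise(emb, t, T=schedule.T)
        if not (np.all(np.isfinite(eps_r)) and np.all(np.isfinite(eps_h))):
            raise FloatingPointError(f"non-finite noise prediction at step t={t}")
        masked = emb.masked_indices
        s_prev = t - 1
        a_ts, var_ts = schedule.step_coeffs(t, s_prev)
        sig_ts = np.sqrt(var_ts)
        if s_prev == 0:
            # final step: deterministic denoised estimate x0 = (x_t - sigma eps)/alpha
            emb.r[masked] = (emb.r[masked] - sig[t] * eps_r) / al[t]
            emb.h_a[masked] = (emb.h_a[masked] - sig[t] * eps_h) / al[t]
        else:
            mu_r = emb.r[masked] / a_ts - (var_ts / (a_ts * sig[t])) * eps_r
            mu_h = emb.h_a[masked] / a_ts - (var_ts / (a_ts * sig[t])) * eps_h
            noise_scale = sig_ts * sig[s_prev] / sig[t]
            for k, code in enumerate(emb.generated_codes):
                atoms = list(emb.ligand_atoms[code])
                rows = np.searchsorted(masked, atoms)
                mu_r[rows] += noise_scale * draw_r((len(atoms), 3), k)
                mu_h[rows] += noise_scale * draw((len(atoms), m), k)
            emb.r[masked] = mu_r
            emb.h_a[masked] = mu_h
        if not np.all(np.isfinite(emb.r[masked])):
            raise FloatingPointError(f"non-finite coordinates at step t={t}")
        # contract: context block never moves
        assert np.array_equal(emb.r[ctx_idx], ctx_r0)

    # decode h_a to exact one-hots (argmax, ties -> lowest index); generated
    # atoms are ligand atoms, so decoding is restricted to non-metal channels
    from .elements import HEAVY_ELEMENTS, is_metal

    ligand_channels = np.array([not is_metal(e) for e in HEAVY_ELEMENTS])
    masked = emb.masked_indices
    scores = np.where(ligand_channels[None, :], emb.h_a[masked], -np.inf)
    hot = np.argmax(scores, axis=1)
    emb.h_a[masked] = 0.0
    emb.h_a[masked, hot] = 1.0

    assert np.array_equal(emb.r[ctx_idx], ctx_r0)
    assert np.array_equal(emb.h_a[ctx_idx], ctx_h0)
    out = embedding_to_complex(emb, metal=cx.metal,
                               source_id=f"{cx.source_id}:gen[{ldg.label}]:seed{seed}",
                               config=config)
    out.target_cn = total_cn
    return out
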