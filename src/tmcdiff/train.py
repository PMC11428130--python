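"""Training loop for the noise-prediction network (NumPy Adam)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .complexes import TMComplex
from .config import DEFAULTS, Config
from .diffusion import training_loss
from .gvp import DenoiserGVP
from .masking import MaskingSample
from .schedule import make_schedule

log = logging.getLogger(__name__)


class Adam:
    def __init__(self, model: DenoiserGVP, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = {name: np.zeros_like(p[k]) for name, p, _, k in model.named_params()}
        self.v = {name: np.zeros_like(p[k]) for name, p, _, k in model.named_params()}

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for name, p, g, k in self.model.named_params():
            grad = g[k]
            self.m[name] = b1 * self.m[name] + (1 - b1) * grad
            self.v[name] = b2 * self.v[name] + (1 - b2) * grad**2
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            p[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainResult:
    model: DenoiserGVP
    epoch_losses: list[float] = field(default_factory=list)
    steps: int = 0


def train(
    samples: Sequence[tuple[TMComplex, MaskingSample]],
    config: Config = DEFAULTS,
    epochs: int = 10,
    seed: int = 0,
    model: Optional[DenoiserGVP] = None,
    optimizer: Optional[Adam] = None,
) -> TrainResult:
    """Train the denoiser on (complex, masking) pairs.

    Deterministic for a given seed: shuffling, step draws and noise all come
    from one seeded generator.  Pass ``model``/``optimizer`` to resume.
    """
    if not samples:
        raise ValueError("no training samples")
    rng = np.random.default_rng(seed)
    schedule = make_schedule(config.steps, config.schedule)
    if model is None:
        model = DenoiserGVP(config, seed=seed)
    opt = optimizer or Adam(model, lr=config.learning_rate)
    result = TrainResult(model=model, steps=opt.t)
    order = np.arange(len(samples))
    bs = config.batch_size
    for epoch in range(epochs):
        rng.shuffle(order)
        losses = []
        for start in range(0, len(order), bs):
            batch = [samples[i] for i in order[start: start + bs]]
            loss = training_loss(batch, model, rng, schedule, config)
            opt.step()
            losses.append(loss)
            result.steps = opt.t
        epoch_loss = float(np.mean(losses))
        result.epoch_losses.append(epoch_loss)
        log.info("epoch %d/%d  loss %.5f", epoch + 1, epochs, epoch_loss)
    return result
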