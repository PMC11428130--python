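"""Equivariant noise-prediction network built from geometric vector perceptrons.

Each atom carries rotation-invariant scalar features ``s`` and rotation-
equivariant 3D vector features ``V``.  A GVP block mixes the two: vector
channels are linearly recombined, their norms feed the scalar path, and the
scalar path gates the vector output.  Message passing runs over the complete
graph (every atom except the atom itself is a neighbour), messages are
aggregated by mean, and each layer updates features residually.  All vector
operations are linear combinations over the channel dimension plus
invariant gating, so the network is O(3)-equivariant by construction:
rotating (or reflecting) the input coordinates rotates the predicted
coordinate noise and leaves the predicted atom-type noise unchanged.

The network, loss and optimizer are plain NumPy (float64) with hand-written
reverse-mode gradients; a finite-difference check in the test suite guards
the backward pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .config import DEFAULTS, Config
from .elements import HEAVY_ELEMENTS
from .embedding import HC_DIM, PointCloudEmbedding

_EPS_NORM = 1e-8
_EPS_DIST = 1e-9


@dataclass
class GVPFeatures:
    """Per-atom scalar (invariant) and vector (equivariant) features."""

    s: np.ndarray   # (N, n_s)
    V: np.ndarray   # (N, n_v, 3)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _silu(z):
    sg = _sigmoid(z)
    return z * sg, sg


def _silu_grad(z, sg):
    return sg * (1.0 + z * (1.0 - sg))


class _GVP:
    """One geometric vector perceptron; owns its parameters and gradients."""

    def __init__(self, name, ds_in, dv_in, ds_out, dv_out, h, rng):
        self.name = name
        self.ds_in, self.dv_in = ds_in, dv_in
        self.ds_out, self.dv_out, self.h = ds_out, dv_out, h
        def init(*shape):
            fan_in = shape[-1]
            return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)
        self.params = {
            "Wh": init(h, dv_in),
            "Ws": init(ds_out, ds_in + h),
            "bs": np.zeros(ds_out),
            "Wmu": init(dv_out, h),
            "Wg": init(dv_out, ds_out) * 0.1,
            "bg": np.zeros(dv_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, s, V):
        p = self.params
        Vh = np.einsum("hd,...di->...hi", p["Wh"], V)
        nrm = np.sqrt(np.sum(Vh**2, axis=-1) + _EPS_NORM)
        sc = np.concatenate([s, nrm], axis=-1)
        z = sc @ p["Ws"].T + p["bs"]
        so, sg = _silu(z)
        Vmu = np.einsum("oh,...hi->...oi", p["Wmu"], Vh)
        gpre = z @ p["Wg"].T + p["bg"]
        g = _sigmoid(gpre)
        Vo = Vmu * g[..., None]
        self._cache = (s, V, Vh, nrm, sc, z, sg, Vmu, g)
        return so, Vo

    def backward(self, dso, dVo):
        s, V, Vh, nrm, sc, z, sg, Vmu, g = self._cache
        p, gr = self.params, self.grads
        bdims = tuple(range(dso.ndim - 1))
        dVmu = dVo * g[..., None]
        dgpre = np.sum(dVo * Vmu, axis=-1) * g * (1.0 - g)
        gr["Wg"] += np.tensordot(dgpre, z, axes=(bdims, bdims))
        gr["bg"] += dgpre.sum(axis=bdims)
        dz = dgpre @ p["Wg"]
        dz += dso * _silu_grad(z, sg)
        gr["Ws"] += np.tensordot(dz, sc, axes=(bdims, bdims))
        gr["bs"] += dz.sum(axis=bdims)
        dsc = dz @ p["Ws"]
        ds = dsc[..., : self.ds_in]
        dnrm = dsc[..., self.ds_in:]
        dVh = (dnrm / nrm)[..., None] * Vh
        dVh += np.einsum("oh,...oi->...hi", p["Wmu"], dVmu)

        def _outer(a, b):  # (..., p, 3) x (..., q, 3) -> (p, q), summing batch+xyz
            af = a.reshape(-1, a.shape[-2], a.shape[-1])
            bf = b.reshape(-1, b.shape[-2], b.shape[-1])
            return np.einsum("bpi,bqi->pq", af, bf)

        gr["Wmu"] += _outer(dVmu, Vh)
        dV = np.einsum("hd,...hi->...di", p["Wh"], dVh)
        gr["Wh"] += _outer(dVh, V)
        self._cache = None
        return ds, dV


class _Linear:
    def __init__(self, name, d_in, d_out, rng, bias=True):
        self.name = name
        self.params = {"W": rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_out, d_in))}
        if bias:
            self.params["b"] = np.zeros(d_out)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x = None

    def forward(self, x):
        self._x = x
        y = x @ self.params["W"].T
        if "b" in self.params:
            y = y + self.params["b"]
        return y

    def backward(self, dy):
        bdims = tuple(range(dy.ndim - 1))
        self.grads["W"] += np.tensordot(dy, self._x, axes=(bdims, bdims))
        if "b" in self.params:
            self.grads["b"] += dy.sum(axis=bdims)
        dx = dy @ self.params["W"]
        self._x = None
        return dx


class _MessageLayer:
    """Complete-graph message passing with residual GVP update."""

    def __init__(self, idx, n_s, n_v, rbf_size, rng):
        h_msg = 2 * n_v + 1
        self.n_s, self.n_v, self.rbf_size = n_s, n_v, rbf_size
        self.gvp_msg = _GVP(f"layer{idx}.msg", 2 * n_s + rbf_size,
                            2 * n_v + 1, n_s, n_v, h_msg, rng)
        self.gvp_upd = _GVP(f"layer{idx}.upd", 2 * n_s, 2 * n_v, n_s, n_v,
                            2 * n_v, rng)
        self._cache = None

    def modules(self):
        return [self.gvp_msg, self.gvp_upd]

    def forward(self, s, V, edge_s, edge_vec):
        """edge_s: (N, N, rbf) invariant edge scalars; edge_vec: (N, N, 1, 3)
        unit displacement vectors (zero on the diagonal)."""
        N = s.shape[0]
        if N < 2:
            raise ValueError("message passing needs at least two atoms (no neighbours)")
        s_i = np.broadcast_to(s[:, None, :], (N, N, self.n_s))
        s_j = np.broadcast_to(s[None, :, :], (N, N, self.n_s))
        se = np.concatenate([s_i, s_j, edge_s], axis=-1)
        V_i = np.broadcast_to(V[:, None], (N, N, self.n_v, 3))
        V_j = np.broadcast_to(V[None, :], (N, N, self.n_v, 3))
        Ve = np.concatenate([V_i, V_j, edge_vec], axis=-2)
        m_s, m_V = self.gvp_msg.forward(se, Ve)
        mask = ~np.eye(N, dtype=bool)
        m_s = m_s * mask[..., None]
        m_V = m_V * mask[..., None, None]
        agg_s = m_s.sum(axis=1) / (N - 1)
        agg_V = m_V.sum(axis=1) / (N - 1)
        us_in = np.concatenate([s, agg_s], axis=-1)
        uV_in = np.concatenate([V, agg_V], axis=-2)
        u_s, u_V = self.gvp_upd.forward(us_in, uV_in)
        self._cache = (N, mask)
        return s + u_s, V + u_V

    def backward(self, ds_out, dV_out):
        N, mask = self._cache
        dus, duV = self.gvp_upd.backward(ds_out, dV_out)
        ds = ds_out + dus[..., : self.n_s]
        dagg_s = dus[..., self.n_s:]
        dV = dV_out + duV[..., : self.n_v, :]
        dagg_V = duV[..., self.n_v:, :]
        dm_s = np.broadcast_to(dagg_s[:, None, :], (N, N, self.n_s)) / (N - 1)
        dm_V = np.broadcast_to(dagg_V[:, None], (N, N, self.n_v, 3)) / (N - 1)
        dm_s = dm_s * mask[..., None]
        dm_V = dm_V * mask[..., None, None]
        dse, dVe = self.gvp_msg.backward(dm_s, dm_V)
        ds += dse[..., : self.n_s].sum(axis=1) + dse[..., self.n_s: 2 * self.n_s].sum(axis=0)
        dV += dVe[..., : self.n_v, :].sum(axis=1) + dVe[..., self.n_v: 2 * self.n_v, :].sum(axis=0)
        # gradients w.r.t. edge geometry are not needed (coordinates are inputs)
        self._cache = None
        return ds, dV


class DenoiserGVP:
    """The noise-prediction network phi.

    Given a (noised) point-cloud embedding and the step index t it predicts,
    for every masked atom, the coordinate noise ``eps_r`` (a 3-vector that
    rotates with the input) and the atom-type noise ``eps_h`` (an m-vector
    invariant under rotation).
    """

    def __init__(self, config: Config = DEFAULTS, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        m = len(HEAVY_ELEMENTS)
        self.m = m
        ds0 = m + config.l_max + HC_DIM + config.time_channels + 1
        ns, nv = config.scalar_width, config.vector_channels
        self.embed_s = _Linear("embed_s", ds0, ns, rng)
        self.embed_v = _Linear("embed_v", 1, nv, rng, bias=False)
        self.layers = [
            _MessageLayer(i, ns, nv, config.rbf_size, rng)
            for i in range(config.n_layers)
        ]
        self.out_s = _Linear("out_s", ns, m, rng)
        self.out_v = _Linear("out_v", nv, 1, rng, bias=False)
        self._mods = [self.embed_s, self.embed_v]
        for lay in self.layers:
            self._mods.extend(lay.modules())
        self._mods += [self.out_s, self.out_v]

    # --- parameter plumbing -------------------------------------------------

    def named_params(self):
        for mod in self._mods:
            for k, v in mod.params.items():
                yield f"{mod.name}.{k}", mod.params, mod.grads, k

    def get_params(self) -> dict[str, np.ndarray]:
        return {name: p[k].copy() for name, p, _, k in self.named_params()}

    def set_params(self, values: dict[str, np.ndarray]) -> None:
        for name, p, _, k in self.named_params():
            p[k][...] = values[name]

    def zero_grad(self):
        for _, _, g, k in self.named_params():
            g[k][...] = 0.0

    def get_grads(self) -> dict[str, np.ndarray]:
        return {name: g[k].copy() for name, _, g, k in self.named_params()}

    def scale_params(self, factor: float) -> None:
        for _, p, _, k in self.named_params():
            p[k] *= factor

    # --- forward ------------------------------------------------------------

    def time_encoding(self, t: int, T: int) -> np.ndarray:
        tc = self.config.time_channels
        tau = t / max(T, 1)
        ks = 2.0 ** np.arange(tc // 2)
        return np.concatenate([np.sin(np.pi * ks * tau), np.cos(np.pi * ks * tau)])

    def featurize(self, emb: PointCloudEmbedding, t: int, T: Optional[int] = None) -> GVPFeatures:
        """Initial features: invariant scalars = scaled h_a + h_Lc + sinusoidal
        step encoding + masked flag; equivariant vectors = the (scaled)
        displacement of each atom from the metal-centred origin."""
        cfg = self.config
        T = T if T is not None else cfg.steps
        N = emb.n_atoms
        tenc = np.broadcast_to(self.time_encoding(t, T), (N, cfg.time_channels))
        s0 = np.concatenate(
            [
                emb.h_a * cfg.scale_ha,
                emb.h_lc * cfg.scale_hlc,
                tenc,
                emb.masked_flags[:, None].astype(np.float64),
            ],
            axis=1,
        )
        V0 = (emb.r * cfg.scale_r)[:, None, :]
        return GVPFeatures(s=s0, V=V0)

    def _edge_geometry(self, r: np.ndarray):
        cfg = self.config
        d = (r[None, :, :] - r[:, None, :]) * cfg.scale_r
        dist = np.sqrt(np.sum(d**2, axis=-1) + _EPS_DIST)
        mu = np.linspace(0.0, cfg.rbf_max * cfg.scale_r, cfg.rbf_size)
        width = mu[1] - mu[0]
        rbf = np.exp(-((dist[..., None] - mu) ** 2) / (2 * width**2))
        unit = d / dist[..., None]
        return rbf, unit[:, :, None, :]

    def message_pass(
        self,
        features: GVPFeatures,
        coordinates: np.ndarray,
        n_layers: Optional[int] = None,
        _embed: bool = True,
    ) -> GVPFeatures:
        """Run the GVP message-passing trunk over the complete graph."""
        if coordinates.shape[0] < 2:
            raise ValueError("message passing needs at least two atoms (no neighbours)")
        n_layers = len(self.layers) if n_layers is None else n_layers
        if n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        edge_s, edge_v = self._edge_geometry(coordinates)
        if _embed:
            s = self.embed_s.forward(features.s)
            V = self.embed_v.forward(
                np.swapaxes(features.V, -1, -2)
            )
            V = np.swapaxes(V, -1, -2)
        else:
            s, V = features.s, features.V
        for lay in self.layers[:n_layers]:
            s, V = lay.forward(s, V, edge_s, edge_v)
        return GVPFeatures(s=s, V=V)

    def predict_noise(
        self, emb: PointCloudEmbedding, t: int, T: Optional[int] = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Predicted (eps_r, eps_h) for the masked atoms: shapes (k, 3), (k, m)."""
        masked = emb.masked_indices
        if masked.size == 0:
            raise ValueError("no masked atoms to predict noise for")
        feats = self.featurize(emb, t, T)
        out = self.message_pass(feats, emb.r)
        eps_h_all = self.out_s.forward(out.s)
        v_t = np.swapaxes(out.V, -1, -2)              # (N, 3, n_v)
        eps_r_all = self.out_v.forward(v_t)[..., 0]   # (N, 3)
        self._last_n_layers = len(self.layers)
        return eps_r_all[masked], eps_h_all[masked]

    # --- training -----------------------------------------------------------

    def loss_and_grad(
        self,
        emb: PointCloudEmbedding,
        t: int,
        target_r: np.ndarray,
        target_h: np.ndarray,
        T: Optional[int] = None,
        accumulate: bool = False,
    ) -> float:
        """MSE between predicted and injected noise over masked atoms' r and
        h_a channels; accumulates parameter gradients."""
        if not accumulate:
            self.zero_grad()
        masked = emb.masked_indices
        eps_r, eps_h = self.predict_noise(emb, t, T)
        k = masked.size
        n_terms = k * (3 + self.m)
        dr = eps_r - target_r
        dh = eps_h - target_h
        loss = (np.sum(dr**2) + np.sum(dh**2)) / n_terms
        # backward
        N = emb.n_atoms
        d_eps_r_all = np.zeros((N, 3))
        d_eps_h_all = np.zeros((N, self.m))
        d_eps_r_all[masked] = 2.0 * dr / n_terms
        d_eps_h_all[masked] = 2.0 * dh / n_terms
        dV = self.out_v.backward(d_eps_r_all[..., None])   # (N, 3, n_v)
        dV = np.swapaxes(dV, -1, -2)                        # (N, n_v, 3)
        ds = self.out_s.backward(d_eps_h_all)
        for lay in reversed(self.layers):
            ds, dV = lay.backward(ds, dV)
        dV0 = self.embed_v.backward(np.swapaxes(dV, -1, -2))
        self.embed_s.backward(ds)
        return float(loss)

    # --- checkpointing ------------------------------------------------------

    def save(self, path: str | Path, schedule_meta: Optional[dict] = None) -> None:
        """Self-describing container: parameters + hyperparameters + vocabulary."""
        meta = {
            "config": self.config.to_dict(),
            "elements": list(HEAVY_ELEMENTS),
            "schedule": schedule_meta or {},
        }
        arrays = self.get_params()
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DenoiserGVP":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        model = cls(Config(**meta["config"]), seed=0)
        model.set_params({k: data[k] for k in data.files if k != "__meta__"})
        return model
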